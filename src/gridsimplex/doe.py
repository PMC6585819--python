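"""Quartic stepwise-regression DoE baseline and its success metrics.

The comparison methodology fits, per response, a polynomial with terms
up to total degree four by classical stepwise regression (partial-F
p-to-enter 0.05, p-to-remove 0.10, no hierarchy enforced), starting from
several postulated initial structures and keeping the lowest-RMSE model.
Predicted responses are pushed through the desirability transform and,
per weight set, compared against the measured desirabilities with two
metrics: the Pearson correlation r between measured and predicted
desirability tables, and the Euclidean distance lambda between measured
and predicted optima in coded units.  Success rates are reported under a
lenient profile (r >= 0.6, lambda <= 2.0) and a stringent one
(r >= 0.95, lambda <= 1.0).
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .desirability import (
    DesirabilityTable,
    WeightVector,
    desirability_table,
    individual_desirability,
    total_desirability,
)
from .grid import Condition, GridSpace, MeasurementTable, ResponseDef
from .weights import WeightGrid, enumerate_weight_sets

#: (r_min, lambda_max) acceptance profiles
PROFILES: dict[str, tuple[float, float]] = {
    "lenient": (0.60, 2.0),
    "stringent": (0.95, 1.0),
}

_SSE_TINY = 1e-12


def quartic_term_pool(n_factors: int, max_degree: int = 4) -> list[tuple[int, ...]]:
    """All monomial exponent tuples with total degree <= ``max_degree``.

    Ordered by total degree, then lexicographically; the intercept
    (all-zero tuple) comes first.  For 3 factors and degree 4 there are
    C(7,4) = 35 terms.
    """
    if n_factors < 1:
        raise ValueError("need at least one factor")
    pool = [
        exps
        for exps in itertools.product(range(max_degree + 1), repeat=n_factors)
        if sum(exps) <= max_degree
    ]
    pool.sort(key=lambda e: (sum(e), e))
    return pool


@dataclass(frozen=True)
class QuarticModel:
    """A fitted polynomial model over centered coded factors."""

    terms: tuple[tuple[int, ...], ...]  # includes the intercept tuple
    coef: tuple[float, ...]
    center: tuple[float, ...]  # per-factor centering offsets (coded units)
    rmse: float

    def __post_init__(self) -> None:
        if self.terms[0] != (0,) * len(self.center):
            raise ValueError("first term must be the intercept")
        if len(set(self.terms)) != len(self.terms):
            raise ValueError("duplicate terms")
        if len(self.coef) != len(self.terms):
            raise ValueError("coefficient count does not match terms")

    @property
    def n_terms(self) -> int:
        return len(self.terms)

    def design(self, conditions: Sequence[Condition]) -> np.ndarray:
        X = np.asarray(conditions, dtype=float) - np.asarray(self.center)
        return _design_matrix(X, self.terms)

    def predict(self, conditions: Sequence[Condition]) -> np.ndarray:
        return self.design(conditions) @ np.asarray(self.coef)


def _design_matrix(Xc: np.ndarray, terms: Sequence[tuple[int, ...]]) -> np.ndarray:
    cols = [np.prod(Xc**np.asarray(exps), axis=1) for exps in terms]
    return np.column_stack(cols)


def _fit_sse(A: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float, int]:
    """Least squares fit returning (coef, SSE, rank)."""
    coef, _, rank, _ = np.linalg.lstsq(A, y, rcond=None)
    resid = y - A @ coef
    return coef, float(resid @ resid), int(rank)


def _partial_f_pvalue(
    sse_reduced: float, sse_full: float, df_full: int
) -> float:
    """p-value of the partial F test for one added term.

    ``df_full`` is the residual degrees of freedom of the larger model.
    With an (essentially) exact fit the test degenerates: the p-value is
    0 when the term removes residual error and 1 when it cannot.
    """
    gain = sse_reduced - sse_full
    if df_full < 1:
        return 1.0
    if sse_full < _SSE_TINY:
        return 0.0 if gain > _SSE_TINY else 1.0
    F = gain / (sse_full / df_full)
    if F <= 0:
        return 1.0
    return float(stats.f.sf(F, 1, df_full))


def stepwise_fit(
    conditions: Sequence[Condition],
    y: Sequence[float],
    *,
    p_enter: float = 0.05,
    p_remove: float = 0.10,
    initial: Sequence[tuple[int, ...]] | None = None,
    max_degree: int = 4,
    max_steps: int = 200,
) -> QuarticModel:
    """Classical stepwise regression over the quartic term pool.

    Alternates forward steps (add the candidate with the smallest
    partial-F p-value, if below ``p_enter``) and backward steps (drop the
    included term with the largest p-value, if above ``p_remove``) until
    neither applies.  No model hierarchy is maintained.  Factors are
    centered (coded integers minus their mean) before monomials are
    built, which tames collinearity among high powers without changing
    predictions.

    Candidate terms whose column is linearly dependent on the current
    design, or that would leave no residual degrees of freedom, are
    skipped with a warning.
    """
    conds = [tuple(c) for c in conditions]
    yv = np.asarray(y, dtype=float)
    if len(conds) != yv.size:
        raise ValueError("conditions and y must align")
    n_factors = len(conds[0])
    n = yv.size

    center = tuple(float(m) for m in np.mean(np.asarray(conds, dtype=float), axis=0))
    Xc = np.asarray(conds, dtype=float) - np.asarray(center)
    pool = quartic_term_pool(n_factors, max_degree)
    intercept = (0,) * n_factors
    columns = {t: np.prod(Xc**np.asarray(t), axis=1) for t in pool}

    model: list[tuple[int, ...]] = [intercept]
    if initial is not None:
        for t in initial:
            t = tuple(t)
            if t == intercept or t in model:
                continue
            if t not in columns:
                raise ValueError(f"initial term {t} outside the degree-{max_degree} pool")
            trial = model + [t]
            A = np.column_stack([columns[tt] for tt in trial])
            if np.linalg.matrix_rank(A) < len(trial) or n - len(trial) < 1:
                warnings.warn(
                    f"initial term {t} dropped: rank-deficient or no residual df"
                )
                continue
            model = trial

    def sse_of(terms: Sequence[tuple[int, ...]]) -> float:
        A = np.column_stack([columns[t] for t in terms])
        return _fit_sse(A, yv)[1]

    for _ in range(max_steps):
        changed = False
        sse_cur = sse_of(model)
        A_cur = np.column_stack([columns[t] for t in model])
        rank_cur = np.linalg.matrix_rank(A_cur)

        # forward: best candidate below p_enter
        best_t, best_p, best_sse = None, None, None
        for t in pool:
            if t in model:
                continue
            trial = model + [t]
            if n - len(trial) < 1:
                continue
            A = np.column_stack([columns[tt] for tt in trial])
            if np.linalg.matrix_rank(A) <= rank_cur:
                warnings.warn(f"candidate term {t} skipped: linearly dependent column")
                continue
            sse_t = _fit_sse(A, yv)[1]
            p = _partial_f_pvalue(sse_cur, sse_t, n - len(trial))
            if p < p_enter and (best_p is None or p < best_p):
                best_t, best_p, best_sse = t, p, sse_t
        if best_t is not None:
            model.append(best_t)
            sse_cur = best_sse
            changed = True

        # backward: worst included term above p_remove
        while len(model) > 1:
            worst_t, worst_p = None, None
            for t in model[1:]:
                reduced = [tt for tt in model if tt != t]
                sse_r = sse_of(reduced)
                p = _partial_f_pvalue(sse_r, sse_cur, n - len(model))
                if worst_p is None or p > worst_p:
                    worst_t, worst_p = t, p
            if worst_p is not None and worst_p > p_remove:
                model.remove(worst_t)
                sse_cur = sse_of(model)
                changed = True
            else:
                break

        if not changed:
            break

    A = np.column_stack([columns[t] for t in model])
    coef, sse, _ = _fit_sse(A, yv)
    rmse = math.sqrt(sse / n)
    return QuarticModel(
        terms=tuple(model), coef=tuple(float(c) for c in coef), center=center, rmse=rmse
    )


def select_model(candidates: Sequence[QuarticModel]) -> QuarticModel:
    """Lowest-RMSE model; ties go to fewer terms, then first-listed."""
    if not candidates:
        raise ValueError("no candidate models")
    return min(
        enumerate(candidates), key=lambda iv: (iv[1].rmse, iv[1].n_terms, iv[0])
    )[1]


def default_initial_structures(n_factors: int) -> list[list[tuple[int, ...]]]:
    """Postulated starting structures for the multi-start stepwise.

    Intercept-only, full quadratic, and full quartic.
    """
    return [
        [],
        [t for t in quartic_term_pool(n_factors) if 0 < sum(t) <= 2],
        [t for t in quartic_term_pool(n_factors) if sum(t) > 0],
    ]


def fit_response(
    conditions: Sequence[Condition],
    y: Sequence[float],
    *,
    p_enter: float = 0.05,
    p_remove: float = 0.10,
) -> QuarticModel:
    """Multi-start stepwise fit of one response; keeps the lowest-RMSE model."""
    n_factors = len(tuple(conditions[0]))
    candidates = [
        stepwise_fit(
            conditions, y, p_enter=p_enter, p_remove=p_remove, initial=init
        )
        for init in default_initial_structures(n_factors)
    ]
    return select_model(candidates)


@dataclass(frozen=True)
class WeightSetAssessment:
    """Success metrics of the DoE baseline for one weight set."""

    weights: WeightVector
    r: float
    lam: float
    measured_argmax: Condition
    predicted_argmax: Condition
    passes: Mapping[str, bool]
    argmax_tied: bool = False


@dataclass(frozen=True)
class DoEAssessment:
    """Per-weight-set metrics and success rates under each profile."""

    per_set: tuple[WeightSetAssessment, ...]
    success_rates: Mapping[str, float]

    @property
    def n_sets(self) -> int:
        return len(self.per_set)


def _argmax_with_tie_flag(table: DesirabilityTable) -> tuple[Condition, bool]:
    conds, vals = table.as_vectors()
    best = float(vals.max())
    winners = [c for c, v in zip(conds, vals) if v == best]
    return winners[0], len(winners) > 1


def assess_doe(
    measured: Sequence[DesirabilityTable],
    predicted: Sequence[DesirabilityTable],
    grid: GridSpace,
    *,
    profiles: Mapping[str, tuple[float, float]] = PROFILES,
) -> DoEAssessment:
    """Compare predicted against measured desirability tables per weight set.

    For each weight set i: r_i is the Pearson correlation between the
    measured and predicted desirability vectors over all conditions, and
    lambda_i the Euclidean distance in coded integer space between the
    measured and predicted argmax conditions (ties resolved
    lexicographically and flagged).  A set passes a profile when
    r_i >= r_min and lambda_i <= lambda_max; the success rate is the
    passing fraction over all sets.
    """
    if len(measured) != len(predicted):
        raise ValueError("measured and predicted table lists differ in length")
    records: list[WeightSetAssessment] = []
    for m, p in zip(measured, predicted):
        if tuple(m.weights.w) != tuple(p.weights.w):
            raise ValueError("weight-set order mismatch between tables")
        if set(m.values) != set(grid.conditions) or set(p.values) != set(grid.conditions):
            raise ValueError("tables must cover all grid conditions")
        conds = sorted(m.values)
        mv = np.asarray([m.values[c] for c in conds])
        pv = np.asarray([p.values[c] for c in conds])
        if np.ptp(mv) == 0 or np.ptp(pv) == 0:
            raise ValueError(
                f"constant desirability table for weights {m.weights.w}: r undefined"
            )
        r = float(stats.pearsonr(mv, pv).statistic)
        m_arg, m_tie = _argmax_with_tie_flag(m)
        p_arg, p_tie = _argmax_with_tie_flag(p)
        lam = float(
            np.linalg.norm(np.asarray(m_arg, float) - np.asarray(p_arg, float))
        )
        passes = {
            name: bool(r >= r_min and lam <= lam_max)
            for name, (r_min, lam_max) in profiles.items()
        }
        records.append(
            WeightSetAssessment(
                weights=m.weights,
                r=r,
                lam=lam,
                measured_argmax=m_arg,
                predicted_argmax=p_arg,
                passes=passes,
                argmax_tied=m_tie or p_tie,
            )
        )
    rates = {
        name: sum(rec.passes[name] for rec in records) / len(records)
        for name in profiles
    }
    return DoEAssessment(per_set=tuple(records), success_rates=rates)


def predicted_desirability_tables(
    models: Sequence[QuarticModel],
    grid: GridSpace,
    defs: Sequence[ResponseDef],
    wgrid: WeightGrid,
) -> list[DesirabilityTable]:
    """Desirability tables of model-predicted responses, one per weight set."""
    conds = grid.conditions
    preds = np.column_stack([m.predict(conds) for m in models])
    tables = []
    for wvec in enumerate_weight_sets(wgrid):
        values = {}
        for cond, row in zip(conds, preds):
            d = [
                individual_desirability(yk, rdef, wk)
                for yk, rdef, wk in zip(row, defs, wvec)
            ]
            values[cond] = total_desirability(d)
        tables.append(DesirabilityTable(weights=wvec, values=values))
    return tables


def doe_baseline_assessment(
    grid: GridSpace,
    table: MeasurementTable,
    defs: Sequence[ResponseDef],
    wgrid: WeightGrid,
    *,
    p_enter: float = 0.05,
    p_remove: float = 0.10,
    average: str = "desirability",
) -> tuple[DoEAssessment, list[QuarticModel]]:
    """Full DoE-baseline pipeline on a measurement table.

    Models are fitted on individual replicate rows of the raw data with
    missing wells excluded (never on surrogates); measured desirability
    tables use the surrogate-imputed data, as the search does.
    """
    from .grid import impute_missing

    models = []
    for k, rdef in enumerate(defs):
        rows_c: list[Condition] = []
        rows_y: list[float] = []
        for cond in sorted(table.entries):
            if (cond, rdef.name) in table.missing:
                continue
            for rep in table.entries[cond]:
                if not math.isnan(rep[k]):
                    rows_c.append(cond)
                    rows_y.append(rep[k])
        models.append(
            fit_response(rows_c, rows_y, p_enter=p_enter, p_remove=p_remove)
        )

    imputed = impute_missing(table, defs)
    measured = [
        desirability_table(imputed, defs, wvec, average=average)
        for wvec in enumerate_weight_sets(wgrid)
    ]
    predicted = predicted_desirability_tables(models, grid, defs, wgrid)
    return assess_doe(measured, predicted, grid), models
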