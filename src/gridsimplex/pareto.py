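"""Pareto dominance on grid conditions and correlation utilities.

A grid condition belongs to the Pareto set when no other condition is at
least as good in every response and strictly better in one, with "good"
oriented by each response's goal.  Desirability optima provably lie on
the Pareto front, so front membership is the sanity check applied to
every search terminus.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .grid import Condition


@dataclass(frozen=True)
class ParetoSet:
    """Nondominated coded conditions."""

    members: frozenset[Condition]

    def __contains__(self, cond: object) -> bool:
        return cond in self.members

    def __len__(self) -> int:
        return len(self.members)


def _orient(vecs: np.ndarray, goals: Sequence[str]) -> np.ndarray:
    """Flip minimized responses so larger is uniformly better."""
    if vecs.shape[1] != len(goals):
        raise ValueError("goal count does not match response count")
    signs = np.asarray([1.0 if g == "maximize" else -1.0 for g in goals])
    return vecs * signs


def dominates(a: Sequence[float], b: Sequence[float], goals: Sequence[str]) -> bool:
    """True iff a is at least as good as b everywhere and strictly better once."""
    av, bv = np.asarray(a, dtype=float), np.asarray(b, dtype=float)
    if av.shape != bv.shape:
        raise ValueError(f"length mismatch: {av.shape} vs {bv.shape}")
    ao = _orient(av[None, :], goals)[0]
    bo = _orient(bv[None, :], goals)[0]
    return bool(np.all(ao >= bo) and np.any(ao > bo))


def pareto_front(
    mean_responses: Mapping[Condition, Sequence[float]],
    goals: Sequence[str],
    *,
    exclude: Iterable[Condition] = (),
) -> ParetoSet:
    """Nondominated subset of grid conditions.

    ``exclude`` removes conditions (typically those carrying surrogate
    imputations, whose values are fabricated rather than measured) from
    consideration.  Conditions with identical response vectors are kept
    together: weak duplicates do not eliminate each other.
    """
    excluded = set(exclude)
    conds = [c for c in sorted(mean_responses) if c not in excluded]
    if not conds:
        return ParetoSet(members=frozenset())
    M = _orient(
        np.asarray([mean_responses[c] for c in conds], dtype=float), goals
    )
    # pairwise dominance, vectorized: dom[j, i] = condition j dominates i
    ge = (M[:, None, :] >= M[None, :, :]).all(axis=2)
    gt = (M[:, None, :] > M[None, :, :]).any(axis=2)
    dominated = (ge & gt).any(axis=0)
    return ParetoSet(
        members=frozenset(c for c, d in zip(conds, dominated) if not d)
    )


def spearman_rho(
    x: Sequence[float], y: Sequence[float], *, method: str = "t"
) -> tuple[float, float]:
    """Spearman rank correlation with a large-sample p-value.

    The p-value uses the t-approximation with n-2 degrees of freedom
    (adequate at the ~48-condition scale of coarse screening grids);
    ``method="permutation"`` runs an exact/randomized permutation test
    instead.
    """
    xa, ya = np.asarray(x, dtype=float), np.asarray(y, dtype=float)
    if xa.size != ya.size:
        raise ValueError("x and y must have equal length")
    if xa.size < 4:
        raise ValueError("need at least 4 observations")
    if np.ptp(xa) == 0 or np.ptp(ya) == 0:
        raise ValueError("constant input: rank correlation undefined")
    if method == "permutation":
        res = stats.permutation_test(
            (xa,),
            lambda perm: stats.spearmanr(perm, ya).statistic,
            permutation_type="pairings",
            n_resamples=9999,
            rng=0,
        )
        rho = float(stats.spearmanr(xa, ya).statistic)
        return rho, float(res.pvalue)
    rho, p = stats.spearmanr(xa, ya)
    return float(rho), float(p)


def pearson_r(x: Sequence[float], y: Sequence[float]) -> float:
    """Product-moment correlation coefficient in [-1, 1]."""
    xa, ya = np.asarray(x, dtype=float), np.asarray(y, dtype=float)
    if xa.size != ya.size:
        raise ValueError("x and y must have equal length")
    if xa.size < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(xa) == 0 or np.ptp(ya) == 0:
        raise ValueError("constant input: correlation undefined")
    return float(stats.pearsonr(xa, ya).statistic)
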