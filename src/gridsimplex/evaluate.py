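"""Many-start convergence studies, efficiency curves, and D_T distributions.

Reproduces the evaluation protocol used to benchmark the lattice simplex
search: deploy the method from many random starting points on the
expanded space XW, classify each terminus (converged to xw*, near-
optimal Pareto member within 1% of the optimum, or fail), track the
improvement of the objective as a function of the experimental budget
(unique conditions in X), and characterize the landscape by the
distribution of D_T normalized to its maximum.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .pareto import ParetoSet
from .simplex import SearchOptions, SearchResult, classify_outcome, run_search
from .weights import ExpandedSpace, global_scalar_optimum

Point = tuple[int, ...]

OUTCOME_CLASSES = ("converged", "near_optimal", "fail")


@dataclass(frozen=True)
class EvaluationReport:
    """Outcome of a many-start convergence study."""

    n_starts: int
    seed: int
    xw_star: Point
    xw_value: float
    starts: tuple[Point, ...]
    results: tuple[SearchResult, ...]
    outcomes: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.results) != self.n_starts or len(self.outcomes) != self.n_starts:
            raise ValueError("results/outcomes must cover every start")

    @property
    def counts(self) -> dict[str, int]:
        return {c: sum(o == c for o in self.outcomes) for c in OUTCOME_CLASSES}

    @property
    def rates_percent(self) -> dict[str, float]:
        return {c: 100.0 * n / self.n_starts for c, n in self.counts.items()}

    def evaluations_summary(self) -> dict[str, float]:
        """Mean and sd of unique experimental conditions per search."""
        n = np.asarray([r.n_unique_x for r in self.results], dtype=float)
        return {"mean": float(n.mean()), "sd": float(n.std(ddof=1))}


def sample_starts(
    space: ExpandedSpace, n_starts: int, seed: int
) -> list[Point]:
    """Random starting points, without replacement when they fit the lattice."""
    if n_starts < 1:
        raise ValueError("need at least one start")
    points = space.points
    rng = np.random.default_rng(seed)
    if n_starts <= len(points):
        idx = rng.choice(len(points), size=n_starts, replace=False)
    else:
        idx = rng.choice(len(points), size=n_starts, replace=True)
    return [points[int(i)] for i in idx]


def convergence_study(
    space: ExpandedSpace,
    front: ParetoSet,
    *,
    n_starts: int = 300,
    seed: int = 0,
    options: SearchOptions | None = None,
    tol: float = 0.01,
) -> EvaluationReport:
    """Deploy the simplex search from many random starts and classify termini.

    ``front`` is the Pareto set computed on the replicate-mean responses
    over X; a terminus off xw* counts as near-optimal only if its
    experimental-condition projection belongs to the front and its D_T
    is within ``tol`` of the optimum.
    """
    xw_star, xw_value = global_scalar_optimum(space)
    bounds = space.bounds()
    starts = sample_starts(space, n_starts, seed)
    results = []
    outcomes = []
    for s in starts:
        res = run_search(s, space.objective, bounds, options, n_x=space.n_x)
        results.append(res)
        outcomes.append(
            classify_outcome(res, xw_star, xw_value, front, n_x=space.n_x, tol=tol)
        )
    return EvaluationReport(
        n_starts=n_starts,
        seed=seed,
        xw_star=xw_star,
        xw_value=xw_value,
        starts=tuple(starts),
        results=tuple(results),
        outcomes=tuple(outcomes),
    )


def best_at_budget(result: SearchResult, n_x: int, budget: int) -> float:
    """Best objective reached within a budget of unique X conditions.

    Walks the trajectory in evaluation order; the running best freezes
    once more than ``budget`` distinct experimental conditions have been
    touched.  Returns -inf if the very first condition already exceeds
    the budget (cannot happen for budget >= 1).
    """
    seen: set[tuple[int, ...]] = set()
    best = -np.inf
    for p, v in zip(result.trajectory, result.values):
        x = p[:n_x]
        if x not in seen:
            if len(seen) >= budget:
                break
            seen.add(x)
        best = max(best, v)
    return best


def efficiency_curves(
    results: Sequence[SearchResult],
    max_value: float,
    n_x: int,
    *,
    budgets: Sequence[int] | None = None,
    thresholds: Sequence[float] = (0.95, 0.99),
) -> pd.DataFrame:
    """Fraction of searches reaching a %max(D_T) level within each budget.

    Returns a tidy frame with columns ``budget``, ``threshold``, and
    ``fraction`` (of searches whose best-so-far within that many unique
    X conditions is at least threshold * max_value).  Fractions are
    non-decreasing in budget for a fixed threshold.
    """
    if max_value <= 0:
        raise ValueError("max_value must be positive")
    if budgets is None:
        top = max(r.n_unique_x for r in results)
        budgets = list(range(1, top + 1))
    rows = []
    for b in budgets:
        bests = np.asarray([best_at_budget(r, n_x, b) for r in results])
        for t in thresholds:
            rows.append(
                {
                    "budget": int(b),
                    "threshold": float(t),
                    "fraction": float(np.mean(bests >= t * max_value)),
                }
            )
    return pd.DataFrame(rows)


def normalized_dt_distribution(
    space: ExpandedSpace, *, bins: int = 20
) -> dict:
    """Distribution of D_T as a percentage of its maximum over XW.

    Returns the histogram (counts and bin edges on the 0-100% scale) and
    the fractions of XW points within 1% and 5% of the maximum — a
    direct measure of how sharply peaked the landscape is.
    """
    values = np.asarray(list(space.objective.values()), dtype=float)
    vmax = values.max()
    if vmax <= 0:
        raise ValueError("max(D_T) is 0: degenerate case study")
    pct = 100.0 * values / vmax
    counts, edges = np.histogram(pct, bins=bins, range=(0.0, 100.0))
    return {
        "counts": counts.tolist(),
        "edges": edges.tolist(),
        "frac_within_1pct": float(np.mean(pct >= 99.0)),
        "frac_within_5pct": float(np.mean(pct >= 95.0)),
        "n_points": int(values.size),
    }
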