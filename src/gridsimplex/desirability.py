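"""Derringer–Suich desirability transforms and replicate averaging.

Each response y_k is mapped to an individual desirability d_k in [0, 1]
through a one-sided power law whose exponent w_k (the weight) shapes the
curve: w = 1 linear, w < 1 concave up (lenient), w > 1 concave down
(demanding).  The total desirability D of a condition is the geometric
mean of the K individual desirabilities, so a single worthless response
annihilates D.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .grid import Condition, MeasurementTable, ResponseDef


@dataclass(frozen=True)
class WeightVector:
    """One positive weight exponent per response."""

    w: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.w) < 1:
            raise ValueError("weight vector must not be empty")
        if any(wk <= 0 for wk in self.w):
            raise ValueError(f"weights must be positive, got {self.w}")

    def __len__(self) -> int:
        return len(self.w)

    def __iter__(self):
        return iter(self.w)


def individual_desirability(y: float, rdef: ResponseDef, w: float) -> float:
    """Individual desirability d in [0, 1] of one response value.

    Maximization: 1 above the target T, 0 below the lower limit L, and
    ``((y-L)/(T-L))**w`` inside the band.  Minimization mirrors this with
    the upper limit U.  Band-edge equalities fall through to the power
    branch; the branches agree there, so this only fixes bit-level
    behavior.
    """
    if w <= 0:
        raise ValueError(f"weight must be positive, got {w}")
    if rdef.goal == "maximize":
        if y > rdef.T:
            return 1.0
        if y < rdef.L:
            return 0.0
        frac = (y - rdef.L) / (rdef.T - rdef.L)
    else:
        if y < rdef.T:
            return 1.0
        if y > rdef.U:
            return 0.0
        frac = (y - rdef.U) / (rdef.T - rdef.U)
    # 0**w -> 0 for all w > 0: continuous at the band edge.
    if frac <= 0.0:
        return 0.0
    return float(frac**w)


def total_desirability(d: Sequence[float]) -> float:
    """Geometric mean of K individual desirabilities.

    D = (prod d_k)^(1/K); D is 0 iff any d_k is 0, and always lies
    between min(d) and max(d).
    """
    arr = np.asarray(d, dtype=float)
    if arr.ndim != 1 or arr.size < 1:
        raise ValueError("need a 1-D vector of at least one desirability")
    if np.any((arr < 0) | (arr > 1)):
        raise ValueError(f"desirabilities must lie in [0, 1], got {list(arr)}")
    if np.any(arr == 0):
        return 0.0
    return float(np.exp(np.mean(np.log(arr))))


@dataclass(frozen=True)
class DesirabilityTable:
    """Replicate-averaged total desirability per condition, for one weight set."""

    weights: WeightVector
    values: Mapping[Condition, float]

    def __post_init__(self) -> None:
        for cond, v in self.values.items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"desirability at {cond} outside [0,1]: {v}")

    def as_vectors(self) -> tuple[list[Condition], np.ndarray]:
        conds = sorted(self.values)
        return conds, np.asarray([self.values[c] for c in conds], dtype=float)

    def argmax(self) -> tuple[Condition, float]:
        """Best condition; ties broken by lexicographically smallest tuple."""
        conds, vals = self.as_vectors()
        best = float(vals.max())
        for c, v in zip(conds, vals):
            if v == best:
                return c, best
        raise RuntimeError("unreachable")


def desirability_table(
    table: MeasurementTable,
    defs: Sequence[ResponseDef],
    weights: WeightVector,
    *,
    average: str = "desirability",
) -> DesirabilityTable:
    """Total desirability per condition, averaged over replicates.

    With ``average="desirability"`` (default) D is computed per replicate
    and the D values are arithmetically averaged; ``average="response"``
    first averages replicate responses and computes one D from the means.
    The table must already be imputed (no NaN left).

    Parameters
    ----------
    table:
        Imputed measurement table.
    defs:
        Response definitions, in the table's response order.
    weights:
        One positive exponent per response.
    """
    if len(defs) != table.K or len(weights) != table.K:
        raise ValueError("defs and weights must match the table's response count")
    if [d.name for d in defs] != list(table.response_names):
        raise ValueError("response definitions out of order with the table")
    if average not in ("desirability", "response"):
        raise ValueError(f"unknown averaging mode {average!r}")

    values: dict[Condition, float] = {}
    for cond in table.entries:
        reps = table.replicate_array(cond)
        if np.isnan(reps).any():
            raise ValueError(
                f"condition {cond} has unresolved missing values; impute first"
            )
        if average == "desirability":
            Ds = [
                total_desirability(
                    [
                        individual_desirability(y, rdef, wk)
                        for y, rdef, wk in zip(rep, defs, weights)
                    ]
                )
                for rep in reps
            ]
            values[cond] = float(np.mean(Ds))
        else:
            means = reps.mean(axis=0)
            values[cond] = total_desirability(
                [
                    individual_desirability(y, rdef, wk)
                    for y, rdef, wk in zip(means, defs, weights)
                ]
            )
    return DesirabilityTable(weights=weights, values=values)
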