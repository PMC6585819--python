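"""Coarse experimental grids with integer-coded factor levels.

High-throughput screening studies in early bioprocess development evaluate
a handful of levels per factor (pH, load density, conductivity, ...) on a
full-factorial lattice.  All downstream machinery in this package operates
on integer codes 1..L assigned to the sorted physical levels of each
factor, so that lattice geometry (simplex moves, Euclidean distances
between optima) is independent of the physical units.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

#: A point on the coded lattice: one integer code per factor.
Condition = tuple[int, ...]


@dataclass(frozen=True)
class Factor:
    """An experimental factor with ordered physical levels.

    Codes are the consecutive integers ``1..L`` assigned in ascending
    level order, so code order always reflects physical order.
    """

    name: str
    levels: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.levels) < 2:
            raise ValueError(
                f"factor {self.name!r} needs at least 2 levels, got {len(self.levels)}"
            )
        if any(b <= a for a, b in zip(self.levels, self.levels[1:])):
            raise ValueError(
                f"factor {self.name!r} levels must be strictly increasing: {self.levels}"
            )

    @property
    def n_levels(self) -> int:
        return len(self.levels)

    @property
    def codes(self) -> tuple[int, ...]:
        return tuple(range(1, len(self.levels) + 1))

    def level_of(self, code: int) -> float:
        """Physical value at an integer code (1-based)."""
        if not 1 <= code <= len(self.levels):
            raise ValueError(f"code {code} out of range 1..{len(self.levels)}")
        return self.levels[code - 1]

    def code_of(self, value: float, *, rtol: float = 1e-9) -> int:
        """Integer code of a physical level value."""
        for i, lv in enumerate(self.levels, start=1):
            if math.isclose(lv, value, rel_tol=rtol, abs_tol=1e-12):
                return i
        raise ValueError(f"{value!r} is not a level of factor {self.name!r}")


def code_levels(values: Sequence[float], name: str = "factor") -> Factor:
    """Build a :class:`Factor` by sorting physical values and coding them 1..L.

    Duplicate values are rejected: they would make the level -> code map
    ambiguous.
    """
    vals = sorted(float(v) for v in values)
    if len(vals) < 2:
        raise ValueError(f"factor {name!r}: fewer than 2 levels")
    for a, b in zip(vals, vals[1:]):
        if math.isclose(a, b, rel_tol=1e-12, abs_tol=1e-12):
            raise ValueError(f"factor {name!r}: duplicate level value {a}")
    return Factor(name=name, levels=tuple(vals))


@dataclass(frozen=True)
class GridSpace:
    """The full-factorial search lattice X over coded factor levels."""

    factors: tuple[Factor, ...]

    @property
    def dimension(self) -> int:
        return len(self.factors)

    @property
    def shape(self) -> tuple[int, ...]:
        return tuple(f.n_levels for f in self.factors)

    @property
    def n_conditions(self) -> int:
        return int(np.prod(self.shape))

    @property
    def conditions(self) -> list[Condition]:
        """All coded conditions in lexicographic order."""
        return list(itertools.product(*(f.codes for f in self.factors)))

    def bounds(self) -> list[tuple[int, int]]:
        """Per-dimension (low, high) code bounds, inclusive."""
        return [(1, f.n_levels) for f in self.factors]

    def physical(self, condition: Condition) -> tuple[float, ...]:
        """Physical factor values at a coded condition."""
        return tuple(f.level_of(c) for f, c in zip(self.factors, condition))

    def __contains__(self, condition: object) -> bool:
        try:
            cond = tuple(condition)  # type: ignore[arg-type]
        except TypeError:
            return False
        return len(cond) == self.dimension and all(
            1 <= c <= f.n_levels for c, f in zip(cond, self.factors)
        )


def build_grid(factors: Sequence[Factor]) -> GridSpace:
    """Assemble a :class:`GridSpace` from coded factors."""
    if len(factors) < 1:
        raise ValueError("need at least one factor")
    return GridSpace(factors=tuple(factors))


@dataclass(frozen=True)
class ResponseDef:
    """Optimization goal and admissible band for one response.

    For a maximized response the band is ``[L, T]`` (values above the
    target T are fully desirable, below the lower limit L worthless).
    For a minimized response the band is ``[T, U]``.
    """

    name: str
    goal: str  # "maximize" | "minimize"
    T: float
    L: float | None = None
    U: float | None = None
    units: str = ""

    def __post_init__(self) -> None:
        if self.goal not in ("maximize", "minimize"):
            raise ValueError(f"goal must be 'maximize' or 'minimize', got {self.goal!r}")
        if self.goal == "maximize":
            if self.L is None:
                raise ValueError(f"response {self.name!r}: maximize goal requires L")
            if not self.L < self.T:
                raise ValueError(
                    f"response {self.name!r}: need L < T, got L={self.L}, T={self.T}"
                )
        else:
            if self.U is None:
                raise ValueError(f"response {self.name!r}: minimize goal requires U")
            if not self.T < self.U:
                raise ValueError(
                    f"response {self.name!r}: need T < U, got T={self.T}, U={self.U}"
                )

    @property
    def band_width(self) -> float:
        return self.T - self.L if self.goal == "maximize" else self.U - self.T

    def surrogate_value(self) -> float:
        """A highly unfavorable value, one full band width outside the band.

        Its individual desirability is exactly 0 for every weight, so a
        search steers away from wells imputed with it.
        """
        if self.goal == "maximize":
            return self.L - self.band_width
        return self.U + self.band_width


def scale_response(y: float, rdef: ResponseDef) -> float:
    """Scale a response to a favorability fraction in [0, 1].

    This is the linear fraction inside the desirability power law
    (weight = 1): ``(y-L)/(T-L)`` for maximization, ``(y-U)/(T-U)`` for
    minimization, clamped to [0, 1].  1 is most favorable.
    """
    if rdef.goal == "maximize":
        frac = (y - rdef.L) / (rdef.T - rdef.L)
    else:
        frac = (y - rdef.U) / (rdef.T - rdef.U)
    return float(min(1.0, max(0.0, frac)))


@dataclass(frozen=True)
class MeasurementTable:
    """Replicate response measurements on a grid.

    ``entries`` maps each coded condition to a list of replicate
    K-vectors (one vector per replicate, ordered).  Missing wells are
    stored as NaN in the vectors and flagged in ``missing`` as
    ``(condition, response name)`` pairs; :func:`impute_missing` replaces
    the NaNs with unfavorable surrogates while retaining the flags for
    reporting.
    """

    grid: GridSpace
    response_names: tuple[str, ...]
    entries: Mapping[Condition, tuple[tuple[float, ...], ...]]
    missing: frozenset[tuple[Condition, str]] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        K = len(self.response_names)
        for cond, reps in self.entries.items():
            if cond not in self.grid:
                raise ValueError(f"condition {cond} outside the grid")
            if len(reps) < 1:
                raise ValueError(f"condition {cond} has no replicates")
            for r in reps:
                if len(r) != K:
                    raise ValueError(
                        f"condition {cond}: replicate has {len(r)} values, expected {K}"
                    )
        names = set(self.response_names)
        for cond, rname in self.missing:
            if rname not in names:
                raise ValueError(f"missing flag names unknown response {rname!r}")

    @property
    def K(self) -> int:
        return len(self.response_names)

    @property
    def conditions(self) -> list[Condition]:
        return sorted(self.entries)

    def replicate_array(self, condition: Condition) -> np.ndarray:
        """Replicates at a condition as an (n_rep, K) array."""
        return np.asarray(self.entries[condition], dtype=float)

    def has_unresolved_missing(self) -> bool:
        return any(
            np.isnan(self.replicate_array(c)).any() for c in self.entries
        )

    def mean_responses(self) -> dict[Condition, np.ndarray]:
        """Replicate-averaged K-vector per condition (NaN-ignoring mean)."""
        out: dict[Condition, np.ndarray] = {}
        for cond in self.entries:
            arr = self.replicate_array(cond)
            with np.errstate(invalid="ignore"):
                out[cond] = np.nanmean(arr, axis=0)
        return out

    def surrogate_conditions(self) -> frozenset[Condition]:
        """Conditions carrying at least one imputed (missing) response."""
        return frozenset(cond for cond, _ in self.missing)


def impute_missing(
    table: MeasurementTable, responses: Sequence[ResponseDef]
) -> MeasurementTable:
    """Replace missing wells with highly unfavorable surrogate values.

    Every flagged ``(condition, response)`` receives a value strictly
    outside the admissible band (below L for a maximized response, above
    U for a minimized one), so its individual desirability is 0 for any
    weight.  The missing flags are retained on the returned table.
    """
    by_name = {r.name: r for r in responses}
    for _, rname in table.missing:
        if rname not in by_name:
            raise ValueError(f"missing flag names response {rname!r} with no definition")
    if list(by_name) != list(table.response_names):
        missing_defs = set(table.response_names) - set(by_name)
        if missing_defs:
            raise ValueError(f"no definition for responses {sorted(missing_defs)}")

    if not table.missing and not table.has_unresolved_missing():
        return table

    surrogate = {
        k: by_name[name].surrogate_value()
        for k, name in enumerate(table.response_names)
    }
    new_entries: dict[Condition, tuple[tuple[float, ...], ...]] = {}
    for cond, reps in table.entries.items():
        fixed = []
        for rep in reps:
            fixed.append(
                tuple(
                    surrogate[k] if math.isnan(v) else v for k, v in enumerate(rep)
                )
            )
        new_entries[cond] = tuple(fixed)
    return replace(table, entries=new_entries)
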