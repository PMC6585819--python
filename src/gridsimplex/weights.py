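"""Weight-set enumeration and the expanded search lattice XW.

Rather than fixing the desirability weights a priori, the candidate
weight levels of each response are treated as extra lattice dimensions:
the experimental grid X is expanded to the joint space XW whose points
are (condition codes ++ weight codes) and whose objective D_T is the
union of the per-weight-set averaged desirability tables.  A single
search over XW then finds the operating condition and weight set with
the globally maximal desirability, xw*.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Mapping, Sequence

from .desirability import DesirabilityTable, WeightVector, desirability_table
from .grid import Condition, GridSpace, MeasurementTable, ResponseDef

#: A point of the expanded lattice: factor codes followed by weight codes.
Point = tuple[int, ...]

DEFAULT_WEIGHT_LEVELS: tuple[float, ...] = (0.5, 1.0, 2.0)


@dataclass(frozen=True)
class WeightGrid:
    """Candidate weight levels per response, coded 1..M like factor levels."""

    levels: tuple[tuple[float, ...], ...]

    def __post_init__(self) -> None:
        for i, lv in enumerate(self.levels):
            if len(lv) < 1:
                raise ValueError(f"response {i}: needs at least one weight level")
            if any(v <= 0 for v in lv):
                raise ValueError(f"response {i}: weight levels must be positive")
            if any(b <= a for a, b in zip(lv, lv[1:])):
                raise ValueError(f"response {i}: weight levels must be strictly increasing")

    @classmethod
    def default(cls, K: int = 3) -> "WeightGrid":
        """Three candidate weights (0.5, 1.0, 2.0) per response."""
        return cls(levels=(DEFAULT_WEIGHT_LEVELS,) * K)

    @property
    def K(self) -> int:
        return len(self.levels)

    @property
    def shape(self) -> tuple[int, ...]:
        return tuple(len(lv) for lv in self.levels)

    def weight_of(self, codes: Sequence[int]) -> WeightVector:
        """Weight vector at a tuple of weight codes (1-based)."""
        return WeightVector(
            w=tuple(self.levels[k][c - 1] for k, c in enumerate(codes))
        )


def enumerate_weight_sets(wgrid: WeightGrid) -> list[WeightVector]:
    """All weight vectors, lexicographic in coded order (index i = 1..I)."""
    return [
        WeightVector(w=combo) for combo in itertools.product(*wgrid.levels)
    ]


@dataclass(frozen=True)
class ExpandedSpace:
    """The joint lattice XW with the concatenated objective D_T."""

    base: GridSpace
    wgrid: WeightGrid
    objective: Mapping[Point, float]

    def __post_init__(self) -> None:
        expected = self.base.n_conditions
        for shp in self.wgrid.shape:
            expected *= shp
        if len(self.objective) != expected:
            raise ValueError(
                f"objective covers {len(self.objective)} points, expected {expected}"
            )
        for p, v in self.objective.items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"objective at {p} outside [0,1]: {v}")

    @property
    def n_x(self) -> int:
        return self.base.dimension

    @property
    def dimension(self) -> int:
        return self.base.dimension + self.wgrid.K

    @property
    def points(self) -> list[Point]:
        return sorted(self.objective)

    def bounds(self) -> list[tuple[int, int]]:
        return self.base.bounds() + [(1, m) for m in self.wgrid.shape]

    def x_part(self, point: Point) -> Condition:
        return tuple(point[: self.n_x])

    def w_part(self, point: Point) -> tuple[int, ...]:
        return tuple(point[self.n_x :])

    def weight_vector_at(self, point: Point) -> WeightVector:
        return self.wgrid.weight_of(self.w_part(point))


def expand_space(
    grid: GridSpace,
    table: MeasurementTable,
    defs: Sequence[ResponseDef],
    wgrid: WeightGrid,
    *,
    average: str = "desirability",
) -> ExpandedSpace:
    """Expand X to XW and populate the concatenated objective D_T.

    For every weight-code combination the replicate-averaged desirability
    table is computed and written onto the slice of XW sharing those
    weight codes, so the value at ``(x ++ wcodes)`` equals the averaged
    total desirability of condition x under that weight set.
    """
    if len(defs) != wgrid.K:
        raise ValueError("weight grid and response definitions disagree on K")
    if set(table.entries) != set(grid.conditions):
        raise ValueError("measurement table does not cover the grid exactly")

    objective: dict[Point, float] = {}
    for wcodes in itertools.product(*(range(1, m + 1) for m in wgrid.shape)):
        wvec = wgrid.weight_of(wcodes)
        dtab = desirability_table(table, defs, wvec, average=average)
        for cond, value in dtab.values.items():
            objective[tuple(cond) + tuple(wcodes)] = value
    return ExpandedSpace(base=grid, wgrid=wgrid, objective=objective)


def global_scalar_optimum(space: ExpandedSpace) -> tuple[Point, float]:
    """The point xw* maximizing D_T over XW, and its value.

    Ties are broken by the lexicographically smallest coded tuple so the
    result is deterministic.
    """
    if not space.objective:
        raise ValueError("empty expanded space")
    best_value = max(space.objective.values())
    best_point = min(p for p, v in space.objective.items() if v == best_value)
    return best_point, float(best_value)
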