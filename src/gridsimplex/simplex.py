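"""Grid-compatible sequential simplex search on an integer-coded lattice.

A Nelder–Mead-family direct search whose vertices are restricted to the
coded lattice of experimental levels.  Moves are reflection of the worst
vertex through the centroid of the others, inside contraction, and a
shrink toward the best vertex; every proposal is rounded half-away-from-
zero to the nearest lattice point and clamped to the bounds.  All
evaluations are cached, so revisiting a point costs nothing — mirroring
the experimental setting where a condition measured once need not be
rerun.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np

from .pareto import ParetoSet

Point = tuple[int, ...]
Bounds = Sequence[tuple[int, int]]


@dataclass(frozen=True)
class SearchOptions:
    """Tunables of the lattice simplex engine.

    ``stall_limit`` counts consecutive iterations in which no newly
    evaluated point improved on the worst vertex; ``use_contraction`` and
    ``use_shrink`` switch the fallback moves off for experimentation with
    a reflection-only policy.  ``poll_on_stall`` enables the convergence
    safeguard: when the simplex stalls or collapses, the axis neighbors
    of the best vertex are polled and the search restarts from an
    improving neighbor, so a search only terminates at a lattice-local
    optimum.
    """

    max_iterations: int = 200
    stall_limit: int = 3
    use_contraction: bool = True
    use_shrink: bool = True
    poll_on_stall: bool = True

    def __post_init__(self) -> None:
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")
        if self.stall_limit < 1:
            raise ValueError("stall_limit must be >= 1")


@dataclass
class SearchResult:
    """Outcome of one simplex search."""

    best_point: Point
    best_value: float
    trajectory: list[Point]  # unique evaluated points, in evaluation order
    values: list[float]  # objective at each trajectory point
    n_evaluations: int  # len(trajectory): unique points in the search lattice
    n_unique_x: int  # distinct experimental conditions touched (X projection)
    terminated_reason: str
    log: list[str] = field(default_factory=list)

    def best_so_far(self) -> np.ndarray:
        """Running maximum of the objective along the trajectory."""
        return np.maximum.accumulate(np.asarray(self.values, dtype=float))


def _round_lattice(vec: np.ndarray, bounds: Bounds) -> Point:
    """Round half away from zero per component, then clamp to bounds."""
    rounded = np.sign(vec) * np.floor(np.abs(vec) + 0.5)
    out = []
    for v, (lo, hi) in zip(rounded, bounds):
        out.append(int(min(hi, max(lo, v))))
    return tuple(out)


def initialize_simplex(start: Point, bounds: Bounds) -> list[Point]:
    """Axis-aligned initial simplex: the start plus one unit step per dimension.

    Steps that would leave the lattice flip to -1, so a valid simplex of
    n+1 distinct vertices exists from any start.  A dimension with a
    single level cannot host a simplex and is rejected.
    """
    n = len(bounds)
    if len(start) != n:
        raise ValueError("start point dimensionality does not match bounds")
    for j, (lo, hi) in enumerate(bounds):
        if hi <= lo:
            raise ValueError(f"dimension {j} has a single level; cannot form a simplex")
        if not lo <= start[j] <= hi:
            raise ValueError(f"start {start} outside bounds in dimension {j}")
    vertices = [tuple(start)]
    for j in range(n):
        step = 1 if start[j] + 1 <= bounds[j][1] else -1
        v = list(start)
        v[j] += step
        vertices.append(tuple(v))
    return vertices


def _worst_index(vertices: Sequence[Point], values: Sequence[float]) -> int:
    """Index of the worst vertex; value ties broken by lexicographic order."""
    return min(range(len(vertices)), key=lambda i: (values[i], vertices[i]))


def _best_index(vertices: Sequence[Point], values: Sequence[float]) -> int:
    return max(range(len(vertices)), key=lambda i: (values[i], tuple(-c for c in vertices[i])))


def propose_move(
    vertices: Sequence[Point],
    values: Sequence[float],
    bounds: Bounds,
) -> tuple[Point, str]:
    """Next candidate point for the current simplex.

    Reflection of the worst vertex through the centroid of the remaining
    vertices, rounded to the lattice; if the rounded reflection lands on
    a current vertex (or back on the rejected worst point) an inside
    contraction (midpoint of worst and centroid) is proposed instead; if
    that also duplicates, a shrink point toward the best vertex.  A
    shrink proposal is always legal, so the cascade cannot fail.
    """
    wi = _worst_index(vertices, values)
    bi = _best_index(vertices, values)
    worst = np.asarray(vertices[wi], dtype=float)
    others = [np.asarray(v, dtype=float) for i, v in enumerate(vertices) if i != wi]
    centroid = np.mean(others, axis=0)

    reflection = _round_lattice(2.0 * centroid - worst, bounds)
    if reflection not in vertices:
        return reflection, "reflection"
    contraction = _round_lattice((worst + centroid) / 2.0, bounds)
    if contraction not in vertices:
        return contraction, "contraction"
    shrink = _round_lattice((worst + np.asarray(vertices[bi], dtype=float)) / 2.0, bounds)
    return shrink, "shrink"


def run_search(
    start: Point,
    objective: Callable[[Point], float] | Mapping[Point, float],
    bounds: Bounds,
    options: SearchOptions | None = None,
    *,
    n_x: int | None = None,
) -> SearchResult:
    """Run one grid-compatible simplex search from a starting point.

    Each iteration proposes a reflection; if its value does not beat the
    current worst vertex an inside contraction is tried, and failing
    that all non-best vertices are shrunk halfway toward the best
    vertex.  The search stops when ``stall_limit`` consecutive
    iterations produce no newly evaluated point improving on the worst
    vertex, when the simplex collapses to one point, or at
    ``max_iterations``.

    Parameters
    ----------
    objective:
        Callable or mapping defined on every lattice point.
    n_x:
        Number of leading dimensions that are experimental conditions;
        ``n_unique_x`` counts distinct projections onto them.  Defaults
        to the full dimensionality.
    """
    opts = options or SearchOptions()
    fn = objective.__getitem__ if isinstance(objective, Mapping) else objective
    nx = len(bounds) if n_x is None else n_x

    cache: dict[Point, float] = {}
    trajectory: list[Point] = []
    values_log: list[float] = []
    log: list[str] = []

    def evaluate(p: Point) -> tuple[float, bool]:
        if p in cache:
            return cache[p], False
        v = float(fn(p))
        cache[p] = v
        trajectory.append(p)
        values_log.append(v)
        return v, True

    vertices = initialize_simplex(tuple(start), bounds)
    values = [evaluate(v)[0] for v in vertices]
    log.append(f"init vertices={vertices}")

    def poll_best() -> Point | None:
        """Evaluate axis neighbors of the best vertex; return the best improver."""
        bi = _best_index(vertices, values)
        base, base_val = vertices[bi], values[bi]
        best_nb, best_nb_val = None, base_val
        for j in range(len(bounds)):
            for step in (+1, -1):
                c = base[j] + step
                if not bounds[j][0] <= c <= bounds[j][1]:
                    continue
                nb = base[:j] + (c,) + base[j + 1 :]
                v, _ = evaluate(nb)
                if v > best_nb_val:
                    best_nb, best_nb_val = nb, v
        return best_nb

    reason = "max_iterations"
    stall = 0
    for it in range(opts.max_iterations):
        degenerate = len(set(vertices)) == 1
        if degenerate or stall >= opts.stall_limit:
            reason = "collapsed" if degenerate else "stalled"
            if not opts.poll_on_stall:
                break
            nb = poll_best()
            if nb is None:
                break
            log.append(f"iter={it} move=poll restart={nb}")
            vertices = initialize_simplex(nb, bounds)
            values = [evaluate(v)[0] for v in vertices]
            stall = 0
            reason = "max_iterations"
            continue

        wi = _worst_index(vertices, values)
        worst_val = values[wi]
        improved = False

        cand, label = propose_move(vertices, values, bounds)
        v, fresh = evaluate(cand)
        log.append(
            f"iter={it} move={label} point={cand} cached={not fresh} value={v:.6g}"
        )
        if v > worst_val and cand not in vertices:
            vertices[wi] = cand
            values[wi] = v
            improved = fresh
        else:
            if label == "reflection" and opts.use_contraction:
                wi = _worst_index(vertices, values)
                worst = np.asarray(vertices[wi], dtype=float)
                others = [
                    np.asarray(p, dtype=float)
                    for i, p in enumerate(vertices)
                    if i != wi
                ]
                centroid = np.mean(others, axis=0)
                cand2 = _round_lattice((worst + centroid) / 2.0, bounds)
                if cand2 not in vertices:
                    v2, fresh2 = evaluate(cand2)
                    log.append(
                        f"iter={it} move=contraction point={cand2} "
                        f"cached={not fresh2} value={v2:.6g}"
                    )
                    if v2 > worst_val:
                        vertices[wi] = cand2
                        values[wi] = v2
                        improved = improved or fresh2
            if not improved and opts.use_shrink:
                bi = _best_index(vertices, values)
                best_vtx = np.asarray(vertices[bi], dtype=float)
                for i in range(len(vertices)):
                    if i == bi:
                        continue
                    nv = _round_lattice(
                        (np.asarray(vertices[i], dtype=float) + best_vtx) / 2.0,
                        bounds,
                    )
                    if nv != vertices[i]:
                        sv, sfresh = evaluate(nv)
                        if sfresh and sv > worst_val:
                            improved = True
                        vertices[i] = nv
                        values[i] = sv
                log.append(f"iter={it} move=shrink vertices={vertices}")

        stall = 0 if improved else stall + 1
    else:
        reason = "max_iterations"

    # ties in the cached maximum go to the earliest-evaluated point
    best_value = max(cache.values())
    best_point = next(p for p in trajectory if cache[p] == best_value)
    return SearchResult(
        best_point=best_point,
        best_value=best_value,
        trajectory=trajectory,
        values=values_log,
        n_evaluations=len(trajectory),
        n_unique_x=len({p[:nx] for p in trajectory}),
        terminated_reason=reason,
        log=log,
    )


def classify_outcome(
    result: SearchResult,
    xw_star: Point,
    xw_value: float,
    front: ParetoSet,
    *,
    n_x: int,
    tol: float = 0.01,
) -> str:
    """Classify a search terminus as converged, near_optimal, or fail.

    Converged means the terminus is exactly xw*.  Near-optimal requires
    Pareto membership of the experimental-condition projection and a
    D_T value within ``tol`` (default 1%) of the value at xw*.
    """
    if not 0.0 < tol < 1.0:
        raise ValueError("tol must lie in (0, 1)")
    if tuple(result.best_point) == tuple(xw_star):
        return "converged"
    x_proj = tuple(result.best_point[:n_x])
    if x_proj in front.members and result.best_value >= (1.0 - tol) * xw_value:
        return "near_optimal"
    return "fail"
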