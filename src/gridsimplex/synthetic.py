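"""Synthetic flowthrough-chromatography case studies.

The generator emulates the shape of coarse high-throughput screening
grids: three factors (pH, load density, conductivity) on a 4 x 3 x 4
lattice, duplicated wells, three responses (%yield maximized; HCP ppm
and host-cell DNA ppb minimized) with nonlinear trends and a built-in
trade-off — conditions that raise the yield also degrade impurity
clearance, so favorability-scaled yield and impurity values are
negatively rank-correlated.  Replicate noise is additive Gaussian on the
yield (a percentage) and multiplicative lognormal on the impurity
contents (positive, right-skewed); a configurable fraction of impurity
wells is dropped to emulate assay failures.

The noiseless surfaces, Pareto set, per-weight-set optima and the global
scalar optimum are returned as ground truth so every downstream stage
can be checked for exact recovery in the noise-free limit.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .desirability import WeightVector
from .grid import (
    Condition,
    GridSpace,
    MeasurementTable,
    ResponseDef,
    build_grid,
    code_levels,
    scale_response,
)
from .pareto import ParetoSet, pareto_front, spearman_rho
from .weights import (
    ExpandedSpace,
    WeightGrid,
    expand_space,
    global_scalar_optimum,
)

RESPONSE_NAMES = ("Yield", "HCP", "DNA")
RESPONSE_GOALS = ("maximize", "minimize", "minimize")
RESPONSE_UNITS = ("%", "ppm", "ppb")


def _logistic(z: np.ndarray | float) -> np.ndarray | float:
    return 1.0 / (1.0 + np.exp(-np.asarray(z, dtype=float)))


@dataclass(frozen=True)
class SurfaceParams:
    """Coefficients of the noiseless response surfaces.

    All surfaces are logistic squashes of low-order polynomials in the
    normalized factor codes u = (code - 1) / (L - 1) in [0, 1] — smooth
    enough to be physically plausible, nonlinear enough that quadratic
    models underfit them.  Yield rises with conductivity and load (weak
    electrostatic binding of the product at high salt, displacement at
    high load); both impurity contents also rise with conductivity
    (clearance worsens as impurities stop binding), HCP with a weak load
    effect and DNA with a pH x conductivity interaction.
    """

    yield_coefs: tuple[float, ...] = (-1.2, 4.0, 1.5, -0.4)  # bias, cond, load, pH
    hcp_coefs: tuple[float, ...] = (-2.2, 4.5, 0.3, 0.4)  # bias, cond, load, pH
    dna_coefs: tuple[float, ...] = (-2.0, 1.5, -0.8, 1.0, 3.0)  # bias, cond, load, pH, pH*cond
    hcp_floor: float = 30.0  # ppm, assay detection limit
    hcp_span: float = 2970.0
    dna_floor: float = 50.0  # ppb
    dna_span: float = 2400.0


@dataclass(frozen=True)
class SyntheticCaseConfig:
    """Configuration of one synthetic case study.

    Defaults follow the 4 x 3 x 4 anion-exchange screening layout:
    pH 6.9-7.8, load 100-300 g/L, conductivity 2.5-10 mS/cm, 48 grid
    conditions run in duplicate.  Noise scales default to roughly 5%
    coefficient of variation; desirability targets default to the best
    noiseless value on the grid and the limits to the worst.
    """

    ph_levels: tuple[float, ...] = (6.9, 7.2, 7.5, 7.8)
    load_levels: tuple[float, ...] = (100.0, 150.0, 300.0)
    conductivity_levels: tuple[float, ...] = (2.5, 4.0, 6.0, 10.0)
    replicates: int = 2
    yield_noise_sd: float = 2.5  # additive, percentage points
    impurity_noise_cv: float = 0.05  # lognormal sigma on HCP and DNA
    missing_fraction: float = 0.05  # of (condition, impurity response) pairs
    surfaces: SurfaceParams = field(default_factory=SurfaceParams)

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise ValueError("need at least one replicate")
        if not 0.0 <= self.missing_fraction <= 0.2:
            raise ValueError("missing fraction must lie in [0, 0.2]")
        if self.yield_noise_sd < 0 or self.impurity_noise_cv < 0:
            raise ValueError("noise scales must be nonnegative")

    def grid(self) -> GridSpace:
        return build_grid(
            [
                code_levels(self.ph_levels, name="pH"),
                code_levels(self.load_levels, name="Load"),
                code_levels(self.conductivity_levels, name="Conductivity"),
            ]
        )


@dataclass(frozen=True)
class GroundTruth:
    """Noiseless surfaces and brute-force optima of a synthetic case."""

    surfaces: Mapping[Condition, tuple[float, float, float]]
    pareto: ParetoSet
    per_weight_argmax: Mapping[tuple[float, ...], Condition]
    xw_star: tuple[int, ...]
    xw_value: float


@dataclass(frozen=True)
class SyntheticCase:
    grid: GridSpace
    table: MeasurementTable
    defs: tuple[ResponseDef, ...]
    truth: GroundTruth
    config: SyntheticCaseConfig
    seed: int


def truth_surfaces(
    config: SyntheticCaseConfig,
) -> dict[Condition, tuple[float, float, float]]:
    """Noiseless (yield %, HCP ppm, DNA ppb) at every grid condition."""
    grid = config.grid()
    sp = config.surfaces
    out: dict[Condition, tuple[float, float, float]] = {}
    for cond in grid.conditions:
        u = np.array(
            [
                (c - 1) / (f.n_levels - 1)
                for c, f in zip(cond, grid.factors)
            ]
        )
        up, ul, uc = u  # pH, load, conductivity
        b = sp.yield_coefs
        y = 100.0 * _logistic(b[0] + b[1] * uc + b[2] * ul + b[3] * up)
        b = sp.hcp_coefs
        hcp = sp.hcp_floor + sp.hcp_span * _logistic(
            b[0] + b[1] * uc + b[2] * ul + b[3] * up
        )
        b = sp.dna_coefs
        dna = sp.dna_floor + sp.dna_span * _logistic(
            b[0] + b[1] * uc + b[2] * ul + b[3] * up + b[4] * up * uc
        )
        out[cond] = (float(y), float(hcp), float(dna))
    return out


def default_response_defs(
    config: SyntheticCaseConfig, *, margin: float = 0.0
) -> tuple[ResponseDef, ...]:
    """Targets at the best noiseless grid value, limits at the worst.

    ``margin`` widens the band by the given fraction of its width on the
    unfavorable side, which keeps every grid desirability strictly
    positive (useful when exercising the Pareto-membership property of
    desirability optima).
    """
    surf = np.asarray(list(truth_surfaces(config).values()))
    y_best, y_worst = surf[:, 0].max(), surf[:, 0].min()
    defs = []
    for k, (name, goal, units) in enumerate(
        zip(RESPONSE_NAMES, RESPONSE_GOALS, RESPONSE_UNITS)
    ):
        vals = surf[:, k]
        if goal == "maximize":
            width = vals.max() - vals.min()
            defs.append(
                ResponseDef(
                    name=name,
                    goal=goal,
                    T=float(vals.max()),
                    L=float(vals.min() - margin * width),
                    units=units,
                )
            )
        else:
            width = vals.max() - vals.min()
            defs.append(
                ResponseDef(
                    name=name,
                    goal=goal,
                    T=float(vals.min()),
                    U=float(vals.max() + margin * width),
                    units=units,
                )
            )
    return tuple(defs)


def ground_truth_optimum(
    config: SyntheticCaseConfig,
    wgrid: WeightGrid | None = None,
    defs: Sequence[ResponseDef] | None = None,
) -> GroundTruth:
    """Exhaustive evaluation of the noiseless surfaces through the full stack."""
    wgrid = wgrid or WeightGrid.default(K=3)
    defs = tuple(defs) if defs is not None else default_response_defs(config)
    grid = config.grid()
    surfaces = truth_surfaces(config)

    entries = {
        cond: (tuple(vals),) for cond, vals in surfaces.items()
    }
    table = MeasurementTable(
        grid=grid, response_names=RESPONSE_NAMES, entries=entries
    )
    space = expand_space(grid, table, defs, wgrid)
    xw_star, xw_value = global_scalar_optimum(space)

    front = pareto_front(surfaces, RESPONSE_GOALS)

    per_weight: dict[tuple[float, ...], Condition] = {}
    from .weights import enumerate_weight_sets
    from .desirability import desirability_table

    for wvec in enumerate_weight_sets(wgrid):
        dtab = desirability_table(table, defs, wvec)
        per_weight[tuple(wvec.w)] = dtab.argmax()[0]

    return GroundTruth(
        surfaces=surfaces,
        pareto=front,
        per_weight_argmax=per_weight,
        xw_star=xw_star,
        xw_value=xw_value,
    )


def generate_case(
    config: SyntheticCaseConfig | None = None, seed: int = 0
) -> SyntheticCase:
    """Generate one synthetic case study: noisy duplicated table + ground truth.

    Replicates are the noiseless surface plus seeded noise, truncated to
    physical ranges (yield in [0, 100]%, contents nonnegative).  Missing
    wells are sampled uniformly over (condition, impurity response)
    pairs and NaN-flagged in every replicate of the affected well; they
    carry the surrogate-imputation flags downstream.
    """
    config = config or SyntheticCaseConfig()
    rng = np.random.default_rng(seed)
    grid = config.grid()
    surfaces = truth_surfaces(config)
    defs = default_response_defs(config)

    conds = grid.conditions
    entries: dict[Condition, tuple[tuple[float, ...], ...]] = {}
    for cond in conds:
        y0, hcp0, dna0 = surfaces[cond]
        reps = []
        for _ in range(config.replicates):
            y = float(np.clip(y0 + rng.normal(0.0, config.yield_noise_sd), 0.0, 100.0))
            hcp = float(hcp0 * np.exp(rng.normal(0.0, config.impurity_noise_cv)))
            dna = float(dna0 * np.exp(rng.normal(0.0, config.impurity_noise_cv)))
            reps.append((y, hcp, dna))
        entries[cond] = tuple(reps)

    # drop impurity wells: NaN in every replicate of the chosen pairs
    impurity_names = [n for n, g in zip(RESPONSE_NAMES, RESPONSE_GOALS) if g == "minimize"]
    pairs = [(c, r) for c in conds for r in impurity_names]
    n_missing = int(round(config.missing_fraction * len(pairs)))
    missing: set[tuple[Condition, str]] = set()
    if n_missing > 0:
        picked = rng.choice(len(pairs), size=n_missing, replace=False)
        for idx in sorted(int(i) for i in picked):
            cond, rname = pairs[idx]
            missing.add((cond, rname))
            k = RESPONSE_NAMES.index(rname)
            entries[cond] = tuple(
                tuple(np.nan if j == k else v for j, v in enumerate(rep))
                for rep in entries[cond]
            )

    table = MeasurementTable(
        grid=grid,
        response_names=RESPONSE_NAMES,
        entries=entries,
        missing=frozenset(missing),
    )
    truth = ground_truth_optimum(config)
    return SyntheticCase(
        grid=grid, table=table, defs=defs, truth=truth, config=config, seed=seed
    )


def scaled_truth_correlations(
    config: SyntheticCaseConfig,
) -> dict[tuple[str, str], tuple[float, float]]:
    """Spearman rho (and p) between favorability-scaled noiseless responses.

    Scaling orients every response so 1 is most favorable; a negative
    rho between scaled yield and a scaled impurity therefore means the
    trade-off is real: conditions good for yield are bad for clearance.
    """
    surfaces = truth_surfaces(config)
    defs = default_response_defs(config)
    conds = sorted(surfaces)
    scaled = {
        name: [scale_response(surfaces[c][k], defs[k]) for c in conds]
        for k, name in enumerate(RESPONSE_NAMES)
    }
    out = {}
    for a, b in itertools.combinations(RESPONSE_NAMES, 2):
        out[(a, b)] = spearman_rho(scaled[a], scaled[b])
    return out
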