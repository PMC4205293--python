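"""Synthetic study inputs with known ground truth.

Generates the three inputs the pipeline needs so every downstream stage is
testable without external downloads:

* diploid microsatellite genotype datasets simulated under a chosen
  demographic scenario, with a configurable within-population inbreeding
  level applied when pairing gene copies into diploids;
* population coordinate tables;
* full factorial suitability-map stacks with planted variance components
  (for the hierarchical-ANOVA uncertainty partition) and a planted range
  dynamic (for the classification stage).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .coalescent import SCENARIO_NAMES, SimulationConfig, build_scenario, simulate_dataset
from .genotypes import GenotypeDataset
from .grids import DEFAULT_PERIODS, SuitabilityStack

#: Study sampling design: (population, diploid sample size); 414 diploids
#: over 20 populations.
STUDY_SAMPLE_SIZES: tuple[tuple[str, int], ...] = (
    ("AGE", 30), ("ARA", 12), ("BAG", 26), ("BAR", 15), ("BOD", 22),
    ("CAC", 30), ("CHG", 24), ("FAT", 35), ("GSV", 8), ("NIQ", 28),
    ("PAN", 23), ("PNE", 16), ("POT", 16), ("PTU", 32), ("SCA", 29),
    ("SDO", 3), ("SEC", 4), ("STZ", 17), ("SUM", 14), ("VIB", 30),
)

#: Approximate extent of the Brazilian savanna sampling region
#: (lon_min, lat_min, lon_max, lat_max).
DEFAULT_EXTENT = (-60.0, -25.0, -40.0, -5.0)


@dataclass(frozen=True)
class SyntheticStudySpec:
    """Design of a synthetic genotype study.

    ``inbreeding`` is the probability that an individual's two gene copies
    are identical by descent at sampling (applied per individual and
    locus); the default 0.21 mirrors the high selfing-induced inbreeding
    typical of mixed-mating savanna trees.
    """

    n_populations: int = 20
    sample_sizes: tuple[int, ...] = tuple(n for _, n in STUDY_SAMPLE_SIZES)
    n_loci: int = 11
    mutation_rate: float = 0.01
    generation_time: float = 12.0
    inbreeding: float = 0.21
    truth_scenario: str = "Expansion_6_0"
    seed: int = 0
    scenario_overrides: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.sample_sizes) != self.n_populations:
            raise ValueError("sample_sizes must have one entry per population")
        if any(s < 1 for s in self.sample_sizes):
            raise ValueError("sample sizes must be >= 1")
        if not (0.0 <= self.inbreeding <= 1.0):
            raise ValueError("inbreeding must lie in [0, 1]")
        if not (0.0 < self.mutation_rate < 1.0):
            raise ValueError("mutation_rate must lie in (0, 1)")
        if self.truth_scenario not in SCENARIO_NAMES:
            raise ValueError(
                f"unknown truth_scenario {self.truth_scenario!r}; choose from {SCENARIO_NAMES}"
            )


def gen_population_coords(
    n: int,
    extent: tuple[float, float, float, float] = DEFAULT_EXTENT,
    seed: int = 0,
) -> pd.DataFrame:
    """Random unique population coordinates inside a lon/lat box."""
    if n < 1:
        raise ValueError("n must be >= 1")
    lon_min, lat_min, lon_max, lat_max = map(float, extent)
    if not all(np.isfinite([lon_min, lat_min, lon_max, lat_max])):
        raise ValueError("extent must be finite")
    if lon_min >= lon_max or lat_min >= lat_max:
        raise ValueError("extent is degenerate")
    rng = np.random.default_rng(seed)
    lons = rng.uniform(lon_min, lon_max, size=n)
    lats = rng.uniform(lat_min, lat_max, size=n)
    names = [name for name, _ in STUDY_SAMPLE_SIZES[:n]] + [
        f"P{i + 1:02d}" for i in range(len(STUDY_SAMPLE_SIZES), n)
    ]
    return pd.DataFrame({"pop_id": names[:n], "lon": lons, "lat": lats})


def gen_observed_dataset(spec: SyntheticStudySpec) -> GenotypeDataset:
    """Simulate a genotype dataset under the spec's truth scenario.

    Runs the structured coalescent, then applies the inbreeding level F at
    diploid formation: with probability F an individual's second gene copy
    is replaced by a duplicate of the first (identity by descent), so the
    expected estimated within-population f equals F.
    """
    scenario = build_scenario(
        spec.truth_scenario, n_demes=spec.n_populations, **spec.scenario_overrides
    )
    config = SimulationConfig(
        sample_sizes=spec.sample_sizes,
        n_loci=spec.n_loci,
        mutation_rate=spec.mutation_rate,
        seed=spec.seed,
    )
    ds = simulate_dataset(config, scenario)
    if spec.inbreeding > 0:
        rng = np.random.default_rng(np.random.SeedSequence([int(spec.seed), 0x1BD]))
        dup = rng.random(size=(ds.n_individuals, ds.n_loci)) < spec.inbreeding
        alleles = ds.alleles.copy()
        alleles[:, :, 1] = np.where(dup, alleles[:, :, 0], alleles[:, :, 1])
        ds = GenotypeDataset(
            alleles=alleles,
            pops=ds.pops,
            pop_names=[name for name, _ in STUDY_SAMPLE_SIZES[: spec.n_populations]]
            if spec.n_populations <= len(STUDY_SAMPLE_SIZES)
            else [],
            locus_names=list(ds.locus_names),
        )
    elif spec.n_populations <= len(STUDY_SAMPLE_SIZES):
        ds = GenotypeDataset(
            alleles=ds.alleles,
            pops=ds.pops,
            pop_names=[name for name, _ in STUDY_SAMPLE_SIZES[: spec.n_populations]],
            locus_names=list(ds.locus_names),
        )
    return ds


# --------------------------------------------------------------------------- #
# suitability stacks


@dataclass(frozen=True)
class SyntheticMapSpec:
    """Design of a synthetic suitability-map stack.

    ``var_*`` are the variance fractions the hierarchical ANOVA should
    recover (they must sum to one); ``planted_dynamic`` moves the
    high-suitability region between periods (``"Stability"``,
    ``"Retraction"``, ``"Expansion"`` or ``None`` for a flat background).
    The default fractions follow the typical ordering for ensemble
    hindcasts: AOGCM > time > algorithm, with the remainder residual.
    """

    grid_shape: tuple[int, int] = (80, 80)
    cell_size: float = 0.5
    n_algorithms: int = 13
    n_aogcms: int = 4
    periods: tuple[str, ...] = DEFAULT_PERIODS
    var_time: float = 0.25
    var_aogcm: float = 0.35
    var_algorithm: float = 0.18
    var_noise: float = 0.22
    planted_dynamic: str | None = "Stability"
    effect_scale: float = 0.08
    seed: int = 0

    def __post_init__(self) -> None:
        if self.grid_shape[0] < 1 or self.grid_shape[1] < 1:
            raise ValueError("grid_shape must be positive")
        fractions = (self.var_time, self.var_aogcm, self.var_algorithm, self.var_noise)
        if any(f < 0 for f in fractions):
            raise ValueError("variance fractions must be nonnegative")
        if abs(sum(fractions) - 1.0) > 1e-9:
            raise ValueError("variance fractions must sum to 1")
        if self.planted_dynamic not in (None, "Stability", "Retraction", "Expansion"):
            raise ValueError(f"unknown planted_dynamic {self.planted_dynamic!r}")


def _component_sigmas(spec: SyntheticMapSpec) -> tuple[float, float, float, float]:
    """Component standard deviations realising the requested SS fractions.

    Solves the linear system equating the expected hierarchical-ANOVA sums
    of squares (per cell, effects i.i.d. across cells and levels) to the
    requested proportional shares of a fixed total.
    """
    n_a, n_g = spec.n_algorithms, spec.n_aogcms
    n_t = len(spec.periods)
    total = (n_a * n_g * n_t - 1) * spec.effect_scale**2
    # rows: E[SS] of time, aogcm(time), algorithm(time), residual
    # cols: sigma^2 of time, aogcm, algorithm, noise
    coef = np.array(
        [
            [(n_t - 1) * n_a * n_g, (n_t - 1) * n_a, (n_t - 1) * n_g, (n_t - 1)],
            [0.0, n_t * (n_g - 1) * n_a, 0.0, n_t * (n_g - 1)],
            [0.0, 0.0, n_t * (n_a - 1) * n_g, n_t * (n_a - 1)],
            [0.0, 0.0, 0.0, n_t * (n_a - 1) * (n_g - 1)],
        ]
    )
    target = total * np.array([spec.var_time, spec.var_aogcm, spec.var_algorithm, spec.var_noise])
    sig2 = np.linalg.solve(coef, target)
    if (sig2 < -1e-12).any():
        raise ValueError(
            "var_time/var_aogcm/var_algorithm/var_noise are not realisable by "
            "nonnegative effect variances at this design size: with few "
            "algorithms or AOGCMs the residual degrees of freedom force a "
            "larger noise share; lower var_noise or enlarge the design"
        )
    return tuple(np.sqrt(np.maximum(sig2, 0.0)))


_DYNAMIC_RADII = {
    # relative blob widths per period, oldest -> youngest
    None: None,
    "Stability": (1.0, 1.0, 1.0),
    "Expansion": (0.625, 1.0, 1.5),
    "Retraction": (1.5, 1.0, 0.625),
}


def _base_surface(spec: SyntheticMapSpec) -> np.ndarray:
    """Mean suitability surface per period: background plus Gaussian blob."""
    nrows, ncols = spec.grid_shape
    n_t = len(spec.periods)
    radii = _DYNAMIC_RADII[spec.planted_dynamic]
    if radii is None:
        return np.full((n_t, nrows, ncols), 0.5)
    rr, cc = np.mgrid[0:nrows, 0:ncols]
    d2 = (rr - (nrows - 1) / 2.0) ** 2 + (cc - (ncols - 1) / 2.0) ** 2
    sigma_base = min(nrows, ncols) / 10.0
    base = np.empty((n_t, nrows, ncols))
    for t in range(n_t):
        # oldest period first; reuse the middle radius for extra periods
        rel = radii[t] if t < len(radii) else radii[-1]
        sigma = sigma_base * rel
        base[t] = 0.15 + 0.65 * np.exp(-d2 / (2.0 * sigma**2))
    return base


def gen_suitability_stack(spec: SyntheticMapSpec) -> SuitabilityStack:
    """Full factorial suitability stack with planted structure.

    Cell value = base surface (period-dependent blob realising the planted
    dynamic) + time effect + AOGCM(time) effect + algorithm(time) effect +
    noise, all Gaussian on the latent scale with component variances
    matching the requested fractions, then clipped to [0, 1].
    """
    rng = np.random.default_rng(spec.seed)
    n_a, n_g = spec.n_algorithms, spec.n_aogcms
    n_t = len(spec.periods)
    nrows, ncols = spec.grid_shape
    s_t, s_g, s_a, s_e = _component_sigmas(spec)
    base = _base_surface(spec)  # (T, rows, cols)

    t_eff = rng.normal(0.0, s_t, size=(n_t, nrows, ncols)) if s_t > 0 else np.zeros((n_t, nrows, ncols))
    g_eff = rng.normal(0.0, s_g, size=(n_g, n_t, nrows, ncols)) if s_g > 0 else np.zeros((n_g, n_t, nrows, ncols))
    a_eff = rng.normal(0.0, s_a, size=(n_a, n_t, nrows, ncols)) if s_a > 0 else np.zeros((n_a, n_t, nrows, ncols))
    values = (
        base[None, None, :, :, :]
        + t_eff[None, None, :, :, :]
        + g_eff[None, :, :, :, :]
        + a_eff[:, None, :, :, :]
    )
    if s_e > 0:
        values = values + rng.normal(0.0, s_e, size=values.shape)
    values = np.clip(values, 0.0, 1.0)
    tss = rng.uniform(0.3, 0.9, size=(n_a, n_g))
    return SuitabilityStack(
        values=values,
        algorithms=[f"alg{i + 1:02d}" for i in range(n_a)],
        aogcms=[f"gcm{i + 1}" for i in range(n_g)],
        periods=list(spec.periods),
        tss=tss,
        xll=DEFAULT_EXTENT[0],
        yll=DEFAULT_EXTENT[1],
        cellsize=spec.cell_size,
        meta={"planted_dynamic": spec.planted_dynamic, "seed": spec.seed},
    )
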