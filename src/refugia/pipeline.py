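"""End-to-end analysis pipeline.

Runs, from a single YAML (or dict) configuration: summary statistics on
the genotype table, simulation-based model selection across demographic
scenarios, suitability-ensemble post-processing (consensus, dynamics
classification, refugium, uncertainty partition) and the spatial-genetics
analyses, writing CSV/JSON tables, ASCII-grid maps, a plain-text log and a
reproducibility manifest.

Per-stage random seeds are derived by hashing the stage name together with
the master seed, so inserting a stage never perturbs another stage's
draws.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .coalescent import SCENARIO_NAMES, SimulationConfig, build_scenario
from .enm import (
    classification_association,
    classify_stack_dynamics,
    consensus_map,
    map_centroid,
    refugium_map,
    variance_partition,
)
from .genotypes import GenotypeDataset
from .grids import SuitabilityStack
from .model_selection import rank_models
from .popgen import mean_expected_heterozygosity, pairwise_fst_matrix, summary_table
from .spatial import (
    envelope_report,
    extract_at_points,
    geographic_distance_matrix,
    haversine_km,
    mantel_test,
)
from .synthetic import (
    SyntheticMapSpec,
    SyntheticStudySpec,
    gen_observed_dataset,
    gen_population_coords,
    gen_suitability_stack,
)

log = logging.getLogger("refugia.pipeline")


class ConfigError(ValueError):
    """Invalid pipeline configuration; the message names the field."""


@dataclass
class PipelineConfig:
    """Validated pipeline settings; see :func:`load_config`."""

    seed: int
    output_dir: Path
    genotypes: Path | None = None
    coords: Path | None = None
    maps_manifest: Path | None = None
    synthetic_study: SyntheticStudySpec | None = None
    synthetic_maps: SyntheticMapSpec | None = None
    synthetic_coords: bool = True
    scenarios: tuple[str, ...] = SCENARIO_NAMES
    replicates: int = 2000
    permutations: int = 9999
    suitability_threshold: float = 0.3
    cutoff: int = 199
    mutation_rate: float = 0.01
    generation_time: float = 12.0
    ar_star_min_n: int = 5
    gene_copies: int = 4

    def __post_init__(self) -> None:
        if self.genotypes is None and self.synthetic_study is None:
            raise ConfigError("config must set either 'genotypes' (path) or 'synthetic.study'")
        if self.maps_manifest is None and self.synthetic_maps is None:
            raise ConfigError("config must set either 'maps_manifest' (path) or 'synthetic.maps'")
        if self.coords is None and not self.synthetic_coords:
            raise ConfigError("config must set 'coords' or enable synthetic coordinates")
        unknown = set(self.scenarios) - set(SCENARIO_NAMES)
        if unknown:
            raise ConfigError(f"scenarios: unknown names {sorted(unknown)}")
        if self.replicates < 1:
            raise ConfigError("replicates must be >= 1")


def load_config(source) -> PipelineConfig:
    """Build a :class:`PipelineConfig` from a YAML path or a dict."""
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            raw = yaml.safe_load(fh)
    else:
        raw = dict(source)
    if "seed" not in raw:
        raise ConfigError("config must set 'seed'")
    if "output_dir" not in raw:
        raise ConfigError("config must set 'output_dir'")
    synth = raw.get("synthetic") or {}
    study = synth.get("study")
    maps = synth.get("maps")
    if study is not None:
        study = SyntheticStudySpec(**{**study, "seed": study.get("seed", raw["seed"])})
    if maps is not None:
        maps = dict(maps)
        if "grid_shape" in maps:
            maps["grid_shape"] = tuple(maps["grid_shape"])
        if "periods" in maps:
            maps["periods"] = tuple(maps["periods"])
        maps = SyntheticMapSpec(**{**maps, "seed": maps.get("seed", raw["seed"])})
    kwargs = {
        k: raw[k]
        for k in (
            "replicates",
            "permutations",
            "suitability_threshold",
            "cutoff",
            "mutation_rate",
            "generation_time",
            "ar_star_min_n",
            "gene_copies",
        )
        if k in raw
    }
    if "scenarios" in raw:
        kwargs["scenarios"] = tuple(raw["scenarios"])
    return PipelineConfig(
        seed=int(raw["seed"]),
        output_dir=Path(raw["output_dir"]),
        genotypes=Path(raw["genotypes"]) if raw.get("genotypes") else None,
        coords=Path(raw["coords"]) if raw.get("coords") else None,
        maps_manifest=Path(raw["maps_manifest"]) if raw.get("maps_manifest") else None,
        synthetic_study=study,
        synthetic_maps=maps,
        **kwargs,
    )


def stage_seed(master: int, stage: str) -> int:
    """Deterministic per-stage seed (< 2**31) from the master seed."""
    digest = hashlib.sha256(f"{stage}".encode()).digest()
    mix = int.from_bytes(digest[:8], "little")
    return int(
        np.random.SeedSequence([int(master), mix & 0x7FFFFFFF]).generate_state(1)[0] & 0x7FFFFFFF
    )


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_pipeline(config: PipelineConfig | dict | str | Path) -> dict:
    """Execute every stage; returns a dict of output artifact paths.

    Stage failures are raised after earlier outputs have been written, so
    partial results survive.
    """
    if not isinstance(config, PipelineConfig):
        config = load_config(config)
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    artifacts: dict[str, str] = {}
    manifest: dict = {
        "package_version": __version__,
        "python": sys.version.split()[0],
        "versions": {
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "master_seed": config.seed,
        "stage_seeds": {},
        "inputs": {},
    }

    try:
        # ----------------------------------------------------------- inputs
        if config.genotypes is not None:
            path = config.genotypes
            dataset = (
                GenotypeDataset.read_genepop(path)
                if path.suffix.lower() in (".gen", ".genepop")
                else GenotypeDataset.read_csv(path)
            )
            manifest["inputs"]["genotypes"] = _digest(path)
        else:
            dataset = gen_observed_dataset(config.synthetic_study)
            manifest["inputs"]["genotypes"] = f"synthetic:{config.synthetic_study.truth_scenario}"
        log.info(
            "genotypes: %d individuals, %d populations, %d loci",
            dataset.n_individuals,
            dataset.n_populations,
            dataset.n_loci,
        )
        if config.maps_manifest is not None:
            stack = SuitabilityStack.read(config.maps_manifest)
            manifest["inputs"]["maps"] = _digest(config.maps_manifest)
        else:
            stack = gen_suitability_stack(config.synthetic_maps)
            manifest["inputs"]["maps"] = "synthetic"
        if config.coords is not None:
            coords = pd.read_csv(config.coords)
            manifest["inputs"]["coords"] = _digest(config.coords)
        else:
            seed = stage_seed(config.seed, "coords")
            manifest["stage_seeds"]["coords"] = seed
            nrows, ncols = stack.grid_shape
            extent = (
                stack.xll,
                stack.yll,
                stack.xll + ncols * stack.cellsize,
                stack.yll + nrows * stack.cellsize,
            )
            coords = gen_population_coords(dataset.n_populations, extent=extent, seed=seed)
            coords["pop_id"] = dataset.pop_names
            coords.to_csv(out / "coords.csv", index=False)
            artifacts["coords"] = str(out / "coords.csv")

        # ---------------------------------------------------- summary stats
        table, overall = summary_table(dataset, g=config.gene_copies)
        n_col = table["n"]
        ar_star = table["Ar"].where(n_col >= config.ar_star_min_n)
        table = table.assign(Ar_star=ar_star)
        table.to_csv(out / "table2.csv")
        pd.DataFrame([overall]).to_csv(out / "overall_fstats.csv", index=False)
        artifacts["summary_stats"] = str(out / "table2.csv")
        log.info("summary stats written; overall FST=%.4f", overall["FST"])

        # --------------------------------------------------- model selection
        observed_he = mean_expected_heterozygosity(dataset)
        sizes = tuple(int(n_col.loc[p]) for p in dataset.pop_names)
        sim_config = SimulationConfig(
            sample_sizes=sizes,
            n_loci=dataset.n_loci,
            mutation_rate=config.mutation_rate,
            seed=stage_seed(config.seed, "model_selection"),
        )
        manifest["stage_seeds"]["model_selection"] = sim_config.seed
        scenarios = [
            build_scenario(name, n_demes=dataset.n_populations) for name in config.scenarios
        ]
        table1 = rank_models(
            observed_he,
            scenarios,
            sim_config,
            R=config.replicates,
            seed=sim_config.seed,
        )
        table1.insert(1, "observed_mean_He", observed_he)
        table1.to_csv(out / "table1.csv", index=False)
        artifacts["model_selection"] = str(out / "table1.csv")
        log.info("model selection done; best model %s", table1["Model"].iloc[0])

        # ------------------------------------------------------- ENM stage
        consensus = {p: consensus_map(stack, p) for p in stack.periods}
        for p, grid in consensus.items():
            grid.write_ascii(out / f"consensus_{p}.asc")
        refug = refugium_map(list(consensus.values()), config.suitability_threshold)
        refug.write_ascii(out / "refugium.asc")
        part = variance_partition(stack)
        for name, grid in part.maps.items():
            grid.write_ascii(out / f"uncertainty_{name}.asc")
        pd.DataFrame([part.proportions]).to_csv(out / "anova_proportions.csv", index=False)
        dynamics = classify_stack_dynamics(stack, config.suitability_threshold, config.cutoff)
        dynamics.to_csv(out / "dynamics.csv", index=False)
        assoc_rows = []
        for pair, sub in dynamics.groupby("pair", sort=True):
            counts = pd.crosstab(sub["algorithm"] + "*" + sub["aogcm"], sub["label"])
            if counts.shape[1] < 2:
                continue
            res = classification_association(counts.to_numpy())
            assoc_rows.append({"pair": pair, **res})
        pd.DataFrame(assoc_rows).to_csv(out / "association.csv", index=False)
        artifacts["enm"] = str(out / "dynamics.csv")
        log.info("ENM post-processing done; proportions %s", part.proportions)

        # --------------------------------------------------- spatial stage
        lons = coords["lon"].to_numpy()
        lats = coords["lat"].to_numpy()
        lin_fst = pairwise_fst_matrix(dataset, linearize=True).to_numpy()
        geo = geographic_distance_matrix(lons, lats)
        with np.errstate(divide="ignore"):
            log_geo = np.where(geo > 0, np.log(geo), 0.0)
        mantel_seed = stage_seed(config.seed, "mantel")
        manifest["stage_seeds"]["mantel"] = mantel_seed
        r, r2, p = mantel_test(lin_fst, log_geo, n_perm=config.permutations, seed=mantel_seed)
        with open(out / "mantel.json", "w") as fh:
            json.dump({"r": r, "r_squared": r2, "p": p, "n_perm": config.permutations}, fh, indent=2)
        artifacts["mantel"] = str(out / "mantel.json")

        geo_table = pd.DataFrame(index=dataset.pop_names)
        geo_table["He"] = table.loc[dataset.pop_names, "He"]
        geo_table["Ar_star"] = table.loc[dataset.pop_names, "Ar_star"]
        for period, grid in consensus.items():
            geo_table[f"suitability_{period}"] = extract_at_points(grid, lons, lats)
        periods = list(stack.periods)
        for older, recent in zip(periods[:-1], periods[1:]):
            geo_table[f"delta_{older}_{recent}"] = (
                geo_table[f"suitability_{recent}"] - geo_table[f"suitability_{older}"]
            )
        for period, grid in consensus.items():
            c_lon, c_lat = map_centroid(grid, config.suitability_threshold)
            geo_table[f"dist_centroid_{period}"] = haversine_km(lons, lats, c_lon, c_lat)
        r_lon, r_lat = map_centroid(refug, 0.5)
        geo_table["dist_refugium"] = haversine_km(lons, lats, r_lon, r_lat)
        geo_table.to_csv(out / "population_geo.csv")
        report = envelope_report(geo_table)
        report.to_csv(out / "quantreg.csv", index=False)
        artifacts["spatial"] = str(out / "quantreg.csv")
        log.info("spatial analyses done; Mantel r=%.3f p=%.3f", r, p)
    finally:
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2)
        artifacts["manifest"] = str(out / "manifest.json")
        log.removeHandler(handler)
        handler.close()
    return artifacts
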