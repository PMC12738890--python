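"""Orchestration: dataset -> diversity/AMOVA/ordination/ABC report.

`run_full_analysis` strings the library stages together in the order a
two-species SSR survey is analysed: diversity table, AMOVA per species,
pairwise FST/Nm, Nei distance with PCoA and UPGMA, optional Evanno delta-K
over externally supplied STRUCTURE log-likelihoods, and the ABC
demographic-inference block on four population groups. Every stochastic
stage receives a seed spawned deterministically from the master seed, and a
manifest records shapes, seeds and timings so deterministic artifacts can
be reproduced byte-identically.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import coalescent_abc as ca
from . import popgen_stats as ps
from . import structure_summaries as ss
from .genotype_core import GenotypeDataset, read_genalex, validate_dataset
from .synthetic_data import STUDY_POPULATIONS, FixtureConfig, make_study_fixture

__all__ = ["RunConfig", "AnalysisReport", "run_full_analysis", "STUDY_ABC_GROUPS"]

logger = logging.getLogger(__name__)

#: four-group structure used for demographic inference of the study design:
#: Pop1 = Northeast China, Pop2 = North China, Pop3 = Shandong (all three
#: T. amurensis), Pop4 = the T. japonica sites.
STUDY_ABC_GROUPS: dict[str, int] = {
    "DGL": 1, "MPS": 1, "DXG": 1,
    "YDS": 2, "ZS": 2,
    "TS": 3, "LU": 3, "LS": 3,
    "HS": 4, "MS": 4, "TMS": 4,
}


@dataclass
class RunConfig:
    """Everything a full analysis run needs; loadable from YAML."""

    input_path: str | None = None
    out_dir: str = "tiliapop_out"
    master_seed: int = 0
    fixture_loci: int = 15
    species_of: dict[str, str] = field(
        default_factory=lambda: {s.label: s.species for s in STUDY_POPULATIONS}
    )
    fst_estimator: str = "ht_hs"
    n_permutations: int = 999
    loglik_path: str | None = None
    run_abc: bool = True
    abc_groups: dict[str, int] = field(default_factory=lambda: dict(STUDY_ABC_GROUPS))
    abc_draws: int = 2_000
    abc_tolerance: float = 0.01
    abc_n_closest: int | None = None
    generation_time: float = 100.0

    def __post_init__(self) -> None:
        if self.generation_time <= 0:
            raise ValueError("generation_time must be positive")
        for name in ("n_permutations", "abc_draws", "fixture_loci"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**raw)

    def to_dict(self) -> dict:
        return {
            k: (dict(v) if isinstance(v, dict) else v)
            for k, v in self.__dict__.items()
        }


@dataclass
class AnalysisReport:
    """All computed tables plus the manifest, as returned and as written."""

    dataset: GenotypeDataset
    diversity: ps.DiversitySummary
    differentiation: ps.DifferentiationResult
    amova_tables: dict[str, ps.AMOVATable]
    species_fst: dict[str, float]
    nei: ps.DistanceMatrix
    pcoa: ss.PCoAResult
    upgma: ss.UPGMATree
    delta_k: ss.DeltaKResult | None
    abc: ca.ABCResult | None
    manifest: dict


def _stage_seeds(master_seed: int, n: int = 8) -> list[int]:
    """Deterministic per-stage seeds spawned from the master seed."""
    return [int(s) for s in np.random.SeedSequence(master_seed).generate_state(n)]


def run_full_analysis(config: RunConfig) -> AnalysisReport:
    """Execute all analysis stages and write the report directory."""
    out = Path(config.out_dir)
    (out / "tables").mkdir(parents=True, exist_ok=True)
    (out / "trees").mkdir(exist_ok=True)
    (out / "abc").mkdir(exist_ok=True)
    seeds = _stage_seeds(config.master_seed)
    manifest: dict = {"master_seed": config.master_seed, "stages": {}, "config": config.to_dict()}

    def stage(name: str, fn):
        t0 = time.perf_counter()
        try:
            result = fn()
        except Exception as exc:
            manifest["stages"][name] = {"error": str(exc)}
            (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
            raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
        dt = time.perf_counter() - t0
        manifest["stages"][name] = {"elapsed_s": round(dt, 3)}
        logger.info("stage %-12s done in %.2fs", name, dt)
        return result

    # -- data ---------------------------------------------------------
    if config.input_path:
        dataset = stage("load", lambda: read_genalex(config.input_path))
    else:
        dataset = stage(
            "fixture",
            lambda: make_study_fixture(
                FixtureConfig(n_loci=config.fixture_loci, seed=seeds[0])
            ),
        )
    report = stage("validate", lambda: validate_dataset(dataset))
    manifest["stages"]["validate"].update(
        n=report.n, n_loci=report.n_loci, missing=report.total_missing_fraction
    )

    species_of = {
        p: config.species_of.get(p, "") for p in dataset.population_labels
    }
    species = [s for s in dict.fromkeys(species_of.values()) if s]

    # -- diversity + differentiation ----------------------------------
    diversity = stage(
        "diversity", lambda: ps.population_summary(dataset, species_of or None)
    )
    diversity.per_population.to_csv(out / "tables" / "diversity.csv")
    if diversity.per_species is not None:
        diversity.per_species.to_csv(out / "tables" / "diversity_species.csv")

    diff = stage("fst", lambda: ps.pairwise_fst(dataset, config.fst_estimator))
    diff.combined_table().to_csv(out / "tables" / "fst_nm.csv")

    species_fst: dict[str, float] = {}
    amova_tables: dict[str, ps.AMOVATable] = {}
    for k, sp in enumerate(species):
        pops = [p for p in dataset.population_labels if species_of[p] == sp]
        if len(pops) < 2:
            continue
        species_fst[sp] = stage(
            f"global_fst[{sp}]",
            lambda pops=pops: ps.global_fst(dataset, pops, config.fst_estimator),
        )
        amova_tables[sp] = stage(
            f"amova[{sp}]",
            lambda pops=pops, k=k: ps.amova(
                dataset, config.n_permutations, seed=seeds[1] + k, populations=pops
            ),
        )
        amova_tables[sp].to_dataframe().to_csv(
            out / "tables" / f"amova_{sp.replace(' ', '_').replace('.', '')}.csv"
        )
    pd.Series(species_fst, name="FST").to_frame().assign(
        Nm=lambda d: d["FST"].map(ps.nm_from_fst)
    ).to_csv(out / "tables" / "species_fst_nm.csv")

    # -- distance, ordination, clustering -----------------------------
    nei = stage("nei", lambda: ps.nei_distance(dataset))
    nei.to_dataframe().to_csv(out / "tables" / "nei_distance.csv")
    pcoa_res = stage("pcoa", lambda: ss.pcoa(nei))
    pcoa_res.coordinates.to_csv(out / "tables" / "pcoa.csv")
    tree = stage("upgma", lambda: ss.upgma(nei))
    (out / "trees" / "upgma.nwk").write_text(tree.newick + "\n")

    delta_k = None
    if config.loglik_path:
        logliks = pd.read_csv(config.loglik_path)
        delta_k = stage("deltak", lambda: ss.evanno_delta_k(logliks))
        delta_k.table.to_csv(out / "tables" / "delta_k.csv")

    # -- ABC demographic inference ------------------------------------
    abc_result = None
    if config.run_abc:
        grouping = {
            p: config.abc_groups.get(p, i + 1)
            for i, p in enumerate(dataset.population_labels)
        }
        n_groups = max(grouping.values())
        group_sizes = [0] * n_groups
        for p, g in grouping.items():
            group_sizes[g - 1] += dataset.population_sizes()[p]
        observed = stage("abc_stats", lambda: ca.summary_stats(dataset, grouping))
        abc_result = stage(
            "abc",
            lambda: ca.run_abc(
                observed,
                sample_sizes=group_sizes,
                n_loci=dataset.n_loci,
                seed=seeds[2],
                n_draws=config.abc_draws,
                tolerance=config.abc_tolerance,
                n_closest=config.abc_n_closest,
                generation_time=config.generation_time,
            ),
        )
        (out / "abc" / "result.json").write_text(
            json.dumps(abc_result.to_report(), indent=2, default=float)
        )
        abc_result.parameter_posterior.samples.to_csv(
            out / "abc" / "adjusted_samples.csv", index=False
        )

    manifest["seeds"] = {"fixture": seeds[0], "amova": seeds[1], "abc": seeds[2]}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return AnalysisReport(
        dataset=dataset,
        diversity=diversity,
        differentiation=diff,
        amova_tables=amova_tables,
        species_fst=species_fst,
        nei=nei,
        pcoa=pcoa_res,
        upgma=tree,
        delta_k=delta_k,
        abc=abc_result,
        manifest=manifest,
    )
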