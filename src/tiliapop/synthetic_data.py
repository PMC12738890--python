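"""Synthetic SSR genotype datasets with controlled population structure.

The study this pipeline targets surveyed 242 trees of two *Tilia* species
(*T. amurensis*, 8 populations; *T. japonica*, 3 populations) at 15
dinucleotide microsatellite loci. The raw genotypes are not public, so this
module generates datasets with the same shape and the statistical structure
the downstream analyses assume: allele-frequency divergence between two
species clusters, weaker divergence among populations within a species, and
a per-population inbreeding coefficient controlling the heterozygote
deficit.

Two generative routes exist:

* :func:`sample_genotypes` — draw genotypes from fixed per-population allele
  frequencies under the inbreeding model
  ``P(A_iA_i) = p_i^2 + f p_i (1 - p_i)``, ``P(A_iA_j) = 2 p_i p_j (1 - f)``.
* :func:`simulate_dataset` — draw a dataset from the coalescent demographic
  simulator (delegates to :mod:`tiliapop.coalescent_abc`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .genotype_core import MISSING, GenotypeDataset, PopulationSpec

__all__ = [
    "STUDY_POPULATIONS",
    "FrequencyModel",
    "FixtureConfig",
    "sample_genotypes",
    "make_frequency_model",
    "make_study_fixture",
    "simulate_dataset",
]

#: The 11 study populations: label, species, sample size (N sums to 242).
STUDY_POPULATIONS: tuple[PopulationSpec, ...] = (
    PopulationSpec("TS", "T. amurensis", 26),
    PopulationSpec("LU", "T. amurensis", 26),
    PopulationSpec("YDS", "T. amurensis", 22),
    PopulationSpec("ZS", "T. amurensis", 22),
    PopulationSpec("LS", "T. amurensis", 29),
    PopulationSpec("DGL", "T. amurensis", 21),
    PopulationSpec("MPS", "T. amurensis", 13),
    PopulationSpec("DXG", "T. amurensis", 25),
    PopulationSpec("HS", "T. japonica", 24),
    PopulationSpec("MS", "T. japonica", 19),
    PopulationSpec("TMS", "T. japonica", 15),
)


@dataclass
class FrequencyModel:
    """Per population x locus allele-frequency vectors plus inbreeding f.

    ``frequencies[(pop, locus)]`` is a pair ``(allele_states, probs)`` of
    equal-length arrays; ``inbreeding[pop]`` is the within-population
    heterozygote-deficit parameter f in [0, 1].
    """

    loci: list[str]
    frequencies: dict[tuple[str, str], tuple[np.ndarray, np.ndarray]]
    inbreeding: dict[str, float] = field(default_factory=dict)

    def validate(self) -> None:
        for (pop, locus), (states, probs) in self.frequencies.items():
            probs = np.asarray(probs, dtype=float)
            if len(states) != len(probs):
                raise ValueError(f"{pop}/{locus}: states and probs differ in length")
            if abs(probs.sum() - 1.0) > 1e-8:
                raise ValueError(
                    f"{pop}/{locus}: frequency vector sums to {probs.sum():.12f}, not 1"
                )
        for pop, f in self.inbreeding.items():
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"{pop}: inbreeding f={f} outside [0, 1]")


@dataclass(frozen=True)
class FixtureConfig:
    """Shape and seed of a generated fixture dataset."""

    populations: tuple[PopulationSpec, ...] = STUDY_POPULATIONS
    n_loci: int = 15
    seed: int = 0

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")


def sample_genotypes(
    model: FrequencyModel,
    specs: list[PopulationSpec] | tuple[PopulationSpec, ...],
    seed: int,
) -> GenotypeDataset:
    """Draw a diploid dataset from fixed allele frequencies with inbreeding.

    For each individual and locus, with probability f a single allele is
    drawn and duplicated (identity by descent), otherwise two alleles are
    drawn independently. This yields exactly
    ``P(hom i) = p_i^2 + f p_i (1 - p_i)`` and
    ``P(het ij) = 2 p_i p_j (1 - f)``, so E[He] = 1 - sum p^2 regardless of
    f and E[Ho] = (1 - f)(1 - sum p^2).
    """
    model.validate()
    rng = np.random.default_rng(seed)
    individuals: list[str] = []
    populations: list[str] = []
    blocks: list[np.ndarray] = []
    for spec in specs:
        f = float(model.inbreeding.get(spec.label, 0.0))
        n = spec.n_samples
        block = np.empty((n, len(model.loci), 2), dtype=np.int64)
        for j, locus in enumerate(model.loci):
            try:
                states, probs = model.frequencies[(spec.label, locus)]
            except KeyError:
                raise ValueError(
                    f"model does not cover population {spec.label!r} at locus {locus!r}"
                ) from None
            a = rng.choice(states, size=n, p=probs)
            b = rng.choice(states, size=n, p=probs)
            ibd = rng.random(n) < f
            b = np.where(ibd, a, b)
            block[:, j, 0] = a
            block[:, j, 1] = b
        individuals.extend(f"{spec.label}_{i + 1}" for i in range(n))
        populations.extend([spec.label] * n)
        blocks.append(block)
    return GenotypeDataset(
        individuals, populations, [str(l) for l in model.loci], np.concatenate(blocks)
    )


def make_frequency_model(
    specs: tuple[PopulationSpec, ...],
    n_loci: int,
    seed: int,
    *,
    min_alleles: int = 6,
    max_alleles: int = 8,
    within_group_concentration: float = 30.0,
    between_group_concentration: float = 8.0,
    max_inbreeding: float = 0.2,
    motif_length: int = 2,
) -> FrequencyModel:
    """Build a hierarchical frequency model with two species-level clusters.

    Per locus, a global Dirichlet(1) frequency vector is drawn over 6-8
    alleles on a dinucleotide ladder; each species group perturbs it with a
    Dirichlet whose concentration controls between-species divergence, and
    each population perturbs its group vector with a tighter Dirichlet
    (within-species divergence). Smaller concentration means more drift:
    for Dirichlet(c*p) the expected Wright fixation index is ~ 1/(c + 1),
    so the defaults give between-species FST around 0.1 and within-species
    FST of a few percent, matching the ordering the analysis expects.
    """
    rng = np.random.default_rng(seed)
    loci = [f"L{j + 1}" for j in range(n_loci)]
    groups = sorted({s.species for s in specs}) or [""]
    freqs: dict[tuple[str, str], tuple[np.ndarray, np.ndarray]] = {}
    floor = 1e-6  # keep Dirichlet parameters strictly positive
    for j, locus in enumerate(loci):
        k = int(rng.integers(min_alleles, max_alleles + 1))
        base_size = int(rng.integers(90, 280))
        states = base_size + motif_length * np.arange(k)
        p_global = rng.dirichlet(np.ones(k))
        p_group = {
            g: rng.dirichlet(np.maximum(p_global, floor) * between_group_concentration)
            for g in groups
        }
        for spec in specs:
            p_pop = rng.dirichlet(
                np.maximum(p_group[spec.species], floor) * within_group_concentration
            )
            p_pop = p_pop / p_pop.sum()
            freqs[(spec.label, locus)] = (states.copy(), p_pop)
    inbreeding = {
        spec.label: float(rng.uniform(0.0, max_inbreeding)) for spec in specs
    }
    return FrequencyModel(loci=loci, frequencies=freqs, inbreeding=inbreeding)


def make_study_fixture(config: FixtureConfig | None = None) -> GenotypeDataset:
    """Generate the study-shaped fixture: 11 populations, N=242, 15 loci.

    The dataset has two internally-similar clusters mirroring the two
    species (8 + 3 populations at the published sample sizes), so that
    between-species pairwise FST exceeds within-species FST. Pure function
    of the seed.
    """
    config = config or FixtureConfig()
    seeds = np.random.SeedSequence(config.seed).generate_state(2)
    model = make_frequency_model(
        tuple(config.populations), config.n_loci, int(seeds[0])
    )
    return sample_genotypes(model, config.populations, int(seeds[1]))


def simulate_dataset(scenario, params, config: FixtureConfig, mutation_model=None):
    """Draw a dataset from the coalescent demographic simulator.

    ``scenario``/``params`` are a :class:`~tiliapop.coalescent_abc.DemographicScenario`
    and its parameter set; the fixture config supplies population specs
    (mapped in order onto the scenario's groups), locus count and seed.
    """
    from . import coalescent_abc as ca

    if mutation_model is None:
        mutation_model = ca.MutationModel.default(config.n_loci)
    sample_sizes = [s.n_samples for s in config.populations]
    return ca.simulate_coalescent(
        scenario,
        params,
        mutation_model,
        sample_sizes=sample_sizes,
        n_loci=config.n_loci,
        seed=config.seed,
        population_labels=[s.label for s in config.populations],
    )
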