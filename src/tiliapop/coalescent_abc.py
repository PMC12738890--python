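"""Coalescent simulation of SSR data and ABC demographic inference.

This module is the demographic-history engine: it simulates microsatellite
datasets under three competing four-group scenarios (nested splits; nested
splits with an admixture origin of group 3; simultaneous merge), draws
parameters from uniform priors with the size and time-ordering constraints,
summarizes datasets with a fixed vector of within-group and pairwise
statistics, and performs approximate Bayesian computation: rejection
sampling, scenario choice by multinomial logistic regression on the closest
simulations, and Beaumont-style local-linear parameter adjustment with
Epanechnikov weights.

Groups are labelled Pop1..Pop4. Scenario 1: Pop3 merges into Pop2 at t1,
Pop2 into Pop1 at t2, Pop1 into Pop4 at t3, and the ancestral population
takes size NA at t4. Scenario 2 replaces the t1 merge by an admixture
origin of Pop3 from Pop2 (probability ra) and Pop4 (1 - ra). Scenario 3
merges all four groups into the ancestral population of size NA at t1.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from ._kernels import simulate_locus, summary_stats_kernel
from .genotype_core import MISSING, GenotypeDataset

__all__ = [
    "Merge",
    "Admixture",
    "Resize",
    "DemographicScenario",
    "ScenarioParameters",
    "PriorConfig",
    "MutationModel",
    "SummaryStatVector",
    "ScenarioPosterior",
    "AdjustedPosterior",
    "ABCResult",
    "scenario",
    "single_population",
    "two_population_split",
    "sample_priors",
    "gsm_step",
    "simulate_coalescent",
    "summary_stats",
    "build_reference_table",
    "abc_reject",
    "scenario_posterior_logistic",
    "adjust_parameters_loclinear",
    "convert_generations",
    "model_check_pca",
    "run_abc",
    "STAT_COLUMNS",
]

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# scenarios and parameters
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Merge:
    """Backward in time: all lineages of ``source`` move to ``dest``."""

    time: str
    source: int  # 1-based group number
    dest: int


@dataclass(frozen=True)
class Admixture:
    """Each lineage of ``source`` moves to ``dest_a`` with probability
    ``rate`` (a parameter symbol), else to ``dest_b``."""

    time: str
    source: int
    dest_a: int
    dest_b: int
    rate: str = "ra"


@dataclass(frozen=True)
class Resize:
    """Deme ``population`` takes size ``size`` (a parameter symbol)."""

    time: str
    population: int
    size: str = "NA"


@dataclass(frozen=True)
class DemographicScenario:
    """An ordered backward-in-time event list over groups Pop1..Pop_n.

    ``time_order`` lists the time symbols whose draws must be
    non-decreasing (nested events). Events sharing a time are applied in
    list order.
    """

    scenario_id: int
    n_groups: int
    events: tuple[Merge | Admixture | Resize, ...]
    time_order: tuple[str, ...]

    @property
    def time_symbols(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for ev in self.events:
            seen.setdefault(ev.time)
        return tuple(seen)

    @property
    def has_admixture(self) -> bool:
        return any(isinstance(ev, Admixture) for ev in self.events)

    @property
    def parameter_names(self) -> tuple[str, ...]:
        names = [f"N{i + 1}" for i in range(self.n_groups)] + ["NA"]
        names += list(self.time_symbols)
        if self.has_admixture:
            names.append("ra")
        return tuple(names)


def scenario(scenario_id: int) -> DemographicScenario:
    """The three competing demographic scenarios (see module docstring)."""
    if scenario_id == 1:
        return DemographicScenario(
            1,
            4,
            (Merge("t1", 3, 2), Merge("t2", 2, 1), Merge("t3", 1, 4), Resize("t4", 4)),
            ("t1", "t2", "t3", "t4"),
        )
    if scenario_id == 2:
        return DemographicScenario(
            2,
            4,
            (
                Admixture("t1", 3, 2, 4, "ra"),
                Merge("t2", 2, 1),
                Merge("t3", 1, 4),
                Resize("t4", 4),
            ),
            ("t1", "t2", "t3", "t4"),
        )
    if scenario_id == 3:
        return DemographicScenario(
            3,
            4,
            (Merge("t1", 1, 4), Merge("t1", 2, 4), Merge("t1", 3, 4), Resize("t1", 4)),
            ("t1",),
        )
    raise ValueError(f"unknown scenario id {scenario_id}")


def single_population() -> DemographicScenario:
    """One panmictic group of size N1; useful for simulator oracles."""
    return DemographicScenario(0, 1, (), ())


def two_population_split(time_symbol: str = "t1") -> DemographicScenario:
    """Two groups merging at one time; useful for divergence oracles."""
    return DemographicScenario(0, 2, (Merge(time_symbol, 2, 1),), (time_symbol,))


@dataclass(frozen=True)
class PriorConfig:
    """Uniform prior bounds for demography and the mutation hyper-priors."""

    size_min: float = 10.0
    size_max: float = 20_000.0
    time_min: float = 10.0
    time_max: float = 10_000.0
    mean_mu_bounds: tuple[float, float] = (1e-4, 1e-3)
    locus_mu_bounds: tuple[float, float] = (1e-5, 1e-2)
    mean_p_bounds: tuple[float, float] = (0.1, 0.3)
    locus_p_bounds: tuple[float, float] = (0.01, 0.9)
    mean_sni_bounds: tuple[float, float] = (1e-8, 1e-4)
    locus_sni_bounds: tuple[float, float] = (1e-9, 1e-3)


@dataclass(frozen=True)
class ScenarioParameters:
    """Concrete effective sizes (diploid), event times (generations), ra."""

    N1: float
    N2: float = 0.0
    N3: float = 0.0
    N4: float = 0.0
    NA: float = 0.0
    t1: float | None = None
    t2: float | None = None
    t3: float | None = None
    t4: float | None = None
    ra: float | None = None

    def __getitem__(self, key: str) -> float:
        v = getattr(self, key)
        if v is None:
            raise KeyError(key)
        return float(v)

    def validate(self, scn: DemographicScenario, prior: PriorConfig | None = None) -> None:
        prior = prior or PriorConfig()
        sizes = [self[f"N{i + 1}"] for i in range(scn.n_groups)]
        for i, v in enumerate(sizes):
            if not prior.size_min <= v <= prior.size_max:
                raise ValueError(f"N{i + 1}={v} outside prior support")
            if scn.scenario_id and v < self["NA"]:
                raise ValueError(f"N{i + 1}={v} < NA={self['NA']}")
        times = [self[sym] for sym in scn.time_order]
        for sym, v in zip(scn.time_order, times):
            if not prior.time_min <= v <= prior.time_max:
                raise ValueError(f"{sym}={v} outside prior support")
        if any(b < a for a, b in zip(times, times[1:])):
            raise ValueError(f"event times not ordered: {times}")
        if scn.has_admixture and not (0.0 < (self.ra or -1.0) < 1.0):
            raise ValueError("ra must lie strictly in (0, 1)")

    @classmethod
    def from_row(cls, row: "pd.Series | dict") -> "ScenarioParameters":
        keys = ["N1", "N2", "N3", "N4", "NA", "t1", "t2", "t3", "t4", "ra"]
        return cls(**{k: float(row[k]) for k in keys if k in row and pd.notna(row[k])})


def sample_priors(
    scn: DemographicScenario,
    n_draws: int,
    seed: int,
    prior: PriorConfig | None = None,
) -> pd.DataFrame:
    """Rejection-sample the uniform priors under the scenario constraints.

    Sizes are integer-uniform on [size_min, size_max] with every group size
    >= NA; times integer-uniform on [time_min, time_max] with the scenario's
    nesting order enforced; ra uniform on (0, 1) for the admixture scenario.
    Raises if the joint acceptance rate falls below 1e-4.
    """
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    prior = prior or PriorConfig()
    rng = np.random.default_rng(seed)
    size_cols = [f"N{i + 1}" for i in range(scn.n_groups)] + ["NA"]
    time_cols = list(scn.time_order)
    out: list[np.ndarray] = []
    got, tried = 0, 0
    while got < n_draws:
        batch = max(4 * (n_draws - got), 1000)
        tried += batch
        sizes = rng.integers(
            int(prior.size_min), int(prior.size_max) + 1, size=(batch, len(size_cols))
        ).astype(float)
        times = rng.integers(
            int(prior.time_min), int(prior.time_max) + 1, size=(batch, len(time_cols))
        ).astype(float)
        ok = np.all(sizes[:, :-1] >= sizes[:, -1:], axis=1)
        if len(time_cols) > 1:
            ok &= np.all(np.diff(times, axis=1) >= 0, axis=1)
        cols = [sizes[ok], times[ok]]
        if scn.has_admixture:
            cols.append(rng.uniform(0.0, 1.0, size=(int(ok.sum()), 1)))
        out.append(np.hstack(cols))
        got += int(ok.sum())
        if tried > 1000 and got / tried < 1e-4:
            raise RuntimeError("prior acceptance rate below 1e-4; check constraints")
    names = size_cols + time_cols + (["ra"] if scn.has_admixture else [])
    return pd.DataFrame(np.vstack(out)[:n_draws], columns=names)


# ---------------------------------------------------------------------------
# mutation model
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MutationModel:
    """Generalized stepwise mutation with single-nucleotide indels.

    ``mu_l``/``p_l``/``sni_l`` are per-locus rates; the means are kept for
    reporting. Alleles live on a bounded ladder of ``range_states``
    contiguous repeat counts centred on ``founding_repeat``; a locus allele
    in nucleotides is ``base_size_nt + motif_length * repeats + offset``
    where the offset accumulates +-1 nt SNI events.
    """

    mu_l: np.ndarray
    p_l: np.ndarray
    sni_l: np.ndarray
    mean_mu: float
    mean_p: float
    mean_sni: float
    motif_length: int = 2
    range_states: int = 40
    founding_repeat: int = 20
    base_size_nt: int = 100

    @property
    def n_loci(self) -> int:
        return len(self.mu_l)

    @property
    def repeat_bounds(self) -> tuple[int, int]:
        lo = self.founding_repeat - (self.range_states - 1) // 2
        return lo, lo + self.range_states - 1

    @classmethod
    def default(
        cls,
        n_loci: int,
        mu: float = 5e-4,
        p: float = 0.22,
        sni: float = 0.0,
        **kwargs,
    ) -> "MutationModel":
        """Constant per-locus rates (no hyper-prior spread)."""
        return cls(
            mu_l=np.full(n_loci, mu),
            p_l=np.full(n_loci, p),
            sni_l=np.full(n_loci, sni),
            mean_mu=mu,
            mean_p=p,
            mean_sni=sni,
            **kwargs,
        )

    @classmethod
    def from_priors(
        cls, n_loci: int, rng: np.random.Generator, prior: PriorConfig | None = None
    ) -> "MutationModel":
        """Draw the hyper-parameters and per-locus rates.

        Means are uniform on their stated ranges; per-locus values come
        from a Gamma with shape 2 around the mean, redrawn until inside
        the per-locus bounds.
        """
        prior = prior or PriorConfig()
        mean_mu = rng.uniform(*prior.mean_mu_bounds)
        mean_p = rng.uniform(*prior.mean_p_bounds)
        mean_sni = rng.uniform(*prior.mean_sni_bounds)

        def gamma_trunc(mean: float, bounds: tuple[float, float]) -> np.ndarray:
            out = np.empty(n_loci)
            need = np.ones(n_loci, bool)
            for _ in range(200):
                k = int(need.sum())
                if not k:
                    break
                draw = rng.gamma(2.0, mean / 2.0, size=k)
                inside = (draw >= bounds[0]) & (draw <= bounds[1])
                idx = np.flatnonzero(need)
                out[idx[inside]] = draw[inside]
                need[idx[inside]] = False
            if need.any():  # extremely skewed mean: clip the stragglers
                out[need] = np.clip(rng.gamma(2.0, mean / 2.0, int(need.sum())), *bounds)
            return out

        return cls(
            mu_l=gamma_trunc(mean_mu, prior.locus_mu_bounds),
            p_l=gamma_trunc(mean_p, prior.locus_p_bounds),
            sni_l=gamma_trunc(mean_sni, prior.locus_sni_bounds),
            mean_mu=mean_mu,
            mean_p=mean_p,
            mean_sni=mean_sni,
        )


def gsm_step(p: float, rng: np.random.Generator) -> int:
    """One generalized-stepwise mutation step.

    Magnitude geometric on {1, 2, ...} with P(|step| = k) = (1-p) p^(k-1);
    sign symmetric. p = 0 recovers the strict stepwise model.
    """
    if not 0.0 <= p < 1.0:
        raise ValueError("GSM coefficient must lie in [0, 1)")
    k = 1
    while rng.random() < p:
        k += 1
    return k if rng.random() < 0.5 else -k


# ---------------------------------------------------------------------------
# simulation
# ---------------------------------------------------------------------------


def _compile_events(
    scn: DemographicScenario, params: ScenarioParameters
) -> tuple[np.ndarray, ...]:
    rows = []
    for order, ev in enumerate(scn.events):
        t = params[ev.time]
        if isinstance(ev, Merge):
            rows.append((t, order, 0, ev.source - 1, ev.dest - 1, 0, 0.0))
        elif isinstance(ev, Admixture):
            rows.append(
                (t, order, 1, ev.source - 1, ev.dest_a - 1, ev.dest_b - 1, params[ev.rate])
            )
        else:
            rows.append((t, order, 2, ev.population - 1, 0, 0, params[ev.size]))
    rows.sort(key=lambda r: (r[0], r[1]))
    ev_time = np.array([r[0] for r in rows], float)
    ev_kind = np.array([r[2] for r in rows], np.int64)
    ev_a = np.array([r[3] for r in rows], np.int64)
    ev_b = np.array([r[4] for r in rows], np.int64)
    ev_c = np.array([r[5] for r in rows], np.int64)
    ev_p = np.array([r[6] for r in rows], float)
    return ev_time, ev_kind, ev_a, ev_b, ev_c, ev_p


def _simulate_size_matrix(
    scn: DemographicScenario,
    params: ScenarioParameters,
    mut: MutationModel,
    sample_sizes: list[int],
    n_loci: int,
    seed: int,
    return_tmrca: bool = False,
):
    """Fast path: (n_loci, n_haploids) allele sizes in nt + haploid group map."""
    if len(sample_sizes) != scn.n_groups:
        raise ValueError(
            f"scenario has {scn.n_groups} groups, got {len(sample_sizes)} sample sizes"
        )
    if all(s == 0 for s in sample_sizes):
        raise ValueError("at least one group must have a positive sample size")
    params.validate(scn) if scn.scenario_id else None
    deme0 = np.concatenate(
        [np.full(2 * s, g, np.int64) for g, s in enumerate(sample_sizes)]
    )
    sizes_init = np.array(
        [params[f"N{i + 1}"] for i in range(scn.n_groups)], float
    )
    evs = _compile_events(scn, params)
    lo, hi = mut.repeat_bounds
    rng = np.random.default_rng(seed)
    locus_seeds = rng.integers(0, 2**31 - 1, size=n_loci)
    sizes_nt = np.empty((n_loci, deme0.size), np.int64)
    tmrcas = np.empty(n_loci)
    for j in range(n_loci):
        rep, off, tm = simulate_locus(
            int(locus_seeds[j]),
            deme0,
            sizes_init,
            *evs,
            float(mut.mu_l[j]),
            float(mut.p_l[j]),
            float(mut.sni_l[j]),
            lo,
            hi,
            mut.founding_repeat,
        )
        sizes_nt[j] = mut.base_size_nt + mut.motif_length * rep + off
        tmrcas[j] = tm
    if return_tmrca:
        return sizes_nt, deme0, tmrcas
    return sizes_nt, deme0


def simulate_coalescent(
    scn: DemographicScenario,
    params: ScenarioParameters,
    mut: MutationModel,
    sample_sizes: list[int],
    n_loci: int,
    seed: int,
    population_labels: list[str] | None = None,
) -> GenotypeDataset:
    """Simulate a diploid SSR dataset under a demographic scenario.

    Each group contributes ``sample_sizes[g]`` diploid individuals; the
    2n haploid genomes per group are simulated jointly per locus and paired
    consecutively (haploids are exchangeable, so this is random pairing).
    Alleles are reported as fragment sizes in nucleotides.
    """
    sizes_nt, deme0 = _simulate_size_matrix(scn, params, mut, sample_sizes, n_loci, seed)
    labels = population_labels or [f"Pop{g + 1}" for g in range(scn.n_groups)]
    individuals, populations = [], []
    for g, s in enumerate(sample_sizes):
        individuals.extend(f"{labels[g]}_{i + 1}" for i in range(s))
        populations.extend([labels[g]] * s)
    n = len(individuals)
    calls = np.empty((n, n_loci, 2), np.int64)
    calls[:, :, 0] = sizes_nt[:, 0::2].T
    calls[:, :, 1] = sizes_nt[:, 1::2].T
    loci = [f"L{j + 1}" for j in range(n_loci)]
    return GenotypeDataset(individuals, populations, loci, calls)


# ---------------------------------------------------------------------------
# summary statistics
# ---------------------------------------------------------------------------

PER_GROUP_STATS = ("A", "H", "V", "M")
PER_PAIR_STATS = ("FST", "DAS", "DM2")


def stat_names(n_groups: int) -> list[str]:
    names = [f"{s}_{g + 1}" for s in PER_GROUP_STATS for g in range(n_groups)]
    for s in PER_PAIR_STATS:
        for a in range(n_groups):
            for b in range(a + 1, n_groups):
                names.append(f"{s}_{a + 1}_{b + 1}")
    return names


#: canonical column order for 4-group reference tables
STAT_COLUMNS = stat_names(4)


@dataclass(frozen=True)
class SummaryStatVector:
    """Fixed-order named vector of ABC summary statistics."""

    values: pd.Series

    @property
    def names(self) -> list[str]:
        return list(self.values.index)

    def to_numpy(self) -> np.ndarray:
        return self.values.to_numpy(dtype=float)

    def __getitem__(self, key: str) -> float:
        return float(self.values[key])


def _stats_from_arrays(
    sizes_nt: np.ndarray, group_of: np.ndarray, motif_length: int = 2
) -> SummaryStatVector:
    """Summary statistics from the haploid allele-size matrix.

    Per group: A (mean alleles/locus), H (mean genic diversity 1 - sum p^2),
    V (mean allele-size variance in squared repeat units), M (mean
    Garza-Williamson ratio, alleles / (repeat-unit range + 1)). Per group
    pair: FST ((HT - HS)/HT on loci-averaged heterozygosities), DAS (one
    minus the mean proportion of shared alleles between cross-group diploid
    genotypes), and (delta mu)^2 (squared difference of mean allele size in
    repeat units, averaged over loci).

    ``group_of`` must assign a group per haploid column, with the two
    haploids of each diploid adjacent; columns are re-sorted by group
    (stable, preserving pairs) before the computation. Loci where a group
    is entirely missing are dropped from that group's means.
    """
    group_of = np.asarray(group_of)
    groups = np.unique(group_of)
    # stable sort of diploid pairs by group keeps haploid pairs adjacent
    n_dip = group_of.size // 2
    dip_group = group_of[0::2]
    order_dip = np.argsort(dip_group, kind="stable")
    cols = np.empty(group_of.size, np.int64)
    cols[0::2] = 2 * order_dip
    cols[1::2] = 2 * order_dip + 1
    sizes = np.ascontiguousarray(sizes_nt[:, cols])
    sorted_groups = dip_group[order_dip]
    gstart = np.zeros(groups.size + 1, np.int64)
    for k, g in enumerate(groups):
        gstart[k + 1] = gstart[k] + 2 * int((sorted_groups == g).sum())
    out = summary_stats_kernel(sizes, gstart, float(motif_length))
    names = stat_names(groups.size)
    vec = pd.Series(out, index=names)
    if vec.isna().any():
        logger.warning(
            "groups with all-missing loci produced undefined statistics: %s",
            list(vec.index[vec.isna()]),
        )
    return SummaryStatVector(vec)


def summary_stats(
    dataset: GenotypeDataset,
    grouping: dict[str, int] | None = None,
    motif_length: int = 2,
) -> SummaryStatVector:
    """ABC summary-statistic vector of a genotype dataset.

    ``grouping`` maps population label to 1-based group number; by default
    each population is its own group in label order.
    """
    pops = dataset.population_labels
    if grouping is None:
        grouping = {p: i + 1 for i, p in enumerate(pops)}
    group_per_ind = np.array([grouping[p] - 1 for p in dataset.populations])
    group_of = np.repeat(group_per_ind, 2)
    sizes_nt = np.empty((dataset.n_loci, 2 * dataset.n), np.int64)
    for j in range(dataset.n_loci):
        sizes_nt[j, 0::2] = dataset.calls[:, j, 0]
        sizes_nt[j, 1::2] = dataset.calls[:, j, 1]
    sizes_nt[sizes_nt == MISSING] = -1
    return _stats_from_arrays(sizes_nt, group_of, motif_length)


# ---------------------------------------------------------------------------
# reference tables and ABC
# ---------------------------------------------------------------------------


def build_reference_table(
    scn: DemographicScenario,
    n_draws: int,
    sample_sizes: list[int],
    n_loci: int,
    seed: int,
    prior: PriorConfig | None = None,
) -> pd.DataFrame:
    """Simulate ``n_draws`` datasets from the prior and summarize each.

    Returns a table with one row per simulation: scenario id, demographic
    parameters, mutation hyper-parameter means, and the summary statistics.
    """
    prior = prior or PriorConfig()
    seeds = np.random.SeedSequence(seed).generate_state(3)
    draws = sample_priors(scn, n_draws, int(seeds[0]), prior)
    rng = np.random.default_rng(int(seeds[1]))
    sim_seeds = np.random.default_rng(int(seeds[2])).integers(0, 2**31 - 1, n_draws)
    rows = []
    for i in range(n_draws):
        params = ScenarioParameters.from_row(draws.iloc[i])
        mut = MutationModel.from_priors(n_loci, rng, prior)
        sizes_nt, deme0 = _simulate_size_matrix(
            scn, params, mut, sample_sizes, n_loci, int(sim_seeds[i])
        )
        stats = _stats_from_arrays(sizes_nt, deme0, mut.motif_length)
        row = {"scenario": scn.scenario_id, **draws.iloc[i].to_dict()}
        row.update(mean_mu=mut.mean_mu, mean_p=mut.mean_p, mean_sni=mut.mean_sni)
        row.update(stats.values.to_dict())
        rows.append(row)
    return pd.DataFrame(rows)


def _stat_cols(reference: pd.DataFrame, observed: SummaryStatVector) -> list[str]:
    return [c for c in observed.names if c in reference.columns]


def _standardized_distances(
    observed: SummaryStatVector,
    reference: pd.DataFrame,
    sd: pd.Series | None = None,
) -> np.ndarray:
    cols = _stat_cols(reference, observed)
    if not cols:
        raise ValueError("reference table shares no statistic columns with observed")
    x = reference[cols].to_numpy(dtype=float)
    obs = observed.values[cols].to_numpy(dtype=float)
    if sd is None:
        sd = reference[cols].std(ddof=1)
    sd = sd[cols].to_numpy(dtype=float)
    keep = sd > 0
    if not keep.all():
        dropped = [c for c, k in zip(cols, keep) if not k]
        logger.warning("zero-variance statistics excluded from distance: %s", dropped)
    if not keep.any():
        raise ValueError("every statistic has zero variance in the reference table")
    z = (x[:, keep] - obs[keep]) / sd[keep]
    return np.sqrt((z**2).sum(axis=1))


def abc_reject(
    observed: SummaryStatVector, reference: pd.DataFrame, tolerance: float
) -> pd.DataFrame:
    """Keep the closest ceil(tolerance * rows) simulations.

    Distance is Euclidean on statistics standardized by the reference
    table's standard deviation; zero-variance statistics are excluded with
    a warning. The returned frame carries a ``distance`` column and is
    sorted ascending.
    """
    if reference.empty:
        raise ValueError("reference table is empty")
    if not 0.0 < tolerance <= 1.0:
        raise ValueError("tolerance must be in (0, 1]")
    d = _standardized_distances(observed, reference)
    n_keep = math.ceil(tolerance * len(reference))
    order = np.argsort(d, kind="stable")[:n_keep]
    out = reference.iloc[order].copy()
    out["distance"] = d[order]
    return out


@dataclass
class ScenarioPosterior:
    """Posterior scenario probabilities with confidence intervals."""

    probabilities: dict[int, float]
    intervals: dict[int, tuple[float, float]]
    method: str
    n_closest: int

    @property
    def best_scenario(self) -> int:
        return max(self.probabilities, key=self.probabilities.get)

    def to_frame(self) -> pd.DataFrame:
        sids = sorted(self.probabilities)
        return pd.DataFrame(
            {
                "posterior_probability": [self.probabilities[s] for s in sids],
                "ci_low": [self.intervals[s][0] for s in sids],
                "ci_high": [self.intervals[s][1] for s in sids],
            },
            index=pd.Index(sids, name="scenario"),
        )


def _wilson(p: float, n: int) -> tuple[float, float]:
    z = 1.959963984540054
    if n == 0:
        return (0.0, 1.0)
    denom = 1 + z**2 / n
    centre = (p + z**2 / (2 * n)) / denom
    half = z / denom * math.sqrt(p * (1 - p) / n + z**2 / (4 * n**2))
    return (max(centre - half, 0.0), min(centre + half, 1.0))


def scenario_posterior_logistic(
    observed: SummaryStatVector,
    references: dict[int, pd.DataFrame],
    n_closest: int,
    seed: int = 0,
) -> ScenarioPosterior:
    """Scenario choice by multinomial logistic regression.

    The per-scenario reference tables are pooled, the ``n_closest``
    simulations to the observed vector (standardized Euclidean distance on
    the pooled table) are retained, and a multinomial logit of scenario
    label on the standardized statistics is evaluated at the observed
    point. Confidence intervals come from the fit covariance by the delta
    method, clipped to [0, 1]. When the regression is degenerate (perfect
    separation, a scenario absent from the closest set, singular design)
    the method falls back to the rejection frequencies with Wilson
    intervals.
    """
    if len(references) < 2:
        raise ValueError("need at least two scenarios")
    pooled = pd.concat(references.values(), ignore_index=True)
    if n_closest > len(pooled):
        raise ValueError("n_closest exceeds the pooled table size")
    cols = _stat_cols(pooled, observed)
    sd = pooled[cols].std(ddof=1)
    mean = pooled[cols].mean()
    d = _standardized_distances(observed, pooled, sd)
    idx = np.argsort(d, kind="stable")[:n_closest]
    subset = pooled.iloc[idx]
    sids = sorted(references.keys())
    counts = subset["scenario"].value_counts()
    missing_sids = [s for s in sids if counts.get(s, 0) == 0]
    if missing_sids:
        logger.warning(
            "scenarios %s absent from the %d closest simulations; probabilities floored at 0",
            missing_sids,
            n_closest,
        )
    probs, intervals = _fit_mnlogit(observed, subset, cols, mean, sd, sids)
    if probs is None:
        frac = {s: counts.get(s, 0) / n_closest for s in sids}
        intervals = {s: _wilson(frac[s], n_closest) for s in sids}
        return ScenarioPosterior(frac, intervals, "rejection", n_closest)
    return ScenarioPosterior(probs, intervals, "logistic", n_closest)


def _fit_mnlogit(observed, subset, cols, mean, sd, sids, ridge: float = 1e-2):
    """Ridge-penalized multinomial logit of scenario on standardized stats.

    A small L2 penalty keeps the fit defined under the (common) complete
    separation of well-distinguished scenarios. The covariance is the
    inverse penalized Hessian at the optimum, in the reference-class
    parametrization; probability CIs follow by the delta method.
    """
    from sklearn.linear_model import LogisticRegression

    present = [s for s in sids if (subset["scenario"] == s).any()]
    if len(present) < 2:
        return None, None
    keep = [c for c in cols if sd[c] > 0]
    z = ((subset[keep] - mean[keep]) / sd[keep]).to_numpy(dtype=float)
    y = subset["scenario"].map({s: i for i, s in enumerate(present)}).to_numpy()
    z0 = ((observed.values[keep] - mean[keep]) / sd[keep]).to_numpy(dtype=float)
    n_classes = len(present)
    try:
        clf = LogisticRegression(C=1.0 / ridge, max_iter=5000)
        clf.fit(z, y)
    except Exception as exc:  # pragma: no cover - degenerate design
        logger.warning("logistic scenario choice failed (%s); using rejection", exc)
        return None, None
    # reference-class coefficients: b_j = w_j - w_0 for class j > 0
    if clf.coef_.shape[0] == 1:  # binary parametrization
        b_mat = np.concatenate([[clf.intercept_[0]], clf.coef_[0]])[:, None]
    else:
        w = np.hstack([clf.intercept_[:, None], clf.coef_])
        b_mat = (w - w[0])[1:].T
    x = np.hstack([np.ones((z.shape[0], 1)), z])
    x0 = np.concatenate([[1.0], z0])
    d1 = x.shape[1]

    def probs_at(xrow, vec):
        b = vec.reshape(d1, n_classes - 1, order="F")
        eta = np.concatenate([[0.0], xrow @ b])
        eta -= eta.max()
        e = np.exp(eta)
        return e / e.sum()

    vec0 = b_mat.flatten(order="F")
    pmat = np.vstack([probs_at(x[i], vec0) for i in range(x.shape[0])])
    dim = d1 * (n_classes - 1)
    hess = np.zeros((dim, dim))
    for j in range(1, n_classes):
        for k in range(1, n_classes):
            wgt = pmat[:, j] * ((1.0 if j == k else 0.0) - pmat[:, k])
            hess[(j - 1) * d1 : j * d1, (k - 1) * d1 : k * d1] = x.T @ (x * wgt[:, None])
    for j in range(n_classes - 1):
        for t in range(1, d1):  # penalize slopes, not intercepts
            hess[j * d1 + t, j * d1 + t] += ridge
    cov = np.linalg.pinv(hess)
    p = probs_at(x0, vec0)
    h = 1e-6
    grads = np.zeros((p.size, dim))
    for j in range(dim):
        vp = vec0.copy()
        vp[j] += h
        grads[:, j] = (probs_at(x0, vp) - p) / h
    var = np.clip(np.einsum("ij,jk,ik->i", grads, cov, grads), 0.0, None)
    half = 1.959963984540054 * np.sqrt(var)
    probs = {s: 0.0 for s in sids}
    intervals = {s: (0.0, 0.0) for s in sids}
    for i, s in enumerate(present):
        probs[s] = float(p[i])
        intervals[s] = (float(max(p[i] - half[i], 0.0)), float(min(p[i] + half[i], 1.0)))
    return probs, intervals


# ---------------------------------------------------------------------------
# parameter adjustment
# ---------------------------------------------------------------------------


@dataclass
class AdjustedPosterior:
    """Local-linear-adjusted posterior samples for the chosen scenario."""

    samples: pd.DataFrame
    medians: pd.Series
    q025: pd.Series
    q975: pd.Series
    adjusted: bool

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"median": self.medians, "q2.5": self.q025, "q97.5": self.q975}
        )


def adjust_parameters_loclinear(
    observed: SummaryStatVector,
    accepted: pd.DataFrame,
    parameters: list[str] | None = None,
    n_components: int | None = 3,
) -> AdjustedPosterior:
    """Beaumont-style local-linear regression adjustment.

    Each parameter is regressed on the accepted simulations' statistics
    with Epanechnikov weights in the rejection distance; adjusted draws are
    the fitted value at the observed point plus the residuals. Size (N*)
    and time (t*) parameters are log-transformed before the regression and
    back-transformed after.

    By default the standardized statistics are first reduced to
    ``n_components`` partial-least-squares components fitted jointly
    against all (transformed) parameters; regressing on a few supervised
    components instead of the full statistic vector keeps the adjustment
    from overfitting a small accepted set, which would yield overconfident
    posteriors. Pass ``n_components=None`` for the classic full-statistics
    regression. A rank-deficient design falls back to the unadjusted
    rejection posterior with a warning.
    """
    if parameters is None:
        parameters = [
            c
            for c in accepted.columns
            if (c.startswith(("N", "t")) and c != "scenario") or c == "ra"
        ]
    if len(accepted) < 2 * len(parameters):
        raise ValueError("accepted set too small for the regression")
    cols = _stat_cols(accepted, observed)
    sd = accepted[cols].std(ddof=1)
    keep = [c for c in cols if sd[c] > 0]
    mean = accepted[keep].mean()
    z = ((accepted[keep] - mean) / sd[keep]).to_numpy(dtype=float)
    z0 = ((observed.values[keep] - mean) / sd[keep]).to_numpy(dtype=float)

    transforms: dict[str, bool] = {}
    ty_all: dict[str, np.ndarray] = {}
    for par in parameters:
        y = accepted[par].to_numpy(dtype=float)
        log_scale = par[0] in ("N", "t") and np.all(y > 0)
        transforms[par] = log_scale
        ty_all[par] = np.log(y) if log_scale else y

    if n_components is not None and len(keep) > n_components:
        try:
            from sklearn.cross_decomposition import PLSRegression

            nc = int(min(n_components, len(keep), len(accepted) - 1))
            y_block = np.column_stack(
                [ty_all[p] for p in parameters if np.ptp(ty_all[p]) > 0]
            )
            pls = PLSRegression(n_components=nc, scale=False).fit(z, y_block)
            z = pls.transform(z)
            z0 = pls.transform(z0[None, :])[0]
        except Exception as exc:  # degenerate accepted set
            logger.warning("PLS reduction failed (%s); using full statistics", exc)

    x = np.hstack([np.ones((len(accepted), 1)), z])
    x0 = np.concatenate([[1.0], z0])
    if "distance" in accepted.columns:
        dmax = float(accepted["distance"].max())
        w = (
            1.0 - (accepted["distance"].to_numpy() / dmax) ** 2
            if dmax > 0
            else np.ones(len(accepted))
        )
        w = np.clip(w, 1e-12, None)
    else:
        w = np.ones(len(accepted))
    sw = np.sqrt(w)[:, None]

    adjusted = True
    if np.linalg.matrix_rank(sw * x) < x.shape[1]:
        logger.warning("singular local-linear design; returning rejection posterior")
        adjusted = False

    out = {}
    for par in parameters:
        ty = ty_all[par]
        if adjusted and np.ptp(ty) > 0:
            beta, *_ = np.linalg.lstsq(sw * x, sw[:, 0] * ty, rcond=None)
            adj = x0 @ beta + (ty - x @ beta)
        else:
            adj = ty
        out[par] = np.exp(adj) if transforms[par] else adj
    samples = pd.DataFrame(out)
    return AdjustedPosterior(
        samples=samples,
        medians=samples.median(),
        q025=samples.quantile(0.025),
        q975=samples.quantile(0.975),
        adjusted=adjusted,
    )


def convert_generations(t: float, generation_time: float = 100.0) -> float:
    """Generations to calendar age in ka BP (thousands of years)."""
    if t <= 0:
        raise ValueError("t must be positive")
    return t * generation_time / 1000.0


# ---------------------------------------------------------------------------
# model checking PCA
# ---------------------------------------------------------------------------


@dataclass
class ModelCheckResult:
    """PCA projection of the observed point into the simulated cloud."""

    observed_coordinates: np.ndarray
    simulated_coordinates: np.ndarray
    explained_variance_ratio: np.ndarray
    percentile_radius: float


def model_check_pca(
    observed: SummaryStatVector,
    simulated: pd.DataFrame,
    n_components: int = 2,
) -> ModelCheckResult:
    """Project the observed statistics into a PCA of the simulated ones.

    Statistics are standardized by the simulated mean/sd (constant columns
    dropped with a warning); the percentile radius is the fraction of
    simulations whose distance from the cloud centre, in component space,
    is at most the observed point's.
    """
    from sklearn.decomposition import PCA

    if len(simulated) < n_components:
        raise ValueError("need at least n_components simulated rows")
    cols = _stat_cols(simulated, observed)
    sd = simulated[cols].std(ddof=1)
    keep = [c for c in cols if sd[c] > 0]
    if len(keep) < len(cols):
        logger.warning(
            "constant statistics dropped before PCA: %s",
            sorted(set(cols) - set(keep)),
        )
    mean = simulated[keep].mean()
    z = ((simulated[keep] - mean) / sd[keep]).to_numpy(dtype=float)
    z0 = ((observed.values[keep] - mean) / sd[keep]).to_numpy(dtype=float)[None, :]
    pca = PCA(n_components=min(n_components, len(keep)))
    sim_coords = pca.fit_transform(z)
    obs_coords = pca.transform(z0)[0]
    r_sim = np.sqrt((sim_coords**2).sum(axis=1))
    r_obs = float(np.sqrt((obs_coords**2).sum()))
    pct = 100.0 * float(np.mean(r_sim <= r_obs))
    return ModelCheckResult(
        observed_coordinates=obs_coords,
        simulated_coordinates=sim_coords,
        explained_variance_ratio=pca.explained_variance_ratio_,
        percentile_radius=pct,
    )


# ---------------------------------------------------------------------------
# full ABC analysis
# ---------------------------------------------------------------------------


@dataclass
class ABCResult:
    """Scenario posterior plus adjusted parameter posterior for the winner."""

    scenario_posterior: ScenarioPosterior
    best_scenario: int
    parameter_posterior: AdjustedPosterior
    parameter_summary: pd.DataFrame
    generation_time: float

    def to_report(self) -> dict:
        return {
            "scenario_posterior": {
                str(s): {
                    "probability": self.scenario_posterior.probabilities[s],
                    "ci": list(self.scenario_posterior.intervals[s]),
                }
                for s in sorted(self.scenario_posterior.probabilities)
            },
            "best_scenario": self.best_scenario,
            "method": self.scenario_posterior.method,
            "parameters": self.parameter_summary.to_dict(orient="index"),
            "generation_time_years": self.generation_time,
        }


def run_abc(
    observed: SummaryStatVector,
    sample_sizes: list[int],
    n_loci: int,
    seed: int,
    scenario_ids: tuple[int, ...] = (1, 2, 3),
    n_draws: int = 10_000,
    tolerance: float = 0.01,
    n_closest: int | None = None,
    prior: PriorConfig | None = None,
    generation_time: float = 100.0,
) -> ABCResult:
    """End-to-end ABC: reference tables, scenario choice, parameter posterior.

    ``n_closest`` defaults to 1% of the pooled reference rows. Event times
    in the parameter summary are also reported in calendar units (ka BP)
    using ``generation_time`` years per generation.
    """
    seeds = np.random.SeedSequence(seed).generate_state(len(scenario_ids) + 1)
    references = {
        sid: build_reference_table(
            scenario(sid), n_draws, sample_sizes, n_loci, int(seeds[i]), prior
        )
        for i, sid in enumerate(scenario_ids)
    }
    pooled_n = sum(len(t) for t in references.values())
    if n_closest is None:
        n_closest = max(math.ceil(0.01 * pooled_n), 50)
    posterior = scenario_posterior_logistic(
        observed, references, n_closest, int(seeds[-1])
    )
    best = posterior.best_scenario
    par_names = [
        c for c in scenario(best).parameter_names if c in references[best].columns
    ]
    # keep enough rows for the local-linear regression at small table sizes
    min_rows = max(2 * len(par_names) + 2, 50)
    eff_tol = max(tolerance, min(1.0, min_rows / len(references[best])))
    accepted = abc_reject(observed, references[best], eff_tol)
    adjusted = adjust_parameters_loclinear(observed, accepted, par_names)
    summary = adjusted.summary()
    for par in summary.index:
        if par.startswith("t"):
            summary.loc[par, "median_ka"] = convert_generations(
                max(summary.loc[par, "median"], 1e-9), generation_time
            )
    return ABCResult(
        scenario_posterior=posterior,
        best_scenario=best,
        parameter_posterior=adjusted,
        parameter_summary=summary,
        generation_time=generation_time,
    )
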