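"""Diversity, differentiation, gene flow, AMOVA and genetic distances.

Implements the per-population diversity summary (Na, Ne, I, Ho, He, FIS with
standard errors across loci), pairwise and global FST with the island-model
gene-flow transform Nm = (1/FST - 1)/4, the Smouse-Peakall squared
codominant genotypic distance, an individual-level AMOVA with permutation
P-values, and Nei's (1978) unbiased genetic distance.

Conventions
-----------
* He is the biased estimator ``1 - sum p^2`` (the GenAlEx default); the
  unbiased variant ``2n/(2n-1) * He`` is available via ``unbiased=True``.
* Population-level FIS is the mean of per-locus ``(He - Ho)/He`` over
  polymorphic loci, with its standard error across loci.
* The default pairwise FST is ``(HT - HS)/HT`` with HT from the unweighted
  mean of the two populations' allele frequencies, each averaged over loci;
  Weir & Cockerham's theta is available via ``estimator="wc"``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotype_core import MISSING, GenotypeDataset

__all__ = [
    "DiversitySummary",
    "DifferentiationResult",
    "AMOVATable",
    "DistanceMatrix",
    "allele_frequencies",
    "diversity_per_locus",
    "fis",
    "population_summary",
    "pairwise_fst",
    "global_fst",
    "nm_from_fst",
    "squared_genotypic_distance",
    "genotypic_distance_matrix",
    "amova",
    "nei_distance",
    "NEI_INFINITE_DISTANCE",
]

logger = logging.getLogger(__name__)

#: sentinel for an infinite Nei distance (zero shared identity)
NEI_INFINITE_DISTANCE = 1e9


# ---------------------------------------------------------------------------
# allele frequencies and per-locus diversity
# ---------------------------------------------------------------------------


def allele_frequencies(
    dataset: GenotypeDataset, population: str, locus: str
) -> pd.Series:
    """Observed allele-state frequencies in one population at one locus.

    Missing genotypes are dropped from the denominator (missing-aware
    counting over 2 x n_called alleles). Returns a Series indexed by allele
    state, summing to 1. Raises ``ValueError`` when every call is missing.
    """
    idx = dataset.indices_of(population)
    j = dataset.loci.index(locus)
    calls = dataset.calls[idx, j, :]
    alleles = calls[calls[:, 0] != MISSING].ravel()
    if alleles.size == 0:
        raise ValueError(f"population {population!r} is all-missing at {locus!r}")
    states, counts = np.unique(alleles, return_counts=True)
    return pd.Series(counts / alleles.size, index=states, name=f"{population}:{locus}")


def _freq_matrix(dataset: GenotypeDataset, locus_index: int) -> pd.DataFrame:
    """Per-population frequency vectors at one locus (pops x allele states).

    Rows are NaN-free; a population with no data at the locus gets NaN.
    """
    j = locus_index
    rows = {}
    all_states = np.unique(dataset.calls[:, j, :][dataset.calls[:, j, 0] != MISSING])
    for pop in dataset.population_labels:
        idx = dataset.indices_of(pop)
        calls = dataset.calls[idx, j, :]
        alleles = calls[calls[:, 0] != MISSING].ravel()
        if alleles.size == 0:
            rows[pop] = pd.Series(np.nan, index=all_states)
            continue
        states, counts = np.unique(alleles, return_counts=True)
        v = pd.Series(0.0, index=all_states)
        v[states] = counts / alleles.size
        rows[pop] = v
    return pd.DataFrame(rows).T


def diversity_per_locus(
    freqs: np.ndarray | pd.Series, genotypes: np.ndarray | None = None
) -> tuple[float, float, float, float, float]:
    """(Na, Ne, I, Ho, He) for one locus from its frequency vector.

    Na = number of alleles with p > 0; Ne = 1/sum p^2; I = -sum p ln p;
    He = 1 - sum p^2. Ho is the fraction of non-missing genotypes with two
    distinct allele states (NaN when ``genotypes`` is not given).
    """
    p = np.asarray(freqs, dtype=float)
    p = p[p > 0]
    ss = float(np.sum(p**2))
    na = int(p.size)
    ne = 1.0 / ss
    shannon = float(-np.sum(p * np.log(p)))
    he = 1.0 - ss
    ho = np.nan
    if genotypes is not None:
        g = np.asarray(genotypes)
        g = g[g[:, 0] != MISSING]
        if g.shape[0]:
            ho = float(np.mean(g[:, 0] != g[:, 1]))
    return na, ne, shannon, ho, he


def fis(ho: float, he: float) -> float:
    """Inbreeding coefficient FIS = (He - Ho)/He; NaN when He = 0.

    A monomorphic locus has no heterozygosity to lose, so FIS is undefined
    there (reported blank, matching the usual table convention).
    """
    if he < 0:
        raise ValueError("He must be nonnegative")
    if he == 0:
        return np.nan
    return (he - ho) / he


# ---------------------------------------------------------------------------
# per-population summary (diversity table)
# ---------------------------------------------------------------------------


@dataclass
class DiversitySummary:
    """Per-population diversity means with standard errors across loci.

    ``per_population`` holds one row per population with columns
    ``Na, Ne, I, Ho, He, Fis`` and ``<stat>_se``; ``per_species`` (optional)
    averages population values within species, with SE across populations.
    """

    per_population: pd.DataFrame
    per_locus: pd.DataFrame
    per_species: pd.DataFrame | None = None

    def formatted(self, decimals: int = 3) -> pd.DataFrame:
        """'value ± SE' presentation table."""
        stats = ["Na", "Ne", "I", "Ho", "He", "Fis"]
        out = {}
        for s in stats:
            out[s] = [
                f"{v:.{decimals}f} ± {se:.{decimals}f}" if np.isfinite(v) else ""
                for v, se in zip(
                    self.per_population[s], self.per_population[f"{s}_se"]
                )
            ]
        return pd.DataFrame(out, index=self.per_population.index)


def _se(x: np.ndarray) -> float:
    x = x[np.isfinite(x)]
    if x.size < 2:
        return 0.0
    return float(np.std(x, ddof=1) / np.sqrt(x.size))


def population_summary(
    dataset: GenotypeDataset,
    species_of: dict[str, str] | None = None,
    unbiased: bool = False,
) -> DiversitySummary:
    """Na/Ne/I/Ho/He/FIS per population, mean ± SE across loci.

    FIS is averaged over polymorphic loci only. With ``species_of`` mapping
    population label to species, species-level mean rows (SE across
    populations) are added, mirroring a two-species summary table.
    """
    records = []
    for pop in dataset.population_labels:
        idx = dataset.indices_of(pop)
        if idx.size == 0:
            raise ValueError(f"population {pop!r} is empty")
        n_ok = 0
        for j, locus in enumerate(dataset.loci):
            calls = dataset.calls[idx, j, :]
            alleles = calls[calls[:, 0] != MISSING].ravel()
            if alleles.size == 0:
                continue
            n_ok += 1
            states, counts = np.unique(alleles, return_counts=True)
            p = counts / alleles.size
            na, ne, shannon, ho, he = diversity_per_locus(p, calls)
            if unbiased:
                n2 = alleles.size
                he = he * n2 / (n2 - 1) if n2 > 1 else he
            records.append(
                {
                    "population": pop,
                    "locus": locus,
                    "Na": na,
                    "Ne": ne,
                    "I": shannon,
                    "Ho": ho,
                    "He": he,
                    "Fis": fis(ho, he),
                }
            )
        if n_ok == 0:
            raise ValueError(f"population {pop!r} has no scored loci")
    per_locus = pd.DataFrame(records)

    rows = {}
    for pop, grp in per_locus.groupby("population", sort=False):
        row = {}
        for s in ["Na", "Ne", "I", "Ho", "He", "Fis"]:
            vals = grp[s].to_numpy(dtype=float)
            finite = vals[np.isfinite(vals)]
            row[s] = float(finite.mean()) if finite.size else np.nan
            row[f"{s}_se"] = _se(vals)
        rows[pop] = row
    per_pop = pd.DataFrame(rows).T.loc[dataset.population_labels]

    per_species = None
    if species_of is not None:
        srows = {}
        species_order = list(dict.fromkeys(species_of.values()))
        for sp in species_order:
            pops = [p for p in per_pop.index if species_of.get(p) == sp]
            if not pops:
                continue
            sub = per_pop.loc[pops]
            row = {}
            for s in ["Na", "Ne", "I", "Ho", "He", "Fis"]:
                vals = sub[s].to_numpy(dtype=float)
                row[s] = float(np.nanmean(vals))
                row[f"{s}_se"] = _se(vals)
            srows[sp] = row
        per_species = pd.DataFrame(srows).T
    return DiversitySummary(per_pop, per_locus, per_species)


# ---------------------------------------------------------------------------
# differentiation and gene flow
# ---------------------------------------------------------------------------


@dataclass
class DifferentiationResult:
    """Pairwise FST / Nm matrices plus optional global per-group values."""

    fst: pd.DataFrame
    nm: pd.DataFrame
    estimator: str = "ht_hs"

    def combined_table(self) -> pd.DataFrame:
        """Nm above the diagonal, FST below, zeros on the diagonal."""
        labels = self.fst.index
        out = pd.DataFrame(0.0, index=labels, columns=labels)
        for i, a in enumerate(labels):
            for j, b in enumerate(labels):
                if i < j:
                    out.loc[a, b] = self.nm.loc[a, b]
                elif i > j:
                    out.loc[a, b] = self.fst.loc[a, b]
        return out


def nm_from_fst(fst: float) -> float:
    """Island-model gene flow Nm = (1/FST - 1)/4; NaN for FST <= 0."""
    if not np.isfinite(fst) or fst <= 0:
        return np.nan
    return (1.0 / fst - 1.0) / 4.0


def _pair_fst_ht_hs(dataset: GenotypeDataset, pops: list[str]) -> float:
    """(HT - HS)/HT, HT from the unweighted mean frequency vector of the
    groups, HS the mean within-group He; both averaged over loci first."""
    hts, hss = [], []
    for j in range(dataset.n_loci):
        fm = _freq_matrix(dataset, j).loc[pops]
        if fm.isna().any(axis=None):
            continue
        hs = float(np.mean(1.0 - (fm.to_numpy() ** 2).sum(axis=1)))
        pbar = fm.to_numpy().mean(axis=0)
        ht = float(1.0 - np.sum(pbar**2))
        hts.append(ht)
        hss.append(hs)
    ht_bar, hs_bar = float(np.mean(hts)), float(np.mean(hss))
    if ht_bar <= 0:
        return 0.0  # jointly monomorphic across all loci
    return (ht_bar - hs_bar) / ht_bar


def _pair_fst_wc(dataset: GenotypeDataset, pops: list[str]) -> float:
    """Weir & Cockerham (1984) theta over the given populations, all loci
    and alleles pooled as sum(a) / sum(a + b + c)."""
    num = den = 0.0
    r = len(pops)
    for j in range(dataset.n_loci):
        ns, freqs, hets = [], [], []
        for pop in pops:
            idx = dataset.indices_of(pop)
            calls = dataset.calls[idx, j, :]
            calls = calls[calls[:, 0] != MISSING]
            if calls.shape[0] == 0:
                break
            ns.append(calls.shape[0])
            alleles = calls.ravel()
            states, counts = np.unique(alleles, return_counts=True)
            freqs.append(dict(zip(states.tolist(), counts / alleles.size)))
            hets.append(calls)
        else:
            n = np.array(ns, dtype=float)
            nbar = n.mean()
            if r < 2 or nbar <= 1:
                continue
            nc = (r * nbar - np.sum(n**2) / (r * nbar)) / (r - 1)
            states = sorted({s for f in freqs for s in f})
            for st in states:
                p = np.array([f.get(st, 0.0) for f in freqs])
                h = np.array(
                    [
                        np.mean((c[:, 0] != c[:, 1]) & ((c[:, 0] == st) | (c[:, 1] == st)))
                        for c in hets
                    ]
                )
                pbar = float(np.sum(n * p) / (r * nbar))
                s2 = float(np.sum(n * (p - pbar) ** 2) / ((r - 1) * nbar))
                hbar = float(np.sum(n * h) / (r * nbar))
                if nc <= 0:
                    continue
                a = (nbar / nc) * (
                    s2
                    - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4.0) / (nbar - 1)
                )
                b = (nbar / (nbar - 1)) * (
                    pbar * (1 - pbar)
                    - (r - 1) / r * s2
                    - (2 * nbar - 1) / (4 * nbar) * hbar
                )
                c_ = hbar / 2.0
                num += a
                den += a + b + c_
    if den == 0:
        return 0.0
    return num / den


def pairwise_fst(
    dataset: GenotypeDataset, estimator: str = "ht_hs"
) -> DifferentiationResult:
    """Pairwise FST (and Nm) between all populations.

    ``estimator``: ``"ht_hs"`` (default, GenAlEx-style (HT-HS)/HT) or
    ``"wc"`` (Weir-Cockerham theta).
    """
    pops = dataset.population_labels
    if len(pops) < 2:
        raise ValueError("need at least two populations")
    pair_fn = {"ht_hs": _pair_fst_ht_hs, "wc": _pair_fst_wc}[estimator]
    fst = pd.DataFrame(0.0, index=pops, columns=pops)
    for i, a in enumerate(pops):
        for b in pops[i + 1 :]:
            v = pair_fn(dataset, [a, b])
            fst.loc[a, b] = fst.loc[b, a] = v
    nm = fst.map(nm_from_fst)
    np.fill_diagonal(nm.values, np.nan)
    return DifferentiationResult(fst=fst, nm=nm, estimator=estimator)


def global_fst(
    dataset: GenotypeDataset,
    populations: list[str] | None = None,
    estimator: str = "ht_hs",
) -> float:
    """Multi-population global FST over the given (default: all) populations."""
    pops = populations or dataset.population_labels
    pair_fn = {"ht_hs": _pair_fst_ht_hs, "wc": _pair_fst_wc}[estimator]
    return pair_fn(dataset, list(pops))


# ---------------------------------------------------------------------------
# Smouse-Peakall genotypic distance and AMOVA
# ---------------------------------------------------------------------------


def squared_genotypic_distance(
    g1: tuple[int, int] | np.ndarray, g2: tuple[int, int] | np.ndarray
) -> int:
    """Smouse-Peakall squared codominant distance at one locus.

    Half the squared Euclidean distance between the two genotypes'
    allele-count vectors: (AA,AA)=0, (AA,AB)=1, (AB,CD)=2, (AA,BC)=3,
    (AA,BB)=4. Both genotypes must be non-missing.
    """
    a = tuple(int(x) for x in g1)
    b = tuple(int(x) for x in g2)
    if MISSING in a or MISSING in b:
        raise ValueError("genotypes must be non-missing")
    states = sorted(set(a) | set(b))
    ca = np.array([a.count(s) for s in states])
    cb = np.array([b.count(s) for s in states])
    return int(round(0.5 * np.sum((ca - cb) ** 2)))


def genotypic_distance_matrix(dataset: GenotypeDataset) -> np.ndarray:
    """Multilocus squared genotypic distances between all individuals.

    Per-locus distances are summed over loci where both individuals are
    scored (pairwise deletion of missing data).
    """
    n = dataset.n
    total = np.zeros((n, n))
    for j in range(dataset.n_loci):
        calls = dataset.calls[:, j, :]
        ok = calls[:, 0] != MISSING
        states = np.unique(calls[ok])
        if states.size == 0:
            continue
        counts = np.zeros((n, states.size))
        for s_idx, s in enumerate(states):
            counts[:, s_idx] = (calls == s).sum(axis=1)
        sq = (counts**2).sum(axis=1)
        d2 = 0.5 * (sq[:, None] + sq[None, :] - 2.0 * counts @ counts.T)
        d2[~ok, :] = 0.0
        d2[:, ~ok] = 0.0
        total += d2
    np.fill_diagonal(total, 0.0)
    return total


@dataclass
class AMOVATable:
    """Among/within-population partition of squared genotypic distances."""

    df_among: int
    df_within: int
    ss_among: float
    ss_within: float
    var_among: float
    var_within: float
    p_value: float
    n_permutations: int

    @property
    def df_total(self) -> int:
        return self.df_among + self.df_within

    @property
    def ss_total(self) -> float:
        return self.ss_among + self.ss_within

    @property
    def var_total(self) -> float:
        return self.var_among + self.var_within

    @property
    def phi_st(self) -> float:
        return self.var_among / self.var_total if self.var_total > 0 else 0.0

    def percentages(self) -> tuple[float, float]:
        """(among %, within %) of total molecular variance."""
        tot = self.var_total
        if tot <= 0:
            return 0.0, 0.0
        return 100.0 * self.var_among / tot, 100.0 * self.var_within / tot

    def to_dataframe(self) -> pd.DataFrame:
        pa, pw = self.percentages()
        return pd.DataFrame(
            {
                "df": [self.df_among, self.df_within, self.df_total],
                "SS": [self.ss_among, self.ss_within, self.ss_total],
                "variance": [self.var_among, self.var_within, self.var_total],
                "pct_of_variation": [round(pa), round(pw), 100],
                "P": [self.p_value, self.p_value, np.nan],
            },
            index=["Among populations", "Within populations", "Total"],
        )


def _amova_components(
    d2: np.ndarray, groups: np.ndarray
) -> tuple[float, float, float, float, int, int]:
    n = d2.shape[0]
    labels, counts = np.unique(groups, return_counts=True)
    k = labels.size
    ss_total = d2.sum() / (2.0 * n)
    ss_within = 0.0
    for lab in labels:
        idx = np.flatnonzero(groups == lab)
        ss_within += d2[np.ix_(idx, idx)].sum() / (2.0 * idx.size)
    ss_among = ss_total - ss_within
    df_among, df_within = k - 1, n - k
    ms_within = ss_within / df_within
    n0 = (n - np.sum(counts**2) / n) / (k - 1)
    var_among = (ss_among / df_among - ms_within) / n0
    return ss_among, ss_within, var_among, ms_within, df_among, df_within


def amova(
    dataset: GenotypeDataset,
    n_permutations: int = 999,
    seed: int = 0,
    populations: list[str] | None = None,
) -> AMOVATable:
    """One-level AMOVA (among vs within populations) with permutation test.

    Uses individual-level Smouse-Peakall squared distances; variance
    components by the usual method of moments with the unequal-sample-size
    coefficient n0. The P-value is the fraction of random relabellings of
    individuals whose among-population component reaches the observed one,
    with the +1 correction.
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    if populations is not None:
        dataset = dataset.subset_populations(populations)
    groups = np.asarray(dataset.populations)
    labels, counts = np.unique(groups, return_counts=True)
    if labels.size < 2:
        raise ValueError("AMOVA needs at least two populations")
    if counts.min() < 2:
        raise ValueError("every population needs at least two individuals")
    d2 = genotypic_distance_matrix(dataset)
    ss_a, ss_w, var_a, var_w, df_a, df_w = _amova_components(d2, groups)

    rng = np.random.default_rng(seed)
    hits = 0
    perm = groups.copy()
    for _ in range(n_permutations):
        rng.shuffle(perm)
        v = _amova_components(d2, perm)[2]
        if v >= var_a:
            hits += 1
    p = (hits + 1) / (n_permutations + 1)
    return AMOVATable(
        df_among=df_a,
        df_within=df_w,
        ss_among=ss_a,
        ss_within=ss_w,
        var_among=var_a,
        var_within=var_w,
        p_value=p,
        n_permutations=n_permutations,
    )


# ---------------------------------------------------------------------------
# Nei (1978) unbiased genetic distance
# ---------------------------------------------------------------------------


@dataclass
class DistanceMatrix:
    """Labeled symmetric nonnegative distance matrix with zero diagonal."""

    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        k = len(self.labels)
        if self.values.shape != (k, k):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(self.values, self.values.T, equal_nan=True):
            raise ValueError("distance matrix must be symmetric")
        if np.nanmin(self.values) < 0:
            raise ValueError("distances must be nonnegative")

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "DistanceMatrix":
        return cls(list(df.index), df.to_numpy(dtype=float))


def nei_distance(dataset: GenotypeDataset) -> DistanceMatrix:
    """Nei's (1978) unbiased genetic distance between populations.

    D = -ln( Jxy_bar / sqrt(Jx_bar * Jy_bar) ) with per-locus unbiased
    within-population identities (2n sum p^2 - 1)/(2n - 1), averaged over
    loci before the ratio. A pair with zero shared identity gets the large
    sentinel ``NEI_INFINITE_DISTANCE`` (with a logged warning) so clustering
    stays well-defined.
    """
    pops = dataset.population_labels
    k = len(pops)
    if k < 2:
        raise ValueError("need at least two populations")
    jx = {p: [] for p in pops}
    jxy: dict[tuple[str, str], list[float]] = {}
    two_n = {}
    for j in range(dataset.n_loci):
        fm = _freq_matrix(dataset, j)
        for pop in pops:
            p = fm.loc[pop].to_numpy()
            if np.isnan(p).any():
                continue
            idx = dataset.indices_of(pop)
            calls = dataset.calls[idx, j, :]
            n2 = 2 * int((calls[:, 0] != MISSING).sum())
            raw = float(np.sum(p**2))
            jx[pop].append((n2 * raw - 1.0) / (n2 - 1.0) if n2 > 1 else raw)
        for a_i, a in enumerate(pops):
            for b in pops[a_i + 1 :]:
                pa, pb = fm.loc[a].to_numpy(), fm.loc[b].to_numpy()
                if np.isnan(pa).any() or np.isnan(pb).any():
                    continue
                jxy.setdefault((a, b), []).append(float(np.sum(pa * pb)))
    mat = np.zeros((k, k))
    for a_i, a in enumerate(pops):
        for b_i in range(a_i + 1, k):
            b = pops[b_i]
            jxb = max(float(np.mean(jx[a])), 0.0)
            jyb = max(float(np.mean(jx[b])), 0.0)
            jxyb = float(np.mean(jxy[(a, b)]))
            if jxyb <= 0 or jxb <= 0 or jyb <= 0:
                logger.warning(
                    "zero shared identity between %s and %s; distance set to sentinel",
                    a,
                    b,
                )
                d = NEI_INFINITE_DISTANCE
            else:
                d = max(-np.log(jxyb / np.sqrt(jxb * jyb)), 0.0)
            mat[a_i, b_i] = mat[b_i, a_i] = d
    return DistanceMatrix(list(pops), mat)
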