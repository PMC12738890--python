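"""Diploid SSR genotype datasets and text I/O.

Alleles are absolute fragment sizes in nucleotides (positive integers), the
way capillary electrophoresis reports them; repeat-count arithmetic happens
only inside the coalescent simulator. A genotype is an unordered pair of
allele states, stored sorted ascending. Missing genotypes are encoded as
``MISSING`` (=-1) in both slots.

Two text formats are supported: a GenAlEx-style CSV (counts header row,
labels row, one row per individual with two columns per locus, missing
code ``0``) and the STRUCTURE flat format (two rows per individual, missing
code ``-9``).
"""

from __future__ import annotations

import io
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "MISSING",
    "GenotypeDataset",
    "PopulationSpec",
    "ValidationReport",
    "GenotypeFormatError",
    "read_genalex",
    "write_genalex",
    "read_structure",
    "write_structure",
    "validate_dataset",
]

#: sentinel allele state for a missing genotype (both slots)
MISSING: int = -1

#: missing genotype code in GenAlEx-style CSV input
GENALEX_MISSING_CODE = "0"
#: missing allele code in STRUCTURE output
STRUCTURE_MISSING_CODE = "-9"


class GenotypeFormatError(ValueError):
    """Raised when an input file violates the expected dialect."""


@dataclass(frozen=True)
class PopulationSpec:
    """A sampled population: label, species tag and number of individuals."""

    label: str
    species: str = ""
    n_samples: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise ValueError(f"population {self.label!r}: n_samples must be >= 1")


@dataclass
class GenotypeDataset:
    """Diploid multilocus genotypes with population assignment.

    Parameters
    ----------
    individuals
        Individual identifiers, one per sample.
    populations
        Population label per individual (same order as ``individuals``).
        Individuals of a population need not be contiguous, but the readers
        and the fixture generator always emit them in population blocks.
    loci
        Locus names; column order is fixed.
    calls
        Integer array of shape ``(n, n_loci, 2)``; each genotype is a pair of
        allele sizes sorted ascending, or ``(MISSING, MISSING)``.
    """

    individuals: list[str]
    populations: list[str]
    loci: list[str]
    calls: np.ndarray

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int64)
        n, nl = len(self.individuals), len(self.loci)
        if len(self.populations) != n:
            raise ValueError("populations must align with individuals")
        if self.calls.shape != (n, nl, 2):
            raise ValueError(
                f"calls shape {self.calls.shape} != ({n}, {nl}, 2)"
            )
        miss = self.calls == MISSING
        if np.any(miss[..., 0] != miss[..., 1]):
            raise ValueError("half-missing genotypes are not representable")
        if np.any((self.calls <= 0) & ~miss):
            raise ValueError("allele states must be positive integers")
        # canonical order: unordered pair stored ascending
        self.calls = np.sort(self.calls, axis=2)

    # -- basic shape ---------------------------------------------------

    @property
    def n(self) -> int:
        return len(self.individuals)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def ploidy(self) -> int:
        return 2

    @property
    def population_labels(self) -> list[str]:
        """Population labels in order of first appearance."""
        seen: dict[str, None] = {}
        for p in self.populations:
            seen.setdefault(p)
        return list(seen)

    def population_sizes(self) -> dict[str, int]:
        return dict(Counter(self.populations))

    def indices_of(self, population: str) -> np.ndarray:
        idx = np.flatnonzero(np.asarray(self.populations) == population)
        if idx.size == 0:
            raise KeyError(f"unknown population {population!r}")
        return idx

    def missing_mask(self) -> np.ndarray:
        """Boolean (n, n_loci) mask of missing genotypes."""
        return self.calls[..., 0] == MISSING

    def subset_populations(self, labels: list[str]) -> "GenotypeDataset":
        """Restrict to the given populations (kept in the given order)."""
        keep = np.concatenate([self.indices_of(l) for l in labels])
        return GenotypeDataset(
            individuals=[self.individuals[i] for i in keep],
            populations=[self.populations[i] for i in keep],
            loci=list(self.loci),
            calls=self.calls[keep].copy(),
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeDataset):
            return NotImplemented
        return (
            self.individuals == other.individuals
            and self.populations == other.populations
            and self.loci == other.loci
            and np.array_equal(self.calls, other.calls)
        )


# ---------------------------------------------------------------------------
# GenAlEx-style CSV
# ---------------------------------------------------------------------------


def read_genalex(path: str | Path | io.TextIOBase) -> GenotypeDataset:
    """Read a GenAlEx-style codominant CSV.

    Expected layout (comma-separated, exactly two header rows)::

        n_loci,n_samples,n_pops,size_1,...,size_k
        Sample,Pop,Locus1,,Locus2,,...
        ind1,POPA,180,182,201,201,...

    Allele code ``0`` means missing (the whole genotype is treated as
    missing if either allele is 0).
    """
    if isinstance(path, io.TextIOBase):
        lines = path.read().splitlines()
        name = "<stream>"
    else:
        name = str(path)
        lines = Path(path).read_text().splitlines()
    lines = [ln for ln in lines if ln.strip()]
    if len(lines) < 3:
        raise GenotypeFormatError(f"{name}: need 2 header rows plus data")

    counts = lines[0].split(",")
    try:
        n_loci, n_samples, n_pops = (int(x) for x in counts[:3])
        declared_sizes = [int(x) for x in counts[3 : 3 + n_pops]]
    except (ValueError, IndexError) as exc:
        raise GenotypeFormatError(f"{name}: line 1: malformed counts header") from exc
    if len(declared_sizes) != n_pops:
        raise GenotypeFormatError(f"{name}: line 1: expected {n_pops} population sizes")

    labels_row = lines[1].split(",")
    # each locus name is followed by a blank column; the final blank may be
    # omitted by writers that trim trailing separators
    if len(labels_row) < 2 + 2 * n_loci - 1:
        raise GenotypeFormatError(
            f"{name}: line 2: expected 2 + {2 * n_loci} label columns"
        )
    labels_row += [""] * (2 + 2 * n_loci - len(labels_row))
    loci = [labels_row[2 + 2 * i] for i in range(n_loci)]
    if any(not l for l in loci):
        raise GenotypeFormatError(f"{name}: line 2: empty locus name")

    data = lines[2:]
    if len(data) != n_samples:
        raise GenotypeFormatError(
            f"{name}: expected {n_samples} data rows, found {len(data)}"
        )
    individuals: list[str] = []
    populations: list[str] = []
    calls = np.full((n_samples, n_loci, 2), MISSING, dtype=np.int64)
    for r, ln in enumerate(data):
        cells = ln.split(",")
        if len(cells) < 2 + 2 * n_loci:  # data rows always carry both alleles
            raise GenotypeFormatError(
                f"{name}: line {r + 3}: expected {2 + 2 * n_loci} columns, got {len(cells)}"
            )
        individuals.append(cells[0])
        populations.append(cells[1])
        for j in range(n_loci):
            a_raw, b_raw = cells[2 + 2 * j].strip(), cells[3 + 2 * j].strip()
            try:
                a, b = int(a_raw), int(b_raw)
            except ValueError as exc:
                raise GenotypeFormatError(
                    f"{name}: line {r + 3}: non-integer allele {a_raw!r}/{b_raw!r}"
                ) from exc
            if a <= 0 or b <= 0:  # GenAlEx missing code 0
                continue
            calls[r, j] = (a, b)

    ds = GenotypeDataset(individuals, populations, loci, calls)
    observed_sizes = ds.population_sizes()
    labels = ds.population_labels
    if len(labels) != n_pops:
        raise GenotypeFormatError(
            f"{name}: header declares {n_pops} populations, data contains {len(labels)}"
        )
    for lab, size in zip(labels, declared_sizes):
        if observed_sizes[lab] != size:
            raise GenotypeFormatError(
                f"{name}: population {lab!r} has {observed_sizes[lab]} rows, header says {size}"
            )
    return ds


def write_genalex(dataset: GenotypeDataset, path: str | Path | io.TextIOBase) -> None:
    """Write the GenAlEx-style CSV read by :func:`read_genalex`."""
    labels = dataset.population_labels
    sizes = dataset.population_sizes()
    out = [
        ",".join(
            [str(dataset.n_loci), str(dataset.n), str(len(labels))]
            + [str(sizes[l]) for l in labels]
        ),
        "Sample,Pop," + ",".join(f"{loc}," for loc in dataset.loci).rstrip(","),
    ]
    for i, (ind, pop) in enumerate(zip(dataset.individuals, dataset.populations)):
        cells = [ind, pop]
        for j in range(dataset.n_loci):
            a, b = dataset.calls[i, j]
            if a == MISSING:
                cells += [GENALEX_MISSING_CODE, GENALEX_MISSING_CODE]
            else:
                cells += [str(a), str(b)]
        out.append(",".join(cells))
    text = "\n".join(out) + "\n"
    if isinstance(path, io.TextIOBase):
        path.write(text)
    else:
        Path(path).write_text(text)


# ---------------------------------------------------------------------------
# STRUCTURE flat text
# ---------------------------------------------------------------------------


def write_structure(dataset: GenotypeDataset, path: str | Path | io.TextIOBase) -> None:
    """Write a two-rows-per-individual STRUCTURE file.

    Columns: individual id, integer population index (1-based, order of first
    appearance), then one allele per locus. Missing alleles become ``-9`` on
    both rows.
    """
    pop_index = {l: k + 1 for k, l in enumerate(dataset.population_labels)}
    rows = []
    for i, (ind, pop) in enumerate(zip(dataset.individuals, dataset.populations)):
        for slot in (0, 1):
            cells = [ind, str(pop_index[pop])]
            for j in range(dataset.n_loci):
                a = dataset.calls[i, j, slot]
                cells.append(STRUCTURE_MISSING_CODE if a == MISSING else str(a))
            rows.append("\t".join(cells))
    text = "\n".join(rows) + "\n"
    if isinstance(path, io.TextIOBase):
        path.write(text)
    else:
        Path(path).write_text(text)


def read_structure(
    path: str | Path | io.TextIOBase,
    loci: list[str] | None = None,
    population_names: dict[int, str] | None = None,
) -> GenotypeDataset:
    """Read back a STRUCTURE file written by :func:`write_structure`.

    Locus names are not stored in the format; pass ``loci`` to restore them
    (defaults to ``L1..Lk``). Population indices map back through
    ``population_names`` when given, else become ``"1"``, ``"2"``, ...
    """
    if isinstance(path, io.TextIOBase):
        lines = path.read().splitlines()
    else:
        lines = Path(path).read_text().splitlines()
    lines = [ln for ln in lines if ln.strip()]
    if len(lines) % 2:
        raise GenotypeFormatError("STRUCTURE file must have an even number of rows")
    individuals, populations, genos = [], [], []
    for r in range(0, len(lines), 2):
        top, bot = lines[r].split(), lines[r + 1].split()
        if top[0] != bot[0] or len(top) != len(bot):
            raise GenotypeFormatError(f"rows {r + 1}/{r + 2}: individual rows disagree")
        individuals.append(top[0])
        pop_idx = int(top[1])
        populations.append(
            population_names[pop_idx] if population_names else str(pop_idx)
        )
        pairs = []
        for a_raw, b_raw in zip(top[2:], bot[2:]):
            a, b = int(a_raw), int(b_raw)
            if a < 0 or b < 0:
                pairs.append((MISSING, MISSING))
            else:
                pairs.append((a, b))
        genos.append(pairs)
    n_loci = len(genos[0])
    if loci is None:
        loci = [f"L{j + 1}" for j in range(n_loci)]
    return GenotypeDataset(individuals, populations, loci, np.array(genos))


# ---------------------------------------------------------------------------
# Validation report
# ---------------------------------------------------------------------------


@dataclass
class ValidationReport:
    """Report-only summary of a dataset's completeness and structure."""

    n: int
    n_loci: int
    population_sizes: dict[str, int]
    missing_fraction_per_locus: dict[str, float]
    monomorphic_loci: list[str]
    warnings: list[str] = field(default_factory=list)

    @property
    def total_missing_fraction(self) -> float:
        return float(np.mean(list(self.missing_fraction_per_locus.values())))


def validate_dataset(dataset: GenotypeDataset) -> ValidationReport:
    """Summarize missingness, population sizes and monomorphic loci."""
    miss = dataset.missing_mask()
    miss_frac = {
        loc: float(miss[:, j].mean()) for j, loc in enumerate(dataset.loci)
    }
    mono = []
    for j, loc in enumerate(dataset.loci):
        obs = dataset.calls[~miss[:, j], j, :]
        if obs.size and np.unique(obs).size == 1:
            mono.append(loc)
    sizes = dataset.population_sizes()
    warnings = [
        f"population {lab!r} has a single individual"
        for lab, n in sizes.items()
        if n == 1
    ]
    for loc, f in miss_frac.items():
        if f == 1.0:
            warnings.append(f"locus {loc!r} is entirely missing")
    return ValidationReport(
        n=dataset.n,
        n_loci=dataset.n_loci,
        population_sizes=sizes,
        missing_fraction_per_locus=miss_frac,
        monomorphic_loci=mono,
        warnings=warnings,
    )
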