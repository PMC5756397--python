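"""Core in-memory containers shared by the pipeline stages.

Two parallel representations of the same populations are carried through the
whole analysis: a :class:`GenotypeMatrix` of individually genotyped samples
(the "array" side) and a :class:`PooledFrequencyTable` of per-population read
counts from pooled sequencing (the "reference" side). Both reduce to a
:class:`FrequencyMatrix` of per-population alternative-allele frequencies,
which is the shared currency of every diversity statistic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import numpy as np

DEFAULT_CHROMOSOMES = frozenset(str(i) for i in range(1, 29))


def normalize_chromosome(name: str) -> str:
    """Chromosome name as an exact string with an optional 'chr' prefix stripped."""
    s = str(name)
    return s[3:] if s.lower().startswith("chr") else s


def chromosome_sort_key(name: str):
    c = normalize_chromosome(name)
    return (0, int(c), "") if c.isdigit() else (1, 0, c)


@dataclass(frozen=True)
class SnpRecord:
    """Identity of one biallelic SNP; the unit matched across data sources."""

    id: str
    chromosome: str
    position: int | None  # 1-based; None = undefined/missing position
    ref_allele: str
    alt_allele: str

    def __post_init__(self):
        if self.position is not None and self.position < 1:
            raise ValueError(f"SNP {self.id}: position must be >= 1, got {self.position}")
        if self.ref_allele == self.alt_allele:
            raise ValueError(f"SNP {self.id}: ref and alt allele are identical ({self.ref_allele})")

    @property
    def key(self) -> tuple[str, int] | None:
        """(normalized chromosome, position) locus key; None if position missing."""
        if self.position is None or not str(self.chromosome):
            return None
        return (normalize_chromosome(self.chromosome), int(self.position))

    def sort_key(self):
        if self.key is None:  # undefined loci sort last, stably by id
            return ((2, 0, ""), 0, self.id)
        return (chromosome_sort_key(self.chromosome), int(self.position), self.id)


def _check_unique(ids: Sequence[str], what: str) -> None:
    if len(set(ids)) != len(ids):
        seen, dup = set(), set()
        for i in ids:
            (dup if i in seen else seen).add(i)
        raise ValueError(f"duplicate {what}: {sorted(dup)[:5]}")


@dataclass
class PopulationPanel:
    """Mapping of sample id to population label, with per-population sizes."""

    assignments: dict[str, str]

    def __post_init__(self):
        if not self.assignments:
            raise ValueError("population panel is empty")

    @property
    def populations(self) -> list[str]:
        seen: dict[str, None] = {}
        for pop in self.assignments.values():
            seen.setdefault(pop, None)
        return list(seen)

    @property
    def sizes(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for pop in self.assignments.values():
            out[pop] = out.get(pop, 0) + 1
        return out

    def population_of(self, sample_id: str) -> str:
        try:
            return self.assignments[sample_id]
        except KeyError:
            raise KeyError(f"sample {sample_id!r} is not in the population panel") from None


@dataclass
class GenotypeMatrix:
    """Individuals x SNPs alternative-allele dosages with metadata.

    ``dosages`` is float64 with values in {0, 1, 2} and NaN for missing calls
    (missing is thereby distinct from a homozygous-reference 0).
    """

    snps: list[SnpRecord]
    sample_ids: list[str]
    sample_populations: list[str]
    dosages: np.ndarray  # (n_samples, n_snps)

    def __post_init__(self):
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.shape != (len(self.sample_ids), len(self.snps)):
            raise ValueError(
                f"dosage shape {self.dosages.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.snps)} SNPs"
            )
        if len(self.sample_populations) != len(self.sample_ids):
            raise ValueError("sample_populations length does not match sample_ids")
        _check_unique([s.id for s in self.snps], "SNP ids")
        _check_unique(self.sample_ids, "sample ids")
        with np.errstate(invalid="ignore"):
            bad = ~(np.isnan(self.dosages) | np.isin(self.dosages, (0.0, 1.0, 2.0)))
        if bad.any():
            raise ValueError("dosages must be in {0, 1, 2} or NaN")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    @property
    def snp_ids(self) -> list[str]:
        return [s.id for s in self.snps]

    @property
    def populations(self) -> list[str]:
        seen: dict[str, None] = {}
        for pop in self.sample_populations:
            seen.setdefault(pop, None)
        return list(seen)

    def snp_index(self) -> dict[str, int]:
        return {s.id: i for i, s in enumerate(self.snps)}

    def take_snps(self, indices: Sequence[int]) -> "GenotypeMatrix":
        idx = list(indices)
        return GenotypeMatrix(
            snps=[self.snps[i] for i in idx],
            sample_ids=list(self.sample_ids),
            sample_populations=list(self.sample_populations),
            dosages=self.dosages[:, idx],
        )

    def take_snp_ids(self, ids: Iterable[str]) -> "GenotypeMatrix":
        index = self.snp_index()
        return self.take_snps([index[i] for i in ids])

    def take_samples(self, indices: Sequence[int]) -> "GenotypeMatrix":
        idx = list(indices)
        return GenotypeMatrix(
            snps=list(self.snps),
            sample_ids=[self.sample_ids[i] for i in idx],
            sample_populations=[self.sample_populations[i] for i in idx],
            dosages=self.dosages[idx, :],
        )


@dataclass
class PooledFrequencyTable:
    """Per-population alternative-read counts and depths from pooled sequencing."""

    snps: list[SnpRecord]
    populations: list[str]
    n_individuals: np.ndarray  # (n_pops,)
    alt_reads: np.ndarray  # (n_pops, n_snps)
    depth: np.ndarray  # (n_pops, n_snps)

    def __post_init__(self):
        self.n_individuals = np.asarray(self.n_individuals, dtype=int)
        self.alt_reads = np.asarray(self.alt_reads, dtype=int)
        self.depth = np.asarray(self.depth, dtype=int)
        shape = (len(self.populations), len(self.snps))
        if self.alt_reads.shape != shape or self.depth.shape != shape:
            raise ValueError("alt_reads/depth shape does not match populations x SNPs")
        _check_unique([s.id for s in self.snps], "SNP ids")
        _check_unique(self.populations, "population labels")
        if (self.n_individuals < 1).any():
            raise ValueError("each pooled population needs n_individuals >= 1")
        if (self.alt_reads < 0).any() or (self.depth < 0).any():
            raise ValueError("read counts must be nonnegative")
        if (self.alt_reads > self.depth).any():
            i, j = np.argwhere(self.alt_reads > self.depth)[0]
            raise ValueError(
                f"alt_reads exceeds depth for population {self.populations[i]} "
                f"at SNP {self.snps[j].id}"
            )

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    @property
    def snp_ids(self) -> list[str]:
        return [s.id for s in self.snps]

    def snp_index(self) -> dict[str, int]:
        return {s.id: i for i, s in enumerate(self.snps)}

    def take_snps(self, indices: Sequence[int]) -> "PooledFrequencyTable":
        idx = list(indices)
        return PooledFrequencyTable(
            snps=[self.snps[i] for i in idx],
            populations=list(self.populations),
            n_individuals=self.n_individuals.copy(),
            alt_reads=self.alt_reads[:, idx],
            depth=self.depth[:, idx],
        )


@dataclass
class FrequencyMatrix:
    """Populations x loci alternative-allele frequencies with sample sizes.

    NaN marks a frequency that could not be estimated (all genotypes missing,
    or zero sequencing depth).
    """

    populations: list[str]
    n_individuals: np.ndarray  # (n_pops,)
    loci: list[str]
    freq: np.ndarray  # (n_pops, n_loci)

    def __post_init__(self):
        self.n_individuals = np.asarray(self.n_individuals, dtype=float)
        self.freq = np.asarray(self.freq, dtype=float)
        if self.freq.shape != (len(self.populations), len(self.loci)):
            raise ValueError("frequency shape does not match populations x loci")
        _check_unique(self.populations, "population labels")
        _check_unique(self.loci, "locus ids")
        if (self.n_individuals < 1).any():
            raise ValueError("n_individuals must be >= 1 for every population")
        with np.errstate(invalid="ignore"):
            bad = ~np.isnan(self.freq) & ((self.freq < 0) | (self.freq > 1))
        if bad.any():
            raise ValueError("frequencies must lie in [0, 1]")

    @property
    def n_populations(self) -> int:
        return len(self.populations)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def mean_sample_size(self) -> float:
        return float(np.mean(self.n_individuals))

    def locus_index(self) -> dict[str, int]:
        return {l: i for i, l in enumerate(self.loci)}

    def population_index(self, label: str) -> int:
        try:
            return self.populations.index(label)
        except ValueError:
            raise KeyError(f"population {label!r} not present") from None

    def take_loci(self, indices: Sequence[int]) -> "FrequencyMatrix":
        idx = np.asarray(list(indices), dtype=int)
        return FrequencyMatrix(
            populations=list(self.populations),
            n_individuals=self.n_individuals.copy(),
            loci=[self.loci[i] for i in idx],
            freq=self.freq[:, idx],
        )

    def take_locus_ids(self, ids: Iterable[str]) -> "FrequencyMatrix":
        index = self.locus_index()
        return self.take_loci([index[i] for i in ids])


@dataclass
class SnpSubset:
    """An ordered list of retained SNP ids plus the name of the filter chain."""

    ids: list[str]
    provenance: str = ""

    def __len__(self) -> int:
        return len(self.ids)

    def __iter__(self) -> Iterator[str]:
        return iter(self.ids)

    def intersect(self, other: "SnpSubset", provenance: str) -> "SnpSubset":
        keep = set(other.ids)
        return SnpSubset([i for i in self.ids if i in keep], provenance)


@dataclass
class DistanceMatrix:
    """Symmetric nonnegative pairwise distances between labelled populations."""

    labels: list[str]
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError("distance matrix shape does not match labels")
        _check_unique(self.labels, "labels")
        finite = np.isfinite(self.values)
        if not np.allclose(
            self.values[finite & finite.T], self.values.T[finite & finite.T], atol=1e-12
        ):
            raise ValueError("distance matrix is not symmetric")
        if np.any(np.diagonal(self.values) != 0):
            raise ValueError("distance matrix diagonal must be zero")
        if np.any(self.values[finite] < 0):
            raise ValueError("distances must be nonnegative")

    @property
    def n(self) -> int:
        return len(self.labels)

    def reorder(self, labels: Sequence[str]) -> "DistanceMatrix":
        if set(labels) != set(self.labels) or len(labels) != len(self.labels):
            raise ValueError("label sets differ; cannot reorder distance matrix")
        idx = [self.labels.index(l) for l in labels]
        return DistanceMatrix(list(labels), self.values[np.ix_(idx, idx)])
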