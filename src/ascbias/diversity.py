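"""Within- and between-population diversity statistics.

All statistics operate on alternative-allele frequencies. For individually
genotyped data the per-population frequency is the alt-allele count over
2 x (non-missing diploids); for pooled sequencing it is the proportion of
alternative reads at the locus. Expected heterozygosity is 2p(1-p) per locus
averaged over loci; the fixation index is the variance-of-frequencies
estimator s^2 / (p_bar (1 - p_bar)) with an optional sample-size-weighted
s^2, averaged over loci as the mean of per-locus ratios. Between-population
distances use Nei's (1972) standard genetic distance in its biallelic form.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .types import (
    DistanceMatrix,
    FrequencyMatrix,
    GenotypeMatrix,
    PooledFrequencyTable,
    SnpRecord,
    SnpSubset,
    normalize_chromosome,
)

AFS_BIN_WIDTH = 0.025
AFS_N_BINS = 40


# ---------------------------------------------------------------------------
# allele frequencies
# ---------------------------------------------------------------------------


def sample_frequencies(geno: GenotypeMatrix) -> FrequencyMatrix:
    """Per-population alt-allele frequencies from individual genotypes.

    A population-locus cell with no genotyped individuals yields NaN; a
    population with no genotype calls anywhere is an error.
    """
    pops = geno.populations
    sample_pops = np.asarray(geno.sample_populations)
    freq = np.empty((len(pops), geno.n_snps))
    n_ind = np.empty(len(pops), dtype=int)
    for i, pop in enumerate(pops):
        rows = sample_pops == pop
        n_ind[i] = int(rows.sum())
        block = geno.dosages[rows]
        if np.isnan(block).all():
            raise ValueError(f"population {pop!r} has no genotype calls at any locus")
        with np.errstate(invalid="ignore"):
            freq[i] = np.nanmean(block, axis=0) / 2.0
    return FrequencyMatrix(pops, n_ind, list(geno.snp_ids), freq)


def pooled_frequencies(pool: PooledFrequencyTable) -> FrequencyMatrix:
    """Alt-read proportions per population per locus; zero depth yields NaN."""
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = np.where(pool.depth > 0, pool.alt_reads / np.maximum(pool.depth, 1), np.nan)
    return FrequencyMatrix(
        list(pool.populations), pool.n_individuals.astype(int), list(pool.snp_ids), freq
    )


# ---------------------------------------------------------------------------
# allele frequency spectrum
# ---------------------------------------------------------------------------


@dataclass
class AFSpectrum:
    """Histogram of allele frequencies in 40 bins of width 0.025.

    Bins are [x, x + 0.025) except the last, which is the closed interval
    [0.975, 1] so that fixed alternative alleles are counted.
    """

    proportions: np.ndarray
    n_snps: int

    def __post_init__(self):
        self.proportions = np.asarray(self.proportions, dtype=float)
        if self.proportions.shape != (AFS_N_BINS,):
            raise ValueError(f"expected {AFS_N_BINS} bins")
        if (self.proportions < 0).any() or abs(self.proportions.sum() - 1.0) > 1e-12:
            raise ValueError("bin proportions must be nonnegative and sum to 1")

    @property
    def bin_edges(self) -> np.ndarray:
        return np.linspace(0.0, 1.0, AFS_N_BINS + 1)

    def counts(self) -> np.ndarray:
        return np.rint(self.proportions * self.n_snps).astype(int)


def afs(freqs) -> AFSpectrum:
    """Bin a frequency vector into the 40-bin spectrum (NaN entries dropped)."""
    f = np.asarray(freqs, dtype=float).ravel()
    f = f[~np.isnan(f)]
    if f.size == 0:
        raise ValueError("cannot build a spectrum from zero frequencies")
    if (f < 0).any() or (f > 1).any():
        raise ValueError("frequencies outside [0, 1]")
    counts, _ = np.histogram(f, bins=np.linspace(0.0, 1.0, AFS_N_BINS + 1))
    return AFSpectrum(counts / f.size, int(f.size))


def pool_spectra(spectra: Sequence[AFSpectrum]) -> AFSpectrum:
    """Combine spectra by SNP-count weights (= spectrum of the concatenation)."""
    total = sum(s.n_snps for s in spectra)
    mixed = sum((s.proportions * s.n_snps for s in spectra), np.zeros(AFS_N_BINS)) / total
    return AFSpectrum(mixed, total)


# ---------------------------------------------------------------------------
# expected heterozygosity
# ---------------------------------------------------------------------------


def expected_heterozygosity(freqs: FrequencyMatrix, subset: SnpSubset | None = None) -> dict[str, float]:
    """Mean 2p(1-p) over loci, per population.

    Loci with a missing frequency are excluded from that population's mean;
    monomorphic loci contribute 0.
    """
    fm = freqs if subset is None else freqs.take_locus_ids(subset.ids)
    if fm.n_loci == 0:
        raise ValueError("expected_heterozygosity over an empty locus set")
    he = 2.0 * fm.freq * (1.0 - fm.freq)
    with np.errstate(invalid="ignore"):
        means = np.nanmean(he, axis=1)
    return {pop: float(m) for pop, m in zip(fm.populations, means)}


# ---------------------------------------------------------------------------
# F_ST
# ---------------------------------------------------------------------------


def _fst_per_locus(
    pa: np.ndarray, pb: np.ndarray, na: float, nb: float, mode: str
) -> tuple[np.ndarray, np.ndarray]:
    """Per-locus F_ST ratios for two populations plus the informative-locus mask."""
    if mode == "equal":
        pbar = (pa + pb) / 2.0
        s2 = ((pa - pbar) ** 2 + (pb - pbar) ** 2) / 2.0
    elif mode == "weighted":
        tot = na + nb
        pbar = (na * pa + nb * pb) / tot
        s2 = (na * (pa - pbar) ** 2 + nb * (pb - pbar) ** 2) / tot
    else:
        raise ValueError(f"unknown F_ST mode {mode!r}")
    den = pbar * (1.0 - pbar)
    ok = ~np.isnan(den) & (den > 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        ratios = np.where(ok, s2 / np.where(ok, den, 1.0), np.nan)
    return ratios, ok


def pairwise_fst(
    freqs: FrequencyMatrix,
    pop_a: str,
    pop_b: str,
    mode: str = "weighted",
    average: str = "ratio-mean",
) -> float:
    """Pairwise fixation index between two populations.

    ``mode='equal'`` uses the unweighted mean frequency and s^2 =
    sum_i (p_i - p_bar)^2 / r; ``mode='weighted'`` the sample-size-weighted
    forms (identical when the two sample sizes agree). Loci where
    p_bar (1 - p_bar) = 0, or with a missing frequency, are excluded.
    ``average='ratio-mean'`` (default) averages per-locus ratios across loci;
    ``average='ratio-of-sums'`` divides summed s^2 by summed p_bar (1-p_bar).
    """
    ia, ib = freqs.population_index(pop_a), freqs.population_index(pop_b)
    pa, pb = freqs.freq[ia], freqs.freq[ib]
    na, nb = float(freqs.n_individuals[ia]), float(freqs.n_individuals[ib])
    ratios, ok = _fst_per_locus(pa, pb, na, nb, mode)
    if not ok.any():
        raise ValueError(f"no informative loci for F_ST between {pop_a} and {pop_b}")
    if average == "ratio-mean":
        return float(np.nanmean(ratios[ok]))
    if average == "ratio-of-sums":
        if mode == "equal":
            pbar = (pa + pb) / 2.0
            s2 = ((pa - pbar) ** 2 + (pb - pbar) ** 2) / 2.0
        else:
            tot = na + nb
            pbar = (na * pa + nb * pb) / tot
            s2 = (na * (pa - pbar) ** 2 + nb * (pb - pbar) ** 2) / tot
        den = pbar * (1 - pbar)
        return float(np.nansum(s2[ok]) / np.nansum(den[ok]))
    raise ValueError(f"unknown average {average!r}")


def fst_pairs(
    freqs: FrequencyMatrix, mode: str = "weighted"
) -> dict[tuple[str, str], float]:
    """All pairwise F_ST values, keyed by (pop_a, pop_b) in population order."""
    out = {}
    for i, a in enumerate(freqs.populations):
        for b in freqs.populations[i + 1 :]:
            out[(a, b)] = pairwise_fst(freqs, a, b, mode=mode)
    return out


# ---------------------------------------------------------------------------
# Nei's standard genetic distance
# ---------------------------------------------------------------------------


def nei_distance_matrix(
    freqs: FrequencyMatrix, subset: SnpSubset | None = None
) -> DistanceMatrix:
    """Nei standard distance D = -ln( J_xy / sqrt(J_x J_y) ) between all pairs.

    For biallelic loci J_x = sum_l (p^2 + q^2), J_xy = sum_l (p_x p_y +
    q_x q_y), each sum running over the loci non-missing in *both* members of
    the pair. A non-positive identity yields +inf with a warning.
    """
    fm = freqs if subset is None else freqs.take_locus_ids(subset.ids)
    if fm.n_populations < 2:
        raise ValueError("need at least two populations for a distance matrix")
    mask = ~np.isnan(fm.freq)
    P = np.where(mask, fm.freq, 0.0)
    Q = np.where(mask, 1.0 - fm.freq, 0.0)
    S = P**2 + Q**2  # per-population homozygosity sum terms (0 at missing)
    J_xy = P @ P.T + Q @ Q.T
    J_x = S @ mask.T.astype(float)  # (x, y): sum of S_x over loci seen in both
    with np.errstate(invalid="ignore", divide="ignore"):
        identity = J_xy / np.sqrt(J_x * J_x.T)
    d = np.full_like(identity, np.inf)
    pos = identity > 0
    with np.errstate(divide="ignore"):
        d[pos] = -np.log(identity[pos])
    if np.isinf(d).any():
        import warnings

        warnings.warn("non-positive genetic identity; reporting infinite Nei distance")
    d = np.where(d < 0, 0.0, d)  # clamp -0.0 / rounding noise on identical pops
    d = (d + d.T) / 2.0
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(list(fm.populations), d)


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------


@dataclass
class PcaResult:
    labels: list[str]
    coordinates: np.ndarray  # (n_labels, k)
    variance_explained: np.ndarray  # (k,)


def pca(freqs: FrequencyMatrix, subset: SnpSubset | None = None, k: int = 2) -> PcaResult:
    """Principal components of the column-centered population x loci matrix.

    Loci with any missing frequency are dropped before centering. Components
    come from the singular value decomposition, ordered by decreasing
    variance; ``variance_explained`` is relative to the total variance, so it
    sums to <= 1 over the first k components.
    """
    fm = freqs if subset is None else freqs.take_locus_ids(subset.ids)
    complete = ~np.isnan(fm.freq).any(axis=0)
    X = fm.freq[:, complete]
    if X.shape[1] < k:
        raise ValueError(f"fewer informative loci ({X.shape[1]}) than components ({k})")
    X = X - X.mean(axis=0, keepdims=True)
    U, s, _ = np.linalg.svd(X, full_matrices=False)
    rank = int((s > s[0] * 1e-12).sum()) if s.size and s[0] > 0 else 0
    if k > rank:
        raise ValueError(f"requested {k} components but the centered matrix has rank {rank}")
    var = s**2
    return PcaResult(
        labels=list(fm.populations),
        coordinates=U[:, :k] * s[:k],
        variance_explained=var[:k] / var.sum(),
    )


def pca_dosages(geno: GenotypeMatrix, subset: SnpSubset | None = None, k: int = 2) -> PcaResult:
    """Individual-level PCA on mean-imputed dosage columns (array-only view)."""
    g = geno if subset is None else geno.take_snp_ids(subset.ids)
    X = g.dosages.copy()
    mu = np.nanmean(X, axis=0)
    nanmask = np.isnan(X)
    X[nanmask] = np.take(mu, np.nonzero(nanmask)[1])
    X = X - X.mean(axis=0, keepdims=True)
    U, s, _ = np.linalg.svd(X, full_matrices=False)
    rank = int((s > s[0] * 1e-12).sum()) if s.size and s[0] > 0 else 0
    if k > rank:
        raise ValueError(f"requested {k} components but the centered matrix has rank {rank}")
    var = s**2
    return PcaResult(list(g.sample_ids), U[:, :k] * s[:k], var[:k] / var.sum())


# ---------------------------------------------------------------------------
# genic / non-genic classification
# ---------------------------------------------------------------------------


def genic_classification(
    snps: Sequence[SnpRecord],
    intervals: Sequence[tuple[str, int, int]],
    freqs=None,
) -> tuple[np.ndarray, dict[str, AFSpectrum] | None]:
    """Classify SNPs as genic iff their position overlaps any gene interval.

    Intervals are (chromosome, start, end), 1-based inclusive on both ends;
    chromosome names are compared after normalization. When a per-SNP
    frequency vector ``freqs`` is supplied, per-class minor-allele-frequency
    spectra are returned alongside the genic mask.
    """
    from intervaltree import IntervalTree

    trees: dict[str, IntervalTree] = {}
    for chrom, start, end in intervals:
        if start < 1 or end < start:
            raise ValueError(f"malformed interval {chrom}:{start}-{end}")
        trees.setdefault(normalize_chromosome(chrom), IntervalTree()).addi(start, end + 1)
    genic = np.zeros(len(snps), dtype=bool)
    for i, snp in enumerate(snps):
        if snp.key is None:
            continue
        chrom, pos = snp.key
        tree = trees.get(chrom)
        genic[i] = bool(tree is not None and tree.overlaps_point(pos))
    if freqs is None:
        return genic, None
    p = np.asarray(freqs, dtype=float)
    maf = np.minimum(p, 1.0 - p)
    spectra = {}
    for label, mask in (("genic", genic), ("non-genic", ~genic)):
        vals = maf[mask]
        vals = vals[~np.isnan(vals)]
        if vals.size:
            spectra[label] = afs(vals)
    return genic, spectra


@dataclass
class DiversityResult:
    """Bundle of per-population He and pairwise F_ST for one SNP subset."""

    subset_name: str
    n_loci: int
    he: dict[str, float]
    fst: dict[tuple[str, str], float]

    def __post_init__(self):
        for pop, v in self.he.items():
            if not (np.isnan(v) or 0.0 <= v <= 0.5 + 1e-12):
                raise ValueError(f"He out of range for {pop}: {v}")
        for pair, v in self.fst.items():
            if not (np.isnan(v) or -1e-12 <= v <= 1.0 + 1e-12):
                raise ValueError(f"F_ST out of range for {pair}: {v}")
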