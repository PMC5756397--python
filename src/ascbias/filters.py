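"""Quality-control rules and bias-mitigation filters for array SNP sets.

Three mitigation filters are provided — LD-based pruning, restriction to SNPs
polymorphic in designated reference (wild) populations, and a minor-allele-
frequency cutoff — together with :func:`build_versions`, which composes them
into the eight canonical data-set versions::

    Array_all, Array_MAF5, GG, GG_MAF5,
    Pruned, Pruned_MAF5, Pruned_GG, Pruned_GG_MAF5

Composition order is prune first, then the reference-polymorphism (GG) filter,
with the MAF cutoff applied last.

Inequality conventions: a SNP survives QC if its call rate is strictly greater
than the threshold; a SNP survives the MAF filter if min(p, 1-p) >= the
cutoff (i.e. only SNPs with MAF strictly below the cutoff are removed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .types import FrequencyMatrix, GenotypeMatrix, SnpSubset


@dataclass
class FilterConfig:
    """Thresholds and parameters of the QC and mitigation filters.

    ``ld_window_snps``/``ld_step_snps``/``vif_max`` mirror the usual
    window-size / step / variance-inflation-factor parameterization of
    sliding-window LD pruning (VIF = 1/(1-r^2), so vif_max = 2 corresponds to
    a pairwise r^2 threshold of 0.5).
    """

    snp_call_rate_min: float = 0.99
    sample_call_rate_min: float = 0.95
    maf_min: float = 0.05
    ld_window_snps: int = 50
    ld_step_snps: int = 5
    vif_max: float = 2.0
    ld_mode: str = "pairwise"  # or "vif"
    reference_populations: list[str] = field(default_factory=list)
    polymorphism_scope: str = "pooled"  # or "each" / "any"

    def __post_init__(self):
        for name in ("snp_call_rate_min", "sample_call_rate_min", "maf_min"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if not self.ld_window_snps > self.ld_step_snps >= 1:
            raise ValueError("need ld_window_snps > ld_step_snps >= 1")
        if not self.vif_max > 1:
            raise ValueError("vif_max must be > 1")
        if self.ld_mode not in ("pairwise", "vif"):
            raise ValueError(f"unknown ld_mode {self.ld_mode!r}")
        if self.polymorphism_scope not in ("pooled", "each", "any"):
            raise ValueError(f"unknown polymorphism_scope {self.polymorphism_scope!r}")

    @property
    def r2_max(self) -> float:
        """Pairwise r^2 threshold implied by the VIF cap."""
        return 1.0 - 1.0 / self.vif_max if math.isfinite(self.vif_max) else 1.0


# ---------------------------------------------------------------------------
# call-rate QC
# ---------------------------------------------------------------------------


def qc_filter(geno: GenotypeMatrix, cfg: FilterConfig) -> tuple[GenotypeMatrix, dict]:
    """Drop low-call-rate SNPs, then low-call-rate samples.

    A SNP is retained iff its call rate is strictly above
    ``cfg.snp_call_rate_min``; samples likewise against
    ``cfg.sample_call_rate_min`` (computed on the retained SNPs).
    """
    if geno.n_snps == 0 or geno.n_samples == 0:
        raise ValueError("qc_filter requires a non-empty genotype matrix")
    called = ~np.isnan(geno.dosages)
    snp_rate = called.mean(axis=0)
    keep_snps = np.flatnonzero(snp_rate > cfg.snp_call_rate_min)
    if keep_snps.size == 0:
        raise ValueError("call-rate QC removed every SNP")
    out = geno.take_snps(keep_snps)
    sample_rate = (~np.isnan(out.dosages)).mean(axis=1)
    keep_samples = np.flatnonzero(sample_rate > cfg.sample_call_rate_min)
    if keep_samples.size == 0:
        raise ValueError("call-rate QC removed every sample")
    out = out.take_samples(keep_samples)
    log = {
        "snps_removed": int(geno.n_snps - keep_snps.size),
        "samples_removed": int(geno.n_samples - keep_samples.size),
        "snps_retained": int(keep_snps.size),
        "samples_retained": int(keep_samples.size),
    }
    return out, log


# ---------------------------------------------------------------------------
# frequency helpers
# ---------------------------------------------------------------------------


def overall_alt_frequency(source) -> np.ndarray:
    """Alt-allele frequency per SNP over all samples/populations pooled.

    For a :class:`GenotypeMatrix` this is the allele count over all
    non-missing genotypes; for a :class:`FrequencyMatrix`, the
    sample-size-weighted mean of the population frequencies.
    """
    if isinstance(source, GenotypeMatrix):
        with np.errstate(invalid="ignore"):
            return np.nanmean(source.dosages, axis=0) / 2.0
    if isinstance(source, FrequencyMatrix):
        w = source.n_individuals[:, None] * ~np.isnan(source.freq)
        p = np.where(np.isnan(source.freq), 0.0, source.freq)
        with np.errstate(invalid="ignore"):
            return (w * p).sum(axis=0) / w.sum(axis=0)
    arr = np.asarray(source, dtype=float)
    if arr.ndim == 1:
        return arr
    raise TypeError("expected GenotypeMatrix, FrequencyMatrix or 1-D frequency vector")


def _snp_ids(source) -> list[str]:
    if isinstance(source, GenotypeMatrix):
        return source.snp_ids
    if isinstance(source, FrequencyMatrix):
        return list(source.loci)
    return [str(i) for i in range(len(np.asarray(source)))]


# ---------------------------------------------------------------------------
# MAF and reference-polymorphism filters
# ---------------------------------------------------------------------------


def maf_filter(freqs_or_geno, maf_min: float) -> SnpSubset:
    """Retain SNPs whose overall minor-allele frequency is >= ``maf_min``."""
    p = overall_alt_frequency(freqs_or_geno)
    maf = np.minimum(p, 1.0 - p)
    with np.errstate(invalid="ignore"):
        keep = maf >= maf_min
    keep &= ~np.isnan(maf)
    ids = _snp_ids(freqs_or_geno)
    return SnpSubset([ids[i] for i in np.flatnonzero(keep)], f"MAF>={maf_min}")


def polymorphic_in_reference(
    geno: GenotypeMatrix,
    reference_populations,
    scope: str = "pooled",
) -> SnpSubset:
    """Retain SNPs segregating in the designated reference populations.

    ``scope`` controls what "polymorphic" means: frequency strictly inside
    (0, 1) in the pooled reference sample (default), in every reference
    population separately ("each"), or in at least one ("any").
    """
    pops = list(reference_populations)
    sample_pops = np.asarray(geno.sample_populations)
    present = set(sample_pops)
    for p in pops:
        if p not in present:
            raise KeyError(f"reference population {p!r} has no samples")
    if scope == "pooled":
        rows = np.isin(sample_pops, pops)
        with np.errstate(invalid="ignore"):
            p_hat = np.nanmean(geno.dosages[rows], axis=0) / 2.0
        keep = (p_hat > 0) & (p_hat < 1)
    else:
        per_pop = []
        for pop in pops:
            rows = sample_pops == pop
            with np.errstate(invalid="ignore"):
                p_hat = np.nanmean(geno.dosages[rows], axis=0) / 2.0
            per_pop.append((p_hat > 0) & (p_hat < 1))
        stacked = np.vstack(per_pop)
        keep = stacked.all(axis=0) if scope == "each" else stacked.any(axis=0)
    ids = geno.snp_ids
    return SnpSubset(
        [ids[i] for i in np.flatnonzero(keep)], f"polymorphic_in({','.join(pops)};{scope})"
    )


# ---------------------------------------------------------------------------
# LD pruning
# ---------------------------------------------------------------------------


def _window_r2_matrix(X: np.ndarray) -> np.ndarray:
    """r^2 matrix among the columns of X over pairwise-complete observations.

    Vectorized via joint-observation sufficient statistics; zero-variance
    columns and pairs with fewer than two shared observations get r^2 = 0.
    """
    ok = ~np.isnan(X)
    if ok.all():
        with np.errstate(invalid="ignore", divide="ignore"):
            c = np.corrcoef(X, rowvar=False)
        r2 = np.nan_to_num(c, nan=0.0) ** 2
        np.fill_diagonal(r2, 0.0)
        return r2
    Mf = ok.astype(float)
    X0 = np.where(ok, X, 0.0)
    n = Mf.T @ Mf  # (a, b): number of rows observed in both columns
    Sx = X0.T @ Mf  # (a, b): sum of column a over those joint rows
    Sxx = (X0 * X0).T @ Mf
    Sxy = X0.T @ X0
    with np.errstate(invalid="ignore", divide="ignore"):
        cov = Sxy - Sx * Sx.T / n
        var_a = Sxx - Sx**2 / n  # variance term of column a on the joint rows
        den = var_a * var_a.T
        r2 = np.where((den > 0) & (n >= 2), cov**2 / den, 0.0)
    r2 = np.nan_to_num(r2, nan=0.0)
    np.fill_diagonal(r2, 0.0)
    return r2


def _clean_window_pairwise(
    X: np.ndarray, kept: list[int], w: int, window: int, r2_max: float, mafs: np.ndarray
) -> bool:
    """Remove SNPs from kept[w:w+window] until no pair exceeds r2_max.

    The violating pair with the largest r^2 is resolved first (ties broken by
    the lexicographically earliest pair); within a pair the lower-MAF member
    is removed, ties removing the later-positioned SNP. Returns True if
    anything was removed.
    """
    removed = False
    while True:
        idx = kept[w : w + window]
        if len(idx) < 2:
            return removed
        r2 = _window_r2_matrix(X[:, idx])
        iu = np.triu_indices(len(idx), k=1)
        flat = r2[iu]
        best = int(np.argmax(flat))
        if flat[best] <= r2_max:
            return removed
        a, b = int(iu[0][best]), int(iu[1][best])
        ia, ib = idx[a], idx[b]
        victim = ib if mafs[ia] >= mafs[ib] else ia
        kept.remove(victim)
        removed = True


def _clean_window_vif(
    X: np.ndarray, kept: list[int], w: int, window: int, vif_max: float
) -> bool:
    """Iteratively remove the SNP with the largest VIF above vif_max.

    VIF_i = 1/(1 - R^2_i) from the least-squares regression of SNP i's
    (mean-imputed) dosages on the other retained window SNPs.
    """
    removed = False
    while True:
        idx = kept[w : w + window]
        if len(idx) < 2:
            return removed
        Z = X[:, idx].copy()
        mu = np.nanmean(Z, axis=0)
        nanmask = np.isnan(Z)
        Z[nanmask] = np.take(mu, np.nonzero(nanmask)[1])
        Z = Z - Z.mean(axis=0)
        vifs = np.zeros(len(idx))
        for j in range(len(idx)):
            y = Z[:, j]
            tss = float(y @ y)
            if tss <= 0:
                continue
            A = np.delete(Z, j, axis=1)
            coef, *_ = np.linalg.lstsq(A, y, rcond=None)
            resid = y - A @ coef
            rss = float(resid @ resid)
            vifs[j] = np.inf if rss <= tss * 1e-12 else tss / rss
        worst = int(np.argmax(vifs))
        if vifs[worst] <= vif_max:
            return removed
        kept.remove(idx[worst])
        removed = True


def ld_prune(geno: GenotypeMatrix, cfg: FilterConfig) -> SnpSubset:
    """Sliding-window LD pruning of dosage columns, per chromosome.

    Windows of ``ld_window_snps`` retained SNPs advance by ``ld_step_snps``;
    in pairwise mode (default) any retained pair with r^2 > 1 - 1/vif_max
    loses its lower-MAF member, in vif mode the SNP whose variance inflation
    factor against the other window SNPs exceeds ``vif_max`` is removed,
    largest first. The per-chromosome pass repeats until a full pass removes
    nothing, which makes the operation idempotent.

    Input SNPs must be sorted by (chromosome, position).
    """
    order = [s.sort_key() for s in geno.snps]
    if order != sorted(order):
        raise ValueError("ld_prune requires SNPs sorted by (chromosome, position); sort them first")
    mafs = np.minimum(overall_alt_frequency(geno), 1 - overall_alt_frequency(geno))
    mafs = np.nan_to_num(mafs, nan=0.0)
    X = geno.dosages
    kept_all: list[int] = []
    chrom_of = [s.sort_key()[0] for s in geno.snps]
    start = 0
    while start < geno.n_snps:
        end = start
        while end < geno.n_snps and chrom_of[end] == chrom_of[start]:
            end += 1
        kept = list(range(start, end))
        changed = True
        while changed:
            changed = False
            w = 0
            while w < max(len(kept) - 1, 1):
                if cfg.ld_mode == "pairwise":
                    if _clean_window_pairwise(X, kept, w, cfg.ld_window_snps, cfg.r2_max, mafs):
                        changed = True
                else:
                    if _clean_window_vif(X, kept, w, cfg.ld_window_snps, cfg.vif_max):
                        changed = True
                w += cfg.ld_step_snps
        kept_all.extend(kept)
        start = end
    ids = geno.snp_ids
    return SnpSubset([ids[i] for i in kept_all], "Pruned")


# ---------------------------------------------------------------------------
# the eight data-set versions
# ---------------------------------------------------------------------------

VERSION_NAMES = (
    "Array_all",
    "Array_MAF5",
    "GG",
    "GG_MAF5",
    "Pruned",
    "Pruned_MAF5",
    "Pruned_GG",
    "Pruned_GG_MAF5",
)


def build_versions(geno: GenotypeMatrix, cfg: FilterConfig) -> dict[str, SnpSubset]:
    """The eight filter combinations applied to a harmonized genotype matrix.

    With no reference populations configured the GG filter is a no-op, so all
    GG versions coincide with their parents.
    """
    all_ids = SnpSubset(list(geno.snp_ids), "Array_all")
    pruned = ld_prune(geno, cfg)
    if cfg.reference_populations:
        gg = polymorphic_in_reference(geno, cfg.reference_populations, cfg.polymorphism_scope)
    else:
        gg = SnpSubset(list(geno.snp_ids), "GG(no-op)")
    maf = maf_filter(geno, cfg.maf_min)

    def chain(base: SnpSubset, name: str, *extra: SnpSubset) -> SnpSubset:
        out = SnpSubset(list(base.ids), name)
        for e in extra:
            out = out.intersect(e, name)
        return out

    return {
        "Array_all": chain(all_ids, "Array_all"),
        "Array_MAF5": chain(all_ids, "Array_MAF5", maf),
        "GG": chain(gg, "GG"),
        "GG_MAF5": chain(gg, "GG_MAF5", maf),
        "Pruned": chain(pruned, "Pruned"),
        "Pruned_MAF5": chain(pruned, "Pruned_MAF5", maf),
        "Pruned_GG": chain(pruned, "Pruned_GG", gg),
        "Pruned_GG_MAF5": chain(pruned, "Pruned_GG_MAF5", gg, maf),
    }
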