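"""The comparison harness: array-version statistics against the reference.

For each filtered version of the array data the harness computes, relative to
the full reference (pooled-sequencing) set:

* Spearman rank correlation and OLS regression of per-population expected
  heterozygosity (array as response, reference as predictor);
* OLS regression of pairwise F_ST over all population pairs;
* the Frobenius distance between the array's Nei distance matrix and Nei
  matrices of replicate reference subsets matched in SNP count (mean +/- SE
  over replicates);
* partition and branch-score distances between the array NJ tree and the
  replicate reference trees, plus the replicate-vs-replicate baseline
  distributions;
* PCA variance explained for both data sets.

Replicate subsets are drawn without replacement from the full reference locus
set, mirroring the matched-SNP-count resampling design that controls for the
scale effect of the number of SNPs on distances.
"""

from __future__ import annotations

import dataclasses
import json
import math
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import stats

from . import diversity, phylo
from .types import (
    FrequencyMatrix,
    GenotypeMatrix,
    PooledFrequencyTable,
    SnpSubset,
)

MAX_BASELINE_PAIRS = 1000


# ---------------------------------------------------------------------------
# building blocks
# ---------------------------------------------------------------------------


@dataclass
class ReplicateSet:
    """Seeded replicate draws of fixed-size SNP subsets from a reference set."""

    n_replicates: int
    n_snps: int
    seed: int
    replicates: list[list[int]]  # locus indices into the reference locus list

    def __post_init__(self):
        for rep in self.replicates:
            if len(set(rep)) != self.n_snps:
                raise ValueError("each replicate must hold n_snps distinct loci")


def draw_replicates(reference_loci, n_snps: int, n_replicates: int, seed: int) -> ReplicateSet:
    """Draw ``n_replicates`` subsets of ``n_snps`` loci without replacement.

    Replicate r uses the deterministic stream ``seed + r``, so individual
    replicates are reproducible in isolation.
    """
    n_total = len(reference_loci)
    if n_snps > n_total:
        raise ValueError(f"cannot draw {n_snps} loci from a set of {n_total}")
    reps = []
    for r in range(n_replicates):
        rng = np.random.default_rng(seed + r)
        idx = rng.choice(n_total, size=n_snps, replace=False)
        idx.sort()
        reps.append(idx.tolist())
    return ReplicateSet(n_replicates, n_snps, seed, reps)


def spearman_rho(x, y) -> float:
    """Spearman rank correlation (average ranks for ties); NaN if undefined."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("spearman_rho needs two equal-length vectors of length >= 3")
    if np.unique(x).size < 2 or np.unique(y).size < 2:
        return float("nan")
    rho = stats.spearmanr(x, y).statistic
    return float(rho)


@dataclass
class RegressionSummary:
    """Ordinary least squares of y on x with the summary columns reported."""

    slope: float
    intercept: float
    r_squared: float
    slope_se: float
    residual_variance: float

    def __post_init__(self):
        if not (np.isnan(self.r_squared) or -1e-12 <= self.r_squared <= 1 + 1e-12):
            raise ValueError(f"R^2 out of [0, 1]: {self.r_squared}")
        if not (np.isnan(self.residual_variance) or self.residual_variance >= -1e-15):
            raise ValueError("residual variance must be nonnegative")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def regress(y, x) -> RegressionSummary:
    """OLS of response ``y`` on predictor ``x``.

    Residual variance is RSS / (n - 2); the slope standard error is the
    standard OLS formula. A zero-variance predictor is an error.
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    if y.shape != x.shape or y.size < 3:
        raise ValueError("regress needs two equal-length vectors of length >= 3")
    if np.ptp(x) == 0:
        raise ValueError("predictor has zero variance")
    fit = stats.linregress(x, y)
    resid = y - (fit.intercept + fit.slope * x)
    rss = float(resid @ resid)
    return RegressionSummary(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        slope_se=float(fit.stderr),
        residual_variance=rss / (y.size - 2),
    )


def _mean_se(values) -> tuple[float, float]:
    v = np.asarray(values, dtype=float)
    se = float(v.std(ddof=1) / math.sqrt(v.size)) if v.size > 1 else 0.0
    return float(v.mean()), se


# ---------------------------------------------------------------------------
# the full report
# ---------------------------------------------------------------------------


@dataclass
class VersionComparison:
    """All comparison statistics for one filtered array version."""

    n_snps: int
    he_spearman_rho: float
    he_regression: RegressionSummary
    fst_regression: RegressionSummary
    frobenius_mean: float
    frobenius_se: float
    partition_mean: float
    partition_se: float
    branch_score_mean: float
    branch_score_se: float
    baseline_frobenius: list[float]
    baseline_partition: list[float]
    baseline_branch_score: list[float]
    pca_variance_explained: list[float]
    he_array: dict[str, float]
    fst_array: dict[str, float]


@dataclass
class ComparisonReport:
    """Per-version comparison blocks plus the shared reference statistics."""

    seed: int
    n_replicates: int
    populations: list[str]
    reference_n_loci: int
    he_reference: dict[str, float]
    fst_reference: dict[str, float]
    reference_pca_variance_explained: list[float]
    versions: dict[str, VersionComparison] = field(default_factory=dict)

    def to_dict(self) -> dict:
        def sanitize(obj):
            if isinstance(obj, float) and math.isnan(obj):
                return None  # undefined statistics serialize as missing
            if isinstance(obj, dict):
                return {k: sanitize(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [sanitize(v) for v in obj]
            return obj

        return sanitize(dataclasses.asdict(self))

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=2, sort_keys=True, allow_nan=False)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    @classmethod
    def from_dict(cls, d: dict) -> "ComparisonReport":
        versions = {
            name: VersionComparison(
                **{
                    **blk,
                    "he_spearman_rho": (
                        float("nan") if blk["he_spearman_rho"] is None else blk["he_spearman_rho"]
                    ),
                    "he_regression": RegressionSummary(**blk["he_regression"]),
                    "fst_regression": RegressionSummary(**blk["fst_regression"]),
                }
            )
            for name, blk in d["versions"].items()
        }
        return cls(
            seed=d["seed"],
            n_replicates=d["n_replicates"],
            populations=list(d["populations"]),
            reference_n_loci=d["reference_n_loci"],
            he_reference=dict(d["he_reference"]),
            fst_reference=dict(d["fst_reference"]),
            reference_pca_variance_explained=list(d["reference_pca_variance_explained"]),
            versions=versions,
        )

    @classmethod
    def from_json(cls, source) -> "ComparisonReport":
        text = Path(source).read_text() if not str(source).lstrip().startswith("{") else str(source)
        return cls.from_dict(json.loads(text))


def _pair_key(a: str, b: str) -> str:
    return f"{a}|{b}"


def _version_seed(seed: int, name: str) -> int:
    return (int(seed) + zlib.crc32(name.encode("utf8"))) % (2**31)


def _baseline_pairs(n: int, seed: int) -> list[tuple[int, int]]:
    pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
    if len(pairs) <= MAX_BASELINE_PAIRS:
        return pairs
    rng = np.random.default_rng(seed)
    chosen = rng.choice(len(pairs), size=MAX_BASELINE_PAIRS, replace=False)
    chosen.sort()
    return [pairs[i] for i in chosen]


def _pca_variance(fm: FrequencyMatrix, k: int) -> list[float]:
    complete = ~np.isnan(fm.freq).any(axis=0)
    X = fm.freq[:, complete]
    X = X - X.mean(axis=0, keepdims=True)
    s = np.linalg.svd(X, compute_uv=False)
    rank = int((s > s[0] * 1e-12).sum()) if s.size and s[0] > 0 else 0
    kk = min(k, rank)
    var = s**2
    return [float(v) for v in (var[:kk] / var.sum())]


def run_comparison(
    array: GenotypeMatrix,
    reference: PooledFrequencyTable,
    versions: dict[str, SnpSubset],
    n_replicates: int = 100,
    seed: int = 0,
    fst_mode: str = "weighted",
    k_pca: int = 3,
) -> ComparisonReport:
    """Compare every filtered array version against the pooled reference.

    ``array`` must be harmonized (its loci a subset of the reference loci with
    matching alleles, matched by (chromosome, position)); ``reference`` is the
    *full* reference table, whose complete locus set provides the reference
    statistics and the replicate draws.
    """
    if not versions:
        raise ValueError("no versions to compare")
    arr_freq = diversity.sample_frequencies(array)
    ref_freq = diversity.pooled_frequencies(reference)
    if set(arr_freq.populations) != set(ref_freq.populations):
        only_a = sorted(set(arr_freq.populations) - set(ref_freq.populations))
        only_r = sorted(set(ref_freq.populations) - set(arr_freq.populations))
        raise ValueError(
            f"population sets differ between array and reference: "
            f"array-only {only_a}, reference-only {only_r}"
        )
    pops = list(ref_freq.populations)
    # reorder the array-side frequency matrix to the reference population order
    order = [arr_freq.populations.index(p) for p in pops]
    arr_freq = FrequencyMatrix(
        pops, arr_freq.n_individuals[order], list(arr_freq.loci), arr_freq.freq[order, :]
    )
    ref_keys = {s.key: i for i, s in enumerate(reference.snps)}
    for s in array.snps:
        if s.key not in ref_keys:
            raise ValueError(f"array locus {s.id} ({s.key}) absent from the reference set")

    he_ref = diversity.expected_heterozygosity(ref_freq)
    fst_ref = diversity.fst_pairs(ref_freq, mode=fst_mode)
    pair_names = list(fst_ref.keys())
    he_ref_vec = np.array([he_ref[p] for p in pops])
    fst_ref_vec = np.array([fst_ref[p] for p in pair_names])

    report = ComparisonReport(
        seed=int(seed),
        n_replicates=int(n_replicates),
        populations=pops,
        reference_n_loci=reference.n_snps,
        he_reference={p: he_ref[p] for p in pops},
        fst_reference={_pair_key(*p): v for p, v in fst_ref.items()},
        reference_pca_variance_explained=_pca_variance(ref_freq, k_pca),
    )

    for name in versions:
        subset = versions[name]
        if len(subset) == 0:
            raise ValueError(f"version {name!r} retained no SNPs")
        arr_sub = arr_freq.take_locus_ids(subset.ids)

        he_arr = diversity.expected_heterozygosity(arr_sub)
        he_arr_vec = np.array([he_arr[p] for p in pops])
        rho = spearman_rho(he_arr_vec, he_ref_vec)
        he_reg = regress(he_arr_vec, he_ref_vec)

        fst_arr = diversity.fst_pairs(arr_sub, mode=fst_mode)
        fst_arr_vec = np.array([fst_arr[p] for p in pair_names])
        fst_reg = regress(fst_arr_vec, fst_ref_vec)

        nei_arr = diversity.nei_distance_matrix(arr_sub)
        tree_arr = phylo.neighbor_joining(nei_arr)

        vseed = _version_seed(seed, name)
        reps = draw_replicates(ref_freq.loci, len(subset), n_replicates, vseed)
        rep_neis, rep_trees = [], []
        for idx in reps.replicates:
            rf = ref_freq.take_loci(idx)
            nm = diversity.nei_distance_matrix(rf)
            rep_neis.append(nm)
            rep_trees.append(phylo.neighbor_joining(nm))

        frob = [phylo.frobenius_distance(nei_arr, nm) for nm in rep_neis]
        part = [float(phylo.partition_distance(tree_arr, t)) for t in rep_trees]
        bsco = [phylo.branch_length_distance(tree_arr, t) for t in rep_trees]
        pairs = _baseline_pairs(n_replicates, vseed + n_replicates)
        base_frob = [phylo.frobenius_distance(rep_neis[i], rep_neis[j]) for i, j in pairs]
        base_part = [float(phylo.partition_distance(rep_trees[i], rep_trees[j])) for i, j in pairs]
        base_bsco = [phylo.branch_length_distance(rep_trees[i], rep_trees[j]) for i, j in pairs]

        f_mean, f_se = _mean_se(frob)
        p_mean, p_se = _mean_se(part)
        b_mean, b_se = _mean_se(bsco)
        report.versions[name] = VersionComparison(
            n_snps=len(subset),
            he_spearman_rho=rho,
            he_regression=he_reg,
            fst_regression=fst_reg,
            frobenius_mean=f_mean,
            frobenius_se=f_se,
            partition_mean=p_mean,
            partition_se=p_se,
            branch_score_mean=b_mean,
            branch_score_se=b_se,
            baseline_frobenius=[float(v) for v in base_frob],
            baseline_partition=[float(v) for v in base_part],
            baseline_branch_score=[float(v) for v in base_bsco],
            pca_variance_explained=_pca_variance(arr_sub, k_pca),
            he_array={p: float(v) for p, v in he_arr.items()},
            fst_array={_pair_key(*p): float(v) for p, v in fst_arr.items()},
        )
    return report
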