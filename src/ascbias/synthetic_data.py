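"""Synthetic structured-population data with discovery-panel ascertainment.

The generator produces everything the pipeline consumes: per-population true
allele frequencies under the Balding-Nichols drift model, Hardy-Weinberg
diploid genotypes with optional template-copied LD blocks, pooled sequencing
reads (Poisson depth, binomial allele sampling), and an "array" SNP set
ascertained through a small discovery panel with a minor-allele-frequency
cutoff — the mechanism that underrepresents rare variants on real genotyping
arrays.

Under Balding-Nichols, a population with drift parameter F has allele
frequency p ~ Beta(p0 (1-F)/F, (1-p0)(1-F)/F) around the ancestral frequency
p0, giving the closed-form moment E[2p(1-p)] = 2 p0 (1-p0) (1-F) used by the
generator's own calibration tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import dendropy
import numpy as np
import yaml

from ._rng import substream
from .types import (
    GenotypeMatrix,
    PooledFrequencyTable,
    PopulationPanel,
    SnpRecord,
    SnpSubset,
)

PACKAGED_SCENARIOS = ("null", "default_bias", "strong_ld")


@dataclass
class ScenarioConfig:
    """All knobs of one simulation scenario.

    ``ancestral_freq_dist`` is ``("uniform", a, b)`` or ``("beta", alpha,
    beta)``. ``population_tree`` is an optional newick string whose tips are
    the population labels and whose edge lengths are per-edge drift parameters
    F; when given it overrides ``f_per_population``. ``ld_decay`` is the
    probability that a locus *keeps* the block template state (0 = independent
    loci, 1 = perfect within-block copying).
    """

    populations: list[str]
    f_per_population: list[float]
    n_loci: int
    n_individuals_per_pop: list[int]
    discovery_panel: list[tuple[str, int]]
    ascertainment_maf_min: float = 0.05
    pool_coverage_mean: float = 20.0
    ancestral_freq_dist: tuple = ("uniform", 0.0, 1.0)
    population_tree: str | None = None
    ld_block_size: int = 1
    ld_decay: float = 0.0
    missing_rate: float = 0.0
    seed: int = 1

    def __post_init__(self):
        if len(self.f_per_population) != len(self.populations):
            raise ValueError("need one drift parameter per population")
        if isinstance(self.n_individuals_per_pop, int):
            self.n_individuals_per_pop = [self.n_individuals_per_pop] * len(self.populations)
        if len(self.n_individuals_per_pop) != len(self.populations):
            raise ValueError("need one sample size per population")
        for f in self.f_per_population:
            if not 0.0 <= f < 1.0:
                raise ValueError(f"drift parameter F must be in [0, 1), got {f}")
        for frac_name in ("ascertainment_maf_min", "ld_decay", "missing_rate"):
            v = getattr(self, frac_name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{frac_name} must be in [0, 1], got {v}")
        if self.n_loci < 1 or self.ld_block_size < 1:
            raise ValueError("n_loci and ld_block_size must be >= 1")
        self.discovery_panel = [(str(p), int(n)) for p, n in self.discovery_panel]
        known = set(self.populations)
        for pop, n in self.discovery_panel:
            if pop not in known:
                raise ValueError(f"discovery-panel population {pop!r} is not simulated")
            if n < 1:
                raise ValueError("panel sizes must be >= 1")
        kind = self.ancestral_freq_dist[0]
        if kind not in ("uniform", "beta"):
            raise ValueError(f"unknown ancestral frequency distribution {kind!r}")

    @classmethod
    def from_dict(cls, d: dict) -> "ScenarioConfig":
        d = dict(d)
        if "ancestral_freq_dist" in d and isinstance(d["ancestral_freq_dist"], dict):
            spec = d["ancestral_freq_dist"]
            d["ancestral_freq_dist"] = (spec["kind"], float(spec["a"]), float(spec["b"]))
        if "discovery_panel" in d:
            d["discovery_panel"] = [(p, n) for p, n in d["discovery_panel"]]
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "ScenarioConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def to_dict(self) -> dict:
        kind, a, b = self.ancestral_freq_dist
        return {
            "populations": list(self.populations),
            "f_per_population": [float(f) for f in self.f_per_population],
            "n_loci": int(self.n_loci),
            "n_individuals_per_pop": [int(n) for n in self.n_individuals_per_pop],
            "discovery_panel": [[p, int(n)] for p, n in self.discovery_panel],
            "ascertainment_maf_min": float(self.ascertainment_maf_min),
            "pool_coverage_mean": float(self.pool_coverage_mean),
            "ancestral_freq_dist": {"kind": kind, "a": float(a), "b": float(b)},
            "population_tree": self.population_tree,
            "ld_block_size": int(self.ld_block_size),
            "ld_decay": float(self.ld_decay),
            "missing_rate": float(self.missing_rate),
            "seed": int(self.seed),
        }

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))


def load_scenario(name_or_path, seed: int | None = None) -> ScenarioConfig:
    """A packaged scenario by name (null / default_bias / strong_ld) or a YAML path."""
    if str(name_or_path) in PACKAGED_SCENARIOS:
        text = resources.files("ascbias").joinpath(f"scenarios/{name_or_path}.yaml").read_text()
        cfg = ScenarioConfig.from_dict(yaml.safe_load(text))
    else:
        cfg = ScenarioConfig.from_yaml(name_or_path)
    if seed is not None:
        cfg.seed = int(seed)
    return cfg


@dataclass
class SyntheticTruth:
    """Ground truth retained alongside the generated data."""

    true_freqs: np.ndarray  # (n_pops, n_loci) population frequencies
    sample_freqs: np.ndarray  # (n_pops, n_loci) realized sample frequencies
    ascertained_mask: np.ndarray | None  # (n_loci,) bool
    block_ids: np.ndarray  # (n_loci,) int
    panel_sample_ids: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# frequencies
# ---------------------------------------------------------------------------


def _bn_draw(p: np.ndarray, f: float, rng: np.random.Generator) -> np.ndarray:
    """One Balding-Nichols drift step around parent frequencies ``p``."""
    if f == 0.0:
        return p.copy()
    if f >= 1.0:
        raise ValueError("drift parameter F = 1 is degenerate and rejected")
    scale = (1.0 - f) / f
    out = p.copy()
    inner = (p > 0) & (p < 1)  # fixed loci stay fixed under pure drift
    out[inner] = rng.beta(p[inner] * scale, (1.0 - p[inner]) * scale)
    return out


def simulate_frequencies(cfg: ScenarioConfig, rng: np.random.Generator | None = None) -> np.ndarray:
    """True per-population allele frequencies, populations x loci.

    Without a population tree, each population drifts independently from the
    ancestral frequency with its own F (a star phylogeny). With a tree, drift
    is applied recursively along edges using the edge lengths as per-edge F,
    so clade structure is recoverable from the resulting frequencies.
    """
    rng = rng if rng is not None else substream(cfg.seed, "frequencies")
    kind, a, b = cfg.ancestral_freq_dist
    if kind == "uniform":
        p0 = rng.uniform(a, b, size=cfg.n_loci)
    else:
        p0 = rng.beta(a, b, size=cfg.n_loci)
    freqs = np.empty((len(cfg.populations), cfg.n_loci))
    if cfg.population_tree is None:
        for i, f in enumerate(cfg.f_per_population):
            freqs[i] = _bn_draw(p0, float(f), rng)
        return freqs
    tree = dendropy.Tree.get(data=cfg.population_tree, schema="newick")
    tips = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
    if tips != set(cfg.populations):
        raise ValueError(
            f"population tree tips {sorted(tips)} do not match populations {sorted(cfg.populations)}"
        )
    node_freq: dict[int, np.ndarray] = {id(tree.seed_node): p0}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        f_edge = float(node.edge.length or 0.0)
        node_freq[id(node)] = _bn_draw(node_freq[id(node.parent_node)], f_edge, rng)
    row = {pop: i for i, pop in enumerate(cfg.populations)}
    for leaf in tree.leaf_node_iter():
        freqs[row[leaf.taxon.label]] = node_freq[id(leaf)]
    return freqs


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------


def _snp_records(n_loci: int) -> list[SnpRecord]:
    width = max(6, len(str(n_loci)))
    return [
        SnpRecord(f"snp{i:0{width}d}", "1", (i + 1) * 100, "A", "G") for i in range(n_loci)
    ]


def simulate_genotypes(
    true_freqs: np.ndarray, cfg: ScenarioConfig
) -> tuple[GenotypeMatrix, SyntheticTruth]:
    """HWE diploid genotypes with template-copied LD blocks and missingness.

    Within a block of ``ld_block_size`` consecutive loci, each haplotype draws
    one uniform "template" value shared across the block; a locus carries the
    alternative allele iff its (template or freshly re-drawn, with probability
    1 - ld_decay) uniform lies below the population frequency. Marginally
    every locus is Bernoulli(p) per haplotype — Hardy-Weinberg holds — while
    shared templates induce within-block correlation.
    """
    true_freqs = np.asarray(true_freqs, dtype=float)
    n_pops, n_loci = true_freqs.shape
    if n_pops != len(cfg.populations):
        raise ValueError("true_freqs row count does not match populations")
    block_ids = np.arange(n_loci) // cfg.ld_block_size
    n_blocks = int(block_ids[-1]) + 1 if n_loci else 0
    snps = _snp_records(n_loci)

    sample_ids: list[str] = []
    sample_pops: list[str] = []
    dosage_blocks = []
    sample_freqs = np.empty_like(true_freqs)
    for i, pop in enumerate(cfg.populations):
        n_ind = cfg.n_individuals_per_pop[i]
        rng = substream(cfg.seed, "genotypes", pop)
        p = true_freqs[i]
        u_shared = rng.random((n_ind, 2, n_blocks))[:, :, block_ids]
        u_fresh = rng.random((n_ind, 2, n_loci))
        redraw = rng.random((n_ind, 2, n_loci)) < (1.0 - cfg.ld_decay)
        u = np.where(redraw, u_fresh, u_shared)
        haplos = u < p[None, None, :]
        dosages = haplos.sum(axis=1).astype(float)
        sample_freqs[i] = dosages.sum(axis=0) / (2.0 * n_ind)
        dosage_blocks.append(dosages)
        sample_ids.extend(f"{pop}_i{j + 1}" for j in range(n_ind))
        sample_pops.extend([pop] * n_ind)
    dosages = np.vstack(dosage_blocks)
    if cfg.missing_rate > 0:
        rng = substream(cfg.seed, "missing")
        dosages[rng.random(dosages.shape) < cfg.missing_rate] = np.nan
    geno = GenotypeMatrix(snps, sample_ids, sample_pops, dosages)
    truth = SyntheticTruth(
        true_freqs=true_freqs,
        sample_freqs=sample_freqs,
        ascertained_mask=None,
        block_ids=block_ids,
    )
    return geno, truth


# ---------------------------------------------------------------------------
# pooled reads
# ---------------------------------------------------------------------------


def simulate_pool_reads(source, cfg: ScenarioConfig) -> PooledFrequencyTable:
    """Pooled sequencing of each population: Poisson depth, binomial reads.

    ``source`` is a populations x loci array of sample allele frequencies (the
    DNA actually in the pool) or a GenotypeMatrix to derive them from.
    """
    if isinstance(source, GenotypeMatrix):
        from .diversity import sample_frequencies

        fm = sample_frequencies(source)
        if fm.populations != list(cfg.populations):
            raise ValueError("genotype populations do not match the scenario")
        freqs = np.nan_to_num(fm.freq, nan=0.0)
    else:
        freqs = np.asarray(source, dtype=float)
    n_pops, n_loci = freqs.shape
    rng = substream(cfg.seed, "pool")
    depth = rng.poisson(cfg.pool_coverage_mean, size=(n_pops, n_loci))
    alt = rng.binomial(depth, freqs)
    return PooledFrequencyTable(
        snps=_snp_records(n_loci),
        populations=list(cfg.populations),
        n_individuals=np.asarray(cfg.n_individuals_per_pop, dtype=int),
        alt_reads=alt,
        depth=depth,
    )


# ---------------------------------------------------------------------------
# discovery-panel ascertainment
# ---------------------------------------------------------------------------


def ascertain(geno: GenotypeMatrix, cfg: ScenarioConfig) -> tuple[SnpSubset, SyntheticTruth]:
    """Select "array" loci through a small discovery panel.

    The panel (drawn once, seeded) consists of ``n`` individuals from each
    listed population. A locus is retained iff it is polymorphic in the panel
    sample and its panel minor-allele frequency is >= the configured cutoff.
    """
    rng = substream(cfg.seed, "panel")
    sample_pops = np.asarray(geno.sample_populations)
    panel_rows: list[int] = []
    for pop, n in cfg.discovery_panel:
        rows = np.flatnonzero(sample_pops == pop)
        if n > rows.size:
            raise ValueError(
                f"panel asks for {n} individuals from {pop!r} but only {rows.size} exist"
            )
        chosen = rng.choice(rows, size=n, replace=False)
        panel_rows.extend(sorted(int(r) for r in chosen))
    panel = geno.dosages[panel_rows, :]
    with np.errstate(invalid="ignore"):
        p = np.nanmean(panel, axis=0) / 2.0
    maf = np.minimum(p, 1.0 - p)
    with np.errstate(invalid="ignore"):
        keep = (p > 0) & (p < 1) & (maf >= cfg.ascertainment_maf_min)
    keep &= ~np.isnan(p)
    ids = geno.snp_ids
    subset = SnpSubset([ids[i] for i in np.flatnonzero(keep)], "ascertained")
    truth = SyntheticTruth(
        true_freqs=np.empty((0, 0)),
        sample_freqs=np.empty((0, 0)),
        ascertained_mask=keep,
        block_ids=np.arange(geno.n_snps) // cfg.ld_block_size,
        panel_sample_ids=[geno.sample_ids[r] for r in panel_rows],
    )
    return subset, truth


# ---------------------------------------------------------------------------
# whole scenarios
# ---------------------------------------------------------------------------


@dataclass
class SimulatedStudy:
    """A complete synthetic study: array side, reference side, and truth."""

    config: ScenarioConfig
    genotypes: GenotypeMatrix  # all simulated loci
    array: GenotypeMatrix  # ascertained loci only
    pool: PooledFrequencyTable  # all simulated loci
    panel: PopulationPanel
    truth: SyntheticTruth


def simulate_scenario(cfg: ScenarioConfig) -> SimulatedStudy:
    """Run the full generator: frequencies, genotypes, pool reads, array loci."""
    true_freqs = simulate_frequencies(cfg)
    geno, truth = simulate_genotypes(true_freqs, cfg)
    pool = simulate_pool_reads(truth.sample_freqs, cfg)
    subset, asc = ascertain(geno, cfg)
    truth.ascertained_mask = asc.ascertained_mask
    truth.panel_sample_ids = asc.panel_sample_ids
    array = geno.take_snp_ids(subset.ids)
    panel = PopulationPanel(dict(zip(geno.sample_ids, geno.sample_populations)))
    return SimulatedStudy(cfg, geno, array, pool, panel, truth)
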