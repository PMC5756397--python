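"""The Balding-Nichols generator, LD blocks, pooled reads and ascertainment."""

import numpy as np
import pytest

from ascbias import diversity, phylo, synthetic_data as sd
from ascbias.types import FrequencyMatrix


def base_cfg(**overrides):
    params = dict(
        populations=["pop1", "pop2"],
        f_per_population=[0.1, 0.1],
        n_loci=2000,
        n_individuals_per_pop=[10, 10],
        discovery_panel=[("pop1", 4)],
        ascertainment_maf_min=0.05,
        ancestral_freq_dist=("uniform", 0.2, 0.8),
        seed=3,
    )
    params.update(overrides)
    return sd.ScenarioConfig(**params)


# ---------------------------------------------------------------------------
# frequencies
# ---------------------------------------------------------------------------


def test_zero_drift_returns_ancestral_exactly():
    cfg = base_cfg(f_per_population=[0.0, 0.0])
    f = sd.simulate_frequencies(cfg)
    np.testing.assert_array_equal(f[0], f[1])


def test_mean_frequency_matches_ancestral_expectation():
    cfg = base_cfg(
        n_loci=100_000, ancestral_freq_dist=("beta", 0.5, 1.5), f_per_population=[0.2, 0.05]
    )
    f = sd.simulate_frequencies(cfg)
    # law of total expectation: E[p] = E[p0] = 0.25 for Beta(0.5, 1.5)
    se = np.sqrt(0.25 * 0.75 / cfg.n_loci)  # conservative bound on SD/sqrt(n)
    for row in f:
        assert abs(row.mean() - 0.25) < 4 * se


@pytest.mark.parametrize("p0,f,expect", [(0.3, 0.1, 0.378), (0.5, 0.05, 0.475), (0.2, 0.3, 0.224)])
def test_heterozygosity_closed_form(p0, f, expect):
    """E[2p(1-p)] = 2 p0 (1-p0) (1-F) under Balding-Nichols drift."""
    cfg = base_cfg(
        populations=["x"],
        f_per_population=[f],
        n_individuals_per_pop=[10],
        discovery_panel=[("x", 4)],
        n_loci=100_000,
        ancestral_freq_dist=("uniform", p0, p0),
    )
    freqs = sd.simulate_frequencies(cfg)
    he = 2 * freqs * (1 - freqs)
    mc_se = he.std() / np.sqrt(cfg.n_loci)
    assert abs(he.mean() - expect) < 4 * mc_se


def test_tree_mode_recovers_clades():
    tree = "((pop1:0.3,pop2:0.3):0.15,(pop3:0.3,pop4:0.3):0.15);"
    cfg = base_cfg(
        populations=["pop1", "pop2", "pop3", "pop4"],
        f_per_population=[0.0] * 4,  # ignored in tree mode
        n_individuals_per_pop=[10] * 4,
        population_tree=tree,
        n_loci=20_000,
        ancestral_freq_dist=("uniform", 0.05, 0.95),
        seed=1,
    )
    freqs = sd.simulate_frequencies(cfg)
    fm = FrequencyMatrix(cfg.populations, np.full(4, 10), [f"l{i}" for i in range(cfg.n_loci)], freqs)
    nj = phylo.neighbor_joining(diversity.nei_distance_matrix(fm))
    truth = phylo.PhyloTree.from_newick(tree)
    assert phylo.partition_distance(nj, truth) == 0


def test_fst_increases_with_drift():
    fsts = []
    for f in (0.01, 0.05, 0.1, 0.2):
        cfg = base_cfg(
            f_per_population=[f, f],
            n_loci=100_000,
            ancestral_freq_dist=("uniform", 0.05, 0.95),
            seed=7,
        )
        freqs = sd.simulate_frequencies(cfg)
        fm = FrequencyMatrix(
            cfg.populations, np.full(2, 10), [f"l{i}" for i in range(cfg.n_loci)], freqs
        )
        fsts.append(diversity.pairwise_fst(fm, "pop1", "pop2", mode="weighted"))
    assert all(a < b for a, b in zip(fsts, fsts[1:]))


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------


def test_fixed_frequency_gives_fixed_genotypes():
    cfg = base_cfg(n_loci=50, ancestral_freq_dist=("uniform", 1.0, 1.0),
                   f_per_population=[0.0, 0.0])
    freqs = sd.simulate_frequencies(cfg)
    geno, truth = sd.simulate_genotypes(freqs, cfg)
    assert (geno.dosages == 2.0).all()
    assert (truth.sample_freqs == 1.0).all()


def test_ld_decay_zero_leaves_loci_uncorrelated():
    cfg = base_cfg(n_loci=400, ld_block_size=20, ld_decay=0.0,
                   n_individuals_per_pop=[60, 60], seed=5)
    freqs = sd.simulate_frequencies(cfg)
    geno, _ = sd.simulate_genotypes(freqs, cfg)
    X = geno.dosages[:60]  # one population
    rs = []
    for j in range(0, 399):
        a, b = X[:, j], X[:, j + 1]
        if a.std() > 0 and b.std() > 0:
            rs.append(np.corrcoef(a, b)[0, 1])
    rs = np.asarray(rs)
    se = 1 / np.sqrt((60 - 1) * len(rs))
    assert abs(rs.mean()) < 4 * se


def test_ld_blocks_raise_within_block_correlation():
    cfg = base_cfg(n_loci=400, ld_block_size=20, ld_decay=0.95,
                   n_individuals_per_pop=[60, 60], seed=5)
    freqs = sd.simulate_frequencies(cfg)
    geno, truth = sd.simulate_genotypes(freqs, cfg)
    X = geno.dosages[:60]
    blocks = truth.block_ids
    within, between = [], []
    rng = np.random.default_rng(0)
    for _ in range(2000):
        i, j = rng.integers(0, 400, size=2)
        if i == j or X[:, i].std() == 0 or X[:, j].std() == 0:
            continue
        r2 = np.corrcoef(X[:, i], X[:, j])[0, 1] ** 2
        (within if blocks[i] == blocks[j] else between).append(r2)
    assert np.mean(within) > 5 * np.mean(between)


def test_missingness_rate():
    cfg = base_cfg(missing_rate=0.1, n_loci=5000)
    freqs = sd.simulate_frequencies(cfg)
    geno, _ = sd.simulate_genotypes(freqs, cfg)
    rate = np.isnan(geno.dosages).mean()
    assert abs(rate - 0.1) < 0.01


# ---------------------------------------------------------------------------
# pooled reads
# ---------------------------------------------------------------------------


def test_pool_reads_basics_and_unbiasedness():
    cfg = base_cfg(n_loci=10_000, seed=11)
    freqs = sd.simulate_frequencies(cfg)
    geno, truth = sd.simulate_genotypes(freqs, cfg)
    pool = sd.simulate_pool_reads(truth.sample_freqs, cfg)
    assert (pool.alt_reads[truth.sample_freqs == 0] == 0).all()
    assert abs(pool.depth.mean() - 20.0) < 4 * 20**0.5 / np.sqrt(pool.depth.size)
    est = diversity.pooled_frequencies(pool).freq
    diff = est - truth.sample_freqs
    diff = diff[~np.isnan(diff)]
    assert abs(diff.mean()) < 3 * diff.std() / np.sqrt(diff.size)


# ---------------------------------------------------------------------------
# ascertainment
# ---------------------------------------------------------------------------


def test_ascertain_degenerate_panel_keeps_all_polymorphic():
    cfg = base_cfg(
        discovery_panel=[("pop1", 10), ("pop2", 10)], ascertainment_maf_min=0.0
    )
    freqs = sd.simulate_frequencies(cfg)
    geno, _ = sd.simulate_genotypes(freqs, cfg)
    subset, truth = sd.ascertain(geno, cfg)
    p = np.nanmean(geno.dosages, axis=0) / 2
    expected = [geno.snp_ids[i] for i in np.flatnonzero((p > 0) & (p < 1))]
    assert subset.ids == expected
    assert truth.ascertained_mask.sum() == len(expected)


def test_ascertain_panel_too_large_errors():
    cfg = base_cfg(discovery_panel=[("pop1", 99)])
    freqs = sd.simulate_frequencies(cfg)
    geno, _ = sd.simulate_genotypes(freqs, cfg)
    with pytest.raises(ValueError, match="pop1"):
        sd.ascertain(geno, cfg)


def test_ascertainment_depletes_rare_and_raises_he():
    """Panel MAF cutoffs underrepresent rare variants and inflate mean He."""
    cfg = sd.load_scenario("default_bias")
    cfg.n_loci = 10_000
    study = sd.simulate_scenario(cfg)
    mask = study.truth.ascertained_mask
    mean_freq = study.truth.true_freqs.mean(axis=0)
    rare_all = (mean_freq < 0.025).mean()
    rare_asc = (mean_freq[mask] < 0.025).mean()
    assert rare_asc < rare_all
    he = 2 * study.truth.true_freqs * (1 - study.truth.true_freqs)
    for i in range(len(cfg.populations)):
        assert he[i, mask].mean() > he[i].mean()


def test_scenario_bit_reproducible():
    cfg = base_cfg(missing_rate=0.01)
    s1 = sd.simulate_scenario(cfg)
    s2 = sd.simulate_scenario(cfg)
    np.testing.assert_array_equal(s1.genotypes.dosages, s2.genotypes.dosages)
    np.testing.assert_array_equal(s1.pool.alt_reads, s2.pool.alt_reads)
    np.testing.assert_array_equal(s1.truth.ascertained_mask, s2.truth.ascertained_mask)
    assert s1.array.snp_ids == s2.array.snp_ids


def test_packaged_scenarios_load():
    for name in sd.PACKAGED_SCENARIOS:
        cfg = sd.load_scenario(name, seed=4)
        assert cfg.seed == 4
        assert len(cfg.populations) == len(cfg.f_per_population)
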