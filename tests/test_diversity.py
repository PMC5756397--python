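"""Allele frequencies, spectra, He, F_ST, Nei distance, PCA, genic overlap."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import oracles
from ascbias import diversity as dv
from ascbias.types import FrequencyMatrix, SnpRecord, SnpSubset
from conftest import make_geno


def fm(freq, n=None, pops=None):
    freq = np.asarray(freq, dtype=float)
    r, L = freq.shape
    return FrequencyMatrix(
        populations=pops or [f"pop{i}" for i in range(r)],
        n_individuals=np.asarray(n if n is not None else [10] * r),
        loci=[f"l{j}" for j in range(L)],
        freq=freq,
    )


# ---------------------------------------------------------------------------
# frequencies
# ---------------------------------------------------------------------------


def test_sample_frequencies_direct_count():
    geno = make_geno(np.array([[1.0], [2.0]]))
    assert dv.sample_frequencies(geno).freq[0, 0] == pytest.approx(0.75)


def test_sample_frequencies_brute_force(rng):
    dos = rng.integers(0, 3, size=(20, 50)).astype(float)
    dos[rng.random(dos.shape) < 0.15] = np.nan
    pops = ["a"] * 8 + ["b"] * 12
    got = dv.sample_frequencies(make_geno(dos, populations=pops))
    for i, pop in enumerate(["a", "b"]):
        rows = [k for k, p in enumerate(pops) if p == pop]
        for j in range(50):
            alt = sum(dos[k, j] for k in rows if not np.isnan(dos[k, j]))
            called = sum(1 for k in rows if not np.isnan(dos[k, j]))
            expect = alt / (2 * called) if called else np.nan
            if np.isnan(expect):
                assert np.isnan(got.freq[i, j])
            else:
                assert got.freq[i, j] == pytest.approx(expect, abs=1e-12)


def test_all_reference_population_is_zero():
    geno = make_geno(np.zeros((4, 3)))
    assert (dv.sample_frequencies(geno).freq == 0).all()


# ---------------------------------------------------------------------------
# spectrum
# ---------------------------------------------------------------------------


def test_afs_boundaries():
    s = dv.afs(np.zeros(10))
    assert s.proportions[0] == 1.0
    s = dv.afs(np.ones(5))
    assert s.proportions[-1] == 1.0  # exactly 1 falls in the closed last bin
    with pytest.raises(ValueError):
        dv.afs(np.array([1.2]))


def test_afs_uniform_draws(rng):
    f = rng.random(100_000)
    s = dv.afs(f)
    se = np.sqrt(0.025 * 0.975 / 100_000)
    assert np.all(np.abs(s.proportions - 0.025) < 4 * se)
    assert s.proportions.sum() == pytest.approx(1.0, abs=1e-12)


def test_afs_pooling_equals_concatenation(rng):
    a, b = rng.random(1000), rng.random(400)
    pooled = dv.pool_spectra([dv.afs(a), dv.afs(b)])
    combined = dv.afs(np.concatenate([a, b]))
    np.testing.assert_allclose(pooled.proportions, combined.proportions, atol=1e-12)


# ---------------------------------------------------------------------------
# expected heterozygosity
# ---------------------------------------------------------------------------


def test_he_extremes_and_order_invariance(rng):
    assert dv.expected_heterozygosity(fm([[0.5, 0.5]]))["pop0"] == pytest.approx(0.5)
    assert dv.expected_heterozygosity(fm([[0.0, 0.0]]))["pop0"] == 0.0
    f = rng.random((3, 40))
    m = fm(f)
    perm = rng.permutation(40)
    shuffled = fm(f[:, perm])
    a = dv.expected_heterozygosity(m)
    b = dv.expected_heterozygosity(shuffled)
    for pop in a:
        assert a[pop] == pytest.approx(b[pop], abs=1e-12)


def test_he_empty_subset_errors():
    with pytest.raises(ValueError):
        dv.expected_heterozygosity(fm([[0.5]]), SnpSubset([], "x"))


# ---------------------------------------------------------------------------
# F_ST
# ---------------------------------------------------------------------------


def test_fst_fixed_difference_and_identity():
    m = fm([[0.0], [1.0]])
    assert dv.pairwise_fst(m, "pop0", "pop1", mode="equal") == pytest.approx(1.0)
    same = fm(np.tile(np.linspace(0.1, 0.9, 20), (2, 1)))
    assert dv.pairwise_fst(same, "pop0", "pop1") == pytest.approx(0.0, abs=1e-15)


def test_fst_weighted_equals_equal_for_same_n(rng):
    f = rng.random((2, 300))
    m = fm(f, n=[17, 17])
    eq = dv.pairwise_fst(m, "pop0", "pop1", mode="equal")
    we = dv.pairwise_fst(m, "pop0", "pop1", mode="weighted")
    assert we == pytest.approx(eq, abs=1e-14)


def test_fst_matches_scalar_oracle(rng):
    for trial in range(20):
        f = rng.random((2, 1000))
        f[rng.random(f.shape) < 0.02] = np.nan
        n = rng.integers(5, 40, size=2)
        m = fm(f, n=n)
        for mode in ("equal", "weighted"):
            expect = oracles.fst_two_pops(f[0], f[1], n[0], n[1], mode)
            got = dv.pairwise_fst(m, "pop0", "pop1", mode=mode)
            assert got == pytest.approx(expect, abs=1e-12)


@settings(max_examples=50, derandomize=True)
@given(st.integers(0, 2**32 - 1))
def test_fst_symmetric_and_label_swap_invariant(seed):
    rng = np.random.default_rng(seed)
    f = rng.random((2, 50))
    m = fm(f, n=[8, 23])
    a = dv.pairwise_fst(m, "pop0", "pop1")
    b = dv.pairwise_fst(m, "pop1", "pop0")
    assert a == pytest.approx(b, abs=1e-12)
    assert 0.0 <= a <= 1.0
    # swapping ref/alt labelling at every locus leaves F_ST unchanged
    swapped = fm(1.0 - f, n=[8, 23])
    assert dv.pairwise_fst(swapped, "pop0", "pop1") == pytest.approx(a, abs=1e-12)


# ---------------------------------------------------------------------------
# Nei distance
# ---------------------------------------------------------------------------


def test_nei_identity_symmetry_and_oracle(rng):
    f = rng.random((4, 500))
    f[rng.random(f.shape) < 0.03] = np.nan
    m = fm(f)
    got = dv.nei_distance_matrix(m)
    expect = oracles.nei_matrix(f)
    np.testing.assert_allclose(got.values, expect, atol=1e-12)
    np.testing.assert_allclose(got.values, got.values.T, atol=1e-15)
    assert np.all(np.diagonal(got.values) == 0)

    twin = fm(np.vstack([f[0], f[0]]), pops=["x", "y"])
    d = dv.nei_distance_matrix(twin)
    assert d.values[0, 1] == pytest.approx(0.0, abs=1e-12)


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------


def test_pca_identical_populations_coincide(rng):
    base = rng.random((3, 100))
    f = np.vstack([base, base[0]])
    res = dv.pca(fm(f), k=2)
    np.testing.assert_allclose(res.coordinates[0], res.coordinates[3], atol=1e-10)
    assert np.all(np.diff(res.variance_explained) <= 1e-12)
    assert np.all((res.variance_explained >= 0) & (res.variance_explained <= 1))


def test_pca_matches_eigendecomposition_oracle(rng):
    # two clades with a large between-clade shift
    f = np.clip(
        np.vstack(
            [rng.random((3, 200)) * 0.2, 0.8 + rng.random((3, 200)) * 0.2]
        ),
        0,
        1,
    )
    m = fm(f)
    res = dv.pca(m, k=2)
    X = f - f.mean(axis=0, keepdims=True)
    cov = X @ X.T
    w, v = np.linalg.eigh(cov)
    order = np.argsort(w)[::-1]
    w, v = w[order], v[:, order]
    # coordinates match the eigenvectors scaled by sqrt(eigenvalues), up to sign
    for k in range(2):
        expect = v[:, k] * np.sqrt(w[k])
        sign = np.sign(expect @ res.coordinates[:, k])
        np.testing.assert_allclose(res.coordinates[:, k], sign * expect, atol=1e-8)
    np.testing.assert_allclose(res.variance_explained, (w / w.sum())[:2], atol=1e-10)
    # PC1 separates the clades with a sign-invariant gap
    pc1 = res.coordinates[:, 0]
    assert max(pc1[:3]) < min(pc1[3:]) or min(pc1[:3]) > max(pc1[3:])


def test_pca_rank_error():
    f = np.tile(np.linspace(0, 1, 10), (3, 1))  # rank-1 after centering? rows equal
    with pytest.raises(ValueError, match="rank"):
        dv.pca(fm(f), k=2)


# ---------------------------------------------------------------------------
# genic classification
# ---------------------------------------------------------------------------


def test_genic_boundaries_and_empty():
    snps = [SnpRecord("a", "1", 100, "A", "G"), SnpRecord("b", "1", 99, "A", "G")]
    mask, _ = dv.genic_classification(snps, [("1", 100, 200)])
    assert mask.tolist() == [True, False]  # gene start coordinate is genic
    mask, _ = dv.genic_classification(snps, [])
    assert not mask.any()


def test_genic_matches_all_pairs_oracle(rng):
    snps = [
        SnpRecord(f"s{i}", str(rng.integers(1, 4)), int(rng.integers(1, 10_000)), "A", "G")
        for i in range(1000)
    ]
    intervals = []
    for _ in range(50):
        start = int(rng.integers(1, 9_500))
        intervals.append((str(rng.integers(1, 4)), start, start + int(rng.integers(1, 500))))
    freqs = rng.random(1000)
    mask, spectra = dv.genic_classification(snps, intervals, freqs)
    np.testing.assert_array_equal(mask, oracles.genic_mask(snps, intervals))
    assert set(spectra) <= {"genic", "non-genic"}
    for s in spectra.values():
        assert s.proportions.sum() == pytest.approx(1.0, abs=1e-12)
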