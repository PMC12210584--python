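import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from anosurv import popgen


def brute_force_pi(matrix: np.ndarray, L: float) -> float:
    """All-pairs Hamming counting, the definitional oracle."""
    n = matrix.shape[0]
    total = sum(
        int((matrix[i] != matrix[j]).sum()) for i, j in itertools.combinations(range(n), 2)
    )
    return total / (n * (n - 1) / 2) / L


# ---------------------------------------------------------------------------
# pi


def test_pi_monomorphic_zero():
    assert popgen.nucleotide_diversity(np.zeros((4, 3)), 10) == 0.0


def test_pi_single_site_example():
    # 4 haplotypes, one site 2 alt / 2 ref, L = 10: (2*2)/6/10
    h = np.array([[1], [1], [0], [0]])
    assert popgen.nucleotide_diversity(h, 10) == pytest.approx(4 / 6 / 10)


@settings(max_examples=30, deadline=None)
@given(st.integers(2, 8), st.integers(1, 12), st.integers(0, 10_000))
def test_pi_matches_all_pairs_oracle_and_is_order_invariant(n, S, seed):
    rng = np.random.default_rng(seed)
    h = rng.integers(0, 2, size=(n, S))
    L = 50.0
    expected = brute_force_pi(h, L)
    assert popgen.nucleotide_diversity(h, L) == pytest.approx(expected, abs=1e-12)
    perm = rng.permutation(n)
    assert popgen.nucleotide_diversity(h[perm], L) == pytest.approx(expected, abs=1e-12)


def test_pi_input_validation():
    with pytest.raises(ValueError):
        popgen.nucleotide_diversity(np.zeros((1, 3)), 10)
    with pytest.raises(ValueError):
        popgen.nucleotide_diversity(np.zeros((4, 3)), 0)


# ---------------------------------------------------------------------------
# Watterson


def test_watterson_examples():
    assert popgen.watterson_theta(0, 10, 100) == 0.0
    assert popgen.watterson_theta(3, 4, 1) == pytest.approx(3 / (1 + 1 / 2 + 1 / 3), abs=1e-4)
    assert popgen.watterson_theta(5, 6, 200) == popgen.watterson_theta(5, 6, 100) / 2


def test_watterson_needs_two_haplotypes():
    with pytest.raises(ValueError):
        popgen.watterson_theta(3, 1, 100)


# ---------------------------------------------------------------------------
# Tajima's D


def textbook_tajimas_d(matrix: np.ndarray) -> float | None:
    """Independent implementation straight from the published constants."""
    n, _ = matrix.shape
    counts = matrix.sum(axis=0)
    seg = (counts > 0) & (counts < n)
    S = int(seg.sum())
    if S == 0:
        return None
    a1 = sum(1 / i for i in range(1, n))
    a2 = sum(1 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3 * (n - 1))
    b2 = 2 * (n**2 + n + 3) / (9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    pairs = n * (n - 1) / 2
    k = 0.0
    for i, j in itertools.combinations(range(n), 2):
        k += (matrix[i] != matrix[j]).sum()
    k /= pairs
    return (k - S / a1) / np.sqrt(e1 * S + e2 * S * (S - 1))


@pytest.mark.parametrize("seed", range(10))
def test_tajimas_d_matches_textbook_implementation(seed):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(4, 30))
    S = int(rng.integers(1, 40))
    h = rng.integers(0, 2, size=(n, S))
    expected = textbook_tajimas_d(h)
    got = popgen.tajimas_d(h)
    if expected is None:
        assert got is None
    else:
        assert got == pytest.approx(expected, abs=1e-12)


def test_tajimas_d_undefined_at_no_segregating_sites():
    assert popgen.tajimas_d(np.zeros((6, 5), dtype=int)) is None


def test_tajimas_d_negative_after_sweep():
    """A cohort dominated by one haplotype with rare variants has D < 0."""
    h = np.zeros((20, 30), dtype=int)
    for j in range(30):  # singletons on scattered backgrounds
        h[j % 20, j] = 1
    assert popgen.tajimas_d(h) < 0


# ---------------------------------------------------------------------------
# Hudson FST


def test_fst_identical_frequencies_near_zero():
    """Two large cohorts drawn at the same site frequencies: FST ~ 0."""
    rng = np.random.default_rng(1)
    freqs = rng.uniform(0.1, 0.9, size=800)
    a = (rng.random(size=(100, 800)) < freqs).astype(int)
    b = (rng.random(size=(100, 800)) < freqs).astype(int)
    r = popgen.hudson_fst_haplotypes(a, b)
    assert abs(r.fst) < 0.01


def test_fst_fixed_differences_is_one():
    a = np.zeros((10, 50), dtype=int)
    b = np.ones((10, 50), dtype=int)
    r = popgen.hudson_fst_haplotypes(a, b)
    assert r.fst == pytest.approx(1.0)


def test_fst_symmetry_exact():
    rng = np.random.default_rng(2)
    a = rng.integers(0, 2, size=(12, 80))
    b = rng.integers(0, 2, size=(16, 80))
    assert popgen.hudson_fst_haplotypes(a, b).fst == popgen.hudson_fst_haplotypes(b, a).fst


def test_fst_split_half_centered_on_zero():
    """Random halves of one cohort show no differentiation on average."""
    rng = np.random.default_rng(3)
    vals = []
    for _ in range(20):
        freqs = rng.uniform(0.05, 0.95, size=400)
        h = (rng.random(size=(60, 400)) < freqs).astype(int)
        vals.append(popgen.hudson_fst_haplotypes(h[:30], h[30:]).fst)
    assert abs(np.mean(vals)) < 0.005


def test_fst_undefined_zero_denominator():
    a = np.zeros((4, 3), dtype=int)
    r = popgen.hudson_fst_haplotypes(a, a)
    assert r.fst is None


def test_fst_excludes_low_count_sites():
    alt1 = np.array([2, 1])
    tot1 = np.array([10, 1])  # second site: < 2 alleles in cohort 1
    alt2 = np.array([8, 1])
    tot2 = np.array([10, 10])
    r = popgen.hudson_fst(alt1, tot1, alt2, tot2)
    assert np.isnan(r.numerator[1])


# ---------------------------------------------------------------------------
# PCA


def _structured_genotypes(seed=0, n=40, S=600, fst=0.1):
    from anosurv.sim import BaldingNicholsSpec, simulate_balding_nichols

    spec = BaldingNicholsSpec(n_sites=S, fst=fst, deme_sizes={"a": n, "b": n})
    demes = simulate_balding_nichols(spec, seed)
    ga, gb = demes["a"], demes["b"]
    from anosurv.io import GenotypeMatrix

    return GenotypeMatrix(
        contig="2R",
        positions=ga.positions,
        ref=ga.ref,
        alt=ga.alt,
        matrix=np.vstack([ga.matrix, gb.matrix]),
        sample_ids=ga.sample_ids + gb.sample_ids,
    )


def test_pca_duplicated_sample_identical_coordinates():
    gen = _structured_genotypes(seed=5)
    m = np.vstack([gen.matrix, gen.matrix[:1]])
    from anosurv.io import GenotypeMatrix

    gen2 = GenotypeMatrix(
        contig="2R", positions=gen.positions, ref=gen.ref, alt=gen.alt,
        matrix=m, sample_ids=gen.sample_ids + ("dup",),
    )
    res = popgen.pca_allele_counts(gen2, n_snps=500, min_maf=0.05)
    assert np.allclose(res.coords[0], res.coords[-1], atol=1e-8)


def test_pca_variance_explained_non_increasing():
    res = popgen.pca_allele_counts(_structured_genotypes(), n_snps=400, min_maf=0.05)
    assert np.all(np.diff(res.variance_explained) <= 1e-12)


def test_pca_separates_demes_on_pc1():
    from sklearn.metrics import silhouette_score

    gen = _structured_genotypes(seed=11, fst=0.1)
    res = popgen.pca_allele_counts(gen, n_snps=600, min_maf=0.05)
    labels = [0] * 40 + [1] * 40
    assert silhouette_score(res.coords[:, :1], labels) > 0.5


def test_pca_site_order_invariant():
    gen = _structured_genotypes(seed=7)
    res1 = popgen.pca_allele_counts(gen, n_snps=10_000, min_maf=0.05)
    rng = np.random.default_rng(0)
    perm = rng.permutation(gen.n_sites)
    from anosurv.io import GenotypeMatrix

    # permute then restore ordering by position so site set is identical
    order = np.argsort(gen.positions[perm])
    gen2 = GenotypeMatrix(
        contig="2R",
        positions=gen.positions[perm][order],
        ref=gen.ref[perm][order],
        alt=gen.alt[perm][order],
        matrix=gen.matrix[:, perm][:, order],
        sample_ids=gen.sample_ids,
    )
    res2 = popgen.pca_allele_counts(gen2, n_snps=10_000, min_maf=0.05)
    assert np.allclose(res1.coords[:, :2], res2.coords[:, :2], atol=1e-8)


def test_windowed_fst_consistent_with_whole_region():
    rng = np.random.default_rng(9)
    a = rng.integers(0, 2, size=(30, 200))
    b = rng.integers(0, 2, size=(30, 200))
    res = popgen.hudson_fst_haplotypes(a, b)
    positions = np.arange(200) * 50  # 10 kb region
    starts, vals = popgen.windowed_fst(res, positions, window_bp=2500)
    assert starts.size == 4
    # recombining the window components reproduces the global estimate
    num = np.nansum(res.numerator)
    den = np.nansum(res.denominator)
    assert num / den == pytest.approx(res.fst)
    assert np.all(np.isfinite(vals))


def test_diversity_stats_refuses_small_cohorts(toy_haplotypes):
    with pytest.raises(ValueError, match="minimum"):
        popgen.diversity_stats(toy_haplotypes, "tiny", 1000.0, min_size=10)
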