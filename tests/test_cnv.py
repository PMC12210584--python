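import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from anosurv import cnv
from anosurv.io import GeneModel
from anosurv.sim import CnvSpec, CoverageSpec, simulate_coverage


# ---------------------------------------------------------------------------
# Normalization


def test_normalize_definition():
    counts = np.full(200, 30.0)
    counts[10] = 60.0
    norm = cnv.normalize_coverage(counts)
    assert norm[0] == pytest.approx(2.0)
    assert norm[10] == pytest.approx(4.0)


def test_normalize_male_x_ploidy():
    counts = np.full(200, 15.0)  # half the autosomal depth
    norm = cnv.normalize_coverage(counts, ploidy=1, median=30.0)
    assert norm[0] == pytest.approx(0.5)
    # at ploidy 1, a count equal to half the autosomal median maps to 1.0
    norm2 = cnv.normalize_coverage(counts, ploidy=1, median=15.0)
    assert norm2[0] == pytest.approx(1.0)


def test_normalize_zero_median_error():
    with pytest.raises(ValueError, match="zero median"):
        cnv.normalize_coverage(np.zeros(10), sample_id="s1")


def test_normalize_mask_excluded_from_median():
    counts = np.concatenate([np.full(50, 30.0), np.full(50, 300.0)])
    mask = np.concatenate([np.zeros(50, bool), np.ones(50, bool)])
    norm = cnv.normalize_coverage(counts, mask=mask)
    assert norm[0] == pytest.approx(2.0)


# ---------------------------------------------------------------------------
# Variance filter


def test_variance_filter_constant_passes():
    ok, v = cnv.coverage_variance_filter(np.full(200, 2.0))
    assert ok and v == 0.0


def test_variance_filter_boundary_is_strict():
    # variance exactly at the threshold passes (removal requires > 0.35)
    x = np.zeros(200)
    x[:100] = 2.0 + np.sqrt(0.35) * 2
    x[100:] = 2.0 - np.sqrt(0.35) * 2
    ok, v = cnv.coverage_variance_filter(x)
    assert v == pytest.approx(0.35)
    assert ok


def test_variance_filter_overdispersed_sample_fails():
    # dispersion k = 3 at mean 30: Var = m + m^2/k = 330, and the
    # median-scaled diploid variance lands near 0.5, past the cutoff
    rng = np.random.default_rng(0)
    k, mean = 3.0, 30.0
    counts = rng.negative_binomial(k, k / (k + mean), size=2000)
    norm = cnv.normalize_coverage(counts.astype(float))
    ok, v = cnv.coverage_variance_filter(norm)
    assert not ok
    assert 0.35 < v < 1.0


def test_variance_filter_needs_windows():
    with pytest.raises(ValueError):
        cnv.coverage_variance_filter(np.full(50, 2.0))


# ---------------------------------------------------------------------------
# Viterbi decoding


def test_decode_flat_baseline_likelihood_ratio_one():
    path = cnv.decode_copy_number(np.full(300, 2.0))
    assert (path.states == 2).all()
    assert path.log_likelihood == pytest.approx(path.null_log_likelihood)


def test_decode_single_outlier_does_not_switch():
    """One 6.0 window among noisy baseline stays at copy 2.

    Noise at the working limit (sd ~ 0.55 per window): the single-window
    emission gain ~ (6-2)^2 / (2 v) ~ 12 cannot pay the two off-diagonal
    transitions (2 * ln((1-stay)/K / stay) ~ -23.3).
    """
    x = 2.0 + 0.55 * np.where(np.arange(50) % 2 == 0, 1.0, -1.0)
    x[25] = 6.0
    path = cnv.decode_copy_number(x)
    assert (path.states == 2).all()


def test_decode_single_outlier_hand_computed_toy():
    """3-window toy with alternating +-0.3 noise: MAD gives v ~ 0.20,
    the middle window's gain for state 3 is (1.2^2 - 0.2^2)/(2 v) ~ 3.5,
    far below the ~23.3 transition cost, so the path stays at 2-2-2.
    """
    x = np.array([2.3, 1.7, 2.3, 1.7, 3.2, 2.3, 1.7, 2.3, 1.7])
    path = cnv.decode_copy_number(x)
    assert (path.states == 2).all()


def test_decode_sustained_amplification_recovered():
    x = np.full(200, 2.0) + np.random.default_rng(1).normal(0, 0.25, 200)
    x[80:100] += 2.0  # copy 4 over 20 windows
    path = cnv.decode_copy_number(x)
    assert (path.states[82:98] == 4).mean() >= 0.9
    assert (path.states[:78] == 2).all() and (path.states[102:] == 2).all()


@settings(max_examples=20, deadline=None)
@given(st.integers(0, 10_000))
def test_viterbi_never_below_forced_baseline(seed):
    rng = np.random.default_rng(seed)
    x = 2.0 + rng.normal(0, 0.4, size=150)
    x[rng.integers(0, 150)] += rng.uniform(0, 4)
    path = cnv.decode_copy_number(x)
    assert path.log_likelihood >= path.null_log_likelihood - 1e-9


def test_decode_rejects_non_finite():
    x = np.full(100, 2.0)
    x[3] = np.nan
    with pytest.raises(ValueError):
        cnv.decode_copy_number(x)


# ---------------------------------------------------------------------------
# Calls


def _cov_matrix(counts_row, span=300):
    counts_row = np.asarray(counts_row, dtype=float)
    return cnv.CoverageMatrix(
        contig="2R",
        starts=np.arange(counts_row.size) * span,
        counts=counts_row[None, :],
        sample_ids=("s1",),
        span=span,
    )


def test_call_requires_five_windows():
    rng = np.random.default_rng(2)
    counts = rng.normal(30, 1.5, 300).clip(1)
    counts[100:104] *= 2  # only 4 windows amplified
    calls, ok, _ = cnv.call_sample_cnvs(_cov_matrix(counts), "s1")
    assert ok and calls == []
    counts[100:105] = 60  # 5 windows
    calls, ok, _ = cnv.call_sample_cnvs(_cov_matrix(counts), "s1")
    assert len(calls) == 1
    assert calls[0].n_windows == 5 and calls[0].copy_number == 4


def test_call_likelihood_ratio_threshold():
    rng = np.random.default_rng(3)
    counts = rng.normal(30, 1.5, 300).clip(1)
    counts[50:70] *= 2
    calls, _, _ = cnv.call_sample_cnvs(_cov_matrix(counts), "s1")
    (call,) = calls
    assert call.log_likelihood_ratio > np.log(1000)
    # an impossible threshold suppresses the call
    calls2, _, _ = cnv.call_sample_cnvs(
        _cov_matrix(counts), "s1", min_likelihood_ratio=float("inf")
    )
    assert calls2 == []


def test_calls_scale_invariant():
    rng = np.random.default_rng(4)
    counts = rng.normal(30, 1.5, 400).clip(1)
    counts[200:220] *= 2
    c1, _, _ = cnv.call_sample_cnvs(_cov_matrix(counts), "s1")
    c2, _, _ = cnv.call_sample_cnvs(_cov_matrix(counts * 7.3), "s1")
    assert [(c.start, c.end, c.copy_number) for c in c1] == [
        (c.start, c.end, c.copy_number) for c in c2
    ]


def test_baseline_path_yields_no_calls():
    counts = np.random.default_rng(5).normal(30, 1.5, 300).clip(1)
    calls, ok, _ = cnv.call_sample_cnvs(_cov_matrix(counts), "s1")
    assert ok and calls == []


def test_deletions_not_emitted_as_calls():
    rng = np.random.default_rng(6)
    counts = rng.normal(30, 1.5, 300).clip(1)
    counts[100:140] *= 0.5  # copy 1 run
    calls, ok, _ = cnv.call_sample_cnvs(_cov_matrix(counts), "s1")
    assert calls == []


def test_male_x_single_copy_gain_called():
    rng = np.random.default_rng(7)
    counts = rng.normal(15, 1.0, 300).clip(1)  # haploid X at half depth
    counts[40:60] *= 2  # copy 2 on a male X: reportable (> 1)
    calls, ok, _ = cnv.call_sample_cnvs(_cov_matrix(counts), "s1", ploidy=1)
    (call,) = calls
    assert call.copy_number == 2


# ---------------------------------------------------------------------------
# Simulation recovery and gene frequencies


def test_simulated_amplification_recovery():
    ids = tuple(f"s{i}" for i in range(12))
    cov, truth_cn, segs = simulate_coverage(
        ids, [CnvSpec(0.4, 4, 100, 10)], CoverageSpec(), 300, seed=11
    )
    bias = cnv.estimate_window_bias(cov)
    carriers = set(segs[0]["carriers"])
    called = set()
    accs = []
    for i, sid in enumerate(ids):
        calls, ok, _ = cnv.call_sample_cnvs(cov, sid, bias=bias)
        called |= {c.sample_id for c in calls}
        norm = cnv.normalize_coverage(cov.row(sid), bias=bias)
        accs.append((cnv.decode_copy_number(norm).states == truth_cn[i]).mean())
    assert called == carriers
    assert np.mean(accs) >= 0.95


def _call(sample, start, end, cn=4):
    return cnv.CNVCall(sample, "2R", start, end, cn, (end - start) // 300, 50.0)


def test_gene_cnv_frequency_thresholds():
    gene = GeneModel("AGAP_G", "2R", "+", ((30_000, 30_900),))
    cohort = tuple(f"s{i}" for i in range(25))
    calls = [_call("s0", 29_700, 31_200)]  # 1 carrier of 25 -> 0.04
    (row,) = cnv.gene_cnv_frequency(calls, [gene], cohort, "c")
    assert row.frequency == pytest.approx(0.04)
    assert not row.reported
    # all 20 of a smaller cohort carry it -> fixation, reported
    cohort20 = tuple(f"s{i}" for i in range(20))
    calls = [_call(s, 29_700, 31_200) for s in cohort20]
    (row,) = cnv.gene_cnv_frequency(calls, [gene], cohort20, "c")
    assert row.frequency == 1.0 and row.reported


def test_gene_cnv_frequency_overlap_semantics():
    gene = GeneModel("AGAP_G", "2R", "+", ((30_000, 30_900),))
    cohort = ("s0",)
    adjacent = [_call("s0", 28_000, 30_000)]  # ends where the gene starts
    (row,) = cnv.gene_cnv_frequency(adjacent, [gene], cohort, "c")
    assert row.carriers == 0
    touching = [_call("s0", 28_000, 30_300)]  # one window of overlap
    (row,) = cnv.gene_cnv_frequency(touching, [gene], cohort, "c")
    assert row.carriers == 1


def test_gene_cnv_frequency_empty_cohort_error():
    with pytest.raises(ValueError, match="empty cohort"):
        cnv.gene_cnv_frequency([], [], (), "c")
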