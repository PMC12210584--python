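"""Cohort diversity and structure statistics.

Implements the standard estimators used for cohort-level surveillance
summaries: nucleotide diversity pi, Watterson's theta, Tajima's D,
Hudson's pairwise FST (ratio of averages), and PCA on allele counts.

Diversity statistics refuse cohorts below a minimum size (default ten
individuals); that gate lives in :func:`diversity_stats`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from anosurv.io import MISSING, GenotypeMatrix, HaplotypeMatrix

log = logging.getLogger(__name__)


@dataclass
class DiversityStats:
    cohort: str
    region: str
    n: int  # haplotype count
    S: int  # segregating sites
    pi: float  # per bp
    theta_w: float  # per bp
    tajima_d: float | None  # None when S == 0 (undefined, never coerced to 0)


@dataclass
class FstResult:
    pair: tuple[str, str]
    fst: float | None
    numerator: np.ndarray  # per-site Hudson numerator
    denominator: np.ndarray  # per-site Hudson denominator


@dataclass
class PcaResult:
    coords: np.ndarray  # (n_samples, n_components)
    variance_explained: np.ndarray  # fraction per component, non-increasing
    sample_ids: tuple[str, ...]
    n_snps: int
    min_maf: float


def _site_allele_counts(matrix: np.ndarray) -> np.ndarray:
    """Alt-allele count per column of a binary haplotype matrix."""
    return matrix.sum(axis=0)


def nucleotide_diversity(haplotypes: np.ndarray, region_length: float) -> float:
    """Mean pairwise Hamming distance per base pair.

    ``pi = sum_{i<j} d(h_i, h_j) / C(n,2) / L``, computed site-wise as
    ``sum_s 2 c_s (n - c_s) / (n (n-1)) / L`` with ``c_s`` the alt count.
    """
    h = np.asarray(haplotypes)
    n = h.shape[0]
    if n < 2:
        raise ValueError("need at least 2 haplotypes")
    if region_length <= 0:
        raise ValueError("region length must be positive")
    c = _site_allele_counts(h).astype(np.float64)
    pairdiff = (2.0 * c * (n - c)).sum() / (n * (n - 1))
    return float(pairdiff / region_length)


def harmonic(n: int) -> float:
    """a_n = sum_{i=1}^{n-1} 1/i."""
    return float(np.sum(1.0 / np.arange(1, n)))


def watterson_theta(S: int, n: int, region_length: float) -> float:
    """Watterson's estimator per bp: S / a_n / L."""
    if n < 2:
        raise ValueError("need at least 2 haplotypes")
    if region_length <= 0:
        raise ValueError("region length must be positive")
    return float(S / harmonic(n) / region_length)


def _tajima_constants(n: int) -> dict[str, float]:
    a1 = harmonic(n)
    a2 = float(np.sum(1.0 / np.arange(1, n) ** 2))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n * n + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / (a1 * a1)
    e1 = c1 / a1
    e2 = c2 / (a1 * a1 + a2)
    return {"a1": a1, "a2": a2, "b1": b1, "b2": b2, "c1": c1, "c2": c2, "e1": e1, "e2": e2}


def tajimas_d(haplotypes: np.ndarray) -> float | None:
    """Tajima's D from a binary haplotype matrix.

    Returns ``None`` (flagged missing) when there are no segregating
    sites: D is undefined there, never zero.
    """
    h = np.asarray(haplotypes)
    n = h.shape[0]
    if n < 4:
        raise ValueError("Tajima's D needs at least 4 haplotypes")
    c = _site_allele_counts(h)
    seg = (c > 0) & (c < n)
    S = int(seg.sum())
    if S == 0:
        return None
    k = _tajima_constants(n)
    cseg = c[seg].astype(np.float64)
    pi_total = (2.0 * cseg * (n - cseg)).sum() / (n * (n - 1))
    var = k["e1"] * S + k["e2"] * S * (S - 1)
    return float((pi_total - S / k["a1"]) / np.sqrt(var))


def hudson_fst(
    alt1: np.ndarray,
    tot1: np.ndarray,
    alt2: np.ndarray,
    tot2: np.ndarray,
    pair: tuple[str, str] = ("A", "B"),
) -> FstResult:
    """Hudson's FST as a ratio of averages over sites.

    Per site: ``N = (p1-p2)^2 - p1(1-p1)/(n1-1) - p2(1-p2)/(n2-1)`` and
    ``D = p1(1-p2) + p2(1-p1)``; ``FST = sum N / sum D``. Sites with
    fewer than two sampled alleles in either cohort are excluded.
    """
    alt1 = np.asarray(alt1, dtype=np.float64)
    alt2 = np.asarray(alt2, dtype=np.float64)
    tot1 = np.asarray(tot1, dtype=np.float64)
    tot2 = np.asarray(tot2, dtype=np.float64)
    ok = (tot1 >= 2) & (tot2 >= 2)
    num = np.full(alt1.shape, np.nan)
    den = np.full(alt1.shape, np.nan)
    p1, p2 = alt1[ok] / tot1[ok], alt2[ok] / tot2[ok]
    n1, n2 = tot1[ok], tot2[ok]
    # grouping keeps fst(A,B) == fst(B,A) bit-exact under swap
    num[ok] = (p1 - p2) ** 2 - (p1 * (1 - p1) / (n1 - 1) + p2 * (1 - p2) / (n2 - 1))
    den[ok] = p1 * (1 - p2) + p2 * (1 - p1)
    dsum = np.nansum(den)
    if not dsum > 0:
        log.warning("Hudson FST undefined for %s: zero denominator", pair)
        return FstResult(pair, None, num, den)
    return FstResult(pair, float(np.nansum(num) / dsum), num, den)


def hudson_fst_haplotypes(
    h1: HaplotypeMatrix | np.ndarray,
    h2: HaplotypeMatrix | np.ndarray,
    pair: tuple[str, str] = ("A", "B"),
) -> FstResult:
    """Hudson FST between two cohorts given their haplotype matrices."""
    m1 = h1.matrix if isinstance(h1, HaplotypeMatrix) else np.asarray(h1)
    m2 = h2.matrix if isinstance(h2, HaplotypeMatrix) else np.asarray(h2)
    if m1.shape[1] != m2.shape[1]:
        raise ValueError("cohorts must share the same site set")
    n1 = np.full(m1.shape[1], m1.shape[0])
    n2 = np.full(m2.shape[1], m2.shape[0])
    return hudson_fst(m1.sum(axis=0), n1, m2.sum(axis=0), n2, pair)


def windowed_fst(
    result: FstResult, positions: np.ndarray, window_bp: int
) -> tuple[np.ndarray, np.ndarray]:
    """Hudson FST in fixed bp windows from a whole-region result.

    Re-uses the per-site numerator/denominator components (ratio of
    averages within each window). Returns (window starts, FST values;
    NaN where a window has no usable sites or a zero denominator).
    """
    positions = np.asarray(positions)
    if positions.size != result.numerator.size:
        raise ValueError("positions must match the per-site components")
    lo = int(positions.min()) // window_bp * window_bp if positions.size else 0
    hi = int(positions.max()) + 1 if positions.size else 0
    starts = np.arange(lo, hi, window_bp)
    vals = np.full(starts.size, np.nan)
    idx = (positions - lo) // window_bp
    for w in range(starts.size):
        sel = idx == w
        dsum = np.nansum(result.denominator[sel])
        if dsum > 0:
            vals[w] = np.nansum(result.numerator[sel]) / dsum
    return starts, vals


def diversity_stats(
    hap: HaplotypeMatrix,
    cohort_name: str,
    region_length: float,
    region: str = "",
    min_size: int = 10,
) -> DiversityStats:
    """Per-cohort diversity summary; refuses cohorts below ``min_size``."""
    n_ind = len(hap.sample_ids)
    if n_ind < min_size:
        raise ValueError(
            f"cohort {cohort_name}: {n_ind} individuals < minimum {min_size} "
            "for diversity statistics"
        )
    h = hap.matrix
    c = _site_allele_counts(h)
    seg = (c > 0) & (c < h.shape[0])
    S = int(seg.sum())
    return DiversityStats(
        cohort=cohort_name,
        region=region or hap.contig,
        n=h.shape[0],
        S=S,
        pi=nucleotide_diversity(h, region_length),
        theta_w=watterson_theta(S, h.shape[0], region_length),
        tajima_d=tajimas_d(h),
    )


def pca_allele_counts(
    gen: GenotypeMatrix,
    n_snps: int = 100_000,
    min_maf: float = 0.2,
    n_components: int = 10,
) -> PcaResult:
    """PCA on mean-centred allele dosages.

    Sites are filtered to segregating, complete (no missing), minor
    allele frequency above ``min_maf``; then thinned evenly along the
    region to ``n_snps`` (all retained, with a warning, when fewer
    qualify). Component signs follow the convention that the
    largest-magnitude loading of each component is positive.
    """
    if gen.n_samples < 2:
        raise ValueError("PCA needs at least 2 samples")
    G = gen.matrix
    complete = ~np.any(G == MISSING, axis=0)
    freq = G.sum(axis=0) / (2.0 * G.shape[0])
    maf = np.minimum(freq, 1.0 - freq)
    keep = complete & (maf > min_maf)
    idx = np.flatnonzero(keep)
    if idx.size == 0:
        raise ValueError("no sites pass the PCA filters")
    if idx.size > n_snps:
        pick = np.linspace(0, idx.size - 1, n_snps).round().astype(int)
        idx = idx[np.unique(pick)]
    else:
        log.warning("only %d sites qualify for PCA (requested %d)", idx.size, n_snps)
    X = G[:, idx].astype(np.float64)
    X -= X.mean(axis=0, keepdims=True)
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    k = min(n_components, s.size)
    # sign convention: largest-|loading| entry of each right singular vector positive
    for j in range(k):
        i_max = np.argmax(np.abs(Vt[j]))
        if Vt[j, i_max] < 0:
            Vt[j] *= -1.0
            U[:, j] *= -1.0
    coords = U[:, :k] * s[:k]
    var = s**2
    return PcaResult(
        coords=coords,
        variance_explained=(var / var.sum())[:k],
        sample_ids=gen.sample_ids,
        n_snps=idx.size,
        min_maf=min_maf,
    )
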