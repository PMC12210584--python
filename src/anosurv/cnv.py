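"""Copy-number inference from windowed read depth with a Gaussian HMM.

Per-sample window counts over fixed 300 bp windows are normalized to
copy-number units (ploidy x count / autosomal median count), and integer
copy number 0..K_max is decoded by Viterbi under a Gaussian emission
model whose mean equals the state and whose variance grows linearly with
the state. Amplification calls are contiguous runs of at least five
windows above ploidy, retained when the likelihood ratio against the
forced-baseline path exceeds 1000. Samples whose normalized coverage
variance exceeds 0.35 are excluded as unreliable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from anosurv.io import GeneModel

log = logging.getLogger(__name__)

WINDOW_SPAN = 300
DEFAULT_K_MAX = 12
DEFAULT_STAY = 1.0 - 1e-4
DEFAULT_MIN_WINDOWS = 5
DEFAULT_MIN_LR = 1000.0
VARIANCE_THRESHOLD = 0.35
_VAR_FLOOR = 1e-4  # keeps emissions finite on noiseless input


@dataclass
class CoverageMatrix:
    """Window read counts for one contig: n samples x W fixed-span windows."""

    contig: str
    starts: np.ndarray  # 0-based window starts, uniform span
    counts: np.ndarray  # (n, W), non-negative
    sample_ids: tuple[str, ...]
    span: int = WINDOW_SPAN

    def __post_init__(self) -> None:
        self.starts = np.asarray(self.starts, dtype=np.int64)
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2 or self.counts.shape != (
            len(self.sample_ids),
            self.starts.size,
        ):
            raise ValueError("counts must be (n samples, n windows)")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")
        if self.starts.size > 1:
            d = np.diff(self.starts)
            if not np.all(d == self.span):
                raise ValueError(f"windows must tile the contig at span {self.span}")

    @property
    def n_windows(self) -> int:
        return self.starts.size

    def row(self, sample_id: str) -> np.ndarray:
        return self.counts[self.sample_ids.index(sample_id)]


@dataclass
class CopyNumberPath:
    states: np.ndarray  # decoded copy number per window
    log_likelihood: float  # Viterbi path joint log-likelihood
    null_log_likelihood: float  # forced all-baseline path
    emission_loglik: np.ndarray  # (K_max+1, W) cached for call scoring
    ploidy: int


@dataclass
class CNVCall:
    sample_id: str
    contig: str
    start: int  # bp, 0-based half-open over the run's windows
    end: int
    copy_number: int  # modal state over the run
    n_windows: int
    log_likelihood_ratio: float  # ln LR vs baseline over the run windows


def read_coverage(path) -> CoverageMatrix:
    """Read a window-count TSV (contig, start, end, one column per sample)."""
    df = pd.read_csv(path, sep="\t")
    contigs = df["contig"].unique()
    if len(contigs) != 1:
        raise ValueError(f"{path}: expected one contig, got {list(contigs)}")
    samples = tuple(c for c in df.columns if c not in ("contig", "start", "end"))
    span = int(df["end"].iloc[0] - df["start"].iloc[0])
    return CoverageMatrix(
        contig=str(contigs[0]),
        starts=df["start"].to_numpy(),
        counts=df[list(samples)].to_numpy().T,
        sample_ids=samples,
        span=span,
    )


def write_coverage(path, cov: CoverageMatrix) -> None:
    df = pd.DataFrame({"contig": cov.contig, "start": cov.starts, "end": cov.starts + cov.span})
    for i, s in enumerate(cov.sample_ids):
        df[s] = cov.counts[i]
    df.to_csv(path, sep="\t", index=False)


def normalize_coverage(
    counts: np.ndarray,
    ploidy: int = 2,
    mask: np.ndarray | None = None,
    median: float | None = None,
    sample_id: str = "",
    bias: np.ndarray | None = None,
) -> np.ndarray:
    """Normalize window counts to copy-number units.

    ``normalized = ploidy * count / median`` where the median is taken
    over this sample's (unmasked) autosomal windows; pass ``median``
    explicitly when normalizing a non-autosomal contig. ``bias`` is an
    optional per-window multiplicative bias track (e.g. from
    :func:`estimate_window_bias`) divided out before scaling.
    """
    counts = np.asarray(counts, dtype=np.float64)
    if bias is not None:
        counts = counts / np.maximum(np.asarray(bias, dtype=np.float64), 1e-6)
    if median is None:
        sel = counts if mask is None else counts[~np.asarray(mask, dtype=bool)]
        median = float(np.median(sel))
    if not median > 0:
        raise ValueError(f"zero median window count for sample {sample_id!r}")
    return ploidy * counts / median


def estimate_window_bias(
    cov: CoverageMatrix, quantile: float = 0.25, clamp: float = 1.5
) -> np.ndarray:
    """Per-window multiplicative bias shared across samples.

    A low across-sample quantile of median-scaled counts per window:
    amplification carriers only raise the upper tail, so the track stays
    unbiased as long as fewer than ``1 - quantile`` of samples are
    amplified at a window. Any constant factor cancels in the per-sample
    median scaling applied afterwards. The track is clamped to
    ``[1/clamp, clamp]``: genuine mappability/GC bias is bounded in
    practice, while a CNV fixed in the cohort would otherwise be
    absorbed into the track (an amplification at fixation shows up as an
    apparent ~2x "bias" and is clipped instead, preserving the call).
    """
    c = cov.counts.astype(np.float64)
    med = np.median(c, axis=1, keepdims=True)
    if not (med > 0).all():
        raise ValueError("zero median window count in bias estimation")
    b = np.quantile(c / med, quantile, axis=0)
    b = b / np.median(b)
    return np.clip(b, 1.0 / clamp, clamp)


def coverage_variance(normalized: np.ndarray, ploidy: int = 2) -> float:
    """Variance of normalized coverage on the diploid-equivalent scale."""
    x = np.asarray(normalized, dtype=np.float64) / ploidy
    if x.size < 100:
        raise ValueError("coverage variance needs at least 100 windows")
    return float(np.var(x))


def coverage_variance_filter(
    normalized: np.ndarray, ploidy: int = 2, threshold: float = VARIANCE_THRESHOLD
) -> tuple[bool, float]:
    """Per-sample reliability gate: fail iff variance strictly exceeds threshold."""
    v = coverage_variance(normalized, ploidy)
    return v <= threshold, v


def _emission_variances(
    normalized: np.ndarray, ploidy: int, k_max: int
) -> np.ndarray:
    """Per-state emission variances sigma0^2 + k * sigma1^2, moment-fit.

    The baseline variance v is estimated robustly from all windows via
    the scaled median absolute deviation (1.4826 * MAD), which ignores
    the minority of CNV windows without the truncation bias a hard
    baseline-window cut would introduce. v is split so the
    state-``ploidy`` variance equals v and variance grows linearly with
    state: sigma0^2 = v/2, sigma1^2 = v / (2 * ploidy).
    """
    center = float(np.median(normalized))
    mad = float(np.median(np.abs(normalized - center)))
    v = max((1.4826 * mad) ** 2, _VAR_FLOOR)
    sigma0_sq = v / 2.0
    sigma1_sq = v / (2.0 * ploidy)
    return sigma0_sq + sigma1_sq * np.arange(k_max + 1)


def decode_copy_number(
    normalized: np.ndarray,
    ploidy: int = 2,
    k_max: int = DEFAULT_K_MAX,
    stay: float = DEFAULT_STAY,
) -> CopyNumberPath:
    """Viterbi decoding of integer copy number from normalized coverage.

    States ``k = 0..k_max`` emit Normal(mean=k, var=sigma0^2 + k*sigma1^2);
    the transition matrix has self-probability ``stay`` with the
    remainder uniform over the other states. The initial distribution
    puts ``stay`` on the baseline (ploidy) state. Also returns the
    log-likelihood of the forced all-baseline path for likelihood-ratio
    filtering.
    """
    x = np.asarray(normalized, dtype=np.float64)
    if not np.isfinite(x).all():
        raise ValueError("normalized coverage contains non-finite values")
    W = x.size
    K = k_max + 1
    x_eval = np.clip(x, None, k_max)  # values above the top state are clamped
    var = _emission_variances(x, ploidy, k_max)
    means = np.arange(K, dtype=np.float64)
    # emission log-density, states x windows
    emit = (
        -0.5 * np.log(2 * np.pi * var)[:, None]
        - 0.5 * (x_eval[None, :] - means[:, None]) ** 2 / var[:, None]
    )
    log_stay = np.log(stay)
    log_off = np.log((1.0 - stay) / (K - 1))
    logT = np.full((K, K), log_off)
    np.fill_diagonal(logT, log_stay)
    log_init = np.full(K, log_off)
    log_init[ploidy] = log_stay

    delta = log_init + emit[:, 0]
    back = np.zeros((W, K), dtype=np.int32)
    for w in range(1, W):
        cand = delta[:, None] + logT  # (from, to)
        back[w] = np.argmax(cand, axis=0)
        delta = cand[back[w], np.arange(K)] + emit[:, w]
    states = np.zeros(W, dtype=np.int64)
    states[-1] = int(np.argmax(delta))
    for w in range(W - 1, 0, -1):
        states[w - 1] = back[w, states[w]]
    loglik = float(np.max(delta))
    null = float(log_init[ploidy] + (W - 1) * log_stay + emit[ploidy].sum())
    return CopyNumberPath(states, loglik, null, emit, ploidy)


def call_cnvs(
    path: CopyNumberPath,
    contig: str,
    window_starts: np.ndarray,
    sample_id: str,
    span: int = WINDOW_SPAN,
    min_windows: int = DEFAULT_MIN_WINDOWS,
    min_likelihood_ratio: float = DEFAULT_MIN_LR,
) -> list[CNVCall]:
    """Amplification calls from a decoded path.

    Maximal runs of windows with copy number above ploidy, length at
    least ``min_windows``; each run is scored by the likelihood ratio of
    the decoded states against the forced-baseline state over the run's
    windows (transitions inside a run cancel), and retained when the
    ratio exceeds ``min_likelihood_ratio``.
    """
    s = path.states
    above = s > path.ploidy
    calls: list[CNVCall] = []
    w = 0
    min_log_lr = float(np.log(min_likelihood_ratio))
    while w < s.size:
        if not above[w]:
            w += 1
            continue
        lo = w
        while w < s.size and above[w]:
            w += 1
        hi = w  # run is [lo, hi)
        if hi - lo < min_windows:
            continue
        idx = np.arange(lo, hi)
        log_lr = float(
            (path.emission_loglik[s[idx], idx] - path.emission_loglik[path.ploidy, idx]).sum()
        )
        if log_lr <= min_log_lr:
            continue
        vals, cnts = np.unique(s[idx], return_counts=True)
        calls.append(
            CNVCall(
                sample_id=sample_id,
                contig=contig,
                start=int(window_starts[lo]),
                end=int(window_starts[hi - 1]) + span,
                copy_number=int(vals[np.argmax(cnts)]),
                n_windows=int(hi - lo),
                log_likelihood_ratio=log_lr,
            )
        )
    return calls


def call_sample_cnvs(
    cov: CoverageMatrix,
    sample_id: str,
    ploidy: int = 2,
    mask: np.ndarray | None = None,
    k_max: int = DEFAULT_K_MAX,
    stay: float = DEFAULT_STAY,
    min_windows: int = DEFAULT_MIN_WINDOWS,
    min_likelihood_ratio: float = DEFAULT_MIN_LR,
    variance_threshold: float = VARIANCE_THRESHOLD,
    bias: np.ndarray | None = None,
) -> tuple[list[CNVCall], bool, float]:
    """Normalize, QC and call one sample on one contig.

    Returns ``(calls, passed_variance_filter, variance)``; calls are
    empty when the sample fails the coverage-variance filter. Pass
    ``bias`` (see :func:`estimate_window_bias`) to remove shared
    per-window structure before decoding.
    """
    norm = normalize_coverage(
        cov.row(sample_id), ploidy=ploidy, mask=mask, sample_id=sample_id, bias=bias
    )
    ok, var = coverage_variance_filter(norm, ploidy, variance_threshold)
    if not ok:
        log.info("sample %s: coverage variance %.3f > %.2f, removed", sample_id, var, variance_threshold)
        return [], False, var
    path = decode_copy_number(norm, ploidy, k_max, stay)
    calls = call_cnvs(
        path, cov.contig, cov.starts, sample_id, cov.span, min_windows, min_likelihood_ratio
    )
    return calls, True, var


@dataclass
class GeneCnvFrequency:
    gene_id: str
    cohort: str
    carriers: int
    cohort_size: int
    frequency: float
    reported: bool


def gene_cnv_frequency(
    calls: list[CNVCall],
    gene_models: list[GeneModel],
    cohort_sample_ids: tuple[str, ...],
    cohort_name: str = "",
    min_report: float = 0.05,
) -> list[GeneCnvFrequency]:
    """Per-gene amplification carrier frequency in a cohort.

    A sample is a carrier of a gene's CNV when any retained call overlaps
    the gene footprint by at least one window. Rows at or below
    ``min_report`` are flagged unreported (kept in the full table).
    """
    if not cohort_sample_ids:
        raise ValueError(f"empty cohort {cohort_name!r}")
    members = set(cohort_sample_ids)
    rows = []
    for gene in gene_models:
        carriers = {
            c.sample_id
            for c in calls
            if c.sample_id in members
            and c.contig == gene.contig
            and c.start < gene.span[1]
            and gene.span[0] < c.end
        }
        freq = len(carriers) / len(cohort_sample_ids)
        rows.append(
            GeneCnvFrequency(
                gene_id=gene.gene_id,
                cohort=cohort_name,
                carriers=len(carriers),
                cohort_size=len(cohort_sample_ids),
                frequency=freq,
                reported=freq > min_report,
            )
        )
    return rows


def calls_to_frame(calls: list[CNVCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "sample": c.sample_id,
                "contig": c.contig,
                "start": c.start,
                "end": c.end,
                "copy_number": c.copy_number,
                "n_windows": c.n_windows,
                "log_likelihood_ratio": c.log_likelihood_ratio,
            }
            for c in calls
        ],
        columns=[
            "sample",
            "contig",
            "start",
            "end",
            "copy_number",
            "n_windows",
            "log_likelihood_ratio",
        ],
    )
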