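"""Garud H12 haplotype-homozygosity selection scan.

H12 pools the top two haplotype classes — ``(p1+p2)^2 + sum_{i>=3} p_i^2``
— making it sensitive to both hard sweeps (one high-frequency haplotype)
and soft sweeps (two). Windows are counted in SNPs, non-overlapping; the
per-cohort window size is calibrated so the genome-wide background stays
low (95th percentile of H12 below 0.1). Scans default to chromosomes 2
and 3; phenotype contrasts subtract the dead cohort's profile from the
alive cohort's on identical windows.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from anosurv.io import GeneModel, HaplotypeMatrix

log = logging.getLogger(__name__)

DEFAULT_GRID = tuple(range(100, 2001, 100))
SCAN_CONTIG_PREFIXES = ("2", "3")  # X excluded from scans by default


@dataclass
class H12Profile:
    cohort: str
    contig: str
    window_start: np.ndarray  # first SNP bp position per window (0-based)
    window_end: np.ndarray  # last SNP bp position per window, inclusive
    n_snps: np.ndarray
    values: np.ndarray  # H12 per window, in [0,1]
    window_size: int  # w, in SNPs
    snp_positions: np.ndarray = field(default_factory=lambda: np.array([], dtype=np.int64))

    @property
    def midpoints(self) -> np.ndarray:
        return (self.window_start + self.window_end) / 2.0

    def window_containing(self, position: int) -> int | None:
        """Index of the window whose bp span contains ``position``."""
        hit = np.flatnonzero(
            (self.window_start <= position) & (position <= self.window_end)
        )
        return int(hit[0]) if hit.size else None


@dataclass
class CalibrationResult:
    grid: tuple[int, ...]
    percentile95: dict[int, float]
    chosen: int
    qualified: bool  # False when no grid size kept the background below cutoff


@dataclass
class SelectionPeak:
    contig: str
    start: int
    end: int
    max_value: float
    gene_ids: tuple[str, ...]


def h12(window: np.ndarray) -> float:
    """H12 for one SNP window (rows = haplotypes).

    Ranks distinct haplotype frequencies ``p1 >= p2 >= ...`` and returns
    ``(p1 + p2)^2 + sum_{i>=3} p_i^2``.
    """
    w = np.asarray(window)
    if w.ndim != 2 or w.shape[0] < 2 or w.shape[1] < 1:
        raise ValueError("window must be 2-D with >=2 haplotypes and >=1 SNP")
    _, counts = np.unique(w, axis=0, return_counts=True)
    p = np.sort(counts / w.shape[0])[::-1]
    if p.size == 1:
        return 1.0
    return float((p[0] + p[1]) ** 2 + np.sum(p[2:] ** 2))


def h12_scan(
    hap: HaplotypeMatrix,
    window_size: int,
    cohort: str = "",
    min_terminal_frac: float = 0.5,
    step: int | None = None,
) -> H12Profile:
    """H12 over consecutive blocks of ``window_size`` SNPs.

    Windows are non-overlapping by default; pass ``step`` smaller than
    ``window_size`` for an overlapping scan. A ragged terminal block
    shorter than ``window_size * min_terminal_frac`` is dropped;
    otherwise it is kept (and its SNP count reported).
    """
    S = hap.n_sites
    if S < window_size:
        raise ValueError(f"{S} SNPs < window size {window_size}")
    if step is None:
        step = window_size
    if step < 1:
        raise ValueError("step must be >= 1")
    starts, ends, nsnps, vals = [], [], [], []
    for lo in range(0, S, step):
        hi = min(lo + window_size, S)
        if hi - lo < window_size and (hi - lo) < window_size * min_terminal_frac:
            break
        vals.append(h12(hap.matrix[:, lo:hi]))
        starts.append(int(hap.positions[lo]))
        ends.append(int(hap.positions[hi - 1]))
        nsnps.append(hi - lo)
    return H12Profile(
        cohort=cohort,
        contig=hap.contig,
        window_start=np.array(starts, dtype=np.int64),
        window_end=np.array(ends, dtype=np.int64),
        n_snps=np.array(nsnps, dtype=np.int64),
        values=np.array(vals, dtype=np.float64),
        window_size=window_size,
        snp_positions=hap.positions.copy(),
    )


def nearest_rank_percentile(values: np.ndarray, q: float) -> float:
    """Nearest-rank percentile: the ceil(q*n)-th smallest value."""
    v = np.sort(np.asarray(values, dtype=np.float64))
    if v.size == 0:
        raise ValueError("empty sample")
    k = int(np.ceil(q * v.size))
    return float(v[max(k, 1) - 1])


def calibrate_window_size(
    hap: HaplotypeMatrix,
    grid: tuple[int, ...] = DEFAULT_GRID,
    cutoff: float = 0.1,
    cohort: str = "",
) -> CalibrationResult:
    """Choose the scan window size for a cohort.

    For each candidate ``w`` in the grid (restricted to sizes the data
    can form at least one window for), the genome-wide H12 distribution
    is computed; the chosen size is the *largest* whose 95th percentile
    falls below ``cutoff``. When none qualifies the smallest candidate is
    returned with ``qualified=False``.
    """
    if not grid:
        raise ValueError("empty window-size grid")
    usable = tuple(w for w in sorted(grid) if w <= hap.n_sites)
    if not usable:
        raise ValueError(
            f"no grid window size fits {hap.n_sites} SNPs (smallest is {min(grid)})"
        )
    pct: dict[int, float] = {}
    for w in usable:
        prof = h12_scan(hap, w, cohort=cohort)
        pct[w] = nearest_rank_percentile(prof.values, 0.95)
    qualifying = [w for w in usable if pct[w] < cutoff]
    if qualifying:
        return CalibrationResult(usable, pct, max(qualifying), True)
    log.warning(
        "cohort %s: no window size keeps H12 95th percentile below %.2f", cohort, cutoff
    )
    return CalibrationResult(usable, pct, min(usable), False)


def delta_h12(profile_alive: H12Profile, profile_dead: H12Profile) -> H12Profile:
    """Per-window H12(alive) - H12(dead) on identical window definitions."""
    same = (
        profile_alive.contig == profile_dead.contig
        and profile_alive.window_size == profile_dead.window_size
        and profile_alive.values.size == profile_dead.values.size
        and np.array_equal(profile_alive.window_start, profile_dead.window_start)
        and np.array_equal(profile_alive.window_end, profile_dead.window_end)
    )
    if not same:
        raise ValueError("profiles have mismatched window definitions")
    return H12Profile(
        cohort=f"{profile_alive.cohort}-minus-{profile_dead.cohort}",
        contig=profile_alive.contig,
        window_start=profile_alive.window_start.copy(),
        window_end=profile_alive.window_end.copy(),
        n_snps=profile_alive.n_snps.copy(),
        values=profile_alive.values - profile_dead.values,
        window_size=profile_alive.window_size,
        snp_positions=profile_alive.snp_positions.copy(),
    )


def contrast_scan(
    hap_alive: HaplotypeMatrix,
    hap_dead: HaplotypeMatrix,
    window_size: int,
) -> H12Profile:
    """Build alive/dead profiles on the shared SNP set and subtract them.

    Both cohorts must carry the same site columns (the usual case when
    they are subsets of one call set); windows then align by construction.
    """
    if not np.array_equal(hap_alive.positions, hap_dead.positions):
        raise ValueError("cohorts must be on the same SNP set for a contrast")
    pa = h12_scan(hap_alive, window_size, cohort="alive")
    pd_ = h12_scan(hap_dead, window_size, cohort="dead")
    return delta_h12(pa, pd_)


def find_peaks(
    profile: H12Profile,
    threshold: float | None = None,
    gene_models: list[GeneModel] | None = None,
    merge_gap: int = 1,
) -> list[SelectionPeak]:
    """Maximal runs of windows above a threshold, merged across short gaps.

    The default threshold is the profile's own 99th percentile
    (nearest-rank) — a reporting convention, so a flat profile yields no
    peaks only when nothing strictly exceeds it.
    """
    if profile.values.size == 0:
        raise ValueError("empty profile")
    if threshold is None:
        threshold = nearest_rank_percentile(profile.values, 0.99)
    above = profile.values > threshold
    idx = np.flatnonzero(above)
    if idx.size == 0:
        return []
    runs: list[list[int]] = [[int(idx[0]), int(idx[0])]]
    for i in idx[1:]:
        if i - runs[-1][1] <= merge_gap + 1:
            runs[-1][1] = int(i)
        else:
            runs.append([int(i), int(i)])
    peaks = []
    for lo, hi in runs:
        start = int(profile.window_start[lo])
        end = int(profile.window_end[hi])
        genes: tuple[str, ...] = ()
        if gene_models:
            genes = tuple(
                g.gene_id
                for g in gene_models
                if g.contig == profile.contig
                and g.span[0] <= end
                and start < g.span[1]
            )
        peaks.append(
            SelectionPeak(
                contig=profile.contig,
                start=start,
                end=end,
                max_value=float(profile.values[lo : hi + 1].max()),
                gene_ids=genes,
            )
        )
    return peaks
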