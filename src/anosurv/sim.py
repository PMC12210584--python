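"""Synthetic cohort generator.

Simulates the statistical structure the analysis assumes so every stage
of the pipeline can be exercised without real sequencing data:

* a forward-in-time diploid Wright-Fisher simulator with an infinite-
  sites mutation model, crossover recombination, symmetric two-deme
  migration and an optional selective sweep with dominance,
* a Balding-Nichols structured-genotype generator (beta-distributed deme
  allele frequencies parameterized by FST),
* negative-binomial window read-depth counts with shared per-window bias
  and embedded copy-number amplifications,
* a logistic bioassay-outcome model in which survival depends on
  resistance genotype,
* a fixture writer emitting VCF / metadata TSV / coverage TSV / GFF3 /
  FASTA plus a truth JSON for recovery tests.

Default parameters are desk-scale study conditions: two demes with
migration tuned to low differentiation (FST of order 0.001-0.01),
cohorts of 10-60 individuals, ~30x depth, amplifications of 1-10 extra
copies spanning 5-100 windows.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from anosurv import io as aio
from anosurv.cnv import WINDOW_SPAN, CoverageMatrix
from anosurv.io import GeneModel, HaplotypeMatrix, SampleRecord

log = logging.getLogger(__name__)

_BASES = np.array(list("ACGT"))


@dataclass
class DemeSpec:
    name: str
    size: int  # diploid population size N
    n_sample: int  # diploids sampled at the end

    def __post_init__(self) -> None:
        if self.n_sample > self.size:
            raise ValueError(f"deme {self.name}: cannot sample {self.n_sample} of {self.size}")


@dataclass
class SweepSpec:
    """A beneficial allele injected after burn-in.

    Genotype fitnesses are 1, 1+hs, 1+s. With ``condition_on_establishment``
    the injection is retried (from the saved post-burn-in state) when the
    allele is lost, up to ``retries`` times. ``stop_freq`` ends the sweep
    phase early once the pooled allele frequency reaches it, so cohorts
    can be sampled mid-sweep (a fixed allele cannot associate with a
    bioassay outcome).
    """

    position: int
    s: float
    h: float = 0.5
    start_freq: float = 0.02
    stop_freq: float | None = None
    max_generations: int = 1000
    condition_on_establishment: bool = True
    retries: int = 100
    n_origins: int | None = None  # None: each injected copy keeps its own
    # background (start_freq distinct origins). 1: hard sweep — injected
    # copies carry a single founder's haplotype around the locus
    # (established single origin; the early stochastic phase is not
    # simulated).
    origin_age: float | None = None  # generations since the single origin;
    # each carrier retains the founder segment over an interval around the
    # locus with Exp(1 / (r * origin_age)) bp extents on each side,
    # emulating recombination during the unsimulated establishment phase.
    # None copies the founder's whole haplotype.

    def __post_init__(self) -> None:
        if self.s <= -1:
            raise ValueError("selection coefficient must exceed -1")
        if not 0 < self.start_freq < 1:
            raise ValueError("start frequency must be in (0,1)")
        if self.n_origins is not None and self.n_origins < 1:
            raise ValueError("n_origins must be >= 1")


@dataclass
class CnvSpec:
    carrier_fraction: float
    copy_number: int
    start_window: int
    n_windows: int

    def __post_init__(self) -> None:
        if not 0 <= self.carrier_fraction <= 1:
            raise ValueError("carrier fraction must be in [0,1]")
        if self.copy_number < 0 or int(self.copy_number) != self.copy_number:
            raise ValueError("copy number must be a non-negative integer")


@dataclass
class CoverageSpec:
    mean_depth: float = 30.0  # mean window count at baseline copy number
    dispersion: float = 100.0  # negative-binomial size parameter k
    window_bias_sd: float = 0.1  # lognormal sd of shared per-window bias

    def __post_init__(self) -> None:
        if self.mean_depth <= 0:
            raise ValueError("mean depth must be positive")


@dataclass
class PhenotypeSpec:
    """Logistic bioassay-survival model: P(alive) = expit(b0 + sum b*dosage)."""

    baseline: float = 0.0  # log-odds of survival with no resistance alleles
    effects: dict[str, float] = field(default_factory=dict)  # locus -> per-allele log-odds


@dataclass
class SimConfig:
    seed: int
    demes: list[DemeSpec]
    length: int = 50_000  # sequence length, bp
    mu: float = 1.25e-5  # mutation rate per bp per generation
    rec: float = 1.0e-5  # recombination rate per bp per generation
    migration: float = 0.25  # per-individual swap probability per generation
    generations: int = 800  # neutral burn-in (~8N at default deme size)
    sweep: SweepSpec | None = None
    cnvs: list[CnvSpec] = field(default_factory=list)
    coverage: CoverageSpec = field(default_factory=CoverageSpec)
    phenotype: PhenotypeSpec = field(default_factory=PhenotypeSpec)
    init: str = "monomorphic"  # or "coalescent": neutral standing variation
    max_cost: float = 2e10  # desk-scale guard on total N * L * T

    def __post_init__(self) -> None:
        for name in ("mu", "rec", "migration"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.init not in ("monomorphic", "coalescent"):
            raise ValueError("init must be 'monomorphic' or 'coalescent'")
        cost = sum(d.size for d in self.demes) * self.length * self.generations
        if cost > self.max_cost:
            raise ValueError(
                f"simulation cost N*L*T = {cost:.2g} exceeds desk-scale guard "
                f"{self.max_cost:.2g}"
            )


def default_config(seed: int) -> SimConfig:
    """Two-deme study conditions with low differentiation (FST ~ 0.005)."""
    return SimConfig(
        seed=seed,
        demes=[DemeSpec("northwest", 100, 30), DemeSpec("central", 100, 30)],
    )


def neutral_config(seed: int) -> SimConfig:
    """Single neutral deme at mutation-drift equilibrium (burn-in 20N).

    Sized for replicate runs: N=50 diploids, 20 sampled, 20 kb at
    4N*mu = 0.005 per bp, used by the equilibrium checks (Tajima's D
    near 0, Watterson theta recovering 4N*mu). A 10N burn-in from the
    monomorphic start still carries a slight excess of rare variants
    (negative D); 20N removes it.
    """
    return SimConfig(
        seed=seed,
        demes=[DemeSpec("pop", 50, 20)],
        length=20_000,
        mu=2.5e-5,
        rec=1.0e-5,
        migration=0.0,
        generations=1000,
    )


#: Calibration grid used for the desk-scale sweep scenario (the
#: full-genome default grid of 100..2000 SNPs assumes real chromosomes).
SWEEP_SCAN_GRID = (100, 150)


def sweep_config(seed: int, s: float = 0.1, stop_freq: float = 0.75) -> SimConfig:
    """Single deme carrying a partial single-origin protective sweep.

    Neutral standing variation comes from a coalescent initialization at
    N=1000 (a forward burn-in at this size is not desk-scale); the
    selective phase runs forward from an established hard sweep at 40%
    until the allele reaches ``stop_freq``. 120 diploids are sampled
    mid-sweep so a bioassay split yields roughly balanced alive/dead
    arms of ~60 under the default logistic model (baseline -3.0, +2
    log-odds per sweep allele) — the end-to-end selection-scan and
    association scenario. The 300 kb genome keeps the sweep's
    haplotype-homozygosity footprint (~15 kb) a small fraction of scan
    windows, as on a real chromosome.
    """
    return SimConfig(
        seed=seed,
        demes=[DemeSpec("pop", 1000, 120)],
        length=300_000,
        mu=1.5e-6,
        rec=4.0e-6,
        migration=0.0,
        generations=0,
        init="coalescent",
        sweep=SweepSpec(
            position=150_000, s=s, h=0.5, start_freq=0.4, n_origins=1,
            origin_age=30.0, stop_freq=stop_freq, max_generations=400,
        ),
        phenotype=PhenotypeSpec(baseline=-3.0, effects={"sweep": 2.0}),
    )


# ---------------------------------------------------------------------------
# Wright-Fisher forward simulation


class _Pop:
    """Haplotypes are immutable sorted int64 arrays of derived-site positions."""

    def __init__(self, demes: list[DemeSpec]):
        self.haps: list[list[np.ndarray]] = [
            [np.array([], dtype=np.int64) for _ in range(2 * d.size)] for d in demes
        ]

    def copy(self) -> "_Pop":
        new = _Pop.__new__(_Pop)
        new.haps = [list(h) for h in self.haps]  # arrays shared (never mutated)
        return new


def _carries(hap: np.ndarray, pos: int) -> bool:
    i = np.searchsorted(hap, pos)
    return bool(i < hap.size and hap[i] == pos)


def _gamete(
    h0: np.ndarray,
    h1: np.ndarray,
    n_cross: int,
    n_mut: int,
    rng: np.random.Generator,
    length: int,
    used: set,
) -> np.ndarray:
    if n_cross == 0:
        gam = h0 if rng.integers(2) == 0 else h1
    else:
        breaks = np.sort(rng.integers(1, length, size=n_cross))
        first = int(rng.integers(2))
        parents = (h0, h1) if first == 0 else (h1, h0)
        edges = np.concatenate(([0], breaks, [length]))
        parts = []
        for seg in range(len(edges) - 1):
            src = parents[seg % 2]
            lo = np.searchsorted(src, edges[seg])
            hi = np.searchsorted(src, edges[seg + 1])
            if hi > lo:
                parts.append(src[lo:hi])
        gam = np.concatenate(parts) if parts else np.array([], dtype=np.int64)
    if n_mut:
        new = []
        while len(new) < n_mut:
            p = int(rng.integers(length))
            if p not in used:
                used.add(p)
                new.append(p)
        gam = np.sort(np.concatenate([gam, np.array(new, dtype=np.int64)]))
    return gam


def _rebuild_used(pop: _Pop, reserved: set[int]) -> set[int]:
    """Recycle extinct mutation positions (infinite-sites with finite L).

    The collision set is rebuilt from positions still segregating so the
    position pool is never exhausted by long runs.
    """
    used: set[int] = set(reserved)
    for deme in pop.haps:
        for h in deme:
            used.update(h.tolist())
    return used


def _sweep_freq(pop: _Pop, pos: int) -> float:
    total = carriers = 0
    for deme in pop.haps:
        for h in deme:
            total += 1
            carriers += _carries(h, pos)
    return carriers / total if total else 0.0


def _generation(
    pop: _Pop,
    demes: list[DemeSpec],
    config: SimConfig,
    rng: np.random.Generator,
    used: set,
    sweep_active: bool,
) -> _Pop:
    rate_c = config.rec * config.length
    rate_m = config.mu * config.length
    sw = config.sweep
    new = _Pop.__new__(_Pop)
    new.haps = []
    for d_i, d in enumerate(demes):
        haps = pop.haps[d_i]
        N = d.size
        if sweep_active and sw is not None and sw.s != 0.0:
            g = np.fromiter(
                (
                    _carries(haps[2 * i], sw.position) + _carries(haps[2 * i + 1], sw.position)
                    for i in range(N)
                ),
                dtype=np.int64,
                count=N,
            )
            w = np.choose(g, [1.0, 1.0 + sw.h * sw.s, 1.0 + sw.s])
            p = w / w.sum()
        else:
            p = None
        parents = rng.choice(N, size=(N, 2), p=p)
        n_cross = rng.poisson(rate_c, size=2 * N)
        n_mut = rng.poisson(rate_m, size=2 * N)
        kids = []
        for i in range(N):
            for j in (0, 1):
                par = parents[i, j]
                kids.append(
                    _gamete(
                        haps[2 * par],
                        haps[2 * par + 1],
                        int(n_cross[2 * i + j]),
                        int(n_mut[2 * i + j]),
                        rng,
                        config.length,
                        used,
                    )
                )
        new.haps.append(kids)
    # symmetric migrant swaps keep deme sizes constant
    if config.migration > 0 and len(demes) > 1:
        for a in range(len(demes)):
            for b in range(a + 1, len(demes)):
                n_pairs = min(demes[a].size, demes[b].size)
                nmig = rng.binomial(n_pairs, config.migration)
                if nmig == 0:
                    continue
                ia = rng.choice(demes[a].size, size=nmig, replace=False)
                ib = rng.choice(demes[b].size, size=nmig, replace=False)
                for x, y in zip(ia, ib):
                    for k in (0, 1):
                        new.haps[a][2 * x + k], new.haps[b][2 * y + k] = (
                            new.haps[b][2 * y + k],
                            new.haps[a][2 * x + k],
                        )
    return new


def _coalescent_init(config: SimConfig, rng: np.random.Generator) -> _Pop:
    """Neutral standing variation for the whole population from a coalescent.

    Replaces the long neutral forward burn-in when only the selective
    phase needs forward dynamics. Continuous-genome (infinite-sites)
    mutations are floored to integer positions; rare collisions drop the
    later site.
    """
    import msprime

    demography = msprime.Demography()
    for d in config.demes:
        demography.add_population(name=d.name, initial_size=d.size)
    if len(config.demes) > 1 and config.migration > 0:
        demography.set_symmetric_migration_rate(
            [d.name for d in config.demes], config.migration
        )
    ts = msprime.sim_ancestry(
        samples={d.name: d.size for d in config.demes},
        demography=demography,
        sequence_length=config.length,
        recombination_rate=config.rec,
        random_seed=int(rng.integers(1, 2**31 - 1)),
    )
    ts = msprime.sim_mutations(
        ts,
        rate=config.mu,
        random_seed=int(rng.integers(1, 2**31 - 1)),
        discrete_genome=False,
    )
    n_haps = ts.num_samples
    carried: list[list[int]] = [[] for _ in range(n_haps)]
    seen: set[int] = set()
    for var in ts.variants():
        p = int(var.site.position)
        if p in seen:
            continue
        seen.add(p)
        for hi in np.flatnonzero(var.genotypes != 0):
            carried[hi].append(p)
    pop = _Pop.__new__(_Pop)
    pop.haps = []
    offset = 0
    for d in config.demes:
        rows = [
            np.array(sorted(carried[offset + j]), dtype=np.int64)
            for j in range(2 * d.size)
        ]
        pop.haps.append(rows)
        offset += 2 * d.size
    return pop


def _splice_segment(
    recipient: np.ndarray, donor: np.ndarray, lo: int, hi: int
) -> np.ndarray:
    """Recipient haplotype with [lo, hi) replaced by the donor's variants."""
    r_lo, r_hi = np.searchsorted(recipient, (lo, hi))
    d_lo, d_hi = np.searchsorted(donor, (lo, hi))
    return np.concatenate([recipient[:r_lo], donor[d_lo:d_hi], recipient[r_hi:]])


def _inject_sweep(
    pop: _Pop, demes: list[DemeSpec], sw: SweepSpec, rng: np.random.Generator,
    rec_rate: float, length: int,
) -> _Pop:
    total = 2 * sum(d.size for d in demes)
    n_init = max(1, round(sw.start_freq * total))
    flat = [(d_i, j) for d_i, d in enumerate(demes) for j in range(2 * d.size)]
    picks = rng.choice(len(flat), size=n_init, replace=False)
    new = pop.copy()
    founder: np.ndarray | None = None
    if sw.n_origins is not None and sw.n_origins == 1 and n_init > 1:
        # established single-origin sweep: recipients carry the founder's
        # haplotype around the locus (the early stochastic phase is not
        # simulated; its recombination erodes the shared segment)
        fd, fj = flat[int(picks[0])]
        founder = new.haps[fd][fj]
        i = np.searchsorted(founder, sw.position)
        if not (i < founder.size and founder[i] == sw.position):
            founder = np.insert(founder, i, sw.position)
    scale = (
        1.0 / (rec_rate * sw.origin_age)
        if (founder is not None and sw.origin_age and rec_rate > 0)
        else None
    )
    for k in picks:
        d_i, j = flat[k]
        if founder is not None:
            if scale is None:
                new.haps[d_i][j] = founder
            else:
                left = int(rng.exponential(scale))
                right = int(rng.exponential(scale))
                lo = max(0, sw.position - left)
                hi = min(length, sw.position + right + 1)
                new.haps[d_i][j] = _splice_segment(new.haps[d_i][j], founder, lo, hi)
            continue
        h = new.haps[d_i][j]
        i = np.searchsorted(h, sw.position)
        if i < h.size and h[i] == sw.position:
            continue
        new.haps[d_i][j] = np.insert(h, i, sw.position)
    return new


def simulate_wf(config: SimConfig):
    """Run the forward Wright-Fisher model and sample cohorts.

    Returns ``(haps_by_deme, truth)``: one :class:`HaplotypeMatrix` per
    deme on the union site set, and a truth dict with the sweep
    trajectory, final sweep frequency, per-sample sweep dosages and the
    reference sequence used for ref/alt assignment. Fully reproducible
    from ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    used: set[int] = set()
    if config.init == "coalescent":
        pop = _coalescent_init(config, rng)
        used = _rebuild_used(pop, set())
    else:
        pop = _Pop(config.demes)
    for g in range(config.generations):
        pop = _generation(pop, config.demes, config, rng, used, sweep_active=False)
        if g % 25 == 24:
            used = _rebuild_used(pop, set())

    trajectory: list[float] = []
    sw = config.sweep
    if sw is not None:
        if sw.position in used:
            used.discard(sw.position)  # reserve the sweep site
            for deme in pop.haps:
                for j, h in enumerate(deme):
                    i = np.searchsorted(h, sw.position)
                    if i < h.size and h[i] == sw.position:
                        deme[j] = np.delete(h, i)
        used.add(sw.position)
        base = pop.copy()
        attempt = 0
        while True:
            attempt += 1
            pop = _inject_sweep(base, config.demes, sw, rng, config.rec, config.length)
            trajectory = [_sweep_freq(pop, sw.position)]
            lost = False
            for g in range(sw.max_generations):
                pop = _generation(pop, config.demes, config, rng, used, sweep_active=True)
                if g % 25 == 24:
                    used = _rebuild_used(pop, {sw.position})
                f = _sweep_freq(pop, sw.position)
                trajectory.append(f)
                if f == 0.0:
                    lost = True
                    break
                if sw.stop_freq is not None and f >= sw.stop_freq:
                    break
            if not (lost and sw.condition_on_establishment):
                break
            if attempt > sw.retries:
                raise RuntimeError(
                    f"sweep lost in all {sw.retries} attempts (s={sw.s})"
                )

    haps_by_deme, sweep_dosage = _sample_matrices(pop, config, rng)
    truth = {
        "seed": config.seed,
        "sweep_position": None if sw is None else sw.position,
        "sweep_trajectory": trajectory,
        "sweep_final_freq": trajectory[-1] if trajectory else None,
        "sweep_dosage": {k: v.tolist() for k, v in sweep_dosage.items()},
        "n_segregating_total": int(len(used)),
    }
    return haps_by_deme, truth


def _sample_matrices(pop: _Pop, config: SimConfig, rng: np.random.Generator):
    """Sample diploids per deme and build matrices on the union site set."""
    sampled: dict[str, list[np.ndarray]] = {}
    for d_i, d in enumerate(config.demes):
        idx = rng.choice(d.size, size=d.n_sample, replace=False)
        rows = []
        for i in idx:
            rows.append(pop.haps[d_i][2 * i])
            rows.append(pop.haps[d_i][2 * i + 1])
        sampled[d.name] = rows

    all_pos = sorted(set().union(*[set(h.tolist()) for rows in sampled.values() for h in rows]) or set())
    pos = np.array(all_pos, dtype=np.int64)
    # deterministic ref/alt letters from a child RNG stream
    letter_rng = np.random.default_rng([config.seed, 0xA11E1E])
    ref_idx = letter_rng.integers(0, 4, size=pos.size)
    alt_off = letter_rng.integers(1, 4, size=pos.size)
    ref = _BASES[ref_idx]
    alt = _BASES[(ref_idx + alt_off) % 4]

    haps_by_deme: dict[str, HaplotypeMatrix] = {}
    sweep_dosage: dict[str, np.ndarray] = {}
    sw_pos = config.sweep.position if config.sweep else None
    for name, rows in sampled.items():
        M = np.zeros((len(rows), pos.size), dtype=np.int8)
        for r, h in enumerate(rows):
            M[r, np.searchsorted(pos, h)] = 1
        ids = tuple(f"{name}_{i:03d}" for i in range(len(rows) // 2))
        haps_by_deme[name] = HaplotypeMatrix("2R", pos, ref.copy(), alt.copy(), M, ids)
        if sw_pos is not None and sw_pos in all_pos:
            col = M[:, int(np.searchsorted(pos, sw_pos))]
            sweep_dosage[name] = (col[0::2] + col[1::2]).astype(np.int64)
        else:
            sweep_dosage[name] = np.zeros(len(rows) // 2, dtype=np.int64)
    return haps_by_deme, sweep_dosage


# ---------------------------------------------------------------------------
# Balding-Nichols structured genotypes


@dataclass
class BaldingNicholsSpec:
    """Beta-distributed deme allele frequencies parameterized by FST.

    Per site and deme the frequency is Beta(p(1-F)/F, (1-p)(1-F)/F) with
    ancestral frequency p; genotypes are Binomial(2, deme frequency).
    """

    n_sites: int
    fst: float  # differentiation F, identical across demes
    deme_sizes: dict[str, int]  # deme name -> diploid sample size
    ancestral_freq: float | np.ndarray = 0.5

    def __post_init__(self) -> None:
        if not 0 <= self.fst < 1:
            raise ValueError("F must be in [0,1)")
        p = np.asarray(self.ancestral_freq)
        if np.any(p <= 0) or np.any(p >= 1):
            raise ValueError("ancestral frequency must be in (0,1)")


def simulate_balding_nichols(spec: BaldingNicholsSpec, seed: int):
    """One GenotypeMatrix per deme (positions 1..n_sites spaced 10 bp)."""
    rng = np.random.default_rng(seed)
    p = np.broadcast_to(np.asarray(spec.ancestral_freq, dtype=np.float64), (spec.n_sites,))
    pos = np.arange(spec.n_sites, dtype=np.int64) * 10
    ref = np.full(spec.n_sites, "A", dtype="U1")
    alt = np.full(spec.n_sites, "T", dtype="U1")
    out: dict[str, aio.GenotypeMatrix] = {}
    for name, n in spec.deme_sizes.items():
        if spec.fst == 0.0:
            q = p
        else:
            a = p * (1 - spec.fst) / spec.fst
            b = (1 - p) * (1 - spec.fst) / spec.fst
            q = rng.beta(a, b)
        G = rng.binomial(2, q, size=(n, spec.n_sites)).astype(np.int8)
        ids = tuple(f"{name}_{i:03d}" for i in range(n))
        out[name] = aio.GenotypeMatrix("2R", pos, ref, alt, G, ids)
    return out


# ---------------------------------------------------------------------------
# Coverage


def simulate_coverage(
    sample_ids: tuple[str, ...],
    cnvs: list[CnvSpec],
    coverage: CoverageSpec,
    n_windows: int,
    seed: int,
    contig: str = "2R",
    ploidy: np.ndarray | None = None,
):
    """Negative-binomial window counts with embedded amplifications.

    Counts are NB with mean ``d * b_w * c / 2`` where ``b_w`` is a
    lognormal per-window bias shared across samples (mimicking
    mappability/GC structure) and ``c`` the individual's true copy
    number (baseline ``ploidy``: 2, or 1 for the male X). Returns the
    CoverageMatrix, the true per-sample copy-number array and the list
    of truth CNV segments.
    """
    if coverage.mean_depth <= 0:
        raise ValueError("zero depth")
    n = len(sample_ids)
    rng = np.random.default_rng(seed)
    base = np.full(n, 2, dtype=np.int64) if ploidy is None else np.asarray(ploidy)
    truth_cn = np.tile(base[:, None], (1, n_windows)).astype(np.int64)
    segments = []
    for spec in cnvs:
        lo, hi = spec.start_window, min(spec.start_window + spec.n_windows, n_windows)
        carriers = np.flatnonzero(rng.random(n) < spec.carrier_fraction)
        for c in carriers:
            truth_cn[c, lo:hi] = spec.copy_number
        segments.append(
            {
                "start_window": int(lo),
                "end_window": int(hi),
                "copy_number": int(spec.copy_number),
                "carriers": [sample_ids[c] for c in carriers],
            }
        )
    bias = rng.lognormal(mean=0.0, sigma=coverage.window_bias_sd, size=n_windows)
    mean = coverage.mean_depth * bias[None, :] * truth_cn / 2.0
    k = coverage.dispersion
    # NB(mean m, size k): p = k / (k + m); guard m == 0 (true copy 0)
    m_safe = np.maximum(mean, 1e-9)
    counts = rng.negative_binomial(k, k / (k + m_safe))
    counts[mean == 0] = 0
    cov = CoverageMatrix(
        contig=contig,
        starts=np.arange(n_windows, dtype=np.int64) * WINDOW_SPAN,
        counts=counts,
        sample_ids=tuple(sample_ids),
        span=WINDOW_SPAN,
    )
    return cov, truth_cn, segments


# ---------------------------------------------------------------------------
# Bioassay


def simulate_bioassay(
    dosages: dict[str, np.ndarray],
    phenotype: PhenotypeSpec,
    seed: int,
) -> np.ndarray:
    """Bernoulli alive/dead outcomes from the logistic survival model.

    ``dosages`` maps locus name to a per-sample dosage array (alt-allele
    count, or copy number minus ploidy for CNVs); loci named in
    ``phenotype.effects`` contribute ``beta * dosage`` to the log-odds.
    """
    rng = np.random.default_rng(seed)
    names = list(dosages)
    n = len(next(iter(dosages.values()))) if names else 0
    eta = np.full(n, phenotype.baseline, dtype=np.float64)
    for locus, beta in phenotype.effects.items():
        if locus not in dosages:
            raise ValueError(f"effect locus {locus!r} missing from dosages")
        eta += beta * np.asarray(dosages[locus], dtype=np.float64)
    p_alive = 1.0 / (1.0 + np.exp(-eta))
    return np.where(rng.random(n) < p_alive, "alive", "dead")


# ---------------------------------------------------------------------------
# Fixture writer


def make_reference(length: int, seed: int, contig: str = "2R") -> dict[str, str]:
    rng = np.random.default_rng([seed, 0xFA57A])
    return {contig: "".join(_BASES[rng.integers(0, 4, size=length)])}


def write_fixture(
    out_dir,
    hap: HaplotypeMatrix,
    samples: list[SampleRecord],
    cov: CoverageMatrix | None = None,
    genes: list[GeneModel] | None = None,
    reference: dict[str, str] | None = None,
    truth: dict | None = None,
) -> dict[str, Path]:
    """Write a simulated cohort as files readable by :mod:`anosurv.io`.

    Output bytes are deterministic for identical inputs (no timestamps).
    On failure, files created by the partial write are removed.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "vcf": out / "cohort.vcf",
        "metadata": out / "metadata.tsv",
        "coverage": out / "coverage.tsv",
        "gff3": out / "genes.gff3",
        "fasta": out / "reference.fa",
        "truth": out / "truth.json",
    }
    written: list[Path] = []
    try:
        aio.write_vcf(paths["vcf"], hap)
        written.append(paths["vcf"])
        aio.write_metadata(paths["metadata"], samples)
        written.append(paths["metadata"])
        if cov is not None:
            from anosurv.cnv import write_coverage

            write_coverage(paths["coverage"], cov)
            written.append(paths["coverage"])
        if genes:
            aio.write_gff3(paths["gff3"], genes)
            written.append(paths["gff3"])
        if reference:
            aio.write_fasta(paths["fasta"], reference)
            written.append(paths["fasta"])
        with open(paths["truth"], "w") as fh:
            json.dump(truth or {}, fh, indent=2, sort_keys=True)
            fh.write("\n")
        written.append(paths["truth"])
    except BaseException:
        for p in written:
            p.unlink(missing_ok=True)
        raise
    return {k: v for k, v in paths.items() if v in written}


def metadata_for(
    ids: tuple[str, ...],
    location: str,
    year: int = 2019,
    insecticide: str = "none",
    outcomes: np.ndarray | None = None,
    latitude: float = 3.717,
    longitude: float = 34.857,
    rng: np.random.Generator | None = None,
) -> list[SampleRecord]:
    """Convenience metadata rows for simulated samples (QC fields passing)."""
    recs = []
    for i, sid in enumerate(ids):
        outcome = "untested" if insecticide == "none" else str(outcomes[i])
        recs.append(
            SampleRecord(
                sample_id=sid,
                location=location,
                year=year,
                latitude=latitude,
                longitude=longitude,
                sex="F",
                insecticide=insecticide,
                outcome=outcome,
                median_coverage=30.0,
                missingness=0.01,
                contamination=0.001,
            )
        )
    return recs
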