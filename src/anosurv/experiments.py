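"""Replicate studies exercising the pipeline on synthetic cohorts.

These runners define the package's standard validation experiments:
parameter recovery for the structured-genotype and Wright-Fisher
generators, CNV-caller recovery and false-positive rates, and the
end-to-end protective-sweep scenario (calibrated H12 scan, alive/dead
Delta-H12 contrast, Fisher association, and the null rejection rate).

Localization convention: a scan "localizes" the sweep when its maximum
falls within one window of the window containing the sweep locus — the
sweep's homozygosity footprint spans several consecutive SNP windows and
window boundaries are arbitrary relative to the locus.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from anosurv import assoc, cnv, selection, sim
from anosurv.popgen import hudson_fst, nucleotide_diversity, tajimas_d, watterson_theta


@dataclass
class SweepStudyResult:
    n_reps: int
    h12_localization_rate: float
    delta_h12_localization_rate: float
    fisher_power: float  # fraction of reps with p < 0.05
    mean_final_freq: float


def sweep_replicate(seed: int) -> tuple[bool, bool, float, float]:
    """One end-to-end protective-sweep replicate.

    Returns (H12 localized, Delta-H12 localized, Fisher p, final sweep
    frequency). The bioassay splits the 120 sampled mosquitoes into
    alive/dead arms; both scan profiles use the per-cohort calibrated
    window size.
    """
    cfg = sim.sweep_config(seed)
    haps, truth = sim.simulate_wf(cfg)
    hap = haps["pop"]
    pos = cfg.sweep.position

    cal = selection.calibrate_window_size(hap, grid=sim.SWEEP_SCAN_GRID)
    prof = selection.h12_scan(hap, cal.chosen)
    k = prof.window_containing(pos)
    h12_hit = k is not None and abs(int(np.argmax(prof.values)) - k) <= 1

    dosage = np.array(truth["sweep_dosage"]["pop"])
    outcome = sim.simulate_bioassay({"sweep": dosage}, cfg.phenotype, seed=seed + 1)
    alive = outcome == "alive"
    ids_alive = [s for s, a in zip(hap.sample_ids, alive) if a]
    ids_dead = [s for s, a in zip(hap.sample_ids, alive) if not a]
    dprof = selection.contrast_scan(
        hap.take_samples(ids_alive), hap.take_samples(ids_dead), cal.chosen
    )
    kd = dprof.window_containing(pos)
    delta_hit = kd is not None and abs(int(np.argmax(dprof.values)) - kd) <= 1

    alt_alive = int(dosage[alive].sum())
    tot_alive = 2 * int(alive.sum())
    alt_dead = int(dosage[~alive].sum())
    tot_dead = 2 * int((~alive).sum())
    res = assoc.fisher_snp_association(
        alt_alive, tot_alive - alt_alive, alt_dead, tot_dead - alt_dead, locus="sweep"
    )
    return h12_hit, delta_hit, res.p_value, truth["sweep_final_freq"]


def run_sweep_study(n_reps: int, seed: int) -> SweepStudyResult:
    h = d = f = 0
    freqs = []
    for rep in range(n_reps):
        h12_hit, delta_hit, p, freq = sweep_replicate(seed + 2 * rep)
        h += h12_hit
        d += delta_hit
        f += p < 0.05
        freqs.append(freq)
    return SweepStudyResult(
        n_reps=n_reps,
        h12_localization_rate=h / n_reps,
        delta_h12_localization_rate=d / n_reps,
        fisher_power=f / n_reps,
        mean_final_freq=float(np.mean(freqs)),
    )


def null_fisher_rejection_rate(
    n_tests: int, seed: int, n_per_arm: int = 60, alpha: float = 0.05
) -> float:
    """Type-I error of the allele-count Fisher test under the null bioassay.

    Genotypes at a random-frequency locus; survival independent of
    genotype (all effects zero). Fisher exact is conservative, so the
    rate should sit below the nominal level.
    """
    rng = np.random.default_rng(seed)
    rejected = 0
    for t in range(n_tests):
        freq = rng.uniform(0.2, 0.8)
        dosage = rng.binomial(2, freq, size=2 * n_per_arm)
        outcome = sim.simulate_bioassay(
            {"locus": dosage}, sim.PhenotypeSpec(baseline=0.0), seed=int(rng.integers(2**31 - 1))
        )
        alive = outcome == "alive"
        if alive.sum() == 0 or (~alive).sum() == 0:
            continue
        aa = int(dosage[alive].sum())
        ta = 2 * int(alive.sum())
        ad = int(dosage[~alive].sum())
        td = 2 * int((~alive).sum())
        r = assoc.fisher_snp_association(aa, ta - aa, ad, td - ad)
        rejected += r.p_value < alpha
    return rejected / n_tests


@dataclass
class CnvStudyResult:
    truth_window_recovery: float  # truth CNV windows covered by retained calls
    window_accuracy: float  # decoded state == truth, all windows all samples
    carrier_recovery: float  # carriers with >= 1 overlapping retained call
    false_positive_sample_rate: float  # null samples with any call


def run_cnv_study(
    seed: int,
    n_reps: int = 5,
    n_samples: int = 20,
    n_windows: int = 300,
    null_reps: int = 10,
    null_windows: int = 500,
) -> CnvStudyResult:
    """Amplification recovery at depth 30 (copy 4, 10 windows, 30% carriers)
    plus the false-positive rate on CNV-free coverage."""
    accs, cov_hits, cov_tot, carr_hit, carr_tot = [], 0, 0, 0, 0
    for rep in range(n_reps):
        ids = tuple(f"s{i}" for i in range(n_samples))
        cov, truth_cn, segs = sim.simulate_coverage(
            ids, [sim.CnvSpec(0.3, 4, 100, 10)], sim.CoverageSpec(), n_windows,
            seed=seed + rep,
        )
        bias = cnv.estimate_window_bias(cov)
        carriers = set(segs[0]["carriers"])
        for i, sid in enumerate(ids):
            calls, ok, _ = cnv.call_sample_cnvs(cov, sid, bias=bias)
            norm = cnv.normalize_coverage(cov.row(sid), bias=bias)
            path = cnv.decode_copy_number(norm)
            accs.append((path.states == truth_cn[i]).mean())
            if sid in carriers:
                carr_tot += 1
                covered = np.zeros(n_windows, bool)
                for c in calls:
                    covered[c.start // cov.span : c.end // cov.span] = True
                amp = truth_cn[i] > 2
                cov_tot += int(amp.sum())
                cov_hits += int((covered & amp).sum())
                carr_hit += any(
                    (c.start // cov.span) < segs[0]["end_window"]
                    and segs[0]["start_window"] < (c.end // cov.span)
                    for c in calls
                )
    fp = tot = 0
    for rep in range(null_reps):
        ids = tuple(f"n{i}" for i in range(n_samples))
        cov, _, _ = sim.simulate_coverage(
            ids, [], sim.CoverageSpec(), null_windows, seed=seed + 10_000 + rep
        )
        bias = cnv.estimate_window_bias(cov)
        for sid in ids:
            calls, ok, _ = cnv.call_sample_cnvs(cov, sid, bias=bias)
            tot += 1
            fp += bool(calls)
    return CnvStudyResult(
        truth_window_recovery=cov_hits / cov_tot if cov_tot else float("nan"),
        window_accuracy=float(np.mean(accs)),
        carrier_recovery=carr_hit / carr_tot if carr_tot else float("nan"),
        false_positive_sample_rate=fp / tot,
    )


@dataclass
class NeutralStudyResult:
    n_reps: int
    mean_tajimas_d: float
    watterson_ratio: float  # mean theta_W / (4 N mu)
    pi_theta_ratio: float


def run_neutral_study(n_reps: int, seed: int) -> NeutralStudyResult:
    ds, thetas, pis = [], [], []
    expected = None
    for rep in range(n_reps):
        cfg = sim.neutral_config(seed + rep)
        expected = 4 * cfg.demes[0].size * cfg.mu
        haps, _ = sim.simulate_wf(cfg)
        m = haps["pop"].matrix
        counts = m.sum(axis=0)
        S = int(((counts > 0) & (counts < m.shape[0])).sum())
        d = tajimas_d(m)
        if d is not None:
            ds.append(d)
        thetas.append(watterson_theta(S, m.shape[0], cfg.length))
        pis.append(nucleotide_diversity(m, cfg.length))
    return NeutralStudyResult(
        n_reps=n_reps,
        mean_tajimas_d=float(np.mean(ds)),
        watterson_ratio=float(np.mean(thetas) / expected),
        pi_theta_ratio=float(np.mean(pis) / np.mean(thetas)),
    )


def run_bn_fst_study(
    seed: int, n_reps: int = 20, n_sites: int = 1000, n_per_deme: int = 50, fst: float = 0.1
) -> float:
    """Mean Hudson FST recovered from Balding-Nichols genotypes."""
    vals = []
    for rep in range(n_reps):
        spec = sim.BaldingNicholsSpec(
            n_sites=n_sites, fst=fst, deme_sizes={"a": n_per_deme, "b": n_per_deme}
        )
        demes = sim.simulate_balding_nichols(spec, seed + rep)
        aa, ta = demes["a"].allele_counts()
        ab, tb = demes["b"].allele_counts()
        vals.append(hudson_fst(aa, ta, ab, tb).fst)
    return float(np.mean(vals))
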