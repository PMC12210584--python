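import json

import numpy as np
import pytest

from anosurv import io as aio
from anosurv import sim
from anosurv.popgen import hudson_fst_haplotypes


def tiny_config(seed, **kw):
    defaults = dict(
        seed=seed,
        demes=[sim.DemeSpec("a", 30, 10), sim.DemeSpec("b", 30, 10)],
        length=5_000,
        mu=5e-5,
        rec=2e-5,
        migration=0.2,
        generations=150,
    )
    defaults.update(kw)
    return sim.SimConfig(**defaults)


# ---------------------------------------------------------------------------
# Wright-Fisher


def test_wf_seed_determinism():
    h1, t1 = sim.simulate_wf(tiny_config(42))
    h2, t2 = sim.simulate_wf(tiny_config(42))
    for name in h1:
        assert np.array_equal(h1[name].matrix, h2[name].matrix)
        assert np.array_equal(h1[name].positions, h2[name].positions)
    assert t1["n_segregating_total"] == t2["n_segregating_total"]


def test_wf_zero_mutation_monomorphic():
    h, _ = sim.simulate_wf(tiny_config(1, mu=0.0))
    assert h["a"].n_sites == 0


def test_wf_panmixia_fst_near_zero():
    """m = 0.5 mixes demes completely: FST ~ 0 averaged over replicates."""
    vals = []
    for rep in range(20):
        h, _ = sim.simulate_wf(tiny_config(100 + rep, migration=0.5, generations=120))
        r = hudson_fst_haplotypes(h["a"], h["b"])
        if r.fst is not None:
            vals.append(r.fst)
    assert abs(np.mean(vals)) <= 0.01


def test_wf_structured_demes_positive_fst():
    vals = []
    for rep in range(5):
        h, _ = sim.simulate_wf(tiny_config(200 + rep, migration=0.005))
        vals.append(hudson_fst_haplotypes(h["a"], h["b"]).fst)
    assert np.mean(vals) > 0.05


def test_wf_sweep_establishes_and_records_trajectory():
    cfg = tiny_config(
        7,
        migration=0.0,
        demes=[sim.DemeSpec("a", 40, 20)],
        generations=80,
        sweep=sim.SweepSpec(
            position=2500, s=0.3, start_freq=0.1, stop_freq=0.6, max_generations=300
        ),
    )
    h, truth = sim.simulate_wf(cfg)
    assert truth["sweep_final_freq"] >= 0.6
    traj = truth["sweep_trajectory"]
    assert 0 < traj[0] < 0.2
    dosage = np.array(truth["sweep_dosage"]["a"])
    assert dosage.shape == (20,)
    # sampled dosage frequency in the neighbourhood of the final frequency
    assert abs(dosage.mean() / 2 - truth["sweep_final_freq"]) < 0.25


def test_wf_sweep_single_origin_shares_background():
    cfg = tiny_config(
        9,
        migration=0.0,
        demes=[sim.DemeSpec("a", 50, 25)],
        generations=200,
        sweep=sim.SweepSpec(
            position=2500, s=0.5, start_freq=0.2, n_origins=1,
            stop_freq=0.8, max_generations=100,
        ),
    )
    h, truth = sim.simulate_wf(cfg)
    hap = h["a"]
    j = np.searchsorted(hap.positions, 2500)
    assert hap.positions[j] == 2500
    carriers = hap.matrix[hap.matrix[:, j] == 1]
    # carrier haplotypes cluster around one core (pairwise similarity high)
    core = carriers.mean(axis=0)
    assert ((core < 0.15) | (core > 0.85)).mean() > 0.7


def test_wf_desk_scale_guard():
    with pytest.raises(ValueError, match="desk-scale"):
        sim.SimConfig(
            seed=0,
            demes=[sim.DemeSpec("a", 500, 10)],
            length=1_000_000,
            generations=100_000,
        )


def test_wf_sweep_lost_raises_after_retries():
    cfg = tiny_config(
        3,
        migration=0.0,
        demes=[sim.DemeSpec("a", 30, 10)],
        generations=10,
        sweep=sim.SweepSpec(
            position=100, s=-0.9, start_freq=0.05, stop_freq=0.99,
            max_generations=200, retries=2,
        ),
    )
    with pytest.raises(RuntimeError, match="sweep lost"):
        sim.simulate_wf(cfg)


# ---------------------------------------------------------------------------
# Balding-Nichols


def test_bn_determinism_and_shapes():
    spec = sim.BaldingNicholsSpec(n_sites=100, fst=0.1, deme_sizes={"a": 10, "b": 15})
    g1 = sim.simulate_balding_nichols(spec, 5)
    g2 = sim.simulate_balding_nichols(spec, 5)
    assert np.array_equal(g1["a"].matrix, g2["a"].matrix)
    assert g1["b"].matrix.shape == (15, 100)


def test_bn_f_zero_degenerate_uses_ancestral():
    spec = sim.BaldingNicholsSpec(n_sites=4000, fst=0.0, deme_sizes={"a": 60, "b": 60})
    g = sim.simulate_balding_nichols(spec, 6)
    freq = g["a"].matrix.mean() / 2
    assert abs(freq - 0.5) < 0.02
    from anosurv.popgen import hudson_fst

    aa, ta = g["a"].allele_counts()
    ab, tb = g["b"].allele_counts()
    assert abs(hudson_fst(aa, ta, ab, tb).fst) < 0.01


def test_bn_invalid_spec():
    with pytest.raises(ValueError):
        sim.BaldingNicholsSpec(n_sites=10, fst=1.5, deme_sizes={"a": 5})
    with pytest.raises(ValueError):
        sim.BaldingNicholsSpec(n_sites=10, fst=0.1, deme_sizes={"a": 5}, ancestral_freq=0.0)


# ---------------------------------------------------------------------------
# Coverage


def test_coverage_no_cnv_truth_all_ploidy():
    ids = ("s1", "s2")
    cov, truth, segs = sim.simulate_coverage(ids, [], sim.CoverageSpec(), 120, seed=1)
    assert (truth == 2).all() and segs == []


def test_coverage_amplification_doubles_mean():
    ids = tuple(f"s{i}" for i in range(4))
    cov, truth, segs = sim.simulate_coverage(
        ids, [sim.CnvSpec(1.0, 4, 100, 10)], sim.CoverageSpec(mean_depth=30), 300, seed=2
    )
    inside = cov.counts[:, 100:110].mean()
    flank = np.concatenate([cov.counts[:, :100], cov.counts[:, 110:]], axis=1).mean()
    assert inside / flank == pytest.approx(2.0, rel=0.1)


def test_coverage_male_x_half_depth():
    ids = tuple(f"s{i}" for i in range(6))
    cov, truth, _ = sim.simulate_coverage(
        ids, [], sim.CoverageSpec(mean_depth=30), 400, seed=3,
        contig="X", ploidy=np.ones(6, dtype=int),
    )
    assert cov.counts.mean() == pytest.approx(15.0, rel=0.05)


def test_coverage_zero_depth_error():
    with pytest.raises(ValueError):
        sim.simulate_coverage(("s1",), [], sim.CoverageSpec(mean_depth=0), 10, seed=1)


# ---------------------------------------------------------------------------
# Bioassay


def test_bioassay_null_half_survive():
    dos = {"locus": np.zeros(1000)}
    out = sim.simulate_bioassay(dos, sim.PhenotypeSpec(baseline=0.0), seed=4)
    frac = (out == "alive").mean()
    assert 0.45 < frac < 0.55  # binomial CI at n=1000


def test_bioassay_saturating_baseline_all_dead():
    dos = {"locus": np.zeros(200)}
    out = sim.simulate_bioassay(dos, sim.PhenotypeSpec(baseline=-20.0), seed=5)
    assert (out == "dead").all()


def test_bioassay_protective_allele_enriched_in_alive():
    rng = np.random.default_rng(6)
    wins = 0
    for rep in range(10):
        dos = rng.binomial(2, 0.4, size=200).astype(float)
        out = sim.simulate_bioassay(
            {"locus": dos}, sim.PhenotypeSpec(baseline=-1.0, effects={"locus": 2.0}),
            seed=700 + rep,
        )
        alive = out == "alive"
        if dos[alive].mean() > dos[~alive].mean():
            wins += 1
    assert wins >= 9


def test_bioassay_unknown_locus_error():
    with pytest.raises(ValueError, match="missing"):
        sim.simulate_bioassay({"x": np.zeros(3)}, sim.PhenotypeSpec(effects={"y": 1.0}), 1)


# ---------------------------------------------------------------------------
# Fixtures


def test_fixture_round_trip_and_byte_determinism(tmp_path):
    cfg = tiny_config(11)
    haps, truth = sim.simulate_wf(cfg)
    hap = haps["a"]
    samples = sim.metadata_for(hap.sample_ids, location="a")
    cov, _, segs = sim.simulate_coverage(
        hap.sample_ids, [sim.CnvSpec(0.5, 4, 3, 6)], sim.CoverageSpec(), 16, seed=12
    )
    genes = [aio.GeneModel("AGAP_T", "2R", "+", ((900, 1200),))]
    ref = sim.make_reference(cfg.length, 11)
    truth = {"cnv_segments": segs}

    out1 = tmp_path / "f1"
    out2 = tmp_path / "f2"
    for out in (out1, out2):
        paths = sim.write_fixture(out, hap, samples, cov=cov, genes=genes,
                                  reference=ref, truth=truth)
    # identical bytes for identical inputs
    for name in ("vcf", "metadata", "coverage", "gff3", "fasta", "truth"):
        assert (out1 / (out2 / paths[name].name).name).read_bytes() == (
            out2 / paths[name].name
        ).read_bytes()

    hap2, gen2 = aio.read_vcf(paths["vcf"])
    assert np.array_equal(hap2.matrix, hap.matrix)
    back = json.loads((out2 / "truth.json").read_text())
    assert back["cnv_segments"] == segs
    meta = aio.read_metadata(out2 / "metadata.tsv")
    assert [s.sample_id for s in meta] == list(hap.sample_ids)


def test_fixture_partial_write_cleanup(tmp_path):
    cfg = tiny_config(13)
    haps, _ = sim.simulate_wf(cfg)
    hap = haps["a"]
    samples = sim.metadata_for(hap.sample_ids, location="a")
    out = tmp_path / "fx"

    class Boom(Exception):
        pass

    import anosurv.sim as simmod

    orig = simmod.aio.write_metadata
    def exploding(*a, **k):
        raise Boom()
    simmod.aio.write_metadata = exploding
    try:
        with pytest.raises(Boom):
            sim.write_fixture(out, hap, samples, truth={})
    finally:
        simmod.aio.write_metadata = orig
    assert not (out / "cohort.vcf").exists()
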