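"""Config-driven orchestration of the full surveillance analysis.

``run_pipeline`` executes, on one contig's inputs: sample QC -> cohort
construction -> diversity / FST / PCA -> CNV calling and gene CNV
frequencies -> H12 scan with calibration and alive/dead contrasts ->
Fisher associations -> diplotype clustering. Each stage writes a tidy
TSV and the run ends with a summary JSON embedding the tool version,
config hash and seed. Stages are individually toggleable; a stage
failure raises an error naming the stage.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from anosurv import __version__, assoc, cluster, cnv, popgen, selection
from anosurv import io as aio

log = logging.getLogger(__name__)

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "out_dir": "anosurv_out",
    "inputs": {},
    "stages": {
        "qc": True,
        "stats": True,
        "cnv": True,
        "h12": True,
        "assoc": True,
        "cluster": True,
    },
    "qc": {"min_median_cov": 10.0, "max_missing": 0.2, "max_contam": 0.045},
    "cohorts": {
        "keys": ["location", "year", "insecticide", "outcome"],
        "min_size": 10,
        "assoc_min_size": 5,
    },
    "stats": {"region_length": None, "pca_snps": 100_000, "min_maf": 0.2},
    "cnv": {
        "k_max": cnv.DEFAULT_K_MAX,
        "stay": cnv.DEFAULT_STAY,
        "min_windows": cnv.DEFAULT_MIN_WINDOWS,
        "min_likelihood_ratio": cnv.DEFAULT_MIN_LR,
        "variance_threshold": cnv.VARIANCE_THRESHOLD,
        "min_report": 0.05,
    },
    "h12": {
        "grid": list(selection.DEFAULT_GRID),
        "cutoff": 0.1,
        # scans default to chromosomes 2 and 3; the X is excluded
        "contig_prefixes": list(selection.SCAN_CONTIG_PREFIXES),
    },
    "assoc": {"min_report": 0.05},
    "cluster": {"gene": None, "cutoff": None, "min_cluster_frac": 0.05},
}


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in override.items():
        out[k] = _merge(base[k], v) if isinstance(v, dict) and isinstance(base.get(k), dict) else v
    return out


def load_config(path) -> dict:
    import yaml

    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    cfg = _merge(DEFAULT_CONFIG, user)
    for key, p in cfg["inputs"].items():
        if p and not Path(p).exists():
            raise FileNotFoundError(f"input {key!r}: {p} does not exist")
    return cfg


def config_hash(cfg: dict) -> str:
    """Hash of the analysis-relevant config (output location excluded)."""
    slim = {k: v for k, v in cfg.items() if k != "out_dir"}
    return hashlib.sha256(json.dumps(slim, sort_keys=True, default=str).encode()).hexdigest()[:16]


def _write(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def run_pipeline(cfg: dict) -> dict:
    """Execute the configured stages; returns the summary dict."""
    cfg = _merge(DEFAULT_CONFIG, cfg)
    out = Path(cfg["out_dir"])
    out.mkdir(parents=True, exist_ok=True)
    stages = cfg["stages"]
    summary: dict = {
        "version": __version__,
        "config_hash": config_hash(cfg),
        "seed": cfg["seed"],
        "stages": {},
    }
    timings: dict[str, float] = {}

    samples = aio.read_metadata(cfg["inputs"]["metadata"])

    # ---- QC -------------------------------------------------------------
    if stages.get("qc", True):
        t0 = time.perf_counter()
        try:
            passing, reasons = aio.qc_filter(samples, **cfg["qc"])
            _write(
                pd.DataFrame(
                    [
                        {"sample_id": s.sample_id, "pass": s.sample_id not in reasons,
                         "reasons": ",".join(reasons.get(s.sample_id, []))}
                        for s in samples
                    ]
                ),
                out / "qc.tsv",
            )
            samples = passing
            summary["stages"]["qc"] = {"n_pass": len(passing), "n_fail": len(reasons)}
        except Exception as e:  # noqa: BLE001
            raise StageError("qc", e) from e
        timings["qc"] = time.perf_counter() - t0

    cohorts = aio.build_cohorts(
        samples, keys=tuple(cfg["cohorts"]["keys"]), min_size=cfg["cohorts"]["min_size"]
    )
    _write(
        pd.DataFrame(
            [{"cohort": c.name, "size": c.size, "eligible": c.eligible, **c.keys} for c in cohorts]
        ),
        out / "cohorts.tsv",
    )
    summary["stages"]["cohorts"] = {"n_cohorts": len(cohorts)}

    hap, gen = aio.read_vcf(cfg["inputs"]["vcf"])
    if cfg["inputs"].get("site_mask"):
        mask = aio.read_site_mask(cfg["inputs"]["site_mask"])
        hap = aio.apply_site_mask(hap, mask)
        gen = aio.apply_site_mask(gen, mask)
    present = set(hap.sample_ids)
    kept = {s.sample_id for s in samples}

    def cohort_hap(c):
        ids = [s for s in c.sample_ids if s in present]
        return hap.take_samples(ids) if ids else None

    # ---- diversity / FST / PCA -----------------------------------------
    if stages.get("stats", True):
        t0 = time.perf_counter()
        try:
            L = cfg["stats"]["region_length"] or int(hap.positions[-1] - hap.positions[0] + 1)
            rows, hmats = [], {}
            for c in cohorts:
                if not c.eligible:
                    continue
                ch = cohort_hap(c)
                if ch is None:
                    continue
                hmats[c.name] = ch
                d = popgen.diversity_stats(ch, c.name, L, min_size=cfg["cohorts"]["min_size"])
                rows.append(
                    {"cohort": d.cohort, "region": d.region, "n": d.n, "S": d.S,
                     "pi": d.pi, "theta_w": d.theta_w,
                     "tajima_d": np.nan if d.tajima_d is None else d.tajima_d}
                )
            _write(pd.DataFrame(rows), out / "diversity.tsv")
            frows = []
            names = sorted(hmats)
            for i, a in enumerate(names):
                for b in names[i + 1 :]:
                    r = popgen.hudson_fst_haplotypes(hmats[a], hmats[b], (a, b))
                    frows.append({"cohort_a": a, "cohort_b": b, "fst": r.fst})
            _write(pd.DataFrame(frows, columns=["cohort_a", "cohort_b", "fst"]), out / "fst.tsv")
            ids = [s for s in gen.sample_ids if s in kept]
            pca = popgen.pca_allele_counts(
                gen.take_samples(ids), n_snps=cfg["stats"]["pca_snps"], min_maf=cfg["stats"]["min_maf"]
            )
            pdf = pd.DataFrame(pca.coords[:, :2], columns=["PC1", "PC2"])
            pdf.insert(0, "sample_id", list(pca.sample_ids))
            _write(pdf, out / "pca.tsv")
            summary["stages"]["stats"] = {
                "n_diversity_cohorts": len(rows),
                "n_fst_pairs": len(frows),
                "pca_snps": pca.n_snps,
                "pca_var_explained_pc1": float(pca.variance_explained[0]),
            }
        except Exception as e:  # noqa: BLE001
            raise StageError("stats", e) from e
        timings["stats"] = time.perf_counter() - t0

    # ---- CNV ------------------------------------------------------------
    calls: list[cnv.CNVCall] = []
    gene_models = (
        aio.read_gff3(cfg["inputs"]["gff3"]) if cfg["inputs"].get("gff3") else []
    )
    if stages.get("cnv", True):
        t0 = time.perf_counter()
        try:
            if not cfg["inputs"].get("coverage"):
                raise FileNotFoundError("CNV stage enabled but no coverage input")
            cov = cnv.read_coverage(cfg["inputs"]["coverage"])
            bias = cnv.estimate_window_bias(cov)
            sex = {s.sample_id: s.sex for s in samples}
            excluded = []
            for sid in cov.sample_ids:
                if sid not in kept:
                    continue
                ploidy = 1 if (cov.contig.startswith("X") and sex.get(sid) == "M") else 2
                c, ok, var = cnv.call_sample_cnvs(
                    cov, sid, ploidy=ploidy,
                    k_max=cfg["cnv"]["k_max"], stay=cfg["cnv"]["stay"],
                    min_windows=cfg["cnv"]["min_windows"],
                    min_likelihood_ratio=cfg["cnv"]["min_likelihood_ratio"],
                    variance_threshold=cfg["cnv"]["variance_threshold"],
                    bias=bias,
                )
                if not ok:
                    excluded.append(sid)
                calls.extend(c)
            _write(cnv.calls_to_frame(calls), out / "cnv_calls.tsv")
            grows = []
            for c in cohorts:
                ids = tuple(s for s in c.sample_ids if s in set(cov.sample_ids))
                if not ids:
                    continue
                for gf in cnv.gene_cnv_frequency(
                    calls, gene_models, ids, c.name, cfg["cnv"]["min_report"]
                ):
                    grows.append(
                        {"cohort": gf.cohort, "gene": gf.gene_id, "carriers": gf.carriers,
                         "size": gf.cohort_size, "frequency": gf.frequency, "reported": gf.reported}
                    )
            _write(pd.DataFrame(grows), out / "cnv_gene_frequency.tsv")
            summary["stages"]["cnv"] = {
                "n_calls": len(calls),
                "n_samples_excluded_variance": len(excluded),
            }
        except Exception as e:  # noqa: BLE001
            raise StageError("cnv", e) from e
        timings["cnv"] = time.perf_counter() - t0

    # ---- H12 ------------------------------------------------------------
    if stages.get("h12", True):
        t0 = time.perf_counter()
        try:
            hrows, drows, prows = [], [], []
            profiles = {}
            prefixes = tuple(cfg["h12"]["contig_prefixes"])
            scan_ok = hap.contig.startswith(prefixes) if prefixes else True
            if not scan_ok:
                log.info("contig %s outside scan set %s; H12 skipped", hap.contig, prefixes)
            for c in cohorts if scan_ok else []:
                if not c.eligible:
                    continue
                ch = cohort_hap(c)
                if ch is None or ch.n_sites < min(cfg["h12"]["grid"]):
                    continue
                cal = selection.calibrate_window_size(
                    ch, tuple(cfg["h12"]["grid"]), cfg["h12"]["cutoff"], c.name
                )
                prof = selection.h12_scan(ch, cal.chosen, cohort=c.name)
                profiles[c.name] = (c, prof)
                for pk in selection.find_peaks(prof, gene_models=gene_models):
                    prows.append(
                        {"cohort": c.name, "contig": pk.contig, "start": pk.start,
                         "end": pk.end, "max_h12": pk.max_value,
                         "genes": ",".join(pk.gene_ids)}
                    )
                for k in range(prof.values.size):
                    hrows.append(
                        {"cohort": c.name, "contig": prof.contig,
                         "start": prof.window_start[k], "end": prof.window_end[k],
                         "n_snps": prof.n_snps[k], "h12": prof.values[k],
                         "window_size": cal.chosen, "calibrated": cal.qualified}
                    )
            # alive/dead contrasts within (location, year, insecticide)
            byarm: dict[tuple, dict[str, object]] = {}
            for name, (c, prof) in profiles.items():
                key = (c.keys.get("location"), c.keys.get("year"), c.keys.get("insecticide"))
                byarm.setdefault(key, {})[c.keys.get("outcome")] = (c, prof)
            for key, arms in byarm.items():
                if "alive" not in arms or "dead" not in arms:
                    continue
                ca, _ = arms["alive"]
                cd, _ = arms["dead"]
                ha, hd = cohort_hap(ca), cohort_hap(cd)
                w = min(arms["alive"][1].window_size, arms["dead"][1].window_size)
                dprof = selection.contrast_scan(ha, hd, w)
                for k in range(dprof.values.size):
                    drows.append(
                        {"location": key[0], "year": key[1], "insecticide": key[2],
                         "start": dprof.window_start[k], "end": dprof.window_end[k],
                         "delta_h12": dprof.values[k]}
                    )
            _write(pd.DataFrame(hrows), out / "h12.tsv")
            _write(pd.DataFrame(drows), out / "delta_h12.tsv")
            _write(
                pd.DataFrame(prows, columns=["cohort", "contig", "start", "end", "max_h12", "genes"]),
                out / "h12_peaks.tsv",
            )
            summary["stages"]["h12"] = {
                "n_profiles": len(profiles),
                "n_contrasts": len(drows),
                "n_peaks": len(prows),
            }
        except Exception as e:  # noqa: BLE001
            raise StageError("h12", e) from e
        timings["h12"] = time.perf_counter() - t0

    # ---- association ----------------------------------------------------
    if stages.get("assoc", True):
        t0 = time.perf_counter()
        try:
            reference = (
                aio.read_fasta(cfg["inputs"]["fasta"]) if cfg["inputs"].get("fasta") else {}
            )
            frows, arows = [], []
            subs_by_gene = {
                g.gene_id: assoc.annotate_aa_substitutions(gen, g, reference)
                for g in gene_models
                if g.contig in reference
            }
            by_sample = {s.sample_id: s for s in samples}
            for c in cohorts:
                ids = [s for s in c.sample_ids if s in present]
                if not ids:
                    continue
                sub_gen = gen.take_samples(ids)
                for gid, subs in subs_by_gene.items():
                    for f in assoc.aa_frequencies(subs, sub_gen, cfg["assoc"]["min_report"]):
                        frows.append(
                            {"cohort": c.name, "gene": f.gene_id, "substitution": f.label,
                             "frequency": f.frequency, "reported": f.reported}
                        )
            # alive vs dead tests per (location, year, insecticide)
            arms: dict[tuple, dict[str, object]] = {}
            for c in cohorts:
                k = (c.keys.get("location"), c.keys.get("year"), c.keys.get("insecticide"))
                if c.keys.get("outcome") in ("alive", "dead"):
                    arms.setdefault(k, {})[c.keys["outcome"]] = c
            min_n = cfg["cohorts"]["assoc_min_size"]
            for k, pair in arms.items():
                if "alive" not in pair or "dead" not in pair:
                    continue
                ca, cd = pair["alive"], pair["dead"]
                if ca.size < min_n or cd.size < min_n:
                    log.info("association skipped for %s: cohort below %d", k, min_n)
                    continue
                ga = gen.take_samples([s for s in ca.sample_ids if s in present])
                gd = gen.take_samples([s for s in cd.sample_ids if s in present])
                for gid, subs in subs_by_gene.items():
                    for s in subs:
                        aa, ta = ga.allele_counts()
                        ad, td = gd.allele_counts()
                        j = s.site_index
                        r = assoc.fisher_snp_association(
                            int(aa[j]), int(ta[j] - aa[j]), int(ad[j]), int(td[j] - ad[j]),
                            locus=f"{gid}:{s.label}",
                        )
                        arows.append(
                            {"location": k[0], "year": k[1], "insecticide": k[2],
                             "locus": r.locus, "kind": "snp", "p": r.p_value,
                             "direction": r.direction}
                        )
                carrier = {cl.sample_id for cl in calls}
                for g in gene_models:
                    gene_carriers = {
                        cl.sample_id for cl in calls
                        if cl.contig == g.contig and cl.start < g.span[1] and g.span[0] < cl.end
                    }
                    r = assoc.fisher_cnv_association(
                        len(gene_carriers & set(ca.sample_ids)), ca.size,
                        len(gene_carriers & set(cd.sample_ids)), cd.size,
                        locus=g.gene_id, min_cohort=min_n,
                    )
                    if r is not None:
                        arows.append(
                            {"location": k[0], "year": k[1], "insecticide": k[2],
                             "locus": r.locus, "kind": "cnv", "p": r.p_value,
                             "direction": r.direction}
                        )
            adf = pd.DataFrame(arows, columns=["location", "year", "insecticide", "locus", "kind", "p", "direction"])
            if len(adf):
                adf["p_bh"] = assoc.bh_adjust(adf["p"].to_numpy())
            _write(pd.DataFrame(frows), out / "aa_frequency.tsv")
            _write(adf, out / "association.tsv")
            summary["stages"]["assoc"] = {"n_frequency_rows": len(frows), "n_tests": len(arows)}
        except Exception as e:  # noqa: BLE001
            raise StageError("assoc", e) from e
        timings["assoc"] = time.perf_counter() - t0

    # ---- clustering ------------------------------------------------------
    if stages.get("cluster", True):
        t0 = time.perf_counter()
        try:
            gene_id = cfg["cluster"]["gene"]
            target = next((g for g in gene_models if g.gene_id == gene_id), None) if gene_id else (
                gene_models[0] if gene_models else None
            )
            if target is not None:
                lo, hi = target.span
                sel = (gen.positions >= lo) & (gen.positions < hi)
                ids = [s for s in gen.sample_ids if s in kept]
                sub = gen.take_samples(ids)
                region = cluster.DiplotypeRegion(
                    region_id=target.gene_id,
                    ids=tuple(ids),
                    vectors=sub.matrix[:, sel],
                )
                tree = cluster.cluster_diplotypes(region)
                reports = cluster.cluster_report(
                    tree, region, cutoff=cfg["cluster"]["cutoff"],
                    min_cluster_frac=cfg["cluster"]["min_cluster_frac"],
                )
                (out / "diplotype_dendrogram.nwk").write_text(tree.to_newick() + "\n")
                _write(
                    pd.DataFrame(
                        [
                            {"cluster": r.label, "size": r.size, "frequency": r.frequency,
                             "mean_heterozygosity": r.mean_heterozygosity,
                             "selection_candidate": r.selection_candidate,
                             "n_exclusive_sites": len(r.exclusive_sites)}
                            for r in reports
                        ]
                    ),
                    out / "diplotype_clusters.tsv",
                )
                summary["stages"]["cluster"] = {
                    "region": target.gene_id,
                    "n_reported_clusters": len(reports),
                }
        except Exception as e:  # noqa: BLE001
            raise StageError("cluster", e) from e
        timings["cluster"] = time.perf_counter() - t0

    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    for stage, dt in timings.items():
        log.info("stage %s: %.2fs", stage, dt)
    return summary
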