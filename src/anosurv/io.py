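"""Data model, file readers/writers and cohort construction.

Internal coordinates are 0-based half-open throughout the package; the
VCF/GFF readers and writers convert to and from the 1-based inclusive
convention of those formats at the boundary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq

log = logging.getLogger(__name__)

MISSING = -1  # sentinel for missing genotype dosage

INSECTICIDES = ("alpha-cypermethrin", "deltamethrin", "pirimiphos-methyl", "none")
OUTCOMES = ("alive", "dead", "untested")

METADATA_COLUMNS = (
    "sample_id",
    "location",
    "year",
    "latitude",
    "longitude",
    "sex",
    "insecticide",
    "outcome",
    "median_coverage",
    "missingness",
    "contamination",
)


@dataclass
class SampleRecord:
    """One sequenced mosquito with collection metadata and QC fields.

    ``outcome`` is 'untested' exactly when ``insecticide`` is 'none';
    tested samples are scored alive or dead in a standardized bioassay.
    """

    sample_id: str
    location: str
    year: int
    latitude: float
    longitude: float
    sex: str
    insecticide: str
    outcome: str
    median_coverage: float = float("nan")
    missingness: float = float("nan")
    contamination: float = float("nan")

    def __post_init__(self) -> None:
        if self.sex not in ("F", "M"):
            raise ValueError(f"sex must be F or M, got {self.sex!r}")
        if self.insecticide not in INSECTICIDES:
            raise ValueError(f"unknown insecticide {self.insecticide!r}")
        if self.outcome not in OUTCOMES:
            raise ValueError(f"unknown outcome {self.outcome!r}")
        if (self.outcome == "untested") != (self.insecticide == "none"):
            raise ValueError(
                f"{self.sample_id}: outcome 'untested' iff insecticide 'none' "
                f"(got outcome={self.outcome!r}, insecticide={self.insecticide!r})"
            )
        if not -90.0 <= self.latitude <= 90.0:
            raise ValueError(f"latitude out of range: {self.latitude}")
        if not -180.0 <= self.longitude <= 180.0:
            raise ValueError(f"longitude out of range: {self.longitude}")
        for name in ("missingness", "contamination"):
            v = getattr(self, name)
            if np.isfinite(v) and not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {v}")

    @property
    def tested(self) -> bool:
        return self.outcome != "untested"


@dataclass
class Cohort:
    """An analysis cohort, usually location x year x insecticide x outcome."""

    name: str
    sample_ids: tuple[str, ...]
    keys: Mapping[str, object] = field(default_factory=dict)
    eligible: bool = True  # size >= min_size for diversity statistics

    def __post_init__(self) -> None:
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError(f"cohort {self.name}: duplicate sample ids")

    @property
    def size(self) -> int:
        return len(self.sample_ids)


@dataclass
class HaplotypeMatrix:
    """Phased binary haplotypes: 2n rows (sample i -> rows 2i, 2i+1), S sites."""

    contig: str
    positions: np.ndarray  # 0-based site coordinates, strictly increasing
    ref: np.ndarray  # ref nucleotide per site
    alt: np.ndarray  # alt nucleotide per site
    matrix: np.ndarray  # (2n, S) of {0,1}, int8
    sample_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.matrix = np.asarray(self.matrix, dtype=np.int8)
        if self.matrix.ndim != 2:
            raise ValueError("matrix must be 2-D")
        if self.matrix.shape[1] != self.positions.size:
            raise ValueError("column count != number of positions")
        if self.matrix.shape[0] != 2 * len(self.sample_ids):
            raise ValueError("row count must be 2 x sample count")
        if self.positions.size > 1 and not np.all(np.diff(self.positions) > 0):
            raise ValueError("positions must be strictly increasing")
        bad = ~np.isin(self.matrix, (0, 1))
        if bad.any():
            raise ValueError("haplotype entries must be 0 or 1")

    @property
    def n_haplotypes(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_sites(self) -> int:
        return self.matrix.shape[1]

    def to_genotypes(self) -> "GenotypeMatrix":
        """Collapse haplotype row pairs to 0/1/2 dosages."""
        dosage = (self.matrix[0::2, :] + self.matrix[1::2, :]).astype(np.int8)
        return GenotypeMatrix(
            contig=self.contig,
            positions=self.positions.copy(),
            ref=self.ref.copy(),
            alt=self.alt.copy(),
            matrix=dosage,
            sample_ids=self.sample_ids,
        )

    def take_samples(self, ids: Sequence[str]) -> "HaplotypeMatrix":
        idx = [self.sample_ids.index(s) for s in ids]
        rows = np.array([(2 * i, 2 * i + 1) for i in idx]).ravel()
        return HaplotypeMatrix(
            contig=self.contig,
            positions=self.positions.copy(),
            ref=self.ref.copy(),
            alt=self.alt.copy(),
            matrix=self.matrix[rows, :],
            sample_ids=tuple(ids),
        )


@dataclass
class GenotypeMatrix:
    """Unphased allele dosages: n samples x S sites of {0,1,2} or MISSING."""

    contig: str
    positions: np.ndarray
    ref: np.ndarray
    alt: np.ndarray
    matrix: np.ndarray  # (n, S) int8
    sample_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.matrix = np.asarray(self.matrix, dtype=np.int8)
        if self.matrix.shape[1] != self.positions.size:
            raise ValueError("column count != number of positions")
        if self.matrix.shape[0] != len(self.sample_ids):
            raise ValueError("row count != sample count")
        bad = ~np.isin(self.matrix, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError("genotype entries must be 0/1/2 or missing")

    @property
    def n_samples(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_sites(self) -> int:
        return self.matrix.shape[1]

    def allele_counts(self) -> tuple[np.ndarray, np.ndarray]:
        """Per-site (alt allele count, called allele total), missing excluded."""
        called = self.matrix != MISSING
        alt = np.where(called, self.matrix, 0).sum(axis=0)
        return alt.astype(np.int64), (2 * called.sum(axis=0)).astype(np.int64)

    def take_samples(self, ids: Sequence[str]) -> "GenotypeMatrix":
        idx = [self.sample_ids.index(s) for s in ids]
        return GenotypeMatrix(
            contig=self.contig,
            positions=self.positions.copy(),
            ref=self.ref.copy(),
            alt=self.alt.copy(),
            matrix=self.matrix[idx, :],
            sample_ids=tuple(ids),
        )


@dataclass
class GeneModel:
    """A transcript's CDS footprint used for codon translation.

    ``cds`` holds 0-based half-open intervals ordered in transcription
    order (for a - strand gene the first interval is the genomically last).
    """

    gene_id: str
    contig: str
    strand: str
    cds: tuple[tuple[int, int], ...]
    name: str | None = None

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        total = sum(e - s for s, e in self.cds)
        if total % 3 != 0:
            raise ValueError(f"{self.gene_id}: CDS length {total} not divisible by 3")
        ivs = sorted(self.cds)
        for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
            if s2 < e1:
                raise ValueError(f"{self.gene_id}: overlapping CDS intervals")

    @property
    def cds_length(self) -> int:
        return sum(e - s for s, e in self.cds)

    @property
    def span(self) -> tuple[int, int]:
        """Genomic footprint (min start, max end), 0-based half-open."""
        return min(s for s, _ in self.cds), max(e for _, e in self.cds)

    def cds_positions(self) -> np.ndarray:
        """Genomic positions of CDS bases in transcription order."""
        parts = []
        for s, e in self.cds:
            block = np.arange(s, e)
            if self.strand == "-":
                block = block[::-1]
            parts.append(block)
        return np.concatenate(parts) if parts else np.array([], dtype=np.int64)


# ---------------------------------------------------------------------------
# VCF


def read_vcf(path, region: str | None = None):
    """Read phased biallelic SNPs from a VCF.

    Returns ``(HaplotypeMatrix, GenotypeMatrix)``. Non-biallelic or
    non-SNP records are skipped (count logged). Records with any unphased
    or missing call contribute to the genotype matrix only.

    Raises ``ValueError`` on mixed contigs unless ``region`` restricts to one.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    sample_ids = tuple(vcf.samples)
    n = len(sample_ids)
    if n == 0:
        raise ValueError(f"{path}: VCF has no samples / GT field")

    contigs: set[str] = set()
    positions, refs, alts = [], [], []
    hap_cols, gt_rows, phased_flags = [], [], []
    n_skipped = 0

    it = vcf(region) if region else vcf
    for var in it:
        if not var.is_snp or len(var.ALT) != 1:
            n_skipped += 1
            continue
        contigs.add(var.CHROM)
        gts = np.array(var.genotypes, dtype=np.int64)  # (n, 3): a0, a1, phased
        a0, a1, ph = gts[:, 0], gts[:, 1], gts[:, 2].astype(bool)
        dosage = np.where((a0 < 0) | (a1 < 0), MISSING, a0 + a1).astype(np.int8)
        site_phased = bool(ph.all() and (a0 >= 0).all() and (a1 >= 0).all())
        positions.append(var.POS - 1)
        refs.append(var.REF)
        alts.append(var.ALT[0])
        gt_rows.append(dosage)
        phased_flags.append(site_phased)
        hap_cols.append(np.stack([a0, a1], axis=1).reshape(-1) if site_phased else None)
    vcf.close()

    if len(contigs) > 1:
        raise ValueError(
            f"{path}: records span contigs {sorted(contigs)}; pass a region"
        )
    if n_skipped:
        log.info("%s: skipped %d non-biallelic-SNP records", path, n_skipped)
    contig = contigs.pop() if contigs else (region.split(":")[0] if region else "")

    pos = np.array(positions, dtype=np.int64)
    ref = np.array(refs, dtype="U1")
    alt = np.array(alts, dtype="U1")
    G = (
        np.stack(gt_rows, axis=1)
        if gt_rows
        else np.zeros((n, 0), dtype=np.int8)
    )
    phased = np.array(phased_flags, dtype=bool)
    H = (
        np.stack([c for c in hap_cols if c is not None], axis=1).astype(np.int8)
        if phased.any()
        else np.zeros((2 * n, 0), dtype=np.int8)
    )
    hap = HaplotypeMatrix(contig, pos[phased], ref[phased], alt[phased], H, sample_ids)
    gen = GenotypeMatrix(contig, pos, ref, alt, G, sample_ids)
    return hap, gen


def write_vcf(path, hap: HaplotypeMatrix) -> None:
    """Write a phased HaplotypeMatrix as a minimal VCF 4.2 text file."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={hap.contig}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(hap.sample_ids)
            + "\n"
        )
        M = hap.matrix
        for j in range(hap.n_sites):
            gts = "\t".join(
                f"{M[2 * i, j]}|{M[2 * i + 1, j]}" for i in range(len(hap.sample_ids))
            )
            fh.write(
                f"{hap.contig}\t{hap.positions[j] + 1}\t.\t{hap.ref[j]}\t"
                f"{hap.alt[j]}\t.\tPASS\t.\tGT\t{gts}\n"
            )


# ---------------------------------------------------------------------------
# Metadata, cohorts, QC


def read_metadata(path) -> list[SampleRecord]:
    """Read the sample metadata TSV (required header, one row per sample)."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    missing = set(METADATA_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: metadata missing columns {sorted(missing)}")
    records = []
    for row in df.itertuples(index=False):
        records.append(
            SampleRecord(
                sample_id=row.sample_id,
                location=row.location,
                year=int(row.year),
                latitude=float(row.latitude),
                longitude=float(row.longitude),
                sex=row.sex,
                insecticide=row.insecticide,
                outcome=row.outcome,
                median_coverage=float(row.median_coverage),
                missingness=float(row.missingness),
                contamination=float(row.contamination),
            )
        )
    return records


def write_metadata(path, samples: Iterable[SampleRecord]) -> None:
    df = pd.DataFrame([{c: getattr(s, c) for c in METADATA_COLUMNS} for s in samples])
    df.to_csv(path, sep="\t", index=False)


def qc_filter(
    samples: Iterable[SampleRecord],
    min_median_cov: float = 10.0,
    max_missing: float = 0.2,
    max_contam: float = 0.045,
):
    """Apply per-sample QC: coverage, data completeness, contamination.

    Bounds are strict in the passing direction: coverage must exceed
    ``min_median_cov``, missingness and contamination must fall below
    their thresholds. Returns ``(passing, reasons)`` where ``reasons``
    maps each failing sample id to the list of failed checks; samples
    with unpopulated QC fields fail with reason 'missing_qc'.
    """
    passing: list[SampleRecord] = []
    reasons: dict[str, list[str]] = {}
    for s in samples:
        why = []
        qc = (s.median_coverage, s.missingness, s.contamination)
        if any(not np.isfinite(v) for v in qc):
            why.append("missing_qc")
        else:
            if not s.median_coverage > min_median_cov:
                why.append("coverage")
            if not s.missingness < max_missing:
                why.append("missingness")
            if not s.contamination < max_contam:
                why.append("contamination")
        if why:
            reasons[s.sample_id] = why
            log.info("QC fail %s: %s", s.sample_id, ",".join(why))
        else:
            passing.append(s)
    return passing, reasons


def build_cohorts(
    samples: Sequence[SampleRecord],
    keys: Sequence[str] = ("location", "year", "insecticide", "outcome"),
    min_size: int = 10,
) -> list[Cohort]:
    """Group samples into cohorts by metadata keys.

    Every sample lands in exactly one cohort; cohorts smaller than
    ``min_size`` are flagged ``eligible=False`` (excluded from diversity
    statistics downstream). An empty key list yields a single cohort.
    """
    ids = [s.sample_id for s in samples]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate sample_id in metadata")
    groups: dict[tuple, list[str]] = {}
    for s in samples:
        k = tuple(getattr(s, key) for key in keys)
        groups.setdefault(k, []).append(s.sample_id)
    cohorts = []
    for k in sorted(groups, key=str):
        name = "_".join(str(v) for v in k) if keys else "all"
        members = tuple(groups[k])
        cohorts.append(
            Cohort(
                name=name,
                sample_ids=members,
                keys=dict(zip(keys, k)),
                eligible=len(members) >= min_size,
            )
        )
    return cohorts


# ---------------------------------------------------------------------------
# GFF3 / FASTA


def read_fasta(path) -> dict[str, str]:
    """Load a reference FASTA as a dict contig -> uppercase sequence."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(path, sequences: Mapping[str, str]) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")


def read_gff3(path) -> list[GeneModel]:
    """Read gene models (one transcript per gene: the first mRNA's CDS)."""
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    models = []
    for gene in db.features_of_type("gene"):
        mrnas = list(db.children(gene, featuretype="mRNA"))
        parent = mrnas[0] if mrnas else gene
        cds = list(db.children(parent, featuretype="CDS", order_by="start"))
        if not cds:
            continue
        intervals = [(c.start - 1, c.end) for c in cds]  # to 0-based half-open
        if gene.strand == "-":
            intervals = intervals[::-1]
        models.append(
            GeneModel(
                gene_id=gene.id,
                contig=gene.seqid,
                strand=gene.strand,
                cds=tuple(intervals),
                name=gene.attributes.get("Name", [None])[0],
            )
        )
    return models


def write_gff3(path, models: Iterable[GeneModel]) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for m in models:
            s, e = m.span
            attrs = f"ID={m.gene_id}" + (f";Name={m.name}" if m.name else "")
            fh.write(
                f"{m.contig}\tanosurv\tgene\t{s + 1}\t{e}\t.\t{m.strand}\t.\t{attrs}\n"
            )
            fh.write(
                f"{m.contig}\tanosurv\tmRNA\t{s + 1}\t{e}\t.\t{m.strand}\t.\t"
                f"ID={m.gene_id}.t1;Parent={m.gene_id}\n"
            )
            for i, (cs, ce) in enumerate(sorted(m.cds)):
                fh.write(
                    f"{m.contig}\tanosurv\tCDS\t{cs + 1}\t{ce}\t.\t{m.strand}\t0\t"
                    f"ID={m.gene_id}.cds{i};Parent={m.gene_id}.t1\n"
                )


def translate_codon(codon: str) -> str:
    """Standard genetic code; '*' for stop."""
    return str(Seq(codon).translate())


# ---------------------------------------------------------------------------
# Optional site mask (accessible intervals)


def read_site_mask(path) -> list[tuple[str, int, int]]:
    """Read a BED file of accessible intervals (0-based half-open).

    Sites outside these intervals are excluded from analysis — an
    externally supplied stand-in for upstream site filters that flag
    less reliable SNP calling.
    """
    intervals = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            contig, start, end = line.split("\t")[:3]
            intervals.append((contig, int(start), int(end)))
    return intervals


def apply_site_mask(matrix, intervals: Sequence[tuple[str, int, int]]):
    """Restrict a Haplotype/GenotypeMatrix to sites inside the mask."""
    keep = np.zeros(matrix.positions.size, dtype=bool)
    for contig, start, end in intervals:
        if contig != matrix.contig:
            continue
        keep |= (matrix.positions >= start) & (matrix.positions < end)
    cls = type(matrix)
    return cls(
        contig=matrix.contig,
        positions=matrix.positions[keep],
        ref=matrix.ref[keep],
        alt=matrix.alt[keep],
        matrix=matrix.matrix[:, keep],
        sample_ids=matrix.sample_ids,
    )
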