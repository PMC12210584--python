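"""Resistance-allele frequencies and bioassay association.

Covers transcript-aware amino-acid substitution calling from biallelic
SNPs (e.g. the pyrethroid target-site substitution Vgsc-L995F), cohort
frequency tables with a 5% reporting threshold, and two-sided Fisher
exact association of SNP alleles or CNV carrier status with bioassay
outcome (alive vs dead).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from anosurv.io import MISSING, GeneModel, GenotypeMatrix, translate_codon

log = logging.getLogger(__name__)

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}

#: Insecticide-resistance gene panel (editable): target-site loci and the
#: major metabolic-resistance gene families under CNV surveillance.
GENE_PANEL: dict[str, str] = {
    "AGAP004707": "Vgsc",
    "AGAP006028": "Rdl",
    "AGAP001356": "Ace1",
    "AGAP009194": "Gste2",
    "AGAP002862": "Cyp6aa1",
    "AGAP002863": "Cyp6aa2",
    "AGAP002865": "Cyp6p3",
    "AGAP002870": "Cyp6p4",
    "AGAP000818": "Cyp9k1",
    "AGAP008212": "Cyp6m2",
    "AGAP008219": "Cyp6z1",
    "AGAP006228": "Coeae1f",
    "AGAP006723": "Coeae2f",
    "AGAP006724": "Coeae2g",
    "AGAP006728": "Coeae7g",
}


@dataclass
class AASubstitution:
    """A nonsynonymous change at one transcript codon from one SNP."""

    gene_id: str
    codon_number: int  # 1-based from transcript start
    ref_aa: str
    alt_aa: str
    site_index: int  # column in the source genotype matrix
    genomic_pos: int  # 0-based
    label: str = field(init=False)

    def __post_init__(self) -> None:
        self.label = f"{self.ref_aa}{self.codon_number}{self.alt_aa}"


@dataclass
class AAFrequency:
    gene_id: str
    label: str
    frequency: float
    alt_alleles: int
    total_alleles: int
    n_variants: int  # distinct nucleotide variants pooled under this label
    reported: bool  # frequency strictly above the reporting threshold
    shares_codon: bool  # another segregating variant hits the same codon


@dataclass
class AssociationResult:
    locus: str
    table: np.ndarray  # 2x2 [[x_alive, y_alive], [x_dead, y_dead]]
    p_value: float
    odds_ratio: float
    direction: int  # +1 enriched in alive, -1 in dead, 0 none
    degenerate: bool = False  # a zero margin; p = 1 by convention


def annotate_aa_substitutions(
    gen: GenotypeMatrix,
    gene: GeneModel,
    reference: dict[str, str],
) -> list[AASubstitution]:
    """Call nonsynonymous substitutions for SNPs inside a gene's CDS.

    Codons are rebuilt from the reference sequence in transcription order
    (reverse-complemented for minus-strand genes), the variant base is
    substituted, and both codons are translated with the standard genetic
    code; only residue-changing records are returned. '*' denotes a stop
    codon, so stop-gains label as e.g. E762*.
    """
    if gene.contig not in reference:
        raise ValueError(f"reference lacks contig {gene.contig}")
    seq = reference[gene.contig]
    cds_pos = gene.cds_positions()  # genomic positions in transcription order
    if cds_pos.size and cds_pos.max() >= len(seq):
        raise ValueError(f"{gene.gene_id}: CDS extends past reference end")
    pos_to_cds = {int(p): i for i, p in enumerate(cds_pos)}
    out = []
    for j, gpos in enumerate(gen.positions):
        idx = pos_to_cds.get(int(gpos))
        if idx is None:
            continue
        codon_number = idx // 3 + 1
        codon_gpos = cds_pos[3 * (codon_number - 1) : 3 * codon_number]
        bases = []
        for p in codon_gpos:
            b = seq[int(p)]
            if b not in _COMPLEMENT:
                raise ValueError(
                    f"{gene.gene_id}: codon {codon_number} spans missing "
                    f"reference base at {gene.contig}:{int(p) + 1}"
                )
            bases.append(b if gene.strand == "+" else _COMPLEMENT[b])
        ref_codon = "".join(bases)
        alt_base = str(gen.alt[j])
        if gene.strand == "-":
            alt_base = _COMPLEMENT[alt_base]
        within = idx - 3 * (codon_number - 1)
        alt_codon = ref_codon[:within] + alt_base + ref_codon[within + 1 :]
        ref_aa, alt_aa = translate_codon(ref_codon), translate_codon(alt_codon)
        exp_ref = seq[int(gpos)]
        if exp_ref != str(gen.ref[j]):
            raise ValueError(
                f"{gene.gene_id}: VCF ref {gen.ref[j]} != reference {exp_ref} "
                f"at {gene.contig}:{int(gpos) + 1}"
            )
        if ref_aa != alt_aa:
            out.append(
                AASubstitution(
                    gene_id=gene.gene_id,
                    codon_number=codon_number,
                    ref_aa=ref_aa,
                    alt_aa=alt_aa,
                    site_index=j,
                    genomic_pos=int(gpos),
                )
            )
    return out


def aa_frequencies(
    substitutions: list[AASubstitution],
    gen: GenotypeMatrix,
    min_report: float = 0.05,
) -> list[AAFrequency]:
    """Cohort frequency per amino-acid substitution label.

    Distinct nucleotide variants encoding the same residue change are
    pooled into one row. Frequency = pooled alt-allele count over called
    alleles. Rows at or below ``min_report`` are marked unreported but
    retained in the returned (full) table.
    """
    if gen.n_samples == 0:
        raise ValueError("empty cohort")
    by_label: dict[tuple[str, str], list[AASubstitution]] = {}
    codon_hits: dict[tuple[str, int], int] = {}
    for s in substitutions:
        by_label.setdefault((s.gene_id, s.label), []).append(s)
        codon_hits[(s.gene_id, s.codon_number)] = (
            codon_hits.get((s.gene_id, s.codon_number), 0) + 1
        )
    rows = []
    for (gene_id, label), subs in sorted(by_label.items()):
        alt = tot = 0
        for s in subs:
            col = gen.matrix[:, s.site_index]
            called = col != MISSING
            alt += int(col[called].sum())
            tot = max(tot, int(2 * called.sum()))
        freq = alt / tot if tot else 0.0
        if freq > 1.0:
            log.warning("%s %s: pooled frequency >1 clamped", gene_id, label)
            freq = 1.0
        shares = any(codon_hits[(s.gene_id, s.codon_number)] > 1 for s in subs)
        if shares:
            log.info("%s %s: co-occurring variants in one codon", gene_id, label)
        rows.append(
            AAFrequency(
                gene_id=gene_id,
                label=label,
                frequency=freq,
                alt_alleles=alt,
                total_alleles=tot,
                n_variants=len(subs),
                reported=freq > min_report,
                shares_codon=shares,
            )
        )
    return rows


def fisher_two_sided_p(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p by probability ordering, exactly.

    Sums hypergeometric probabilities of all tables with the observed
    margins whose point probability does not exceed the observed one.
    The comparison uses exact integer weights C(r1,x)C(r2,c1-x), so
    ties are resolved exactly rather than to floating-point tolerance.
    """
    from fractions import Fraction
    from math import comb

    r1, r2, c1 = a + b, c + d, a + c
    lo, hi = max(0, c1 - r2), min(r1, c1)
    weights = [comb(r1, x) * comb(r2, c1 - x) for x in range(lo, hi + 1)]
    obs = weights[a - lo]
    num = sum(w for w in weights if w <= obs)
    return float(Fraction(num, comb(r1 + r2, c1)))


def _fisher_2x2(table: np.ndarray, locus: str) -> AssociationResult:
    t = np.asarray(table, dtype=np.int64)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("need a 2x2 table of non-negative counts")
    degenerate = bool((t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any())
    if degenerate:
        log.info("%s: zero margin, p = 1 by convention", locus)
        p = 1.0
        odds = float("nan")
    else:
        p = fisher_two_sided_p(int(t[0, 0]), int(t[0, 1]), int(t[1, 0]), int(t[1, 1]))
        with np.errstate(divide="ignore", invalid="ignore"):
            odds = (
                float(t[0, 0] * t[1, 1] / (t[0, 1] * t[1, 0]))
                if t[0, 1] * t[1, 0] > 0
                else float("inf") if t[0, 0] * t[1, 1] > 0 else float("nan")
            )
    with np.errstate(divide="ignore", invalid="ignore"):
        f_alive = t[0, 0] / max(t[0].sum(), 1)
        f_dead = t[1, 0] / max(t[1].sum(), 1)
    direction = 0 if f_alive == f_dead else (1 if f_alive > f_dead else -1)
    return AssociationResult(
        locus=locus,
        table=t,
        p_value=float(p),
        odds_ratio=float(odds),
        direction=direction,
        degenerate=degenerate,
    )


def fisher_snp_association(
    alt_alive: int, ref_alive: int, alt_dead: int, ref_dead: int, locus: str = ""
) -> AssociationResult:
    """Two-sided Fisher exact test on allele counts (alt/ref x alive/dead).

    Uses the probability-ordering definition of the two-sided p-value:
    the sum of hypergeometric probabilities of all tables with the same
    margins that are no more probable than the observed one.
    """
    return _fisher_2x2(
        [[alt_alive, ref_alive], [alt_dead, ref_dead]], locus or "snp"
    )


def fisher_cnv_association(
    carriers_alive: int,
    n_alive: int,
    carriers_dead: int,
    n_dead: int,
    locus: str = "",
    min_cohort: int = 5,
) -> AssociationResult | None:
    """Fisher exact test on CNV carrier status (carrier/non x alive/dead).

    Cohorts with fewer than ``min_cohort`` samples in either arm are
    excluded from testing (returns ``None``, logged).
    """
    if n_alive < min_cohort or n_dead < min_cohort:
        log.info(
            "%s: cohort below %d samples (alive=%d, dead=%d), test skipped",
            locus or "cnv", min_cohort, n_alive, n_dead,
        )
        return None
    if carriers_alive > n_alive or carriers_dead > n_dead:
        raise ValueError("carrier count exceeds cohort size")
    return _fisher_2x2(
        [
            [carriers_alive, n_alive - carriers_alive],
            [carriers_dead, n_dead - carriers_dead],
        ],
        locus or "cnv",
    )


def cnv_class_association(
    classes_alive: dict[int, int],
    classes_dead: dict[int, int],
    locus: str = "",
    n_permutations: int = 10_000,
    seed: int = 0,
) -> float:
    """Secondary test over copy-number classes (r x 2 table).

    Monte-Carlo permutation p-value for independence of the copy-number
    class distribution and outcome, using the chi-square statistic as
    the ordering criterion. The primary carrier-status Fisher test is
    :func:`fisher_cnv_association`; this one retains the full class
    distribution at the cost of a simulated null.
    """
    keys = sorted(set(classes_alive) | set(classes_dead))
    table = np.array(
        [[classes_alive.get(k, 0) for k in keys], [classes_dead.get(k, 0) for k in keys]],
        dtype=np.int64,
    )
    if table.sum() == 0 or len(keys) < 2:
        return 1.0

    def stat(t):
        rs = t.sum(axis=1, keepdims=True)
        cs = t.sum(axis=0, keepdims=True)
        e = rs * cs / t.sum()
        with np.errstate(divide="ignore", invalid="ignore"):
            x = (t - e) ** 2 / e
        return np.nansum(x)

    obs = stat(table)
    labels = np.repeat([0, 1], table.sum(axis=1))
    values = np.concatenate([np.repeat(keys, table[0]), np.repeat(keys, table[1])])
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_permutations):
        perm = rng.permutation(values)
        t = np.array(
            [
                [int((perm[labels == 0] == k).sum()) for k in keys],
                [int((perm[labels == 1] == k).sum()) for k in keys],
            ]
        )
        hits += stat(t) >= obs - 1e-12
    return (hits + 1) / (n_permutations + 1)


def bh_adjust(p_values: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (reported alongside raw p)."""
    return stats.false_discovery_control(np.asarray(p_values, dtype=np.float64))
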