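"""Variant-table parsing, the post-calling filter cascade, and effect annotation.

Variant calls from haploid evolved clones arrive as per-cohort VCFs (one
per caller).  Before any hotspot analysis they pass through a cascade
mirroring standard short-read post-processing:

1. **Hard site filters** — per-type thresholds on the caller's site
   annotations.  SNPs are failed for QUAL < 30, QD < 2, MQ < 40,
   FS > 60, SOR > 4, MQRankSum < -12.5 or ReadPosRankSum < -8; indels
   for QD < 2, QUAL < 30, FS > 200 or ReadPosRankSum < -20.  All
   comparisons are strict, so a value exactly at a threshold passes.
2. **Per-sample masking** — a sample call is marked missing when its
   read depth is below 4, the allelic depth of the second most common
   allele exceeds 4, or the second/first allelic-depth ratio exceeds
   0.2 (cross-contamination and ambiguous-support guard).
3. **Cohort filters** — sites are removed for mean depth across samples
   below 10, total depth above 20,000, QUAL below 20, MQ below 40, and
   degenerate frequency (AF > 0.99 or AC = 0), with AF/AC recomputed
   over unmasked, non-parental samples after masking.
4. **Parental subtraction** — any variant carried (unmasked) by a
   parental control sample is removed: it predates selection.

A record missing an annotation required by an active rule fails that
rule (fail-closed) and the failure is logged in the audit trail.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from Bio.Seq import Seq

__all__ = [
    "SNP_HARD_RULES",
    "INDEL_HARD_RULES",
    "SampleCall",
    "VariantRecord",
    "VariantTable",
    "GeneModel",
    "EffectAnnotation",
    "parse_variant_table",
    "apply_hard_site_filters",
    "mask_sample_calls",
    "apply_cohort_filters",
    "run_filter_cascade",
    "annotate_effects",
    "audit_frame",
]

# (key, operator, threshold): a record is FAILED when `value op threshold`
SNP_HARD_RULES = {
    "QUAL": ("<", 30.0),
    "QD": ("<", 2.0),
    "MQ": ("<", 40.0),
    "FS": (">", 60.0),
    "SOR": (">", 4.0),
    "MQRankSum": ("<", -12.5),
    "ReadPosRankSum": ("<", -8.0),
}
INDEL_HARD_RULES = {
    "QD": ("<", 2.0),
    "QUAL": ("<", 30.0),
    "FS": (">", 200.0),
    "ReadPosRankSum": ("<", -20.0),
}

_VALID_OPS = {"<", ">"}

EFFECT_CLASSES = (
    "synonymous",
    "missense",
    "stop_gained",
    "start_lost",
    "frameshift",
    "inframe_indel",
    "upstream",
    "intergenic",
)


@dataclass
class SampleCall:
    """One sample's genotype at one site (haploid: gt in {0, 1, None})."""

    sample_id: str
    gt: int | None
    dp: int | None
    ad: tuple[int, ...]  # per-allele depths, reference first
    masked: bool = False


@dataclass
class EffectAnnotation:
    gene_id: str | None
    effect_class: str
    protein_change: str | None = None  # e.g. "R110G"

    def __post_init__(self) -> None:
        if self.effect_class not in EFFECT_CLASSES:
            raise ValueError(f"unknown effect class {self.effect_class!r}")


@dataclass
class VariantRecord:
    """One site x alternate allele with its caller annotations and calls."""

    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    qual: float | None
    annotations: dict[str, float] = field(default_factory=dict)
    calls: dict[str, SampleCall] = field(default_factory=dict)
    filter_status: tuple[str, ...] = ()  # () == pass
    effect: EffectAnnotation | None = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.ref == self.alt:
            raise ValueError(f"ref == alt at {self.chrom}:{self.pos}")

    @property
    def variant_type(self) -> str:
        return "indel" if len(self.ref) != len(self.alt) else "snp"

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def passes(self) -> bool:
        return not self.filter_status

    def carriers(self, exclude: set[str] | frozenset[str] = frozenset()) -> list[str]:
        """Samples carrying the alternate allele, unmasked."""
        return [
            s
            for s, c in self.calls.items()
            if c.gt == 1 and not c.masked and s not in exclude
        ]


@dataclass
class VariantTable:
    """Ordered variant records plus the cohort's sample roster."""

    records: list[VariantRecord]
    samples: list[str]
    caller: str | None = None

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def passing(self) -> "VariantTable":
        """Table restricted to records with an empty filter status."""
        return VariantTable(
            [r for r in self.records if r.passes], list(self.samples), self.caller
        )


@dataclass(frozen=True)
class GeneModel:
    """Intronless-friendly gene model: CDS intervals plus a promoter window."""

    gene_id: str
    chrom: str
    strand: str  # "+" | "-"
    cds: tuple[tuple[int, int], ...]  # 0-based half-open, ascending
    promoter_window_bp: int = 500

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        ivs = tuple(tuple(iv) for iv in self.cds)
        object.__setattr__(self, "cds", ivs)
        for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
            if e1 > s2:
                raise ValueError(f"{self.gene_id}: CDS intervals overlap or unsorted")
        if self.cds_length % 3 != 0:
            raise ValueError(f"{self.gene_id}: CDS length not divisible by 3")

    @property
    def cds_length(self) -> int:
        return sum(e - s for s, e in self.cds)

    @property
    def span(self) -> tuple[int, int]:
        return self.cds[0][0], self.cds[-1][1]

    def promoter_interval(self) -> tuple[int, int]:
        """0-based half-open window immediately upstream of the TSS."""
        s, e = self.span
        if self.strand == "+":
            return max(0, s - self.promoter_window_bp), s
        return e, e + self.promoter_window_bp

    def contains_cds(self, pos0: int) -> bool:
        return any(s <= pos0 < e for s, e in self.cds)

    def cds_offset(self, pos0: int) -> int:
        """Offset of a genomic position within the coding sequence (5'->3')."""
        off = 0
        for s, e in self.cds:
            if s <= pos0 < e:
                off += pos0 - s
                break
            off += e - s
        else:
            raise ValueError(f"{pos0} not in CDS of {self.gene_id}")
        if self.strand == "+":
            return off
        return self.cds_length - 1 - off


# ---------------------------------------------------------------------------
# parsing


def parse_variant_table(
    path, reference: dict[str, str] | None = None, caller: str | None = None
) -> VariantTable:
    """Read a VCF (v4.2, FORMAT GT:DP:AD) into a :class:`VariantTable`.

    Multi-allelic sites are split into one record per alternate allele;
    the full per-allele AD vector is kept on every split record so that
    "second most common allele" masking still sees all alleles.  INFO
    keys that are absent are simply not recorded.  Contigs not present
    in ``reference`` (when given) are kept with a warning.
    """
    import pysam

    table = VariantTable(records=[], samples=[], caller=caller)
    try:
        vf = pysam.VariantFile(str(path))
    except (OSError, ValueError) as exc:
        raise ValueError(f"cannot parse VCF {path}: {exc}") from exc
    with vf:
        table.samples = list(vf.header.samples)
        seen_unknown: set[str] = set()
        for rec in vf:
            if reference is not None and rec.chrom not in reference:
                if rec.chrom not in seen_unknown:
                    warnings.warn(
                        f"contig {rec.chrom!r} not in reference; kept", stacklevel=2
                    )
                    seen_unknown.add(rec.chrom)
            alts = rec.alts or ()
            for ai, alt in enumerate(alts):
                annotations: dict[str, float] = {}
                for key in (
                    "QD",
                    "MQ",
                    "FS",
                    "SOR",
                    "MQRankSum",
                    "ReadPosRankSum",
                    "DP",
                    "AF",
                    "AC",
                ):
                    if key in rec.info:
                        val = rec.info[key]
                        if isinstance(val, tuple):
                            val = val[ai] if ai < len(val) else val[0]
                        if val is not None:
                            annotations[key] = float(val)
                calls = {}
                for sample in table.samples:
                    sc = rec.samples[sample]
                    gt_tuple = sc.get("GT")
                    allele = gt_tuple[0] if gt_tuple else None
                    gt = None if allele is None else (1 if allele == ai + 1 else 0)
                    dp = sc.get("DP")
                    ad = sc.get("AD")
                    ad_t = tuple(int(x) for x in ad if x is not None) if ad else ()
                    calls[sample] = SampleCall(sample, gt, dp, ad_t)
                table.records.append(
                    VariantRecord(
                        chrom=rec.chrom,
                        pos=rec.pos,
                        ref=rec.ref,
                        alt=alt,
                        qual=rec.qual,
                        annotations=annotations,
                        calls=calls,
                    )
                )
    return table


# ---------------------------------------------------------------------------
# filters


def _rule_value(record: VariantRecord, key: str) -> float | None:
    if key == "QUAL":
        return record.qual
    return record.annotations.get(key)


def apply_hard_site_filters(
    table: VariantTable,
    snp_rules: dict = SNP_HARD_RULES,
    indel_rules: dict = INDEL_HARD_RULES,
    audit: list | None = None,
) -> VariantTable:
    """Mark each record with the hard-filter rules it fails.

    No records are deleted; ``filter_status`` lists failing rule names
    (empty = pass).  A record missing an annotation that an active rule
    needs fails that rule (fail-closed).  Idempotent.
    """
    for rules in (snp_rules, indel_rules):
        for key, (op, _thr) in rules.items():
            if op not in _VALID_OPS:
                raise ValueError(f"unknown comparison {op!r} for rule {key}")
    out_records = []
    for rec in table.records:
        rules = snp_rules if rec.variant_type == "snp" else indel_rules
        failed = []
        for key, (op, thr) in rules.items():
            val = _rule_value(rec, key)
            if val is None:
                failed.append(key)
                if audit is not None:
                    audit.append(
                        _audit_row(rec, "hard_filter", key, "fail-closed (missing)")
                    )
                continue
            if (op == "<" and val < thr) or (op == ">" and val > thr):
                failed.append(key)
                if audit is not None:
                    audit.append(_audit_row(rec, "hard_filter", key, "fail"))
        out_records.append(replace(rec, filter_status=tuple(failed)))
    return VariantTable(out_records, list(table.samples), table.caller)


def mask_sample_calls(
    table: VariantTable,
    min_dp: int = 4,
    max_second_ad: int = 4,
    max_ad_ratio: float = 0.2,
    audit: list | None = None,
) -> VariantTable:
    """Mask sample calls with low depth or ambiguous allele support.

    A call is masked (treated as missing downstream) iff dp < ``min_dp``,
    the second-largest AD exceeds ``max_second_ad``, or the ratio of the
    second-largest to the largest AD exceeds ``max_ad_ratio``.
    Comparisons are strict, so boundary values are kept.  Calls whose AD
    vector is all zero despite dp > 0 are masked and logged.
    """
    out_records = []
    for rec in table.records:
        new_calls = {}
        for sample, call in rec.calls.items():
            masked = False
            reason = None
            dp = call.dp if call.dp is not None else 0
            ads = sorted(call.ad, reverse=True)
            ad1 = ads[0] if ads else 0
            ad2 = ads[1] if len(ads) > 1 else 0
            if dp < min_dp:
                masked, reason = True, "low-dp"
            elif ad1 == 0 and dp > 0:
                masked, reason = True, "ad-all-zero"
            elif ad2 > max_second_ad:
                masked, reason = True, "second-ad"
            elif ad1 > 0 and ad2 / ad1 > max_ad_ratio:
                masked, reason = True, "ad-ratio"
            if masked and audit is not None:
                audit.append(_audit_row(rec, "sample_mask", reason, f"mask:{sample}"))
            new_calls[sample] = replace(call, masked=masked)
        out_records.append(replace(rec, calls=new_calls))
    return VariantTable(out_records, list(table.samples), table.caller)


def _recompute_af_ac(rec: VariantRecord, parental: frozenset[str]) -> tuple[float, int]:
    ac = 0
    n_called = 0
    for sample, call in rec.calls.items():
        if sample in parental or call.masked or call.gt is None:
            continue
        n_called += 1
        if call.gt == 1:
            ac += 1
    af = ac / n_called if n_called else 0.0
    return af, ac


def apply_cohort_filters(
    table: VariantTable,
    parental_sample_ids,
    min_mean_dp: float = 10.0,
    max_total_dp: float = 20000.0,
    min_qual: float = 20.0,
    min_mq: float = 40.0,
    max_af: float = 0.99,
    audit: list | None = None,
) -> VariantTable:
    """Remove sites failing cohort-level criteria, then subtract parental.

    AF and AC are recomputed over unmasked, non-parental samples with
    non-missing genotypes (masking must have been applied).  A record is
    removed when: mean read depth across all samples < ``min_mean_dp``;
    total read depth (INFO DP, else the sum of sample depths)
    > ``max_total_dp``; QUAL < ``min_qual``; MQ < ``min_mq``;
    AF > ``max_af`` or AC = 0; or any parental sample carries the
    alternate allele unmasked.  Removal reasons go to the audit trail.
    The recomputed AF/AC are stored on surviving records (the caller's
    INFO values, if any, are overwritten at this stage).
    """
    parental = frozenset(parental_sample_ids)
    unknown = parental - set(table.samples)
    if unknown:
        raise KeyError(f"parental samples not in table: {sorted(unknown)}")
    kept = []
    for rec in table.records:
        af, ac = _recompute_af_ac(rec, parental)
        reasons = []
        dps = [c.dp for c in rec.calls.values() if c.dp is not None]
        mean_dp = float(np.mean(dps)) if dps else 0.0
        total_dp = rec.annotations.get("DP", float(sum(dps)))
        if mean_dp < min_mean_dp:
            reasons.append("mean-depth")
        if total_dp > max_total_dp:
            reasons.append("total-depth")
        if rec.qual is None or rec.qual < min_qual:
            reasons.append("qual")
        mq = rec.annotations.get("MQ")
        if mq is None or mq < min_mq:
            reasons.append("mq")
        if af > max_af or ac == 0:
            reasons.append("frequency")
        if any(
            c.gt == 1 and not c.masked
            for s, c in rec.calls.items()
            if s in parental
        ):
            reasons.append("parental")
        if reasons:
            if audit is not None:
                for r in reasons:
                    audit.append(_audit_row(rec, "cohort_filter", r, "remove"))
            continue
        new_annotations = dict(rec.annotations)
        new_annotations["AF"] = af
        new_annotations["AC"] = float(ac)
        kept.append(replace(rec, annotations=new_annotations))
    return VariantTable(kept, list(table.samples), table.caller)


def run_filter_cascade(
    table: VariantTable,
    parental_sample_ids,
    audit: list | None = None,
) -> VariantTable:
    """Full post-calling cascade: hard filters, masking, cohort filters.

    Records failing hard site filters are dropped before cohort
    statistics are computed, matching the order in which the study's
    pipeline applied them.
    """
    marked = apply_hard_site_filters(table, audit=audit)
    surviving = marked.passing()
    masked = mask_sample_calls(surviving, audit=audit)
    return apply_cohort_filters(masked, parental_sample_ids, audit=audit)


# ---------------------------------------------------------------------------
# effect annotation


def _codon_at(gene: GeneModel, reference: dict[str, str], codon_index: int) -> str:
    seq = "".join(reference[gene.chrom][s:e] for s, e in gene.cds)
    if gene.strand == "-":
        seq = str(Seq(seq).reverse_complement())
    return seq[3 * codon_index : 3 * codon_index + 3]


def _classify_cds_snp(
    gene: GeneModel, reference: dict[str, str], pos0: int, ref: str, alt: str
) -> EffectAnnotation:
    offset = gene.cds_offset(pos0)
    codon_index = offset // 3
    within = offset % 3
    codon = _codon_at(gene, reference, codon_index)
    ref_base, alt_base = ref, alt
    if gene.strand == "-":
        ref_base = str(Seq(ref).reverse_complement())
        alt_base = str(Seq(alt).reverse_complement())
    if codon[within] != ref_base:
        raise ValueError(
            f"reference mismatch in {gene.gene_id} codon {codon_index + 1}: "
            f"codon {codon} vs ref allele {ref_base}"
        )
    new_codon = codon[:within] + alt_base + codon[within + 1 :]
    aa_ref = str(Seq(codon).translate())
    aa_alt = str(Seq(new_codon).translate())
    residue = codon_index + 1
    change = f"{aa_ref}{residue}{aa_alt}"
    if codon_index == 0 and aa_ref == "M" and aa_alt != "M":
        return EffectAnnotation(gene.gene_id, "start_lost", change)
    if aa_alt == "*" and aa_ref != "*":
        return EffectAnnotation(gene.gene_id, "stop_gained", change)
    if aa_ref == aa_alt:
        return EffectAnnotation(gene.gene_id, "synonymous", change)
    return EffectAnnotation(gene.gene_id, "missense", change)


def annotate_effects(
    table: VariantTable,
    gene_models,
    reference: dict[str, str],
    audit: list | None = None,
) -> VariantTable:
    """Assign a coding-effect annotation to every record.

    SNPs inside a CDS are classified by codon translation before/after
    (synonymous, missense, stop_gained, or start_lost when codon 1 loses
    its methionine); CDS indels are frameshift when the length change is
    not a multiple of 3, else inframe_indel; variants in the promoter
    window upstream of the TSS are ``upstream``; everything else is
    ``intergenic``.  Minus-strand genes are handled by reverse
    complement, and protein changes use 1-based residue numbering.  A
    record whose ref allele disagrees with the reference sequence gets
    no annotation, an audit entry, and processing continues.
    """
    genes = list(gene_models)
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    out_records = []
    for rec in table.records:
        pos0 = rec.pos - 1
        effect = EffectAnnotation(None, "intergenic")
        try:
            chrom_seq = reference.get(rec.chrom)
            if chrom_seq is not None and rec.variant_type == "snp":
                if chrom_seq[pos0 : pos0 + len(rec.ref)] != rec.ref:
                    raise ValueError(
                        f"ref allele {rec.ref} disagrees with reference at "
                        f"{rec.chrom}:{rec.pos}"
                    )
            for gene in by_chrom.get(rec.chrom, []):
                if gene.contains_cds(pos0):
                    if rec.variant_type == "snp":
                        effect = _classify_cds_snp(
                            gene, reference, pos0, rec.ref, rec.alt
                        )
                    else:
                        delta = abs(len(rec.ref) - len(rec.alt))
                        cls = "frameshift" if delta % 3 else "inframe_indel"
                        effect = EffectAnnotation(gene.gene_id, cls)
                    break
                ps, pe = gene.promoter_interval()
                if ps <= pos0 < pe:
                    effect = EffectAnnotation(gene.gene_id, "upstream")
                    break
        except ValueError as exc:
            if audit is not None:
                audit.append(_audit_row(rec, "annotation", "ref-mismatch", str(exc)))
            out_records.append(replace(rec, effect=None))
            continue
        out_records.append(replace(rec, effect=effect))
    return VariantTable(out_records, list(table.samples), table.caller)


# ---------------------------------------------------------------------------
# audit trail


def _audit_row(rec: VariantRecord, stage: str, rule: str | None, action: str) -> dict:
    return {
        "chrom": rec.chrom,
        "pos": rec.pos,
        "ref": rec.ref,
        "alt": rec.alt,
        "stage": stage,
        "rule": rule,
        "action": action,
    }


def audit_frame(audit: list) -> pd.DataFrame:
    """Audit entries as a DataFrame (variant key, stage, rule, action)."""
    cols = ["chrom", "pos", "ref", "alt", "stage", "rule", "action"]
    return pd.DataFrame(audit, columns=cols)
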