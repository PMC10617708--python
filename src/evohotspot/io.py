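"""File formats: FASTA, GFF3 (intronless subset), VCF v4.2, TSV, truth JSON.

All on-disk coordinates follow each format's convention (GFF3 and VCF
1-based inclusive, BED 0-based half-open); in-memory gene models and
windows are 0-based half-open throughout the package.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .cnv import CNVSegment
from .variants import GeneModel, VariantTable

__all__ = [
    "write_fasta",
    "read_fasta",
    "write_gff3",
    "read_gff3",
    "write_vcf",
    "write_truth_json",
    "write_manifest",
    "read_manifest",
    "write_cnv_bed",
]


def write_fasta(sequences: dict, path) -> None:
    records = [
        SeqRecord(Seq(seq), id=chrom, description="") for chrom, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path) -> dict:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_gff3(genes, path) -> None:
    """Write gene models as GFF3 gene + CDS features (1-based inclusive)."""
    lines = ["##gff-version 3"]
    for g in genes:
        s, e = g.span
        attrs = f"ID={g.gene_id};promoter_window={g.promoter_window_bp}"
        lines.append(
            "\t".join(
                [g.chrom, "evohotspot", "gene", str(s + 1), str(e), ".", g.strand, ".", attrs]
            )
        )
        for cs, ce in g.cds:
            lines.append(
                "\t".join(
                    [
                        g.chrom,
                        "evohotspot",
                        "CDS",
                        str(cs + 1),
                        str(ce),
                        ".",
                        g.strand,
                        "0",
                        f"Parent={g.gene_id}",
                    ]
                )
            )
    Path(path).write_text("\n".join(lines) + "\n")


def read_gff3(path, default_promoter_window: int = 500) -> list[GeneModel]:
    """Read the intronless GFF3 subset written by :func:`write_gff3`."""
    genes: dict[str, dict] = {}
    order: list[str] = []
    for raw in Path(path).read_text().splitlines():
        if not raw or raw.startswith("#"):
            continue
        fields = raw.split("\t")
        if len(fields) != 9:
            raise ValueError(f"malformed GFF3 line: {raw!r}")
        chrom, _, ftype, start, end, _, strand, _, attrs = fields
        attr = dict(
            kv.split("=", 1) for kv in attrs.rstrip(";").split(";") if "=" in kv
        )
        if ftype == "gene":
            gid = attr["ID"]
            genes[gid] = {
                "chrom": chrom,
                "strand": strand,
                "cds": [],
                "promoter": int(attr.get("promoter_window", default_promoter_window)),
            }
            order.append(gid)
        elif ftype == "CDS":
            gid = attr["Parent"]
            genes[gid]["cds"].append((int(start) - 1, int(end)))
    return [
        GeneModel(
            gene_id=gid,
            chrom=g["chrom"],
            strand=g["strand"],
            cds=tuple(sorted(g["cds"])),
            promoter_window_bp=g["promoter"],
        )
        for gid, g in ((gid, genes[gid]) for gid in order)
    ]


def write_vcf(table: VariantTable, path, contig_lengths: dict | None = None) -> None:
    """Write a VariantTable as VCF v4.2 with FORMAT GT:DP:AD.

    Failing records carry their rule names in FILTER; passing records
    get PASS.  AD is projected to (ref, alt) for each record.
    """
    import pysam

    header = pysam.VariantHeader()
    contigs = contig_lengths or {}
    seen = {r.chrom for r in table.records}
    for chrom in sorted(seen | set(contigs)):
        header.contigs.add(chrom, length=contigs.get(chrom))
    for name in ("QD", "MQ", "FS", "SOR", "MQRankSum", "ReadPosRankSum"):
        header.info.add(name, 1, "Float", f"{name} site annotation")
    header.info.add("AF", "A", "Float", "Alternate allele frequency")
    header.info.add("DP", 1, "Integer", "Total read depth across samples")
    header.info.add("AC", "A", "Integer", "Alternate allele count")
    header.formats.add("GT", 1, "String", "Genotype (haploid)")
    header.formats.add("DP", 1, "Integer", "Sample read depth")
    header.formats.add("AD", "R", "Integer", "Per-allele read depths")
    filters = sorted(
        {rule for rec in table.records for rule in rec.filter_status}
    )
    for rule in filters:
        header.filters.add(rule, None, None, f"failed {rule} hard filter")
    for sample in table.samples:
        header.add_sample(sample)
    with pysam.VariantFile(str(path), "w", header=header) as vf:
        for rec in table.records:
            out = vf.new_record(
                contig=rec.chrom,
                start=rec.pos - 1,
                stop=rec.pos - 1 + len(rec.ref),
                alleles=(rec.ref, rec.alt),
                qual=rec.qual,
            )
            for key, val in rec.annotations.items():
                if key in ("DP", "AC"):
                    out.info[key] = int(round(val))
                else:
                    out.info[key] = float(val)
            if rec.filter_status:
                for rule in rec.filter_status:
                    out.filter.add(rule)
            else:
                out.filter.add("PASS")
            for sample in table.samples:
                call = rec.calls.get(sample)
                if call is None:
                    continue
                sc = out.samples[sample]
                sc["GT"] = (None,) if (call.masked or call.gt is None) else (call.gt,)
                if call.dp is not None:
                    sc["DP"] = call.dp
                if call.ad:
                    ad = call.ad if len(call.ad) == 2 else (call.ad + (0, 0))[:2]
                    sc["AD"] = tuple(int(x) for x in ad)
            vf.write(out)


def write_truth_json(truth, path) -> None:
    """Serialize a TruthSet (config included) as JSON."""

    def variant(v):
        return None if v is None else dataclasses.asdict(v)

    payload = {
        "config": dataclasses.asdict(truth.config),
        "mutants": [
            {
                "mutant_id": m.mutant_id,
                "background": m.background,
                "preculture": m.preculture,
                "rho_status": m.rho_status,
                "causal": variant(m.causal),
                "background_variants": [variant(v) for v in m.background_variants],
            }
            for m in truth.mutants
        ],
        "parental_variants": {
            bg: [variant(v) for v in vs] for bg, vs in truth.parental_variants.items()
        },
        "cnv_plants": [list(c) for c in truth.cnv_plants],
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def write_manifest(truth, path) -> None:
    """Cohort manifest TSV: genome_id, background, preculture, rho_status."""
    pd.DataFrame(
        [
            (m.mutant_id, m.background, m.preculture, m.rho_status)
            for m in truth.mutants
        ],
        columns=["genome_id", "background", "preculture", "rho_status"],
    ).to_csv(path, sep="\t", index=False)


def read_manifest(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"genome_id", "background", "preculture"}
    if not required.issubset(df.columns):
        raise ValueError(f"manifest needs columns {sorted(required)}")
    return df


def write_cnv_bed(segments: list[CNVSegment], path) -> None:
    """CNV segments as BED: chrom, start, end, name, mean_normalized, direction."""
    lines = [
        "\t".join(
            [
                s.chrom,
                str(s.start),
                str(s.end),
                f"{s.direction}_{i + 1}",
                f"{s.mean_normalized:.3f}",
                s.direction,
            ]
        )
        for i, s in enumerate(segments)
    ]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))
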