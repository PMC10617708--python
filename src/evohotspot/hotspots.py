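"""Hotspot evidence: per-gene aggregation of filtered, annotated variants.

A resistance "hotspot" is a gene that accumulates many *distinct*
mutations across independently evolved genomes.  The number of unique
variants per gene separates a true mutational target from caller noise
far better than raw genome counts, because noise variants recur in few
genomes and rarely replicate across callers.  This module builds that
evidence: per-gene distinct-variant and genome counts, caller-
concordance sets (the upset-plot view), the per-genome mutated-gene
count distribution, preculture sharing diagnostics (mutants selected
from one preculture may share a pre-existing mutation and are not
independent origins), and the partition of a gene's distinct mutations
by genetic background.

Variant identity is nucleotide-level (chrom, pos, ref, alt).  A
protein-level rollup is provided separately: two adjacent nucleotide
changes that produce one amino-acid substitution collapse to a single
protein change there.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .variants import VariantTable

__all__ = [
    "HotspotSummary",
    "SharingRecord",
    "ConcordanceResult",
    "gene_hotspot_summary",
    "caller_concordance",
    "mutation_sharing_by_preculture",
    "partition_distinct_mutations_by_background",
    "protein_level_rollup",
]


@dataclass(frozen=True)
class HotspotSummary:
    gene_id: str
    n_distinct_variants: int
    n_genomes: int
    caller_set: frozenset[str]  # callers that detected >= 1 variant in the gene
    variant_genome_counts: tuple[tuple[tuple, int], ...]  # ((key, n_genomes), ...)


@dataclass(frozen=True)
class SharingRecord:
    preculture: str
    n_genomes: int
    n_unique_causal_mutations: int
    mutation_member_counts: tuple[tuple[tuple, int], ...]

    @property
    def shared_origin(self) -> bool:
        return self.n_unique_causal_mutations < self.n_genomes


@dataclass(frozen=True)
class ConcordanceResult:
    """Variant- and gene-level membership in {A only, B only, both}."""

    caller_a: str
    caller_b: str
    variants_a_only: frozenset
    variants_b_only: frozenset
    variants_both: frozenset
    genes_a_only: frozenset
    genes_b_only: frozenset
    genes_both: frozenset


def _iter_gene_records(table: VariantTable, parental: frozenset[str]):
    """(gene_id, variant key, carrier genomes) for genic records."""
    for rec in table.records:
        if rec.effect is None or rec.effect.gene_id is None:
            continue
        carriers = rec.carriers(exclude=parental)
        if carriers:
            yield rec.effect.gene_id, rec.key, carriers


def gene_hotspot_summary(
    tables: dict[str, VariantTable],
    parental_sample_ids=(),
) -> tuple[list[HotspotSummary], pd.Series]:
    """Aggregate per-gene hotspot evidence across caller tables.

    ``tables`` maps caller name -> filtered+annotated table.  Returns the
    per-gene summaries ranked by distinct-variant count (descending; ties
    broken by genome count then gene id) and a per-genome Series counting
    mutated genes (union over callers), i.e. the distribution of genes
    with variants per genome.
    """
    parental = frozenset(parental_sample_ids)
    gene_variants: dict[str, set] = {}
    gene_genomes: dict[str, set] = {}
    gene_callers: dict[str, set] = {}
    variant_genomes: dict[str, dict[tuple, set]] = {}
    genome_genes: dict[str, set] = {}
    for caller, table in tables.items():
        for gene_id, key, carriers in _iter_gene_records(table, parental):
            gene_variants.setdefault(gene_id, set()).add(key)
            gene_genomes.setdefault(gene_id, set()).update(carriers)
            gene_callers.setdefault(gene_id, set()).add(caller)
            variant_genomes.setdefault(gene_id, {}).setdefault(key, set()).update(
                carriers
            )
            for g in carriers:
                genome_genes.setdefault(g, set()).add(gene_id)
    summaries = [
        HotspotSummary(
            gene_id=g,
            n_distinct_variants=len(gene_variants[g]),
            n_genomes=len(gene_genomes[g]),
            caller_set=frozenset(gene_callers[g]),
            variant_genome_counts=tuple(
                sorted((k, len(v)) for k, v in variant_genomes[g].items())
            ),
        )
        for g in gene_variants
    ]
    summaries.sort(key=lambda s: (-s.n_distinct_variants, -s.n_genomes, s.gene_id))
    per_genome = pd.Series(
        {g: len(genes) for g, genes in genome_genes.items()}, dtype=int
    ).sort_index()
    per_genome.name = "n_mutated_genes"
    return summaries, per_genome


def caller_concordance(
    table_a: VariantTable, table_b: VariantTable, parental_sample_ids=()
) -> ConcordanceResult:
    """Partition detections between two callers run on the same cohort.

    Variant identity is (chrom, pos, ref, alt, genome).  Gene-level
    membership is the union of its variants' memberships, so a gene with
    one variant seen by both callers and another seen only by one
    appears in several sets, as in an upset plot.
    """
    parental = frozenset(parental_sample_ids)

    def detections(table):
        variants, genes = set(), {}
        for gene_id, key, carriers in _iter_gene_records(table, parental):
            for g in carriers:
                variants.add(key + (g,))
                genes.setdefault(gene_id, set()).add(key + (g,))
        return variants, genes

    va, ga = detections(table_a)
    vb, gb = detections(table_b)
    genes_a_only, genes_b_only, genes_both = set(), set(), set()
    for gene in set(ga) | set(gb):
        da, db = ga.get(gene, set()), gb.get(gene, set())
        if da - db:
            genes_a_only.add(gene)
        if db - da:
            genes_b_only.add(gene)
        if da & db:
            genes_both.add(gene)
    return ConcordanceResult(
        caller_a=table_a.caller or "A",
        caller_b=table_b.caller or "B",
        variants_a_only=frozenset(va - vb),
        variants_b_only=frozenset(vb - va),
        variants_both=frozenset(va & vb),
        genes_a_only=frozenset(genes_a_only),
        genes_b_only=frozenset(genes_b_only),
        genes_both=frozenset(genes_both),
    )


def exclusive_gene_sets(result: ConcordanceResult) -> dict[str, frozenset]:
    """Upset-style exclusive gene sets: a gene counts once, in 'both' if any
    of its variants was detected by both callers, else in its single-caller
    set.  The three sets are disjoint and their union is all mutated genes."""
    both = result.genes_both
    a_only = result.genes_a_only - both
    b_only = result.genes_b_only - both
    return {"a_only": frozenset(a_only - b_only),
            "b_only": frozenset(b_only - a_only),
            "both": frozenset(both | (a_only & b_only))}


def mutation_sharing_by_preculture(
    causal_assignments: dict[str, tuple | None],
    preculture_of: dict[str, str],
) -> list[SharingRecord]:
    """Per-preculture counts of genomes vs unique causal mutations.

    ``causal_assignments`` maps genome -> causal-variant key (or None
    when no causal mutation was identified); ``preculture_of`` maps
    genome -> preculture id.  A preculture whose unique-mutation count
    is below its genome count contains shared (non-independent) origins.
    Precultures with no genomes simply do not appear.
    """
    missing = set(causal_assignments) - set(preculture_of)
    if missing:
        raise KeyError(f"genomes missing from preculture manifest: {sorted(missing)}")
    per: dict[str, dict] = {}
    for genome, key in causal_assignments.items():
        pc = preculture_of[genome]
        entry = per.setdefault(pc, {"n": 0, "mutations": {}})
        entry["n"] += 1
        if key is not None:
            entry["mutations"][key] = entry["mutations"].get(key, 0) + 1
    return sorted(
        (
            SharingRecord(
                preculture=pc,
                n_genomes=entry["n"],
                n_unique_causal_mutations=len(entry["mutations"]),
                mutation_member_counts=tuple(sorted(entry["mutations"].items())),
            )
            for pc, entry in per.items()
        ),
        key=lambda r: r.preculture,
    )


def partition_distinct_mutations_by_background(
    tables,
    gene_id: str,
    background_of: dict[str, str],
    parental_sample_ids=(),
) -> tuple[frozenset, frozenset, frozenset]:
    """Split a gene's distinct mutations into (A-private, B-private, shared).

    ``tables`` is an iterable of annotated VariantTables (e.g. one per
    caller per background); mutations are keyed (pos, ref, alt) within
    ``gene_id`` and assigned to the backgrounds of the genomes that carry
    them.  The union of the three returned sets is the gene's full
    distinct-mutation catalogue, so their sizes always add to the
    distinct-union size.
    """
    backgrounds = sorted(set(background_of.values()))
    if len(backgrounds) > 2:
        raise ValueError(f"expected at most 2 backgrounds, got {backgrounds}")
    parental = frozenset(parental_sample_ids)
    carriers_by_mutation: dict[tuple, set] = {}
    for table in tables:
        for gid, key, carriers in _iter_gene_records(table, parental):
            if gid != gene_id:
                continue
            mut = key[1:]  # (pos, ref, alt)
            bgs = carriers_by_mutation.setdefault(mut, set())
            for g in carriers:
                if g not in background_of:
                    raise KeyError(f"genome {g!r} missing from background manifest")
                bgs.add(background_of[g])
    if not backgrounds:
        return frozenset(), frozenset(), frozenset()
    bg_a = backgrounds[0]
    private_a, private_b, shared = set(), set(), set()
    for mut, bgs in carriers_by_mutation.items():
        if len(bgs) == 2:
            shared.add(mut)
        elif bg_a in bgs:
            private_a.add(mut)
        else:
            private_b.add(mut)
    return frozenset(private_a), frozenset(private_b), frozenset(shared)


def protein_level_rollup(tables, gene_id: str, parental_sample_ids=()) -> pd.DataFrame:
    """Distinct amino-acid changes in a gene, with genome counts.

    Secondary view of the hotspot catalogue: nucleotide-level mutations
    sharing one protein change (e.g. two adjacent substitutions in the
    same codon) collapse to a single row.  Non-coding and frameshift
    records (no single-residue protein change) are grouped under their
    effect class.
    """
    rows: dict[tuple, set] = {}
    parental = frozenset(parental_sample_ids)
    for table in tables:
        for rec in table.records:
            if rec.effect is None or rec.effect.gene_id != gene_id:
                continue
            carriers = rec.carriers(exclude=parental)
            if not carriers:
                continue
            label = rec.effect.protein_change or rec.effect.effect_class
            rows.setdefault((label, rec.effect.effect_class), set()).update(carriers)
    out = pd.DataFrame(
        [
            {"protein_change": lab, "effect_class": cls, "n_genomes": len(gs)}
            for (lab, cls), gs in rows.items()
        ]
    )
    if len(out):
        out = out.sort_values(
            ["n_genomes", "protein_change"], ascending=[False, True]
        ).reset_index(drop=True)
    return out
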