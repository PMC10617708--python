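"""Generate a small synthetic resistance-evolution study and write its files.

Builds a two-chromosome reference with gene models, plants causal
loss-of-function mutations (90% in the hotspot gene FUR1) across two
backgrounds of haploid mutants, and writes FASTA/GFF3/VCF/TSV inputs for
the rest of the pipeline.
"""

from collections import Counter
from pathlib import Path

from evohotspot import io, simdata

out = Path("scratch/example_study")
out.mkdir(parents=True, exist_ok=True)

config = simdata.SimConfig(seed=42, n_mutants_per_background=40, n_precultures=8)
genome = simdata.generate_genome(config)
truth = simdata.simulate_cohort(genome, config)

io.write_fasta(genome.sequences, out / "reference.fa")
io.write_gff3(genome.genes, out / "genes.gff3")
io.write_manifest(truth, out / "manifest.tsv")
io.write_truth_json(truth, out / "truth.json")
lengths = {c: len(s) for c, s in genome.sequences.items()}
for name, profile in simdata.DEFAULT_CALLER_PROFILES.items():
    for bg in config.backgrounds:
        table = simdata.emit_caller_calls(truth, profile, background=bg)
        io.write_vcf(table, out / f"{name}_{bg}.vcf", lengths)

causal_genes = Counter(
    m.causal.gene_id if m.causal else "none" for m in truth.mutants
)
print(f"mutants simulated:        {len(truth.mutants)}")
print(f"causal genes:             {dict(causal_genes)}")
print(f"files written to:         {out}/")
# Most mutants carry their planted resistance mutation in FUR1; the rest
# have no identified causal gene, mimicking unexplained resistant clones.
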