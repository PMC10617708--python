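"""Run the post-calling filter cascade on one simulated caller table.

Hard site filters (QUAL/QD/MQ/FS/SOR/rank sums), per-sample masking
(depth and allele-balance rules) and cohort-level filters with parental
subtraction, with every action logged to an audit trail.
"""

from evohotspot import simdata, variants

config = simdata.SimConfig(seed=42, n_mutants_per_background=40, n_precultures=8)
genome = simdata.generate_genome(config)
truth = simdata.simulate_cohort(genome, config)
table = simdata.emit_caller_calls(
    truth, simdata.DEFAULT_CALLER_PROFILES["tolerant"], background="A"
)

audit: list = []
filtered = variants.run_filter_cascade(table, ["A_parent"], audit=audit)
annotated = variants.annotate_effects(filtered, genome.genes, genome.sequences)

log = variants.audit_frame(audit)
print(f"records in:               {len(table)}")
print(f"records surviving:        {len(filtered)}")
print("actions by stage:")
print(log.groupby(["stage", "rule"]).size().to_string())
# Hard filters remove low-confidence sites, masking blanks ambiguous
# sample calls, and cohort rules drop fixed/parental variants; what
# survives is the per-genome mutation catalogue used for hotspot calling.
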