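"""Screen a biased coverage track for copy-number variants.

A 15-kb amplification at copy ratio 5 is planted together with GC bias
and chromosome-end inflation; median-ratio GC correction plus per-half
LOWESS division flattens the biases while preserving the CNV.
"""

from evohotspot import cnv, simdata

plant = ("chr2", 60_000, 75_000, 5.0)
config = simdata.SimConfig(seed=11, cnv_plants=(plant,))
genome = simdata.generate_genome(config)
bias = simdata.BiasConfig(base_depth=60, gc_slope=1.2, end_ramp_factor=2.0)

track = simdata.simulate_coverage_track(genome, config, bias)
normalized = cnv.normalize_coverage(track)
segments = cnv.call_cnv_segments(normalized, amp_threshold=4.0, del_threshold=0.25)

print(f"windows analysed:          {len(normalized)}")
print(f"median normalized coverage: {normalized['normalized'].median():.3f}")
for s in segments:
    print(
        f"segment: {s.chrom}:{s.start}-{s.end}  {s.direction}  "
        f"mean normalized {s.mean_normalized:.2f} over {s.n_windows} windows"
    )
# The normalized median sits at 1; the only reported segment matches the
# planted amplification, despite the GC and end biases in the raw track.
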