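"""Classify junction reads against a two-donor event and compute the in-ex ratio.

Builds a tiny SJ.out.tab-style evidence list for the packaged GN[N/S]K event
and counts reads supporting each donor.  The in-ex ratio ranges from -1 (all
reads use the upstream donor, GN[N/S]K excluded) to +1 (all use the
downstream donor, GN[N/S]K included).
"""

from altdonor import JunctionEvidence, count_sample_junctions, gnnk_event

spec = gnnk_event()
print(f"event: {spec.gene_id} {spec.chrom}:{spec.sds1}/{spec.sds2} -> {spec.sas} "
      f"({spec.donor_offset} nt between donors)")

evidence = [
    JunctionEvidence(spec.chrom, spec.sds2, spec.sas, strand="+", unique_reads=7),  # inclusion
    JunctionEvidence(spec.chrom, spec.sds1, spec.sas, strand="+", unique_reads=3),  # exclusion
    JunctionEvidence(spec.chrom, spec.sds1, spec.sas + 50, strand="+", unique_reads=9),  # other
]
counts = count_sample_junctions(evidence, spec, sample_id="demo")
print(f"inclusion={counts.inclusion_reads} exclusion={counts.exclusion_reads} "
      f"in-ex ratio={counts.inex_ratio:+.3f}")
print("a positive ratio means the GN[N/S]K+ isoform dominates in this sample")
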