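"""Summarize the packaged 91-genome reference table.

Reproduces the panel-level composition statistics: genome sizes and G+C
contents of the 90 in-group Myxococcus/Corallococcus/Pyxidicoccus strains
(the Aggregicoccus outgroup is excluded).
"""

from markergauge import load_reference_metadata, summarize_metadata

table = load_reference_metadata()
s = summarize_metadata(table, exclude_outgroup=True).rounded()

print(f"in-group genomes: {s.n}")
print(f"genome size (Mbp): {s.size_min}-{s.size_max}, "
      f"mean {s.size_mean} +/- {s.size_sd}")
print(f"G+C content (%):   {s.gc_min}-{s.gc_max}, "
      f"mean {s.gc_mean} +/- {s.gc_sd}")
print(f"assembly levels:   {s.assembly_level_counts}")

# The size mean/sd characterize how large and variable these myxobacterial
# genomes are (about 10 Mbp, among the largest bacterial genomes); the
# narrow G+C band (~69-71%) is typical of the group.
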