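"""Amplify the gyrB marker in silico and trim to the comparison window.

Simulates one full-length marker gene carrying the primer annealing sites
at their anchoring positions, runs the PCR primer pair over it, and trims
the product to the fixed 966-bp window used for all identity comparisons.
"""

from markergauge import (DEFAULT_PRIMERS, MarkerSequence, PanelSpec,
                         find_primer_sites, generate_panel, in_silico_pcr,
                         trim_to_window)

panel = generate_panel(PanelSpec(n_species=1, strains_per_species=2,
                                 intra_sub_rate=0.0, seed=42))
gene = panel.genes[0]
print(f"gene {gene.strain_id}: {len(gene.sequence)} bp")

fwd_sites = find_primer_sites(gene.sequence, DEFAULT_PRIMERS.forward)
print(f"forward primer sites: {fwd_sites}")

amplicon = in_silico_pcr(gene.sequence, DEFAULT_PRIMERS,
                         strain_id=gene.strain_id)[0]
print(f"product: positions {amplicon.start}-{amplicon.end} "
      f"({amplicon.length} bp, strand {amplicon.strand})")

window = trim_to_window(MarkerSequence(gene.strain_id, "amplicon",
                                       amplicon.sequence))
print(f"comparison window: {len(window.sequence)} bp")

# The product spans gene positions 348-1426 (1,079 bp); dropping 113 bases
# from its 5' end leaves the 966-bp window that the species threshold is
# calibrated on.
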