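# Methods

## The problem and the approach

Species in the genera *Myxococcus*, *Corallococcus*, and *Pyxidicoccus*
are circumscribed genomically: two strains are conspecific when their
digital DNA–DNA hybridization (dDDH) is at least 70%. dDDH needs genome
assemblies; routine typing of isolates does not get them. The package
operationalizes a two-step substitute: (1) calibrate, on a reference panel
with both marker identities and dDDH values, a monotone curve
dDDH = f(identity) and invert it at 70% to obtain a marker identity
threshold; (2) type new isolates by comparing their marker sequence to the
panel at that threshold, falling back on phylogenetic placement where
identity alone is ambiguous.

The marker is a PCR fragment of *gyrB* (single copy, faster-evolving than
16S rRNA). The primer pair `Myxoco_gyrBF` (AGCAAGTTCGGCAACGG) /
`Myxoco_gyrBR` (AGCATCTTCTCGAAGCG) yields a 1,079-bp product spanning gene
positions 348–1,426; after trimming sequencing-quality margins the fixed
comparison unit is a 966-bp window.

## Conventions and parameter defaults

**Quality gate.** Completeness > 95% and contamination < 5%, both strict
inequalities and both configurable. The packaged reference table keeps all
90 in-group strains by default; one row (contamination 5.1%) nominally
violates the gate, so gating is opt-in rather than automatic.

**Composition statistics.** Assembly size counts every residue including
ambiguity codes; G+C is computed over unambiguous A/C/G/T only (a sequence
with no unambiguous base has undefined G+C). Reported summaries use the
sample (n−1) standard deviation and half-even rounding to 2 decimals.

**Primer matching.** IUPAC set-intersection compatibility, at most 2
mismatches per site, and an exact 3-base 3'-terminal block (all
configurable). These are conventional in-silico PCR settings: 3' mismatches
abort extension in practice, internal ones often do not.

**Window coordinates.** Only the product length (1,079) and the window
length (966) are fixed by the protocol; the cut positions inside the
product are a convention. The default window drops 113 bases from the
product 5' end and none from the 3' end, i.e. gene positions 461–1,426.
This reproduces the 966-bp length deterministically and is overridable via
`WindowSpec`. Windows reject inputs with more than 2% ambiguous bases.
Sanger reads are stripped of terminal ambiguity runs first and can be
located against a reference window by infix alignment instead of fixed
offsets.

**Identity.** Optimal pairwise global alignment under affine gaps
(match +2, mismatch −1, gap open −5, gap extend −1; a length-L gap costs
open + (L−1)·extend), then identity = matches / columns with terminal-gap
columns excluded and internal gap columns counted. Pairwise alignment
(rather than extraction from a joint MSA) keeps each value independent of
panel composition; against MSA-derived identities this can differ by
roughly 0.1–0.2 points. Among co-optimal alignments the aligner's first
(deterministic) alignment is used; the score, and hence identity in
practice, does not depend on that choice for the fixed-window comparisons
this package makes. Equal-length pairs take a gap-free shortcut whenever
the ungapped alignment already attains the optimal score.

**Welch's t.** The intra/inter identity comparison uses the
unequal-variance t-test: the two samples differ grossly in size and
spread, so the pooled-variance form would be miscalibrated.

**dDDH.** Imported matrices are authoritative: CSV input is symmetrized by
averaging when |a_ij − a_ji| ≤ 0.1 and rejected beyond that. The built-in
`approximate_ddh` is a deliberately simple fragment-mapping estimator
(1,020-bp fragments, 16-mer seeding, edit-distance infix alignment,
pooled identity over mapped fragments pushed through the packaged
calibration curve); it is *not* a GGDC replication — GGDC's formula 2
depends on BLAST HSP behavior and fitted GLM coefficients — and its
outputs always carry `source="approximated"`.

**Clustering rule.** The 70% criterion is pairwise; turning it into
species requires a grouping rule. Single-linkage connected components with
an inclusive boundary (≥ 70%) is the default: it reproduces group-style
assignments and makes any non-transitivity explicit in the partition's
`conflicts` list instead of hiding it. Complete linkage is available for
a stricter reading. Cluster labels are deterministic (ordered by smallest
member id).

**Calibration.** The exp3P parameterization is y = a·e^(b·x) + c.
Initialization sets c₀ slightly below min(y) and log-linearizes; five
perturbations of c₀ seed a multi-start, keeping the lowest SSE. All
unordered pairs enter unweighted. The inverse at a target dDDH is closed
form; inversion round-trips to < 10⁻⁶ on the fitted range. The
identity-vs-identity comparison (complete gene vs window) uses the linear
model, where the relationship genuinely is linear.

**Classification.** Threshold first, tree second: hits at or above the
threshold that agree on one species give `assigned`; no hit gives
`putative_new_species`; conflicting hits, or a best hit inside the panel's
declared intra/inter overlap interval, are resolved by neighbor-joining
placement of the query among the references on (100 − identity)/100
distances — the query takes the species of its smallest enclosing
species-pure reference cluster, else `ambiguous`. NJ (not maximum
likelihood) is the placement engine by design: at panel scale the
distances are nearly additive and NJ is exact on additive matrices.
Best-hit ties break by species majority, then lexicographic strain id, so
panel order never matters.

## The synthetic generator

`generate_panel` emulates the statistical structure of the real reference
panel, not its biology: one random root gene per panel (length drawn
uniformly from 2,448–2,466 bp, the observed range of complete *gyrB*
genes), species ancestors diverged from the root at `inter_sub_rate` per
site, strains diverged from their ancestor at `intra_sub_rate`, equal-rate
substitution with no rate heterogeneity or indels. Primer sites are
written at the anchoring positions and masked from mutation (a
`degrade_primers` mode unmasks them to exercise failure paths). dDDH is
generated by applying a planted monotone exp3p curve to realized gene
identities plus Gaussian noise (sd 1.0 by default), truncated to [0, 100].

Defaults: `intra_sub_rate = 0.003` and `inter_sub_rate = 0.05`, giving
expected pairwise window identities near 99.4% within species and near
90% between species — bracketing the threshold the way the real panel's
97.6–100% intra and 88.5–99.1% inter ranges do. The planted curve is
anchored at f(100) = 100 and f(98.6) = 70 with asymptote c = 20, so the
analytic identity threshold of simulated panels is 98.6% by construction
and unrelated genomes land near 20% dDDH, the right order of magnitude
for across-genus comparisons.

What passing tests on these panels show: the pipeline's machinery —
extraction geometry, identity computation, curve fitting and inversion,
clustering, classification — is correct on data whose ground truth is
known exactly. What they do not show: robustness to real-data features the
generator omits (indels and sequencing error in amplicons, rate variation
across sites, recombination, non-transitive dDDH structure, contaminated
assemblies). Those paths are exercised separately by targeted failure-mode
tests, not by the end-to-end recovery results.

## Problem sizes

The shipped tests and the acceptance script run at desk scale by choice:
panels of 8–30 species with 3–5 strains (32–150 genes), 966-bp windows,
ten 200-point calibration clouds, 200 alignment-oracle pairs of length
≤ 8, and one end-to-end run with 26 references and 8 queries. These sizes
make every stage's ground truth checkable exactly while keeping the whole
suite in the tens of seconds.

## Known limitations

- Identity values can differ slightly (≤ ~0.2 points) from MSA-derived
  pipelines because alignment is pairwise.
- `approximate_ddh` is a screening tool; its absolute scale is only as
  good as the packaged calibration curve, and it is asymmetric at the
  fragment-grid level (symmetric to a few points; average both directions
  if that matters).
- The exp3P fit is only as identifiable as the data's spread: two tight
  identity blobs constrain the crossing point well but the individual
  parameters (a, b, c) poorly.
- Bootstrap support uses plain column resampling with NJ rebuilds, which
  is not comparable to ultrafast-bootstrap values from ML trees.
- The window trim offsets within the amplicon are a documented convention;
  against externally trimmed data, set `WindowSpec` explicitly rather than
  relying on the default.
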