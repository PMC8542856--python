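"""In-silico PCR and marker extraction.

Locates degenerate-primer annealing sites under IUPAC-compatible matching,
pairs properly oriented sites into amplicons, trims amplicons to the fixed
comparison window, and pulls full-length marker genes out of assemblies by
k-mer-seeded homology search.

The default primer pair targets the gyrB gene of Myxococcus, Corallococcus
and Pyxidicoccus: with a full-length gene template carrying the annealing
sites at gene positions 348-364 and 1410-1426, the product spans positions
348-1426 (1,079 bp), and the default window keeps gene positions 461-1426
(966 bp; 113 bases trimmed from the amplicon 5' end).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import List, Literal, Optional, Sequence, Tuple

import edlib

from .sequences import IUPAC, UNAMBIGUOUS, bases_compatible, reverse_complement

Region = Literal["complete_gene", "amplicon", "window"]
Source = Literal["genome", "sanger"]


class MarkerAbsentError(ValueError):
    pass


class WindowError(ValueError):
    pass


@dataclass(frozen=True)
class PrimerPair:
    """A PCR primer pair; the reverse primer is given 5'->3' on the opposite strand."""

    name: str
    forward: str
    reverse: str
    max_mismatches: int = 2
    three_prime_exact: int = 3
    annealing_temp_c: Optional[float] = None

    def __post_init__(self) -> None:
        if not self.forward or not self.reverse:
            raise ValueError("primers must be non-empty")
        for p in (self.forward, self.reverse):
            bad = set(p.upper()) - set(IUPAC)
            if bad:
                raise ValueError(f"non-IUPAC characters in primer: {sorted(bad)}")
        if self.max_mismatches < 0 or self.three_prime_exact < 0:
            raise ValueError("mismatch policy must be non-negative")


#: The published gyrB primer pair (annealing at 63 degC).
DEFAULT_PRIMERS = PrimerPair(
    name="Myxoco_gyrB",
    forward="AGCAAGTTCGGCAACGG",
    reverse="AGCATCTTCTCGAAGCG",
    annealing_temp_c=63.0,
)


@dataclass(frozen=True)
class Amplicon:
    """A PCR product. Coordinates are 1-based inclusive on the template's
    forward strand; `sequence` is reported 5'->3' in amplicon orientation."""

    strain_id: str
    contig_id: str
    start: int
    end: int
    strand: str  # '+' or '-'
    sequence: str

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def __post_init__(self) -> None:
        if self.length != len(self.sequence):
            raise ValueError("amplicon length inconsistent with coordinates")


@dataclass(frozen=True)
class MarkerSequence:
    """A marker gene, amplicon, or fixed comparison window for one strain."""

    strain_id: str
    region: Region
    sequence: str
    source: Source = "genome"


@dataclass(frozen=True)
class WindowSpec:
    """Fixed comparison window cut out of an amplicon.

    `offset5` / `offset3` are the number of bases dropped from the 5' and
    3' ends; `length` is the resulting window size. The defaults reproduce
    the 966-bp window from the 1,079-bp product.
    """

    name: str = "default966"
    length: int = 966
    offset5: int = 113
    offset3: int = 0
    max_ambiguous_frac: float = 0.02


DEFAULT_WINDOW = WindowSpec()


def _site_matches(primer: str, site: str, max_mismatches: int, three_prime_exact: int
                  ) -> Optional[int]:
    """Mismatch count if `primer` (5'->3') matches `site` (same orientation)."""
    mism = 0
    n = len(primer)
    for k, (p, t) in enumerate(zip(primer, site)):
        if not bases_compatible(p, t):
            if k >= n - three_prime_exact:
                return None  # 3'-terminal block must match exactly
            mism += 1
            if mism > max_mismatches:
                return None
    return mism


def find_primer_sites(template: str, primer: str,
                      max_mismatches: int = 0, three_prime_exact: int = 0,
                      ) -> List[Tuple[int, str, int]]:
    """All annealing sites of `primer` on both strands of `template`.

    Returns (position, strand, mismatch_count) triples sorted by position,
    where position is the 1-based start of the site on the forward strand.
    Matching is IUPAC-compatible (set intersection) with at most
    `max_mismatches` mismatches outside an exact 3'-terminal block of
    `three_prime_exact` bases.
    """
    template = template.upper()
    primer = primer.upper()
    n, L = len(template), len(primer)
    if n < L:
        return []
    rc_view = reverse_complement(template)
    sites: List[Tuple[int, str, int]] = []
    for i in range(n - L + 1):
        m = _site_matches(primer, template[i:i + L], max_mismatches, three_prime_exact)
        if m is not None:
            sites.append((i + 1, "+", m))
        # reverse-strand site occupying forward positions i+1 .. i+L
        m = _site_matches(primer, rc_view[n - L - i:n - i], max_mismatches, three_prime_exact)
        if m is not None:
            sites.append((i + 1, "-", m))
    sites.sort(key=lambda s: (s[0], s[1]))
    return sites


def in_silico_pcr(template: str, pair: PrimerPair = DEFAULT_PRIMERS,
                  min_len: int = 100, max_len: int = 5000,
                  strain_id: str = "query", contig_id: str = "contig",
                  ) -> List[Amplicon]:
    """Enumerate PCR products of a primer pair on a template.

    A product requires a forward-primer site and a reverse-primer site in
    convergent orientation with product length within [min_len, max_len];
    the product includes both annealing regions. Multiple products are all
    returned with a "non-unique amplification" warning.
    """
    if min_len > max_len:
        raise ValueError("min_len must not exceed max_len")
    fwd = find_primer_sites(template, pair.forward, pair.max_mismatches, pair.three_prime_exact)
    rev = find_primer_sites(template, pair.reverse, pair.max_mismatches, pair.three_prime_exact)
    Lr = len(pair.reverse)
    Lf = len(pair.forward)
    products: List[Amplicon] = []
    # '+' products: forward primer on + strand, reverse primer on - strand.
    for fpos, fstrand, _ in fwd:
        for rpos, rstrand, _ in rev:
            if fstrand == "+" and rstrand == "-":
                start, end = fpos, rpos + Lr - 1
                if end > start and min_len <= end - start + 1 <= max_len:
                    products.append(Amplicon(strain_id, contig_id, start, end, "+",
                                             template[start - 1:end].upper()))
            elif fstrand == "-" and rstrand == "+":
                # roles swapped: product runs on the reverse strand
                start, end = rpos, fpos + Lf - 1
                if end > start and min_len <= end - start + 1 <= max_len:
                    products.append(Amplicon(strain_id, contig_id, start, end, "-",
                                             reverse_complement(template[start - 1:end].upper())))
    if len(products) > 1:
        warnings.warn(f"{strain_id}/{contig_id}: non-unique amplification "
                      f"({len(products)} products)", stacklevel=2)
    products.sort(key=lambda a: (a.start, a.strand))
    return products


def _strip_terminal_ambiguity(seq: str) -> str:
    lo, hi = 0, len(seq)
    while lo < hi and seq[lo] not in UNAMBIGUOUS:
        lo += 1
    while hi > lo and seq[hi - 1] not in UNAMBIGUOUS:
        hi -= 1
    return seq[lo:hi]


def trim_to_window(marker: MarkerSequence, window: WindowSpec = DEFAULT_WINDOW,
                   reference_window: Optional[str] = None) -> MarkerSequence:
    """Cut a marker down to the fixed comparison window.

    Inputs already of window length are returned unchanged (relabelled as
    region="window"). Genome-derived amplicons are cut at the configured
    offsets. Sanger reads are first stripped of leading/trailing ambiguity
    calls; when a `reference_window` is supplied the window is located by
    infix edit-distance alignment against it instead of fixed offsets.
    """
    seq = marker.sequence.upper()
    if len(seq) == window.length:
        trimmed = seq
    else:
        if marker.source == "sanger":
            seq = _strip_terminal_ambiguity(seq)
        if len(seq) < window.length:
            raise WindowError(
                f"{marker.strain_id}: input ({len(seq)} bp) shorter than window "
                f"({window.length} bp)")
        if marker.source == "sanger" and reference_window is not None:
            res = edlib.align(reference_window, seq, mode="HW", task="locations")
            start, end = res["locations"][0]
            mid = (start + end + 1) // 2
            lo = min(max(0, mid - window.length // 2), len(seq) - window.length)
            trimmed = seq[lo:lo + window.length]
        else:
            trimmed = seq[window.offset5:window.offset5 + window.length]
        if len(trimmed) < window.length:
            raise WindowError(
                f"{marker.strain_id}: only {len(trimmed)} bases left after trim offsets")
    ambiguous = [i + 1 for i, b in enumerate(trimmed) if b not in UNAMBIGUOUS]
    if len(ambiguous) > window.max_ambiguous_frac * window.length:
        shown = ", ".join(map(str, ambiguous[:20]))
        raise WindowError(
            f"{marker.strain_id}: {len(ambiguous)} ambiguous bases inside window "
            f"(positions {shown}{'...' if len(ambiguous) > 20 else ''})")
    return MarkerSequence(marker.strain_id, "window", trimmed, marker.source)


@dataclass(frozen=True)
class MarkerLocus:
    contig_index: int
    start: int          # 1-based inclusive, forward strand
    end: int
    strand: str
    identity: float     # percent vs the reference marker
    coverage: float     # locus length / reference length
    sequence: str       # coding orientation (reference orientation)


def _kmer_set(seq: str, k: int) -> set:
    return {seq[i:i + k] for i in range(len(seq) - k + 1)}


def extract_marker_by_homology(genome, reference_marker: str,
                               min_identity: float = 80.0,
                               min_coverage: float = 0.8,
                               seed_k: int = 16,
                               ) -> Tuple[MarkerSequence, List[MarkerLocus]]:
    """Find the marker gene in an assembly by homology to a reference copy.

    Seeds candidate regions with shared k-mers, refines each with infix
    edit-distance alignment of the reference against the contig, and keeps
    loci passing the identity/coverage gates. Returns the best locus as a
    complete-gene MarkerSequence in coding (reference) orientation plus all
    accepted loci; more than one accepted locus triggers a "multi-copy
    marker" warning, zero raises MarkerAbsentError.
    """
    ref = reference_marker.upper()
    if not ref:
        raise ValueError("empty reference marker")
    ref_kmers = _kmer_set(ref, seed_k)
    loci: List[MarkerLocus] = []
    for ci, contig in enumerate(genome.contigs):
        contig = contig.upper()
        for strand, view in (("+", contig), ("-", reverse_complement(contig))):
            if len(view) < seed_k or not (_kmer_set(view, seed_k) & ref_kmers):
                continue
            # masked re-search so tandem/multi-copy loci are all reported
            work = view
            for _ in range(8):
                res = edlib.align(ref, work, mode="HW", task="locations")
                if res["editDistance"] < 0 or not res["locations"]:
                    break
                s, e = res["locations"][0]
                locus_seq = view[s:e + 1]
                identity = 100.0 * (1.0 - res["editDistance"]
                                    / max(len(ref), len(locus_seq)))
                coverage = len(locus_seq) / len(ref)
                if identity < min_identity or coverage < min_coverage:
                    break
                if strand == "+":
                    start, end = s + 1, e + 1
                else:  # map back to forward-strand coordinates
                    start, end = len(contig) - e, len(contig) - s
                loci.append(MarkerLocus(ci, start, end, strand, identity,
                                        coverage, locus_seq))
                work = work[:s] + "#" * (e - s + 1) + work[e + 1:]
    if not loci:
        raise MarkerAbsentError(f"{genome.strain_id}: marker absent "
                                f"(no locus >= {min_identity}% identity)")
    loci.sort(key=lambda l: (-l.identity, -l.coverage, l.contig_index, l.start))
    if len(loci) > 1:
        warnings.warn(f"{genome.strain_id}: multi-copy marker ({len(loci)} loci)",
                      stacklevel=2)
    best = loci[0]
    return MarkerSequence(genome.strain_id, "complete_gene", best.sequence, "genome"), loci
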