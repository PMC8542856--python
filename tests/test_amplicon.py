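"""Primer-site finding, in-silico PCR geometry, window trimming, and
homology extraction."""

import numpy as np
import pytest

from markergauge import (DEFAULT_PRIMERS, DEFAULT_WINDOW, MarkerAbsentError,
                         MarkerSequence, PrimerPair, WindowError,
                         extract_marker_by_homology, find_primer_sites,
                         in_silico_pcr, trim_to_window)
from markergauge.genomes import GenomeRecord
from markergauge.sequences import random_sequence, reverse_complement
from markergauge.synthetic import FORWARD_ANCHOR, REVERSE_ANCHOR

from conftest import brute_force_primer_sites


class TestFindPrimerSites:
    def test_exact_forward_site(self):
        sites = find_primer_sites("AAAACGTACGAAAA", "ACGTACG")
        assert sites == [(4, "+", 0)]

    def test_iupac_degenerate_base(self):
        # R matches A or G but not C/T
        for base in "AG":
            sites = find_primer_sites(f"TTT{base}CGTTT", "RCG")
            assert (4, "+", 0) in sites
        for base in "CT":
            sites = find_primer_sites(f"TTT{base}CGTTT", "RCG")
            assert all(s != (4, "+", 0) for s in sites)

    def test_strand_symmetry(self):
        template = "AAAACGTACGAAAA"
        flipped = reverse_complement(template)
        fwd = find_primer_sites(template, "ACGTACG")
        rev = find_primer_sites(flipped, "ACGTACG")
        assert len(fwd) == len(rev) == 1
        assert rev[0][1] == "-"

    def test_three_prime_exact_blocks_terminal_mismatch(self):
        template = "AAACGTACGAAA"
        # mismatch at primer 3' terminus: rejected even with budget
        assert find_primer_sites(template, "CGTACT", 2, 3) == []
        # same mismatch count at the 5' end: site accepted
        sites = find_primer_sites(template, "TGTACG", 2, 3)
        assert (4, "+", 1) in sites
        assert sites == brute_force_primer_sites(template, "TGTACG", 2, 3)

    def test_matches_brute_force_oracle(self, rng):
        primer = "ACGRTC"
        for _ in range(40):
            template = random_sequence(rng, int(rng.integers(6, 120)))
            got = find_primer_sites(template, primer, 1, 2)
            expected = brute_force_primer_sites(template, primer, 1, 2)
            assert got == expected


class TestInSilicoPcr:
    def test_anchored_gene_yields_1079_product(self, small_panel):
        gene = small_panel.genes[0]
        products = in_silico_pcr(gene.sequence, strain_id=gene.strain_id)
        assert len(products) == 1
        amp = products[0]
        assert (amp.start, amp.end, amp.length) == (FORWARD_ANCHOR, REVERSE_ANCHOR, 1079)
        assert amp.sequence.startswith(DEFAULT_PRIMERS.forward)
        assert amp.sequence.endswith(reverse_complement(DEFAULT_PRIMERS.reverse))

    def test_missing_reverse_site_gives_no_product(self):
        template = "T" * 30 + DEFAULT_PRIMERS.forward + "T" * 300
        assert in_silico_pcr(template) == []

    def test_toy_template_coordinates(self):
        pair = PrimerPair("toy", "ACGACG", "TTGGCC", max_mismatches=0,
                          three_prime_exact=0)
        # plant fwd at 11..16 and revcomp(rev)=GGCCAA at 41..46
        template = ("T" * 10 + "ACGACG" + "T" * 24 + "GGCCAA" + "T" * 10)
        products = in_silico_pcr(template, pair, min_len=10, max_len=100)
        assert [(p.start, p.end, p.strand) for p in products] == [(11, 46, "+")]
        assert products[0].sequence == template[10:46]

    def test_strand_equivalence(self, small_panel):
        gene = small_panel.genes[0].sequence
        fwd = in_silico_pcr(gene)[0]
        rev = in_silico_pcr(reverse_complement(gene))[0]
        assert rev.strand == "-"
        assert rev.sequence == fwd.sequence  # amplicon orientation is fixed

    def test_multiple_products_flagged(self):
        pair = PrimerPair("toy", "ACGACG", "TTGGCC", 0, 0)
        template = ("ACGACG" + "T" * 20 + "GGCCAA" + "T" * 20 + "GGCCAA")
        with pytest.warns(UserWarning, match="non-unique"):
            products = in_silico_pcr(template, pair, 10, 100)
        assert len(products) == 2


class TestTrimToWindow:
    def test_amplicon_to_966(self, small_panel):
        gene = small_panel.genes[0]
        amp = in_silico_pcr(gene.sequence, strain_id=gene.strain_id)[0]
        win = trim_to_window(MarkerSequence(gene.strain_id, "amplicon", amp.sequence))
        assert win.region == "window"
        assert len(win.sequence) == 966
        # the window is the gene substring at positions 461..1426
        assert win.sequence == gene.sequence[460:1426]

    def test_exact_window_returned_unchanged(self):
        seq = "ACGT" * 242 + "AC"  # 970 -> no; use exact length
        seq = ("ACGT" * 242)[:966]
        out = trim_to_window(MarkerSequence("q", "amplicon", seq))
        assert out.sequence == seq

    def test_short_fragment_rejected(self):
        with pytest.raises(WindowError, match="shorter than window"):
            trim_to_window(MarkerSequence("q", "amplicon", "A" * 900))

    def test_too_many_ambiguous_bases_rejected(self):
        # 30 Ns placed just after the 5' trim offset, inside the window
        seq = ("A" * 113 + "N" * 30 + "ACGT" * 250)[:1079]
        marker = MarkerSequence("q", "amplicon", seq)
        with pytest.raises(WindowError, match="ambiguous"):
            trim_to_window(marker)

    def test_sanger_read_ambiguity_stripped(self, small_panel):
        gene = small_panel.genes[0]
        amp = in_silico_pcr(gene.sequence)[0].sequence
        read = "NNNN" + amp + "NN"
        win = trim_to_window(MarkerSequence("iso1", "amplicon", read, source="sanger"))
        assert win.sequence == gene.sequence[460:1426]


class TestHomologyExtraction:
    def test_exact_copy_found(self, small_panel):
        ref = small_panel.genes[0].sequence
        genome = GenomeRecord("g", ["T" * 200 + ref + "G" * 150])
        marker, loci = extract_marker_by_homology(genome, ref)
        assert marker.sequence == ref
        assert loci[0].identity == pytest.approx(100.0)
        assert (loci[0].start, loci[0].end) == (201, 200 + len(ref))

    def test_reverse_complement_genome_gives_same_sequence(self, small_panel):
        ref = small_panel.genes[0].sequence
        contig = "T" * 200 + ref + "G" * 150
        fwd, _ = extract_marker_by_homology(GenomeRecord("g", [contig]), ref)
        rev, _ = extract_marker_by_homology(
            GenomeRecord("g", [reverse_complement(contig)]), ref)
        assert fwd.sequence == rev.sequence == ref

    def test_mutated_copy_identity(self, rng, small_panel):
        ref = small_panel.genes[0].sequence
        arr = np.array(list(ref))
        n_mut = int(0.05 * len(arr))
        pos = rng.choice(len(arr), size=n_mut, replace=False)
        for i in pos:
            arr[i] = rng.choice([b for b in "ACGT" if b != arr[i]])
        genome = GenomeRecord("g", ["A" * 100 + "".join(arr) + "C" * 100])
        _, loci = extract_marker_by_homology(genome, ref)
        assert loci[0].identity == pytest.approx(100 * (1 - n_mut / len(arr)), abs=0.5)

    def test_absent_marker_raises(self, rng):
        genome = GenomeRecord("g", [random_sequence(rng, 500)])
        with pytest.raises(MarkerAbsentError):
            extract_marker_by_homology(genome, random_sequence(rng, 300))

    def test_multi_copy_warns(self, small_panel):
        ref = small_panel.genes[0].sequence
        genome = GenomeRecord("g", ["T" * 50 + ref + "A" * 80 + ref + "G" * 50])
        with pytest.warns(UserWarning, match="multi-copy"):
            _, loci = extract_marker_by_homology(genome, ref)
        assert len(loci) == 2
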