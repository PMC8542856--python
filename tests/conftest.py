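"""Shared fixtures and independent oracles for the test suite.

The oracles here are deliberately naive re-derivations used to check the
library implementations: an exhaustive affine-gap alignment enumerator
(no dynamic programming reuse) and a brute-force primer-site scanner.
"""

from __future__ import annotations

import numpy as np
import pytest

from markergauge import PanelSpec, generate_panel, in_silico_pcr, trim_to_window
from markergauge.amplicon import MarkerSequence
from markergauge.sequences import IUPAC, reverse_complement


# ---------------------------------------------------------------- oracles

def exhaustive_align_score(a: str, b: str, match=2.0, mismatch=-1.0,
                           gap_open=-5.0, gap_extend=-1.0) -> float:
    """Maximum global alignment score by exhaustive path enumeration.

    Every monotone alignment path is scored independently; a gap run of
    length L costs gap_open + (L-1)*gap_extend. Exponential time — only
    for sequences of length <= 8.
    """

    def rec(i: int, j: int, last: str) -> float:
        if i == len(a) and j == len(b):
            return 0.0
        best = -np.inf
        if i < len(a) and j < len(b):
            s = match if a[i] == b[j] else mismatch
            best = max(best, s + rec(i + 1, j + 1, "M"))
        if i < len(a):  # gap in b
            s = gap_extend if last == "A" else gap_open
            best = max(best, s + rec(i + 1, j, "A"))
        if j < len(b):  # gap in a
            s = gap_extend if last == "B" else gap_open
            best = max(best, s + rec(i, j + 1, "B"))
        return best

    return rec(0, 0, "M")


def brute_force_primer_sites(template: str, primer: str, max_mismatches: int,
                             three_prime_exact: int):
    """All-offsets primer scan written independently of the library.

    For the reverse strand the site window is compared against the
    reverse complement of the primer, with the exact 3'-block therefore
    at the *left* end of the window.
    """
    template, primer = template.upper(), primer.upper()
    L = len(primer)
    rc_primer = reverse_complement(primer)
    hits = []
    for i in range(len(template) - L + 1):
        win = template[i:i + L]
        # forward: primer 3' end at right edge of the window
        ok = True
        mism = 0
        for k in range(L):
            if not (IUPAC[primer[k]] & IUPAC[win[k]]):
                if k >= L - three_prime_exact:
                    ok = False
                    break
                mism += 1
        if ok and mism <= max_mismatches:
            hits.append((i + 1, "+", mism))
        # reverse: compare window to revcomp(primer); primer position L-1-k
        ok = True
        mism = 0
        for k in range(L):
            if not (IUPAC[rc_primer[k]] & IUPAC[win[k]]):
                if (L - 1 - k) >= L - three_prime_exact:
                    ok = False
                    break
                mism += 1
        if ok and mism <= max_mismatches:
            hits.append((i + 1, "-", mism))
    hits.sort(key=lambda h: (h[0], h[1]))
    return hits


# ---------------------------------------------------------------- fixtures

@pytest.fixture(scope="session")
def small_panel():
    """4 species x 3 strains, fixed seed — shared across tests."""
    return generate_panel(PanelSpec(n_species=4, strains_per_species=3, seed=11))


@pytest.fixture(scope="session")
def small_windows(small_panel):
    """966-bp comparison windows extracted from the small panel by PCR."""
    wins = []
    for gene in small_panel.genes:
        amp = in_silico_pcr(gene.sequence, strain_id=gene.strain_id)[0]
        wins.append(trim_to_window(
            MarkerSequence(gene.strain_id, "amplicon", amp.sequence)))
    return wins


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
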