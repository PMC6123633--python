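"""Literal reference implementation of the NG86 pairwise dN/dS estimator.

Written directly from the published formulas, independently of the package's
implementation: its own genetic-code table, its own site counting and its own
pathway enumeration.  Used only as a test oracle.

Conventions (matching the estimator under test): at each codon position the
three possible changes are classified and changes to stop codons are dropped,
the position contributing one site split by the synonymous fraction among the
remaining changes; observed multi-codon differences are averaged over all
equally weighted orderings of the changed positions, excluding orderings that
pass through a stop codon (all orderings used if every one is blocked);
distances are Jukes-Cantor corrected, d = -(3/4) ln(1 - 4p/3).
"""

import math
from itertools import permutations

# standard nuclear genetic code, written out
CODE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}

BASES = "TCAG"


def syn_nonsyn_sites(codon):
    """(S, N) potential site counts for one codon."""
    s_total = 0.0
    for pos in range(3):
        syn = 0
        considered = 0
        for base in BASES:
            if base == codon[pos]:
                continue
            mutant = codon[:pos] + base + codon[pos + 1:]
            if CODE[mutant] == "*":
                continue
            considered += 1
            if CODE[mutant] == CODE[codon]:
                syn += 1
        if considered > 0:
            s_total += syn / considered
    return s_total, 3.0 - s_total


def observed_differences(c1, c2):
    """(Sd, Nd) observed synonymous/nonsynonymous differences for one pair."""
    positions = [i for i in range(3) if c1[i] != c2[i]]
    if not positions:
        return 0.0, 0.0

    def enumerate_paths(skip_stops):
        paths = []
        for order in permutations(positions):
            syn = 0
            non = 0
            current = c1
            blocked = False
            for pos in order:
                following = current[:pos] + c2[pos] + current[pos + 1:]
                if CODE[following] == "*" and skip_stops:
                    blocked = True
                    break
                if CODE[current] == CODE[following]:
                    syn += 1
                else:
                    non += 1
                current = following
            if not blocked:
                paths.append((syn, non))
        return paths

    paths = enumerate_paths(skip_stops=True)
    if not paths:
        paths = enumerate_paths(skip_stops=False)
    sd = sum(p[0] for p in paths) / len(paths)
    nd = sum(p[1] for p in paths) / len(paths)
    return sd, nd


def jc_distance(p):
    """Jukes-Cantor corrected distance; (inf, True) past saturation."""
    if p >= 0.75:
        return float("inf"), True
    if p <= 0.0:
        return 0.0, False
    return -0.75 * math.log(1.0 - (4.0 / 3.0) * p), False


def ng86_reference(seq1, seq2):
    """dN, dS, S, N per NG86 for two equal-length in-frame sequences.

    Codon columns containing a gap, an ambiguous base, or a stop codon in
    either sequence are skipped.
    """
    assert len(seq1) == len(seq2) and len(seq1) % 3 == 0
    S = N = Sd = Nd = 0.0
    for i in range(0, len(seq1), 3):
        c1 = seq1[i:i + 3].upper()
        c2 = seq2[i:i + 3].upper()
        usable = (
            c1 in CODE and c2 in CODE and CODE[c1] != "*" and CODE[c2] != "*"
        )
        if not usable:
            continue
        s1, n1 = syn_nonsyn_sites(c1)
        s2, n2 = syn_nonsyn_sites(c2)
        S += (s1 + s2) / 2.0
        N += (n1 + n2) / 2.0
        sd, nd = observed_differences(c1, c2)
        Sd += sd
        Nd += nd
    ps = Sd / S if S else 0.0
    pn = Nd / N if N else 0.0
    dS, _ = jc_distance(ps)
    dN, _ = jc_distance(pn)
    return dN, dS, S, N
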