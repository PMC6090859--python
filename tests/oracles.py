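"""Independent brute-force oracles used by the test suite.

These deliberately share no code with the package implementation: the genetic
code is taken straight from Biopython's table, sites are counted by literal
mutant enumeration, pathway averaging is done with exact Fractions over
explicitly generated orderings, and clade labels come from direct set
arithmetic.
"""

from fractions import Fraction
from itertools import permutations

from Bio.Data import CodonTable

_t = CodonTable.unambiguous_dna_by_id[1]
CODE = dict(_t.forward_table)
STOPS = set(_t.stop_codons)
SENSE = sorted(CODE)


def oracle_sites(codon):
    """Fractions of synonymous/nonsynonymous sites by mutant enumeration."""
    syn = Fraction(0)
    non = Fraction(0)
    for i in range(3):
        for b in "ACGT":
            if b == codon[i]:
                continue
            mut = codon[:i] + b + codon[i + 1 :]
            if mut in STOPS or CODE[mut] != CODE[codon]:
                non += Fraction(1, 3)
            else:
                syn += Fraction(1, 3)
    return syn, non


def oracle_diffs(ca, cb):
    """Pathway-averaged syn/nonsyn differences with exact arithmetic."""
    pos = [i for i in range(3) if ca[i] != cb[i]]
    if not pos:
        return Fraction(0), Fraction(0)
    stopfree, everything = [], []
    for order in permutations(pos):
        cur, syn, non, sawstop = ca, Fraction(0), Fraction(0), False
        for i in order:
            nxt = cur[:i] + cb[i] + cur[i + 1 :]
            if nxt in STOPS or cur in STOPS:
                sawstop = sawstop or nxt in STOPS
                non += 1
            elif CODE[cur] == CODE[nxt]:
                syn += 1
            else:
                non += 1
            cur = nxt
        everything.append((syn, non))
        if not sawstop:
            stopfree.append((syn, non))
    pool = stopfree or everything
    n = len(pool)
    return (
        sum(p[0] for p in pool) / n,
        sum(p[1] for p in pool) / n,
    )


def oracle_clade_label(group_species, species_types):
    """Clade label by direct set arithmetic over photosynthesis types."""
    present = {species_types[s] for s in group_species}
    order = [t for t in ("NVP", "C3", "CAM", "C4") if t in present]
    if len(order) == 1:
        return order[0] + "-only"
    return ":".join(order)
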