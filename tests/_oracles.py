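"""Brute-force reference implementations used only by the test suite.

These deliberately avoid the package's own machinery: motif scanning via
explicit IUPAC k-mer expansion and substring search, codon effects via a
direct genetic-code lookup, tandem runs via naive consecutive grouping.
"""

import itertools

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "D": "AGT", "Y": "CT", "W": "AT", "R": "AG", "H": "ACT",
}

#: (pattern, offset of the mutable base, base class)
MOTIF_PATTERNS = (("DGYW", 1, "GC"), ("WRCH", 2, "GC"), ("WA", 1, "AT"), ("TW", 0, "AT"))


def expand_pattern(pattern: str) -> set[str]:
    return {"".join(kmer) for kmer in itertools.product(*(IUPAC[ch] for ch in pattern))}


def brute_force_targets(seq: str) -> tuple[set[int], set[int]]:
    """Hotspot target positions by exhaustive k-mer comparison."""
    gc, at = set(), set()
    for pattern, offset, klass in MOTIF_PATTERNS:
        kmers = expand_pattern(pattern)
        k = len(pattern)
        for i in range(len(seq) - k + 1):
            if seq[i : i + k] in kmers:
                (gc if klass == "GC" else at).add(i + offset)
    return gc, at


# standard nuclear genetic code, written out independently of biopython
GENETIC_CODE = {}
_AA = (
    "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"
)
for _i, _codon in enumerate("".join(c) for c in itertools.product("TCAG", repeat=3)):
    GENETIC_CODE[_codon] = _AA[_i]


def codon_effect(codon: str, position: int, new_base: str) -> str:
    """SYN/NSYN by direct lookup for a single substitution in one codon."""
    mutant = codon[:position] + new_base + codon[position + 1 :]
    return "SYN" if GENETIC_CODE[codon] == GENETIC_CODE[mutant] else "NSYN"


def consecutive_runs(columns: set[int]) -> list[tuple[int, ...]]:
    """Maximal runs of >=2 consecutive integers, naive implementation."""
    runs = []
    for col in sorted(columns):
        if runs and col == runs[-1][-1] + 1:
            runs[-1].append(col)
        else:
            runs.append([col])
    return [tuple(r) for r in runs if len(r) >= 2]
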