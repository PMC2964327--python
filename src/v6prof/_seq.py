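"""Low-level nucleotide helpers shared across the pipeline.

IUPAC-aware comparison follows one asymmetric convention throughout: a
degenerate letter in a *primer* matches any base in its set, while an 'N' in
an observed *read* matches nothing (it is evidence of a failed base call, not
a wildcard).
"""

from __future__ import annotations

from Bio.Data.IUPACData import ambiguous_dna_values
from Bio.Seq import reverse_complement as _bio_revcomp

#: expansion of every IUPAC nucleotide letter into its base set
IUPAC_SETS: dict[str, frozenset[str]] = {
    letter: frozenset(bases) for letter, bases in ambiguous_dna_values.items()
}

_COMPLEMENT = str.maketrans("ACGTRYKMBVDHNacgtrykmbvdhn", "TGCAYRMKVBHDNtgcayrmkvbhdn")


def revcomp(seq: str) -> str:
    """Reverse complement, preserving IUPAC degeneracy codes."""
    if set(seq.upper()) <= set("ACGTN"):
        return _bio_revcomp(seq)
    return seq.translate(_COMPLEMENT)[::-1]


def iupac_match(pattern_char: str, read_char: str) -> bool:
    """Does one primer letter match one observed read base?

    The read base must be a concrete A/C/G/T inside the pattern letter's
    IUPAC set; an observed N never matches (counts as a mismatch).
    """
    if read_char == "N":
        return False
    try:
        return read_char in IUPAC_SETS[pattern_char]
    except KeyError:
        raise ValueError(f"invalid IUPAC letter in pattern: {pattern_char!r}") from None


def iupac_mismatches(pattern: str, text: str) -> int:
    """Count IUPAC-aware mismatches between equal-length strings."""
    if len(pattern) != len(text):
        raise ValueError(
            f"length mismatch: pattern {len(pattern)} vs text {len(text)}"
        )
    return sum(not iupac_match(p, t) for p, t in zip(pattern, text))
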