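"""Small DNA-string helpers shared across modules.

All sequence handling in the package is on uppercase DNA strings; RNA input
(miRNA mature sequences) is normalized to DNA at the boundary.
"""

from __future__ import annotations

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

DNA_ALPHABET = frozenset("ACGTN")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N-safe)."""
    return seq.translate(_COMPLEMENT)[::-1]


def rna_to_dna(seq: str) -> str:
    """Uppercase and convert U->T."""
    return seq.upper().replace("U", "T")


def find_all(haystack: str, needle: str) -> list[int]:
    """All (possibly overlapping) start offsets of ``needle`` in ``haystack``."""
    hits = []
    i = haystack.find(needle)
    while i != -1:
        hits.append(i)
        i = haystack.find(needle, i + 1)
    return hits
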