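"""Independent reference computations used by unit and acceptance tests.

These deliberately re-derive results through different mechanics than the
package (exhaustive enumeration, vectorized window comparisons) so that
agreement is evidence, not tautology.
"""

from __future__ import annotations

import numpy as np

_COMP = str.maketrans("ACGTN", "TGCAN")


def _rc(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def _occurrences(haystack: str, needle: str) -> list[int]:
    out, i = [], haystack.find(needle)
    while i != -1:
        out.append(i)
        i = haystack.find(needle, i + 1)
    return out


def brute_force_split(seq, genome, anchor_min=20, max_span=100_000, shift_max=5):
    """Enumerate every (orientation, breakpoint, occurrence, occurrence)
    combination of a two-segment exact placement and apply the back-splice
    selection rules verbatim: same chromosome, reversed order (acceptor
    upstream of donor end), span <= max_span. Placements related by a
    breakpoint shift (the read still matching both loci) are one placement;
    each is canonicalized by sliding to its most-negative valid shift.
    Returns the set of canonical (chrom, acceptor_start, donor_end).
    """
    placements = set()
    for oriented in (seq, _rc(seq)):
        n = len(oriented)
        for b in range(anchor_min, n - anchor_min + 1):
            for chrom, cseq in genome.chroms.items():
                occ5 = _occurrences(cseq, oriented[:b])
                if not occ5:
                    continue
                for p5 in occ5:
                    for p3 in _occurrences(cseq, oriented[b:]):
                        de, acc = p5 + b, p3
                        if acc < de and de - acc <= max_span:
                            s = 0
                            while s > -shift_max:
                                t = s - 1
                                if de + t < 0 or acc + t < 0:
                                    break
                                if cseq[de + t : de + s] == cseq[acc + t : acc + s]:
                                    s = t
                                else:
                                    break
                            placements.add((chrom, acc + s, de + s))
    return placements


def numpy_site_oracle(seq: str, m8: str) -> dict[str, int]:
    """Vectorized canonical-site scan anchored on the 6-mer seed core.

    A core occurrence is an 8mer when both the m8 base on its left and an A
    on its right match, a 7mer-m8 with only the left, a 7mer-A1 with only
    the right.
    """
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    n = len(arr)
    core = m8[1:]
    k = len(core)
    if n < k:
        return {"8mer": 0, "7mer-m8": 0, "7mer-A1": 0}
    hits = np.ones(n - k + 1, dtype=bool)
    for i, ch in enumerate(core.encode()):
        hits &= arr[i : n - k + 1 + i] == ch
    idx = np.flatnonzero(hits)
    m8_left = np.zeros(len(idx), dtype=bool)
    left_ok = idx > 0
    m8_left[left_ok] = arr[idx[left_ok] - 1] == ord(m8[0])
    a_right = np.zeros(len(idx), dtype=bool)
    right_ok = idx + k < n
    a_right[right_ok] = arr[idx[right_ok] + k] == ord("A")
    return {
        "8mer": int((m8_left & a_right).sum()),
        "7mer-m8": int((m8_left & ~a_right).sum()),
        "7mer-A1": int((~m8_left & a_right).sum()),
    }
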