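"""Back-spliced junction discovery by two-part split alignment.

Reads that fail full-length alignment (<=2 mismatches) are searched for an
exact two-segment decomposition in which the 5' read segment maps genomically
downstream of the 3' segment on the same chromosome, no more than 100 kb away
-- the signature of a back-splice. Candidate breakpoints are then shifted
(within +/-5 nt, wherever the read still matches both loci exactly) onto GT-AG
splice signals, which also fixes the junction strand; junctions are aggregated
per sample and candidates supported by >=2 independent (non-duplicate) reads
are called.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

from ._seq import find_all, revcomp
from .formats import MIN_DISCOVERY_READ_LEN, GenomeRef, ReadRecord

log = logging.getLogger(__name__)

DEFAULT_MAX_SPAN = 100_000
DEFAULT_ANCHOR_MIN = 20
DEFAULT_SHIFT_MAX = 5
DEFAULT_SIGNAL_WINDOW = 10

# Forward-genome flanks implied by each (signal, junction strand) pair.
# A minus-strand GT-AG intron reads CT...AC on the forward strand, crossed:
# the dinucleotide after donor_end is the reverse complement of the intron's
# 3' "AG", and the one before acceptor_start mirrors the 5' "GT".
_SIGNAL_FLANKS = {
    ("GT-AG", "+"): ("GT", "AG"),
    ("GT-AG", "-"): ("CT", "AC"),
    ("AT-AC", "+"): ("AT", "AC"),
    ("AT-AC", "-"): ("GT", "AT"),
}


@dataclass
class SplitAlignment:
    """An exact two-segment placement of one read, in back-spliced order."""

    read_id: str
    chrom: str
    orientation: str  # "+" if the read matched as given, "-" if its revcomp did
    break_offset: int  # read coordinate splitting 5' and 3' segments
    seg5_interval: tuple[int, int]  # genomic interval of the read's 5' segment
    seg3_interval: tuple[int, int]
    sequence: str = ""  # oriented read sequence (forward-genome frame)
    sample_id: str = "sample"

    @property
    def reversed_order(self) -> bool:
        return self.seg3_interval[0] < self.seg5_interval[1]

    @property
    def acceptor_start(self) -> int:
        return self.seg3_interval[0]

    @property
    def donor_end(self) -> int:
        return self.seg5_interval[1]

    @property
    def span(self) -> int:
        return self.donor_end - self.acceptor_start


@dataclass
class BackspliceJunction:
    """A donor -> upstream-acceptor joint on one chromosome.

    ``acceptor_start`` is the first exonic base of the back-spliced acceptor
    exon; ``donor_end`` is one past the last exonic base of the donor exon
    (0-based half-open, forward strand).
    """

    chrom: str
    strand: str
    acceptor_start: int
    donor_end: int
    signal_class: str = "other"  # GT-AG | AT-AC | other
    support: dict = field(default_factory=dict)  # sample_id -> read count

    def __post_init__(self) -> None:
        if not self.acceptor_start < self.donor_end:
            raise ValueError("back-splice requires acceptor_start < donor_end")

    @property
    def key(self) -> tuple:
        return (self.chrom, self.strand, self.acceptor_start, self.donor_end)

    @property
    def span(self) -> int:
        return self.donor_end - self.acceptor_start

    @property
    def junction_id(self) -> str:
        return f"{self.chrom}:{self.acceptor_start}-{self.donor_end}:{self.strand}"


# ---------------------------------------------------------------------------
# Linear prefilter
# ---------------------------------------------------------------------------


def collapse_duplicates(reads: Sequence[ReadRecord]) -> list[ReadRecord]:
    """PCR-duplicate removal: identical sequences collapse to one representative."""
    seen: dict[str, ReadRecord] = {}
    for r in reads:
        seen.setdefault(r.sequence, r)
    return list(seen.values())


def _full_length_placements(
    seq: str, genome: GenomeRef, max_mismatches: int
) -> list[tuple[str, int, str, int]]:
    """All (chrom, pos, orientation, n_mismatches) full-length placements of
    ``seq`` with <= ``max_mismatches`` substitutions (no gaps).

    Seed-and-verify: with k mismatches allowed, one of k+1 disjoint read
    segments must match exactly (pigeonhole), so exact hits of those segments
    enumerate every candidate offset.
    """
    n = len(seq)
    chunk = n // (max_mismatches + 1)
    placements = []
    seen = set()
    for orientation, oriented in (("+", seq), ("-", revcomp(seq))):
        for chrom, chrom_seq in genome.chroms.items():
            clen = len(chrom_seq)
            candidates = set()
            for i in range(max_mismatches + 1):
                lo = i * chunk
                seed = oriented[lo : lo + chunk]
                for hit in find_all(chrom_seq, seed):
                    pos = hit - lo
                    if 0 <= pos <= clen - n:
                        candidates.add(pos)
            for pos in candidates:
                window = chrom_seq[pos : pos + n]
                mm = sum(a != b for a, b in zip(oriented, window))
                if mm <= max_mismatches and (chrom, pos, orientation) not in seen:
                    seen.add((chrom, pos, orientation))
                    placements.append((chrom, pos, orientation, mm))
    return placements


@dataclass
class MappedRead:
    read_id: str
    sample_id: str
    chrom: str
    start: int
    end: int
    strand: str
    n_mismatches: int
    ambiguous: bool = False


def linear_prefilter(
    reads: Sequence[ReadRecord],
    genome: GenomeRef,
    max_mismatches: int = 2,
    collapse: bool = True,
) -> tuple[list[MappedRead], list[ReadRecord]]:
    """Split reads into a full-length-mappable set and an unmapped set.

    Duplicate sequences are collapsed first (PCR-duplicate removal); any read
    with a full-length placement at <= ``max_mismatches`` leaves circRNA
    discovery. Mapped reads are retained (best placement) for expression
    estimates; reads with several equally good placements are marked ambiguous.
    """
    unique = collapse_duplicates(reads) if collapse else list(reads)
    mapped: list[MappedRead] = []
    unmapped: list[ReadRecord] = []
    for r in unique:
        placements = _full_length_placements(r.sequence, genome, max_mismatches)
        if not placements:
            unmapped.append(r)
            continue
        best_mm = min(p[3] for p in placements)
        best = [p for p in placements if p[3] == best_mm]
        chrom, pos, orientation, mm = best[0]
        mapped.append(
            MappedRead(
                read_id=r.read_id,
                sample_id=r.sample_id,
                chrom=chrom,
                start=pos,
                end=pos + len(r.sequence),
                strand=orientation,
                n_mismatches=mm,
                ambiguous=len(best) > 1,
            )
        )
    return mapped, unmapped


# ---------------------------------------------------------------------------
# Split alignment
# ---------------------------------------------------------------------------


def _split_candidates_oriented(
    oriented: str,
    genome: GenomeRef,
    anchor_min: int,
    max_span: int,
) -> list[tuple[str, int, int, int]]:
    """(chrom, breakpoint, acceptor_start, donor_end) for every exact
    two-segment, reversed-order, same-chromosome placement of ``oriented``."""
    n = len(oriented)
    out = []
    for b in range(anchor_min, n - anchor_min + 1):
        seg5, seg3 = oriented[:b], oriented[b:]
        for chrom, chrom_seq in genome.chroms.items():
            occ5 = find_all(chrom_seq, seg5)
            if not occ5:
                continue
            occ3 = find_all(chrom_seq, seg3)
            for p5 in occ5:
                donor_end = p5 + b
                for p3 in occ3:
                    # reversed order: acceptor upstream of donor end
                    if p3 < donor_end and donor_end - p3 <= max_span:
                        out.append((chrom, b, p3, donor_end))
    return out


def _shift_validity(
    genome: GenomeRef, chrom: str, acceptor_start: int, donor_end: int, s: int
) -> bool:
    """True if moving the breakpoint by ``s`` leaves the read matching both
    loci exactly (the transferred bases must agree across the two loci)."""
    chrom_seq = genome.chroms[chrom]
    if s == 0:
        return True
    if s > 0:
        if donor_end + s > len(chrom_seq) or acceptor_start + s > len(chrom_seq):
            return False
        return chrom_seq[donor_end : donor_end + s] == chrom_seq[acceptor_start : acceptor_start + s]
    t = -s
    if donor_end - t < 0 or acceptor_start - t < 0:
        return False
    return chrom_seq[donor_end - t : donor_end] == chrom_seq[acceptor_start - t : acceptor_start]


def _canonical_junction(
    genome: GenomeRef, chrom: str, acceptor_start: int, donor_end: int, shift_max: int
) -> tuple[int, int]:
    """Canonical representative of the shift-equivalence class of a junction
    (minimal valid shift), used to group redundant breakpoints of one read."""
    s = 0
    while s > -shift_max and _shift_validity(genome, chrom, acceptor_start, donor_end, s - 1):
        s -= 1
    return (acceptor_start + s, donor_end + s)


def find_split_alignments(
    reads: Sequence[ReadRecord],
    genome: GenomeRef,
    anchor_min: int = DEFAULT_ANCHOR_MIN,
    max_span: int = DEFAULT_MAX_SPAN,
) -> list[SplitAlignment]:
    """Exact two-segment (no mismatch, no gap) back-splice placements.

    Each read is tried in both orientations; every breakpoint with both
    segments >= ``anchor_min`` matching the genome exactly is enumerated, and
    only same-chromosome, reversed-order, <= ``max_span`` pairs are kept.
    Reads whose surviving placements map to more than one genomic junction
    (beyond breakpoint-shift redundancy) are discarded as ambiguous.
    """
    out = []
    for r in reads:
        if len(r.sequence) < MIN_DISCOVERY_READ_LEN:
            continue
        per_junction: dict[tuple, tuple] = {}
        for orientation, oriented in (("+", r.sequence), ("-", revcomp(r.sequence))):
            for chrom, b, acc, de in _split_candidates_oriented(
                oriented, genome, anchor_min, max_span
            ):
                canon = (chrom, orientation) + _canonical_junction(
                    genome, chrom, acc, de, DEFAULT_SHIFT_MAX
                )
                per_junction.setdefault(canon, (chrom, orientation, b, acc, de, oriented))
        # A palindromic-ish read can yield the same junction from both
        # orientations; treat those as one placement.
        distinct = {(c[0],) + c[2:] for c in per_junction}
        if len(distinct) != 1:
            continue  # no placement, or ambiguous multi-placement
        chrom, orientation, b, acc, de, oriented = next(iter(per_junction.values()))
        out.append(
            SplitAlignment(
                read_id=r.read_id,
                chrom=chrom,
                orientation=orientation,
                break_offset=b,
                seg5_interval=(de - b, de),
                seg3_interval=(acc, acc + len(oriented) - b),
                sequence=oriented,
                sample_id=r.sample_id,
            )
        )
    return out


# ---------------------------------------------------------------------------
# Splice-signal refinement
# ---------------------------------------------------------------------------


def _signal_at(genome: GenomeRef, chrom: str, acceptor_start: int, donor_end: int):
    """(signal_class, strand) implied by the flanking dinucleotides, or None."""
    chrom_seq = genome.chroms[chrom]
    if donor_end + 2 > len(chrom_seq) or acceptor_start - 2 < 0:
        return None
    after = chrom_seq[donor_end : donor_end + 2]
    before = chrom_seq[acceptor_start - 2 : acceptor_start]
    for (signal, strand), (want_after, want_before) in _SIGNAL_FLANKS.items():
        if after == want_after and before == want_before:
            return signal, strand
    return None


def _flanks_contain_n(genome, chrom, acceptor_start, donor_end, window):
    chrom_seq = genome.chroms[chrom]
    donor_flank = chrom_seq[donor_end : donor_end + window]
    acceptor_flank = chrom_seq[max(0, acceptor_start - window) : acceptor_start]
    return "N" in donor_flank or "N" in acceptor_flank


def refine_splice_signal(
    aln: SplitAlignment,
    genome: GenomeRef,
    window: int = DEFAULT_SIGNAL_WINDOW,
    shift_max: int = DEFAULT_SHIFT_MAX,
) -> BackspliceJunction:
    """Slide the breakpoint onto a GT-AG (or, failing that, AT-AC) signal.

    Valid shifts are those for which the read still matches both loci exactly;
    the smallest |s| wins, ties broken toward negative s. Junctions whose
    flanking windows contain N, or with no signal at any valid shift, are
    classified ``other`` at the unshifted coordinates.
    """
    acc0, de0 = aln.acceptor_start, aln.donor_end
    if not aln.reversed_order:
        raise ValueError("refine_splice_signal expects a reversed-order alignment")
    if _flanks_contain_n(genome, aln.chrom, acc0, de0, window):
        return BackspliceJunction(aln.chrom, aln.orientation, acc0, de0, "other")

    shifts = sorted(range(-shift_max, shift_max + 1), key=lambda s: (abs(s), s))
    valid = [s for s in shifts if _shift_validity(genome, aln.chrom, acc0, de0, s)]
    for wanted in ("GT-AG", "AT-AC"):
        for s in valid:
            hit = _signal_at(genome, aln.chrom, acc0 + s, de0 + s)
            if hit is not None and hit[0] == wanted:
                return BackspliceJunction(aln.chrom, hit[1], acc0 + s, de0 + s, wanted)
    return BackspliceJunction(aln.chrom, aln.orientation, acc0, de0, "other")


# ---------------------------------------------------------------------------
# Candidate calling
# ---------------------------------------------------------------------------


def call_candidates(
    refined: Iterable[tuple[BackspliceJunction, str]],
    min_reads: int = 2,
) -> list[BackspliceJunction]:
    """Aggregate per-read junctions into candidates.

    ``refined`` yields (junction, sample_id) per supporting read (duplicates
    already collapsed upstream). Junctions supported by fewer than
    ``min_reads`` reads in every sample are dropped. Non-GT-AG candidates are
    retained, flagged by their signal_class, for diagnostics; the catalog
    stage excludes them.
    """
    grouped: dict[tuple, BackspliceJunction] = {}
    for junction, sample_id in refined:
        agg = grouped.setdefault(
            junction.key,
            BackspliceJunction(
                junction.chrom,
                junction.strand,
                junction.acceptor_start,
                junction.donor_end,
                junction.signal_class,
            ),
        )
        agg.support[sample_id] = agg.support.get(sample_id, 0) + 1
    return [
        j
        for j in grouped.values()
        if any(count >= min_reads for count in j.support.values())
    ]


def detect_junctions(
    reads: Sequence[ReadRecord],
    genome: GenomeRef,
    min_reads: int = 2,
    max_mismatches: int = 2,
    anchor_min: int = DEFAULT_ANCHOR_MIN,
    max_span: int = DEFAULT_MAX_SPAN,
) -> tuple[list[BackspliceJunction], list[MappedRead]]:
    """Full discovery pass: prefilter -> split-align -> refine -> call.

    Reads may mix samples (ReadRecord.sample_id); support is tallied per
    sample. Returns called candidates plus the linearly mapped reads (for
    expression estimation).
    """
    mapped: list[MappedRead] = []
    refined: list[tuple[BackspliceJunction, str]] = []
    for sample_id in sorted({r.sample_id for r in reads}):
        sample_reads = [r for r in reads if r.sample_id == sample_id]
        sample_mapped, unmapped = linear_prefilter(sample_reads, genome, max_mismatches)
        mapped.extend(sample_mapped)
        alignments = find_split_alignments(unmapped, genome, anchor_min, max_span)
        for aln in alignments:
            refined.append((refine_splice_signal(aln, genome), aln.sample_id))
    return call_candidates(refined, min_reads=min_reads), mapped


# ---------------------------------------------------------------------------
# Diagnostics
# ---------------------------------------------------------------------------


def dinucleotide_enrichment(
    candidates: Sequence[BackspliceJunction],
    genome: GenomeRef,
    window: int = DEFAULT_SIGNAL_WINDOW,
    min_support: int = 5,
) -> pd.DataFrame:
    """Dinucleotide frequencies at each offset of the intronic windows
    flanking candidate junctions (donor side and acceptor side), strand-aware,
    over candidates with >= ``min_support`` junction-spanning reads.

    For a GT-AG back-splice, offset 0 on the donor side reads GT and the last
    offset on the acceptor side reads AG.
    """
    rows = []
    kept = [c for c in candidates if sum(c.support.values()) >= min_support]
    counts: dict[tuple, dict[str, int]] = defaultdict(lambda: defaultdict(int))
    for c in kept:
        chrom_seq = genome.chroms[c.chrom]
        donor_flank = chrom_seq[c.donor_end : c.donor_end + window]
        acceptor_flank = chrom_seq[max(0, c.acceptor_start - window) : c.acceptor_start]
        if c.strand == "-":
            donor_flank, acceptor_flank = revcomp(acceptor_flank), revcomp(donor_flank)
        for side, flank in (("donor", donor_flank), ("acceptor", acceptor_flank)):
            for off in range(len(flank) - 1):
                counts[(side, off)][flank[off : off + 2]] += 1
    dinucs = [a + b for a in "ACGT" for b in "ACGT"]
    for (side, off), tallies in sorted(counts.items()):
        total = sum(tallies.values())
        row = {"side": side, "offset": off}
        for d in dinucs:
            row[d] = tallies.get(d, 0) / total if total else 0.0
        rows.append(row)
    return pd.DataFrame(rows, columns=["side", "offset"] + dinucs)
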