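"""Mate-read analyses around back-spliced junctions.

A true circle has no "outside": the mate of a junction-spanning read must map
within the circle, so mates mapping strictly beyond the acceptor or donor
betray a linear (trans-spliced) molecule. Mates also report on the circle's
interior -- whether the introns between circularized exons were spliced out
or retained -- and poly(A)-selected libraries provide an orthogonal test,
since circles lack poly(A) tails and should vanish from them.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from ._seq import revcomp
from .detect import _full_length_placements
from .formats import ExonModel, GenomeRef, ReadRecord
from .quantify import CircRNARecord, JunctionCounts, circle_probes, merge_intervals

log = logging.getLogger(__name__)

DEFAULT_MAX_CIRC_LEN = 400  # from the ~200-nt fragment length
DEFAULT_RETENTION_WINDOW = 200
SPLICE_WORD_HALF = 10

OUTSIDE_CATEGORIES = {"upstream_of_acceptor", "downstream_of_donor", "neighbor_exon"}


@dataclass
class MatePlacement:
    """Where the mate of one junction-spanning read landed."""

    junction_id: str
    read_id: str
    chrom: str
    start: int
    end: int
    category: str  # inside_circle | upstream_of_acceptor | downstream_of_donor | neighbor_exon | intron | other
    dist_acceptor: int  # signed, transcript-oriented; negative = upstream of the acceptor
    dist_donor: int  # signed; positive = downstream of the donor


def pair_reads(reads: Sequence[ReadRecord]) -> dict[str, dict[int, ReadRecord]]:
    """Group reads into fragments by id; raises on single-end data."""
    pairs: dict[str, dict[int, ReadRecord]] = {}
    paired = False
    for r in reads:
        if r.mate_index is not None:
            paired = True
            pairs.setdefault(r.fragment_id, {})[r.mate_index] = r
    if not paired:
        raise ValueError("paired-end data required: no /1 or /2 mate indices found")
    return pairs


def junction_spanning_pairs(
    record: CircRNARecord,
    pairs: dict[str, dict[int, ReadRecord]],
    genome: GenomeRef,
) -> list[tuple[ReadRecord, ReadRecord]]:
    """(junction read, mate) for every fragment with a junction-spanning end."""
    donor_probe, acceptor_probe = circle_probes(record.junction, genome, record.exon_model)
    word = donor_probe + acceptor_probe
    word_rc = revcomp(word)
    out = []
    for mates in pairs.values():
        for idx, other in ((1, 2), (2, 1)):
            r = mates.get(idx)
            m = mates.get(other)
            if r is None or m is None:
                continue
            if word in r.sequence or word_rc in r.sequence:
                out.append((r, m))
    return out


def _map_mate(mate: ReadRecord, genome: GenomeRef, max_mismatches: int = 2):
    """Unique-best contiguous placement of a mate, or None (same contract as
    the linear prefilter; ambiguous placements are discarded)."""
    placements = _full_length_placements(mate.sequence, genome, max_mismatches)
    if not placements:
        return None
    best_mm = min(p[3] for p in placements)
    best = [p for p in placements if p[3] == best_mm]
    if len(best) > 1:
        return None
    chrom, pos, _, _ = best[0]
    return chrom, pos, pos + len(mate.sequence)


def _categorize(
    record: CircRNARecord,
    chrom: str,
    start: int,
    end: int,
    gene_exons: list[tuple[int, int]] | None,
) -> str:
    j = record.junction
    if chrom != j.chrom:
        return "other"
    acc, de = j.acceptor_start, j.donor_end
    if acc <= start and end <= de:
        if gene_exons is not None:
            covered = sum(max(0, min(end, b) - max(start, a)) for a, b in gene_exons)
            if covered < end - start:  # part of the mate lies on intronic bases
                return "intron"
        return "inside_circle"
    if end <= acc or start >= de:
        if gene_exons is not None and any(start < b and a < end for a, b in gene_exons):
            return "neighbor_exon"
        left = end <= acc
        if j.strand == "+":
            return "upstream_of_acceptor" if left else "downstream_of_donor"
        return "downstream_of_donor" if left else "upstream_of_acceptor"
    return "other"  # straddles a junction boundary


def place_mates(
    record: CircRNARecord,
    pairs: dict[str, dict[int, ReadRecord]],
    genome: GenomeRef,
    models: Sequence[ExonModel] | None = None,
) -> list[MatePlacement]:
    """Map and categorize the mates of a junction's spanning reads."""
    gene_exons = None
    if models is not None:
        exons = [
            iv
            for m in models
            if m.gene_id == record.exon_model.gene_id and m.chrom == record.junction.chrom
            for iv in m.exons
        ]
        gene_exons = merge_intervals(exons) if exons else None
    j = record.junction
    out = []
    for _, mate in junction_spanning_pairs(record, pairs, genome):
        hit = _map_mate(mate, genome)
        if hit is None:
            continue
        chrom, start, end = hit
        category = _categorize(record, chrom, start, end, gene_exons)
        sign = 1 if j.strand == "+" else -1
        out.append(
            MatePlacement(
                junction_id=record.circ_id,
                read_id=mate.read_id,
                chrom=chrom,
                start=start,
                end=end,
                category=category,
                dist_acceptor=sign * (start - j.acceptor_start),
                dist_donor=sign * (end - j.donor_end),
            )
        )
    return out


# ---------------------------------------------------------------------------
# Trans-splicing discrimination
# ---------------------------------------------------------------------------


def trans_splice_test(
    records: Sequence[CircRNARecord],
    reads: Sequence[ReadRecord],
    genome: GenomeRef,
    models: Sequence[ExonModel] | None = None,
    max_len: int = DEFAULT_MAX_CIRC_LEN,
) -> pd.DataFrame:
    """Count outside-mapping mates for circles short enough to be informative.

    Only circRNAs with exonic length < ``max_len`` are considered (a mate
    ~200 nt away cannot escape a longer circle). Mates mapping strictly
    upstream of the acceptor or downstream of the donor (including those on
    neighboring exons) are trans-splicing evidence.
    """
    pairs = pair_reads(reads)
    rows = []
    for rec in records:
        if rec.exonic_length >= max_len:
            continue
        placements = place_mates(rec, pairs, genome, models)
        tally = {c: 0 for c in (
            "inside_circle", "intron", "upstream_of_acceptor",
            "downstream_of_donor", "neighbor_exon", "other",
        )}
        for p in placements:
            tally[p.category] += 1
        evidence = sum(tally[c] for c in OUTSIDE_CATEGORIES)
        rows.append(
            {"junction_id": rec.circ_id, "n_mates_mapped": len(placements),
             **tally, "trans_evidence": evidence}
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Intron retention inside circles
# ---------------------------------------------------------------------------


def _transcript_ordered_exons(model: ExonModel) -> list[tuple[int, int]]:
    return list(reversed(model.exons)) if model.strand == "-" else list(model.exons)


def _splice_words(
    model: ExonModel, genome: GenomeRef, half: int = SPLICE_WORD_HALF
) -> list[tuple[str, list[str]]]:
    """(spliced_word, retained_words) per internal splice site of the circle.

    Transcript-oriented: the spliced word joins the exon end to the next
    exon; retention is probed at both intron ends (exon|intron and
    intron|next exon). Probing both ends keeps the estimate unbiased: a
    fragment anchored on the back-splice junction can reach the spliced
    joint from either side of the circle, and the two retained words give
    the retained template the same two reachable configurations.
    """
    words = []
    exons = _transcript_ordered_exons(model)
    for (up, down) in zip(exons, exons[1:]):
        if model.strand == "+":
            exon_tail = genome.fetch(model.chrom, up[1] - half, up[1])
            next_exon = genome.fetch(model.chrom, down[0], down[0] + half)
            intron_head = genome.fetch(model.chrom, up[1], up[1] + half)
            intron_tail = genome.fetch(model.chrom, down[0] - half, down[0])
        else:
            exon_tail = genome.fetch(model.chrom, up[0], up[0] + half, "-")
            next_exon = genome.fetch(model.chrom, down[1] - half, down[1], "-")
            intron_head = genome.fetch(model.chrom, up[0] - half, up[0], "-")
            intron_tail = genome.fetch(model.chrom, down[1], down[1] + half, "-")
        words.append(
            (exon_tail + next_exon, [exon_tail + intron_head, intron_tail + next_exon])
        )
    return words


def intron_retention(
    records: Sequence[CircRNARecord],
    reads: Sequence[ReadRecord],
    genome: GenomeRef,
    window: int = DEFAULT_RETENTION_WINDOW,
) -> pd.DataFrame:
    """Estimate the retained fraction of introns inside circles.

    The mates of junction-spanning reads land inside the circle, within
    ~``window`` nt of the back-spliced boundaries for ~200-nt fragments.
    A mate overlapping an internal splice site is classified by the sequence
    that follows the exon end: the next exon (spliced) or the intron
    (retained). Retained fraction = intron mates / (intron + exon mates);
    NaN when no mate is informative.
    """
    pairs = pair_reads(reads)
    rows = []
    for rec in records:
        if len(rec.exon_model.exons) < 2:
            continue
        words = _splice_words(rec.exon_model, genome)
        n_exon = n_intron = 0
        for _, mate in junction_spanning_pairs(rec, pairs, genome):
            seqs = (mate.sequence, revcomp(mate.sequence))
            hit = None
            for spliced_word, retained_words in words:
                if any(w in s for w in retained_words for s in seqs):
                    hit = "intron"
                    break
                if any(spliced_word in s for s in seqs):
                    hit = "exon"
                    break
            if hit == "intron":
                n_intron += 1
            elif hit == "exon":
                n_exon += 1
        total = n_exon + n_intron
        rows.append(
            {
                "junction_id": rec.circ_id,
                "n_exon_mates": n_exon,
                "n_intron_mates": n_intron,
                "retained_fraction": (n_intron / total) if total else math.nan,
            }
        )
    return pd.DataFrame(rows)


def pooled_retention(table: pd.DataFrame) -> float:
    """Retention estimate pooled over junctions (NaN if uninformative)."""
    n_intron = table["n_intron_mates"].sum()
    total = n_intron + table["n_exon_mates"].sum()
    return (n_intron / total) if total else math.nan


# ---------------------------------------------------------------------------
# Poly(A) comparison
# ---------------------------------------------------------------------------


def polya_compare(
    records: Sequence[CircRNARecord],
    nonpolya_counts: dict[str, JunctionCounts],
    polya_counts: dict[str, JunctionCounts],
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Pair per-junction circular fractions between a non-poly(A)-selected
    and a poly(A)-selected library; junctions absent from both are excluded.

    Returns the paired table and summary counts of junctions detected
    (fraction > 0) in each library and in both.
    """
    rows = []
    for rec in records:
        non = nonpolya_counts.get(rec.circ_id)
        pol = polya_counts.get(rec.circ_id)
        f_non = non.fraction if non else 0.0
        f_pol = pol.fraction if pol else 0.0
        if f_non == 0.0 and f_pol == 0.0:
            continue
        rows.append(
            {
                "junction_id": rec.circ_id,
                "fraction_nonpolya": f_non,
                "fraction_polya": f_pol,
            }
        )
    table = pd.DataFrame(rows, columns=["junction_id", "fraction_nonpolya", "fraction_polya"])
    summary = {
        "detected_nonpolya": int((table["fraction_nonpolya"] > 0).sum()) if len(table) else 0,
        "detected_polya": int((table["fraction_polya"] > 0).sum()) if len(table) else 0,
        "detected_both": int(
            ((table["fraction_nonpolya"] > 0) & (table["fraction_polya"] > 0)).sum()
        )
        if len(table)
        else 0,
    }
    return table, summary
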