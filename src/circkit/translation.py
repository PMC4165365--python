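"""Translation assessment from ribosome-protected fragments (RPFs).

For each circRNA with annotated linear junctions at both splice sites, three
20-mer probes are built from spliced sequence (10 nt each side of a joint):
the circular junction, the donor's linear junction, and the acceptor's
linear junction. Counting probe-containing reads in an RPF library versus an
RNA-seq library asks whether ribosomes ever cross the circular junction; a
translated circle would yield circular-probe RPFs, an untranslated one only
linear-junction RPFs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from ._seq import find_all, revcomp
from .formats import ExonModel, GenomeRef, ReadRecord
from .quantify import CircRNARecord

log = logging.getLogger(__name__)

PROBE_HALF = 10


@dataclass
class JunctionProbeSet:
    circ_id: str
    circular_probe: str  # 10 nt each side of the back-splice
    linear_donor_probe: str  # across the donor's annotated linear junction
    linear_acceptor_probe: str  # across the acceptor's annotated linear junction
    paralog_risk: bool = False


def _transcript_ordered_exons(model: ExonModel) -> list[tuple[int, int]]:
    return list(reversed(model.exons)) if model.strand == "-" else list(model.exons)


def _exon_tail(genome: GenomeRef, model: ExonModel, exon, half: int) -> str:
    """Last ``half`` nt of an exon in transcript orientation."""
    a, b = exon
    if model.strand == "+":
        return genome.fetch(model.chrom, b - half, b)
    return genome.fetch(model.chrom, a, a + half, "-")


def _exon_head(genome: GenomeRef, model: ExonModel, exon, half: int) -> str:
    a, b = exon
    if model.strand == "+":
        return genome.fetch(model.chrom, a, a + half)
    return genome.fetch(model.chrom, b - half, b, "-")


def build_probes(
    record: CircRNARecord,
    models: Sequence[ExonModel],
    genome: GenomeRef,
    half: int = PROBE_HALF,
) -> JunctionProbeSet | None:
    """Probe set for one circRNA, or None when either splice site lacks an
    annotated linear partner exon (such circles leave the analysis)."""
    j = record.junction
    host = next(
        (
            m
            for m in models
            if m.chrom == j.chrom
            and m.strand == j.strand
            and any(a == j.acceptor_start for a, _ in m.exons)
            and any(b == j.donor_end for _, b in m.exons)
        ),
        None,
    )
    if host is None:
        return None
    exons = _transcript_ordered_exons(host)
    # transcript-order indices of the circle's first (acceptor) and last
    # (donor) exon; on the minus strand the acceptor sits at the genomic
    # high boundary of the junction interval
    if host.strand == "+":
        first = next(i for i, e in enumerate(exons) if e[0] == j.acceptor_start)
        last = next(i for i, e in enumerate(exons) if e[1] == j.donor_end)
    else:
        first = next(i for i, e in enumerate(exons) if e[1] == j.donor_end)
        last = next(i for i, e in enumerate(exons) if e[0] == j.acceptor_start)
    acceptor_exon, donor_exon = exons[first], exons[last]
    if first == 0 or last == len(exons) - 1:
        return None  # no annotated linear junction on one side
    if min(e[1] - e[0] for e in (acceptor_exon, donor_exon)) < half:
        log.warning("exon shorter than %d nt at %s; probes skipped", half, record.circ_id)
        return None
    circ_seq = record.spliced_sequence(genome)
    circular = circ_seq[-half:] + circ_seq[:half]
    linear_donor = _exon_tail(genome, host, donor_exon, half) + _exon_head(
        genome, host, exons[last + 1], half
    )
    linear_acceptor = _exon_tail(genome, host, exons[first - 1], half) + _exon_head(
        genome, host, acceptor_exon, half
    )
    return JunctionProbeSet(
        circ_id=record.circ_id,
        circular_probe=circular,
        linear_donor_probe=linear_donor,
        linear_acceptor_probe=linear_acceptor,
    )


def _count_reads_with(reads: Sequence[ReadRecord], probe: str) -> int:
    probe_rc = revcomp(probe)
    return sum(1 for r in reads if probe in r.sequence or probe_rc in r.sequence)


def probe_counts(
    probes: JunctionProbeSet,
    reads: Sequence[ReadRecord],
) -> dict:
    """Per-probe read counts and the circular-fraction analog.

    Availability at each splice site includes the junction evidence
    (n_d = linear_donor + circ, n_a = linear_acceptor + circ), so the
    statistic circ / (circ + linear_donor + linear_acceptor + 1) mirrors
    n_j/(n_d + n_a - n_j + 1), is 0 when no read crosses the circular
    junction and approaches 1 for a purely circular locus.
    """
    c = _count_reads_with(reads, probes.circular_probe)
    d = _count_reads_with(reads, probes.linear_donor_probe)
    a = _count_reads_with(reads, probes.linear_acceptor_probe)
    return {
        "circ_id": probes.circ_id,
        "n_circular": c,
        "n_linear_donor": d,
        "n_linear_acceptor": a,
        "fraction": c / (c + d + a + 1),
    }


def paralog_filter(
    probe_sets: Sequence[JunctionProbeSet],
    genome: GenomeRef,
) -> list[JunctionProbeSet]:
    """Flag probe sets whose circular 20-mer occurs contiguously in the genome.

    A back-splice junction word should exist only across the joint; a
    contiguous genomic occurrence (either strand) means an adjacent paralog
    or duplication can emit junction-identical reads, so the circle is
    flagged paralog-risk and excluded from translation claims.
    """
    for ps in probe_sets:
        word = ps.circular_probe
        word_rc = revcomp(word)
        ps.paralog_risk = any(
            find_all(chrom_seq, word) or find_all(chrom_seq, word_rc)
            for chrom_seq in genome.chroms.values()
        )
    return [ps for ps in probe_sets if not ps.paralog_risk]


def translation_report(
    records: Sequence[CircRNARecord],
    models: Sequence[ExonModel],
    genome: GenomeRef,
    rna_reads: Sequence[ReadRecord],
    rpf_reads: Sequence[ReadRecord],
) -> pd.DataFrame:
    """Fig-5-style analysis: RNA vs RPF counts and fractions per circle.

    Eligibility follows the RPF data: only circles whose both linear
    junctions are supported by RPF reads are analyzed; paralog-risk probe
    sets are excluded first.
    """
    probe_sets = [ps for rec in records if (ps := build_probes(rec, models, genome))]
    probe_sets = paralog_filter(probe_sets, genome)
    rows = []
    for ps in probe_sets:
        rna = probe_counts(ps, rna_reads)
        rpf = probe_counts(ps, rpf_reads)
        eligible = rpf["n_linear_donor"] >= 1 and rpf["n_linear_acceptor"] >= 1
        rows.append(
            {
                "circ_id": ps.circ_id,
                "rna_circular": rna["n_circular"],
                "rna_linear_donor": rna["n_linear_donor"],
                "rna_linear_acceptor": rna["n_linear_acceptor"],
                "rna_fraction": rna["fraction"],
                "rpf_circular": rpf["n_circular"],
                "rpf_linear_donor": rpf["n_linear_donor"],
                "rpf_linear_acceptor": rpf["n_linear_acceptor"],
                "rpf_fraction": rpf["fraction"],
                "rpf_eligible": eligible,
            }
        )
    return pd.DataFrame(rows)
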