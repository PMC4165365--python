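"""Junction-level circular fractions, expression, abundance and the catalog.

The circular fraction of a junction is n_junction / (n_donor + n_acceptor -
n_junction + 1), counted from 20-nt probes flanking the back-splice: the
donor probe is the last 20 exonic nt ending at the donor end, the acceptor
probe the first 20 exonic nt from the acceptor start, and a read only counts
toward a probe if it has at least a probe's worth of sequence space left for
the other one. Junction reads contain both probes adjacent in back-spliced
order, so n_junction <= min(n_donor, n_acceptor) by construction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from ._seq import revcomp
from .detect import BackspliceJunction, MappedRead
from .formats import ExonModel, GenomeRef, ReadRecord

log = logging.getLogger(__name__)

DEFAULT_PROBE_LEN = 20
DEFAULT_MIN_FRACTION = 0.10
DEFAULT_MIN_SAMPLES = 2
EXPRESSED_FPKM = 0.1  # "expressed" threshold for transcriptome-share comparisons


# ---------------------------------------------------------------------------
# Types
# ---------------------------------------------------------------------------


@dataclass
class JunctionCounts:
    """Boundary-availability and junction-spanning read counts for one sample."""

    n_donor: int
    n_acceptor: int
    n_junction: int
    sample_id: str = "sample"

    def __post_init__(self) -> None:
        if min(self.n_donor, self.n_acceptor, self.n_junction) < 0:
            raise ValueError("counts must be non-negative")
        if self.n_junction > min(self.n_donor, self.n_acceptor):
            raise ValueError("junction reads contain both probes: n_j <= min(n_d, n_a)")

    @property
    def fraction(self) -> float:
        return circular_fraction(self)


@dataclass
class CircRNARecord:
    """Catalog entry: junction + inferred exon model + per-sample fractions."""

    circ_id: str
    junction: BackspliceJunction
    exon_model: ExonModel
    annotation_class: str = "intergenic"
    fractions: dict = field(default_factory=dict)  # sample -> fraction
    counts: dict = field(default_factory=dict)  # sample -> JunctionCounts
    inferred_fpkm: dict = field(default_factory=dict)  # sample -> FPKM

    @property
    def exonic_length(self) -> int:
        return self.exon_model.exonic_length

    def spliced_sequence(self, genome: GenomeRef) -> str:
        return self.exon_model.spliced_sequence(genome)

    def expressed_samples(self) -> list[str]:
        """Samples in which both boundary sites show any availability."""
        return [
            s
            for s, c in self.counts.items()
            if c.n_donor >= 1 and c.n_acceptor >= 1
        ]


@dataclass
class ExpressionRecord:
    gene_id: str
    sample_id: str
    fragments: int
    exonic_kb: float
    fpkm: float


# ---------------------------------------------------------------------------
# The circular-fraction statistic
# ---------------------------------------------------------------------------


def circular_fraction(counts: JunctionCounts) -> float:
    """n_j / (n_d + n_a - n_j + 1); in [0, 1) (the +1 keeps it defined)."""
    return counts.n_junction / (counts.n_donor + counts.n_acceptor - counts.n_junction + 1)


# ---------------------------------------------------------------------------
# Probe construction and read counting
# ---------------------------------------------------------------------------


def circle_probes(
    junction: BackspliceJunction,
    genome: GenomeRef,
    exon_model: ExonModel | None = None,
    probe_len: int = DEFAULT_PROBE_LEN,
) -> tuple[str, str]:
    """(donor_probe, acceptor_probe) in transcript orientation.

    Probes come from the circle's spliced exonic sequence: its last
    ``probe_len`` nt end at the donor site and its first ``probe_len`` nt
    start at the acceptor site. Circles shorter than two probes get truncated
    probes (flagged by a warning).
    """
    if exon_model is None:
        exon_model = ExonModel(
            gene_id=junction.junction_id,
            transcript_id=junction.junction_id,
            chrom=junction.chrom,
            strand=junction.strand,
            exons=[(junction.acceptor_start, junction.donor_end)],
        )
    seq = exon_model.spliced_sequence(genome)
    if len(seq) < 2 * probe_len:
        log.warning(
            "circle %s spliced length %d < 2x probe length; probes truncated",
            junction.junction_id,
            len(seq),
        )
        probe_len = max(1, len(seq) // 2)
    return seq[-probe_len:], seq[:probe_len]


def probe_hits(
    reads: Iterable[ReadRecord],
    donor_probe: str,
    acceptor_probe: str,
) -> tuple[int, int, int, list[str]]:
    """Count reads containing each probe with sequence space for the other.

    Matching is exact substring, both read orientations tried; a read counts
    at most once per counter. Returns (n_donor, n_acceptor, n_junction,
    junction read ids).
    """
    word = donor_probe + acceptor_probe  # reading along the circle
    dlen, alen = len(donor_probe), len(acceptor_probe)
    n_d = n_a = n_j = 0
    junction_ids = []
    for r in reads:
        got_d = got_a = got_j = False
        for seq in (r.sequence, revcomp(r.sequence)):
            if not got_j and word in seq:
                got_j = True
            if not got_d:
                i = seq.find(donor_probe)
                while i != -1:
                    if len(seq) - (i + dlen) >= alen:  # room for the acceptor probe
                        got_d = True
                        break
                    i = seq.find(donor_probe, i + 1)
            if not got_a:
                i = seq.find(acceptor_probe)
                while i != -1:
                    if i >= dlen:  # room for the donor probe upstream
                        got_a = True
                        break
                    i = seq.find(acceptor_probe, i + 1)
        # a junction read contains both probes by construction
        got_d = got_d or got_j
        got_a = got_a or got_j
        n_d += got_d
        n_a += got_a
        n_j += got_j
        if got_j:
            junction_ids.append(r.read_id)
    return n_d, n_a, n_j, junction_ids


def count_junction_reads(
    junction: BackspliceJunction,
    reads: Sequence[ReadRecord],
    genome: GenomeRef,
    exon_model: ExonModel | None = None,
    probe_len: int = DEFAULT_PROBE_LEN,
    sample_id: str | None = None,
) -> JunctionCounts:
    """Quantify one junction in one sample's reads."""
    donor_probe, acceptor_probe = circle_probes(junction, genome, exon_model, probe_len)
    n_d, n_a, n_j, _ = probe_hits(reads, donor_probe, acceptor_probe)
    if sample_id is None:
        sample_id = reads[0].sample_id if reads else "sample"
    return JunctionCounts(n_d, n_a, n_j, sample_id=sample_id)


# ---------------------------------------------------------------------------
# Gene expression
# ---------------------------------------------------------------------------


def merge_intervals(intervals: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    merged: list[list[int]] = []
    for a, b in sorted(intervals):
        if merged and a <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], b)
        else:
            merged.append([a, b])
    return [tuple(iv) for iv in merged]


def gene_exon_union(models: Sequence[ExonModel], gene_id: str) -> tuple[str, list[tuple[int, int]]]:
    """Gene locus = union of exons of all transcripts sharing gene_id."""
    exons = []
    chrom = None
    for m in models:
        if m.gene_id == gene_id:
            chrom = m.chrom
            exons.extend(m.exons)
    if chrom is None:
        raise KeyError(gene_id)
    return chrom, merge_intervals(exons)


def _overlaps_union(chrom: str, start: int, end: int, union_chrom: str, union) -> bool:
    if chrom != union_chrom:
        return False
    for a, b in union:
        if start < b and a < end:
            return True
    return False


def gene_fpkm(
    models: Sequence[ExonModel],
    mapped: Sequence[MappedRead],
    total_fragments: int | None = None,
) -> list[ExpressionRecord]:
    """FPKM per gene per sample from full-length-mapped reads.

    A fragment (mates paired by read id) is assigned to every gene whose
    merged exonic union its alignment overlaps -- the inclusive counting
    choice. FPKM = fragments / (exonic kb x total mapped fragments / 1e6).
    """
    by_sample: dict[str, dict[str, list[MappedRead]]] = {}
    for m in mapped:
        if m.ambiguous:
            continue
        frag_id = m.read_id[:-2] if m.read_id.endswith(("/1", "/2")) else m.read_id
        by_sample.setdefault(m.sample_id, {}).setdefault(frag_id, []).append(m)
    gene_ids = sorted({m.gene_id for m in models})
    unions = {g: gene_exon_union(models, g) for g in gene_ids}
    out = []
    for sample_id, fragments in sorted(by_sample.items()):
        total = total_fragments if total_fragments is not None else len(fragments)
        if total == 0:
            raise ValueError(f"sample {sample_id} has zero mapped fragments; FPKM undefined")
        for g in gene_ids:
            union_chrom, union = unions[g]
            n = sum(
                any(_overlaps_union(p.chrom, p.start, p.end, union_chrom, union) for p in placements)
                for placements in fragments.values()
            )
            kb = sum(b - a for a, b in union) / 1000.0
            out.append(
                ExpressionRecord(
                    gene_id=g,
                    sample_id=sample_id,
                    fragments=n,
                    exonic_kb=kb,
                    fpkm=n / (kb * total / 1e6),
                )
            )
    return out


def infer_abundance(fraction: float, gene_fpkm_value: float, exonic_length: int | None = None):
    """Inferred circRNA FPKM (fraction x gene FPKM) and, when the exonic
    length is given, the read weight fraction x FPKM x length used for
    transcriptome-share estimates."""
    inferred = fraction * gene_fpkm_value
    if exonic_length is None:
        return inferred
    return inferred, inferred * exonic_length


def transcriptome_share(
    circ_records: Sequence[CircRNARecord],
    expression: Sequence[ExpressionRecord],
    models: Sequence[ExonModel],
    sample_id: str,
    expressed_fpkm: float = EXPRESSED_FPKM,
) -> float:
    """Share of exon-mapping reads estimated to derive from circRNAs.

    Numerator sums fraction x gene FPKM x circRNA exonic length; denominator
    sums FPKM x exonic length over expressed protein-coding genes.
    """
    fpkm_by_gene = {e.gene_id: e for e in expression if e.sample_id == sample_id}
    denom = 0.0
    coding_genes = {m.gene_id for m in models if m.is_coding()}
    for gene_id, e in fpkm_by_gene.items():
        if gene_id in coding_genes and e.fpkm >= expressed_fpkm:
            denom += e.fpkm * e.exonic_kb * 1000.0
    num = 0.0
    for rec in circ_records:
        gene_id = rec.exon_model.gene_id
        e = fpkm_by_gene.get(gene_id)
        if e is None or e.fpkm < expressed_fpkm:
            continue
        num += rec.fractions.get(sample_id, 0.0) * e.fpkm * rec.exonic_length
    if denom == 0.0:
        raise ValueError("no expressed coding genes; share undefined")
    return num / denom


# ---------------------------------------------------------------------------
# Exon-model assignment and annotation classes
# ---------------------------------------------------------------------------


def _utr_overlap(model: ExonModel, circ_exons: list[tuple[int, int]]) -> tuple[bool, bool, bool]:
    """(overlaps CDS, overlaps 5'UTR, overlaps 3'UTR) for the circle's exons."""
    if not model.cds:
        return False, False, False
    cds_lo = model.cds[0][0]
    cds_hi = model.cds[-1][1]
    # exonic regions genomically left/right of the CDS span
    left = [(max(a, 0), min(b, cds_lo)) for a, b in model.exons if a < cds_lo]
    right = [(max(a, cds_hi), b) for a, b in model.exons if b > cds_hi]
    left = [(a, b) for a, b in left if b > a]
    right = [(a, b) for a, b in right if b > a]
    if model.strand == "+":
        utr5, utr3 = left, right
    else:
        utr5, utr3 = right, left

    def hits(regions):
        return any(a < d and c < b for a, b in circ_exons for c, d in regions)

    in_cds = any(a < d and c < b for a, b in circ_exons for c, d in model.cds)
    return in_cds, hits(utr5), hits(utr3)


def _class_from_model(model: ExonModel, circ_exons: list[tuple[int, int]]) -> str:
    if not model.is_coding():
        return "lincRNA" if "lincRNA" in model.gene_type else "noncoding-other"
    in_cds, in_utr5, in_utr3 = _utr_overlap(model, circ_exons)
    if not in_cds:
        return "noncoding-other"
    if in_utr5 and in_utr3:
        return "both-UTR"
    if in_utr5:
        return "+5'UTR"
    if in_utr3:
        return "+3'UTR"
    return "CDS-only"


def assign_exon_model(
    junction: BackspliceJunction,
    models: Sequence[ExonModel],
) -> tuple[ExonModel, str]:
    """Infer the circle's internal exon structure from the annotation.

    Assumes the circRNA shares the exon structure of an annotated transcript
    whose boundaries include the back-spliced acceptor (an exon start) and
    donor (an exon end); among matches, the one contributing the most exons
    inside the interval wins, then the longest. When no transcript matches,
    the model falls back to one exon spanning the junction and the class is
    assigned from plain overlap (sense, antisense, or intergenic).
    """
    acc, de = junction.acceptor_start, junction.donor_end
    matches = []
    for m in models:
        if m.chrom != junction.chrom or m.strand != junction.strand:
            continue
        if any(a == acc for a, _ in m.exons) and any(b == de for _, b in m.exons):
            inside = [(a, b) for a, b in m.exons if acc <= a and b <= de]
            if inside:
                matches.append((len(inside), sum(b - a for a, b in inside), m, inside))
    if matches:
        matches.sort(key=lambda t: (-t[0], -t[1], t[2].transcript_id))
        _, _, m, inside = matches[0]
        circ_model = ExonModel(
            gene_id=m.gene_id,
            transcript_id=f"{m.transcript_id}|circ",
            chrom=m.chrom,
            strand=m.strand,
            exons=inside,
            cds=[(max(a, acc), min(b, de)) for a, b in m.cds if max(a, acc) < min(b, de)],
            gene_type=m.gene_type,
        )
        return circ_model, _class_from_model(m, inside)

    circ_exons = [(acc, de)]
    fallback = ExonModel(
        gene_id=junction.junction_id,
        transcript_id=junction.junction_id,
        chrom=junction.chrom,
        strand=junction.strand,
        exons=circ_exons,
    )
    sense = [
        m
        for m in models
        if m.chrom == junction.chrom
        and m.strand == junction.strand
        and m.start < de
        and acc < m.end
    ]
    if sense:
        best = max(
            sense,
            key=lambda m: sum(max(0, min(b, de) - max(a, acc)) for a, b in m.exons),
        )
        return fallback, _class_from_model(best, circ_exons)
    antisense = [
        m
        for m in models
        if m.chrom == junction.chrom
        and m.strand != junction.strand
        and m.start < de
        and acc < m.end
    ]
    if antisense:
        return fallback, "antisense"
    return fallback, "intergenic"


# ---------------------------------------------------------------------------
# Catalog filtering
# ---------------------------------------------------------------------------


def catalog_filter(
    records: Sequence[CircRNARecord],
    min_fraction: float = DEFAULT_MIN_FRACTION,
    min_samples: int = DEFAULT_MIN_SAMPLES,
) -> tuple[list[CircRNARecord], list[str]]:
    """Apply the catalog filters.

    Keeps GT-AG junctions whose circular fraction is >= ``min_fraction`` in at
    least ``min_samples`` samples. Also returns ids of the high-fraction
    sublist: fraction >= 50% in most (>half) of the samples in which the locus
    shows any donor and acceptor availability.
    """
    kept = []
    high = []
    for rec in records:
        if rec.junction.signal_class != "GT-AG":
            continue
        n_pass = sum(1 for f in rec.fractions.values() if f >= min_fraction)
        if n_pass < min_samples:
            continue
        kept.append(rec)
        expressed = rec.expressed_samples() or list(rec.fractions)
        n_high = sum(1 for s in expressed if rec.fractions.get(s, 0.0) >= 0.5)
        if n_high > len(expressed) / 2:
            high.append(rec.circ_id)
    return kept, high
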