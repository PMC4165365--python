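"""Synthetic genomes, transcript mixtures and reads with known ground truth.

The generator builds a small multi-gene genome whose introns carry canonical
GT..AG signals, plants one circular isoform per chosen gene at a controlled
circular fraction, and emits ~200-nt paired-end fragments (reads are the
fragment ends) plus optional RPF-like 30-nt reads confined to linear mRNAs.

Circular-fraction semantics
---------------------------
``true_fraction`` f is the estimand of the junction-read statistic
n_j/(n_d + n_a - n_j + 1): every read informative about the donor or acceptor
boundary is a back-spliced junction read with probability f. With fragments
sampled proportionally to molecules x length, a molecule-level circular
proportion m produces an expected statistic of m/(2-m) (a linear molecule
exposes two boundary windows, a circle one), so the generator converts f into
m = 2f/(1+f) when weighting templates. The limits agree: f=0 -> no circles,
f=1 -> no linear molecules.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._seq import revcomp
from .detect import BackspliceJunction
from .formats import ExonModel, GenomeRef, ReadRecord

log = logging.getLogger(__name__)

DEFAULT_FRAGMENT_MEAN = 200.0
DEFAULT_FRAGMENT_SD = 20.0
DEFAULT_READ_LEN = 100
DEFAULT_RPF_LEN = 30


# ---------------------------------------------------------------------------
# Ground truth
# ---------------------------------------------------------------------------


@dataclass
class CircTruth:
    """One planted circle: which exons of which gene circularize."""

    gene_id: str
    chrom: str
    strand: str
    acceptor_start: int
    donor_end: int
    exon_indices: tuple[int, ...]  # genomic-order indices into the gene model
    trans_spliced: bool = False  # emit a linear shuffled-exon mimic instead

    @property
    def junction_id(self) -> str:
        return f"{self.chrom}:{self.acceptor_start}-{self.donor_end}:{self.strand}"

    def junction(self) -> BackspliceJunction:
        return BackspliceJunction(
            self.chrom, self.strand, self.acceptor_start, self.donor_end, "GT-AG"
        )


@dataclass
class SimTruth:
    """Everything a recovery test needs to score the pipeline."""

    circles: list[CircTruth]
    fractions: dict[str, dict[str, float]]  # gene_id -> sample_id -> f in [0,1]
    intron_retention_rate: float = 0.0
    fragment_length_mean: float = DEFAULT_FRAGMENT_MEAN
    fragment_length_sd: float = DEFAULT_FRAGMENT_SD
    read_length: int = DEFAULT_READ_LEN
    seed: int = 0

    def __post_init__(self) -> None:
        for circ in self.circles:
            if not circ.acceptor_start < circ.donor_end:
                raise ValueError("truth junction violates acceptor_start < donor_end")
        for per_sample in self.fractions.values():
            for f in per_sample.values():
                if not 0.0 <= f <= 1.0:
                    raise ValueError("true fractions must lie in [0, 1]")
        if not 0.0 <= self.intron_retention_rate <= 1.0:
            raise ValueError("intron_retention_rate must lie in [0, 1]")

    def fraction_for(self, gene_id: str, sample_id: str) -> float:
        return self.fractions.get(gene_id, {}).get(sample_id, 0.0)

    def samples(self) -> list[str]:
        out: list[str] = []
        for per_sample in self.fractions.values():
            for s in per_sample:
                if s not in out:
                    out.append(s)
        return out

    def to_table(self) -> pd.DataFrame:
        rows = []
        for circ in self.circles:
            row = {
                "gene_id": circ.gene_id,
                "junction_id": circ.junction_id,
                "chrom": circ.chrom,
                "strand": circ.strand,
                "acceptor_start": circ.acceptor_start,
                "donor_end": circ.donor_end,
                "trans_spliced": circ.trans_spliced,
            }
            for sample, f in self.fractions.get(circ.gene_id, {}).items():
                row[f"frac_{sample}"] = f
            rows.append(row)
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Genome construction
# ---------------------------------------------------------------------------


def _random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=n)])


def make_genome(
    n_genes: int = 5,
    exons_per_gene: int = 5,
    exon_len_range: tuple[int, int] = (120, 180),
    intron_len_range: tuple[int, int] = (60, 100),
    seed: int = 0,
    spacer_len: int = 150,
    strands: str | None = None,
    chrom: str = "chrS",
) -> tuple[GenomeRef, list[ExonModel]]:
    """Random genome with ``n_genes`` spliced genes on one chromosome.

    Every intron starts GT and ends AG on the gene's strand; all exons are
    treated as coding (CDS = exons). Deterministic given ``seed``. ``strands``
    may fix all genes to "+" or "-"; by default they alternate.
    """
    if min(n_genes, exons_per_gene, exon_len_range[0], intron_len_range[0]) <= 0:
        raise ValueError("all counts must be positive")
    rng = np.random.default_rng(seed)
    parts = [_random_dna(rng, spacer_len)]
    pos = spacer_len
    models = []
    for g in range(n_genes):
        strand = strands if strands in ("+", "-") else ("+" if g % 2 == 0 else "-")
        exons = []
        for e in range(exons_per_gene):
            elen = int(rng.integers(exon_len_range[0], exon_len_range[1] + 1))
            parts.append(_random_dna(rng, elen))
            exons.append((pos, pos + elen))
            pos += elen
            if e < exons_per_gene - 1:
                ilen = int(rng.integers(intron_len_range[0], intron_len_range[1] + 1))
                intron = "GT" + _random_dna(rng, ilen - 4) + "AG"
                if strand == "-":
                    intron = revcomp(intron)  # reads GT..AG on the minus strand
                parts.append(intron)
                pos += ilen
        parts.append(_random_dna(rng, spacer_len))
        pos += spacer_len
        models.append(
            ExonModel(
                gene_id=f"gene{g}",
                transcript_id=f"gene{g}.t1",
                chrom=chrom,
                strand=strand,
                exons=exons,
                cds=list(exons),
            )
        )
    genome = GenomeRef({chrom: "".join(parts)})
    return genome, models


def make_truth(
    models: list[ExonModel],
    fractions: dict[str, dict[str, float]],
    circle_exons: tuple[int, int] = (1, 3),
    intron_retention_rate: float = 0.0,
    trans_splice_genes: set[str] | None = None,
    seed: int = 0,
    **kwargs,
) -> SimTruth:
    """Plant one circle per gene named in ``fractions``.

    ``circle_exons`` gives the inclusive genomic-order exon index range that
    circularizes (default: the middle three of a five-exon gene, so annotated
    linear junctions exist on both sides).
    """
    trans_splice_genes = trans_splice_genes or set()
    by_gene = {m.gene_id: m for m in models}
    circles = []
    for gene_id in fractions:
        m = by_gene[gene_id]
        lo, hi = circle_exons
        if not (0 <= lo <= hi < len(m.exons)):
            raise ValueError(f"circle exon range {circle_exons} invalid for {gene_id}")
        circles.append(
            CircTruth(
                gene_id=gene_id,
                chrom=m.chrom,
                strand=m.strand,
                acceptor_start=m.exons[lo][0],
                donor_end=m.exons[hi][1],
                exon_indices=tuple(range(lo, hi + 1)),
                trans_spliced=gene_id in trans_splice_genes,
            )
        )
    return SimTruth(
        circles=circles,
        fractions=fractions,
        intron_retention_rate=intron_retention_rate,
        seed=seed,
        **kwargs,
    )


# ---------------------------------------------------------------------------
# Templates
# ---------------------------------------------------------------------------


def _circle_spliced_sequence(genome: GenomeRef, model: ExonModel, circ: CircTruth) -> str:
    seq = "".join(genome.fetch(model.chrom, *model.exons[i]) for i in circ.exon_indices)
    return revcomp(seq) if model.strand == "-" else seq


def _circle_retained_sequence(genome: GenomeRef, model: ExonModel, circ: CircTruth) -> str:
    seq = genome.fetch(model.chrom, circ.acceptor_start, circ.donor_end)
    return revcomp(seq) if model.strand == "-" else seq


def _trans_template(genome: GenomeRef, model: ExonModel, circ: CircTruth) -> str:
    """Linear shuffled-exon mimic: the full transcript with the circle's exons
    repeated, yielding junction-identical reads but a polyadenylated molecule
    whose mates can map outside the would-be circle."""
    exon_seqs = [genome.fetch(model.chrom, a, b) for a, b in model.exons]
    if model.strand == "-":
        # transcript order for a minus-strand gene runs right to left
        exon_seqs = [revcomp(s) for s in reversed(exon_seqs)]
        block = [len(model.exons) - 1 - i for i in reversed(circ.exon_indices)]
    else:
        block = list(circ.exon_indices)
    n = len(exon_seqs)
    upstream = list(range(0, block[-1] + 1))
    downstream = list(range(block[-1] + 1, n))
    return "".join(exon_seqs[i] for i in upstream + block + downstream)


@dataclass
class _Template:
    name: str
    sequence: str
    circular: bool
    weight: float
    gene_id: str


def _gene_templates(
    genome: GenomeRef,
    model: ExonModel,
    truth: SimTruth,
    sample_id: str,
    polya_selected: bool,
) -> list[_Template]:
    f = truth.fraction_for(model.gene_id, sample_id)
    circ = next((c for c in truth.circles if c.gene_id == model.gene_id), None)
    linear_seq = model.spliced_sequence(genome)

    def _starts(seq: str, circular: bool) -> float:
        # fragments start uniformly over the valid start positions: the full
        # period of a circle, but only L - F + 1 positions of a linear
        # template; weighting by starts (not raw length) keeps per-window
        # read coverage proportional to molecule counts for every template
        if circular:
            return float(len(seq))
        return float(max(len(seq) - truth.fragment_length_mean + 1.0, 1.0))

    out = [
        _Template(
            f"{model.gene_id}:linear", linear_seq, False,
            (1.0 - f) * _starts(linear_seq, False), model.gene_id,
        )
    ]
    if circ is None or f == 0.0:
        return out
    for i in circ.exon_indices:
        a, b = model.exons[i]
        if not (circ.acceptor_start <= a and b <= circ.donor_end):
            raise ValueError("truth junction not on exon boundaries")
    if circ.acceptor_start not in [a for a, _ in model.exons] or circ.donor_end not in [
        b for _, b in model.exons
    ]:
        raise ValueError("truth junction not on exon boundaries")
    if circ.trans_spliced:
        seq = _trans_template(genome, model, circ)
        out.append(
            _Template(
                f"{model.gene_id}:trans", seq, False,
                2.0 * f * _starts(seq, False), model.gene_id,
            )
        )
        return out
    if polya_selected:
        return out  # circles lack poly(A) tails and drop out of the library
    r = truth.intron_retention_rate
    spliced = _circle_spliced_sequence(genome, model, circ)
    if r < 1.0:
        out.append(
            _Template(
                f"{model.gene_id}:circ", spliced, True,
                2.0 * f * (1.0 - r) * _starts(spliced, True), model.gene_id,
            )
        )
    if r > 0.0:
        retained = _circle_retained_sequence(genome, model, circ)
        out.append(
            _Template(
                f"{model.gene_id}:circ_ret", retained, True,
                2.0 * f * r * _starts(retained, True), model.gene_id,
            )
        )
    return out


# ---------------------------------------------------------------------------
# Read generation
# ---------------------------------------------------------------------------


def _mutate(rng: np.random.Generator, seq: str, error_rate: float) -> str:
    if error_rate <= 0.0:
        return seq
    arr = list(seq)
    for i in np.flatnonzero(rng.random(len(arr)) < error_rate):
        arr[i] = rng.choice([b for b in "ACGT" if b != arr[i]])
    return "".join(arr)


def make_reads(
    genome: GenomeRef,
    models: list[ExonModel],
    truth: SimTruth,
    n_fragments: int,
    sample_id: str = "sample",
    polya_selected: bool = False,
    seed: int | None = None,
    error_rate: float = 0.0,
) -> list[ReadRecord]:
    """Paired-end fragments from the linear + circular transcript mixture.

    Fragments are allocated across templates proportionally to weight
    (molecules x length, see module docstring), drawn with Normal(fragment
    mean, sd) lengths; reads are the two fragment ends, read 2 reverse
    complemented. Circular templates are tiled three times so a fragment can
    start anywhere in one period and run across the back-splice junction.
    With ``polya_selected`` the circular templates are excluded entirely.
    """
    rng = np.random.default_rng(truth.seed if seed is None else seed)
    templates = []
    for m in models:
        templates.extend(_gene_templates(genome, m, truth, sample_id, polya_selected))
    weights = np.array([t.weight for t in templates], dtype=float)
    if weights.sum() <= 0:
        return []
    counts = rng.multinomial(n_fragments, weights / weights.sum())
    read_len = truth.read_length
    reads = []
    idx = 0
    for t, n in zip(templates, counts):
        period = len(t.sequence)
        tiled = t.sequence * 3 if t.circular else t.sequence
        for _ in range(n):
            frag = int(round(rng.normal(truth.fragment_length_mean, truth.fragment_length_sd)))
            frag = max(read_len, min(frag, len(tiled)))
            if t.circular:
                start = int(rng.integers(0, period))
            else:
                start = int(rng.integers(0, len(tiled) - frag + 1))
            r1 = tiled[start : start + read_len]
            r2 = revcomp(tiled[start + frag - read_len : start + frag])
            rid = f"{sample_id}:{t.name}:{idx}"
            reads.append(
                ReadRecord(f"{rid}/1", _mutate(rng, r1, error_rate), sample_id, mate_index=1)
            )
            reads.append(
                ReadRecord(f"{rid}/2", _mutate(rng, r2, error_rate), sample_id, mate_index=2)
            )
            idx += 1
    return reads


def make_rpf(
    genome: GenomeRef,
    models: list[ExonModel],
    n_reads: int,
    read_len: int = DEFAULT_RPF_LEN,
    seed: int = 0,
    sample_id: str = "rpf",
) -> list[ReadRecord]:
    """Ribosome-protected-fragment-like short reads from linear mRNAs only.

    Translation is confined to the linear spliced isoforms, so no read can
    span a back-splice junction -- the ground truth for translation tests.
    """
    rng = np.random.default_rng(seed)
    seqs = [m.spliced_sequence(genome) for m in models]
    weights = np.array([max(len(s) - read_len + 1, 0) for s in seqs], dtype=float)
    counts = rng.multinomial(n_reads, weights / weights.sum())
    reads = []
    idx = 0
    for m, seq, n in zip(models, seqs, counts):
        starts = rng.integers(0, len(seq) - read_len + 1, size=n)
        for s in starts:
            reads.append(
                ReadRecord(f"{sample_id}:{m.gene_id}:{idx}", seq[int(s) : int(s) + read_len], sample_id)
            )
            idx += 1
    return reads
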