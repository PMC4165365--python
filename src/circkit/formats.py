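"""Readers and writers for the external formats the pipeline touches.

One fixed internal convention is used everywhere: coordinates are 0-based,
half-open, on the forward genomic strand; the strand is carried separately.
GTF (1-based, inclusive) is converted at this boundary; BED12 is used as-is.
"""

from __future__ import annotations

import gzip
import logging
import os
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from ._seq import DNA_ALPHABET, revcomp

log = logging.getLogger(__name__)

MIN_DISCOVERY_READ_LEN = 40


def _open_text(path, mode: str = "rt"):
    """Open a possibly gzip-compressed text file."""
    path = os.fspath(path)
    if path.endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class GenomeRef:
    """In-memory reference genome: ordered chromosome names -> uppercase DNA."""

    chroms: dict[str, str]

    def __post_init__(self) -> None:
        for name, seq in self.chroms.items():
            bad = set(seq) - DNA_ALPHABET
            if bad:
                raise ValueError(f"chromosome {name!r} has non-ACGTN characters: {sorted(bad)}")

    @property
    def chrom_names(self) -> list[str]:
        return list(self.chroms)

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.chroms

    def length(self, chrom: str) -> int:
        return len(self.chroms[chrom])

    def fetch(self, chrom: str, start: int, end: int, strand: str = "+") -> str:
        """Sequence of ``[start, end)`` on ``chrom``; minus strand returns the
        reverse complement."""
        seq = self.chroms[chrom]
        if not (0 <= start <= end <= len(seq)):
            raise ValueError(
                f"fetch {chrom}:{start}-{end} out of bounds (length {len(seq)})"
            )
        sub = seq[start:end]
        return revcomp(sub) if strand == "-" else sub


@dataclass
class ExonModel:
    """Exon structure of one transcript.

    ``exons`` (and ``cds``, when present) are 0-based half-open intervals on the
    forward strand, sorted by genomic start regardless of transcript strand.
    """

    gene_id: str
    transcript_id: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]
    cds: list[tuple[int, int]] = field(default_factory=list)
    gene_type: str = "protein_coding"

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        self.exons = sorted((int(a), int(b)) for a, b in self.exons)
        self.cds = sorted((int(a), int(b)) for a, b in self.cds)
        for (a, b), (c, d) in zip(self.exons, self.exons[1:]):
            if c < b:
                raise ValueError(f"overlapping exons in {self.transcript_id}: {(a, b)} {(c, d)}")
        if self.exonic_length <= 0:
            raise ValueError(f"transcript {self.transcript_id} has zero exonic length")

    @property
    def exonic_length(self) -> int:
        return sum(b - a for a, b in self.exons)

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    def introns(self) -> list[tuple[int, int]]:
        return [(b, c) for (_, b), (c, _) in zip(self.exons, self.exons[1:])]

    def spliced_sequence(self, genome: GenomeRef) -> str:
        """Exon concatenation in transcript (5'->3') orientation."""
        seq = "".join(genome.fetch(self.chrom, a, b) for a, b in self.exons)
        return revcomp(seq) if self.strand == "-" else seq

    def is_coding(self) -> bool:
        return bool(self.cds)


@dataclass
class ReadRecord:
    """A sequencing read; plumbing type shared by simulator and pipeline."""

    read_id: str
    sequence: str
    sample_id: str = "sample"
    mate_index: int | None = None

    @property
    def fragment_id(self) -> str:
        rid = self.read_id
        if rid.endswith("/1") or rid.endswith("/2"):
            return rid[:-2]
        return rid


# ---------------------------------------------------------------------------
# Genome / annotation loading
# ---------------------------------------------------------------------------


def load_genome(path) -> GenomeRef:
    """Load a FASTA file into a :class:`GenomeRef` (lowercase normalized)."""
    chroms: dict[str, str] = {}
    with _open_text(path) as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            if rec.id in chroms:
                raise ValueError(f"duplicate chromosome name {rec.id!r}")
            chroms[rec.id] = str(rec.seq).upper()
    if not chroms:
        raise ValueError(f"no FASTA records found in {path}")
    return GenomeRef(chroms)


def _load_gtf(path) -> list[ExonModel]:
    from gffutils.iterators import DataIterator

    def _attr(feature, key, default=None):
        vals = feature.attributes.get(key, [])
        return vals[0] if vals else default

    exons: dict[str, dict] = {}
    for feature in DataIterator(os.fspath(path)):
        if feature.featuretype not in ("exon", "CDS"):
            continue
        tid = _attr(feature, "transcript_id")
        if tid is None:
            continue
        entry = exons.setdefault(
            tid,
            {
                "gene_id": _attr(feature, "gene_id", tid),
                "chrom": feature.seqid,
                "strand": feature.strand,
                "exons": [],
                "cds": [],
                "gene_type": _attr(
                    feature, "gene_type", _attr(feature, "gene_biotype", "protein_coding")
                ),
            },
        )
        # GTF is 1-based inclusive; internal is 0-based half-open.
        iv = (feature.start - 1, feature.end)
        entry["exons" if feature.featuretype == "exon" else "cds"].append(iv)
    models = []
    for tid, entry in exons.items():
        if not entry["exons"]:
            log.warning("transcript %s has zero exons; skipped", tid)
            continue
        models.append(
            ExonModel(
                gene_id=entry["gene_id"],
                transcript_id=tid,
                chrom=entry["chrom"],
                strand=entry["strand"],
                exons=entry["exons"],
                cds=entry["cds"],
                gene_type=entry["gene_type"],
            )
        )
    return models


def _load_bed12(path) -> list[ExonModel]:
    models = []
    with _open_text(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            f = line.rstrip("\n").split("\t")
            chrom, chrom_start, name, strand = f[0], int(f[1]), f[3], f[5]
            thick_start, thick_end = int(f[6]), int(f[7])
            sizes = [int(x) for x in f[10].rstrip(",").split(",")]
            starts = [int(x) for x in f[11].rstrip(",").split(",")]
            if not sizes:
                log.warning("BED12 record %s has zero blocks; skipped", name)
                continue
            exons = [(chrom_start + s, chrom_start + s + sz) for s, sz in zip(starts, sizes)]
            cds = []
            if thick_end > thick_start:
                cds = [
                    (max(a, thick_start), min(b, thick_end))
                    for a, b in exons
                    if min(b, thick_end) > max(a, thick_start)
                ]
            models.append(
                ExonModel(
                    gene_id=name,
                    transcript_id=name,
                    chrom=chrom,
                    strand=strand,
                    exons=exons,
                    cds=cds,
                )
            )
    return models


def load_annotation(path) -> list[ExonModel]:
    """Load transcript models from a GTF (exon/CDS features) or BED12 file."""
    path = os.fspath(path)
    stem = path[:-3] if path.endswith(".gz") else path
    if stem.endswith((".bed", ".bed12")):
        return _load_bed12(path)
    return _load_gtf(path)


def write_gtf(models: Iterable[ExonModel], path) -> None:
    """Write exon (and CDS) features; internal half-open back to 1-based GTF."""
    with _open_text(path, "wt") as fh:
        for m in models:
            attrs = (
                f'gene_id "{m.gene_id}"; transcript_id "{m.transcript_id}"; '
                f'gene_type "{m.gene_type}";'
            )
            for ftype, intervals in (("exon", m.exons), ("CDS", m.cds)):
                for a, b in intervals:
                    fh.write(
                        "\t".join(
                            [m.chrom, "circkit", ftype, str(a + 1), str(b), ".", m.strand, ".", attrs]
                        )
                        + "\n"
                    )


def write_genome_fasta(genome: GenomeRef, path, width: int = 70) -> None:
    with _open_text(path, "wt") as fh:
        for name, seq in genome.chroms.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Reads
# ---------------------------------------------------------------------------


def read_fastq(path, sample_id: str = "sample") -> list[ReadRecord]:
    """Load a (possibly gzipped) FASTQ file; mate index taken from /1 or /2."""
    reads = []
    with _open_text(path) as fh:
        for rid, seq, _ in FastqGeneralIterator(fh):
            rid = rid.split()[0]
            mate = None
            if rid.endswith("/1"):
                mate = 1
            elif rid.endswith("/2"):
                mate = 2
            reads.append(ReadRecord(rid, seq.upper(), sample_id=sample_id, mate_index=mate))
    return reads


def write_fastq(reads: Iterable[ReadRecord], path) -> None:
    with _open_text(path, "wt") as fh:
        for r in reads:
            fh.write(f"@{r.read_id}\n{r.sequence}\n+\n{'I' * len(r.sequence)}\n")


# ---------------------------------------------------------------------------
# Catalog serialization
# ---------------------------------------------------------------------------

_CATALOG_FIXED_COLS = [
    "circ_id",
    "chrom",
    "strand",
    "acceptor_start",
    "donor_end",
    "exonic_length",
    "signal_class",
    "annotation_class",
    "exon_starts",
    "exon_ends",
]


def write_catalog(records: Sequence, path, bed_path=None) -> None:
    """Write circRNA records to TSV, plus a BED12 companion with exon blocks.

    One row per circRNA: identity, junction coordinates, exon model, class, and
    one ``frac_<sample>`` column per quantified sample.
    """
    samples: list[str] = []
    for rec in records:
        for s in rec.fractions:
            if s not in samples:
                samples.append(s)
    cols = _CATALOG_FIXED_COLS + [f"frac_{s}" for s in samples]
    with _open_text(path, "wt") as fh:
        fh.write("\t".join(cols) + "\n")
        for rec in records:
            exons = rec.exon_model.exons
            row = [
                rec.circ_id,
                rec.junction.chrom,
                rec.junction.strand,
                str(rec.junction.acceptor_start),
                str(rec.junction.donor_end),
                str(rec.exonic_length),
                rec.junction.signal_class,
                rec.annotation_class,
                ",".join(str(a) for a, _ in exons),
                ",".join(str(b) for _, b in exons),
            ]
            row += [repr(rec.fractions.get(s, 0.0)) for s in samples]
            fh.write("\t".join(row) + "\n")
    if bed_path is None:
        bed_path = os.fspath(path) + ".bed12"
    with _open_text(bed_path, "wt") as fh:
        for rec in records:
            exons = rec.exon_model.exons
            start = rec.junction.acceptor_start
            sizes = ",".join(str(b - a) for a, b in exons)
            offsets = ",".join(str(a - start) for a, _ in exons)
            fh.write(
                "\t".join(
                    [
                        rec.junction.chrom,
                        str(start),
                        str(rec.junction.donor_end),
                        rec.circ_id,
                        str(max(rec.junction.support.values(), default=0)),
                        rec.junction.strand,
                        str(start),
                        str(start),
                        "0",
                        str(len(exons)),
                        sizes,
                        offsets,
                    ]
                )
                + "\n"
            )


def read_catalog(path) -> list:
    """Read a catalog TSV back into CircRNARecord objects (round-trip identity)."""
    from .detect import BackspliceJunction
    from .quantify import CircRNARecord

    records = []
    with _open_text(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        sample_cols = [c for c in header if c.startswith("frac_")]
        for line in fh:
            vals = dict(zip(header, line.rstrip("\n").split("\t")))
            junction = BackspliceJunction(
                chrom=vals["chrom"],
                strand=vals["strand"],
                acceptor_start=int(vals["acceptor_start"]),
                donor_end=int(vals["donor_end"]),
                signal_class=vals["signal_class"],
            )
            starts = [int(x) for x in vals["exon_starts"].split(",")]
            ends = [int(x) for x in vals["exon_ends"].split(",")]
            model = ExonModel(
                gene_id=vals["circ_id"],
                transcript_id=vals["circ_id"],
                chrom=vals["chrom"],
                strand=vals["strand"],
                exons=list(zip(starts, ends)),
            )
            fractions = {c[len("frac_"):]: float(vals[c]) for c in sample_cols}
            records.append(
                CircRNARecord(
                    circ_id=vals["circ_id"],
                    junction=junction,
                    exon_model=model,
                    annotation_class=vals["annotation_class"],
                    fractions=fractions,
                )
            )
    return records
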