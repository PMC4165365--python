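"""Cross-species circRNA comparison and codon-position conservation tests.

Cross-species coordinate mapping is consumed as a paired-interval table (the
product of a liftOver-style tool), not computed; per-base conservation
scores are consumed as bedGraph text. The statistical surface: a 2x2
ortholog enrichment table, splice-site-level overlap classes, Spearman
correlation of average circular fractions, and paired per-codon-position
comparisons of circular vs. neighboring linear coding exons, including a
matched-control-cohort null for the wobble (third) position.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .formats import ExonModel
from .quantify import CircRNARecord, JunctionCounts

log = logging.getLogger(__name__)

BOUNDARY_TOL = 2  # nt tolerance for "same splice sites" across a lifted map
DEFAULT_N_COHORTS = 1000
MAX_MISSING_FRACTION = 0.5  # exon excluded when track covers less than half


# ---------------------------------------------------------------------------
# Coordinate map
# ---------------------------------------------------------------------------


@dataclass
class CoordinateMap:
    """Strand-aware pairs of species-A -> species-B intervals.

    Table columns: chromA, startA, endA, strandA, chromB, startB, endB,
    strandB; coordinates 0-based half-open. Positions are mapped per
    boundary by offset within the containing interval (reversed when the
    strands differ).
    """

    pairs: pd.DataFrame

    @classmethod
    def from_table(cls, path) -> "CoordinateMap":
        cols = ["chromA", "startA", "endA", "strandA", "chromB", "startB", "endB", "strandB"]
        pairs = pd.read_csv(path, sep="\t", comment="#", names=cols, dtype={1: int})
        return cls(pairs)

    def __post_init__(self) -> None:
        bad = (self.pairs["endA"] <= self.pairs["startA"]) | (
            self.pairs["endB"] <= self.pairs["startB"]
        )
        if bad.any():
            raise ValueError("degenerate mapped interval in coordinate map")

    def map_position(self, chrom: str, pos: int):
        """(chromB, pos, strand_flip) for a species-A position, or None."""
        for row in self.pairs.itertuples(index=False):
            if row.chromA == chrom and row.startA <= pos <= row.endA:
                offset = pos - row.startA
                if row.strandA == row.strandB:
                    return row.chromB, row.startB + offset, False
                return row.chromB, row.endB - offset, True
        return None


# ---------------------------------------------------------------------------
# Conservation track
# ---------------------------------------------------------------------------


@dataclass
class ConservationTrack:
    """Per-base scores (phyloP-like); missing positions are NaN."""

    scores: dict[str, dict[int, float]]

    @classmethod
    def from_bedgraph(cls, path) -> "ConservationTrack":
        table = pd.read_csv(
            path, sep="\t", comment="#",
            names=["chrom", "start", "end", "score"],
        )
        scores: dict[str, dict[int, float]] = {}
        for row in table.itertuples(index=False):
            if not np.isfinite(row.score):
                raise ValueError("conservation scores must be finite where present")
            per = scores.setdefault(row.chrom, {})
            for pos in range(int(row.start), int(row.end)):
                per[pos] = float(row.score)
        return cls(scores)

    def values(self, chrom: str, start: int, end: int) -> np.ndarray:
        per = self.scores.get(chrom, {})
        return np.array([per.get(pos, np.nan) for pos in range(start, end)])


# ---------------------------------------------------------------------------
# Ortholog-level enrichment
# ---------------------------------------------------------------------------


def ortholog_circ_enrichment(
    genes_with_circ_a: set[str],
    genes_with_circ_b: set[str],
    orthologs: pd.DataFrame,
) -> dict:
    """Does having a circRNA in species A predict one in the B ortholog?

    ``orthologs`` has columns geneA, geneB (one-to-one pairs). Returns the
    2x2 table, conditional proportions and the odds ratio with Fisher's
    exact p-value.
    """
    if orthologs.duplicated(subset=["geneA"]).any() or orthologs.duplicated(subset=["geneB"]).any():
        raise ValueError("ortholog table must contain unique one-to-one pairs")
    a = orthologs["geneA"].isin(genes_with_circ_a).to_numpy()
    b = orthologs["geneB"].isin(genes_with_circ_b).to_numpy()
    table = np.array(
        [[int((a & b).sum()), int((a & ~b).sum())],
         [int((~a & b).sum()), int((~a & ~b).sum())]]
    )
    with_a = table[0].sum()
    without_a = table[1].sum()
    prop_given_circ = table[0, 0] / with_a if with_a else np.nan
    prop_given_no_circ = table[1, 0] / without_a if without_a else np.nan
    odds_ratio, p = stats.fisher_exact(table)
    return {
        "table": table,
        "prop_b_circ_given_a_circ": prop_given_circ,
        "prop_b_circ_given_a_no_circ": prop_given_no_circ,
        "odds_ratio": odds_ratio,
        "p_value": p,
    }


# ---------------------------------------------------------------------------
# Splice-site-level overlap
# ---------------------------------------------------------------------------


def overlap_class(
    junction,
    target_catalog: Sequence[CircRNARecord],
    coord_map: CoordinateMap,
    tolerance: int = BOUNDARY_TOL,
) -> str:
    """same_splice_sites | partial_overlap | no_overlap | unmappable."""
    acc = coord_map.map_position(junction.chrom, junction.acceptor_start)
    don = coord_map.map_position(junction.chrom, junction.donor_end)
    if acc is None or don is None:
        return "unmappable"
    (chrom_a, pos_a, _), (chrom_d, pos_d, _) = acc, don
    if chrom_a != chrom_d:
        return "unmappable"
    lo, hi = sorted((pos_a, pos_d))
    for rec in target_catalog:
        j = rec.junction
        if j.chrom != chrom_a:
            continue
        if abs(j.acceptor_start - lo) <= tolerance and abs(j.donor_end - hi) <= tolerance:
            return "same_splice_sites"
    for rec in target_catalog:
        j = rec.junction
        if j.chrom == chrom_a and lo < j.donor_end and j.acceptor_start < hi:
            return "partial_overlap"
    return "no_overlap"


def classify_catalog_overlap(
    catalog_a: Sequence[CircRNARecord],
    catalog_b: Sequence[CircRNARecord],
    coord_map: CoordinateMap,
    tolerance: int = BOUNDARY_TOL,
) -> pd.Series:
    classes = {
        rec.circ_id: overlap_class(rec.junction, catalog_b, coord_map, tolerance)
        for rec in catalog_a
    }
    return pd.Series(classes, name="overlap_class")


# ---------------------------------------------------------------------------
# Circular-fraction correlation between species
# ---------------------------------------------------------------------------


def average_expressed_fraction(per_sample: dict[str, JunctionCounts]) -> float:
    """Mean fraction over samples with any donor and acceptor availability."""
    vals = [
        c.fraction for c in per_sample.values() if c.n_donor >= 1 and c.n_acceptor >= 1
    ]
    return float(np.mean(vals)) if vals else np.nan


def cf_correlation(
    pairs: Sequence[tuple[str, str]],
    counts_a: dict[str, dict[str, JunctionCounts]],
    counts_b: dict[str, dict[str, JunctionCounts]],
) -> tuple[float, float, int]:
    """Spearman correlation of average circular fractions across conserved
    circRNA pairs; returns (rho, p, n used)."""
    xs, ys = [], []
    for id_a, id_b in pairs:
        fa = average_expressed_fraction(counts_a.get(id_a, {}))
        fb = average_expressed_fraction(counts_b.get(id_b, {}))
        if np.isfinite(fa) and np.isfinite(fb):
            xs.append(fa)
            ys.append(fb)
    if len(xs) < 3:
        raise ValueError(f"need >=3 conserved pairs with data, got {len(xs)}")
    rho, p = stats.spearmanr(xs, ys)
    return float(rho), float(p), len(xs)


# ---------------------------------------------------------------------------
# Codon-position conservation
# ---------------------------------------------------------------------------


def _codon_position_means(
    model: ExonModel,
    exons: Sequence[tuple[int, int]],
    track: ConservationTrack,
) -> np.ndarray | None:
    """Mean track score at codon positions 1..3 over the given coding exons.

    The reading frame is propagated along the spliced CDS of ``model``:
    the codon position of a base is (its index within the spliced CDS mod 3)
    + 1, in transcript orientation.
    """
    cds = list(model.cds)
    if not cds:
        return None
    if model.strand == "-":
        cds = list(reversed(cds))
    wanted = [tuple(e) for e in exons]
    sums = np.zeros(3)
    counts = np.zeros(3)
    cds_index = 0
    for a, b in cds:
        length = b - a
        genomic = np.arange(a, b)
        if model.strand == "-":
            offsets = cds_index + np.arange(length)[::-1]  # rightmost base first
        else:
            offsets = cds_index + np.arange(length)
        positions = offsets % 3  # 0-based codon position per genomic base
        overlapped = [
            (max(a, ea), min(b, eb)) for ea, eb in wanted if max(a, ea) < min(b, eb)
        ]
        for oa, ob in overlapped:
            vals = track.values(model.chrom, oa, ob)
            pos = positions[(genomic >= oa) & (genomic < ob)]
            missing = np.isnan(vals)
            if missing.mean() > MAX_MISSING_FRACTION:
                continue
            for k in range(3):
                sel = (pos == k) & ~missing
                sums[k] += vals[sel].sum()
                counts[k] += sel.sum()
        cds_index += length
    if (counts == 0).any():
        return None
    return sums / counts


def neighbor_coding_exons(model: ExonModel, acceptor_start: int, donor_end: int):
    """Nearest coding exons outside [acceptor_start, donor_end): one upstream
    and one downstream when present (genomic sense)."""
    left = [e for e in model.cds if e[1] <= acceptor_start]
    right = [e for e in model.cds if e[0] >= donor_end]
    out = []
    if left:
        out.append(max(left, key=lambda e: e[1]))
    if right:
        out.append(min(right, key=lambda e: e[0]))
    return out


def codon_position_conservation(
    records: Sequence[CircRNARecord],
    models: Sequence[ExonModel],
    track: ConservationTrack,
) -> tuple[pd.DataFrame, dict[int, float]]:
    """Per-circRNA codon-position means for circular vs. neighboring linear
    coding exons, plus a paired two-sided test per position.

    Only coding exons contribute; circRNAs without neighboring coding exons
    (or without frame information) are excluded. The paired comparison is a
    Wilcoxon signed-rank test (the paired form of the rank test) per codon
    position.
    """
    by_gene: dict[str, list[ExonModel]] = {}
    for m in models:
        by_gene.setdefault(m.gene_id, []).append(m)
    rows = []
    for rec in records:
        candidates = by_gene.get(rec.exon_model.gene_id, [])
        host = next((m for m in candidates if m.is_coding()), None)
        if host is None:
            continue
        acc, de = rec.junction.acceptor_start, rec.junction.donor_end
        circ_cds = [
            (max(a, acc), min(b, de)) for a, b in host.cds if max(a, acc) < min(b, de)
        ]
        neighbors = neighbor_coding_exons(host, acc, de)
        if not circ_cds or not neighbors:
            continue
        circ_means = _codon_position_means(host, circ_cds, track)
        neigh_means = _codon_position_means(host, neighbors, track)
        if circ_means is None or neigh_means is None:
            continue
        rows.append(
            {
                "circ_id": rec.circ_id,
                **{f"circ_pos{k + 1}": circ_means[k] for k in range(3)},
                **{f"neighbor_pos{k + 1}": neigh_means[k] for k in range(3)},
            }
        )
    table = pd.DataFrame(rows)
    pvalues: dict[int, float] = {}
    for k in (1, 2, 3):
        if len(table) < 2:
            pvalues[k] = np.nan
            continue
        diff = (table[f"circ_pos{k}"] - table[f"neighbor_pos{k}"]).to_numpy()
        diff[np.isclose(diff, 0.0, atol=1e-10)] = 0.0  # float noise is a tie
        if (diff == 0).all():
            pvalues[k] = 1.0
        else:
            pvalues[k] = float(
                stats.wilcoxon(diff, alternative="two-sided", zero_method="wilcox").pvalue
            )
    return table, pvalues


def matched_conservation_cohort(
    circ_table: pd.DataFrame,
    pool_table: pd.DataFrame,
    n_cohorts: int = DEFAULT_N_COHORTS,
    seed: int = 0,
    bin_width: float = 0.25,
) -> dict:
    """Null distribution for the third-position conservation of circ exons.

    ``circ_table``/``pool_table`` have columns pos1, pos2, pos3 (mean score
    per exon or per circRNA). Each control cohort is sampled from the pool to
    match, bin for bin, the circ set's distribution of mean position-1&2
    scores (bins of ``bin_width``); the circ set's mean position-3 score is
    placed as a percentile within the 1,000 cohort means.
    """
    if len(pool_table) < len(circ_table):
        raise ValueError("control pool smaller than the circ set")
    rng = np.random.default_rng(seed)
    key_circ = ((circ_table["pos1"] + circ_table["pos2"]) / 2 / bin_width).apply(np.floor)
    key_pool = ((pool_table["pos1"] + pool_table["pos2"]) / 2 / bin_width).apply(np.floor)
    pool_by_bin = {b: pool_table.index[key_pool == b].to_numpy() for b in key_pool.unique()}
    bin_counts = key_circ.value_counts()
    cohort_means = np.empty(n_cohorts)
    for c in range(n_cohorts):
        chosen = []
        for b, k in bin_counts.items():
            pool = pool_by_bin.get(b, np.array([]))
            if len(pool) >= k:
                chosen.append(rng.choice(pool, size=int(k), replace=False))
            else:
                if len(pool) == 0:
                    all_pool = pool_table.index.to_numpy()
                    log.warning("empty control bin %s; sampling from full pool", b)
                    chosen.append(rng.choice(all_pool, size=int(k), replace=True))
                else:
                    log.warning("short control bin %s; sampling with replacement", b)
                    chosen.append(rng.choice(pool, size=int(k), replace=True))
        idx = np.concatenate(chosen)
        cohort_means[c] = pool_table.loc[idx, "pos3"].mean()
    circ_mean = circ_table["pos3"].mean()
    percentile = 100.0 * (cohort_means < circ_mean).mean()
    return {
        "circ_pos3_mean": float(circ_mean),
        "cohort_pos3_means": cohort_means,
        "percentile": float(percentile),
    }
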