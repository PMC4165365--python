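"""Cell-type specificity of circular junctions vs. matched linear controls.

The specificity of an expression profile p over T samples is
max_t (1 - sqrt(JSD(p, e_t))) with base-2 Jensen-Shannon divergence and e_t
the idealized single-sample profile; it is 1 iff all expression sits in one
sample and decreases toward uniform profiles. Because junction-spanning read
counts grow with expression, circRNAs are compared against a cohort of
linearly spliced junctions sampled to match the circRNA set's distribution
of total junction-spanning reads (log2 bins).
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import jensenshannon

from ._seq import revcomp
from .formats import ExonModel, GenomeRef, ReadRecord

log = logging.getLogger(__name__)


def js_specificity(values: Sequence[float]) -> float:
    """Specificity score of one feature's per-sample expression values.

    ``values`` are non-negative (junction-spanning read counts); an all-zero
    profile has no defined score and raises ValueError (callers skip such
    features).
    """
    v = np.asarray(values, dtype=float)
    if v.ndim != 1 or len(v) < 2:
        raise ValueError("profile must be a 1-D vector over >=2 samples")
    if (v < 0).any():
        raise ValueError("profile values must be non-negative")
    total = v.sum()
    if total == 0:
        raise ValueError("all-zero profile has no specificity score")
    p = v / total
    best = 0.0
    for t in range(len(p)):
        e = np.zeros_like(p)
        e[t] = 1.0
        score = 1.0 - jensenshannon(p, e, base=2)
        best = max(best, score)
    return float(best)


def score_profiles(profiles: pd.DataFrame) -> pd.Series:
    """js_specificity per row of a features x samples count matrix;
    all-zero rows are skipped."""
    scores = {}
    for feature, row in profiles.iterrows():
        if row.sum() > 0:
            scores[feature] = js_specificity(row.to_numpy())
    return pd.Series(scores, name="specificity")


# ---------------------------------------------------------------------------
# Expression-matched linear cohort
# ---------------------------------------------------------------------------


def _log2_bin(total: float) -> int:
    return int(np.floor(np.log2(total + 1.0)))


def matched_linear_cohort(
    circ_profiles: pd.DataFrame,
    linear_profiles: pd.DataFrame,
    seed: int = 0,
) -> tuple[list, pd.Series, pd.Series]:
    """Sample linear junctions matching the circRNA expression histogram.

    Total junction-spanning reads are binned in unit-width log2(total+1)
    bins; for each bin, as many linear junctions as circRNAs are drawn
    without replacement (with replacement, with a warning, when a bin runs
    short). Returns (cohort ids, circ scores, cohort scores).
    """
    if circ_profiles.empty or linear_profiles.empty:
        raise ValueError("both profile pools must be nonempty")
    rng = np.random.default_rng(seed)
    circ_totals = circ_profiles.sum(axis=1)
    circ_totals = circ_totals[circ_totals > 0]
    lin_totals = linear_profiles.sum(axis=1)
    lin_totals = lin_totals[lin_totals > 0]
    lin_bins: dict[int, list] = {}
    for feature, total in lin_totals.items():
        lin_bins.setdefault(_log2_bin(total), []).append(feature)
    cohort: list = []
    for b, group in circ_totals.groupby(circ_totals.map(_log2_bin)):
        pool = lin_bins.get(b, [])
        k = len(group)
        if len(pool) >= k:
            chosen = rng.choice(pool, size=k, replace=False)
        else:
            if not pool:
                raise ValueError(f"no linear junctions available in expression bin {b}")
            log.warning(
                "expression bin %d has %d linear candidates for %d circRNAs; "
                "sampling with replacement",
                b, len(pool), k,
            )
            chosen = rng.choice(pool, size=k, replace=True)
        cohort.extend(chosen.tolist())
    circ_scores = score_profiles(circ_profiles.loc[circ_totals.index])
    cohort_scores = score_profiles(linear_profiles.loc[cohort])
    return cohort, circ_scores, cohort_scores


# ---------------------------------------------------------------------------
# Linear-junction profiles (control pool)
# ---------------------------------------------------------------------------


def linear_junction_counts(
    models: Sequence[ExonModel],
    reads_by_sample: dict[str, Sequence[ReadRecord]],
    genome: GenomeRef,
    probe_len: int = 20,
) -> pd.DataFrame:
    """Junction-spanning read counts for every annotated exon-exon junction.

    A read spans a linear junction when it contains the 2x``probe_len``-mer
    across the spliced joint (either orientation). Returns a junctions x
    samples count matrix indexed by "gene:exon_i-exon_j" ids.
    """
    words = {}
    for m in models:
        exons = list(reversed(m.exons)) if m.strand == "-" else list(m.exons)
        for i, (up, down) in enumerate(zip(exons, exons[1:])):
            if m.strand == "+":
                word = genome.fetch(m.chrom, up[1] - probe_len, up[1]) + genome.fetch(
                    m.chrom, down[0], down[0] + probe_len
                )
            else:
                word = genome.fetch(m.chrom, up[0], up[0] + probe_len, "-") + genome.fetch(
                    m.chrom, down[1] - probe_len, down[1], "-"
                )
            words[f"{m.transcript_id}:junction{i}"] = word
    samples = sorted(reads_by_sample)
    counts = pd.DataFrame(0, index=list(words), columns=samples)
    for sample in samples:
        for r in reads_by_sample[sample]:
            seqs = (r.sequence, revcomp(r.sequence))
            for jid, word in words.items():
                if any(word in s for s in seqs):
                    counts.loc[jid, sample] += 1
    return counts


# ---------------------------------------------------------------------------
# Circular-fraction matrix
# ---------------------------------------------------------------------------


def cf_matrix(
    counts: dict[str, dict[str, "JunctionCounts"]],
    min_avail: int = 5,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Circular-fraction matrix over well-measured junctions.

    ``counts`` maps junction id -> sample -> JunctionCounts. Rows are kept
    only when both the donor and the acceptor site are supported by
    >= ``min_avail`` reads in every sample. Returns (fractions matrix,
    pairwise Spearman correlation between samples).
    """
    samples = sorted({s for per in counts.values() for s in per})
    rows = {}
    for jid, per_sample in counts.items():
        if set(per_sample) != set(samples):
            continue
        if all(
            per_sample[s].n_donor >= min_avail and per_sample[s].n_acceptor >= min_avail
            for s in samples
        ):
            rows[jid] = [per_sample[s].fraction for s in samples]
    matrix = pd.DataFrame.from_dict(rows, orient="index", columns=samples)
    if matrix.empty:
        log.warning("no junction passes the >=%d-read availability filter", min_avail)
        return matrix, pd.DataFrame(index=samples, columns=samples, dtype=float)
    rho = matrix.corr(method="spearman")
    return matrix, rho
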