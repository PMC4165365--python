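"""miRNA-sponge assessment: canonical seed sites, permutation nulls, clusters.

A miRNA's seed is nucleotides 2-8 of its mature sequence. On a target (DNA
space), the canonical site classes anchored at the position opposite miRNA
nucleotide 1 are: 8mer (perfect match to positions 2-8 plus an A opposite
position 1), 7mer-m8 (match to 2-8), and 7mer-A1 (match to 2-7 plus the A).
The classes are disjoint per occurrence with 8mer taking precedence, so the
total is the combined count of 7- and 8-nucleotide sites. The null model
re-runs the count with each family's 8mer replaced by a random permutation
that preserves its mononucleotide composition, its CG-dinucleotide count and
the terminal A -- a composition-matched control word with similar expected
genome-wide abundance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from functools import lru_cache
from itertools import permutations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ._seq import revcomp, rna_to_dna
from .formats import GenomeRef

log = logging.getLogger(__name__)

SEED_LEN = 7
DEFAULT_N_COHORTS = 1000


# ---------------------------------------------------------------------------
# Families and site words
# ---------------------------------------------------------------------------


@dataclass
class MirnaFamily:
    name: str
    mature: str  # RNA alphabet as given; normalized to DNA internally
    tier: str = "vertebrate"  # vertebrate | mammal

    def __post_init__(self) -> None:
        if len(self.mature) < 8:
            raise ValueError(f"mature sequence of {self.name} shorter than 8 nt")

    @property
    def seed(self) -> str:
        """Nucleotides 2-8 of the mature sequence (DNA space)."""
        return rna_to_dna(self.mature)[1:8]


def site_words(family: MirnaFamily) -> dict[str, str]:
    """Target-site words (DNA space) for one family.

    7mer-m8 is the reverse complement of the seed; 8mer appends the A
    opposite miRNA position 1; 7mer-A1 is the reverse complement of
    positions 2-7 plus that A.
    """
    m8 = revcomp(family.seed)
    return {"8mer": m8 + "A", "7mer-m8": m8, "7mer-A1": m8[1:] + "A"}


def load_families(path) -> list[MirnaFamily]:
    """TSV with columns name, mature sequence, and optional tier."""
    table = pd.read_csv(path, sep="\t", comment="#", header=None)
    out = []
    for row in table.itertuples(index=False):
        tier = row[2] if len(row) > 2 and isinstance(row[2], str) else "vertebrate"
        out.append(MirnaFamily(name=str(row[0]), mature=str(row[1]), tier=tier))
    return out


# ---------------------------------------------------------------------------
# Site counting
# ---------------------------------------------------------------------------


@dataclass
class SeedSiteTally:
    circ_id: str
    family: str
    counts: dict[str, int]

    @property
    def total(self) -> int:
        return sum(self.counts.values())


def _count_words(seq: str, m8: str) -> dict[str, int]:
    """Anchor-based scan: every occurrence of the 6-mer core (seed positions
    2-7 complement) is classified by its m8 and A1 context, once."""
    core = m8[1:]  # 6-mer shared by all three site words
    tally = {"8mer": 0, "7mer-m8": 0, "7mer-A1": 0}
    n = len(seq)
    i = seq.find(core)
    while i != -1:
        has_m8 = i > 0 and seq[i - 1] == m8[0]
        has_a1 = i + len(core) < n and seq[i + len(core)] == "A"
        if has_m8 and has_a1:
            tally["8mer"] += 1
        elif has_m8:
            tally["7mer-m8"] += 1
        elif has_a1:
            tally["7mer-A1"] += 1
        i = seq.find(core, i + 1)
    return tally


def count_sites(
    sequence: str,
    family: MirnaFamily,
    circ_id: str = "",
    wrap_junction: bool = False,
    words: dict[str, str] | None = None,
) -> SeedSiteTally:
    """Canonical site counts in a circRNA's concatenated exonic sequence.

    Sites are not counted across the circular junction unless
    ``wrap_junction`` is set, which appends the first 7 nt to the end for
    circle-aware scanning. ``words`` may supply permuted control words.
    """
    seq = rna_to_dna(sequence)
    if wrap_junction:
        seq = seq + seq[:SEED_LEN]
    w = words if words is not None else site_words(family)
    return SeedSiteTally(circ_id=circ_id, family=family.name, counts=_count_words(seq, w["7mer-m8"]))


def tally_catalog(
    sequences: dict[str, str],
    families: Sequence[MirnaFamily],
    wrap_junction: bool = False,
    words_by_family: dict[str, dict[str, str]] | None = None,
) -> pd.DataFrame:
    """circRNA x family table of total site counts (plus per-class columns)."""
    rows = []
    for circ_id, seq in sequences.items():
        for fam in families:
            words = words_by_family.get(fam.name) if words_by_family else None
            t = count_sites(seq, fam, circ_id, wrap_junction, words)
            rows.append({"circ_id": circ_id, "family": fam.name, **t.counts, "total": t.total})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Permutation null
# ---------------------------------------------------------------------------


def _cg_count(word: str) -> int:
    return sum(1 for i in range(len(word) - 1) if word[i : i + 2] == "CG")


@lru_cache(maxsize=1024)
def valid_permutations(word8: str) -> tuple[str, ...]:
    """All distinct permutations of an 8mer word that keep its mononucleotide
    composition (automatic), its CG-dinucleotide count, and a 3'-terminal A."""
    target_cg = _cg_count(word8)
    seen = set()
    out = []
    for perm in permutations(word8):
        cand = "".join(perm)
        if cand in seen:
            continue
        seen.add(cand)
        if cand[-1] == "A" and _cg_count(cand) == target_cg:
            out.append(cand)
    return tuple(sorted(out))


def permuted_word(word8: str, rng: np.random.Generator) -> str:
    """One uniformly sampled valid permutation (the word itself, with a
    warning, when no other permutation satisfies the constraints)."""
    candidates = valid_permutations(word8)
    if candidates == (word8,):
        log.warning("8mer %s has no valid permutation other than itself", word8)
        return word8
    return candidates[int(rng.integers(0, len(candidates)))]


def permuted_site_words(word8: str, rng: np.random.Generator) -> dict[str, str]:
    """Control words: permute the 8mer, then re-derive the 7mers from it."""
    w = permuted_word(word8, rng)
    return {"8mer": w, "7mer-m8": w[:-1], "7mer-A1": w[1:]}


def permuted_cohorts(
    sequences: dict[str, str],
    families: Sequence[MirnaFamily],
    n_cohorts: int = DEFAULT_N_COHORTS,
    seed: int = 0,
    wrap_junction: bool = False,
) -> dict:
    """Null site-count distributions from permuted control words.

    Per cohort, every family's 8mer is replaced by a valid permutation and
    the counting is rerun. Returns the per-pair null mean and max envelope
    (arrays indexed like the observed table) plus the observed counts.
    """
    rng = np.random.default_rng(seed)
    observed = tally_catalog(sequences, families, wrap_junction)
    totals = np.zeros((n_cohorts, len(observed)))
    for c in range(n_cohorts):
        words_by_family = {
            fam.name: permuted_site_words(site_words(fam)["8mer"], rng) for fam in families
        }
        null = tally_catalog(sequences, families, wrap_junction, words_by_family)
        totals[c] = null["total"].to_numpy()
    return {
        "observed": observed,
        "null_totals": totals,
        "null_mean": totals.mean(axis=0),
        "null_max": totals.max(axis=0),
    }


# ---------------------------------------------------------------------------
# Crosslink-cluster analyses
# ---------------------------------------------------------------------------


@dataclass
class ClusterTrack:
    """Crosslink clusters of one RNA-binding protein, per chromosome."""

    protein: str
    intervals: dict[str, list[tuple[int, int]]]

    def __post_init__(self) -> None:
        self.intervals = {c: sorted(ivs) for c, ivs in self.intervals.items()}

    @classmethod
    def from_bed(cls, path, protein: str = "") -> "ClusterTrack":
        table = pd.read_csv(path, sep="\t", comment="#", header=None, usecols=[0, 1, 2])
        intervals: dict[str, list[tuple[int, int]]] = {}
        for row in table.itertuples(index=False):
            intervals.setdefault(str(row[0]), []).append((int(row[1]), int(row[2])))
        return cls(protein=protein, intervals=intervals)

    def overlapping(self, chrom: str, exons: Sequence[tuple[int, int]]) -> list[tuple[int, int]]:
        out = []
        for iv in self.intervals.get(chrom, []):
            if any(iv[0] < b and a < iv[1] for a, b in exons):
                out.append(iv)
        return out


def cluster_density_compare(
    clusters: ClusterTrack,
    circ_exon_sets: Sequence[tuple[str, list[tuple[int, int]]]],
    neighbor_exon_sets: Sequence[tuple[str, list[tuple[int, int]]]],
) -> tuple[pd.DataFrame, float]:
    """Paired cluster densities (clusters per exonic kb) for circular vs.
    neighboring exon sets, with a paired two-sided signed-rank test.

    The two sequences must be index-aligned (one pair per circRNA); entries
    with an empty neighbor exon set are excluded.
    """
    rows = []
    for (chrom_c, circ_exons), (chrom_n, neigh_exons) in zip(circ_exon_sets, neighbor_exon_sets):
        if not neigh_exons:
            continue
        kb_c = sum(b - a for a, b in circ_exons) / 1000.0
        kb_n = sum(b - a for a, b in neigh_exons) / 1000.0
        if kb_c == 0 or kb_n == 0:
            continue
        rows.append(
            {
                "circ_density": len(clusters.overlapping(chrom_c, circ_exons)) / kb_c,
                "neighbor_density": len(clusters.overlapping(chrom_n, neigh_exons)) / kb_n,
            }
        )
    table = pd.DataFrame(rows)
    if len(table) < 2:
        return table, float("nan")
    diff = table["circ_density"] - table["neighbor_density"]
    if (diff == 0).all():
        return table, 1.0
    p = float(stats.wilcoxon(diff, alternative="two-sided", zero_method="wilcox").pvalue)
    return table, p


def assign_clusters_to_family(
    clusters: ClusterTrack,
    records: Sequence,
    genome: GenomeRef,
    families: Sequence[MirnaFamily],
) -> pd.DataFrame:
    """Cluster counts per circRNA x family.

    A cluster overlapping a circle's exons is assigned to every family whose
    8mer/7mer-m8/7mer-A1 word occurs in the cluster's sequence (the circle's
    strand orientation).
    """
    rows = []
    for rec in records:
        j = rec.junction
        hits = clusters.overlapping(j.chrom, rec.exon_model.exons)
        tallies = {fam.name: 0 for fam in families}
        for a, b in hits:
            seq = genome.fetch(j.chrom, a, b, j.strand)
            for fam in families:
                if any(word in seq for word in site_words(fam).values()):
                    tallies[fam.name] += 1
        for fam in families:
            rows.append({"circ_id": rec.circ_id, "family": fam.name, "clusters": tallies[fam.name]})
    return pd.DataFrame(rows)
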