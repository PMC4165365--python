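"""Cross-species comparison and codon-position conservation statistics."""

import numpy as np
import pandas as pd
import pytest

from circkit.conservation import (
    ConservationTrack,
    CoordinateMap,
    cf_correlation,
    codon_position_conservation,
    matched_conservation_cohort,
    ortholog_circ_enrichment,
    overlap_class,
)
from circkit.detect import BackspliceJunction
from circkit.formats import ExonModel
from circkit.quantify import CircRNARecord, JunctionCounts


def _record(circ_id, chrom, acc, de, strand="+", gene="g"):
    j = BackspliceJunction(chrom, strand, acc, de, "GT-AG")
    model = ExonModel(gene, circ_id, chrom, strand, exons=[(acc, de)])
    return CircRNARecord(circ_id, j, model)


def _identity_map(chrom="chr1", length=100_000):
    pairs = pd.DataFrame(
        [[chrom, 0, length, "+", chrom, 0, length, "+"]],
        columns=["chromA", "startA", "endA", "strandA", "chromB", "startB", "endB", "strandB"],
    )
    return CoordinateMap(pairs)


class TestOrthologEnrichment:
    def test_enrichment_table_proportions(self):
        """A 66/34/19/81 cross-tabulation yields 66% vs 19% proportions."""
        orth = pd.DataFrame(
            {"geneA": [f"m{i}" for i in range(200)], "geneB": [f"h{i}" for i in range(200)]}
        )
        ga = {f"m{i}" for i in range(100)}
        gb = {f"h{i}" for i in range(66)} | {f"h{i}" for i in range(100, 119)}
        res = ortholog_circ_enrichment(ga, gb, orth)
        assert res["table"].tolist() == [[66, 34], [19, 81]]
        assert res["prop_b_circ_given_a_circ"] == pytest.approx(0.66)
        assert res["prop_b_circ_given_a_no_circ"] == pytest.approx(0.19)
        assert res["odds_ratio"] > 1 and res["p_value"] < 1e-6

    def test_independent_labels_odds_near_one(self):
        """Permutation oracle: independent labels give OR ~ 1 on average."""
        rng = np.random.default_rng(0)
        orth = pd.DataFrame(
            {"geneA": [f"m{i}" for i in range(500)], "geneB": [f"h{i}" for i in range(500)]}
        )
        ors = []
        for _ in range(20):
            ga = {f"m{i}" for i in rng.choice(500, 150, replace=False)}
            gb = {f"h{i}" for i in rng.choice(500, 150, replace=False)}
            ors.append(ortholog_circ_enrichment(ga, gb, orth)["odds_ratio"])
        assert np.median(ors) == pytest.approx(1.0, abs=0.35)

    def test_empty_catalogs(self):
        orth = pd.DataFrame({"geneA": ["m1"], "geneB": ["h1"]})
        res = ortholog_circ_enrichment(set(), set(), orth)
        assert res["table"][0].sum() == 0
        assert np.isnan(res["prop_b_circ_given_a_circ"])

    def test_duplicate_pairs_rejected(self):
        orth = pd.DataFrame({"geneA": ["m1", "m1"], "geneB": ["h1", "h2"]})
        with pytest.raises(ValueError):
            ortholog_circ_enrichment(set(), set(), orth)


class TestOverlapClass:
    def test_identity_map_same_sites(self):
        target = [_record("h1", "chr1", 100, 400)]
        j = BackspliceJunction("chr1", "+", 100, 400, "GT-AG")
        assert overlap_class(j, target, _identity_map()) == "same_splice_sites"

    def test_within_tolerance_still_same(self):
        target = [_record("h1", "chr1", 102, 398)]
        j = BackspliceJunction("chr1", "+", 100, 400, "GT-AG")
        assert overlap_class(j, target, _identity_map()) == "same_splice_sites"

    def test_boundaries_off_by_fifty_is_partial(self):
        target = [_record("h1", "chr1", 150, 450)]
        j = BackspliceJunction("chr1", "+", 100, 400, "GT-AG")
        assert overlap_class(j, target, _identity_map()) == "partial_overlap"

    def test_gene_desert_no_overlap(self):
        target = [_record("h1", "chr1", 10_000, 10_400)]
        j = BackspliceJunction("chr1", "+", 100, 400, "GT-AG")
        assert overlap_class(j, target, _identity_map()) == "no_overlap"

    def test_unmappable_reported_separately(self):
        target = [_record("h1", "chr1", 100, 400)]
        j = BackspliceJunction("chr2", "+", 100, 400, "GT-AG")
        assert overlap_class(j, target, _identity_map()) == "unmappable"

    def test_classes_partition(self):
        rng = np.random.default_rng(4)
        target = [_record(f"h{i}", "chr1", a, a + 300) for i, a in enumerate(range(0, 5000, 500))]
        classes = []
        for _ in range(50):
            acc = int(rng.integers(0, 8000))
            j = BackspliceJunction("chr1", "+", acc, acc + int(rng.integers(100, 400)), "GT-AG")
            classes.append(overlap_class(j, target, _identity_map()))
        assert set(classes) <= {"same_splice_sites", "partial_overlap", "no_overlap", "unmappable"}
        assert len(classes) == 50


class TestCfCorrelation:
    @staticmethod
    def _counts_from_fractions(fracs, n=50):
        out = {}
        for i, f in enumerate(fracs):
            j = int(round(f * n))
            out[f"c{i}"] = {"s1": JunctionCounts(n, n, j, "s1")}
        return out

    def test_identical_vectors_rho_one(self):
        fr = np.linspace(0.1, 0.9, 10)
        a = self._counts_from_fractions(fr)
        rho, p, n = cf_correlation([(f"c{i}", f"c{i}") for i in range(10)], a, a)
        assert rho == pytest.approx(1.0) and n == 10

    def test_independent_fractions_rho_near_zero(self):
        rng = np.random.default_rng(6)
        rhos = []
        for _ in range(20):
            a = self._counts_from_fractions(rng.uniform(0.05, 0.95, 30))
            b = self._counts_from_fractions(rng.uniform(0.05, 0.95, 30))
            rho, _, _ = cf_correlation([(f"c{i}", f"c{i}") for i in range(30)], a, b)
            rhos.append(rho)
        assert abs(np.median(rhos)) < 0.2

    def test_correlated_fractions_moderate_positive_rho(self):
        """Noisy shared fractions: a moderate positive correlation, the
        qualitative cross-species behavior."""
        rng = np.random.default_rng(7)
        base = rng.uniform(0.1, 0.9, 130)
        a = self._counts_from_fractions(base)
        noisy = np.clip(base + rng.normal(0, 0.35, 130), 0.0, 1.0)
        b = self._counts_from_fractions(noisy)
        rho, p, n = cf_correlation([(f"c{i}", f"c{i}") for i in range(130)], a, b)
        assert n == 130 and 0.1 < rho < 0.95 and p < 0.05

    def test_too_few_pairs_is_error(self):
        a = self._counts_from_fractions([0.5])
        with pytest.raises(ValueError):
            cf_correlation([("c0", "c0")], a, a)

    def test_unexpressed_samples_excluded_from_average(self):
        counts = {"c0": {"s1": JunctionCounts(10, 10, 5, "s1"), "s2": JunctionCounts(0, 0, 0, "s2")}}
        from circkit.conservation import average_expressed_fraction

        assert average_expressed_fraction(counts["c0"]) == pytest.approx(5 / 16)


def _coding_world(n_genes=30, seed=0):
    """Toy coding genes: 3 CDS exons each; the middle exon circularizes."""
    rng = np.random.default_rng(seed)
    models, records = [], []
    pos = 0
    for i in range(n_genes):
        lens = rng.integers(60, 120, size=3) * 3  # keep frames varied but whole codons optional
        exons = []
        for L in lens:
            exons.append((pos, pos + int(L)))
            pos += int(L) + 90
        m = ExonModel(f"g{i}", f"g{i}.t1", "chr1", "+", exons=exons, cds=exons)
        models.append(m)
        acc, de = exons[1]
        records.append(
            CircRNARecord(
                f"c{i}", BackspliceJunction("chr1", "+", acc, de, "GT-AG"),
                ExonModel(f"g{i}", f"c{i}", "chr1", "+", exons=[exons[1]], cds=[exons[1]]),
            )
        )
    return models, records, pos


def _track_from_array(scores):
    return ConservationTrack({"chr1": {i: float(v) for i, v in enumerate(scores)}})


class TestCodonPositionConservation:
    def test_constant_track_all_p_one(self):
        models, records, length = _coding_world()
        track = _track_from_array(np.full(length, 1.3))
        table, pvals = codon_position_conservation(records, models, track)
        assert len(table) == len(records)
        for k in (1, 2, 3):
            assert np.allclose(table[f"circ_pos{k}"], 1.3)
            assert pvals[k] == 1.0

    def test_frame_propagation_oracle(self):
        """Codon position of base b is ((index within spliced CDS) mod 3)+1:
        a track valued by that rule produces means exactly 1, 2, 3."""
        models, records, length = _coding_world(n_genes=5)
        scores = np.zeros(length)
        for m in models:
            idx = 0
            for a, b in m.cds:
                for g in range(a, b):
                    scores[g] = (idx % 3) + 1
                    idx += 1
        track = _track_from_array(scores)
        table, _ = codon_position_conservation(records, models, track)
        for k in (1, 2, 3):
            assert np.allclose(table[f"circ_pos{k}"], k)
            assert np.allclose(table[f"neighbor_pos{k}"], k)

    def test_planted_position3_shift_detected_only_there(self):
        """+0.5 at position 3 of circular exons: position-3 test significant,
        positions 1-2 not (constructed-signal oracle)."""
        models, records, length = _coding_world(n_genes=40, seed=3)
        rng = np.random.default_rng(12)
        scores = rng.normal(0, 0.3, length)
        for m, rec in zip(models, records):
            idx = 0
            circ = rec.exon_model.exons[0]
            for a, b in m.cds:
                for g in range(a, b):
                    if idx % 3 == 2 and circ[0] <= g < circ[1]:
                        scores[g] += 0.5
                    idx += 1
        table, pvals = codon_position_conservation(records, models, _track_from_array(scores))
        assert pvals[3] < 0.01
        assert pvals[1] > 0.05 and pvals[2] > 0.05

    def test_missing_coverage_excludes(self):
        models, records, length = _coding_world(n_genes=3)
        track = ConservationTrack({"chr1": {}})  # empty track
        table, pvals = codon_position_conservation(records, models, track)
        assert table.empty


class TestMatchedConservationCohort:
    @staticmethod
    def _tables(seed=0, n_circ=40, n_pool=400, shift=0.0):
        rng = np.random.default_rng(seed)
        pool = pd.DataFrame(
            {
                "pos1": rng.normal(1.0, 0.3, n_pool),
                "pos2": rng.normal(1.0, 0.3, n_pool),
                "pos3": rng.normal(0.2, 0.3, n_pool),
            }
        )
        circ = pool.sample(n=n_circ, random_state=1).reset_index(drop=True).copy()
        circ["pos3"] += shift
        return circ, pool

    def test_self_null_percentile_central(self):
        circ, pool = self._tables()
        res = matched_conservation_cohort(circ, pool, n_cohorts=400, seed=2)
        assert 5 < res["percentile"] < 95

    def test_planted_shift_extreme_percentile(self):
        circ, pool = self._tables(shift=0.5)
        res = matched_conservation_cohort(circ, pool, n_cohorts=400, seed=2)
        assert res["percentile"] > 99

    def test_pool_smaller_than_set_is_error(self):
        circ, pool = self._tables()
        with pytest.raises(ValueError):
            matched_conservation_cohort(pool, circ)


class TestCoordinateMapStrand:
    def test_strand_flip_reverses_offsets(self):
        pairs = pd.DataFrame(
            [["chr1", 0, 1000, "+", "chr9", 5000, 6000, "-"]],
            columns=["chromA", "startA", "endA", "strandA", "chromB", "startB", "endB", "strandB"],
        )
        cm = CoordinateMap(pairs)
        chrom, pos, flipped = cm.map_position("chr1", 10)
        assert (chrom, pos, flipped) == ("chr9", 5990, True)

    def test_degenerate_interval_rejected(self):
        pairs = pd.DataFrame(
            [["chr1", 10, 10, "+", "chr9", 0, 5, "+"]],
            columns=["chromA", "startA", "endA", "strandA", "chromB", "startB", "endB", "strandB"],
        )
        with pytest.raises(ValueError):
            CoordinateMap(pairs)
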