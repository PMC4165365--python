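"""Shared fixtures: tiny hand-built loci and seeded simulated datasets."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from circkit import simulate as sim
from circkit.detect import detect_junctions
from circkit.formats import ExonModel, GenomeRef
from circkit.pipeline import build_records, quantify_records


@pytest.fixture(scope="session")
def toy_genome():
    """A 300-nt chromosome with one 3-exon plus-strand gene, hand-placed.

    exon1 [20,60) exon2 [80,120) exon3 [140,180); introns carry GT..AG.
    """
    rng = np.random.default_rng(42)
    bases = list("".join(np.array(list("ACGT"))[rng.integers(0, 4, 300)]))
    for pos, dinuc in [(60, "GT"), (78, "AG"), (120, "GT"), (138, "AG")]:
        bases[pos : pos + 2] = dinuc
    genome = GenomeRef({"chr1": "".join(bases)})
    model = ExonModel(
        gene_id="toy",
        transcript_id="toy.t1",
        chrom="chr1",
        strand="+",
        exons=[(20, 60), (80, 120), (140, 180)],
        cds=[(20, 60), (80, 120), (140, 180)],
    )
    return genome, model


@pytest.fixture(scope="session")
def sim_world():
    """Three genes (mixed strands), two samples, circles at f=0.5 and 0.3."""
    genome, models = sim.make_genome(n_genes=3, seed=101)
    fractions = {m.gene_id: {"s1": 0.5, "s2": 0.3} for m in models}
    truth = sim.make_truth(models, fractions, seed=101)
    reads_by_sample = {
        "s1": sim.make_reads(genome, models, truth, 1200, "s1", seed=201),
        "s2": sim.make_reads(genome, models, truth, 1200, "s2", seed=202),
    }
    return {
        "genome": genome,
        "models": models,
        "truth": truth,
        "reads_by_sample": reads_by_sample,
    }


@pytest.fixture(scope="session")
def sim_pipeline(sim_world):
    """Discovery + quantification run on the simulated world."""
    all_reads = [r for reads in sim_world["reads_by_sample"].values() for r in reads]
    candidates, mapped = detect_junctions(all_reads, sim_world["genome"])
    gt_ag = [j for j in candidates if j.signal_class == "GT-AG"]
    records = build_records(gt_ag, sim_world["models"])
    quantify_records(records, sim_world["reads_by_sample"], sim_world["genome"])
    return {**sim_world, "candidates": candidates, "mapped": mapped, "records": records}
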