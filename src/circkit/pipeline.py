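"""End-to-end orchestration: detect -> quantify -> filter -> catalog.

Thin driver used by both the command-line interface and tests; every stage
is a plain library call, outputs are re-loadable text tables, and the run is
deterministic given (inputs, config, seed).
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
from dataclasses import dataclass, field
from typing import Sequence

import pandas as pd

from . import __version__
from .detect import BackspliceJunction, detect_junctions
from .formats import ExonModel, GenomeRef, ReadRecord, load_annotation, load_genome, read_fastq, write_catalog
from .quantify import (
    CircRNARecord,
    assign_exon_model,
    catalog_filter,
    count_junction_reads,
)

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Paths, thresholds and the seed for one pipeline run.

    Thresholds default to the printed constants of the method: >=2 supporting
    reads, circular fraction >=10% in >=2 samples, junction span <=100 kb,
    20-nt probes, 10-nt signal windows with <=5-nt breakpoint shifts, 200-nt
    retention windows, <400-nt circles for the mate test, 1,000 permutation
    cohorts.
    """

    genome: str = ""
    annotation: str = ""
    samples: dict[str, list[str]] = field(default_factory=dict)  # sample -> FASTQ paths
    out_dir: str = "circkit_out"
    min_reads: int = 2
    min_fraction: float = 0.10
    min_samples: int = 2
    max_span: int = 100_000
    anchor_min: int = 20
    probe_len: int = 20
    window: int = 10
    shift_max: int = 5
    retention_window: int = 200
    maxlen_trans: int = 400
    cohorts: int = 1000
    seed: int = 0

    def validate(self) -> None:
        for name in (
            "min_reads", "min_samples", "max_span", "anchor_min", "probe_len",
            "window", "shift_max", "retention_window", "maxlen_trans", "cohorts",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"threshold {name} must be positive")
        if not 0 <= self.min_fraction:
            raise ValueError("min_fraction must be non-negative")


def load_config(path) -> RunConfig:
    """Parse a key = value config file; ``sample.<name>`` keys list FASTQs."""
    cfg = RunConfig()
    with open(path) as fh:
        for line in fh:
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            key, _, value = line.partition("=")
            key, value = key.strip(), value.strip()
            if key.startswith("sample."):
                cfg.samples[key[len("sample."):]] = [v.strip() for v in value.split(",")]
            elif hasattr(cfg, key):
                current = getattr(cfg, key)
                if isinstance(current, bool):
                    setattr(cfg, key, value.lower() in ("1", "true", "yes"))
                elif isinstance(current, int):
                    setattr(cfg, key, int(value))
                elif isinstance(current, float):
                    setattr(cfg, key, float(value))
                else:
                    setattr(cfg, key, value)
            else:
                raise ValueError(f"unknown config key {key!r}")
    return cfg


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------


def build_records(
    junctions: Sequence[BackspliceJunction],
    models: Sequence[ExonModel],
) -> list[CircRNARecord]:
    """Attach exon models and annotation classes to called junctions."""
    records = []
    for j in junctions:
        model, annotation_class = assign_exon_model(j, models)
        records.append(
            CircRNARecord(
                circ_id=j.junction_id,
                junction=j,
                exon_model=model,
                annotation_class=annotation_class,
            )
        )
    return records


def quantify_records(
    records: Sequence[CircRNARecord],
    reads_by_sample: dict[str, Sequence[ReadRecord]],
    genome: GenomeRef,
    probe_len: int = 20,
) -> None:
    """Fill per-sample junction counts and circular fractions in place."""
    for rec in records:
        for sample_id, reads in sorted(reads_by_sample.items()):
            counts = count_junction_reads(
                rec.junction, reads, genome, rec.exon_model, probe_len, sample_id=sample_id
            )
            rec.counts[sample_id] = counts
            rec.fractions[sample_id] = counts.fraction


def counts_table(records: Sequence[CircRNARecord]) -> pd.DataFrame:
    rows = []
    for rec in records:
        for sample_id, c in sorted(rec.counts.items()):
            rows.append(
                {
                    "circ_id": rec.circ_id,
                    "sample_id": sample_id,
                    "n_donor": c.n_donor,
                    "n_acceptor": c.n_acceptor,
                    "n_junction": c.n_junction,
                    "fraction": c.fraction,
                }
            )
    return pd.DataFrame(
        rows, columns=["circ_id", "sample_id", "n_donor", "n_acceptor", "n_junction", "fraction"]
    )


def run_pipeline(config: RunConfig) -> dict:
    """Run discovery and quantification per the config; write the catalog.

    Returns a dict with the catalog records, the full candidate set, the
    per-sample counts table and output paths. Fails fast, naming the stage,
    when an input is missing.
    """
    config.validate()
    for label, path in [("genome", config.genome)] + [
        (f"reads[{s}]", p) for s, paths in config.samples.items() for p in paths
    ]:
        if not path or not os.path.exists(path):
            raise FileNotFoundError(f"stage input: missing {label}: {path!r}")
    if not config.samples:
        raise FileNotFoundError("stage input: no samples configured")

    genome = load_genome(config.genome)
    models = load_annotation(config.annotation) if config.annotation else []

    reads_by_sample: dict[str, list[ReadRecord]] = {}
    for sample_id, paths in sorted(config.samples.items()):
        reads: list[ReadRecord] = []
        for p in paths:
            reads.extend(read_fastq(p, sample_id=sample_id))
        reads_by_sample[sample_id] = reads
    all_reads = [r for reads in reads_by_sample.values() for r in reads]

    log.info("detect: %d reads, %d samples", len(all_reads), len(reads_by_sample))
    candidates, mapped = detect_junctions(
        all_reads,
        genome,
        min_reads=config.min_reads,
        anchor_min=config.anchor_min,
        max_span=config.max_span,
    )
    gt_ag = [j for j in candidates if j.signal_class == "GT-AG"]
    log.info("detect: %d candidates (%d GT-AG)", len(candidates), len(gt_ag))

    records = build_records(gt_ag, models)
    quantify_records(records, reads_by_sample, genome, probe_len=config.probe_len)
    catalog, high_fraction = catalog_filter(
        records, min_fraction=config.min_fraction, min_samples=config.min_samples
    )
    log.info("catalog: %d circRNAs (%d high-fraction)", len(catalog), len(high_fraction))

    os.makedirs(config.out_dir, exist_ok=True)
    catalog_path = os.path.join(config.out_dir, "catalog.tsv")
    counts_path = os.path.join(config.out_dir, "junction_counts.tsv")
    provenance_path = os.path.join(config.out_dir, "run_config.json")
    write_catalog(catalog, catalog_path)
    counts_table(records).to_csv(counts_path, sep="\t", index=False)
    with open(provenance_path, "w") as fh:
        json.dump(
            {"circkit_version": __version__, **dataclasses.asdict(config)},
            fh,
            indent=2,
            sort_keys=True,
        )
        fh.write("\n")

    return {
        "genome": genome,
        "models": models,
        "reads_by_sample": reads_by_sample,
        "candidates": candidates,
        "mapped": mapped,
        "records": records,
        "catalog": catalog,
        "high_fraction": high_fraction,
        "paths": {
            "catalog": catalog_path,
            "counts": counts_path,
            "provenance": provenance_path,
        },
    }
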