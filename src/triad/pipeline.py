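"""End-to-end orchestration: validate -> enumerate -> simulate -> call -> profile.

A :class:`RunConfig` captures every input path, library parameter and seed
so that a whole run is reproducible from one JSON file.  Outputs are plain
TSV/JSON artifacts, each re-loadable by the module that produced it.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import sys
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from triad import genemodel, mechanism, diversity, readsim, indelcaller, biasprofile

logger = logging.getLogger("triad")


@dataclass
class RunConfig:
    """Full configuration of one pipeline run; JSON round-trippable."""

    target_fasta: str | None = None
    reads_fastq: str | None = None
    output_dir: str = "triad_out"
    kind: str = "del3"
    # synthetic target (used when no FASTA is given)
    target_length: int = 999
    target_gc: float = 0.5
    # simulator
    simulate: bool = True
    n_variants: int = 300
    mean_depth: float = 30.0
    error_rate: float = 0.001
    frameshift_rate: float = 0.04
    abundance_sigma: float = 1.0
    read_mode: str = "merged"
    # alignment scoring
    match: float = 5.0
    mismatch: float = -4.0
    gap_open: float = 15.0
    gap_extend: float = 0.5
    # analysis thresholds
    consensus_threshold: float = 0.75
    censor_floor: float = 0.01
    # seeds
    seed: int = 0

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        data = json.loads(Path(path).read_text())
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


class StageError(RuntimeError):
    """A pipeline stage failed; message names the stage."""


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages and write all artifacts.

    Returns a report dict (also written as ``report.json``) with per-stage
    summaries, including closed-loop recovery of simulated truth edits
    when the simulator is enabled.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"config": asdict(config), "stages": {}}

    # -- validate -----------------------------------------------------------
    try:
        if config.target_fasta:
            gene = genemodel.read_fasta(config.target_fasta)
        else:
            gene = genemodel.generate_synthetic_target(
                config.target_length, config.target_gc, seed=config.seed)
        hits = genemodel.scan_restriction_sites(gene.context)
        if hits:
            raise ValueError(f"{len(hits)} forbidden restriction site(s) present")
    except Exception as e:
        raise StageError(f"validate: {e}") from e
    genemodel.write_fasta(gene, out / "target.fasta")
    report["stages"]["validate"] = {"gene_id": gene.id, "length": len(gene.seq)}

    # -- enumerate / diversity ---------------------------------------------
    try:
        sites = mechanism.enumerate_sites(gene, config.kind)
        naive = diversity.theoretical_diversity(gene, config.kind, "dna_naive")
        report["stages"]["enumerate"] = {"n_sites": len(sites), "dna_naive": naive.count}
        if naive.count <= 200_000:
            unique = diversity.theoretical_diversity(gene, config.kind, "dna_unique")
            report["stages"]["enumerate"]["dna_unique"] = unique.count
    except Exception as e:
        raise StageError(f"enumerate: {e}") from e

    # -- simulate ------------------------------------------------------------
    reads: list[tuple[str, str]]
    truth = None
    if config.simulate:
        try:
            sample = readsim.sample_library(
                gene, config.kind, config.n_variants,
                frameshift_rate=config.frameshift_rate,
                abundance_sigma=config.abundance_sigma, seed=config.seed)
            readset = readsim.simulate_reads(
                sample, mean_depth=config.mean_depth, error_rate=config.error_rate,
                mode=config.read_mode, seed=config.seed + 1)
            readsim.write_fastq(readset, out / "reads.fastq")
            readsim.write_truth(readset, out / "truth.tsv")
            reads, truth = readset.records, readset.truth
        except Exception as e:
            raise StageError(f"simulate: {e}") from e
        report["stages"]["simulate"] = {"n_variants": len(sample.members),
                                        "n_reads": len(readset.records),
                                        "n_frameshift_variants": sample.n_frameshift()}
    elif config.reads_fastq:
        reads = readsim.read_fastq(config.reads_fastq)
    else:
        raise StageError("call: no reads available (set simulate or reads_fastq)")

    # -- call ----------------------------------------------------------------
    try:
        scoring = indelcaller.AlignmentScoring(
            match=config.match, mismatch=config.mismatch,
            gap_open=config.gap_open, gap_extend=config.gap_extend)
        calls, dropped = indelcaller.process_reads(reads, gene.seq, scoring)
        table = indelcaller.aggregate_counts(calls, len(gene.seq))
        summary = indelcaller.summarize_calls(calls)
        summary["unmerged_pairs_dropped"] = dropped
    except Exception as e:
        raise StageError(f"call: {e}") from e
    indelcaller.calls_table(calls).to_csv(out / "calls.tsv", sep="\t", index=False)
    table.edits.to_csv(out / "counts.tsv", sep="\t", index=False)
    (out / "call_summary.json").write_text(json.dumps(summary, indent=2))
    report["stages"]["call"] = summary

    if truth is not None:
        report["stages"]["call"]["truth_recovery"] = truth_recovery(calls, truth)

    # -- profile -------------------------------------------------------------
    try:
        pwm = biasprofile.transposition_pwm(table, gene, threshold=config.consensus_threshold)
        cov = biasprofile.coverage_summary(table, gene)
        gc = biasprofile.gc_profile(gene)
    except Exception as e:
        raise StageError(f"profile: {e}") from e
    pwm.to_frame().to_csv(out / "pwm.tsv", sep="\t")
    profile = {"consensus": pwm.consensus,
               "position_coverage": cov.position_coverage,
               "reads_per_variant_histogram": cov.histogram,
               "gc_mean": float(np.mean(gc))}
    (out / "profile.json").write_text(json.dumps(profile, indent=2))
    report["stages"]["profile"] = profile

    (out / "report.json").write_text(json.dumps(report, indent=2))
    return report


def truth_recovery(calls, truth: pd.DataFrame) -> dict:
    """Fraction of in-frame truth reads called with the exact canonical edit."""
    by_id = {}
    for c in calls:
        rid = c.read_id.split("/")[0]
        by_id[rid] = c
    n = exact = 0
    for _, row in truth.iterrows():
        if not row["in_frame"]:
            continue
        c = by_id.get(row["read_id"])
        n += 1
        if c is None:
            continue
        ins = row["inserted"] if isinstance(row["inserted"], str) else ""
        if (c.left_pos == row["left_pos"] and c.length == row["length"]
                and c.inserted == ins and c.kind in ("deletion", "insertion")):
            exact += 1
    return {"n_in_frame_reads": n, "exact_calls": exact,
            "recovery": exact / n if n else 0.0}
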