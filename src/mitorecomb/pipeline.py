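"""End-to-end composition: quartets -> read classification -> rates -> report.

The pipeline ties the stages together for both real inputs (genome + repeat
annotations + long reads or precomputed PAF alignments) and simulated inputs
(a :class:`~mitorecomb.synthetic_data.SimulationConfig`).  All stages are
deterministic given the seed and inputs; stage logs go to standard error.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from . import io as mio
from .read_support import AlignmentRecord, QuartetIndex, SupportLabel, classify_read, count_support
from .recomb_stats import (
    CorrelationResult,
    RecombinationRecord,
    SupportCounts,
    length_rate_correlation,
    make_report,
)
from .repeat_model import CircularGenome, ConformationQuartet, RepeatPair, build_quartet
from .synthetic_data import SimulationConfig, generate_master_circle, simulate_reads

logger = logging.getLogger("mitorecomb")

__all__ = [
    "PipelineParams",
    "build_quartets",
    "classify_reads",
    "classify_paf",
    "summarize",
    "run_simulated_pipeline",
]


@dataclass
class PipelineParams:
    """Thresholds shared across pipeline stages."""

    min_flank: int = 100
    min_flank_contig: int = 1000
    min_identity: float = 0.7
    matcher_k: int = 15

    def __post_init__(self) -> None:
        if self.min_flank <= 0 or self.min_flank_contig <= 0:
            raise ValueError("flank thresholds must be positive")
        if not 0 < self.min_identity <= 1:
            raise ValueError("min_identity must lie in (0, 1]")


def build_quartets(
    genome: CircularGenome,
    repeats: Sequence[RepeatPair],
    params: PipelineParams = PipelineParams(),
) -> dict[str, ConformationQuartet]:
    out = {}
    for rp in repeats:
        out[rp.id] = build_quartet(genome, rp, min_flank_contig=params.min_flank_contig)
    logger.info("built %d conformation quartets", len(out))
    return out


def classify_reads(
    quartets: Mapping[str, ConformationQuartet],
    reads: Iterable[tuple[str, str]],
    params: PipelineParams = PipelineParams(),
    focal: Mapping[str, str] | None = None,
) -> list[SupportLabel]:
    """Classify reads against quartets with the built-in matcher.

    Without ``focal``, every read is evaluated against every quartet (one
    label per (read, repeat)).  With ``focal`` (read_id -> repeat_id, as
    recorded by junction-mode simulation), each read is evaluated only
    against its focal repeat -- junction-mode reads are sampled per repeat,
    so only those pairs are meaningful evidence.
    """
    reads = list(reads)
    indexes = {rid: QuartetIndex(q, k=params.matcher_k) for rid, q in quartets.items()}
    labels: list[SupportLabel] = []
    for rid, index in indexes.items():
        n_done = 0
        for read_id, seq in reads:
            if focal is not None and focal.get(read_id) != rid:
                continue
            records = index.match(read_id, seq)
            labels.append(
                classify_read(
                    records,
                    quartets[rid],
                    min_flank=params.min_flank,
                    min_identity=params.min_identity,
                    read_id=read_id,
                )
            )
            n_done += 1
        logger.info("repeat %s: classified %d reads", rid, n_done)
    return labels


def classify_paf(
    quartets: Mapping[str, ConformationQuartet],
    records: Sequence[AlignmentRecord],
    params: PipelineParams = PipelineParams(),
) -> list[SupportLabel]:
    """Classify externally aligned reads (PAF records) per (read, repeat)."""
    grouped: dict[tuple[str, str], list[AlignmentRecord]] = {}
    for rec in records:
        if rec.repeat_id not in quartets:
            raise ValueError(f"PAF references unknown repeat {rec.repeat_id!r}")
        grouped.setdefault((rec.read_id, rec.repeat_id), []).append(rec)
    labels = []
    for (read_id, rid), recs in sorted(grouped.items()):
        labels.append(
            classify_read(
                recs,
                quartets[rid],
                min_flank=params.min_flank,
                min_identity=params.min_identity,
            )
        )
    return labels


def summarize(
    labels: Sequence[SupportLabel],
    repeats: Sequence[RepeatPair],
    quartets: Mapping[str, ConformationQuartet] | None = None,
) -> tuple[list[SupportCounts], pd.DataFrame, CorrelationResult | None]:
    """Counts per repeat, report table, and (when >= 3 rates) correlation."""
    by_repeat: dict[str, list[SupportLabel]] = {rp.id: [] for rp in repeats}
    for l in labels:
        if l.repeat_id in by_repeat:
            by_repeat[l.repeat_id].append(l)
    counts = []
    for rp in repeats:
        ls = by_repeat[rp.id]
        c = count_support(ls) if ls else SupportCounts(rp.id, 0, 0, 0, 0)
        if not ls:
            c = SupportCounts(repeat_id=rp.id, m1=0, m2=0, s1=0, s2=0)
        counts.append(c)
    report = make_report(
        counts, repeats={rp.id: rp for rp in repeats}, quartets=dict(quartets) if quartets else None
    )
    records = [
        RecombinationRecord(
            repeat_id=rp.id,
            length=rp.length,
            orientation=rp.orientation,
            rate=c.rate,
            activity=c.activity,
        )
        for rp, c in zip(repeats, counts)
    ]
    corr = None
    usable = [r for r in records if r.rate is not None]
    if len(usable) >= 3:
        corr = length_rate_correlation(records)
    return counts, report, corr


def run_simulated_pipeline(
    config: SimulationConfig,
    seed: int | None = None,
    params: PipelineParams = PipelineParams(),
    outdir: str | Path | None = None,
):
    """Simulate a dataset and push it through the full analysis.

    Returns (genome, repeats, truth, counts, report, correlation); when
    ``outdir`` is given, also writes genome/annotations/reads/labels/counts/
    report/correlation files there.
    """
    genome, repeats, model = generate_master_circle(config, seed=seed)
    reads, truth = simulate_reads(model, config, seed=None if seed is None else seed + 1)
    quartets = build_quartets(genome, repeats, params)
    focal = None
    if config.mode == "junction":
        focal = {
            rt.read_id: rt.focal_repeat
            for rt in truth.reads.values()
            if rt.focal_repeat is not None
        }
    labels = classify_reads(
        quartets, [(r.id, r.sequence) for r in reads], params, focal=focal
    )
    counts, report, corr = summarize(labels, repeats, quartets)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        mio.write_genome(genome, outdir / "genome.fasta", outdir / "contigs.tsv")
        mio.write_repeat_annotations(repeats, outdir / "repeats.tsv")
        mio.write_reads_fastq(reads, outdir / "reads.fastq")
        mio.write_labels(labels, outdir / "labels.tsv")
        mio.write_counts(counts, outdir / "counts.tsv")
        report.to_csv(outdir / "report.tsv", sep="\t", index=False)
        (outdir / "config.json").write_text(config.to_json())
        if corr is not None:
            (outdir / "correlation.json").write_text(
                json.dumps({"r": corr.r, "p": corr.p, "n": corr.n}, indent=2)
            )
        logger.info("wrote pipeline outputs to %s", outdir)
    return genome, repeats, truth, counts, report, corr
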