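"""End-to-end orchestration: FASTA (+ reads or SAM/BAM) -> metrics -> score.

Also houses the training workflow (feature-selection cascade, model
comparison across all families on one shared split, final refit).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd

from asmqual.assembly import AssemblyRecord, contiguity_metrics, read_fasta
from asmqual.features import FeatureReport, run_cascade
from asmqual.flags import FlagParams, accuracy_metrics, flag_errors
from asmqual.mapping import (
    MappingError,
    PairedAlignmentSet,
    load_fastq_pairs,
    map_reads,
    read_alignments,
)
from asmqual.metrics import METRIC_NAMES, metrics_row, validate_metrics_table
from asmqual.model import (
    EvalResult,
    FAMILIES,
    QualityModelResults,
    SplitSpec,
    select_best,
    split_data,
    train_model,
)

log = logging.getLogger("asmqual")


@dataclass
class RunConfig:
    """Validated configuration for one pipeline run."""

    mode: str                                  # score|metrics|train|refscore|simulate
    assembly: str | Path | None = None
    reads1: str | Path | None = None
    reads2: str | Path | None = None
    alignments: str | Path | None = None       # SAM/BAM; skips mapping
    model_path: str | Path | None = None
    min_identity: float = 0.5
    flag_params: FlagParams = field(default_factory=FlagParams)
    per_sequence: bool = False                 # score each scaffold separately
    coverage_floor: float = 10.0
    coverage_hard_floor: float = 2.0
    seed: int = 0

    def validate(self) -> None:
        modes = {"score", "metrics", "train", "refscore", "simulate"}
        if self.mode not in modes:
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mode in ("score", "metrics"):
            if self.assembly is None:
                raise ValueError(f"mode {self.mode!r} requires an assembly path")
            if self.alignments is None and (self.reads1 is None or self.reads2 is None):
                raise ValueError(
                    f"mode {self.mode!r} requires paired reads or an alignment file"
                )
        if self.mode == "score" and self.model_path is None:
            raise ValueError("mode 'score' requires a model path")


def compute_metrics(
    asm: AssemblyRecord,
    aln: PairedAlignmentSet,
    flag_params: FlagParams | None = None,
    per_sequence: bool = False,
) -> pd.DataFrame:
    """Metric rows for the whole assembly and optionally each sequence."""
    rows = []
    tracks = flag_errors(aln, asm, flag_params)
    whole = metrics_row(contiguity_metrics(asm), accuracy_metrics(tracks, aln))
    whole["sequence"] = "__assembly__"
    rows.append(whole)
    if per_sequence:
        for sid, seq in asm.sequences:
            sub = AssemblyRecord.from_sequences([(sid, seq)])
            sub_aln = _restrict(aln, sid)
            if sub_aln is None:
                warnings.warn(f"sequence {sid!r} has no alignments; skipped")
                continue
            sub_tracks = flag_errors(sub_aln, sub, flag_params)
            row = metrics_row(
                contiguity_metrics(sub), accuracy_metrics(sub_tracks, sub_aln)
            )
            row["sequence"] = sid
            rows.append(row)
    return pd.DataFrame(rows)[["sequence", *METRIC_NAMES]]


def _restrict(aln: PairedAlignmentSet, sid: str) -> PairedAlignmentSet | None:
    sub = [a for a in aln.alignments if a.target == sid]
    if not sub:
        return None
    return PairedAlignmentSet(
        alignments=sub,
        insert_mean=aln.insert_mean,
        insert_sd=aln.insert_sd,
        mapped_read_count=len(sub),
        proper_pair_count=sum(1 for a in sub if a.proper),
        total_read_count=len(sub),
        fragments=[f for f in aln.fragments if f[0] == sid],
    )


def _get_alignments(cfg: RunConfig, asm: AssemblyRecord) -> PairedAlignmentSet:
    if cfg.alignments is not None:
        log.info("using supplied alignment file %s (mapping skipped)", cfg.alignments)
        return read_alignments(cfg.alignments, asm)
    pairs = load_fastq_pairs(cfg.reads1, cfg.reads2)
    log.info("mapping %d read pairs (min identity %.2f)", len(pairs), cfg.min_identity)
    return map_reads(asm, pairs, min_identity=cfg.min_identity)


def _check_coverage(aln: PairedAlignmentSet, asm: AssemblyRecord, cfg: RunConfig):
    depth = sum(a.end - a.start for a in aln.alignments) / asm.total_length
    if depth < cfg.coverage_hard_floor:
        raise MappingError(
            f"mean mapped depth {depth:.1f}x is below the hard floor "
            f"({cfg.coverage_hard_floor}x)"
        )
    if depth < cfg.coverage_floor:
        warnings.warn(
            f"mean mapped depth {depth:.1f}x is below the recommended "
            f"{cfg.coverage_floor}x; at least 10x coverage with a 350-550 bp "
            "insert is advised"
        )


def score_assembly(cfg: RunConfig) -> pd.DataFrame:
    """Score an assembly with a saved model: metrics + predicted score rows.

    The returned frame states the granularity scored in its ``sequence``
    column (``__assembly__`` = the concatenated whole-assembly metric set,
    including unplaced pieces).
    """
    cfg.validate()
    asm = read_fasta(cfg.assembly)
    aln = _get_alignments(cfg, asm)
    _check_coverage(aln, asm, cfg)
    table = compute_metrics(asm, aln, cfg.flag_params, per_sequence=cfg.per_sequence)
    results = QualityModelResults.load(cfg.model_path)
    table["score"] = results.predict(table)
    return table


def metrics_only(cfg: RunConfig) -> pd.DataFrame:
    cfg.validate()
    asm = read_fasta(cfg.assembly)
    aln = _get_alignments(cfg, asm)
    _check_coverage(aln, asm, cfg)
    return compute_metrics(asm, aln, cfg.flag_params, per_sequence=cfg.per_sequence)


@dataclass
class TrainReport:
    """Everything the training workflow produced."""

    feature_report: FeatureReport
    evaluations: dict[str, EvalResult]
    best_family: str
    final: QualityModelResults
    split: SplitSpec


def train_workflow(
    cfg: RunConfig,
    table: pd.DataFrame,
    families: Sequence[str] = FAMILIES,
    n_trees: int = 500,
) -> TrainReport:
    """Feature selection, shared 80/20 split, family comparison, final refit."""
    validate_metrics_table(table)
    report = run_cascade(table, seed=cfg.seed, n_trees=n_trees)
    spec = SplitSpec(train_fraction=0.8, seed=cfg.seed)
    train, test = split_data(table, spec)
    log.info("split: %d train / %d test rows", len(train), len(test))
    evals: dict[str, EvalResult] = {}
    for fam in families:
        res = train_model(
            train, fam, seed=cfg.seed,
            features=report.final_features, n_trees=n_trees,
        )
        evals[fam] = res.evaluate(test)
        log.info(
            "%-12s rmse=%.3f r2=%.3f", fam, evals[fam].rmse, evals[fam].r_squared
        )
    best = select_best(evals)
    final = train_model(
        table, best, seed=cfg.seed, features=report.final_features, n_trees=n_trees
    )
    return TrainReport(
        feature_report=report,
        evaluations=evals,
        best_family=best,
        final=final,
        split=spec,
    )
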