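"""The canonical 13-metric feature vector and table validation."""

from __future__ import annotations

import pandas as pd

from asmqual.assembly import ContiguityMetrics
from asmqual.flags import AccuracyMetrics

#: Model feature names, in canonical column order.
METRIC_NAMES: tuple[str, ...] = (
    "normN50",
    "gap_perc",
    "prop_pair_perc",
    "FCD_err_in_contig",
    "FCD_err_over_gap",
    "low_fc_in_contig",
    "low_fc_over_gap",
    "links",
    "clip",
    "coll_repeat",
    "low_read_cov",
    "error_free_bases",
    "norm_contig_number",
)

#: The feature subset the default scoring model consumes.
MODEL_FEATURES: tuple[str, ...] = (
    "normN50",
    "gap_perc",
    "clip",
    "error_free_bases",
    "low_fc_over_gap",
    "low_fc_in_contig",
)


def metrics_row(
    cont: ContiguityMetrics, acc: AccuracyMetrics
) -> dict[str, float]:
    """Combine contiguity and accuracy metrics into one named feature row."""
    return {
        "normN50": cont.norm_n50,
        "gap_perc": cont.gap_perc,
        "prop_pair_perc": acc.prop_pair_perc,
        "FCD_err_in_contig": acc.fcd_err_in_contig,
        "FCD_err_over_gap": acc.fcd_err_over_gap,
        "low_fc_in_contig": acc.low_fc_in_contig,
        "low_fc_over_gap": acc.low_fc_over_gap,
        "links": acc.links,
        "clip": acc.clip,
        "coll_repeat": acc.coll_repeat,
        "low_read_cov": acc.low_read_cov,
        "error_free_bases": acc.error_free_bases,
        "norm_contig_number": cont.norm_contig_number,
    }


def validate_metrics_table(
    table: pd.DataFrame, target: str = "score", require_target: bool = True
) -> pd.DataFrame:
    """Check the 13-metric schema; raises ValueError listing problems."""
    missing = [c for c in METRIC_NAMES if c not in table.columns]
    problems = []
    if missing:
        problems.append(f"missing columns: {missing}")
    if require_target and target not in table.columns:
        problems.append(f"missing target column: {target!r}")
    if not problems:
        cols = list(METRIC_NAMES) + ([target] if require_target else [])
        na = table[cols].isna().any()
        bad = list(na[na].index)
        if bad:
            problems.append(f"missing values in columns: {bad}")
    if problems:
        raise ValueError("metrics table invalid: " + "; ".join(problems))
    return table
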