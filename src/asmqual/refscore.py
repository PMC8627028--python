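"""Reference-based quality scoring.

The training target for the quality model is derived from a whole-sequence
comparison of an assembly against a trusted reference: the *percent
matching bases* (PMB),

    PMB = (ref_length - total_differences) / ref_length * 100,

followed by two rounds of scaling.  *Internal* scaling compares the
chromosomes of one organism to an ideal metric vector (Euclidean distance)
and keeps the best chromosome's PMB unchanged; *external* scaling does the
same across organisms using each organism's best chromosome.

``total_differences`` is defined here as the number of reference bases that
cannot be paired with an equal query base in any order-preserving
alignment, i.e. ``ref_length - LCS(ref, query)``.  This is deterministic
and free of alignment tie-breaking.  Small pairs are solved exactly with a
bit-parallel LCS; large pairs are anchored on unique k-mers chained by
longest increasing subsequence, with per-gap exact LCS.
"""

from __future__ import annotations

import bisect
import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from asmqual.assembly import AssemblyRecord

#: Metrics entering the Euclidean ideal-distance, with their ideal values.
#: These are the 12 percent-scale metrics; the contig count per Mbp is
#: excluded because it has no finite worst bound.
IDEAL_VECTOR: dict[str, float] = {
    "normN50": 100.0,
    "gap_perc": 0.0,
    "prop_pair_perc": 100.0,
    "FCD_err_in_contig": 0.0,
    "FCD_err_over_gap": 0.0,
    "low_fc_in_contig": 0.0,
    "low_fc_over_gap": 0.0,
    "links": 0.0,
    "clip": 0.0,
    "coll_repeat": 0.0,
    "low_read_cov": 0.0,
    "error_free_bases": 100.0,
}

#: Distance from the ideal vector to the all-worst vector (every metric at
#: the opposite bound, 100 percentage points away): the fixed normaliser D
#: of the scaling formula.
WORST_DISTANCE: float = float(np.sqrt(len(IDEAL_VECTOR)) * 100.0)


@dataclass
class DiffSummary:
    """Outcome of a query-vs-reference comparison."""

    ref_length: int
    total_differences: int

    def __post_init__(self) -> None:
        if not 0 <= self.total_differences <= self.ref_length:
            raise ValueError("total_differences outside [0, ref_length]")


# ---------------------------------------------------------------------------
# Longest-common-subsequence machinery


def _llcs_bitparallel(a: str, b: str) -> int:
    """Length of the LCS of a and b via the Allison-Dix bit-vector scan.

    O(len(a) * len(b) / wordsize) using Python big-int arithmetic; `a` is
    held in the bit row.
    """
    if not a or not b:
        return 0
    masks: dict[str, int] = {}
    for i, ch in enumerate(a):
        masks[ch] = masks.get(ch, 0) | (1 << i)
    row = 0
    for ch in b:
        x = masks.get(ch, 0) | row
        row = x & ~(x - ((row << 1) | 1))
    return row.bit_count()


def _unique_kmer_positions(seq: str, k: int) -> dict[str, int]:
    pos: dict[str, int] = {}
    dup: set[str] = set()
    for i in range(len(seq) - k + 1):
        km = seq[i : i + k]
        if km in dup:
            continue
        if km in pos:
            del pos[km]
            dup.add(km)
        else:
            pos[km] = i
    return pos


def _chain_anchors(anchors: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Longest increasing subsequence of (ref_pos, query_pos) anchors.

    Anchors are sorted by ref_pos; the chain is strictly increasing in
    query_pos (patience sorting, O(n log n)).
    """
    if not anchors:
        return []
    anchors.sort()
    tails: list[int] = []  # query positions
    backptr: list[int] = []
    tail_idx: list[int] = []
    for idx, (_, q) in enumerate(anchors):
        j = bisect.bisect_left(tails, q)
        if j == len(tails):
            tails.append(q)
            tail_idx.append(idx)
        else:
            tails[j] = q
            tail_idx[j] = idx
        backptr.append(tail_idx[j - 1] if j > 0 else -1)
    chain = []
    i = tail_idx[-1]
    while i >= 0:
        chain.append(anchors[i])
        i = backptr[i]
    chain.reverse()
    return chain


def _anchored_matches(ref: str, query: str, k: int) -> int:
    """Matched reference bases via unique-k-mer anchor chaining.

    Overlapping collinear anchors are merged into runs; the sequence
    stretches between consecutive runs are solved with the exact
    bit-parallel LCS.
    """
    ra = _unique_kmer_positions(ref, k)
    qa = _unique_kmer_positions(query, k)
    anchors = [(rp, qa[km]) for km, rp in ra.items() if km in qa]
    chain = _chain_anchors(anchors)
    if not chain:
        warnings.warn(
            "no alignment anchors found; sequences treated as fully diverged",
            stacklevel=3,
        )
        return 0
    # Merge chained anchors into non-overlapping collinear runs.
    runs: list[list[int]] = []  # [ref_start, ref_end, q_start, q_end]
    for rp, qp in chain:
        if runs and rp - runs[-1][0] == qp - runs[-1][2] and rp <= runs[-1][1]:
            runs[-1][1] = rp + k
            runs[-1][3] = qp + k
            continue
        if runs and (rp < runs[-1][1] or qp < runs[-1][3]):
            # off-diagonal overlap with the previous run: trim this anchor
            shift = max(runs[-1][1] - rp, runs[-1][3] - qp)
            if shift >= k:
                continue
            rp += shift
            qp += shift
            runs.append([rp, rp + k - shift, qp, qp + k - shift])
            continue
        runs.append([rp, rp + k, qp, qp + k])
    matches = sum(r[1] - r[0] for r in runs)
    # Close the gaps (including the two flanks) exactly.
    prev_r, prev_q = 0, 0
    segments = []
    for r0, r1, q0, q1 in runs:
        segments.append((prev_r, r0, prev_q, q0))
        prev_r, prev_q = r1, q1
    segments.append((prev_r, len(ref), prev_q, len(query)))
    for r0, r1, q0, q1 in segments:
        if r1 > r0 and q1 > q0:
            matches += _llcs_bitparallel(ref[r0:r1], query[q0:q1])
    return matches


_EXACT_LIMIT = 16_000_000  # ref*query cells below which the exact LCS is used


def count_differences(
    query: AssemblyRecord | str,
    ref: AssemblyRecord | str,
    k: int = 21,
) -> DiffSummary:
    """Count reference bases not matched by the query.

    Multi-scaffold inputs are concatenated in their stored order (the
    simulators preserve reference order when fragmenting; for externally
    scaffolded assemblies, order them beforehand).
    """
    qs = _concat(query)
    rs = _concat(ref)
    if len(rs) == 0:
        raise ValueError("empty reference")
    if len(qs) == 0:
        return DiffSummary(ref_length=len(rs), total_differences=len(rs))
    if qs == rs:
        return DiffSummary(ref_length=len(rs), total_differences=0)
    if len(qs) * len(rs) <= _EXACT_LIMIT:
        matches = _llcs_bitparallel(rs, qs)
    else:
        matches = _anchored_matches(rs, qs, k)
    return DiffSummary(ref_length=len(rs), total_differences=len(rs) - matches)


def _concat(x: AssemblyRecord | str) -> str:
    if isinstance(x, AssemblyRecord):
        return "".join(s for _, s in x.sequences).upper()
    return str(x).upper()


# ---------------------------------------------------------------------------
# Scoring and scaling


def percent_matching_bases(d: DiffSummary) -> float:
    """PMB = (ref_length - total_differences) / ref_length * 100."""
    if d.ref_length <= 0:
        raise ValueError("reference length must be positive")
    return (d.ref_length - d.total_differences) / d.ref_length * 100.0


def ideal_distance(
    metrics: Mapping[str, float],
    ideal: Mapping[str, float] | None = None,
) -> float:
    """Euclidean distance of a metric vector from the ideal vector."""
    ideal = IDEAL_VECTOR if ideal is None else ideal
    sq = 0.0
    for name, target in ideal.items():
        if name not in metrics:
            raise KeyError(f"metric {name!r} missing from metrics vector")
        v = metrics[name]
        if pd.isna(v):
            raise KeyError(f"metric {name!r} is NaN")
        sq += (float(v) - target) ** 2
    return float(np.sqrt(sq))


def _scale_factor(d: float, d_best: float, worst: float) -> float:
    return max(0.0, 1.0 - (d - d_best) / worst)


def internal_scale(
    instances: pd.DataFrame,
    worst_distance: float = WORST_DISTANCE,
) -> pd.DataFrame:
    """Scale PMB within one organism's chromosomes.

    ``instances`` needs columns ``pmb`` and ``distance``.  The chromosome
    with the smallest distance from the ideal metric vector keeps its PMB;
    every other row i is scaled by 1 - (d_i - d_best)/D where D is the
    ideal-to-worst distance.  Returns a copy with a ``scaled_score`` column.
    """
    if len(instances) == 0:
        raise ValueError("no instances to scale")
    out = instances.copy()
    d_best = float(out["distance"].min())
    factors = out["distance"].map(lambda d: _scale_factor(d, d_best, worst_distance))
    out["scaled_score"] = (out["pmb"] * factors).clip(lower=0.0)
    return out


def external_scale(
    per_organism: pd.DataFrame,
    worst_distance: float = WORST_DISTANCE,
) -> pd.DataFrame:
    """Scale internally-scaled scores across organisms.

    ``per_organism`` needs columns ``organism``, ``distance`` and
    ``scaled_score`` (from :func:`internal_scale` applied per organism).
    Each organism's scale factor comes from its best chromosome's distance
    relative to the globally best chromosome's distance.  Adds a
    ``final_score`` column.
    """
    if len(per_organism) == 0:
        raise ValueError("no organisms to scale")
    out = per_organism.copy()
    best_per_org = out.groupby("organism")["distance"].min()
    d_global = float(best_per_org.min())
    factors = best_per_org.map(lambda d: _scale_factor(d, d_global, worst_distance))
    out["final_score"] = (
        out["scaled_score"] * out["organism"].map(factors)
    ).clip(lower=0.0)
    return out


def score_instances(
    instances: pd.DataFrame,
    worst_distance: float = WORST_DISTANCE,
) -> pd.DataFrame:
    """Apply internal scaling per organism, then external scaling.

    ``instances`` needs ``organism``, ``pmb`` and ``distance`` columns.
    """
    scaled = pd.concat(
        [
            internal_scale(g, worst_distance)
            for _, g in instances.groupby("organism", sort=False)
        ]
    )
    return external_scale(scaled, worst_distance)
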