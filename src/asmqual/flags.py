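"""Per-base error-evidence tracks and the accuracy metrics derived from them.

Scans each assembled sequence base-by-base for read-mapping evidence of
problems: clustered soft-clip points, low read or fragment (physical)
coverage, fragment-coverage-distribution (FCD) deviation, read pairs
linking distant loci, and collapsed repeats.  Bases supported by enough
perfectly matching, unclipped reads and free of every flag are error-free.
Each flag is reported as a percent of total assembly bases.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator

import numpy as np
from scipy.ndimage import uniform_filter1d

from asmqual.assembly import AssemblyRecord
from asmqual.mapping import MappingError, PairedAlignmentSet

#: Error-flag track names, in reporting order.
FLAG_NAMES = (
    "clip",
    "low_read_cov",
    "low_fc_in_contig",
    "low_fc_over_gap",
    "fcd_err_in_contig",
    "fcd_err_over_gap",
    "links",
    "coll_repeat",
)


@dataclass
class FlagParams:
    """Thresholds for the error-flag engine.

    Coverage thresholds are relative to the global mean depth so 10-30x
    libraries behave alike.  ``fcd_cutoff_frac`` bounds the windowed mean
    absolute deviation of fragment depth from its local flat fit, as a
    fraction of mean fragment depth; the window is one insert mean.
    """

    min_clip_support: int = 2
    min_clip_len: int = 5
    clip_window: int = 5
    low_cov_frac: float = 0.25
    low_fc_frac: float = 0.25
    fcd_cutoff_frac: float = 0.3
    min_link_support: int = 2
    link_distance_factor: float = 10.0
    coll_repeat_factor: float = 2.0
    min_perfect: int = 5


@dataclass
class FlagTracks:
    """Boolean evidence tracks plus depth tracks, one array set per sequence."""

    flags: dict[str, dict[str, np.ndarray]]       # flag name -> seq id -> bool
    error_free: dict[str, np.ndarray]
    read_depth: dict[str, np.ndarray]
    fragment_depth: dict[str, np.ndarray]
    perfect_depth: dict[str, np.ndarray]
    total_bases: int

    def flag_fraction(self, name: str) -> float:
        flagged = sum(int(a.sum()) for a in self.flags[name].values())
        return flagged / self.total_bases

    def to_bed(self, name: str) -> Iterator[tuple[str, int, int]]:
        """Yield flagged intervals as BED-style (seq, start, end) records."""
        track = self.error_free if name == "error_free" else self.flags[name]
        for sid, arr in track.items():
            for a, b in _runs(arr):
                yield sid, a, b


@dataclass
class AccuracyMetrics:
    """Read-mapping accuracy metrics, all as percents."""

    prop_pair_perc: float
    clip: float
    low_read_cov: float
    low_fc_in_contig: float
    low_fc_over_gap: float
    fcd_err_in_contig: float
    fcd_err_over_gap: float
    links: float
    coll_repeat: float
    error_free_bases: float


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal True runs of a boolean array, half-open."""
    if mask.size == 0:
        return []
    diff = np.diff(mask.astype(np.int8))
    starts = list(np.flatnonzero(diff == 1) + 1)
    ends = list(np.flatnonzero(diff == -1) + 1)
    if mask[0]:
        starts = [0] + starts
    if mask[-1]:
        ends = ends + [mask.size]
    return list(zip(starts, ends))


def _interval_depth(length: int, intervals: list[tuple[int, int]]) -> np.ndarray:
    d = np.zeros(length + 1, dtype=np.int32)
    for a, b in intervals:
        a = max(0, min(a, length))
        b = max(0, min(b, length))
        if b > a:
            d[a] += 1
            d[b] -= 1
    return np.cumsum(d[:-1]).astype(np.int32)


def fragment_depth(
    aln: PairedAlignmentSet, asm: AssemblyRecord
) -> dict[str, np.ndarray]:
    """Per-base physical (fragment) coverage from proper pairs.

    Each properly oriented pair whose insert lies within mean +/- 3 sd
    contributes +1 over [leftmost start, rightmost end).  Pairs spanning
    two sequences contribute nothing here (they feed the links flag).
    """
    by_seq: dict[str, list[tuple[int, int]]] = {sid: [] for sid, _ in asm.sequences}
    for sid, a, b in aln.fragments:
        by_seq[sid].append((a, b))
    return {
        sid: _interval_depth(len(s), by_seq[sid]) for sid, s in asm.sequences
    }


def _read_depths(
    aln: PairedAlignmentSet, asm: AssemblyRecord
) -> tuple[dict[str, np.ndarray], dict[str, np.ndarray]]:
    read_depth = {sid: np.zeros(len(s), dtype=np.int32) for sid, s in asm.sequences}
    perfect = {sid: np.zeros(len(s), dtype=np.int32) for sid, s in asm.sequences}
    for a in aln.alignments:
        rd = read_depth[a.target]
        rd_view = rd[a.start : a.end]
        rd_view += 1
        if not a.clipped:
            pf = perfect[a.target]
            span = a.end - a.start
            # perfect support = unclipped alignment matching at that base
            pf[a.start : a.end] += a.match[:span]
    return read_depth, perfect


def flag_errors(
    aln: PairedAlignmentSet,
    asm: AssemblyRecord,
    params: FlagParams | None = None,
) -> FlagTracks:
    """Compute all error-flag tracks for an assembly.

    The first and last insert-mean bases of every sequence are excluded
    from fragment-coverage flags (fcd, low_fc, coll_repeat): fragments
    cannot fully cover sequence ends, so depth there is structurally low.
    """
    p = params or FlagParams()
    read_depth, perfect_depth = _read_depths(aln, asm)
    frag_depth = fragment_depth(aln, asm)
    total_bases = asm.total_length
    mean_rd = sum(int(d.sum()) for d in read_depth.values()) / total_bases
    mean_fd = sum(int(d.sum()) for d in frag_depth.values()) / total_bases
    if mean_rd == 0:
        raise MappingError("insufficient coverage: mean read depth is zero")
    w = max(10, int(round(aln.insert_mean)))

    flags: dict[str, dict[str, np.ndarray]] = {n: {} for n in FLAG_NAMES}
    error_free: dict[str, np.ndarray] = {}

    link_intervals: dict[str, list[tuple[int, int]]] = {
        sid: [] for sid, _ in asm.sequences
    }
    clip_intervals: dict[str, list[tuple[int, int]]] = {
        sid: [] for sid, _ in asm.sequences
    }
    link_dist = p.link_distance_factor * aln.insert_mean
    for a in aln.alignments:
        if a.mate_target is not None and (
            a.mate_target != a.target or abs(a.mate_start - a.start) > link_dist
        ):
            link_intervals[a.target].append((a.start, a.end))
        if a.left_clip >= p.min_clip_len:
            clip_intervals[a.target].append(
                (a.start - p.clip_window, a.start + p.clip_window)
            )
        if a.right_clip >= p.min_clip_len:
            clip_intervals[a.target].append(
                (a.end - p.clip_window, a.end + p.clip_window)
            )

    for sid, seq in asm.sequences:
        n = len(seq)
        rd = read_depth[sid]
        fd = frag_depth[sid]
        gap_mask = np.zeros(n, dtype=bool)
        for a, b in asm.gap_runs_for(sid):
            gap_mask[a:b] = True
        interior = np.zeros(n, dtype=bool)
        if n > 2 * w:
            interior[w : n - w] = True

        flags["clip"][sid] = _interval_depth(n, clip_intervals[sid]) >= p.min_clip_support
        flags["links"][sid] = _interval_depth(n, link_intervals[sid]) >= p.min_link_support
        flags["low_read_cov"][sid] = rd < p.low_cov_frac * mean_rd

        low_fc = (fd < p.low_fc_frac * mean_fd) & interior
        fcd = np.zeros(n, dtype=bool)
        if n > 2 * w and mean_fd > 0:
            fdf = fd.astype(float)
            local = uniform_filter1d(fdf, size=w, mode="nearest")
            mad = uniform_filter1d(np.abs(fdf - local), size=w, mode="nearest")
            fcd = (mad > p.fcd_cutoff_frac * mean_fd) & interior
        for name, mask in (("low_fc", low_fc), ("fcd_err", fcd)):
            over_gap = np.zeros(n, dtype=bool)
            in_contig = np.zeros(n, dtype=bool)
            for a, b in _runs(mask):
                if gap_mask[a:b].any():
                    over_gap[a:b] = True
                else:
                    in_contig[a:b] = True
            flags[f"{name}_over_gap"][sid] = over_gap
            flags[f"{name}_in_contig"][sid] = in_contig

        coll = np.zeros(n, dtype=bool)
        high = (fd > p.coll_repeat_factor * mean_fd) & interior
        for a, b in _runs(high):
            if b - a >= w:
                coll[a:b] = True
        flags["coll_repeat"][sid] = coll

        any_flag = np.zeros(n, dtype=bool)
        for name in FLAG_NAMES:
            any_flag |= flags[name][sid]
        error_free[sid] = (perfect_depth[sid] >= p.min_perfect) & ~any_flag

    return FlagTracks(
        flags=flags,
        error_free=error_free,
        read_depth=read_depth,
        fragment_depth=frag_depth,
        perfect_depth=perfect_depth,
        total_bases=total_bases,
    )


def accuracy_metrics(
    tracks: FlagTracks, aln: PairedAlignmentSet
) -> AccuracyMetrics:
    """Convert flag tracks and pair counts into percent-scale metrics."""
    if aln.mapped_read_count == 0:
        raise MappingError("no mapped reads")
    pct = lambda name: 100.0 * tracks.flag_fraction(name)
    ef = sum(int(a.sum()) for a in tracks.error_free.values())
    return AccuracyMetrics(
        prop_pair_perc=100.0 * aln.proper_pair_count / aln.mapped_read_count,
        clip=pct("clip"),
        low_read_cov=pct("low_read_cov"),
        low_fc_in_contig=pct("low_fc_in_contig"),
        low_fc_over_gap=pct("low_fc_over_gap"),
        fcd_err_in_contig=pct("fcd_err_in_contig"),
        fcd_err_over_gap=pct("fcd_err_over_gap"),
        links=pct("links"),
        coll_repeat=pct("coll_repeat"),
        error_free_bases=100.0 * ef / tracks.total_bases,
    )
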