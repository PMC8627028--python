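"""Native paired-end read mapping onto an assembly.

A k-mer seed-and-extend mapper with banded gap-aware extension (edlib) and
deterministic tie-breaking by (target id, position).  It is deliberately
simple: exact seed k-mers vote for (target, diagonal) candidates, the best
candidate is aligned, and poorly matching read ends are soft-clipped by a
maximal-scoring-segment trim.  A coordinate-sorted SAM/BAM produced by any
mapper may be supplied instead, bypassing this module's aligner.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import edlib
import numpy as np
import pysam

from asmqual.assembly import AssemblyRecord, reverse_complement
from asmqual.simulate import ReadPair


class MappingError(ValueError):
    """Raised for unusable read input or empty mapping results."""


@dataclass
class Alignment:
    """One accepted read alignment (core segment after end trimming)."""

    read_id: str
    mate: int                 # 1 or 2
    target: str
    start: int                # target interval of the unclipped core
    end: int
    strand: str               # '+' or '-'
    left_clip: int            # read bases trimmed on the read's left (as aligned)
    right_clip: int
    match: np.ndarray         # bool per target base in [start, end)
    read_length: int
    n_match: int
    mate_target: str | None = None
    mate_start: int | None = None
    proper: bool = False

    @property
    def identity(self) -> float:
        return self.n_match / self.read_length

    @property
    def clipped(self) -> bool:
        return self.left_clip > 0 or self.right_clip > 0


@dataclass
class PairedAlignmentSet:
    """Alignments plus library statistics for one assembly."""

    alignments: list[Alignment]
    insert_mean: float
    insert_sd: float
    mapped_read_count: int
    proper_pair_count: int        # reads (not pairs) in proper pairs
    total_read_count: int
    fragments: list[tuple[str, int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.insert_mean <= 0:
            raise MappingError("insert mean must be positive")
        if self.proper_pair_count > self.mapped_read_count:
            raise MappingError("more proper-paired reads than mapped reads")


# ---------------------------------------------------------------------------
# Seed index


class _KmerIndex:
    def __init__(self, asm: AssemblyRecord, k: int, max_hits: int) -> None:
        self.k = k
        self.targets = [(sid, s.upper()) for sid, s in asm.sequences]
        self.order = {sid: i for i, (sid, _) in enumerate(self.targets)}
        index: dict[str, list[tuple[int, int]]] = {}
        banned: set[str] = set()
        for ti, (_, seq) in enumerate(self.targets):
            for i in range(len(seq) - k + 1):
                km = seq[i : i + k]
                if km in banned or "N" in km:
                    continue
                hits = index.setdefault(km, [])
                hits.append((ti, i))
                if len(hits) > max_hits:
                    del index[km]
                    banned.add(km)
        self.index = index

    def lookup(self, kmer: str) -> list[tuple[int, int]]:
        return self.index.get(kmer, ())


# ---------------------------------------------------------------------------
# Single-read alignment


def _trim_ends(per_base: list[tuple[int | None, bool, int]]) -> tuple[int, int]:
    """Maximal-scoring segment over read bases: +1 match, -2 otherwise.

    ``per_base`` holds (target_pos or None, is_match, pending_deletion_len)
    per read base in read orientation.  Returns (i0, i1) half-open read-base
    window of the retained core; everything outside is soft clip.
    """
    best, best_rng = 0.0, (0, 0)
    cur, cur_start = 0.0, 0
    for i, (tpos, m, dlen) in enumerate(per_base):
        gain = (1.0 if m else -2.0) - 2.0 * dlen
        if cur <= 0:
            cur, cur_start = gain, i
        else:
            cur += gain
        if cur > best:
            best, best_rng = cur, (cur_start, i + 1)
    return best_rng


_CIG_RE = re.compile(r"(\d+)([=XIDM])")


def _align_candidate(
    oread: str, target: str, diag: int, pad: int
) -> tuple[int, int, int, int, np.ndarray, int] | None:
    """Align an oriented read near a candidate diagonal.

    Returns (start, end, left_clip, right_clip, match_array, n_match) in
    target coordinates, or None when no positive-scoring core exists.
    """
    L = len(oread)
    w0 = max(0, diag - pad)
    w1 = min(len(target), diag + L + pad)
    window = target[w0:w1]
    if not window:
        return None
    res = edlib.align(oread, window, mode="HW", task="path")
    if res["editDistance"] < 0 or not res.get("cigar"):
        return None
    tpos = w0 + res["locations"][0][0]
    per_base: list[tuple[int | None, bool, int]] = []
    qi = 0
    pending_del = 0
    for num, op in _CIG_RE.findall(res["cigar"]):
        n = int(num)
        if op in "=XM":
            for _ in range(n):
                m = oread[qi] == target[tpos] if tpos < len(target) else False
                per_base.append((tpos, m, pending_del))
                pending_del = 0
                qi += 1
                tpos += 1
        elif op == "I":  # read-only bases
            for _ in range(n):
                per_base.append((None, False, pending_del))
                pending_del = 0
                qi += 1
        elif op == "D":  # target-only bases
            pending_del += n
            tpos += n
    i0, i1 = _trim_ends(per_base)
    core = [pb for pb in per_base[i0:i1] if pb[0] is not None]
    if not core:
        return None
    start, end = core[0][0], core[-1][0] + 1
    match = np.zeros(end - start, dtype=bool)
    n_match = 0
    for tp, m, _ in core:
        if m:
            match[tp - start] = True
            n_match += 1
    return start, end, i0, L - i1, match, n_match


def _map_single(
    read: str,
    index: _KmerIndex,
    seed_step: int,
    n_candidates: int,
    hamming_accept: float,
) -> Alignment | None:
    """Map one read; returns a template Alignment (read_id/mate unset)."""
    k = index.k
    read = read.upper()
    L = len(read)
    if L < k:
        return None
    votes: dict[tuple[int, int, int], int] = {}
    for oi, oread in enumerate((read, reverse_complement(read))):
        offsets = list(range(0, L - k + 1, seed_step))
        if offsets[-1] != L - k:
            offsets.append(L - k)
        for off in offsets:
            for ti, pos in index.lookup(oread[off : off + k]):
                key = (oi, ti, pos - off)
                votes[key] = votes.get(key, 0) + 1
    if not votes:
        return None
    # cluster nearby diagonals of the same (orientation, target)
    clusters: dict[tuple[int, int, int], int] = {}
    for (oi, ti, diag) in sorted(votes):
        v = votes[(oi, ti, diag)]
        merged = False
        for (coi, cti, cdiag), cv in list(clusters.items()):
            if coi == oi and cti == ti and abs(diag - cdiag) <= 25:
                rep = cdiag if cv >= v else diag
                clusters.pop((coi, cti, cdiag))
                clusters[(oi, ti, rep)] = cv + v
                merged = True
                break
        if not merged:
            clusters[(oi, ti, diag)] = v
    ranked = sorted(clusters.items(), key=lambda kv: (-kv[1], kv[0][1], kv[0][2], kv[0][0]))
    pad = int(0.15 * L) + 10
    best: tuple[int, tuple, int, int] | None = None  # (n_match, result, ti, oi)
    for (oi, ti, diag), _v in ranked[:n_candidates]:
        target = index.targets[ti][1]
        oread = read if oi == 0 else reverse_complement(read)
        res = None
        if 0 <= diag and diag + L <= len(target):
            # ungapped fast path on the exact diagonal
            t_arr = np.frombuffer(target[diag : diag + L].encode(), dtype="S1")
            r_arr = np.frombuffer(oread.encode(), dtype="S1")
            eq = t_arr == r_arr
            nm = int(eq.sum())
            if nm >= hamming_accept * L:
                res = (diag, diag + L, 0, 0, eq, nm)
        if res is None:
            res = _align_candidate(oread, target, diag, pad)
        if res is None:
            continue
        cand = (res[5], res, ti, oi)
        if best is None or cand[0] > best[0] or (
            cand[0] == best[0] and (ti, res[0]) < (best[2], best[1][0])
        ):
            best = cand
    if best is None:
        return None
    _, (start, end, lclip, rclip, match, n_match), ti, oi = best
    return Alignment(
        read_id="", mate=0, target=index.targets[ti][0],
        start=start, end=end, strand="+" if oi == 0 else "-",
        left_clip=lclip, right_clip=rclip, match=match,
        read_length=L, n_match=n_match,
    )


# ---------------------------------------------------------------------------
# Pairing and the public entry point


def _robust_insert_stats(inserts: Sequence[int]) -> tuple[float, float]:
    arr = np.asarray(inserts, dtype=float)
    med = float(np.median(arr))
    mad = float(np.median(np.abs(arr - med)))
    sd = max(1.4826 * mad, 1.0)
    return med, sd


def map_reads(
    asm: AssemblyRecord,
    reads: Iterable[ReadPair],
    min_identity: float = 0.5,
    k: int = 21,
    seed_step: int | None = None,
    max_hits: int = 8,
    n_candidates: int = 3,
) -> PairedAlignmentSet:
    """Map read pairs to an assembly.

    ``reads`` yields (read id, mate1, mate2) tuples (see
    :func:`asmqual.mapping.load_fastq_pairs`).  Alignments whose matched
    fraction of the read falls below ``min_identity`` are discarded (0.5 is
    the chromosome/whole-assembly default; use 0.75 for scaffolds).
    Deterministic: ties break by (target id, position).
    """
    if not 0 < min_identity <= 1:
        raise MappingError(f"min_identity must be in (0, 1], got {min_identity}")
    pairs = list(reads)
    if not pairs:
        raise MappingError("no reads supplied")
    index = _KmerIndex(asm, k=k, max_hits=max_hits)
    hamming_accept = max(min_identity, 0.75)
    alignments: list[Alignment] = []
    pair_slots: list[tuple[Alignment | None, Alignment | None]] = []
    total_reads = 0
    for rid, r1, r2 in pairs:
        total_reads += 2
        step1 = seed_step or max(1, len(r1) // 10)
        step2 = seed_step or max(1, len(r2) // 10)
        a1 = _map_single(r1, index, step1, n_candidates, hamming_accept)
        a2 = _map_single(r2, index, step2, n_candidates, hamming_accept)
        if a1 is not None and a1.identity >= min_identity:
            a1.read_id, a1.mate = rid, 1
        else:
            a1 = None
        if a2 is not None and a2.identity >= min_identity:
            a2.read_id, a2.mate = rid, 2
        else:
            a2 = None
        pair_slots.append((a1, a2))
    # library insert statistics from opposite-strand same-target pairs
    inserts = []
    for a1, a2 in pair_slots:
        if a1 and a2 and a1.target == a2.target and a1.strand != a2.strand:
            outer = max(a1.end, a2.end) - min(a1.start, a2.start)
            inserts.append(outer)
    if inserts:
        ins_mean, ins_sd = _robust_insert_stats(inserts)
    else:
        ins_mean, ins_sd = 2.0 * len(pairs[0][1]), float(len(pairs[0][1])) / 10
        warnings.warn("no candidate proper pairs; insert statistics are a guess")
    mapped = 0
    proper_reads = 0
    fragments: list[tuple[str, int, int]] = []
    for a1, a2 in pair_slots:
        for a, other in ((a1, a2), (a2, a1)):
            if a is None:
                continue
            mapped += 1
            if other is not None:
                a.mate_target = other.target
                a.mate_start = other.start
            alignments.append(a)
        if a1 and a2 and a1.target == a2.target and a1.strand != a2.strand:
            fwd, rev = (a1, a2) if a1.strand == "+" else (a2, a1)
            outer = max(a1.end, a2.end) - min(a1.start, a2.start)
            if fwd.start <= rev.start and abs(outer - ins_mean) <= 3 * ins_sd:
                a1.proper = a2.proper = True
                proper_reads += 2
                left = min(a1.start, a2.start)
                fragments.append((a1.target, left, left + outer))
    if mapped == 0:
        raise MappingError("no alignments: zero reads mapped")
    return PairedAlignmentSet(
        alignments=alignments,
        insert_mean=ins_mean,
        insert_sd=ins_sd,
        mapped_read_count=mapped,
        proper_pair_count=proper_reads,
        total_read_count=total_reads,
        fragments=fragments,
    )


def load_fastq_pairs(path1: str | Path, path2: str | Path) -> list[ReadPair]:
    """Load matched-order mate files (optionally gzipped) as read pairs."""
    from Bio.SeqIO.QualityIO import FastqGeneralIterator
    import gzip

    def _records(path):
        path = str(path)
        opener = gzip.open if path.endswith(".gz") else open
        with opener(path, "rt") as fh:
            yield from FastqGeneralIterator(fh)

    ones = list(_records(path1))
    twos = list(_records(path2))
    if len(ones) != len(twos):
        raise MappingError(
            f"mismatched pair files: {len(ones)} vs {len(twos)} reads"
        )
    pairs = []
    for (t1, s1, _), (t2, s2, _) in zip(ones, twos):
        n1 = t1.split()[0].removesuffix("/1")
        n2 = t2.split()[0].removesuffix("/2")
        if n1 != n2:
            raise MappingError(f"mismatched read ids: {n1!r} vs {n2!r}")
        pairs.append((n1, s1, s2))
    return pairs


# ---------------------------------------------------------------------------
# SAM interchange


def _match_cigar(a: Alignment) -> list[tuple[int, int]]:
    """CIGAR encoding the per-target-base match calls with =/X ops.

    The core is written as runs of 7 (=) and 8 (X) over its target span;
    any surplus read bases beyond the target span are appended as one
    insertion so query-length bookkeeping stays exact.
    """
    cig: list[tuple[int, int]] = []
    if a.left_clip:
        cig.append((4, a.left_clip))
    span = a.end - a.start
    i = 0
    while i < span:
        op = 7 if a.match[i] else 8
        j = i
        while j < span and (7 if a.match[j] else 8) == op:
            j += 1
        cig.append((op, j - i))
        i = j
    core = a.read_length - a.left_clip - a.right_clip
    if core > span:
        cig.append((1, core - span))
    if a.right_clip:
        cig.append((4, a.right_clip))
    return cig


def write_sam(aln: PairedAlignmentSet, asm: AssemblyRecord, path: str | Path) -> None:
    """Write accepted alignments as coordinate-sorted SAM (core segments).

    Per-base match calls are preserved exactly through =/X CIGAR ops, so
    :func:`read_alignments` reconstructs the same tracks without read
    sequences (emitted as '*').
    """
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": sid, "LN": len(s)} for sid, s in asm.sequences],
    }
    tid = {sid: i for i, (sid, _) in enumerate(asm.sequences)}
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for a in sorted(aln.alignments, key=lambda x: (tid[x.target], x.start)):
            seg = pysam.AlignedSegment(out.header)
            seg.query_name = a.read_id
            seg.reference_id = tid[a.target]
            seg.reference_start = a.start
            flag = 0x1
            if a.strand == "-":
                flag |= 0x10
            flag |= 0x40 if a.mate == 1 else 0x80
            if a.proper:
                flag |= 0x2
            seg.flag = flag
            seg.cigartuples = _match_cigar(a)
            seg.mapping_quality = 60
            if a.mate_target is not None:
                seg.next_reference_id = tid[a.mate_target]
                seg.next_reference_start = a.mate_start
            out.write(seg)


def _match_from_segment(seg, tseq: str, start: int, end: int) -> tuple[np.ndarray, int]:
    """Per-target-base match calls from a SAM record.

    Prefers explicit =/X CIGAR ops; falls back to comparing the stored
    read sequence against the assembly, and finally (no sequence, M ops
    only) to all-match within aligned blocks.
    """
    match = np.zeros(end - start, dtype=bool)
    cig = seg.cigartuples or []
    if any(op in (7, 8) for op, _ in cig):
        t = 0
        for op, n in cig:
            if op == 7:
                match[t : t + n] = True
                t += n
            elif op in (8, 0):
                t += n
            elif op in (2, 3):
                t += n
        return match, int(match.sum())
    qseq = seg.query_sequence
    for qpos, tpos in seg.get_aligned_pairs(matches_only=True):
        if qseq is None or qseq[qpos].upper() == tseq[tpos].upper():
            match[tpos - start] = True
    return match, int(match.sum())


def read_alignments(path: str | Path, asm: AssemblyRecord) -> PairedAlignmentSet:
    """Build a PairedAlignmentSet from a SAM/BAM (any origin).

    Proper-pair fragments and insert statistics are reconstructed by
    pairing mates by read name, so TLEN fields are not required.
    """
    targets = dict(asm.sequences)
    alignments: list[Alignment] = []
    mapped = 0
    proper_reads = 0
    total = 0
    proper_mates: dict[str, list[Alignment]] = {}
    with pysam.AlignmentFile(str(path), check_sq=False) as fh:
        for seg in fh:
            if seg.is_secondary or seg.is_supplementary:
                continue
            total += 1
            if seg.is_unmapped or seg.reference_name is None:
                continue
            mapped += 1
            tseq = targets.get(seg.reference_name)
            if tseq is None:
                raise MappingError(
                    f"alignment target {seg.reference_name!r} not in assembly"
                )
            start, end = seg.reference_start, seg.reference_end
            match, n_match = _match_from_segment(seg, tseq, start, end)
            cig = seg.cigartuples or []
            lclip = cig[0][1] if cig and cig[0][0] in (4, 5) else 0
            rclip = cig[-1][1] if cig and cig[-1][0] in (4, 5) else 0
            a = Alignment(
                read_id=seg.query_name,
                mate=2 if seg.is_read2 else 1,
                target=seg.reference_name,
                start=start,
                end=end,
                strand="-" if seg.is_reverse else "+",
                left_clip=lclip,
                right_clip=rclip,
                match=match,
                read_length=(seg.query_length or (end - start)) or (end - start),
                n_match=n_match,
                mate_target=seg.next_reference_name,
                mate_start=(
                    seg.next_reference_start
                    if seg.next_reference_start is not None
                    and seg.next_reference_start >= 0
                    else None
                ),
                proper=seg.is_proper_pair,
            )
            alignments.append(a)
            if seg.is_proper_pair:
                proper_reads += 1
                proper_mates.setdefault(seg.query_name, []).append(a)
    if mapped == 0:
        raise MappingError("no alignments: zero mapped records in file")
    inserts: list[int] = []
    fragments: list[tuple[str, int, int]] = []
    for rid in sorted(proper_mates):
        mates = proper_mates[rid]
        if len(mates) == 2 and mates[0].target == mates[1].target:
            left = min(m.start for m in mates)
            right = max(m.end for m in mates)
            inserts.append(right - left)
            fragments.append((mates[0].target, left, right))
    if inserts:
        ins_mean, ins_sd = _robust_insert_stats(inserts)
    else:
        ins_mean, ins_sd = 450.0, 45.0
        warnings.warn("no proper pairs in alignment file; assuming a 450 bp insert")
    return PairedAlignmentSet(
        alignments=alignments,
        insert_mean=ins_mean,
        insert_sd=ins_sd,
        mapped_read_count=mapped,
        proper_pair_count=proper_reads,
        total_read_count=total,
        fragments=fragments,
    )
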