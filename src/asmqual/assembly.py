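"""Assembly containers and contiguity/completeness metrics.

An assembly is an ordered list of scaffolds.  Runs of N are treated as
gaps; scaffolds split at gaps give contigs.  All coordinates are 0-based,
half-open.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO

# ACGTN plus the IUPAC ambiguity codes, either case.
_VALID_RE = re.compile(r"[^ACGTNRYSWKMBDHVacgtnryswkmbdhv]")
_GAP_RE = re.compile(r"[Nn]+")

_COMPLEMENT = str.maketrans("ACGTNRYSWKMBDHV", "TGCANYRSWMKVHDB")


def reverse_complement(seq: str) -> str:
    return seq.upper().translate(_COMPLEMENT)[::-1]


class AssemblyError(ValueError):
    """Raised for malformed assembly input."""


@dataclass
class AssemblyRecord:
    """Ordered scaffolds with gap-run annotation.

    Attributes
    ----------
    sequences : list of (id, bases)
        Scaffold id and DNA string.  Order is preserved from the input.
    gap_runs : list of (seq_id, start, end)
        Maximal runs of N/n per scaffold, 0-based half-open.
    total_length : int
        Sum of scaffold lengths in bp.
    """

    sequences: list[tuple[str, str]]
    gap_runs: list[tuple[str, int, int]] = field(default_factory=list)
    total_length: int = 0

    def __post_init__(self) -> None:
        if not self.gap_runs and not self.total_length:
            self.gap_runs = _find_gap_runs(self.sequences)
            self.total_length = sum(len(s) for _, s in self.sequences)

    @classmethod
    def from_sequences(cls, sequences: Iterable[tuple[str, str]]) -> "AssemblyRecord":
        seqs = [(str(i), str(s)) for i, s in sequences]
        _validate(seqs)
        return cls(sequences=seqs)

    @property
    def ids(self) -> list[str]:
        return [i for i, _ in self.sequences]

    def seq(self, seq_id: str) -> str:
        for i, s in self.sequences:
            if i == seq_id:
                return s
        raise KeyError(seq_id)

    def lengths(self) -> list[int]:
        return [len(s) for _, s in self.sequences]

    def gap_runs_for(self, seq_id: str) -> list[tuple[int, int]]:
        return [(a, b) for i, a, b in self.gap_runs if i == seq_id]

    def n_gap_bases(self) -> int:
        return sum(b - a for _, a, b in self.gap_runs)

    def contig_lengths(self, min_gap: int = 1) -> list[int]:
        """Scaffold lengths split at gap runs of >= min_gap N bases."""
        out: list[int] = []
        for sid, s in self.sequences:
            cuts = [
                (a, b) for i, a, b in self.gap_runs if i == sid and (b - a) >= min_gap
            ]
            prev = 0
            for a, b in cuts:
                if a > prev:
                    out.append(a - prev)
                prev = b
            if len(s) > prev:
                out.append(len(s) - prev)
        return out


def _find_gap_runs(sequences: Sequence[tuple[str, str]]) -> list[tuple[str, int, int]]:
    runs = []
    for sid, s in sequences:
        for m in _GAP_RE.finditer(s):
            runs.append((sid, m.start(), m.end()))
    return runs


def _validate(seqs: Sequence[tuple[str, str]]) -> None:
    if not seqs:
        raise AssemblyError("empty assembly: no sequences found")
    seen: set[str] = set()
    for sid, s in seqs:
        if not sid:
            raise AssemblyError("empty sequence id")
        if sid in seen:
            raise AssemblyError(f"duplicate sequence id: {sid!r}")
        seen.add(sid)
        m = _VALID_RE.search(s)
        if m is not None:
            raise AssemblyError(
                f"non-IUPAC character {s[m.start()]!r} in sequence {sid!r} "
                f"at position {m.start()}"
            )


def read_fasta(path: str | Path) -> AssemblyRecord:
    """Read a (multi-record, wrapped or unwrapped) FASTA into an AssemblyRecord.

    Raises AssemblyError for an empty file, duplicate ids, or characters
    outside the IUPAC alphabet (naming the offending position).
    """
    records = [(r.id, str(r.seq)) for r in SeqIO.parse(str(path), "fasta")]
    return AssemblyRecord.from_sequences(records)


def write_fasta(asm: AssemblyRecord, path: str | Path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for sid, s in asm.sequences:
            fh.write(f">{sid}\n")
            for i in range(0, len(s), width):
                fh.write(s[i : i + width] + "\n")


def nxx(lengths: Sequence[int], x: float) -> int:
    """Nx statistic: smallest length L with sum(lengths >= L) >= x * total.

    ``nxx(lengths, 0.5)`` is the N50, ``nxx(lengths, 0.9)`` the N90.
    """
    if not lengths:
        raise AssemblyError("nxx of an empty length list")
    if not 0 < x <= 1:
        raise ValueError(f"x must be in (0, 1], got {x}")
    total = sum(lengths)
    acc = 0
    for n in sorted(lengths, reverse=True):
        acc += n
        if acc >= x * total:
            return n
    return min(lengths)  # unreachable for x <= 1


@dataclass
class ContiguityMetrics:
    """Completeness/continuity metrics for one assembly.

    ``norm_n50``/``norm_n90`` are the N50/N90 as a percent of total length,
    so a single-piece assembly has norm_n50 = 100.  ``norm_contig_number``
    is the contig count per Mbp of assembly.
    """

    gap_perc: float
    n50: int
    n90: int
    norm_n50: float
    norm_n90: float
    scaffold_number: int
    contig_number: int
    contig_n50: int
    norm_contig_number: float
    avg_scaffold_length: float


def contiguity_metrics(asm: AssemblyRecord, min_gap: int = 1) -> ContiguityMetrics:
    """Compute contiguity metrics from assembly sequence alone."""
    lengths = asm.lengths()
    if not lengths:
        raise AssemblyError("empty assembly")
    total = asm.total_length
    contigs = asm.contig_lengths(min_gap=min_gap) or [0]
    n50 = nxx(lengths, 0.5)
    n90 = nxx(lengths, 0.9)
    return ContiguityMetrics(
        gap_perc=100.0 * asm.n_gap_bases() / total,
        n50=n50,
        n90=n90,
        norm_n50=100.0 * n50 / total,
        norm_n90=100.0 * n90 / total,
        scaffold_number=len(lengths),
        contig_number=len(contigs),
        contig_n50=nxx(contigs, 0.5) if any(contigs) else 0,
        norm_contig_number=len(contigs) / (total / 1e6),
        avg_scaffold_length=total / len(lengths),
    )
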