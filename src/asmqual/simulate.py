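"""Simulators: degraded assemblies, paired-end reads, synthetic training sets.

These stand in for public assemblies and read archives so that the whole
pipeline — metric computation, reference scoring, model training — can be
exercised on generated data.  Every function is driven by an explicit seed
and reproduces bit-identical output for a fixed seed.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from asmqual.assembly import AssemblyRecord, reverse_complement

_BASES = np.frombuffer(b"ACGT", dtype="S1")


def random_assembly(
    n_sequences: int,
    length: int,
    seed: int,
    prefix: str = "seq",
) -> AssemblyRecord:
    """Uniform-random ACGT assembly of ``n_sequences`` scaffolds of ``length`` bp."""
    rng = np.random.default_rng(seed)
    seqs = []
    for i in range(n_sequences):
        arr = rng.integers(0, 4, size=length)
        seqs.append((f"{prefix}{i + 1}", _BASES[arr].tobytes().decode()))
    return AssemblyRecord.from_sequences(seqs)


@dataclass
class ErrorProfile:
    """Event rates for assembly degradation.

    Rates are per base; indel sizes follow a capped geometric distribution;
    CNV events duplicate (tandem) or delete a segment; gap events overwrite
    a segment with N.  ``fragmentation`` is the target scaffold count after
    random cutting.
    """

    snp_rate: float = 0.0
    indel_rate: float = 0.0
    indel_geom_p: float = 0.5
    indel_max: int = 50
    cnv_events: int = 0
    cnv_length_mean: int = 1000
    gap_events: int = 0
    gap_length_mean: int = 500
    fragmentation: int = 1
    label: str = ""

    def __post_init__(self) -> None:
        for r in (self.snp_rate, self.indel_rate):
            if not 0.0 <= r <= 1.0:
                raise ValueError(f"rate {r} outside [0, 1]")


@dataclass
class ReadProfile:
    """Paired-end library description.

    Defaults follow the recommended input for scoring: >= 10-fold coverage
    with an insert around 350-550 bp; 20-fold, 450 +/- 45 bp, 150 bp reads.
    """

    coverage: float = 20.0
    read_length: int = 150
    insert_mean: int = 450
    insert_sd: int = 45
    base_error_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.coverage <= 0:
            raise ValueError("coverage must be positive")


def _other_base(rng: np.random.Generator, base: str) -> str:
    choices = [b for b in "ACGT" if b != base]
    return choices[rng.integers(0, 3)]


def mutate_assembly(
    asm: AssemblyRecord,
    profile: ErrorProfile,
    seed: int,
) -> tuple[AssemblyRecord, list[dict]]:
    """Inject SNPs, indels, CNVs and gaps; return the mutant and a truth log.

    Events never start inside an existing gap run.  The truth log records
    each event with its coordinate on the original sequence and, for
    structural events, the junction coordinate on the mutated sequence.
    """
    rng = np.random.default_rng(seed)
    truth: list[dict] = []
    out_seqs: list[tuple[str, str]] = []
    for sid, seq in asm.sequences:
        arr = np.frombuffer(seq.upper().encode(), dtype="S1").copy()
        n = len(arr)
        eligible = np.ones(n, dtype=bool)
        for a, b in asm.gap_runs_for(sid):
            eligible[a:b] = False

        # SNPs first, in place (coordinates unaffected by later indels
        # because structural events are applied right-to-left afterwards).
        if profile.snp_rate > 0:
            hit = (rng.random(n) < profile.snp_rate) & eligible
            for pos in np.flatnonzero(hit):
                old = arr[pos].decode()
                new = _other_base(rng, old)
                arr[pos] = new.encode()
                truth.append(
                    {"type": "snp", "seq": sid, "start": int(pos),
                     "end": int(pos) + 1, "detail": f"{old}>{new}"}
                )

        # Structural events collected, then applied right-to-left.
        events: list[tuple[int, str, dict]] = []
        if profile.indel_rate > 0:
            hit = (rng.random(n) < profile.indel_rate) & eligible
            for pos in np.flatnonzero(hit):
                size = int(min(rng.geometric(profile.indel_geom_p), profile.indel_max))
                kind = "ins" if rng.random() < 0.5 else "del"
                events.append((int(pos), kind, {"size": size}))
        for _ in range(profile.cnv_events):
            length = max(1, int(rng.exponential(profile.cnv_length_mean)))
            pos = int(rng.integers(0, max(1, n - length)))
            kind = "cnv_gain" if rng.random() < 0.5 else "cnv_loss"
            events.append((pos, kind, {"size": length}))
        for _ in range(profile.gap_events):
            length = max(1, int(rng.exponential(profile.gap_length_mean)))
            pos = int(rng.integers(0, max(1, n - length)))
            events.append((pos, "gap", {"size": length}))

        events.sort(key=lambda e: e[0], reverse=True)
        pieces = arr
        for pos, kind, info in events:
            size = info["size"]
            if kind == "ins":
                ins = _BASES[rng.integers(0, 4, size=size)]
                pieces = np.concatenate([pieces[:pos], ins, pieces[pos:]])
            elif kind == "del":
                pieces = np.concatenate([pieces[:pos], pieces[pos + size:]])
            elif kind == "cnv_gain":
                seg = pieces[pos : pos + size]
                pieces = np.concatenate([pieces[:pos], seg, pieces[pos:]])
            elif kind == "cnv_loss":
                pieces = np.concatenate([pieces[:pos], pieces[pos + size:]])
            elif kind == "gap":
                pieces = pieces.copy()
                pieces[pos : pos + size] = b"N"
            truth.append(
                {"type": kind, "seq": sid, "start": pos,
                 "end": pos + size, "detail": f"size={size}"}
            )
        out_seqs.append((sid, pieces.tobytes().decode()))
    return AssemblyRecord.from_sequences(out_seqs), truth


def fragment_assembly(
    asm: AssemblyRecord,
    n_pieces: int,
    seed: int,
) -> AssemblyRecord:
    """Cut the assembly at uniform random positions into ``n_pieces`` scaffolds.

    Sequence content is conserved; pieces keep reference order and are
    suffixed ``_p1``, ``_p2``, ...
    """
    if n_pieces < 1:
        raise ValueError("n_pieces must be >= 1")
    if n_pieces == 1:
        return asm
    rng = np.random.default_rng(seed)
    total = asm.total_length
    if n_pieces > total:
        raise ValueError("more pieces than bases")
    # global cut positions over the concatenation, then mapped to sequences
    cuts = sorted(rng.choice(total - 1, size=n_pieces - 1, replace=False) + 1)
    out: list[tuple[str, str]] = []
    offset = 0
    for sid, seq in asm.sequences:
        local = [c - offset for c in cuts if offset < c < offset + len(seq)]
        bounds = [0] + local + [len(seq)]
        if len(bounds) == 2:
            out.append((sid, seq))
        else:
            for i in range(len(bounds) - 1):
                out.append((f"{sid}_p{i + 1}", seq[bounds[i] : bounds[i + 1]]))
        offset += len(seq)
    return AssemblyRecord.from_sequences([(i, s) for i, s in out if s])


# ---------------------------------------------------------------------------
# Read simulation

ReadPair = tuple[str, str, str]  # (read id, mate1 seq, mate2 seq)


def simulate_reads(
    asm: AssemblyRecord,
    profile: ReadProfile,
    seed: int,
) -> list[ReadPair]:
    """Simulate paired-end reads from uniformly placed fragments.

    Fragment lengths are normal(insert_mean, insert_sd) clipped to
    [read_length, sequence length]; fragments containing N are resampled a
    few times, then kept.  Mate 1 is the left (forward) fragment end and
    mate 2 the reverse-complemented right end; which physical end becomes
    mate 1 is randomised per pair.  Read count = coverage * total_length /
    (2 * read_length), rounded.
    """
    rng = np.random.default_rng(seed)
    rl = profile.read_length
    usable = [(sid, s.upper()) for sid, s in asm.sequences if len(s) >= profile.insert_mean]
    if not usable:
        raise ValueError(
            f"no sequence is at least insert_mean ({profile.insert_mean} bp) long"
        )
    lengths = np.array([len(s) for _, s in usable], dtype=float)
    weights = lengths / lengths.sum()
    n_pairs = round(profile.coverage * asm.total_length / (2 * rl))
    pairs: list[ReadPair] = []
    for i in range(n_pairs):
        for _attempt in range(10):
            si = int(rng.choice(len(usable), p=weights))
            sid, seq = usable[si]
            insert = int(np.clip(rng.normal(profile.insert_mean, profile.insert_sd),
                                 rl, len(seq)))
            start = int(rng.integers(0, len(seq) - insert + 1))
            frag = seq[start : start + insert]
            if "N" not in frag:
                break
        r1 = frag[:rl]
        r2 = reverse_complement(frag[-rl:])
        if rng.random() < 0.5:
            r1, r2 = r2, r1  # randomise which physical end is mate 1
        pairs.append((f"rd{i + 1}", r1, r2))
    if profile.base_error_rate > 0:
        pairs = [
            (rid, _add_errors(r1, profile.base_error_rate, rng),
             _add_errors(r2, profile.base_error_rate, rng))
            for rid, r1, r2 in pairs
        ]
    return pairs


def _add_errors(read: str, rate: float, rng: np.random.Generator) -> str:
    arr = list(read)
    for pos in np.flatnonzero(rng.random(len(arr)) < rate):
        if arr[pos] in "ACGT":
            arr[pos] = _other_base(rng, arr[pos])
    return "".join(arr)


def write_fastq_pairs(
    pairs: Sequence[ReadPair],
    path1: str | Path,
    path2: str | Path,
) -> None:
    """Write mate files; ``.gz`` suffixes are honoured."""
    def _open(p):
        p = str(p)
        return gzip.open(p, "wt") if p.endswith(".gz") else open(p, "w")

    with _open(path1) as f1, _open(path2) as f2:
        for rid, r1, r2 in pairs:
            f1.write(f"@{rid}/1\n{r1}\n+\n{'I' * len(r1)}\n")
            f2.write(f"@{rid}/2\n{r2}\n+\n{'I' * len(r2)}\n")


# ---------------------------------------------------------------------------
# Training-set generation

#: The default degradation gradient: five quality levels per genome with
#: single-base error rates 0/5/10/15/20%, mild accompanying indel and gap
#: load, and increasing fragmentation.  These are the study conditions the
#: end-to-end recovery checks run under.
DEFAULT_GRADIENT: tuple[ErrorProfile, ...] = (
    ErrorProfile(label="lvl0"),
    ErrorProfile(snp_rate=0.05, indel_rate=0.002, gap_events=1,
                 fragmentation=2, label="lvl5"),
    ErrorProfile(snp_rate=0.10, indel_rate=0.004, gap_events=2,
                 fragmentation=4, label="lvl10"),
    ErrorProfile(snp_rate=0.15, indel_rate=0.006, gap_events=3,
                 fragmentation=6, label="lvl15"),
    ErrorProfile(snp_rate=0.20, indel_rate=0.008, gap_events=4,
                 fragmentation=8, label="lvl20"),
)


def generate_training_set(
    n_genomes: int = 20,
    quality_gradient: Sequence[ErrorProfile] = DEFAULT_GRADIENT,
    ref_length: int = 25_000,
    read_profile: ReadProfile | None = None,
    seed: int = 0,
    min_identity: float = 0.5,
) -> pd.DataFrame:
    """Build a scored metrics table from synthetic genomes.

    For each genome a random reference is drawn; each profile in the
    gradient produces a degraded copy.  Reads are simulated from the
    *pre-degradation* reference and mapped to the degraded copy, so the
    mapping metrics see the injected errors, mirroring real reads mapped to
    an imperfect assembly.  Reference scoring (PMB + internal/external
    scaling) supplies the target column ``score``.
    """
    from asmqual.flags import accuracy_metrics, flag_errors
    from asmqual.mapping import map_reads
    from asmqual.metrics import metrics_row
    from asmqual.refscore import (count_differences, ideal_distance,
                                  percent_matching_bases, score_instances)
    from asmqual.assembly import contiguity_metrics

    if n_genomes < 2:
        raise ValueError("need at least two genomes (external scaling)")
    rp = read_profile or ReadProfile()
    rng = np.random.default_rng(seed)
    rows = []
    for g in range(n_genomes):
        gseed = int(rng.integers(0, 2**31 - 1))
        ref = random_assembly(1, ref_length, seed=gseed, prefix=f"g{g + 1}s")
        reads = simulate_reads(ref, rp, seed=gseed + 1)
        for j, profile in enumerate(quality_gradient):
            degraded, _ = mutate_assembly(ref, profile, seed=gseed + 2 + j)
            if profile.fragmentation > 1:
                degraded = fragment_assembly(
                    degraded, profile.fragmentation, seed=gseed + 100 + j
                )
            aln = map_reads(degraded, reads, min_identity=min_identity)
            tracks = flag_errors(aln, degraded)
            row = metrics_row(
                contiguity_metrics(degraded), accuracy_metrics(tracks, aln)
            )
            row["organism"] = f"genome{g + 1}"
            row["instance"] = f"genome{g + 1}/{profile.label or f'lvl{j}'}"
            row["generation"] = "simulated_error" if j else "real"
            row["snp_rate"] = profile.snp_rate
            row["pmb"] = percent_matching_bases(count_differences(degraded, ref))
            row["distance"] = ideal_distance(row)
            rows.append(row)
    table = pd.DataFrame(rows)
    table = score_instances(table)
    table = table.rename(columns={"final_score": "score"})
    return table.reset_index(drop=True)


def synthetic_metrics_table(
    n: int = 400,
    noise_sd: float = 5.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Cheap parametric metrics table for model benchmarking.

    Draws a latent per-instance error rate and fragmentation, maps them
    through a saturating response (mimicking how read mapping collapses at
    high divergence) to the 13 metrics, and sets ``score`` to a smooth
    nonlinear function of the metrics plus Gaussian noise of sd
    ``noise_sd``.  No sequences or mapping are involved, so n can be large.
    """
    rng = np.random.default_rng(seed)
    e = rng.uniform(0.0, 0.30, n)            # latent error rate
    frag = rng.integers(1, 12, n).astype(float)
    gap = rng.uniform(0, 20, n)
    mapped = 1.0 / (1.0 + np.exp((e - 0.12) * 40.0))   # mapping collapse
    jit = lambda s: rng.normal(0.0, s, n)

    t = pd.DataFrame(
        {
            "normN50": np.clip(100.0 / frag + jit(2), 0, 100),
            "gap_perc": np.clip(gap + jit(1), 0, 100),
            "prop_pair_perc": np.clip(100 * mapped + jit(3), 0, 100),
            "FCD_err_in_contig": np.clip(5 * e * 100 / 30 * (1 - mapped) + jit(1), 0, 100),
            "FCD_err_over_gap": np.clip(gap * 0.4 + jit(1), 0, 100),
            "low_fc_in_contig": np.clip(60 * (1 - mapped) + jit(3), 0, 100),
            "low_fc_over_gap": np.clip(gap * 0.8 + 10 * (1 - mapped) + jit(2), 0, 100),
            "links": np.clip(8 * (1 - mapped) + jit(1), 0, 100),
            "clip": np.clip(40 * e * mapped * 10 / 3 + jit(2), 0, 100),
            "coll_repeat": np.clip(jit(1) + 1, 0, 100),
            "low_read_cov": np.clip(50 * (1 - mapped) + jit(2), 0, 100),
            "error_free_bases": np.clip(100 * (1 - e) * mapped + jit(3), 0, 100),
            "norm_contig_number": frag / 0.025 + jit(5),
        }
    )
    score = (
        100.0
        * (1 - e)
        * mapped ** 0.5
        * (0.6 + 0.4 * t["normN50"] / 100)
        * (1 - 0.4 * t["gap_perc"] / 100)
    )
    t["score"] = score + rng.normal(0.0, noise_sd, n)
    return t
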