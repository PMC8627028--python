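"""Independent oracles used by the test suite.

These deliberately use different algorithms from the package code they
check (full-matrix dynamic programming, brute-force enumeration).
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def lcs_quadratic(a: str, b: str) -> int:
    """Full-matrix LCS by the classic quadratic DP (running-max row form)."""
    A = np.frombuffer(a.encode(), dtype="S1")
    B = np.frombuffer(b.encode(), dtype="S1")
    prev = np.zeros(len(B) + 1, dtype=np.int32)
    for i in range(len(A)):
        eq = (B == A[i]).astype(np.int32)
        cand = np.maximum(prev[1:], prev[:-1] + eq)
        cur = np.empty_like(prev)
        cur[0] = 0
        cur[1:] = np.maximum.accumulate(cand)
        prev = cur
    return int(prev[-1])


def oracle_diffs(ref: str, query: str) -> int:
    """Reference bases unmatched under a match-maximising alignment."""
    return len(ref) - lcs_quadratic(ref, query)


def oracle_nxx(lengths, x):
    """Largest length L with sum(l for l >= L) >= x * total, by enumeration."""
    total = sum(lengths)
    for L in sorted(set(lengths), reverse=True):
        if sum(l for l in lengths if l >= L) >= x * total:
            return L
    raise AssertionError("unreachable for x <= 1")


def discrete_mi(*cols) -> float:
    """I(X1..Xk-1 ; Xk) for discrete columns by direct enumeration (nats)."""
    *xs, y = [np.asarray(c) for c in cols]
    n = len(y)
    joint = list(zip(*(tuple(x) for x in xs)))
    mi = 0.0
    for jx in set(joint):
        for yy in set(y.tolist()):
            pxy = sum(1 for a, b in zip(joint, y) if a == jx and b == yy) / n
            if pxy == 0:
                continue
            px = joint.count(jx) / n
            py = (y == yy).mean()
            mi += pxy * math.log(pxy / (px * py))
    return mi


def brute_jmim_order(cols: dict[str, np.ndarray], y: np.ndarray) -> list[str]:
    """Greedy JMIM selection by brute-force joint-MI evaluation."""
    names = list(cols)
    sel = [max(names, key=lambda f: (discrete_mi(cols[f], y), -names.index(f)))]
    while len(sel) < len(names):
        rest = [f for f in names if f not in sel]
        score = {
            f: min(discrete_mi(cols[f], cols[s], y) for s in sel) for f in rest
        }
        sel.append(max(rest, key=lambda f: (score[f], -rest.index(f))))
    return sel
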