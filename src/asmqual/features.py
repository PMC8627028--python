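"""Feature-selection cascade for the quality metrics.

Five stages reduce the 13 metrics to the model's feature subset:

1. marginal Pearson filter (drop |r| < 0.1 against the target score);
2. pairwise correlation matrix (multicollinearity report);
3. joint-mutual-information maximisation (JMIM) ranking;
4. permutation importance (%IncMSE) from a random-forest fit;
5. exhaustive best-subset linear regression up to size 6, with an
   automatic exclusion of features whose fitted coefficient sign
   contradicts their marginal correlation sign.
"""

from __future__ import annotations

import itertools
import json
import warnings
from dataclasses import asdict, dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from asmqual.metrics import METRIC_NAMES


@dataclass
class FeatureReport:
    """Everything the cascade computed, serialisable as JSON."""

    pearson_r: dict[str, float]
    retained: list[str]
    correlation_matrix: pd.DataFrame
    collinear_pairs: list[tuple[str, str, float]]
    jmim_ranking: list[str]
    inc_mse: dict[str, float]
    best_subsets: dict[int, tuple[list[str], float, float]]  # size -> (set, R2, RSS)
    final_features: list[str]
    sign_excluded: list[str]

    def to_json(self) -> str:
        d = asdict(self)
        d["correlation_matrix"] = self.correlation_matrix.to_dict()
        d["best_subsets"] = {
            str(k): {"features": f, "r_squared": r2, "rss": rss}
            for k, (f, r2, rss) in self.best_subsets.items()
        }
        return json.dumps(d, indent=2)


def _features_of(t: pd.DataFrame) -> list[str]:
    return [c for c in METRIC_NAMES if c in t.columns]


def pearson_filter(
    t: pd.DataFrame,
    target: str = "score",
    lo: float = -0.1,
    hi: float = 0.1,
    features: Sequence[str] | None = None,
) -> tuple[list[str], dict[str, float]]:
    """Drop features whose Pearson r against the target lies in (lo, hi).

    Returns (retained features, r per feature).  Zero-variance features
    have undefined r and are removed with a warning.
    """
    if len(t) < 3:
        raise ValueError("need at least 3 rows for a correlation filter")
    y = t[target].to_numpy(float)
    if np.ptp(y) == 0:
        raise ValueError("target has zero variance")
    feats = list(features) if features is not None else _features_of(t)
    rs: dict[str, float] = {}
    keep: list[str] = []
    for f in feats:
        x = t[f].to_numpy(float)
        if np.ptp(x) == 0:
            warnings.warn(f"feature {f!r} has zero variance; removed")
            rs[f] = float("nan")
            continue
        r = float(stats.pearsonr(x, y).statistic)
        rs[f] = r
        if r <= lo or r >= hi:
            keep.append(f)
    return keep, rs


def correlation_matrix(
    t: pd.DataFrame,
    features: Sequence[str] | None = None,
    collinear_threshold: float = 0.8,
) -> tuple[pd.DataFrame, list[tuple[str, str, float]]]:
    """Pairwise Pearson r among features, with |r| > threshold pairs flagged."""
    feats = list(features) if features is not None else _features_of(t)
    if len(t) < 3:
        raise ValueError("need at least 3 rows")
    mat = t[feats].corr(method="pearson")
    flagged = [
        (feats[i], feats[j], float(mat.iloc[i, j]))
        for i in range(len(feats))
        for j in range(i + 1, len(feats))
        if abs(mat.iloc[i, j]) > collinear_threshold
    ]
    return mat, flagged


# ---------------------------------------------------------------------------
# Joint mutual information


def _discretize(x: np.ndarray, bins: int) -> np.ndarray:
    """Equal-frequency binning; ties collapse bins (qcut, duplicates dropped)."""
    if np.unique(x).size <= bins:
        _, inv = np.unique(x, return_inverse=True)
        return inv
    codes = pd.qcut(x, q=bins, labels=False, duplicates="drop")
    return np.asarray(codes, dtype=int)


def _mi(*cols: np.ndarray) -> float:
    """Mutual information I(X1,...,Xk-1 ; Xk) of discrete columns, in nats.

    The first k-1 columns are treated jointly as one variable.
    """
    *xs, y = cols
    if len(xs) == 1:
        joint_x = xs[0]
    else:
        joint_x = np.ravel_multi_index(
            tuple(x.astype(int) for x in xs),
            tuple(int(x.max()) + 1 for x in xs),
        )
    n = y.size
    xy = pd.crosstab(joint_x, y).to_numpy(float) / n
    px = xy.sum(axis=1, keepdims=True)
    py = xy.sum(axis=0, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        term = xy * np.log(xy / (px * py))
    return float(np.nansum(term))


def jmim_rank(
    t: pd.DataFrame,
    features: Sequence[str],
    k: int,
    target: str = "score",
    bins: int = 10,
) -> list[str]:
    """Greedy JMIM feature ranking.

    Starts from the feature with maximal I(X; Y), then repeatedly adds the
    candidate X maximising min over selected S of I(X, X_s; Y).  Ties break
    by the order features were given.  Returns the first ``k`` selections.
    """
    feats = list(features)
    if k > len(feats):
        raise ValueError(f"k={k} exceeds {len(feats)} candidate features")
    disc = {f: _discretize(t[f].to_numpy(float), bins) for f in feats}
    y = _discretize(t[target].to_numpy(float), bins)
    mi1 = {f: _mi(disc[f], y) for f in feats}
    selected = [max(feats, key=lambda f: (mi1[f], -feats.index(f)))]
    while len(selected) < k:
        rest = [f for f in feats if f not in selected]
        scores = {
            f: min(_mi(disc[f], disc[s], y) for s in selected) for f in rest
        }
        selected.append(max(rest, key=lambda f: (scores[f], -rest.index(f))))
    return selected


# ---------------------------------------------------------------------------
# Permutation importance (out-of-bag %IncMSE)


def permutation_importance(
    results,
    t: pd.DataFrame,
    reps: int = 5,
    seed: int = 0,
    target: str = "score",
) -> dict[str, float]:
    """%IncMSE per feature from a fitted random forest.

    For every tree, the out-of-bag rows are predicted with each feature
    column permuted; the percent increase of OOB MSE over the unpermuted
    OOB MSE, averaged over trees and ``reps`` permutations, is the
    importance.  ``results`` is a fitted rf QualityModelResults (or a bare
    sklearn RandomForestRegressor with a ``feature_names`` attribute).
    """
    from sklearn.ensemble import RandomForestRegressor

    if reps < 1:
        raise ValueError("reps must be >= 1")
    est = getattr(results, "estimator", results)
    feats = list(getattr(results, "feature_names", None) or est.feature_names)
    forest = est[-1] if hasattr(est, "steps") else est
    if not isinstance(forest, RandomForestRegressor) or not hasattr(
        forest, "estimators_"
    ):
        raise ValueError("permutation importance needs a fitted random forest")
    X = t[feats].to_numpy(float)
    y = t[target].to_numpy(float)
    n = len(t)
    rng = np.random.default_rng(seed)
    inc = {f: [] for f in feats}
    for tree, unsampled in zip(
        forest.estimators_,
        (_oob_indices(forest, i, n) for i in range(len(forest.estimators_))),
    ):
        if unsampled.size < 2:
            continue
        Xo, yo = X[unsampled], y[unsampled]
        base = float(np.mean((tree.predict(Xo) - yo) ** 2))
        if base == 0:
            continue
        for j, f in enumerate(feats):
            deltas = []
            for _ in range(reps):
                Xp = Xo.copy()
                Xp[:, j] = rng.permutation(Xp[:, j])
                mse = float(np.mean((tree.predict(Xp) - yo) ** 2))
                deltas.append((mse - base) / base)
            inc[f].append(100.0 * float(np.mean(deltas)))
    return {f: float(np.mean(v)) if v else 0.0 for f, v in inc.items()}


def _oob_indices(forest, i: int, n: int) -> np.ndarray:
    """Out-of-bag row indices of tree ``i``.

    Replays the unweighted bootstrap draw each tree was built with (a
    full-size ``randint`` resample seeded by the tree's random_state) and
    returns the complement.
    """
    from sklearn.utils import check_random_state

    rs = check_random_state(forest.estimators_[i].random_state)
    sampled = rs.randint(0, n, n)
    mask = np.ones(n, dtype=bool)
    mask[sampled] = False
    return np.flatnonzero(mask)


# ---------------------------------------------------------------------------
# Exhaustive best-subset regression


def _ols_fit(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float, float]:
    A = np.column_stack([np.ones(len(X)), X])
    coef, *_ = np.linalg.lstsq(A, y, rcond=None)
    resid = y - A @ coef
    rss = float(resid @ resid)
    tss = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - rss / tss if tss > 0 else 0.0
    return coef[1:], r2, rss


def exhaustive_subset_search(
    t: pd.DataFrame,
    candidates: Sequence[str],
    max_size: int = 6,
    target: str = "score",
) -> tuple[dict[int, tuple[list[str], float, float]], list[str], list[str]]:
    """OLS over every candidate subset of size 1..max_size.

    Returns (best subset per size with R^2 and RSS, final feature set,
    sign-excluded features).  The final set is the highest-R^2 subset in
    which no fitted coefficient contradicts the sign of that feature's
    marginal correlation with the target — the automatic form of dropping
    a feature whose regression weight flips sign under multicollinearity.
    """
    cands = list(candidates)
    if len(cands) > 20:
        raise ValueError("more than 20 candidates; exhaustive search refused")
    y = t[target].to_numpy(float)
    marginal = {
        f: np.sign(np.corrcoef(t[f].to_numpy(float), y)[0, 1]) for f in cands
    }
    best_per_size: dict[int, tuple[list[str], float, float]] = {}
    all_fits: list[tuple[list[str], np.ndarray, float, float]] = []
    for size in range(1, min(max_size, len(cands)) + 1):
        if len(t) <= size + 1:
            warnings.warn(f"subsets of size {size} skipped: too few rows")
            continue
        best = None
        for combo in itertools.combinations(cands, size):
            X = t[list(combo)].to_numpy(float)
            coef, r2, rss = _ols_fit(X, y)
            all_fits.append((list(combo), coef, r2, rss))
            if best is None or (r2, -rss) > (best[1], -best[2]):
                best = (list(combo), r2, rss)
        if best is not None:
            best_per_size[size] = best
    # final set: best consistent-sign subset across all sizes
    consistent = []
    for combo, coef, r2, rss in all_fits:
        if all(
            marginal[f] == 0 or np.sign(c) == marginal[f]
            for f, c in zip(combo, coef)
        ):
            consistent.append((combo, r2, rss))
    excluded: list[str] = []
    if consistent:
        final, _, _ = max(consistent, key=lambda x: (x[1], -x[2]))
        top_overall = max(all_fits, key=lambda x: (x[2], -x[3]))[0]
        excluded = sorted(set(top_overall) - set(final))
    else:
        final = best_per_size[max(best_per_size)][0]
    return best_per_size, final, excluded


def run_cascade(
    t: pd.DataFrame,
    target: str = "score",
    seed: int = 0,
    max_subset_size: int = 6,
    n_trees: int = 500,
) -> FeatureReport:
    """Run the full selection cascade and return a FeatureReport."""
    from asmqual.model import AssemblyQualityModel

    retained, rs = pearson_filter(t, target=target)
    mat, flagged = correlation_matrix(t)
    ranking = jmim_rank(t, retained, k=len(retained), target=target)
    rf = AssemblyQualityModel(
        t, features=retained, target=target, family="rf"
    ).fit(seed=seed, n_trees=n_trees)
    inc = permutation_importance(rf, t, reps=3, seed=seed, target=target)
    # stages 3 and 4 each nominate removals: bottom-2 of the JMIM ranking
    # and the weakest %IncMSE features; candidates = retained minus those
    # nominated by the JMIM stage.
    jmim_drop = ranking[-2:] if len(ranking) > 4 else []
    candidates = [f for f in retained if f not in jmim_drop]
    best_subsets, final, sign_excluded = exhaustive_subset_search(
        t, candidates, max_size=max_subset_size, target=target
    )
    return FeatureReport(
        pearson_r=rs,
        retained=retained,
        correlation_matrix=mat,
        collinear_pairs=flagged,
        jmim_ranking=ranking,
        inc_mse=inc,
        best_subsets=best_subsets,
        final_features=final,
        sign_excluded=sign_excluded,
    )
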