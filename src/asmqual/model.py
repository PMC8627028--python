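"""Regression models mapping a metrics vector to a quality score.

Organised as a model/results pair: :class:`AssemblyQualityModel` is built
from a scored metrics table and a family name; ``fit()`` tunes the
family's hyperparameters by cross-validated RMSE and returns a
:class:`QualityModelResults` carrying the fitted estimator, the tuning
trace, provenance (seed, data digest) and prediction/evaluation/summary
methods.

Families and their tuning protocols:

================  =====================================  =======================
family            estimator                              cross-validation
================  =====================================  =======================
glm               ordinary least squares                 10-fold, 10 repeats
elastic_net       elastic net                            10-fold; alpha/lambda grid
knn               k-nearest neighbours (standardised)    10-fold, 5 repeats; odd k 3..21
rf                random forest, 500 trees               10-fold; mtry in {2, 4, 6}
svm_linear        SVR, linear kernel (standardised)      5-fold; C in {0.25..4}
svm_poly          SVR, polynomial kernel (standardised)  5-fold; C grid x degree {2, 3}
================  =====================================  =======================
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import joblib
import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor
from sklearn.linear_model import ElasticNet, LinearRegression
from sklearn.model_selection import (
    GridSearchCV,
    KFold,
    RepeatedKFold,
    cross_val_score,
)
from sklearn.neighbors import KNeighborsRegressor
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVR

from asmqual.metrics import MODEL_FEATURES

FAMILIES = ("glm", "elastic_net", "knn", "rf", "svm_linear", "svm_poly")


@dataclass
class SplitSpec:
    """Seeded train/test partition: |train| = round(train_fraction * n)."""

    train_fraction: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must be in (0, 1)")


def split_data(
    t: pd.DataFrame, spec: SplitSpec
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Random, reproducible train/test split of a metrics table."""
    n = len(t)
    if n < 5:
        raise ValueError("need at least 5 rows to split")
    n_train = round(spec.train_fraction * n)
    rng = np.random.default_rng(spec.seed)
    perm = rng.permutation(n)
    return t.iloc[np.sort(perm[:n_train])], t.iloc[np.sort(perm[n_train:])]


@dataclass
class EvalResult:
    """Test-set performance: RMSE plus two R-squared conventions.

    ``r_squared`` is the squared Pearson correlation between predictions
    and observed scores (a line-of-best-fit R^2); ``r_squared_resid`` is
    1 - SS_res/SS_tot.
    """

    rmse: float
    r_squared: float
    r_squared_resid: float


def _grid(family: str, seed: int, n_trees: int):
    if family == "glm":
        return (
            LinearRegression(),
            {},
            RepeatedKFold(n_splits=10, n_repeats=10, random_state=seed),
        )
    if family == "elastic_net":
        est = Pipeline(
            [("scale", StandardScaler()), ("m", ElasticNet(max_iter=50_000))]
        )
        grid = {
            "m__l1_ratio": np.round(np.arange(0.0, 1.01, 0.1), 2),
            "m__alpha": np.logspace(-4, 1, 11),
        }
        return est, grid, KFold(10, shuffle=True, random_state=seed)
    if family == "knn":
        est = Pipeline([("scale", StandardScaler()), ("m", KNeighborsRegressor())])
        return (
            est,
            {"m__n_neighbors": list(range(3, 22, 2))},
            RepeatedKFold(n_splits=10, n_repeats=5, random_state=seed),
        )
    if family == "rf":
        est = RandomForestRegressor(
            n_estimators=n_trees, random_state=seed, n_jobs=1
        )
        return (
            est,
            {"max_features": [2, 4, 6]},
            KFold(10, shuffle=True, random_state=seed),
        )
    if family in ("svm_linear", "svm_poly"):
        kernel = "linear" if family == "svm_linear" else "poly"
        est = Pipeline([("scale", StandardScaler()), ("m", SVR(kernel=kernel))])
        grid = {"m__C": [0.25, 0.5, 1.0, 2.0, 4.0]}
        if kernel == "poly":
            grid["m__degree"] = [2, 3]
        return est, grid, KFold(5, shuffle=True, random_state=seed)
    raise ValueError(f"unknown model family {family!r}")


class AssemblyQualityModel:
    """A quality-score regressor specified by (table, features, family).

    Parameters
    ----------
    table : DataFrame
        Scored metrics table; must contain the feature columns and the
        target column.
    features : sequence of str, optional
        Feature subset (default: the six-metric scoring set).
    target : str
        Target column name (default ``"score"``).
    family : str
        One of ``glm, elastic_net, knn, rf, svm_linear, svm_poly``.
    """

    def __init__(
        self,
        table: pd.DataFrame,
        features: Sequence[str] | None = None,
        target: str = "score",
        family: str = "rf",
    ) -> None:
        if family not in FAMILIES:
            raise ValueError(f"unknown model family {family!r}")
        self.features = list(features) if features is not None else list(MODEL_FEATURES)
        self.target = target
        self.family = family
        missing = [c for c in self.features + [target] if c not in table.columns]
        if missing:
            raise ValueError(f"table lacks columns: {missing}")
        if table[target].nunique() < 2 and family != "glm":
            # a constant target is legal only as a degenerate fit check
            warnings.warn("target is constant; model will predict a constant")
        self.table = table.reset_index(drop=True)

    @classmethod
    def from_dataframe(
        cls,
        table: pd.DataFrame,
        features: Sequence[str] | None = None,
        target: str = "score",
        family: str = "rf",
    ) -> "AssemblyQualityModel":
        return cls(table, features=features, target=target, family=family)

    def fit(self, seed: int = 0, n_trees: int = 500) -> "QualityModelResults":
        """Tune by CV RMSE and fit on the full table."""
        folds = {"glm": 10, "elastic_net": 10, "knn": 10, "rf": 10}.get(
            self.family, 5
        )
        if len(self.table) < 2 * folds:
            raise ValueError(
                f"need at least {2 * folds} rows for {folds}-fold tuning, "
                f"got {len(self.table)}"
            )
        X = self.table[self.features].to_numpy(float)
        y = self.table[self.target].to_numpy(float)
        est, grid, cv = _grid(self.family, seed, n_trees)
        if self.family == "rf":
            grid = {
                "max_features": [m for m in grid["max_features"]
                                 if m <= len(self.features)]
            }
        if grid:
            search = GridSearchCV(
                est, grid, cv=cv, scoring="neg_root_mean_squared_error", n_jobs=1
            )
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                search.fit(X, y)
            estimator = search.best_estimator_
            hyper = dict(search.best_params_)
            cv_rmse = -float(search.best_score_)
        else:
            scores = cross_val_score(
                est, X, y, cv=cv, scoring="neg_root_mean_squared_error"
            )
            cv_rmse = -float(np.mean(scores))
            estimator = est.fit(X, y)
            hyper = {}
        return QualityModelResults(
            model=self,
            estimator=estimator,
            hyperparameters=hyper,
            cv_rmse=cv_rmse,
            seed=seed,
            data_digest=_digest(self.table, self.features, self.target),
        )


def _digest(t: pd.DataFrame, features: Sequence[str], target: str) -> str:
    h = hashlib.sha256()
    h.update(
        t[list(features) + [target]].round(9).to_csv(index=False).encode()
    )
    return h.hexdigest()[:16]


@dataclass
class QualityModelResults:
    """A fitted quality model plus provenance."""

    model: AssemblyQualityModel
    estimator: object
    hyperparameters: dict
    cv_rmse: float
    seed: int
    data_digest: str

    @property
    def feature_names(self) -> list[str]:
        return self.model.features

    @property
    def family(self) -> str:
        return self.model.family

    def predict(self, m: pd.DataFrame | Mapping[str, float]) -> np.ndarray | float:
        """Predict quality score(s) for a metrics vector or table.

        Scores above 100 are legal: they indicate a sequence cleaner than
        the best training chromosome.
        """
        single = not isinstance(m, pd.DataFrame)
        df = pd.DataFrame([m]) if single else m
        missing = [c for c in self.feature_names if c not in df.columns]
        if missing:
            raise ValueError(f"metrics vector lacks features: {missing}")
        X = df[self.feature_names].to_numpy(float)
        pred = self.estimator.predict(X)
        return float(pred[0]) if single else pred

    def evaluate(self, test: pd.DataFrame) -> EvalResult:
        """RMSE and R-squared of the fitted model on a held-out table."""
        if len(test) == 0:
            raise ValueError("empty test table")
        y = test[self.model.target].to_numpy(float)
        pred = self.predict(test)
        rmse = float(np.sqrt(np.mean((pred - y) ** 2)))
        if np.ptp(pred) == 0 or np.ptp(y) == 0:
            warnings.warn("constant predictions or targets; r_squared set to 0")
            r2p = 0.0
        else:
            r2p = float(np.corrcoef(pred, y)[0, 1] ** 2)
        tss = float(((y - y.mean()) ** 2).sum())
        r2r = 1.0 - float(((y - pred) ** 2).sum()) / tss if tss > 0 else 0.0
        return EvalResult(rmse=rmse, r_squared=r2p, r_squared_resid=r2r)

    def summary(self) -> str:
        lines = [
            "Assembly quality model",
            "======================",
            f"family:          {self.family}",
            f"features:        {', '.join(self.feature_names)}",
            f"n observations:  {len(self.model.table)}",
            f"tuned params:    {self.hyperparameters or '(none)'}",
            f"CV RMSE:         {self.cv_rmse:.4f}",
            f"seed:            {self.seed}",
            f"data digest:     {self.data_digest}",
        ]
        return "\n".join(lines)

    # -- persistence -------------------------------------------------------

    def save(self, directory: str | Path) -> None:
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        meta = {
            "family": self.family,
            "features": self.feature_names,
            "target": self.model.target,
            "hyperparameters": {
                k: (v.item() if hasattr(v, "item") else v)
                for k, v in self.hyperparameters.items()
            },
            "cv_rmse": self.cv_rmse,
            "seed": self.seed,
            "data_digest": self.data_digest,
        }
        (d / "metadata.json").write_text(json.dumps(meta, indent=2))
        joblib.dump(self.estimator, d / "estimator.joblib")

    @classmethod
    def load(cls, directory: str | Path) -> "QualityModelResults":
        d = Path(directory)
        meta = json.loads((d / "metadata.json").read_text())
        estimator = joblib.load(d / "estimator.joblib")
        shell = AssemblyQualityModel.__new__(AssemblyQualityModel)
        shell.features = meta["features"]
        shell.target = meta["target"]
        shell.family = meta["family"]
        shell.table = pd.DataFrame(columns=meta["features"] + [meta["target"]])
        return cls(
            model=shell,
            estimator=estimator,
            hyperparameters=meta["hyperparameters"],
            cv_rmse=meta["cv_rmse"],
            seed=meta["seed"],
            data_digest=meta["data_digest"],
        )


# ---------------------------------------------------------------------------
# Functional wrappers


def train_model(
    train: pd.DataFrame,
    family: str,
    seed: int = 0,
    features: Sequence[str] | None = None,
    target: str = "score",
    n_trees: int = 500,
) -> QualityModelResults:
    return AssemblyQualityModel(
        train, features=features, target=target, family=family
    ).fit(seed=seed, n_trees=n_trees)


def evaluate(results: QualityModelResults, test: pd.DataFrame) -> EvalResult:
    return results.evaluate(test)


def select_best(results: Mapping[str, EvalResult]) -> str:
    """Family with the lowest RMSE; ties by higher R^2, then family order."""
    if not results:
        raise ValueError("no evaluation results")
    order = {f: i for i, f in enumerate(FAMILIES)}
    return min(
        results,
        key=lambda f: (results[f].rmse, -results[f].r_squared, order.get(f, 99)),
    )


def finalize_and_predict(
    family: str,
    t: pd.DataFrame,
    m: Mapping[str, float] | pd.DataFrame,
    seed: int = 0,
    features: Sequence[str] | None = None,
    target: str = "score",
    n_trees: int = 500,
) -> float | np.ndarray:
    """Retrain ``family`` on the full table and predict for ``m``."""
    res = train_model(
        t, family, seed=seed, features=features, target=target, n_trees=n_trees
    )
    return res.predict(m)
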