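"""Stacked regression head: SVR + gradient-boosted trees + linear blend.

The encoder's 256-dimensional embeddings feed two base regressors — an
RBF-kernel support-vector regression and a gradient-boosted tree ensemble —
whose predictions are blended by an ordinary-least-squares meta-learner
(two weights + intercept).  To keep the meta-fit honest, the base
predictions used for it come from internal 5-fold out-of-fold predictions
on the training split; fitting OLS on in-sample base predictions would
overweight whichever base learner overfits hardest.  Both base learners are
then refit on the full training split for deployment.
"""

from __future__ import annotations

import pickle
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.base import clone
from sklearn.linear_model import LinearRegression
from sklearn.model_selection import KFold
from sklearn.svm import SVR
from xgboost import XGBRegressor

from .errors import DimensionError, InsufficientDataError
from .nn import ModelConfig

__all__ = ["TrainedEnsemble", "fit_ensemble", "default_base_estimators"]

_META_FOLDS = 5


def default_base_estimators(cfg: ModelConfig):
    """The standard base-learner pair: RBF-kernel SVR and boosted trees."""
    svr = SVR(kernel="rbf", C=cfg.svr_c, epsilon=cfg.svr_epsilon)
    xgb = XGBRegressor(
        n_estimators=cfg.xgb_n_estimators, max_depth=cfg.xgb_max_depth,
        learning_rate=cfg.xgb_learning_rate, random_state=cfg.seed,
        n_jobs=1, verbosity=0,
    )
    return svr, xgb


@dataclass
class TrainedEnsemble:
    """Two fitted base regressors plus OLS meta-coefficients."""

    base_estimators: tuple            # fitted on the full training split
    meta_weights: np.ndarray          # (2,)
    meta_intercept: float
    config: ModelConfig

    def predict(self, embeddings: np.ndarray) -> np.ndarray:
        """w1 * SVR(emb) + w2 * GBT(emb) + b, one scalar per row."""
        embeddings = np.atleast_2d(np.asarray(embeddings, dtype=float))
        base = np.column_stack([est.predict(embeddings)
                                for est in self.base_estimators])
        return base @ self.meta_weights + self.meta_intercept

    def save(self, directory: str | Path) -> None:
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        with open(d / "base_learners.pkl", "wb") as fh:
            pickle.dump(self.base_estimators, fh)
        np.savetxt(d / "meta_coefficients.txt",
                   np.append(self.meta_weights, self.meta_intercept))
        self.config.to_json(d / "config.json")

    @classmethod
    def load(cls, directory: str | Path) -> "TrainedEnsemble":
        d = Path(directory)
        with open(d / "base_learners.pkl", "rb") as fh:
            base = pickle.load(fh)
        coefs = np.loadtxt(d / "meta_coefficients.txt")
        return cls(tuple(base), coefs[:-1], float(coefs[-1]),
                   ModelConfig.from_json(d / "config.json"))


def fit_ensemble(embeddings: np.ndarray, affinities: np.ndarray,
                 cfg: ModelConfig | None = None,
                 base_estimators: tuple | None = None) -> TrainedEnsemble:
    """Fit the two base regressors and the OLS meta-learner.

    ``base_estimators`` may inject alternative (unfitted) scikit-learn style
    regressors, e.g. oracles in tests; defaults to SVR + XGBoost.
    """
    cfg = cfg or ModelConfig()
    X = np.asarray(embeddings, dtype=float)
    y = np.asarray(affinities, dtype=float)
    if X.ndim != 2 or len(X) != len(y):
        raise DimensionError("embeddings and affinities are misaligned")
    if len(y) < 10:
        raise InsufficientDataError(f"need >= 10 samples, got {len(y)}")
    templates = base_estimators or default_base_estimators(cfg)

    # out-of-fold base predictions for an honest meta-fit
    oof = np.zeros((len(y), len(templates)))
    kf = KFold(n_splits=min(_META_FOLDS, len(y)), shuffle=True,
               random_state=cfg.seed)
    for train_idx, test_idx in kf.split(X):
        for j, template in enumerate(templates):
            est = clone(template)
            est.fit(X[train_idx], y[train_idx])
            oof[test_idx, j] = est.predict(X[test_idx])
    meta = LinearRegression().fit(oof, y)

    fitted = tuple(clone(t).fit(X, y) for t in templates)
    return TrainedEnsemble(fitted, np.asarray(meta.coef_, dtype=float),
                           float(meta.intercept_), cfg)
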