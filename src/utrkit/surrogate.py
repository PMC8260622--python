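"""Surrogate regressors mapping sequence features to TE / mRNA level.

The learned function replaces the wet lab inside the genetic-algorithm loop:
it is trained on features of endogenous 5' UTRs against their measured
translation efficiency (or mRNA level) and then scores arbitrary candidate
sequences.  Evaluation follows 5-fold cross-validation with non-overlapping
test folds, reporting the Spearman correlation (average ranks for ties)
between predicted and actual values per fold; the final model is refit on
all data.

Targets are log-transformed (log2(y + 1e-3)) before regression by default,
since TE and RPKM are right-skewed, and predictions are transformed back.
Four model families are supported: a random forest (500 trees, the classic
default), an elastic-net linear model, a single regression tree, and an RBF
support-vector machine.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import spearmanr
from sklearn.base import BaseEstimator, RegressorMixin, clone
from sklearn.ensemble import RandomForestRegressor
from sklearn.linear_model import ElasticNetCV
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVR
from sklearn.tree import DecisionTreeRegressor

from .io import UtrkitError

MODEL_SPECS = ("random_forest", "linear_l1l2", "single_tree", "svm")
_LOG_OFFSET = 1e-3


def _base_estimator(model: str, n_estimators: int, random_state: int):
    if model == "random_forest":
        return RandomForestRegressor(
            n_estimators=n_estimators, random_state=random_state, n_jobs=1
        )
    if model == "linear_l1l2":
        return make_pipeline(
            StandardScaler(),
            ElasticNetCV(
                l1_ratio=[0.1, 0.5, 0.9],
                alphas=20,
                cv=3,
                random_state=random_state,
                max_iter=5000,
            ),
        )
    if model == "single_tree":
        return DecisionTreeRegressor(random_state=random_state)
    if model == "svm":
        return make_pipeline(StandardScaler(), SVR())
    raise UtrkitError(f"unknown model spec {model!r}; choose from {MODEL_SPECS}")


class SurrogateRegressor(RegressorMixin, BaseEstimator):
    """Cross-validated sequence-feature regressor with a frozen schema.

    Parameters
    ----------
    model : {"random_forest", "linear_l1l2", "single_tree", "svm"}
    target : {"TE", "mRNA"}
        Label only; recorded with the model.
    n_folds : int, default 5
    log_transform : bool, default True
        Regress on log2(y + 1e-3) and back-transform predictions.
    n_estimators : int, default 500
        Trees for the random forest.
    random_state : int, default 0
        Drives the fold shuffle and any stochastic base estimator.

    Fitted attributes
    -----------------
    cv_spearman_ : list of per-fold Spearman correlations
    cv_spearman_mean_ : their mean
    fold_assignment_ : int array, fold index of every training row
    schema_hash_ : hash of the feature schema the model accepts
    """

    def __init__(
        self,
        model: str = "random_forest",
        target: str = "TE",
        n_folds: int = 5,
        log_transform: bool = True,
        n_estimators: int = 500,
        random_state: int = 0,
    ):
        self.model = model
        self.target = target
        self.n_folds = n_folds
        self.log_transform = log_transform
        self.n_estimators = n_estimators
        self.random_state = random_state

    # -- helpers ----------------------------------------------------------
    def _fwd(self, y: np.ndarray) -> np.ndarray:
        if not self.log_transform:
            return y
        if (y < 0).any():
            raise UtrkitError("log_transform requires non-negative targets")
        return np.log2(y + _LOG_OFFSET)

    def _inv(self, y: np.ndarray) -> np.ndarray:
        if not self.log_transform:
            return y
        return np.maximum(np.exp2(y) - _LOG_OFFSET, 0.0)

    def _folds(self, n: int) -> np.ndarray:
        rng = np.random.default_rng(self.random_state)
        order = rng.permutation(n)
        assignment = np.empty(n, dtype=int)
        for fold, chunk in enumerate(np.array_split(order, self.n_folds)):
            assignment[chunk] = fold
        return assignment

    # -- estimator API ----------------------------------------------------
    def fit(self, X, y, feature_names: Sequence[str] | None = None,
            schema_hash: str | None = None, fold_assignment=None):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if X.ndim != 2 or len(X) != len(y):
            raise UtrkitError("X must be 2-D with one row per target value")
        if np.isnan(X).any() or np.isnan(y).any():
            raise UtrkitError("missing values are not allowed")
        if len(y) < 10 * self.n_folds:
            raise UtrkitError(
                f"need >= {10 * self.n_folds} rows for {self.n_folds}-fold CV,"
                f" got {len(y)}"
            )
        self.n_features_in_ = X.shape[1]
        self.feature_names_in_ = (
            np.asarray(feature_names, dtype=object)
            if feature_names is not None
            else None
        )
        self.schema_hash_ = schema_hash
        yt = self._fwd(y)
        if fold_assignment is not None:
            assignment = np.asarray(fold_assignment, dtype=int)
            if len(assignment) != len(y):
                raise UtrkitError("fold_assignment length mismatch")
        else:
            assignment = self._folds(len(y))
        self.fold_assignment_ = assignment
        self.cv_spearman_ = []
        for fold in range(self.n_folds):
            test = assignment == fold
            if test.sum() == 0:
                raise UtrkitError(f"fold {fold} is empty")
            est = _base_estimator(
                self.model, self.n_estimators, self.random_state
            )
            est.fit(X[~test], yt[~test])
            pred = est.predict(X[test])
            if np.ptp(pred) == 0 or np.ptp(yt[test]) == 0:
                rho = 0.0  # constant output carries no ranking information
            else:
                rho = spearmanr(pred, yt[test]).statistic
            self.cv_spearman_.append(float(rho))
        self.cv_spearman_mean_ = float(np.mean(self.cv_spearman_))
        self.estimator_ = _base_estimator(
            self.model, self.n_estimators, self.random_state
        )
        self.estimator_.fit(X, yt)
        return self

    def predict(self, X, schema_hash: str | None = None) -> np.ndarray:
        if not hasattr(self, "estimator_"):
            raise UtrkitError("SurrogateRegressor is not fitted")
        if (
            schema_hash is not None
            and self.schema_hash_ is not None
            and schema_hash != self.schema_hash_
        ):
            raise UtrkitError(
                f"feature schema mismatch: model={self.schema_hash_} "
                f"input={schema_hash}"
            )
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self.n_features_in_:
            raise UtrkitError(
                f"expected {self.n_features_in_} features, got {X.shape[1]}"
            )
        return self._inv(self.estimator_.predict(X))


def train_surrogate(
    X,
    y,
    target: str = "TE",
    model_spec: str = "random_forest",
    n_folds: int = 5,
    seed: int = 0,
    log_transform: bool = True,
    feature_names: Sequence[str] | None = None,
    schema_hash: str | None = None,
) -> SurrogateRegressor:
    """Fit one cross-validated surrogate model (thin wrapper)."""
    reg = SurrogateRegressor(
        model=model_spec,
        target=target,
        n_folds=n_folds,
        log_transform=log_transform,
        random_state=seed,
    )
    return reg.fit(X, y, feature_names=feature_names, schema_hash=schema_hash)


def compare_models(
    X,
    y,
    specs: Sequence[str] = MODEL_SPECS,
    n_folds: int = 5,
    seed: int = 0,
    log_transform: bool = True,
) -> pd.DataFrame:
    """Rank model families by mean CV Spearman under shared fold assignments."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    shared = SurrogateRegressor(n_folds=n_folds, random_state=seed)._folds(
        len(y)
    )
    rows = []
    for spec in specs:
        reg = SurrogateRegressor(
            model=spec,
            n_folds=n_folds,
            random_state=seed,
            log_transform=log_transform,
        )
        reg.fit(X, y, fold_assignment=shared)
        rows.append(
            {
                "model": spec,
                "cv_spearman_mean": reg.cv_spearman_mean_,
                "cv_spearman_folds": reg.cv_spearman_,
            }
        )
    out = pd.DataFrame(rows).sort_values(
        "cv_spearman_mean", ascending=False, kind="mergesort"
    )
    return out.reset_index(drop=True)


def predict_expression(
    model_te: SurrogateRegressor, model_rna: SurrogateRegressor, fv
) -> np.ndarray:
    """Predicted protein expression = predicted mRNA level x predicted TE."""
    if (
        model_te.schema_hash_ is not None
        and model_rna.schema_hash_ is not None
        and model_te.schema_hash_ != model_rna.schema_hash_
    ):
        raise UtrkitError("TE and mRNA models use different feature schemas")
    fv = np.atleast_2d(np.asarray(fv, dtype=float))
    return model_rna.predict(fv) * model_te.predict(fv)


def surrogate_fitness(
    featurizer, model_te: SurrogateRegressor,
    model_rna: SurrogateRegressor | None = None,
):
    """Build a sequence -> fitness callable for the genetic algorithm.

    With only a TE model, fitness is predicted TE; with both models, fitness
    is predicted protein expression (mRNA x TE).
    """
    def fitness(seq: str) -> float:
        fv = featurizer.transform([seq])
        if model_rna is None:
            return float(model_te.predict(fv)[0])
        return float(predict_expression(model_te, model_rna, fv)[0])

    return fitness
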