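"""Stomatal-conductance regression: SVR, random forest, k-nearest neighbours.

The sample is partitioned once into a modelling and a validation set at a
7:3 ratio (optionally stratified by irrigation treatment), models are fitted
on the modelling set, and both sets are scored with the coefficient of
determination R^2 = 1 - RSS/TSS and the root mean square error.

Hyperparameters follow the study design they emulate: SVR with an RBF
kernel, C = 1, gamma = 2; random forest with 50 trees; k-nearest neighbours
at its common defaults (5 neighbours, uniform weights, Euclidean metric) —
all overridable.  Features are min-max rescaled to [0, 1] on the modelling
set only before SVR and KNR (an RBF kernel with gamma = 2 needs features on
an O(1) or smaller scale, and z-scoring five features pushes typical squared
pairwise distances to ~10, collapsing the kernel); the forest sees raw
features.  SVR additionally sees a z-scored response, since its default
epsilon tube (0.1) dwarfs raw conductance values.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor
from sklearn.model_selection import KFold, train_test_split
from sklearn.neighbors import KNeighborsRegressor
from sklearn.preprocessing import MinMaxScaler
from sklearn.svm import SVR

from canopysc.features import TEXTURE_POOL, VI_POOL

#: screened predictor sets used by default for the three model inputs
FEATURE_SETS: dict[str, tuple[str, ...]] = {
    "vi": ("b808", "cvi", "ndgi", "ndre"),
    "texture": ("b808_var", "b808_con", "b808_sec", "b808_cor"),
    "combined": ("ndre", "rvi", "b808_var", "b808_sec", "b808_cor"),
}

MODEL_FAMILIES: tuple[str, ...] = ("svr", "rf", "knr")


@dataclass(frozen=True)
class SplitSpec:
    train_fraction: float = 0.7
    seed: int = 0
    stratify_by: str | None = None

    def __post_init__(self) -> None:
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must be in (0, 1)")


@dataclass(frozen=True)
class ModelSpec:
    family: str
    hyperparams: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.family not in MODEL_FAMILIES:
            raise ValueError(f"unknown family {self.family!r}; choose from {MODEL_FAMILIES}")

    def make_estimator(self, seed: int | None = None):
        hp = dict(self.hyperparams)
        if self.family == "svr":
            hp.setdefault("C", 1.0)
            hp.setdefault("kernel", "rbf")
            hp.setdefault("gamma", 2.0)
            return SVR(**hp)
        if self.family == "rf":
            hp.setdefault("n_estimators", 50)
            hp.setdefault("random_state", seed if seed is not None else 0)
            return RandomForestRegressor(**hp)
        hp.setdefault("n_neighbors", 5)
        hp.setdefault("weights", "uniform")
        hp.setdefault("p", 2)
        return KNeighborsRegressor(**hp)

    @property
    def standardize(self) -> bool:
        return self.family in ("svr", "knr")

    @property
    def standardize_y(self) -> bool:
        # the default epsilon-tube (0.1) dwarfs the conductance scale
        # (~0.015 mol m-2 s-1); SVR must see a unit-variance response
        return self.family == "svr"


@dataclass
class ModelReport:
    model: ModelSpec
    feature_set: str
    features: tuple[str, ...]
    train_r2: float
    train_rmse: float
    val_r2: float
    val_rmse: float
    train_pred: np.ndarray
    val_pred: np.ndarray
    train_y: np.ndarray
    val_y: np.ndarray
    #: mean residual (pred - measured) among the lowest-quartile measured
    #: values: positive means low conductance is over-predicted
    low_sc_bias: float = float("nan")

    def summary(self) -> dict[str, float | str]:
        return {
            "model": self.model.family,
            "feature_set": self.feature_set,
            "train_r2": self.train_r2,
            "train_rmse": self.train_rmse,
            "val_r2": self.val_r2,
            "val_rmse": self.val_rmse,
            "low_sc_bias": self.low_sc_bias,
        }


def split(
    table: pd.DataFrame, spec: SplitSpec
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Seeded 7:3 (by default) partition into modelling and validation sets."""
    if len(table) < 10:
        raise ValueError("need at least 10 samples to split")
    strat = table[spec.stratify_by] if spec.stratify_by else None
    train, val = train_test_split(
        table,
        train_size=spec.train_fraction,
        random_state=spec.seed,
        stratify=strat,
    )
    return train.reset_index(drop=True), val.reset_index(drop=True)


def r2_score(y: Sequence[float], yhat: Sequence[float]) -> float:
    """R^2 = 1 - sum (y - yhat)^2 / sum (y - ybar)^2; negative for fits
    worse than the mean predictor."""
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    if y.shape != yhat.shape:
        raise ValueError("length mismatch")
    if y.size < 2:
        raise ValueError("need at least 2 observations")
    tss = float(((y - y.mean()) ** 2).sum())
    if tss == 0:
        raise ValueError("constant y: R^2 undefined")
    rss = float(((y - yhat) ** 2).sum())
    return 1.0 - rss / tss


def rmse_score(y: Sequence[float], yhat: Sequence[float]) -> float:
    """Root mean square error sqrt(mean (y - yhat)^2)."""
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    if y.shape != yhat.shape:
        raise ValueError("length mismatch")
    if y.size < 1:
        raise ValueError("need at least 1 observation")
    return float(np.sqrt(((y - yhat) ** 2).mean()))


def fit_predict(
    train: pd.DataFrame,
    validation: pd.DataFrame,
    spec: ModelSpec,
    feature_set: str | Sequence[str] = "combined",
    response: str = "sc",
    seed: int = 0,
) -> ModelReport:
    """Fit one model family on one feature set and score both partitions."""
    if isinstance(feature_set, str):
        set_name = feature_set
        features = FEATURE_SETS[feature_set]
    else:
        set_name = "custom"
        features = tuple(feature_set)
    missing = [c for c in features if c not in train.columns]
    if missing:
        raise ValueError(f"features not in table: {missing}")
    Xtr = train[list(features)].to_numpy(dtype=float)
    Xva = validation[list(features)].to_numpy(dtype=float)
    ytr = train[response].to_numpy(dtype=float)
    yva = validation[response].to_numpy(dtype=float)
    if not (np.isfinite(Xtr).all() and np.isfinite(Xva).all()):
        raise ValueError("non-finite feature values")

    if spec.standardize:
        # min-max to [0,1], fitted on the modelling set only.  With an RBF
        # gamma of 2, unit-variance features put typical pairwise squared
        # distances near 2*d and the kernel collapses to the identity;
        # [0,1] features keep them ~d/6 and the kernel stays informative.
        scaler = MinMaxScaler().fit(Xtr)
        Xtr = scaler.transform(Xtr)
        Xva = scaler.transform(Xva)

    est = spec.make_estimator(seed=seed)
    if spec.standardize_y:
        y_mu, y_sd = ytr.mean(), ytr.std()
        if y_sd == 0:
            raise ValueError("constant response in the modelling set")
        est.fit(Xtr, (ytr - y_mu) / y_sd)
        pred_tr = est.predict(Xtr) * y_sd + y_mu
        pred_va = est.predict(Xva) * y_sd + y_mu
    else:
        est.fit(Xtr, ytr)
        pred_tr = est.predict(Xtr)
        pred_va = est.predict(Xva)

    low = yva <= np.quantile(yva, 0.25)
    low_bias = float((pred_va[low] - yva[low]).mean()) if low.any() else float("nan")

    return ModelReport(
        model=spec,
        feature_set=set_name,
        features=features,
        train_r2=r2_score(ytr, pred_tr),
        train_rmse=rmse_score(ytr, pred_tr),
        val_r2=r2_score(yva, pred_va),
        val_rmse=rmse_score(yva, pred_va),
        train_pred=pred_tr,
        val_pred=pred_va,
        train_y=ytr,
        val_y=yva,
        low_sc_bias=low_bias,
    )


def run_model_grid(
    table: pd.DataFrame,
    split_spec: SplitSpec | None = None,
    feature_sets: dict[str, Sequence[str]] | None = None,
    response: str = "sc",
) -> list[ModelReport]:
    """All three model families on all three feature sets: 9 reports."""
    split_spec = split_spec or SplitSpec()
    feature_sets = dict(feature_sets) if feature_sets else dict(FEATURE_SETS)
    train, val = split(table, split_spec)
    reports = []
    for set_name, features in feature_sets.items():
        for family in MODEL_FAMILIES:
            rep = fit_predict(
                train, val, ModelSpec(family), features,
                response=response, seed=split_spec.seed,
            )
            rep.feature_set = set_name
            reports.append(rep)
    return reports


def grid_summary(reports: Sequence[ModelReport]) -> pd.DataFrame:
    return pd.DataFrame([r.summary() for r in reports])


def kfold_scores(
    table: pd.DataFrame,
    spec: ModelSpec,
    feature_set: str | Sequence[str] = "combined",
    n_splits: int = 3,
    response: str = "sc",
    seed: int = 0,
) -> pd.DataFrame:
    """Optional k-fold utility: per-fold validation R^2 and RMSE."""
    kf = KFold(n_splits=n_splits, shuffle=True, random_state=seed)
    rows = []
    for fold, (tr, va) in enumerate(kf.split(table)):
        rep = fit_predict(
            table.iloc[tr], table.iloc[va], spec, feature_set,
            response=response, seed=seed,
        )
        rows.append({"fold": fold, "val_r2": rep.val_r2, "val_rmse": rep.val_rmse})
    return pd.DataFrame(rows)
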