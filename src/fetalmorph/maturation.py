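"""Fetal brain maturation index.

The 28 IDPs are standardised (zero mean, unit variance), confounds (sex,
study site, visible hemisphere) are removed by simultaneous linear
projection

    X_hat = X − V V⁺ X,

with V the demeaned confound encoding and V⁺ its Moore–Penrose
pseudo-inverse, and gestational age is regressed from the deconfounded
features with a random forest (100 trees, ceil(0.15 × n_features)
candidate features per split) under three-fold cross-validation split at
the subject level.  Standardisation and deconfounding parameters are
estimated on training folds only.  The per-scan brain-age delta is
predicted minus chronological age; reported metrics are out-of-fold MAE
(days), Pearson r and the intraclass correlation ICC(A,1) (two-way
absolute agreement, single measures).

For each confound V1 acting alone, the percentage variance explained of
feature j is

    %VE_j = 100 · (X1_j' X1_j) / (X_j' X_j),  X1 = V1 V1⁺ X,

and the unique variance explained beyond the remaining confounds Vn is

    %UVE_j = 100 · (X_j' X_j − Xn_j' Xn_j) / (X_j' X_j),  Xn = Vn Vn⁺ X.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestRegressor
from sklearn.inspection import permutation_importance
from sklearn.model_selection import GroupKFold

DEFAULT_CONFOUNDS = ("sex", "site", "hemisphere")


@dataclass
class ConfoundMatrix:
    """Demeaned numeric encoding of confound variables."""

    V: np.ndarray
    columns: list[str]
    means: np.ndarray  # column means before demeaning (training statistics)
    encoding: dict[str, list[str]] = field(default_factory=dict)

    def encode_new(self, meta: pd.DataFrame) -> np.ndarray:
        """Encode new rows with this matrix's levels and training means."""
        cols = []
        for name, levels in self.encoding.items():
            vals = meta[name].astype(str)
            if len(levels) == 2 and self.encoding_is_binary(name):
                cols.append((vals == levels[1]).to_numpy(dtype=np.float64))
            else:
                for lv in levels:
                    cols.append((vals == lv).to_numpy(dtype=np.float64))
        V = np.column_stack(cols) if cols else np.empty((len(meta), 0))
        return V - self.means

    def encoding_is_binary(self, name: str) -> bool:
        return sum(c.startswith(f"{name}=") for c in self.columns) == 1


def encode_confounds(
    meta: pd.DataFrame, confounds: tuple[str, ...] = DEFAULT_CONFOUNDS
) -> ConfoundMatrix:
    """Numerically encode and demean confounds.

    Binary confounds (sex, hemisphere) become a single indicator column;
    multi-level confounds (site) become one indicator per level — the
    resulting rank deficiency is absorbed by the pseudo-inverse.
    Single-level confounds are dropped with a warning.
    """
    cols: list[np.ndarray] = []
    names: list[str] = []
    encoding: dict[str, list[str]] = {}
    for name in confounds:
        levels = sorted(meta[name].astype(str).unique())
        if len(levels) < 2:
            warnings.warn(
                f"confound {name!r} has a single level and was dropped",
                stacklevel=2,
            )
            continue
        vals = meta[name].astype(str)
        if len(levels) == 2:
            cols.append((vals == levels[1]).to_numpy(dtype=np.float64))
            names.append(f"{name}={levels[1]}")
        else:
            for lv in levels:
                cols.append((vals == lv).to_numpy(dtype=np.float64))
                names.append(f"{name}={lv}")
        encoding[name] = levels
    V = np.column_stack(cols) if cols else np.empty((len(meta), 0))
    means = V.mean(axis=0) if V.size else np.zeros(V.shape[1])
    return ConfoundMatrix(V=V - means, columns=names, means=means, encoding=encoding)


@dataclass
class DeconfoundResult:
    X_hat: np.ndarray
    projection: np.ndarray  # V V⁺, reusable on aligned rows


def deconfound(X: np.ndarray, V: np.ndarray) -> DeconfoundResult:
    """Project out the confound subspace: X_hat = X − V V⁺ X."""
    X = np.asarray(X, dtype=np.float64)
    V = np.asarray(V, dtype=np.float64)
    if X.shape[0] != V.shape[0]:
        raise ValueError("X and V must have the same number of rows")
    if V.shape[1] == 0:
        return DeconfoundResult(X_hat=X.copy(), projection=np.zeros((0, 0)))
    P = V @ np.linalg.pinv(V)
    return DeconfoundResult(X_hat=X - P @ X, projection=P)


def variance_explained(
    X: np.ndarray, V: np.ndarray, which: slice | np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """%VE and %UVE per feature for the confound columns selected by *which*.

    Zero-variance features yield NaN.
    """
    X = np.asarray(X, dtype=np.float64)
    V = np.asarray(V, dtype=np.float64)
    col_idx = np.arange(V.shape[1])[which]
    rest_idx = np.setdiff1d(np.arange(V.shape[1]), col_idx)
    V1 = V[:, col_idx].reshape(len(V), -1)
    Vn = V[:, rest_idx].reshape(len(V), -1)

    denom = np.einsum("ij,ij->j", X, X)
    with np.errstate(invalid="ignore", divide="ignore"):
        X1 = V1 @ np.linalg.pinv(V1) @ X
        ve = 100.0 * np.einsum("ij,ij->j", X1, X1) / denom
        if Vn.shape[1]:
            Xn = Vn @ np.linalg.pinv(Vn) @ X
            explained_rest = np.einsum("ij,ij->j", Xn, Xn)
        else:
            explained_rest = np.zeros_like(denom)
        # unique contribution: total joint minus what the others explain
        Xall = V @ np.linalg.pinv(V) @ X
        explained_all = np.einsum("ij,ij->j", Xall, Xall)
        uve = 100.0 * (explained_all - explained_rest) / denom
    ve[denom == 0] = np.nan
    uve[denom == 0] = np.nan
    return ve, uve


@dataclass
class FoldState:
    forest: RandomForestRegressor
    feature_means: np.ndarray
    feature_stds: np.ndarray
    confounds: ConfoundMatrix | None
    V_train: np.ndarray
    train_idx: np.ndarray
    test_idx: np.ndarray


@dataclass
class MaturationModel:
    """Per-fold forests with subject-level cross-validation bookkeeping."""

    folds: list[FoldState]
    feature_names: list[str]
    n_estimators: int = 100
    max_feature_ratio: float = 0.15
    seed: int = 0

    def predictions(self, X_raw: np.ndarray, meta: pd.DataFrame) -> np.ndarray:
        """Out-of-fold predictions for every scan (training statistics only)."""
        pred = np.full(len(X_raw), np.nan)
        for fold in self.folds:
            Xt = (X_raw[fold.test_idx] - fold.feature_means) / fold.feature_stds
            if fold.confounds is not None and fold.V_train.shape[1]:
                Vt = fold.confounds.encode_new(meta.iloc[fold.test_idx])
                Xt = Xt - Vt @ np.linalg.pinv(fold.V_train) @ (
                    (X_raw[fold.train_idx] - fold.feature_means) / fold.feature_stds
                )
            pred[fold.test_idx] = fold.forest.predict(Xt)
        return pred


def _max_features(ratio: float, n_features: int) -> int:
    return max(1, math.ceil(ratio * n_features))


def fit_maturation_model(
    table: pd.DataFrame,
    feature_names: list[str],
    confounds: tuple[str, ...] = DEFAULT_CONFOUNDS,
    n_splits: int = 3,
    n_estimators: int = 100,
    max_feature_ratio: float = 0.15,
    seed: int = 0,
    ga_col: str = "ga_weeks",
    group_col: str = "fetus_id",
) -> MaturationModel:
    """Fit per-fold forests under subject-level grouped cross-validation.

    Standardisation and deconfounding are estimated on each training
    split and applied to its test split; no fetus contributes scans to
    both sides of any fold.
    """
    if len(table) < 50:
        raise ValueError("need at least 50 scans to fit the maturation model")
    groups = table[group_col].to_numpy()
    if len(np.unique(groups)) < n_splits:
        raise ValueError(f"need at least {n_splits} distinct fetuses")
    X_raw = table[feature_names].to_numpy(dtype=np.float64)
    y = table[ga_col].to_numpy(dtype=np.float64)

    folds: list[FoldState] = []
    splitter = GroupKFold(n_splits=n_splits)
    for k, (train_idx, test_idx) in enumerate(splitter.split(X_raw, y, groups)):
        if set(groups[train_idx]) & set(groups[test_idx]):
            raise RuntimeError("subject leakage across a CV fold")
        mu = X_raw[train_idx].mean(axis=0)
        sd = X_raw[train_idx].std(axis=0)
        sd[sd == 0] = 1.0
        Xtr = (X_raw[train_idx] - mu) / sd
        cm = None
        V_train = np.empty((len(train_idx), 0))
        if confounds:
            cm = encode_confounds(table.iloc[train_idx], confounds)
            V_train = cm.V
            Xtr = deconfound(Xtr, V_train).X_hat
        forest = RandomForestRegressor(
            n_estimators=n_estimators,
            max_features=_max_features(max_feature_ratio, len(feature_names)),
            random_state=seed + k,
            n_jobs=1,
        )
        forest.fit(Xtr, y[train_idx])
        folds.append(
            FoldState(
                forest=forest,
                feature_means=mu,
                feature_stds=sd,
                confounds=cm,
                V_train=V_train,
                train_idx=train_idx,
                test_idx=test_idx,
            )
        )
    return MaturationModel(
        folds=folds,
        feature_names=list(feature_names),
        n_estimators=n_estimators,
        max_feature_ratio=max_feature_ratio,
        seed=seed,
    )


def icc_absolute_agreement(x: np.ndarray, y: np.ndarray) -> float:
    """ICC(A,1): two-way absolute-agreement, single measures (McGraw–Wong).

    The two "raters" here are predicted and chronological age.
    """
    data = np.column_stack([x, y]).astype(np.float64)
    n, k = data.shape
    mean_rows = data.mean(axis=1)
    mean_cols = data.mean(axis=0)
    grand = data.mean()
    ms_rows = k * np.sum((mean_rows - grand) ** 2) / (n - 1)
    ms_cols = n * np.sum((mean_cols - grand) ** 2) / (k - 1)
    sse = np.sum((data - mean_rows[:, None] - mean_cols[None, :] + grand) ** 2)
    ms_err = sse / ((n - 1) * (k - 1))
    denom = ms_rows + (k - 1) * ms_err + k * (ms_cols - ms_err) / n
    if denom == 0:
        return 1.0
    return float((ms_rows - ms_err) / denom)


@dataclass
class MaturationReport:
    mae_days: float
    pearson_r: float
    icc: float
    brain_age_delta_days: np.ndarray
    predictions_weeks: np.ndarray


def evaluate_maturation(
    model: MaturationModel, table: pd.DataFrame, ga_col: str = "ga_weeks"
) -> MaturationReport:
    """Out-of-fold MAE (days), Pearson r, ICC(A,1) and per-scan brain-age delta."""
    X_raw = table[model.feature_names].to_numpy(dtype=np.float64)
    y = table[ga_col].to_numpy(dtype=np.float64)
    pred = model.predictions(X_raw, table)
    if np.any(np.isnan(pred)):
        raise RuntimeError("missing out-of-fold predictions")
    delta_days = (pred - y) * 7.0
    if np.std(pred) == 0 or np.std(y) == 0:
        r = 1.0 if np.allclose(pred, y) else 0.0
    else:
        r = float(stats.pearsonr(pred, y)[0])
    return MaturationReport(
        mae_days=float(np.mean(np.abs(delta_days))),
        pearson_r=r,
        icc=icc_absolute_agreement(pred, y),
        brain_age_delta_days=delta_days,
        predictions_weeks=pred,
    )


def feature_importance(
    model: MaturationModel,
    table: pd.DataFrame,
    ga_col: str = "ga_weeks",
    n_repeats: int = 5,
) -> pd.DataFrame:
    """Impurity and permutation importances, ranked.

    Impurity importances are averaged over folds (they sum to 1);
    permutation importances are computed on each fold's held-out scans
    and averaged.
    """
    X_raw = table[model.feature_names].to_numpy(dtype=np.float64)
    y = table[ga_col].to_numpy(dtype=np.float64)
    impurity = np.zeros(len(model.feature_names))
    permutation = np.zeros(len(model.feature_names))
    for k, fold in enumerate(model.folds):
        impurity += fold.forest.feature_importances_
        Xt = (X_raw[fold.test_idx] - fold.feature_means) / fold.feature_stds
        if fold.confounds is not None and fold.V_train.shape[1]:
            Vt = fold.confounds.encode_new(table.iloc[fold.test_idx])
            Xt = Xt - Vt @ np.linalg.pinv(fold.V_train) @ (
                (X_raw[fold.train_idx] - fold.feature_means) / fold.feature_stds
            )
        res = permutation_importance(
            fold.forest,
            Xt,
            y[fold.test_idx],
            n_repeats=n_repeats,
            random_state=model.seed + k,
            n_jobs=1,
        )
        permutation += res.importances_mean
    impurity /= len(model.folds)
    permutation /= len(model.folds)
    out = pd.DataFrame(
        {
            "feature": model.feature_names,
            "impurity_importance": impurity,
            "permutation_importance": permutation,
        }
    ).sort_values("permutation_importance", ascending=False, ignore_index=True)
    out["rank"] = np.arange(1, len(out) + 1)
    return out
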