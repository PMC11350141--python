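"""Random-forest MCI classification with LOOCV-driven feature selection.

The protocol: assemble one row per subject (task-averaged LDLPFC NVC
beta, CEEV ratio, the four task-averaged connectivity metrics, and
demographic/comorbidity covariates); run leave-one-out cross-validation,
refitting standardization and one-hot encoding inside each training fold
(no leakage), and average the Gini importances over folds; keep the top
k = 3 features; evaluate the final forest (500 trees) on a stratified
single split and over 100 repeated 80/20 train/test splits.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from sklearn.compose import ColumnTransformer
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import accuracy_score, precision_score, recall_score
from sklearn.model_selection import LeaveOneOut, train_test_split
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import OneHotEncoder, StandardScaler

__all__ = [
    "NUMERIC_FEATURES",
    "CATEGORICAL_FEATURES",
    "assemble_features",
    "loocv_importance",
    "select_top_k",
    "evaluate_split",
    "repeated_splits",
]

NUMERIC_FEATURES = (
    "ldlpfc_beta", "ceev_ratio_pct", "wd_ldp", "d_ldp", "d_bar", "wd_bar",
    "age", "hypertension", "depression_prior",
)
CATEGORICAL_FEATURES = ("sex",)
LABEL = "group"


def assemble_features(
    nvc: pd.Series,
    fc_metrics: pd.DataFrame,
    ev_summaries: pd.DataFrame,
    cohort: pd.DataFrame,
) -> pd.DataFrame:
    """Join per-subject pipeline outputs into the classification matrix.

    ``nvc``: subject-indexed LDLPFC beta.  ``fc_metrics``: subject-indexed
    columns wd_ldp, d_ldp, d_bar, wd_bar.  ``ev_summaries``:
    subject-indexed ceev_ratio_pct.  Subjects missing any block are
    dropped and named in a warning.
    """
    df = cohort.set_index("subject_id")[
        ["group", "age", "sex", "hypertension", "depression_prior"]
    ].copy()
    df["ldlpfc_beta"] = nvc
    for col in ("wd_ldp", "d_ldp", "d_bar", "wd_bar"):
        df[col] = fc_metrics[col]
    df["ceev_ratio_pct"] = ev_summaries["ceev_ratio_pct"]
    incomplete = df.index[df.isna().any(axis=1)].tolist()
    if incomplete:
        warnings.warn(f"dropping incomplete subjects: {incomplete}")
        df = df.dropna()
    if df.empty:
        raise ValueError("no subject has complete features")
    return df.reset_index()


def _make_pipeline(features: list[str], n_trees: int, seed: int) -> Pipeline:
    numeric = [f for f in features if f not in CATEGORICAL_FEATURES]
    categorical = [f for f in features if f in CATEGORICAL_FEATURES]
    pre = ColumnTransformer(
        [
            ("num", StandardScaler(), numeric),
            ("cat", OneHotEncoder(handle_unknown="ignore"), categorical),
        ]
    )
    forest = RandomForestClassifier(n_estimators=n_trees, random_state=seed)
    return Pipeline([("pre", pre), ("forest", forest)])


def _fold_importances(pipe: Pipeline, features: list[str]) -> pd.Series:
    """Gini importances mapped back to input features (one-hot columns
    summed into their parent)."""
    names = pipe.named_steps["pre"].get_feature_names_out()
    imp = pipe.named_steps["forest"].feature_importances_
    out = dict.fromkeys(features, 0.0)
    for name, v in zip(names, imp):
        base = name.split("__", 1)[1]
        for f in features:
            if base == f or base.startswith(f + "_"):
                out[f] += float(v)
                break
    return pd.Series(out)


def loocv_importance(
    features: pd.DataFrame,
    feature_cols: list[str] | None = None,
    n_trees: int = 100,
    seed: int = 0,
) -> pd.Series:
    """Mean Gini importance per feature across leave-one-out folds.

    Standardization and encoding are fit within each training fold.
    Single-class training folds are skipped with a warning.
    """
    cols = list(feature_cols or NUMERIC_FEATURES + CATEGORICAL_FEATURES)
    X = features[cols]
    y = features[LABEL].to_numpy()
    if len(features) < 3:
        raise ValueError("need at least 3 subjects for LOOCV")
    per_fold = []
    for k, (train, _test) in enumerate(LeaveOneOut().split(X)):
        if len(np.unique(y[train])) < 2:
            warnings.warn(f"fold {k}: single-class training set; skipped")
            continue
        pipe = _make_pipeline(cols, n_trees, seed)
        pipe.fit(X.iloc[train], y[train])
        per_fold.append(_fold_importances(pipe, cols))
    return pd.concat(per_fold, axis=1).mean(axis=1)


def select_top_k(importances: pd.Series, k: int = 3) -> list[str]:
    """The k features with highest mean importance; ties broken by the
    fixed feature order (position in the index)."""
    if k > len(importances):
        raise ValueError(f"k={k} exceeds {len(importances)} scored features")
    order = sorted(
        range(len(importances)),
        key=lambda i: (-importances.iloc[i], i),
    )
    return [importances.index[i] for i in order[:k]]


def evaluate_split(
    features: pd.DataFrame,
    selected: list[str],
    train_frac: float = 0.8,
    n_trees: int = 500,
    seed: int = 0,
) -> dict[str, float]:
    """Stratified single-split evaluation of the final forest.

    Precision and recall are support-weighted across classes; F1 is the
    harmonic mean of the reported precision and recall.
    """
    X = features[selected]
    y = features[LABEL].to_numpy()
    X_tr, X_te, y_tr, y_te = train_test_split(
        X, y, train_size=train_frac, stratify=y, random_state=seed
    )
    if len(np.unique(y_te)) < 2 or len(np.unique(y_tr)) < 2:
        raise ValueError("train and test sets must both contain both classes")
    pipe = _make_pipeline(selected, n_trees, seed)
    pipe.fit(X_tr, y_tr)
    pred = pipe.predict(X_te)
    acc = accuracy_score(y_te, pred)
    prec = precision_score(y_te, pred, average="weighted", zero_division=0)
    rec = recall_score(y_te, pred, average="weighted", zero_division=0)
    f1 = 2 * prec * rec / (prec + rec) if (prec + rec) > 0 else 0.0
    return {
        "accuracy": float(acc), "precision": float(prec),
        "recall": float(rec), "f1": float(f1),
    }


def repeated_splits(
    features: pd.DataFrame,
    selected: list[str],
    n_runs: int = 100,
    train_frac: float = 0.8,
    n_trees: int = 500,
    seed: int = 0,
) -> dict[str, float]:
    """Mean and SD of test accuracy over ``n_runs`` stratified splits with
    distinct seeds derived from ``seed``."""
    from .simulate import subseed

    accs = []
    failed = 0
    for i in range(n_runs):
        try:
            m = evaluate_split(
                features, selected, train_frac=train_frac, n_trees=n_trees,
                seed=subseed(seed, "split", i),
            )
            accs.append(m["accuracy"])
        except ValueError:
            failed += 1
    if not accs:
        raise ValueError("every split failed")
    return {
        "mean_accuracy": float(np.mean(accs)),
        "sd_accuracy": float(np.std(accs, ddof=1)) if len(accs) > 1 else 0.0,
        "n_runs": len(accs),
        "n_failed": failed,
    }
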