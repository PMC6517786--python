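"""Combine crowd ratings into amplified labels.

Two aggregators are provided. The equal-weight baseline averages, per
slice, each rater's mean rating of that slice (one vote per rater per
slice). The weighted aggregator treats raters as features: the design
matrix has one row per slice and one column per rater, the entry being
that rater's mean rating of that slice, with genuinely missing entries
(rater never saw the slice) kept missing — never imputed as 0. A
gradient-boosted tree ensemble with native missing-value routing is fit
against expert gold-standard labels, hyperparameters chosen by
stratified cross-validated grid search; its probability output on every
slice is the amplified label in [0, 1]. The per-rater importance F —
the number of tree splits on that rater's column summed over the
ensemble — measures how much the model trusts each rater.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import GridSearchCV, StratifiedKFold, train_test_split
from xgboost import XGBClassifier

from .metrics import auc_mann_whitney

__all__ = [
    "build_design_matrix",
    "equal_weight_scores",
    "RaterWeightModel",
    "RaterWeightResults",
    "fit_weighted_aggregator",
    "amplify_labels",
    "training_size_sweep",
]


def build_design_matrix(events: pd.DataFrame, raters=None) -> pd.DataFrame:
    """Slices x raters matrix of per-pair mean ratings (NaN = never rated).

    Repeat ratings of the same slice by one rater average to a value in
    [0, 1]; a missing entry means the rater never saw that slice and is
    semantically distinct from 0 (= always failed).
    """
    if len(events) == 0:
        raise ValueError("events table is empty")
    df = events if raters is None else events[events["rater_id"].isin(set(raters))]
    design = df.pivot_table(
        index="slice_id", columns="rater_id", values="rating", aggfunc="mean"
    )
    if raters is not None:
        design = design.reindex(columns=sorted(set(raters)))
    design.index.name = "slice_id"
    return design


def equal_weight_scores(
    events: pd.DataFrame, raters=None, rater_first: bool = True
) -> pd.Series:
    """Equal-weight amplified labels.

    With ``rater_first`` (default) each rater contributes one vote per
    slice — the mean over raters of per-rater mean ratings, i.e. the
    row-mean of the design matrix. With ``rater_first=False`` the plain
    mean over rating events is used instead. Slices with no ratings from
    the retained raters simply do not appear.
    """
    if len(events) == 0:
        raise ValueError("events table is empty")
    if rater_first:
        design = build_design_matrix(events, raters=raters)
        scores = design.mean(axis=1, skipna=True).dropna()
    else:
        df = events if raters is None else events[events["rater_id"].isin(set(raters))]
        scores = df.groupby("slice_id")["rating"].mean()
    scores.name = "score"
    return scores


@dataclass
class RaterWeightResults:
    """Fitted weighted aggregator.

    Carries the chosen hyperparameters, per-rater split-count importance
    F, the cross-validated AUC of the selected configuration, and the
    training column order needed to score new design matrices.
    """

    model: XGBClassifier
    columns: list[str]
    best_params: dict
    cv_auc: float
    importance_f: pd.Series
    n_estimators: int
    seed: int

    def predict_scores(self, design: pd.DataFrame) -> pd.Series:
        """Amplified label in [0, 1] per slice; columns are aligned to
        the training raters (unseen raters dropped with a warning,
        absent training raters treated as missing)."""
        extra = [c for c in design.columns if c not in self.columns]
        if extra:
            warnings.warn(f"dropping {len(extra)} rater column(s) unseen at fit time")
        x = design.reindex(columns=self.columns)
        proba = self.model.predict_proba(x.to_numpy(dtype=float))[:, 1]
        return pd.Series(proba, index=design.index, name="score")

    def summary(self) -> str:
        top = self.importance_f.sort_values(ascending=False).head(10)
        lines = [
            "Weighted rater aggregation (gradient-boosted trees)",
            f"  raters (features): {len(self.columns)}",
            f"  n_estimators:      {self.n_estimators}",
            f"  best max_depth:    {self.best_params['max_depth']}",
            f"  best learning_rate:{self.best_params['learning_rate']}",
            f"  CV AUC:            {self.cv_auc:.4f}",
            f"  total splits (sum F): {int(self.importance_f.sum())}",
            "  top raters by importance F:",
        ]
        lines += [f"    {r:<12} F={int(v)}" for r, v in top.items()]
        return "\n".join(lines)


class RaterWeightModel:
    """Gold-supervised rater weighting model.

    Parameters
    ----------
    design
        Design matrix restricted to gold-standard slices (rows) with
        rater columns; NaN marks unrated pairs.
    labels
        Binary gold labels aligned with ``design`` rows (1 = pass).
    """

    def __init__(self, design: pd.DataFrame, labels) -> None:
        labels = pd.Series(np.asarray(labels).astype(int), index=design.index)
        if not np.isin(labels.unique(), (0, 1)).all():
            raise ValueError("gold labels must be binary 0/1")
        if labels.nunique() < 2:
            raise ValueError("gold labels must contain both classes")
        self.design = design
        self.labels = labels

    def fit(
        self,
        n_estimators: int = 600,
        depth_grid: tuple[int, ...] = (2, 6),
        lr_grid: tuple[float, ...] = (0.01, 0.1),
        cv_folds: int = 10,
        seed: int = 0,
    ) -> RaterWeightResults:
        """Grid-search depth and learning rate by stratified CV AUC."""
        y = self.labels.to_numpy()
        x = self.design.to_numpy(dtype=float)
        min_class = int(np.bincount(y).min())
        folds = min(cv_folds, min_class)
        if folds < cv_folds:
            warnings.warn(
                f"reducing CV folds from {cv_folds} to {folds} (minority class size)"
            )
        if folds < 2:
            raise ValueError("need at least 2 examples of each class for CV")

        base = XGBClassifier(
            n_estimators=n_estimators,
            tree_method="hist",
            eval_metric="logloss",
            random_state=seed,
            n_jobs=1,
        )
        cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
        search = GridSearchCV(
            base,
            param_grid={"max_depth": list(depth_grid), "learning_rate": list(lr_grid)},
            scoring="roc_auc",
            cv=cv,
            refit=True,
        )
        search.fit(x, y)
        model: XGBClassifier = search.best_estimator_

        booster = model.get_booster()
        booster.feature_names = [str(c) for c in self.design.columns]
        raw_f = booster.get_score(importance_type="weight")
        importance = pd.Series(
            {c: float(raw_f.get(str(c), 0.0)) for c in self.design.columns},
            name="F",
        )
        return RaterWeightResults(
            model=model,
            columns=list(self.design.columns),
            best_params=search.best_params_,
            cv_auc=float(search.best_score_),
            importance_f=importance,
            n_estimators=n_estimators,
            seed=seed,
        )


def fit_weighted_aggregator(
    design: pd.DataFrame,
    gold,
    n_estimators: int = 600,
    depth_grid: tuple[int, ...] = (2, 6),
    lr_grid: tuple[float, ...] = (0.01, 0.1),
    cv_folds: int = 10,
    seed: int = 0,
) -> RaterWeightResults:
    """Functional wrapper around :class:`RaterWeightModel`."""
    return RaterWeightModel(design, gold).fit(
        n_estimators=n_estimators,
        depth_grid=depth_grid,
        lr_grid=lr_grid,
        cv_folds=cv_folds,
        seed=seed,
    )


def amplify_labels(results: RaterWeightResults, design: pd.DataFrame) -> pd.DataFrame:
    """Score every slice in ``design`` with the fitted aggregator."""
    scores = results.predict_scores(design)
    return pd.DataFrame({"slice_id": scores.index, "score": scores.to_numpy()})


def split_gold(
    design: pd.DataFrame, gold, test_fraction: float = 1 / 3, seed: int = 0
):
    """Stratified train/test split of the gold slices (default 2/3 : 1/3)."""
    gold = pd.Series(np.asarray(gold).astype(int), index=design.index)
    idx_train, idx_test = train_test_split(
        design.index,
        test_size=test_fraction,
        stratify=gold,
        random_state=seed,
    )
    return (
        design.loc[idx_train],
        gold.loc[idx_train],
        design.loc[idx_test],
        gold.loc[idx_test],
    )


def training_size_sweep(
    design: pd.DataFrame,
    gold,
    sizes,
    seed: int = 0,
    test_fraction: float = 1 / 3,
    **fit_kwargs,
) -> pd.DataFrame:
    """Test-set AUC as a function of training-set size.

    A fixed stratified held-out split is made once; for each requested
    size a stratified random subset of the training rows is used to fit
    the aggregator and the AUC on the fixed test split is recorded.
    Sizes too small to contain both classes are skipped and flagged.
    """
    x_train, y_train, x_test, y_test = split_gold(
        design, gold, test_fraction=test_fraction, seed=seed
    )
    rows = []
    for size in sizes:
        if size > len(x_train):
            raise ValueError(f"size {size} exceeds the training pool ({len(x_train)})")
        if size == len(x_train):
            sub = x_train.index
        else:
            sub, _ = train_test_split(
                x_train.index,
                train_size=size,
                stratify=y_train,
                random_state=seed + size,
            )
        y_sub = y_train.loc[sub]
        if y_sub.nunique() < 2:
            rows.append({"size": size, "auc": np.nan, "skipped": True})
            continue
        res = fit_weighted_aggregator(
            x_train.loc[sub], y_sub, seed=seed, **fit_kwargs
        )
        auc = auc_mann_whitney(res.predict_scores(x_test), y_test)
        rows.append({"size": size, "auc": auc, "skipped": False})
    return pd.DataFrame(rows)
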