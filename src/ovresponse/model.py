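"""Gradient-boosted prediction of the MII oocyte count with explanation.

The learner is LightGBM's gradient-boosted decision trees with the
study's settings (100 trees, five leaves, maximum depth 16, l2 loss),
validated by five-fold cross-validation grouped by patient so that no
patient's stimulations straddle a fold boundary.  Error metrics (RMSE,
MAE, MAPE) come from the pooled out-of-fold predictions; explanations are
exact TreeSHAP contributions, which are additive: base value plus the
per-feature contributions reconstruct the prediction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

__all__ = [
    "ModelConfig",
    "CVMetrics",
    "CVResult",
    "SelectionTrace",
    "ShapExplanation",
    "error_metrics",
    "trivial_baseline",
    "assign_grouped_folds",
    "train_gbm_cv",
    "forward_select",
    "genetic_combination_search",
    "shap_values",
    "shap_importance",
    "explain_patient",
]


@dataclass
class ModelConfig:
    """Boosting and cross-validation settings (study defaults)."""

    n_trees: int = 100
    num_leaves: int = 5
    max_depth: int = 16
    learning_rate: float = 0.1
    n_folds: int = 5
    min_child_samples: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trees < 1 or self.n_folds < 2:
            raise ValueError("need n_trees >= 1 and n_folds >= 2")


@dataclass
class CVMetrics:
    """RMSE/MAE in oocytes, MAPE as a fraction; pooled out-of-fold."""

    rmse: float
    mae: float
    mape: float
    n: int
    n_mape_excluded: int = 0  # zero-outcome rows excluded from MAPE only
    per_fold: pd.DataFrame | None = None


def error_metrics(predictions, actuals) -> CVMetrics:
    """RMSE, MAE and MAPE of a prediction vector.

    MAPE averages |error| / actual over observations with a positive
    actual count; rows with zero actual MII are excluded from MAPE only
    (their count is reported), since a relative error is undefined there.
    """
    pred = np.asarray(predictions, dtype=float)
    act = np.asarray(actuals, dtype=float)
    if pred.shape != act.shape or pred.size == 0:
        raise ValueError("predictions and actuals must be equal-length, non-empty")
    if (act < 0).any():
        raise ValueError("actual MII counts must be nonnegative")
    err = pred - act
    rmse = float(np.sqrt(np.mean(err**2)))
    mae = float(np.mean(np.abs(err)))
    nz = act > 0
    mape = float(np.mean(np.abs(err[nz]) / act[nz])) if nz.any() else np.nan
    return CVMetrics(rmse, mae, mape, len(act), int((~nz).sum()))


def trivial_baseline(outcomes) -> CVMetrics:
    """Constant mean predictor; its RMSE is the outcome's population SD."""
    y = np.asarray(outcomes, dtype=float)
    if len(y) < 2:
        raise ValueError("need at least two processes")
    return error_metrics(np.full_like(y, y.mean()), y)


def assign_grouped_folds(patient_ids, n_folds: int, seed: int) -> np.ndarray:
    """Fold index per process, grouped so no patient spans folds.

    Patients are shuffled with the seed and dealt round-robin, which also
    balances fold sizes when patients contribute unequal process counts.
    """
    patient_ids = pd.Series(patient_ids).reset_index(drop=True)
    patients = patient_ids.unique()
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(patients))
    fold_of_patient = {patients[j]: i % n_folds for i, j in enumerate(order)}
    return patient_ids.map(fold_of_patient).to_numpy()


def _make_model(config: ModelConfig, seed_offset: int = 0):
    import lightgbm as lgb

    return lgb.LGBMRegressor(
        boosting_type="gbdt",
        objective="regression",  # l2 loss
        n_estimators=config.n_trees,
        num_leaves=config.num_leaves,
        max_depth=config.max_depth,
        learning_rate=config.learning_rate,
        min_child_samples=config.min_child_samples,
        random_state=config.seed + seed_offset,
        deterministic=True,
        force_row_wise=True,
        verbose=-1,
        n_jobs=1,
    )


@dataclass
class CVResult:
    metrics: CVMetrics
    oof_predictions: pd.Series
    folds: np.ndarray
    model: object  # final model refit on all data (for explanation)
    feature_names: list[str]


def train_gbm_cv(
    feature_table: pd.DataFrame,
    outcomes,
    patient_ids,
    config: ModelConfig | None = None,
    folds: np.ndarray | None = None,
) -> CVResult:
    """Grouped k-fold CV of the boosted model + a final full-data refit.

    Missing feature values are passed through to LightGBM, which routes
    them natively at each split.  ``folds`` may be supplied to reuse one
    fixed assignment across model variants (required whenever RMSEs are
    compared); otherwise it derives deterministically from the seed.
    """
    if config is None:
        config = ModelConfig()
    X = feature_table.astype(float)
    y = np.asarray(outcomes, dtype=float)
    if folds is None:
        folds = assign_grouped_folds(patient_ids, config.n_folds, config.seed)
    pid = pd.Series(patient_ids).reset_index(drop=True)
    for f in range(config.n_folds):
        if (folds == f).sum() < 5:
            raise ValueError(f"fold {f} has fewer than 5 observations")
        overlap = set(pid[folds == f]) & set(pid[folds != f])
        if overlap:
            raise AssertionError(f"patient(s) {sorted(overlap)[:3]} span folds")

    oof = np.full(len(y), np.nan)
    rows = []
    for f in range(config.n_folds):
        test = folds == f
        model = _make_model(config, seed_offset=f)
        model.fit(X[~test], y[~test])
        oof[test] = model.predict(X[test])
        m = error_metrics(oof[test], y[test])
        rows.append({"fold": f, "rmse": m.rmse, "mae": m.mae, "mape": m.mape,
                     "n": int(test.sum())})
    metrics = error_metrics(oof, y)
    metrics.per_fold = pd.DataFrame(rows)
    final = _make_model(config).fit(X, y)
    return CVResult(
        metrics=metrics,
        oof_predictions=pd.Series(oof, index=feature_table.index, name="oof_pred"),
        folds=folds,
        model=final,
        feature_names=list(feature_table.columns),
    )


# ---------------------------------------------------------------------------
# feature selection


@dataclass
class SelectionTrace:
    iterations: pd.DataFrame  # candidate, pearson_r, rmse_without, rmse_with, accepted
    selected: list[str]
    baseline_rmse: float


def forward_select(
    candidate_features: pd.DataFrame,
    outcomes,
    patient_ids,
    config: ModelConfig | None = None,
) -> SelectionTrace:
    """Greedy forward selection of features by cross-validated RMSE.

    Candidates are visited in descending |Pearson r| with the outcome
    (pairwise-complete), starting from the trivial mean benchmark; a
    candidate is kept iff retraining with it strictly lowers the CV RMSE
    on the same fold assignment.  An empty selection (nothing helps) is a
    valid outcome.
    """
    if config is None:
        config = ModelConfig()
    y = np.asarray(outcomes, dtype=float)
    folds = assign_grouped_folds(patient_ids, config.n_folds, config.seed)
    corr = {}
    for c in candidate_features.columns:
        x = candidate_features[c].astype(float)
        ok = x.notna()
        corr[c] = (
            abs(np.corrcoef(x[ok], y[ok.to_numpy()])[0, 1])
            if ok.sum() >= 3 and x[ok].std() > 0
            else 0.0
        )
    order = sorted(corr, key=lambda c: (-corr[c], c))

    current: list[str] = []
    best_rmse = trivial_baseline(y).rmse
    baseline = best_rmse
    rows = []
    for cand in order:
        trial = current + [cand]
        res = train_gbm_cv(candidate_features[trial], y, patient_ids, config, folds)
        accepted = res.metrics.rmse < best_rmse
        rows.append(
            {
                "candidate": cand,
                "pearson_r": corr[cand],
                "rmse_without": best_rmse,
                "rmse_with": res.metrics.rmse,
                "accepted": accepted,
            }
        )
        if accepted:
            current = trial
            best_rmse = res.metrics.rmse
    return SelectionTrace(pd.DataFrame(rows), current, baseline)


def genetic_combination_search(
    genetic_features: pd.DataFrame,
    clinical_features: pd.DataFrame,
    outcomes,
    patient_ids,
    config: ModelConfig | None = None,
) -> tuple[tuple[str, ...], pd.DataFrame]:
    """Exhaustive search over genetic-feature subsets added to the
    clinical model (2^n - 1 combinations, identical folds throughout).

    Returns the subset minimizing CV RMSE (ties toward the smaller, then
    lexicographically earlier subset) and the full score table.
    """
    if config is None:
        config = ModelConfig()
    names = sorted(genetic_features.columns)
    if not 1 <= len(names) <= 7:
        raise ValueError("combination search supports 1-7 genetic features")
    y = np.asarray(outcomes, dtype=float)
    folds = assign_grouped_folds(patient_ids, config.n_folds, config.seed)
    records = []
    for size in range(1, len(names) + 1):
        for subset in combinations(names, size):
            table = pd.concat(
                [clinical_features, genetic_features[list(subset)]], axis=1
            )
            res = train_gbm_cv(table, y, patient_ids, config, folds)
            records.append(
                {"subset": subset, "size": size, "rmse": res.metrics.rmse,
                 "mae": res.metrics.mae, "mape": res.metrics.mape}
            )
    table = pd.DataFrame(records)
    best = table.sort_values(["rmse", "size", "subset"], kind="mergesort").iloc[0]
    return tuple(best["subset"]), table


# ---------------------------------------------------------------------------
# SHAP explanation


def shap_values(model, feature_table: pd.DataFrame):
    """Exact TreeSHAP contributions: (per-feature matrix, base values)."""
    booster = getattr(model, "booster_", model)
    contrib = booster.predict(
        feature_table.astype(float).to_numpy(), pred_contrib=True
    )
    return contrib[:, :-1], contrib[:, -1]


def shap_importance(model, feature_table: pd.DataFrame) -> pd.Series:
    """Global importance: mean |SHAP value| per feature, descending."""
    names = list(feature_table.columns)
    model_names = list(getattr(model, "feature_name_", names))
    if names != model_names:
        raise ValueError(
            f"feature table columns {names} do not match model schema {model_names}"
        )
    contrib, _ = shap_values(model, feature_table)
    return (
        pd.Series(np.abs(contrib).mean(axis=0), index=names, name="mean_abs_shap")
        .sort_values(ascending=False)
    )


@dataclass
class ShapExplanation:
    """Additive decomposition of one prediction."""

    process_id: str
    base_value: float
    contributions: pd.Series  # per feature, oocytes
    prediction: float

    def __post_init__(self) -> None:
        total = self.base_value + self.contributions.sum()
        if abs(total - self.prediction) > 1e-6:
            raise AssertionError(
                f"SHAP additivity violated: {total} != {self.prediction}"
            )

    def cumulative_genetic_impact(self, genetic_names) -> float:
        """Sum of the genetic features' contributions (oocytes)."""
        present = [n for n in genetic_names if n in self.contributions.index]
        return float(self.contributions[present].sum())


def explain_patient(model, feature_row: pd.Series) -> ShapExplanation:
    """Per-feature additive explanation of a single process's prediction."""
    names = list(getattr(model, "feature_name_", feature_row.index))
    missing = [n for n in names if n not in feature_row.index]
    if missing:
        raise ValueError(f"feature row lacks model feature(s): {missing}")
    table = feature_row[names].to_frame().T.astype(float)
    contrib, base = shap_values(model, table)
    pred = float(model.predict(table)[0])
    return ShapExplanation(
        process_id=str(feature_row.name),
        base_value=float(base[0]),
        contributions=pd.Series(contrib[0], index=names),
        prediction=pred,
    )
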