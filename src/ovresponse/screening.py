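"""Per-variant statistical screening and shadow-feature (Boruta) ranking.

Stage one of the feature-discovery funnel: every panel variant is tested
for a shift in the MII-count distribution between reference and
alternative-allele carriers (Kolmogorov-Smirnov + Mann-Whitney U, alpha
0.05, no multiplicity correction by default), then variants are ranked by
importance against permuted "shadow" copies of themselves, and the
rankings are combined by mean rank to pre-select the top candidates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import Cohort

__all__ = [
    "VariantTestResult",
    "VariantRanking",
    "variant_distribution_tests",
    "screen_all_variants",
    "boruta_rank",
    "combine_rankings",
]


@dataclass
class VariantTestResult:
    variant_id: str
    n_ref_carriers: int
    n_alt_carriers: int
    ks_statistic: float
    ks_p: float
    mwu_statistic: float
    mwu_p: float
    direction: str  # 'higher' | 'lower' | 'none'
    alpha: float = 0.05
    testable: bool = True


def variant_distribution_tests(
    cohort: Cohort,
    variant_id: str,
    alpha: float = 0.05,
    alternative: str = "two-sided",
) -> VariantTestResult:
    """KS and Mann-Whitney U tests of MII counts, split by alt-presence.

    Carriers of at least one alternative allele form one group, homozygous
    reference the other; processes with a missing genotype at the variant
    are excluded.  The Mann-Whitney null is exact when both groups have
    <= 8 observations and the data are tie-free, otherwise the normal
    approximation with tie correction is used.  ``direction`` is 'higher'
    ('lower') when both tests reject at ``alpha`` and the carriers' median
    MII count is above (below) the non-carriers'; monomorphic or
    undersized splits come back flagged untestable.
    """
    j = cohort.genotypes.index_of(variant_id)
    presence = cohort.genotypes.alt_presence()[:, j]
    mii = cohort.mii_counts.to_numpy(dtype=float)
    ok = ~np.isnan(presence)
    ref = mii[ok & (presence == 0)]
    alt = mii[ok & (presence == 1)]
    if len(ref) < 2 or len(alt) < 2:
        return VariantTestResult(
            variant_id, len(ref), len(alt), np.nan, np.nan, np.nan, np.nan,
            "none", alpha, testable=False,
        )
    ks = stats.ks_2samp(alt, ref)
    pooled = np.concatenate([ref, alt])
    method = (
        "exact"
        if len(ref) <= 8 and len(alt) <= 8 and len(np.unique(pooled)) == len(pooled)
        else "asymptotic"
    )
    mwu = stats.mannwhitneyu(alt, ref, alternative=alternative, method=method)
    direction = "none"
    if ks.pvalue < alpha and mwu.pvalue < alpha:
        direction = "higher" if np.median(alt) > np.median(ref) else "lower"
    return VariantTestResult(
        variant_id, len(ref), len(alt),
        float(ks.statistic), float(ks.pvalue),
        float(mwu.statistic), float(mwu.pvalue),
        direction, alpha,
    )


def screen_all_variants(cohort: Cohort, alpha: float = 0.05) -> pd.DataFrame:
    """Run :func:`variant_distribution_tests` over the whole panel."""
    rows = [
        variant_distribution_tests(cohort, vid, alpha)
        for vid in cohort.genotypes.variant_ids
    ]
    return pd.DataFrame([r.__dict__ for r in rows]).set_index("variant_id")


# ---------------------------------------------------------------------------
# shadow-feature ranking


@dataclass
class VariantRanking:
    """Importance ranking of variants produced by one shadow-feature run
    (or by combining several runs)."""

    method: str
    table: pd.DataFrame  # index variant_id; columns: score, rank, decision
    stable: bool = True

    @property
    def ordered_ids(self) -> list[str]:
        return list(self.table.sort_values("rank").index)

    def confirmed(self) -> list[str]:
        return list(self.table.index[self.table["decision"] == "confirmed"])


def _rf_permutation_importance(Xtr, ytr, Xte, yte, rng, n_trees, n_repeats):
    from sklearn.ensemble import RandomForestRegressor
    from sklearn.inspection import permutation_importance

    rf = RandomForestRegressor(
        n_estimators=n_trees, max_features=0.5,
        random_state=int(rng.integers(2**31)), n_jobs=1,
    )
    rf.fit(Xtr, ytr)
    res = permutation_importance(
        rf, Xte, yte, n_repeats=n_repeats,
        random_state=int(rng.integers(2**31)), n_jobs=1,
    )
    return res.importances_mean


def _gbm_shap_importance(Xtr, ytr, Xte, yte, rng, n_trees, _n_repeats):
    import lightgbm as lgb

    model = lgb.LGBMRegressor(
        n_estimators=n_trees, num_leaves=5, max_depth=16,
        random_state=int(rng.integers(2**31)), verbose=-1, n_jobs=1,
        feature_fraction=0.5, bagging_fraction=0.6, bagging_freq=1,
    )
    model.fit(Xtr, ytr)
    import warnings as _warnings

    with _warnings.catch_warnings():
        # lightgbm's sklearn wrapper assigns synthetic column names on fit,
        # then complains they are absent at predict time on plain arrays
        _warnings.simplefilter("ignore", UserWarning)
        contrib = model.predict(Xte, pred_contrib=True)[:, :-1]
    return np.abs(contrib).mean(axis=0)


_ENGINES = {
    "boruta-rf": _rf_permutation_importance,
    "boruta-shap-gbm": _gbm_shap_importance,
}


@dataclass
class BorutaConfig:
    n_iterations: int = 100
    alpha: float = 0.05
    n_trees: int = 100
    n_permutation_repeats: int = 3
    min_iterations: int = 10
    seed: int = 0


def boruta_rank(
    feature_matrix: pd.DataFrame,
    outcome,
    importance_engine: str = "boruta-rf",
    config: BorutaConfig | None = None,
    method_label: str | None = None,
) -> VariantRanking:
    """Rank features against permuted shadow copies of themselves.

    Each iteration appends a column-permuted copy of every feature, draws
    a fresh 70/30 train/test split, fits the importance engine on the
    training part ('boruta-rf': random forest scored by held-out
    permutation importance; 'boruta-shap-gbm': gradient-boosted trees
    scored by held-out mean |SHAP| value; both engines subsample features
    so iterations are genuine replicates), and records a *hit* for every
    real feature whose importance beats the best shadow.  A feature is
    confirmed when a Bonferroni-corrected two-sided binomial test on its
    hit count (against p = 1/2, level ``config.alpha``) rejects on the
    high side; everything else — including the tentative middle ground —
    is reported rejected.  Score = hit fraction; rank = descending mean
    importance.  Column order does not affect decisions; the seed fixes
    everything.
    """
    if config is None:
        config = BorutaConfig()
    engine = _ENGINES[importance_engine]
    # canonical column order so permuting input columns cannot change results
    order = sorted(feature_matrix.columns)
    Xdf = feature_matrix[order]
    X = np.nan_to_num(Xdf.to_numpy(dtype=float), nan=0.0)
    y = np.asarray(outcome, dtype=float)
    rng = np.random.default_rng(config.seed)
    p = X.shape[1]

    hits = np.zeros(p)
    imp_hist = np.empty((config.n_iterations, p))
    best_shadow_hist = np.empty(config.n_iterations)
    n_rows = X.shape[0]
    for it in range(config.n_iterations):
        shadow = X.copy()
        for j in range(p):
            rng.shuffle(shadow[:, j])
        Z = np.hstack([X, shadow])
        idx = rng.permutation(n_rows)
        cut = max(int(0.7 * n_rows), 1)
        tr, te = idx[:cut], idx[cut:]
        if len(te) == 0:
            tr = te = idx
        imp = engine(Z[tr], y[tr], Z[te], y[te], rng, config.n_trees,
                     config.n_permutation_repeats)
        real, sh = imp[:p], imp[p:]
        best_shadow = sh.max() if p else 0.0
        hits += real > best_shadow
        imp_hist[it] = real
        best_shadow_hist[it] = best_shadow

    n = config.n_iterations
    # Bonferroni-corrected two-sided binomial on the hit counts; features in
    # the tentative middle ground are resolved conservatively (rejected):
    # uncorrected or median-importance resolutions let the luckiest in-sample
    # noise feature through, defeating the screen's specificity.
    threshold = config.alpha / max(p, 1)
    decisions = []
    for j in range(p):
        pv = stats.binomtest(int(hits[j]), n, 0.5).pvalue
        decisions.append(
            "confirmed" if pv < threshold and hits[j] > n / 2 else "rejected"
        )
    mean_imp = imp_hist.mean(axis=0)
    table = pd.DataFrame(
        {
            "score": hits / n,
            "mean_importance": mean_imp,
            "decision": decisions,
        },
        index=pd.Index(order, name="variant_id"),
    )
    table["rank"] = (
        table[["mean_importance", "score"]]
        .apply(tuple, axis=1)
        .rank(ascending=False, method="first")
        .astype(int)
    )
    return VariantRanking(
        method=method_label or importance_engine,
        table=table.sort_values("rank"),
        stable=n >= config.min_iterations,
    )


def combine_rankings(rankings: list[VariantRanking], k: int = 20) -> VariantRanking:
    """Mean-rank aggregation of several rankings over the same variant set.

    Combined score is the mean rank across inputs (lower is better); ties
    break by mean per-method score (higher better), then variant id.
    Returns the top ``k`` variants.
    """
    if len(rankings) < 2:
        raise ValueError("need at least two rankings to combine")
    base = set(rankings[0].table.index)
    for r in rankings[1:]:
        if set(r.table.index) != base:
            raise ValueError("rankings cover different variant sets")
    ranks = pd.concat([r.table["rank"] for r in rankings], axis=1).mean(axis=1)
    scores = pd.concat([r.table["score"] for r in rankings], axis=1).mean(axis=1)
    table = pd.DataFrame(
        {"mean_rank": ranks.to_numpy(), "mean_score": scores.to_numpy(),
         "vid": list(ranks.index)}
    )
    table = table.sort_values(
        ["mean_rank", "mean_score", "vid"],
        ascending=[True, False, True],
        kind="mergesort",
    ).set_index("vid")
    table.index.name = "variant_id"
    table["rank"] = np.arange(1, len(table) + 1)
    table["score"] = -table["mean_rank"]
    table["decision"] = np.where(table["rank"] <= k, "confirmed", "rejected")
    return VariantRanking(method="combined", table=table.head(k))
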