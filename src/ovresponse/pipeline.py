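"""End-to-end orchestration: screening -> features -> model -> explanation.

``run_pipeline`` drives the whole discovery funnel on one cohort:

1. per-variant KS / Mann-Whitney screening,
2. shadow-feature rankings (RF and GBM engines, with and without AMH)
   combined by mean rank into a top-k candidate pool,
3. correspondence analysis of the candidate x MII-group table -> the
   proximity count feature,
4. self-organizing map -> enriched-node characteristic variants ->
   exhaustive subset search -> the standardized count feature,
5. haplotype blocks -> candidate-haplotype screening -> decision-tree
   reduction -> binary reduced-haplotype features,
6. clinical forward selection, genetic combination search, and the final
   clinical-genetic model with TreeSHAP explanations.

Every stage draws its seed from one master seed; clinical-only and
clinical-genetic metrics are always compared on identical fold
assignments.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import ca as ca_mod
from . import haplotypes as hap_mod
from . import model as model_mod
from . import screening as screen_mod
from . import som as som_mod
from .cohort import Cohort, bin_mii_counts
from .model import ModelConfig
from .screening import BorutaConfig
from .som import SomConfig

__all__ = ["PipelineConfig", "run_pipeline"]

CLINICAL_CANDIDATES = [
    "amh", "afc_day1", "age", "prev_mii", "prev_denuded", "pcos",
    "bmi", "fsh", "lh", "e2", "stim_days", "gonadotropin_dose",
]


@dataclass
class PipelineConfig:
    """Stage parameters; scale knobs default to desk-scale settings."""

    seed: int = 0
    top_k_variants: int = 20
    boruta: BorutaConfig = field(default_factory=lambda: BorutaConfig(n_iterations=30))
    model: ModelConfig = field(default_factory=ModelConfig)
    som: SomConfig = field(default_factory=lambda: SomConfig(n_iterations=20_000))
    som_subset_pool: int = 10  # candidate variants entering the subset search
    ca_k: int = 3
    block_method: str = "four-gamete"
    n_haplotype_features: int = 2
    haplotype_freq_floor: float = 0.05
    clinical_candidates: list[str] = field(
        default_factory=lambda: list(CLINICAL_CANDIDATES)
    )
    alpha: float = 0.05


def _clinical_frame(cohort: Cohort, columns) -> pd.DataFrame:
    df = cohort.clinical[list(columns)].copy()
    if "pcos" in df:
        df["pcos"] = df["pcos"].astype(float)
    return df.astype(float)


def run_pipeline(cohort: Cohort, config: PipelineConfig | None = None) -> dict:
    """Run the full analysis on a cohort with genotypes; returns a report.

    The report is a plain JSON-serializable dict of every stage's main
    outputs (selected features, metrics, seeds); heavier tables are
    attached under the ``tables`` key as DataFrames.
    """
    if config is None:
        config = PipelineConfig()
    if cohort.genotypes is None:
        raise ValueError("pipeline needs genotype data")
    rng = np.random.default_rng(config.seed)
    stage_seed = {
        name: int(rng.integers(2**31))
        for name in ("boruta_rf", "boruta_gbm", "boruta_amh", "som", "model", "reduce")
    }
    report: dict = {"seed": config.seed, "stage_seeds": stage_seed, "stages": []}
    tables: dict = {}
    y = cohort.mii_counts.to_numpy(dtype=float)
    pid = cohort.patient_ids
    mcfg = ModelConfig(**{**config.model.__dict__, "seed": stage_seed["model"]})
    folds = model_mod.assign_grouped_folds(pid, mcfg.n_folds, mcfg.seed)

    try:
        # -- stage 1: distribution tests ---------------------------------
        stage = "statistical_screening"
        partition = bin_mii_counts(cohort)
        tests = screen_mod.screen_all_variants(cohort, alpha=config.alpha)
        sig = tests[tests["direction"] != "none"]
        report["mii_group_sizes"] = partition.sizes.to_dict()
        report["n_variants_tested"] = int(len(tests))
        report["n_significant_higher"] = int((sig["direction"] == "higher").sum())
        report["n_significant_lower"] = int((sig["direction"] == "lower").sum())
        tables["variant_tests"] = tests
        report["stages"].append(stage)

        # -- stage 2: shadow-feature ranking -----------------------------
        stage = "variant_ranking"
        ap = cohort.genotypes.alt_presence_frame()
        rankings = [
            screen_mod.boruta_rank(
                ap, y, "boruta-rf",
                BorutaConfig(**{**config.boruta.__dict__, "seed": stage_seed["boruta_rf"]}),
            ),
            screen_mod.boruta_rank(
                ap, y, "boruta-shap-gbm",
                BorutaConfig(**{**config.boruta.__dict__, "seed": stage_seed["boruta_gbm"]}),
            ),
            screen_mod.boruta_rank(
                ap.assign(amh=cohort.clinical["amh"].to_numpy()), y, "boruta-rf",
                BorutaConfig(**{**config.boruta.__dict__, "seed": stage_seed["boruta_amh"]}),
                method_label="boruta-rf-with-amh",
            ),
        ]
        # AMH is a helper covariate in the third run, not a variant
        rankings[2].table = rankings[2].table.drop(index="amh")
        rankings[2].table["rank"] = (
            rankings[2].table["rank"].rank(method="first").astype(int)
        )
        combined = screen_mod.combine_rankings(rankings, k=config.top_k_variants)
        top = combined.ordered_ids
        report["top_variants"] = top
        tables["combined_ranking"] = combined.table
        report["stages"].append(stage)

        # -- stage 3: correspondence analysis ----------------------------
        stage = "ca_feature"
        table = ca_mod.build_contingency(cohort, partition, top)
        ca_res = ca_mod.fit_ca(table)
        iv_ca, distances = ca_mod.select_proximal_variants(
            ca_res, target_group=">11", k=config.ca_k
        )
        report["ca_total_inertia"] = ca_res.total_inertia
        report["ca_inertia_first_two"] = float(
            ca_res.inertia_proportions[: min(2, ca_res.n_dims)].sum()
        )
        report["iv_ca_variants"] = iv_ca.variant_ids
        tables["ca_distances"] = distances.sort_values()
        feat_ca = ca_mod.evaluate_count_feature(iv_ca, cohort.genotypes)
        report["stages"].append(stage)

        # -- clinical forward selection (needed as the genetic stages'
        # evaluation context) ---------------------------------------------
        stage = "clinical_selection"
        clin_all = _clinical_frame(cohort, [c for c in config.clinical_candidates
                                            if c in cohort.clinical])
        trace = model_mod.forward_select(clin_all, y, pid, mcfg)
        selected_clinical = trace.selected
        if not selected_clinical:
            warnings.warn("no clinical feature improved on the trivial baseline",
                          stacklevel=2)
        clin = clin_all[selected_clinical]
        clin_res = model_mod.train_gbm_cv(clin, y, pid, mcfg, folds)
        report["baseline_rmse"] = trace.baseline_rmse
        report["selected_clinical"] = selected_clinical
        report["clinical_metrics"] = {
            "rmse": clin_res.metrics.rmse,
            "mae": clin_res.metrics.mae,
            "mape": clin_res.metrics.mape,
        }
        tables["clinical_selection"] = trace.iterations
        report["stages"].append(stage)

        def rmse_with_feature(feature: pd.Series | None) -> float:
            cols = [clin] if feature is None else [clin, feature.rename("g")]
            res = model_mod.train_gbm_cv(pd.concat(cols, axis=1), y, pid, mcfg, folds)
            return res.metrics.rmse

        # -- stage 4: SOM feature ----------------------------------------
        stage = "som_feature"
        som_cfg = SomConfig(**{**config.som.__dict__, "seed": stage_seed["som"]})
        top_geno = cohort.genotypes.subset_variants(top)
        som = som_mod.train_som(top_geno, som_cfg)
        enriched = som_mod.node_enrichment(
            som, partition, top_geno, groups=["<=2", ">11"]
        )
        pool: dict[str, float] = {}
        for node in enriched:
            for vid, diff in node.characteristic_variants.items():
                pool[vid] = max(pool.get(vid, -np.inf), abs(diff))
        candidates = sorted(pool, key=lambda v: (-pool[v], v))[: config.som_subset_pool]
        report["som_qe"] = som.quantization_error
        report["som_n_enriched_nodes"] = len(enriched)
        report["som_candidates"] = candidates
        if candidates:
            def eval_subset(subset):
                feat = som_mod.build_standardized_feature(
                    subset, cohort.genotypes, name="IV-SOM"
                )
                return rmse_with_feature(
                    som_mod.evaluate_standardized_feature(feat, cohort.genotypes)
                )

            best_subset, search_trace = som_mod.subset_search(candidates, eval_subset)
            iv_som = som_mod.build_standardized_feature(
                list(best_subset), cohort.genotypes, name="IV-SOM"
            )
            feat_som = som_mod.evaluate_standardized_feature(iv_som, cohort.genotypes)
            report["iv_som_variants"] = list(best_subset)
            tables["som_subset_search"] = search_trace
        else:
            feat_som = None
            report["iv_som_variants"] = []
        report["stages"].append(stage)

        # -- stage 5: haplotype features ---------------------------------
        stage = "haplotype_features"
        blocks = hap_mod.detect_blocks(cohort.genotypes, method=config.block_method)
        screened = hap_mod.screen_haplotypes(
            blocks, cohort.genotypes, rmse_with_feature,
            baseline_rmse=clin_res.metrics.rmse,
            freq_floor=config.haplotype_freq_floor,
        )
        hap_features: dict[str, pd.Series] = {}
        hap_defs = {}
        if not screened.empty:
            used_blocks: list[int] = []
            red_cfg = hap_mod.ReductionConfig(seed=stage_seed["reduce"])
            for _, row in screened.iterrows():
                if row["block"] in used_blocks or row["rmse_reduction"] <= 0:
                    continue
                used_blocks.append(row["block"])
                nvar = len(row["variant_ids"])
                fname = f"IV{nvar}-H{len(hap_features) + 1}"
                reduced = hap_mod.reduce_haplotype(
                    list(row["variant_ids"]), cohort.genotypes, red_cfg, name=fname
                )
                reduced.name = f"IV{nvar}-{len(reduced.baseline)}"
                hap_features[reduced.name] = hap_mod.evaluate_reduced_haplotype(
                    reduced, cohort.genotypes
                ).rename(reduced.name)
                hap_defs[reduced.name] = {
                    "baseline": reduced.baseline,
                    "frequency": reduced.frequency,
                    "k_clusters": reduced.k_clusters,
                    "source_block": list(row["variant_ids"]),
                }
                if len(hap_features) >= config.n_haplotype_features:
                    break
        report["n_blocks"] = len(blocks)
        report["n_candidate_haplotypes"] = int(len(screened))
        report["reduced_haplotypes"] = hap_defs
        tables["haplotype_screen"] = screened
        report["stages"].append(stage)

        # -- stage 6: genetic combination search + final model -----------
        stage = "final_model"
        genetic = {"IV-CA": feat_ca}
        if feat_som is not None:
            genetic["IV-SOM"] = feat_som
        genetic.update(hap_features)
        genetic_df = pd.DataFrame(genetic)
        best_combo, combo_table = model_mod.genetic_combination_search(
            genetic_df, clin, y, pid, mcfg
        )
        final_table = pd.concat([clin, genetic_df[list(best_combo)]], axis=1)
        final_res = model_mod.train_gbm_cv(final_table, y, pid, mcfg, folds)
        importance = model_mod.shap_importance(final_res.model, final_table)
        report["n_genetic_combinations"] = int(len(combo_table))
        report["best_genetic_combination"] = list(best_combo)
        report["clinical_genetic_metrics"] = {
            "rmse": final_res.metrics.rmse,
            "mae": final_res.metrics.mae,
            "mape": final_res.metrics.mape,
        }
        report["rmse_reduction_vs_clinical"] = (
            report["clinical_metrics"]["rmse"] - final_res.metrics.rmse
        )
        report["shap_importance"] = importance.to_dict()
        tables["combination_search"] = combo_table
        report["tables"] = tables
        report["final_feature_table"] = final_table
        report["final_model"] = final_res.model
        report["genetic_feature_names"] = list(best_combo)
        report["stages"].append(stage)
    except Exception as exc:
        report["failed_stage"] = stage
        report["error"] = repr(exc)
        report["tables"] = tables
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc
    return report
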