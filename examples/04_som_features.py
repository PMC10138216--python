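"""Self-organizing map features: enriched nodes -> subset search -> z-score.

A 6x6 hexagonal SOM is trained on binary genotype vectors; map nodes
where the extreme MII groups are over-represented yield candidate
variants, an exhaustive subset search picks the combination whose
standardized carrier count most reduces a simple model's CV RMSE, and
the winning feature is frozen as a z-score on the defining cohort.
"""

import numpy as np

import ovresponse as ov
from ovresponse.som import SomConfig

cohort, _ = ov.generate_cohort(ov.GeneratorConfig(seed=1, n_patients=264))
part = ov.bin_mii_counts(cohort)

geno = cohort.genotypes.subset_variants([v.variant_id for v in ov.TABLE_PANEL])
som = ov.train_som(geno, SomConfig(n_iterations=20_000, seed=3))
print(f"SOM quantization error: {som.quantization_error:.2f}")

enriched = ov.node_enrichment(som, part, geno, top_m=10, groups=["<=2", ">11"])
for node in enriched[:3]:
    print(
        f"node {node.node}: {node.n_observations} obs, group {node.group} "
        f"share {node.group_share:.0%} vs population {node.population_share:.0%}"
    )

pool = sorted({v for e in enriched for v in e.characteristic_variants.index[:4]})[:8]
print(f"\nsubset-search pool ({len(pool)} variants): {pool}")

y = cohort.mii_counts.to_numpy(dtype=float)
folds = ov.assign_grouped_folds(cohort.patient_ids, 5, seed=1)
amh = np.log1p(cohort.clinical.amh.to_numpy())


def cv_rmse(subset):
    feat = ov.build_standardized_feature(list(subset), cohort.genotypes)
    g = np.nan_to_num(
        ov.evaluate_standardized_feature(feat, cohort.genotypes).to_numpy(), nan=0.0
    )
    X = np.column_stack([np.ones_like(y), amh, g])
    oof = np.empty_like(y)
    for f in range(5):
        te = folds == f
        beta, *_ = np.linalg.lstsq(X[~te], y[~te], rcond=None)
        oof[te] = X[te] @ beta
    return float(np.sqrt(np.mean((oof - y) ** 2)))


best, trace = ov.subset_search(pool, cv_rmse)
print(f"evaluated {len(trace)} subsets; best: {best}")
feat = ov.build_standardized_feature(list(best), cohort.genotypes)
vals = ov.evaluate_standardized_feature(feat, cohort.genotypes)
print(f"standardized feature: mean {np.nanmean(vals):+.2e}, sd {np.nanstd(vals):.3f}")
# The standardization constants are frozen from this cohort and reused
# verbatim when the feature is evaluated on new patients.
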