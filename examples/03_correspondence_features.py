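"""Correspondence analysis of the variant x MII-group table.

Processes are binned into five MII-count groups; the carrier counts of
candidate variants per group form a contingency table whose CA map
places variants and groups in the same plane.  The variants nearest the
high-yield group (">11") define a count-type genetic feature.
"""

import ovresponse as ov

cohort, _ = ov.generate_cohort(ov.GeneratorConfig(seed=1, n_patients=264))
part = ov.bin_mii_counts(cohort)

candidates = [v.variant_id for v in ov.TABLE_PANEL]
table = ov.build_contingency(cohort, part, candidates)
res = ov.fit_ca(table)
print(f"total inertia (chi2/n): {res.total_inertia:.4f}")
print(
    "first two dimensions explain "
    f"{100 * res.inertia_proportions[:2].sum():.0f}% of the inertia"
)

feature, distances = ov.select_proximal_variants(res, target_group=">11", k=3)
print("\nvariants closest to the >11-oocyte group:")
print(distances.sort_values().head(5).to_string())
values = ov.evaluate_count_feature(feature, cohort.genotypes)
print(f"\ncount feature over {feature.variant_ids}:")
print(values.value_counts(dropna=False).sort_index().to_string())
# The feature value is the number of member variants carried as
# alternative (0-3); missing genotypes propagate as missing values.
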