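"""Generate a synthetic IVF-stimulation cohort and inspect its structure.

The generator reproduces the statistical shape of a clinical-genetic
ovarian stimulation study: log-normal AMH truncated at the 15 ng/mL
exclusion bound, AFC correlated with AMH, a 122-variant panel with
published allele frequencies and three LD blocks, missing history for
first stimulations, and a negative-binomial MII-oocyte outcome driven by
AMH, AFC, age and two planted genetic effects.
"""

import numpy as np

import ovresponse as ov

cohort, truth = ov.generate_cohort(ov.GeneratorConfig(seed=1, n_patients=264))

clin = cohort.clinical
print(f"{cohort.n_patients} patients, {cohort.n_processes} stimulation processes")
print(f"age  {clin.age.mean():5.2f} +/- {clin.age.std():.2f} years")
print(f"AMH  {clin.amh.mean():5.2f} +/- {clin.amh.std():.2f} ng/mL (max {clin.amh.max():.2f})")
print(f"AFC  {clin.afc_day1.mean():5.2f} follicles <= 10 mm")
print(f"MII  {clin.mii_count.mean():5.2f} +/- {clin.mii_count.std():.2f} oocytes")
print(f"r(AMH, MII) = {np.corrcoef(clin.amh, clin.mii_count)[0, 1]:.2f}")
print(f"previous-stimulation data missing for {clin.prev_mii.isna().mean():.0%} "
      "of processes (first stimulations)")

part = ov.bin_mii_counts(cohort)
print("\nMII-count groups:", {k: int(v) for k, v in part.sizes.items()})
print("\nplanted effects:", [(e.name, e.kind, e.beta) for e in truth.effects])
# The five group sizes sum to the cohort; the planted effects are what the
# downstream feature-discovery stages are expected to recover.
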