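"""Haplotype blocks, LD statistics and the binary reduced haplotype.

Pairwise D'/r2 come from the two-locus EM on unphased dosages; blocks
are detected with the four-gamete rule; and a multi-variant block is
reduced — by UMAP embedding, K-means clustering and a decision tree —
to the few variants whose reference states identify the dominant
patient group (the binary reduced-haplotype feature).
"""

import numpy as np

import ovresponse as ov
from ovresponse.simulate import LDBlockSpec

# tighten the founder pools (|D'| = 1 within blocks) so the planted block
# structure is crisp at this cohort size
config = ov.GeneratorConfig(
    seed=1, n_patients=264,
    ld_blocks=[
        LDBlockSpec(ids, target_dprime=1.0)
        for ids in ov.DEFAULT_LD_BLOCKS.values()
    ],
)
cohort, _ = ov.generate_cohort(config)
geno = cohort.genotypes

prlr = ov.DEFAULT_LD_BLOCKS["PRLR"]
s = ov.estimate_two_locus_ld(geno, (prlr[0], prlr[1]))
print(f"{prlr[0]} x {prlr[1]}: D' = {s.d_prime:.2f}, r2 = {s.r2:.2f} "
      f"({s.n_chromosomes} chromosomes)")

blocks = ov.detect_blocks(geno, "four-gamete")
multi = [b for b in blocks if len(b) > 1]
print(f"\n{len(blocks)} blocks, {len(multi)} with more than one variant:")
for b in multi[:5]:
    top = b.haplotypes.iloc[0]
    print(f"  {b.chrom}: {len(b)} variants, top haplotype "
          f"{top.haplotype} at frequency {top.frequency:.2f}")

block = max(multi, key=len)
red = ov.reduce_haplotype(block.variant_ids, geno,
                          ov.ReductionConfig(seed=5), name="reduced")
print(f"\nreduced the {len(block)}-variant block to {len(red.baseline)} "
      f"path variant(s): {red.baseline}")
vals = ov.evaluate_reduced_haplotype(red, geno)
print(f"feature value 1 (all path variants at baseline) for "
      f"{np.nanmean(vals):.0%} of processes")
# Any alternative allele on the decision path sets the feature to 0;
# a missing path genotype leaves it missing for the learner to route.
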