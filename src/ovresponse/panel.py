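"""The default 14-gene reproduction panel used by the synthetic generator.

The 22 named variants below are the published feature variants of the
oocyte-yield study (three count-feature variants found by correspondence
analysis, six by the self-organizing map, and the members of the three
reduced haplotypes, plus three further SOM-screen variants).  Alternative
allele frequencies are the study cohort's where published; the three
variants marked ``synthetic freq`` carry plausible invented frequencies.
Unpublished alt alleles are arbitrary (the pipeline only uses binary
alt-presence, never the base identity).
"""

from __future__ import annotations

from .cohort import VariantDef

__all__ = ["TABLE_PANEL", "DEFAULT_LD_BLOCKS", "default_panel"]

#: published feature variants: (rsID, gene, chrom, pos, ref, alt, alt freq)
TABLE_PANEL = [
    VariantDef("rs62137532", "LHCGR", "chr2", 48687476, "C", "G", 0.15),  # synthetic freq
    VariantDef("rs11887058", "LHCGR", "chr2", 48729336, "C", "T", 0.428),
    VariantDef("rs80111020", "FSHR", "chr2", 48962060, "A", "G", 0.091),
    VariantDef("rs6166", "FSHR", "chr2", 48962782, "C", "T", 0.701),
    VariantDef("rs387032", "PRLR", "chr5", 35061629, "T", "C", 0.155),
    VariantDef("rs401694", "PRLR", "chr5", 35062516, "C", "T", 0.235),
    VariantDef("rs112461", "PRLR", "chr5", 35063190, "A", "T", 0.242),
    VariantDef("rs1057828", "PRLR", "chr5", 35064413, "C", "T", 0.061),
    VariantDef("rs56251626", "PRLR", "chr5", 35064922, "C", "T", 0.064),
    VariantDef("rs62355478", "PRLR", "chr5", 35065548, "C", "T", 0.008),
    VariantDef("rs78373811", "PRLR", "chr5", 35068146, "G", "A", 0.087),
    VariantDef("rs186609463", "PRLR", "chr5", 35069864, "G", "A", 0.015),
    VariantDef("rs11739194", "GDF9", "chr5", 132865538, "T", "C", 0.515),
    VariantDef("rs75061517", "GDF9", "chr5", 132866082, "T", "C", 0.311),
    VariantDef("rs17166294", "GDF9", "chr5", 132866205, "T", "C", 0.288),
    VariantDef("rs30177", "GDF9", "chr5", 132866719, "C", "G", 0.924),
    VariantDef("rs2077647", "ESR1", "chr6", 151807942, "T", "C", 0.45),  # synthetic freq
    VariantDef("rs2273206", "ESR1", "chr6", 152061176, "G", "T", 0.12),  # synthetic freq
    VariantDef("rs2273207", "ESR1", "chr6", 152061190, "A", "G", 0.117),
    VariantDef("rs2207396", "ESR1", "chr6", 152061247, "G", "A", 0.356),
    VariantDef("rs676349", "FSHB", "chr11", 30234435, "A", "G", 0.523),
    VariantDef("rs928554", "ESR2", "chr14", 64227477, "C", "T", 0.731),
]

#: default LD blocks (by rsID): the two-variant FSHR block, the
#: eight-variant PRLR block and the four-variant GDF9 run mirror the
#: study's three reduced haplotypes (2, 8 and 3 member variants).
DEFAULT_LD_BLOCKS = {
    "FSHR": ["rs80111020", "rs6166"],
    "PRLR": [
        "rs387032", "rs401694", "rs112461", "rs1057828",
        "rs56251626", "rs62355478", "rs78373811", "rs186609463",
    ],
    "GDF9": ["rs11739194", "rs75061517", "rs17166294", "rs30177"],
}


def default_panel(n_null: int = 100, null_freq_range=(0.05, 0.5), seed: int = 7):
    """The named panel plus ``n_null`` independent filler variants.

    Null variants are spread over the panel genes' chromosomes at synthetic
    positions, with alt frequencies drawn once (module-level seed) from
    ``null_freq_range``; they carry no outcome effect under the default
    generator and exist so that screening specificity is testable.
    """
    import numpy as np

    rng = np.random.default_rng(seed)
    panel = list(TABLE_PANEL)
    chroms = ["chr2", "chr5", "chr6", "chr11", "chr14", "chrX", "chr19", "chr12"]
    lo, hi = null_freq_range
    for i in range(n_null):
        chrom = chroms[i % len(chroms)]
        panel.append(
            VariantDef(
                f"rsN{i:04d}",
                "NULL",
                chrom,
                200_000_000 + 10_000 * i,  # beyond real gene loci, well spaced
                "A",
                "G",
                float(rng.uniform(lo, hi)),
            )
        )
    panel.sort(key=lambda v: (v.chrom, v.pos))
    return panel
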