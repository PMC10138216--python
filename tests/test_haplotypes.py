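"""LD estimation, block detection and haplotype reduction against oracles."""

import numpy as np
import pandas as pd
import pytest

import ovresponse as ov
from ovresponse.haplotypes import (
    BlockParams,
    ReducedHaplotype,
    ReductionConfig,
    _em_two_locus,
)
from ovresponse.simulate import EffectSpec, GeneratorConfig, LDBlockSpec

from conftest import make_panel


def geno_from_dosage(dosage, chrom="chr1"):
    dosage = np.asarray(dosage, dtype=float)
    panel = make_panel(dosage.shape[1], chrom=chrom)
    return ov.GenotypeMatrix(
        [f"p{i}" for i in range(len(dosage))], panel, dosage
    )


class TestTwoLocusEM:
    def test_complete_ld_gives_dprime_one(self):
        # only AB and ab haplotypes present (dosages perfectly coupled)
        geno = geno_from_dosage([[2, 2], [0, 0], [1, 1], [2, 2], [0, 0]])
        s = ov.estimate_two_locus_ld(geno, ("rschr1_0", "rschr1_1"))
        assert s.d_prime == pytest.approx(1.0, abs=1e-6)
        assert sum(s.hap_freqs.values()) == pytest.approx(1.0)

    def test_independent_loci_near_zero_dprime(self):
        rng = np.random.default_rng(0)
        dosage = rng.binomial(2, 0.5, size=(800, 2))
        s = ov.estimate_two_locus_ld(
            geno_from_dosage(dosage), ("rschr1_0", "rschr1_1")
        )
        assert s.d_prime < 0.15

    def test_no_double_het_equals_direct_count(self):
        # 6-individual toy without double heterozygotes: EM = gamete counting
        dosage = np.array(
            [[2, 2], [2, 1], [0, 0], [0, 1], [1, 2], [0, 0]], dtype=float
        )
        geno = geno_from_dosage(dosage)
        s = ov.estimate_two_locus_ld(geno, ("rschr1_0", "rschr1_1"))
        # hand count of the 12 gametes:
        # (2,2): AB,AB  (2,1): AB,Ab  (0,0): ab,ab  (0,1): aB,ab
        # (1,2): AB,aB  (0,0): ab,ab
        expect = {"11": 4 / 12, "10": 1 / 12, "01": 2 / 12, "00": 5 / 12}
        for k, v in expect.items():
            assert s.hap_freqs[k] == pytest.approx(v, abs=1e-9)

    def test_em_matches_grid_search_mle_with_double_hets(self):
        rng = np.random.default_rng(4)
        # correlated pair with plenty of double heterozygotes
        h = rng.binomial(1, 0.5, size=(400, 2))
        h2 = np.where(rng.uniform(size=(400, 2)) < 0.8, h, rng.binomial(1, 0.5, (400, 2)))
        dosage = h + h2
        geno = geno_from_dosage(dosage)
        s = ov.estimate_two_locus_ld(geno, ("rschr1_0", "rschr1_1"))
        # oracle: 1-D likelihood grid over f11 with margins fixed at MLE
        a, b = dosage[:, 0], dosage[:, 1]
        pa, pb = a.mean() / 2, b.mean() / 2
        lo, hi = max(0, pa + pb - 1), min(pa, pb)
        best_f11, best_ll = None, -np.inf
        for f11 in np.linspace(lo + 1e-6, hi - 1e-6, 4001):
            f = np.clip(
                np.array(
                    [[1 - pa - pb + f11, pb - f11], [pa - f11, f11]]
                ),
                1e-12, None,
            )
            ll = 0.0
            for ga, gb in zip(a, b):
                pav = [(0, 0)] if ga == 0 else [(1, 1)] if ga == 2 else [(0, 1), (1, 0)]
                pbv = [(0, 0)] if gb == 0 else [(1, 1)] if gb == 2 else [(0, 1), (1, 0)]
                prob = sum(
                    f[a1, b1] * f[a2, b2] for a1, a2 in pav for b1, b2 in pbv
                )
                ll += np.log(prob)
            if ll > best_ll:
                best_ll, best_f11 = ll, f11
        assert s.hap_freqs["11"] == pytest.approx(best_f11, abs=2e-3)

    def test_dprime_invariant_to_allele_swap(self):
        rng = np.random.default_rng(7)
        dosage = rng.binomial(2, [0.3, 0.6], size=(300, 2)).astype(float)
        geno = geno_from_dosage(dosage)
        s1 = ov.estimate_two_locus_ld(geno, ("rschr1_0", "rschr1_1"))
        swapped = dosage.copy()
        swapped[:, 0] = 2 - swapped[:, 0]
        s2 = ov.estimate_two_locus_ld(
            geno_from_dosage(swapped), ("rschr1_0", "rschr1_1")
        )
        assert s1.d_prime == pytest.approx(s2.d_prime, abs=1e-6)

    def test_monomorphic_flagged(self):
        geno = geno_from_dosage([[0, 1], [0, 2], [0, 0]])
        s = ov.estimate_two_locus_ld(geno, ("rschr1_0", "rschr1_1"))
        assert not s.defined


def brute_force_four_gamete_blocks(geno, vids, floor=0.01):
    """Independent oracle: maximal left-to-right runs over a recombinant-pair
    matrix built by direct gamete counting (no double hets in the toys)."""

    def recombinant(v1, v2):
        i, j = geno.index_of(v1), geno.index_of(v2)
        a, b = geno.dosage[:, i], geno.dosage[:, j]
        gametes = {"00": 0, "01": 0, "10": 0, "11": 0}
        for ga, gb in zip(a, b):
            av = [0, 0] if ga == 0 else [1, 1] if ga == 2 else [0, 1]
            bv = [0, 0] if gb == 0 else [1, 1] if gb == 2 else [0, 1]
            assert not (ga == 1 and gb == 1), "oracle needs no double hets"
            if ga == 1:
                gametes[f"0{bv[0]}"] += 1
                gametes[f"1{bv[1]}"] += 1
            elif gb == 1:
                gametes[f"{av[0]}0"] += 1
                gametes[f"{av[1]}1"] += 1
            else:
                gametes[f"{av[0]}{bv[0]}"] += 2
        total = sum(gametes.values())
        return all(v / total >= floor for v in gametes.values())

    blocks, i = [], 0
    while i < len(vids):
        j = i
        while j + 1 < len(vids) and not any(
            recombinant(vids[k], vids[j + 1]) for k in range(i, j + 1)
        ):
            j += 1
        blocks.append(vids[i : j + 1])
        i = j + 1
    return blocks


class TestBlockDetection:
    def test_three_snp_four_gamete_example(self):
        # pair (0,1) shows 3 gametes; pairs (0,2) and (1,2) show all 4
        dosage = np.array(
            [
                [2, 2, 2],
                [2, 2, 0],
                [0, 0, 2],
                [0, 0, 0],
                [2, 2, 2],
                [0, 0, 2],
                [2, 2, 0],
                [0, 2, 0],
            ],
            dtype=float,
        ) * np.array([1, 1, 1])
        geno = geno_from_dosage(dosage)
        blocks = ov.detect_blocks(
            geno, "four-gamete", BlockParams(maf_floor=0.0)
        )
        spans = [b.variant_ids for b in blocks]
        assert spans == [["rschr1_0", "rschr1_1"], ["rschr1_2"]]

    @pytest.mark.parametrize("seed", range(4))
    def test_four_gamete_matches_bruteforce(self, seed):
        rng = np.random.default_rng(seed)
        # homozygous-only dosages: EM reduces to exact gamete counting,
        # so implementation and oracle see identical haplotype spectra
        n_var = rng.integers(5, 13)
        dosage = 2.0 * rng.binomial(1, rng.uniform(0.2, 0.8, n_var), size=(60, n_var))
        geno = geno_from_dosage(dosage)
        params = BlockParams(maf_floor=0.0)
        got = [
            b.variant_ids for b in ov.detect_blocks(geno, "four-gamete", params)
        ]
        want = brute_force_four_gamete_blocks(geno, geno.variant_ids)
        assert got == want

    def test_single_snp_chromosome_is_singleton_block(self):
        geno = geno_from_dosage([[2], [0], [1], [2]])
        blocks = ov.detect_blocks(geno, "four-gamete", BlockParams(maf_floor=0.0))
        assert len(blocks) == 1
        assert blocks[0].variant_ids == ["rschr1_0"]

    def test_planted_blocks_recovered(self):
        # two founder-pool blocks in complete LD plus independent spacers
        panel = (
            [ov.VariantDef(f"rsA{i}", "G1", "chr1", 100 + i, "A", "G", 0.4)
             for i in range(3)]
            + [ov.VariantDef("rsMid", "G1", "chr1", 500, "A", "G", 0.5)]
            + [ov.VariantDef(f"rsB{i}", "G1", "chr1", 900 + i, "A", "G", 0.3)
               for i in range(3)]
        )
        cfg = GeneratorConfig(
            seed=17, panel=panel,
            ld_blocks=[
                LDBlockSpec([f"rsA{i}" for i in range(3)], target_dprime=1.0),
                LDBlockSpec([f"rsB{i}" for i in range(3)], target_dprime=1.0),
            ],
            effects=EffectSpec(genetic=[]),
        )
        geno, _ = ov.sample_genotypes_with_ld(cfg, 500)
        blocks = ov.detect_blocks(geno, "four-gamete")
        multi = [tuple(b.variant_ids) for b in blocks if len(b) > 1]
        assert ("rsA0", "rsA1", "rsA2") in multi
        assert ("rsB0", "rsB1", "rsB2") in multi

    def test_solid_spine_requires_endpoint_ld(self):
        cfg = GeneratorConfig(
            seed=23,
            panel=[ov.VariantDef(f"rsA{i}", "G1", "chr1", 100 + i, "A", "G", 0.4)
                   for i in range(4)],
            ld_blocks=[LDBlockSpec([f"rsA{i}" for i in range(4)],
                                   target_dprime=1.0)],
            effects=EffectSpec(genetic=[]),
        )
        geno, _ = ov.sample_genotypes_with_ld(cfg, 400)
        blocks = ov.detect_blocks(geno, "solid-spine")
        assert [len(b) for b in blocks] == [4]

    def test_confidence_interval_method_on_strong_block(self):
        cfg = GeneratorConfig(
            seed=29,
            panel=[ov.VariantDef(f"rsA{i}", "G1", "chr1", 100 + i, "A", "G", 0.45)
                   for i in range(3)],
            ld_blocks=[LDBlockSpec([f"rsA{i}" for i in range(3)],
                                   target_dprime=1.0)],
            effects=EffectSpec(genetic=[]),
        )
        geno, _ = ov.sample_genotypes_with_ld(cfg, 400)
        blocks = ov.detect_blocks(geno, "confidence-intervals")
        assert [len(b) for b in blocks] == [3]

    def test_unsorted_input_rejected(self):
        panel = [
            ov.VariantDef("rsB", "G", "chr1", 200, "A", "G"),
            ov.VariantDef("rsA", "G", "chr1", 100, "A", "G"),
        ]
        geno = ov.GenotypeMatrix(["p0"], panel, np.array([[1.0, 1.0]]))
        with pytest.raises(ValueError, match="sorted"):
            ov.detect_blocks(geno, "four-gamete", BlockParams(maf_floor=0.0))


class TestBlockHaplotypes:
    def test_em_spectrum_sums_to_one_and_matches_counting(self):
        # <= 1 het site per row: phases unambiguous, EM = direct counting
        dosage = np.array(
            [[2, 2, 2], [0, 0, 0], [2, 2, 2], [1, 2, 2], [0, 0, 1]], dtype=float
        )
        geno = geno_from_dosage(dosage)
        table = ov.block_haplotype_frequencies(
            geno, geno.variant_ids, freq_floor=0.0
        )
        freqs = dict(zip(table["haplotype"], table["frequency"]))
        assert sum(freqs.values()) == pytest.approx(1.0)
        # hand count over the 10 chromosomes: rows resolve unambiguously to
        # 111 x5, 000 x3, 011 x1, 001 x1
        assert freqs["111"] == pytest.approx(5 / 10, abs=1e-6)
        assert freqs["000"] == pytest.approx(3 / 10, abs=1e-6)
        assert freqs["011"] == pytest.approx(1 / 10, abs=1e-6)
        assert freqs["001"] == pytest.approx(1 / 10, abs=1e-6)


class TestScreenHaplotypes:
    def make_blocks(self):
        # only three gametes (11, 00, rare 10): the pair stays one block
        dosage = np.array(
            [[2, 2]] * 4 + [[0, 0]] * 4 + [[2, 0]], dtype=float
        )
        geno = geno_from_dosage(dosage)
        blocks = ov.detect_blocks(geno, "four-gamete", BlockParams(maf_floor=0.0))
        assert [len(b) for b in blocks] == [2]
        return geno, blocks

    def test_stub_callback_ranks_favored_candidate_first(self):
        geno, blocks = self.make_blocks()

        def cb(feat):
            return 1.0 if feat.name.endswith("11") else 2.0

        ranked = ov.screen_haplotypes(blocks, geno, cb, baseline_rmse=2.5,
                                      freq_floor=0.05)
        assert ranked.iloc[0]["haplotype"] == "11"
        assert ranked.iloc[0]["rmse_reduction"] == pytest.approx(1.5)

    def test_frequency_floor_excludes_rare(self):
        geno, blocks = self.make_blocks()
        ranked = ov.screen_haplotypes(
            blocks, geno, lambda f: 1.0, baseline_rmse=2.0, freq_floor=0.2
        )
        assert set(ranked["haplotype"]) == {"11", "00"}  # the 0.11 "10" is out


class TestReduceHaplotype:
    def build_cluster_genotypes(self, seed=0):
        """8-variant block: v0 and v1 perfectly separate the dominant
        all-reference cluster from the two carrier clusters."""
        rng = np.random.default_rng(seed)
        rows = []
        for _ in range(80):  # dominant cluster: all reference
            rows.append(np.zeros(8))
        for _ in range(35):  # cluster 2: v0 alt, v2..v4 usually alt
            r = np.zeros(8)
            r[0] = 1
            r[2:5] = rng.binomial(1, 0.8, 3)
            rows.append(r)
        for _ in range(35):  # cluster 3: v1 alt, v5..v7 usually alt
            r = np.zeros(8)
            r[1] = 1
            r[5:8] = rng.binomial(1, 0.8, 3)
            rows.append(r)
        return geno_from_dosage(np.array(rows))

    def test_two_determining_variants_form_the_path(self):
        geno = self.build_cluster_genotypes()
        red = ov.reduce_haplotype(
            geno.variant_ids, geno, ReductionConfig(seed=3), name="IV8"
        )
        assert set(red.baseline) == {"rschr1_0", "rschr1_1"}
        assert red.baseline == {"rschr1_0": 0, "rschr1_1": 0}
        assert red.frequency == pytest.approx(80 / 150)

    def test_eq4_evaluation(self):
        feature = ReducedHaplotype(
            "f", {"rschr1_0": 0, "rschr1_1": 0}, frequency=0.5
        )
        geno = geno_from_dosage(
            [[0, 0, 1], [1, 0, 0], [0, np.nan, 0]]
        )
        vals = ov.evaluate_reduced_haplotype(feature, geno)
        assert vals.iloc[0] == 1.0  # all path variants at baseline
        assert vals.iloc[1] == 0.0  # any alternative on the path -> 0
        assert np.isnan(vals.iloc[2])  # missing path genotype -> missing

    def test_degenerate_block_keeps_modal_pattern(self):
        geno = geno_from_dosage(np.zeros((30, 4)))
        with pytest.warns(UserWarning, match="degenerate"):
            red = ov.reduce_haplotype(geno.variant_ids, geno,
                                      ReductionConfig(seed=0))
        assert red.frequency == pytest.approx(1.0)
        assert len(red.baseline) == 4

    def test_reduction_is_deterministic(self):
        geno = self.build_cluster_genotypes()
        a = ov.reduce_haplotype(geno.variant_ids, geno, ReductionConfig(seed=5))
        b = ov.reduce_haplotype(geno.variant_ids, geno, ReductionConfig(seed=5))
        assert a.baseline == b.baseline
        assert a.k_clusters == b.k_clusters
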