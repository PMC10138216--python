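"""Synthetic IVF-stimulation cohorts with planted clinical and genetic effects.

The generator emulates the statistical structure the analysis pipeline
assumes: clinical marginals matching the study's baseline table (ages
~34.5 +/- 4.2 y, log-normal AMH truncated at the 15 ng/mL exclusion bound,
AFC correlated with AMH), a variant panel with the published allele
frequencies, block-structured linkage disequilibrium induced by founder
haplotype pools, structurally missing previous-stimulation fields (first
stimulations have no history), and an MII-oocyte count drawn from a
negative binomial whose log-mean is a linear model in AMH, AFC, age and
planted genetic features.  Ground truth (founder pools, causal variant
sets, coefficients) is returned alongside so recovery is testable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .cohort import Cohort, GenotypeMatrix, VariantDef, CLINICAL_COLUMNS
from .panel import DEFAULT_LD_BLOCKS, default_panel

__all__ = [
    "LDBlockSpec",
    "ClinicalParams",
    "GeneticEffect",
    "EffectSpec",
    "GeneratorConfig",
    "GroundTruth",
    "sample_genotypes_with_ld",
    "generate_cohort",
]


@dataclass
class LDBlockSpec:
    """A run of panel variants tied together by a founder-haplotype pool.

    ``target_dprime`` controls how often founder alleles are drawn from a
    shared latent uniform (comonotone draw -> complete LD) versus
    independently; 1.0 gives |D'| = 1 for every pair by construction.
    An explicit ``founders`` array (n_founders x n_variants, 0/1) overrides
    the pool construction entirely.
    """

    variant_ids: list[str]
    target_dprime: float = 0.95
    n_founders: int = 200
    founders: np.ndarray | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.target_dprime <= 1.0:
            raise ValueError("target_dprime must lie in [0, 1]")
        if self.n_founders < 2:
            raise ValueError("need at least two founder haplotypes")


@dataclass
class ClinicalParams:
    """Mean/SD (or distribution) parameters for the clinical covariates.

    Defaults reproduce the genotyped study group's baseline table.  AMH is
    log-normal truncated at ``amh_ceiling`` with a mild negative age trend
    on the log scale; AFC is negative-binomial with mean increasing in AMH.
    """

    age_mean: float = 34.55
    age_sd: float = 4.20
    age_range: tuple[int, int] = (18, 46)
    bmi_mean: float = 23.15
    bmi_sd: float = 4.11
    fsh_mean: float = 7.25
    fsh_sd: float = 3.53
    lh_mean: float = 6.10
    lh_sd: float = 4.63
    e2_mean: float = 16.62
    e2_sd: float = 16.73
    stim_days_mean: float = 9.77
    stim_days_sd: float = 3.10
    dose_mean: float = 2347.36
    dose_sd: float = 795.42
    amh_log_mu: float = 0.83
    amh_log_sd: float = 0.88
    amh_age_slope: float = -0.03  # per year on the log scale
    amh_ceiling: float = 15.0
    afc_base: float = 6.0
    afc_amh_slope: float = 2.2
    afc_nb_r: float = 3.0
    pcos_prevalence: float = 0.08


@dataclass
class GeneticEffect:
    """One planted genetic feature entering the outcome's log-mean.

    ``kind`` is ``"count"`` (number of member variants carried as
    alternative, the IV-CA / SOM-feature analogue) or ``"haplotype"``
    (binary: 1 iff every member variant is homozygous reference, the
    reduced-haplotype analogue).
    """

    name: str
    kind: str
    variant_ids: list[str]
    beta: float

    def __post_init__(self) -> None:
        if self.kind not in ("count", "haplotype"):
            raise ValueError(f"unknown genetic-effect kind {self.kind!r}")

    def evaluate(self, alt_presence: np.ndarray, col_index) -> np.ndarray:
        cols = [col_index[v] for v in self.variant_ids]
        sub = alt_presence[:, cols]
        if self.kind == "count":
            return sub.sum(axis=1)
        return (sub == 0).all(axis=1).astype(float)


@dataclass
class EffectSpec:
    """Coefficients of the MII outcome model (negative-binomial log link).

    log mu = beta0 + beta_amh*log(1+AMH) + beta_afc*(AFC - afc_ref)
           + beta_age*(age - age_ref) + sum_g beta_g * g.
    AFC and age are centred at the cohort's nominal means so beta0 sets
    the outcome scale directly; dispersion is the NB shape (variance
    mu + mu^2/dispersion).
    """

    beta0: float = 0.94
    beta_amh: float = 0.45
    beta_afc: float = 0.020
    beta_age: float = -0.010
    afc_ref: float = 13.41
    age_ref: float = 34.55
    dispersion: float = 6.0
    genetic: list[GeneticEffect] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.dispersion <= 0:
            raise ValueError("dispersion must be positive")


def default_genetic_effects() -> list[GeneticEffect]:
    """Planted effects mirroring the study's feature families: a count
    feature over the three CA variants and a protective all-reference
    haplotype over the PRLR block."""
    return [
        GeneticEffect(
            "planted_count", "count",
            ["rs11887058", "rs112461", "rs2207396"], beta=0.07,
        ),
        GeneticEffect(
            "planted_haplotype", "haplotype",
            DEFAULT_LD_BLOCKS["PRLR"], beta=0.15,
        ),
    ]


@dataclass
class GeneratorConfig:
    """Full recipe for one synthetic cohort; ``seed`` is mandatory."""

    seed: int
    n_patients: int = 264
    second_process_prob: float = 252 / 264  # expected 516 processes from 264 patients
    panel: list[VariantDef] = field(default_factory=default_panel)
    ld_blocks: list[LDBlockSpec] = field(
        default_factory=lambda: [
            LDBlockSpec(ids) for ids in DEFAULT_LD_BLOCKS.values()
        ]
    )
    clinical: ClinicalParams = field(default_factory=ClinicalParams)
    effects: EffectSpec = field(
        default_factory=lambda: EffectSpec(genetic=default_genetic_effects())
    )
    missing_afc_fraction: float = 0.10
    missing_genotype_fraction: float = 0.02

    def __post_init__(self) -> None:
        ids = [v.variant_id for v in self.panel]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate variant ids in panel")
        covered: set[str] = set()
        for block in self.ld_blocks:
            unknown = set(block.variant_ids) - set(ids)
            if unknown:
                raise ValueError(f"LD block names unknown variants: {sorted(unknown)}")
            if covered & set(block.variant_ids):
                raise ValueError("LD blocks must cover disjoint variant sets")
            covered |= set(block.variant_ids)
        for eff in self.effects.genetic:
            unknown = set(eff.variant_ids) - set(ids)
            if unknown:
                raise ValueError(
                    f"genetic effect {eff.name!r} names unknown variants: {sorted(unknown)}"
                )


@dataclass
class GroundTruth:
    """What was planted: founder pools, causal sets, coefficients."""

    effects: list[GeneticEffect]
    effect_spec: EffectSpec
    founders: dict[str, np.ndarray]  # block key -> n_founders x n_variants 0/1

    def to_json(self, path) -> None:
        payload = {
            "effects": [asdict(e) for e in self.effects],
            "effect_spec": {
                k: v for k, v in asdict(self.effect_spec).items() if k != "genetic"
            },
            "founders": {k: v.astype(int).tolist() for k, v in self.founders.items()},
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


def _founder_pool(freqs: np.ndarray, target_d: float, n: int, rng) -> np.ndarray:
    """Founder haplotypes whose allele marginals match ``freqs`` in
    expectation, with pairwise LD rising with ``target_d``.

    Each founder draws one shared latent uniform; every site copies it
    with probability ``target_d`` (comonotone -> allele = [u < freq]) and
    draws a fresh uniform otherwise.  target_d = 1 yields perfectly nested
    haplotypes, hence |D'| = 1 for all pairs.
    """
    pool = np.empty((n, len(freqs)))
    for i in range(n):
        u_shared = rng.uniform()
        use_shared = rng.uniform(size=len(freqs)) < target_d
        u = np.where(use_shared, u_shared, rng.uniform(size=len(freqs)))
        pool[i] = (u < freqs).astype(float)
    return pool


def sample_genotypes_with_ld(
    config: GeneratorConfig, n: int, rng=None
) -> tuple[GenotypeMatrix, dict[str, np.ndarray]]:
    """Draw ``n`` diploid genotype rows over the configured panel.

    Variants inside an LD block are generated by drawing two founder
    haplotypes per individual from the block's pool (dosage = sum);
    uncovered variants are independent binomial(2, freq) draws.  Returns
    the matrix and the founder pools actually used (keyed by the block's
    first variant id).
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    ids = [v.variant_id for v in config.panel]
    col = {vid: j for j, vid in enumerate(ids)}
    freqs = np.array(
        [v.alt_frequency if v.alt_frequency is not None else 0.2 for v in config.panel]
    )
    dosage = rng.binomial(2, freqs, size=(n, len(ids))).astype(float)

    founders: dict[str, np.ndarray] = {}
    for block in config.ld_blocks:
        cols = [col[v] for v in block.variant_ids]
        if block.founders is not None:
            pool = np.asarray(block.founders, dtype=float)
            if pool.shape[1] != len(cols):
                raise ValueError("founder pool width does not match block size")
        else:
            pool = _founder_pool(freqs[cols], block.target_dprime, block.n_founders, rng)
        founders[block.variant_ids[0]] = pool
        picks = rng.integers(0, len(pool), size=(n, 2))
        dosage[:, cols] = pool[picks[:, 0]] + pool[picks[:, 1]]
    return GenotypeMatrix([f"P{i:05d}" for i in range(n)], config.panel, dosage), founders


def _trunc_normal(rng, mean, sd, low, high, size):
    """Truncated normal by resampling (ranges used here reject < 20%)."""
    out = rng.normal(mean, sd, size=size)
    bad = (out < low) | (out > high)
    while bad.any():
        out[bad] = rng.normal(mean, sd, size=bad.sum())
        bad = (out < low) | (out > high)
    return out


def generate_cohort(config: GeneratorConfig) -> tuple[Cohort, GroundTruth]:
    """Generate a full cohort (clinical + genotypes + MII outcome).

    Patients contribute one or two stimulations; the second carries the
    first's oocyte counts as its previous-stimulation fields while first
    stimulations have those fields structurally missing.  The MII count is
    negative binomial with the log-linear mean of :class:`EffectSpec`.
    Identical seeds give byte-identical cohorts.
    """
    rng = np.random.default_rng(config.seed)
    cp, eff = config.clinical, config.effects

    n_pat = config.n_patients
    two = rng.uniform(size=n_pat) < config.second_process_prob
    n_proc = int(n_pat + two.sum())

    # patient-level draws
    age_p = np.clip(
        np.round(_trunc_normal(rng, cp.age_mean, cp.age_sd, *cp.age_range, size=n_pat)),
        *cp.age_range,
    )
    log_amh = rng.normal(
        cp.amh_log_mu + cp.amh_age_slope * (age_p - eff.age_ref), cp.amh_log_sd
    )
    amh_p = np.exp(log_amh)
    over = amh_p > cp.amh_ceiling
    while over.any():  # truncation at the exclusion bound, by resampling
        amh_p[over] = np.exp(
            rng.normal(
                cp.amh_log_mu + cp.amh_age_slope * (age_p[over] - eff.age_ref),
                cp.amh_log_sd,
            )
        )
        over = amh_p > cp.amh_ceiling
    pcos_p = rng.uniform(size=n_pat) < cp.pcos_prevalence
    bmi_p = _trunc_normal(rng, cp.bmi_mean, cp.bmi_sd, 15.0, 45.0, size=n_pat)

    genotypes, founders = sample_genotypes_with_ld(config, n_pat, rng)
    ap_pat = genotypes.alt_presence()
    col = {vid: j for j, vid in enumerate(genotypes.variant_ids)}
    genetic_term_p = np.zeros(n_pat)
    for g in eff.genetic:
        genetic_term_p += g.beta * g.evaluate(ap_pat, col)

    # process-level assembly
    rows = []
    pat_of_proc = []
    for i in range(n_pat):
        k = 2 if two[i] else 1
        for j in range(k):
            pat_of_proc.append(i)
            rows.append((i, j))
    pat_of_proc = np.asarray(pat_of_proc)
    second = np.asarray([j == 1 for _, j in rows])

    afc = rng.negative_binomial(
        cp.afc_nb_r,
        cp.afc_nb_r / (cp.afc_nb_r + cp.afc_base + cp.afc_amh_slope * amh_p[pat_of_proc]),
        size=n_proc,
    ).astype(float)
    fsh = _trunc_normal(rng, cp.fsh_mean, cp.fsh_sd, 0.1, np.inf, size=n_proc)
    lh = _trunc_normal(rng, cp.lh_mean, cp.lh_sd, 0.1, np.inf, size=n_proc)
    e2 = _trunc_normal(rng, cp.e2_mean, cp.e2_sd, 0.5, np.inf, size=n_proc)
    stim = np.round(_trunc_normal(rng, cp.stim_days_mean, cp.stim_days_sd, 3, 21, size=n_proc))
    dose = _trunc_normal(rng, cp.dose_mean, cp.dose_sd, 300, np.inf, size=n_proc)

    age = age_p[pat_of_proc] + second  # second stimulation ~a year later
    amh = amh_p[pat_of_proc]

    linpred = (
        eff.beta0
        + eff.beta_amh * np.log1p(amh)
        + eff.beta_afc * (afc - eff.afc_ref)
        + eff.beta_age * (age - eff.age_ref)
        + genetic_term_p[pat_of_proc]
    )
    if not np.isfinite(linpred).all():
        raise ValueError("non-finite linear predictor; check effect coefficients")
    mu = np.exp(linpred)
    theta = eff.dispersion
    mii = rng.negative_binomial(theta, theta / (theta + mu), size=n_proc)
    denuded = mii + rng.poisson(1.75, size=n_proc)

    # previous-stimulation history: second processes inherit the first's counts
    prev_mii = np.full(n_proc, np.nan)
    prev_den = np.full(n_proc, np.nan)
    first_proc_of_patient = {}
    for k, (i, j) in enumerate(rows):
        if j == 0:
            first_proc_of_patient[i] = k
        else:
            prev_mii[k] = mii[first_proc_of_patient[i]]
            prev_den[k] = denuded[first_proc_of_patient[i]]

    afc_obs = afc.copy()
    afc_obs[rng.uniform(size=n_proc) < config.missing_afc_fraction] = np.nan

    process_ids = [f"S{i:04d}-{j + 1}" for i, j in rows]
    clinical = pd.DataFrame(
        {
            "patient_id": [f"PT{i:04d}" for i in pat_of_proc],
            "age": age,
            "bmi": bmi_p[pat_of_proc],
            "amh": amh,
            "fsh": fsh,
            "lh": lh,
            "e2": e2,
            "afc_day1": afc_obs,
            "pcos": pcos_p[pat_of_proc],
            "prev_mii": prev_mii,
            "prev_denuded": prev_den,
            "stim_days": stim,
            "gonadotropin_dose": dose,
            "mii_count": mii,
            "denuded_count": denuded.astype(float),
        },
        index=pd.Index(process_ids, name="process_id"),
    )[CLINICAL_COLUMNS]

    proc_dosage = genotypes.dosage[pat_of_proc].copy()
    if config.missing_genotype_fraction > 0:
        mask = rng.uniform(size=proc_dosage.shape) < config.missing_genotype_fraction
        proc_dosage[mask] = np.nan
    proc_geno = GenotypeMatrix(process_ids, config.panel, proc_dosage)

    cohort = Cohort(clinical=clinical, genotypes=proc_geno)
    truth = GroundTruth(effects=list(eff.genetic), effect_spec=eff, founders=founders)
    return cohort, truth
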