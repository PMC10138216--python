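"""Linkage disequilibrium, haplotype blocks and reduced binary haplotype features.

Pairwise LD (D', r2) is estimated from unphased dosages with the
two-locus EM algorithm; blocks are detected per chromosome with the three
classical rules (D'-confidence intervals, four-gamete, solid spine of
LD); block haplotypes above a frequency floor are screened as binary
carrier features against the predictive model; and large blocks are
reduced to a small root-to-leaf variant path via embedding + clustering +
a decision tree, giving the binary reduced-haplotype feature (1 iff every
path variant matches its baseline allele state).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import product

import numpy as np
import pandas as pd

from .cohort import GenotypeMatrix

__all__ = [
    "LDStats",
    "HaploBlock",
    "ReducedHaplotype",
    "BlockParams",
    "ReductionConfig",
    "estimate_two_locus_ld",
    "block_haplotype_frequencies",
    "detect_blocks",
    "screen_haplotypes",
    "reduce_haplotype",
    "evaluate_reduced_haplotype",
]


# ---------------------------------------------------------------------------
# two-locus EM


@dataclass
class LDStats:
    variant_a: str
    variant_b: str
    hap_freqs: dict[str, float]  # '00', '01', '10', '11' (ref=0, alt=1)
    D: float
    d_prime: float
    r2: float
    n_chromosomes: int
    em_iterations: int
    converged: bool
    defined: bool = True


def _em_two_locus(dos_a: np.ndarray, dos_b: np.ndarray, tol=1e-6, max_iter=1000):
    """EM haplotype frequencies for two loci from unphased dosages.

    Only the double heterozygote is phase-ambiguous; every other genotype
    cell contributes known gamete counts.  Returns (freqs[2,2], iters,
    converged, n_chromosomes); freqs indexed [allele_a, allele_b].
    """
    ok = ~(np.isnan(dos_a) | np.isnan(dos_b))
    a, b = dos_a[ok].astype(int), dos_b[ok].astype(int)
    n_ind = len(a)
    cells = np.zeros((3, 3))
    for ga, gb in zip(a, b):
        cells[ga, gb] += 1
    # known gamete counts: individual (ga, gb) with not both het contributes
    # haplotypes deterministically
    counts = np.zeros((2, 2))
    for ga in range(3):
        for gb in range(3):
            n = cells[ga, gb]
            if n == 0 or (ga == 1 and gb == 1):
                continue
            # expand genotype into the two constituent haplotypes
            av = [0, 0] if ga == 0 else [1, 1] if ga == 2 else [0, 1]
            bv = [0, 0] if gb == 0 else [1, 1] if gb == 2 else [0, 1]
            if ga == 1:
                # one chromosome carries the alt of locus a; locus b homozygous
                counts[0, bv[0]] += n
                counts[1, bv[1]] += n
            elif gb == 1:
                counts[av[0], 0] += n
                counts[av[1], 1] += n
            else:
                counts[av[0], bv[0]] += 2 * n
    n_dh = cells[1, 1]
    total = 2 * n_ind
    pa = (a.sum()) / total if total else 0.0
    pb = (b.sum()) / total if total else 0.0
    f = np.array([[(1 - pa) * (1 - pb), (1 - pa) * pb], [pa * (1 - pb), pa * pb]])
    f = np.clip(f, 1e-12, None)
    f /= f.sum()
    it, converged = 0, True
    if n_dh > 0:
        converged = False
        for it in range(1, max_iter + 1):
            w = f[1, 1] * f[0, 0] / (f[1, 1] * f[0, 0] + f[1, 0] * f[0, 1] + 1e-300)
            new = counts.copy()
            new[1, 1] += n_dh * w
            new[0, 0] += n_dh * w
            new[1, 0] += n_dh * (1 - w)
            new[0, 1] += n_dh * (1 - w)
            new /= total
            if np.abs(new - f).max() < tol:
                f = new
                converged = True
                break
            f = new
    else:
        f = counts / total if total else f
    return f, it, converged, total


def estimate_two_locus_ld(
    genotypes: GenotypeMatrix, pair: tuple[str, str]
) -> LDStats:
    """D, |D'| and r2 for one variant pair via the two-locus EM.

    Monomorphic members make LD undefined (flagged, not raised).  |D'| is
    invariant to swapping allele labels at either locus.
    """
    ia, ib = genotypes.index_of(pair[0]), genotypes.index_of(pair[1])
    f, it, conv, n_chr = _em_two_locus(
        genotypes.dosage[:, ia], genotypes.dosage[:, ib]
    )
    pa, pb = f[1].sum(), f[:, 1].sum()
    hap = {"00": f[0, 0], "01": f[0, 1], "10": f[1, 0], "11": f[1, 1]}
    if pa in (0.0, 1.0) or pb in (0.0, 1.0):
        return LDStats(pair[0], pair[1], hap, 0.0, np.nan, np.nan, n_chr, it, conv,
                       defined=False)
    D = f[1, 1] - pa * pb
    if D >= 0:
        dmax = min(pa * (1 - pb), (1 - pa) * pb)
    else:
        dmax = min(pa * pb, (1 - pa) * (1 - pb))
    d_prime = abs(D) / dmax if dmax > 0 else np.nan
    r2 = D**2 / (pa * (1 - pa) * pb * (1 - pb))
    return LDStats(pair[0], pair[1], hap, float(D), float(d_prime), float(r2),
                   n_chr, it, conv)


def _dprime_ci(genotypes, ia, ib, grid=101):
    """Likelihood-based two-sided 90% interval for |D'|.

    Allele frequencies are fixed at their MLEs; the genotype-data
    likelihood is evaluated on a |D'| grid (signed toward the point
    estimate), normalized, and the 5th/95th percentiles of the resulting
    distribution are returned.
    """
    dos_a, dos_b = genotypes.dosage[:, ia], genotypes.dosage[:, ib]
    ok = ~(np.isnan(dos_a) | np.isnan(dos_b))
    a, b = dos_a[ok].astype(int), dos_b[ok].astype(int)
    if len(a) == 0:
        return np.nan, np.nan
    pa, pb = a.mean() / 2, b.mean() / 2
    if pa in (0.0, 1.0) or pb in (0.0, 1.0):
        return np.nan, np.nan
    f_hat, *_ = _em_two_locus(dos_a, dos_b)
    D_hat = f_hat[1, 1] - f_hat[1].sum() * f_hat[:, 1].sum()
    sign = 1.0 if D_hat >= 0 else -1.0
    if sign > 0:
        dmax = min(pa * (1 - pb), (1 - pa) * pb)
    else:
        dmax = min(pa * pb, (1 - pa) * (1 - pb))
    if dmax <= 0:
        return np.nan, np.nan
    dp_grid = np.linspace(0, 1, grid)
    loglik = np.full(grid, -np.inf)
    cells = np.zeros((3, 3))
    for ga, gb in zip(a, b):
        cells[ga, gb] += 1
    for k, dp in enumerate(dp_grid):
        D = sign * dp * dmax
        f11 = pa * pb + D
        f10 = pa * (1 - pb) - D
        f01 = (1 - pa) * pb - D
        f00 = (1 - pa) * (1 - pb) + D
        fr = np.clip(np.array([[f00, f01], [f10, f11]]), 1e-12, None)
        # genotype probabilities under random mating
        ll = 0.0
        for ga in range(3):
            for gb in range(3):
                n = cells[ga, gb]
                if n == 0:
                    continue
                pav = [(0, 0)] if ga == 0 else [(1, 1)] if ga == 2 else [(0, 1), (1, 0)]
                pbv = [(0, 0)] if gb == 0 else [(1, 1)] if gb == 2 else [(0, 1), (1, 0)]
                prob = 0.0
                for (a1, a2) in pav:
                    for (b1, b2) in pbv:
                        prob += fr[a1, b1] * fr[a2, b2]
                ll += n * np.log(prob)
        loglik[k] = ll
    lik = np.exp(loglik - loglik.max())
    cdf = np.cumsum(lik) / lik.sum()
    lo = dp_grid[np.searchsorted(cdf, 0.05)]
    hi = dp_grid[min(np.searchsorted(cdf, 0.95), grid - 1)]
    return float(lo), float(hi)


# ---------------------------------------------------------------------------
# block detection


@dataclass
class BlockParams:
    """Thresholds of the three block rules (Haploview-style defaults)."""

    maf_floor: float = 0.05
    four_gamete_floor: float = 0.01  # all four haplotypes above -> recombination
    ci_strong_low: float = 0.70
    ci_strong_high: float = 0.98
    ci_recomb_high: float = 0.90
    ci_strong_fraction: float = 0.95
    spine_dprime: float = 0.80
    hap_freq_floor: float = 0.01  # reporting floor for per-block haplotypes


@dataclass
class HaploBlock:
    method: str
    chrom: str
    variant_ids: list[str]
    haplotypes: pd.DataFrame = field(default_factory=pd.DataFrame)
    # columns: haplotype (0/1 string), frequency

    def __len__(self) -> int:
        return len(self.variant_ids)


def _phase_expansions(row: np.ndarray):
    """All ordered (hap1, hap2) resolutions of one unphased dosage vector."""
    het = np.nonzero(row == 1)[0]
    base1 = (row == 2).astype(int)
    base2 = base1.copy()
    out = []
    for bits in product((0, 1), repeat=len(het)):
        h1, h2 = base1.copy(), base2.copy()
        for pos, bit in zip(het, bits):
            h1[pos], h2[pos] = bit, 1 - bit
        out.append((tuple(h1), tuple(h2)))
    return out


def _em_multilocus(dosage: np.ndarray, tol=1e-8, max_iter=500, max_expand_het=16):
    """EM haplotype frequencies for one block from complete-data rows."""
    rows = dosage[~np.isnan(dosage).any(axis=1)].astype(int)
    if len(rows) == 0:
        return {}
    expansions = []
    haps: set[tuple] = set()
    for r in rows:
        if (r == 1).sum() > max_expand_het:
            raise ValueError("row too heterozygous for exhaustive phase expansion")
        exp = _phase_expansions(r)
        expansions.append(exp)
        for h1, h2 in exp:
            haps.add(h1)
            haps.add(h2)
    haps = sorted(haps)
    idx = {h: i for i, h in enumerate(haps)}
    f = np.full(len(haps), 1.0 / len(haps))
    n_chr = 2 * len(rows)
    for _ in range(max_iter):
        new = np.zeros_like(f)
        for exp in expansions:
            w = np.array([f[idx[h1]] * f[idx[h2]] for h1, h2 in exp])
            s = w.sum()
            if s <= 0:
                w = np.full(len(exp), 1.0 / len(exp))
            else:
                w /= s
            for (h1, h2), wk in zip(exp, w):
                new[idx[h1]] += wk
                new[idx[h2]] += wk
        new /= n_chr
        if np.abs(new - f).max() < tol:
            f = new
            break
        f = new
    return {h: float(fr) for h, fr in zip(haps, f) if fr > 1e-9}


def block_haplotype_frequencies(
    genotypes: GenotypeMatrix,
    variant_ids: list[str],
    freq_floor: float = 0.01,
    max_exhaustive: int = 12,
) -> pd.DataFrame:
    """EM haplotype spectrum of one block (exhaustive up to
    ``max_exhaustive`` variants, partition-ligation beyond).

    Partition-ligation splits the block in half, solves each side, keeps
    the 20 most frequent side-haplotypes and runs EM over their cross
    products restricted to phase-compatible rows.
    """
    cols = [genotypes.index_of(v) for v in variant_ids]
    dos = genotypes.dosage[:, cols]
    if len(variant_ids) <= max_exhaustive:
        freqs = _em_multilocus(dos)
    else:
        freqs = _partition_ligation(dos, max_exhaustive)
    table = pd.DataFrame(
        {
            "haplotype": ["".join(map(str, h)) for h in freqs],
            "frequency": list(freqs.values()),
        }
    ).sort_values("frequency", ascending=False, kind="mergesort")
    return table[table["frequency"] >= freq_floor].reset_index(drop=True)


def _partition_ligation(dos: np.ndarray, max_exhaustive: int, keep=20):
    half = dos.shape[1] // 2
    left = (
        _em_multilocus(dos[:, :half])
        if half <= max_exhaustive
        else _partition_ligation(dos[:, :half], max_exhaustive, keep)
    )
    right = (
        _em_multilocus(dos[:, half:])
        if dos.shape[1] - half <= max_exhaustive
        else _partition_ligation(dos[:, half:], max_exhaustive, keep)
    )
    top_l = sorted(left, key=left.get, reverse=True)[:keep]
    top_r = sorted(right, key=right.get, reverse=True)[:keep]
    cands = [l + r for l in top_l for r in top_r]
    idx = {h: i for i, h in enumerate(cands)}
    f = np.array([left[l] * right[r] for l in top_l for r in top_r])
    f = np.clip(f, 1e-12, None)
    f /= f.sum()
    rows = dos[~np.isnan(dos).any(axis=1)].astype(int)
    compat = []
    for r in rows:
        pairs = [
            (idx[h1], idx[h2])
            for h1 in cands
            for h2 in cands
            if all(h1[k] + h2[k] == r[k] for k in range(len(r)))
        ]
        if pairs:
            compat.append(pairs)
    if not compat:
        return dict(zip(cands, f))
    n_chr = 2 * len(compat)
    for _ in range(200):
        new = np.zeros_like(f)
        for pairs in compat:
            w = np.array([f[i] * f[j] for i, j in pairs])
            s = w.sum()
            w = w / s if s > 0 else np.full(len(pairs), 1 / len(pairs))
            for (i, j), wk in zip(pairs, w):
                new[i] += wk
                new[j] += wk
        new /= n_chr
        if np.abs(new - f).max() < 1e-8:
            f = new
            break
        f = new
    return {h: float(fr) for h, fr in zip(cands, f) if fr > 1e-9}


def _is_recombinant_pair(genotypes, ia_vid, ib_vid, floor):
    stats = estimate_two_locus_ld(genotypes, (ia_vid, ib_vid))
    if not stats.defined:
        return False
    return all(v >= floor for v in stats.hap_freqs.values())


def detect_blocks(
    genotypes: GenotypeMatrix,
    method: str = "four-gamete",
    params: BlockParams | None = None,
) -> list[HaploBlock]:
    """Partition each chromosome's variants into haplotype blocks.

    Methods: ``four-gamete`` (a pair shows recombination when all four
    EM haplotype frequencies exceed the floor; blocks are maximal runs
    with no recombinant internal pair), ``solid-spine`` (maximal runs
    whose first and last variant each have |D'| >= threshold with every
    variant between them, and with each other), and
    ``confidence-intervals`` (Gabriel-style: a pair is in strong LD when
    its |D'| CI lies above (0.70, 0.98); candidate spans where at least
    95% of informative pairs are strong are accepted longest-first).
    Variants below the MAF floor are excluded; uncovered variants come
    back as singleton blocks.  Input must be position-sorted per
    chromosome.
    """
    if params is None:
        params = BlockParams()
    if method not in ("four-gamete", "solid-spine", "confidence-intervals"):
        raise ValueError(f"unknown block method {method!r}")

    by_chrom: dict[str, list[int]] = {}
    for j, v in enumerate(genotypes.variants):
        by_chrom.setdefault(v.chrom, []).append(j)
    blocks: list[HaploBlock] = []
    ap = genotypes.alt_presence()
    for chrom, idxs in sorted(by_chrom.items()):
        pos = [genotypes.variants[j].pos for j in idxs]
        if pos != sorted(pos):
            raise ValueError(f"variants on {chrom} are not position-sorted")
        # MAF filter on allele (dosage) frequency
        kept = []
        for j in idxs:
            d = genotypes.dosage[:, j]
            p = np.nanmean(d) / 2 if np.isfinite(np.nanmean(d)) else 0.0
            if min(p, 1 - p) >= params.maf_floor:
                kept.append(j)
        if not kept:
            continue
        vids = [genotypes.variants[j].variant_id for j in kept]
        runs = _detect_runs(genotypes, vids, method, params)
        for run in runs:
            haps = (
                block_haplotype_frequencies(genotypes, run, params.hap_freq_floor)
                if len(run) > 1
                else _single_variant_haps(ap, genotypes, run[0], params.hap_freq_floor)
            )
            blocks.append(HaploBlock(method, chrom, run, haps))
    return blocks


def _single_variant_haps(ap, genotypes, vid, floor):
    j = genotypes.index_of(vid)
    d = genotypes.dosage[:, j]
    p = float(np.nanmean(d) / 2)
    table = pd.DataFrame(
        {"haplotype": ["1", "0"], "frequency": [p, 1 - p]}
    ).sort_values("frequency", ascending=False, kind="mergesort")
    return table[table["frequency"] >= floor].reset_index(drop=True)


def _detect_runs(genotypes, vids, method, params):
    n = len(vids)
    if method == "four-gamete":
        recomb = {}

        def is_ok(i, j):
            if (i, j) not in recomb:
                recomb[(i, j)] = _is_recombinant_pair(
                    genotypes, vids[i], vids[j], params.four_gamete_floor
                )
            return not recomb[(i, j)]

        runs, i = [], 0
        while i < n:
            j = i
            while j + 1 < n and all(is_ok(k, j + 1) for k in range(i, j + 1)):
                j += 1
            runs.append(vids[i : j + 1])
            i = j + 1
        return runs

    dp = {}

    def dprime(i, j):
        if (i, j) not in dp:
            dp[(i, j)] = estimate_two_locus_ld(genotypes, (vids[i], vids[j])).d_prime
        v = dp[(i, j)]
        return -1.0 if v is None or np.isnan(v) else v

    if method == "solid-spine":
        runs, i = [], 0
        while i < n:
            j = i
            while j + 1 < n:
                jj = j + 1
                ok = dprime(i, jj) >= params.spine_dprime and all(
                    dprime(i, k) >= params.spine_dprime
                    and dprime(k, jj) >= params.spine_dprime
                    for k in range(i + 1, jj)
                )
                if ok:
                    j = jj
                else:
                    break
            runs.append(vids[i : j + 1])
            i = j + 1
        return runs

    # confidence intervals (Gabriel-style)
    ci = {}

    def bounds(i, j):
        if (i, j) not in ci:
            ci[(i, j)] = _dprime_ci(
                genotypes, genotypes.index_of(vids[i]), genotypes.index_of(vids[j])
            )
        return ci[(i, j)]

    def classify(i, j):
        lo, hi = bounds(i, j)
        if np.isnan(lo):
            return "uninformative"
        if lo >= params.ci_strong_low and hi >= params.ci_strong_high:
            return "strong"
        if hi < params.ci_recomb_high:
            return "recomb"
        return "uninformative"

    spans = sorted(
        ((i, j) for i in range(n) for j in range(i + 1, n)),
        key=lambda s: (-(s[1] - s[0]), s[0]),
    )
    taken = np.zeros(n, dtype=bool)
    runs = []
    for i, j in spans:
        if taken[i : j + 1].any():
            continue
        kinds = [classify(a, b) for a in range(i, j + 1) for b in range(a + 1, j + 1)]
        informative = [k for k in kinds if k != "uninformative"]
        if not informative:
            continue
        strong = sum(k == "strong" for k in informative)
        if classify(i, j) == "strong" and strong / len(informative) >= params.ci_strong_fraction:
            runs.append((i, j))
            taken[i : j + 1] = True
    for i in range(n):
        if not taken[i]:
            runs.append((i, i))
    runs.sort()
    return [vids[i : j + 1] for i, j in runs]


# ---------------------------------------------------------------------------
# haplotype screening and reduction


def screen_haplotypes(
    blocks: list[HaploBlock],
    genotypes: GenotypeMatrix,
    model_eval_callback,
    baseline_rmse: float,
    freq_floor: float = 0.05,
) -> pd.DataFrame:
    """Rank block haplotypes by the RMSE of a model including each one.

    Every haplotype of every multi-variant block with EM frequency at or
    above ``freq_floor`` becomes a binary candidate feature (a process
    carries it iff its alt-presence vector over the block equals the
    haplotype's allele pattern, missing propagated).
    ``model_eval_callback(feature_series) -> cross-validated RMSE`` must
    use fixed folds.  Candidates are ranked by RMSE (ascending); the
    ``rmse_reduction`` column is relative to ``baseline_rmse``.
    """
    records = []
    for bi, block in enumerate(blocks):
        if len(block) < 2:
            continue
        cols = [genotypes.index_of(v) for v in block.variant_ids]
        ap = genotypes.alt_presence()[:, cols]
        for _, row in block.haplotypes.iterrows():
            if row["frequency"] < freq_floor:
                continue
            pattern = np.array([int(ch) for ch in row["haplotype"]], dtype=float)
            match = (ap == pattern).all(axis=1).astype(float)
            match[np.isnan(ap).any(axis=1)] = np.nan
            feat = pd.Series(
                match, index=genotypes.process_ids,
                name=f"{block.method}:{block.chrom}:{bi}:{row['haplotype']}",
            )
            rmse = float(model_eval_callback(feat))
            records.append(
                {
                    "block": bi,
                    "method": block.method,
                    "chrom": block.chrom,
                    "variant_ids": tuple(block.variant_ids),
                    "haplotype": row["haplotype"],
                    "frequency": row["frequency"],
                    "rmse": rmse,
                    "rmse_reduction": baseline_rmse - rmse,
                }
            )
    out = pd.DataFrame(records)
    if out.empty:
        warnings.warn("no candidate haplotype above the frequency floor", stacklevel=2)
        return out
    out = out.sort_values(
        ["rmse", "frequency"], ascending=[True, False], kind="mergesort"
    ).reset_index(drop=True)
    if (out["rmse_reduction"] <= 0).all():
        warnings.warn("no candidate haplotype reduces the RMSE", stacklevel=2)
    return out


@dataclass
class ReductionConfig:
    umap_neighbors: int = 15
    umap_min_dist: float = 0.1
    k_range: tuple[int, int] = (2, 10)
    seed: int = 0


@dataclass
class ReducedHaplotype:
    """Binary feature: 1 iff every path variant matches its baseline state."""

    name: str
    baseline: dict[str, int]  # variant_id -> required alt-presence state
    frequency: float  # empirical share of value 1 on the defining cohort
    k_clusters: int = 0
    largest_cluster_size: int = 0

    @property
    def variant_ids(self) -> list[str]:
        return list(self.baseline)


def reduce_haplotype(
    block_variants: list[str],
    genotypes: GenotypeMatrix,
    config: ReductionConfig | None = None,
    name: str = "reduced",
) -> ReducedHaplotype:
    """Shrink a block to the decision-path variants of its dominant group.

    Alt-presence vectors over the block are embedded in 2-D (UMAP,
    Hamming metric, fixed seed), clustered with K-means (k chosen by
    silhouette over ``k_range``), and a decision tree grown to purity
    predicts the cluster labels from the variants.  The root-to-leaf path
    reaching the leaf that captures the most members of the largest
    cluster defines the reduced haplotype; each path variant's required
    state is the branch taken (0 = reference, 1 = alternative).  If the
    embedding is degenerate (all rows identical) the original block with
    its modal states is kept.
    """
    if config is None:
        config = ReductionConfig()
    if len(block_variants) < 2:
        raise ValueError("reduction needs a block of at least two variants")
    cols = [genotypes.index_of(v) for v in block_variants]
    ap_raw = genotypes.alt_presence()[:, cols]
    X = np.nan_to_num(ap_raw, nan=0.0)

    distinct = np.unique(X, axis=0)
    if len(distinct) == 1:
        warnings.warn("degenerate block (all rows identical); keeping full block",
                      stacklevel=2)
        modal = {v: int(X[0, k]) for k, v in enumerate(block_variants)}
        return _finalize_reduced(name, modal, ap_raw, block_variants, 1, len(X))

    import umap  # heavy import (numba); deferred

    n_neighbors = min(config.umap_neighbors, len(X) - 1)
    emb = umap.UMAP(
        n_neighbors=n_neighbors,
        min_dist=config.umap_min_dist,
        metric="hamming",
        random_state=config.seed,
        n_jobs=1,
    ).fit_transform(X)

    from sklearn.cluster import KMeans
    from sklearn.metrics import silhouette_score
    from sklearn.tree import DecisionTreeClassifier

    k_lo, k_hi = config.k_range
    k_hi = min(k_hi, len(distinct), len(X) - 1)
    best_k, best_s, best_labels = None, -np.inf, None
    for k in range(k_lo, k_hi + 1):
        km = KMeans(n_clusters=k, random_state=config.seed, n_init=10).fit(emb)
        if len(np.unique(km.labels_)) < 2:
            continue
        s = silhouette_score(emb, km.labels_)
        if s > best_s:
            best_k, best_s, best_labels = k, s, km.labels_
    if best_labels is None:
        warnings.warn("clustering failed; keeping full block", stacklevel=2)
        modal = {
            v: int(np.round(np.nanmean(X[:, k]))) for k, v in enumerate(block_variants)
        }
        return _finalize_reduced(name, modal, ap_raw, block_variants, 1, len(X))

    tree = DecisionTreeClassifier(random_state=config.seed).fit(X, best_labels)
    largest = int(np.bincount(best_labels).argmax())
    path_states = _largest_cluster_path(tree.tree_, X, best_labels, largest)
    baseline = {block_variants[f]: s for f, s in path_states}
    if not baseline:  # root is already pure: single cluster dominates every split
        modal = {
            v: int(np.round(X[:, k].mean())) for k, v in enumerate(block_variants)
        }
        baseline = modal
    largest_size = int((best_labels == largest).sum())
    return _finalize_reduced(
        name, baseline, ap_raw, block_variants, best_k, largest_size
    )


def _largest_cluster_path(t, X, labels, largest):
    """Feature/state pairs on the root-to-leaf path of the leaf holding the
    most members of the target cluster."""
    # leaf assignment per sample
    node_of = np.zeros(len(X), dtype=int)
    # walk samples down the tree
    for i, x in enumerate(X):
        node = 0
        while t.children_left[node] != -1:
            f = t.feature[node]
            node = (
                t.children_left[node]
                if x[f] <= t.threshold[node]
                else t.children_right[node]
            )
        node_of[i] = node
    leaves = np.unique(node_of)
    counts = {
        leaf: int(((node_of == leaf) & (labels == largest)).sum()) for leaf in leaves
    }
    target_leaf = max(sorted(counts), key=lambda leaf: counts[leaf])
    # recover the path from the root
    path = []
    node = 0
    while t.children_left[node] != -1:
        f = int(t.feature[node])
        left = t.children_left[node]
        # does the target leaf live in the left subtree?
        if _subtree_contains(t, left, target_leaf):
            path.append((f, 0))  # x[f] <= 0.5 -> reference state
            node = left
        else:
            path.append((f, 1))
            node = t.children_right[node]
    # a feature may be split twice on the path; keep the final state
    return list({f: s for f, s in path}.items())


def _subtree_contains(t, node, target):
    if node == target:
        return True
    if t.children_left[node] == -1:
        return False
    return _subtree_contains(t, t.children_left[node], target) or _subtree_contains(
        t, t.children_right[node], target
    )


def _finalize_reduced(name, baseline, ap_raw, block_variants, k, largest_size):
    col = {v: k for k, v in enumerate(block_variants)}
    states = np.array([baseline[v] for v in baseline], dtype=float)
    cols = [col[v] for v in baseline]
    sub = ap_raw[:, cols]
    match = (sub == states).all(axis=1).astype(float)
    match[np.isnan(sub).any(axis=1)] = np.nan
    freq = float(np.nanmean(match)) if np.isfinite(match).any() else np.nan
    return ReducedHaplotype(name, dict(baseline), freq, k, largest_size)


def evaluate_reduced_haplotype(
    feature: ReducedHaplotype, genotypes: GenotypeMatrix
) -> pd.Series:
    """Binary indicator per process; missing path genotypes propagate."""
    cols = [genotypes.index_of(v) for v in feature.baseline]
    states = np.array(list(feature.baseline.values()), dtype=float)
    sub = genotypes.alt_presence()[:, cols]
    match = (sub == states).all(axis=1).astype(float)
    match[np.isnan(sub).any(axis=1)] = np.nan
    return pd.Series(match, index=genotypes.process_ids, name=feature.name)
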