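"""Self-organizing map over genotype vectors and the standardized count feature.

A 6x6 hexagonal SOM is trained online on binary alt-presence vectors; map
nodes where a high- or low-yield MII group is over-represented yield the
node's most characteristic variants (largest alt-frequency excess over
the population), and an exhaustive subset search over those candidates
picks the variant set whose standardized carrier count most improves the
predictive model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

from .cohort import GenotypeMatrix, MIIGroupPartition

__all__ = [
    "SomConfig",
    "SomModel",
    "NodeEnrichment",
    "StandardizedCountFeature",
    "train_som",
    "node_enrichment",
    "subset_search",
    "build_standardized_feature",
    "evaluate_standardized_feature",
]


@dataclass
class SomConfig:
    """Training hyperparameters (defaults are the study's settings)."""

    grid: tuple[int, int] = (6, 6)
    topology: str = "hexagonal"
    sigma: float = 1.5
    learning_rate: float = 0.7
    n_iterations: int = 100_000
    metric: str = "manhattan"
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.grid) < 1 or self.sigma <= 0 or self.n_iterations < 1:
            raise ValueError("invalid SOM configuration")
        if self.topology not in ("hexagonal", "rectangular"):
            raise ValueError(f"unknown topology {self.topology!r}")
        if self.metric not in ("manhattan", "euclidean"):
            raise ValueError(f"unknown metric {self.metric!r}")


def _grid_distances(nx: int, ny: int, topology: str) -> np.ndarray:
    """Pairwise node distances on the map lattice.

    Hexagonal grids use odd-r offset -> axial coordinates, with the
    standard hex distance (|dq| + |dr| + |dq+dr|) / 2; rectangular grids
    use Euclidean distance on the integer lattice.
    """
    coords = [(i, j) for i in range(nx) for j in range(ny)]
    n = len(coords)
    D = np.zeros((n, n))
    if topology == "hexagonal":
        # odd-r horizontal layout: row r, col c -> axial (q, r)
        axial = [(c - (r - (r & 1)) // 2, r) for r, c in coords]
        for a in range(n):
            qa, ra = axial[a]
            for b in range(a + 1, n):
                qb, rb = axial[b]
                dq, dr = qa - qb, ra - rb
                D[a, b] = D[b, a] = (abs(dq) + abs(dr) + abs(dq + dr)) / 2
    else:
        arr = np.asarray(coords, dtype=float)
        diff = arr[:, None, :] - arr[None, :, :]
        D = np.sqrt((diff**2).sum(-1))
    return D


@dataclass
class SomModel:
    """Trained map: one weight vector per node plus fit diagnostics."""

    weights: np.ndarray  # (n_nodes, n_features)
    config: SomConfig
    node_coords: list[tuple[int, int]]
    bmus: np.ndarray  # best matching unit index per training observation
    quantization_error: float

    def _distances_to_nodes(self, X: np.ndarray) -> np.ndarray:
        if self.config.metric == "manhattan":
            return np.abs(X[:, None, :] - self.weights[None, :, :]).sum(-1)
        return np.sqrt(((X[:, None, :] - self.weights[None, :, :]) ** 2).sum(-1))

    def bmu(self, X: np.ndarray) -> np.ndarray:
        """Index of the nearest node for each row of X."""
        return self._distances_to_nodes(np.asarray(X, dtype=float)).argmin(axis=1)

    def quantization(self, X: np.ndarray) -> float:
        """Mean distance of observations to their best matching units."""
        d = self._distances_to_nodes(np.asarray(X, dtype=float))
        return float(d.min(axis=1).mean())


def train_som(genotypes, config: SomConfig | None = None) -> SomModel:
    """Online SOM training on alt-presence vectors.

    ``genotypes`` may be a :class:`GenotypeMatrix` (its alt-presence view
    is used, missing imputed to 0 for map training only) or a plain
    array.  Per iteration one observation is drawn at random, its BMU
    found under the configured metric, and all node weights moved toward
    it with a Gaussian neighborhood over lattice distance; learning rate
    and neighborhood width decay linearly over the iteration budget.
    Fixed seed gives identical weights.
    """
    if config is None:
        config = SomConfig()
    if isinstance(genotypes, GenotypeMatrix):
        X = genotypes.alt_presence()
        n_missing = int(np.isnan(X).sum())
        if n_missing:
            warnings.warn(
                f"imputing {n_missing} missing genotypes to 0 for SOM training",
                stacklevel=2,
            )
            X = np.nan_to_num(X, nan=0.0)
    else:
        X = np.asarray(genotypes, dtype=float)
    if np.isnan(X).any():
        X = np.nan_to_num(X, nan=0.0)
    if len(np.unique(X, axis=0)) == 1:
        warnings.warn("all training rows identical; map will collapse", stacklevel=2)

    rng = np.random.default_rng(config.seed)
    nx, ny = config.grid
    n_nodes = nx * ny
    node_coords = [(i, j) for i in range(nx) for j in range(ny)]
    grid_d = _grid_distances(nx, ny, config.topology)
    # init from data range so binary inputs start inside [0, 1]
    W = rng.uniform(X.min(axis=0), X.max(axis=0) + 1e-9, size=(n_nodes, X.shape[1]))

    T = config.n_iterations
    picks = rng.integers(0, X.shape[0], size=T)
    for t in range(T):
        x = X[picks[t]]
        frac = 1.0 - t / T  # linear decay to (almost) zero
        lr = config.learning_rate * frac
        sigma = max(config.sigma * frac, 1e-3)
        if config.metric == "manhattan":
            d = np.abs(W - x).sum(axis=1)
        else:
            d = np.sqrt(((W - x) ** 2).sum(axis=1))
        b = int(d.argmin())
        h = np.exp(-(grid_d[b] ** 2) / (2 * sigma**2))
        W += (lr * h)[:, None] * (x - W)

    model = SomModel(W, config, node_coords, np.empty(0, dtype=int), 0.0)
    model.bmus = model.bmu(X)
    model.quantization_error = model.quantization(X)
    return model


@dataclass
class NodeEnrichment:
    """One map node where an MII group is over-represented."""

    node: tuple[int, int]
    n_observations: int
    group: str
    group_share: float  # share of the group within the node
    population_share: float
    characteristic_variants: pd.Series = field(default_factory=pd.Series)
    # alt frequency in node minus alt frequency in population, descending


def node_enrichment(
    model: SomModel,
    partition: MIIGroupPartition,
    genotypes: GenotypeMatrix,
    top_m: int = 10,
    enrichment_ratio: float = 2.0,
    min_node_size: int = 10,
    groups: list[str] | None = None,
) -> list[NodeEnrichment]:
    """Find nodes over-representing an MII group and their marker variants.

    A node is enriched for group g when (share of g within the node)
    >= enrichment_ratio x (population share of g) and the node holds at
    least ``min_node_size`` observations.  For each enriched node the
    ``top_m`` variants with the largest percentage difference (node alt
    frequency minus population alt frequency) are reported.
    """
    ap = genotypes.alt_presence()
    X = np.nan_to_num(ap, nan=0.0)
    bmus = model.bmu(X)
    labels = partition.assignment.reindex(genotypes.process_ids).to_numpy()
    pop_freq = pd.Series(np.nanmean(ap, axis=0), index=genotypes.variant_ids)
    n_total = len(labels)
    out: list[NodeEnrichment] = []
    check_groups = groups if groups is not None else partition.labels
    for node_idx, coord in enumerate(model.node_coords):
        in_node = bmus == node_idx
        size = int(in_node.sum())
        if size < min_node_size:
            continue
        node_freq = pd.Series(
            np.nanmean(ap[in_node], axis=0), index=genotypes.variant_ids
        )
        diff = (node_freq - pop_freq).sort_values(ascending=False)
        for g in check_groups:
            pop_share = (labels == g).sum() / n_total
            node_share = (labels[in_node] == g).sum() / size
            if pop_share > 0 and node_share >= enrichment_ratio * pop_share:
                out.append(
                    NodeEnrichment(
                        node=coord,
                        n_observations=size,
                        group=g,
                        group_share=node_share,
                        population_share=pop_share,
                        characteristic_variants=diff.head(top_m),
                    )
                )
    return out


def subset_search(
    candidate_variants: list[str],
    evaluate_callback,
    max_size: int | None = None,
) -> tuple[tuple[str, ...], pd.DataFrame]:
    """Exhaustive search over non-empty variant subsets for minimal RMSE.

    ``evaluate_callback(subset) -> cross-validated RMSE`` must use a fixed
    fold assignment so scores are comparable.  Candidate counts above 15
    are refused (2^15 - 1 evaluations is the enumeration bound).  Ties
    break toward the smaller subset, then lexicographically.  Returns the
    winner and the full score trace.
    """
    p = len(candidate_variants)
    if p == 0:
        raise ValueError("no candidate variants")
    if p > 15:
        raise ValueError(
            f"{p} candidates exceed the exhaustive-enumeration bound of 15"
        )
    sizes = range(1, (max_size or p) + 1)
    records = []
    for size in sizes:
        for subset in combinations(sorted(candidate_variants), size):
            records.append((subset, float(evaluate_callback(list(subset)))))
    trace = pd.DataFrame(records, columns=["subset", "rmse"])
    trace["size"] = trace["subset"].map(len)
    best = trace.sort_values(["rmse", "size", "subset"], kind="mergesort").iloc[0]
    return tuple(best["subset"]), trace


@dataclass
class StandardizedCountFeature:
    """Carrier count over a variant set, z-scored on its defining cohort.

    The raw value is the number of member variants carried as alternative;
    the standardization constants (mean, SD) are frozen from the defining
    cohort and reused verbatim for new data.
    """

    name: str
    variant_ids: list[str]
    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.sd <= 0:
            raise ValueError("degenerate feature: zero variance on defining cohort")


def build_standardized_feature(
    variant_subset: list[str], genotypes: GenotypeMatrix, name: str = "IV-SOM"
) -> StandardizedCountFeature:
    """Freeze standardization constants from the defining cohort."""
    cols = [genotypes.index_of(v) for v in variant_subset]
    sub = genotypes.alt_presence()[:, cols]
    raw = sub.sum(axis=1)
    raw[np.isnan(sub).any(axis=1)] = np.nan
    mean = float(np.nanmean(raw))
    sd = float(np.nanstd(raw))  # population SD: constants describe this cohort
    if sd == 0 or np.isnan(sd):
        raise ValueError("degenerate feature: zero variance on defining cohort")
    return StandardizedCountFeature(name, list(variant_subset), mean, sd)


def evaluate_standardized_feature(
    feature: StandardizedCountFeature, genotypes: GenotypeMatrix
) -> pd.Series:
    """(count - frozen mean) / frozen SD per process; missing propagates."""
    cols = [genotypes.index_of(v) for v in feature.variant_ids]
    sub = genotypes.alt_presence()[:, cols]
    raw = sub.sum(axis=1)
    raw[np.isnan(sub).any(axis=1)] = np.nan
    return pd.Series(
        (raw - feature.mean) / feature.sd, index=genotypes.process_ids,
        name=feature.name,
    )
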