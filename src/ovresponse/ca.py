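"""Correspondence analysis of the variant x MII-group table.

The carrier counts of candidate variants within the five MII-count groups
form a contingency table; CA places variants (rows) and groups (columns)
in a shared low-dimensional map, and the variants nearest the high-yield
group define a count-type genetic feature (number of those variants a
process carries as alternative).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import Cohort, GenotypeMatrix, MIIGroupPartition

__all__ = [
    "ContingencyTable",
    "CAResult",
    "CountFeature",
    "build_contingency",
    "fit_ca",
    "select_proximal_variants",
    "evaluate_count_feature",
]


@dataclass
class CountFeature:
    """Count of member variants carried as alternative (0..|set|).

    A missing genotype at any member makes the value missing; the
    downstream learner handles missing values natively.
    """

    name: str
    variant_ids: list[str]

    def __len__(self) -> int:
        return len(self.variant_ids)


def evaluate_count_feature(feature: CountFeature, genotypes: GenotypeMatrix) -> pd.Series:
    """Per-process value of a count feature; missing members propagate."""
    cols = [genotypes.index_of(v) for v in feature.variant_ids]
    sub = genotypes.alt_presence()[:, cols]
    values = sub.sum(axis=1)
    values[np.isnan(sub).any(axis=1)] = np.nan
    return pd.Series(values, index=genotypes.process_ids, name=feature.name)


def build_contingency(
    cohort: Cohort, partition: MIIGroupPartition, candidate_variants: list[str]
) -> pd.DataFrame:
    """Alt-carrier counts of each candidate variant within each MII group.

    Entry (v, g) = number of processes in group g carrying at least one
    alternative allele at v; missing genotypes do not count.  All-zero
    rows are kept but flagged with a warning.
    """
    geno = cohort.genotypes
    ap = geno.alt_presence_frame()[candidate_variants]
    groups = partition.assignment.reindex(ap.index)
    table = pd.DataFrame(
        0, index=pd.Index(candidate_variants, name="variant_id"),
        columns=pd.Index(partition.labels, name="mii_group"), dtype=int,
    )
    for label in partition.labels:
        sub = ap[groups == label]
        table[label] = (sub == 1).sum(axis=0).astype(int)
    empty_groups = [g for g in partition.labels if (groups == g).sum() == 0]
    if empty_groups:
        warnings.warn(f"empty MII group(s): {empty_groups}", stacklevel=2)
    zero_rows = table.index[(table == 0).all(axis=1)]
    if len(zero_rows):
        warnings.warn(
            f"variant(s) with no alt carriers: {list(zero_rows)}", stacklevel=2
        )
    return table


@dataclass
class CAResult:
    """Principal coordinates and inertia decomposition of one table."""

    row_coords: pd.DataFrame
    col_coords: pd.DataFrame
    singular_values: np.ndarray
    total_inertia: float
    inertia_proportions: np.ndarray = field(default_factory=lambda: np.array([]))

    @property
    def n_dims(self) -> int:
        return self.row_coords.shape[1]


def fit_ca(table: pd.DataFrame) -> CAResult:
    """Classical correspondence analysis of a two-way count table.

    SVD of the standardized residuals of the correspondence matrix; rows
    and columns are both returned in principal coordinates (symmetric
    map), so that the cross-set proximity rule downstream has comparable
    scales.  Total inertia equals the table's Pearson chi-square / n.
    Rank-0 residuals (perfect independence) give zero inertia and no
    coordinates.
    """
    N = table.to_numpy(dtype=float)
    if N.min() < 0:
        raise ValueError("contingency table has negative entries")
    n = N.sum()
    if n == 0:
        raise ValueError("empty contingency table")
    # drop all-zero rows/columns: they have no profile
    keep_r = N.sum(axis=1) > 0
    keep_c = N.sum(axis=0) > 0
    N = N[np.ix_(keep_r, keep_c)]
    rlab = table.index[keep_r]
    clab = table.columns[keep_c]
    if N.shape[0] < 2 or N.shape[1] < 2:
        raise ValueError("need at least 2 non-degenerate rows and columns")

    P = N / n
    r = P.sum(axis=1)
    c = P.sum(axis=0)
    S = (P - np.outer(r, c)) / np.sqrt(np.outer(r, c))
    U, sv, Vt = np.linalg.svd(S, full_matrices=False)
    keep = sv > 1e-12
    U, sv, Vt = U[:, keep], sv[keep], Vt[keep]
    total = float((sv**2).sum())
    dims = [f"dim{i}" for i in range(len(sv))]
    row = pd.DataFrame((U * sv) / np.sqrt(r)[:, None], index=rlab, columns=dims)
    col = pd.DataFrame((Vt.T * sv) / np.sqrt(c)[:, None], index=clab, columns=dims)
    props = sv**2 / total if total > 0 else np.zeros(0)
    return CAResult(row, col, sv, total, props)


def select_proximal_variants(
    ca_result: CAResult,
    target_group: str = ">11",
    k: int = 3,
    name: str = "IV-CA",
) -> tuple[CountFeature, pd.Series]:
    """The k variants nearest the target group in the first two CA dims.

    Distance is Euclidean between each variant's row point and the target
    group's column point over dimensions 0-1 (or dimension 0 alone for a
    rank-1 solution); ties break lexicographically by variant id.  Returns
    the count feature over the winners and the full distance series.
    """
    if target_group not in ca_result.col_coords.index:
        raise KeyError(f"group {target_group!r} has no CA coordinates")
    ndim = min(2, ca_result.n_dims)
    if ndim == 0:
        raise ValueError("CA solution has no dimensions (zero inertia)")
    rows = ca_result.row_coords.iloc[:, :ndim]
    target = ca_result.col_coords.loc[target_group].iloc[:ndim]
    dist = np.sqrt(((rows - target) ** 2).sum(axis=1)).rename("distance")
    order = dist.to_frame().assign(vid=dist.index).sort_values(
        ["distance", "vid"], kind="mergesort"
    )
    if k > len(order):
        warnings.warn(
            f"only {len(order)} variants available for k={k}", stacklevel=2
        )
    chosen = list(order.index[:k])
    return CountFeature(name, chosen), dist
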