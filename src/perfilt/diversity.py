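"""Diversity statistics used to evaluate the effect of filtering.

Alpha (within-sample) diversity is the Shannon index

    H = -sum_i p_i ln(p_i)

over the taxa with positive proportion ``p_i`` in a sample (natural
logarithm).  Beta (between-sample) diversity uses Bray-Curtis
dissimilarity, visualised by classical principal coordinates analysis
(PCoA).  Per the convention adopted here, per-axis variance fractions
divide each eigenvalue by the sum of *all* eigenvalues, negative ones
included (Bray-Curtis matrices are generally non-Euclidean, so negative
eigenvalues are informative about the embedding distortion and are not
zeroed); coordinates are emitted for positive eigenvalues only.

Group differences in alpha diversity are tested with Dunn's rank-based
pairwise test (tie-corrected) and Benjamini-Hochberg adjustment.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform
from statsmodels.stats.multitest import multipletests

from .taxa_table import TaxaTable, TaxaTableError

logger = logging.getLogger("perfilt")


@dataclass
class DiversityProfile:
    """Per-sample Shannon index and observed richness."""

    shannon: dict[str, float]
    s_observed: dict[str, int]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"shannon": pd.Series(self.shannon),
                             "s_observed": pd.Series(self.s_observed)}) \
            .rename_axis("sample_id")

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t")


@dataclass
class DistanceMatrix:
    """Symmetric dissimilarity matrix with zero diagonal."""

    labels: list[str]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (len(self.labels), len(self.labels)):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(m, m.T, atol=1e-12):
            raise ValueError("distance matrix is not symmetric")
        np.fill_diagonal(m, 0.0)
        self.matrix = m

    @property
    def n(self) -> int:
        return len(self.labels)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.labels, columns=self.labels)


@dataclass
class Ordination:
    """PCoA result: sample coordinates plus the full eigenvalue spectrum.

    ``eigenvalues`` holds all n eigenvalues sorted descending (negatives
    kept); ``variance_explained[i] = eigenvalue[i] / sum(all eigenvalues)``.
    """

    coordinates: pd.DataFrame
    eigenvalues: np.ndarray
    variance_explained: np.ndarray

    def to_tsv(self, path: str | Path) -> None:
        self.coordinates.to_csv(path, sep="\t")


@dataclass
class DunnResult:
    """Pairwise Dunn's test table: z statistic, raw and BH-adjusted p."""

    table: pd.DataFrame  # columns: group1, group2, z, p_raw, p_adj

    def to_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


# ----------------------------------------------------------------------
# alpha diversity
# ----------------------------------------------------------------------

def shannon_index(table: TaxaTable) -> DiversityProfile:
    """Shannon index H = -sum p_i ln p_i per sample (natural log).

    Samples with zero library size get H = 0 (with a warning); samples
    with a single observed taxon have H = 0 by construction.
    """
    counts = table.counts.astype(float)
    lib = counts.sum(axis=1)
    zero = lib == 0
    if zero.any():
        logger.warning("Shannon index set to 0 for zero-library sample(s): %s",
                       ", ".join(np.array(table.sample_ids)[zero]))
    shannon: dict[str, float] = {}
    s_obs: dict[str, int] = {}
    for i, sid in enumerate(table.sample_ids):
        row = counts[i]
        s_obs[sid] = int(np.count_nonzero(row))
        if lib[i] == 0:
            shannon[sid] = 0.0
            continue
        p = row[row > 0] / lib[i]
        shannon[sid] = float(-(p * np.log(p)).sum())
    return DiversityProfile(shannon=shannon, s_observed=s_obs)


# ----------------------------------------------------------------------
# beta diversity
# ----------------------------------------------------------------------

def bray_curtis(table: TaxaTable, proportions: bool = False) -> DistanceMatrix:
    """Pairwise Bray-Curtis dissimilarities between samples.

    BC(u, v) = 1 - 2 * sum_i min(u_i, v_i) / (sum u + sum v), computed on
    raw counts by default (``proportions=True`` normalises rows first as
    a sensitivity option).  A pair of all-zero samples has no defined
    dissimilarity and raises an error.
    """
    x = table.counts.astype(float)
    lib = x.sum(axis=1)
    if np.count_nonzero(lib == 0) >= 2:
        zero = [s for s, t in zip(table.sample_ids, lib) if t == 0]
        raise TaxaTableError(
            "Bray-Curtis undefined for a pair of all-zero samples: "
            + ", ".join(zero)
        )
    if proportions:
        safe = np.where(lib == 0, 1.0, lib)
        x = x / safe[:, None]
    d = squareform(pdist(x, metric="braycurtis"))
    return DistanceMatrix(labels=list(table.sample_ids), matrix=d)


def pcoa(dist: DistanceMatrix, n_axes: int = 2) -> Ordination:
    """Classical (Gower) principal coordinates analysis.

    Double-centers the squared distances, eigendecomposes, and keeps the
    full spectrum: per-axis variance fractions are eigenvalue / sum of
    all eigenvalues (negative eigenvalues retained in the denominator).
    Coordinates are emitted only for positive eigenvalues, up to
    ``n_axes`` axes.
    """
    n = dist.n
    if not 1 <= n_axes <= n - 1:
        raise ValueError(f"n_axes must be in [1, {n - 1}]")
    d2 = dist.matrix ** 2
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ d2 @ j
    b = (b + b.T) / 2.0  # enforce exact symmetry for eigh
    eigvals, eigvecs = np.linalg.eigh(b)
    order = np.argsort(eigvals)[::-1]
    eigvals = eigvals[order]
    eigvecs = eigvecs[:, order]
    total = eigvals.sum()
    variance_explained = eigvals / total
    n_pos = int(np.count_nonzero(eigvals > 0))
    n_coord = min(n_axes, n_pos)
    coords = eigvecs[:, :n_coord] * np.sqrt(eigvals[:n_coord])
    frame = pd.DataFrame(coords, index=pd.Index(dist.labels, name="sample_id"),
                         columns=[f"PCo{i + 1}" for i in range(n_coord)])
    return Ordination(coordinates=frame, eigenvalues=eigvals,
                      variance_explained=variance_explained)


# ----------------------------------------------------------------------
# group comparisons
# ----------------------------------------------------------------------

def dunn_bh(values: Mapping[str, float],
            groups: Mapping[str, str]) -> DunnResult:
    """Dunn's pairwise rank test with Benjamini-Hochberg adjustment.

    All observations are ranked jointly (mid-ranks for ties); for groups
    i and j the statistic is

        z = (Rbar_i - Rbar_j) / sqrt([N(N+1)/12 - T/(12(N-1))] (1/n_i + 1/n_j))

    with the tie correction T = sum_t (t^3 - t) over tie groups.  When
    every observation is tied the standard error vanishes; z is then 0
    and p = 1.  P-values are two-sided normal tails, BH-adjusted over
    all group pairs.
    """
    ids = [s for s in values if s in groups]
    if len(ids) < len(values):
        missing = sorted(set(values) - set(groups))
        raise ValueError(f"samples missing a group label: {missing}")
    y = np.array([values[s] for s in ids], dtype=float)
    g = np.array([groups[s] for s in ids])
    labels = sorted(set(g.tolist()))
    if len(labels) < 2:
        raise ValueError("Dunn's test needs at least 2 groups")
    sizes = {lab: int(np.count_nonzero(g == lab)) for lab in labels}
    if min(sizes.values()) < 2:
        small = [lab for lab, nl in sizes.items() if nl < 2]
        raise ValueError(f"each group needs >= 2 samples; too small: {small}")

    n_total = y.size
    ranks = stats.rankdata(y)
    mean_rank = {lab: float(ranks[g == lab].mean()) for lab in labels}
    _, tie_counts = np.unique(y, return_counts=True)
    tie_term = float(((tie_counts ** 3) - tie_counts).sum())
    var_base = n_total * (n_total + 1) / 12.0 - tie_term / (12.0 * (n_total - 1))

    rows = []
    for a, b in itertools.combinations(labels, 2):
        se2 = var_base * (1.0 / sizes[a] + 1.0 / sizes[b])
        if se2 <= 0.0:
            z = 0.0
        else:
            z = (mean_rank[a] - mean_rank[b]) / np.sqrt(se2)
        p = float(2.0 * stats.norm.sf(abs(z)))
        rows.append({"group1": a, "group2": b, "z": z, "p_raw": p})
    frame = pd.DataFrame(rows)
    frame["p_adj"] = multipletests(frame["p_raw"].to_numpy(), method="fdr_bh")[1]
    return DunnResult(table=frame)


# ----------------------------------------------------------------------
# combined-matrix ordination
# ----------------------------------------------------------------------

def combined_ordination(tables: Sequence[tuple[str, TaxaTable]],
                        n_axes: int = 2,
                        proportions: bool = False) -> Ordination:
    """Joint PCoA of several filtered views of the same samples.

    Builds a combined matrix whose rows are each sample replicated once
    per method label and whose columns are the union of taxa (zeros
    where a taxon was filtered out of a view), then applies Bray-Curtis
    and PCoA to the stacked matrix.  Output rows carry
    ``(sample, method)`` labels.
    """
    if not tables:
        raise ValueError("need at least one (label, table) pair")
    base_samples = tables[0][1].sample_ids
    for label, t in tables:
        if t.sample_ids != base_samples:
            raise ValueError(f"table {label!r} does not share the sample set")
    union: list[str] = []
    seen: set[str] = set()
    for _, t in tables:
        for tx in t.taxon_ids:
            if tx not in seen:
                seen.add(tx)
                union.append(tx)
    col = {tx: j for j, tx in enumerate(union)}
    blocks = []
    row_labels: list[tuple[str, str]] = []
    for label, t in tables:
        block = np.zeros((t.n_samples, len(union)), dtype=np.int64)
        idx = [col[tx] for tx in t.taxon_ids]
        block[:, idx] = t.counts
        blocks.append(block)
        row_labels.extend((s, label) for s in t.sample_ids)
    stacked = np.vstack(blocks)
    flat_ids = [f"{s}::{m}" for s, m in row_labels]
    combined = TaxaTable(stacked, flat_ids, union)
    ord_res = pcoa(bray_curtis(combined, proportions=proportions), n_axes=n_axes)
    index = pd.MultiIndex.from_tuples(row_labels, names=["sample_id", "method"])
    coords = ord_res.coordinates.set_axis(index, axis=0)
    return Ordination(coordinates=coords, eigenvalues=ord_res.eigenvalues,
                      variance_explained=ord_res.variance_explained)
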