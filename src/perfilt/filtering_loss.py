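"""Filtering loss: the covariance contribution of removed taxa.

For a samples-by-taxa count matrix ``X`` and a removal set ``J``, the
filtering loss is

    FL(J) = 1 - ||X_{-J}' X_{-J}||_F^2 / ||X' X||_F^2

where ``X_{-J}`` drops the columns in ``J`` and ``||.||_F`` is the
Frobenius norm.  FL measures the fraction of the squared Frobenius mass
of the taxa cross-product (Gram) matrix lost by removing ``J``:
FL(empty) = 0, FL(all taxa) = 1, and FL is monotone under set inclusion.

Along an importance ordering of the taxa, ``DFL[j] = FL(first j) -
FL(first j-1)`` is the incremental loss of removing the j-th least
important taxon; the DFL values sum to 1 and are the statistic on which
the filtering tests in :mod:`perfilt.filters` operate.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .taxa_table import TaxaTable, TaxaTableError

#: tolerance on conservation checks (sum of DFL = 1)
CONSERVATION_TOL = 1e-10

CRITERIA = ("abundance", "total-count")


@dataclass
class TaxaOrdering:
    """Permutation of taxon indices in ascending importance.

    Position 0 holds the least important taxon — the first candidate for
    removal.  (Abundance rank 1 = most abundant taxon is therefore the
    *last* entry.)
    """

    order: np.ndarray
    criterion: str
    tie_break: str = "total count ascending, then taxon id ascending"

    def __post_init__(self) -> None:
        order = np.asarray(self.order, dtype=int)
        p = order.size
        if sorted(order.tolist()) != list(range(p)):
            raise ValueError("order must be a permutation of 0..p-1")
        self.order = order

    @property
    def p(self) -> int:
        return self.order.size


@dataclass
class FilteringLossResult:
    """Cumulative FL and per-taxon DFL along an ordering.

    ``fl[j]`` is the loss of removing the first ``j`` taxa of the
    ordering (``j = 0..p``, both endpoints included so downstream
    cutoffs index positions unambiguously); ``dfl[j-1] = fl[j] - fl[j-1]``.
    """

    ordering: TaxaOrdering
    fl: np.ndarray
    dfl: np.ndarray

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# ordering criterion: {self.ordering.criterion}\n")
            fh.write("position\tdfl\n")
            for j, d in enumerate(self.dfl, start=1):
                fh.write(f"{j}\t{d!r}\n")


def order_taxa(table: TaxaTable, criterion: str = "abundance") -> TaxaOrdering:
    """Order taxa by ascending importance.

    ``abundance`` ranks by the number of samples a taxon is present in
    (the convention used for mock-community heatmaps, where the most
    abundant taxon has rank 1); ``total-count`` ranks by the taxon's
    total read count.  Ties break by total count ascending, then by
    taxon id (lexicographic, ascending) so the ordering is deterministic.
    """
    if criterion not in CRITERIA:
        raise ValueError(f"criterion must be one of {CRITERIA}")
    if table.n_taxa < 1:
        raise TaxaTableError("table has no taxa to order")
    totals = table.counts.sum(axis=0)
    presence = table.presence.sum(axis=0)
    ids = np.array(table.taxon_ids)
    # np.lexsort: last key is primary
    lex_rank = np.argsort(np.argsort(ids))  # lexicographic rank of each id
    if criterion == "abundance":
        order = np.lexsort((lex_rank, totals, presence))
    else:
        order = np.lexsort((lex_rank, presence, totals))
    return TaxaOrdering(order=order, criterion=criterion)


def _gram_squared(table: TaxaTable) -> tuple[np.ndarray, float]:
    x = table.counts.astype(np.float64)
    gram = x.T @ x
    g2 = gram * gram
    total = float(g2.sum())
    if total == 0.0:
        raise TaxaTableError("filtering loss undefined on an all-zero table")
    return g2, total


def filtering_loss(table: TaxaTable, removed: Iterable[int | str]) -> float:
    """FL of removing a set of taxa (given by index or id)."""
    removed = list(removed)
    if removed and isinstance(removed[0], str):
        removed_idx = table.taxon_indices(removed)  # type: ignore[arg-type]
    else:
        removed_idx = np.asarray(removed, dtype=int)
    g2, total = _gram_squared(table)
    keep = np.ones(table.n_taxa, dtype=bool)
    keep[removed_idx] = False
    kept_mass = float(g2[np.ix_(keep, keep)].sum())
    return 1.0 - kept_mass / total


def dfl_sequence(table: TaxaTable, ordering: TaxaOrdering | None = None) -> FilteringLossResult:
    """FL/DFL along an ordering, computed by incremental Gram updates.

    Equivalent to ``p`` independent :func:`filtering_loss` calls but a
    factor ``p`` cheaper: removing taxon ``c`` from the kept set ``K``
    adds ``2 * sum_{l in K, l != c} G2[c, l] + G2[c, c]`` to the removed
    Frobenius mass, where ``G2`` is the elementwise square of the Gram
    matrix.  Accumulation uses Kahan compensated summation; the result
    is a deterministic, sequential computation independent of any
    chunking strategy.
    """
    if ordering is None:
        ordering = order_taxa(table)
    if ordering.p != table.n_taxa:
        raise ValueError("ordering must cover all taxa of the table")
    g2, total = _gram_squared(table)
    rowsum = g2.sum(axis=1)  # over currently-kept columns; updated in place
    p = table.n_taxa
    fl = np.empty(p + 1)
    fl[0] = 0.0
    acc = 0.0
    comp = 0.0  # Kahan compensation
    for j, c in enumerate(ordering.order, start=1):
        delta = 2.0 * rowsum[c] - g2[c, c]
        y = delta - comp
        t = acc + y
        comp = (t - acc) - y
        acc = t
        rowsum -= g2[:, c]
        fl[j] = acc / total
    dfl = np.diff(fl)
    # exact-arithmetic DFL is non-negative; clamp rounding-level negatives
    neg = dfl < 0
    if np.any(dfl < -1e-9):
        raise AssertionError("incremental filtering loss lost precision")
    dfl[neg] = 0.0
    return FilteringLossResult(ordering=ordering, fl=fl, dfl=dfl)
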