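"""Core count-table data model, readers/writers and preprocessing.

A taxa table (also called a derived feature table or OTU/ASV table) is a
matrix of non-negative read counts with samples in rows and taxa in
columns.  Everything in this package operates on :class:`TaxaTable` in
that canonical orientation; transposed input is handled at read time.

Supported on-disk formats are TSV/CSV (first column = sample id, header
row = taxon ids, or the transpose with ``orientation="taxa-by-samples"``)
and the dense BIOM 1.0 JSON dialect (rows = observations/taxa, columns =
samples, per the BIOM convention).  Sparse/HDF5 BIOM is out of scope.
"""

from __future__ import annotations

import datetime
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("perfilt")

#: reserved per-sample metadata column names
META_COLUMNS = ("lab", "dilution", "dna_conc", "group")

FORMATS = ("tsv", "csv", "biom-json")
ORIENTATIONS = ("samples-by-taxa", "taxa-by-samples")


class TaxaTableError(ValueError):
    """Raised for malformed tables or invalid table operations."""


def _find_duplicates(ids: Sequence[str]) -> list[str]:
    seen: set[str] = set()
    dups: list[str] = []
    for x in ids:
        if x in seen and x not in dups:
            dups.append(x)
        seen.add(x)
    return dups


@dataclass
class TaxaTable:
    """Samples-by-taxa matrix of non-negative integer counts.

    Parameters
    ----------
    counts
        2-D array of shape ``(n_samples, n_taxa)``; entries must be
        non-negative and integral (integer dtype, or floats that are
        exact integers — these are cast).
    sample_ids, taxon_ids
        Unique string identifiers for rows and columns.
    sample_meta
        Optional DataFrame indexed by sample id; the reserved columns
        ``lab``, ``dilution``, ``dna_conc`` and ``group`` are understood
        by downstream analyses.
    taxon_meta
        Optional mapping taxon id -> taxonomy string (opaque).
    """

    counts: np.ndarray
    sample_ids: list[str]
    taxon_ids: list[str]
    sample_meta: pd.DataFrame | None = None
    taxon_meta: dict[str, str] | None = None

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        if counts.ndim != 2:
            raise TaxaTableError(f"counts must be 2-D, got {counts.ndim}-D")
        if not np.issubdtype(counts.dtype, np.integer):
            if not np.issubdtype(counts.dtype, np.number):
                raise TaxaTableError("counts must be numeric")
            if not np.all(np.isfinite(counts)) or np.any(counts != np.round(counts)):
                bad = np.argwhere(~np.isfinite(counts) | (counts != np.round(counts)))[0]
                raise TaxaTableError(
                    f"non-integral count at row {bad[0]}, column {bad[1]}"
                )
            counts = counts.astype(np.int64)
        if np.any(counts < 0):
            r, c = np.argwhere(counts < 0)[0]
            raise TaxaTableError(
                f"negative count at sample {self.sample_ids[r]!r}, "
                f"taxon {self.taxon_ids[c]!r}"
            )
        self.counts = counts
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.taxon_ids = [str(t) for t in self.taxon_ids]
        if counts.shape != (len(self.sample_ids), len(self.taxon_ids)):
            raise TaxaTableError(
                f"counts shape {counts.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.taxon_ids)} taxa"
            )
        for kind, ids in (("sample", self.sample_ids), ("taxon", self.taxon_ids)):
            dups = _find_duplicates(ids)
            if dups:
                raise TaxaTableError(f"duplicate {kind} id(s): {', '.join(dups)}")
        if self.sample_meta is not None:
            unknown = set(map(str, self.sample_meta.index)) - set(self.sample_ids)
            if unknown:
                raise TaxaTableError(
                    f"sample_meta contains unknown sample id(s): {sorted(unknown)}"
                )
        zero = self.zero_library_samples
        if zero:
            # kept, but flagged: diversity operations decide their own policy
            logger.warning("samples with zero library size: %s", ", ".join(zero))

    # ------------------------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.counts.shape[0]

    @property
    def n_taxa(self) -> int:
        return self.counts.shape[1]

    @property
    def library_sizes(self) -> pd.Series:
        """Per-sample total read count (row sums)."""
        return pd.Series(self.counts.sum(axis=1), index=self.sample_ids, name="library_size")

    @property
    def zero_library_samples(self) -> list[str]:
        sums = self.counts.sum(axis=1)
        return [s for s, t in zip(self.sample_ids, sums) if t == 0]

    @property
    def presence(self) -> np.ndarray:
        """Boolean samples-by-taxa matrix of positive counts."""
        return self.counts > 0

    def prevalence(self) -> pd.Series:
        """Number of samples in which each taxon has a positive count."""
        return pd.Series(self.presence.sum(axis=0), index=self.taxon_ids, name="prevalence")

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=pd.Index(self.sample_ids, name="sample_id"),
                            columns=self.taxon_ids)

    # ------------------------------------------------------------------
    def taxon_indices(self, taxa: Iterable[str]) -> np.ndarray:
        pos = {t: i for i, t in enumerate(self.taxon_ids)}
        try:
            return np.array([pos[t] for t in taxa], dtype=int)
        except KeyError as e:
            raise TaxaTableError(f"unknown taxon id {e.args[0]!r}") from None

    def select_taxa(self, taxa: Sequence[str]) -> "TaxaTable":
        """Return a table restricted to ``taxa`` (kept in the given order)."""
        idx = self.taxon_indices(taxa)
        meta = None
        if self.taxon_meta is not None:
            meta = {t: self.taxon_meta[t] for t in taxa if t in self.taxon_meta}
        return TaxaTable(self.counts[:, idx], list(self.sample_ids), list(taxa),
                         self.sample_meta, meta)

    def select_samples(self, samples: Sequence[str]) -> "TaxaTable":
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        idx = np.array([pos[s] for s in samples], dtype=int)
        meta = None
        if self.sample_meta is not None:
            meta = self.sample_meta.loc[[s for s in samples if s in self.sample_meta.index]]
        return TaxaTable(self.counts[idx], list(samples), list(self.taxon_ids),
                         meta, self.taxon_meta)

    def with_sample_meta(self, meta: pd.DataFrame) -> "TaxaTable":
        return replace(self, sample_meta=meta)


# ----------------------------------------------------------------------
# readers / writers
# ----------------------------------------------------------------------

def _read_delimited(path: Path, sep: str, orientation: str) -> TaxaTable:
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split(sep)
    col_ids = [c.strip() for c in header[1:]]
    dups = _find_duplicates(col_ids)
    if dups:
        raise TaxaTableError(f"duplicate column id(s) in {path}: {', '.join(dups)}")
    df = pd.read_csv(path, sep=sep, index_col=0)
    df.columns = col_ids
    row_ids = [str(r) for r in df.index]
    dups = _find_duplicates(row_ids)
    if dups:
        raise TaxaTableError(f"duplicate row id(s) in {path}: {', '.join(dups)}")
    values = df.to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        for j, col in enumerate(df.columns):
            coerced = pd.to_numeric(df[col], errors="coerce")
            if coerced.isna().any():
                i = int(np.argmax(coerced.isna().to_numpy()))
                raise TaxaTableError(
                    f"non-numeric count at row {row_ids[i]!r}, column {col!r} in {path}"
                )
        values = df.apply(pd.to_numeric).to_numpy()
    if orientation == "taxa-by-samples":
        return TaxaTable(values.T, col_ids, row_ids)
    return TaxaTable(values, row_ids, col_ids)


def _read_biom_json(path: Path) -> TaxaTable:
    with open(path) as fh:
        doc = json.load(fh)
    if doc.get("matrix_type") != "dense":
        raise TaxaTableError(
            "only the dense BIOM JSON dialect is supported "
            f"(got matrix_type={doc.get('matrix_type')!r})"
        )
    taxa = [str(r["id"]) for r in doc["rows"]]        # BIOM rows = observations
    samples = [str(c["id"]) for c in doc["columns"]]  # BIOM columns = samples
    data = np.asarray(doc["data"])
    if data.shape != (len(taxa), len(samples)):
        raise TaxaTableError(
            f"BIOM data shape {data.shape} does not match rows x columns "
            f"({len(taxa)} x {len(samples)})"
        )
    return TaxaTable(data.T, samples, taxa)


def read_taxa_table(path: str | Path, format: str = "tsv",
                    orientation: str = "samples-by-taxa") -> TaxaTable:
    """Read a taxa table from disk.

    ``orientation`` applies to the delimited formats only; BIOM carries
    its own convention (rows = taxa).  The returned table is always in
    the canonical samples-by-taxa orientation.
    """
    if format not in FORMATS:
        raise TaxaTableError(f"unknown format {format!r}; expected one of {FORMATS}")
    if orientation not in ORIENTATIONS:
        raise TaxaTableError(f"unknown orientation {orientation!r}")
    path = Path(path)
    if format == "biom-json":
        return _read_biom_json(path)
    return _read_delimited(path, "\t" if format == "tsv" else ",", orientation)


def write_taxa_table(table: TaxaTable, path: str | Path, format: str = "tsv",
                     orientation: str = "samples-by-taxa") -> None:
    """Write a taxa table; inverse of :func:`read_taxa_table`."""
    if format not in FORMATS:
        raise TaxaTableError(f"unknown format {format!r}; expected one of {FORMATS}")
    path = Path(path)
    if format == "biom-json":
        doc = {
            "id": None,
            "format": "Biological Observation Matrix 1.0.0",
            "format_url": "http://biom-format.org",
            "type": "OTU table",
            "generated_by": "perfilt",
            "date": datetime.datetime.now().isoformat(),
            "matrix_type": "dense",
            "matrix_element_type": "int",
            "shape": [table.n_taxa, table.n_samples],
            "rows": [{"id": t, "metadata": None} for t in table.taxon_ids],
            "columns": [{"id": s, "metadata": None} for s in table.sample_ids],
            "data": table.counts.T.tolist(),
        }
        with open(path, "w") as fh:
            json.dump(doc, fh)
        return
    sep = "\t" if format == "tsv" else ","
    df = table.to_dataframe()
    if orientation == "taxa-by-samples":
        df = df.T
        df.index.name = "taxon_id"
    df.to_csv(path, sep=sep)


def read_sample_metadata(path: str | Path, sep: str = "\t") -> pd.DataFrame:
    """Read per-sample metadata keyed by sample id (first column).

    Reserved column names: ``lab``, ``dilution``, ``dna_conc``, ``group``.
    """
    meta = pd.read_csv(path, sep=sep, index_col=0)
    meta.index = meta.index.astype(str)
    return meta


# ----------------------------------------------------------------------
# preprocessing
# ----------------------------------------------------------------------

def collapse_taxa_by_name(table: TaxaTable,
                          name_key: Callable[[str], str]) -> TaxaTable:
    """Combine taxa whose names map to the same label.

    Columns mapping to one label are replaced by their elementwise sum;
    the output column order follows first occurrence.  The grand total
    of counts is preserved.  How species-level names should be
    normalised (case, rank prefixes) is dataset-specific, hence
    ``name_key`` is user-supplied.
    """
    labels = [str(name_key(t)) for t in table.taxon_ids]
    order: list[str] = []
    groups: dict[str, list[int]] = {}
    for j, lab in enumerate(labels):
        if lab not in groups:
            groups[lab] = []
            order.append(lab)
        groups[lab].append(j)
    cols = [table.counts[:, groups[lab]].sum(axis=1) for lab in order]
    return TaxaTable(np.column_stack(cols), list(table.sample_ids), order,
                     table.sample_meta, None)


def prevalence_filter(table: TaxaTable, min_prevalence_fraction: float) -> TaxaTable:
    """Remove taxa observed in *less than* a fraction of the samples.

    A taxon present in exactly ``min_prevalence_fraction * n_samples``
    samples is kept (strict "less than" removal semantics).
    """
    if not 0 < min_prevalence_fraction <= 1:
        raise TaxaTableError("min_prevalence_fraction must be in (0, 1]")
    if table.n_samples == 0 or table.n_taxa == 0:
        raise TaxaTableError("cannot prevalence-filter an empty table")
    positives = table.presence.sum(axis=0)
    keep = positives >= min_prevalence_fraction * table.n_samples
    if not keep.any():
        raise TaxaTableError(
            "prevalence filter would remove every taxon; lower the threshold"
        )
    kept = [t for t, k in zip(table.taxon_ids, keep) if k]
    return table.select_taxa(kept)
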