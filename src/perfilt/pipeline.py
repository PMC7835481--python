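"""End-to-end evaluation workflow: filter -> diversity -> tests -> reports.

Reproduces the comparison structure used to evaluate filtering on mock
data: each configured filtering method is applied to the input table,
then alpha diversity (before/after), pairwise lab-variability tests
(Dunn + BH), a combined-matrix ordination across all methods, and —
when ground truth or DNA concentrations are available — recovery
metrics and the filtering-vs-contaminant-removal comparison are written
as plain-text TSV/JSON.  A run manifest records the seed, parameters
and package versions; rerunning the same config reproduces all numeric
outputs exactly.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__
from .contaminants import compare_removal_methods, frequency_contaminant_scores
from .diversity import combined_ordination, dunn_bh, shannon_index
from .filters import (DEFAULT_ALPHA, DEFAULT_K, FilterResult,
                      perfect_permutation_fast, perfect_permutation_full,
                      perfect_simultaneous, rule_of_thumb_filter)
from .mock import MockTruth, score_recovery
from .taxa_table import (TaxaTable, TaxaTableError, read_sample_metadata,
                         read_taxa_table, write_taxa_table)

logger = logging.getLogger("perfilt")

SUPPORTED_METHODS = ("simultaneous", "permutation", "permutation-fast", "thumb")


class ConfigError(ValueError):
    """Invalid configuration (missing files, unknown methods)."""


class DataError(ValueError):
    """Input data cannot be parsed or is inconsistent."""


@dataclass
class EvaluationConfig:
    """Configuration of one evaluation run.

    ``group_var`` names the sample-metadata column used for the pairwise
    Dunn tests (``lab``, ``dilution`` or ``group``).  ``methods`` is a
    subset of {simultaneous, permutation, permutation-fast, thumb}.
    """

    table_path: str
    outdir: str
    table_format: str = "tsv"
    orientation: str = "samples-by-taxa"
    metadata_path: str | None = None
    truth_path: str | None = None
    methods: tuple[str, ...] = ("simultaneous", "permutation")
    alpha: float = DEFAULT_ALPHA
    k: int = DEFAULT_K
    seed: int = 0
    group_var: str = "lab"
    thumb_min_count: int = 0
    thumb_min_samples: int = 5
    contaminant_threshold: float = 0.1
    contaminant_min_positive: int = 3
    make_plots: bool = False

    @classmethod
    def from_json(cls, path: str | Path) -> "EvaluationConfig":
        try:
            with open(path) as fh:
                raw = json.load(fh)
        except (OSError, json.JSONDecodeError) as e:
            raise ConfigError(f"cannot read config {path}: {e}") from e
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
        if "methods" in raw:
            raw["methods"] = tuple(raw["methods"])
        return cls(**raw)

    def validate(self) -> None:
        if not Path(self.table_path).exists():
            raise ConfigError(f"table file not found: {self.table_path}")
        for p in (self.metadata_path, self.truth_path):
            if p is not None and not Path(p).exists():
                raise ConfigError(f"input file not found: {p}")
        bad = set(self.methods) - set(SUPPORTED_METHODS)
        if bad:
            raise ConfigError(f"unsupported method(s): {sorted(bad)}; "
                              f"supported: {SUPPORTED_METHODS}")
        if not self.methods:
            raise ConfigError("at least one filtering method is required")


def _apply_method(method: str, table: TaxaTable,
                  config: EvaluationConfig) -> FilterResult:
    if method == "simultaneous":
        return perfect_simultaneous(table, alpha=config.alpha)
    if method == "permutation":
        return perfect_permutation_full(table, alpha=config.alpha, k=config.k,
                                        seed=config.seed)
    if method == "permutation-fast":
        return perfect_permutation_fast(table, alpha=config.alpha, k=config.k,
                                        seed=config.seed)
    return rule_of_thumb_filter(table, min_count=config.thumb_min_count,
                                min_samples=config.thumb_min_samples)


def _filtered_view(table: TaxaTable, result: FilterResult) -> TaxaTable:
    kept = [t for t in table.taxon_ids if t in result.retained]
    return table.select_taxa(kept)


def _try_dunn(profile_frame: pd.DataFrame, meta: pd.DataFrame,
              group_var: str, out: Path, errors: dict, tag: str) -> None:
    try:
        values = profile_frame["shannon"].to_dict()
        groups = meta[group_var].astype(str).to_dict()
        dunn_bh(values, groups).to_tsv(out)
    except (KeyError, ValueError) as e:
        errors[f"dunn_{tag}"] = str(e)
        logger.warning("skipping Dunn test (%s): %s", tag, e)


def run_evaluation(config: EvaluationConfig) -> dict:
    """Run the evaluation bundle; returns the manifest (also written).

    Partial failures (e.g. a degenerate fit in one method) are recorded
    per-method in the manifest without aborting the bundle.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    try:
        table = read_taxa_table(config.table_path, format=config.table_format,
                                orientation=config.orientation)
    except (TaxaTableError, OSError, KeyError) as e:
        raise DataError(f"cannot read taxa table: {e}") from e
    meta = table.sample_meta
    if config.metadata_path:
        try:
            meta = read_sample_metadata(config.metadata_path)
        except (OSError, pd.errors.ParserError) as e:
            raise DataError(f"cannot read sample metadata: {e}") from e
        table = table.with_sample_meta(meta)
    truth = None
    if config.truth_path:
        labels = MockTruth.read_labels(config.truth_path)
        if set(labels) != set(table.taxon_ids):
            raise DataError("truth labels do not match the table's taxa")
        truth = MockTruth(labels=labels,
                          sample_info=meta if meta is not None else pd.DataFrame())

    errors: dict[str, str] = {}
    outputs: list[str] = []

    def _emit(name: str) -> Path:
        outputs.append(name)
        return outdir / name

    logger.info("stage: unfiltered diversity")
    before = shannon_index(table)
    before.to_tsv(_emit("shannon_unfiltered.tsv"))
    if meta is not None:
        _try_dunn(before.to_frame(), meta, config.group_var,
                  _emit("dunn_unfiltered.tsv"), errors, "unfiltered")

    results: dict[str, FilterResult] = {}
    views: list[tuple[str, TaxaTable]] = [("unfiltered", table)]
    for method in config.methods:
        logger.info("stage: filtering (%s)", method)
        try:
            res = _apply_method(method, table, config)
        except (ValueError, TaxaTableError) as e:
            errors[method] = str(e)
            logger.warning("method %s failed: %s", method, e)
            continue
        results[method] = res
        filtered = _filtered_view(table, res)
        views.append((method, filtered))
        res.to_json(_emit(f"filter_{method}.json"))
        write_taxa_table(filtered, _emit(f"filtered_{method}.tsv"))
        after = shannon_index(filtered)
        after.to_tsv(_emit(f"shannon_{method}.tsv"))
        if meta is not None:
            _try_dunn(after.to_frame(), meta, config.group_var,
                      _emit(f"dunn_{method}.tsv"), errors, method)
        if truth is not None:
            rec = score_recovery(res, truth)
            pd.DataFrame([rec.to_dict()]).to_csv(
                _emit(f"recovery_{method}.tsv"), sep="\t", index=False)

    logger.info("stage: combined ordination (%d views)", len(views))
    try:
        ordi = combined_ordination(views, n_axes=2)
        ordi.to_tsv(_emit("combined_ordination_coords.tsv"))
        with open(_emit("combined_ordination_eigen.json"), "w") as fh:
            json.dump({"eigenvalues": ordi.eigenvalues.tolist(),
                       "variance_explained": ordi.variance_explained.tolist()},
                      fh, indent=1)
        if config.make_plots:
            _plot_ordination(ordi, _emit("combined_ordination.png"))
    except (ValueError, TaxaTableError) as e:
        errors["combined_ordination"] = str(e)

    if meta is not None and "dna_conc" in meta.columns:
        logger.info("stage: contaminant scoring")
        try:
            scores = frequency_contaminant_scores(
                table, meta["dna_conc"],
                min_positive=config.contaminant_min_positive,
                threshold=config.contaminant_threshold)
            scores.to_tsv(_emit("contaminant_scores.tsv"))
            for method, res in results.items():
                cmp_res = compare_removal_methods(table, res, scores)
                frame = cmp_res.to_frame()
                frame.to_csv(_emit(f"comparison_{method}.tsv"), sep="\t")
                cmp_res.rank_summary.to_csv(
                    _emit(f"comparison_ranks_{method}.tsv"), sep="\t", index=False)
        except (TaxaTableError, ValueError) as e:
            errors["contaminant_scores"] = str(e)

    manifest = {
        "perfilt_version": __version__,
        "numpy_version": np.__version__,
        "pandas_version": pd.__version__,
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in asdict(config).items()},
        "seed": config.seed,
        "n_samples": table.n_samples,
        "n_taxa": table.n_taxa,
        "retained_counts": {m: len(r.retained) for m, r in results.items()},
        "removed_counts": {m: len(r.removed) for m, r in results.items()},
        "errors": errors,
        "outputs": outputs,
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest


def _plot_ordination(ordi, path: Path) -> None:
    try:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
    except ImportError:
        logger.warning("matplotlib unavailable; skipping plot")
        return
    coords = ordi.coordinates
    fig, ax = plt.subplots(figsize=(5, 4))
    methods = coords.index.get_level_values("method")
    for m in dict.fromkeys(methods):
        sub = coords[methods == m]
        ax.scatter(sub.iloc[:, 0], sub.iloc[:, 1], s=12, label=m, alpha=0.7)
    ve = ordi.variance_explained
    ax.set_xlabel(f"PCo1 ({100 * ve[0]:.1f}%)")
    if coords.shape[1] > 1:
        ax.set_ylabel(f"PCo2 ({100 * ve[1]:.1f}%)")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
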