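"""Frequency-based contaminant scoring and the filtering-vs-removal comparison.

Reagent contaminants contribute a roughly constant amount of DNA per
sample, so when the amount of true sample DNA varies, the *frequency*
(relative abundance) of a contaminant taxon varies inversely with total
DNA concentration, while a true taxon's frequency is independent of it.
For each sufficiently observed taxon, two least-squares models are
compared on (log10 concentration, log10 frequency) over the samples
where the taxon is present:

* contaminant model  M1: slope fixed at -1, free intercept;
* non-contaminant model  M0: slope 0 (constant frequency), free intercept.

The score is the CDF of an F(n-1, n-1) variable at SSR(M1)/SSR(M0):
scores near 0 mean the contaminant model fits far better, and a taxon is
classified as a contaminant when its score is at or below the threshold
(default 0.1).  Taxa present in fewer than ``min_positive`` samples give
an unstable fit and are scored NA / undetermined.

The exact statistic behind the published frequency-based tool is not
normative here; this score preserves its orientation (small =
contaminant) and threshold idiom, which is what the comparison with
rare-taxa filtering requires.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .filters import FilterResult
from .taxa_table import TaxaTable, TaxaTableError

logger = logging.getLogger("perfilt")

DEFAULT_THRESHOLD = 0.1
DEFAULT_MIN_POSITIVE = 3

CLASS_CONTAMINANT = "contaminant"
CLASS_NON_CONTAMINANT = "non-contaminant"
CLASS_UNDETERMINED = "undetermined"


@dataclass
class ContaminantScore:
    """Per-taxon contaminant scores and threshold classification.

    ``table`` columns: ``taxon``, ``n_positive``, ``score`` (NaN when
    ``n_positive < min_positive``) and ``classification``.
    """

    table: pd.DataFrame
    threshold: float
    min_positive: int

    @property
    def scores(self) -> pd.Series:
        return self.table.set_index("taxon")["score"]

    @property
    def contaminants(self) -> set[str]:
        mask = self.table["classification"] == CLASS_CONTAMINANT
        return set(self.table.loc[mask, "taxon"])

    def to_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def frequency_contaminant_scores(table: TaxaTable,
                                 dna_conc: Mapping[str, float] | pd.Series,
                                 min_positive: int = DEFAULT_MIN_POSITIVE,
                                 threshold: float = DEFAULT_THRESHOLD) -> ContaminantScore:
    """Score every taxon for frequency/concentration anticorrelation.

    ``dna_conc`` maps each sample id to its (positive) total DNA
    concentration.  Zero-library samples are excluded with a warning.
    Multiplying all concentrations by a positive constant leaves the
    scores unchanged (the free intercepts absorb the scale).
    """
    conc = pd.Series(dna_conc, dtype=float)
    missing = [s for s in table.sample_ids if s not in conc.index]
    if missing:
        raise TaxaTableError(f"dna_conc missing for sample(s): {missing}")
    conc = conc.loc[table.sample_ids]
    if (conc <= 0).any() or not np.isfinite(conc).all():
        bad = conc.index[(conc <= 0) | ~np.isfinite(conc)].tolist()
        raise TaxaTableError(f"non-positive DNA concentration for sample(s): {bad}")

    lib = table.counts.sum(axis=1).astype(float)
    usable = lib > 0
    if not usable.all():
        excluded = [s for s, u in zip(table.sample_ids, usable) if not u]
        logger.warning("excluding zero-library sample(s) from contaminant "
                       "scoring: %s", ", ".join(excluded))
    counts = table.counts[usable].astype(float)
    freq = counts / lib[usable][:, None]
    log_c = np.log10(conc.to_numpy()[usable])

    rows = []
    for j, taxon in enumerate(table.taxon_ids):
        pos = freq[:, j] > 0
        n_pos = int(pos.sum())
        if n_pos < min_positive:
            rows.append({"taxon": taxon, "n_positive": n_pos,
                         "score": np.nan, "classification": CLASS_UNDETERMINED})
            continue
        y = np.log10(freq[pos, j])
        x = log_c[pos]
        ssr0 = float(((y - y.mean()) ** 2).sum())        # slope 0
        r = y + x                                        # slope -1 residual basis
        ssr1 = float(((r - r.mean()) ** 2).sum())
        if ssr1 == 0.0:
            score = 0.0
        elif ssr0 == 0.0:
            score = 1.0
        else:
            score = float(stats.f.cdf(ssr1 / ssr0, n_pos - 1, n_pos - 1))
        rows.append({"taxon": taxon, "n_positive": n_pos, "score": score,
                     "classification": (CLASS_CONTAMINANT if score <= threshold
                                        else CLASS_NON_CONTAMINANT)})
    return ContaminantScore(table=pd.DataFrame(rows), threshold=threshold,
                            min_positive=min_positive)


@dataclass
class RemovalComparison:
    """Overlap report between a filtering result and contaminant calls.

    ``contingency`` counts (both removed, filter only, contaminant only,
    neither) over the shared taxa set; ``rank_summary`` gives the
    abundance-rank distribution (rank 1 = most prevalent taxon) of each
    removed set.
    """

    contingency: tuple[int, int, int, int]
    filter_only: set[str]
    contaminant_only: set[str]
    both: set[str]
    neither: set[str]
    rank_summary: pd.DataFrame
    all_na: bool = False

    def to_frame(self) -> pd.DataFrame:
        both, f_only, c_only, neither = self.contingency
        return pd.DataFrame(
            {"removed_by_contaminant_score": [both, c_only],
             "kept_by_contaminant_score": [f_only, neither]},
            index=pd.Index(["removed_by_filter", "kept_by_filter"], name=""),
        )


def compare_removal_methods(table: TaxaTable, filt: FilterResult,
                            contam: ContaminantScore) -> RemovalComparison:
    """Compare what filtering removes with what contaminant scoring flags.

    Filtering targets rare taxa (low covariance contribution) while the
    frequency score targets persistent contaminants that may be abundant;
    the report quantifies the overlap and the complementarity of the two
    removed sets, plus where each removed set sits in the abundance
    ranking.
    """
    taxa = set(table.taxon_ids)
    if not filt.retained | filt.removed == taxa or \
            set(contam.table["taxon"]) != taxa:
        raise ValueError("both results must refer to the taxa of the table")
    flagged = contam.contaminants
    all_na = contam.table["score"].isna().all()
    if all_na:
        logger.warning("all contaminant scores are NA; comparison degenerates "
                       "to a filter-only summary")
    removed_f = set(filt.removed)
    both = removed_f & flagged
    f_only = removed_f - flagged
    c_only = flagged - removed_f
    neither = taxa - removed_f - flagged

    # abundance rank: 1 = most prevalent (present in the most samples)
    prevalence = table.prevalence()
    order = prevalence.sort_values(ascending=False, kind="stable").index
    rank = pd.Series(np.arange(1, len(order) + 1), index=order)
    summaries = []
    for name, group in (("filter", removed_f), ("contaminant_score", flagged)):
        ranks = rank.loc[sorted(group)] if group else pd.Series(dtype=float)
        summaries.append({
            "method": name, "n_removed": len(group),
            "min_rank": float(ranks.min()) if len(ranks) else np.nan,
            "median_rank": float(ranks.median()) if len(ranks) else np.nan,
            "max_rank": float(ranks.max()) if len(ranks) else np.nan,
        })
    return RemovalComparison(
        contingency=(len(both), len(f_only), len(c_only), len(neither)),
        filter_only=f_only, contaminant_only=c_only, both=both, neither=neither,
        rank_summary=pd.DataFrame(summaries), all_na=all_na,
    )
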