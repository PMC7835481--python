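"""Taxa filtering tests: simultaneous, permutation, fast permutation, rules of thumb.

The statistical filters decide how many of the least-important taxa can
be removed before the filtering loss (see :mod:`perfilt.filtering_loss`)
increases by more than chance:

* **simultaneous** — one null distribution (skew-normal on log DFL) is
  fitted to the DFL values of *all* positions at once, under the working
  assumption that a large fraction of the taxa is low-signal noise; the
  cutoff is the first position whose DFL is significantly large.
* **permutation (full)** — for every position ``j`` a null of ``k``
  values is built, each the DFL at position ``j`` of a uniformly random
  taxa ordering of the same table; a per-position p-value is the upper
  tail of the observed DFL against that null.
* **permutation (fast)** — identical per-position nulls (position-keyed
  random substreams derived from the seed), but the p-value is evaluated
  only at probed positions: a galloping search (1, 2, 4, 8, ...) finds a
  significant position cheaply — most taxa being noise, the cutoff is
  usually early — and an unbalanced binary search then locates the first
  crossing inside the bracketing interval.  When the significance
  indicator is monotone with a single crossing this returns exactly the
  full method's cutoff at O(log p) instead of O(p) position evaluations.

Per-position p-values are smoothed by a centered running mean of window
3 before thresholding (raw permutation p-values are noisy and the model
implies a single noise/signal changepoint); the cutoff ``j*`` is the
smallest position whose smoothed p-value is <= alpha, and positions
``1..j*-1`` are removed.  Default alpha is 0.1.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable

import numpy as np
from scipy import stats

from .filtering_loss import TaxaOrdering, dfl_sequence, order_taxa, _gram_squared
from .taxa_table import TaxaTable

logger = logging.getLogger("perfilt")

DEFAULT_ALPHA = 0.1
DEFAULT_K = 1000
MIN_PERMUTATIONS = 100

#: maximum |skewness| attainable by a skew-normal distribution
_MAX_SN_SKEW = 0.5 * (4.0 - math.pi) * (math.sqrt(2.0 / math.pi)) ** 3 \
    / (1.0 - 2.0 / math.pi) ** 1.5


class DegenerateDFLError(ValueError):
    """Raised when the DFL values cannot support a null-distribution fit."""


@dataclass
class FilterResult:
    """Outcome of a filtering method.

    ``pvalues`` maps ordering position (1-based) to the monotonized
    (smoothed, then running-minimum) p-value used for thresholding; for
    the fast method it holds smoothed p-values at probed positions only.
    ``raw_pvalues`` keeps the unsmoothed per-position values.
    """

    method: str
    retained: set[str]
    removed: set[str]
    alpha: float | None = None
    pvalues: dict[int, float] | None = None
    raw_pvalues: dict[int, float] | None = None
    k_permutations: int | None = None
    seed: int | None = None
    probes: list[int] = field(default_factory=list)
    cutoff_position: int | None = None
    no_cutoff: bool = False
    ordering: TaxaOrdering | None = None

    def __post_init__(self) -> None:
        if self.retained & self.removed:
            raise ValueError("retained and removed sets overlap")
        for d in (self.pvalues, self.raw_pvalues):
            if d and not all(0.0 <= v <= 1.0 for v in d.values()):
                raise ValueError("p-values must lie in [0, 1]")

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "alpha": self.alpha,
            "k_permutations": self.k_permutations,
            "seed": self.seed,
            "cutoff_position": self.cutoff_position,
            "no_cutoff": self.no_cutoff,
            "retained": sorted(self.retained),
            "removed": sorted(self.removed),
            "probes": list(self.probes),
            "pvalues": {str(k): v for k, v in (self.pvalues or {}).items()},
        }

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1, sort_keys=True)


# ----------------------------------------------------------------------
# skew-normal null fit
# ----------------------------------------------------------------------

#: minimum break (in log-DFL units) between the low-signal bulk and a
#: detached high-signal mode for the mode to be excluded from the null
#: fit; e^5 ~ 150-fold jump in DFL.  Count discreteness in sparse taxa
#: produces breaks of 1-3 log units, a genuine noise/signal separation
#: is typically > 8, so the rule is insensitive to its exact value.
NULL_TRIM_GAP = 5.0


def _trim_upper_mode(x: np.ndarray, min_gap: float = NULL_TRIM_GAP) -> np.ndarray:
    """Drop a detached upper mode: everything above the first gap of at
    least ``min_gap`` among the sorted values above the median.  Samples
    without such a break (any unimodal or continuous spectrum) are
    returned unchanged."""
    xs = np.sort(x)
    n = xs.size
    gaps = np.diff(xs)
    for i in range(n // 2, n - 1):
        if gaps[i] >= min_gap:
            kept = xs[: i + 1]
            if kept.size >= 3 and kept.std() > 0:
                return kept
            break
    return x


def fit_skewnorm(x: np.ndarray, trim_extremes: bool = False):
    """Fit a three-parameter skew-normal by moment matching.

    With ``trim_extremes`` the fit describes the low-signal *bulk*: a
    cleanly detached upper mode (see :func:`_trim_upper_mode`) is
    dropped before moment matching.  A plain moment (or ML) fit on data
    containing a far-out block of strong-signal DFL values inflates the
    null scale until the signal boundary is no longer significant;
    trimming keeps the null anchored to the noise bulk, which is the
    modeling assumption of the filtering tests.  Continuous spectra are
    not trimmed at all.

    Sample skewness is clipped to 99.5% of the skew-normal's attainable
    range before inversion.  Returns a frozen scipy distribution, or
    ``None`` when the data are degenerate (fewer than 3 values or zero
    variance) — callers then fall back to an empirical tail.
    """
    x = np.asarray(x, dtype=float)
    if trim_extremes and x.size >= 3:
        x = _trim_upper_mode(x)
    if x.size < 3:
        return None
    m = x.mean()
    s = x.std(ddof=0)
    if s == 0.0 or not np.isfinite(s):
        return None
    g1 = float(np.clip(stats.skew(x, bias=True), -0.995 * _MAX_SN_SKEW,
                       0.995 * _MAX_SN_SKEW))
    b = math.sqrt(2.0 / math.pi)
    u = (2.0 * abs(g1) / (4.0 - math.pi)) ** (1.0 / 3.0)
    bdelta2 = u * u / (1.0 + u * u)          # (b*delta)^2
    delta = math.copysign(math.sqrt(bdelta2) / b, g1)
    delta = max(min(delta, 0.999999), -0.999999)
    a = delta / math.sqrt(1.0 - delta * delta)
    omega = s / math.sqrt(1.0 - bdelta2)
    xi = m - omega * b * delta
    return stats.skewnorm(a, loc=xi, scale=omega)


# ----------------------------------------------------------------------
# smoothing / cutoff machinery
# ----------------------------------------------------------------------

def _smooth_window3(raw: Callable[[int], float], j: int, j_max: int) -> float:
    """Centered running median of window 3, shrunk at the edges.

    The median is edge-preserving: it suppresses isolated dips in the
    noisy per-position p-values without shifting the noise/signal
    changepoint, whereas a running mean always drags one pre-boundary
    value into the window at the first significant position and so
    biases the cutoff one position into the signal block.
    """
    lo, hi = max(1, j - 1), min(j_max, j + 1)
    return float(np.median([raw(q) for q in range(lo, hi + 1)]))


def _build_result(method: str, table: TaxaTable, ordering: TaxaOrdering,
                  alpha: float, raw: dict[int, float], smoothed: dict[int, float],
                  cutoff: int | None, *, k: int | None = None,
                  seed: int | None = None, probes: list[int] | None = None,
                  monotonize: bool = True) -> FilterResult:
    ids = np.array(table.taxon_ids)
    if cutoff is None:
        removed_ids: set[str] = set()
        retained_ids = set(table.taxon_ids)
    else:
        removed_ids = set(ids[ordering.order[: cutoff - 1]])
        retained_ids = set(ids[ordering.order[cutoff - 1:]])
    pvals = dict(smoothed)
    if monotonize and smoothed:
        positions = sorted(smoothed)
        running = math.inf
        for j in positions:
            running = min(running, smoothed[j])
            pvals[j] = running
    return FilterResult(
        method=method, retained=retained_ids, removed=removed_ids, alpha=alpha,
        pvalues=pvals, raw_pvalues=dict(raw), k_permutations=k, seed=seed,
        probes=list(probes or []), cutoff_position=cutoff,
        no_cutoff=cutoff is None, ordering=ordering,
    )


def _first_crossing(smoothed: dict[int, float], alpha: float) -> int | None:
    for j in sorted(smoothed):
        if smoothed[j] <= alpha:
            return j
    return None


# ----------------------------------------------------------------------
# simultaneous filter
# ----------------------------------------------------------------------

def perfect_simultaneous(table: TaxaTable, alpha: float = DEFAULT_ALPHA,
                         ordering: TaxaOrdering | None = None) -> FilterResult:
    """Simultaneous filtering test.

    One skew-normal null is fitted to the log DFL values of all
    positions (with a detached strong-signal mode excluded from the fit,
    mirroring the assumption that most taxa are low-signal noise); the
    per-position p-value is the fitted upper-tail probability of the
    observed log DFL, floored by the empirical tail over all DFL values
    for observations inside the bulk's range (see :func:`_tail_pvalue`
    for the rationale).  Positions with DFL = 0 (taxa contributing
    nothing to the covariance) get p = 1.
    """
    if not 0 < alpha <= 1:
        raise ValueError("alpha must be in (0, 1]")
    if table.n_taxa < 3:
        raise DegenerateDFLError("simultaneous filtering needs at least 3 taxa")
    if ordering is None:
        ordering = order_taxa(table)
    res = dfl_sequence(table, ordering)
    dfl = res.dfl
    pos_vals = dfl[dfl > 0]
    if pos_vals.size < 3 or np.ptp(np.log(pos_vals)) == 0.0:
        raise DegenerateDFLError(
            "degenerate DFL values (all equal or near-zero variance); "
            "cannot fit the simultaneous null distribution"
        )
    log_all = np.log(pos_vals)
    cut = _signal_mode_cut(log_all)
    bulk = log_all[log_all < cut]
    dist = fit_skewnorm(bulk if bulk.size >= 3 else log_all)
    if dist is None:
        raise DegenerateDFLError("skew-normal fit failed on degenerate DFL values")
    p = table.n_taxa

    def _p_of(value: float) -> float:
        if value <= 0.0:
            return 1.0
        fitted = float(np.clip(dist.sf(np.log(value)), 0.0, 1.0))
        if np.log(value) >= cut:
            return fitted
        empirical = float(np.count_nonzero(pos_vals >= value) / pos_vals.size)
        return max(fitted, empirical)

    raw = {j: _p_of(float(dfl[j - 1])) for j in range(1, p + 1)}
    smoothed = {j: _smooth_window3(lambda q: raw[q], j, p) for j in range(1, p + 1)}
    cutoff = _first_crossing(smoothed, alpha)
    return _build_result("simultaneous", table, ordering, alpha, raw, smoothed, cutoff)


# ----------------------------------------------------------------------
# permutation filters
# ----------------------------------------------------------------------

def _null_dfls(g2: np.ndarray, total: float, rowsum_full: np.ndarray,
               j: int, k: int, rng: np.random.Generator) -> np.ndarray:
    """k null DFL values at position j: DFL of a uniformly random ordering.

    Each draw removes a uniformly random set of ``j`` taxa; the draw's
    DFL is the incremental loss of the j-th removed taxon given the
    first ``j-1``.
    """
    p = g2.shape[0]
    perms = rng.permuted(np.tile(np.arange(p), (k, 1)), axis=1)
    c = perms[:, j - 1]
    if j > 1:
        prior = perms[:, : j - 1]
        s_prior = np.take_along_axis(g2[c], prior, axis=1).sum(axis=1)
    else:
        s_prior = np.zeros(k)
    delta = 2.0 * (rowsum_full[c] - g2[c, c] - s_prior) + g2[c, c]
    return delta / total


def _signal_mode_cut(log_dfl: np.ndarray) -> float:
    """Log-DFL level above which a value belongs to a detached
    strong-signal mode of the observed spectrum (+inf when the spectrum
    has no such break)."""
    bulk = _trim_upper_mode(log_dfl)
    if bulk.size == log_dfl.size:
        return math.inf
    return float(bulk.max()) + NULL_TRIM_GAP / 2.0


def _tail_pvalue(obs: float, null: np.ndarray, tail: str,
                 signal_cut: float = math.inf) -> float:
    """Upper-tail probability of the observed DFL against a null sample.

    The fitted tail is a hybrid: the skew-normal is fitted to the null's
    noise-level bulk (draws above ``signal_cut`` — the observed
    spectrum's noise/signal break — are strong-signal draws and are
    excluded), and its extrapolated tail is trusted only for
    observations above the break, i.e. those that plausibly belong to
    the signal mode.  An observation below the break never gets a
    smaller p-value than its +1-smoothed empirical tail against the
    *full* null, which protects against parametric tail misfit on wide
    or clustered null samples.  Without a break (``signal_cut`` = inf,
    any continuous spectrum) this reduces to the plain fitted tail
    floored by the empirical one.
    """
    if obs <= 0.0:
        return 1.0
    empirical = float((1 + np.count_nonzero(null >= obs)) / (null.size + 1))
    if tail == "empirical":
        return empirical
    log_pos = np.log(null[null > 0]) if np.any(null > 0) else np.empty(0)
    bulk = log_pos[log_pos < signal_cut]
    dist = fit_skewnorm(bulk) if bulk.size >= 10 else None
    if dist is None:  # degenerate null: fall back to the empirical tail
        return empirical
    fitted = float(np.clip(dist.sf(math.log(obs)), 0.0, 1.0))
    if math.log(obs) >= signal_cut:
        return fitted
    return max(fitted, empirical)


class _PositionPvalues:
    """Lazy per-position permutation p-values with position-keyed streams.

    Position ``j`` draws its nulls from ``default_rng([seed, j])`` so the
    full and fast methods see identical draws at every position they
    share, regardless of evaluation order.
    """

    def __init__(self, table: TaxaTable, ordering: TaxaOrdering, k: int,
                 seed: int, tail: str):
        self.g2, self.total = _gram_squared(table)
        self.rowsum = self.g2.sum(axis=1)
        self.dfl = dfl_sequence(table, ordering).dfl
        self.k = k
        self.seed = seed
        self.tail = tail
        pos = self.dfl[self.dfl > 0]
        self.signal_cut = _signal_mode_cut(np.log(pos)) if pos.size else math.inf
        self._cache: dict[int, float] = {}

    def __call__(self, j: int) -> float:
        if j not in self._cache:
            rng = np.random.default_rng([self.seed, j])
            null = _null_dfls(self.g2, self.total, self.rowsum, j, self.k, rng)
            self._cache[j] = _tail_pvalue(float(self.dfl[j - 1]), null, self.tail,
                                          signal_cut=self.signal_cut)
        return self._cache[j]


def _check_permutation_args(table: TaxaTable, alpha: float, k: int) -> None:
    if not 0 < alpha <= 1:
        raise ValueError("alpha must be in (0, 1]")
    if k < MIN_PERMUTATIONS:
        raise ValueError(f"k must be >= {MIN_PERMUTATIONS} permutations, got {k}")
    if table.n_taxa < 2:
        raise ValueError("permutation filtering needs at least 2 taxa")


def perfect_permutation_full(table: TaxaTable, alpha: float = DEFAULT_ALPHA,
                             k: int = DEFAULT_K,
                             ordering: TaxaOrdering | None = None,
                             seed: int = 0,
                             tail: str = "fitted") -> FilterResult:
    """Full permutation filtering test (every position j = 1..p-1 evaluated).

    ``tail="fitted"`` (default) uses a skew-normal fitted to the log
    null DFLs; ``tail="empirical"`` uses the +1-smoothed empirical tail.
    Reproducible given ``seed``.
    """
    _check_permutation_args(table, alpha, k)
    if ordering is None:
        ordering = order_taxa(table)
    pv = _PositionPvalues(table, ordering, k, seed, tail)
    j_max = table.n_taxa - 1
    raw = {j: pv(j) for j in range(1, j_max + 1)}
    smoothed = {j: _smooth_window3(pv, j, j_max) for j in range(1, j_max + 1)}
    cutoff = _first_crossing(smoothed, alpha)
    return _build_result("permutation-full", table, ordering, alpha, raw,
                         smoothed, cutoff, k=k, seed=seed)


def perfect_permutation_fast(table: TaxaTable, alpha: float = DEFAULT_ALPHA,
                             k: int = DEFAULT_K,
                             ordering: TaxaOrdering | None = None,
                             seed: int = 0,
                             tail: str = "fitted") -> FilterResult:
    """Fast permutation filtering via galloping + unbalanced binary search.

    Evaluates the smoothed permutation p-value only at probed positions
    and returns the same cutoff as :func:`perfect_permutation_full`
    whenever the significance indicator is monotone in ``j`` with a
    single crossing.  Probed positions are recorded in
    ``FilterResult.probes``; their count is bounded by
    ``2*ceil(log2 p) + 4``.
    """
    _check_permutation_args(table, alpha, k)
    if ordering is None:
        ordering = order_taxa(table)
    pv = _PositionPvalues(table, ordering, k, seed, tail)
    j_max = table.n_taxa - 1
    probes: list[int] = []
    smoothed: dict[int, float] = {}

    def probe(j: int) -> float:
        if j not in smoothed:
            probes.append(j)
            smoothed[j] = _smooth_window3(pv, j, j_max)
        return smoothed[j]

    # galloping phase: 1, 2, 4, 8, ... capped at j_max
    lo, j = 0, 1
    hi: int | None = None
    while True:
        if probe(j) <= alpha:
            hi = j
            break
        if j >= j_max:
            break
        lo, j = j, min(2 * j, j_max)

    if hi is None:
        return _build_result("permutation-fast", table, ordering, alpha,
                             pv._cache, smoothed, None, k=k, seed=seed,
                             probes=probes, monotonize=False)

    # unbalanced binary search for the first crossing inside (lo, hi]
    while hi - lo > 1:
        mid = (lo + hi) // 2
        if probe(mid) <= alpha:
            hi = mid
        else:
            lo = mid
    cutoff = hi

    # verify the final interval boundaries; a violation means the
    # significance indicator is non-monotone inside the interval
    ok = probe(cutoff) <= alpha and (cutoff == 1 or probe(cutoff - 1) > alpha)
    if not ok:
        logger.warning("non-monotone p-value crossing detected near position %d; "
                       "falling back to a linear scan of the interval", cutoff)
        cutoff = None
        for q in range(1, j_max + 1):
            if probe(q) <= alpha:
                cutoff = q
                break

    return _build_result("permutation-fast", table, ordering, alpha, pv._cache,
                         smoothed, cutoff, k=k, seed=seed, probes=probes,
                         monotonize=False)


# ----------------------------------------------------------------------
# rules of thumb
# ----------------------------------------------------------------------

def rule_of_thumb_filter(table: TaxaTable, min_count: int = 0,
                         min_samples: int = 1,
                         min_prevalence_pct: float | None = None) -> FilterResult:
    """Heuristic filter: keep taxa with counts above ``min_count`` in at
    least ``min_samples`` samples.

    When ``min_prevalence_pct`` is given, the prevalence-percent variant
    is used instead: keep taxa present (count > 0) in at least that
    percentage of samples.
    """
    if min_count < 0 or min_samples < 1:
        raise ValueError("min_count must be >= 0 and min_samples >= 1")
    if min_prevalence_pct is not None:
        if not 0 < min_prevalence_pct <= 100:
            raise ValueError("min_prevalence_pct must be in (0, 100]")
        keep = table.presence.sum(axis=0) >= min_prevalence_pct / 100.0 * table.n_samples
    else:
        if min_samples > table.n_samples:
            logger.warning("min_samples=%d exceeds the %d samples available; "
                           "every taxon will be removed", min_samples, table.n_samples)
        keep = (table.counts > min_count).sum(axis=0) >= min_samples
    ids = np.array(table.taxon_ids)
    return FilterResult(method="rule-of-thumb",
                        retained=set(ids[keep]), removed=set(ids[~keep]))
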