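"""Synthetic mock-community generator with per-taxon ground truth.

Two laboratory designs from the mock-community quality-control
literature are emulated so that every analysis in this package can be
exercised without downloading external data:

* **multi-lab mock communities** — a fixed panel of signal taxa with
  known proportions is observed in every sample of every lab, while each
  processing lab additionally produces its own sparse, low-count noise
  taxa (sequencing/classification artifacts specific to a pipeline);
* **dilution series** — one or a few signal taxa are serially diluted
  (10-fold per step by default) so their expected counts shrink with
  dilution level, while reagent contaminants contribute
  dilution-independent expected counts; the contaminant share of each
  sample therefore rises as true biomass falls, and recorded DNA
  concentration decays geometrically with the dilution level.

Counts are Poisson around the per-sample expectations (an optional
gamma-mixing knob adds overdispersion).  Generation is fully
reproducible from the design's seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .filters import FilterResult
from .taxa_table import TaxaTable

LABEL_SIGNAL = "signal"
LABEL_NOISE = "noise"
LABEL_CONTAMINANT = "contaminant"


def geometric_proportions(n: int, ratio: float = 0.85) -> np.ndarray:
    """Decaying abundance profile for a signal panel (sums to 1)."""
    w = ratio ** np.arange(n)
    return w / w.sum()


@dataclass
class MockDesign:
    """Parameters of a synthetic mock-community experiment.

    One sample is generated per (lab, dilution level, replicate); a
    design with a single dilution level ``[0]`` is a plain multi-lab
    mock, a design with one replicate and several levels is a dilution
    series.  ``library_size_mean`` is the expected signal read total of
    an undiluted sample; signal expectations scale by
    ``dilution_factor**(-dilution)`` while contaminant expectations do
    not, and lab-specific noise taxa appear only within their own lab
    with ``noise_prevalence`` presence probability and low Poisson
    counts.
    """

    n_signal: int = 22
    signal_props: np.ndarray | None = None
    n_noise_per_lab: int = 20
    labs: tuple[str, ...] = ("BL-1", "BL-2", "BL-3")
    samples_per_lab: int = 20
    dilution_levels: tuple[int, ...] = (0,)
    dilution_factor: float = 10.0
    n_contaminant: int = 0
    contaminant_mean_count: float = 20.0
    noise_prevalence: float = 0.1
    noise_mean_count: float = 5.0
    library_size_mean: int = 50_000
    dna_conc_base: float = 10.0
    overdispersion: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.signal_props is None:
            self.signal_props = geometric_proportions(self.n_signal)
        props = np.asarray(self.signal_props, dtype=float)
        if props.size != self.n_signal or np.any(props <= 0) or \
                not np.isclose(props.sum(), 1.0):
            raise ValueError("signal_props must be positive and sum to 1 "
                             f"over {self.n_signal} taxa")
        self.signal_props = props / props.sum()
        if self.dilution_factor <= 1:
            raise ValueError("dilution_factor must exceed 1")
        if any(d < 0 for d in self.dilution_levels):
            raise ValueError("dilution levels must be >= 0")
        if not 0 < self.noise_prevalence < 1:
            raise ValueError("noise_prevalence must lie in (0, 1)")
        for name in ("library_size_mean", "contaminant_mean_count",
                     "noise_mean_count", "dna_conc_base"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.samples_per_lab < 1 or self.n_signal < 1:
            raise ValueError("need at least one sample per lab and one signal taxon")


def mbqc_design(seed: int = 0, **overrides) -> MockDesign:
    """Multi-lab oral-mock design: 22 signal taxa, 3 labs x 20 samples,
    20 lab-specific noise taxa per lab, no dilution."""
    return MockDesign(seed=seed, **overrides)


def dilution_design(seed: int = 0, **overrides) -> MockDesign:
    """Dilution-series design: a few signal taxa diluted 10-fold over 6
    levels at 3 institutes, with persistent reagent contaminants.

    The undiluted signal library (1e6 expected reads) dominates
    sequencing output through the middle dilutions, the regime in which
    contaminant frequency is inversely proportional to DNA concentration.
    """
    params = dict(
        n_signal=3, signal_props=np.array([0.7, 0.2, 0.1]),
        labs=("ICL", "UB", "WTSI"), samples_per_lab=1,
        dilution_levels=(0, 1, 2, 3, 4, 5), dilution_factor=10.0,
        n_contaminant=15, contaminant_mean_count=20.0,
        n_noise_per_lab=10, noise_prevalence=0.2, noise_mean_count=3.0,
        library_size_mean=1_000_000, seed=seed,
    )
    params.update(overrides)
    return MockDesign(**params)


@dataclass
class MockTruth:
    """Ground truth emitted with a generated table.

    ``labels`` maps taxon id -> {signal, noise, contaminant};
    ``sample_info`` is indexed by sample id with columns ``lab``,
    ``dilution`` and ``dna_conc`` (= base / factor**dilution).
    """

    labels: dict[str, str]
    sample_info: pd.DataFrame

    def taxa(self, label: str) -> set[str]:
        return {t for t, lab in self.labels.items() if lab == label}

    def to_tsv(self, path: str | Path) -> None:
        pd.Series(self.labels, name="label").rename_axis("taxon_id") \
            .to_csv(path, sep="\t")

    @staticmethod
    def read_labels(path: str | Path) -> dict[str, str]:
        s = pd.read_csv(path, sep="\t", index_col=0)["label"]
        return {str(k): str(v) for k, v in s.items()}


def _draw_counts(rng: np.random.Generator, mean: np.ndarray,
                 overdispersion: float) -> np.ndarray:
    mean = np.clip(mean, 0.0, None)
    if overdispersion > 0:
        # gamma-Poisson mixture: variance = mean * (1 + overdispersion * mean)
        shape = 1.0 / overdispersion
        mean = rng.gamma(shape, mean * overdispersion)
    return rng.poisson(mean)


def generate_mock(design: MockDesign) -> tuple[TaxaTable, MockTruth]:
    """Generate a count table and its ground truth from a design.

    Rows: one sample per (lab, dilution level, replicate).  Columns:
    signal taxa, then per-lab noise taxa, then contaminants — the column
    count is ``n_signal + len(labs) * n_noise_per_lab + n_contaminant``
    regardless of which taxa end up observed.
    """
    rng = np.random.default_rng(design.seed)
    labs = list(design.labs)
    signal_ids = [f"signal_{i + 1:02d}" for i in range(design.n_signal)]
    noise_ids = [f"noise_{lab}_{i + 1:02d}"
                 for lab in labs for i in range(design.n_noise_per_lab)]
    contam_ids = [f"contam_{i + 1:02d}" for i in range(design.n_contaminant)]
    taxon_ids = signal_ids + noise_ids + contam_ids
    noise_lab = {f"noise_{lab}_{i + 1:02d}": lab
                 for lab in labs for i in range(design.n_noise_per_lab)}

    # per-contaminant mean heterogeneity, drawn once per design
    contam_means = design.contaminant_mean_count * \
        rng.lognormal(mean=0.0, sigma=0.5, size=design.n_contaminant)

    sample_rows = []
    sample_ids = []
    meta_rows = []
    for lab in labs:
        for d in design.dilution_levels:
            for r in range(design.samples_per_lab):
                sid = f"{lab}_d{d}_s{r + 1:02d}"
                sample_ids.append(sid)
                scale = design.dilution_factor ** (-d)
                row = np.zeros(len(taxon_ids), dtype=np.int64)
                mu_sig = design.library_size_mean * scale * design.signal_props
                row[: design.n_signal] = _draw_counts(rng, mu_sig,
                                                      design.overdispersion)
                for jn, nid in enumerate(noise_ids, start=design.n_signal):
                    if noise_lab[nid] == lab and \
                            rng.random() < design.noise_prevalence:
                        row[jn] = _draw_counts(
                            rng, np.array([design.noise_mean_count]),
                            design.overdispersion)[0]
                if design.n_contaminant:
                    row[design.n_signal + len(noise_ids):] = _draw_counts(
                        rng, contam_means, design.overdispersion)
                sample_rows.append(row)
                meta_rows.append({
                    "lab": lab, "dilution": d,
                    "dna_conc": design.dna_conc_base
                    / design.dilution_factor ** d,
                })
    counts = np.vstack(sample_rows)
    sample_info = pd.DataFrame(meta_rows,
                               index=pd.Index(sample_ids, name="sample_id"))
    labels = {t: LABEL_SIGNAL for t in signal_ids}
    labels.update({t: LABEL_NOISE for t in noise_ids})
    labels.update({t: LABEL_CONTAMINANT for t in contam_ids})
    table = TaxaTable(counts, sample_ids, taxon_ids, sample_meta=sample_info)
    return table, MockTruth(labels=labels, sample_info=sample_info)


@dataclass
class RecoveryMetrics:
    """How well a filter recovered the mock ground truth."""

    signal_sensitivity: float
    noise_removal_rate: float
    contaminant_removal_rate: float

    def to_dict(self) -> dict[str, float]:
        return {"signal_sensitivity": self.signal_sensitivity,
                "noise_removal_rate": self.noise_removal_rate,
                "contaminant_removal_rate": self.contaminant_removal_rate}


def score_recovery(filt: FilterResult, truth: MockTruth) -> RecoveryMetrics:
    """Signal sensitivity and noise/contaminant removal rates of a filter."""
    universe = filt.retained | filt.removed
    if universe != set(truth.labels):
        raise ValueError("filter result and truth cover different taxa")

    def _rate(label: str, of: set[str]) -> float:
        group = truth.taxa(label)
        if not group:
            return float("nan")
        return len(group & of) / len(group)

    return RecoveryMetrics(
        signal_sensitivity=_rate(LABEL_SIGNAL, filt.retained),
        noise_removal_rate=_rate(LABEL_NOISE, filt.removed),
        contaminant_removal_rate=_rate(LABEL_CONTAMINANT, filt.removed),
    )
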