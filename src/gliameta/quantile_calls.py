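"""Four-bin detection calls of a target gene against per-dataset quantiles.

Every dataset is log2(1+x)-transformed, all gene x sample log2 values are
pooled, and the 25th/50th/75th percentile landmarks of that pool are the
reference against which the target gene's dataset-level value is classified:

* ``above_median`` — at or above the pooled median,
* ``between_q25_and_median`` — in [Q1, median),
* ``below_q25`` — below the first quartile,
* ``not_detected`` — the gene is missing from the matrix (e.g. the limited
  gene detection of a Mars-seq dataset) or is zero in every sample.

These are the bins drawn on per-dataset violin plots and summarized as
"N out of M datasets" per tissue group.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .dataset_io import ExpressionDataset, resolve_target

log = logging.getLogger(__name__)

ABOVE_MEDIAN = "above_median"
BETWEEN_Q25_AND_MEDIAN = "between_q25_and_median"
BELOW_Q25 = "below_q25"
NOT_DETECTED = "not_detected"

#: detection bins ordered from least to most detectable
BIN_ORDER = [NOT_DETECTED, BELOW_Q25, BETWEEN_Q25_AND_MEDIAN, ABOVE_MEDIAN]

#: quantile convention: linear interpolation between order statistics
#: (R type-7 / numpy "linear"), configurable per call
DEFAULT_QUANTILE_METHOD = "linear"


class DomainError(ValueError):
    """Value outside the mathematical domain of an operation."""


def log2_plus_one(values: np.ndarray) -> np.ndarray:
    """Elementwise log2(1+x); adding 1 keeps zero counts at exactly 0."""
    values = np.asarray(values, dtype=float)
    if np.any(values < 0):
        raise DomainError("log2_plus_one requires non-negative inputs")
    return np.log2(1.0 + values)


@dataclass(frozen=True)
class QuantileLandmarks:
    """25th/50th/75th percentiles of a pool of log2 values."""

    q25: float
    q50: float
    q75: float
    n_values: int

    def __post_init__(self) -> None:
        if self.n_values < 1:
            raise ValueError("landmarks require at least one value")
        if not (self.q25 <= self.q50 <= self.q75):
            raise ValueError(
                f"landmarks must be ordered: {self.q25}, {self.q50}, {self.q75}"
            )


@dataclass(frozen=True)
class DetectionCall:
    """The target gene's detection bin in one dataset."""

    dataset_id: str
    value: str
    target_log2: float | None
    landmarks: QuantileLandmarks | None = None
    group: str = "default"
    platform: str = ""
    species: str = ""

    def __post_init__(self) -> None:
        if self.value not in BIN_ORDER:
            raise ValueError(f"unknown detection bin {self.value!r}")
        if (self.value == NOT_DETECTED) != (self.target_log2 is None):
            raise ValueError(
                "not_detected calls and only those must carry an absent target value"
            )


@dataclass(frozen=True)
class DetectionSummary:
    """Per-group counts of datasets by detection bin."""

    group: str
    n_total: int
    n_detected: int
    n_above_median: int
    n_between: int
    n_below_q25: int
    n_not_detected: int

    def __post_init__(self) -> None:
        bins = (self.n_above_median, self.n_between, self.n_below_q25,
                self.n_not_detected)
        if sum(bins) != self.n_total:
            raise ValueError("bin counts must sum to n_total")
        if self.n_detected != self.n_total - self.n_not_detected:
            raise ValueError("n_detected must equal n_total - not_detected")

    @property
    def sentence(self) -> str:
        return f"{self.n_detected} out of {self.n_total}"


@dataclass
class ViolinSummary:
    """Everything needed to draw one dataset's violin: pooled values,
    landmarks, and the target-gene overlay value (None when not detected)."""

    dataset_id: str
    pooled_log2: np.ndarray
    landmarks: QuantileLandmarks
    target_log2: float | None
    group: str = "default"


def landmarks(
    pooled_log2: np.ndarray, method: str = DEFAULT_QUANTILE_METHOD
) -> QuantileLandmarks:
    """Quantile landmarks of a pooled log2-value vector.

    Permutation-invariant; uses linear interpolation between order statistics
    by default (any numpy quantile method name is accepted).
    """
    pooled = np.asarray(pooled_log2, dtype=float).ravel()
    if pooled.size == 0:
        raise ValueError("cannot compute landmarks of an empty vector")
    q25, q50, q75 = np.quantile(pooled, [0.25, 0.5, 0.75], method=method)
    return QuantileLandmarks(float(q25), float(q50), float(q75), int(pooled.size))


def classify(value: float, lm: QuantileLandmarks) -> str:
    """Bin a target log2 value against landmarks (lower bounds closed upward:
    a value exactly at the median counts as above it)."""
    if value >= lm.q50:
        return ABOVE_MEDIAN
    if value >= lm.q25:
        return BETWEEN_Q25_AND_MEDIAN
    return BELOW_Q25


def target_level(ds: ExpressionDataset, target: str) -> float | None:
    """Dataset-level target value: mean over samples of per-sample log2(1+x).

    None when the gene is absent from the matrix or exactly zero in every
    sample (the "not expressed" rule).  The same value feeds both the
    detection call and the module-score table's target column.
    """
    raw = resolve_target(ds, target)
    if raw is None:
        return None
    if not ds.is_log2 and np.all(raw == 0):
        return None
    vec = raw if ds.is_log2 else log2_plus_one(raw)
    return float(np.mean(vec))


def dataset_landmarks(
    ds: ExpressionDataset,
    mode: str = "pooled",
    method: str = DEFAULT_QUANTILE_METHOD,
) -> QuantileLandmarks:
    """Landmarks of one dataset's log2 values.

    ``pooled`` (default) pools all genes and samples into one vector;
    ``per_sample`` computes landmarks per sample and averages each of the
    three landmarks across samples.
    """
    mat = ds.values if ds.is_log2 else log2_plus_one(ds.values)
    if mode == "pooled":
        return landmarks(mat.ravel(), method=method)
    if mode == "per_sample":
        per = np.quantile(mat, [0.25, 0.5, 0.75], axis=0, method=method)
        q25, q50, q75 = per.mean(axis=1)
        return QuantileLandmarks(float(q25), float(q50), float(q75), int(mat.size))
    raise ValueError(f"unknown landmark mode {mode!r}")


def call_target(
    ds: ExpressionDataset,
    target: str,
    mode: str = "pooled",
    method: str = DEFAULT_QUANTILE_METHOD,
) -> DetectionCall:
    """Classify *target* into one of the four detection bins for *ds*."""
    lm = dataset_landmarks(ds, mode=mode, method=method)
    level = target_level(ds, target)
    value = NOT_DETECTED if level is None else classify(level, lm)
    return DetectionCall(
        dataset_id=ds.dataset_id, value=value, target_log2=level,
        landmarks=lm, group=ds.group, platform=ds.platform, species=ds.species,
    )


def summarize_group(calls: Sequence[DetectionCall], group: str) -> DetectionSummary:
    """Count calls per bin for one tissue group ("N out of M" summary)."""
    if not calls:
        raise ValueError("cannot summarize an empty list of calls")
    counts = {b: 0 for b in BIN_ORDER}
    for c in calls:
        counts[c.value] += 1
    n_total = len(calls)
    return DetectionSummary(
        group=group,
        n_total=n_total,
        n_detected=n_total - counts[NOT_DETECTED],
        n_above_median=counts[ABOVE_MEDIAN],
        n_between=counts[BETWEEN_Q25_AND_MEDIAN],
        n_below_q25=counts[BELOW_Q25],
        n_not_detected=counts[NOT_DETECTED],
    )


def violin_table(
    ds_list: Sequence[ExpressionDataset],
    target: str,
    mode: str = "pooled",
    method: str = DEFAULT_QUANTILE_METHOD,
) -> list[ViolinSummary]:
    """One ViolinSummary per dataset, in input (registry) order."""
    out = []
    for ds in ds_list:
        mat = ds.values if ds.is_log2 else log2_plus_one(ds.values)
        pooled = mat.ravel()
        out.append(
            ViolinSummary(
                dataset_id=ds.dataset_id,
                pooled_log2=pooled,
                landmarks=landmarks(pooled, method=method)
                if mode == "pooled"
                else dataset_landmarks(ds, mode=mode, method=method),
                target_log2=target_level(ds, target),
                group=ds.group,
            )
        )
    return out


def calls_frame(calls: Sequence[DetectionCall], target: str) -> pd.DataFrame:
    """Tidy per-dataset call table (detection_calls.tsv layout)."""
    rows = []
    for c in calls:
        lm = c.landmarks
        rows.append({
            "dataset_id": c.dataset_id, "group": c.group,
            "platform": c.platform, "species": c.species, "target": target,
            "target_log2": np.nan if c.target_log2 is None else c.target_log2,
            "q25": lm.q25 if lm else np.nan,
            "q50": lm.q50 if lm else np.nan,
            "q75": lm.q75 if lm else np.nan,
            "call": c.value,
            "detected_above_q25": c.value in (ABOVE_MEDIAN, BETWEEN_Q25_AND_MEDIAN),
        })
    return pd.DataFrame(rows)


def summary_frame(summaries: Sequence[DetectionSummary]) -> pd.DataFrame:
    """Tidy per-group summary table (detection_summary.tsv layout)."""
    return pd.DataFrame([{
        "group": s.group, "n_total": s.n_total, "n_detected": s.n_detected,
        "n_above_median": s.n_above_median, "n_between": s.n_between,
        "n_below_q25": s.n_below_q25, "n_not_detected": s.n_not_detected,
        "sentence": s.sentence,
    } for s in summaries])


def plot_violins(summaries: Sequence[ViolinSummary], path: str) -> str:
    """Render one violin per dataset with landmark lines and target overlay."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(max(4, 0.8 * len(summaries)), 4))
    positions = np.arange(1, len(summaries) + 1)
    ax.violinplot([s.pooled_log2 for s in summaries], positions=positions,
                  showextrema=False)
    for pos, s in zip(positions, summaries):
        for q, style in ((s.landmarks.q25, ":"), (s.landmarks.q50, "-"),
                         (s.landmarks.q75, ":")):
            ax.hlines(q, pos - 0.3, pos + 0.3, linestyles=style,
                      colors="black", linewidth=0.8)
        if s.target_log2 is not None:
            ax.plot(pos, s.target_log2, "o", color="crimson", markersize=5)
        else:
            ax.plot(pos, 0, "x", color="gray", markersize=5)
    ax.set_xticks(positions)
    ax.set_xticklabels([s.dataset_id for s in summaries], rotation=60,
                       ha="right", fontsize=7)
    ax.set_ylabel("log2(1+x) expression")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path
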