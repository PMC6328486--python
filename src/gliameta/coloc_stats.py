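"""Colocalization percentages and sex comparisons from cell-count tables.

Input rows are microscopy field counts from a double-reporter mouse line: per
region (brain area or spinal segment), sex, animal and field, the number of
reporter-positive microglia and the number among them that are also positive
for the target receptor.  The statistics layer computes percent
double-positive per replication unit (animal by default — fields within an
animal are pseudo-replicates — or field), summarizes mean +/- SEM per
(region, sex), and compares sexes with a normality-gated two-sample test:
Shapiro-Wilk on both groups, Welch's t-test when both pass, Mann-Whitney
otherwise.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.stats

log = logging.getLogger(__name__)

DEFAULT_ALPHA = 0.05
#: alpha for the Shapiro-Wilk normality gate
NORMALITY_ALPHA = 0.05

COUNT_COLUMNS = ["region", "sex", "animal_id", "field_id",
                 "n_marker_pos", "n_double_pos"]


@dataclass(frozen=True)
class CellCountRecord:
    """Counts from one microscopic field."""

    region: str
    sex: str
    animal_id: str
    field_id: str
    n_marker_pos: int
    n_double_pos: int

    def __post_init__(self) -> None:
        if self.n_marker_pos < 0:
            raise ValueError("n_marker_pos must be >= 0")
        if not 0 <= self.n_double_pos <= self.n_marker_pos:
            raise ValueError(
                f"{self.region}/{self.animal_id}/{self.field_id}: "
                f"n_double_pos {self.n_double_pos} outside "
                f"[0, {self.n_marker_pos}]"
            )


@dataclass(frozen=True)
class RegionSummary:
    """Mean +/- SEM percent double-positive for one (region, sex)."""

    region: str
    sex: str
    n_units: int
    mean_pct: float
    sem: float | None
    unit: str

    def __post_init__(self) -> None:
        if not 0.0 <= self.mean_pct <= 100.0:
            raise ValueError(f"mean percentage out of [0,100]: {self.mean_pct}")
        if self.sem is not None and self.sem < 0:
            raise ValueError("SEM must be non-negative")


@dataclass(frozen=True)
class SexComparison:
    """Normality-gated two-sample comparison of female vs male percentages."""

    region: str
    test_used: str                 # "unpaired_t" or "mann_whitney"
    statistic: float
    p: float
    normality_p_female: float | None
    normality_p_male: float | None
    n_female: int
    n_male: int
    significant: bool
    alpha: float = DEFAULT_ALPHA


def percent_positive(rec: CellCountRecord) -> float | None:
    """Percent double-positive in one field; None (skip, logged) when the
    field has no reporter-positive cells to form a denominator."""
    if rec.n_marker_pos == 0:
        log.info("%s/%s/%s: no marker-positive cells; field skipped",
                 rec.region, rec.animal_id, rec.field_id)
        return None
    return 100.0 * rec.n_double_pos / rec.n_marker_pos


def read_counts(path: str | Path) -> list[CellCountRecord]:
    """Read a counts TSV (region, sex, animal_id, field_id, n_marker_pos,
    n_double_pos; an optional ``segment`` column is folded into region)."""
    frame = pd.read_csv(path, sep="\t", dtype=str)
    if "segment" in frame.columns and "region" not in frame.columns:
        frame = frame.rename(columns={"segment": "region"})
    missing = [c for c in COUNT_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"{path}: missing count columns {missing}")
    return [
        CellCountRecord(
            region=str(r["region"]), sex=str(r["sex"]),
            animal_id=str(r["animal_id"]), field_id=str(r["field_id"]),
            n_marker_pos=int(r["n_marker_pos"]),
            n_double_pos=int(r["n_double_pos"]),
        )
        for _, r in frame.iterrows()
    ]


def unit_percentages(
    records: Sequence[CellCountRecord], unit: str = "animal"
) -> dict[tuple[str, str], list[float]]:
    """Replication-unit percentages keyed by (region, sex).

    ``animal`` pools counts within each animal (sum double / sum marker);
    ``field`` treats every field as a unit.  Fields with zero denominator are
    skipped (animal pooling still uses their zero counts harmlessly).
    """
    if unit not in ("animal", "field"):
        raise ValueError(f"unknown replication unit {unit!r}")
    out: dict[tuple[str, str], list[float]] = {}
    if unit == "field":
        for rec in records:
            pct = percent_positive(rec)
            if pct is not None:
                out.setdefault((rec.region, rec.sex), []).append(pct)
        return out
    pooled: dict[tuple[str, str, str], list[int]] = {}
    for rec in records:
        key = (rec.region, rec.sex, rec.animal_id)
        tot = pooled.setdefault(key, [0, 0])
        tot[0] += rec.n_double_pos
        tot[1] += rec.n_marker_pos
    for (region, sex, animal), (dbl, marker) in pooled.items():
        if marker == 0:
            log.info("%s/%s: animal %s has no marker-positive cells; skipped",
                     region, sex, animal)
            continue
        out.setdefault((region, sex), []).append(100.0 * dbl / marker)
    return out


def summarize_region(
    records: Sequence[CellCountRecord], unit: str = "animal"
) -> list[RegionSummary]:
    """Mean +/- SEM of unit percentages per (region, sex).

    SEM = sd/sqrt(n) with the sample (n-1) sd; with a single unit the mean is
    reported and the SEM is absent rather than zero.
    """
    summaries = []
    for (region, sex), pcts in unit_percentages(records, unit).items():
        arr = np.asarray(pcts, dtype=float)
        sem = float(arr.std(ddof=1) / np.sqrt(arr.size)) if arr.size >= 2 else None
        if sem is None:
            log.warning("%s/%s: single replication unit; SEM not defined",
                        region, sex)
        summaries.append(RegionSummary(
            region=region, sex=sex, n_units=int(arr.size),
            mean_pct=float(arr.mean()), sem=sem, unit=unit,
        ))
    return summaries


def compare_sexes(
    group_female: Sequence[float],
    group_male: Sequence[float],
    region: str = "",
    alpha: float = DEFAULT_ALPHA,
    force_test: str | None = None,
    equal_var: bool = True,
) -> SexComparison:
    """Compare female vs male unit percentages.

    Both groups are tested for normality (Shapiro-Wilk at alpha 0.05; groups
    of fewer than 3 units cannot be assessed and fail the gate).  Both pass
    -> two-sided unpaired Student's t-test (pooled variance; with the
    two-to-three animals per sex typical of these cohorts the pooled test
    holds its nominal level, whereas Welch's degrees-of-freedom approximation
    is noticeably conservative — pass ``equal_var=False`` for Welch);
    otherwise two-sided Mann-Whitney with mid-rank tie handling (exact null
    when sample sizes allow).  *force_test* overrides the gate
    ("unpaired_t" or "mann_whitney").
    """
    f = np.asarray(group_female, dtype=float)
    m = np.asarray(group_male, dtype=float)
    if f.size < 2 or m.size < 2:
        raise ValueError("compare_sexes requires >= 2 units per group")

    def _shapiro_p(x: np.ndarray) -> float | None:
        if x.size < 3 or np.ptp(x) == 0:
            return None
        return float(scipy.stats.shapiro(x).pvalue)

    pf, pm = _shapiro_p(f), _shapiro_p(m)
    if force_test is None:
        both_normal = (pf is not None and pf > NORMALITY_ALPHA
                       and pm is not None and pm > NORMALITY_ALPHA)
        test = "unpaired_t" if both_normal else "mann_whitney"
    elif force_test in ("unpaired_t", "mann_whitney"):
        test = force_test
    else:
        raise ValueError(f"unknown test {force_test!r}")

    if test == "unpaired_t":
        res = scipy.stats.ttest_ind(f, m, equal_var=equal_var)
        stat, p = float(res.statistic), float(res.pvalue)
        if np.isnan(p):  # identical constant groups
            stat, p = 0.0, 1.0
    else:
        res = scipy.stats.mannwhitneyu(f, m, alternative="two-sided",
                                       method="auto")
        stat, p = float(res.statistic), float(res.pvalue)
    return SexComparison(
        region=region, test_used=test, statistic=stat, p=p,
        normality_p_female=pf, normality_p_male=pm,
        n_female=int(f.size), n_male=int(m.size),
        significant=p <= alpha, alpha=alpha,
    )


def compare_all_regions(
    records: Sequence[CellCountRecord],
    unit: str = "animal",
    alpha: float = DEFAULT_ALPHA,
) -> list[SexComparison]:
    """Run the sex comparison for every region with both sexes present."""
    per_unit = unit_percentages(records, unit)
    regions = sorted({r for r, _ in per_unit})
    out = []
    for region in regions:
        f = per_unit.get((region, "female"), [])
        m = per_unit.get((region, "male"), [])
        if len(f) < 2 or len(m) < 2:
            log.warning("%s: fewer than 2 units in one sex; comparison skipped",
                        region)
            continue
        out.append(compare_sexes(f, m, region=region, alpha=alpha))
    return out


def region_frame(summaries: Sequence[RegionSummary]) -> pd.DataFrame:
    return pd.DataFrame([{
        "region": s.region, "sex": s.sex, "unit": s.unit, "n_units": s.n_units,
        "mean_pct": s.mean_pct, "sem": np.nan if s.sem is None else s.sem,
    } for s in summaries])


def comparisons_frame(comparisons: Sequence[SexComparison]) -> pd.DataFrame:
    return pd.DataFrame([{
        "region": c.region, "test_used": c.test_used, "statistic": c.statistic,
        "p": c.p, "normality_p_female": c.normality_p_female,
        "normality_p_male": c.normality_p_male, "n_female": c.n_female,
        "n_male": c.n_male, "significant": c.significant,
    } for c in comparisons])
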