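"""Cross-dataset z-scoring and Spearman correlation of target vs modules.

Within one tissue group the dataset-level scores (target gene and each
module) are standardized across datasets to z-scores, declared outlier
datasets are excluded, and the target column is correlated with every module
column using Spearman's rank correlation.

rho is the Pearson correlation of mid-ranks.  The two-sided p-value is
computed by *exact permutation enumeration* for small n — every assignment of
y-ranks to x-ranks is counted — and by the usual t-distribution approximation
above the configurable exact threshold.  Tie-free enumeration is done with a
dynamic program over the distribution of the rank cross-product, which keeps
the exact path cheap well past the point where listing all n! permutations
becomes infeasible; with ties present the observed tied values themselves are
permuted (a conditional null), which is limited to n small enough to
enumerate outright.

Because ranks are invariant under any strictly increasing transform, the
z-score step cannot change rho or its p-value; it standardizes the scores for
display only.  That invariance is asserted by the test suite.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.stats
from statsmodels.stats.multitest import multipletests

from .dataset_io import DatasetRecord
from .module_scores import ModuleScoreTable

log = logging.getLogger(__name__)

DEFAULT_ALPHA = 0.05
#: n at or below which p-values come from exact permutation enumeration
DEFAULT_EXACT_THRESHOLD = 8
#: with ties, exact enumeration lists n! permutations outright; cap n
MAX_ENUMERATION_N = 9
#: |z| beyond which a dataset's Microglia score earns an advisory flag
ADVISORY_Z = 2.5

_EPS = 1e-12


class ConstantInputError(ValueError):
    """A statistic is undefined because the input vector is constant."""


def zscore(values: np.ndarray) -> np.ndarray:
    """Standardize with the sample (n-1) standard deviation.

    Errors on constant input rather than returning silent zeros — a constant
    column carries no rank information and must be handled explicitly.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("zscore requires a 1-D vector with n >= 2")
    sd = x.std(ddof=1)
    if sd == 0:
        raise ConstantInputError("cannot z-score a constant vector")
    return (x - x.mean()) / sd


@dataclass
class ZScoreMatrix:
    """Cross-dataset z-scores for one tissue group, with the exclusion log."""

    group: str
    frame: pd.DataFrame                  # rows: retained dataset_ids
    exclusions: list[dict] = field(default_factory=list)
    advisories: list[dict] = field(default_factory=list)


@dataclass(frozen=True)
class CorrelationResult:
    """Spearman rho and p for one (target, module) pair in one group."""

    group: str
    target: str
    module: str
    n: int
    rho: float
    p: float
    p_method: str            # "exact_permutation" or "t_approximation"
    significant: bool
    alpha: float = DEFAULT_ALPHA

    def __post_init__(self) -> None:
        if not -1.0 - 1e-9 <= self.rho <= 1.0 + 1e-9:
            raise ValueError(f"rho out of range: {self.rho}")
        if not 0.0 < self.p <= 1.0:
            raise ValueError(f"p out of range: {self.p}")
        if self.significant != (self.p <= self.alpha):
            raise ValueError("significance flag inconsistent with p and alpha")


# ---------------------------------------------------------------------------
# Spearman rho and exact permutation p
# ---------------------------------------------------------------------------

def _midranks(x: np.ndarray) -> np.ndarray:
    return scipy.stats.rankdata(x, method="average")


def _rank_pearson(rx: np.ndarray, ry: np.ndarray) -> float:
    rxc = rx - rx.mean()
    ryc = ry - ry.mean()
    denom = math.sqrt(float(rxc @ rxc) * float(ryc @ ryc))
    return float(rxc @ ryc) / denom


@lru_cache(maxsize=32)
def _rank_product_null(n: int) -> tuple[np.ndarray, np.ndarray]:
    """Exact null distribution of T = sum(i * pi(i)) over permutations pi of
    1..n, as (support, counts).  Dynamic program over rank subsets: masks are
    processed in popcount order; position k+1 receives each unused rank."""
    t_max = sum(i * i for i in range(1, n + 1))
    full = (1 << n) - 1
    table = np.zeros((1 << n, t_max + 1), dtype=float)
    table[0, 0] = 1.0
    masks_by_pop: list[list[int]] = [[] for _ in range(n + 1)]
    for mask in range(1 << n):
        masks_by_pop[bin(mask).count("1")].append(mask)
    for pop in range(n):
        pos = pop + 1  # next position to fill
        for mask in masks_by_pop[pop]:
            row = table[mask]
            if not row.any():
                continue
            for rank in range(1, n + 1):
                bit = 1 << (rank - 1)
                if mask & bit:
                    continue
                shift = pos * rank
                table[mask | bit, shift:] += row[: t_max + 1 - shift]
    dist = table[full]
    support = np.nonzero(dist)[0]
    return support, dist[support]


def _exact_p_no_ties(rx: np.ndarray, ry: np.ndarray) -> float:
    """Exact two-sided p for tie-free ranks via the DP null of T = sum x_i*y_i."""
    n = rx.size
    t_obs = float(rx @ ry)
    support, counts = _rank_product_null(n)
    mu = n * (n + 1) ** 2 / 4.0
    scale = (n * (n * n - 1)) / 12.0
    rho_support = (support - mu) / scale
    rho_obs = (t_obs - mu) / scale
    mask = np.abs(rho_support) >= abs(rho_obs) - _EPS
    return float(counts[mask].sum() / math.factorial(n))


def _exact_p_enumerate(rx: np.ndarray, ry: np.ndarray) -> float:
    """Exact two-sided p by full enumeration of permutations of the observed
    y mid-ranks (conditional null under ties)."""
    n = rx.size
    perms = np.array(list(itertools.permutations(ry)), dtype=float)
    rxc = rx - rx.mean()
    pc = perms - perms.mean(axis=1, keepdims=True)
    denom = np.sqrt(float(rxc @ rxc) * (pc * pc).sum(axis=1))
    rhos = pc @ rxc / denom
    rho_obs = _rank_pearson(rx, ry)
    return float(np.mean(np.abs(rhos) >= abs(rho_obs) - _EPS))


def _t_approx_p(rho: float, n: int) -> float:
    if abs(rho) >= 1.0:
        return 0.0  # clamped to the smallest positive float by the caller
    t = rho * math.sqrt((n - 2) / (1.0 - rho * rho))
    return float(2.0 * scipy.stats.t.sf(abs(t), df=n - 2))


@dataclass(frozen=True)
class SpearmanResult:
    rho: float
    p: float
    method: str
    n: int


def spearman(
    x: Sequence[float],
    y: Sequence[float],
    exact_threshold: int = DEFAULT_EXACT_THRESHOLD,
) -> SpearmanResult:
    """Spearman rank correlation with exact-permutation or t-approximate p.

    rho is the Pearson correlation of mid-ranks (average ranks for ties).
    For n <= *exact_threshold* the two-sided p counts permutations with
    |rho_perm| >= |rho_obs|; above it the t approximation with n-2 degrees of
    freedom is used.  The method actually applied is recorded in the result.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    n = x.size
    if n < 3:
        raise ValueError("spearman requires n >= 3")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ConstantInputError("spearman is undefined for constant input")
    rx, ry = _midranks(x), _midranks(y)
    rho = _rank_pearson(rx, ry)
    has_ties = (np.unique(rx).size < n) or (np.unique(ry).size < n)
    if n <= exact_threshold:
        if not has_ties:
            p = _exact_p_no_ties(rx, ry)
            method = "exact_permutation"
        elif n <= MAX_ENUMERATION_N:
            log.info("spearman: ties present at n=%d; enumerating the "
                     "conditional permutation null", n)
            p = _exact_p_enumerate(rx, ry)
            method = "exact_permutation"
        else:
            log.warning("spearman: ties at n=%d exceed enumeration limit; "
                        "falling back to t approximation", n)
            p = _t_approx_p(rho, n)
            method = "t_approximation"
    else:
        p = _t_approx_p(rho, n)
        method = "t_approximation"
    p = min(max(p, np.nextafter(0, 1)), 1.0)
    return SpearmanResult(rho=rho, p=p, method=method, n=n)


# ---------------------------------------------------------------------------
# group-level orchestration
# ---------------------------------------------------------------------------

def apply_exclusions(
    table: ModuleScoreTable,
    registry: Sequence[DatasetRecord] | Mapping[str, bool],
    group: str = "default",
    advisory_z: float = ADVISORY_Z,
) -> ZScoreMatrix:
    """Drop datasets flagged ``include_in_correlation=false``, z-score the
    retained rows, and flag (never remove) extreme Microglia z-scores.

    The advisory flag marks datasets whose Microglia-module z exceeds
    |z| > *advisory_z* as candidates for the "varied substantially from all
    other datasets" judgement, which remains a registry decision.
    """
    if isinstance(registry, Mapping):
        include = dict(registry)
    else:
        include = {r.dataset_id: r.include_in_correlation for r in registry}
    scores = table.dataset_scores
    exclusions = []
    keep = []
    for ds_id in scores.index:
        if include.get(ds_id, True):
            keep.append(ds_id)
        else:
            exclusions.append({"dataset_id": ds_id,
                               "reason": "registry include_in_correlation=false"})
            log.warning("%s: dataset %s excluded from correlation (registry flag)",
                        group, ds_id)
    if len(keep) < 3:
        raise ValueError(
            f"{group}: only {len(keep)} datasets retained after exclusion; "
            "at least 3 are required for a correlation"
        )
    retained = scores.loc[keep]
    zframe = pd.DataFrame(index=retained.index, columns=retained.columns,
                          dtype=float)
    for col in retained.columns:
        vals = retained[col].to_numpy(dtype=float)
        ok = ~np.isnan(vals)
        if ok.sum() >= 2 and np.unique(vals[ok]).size > 1:
            z = np.full(vals.shape, np.nan)
            z[ok] = zscore(vals[ok])
            zframe[col] = z
        else:
            zframe[col] = np.nan
            log.warning("%s: column %s constant or too sparse to z-score",
                        group, col)
    advisories = []
    if "Microglia" in zframe.columns:
        mz = zframe["Microglia"]
        for ds_id, z in mz.items():
            if np.isfinite(z) and abs(z) > advisory_z:
                advisories.append({"dataset_id": ds_id, "column": "Microglia",
                                   "z": float(z)})
                log.warning("%s: advisory — %s Microglia z=%.2f exceeds |z|>%.1f",
                            group, ds_id, z, advisory_z)
    return ZScoreMatrix(group=group, frame=zframe, exclusions=exclusions,
                        advisories=advisories)


def correlate_group(
    zm: ZScoreMatrix,
    target: str,
    alpha: float = DEFAULT_ALPHA,
    exact_threshold: int = DEFAULT_EXACT_THRESHOLD,
) -> list[CorrelationResult]:
    """Spearman rho/p of the target column against every module column.

    No multiple-testing adjustment is applied to the per-module results
    (per-comparison alpha); :func:`correlations_frame` additionally emits a
    Holm-adjusted column for users who want family-wise control.
    """
    if target not in zm.frame.columns:
        raise ValueError(f"target column {target!r} absent from z-score matrix")
    tcol = zm.frame[target]
    results = []
    for module in zm.frame.columns:
        if module == target:
            continue
        pair = pd.concat([tcol, zm.frame[module]], axis=1).dropna()
        if len(pair) < 3:
            log.warning("%s: %s vs %s has n=%d < 3; skipped",
                        zm.group, target, module, len(pair))
            continue
        x = pair.iloc[:, 0].to_numpy()
        y = pair.iloc[:, 1].to_numpy()
        try:
            res = spearman(x, y, exact_threshold=exact_threshold)
        except ConstantInputError:
            log.warning("%s: %s vs %s constant after NaN removal; skipped",
                        zm.group, target, module)
            continue
        results.append(CorrelationResult(
            group=zm.group, target=target, module=module, n=res.n,
            rho=res.rho, p=res.p, p_method=res.method,
            significant=res.p <= alpha, alpha=alpha,
        ))
    return results


def significance_stars(p: float) -> str:
    """Figure-legend star convention: * <=0.05, ** <=0.01, *** <=0.001,
    **** <=0.0001."""
    for stars, cut in (("****", 1e-4), ("***", 1e-3), ("**", 1e-2), ("*", 0.05)):
        if p <= cut:
            return stars
    return ""


def correlations_frame(results: Sequence[CorrelationResult]) -> pd.DataFrame:
    """Tidy correlation table with stars and a labelled Holm-adjusted column."""
    frame = pd.DataFrame([{
        "group": r.group, "target": r.target, "module": r.module, "n": r.n,
        "rho": r.rho, "p": r.p, "p_method": r.p_method,
        "significant": r.significant, "stars": significance_stars(r.p),
    } for r in results])
    if len(frame):
        frame["p_holm_nonpaper"] = np.nan
        for grp, sub in frame.groupby("group"):
            adj = multipletests(sub["p"].to_numpy(), method="holm")[1]
            frame.loc[sub.index, "p_holm_nonpaper"] = adj
    return frame


def zscores_frame(zm: ZScoreMatrix) -> pd.DataFrame:
    """Long-format z-score table (group, dataset_id, column, z)."""
    melted = zm.frame.reset_index(names="dataset_id").melt(
        id_vars="dataset_id", var_name="column", value_name="z")
    melted.insert(0, "group", zm.group)
    return melted
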