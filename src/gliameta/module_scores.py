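"""Gene-module (signature) registry and mean-log2 module scoring.

A module is a curated set of genes that characterizes a cell type (Microglia,
Macrophage, ...) or an activation state (Interferon, LPS, ...).  Its score in
a sample is the arithmetic mean of the module genes' log2(1+x) values; the
dataset-level score is the mean of the per-sample scores.  The default
registry ships eleven modules in three categories (myeloid, activation,
neuron/astrocyte) with representative marker genes; users reproducing a
specific published analysis should substitute the exact curated lists from
that analysis' source, which are not redistributed here.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .dataset_io import ExpressionDataset, canonical_symbol
from .quantile_calls import target_level

log = logging.getLogger(__name__)

CATEGORIES = frozenset({"myeloid", "activation", "neuron_astro"})

#: minimum fraction of module genes that must be present in a matrix before
#: the score is considered well-covered
DEFAULT_COVERAGE_THRESHOLD = 0.5


@dataclass
class GeneModule:
    """A named gene set with species-specific symbol spellings."""

    name: str
    category: str
    symbols: dict[str, list[str]]  # species -> symbols in that species' spelling
    provenance: str = ""

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(
                f"module {self.name!r}: unknown category {self.category!r}; "
                f"allowed: {sorted(CATEGORIES)}"
            )
        if not any(self.symbols.get(sp) for sp in self.symbols):
            raise ValueError(f"module {self.name!r} has no genes")

    def symbols_for(self, species: str) -> list[str]:
        syms = self.symbols.get(species, [])
        if not syms:
            raise ValueError(
                f"module {self.name!r} has no genes for species {species!r}"
            )
        return syms

    def keys_for(self, species: str) -> list[str]:
        return [canonical_symbol(s) for s in self.symbols_for(species)]


@dataclass
class ModuleScore:
    """Score of one module in one dataset."""

    dataset_id: str
    module: str
    per_sample: np.ndarray | None
    dataset_mean: float | None
    coverage: float
    n_present: int
    n_total: int
    low_coverage: bool


@dataclass
class ModuleScoreTable:
    """Dataset x (modules + target) score matrix with per-sample companion.

    ``dataset_scores`` holds dataset-level mean-log2 scores (NaN marks an
    absent score, e.g. the target gene missing from a Mars-seq matrix);
    ``coverage`` the fraction of module genes found in each matrix;
    ``low_coverage`` flags cells under the coverage threshold.
    """

    target: str
    dataset_scores: pd.DataFrame
    sample_scores: pd.DataFrame
    coverage: pd.DataFrame
    low_coverage: pd.DataFrame

    @property
    def module_names(self) -> list[str]:
        return [c for c in self.dataset_scores.columns if c != self.target]


def _module_rows(modules: Iterable[GeneModule]) -> pd.DataFrame:
    rows = []
    for m in modules:
        for species, syms in m.symbols.items():
            for s in syms:
                rows.append({"module": m.name, "category": m.category,
                             "species": species, "symbol": s})
    return pd.DataFrame(rows)


def _modules_from_rows(rows: pd.DataFrame, provenance: str = "") -> list[GeneModule]:
    required = {"module", "category", "species", "symbol"}
    missing = required - set(rows.columns)
    if missing:
        raise ValueError(f"module table missing columns {sorted(missing)}")
    modules: list[GeneModule] = []
    seen: set[str] = set()
    for name, sub in rows.groupby("module", sort=False):
        if name in seen:
            raise ValueError(f"duplicate module name {name!r}")
        seen.add(name)
        cats = sub["category"].unique()
        if len(cats) != 1:
            raise ValueError(f"module {name!r} appears in several categories: {cats}")
        symbols = {
            sp: list(dict.fromkeys(s["symbol"]))
            for sp, s in sub.groupby("species", sort=False)
        }
        modules.append(GeneModule(str(name), str(cats[0]), symbols, provenance))
    if not modules:
        raise ValueError("module table defines no modules")
    return modules


def load_modules(path: str | Path) -> list[GeneModule]:
    """Load a module registry from TSV (module, category, species, symbol
    columns) or JSON (list of {name, category, symbols:{species:[...]}})."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        payload = json.loads(path.read_text())
        modules = []
        names = set()
        for entry in payload:
            if entry["name"] in names:
                raise ValueError(f"duplicate module name {entry['name']!r}")
            names.add(entry["name"])
            modules.append(GeneModule(
                entry["name"], entry["category"],
                {sp: list(v) for sp, v in entry["symbols"].items()},
                entry.get("provenance", str(path)),
            ))
        if not modules:
            raise ValueError(f"{path}: no modules defined")
        return modules
    rows = pd.read_csv(path, sep="\t", dtype=str)
    return _modules_from_rows(rows, provenance=str(path))


def default_modules() -> list[GeneModule]:
    """The packaged eleven-module registry (3 myeloid + 4 activation +
    4 neuron/astrocyte), built from representative markers."""
    with resources.files("gliameta").joinpath("data/default_modules.tsv").open() as fh:
        rows = pd.read_csv(fh, sep="\t", dtype=str)
    return _modules_from_rows(rows, provenance="gliameta default registry")


def load_cross_expression(path: str | Path) -> dict[str, set[str]]:
    """Cross-expression table: symbol -> set of cell types expressing it."""
    rows = pd.read_csv(path, sep="\t", dtype=str)
    table: dict[str, set[str]] = {}
    for _, r in rows.iterrows():
        table.setdefault(canonical_symbol(r["symbol"]), set()).add(
            r["cell_type"].strip().lower())
    return table


def filter_exclusive(
    modules: Sequence[GeneModule],
    cross_expression: Mapping[str, set[str]],
) -> tuple[list[GeneModule], list[dict]]:
    """Drop module genes that the cross-expression table marks as expressed
    by any cell type other than the module's own.

    Returns the filtered modules and a removal log (module, symbol, reason).
    A module whose genes are all removed is an error, not an empty module.
    """
    filtered: list[GeneModule] = []
    removals: list[dict] = []
    for m in modules:
        own = m.name.strip().lower()
        new_symbols: dict[str, list[str]] = {}
        for species, syms in m.symbols.items():
            kept = []
            for s in syms:
                others = {
                    ct for ct in cross_expression.get(canonical_symbol(s), set())
                    if ct != own
                }
                if others:
                    removals.append({
                        "module": m.name, "species": species, "symbol": s,
                        "reason": f"expressed by {', '.join(sorted(others))}",
                    })
                    log.info("filter_exclusive: removed %s from %s (%s)",
                             s, m.name, sorted(others))
                else:
                    kept.append(s)
            new_symbols[species] = kept
        if not any(new_symbols.values()):
            raise ValueError(
                f"module {m.name!r} emptied by the cross-expression filter"
            )
        filtered.append(GeneModule(m.name, m.category, new_symbols, m.provenance))
    return filtered, removals


def score_module(ds: ExpressionDataset, module: GeneModule,
                 coverage_threshold: float = DEFAULT_COVERAGE_THRESHOLD) -> ModuleScore:
    """Mean log2 score of *module* in *ds* (which must be log2-transformed).

    The mean runs over the module genes present in the matrix; genes missing
    from the platform's panel reduce coverage rather than being imputed as
    zero.  A score over no genes at all is reported as absent, not 0.
    """
    if not ds.is_log2:
        raise ValueError(f"{ds.dataset_id}: dataset must be log2-transformed "
                         "before scoring (use ExpressionDataset.to_log2)")
    wanted = set(module.keys_for(ds.species))
    idx = [i for i, k in enumerate(ds.symbol_keys) if k in wanted]
    n_total = len(wanted)
    coverage = len(idx) / n_total
    if not idx:
        return ModuleScore(ds.dataset_id, module.name, None, None,
                           0.0, 0, n_total, True)
    per_sample = ds.values[idx, :].mean(axis=0)
    low = coverage < coverage_threshold
    if low:
        log.warning("%s: module %s coverage %.2f below threshold %.2f",
                    ds.dataset_id, module.name, coverage, coverage_threshold)
    return ModuleScore(ds.dataset_id, module.name, per_sample,
                       float(per_sample.mean()), coverage, len(idx), n_total, low)


def score_all(
    ds_list: Sequence[ExpressionDataset],
    modules: Sequence[GeneModule],
    target: str,
    coverage_threshold: float = DEFAULT_COVERAGE_THRESHOLD,
) -> ModuleScoreTable:
    """Score every module and the target gene in every dataset.

    The target column reuses the exact dataset-level value that the detection
    call is made on, so the two stages can never disagree.
    """
    names = [m.name for m in modules]
    ids = [ds.dataset_id for ds in ds_list]
    scores = pd.DataFrame(np.nan, index=ids, columns=names + [target])
    coverage = pd.DataFrame(np.nan, index=ids, columns=names)
    low = pd.DataFrame(False, index=ids, columns=names)
    sample_rows = []
    for ds in ds_list:
        ds2 = ds.to_log2()
        for m in modules:
            ms = score_module(ds2, m, coverage_threshold)
            coverage.loc[ds.dataset_id, m.name] = ms.coverage
            low.loc[ds.dataset_id, m.name] = ms.low_coverage
            if ms.dataset_mean is not None:
                scores.loc[ds.dataset_id, m.name] = ms.dataset_mean
                for sid, val in zip(ds.sample_ids, ms.per_sample):
                    sample_rows.append({
                        "dataset_id": ds.dataset_id, "sample_id": sid,
                        "column": m.name, "score": float(val),
                    })
        level = target_level(ds2, target)
        if level is not None:
            scores.loc[ds.dataset_id, target] = level
    sample_scores = pd.DataFrame(
        sample_rows, columns=["dataset_id", "sample_id", "column", "score"]
    )
    return ModuleScoreTable(target, scores, sample_scores, coverage, low)
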