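"""Synthetic dataset collections and cell-count tables with planted truth.

The generator emulates the kind of evidence the meta-analysis consumes — a
collection of 5-17 purified-microglia expression datasets per tissue group,
heterogeneous in platform — with every quantity of interest planted and
recorded in a manifest, so each pipeline stage can be tested against known
ground truth:

* per-gene baseline abundances on the log2 scale, with cell-type module
  genes shifted up (Microglia strongly, e.g. +3 log2 units; other modules
  mildly), mirroring what purified microglia actually look like;
* platform noise: log-normal intensities for microarray, negative-binomial
  counts for RNA-seq, and RNA-seq plus gene-level dropout for Mars-seq-like
  data, where lowly expressed genes disappear from the gene list entirely;
* the target gene either pinned to a chosen detection bin (via the pooled
  log2 quantile of the generated matrix) or tied to a named module with a
  chosen cross-dataset Spearman correlation, planted through a Gaussian
  copula on per-dataset latent effects;
* colocalization count tables: Poisson cells per field, binomial
  double-positives at a per-(region, sex) true fraction.

Everything is driven by one integer seed; a fixed seed reproduces the
collection byte-for-byte.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from .dataset_io import (
    DatasetRecord,
    ExpressionDataset,
    write_expression_matrix,
    write_registry,
)
from .module_scores import GeneModule, default_modules

#: default planted log2 shifts per module: Microglia dominant, others mild
DEFAULT_MODULE_SHIFTS = {
    "Microglia": 3.0,
    "Macrophage": 1.0,
    "Neutrophil_Monocyte": 0.5,
    "Interferon": 0.5,
    "Proliferation": 1.0,
    "LPS": 0.5,
    "Neurodegeneration": 0.0,
    "Neuron": 0.0,
    "Excitatory": 0.0,
    "GABAergic": 0.0,
    "Astrocyte": 0.5,
}

TARGET_BINS = ("above_median", "between_q25_and_median", "below_q25",
               "not_detected")

#: pooled-quantile positions at which a planted bin places the target
_BIN_QUANTILE = {
    "above_median": 0.75,
    "between_q25_and_median": 0.375,
    "below_q25": 0.10,
}


@dataclass
class SyntheticCollectionConfig:
    """Study conditions for one synthetic dataset collection."""

    seed: int = 0
    n_datasets: int = 12
    n_genes: int = 12000
    n_samples_range: tuple[int, int] = (1, 6)
    platforms: tuple[str, ...] = ("microarray", "rnaseq")  # cycled over datasets
    species: str = "mouse"
    tissue: str = "whole_brain"
    group: str = "whole_brain"
    target_symbol: str = "Oprm1"
    module_shifts: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_MODULE_SHIFTS))
    #: per-(dataset, module) random effect sd, log2 units
    module_effect_sd: float = 0.5
    #: cross-dataset latent sd for the target (and the rho-linked module)
    latent_sd: float = 1.5
    #: baseline gene abundance: log2 means ~ Normal(base_mean, base_sd), >= 0
    base_mean_log2: float = 4.0
    base_sd_log2: float = 2.0
    target_base_log2: float = 3.0
    #: microarray within-sample log2 noise sd
    microarray_sd: float = 0.25
    #: negative binomial dispersion (var = mu + disp * mu^2)
    nb_dispersion: float = 0.3
    #: sc_like gene-level dropout: remove genes in the lowest abundance stratum
    dropout_quantile: float = 0.7
    #: planted detection bin (same for every dataset), or None
    target_bin: str | None = None
    #: planted cross-dataset Spearman correlation with `rho_module`, or None
    target_rho: float | None = None
    rho_module: str = "Microglia"

    def __post_init__(self) -> None:
        if self.target_bin is not None and self.target_rho is not None:
            raise ValueError(
                "config requests both a planted detection bin and a planted "
                "correlation; choose one"
            )
        if self.target_bin is not None and self.target_bin not in TARGET_BINS:
            raise ValueError(f"unknown target bin {self.target_bin!r}")
        if self.target_rho is not None and not -1.0 <= self.target_rho <= 1.0:
            raise ValueError("planted rho must lie in [-1, 1]")
        if not 0.0 <= self.dropout_quantile <= 1.0:
            raise ValueError("dropout quantile must lie in [0, 1]")
        if self.n_datasets < 1 or self.n_genes < 200:
            raise ValueError("need at least 1 dataset and 200 genes")
        lo, hi = self.n_samples_range
        if not 1 <= lo <= hi:
            raise ValueError("invalid n_samples_range")


@dataclass
class SyntheticCollection:
    """Generated datasets plus registry records and the ground-truth manifest."""

    datasets: list[ExpressionDataset]
    records: list[DatasetRecord]
    manifest: dict

    def write(self, outdir: str | Path) -> Path:
        """Write matrices (TSV), registry (YAML) and manifest (JSON)."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for ds, rec in zip(self.datasets, self.records):
            write_expression_matrix(ds, outdir / rec.path)
        write_registry(self.records, outdir / "registry.yaml")
        (outdir / "manifest.json").write_text(
            json.dumps(self.manifest, indent=2, sort_keys=True))
        return outdir


def _copula_correlation(rho_s: float) -> float:
    """Pearson correlation of a bivariate normal whose ranks have Spearman
    correlation *rho_s* (2 sin(pi rho_s / 6))."""
    return 2.0 * math.sin(math.pi * rho_s / 6.0)


def _gene_universe(cfg: SyntheticCollectionConfig,
                   modules: Sequence[GeneModule]) -> tuple[list[str], dict[str, list[int]]]:
    """Symbol list (modules first, then background) and module row indices."""
    symbols: list[str] = []
    index: dict[str, int] = {}
    module_rows: dict[str, list[int]] = {}
    for m in modules:
        rows = []
        for s in m.symbols_for(cfg.species):
            if s not in index:
                index[s] = len(symbols)
                symbols.append(s)
            rows.append(index[s])
        module_rows[m.name] = rows
    n_background = cfg.n_genes - len(symbols) - 1  # -1 reserves the target row
    if n_background < 10:
        raise ValueError(
            f"n_genes={cfg.n_genes} leaves too few background genes beyond "
            f"the {len(symbols)} module genes"
        )
    symbols.extend(f"Bg{i:05d}" for i in range(n_background))
    return symbols, module_rows


def _sample_matrix(rng: np.random.Generator, mean_log2: np.ndarray,
                   n_samples: int, platform: str,
                   cfg: SyntheticCollectionConfig) -> np.ndarray:
    """Draw a genes x samples matrix around per-gene log2 means."""
    g = mean_log2.size
    if platform == "microarray":
        noise = rng.normal(0.0, cfg.microarray_sd, size=(g, n_samples))
        return np.exp2(mean_log2[:, None] + noise)
    mu = np.exp2(mean_log2)  # linear-scale NB mean
    size = 1.0 / cfg.nb_dispersion
    p = size / (size + mu)
    return rng.negative_binomial(size, p[:, None],
                                 size=(g, n_samples)).astype(float)


def generate_collection(cfg: SyntheticCollectionConfig) -> SyntheticCollection:
    """Generate one dataset collection with its ground-truth manifest."""
    modules = default_modules()
    unknown = set(cfg.module_shifts) - {m.name for m in modules}
    if unknown:
        raise ValueError(f"module shifts for unknown modules: {sorted(unknown)}")
    symbols, module_rows = _gene_universe(cfg, modules)

    master = np.random.default_rng(cfg.seed)
    child_seeds = master.integers(0, 2**31 - 1, size=cfg.n_datasets)

    # cross-dataset latents for the target and the rho-linked module
    if cfg.target_rho is not None:
        r = _copula_correlation(cfg.target_rho)
        cov = np.array([[1.0, r], [r, 1.0]])
        latents = master.multivariate_normal([0.0, 0.0], cov,
                                             size=cfg.n_datasets)
        z_target, z_module = latents[:, 0], latents[:, 1]
    else:
        z_target = master.normal(0.0, 1.0, size=cfg.n_datasets)
        z_module = np.zeros(cfg.n_datasets)

    datasets: list[ExpressionDataset] = []
    records: list[DatasetRecord] = []
    truths: list[dict] = []
    lo, hi = cfg.n_samples_range

    for d in range(cfg.n_datasets):
        rng = np.random.default_rng(int(child_seeds[d]))
        platform = cfg.platforms[d % len(cfg.platforms)]
        n_samples = int(rng.integers(lo, hi + 1))

        mean_log2 = rng.normal(cfg.base_mean_log2, cfg.base_sd_log2,
                               size=len(symbols)).clip(min=0.0)
        effects: dict[str, float] = {}
        for m in modules:
            shift = cfg.module_shifts.get(m.name, 0.0)
            if cfg.target_rho is not None and m.name == cfg.rho_module:
                eff = cfg.latent_sd * float(z_module[d])
            else:
                eff = float(rng.normal(0.0, cfg.module_effect_sd))
            effects[m.name] = eff
            rows = module_rows[m.name]
            mean_log2[rows] = (cfg.base_mean_log2 + shift + eff
                               + rng.normal(0.0, 0.5, size=len(rows))).clip(min=0.0)

        values = _sample_matrix(rng, mean_log2, n_samples, platform, cfg)
        gene_list = list(symbols)

        if platform == "sc_like":
            # Mars-seq-like limited detection: lowly expressed genes vanish
            cut = np.quantile(mean_log2, cfg.dropout_quantile)
            keep = mean_log2 > cut
            values = values[keep]
            gene_list = [s for s, k in zip(gene_list, keep) if k]

        true_bin = cfg.target_bin
        target_latent = float(z_target[d])
        if cfg.target_bin is not None:
            if cfg.target_bin == "not_detected":
                if platform != "sc_like":
                    # present in the gene list but zero in every sample
                    gene_list = gene_list + [cfg.target_symbol]
                    values = np.vstack([values, np.zeros((1, n_samples))])
            else:
                pooled = np.log2(1.0 + values).ravel()
                q = float(np.quantile(pooled, _BIN_QUANTILE[cfg.target_bin]))
                tvals = np.exp2(q + rng.normal(0.0, 0.02, size=n_samples)) - 1.0
                gene_list = gene_list + [cfg.target_symbol]
                values = np.vstack([values, tvals.clip(min=0.0)[None, :]])
        else:
            t_mean = cfg.target_base_log2 + cfg.latent_sd * target_latent
            tvals = _sample_matrix(rng, np.array([max(t_mean, 0.0)]),
                                   n_samples, platform, cfg)[0]
            dropped = False
            if platform == "sc_like":
                cut = np.quantile(mean_log2, cfg.dropout_quantile)
                dropped = max(t_mean, 0.0) <= cut
            if not dropped:
                gene_list = gene_list + [cfg.target_symbol]
                values = np.vstack([values, tvals[None, :]])

        ds_id = f"SYN{d + 1:03d}"
        ds = ExpressionDataset(
            dataset_id=ds_id, gene_symbols=gene_list,
            sample_ids=[f"{ds_id}_s{j + 1}" for j in range(n_samples)],
            values=values, platform=platform, species=cfg.species,
            tissue=cfg.tissue, group=cfg.group,
        )
        datasets.append(ds)
        records.append(DatasetRecord(
            dataset_id=ds_id, path=f"{ds_id}.tsv", platform=platform,
            species=cfg.species, tissue=cfg.tissue, group=cfg.group,
            display_label=ds_id,
        ))
        truths.append({
            "dataset_id": ds_id, "platform": platform, "n_samples": n_samples,
            "n_genes": len(gene_list), "true_bin": true_bin,
            "z_target": target_latent,
            "z_module": float(z_module[d]),
            "module_effects": effects,
            "target_present": cfg.target_symbol in gene_list,
        })

    manifest = {
        "seed": cfg.seed,
        "group": cfg.group,
        "target_symbol": cfg.target_symbol,
        "target_bin": cfg.target_bin,
        "target_rho": cfg.target_rho,
        "rho_module": cfg.rho_module if cfg.target_rho is not None else None,
        "module_shifts": cfg.module_shifts,
        "datasets": truths,
    }
    return SyntheticCollection(datasets, records, manifest)


# ---------------------------------------------------------------------------
# colocalization counts
# ---------------------------------------------------------------------------

#: default true double-positive fractions per (region: (female, male)),
#: spanning the 0.35-0.52 range typical of brain areas and 0.37-0.42 of
#: spinal segments, with a planted female<male gap in the VTA
DEFAULT_REGION_FRACTIONS = {
    "FCx": (0.42, 0.44),
    "NAcc": (0.40, 0.42),
    "CeA": (0.49, 0.52),
    "VTA": (0.35, 0.50),
    "PAG": (0.45, 0.47),
    "cervical": (0.37, 0.39),
    "thoracic": (0.38, 0.41),
    "lumbar": (0.40, 0.42),
}


@dataclass
class SyntheticColocConfig:
    """Study conditions for a synthetic reporter-mouse counting experiment."""

    seed: int = 0
    regions: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_REGION_FRACTIONS))
    n_animals: int = 3          # per sex, as in a typical reporter cohort
    n_fields: int = 10          # microscopic fields per animal
    cells_per_field_mean: float = 40.0   # Poisson mean of reporter+ cells

    def __post_init__(self) -> None:
        for region, fracs in self.regions.items():
            for frac in fracs:
                if not 0.0 <= frac <= 1.0:
                    raise ValueError(
                        f"{region}: true fraction {frac} outside [0, 1]")
        if self.n_animals < 1 or self.n_fields < 1:
            raise ValueError("need at least one animal and one field")
        if self.cells_per_field_mean <= 0:
            raise ValueError("cells_per_field_mean must be positive")


def generate_coloc(cfg: SyntheticColocConfig):
    """Generate a cell-count table: cells ~ Poisson, double+ ~ Binomial.

    Returns (records, manifest) where records are
    :class:`~gliameta.coloc_stats.CellCountRecord`.
    """
    from .coloc_stats import CellCountRecord

    rng = np.random.default_rng(cfg.seed)
    records = []
    for region, (f_frac, m_frac) in cfg.regions.items():
        for sex, frac in (("female", f_frac), ("male", m_frac)):
            for a in range(cfg.n_animals):
                animal = f"{sex[0].upper()}{a + 1}"
                for fld in range(cfg.n_fields):
                    cells = int(rng.poisson(cfg.cells_per_field_mean))
                    double = int(rng.binomial(cells, frac)) if cells else 0
                    records.append(CellCountRecord(
                        region=region, sex=sex, animal_id=animal,
                        field_id=f"f{fld + 1}", n_marker_pos=cells,
                        n_double_pos=double,
                    ))
    manifest = {
        "seed": cfg.seed,
        "true_fractions": {r: {"female": f, "male": m}
                           for r, (f, m) in cfg.regions.items()},
        "n_animals": cfg.n_animals, "n_fields": cfg.n_fields,
        "cells_per_field_mean": cfg.cells_per_field_mean,
    }
    return records, manifest


def write_coloc(records, manifest: dict, outdir: str | Path) -> Path:
    """Write counts.tsv and manifest.json."""
    import pandas as pd

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    frame = pd.DataFrame([{
        "region": r.region, "sex": r.sex, "animal_id": r.animal_id,
        "field_id": r.field_id, "n_marker_pos": r.n_marker_pos,
        "n_double_pos": r.n_double_pos,
    } for r in records])
    frame.to_csv(outdir / "counts.tsv", sep="\t", index=False)
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True))
    return outdir
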