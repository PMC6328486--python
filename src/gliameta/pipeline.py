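"""End-to-end orchestration: registry -> calls -> scores -> correlations.

One :class:`PipelineConfig` drives the full analysis: load the registry and
matrices, make per-dataset detection calls and per-group "N out of M"
summaries, score the gene modules, z-score and correlate within each tissue
group, and — when a counts table is supplied — run the colocalization
statistics.  All tables are written as TSV, and the run is reproducible: the
same inputs and config hash to the same outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import coloc_stats, correlation, dataset_io, module_scores, quantile_calls

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Everything one analysis run needs, loadable from YAML."""

    registry: str
    target: str = "Oprm1"
    modules_path: str | None = None          # None -> packaged defaults
    cross_expression: str | None = None      # optional exclusivity filter table
    counts: str | None = None                # colocalization counts.tsv
    groups: list[str] | None = None          # None -> every group in registry
    quantile_mode: str = "pooled"            # or "per_sample"
    quantile_method: str = quantile_calls.DEFAULT_QUANTILE_METHOD
    alpha: float = 0.05
    exact_threshold: int = correlation.DEFAULT_EXACT_THRESHOLD
    coloc_unit: str = "animal"
    outdir: str = "gliameta_out"
    base_dir: str = "."
    make_figures: bool = False

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        payload = yaml.safe_load(Path(path).read_text())
        cfg = cls(**payload)
        cfg.base_dir = str(Path(path).parent)
        return cfg

    def hash(self) -> str:
        """Reproducible hash of the configuration."""
        payload = json.dumps(self.__dict__, sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class ReportBundle:
    """All result tables of one run; absent stages carry a skip reason."""

    config_hash: str
    detection_calls: pd.DataFrame
    detection_summary: pd.DataFrame
    module_scores: pd.DataFrame
    sample_scores: pd.DataFrame
    coverage: pd.DataFrame
    zscores: pd.DataFrame
    exclusions: pd.DataFrame
    correlations: pd.DataFrame
    region_summary: pd.DataFrame | None
    sex_comparisons: pd.DataFrame | None
    skipped: dict[str, str] = field(default_factory=dict)
    summaries: list = field(default_factory=list)
    violin_data: dict = field(default_factory=dict)


def run(config: PipelineConfig) -> ReportBundle:
    """Execute the full pipeline and write every table under ``outdir``."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    base = Path(config.base_dir)

    registry_path = Path(config.registry)
    if not registry_path.is_absolute():
        registry_path = base / registry_path
    records = dataset_io.load_registry(registry_path)
    datasets = dataset_io.load_datasets(records, base_dir=registry_path.parent)
    groups = config.groups or list(dict.fromkeys(r.group for r in records))

    if config.modules_path:
        modules = module_scores.load_modules(base / config.modules_path)
    else:
        modules = module_scores.default_modules()
    if config.cross_expression:
        cross = module_scores.load_cross_expression(base / config.cross_expression)
        modules, removals = module_scores.filter_exclusive(modules, cross)
        log.info("exclusivity filter removed %d genes", len(removals))

    all_calls, summaries, violins = [], [], {}
    zrows, excl_rows, corr_results = [], [], []
    for group in groups:
        ds_group = [d for d in datasets if d.group == group]
        if not ds_group:
            log.warning("group %s has no datasets; skipped", group)
            continue
        calls = [quantile_calls.call_target(d, config.target,
                                            mode=config.quantile_mode,
                                            method=config.quantile_method)
                 for d in ds_group]
        all_calls.extend(calls)
        summaries.append(quantile_calls.summarize_group(calls, group))
        violins[group] = quantile_calls.violin_table(
            ds_group, config.target, mode=config.quantile_mode,
            method=config.quantile_method)

        table = module_scores.score_all(ds_group, modules, config.target)
        group_records = [r for r in records if r.group == group]
        try:
            zm = correlation.apply_exclusions(table, group_records, group=group)
        except ValueError as exc:
            log.warning("group %s: correlation skipped (%s)", group, exc)
            continue
        zrows.append(correlation.zscores_frame(zm))
        excl_rows.extend({"group": group, **e} for e in zm.exclusions)
        corr_results.extend(correlation.correlate_group(
            zm, config.target, alpha=config.alpha,
            exact_threshold=config.exact_threshold))

    # score table over all datasets (registry order), for export
    full_table = module_scores.score_all(datasets, modules, config.target)

    bundle = ReportBundle(
        config_hash=config.hash(),
        detection_calls=quantile_calls.calls_frame(all_calls, config.target),
        detection_summary=quantile_calls.summary_frame(summaries),
        module_scores=full_table.dataset_scores.reset_index(names="dataset_id"),
        sample_scores=full_table.sample_scores,
        coverage=full_table.coverage.reset_index(names="dataset_id"),
        zscores=pd.concat(zrows, ignore_index=True) if zrows
        else pd.DataFrame(columns=["group", "dataset_id", "column", "z"]),
        exclusions=pd.DataFrame(excl_rows,
                                columns=["group", "dataset_id", "reason"]),
        correlations=correlation.correlations_frame(corr_results),
        region_summary=None,
        sex_comparisons=None,
        summaries=summaries,
        violin_data=violins,
    )

    if config.counts:
        counts_path = Path(config.counts)
        if not counts_path.is_absolute():
            counts_path = base / counts_path
        recs = coloc_stats.read_counts(counts_path)
        bundle.region_summary = coloc_stats.region_frame(
            coloc_stats.summarize_region(recs, unit=config.coloc_unit))
        bundle.sex_comparisons = coloc_stats.comparisons_frame(
            coloc_stats.compare_all_regions(recs, unit=config.coloc_unit,
                                            alpha=config.alpha))
    else:
        bundle.skipped["region_summary"] = "no counts table supplied"
        bundle.skipped["sex_comparisons"] = "no counts table supplied"

    _write_bundle(bundle, outdir, config)
    return bundle


def _write_bundle(bundle: ReportBundle, outdir: Path,
                  config: PipelineConfig) -> None:
    tables = {
        "detection_calls.tsv": bundle.detection_calls,
        "detection_summary.tsv": bundle.detection_summary,
        "module_scores.tsv": bundle.module_scores,
        "module_scores_samples.tsv": bundle.sample_scores,
        "coverage.tsv": bundle.coverage,
        "zscores.tsv": bundle.zscores,
        "exclusions.tsv": bundle.exclusions,
        "correlations.tsv": bundle.correlations,
        "region_summary.tsv": bundle.region_summary,
        "sex_comparisons.tsv": bundle.sex_comparisons,
    }
    for name, frame in tables.items():
        if frame is not None:
            tmp = outdir / (name + ".tmp")
            frame.to_csv(tmp, sep="\t", index=False, float_format="%.10g")
            tmp.replace(outdir / name)
    run_log = {
        "config_hash": bundle.config_hash,
        "config": {k: str(v) for k, v in config.__dict__.items()},
        "skipped": bundle.skipped,
    }
    (outdir / "run.json").write_text(json.dumps(run_log, indent=2))
    if config.make_figures:
        for group, violins in bundle.violin_data.items():
            quantile_calls.plot_violins(
                violins, str(outdir / f"violins_{group}.png"))


def render_report(bundle: ReportBundle, path: str | Path) -> Path:
    """Write a human-readable markdown summary of one run."""
    lines = ["# Target-gene detection report", ""]
    lines.append(f"Config hash: `{bundle.config_hash}`")
    lines.append("")
    lines.append("## Detection by tissue group")
    lines.append("")
    for s in bundle.summaries:
        lines.append(
            f"- **{s.group}**: detected in {s.sentence} datasets "
            f"({s.n_above_median} above the median, {s.n_between} between "
            f"median and first quartile, {s.n_below_q25} below the first "
            f"quartile, {s.n_not_detected} not detected)."
        )
    if len(bundle.correlations):
        lines += ["", "## Correlations (target vs module, per group)", ""]
        lines.append("| group | module | n | rho | p | method | |")
        lines.append("|---|---|---|---|---|---|---|")
        for _, r in bundle.correlations.iterrows():
            lines.append(
                f"| {r['group']} | {r['module']} | {r['n']} | {r['rho']:.3f} "
                f"| {r['p']:.4g} | {r['p_method']} | {r['stars']} |")
    if bundle.region_summary is not None:
        lines += ["", "## Colocalization (percent double-positive)", ""]
        lines.append("| region | sex | n | mean % | SEM |")
        lines.append("|---|---|---|---|---|")
        for _, r in bundle.region_summary.iterrows():
            sem = "-" if pd.isna(r["sem"]) else f"{r['sem']:.2f}"
            lines.append(f"| {r['region']} | {r['sex']} | {r['n_units']} "
                         f"| {r['mean_pct']:.1f} | {sem} |")
    for name, reason in bundle.skipped.items():
        lines.append(f"\n*{name} skipped: {reason}*")
    path = Path(path)
    path.write_text("\n".join(lines) + "\n")
    return path
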