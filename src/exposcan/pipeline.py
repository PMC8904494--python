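"""End-to-end orchestration: simulate -> harmonize -> screen -> prioritize.

A single run is driven by one configuration mapping (YAML/JSON on disk)
with per-stage sections, executes the stages in flowchart order, writes
every artifact into an output directory and records a manifest (config
snapshot, seed, stage timings, record counts and SHA-256 digests of all
output files) sufficient to re-run deterministic stages bit-identically.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__, schema
from .change import screen_change
from .discovery import (
    call_signals,
    correlation_matrix,
    hcluster,
    linkage_to_newick,
    prioritize,
    rank_and_select,
)
from .harmonize import HarmonizeConfig, harmonize_table
from .synthetic import ConfigError, GeneratorConfig, generate_cohort


@dataclass
class RunManifest:
    """Provenance record of a pipeline run."""

    config: dict
    seed: int
    package_version: str
    stage_seconds: dict[str, float] = field(default_factory=dict)
    record_counts: dict[str, int] = field(default_factory=dict)
    file_digests: dict[str, str] = field(default_factory=dict)
    completed_stages: list[str] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True, default=str)


def _digest(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


DEFAULT_CONFIG: dict = {
    "seed": 0,
    "simulate": {},  # GeneratorConfig overrides; omit to load cohort from disk
    "inputs": {},  # {"cohort": path, "catalog": path} when not simulating
    "harmonize": {},  # HarmonizeConfig overrides
    "screen": {
        "traits": None,  # default: all nine
        "modes": ["average", "change"],
        "target_years": 10.0,
        "tolerance_years": 2.0,
    },
    "discovery": {
        "alpha": 0.05,
        "top_k": 5,
        "min_traits": 5,
        "n_clusters": 4,
    },
    "plots": True,
}


def load_config(path: str | Path) -> dict:
    """Read a YAML or JSON pipeline configuration."""
    text = Path(path).read_text()
    cfg = yaml.safe_load(text)
    if not isinstance(cfg, dict):
        raise ConfigError("pipeline config must be a mapping")
    return cfg


def _merged(user: dict) -> dict:
    cfg = json.loads(json.dumps(DEFAULT_CONFIG))  # deep copy
    for key, val in user.items():
        if isinstance(val, dict) and isinstance(cfg.get(key), dict):
            cfg[key].update(val)
        else:
            cfg[key] = val
    return cfg


def run_pipeline(config: dict | str | Path, out_dir: str | Path) -> RunManifest:
    """Execute the full pipeline and write all artifacts to ``out_dir``.

    Raises on invalid configuration before any computation; per-model
    failures inside the screens are recorded in the result tables, not
    raised.  The same config and seed always reproduce byte-identical
    result tables.
    """
    if not isinstance(config, dict):
        config = load_config(config)
    cfg = _merged(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(cfg.get("seed", 0))
    disc = cfg["discovery"]
    traits = cfg["screen"].get("traits") or list(schema.TRAITS)
    if disc["min_traits"] > len(traits):
        raise ConfigError(
            f"min_traits={disc['min_traits']} exceeds the number of traits ({len(traits)})"
        )
    manifest = RunManifest(config=cfg, seed=seed, package_version=__version__)

    def _stage(name):
        manifest.completed_stages.append(name)

    def _write_csv(df: pd.DataFrame, name: str) -> None:
        path = out / name
        df.to_csv(path, index=False)
        manifest.file_digests[name] = _digest(path)

    def _write_text(text: str, name: str) -> None:
        path = out / name
        path.write_text(text)
        manifest.file_digests[name] = _digest(path)

    # --- simulate or load ---------------------------------------------
    t0 = time.perf_counter()
    if cfg.get("inputs") and cfg["inputs"].get("cohort"):
        cohort = pd.read_csv(cfg["inputs"]["cohort"])
        catalog = pd.read_csv(cfg["inputs"]["catalog"])
        truth = None
    else:
        gen_kwargs = dict(cfg.get("simulate") or {})
        gen_kwargs.setdefault("seed", seed)
        if "planted_effects" in gen_kwargs:
            gen_kwargs["planted_effects"] = [
                tuple(e) for e in gen_kwargs["planted_effects"]
            ]
        gcfg = GeneratorConfig(**gen_kwargs)
        cohort, catalog, truth = generate_cohort(gcfg)
        _write_csv(cohort, "cohort.csv")
        _write_csv(catalog, "catalog.csv")
        _write_text(json.dumps(truth.to_json_dict(), indent=2), "truth.json")
    manifest.record_counts["cohort_rows"] = len(cohort)
    manifest.record_counts["exposures"] = len(catalog)
    manifest.stage_seconds["simulate"] = time.perf_counter() - t0
    _stage("simulate")

    # --- harmonize ----------------------------------------------------
    t0 = time.perf_counter()
    hcfg = HarmonizeConfig(**(cfg.get("harmonize") or {}))
    clean, catalog2, exlog = harmonize_table(cohort, catalog, hcfg)
    _write_csv(clean, "clean.csv")
    _write_csv(catalog2, "catalog_clean.csv")
    _write_text(json.dumps(exlog.to_json_dict(), indent=2), "exclusion_log.json")
    _write_text(exlog.to_text(), "exclusion_log.txt")
    manifest.record_counts["clean_rows"] = len(clean)
    manifest.record_counts["exposures_after_dominance"] = len(catalog2)
    manifest.stage_seconds["harmonize"] = time.perf_counter() - t0
    _stage("harmonize")

    # --- screens ------------------------------------------------------
    results = []
    modes = cfg["screen"].get("modes") or ["average", "change"]
    if "average" in modes:
        t0 = time.perf_counter()
        from .mixedmodel import screen_average

        res_avg = screen_average(clean, catalog2, traits=traits)
        _write_csv(res_avg, "results_average.csv")
        results.append(res_avg)
        manifest.record_counts["average_models"] = len(res_avg)
        manifest.stage_seconds["screen_average"] = time.perf_counter() - t0
        _stage("screen_average")
    if "change" in modes:
        t0 = time.perf_counter()
        res_chg = screen_change(
            clean,
            catalog2,
            traits=traits,
            target_years=float(cfg["screen"]["target_years"]),
            tolerance_years=float(cfg["screen"]["tolerance_years"]),
        )
        _write_csv(res_chg, "results_change.csv")
        results.append(res_chg)
        manifest.record_counts["change_models"] = len(res_chg)
        manifest.stage_seconds["screen_change"] = time.perf_counter() - t0
        _stage("screen_change")
    all_results = pd.concat(results, ignore_index=True)

    # --- discovery ----------------------------------------------------
    t0 = time.perf_counter()
    signals = call_signals(all_results, alpha=float(disc["alpha"]))
    _write_csv(signals, "signals.csv")
    top = rank_and_select(
        signals[signals["mode"] == "average"] if "average" in modes else signals,
        top_k=int(disc["top_k"]),
    )
    _write_csv(top, "top_sets.csv")
    report = prioritize(top, catalog2, min_traits=int(disc["min_traits"]))
    if len(report.prioritized) >= 2:
        corr = correlation_matrix(clean, report.prioritized)
        Z, leaf_order, labels = hcluster(corr, n_clusters=int(disc["n_clusters"]))
        report.correlation = corr
        report.linkage = Z
        report.leaf_order = leaf_order
        report.cluster_labels = labels
        _write_csv(corr.reset_index().rename(columns={"index": "variable"}), "correlation.csv")
        _write_text(linkage_to_newick(Z, list(corr.index)), "dendrogram.nwk")
    _write_text(json.dumps(report.to_json_dict(), indent=2), "priority.json")
    manifest.record_counts["tentative_signals"] = int(signals["tentative"].sum())
    manifest.record_counts["prioritized"] = len(report.prioritized)
    manifest.stage_seconds["discovery"] = time.perf_counter() - t0
    _stage("discovery")

    # --- report -------------------------------------------------------
    if cfg.get("plots", True):
        try:
            from .plots import manhattan_plot, correlation_heatmap

            for mode_name, res in zip(modes, results):
                fig_path = out / f"manhattan_{mode_name}.png"
                manhattan_plot(
                    signals[signals["mode"] == mode_name], fig_path
                )
                manifest.file_digests[fig_path.name] = _digest(fig_path)
            if report.correlation is not None:
                hm = out / "heatmap.png"
                correlation_heatmap(report.correlation, hm, leaf_order=report.leaf_order)
                manifest.file_digests[hm.name] = _digest(hm)
        except Exception:
            pass  # plots are diagnostic; never fail a run over rendering
    _write_text(_render_report(signals, report, traits), "report.md")
    _stage("report")

    (out / "manifest.json").write_text(manifest.to_json())
    return manifest


def _render_report(signals: pd.DataFrame, report, traits) -> str:
    """Consolidated Markdown run report."""
    lines = ["# Exposome screen report", ""]
    ok = signals[signals["status"] == "ok"]
    lines.append("## Tentative signals per trait and mode")
    lines.append("")
    lines.append("| trait | mode | tested | tentative |")
    lines.append("|---|---|---:|---:|")
    for (trait, mode), grp in ok.groupby(["trait", "mode"]):
        lines.append(
            f"| {trait} | {mode} | {len(grp)} | {int(grp['tentative'].sum())} |"
        )
    lines.append("")
    lines.append("## Tentative signals per category (average mode)")
    lines.append("")
    avg = ok[(ok["mode"] == "average") & ok["tentative"]]
    lines.append("| category | signals |")
    lines.append("|---|---:|")
    for cat, grp in avg.groupby("category"):
        lines.append(f"| {cat} | {len(grp)} |")
    lines.append("")
    lines.append("## Prioritized modifiable variables")
    lines.append("")
    if report.prioritized:
        for var in report.prioritized:
            cnt = int(report.trait_counts.get(var, 0))
            cluster = (
                int(report.cluster_labels[var])
                if report.cluster_labels is not None and var in report.cluster_labels
                else "-"
            )
            lines.append(f"- {var}: top-ranked for {cnt}/{len(traits)} traits, cluster {cluster}")
    else:
        lines.append("(none)")
    if report.excluded:
        lines.append("")
        lines.append("Excluded candidates:")
        for var, reason in report.excluded.items():
            lines.append(f"- {var}: {reason}")
    lines.append("")
    return "\n".join(lines)
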