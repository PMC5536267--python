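"""End-to-end pipeline orchestration with a reproducible run manifest.

Stages (each consumes/produces the plain-CSV/JSON artifacts defined by the
module it wraps):

    simulate -> choices.csv, agents.csv
    extract  -> ips.csv (exclusions applied), median_ips.csv
    fit      -> fits.csv
    select   -> selection.csv, selection_summary.json
    stats    -> stats_report.json, stats.csv

``run_all`` composes the stages and writes manifest.json recording the
config hash, seed, package version, per-stage outputs and warnings, so a
run is reproducible file-for-file from its manifest.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cohort import CohortConfig, generate_cohort
from .design import (DesignSpec, load_config, read_choices, read_ip_table,
                     validate_choices, write_choices, write_ip_table)
from .fitting import fit_all
from .indifference import (apply_exclusions, extract_ips, group_median_ips)
from .nonparametrics import flatten_report, run_comparison_suite
from .selection import (aggregate_sum, best_model_frequencies, deltas,
                        selection_table)

__all__ = ["PipelineConfig", "stage_simulate", "stage_extract", "stage_fit",
           "stage_select", "stage_stats", "run_all"]

log = logging.getLogger(__name__)


class PipelineConfig:
    """Design + cohort configuration with strict key checking."""

    def __init__(self, design: DesignSpec, cohort: CohortConfig):
        self.design = design
        self.cohort = cohort

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        unknown = set(data) - {"design", "cohort"}
        if unknown:
            raise ValueError(f"unknown config sections: {sorted(unknown)}")
        design = DesignSpec.from_dict(data.get("design", {}))
        cohort_data = dict(data.get("cohort", {}))
        if "seed" not in cohort_data:
            raise ValueError("config must provide cohort.seed")
        return cls(design, CohortConfig.from_dict(cohort_data))

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        return cls.from_dict(load_config(path))

    def to_dict(self) -> dict:
        return {"design": {
                    "effort_domains": list(self.design.effort_domains),
                    "amounts": list(self.design.amounts),
                    "effort_levels": list(self.design.effort_levels),
                    "delay_minutes": self.design.delay_minutes,
                    "include_zero_effort_pages":
                        self.design.include_zero_effort_pages},
                "cohort": {
                    "seed": self.cohort.seed,
                    "n_agents": self.cohort.n_agents,
                    "true_model": self.cohort.true_model,
                    "l_medians": list(self.cohort.l_medians),
                    "s_medians": list(self.cohort.s_medians),
                    "log_sd_l": self.cohort.log_sd_l,
                    "log_sd_s": self.cohort.log_sd_s,
                    "rho_l": self.cohort.rho_l,
                    "rho_s": self.cohort.rho_s,
                    "noise_sigma": self.cohort.noise_sigma}}

    def hash(self) -> str:
        canonical = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canonical.encode()).hexdigest()[:16]


def _json_default(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def stage_simulate(config: PipelineConfig, out_dir: Path) -> dict:
    out_dir.mkdir(parents=True, exist_ok=True)
    agents, choices = generate_cohort(config.cohort, config.design)
    agents_path = out_dir / "agents.csv"
    choices_path = out_dir / "choices.csv"
    agents.to_csv(agents_path, index=False)
    write_choices(choices, choices_path)
    return {"agents": str(agents_path), "choices": str(choices_path)}


def stage_extract(choices_path, config: PipelineConfig,
                  out_dir: Path) -> dict:
    out_dir.mkdir(parents=True, exist_ok=True)
    choices = read_choices(choices_path)
    violations = validate_choices(choices)
    if violations:
        log.warning("single-switch violations in %d condition(s)",
                    len(violations))
    ips = extract_ips(choices, config.design)
    ips = apply_exclusions(ips, config.design)
    ips_path = out_dir / "ips.csv"
    write_ip_table(ips, ips_path)
    medians = group_median_ips(ips)
    median_path = out_dir / "median_ips.csv"
    write_ip_table(medians, median_path)
    return {"ips": str(ips_path), "median_ips": str(median_path),
            "warnings": [f"single_switch_violation:{v}" for v in violations]}


def stage_fit(ips_path, config: PipelineConfig, out_dir: Path,
              models=None, units: str = "both") -> dict:
    out_dir.mkdir(parents=True, exist_ok=True)
    ips = read_ip_table(ips_path)
    fits = fit_all(ips, models=models, spec=config.design, units=units)
    fits_path = out_dir / "fits.csv"
    fits.to_csv(fits_path, index=False)
    return {"fits": str(fits_path)}


def stage_select(fits_path, out_dir: Path) -> dict:
    out_dir.mkdir(parents=True, exist_ok=True)
    fits = pd.read_csv(fits_path)
    sel = selection_table(fits)
    sel_path = out_dir / "selection.csv"
    sel.to_csv(sel_path, index=False)

    summary: dict = {"median_unit": {}, "summed": {}, "frequencies": {}}
    for domain, dom_sel in sel.groupby("domain"):
        med = dom_sel[dom_sel["unit"] == "MEDIAN"]
        indiv = dom_sel[dom_sel["unit"] != "MEDIAN"]
        summary["median_unit"][domain] = {}
        summary["summed"][domain] = {}
        summary["frequencies"][domain] = {}
        for criterion in ("aicc", "bic"):
            if not med.empty:
                vals = med.set_index("model")[criterion]
                if vals.notna().all():
                    summary["median_unit"][domain][criterion] = (
                        deltas(vals).round(6).to_dict())
            if not indiv.empty:
                try:
                    summary["summed"][domain][criterion] = (
                        aggregate_sum(indiv, criterion).round(6).to_dict())
                    freq = best_model_frequencies(indiv, criterion)
                    summary["frequencies"][domain][criterion] = {
                        m: {"count": int(row["count"]),
                            "ratio": float(row["ratio"])}
                        for m, row in freq.iterrows()}
                except ValueError as exc:
                    log.warning("%s/%s aggregation skipped: %s",
                                domain, criterion, exc)
    summary_path = out_dir / "selection_summary.json"
    summary_path.write_text(json.dumps(summary, indent=2,
                                       default=_json_default))
    return {"selection": str(sel_path),
            "selection_summary": str(summary_path)}


def stage_stats(fits_path, out_dir: Path,
                reference_model: str = "power") -> dict:
    out_dir.mkdir(parents=True, exist_ok=True)
    fits = pd.read_csv(fits_path)
    report = run_comparison_suite(fits, reference_model=reference_model)
    report_path = out_dir / "stats_report.json"
    report_path.write_text(json.dumps(report, indent=2,
                                      default=_json_default))
    flat = flatten_report(report)
    flat_path = out_dir / "stats.csv"
    flat.to_csv(flat_path, index=False)
    return {"stats_report": str(report_path), "stats": str(flat_path)}


def run_all(config: PipelineConfig, out_dir,
            models=None, units: str = "both",
            reference_model: str = "power") -> dict:
    """Run simulate -> extract -> fit -> select -> stats; write manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config_hash": config.hash(),
        "seed": config.cohort.seed,
        "version": __version__,
        "config": config.to_dict(),
        "stages": {},
        "warnings": [],
    }
    sim = stage_simulate(config, out_dir)
    manifest["stages"]["simulate"] = sim
    ext = stage_extract(sim["choices"], config, out_dir)
    manifest["warnings"].extend(ext.pop("warnings", []))
    manifest["stages"]["extract"] = ext
    fit = stage_fit(ext["ips"], config, out_dir, models=models, units=units)
    manifest["stages"]["fit"] = fit
    sel = stage_select(fit["fits"], out_dir)
    manifest["stages"]["select"] = sel
    stats = stage_stats(fit["fits"], out_dir, reference_model)
    manifest["stages"]["stats"] = stats
    manifest_path = out_dir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2,
                                        default=_json_default))
    manifest["manifest_path"] = str(manifest_path)
    return manifest
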