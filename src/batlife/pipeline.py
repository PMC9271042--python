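"""End-to-end orchestration: simulate -> traits -> models -> demography -> pedigree.

One structured YAML configuration drives every stage; each stage writes
machine-readable outputs (CSV/JSON) under the run directory and the whole run
is summarized in a manifest with content hashes so that identical
configuration + seed reproduces identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import pathlib
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .synthetic import ConfigError, SimulationConfig, simulate_population
from .life_history import (build_person_period, cohort_summary, compute_traits,
                           lifespan_by_afr_group)
from .vital_rates import (ModelSpec, SmoothTerm, fit_model,
                          fit_mortality_with_reproduction_costs,
                          sensitivity_excluding_year)
from .demography import lambda_vs_size
from .pedigree import AssignmentConfig, assign_maternity, locus_diagnostics

__all__ = ["AnalysisConfig", "RunManifest", "load_config", "run_pipeline", "STAGES"]

log = logging.getLogger("batlife")

STAGES = ("simulate", "traits", "fit", "demography", "pedigree")


@dataclass
class AnalysisConfig:
    """Analysis settings layered on top of the simulation configuration."""

    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    # vital-rate models
    k_prediction: int = 10  # basis dimension for prediction surfaces
    k_explanatory: int = 6
    gamma: float = 1.4
    random_terms: tuple = ("colony_id", "year")
    # demography
    x_max: int = 21
    female_fraction: float = 0.518
    first_year_survival: float = 1.0
    size_grid_min: float = 40.0
    size_grid_max: float = 45.5
    size_grid_step: float = 0.5
    r0_definition: str = "standard"
    # pedigree
    assignment: AssignmentConfig = field(default_factory=AssignmentConfig)
    # optional sensitivity refit excluding one calendar year
    exclude_year: int | None = None

    @classmethod
    def from_dict(cls, d: dict) -> "AnalysisConfig":
        d = dict(d)
        sim = d.pop("simulation", {})
        assign = d.pop("assignment", {})
        known = {f.name for f in cls.__dataclass_fields__.values()}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown analysis configuration keys: {sorted(unknown)}")
        if "random_terms" in d:
            d["random_terms"] = tuple(d["random_terms"])
        cfg = cls(simulation=SimulationConfig.from_dict(sim),
                  assignment=AssignmentConfig(**assign), **d)
        if cfg.k_prediction < 3 or cfg.k_explanatory < 3:
            raise ConfigError("basis dimensions must be >= 3")
        if cfg.size_grid_step <= 0 or cfg.size_grid_max <= cfg.size_grid_min:
            raise ConfigError("size grid must be increasing with positive step")
        if not 0.0 <= cfg.female_fraction <= 1.0:
            raise ConfigError("female_fraction must be in [0, 1]")
        return cfg


def load_config(path) -> AnalysisConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigError("configuration file must contain a mapping")
    return AnalysisConfig.from_dict(raw)


@dataclass
class RunManifest:
    """Inventory of one pipeline run: config hash, seed, outputs, stage status."""

    config_hash: str
    seed: int
    version: str
    stages: dict = field(default_factory=dict)  # stage -> {status, seconds}
    outputs: dict = field(default_factory=dict)  # name -> {path, sha256}

    def record_output(self, name: str, path: pathlib.Path) -> None:
        digest = hashlib.sha256(path.read_bytes()).hexdigest()
        self.outputs[name] = {"path": str(path), "sha256": digest}

    def to_dict(self) -> dict:
        return {"config_hash": self.config_hash, "seed": self.seed,
                "version": self.version, "stages": self.stages,
                "outputs": self.outputs}


def _write_json(path: pathlib.Path, obj) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1, default=_jsonable)


def _jsonable(x):
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    if isinstance(x, np.ndarray):
        return x.tolist()
    raise TypeError(f"not JSON-serializable: {type(x)}")


def run_pipeline(config: AnalysisConfig | str | pathlib.Path, outdir,
                 seed: int | None = None,
                 stages: tuple = STAGES) -> RunManifest:
    """Run the configured analysis end to end, writing outputs under ``outdir``.

    ``seed`` overrides the configured simulation seed.  A failing stage aborts
    the run with the stage named; outputs of completed stages are retained.
    """
    if not isinstance(config, AnalysisConfig):
        config = load_config(config)
    if seed is not None:
        config.simulation.seed = int(seed)
    outdir = pathlib.Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    cfg_text = yaml.safe_dump({"simulation": config.simulation.to_dict()},
                              sort_keys=True)
    manifest = RunManifest(
        config_hash=hashlib.sha256(cfg_text.encode()).hexdigest()[:16],
        seed=config.simulation.seed, version=__version__)

    state: dict = {}
    summary: dict = {"seed": config.simulation.seed}
    for stage in STAGES:
        if stage not in stages:
            continue
        t0 = time.time()
        log.info("stage %s: starting (seed=%d)", stage, config.simulation.seed)
        try:
            _run_stage(stage, config, outdir, state, summary, manifest)
        except Exception:
            manifest.stages[stage] = {"status": "failed",
                                      "seconds": round(time.time() - t0, 2)}
            _finalize(outdir, manifest, summary)
            log.exception("stage %s failed; partial outputs retained", stage)
            raise
        manifest.stages[stage] = {"status": "ok",
                                  "seconds": round(time.time() - t0, 2)}
        log.info("stage %s: done in %.1fs", stage, time.time() - t0)
    _finalize(outdir, manifest, summary)
    return manifest


def _finalize(outdir: pathlib.Path, manifest: RunManifest, summary: dict) -> None:
    _write_json(outdir / "summary.json", summary)
    manifest.record_output("summary", outdir / "summary.json")
    with open(outdir / "report.txt", "w") as fh:
        fh.write(_human_report(summary))
    _write_json(outdir / "manifest.json", manifest.to_dict())


def _run_stage(stage: str, config: AnalysisConfig, outdir: pathlib.Path,
               state: dict, summary: dict, manifest: RunManifest) -> None:
    if stage == "simulate":
        pop = simulate_population(config.simulation)
        state["pop"] = pop
        paths = pop.write_csv(outdir)
        for name, p in paths.items():
            manifest.record_output(name, p)
        summary["n_individuals"] = len(pop.individuals)
        return

    pop = state.get("pop")
    if pop is None:
        raise RuntimeError(f"stage {stage!r} requires the simulate stage")
    ind, ev = state.setdefault("tables", (pop.individuals_frame(),
                                          pop.events_frame()))

    if stage == "traits":
        traits = compute_traits(ind, ev, study_end_year=pop.study_end_year)
        pp = build_person_period(ind, ev, pop.census, traits=traits,
                                 study_end_year=pop.study_end_year)
        state["traits"], state["pp"] = traits, pp
        traits.to_csv(outdir / "traits.csv", index=False)
        pp.to_csv(outdir / "person_period.csv", index=False)
        manifest.record_output("traits", outdir / "traits.csv")
        manifest.record_output("person_period", outdir / "person_period.csv")
        summary["cohort"] = cohort_summary(traits)
        kr = lifespan_by_afr_group(traits)
        summary["lifespan_by_afr"] = {
            "kruskal_H": round(kr.statistic, 2), "df": kr.df,
            "pvalue": kr.pvalue,
            "groups": kr.group_stats.round(2).to_dict(orient="records")}
        summary["size_center_mm"] = pp.attrs["size_center_mm"]
        return

    if stage == "fit":
        pp = state["pp"]
        k = config.k_prediction
        smooths = (SmoothTerm("size_centered", k=k), SmoothTerm("age", k=k))
        spec_r = ModelSpec(response="reproduced", smooth=smooths,
                           random=config.random_terms, gamma=config.gamma)
        spec_m = ModelSpec(response="died", smooth=smooths,
                           random=config.random_terms, gamma=config.gamma)
        state["model_repro"] = fit_model(pp, spec_r)
        state["model_mort"] = fit_model(pp, spec_m)
        cost = fit_mortality_with_reproduction_costs(
            pp, k=config.k_explanatory, random=config.random_terms,
            gamma=config.gamma)
        state["model_cost"] = cost
        models = {"reproduction": state["model_repro"].summary(),
                  "mortality": state["model_mort"].summary(),
                  "mortality_with_costs": cost.summary()}
        if config.exclude_year is not None:
            restricted = pp.loc[pp["complete_life"].astype(bool)
                                & (pp["afr_covariate"] > 0)]
            sens = sensitivity_excluding_year(restricted, config.exclude_year,
                                              cost.spec)
            models["sensitivity_excluding_year"] = {
                "year": sens.excluded_year, "n_removed": sens.n_removed,
                "linear_coef_delta": sens.linear_coef_delta,
                "reduced": sens.reduced.summary()}
        _write_json(outdir / "models.json", models)
        manifest.record_output("models", outdir / "models.json")
        summary["models"] = models
        return

    if stage == "demography":
        pp = state["pp"]
        grid = np.arange(config.size_grid_min,
                         config.size_grid_max + 1e-9, config.size_grid_step)
        res = lambda_vs_size(state["model_mort"], state["model_repro"], grid,
                             size_center_mm=summary["size_center_mm"],
                             x_max=config.x_max,
                             female_fraction=config.female_fraction,
                             first_year_survival=config.first_year_survival,
                             r0_definition=config.r0_definition)
        res.table.to_csv(outdir / "demography.csv", index=False)
        manifest.record_output("demography", outdir / "demography.csv")
        interval = res.viable_interval
        _write_json(outdir / "viable_interval.json", {
            "viable_interval_mm": interval,
            "female_fraction": config.female_fraction,
            "first_year_survival": config.first_year_survival,
            "x_max": config.x_max})
        manifest.record_output("viable_interval", outdir / "viable_interval.json")
        state["demography"] = res
        summary["demography"] = {
            "viable_interval_mm": interval,
            "lambda_max": float(res.table["lam"].max()),
            "T_range": [float(res.table["T"].min()), float(res.table["T"].max())]}
        return

    if stage == "pedigree":
        gt = pop.genotypes
        diag = locus_diagnostics(gt)
        diag.per_locus.to_csv(outdir / "locus_diagnostics.csv", index=False)
        manifest.record_output("locus_diagnostics", outdir / "locus_diagnostics.csv")
        offs = ind[(ind["mother_id"] != "") & ind["mother_id"].notna()]
        alive = ev[["individual_id", "colony_id", "year"]]
        cand = {}
        for _, r in offs.iterrows():
            pool = alive[(alive["colony_id"] == r["colony_id"])
                         & (alive["year"] == r["birth_year"])]
            ids = [x for x in pool["individual_id"] if x != r["individual_id"]]
            if ids:
                cand[r["individual_id"]] = ids
        res = assign_maternity(list(cand), cand, gt, config.assignment)
        res.to_csv(outdir / "assignments.csv", index=False)
        manifest.record_output("assignments", outdir / "assignments.csv")
        truth = ind.set_index("individual_id")["mother_id"]
        acc = res.loc[res["accepted"]]
        correct = (acc.set_index("offspring_id")["best_candidate_id"]
                   == truth.loc[acc["offspring_id"]]).mean() if len(acc) else 0.0
        summary["pedigree"] = {
            "combined_ne1": diag.combined_ne1,
            "n_offspring": int(len(res)),
            "assignment_rate_pct": round(100.0 * len(acc) / len(res), 1),
            "correct_among_accepted_pct": round(100.0 * float(correct), 1),
            "delta_threshold": res.attrs["delta_threshold"]}
        return

    raise ValueError(f"unknown stage {stage!r}")


def _human_report(summary: dict) -> str:
    lines = [f"batlife run (seed {summary.get('seed')})", "=" * 40]
    if "cohort" in summary:
        c = summary["cohort"]
        lines += [
            f"complete-life females: {c['n_total']} "
            f"({c['pct_never_reproduced']:.0f}% never reproduced)",
            f"forearm length: {c['mean_fal_mm']} +/- {c['sd_fal_mm']} mm",
            f"lifetime reproductive success: {c['mean_lrs']} +/- {c['sd_lrs']}",
            f"age at first reproduction: {c['mean_afr']} +/- {c['sd_afr']} y",
        ]
    if "models" in summary:
        mwc = summary["models"]["mortality_with_costs"]
        lines += ["mortality model with reproduction costs:",
                  f"  deviance explained: {mwc['deviance_explained']:.1%}",
                  "  p-values: " + ", ".join(
                      f"{k}={v:.3g}" for k, v in mwc["pvalues"].items()
                      if v is not None)]
    if "demography" in summary:
        d = summary["demography"]
        vi = d["viable_interval_mm"]
        vi_txt = (f"{vi[0]:.2f}-{vi[1]:.2f} mm" if vi else "none")
        lines += [f"viable size window (lambda > 1): {vi_txt}",
                  f"generation time range: {d['T_range'][0]:.2f}-"
                  f"{d['T_range'][1]:.2f} y"]
    if "pedigree" in summary:
        p = summary["pedigree"]
        lines += [f"maternity assignment: {p['assignment_rate_pct']}% of "
                  f"{p['n_offspring']} offspring "
                  f"({p['correct_among_accepted_pct']}% correct)"]
    return "\n".join(lines) + "\n"
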