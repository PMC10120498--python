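"""Config-driven orchestration of the full two-stage analysis.

``run_analysis`` reproduces the whole workflow on one dataset: load (or
simulate) -> arm summaries -> optional hyperparameter cross-validation ->
stage-1 CATE estimation per outcome -> convergence diagnostics -> stage-2
subgroup trees, quartile tables and partial-dependence curves -> extreme-
imputation sensitivity -> plain-text/TSV/JSON report bundle with a
provenance manifest.  Outputs are deterministic given (config, seed).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import platform
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .bart import BartConfig, FAST_PROFILE, PAPER_PROFILE
from .cate import estimate_cate, partial_dependence, quartile_summary
from .cv import build_grid, cross_validate
from .diagnostics import diagnose
from .sensitivity import run_sensitivity
from .subgroup_tree import fit_subgroup_tree, render_tree
from .synthetic import default_marginals, generate_trial, scenario
from .trial_data import (
    load_trial_table,
    standardize_covariates,
    summarize_by_arm,
    summary_to_frame,
)

__all__ = ["RunConfig", "run_analysis", "load_run_config"]

PROFILES = {"paper": PAPER_PROFILE, "fast": FAST_PROFILE}


@dataclass
class RunConfig:
    """Analysis configuration (YAML/JSON serializable)."""

    input_path: str | None = None          # delimited trial table, or
    scenario: str | None = None            # a named synthetic scenario
    n: int = 982
    outcomes: tuple[str, ...] = ("dawols", "mortality")
    profile: str = "fast"                  # "paper" | "fast"
    link: str = "probit"
    run_cv: bool = False
    cv_k: int = 10
    max_depth: int = 3
    min_leaf: int = 20
    cp: float = 0.01
    pd_covariates: tuple[str, ...] = ("age", "weight")
    pd_grid_size: int = 25
    run_sensitivity: bool = True
    seed: int = 0
    column_map: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if (self.input_path is None) == (self.scenario is None):
            raise ValueError("exactly one of input_path or scenario must be set")
        if self.profile not in PROFILES:
            raise ValueError(f"profile must be one of {sorted(PROFILES)}")
        for o in self.outcomes:
            if o not in ("dawols", "mortality"):
                raise ValueError(f"unknown outcome {o!r}")


def load_run_config(path) -> RunConfig:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if "outcomes" in doc:
        doc["outcomes"] = tuple(doc["outcomes"])
    if "pd_covariates" in doc:
        doc["pd_covariates"] = tuple(doc["pd_covariates"])
    return RunConfig(**doc)


def _stage(name: str):
    """Context that re-raises any stage failure tagged with the stage name."""
    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None:
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
            return False

    return _Ctx()


def run_analysis(config: RunConfig, outdir) -> dict:
    """Run the full pipeline; returns a manifest of written artifacts."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: list[str] = []

    def write(name: str, text: str) -> None:
        (out / name).write_text(text)
        artifacts.append(name)

    with _stage("load"):
        if config.scenario is not None:
            ds = generate_trial(config.n, default_marginals(), scenario(config.scenario),
                                seed=config.seed)
        else:
            ds = load_trial_table(config.input_path, column_map=config.column_map or None)

    with _stage("summary"):
        summary = summarize_by_arm(ds)
        write("table1.json", json.dumps(summary, indent=2))
        summary_to_frame(summary).to_csv(out / "table1.tsv", sep="\t", index=False)
        artifacts.append("table1.tsv")

    with _stage("standardize"):
        sds = standardize_covariates(ds)

    base_cfg = PROFILES[config.profile]
    selected: dict[str, BartConfig] = {}
    if config.run_cv:
        with _stage("cross_validation"):
            for outcome in config.outcomes:
                res = cross_validate(sds, outcome, grid=build_grid(), k=config.cv_k,
                                     seed=config.seed)
                res.to_frame().to_csv(out / f"cv_{outcome}.tsv", sep="\t", index=False)
                artifacts.append(f"cv_{outcome}.tsv")
                sel = res.selected
                selected[outcome] = replace(base_cfg, power=sel.power, base=sel.base, m=sel.m)
                write(
                    f"cv_{outcome}_selection.json",
                    json.dumps({"power": sel.power, "base": sel.base, "m": sel.m,
                                "mean_error": float(res.mean_errors[res.selected_index])},
                               indent=2),
                )

    fits = {}
    for outcome in config.outcomes:
        cfg = replace(selected.get(outcome, base_cfg), seed=config.seed)
        with _stage(f"cate_{outcome}"):
            fit = estimate_cate(sds, outcome, cfg, link=config.link)
            fits[outcome] = fit
            df = fit.result.to_frame()
            df.to_csv(out / f"cate_{outcome}.tsv", sep="\t", index=False)
            artifacts.append(f"cate_{outcome}.tsv")
        with _stage(f"diagnostics_{outcome}"):
            rep = diagnose(fit.draws, seed=config.seed)
            write(f"diagnostics_{outcome}.json", rep.to_json())
            write(f"diagnostics_{outcome}.txt", rep.to_text())
        with _stage(f"partial_dependence_{outcome}"):
            for cov in config.pd_covariates:
                curve = partial_dependence(fit, cov, grid_size=config.pd_grid_size)
                curve.to_frame().to_csv(out / f"pd_{outcome}_{cov}.tsv", sep="\t", index=False)
                artifacts.append(f"pd_{outcome}_{cov}.tsv")
        with _stage(f"subgroup_tree_{outcome}"):
            tree = fit_subgroup_tree(sds, fit.result, max_depth=config.max_depth,
                                     min_leaf=config.min_leaf, cp=config.cp)
            write(f"tree_{outcome}.txt", render_tree(tree, "text"))
            write(f"tree_{outcome}.json", render_tree(tree, "json"))
            write(f"tree_{outcome}.dot", render_tree(tree, "dot"))
        with _stage(f"quartiles_{outcome}"):
            qs = quartile_summary(fits[outcome])
            qs.groups.to_csv(out / f"quartiles_{outcome}.tsv", sep="\t", index=False)
            artifacts.append(f"quartiles_{outcome}.tsv")

    if config.run_sensitivity:
        with _stage("sensitivity"):
            cfg = replace(base_cfg, seed=config.seed)
            rep = run_sensitivity(ds, outcomes=tuple(config.outcomes), cfg=cfg,
                                  link=config.link, max_depth=config.max_depth,
                                  min_leaf=config.min_leaf, cp=config.cp)
            write("sensitivity.json", rep.to_json())
            rep.comparisons.to_csv(out / "sensitivity_comparison.tsv", sep="\t", index=False)
            artifacts.append("sensitivity_comparison.tsv")

    cfg_dict = dataclasses.asdict(config)
    artifacts.append("manifest.json")
    manifest = {
        "config": cfg_dict,
        "config_hash": hashlib.sha256(
            json.dumps(cfg_dict, sort_keys=True, default=str).encode()
        ).hexdigest(),
        "seed": config.seed,
        "versions": {
            "bartcate": __version__,
            "python": platform.python_version(),
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "artifacts": sorted(set(artifacts)),
    }
    write("manifest.json", json.dumps(manifest, indent=2))
    return manifest
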