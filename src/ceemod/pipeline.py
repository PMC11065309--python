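"""End-to-end pipeline orchestration with stage-scoped seeds and a manifest.

A single run seed is fanned out to per-stage child seeds through
``numpy.random.SeedSequence(seed).spawn``, in a fixed stage order, so each
stage is independently reproducible and the whole run is bit-for-bit
deterministic.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np

from . import engine, reporting
from .cohort import GeneratorConfig, generate_cohort, summarize_cohort, write_cohort
from .estimation import estimate_parameters
from .params import ParameterSet, load_parameters
from .psa import PSAConfig, run_psa
from .scenarios import one_way_sensitivity, scenario_sd

log = logging.getLogger("ceemod")

STAGES = ("simulate", "estimate", "basecase", "psa", "sensitivity", "scenario_sd")


def stage_seeds(seed: int) -> dict[str, int]:
    """Derive one 31-bit child seed per stage from the run seed."""
    children = np.random.SeedSequence(seed).spawn(len(STAGES))
    return {stage: int(child.generate_state(1)[0] % (2**31))
            for stage, child in zip(STAGES, children)}


def run_pipeline(
    config_path: str | Path | None,
    stages: set[str] | frozenset[str],
    seed: int,
    out_dir: str | Path,
    n_draws: int = 10_000,
) -> dict:
    """Execute the requested stages in dependency order; write CSV/JSON
    outputs and a manifest to ``out_dir``; return the manifest."""
    unknown = set(stages) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    params: ParameterSet = load_parameters(config_path)
    seeds = stage_seeds(seed)
    outputs: list[Path] = []

    cohort = None
    if "simulate" in stages:
        log.info("stage simulate: generating synthetic cohort")
        cfg = GeneratorConfig.from_parameters(params, seed=seeds["simulate"])
        cohort = generate_cohort(cfg)
        path = out / "cohort.csv"
        write_cohort(cohort, path)
        reporting.write_json(summarize_cohort(cohort), out / "cohort_summary.json")
        outputs += [path, out / "cohort_summary.json"]

    if "estimate" in stages:
        if cohort is None:
            cfg = GeneratorConfig.from_parameters(params, seed=seeds["simulate"])
            cohort = generate_cohort(cfg)
        log.info("stage estimate: fitting adjusted regressions")
        est = estimate_parameters(cohort)
        report = {
            "event_means": dict(est.events.adjusted_means),
            "cost_means": dict(est.costs.adjusted_means),
            "discharge_probs": {a: list(sp.as_tuple())
                                for a, sp in est.discharge.state_probs.items()},
        }
        reporting.write_json(report, out / "estimates.json")
        est.events.coefficients.to_csv(out / "coef_events.csv")
        est.costs.coefficients.to_csv(out / "coef_costs.csv")
        outputs += [out / "estimates.json", out / "coef_events.csv", out / "coef_costs.csv"]

    if "basecase" in stages:
        log.info("stage basecase: deterministic evaluation")
        result = engine.evaluate_base_case(params)
        reporting.base_case_frame(result).to_csv(out / "basecase.csv", index=False)
        reporting.write_json(reporting.base_case_report(result), out / "basecase.json")
        (out / "basecase.txt").write_text(reporting.render_base_case_text(result) + "\n")
        outputs += [out / "basecase.csv", out / "basecase.json", out / "basecase.txt"]

    if "psa" in stages:
        log.info("stage psa: %d Monte-Carlo draws", n_draws)
        result = run_psa(params, PSAConfig(n_draws=n_draws, seed=seeds["psa"]))
        reporting.psa_draws_frame(result).to_csv(out / "psa_draws.csv", index=False)
        reporting.ceac_frame(result).to_csv(out / "ceac.csv", index=False)
        reporting.write_json(reporting.psa_summary(result), out / "psa_summary.json")
        reporting.plot_ce_plane(result, out / "ce_plane.png")
        reporting.plot_ceac(result, out / "ceac.png")
        outputs += [out / "psa_draws.csv", out / "ceac.csv", out / "psa_summary.json",
                    out / "ce_plane.png", out / "ceac.png"]

    if "sensitivity" in stages:
        log.info("stage sensitivity: one-way scenarios")
        for parameter, values in (("product_life", [5, 10, 15]),
                                  ("cableless_rate", [0.0, 0.123, 0.23, 0.5, 1.0])):
            frame = one_way_sensitivity(params, parameter, values)
            path = out / f"sensitivity_{parameter}.csv"
            frame.to_csv(path, index=False)
            outputs.append(path)

    if "scenario_sd" in stages:
        log.info("stage scenario_sd: sd-fraction scenarios")
        frame = scenario_sd(params, psa_cfg=PSAConfig(n_draws=n_draws, seed=seeds["scenario_sd"]))
        frame.to_csv(out / "scenario_sd.csv", index=False)
        outputs.append(out / "scenario_sd.csv")

    manifest = reporting.build_manifest("run_pipeline", config_path, seed, outputs, seeds)
    reporting.write_json(manifest, out / "manifest.json")
    return manifest
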