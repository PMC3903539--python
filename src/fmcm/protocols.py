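"""Benchmark protocols on the synthetic scenario.

These functions bundle the repeated experimental designs: planted-signal
recovery of the module screen, the module-screen vs whole-signature
reproducibility comparison under cohort subsampling, and reference-based
accuracy/specificity. They are used by the CLI ``evaluate`` command and by
the reproducibility scripts.
"""

from __future__ import annotations

import itertools
import logging
import statistics
from typing import Mapping

import numpy as np
import pandas as pd

from . import sam, simulate
from .connectivity import BENEFICIAL, HARMFUL, NullESCache
from .evaluation import (
    accuracy_specificity,
    igcm_baseline,
    reproducibility,
    selected_drugs,
    _subsample,
)
from .io import ExpressionMatrix, ReferenceDrugSet
from .pipeline import PipelineInputs, RunConfig, run_fmcm, run_igcm

log = logging.getLogger(__name__)


def synthetic_inputs(
    seed: int, scenario: simulate.ScenarioConfig | None = None
) -> tuple[PipelineInputs, ReferenceDrugSet, pd.DataFrame, pd.DataFrame]:
    """Default synthetic scenario -> (inputs, reference, gene truth, drug truth)."""
    cfg = (scenario or simulate.ScenarioConfig()).with_seed(seed)
    m, gene_truth = simulate.gen_cohort(cfg)
    ppi, onto = simulate.gen_ppi_and_ontology(cfg)
    lib, ref, effects = simulate.gen_drug_library(cfg)
    return PipelineInputs(m, ppi, onto, lib), ref, gene_truth, effects


def planted_recovery(
    seed: int,
    cfg: RunConfig | None = None,
    scenario: simulate.ScenarioConfig | None = None,
) -> dict[str, float]:
    """Fractions of planted drug effects recovered by the module screen.

    * ``reverse_recovered``: (reverse drug, target module) pairs classified
      beneficial, over all such pairs;
    * ``mimic_flagged``: (mimic drug, target module) pairs classified
      harmful;
    * ``false_beneficial``: (null drug, module) results classified
      beneficial, over all such results.
    """
    cfg = cfg or RunConfig(seed=seed)
    inputs, _, _, effects = synthetic_inputs(seed, scenario)
    run = run_fmcm(inputs, cfg)
    cls: dict[tuple[str, str], str] = {}
    for module, results in run.results.items():
        for r in results:
            cls[(module, r.drug)] = r.classification

    def pair_rate(effect: str, wanted: str) -> float:
        drugs = effects.index[effects["effect"] == effect]
        pairs = [
            (target, d) for d in drugs for target in simulate.target_list(effects, d)
        ]
        if not pairs:
            return float("nan")
        hits = sum(1 for p in pairs if cls.get(p) == wanted)
        return hits / len(pairs)

    null_drugs = set(effects.index[effects["effect"] == simulate.NONE])
    null_calls = [
        c for (mod, drug), c in cls.items() if drug in null_drugs
    ]
    false_beneficial = (
        sum(1 for c in null_calls if c == BENEFICIAL) / len(null_calls)
        if null_calls
        else float("nan")
    )
    return {
        "reverse_recovered": pair_rate(simulate.REVERSE, BENEFICIAL),
        "mimic_flagged": pair_rate(simulate.MIMIC, HARMFUL),
        "false_beneficial": false_beneficial,
        "n_modules_scored": float(len(run.results)),
    }


def planted_recovery_mean(
    seeds: list[int], cfg: RunConfig | None = None, scenario: simulate.ScenarioConfig | None = None
) -> dict[str, float]:
    """Average the recovery rates over several scenario seeds."""
    runs = [planted_recovery(s, cfg, scenario) for s in seeds]
    return {
        key: float(np.nanmean([r[key] for r in runs]))
        for key in runs[0]
    }


def reproducibility_comparison(
    inputs: PipelineInputs,
    cfg: RunConfig | None = None,
    runs: int = 10,
    per_group: int = 20,
    seed: int = 0,
) -> dict:
    """Module-screen vs whole-signature reproducibility under subsampling.

    Draws ``runs`` random ``per_group``+``per_group`` subsamples (pairing
    respected) and applies BOTH procedures to each, so the comparison is
    paired. The module screen's selected set per run is the set of
    (module, drug) decisions; reproducibility is computed module-wise and
    averaged. The baseline's set per fold-change level is its beneficial
    and harmful drugs; values are computed per level and averaged.
    """
    cfg = cfg or RunConfig()
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x5AB5]))
    run_seeds = rng.integers(0, 2**31 - 1, size=runs)
    cache = NullESCache(n_perm=cfg.conn_n_perm, seed=seed)
    modules = list(cfg.module_terms)
    fmcm_sets: list[set[tuple[str, str]]] = []
    igcm_sets: list[dict[float, set[str]]] = []
    for i in range(runs):
        sub = _subsample(inputs.expression, per_group, rng)
        sub_inputs = PipelineInputs(sub, inputs.ppi, inputs.ontology, inputs.library)
        run_cfg = RunConfig(**{**cfg.__dict__, "seed": int(run_seeds[i])})
        deg_tbl = sam.deg_table(sub, n_perm=cfg.sam_n_perm, seed=int(run_seeds[i]))
        fm = run_fmcm(sub_inputs, run_cfg, deg_tbl=deg_tbl, cache=cache)
        decisions = {
            (mod, r.drug)
            for mod, results in fm.results.items()
            for r in results
            if r.classification in (BENEFICIAL, HARMFUL)
        }
        fmcm_sets.append(decisions)
        batches = run_igcm(sub_inputs, run_cfg, deg_tbl=deg_tbl, cache=cache)
        igcm_sets.append({fc: selected_drugs(res) for fc, res in batches.items()})

    pair_idx = list(itertools.combinations(range(runs), 2))
    fmcm_per_module: dict[str, list[float]] = {}
    for module in modules:
        per_run = [{d for m_, d in s if m_ == module} for s in fmcm_sets]
        fmcm_per_module[module] = [
            reproducibility(per_run[i], per_run[j]) for i, j in pair_idx
        ]
    igcm_per_fc: dict[float, list[float]] = {}
    for fc in cfg.igcm_fc_grid:
        per_run = [s.get(fc, set()) for s in igcm_sets]
        igcm_per_fc[fc] = [
            reproducibility(per_run[i], per_run[j]) for i, j in pair_idx
        ]
    fmcm_values = [v for vals in fmcm_per_module.values() for v in vals]
    igcm_values = [v for vals in igcm_per_fc.values() for v in vals]
    return {
        "fmcm_mean": statistics.fmean(fmcm_values) if fmcm_values else 0.0,
        "igcm_mean": statistics.fmean(igcm_values) if igcm_values else 0.0,
        "fmcm_per_module": {m: statistics.fmean(v) if v else 0.0 for m, v in fmcm_per_module.items()},
        "igcm_per_fc": {fc: statistics.fmean(v) if v else 0.0 for fc, v in igcm_per_fc.items()},
        "n_pairs": len(pair_idx),
    }


def evaluate_protocol(
    inputs: PipelineInputs,
    reference: ReferenceDrugSet,
    cfg: RunConfig | None = None,
    runs: int = 10,
    per_group: int = 20,
) -> dict:
    """Accuracy/specificity of both procedures plus the reproducibility
    comparison, as one JSON-serializable report."""
    cfg = cfg or RunConfig()
    run = run_fmcm(inputs, cfg)
    beneficial, harmful = set(), set()
    for results in run.results.values():
        for r in results:
            if r.classification == BENEFICIAL:
                beneficial.add(r.drug)
            elif r.classification == HARMFUL:
                harmful.add(r.drug)
    harmful -= beneficial  # a drug beneficial somewhere counts as beneficial
    rep = accuracy_specificity(beneficial, harmful, reference)
    batches = run_igcm(inputs, cfg)
    igcm_reports = {}
    for fc, results in batches.items():
        b = {r.drug for r in results if r.classification == BENEFICIAL}
        h = {r.drug for r in results if r.classification == HARMFUL} - b
        r_ = accuracy_specificity(b, h, reference)
        igcm_reports[f"FC{fc:g}"] = {
            "accuracy": r_.accuracy,
            "specificity": r_.specificity,
            "nb": r_.nb,
            "na": r_.na,
        }
    comparison = reproducibility_comparison(inputs, cfg, runs=runs, per_group=per_group, seed=cfg.seed)
    return {
        "fmcm": {
            "accuracy": rep.accuracy,
            "specificity": rep.specificity,
            "nb": rep.nb,
            "na": rep.na,
        },
        "igcm": igcm_reports,
        "reproducibility": {
            "fmcm_mean": comparison["fmcm_mean"],
            "igcm_mean": comparison["igcm_mean"],
        },
    }
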