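"""Benchmarking: accuracy/specificity against a reference drug list,
reproducibility under cohort subsampling, and the whole-signature
(individual-gene) connectivity-map baseline.

Conventions follow the screen's own bookkeeping: NB and NA are the counts
of drugs predicted beneficial and harmful; TP and FN are the known
anti-tumor agents among them; TN = NA - FN and FP = NB - TP, so

    accuracy    = (TP + TN) / (NB + NA)
    specificity = TN / (FP + TN)

Reproducibility between two selected drug sets A, B is |A ∩ B| divided by
the geometric mean of |A| and |B|. The subsampling protocol repeats a
drug-selection procedure on 10 random 20+20-sample subsets and reports
all 45 pairwise values.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass
from typing import Callable, Hashable, Mapping, Sequence

import numpy as np
import pandas as pd

from .connectivity import (
    BENEFICIAL,
    HARMFUL,
    ConnectivityResult,
    NullESCache,
    score_query,
)
from .io import CASE, CONTROL, DrugLibrary, ExpressionMatrix, ReferenceDrugSet
from . import sam

log = logging.getLogger(__name__)


@dataclass
class EvalReport:
    nb: int
    na: int
    tp: int
    fn: int

    @property
    def tn(self) -> int:
        return self.na - self.fn

    @property
    def fp(self) -> int:
        return self.nb - self.tp

    @property
    def accuracy(self) -> float | None:
        denom = self.nb + self.na
        return (self.tp + self.tn) / denom if denom else None

    @property
    def specificity(self) -> float | None:
        denom = self.fp + self.tn
        return self.tn / denom if denom else None


def accuracy_specificity(
    beneficial: set[str], harmful: set[str], reference: ReferenceDrugSet
) -> EvalReport:
    """Score predictions against known anti-tumor agents.

    Zero denominators leave accuracy/specificity as None (undefined), never 0.
    """
    if beneficial & harmful:
        raise ValueError("beneficial and harmful prediction sets must be disjoint")
    tp = len(beneficial & reference.anti_tumor)
    fn = len(harmful & reference.anti_tumor)
    return EvalReport(nb=len(beneficial), na=len(harmful), tp=tp, fn=fn)


def reproducibility(set_a: set, set_b: set) -> float:
    """|A ∩ B| / sqrt(|A| * |B|); 0 when either set is empty."""
    if not set_a or not set_b:
        return 0.0
    return len(set_a & set_b) / math.sqrt(len(set_a) * len(set_b))


def _subsample(
    m: ExpressionMatrix, per_group: int, rng: np.random.Generator
) -> ExpressionMatrix:
    """Draw per_group samples from each condition (pairing-respecting)."""
    if m.pairing is not None:
        subjects = pd.unique(m.pairing.loc[list(m.values.columns)])
        if len(subjects) < per_group:
            raise ValueError(
                f"need >= {per_group} subjects, got {len(subjects)}"
            )
        chosen = rng.choice(subjects, size=per_group, replace=False)
        keep = [s for s in m.values.columns if m.pairing[s] in set(chosen)]
    else:
        keep = []
        for cond in (CONTROL, CASE):
            pool = m.samples_for(cond)
            if len(pool) < per_group:
                raise ValueError(f"condition {cond!r} has < {per_group} samples")
            keep.extend(rng.choice(pool, size=per_group, replace=False))
    return m.subset_samples(sorted(keep))


def subsample_protocol(
    m: ExpressionMatrix,
    select_drugs: Callable[[ExpressionMatrix, int], set[Hashable]],
    runs: int = 10,
    per_group: int = 20,
    seed: int = 0,
) -> tuple[list[float], list[set[Hashable]]]:
    """Run a drug-selection procedure on ``runs`` random 20+20 subsamples.

    ``select_drugs(matrix, run_seed)`` returns the selected drug set
    (beneficial ∪ harmful decisions) for one subsample. Returns all
    C(runs, 2) pairwise reproducibility values plus the per-run sets.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x5AB5]))
    run_seeds = rng.integers(0, 2**31 - 1, size=runs)
    sets = []
    for i in range(runs):
        sub = _subsample(m, per_group, rng)
        sets.append(select_drugs(sub, int(run_seeds[i])))
    values = [
        reproducibility(sets[i], sets[j])
        for i, j in itertools.combinations(range(runs), 2)
    ]
    return values, sets


def igcm_baseline(
    m: ExpressionMatrix,
    lib: DrugLibrary,
    fdr_max: float = 0.01,
    fc_grid: Sequence[float] = (3.0, 3.5, 4.0, 4.5, 5.0),
    sam_n_perm: int = 1000,
    conn_n_perm: int = 10000,
    seed: int = 0,
    max_tags: int = 1000,
    cache: NullESCache | None = None,
    deg_tbl: pd.DataFrame | None = None,
) -> dict[float, list[ConnectivityResult]]:
    """Whole-signature baseline: one up/down DEG query per fold-change level.

    Tag lists longer than ``max_tags`` per direction are truncated to the
    top-|d| genes (the rank-library query-size constraint). Empty DEG lists
    are skipped with a warning.
    """
    if deg_tbl is None:
        deg_tbl = sam.deg_table(m, n_perm=sam_n_perm, seed=seed)
    if cache is None:
        cache = NullESCache(n_perm=conn_n_perm, seed=seed)
    out: dict[float, list[ConnectivityResult]] = {}
    for fc in fc_grid:
        degs = sam.select_degs(deg_tbl, fdr_max=fdr_max, fc_min=fc)
        if degs.empty:
            log.warning("no DEGs at FC threshold %g; batch skipped", fc)
            continue
        up = degs.loc[degs["direction"] == sam.UP]
        down = degs.loc[degs["direction"] == sam.DOWN]

        def top(tbl: pd.DataFrame) -> set[str]:
            if len(tbl) > max_tags:
                log.warning("tag list truncated from %d to %d by |d|", len(tbl), max_tags)
                tbl = tbl.reindex(tbl["d"].abs().sort_values(ascending=False).index).head(max_tags)
            return set(tbl.index)

        up_tags, down_tags = top(up), top(down)
        if not up_tags and not down_tags:
            continue
        out[fc] = score_query(
            lib, f"DEG_FC{fc:g}", up_tags, down_tags, seed=seed, cache=cache
        )
    return out


def selected_drugs(results: list[ConnectivityResult]) -> set[str]:
    """Beneficial ∪ harmful drugs from one query's results."""
    return {r.drug for r in results if r.classification in (BENEFICIAL, HARMFUL)}


def module_decisions(
    results_by_module: Mapping[str, list[ConnectivityResult]]
) -> set[tuple[str, str]]:
    """(module, drug) decisions over all module queries (class != neutral)."""
    out = set()
    for module, results in results_by_module.items():
        for r in results:
            if r.classification in (BENEFICIAL, HARMFUL):
                out.add((module, r.drug))
    return out


def modulewise_reproducibility(
    sets_by_run: list[set[tuple[str, str]]], modules: Sequence[str]
) -> dict[str, list[float]]:
    """Per-module pairwise reproducibility from (module, drug) decision sets."""
    out: dict[str, list[float]] = {}
    for module in modules:
        per_run = [
            {drug for mod, drug in s if mod == module} for s in sets_by_run
        ]
        out[module] = [
            reproducibility(per_run[i], per_run[j])
            for i, j in itertools.combinations(range(len(per_run)), 2)
        ]
    return out
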