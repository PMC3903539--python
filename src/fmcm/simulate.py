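"""Seeded generators for every pipeline input, with planted ground truth.

The default scenario emulates the study conditions end to end: a paired
cohort of 32 subjects (one control and one case sample each), 2,000 genes
of which eight 40-gene functional modules carry planted differential
expression (|log2 FC| = 2, i.e. linear FC = 4) and module-wide
co-expression through a shared latent factor whose strength differs by
condition (dense in the condition matching the module's direction of
dysregulation); a protein-interaction layer containing a fixed fraction of
within-module pairs plus sparse random background; a three-level ontology
whose leaves are the planted modules; and a 200-drug, 3-instances-per-drug
rank-profile library in which 30 drugs reverse their target module's
signature, 30 mimic it, and the rest are uniform random permutations.

Rank profiles are produced by sorting a planted score plus standard Gumbel
noise, so effect strength maps smoothly onto rank perturbation. All
randomness flows from one scenario seed through named substreams.

What this emulates — and what it does not: real cohort arrays carry batch
effects, probe saturation, and correlated annotation errors; none of those
are modelled, so passing tests demonstrate the machinery, not robustness
to array artifacts.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .gstop import DEFAULT_MODULE_TERMS
from .io import (
    CASE,
    CONTROL,
    DrugLibrary,
    ExpressionMatrix,
    Ontology,
    PPINetwork,
    ReferenceDrugSet,
)

REVERSE = "reverse"
MIMIC = "mimic"
NONE = "none"


@dataclass(frozen=True)
class ModuleSpec:
    """One planted functional module."""

    term: str
    label: str
    size: int = 40
    direction: str = "up"  # disease-condition direction of dysregulation
    log2_fc: float = 2.0
    factor_sd_dense: float = 1.0   # co-expression factor SD, dense condition
    factor_sd_sparse: float = 0.45  # ... sparse condition


@dataclass(frozen=True)
class ScenarioConfig:
    """Full synthetic-scenario specification (defaults = study conditions)."""

    n_genes: int = 2000
    n_subjects: int = 32
    modules: tuple[ModuleSpec, ...] = ()
    baseline_mean: float = 7.0
    baseline_sd: float = 1.0
    subject_sd: float = 0.3
    noise_sd: float = 0.55
    ppi_within: float = 0.2
    ppi_background: float = 0.002
    n_decoy_terms: int = 4
    decoy_term_size: int = 50
    n_drugs: int = 200
    instances_per_drug: int = 3
    n_reverse: int = 30
    n_mimic: int = 30
    drug_strength: float = 4.0
    background_effect: float = 0.25  # whole-signature effect, fraction of strength
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.modules:
            terms = list(DEFAULT_MODULE_TERMS.items())
            mods = tuple(
                ModuleSpec(term, label, direction="up" if i % 2 == 0 else "down")
                for i, (term, label) in enumerate(terms)
            )
            object.__setattr__(self, "modules", mods)
        total = sum(m.size for m in self.modules)
        if total > self.n_genes:
            raise ValueError("module genes exceed n_genes")
        if self.n_reverse + self.n_mimic > self.n_drugs:
            raise ValueError("planted drugs exceed n_drugs")
        for value in (self.n_genes, self.n_subjects, self.n_drugs, self.instances_per_drug):
            if value <= 0:
                raise ValueError("all counts must be positive")

    def with_seed(self, seed: int) -> "ScenarioConfig":
        return replace(self, seed=seed)


def _rng(cfg: ScenarioConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([cfg.seed, stream]))


def gene_names(cfg: ScenarioConfig) -> list[str]:
    return [f"G{i:04d}" for i in range(cfg.n_genes)]


def module_gene_map(cfg: ScenarioConfig) -> dict[str, list[str]]:
    """Deterministic assignment of the first genes to the planted modules."""
    names = gene_names(cfg)
    out: dict[str, list[str]] = {}
    offset = 0
    for spec in cfg.modules:
        out[spec.term] = names[offset : offset + spec.size]
        offset += spec.size
    return out


def gen_cohort(cfg: ScenarioConfig) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Paired control/case cohort with planted module shifts and co-expression.

    Returns the expression matrix and a per-gene truth table (module,
    direction, log2_fc; background genes have module = "").
    """
    rng = _rng(cfg, 1)
    names = gene_names(cfg)
    mod_genes = module_gene_map(cfg)
    n_sub = cfg.n_subjects
    samples = [f"S{i:02d}_{cond}" for i in range(n_sub) for cond in (CONTROL, CASE)]
    condition = pd.Series(
        {s: (CASE if s.endswith(CASE) else CONTROL) for s in samples}
    )
    pairing = pd.Series({s: s.split("_")[0] for s in samples})

    mu = rng.normal(cfg.baseline_mean, cfg.baseline_sd, size=cfg.n_genes)
    x = np.tile(mu[:, None], (1, len(samples)))
    # gene-specific subject baseline, shared by the subject's two samples
    subj_effect = rng.normal(0.0, cfg.subject_sd, size=(cfg.n_genes, n_sub))
    for j, s in enumerate(samples):
        x[:, j] += subj_effect[:, int(s[1:3])]
    x += rng.normal(0.0, cfg.noise_sd, size=x.shape)

    case_cols = np.array([condition[s] == CASE for s in samples])
    gene_idx = {g: i for i, g in enumerate(names)}
    truth_rows = []
    for spec in cfg.modules:
        rows = np.array([gene_idx[g] for g in mod_genes[spec.term]])
        shift = spec.log2_fc if spec.direction == "up" else -spec.log2_fc
        x[np.ix_(rows, np.flatnonzero(case_cols))] += shift
        # shared latent factor: dense in the condition matching the direction;
        # centred within each condition so the planted fold change is exact
        dense_case = spec.direction == "up"
        for is_case in (False, True):
            cols = np.flatnonzero(case_cols == is_case)
            sd = spec.factor_sd_dense if is_case == dense_case else spec.factor_sd_sparse
            f = rng.normal(0.0, sd, size=cols.size)
            f -= f.mean()
            x[np.ix_(rows, cols)] += f[None, :]
        for g in mod_genes[spec.term]:
            truth_rows.append(
                {"gene": g, "module": spec.term, "direction": spec.direction, "log2_fc": spec.log2_fc}
            )
    planted = {r["gene"] for r in truth_rows}
    for g in names:
        if g not in planted:
            truth_rows.append({"gene": g, "module": "", "direction": "", "log2_fc": 0.0})
    truth = pd.DataFrame(truth_rows).set_index("gene").loc[names]
    values = pd.DataFrame(x, index=names, columns=samples)
    return ExpressionMatrix(values, condition, pairing), truth


def gen_ppi_and_ontology(cfg: ScenarioConfig) -> tuple[PPINetwork, Ontology]:
    """Protein-interaction edges plus a 3-level annotation DAG.

    The interaction layer holds each within-module gene pair with
    probability ``ppi_within`` plus Erdős–Rényi background at
    ``ppi_background``; the ontology's leaves are the planted module terms
    (with a few decoy leaves of random background genes), aggregated by two
    mid-level parents under a single root.
    """
    rng = _rng(cfg, 2)
    names = gene_names(cfg)
    mod_genes = module_gene_map(cfg)
    edges: set[frozenset[str]] = set()
    for spec in cfg.modules:
        genes = mod_genes[spec.term]
        for i in range(len(genes)):
            for j in range(i + 1, len(genes)):
                if rng.random() < cfg.ppi_within:
                    edges.add(frozenset((genes[i], genes[j])))
    n = cfg.n_genes
    n_background = rng.binomial(n * (n - 1) // 2, cfg.ppi_background)
    while n_background > 0:
        i, j = rng.integers(0, n, size=2)
        if i == j:
            continue
        e = frozenset((names[i], names[j]))
        if e not in edges:
            edges.add(e)
            n_background -= 1
    ppi = PPINetwork(frozenset(edges))

    term_genes: dict[str, set[str]] = {t: set(g) for t, g in mod_genes.items()}
    background = [g for g in names if not any(g in s for s in mod_genes.values())]
    for d in range(cfg.n_decoy_terms):
        picked = rng.choice(len(background), size=min(cfg.decoy_term_size, len(background)), replace=False)
        term_genes[f"DECOY{d}"] = {background[i] for i in picked}
    terms = sorted(term_genes)
    half = len(terms) // 2
    term_parents = {t: {"BRANCH_A" if i < half else "BRANCH_B"} for i, t in enumerate(terms)}
    term_parents["BRANCH_A"] = {"ROOT"}
    term_parents["BRANCH_B"] = {"ROOT"}
    names_map = {t: DEFAULT_MODULE_TERMS.get(t, t) for t in terms}
    return ppi, Ontology(term_genes, term_parents, names_map)


def drug_effects(cfg: ScenarioConfig) -> pd.DataFrame:
    """Planted per-drug effect table: drug, effect, target modules.

    ``targets`` is a comma-joined module-term list. Most planted drugs act
    on a single module; the first two reverse drugs are broad (three and
    two target modules), mirroring the few wide-coverage hits real screens
    produce and guaranteeing that exact covers within six components exist.
    """
    terms = [m.term for m in cfg.modules]
    rows = []
    for i in range(cfg.n_drugs):
        name = f"drug{i:03d}"
        if i < cfg.n_reverse:
            effect = REVERSE
            if i == 0 and len(terms) >= 3:
                targets = terms[:3]
            elif i == 1 and len(terms) >= 5:
                targets = terms[3:5]
            else:
                targets = [terms[i % len(terms)]]
        elif i < cfg.n_reverse + cfg.n_mimic:
            effect, targets = MIMIC, [terms[i % len(terms)]]
        else:
            effect, targets = NONE, []
        rows.append({"drug": name, "effect": effect, "targets": ",".join(targets)})
    return pd.DataFrame(rows).set_index("drug")


def target_list(effects: pd.DataFrame, drug: str) -> list[str]:
    """Parse the comma-joined target column for one drug."""
    raw = effects.loc[drug, "targets"]
    return [t for t in str(raw).split(",") if t]


def gen_drug_library(
    cfg: ScenarioConfig,
) -> tuple[DrugLibrary, ReferenceDrugSet, pd.DataFrame]:
    """Rank-profile library with planted signature-reversing/mimicking drugs.

    Each instance ranking sorts ``planted score + Gumbel noise`` in
    decreasing order (rank 1 = most up-regulated under the treatment). A
    reverse drug pushes its target module's up-genes toward the bottom and
    down-genes toward the top; a mimic drug does the opposite; null drugs
    are pure noise. Reverse drugs are labelled known anti-tumor agents and
    mimic drugs known harmful agents in the reference set.
    """
    rng = _rng(cfg, 3)
    names = gene_names(cfg)
    mod_genes = module_gene_map(cfg)
    directions = {m.term: m.direction for m in cfg.modules}
    effects = drug_effects(cfg)
    n = cfg.n_genes
    cols, col_names, inst_drug = [], [], {}
    gene_idx = {g: i for i, g in enumerate(names)}
    for drug, row in effects.iterrows():
        base = np.zeros(n)
        if row["effect"] != NONE:
            sign = -1.0 if row["effect"] == REVERSE else 1.0
            # mild whole-signature effect on every disease module: one
            # disease's module signatures are correlated, so a drug that
            # reverses (mimics) one module mildly reverses (mimics) the rest
            for spec in cfg.modules:
                idx = [gene_idx[g] for g in mod_genes[spec.term]]
                mod_sign = 1.0 if spec.direction == "up" else -1.0
                base[idx] = sign * mod_sign * cfg.drug_strength * cfg.background_effect
            for target in target_list(effects, str(drug)):
                idx = [gene_idx[g] for g in mod_genes[target]]
                mod_sign = 1.0 if directions[target] == "up" else -1.0
                base[idx] = sign * mod_sign * cfg.drug_strength
        for k in range(cfg.instances_per_drug):
            score = base + rng.gumbel(0.0, 1.0, size=n)
            order = np.argsort(-score, kind="stable")
            ranks = np.empty(n, dtype=int)
            ranks[order] = np.arange(1, n + 1)
            inst = f"{drug}_i{k}"
            cols.append(ranks)
            col_names.append(inst)
            inst_drug[inst] = str(drug)
    rankings = pd.DataFrame(np.column_stack(cols), index=names, columns=col_names)
    lib = DrugLibrary(rankings, pd.Series(inst_drug))
    ref = ReferenceDrugSet(
        anti_tumor=frozenset(effects.index[effects["effect"] == REVERSE]),
        harmful_reference=frozenset(effects.index[effects["effect"] == MIMIC]),
    )
    return lib, ref, effects
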