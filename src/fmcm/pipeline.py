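"""End-to-end orchestration of the module-connectivity drug screen.

Stages: (1) condition-specific co-expression graphs restricted to the
interaction layer; (2) differential expression; (3) trend-of-progression
gene filter; (4) signed functional modules; (5) per-module connectivity
scoring against the drug library; (6) function-drug association map; (7)
exact-cover compound enumeration. Every stage output can be persisted; a
run is fully reproducible from (inputs, config, seed), and every output
file carries the configuration hash.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import sam
from .connectivity import ConnectivityResult, NullESCache, results_table, score_query
from .evaluation import igcm_baseline
from .fdam import FDAM, build_fdam, compounds_table, therapeutic_compounds
from .gstop import (
    DEFAULT_MODULE_TERMS,
    FunctionalModule,
    assemble_modules,
    gstop_filter,
    modules_to_gmt,
)
from .io import (
    CASE,
    CONTROL,
    DrugLibrary,
    ExpressionMatrix,
    Ontology,
    PPINetwork,
    write_gmt,
)
from .network import FFN, CondGraph, build_ggin, conditional_go_enrichment, pearson_edge_stats, reduce_to_ffn
from .sam import directions_of

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """All thresholds and sizes of one screening run."""

    p0: float = 0.001
    fdr_max: float = 0.01
    fc_min: float = 2.0
    beneficial_max: float = -0.5
    harmful_min: float = 0.3
    p_max: float = 0.005
    component_es_max: float = -0.75
    max_components: int = 6
    max_class_degree: int = 2
    enrichment_alpha: float = 0.01
    module_terms: dict[str, str] = field(default_factory=lambda: dict(DEFAULT_MODULE_TERMS))
    sam_n_perm: int = 1000
    conn_n_perm: int = 10000
    igcm_fc_grid: tuple[float, ...] = (3.0, 3.5, 4.0, 4.5, 5.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.p0 <= 1 and 0 < self.fdr_max < 1 and self.fc_min > 1):
            raise ValueError("thresholds out of documented ranges")
        if not (self.beneficial_max < 0 < self.harmful_min):
            raise ValueError("beneficial_max must be negative, harmful_min positive")

    def hash(self) -> str:
        payload = yaml.safe_dump(_plain(asdict(self)), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(_plain(asdict(self)), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        if "igcm_fc_grid" in data:
            data["igcm_fc_grid"] = tuple(data["igcm_fc_grid"])
        return cls(**data)


def _plain(obj):
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    return obj


@dataclass
class PipelineInputs:
    expression: ExpressionMatrix
    ppi: PPINetwork
    ontology: Ontology
    library: DrugLibrary


@dataclass
class FMCMRun:
    """Everything a screening run produces."""

    config: RunConfig
    ggin_nor: CondGraph
    ggin_ade: CondGraph
    ffn_nor: FFN
    ffn_ade: FFN
    deg_table: pd.DataFrame
    degs: pd.DataFrame
    cancer_genes: set[str]
    modules: list[FunctionalModule]
    results: dict[str, list[ConnectivityResult]]
    fdam: FDAM | None
    compounds: list

    def all_results(self) -> list[ConnectivityResult]:
        return [r for rs in self.results.values() for r in rs]


def _stage_seed(cfg: RunConfig, stage: int) -> int:
    h = hashlib.sha256(f"{cfg.seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31 - 1)


def build_condition_networks(
    m: ExpressionMatrix, ppi: PPINetwork, onto: Ontology, cfg: RunConfig
) -> tuple[CondGraph, CondGraph, FFN, FFN]:
    """Stage 1: per-condition graphs + their function-function reductions."""
    universe = set(m.gene_ids) & onto.annotated_genes
    graphs, ffns = {}, {}
    for cond in (CONTROL, CASE):
        stats = pearson_edge_stats(m, ppi, cond)
        graph = build_ggin(stats, cfg.p0, cond)
        graphs[cond] = graph
        selected = graph.nodes & universe
        if selected:
            enr = conditional_go_enrichment(selected, onto, universe, cfg.enrichment_alpha)
            terms = list(enr.loc[enr["significant"], "term"])
        else:
            terms = []
        if terms:
            ffns[cond] = reduce_to_ffn(graph, terms, onto)
        else:
            log.warning("no enriched terms for condition %r", cond)
            ffns[cond] = FFN(cond, {})
    return graphs[CONTROL], graphs[CASE], ffns[CONTROL], ffns[CASE]


def run_fmcm(
    inputs: PipelineInputs,
    cfg: RunConfig | None = None,
    out_dir: str | Path | None = None,
    deg_tbl: pd.DataFrame | None = None,
    cache: NullESCache | None = None,
) -> FMCMRun:
    """Run the full module-connectivity screen.

    Any stage failure aborts with a stage-labelled message. With
    ``out_dir`` every intermediate is persisted; identical inputs, config
    and seed give byte-identical output files.
    """
    cfg = cfg or RunConfig()
    m, ppi, onto, lib = inputs.expression, inputs.ppi, inputs.ontology, inputs.library

    def stage(name: str):
        log.info("stage: %s", name)

    try:
        stage("condition networks")
        ggin_nor, ggin_ade, ffn_nor, ffn_ade = build_condition_networks(m, ppi, onto, cfg)
    except Exception as exc:
        raise RuntimeError(f"[networks] {exc}") from exc

    try:
        stage("differential expression")
        if deg_tbl is None:
            deg_tbl = sam.deg_table(m, n_perm=cfg.sam_n_perm, seed=_stage_seed(cfg, 2))
        degs = sam.select_degs(deg_tbl, cfg.fdr_max, cfg.fc_min)
    except Exception as exc:
        raise RuntimeError(f"[differential-expression] {exc}") from exc

    try:
        stage("trend filter + modules")
        directions = directions_of(degs)
        cancer_genes = gstop_filter(ggin_nor, ggin_ade, directions)
        modules = assemble_modules(
            cancer_genes & set(degs.index), directions, ffn_nor, ffn_ade, cfg.module_terms
        )
    except Exception as exc:
        raise RuntimeError(f"[modules] {exc}") from exc

    try:
        stage("connectivity scoring")
        if cache is None:
            cache = NullESCache(n_perm=cfg.conn_n_perm, seed=_stage_seed(cfg, 4))
        results: dict[str, list[ConnectivityResult]] = {}
        for mod in modules:
            if not mod.genes:
                log.warning("module %s empty; drug scoring skipped", mod.term_id)
                continue
            results[mod.term_id] = score_query(
                lib,
                mod.term_id,
                mod.up_genes,
                mod.down_genes,
                beneficial_max=cfg.beneficial_max,
                harmful_min=cfg.harmful_min,
                p_max=cfg.p_max,
                cache=cache,
            )
    except Exception as exc:
        raise RuntimeError(f"[connectivity] {exc}") from exc

    try:
        stage("association map + compounds")
        flat = [r for rs in results.values() for r in rs]
        try:
            fdam = build_fdam(flat)
        except ValueError as exc:
            log.warning("association map empty: %s", exc)
            fdam, compounds = None, []
        else:
            _, compounds = therapeutic_compounds(
                fdam, cfg.max_components, cfg.component_es_max, cfg.max_class_degree
            )
    except Exception as exc:
        raise RuntimeError(f"[compounds] {exc}") from exc

    run = FMCMRun(
        config=cfg,
        ggin_nor=ggin_nor,
        ggin_ade=ggin_ade,
        ffn_nor=ffn_nor,
        ffn_ade=ffn_ade,
        deg_table=deg_tbl,
        degs=degs,
        cancer_genes=cancer_genes,
        modules=modules,
        results=results,
        fdam=fdam,
        compounds=compounds,
    )
    if out_dir is not None:
        persist_run(run, Path(out_dir))
    return run


def run_igcm(
    inputs: PipelineInputs,
    cfg: RunConfig | None = None,
    out_dir: str | Path | None = None,
    deg_tbl: pd.DataFrame | None = None,
    cache: NullESCache | None = None,
) -> dict[float, list[ConnectivityResult]]:
    """Whole-signature baseline over the configured fold-change grid."""
    cfg = cfg or RunConfig()
    if not inputs.library.instances:
        raise ValueError("[igcm] drug library is empty")
    if cache is None:
        cache = NullESCache(n_perm=cfg.conn_n_perm, seed=_stage_seed(cfg, 4))
    batches = igcm_baseline(
        inputs.expression,
        inputs.library,
        fdr_max=cfg.fdr_max,
        fc_grid=cfg.igcm_fc_grid,
        sam_n_perm=cfg.sam_n_perm,
        seed=_stage_seed(cfg, 2),
        cache=cache,
        deg_tbl=deg_tbl,
    )
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        flat = [r for rs in batches.values() for r in rs]
        _write_tsv(results_table(flat), out / "igcm_results.tsv", cfg)
        cfg.to_yaml(out / "config.yaml")
    return batches


# ---------------------------------------------------------------------------
# persistence
# ---------------------------------------------------------------------------


def _write_tsv(df: pd.DataFrame, path: Path, cfg: RunConfig) -> None:
    with open(path, "w") as fh:
        fh.write(f"# config_hash={cfg.hash()}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.6g")


def persist_run(run: FMCMRun, out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    cfg = run.config
    cfg.to_yaml(out / "config.yaml")
    (out / "provenance.json").write_text(
        json.dumps({"config_hash": cfg.hash(), "seed": cfg.seed}, indent=2, sort_keys=True)
        + "\n"
    )
    for label, graph in (("nor", run.ggin_nor), ("ade", run.ggin_ade)):
        _write_tsv(graph.edge_table(), out / f"ggin_{label}_edges.tsv", cfg)
        _write_tsv(graph.node_table(), out / f"ggin_{label}_nodes.tsv", cfg)
    for label, ffn in (("nor", run.ffn_nor), ("ade", run.ffn_ade)):
        _write_tsv(ffn.node_table(), out / f"ffn_{label}_nodes.tsv", cfg)
        _write_tsv(ffn.edge_table(), out / f"ffn_{label}_edges.tsv", cfg)
    deg = run.deg_table.copy()
    deg.insert(0, "gene", deg.index)
    _write_tsv(deg, out / "deg_table.tsv", cfg)
    write_gmt(modules_to_gmt(run.modules), out / "modules.gmt")
    _write_tsv(results_table(run.all_results()), out / "connectivity.tsv", cfg)
    if run.fdam is not None:
        _write_tsv(run.fdam.links, out / "fdam.tsv", cfg)
    _write_tsv(compounds_table(run.compounds), out / "compounds.tsv", cfg)
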