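"""Gene selection by trend of disease progression (GSToP) and assembly of
the signed functional modules that query the drug library.

A candidate gene survives the trend filter iff it appears in at least one
of the two condition graphs and its network prominence moves with its
expression change: for an up-regulated gene, degree and clustering
coefficient must be non-decreasing from the control graph to the disease
graph with at least one strict increase; for a down-regulated gene the
mirrored inequalities hold. A gene absent from one graph scores (0, 0)
there, which makes the comparison total while still requiring presence
somewhere.

Functional modules are the configured ontology terms (by default the
eight disease functions: apoptosis, cell cycle, cell proliferation, DNA
replication, immune system process, RNA metabolic process, transcription,
signal transduction), each holding the trend-surviving differentially
expressed genes annotated to the term, split by expression direction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping

from .network import CondGraph, FFN
from .sam import DOWN, UP

log = logging.getLogger(__name__)

#: Abbreviation -> label for the default module terms.
DEFAULT_MODULE_TERMS: dict[str, str] = {
    "At": "apoptosis",
    "CC": "cell cycle",
    "CP": "cell proliferation",
    "DR": "DNA replication",
    "IS": "immune system process",
    "RM": "RNA metabolic process",
    "Ts": "transcription",
    "ST": "signal transduction",
}


@dataclass
class FunctionalModule:
    """An ontology term with its signed (up/down) surviving gene sets."""

    term_id: str
    label: str
    up_genes: set[str] = field(default_factory=set)
    down_genes: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        overlap = self.up_genes & self.down_genes
        if overlap:
            raise ValueError(f"module {self.term_id}: genes in both directions: {sorted(overlap)[:5]}")

    @property
    def genes(self) -> set[str]:
        return self.up_genes | self.down_genes

    @property
    def size(self) -> int:
        return len(self.up_genes) + len(self.down_genes)


def gstop_filter(
    nor: CondGraph,
    ade: CondGraph,
    directions: Mapping[str, str],
    candidates: set[str] | None = None,
) -> set[str]:
    """Return the candidate genes passing the trend-of-progression filter.

    ``directions`` maps each candidate to "up"/"down". A candidate with no
    direction is an error; a candidate in neither graph simply fails.
    """
    if candidates is None:
        candidates = set(directions)
    kept: set[str] = set()
    for gene in candidates:
        if gene not in directions:
            raise KeyError(f"gene {gene!r} has no expression direction")
        in_nor = gene in nor.graph
        in_ade = gene in ade.graph
        if not (in_nor or in_ade):
            continue
        k_n, c_n = nor.metrics(gene)
        k_a, c_a = ade.metrics(gene)
        if directions[gene] == UP:
            ok = k_a >= k_n and c_a >= c_n and (k_a > k_n or c_a > c_n)
        elif directions[gene] == DOWN:
            ok = k_n >= k_a and c_n >= c_a and (k_n > k_a or c_n > c_a)
        else:
            raise ValueError(f"gene {gene!r}: direction must be up/down, got {directions[gene]!r}")
        if ok:
            kept.add(gene)
    return kept


def assemble_modules(
    cancer_genes: set[str],
    directions: Mapping[str, str],
    ffn_nor: FFN | Mapping[str, set[str]],
    ffn_ade: FFN | Mapping[str, set[str]],
    module_terms: Mapping[str, str] = DEFAULT_MODULE_TERMS,
) -> list[FunctionalModule]:
    """Build signed functional modules from the SAM ∩ GSToP gene set.

    For each module term the gene scope is the union of the term's gene
    sets in the control and disease function-function networks; module
    members are the cancer genes (trend survivors that are also DEGs) in
    that scope, split by DEG direction. Empty modules are retained but
    flagged with a warning so drug scoring can skip them.
    """
    scope_nor = ffn_nor.term_genes if isinstance(ffn_nor, FFN) else dict(ffn_nor)
    scope_ade = ffn_ade.term_genes if isinstance(ffn_ade, FFN) else dict(ffn_ade)
    modules = []
    for term, label in module_terms.items():
        scope = scope_nor.get(term, set()) | scope_ade.get(term, set())
        members = cancer_genes & scope & set(directions)
        up = {g for g in members if directions[g] == UP}
        down = members - up
        if not members:
            log.warning("module %s (%s) is empty", term, label)
        modules.append(FunctionalModule(term, label, up, down))
    return modules


def modules_to_gmt(modules: list[FunctionalModule]) -> dict[str, set[str]]:
    """One GMT entry per module-direction (e.g. ``CC_up``, ``CC_down``)."""
    out: dict[str, set[str]] = {}
    for mod in modules:
        out[f"{mod.term_id}_up"] = set(mod.up_genes)
        out[f"{mod.term_id}_down"] = set(mod.down_genes)
    return out


def modules_from_gmt(sets: Mapping[str, set[str]], module_terms: Mapping[str, str] = DEFAULT_MODULE_TERMS) -> list[FunctionalModule]:
    """Inverse of :func:`modules_to_gmt`."""
    modules = []
    for term, label in module_terms.items():
        up = set(sets.get(f"{term}_up", set()))
        down = set(sets.get(f"{term}_down", set()))
        if f"{term}_up" in sets or f"{term}_down" in sets:
            modules.append(FunctionalModule(term, label, up, down))
    return modules
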