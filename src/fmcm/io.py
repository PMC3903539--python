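"""Readers and writers for every external format the pipeline touches.

All formats are plain tab-separated text:

* expression: genes x samples TSV plus a two-column sample->condition table
* protein-protein interactions: two-column symbol pairs
* ontology: gene->term and term->parent tables
* gene sets: standard GMT
* drug rank-profile library: rank matrix (genes x instances) plus an
  instance->drug table
* reference drugs: two-column (drug, label) table

Validation is strict: malformed input raises ``FormatError`` naming the
offending row/column rather than silently coercing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

CONTROL = "control"
CASE = "case"


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


# ---------------------------------------------------------------------------
# domain containers
# ---------------------------------------------------------------------------


@dataclass
class ExpressionMatrix:
    """Genes x samples intensity matrix (log2 scale) with condition labels.

    ``values`` is indexed by gene symbol with one column per sample.
    ``condition`` maps each sample to ``"control"`` or ``"case"``.
    ``pairing`` optionally maps each sample to a subject identifier; when
    present every subject must contribute exactly one control and one case
    sample (a paired cohort).
    """

    values: pd.DataFrame
    condition: pd.Series
    pairing: pd.Series | None = None

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.values.index.duplicated().any():
            dupes = self.values.index[self.values.index.duplicated()].tolist()
            raise FormatError(f"duplicate gene identifiers: {dupes[:5]}")
        missing = [s for s in self.values.columns if s not in self.condition.index]
        if missing:
            raise FormatError(f"samples without a condition label: {missing[:5]}")
        bad = set(self.condition.loc[list(self.values.columns)]) - {CONTROL, CASE}
        if bad:
            raise FormatError(f"unknown condition labels: {sorted(bad)}")
        if self.pairing is not None:
            pair = self.pairing.loc[list(self.values.columns)]
            for subject, samples in pair.groupby(pair).groups.items():
                labels = sorted(self.condition.loc[list(samples)])
                if labels != [CASE, CONTROL]:
                    raise FormatError(
                        f"subject {subject!r} must have exactly one control and "
                        f"one case sample, got {labels}"
                    )

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def samples_for(self, condition: str) -> list[str]:
        return [s for s in self.values.columns if self.condition[s] == condition]

    def subset_samples(self, samples: Iterable[str]) -> "ExpressionMatrix":
        samples = list(samples)
        pairing = self.pairing.loc[samples] if self.pairing is not None else None
        return ExpressionMatrix(
            self.values[samples].copy(), self.condition.loc[samples].copy(), pairing
        )


@dataclass(frozen=True)
class PPINetwork:
    """Undirected protein-protein interaction network (symbol pairs)."""

    edges: frozenset[frozenset[str]]

    @property
    def genes(self) -> set[str]:
        return {g for e in self.edges for g in e}

    def __len__(self) -> int:
        return len(self.edges)

    def pairs(self) -> list[tuple[str, str]]:
        """Edges as sorted 2-tuples, in deterministic order."""
        return sorted(tuple(sorted(e)) for e in self.edges)


@dataclass
class Ontology:
    """Gene-annotation DAG: term -> directly annotated genes, term -> parents."""

    term_genes: dict[str, set[str]]
    term_parents: dict[str, set[str]]
    term_names: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for term in self.term_parents:
            self.term_genes.setdefault(term, set())
            for parent in self.term_parents[term]:
                self.term_genes.setdefault(parent, set())
        g = self.dag()
        if not nx.is_directed_acyclic_graph(g):
            cycle = nx.find_cycle(g)
            raise FormatError(f"ontology parent relation is cyclic: {cycle}")

    def dag(self) -> nx.DiGraph:
        """Child -> parent digraph over all known terms."""
        g = nx.DiGraph()
        g.add_nodes_from(self.term_genes)
        for child, parents in self.term_parents.items():
            g.add_edges_from((child, p) for p in parents)
        return g

    def descendants(self, term: str) -> set[str]:
        return nx.ancestors(self.dag(), term)  # child->parent edges

    def effective_genes(self, term: str) -> set[str]:
        """Genes annotated to ``term`` directly or via any descendant term."""
        genes = set(self.term_genes.get(term, ()))
        for d in self.descendants(term):
            genes |= self.term_genes.get(d, set())
        return genes

    @property
    def annotated_genes(self) -> set[str]:
        return {g for gs in self.term_genes.values() for g in gs}


@dataclass
class DrugLibrary:
    """Instance-level full-gene rank profiles with an instance->drug map.

    ``rankings`` is a genes x instances DataFrame of integer ranks; each
    column is a permutation of 1..n_genes, rank 1 = most up-regulated by the
    treatment. ``instance_drug`` maps every instance (column) to one drug.
    """

    rankings: pd.DataFrame
    instance_drug: pd.Series

    def __post_init__(self) -> None:
        n = len(self.rankings.index)
        expected = np.arange(1, n + 1)
        for col in self.rankings.columns:
            ranks = np.sort(self.rankings[col].to_numpy())
            if not np.array_equal(ranks, expected):
                raise FormatError(
                    f"instance {col!r}: column is not a permutation of 1..{n}"
                )
        unmapped = [c for c in self.rankings.columns if c not in self.instance_drug.index]
        if unmapped:
            raise FormatError(f"instances without a drug mapping: {unmapped[:5]}")

    @property
    def gene_universe(self) -> list[str]:
        return list(self.rankings.index)

    @property
    def instances(self) -> list[str]:
        return list(self.rankings.columns)

    @property
    def drugs(self) -> list[str]:
        return sorted(set(self.instance_drug.loc[list(self.rankings.columns)]))

    def instances_of(self, drug: str) -> list[str]:
        return sorted(
            c for c in self.rankings.columns if self.instance_drug[c] == drug
        )


@dataclass(frozen=True)
class ReferenceDrugSet:
    """Reference labels: known anti-tumor drugs and known harmful agents."""

    anti_tumor: frozenset[str]
    harmful_reference: frozenset[str] = frozenset()


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------


def read_condition_table(path: str | Path) -> tuple[pd.Series, pd.Series | None]:
    """Read a sample table: sample, condition[, subject] (TSV, with header)."""
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    if df.shape[1] < 2:
        raise FormatError(f"{path}: condition table needs >=2 columns")
    df = df.set_index(df.columns[0])
    condition = df.iloc[:, 0]
    pairing = df.iloc[:, 1] if len(df.columns) >= 2 else None
    return condition, pairing


def read_expression(
    path: str | Path,
    condition: Mapping[str, str] | pd.Series,
    pairing: Mapping[str, str] | pd.Series | None = None,
) -> ExpressionMatrix:
    """Read a genes x samples TSV (header = sample ids, first column = genes).

    Duplicate gene rows are collapsed by per-gene maximum intensity. Any
    non-numeric cell is a hard error naming the row and column.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str, comment="#")
    values = pd.DataFrame(index=df.index, columns=df.columns, dtype=float)
    for col in df.columns:
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[converted.isna() & df[col].notna()]
        if len(bad):
            raise FormatError(
                f"{path}: non-numeric value at gene {bad[0]!r}, sample {col!r}"
            )
        if converted.isna().any():
            missing = df.index[converted.isna()][0]
            raise FormatError(f"{path}: missing value at gene {missing!r}, sample {col!r}")
        values[col] = converted
    if values.index.duplicated().any():
        n_dup = int(values.index.duplicated().sum())
        log.info("collapsing %d duplicate gene rows by per-gene maximum", n_dup)
        values = values.groupby(level=0, sort=False).max()
    condition = pd.Series(dict(condition)) if not isinstance(condition, pd.Series) else condition
    missing = [s for s in values.columns if s not in condition.index]
    if missing:
        raise FormatError(f"{path}: no condition label for sample(s) {missing[:5]}")
    if pairing is not None and not isinstance(pairing, pd.Series):
        pairing = pd.Series(dict(pairing))
    return ExpressionMatrix(values, condition, pairing)


def read_ppi(path: str | Path) -> PPINetwork:
    """Read a two-column TSV of interacting gene symbols.

    Symmetric duplicates and self-loops are dropped; the retained edge count
    is logged. An empty file is an error.
    """
    edges: set[frozenset[str]] = set()
    n_lines = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise FormatError(f"{path}:{lineno}: expected 2 columns")
            a, b = fields[0], fields[1]
            n_lines += 1
            if a == b:
                continue  # self-loop
            edges.add(frozenset((a, b)))
    if n_lines == 0:
        raise FormatError(f"{path}: empty interaction file")
    log.info("read %d interactions (%d input lines)", len(edges), n_lines)
    return PPINetwork(frozenset(edges))


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """Read a GMT gene-set file: name, description, genes... (tab-separated).

    Genes repeated within a line are counted once. A repeated set name is an
    error (ambiguous definition).
    """
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: GMT line needs >=3 fields")
            name = fields[0]
            if name in sets:
                raise FormatError(f"{path}:{lineno}: duplicate gene-set name {name!r}")
            sets[name] = {g for g in fields[2:] if g}
    return sets


def read_ontology(
    gene_term_path: str | Path,
    term_parent_path: str | Path,
    term_name_path: str | Path | None = None,
) -> Ontology:
    """Read an ontology from gene->term and term->parent two-column TSVs."""
    term_genes: dict[str, set[str]] = {}
    with open(gene_term_path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise FormatError(f"{gene_term_path}:{lineno}: expected 2 columns")
            gene, term = fields[0], fields[1]
            term_genes.setdefault(term, set()).add(gene)
    term_parents: dict[str, set[str]] = {}
    with open(term_parent_path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise FormatError(f"{term_parent_path}:{lineno}: expected 2 columns")
            child, parent = fields[0], fields[1]
            term_parents.setdefault(child, set()).add(parent)
    names: dict[str, str] = {}
    if term_name_path is not None:
        with open(term_name_path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                fields = line.split("\t")
                if len(fields) >= 2:
                    names[fields[0]] = fields[1]
    return Ontology(term_genes, term_parents, names)


def read_drug_library(rank_path: str | Path, instance_path: str | Path) -> DrugLibrary:
    """Read a rank-matrix TSV (genes x instances) and an instance->drug TSV.

    Every column must be a permutation of 1..n_genes; violations are errors
    naming the instance. Every instance must map to exactly one drug.
    """
    ranks = pd.read_csv(rank_path, sep="\t", index_col=0, comment="#")
    try:
        ranks = ranks.astype(int)
    except ValueError as exc:
        raise FormatError(f"{rank_path}: non-integer rank cell ({exc})") from exc
    inst = pd.read_csv(instance_path, sep="\t", dtype=str, comment="#")
    if inst.shape[1] < 2:
        raise FormatError(f"{instance_path}: instance table needs 2 columns")
    first = inst.columns[0]
    if inst[first].duplicated().any():
        dup = inst[first][inst[first].duplicated()].iloc[0]
        raise FormatError(f"{instance_path}: instance {dup!r} mapped more than once")
    instance_drug = inst.set_index(first).iloc[:, 0]
    return DrugLibrary(ranks, instance_drug)


def read_reference_drugs(path: str | Path) -> ReferenceDrugSet:
    """Read a two-column (drug, label) TSV; labels: anti_tumor, harmful_reference."""
    anti, harmful = set(), set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise FormatError(f"{path}:{lineno}: expected 2 columns")
            drug, label = fields[0], fields[1]
            if label == "anti_tumor":
                anti.add(drug)
            elif label == "harmful_reference":
                harmful.add(drug)
            else:
                raise FormatError(f"{path}:{lineno}: unknown label {label!r}")
    return ReferenceDrugSet(frozenset(anti), frozenset(harmful))


# ---------------------------------------------------------------------------
# writers (round-trip counterparts of the readers)
# ---------------------------------------------------------------------------


def write_expression(m: ExpressionMatrix, path: str | Path) -> None:
    m.values.to_csv(path, sep="\t", index_label="gene", float_format="%.6g")


def write_condition_table(m: ExpressionMatrix, path: str | Path) -> None:
    df = pd.DataFrame({"condition": m.condition.loc[list(m.values.columns)]})
    if m.pairing is not None:
        df["subject"] = m.pairing.loc[list(m.values.columns)]
    df.to_csv(path, sep="\t", index_label="sample")


def write_ppi(ppi: PPINetwork, path: str | Path) -> None:
    with open(path, "w") as fh:
        for a, b in ppi.pairs():
            fh.write(f"{a}\t{b}\n")


def write_gmt(sets: Mapping[str, Iterable[str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name in sorted(sets):
            genes = "\t".join(sorted(set(sets[name])))
            fh.write(f"{name}\tna\t{genes}\n")


def write_ontology(onto: Ontology, gene_term_path: str | Path, term_parent_path: str | Path) -> None:
    with open(gene_term_path, "w") as fh:
        for term in sorted(onto.term_genes):
            for gene in sorted(onto.term_genes[term]):
                fh.write(f"{gene}\t{term}\n")
    with open(term_parent_path, "w") as fh:
        for child in sorted(onto.term_parents):
            for parent in sorted(onto.term_parents[child]):
                fh.write(f"{child}\t{parent}\n")


def write_drug_library(lib: DrugLibrary, rank_path: str | Path, instance_path: str | Path) -> None:
    lib.rankings.to_csv(rank_path, sep="\t", index_label="gene")
    df = pd.DataFrame({"drug": lib.instance_drug.loc[list(lib.rankings.columns)]})
    df.to_csv(instance_path, sep="\t", index_label="instance")


def write_reference_drugs(ref: ReferenceDrugSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for drug in sorted(ref.anti_tumor):
            fh.write(f"{drug}\tanti_tumor\n")
        for drug in sorted(ref.harmful_reference):
            fh.write(f"{drug}\tharmful_reference\n")
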