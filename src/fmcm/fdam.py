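"""Function-drug association map (FDAM) and therapeutic drug compounds.

The FDAM is a bipartite map linking functional modules to drugs through
classified (beneficial/harmful) connectivity edges; only drugs with at
least one beneficial link are admitted. A drug's degree counts all of its
links, beneficial and harmful alike.

A therapeutic compound is an EXACT cover of the module set by purely
beneficial drugs: component beneficial-module sets are pairwise disjoint
and their union is the full module set, so no module is treated twice and
none is missed. Drugs whose beneficial coverage is small (|set| <= 2 by
default) and identical are interchangeable and collapse into a single
class slot; broader-coverage drugs stay individual. Components must pass a
per-link enrichment-score filter (every beneficial link at or below
-0.75 by default).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .connectivity import BENEFICIAL, HARMFUL, ConnectivityResult

log = logging.getLogger(__name__)

COMPONENT_ES_MAX = -0.75


@dataclass
class FDAM:
    """Bipartite module <-> drug map with classified links."""

    links: pd.DataFrame  # columns: module, drug, es, class

    def __post_init__(self) -> None:
        required = {"module", "drug", "es", "class"}
        if not required <= set(self.links.columns):
            raise ValueError(f"FDAM links need columns {sorted(required)}")
        bad = set(self.links["class"]) - {BENEFICIAL, HARMFUL}
        if bad:
            raise ValueError(f"FDAM links must be classified, got {sorted(bad)}")
        by_drug = self.links.groupby("drug")["class"]
        no_benefit = [d for d, cls in by_drug if BENEFICIAL not in set(cls)]
        if no_benefit:
            raise ValueError(
                f"every FDAM drug needs >=1 beneficial link; violated by {no_benefit[:5]}"
            )

    @property
    def modules(self) -> list[str]:
        return sorted(set(self.links["module"]))

    @property
    def drugs(self) -> list[str]:
        return sorted(set(self.links["drug"]))

    def degree(self, drug: str) -> int:
        """Number of links (beneficial + harmful) the drug carries."""
        return int((self.links["drug"] == drug).sum())

    def beneficial_modules(self, drug: str) -> set[str]:
        sel = (self.links["drug"] == drug) & (self.links["class"] == BENEFICIAL)
        return set(self.links.loc[sel, "module"])

    def harmful_modules(self, drug: str) -> set[str]:
        sel = (self.links["drug"] == drug) & (self.links["class"] == HARMFUL)
        return set(self.links.loc[sel, "module"])

    def beneficial_es(self, drug: str) -> dict[str, float]:
        sel = (self.links["drug"] == drug) & (self.links["class"] == BENEFICIAL)
        return dict(zip(self.links.loc[sel, "module"], self.links.loc[sel, "es"]))


@dataclass(frozen=True)
class Slot:
    """A compound component: one drug, or an interchangeability class.

    ``drug_es`` maps each member drug to the worst (largest) enrichment
    score among its beneficial links.
    """

    name: str
    modules: frozenset[str]
    drug_es: tuple[tuple[str, float], ...]  # (drug, worst beneficial ES)

    @property
    def drugs(self) -> tuple[str, ...]:
        return tuple(d for d, _ in self.drug_es)


@dataclass(frozen=True)
class Compound:
    """An exact cover of the module set by disjoint beneficial slots."""

    components: tuple[Slot, ...]

    @property
    def covered(self) -> frozenset[str]:
        return frozenset(m for slot in self.components for m in slot.modules)

    @property
    def degree_ratio(self) -> tuple[int, ...]:
        return tuple(sorted((len(s.modules) for s in self.components), reverse=True))

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(s.name for s in self.components)


def build_fdam(results: Iterable[ConnectivityResult]) -> FDAM:
    """Assemble the FDAM from classified per-module connectivity results.

    Neutral results are ignored; drugs with only harmful links are dropped
    (a drug enters the map only through at least one beneficial link).
    """
    rows = [
        {"module": r.query_id, "drug": r.drug, "es": r.es, "class": r.classification}
        for r in results
        if r.classification in (BENEFICIAL, HARMFUL)
    ]
    df = pd.DataFrame(rows, columns=["module", "drug", "es", "class"])
    if df.empty:
        raise ValueError("no classified (non-neutral) links; FDAM would be empty")
    with_benefit = set(df.loc[df["class"] == BENEFICIAL, "drug"])
    dropped = sorted(set(df["drug"]) - with_benefit)
    if dropped:
        log.info("dropping %d drug(s) with only harmful links", len(dropped))
    df = df.loc[df["drug"].isin(with_benefit)].reset_index(drop=True)
    df = df.sort_values(["drug", "module"], kind="stable").reset_index(drop=True)
    return FDAM(df)


def fdam_from_table(links: pd.DataFrame) -> FDAM:
    """Build an FDAM from a (module, drug, es) table, classifying by sign.

    Links with es < -0.5 are beneficial, es > 0.3 harmful; anything in
    between is rejected (a published map should contain only classified
    links).
    """
    cls = []
    for es in links["es"]:
        if es < -0.5:
            cls.append(BENEFICIAL)
        elif es > 0.3:
            cls.append(HARMFUL)
        else:
            raise ValueError(f"unclassifiable link with es={es}")
    df = links.copy()
    df["class"] = cls
    return FDAM(df[["module", "drug", "es", "class"]].reset_index(drop=True))


def purely_beneficial(fdam: FDAM) -> set[str]:
    """Drugs with zero harmful links (the candidate therapeutic drugs)."""
    return {d for d in fdam.drugs if not fdam.harmful_modules(d)}


def collapse_classes(
    drugs: Mapping[str, set[str]],
    max_class_degree: int = 2,
    drug_es: Mapping[str, float] | None = None,
) -> list[Slot]:
    """Collapse drugs with identical small beneficial coverage into slots.

    Drugs whose beneficial-module sets are identical and of size at most
    ``max_class_degree`` merge into one interchangeability class slot
    (named by the sorted module abbreviations); drugs with broader coverage
    remain individual slots under their own names.
    """
    drug_es = dict(drug_es or {})
    slots: list[Slot] = []
    classes: dict[frozenset[str], list[str]] = {}
    for drug in sorted(drugs):
        mods = frozenset(drugs[drug])
        if not mods:
            continue
        if len(mods) <= max_class_degree:
            classes.setdefault(mods, []).append(drug)
        else:
            slots.append(
                Slot(drug, mods, ((drug, drug_es.get(drug, float("nan"))),))
            )
    for mods, members in classes.items():
        name = "+".join(sorted(mods))
        slots.append(
            Slot(
                name,
                mods,
                tuple((d, drug_es.get(d, float("nan"))) for d in sorted(members)),
            )
        )
    return sorted(slots, key=lambda s: s.name)


def _filter_slot(slot: Slot, component_es_max: float | None) -> Slot | None:
    """Drop member drugs failing the per-link ES filter; None if emptied.

    A drug passes when the worst of its beneficial links is at or below
    ``component_es_max``; drugs with unknown ES (NaN) are kept.
    """
    if component_es_max is None:
        return slot
    kept = tuple(
        (d, es) for d, es in slot.drug_es if not (es == es and es > component_es_max)
    )
    if not kept:
        return None
    return Slot(slot.name, slot.modules, kept)


def enumerate_compounds(
    slots: Sequence[Slot],
    modules: Iterable[str],
    max_components: int = 6,
    component_es_max: float | None = COMPONENT_ES_MAX,
) -> list[Compound]:
    """Enumerate all exact covers of ``modules`` by at most ``max_components``
    pairwise-disjoint slots.

    Depth-first search over a fixed module order: at each step branch over
    the slots that cover the first uncovered module and are disjoint from
    the partial cover. Output order is deterministic (lexicographic by the
    tuple of slot names).
    """
    if max_components < 1:
        raise ValueError("max_components must be >= 1")
    modules = sorted(set(modules))
    usable = []
    for slot in sorted(slots, key=lambda s: s.name):
        filtered = _filter_slot(slot, component_es_max)
        if filtered is not None and filtered.modules <= set(modules):
            usable.append(filtered)
    by_module: dict[str, list[Slot]] = {m: [] for m in modules}
    for slot in usable:
        for m in slot.modules:
            by_module[m].append(slot)

    covers: list[Compound] = []
    target = set(modules)

    def dfs(covered: set[str], chosen: list[Slot]) -> None:
        if covered == target:
            covers.append(Compound(tuple(sorted(chosen, key=lambda s: (-len(s.modules), s.name)))))
            return
        if len(chosen) >= max_components:
            return
        first_uncovered = next(m for m in modules if m not in covered)
        for slot in by_module[first_uncovered]:
            if slot.modules & covered:
                continue
            chosen.append(slot)
            dfs(covered | slot.modules, chosen)
            chosen.pop()

    dfs(set(), [])
    if not covers:
        log.info("no exact cover of %d modules exists within %d components", len(modules), max_components)
    covers.sort(key=lambda c: (len(c.components), c.names))
    return covers


def compounds_table(compounds: list[Compound]) -> pd.DataFrame:
    rows = [
        {
            "compound": i + 1,
            "n_components": len(c.components),
            "components": " + ".join(c.names),
            "degree_ratio": ":".join(str(d) for d in c.degree_ratio),
        }
        for i, c in enumerate(compounds)
    ]
    return pd.DataFrame(rows, columns=["compound", "n_components", "components", "degree_ratio"])


def therapeutic_compounds(
    fdam: FDAM,
    max_components: int = 6,
    component_es_max: float | None = COMPONENT_ES_MAX,
    max_class_degree: int = 2,
) -> tuple[list[Slot], list[Compound]]:
    """End-to-end compound search: purely beneficial drugs -> slots -> covers."""
    pure = purely_beneficial(fdam)
    coverage = {d: fdam.beneficial_modules(d) for d in pure}
    worst_es = {d: max(fdam.beneficial_es(d).values()) for d in pure}
    slots = collapse_classes(coverage, max_class_degree, worst_es)
    compounds = enumerate_compounds(slots, fdam.modules, max_components, component_es_max)
    return slots, compounds
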