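"""Two-level Kolmogorov-Smirnov connectivity scoring of signed gene sets
against a drug rank-profile library.

Level 1 (instance). For a tag set occupying sorted positions V(1..t) in an
instance's n-gene ranking, the signed KS statistic is

    a = max_j ( j/t - V(j)/n ),   b = max_j ( V(j)/n - (j-1)/t )
    ks = a  if a > b  else  -b

(positive = tags concentrate at the top, i.e. the instance up-regulates
them). The instance connectivity of a signed query is

    s = ks_up - ks_down   if the two statistics have opposite signs,
    s = 0                 otherwise;

with a single tag list, s = ks_up or s = -ks_down. Positive s means the
instance mimics the disease signature; negative s means it reverses it.

Level 2 (drug). All instances are ordered by s (descending, ties broken
lexicographically by instance id) and the drug's enrichment score ES is the
KS statistic of its instances' positions in that ordering. ES < 0 means
the drug's instances sit among the signature-reversing instances.

A drug is called beneficial when ES < -0.5 with an instance-set
randomization p < 0.005, harmful when ES > 0.3 (no p gate), else neutral.
The randomization null draws same-size instance sets uniformly; since such
draws depend only on (set size, library size), the null sample is cached
per (t, n) pair — an exact reformulation, not an approximation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import DrugLibrary

log = logging.getLogger(__name__)

BENEFICIAL = "beneficial"
HARMFUL = "harmful"
NEUTRAL = "neutral"

#: default classification thresholds
BENEFICIAL_MAX = -0.5
HARMFUL_MIN = 0.3
P_MAX = 0.005


@dataclass(frozen=True)
class ConnectivityResult:
    query_id: str
    drug: str
    es: float
    perm_p: float
    n_instances: int
    classification: str


def ks_score(tag_positions: Sequence[int], n: int) -> float:
    """Signed KS statistic of tag positions within a ranking of length n."""
    pos = np.asarray(sorted(tag_positions), dtype=float)
    t = pos.size
    if t == 0:
        raise ValueError("empty tag position list")
    if t > n or pos[0] < 1 or pos[-1] > n or np.unique(pos).size != t:
        raise ValueError(f"positions must be distinct integers in 1..{n}")
    j = np.arange(1, t + 1, dtype=float)
    a = float(np.max(j / t - pos / n))
    b = float(np.max(pos / n - (j - 1) / t))
    return a if a > b else -b


def _positions(ranking: pd.Series, tags: set[str]) -> np.ndarray:
    """Ranks occupied by tag genes; tags absent from the universe dropped."""
    present = [g for g in tags if g in ranking.index]
    dropped = len(tags) - len(present)
    if dropped:
        log.warning("%d tag gene(s) absent from library universe; dropped", dropped)
    if not present:
        raise ValueError("no tag gene present in the library gene universe")
    return ranking.loc[present].to_numpy()


def instance_connectivity(
    up_tags: set[str], down_tags: set[str], ranking: pd.Series
) -> float:
    """Connectivity s of a signed query to one instance ranking."""
    if not up_tags and not down_tags:
        raise ValueError("at least one of up/down tag sets must be non-empty")
    n = len(ranking)
    ks_up = ks_score(_positions(ranking, up_tags), n) if up_tags else None
    ks_down = ks_score(_positions(ranking, down_tags), n) if down_tags else None
    if ks_up is not None and ks_down is not None:
        if np.sign(ks_up) == np.sign(ks_down):
            return 0.0
        return ks_up - ks_down
    if ks_up is not None:
        return ks_up
    return -ks_down


def score_instances(
    lib: DrugLibrary, up_tags: set[str], down_tags: set[str]
) -> pd.Series:
    """Instance -> connectivity s for a signed query, vectorized over tags."""
    if not up_tags and not down_tags:
        raise ValueError("at least one of up/down tag sets must be non-empty")
    n = len(lib.rankings.index)
    index = set(lib.rankings.index)
    s = pd.Series(0.0, index=lib.rankings.columns)

    def tag_ks(tags: set[str]) -> np.ndarray | None:
        present = sorted(tags & index)
        if len(present) < len(tags):
            log.warning(
                "%d tag gene(s) absent from library universe; dropped",
                len(tags) - len(present),
            )
        if not present:
            return None
        pos = np.sort(lib.rankings.loc[present].to_numpy(dtype=float), axis=0)
        t = pos.shape[0]
        j = np.arange(1, t + 1, dtype=float)[:, None]
        a = (j / t - pos / n).max(axis=0)
        b = (pos / n - (j - 1) / t).max(axis=0)
        return np.where(a > b, a, -b)

    ks_up = tag_ks(up_tags) if up_tags else None
    ks_down = tag_ks(down_tags) if down_tags else None
    if ks_up is None and ks_down is None:
        raise ValueError("all tag genes absent from the library gene universe")
    if ks_up is not None and ks_down is not None:
        vals = np.where(np.sign(ks_up) == np.sign(ks_down), 0.0, ks_up - ks_down)
    elif ks_up is not None:
        vals = ks_up
    else:
        vals = -ks_down
    s[:] = vals
    return s


def instance_order(s_by_instance: Mapping[str, float] | pd.Series) -> list[str]:
    """Instances ordered by s descending, ties lexicographic by instance id."""
    items = list(pd.Series(s_by_instance).items())
    return [k for k, _ in sorted(items, key=lambda kv: (-kv[1], kv[0]))]


def drug_es(lib: DrugLibrary, s_by_instance: Mapping[str, float] | pd.Series) -> pd.Series:
    """Drug-level enrichment score: KS of each drug's instance positions."""
    order = instance_order(s_by_instance)
    position = {inst: i + 1 for i, inst in enumerate(order)}
    n = len(order)
    out = {}
    for drug in lib.drugs:
        insts = lib.instances_of(drug)
        if not insts:
            log.warning("drug %r has no instances; skipped", drug)
            continue
        if len(insts) == n:
            log.warning("drug %r owns every library instance (degenerate ES)", drug)
        out[drug] = ks_score([position[i] for i in insts], n)
    return pd.Series(out, name="es").sort_index()


class NullESCache:
    """Cached randomization null: ES of uniform random t-subsets of 1..n.

    The instance-set randomization null depends only on (t, n), so one
    sample of ``n_perm`` null scores serves every drug with t instances.
    """

    def __init__(self, n_perm: int = 10000, seed: int = 0) -> None:
        if n_perm < 1000:
            raise ValueError("n_perm must be >= 1000")
        self.n_perm = n_perm
        self._seed = seed
        self._cache: dict[tuple[int, int], np.ndarray] = {}

    def null_scores(self, t: int, n: int) -> np.ndarray:
        key = (t, n)
        if key not in self._cache:
            rng = np.random.default_rng(np.random.SeedSequence([self._seed, t, n]))
            scores = np.empty(self.n_perm)
            j = np.arange(1, t + 1, dtype=float)
            for i in range(self.n_perm):
                pos = np.sort(rng.choice(n, size=t, replace=False) + 1).astype(float)
                a = np.max(j / t - pos / n)
                b = np.max(pos / n - (j - 1) / t)
                scores[i] = a if a > b else -b
            self._cache[key] = scores
        return self._cache[key]

    def p_value(self, es: float, t: int, n: int) -> float:
        """Add-one-smoothed same-sign tail probability of |ES*| >= |ES|."""
        null = self.null_scores(t, n)
        if es >= 0:
            extreme = int(np.sum(null >= es))
        else:
            extreme = int(np.sum(null <= es))
        return (1 + extreme) / (1 + self.n_perm)


def permutation_p(
    lib: DrugLibrary,
    s_by_instance: Mapping[str, float] | pd.Series,
    drug: str,
    n_perm: int = 10000,
    seed: int = 0,
    cache: NullESCache | None = None,
) -> float:
    """Randomization p for one drug's ES (same-sign tail, add-one smoothed)."""
    if cache is None:
        cache = NullESCache(n_perm=n_perm, seed=seed)
    insts = lib.instances_of(drug)
    n = len(lib.instances)
    order = instance_order(s_by_instance)
    position = {inst: i + 1 for i, inst in enumerate(order)}
    es = ks_score([position[i] for i in insts], n)
    return cache.p_value(es, len(insts), n)


def classify(
    es: float,
    p: float,
    beneficial_max: float = BENEFICIAL_MAX,
    harmful_min: float = HARMFUL_MIN,
    p_max: float = P_MAX,
) -> str:
    """Beneficial iff ES below threshold AND p below gate; harmful iff ES
    above threshold (no p requirement); else neutral."""
    if not (beneficial_max < 0 < harmful_min):
        raise ValueError("thresholds must satisfy beneficial_max < 0 < harmful_min")
    if es < beneficial_max and p < p_max:
        return BENEFICIAL
    if es > harmful_min:
        return HARMFUL
    return NEUTRAL


def score_query(
    lib: DrugLibrary,
    query_id: str,
    up_tags: set[str],
    down_tags: set[str],
    n_perm: int = 10000,
    seed: int = 0,
    beneficial_max: float = BENEFICIAL_MAX,
    harmful_min: float = HARMFUL_MIN,
    p_max: float = P_MAX,
    cache: NullESCache | None = None,
) -> list[ConnectivityResult]:
    """Score one signed query against every drug in the library."""
    s = score_instances(lib, up_tags, down_tags)
    es = drug_es(lib, s)
    if cache is None:
        cache = NullESCache(n_perm=n_perm, seed=seed)
    n = len(lib.instances)
    results = []
    for drug, score in es.items():
        t = len(lib.instances_of(drug))
        p = cache.p_value(float(score), t, n)
        results.append(
            ConnectivityResult(
                query_id=query_id,
                drug=str(drug),
                es=float(score),
                perm_p=p,
                n_instances=t,
                classification=classify(float(score), p, beneficial_max, harmful_min, p_max),
            )
        )
    return results


def results_table(results: list[ConnectivityResult]) -> pd.DataFrame:
    rows = [
        {
            "query_id": r.query_id,
            "drug": r.drug,
            "es": r.es,
            "p": r.perm_p,
            "n_instances": r.n_instances,
            "class": r.classification,
        }
        for r in results
    ]
    return pd.DataFrame(
        rows, columns=["query_id", "drug", "es", "p", "n_instances", "class"]
    )
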