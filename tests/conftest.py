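import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from fmcm.io import CASE, CONTROL, DrugLibrary, ExpressionMatrix
from fmcm.pipeline import RunConfig
from fmcm.simulate import ModuleSpec, ScenarioConfig

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


SMALL_TERMS = {"At": "apoptosis", "CC": "cell cycle", "CP": "cell proliferation", "DR": "DNA replication"}


@pytest.fixture(scope="session")
def small_scenario() -> ScenarioConfig:
    """A reduced scenario for cheap end-to-end tests."""
    mods = tuple(
        ModuleSpec(term, label, size=20, direction="up" if i % 2 == 0 else "down")
        for i, (term, label) in enumerate(SMALL_TERMS.items())
    )
    return ScenarioConfig(
        n_genes=400,
        n_subjects=24,
        modules=mods,
        n_drugs=40,
        instances_per_drug=3,
        n_reverse=8,
        n_mimic=8,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_config() -> RunConfig:
    return RunConfig(
        module_terms=dict(SMALL_TERMS),
        sam_n_perm=200,
        conn_n_perm=2000,
        seed=7,
    )


def paired_matrix(
    control: np.ndarray, case: np.ndarray, genes: list[str] | None = None
) -> ExpressionMatrix:
    """Build a paired two-condition matrix from (genes x subjects) arrays."""
    control = np.atleast_2d(control)
    case = np.atleast_2d(case)
    n_genes, n_sub = control.shape
    genes = genes or [f"g{i}" for i in range(n_genes)]
    cols, data = [], []
    for j in range(n_sub):
        cols += [f"S{j:02d}_control", f"S{j:02d}_case"]
    values = np.empty((n_genes, 2 * n_sub))
    values[:, 0::2] = control
    values[:, 1::2] = case
    condition = pd.Series(
        {c: (CASE if c.endswith("case") else CONTROL) for c in cols}
    )
    pairing = pd.Series({c: c.split("_")[0] for c in cols})
    return ExpressionMatrix(pd.DataFrame(values, index=genes, columns=cols), condition, pairing)


def library_from_rankings(rank_columns: dict[str, list[str]], instance_drug: dict[str, str]) -> DrugLibrary:
    """Build a DrugLibrary from per-instance gene orderings (top first)."""
    genes = sorted(rank_columns[next(iter(rank_columns))])
    data = {}
    for inst, order in rank_columns.items():
        ranks = {g: i + 1 for i, g in enumerate(order)}
        data[inst] = [ranks[g] for g in genes]
    df = pd.DataFrame(data, index=genes)
    return DrugLibrary(df, pd.Series(instance_drug))
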