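"""SAM-style differential expression with permutation FDR.

The moderated t-like statistic is

    d_i = (mean_case_i - mean_control_i) / (s_i + s0)

with s_i the pooled gene-specific standard error and s0 a small "fudge
factor" that damps the statistic for genes with near-zero variance. Fold
change is computed on the linear scale from log2 intensities as
2**(mean_case - mean_control), so "FC > 2" selects both FC > 2 and
FC < 1/2 (reciprocal rule for down-regulation).

The false discovery rate is estimated by permutation: for each gene the
q-value is the median, over permuted datasets, of the number of permuted
|d*| at least as large as the gene's |d|, divided by the observed count at
that threshold, clipped to [0, 1] and monotonized down the |d| ranking so
that threshold sets are nested. Permutations respect subject pairing
(sign flips) when pairing is present, otherwise full label permutations.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .io import CASE, CONTROL, ExpressionMatrix

UP = "up"
DOWN = "down"


def _group_arrays(m: ExpressionMatrix) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Return (values, case_mask, columns) with >=2 samples per condition."""
    x = m.values.to_numpy(dtype=float)
    labels = m.condition.loc[list(m.values.columns)].to_numpy()
    case_mask = labels == CASE
    if case_mask.sum() < 2 or (~case_mask).sum() < 2:
        raise ValueError(
            f"need >=2 samples per condition, got case={int(case_mask.sum())} "
            f"control={int((~case_mask).sum())}"
        )
    return x, case_mask, np.asarray(m.values.columns)


def _d_and_s(x: np.ndarray, case_mask: np.ndarray, s0: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized d statistic, pooled SE s_i and mean log2 difference."""
    xc = x[:, case_mask]
    xn = x[:, ~case_mask]
    n1, n2 = xc.shape[1], xn.shape[1]
    diff = xc.mean(axis=1) - xn.mean(axis=1)
    ss = ((xc - xc.mean(axis=1, keepdims=True)) ** 2).sum(axis=1) + (
        (xn - xn.mean(axis=1, keepdims=True)) ** 2
    ).sum(axis=1)
    s = np.sqrt((1.0 / n1 + 1.0 / n2) * ss / (n1 + n2 - 2))
    denom = s + s0
    with np.errstate(divide="ignore", invalid="ignore"):
        d = np.where(denom > 0, diff / np.where(denom > 0, denom, 1.0), np.where(diff > 0, np.inf, np.where(diff < 0, -np.inf, 0.0)))
    return d, s, diff


def sam_statistic(m: ExpressionMatrix, s0: float = 0.0) -> pd.DataFrame:
    """Per-gene d statistic, pooled SE and linear-scale fold change.

    With ``s0 == 0`` a gene whose pooled SE is zero gets an infinite d
    (flagged in the ``finite`` column); any positive s0 guarantees finite d.
    """
    if s0 < 0:
        raise ValueError("s0 must be >= 0")
    x, case_mask, _ = _group_arrays(m)
    d, s, diff = _d_and_s(x, case_mask, s0)
    return pd.DataFrame(
        {
            "d": d,
            "s": s,
            "fold_change": np.exp2(diff),
            "finite": np.isfinite(d),
        },
        index=m.values.index,
    )


def estimate_s0(s_values: np.ndarray | list[float], d_numerator: np.ndarray | None = None, n_windows: int = 100) -> float:
    """Choose the fudge factor s0 from candidate percentiles of s_i.

    Candidates are the 0, 5, ..., 95th percentiles of the gene-wise pooled
    SEs. For each candidate the genes are split into quantile windows by
    s_i; the chosen s0 minimizes the coefficient of variation, across
    windows, of the median absolute deviation of d = r_i / (s_i + s0),
    where r_i is the raw mean-difference numerator. Deterministic.
    """
    s = np.asarray(s_values, dtype=float)
    if s.size == 0:
        raise ValueError("empty s list")
    if s.size < 10:
        raise ValueError("need >=10 genes to estimate s0")
    if np.allclose(s, s[0]):
        return float(s[0])
    if d_numerator is None:
        raise ValueError("d_numerator (per-gene mean differences) is required")
    r = np.asarray(d_numerator, dtype=float)
    order = np.argsort(s, kind="stable")
    s_sorted, r_sorted = s[order], r[order]
    nw = max(2, min(n_windows, s.size // 5))
    windows = np.array_split(np.arange(s.size), nw)
    candidates = np.percentile(s, np.arange(0, 100, 5))
    best_s0, best_cv = float(candidates[0]), np.inf
    for s0 in candidates:
        d = r_sorted / (s_sorted + s0)
        mads = np.array([np.median(np.abs(d[w] - np.median(d[w]))) for w in windows])
        mean = mads.mean()
        if mean == 0:
            continue
        cv = mads.std(ddof=0) / mean
        if cv < best_cv - 1e-12:
            best_cv, best_s0 = cv, float(s0)
    return best_s0


def _permuted_masks(
    m: ExpressionMatrix, n_perm: int, rng: np.random.Generator
) -> np.ndarray:
    """(n_perm, n_samples) boolean case masks under the permutation null.

    Paired cohort: per subject, swap its control/case labels with
    probability 1/2 (sign-flip scheme). Unpaired: full label permutation.
    """
    labels = m.condition.loc[list(m.values.columns)].to_numpy()
    base = labels == CASE
    n_samples = base.size
    masks = np.empty((n_perm, n_samples), dtype=bool)
    if m.pairing is not None:
        pairing = m.pairing.loc[list(m.values.columns)].to_numpy()
        subjects = pd.unique(pairing)
        cols_of = {subj: np.flatnonzero(pairing == subj) for subj in subjects}
        for p in range(n_perm):
            mask = base.copy()
            flips = rng.random(len(subjects)) < 0.5
            for subj, flip in zip(subjects, flips):
                if flip:
                    idx = cols_of[subj]
                    mask[idx] = ~mask[idx]
            masks[p] = mask
    else:
        for p in range(n_perm):
            masks[p] = rng.permutation(base)
    return masks


def sam_fdr(
    m: ExpressionMatrix, s0: float, n_perm: int = 1000, seed: int = 0
) -> pd.Series:
    """Permutation q-value per gene (see module docstring for the estimator)."""
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    x, case_mask, _ = _group_arrays(m)
    d_obs, _, _ = _d_and_s(x, case_mask, s0)
    abs_obs = np.abs(d_obs)
    order = np.argsort(-abs_obs, kind="stable")  # descending |d|
    thresholds = abs_obs[order]
    # observed count of |d| >= threshold is just the 1-based rank
    obs_counts = np.arange(1, abs_obs.size + 1)

    rng = np.random.default_rng(seed)
    masks = _permuted_masks(m, n_perm, rng)
    sorted_thr = np.sort(thresholds)  # ascending, for searchsorted
    perm_counts = np.empty((n_perm, abs_obs.size), dtype=np.int64)
    for p in range(n_perm):
        d_perm, _, _ = _d_and_s(x, masks[p], s0)
        abs_perm = np.sort(np.abs(d_perm))
        # count of permuted |d*| >= each observed threshold
        counts_asc = abs_perm.size - np.searchsorted(abs_perm, sorted_thr, side="left")
        perm_counts[p] = counts_asc[::-1]  # align to descending thresholds
    med = np.median(perm_counts, axis=0)
    q_sorted = np.clip(med / obs_counts, 0.0, 1.0)
    q_sorted = np.maximum.accumulate(q_sorted)  # monotone in descending |d|
    q = np.empty_like(q_sorted)
    q[order] = q_sorted
    return pd.Series(q, index=m.values.index, name="q")


def deg_table(
    m: ExpressionMatrix,
    s0: float | None = None,
    n_perm: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Full differential-expression table: d, fold_change, q, direction.

    When ``s0`` is None it is estimated from the data (percentile search).
    """
    if s0 is None:
        x, case_mask, _ = _group_arrays(m)
        _, s, diff = _d_and_s(x, case_mask, 0.0)
        s0 = estimate_s0(s, diff)
    stats = sam_statistic(m, s0)
    q = sam_fdr(m, s0, n_perm=n_perm, seed=seed)
    out = pd.DataFrame(
        {
            "d": stats["d"],
            "fold_change": stats["fold_change"],
            "q": q,
            "direction": np.where(stats["fold_change"] > 1.0, UP, DOWN),
        }
    )
    out.attrs["s0"] = float(s0)
    return out


def select_degs(table: pd.DataFrame, fdr_max: float = 0.01, fc_min: float = 2.0) -> pd.DataFrame:
    """Select differentially expressed genes by q and reciprocal fold change.

    Keeps genes with q < fdr_max and (FC > fc_min or FC < 1/fc_min),
    tagged up/down. ``fc_min`` must exceed 1.
    """
    if fc_min <= 1:
        raise ValueError("fc_min must be > 1")
    fc = table["fold_change"]
    keep = (table["q"] < fdr_max) & ((fc > fc_min) | (fc < 1.0 / fc_min))
    return table.loc[keep]


def directions_of(degs: pd.DataFrame) -> dict[str, str]:
    """gene -> up/down mapping from a selected DEG table."""
    return dict(zip(degs.index, degs["direction"]))


def write_deg_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index_label="gene", float_format="%.6g")
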