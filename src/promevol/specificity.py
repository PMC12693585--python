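"""Tissue-specificity index tau and tissue-restricted gene-set selection.

tau grades how concentrated a gene's expression is across tissues:
tau = sum_i (1 - x_i / x_max) / (N - 1), 0 for uniform expression and 1
for single-tissue expression. Gene sets are built by requiring tau above
a threshold AND the expression maximum in the target tissue, so that the
index identifies not just specificity but the tissue that dominates.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def tau(profile, log_transform: bool = False) -> float:
    """Tissue-specificity index in [0, 1]; NaN for an all-zero profile.

    Parameters
    ----------
    profile : array-like of non-negative expression values, length >= 2.
    log_transform : apply log2(x + 1) before computing the index.
    """
    x = np.asarray(profile, dtype=float)
    if x.ndim != 1 or len(x) < 2:
        raise ValueError("profile must be a 1-D vector over >= 2 tissues")
    if np.any(x < 0) or not np.all(np.isfinite(x)):
        raise ValueError("expression values must be finite and non-negative")
    if log_transform:
        x = np.log2(x + 1.0)
    xmax = x.max()
    if xmax == 0:
        return float("nan")
    return float(np.sum(1.0 - x / xmax) / (len(x) - 1))


def tau_table(matrix: pd.DataFrame, log_transform: bool = False) -> pd.DataFrame:
    """Per-gene tau and top tissue for a gene x tissue expression matrix.

    Returns a DataFrame with columns gene, tau, top_tissue in the input
    gene order. tau is NaN for all-zero genes.
    """
    _validate_matrix(matrix)
    taus = [tau(row, log_transform=log_transform) for row in matrix.to_numpy()]
    top = matrix.idxmax(axis=1)
    return pd.DataFrame({"gene": matrix.index, "tau": taus, "top_tissue": top.to_numpy()})


def select_gene_set(
    matrix: pd.DataFrame,
    target_tissue: str,
    tau_min: float = 0.9,
    log_transform: bool = False,
) -> list[str]:
    """Genes with tau >= tau_min whose expression peaks in ``target_tissue``.

    Original matrix order is preserved. All-zero genes never qualify.
    """
    _validate_matrix(matrix)
    if target_tissue not in matrix.columns:
        raise KeyError(f"unknown tissue {target_tissue!r}")
    table = tau_table(matrix, log_transform=log_transform)
    keep = (table["tau"] >= tau_min) & (table["top_tissue"] == target_tissue)
    return table.loc[keep.fillna(False), "gene"].tolist()


def top_specific_genes(
    matrix: pd.DataFrame,
    target_tissue: str,
    k: int = 50,
    tau_min: float = 0.9,
) -> list[str]:
    """The k most tissue-specific genes peaking in the target tissue.

    Ranks qualifying genes by tau descending, ties broken by gene id, and
    truncates to k (the Malpighian-tubule-style control set).
    """
    table = tau_table(matrix)
    keep = (table["tau"] >= tau_min) & (table["top_tissue"] == target_tissue)
    sub = table.loc[keep.fillna(False)].sort_values(
        ["tau", "gene"], ascending=[False, True], kind="mergesort"
    )
    return sub["gene"].head(k).tolist()


def random_control_sample(universe, exclude, k: int, seed) -> list[str]:
    """k distinct genes drawn from universe \\ exclude, reproducible per seed."""
    exclude = set(exclude)
    pool = [g for g in universe if g not in exclude]
    if k < 0:
        raise ValueError("k must be non-negative")
    if len(pool) < k:
        raise ValueError(f"universe has only {len(pool)} genes outside the excluded set, need {k}")
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(pool), size=k, replace=False)
    return [pool[i] for i in idx]


def _validate_matrix(matrix: pd.DataFrame) -> None:
    if matrix.shape[1] < 2:
        raise ValueError("tissue matrix needs >= 2 tissues")
    if matrix.index.duplicated().any():
        raise ValueError("duplicate gene ids in tissue matrix")
    if (matrix.to_numpy() < 0).any():
        raise ValueError("tissue matrix must be non-negative")
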