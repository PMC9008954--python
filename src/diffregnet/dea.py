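"""SAM-style differential expression screen and Ward sample clustering.

The screen computes, per gene, the moderated relative difference

    d = (mean_A - mean_B) / (s + s0)

where ``s`` is the two-class unpaired pooled standard error and ``s0`` a
fudge constant damping the statistic for low-variance genes. Significance
is assessed by permuting condition labels: the per-gene q-value is the
median (across permutations) number of null |d| values at least as extreme,
divided by the observed count, clipped to [0, 1] and made monotone in |d|.

By default ``s0`` is the 5th percentile of the per-gene standard errors, a
deterministic stand-in for the full quantile-tuning procedure of the
original method.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch

from ._stats import exceedance_counts, monotonize_fdr
from .dataio import ExpressionDataset

S0_PERCENTILE = 5.0


@dataclass
class SamParams:
    """Parameters of the SAM screen.

    ``s0=None`` requests the automatic choice (5th percentile of the
    per-gene pooled standard errors). ``q_cut``/``lfc_cut`` are the joint
    significance thresholds (q < 0.05 and |log2 fold change| > 1.5 by
    default).
    """

    s0: float | None = None
    n_perm: int = 200
    seed: int = 0
    q_cut: float = 0.05
    lfc_cut: float = 1.5

    def __post_init__(self) -> None:
        if self.s0 is not None and self.s0 < 0:
            raise ValueError("s0 must be nonnegative")
        if self.n_perm < 1:
            raise ValueError("n_perm must be positive")


def _pooled_se(x_a: np.ndarray, x_b: np.ndarray) -> np.ndarray:
    n_a, n_b = x_a.shape[1], x_b.shape[1]
    ss = ((x_a - x_a.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    ss += ((x_b - x_b.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    return np.sqrt((1.0 / n_a + 1.0 / n_b) * ss / (n_a + n_b - 2))


def sam_test(ds: ExpressionDataset, params: SamParams | None = None) -> pd.DataFrame:
    """Two-class unpaired SAM screen with permutation q-values.

    Returns a frame (gene, d_stat, log2_fc, q_value, significant) sorted by
    |d_stat| descending. Condition A is the first label in sorted order, so
    positive ``d``/``log2_fc`` mean higher expression in A.
    """
    params = params or SamParams()
    cond_a, cond_b = ds.conditions
    mat = ds.values.to_numpy(dtype=float)
    labels = ds.condition_of.to_numpy()
    idx_a = np.flatnonzero(labels == cond_a)
    idx_b = np.flatnonzero(labels == cond_b)
    if len(idx_a) < 3 or len(idx_b) < 3:
        raise ValueError("sam_test requires >= 3 samples per condition")

    x_a, x_b = mat[:, idx_a], mat[:, idx_b]
    diff = x_a.mean(axis=1) - x_b.mean(axis=1)
    s = _pooled_se(x_a, x_b)
    s0 = float(np.percentile(s, S0_PERCENTILE)) if params.s0 is None else float(params.s0)
    denom = s + s0
    if np.any((denom == 0) & (diff != 0)):
        raise ValueError(
            "s + s0 = 0 for a gene with unequal group means; supply a positive s0"
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        d = np.where(denom > 0, diff / denom, 0.0)

    abs_d = np.abs(d)
    rng = np.random.default_rng(params.seed)
    n = mat.shape[1]
    counts = np.empty((params.n_perm, len(d)))
    for p in range(params.n_perm):
        # permute the label vector: exactly symmetric under condition swap
        perm_labels = labels[rng.permutation(n)]
        pa, pb = mat[:, perm_labels == cond_a], mat[:, perm_labels == cond_b]
        pd_diff = pa.mean(axis=1) - pb.mean(axis=1)
        ps = _pooled_se(pa, pb)
        with np.errstate(divide="ignore", invalid="ignore"):
            null_d = np.where(ps + s0 > 0, pd_diff / (ps + s0), 0.0)
        counts[p] = exceedance_counts(abs_d, np.abs(null_d))
    median_null = np.median(counts, axis=0)
    obs_ge = exceedance_counts(abs_d, abs_d)
    q = np.clip(median_null / obs_ge, 0.0, 1.0)
    q = monotonize_fdr(abs_d, q)

    out = pd.DataFrame(
        {
            "gene": ds.genes,
            "d_stat": d,
            "log2_fc": diff,
            "q_value": q,
            "significant": (q < params.q_cut) & (np.abs(diff) > params.lfc_cut),
        }
    )
    out = out.iloc[np.lexsort((out["gene"].to_numpy(), -out["d_stat"].abs().to_numpy()))]
    return out.reset_index(drop=True)


def ward_cluster(data, genes) -> tuple[np.ndarray, pd.Series]:
    """Ward-linkage hierarchical clustering of samples over a gene subset.

    ``data`` may be an :class:`ExpressionDataset` or a genes x samples
    DataFrame. Returns the scipy linkage matrix and the 2-cluster label per
    sample (Euclidean distance over the selected genes).
    """
    frame = data.values if isinstance(data, ExpressionDataset) else data
    genes = list(genes)
    if not genes:
        raise ValueError("ward_cluster requires a non-empty gene subset")
    missing = [g for g in genes if g not in frame.index]
    if missing:
        raise ValueError(f"genes not in dataset: {missing[:5]}")
    points = frame.loc[genes].to_numpy(dtype=float).T  # samples x genes
    if points.shape[0] < 2:
        raise ValueError("ward_cluster requires >= 2 samples")
    linkage = sch.linkage(points, method="ward", metric="euclidean")
    labels = sch.fcluster(linkage, t=2, criterion="maxclust")
    return linkage, pd.Series(labels, index=list(frame.columns), name="cluster")
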