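"""Small shared statistical helpers: permutation machinery, FDR monotonization
and the log-fold-change envelope filter used by both the co-expression and
the regulation-efficacy screens."""

from __future__ import annotations

import numpy as np


def monotonize_fdr(scores: np.ndarray, fdr: np.ndarray) -> np.ndarray:
    """Make the FDR estimate nonincreasing in the statistic.

    For each item the reported value is the minimum raw FDR over all items
    with a smaller-or-equal score (the usual q-value construction: a more
    extreme statistic can never have a larger q than a less extreme one).
    """
    scores = np.asarray(scores, dtype=float)
    fdr = np.asarray(fdr, dtype=float)
    order = np.argsort(scores, kind="stable")  # ascending: least significant first
    out = np.empty_like(fdr)
    running = np.inf
    for idx in order:
        running = min(running, fdr[idx])
        out[idx] = running
    # items tied on the score must share the same q
    sorted_scores = scores[order]
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and sorted_scores[j + 1] == sorted_scores[i]:
            j += 1
        if j > i:
            tied = order[i : j + 1]
            out[tied] = out[tied].min()
        i = j + 1
    return out


def exceedance_counts(observed: np.ndarray, pool: np.ndarray) -> np.ndarray:
    """#{pool >= observed_i} for every i, via a single sort."""
    pool_sorted = np.sort(np.asarray(pool, dtype=float))
    obs = np.asarray(observed, dtype=float)
    return len(pool_sorted) - np.searchsorted(pool_sorted, obs, side="left")


def permuted_group_indices(rng: np.random.Generator, n_a: int, n_b: int):
    """One random relabelling: indices of the pseudo-A and pseudo-B groups."""
    perm = rng.permutation(n_a + n_b)
    return perm[:n_a], perm[n_a:]


def lfc_envelope_exceeds(
    m: np.ndarray, f: np.ndarray, bins: int, env_q: float
) -> tuple[np.ndarray, dict]:
    """Flag points whose fold change ``f`` exceeds the fitted envelope curve.

    Points are binned into ``bins`` equal-count bins by the magnitude ``m``;
    within each bin the ``env_q`` quantile of ``f`` defines an envelope
    point, and a power law ``f_hat(m) = a * m**b`` is least-squares fitted
    to the usable envelope points in log-log space. A point is flagged iff
    ``f > f_hat(m)``. When fewer than two usable envelope points exist
    (e.g. the bulk of ``f`` is exactly zero) the filter degrades to a global
    ``env_q``-quantile threshold on ``f``.

    Returns the boolean flags and a small diagnostics dict.
    """
    m = np.asarray(m, dtype=float)
    f = np.asarray(f, dtype=float)
    if len(m) == 0:
        return np.zeros(0, dtype=bool), {"mode": "empty"}
    # canonical order so the result is invariant to input permutation
    order = np.lexsort((f, m))
    chunks = np.array_split(order, bins)
    pts_m, pts_f = [], []
    for chunk in chunks:
        if len(chunk) == 0:
            continue
        mq = float(np.median(m[chunk]))
        fq = float(np.quantile(f[chunk], env_q))
        if mq > 0.0 and fq > 0.0:
            pts_m.append(mq)
            pts_f.append(fq)
    if len(pts_m) >= 2 and len(set(pts_m)) >= 2:
        slope, intercept = np.polyfit(np.log(pts_m), np.log(pts_f), 1)
        a, b = float(np.exp(intercept)), float(slope)
        with np.errstate(divide="ignore", invalid="ignore"):
            f_hat = np.where(m > 0, a * np.power(np.maximum(m, 1e-300), b), np.inf)
        return f > f_hat, {"mode": "powerlaw", "a": a, "b": b, "n_points": len(pts_m)}
    threshold = float(np.quantile(f, env_q))
    return f > threshold, {"mode": "global_quantile", "threshold": threshold}


def ranking_auroc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Probability that a random positive outscores a random negative.

    Exact rank-based computation; ties contribute 0.5. Raises on degenerate
    label sets.
    """
    from scipy.stats import rankdata

    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    n_pos = int(labels.sum())
    n_neg = int(len(labels) - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUROC undefined: need at least one positive and one negative")
    ranks = rankdata(scores)  # midranks for ties
    r_pos = ranks[labels].sum()
    return float((r_pos - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))
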