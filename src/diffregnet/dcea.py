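"""Differential co-expression analysis.

Two complementary screens over per-condition Pearson correlations of gene
pairs:

* ``dcp_*`` — a per-gene statistic: the root-mean-square change of a gene's
  correlations with its *qualified* partners between the two conditions,
  with significance from a sample-label permutation FDR (differentially
  co-expressed genes, DCGs);
* ``lfc_dcls`` — a per-pair screen flagging links whose correlation fold
  change exceeds an envelope curve fitted over the correlation-magnitude
  range, plus a direct rule for strong sign switches (differentially
  co-expressed links, DCLs).

Pair tables are plain DataFrames with one row per unordered gene pair
(gene_u before gene_v in dataset order), the tabular form of the
pair-correlation records.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from ._stats import exceedance_counts, lfc_envelope_exceeds, monotonize_fdr
from .dataio import ExpressionDataset

logger = logging.getLogger(__name__)

PAIR_COLUMNS = ["gene_u", "gene_v", "r_a", "r_b", "valid", "qualified"]


def _condition_corr(mat: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Full correlation matrix; zero-variance genes get 0 rows/cols."""
    sd = mat.std(axis=1, ddof=1)
    degenerate = sd == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        corr = np.corrcoef(mat)
    corr = np.atleast_2d(corr)
    corr[~np.isfinite(corr)] = 0.0
    if degenerate.any():
        corr[degenerate, :] = 0.0
        corr[:, degenerate] = 0.0
    return corr, degenerate


def pair_correlations(ds: ExpressionDataset) -> pd.DataFrame:
    """Per-condition Pearson correlation for every unordered gene pair.

    Pairs touching a zero-variance gene (in either condition) carry
    correlation 0 and ``valid=False``; they can never qualify.
    """
    cond_a, cond_b = ds.conditions
    if len(ds.samples_in(cond_a)) < 3 or len(ds.samples_in(cond_b)) < 3:
        raise ValueError("pair_correlations requires >= 3 samples per condition")
    corr_a, degen_a = _condition_corr(ds.matrix(cond_a))
    corr_b, degen_b = _condition_corr(ds.matrix(cond_b))
    degenerate = degen_a | degen_b
    if degenerate.any():
        bad = [g for g, flag in zip(ds.genes, degenerate) if flag]
        logger.warning(
            "%d zero-variance genes; their pairs are marked unqualified: %s",
            len(bad),
            bad[:5],
        )
    iu, iv = np.triu_indices(len(ds.genes), k=1)
    genes = np.asarray(ds.genes, dtype=object)
    valid = ~(degenerate[iu] | degenerate[iv])
    return pd.DataFrame(
        {
            "gene_u": genes[iu],
            "gene_v": genes[iv],
            "r_a": corr_a[iu, iv],
            "r_b": corr_b[iu, iv],
            "valid": valid,
            "qualified": valid.copy(),
        }
    )


def qualify_pairs(pairs: pd.DataFrame, q_keep: float = 0.25) -> pd.DataFrame:
    """Keep the strongest-correlated fraction ``q_keep`` of pairs.

    A pair qualifies iff max(|r_a|, |r_b|) reaches the (1 - q_keep)
    quantile of that magnitude over all pairs; ties at the threshold are
    kept, and invalid (zero-variance) pairs never qualify.
    """
    if not 0 < q_keep <= 1:
        raise ValueError("q_keep must be in (0, 1]")
    out = pairs.copy()
    m = np.maximum(out["r_a"].abs(), out["r_b"].abs()).to_numpy()
    threshold = float(np.quantile(m, 1.0 - q_keep))
    out["qualified"] = (m >= threshold) & out["valid"].to_numpy()
    return out


def _per_gene_rms(pairs: pd.DataFrame) -> pd.DataFrame:
    """Root-mean-square correlation change per gene over qualified pairs."""
    q = pairs[pairs["qualified"]]
    sq = (q["r_a"].to_numpy() - q["r_b"].to_numpy()) ** 2
    sums: dict[str, float] = {}
    counts: dict[str, int] = {}
    for gene_col in ("gene_u", "gene_v"):
        for g, v in zip(q[gene_col].to_numpy(), sq):
            sums[g] = sums.get(g, 0.0) + v
            counts[g] = counts.get(g, 0) + 1
    genes = sorted(sums)
    return pd.DataFrame(
        {
            "gene": genes,
            "dcp_score": [np.sqrt(sums[g] / counts[g]) for g in genes],
            "n_pairs": [counts[g] for g in genes],
        }
    )


def dcp_scores(pairs: pd.DataFrame) -> pd.DataFrame:
    """DCp statistic per gene: sqrt(sum_j (r_a,ij - r_b,ij)^2 / n_i) over the
    gene's qualified partners j. Genes with no qualified pair are omitted."""
    if not pairs["qualified"].any():
        raise ValueError("no qualified pairs; run qualify_pairs first or relax q_keep")
    out = _per_gene_rms(pairs)
    n_dropped = len(set(pairs["gene_u"]) | set(pairs["gene_v"])) - len(out)
    if n_dropped:
        logger.info("%d genes had no qualified pair and were omitted", n_dropped)
    return out.iloc[np.lexsort((out["gene"].to_numpy(), -out["dcp_score"].to_numpy()))].reset_index(
        drop=True
    )


def dcp_fdr(
    ds: ExpressionDataset, pairs: pd.DataFrame, n_perm: int = 100, seed: int = 0
) -> pd.DataFrame:
    """DCp scores with a sample-label permutation FDR.

    Labels are permuted ``n_perm`` times (seeded); the statistic is
    recomputed on the same qualified pair set each time. The per-gene FDR is
    the pooled null exceedance count divided by ``n_perm`` and by the number
    of observed scores at least as large, clipped to [0, 1] and made
    monotone in the score.
    """
    if n_perm < 50:
        raise ValueError("n_perm must be >= 50 for a usable FDR estimate")
    observed = _per_gene_rms(pairs)
    if observed.empty:
        raise ValueError("no qualified pairs; run qualify_pairs first")

    gene_index = {g: i for i, g in enumerate(ds.genes)}
    q = pairs[pairs["qualified"]]
    iu = np.asarray([gene_index[g] for g in q["gene_u"]], dtype=int)
    iv = np.asarray([gene_index[g] for g in q["gene_v"]], dtype=int)
    mat = ds.values.to_numpy(dtype=float)
    labels = ds.condition_of.to_numpy()
    cond_a, cond_b = ds.conditions

    # per-gene accumulation layout shared by observed and null passes
    obs_genes = observed["gene"].to_numpy()
    slot = {g: i for i, g in enumerate(obs_genes)}
    su = np.asarray([slot[g] for g in q["gene_u"]], dtype=int)
    sv = np.asarray([slot[g] for g in q["gene_v"]], dtype=int)
    n_counts = observed["n_pairs"].to_numpy(dtype=float)

    rng = np.random.default_rng(seed)
    null_scores = np.empty((n_perm, len(obs_genes)))
    n = mat.shape[1]
    for p in range(n_perm):
        perm_labels = labels[rng.permutation(n)]
        corr_a, _ = _condition_corr(mat[:, perm_labels == cond_a])
        corr_b, _ = _condition_corr(mat[:, perm_labels == cond_b])
        sq = (corr_a[iu, iv] - corr_b[iu, iv]) ** 2
        acc = np.zeros(len(obs_genes))
        np.add.at(acc, su, sq)
        np.add.at(acc, sv, sq)
        null_scores[p] = np.sqrt(acc / n_counts)

    obs = observed["dcp_score"].to_numpy()
    null_ge = exceedance_counts(obs, null_scores.ravel()) / float(n_perm)
    obs_ge = exceedance_counts(obs, obs)
    fdr = np.clip(null_ge / obs_ge, 0.0, 1.0)
    fdr = monotonize_fdr(obs, fdr)
    out = observed.assign(fdr=fdr)
    return out.iloc[np.lexsort((out["gene"].to_numpy(), -out["dcp_score"].to_numpy()))].reset_index(
        drop=True
    )


def lfc_dcls(
    pairs: pd.DataFrame, bins: int = 20, env_q: float = 0.9, eps: float = 1e-3
) -> pd.DataFrame:
    """Differentially co-expressed links by the modified log-fold-change rule.

    Qualified pairs whose correlations switch sign with both magnitudes
    >= 0.25 are flagged ``switched`` directly. The remaining qualified pairs
    are screened against a power-law envelope of the fold change
    f = |ln((|r_a|+eps)/(|r_b|+eps))| fitted over the correlation magnitude
    m = max(|r_a|, |r_b|); a pair is flagged ``same-sign`` iff f exceeds the
    envelope. Returns flagged pairs sorted by fold change, descending.
    """
    if eps <= 0:
        raise ValueError("eps must be positive")
    q = pairs[pairs["qualified"]].reset_index(drop=True)
    if len(q) < bins:
        raise ValueError(
            f"only {len(q)} qualified pairs for {bins} bins; reduce bins"
        )
    r_a = q["r_a"].to_numpy()
    r_b = q["r_b"].to_numpy()
    f = np.abs(np.log((np.abs(r_a) + eps) / (np.abs(r_b) + eps)))
    switched = (np.sign(r_a) * np.sign(r_b) < 0) & (
        np.minimum(np.abs(r_a), np.abs(r_b)) >= 0.25
    )
    rest = ~switched
    flags = np.zeros(len(q), dtype=bool)
    if rest.any():
        m = np.maximum(np.abs(r_a[rest]), np.abs(r_b[rest]))
        exceeded, _ = lfc_envelope_exceeds(m, f[rest], bins=bins, env_q=env_q)
        flags[np.flatnonzero(rest)[exceeded]] = True

    out = q.loc[switched | flags, ["gene_u", "gene_v", "r_a", "r_b"]].copy()
    out["lfc_score"] = f[switched | flags]
    out["cls"] = np.where(switched[switched | flags], "switched", "same-sign")
    order = np.lexsort(
        (out["gene_v"].to_numpy(), out["gene_u"].to_numpy(), -out["lfc_score"].to_numpy())
    )
    return out.iloc[order].reset_index(drop=True)
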