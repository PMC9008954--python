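"""Condition-specific gene regulatory network inference.

For each differentially co-expressed target gene, candidate regulators from
the TF->target prior are prefiltered by marginal correlation, then a
bidirectional stepwise multivariate linear regression selects the crucial
regulators; the fitted coefficients are the regulation efficacies.

Target and regulator expressions are z-scored within the condition before
fitting, so efficacies are standardized coefficients and directly
comparable between the two condition-specific networks — the quantity the
differential-regulation statistics operate on.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import f as f_dist

from .dataio import RegulatoryPrior, ValidationError

logger = logging.getLogger(__name__)

_PERFECT_FIT_TOL = 1e-12


@dataclass
class GRN:
    """One condition-specific directed weighted network.

    ``links`` maps (tf, target) to the regulation efficacy (nonzero by
    construction); ``tfs``/``targets`` are derived from the link set.
    """

    condition: str
    links: dict[tuple[str, str], float]

    def __post_init__(self) -> None:
        for (tf, tg), eff in self.links.items():
            if tf == tg:
                raise ValidationError(f"self-link {tf}->{tg} in GRN")
            if eff == 0:
                raise ValidationError(f"zero-efficacy link {tf}->{tg} must not be stored")

    @property
    def tfs(self) -> set[str]:
        return {tf for tf, _ in self.links}

    @property
    def targets(self) -> set[str]:
        return {tg for _, tg in self.links}

    @property
    def genes(self) -> set[str]:
        return self.tfs | self.targets

    def targets_of(self, tf: str) -> set[str]:
        return {tg for t, tg in self.links if t == tf}

    def __len__(self) -> int:
        return len(self.links)


@dataclass
class StepwiseConfig:
    """Prefilter and stepwise-selection constants.

    ``r_min`` is the marginal-correlation floor for candidate regulators,
    ``max_candidates`` caps the candidate list, and ``alpha_enter`` /
    ``alpha_remove`` are the partial-F entry/removal p-value thresholds of
    classical bidirectional stepwise selection.
    """

    r_min: float = 0.25
    max_candidates: int = 10
    alpha_enter: float = 0.05
    alpha_remove: float = 0.10
    max_steps: int = 50

    def __post_init__(self) -> None:
        if not (0 < self.alpha_enter <= self.alpha_remove < 1):
            raise ValueError("need 0 < alpha_enter <= alpha_remove < 1")
        if self.r_min < 0 or self.max_candidates < 1 or self.max_steps < 1:
            raise ValueError("invalid stepwise configuration")


def prefilter_regulators(
    expr: pd.DataFrame, prior: RegulatoryPrior, target: str, cfg: StepwiseConfig
) -> list[str]:
    """Candidate regulators of ``target``: prior TFs measured in the data
    with |Pearson r| >= r_min, sorted by |r| descending (ties by TF id),
    truncated to ``max_candidates``."""
    if target not in expr.index:
        return []
    y = expr.loc[target].to_numpy(dtype=float)
    if y.std(ddof=1) == 0:
        return []
    scored: list[tuple[float, str]] = []
    for tf in prior.regulators_of(target):
        if tf not in expr.index:
            continue
        x = expr.loc[tf].to_numpy(dtype=float)
        if x.std(ddof=1) == 0:
            continue
        r = float(np.corrcoef(x, y)[0, 1])
        if np.isfinite(r) and abs(r) >= cfg.r_min:
            scored.append((abs(r), tf))
    scored.sort(key=lambda t: (-t[0], t[1]))
    return [tf for _, tf in scored[: cfg.max_candidates]]


def _zscore_rows(expr: pd.DataFrame, genes: list[str]) -> dict[str, np.ndarray]:
    out = {}
    block = expr.loc[genes].to_numpy(dtype=float)
    mu = block.mean(axis=1, keepdims=True)
    sd = block.std(axis=1, ddof=1, keepdims=True)
    if np.any(sd == 0):
        bad = [g for g, s in zip(genes, sd.ravel()) if s == 0]
        raise ValueError(f"zero-variance genes cannot be z-scored: {bad[:5]}")
    z = (block - mu) / sd
    for g, row in zip(genes, z):
        out[g] = row
    return out


def _rss(y: np.ndarray, cols: list[np.ndarray]) -> tuple[float, int]:
    """Residual sum of squares of the least-squares fit; also the rank."""
    if not cols:
        return float(y @ y), 0
    x = np.column_stack(cols)
    coef, residuals, rank, _ = np.linalg.lstsq(x, y, rcond=None)
    resid = y - x @ coef
    return float(resid @ resid), int(rank)


def _partial_f_p(rss_small: float, rss_big: float, df2: int) -> float:
    """p-value for dropping one term: F = (rss_small - rss_big)/(rss_big/df2)."""
    if df2 <= 0:
        return 1.0
    if rss_big <= _PERFECT_FIT_TOL * max(1.0, rss_small):
        return 0.0
    f_stat = max(rss_small - rss_big, 0.0) / (rss_big / df2)
    return float(f_dist.sf(f_stat, 1, df2))


def fit_target_model(
    expr: pd.DataFrame, target: str, candidates: list[str], cfg: StepwiseConfig
) -> dict[str, float]:
    """Bidirectional stepwise regression of a target on its candidate TFs.

    All variables are z-scored within the condition (no intercept is needed
    on centered data). Candidates enter when their partial-F p-value is
    below ``alpha_enter`` (ties broken by candidate order) and leave when it
    rises above ``alpha_remove``. Returns the final-model coefficients for
    the selected TFs only; rank-deficient additions are skipped with a log
    message.
    """
    if not candidates:
        raise ValueError("fit_target_model requires a non-empty candidate list")
    n = expr.shape[1]
    if n < 3:
        raise ValueError("need at least 3 samples to fit")
    max_p = max(1, n - 2)
    if len(candidates) > max_p:
        logger.warning(
            "target %s: truncating %d candidates to %d (n=%d samples)",
            target,
            len(candidates),
            max_p,
            n,
        )
        candidates = candidates[:max_p]
    z = _zscore_rows(expr, [target] + [c for c in candidates if c != target])
    y = z[target]
    candidates = [c for c in candidates if c != target]

    selected: list[str] = []
    rss_cur, _ = _rss(y, [])
    for _ in range(cfg.max_steps):
        changed = False
        # forward: best admissible candidate by partial-F p-value
        if rss_cur > _PERFECT_FIT_TOL * n:
            best_p, best_c, best_rss = np.inf, None, rss_cur
            for c in candidates:
                if c in selected:
                    continue
                cols = [z[s] for s in selected] + [z[c]]
                rss_new, rank = _rss(y, cols)
                if rank < len(cols):
                    logger.info("target %s: skipping rank-deficient candidate %s", target, c)
                    continue
                p_val = _partial_f_p(rss_cur, rss_new, n - len(cols))
                if p_val < best_p:  # strict: ties keep the earlier candidate
                    best_p, best_c, best_rss = p_val, c, rss_new
            if best_c is not None and best_p < cfg.alpha_enter:
                selected.append(best_c)
                rss_cur = best_rss
                changed = True
        # backward: drop the least useful selected term
        if selected:
            worst_p, worst_c = -1.0, None
            for c in selected:
                others = [z[s] for s in selected if s != c]
                rss_wo, _ = _rss(y, others)
                p_val = _partial_f_p(rss_wo, rss_cur, n - len(selected))
                if p_val > worst_p:
                    worst_p, worst_c = p_val, c
            if worst_c is not None and worst_p > cfg.alpha_remove:
                selected.remove(worst_c)
                rss_cur, _ = _rss(y, [z[s] for s in selected])
                changed = True
        if not changed:
            break

    if not selected:
        return {}
    x = np.column_stack([z[s] for s in selected])
    coef, *_ = np.linalg.lstsq(x, y, rcond=None)
    return {s: float(c) for s, c in zip(selected, coef) if c != 0.0}


def build_grn(
    ds,
    condition: str,
    prior: RegulatoryPrior,
    dcgs,
    cfg: StepwiseConfig | None = None,
) -> GRN:
    """One condition-specific GRN: one stepwise fit per DCG target.

    Targets without any prefiltered candidate regulator are skipped (and
    counted in the log); the resulting link set is always a subset of the
    prior pairs.
    """
    cfg = cfg or StepwiseConfig()
    dcgs = sorted(set(dcgs))
    if not dcgs:
        logger.warning("build_grn(%s): empty DCG set, returning empty GRN", condition)
        return GRN(condition=condition, links={})
    expr = ds.frame(condition)
    links: dict[tuple[str, str], float] = {}
    n_skipped = 0
    for target in dcgs:
        if target not in expr.index:
            n_skipped += 1
            continue
        candidates = prefilter_regulators(expr, prior, target, cfg)
        if not candidates:
            n_skipped += 1
            continue
        for tf, eff in fit_target_model(expr, target, candidates, cfg).items():
            links[(tf, target)] = eff
    grn = GRN(condition=condition, links=links)
    logger.info(
        "GRN[%s]: %d links, %d TFs, %d targets (%d of %d DCG targets skipped)",
        condition,
        len(grn),
        len(grn.tfs),
        len(grn.targets),
        n_skipped,
        len(dcgs),
    )
    return grn


def grn_summary(grns: list[GRN]) -> pd.DataFrame:
    """Per-network basic statistics (condition, links, tfs, targets)."""
    return pd.DataFrame(
        [
            {
                "condition": g.condition,
                "links": len(g),
                "tfs": len(g.tfs),
                "targets": len(g.targets),
            }
            for g in grns
        ]
    )
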