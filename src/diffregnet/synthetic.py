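"""Two-condition synthetic expression data from a planted, partially rewired
linear regulatory network, with full ground truth.

The generator emulates the statistical structure assumed by the inference
pipeline: TF expressions are i.i.d. standard normal across samples
(regulators are exogenous), each target gene is a linear combination of its
planted regulators plus Gaussian noise, and condition B's network differs
from condition A on a chosen fraction of links (dropped, sign-flipped, or
newly added). The emitted regulatory prior contains the union of both
conditions' true links plus random decoy pairs, so prior contamination is
part of the recovery problem.

Defaults mirror a two-group transcriptome study of moderate size: 300 genes
of which 15 are TFs, eight targets per TF, 60 samples per condition, 30% of
links rewired and residual noise of 0.5 on the (log-scale) expression
values.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._stats import ranking_auroc
from .dataio import ExpressionDataset, RegulatoryPrior


@dataclass
class SimConfig:
    """Generator settings; see the module docstring for the data model."""

    n_genes: int = 300
    n_tfs: int = 15
    n_samples_a: int = 60
    n_samples_b: int = 60
    targets_per_tf: int = 8
    rewire_fraction: float = 0.3
    effect_range: tuple[float, float] = (0.75, 2.0)
    noise_sd: float = 0.5
    decoy_prior_fraction: float = 0.5
    max_regulators_per_target: int = 2
    coef_change_tolerance: float = 0.2
    seed: int = 1

    def __post_init__(self) -> None:
        if self.n_tfs >= self.n_genes:
            raise ValueError("n_tfs must be smaller than n_genes")
        for name in ("n_genes", "n_tfs", "n_samples_a", "n_samples_b", "targets_per_tf"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 <= self.rewire_fraction <= 1:
            raise ValueError("rewire_fraction must be in [0, 1]")
        lo, hi = self.effect_range
        if not 0 < lo <= hi:
            raise ValueError("effect_range must satisfy 0 < low <= high")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if self.decoy_prior_fraction < 0:
            raise ValueError("decoy_prior_fraction must be nonnegative")
        capacity = (self.n_genes - self.n_tfs) * self.max_regulators_per_target
        if self.n_tfs * self.targets_per_tf > capacity:
            raise ValueError(
                f"infeasible configuration: {self.n_tfs * self.targets_per_tf} links "
                f"requested but only {capacity} target slots available"
            )


@dataclass
class GroundTruth:
    """Planted networks and rewiring bookkeeping emitted by the generator.

    ``true_links_a``/``true_links_b`` hold the raw planted coefficients;
    ``std_links_a``/``std_links_b`` the corresponding standardized
    coefficients (scaled by the empirical SDs of the generated data), which
    is the scale on which regression efficacies are estimated.
    """

    true_links_a: dict[tuple[str, str], float]
    true_links_b: dict[tuple[str, str], float]
    rewired_links: set[tuple[str, str]]
    rewired_genes: set[str]
    prior_decoys: set[tuple[str, str]]
    std_links_a: dict[tuple[str, str], float] = field(default_factory=dict)
    std_links_b: dict[tuple[str, str], float] = field(default_factory=dict)

    def to_json(self, path) -> None:
        def enc_map(d):
            return {f"{tf}|{tg}": v for (tf, tg), v in sorted(d.items())}

        payload = {
            "true_links_a": enc_map(self.true_links_a),
            "true_links_b": enc_map(self.true_links_b),
            "std_links_a": enc_map(self.std_links_a),
            "std_links_b": enc_map(self.std_links_b),
            "rewired_links": sorted(f"{tf}|{tg}" for tf, tg in self.rewired_links),
            "rewired_genes": sorted(self.rewired_genes),
            "prior_decoys": sorted(f"{tf}|{tg}" for tf, tg in self.prior_decoys),
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        with open(path, encoding="utf-8") as fh:
            payload = json.load(fh)

        def dec_map(d):
            return {tuple(k.split("|")): float(v) for k, v in d.items()}

        return cls(
            true_links_a=dec_map(payload["true_links_a"]),
            true_links_b=dec_map(payload["true_links_b"]),
            rewired_links={tuple(s.split("|")) for s in payload["rewired_links"]},
            rewired_genes=set(payload["rewired_genes"]),
            prior_decoys={tuple(s.split("|")) for s in payload["prior_decoys"]},
            std_links_a=dec_map(payload["std_links_a"]),
            std_links_b=dec_map(payload["std_links_b"]),
        )


def _plant_network(cfg: SimConfig, rng: np.random.Generator, tfs, targets_pool):
    """Condition-A links: each TF draws targets without exceeding the
    per-target regulator cap; coefficients are uniform magnitudes in
    effect_range with random sign."""
    load = {g: 0 for g in targets_pool}
    links: dict[tuple[str, str], float] = {}
    for tf in tfs:
        eligible = [g for g in targets_pool if load[g] < cfg.max_regulators_per_target]
        chosen = rng.choice(len(eligible), size=cfg.targets_per_tf, replace=False)
        for i in chosen:
            g = eligible[i]
            load[g] += 1
            magnitude = rng.uniform(*cfg.effect_range)
            links[(tf, g)] = float(rng.choice([-1.0, 1.0]) * magnitude)
    return links


def _rewire(cfg: SimConfig, rng: np.random.Generator, links_a, tfs, targets_pool):
    """Condition-B links: apply drop / sign-flip / add events to a fraction
    of the condition-A network."""
    links_b = dict(links_a)
    n_rewire = int(round(cfg.rewire_fraction * len(links_a)))
    rewired: set[tuple[str, str]] = set()
    if n_rewire == 0:
        return links_b, rewired
    actions = rng.choice(["drop", "flip", "add"], size=n_rewire)
    n_modify = int(np.sum(actions != "add"))
    n_modify = min(n_modify, len(links_a))
    ordered = sorted(links_a)
    modify_idx = rng.choice(len(ordered), size=n_modify, replace=False)
    modify_actions = [a for a in actions if a != "add"][:n_modify]
    for idx, action in zip(modify_idx, modify_actions):
        edge = ordered[idx]
        if action == "drop":
            del links_b[edge]
        else:
            links_b[edge] = -links_b[edge]
        rewired.add(edge)
    n_add = n_rewire - n_modify
    load_b: dict[str, int] = {}
    for _, tg in links_b:
        load_b[tg] = load_b.get(tg, 0) + 1
    attempts = 0
    while n_add > 0 and attempts < 10000:
        attempts += 1
        tf = tfs[rng.integers(len(tfs))]
        tg = targets_pool[rng.integers(len(targets_pool))]
        if (tf, tg) in links_a or (tf, tg) in links_b:
            continue
        if load_b.get(tg, 0) >= cfg.max_regulators_per_target:
            continue
        magnitude = rng.uniform(*cfg.effect_range)
        links_b[(tf, tg)] = float(rng.choice([-1.0, 1.0]) * magnitude)
        load_b[tg] = load_b.get(tg, 0) + 1
        rewired.add((tf, tg))
        n_add -= 1
    return links_b, rewired


def _expression(cfg, rng, tfs, other_genes, links, n_samples):
    """One condition's genes x samples matrix under a linear model."""
    tf_mat = rng.standard_normal((len(tfs), n_samples))
    tf_index = {t: i for i, t in enumerate(tfs)}
    other = rng.standard_normal((len(other_genes), n_samples)) * cfg.noise_sd
    gene_index = {g: i for i, g in enumerate(other_genes)}
    for (tf, tg), coef in links.items():
        other[gene_index[tg]] += coef * tf_mat[tf_index[tf]]
    return np.vstack([tf_mat, other])


def simulate_two_condition(
    cfg: SimConfig,
) -> tuple[ExpressionDataset, RegulatoryPrior, GroundTruth]:
    """Generate the paired dataset, the (decoy-contaminated) prior and the
    ground truth; fully reproducible from ``cfg.seed``."""
    rng = np.random.default_rng(cfg.seed)
    tfs = [f"TF{i + 1:03d}" for i in range(cfg.n_tfs)]
    targets_pool = [f"G{i + 1:04d}" for i in range(cfg.n_genes - cfg.n_tfs)]

    links_a = _plant_network(cfg, rng, tfs, targets_pool)
    links_b, rewired = _rewire(cfg, rng, links_a, tfs, targets_pool)

    mat_a = _expression(cfg, rng, tfs, targets_pool, links_a, cfg.n_samples_a)
    mat_b = _expression(cfg, rng, tfs, targets_pool, links_b, cfg.n_samples_b)
    genes = tfs + targets_pool
    samples = [f"A{i + 1:03d}" for i in range(cfg.n_samples_a)] + [
        f"B{i + 1:03d}" for i in range(cfg.n_samples_b)
    ]
    values = pd.DataFrame(np.hstack([mat_a, mat_b]), index=genes, columns=samples)
    condition_of = pd.Series(
        ["A"] * cfg.n_samples_a + ["B"] * cfg.n_samples_b, index=samples, dtype=object
    )
    ds = ExpressionDataset(values=values, condition_of=condition_of)

    union = set(links_a) | set(links_b)
    n_decoys = int(round(cfg.decoy_prior_fraction * len(union)))
    decoys: set[tuple[str, str]] = set()
    attempts = 0
    while len(decoys) < n_decoys and attempts < 100000:
        attempts += 1
        pair = (
            tfs[rng.integers(len(tfs))],
            targets_pool[rng.integers(len(targets_pool))],
        )
        if pair not in union:
            decoys.add(pair)
    prior = RegulatoryPrior(pairs=union | decoys)

    def std_coefs(links, cond):
        frame = ds.frame(cond)
        sd = frame.std(axis=1, ddof=1)
        return {
            (tf, tg): float(c * sd[tf] / sd[tg]) for (tf, tg), c in links.items()
        }

    truth = GroundTruth(
        true_links_a=links_a,
        true_links_b=links_b,
        rewired_links=rewired,
        rewired_genes={g for edge in rewired for g in edge},
        prior_decoys=decoys,
        std_links_a=std_coefs(links_a, "A"),
        std_links_b=std_coefs(links_b, "B"),
    )
    return ds, prior, truth


@dataclass
class RecoveryMetrics:
    precision_at_k: float
    auroc: float
    n_positives: int
    n_negatives: int


def evaluate_recovery(
    ranked: pd.DataFrame, truth: GroundTruth, k: int, universe=None
) -> RecoveryMetrics:
    """Precision@k and AUROC of a ranked DRG or DRL table against the truth.

    The table kind is inferred from its columns (``gene`` for DRGs,
    ``tf``/``target`` for DRLs). When ``universe`` (an iterable of all items
    that could have been ranked) is given, items missing from the table are
    placed in a single tie below every ranked item, so failing to rank a
    rewired item counts against the AUROC.
    """
    if "gene" in ranked.columns:
        items = list(ranked["gene"])
        positives = set(truth.rewired_genes)
    elif {"tf", "target"}.issubset(ranked.columns):
        items = list(zip(ranked["tf"], ranked["target"]))
        positives = set(truth.rewired_links)
    else:
        raise ValueError("ranked table must have a 'gene' or 'tf'/'target' columns")
    if k < 1 or k > len(items):
        raise ValueError(f"k={k} outside the ranked table of size {len(items)}")

    precision = sum(1 for it in items[:k] if it in positives) / k

    scores = {it: -rank for rank, it in enumerate(items, start=1)}
    if universe is not None:
        floor = -(len(items) + 1)
        for it in universe:
            scores.setdefault(it, floor)
    all_items = list(scores)
    score_arr = np.array([scores[it] for it in all_items], dtype=float)
    label_arr = np.array([it in positives for it in all_items])
    auroc = ranking_auroc(score_arr, label_arr)
    return RecoveryMetrics(
        precision_at_k=float(precision),
        auroc=auroc,
        n_positives=int(label_arr.sum()),
        n_negatives=int(len(label_arr) - label_arr.sum()),
    )


def write_fixtures(ds, prior, truth, outdir) -> dict[str, str]:
    """Write the generated study in the pipeline's input formats plus the
    ground-truth JSON; returns the file map."""
    import os

    from .dataio import write_expression, write_prior

    os.makedirs(outdir, exist_ok=True)
    paths = {
        "expression": os.path.join(outdir, "expression.tsv"),
        "labels": os.path.join(outdir, "labels.tsv"),
        "prior": os.path.join(outdir, "prior.tsv"),
        "ground_truth": os.path.join(outdir, "ground_truth.json"),
    }
    write_expression(ds, paths["expression"], paths["labels"])
    write_prior(prior, paths["prior"])
    truth.to_json(paths["ground_truth"])
    return paths
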