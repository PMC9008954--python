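"""End-to-end orchestration: expression data (loaded or simulated) ->
differential co-expression -> per-condition GRN fitting -> differential
regulation and topology tables, all driven by a single config and seed.

Rerunning with the same config reproduces every output table bit for bit:
all permutation loops and the simulator draw their seeds deterministically
from the config.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import yaml

from . import __version__
from . import dataio, dcea, dea, dra, topology
from .dea import SamParams
from .grn import StepwiseConfig, build_grn, grn_summary
from .synthetic import SimConfig, simulate_two_condition, write_fixtures

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Everything one run needs: either the three input paths or a synthetic
    block (exactly one), plus the per-stage parameter blocks."""

    expression: str | None = None
    labels: str | None = None
    prior: str | None = None
    synthetic: SimConfig | None = None
    condition_a: str | None = None
    seed: int = 0
    run_dea: bool = True
    sam: SamParams = field(default_factory=SamParams)
    q_keep: float = 0.25
    dcp_permutations: int = 100
    dcg_fdr_cut: float = 0.05
    lfc_bins: int = 20
    lfc_env_q: float = 0.9
    lfc_eps: float = 1e-3
    stepwise: StepwiseConfig = field(default_factory=StepwiseConfig)
    drl_bins: int = 20
    drl_env_q: float = 0.9
    drl_eps: float = 1e-3
    top_fraction: float = 0.01

    def __post_init__(self) -> None:
        paths = [self.expression, self.labels, self.prior]
        has_paths = any(p is not None for p in paths)
        if has_paths and self.synthetic is not None:
            raise ValueError("config must give either input paths or a synthetic block, not both")
        if not has_paths and self.synthetic is None:
            raise ValueError("config must give input paths or a synthetic block")
        if has_paths and not all(p is not None for p in paths):
            raise ValueError("expression, labels and prior paths must all be given")

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        raw = dict(raw)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "synthetic" in raw and raw["synthetic"] is not None:
            sim = dict(raw["synthetic"])
            if "effect_range" in sim:
                sim["effect_range"] = tuple(sim["effect_range"])
            raw["synthetic"] = SimConfig(**sim)
        if "sam" in raw and raw["sam"] is not None:
            raw["sam"] = SamParams(**raw["sam"])
        if "stepwise" in raw and raw["stepwise"] is not None:
            raw["stepwise"] = StepwiseConfig(**raw["stepwise"])
        return cls(**raw)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
        if not isinstance(raw, dict):
            raise ValueError(f"config {path} must be a mapping")
        return cls.from_dict(raw)

    def canonical(self) -> str:
        def clean(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {f.name: clean(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
            if isinstance(obj, (list, tuple)):
                return [clean(x) for x in obj]
            return obj

        return json.dumps(clean(self), sort_keys=True)


def _derived_seeds(seed: int, n: int) -> list[int]:
    state = np.random.SeedSequence(seed).generate_state(n, dtype=np.uint32)
    return [int(s % (2**31)) for s in state]


def run_pipeline(cfg: PipelineConfig, outdir) -> dict:
    """Execute the full analysis and write all tables under ``outdir``.

    Returns the run manifest (also written as ``manifest.json``): config
    hash, seed, package version, and per-artifact row counts.
    """
    os.makedirs(outdir, exist_ok=True)
    seeds = _derived_seeds(cfg.seed, 3)
    artifacts: dict[str, dict] = {}

    def emit(name: str, table) -> None:
        path = os.path.join(outdir, f"{name}.tsv")
        dataio.write_table(table, path)
        artifacts[name] = {"path": f"{name}.tsv", "rows": int(len(table))}

    # --- inputs -----------------------------------------------------------
    if cfg.synthetic is not None:
        ds, prior, truth = simulate_two_condition(cfg.synthetic)
        fixture_paths = write_fixtures(ds, prior, truth, os.path.join(outdir, "input"))
        logger.info("simulated study written to %s", os.path.join(outdir, "input"))
        for key, p in fixture_paths.items():
            artifacts[f"input_{key}"] = {"path": os.path.relpath(p, outdir), "rows": None}
    else:
        ds = dataio.load_expression(cfg.expression, cfg.labels)
        prior = dataio.load_prior(cfg.prior)

    cond_a, cond_b = ds.conditions
    if cfg.condition_a is not None:
        if cfg.condition_a not in (cond_a, cond_b):
            raise ValueError(f"condition_a={cfg.condition_a!r} not a label of the dataset")
        if cfg.condition_a == cond_b:
            cond_a, cond_b = cond_b, cond_a

    # --- differential expression QC --------------------------------------
    if cfg.run_dea:
        sam = dataclasses.replace(cfg.sam, seed=seeds[0])
        emit("degs", dea.sam_test(ds, sam))

    # --- differential co-expression --------------------------------------
    pairs = dcea.qualify_pairs(dcea.pair_correlations(ds), q_keep=cfg.q_keep)
    dcg_table = dcea.dcp_fdr(ds, pairs, n_perm=cfg.dcp_permutations, seed=seeds[1])
    emit("dcgs", dcg_table)
    emit(
        "dcls",
        dcea.lfc_dcls(pairs, bins=cfg.lfc_bins, env_q=cfg.lfc_env_q, eps=cfg.lfc_eps),
    )
    dcg_set = set(dcg_table.loc[dcg_table["fdr"] < cfg.dcg_fdr_cut, "gene"])
    logger.info("%d DCGs at FDR < %g", len(dcg_set), cfg.dcg_fdr_cut)

    # --- condition-specific GRNs ------------------------------------------
    grn_a = build_grn(ds, cond_a, prior, dcg_set, cfg.stepwise)
    grn_b = build_grn(ds, cond_b, prior, dcg_set, cfg.stepwise)
    for grn, tag in ((grn_a, "grn_a"), (grn_b, "grn_b")):
        path = os.path.join(outdir, f"{tag}.tsv")
        dataio.write_network(grn, path)
        artifacts[tag] = {"path": f"{tag}.tsv", "rows": len(grn)}
    emit("grn_summary", grn_summary([grn_a, grn_b]))

    # --- differential regulation ------------------------------------------
    if grn_a.links or grn_b.links:
        emit("drgs", dra.rank_drgs(grn_a, grn_b, top_fraction=cfg.top_fraction))
        emit(
            "drls",
            dra.detect_drls(
                grn_a, grn_b, bins=cfg.drl_bins, env_q=cfg.drl_env_q, eps=cfg.drl_eps
            ),
        )
        emit("tdr", dra.tdr_table(grn_a, grn_b))
    else:
        logger.warning("both GRNs empty; differential regulation tables skipped")

    # --- topology ----------------------------------------------------------
    if grn_a.links and grn_b.links:
        emit("topology", topology.summary_table(grn_a, grn_b))
        overlap = topology.classify_links(grn_a, grn_b)
        import pandas as pd

        emit(
            "link_overlap",
            pd.DataFrame(
                [
                    {
                        "overlapped": overlap.overlapped,
                        f"{cond_a}_specific": overlap.a_specific,
                        f"{cond_b}_specific": overlap.b_specific,
                    }
                ]
            ),
        )

    manifest = {
        "config_sha256": hashlib.sha256(cfg.canonical().encode()).hexdigest(),
        "seed": cfg.seed,
        "package_version": __version__,
        "condition_a": cond_a,
        "condition_b": cond_b,
        "artifacts": artifacts,
    }
    with open(os.path.join(outdir, "manifest.json"), "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest
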