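"""Differential regulation analysis between two condition-specific GRNs.

Three statistics quantify regulatory rewiring:

* ``DR_i = sqrt(sum_j (X_ij - Y_ij)^2 / n)`` — per-gene root-mean-square
  change of regulation efficacy over the union of the gene's incident links
  in the two networks (links absent from one network contribute efficacy
  0); genes with high DR are the differentially regulated genes (DRGs);
* ``DRL = |X - Y|`` — per-link absolute efficacy change, with a
  log-fold-change envelope filter marking detected links (DRLs);
* ``TDR`` — target diversity of a regulator, the Jaccard distance between a
  TF's target sets in the two networks.

The union of a gene's incident links counts distinct *directed* edges, both
incoming and outgoing, so a TF accumulates changes over its regulons as
well as over its own regulators.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._stats import lfc_envelope_exceeds
from .grn import GRN

logger = logging.getLogger(__name__)


def _incident_union(grn_a: GRN, grn_b: GRN, gene: str) -> list[tuple[str, str]]:
    edges = set(grn_a.links) | set(grn_b.links)
    return sorted(e for e in edges if gene in e)


def dr_score(grn_a: GRN, grn_b: GRN, gene: str) -> tuple[float, int]:
    """DR value of one gene and the size n of its incident link union.

    Raises for a gene isolated in both networks (n = 0 leaves the
    root-mean-square undefined).
    """
    edges = _incident_union(grn_a, grn_b, gene)
    if not edges:
        raise ValueError(f"gene {gene!r} is isolated in both GRNs; DR undefined")
    sq = [
        (grn_a.links.get(e, 0.0) - grn_b.links.get(e, 0.0)) ** 2
        for e in edges
    ]
    return float(np.sqrt(sum(sq) / len(edges))), len(edges)


def rank_drgs(grn_a: GRN, grn_b: GRN, top_fraction: float = 0.01) -> pd.DataFrame:
    """Ranked differential-regulation table over all non-isolated genes.

    Sorted by DR descending with a lexicographic tie-break on the gene ID;
    ``top_flag`` marks the top ``top_fraction`` of genes (at least one),
    restricted to genes with DR > 0.
    """
    genes = sorted(grn_a.genes | grn_b.genes)
    if not genes:
        return pd.DataFrame(columns=["gene", "dr_value", "n_union_links", "rank", "top_flag"])
    rows = []
    for g in genes:
        dr, n = dr_score(grn_a, grn_b, g)
        rows.append((g, dr, n))
    out = pd.DataFrame(rows, columns=["gene", "dr_value", "n_union_links"])
    order = np.lexsort((out["gene"].to_numpy(), -out["dr_value"].to_numpy()))
    out = out.iloc[order].reset_index(drop=True)
    out["rank"] = np.arange(1, len(out) + 1)
    k = max(1, int(np.ceil(top_fraction * len(out))))
    out["top_flag"] = (out["rank"] <= k) & (out["dr_value"] > 0)
    return out


def drl_value(x_a: float, x_b: float) -> float:
    """Absolute change of regulation efficacy between the two networks."""
    return abs(float(x_a) - float(x_b))


def detect_drls(
    grn_a: GRN, grn_b: GRN, bins: int = 20, env_q: float = 0.9, eps: float = 1e-3
) -> pd.DataFrame:
    """Differentially regulated links over the union of both link sets.

    Each candidate link carries its two efficacies (0 where absent), the
    absolute change ``delta`` and the envelope-filter verdict
    ``passed_filter`` (links switching regulation sign with both magnitudes
    >= 0.25 pass directly). The table is ranked by delta, descending. When
    there are fewer candidates than bins the envelope cannot be fitted and
    every link passes, with a logged notice.
    """
    if eps <= 0:
        raise ValueError("eps must be positive")
    edges = sorted(set(grn_a.links) | set(grn_b.links))
    if not edges:
        raise ValueError("both GRNs are empty; no candidate links")
    x_a = np.array([grn_a.links.get(e, 0.0) for e in edges])
    x_b = np.array([grn_b.links.get(e, 0.0) for e in edges])
    delta = np.abs(x_a - x_b)
    f = np.abs(np.log((np.abs(x_a) + eps) / (np.abs(x_b) + eps)))
    if len(edges) < bins:
        logger.info(
            "only %d candidate links (< %d bins): envelope skipped, all links pass",
            len(edges),
            bins,
        )
        passed = np.ones(len(edges), dtype=bool)
    else:
        switched = (np.sign(x_a) * np.sign(x_b) < 0) & (
            np.minimum(np.abs(x_a), np.abs(x_b)) >= 0.25
        )
        passed = switched.copy()
        rest = ~switched
        if rest.any():
            m = np.maximum(np.abs(x_a[rest]), np.abs(x_b[rest]))
            exceeded, _ = lfc_envelope_exceeds(m, f[rest], bins=bins, env_q=env_q)
            passed[np.flatnonzero(rest)[exceeded]] = True
    out = pd.DataFrame(
        {
            "tf": [e[0] for e in edges],
            "target": [e[1] for e in edges],
            "x_a": x_a,
            "x_b": x_b,
            "delta": delta,
            "lfc_score": f,
            "passed_filter": passed,
        }
    )
    order = np.lexsort((out["target"].to_numpy(), out["tf"].to_numpy(), -delta))
    return out.iloc[order].reset_index(drop=True)


@dataclass
class TDRRecord:
    tf: str
    n_targets_a: int
    n_targets_b: int
    tdr: float


def tdr(grn_a: GRN, grn_b: GRN, tf: str) -> TDRRecord:
    """Target diversity of a regulator: Jaccard distance of its target sets.

    0 when the TF regulates identical target sets in both networks, 1 when
    the sets are disjoint.
    """
    t_a, t_b = grn_a.targets_of(tf), grn_b.targets_of(tf)
    union = t_a | t_b
    if not union:
        raise ValueError(f"TF {tf!r} has no targets in either GRN; TDR undefined")
    value = 1.0 - len(t_a & t_b) / len(union)
    return TDRRecord(tf=tf, n_targets_a=len(t_a), n_targets_b=len(t_b), tdr=value)


def tdr_table(grn_a: GRN, grn_b: GRN) -> pd.DataFrame:
    """TDR for every TF appearing in either network, sorted by TDR descending."""
    tfs = sorted(grn_a.tfs | grn_b.tfs)
    rows = [tdr(grn_a, grn_b, t) for t in tfs]
    out = pd.DataFrame(
        {
            "tf": [r.tf for r in rows],
            "n_targets_a": [r.n_targets_a for r in rows],
            "n_targets_b": [r.n_targets_b for r in rows],
            "tdr": [r.tdr for r in rows],
        }
    )
    order = np.lexsort((out["tf"].to_numpy(), -out["tdr"].to_numpy()))
    return out.iloc[order].reset_index(drop=True)
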