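"""Worked example: published regulation efficacies of the transcription
factor CREB1 on seven targets in normal gastric mucosa versus gastric
cancer condition-specific regulatory networks.

These seven links are the in-print case study for the differential
regulation statistics: the per-link absolute efficacy change (DRL value)
and the restricted root-mean-square DR value over exactly these links can
be recomputed from the efficacies alone. An efficacy of 0.0 means the link
is absent from that condition's network (e.g. CREB1 did not regulate MBNL1
in normal mucosa).
"""

from __future__ import annotations

from .grn import GRN

# target -> (efficacy in normal, efficacy in cancer)
CREB1_EFFICACIES: dict[str, tuple[float, float]] = {
    "TRIM15": (2.596, -0.483),
    "TCEAL2": (-2.315, 0.000),
    "NHERF1": (1.796, -0.437),
    "RBPMS2": (-1.897, 0.000),
    "FERMT2": (-0.673, 1.049),
    "FAM20C": (-1.616, 0.000),
    "MBNL1": (0.000, 0.894),
}

# published per-link absolute changes, in the published rank order
CREB1_PUBLISHED_DRL: list[tuple[str, float]] = [
    ("TRIM15", 3.079),
    ("TCEAL2", 2.315),
    ("NHERF1", 2.233),
    ("RBPMS2", 1.897),
    ("FERMT2", 1.722),
    ("FAM20C", 1.616),
    ("MBNL1", 0.894),
]


def creb1_example_grns() -> tuple[GRN, GRN]:
    """The two single-TF networks spanned by the seven published links.

    Links with efficacy 0.0 in a condition are absent from that condition's
    network, exactly as in the published tables.
    """
    normal = {
        ("CREB1", tg): eff for tg, (eff, _) in CREB1_EFFICACIES.items() if eff != 0.0
    }
    cancer = {
        ("CREB1", tg): eff for tg, (_, eff) in CREB1_EFFICACIES.items() if eff != 0.0
    }
    return GRN(condition="normal", links=normal), GRN(condition="cancer", links=cancer)
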