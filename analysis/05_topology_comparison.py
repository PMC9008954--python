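"""Topological comparison of the two fitted networks.

Per-condition mean in/out-degree, betweenness, clustering and closeness
with rank-sum p-values, plus the overlapped / condition-specific link
split. Writes results/topology/.
"""

import pathlib

import pandas as pd

from diffregnet import dataio
from diffregnet.topology import classify_links, summary_table

ROOT = pathlib.Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    grn_a = dataio.read_network(ROOT / "grn" / "grn_A.tsv", condition="A")
    grn_b = dataio.read_network(ROOT / "grn" / "grn_B.tsv", condition="B")
    out = ROOT / "topology"
    out.mkdir(parents=True, exist_ok=True)

    table = summary_table(grn_a, grn_b)
    dataio.write_table(table, out / "topology_summary.tsv")
    print(table.to_string(index=False))

    overlap = classify_links(grn_a, grn_b)
    row = pd.DataFrame(
        [
            {
                "overlapped": overlap.overlapped,
                "A_specific": overlap.a_specific,
                "B_specific": overlap.b_specific,
            }
        ]
    )
    dataio.write_table(row, out / "link_overlap.tsv")
    frac_a = overlap.a_specific / len(grn_a)
    frac_b = overlap.b_specific / len(grn_b)
    print(
        f"link overlap: {overlap.overlapped} shared; condition-specific fraction "
        f"A {frac_a:.2f}, B {frac_b:.2f}"
    )


if __name__ == "__main__":
    main()
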