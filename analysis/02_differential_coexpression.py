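"""Differential expression QC and differential co-expression screening.

Reads the simulated study from results/sim/, runs the SAM screen (QC), the
DCp statistic with permutation FDR (DCGs) and the modified log-fold-change
link screen (DCLs); writes the tables under results/dcea/.
"""

import pathlib

from diffregnet import dataio, dcea
from diffregnet.dea import SamParams, sam_test

ROOT = pathlib.Path(__file__).resolve().parents[1] / "results"
DCG_FDR_CUT = 0.05


def main() -> None:
    ds = dataio.load_expression(ROOT / "sim" / "expression.tsv", ROOT / "sim" / "labels.tsv")
    out = ROOT / "dcea"
    out.mkdir(parents=True, exist_ok=True)

    degs = sam_test(ds, SamParams(n_perm=200, seed=11))
    dataio.write_table(degs, out / "degs.tsv")
    print(f"SAM screen: {int(degs['significant'].sum())} DEGs of {len(degs)} genes")

    pairs = dcea.qualify_pairs(dcea.pair_correlations(ds), q_keep=0.25)
    print(f"{int(pairs['qualified'].sum())} of {len(pairs)} gene pairs qualified")

    dcgs = dcea.dcp_fdr(ds, pairs, n_perm=100, seed=12)
    dataio.write_table(dcgs, out / "dcgs.tsv")
    n_dcg = int((dcgs["fdr"] < DCG_FDR_CUT).sum())
    print(f"DCp screen: {n_dcg} DCGs at FDR < {DCG_FDR_CUT}")

    dcls = dcea.lfc_dcls(pairs)
    dataio.write_table(dcls, out / "dcls.tsv")
    print(
        f"LFC screen: {len(dcls)} DCLs "
        f"({int((dcls['cls'] == 'switched').sum())} sign-switched)"
    )


if __name__ == "__main__":
    main()
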