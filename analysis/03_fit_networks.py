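"""Fit the two condition-specific regulatory networks.

For every DCG (from step 02) with at least one prefiltered candidate
regulator in the prior, a bidirectional stepwise regression selects its
regulators per condition; coefficients on z-scored data are the regulation
efficacies. Writes edge lists and a basic-statistics summary under
results/grn/.
"""

import pathlib

import pandas as pd

from diffregnet import dataio
from diffregnet.grn import StepwiseConfig, build_grn, grn_summary

ROOT = pathlib.Path(__file__).resolve().parents[1] / "results"
DCG_FDR_CUT = 0.05


def main() -> None:
    ds = dataio.load_expression(ROOT / "sim" / "expression.tsv", ROOT / "sim" / "labels.tsv")
    prior = dataio.load_prior(ROOT / "sim" / "prior.tsv")
    dcg_table = pd.read_csv(ROOT / "dcea" / "dcgs.tsv", sep="\t")
    dcgs = set(dcg_table.loc[dcg_table["fdr"] < DCG_FDR_CUT, "gene"])
    print(f"{len(dcgs)} DCG targets, {len(prior.pairs)} prior pairs")

    out = ROOT / "grn"
    out.mkdir(parents=True, exist_ok=True)
    cfg = StepwiseConfig()
    grns = []
    for cond in ds.conditions:
        grn = build_grn(ds, cond, prior, dcgs, cfg)
        dataio.write_network(grn, out / f"grn_{cond}.tsv")
        dataio.write_graphml(grn, out / f"grn_{cond}.graphml")
        grns.append(grn)
        print(
            f"GRN[{cond}]: {len(grn)} links, {len(grn.tfs)} TFs, "
            f"{len(grn.targets)} targets"
        )
    dataio.write_table(grn_summary(grns), out / "grn_summary.tsv")


if __name__ == "__main__":
    main()
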