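"""Generate the default synthetic two-condition study.

Writes a 300-gene (15 TFs) x 120-sample expression matrix, condition
labels, a decoy-contaminated TF->target prior and the planted ground truth
under results/sim/. Later analysis steps read exactly these files.
"""

import pathlib

from diffregnet.synthetic import SimConfig, simulate_two_condition, write_fixtures

OUT = pathlib.Path(__file__).resolve().parents[1] / "results" / "sim"


def main() -> None:
    cfg = SimConfig(seed=1)
    ds, prior, truth = simulate_two_condition(cfg)
    paths = write_fixtures(ds, prior, truth, OUT)
    print(f"simulated {len(ds.genes)} genes x {len(ds.samples)} samples")
    print(
        f"planted links: {len(truth.true_links_a)} (A) / {len(truth.true_links_b)} (B); "
        f"{len(truth.rewired_links)} rewired, {len(truth.prior_decoys)} prior decoys"
    )
    for name, path in sorted(paths.items()):
        print(f"  wrote {name}: {path}")


if __name__ == "__main__":
    main()
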