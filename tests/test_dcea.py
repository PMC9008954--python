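import numpy as np
import pandas as pd
import pytest

from diffregnet import dcea

from conftest import make_dataset


def pair_frame(r_a, r_b, qualified=None):
    n = len(r_a)
    return pd.DataFrame(
        {
            "gene_u": [f"u{i}" for i in range(n)],
            "gene_v": [f"v{i}" for i in range(n)],
            "r_a": np.asarray(r_a, dtype=float),
            "r_b": np.asarray(r_b, dtype=float),
            "valid": True,
            "qualified": True if qualified is None else qualified,
        }
    )


class TestPairCorrelations:
    def test_perfect_positive_and_negative(self):
        mat = [
            [1, 2, 3, 1, 2, 3],
            [2, 4, 6, 2, 4, 6],
            [3, 2, 1, 3, 2, 1],
        ]
        pairs = dcea.pair_correlations(make_dataset(mat))
        by = pairs.set_index(["gene_u", "gene_v"])
        assert by.loc[("g1", "g2"), "r_a"] == pytest.approx(1.0)
        assert by.loc[("g1", "g3"), "r_a"] == pytest.approx(-1.0)

    def test_matches_covariance_formula_oracle(self, rng):
        mat = rng.standard_normal((5, 20))
        ds = make_dataset(mat)
        pairs = dcea.pair_correlations(ds)

        def pearson(x, y):
            xc, yc = x - x.mean(), y - y.mean()
            return float((xc @ yc) / np.sqrt((xc @ xc) * (yc @ yc)))

        for _, row in pairs.iterrows():
            i = ds.genes.index(row.gene_u)
            j = ds.genes.index(row.gene_v)
            assert row.r_a == pytest.approx(pearson(mat[i, :10], mat[j, :10]), abs=1e-12)
            assert row.r_b == pytest.approx(pearson(mat[i, 10:], mat[j, 10:]), abs=1e-12)

    def test_zero_variance_gene_marked_invalid(self, caplog):
        mat = [
            [1.0] * 6,  # flat in both conditions
            [1, 2, 3, 4, 5, 6],
            [2, 1, 3, 0, 5, 4],
        ]
        with caplog.at_level("WARNING", logger="diffregnet.dcea"):
            pairs = dcea.pair_correlations(make_dataset(mat))
        flat = pairs[(pairs.gene_u == "g1") | (pairs.gene_v == "g1")]
        assert (flat.r_a == 0).all() and (flat.r_b == 0).all()
        assert not flat.valid.any()
        assert not dcea.qualify_pairs(pairs, q_keep=1.0).loc[flat.index, "qualified"].any()


class TestQualifyPairs:
    def test_keep_all_at_degenerate_threshold(self):
        pairs = pair_frame([0.9, 0.1, 0.4], [0.2, 0.3, 0.1])
        assert dcea.qualify_pairs(pairs, q_keep=1.0)["qualified"].all()

    def test_median_threshold_keeps_top_half(self):
        pairs = pair_frame([0.9, 0.7, 0.3, 0.1], [0.0, 0.0, 0.0, 0.0])
        out = dcea.qualify_pairs(pairs, q_keep=0.5)
        assert out["qualified"].tolist() == [True, True, False, False]

    def test_ties_all_kept(self):
        pairs = pair_frame([0.5] * 4, [0.2] * 4)
        assert dcea.qualify_pairs(pairs, q_keep=0.25)["qualified"].all()

    @pytest.mark.parametrize("bad", [0.0, -0.1, 1.5])
    def test_invalid_fraction_rejected(self, bad):
        with pytest.raises(ValueError):
            dcea.qualify_pairs(pair_frame([0.5], [0.5]), q_keep=bad)


class TestDcpScores:
    def test_hand_computed_rms(self):
        # one gene with pair changes 0.9->0.1 and 0.8->-0.2
        pairs = pd.DataFrame(
            {
                "gene_u": ["x", "x"],
                "gene_v": ["p", "q"],
                "r_a": [0.9, 0.8],
                "r_b": [0.1, -0.2],
                "valid": True,
                "qualified": True,
            }
        )
        out = dcea.dcp_scores(pairs).set_index("gene")
        assert out.loc["x", "dcp_score"] == pytest.approx(np.sqrt((0.8**2 + 1.0**2) / 2))
        assert out.loc["x", "n_pairs"] == 2

    def test_unchanged_correlations_give_zero(self):
        pairs = pair_frame([0.3, -0.6], [0.3, -0.6])
        assert (dcea.dcp_scores(pairs)["dcp_score"] == 0).all()

    def test_single_maximal_flip_gives_two(self):
        pairs = pair_frame([1.0], [-1.0])
        assert dcea.dcp_scores(pairs)["dcp_score"].iloc[0] == pytest.approx(2.0)

    def test_matches_double_loop_oracle(self, rng):
        ds = make_dataset(rng.standard_normal((8, 24)))
        pairs = dcea.qualify_pairs(dcea.pair_correlations(ds), q_keep=0.6)
        out = dcea.dcp_scores(pairs).set_index("gene")
        q = pairs[pairs.qualified]
        for gene in out.index:
            sq = [
                (row.r_a - row.r_b) ** 2
                for _, row in q.iterrows()
                if gene in (row.gene_u, row.gene_v)
            ]
            assert out.loc[gene, "dcp_score"] == pytest.approx(
                np.sqrt(sum(sq) / len(sq)), abs=1e-12
            )


class TestDcpFdr:
    def test_too_few_permutations_rejected(self, rng):
        ds = make_dataset(rng.standard_normal((4, 12)))
        pairs = dcea.qualify_pairs(dcea.pair_correlations(ds), q_keep=1.0)
        with pytest.raises(ValueError, match=">= 50"):
            dcea.dcp_fdr(ds, pairs, n_perm=10, seed=0)

    def test_identical_condition_matrices_give_zero_scores(self, rng):
        block = rng.standard_normal((5, 8))
        ds = make_dataset(np.hstack([block, block]))
        pairs = dcea.qualify_pairs(dcea.pair_correlations(ds), q_keep=1.0)
        out = dcea.dcp_fdr(ds, pairs, n_perm=50, seed=0)
        assert (out["dcp_score"] == 0).all()
        assert (out["fdr"] == 1.0).all()

    def test_planted_correlation_flip_is_top_ranked(self):
        rng = np.random.default_rng(5)
        n = 30
        base = rng.standard_normal((10, 2 * n))
        # g1 tracks g2 positively in A, negatively in B
        driver = rng.standard_normal(2 * n)
        base[0] = np.concatenate([driver[:n], driver[n:]]) + 0.2 * rng.standard_normal(2 * n)
        base[1] = np.concatenate([driver[:n], -driver[n:]]) + 0.2 * rng.standard_normal(2 * n)
        ds = make_dataset(base)
        pairs = dcea.qualify_pairs(dcea.pair_correlations(ds), q_keep=0.25)
        out = dcea.dcp_fdr(ds, pairs, n_perm=60, seed=2)
        top = out.iloc[out["fdr"].to_numpy().argmin()]
        assert out.iloc[0]["gene"] in {"g1", "g2"}
        assert top["gene"] in {"g1", "g2"}

    def test_condition_exchange_invariance(self, rng):
        ds = make_dataset(rng.standard_normal((6, 16)))
        swapped = make_dataset(
            ds.values.to_numpy(),
            genes=ds.genes,
            samples=ds.samples,
            labels=["B" if c == "A" else "A" for c in ds.condition_of],
        )
        pairs = dcea.qualify_pairs(dcea.pair_correlations(ds), q_keep=0.5)
        pairs_sw = dcea.qualify_pairs(dcea.pair_correlations(swapped), q_keep=0.5)
        a = dcea.dcp_fdr(ds, pairs, n_perm=50, seed=3)
        b = dcea.dcp_fdr(swapped, pairs_sw, n_perm=50, seed=3)
        pd.testing.assert_frame_equal(a, b)


class TestLfcDcls:
    def test_no_change_yields_no_same_sign_links(self):
        r = np.linspace(0.1, 0.9, 60)
        out = dcea.lfc_dcls(pair_frame(r, r), bins=10)
        assert (out["cls"] != "same-sign").all()

    def test_strong_sign_flip_flagged_switched(self):
        r_a = np.concatenate([[0.8], np.linspace(0.1, 0.9, 60)])
        r_b = np.concatenate([[-0.8], np.linspace(0.1, 0.9, 60)])
        out = dcea.lfc_dcls(pair_frame(r_a, r_b), bins=10)
        flagged = out[(out.gene_u == "u0")]
        assert len(flagged) == 1 and flagged["cls"].iloc[0] == "switched"

    def test_stable_background_plus_outlier(self):
        r = np.linspace(0.1, 0.9, 500)
        pairs = pd.concat(
            [
                pair_frame(r, r),
                pd.DataFrame(
                    [
                        {
                            "gene_u": "x",
                            "gene_v": "y",
                            "r_a": 0.9,
                            "r_b": 0.05,
                            "valid": True,
                            "qualified": True,
                        }
                    ]
                ),
            ],
            ignore_index=True,
        )
        out = dcea.lfc_dcls(pairs)
        assert len(out) == 1
        assert (out["gene_u"].iloc[0], out["gene_v"].iloc[0]) == ("x", "y")

    def test_pair_order_invariance_and_envelope_monotonicity(self):
        rng = np.random.default_rng(3)
        n = 600
        m = rng.uniform(0.2, 0.95, n)
        shrink = np.abs(rng.normal(0, 0.25, n)) * (1.2 - m)
        pairs = pair_frame(m, np.maximum(m * np.exp(-shrink), 1e-4))
        sizes = [len(dcea.lfc_dcls(pairs, bins=20, env_q=q)) for q in (0.8, 0.9, 0.95)]
        assert sizes[0] >= sizes[1] >= sizes[2] > 0
        shuffled = pairs.sample(frac=1.0, random_state=1).reset_index(drop=True)
        pd.testing.assert_frame_equal(
            dcea.lfc_dcls(pairs, bins=20), dcea.lfc_dcls(shuffled, bins=20)
        )

    def test_fewer_pairs_than_bins_rejected(self):
        with pytest.raises(ValueError, match="reduce bins"):
            dcea.lfc_dcls(pair_frame([0.5, 0.4], [0.1, 0.2]), bins=20)
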