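import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from diffregnet import dra
from diffregnet.examples import CREB1_PUBLISHED_DRL, creb1_example_grns
from diffregnet.grn import GRN

from conftest import random_grn_pair

finite = st.floats(-10, 10, allow_nan=False)


def brute_force_dr(grn_a: GRN, grn_b: GRN, gene: str):
    """Independent union-loop oracle for the DR statistic."""
    total, n = 0.0, 0
    for edge in set(grn_a.links) | set(grn_b.links):
        if gene in edge:
            total += (grn_a.links.get(edge, 0.0) - grn_b.links.get(edge, 0.0)) ** 2
            n += 1
    return np.sqrt(total / n), n


class TestDrScore:
    def test_identical_grns_give_zero(self):
        links = {("t1", "g1"): 1.0, ("t1", "g2"): -0.5}
        a = GRN("A", dict(links))
        b = GRN("B", dict(links))
        for gene in ("t1", "g1", "g2"):
            assert dra.dr_score(a, b, gene)[0] == 0.0

    def test_single_link_change(self):
        a = GRN("A", {("t1", "g1"): 2.0})
        b = GRN("B", {("t1", "g1"): -1.0})
        assert dra.dr_score(a, b, "g1") == (3.0, 1)

    def test_creb1_restricted_dr(self):
        gn, gc = creb1_example_grns()
        value, n = dra.dr_score(gn, gc, "CREB1")
        assert n == 7
        deltas = [d for _, d in CREB1_PUBLISHED_DRL]
        assert value == pytest.approx(np.sqrt(sum(d**2 for d in deltas) / 7), abs=1e-6)
        assert round(value, 4) == 2.0633

    def test_isolated_gene_rejected(self):
        a = GRN("A", {("t1", "g1"): 1.0})
        b = GRN("B", {("t1", "g1"): 1.0})
        with pytest.raises(ValueError, match="isolated"):
            dra.dr_score(a, b, "g9")

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(25):
            a, b = random_grn_pair(rng, n_genes=12, n_links=18)
            for gene in sorted(a.genes | b.genes):
                got = dra.dr_score(a, b, gene)
                want = brute_force_dr(a, b, gene)
                assert got[1] == want[1]
                assert got[0] == pytest.approx(want[0], abs=1e-12)

    def test_symmetry_and_rms_bounds(self, rng):
        a, b = random_grn_pair(rng, n_genes=10, n_links=15)
        for gene in sorted(a.genes | b.genes):
            v_ab, n = dra.dr_score(a, b, gene)
            v_ba, _ = dra.dr_score(b, a, gene)
            assert v_ab == pytest.approx(v_ba, abs=1e-15)
            deltas = [
                abs(a.links.get(e, 0.0) - b.links.get(e, 0.0))
                for e in set(a.links) | set(b.links)
                if gene in e
            ]
            assert max(deltas) / np.sqrt(n) - 1e-12 <= v_ab <= max(deltas) + 1e-12


class TestRankDrgs:
    def test_tie_break_is_lexicographic(self):
        a = GRN("A", {("t1", "ga"): 3.0, ("t2", "gb"): 1.0, ("t3", "gc"): 1.0})
        b = GRN("B", {})
        table = dra.rank_drgs(a, b)
        target_rows = table[table.gene.isin(["ga", "gb", "gc"])]
        assert list(target_rows.gene) == ["ga", "gb", "gc"]
        assert list(target_rows["rank"]) == sorted(target_rows["rank"])

    def test_identical_grns_flag_nothing(self):
        links = {("t1", "g1"): 1.0, ("t2", "g2"): 2.0}
        table = dra.rank_drgs(GRN("A", dict(links)), GRN("B", dict(links)))
        assert (table.dr_value == 0).all()
        assert not table.top_flag.any()

    def test_heavily_rewired_genes_rank_first(self, rng):
        # 200 targets with tiny changes, 5 with large flips
        links_a = {("t1", f"g{i:03d}"): 1.0 for i in range(200)}
        links_b = {k: 1.0 + 0.01 * rng.normal() for k in links_a}
        rewired = [f"g{i:03d}" for i in (7, 42, 99, 123, 180)]
        for g in rewired:
            links_b[("t1", g)] = -4.0
        table = dra.rank_drgs(GRN("A", links_a), GRN("B", links_b))
        top5 = set(table[table.gene != "t1"].head(5).gene)
        assert top5 == set(rewired)

    def test_empty_grns_give_empty_table(self):
        table = dra.rank_drgs(GRN("A", {}), GRN("B", {}))
        assert table.empty


class TestDrlValue:
    @pytest.mark.parametrize(
        "x_a,x_b,expected",
        [
            (2.596, -0.483, 3.079),  # published CREB1-TRIM15 row
            (0.0, 0.894, 0.894),  # published CREB1-MBNL1 row
            (1.796, -0.437, 2.233),
        ],
    )
    def test_published_rows(self, x_a, x_b, expected):
        assert dra.drl_value(x_a, x_b) == pytest.approx(expected, abs=1e-12)

    @given(c=finite)
    @settings(max_examples=50, derandomize=True, deadline=None)
    def test_identity_is_zero(self, c):
        assert dra.drl_value(c, c) == 0.0

    @given(x=finite, y=finite)
    @settings(max_examples=100, derandomize=True, deadline=None)
    def test_symmetry_and_nonnegativity(self, x, y):
        assert dra.drl_value(x, y) == dra.drl_value(y, x) >= 0.0


class TestDetectDrls:
    def test_published_creb1_ranking(self):
        gn, gc = creb1_example_grns()
        table = dra.detect_drls(gn, gc)
        assert list(table.target) == [t for t, _ in CREB1_PUBLISHED_DRL]
        np.testing.assert_allclose(
            table.delta, [d for _, d in CREB1_PUBLISHED_DRL], atol=1e-12
        )
        assert table.passed_filter.all()  # 7 links < bins: envelope skipped

    def test_identical_grns_all_zero(self):
        links = {(f"t{i % 3}", f"g{i}"): 1.0 for i in range(30)}
        table = dra.detect_drls(GRN("A", dict(links)), GRN("B", dict(links)))
        assert (table.delta == 0).all()
        assert not table.passed_filter.any()

    def test_flipped_link_ranked_first_and_passes(self, rng):
        links_a = {("t1", f"g{i:03d}"): 1.0 + 0.05 * rng.normal() for i in range(300)}
        links_b = {k: v + 0.01 * rng.normal() for k, v in links_a.items()}
        links_a[("t1", "flip")] = 1.2
        links_b[("t1", "flip")] = -1.2
        table = dra.detect_drls(GRN("A", links_a), GRN("B", links_b))
        assert (table.tf.iloc[0], table.target.iloc[0]) == ("t1", "flip")
        assert table.passed_filter.iloc[0]

    def test_delta_column_nonincreasing_permutation(self, rng):
        a, b = random_grn_pair(rng, n_genes=15, n_links=25)
        table = dra.detect_drls(a, b, bins=5)
        assert (np.diff(table.delta) <= 1e-15).all()
        assert set(zip(table.tf, table.target)) == set(a.links) | set(b.links)

    def test_both_empty_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            dra.detect_drls(GRN("A", {}), GRN("B", {}))


class TestTdr:
    def test_identical_target_sets(self):
        links = {("t1", "g1"): 1.0, ("t1", "g2"): 2.0}
        assert dra.tdr(GRN("A", dict(links)), GRN("B", dict(links)), "t1").tdr == 0.0

    def test_disjoint_target_sets(self):
        a = GRN("A", {("t1", "g1"): 1.0})
        b = GRN("B", {("t1", "g2"): 1.0})
        assert dra.tdr(a, b, "t1").tdr == 1.0

    def test_partial_overlap(self):
        a = GRN("A", {("t1", g): 1.0 for g in ("g1", "g2", "g3")})
        b = GRN("B", {("t1", g): 1.0 for g in ("g2", "g3", "g4")})
        assert dra.tdr(a, b, "t1").tdr == pytest.approx(0.5)

    def test_unknown_tf_rejected(self):
        a = GRN("A", {("t1", "g1"): 1.0})
        with pytest.raises(ValueError, match="no targets"):
            dra.tdr(a, a, "t9")

    def test_rewired_tfs_exceed_half_when_most_targets_change(self):
        # majority target turnover pushes every TF's diversity above 0.5
        a = GRN("A", {(f"t{j}", f"g{j}_{i}"): 1.0 for j in range(3) for i in range(6)})
        b_links = {}
        for j in range(3):
            for i in range(6):
                key = f"g{j}_{i}" if i < 2 else f"h{j}_{i}"  # 4 of 6 targets replaced
                b_links[(f"t{j}", key)] = 1.0
        b = GRN("B", b_links)
        table = dra.tdr_table(a, b)
        assert (table.tdr > 0.5).all()
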