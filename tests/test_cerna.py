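"""Triplet screening, network assembly and recovery scoring."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cernanet import (
    CeRNACriteria,
    build_network,
    candidate_triplets,
    correlate,
    evaluate_recovery,
    hub_rank,
    screen_triplets,
)
from cernanet.cerna import CeRNATriplet, CorrelationResult, top_k_mirnas, triplets_to_frame
from cernanet.errors import DataError, DegenerateFeatureError
from cernanet.io import InteractionTable

from conftest import make_matrix


def de_frame(ids, direction="down"):
    if isinstance(direction, str):
        direction = [direction] * len(ids)
    return pd.DataFrame({"feature_id": ids, "direction": direction})


def interactions(pairs, kind):
    return InteractionTable(
        pd.DataFrame(
            [(m, t, kind, "test") for m, t in pairs],
            columns=["mirna_id", "target_id", "target_kind", "source"],
        )
    )


class TestCorrelate:
    def test_perfect_positive_and_negative(self):
        pos = correlate([1, 2, 3], [2, 4, 6])
        neg = correlate([1, 2, 3], [6, 4, 2])
        assert (pos.r, pos.p) == (1.0, 0.0)
        assert (neg.r, neg.p) == (-1.0, 0.0)

    def test_known_five_point_example(self):
        res = correlate([1, 2, 3, 4, 5], [2, 1, 4, 3, 5])
        assert res.r == pytest.approx(0.8, abs=1e-12)
        # oracle: numerical t-distribution tail with df = 3
        t = 0.8 * np.sqrt(3 / (1 - 0.64))
        assert res.p == pytest.approx(2 * stats.t.sf(t, 3), abs=1e-12)
        assert res.p == pytest.approx(0.104, abs=5e-4)

    def test_agrees_with_scipy_pearsonr(self):
        rng = np.random.default_rng(4)
        for _ in range(25):
            x, y = rng.normal(size=(2, 10))
            res = correlate(x, y)
            ref = stats.pearsonr(x, y)
            assert res.r == pytest.approx(ref.statistic, abs=1e-12)
            assert res.p == pytest.approx(ref.pvalue, abs=1e-10)

    def test_spearman_agrees_with_scipy(self):
        rng = np.random.default_rng(8)
        x = rng.normal(size=12)
        y = rng.normal(size=12) + x
        res = correlate(x, y, method="spearman")
        ref = stats.spearmanr(x, y)
        assert res.r == pytest.approx(ref.statistic, abs=1e-12)

    def test_correlation_p_matches_permutation_oracle(self):
        rng = np.random.default_rng(12)
        x = rng.normal(size=10)
        y = x * 0.7 + rng.normal(size=10)
        res = correlate(x, y)
        r_obs = abs(res.r)
        hits = 0
        n_perm = 5000
        for _ in range(n_perm):
            yp = rng.permutation(y)
            hits += abs(np.corrcoef(x, yp)[0, 1]) >= r_obs - 1e-12
        assert res.p == pytest.approx(hits / n_perm, abs=0.06)

    def test_degenerate_and_invalid_inputs(self):
        with pytest.raises(DegenerateFeatureError):
            correlate([1, 1, 1], [1, 2, 3])
        with pytest.raises(DataError):
            correlate([1, 2], [1, 2])


class TestCandidates:
    def test_single_shared_mirna_triplet(self):
        cands = candidate_triplets(
            de_frame(["l1"]), de_frame(["m1"], "up"), de_frame(["g1"]),
            interactions([("m1", "g1")], "mRNA"),
            interactions([("m1", "l1")], "lncRNA"),
        )
        assert cands == [("l1", "m1", "g1")]

    def test_non_de_mirna_blocks_the_triplet(self):
        cands = candidate_triplets(
            de_frame(["l1"]), de_frame(["m1"], "ns"), de_frame(["g1"]),
            interactions([("m1", "g1")], "mRNA"),
            interactions([("m1", "l1")], "lncRNA"),
        )
        assert cands == []

    def test_full_cross_product_count(self):
        mirs = [f"m{i}" for i in range(3)]
        genes = [f"g{i}" for i in range(4)]
        lncs = [f"l{i}" for i in range(2)]
        cands = candidate_triplets(
            de_frame(lncs), de_frame(mirs, "up"), de_frame(genes),
            interactions([(m, g) for m in mirs for g in genes], "mRNA"),
            interactions([(m, l) for m in mirs for l in lncs], "lncRNA"),
        )
        assert len(cands) == 24  # oracle: 3 * 4 * 2 exhaustive cross product
        assert cands == sorted(set(cands))

    def test_kind_mismatch_is_an_error(self):
        with pytest.raises(DataError):
            candidate_triplets(
                de_frame(["l1"]), de_frame(["m1"], "up"), de_frame(["g1"]),
                interactions([("m1", "g1")], "lncRNA"),  # wrong kind for mRNA slot
                interactions([("m1", "l1")], "lncRNA"),
            )

    def test_top_k_mirna_prefilter(self):
        mir_lnc = interactions(
            [("m1", "l1"), ("m1", "l2"), ("m1", "l3"), ("m2", "l1"), ("m3", "l9")],
            "lncRNA",
        )
        de_lnc = de_frame(["l1", "l2", "l3"])
        assert top_k_mirnas(de_lnc, mir_lnc, 1) == {"m1"}
        assert top_k_mirnas(de_lnc, mir_lnc, 2) == {"m1", "m2"}


def perfect_triplet_matrices():
    """miRNA = 1..10, mRNA = 11 - miRNA, lncRNA = 12 - miRNA, plus a
    constant decoy mRNA that must be excluded as degenerate."""
    mir = np.arange(1.0, 11.0)
    lnc = make_matrix([12 - mir], kind="lncRNA", scale="log2cpm", feature_ids=["l1"])
    mirna = make_matrix([mir], kind="miRNA", scale="log2cpm", feature_ids=["m1"])
    mrna = make_matrix(
        [11 - mir, np.full(10, 3.0)], kind="mRNA", scale="log2cpm",
        feature_ids=["g1", "gflat"],
    )
    return lnc, mirna, mrna


class TestScreen:
    def test_planted_perfect_triplet_passes_and_degenerate_is_excluded(self):
        lnc, mirna, mrna = perfect_triplet_matrices()
        out = screen_triplets(
            [("l1", "m1", "g1"), ("l1", "m1", "gflat")], lnc, mirna, mrna
        )
        assert [t.key for t in out] == [("l1", "m1", "g1")]
        assert out[0].passed
        assert out[0].corr_lnc_mrna.r == pytest.approx(1.0)
        assert out[0].corr_mir_mrna.r == pytest.approx(-1.0)

    def test_boundary_r_fails_strictly(self):
        res = CorrelationResult(r=0.3, p=0.001, n=10)
        crit = CeRNACriteria()
        assert not (res.r > crit.r_pos_min)

    def test_empty_candidate_list(self):
        lnc, mirna, mrna = perfect_triplet_matrices()
        assert screen_triplets([], lnc, mirna, mrna) == []

    def test_mismatched_sample_sets_rejected(self):
        lnc, mirna, mrna = perfect_triplet_matrices()
        shuffled = mrna.values[list(reversed(mrna.sample_ids))]
        bad = make_matrix(
            shuffled.to_numpy(), kind="mRNA", scale="log2cpm",
            feature_ids=list(mrna.values.index),
        )
        bad.values.columns = list(reversed(mrna.sample_ids))
        bad.groups.index = list(bad.values.columns)
        with pytest.raises(DataError, match="sample set"):
            screen_triplets([("l1", "m1", "g1")], lnc, mirna, bad)

    def test_sample_order_invariance(self):
        rng = np.random.default_rng(31)
        lnc, mirna, mrna = perfect_triplet_matrices()
        # jitter so correlations are not exactly +-1
        for m in (lnc, mirna, mrna):
            m.values += rng.normal(0, 0.4, m.values.shape)
        base = screen_triplets([("l1", "m1", "g1")], lnc, mirna, mrna)
        perm = rng.permutation(10)
        cols = [lnc.sample_ids[i] for i in perm]

        def reorder(m):
            out = make_matrix(
                m.values[cols].to_numpy(), kind=m.kind, scale="log2cpm",
                feature_ids=list(m.values.index),
            )
            out.values.columns = cols
            out.groups = m.groups[cols]
            return out

        permuted = screen_triplets(
            [("l1", "m1", "g1")], reorder(lnc), reorder(mirna), reorder(mrna)
        )
        assert base[0].corr_lnc_mrna.r == pytest.approx(permuted[0].corr_lnc_mrna.r)
        assert base[0].passed == permuted[0].passed

    def test_relabeling_invariance(self, small_dataset):
        from cernanet import run_de
        from cernanet.diffexpr import log2cpm

        ds = small_dataset
        tl, _ = run_de(ds.lncrna)
        tm, _ = run_de(ds.mirna)
        tg, _ = run_de(ds.mrna)
        cands = candidate_triplets(tl, tm, tg, ds.mir_mrna, ds.mir_lncrna)
        out = screen_triplets(
            cands, log2cpm(ds.lncrna), log2cpm(ds.mirna), log2cpm(ds.mrna)
        )

        rename = lambda fid: "X_" + fid  # noqa: E731
        tl2, tm2, tg2 = (
            t.assign(feature_id=t["feature_id"].map(rename)) for t in (tl, tm, tg)
        )
        re_tab = lambda tab: InteractionTable(  # noqa: E731
            tab.frame.assign(
                mirna_id=tab.frame["mirna_id"].map(rename),
                target_id=tab.frame["target_id"].map(rename),
            )
        )
        re_mat = lambda m: make_matrix(  # noqa: E731
            m.values.to_numpy(), kind=m.kind, scale=m.scale,
            feature_ids=[rename(f) for f in m.values.index],
        )
        cands2 = candidate_triplets(
            tl2, tm2, tg2, re_tab(ds.mir_mrna), re_tab(ds.mir_lncrna)
        )
        from cernanet.diffexpr import log2cpm as l2

        out2 = screen_triplets(
            cands2, re_mat(l2(ds.lncrna)), re_mat(l2(ds.mirna)), re_mat(l2(ds.mrna))
        )
        assert {(t.key, t.passed) for t in out2} == {
            ((rename(l), rename(m), rename(g)), t.passed)
            for t in out
            for (l, m, g) in [t.key]
        }


def passed_triplet(l, m, g):
    ok = CorrelationResult(r=0.9, p=0.001, n=10)
    neg = CorrelationResult(r=-0.9, p=0.001, n=10)
    return CeRNATriplet(l, m, g, ok, neg, neg, passed=True)


def de_tables_for(triplets):
    lncs = sorted({t.lncrna_id for t in triplets})
    mirs = sorted({t.mirna_id for t in triplets})
    genes = sorted({t.mrna_id for t in triplets})
    return {
        "lncRNA": de_frame(lncs, "down"),
        "miRNA": de_frame(mirs, "up"),
        "mRNA": de_frame(genes, "down"),
    }


class TestNetwork:
    def test_single_triplet_summary(self):
        trips = [passed_triplet("l1", "m1", "g1")]
        net = build_network(trips, de_tables_for(trips))
        assert net.summary() == {
            "n_lncRNA": 1, "n_miRNA": 1, "n_mRNA": 1,
            "n_sponge_edges": 1, "n_target_edges": 1,
        }
        assert net.nodes["m1"] == ("miRNA", "up")

    def test_shared_sponge_edge_deduplicated(self):
        trips = [passed_triplet("l1", "m1", "g1"), passed_triplet("l1", "m1", "g2")]
        net = build_network(trips, de_tables_for(trips))
        assert net.summary() == {
            "n_lncRNA": 1, "n_miRNA": 1, "n_mRNA": 2,
            "n_sponge_edges": 1, "n_target_edges": 2,
        }

    def test_edge_counts_equal_unique_pair_counts(self):
        rng = np.random.default_rng(2)
        trips = [
            passed_triplet(f"l{rng.integers(5)}", f"m{rng.integers(4)}", f"g{rng.integers(8)}")
            for _ in range(20)
        ]
        net = build_network(trips, de_tables_for(trips))
        lm = {(t.lncrna_id, t.mirna_id) for t in trips}
        mg = {(t.mirna_id, t.mrna_id) for t in trips}
        s = net.summary()
        assert s["n_sponge_edges"] == len(lm)
        assert s["n_target_edges"] == len(mg)

    def test_member_missing_from_de_tables_is_an_error(self):
        trips = [passed_triplet("l1", "m1", "g1")]
        tables = de_tables_for(trips)
        tables["mRNA"] = de_frame([], "down")
        with pytest.raises(DataError, match="g1"):
            build_network(trips, tables)

    def test_unpassed_triplet_rejected(self):
        t = passed_triplet("l1", "m1", "g1")
        bad = CeRNATriplet(
            t.lncrna_id, t.mirna_id, t.mrna_id,
            t.corr_lnc_mrna, t.corr_mir_mrna, t.corr_mir_lnc, passed=False,
        )
        with pytest.raises(DataError):
            build_network([bad], de_tables_for([t]))


class TestHubRank:
    def test_star_degree(self):
        trips = [passed_triplet(f"l{i % 2}", "m1", f"g{i}") for i in range(5)]
        net = build_network(trips, de_tables_for(trips))
        ranked = hub_rank(net, "miRNA")
        assert ranked[0] == ("m1", 7)  # 2 sponge + 5 target edges

    def test_single_triplet_all_degree_one(self):
        trips = [passed_triplet("l1", "m1", "g1")]
        net = build_network(trips, de_tables_for(trips))
        for kind, node in (("lncRNA", "l1"), ("mRNA", "g1")):
            assert hub_rank(net, kind) == [(node, 1)]
        assert hub_rank(net, "miRNA") == [("m1", 2)]

    def test_absent_kind_gives_empty_list(self):
        from cernanet.cerna import CeRNANetwork

        assert hub_rank(CeRNANetwork(nodes={}, edges=set()), "mRNA") == []


class TestRecovery:
    def test_exact_recovery(self):
        p, r, f1 = evaluate_recovery([("l1", "m1", "g1")], [("l1", "m1", "g1")])
        assert (p, r, f1) == (1.0, 1.0, 1.0)

    def test_nothing_passed(self):
        p, r, f1 = evaluate_recovery([], [("l1", "m1", "g1")])
        assert (p, r, f1) == (0.0, 0.0, 0.0)

    def test_both_empty(self):
        assert evaluate_recovery([], []) == (1.0, 1.0, 1.0)

    def test_partial_overlap_arithmetic(self):
        planted = [(f"l{i}", f"m{i}", f"g{i}") for i in range(20)]
        passed = planted[:18] + [("lx1", "mx1", "gx1"), ("lx2", "mx2", "gx2")]
        p, r, _ = evaluate_recovery(passed, planted)
        assert p == pytest.approx(0.9)
        assert r == pytest.approx(0.9)


class TestTripletFrame:
    def test_columns_and_round_trip(self, tmp_path):
        trips = [passed_triplet("l1", "m1", "g1")]
        frame = triplets_to_frame(trips)
        assert list(frame.columns) == [
            "lncrna_id", "mirna_id", "mrna_id",
            "r_lnc_mrna", "p_lnc_mrna", "r_mir_mrna", "p_mir_mrna",
            "r_mir_lnc", "p_mir_lnc", "passed",
        ]
        frame.to_csv(tmp_path / "t.tsv", sep="\t", index=False)
        back = pd.read_csv(tmp_path / "t.tsv", sep="\t")
        assert back["passed"].iloc[0]
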