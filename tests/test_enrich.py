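import math

import numpy as np
import pandas as pd
import pytest

from sexmeta.enrich import (
    fisher_ora,
    filter_consistent_interactions,
    read_gmt,
    read_network,
    regulon_activity,
    regulons_from_network,
    signed_score,
)


def hypergeom_tail_enumeration(k, N, K, n):
    """P(X >= k) by explicit enumeration of the hypergeometric pmf."""
    total = 0.0
    for x in range(k, min(K, n) + 1):
        total += math.comb(K, x) * math.comb(N - K, n - x) / math.comb(N, n)
    return total


class TestFisherOra:
    def test_worked_example_matches_enumeration(self):
        background = [f"g{i}" for i in range(100)]
        degs = background[:10]
        collection = {"set1": set(degs[:3]) | set(background[90:92])}  # 3 of 5 are DEGs
        res = fisher_ora(degs, background, collection)
        expected = hypergeom_tail_enumeration(3, 100, 5, 10)
        assert res.loc["set1", "p"] == pytest.approx(expected, abs=1e-12)
        assert res.loc["set1", "overlap"] == 3

    def test_disjoint_set_and_whole_background(self):
        background = [f"g{i}" for i in range(30)]
        degs = background[:5]
        res = fisher_ora(degs, background, {
            "disjoint": set(background[20:25]),
            "everything": set(background),
        })
        assert res.loc["disjoint", "p"] == 1.0
        assert res.loc["everything", "p"] == 1.0
        assert res.loc["everything", "overlap"] == 5

    def test_random_instances_match_enumeration(self):
        rng = np.random.default_rng(6)
        for _ in range(50):
            N = int(rng.integers(10, 51))
            background = [f"g{i}" for i in range(N)]
            n = int(rng.integers(1, N))
            degs = list(rng.choice(background, size=n, replace=False))
            K = int(rng.integers(1, N))
            members = set(rng.choice(background, size=K, replace=False))
            res = fisher_ora(degs, background, {"s": members})
            k = len(set(degs) & members)
            assert res.loc["s", "p"] == pytest.approx(
                hypergeom_tail_enumeration(k, N, K, n), abs=1e-12
            )

    def test_gene_ratio_uses_annotated_deg_denominator(self):
        background = [f"g{i}" for i in range(40)]
        degs = background[:8]
        collection = {
            "a": set(background[0:4]),     # 4 DEGs
            "b": set(background[6:12]),    # 2 DEGs
        }
        res = fisher_ora(degs, background, collection)
        # 6 distinct DEGs carry any annotation
        assert res.loc["a", "gene_ratio"] == "4/6"
        assert res.loc["b", "gene_ratio"] == "2/6"

    def test_empty_deg_list_warns_and_deg_superset_raises(self):
        background = ["a", "b", "c"]
        with pytest.warns(RuntimeWarning):
            res = fisher_ora([], background, {"s": {"a"}})
        assert (res["p"] == 1).all()
        with pytest.raises(ValueError):
            fisher_ora(["z"], background, {"s": {"a"}})


class TestRegulonActivity:
    @staticmethod
    def _stats(seed=0, n=200):
        rng = np.random.default_rng(seed)
        return pd.Series(rng.normal(0, 2, n), index=[f"g{i}" for i in range(n)])

    def test_coherent_up_targets_give_positive_activity(self):
        stats = self._stats()
        strong_up = stats.nlargest(10).index
        regulons = {"TF1": [(g, 1) for g in strong_up]}
        act = regulon_activity(regulons, {"F": stats}, n_perm=500, seed=1)
        assert act.loc["TF1", "activity_f"] > 2

    def test_inhibitory_edges_flip_sign(self):
        stats = self._stats()
        strong_up = stats.nlargest(10).index
        regulons = {"TF1": [(g, -1) for g in strong_up]}
        act = regulon_activity(regulons, {"F": stats}, n_perm=500, seed=1)
        assert act.loc["TF1", "activity_f"] < -2

    def test_identical_sex_statistics_give_zero_difference(self):
        stats = self._stats()
        regulons = {"TF1": [(g, 1) for g in stats.index[:8]],
                    "TF2": [(g, -1) for g in stats.index[50:60]]}
        act = regulon_activity(regulons, {"F": stats, "M": stats.copy()}, n_perm=300, seed=2)
        np.testing.assert_allclose(act["difference"], 0.0, atol=1e-12)

    def test_antisymmetric_in_target_statistics(self):
        stats = self._stats(3)
        regulons = {"TF1": [(g, 1) for g in stats.index[:12]]}
        a = regulon_activity(regulons, {"F": stats}, n_perm=400, seed=7)
        b = regulon_activity(regulons, {"F": -stats}, n_perm=400, seed=7)
        assert a.loc["TF1", "activity_f"] == pytest.approx(-b.loc["TF1", "activity_f"])

    def test_permutation_calibration_under_random_statistics(self):
        rng = np.random.default_rng(8)
        stats = self._stats(8, n=500)
        regulons = {
            f"TF{i}": [(g, 1) for g in rng.choice(stats.index, 10, replace=False)]
            for i in range(40)
        }
        act = regulon_activity(regulons, {"F": stats}, n_perm=1000, seed=9)
        z = act["activity_f"]
        assert abs(z.mean()) < 3 / np.sqrt(len(z))  # ~3 SE of 0
        assert 0.7 < z.std() < 1.3

    def test_small_regulons_skipped(self):
        stats = self._stats()
        act = regulon_activity({"tiny": [("g0", 1), ("g1", 1)]}, {"F": stats}, n_perm=100)
        assert "tiny" not in act.index


class TestNetworkFilter:
    @staticmethod
    def _net(rows):
        return pd.DataFrame(rows, columns=["source", "target", "sign", "evidence"])

    def test_sign_consistency_rules(self):
        lfc = pd.Series({"TF": 0.4, "up_a": 0.6, "up_i": 0.6,
                         "down_a": -0.6, "down_i": -0.6, "flat": 0.0})
        net = self._net([
            ("TF", "down_a", "+", "A"),  # activation, opposite signs -> removed
            ("TF", "up_a", "+", "A"),    # activation, same sign -> kept
            ("TF", "down_i", "-", "A"),  # inhibition, opposite signs -> kept
            ("TF", "up_i", "-", "A"),    # inhibition, same sign -> removed
            ("TF", "flat", "+", "A"),    # zero LFC -> dropped
            ("TF", "missing", "+", "A"),
        ])
        out = filter_consistent_interactions(net, lfc)
        kept = set(zip(out["target"], out["sign"]))
        assert kept == {("up_a", "+"), ("down_i", "-")}

    def test_idempotent_and_never_adds_edges(self):
        rng = np.random.default_rng(5)
        genes = [f"g{i}" for i in range(20)]
        lfc = pd.Series(rng.normal(0, 1, 20), index=genes)
        net = self._net([
            (genes[int(rng.integers(20))], genes[int(rng.integers(20))],
             rng.choice(["+", "-"]), "B")
            for _ in range(50)
        ])
        once = filter_consistent_interactions(net, lfc)
        twice = filter_consistent_interactions(once, lfc)
        pd.testing.assert_frame_equal(once, twice)
        assert len(once) <= len(net)

    def test_ambiguous_duplicate_edges_excluded(self):
        lfc = pd.Series({"TF": 1.0, "t": 1.0})
        net = self._net([("TF", "t", "+", "A"), ("TF", "t", "-", "A")])
        assert len(filter_consistent_interactions(net, lfc)) == 0


def test_gmt_and_network_io(tmp_path):
    gmt = tmp_path / "sets.gmt"
    gmt.write_text("setA\tdesc\tg1\tg2\tg3\nsetB\tdesc\tg2\n")
    sets = read_gmt(gmt)
    assert sets == {"setA": {"g1", "g2", "g3"}, "setB": {"g2"}}

    net_path = tmp_path / "net.tsv"
    net_path.write_text("source\ttarget\tsign\tevidence\nTF1\tg1\t+\tA\nTF1\tg2\t-\tB\n")
    net = read_network(net_path)
    regs = regulons_from_network(net)
    assert regs == {"TF1": [("g1", 1), ("g2", -1)]}

    meta = pd.DataFrame({"lfc": [1.0, -2.0], "p": [0.01, 0.5]}, index=["g1", "g2"])
    scores = signed_score(meta)
    assert scores["g1"] == pytest.approx(2.0)
    assert scores["g2"] == pytest.approx(-math.log10(0.5) * -1)
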