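import math

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from lnckit.errors import ValidationError
from lnckit.io import FeatureAnnotation
from lnckit.network import (
    CoexpressionNetwork,
    build_network,
    hub_report,
    neighbor_jaccard,
    select_edges,
    select_vertices,
)
from lnckit.simulate import simulate_confirmation_cohort, simulate_discovery_cohort

from _oracles import edges_bruteforce


def _de(feature_ids, fdrs, log2fcs=None):
    return pd.DataFrame(
        {
            "feature_id": feature_ids,
            "fdr": fdrs,
            "log2fc": log2fcs if log2fcs is not None else np.ones(len(feature_ids)),
        }
    )


def _annotation(lnc_ids, pcg_ids):
    ids = list(lnc_ids) + list(pcg_ids)
    return FeatureAnnotation(
        pd.DataFrame(
            {
                "feature_id": ids,
                "symbol": ids,
                "biotype": ["lincRNA"] * len(lnc_ids) + ["protein_coding"] * len(pcg_ids),
                "is_lncRNA": [True] * len(lnc_ids) + [False] * len(pcg_ids),
            }
        )
    )


class TestSelectVertices:
    def test_empty_confirmation_gives_no_vertices(self):
        d = _de(["l1", "p1"], [0.01, 0.01])
        c = _de([], [])
        lnc, pcg = select_vertices(d, c, _annotation(["l1"], ["p1"]))
        assert lnc == [] and pcg == []

    def test_tightening_thresholds_never_adds_vertices(self, rng):
        ids = [f"l{i}" for i in range(20)] + [f"p{i}" for i in range(30)]
        ann = _annotation([f"l{i}" for i in range(20)], [f"p{i}" for i in range(30)])
        d = _de(ids, rng.uniform(size=50))
        c = _de(ids, rng.uniform(size=50))
        loose = select_vertices(d, c, ann, fdr_disc=0.5, fdr_conf=0.5)
        tight = select_vertices(d, c, ann, fdr_disc=0.2, fdr_conf=0.05)
        assert set(tight[0]) <= set(loose[0])
        assert set(tight[1]) <= set(loose[1])

    def test_unannotated_feature_excluded_with_warning(self, caplog):
        d = _de(["l1", "ghost"], [0.01, 0.01])
        c = _de(["l1", "ghost"], [0.001, 0.001])
        with caplog.at_level("WARNING"):
            lnc, pcg = select_vertices(d, c, _annotation(["l1"], []))
        assert lnc == ["l1"] and pcg == []
        assert "lack annotation" in caplog.text


class TestSelectEdges:
    def test_ceiling_rule_exact_counts(self, rng):
        corr = pd.DataFrame(
            rng.uniform(-1, 1, size=(20, 50)),
            index=[f"l{i:02d}" for i in range(20)],
            columns=[f"p{i:02d}" for i in range(50)],
        )
        edges = select_edges(corr, edge_fraction=0.005)  # ceil(5.0) = 5
        assert (edges["sign"] == "positive").sum() == 5
        assert (edges["sign"] == "negative").sum() == 5

    def test_ceiling_rounds_up_fractional(self, rng):
        corr = pd.DataFrame(
            rng.uniform(-1, 1, size=(10, 10)),
            index=[f"l{i}" for i in range(10)],
            columns=[f"p{i}" for i in range(10)],
        )
        edges = select_edges(corr, edge_fraction=0.005)  # ceil(0.5) = 1
        assert (edges["sign"] == "positive").sum() == 1
        assert (edges["sign"] == "negative").sum() == 1

    def test_matches_full_sort_oracle_over_many_seeds(self):
        for seed in range(50):
            rng = np.random.default_rng(seed)
            corr = pd.DataFrame(
                np.round(rng.uniform(-1, 1, size=(20, 30)), 2),  # rounding makes ties
                index=[f"l{i:02d}" for i in range(20)],
                columns=[f"p{i:02d}" for i in range(30)],
            )
            frac = rng.choice([0.005, 0.01, 0.05])
            edges = select_edges(corr, edge_fraction=frac)
            got = {
                (r.lnc_id, r.pcg_id): (r.r, r.sign)
                for r in edges.itertuples(index=False)
            }
            assert got == edges_bruteforce(corr, frac)

    def test_nan_entries_never_selected(self, rng):
        corr = pd.DataFrame(
            rng.uniform(-1, 1, size=(4, 4)),
            index=list("abcd"),
            columns=list("wxyz"),
        )
        corr.iloc[0, 0] = np.nan
        edges = select_edges(corr, edge_fraction=0.5)
        assert not ((edges["lnc_id"] == "a") & (edges["pcg_id"] == "w")).any()
        # candidate pool excludes the NaN: ceil(0.5 * 15) = 8 per sign
        assert len(edges) <= 2 * math.ceil(0.5 * 15)

    def test_fraction_out_of_range_rejected(self, rng):
        corr = pd.DataFrame(rng.uniform(-1, 1, size=(2, 2)))
        with pytest.raises(ValidationError):
            select_edges(corr, edge_fraction=0.0)
        with pytest.raises(ValidationError):
            select_edges(corr, edge_fraction=0.6)


class TestBuildNetwork:
    @pytest.fixture(scope="class")
    @staticmethod
    def planted_run():
        from lnckit.config import SimulationConfig

        cfg = SimulationConfig(
            n_features=600,
            frac_lncRNA=0.2,
            n_true_de=60,
            planted_set_size=30,
            n_tumor_confirm=300,
            n_normal_confirm=30,
            seed=77,
        )
        *_, truth = simulate_discovery_cohort(cfg)
        counts, sheet = simulate_confirmation_cohort(cfg, truth)
        return cfg, truth, counts, sheet

    def test_bipartite_and_deterministic(self, planted_run):
        _, truth, counts, sheet = planted_run
        lnc = list(truth.loc[truth.is_de & truth.is_lncRNA, "feature_id"])
        pcg = list(truth.loc[truth.is_de & ~truth.is_lncRNA, "feature_id"])
        net1 = build_network(counts, sheet, (lnc, pcg), edge_fraction=0.01)
        net2 = build_network(counts, sheet, (list(reversed(lnc)), pcg), edge_fraction=0.01)
        assert nx.is_bipartite(net1.graph)
        pd.testing.assert_frame_equal(net1.edges, net2.edges)

    def test_sample_relabeling_leaves_network_unchanged(self, planted_run, rng):
        _, truth, counts, sheet = planted_run
        lnc = list(truth.loc[truth.is_de & truth.is_lncRNA, "feature_id"])
        pcg = list(truth.loc[truth.is_de & ~truth.is_lncRNA, "feature_id"])
        net1 = build_network(counts, sheet, (lnc, pcg), edge_fraction=0.01)
        perm = list(rng.permutation(counts.sample_ids))
        net2 = build_network(counts.subset_samples(perm), sheet, (lnc, pcg), edge_fraction=0.01)
        pd.testing.assert_frame_equal(net1.edges, net2.edges)

    def test_too_few_samples_is_error(self, planted_run):
        _, truth, counts, sheet = planted_run
        with pytest.raises(ValidationError, match="3 samples"):
            build_network(
                counts.subset_samples(counts.sample_ids[:2]),
                sheet,
                (["LNC00001"], ["PCG00001"]),
                sample_subset="all",
            )


class TestHubReport:
    def _star(self):
        g = nx.Graph()
        g.add_node("lnc1", cls="lncRNA")
        g.add_node("lnc2", cls="lncRNA")
        for i in range(5):
            g.add_node(f"p{i}", cls="protein_coding")
            g.add_edge("lnc1", f"p{i}", r=0.9, sign="positive")
        g.add_edge("lnc2", "p0", r=-0.8, sign="negative")
        return CoexpressionNetwork(graph=g)

    def test_star_graph_top_hub(self):
        report = hub_report(self._star())
        assert report.loc[0, "feature_id"] == "lnc1"
        assert report.loc[0, "degree"] == 5
        assert report.loc[0, "n_positive"] == 5

    def test_jaccard_identical_and_disjoint(self):
        net = self._star()
        assert neighbor_jaccard(net, "lnc1", "lnc1") == 1.0
        assert neighbor_jaccard(net, "lnc1", "lnc2") == pytest.approx(1 / 5)

    def test_jaccard_matches_bruteforce_on_random_graphs(self, rng):
        for _ in range(20):
            g = nx.Graph()
            lncs = [f"l{i}" for i in range(4)]
            pcgs = [f"p{i}" for i in range(12)]
            for n in lncs:
                g.add_node(n, cls="lncRNA")
            for n in pcgs:
                g.add_node(n, cls="protein_coding")
            for l in lncs:
                for p in pcgs:
                    if rng.random() < 0.3:
                        g.add_edge(l, p, r=0.5, sign="positive")
            net = CoexpressionNetwork(graph=g)
            a, b = rng.choice(lncs, 2, replace=False)
            na, nb = set(g.neighbors(a)), set(g.neighbors(b))
            expected = len(na & nb) / len(na | nb) if (na | nb) else 0.0
            assert neighbor_jaccard(net, a, b) == pytest.approx(expected)

    def test_empty_network_empty_report(self):
        assert hub_report(CoexpressionNetwork(graph=nx.Graph())).empty
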