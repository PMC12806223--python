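"""Disease-network filters, axis enumeration and scoring."""

import numpy as np
import pandas as pd
import pytest

from cerna_axis.cerna import (
    CeRNAAxis,
    DiseaseNetwork,
    NodeDE,
    correlation_filter,
    direction_filter,
    enumerate_axes,
    prune_mirnas,
    score_axes,
    subset_network,
)
from cerna_axis.diffexpr import DESets, ExpressionMatrix
from cerna_axis.refnet import InteractionRecord, build_reference
from conftest import random_disease_network


def _net(edges_lnc, edges_m, directions):
    net = DiseaseNetwork()
    for lnc, mi in edges_lnc:
        net.lnc_mi[(lnc, mi)] = {"src"}
    for mi, m in edges_m:
        net.mi_m[(mi, m)] = {"src"}
    for n, d in directions.items():
        cls = "lncRNA" if n.startswith("L") else "miRNA" if n.startswith("mi") else "mRNA"
        net.nodes[n] = NodeDE(node_class=cls, direction=d, log2fc=3.0, p=0.01)
    return net


def _de_sets(directions):
    s = DESets()
    for g, d in directions.items():
        s.direction[g] = d
        s.log2fc[g] = 3.0 if d == "up" else -3.0
        s.p[g] = 0.01
    return s


class TestSubsetNetwork:
    def _ref(self):
        recs = [
            InteractionRecord("L1", "mi1", "lnc_mi", "dbA"),
            InteractionRecord("L2", "mi1", "lnc_mi", "dbA"),
            InteractionRecord("M1", "mi1", "mi_m", "dbA"),
        ]
        return build_reference(recs)

    def test_edge_kept_when_both_endpoints_de(self):
        net = subset_network(self._ref(), _de_sets({"L1": "up", "mi1": "down"}))
        assert ("L1", "mi1") in net.lnc_mi

    def test_edge_dropped_when_one_endpoint_not_de(self):
        net = subset_network(self._ref(), _de_sets({"L1": "up", "mi1": "down"}))
        assert ("L2", "mi1") not in net.lnc_mi
        assert "L2" not in net.nodes

    def test_empty_overlap_warns_not_raises(self):
        with pytest.warns(UserWarning, match="do not overlap"):
            net = subset_network(self._ref(), _de_sets({"ZZZ": "up"}))
        assert net.n_edges == 0

    def test_random_overlap_matches_double_membership_oracle(self):
        rng = np.random.default_rng(0)
        recs = []
        for _ in range(500):
            if rng.random() < 0.5:
                recs.append(
                    InteractionRecord(
                        f"L{rng.integers(40)}", f"mi{rng.integers(25)}", "lnc_mi", "dbA"
                    )
                )
            else:
                recs.append(
                    InteractionRecord(
                        f"M{rng.integers(60)}", f"mi{rng.integers(25)}", "mi_m", "dbA"
                    )
                )
        ref = build_reference(recs)
        de_nodes = {
            n: ("up" if rng.random() < 0.5 else "down")
            for n in ref.node_class
            if rng.random() < 0.4
        }
        net = subset_network(ref, _de_sets(de_nodes))
        assert set(net.lnc_mi) == {
            e for e in ref.lnc_mi if e[0] in de_nodes and e[1] in de_nodes
        }
        assert set(net.mi_m) == {
            e for e in ref.mi_m if e[0] in de_nodes and e[1] in de_nodes
        }


class TestDirectionFilter:
    def test_concordant_removed_discordant_kept(self):
        net = _net(
            [("L1", "mi1"), ("L2", "mi1")],
            [],
            {"L1": "up", "L2": "down", "mi1": "up"},
        )
        out = direction_filter(net)
        assert ("L1", "mi1") not in out.lnc_mi
        assert ("L2", "mi1") in out.lnc_mi

    def test_all_discordant_network_is_fixed_point(self):
        net = _net(
            [("L1", "mi1"), ("L2", "mi2")],
            [("mi1", "M1"), ("mi2", "M2")],
            {"L1": "up", "L2": "up", "mi1": "down", "mi2": "down",
             "M1": "up", "M2": "up"},
        )
        out = direction_filter(net)
        assert out.lnc_mi == net.lnc_mi and out.mi_m == net.mi_m

    def test_missing_direction_is_error(self):
        net = _net([("L1", "mi1")], [], {"L1": "up", "mi1": "up"})
        net.nodes["mi1"] = NodeDE("miRNA", "ns", 0.0, 1.0)
        with pytest.raises(ValueError, match="direction"):
            direction_filter(net)

    def test_random_networks_match_sign_discordance_oracle(self):
        for seed in range(10):
            net = random_disease_network(np.random.default_rng(seed))
            out = direction_filter(net)
            d = {n: nd.direction for n, nd in net.nodes.items()}
            assert set(out.lnc_mi) == {
                (a, b) for a, b in net.lnc_mi if d[a] != d[b]
            }
            assert set(out.mi_m) == {
                (a, b) for a, b in net.mi_m if d[a] != d[b]
            }


class TestCorrelationFilter:
    def _expr(self, vectors):
        df = pd.DataFrame(vectors).T  # genes as rows
        groups = {c: ("case" if i < len(df.columns) // 2 else "control")
                  for i, c in enumerate(df.columns)}
        classes = {
            g: ("lncRNA" if g.startswith("L") else "miRNA" if g.startswith("mi") else "mRNA")
            for g in df.index
        }
        return ExpressionMatrix(df, groups, classes)

    def test_perfect_anticorrelation_kept(self):
        x = np.arange(12.0)
        expr = self._expr({"L1": x, "mi1": 100 - 2 * x})
        net = _net([("L1", "mi1")], [], {"L1": "up", "mi1": "down"})
        out = correlation_filter(net, expr)
        assert ("L1", "mi1") in out.lnc_mi
        assert out.edge_corr[("L1", "mi1")][1] == pytest.approx(-1.0)

    def test_identical_vectors_dropped(self):
        x = np.arange(12.0)
        expr = self._expr({"L1": x, "mi1": x})
        net = _net([("L1", "mi1")], [], {"L1": "up", "mi1": "down"})
        out = correlation_filter(net, expr)
        assert out.n_edges == 0

    def test_constant_vector_dropped_with_warning(self):
        expr = self._expr({"L1": np.arange(12.0), "mi1": np.full(12, 7.0)})
        net = _net([("L1", "mi1")], [], {"L1": "up", "mi1": "down"})
        with pytest.warns(UserWarning, match="constant"):
            out = correlation_filter(net, expr)
        assert out.n_edges == 0

    def test_planted_anticorrelation_separates_from_decoys(self):
        kept_planted = kept_decoy = n_planted = n_decoy = 0
        for seed in range(20):
            rng = np.random.default_rng(100 + seed)
            vectors = {}
            edges = []
            directions = {}
            for i in range(5):  # planted rho ~ -0.8
                x = rng.normal(size=12)
                vectors[f"L{i}"] = 1000 + 100 * x
                vectors[f"mi{i}"] = 1000 - 100 * (x + 0.75 * rng.normal(size=12))
                edges.append((f"L{i}", f"mi{i}"))
                directions[f"L{i}"] = "up"
                directions[f"mi{i}"] = "down"
            for i in range(5, 15):  # independent decoys
                vectors[f"L{i}"] = 1000 + 100 * rng.normal(size=12)
                vectors[f"mi{i}"] = 1000 + 100 * rng.normal(size=12)
                edges.append((f"L{i}", f"mi{i}"))
                directions[f"L{i}"] = "up"
                directions[f"mi{i}"] = "down"
            expr = self._expr(vectors)
            net = _net(edges, [], directions)
            # bivariate-normal construction: Pearson is the matched method
            out = correlation_filter(net, expr, method="pearson")
            kept_planted += sum(1 for i in range(5) if (f"L{i}", f"mi{i}") in out.lnc_mi)
            kept_decoy += sum(1 for i in range(5, 15) if (f"L{i}", f"mi{i}") in out.lnc_mi)
            n_planted += 5
            n_decoy += 10
        assert kept_planted / n_planted >= 0.9
        assert 1 - kept_decoy / n_decoy >= 0.9

    def test_minimum_four_samples_accepted(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        expr = self._expr({"L1": x, "mi1": 10 - x})
        net = _net([("L1", "mi1")], [], {"L1": "up", "mi1": "down"})
        out = correlation_filter(net, expr)
        assert ("L1", "mi1") in out.lnc_mi


class TestPruneMirnas:
    def test_mirna_without_lncrna_partner_removed(self):
        net = _net(
            [],
            [("mi1", "M1"), ("mi1", "M2")],
            {"mi1": "down", "M1": "up", "M2": "up"},
        )
        out = prune_mirnas(net)
        assert out.n_edges == 0 and not out.nodes

    def test_mirna_with_both_partner_classes_kept(self):
        net = _net(
            [("L1", "mi1")],
            [("mi1", "M1")],
            {"L1": "up", "mi1": "down", "M1": "up"},
        )
        out = prune_mirnas(net)
        assert out.n_edges == 2

    def test_matches_loop_until_stable_oracle_and_invariant(self):
        for seed in range(20):
            net = random_disease_network(np.random.default_rng(200 + seed), density=0.08)
            out = prune_mirnas(net)
            # independent loop-until-stable reference
            lnc_mi, mi_m = dict(net.lnc_mi), dict(net.mi_m)
            changed = True
            while changed:
                changed = False
                mirnas = {e[1] for e in lnc_mi} | {e[0] for e in mi_m}
                for mi in mirnas:
                    has_l = any(e[1] == mi for e in lnc_mi)
                    has_m = any(e[0] == mi for e in mi_m)
                    if not (has_l and has_m):
                        lnc_mi = {e: s for e, s in lnc_mi.items() if e[1] != mi}
                        mi_m = {e: s for e, s in mi_m.items() if e[0] != mi}
                        changed = True
            assert out.lnc_mi == lnc_mi and out.mi_m == mi_m
            for mi in out.mirnas():
                assert any(e[1] == mi for e in out.lnc_mi)
                assert any(e[0] == mi for e in out.mi_m)


class TestEnumerateAxes:
    def test_degree_product_with_consistent_directions(self):
        net = _net(
            [("L1", "mi1"), ("L2", "mi1")],
            [("mi1", "M1"), ("mi1", "M2"), ("mi1", "M3")],
            {"L1": "up", "L2": "up", "mi1": "down",
             "M1": "up", "M2": "up", "M3": "up"},
        )
        axes = enumerate_axes(net)
        assert len(axes) == 6
        assert [a.key for a in axes] == sorted(a.key for a in axes)

    def test_empty_network_yields_no_axes(self):
        assert enumerate_axes(DiseaseNetwork()) == []

    def test_direction_mismatch_between_lnc_and_mrna_excluded(self):
        net = _net(
            [("L1", "mi1")],
            [("mi1", "M1")],
            {"L1": "up", "mi1": "down", "M1": "down"},
        )
        assert enumerate_axes(net) == []

    def test_count_equals_degree_product_formula_on_random_networks(self):
        for seed in range(20):
            net = random_disease_network(np.random.default_rng(300 + seed))
            axes = enumerate_axes(net)
            d = {n: nd.direction for n, nd in net.nodes.items()}
            expected = 0
            for mi in net.mirnas():
                lncs = [a for a, b in net.lnc_mi if b == mi]
                ms = [c for b, c in net.mi_m if b == mi]
                expected += sum(
                    1 for a in lncs for c in ms if d[a] == d[c]
                )
            assert len(axes) == expected


class TestScoreAxes:
    def _axis(self, lnc="L1", mi="mi1", m="M1", **kw):
        defaults = dict(lnc_support=0, m_support=0, lnc_log2fc=0.0,
                        mi_log2fc=0.0, m_log2fc=0.0)
        defaults.update(kw)
        return CeRNAAxis(lncrna=lnc, mirna=mi, mrna=m, **defaults)

    def test_zero_evidence_scores_zero(self):
        scored = score_axes([self._axis()])
        assert scored[0].score == 0.0

    def test_monotone_in_risk_snps(self):
        a = self._axis(lnc="L1", n_risk_snps_lnc=0, n_risk_snps_m=0)
        b = self._axis(lnc="L2", n_risk_snps_lnc=3, n_risk_snps_m=1)
        scored = score_axes([a, b])
        assert scored[0].lncrna == "L2"

    def test_negative_weight_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            score_axes([self._axis()], weights=(1, -1, 1, 1))

    def test_fold_change_capped(self):
        a = self._axis(lnc_log2fc=50.0, mi_log2fc=-50.0, m_log2fc=50.0)
        assert score_axes([a], weights=(1, 0, 0, 0))[0].score == pytest.approx(10.0)

    def test_ranking_matches_formula_oracle(self):
        rng = np.random.default_rng(77)
        axes = []
        for i in range(50):
            axes.append(
                self._axis(
                    lnc=f"L{i}", mi=f"mi{i}", m=f"M{i}",
                    lnc_support=int(rng.integers(1, 4)),
                    m_support=int(rng.integers(1, 4)),
                    lnc_log2fc=float(rng.normal(0, 6)),
                    mi_log2fc=float(rng.normal(0, 6)),
                    m_log2fc=float(rng.normal(0, 6)),
                    lnc_mi_rho=float(rng.uniform(-1, 0)),
                    mi_m_rho=float(rng.uniform(-1, 0)),
                    n_risk_snps_lnc=int(rng.integers(0, 5)),
                    n_risk_snps_m=int(rng.integers(0, 5)),
                )
            )
        w = (0.5, 1.5, 2.0, 3.0)
        scored = score_axes(axes, weights=w, cap=10.0)

        def oracle(ax):
            fc = np.mean([min(abs(ax.lnc_log2fc), 10), min(abs(ax.mi_log2fc), 10),
                          min(abs(ax.m_log2fc), 10)])
            rho = np.mean([abs(ax.lnc_mi_rho), abs(ax.mi_m_rho)])
            return (w[0] * fc + w[1] * (ax.lnc_support + ax.m_support)
                    + w[2] * (ax.n_risk_snps_lnc + ax.n_risk_snps_m) + w[3] * rho)

        expected = sorted(axes, key=lambda ax: (-oracle(ax), ax.key))
        assert [a.key for a in scored] == [a.key for a in expected]
        for got in scored:
            orig = next(a for a in axes if a.key == got.key)
            assert got.score == pytest.approx(oracle(orig))


class TestRelabelingCommutes:
    def test_filters_commute_with_node_relabeling(self):
        rng = np.random.default_rng(13)
        net = random_disease_network(rng)
        mapping = {n: f"x_{n}" for n in net.nodes}

        def relabel(d):
            out = DiseaseNetwork(
                lnc_mi={(mapping[a], mapping[b]): set(s) for (a, b), s in d.lnc_mi.items()},
                mi_m={(mapping[a], mapping[b]): set(s) for (a, b), s in d.mi_m.items()},
                nodes={mapping[n]: nd for n, nd in d.nodes.items()},
            )
            return out

        for f in (direction_filter, prune_mirnas):
            a = relabel(f(net))
            b = f(relabel(net))
            assert a.lnc_mi == b.lnc_mi and a.mi_m == b.mi_m
            assert a.nodes == b.nodes
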