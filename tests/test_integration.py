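import math

import numpy as np
import pytest

import glucoshift as gs
from glucoshift.diffexpr import SummativeRecord, _classify_summative
from glucoshift.metabolome import DECRecord


def summative(ec, lfc, p, config=None):
    rec = SummativeRecord(ec, 1, lfc, p, 0, "", False)
    rec.reg_class = _classify_summative(lfc, p, config or gs.AnalysisConfig())
    return rec


def fig5_summative_calls(config):
    """Direction calls mirroring the study's pathway heatmaps:
    EMP-upper 2 of 4 down, ED mixed (1 down, 2 up, 3 absent),
    OPP 5 of 6 up, EMP-lower 3 of 4 down."""
    spec = {
        # EMP upper: GPI/FBP unchanged, FBPAL moderately down, TPI significantly down
        "5.3.1.9": (0.05, 0.9), "3.1.3.11": (0.1, 0.8),
        "4.1.2.13": (-0.4, 0.3), "5.3.1.1": (-1.2, 0.01),
        # ED: GCK moderately down, GPDH/PGCL moderately up
        "2.7.1.12": (-0.35, 0.4), "1.1.1.49": (0.3, 0.3), "3.1.1.31": (0.35, 0.2),
        # OPP: five up (significant or moderate), ribokinase unchanged
        "1.1.1.44": (0.5, 0.2), "5.1.3.1": (1.3, 0.02), "5.3.1.6": (0.4, 0.1),
        "2.2.1.1": (1.1, 0.03), "2.2.1.2": (0.6, 0.1), "2.7.1.15": (-0.1, 0.9),
        # EMP lower: GAPDH sig down, PGK/PPH moderately down, PK unchanged
        "1.2.1.12": (-1.4, 0.02), "2.7.2.3": (-0.3, 0.2),
        "4.2.1.11": (-0.5, 0.2), "2.7.1.40": (0.1, 0.7),
    }
    return {ec: summative(ec, lfc, p, config) for ec, (lfc, p) in spec.items()}


class TestBuiltinGraphs:
    def test_schema_lists_the_catalogued_ecs(self):
        g = gs.builtin_graphs()
        assert set(g["EMP_upper"].enzymes) == {"5.3.1.9", "3.1.3.11", "4.1.2.13", "5.3.1.1"}
        assert set(g["ED"].enzymes) == {"2.7.1.12", "1.1.1.49", "3.1.1.31"}
        assert set(g["ED"].absent_enzymes) == {"1.1.5.2", "4.1.2.14", "4.2.1.12"}
        assert set(g["OPP"].enzymes) == {
            "1.1.1.44", "5.1.3.1", "5.3.1.6", "2.2.1.1", "2.2.1.2", "2.7.1.15"
        }
        assert set(g["EMP_lower"].enzymes) == {"1.2.1.12", "2.7.2.3", "4.2.1.11", "2.7.1.40"}
        assert "2.4.1.242" in g["starch_biosynthesis"].enzymes

    def test_edges_reference_declared_nodes(self):
        for graph in gs.builtin_graphs().values():
            for substrate, ec, product in graph.edges:
                assert ec in graph.all_enzymes
                assert substrate in graph.compounds and product in graph.compounds


class TestCallEnzymes:
    def test_threshold_arithmetic(self, config):
        g = gs.PathwayGraph("toy", enzymes=("1.1.1.1", "2.2.2.2", "3.3.3.3"))
        recs = {
            "1.1.1.1": summative("1.1.1.1", 1.5, 0.01),  # 2^1.5 = 2.83 > 2, p < 0.05
            "2.2.2.2": summative("2.2.2.2", 0.3, 0.5),  # 1.23-fold: moderate
            "3.3.3.3": summative("3.3.3.3", 0.1, 0.9),
        }
        calls = {c.node_id: c for c in gs.call_enzymes(g, recs)}
        assert (calls["1.1.1.1"].grade, calls["1.1.1.1"].direction) == ("significant", "up")
        assert (calls["2.2.2.2"].grade, calls["2.2.2.2"].direction) == ("moderate", "up")
        assert calls["3.3.3.3"].grade == "unchanged"

    def test_absent_ec_is_missing(self):
        g = gs.PathwayGraph("toy", enzymes=("1.1.1.1",), absent_enzymes=("9.9.9.9",))
        calls = {c.node_id: c for c in gs.call_enzymes(g, {})}
        assert calls["1.1.1.1"].grade == "missing"
        assert calls["9.9.9.9"].grade == "missing"


class TestCallMetabolites:
    def test_tristate_thresholds(self, config):
        g = gs.PathwayGraph("toy", enzymes=(), compounds=("a", "b", "c"))
        decs = [
            DECRecord("a", 4.0, 0.001, "up"),  # 16-fold
            DECRecord("b", math.log2(1.25), 0.5, "unchanged"),  # 1.25-fold
        ]
        calls = {c.node_id: c for c in gs.call_metabolites(g, decs, config)}
        assert calls["a"].grade == "significant" and calls["a"].direction == "up"
        assert calls["b"].grade == "moderate" and calls["b"].direction == "up"
        assert calls["c"].grade == "missing"


class TestEvaluateAndCompareRoutes:
    def test_study_fixture_prefers_opp_at_published_p(self, config):
        graphs = gs.builtin_graphs()
        recs = fig5_summative_calls(config)
        verdicts = []
        for name in ("EMP_upper", "ED", "OPP", "EMP_lower"):
            g = graphs[name]
            verdicts.append(gs.evaluate_route(g, gs.call_enzymes(g, recs)))
        verdicts, text = gs.compare_routes(verdicts)
        by_name = {v.pathway: v for v in verdicts}
        opp = by_name["OPP"]
        assert (opp.n_enzymes, opp.m_same, opp.direction) == (6, 5, "up")
        assert opp.p_value == pytest.approx(1.74e-07, rel=0.01)
        assert opp.preferred is True
        assert sum(v.preferred for v in verdicts) == 1
        assert "preferred" in text

    def test_null_fixture_prefers_nothing(self, config):
        graphs = gs.builtin_graphs()
        recs = {ec: summative(ec, 0.0, 1.0) for g in graphs.values() for ec in g.enzymes}
        verdicts = [
            gs.evaluate_route(graphs[n], gs.call_enzymes(graphs[n], recs))
            for n in ("EMP_upper", "ED", "OPP", "EMP_lower")
        ]
        verdicts, _ = gs.compare_routes(verdicts)
        assert all(v.p_value == 1.0 and not v.preferred for v in verdicts)

    def test_all_up_four_of_four(self, config):
        g = gs.PathwayGraph("toy", enzymes=("1.1.1.1", "2.2.2.2", "3.3.3.3", "4.4.4.4"))
        recs = {ec: summative(ec, 2.0, 0.01) for ec in g.enzymes}
        v = gs.evaluate_route(g, gs.call_enzymes(g, recs))
        assert (v.n_enzymes, v.m_same) == (4, 4)
        assert v.p_value == pytest.approx(1.5e-05, rel=0.02)

    def test_no_data_route_warns_with_p_one(self):
        g = gs.PathwayGraph("toy", enzymes=("1.1.1.1",))
        v = gs.evaluate_route(g, gs.call_enzymes(g, {}))
        assert v.p_value == 1.0 and v.warning

    def test_invariant_to_node_ordering(self, config):
        graphs = gs.builtin_graphs()
        recs = fig5_summative_calls(config)
        g = graphs["OPP"]
        shuffled = gs.PathwayGraph(g.name, tuple(reversed(g.enzymes)), g.absent_enzymes,
                                   g.compounds, g.edges)
        v1 = gs.evaluate_route(g, gs.call_enzymes(g, recs))
        v2 = gs.evaluate_route(shuffled, gs.call_enzymes(shuffled, recs))
        assert (v1.n_enzymes, v1.m_same, v1.p_value) == (v2.n_enzymes, v2.m_same, v2.p_value)

    def test_metabolite_support_and_conflict_partition(self, config):
        graphs = gs.builtin_graphs()
        recs = fig5_summative_calls(config)
        decs = [
            DECRecord("xylulose-5-phosphate", 1.0, 0.2, "unchanged"),  # moderate up
            DECRecord("fructose-6-phosphate", 0.5, 0.3, "unchanged"),  # moderate up
            DECRecord("ribose-5-phosphate", -0.6, 0.3, "unchanged"),  # moderate down
        ]
        g = graphs["OPP"]
        v = gs.evaluate_route(g, gs.call_enzymes(g, recs), gs.call_metabolites(g, decs, config))
        assert "xylulose-5-phosphate" in v.supporting_metabolites
        assert "fructose-6-phosphate" in v.supporting_metabolites
        assert v.conflicting_metabolites == ["ribose-5-phosphate"]

    def test_tie_breaks_deterministically_by_name(self, config):
        g1 = gs.PathwayGraph("alpha", enzymes=("1.1.1.1", "2.2.2.2", "5.5.5.5"))
        g2 = gs.PathwayGraph("beta", enzymes=("3.3.3.3", "4.4.4.4", "6.6.6.6"))
        recs = {ec: summative(ec, 2.0, 0.01) for ec in (*g1.enzymes, *g2.enzymes)}
        v = [gs.evaluate_route(g, gs.call_enzymes(g, recs)) for g in (g2, g1)]
        v, _ = gs.compare_routes(v)
        preferred = [x.pathway for x in v if x.preferred]
        assert preferred == ["alpha"]

    def test_consistency_matches_enumeration_for_all_small_n(self):
        # evaluate_route p-values come from the same exact tail as the oracle
        from fractions import Fraction
        from math import comb

        for n in range(1, 13):
            for m in range(1, n + 1):
                p = gs.pathway_consistency(n, m).p_value
                pr = Fraction(1, 2**m)
                want = float(
                    sum(comb(n, j) * pr**j * (1 - pr) ** (n - j) for j in range(m, n + 1))
                )
                assert p == pytest.approx(want, rel=1e-12)


class TestGsrFunctionReport:
    def test_direction_counts_and_consistency(self):
        records = (
            [gs.GSRRecord(f"g{i}", 1, -1, 2.0, "positive_gsr", 2.0) for i in range(6)]
            + [gs.GSRRecord(f"g{i}", -1, 1, -2.0, "negative_gsr", 2.0) for i in range(6, 8)]
            + [gs.GSRRecord(f"g{i}", 1, -1, 1.0, "positive_gsr", 1.0) for i in range(8, 12)]
        )
        pmap = gs.PathwayMap()
        pmap.add("p00910", "Nitrogen metabolism", [f"g{i}" for i in range(8)])
        pmap.add("p00730", "Thiamine metabolism", [f"g{i}" for i in range(8, 12)])
        reports = {r.pathway_id: r for r in gs.gsr_function_report(records, pmap, 9277)}
        nitrogen = reports["p00910"]
        assert (nitrogen.n_gsr, nitrogen.m_same, nitrogen.direction) == (8, 6, "up")
        assert nitrogen.p_value == pytest.approx(3.9e-10, rel=0.02)
        thiamine = reports["p00730"]
        assert (thiamine.n_gsr, thiamine.m_same) == (4, 4)
        assert thiamine.p_value == pytest.approx(1.5e-05, rel=0.02)

    def test_single_gene_pathway(self):
        records = [gs.GSRRecord("g1", 1, -1, 2.0, "positive_gsr", 2.0)]
        pmap = gs.PathwayMap()
        pmap.add("pX", "toy", ["g1"])
        r = gs.gsr_function_report(records, pmap, 100)[0]
        assert r.p_value == pytest.approx(0.5)

    def test_pipeline_prefers_opp_when_planted(self, config):
        """Counts -> summative -> calls -> verdicts on a constructed matrix in
        which every OPP enzyme is planted up and every EMP-upper enzyme down."""
        import pandas as pd

        graphs = gs.builtin_graphs()
        opp, emp = graphs["OPP"], graphs["EMP_upper"]
        rng = np.random.default_rng(21)
        ecs = list(opp.enzymes) + list(emp.enzymes)
        n_bg = 200
        gene_ids = [f"enz{i}" for i in range(len(ecs))] + [f"bg{i}" for i in range(n_bg)]
        base = rng.uniform(80, 300, len(gene_ids))
        fold = np.ones(len(gene_ids))
        fold[: len(opp.enzymes)] = 8.0  # OPP up in HH
        fold[len(opp.enzymes) : len(ecs)] = 1 / 8.0  # EMP upper down
        counts = np.empty((len(gene_ids), 6), dtype=np.int64)
        for j in range(3):
            counts[:, j] = rng.poisson(base)
        for j in range(3, 6):
            counts[:, j] = rng.poisson(base * fold)
        sample_ids = [f"LL_{i}" for i in (1, 2, 3)] + [f"HH_{i}" for i in (1, 2, 3)]
        meta = pd.DataFrame(
            {"condition": ["LL"] * 3 + ["HH"] * 3, "replicate": [1, 2, 3] * 2},
            index=sample_ids,
        )
        matrix = gs.CountMatrix(
            counts=pd.DataFrame(counts, index=gene_ids, columns=sample_ids),
            sample_meta=meta,
        )
        ann = pd.DataFrame(index=pd.Index(gene_ids, name="gene_id"))
        ann["product"] = ""
        ann["ec_numbers"] = [[ec] for ec in ecs] + [[] for _ in range(n_bg)]
        ann["pathway_ids"] = [[] for _ in gene_ids]
        ann["isoform_group"] = [None] * len(gene_ids)
        annotation = gs.GeneAnnotationTable(ann)
        summ = gs.summative_call(matrix, annotation, "ec", ("LL", "HH"), config)
        by_ec = {r.group_id: r for r in summ}
        verdicts = [
            gs.evaluate_route(g, gs.call_enzymes(g, by_ec)) for g in (opp, emp)
        ]
        verdicts, _ = gs.compare_routes(verdicts)
        assert [v.pathway for v in verdicts if v.preferred] == ["OPP"]
        opp_v = next(v for v in verdicts if v.pathway == "OPP")
        assert opp_v.m_same == 6 and opp_v.direction == "up"
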