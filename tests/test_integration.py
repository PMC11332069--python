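import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from chiralome.config import AnalysisConfig
from chiralome.integration import (
    CorrelationEdge,
    coefficient_of_variation,
    correlate,
    cv_filter,
    de_gene_filter,
    fisher_combine,
    hypergeometric_enrichment,
    joint_pathway_analysis,
    overlap_with_pathway_genes,
    topology_impact,
)
from chiralome.io_formats import ExpressionMatrix, PathwayDefinition
from tests.oracles import chi2_sf_even_df, hypergeom_enumeration, pearson_loop


def expr_from(rows: dict[str, list[float]]) -> ExpressionMatrix:
    frame = pd.DataFrame(rows).T
    frame.columns = [f"s{i+1}" for i in range(frame.shape[1])]
    frame.index.name = "gene"
    return ExpressionMatrix(tpm=frame)


class TestCVFilter:
    def test_constant_gene_excluded(self, config):
        expr = expr_from({"G1": [5.0, 5.0, 5.0]})
        assert cv_filter(expr, config) == []

    def test_hand_computed_exclusion(self, config):
        # sd = 0.4472, mean = 1.2 -> CV = 0.3727 > 0.25
        expr = expr_from({"G1": [1, 1, 1, 1, 2]})
        cv = coefficient_of_variation(expr)["G1"]
        assert cv == pytest.approx(0.447213595 / 1.2, rel=1e-6)
        assert cv_filter(expr, config) == []

    def test_hand_computed_retention(self, config):
        # sd = 0.35355, mean = 10 -> CV = 0.035355 in (0, 0.25)
        expr = expr_from({"G1": [10, 10.5, 9.5, 10, 10]})
        cv = coefficient_of_variation(expr)["G1"]
        assert cv == pytest.approx(0.0353553, rel=1e-5)
        assert cv_filter(expr, config) == ["G1"]

    def test_zero_mean_excluded(self, config):
        expr = expr_from({"G1": [0.0, 0.0, 0.0]})
        assert cv_filter(expr, config) == []

    def test_single_sample_raises(self, config):
        expr = expr_from({"G1": [1.0]})
        with pytest.raises(ValueError):
            cv_filter(expr, config)


class TestDEGeneFilter:
    def test_strict_threshold(self, config):
        assert de_gene_filter({"A": 1.6, "B": 1.5}, config) == ["A"]

    def test_reciprocal_in_absolute_mode(self, config):
        assert de_gene_filter({"A": 0.5}, config) == ["A"]

    def test_signed_mode(self):
        config = AnalysisConfig(gene_fc_absolute=False)
        assert de_gene_filter({"A": 0.5, "B": 2.0}, config) == ["B"]

    @pytest.mark.parametrize("seed", range(5))
    def test_loop_oracle(self, seed, config):
        rng = np.random.default_rng(seed)
        fc = {f"G{i}": v for i, v in enumerate(rng.lognormal(0, 0.7, 50))}
        got = set(de_gene_filter(fc, config))
        expected = {g for g, v in fc.items() if v > 1.5 or v < 1 / 1.5}
        assert got == expected


class TestCorrelate:
    def test_perfect_linearity(self, config):
        met = pd.DataFrame([[1.0, 2.0, 3.0, 4.0, 5.0]], index=["m"],
                           columns=[f"s{i+1}" for i in range(5)])
        expr = expr_from({"G1": [3.0, 5.0, 7.0, 9.0, 11.0]})  # 2*m + 1
        (edge,) = correlate(expr, met, config)
        assert edge.r == pytest.approx(1.0)
        assert edge.n == 5

    def test_negative_correlation_no_edge(self, config):
        met = pd.DataFrame([[1.0, 2.0, 3.0]], index=["m"], columns=["s1", "s2", "s3"])
        expr = expr_from({"G1": [3.0, 2.0, 1.0]})
        assert correlate(expr, met, config) == []

    def test_zero_variance_skipped(self, config):
        met = pd.DataFrame([[1.0, 2.0, 3.0]], index=["m"], columns=["s1", "s2", "s3"])
        expr = expr_from({"G1": [4.0, 4.0, 4.0]})
        assert correlate(expr, met, config) == []

    def test_loop_oracle_50x3(self, config):
        rng = np.random.default_rng(7)
        genes = {f"G{i}": list(rng.lognormal(3, 1, 5)) for i in range(50)}
        expr = expr_from(genes)
        met = pd.DataFrame(
            rng.lognormal(3, 1, (3, 5)),
            index=["m1", "m2", "m3"],
            columns=expr.tpm.columns,
        )
        loose = AnalysisConfig(r_min=-1.0)  # emit every edge for comparison
        edges = {(e.gene, e.metabolite): e.r for e in correlate(expr, met, loose)}
        for g, vals in genes.items():
            for m in met.index:
                expected = pearson_loop(vals, list(met.loc[m]))
                assert edges[(g, m)] == pytest.approx(expected, abs=1e-12)

    def test_sample_order_enforced(self, config):
        met = pd.DataFrame([[1.0, 2.0, 3.0]], index=["m"], columns=["s3", "s1", "s2"])
        expr = expr_from({"G1": [2.0, 3.0, 1.0]})  # on s1,s2,s3: r=1 vs met order
        (edge,) = correlate(expr, met, config)
        assert edge.r == pytest.approx(1.0)

    def test_joint_sample_permutation_invariant(self, config):
        rng = np.random.default_rng(8)
        samples = [f"s{i+1}" for i in range(5)]
        expr = expr_from({"G1": list(rng.lognormal(3, 1, 5))})
        met = pd.DataFrame([rng.lognormal(3, 1, 5)], index=["m"], columns=samples)
        loose = AnalysisConfig(r_min=-1.0)
        (e1,) = correlate(expr, met, loose)
        perm = ["s4", "s2", "s5", "s1", "s3"]
        (e2,) = correlate(
            ExpressionMatrix(tpm=expr.tpm[perm]), met[perm], loose
        )
        assert e1.r == pytest.approx(e2.r, rel=1e-12)

    def test_too_few_samples_raises(self, config):
        met = pd.DataFrame([[1.0, 2.0]], index=["m"], columns=["s1", "s2"])
        expr = expr_from({"G1": [1.0, 2.0]})
        with pytest.raises(ValueError):
            correlate(expr, met, config)


class TestOverlap:
    def pathway(self, pid, genes):
        return PathwayDefinition(pathway_id=pid, name=pid, gene_members=frozenset(genes))

    def test_intersection(self):
        edges = [CorrelationEdge("G1", "m", 0.9, 5), CorrelationEdge("G2", "m", 0.8, 5)]
        frame = overlap_with_pathway_genes(edges, [self.pathway("P1", {"G2", "G3"})])
        assert list(frame["gene"]) == ["G2"]
        assert list(frame["pathways"]) == ["P1"]

    def test_disjoint_empty(self):
        edges = [CorrelationEdge("G1", "m", 0.9, 5)]
        frame = overlap_with_pathway_genes(edges, [self.pathway("P1", {"G9"})])
        assert frame.empty

    def test_planted_overlap_recovered(self):
        planted = {f"G{i}" for i in range(5)}
        edges = [CorrelationEdge(g, "m", 0.9, 5) for g in planted | {"X1", "X2"}]
        pathways = [self.pathway("P1", planted | {"Y1"}), self.pathway("P2", {"Y2"})]
        frame = overlap_with_pathway_genes(edges, pathways)
        assert set(frame["gene"]) == planted


class TestHypergeometric:
    def test_hand_combinatorics(self):
        universe = [f"u{i}" for i in range(10)]
        members = universe[:5]
        query = universe[:5]
        # C(5,5)*C(5,0)/C(10,5) = 1/252
        assert hypergeometric_enrichment(query, members, universe) == pytest.approx(
            1 / 252
        )

    def test_empty_query_vacuous(self):
        universe = [f"u{i}" for i in range(10)]
        assert hypergeometric_enrichment([], universe[:5], universe) == 1.0

    @pytest.mark.parametrize(
        "n_u,n_m,n_q", [(10, 4, 3), (12, 6, 5), (15, 5, 7), (8, 8, 3)]
    )
    def test_enumeration_oracle(self, n_u, n_m, n_q):
        universe = [f"u{i}" for i in range(n_u)]
        members = universe[:n_m]
        for k in range(0, min(n_m, n_q) + 1):
            if n_q - k > n_u - n_m:
                continue  # not enough non-members to fill the query
            query = members[:k] + universe[n_m:][: n_q - k]
            p = hypergeometric_enrichment(query, members, universe)
            assert p == pytest.approx(
                hypergeom_enumeration(n_u, n_m, n_q, k), rel=1e-10
            )

    def test_monotone_in_overlap(self):
        universe = [f"u{i}" for i in range(12)]
        members = universe[:6]
        last = 1.1
        for k in range(0, 6):
            query = members[:k] + universe[6:][: 5 - k]
            p = hypergeometric_enrichment(query, members, universe)
            assert p <= last
            last = p

    def test_member_outside_universe_raises(self):
        with pytest.raises(ValueError, match="outside universe"):
            hypergeometric_enrichment(["a"], ["a", "z"], ["a", "b"])


class TestFisherCombine:
    def test_all_ones(self):
        assert fisher_combine([1.0, 1.0]) == pytest.approx(1.0)

    def test_single_p_identity(self):
        for p in (0.01, 0.2, 0.7):
            assert fisher_combine([p]) == pytest.approx(p, rel=1e-10)

    def test_two_times_005_chi2_oracle(self):
        x = -2 * (math.log(0.05) + math.log(0.05))
        expected = chi2_sf_even_df(x, 4)
        got = fisher_combine([0.05, 0.05])
        assert got == pytest.approx(expected, rel=1e-10)
        assert got == pytest.approx(0.0175, abs=2e-4)

    @settings(max_examples=50)
    @given(
        ps=st.lists(st.floats(min_value=1e-6, max_value=1.0), min_size=1, max_size=6)
    )
    def test_permutation_invariant_and_oracle(self, ps):
        p1 = fisher_combine(ps)
        p2 = fisher_combine(list(reversed(ps)))
        assert p1 == pytest.approx(p2, rel=1e-12)
        x = -2 * sum(math.log(p) for p in ps)
        assert p1 == pytest.approx(chi2_sf_even_df(x, 2 * len(ps)), rel=1e-9)

    def test_nonpositive_raises(self):
        with pytest.raises(ValueError):
            fisher_combine([0.0, 0.5])


class TestTopologyImpact:
    def star(self):
        members = {"c", "l1", "l2", "l3", "l4"}
        edges = tuple(("c", leaf) for leaf in sorted(members - {"c"}))
        return PathwayDefinition(
            pathway_id="P", name="star", gene_members=frozenset(members), topology=edges
        )

    def test_all_hit_is_one(self):
        pw = self.star()
        assert topology_impact(pw, pw.members) == pytest.approx(1.0)

    def test_no_hit_is_zero(self):
        assert topology_impact(self.star(), set()) == 0.0

    def test_star_center_half(self):
        # center degree 4 over total degree 8
        assert topology_impact(self.star(), {"c"}) == pytest.approx(0.5)

    def test_no_topology_falls_back_to_fraction(self):
        pw = PathwayDefinition(
            pathway_id="P", name="flat", gene_members=frozenset({"a", "b", "c", "d"})
        )
        assert topology_impact(pw, {"a"}) == pytest.approx(0.25)

    def test_hit_outside_members_raises(self):
        with pytest.raises(ValueError):
            topology_impact(self.star(), {"zzz"})


class TestJointPathwayAnalysis:
    def universes(self):
        genes = [f"G{i}" for i in range(20)]
        cpds = [f"C{i}" for i in range(10)]
        return genes, cpds

    def test_gene_only_pathway_excluded_from_report(self, config):
        genes, cpds = self.universes()
        pw = PathwayDefinition(
            pathway_id="P1", name="genes only", gene_members=frozenset(genes[:5])
        )
        (res,) = joint_pathway_analysis(genes[:5], cpds[:3], [pw], genes, cpds, config)
        assert math.isnan(res.p_cmpd)
        assert res.hits_cmpd == 0
        assert not res.reported

    def test_fully_covered_pathway_smallest_p(self, config):
        genes, cpds = self.universes()
        covered = PathwayDefinition(
            pathway_id="P1", name="covered",
            gene_members=frozenset(genes[:4]), compound_members=frozenset(cpds[:2]),
        )
        uncovered = PathwayDefinition(
            pathway_id="P2", name="uncovered",
            gene_members=frozenset(genes[10:14]), compound_members=frozenset(cpds[5:7]),
        )
        res = joint_pathway_analysis(
            genes[:4], cpds[:2], [covered, uncovered], genes, cpds, config
        )
        by_id = {r.pathway_id: r for r in res}
        assert by_id["P1"].p_combined < by_id["P2"].p_combined

    def test_matches_stepwise_oracle(self, config):
        genes, cpds = self.universes()
        rng = np.random.default_rng(0)
        pathways = []
        for p in range(5):
            g = frozenset(rng.choice(genes, size=6, replace=False))
            c = frozenset(rng.choice(cpds, size=3, replace=False))
            edges = tuple(
                (a, b)
                for i, a in enumerate(sorted(g | c))
                for b in sorted(g | c)[i + 1:]
                if rng.random() < 0.4
            )
            pathways.append(
                PathwayDefinition(
                    pathway_id=f"P{p}", name=f"p{p}",
                    gene_members=g, compound_members=c, topology=edges,
                )
            )
        gene_query = set(rng.choice(genes, size=8, replace=False))
        cmpd_query = set(rng.choice(cpds, size=4, replace=False))
        results = joint_pathway_analysis(
            gene_query, cmpd_query, pathways, genes, cpds, config
        )
        for res, pw in zip(results, pathways):
            p_gene = hypergeometric_enrichment(gene_query, pw.gene_members, genes)
            p_cmpd = hypergeometric_enrichment(cmpd_query, pw.compound_members, cpds)
            expected_combined = fisher_combine([p_gene, p_cmpd])
            hits = (gene_query & pw.gene_members) | (cmpd_query & pw.compound_members)
            assert res.p_combined == pytest.approx(expected_combined, rel=1e-12)
            assert res.impact == pytest.approx(topology_impact(pw, hits), rel=1e-12)
            assert res.hits_gene == len(gene_query & pw.gene_members)
            assert res.hits_cmpd == len(cmpd_query & pw.compound_members)

    def test_reported_filter_thresholds(self):
        genes, cpds = self.universes()
        pw = PathwayDefinition(
            pathway_id="P1", name="x",
            gene_members=frozenset(genes[:4]), compound_members=frozenset(cpds[:2]),
        )
        config = AnalysisConfig()
        (res,) = joint_pathway_analysis(genes[:4], cpds[:2], [pw], genes, cpds, config)
        assert res.reported  # fully covered: tiny p, impact 1.0
        strict = AnalysisConfig(p_combined_max=1e-12)
        (res2,) = joint_pathway_analysis(genes[:4], cpds[:2], [pw], genes, cpds, strict)
        assert not res2.reported
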