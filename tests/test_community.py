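"""Community metrics: taxon grouping, MW-scores, contributions, networks, flows."""

import itertools

import numpy as np
import pandas as pd
import pytest

from cycleprofiler import (
    CommunityProfile,
    ConfigError,
    assign_taxon_group,
    build_functional_network,
    contribution_percentages,
    mw_scores,
    sankey_flows,
    sequential_profile,
)
from tests.conftest import make_community

GAMMA = ("d__Bacteria;p__Proteobacteria;c__Gammaproteobacteria;o__Xanthomonadales;"
         "f__Xanthomonadaceae;g__Lysobacter;s__")
NITRO = "d__Bacteria;p__Nitrospirota;c__Nitrospiria;o__Nitrospirales;f__Nitrospiraceae;g__Nitrospira;s__"


class TestAssignTaxonGroup:
    def test_proteobacteria_replaced_by_class_at_phylum_rank(self):
        assert assign_taxon_group(GAMMA, "phylum") == "Gammaproteobacteria"

    def test_other_phyla_read_directly(self):
        assert assign_taxon_group(NITRO, "phylum") == "Nitrospirota"

    def test_substitution_only_at_phylum_rank(self):
        assert assign_taxon_group(GAMMA, "order") == "Xanthomonadales"

    def test_unnamed_rank_falls_back_to_deepest_named(self):
        lineage = "d__Bacteria;p__Nitrospirota;c__Nitrospiria;o__;f__;g__;s__"
        assert assign_taxon_group(lineage, "genus") == "Unclassified_Nitrospiria"

    @pytest.mark.parametrize("bad", ["", "not a lineage", "p__Firmicutes;d__Bacteria"])
    def test_unparseable_lineage(self, bad):
        with pytest.raises(ConfigError):
            assign_taxon_group(bad, "phylum")


def two_genome_profile():
    presence = pd.DataFrame([[1, 0], [1, 1]], index=["g1", "g2"], columns=["f1", "f2"])
    coverage = pd.Series({"g1": 10.0, "g2": 30.0})
    groups = pd.Series({"g1": "p1", "g2": "p2"})
    return CommunityProfile(presence=presence, coverage=coverage, groups=groups)


class TestMwScores:
    def test_hand_example(self):
        mw = mw_scores(two_genome_profile())
        assert mw["f1"] == pytest.approx(4 / 7, abs=1e-12)
        assert mw["f2"] == pytest.approx(3 / 7, abs=1e-12)

    def test_single_genome_single_function(self):
        profile = CommunityProfile(
            presence=pd.DataFrame([[1]], index=["g1"], columns=["f1"]),
            coverage=pd.Series({"g1": 5.0}), groups=pd.Series({"g1": "p1"}))
        assert mw_scores(profile)["f1"] == 1.0

    def test_uniform_scaling_invariance(self):
        p = two_genome_profile()
        scaled = CommunityProfile(presence=p.presence, coverage=p.coverage * 13.7,
                                  groups=p.groups)
        pd.testing.assert_series_equal(mw_scores(p), mw_scores(scaled))

    def test_zero_denominator_is_error(self):
        profile = CommunityProfile(
            presence=pd.DataFrame([[0]], index=["g1"], columns=["f1"]),
            coverage=pd.Series({"g1": 5.0}), groups=pd.Series({"g1": "p1"}))
        with pytest.raises(ConfigError):
            mw_scores(profile)

    def test_genome_relabeling_equivariance(self, rng):
        presence, coverage, groups = make_community(rng, 8, 5)
        p = CommunityProfile(presence=presence, coverage=coverage, groups=groups)
        perm = rng.permutation(presence.index.tolist()).tolist()
        q = CommunityProfile(presence=presence.loc[perm], coverage=coverage.loc[perm],
                             groups=groups.loc[perm])
        pd.testing.assert_series_equal(mw_scores(p), mw_scores(q))


class TestContributionPercentages:
    def test_hand_example(self):
        cperc = contribution_percentages(two_genome_profile())
        assert cperc.at["f1", "p1"] == pytest.approx(25.0, abs=1e-12)
        assert cperc.at["f1", "p2"] == pytest.approx(75.0, abs=1e-12)
        assert cperc.at["f2", "p2"] == pytest.approx(100.0, abs=1e-12)

    def test_single_group_gets_everything(self, rng):
        presence, coverage, _ = make_community(rng, 6, 4)
        groups = pd.Series("only", index=presence.index)
        p = CommunityProfile(presence=presence, coverage=coverage, groups=groups)
        cperc = contribution_percentages(p)
        for f in p.functions:
            if presence[f].sum() > 0:
                assert cperc.at[f, "only"] == pytest.approx(100.0, abs=1e-12)

    def test_rows_sum_to_100_unrounded(self, rng):
        for _ in range(30):
            presence, coverage, groups = make_community(
                rng, int(rng.integers(2, 15)), int(rng.integers(1, 12)))
            p = CommunityProfile(presence=presence, coverage=coverage, groups=groups)
            cperc = contribution_percentages(p)
            for f in p.functions:
                if presence[f].sum() > 0:
                    assert cperc.loc[f].sum() == pytest.approx(100.0, abs=1e-9)
                else:
                    assert cperc.loc[f].isna().all()


def naive_mw_cperc(presence, coverage, groups):
    """Independent double-loop evaluation of the two score definitions."""
    total = 0.0
    for g in presence.index:
        for f in presence.columns:
            total += coverage[g] * presence.at[g, f]
    mw = {}
    for f in presence.columns:
        mw[f] = sum(coverage[g] * presence.at[g, f] for g in presence.index) / total
    cperc = {}
    for f in presence.columns:
        denom = sum(coverage[g] * presence.at[g, f] for g in presence.index)
        if denom > 0:
            for p in sorted(groups.unique()):
                num = sum(coverage[g] * presence.at[g, f]
                          for g in presence.index if groups[g] == p)
                cperc[(f, p)] = 100.0 * num / denom
    return mw, cperc


class TestOracleEquivalence:
    def test_matches_double_loop_on_random_communities(self, rng):
        for _ in range(60):
            presence, coverage, groups = make_community(
                rng, int(rng.integers(1, 15)), int(rng.integers(1, 12)))
            p = CommunityProfile(presence=presence, coverage=coverage, groups=groups)
            mw = mw_scores(p)
            cperc = contribution_percentages(p)
            ref_mw, ref_cperc = naive_mw_cperc(presence, coverage, groups)
            assert mw.sum() == pytest.approx(1.0, abs=1e-12)
            for f in presence.columns:
                assert mw[f] == pytest.approx(ref_mw[f], abs=1e-12)
            for (f, g), v in ref_cperc.items():
                assert cperc.at[f, g] == pytest.approx(v, abs=1e-12)


class TestFunctionalNetwork:
    def test_single_step_genome_contributes_no_edges(self):
        sp = pd.DataFrame([[1, 0]], index=["g1"], columns=["a", "b"])
        cov = pd.DataFrame([[10.0, 0.0]], index=["g1"], columns=["a", "b"])
        edges, graph = build_functional_network(sp, pd.Series({"g1": "p1"}), cov)
        assert edges == [] and graph.number_of_edges() == 0

    def test_edge_weight_is_mean_of_step_coverages(self):
        sp = pd.DataFrame([[1, 1]], index=["g1"], columns=["a", "b"])
        cov = pd.DataFrame([[10.0, 20.0]], index=["g1"], columns=["a", "b"])
        (edge,), _ = build_functional_network(sp, pd.Series({"g1": "p1"}), cov)
        assert edge.weight == 15.0 and edge.n_genomes == 1

    def test_one_edge_per_group_pair_with_genome_count(self):
        sp = pd.DataFrame([[1, 1], [1, 1]], index=["g1", "g2"], columns=["a", "b"])
        cov = pd.DataFrame([[10.0, 20.0], [5.0, 5.0]], index=["g1", "g2"],
                           columns=["a", "b"])
        groups = pd.Series({"g1": "p1", "g2": "p1"})
        edges, _ = build_functional_network(sp, groups, cov)
        assert len(edges) == 1
        assert edges[0].n_genomes == 2
        assert edges[0].weight == pytest.approx((15.0 + 25.0) / 2)

    def test_edge_count_matches_brute_force(self, rng):
        for _ in range(20):
            n, k = int(rng.integers(2, 10)), int(rng.integers(2, 6))
            sp = pd.DataFrame(rng.integers(0, 2, size=(n, k)),
                              index=[f"g{i}" for i in range(n)],
                              columns=[f"s{j}" for j in range(k)])
            cov = pd.DataFrame(rng.uniform(0, 10, size=(n, k)),
                               index=sp.index, columns=sp.columns)
            groups = pd.Series([f"p{int(x)}" for x in rng.integers(0, 3, size=n)],
                               index=sp.index)
            edges, graph = build_functional_network(sp, groups, cov)
            expected = 0
            for p in groups.unique():
                members = sp.loc[groups == p]
                for a, b in itertools.combinations(sp.columns, 2):
                    if ((members[a] == 1) & (members[b] == 1)).any():
                        expected += 1
            assert len(edges) == expected == graph.number_of_edges()
            for node, deg in graph.degree():
                assert graph.nodes[node]["degree"] == deg


class TestSankeyFlows:
    cycle_map = {"f1": "Nitrogen", "f2": "Sulfur"}

    def test_group_flow_accumulates_coverage(self):
        flows, sizes = sankey_flows(two_genome_profile(), self.cycle_map)
        by = {(f.source, f.target): f.weight for f in flows}
        assert by[("p2", "f1")] == 30.0 and by[("p1", "f1")] == 10.0
        assert by[("p2", "f2")] == 30.0
        assert sizes["p1"] == 1 and sizes["p2"] == 1

    def test_conservation_function_to_cycle(self):
        flows, _ = sankey_flows(two_genome_profile(), self.cycle_map)
        incoming = sum(f.weight for f in flows if f.target == "f1")
        out = [f.weight for f in flows if f.source == "f1"]
        assert out == [pytest.approx(incoming)]

    def test_absent_function_has_no_flows(self):
        p = two_genome_profile()
        p.presence["f3"] = 0
        flows, _ = sankey_flows(p, dict(self.cycle_map))
        assert not any(f.source == "f3" or f.target == "f3" for f in flows)

    def test_unmapped_function_is_error(self):
        with pytest.raises(ConfigError, match="f2"):
            sankey_flows(two_genome_profile(), {"f1": "Nitrogen"})


class TestSequentialProfile:
    def test_hand_example(self):
        sp = pd.DataFrame([[1, 0], [1, 1]], index=["g1", "g2"], columns=["A", "B"])
        cov = pd.Series({"g1": 10.0, "g2": 30.0})
        chain = sequential_profile("toy", ["A", "B"], sp, cov)
        assert chain.n_genomes == (2, 1)
        assert chain.abundance_pct == (100.0, 75.0)
        assert chain.pair_genomes == (1,)

    def test_absent_steps_all_zero(self):
        sp = pd.DataFrame([[0, 0]], index=["g1"], columns=["A", "B"])
        chain = sequential_profile("toy", ["A", "B"], sp, pd.Series({"g1": 4.0}))
        assert chain.n_genomes == (0, 0) and chain.abundance_pct == (0.0, 0.0)

    def test_single_genome_whole_chain(self):
        sp = pd.DataFrame([[1, 1, 1]], index=["g1"], columns=["A", "B", "C"])
        chain = sequential_profile("toy", ["A", "B", "C"], sp, pd.Series({"g1": 2.0}))
        assert chain.n_genomes == (1, 1, 1)
        assert chain.abundance_pct == (100.0, 100.0, 100.0)

    def test_unknown_step_is_error(self):
        sp = pd.DataFrame([[1]], index=["g1"], columns=["A"])
        with pytest.raises(ConfigError, match="Z"):
            sequential_profile("toy", ["A", "Z"], sp, pd.Series({"g1": 1.0}))
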