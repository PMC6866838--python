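import logging

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from richclubnet.connectome import Connectome
from richclubnet import metrics, richclub

import oracles
from conftest import make_connectome


def triangle_plus_pendant():
    # triangle {a,b,c} of weight 2 plus pendant edge a-d of weight 1
    return make_connectome(
        4, [(0, 1, 2.0), (1, 2, 2.0), (0, 2, 2.0), (0, 3, 1.0)]
    )


class TestWeightedRichClub:
    def test_club_holds_all_strongest_edges(self):
        c = triangle_plus_pendant()
        # k=1: club {a,b,c}; W=6 over top-3 weights {2,2,2} -> 1
        assert richclub.weighted_rich_club(c, 1) == pytest.approx(1.0)

    def test_undefined_when_club_too_small(self):
        c = triangle_plus_pendant()
        assert np.isnan(richclub.weighted_rich_club(c, 2))

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(17)
        checked = 0
        for _ in range(50):
            n = int(rng.integers(4, 9))
            w = oracles.random_weighted_graph(rng, n)
            c = Connectome(w)
            for k in range(0, n - 1):
                expected = oracles.brute_weighted_rich_club(w, k)
                got = richclub.weighted_rich_club(c, k)
                if np.isnan(expected):
                    assert np.isnan(got)
                else:
                    assert got == pytest.approx(expected, abs=1e-9)
                    checked += 1
        assert checked > 50

    @given(st.floats(0.1, 50.0))
    def test_invariant_under_uniform_weight_rescaling(self, factor):
        c = triangle_plus_pendant()
        scaled = Connectome(c.weights * factor)
        for k in (0, 1):
            assert richclub.weighted_rich_club(scaled, k) == pytest.approx(
                richclub.weighted_rich_club(c, k)
            )


class TestNormalizedRichClub:
    def test_erdos_renyi_is_near_one(self):
        rng = np.random.default_rng(30)
        w = oracles.random_weighted_graph(rng, 30, p=0.3)
        c = Connectome(w)
        ks = np.arange(1, int(np.percentile(metrics.degree(c), 70)))
        curve = richclub.normalized_rich_club(c, ks, n_null=60, seed=2)
        assert np.nanmean(curve.phi_norm) == pytest.approx(1.0, abs=0.1)

    def test_fixed_seed_reproducible(self):
        rng = np.random.default_rng(31)
        c = Connectome(oracles.random_weighted_graph(rng, 15, p=0.4))
        c1 = richclub.normalized_rich_club(c, np.array([2, 3]), n_null=5, seed=9)
        c2 = richclub.normalized_rich_club(c, np.array([2, 3]), n_null=5, seed=9)
        np.testing.assert_array_equal(c1.phi_norm, c2.phi_norm)


class TestRichNodeSelection:
    def test_recovers_planted_hubs(self, tiny_cohort):
        from richclubnet.connectome import build_connectome, threshold_edges

        conns = [
            threshold_edges(build_connectome(t, 30, 10.0), 1.0)
            for t in tiny_cohort.tables.values()
        ]
        got = richclub.select_rich_nodes_group_mean(conns, 4)
        assert set(got.tolist()) == set(tiny_cohort.template.hub_set.tolist())
        got_avg = richclub.select_rich_nodes_group_average_network(conns, 0.30, 4)
        assert set(got_avg.tolist()) == set(tiny_cohort.template.hub_set.tolist())

    def test_star_centre_selected(self):
        star = make_connectome(5, [(0, i, 1) for i in range(1, 5)])
        assert richclub.select_rich_nodes_group_mean([star], 1).tolist() == [0]

    def test_identical_subjects_schemes_agree(self):
        c = triangle_plus_pendant()
        ind = richclub.select_rich_nodes_individual(c, 0.5)
        grp = richclub.select_rich_nodes_group_mean([c, c, c], 2)
        avg = richclub.select_rich_nodes_group_average_network([c, c, c], 1.0, 2)
        assert ind.tolist() == grp.tolist() == avg.tolist()

    def test_individual_fraction_arithmetic(self):
        # 0.09 * 90 rounds to 8; 0.2 * 10 rounds to 2
        rng = np.random.default_rng(5)
        big = Connectome(oracles.random_weighted_graph(rng, 90, p=0.2))
        assert len(richclub.select_rich_nodes_individual(big, 0.09)) == 8
        small = Connectome(oracles.random_weighted_graph(rng, 10, p=0.6))
        assert len(richclub.select_rich_nodes_individual(small, 0.2)) == 2

    def test_tie_at_cut_is_deterministic_and_logged(self, caplog):
        # two leaves tied in degree: higher-strength one wins
        c = make_connectome(4, [(0, 1, 5.0), (0, 2, 1.0), (0, 3, 3.0)])
        with caplog.at_level(logging.WARNING, logger="richclubnet.richclub"):
            got = richclub.select_rich_nodes_group_mean([c], 2)
        assert got.tolist() == [0, 1]
        assert any("tie" in rec.message for rec in caplog.records)


class TestEdgeClassification:
    def test_definition(self):
        c = make_connectome(4, [(0, 1, 1), (0, 2, 1), (2, 3, 1)])
        cm = richclub.classify_edges(c, np.array([0, 1]))
        assert cm.classes[0, 1] == richclub.RICH
        assert cm.classes[0, 2] == richclub.FEEDER
        assert cm.classes[2, 3] == richclub.PERIPHERAL

    def test_empty_and_full_rich_sets(self):
        c = triangle_plus_pendant()
        all_peripheral = richclub.classify_edges(c, np.array([], dtype=int))
        iu = np.triu_indices(4, 1)
        assert np.all(all_peripheral.classes[iu] == richclub.PERIPHERAL)
        all_rich = richclub.classify_edges(c, np.arange(4))
        assert np.all(all_rich.classes[iu] == richclub.RICH)

    def test_out_of_range_errors(self):
        c = triangle_plus_pendant()
        with pytest.raises(ValueError):
            richclub.classify_edges(c, np.array([9]))

    def test_complete_graph_class_pair_counts(self):
        # n=90 with 8 rich nodes: C(8,2)=28, 8*82=656, C(82,2)=3321
        w = np.ones((90, 90))
        np.fill_diagonal(w, 0.0)
        c = Connectome(w)
        cm = richclub.classify_edges(c, np.arange(8))
        cs = richclub.class_strengths(c, cm)
        assert cs.counts == {"rich": 28, "feeder": 656, "peripheral": 3321}
        assert sum(cs.counts.values()) == 90 * 89 // 2


class TestClassStrengths:
    def test_triangle_all_rich(self):
        tri = make_connectome(3, [(0, 1, 1), (1, 2, 2), (0, 2, 3)])
        cs = richclub.class_strengths(tri, richclub.classify_edges(tri, np.arange(3)))
        assert cs.strengths == {"rich": 6.0, "feeder": 0.0, "peripheral": 0.0}

    def test_partition_conserves_totals_on_random_graphs(self):
        rng = np.random.default_rng(23)
        for trial in range(100):
            n = int(rng.integers(5, 15))
            c = Connectome(oracles.random_weighted_graph(rng, n, p=0.5))
            rich = rng.choice(n, size=int(rng.integers(0, n)), replace=False)
            cs = richclub.class_strengths(c, richclub.classify_edges(c, rich))
            assert sum(cs.strengths.values()) == pytest.approx(
                metrics.total_strength(c), rel=1e-9
            )
            assert sum(cs.counts.values()) == c.n_edges()

    def test_normalized_strengths_sum_to_one(self):
        c = triangle_plus_pendant()
        cs = richclub.class_strengths(
            c, richclub.classify_edges(c, np.array([0, 1])), normalize_by_total=True
        )
        assert sum(cs.strengths.values()) == pytest.approx(1.0)

    def test_empty_class_ratio_flagged(self):
        tri = make_connectome(3, [(0, 1, 1), (1, 2, 2), (0, 2, 3)])
        with pytest.warns(UserWarning, match="ratio undefined"):
            cs = richclub.class_strengths(
                tri, richclub.classify_edges(tri, np.arange(3))
            )
        assert np.isnan(cs.ratio_rich_feeder)


class TestLengthMedianSplit:
    def test_even_and_odd_splits(self):
        c = make_connectome(
            6,
            [(0, 1, 1), (0, 2, 1), (0, 3, 1), (0, 4, 1)],
            lengths=[1.0, 2.0, 3.0, 4.0],
        )
        cm = richclub.classify_edges(c, np.array([], dtype=int))
        split = richclub.length_median_split(c, cm)
        assert split["peripheral"]["short"]["n_edges"] == 2
        assert split["peripheral"]["long"]["mean_length"] == pytest.approx(3.5)
        # odd count: median element goes to "short"
        c3 = make_connectome(
            5, [(0, 1, 1), (0, 2, 1), (0, 3, 1)], lengths=[1.0, 2.0, 3.0]
        )
        split3 = richclub.length_median_split(
            c3, richclub.classify_edges(c3, np.array([], dtype=int))
        )
        assert split3["peripheral"]["short"]["n_edges"] == 2
        assert split3["peripheral"]["long"]["n_edges"] == 1

    def test_empty_class_gives_empty_subsets(self):
        tri = make_connectome(3, [(0, 1, 1)], lengths=[5.0])
        split = richclub.length_median_split(
            tri, richclub.classify_edges(tri, np.arange(3))
        )
        assert split["feeder"]["short"]["n_edges"] == 0

    def test_long_feeder_exceeds_rich_length(self, template90):
        # physically longest feeder tracts outrun the rich-club mean length
        from richclubnet import cohort
        from richclubnet.connectome import build_connectome, threshold_edges

        sums = {"rich": [], "feeder_long": []}
        for s in range(3):
            tab = cohort.sample_subject_streamlines(template90, 0.6, seed=60 + s)
            c = threshold_edges(build_connectome(tab, 90, 10.0), 1.0)
            cm = richclub.classify_edges(c, template90.hub_set)
            split = richclub.length_median_split(c, cm)
            sums["rich"].append(split["rich"]["all"]["mean_length"])
            sums["feeder_long"].append(split["feeder"]["long"]["mean_length"])
        assert np.mean(sums["feeder_long"]) > np.mean(sums["rich"])


class TestPercentReduction:
    def test_headline_arithmetic(self):
        assert richclub.percent_reduction([10.0], [6.3]) == pytest.approx(37.0)

    def test_equal_means_zero(self):
        assert richclub.percent_reduction([2.0, 4.0], [3.0, 3.0]) == 0.0

    def test_boundary_and_error(self):
        assert richclub.percent_reduction([5.0], [0.0]) == 100.0
        with pytest.raises(ValueError):
            richclub.percent_reduction([0.0], [1.0])
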