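import filecmp

import numpy as np
import pandas as pd
import pytest
import scipy.stats

from richclubnet import cohort, metrics, richclub
from richclubnet.connectome import build_connectome, threshold_edges
from richclubnet.cohort import (
    CohortConfig,
    TemplateNetwork,
    apply_svd_lesion,
    generate_cognition,
    generate_cohort,
    generate_template,
    sample_subject_streamlines,
    write_cohort,
)


def single_edge_template(expected_count=5.0):
    """Hand-built 3-node template with one deterministic edge of known count."""
    pos = np.array([[0.0, 0.0, 0.0], [10.0, 0.0, 0.0], [0.0, 50.0, 0.0]])
    prob = np.zeros((3, 3))
    prob[0, 1] = prob[1, 0] = 1.0
    cmean = np.zeros((3, 3))
    cmean[0, 1] = cmean[1, 0] = expected_count
    d = np.sqrt(((pos[:, None] - pos[None]) ** 2).sum(-1))
    return TemplateNetwork(
        node_positions=pos,
        hub_set=np.array([0]),
        base_weight=prob * cmean,
        base_prob=prob,
        count_mean=cmean,
        distances=d,
        noise_prob=0.0,
    )


class TestTemplate:
    def test_planted_hubs_have_top_expected_degree(self, template90):
        ed = template90.expected_degree()
        assert set(np.argsort(ed)[-8:]) == set(template90.hub_set.tolist())

    def test_symmetry_and_zero_diagonal(self):
        t = generate_template(10, 2, seed=7)
        np.testing.assert_array_equal(t.base_weight, t.base_weight.T)
        np.testing.assert_array_equal(t.base_prob, t.base_prob.T)
        assert np.all(np.diag(t.base_weight) == 0)
        assert np.all(np.diag(t.base_prob) == 0)
        assert t.base_prob.max() <= 1.0

    def test_same_seed_identical(self):
        t1 = generate_template(20, 3, seed=5)
        t2 = generate_template(20, 3, seed=5)
        np.testing.assert_array_equal(t1.node_positions, t2.node_positions)
        np.testing.assert_array_equal(t1.base_prob, t2.base_prob)

    def test_hubs_more_distant_than_nonhubs(self, template90):
        d = template90.distances
        hubs = template90.hub_set
        non = np.setdiff1d(np.arange(90), hubs)
        hub_mean = d[np.ix_(hubs, hubs)][np.triu_indices(len(hubs), 1)].mean()
        non_mean = d[np.ix_(non, non)][np.triu_indices(len(non), 1)].mean()
        assert hub_mean > non_mean

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            generate_template(0, 1)
        with pytest.raises(ValueError):
            generate_template(10, 10)


class TestSubjectSampling:
    def test_no_streamlines_between_unconnected_pairs(self):
        t = single_edge_template()
        table = sample_subject_streamlines(t, noise_sd=0.0, seed=3)
        pairs = set(zip(table["node_i"], table["node_j"]))
        assert pairs <= {(1, 2)}

    def test_same_seed_identical_tables(self, small_template):
        t1 = sample_subject_streamlines(small_template, 0.6, seed=12)
        t2 = sample_subject_streamlines(small_template, 0.6, seed=12)
        pd.testing.assert_frame_equal(t1, t2)

    def test_poisson_streamline_count_mean(self):
        # Monte-Carlo check: mean count over many subjects ~ expected count 5
        t = single_edge_template(expected_count=5.0)
        rng_seeds = range(2000)
        counts = [
            len(sample_subject_streamlines(t, noise_sd=0.0, seed=s))
            for s in rng_seeds
        ]
        se = np.std(counts, ddof=1) / np.sqrt(len(counts))
        assert abs(np.mean(counts) - 5.0) < 3 * se + 1e-9

    def test_lengths_positive_and_near_distance(self, small_template):
        table = sample_subject_streamlines(small_template, 0.6, seed=2)
        assert (table["length_mm"] > 0).all()
        d = small_template.distances
        i = table["node_i"].to_numpy() - 1
        j = table["node_j"].to_numpy() - 1
        rel = table["length_mm"].to_numpy() / d[i, j]
        assert 0.5 < rel.min() and rel.max() < 1.6


class TestLesion:
    def test_identity_factors_change_nothing(self, small_template):
        table = sample_subject_streamlines(small_template, 0.5, seed=4)
        classes = richclub.pair_classes(30, small_template.hub_set)
        out = apply_svd_lesion(table, classes, (1.0, 1.0, 1.0), 1.5, seed=9)
        pd.testing.assert_frame_equal(out, table)

    def test_zero_factor_removes_class(self, small_template):
        table = sample_subject_streamlines(small_template, 0.5, seed=4)
        classes = richclub.pair_classes(30, small_template.hub_set)
        out = apply_svd_lesion(table, classes, (0.0, 1.0, 1.0), 1.0, seed=9)
        i = out["node_i"].to_numpy() - 1
        j = out["node_j"].to_numpy() - 1
        assert not np.any(classes[i, j] == richclub.RICH)

    def test_expected_strength_ratio_half(self, small_template):
        # f_rich = 0.5: retained rich streamline fraction ~ 0.5 over 200 subjects
        classes = richclub.pair_classes(30, small_template.hub_set)
        kept, total = 0, 0
        for s in range(200):
            table = sample_subject_streamlines(small_template, 0.0, seed=s)
            les = apply_svd_lesion(table, classes, (0.5, 1.0, 1.0), 1.0, seed=s)
            i = table["node_i"].to_numpy() - 1
            j = table["node_j"].to_numpy() - 1
            total += int((classes[i, j] == richclub.RICH).sum())
            i2 = les["node_i"].to_numpy() - 1
            j2 = les["node_j"].to_numpy() - 1
            kept += int((classes[i2, j2] == richclub.RICH).sum())
        assert kept / total == pytest.approx(0.5, abs=0.03)

    def test_unknown_class_errors(self):
        table = pd.DataFrame(
            {"subject_id": ["s"], "node_i": [1], "node_j": [1], "length_mm": [5.0]}
        )
        classes = richclub.pair_classes(3, np.array([0]))
        with pytest.raises(ValueError, match="unknown edge class"):
            apply_svd_lesion(table, classes, (0.5, 0.5, 0.5), 1.0, seed=0)


class TestCognition:
    def test_identity_case(self):
        rz = np.array([-1.0, 0.5, 2.0])
        speed = generate_cognition(rz, np.zeros(3), (1.0, 0.0, 0.0), seed=0)
        np.testing.assert_allclose(speed, rz)

    def test_null_coefficients_uncorrelated(self):
        rng = np.random.default_rng(14)
        rz = rng.normal(size=1000)
        lac = rng.poisson(1.0, size=1000)
        speed = generate_cognition(rz, lac, (0.0, 0.0, 1.0), seed=5)
        assert abs(np.corrcoef(rz, speed)[0, 1]) < 0.1

    def test_fixed_seed_reproducible(self):
        rz = np.linspace(-1, 1, 20)
        lac = np.arange(20) % 3
        s1 = generate_cognition(rz, lac, (0.3, -0.3, 0.8), seed=11)
        s2 = generate_cognition(rz, lac, (0.3, -0.3, 0.8), seed=11)
        np.testing.assert_array_equal(s1, s2)


class TestGenerateCohort:
    @pytest.mark.parametrize("n_control,n_svd", [(50, 115), (108, 49)])
    def test_group_sizes(self, n_control, n_svd):
        cfg = CohortConfig(
            n_control=n_control, n_svd=n_svd, n_nodes=30, n_hubs=4, seed=2
        )
        coh = generate_cohort(cfg)
        assert len(coh.subjects) == n_control + n_svd
        assert (coh.subjects["group"] == "control").sum() == n_control
        assert len(coh.tables) == n_control + n_svd

    def test_metadata_invariants(self, tiny_cohort):
        meta = tiny_cohort.subjects
        assert (meta["wmh_ml"] >= 0).all()
        assert (meta["lacune_count"] >= 0).all()
        assert meta["lacune_count"].dtype.kind == "i"

    def test_byte_identical_under_same_seed(self, tmp_path):
        cfg = CohortConfig(n_control=3, n_svd=4, n_nodes=20, n_hubs=2, seed=33)
        d1, d2 = tmp_path / "a", tmp_path / "b"
        write_cohort(generate_cohort(cfg), d1)
        write_cohort(generate_cohort(cfg), d2)
        for name in ("streamlines.tsv", "metadata.tsv", "manifest.yaml"):
            assert filecmp.cmp(d1 / name, d2 / name, shallow=False)

    def test_control_degrees_right_skewed(self, tiny_cohort):
        degs = []
        for sid in tiny_cohort.subjects.query("group == 'control'")["subject_id"]:
            c = threshold_edges(
                build_connectome(tiny_cohort.tables[sid], 30, 10.0), 1.0
            )
            degs.append(metrics.degree(c))
        assert scipy.stats.skew(np.mean(degs, axis=0)) > 0

    def test_mean_length_ordering(self, tiny_cohort):
        means = {"rich": [], "feeder": [], "peripheral": []}
        classes = richclub.pair_classes(30, tiny_cohort.template.hub_set)
        for sid in tiny_cohort.subjects.query("group == 'control'")["subject_id"]:
            c = threshold_edges(
                build_connectome(tiny_cohort.tables[sid], 30, 10.0), 1.0
            )
            iu = np.triu_indices(30, 1)
            w, ln, cl = c.weights[iu], c.mean_length[iu], classes[iu]
            for code, name in richclub.CLASS_NAMES.items():
                sel = (w > 0) & (cl == code)
                means[name].append(ln[sel].mean())
        assert (
            np.mean(means["rich"])
            > np.mean(means["feeder"])
            > np.mean(means["peripheral"])
        )

    def test_config_validation(self):
        with pytest.raises(ValueError):
            CohortConfig(n_control=0)
        with pytest.raises(ValueError):
            CohortConfig(lesion_factors=(0.5, 1.2, 0.5))

    def test_config_yaml_round_trip(self, tmp_path):
        cfg = CohortConfig(n_control=7, n_svd=9, seed=4)
        path = tmp_path / "cfg.yaml"
        cfg.to_yaml(path)
        assert CohortConfig.from_yaml(path) == cfg
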