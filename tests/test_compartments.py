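"""O/E transform, PC1 calling, orientation, switch classification."""

import numpy as np
import pytest
from scipy import stats as sps

import hicomp as h

from conftest import random_symmetric


class TestObservedOverExpected:
    def test_six_by_six_fixture_matches_direct_division(self):
        m = random_symmetric(np.random.default_rng(0), 6)
        oe = h.observed_over_expected(m)
        for d in range(1, 6):
            expected = np.diagonal(m, d).mean()
            np.testing.assert_allclose(
                np.diagonal(oe, d), np.diagonal(m, d) / expected)

    def test_diagonal_means_equal_one(self, maps_500):
        oe = h.observed_over_expected(maps_500[0].matrix)
        for d in range(1, 100):
            assert np.nanmean(np.diagonal(oe, d)) == pytest.approx(1.0)

    def test_scale_invariance(self):
        m = random_symmetric(np.random.default_rng(1), 8)
        a = h.observed_over_expected(m)
        b = h.observed_over_expected(2.0 * m)
        np.testing.assert_allclose(a, b, equal_nan=True)

    def test_matrix_equal_to_diagonal_means_gives_ones(self):
        n = 7
        m = np.zeros((n, n))
        for d in range(1, n):
            for i in range(n - d):
                m[i, i + d] = m[i + d, i] = 10.0 / d
        oe = h.observed_over_expected(m)
        off = ~np.eye(n, dtype=bool)
        np.testing.assert_allclose(oe[off], 1.0)

    def test_masked_rows_nan(self):
        m = random_symmetric(np.random.default_rng(2), 6)
        mask = np.zeros(6, dtype=bool)
        mask[2] = True
        oe = h.observed_over_expected(m, mask)
        assert np.isnan(oe[2, :]).all() and np.isnan(oe[:, 2]).all()


def two_block_plaid(n=20, p=0.5):
    """Analytic plaid in expectation: two alternating label blocks."""
    labels = np.array(["A"] * (n // 2) + ["B"] * (n - n // 2))
    idx = np.arange(n)
    d = np.abs(idx[:, None] - idx[None, :]).astype(float)
    with np.errstate(divide="ignore"):
        decay = np.where(d > 0, 1.0 / d, 0.0)
    same = labels[:, None] == labels[None, :]
    m = decay * (1 + p * same)
    return m, labels


class TestCompartmentPC1:
    def test_two_block_plaid_sign_pattern(self):
        m, labels = two_block_plaid()
        oe = h.observed_over_expected(m)
        pc1 = h.compartment_pc1(oe)
        pc1 = h.orient_pc1(pc1, (labels == "A").astype(float))
        assert ((pc1 > 0) == (labels == "A")).all()

    def test_eigenvector_sign_ambiguity_is_resolved_by_orientation(self):
        m, labels = two_block_plaid()
        oe = h.observed_over_expected(m)
        pc1 = h.compartment_pc1(oe)
        dens = (labels == "A").astype(float)
        a = h.orient_pc1(pc1, dens)
        b = h.orient_pc1(-pc1, dens)
        np.testing.assert_allclose(a, b)

    def test_recovery_from_noisy_synthetic_map(self, truth_500, params_1m, maps_500):
        iced, _, _ = h.ice_contact_matrix(maps_500[0])
        oe = h.observed_over_expected(iced.matrix, iced.gap_mask)
        pc1 = h.compartment_pc1(oe, iced.gap_mask)
        labels = (truth_500.labels_c1["chr1"] == "A").astype(float)
        r = abs(sps.pointbiserialr(labels, pc1).correlation)
        assert r > 0.9

    def test_pure_decay_gives_no_compartment_signal(self):
        """With plaid strength 0, PC1 is uncorrelated with planted labels."""
        rs = []
        p0 = h.SimulationParams(depth=1e6, plaid_strength=0.0)
        for seed in range(8):
            t = h.plant_architecture({"chr1": 300}, 100_000, seed=seed)
            m = h.simulate_contact_map(t, p0, 1, 100 + seed)["chr1"]
            iced, _, _ = h.ice_contact_matrix(m)
            oe = h.observed_over_expected(iced.matrix, iced.gap_mask)
            pc1 = h.compartment_pc1(oe, iced.gap_mask)
            labels = (t.labels_c1["chr1"] == "A").astype(float)
            rs.append(sps.pointbiserialr(labels, pc1).correlation)
        assert abs(np.mean(rs)) < 0.2

    def test_too_few_bins_rejected(self):
        with pytest.raises(h.ParameterError):
            h.compartment_pc1(np.ones((5, 5)))

    def test_degenerate_constant_matrix_rejected(self):
        with pytest.raises(h.ParameterError):
            h.compartment_pc1(np.ones((15, 15)))


class TestOrientPC1:
    def test_negative_correlation_flips(self):
        rng = np.random.default_rng(3)
        dens = rng.uniform(0, 10, 50)
        pc1 = -dens + rng.normal(0, 1, 50)  # PCC < 0
        out = h.orient_pc1(pc1, dens)
        np.testing.assert_allclose(out, -pc1)
        assert np.corrcoef(out, dens)[0, 1] >= 0

    def test_positive_correlation_unchanged(self):
        rng = np.random.default_rng(4)
        dens = rng.uniform(0, 10, 50)
        pc1 = dens + rng.normal(0, 1, 50)
        np.testing.assert_allclose(h.orient_pc1(pc1, dens), pc1)

    def test_idempotent(self):
        rng = np.random.default_rng(5)
        dens = rng.uniform(0, 10, 30)
        pc1 = rng.normal(0, 1, 30)
        once = h.orient_pc1(pc1, dens)
        np.testing.assert_allclose(h.orient_pc1(once, dens), once)

    def test_zero_variance_density_undefined(self):
        with pytest.raises(h.UndefinedValueError):
            h.orient_pc1(np.array([1.0, -2.0, 3.0]), np.ones(3))


class TestClassifyBins:
    def test_rule_application(self):
        track = h.classify_bins(np.array([0.2, 0.1, -0.3, -0.1, 0.4]))
        assert list(track.labels) == ["A", "A", "B", "B", "A"]
        assert track.segments == [(0, 2, "A"), (2, 4, "B"), (4, 5, "A")]

    def test_all_positive_single_segment(self):
        track = h.classify_bins(np.array([0.5, 0.2, 0.9]))
        assert track.segments == [(0, 3, "A")]

    def test_exact_zero_and_nan_masked(self):
        track = h.classify_bins(np.array([0.5, 0.0, np.nan, -0.5]))
        assert list(track.labels) == ["A", ".", ".", "B"]
        assert track.segments == [(0, 1, "A"), (3, 4, "B")]


class TestSwitchClassification:
    def mk(self, labels):
        labels = np.asarray(list(labels))
        pc1 = np.where(labels == "A", 1.0,
                       np.where(labels == "B", -1.0, np.nan))
        return h.classify_bins(pc1)

    def test_identical_tracks_no_switch(self):
        t = self.mk(["A", "B", "A"])
        st = h.switch_classification(t, self.mk(["A", "B", "A"]))
        assert st.switched_fraction == 0.0

    def test_four_bin_toy(self):
        st = h.switch_classification(self.mk("AABB"), self.mk("BABA"))
        assert st.counts == {"A-common": 1, "B-common": 1, "AtoB": 1, "BtoA": 1}
        assert st.switched_fraction == 0.5
        assert st.ab_share_of_switched == 0.5

    def test_masked_propagates(self):
        st = h.switch_classification(self.mk(["A", ".", "B"]),
                                     self.mk(["A", "B", "."]))
        assert st.n_unmasked == 1

    def test_antisymmetry(self):
        rng = np.random.default_rng(6)
        l1 = rng.choice(list("AB"), 100)
        l2 = rng.choice(list("AB"), 100)
        fwd = h.switch_classification(self.mk(l1), self.mk(l2))
        rev = h.switch_classification(self.mk(l2), self.mk(l1))
        assert fwd.counts["AtoB"] == rev.counts["BtoA"]
        assert fwd.counts["BtoA"] == rev.counts["AtoB"]

    def test_length_mismatch_rejected(self):
        with pytest.raises(h.ParameterError):
            h.switch_classification(self.mk("AB"), self.mk("ABA"))


class TestCompareSwitchRates:
    def test_equal_rates_null(self):
        stat, p = h.compare_switch_rates(30, 1000, 30, 1000)
        assert stat == pytest.approx(0.0) and p == pytest.approx(1.0)

    def test_matches_textbook_formula(self):
        # hand 2x2 chi-squared without continuity correction
        a, b = 30, 970   # condition: switched / not
        c, d = 10, 990   # replicate baseline
        n = a + b + c + d
        expected_stat = n * (a * d - b * c) ** 2 / (
            (a + b) * (c + d) * (a + c) * (b + d))
        stat, p = h.compare_switch_rates(30, 1000, 10, 1000)
        assert stat == pytest.approx(expected_stat)
        assert p == pytest.approx(sps.chi2.sf(expected_stat, 1))

    def test_p_decreases_with_rate_gap(self):
        ps = [h.compare_switch_rates(30 + gap, 1000, 30, 1000)[1]
              for gap in (0, 10, 20, 40, 80)]
        assert all(b < a for a, b in zip(ps, ps[1:]))

    def test_zero_total_rejected(self):
        with pytest.raises(h.ParameterError):
            h.compare_switch_rates(0, 0, 1, 10)


class TestIntraCompartmentStrength:
    def test_printed_fixture_mean(self):
        m = random_symmetric(np.random.default_rng(7), 6)
        [(seg, mean)] = h.intra_compartment_strength(m, [(1, 4, "B-common")])
        cells = [m[1, 2], m[1, 3], m[2, 3]]
        assert mean == pytest.approx(np.mean(cells))

    def test_fully_masked_segment_skipped(self):
        m = random_symmetric(np.random.default_rng(8), 6)
        mask = np.zeros(6, dtype=bool)
        mask[[1, 2, 3]] = True
        out = h.intra_compartment_strength(m, [(1, 4, "A-common")], mask)
        assert out == []

    def test_bb_boost_detected_in_b_common_only(self):
        """Planted B-B strengthening shifts B-common segment means in
        condition 2; A-common stays null (3 chromosomes, >= 30 segments)."""
        chroms = {f"chr{i}": 500 for i in (1, 2, 3)}
        t = h.plant_architecture(chroms, 100_000, seed=20)
        p = h.SimulationParams(depth=1e6)
        means = {"A-common": ([], []), "B-common": ([], [])}
        for chrom in chroms:
            m1 = h.simulate_contact_map(t, p, 1, 300)[chrom].matrix
            m2 = h.simulate_contact_map(t, p, 2, 301)[chrom].matrix
            cats = h.truth_switch_categories(t, chrom)
            segs = h.category_segments(cats)
            for cond, m in ((0, m1), (1, m2)):
                for (s, e, c), mean in h.intra_compartment_strength(
                        m, [x for x in segs if x[2] in means]):
                    means[c][cond].append(mean)
        _, p_b = h.wilcoxon_rank_sum(*[np.array(v) for v in means["B-common"]])
        _, p_a = h.wilcoxon_rank_sum(*[np.array(v) for v in means["A-common"]])
        assert len(means["B-common"][0]) >= 30
        assert p_b < 0.01
        assert p_a > 0.05
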