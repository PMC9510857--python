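"""The generator must plant exactly the architecture the analysis assumes."""

import numpy as np
import pytest
from scipy import stats as sps

import hicomp as h
from hicomp.synthetic import FRAGMENT_BP


class TestPlantArchitecture:
    def test_no_switch_identity(self):
        t = h.plant_architecture({"chr1": 200}, 100_000, switch_fraction=0.0, seed=0)
        for c in t.chroms:
            assert (t.labels_c1[c] == t.labels_c2[c]).all()

    def test_switch_counts_exact(self):
        t = h.plant_architecture(
            {"chr1": 5000, "chr2": 5000}, 100_000,
            switch_fraction=0.06, ab_to_ba_ratio=0.72, seed=3,
        )
        assert abs(t.n_switched() - 600) <= 1
        assert abs(t.n_switched_ab() - 432) <= 1

    def test_invariants(self):
        t = h.plant_architecture({"chr1": 300, "chr2": 150}, 40_000, seed=5)
        for c in t.chroms:
            n = t.chrom_lengths[c]
            assert t.labels_c1[c].size == t.labels_c2[c].size == n
            borders = t.tad_borders[c]
            assert all(b2 > b1 for b1, b2 in zip(borders, borders[1:]))
            assert borders[0] >= 0 and borders[-1] < n
            assert (t.bias[c] > 0).all()

    def test_switches_are_contiguous_runs(self):
        t = h.plant_architecture({"chr1": 2000}, 100_000, seed=11)
        sw = t.switched_bins("chr1").astype(int)
        n_runs = int(np.abs(np.diff(np.concatenate([[0], sw, [0]]))).sum()) // 2
        # far fewer runs than switched bins: whole segments flip, not single bins
        assert 0 < n_runs < sw.sum() / 3

    def test_seeded_determinism(self):
        a = h.plant_architecture({"chr1": 200}, 100_000, seed=42)
        b = h.plant_architecture({"chr1": 200}, 100_000, seed=42)
        assert a.to_json() == b.to_json()

    def test_too_short_chromosome_rejected(self):
        with pytest.raises(h.ParameterError):
            h.plant_architecture({"chr1": 10}, 100_000, seed=0)

    def test_json_round_trip(self):
        t = h.plant_architecture({"chr1": 120}, 40_000, seed=2)
        t2 = h.PlantedTruth.from_json(t.to_json())
        assert t2.to_json() == t.to_json()


class TestSimulateContactMap:
    def test_decay_goodness_of_fit(self):
        """Diagonal means follow the planted power law within Poisson error."""
        t = h.plant_architecture({"chr1": 300}, 100_000, switch_fraction=0.0, seed=1)
        t.bias["chr1"][:] = 1.0
        p = h.SimulationParams(depth=1e6, plaid_strength=0.0, tad_enrichment=0.0)
        E = h.expected_contact_matrix(t, p, "chr1", 1)
        m = h.simulate_contact_map(t, p, 1, 99)["chr1"].matrix
        obs = np.array([np.diagonal(m, d).sum() for d in range(1, 300)])
        lam = np.array([np.diagonal(E, d).sum() for d in range(1, 300)])
        chi2 = ((obs - lam) ** 2 / lam).sum()
        p_gof = sps.chi2.sf(chi2, df=obs.size)
        assert p_gof > 0.01

    def test_boost_identity(self, params_1m):
        t = h.plant_architecture({"chr1": 200}, 100_000, bb_boost=1.0, seed=4)
        e1 = h.expected_contact_matrix(t, params_1m, "chr1", 1)
        e2 = h.expected_contact_matrix(t, params_1m, "chr1", 2)
        # identical labels (flip a truth with no switches to be exact)
        t0 = h.plant_architecture({"chr1": 200}, 100_000, bb_boost=1.0,
                                  switch_fraction=0.0, seed=4)
        e1 = h.expected_contact_matrix(t0, params_1m, "chr1", 1)
        e2 = h.expected_contact_matrix(t0, params_1m, "chr1", 2)
        np.testing.assert_allclose(e1, e2)

    def test_bb_boost_scales_bb_cells_only(self, params_1m):
        t = h.plant_architecture({"chr1": 200}, 100_000, bb_boost=2.0,
                                 switch_fraction=0.0, seed=4)
        e1 = h.expected_contact_matrix(t, params_1m, "chr1", 1)
        e2 = h.expected_contact_matrix(t, params_1m, "chr1", 2)
        lab = t.labels_c2["chr1"]
        bb = (lab == "B")[:, None] & (lab == "B")[None, :]
        np.testing.assert_allclose(e2[bb], 2.0 * e1[bb])
        np.testing.assert_allclose(e2[~bb], e1[~bb])

    def test_bias_bilinearity(self, params_1m):
        """Doubling all biases scales the pre-normalization model by 4,
        which the depth calibration exactly cancels."""
        t = h.plant_architecture({"chr1": 100}, 100_000, switch_fraction=0.0, seed=6)
        e1 = h.expected_contact_matrix(t, params_1m, "chr1", 1)
        t.bias["chr1"] = 2.0 * t.bias["chr1"]
        e2 = h.expected_contact_matrix(t, params_1m, "chr1", 1)
        np.testing.assert_allclose(e1, e2, rtol=1e-12)

    def test_expected_total_matches_depth(self, truth_500, params_1m):
        E = h.expected_contact_matrix(truth_500, params_1m, "chr1", 1)
        total = np.triu(E, 1).sum()
        assert abs(total - params_1m.depth) / params_1m.depth < 0.02

    def test_symmetry_nonnegative_zero_diagonal(self, maps_500):
        m = maps_500[0].matrix
        assert (m == m.T).all()
        assert (m >= 0).all()
        assert (np.diag(m) == 0).all()
        assert (m == np.round(m)).all()
        assert not maps_500[0].gap_mask.any()

    def test_seeded_determinism(self, truth_500, params_1m):
        a = h.simulate_contact_map(truth_500, params_1m, 1, 5)["chr1"]
        b = h.simulate_contact_map(truth_500, params_1m, 1, 5)["chr1"]
        np.testing.assert_array_equal(a.matrix, b.matrix)

    def test_bad_alpha_rejected(self):
        with pytest.raises(h.ParameterError):
            h.SimulationParams(decay_exponent=0.0)

    def test_planted_gaps_zeroed(self, params_1m):
        t = h.plant_architecture({"chr1": 100}, 100_000, gap_fraction=0.05, seed=8)
        m = h.simulate_contact_map(t, params_1m, 1, 1)["chr1"]
        gaps = t.gap_bins["chr1"]
        assert len(gaps) == 5
        assert m.gap_mask[gaps].all()
        assert (m.matrix[gaps, :] == 0).all()


class TestSimulatePairs:
    def test_no_artifacts_all_retained(self, truth_500, params_1m):
        lines = h.simulate_pairs(truth_500, params_1m, 500, seed=3)
        valid, stats = h.filter_pairs(h.parse_pairs(lines))
        assert stats.n_valid == stats.n_input == 500

    def test_planted_low_mapq_fraction_recovered(self, truth_500, params_1m):
        lines = h.simulate_pairs(
            truth_500, params_1m, 10_000,
            artifact_rates={"low_mapq": 0.2}, seed=5,
        )
        _, stats = h.filter_pairs(h.parse_pairs(lines))
        assert abs(stats.n_low_mapq - 2000) <= 3 * np.sqrt(1600)

    def test_all_artifact_buckets_recovered(self, truth_500, params_1m):
        rates = {"low_mapq": 0.1, "same_fragment": 0.1, "dangling": 0.1}
        lines = h.simulate_pairs(truth_500, params_1m, 20_000,
                                 artifact_rates=rates, seed=6)
        _, stats = h.filter_pairs(h.parse_pairs(lines))
        tol = 3 * np.sqrt(20_000 * 0.1 * 0.9)
        assert abs(stats.n_low_mapq - 2000) <= tol
        assert abs(stats.n_same_fragment - 2000) <= tol
        assert abs(stats.n_dangling - 2000) <= tol

    def test_trans_fraction_recovered(self):
        t = h.plant_architecture({"chr1": 100, "chr2": 100}, 100_000, seed=2)
        p = h.SimulationParams(depth=1e5)
        lines = h.simulate_pairs(t, p, 20_000, seed=7, trans_fraction=0.43)
        _, stats = h.filter_pairs(h.parse_pairs(lines))
        assert abs(h.trans_fraction(stats) - 0.43) < 0.015

    def test_byte_identical_given_seed(self, truth_500, params_1m):
        a = h.simulate_pairs(truth_500, params_1m, 200, seed=9)
        b = h.simulate_pairs(truth_500, params_1m, 200, seed=9)
        assert a == b

    def test_rates_over_one_rejected(self, truth_500, params_1m):
        with pytest.raises(h.ParameterError):
            h.simulate_pairs(truth_500, params_1m, 10,
                             artifact_rates={"low_mapq": 0.9, "dangling": 0.2})

    def test_valid_cis_pairs_reproduce_architecture(self, truth_500, params_1m):
        """Binning the valid pairs recovers the planted contact profile."""
        lines = h.simulate_pairs(truth_500, params_1m, 50_000, seed=10)
        valid, _ = h.filter_pairs(h.parse_pairs(lines))
        genome = truth_500.genome()
        mats, _ = h.bin_pairs(valid, genome)
        E = h.expected_contact_matrix(truth_500, params_1m, "chr1", 1)
        m = mats["chr1"].matrix
        # correlation between realized and expected short-range profile
        d = np.arange(1, 100)
        obs = np.array([np.diagonal(m, k).mean() for k in d])
        exp = np.array([np.diagonal(E, k).mean() for k in d])
        assert np.corrcoef(obs, exp)[0, 1] > 0.98


class TestSimulateExpression:
    def test_planted_effect_location(self, truth_500):
        p = h.SimulationParams(depth=1e6, n_replicates=3, n_genes=1000)
        counts, ann = h.simulate_expression(truth_500, p, effect_log2fc=3.0, seed=1)
        assert counts.shape == (1000, 6)
        assert len(truth_500.de_genes) > 0
        ann = h.genes_to_bins(ann, truth_500.bin_size)
        for gid in truth_500.de_genes:
            b = int(ann.set_index("gene_id").loc[gid, "bin"])
            assert truth_500.labels_c1["chr1"][b] == "B"
            assert truth_500.labels_c2["chr1"][b] == "A"

    def test_gene_midpoint_stays_in_assigned_bin(self, truth_500):
        p = h.SimulationParams(n_genes=500)
        _, ann = h.simulate_expression(truth_500, p, seed=2)
        mid = (ann["start"] + ann["end"]) // 2
        assert ((mid // truth_500.bin_size) < 500).all()
        assert (ann["start"] >= 0).all()

    def test_determinism(self, truth_500):
        p = h.SimulationParams(n_genes=200)
        a, _ = h.simulate_expression(truth_500, p, seed=3)
        b, _ = h.simulate_expression(truth_500, p, seed=3)
        assert a.equals(b)

    def test_null_effect_has_no_category_shift(self):
        """With effect 0 no category shows a planted shift: the association
        test fires at no more than its nominal rate across seeds (the
        per-gene pairing makes the rank-sum conservative, never liberal)."""
        t = h.plant_architecture({"chr1": 500}, 100_000, seed=4)
        p = h.SimulationParams(n_replicates=3, n_genes=300)
        cats = h.truth_switch_categories(t, "chr1")
        pvals = []
        for seed in range(60):
            counts, ann = h.simulate_expression(t, p, effect_log2fc=0.0, seed=seed)
            tpm = h.tpm(counts, ann.set_index("gene_id").loc[counts.index, "length"])
            res = h.expression_by_category(
                tpm, ann, {"chr1": cats}, 100_000, [1, 1, 1, 2, 2, 2])
            pvals.extend(
                res[c].p_value for c in ("A-common", "B-common", "BtoA")
                if res[c].p_value is not None
            )
        assert np.mean(np.asarray(pvals) < 0.05) <= 0.1
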