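import numpy as np
import pytest
from scipy.spatial.distance import pdist

from ieegconn import (
    SimConfig,
    fit_intercept_only,
    generate_boundary_mask,
    generate_cohort_table,
    generate_electrodes,
    generate_streamline_counts,
    generate_truth_networks,
    jaccard_index,
)
from ieegconn.contact_areas import build_contact_areas
from ieegconn.structural import binarize_structural, streamline_density
from ieegconn.synthetic import stim_pairs


class TestGenerateElectrodes:
    def test_4x4_grid_has_16_contacts_at_10mm_pitch(self):
        cfg = SimConfig(modality="ECoG", grid_rows=4, grid_cols=4)
        es = generate_electrodes(cfg)
        assert es.n_contacts == 16
        d = pdist(es.coords)
        assert d.min() == pytest.approx(10.0)
        # coplanar
        assert np.ptp(es.coords[:, 2]) == 0.0

    def test_single_contact_shaft_at_origin(self):
        cfg = SimConfig(modality="sEEG", n_shafts=1, contacts_per_shaft=1)
        es = generate_electrodes(cfg)
        assert es.n_contacts == 1
        assert np.allclose(es.coords[0], 0.0)  # shaft origin

    def test_shaft_pitch_3p5mm_within_shaft(self):
        cfg = SimConfig(modality="sEEG", n_shafts=2, contacts_per_shaft=8,
                        shaft_pitch_mm=3.5)
        es = generate_electrodes(cfg)
        assert es.n_contacts == 16
        shaft_a = es.coords[:8]
        gaps = np.linalg.norm(np.diff(shaft_a, axis=0), axis=1)
        assert np.allclose(gaps, 3.5)
        # collinear within a shaft
        assert np.linalg.matrix_rank(shaft_a - shaft_a[0], tol=1e-9) == 1

    def test_labels_unique_and_deterministic(self):
        cfg = SimConfig(modality="sEEG", n_shafts=3, contacts_per_shaft=4)
        a = generate_electrodes(cfg)
        b = generate_electrodes(cfg)
        assert a.labels == b.labels
        assert np.array_equal(a.coords, b.coords)
        assert len(set(a.labels)) == len(a.labels)


class TestGenerateBoundaryMask:
    def test_64_voxels_constructible_for_every_contact(self, seeg_config):
        es = generate_electrodes(seeg_config)
        mask = generate_boundary_mask(seeg_config, es)
        centers = mask.voxel_centers_mm(mask.true_voxel_indices())
        for coord in es.coords:
            d = np.linalg.norm(centers - coord, axis=1)
            assert (d <= 10.0).sum() >= 64

    def test_full_areas_from_saturated_mask(self):
        cfg = SimConfig(modality="ECoG", grid_rows=2, grid_cols=2)
        es = generate_electrodes(cfg)
        mask = generate_boundary_mask(cfg, es)
        mask.data[:] = True  # saturate
        areas = build_contact_areas(es, mask)
        assert all(areas.n_voxels(l) == 64 for l in areas.labels)

    def test_invalid_shape_rejected(self):
        cfg = SimConfig(mask_shape=(0, 5, 5))
        with pytest.raises(ValueError, match="positive"):
            generate_boundary_mask(cfg)


class TestGenerateTruthNetworks:
    def test_full_overlap_equal_density_gives_identical_networks(self):
        cfg = SimConfig(modality="sEEG", n_shafts=4, contacts_per_shaft=8,
                        d_sc=0.2, d_ec=0.2, overlap=1.0)
        truth = generate_truth_networks(cfg)
        # identical up to the density-rounding remainder (EC edges come in
        # 4-edge stimulation-pair blocks, SC edges are free)
        sym_diff = truth.sc_true.edge_set() ^ truth.ec_true.edge_set()
        assert len(sym_diff) == abs(truth.sc_true.n_edges
                                    - truth.ec_true.n_edges)
        assert truth.planted_ji >= 0.9

    def test_zero_overlap_gives_ji_zero(self):
        cfg = SimConfig(modality="sEEG", n_shafts=4, contacts_per_shaft=8,
                        overlap=0.0)
        truth = generate_truth_networks(cfg)
        assert truth.planted_ji == 0.0
        assert jaccard_index(truth.sc_true, truth.ec_true) == 0.0

    def test_planted_ji_equals_jaccard_of_truths(self):
        """The stored planted value is exactly Jaccard(SC_true, EC_true)
        across a range of feasible configurations."""
        rng = np.random.default_rng(5)
        for _ in range(12):
            cfg = SimConfig(
                modality="sEEG", n_shafts=4, contacts_per_shaft=8,
                d_sc=float(rng.uniform(0.08, 0.3)),
                d_ec=float(rng.uniform(0.08, 0.3)),
                overlap=float(rng.uniform(0, 1)),
                seed=int(rng.integers(2**31)),
            )
            truth = generate_truth_networks(cfg)
            assert jaccard_index(truth.sc_true, truth.ec_true) == \
                pytest.approx(truth.planted_ji)

    def test_densities_near_targets(self):
        from ieegconn import density

        cfg = SimConfig(modality="sEEG", n_shafts=8, contacts_per_shaft=8)
        truth = generate_truth_networks(cfg)
        assert density(truth.sc_true) == pytest.approx(0.20, abs=0.01)
        assert density(truth.ec_true) == pytest.approx(0.23, abs=0.01)

    def test_infeasible_combination_rejected(self):
        cfg = SimConfig(modality="sEEG", n_shafts=4, contacts_per_shaft=8,
                        d_sc=0.9, d_ec=0.9, overlap=0.0)
        with pytest.raises(ValueError, match="infeasible"):
            generate_truth_networks(cfg)

    def test_ec_truth_has_no_within_pair_edges(self, seeg_config):
        truth = generate_truth_networks(seeg_config)
        edges = truth.ec_true.edge_set()
        for a, b in truth.stim_pairs:
            assert frozenset((a, b)) not in edges


class TestGenerateStreamlineCounts:
    def test_planted_false_positive_rate(self, seeg_config):
        es = generate_electrodes(seeg_config)
        mask = generate_boundary_mask(seeg_config, es)
        areas = build_contact_areas(es, mask)
        truth = generate_truth_networks(seeg_config)
        counts = generate_streamline_counts(truth, areas, fp_rate=0.05,
                                            seed=99)
        net = binarize_structural(streamline_density(counts, areas),
                                  counts.labels)
        spurious = net.edge_set() - truth.sc_true.edge_set()
        n = truth.sc_true.n_nodes
        n_nonedges = n * (n - 1) // 2 - truth.sc_true.n_edges
        expected = 0.05 * n_nonedges
        sd = np.sqrt(n_nonedges * 0.05 * 0.95)
        assert abs(len(spurious) - expected) <= 4 * sd
        assert truth.sc_true.edge_set() <= net.edge_set()

    def test_true_edge_count_inverts_density_formula(self, ecog_patient):
        """Full-size areas (64 mm^3 each) force counts of at least 13
        so that count / 128 > 0.1."""
        truth, areas = ecog_patient["truth"], ecog_patient["areas"]
        counts = ecog_patient["counts"]
        labels = list(counts.labels)
        for i in range(len(labels)):
            for j in range(i + 1, len(labels)):
                if truth.sc_true.adjacency[i, j]:
                    v = areas.vea(labels[i]) + areas.vea(labels[j])
                    assert counts.counts[i, j] > 0.1 * v


class TestStimPairs:
    def test_pairs_adjacent_disjoint_within_rows(self):
        cfg = SimConfig(modality="ECoG", grid_rows=2, grid_cols=4)
        es = generate_electrodes(cfg)
        pairs = stim_pairs(cfg, es)
        assert pairs == [("G01", "G02"), ("G03", "G04"),
                         ("G05", "G06"), ("G07", "G08")]
        flat = [c for p in pairs for c in p]
        assert len(flat) == len(set(flat))
        coords = {lab: c for lab, c in zip(es.labels, es.coords)}
        for a, b in pairs:
            assert np.linalg.norm(coords[a] - coords[b]) == pytest.approx(10.0)


class TestGenerateCohortTable:
    def test_scale_matches_13_patients_66_nodes(self):
        table = generate_cohort_table(SimConfig(), seed=0)
        assert len(table) == 13 * 66
        assert table["patient"].nunique() == 13

    def test_empirical_icc_converges_to_planted_value(self):
        """At 50 patients the fitted intercept-only ICC is within 0.05 of
        the generative 0.37 (null fixed effects isolate the variance split)."""
        cfg = SimConfig(n_patients=50, nodes_per_patient=66,
                        beta_ecd=0.0, beta_np=0.0)
        table = generate_cohort_table(cfg, seed=31)
        fit = fit_intercept_only(table, standardize=False)
        assert abs(fit.icc - 0.37) < 0.05

    def test_planted_fixed_effects_recovered(self):
        from ieegconn import fit_multilevel

        cfg = SimConfig(n_patients=30, nodes_per_patient=66)
        table = generate_cohort_table(cfg, seed=77)
        fit = fit_multilevel(table, predictors=("ec_degree", "proximity"),
                             standardize=False)
        assert fit.terms.loc["ec_degree", "beta"] == pytest.approx(0.13,
                                                                   abs=0.05)
        assert fit.terms.loc["proximity", "beta"] == pytest.approx(-0.13,
                                                                   abs=0.05)

    def test_two_patient_minimum(self):
        with pytest.raises(ValueError, match="at least 2"):
            generate_cohort_table(SimConfig(n_patients=1), seed=0)
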