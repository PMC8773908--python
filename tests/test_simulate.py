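"""Simulator: cell geometry, molecule sampling, rendering and scenarios."""

import numpy as np
import pandas as pd
import pytest

import circfish as cf


def small_config(**overrides):
    defaults = dict(field_shape=(16, 256, 256), n_cells=2, rng_seed=7)
    defaults.update(overrides)
    return cf.SimulationConfig(**defaults)


class TestGenerateCells:
    def test_single_cell_has_one_label_and_nucleus_inside_cell(self):
        nuc, cells = cf.generate_cells(small_config(n_cells=1))
        assert set(np.unique(nuc)) == {0, 1}
        assert set(np.unique(cells)) == {0, 1}
        assert (cells[nuc == 1] == 1).all()

    def test_deterministic_under_seed(self):
        cfg = small_config(n_cells=3, field_shape=(16, 384, 384))
        a = cf.generate_cells(cfg)
        b = cf.generate_cells(cfg)
        assert np.array_equal(a[0], b[0]) and np.array_equal(a[1], b[1])

    def test_many_nuclei_pairwise_disjoint(self):
        cfg = small_config(n_cells=25, field_shape=(16, 1024, 1024), rng_seed=1)
        nuc, cells = cf.generate_cells(cfg)
        labels = set(np.unique(nuc)) - {0}
        assert len(labels) == 25
        # exhaustive pairwise check: each pixel carries exactly one label,
        # and every nucleus is 4-connected to only its own territory
        for lab in labels:
            assert (cells[nuc == lab] == lab).all()

    def test_field_too_small_raises(self):
        with pytest.raises(ValueError, match="larger field"):
            cf.generate_cells(small_config(field_shape=(16, 64, 64)))


class TestSampleMolecules:
    def test_zero_means_give_empty_table(self):
        cfg = small_config(mean_counts={"linear": 0, "circular": 0, "fragment": 0})
        nuc, cells = cf.generate_cells(cfg)
        gt = cf.sample_molecules(cfg, nuc, cells)
        assert len(gt.molecules) == 0

    def test_nuclear_fraction_within_binomial_bounds(self):
        cfg = cf.SimulationConfig(
            field_shape=(16, 1024, 1024), n_cells=20, rng_seed=5,
            mean_counts={"linear": 50.0, "circular": 0.0, "fragment": 0.0},
            nuclear_fraction={"linear": 0.25, "circular": 0.5, "fragment": 0.25},
        )
        nuc, cells = cf.generate_cells(cfg)
        gt = cf.sample_molecules(cfg, nuc, cells)
        n = len(gt.molecules)
        observed = (gt.molecules["compartment"] == "nuclear").mean()
        sd = np.sqrt(0.25 * 0.75 / n)
        assert abs(observed - 0.25) < 3 * sd

    def test_total_count_within_poisson_bounds(self):
        cfg = cf.SimulationConfig(
            field_shape=(16, 1024, 1024), n_cells=20, rng_seed=9,
            mean_counts={"linear": 0.0, "circular": 10.0, "fragment": 0.0},
        )
        nuc, cells = cf.generate_cells(cfg)
        gt = cf.sample_molecules(cfg, nuc, cells)
        expected = 200.0
        assert abs(len(gt.molecules) - expected) < 3 * np.sqrt(expected)

    def test_compartment_flag_consistent_with_nuclear_mask(self):
        cfg = small_config(rng_seed=3)
        nuc, cells = cf.generate_cells(cfg)
        gt = cf.sample_molecules(cfg, nuc, cells)
        y = np.rint(gt.molecules["y_nm"] / cfg.voxel_size_nm[1]).astype(int)
        x = np.rint(gt.molecules["x_nm"] / cfg.voxel_size_nm[2]).astype(int)
        on_nucleus = nuc[y, x] > 0
        assert np.array_equal(on_nucleus, gt.molecules["compartment"] == "nuclear")
        assert np.array_equal(nuc[y, x] * 0 + cells[y, x], gt.molecules["cell_id"])

    def test_fixed_count_model(self):
        cfg = small_config(count_model="fixed")
        nuc, cells = cf.generate_cells(cfg)
        gt = cf.sample_molecules(cfg, nuc, cells)
        assert gt.class_counts() == {"linear": 60, "circular": 20, "fragment": 6}


class TestRender:
    def test_empty_ground_truth_renders_pure_background(self, molecule_table):
        cfg = small_config(n_cells=1, noise=False)
        nuc, cells = cf.generate_cells(cfg)
        gt = cf.GroundTruth(molecule_table([], "linear").iloc[:0], nuc, cells, cfg)
        stack = cf.render(gt, cfg)
        for name in ("PL", "PC"):
            assert np.all(stack[name] == cfg.background_level)

    def test_single_linear_molecule_coemits_in_both_channels(
        self, single_molecule_stack
    ):
        _, _, stack = single_molecule_stack
        pl_peak = np.unravel_index(np.argmax(stack["PL"]), stack.shape)
        pc_peak = np.unravel_index(np.argmax(stack["PC"]), stack.shape)
        assert pl_peak == pc_peak

    def test_integrated_intensity_matches_gaussian_integral(self, molecule_table):
        cfg = cf.SimulationConfig(
            field_shape=(16, 128, 128), n_cells=1, rng_seed=0, noise=False,
            registration_sd_nm=0.0, nucleus_semiaxis_px=(20.0, 28.0),
            cyto_radius_px=20,
        )
        rng = np.random.default_rng(12)
        # keep every molecule >4 sigma from all borders so no flux is clipped
        positions = [
            (
                rng.uniform(1500, 1600),
                rng.uniform(1500, 128 * 130 - 1500),
                rng.uniform(1500, 128 * 130 - 1500),
            )
            for _ in range(50)
        ]
        maps = np.ones((128, 128), dtype=np.int32)
        gt = cf.GroundTruth(molecule_table(positions, "circular"), maps, maps, cfg)
        stack = cf.render(gt, cfg, channels=("PC",))
        integrated = (stack["PC"] - cfg.background_level).sum()
        vz, vy, vx = cfg.voxel_size_nm
        sigma_vox = (350 / vz, 170 / vy, 170 / vx)
        expected = 50 * cfg.spot_amplitude * (2 * np.pi) ** 1.5 * np.prod(sigma_vox)
        assert integrated == pytest.approx(expected, rel=0.01)

    def test_bit_exact_reproducibility_with_noise(self):
        cfg = small_config(noise=True)
        first = cf.simulate_scene(cfg)
        second = cf.simulate_scene(cfg)
        pd.testing.assert_frame_equal(first[0].molecules, second[0].molecules)
        for name in first[1].channels:
            assert np.array_equal(first[1][name], second[1][name])

    def test_min_separation_respected(self, molecule_table):
        cfg = small_config(
            n_cells=1, min_molecule_separation_nm=600.0, count_model="fixed",
            mean_counts={"linear": 40, "circular": 20, "fragment": 5},
        )
        nuc, cells = cf.generate_cells(cfg)
        gt = cf.sample_molecules(cfg, nuc, cells)
        pos = gt.molecules[["z_nm", "y_nm", "x_nm"]].to_numpy()
        from scipy.spatial import cKDTree

        d, _ = cKDTree(pos).query(pos, k=2)
        assert d[:, 1].min() >= 600.0


class TestScenarios:
    @pytest.fixture(scope="class")
    def ground_truth(self):
        cfg = cf.SimulationConfig(
            field_shape=(16, 1024, 1024), n_cells=20, rng_seed=17,
            mean_counts={"linear": 40.0, "circular": 20.0, "fragment": 5.0},
        )
        nuc, cells = cf.generate_cells(cfg)
        return cf.sample_molecules(cfg, nuc, cells)

    def test_zero_time_is_identity(self, ground_truth):
        after = cf.apply_rnase_r(ground_truth, 0.0)
        pd.testing.assert_frame_equal(after.molecules, ground_truth.molecules)

    def test_negative_time_rejected(self, ground_truth):
        with pytest.raises(ValueError):
            cf.apply_rnase_r(ground_truth, -1.0)

    def test_linear_survival_follows_half_life(self, ground_truth):
        n_linear = (ground_truth.molecules["rna_class"] == "linear").sum()
        after = cf.apply_rnase_r(ground_truth, 4.0, linear_half_life_h=1.0)
        survivors = (after.molecules["rna_class"] == "linear").sum()
        p = 2.0 ** -4
        sd = np.sqrt(n_linear * p * (1 - p))
        assert abs(survivors - n_linear * p) < 3 * sd

    def test_circular_survival_follows_half_life(self, ground_truth):
        n_circ = (ground_truth.molecules["rna_class"] == "circular").sum()
        after = cf.apply_rnase_r(ground_truth, 24.0, circular_half_life_h=48.0)
        survivors = (after.molecules["rna_class"] == "circular").sum()
        p = 2.0 ** -0.5  # ~70.7%
        sd = np.sqrt(n_circ * p * (1 - p))
        assert abs(survivors - n_circ * p) < 3 * sd

    def test_digestion_monotone_in_time(self, ground_truth):
        t1 = cf.apply_rnase_r(ground_truth, 1.0)
        t2 = cf.apply_rnase_r(ground_truth, 2.0)
        assert set(t2.molecules["molecule_id"]) <= set(t1.molecules["molecule_id"])

    def test_knockdown_identity_and_complete(self, ground_truth):
        same = cf.apply_knockdown(ground_truth, "circular", 0.0)
        pd.testing.assert_frame_equal(same.molecules, ground_truth.molecules)
        gone = cf.apply_knockdown(ground_truth, "circular", 1.0)
        counts = gone.class_counts()
        assert counts["circular"] == 0
        assert counts["linear"] == ground_truth.class_counts()["linear"]

    def test_partial_knockdown_within_binomial_bounds(self, ground_truth):
        n_circ = ground_truth.class_counts()["circular"]
        after = cf.apply_knockdown(ground_truth, "circular", 0.8)
        survivors = after.class_counts()["circular"]
        sd = np.sqrt(n_circ * 0.2 * 0.8)
        assert abs(survivors - 0.2 * n_circ) < 3 * sd

    def test_multiplex_render_has_one_channel_per_circrna(self, ground_truth):
        cfg = cf.SimulationConfig(
            field_shape=(16, 256, 256), n_cells=1, rng_seed=2, noise=False,
            mean_counts={"linear": 0.0, "circular": 5.0, "fragment": 0.0},
        )
        nuc, cells = cf.generate_cells(cfg)
        gt_a = cf.sample_molecules(cfg, nuc, cells)
        stack = cf.render_multiplex({"PC_ZNF609": gt_a, "PC_CSNK1G3": gt_a}, cfg)
        assert set(stack.channels) == {"PC_ZNF609", "PC_CSNK1G3", "DAPI"}
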