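"""Nuclear segmentation, spot assignment and per-cell statistics."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

import circfish as cf
from circfish.quantify import SegmentationParams, star_code


def pooled_t(a, b):
    """Independent oracle: textbook pooled-variance two-sample t."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    na, nb = len(a), len(b)
    sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    t = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / na + 1 / nb))
    p = 2 * sps.t.sf(abs(t), na + nb - 2)
    return t, p


class TestSegmentNuclei:
    def test_simulator_nuclei_recovered_pixel_perfect(self):
        cfg = cf.SimulationConfig(
            field_shape=(16, 1024, 1024), n_cells=10, rng_seed=21, noise=False,
            mean_counts={"linear": 0.0, "circular": 0.0, "fragment": 0.0},
        )
        nuc_true, cells_true = cf.generate_cells(cfg)
        gt = cf.GroundTruth(
            cf.sample_molecules(cfg, nuc_true, cells_true).molecules,
            nuc_true, cells_true, cfg,
        )
        stack = cf.render(gt, cfg, channels=("DAPI",))
        maps = cf.segment_nuclei(stack["DAPI"])
        assert len(maps.cell_ids) == 10
        for lab in set(np.unique(nuc_true)) - {0}:
            truth = nuc_true == lab
            seg_label = np.bincount(maps.nuclear_labels[truth]).argmax()
            seg = maps.nuclear_labels == seg_label
            jaccard = (truth & seg).sum() / (truth | seg).sum()
            assert jaccard >= 0.99

    def test_blank_dapi_rejected(self):
        with pytest.raises(ValueError, match="no nuclei"):
            cf.segment_nuclei(np.zeros((8, 128, 128)))

    def test_close_nuclei_split_by_watershed(self):
        from skimage.draw import disk

        img = np.zeros((200, 200))
        for center in ((100, 70), (100, 111)):  # 5-pixel background gap
            rr, cc = disk(center, 18)
            img[rr, cc] = 300.0
        maps = cf.segment_nuclei(
            img, SegmentationParams(peak_min_distance_px=10, min_area_px=100,
                                    exclude_border_cells=False)
        )
        assert len(maps.cell_ids) == 2


class TestAssignAndCount:
    @pytest.fixture(scope="class")
    def assigned_scene(self, noise_free_scene):
        cfg, gt, stack = noise_free_scene
        maps = cf.CellLabelMap(gt.nuclear_label_map, gt.cell_label_map)
        spots = gt.molecules.rename(columns={"rna_class": "class"})
        annotated = cf.assign_spots(spots, maps, cfg.voxel_size_nm)
        return cfg, gt, maps, annotated

    def test_ground_truth_molecules_assigned_to_their_cells(self, assigned_scene):
        _, gt, _, annotated = assigned_scene
        ok = annotated["assigned"]
        assert ok.all()
        assert np.array_equal(annotated["cell_id"], gt.molecules["cell_id"])
        assert np.array_equal(annotated["compartment"], gt.molecules["compartment"])

    def test_background_spot_flagged_unassigned(self, assigned_scene):
        cfg, _, maps, _ = assigned_scene
        corner = pd.DataFrame(
            {"class": ["linear"], "z_nm": [0.0], "y_nm": [0.0], "x_nm": [0.0]}
        )
        out = cf.assign_spots(corner, maps, cfg.voxel_size_nm)
        assert not out["assigned"].iloc[0] and out["cell_id"].iloc[0] == 0

    def test_counts_conserve_assigned_spots(self, assigned_scene):
        _, gt, maps, annotated = assigned_scene
        counts = cf.per_cell_counts(annotated, maps)
        for cls in ("linear", "circular", "fragment"):
            assert counts[cls].sum() == (annotated["class"] == cls).sum()
            assert (counts[f"{cls}_nuclear"] <= counts[cls]).all()

    def test_zero_count_cells_included(self, assigned_scene):
        cfg, gt, maps, annotated = assigned_scene
        empty = annotated.iloc[:0]
        counts = cf.per_cell_counts(empty, maps)
        assert list(counts["cell_id"]) == maps.cell_ids
        assert (counts["linear"] == 0).all()

    def test_counts_from_ground_truth_match_molecule_table(self, noise_free_scene):
        _, gt, _ = noise_free_scene
        counts = cf.counts_from_ground_truth(gt)
        assert counts["linear"].sum() == gt.class_counts()["linear"]
        assert counts["circular_nuclear"].sum() == (
            (gt.molecules["rna_class"] == "circular")
            & (gt.molecules["compartment"] == "nuclear")
        ).sum()


class TestSummarize:
    def counts_frame(self, linear):
        return pd.DataFrame(
            {
                "cell_id": range(1, len(linear) + 1),
                "linear": linear,
                "circular": 0,
                "fragment": 0,
                "linear_nuclear": 0,
                "circular_nuclear": 0,
                "fragment_nuclear": 0,
            }
        )

    def test_condition_against_itself_is_ns(self):
        a = self.counts_frame([10, 12, 11, 13])
        with pytest.warns(UserWarning, match="recommended"):
            out = cf.summarize({"A": a, "B": a.copy()})
        row = out.comparisons.query("`class` == 'linear'").iloc[0]
        assert row["t"] == 0.0 and row["p"] == 1.0 and row["stars"] == "ns"

    def test_pooled_t_on_textbook_samples(self):
        a = self.counts_frame([10, 12, 11, 13])
        b = self.counts_frame([20, 22, 21, 23])
        with pytest.warns(UserWarning):
            out = cf.summarize({"A": a, "B": b})
        row = out.comparisons.query("`class` == 'linear'").iloc[0]
        t_ref, p_ref = pooled_t([10, 12, 11, 13], [20, 22, 21, 23])
        assert t_ref == pytest.approx(-10.954451, abs=1e-6)
        assert row["t"] == pytest.approx(t_ref, abs=1e-9)
        assert row["p"] < 0.001 and row["stars"] == "***"

    def test_t_test_agrees_with_independent_formula(self):
        rng = np.random.default_rng(8)
        for _ in range(100):
            a = rng.poisson(20, size=rng.integers(3, 30)).astype(float)
            b = rng.poisson(rng.integers(10, 30), size=rng.integers(3, 30)).astype(float)
            with pytest.warns(UserWarning):
                out = cf.summarize(
                    {"A": self.counts_frame(a), "B": self.counts_frame(b)}
                )
            row = out.comparisons.query("`class` == 'linear'").iloc[0]
            t_ref, p_ref = pooled_t(a, b)
            assert row["t"] == pytest.approx(t_ref, abs=1e-6)
            assert row["p"] == pytest.approx(p_ref, abs=1e-6)

    def test_ci_halfwidth_is_1p96_sem(self):
        values = [10.0, 12.0, 11.0, 13.0]
        with pytest.warns(UserWarning):
            out = cf.summarize({"A": self.counts_frame(values)})
        row = out.per_condition.query("`class` == 'linear'").iloc[0]
        expected = 1.96 * np.std(values, ddof=1) / 2.0
        assert row["ci95_halfwidth"] == pytest.approx(expected)

    def test_single_cell_condition_skips_test_with_warning(self):
        a = self.counts_frame([10.0])
        b = self.counts_frame([12.0, 14.0])
        with pytest.warns(UserWarning, match="< 2 cells"):
            out = cf.summarize({"A": a, "B": b}, min_cells=1)
        assert len(out.comparisons) == 0

    def test_star_code_mapping(self):
        assert star_code(0.0005) == "***"
        assert star_code(0.01) == "*"
        assert star_code(0.2) == "ns"


class TestLocalizationFractions:
    def test_all_nuclear_gives_fraction_one(self):
        counts = pd.DataFrame(
            {
                "cell_id": [1, 2],
                "linear": [5, 3],
                "circular": [0, 0],
                "fragment": [0, 0],
                "linear_nuclear": [5, 3],
                "circular_nuclear": [0, 0],
                "fragment_nuclear": [0, 0],
            }
        )
        out = cf.localization_fractions(counts)
        linear = out.query("`class` == 'linear'").iloc[0]
        assert linear["nuclear_fraction"] == 1.0
        assert linear["cytoplasmic_fraction"] == 0.0

    def test_absent_class_reports_nan(self):
        counts = pd.DataFrame(
            {
                "cell_id": [1],
                "linear": [5],
                "circular": [0],
                "fragment": [0],
                "linear_nuclear": [2],
                "circular_nuclear": [0],
                "fragment_nuclear": [0],
            }
        )
        out = cf.localization_fractions(counts)
        circ = out.query("`class` == 'circular'").iloc[0]
        assert np.isnan(circ["nuclear_fraction"]) and circ["n_cells"] == 0

    def test_fraction_recovery_from_ground_truth(self):
        cfg = cf.SimulationConfig(
            field_shape=(16, 1024, 1024), n_cells=25, rng_seed=31,
        )
        nuc, cells = cf.generate_cells(cfg)
        gt = cf.sample_molecules(cfg, nuc, cells)
        out = cf.localization_fractions(cf.counts_from_ground_truth(gt))
        linear = out.query("`class` == 'linear'").iloc[0]
        circ = out.query("`class` == 'circular'").iloc[0]
        assert abs(linear["nuclear_fraction"] - 0.25) < 3 * linear["ci95_halfwidth"]
        assert abs(circ["nuclear_fraction"] - 0.50) < 3 * circ["ci95_halfwidth"]
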