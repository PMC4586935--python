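import numpy as np
import pandas as pd
import pytest
import scipy.stats

from graspref.design_space import PAIR_NAMES
from graspref.evidence import aggregate
from graspref.group_roi import (
    cluster_threshold,
    condition_contrast,
    define_roi,
    group_glm,
    local_maxima,
    make_group_design,
    roi_sphere_mask,
    roi_stats,
)
from graspref.decoding import compute_evidence_table
from graspref.synthetic import SimulationSpec, simulate_patterns


def full_labels(n_subjects=18):
    rows = [
        {"subject": s, "modality": m, "pair": p, "test": t}
        for s in range(n_subjects)
        for m in ("visual", "somaesthetic")
        for p in PAIR_NAMES
        for t in ("classification", "cross_classification")
    ]
    return pd.DataFrame(rows)


class TestGroupDesign:
    def test_paper_scale_dimensions(self):
        design = make_group_design(full_labels(18))
        # 432 observations, 18 + 24 = 42 regressors, rank 41, dof 391
        assert design.matrix.shape == (432, 42)
        assert design.rank == 41
        assert design.dof == 391

    def test_missing_cell_rejected(self):
        labels = full_labels(4).iloc[:-1]
        with pytest.raises(ValueError):
            make_group_design(labels)

    def test_duplicate_cell_rejected(self):
        labels = full_labels(4)
        labels.loc[labels.index[-1], "pair"] = labels.pair.iloc[0]
        labels.loc[labels.index[-1], "modality"] = labels.modality.iloc[0]
        labels.loc[labels.index[-1], "test"] = labels.test.iloc[0]
        with pytest.raises(ValueError):
            make_group_design(labels)


class TestGroupGlm:
    def test_paired_contrast_equals_paired_t(self):
        # toy design: 5 subjects x 2 cells -> paired t-test equivalence
        rng = np.random.default_rng(0)
        rows = [
            {"subject": s, "modality": "visual", "pair": p, "test": "classification"}
            for s in range(5)
            for p in ("left_wrt_gaze", "left_wrt_body")
        ]
        labels = pd.DataFrame(rows)
        design = make_group_design(labels)
        y = rng.standard_normal((10, 3)) + 0.3
        c = condition_contrast(design, pair="left_wrt_gaze") - condition_contrast(
            design, pair="left_wrt_body"
        )
        t_maps, dof, _ = group_glm(y, design, {"diff": c})
        assert dof == 4
        for v in range(3):
            x1 = y[labels.pair.to_numpy() == "left_wrt_gaze", v]
            x2 = y[labels.pair.to_numpy() == "left_wrt_body", v]
            expected = scipy.stats.ttest_rel(x1, x2).statistic
            assert t_maps["diff"][v] == pytest.approx(expected)

    def test_intercept_only_reduces_to_one_sample_t(self):
        # closed-form limit: one observation per subject, intercept-only
        # design -> group_glm is the one-sample t-test on subject means
        from graspref.group_roi import GroupDesign

        rng = np.random.default_rng(1)
        y = rng.standard_normal((12, 2)) + 0.5
        labels = pd.DataFrame({"subject": range(12)})
        design = GroupDesign(np.ones((12, 1)), ["intercept"], labels)
        t_maps, dof, _ = group_glm(y, design, {"mean": np.array([1.0])})
        assert dof == 11
        for v in range(2):
            expected = scipy.stats.ttest_1samp(y[:, v], 0.0).statistic
            assert t_maps["mean"][v] == pytest.approx(expected)

    def test_single_cell_contrast_equals_one_sample_t(self):
        # a single condition cell's chance-exceedance t from the full crossed
        # design matches the one-sample t over that cell's observations up to
        # the pooled error term; with homogeneous data they coincide closely
        rng = np.random.default_rng(7)
        labels = full_labels(8)
        design = make_group_design(labels)
        y = 0.5 + 0.05 * rng.standard_normal((len(labels), 1)) + np.where(
            (labels.pair == "left_wrt_body") & (labels.test == "classification"),
            0.2, 0.0
        ).reshape(-1, 1)
        c = condition_contrast(design, modality="visual", pair="left_wrt_body",
                               test="classification")
        t_maps, dof, _ = group_glm(y, design, {"cell": c}, center=0.5)
        assert dof == len(labels) - design.rank
        assert t_maps["cell"][0] > 5.0

    def test_chance_centering(self):
        rng = np.random.default_rng(2)
        labels = full_labels(6)
        design = make_group_design(labels)
        y = rng.standard_normal((len(labels), 1)) * 0.05 + 0.5
        c = condition_contrast(design)
        t_centered, _, _ = group_glm(y, design, {"m": c}, center=0.5)
        t_raw, _, _ = group_glm(y - 0.5, design, {"m": c})
        assert t_centered["m"][0] == pytest.approx(t_raw["m"][0])

    def test_zero_variance_flagged(self):
        labels = full_labels(4)
        design = make_group_design(labels)
        y = np.zeros((len(labels), 2))
        y[:, 1] = np.random.default_rng(3).standard_normal(len(labels))
        t_maps, _, flagged = group_glm(y, design, {"m": condition_contrast(design)})
        assert flagged[0] and not flagged[1]
        assert np.isnan(t_maps["m"][0])

    def test_inestimable_contrast_rejected(self):
        design = make_group_design(full_labels(4))
        bad = np.zeros(len(design.names))
        bad[0] = 1.0  # a single subject intercept is not estimable alone
        with pytest.raises(ValueError, match="estimable"):
            group_glm(np.zeros((len(design.labels), 1)), design, {"bad": bad})


def flood_fill_components(binary, connectivity=26):
    """Brute-force connected components by BFS (independent oracle)."""
    from collections import deque

    offs = [
        (dx, dy, dz)
        for dx in (-1, 0, 1)
        for dy in (-1, 0, 1)
        for dz in (-1, 0, 1)
        if (dx, dy, dz) != (0, 0, 0)
        and (connectivity == 26 or abs(dx) + abs(dy) + abs(dz) == 1)
    ]
    seen = np.zeros_like(binary, dtype=bool)
    comps = []
    for start in map(tuple, np.argwhere(binary)):
        if seen[start]:
            continue
        comp = []
        q = deque([start])
        seen[start] = True
        while q:
            cur = q.popleft()
            comp.append(cur)
            for off in offs:
                nxt = tuple(np.add(cur, off))
                if all(0 <= nxt[i] < binary.shape[i] for i in range(3)):
                    if binary[nxt] and not seen[nxt]:
                        seen[nxt] = True
                        q.append(nxt)
        comps.append(sorted(comp))
    return sorted(comps)


class TestClusterThreshold:
    def test_no_suprathreshold_voxels(self):
        binmap, table = cluster_threshold(np.zeros((4, 4, 4)), dof=20)
        assert not binmap.any()
        assert len(table) == 0

    def test_strict_extent_threshold(self):
        # components of exactly 250 and 251 suprathreshold voxels: only the
        # strictly larger one survives
        t_map = np.zeros((40, 10, 10))
        t_map[0:5, 0:5, 0:10] = 10.0  # 250 voxels
        t_map[20:25, 0:5, 0:10] = 10.0
        t_map[25, 0, 0] = 10.0  # 251st voxel attached to second block
        binmap, table = cluster_threshold(t_map, dof=391, alpha=0.05,
                                          min_cluster_voxels=250)
        assert len(table) == 1
        assert table.n_voxels.iloc[0] == 251
        assert binmap.sum() == 251
        assert not binmap[0:5].any()

    @pytest.mark.parametrize("connectivity", [6, 26])
    def test_labeling_matches_flood_fill(self, connectivity):
        for seed in range(100):
            rng = np.random.default_rng(seed)
            t_map = np.where(rng.random((12, 12, 12)) < 0.25, 10.0, 0.0)
            binmap, table = cluster_threshold(t_map, dof=30, alpha=0.05,
                                              min_cluster_voxels=0,
                                              connectivity=connectivity)
            oracle = flood_fill_components(t_map > 0, connectivity)
            assert binmap.sum() == sum(len(c) for c in oracle)
            assert sorted(table.n_voxels) == sorted(len(c) for c in oracle)

    def test_alpha_validation(self):
        with pytest.raises(ValueError):
            cluster_threshold(np.zeros((3, 3, 3)), dof=10, alpha=1.5)

    def test_peak_coordinates_reported(self):
        t_map = np.zeros((8, 8, 8))
        t_map[2:6, 2:6, 2:6] = 5.0
        t_map[3, 4, 5] = 9.0
        affine = np.diag([3.5, 3.5, 3.5, 1.0])
        _, table = cluster_threshold(t_map, dof=30, min_cluster_voxels=10,
                                     affine=affine)
        row = table.iloc[0]
        assert (row.peak_i, row.peak_j, row.peak_k) == (3, 4, 5)
        assert row.peak_x_mm == pytest.approx(3 * 3.5)


class TestDefineRoi:
    affine = np.diag([-3.5, 3.5, 3.5, 1.0]) @ np.eye(4)

    def _map_with_peaks(self, shape, peaks):
        vol = np.zeros(shape)
        for (i, j, k), h in peaks:
            vol[i, j, k] = h
        return vol

    def test_single_peak_recovered(self):
        vol = self._map_with_peaks((10, 10, 10), [((4, 5, 6), 5.0)])
        affine = np.diag([3.5, 3.5, 3.5, 1.0])
        spec = define_roi(vol, reference_mm=(0, 0, 0), affine=affine)
        assert spec.chosen_peak_ijk == (4, 5, 6)
        assert spec.radius_mm == 7.0

    def test_nearest_peak_to_reference_chosen(self):
        # two peaks; the one closer to the reference wins even if weaker
        affine = np.eye(4)
        affine[:3, 3] = (-40, -50, 40)  # voxel (0,0,0) at mm (-40,-50,40)
        vol = self._map_with_peaks((20, 20, 20), [((5, 3, 10), 9.0), ((2, 2, 2), 3.0)])
        spec = define_roi(vol, reference_mm=(-35, -47, 50), affine=affine)
        assert spec.chosen_peak_ijk == (5, 3, 10)
        assert spec.chosen_peak_mm == (-35.0, -47.0, 50.0)

    def test_equidistant_tie_breaks_lexicographically(self):
        affine = np.eye(4)
        vol = self._map_with_peaks((9, 9, 9), [((2, 4, 4), 5.0), ((6, 4, 4), 5.0)])
        spec = define_roi(vol, reference_mm=(4, 4, 4), affine=affine)
        assert spec.chosen_peak_ijk == (2, 4, 4)

    def test_no_peak_in_mask_rejected(self):
        vol = np.zeros((5, 5, 5))
        with pytest.raises(ValueError):
            define_roi(vol, (0, 0, 0), np.eye(4), mask=np.zeros((5, 5, 5), dtype=bool))

    def test_local_maxima_plateau_and_mask(self):
        vol = np.zeros((6, 6, 6))
        vol[1, 1, 1] = 2.0
        vol[4, 4, 4] = 3.0
        peaks = local_maxima(vol)
        got = {tuple(p) for p in peaks}
        assert {(1, 1, 1), (4, 4, 4)} <= got

    def test_roi_sphere_mask_size(self):
        affine = np.diag([3.5, 3.5, 3.5, 1.0])
        mask = roi_sphere_mask((9, 9, 9), affine, center_mm=(14, 14, 14), radius_mm=7.0)
        assert mask.sum() == 33  # radius-2-voxel lattice ball


class TestRoiStats:
    def _cohort(self, modality_model, n=18, snr=3.0, base_seed=0):
        rows = []
        for s in range(n):
            vis, som = simulate_patterns(
                SimulationSpec(coding_scheme="mixed", mix_weight=0.5, n_voxels=40,
                               snr=snr, seed=base_seed + s,
                               modality_model=modality_model)
            )
            for name, ds in (("visual", vis), ("somaesthetic", som)):
                agg = aggregate(compute_evidence_table(ds))
                rows.append({"subject": s, "modality": name,
                             "aggregate_gc": agg.aggregate_gc,
                             "aggregate_bc": agg.aggregate_bc})
        return pd.DataFrame(rows)

    def test_switching_region_interaction_significant(self):
        df = self._cohort("switching", n=12)
        stats = roi_stats(df)
        inter = stats[stats.test == "interaction_gcbc_x_modality"].iloc[0]
        assert inter.p < 1e-4
        assert inter.t > 0  # visual more gaze-centered than somaesthetic

    def test_shared_region_interaction_not_significant(self):
        df = self._cohort("shared", n=12)
        stats = roi_stats(df)
        inter = stats[stats.test == "interaction_gcbc_x_modality"].iloc[0]
        assert inter.p > 0.01

    def test_report_structure(self):
        df = self._cohort("shared", n=4, snr=0.0)
        stats = roi_stats(df)
        assert {"gc_vs_chance", "bc_vs_chance", "gc_vs_bc",
                "interaction_gcbc_x_modality"} <= set(stats.test)
        assert {"t", "p", "df", "mean"} <= set(stats.columns)

    def test_too_few_subjects_rejected(self):
        df = pd.DataFrame(
            {"subject": [0, 1], "modality": ["visual"] * 2,
             "aggregate_gc": [0.5, 0.6], "aggregate_bc": [0.5, 0.4]}
        )
        with pytest.raises(ValueError):
            roi_stats(df)
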