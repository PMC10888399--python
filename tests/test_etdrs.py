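"""ETDRS geometry, sectorization, subsets and t-test ranking."""

import numpy as np
import pandas as pd
import pytest

from fliopipe.etdrs import (
    FEATURE_NAMES,
    SECTORS,
    SUBSETS,
    GridGeometry,
    TTestResult,
    build_feature_table,
    build_masks,
    extract_features,
    sector_mean,
    select_subset,
    subset_columns,
    ttest_rank,
)
from fliopipe.model import FeatureTable, FlioMeasurement


def brute_force_sector_means(matrix, geometry):
    """Per-pixel loop oracle: ring by radius in mm, quadrant by angle."""
    cy, cx = geometry.center_px
    pitch = geometry.mm_per_pixel
    r_c, r_ir, r_or = geometry.ring_radii_mm
    sums = {s: 0.0 for s in SECTORS}
    counts = {s: 0 for s in SECTORS}
    for i in range(matrix.shape[0]):
        for j in range(matrix.shape[1]):
            dy, dx = (cy - i) * pitch, (j - cx) * pitch
            r = (dy * dy + dx * dx) ** 0.5
            if r > r_or:
                continue
            if r <= r_c:
                sec = "C"
            else:
                ring = "1" if r <= r_ir else "2"
                if abs(dy) >= abs(dx):
                    quad = "S" if dy > 0 else "I"
                else:
                    horiz = "T" if dx < 0 else "N"  # OD orientation
                    if geometry.laterality == "OS":
                        horiz = "N" if horiz == "T" else "T"
                    quad = horiz
                sec = quad + ring
            v = matrix[i, j]
            if np.isfinite(v):
                sums[sec] += v
                counts[sec] += 1
    return {s: (sums[s] / counts[s] if counts[s] else np.nan) for s in SECTORS}


class TestGeometry:
    def test_ring_radii_in_pixels(self):
        g = GridGeometry()
        radii = [r / g.mm_per_pixel for r in g.ring_radii_mm]
        np.testing.assert_allclose(radii, [14.2222, 42.6667, 85.3333], rtol=1e-4)

    def test_outer_radius_must_fit(self):
        # a 10-degree field spans only 3 mm, so the 6 mm grid cannot fit
        with pytest.raises(ValueError, match="exceeds"):
            GridGeometry(field_of_view_deg=10.0)

    def test_mask_partition_exact(self):
        g = GridGeometry()
        masks = build_masks(g)
        total = np.zeros(g.image_shape, dtype=int)
        for s in SECTORS:
            total += masks[s].astype(int)
        assert total.max() == 1  # pairwise disjoint
        inside = g.radius_mm() <= g.ring_radii_mm[2]
        assert np.array_equal(total.astype(bool), inside)

    def test_mask_areas_match_circle_areas(self):
        g = GridGeometry()
        masks = build_masks(g)
        r_px = [r / g.mm_per_pixel for r in g.ring_radii_mm]
        areas = {
            "C": np.pi * r_px[0] ** 2,
            "inner": np.pi * (r_px[1] ** 2 - r_px[0] ** 2),
            "outer": np.pi * (r_px[2] ** 2 - r_px[1] ** 2),
        }
        assert masks["C"].sum() == pytest.approx(areas["C"], rel=0.01)
        inner = sum(masks[q + "1"].sum() for q in "NSTI")
        outer = sum(masks[q + "2"].sum() for q in "NSTI")
        assert inner == pytest.approx(areas["inner"], rel=0.01)
        assert outer == pytest.approx(areas["outer"], rel=0.01)

    def test_center_pixel_in_central_disc(self):
        g = GridGeometry(image_shape=(255, 255))  # odd size: exact center pixel
        masks = build_masks(g)
        assert masks["C"][127, 127]

    def test_od_os_swaps_nasal_temporal_only(self):
        od = build_masks(GridGeometry(laterality="OD"))
        os_ = build_masks(GridGeometry(laterality="OS"))
        for sec in ("C", "S1", "I1", "S2", "I2"):
            assert np.array_equal(od[sec], os_[sec])
        for ring in "12":
            assert np.array_equal(od["N" + ring], os_["T" + ring])
            assert np.array_equal(od["T" + ring], os_["N" + ring])

    def test_os_equals_mirrored_od(self, rng):
        """Extracting from an OS image == extracting its horizontal mirror with OD geometry."""
        od = build_masks(GridGeometry(laterality="OD"))
        os_ = build_masks(GridGeometry(laterality="OS"))
        # exact pixel-set symmetry of the masks under horizontal mirroring
        for sec in SECTORS:
            assert np.array_equal(os_[sec], np.fliplr(od[sec]))
        matrix = rng.normal(250, 20, (256, 256))
        os_means = sector_mean(matrix, os_)
        od_means = sector_mean(np.fliplr(matrix), od)
        for sec in SECTORS:
            np.testing.assert_allclose(os_means[sec], od_means[sec], rtol=1e-12)


class TestSectorMean:
    def test_constant_matrix(self):
        masks = build_masks(GridGeometry())
        means = sector_mean(np.full((256, 256), 7.25), masks)
        assert all(v == 7.25 for v in means.values())

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_oracle(self, seed):
        g = GridGeometry(image_shape=(64, 64))
        rng = np.random.default_rng(seed)
        matrix = rng.normal(250, 30, (64, 64))
        matrix[rng.random((64, 64)) < 0.05] = np.nan
        fast = sector_mean(matrix, build_masks(g))
        slow = brute_force_sector_means(matrix, g)
        for sec in SECTORS:
            np.testing.assert_allclose(fast[sec], slow[sec], rtol=1e-12)

    def test_missing_aware_mean(self):
        g = GridGeometry()
        masks = build_masks(g)
        matrix = np.full((256, 256), 10.0)
        c_idx = np.argwhere(masks["C"])
        half = c_idx[: len(c_idx) // 2]
        matrix[half[:, 0], half[:, 1]] = np.nan
        means = sector_mean(matrix, masks)
        assert means["C"] == 10.0

    def test_all_missing_sector_is_nan(self):
        g = GridGeometry()
        masks = build_masks(g)
        matrix = np.full((256, 256), 10.0)
        matrix[masks["C"]] = np.nan
        assert np.isnan(sector_mean(matrix, masks)["C"])

    def test_shape_mismatch_fatal(self):
        masks = build_masks(GridGeometry())
        with pytest.raises(ValueError, match="shape"):
            sector_mean(np.zeros((64, 64)), masks)


class TestExtractFeatures:
    def test_constant_measurement(self):
        tau = {ch: np.full((256, 256), 250.0) for ch in ("SSC", "LSC")}
        inten = {ch: np.full((256, 256), 100.0) for ch in ("SSC", "LSC")}
        vec = extract_features(FlioMeasurement("s", "OD", tau, inten))
        assert len(vec) == 36 and list(vec.index) == list(FEATURE_NAMES)
        assert (vec[[n for n in FEATURE_NAMES if n.startswith("tau_m")]] == 250.0).all()
        assert (vec[[n for n in FEATURE_NAMES if n.startswith("intensity")]] == 100.0).all()

    def test_heavy_smokers_shifted_in_inner_ring_ssc(self, default_table):
        feats = default_table.features
        labels = np.array(default_table.labels)
        ir_ssc = [f"tau_m_SSC_{s}" for s in ("N1", "S1", "T1", "I1")]
        heavy = feats.loc[labels == "heavy_smoker", ir_ssc].mean().mean()
        non = feats.loc[labels == "non_smoker", ir_ssc].mean().mean()
        assert heavy - non > 5.0  # dose-weighted +15 ps effect


class TestSubsets:
    # cardinalities as printed in the experiment tables
    @pytest.mark.parametrize(
        "name,n",
        [
            ("all", 36), ("intensity", 18), ("tau_m", 18), ("tau_ssc", 9),
            ("tau_lsc", 9), ("tau_ir", 8), ("tau_or", 8),
            ("tau_ir_ssc_or_lsc", 8), ("tau_or_ssc_ir_lsc", 8),
        ],
    )
    def test_cardinalities(self, name, n):
        assert len(subset_columns(name)) == n

    def test_ir_ssc_or_lsc_columns(self):
        cols = subset_columns("tau_ir_ssc_or_lsc")
        expected = {f"tau_m_SSC_{s}" for s in ("N1", "S1", "T1", "I1")} | {
            f"tau_m_LSC_{s}" for s in ("N2", "S2", "T2", "I2")
        }
        assert set(cols) == expected

    def test_all_is_identity(self, default_table):
        sub = select_subset(default_table, "all")
        assert sub.feature_names == list(FEATURE_NAMES)

    def test_unknown_name_lists_valid_names(self, default_table):
        with pytest.raises(KeyError, match="tau_ir_ssc_or_lsc"):
            select_subset(default_table, "bogus")

    def test_ttest_top3_selects_three_tau_features(self, default_table):
        sub = select_subset(default_table, "ttest_top3")
        assert len(sub.feature_names) == 3
        assert all(name.startswith("tau_m") for name in sub.feature_names)


class TestTTest:
    def test_closed_form_example(self):
        """A = {1,2,3}, B = {4,5,6}: pooled sd 1, df 4 -> t = -3.674, p = 0.0213."""
        table = pd.DataFrame({"f": [1.0, 2, 3, 4, 5, 6]})
        labels = np.array([0, 0, 0, 1, 1, 1])
        (res,) = ttest_rank(table, labels)
        assert res.t == pytest.approx(-3.674, abs=1e-3)
        assert res.p == pytest.approx(0.0213, abs=1e-3)
        assert res.pooled_sd == pytest.approx(1.0)

    def test_identical_groups(self):
        table = pd.DataFrame({"f": [2.0, 2, 2, 2]})
        (res,) = ttest_rank(table, np.array([0, 0, 1, 1]))
        assert res.t == 0.0 and res.p == 1.0

    def test_small_class_fatal(self):
        table = pd.DataFrame({"f": [1.0, 2, 3]})
        with pytest.raises(ValueError, match="at least 2"):
            ttest_rank(table, np.array([0, 0, 1]))

    def test_sorted_by_significance(self, rng):
        n = 40
        labels = np.array([0] * 20 + [1] * 20)
        table = pd.DataFrame(
            {
                "strong": rng.normal(0, 1, n) + labels * 3.0,
                "weak": rng.normal(0, 1, n) + labels * 0.3,
                "null": rng.normal(0, 1, n),
            }
        )
        ranked = ttest_rank(table, labels)
        assert ranked[0].feature == "strong"
        assert [r.p for r in ranked] == sorted(r.p for r in ranked)

    def test_true_effect_features_rank_top_on_synthetic_cohorts(self):
        """Across seeds, the injected IR-SSC / OR-LSC sectors dominate the top ranks."""
        from fliopipe.synthetic import SyntheticConfig, generate_cohort

        effect_features = {f"tau_m_SSC_{s}" for s in ("N1", "S1", "T1", "I1")} | {
            f"tau_m_LSC_{s}" for s in ("N2", "S2", "T2", "I2")
        }
        hits = 0
        n_seeds = 10
        for seed in range(n_seeds):
            cohort, _ = generate_cohort(SyntheticConfig(seed=100 + seed, octa_slabs=()))
            table = build_feature_table(cohort)
            sub = table.restrict_statuses(("non_smoker", "heavy_smoker"))
            tau = sub.select_columns(subset_columns("tau_m"))
            ranked = ttest_rank(tau, sub.binary_labels("heavy_smoker"))
            top3 = {r.feature for r in ranked[:3]}
            if top3 <= effect_features:
                hits += 1
        assert hits >= 9
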