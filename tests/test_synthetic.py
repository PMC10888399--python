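"""Synthetic cohort generator: determinism, design counts, injected effects."""

import numpy as np
import pytest

from fliopipe.etdrs import FEATURE_NAMES, build_feature_table
from fliopipe.synthetic import (
    SyntheticConfig,
    dose_factor,
    generate_cohort,
    generate_flio,
    generate_vessel_mask,
    subject_tau_offsets,
)
from fliopipe.model import SubjectRecord

IR_SSC = [f"tau_m_SSC_{s}" for s in ("N1", "S1", "T1", "I1")]
OR_LSC = [f"tau_m_LSC_{s}" for s in ("N2", "S2", "T2", "I2")]


class TestDesign:
    def test_default_design_counts(self, default_cohort):
        _, cohort, _ = default_cohort
        assert len(cohort.subjects) == 54
        assert len(cohort.flio) == 108
        assert cohort.counts() == {
            "non_smoker": 26,
            "light_smoker": 14,
            "heavy_smoker": 14,
        }

    def test_pack_ranges_respect_heavy_threshold(self, default_cohort):
        _, cohort, _ = default_cohort
        for s in cohort.subjects:
            if s.smoking_status == "light_smoker":
                assert 500 < s.cumulative_packs <= 2500
            elif s.smoking_status == "heavy_smoker":
                assert 2500 < s.cumulative_packs <= 8000
            else:
                assert s.cumulative_packs == 0 and s.years_smoked == 0

    def test_negative_group_size_fatal(self):
        with pytest.raises(ValueError):
            SyntheticConfig(n_light=-1)

    def test_dose_factor_saturates(self):
        cfg = SyntheticConfig()
        assert dose_factor(0, cfg) == 0.0
        assert dose_factor(2500, cfg) == 0.5
        assert dose_factor(9000, cfg) == 1.0

    def test_ground_truth_doses(self, default_cohort):
        cfg, cohort, truth = default_cohort
        for s in cohort.subjects:
            assert truth.dose_factors[s.subject_id] == pytest.approx(
                min(s.cumulative_packs / cfg.dose_saturation_packs, 1.0)
            )
            if s.smoking_status == "non_smoker":
                assert truth.dose_factors[s.subject_id] == 0.0


class TestDeterminism:
    def test_same_seed_bit_identical(self):
        cfg = SyntheticConfig(
            n_non_smokers=2, n_light=1, n_heavy=1, image_shape=(32, 32),
            octa_slabs=("SVC",), octa_shape=(64, 64), seed=9,
        )
        a, _ = generate_cohort(cfg)
        b, _ = generate_cohort(cfg)
        for ma, mb in zip(a.flio, b.flio):
            for ch in ("SSC", "LSC"):
                np.testing.assert_array_equal(ma.tau_m[ch], mb.tau_m[ch])
                np.testing.assert_array_equal(ma.intensity[ch], mb.intensity[ch])
        for oa, ob in zip(a.octa, b.octa):
            np.testing.assert_array_equal(oa.slabs["SVC"], ob.slabs["SVC"])

    def test_different_seed_differs(self):
        cfg = SyntheticConfig(n_non_smokers=1, n_light=0, n_heavy=0,
                              image_shape=(32, 32), octa_slabs=(), seed=1)
        cfg2 = SyntheticConfig(n_non_smokers=1, n_light=0, n_heavy=0,
                               image_shape=(32, 32), octa_slabs=(), seed=2)
        a, _ = generate_cohort(cfg)
        b, _ = generate_cohort(cfg2)
        assert not np.array_equal(a.flio[0].tau_m["SSC"], b.flio[0].tau_m["SSC"])


class TestInjectedEffects:
    def test_nonsmoker_sector_means_at_baseline(self, default_cohort, default_table):
        cfg, _, _ = default_cohort
        labels = np.array(default_table.labels)
        non = default_table.features.loc[labels == "non_smoker", IR_SSC]
        # subject offsets (sd 12) average out over 52 eyes; SE ~ 12/sqrt(26)
        assert abs(non.mean().mean() - cfg.tau_baseline_ps["SSC"]) < 3 * 12 / np.sqrt(26)

    def test_saturated_heavy_smoker_mean_shift_matches_effect(self):
        """Monte-Carlo estimate of the IR-SSC generative mean at full dose."""
        cfg = SyntheticConfig(image_shape=(64, 64), octa_slabs=())
        subject = SubjectRecord("h", 30, "M", 15, 6000)  # dose factor 1.0
        assert dose_factor(subject.cumulative_packs, cfg) == 1.0
        from fliopipe.etdrs import GridGeometry, build_masks

        geom = GridGeometry(image_shape=(64, 64))
        masks = build_masks(geom)
        ir = np.zeros((64, 64), bool)
        for s in ("N1", "S1", "T1", "I1"):
            ir |= masks[s]
        shifts = []
        for rep in range(200):
            rng = np.random.Generator(np.random.PCG64([rep]))
            m = generate_flio(subject, "OD", rng, cfg)
            shifts.append(m.tau_m["SSC"][ir].mean() - cfg.tau_baseline_ps["SSC"])
        # mean shift == effect_ir_ssc_ps within Monte-Carlo error of the
        # spatial field + eye noise (no subject offset passed here)
        se = np.std(shifts, ddof=1) / np.sqrt(len(shifts))
        assert np.mean(shifts) == pytest.approx(cfg.effect_ir_ssc_ps, abs=4 * se + 0.1)

    def test_dose_monotonicity_of_expected_ir_ssc_mean(self):
        """With identical noise, higher cumulative packs shift IR-SSC up."""
        cfg = SyntheticConfig(image_shape=(64, 64), octa_slabs=())
        from fliopipe.etdrs import GridGeometry, build_masks

        masks = build_masks(GridGeometry(image_shape=(64, 64)))
        ir = np.zeros((64, 64), bool)
        for s in ("N1", "S1", "T1", "I1"):
            ir |= masks[s]
        means = []
        for packs in (0, 1000, 2500, 5000, 8000):
            years = 0 if packs == 0 else 10
            subj = SubjectRecord("x", 30, "F", years, packs)
            rng = np.random.Generator(np.random.PCG64([42]))  # same noise each time
            m = generate_flio(subj, "OD", rng, cfg)
            means.append(m.tau_m["SSC"][ir].mean())
        assert all(b >= a for a, b in zip(means, means[1:]))

    def test_effect_locality(self):
        """In expectation, sectors outside IR-SSC and OR-LSC differ between
        groups by < 0.2 x effect (single cohorts carry ~4 ps of subject-offset
        sampling noise, so the check averages over cohort seeds)."""
        tau_cols = [n for n in FEATURE_NAMES if n.startswith("tau_m")]
        off_target = [c for c in tau_cols if c not in IR_SSC + OR_LSC]
        diffs = []
        for seed in range(8):
            cfg = SyntheticConfig(seed=400 + seed, octa_slabs=(), image_shape=(64, 64))
            cohort, _ = generate_cohort(cfg)
            table = build_feature_table(cohort)
            labels = np.array(table.labels)
            heavy = table.features.loc[labels == "heavy_smoker", off_target].mean()
            non = table.features.loc[labels == "non_smoker", off_target].mean()
            diffs.append(heavy - non)
        mean_diff = sum(diffs) / len(diffs)
        assert mean_diff.abs().max() < 0.2 * abs(cfg.effect_ir_ssc_ps)

    def test_eyes_of_one_subject_more_similar_than_random_pairs(self, default_table):
        feats = default_table.features
        centered = feats - feats.mean(axis=0)
        scaled = (centered / feats.std(axis=0)).to_numpy()
        by_subject = {}
        for i, (sid, eye) in enumerate(zip(default_table.subject_ids, default_table.eyes)):
            by_subject.setdefault(sid, {})[eye] = scaled[i]
        within = [
            np.corrcoef(eyes["OD"], eyes["OS"])[0, 1]
            for eyes in by_subject.values()
            if len(eyes) == 2
        ]
        rng = np.random.default_rng(0)
        sids = list(by_subject)
        between = []
        for _ in range(200):
            a, b = rng.choice(len(sids), size=2, replace=False)
            between.append(
                np.corrcoef(by_subject[sids[a]]["OD"], by_subject[sids[b]]["OS"])[0, 1]
            )
        assert np.mean(within) > np.mean(between)

    def test_null_config_removes_group_difference(self, null_table):
        labels = np.array(null_table.labels)
        heavy = null_table.features.loc[labels == "heavy_smoker", IR_SSC].mean().mean()
        non = null_table.features.loc[labels == "non_smoker", IR_SSC].mean().mean()
        # no injected effect: difference only from subject offsets, SE ~ 3.3 ps
        assert abs(heavy - non) < 10.0

    def test_intensity_carries_no_group_signal(self, default_table):
        labels = np.array(default_table.labels)
        int_cols = [n for n in FEATURE_NAMES if n.startswith("intensity")]
        heavy = default_table.features.loc[labels == "heavy_smoker", int_cols].mean().mean()
        non = default_table.features.loc[labels == "non_smoker", int_cols].mean().mean()
        assert abs(heavy - non) < 3.0


class TestVesselGenerator:
    def test_zero_density_all_background(self, rng):
        assert not generate_vessel_mask((64, 64), 0.0, rng).any()

    @pytest.mark.parametrize("density", [0.08, 0.12, 0.2])
    def test_achieved_density_close_to_target(self, rng, density):
        mask = generate_vessel_mask((256, 256), density, rng)
        assert mask.mean() == pytest.approx(density, abs=0.03)

    def test_octa_slabs_independent_of_group_by_default(self):
        """Null-model check: with octa_effect = 0, slab mean intensity does
        not separate non-smokers from heavy smokers (t-test rarely significant)."""
        from scipy import stats

        sig = 0
        n_seeds = 20
        for seed in range(n_seeds):
            cfg = SyntheticConfig(
                n_non_smokers=6, n_light=0, n_heavy=6,
                image_shape=(32, 32), octa_shape=(96, 96),
                octa_slabs=("SVC",), octa_exclude_one_light_smoker=False,
                seed=300 + seed,
            )
            cohort, _ = generate_cohort(cfg)
            status = cohort.status_by_subject
            means = {"non_smoker": [], "heavy_smoker": []}
            for stack in cohort.octa:
                means[status[stack.subject_id]].append(stack.slabs["SVC"].mean())
            _, p = stats.ttest_ind(means["non_smoker"], means["heavy_smoker"])
            if p < 0.05:
                sig += 1
        assert sig <= 0.1 * n_seeds + 1
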