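"""Profiles, relative affinity, mJRL classification, profile comparison."""

import pytest

from facprof import (
    ClassificationThresholds,
    ColumnCalibration,
    RetardationMeasurement,
    SimulationConfig,
    build_profile,
    classify_mjrl,
    compare_profiles,
    relative_affinity,
    run_archetype_experiment,
)
from facprof.errors import ProfileEmptyError, ValidationError
from facprof.profiling import ProfileEntry, SpecificityProfile, load_profile, save_profile

A0 = 2.5e-9


def synthetic_profile(kas, cal=None, name="test"):
    """Profile built directly from a Ka map (0 => below detection)."""
    cal = cal or ColumnCalibration(name, bt_nmol=0.63, kd_ref_M=3.01e-5)
    entries = {
        g: ProfileEntry(None if ka == 0 else 1.0 / ka, ka, ka == 0)
        for g, ka in kas.items()
    }
    return SpecificityProfile(lectin_name=name, entries=entries, calibration=cal)


class TestBuildProfile:
    def test_chained_ka_value(self, ppl3s_cal, panel):
        m = [RetardationMeasurement("001", A0, 20.93)]
        with pytest.warns(UserWarning, match="below detection"):
            profile = build_profile(m, ppl3s_cal, panel)
        entry = profile.entries["001"]
        assert entry.ka_per_M == pytest.approx(3.32e4, rel=1e-2)
        assert not entry.below_detection
        # every other panel glycan is flagged, Ka 0
        assert profile.entries["002"].below_detection
        assert profile.entries["002"].ka_per_M == 0.0

    def test_detection_floor(self, ppl3s_cal, panel):
        m = [RetardationMeasurement("001", A0, 0.2)]
        with pytest.warns(UserWarning):
            profile = build_profile(m, ppl3s_cal, panel)
        assert profile.entries["001"].below_detection
        assert profile.entries["001"].ka_per_M == 0.0

    def test_unknown_glycan_rejected(self, ppl3s_cal, panel):
        m = [RetardationMeasurement("zzz", A0, 5.0)]
        with pytest.raises(ValidationError, match="zzz"):
            build_profile(m, ppl3s_cal, panel)


class TestRelativeAffinity:
    def test_proportional_scaling(self):
        p = synthetic_profile({"g1": 2e6, "g2": 1e6, "g3": 0})
        assert relative_affinity(p) == pytest.approx(
            {"g1": 100.0, "g2": 50.0, "g3": 0.0}
        )

    def test_single_detectable_entry_is_100(self):
        p = synthetic_profile({"g1": 0, "g2": 5e3})
        assert relative_affinity(p)["g2"] == 100.0

    def test_scale_invariance(self):
        kas = {"g1": 2e6, "g2": 1e6, "g3": 4e5}
        a = relative_affinity(synthetic_profile(kas))
        b = relative_affinity(
            synthetic_profile({g: 10 * ka for g, ka in kas.items()})
        )
        assert a == pytest.approx(b)

    def test_all_below_detection_is_error(self):
        p = synthetic_profile({"g1": 0, "g2": 0})
        with pytest.raises(ProfileEmptyError, match="empty"):
            relative_affinity(p)


@pytest.fixture(scope="module")
def runs(panel):
    cfg = SimulationConfig(seed=42)
    return {
        name: run_archetype_experiment(name, panel, cfg)
        for name in ("PPL2A_like", "PPL3_like", "PPL4_like")
    }


class TestClassification:
    def test_strong_complex_binder_is_group_A1(self, runs):
        asg = runs["PPL2A_like"].assignment
        assert (asg.group, asg.subgroup) == ("A", "1")

    def test_weak_paralog_is_also_A1(self, runs):
        asg = runs["PPL3_like"].assignment
        assert (asg.group, asg.subgroup) == ("A", "1")

    def test_mannose_only_binder_is_A_unclassified(self, runs):
        asg = runs["PPL4_like"].assignment
        assert (asg.group, asg.subgroup) == ("A", "unclassified")
        assert "failing_criterion_complex_fraction_min" in asg.evidence

    def test_glycolipids_below_detection_for_complex_binder(self, runs, panel):
        profile = runs["PPL2A_like"].profile
        for gid in panel.ids_in_classes(["glycolipid"]):
            assert profile.entries[gid].below_detection

    def test_mannose_arm_sentinels_for_mannose_binder(self, runs, panel):
        """Only the alpha1-6-arm glycolipids are seen by the PPL4-like lectin."""
        profile = runs["PPL4_like"].profile
        detectable_gl = {
            g for g in panel.ids_in_classes(["glycolipid"])
            if not profile.entries[g].below_detection
        }
        assert detectable_gl == {"914", "915"}

    def test_complex_without_mannose_is_group_B(self, panel):
        # binds complex-type glycans only: below threshold on the mannose axis
        from facprof.glycan_panel import COMPLEX_CLASSES

        kas = {g: 0.0 for g in panel.ids}
        for g in panel.ids_in_classes(COMPLEX_CLASSES):
            kas[g] = 1e6
        asg = classify_mjrl(synthetic_profile(kas), panel)
        assert asg.group == "B"

    def test_rescaling_invariance(self, panel):
        from facprof.glycan_panel import COMPLEX_CLASSES

        kas = {g: 0.0 for g in panel.ids}
        for g in panel.ids_in_classes(COMPLEX_CLASSES):
            kas[g] = 1e6
        a = classify_mjrl(synthetic_profile(kas), panel)
        b = classify_mjrl(
            synthetic_profile({g: 100 * ka for g, ka in kas.items()}), panel
        )
        assert (a.group, a.subgroup) == (b.group, b.subgroup)

    def test_bad_thresholds_rejected(self):
        with pytest.raises(ValidationError):
            ClassificationThresholds(theta_A=1.5)


class TestCompareProfiles:
    def test_uniform_scaling_is_concordant(self, panel):
        kas = {g: 0.0 for g in panel.ids}
        for i, g in enumerate(panel.ids[:40]):
            kas[g] = 1e6 * (1 + i)
        cal = ColumnCalibration("big", bt_nmol=5.0, kd_ref_M=1e-5)
        p1 = synthetic_profile(kas, cal=cal, name="p1")
        p2 = synthetic_profile(
            {g: 0.01 * ka for g, ka in kas.items()}, cal=cal, name="p2"
        )
        res = compare_profiles(p1, p2, panel)
        assert res["concordance"] == pytest.approx(1.0, abs=1e-3)
        assert res["discordant"] == []

    def test_self_comparison(self, panel):
        kas = {g: (1e6 if i % 3 else 0.0) for i, g in enumerate(panel.ids)}
        kas[panel.ids[1]] = 5e6
        p = synthetic_profile(kas)
        res = compare_profiles(p, p, panel)
        assert res["concordance"] == pytest.approx(1.0)
        assert res["discordant"] == []

    def test_archetype_pair_discordant_is_plant_core_glycan(self, panel):
        cfg = SimulationConfig(seed=7)
        r2a = run_archetype_experiment("PPL2A_like", panel, cfg)
        r3 = run_archetype_experiment("PPL3_like", panel, cfg)
        res = compare_profiles(r2a.profile, r3.profile, panel)
        assert res["discordant"] == ["017"]
        # global offset reflects the ~100-fold affinity difference
        assert res["median_log10_offset"] == pytest.approx(2.0, abs=0.2)

    def test_disjoint_detectable_sets_undefined(self, panel):
        ids = list(panel.ids)
        p1 = synthetic_profile({g: (1e6 if g == ids[0] else 0.0) for g in ids})
        p2 = synthetic_profile({g: (1e6 if g == ids[1] else 0.0) for g in ids})
        res = compare_profiles(p1, p2, panel)
        assert res["concordance"] is None


def test_profile_json_round_trip(tmp_path, panel, ppl3s_cal):
    m = [
        RetardationMeasurement("001", A0, 20.93),
        RetardationMeasurement("002", A0, 5.0),
    ]
    with pytest.warns(UserWarning):
        profile = build_profile(m, ppl3s_cal, panel)
    path = tmp_path / "profile.json"
    save_profile(profile, path)
    loaded = load_profile(path)
    assert loaded.entries == profile.entries
    assert loaded.lectin_name == profile.lectin_name
    assert loaded.calibration.bt_nmol == profile.calibration.bt_nmol
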