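"""Interpretive logic: QC, differencing, extent, the classifier cascade."""

import numpy as np
import pytest

from phytascreen.chromatogram import synthesize
from phytascreen.kinetics import (
    CommunityModel,
    EnzymeModel,
    class_profile,
    simulate_timecourse,
)
from phytascreen.profiles import PI_POOL, ClassProfile
from phytascreen.profiling import (
    ClassifierParams,
    analyze_screen,
    classify_activity,
    degradation_extent,
    diff_profiles,
    substrate_qc,
)
from phytascreen.synthetic import ENZYME_PRESETS, make_substrate, preset_enzyme


def norm(**kw):
    return ClassProfile(amounts=dict(kw), normalized=True)


# --- substrate QC ---------------------------------------------------------


def test_qc_clean_substrate_passes():
    rep = substrate_qc(norm(**{"InsP6": 0.95, "InsP5 [1/3-OH]": 0.05}))
    assert rep.impurity == pytest.approx(0.05)
    assert rep.passed
    assert rep.impurity_classes == {"InsP5 [1/3-OH]": 0.05}


def test_qc_pure_and_dirty():
    assert substrate_qc(norm(InsP6=1.0)).impurity == 0.0
    rep = substrate_qc(norm(**{"InsP6": 0.75, "InsP3": 0.25}))
    assert not rep.passed


def test_qc_rejects_unnormalized():
    with pytest.raises(ValueError):
        substrate_qc(ClassProfile(amounts={"InsP6": 2.0}, normalized=True))


# --- differencing and extent ---------------------------------------------


def test_diff_identical_profiles_all_zero():
    p = norm(**{"InsP6": 0.9, PI_POOL: 0.1})
    delta, flagged = diff_profiles(p, p)
    assert all(v == 0 for v in delta.values())
    assert flagged == []


def test_diff_flags_new_product_peaks():
    ref = norm(**{"InsP6": 0.95, "InsP5 [1/3-OH]": 0.05})
    test = norm(**{"InsP6": 0.82, "InsP5 [1/3-OH]": 0.10, PI_POOL: 0.08})
    delta, flagged = diff_profiles(test, ref)
    assert delta["InsP5 [1/3-OH]"] > 0 and delta[PI_POOL] > 0
    assert PI_POOL in flagged


def test_diff_requires_normalized():
    with pytest.raises(ValueError):
        diff_profiles(ClassProfile(amounts={"InsP6": 1.0}), norm(InsP6=1.0))


def test_degradation_extent_bounds():
    t0 = norm(**{"InsP6": 0.95, "InsP5 [1/3-OH]": 0.05})
    assert degradation_extent(t0, t0) == 1.0
    assert degradation_extent(norm(**{"InsP5 [1/3-OH]": 1.0}), t0) == 0.0
    with pytest.raises(ValueError):
        degradation_extent(t0, norm(**{"InsP5 [1/3-OH]": 1.0}))


# --- classifier unit cases -----------------------------------------------

T0 = norm(**{"InsP6": 0.95, "InsP5 [1/3-OH]": 0.05})


def test_classifier_no_activity_iff_loss_below_threshold():
    assert classify_activity(T0, T0).label == "NO_ACTIVITY"
    barely = norm(**{"InsP6": 0.92, "InsP5 [1/3-OH]": 0.05, PI_POOL: 0.03})
    assert classify_activity(barely, T0).label == "NO_ACTIVITY"  # 3.2% loss


def test_classifier_dominant_13oh_is_3phytase():
    tn = norm(**{"InsP6": 0.70, "InsP5 [1/3-OH]": 0.28, "InsP5 [4/6-OH]": 0.02, PI_POOL: 0.2})
    assert classify_activity(tn, T0).label == "PHYTASE_3"


def test_classifier_dominant_46oh_low_5oh_is_46phytase():
    tn = norm(**{"InsP6": 0.40, "InsP5 [4/6-OH]": 0.55, "InsP5 [1/3-OH]": 0.05})
    assert classify_activity(tn, T0).label == "PHYTASE_4_6"


def test_classifier_minpp_gate():
    tn = norm(
        **{
            "InsP6": 0.40,
            "InsP5 [4/6-OH]": 0.48,
            "InsP5 [5-OH]": 0.10,
            "InsP5 [1/3-OH]": 0.02,
        }
    )
    assert classify_activity(tn, T0).label == "MINPP_LIKE"


def test_classifier_dominant_5oh_is_5phytase():
    tn = norm(**{"InsP6": 0.40, "InsP5 [5-OH]": 0.55, "InsP5 [2-OH]": 0.05})
    assert classify_activity(tn, T0).label == "PHYTASE_5"


def test_classifier_2oh_is_unclassified():
    tn = norm(**{"InsP6": 0.40, "InsP5 [2-OH]": 0.60})
    assert classify_activity(tn, T0).label == "UNCLASSIFIED_2POS"


def test_classifier_no_dominant_class_is_mixed():
    tn = norm(
        **{
            "InsP6": 0.30,
            "InsP5 [4/6-OH]": 0.25,
            "InsP5 [1/3-OH]": 0.25,
            "InsP5 [5-OH]": 0.20,
        }
    )
    assert classify_activity(tn, T0).label == "MIXED_COMMUNITY"


def test_classifier_sorption_like_loss_reports_mixed_with_note():
    # InsP6 lost with no InsP5 above threshold: falls through with a note
    res = classify_activity(
        ClassProfile(amounts={"InsP6": 0.3}, normalized=True), T0
    )
    assert res.label == "MIXED_COMMUNITY"
    assert any("sorption" in n for n in res.notes)


def test_classification_invariant_to_scaling_and_pi():
    tn = norm(
        **{
            "InsP6": 0.40,
            "InsP5 [4/6-OH]": 0.48,
            "InsP5 [5-OH]": 0.08,
            "InsP5 [1/3-OH]": 0.02,
            PI_POOL: 0.02,
        }
    )
    base = classify_activity(tn, T0).label
    scaled = ClassProfile(
        amounts={c: 3.7 * v for c, v in tn.items()}, normalized=True
    )
    t0_scaled = ClassProfile(
        amounts={c: 3.7 * v for c, v in T0.items()}, normalized=True
    )
    assert classify_activity(scaled, t0_scaled).label == base
    no_pi = tn.without_pi()
    assert classify_activity(no_pi, T0).label == base


# --- confusion matrix on the pure presets ---------------------------------

EXPECTED_LABEL = {
    "bsubtilis_bpp": "PHYTASE_3",
    "buttiauxella_appa": "PHYTASE_4_6",
    "five_phytase": "PHYTASE_5",
    "ac12_minpp": "MINPP_LIKE",
    "pputida_null": "NO_ACTIVITY",
}


@pytest.mark.parametrize("preset,expected", sorted(EXPECTED_LABEL.items()))
def test_classifier_identity_on_pure_presets(preset, expected):
    """Each pure enzyme preset recovers its own label over 20 random rates."""
    base = preset_enzyme(preset)
    sub = make_substrate()
    rng = np.random.default_rng(99)
    for _ in range(20):
        k = base.k * rng.uniform(0.75, 1.5)
        e = EnzymeModel(base.name, base.class_label, base.weights, k)
        c = CommunityModel(enzymes=[(e, 1.0)])
        tc = simulate_timecourse(c, sub, np.linspace(0, 2, 21))
        pn = class_profile(tc, 2.0, normalize=True)
        p0 = class_profile(tc, 0.0, normalize=True)
        assert classify_activity(pn, p0).label == expected, (preset, k)


# --- noise robustness ------------------------------------------------------


@pytest.mark.parametrize(
    "preset,expected",
    [
        ("pputida_null", "NO_ACTIVITY"),
        ("bsubtilis_bpp", "PHYTASE_3"),
        ("buttiauxella_appa", "PHYTASE_4_6"),
    ],
)
def test_label_stable_under_noise_at_snr20(rt, preset, expected):
    """Labels persist in >= 95% of 100 noisy replicates at S/N 20."""
    e = preset_enzyme(preset)
    c = CommunityModel(enzymes=[(e, 1.0)])
    tc = simulate_timecourse(c, make_substrate(), np.linspace(0, 2, 21))
    p0 = class_profile(tc, 0.0)
    pn = class_profile(tc, 2.0)
    height = max(
        a / (rt.sigma(cl) * np.sqrt(2 * np.pi))
        for cl, a in p0.items()
        if cl in rt.entries and a > 0
    )
    hits = 0
    for seed in range(100):
        c0 = synthesize(p0, rt, noise_sd=height / 20, seed=seed)
        cn = synthesize(pn, rt, noise_sd=height / 20, seed=10_000 + seed)
        rep = analyze_screen(c0, cn, rt)
        hits += rep.classification.label == expected
    assert hits >= 95, hits


def test_analyze_screen_stage_errors_are_labelled(rt):
    import numpy as np

    from phytascreen.chromatogram import Chromatogram

    tiny = Chromatogram(times=np.array([0.0, 0.01]), signal=np.array([0.0, 0.0]))
    with pytest.raises(RuntimeError, match="t0"):
        analyze_screen(tiny, tiny, rt)
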