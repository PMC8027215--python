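"""Standard calibration, density windows, and the labelling criteria."""

import numpy as np
import pytest

from nasip.classify import (
    Status,
    Thresholds,
    calibrate,
    classify,
    classify_table,
    criterion_inter,
    criterion_intra,
    fixed_calibration,
    gc_confound_check,
    partition_windows,
    presence_rule,
)
from nasip.errors import NasipError
from nasip.gradient import (
    GradientSpec,
    Taxon,
    reference_community,
    simulate_gradient,
    simulate_standards,
    REFERENCE_TRUTH,
)

from conftest import make_table

RNA_FRACTION_WIDTH = (1.830 - 1.750) / 12


def _standard(profile, densities, name="std"):
    return make_table([profile], densities, otus=[name], medium="rna")


def test_calibrate_perfectly_separated_standards():
    dens = [1.82, 1.81, 1.80, 1.79, 1.78]
    unlab = _standard([0, 0, 0, 60, 40], dens, "u")
    lab = _standard([30, 50, 20, 0, 0], dens, "l")
    cal = calibrate((unlab, lab))
    # threshold = lightest fraction occupied by the labelled band
    assert cal.threshold_density == pytest.approx(1.80)
    assert cal.source == "standards"
    assert cal.strong_density >= cal.threshold_density


def test_calibrate_identical_standards_falls_back_to_fixed():
    dens = [1.82, 1.81, 1.80]
    unlab = _standard([10, 80, 10], dens, "u")
    lab = _standard([10, 80, 10], dens, "l")
    with pytest.warns(UserWarning, match="fixed"):
        cal = calibrate((unlab, lab))
    assert cal.source == "fixed"
    assert cal.threshold_density == pytest.approx(1.797)


def test_calibrate_simulated_rna_standards_near_reported_threshold():
    """End-to-end: default simulated RNA standards calibrate to within one
    fraction width of the 1.797 g/ml RNA-SIP threshold."""
    spec = GradientSpec(medium="rna", seed=9)
    cal = calibrate(simulate_standards(spec))
    assert abs(cal.threshold_density - 1.797) <= RNA_FRACTION_WIDTH


def test_calibrate_input_validation():
    dens = [1.82, 1.81]
    multi = make_table([[1.0, 2.0], [3.0, 4.0]], dens)
    single = _standard([1, 2], dens)
    with pytest.raises(NasipError, match="single"):
        calibrate((multi, single))
    other_grid = _standard([1, 2], [1.83, 1.80])
    with pytest.raises(NasipError, match="grid"):
        calibrate((single, other_grid))


@pytest.mark.parametrize(
    "medium,density,expected_heavy",
    [
        ("rna", 1.806, True),
        ("rna", 1.797, True),
        ("rna", 1.790, False),
        ("dna", 1.706, True),
        ("dna", 1.6894, False),
    ],
)
def test_partition_windows_threshold(medium, density, expected_heavy):
    cal = fixed_calibration(medium)
    table = make_table([[1.0, 1.0]], [density, density - 0.1])
    win = partition_windows(table, cal)
    assert ("F1" in win.heavy) is expected_heavy


def test_partition_rank_labels_cover_fraction_order():
    table = make_table([np.ones(8)], np.linspace(1.83, 1.75, 8))
    win = partition_windows(table, fixed_calibration("rna"))
    labels = [win.rank_labels[f] for f in table.fraction_ids]
    assert labels == ["heavy", "heavy", "middle", "middle",
                      "light", "light", "ultra-light", "ultra-light"]


def test_empty_heavy_window_means_no_calls():
    table = make_table([[0.9, 0.1], [0.1, 0.9]], [1.70, 1.69],
                       medium="rna", scaled=True)
    cal = fixed_calibration("rna")  # every fraction below 1.797
    calls = classify_table(table, table, cal)
    assert set(calls["status"]) == {Status.UNLABELLED.value}


# -- criteria around the 5-percentage-point boundary -------------------

def _pair(heavy_pct, light_pct, control_pct):
    """Labelled table: F1 heavy, F2 light; control flat at control_pct."""
    dens = [1.81, 1.78]
    rest_h, rest_l = 100 - heavy_pct, 100 - light_pct
    labelled = make_table(
        [[heavy_pct / 100, light_pct / 100], [rest_h / 100, rest_l / 100]],
        dens, otus=["x", "bg"], medium="rna", scaled=True)
    control = make_table(
        [[control_pct / 100, control_pct / 100],
         [1 - control_pct / 100, 1 - control_pct / 100]],
        dens, otus=["x", "bg"], medium="rna", scaled=True)
    return labelled, control


@pytest.mark.parametrize(
    "heavy,control,expected",
    [
        (9.0, 2.0, True),    # +7 points
        (6.0, 2.0, False),   # +4 points
        (6.9, 2.0, False),   # +4.9
        (7.0, 2.0, False),   # exactly +5 -> "more than 5%" fails
        (7.1, 2.0, True),    # +5.1
        (0.0, 0.0, False),   # absent everywhere
    ],
)
def test_criterion_inter_boundary(heavy, control, expected):
    labelled, ctl = _pair(heavy, 1.0, control)
    win = partition_windows(labelled, fixed_calibration("rna"))
    passed, evidence = criterion_inter("x", labelled, ctl, win)
    assert passed is expected
    assert evidence["heavy_max_pct"] == pytest.approx(heavy)
    assert evidence["control_max_pct"] == pytest.approx(control)


@pytest.mark.parametrize(
    "heavy,light,expected",
    [
        (20.0, 3.0, True),
        (6.0, 4.0, False),
        (9.9, 5.0, False),   # +4.9
        (10.0, 5.0, False),  # exactly +5
        (10.1, 5.0, True),   # +5.1
        (8.0, 8.0, False),   # uniform OTU
    ],
)
def test_criterion_intra_boundary(heavy, light, expected):
    labelled, _ = _pair(heavy, light, 1.0)
    win = partition_windows(labelled, fixed_calibration("rna"))
    passed, evidence = criterion_intra("x", labelled, win)
    assert passed is expected
    assert evidence["light_max_pct"] == pytest.approx(light)


def test_criterion_unknown_otu_rejected():
    labelled, ctl = _pair(9.0, 1.0, 2.0)
    win = partition_windows(labelled, fixed_calibration("rna"))
    with pytest.raises(NasipError, match="absent"):
        criterion_inter("nope", labelled, ctl, win)


# -- presence rule ------------------------------------------------------

def test_presence_rule_detects_control_absent_otu():
    labelled, ctl = _pair(90.0, 0.0, 0.0)
    win = partition_windows(labelled, fixed_calibration("rna"))
    assert presence_rule("x", labelled, ctl, win) is True


def test_presence_rule_defers_for_high_background():
    labelled, ctl = _pair(90.0, 0.0, 2.0)  # detectable in controls
    win = partition_windows(labelled, fixed_calibration("rna"))
    assert presence_rule("x", labelled, ctl, win) is False


def test_presence_rule_needs_heavy_detection():
    labelled, ctl = _pair(0.0, 40.0, 0.0)  # only light-fraction presence
    win = partition_windows(labelled, fixed_calibration("rna"))
    assert presence_rule("x", labelled, ctl, win) is False


# -- combined classification -------------------------------------------

def test_classify_requires_both_criteria():
    # passes intra (20 vs 3) but fails inter (control max 18)
    labelled, ctl = _pair(20.0, 3.0, 18.0)
    call = classify("x", labelled, ctl, fixed_calibration("rna"))
    assert call.criterion2 and not call.criterion1
    assert call.status is Status.UNLABELLED


def test_classify_partial_vs_strong_by_peak_density():
    cal = fixed_calibration("rna")
    dens = [1.820, 1.806, 1.780]
    ctl = make_table([[0.02] * 3, [0.98] * 3], dens, otus=["x", "bg"],
                     medium="rna", scaled=True)
    partial = make_table([[0.10, 0.60, 0.05], [0.90, 0.40, 0.95]], dens,
                         otus=["x", "bg"], medium="rna", scaled=True)
    call = classify("x", partial, ctl, cal)
    assert call.status is Status.PARTIALLY_LABELLED
    assert call.peak_density == pytest.approx(1.806)
    strong = make_table([[0.60, 0.10, 0.05], [0.40, 0.90, 0.95]], dens,
                        otus=["x", "bg"], medium="rna", scaled=True)
    call = classify("x", strong, ctl, cal)
    assert call.status is Status.STRONGLY_LABELLED
    assert call.peak_density == pytest.approx(1.820)


def test_classify_low_background_path():
    labelled, ctl = _pair(90.0, 0.0, 0.0)
    call = classify("x", labelled, ctl, fixed_calibration("rna"))
    assert call.background == "low"
    assert call.status is Status.PRESENT_IN_HEAVY


@pytest.mark.parametrize(
    "gc,medium,expected",
    [
        (0.30, "dna", True),   # 1.6894 < 1.702: GC cannot explain heavy DNA
        (0.55, "rna", True),   # 1.780 < 1.797
        (0.60, "dna", False),  # 1.7188 > 1.702: heavy banding may be GC-driven
    ],
)
def test_gc_confound_check(gc, medium, expected):
    assert gc_confound_check(gc, medium, fixed_calibration(medium)) is expected


def test_classify_flags_gc_confounded_call():
    cal = fixed_calibration("dna")
    dens = [1.706, 1.680]
    ctl = make_table([[0.02, 0.02], [0.98, 0.98]], dens, otus=["x", "bg"],
                     scaled=True)
    labelled = make_table([[0.50, 0.02], [0.50, 0.98]], dens,
                          otus=["x", "bg"], scaled=True)
    with pytest.warns(UserWarning, match="GC-driven"):
        call = classify("x", labelled, ctl, cal, gc=0.60)
    assert call.gc_warning
    clean = classify("x", labelled, ctl, cal, gc=0.30)
    assert not clean.gc_warning


def test_raising_delta_never_creates_labelled_calls():
    """Monotonicity: criteria are AND-gated strict thresholds, so a larger
    delta can only demote calls."""
    lab = simulate_gradient(reference_community(True),
                            GradientSpec(medium="dna", seed=4))
    ctl = simulate_gradient(reference_community(False),
                            GradientSpec(medium="dna", seed=10004))
    cal = fixed_calibration("dna")
    labelled_sets = []
    for delta in (2.0, 5.0, 10.0, 30.0, 60.0):
        calls = classify_table(lab, ctl, cal, Thresholds(delta_points=delta))
        labelled_sets.append(
            set(calls.index[calls["status"] != Status.UNLABELLED.value])
        )
    for bigger, smaller in zip(labelled_sets, labelled_sets[1:]):
        assert smaller <= bigger


def test_parameter_recovery_single_run():
    lab = simulate_gradient(reference_community(True),
                            GradientSpec(medium="dna", seed=0))
    ctl = simulate_gradient(reference_community(False),
                            GradientSpec(medium="dna", seed=10000))
    calls = classify_table(lab, ctl, fixed_calibration("dna"))
    for otu, truth in REFERENCE_TRUTH.items():
        assert calls.at[otu, "status"] == truth


def test_no_false_calls_without_labelling():
    """Specificity spot-check: unlabelled community vs unlabelled control."""
    for seed in range(10):
        a = simulate_gradient(reference_community(False),
                              GradientSpec(medium="dna", seed=seed))
        b = simulate_gradient(reference_community(False),
                              GradientSpec(medium="dna", seed=seed + 5000))
        calls = classify_table(a, b, fixed_calibration("dna"))
        high = calls[calls["background"] == "high"]
        assert set(high["status"]) <= {Status.UNLABELLED.value}


def test_presence_rule_recovers_rare_fully_labelled_taxon():
    """Ultra-sensitivity: a fully labelled taxon at 1e-5 community
    abundance is recovered once heavy fractions are sequenceable and its
    expected heavy-fraction read count is >= 10."""
    rare = 1e-5
    community = [
        Taxon("bulk1", 0.30, 0.60 - rare, 0.0),
        Taxon("bulk2", 0.35, 0.20, 0.0),
        Taxon("helper", 0.40, 0.20, 1.0),  # abundant labelled co-occupant
        Taxon("rare", 0.28, rare, 1.0),    # bands below the helper
    ]
    control = [Taxon(t.taxon_id, t.gc, t.abundance, 0.0) for t in community]
    spec = GradientSpec(medium="dna", read_depth=200_000,
                        template_floor=1e-6, seed=21)
    lab = simulate_gradient(community, spec)
    ctl = simulate_gradient(control, GradientSpec(
        medium="dna", read_depth=200_000, template_floor=1e-6, seed=22))
    call = classify("rare", lab, ctl, fixed_calibration("dna"))
    assert call.background == "low"
    assert call.status is Status.PRESENT_IN_HEAVY
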