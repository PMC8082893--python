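import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from guideval import stats as gs
from conftest import make_records


# ---------------------------------------------------------------------------
# Summaries
# ---------------------------------------------------------------------------

def test_all_zero_errors_summarize_to_zero():
    rng = np.random.default_rng(0)
    rec = make_records(rng, sd=1e-12, mean=0.0)
    s = gs.summarize_by_modality(rec)
    assert s["dT_mean"].abs().max() < 1e-9


def test_two_record_hand_arithmetic():
    rows = []
    for i, v in enumerate((1.0, 3.0)):
        for mod in ("CT", "sCT"):
            rows.append(dict(observer=1, specimen=i, bone="radius", location="distal",
                             modality=mod, repeat=0, dx=0, dy=0, dz=0, dT=v,
                             phix=0, phiy=0, phiz=0, dR=0, icp_rms=0, converged=True))
    s = gs.summarize_by_modality(gs.records_frame(rows))
    assert s["dT_mean"].iloc[0] == pytest.approx(2.0)
    assert s["dT_sd"].iloc[0] == pytest.approx(np.sqrt(2.0))


def test_z_dominant_noise_shows_in_summary():
    rng = np.random.default_rng(1)
    rows = []
    for obs in (1, 2):
        for g in range(16):
            for mod in ("CT", "sCT"):
                rows.append(dict(observer=obs, specimen=g, bone="radius",
                                 location="distal", modality=mod, repeat=0,
                                 dx=rng.normal(0, 1), dy=rng.normal(0, 0.5),
                                 dz=rng.normal(0, 2.5), dT=0, phix=0, phiy=0,
                                 phiz=0, dR=0, icp_rms=0, converged=True))
    s = gs.summarize_by_modality(gs.records_frame(rows))
    assert (s["dz_mean"] > s["dx_mean"]).all()
    assert (s["dz_mean"] > s["dy_mean"]).all()


def test_max_diff_columns_hand_case():
    rows = []
    for obs, v in ((1, 1.0), (2, 4.0), (3, 2.0)):
        for mod in ("CT", "sCT"):
            rows.append(dict(observer=obs, specimen=0, bone="radius", location="distal",
                             modality=mod, repeat=0, dx=0, dy=0, dz=0, dT=v,
                             phix=0, phiy=0, phiz=0, dR=v, icp_rms=0, converged=True))
    s = gs.summarize_by_modality(gs.records_frame(rows))
    assert s["dT_max_diff"].iloc[0] == pytest.approx(3.0)  # 4 - 1


def test_missing_modality_raises():
    rng = np.random.default_rng(2)
    rec = make_records(rng)
    only_ct = rec[rec["modality"] == "CT"]
    with pytest.raises(ValueError):
        gs.summarize_by_modality(only_ct)


# ---------------------------------------------------------------------------
# Repeated-measures ANOVA
# ---------------------------------------------------------------------------

def test_identical_modalities_give_zero_F():
    rows = []
    rng = np.random.default_rng(3)
    for g in range(8):
        v = abs(rng.normal(2, 1))
        for mod in ("CT", "sCT"):
            rows.append(dict(observer=1, specimen=g, bone="radius", location="distal",
                             modality=mod, repeat=0, dx=0, dy=0, dz=0, dT=v,
                             phix=0, phiy=0, phiz=0, dR=0, icp_rms=0, converged=True))
    res = gs.rm_anova(gs.records_frame(rows), "dT")
    modality = [r for r in res if r.effect == "modality"][0]
    assert modality.F == pytest.approx(0.0, abs=1e-9)
    assert modality.p == pytest.approx(1.0)


def test_modality_F_equals_paired_t_squared():
    rng = np.random.default_rng(4)
    rows = []
    vals = {}
    for g in range(6):
        for mod in ("CT", "sCT"):
            v = abs(rng.normal(2, 1))
            vals[(g, mod)] = v
            rows.append(dict(observer=1, specimen=g, bone="radius", location="distal",
                             modality=mod, repeat=0, dx=0, dy=0, dz=0, dT=v,
                             phix=0, phiy=0, phiz=0, dR=0, icp_rms=0, converged=True))
    res = gs.rm_anova(gs.records_frame(rows), "dT")
    ct = [vals[(g, "CT")] for g in range(6)]
    sct = [vals[(g, "sCT")] for g in range(6)]
    t, p = sps.ttest_rel(ct, sct)
    modality = [r for r in res if r.effect == "modality"][0]
    assert modality.F == pytest.approx(t**2, rel=1e-9)
    assert modality.p == pytest.approx(p, rel=1e-9)


def test_mixed_anova_reports_observer_effect():
    rng = np.random.default_rng(5)
    rec = make_records(rng, n_guides=8, n_observers=3)
    effects = {r.effect for r in gs.rm_anova(rec, "dT")}
    assert {"modality", "observer"} <= effects


def test_unbalanced_design_raises_with_cells():
    rng = np.random.default_rng(6)
    rec = make_records(rng)
    broken = rec.drop(rec[(rec.observer == 1) & (rec.specimen == 0)
                          & (rec.modality == "sCT")].index)
    with pytest.raises(ValueError, match="unbalanced"):
        gs.rm_anova(broken, "dT")


# ---------------------------------------------------------------------------
# Bland-Altman
# ---------------------------------------------------------------------------

def test_identical_arrays_zero_width_loa():
    vals = np.array([1.0, 2.0, 3.0])
    ba = gs.bland_altman(vals, vals, inter_deviations=np.array([0.1, -0.1, 0.2, -0.2]))
    assert ba.mean_difference == 0.0
    assert ba.loa_low == ba.loa_high == 0.0
    assert ba.fraction_within_inter_loa == 1.0
    assert ba.equivalent


def test_hand_set_differences():
    ct = np.array([1.0, 0.0, 1.0, 0.0])
    sct = np.array([0.0, 1.0, 0.0, 1.0])  # differences +1,-1,+1,-1
    ba = gs.bland_altman(ct, sct)
    assert ba.mean_difference == pytest.approx(0.0)
    sd = np.std([1, -1, 1, -1], ddof=1)  # = 2/sqrt(3)
    assert sd == pytest.approx(2 / np.sqrt(3))
    assert ba.loa_high == pytest.approx(1.96 * sd)


def test_normal_coverage_of_loa():
    rng = np.random.default_rng(7)
    d = rng.normal(0, 1, 10_000)
    ba = gs.bland_altman(d, np.zeros_like(d))
    frac = np.mean((d >= ba.loa_low) & (d <= ba.loa_high))
    assert frac == pytest.approx(0.95, abs=0.01)


def test_inter_rule_max():
    dev = np.array([0.5, -1.5, 1.0, -0.5])
    ba = gs.bland_altman(np.array([1.0, 1.1]), np.array([1.0, 1.0]),
                         inter_deviations=dev, inter_rule="max")
    assert ba.inter_loa == pytest.approx(1.5)


def test_length_mismatch_raises():
    with pytest.raises(ValueError):
        gs.bland_altman(np.zeros(3), np.zeros(4))


def test_intra_pairs_and_helpers_from_records():
    rng = np.random.default_rng(8)
    rec = make_records(rng, n_guides=8, n_observers=3, repeat_observer=2)
    pairs = gs.intra_observer_pairs(rec, "dT")
    assert pairs.shape == (16, 2)  # 8 guides x 2 modalities
    wide = gs.paired_modality_differences(rec, "dT")
    assert len(wide) == 8
    dev = gs.observer_deviations(rec, "dT")
    assert len(dev) == 8 * 2 * 3
    assert abs(dev.mean()) < 1e-9  # deviations from group means sum to zero


# ---------------------------------------------------------------------------
# Outliers
# ---------------------------------------------------------------------------

def test_gross_outlier_flagged():
    flags = gs.flag_outliers(np.array([1.0, 2.0, 3.0, 100.0]))
    assert list(flags) == [False, False, False, True]


def test_constant_group_no_flags():
    assert not gs.flag_outliers(np.full(6, 2.0)).any()


def test_symmetric_sequence_no_flags():
    assert not gs.flag_outliers(np.arange(1.0, 9.0)).any()


def test_grouped_flagging_is_per_observer():
    values = np.array([1.0, 1.1, 0.9, 1.0, 10.0, 10.2, 9.9, 10.1])
    groups = np.array([0, 0, 0, 0, 1, 1, 1, 1])
    assert not gs.flag_outliers(values, groups).any()


def test_small_group_raises():
    with pytest.raises(ValueError, match="4"):
        gs.flag_outliers(np.array([1.0, 2.0, 3.0]))


# ---------------------------------------------------------------------------
# Power / sample size
# ---------------------------------------------------------------------------

def test_printed_design_sample_size():
    assert gs.required_sample_size(gs.PowerSpec(delta=1, sd=1)) == 16


def test_scale_invariance():
    assert gs.required_sample_size(gs.PowerSpec(delta=2, sd=2)) == 16
    rng = np.random.default_rng(9)
    for _ in range(20):
        d, s, k = rng.uniform(0.5, 3), rng.uniform(0.5, 3), rng.uniform(0.1, 10)
        assert gs.required_sample_size(
            gs.PowerSpec(delta=d, sd=s)
        ) == gs.required_sample_size(gs.PowerSpec(delta=k * d, sd=k * s))


def test_half_effect_size():
    assert gs.required_sample_size(gs.PowerSpec(delta=1, sd=2)) == 63


def test_monotone_decreasing_in_delta():
    ns = [gs.required_sample_size(gs.PowerSpec(delta=d, sd=1))
          for d in (0.25, 0.5, 1.0, 2.0)]
    assert ns == sorted(ns, reverse=True)


def test_t_based_variant_slightly_larger():
    n_z = gs.required_sample_size(gs.PowerSpec(delta=1, sd=1))
    n_t = gs.required_sample_size(gs.PowerSpec(delta=1, sd=1), use_t=True)
    assert n_t >= n_z
    assert n_t == 17


def test_zero_delta_rejected():
    with pytest.raises(ValueError):
        gs.required_sample_size(gs.PowerSpec(delta=0, sd=1))


def test_power_spec_validation():
    with pytest.raises(ValueError):
        gs.PowerSpec(delta=1, sd=-1)
    with pytest.raises(ValueError):
        gs.PowerSpec(delta=1, sd=1, power=1.2)
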