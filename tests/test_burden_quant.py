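"""Volume quantification, visual-score bins, burden scores and agreement stats."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from csvdseg.burden_quant import (marker_volume, bin_visual_scores,
                                  total_burden_score, zscore_burden,
                                  pearson_r, bland_altman, anova_lsd,
                                  agreement_report)
from csvdseg.phantom_sim import PhantomSpec, MARKER_SOURCE, generate_patient
from csvdseg import MARKERS


# ---------------------------------------------------------------------------
# volumes
# ---------------------------------------------------------------------------

def test_marker_volume_arithmetic():
    m = np.zeros((10, 10, 10), dtype=bool)
    m.ravel()[:100] = True
    assert marker_volume(m, (1, 1, 2)) == 200.0
    assert marker_volume(np.zeros((4, 4), dtype=bool), (1, 1)) == 0.0
    with pytest.raises(ValueError):
        marker_volume(np.array([0.5, 1.0]), (1,))
    with pytest.raises(ValueError):
        marker_volume(m, (1, -1, 1))


def test_volume_agrees_with_phantom_ground_truth(small_patient, small_spec):
    _, gt = small_patient
    for m in MARKERS:
        sp = small_spec.spacing_per_sequence[MARKER_SOURCE[m]]
        expected = sum(i["volume_mm3"] for i in gt.instances[m])
        assert np.isclose(marker_volume(gt.masks[m], sp), expected)


# ---------------------------------------------------------------------------
# visual bins and total burden
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("counts, key, expected", [
    ({"CMB": 0, "lacune": 0, "EPVS_bg": 0}, "CMB", 0),
    ({"CMB": 10, "lacune": 0, "EPVS_bg": 0}, "CMB", 1),
    ({"CMB": 11, "lacune": 0, "EPVS_bg": 0}, "CMB", 2),
    ({"CMB": 0, "lacune": 4, "EPVS_bg": 0}, "lacune", 1),
    ({"CMB": 0, "lacune": 5, "EPVS_bg": 0}, "lacune", 2),
    ({"CMB": 0, "lacune": 0, "EPVS_bg": 15}, "EPVS_bg", 2),
    ({"CMB": 0, "lacune": 0, "EPVS_bg": 40}, "EPVS_bg", 3),
    ({"CMB": 0, "lacune": 0, "EPVS_bg": 41}, "EPVS_bg", 4),
])
def test_visual_bins(counts, key, expected):
    assert bin_visual_scores(counts)[key] == expected


def test_wmh_grade_from_fazekas():
    base = {"CMB": 0, "lacune": 0, "EPVS_bg": 0}
    assert bin_visual_scores(base, fazekas_sum=2)["WMH"] == 0
    assert bin_visual_scores(base, fazekas_sum=4)["WMH"] == 1
    assert bin_visual_scores(base, fazekas_sum=6)["WMH"] == 2
    with pytest.raises(ValueError):
        bin_visual_scores(base, fazekas_sum=7)
    with pytest.raises(ValueError):
        bin_visual_scores({"CMB": -1, "lacune": 0, "EPVS_bg": 0})


def test_total_burden_extremes_and_single_point():
    none = {"CMB": 0, "lacune": 0, "EPVS_bg": 0}
    assert total_burden_score(bin_visual_scores(none, 0), none) == 0
    heavy = {"CMB": 12, "lacune": 5, "EPVS_bg": 25}
    assert total_burden_score(bin_visual_scores(heavy, 6), heavy) == 4
    one = {"CMB": 0, "lacune": 1, "EPVS_bg": 5}
    assert total_burden_score(bin_visual_scores(one, 2), one) == 1


def test_total_burden_monotone_under_added_lesions(rng):
    for _ in range(50):
        counts = {"CMB": int(rng.integers(0, 20)),
                  "lacune": int(rng.integers(0, 8)),
                  "EPVS_bg": int(rng.integers(0, 50))}
        faz = int(rng.integers(0, 7))
        s0 = total_burden_score(bin_visual_scores(counts, faz), counts)
        key = rng.choice(["CMB", "lacune", "EPVS_bg"])
        more = dict(counts, **{key: counts[key] + 1})
        s1 = total_burden_score(bin_visual_scores(more, faz), more)
        assert s1 >= s0


def test_total_burden_missing_bins():
    with pytest.raises(ValueError):
        total_burden_score({"CMB": 1}, {"CMB": 1, "lacune": 0, "EPVS_bg": 0})


# ---------------------------------------------------------------------------
# Z scores
# ---------------------------------------------------------------------------

def test_zscore_standardisation(rng):
    vols = pd.DataFrame(rng.lognormal(3, 1, (40, 4)), columns=MARKERS)
    z = zscore_burden(vols)
    for m in MARKERS:
        assert abs(z[m].mean()) < 1e-9
        assert abs(z[m].to_numpy().std() - 1.0) < 1e-9
    assert np.allclose(z["z_sum"], z[list(MARKERS)].sum(axis=1))


def test_zscore_two_patient_symmetry():
    vols = pd.DataFrame({"WMH": [0.0, 4.0]})
    z = zscore_burden(vols)
    assert np.allclose(sorted(z["WMH"]), [-1.0, 1.0])


def test_zscore_zero_sd_marker_warns():
    vols = pd.DataFrame({"WMH": [1.0, 2.0, 3.0], "CMB": [5.0, 5.0, 5.0]})
    with pytest.warns(UserWarning):
        z = zscore_burden(vols)
    assert np.all(z["CMB"] == 0.0)
    with pytest.raises(ValueError):
        zscore_burden(vols.iloc[:1])


# ---------------------------------------------------------------------------
# Pearson / Bland-Altman / ANOVA-LSD
# ---------------------------------------------------------------------------

def test_pearson_closed_forms():
    x = np.array([1.0, 2.0, 3.0])
    assert np.isclose(pearson_r(x, x), 1.0, atol=1e-12)
    assert np.isclose(pearson_r(x, -x), -1.0, atol=1e-12)
    assert np.isclose(pearson_r(x, [2, 4, 7]), 0.9934, atol=5e-5)
    with pytest.raises(ValueError):
        pearson_r(x, np.ones(3))
    with pytest.raises(ValueError):
        pearson_r([1, 2], [3, 4])


def test_bland_altman_offsets_and_coverage(rng):
    x = rng.normal(size=100)
    ba = bland_altman(x, x)
    assert ba["mean_diff"] == 0.0 and ba["loa"] == (0.0, 0.0)
    ba2 = bland_altman(x, x + 3.0)
    assert np.isclose(ba2["mean_diff"], 3.0) and np.isclose(ba2["sd_diff"], 0.0)
    # ~95% of paired differences fall inside the limits at large n
    y = x + rng.normal(0, 0.5, size=100)
    x_big = rng.normal(size=10_000)
    y_big = x_big + rng.normal(0, 0.5, size=10_000)
    ba3 = bland_altman(x_big, y_big)
    d = y_big - x_big
    frac = np.mean((d >= ba3["loa"][0]) & (d <= ba3["loa"][1]))
    assert 0.94 < frac < 0.96


def test_anova_identical_groups():
    g = [np.array([1.0, 2.0, 3.0])] * 3
    res = anova_lsd(g)
    assert np.isclose(res["F"], 0.0)
    assert np.isclose(res["p"], 1.0)


def test_anova_two_groups_equals_pooled_t_test(rng):
    a, b = rng.normal(0, 1, 12), rng.normal(0.8, 1, 15)
    res = anova_lsd([a, b])
    t, p = stats.ttest_ind(a, b, equal_var=True)
    assert np.isclose(res["F"], t ** 2)
    assert np.isclose(res["p"], p)
    assert np.isclose(res["pairwise_lsd_p"][(0, 1)], p)


def test_anova_detects_large_shift(rng):
    g = [rng.normal(0, 1, 20), rng.normal(0, 1, 20), rng.normal(5, 1, 20)]
    res = anova_lsd(g)
    assert res["p"] < 0.001
    assert res["pairwise_lsd_p"][(0, 2)] < 0.001
    with pytest.raises(ValueError):
        anova_lsd([np.array([1.0])])


def test_agreement_report_structure(rng):
    true = pd.DataFrame(rng.lognormal(3, 1, (20, 4)), columns=MARKERS)
    pred = true * rng.normal(1.0, 0.05, (20, 4))
    rep = agreement_report(pred, true)
    for m in MARKERS:
        assert rep[m]["pearson_r"] > 0.9
        assert rep[m]["loa"][0] <= rep[m]["mean_diff"] <= rep[m]["loa"][1]
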