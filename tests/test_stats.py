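"""ROI sampling, CV machinery, ANOVA, Welch tests, BH adjustment."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import lipidmsi as lm
import lipidmsi.preprocess as pp
from lipidmsi.stats import (
    bh_adjust,
    cv_percent,
    cv_summary,
    one_way_anova,
    select_rois,
    two_way_anova,
    welch_t_test,
)


def test_select_rois_exact_fit():
    labels = np.full((3, 3), "liver")
    mask = lm.TissueMask(3, 3, labels)
    rois = select_rois(mask, "liver", 1, seed=0)
    assert sorted(rois[0].pixels) == list(range(9))
    with pytest.raises(ValueError, match="only 1"):
        select_rois(mask, "liver", 2, seed=0)


def test_select_rois_phantom_liver(default_phantom):
    _, _, truth = default_phantom
    rois = select_rois(truth.mask, "liver", 3, seed=1)
    pixels = [p for r in rois for p in r.pixels]
    assert len(set(pixels)) == 27  # disjoint
    flat = truth.mask.flat()
    assert all(flat[p] == "liver" for p in pixels)
    # deterministic per seed
    again = select_rois(truth.mask, "liver", 3, seed=1)
    assert [r.pixels for r in again] == [r.pixels for r in rois]


@pytest.mark.parametrize("values, expected", [
    ([7, 7, 7], 0.0),
    ([8, 10, 12], 20.0),
    ([5, 10, 15], 50.0),
])
def test_cv_percent_closed_form(values, expected):
    assert cv_percent(values) == pytest.approx(expected)


def test_cv_percent_errors():
    with pytest.raises(ValueError):
        cv_percent([5.0])
    with pytest.raises(ValueError):
        cv_percent([0.0, 0.0])


def _roi_cv_fraction(noise_cv, seed):
    spec = lm.PhantomSpec(seed=seed, noise_cv=noise_cv)
    datasets, truth = lm.simulate_dataset(spec)
    table = pp.pick_features(pp.tic_normalize(datasets[0]))
    rois = select_rois(truth.mask, "muscle", 5, seed=seed)
    return cv_summary(table, rois).frac_below_20


def test_cv_summary_fraction_tracks_planted_noise():
    low = [_roi_cv_fraction(0.10, s) for s in (1, 2, 3)]
    high = [_roi_cv_fraction(0.40, s) for s in (1, 2, 3)]
    assert all(f >= 0.9 for f in low)
    assert all(f < 0.5 for f in high)
    assert np.mean(high) < np.mean(low)


def test_cv_summary_single_feature_threshold():
    t = pp.FeatureTable("r", "negative", ["x"], [300.0],
                        np.full((1, 36), 10.0) + np.tile([0, 1.9], 18))
    labels = np.full((6, 6), "liver")
    mask = lm.TissueMask(6, 6, labels)
    rois = select_rois(mask, "liver", 2, seed=0)
    cv = cv_summary(t, rois)
    assert cv.per_feature_cv[0] < 20
    assert cv.frac_below_20 == 1.0


def test_one_way_anova_hand_example():
    f, p = one_way_anova([[1, 2], [5, 6], [9, 10]])
    assert f == pytest.approx(64.0)  # MSB 32, MSW 0.5
    assert p == pytest.approx(0.0034656, abs=1e-5)


def test_one_way_anova_identical_groups():
    f, p = one_way_anova([[1, 2, 3], [1, 2, 3]])
    assert f == pytest.approx(0.0)
    assert p == pytest.approx(1.0)
    with pytest.raises(ValueError):
        one_way_anova([[5, 5], [5, 5]])


def test_one_way_anova_equals_pooled_t_squared():
    rng = np.random.default_rng(3)
    a, b = rng.normal(0, 1, 10), rng.normal(0.5, 1, 12)
    f, p_f = one_way_anova([a, b])
    t, p_t = welch_t_test(a, b, equal_var=True)
    assert f == pytest.approx(t ** 2)
    assert p_f == pytest.approx(p_t)


def test_phantom_tic_separates_tissues(default_phantom):
    _, datasets, truth = default_phantom
    flat = truth.mask.flat()
    tic = datasets[0].tic()
    groups = []
    for tissue in ("muscle", "liver", "brain"):
        rois = select_rois(truth.mask, tissue, 3, seed=2)
        groups.append([float(np.mean(tic[list(r.pixels)])) for r in rois])
    assert flat is not None
    _, p = one_way_anova(groups)
    assert p < 0.001


def test_two_way_anova_null_and_effect():
    # all cells identical -> all F = 0
    cells = {(a, b): [2.0, 2.0] for a in "xy" for b in "uv"}
    out = two_way_anova(cells)
    assert np.allclose(out["F"], 0.0)
    # planted tissue effect is detected, absent interaction is not
    rng = np.random.default_rng(7)
    detected = inter = 0
    n_sim = 40
    for _ in range(n_sim):
        cells = {}
        for i, a in enumerate("xyz"):
            for j, b in enumerate("uvw"):
                mu = 2.0 * i + 0.5 * j  # additive: no interaction
                cells[(a, b)] = list(mu + rng.normal(0, 1, 3))
        out = two_way_anova(cells)
        detected += out.loc["C(a)", "p"] < 0.05
        inter += out.loc["C(a):C(b)", "p"] < 0.05
    assert detected >= 0.9 * n_sim
    assert inter <= 0.15 * n_sim


def test_two_way_anova_unbalanced_rejected():
    cells = {("a", "x"): [1, 2], ("a", "y"): [1.0],
             ("b", "x"): [1, 2], ("b", "y"): [1, 2]}
    with pytest.raises(ValueError, match="balanced|unbalanced"):
        two_way_anova(cells)


def test_welch_t_examples():
    t, p = welch_t_test([1, 2, 3], [1, 2, 3])
    assert t == 0.0 and p == pytest.approx(1.0)
    _, p = welch_t_test([1, 2, 3], [101, 102, 103])
    assert p < 1e-4
    t, _ = welch_t_test([2.1, 2.5, 2.3], [1.1, 1.4, 1.2])
    assert t == pytest.approx(7.341, abs=0.01)
    t, p = welch_t_test([3, 3], [3, 3])
    assert (t, p) == (0.0, 1.0)


def test_bh_adjust_worked_examples():
    assert bh_adjust([0.02]) == pytest.approx([0.02])
    assert np.allclose(bh_adjust([0.01, 0.02, 0.03, 0.04]), 0.04)
    assert np.allclose(bh_adjust([0.005, 0.9]), [0.01, 0.9])
    with pytest.raises(ValueError):
        bh_adjust([0.5, 1.5])


@settings(max_examples=50, deadline=None, derandomize=True)
@given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=30))
def test_bh_adjust_properties(pvals):
    q = bh_adjust(pvals)
    p = np.asarray(pvals)
    assert np.all(q >= p - 1e-12)
    assert np.all(q <= 1.0)
    order = np.argsort(p)
    assert np.all(np.diff(q[order]) >= -1e-12)  # order preserving


def test_bh_fdr_control_under_uniform_null():
    rng = np.random.default_rng(11)
    rates = []
    for _ in range(20):
        q = bh_adjust(rng.uniform(0, 1, 1000))
        rates.append(np.mean(q < 0.05))
    se = np.std(rates, ddof=1) / np.sqrt(len(rates))
    assert np.mean(rates) <= 0.05 + 2 * se + 1e-9
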