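import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import stats

from ergrisk import (
    TrichotomyResult,
    accuracy_at,
    intersection_point,
    se_sp_profile,
    tg_roc_thresholds,
    trichotomize,
    trichotomy_table,
    uncertain_interval,
)
from ergrisk.trichotomy import _candidate_grid

from conftest import pred_from


def exhaustive_tg_roc(pred, theta):
    """Independent oracle: scan every candidate threshold directly."""
    y, p = pred.y_true, pred.p
    scores = np.unique(p)
    mids = [(a + b) / 2 for a, b in zip(scores[:-1], scores[1:])]
    cands = np.unique(np.concatenate([
        [np.nextafter(scores[0], -np.inf)], scores, mids,
        [np.nextafter(scores[-1], np.inf)],
    ]))
    se = {t: np.mean(p[y == 1] >= t) for t in cands}
    sp = {t: np.mean(p[y == 0] < t) for t in cands}
    t_low = max(t for t in cands if se[t] >= theta)
    t_high = min(t for t in cands if sp[t] >= theta)
    return t_low, t_high


def exhaustive_uncertain_interval(pred, x_star, max_sesp):
    """Independent oracle: mask-based counting over all O(m^2) grid pairs."""
    y, p = pred.y_true, pred.p
    grid = _candidate_grid(p)
    best, best_key = None, None
    for lo in grid[grid <= x_star]:
        for hi in grid[grid >= x_star]:
            inside = (p >= lo) & (p <= hi)
            pos = inside & (p >= x_star)
            tp = np.sum(pos & (y == 1))
            fp = np.sum(pos & (y == 0))
            fn = np.sum(inside & ~pos & (y == 1))
            tn = np.sum(inside & ~pos & (y == 0))
            if tp + fn == 0 or tn + fp == 0:
                continue
            if tp / (tp + fn) <= max_sesp and tn / (tn + fp) <= max_sesp:
                key = (-(tp + fn + tn + fp), hi - lo, lo)
                if best_key is None or key < best_key:
                    best_key, best = key, (lo, hi)
    return best


class TestSeSpProfile:
    def test_sentinel_endpoints(self, informative_pred):
        prof = se_sp_profile(informative_pred)
        assert prof["se"].iloc[0] == 1.0 and prof["sp"].iloc[0] == 0.0
        assert prof["se"].iloc[-1] == 0.0 and prof["sp"].iloc[-1] == 1.0

    def test_monotone_in_threshold(self, informative_pred):
        prof = se_sp_profile(informative_pred)
        assert np.all(np.diff(prof["se"]) <= 0)
        assert np.all(np.diff(prof["sp"]) >= 0)

    def test_eight_score_fixture_matches_hand_count(self):
        y = np.array([1, 1, 1, 1, 0, 0, 0, 0])
        p = np.array([0.9, 0.7, 0.6, 0.4, 0.5, 0.3, 0.3, 0.1])
        prof = se_sp_profile(pred_from(y, p)).set_index("threshold")
        # at t = 0.5: cases >= 0.5 are 0.9, 0.7, 0.6 -> Se = 3/4
        #             controls < 0.5 are 0.3, 0.3, 0.1 -> Sp = 3/4
        assert prof.loc[0.5, "se"] == pytest.approx(0.75)
        assert prof.loc[0.5, "sp"] == pytest.approx(0.75)
        # at t = 0.3: Se = 4/4, Sp = 1/4 (only 0.1 below)
        assert prof.loc[0.3, "se"] == pytest.approx(1.0)
        assert prof.loc[0.3, "sp"] == pytest.approx(0.25)


class TestTgRoc:
    def test_perfect_separation_collapses_to_empty_zone(self):
        pred = pred_from([0] * 10 + [1] * 10, [0.1] * 10 + [0.9] * 10)
        thr = tg_roc_thresholds(pred, theta=0.9)
        assert thr.collapsed
        assert thr.t_low == thr.t_high
        res = trichotomy_table(pred, thr.t_low, thr.t_high)
        assert res.sensitivity == 1.0 and res.specificity == 1.0

    def test_uninformative_scores_wide_zone(self, rng):
        y = np.array([1] * 500 + [0] * 500)
        p = rng.uniform(0, 1, 1000)
        thr = tg_roc_thresholds(pred_from(y, p), theta=0.9)
        assert thr.t_high - thr.t_low > 0.6

    def test_matches_exhaustive_scan_on_gaussian_fixture(self, informative_pred):
        thr = tg_roc_thresholds(informative_pred, theta=0.9)
        lo, hi = exhaustive_tg_roc(informative_pred, 0.9)
        assert thr.t_low == pytest.approx(lo, abs=1e-15)
        assert thr.t_high == pytest.approx(hi, abs=1e-15)

    def test_theta_domain(self, informative_pred):
        with pytest.raises(ValueError):
            tg_roc_thresholds(informative_pred, theta=0.4)

    def test_cutoffs_deliver_promised_certain_zone_se_sp(self, informative_pred):
        thr = tg_roc_thresholds(informative_pred, theta=0.9)
        y, p = informative_pred.y_true, informative_pred.p
        assert np.mean(p[y == 1] >= thr.t_low) >= 0.9
        assert np.mean(p[y == 0] < thr.t_high) >= 0.9


class TestIntersection:
    def test_symmetric_gaussians_cross_at_midpoint(self, informative_pred):
        x = intersection_point(informative_pred)
        assert x == pytest.approx(0.5, abs=0.03)

    def test_unequal_variance_matches_analytic_root(self, rng):
        # N(0.30, 0.05) vs N(0.60, 0.15): density-equality root from the
        # quadratic in x solved analytically
        neg = rng.normal(0.30, 0.05, 4000)
        pos = rng.normal(0.60, 0.15, 4000)
        pred = pred_from(
            np.concatenate([np.ones(4000, int), np.zeros(4000, int)]),
            np.clip(np.concatenate([pos, neg]), 0.001, 0.999),
        )
        coeffs = [
            1 / (2 * 0.05**2) - 1 / (2 * 0.15**2),
            0.60 / 0.15**2 - 0.30 / 0.05**2,
            0.30**2 / (2 * 0.05**2) - 0.60**2 / (2 * 0.15**2) - np.log(0.15 / 0.05),
        ]
        roots = np.roots(coeffs)
        root = roots[(roots > 0.30) & (roots < 0.60)][0]
        assert intersection_point(pred) == pytest.approx(root, abs=0.02)

    def test_constant_group_scores_rejected(self):
        pred = pred_from([1, 1, 0, 0], [0.7, 0.7, 0.2, 0.3])
        with pytest.raises(ValueError, match="constant"):
            intersection_point(pred)

    def test_identical_distributions_fall_back_to_pooled_median(self, rng):
        vals = rng.uniform(0.2, 0.8, 400)
        y = np.array([1, 0] * 200)
        x = intersection_point(pred_from(y, vals))
        assert 0.2 <= x <= 0.8


class TestUncertainInterval:
    def test_perfect_separation_empty_interval(self):
        pred = pred_from([0] * 20 + [1] * 20,
                         np.concatenate([np.linspace(0.05, 0.3, 20),
                                         np.linspace(0.7, 0.95, 20)]))
        thr = uncertain_interval(pred, max_sesp=0.55)
        assert thr.t_low == thr.t_high

    def test_uninformative_scores_cover_most_of_range(self, rng):
        # labels independent of scores; the intersection is pinned at the
        # centre since identical densities have no determined crossing
        p = rng.uniform(0, 1, 600)
        y = (rng.random(600) < 0.5).astype(int)
        thr = uncertain_interval(pred_from(y, p), max_sesp=0.55, intersection=0.5)
        assert thr.t_high - thr.t_low > 0.8

    def test_matches_brute_force_on_60_subject_fixture(self, rng):
        pos = np.clip(rng.normal(0.6, 0.15, 30), 0.01, 0.99)
        neg = np.clip(rng.normal(0.4, 0.15, 30), 0.01, 0.99)
        pred = pred_from(
            np.concatenate([np.ones(30, int), np.zeros(30, int)]),
            np.concatenate([pos, neg]),
        )
        x_star = intersection_point(pred)
        thr = uncertain_interval(pred, max_sesp=0.55)
        oracle = exhaustive_uncertain_interval(pred, x_star, 0.55)
        assert oracle is not None
        assert thr.t_low == pytest.approx(oracle[0], abs=1e-15)
        assert thr.t_high == pytest.approx(oracle[1], abs=1e-15)

    def test_max_sesp_domain(self, informative_pred):
        with pytest.raises(ValueError):
            uncertain_interval(informative_pred, max_sesp=0.5)


class TestTrichotomyTable:
    def test_published_tg_roc_cells(self):
        res = TrichotomyResult.from_cells(a=31, b=2, u_case=26, u_control=21,
                                          c=3, d=17)
        assert res.n == 100
        assert res.sensitivity == pytest.approx(31 / 34, abs=1e-12)
        assert res.specificity == pytest.approx(17 / 19, abs=1e-12)
        assert round(res.sensitivity, 2) == 0.91
        assert round(res.specificity, 2) == 0.89

    def test_published_uncertain_interval_cells(self):
        res = TrichotomyResult.from_cells(a=33, b=3, u_case=23, u_control=15,
                                          c=4, d=22)
        assert res.sensitivity == pytest.approx(33 / 37, abs=1e-12)
        assert res.specificity == pytest.approx(22 / 25, abs=1e-12)
        assert res.accuracy == pytest.approx(55 / 62, abs=1e-12)
        assert round(res.accuracy, 2) == 0.89

    def test_collapsed_cutoffs_reduce_to_dichotomy(self):
        y = [1, 0, 1, 0, 1, 1, 0, 0]
        p = [0.9, 0.1, 0.7, 0.6, 0.3, 0.8, 0.45, 0.2]
        pred = pred_from(y, p)
        res = trichotomy_table(pred, 0.5, 0.5)
        assert res.n_uncertain == 0
        # dichotomy at 0.5: Se = 3/4 (0.3 case missed), Sp = 3/4 (0.6 control)
        assert res.sensitivity == pytest.approx(0.75)
        assert res.specificity == pytest.approx(0.75)
        assert res.accuracy == pytest.approx(accuracy_at(pred, 0.5))

    def test_boundary_scores_fall_in_uncertain_zone(self):
        pred = pred_from([1, 0, 1, 0], [0.3, 0.5, 0.7, 0.9])
        res = trichotomy_table(pred, 0.5, 0.7)
        assert res.u_control == 1 and res.u_case == 1  # 0.5 and 0.7 inclusive
        assert res.a == 0 and res.b == 1 and res.c == 1 and res.d == 0

    def test_invalid_cutoff_order(self):
        with pytest.raises(ValueError):
            trichotomy_table(pred_from([1, 0], [0.6, 0.4]), 0.8, 0.2)


@given(st.data())
def test_cell_conservation_property(data):
    n = data.draw(st.integers(6, 40))
    y = np.array(data.draw(st.lists(st.integers(0, 1), min_size=n, max_size=n)))
    p = np.array(data.draw(st.lists(
        st.floats(0.01, 0.99, allow_nan=False), min_size=n, max_size=n
    )))
    lo = data.draw(st.floats(0.05, 0.9))
    hi = data.draw(st.floats(lo, 0.95))
    res = trichotomy_table(pred_from(y, p), lo, hi)
    assert res.n == n
    assert res.a + res.u_case + res.c == y.sum()
    assert res.b + res.u_control + res.d == n - y.sum()


def test_certainty_gain_over_youden_dichotomy(informative_pred):
    """On informative scores, the certain-zone accuracy beats the best single
    threshold's accuracy: dropping ambiguous subjects raises correctness."""
    prof = se_sp_profile(informative_pred)
    youden = prof.loc[(prof["se"] + prof["sp"]).idxmax(), "threshold"]
    dich_acc = accuracy_at(informative_pred, youden)
    tg = trichotomize(informative_pred, "tgroc", theta=0.9)
    assert tg.accuracy >= dich_acc
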