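"""Fit-quality statistics: printed formulas, oracle equivalence, invariances."""

import math

import numpy as np
import pytest

from echtkin import assessment
from echtkin.assessment import curve_distance, mpress, press, r2_ra2, se, sse
from echtkin.fitting import (
    GompertzCurveFit,
    MGECurveFit,
    VolumeSeries,
    fit_tgk1,
    fit_tgk2,
    mpress_for_result,
    press_for_result,
)
from echtkin.growth_models import EChTParams, GompertzParams, gompertz_volume, mge_volume

FULL_DAYS = np.array([0.0, 3, 7, 10, 13, 14, 17, 20, 24, 27, 31])


class TestResidualStatistics:
    def test_sse_examples(self):
        assert sse([1.0, 2.0], [1.0, 2.0]) == 0.0
        assert sse([1.0, 2.0], [1.1, 1.9]) == pytest.approx(0.02, rel=1e-12)
        with pytest.raises(ValueError):
            sse([1.0], [1.0, 2.0])

    def test_se_examples(self):
        obs = np.linspace(0.1, 1.0, 11)
        assert se(obs, obs, k=2) == 0.0
        pred = obs.copy()
        pred[0] += 0.3  # SSE = 0.09, n1 = 11, k = 2
        assert se(obs, pred, k=2) == pytest.approx(0.1, rel=1e-12)
        assert se(obs, obs + 0.2, k=2) == pytest.approx(2 * se(obs, obs + 0.1, k=2))
        with pytest.raises(ValueError):
            se([1.0, 2.0], [1.0, 2.0], k=2)

    def test_r2_examples(self):
        obs = np.linspace(0.1, 1.0, 11)
        r2, ra2 = r2_ra2(obs, obs, k=2)
        assert r2 == pytest.approx(1.0) and ra2 == pytest.approx(1.0)
        # construct predictions with r^2 = 0.99 and check the adjusted form
        tss = np.sum(obs**2) - obs.sum() ** 2 / obs.size
        pred = obs.copy()
        pred[5] += math.sqrt(0.01 * tss)
        r2, ra2 = r2_ra2(obs, pred, k=2)
        assert r2 == pytest.approx(0.99, rel=1e-12)
        assert ra2 == pytest.approx((10 * 0.99 - 1) / 9, rel=1e-12)

    def test_adjusted_never_exceeds_r2(self, rng):
        for _ in range(20):
            obs = np.exp(rng.normal(0, 0.5, 11))
            pred = obs * np.exp(rng.normal(0, 0.1, 11))
            r2, ra2 = r2_ra2(obs, pred, k=2)
            assert ra2 <= r2 + 1e-12

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            r2_ra2(np.full(5, 1.0), np.full(5, 1.0), k=2)

    def test_statistics_invariant_to_reordering(self, rng):
        obs = np.exp(rng.normal(0, 0.5, 9))
        pred = obs * np.exp(rng.normal(0, 0.1, 9))
        perm = rng.permutation(9)
        assert sse(obs, pred) == pytest.approx(sse(obs[perm], pred[perm]), rel=1e-14)
        assert r2_ra2(obs, pred)[0] == pytest.approx(
            r2_ra2(obs[perm], pred[perm])[0], rel=1e-14
        )


class TestCurveDistance:
    def test_identical_curves(self):
        v = np.array([0.1, 0.5, 1.0])
        assert curve_distance(v, v) == (0.0, 0.0)

    def test_constant_offset(self):
        v = np.linspace(0.1, 1.0, 7)
        dmax, rmse = curve_distance(v, v + 0.25)
        assert dmax == pytest.approx(0.25) and rmse == pytest.approx(0.25)

    def test_mixed_differences(self):
        dmax, rmse = curve_distance(np.array([0.0, 0.0]), np.array([3.0, 4.0]))
        assert dmax == 4.0
        assert rmse == pytest.approx(math.sqrt(25 / 2))

    def test_dmax_bounds_every_pointwise_difference(self, rng):
        f = rng.uniform(0, 2, 30)
        g = rng.uniform(0, 2, 30)
        dmax, _ = curve_distance(f, g)
        assert np.all(np.abs(f - g) <= dmax)

    def test_grid_mismatch_rejected(self):
        with pytest.raises(ValueError):
            curve_distance(np.zeros(3), np.zeros(4))


def _noisy_gompertz_result(rng, noise=0.02):
    p = GompertzParams(0.01, 0.35, 0.04)
    v = gompertz_volume(FULL_DAYS, p) * np.exp(rng.normal(0, noise, FULL_DAYS.size))
    return fit_tgk1(VolumeSeries(FULL_DAYS, v))


def _noisy_mge_result(rng, noise=0.02):
    p = GompertzParams(0.5, 0.49, 0.03)
    e = EChTParams(6.0, 4.0, 8.0)
    t = np.array([0.0, 1, 4, 7, 11, 14, 18])
    v = mge_volume(t, p, e) * np.exp(rng.normal(0, noise, t.size))
    return fit_tgk2(VolumeSeries(t, v), 0.49, 0.03, 6.0)


def _brute_force_press(result, mode="printed"):
    """Independent leave-one-out loop with cold-start refits."""
    days, vols = result.days, result.volumes
    n1, k = days.size, result.k
    idx = range(n1 - 1) if mode == "printed" else range(n1)
    total = 0.0
    for j in idx:
        keep = np.ones(n1, dtype=bool)
        keep[j] = False
        if "alpha" in result.params:
            est = GompertzCurveFit(v0=result.v0)
        else:
            est = MGECurveFit(
                current=result.frozen["current"],
                alpha=result.frozen["alpha"], beta=result.frozen["beta"],
                v0=result.v0,
            )
        est.fit(days[keep].reshape(-1, 1), vols[keep])
        total += (float(est.predict(np.array([[days[j]]]))[0]) - vols[j]) ** 2
    return total / (n1 - k) if mode == "printed" else total


def _brute_force_mpress(result, m):
    days, vols = result.days, result.volumes
    if "alpha" in result.params:
        est = GompertzCurveFit(v0=result.v0)
    else:
        est = MGECurveFit(
            current=result.frozen["current"],
            alpha=result.frozen["alpha"], beta=result.frozen["beta"],
            v0=result.v0,
        )
    est.fit(days[:m].reshape(-1, 1), vols[:m])
    pred = est.predict(days[m:].reshape(-1, 1))
    d = pred - vols[m:]
    return float(d @ d) / (days.size - m)


class TestPressAndMpress:
    def test_noiseless_press_vanishes(self, rng):
        r = _noisy_gompertz_result(rng, noise=0.0)
        assert press_for_result(r) <= 1e-8
        assert mpress_for_result(r, m=3) <= 1e-8

    def test_press_matches_brute_force_oracle(self, rng):
        for make in (_noisy_gompertz_result, _noisy_mge_result):
            for _ in range(5):
                r = make(rng)
                assert press_for_result(r) == pytest.approx(
                    _brute_force_press(r), abs=1e-10
                )

    def test_standard_mode_is_unnormalised_full_sum(self, rng):
        r = _noisy_gompertz_result(rng)
        printed = press_for_result(r, mode="printed")
        standard = press_for_result(r, mode="standard")
        # standard includes the last deletion and drops the 1/(n1-k) factor
        assert standard >= printed * (r.n_points - r.k) - 1e-12

    def test_mpress_matches_brute_force(self, rng):
        for make in (_noisy_gompertz_result, _noisy_mge_result):
            r = make(rng, noise=0.01)
            for m in (3, 4, 5):
                assert mpress_for_result(r, m=m) == pytest.approx(
                    _brute_force_mpress(r, m), abs=1e-10
                )

    def test_mpress_similar_across_m_on_post_treatment_windows(self, rng):
        """Forecast error from the first 3, 4 or 5 points stays within a
        factor of ~3 (in the median) on low-noise post-treatment series."""
        vals = {3: [], 4: [], 5: []}
        for _ in range(60):
            r = _noisy_mge_result(rng, noise=0.01)
            for m in (3, 4, 5):
                vals[m].append(mpress_for_result(r, m=m))
        medians = {m: float(np.median(v)) for m, v in vals.items()}
        assert max(medians.values()) <= 5.0 * min(medians.values())

    def test_press_nonnegative_and_mode_validation(self, rng):
        r = _noisy_gompertz_result(rng)
        assert press_for_result(r) >= 0.0
        with pytest.raises(ValueError):
            press(r.days, r.volumes, lambda *a: 0.0, mode="bogus")

    def test_mpress_range_validation(self, rng):
        r = _noisy_gompertz_result(rng)
        with pytest.raises(ValueError):
            mpress_for_result(r, m=2)
        with pytest.raises(ValueError):
            mpress_for_result(r, m=r.n_points)


class TestAssessFit:
    def test_report_consistency(self, rng):
        r = _noisy_gompertz_result(rng)
        rep = assessment.assess_fit(r.volumes, r.predicted, k=2)
        assert rep.sse == pytest.approx(r.sse, rel=1e-14)
        assert rep.se == pytest.approx(math.sqrt(rep.sse / (rep.n1 - 2)), rel=1e-14)
        assert rep.dmax == pytest.approx(np.max(np.abs(r.residuals)), rel=1e-14)
        assert rep.dmax >= rep.rmse

    def test_satisfactory_flag_uses_study_threshold(self):
        obs = np.linspace(0.1, 1.0, 11)
        rep = assessment.assess_fit(obs, obs * 1.001, k=2)
        assert rep.satisfactory and rep.ra2 > 0.98
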