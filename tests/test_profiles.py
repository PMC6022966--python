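"""LOESS smoothing, relative activity and biaxial trajectory pairing."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from ptdyn.profiles import (SignatureProfile, biaxial_trajectory, loess_fit,
                            loess_smooth, relative_activity)


def _series(values, prefix="c"):
    return pd.Series(np.asarray(values, dtype=float),
                     index=[f"{prefix}{i}" for i in range(len(values))])


def _profile(pt, values, **kwargs):
    return loess_smooth(_series(pt), _series(values), **kwargs)


class TestLoess:
    @pytest.mark.parametrize("degree", [1, 2])
    def test_reproduces_linear_signal_exactly(self, rng, degree):
        pt = np.sort(rng.uniform(0, 1, 40))
        values = 2.0 * pt - 0.5
        profile = _profile(pt, values, degree=degree)
        np.testing.assert_allclose(profile.smooth, profile.raw, atol=1e-8)

    def test_constant_input_gives_constant_smooth(self, rng):
        pt = np.sort(rng.uniform(0, 1, 30))
        profile = _profile(pt, np.full(30, 3.3))
        np.testing.assert_allclose(profile.smooth, 3.3, atol=1e-10)

    def test_smoothing_reduces_noise_around_sine(self, rng):
        pt = np.sort(rng.uniform(0, 1, 200))
        truth = np.sin(2 * np.pi * pt)
        noisy = truth + rng.normal(0, 0.5, 200)
        profile = _profile(pt, noisy, span=0.3)
        rmse_smooth = np.sqrt(np.mean((profile.smooth - truth) ** 2))
        rmse_raw = np.sqrt(np.mean((noisy - truth) ** 2))
        assert rmse_smooth < rmse_raw

    def test_degree_one_matches_statsmodels_lowess(self, rng):
        """Independent cross-check: local-linear tricube fit vs statsmodels."""
        x = np.sort(rng.uniform(0, 1, 80))
        y = np.sin(3 * x) + rng.normal(0, 0.2, 80)
        span = 0.5
        ours = loess_fit(x, y, x, span=span, degree=1)
        theirs = sm.nonparametric.lowess(y, x, frac=span, it=0,
                                         return_sorted=False)
        # interior points: identical windows and weights
        interior = slice(10, 70)
        np.testing.assert_allclose(ours[interior], theirs[interior], atol=1e-6)

    def test_window_too_small_suggests_larger_span(self):
        with pytest.raises(ValueError, match="span"):
            loess_fit(np.linspace(0, 1, 20), np.zeros(20),
                      np.array([0.5]), span=0.05, degree=2)

    def test_too_few_observations_rejected(self):
        with pytest.raises(ValueError, match="at least"):
            loess_fit(np.array([0.0, 1.0]), np.array([0.0, 1.0]),
                      np.array([0.5]))


class TestRelativeActivity:
    def test_affine_map_example(self):
        profile = SignatureProfile("s", ["a", "b", "c"],
                                   np.array([0.0, 0.5, 1.0]),
                                   np.array([2.0, 4.0, 6.0]),
                                   np.array([2.0, 4.0, 6.0]), 0.5, 2)
        np.testing.assert_allclose(relative_activity(profile).values,
                                   [0.0, 0.5, 1.0])

    def test_exact_zero_one_bounds(self, rng):
        pt = np.sort(rng.uniform(0, 1, 50))
        profile = _profile(pt, np.cos(4 * pt) + rng.normal(0, 0.1, 50))
        rel = relative_activity(profile).values
        assert rel.min() == 0.0 and rel.max() == 1.0

    def test_idempotent_on_unit_range_profile(self):
        profile = SignatureProfile("s", ["a", "b", "c"],
                                   np.array([0.0, 0.5, 1.0]),
                                   np.array([0.0, 0.25, 1.0]),
                                   np.array([0.0, 0.25, 1.0]), 0.5, 2)
        np.testing.assert_allclose(relative_activity(profile).values,
                                   profile.smooth)

    def test_constant_profile_is_degenerate(self):
        profile = SignatureProfile("s", ["a", "b", "c"],
                                   np.array([0.0, 0.5, 1.0]),
                                   np.ones(3), np.ones(3), 0.5, 2)
        with pytest.raises(ValueError, match="degenerate"):
            relative_activity(profile)

    def test_smooth_then_rescale_commutes_with_positive_affine(self, rng):
        pt = np.sort(rng.uniform(0, 1, 60))
        values = np.sin(2 * pt) + rng.normal(0, 0.2, 60)
        base = relative_activity(_profile(pt, values)).values
        transformed = relative_activity(_profile(pt, 3.7 * values + 11.0)).values
        np.testing.assert_allclose(base, transformed, atol=1e-9)


class TestBiaxialTrajectory:
    def test_pairs_smooth_curves_pointwise(self, rng):
        pt = np.sort(rng.uniform(0, 1, 30))
        pa = _profile(pt, pt)
        pb = _profile(pt, 1 - pt)
        pair = biaxial_trajectory(pa, pb)
        np.testing.assert_allclose(pair.a + pair.b, 1.0, atol=1e-8)

    def test_swapping_inputs_transposes_curve(self, rng):
        pt = np.sort(rng.uniform(0, 1, 30))
        pa = _profile(pt, np.exp(pt))
        pb = _profile(pt, pt ** 2)
        ab = biaxial_trajectory(pa, pb)
        ba = biaxial_trajectory(pb, pa)
        np.testing.assert_allclose(ab.a, ba.b)
        np.testing.assert_allclose(ab.b, ba.a)

    def test_cell_mismatch_rejected(self, rng):
        pt = np.sort(rng.uniform(0, 1, 30))
        pa = _profile(pt, pt)
        pb = loess_smooth(_series(pt, prefix="x"), _series(pt, prefix="x"))
        with pytest.raises(ValueError, match="different cells"):
            biaxial_trajectory(pa, pb)
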