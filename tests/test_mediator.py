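"""Linear mediator models: fit, prediction, nadir search, BMI screen."""

import numpy as np
import pandas as pd
import pytest

from bmimed.design import DesignSpec, Term
from bmimed.mediator import (REFERENCE_PROFILE, bmi_wald_test, find_nadir,
                             fit_mediator, predict_mediator)
from bmimed.splines import SplineSpec, place_knots, rcs_basis


def make_frame(rng, n=2000, curve=0.05, nadir=25.0, noise=1.0, slope=None,
               bmi_range=(17.0, 42.0)):
    """Synthetic mediator table: EAA quadratic (or linear) in BMI plus age/sex."""
    bmi = rng.uniform(*bmi_range, n)
    age = rng.uniform(51.0, 95.0, n)
    sex = rng.choice(["male", "female"], n)
    if slope is None:
        signal = curve * (bmi - nadir) ** 2
    else:
        signal = slope * bmi
    eaa = signal + 0.02 * (age - 70.0) - 0.4 * (sex == "female") \
        + rng.normal(0, noise, n)
    return pd.DataFrame({
        "bmi": bmi, "baseline_age": age, "sex": sex, "eaa_grimage": eaa,
        "grimage_age": age + eaa,
    })


def quadratic_design(df, k=4):
    return DesignSpec(terms=(
        Term("bmi", "spline", place_knots(df["bmi"].to_numpy(), k=k)),
        Term("baseline_age", "linear"),
        Term("sex", "categorical"),
    ))


class TestFitMediator:
    def test_recovers_quadratic_curve(self, rng):
        df = make_frame(rng, n=4000)
        fit = fit_mediator(df, "grimage", quadratic_design(df))
        grid = np.linspace(19.0, 40.0, 43)
        prof = pd.DataFrame([{**REFERENCE_PROFILE}] * len(grid))
        pred = predict_mediator(fit, grid, prof)
        truth = 0.05 * (grid - 25.0) ** 2 + 0.02 * (70.0 - 70.0)
        # within a few noise SEs of the generating curve across the range
        assert np.max(np.abs(pred - truth)) < 0.35

    def test_null_bmi_effect_not_flagged_significant(self, rng):
        df = make_frame(rng, curve=0.0)
        fit = fit_mediator(df, "grimage", quadratic_design(df))
        assert bmi_wald_test(fit)["p_value"] > 0.01  # no real signal

    def test_strong_bmi_effect_flagged_significant(self, rng):
        df = make_frame(rng, curve=0.05)
        fit = fit_mediator(df, "grimage", quadratic_design(df))
        assert bmi_wald_test(fit)["p_value"] < 1e-6

    def test_weights_scale_invariance(self, rng):
        df = make_frame(rng, n=500)
        w = rng.uniform(0.5, 2.0, len(df))
        f1 = fit_mediator(df, "grimage", quadratic_design(df), weights=w)
        f2 = fit_mediator(df, "grimage", quadratic_design(df), weights=2 * w)
        np.testing.assert_allclose(f1.coef, f2.coef, rtol=1e-10)
        assert f1.resid_sd == pytest.approx(f2.resid_sd, rel=1e-10)

    def test_residuals_orthogonal_to_design(self, rng):
        df = make_frame(rng, n=1500)
        des = quadratic_design(df)
        fit = fit_mediator(df, "grimage", des)
        Xc = np.column_stack([np.ones(len(df)), des.build(df)])
        r = df["eaa_grimage"].to_numpy() - Xc @ fit.coef
        # normalise columns so the tolerance is scale-free
        Xn = Xc / np.abs(Xc).max(axis=0)
        assert np.max(np.abs(Xn.T @ r)) / len(df) < 1e-8

    def test_collinear_design_reported(self, rng):
        df = make_frame(rng, n=300)
        df["bmi_copy"] = df["bmi"]
        des = DesignSpec(terms=(
            Term("bmi", "spline", place_knots(df["bmi"].to_numpy(), 4)),
            Term("bmi_copy", "linear"),
        ))
        with pytest.raises(np.linalg.LinAlgError, match="collinear"):
            fit_mediator(df, "grimage", des)

    def test_design_without_bmi_rejected(self, rng):
        df = make_frame(rng, n=100)
        with pytest.raises(ValueError, match="BMI"):
            fit_mediator(df, "grimage", DesignSpec(terms=(Term("baseline_age"),)))


class TestPredictMediator:
    def test_intercept_only_prediction_is_constant(self, rng):
        df = make_frame(rng, n=800)
        fit = fit_mediator(df, "grimage", quadratic_design(df))
        fit.coef[:] = 0.0
        fit.coef[0] = 3.25
        prof = pd.DataFrame([REFERENCE_PROFILE] * 3)
        np.testing.assert_allclose(
            predict_mediator(fit, np.array([19.0, 27.0, 35.0]), prof), 3.25)

    def test_contrast_matches_hand_computed_basis_difference(self, rng):
        df = make_frame(rng, n=1000)
        fit = fit_mediator(df, "grimage", quadratic_design(df))
        prof = pd.DataFrame([REFERENCE_PROFILE])
        d = predict_mediator(fit, 35.0, prof)[0] - predict_mediator(fit, 27.0, prof)[0]
        spec = fit.spline_spec
        basis_diff = rcs_basis(np.array([35.0]), spec) - rcs_basis(np.array([27.0]), spec)
        sl = fit.design_spec.slices()["bmi"]
        hand = float(basis_diff[0] @ fit.coef[1 + sl.start:1 + sl.stop])
        assert d == pytest.approx(hand, abs=1e-10)

    def test_monotone_generator_gives_monotone_predictions(self, rng):
        df = make_frame(rng, n=4000, slope=0.3)
        fit = fit_mediator(df, "grimage", quadratic_design(df))
        grid = np.linspace(20.0, 40.0, 100)
        prof = pd.DataFrame([REFERENCE_PROFILE] * 100)
        pred = predict_mediator(fit, grid, prof)
        assert np.sum(np.diff(pred) <= 0) < 5  # essentially increasing

    def test_out_of_support_warns(self, rng):
        df = make_frame(rng, n=200)
        fit = fit_mediator(df, "grimage", quadratic_design(df))
        with pytest.warns(UserWarning, match="support"):
            predict_mediator(fit, 12.0, pd.DataFrame([REFERENCE_PROFILE]))


class TestFindNadir:
    def test_quadratic_minimum_recovered(self, rng):
        # BMI support symmetric about the true minimum: the least-squares
        # spline approximation of the quadratic then has an unbiased argmin
        df = make_frame(rng, n=4000, nadir=25.0, bmi_range=(15.0, 35.0))
        fit = fit_mediator(df, "grimage", quadratic_design(df))
        nad = find_nadir(fit)
        assert not nad.boundary and not nad.flat
        assert nad.bmi == pytest.approx(25.0, abs=0.3)

    def test_linear_generator_hits_boundary(self, rng):
        df = make_frame(rng, n=4000, slope=0.3)
        fit = fit_mediator(df, "grimage", quadratic_design(df))
        assert find_nadir(fit).boundary

    def test_flat_profile_flagged(self, rng):
        df = make_frame(rng, n=500)
        fit = fit_mediator(df, "grimage", quadratic_design(df))
        sl = fit.design_spec.slices()["bmi"]
        fit.coef[1 + sl.start:1 + sl.stop] = 0.0
        assert find_nadir(fit).flat

    def test_invariant_to_additive_shift(self, rng):
        df = make_frame(rng, n=3000)
        fit = fit_mediator(df, "grimage", quadratic_design(df))
        shifted = df.assign(eaa_grimage=df["eaa_grimage"] + 7.5)
        fit2 = fit_mediator(shifted, "grimage", quadratic_design(df))
        assert find_nadir(fit).bmi == pytest.approx(find_nadir(fit2).bmi, abs=1e-6)
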