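"""Linear mediator models: epigenetic age acceleration on splined BMI.

Each clock's EAA (or DunedinPACE, on its own pace scale) is regressed on a
restricted cubic spline in BMI plus the covariate set shared with the paired
outcome model.  Age enters linearly by default and may be splined where the
age-EAA relation is nonlinear.  Fits are ordinary (or survey-weighted) least
squares via statsmodels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .cohort import mediator_column
from .design import DesignSpec, Term, check_full_rank
from .splines import SplineSpec, rcs_basis

__all__ = [
    "MediatorFit",
    "NadirResult",
    "REFERENCE_PROFILE",
    "fit_mediator",
    "predict_mediator",
    "predict_mediator_ci",
    "find_nadir",
    "bmi_wald_test",
]

#: Covariate profile used for published-style curves and nadir reporting:
#: a 70-year-old white male, never-smoker, metabolically unhealthy, with
#: high-school education or below.
REFERENCE_PROFILE = {
    "baseline_age": 70.0,
    "sex": "male",
    "ethnicity": "white",
    "education": "below",
    "smoking": "never",
    "metab_unhealthy": 1.0,
}

#: BMI range [kg/m^2] outside which prediction is linear extrapolation.
BMI_SUPPORT = (15.0, 60.0)


@dataclass
class MediatorFit:
    clock: str
    design_spec: DesignSpec
    names: list  # "(intercept)" + design columns
    coef: np.ndarray
    cov: np.ndarray
    resid_sd: float
    weighted: bool
    n: int

    @property
    def spline_spec(self) -> SplineSpec:
        return self.design_spec.term("bmi").spline

    def summary_frame(self) -> pd.DataFrame:
        se = np.sqrt(np.diag(self.cov))
        return pd.DataFrame(
            {"coef": self.coef, "se": se, "z": self.coef / se}, index=self.names
        )


def fit_mediator(
    data: pd.DataFrame,
    clock: str,
    design_spec: DesignSpec,
    weights=None,
) -> MediatorFit:
    """(Weighted) least-squares fit of a clock's mediator on the design.

    The design must contain a splined ``bmi`` term; the residual SD is the
    unbiased estimator ``sqrt(SSR / (n - p))``.
    """
    if not design_spec.has("bmi"):
        raise ValueError("mediator design must include a BMI term")
    y = data[mediator_column(clock)].to_numpy(dtype=float)
    X = design_spec.build(data)
    names = ["(intercept)", *design_spec.column_names]
    Xc = np.column_stack([np.ones(len(y)), X])
    check_full_rank(Xc, names)
    w = np.ones(len(y)) if weights is None else np.asarray(weights, dtype=float)
    model = sm.WLS(y, Xc, weights=w)
    res = model.fit()
    resid = y - Xc @ res.params
    dof = len(y) - Xc.shape[1]
    resid_sd = float(np.sqrt(np.sum(w * resid**2) / (np.sum(w) / len(y)) / dof))
    return MediatorFit(
        clock=clock,
        design_spec=design_spec,
        names=names,
        coef=np.asarray(res.params),
        cov=np.asarray(res.cov_params()),
        resid_sd=resid_sd,
        weighted=weights is not None,
        n=len(y),
    )


def _design_rows(fit: MediatorFit, data: pd.DataFrame, bmi) -> np.ndarray:
    X = fit.design_spec.build(data, overrides={"bmi": bmi})
    return np.column_stack([np.ones(len(data)), X])


def predict_mediator(
    fit: MediatorFit,
    bmi,
    covariates: pd.DataFrame,
    return_sd: bool = False,
):
    """Predicted mediator mean at the requested BMI, covariates as observed.

    ``bmi`` may be a scalar (broadcast) or a per-row array.  Outside the
    supported BMI range the restricted spline extrapolates linearly; a
    warning is emitted.  With ``return_sd`` the residual SD accompanies the
    mean, defining the predictive distribution for draw-based mediation.
    """
    b = np.asarray(bmi, dtype=float)
    if np.any(b < BMI_SUPPORT[0]) or np.any(b > BMI_SUPPORT[1]):
        warnings.warn(
            f"BMI outside support {BMI_SUPPORT}; restricted-spline prediction "
            "extrapolates linearly there",
            stacklevel=2,
        )
    pred = _design_rows(fit, covariates, bmi) @ fit.coef
    if return_sd:
        return pred, fit.resid_sd
    return pred


def predict_mediator_ci(
    fit: MediatorFit,
    bmi,
    covariates: pd.DataFrame,
    level: float = 0.95,
) -> pd.DataFrame:
    """Predicted mediator mean with pointwise Wald confidence bands."""
    from scipy import stats

    X = _design_rows(fit, covariates, np.asarray(bmi, dtype=float))
    mean = X @ fit.coef
    se = np.sqrt(np.einsum("ij,jk,ik->i", X, fit.cov, X))
    z = stats.norm.ppf(0.5 + level / 2.0)
    return pd.DataFrame({"bmi": np.broadcast_to(np.asarray(bmi, float), (len(X),)),
                         "predicted": mean,
                         "ci_low": mean - z * se,
                         "ci_high": mean + z * se})


@dataclass
class NadirResult:
    bmi: float
    predicted: float
    boundary: bool  # minimum sits on the search boundary
    flat: bool  # no interior nadir: BMI profile is (numerically) flat


def find_nadir(
    fit: MediatorFit,
    search_range=(18.0, 45.0),
    step: float = 0.01,
    profile: dict | None = None,
    flat_tol: float = 1e-9,
) -> NadirResult:
    """BMI minimising the predicted mediator at a fixed covariate profile.

    Grid search at ``step`` resolution refined by local quadratic
    interpolation; a minimum on the edge of ``search_range`` is flagged
    ``boundary`` and an (effectively) flat BMI profile is flagged ``flat``.
    """
    profile_row = pd.DataFrame([{**REFERENCE_PROFILE, **(profile or {})}])
    grid = np.arange(search_range[0], search_range[1] + step / 2, step)
    cov_grid = profile_row.loc[profile_row.index.repeat(len(grid))].reset_index(drop=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        pred = predict_mediator(fit, grid, cov_grid)
    if float(np.ptp(pred)) < flat_tol * max(1.0, float(np.max(np.abs(pred)))):
        return NadirResult(bmi=float("nan"), predicted=float(pred.mean()),
                           boundary=False, flat=True)
    i = int(np.argmin(pred))
    if i == 0 or i == len(grid) - 1:
        return NadirResult(bmi=float(grid[i]), predicted=float(pred[i]),
                           boundary=True, flat=False)
    # Quadratic interpolation through the three bracketing grid points.
    y0, y1, y2 = pred[i - 1], pred[i], pred[i + 1]
    denom = y0 - 2 * y1 + y2
    offset = 0.5 * (y0 - y2) / denom if denom > 0 else 0.0
    x_star = grid[i] + offset * step
    y_star = y1 - 0.25 * (y0 - y2) * offset if denom > 0 else y1
    return NadirResult(bmi=float(x_star), predicted=float(y_star),
                       boundary=False, flat=False)


def bmi_wald_test(fit: MediatorFit) -> dict:
    """Joint Wald test that every BMI basis coefficient is zero.

    This is the screen deciding whether a clock can act as a mediator at all;
    clocks whose BMI association is indistinguishable from zero are dropped
    from mediation.
    """
    from scipy import stats

    sl = fit.design_spec.slices()["bmi"]
    idx = np.arange(1 + sl.start, 1 + sl.stop)  # shift past the intercept
    b = fit.coef[idx]
    V = fit.cov[np.ix_(idx, idx)]
    stat = float(b @ np.linalg.solve(V, b))
    df = len(idx)
    p = float(stats.chi2.sf(stat, df))
    return {"stat": stat, "df": df, "p_value": p}
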