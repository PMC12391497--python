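"""Counterfactual mediation: ADE / ACME in years of mean survival time.

The estimand follows the potential-outcomes decomposition for a single
mediator.  Let ``m_i(e)`` be subject *i*'s mediator value predicted at BMI
level ``e`` (their other covariates at observed values) and let
``Y_i(b, m)`` be the model-predicted mean *residual* survival time from
subject *i*'s own baseline age with BMI set to ``b`` and the mediator set to
``m``.  With exposed level ``e1`` and reference level ``e0``:

    ACME(e) = mean_i[ Y_i(e,  m_i(e1)) - Y_i(e,  m_i(e0)) ]
    ADE(e)  = mean_i[ Y_i(e1, m_i(e))  - Y_i(e0, m_i(e))  ]

and the reported effects average over ``e in {e1, e0}``:

    acme = (ACME(e1) + ACME(e0)) / 2,   ade = (ADE(e1) + ADE(e0)) / 2,
    total = mean_i[ Y_i(e1, m_i(e1)) - Y_i(e0, m_i(e0)) ].

Under this averaging, ``ade + acme == total`` algebraically.  Uncertainty
comes from a nonparametric subject-level bootstrap (both models refit per
resample, spline knots frozen at their original placement) with percentile
intervals.

Only the BMI basis columns and the mediator column of the outcome design
change between counterfactual arms, so the engine caches the observed
design matrices once and swaps those columns in place; a bootstrap resample
is then two small refits plus vectorised survival quadrature.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import mediator_column
from .design import DesignSpec
from .gompertz import (ConvergenceError, GompertzFit, fit_gompertz_ph,
                       residual_life_gl)
from .mediator import MediatorFit, fit_mediator
from .splines import rcs_basis

__all__ = [
    "ExposureContrast",
    "EffectEstimates",
    "MediationResult",
    "DEFAULT_CONTRASTS",
    "estimate_effects",
    "effects_from_fits",
    "bootstrap_mediation",
    "proportion_mediated",
]


@dataclass(frozen=True)
class ExposureContrast:
    """One exposed-vs-reference BMI comparison, in kg/m^2."""

    exposed_bmi: float
    reference_bmi: float
    label: str = "custom"

    def __post_init__(self) -> None:
        if self.exposed_bmi == self.reference_bmi:
            raise ValueError("exposed and reference BMI must differ")

    def swapped(self) -> "ExposureContrast":
        return ExposureContrast(self.reference_bmi, self.exposed_bmi,
                                label=f"{self.label}-swapped")


#: The published contrasts: low 19 vs 27 and high 35 vs 27 kg/m^2.
DEFAULT_CONTRASTS = (
    ExposureContrast(19.0, 27.0, label="low"),
    ExposureContrast(35.0, 27.0, label="high"),
)


@dataclass
class EffectEstimates:
    ade: float
    acme: float
    total: float
    mediator_fit: MediatorFit | None = None
    outcome_fit: GompertzFit | None = None


@dataclass
class MediationResult:
    clock: str
    contrast: ExposureContrast
    ade: float
    acme: float
    total: float
    prop_mediated: float  # NaN when ADE and ACME point in opposite directions
    ci_ade: tuple
    ci_acme: tuple
    ci_total: tuple
    n_boot: int
    n_boot_failed: int
    seed: int
    mode: str

    def to_row(self) -> dict:
        return {
            "clock": self.clock,
            "contrast": self.contrast.label,
            "exposed_bmi": self.contrast.exposed_bmi,
            "reference_bmi": self.contrast.reference_bmi,
            "ade": self.ade,
            "acme": self.acme,
            "total": self.total,
            "prop_mediated": self.prop_mediated,
            "ade_ci_low": self.ci_ade[0],
            "ade_ci_high": self.ci_ade[1],
            "acme_ci_low": self.ci_acme[0],
            "acme_ci_high": self.ci_acme[1],
            "total_ci_low": self.ci_total[0],
            "total_ci_high": self.ci_total[1],
            "n_boot": self.n_boot,
            "n_boot_failed": self.n_boot_failed,
            "seed": self.seed,
            "mode": self.mode,
        }


def proportion_mediated(ade: float, acme: float) -> float:
    """ACME / (ADE + ACME); NaN when the two effects disagree in direction.

    The share of the total effect flowing through the mediator is only
    meaningful when direct and mediated effects point the same way.
    """
    total = ade + acme
    if ade * acme < 0 or total == 0:
        return float("nan")
    return acme / total


def _validate_designs(clock, mediator_design, outcome_design, mode,
                      warn_spline=True):
    mvar = mediator_column(clock)
    if not outcome_design.has(mvar):
        raise ValueError(f"outcome design must contain the mediator column {mvar!r}")
    if mode not in ("mean_substitution", "draw_based"):
        raise ValueError(f"unknown mode {mode!r}")
    if (mode == "mean_substitution" and warn_spline
            and outcome_design.term(mvar).kind == "spline"):
        warnings.warn(
            "mediator enters the outcome model through a spline; "
            "mean-substitution is biased there — prefer mode='draw_based' "
            "with >= 200 draws per subject",
            stacklevel=3,
        )
    return mvar


class _Workspace:
    """Cached design matrices + column bookkeeping for fast refits."""

    def __init__(self, data: pd.DataFrame, clock: str,
                 mediator_design: DesignSpec, outcome_design: DesignSpec,
                 weights=None, n_nodes: int = 64, a_max: float = 130.0):
        self.mvar = mediator_column(clock)
        self.clock = clock
        self.mediator_design = mediator_design
        self.outcome_design = outcome_design
        self.n_nodes = n_nodes
        self.a_max = a_max
        n = len(data)
        self.n = n
        self.y = data[self.mvar].to_numpy(dtype=float)
        self.Xm = np.column_stack([np.ones(n), mediator_design.build(data)])
        self.Xo = outcome_design.build(data)
        self.entry = data["baseline_age"].to_numpy(dtype=float)
        self.exit = self.entry + data["followup_years"].to_numpy(dtype=float)
        self.event = data["died"].to_numpy(dtype=float)
        self.w = None if weights is None else np.asarray(weights, dtype=float)

        msl = mediator_design.slices()["bmi"]
        self.m_bmi_idx = np.arange(1 + msl.start, 1 + msl.stop)  # past intercept
        self.m_other_idx = np.array(
            [j for j in range(self.Xm.shape[1]) if j not in set(self.m_bmi_idx)]
        )
        osl = outcome_design.slices()
        self.o_bmi_idx = np.arange(osl["bmi"].start, osl["bmi"].stop)
        self.o_med_idx = np.arange(osl[self.mvar].start, osl[self.mvar].stop)
        self.o_static_idx = np.array(
            [j for j in range(self.Xo.shape[1])
             if j not in set(self.o_bmi_idx) | set(self.o_med_idx)]
        )
        self.m_spline = mediator_design.term("bmi").spline
        self.o_bmi_spline = outcome_design.term("bmi").spline
        med_term = outcome_design.term(self.mvar)
        self.o_med_spline = med_term.spline if med_term.kind == "spline" else None

    def _ols(self, Xm, y, w):
        if w is None:
            coef, _, _, _ = np.linalg.lstsq(Xm, y, rcond=None)
            resid = y - Xm @ coef
            sd = np.sqrt(resid @ resid / (len(y) - Xm.shape[1]))
        else:
            sw = np.sqrt(w)
            coef, _, _, _ = np.linalg.lstsq(Xm * sw[:, None], y * sw, rcond=None)
            resid = y - Xm @ coef
            sd = np.sqrt((w * resid**2).sum() / w.mean() / (len(y) - Xm.shape[1]))
        return coef, float(sd)

    def _med_basis_row(self, b: float) -> np.ndarray:
        return rcs_basis(np.array([b]), self.m_spline)[0]

    def _out_bmi_row(self, b: float) -> np.ndarray:
        return rcs_basis(np.array([b]), self.o_bmi_spline)[0]

    def _med_term(self, m: np.ndarray, beta_med: np.ndarray) -> np.ndarray:
        if self.o_med_spline is None:
            return m * beta_med[0]
        return rcs_basis(m, self.o_med_spline) @ beta_med

    def estimate(self, contrast: ExposureContrast, idx=None,
                 mode: str = "mean_substitution", n_draws: int = 200,
                 rng: np.random.Generator | None = None,
                 outcome_start=None) -> tuple:
        """(ade, acme, total, med_coef, out_fit) on the (re)sample ``idx``."""
        if idx is None:
            Xm, y, Xo = self.Xm, self.y, self.Xo
            entry, exit_, event = self.entry, self.exit, self.event
            w = self.w
        else:
            Xm, y, Xo = self.Xm[idx], self.y[idx], self.Xo[idx]
            entry, exit_, event = self.entry[idx], self.exit[idx], self.event[idx]
            w = None if self.w is None else self.w[idx]

        med_coef, resid_sd = self._ols(Xm, y, w)
        out_fit = fit_gompertz_ph(entry, exit_, event, X=Xo, weights=w,
                                  start=outcome_start)
        beta = out_fit.beta
        e1, e0 = contrast.exposed_bmi, contrast.reference_bmi

        # counterfactual mediator means
        m_other = Xm[:, self.m_other_idx] @ med_coef[self.m_other_idx]
        m_mean = {
            e: m_other + self._med_basis_row(e) @ med_coef[self.m_bmi_idx]
            for e in (e1, e0)
        }
        if mode == "mean_substitution":
            m_sets = {e: m[None, :] for e, m in m_mean.items()}
        else:
            rng = rng or np.random.default_rng()
            eps = rng.normal(0.0, resid_sd, size=(n_draws, len(y)))
            m_sets = {e: m[None, :] + eps for e, m in m_mean.items()}

        lp_static = out_fit.log_b + Xo[:, self.o_static_idx] @ beta[self.o_static_idx]
        bmi_term = {e: self._out_bmi_row(e) @ beta[self.o_bmi_idx] for e in (e1, e0)}
        beta_med = beta[self.o_med_idx]

        Y = {}
        for b in (e1, e0):
            for m_key in (e1, e0):
                acc = np.zeros(len(y))
                for m_row in m_sets[m_key]:
                    lp = lp_static + bmi_term[b] + self._med_term(m_row, beta_med)
                    acc += residual_life_gl(out_fit.gamma, lp, entry,
                                            a_max=self.a_max, n_nodes=self.n_nodes)
                Y[(b, m_key)] = acc / m_sets[m_key].shape[0]

        acme = 0.5 * float(np.mean((Y[(e1, e1)] - Y[(e1, e0)])
                                   + (Y[(e0, e1)] - Y[(e0, e0)])))
        ade = 0.5 * float(np.mean((Y[(e1, e1)] - Y[(e0, e1)])
                                  + (Y[(e1, e0)] - Y[(e0, e0)])))
        total = float(np.mean(Y[(e1, e1)] - Y[(e0, e0)]))
        return ade, acme, total, med_coef, out_fit


def estimate_effects(
    data: pd.DataFrame,
    clock: str,
    contrast: ExposureContrast,
    mediator_design: DesignSpec,
    outcome_design: DesignSpec,
    mode: str = "mean_substitution",
    n_draws: int = 200,
    rng: np.random.Generator | None = None,
    weights=None,
    n_nodes: int = 64,
    keep_fits: bool = True,
    outcome_start=None,
    _warn_spline_mediator: bool = True,
) -> EffectEstimates:
    """Point estimates of ADE, ACME and the total effect, in years.

    ``mode='mean_substitution'`` fixes the counterfactual mediator at its
    predicted mean (the published algorithm); ``'draw_based'`` averages the
    outcome over ``n_draws`` Normal(mean, resid_sd) draws per subject, which
    is the exact estimand when the mediator enters the outcome nonlinearly.
    """
    _validate_designs(clock, mediator_design, outcome_design, mode,
                      warn_spline=_warn_spline_mediator)
    ws = _Workspace(data, clock, mediator_design, outcome_design,
                    weights=weights, n_nodes=n_nodes)
    ade, acme, total, _, out_fit = ws.estimate(
        contrast, mode=mode, n_draws=n_draws, rng=rng,
        outcome_start=outcome_start,
    )
    med_fit = None
    if keep_fits:
        med_fit = fit_mediator(data, clock, mediator_design, weights=weights)
        out_fit.names = outcome_design.column_names
        out_fit.design_spec = outcome_design
    return EffectEstimates(ade=ade, acme=acme, total=total,
                           mediator_fit=med_fit,
                           outcome_fit=out_fit if keep_fits else None)


def effects_from_fits(
    data: pd.DataFrame,
    clock: str,
    contrast: ExposureContrast,
    mediator_fit: MediatorFit,
    outcome_fit: GompertzFit,
    mode: str = "mean_substitution",
    n_draws: int = 200,
    rng: np.random.Generator | None = None,
    n_nodes: int = 64,
) -> EffectEstimates:
    """ADE/ACME/total from already-fitted models (no refitting).

    Useful for sensitivity probes that modify coefficients directly — e.g.
    zeroing the mediator path to confirm the mediated effect vanishes.
    """
    if outcome_fit.design_spec is None:
        raise ValueError("outcome fit must carry its design spec")
    ws = _Workspace(data, clock, mediator_fit.design_spec,
                    outcome_fit.design_spec, n_nodes=n_nodes)
    med_coef = mediator_fit.coef
    beta = outcome_fit.beta
    e1, e0 = contrast.exposed_bmi, contrast.reference_bmi
    m_other = ws.Xm[:, ws.m_other_idx] @ med_coef[ws.m_other_idx]
    m_mean = {e: m_other + ws._med_basis_row(e) @ med_coef[ws.m_bmi_idx]
              for e in (e1, e0)}
    if mode == "mean_substitution":
        m_sets = {e: m[None, :] for e, m in m_mean.items()}
    elif mode == "draw_based":
        rng = rng or np.random.default_rng()
        eps = rng.normal(0.0, mediator_fit.resid_sd, size=(n_draws, ws.n))
        m_sets = {e: m[None, :] + eps for e, m in m_mean.items()}
    else:
        raise ValueError(f"unknown mode {mode!r}")
    lp_static = outcome_fit.log_b + ws.Xo[:, ws.o_static_idx] @ beta[ws.o_static_idx]
    bmi_term = {e: ws._out_bmi_row(e) @ beta[ws.o_bmi_idx] for e in (e1, e0)}
    beta_med = beta[ws.o_med_idx]
    Y = {}
    for b in (e1, e0):
        for m_key in (e1, e0):
            acc = np.zeros(ws.n)
            for m_row in m_sets[m_key]:
                lp = lp_static + bmi_term[b] + ws._med_term(m_row, beta_med)
                acc += residual_life_gl(outcome_fit.gamma, lp, ws.entry,
                                        a_max=ws.a_max, n_nodes=n_nodes)
            Y[(b, m_key)] = acc / m_sets[m_key].shape[0]
    acme = 0.5 * float(np.mean((Y[(e1, e1)] - Y[(e1, e0)])
                               + (Y[(e0, e1)] - Y[(e0, e0)])))
    ade = 0.5 * float(np.mean((Y[(e1, e1)] - Y[(e0, e1)])
                              + (Y[(e1, e0)] - Y[(e0, e0)])))
    total = float(np.mean(Y[(e1, e1)] - Y[(e0, e0)]))
    return EffectEstimates(ade=ade, acme=acme, total=total,
                           mediator_fit=mediator_fit, outcome_fit=outcome_fit)


def bootstrap_mediation(
    data: pd.DataFrame,
    clock: str,
    contrast: ExposureContrast,
    mediator_design: DesignSpec,
    outcome_design: DesignSpec,
    n_boot: int = 3000,
    seed: int = 0,
    mode: str = "mean_substitution",
    n_draws: int = 200,
    weights=None,
    n_nodes: int = 64,
) -> MediationResult:
    """Subject-level nonparametric bootstrap with 95% percentile intervals.

    Both models are refit on every resample; spline knots stay frozen at
    their full-sample placement so the estimand does not drift across
    resamples.  Non-convergent resamples are dropped and counted (a warning
    fires past 2%).  Deterministic given ``seed``.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be positive")
    _validate_designs(clock, mediator_design, outcome_design, mode)
    rng = np.random.default_rng(seed)
    ws = _Workspace(data, clock, mediator_design, outcome_design,
                    weights=weights, n_nodes=n_nodes)
    ade, acme, total, _, out_fit = ws.estimate(contrast, mode=mode,
                                               n_draws=n_draws, rng=rng)
    warm = (out_fit.gamma, out_fit.log_b, out_fit.beta)
    draws = np.empty((n_boot, 3))
    n_failed = 0
    n = ws.n
    for b in range(n_boot):
        idx = rng.integers(0, n, size=n)
        try:
            a_b, c_b, t_b, _, _ = ws.estimate(
                contrast, idx=idx, mode=mode, n_draws=n_draws, rng=rng,
                outcome_start=warm,
            )
            draws[b] = (a_b, c_b, t_b)
        except (ConvergenceError, np.linalg.LinAlgError, ValueError):
            draws[b] = np.nan
            n_failed += 1
    ok = draws[~np.isnan(draws).any(axis=1)]
    if ok.shape[0] == 0:
        raise ConvergenceError("every bootstrap resample failed to converge")
    if n_failed > 0.02 * n_boot:
        warnings.warn(
            f"{n_failed}/{n_boot} bootstrap resamples failed to converge",
            stacklevel=2,
        )
    lo, hi = np.percentile(ok, [2.5, 97.5], axis=0)
    return MediationResult(
        clock=clock,
        contrast=contrast,
        ade=ade,
        acme=acme,
        total=total,
        prop_mediated=proportion_mediated(ade, acme),
        ci_ade=(float(lo[0]), float(hi[0])),
        ci_acme=(float(lo[1]), float(hi[1])),
        ci_total=(float(lo[2]), float(hi[2])),
        n_boot=n_boot,
        n_boot_failed=n_failed,
        seed=seed,
        mode=mode,
    )
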