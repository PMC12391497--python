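"""Cohort preparation: height cleaning, BMI, exclusions, metabolic health, EAA.

Turns a raw subject table (one row per participant, delimited text) into the
analysis sample.  The steps, in order:

1. clean per-wave self-reported heights within person and average them;
2. compute BMI = weight [kg] / height [m]^2;
3. apply the exclusion cascade (short stature, extreme BMI, erratic heights,
   then missing-data rules), logging every excluded id under the first rule
   it hits;
4. classify metabolic health from the four component flags (hypertension,
   hyperglycaemia, hypertriglyceridaemia, low HDL-C), under a strict
   (any component present = unhealthy) or less-strict (two or more =
   unhealthy) definition;
5. construct epigenetic age acceleration (EAA) per clock as the residual of
   an OLS regression of clock age on chronological age, on the post-exclusion
   sample.  DunedinPACE is a pace-of-ageing measure and passes through
   unresidualised.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CLOCKS",
    "MEDIATION_CLOCKS",
    "PrepConfig",
    "ExclusionLog",
    "clean_height",
    "compute_bmi",
    "apply_exclusions",
    "classify_metabolic_health",
    "compute_eaa",
    "prepare_cohort",
    "mediator_column",
    "characteristics_table",
]

#: Residualised clocks, in reporting order.
CLOCKS = ("horvath1", "horvath2", "hannum", "phenoage", "grimage")
#: Mediators carried into the mediation analyses by default.
MEDIATION_CLOCKS = ("hannum", "phenoage", "grimage", "dunedin_pace")

METABOLIC_FLAGS = ("hypertension", "hyperglycemia", "hypertriglyceridemia", "low_hdl")

#: Exclusion rules in the order they claim subjects (first rule wins).
EXCLUSION_RULES = (
    "height_below_min",
    "bmi_above_max",
    "height_variation",
    "missing_metabolic",
    "missing_smoking",
    "missing_weight",
    "missing_height",
    "missing_vital_status",
)


@dataclass(frozen=True)
class PrepConfig:
    """Tunable preparation rules.

    ``height_dev_threshold`` is in units of the subject's own across-wave
    standard deviation; wave heights further than that from the subject's
    mean are set missing before averaging.  ``height_max_spread`` [m] is the
    residual across-wave SD above which the subject is flagged for the
    erratic-height exclusion.
    """

    height_dev_threshold: float = 1.0
    height_min_m: float = 1.35
    height_max_spread_m: float = 0.05
    bmi_max: float = 60.0
    metabolic_definition: str = "strict"  # or "less_strict"
    eaa_direction: str = "clock_on_age"  # or "age_on_clock"

    def __post_init__(self) -> None:
        if self.metabolic_definition not in ("strict", "less_strict"):
            raise ValueError(f"unknown metabolic definition {self.metabolic_definition!r}")
        if self.eaa_direction not in ("clock_on_age", "age_on_clock"):
            raise ValueError(f"unknown EAA direction {self.eaa_direction!r}")


@dataclass
class ExclusionLog:
    n_input: int = 0
    n_output: int = 0
    counts: dict = field(default_factory=dict)
    ids: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"rule": list(self.counts), "n_excluded": list(self.counts.values())}
        )


def clean_height(
    heights_by_wave,
    dev_threshold: float = 1.0,
    max_spread_m: float = 0.05,
) -> tuple[float, bool]:
    """Clean one subject's per-wave heights (metres).

    Wave values deviating from the subject's across-wave mean by more than
    ``dev_threshold`` times the subject's across-wave SD are dropped; the
    mean of what remains is returned.  Returns ``(mean_height, flag)`` where
    ``flag`` marks the erratic-height exclusion: everything was dropped, or
    the surviving values still spread more than ``max_spread_m``.  A subject
    with no recorded height at all gets ``(nan, False)`` — that is a
    missing-height case, not an erratic one.
    """
    h = np.asarray(list(heights_by_wave), dtype=float)
    h = h[np.isfinite(h)]
    if h.size == 0:
        return float("nan"), False
    if h.size == 1:
        return float(h[0]), False
    sd = float(np.std(h, ddof=1))
    if sd > 0:
        keep = np.abs(h - h.mean()) <= dev_threshold * sd
        h = h[keep]
    if h.size == 0:
        return float("nan"), True
    spread = float(np.std(h, ddof=1)) if h.size > 1 else 0.0
    return float(np.mean(h)), spread > max_spread_m


def compute_bmi(weight_kg, height_m):
    """BMI = weight [kg] / height [m]^2; vectorised; inputs must be positive."""
    w = np.asarray(weight_kg, dtype=float)
    h = np.asarray(height_m, dtype=float)
    with np.errstate(invalid="ignore"):
        if np.any(w[np.isfinite(w)] <= 0) or np.any(h[np.isfinite(h)] <= 0):
            raise ValueError("weight and height must be positive")
    return w / h**2


def classify_metabolic_health(flags, definition: str = "strict"):
    """Binary metabolically-unhealthy indicator from the four component flags.

    ``flags``: length-4 sequence (or (n, 4) array) of {0, 1, NaN}.  At most
    one flag may be missing (a missing flag counts as component-absent);
    more than one missing should have been excluded upstream and raises.

    strict: unhealthy iff >= 1 component present.
    less_strict: unhealthy iff >= 2 components present ("no more than one"
    component still counts as healthy).
    """
    a = np.atleast_2d(np.asarray(flags, dtype=float))
    if a.shape[1] != len(METABOLIC_FLAGS):
        raise ValueError(f"expected {len(METABOLIC_FLAGS)} flags, got {a.shape[1]}")
    n_missing = np.isnan(a).sum(axis=1)
    if np.any(n_missing > 1):
        raise ValueError("more than one missing metabolic flag; record should be excluded")
    count = np.nansum(a, axis=1)
    if definition == "strict":
        out = (count >= 1).astype(int)
    elif definition == "less_strict":
        out = (count >= 2).astype(int)
    else:
        raise ValueError(f"unknown metabolic definition {definition!r}")
    return out if np.ndim(flags) > 1 else int(out[0])


def compute_eaa(clock_age, chron_age, direction: str = "clock_on_age") -> np.ndarray:
    """EAA residuals from a simple OLS of clock age on chronological age.

    ``direction='clock_on_age'`` (default, the field convention: positive
    residual = epigenetically older than expected for one's age) regresses
    clock age on chronological age; ``'age_on_clock'`` reverses the roles.
    Residuals have mean 0 and zero sample covariance with the regressor.
    """
    y = np.asarray(clock_age, dtype=float)
    t = np.asarray(chron_age, dtype=float)
    if y.size < 3:
        raise ValueError("need at least 3 subjects to residualise")
    if direction == "age_on_clock":
        y, t = t, y
    if np.ptp(t) == 0:
        raise ValueError("regressor is constant; cannot residualise")
    X = np.column_stack([np.ones_like(t), t])
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    return y - X @ coef


def _height_wave_columns(df: pd.DataFrame) -> list[str]:
    cols = [c for c in df.columns if c.startswith("height_w")]
    if not cols:
        raise ValueError("no per-wave height columns (height_w*) in input table")
    return sorted(cols)


def apply_exclusions(df: pd.DataFrame, config: PrepConfig) -> tuple[pd.DataFrame, ExclusionLog]:
    """Apply the exclusion cascade; first matching rule claims the subject.

    Expects columns ``height`` (cleaned mean), ``height_flag`` (erratic
    indicator), ``bmi``, the four metabolic flags, ``smoking``, ``weight``
    and ``died``.
    """
    log = ExclusionLog(n_input=len(df))
    masks = {
        "height_below_min": df["height"] < config.height_min_m,
        "bmi_above_max": df["bmi"] > config.bmi_max,
        "height_variation": df["height_flag"].astype(bool),
        "missing_metabolic": df[list(METABOLIC_FLAGS)].isna().sum(axis=1) > 1,
        "missing_smoking": df["smoking"].isna(),
        "missing_weight": df["weight"].isna(),
        "missing_height": df["height"].isna() & ~df["height_flag"].astype(bool),
        "missing_vital_status": df["died"].isna(),
    }
    claimed = pd.Series(False, index=df.index)
    for rule in EXCLUSION_RULES:
        hit = masks[rule].fillna(False) & ~claimed
        log.counts[rule] = int(hit.sum())
        log.ids[rule] = df.loc[hit, "id"].tolist() if "id" in df else df.index[hit].tolist()
        claimed |= hit
    out = df.loc[~claimed].copy()
    log.n_output = len(out)
    return out, log


def prepare_cohort(df: pd.DataFrame, config: PrepConfig | None = None) -> tuple[pd.DataFrame, ExclusionLog]:
    """Raw subject table -> analysis sample plus exclusion log."""
    config = config or PrepConfig()
    df = df.copy()
    wave_cols = _height_wave_columns(df)
    cleaned = [
        clean_height(row, config.height_dev_threshold, config.height_max_spread_m)
        for row in df[wave_cols].to_numpy()
    ]
    df["height"] = [c[0] for c in cleaned]
    df["height_flag"] = [c[1] for c in cleaned]
    df["bmi"] = compute_bmi(df["weight"].to_numpy(), df["height"].to_numpy())

    out, log = apply_exclusions(df, config)

    out["metab_unhealthy"] = classify_metabolic_health(
        out[list(METABOLIC_FLAGS)].to_numpy(), config.metabolic_definition
    )
    # EAA is sample-relative: residualise on the post-exclusion sample only.
    for clock in CLOCKS:
        out[f"eaa_{clock}"] = compute_eaa(
            out[f"{clock}_age"].to_numpy(),
            out["baseline_age"].to_numpy(),
            config.eaa_direction,
        )
    out["exit_age"] = out["baseline_age"] + out["followup_years"]
    if (out["followup_years"] <= 0).any():
        raise ValueError("non-positive follow-up time after exclusions")
    return out.reset_index(drop=True), log


def mediator_column(clock: str) -> str:
    """Data column holding the mediator for a given clock."""
    if clock == "dunedin_pace":
        return "dunedin_pace"
    if clock not in CLOCKS:
        raise KeyError(f"unknown clock {clock!r}")
    return f"eaa_{clock}"


def _bmi_category(bmi: pd.Series) -> pd.Series:
    return pd.cut(
        bmi,
        bins=[0, 25.0, 30.0, np.inf],
        right=False,
        labels=["<25.0", "25.0-29.9", ">=30.0"],
    )


def characteristics_table(df: pd.DataFrame) -> pd.DataFrame:
    """Descriptive table by BMI category: mean (SD) / n (%) per characteristic."""
    df = df.assign(bmi_cat=_bmi_category(df["bmi"]))
    groups = {"Overall": df, **{str(k): g for k, g in df.groupby("bmi_cat", observed=True)}}
    continuous = {
        "Follow-up time (years)": "followup_years",
        "Baseline age (years)": "baseline_age",
        "BMI (kg/m2)": "bmi",
        **{f"EAA {c}": f"eaa_{c}" for c in CLOCKS},
        "DunedinPACE": "dunedin_pace",
    }
    binary = {
        "Female": ("sex", "female"),
        "Education <= high school": ("education", "below"),
        "Never smoker": ("smoking", "never"),
        "Former smoker": ("smoking", "former"),
        "Current smoker": ("smoking", "current"),
        "White": ("ethnicity", "white"),
        "Black": ("ethnicity", "black"),
        "Other ethnicity": ("ethnicity", "other"),
    }
    rows = {}
    rows["n"] = {name: f"{len(g)}" for name, g in groups.items()}
    for label, col in continuous.items():
        if col not in df:
            continue
        rows[label] = {
            name: f"{g[col].mean():.1f} ({g[col].std():.1f})" for name, g in groups.items()
        }
    for label, (col, level) in binary.items():
        rows[label] = {
            name: f"{(g[col] == level).sum()} ({100 * (g[col] == level).mean():.1f}%)"
            for name, g in groups.items()
        }
    for col, label in [
        *[(f, f.replace("_", " ").capitalize()) for f in METABOLIC_FLAGS],
        ("metab_unhealthy", "Metabolically unhealthy"),
        ("died", "Deceased"),
    ]:
        if col not in df:
            continue
        rows[label] = {
            name: f"{int(g[col].sum())} ({100 * g[col].mean():.1f}%)"
            for name, g in groups.items()
        }
    return pd.DataFrame(rows).T
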