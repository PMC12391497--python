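"""Restricted cubic spline (natural cubic spline) bases.

The regressions in this package model BMI, epigenetic age acceleration and
(optionally) age with restricted cubic splines: piecewise cubics constrained
to be linear beyond the boundary knots.  The basis is the classic restricted
truncated-power construction (Harrell), *without* the usual rescaling by the
squared knot range, so every coefficient is reproducible bit-for-bit from the
knot locations alone.

With knots t_1 < ... < t_k the basis has k-1 columns: the identity column x
and, for j = 1..k-2,

    C_j(x) = (x - t_j)_+^3
             - (x - t_{k-1})_+^3 * (t_k - t_j) / (t_k - t_{k-1})
             + (x - t_k)_+^3     * (t_{k-1} - t_j) / (t_k - t_{k-1}),

which is 0 below t_1 and exactly linear above t_k.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["SplineSpec", "place_knots", "rcs_basis", "KNOT_QUANTILES"]

#: Conventional outer/inner quantiles for k = 3, 4, 5 knots.
KNOT_QUANTILES: dict[int, tuple[float, ...]] = {
    3: (0.10, 0.50, 0.90),
    4: (0.05, 0.35, 0.65, 0.95),
    5: (0.05, 0.275, 0.50, 0.725, 0.95),
}


class DegeneratePredictorError(ValueError):
    """Predictor has too few distinct values to place the requested knots."""


@dataclass(frozen=True)
class SplineSpec:
    """Knot locations for a restricted cubic spline, on the predictor's scale.

    ``n_basis`` (number of knots minus one) counts the basis columns,
    including the leading linear column.
    """

    knots: tuple[float, ...]

    def __post_init__(self) -> None:
        knots = tuple(float(t) for t in self.knots)
        if len(knots) < 3:
            raise ValueError(f"need at least 3 knots, got {len(knots)}")
        if not all(a < b for a, b in zip(knots, knots[1:])):
            raise ValueError(f"knots must be strictly increasing: {knots}")
        object.__setattr__(self, "knots", knots)

    @property
    def n_basis(self) -> int:
        return len(self.knots) - 1

    def to_dict(self) -> dict:
        return {"knots": list(self.knots)}

    @classmethod
    def from_dict(cls, d: dict) -> "SplineSpec":
        return cls(knots=tuple(d["knots"]))


def place_knots(x, k: int = 4) -> SplineSpec:
    """Place ``k`` knots at the conventional sample quantiles of ``x``.

    Raises :class:`DegeneratePredictorError` if ``x`` has fewer than ``k``
    distinct values or the quantiles coincide.
    """
    if k not in KNOT_QUANTILES:
        raise ValueError(f"knot count must be one of {sorted(KNOT_QUANTILES)}, got {k}")
    x = np.asarray(x, dtype=float)
    x = x[np.isfinite(x)]
    if np.unique(x).size < k:
        raise DegeneratePredictorError(
            f"predictor has {np.unique(x).size} distinct values; need >= {k}"
        )
    knots = np.quantile(x, KNOT_QUANTILES[k])
    if not np.all(np.diff(knots) > 0):
        raise DegeneratePredictorError(
            f"coincident knot quantiles {knots}; predictor too concentrated"
        )
    return SplineSpec(knots=tuple(knots))


def rcs_basis(x, spec: SplineSpec) -> np.ndarray:
    """Evaluate the restricted cubic spline basis at ``x``.

    Returns an array of shape ``(len(x), spec.n_basis)`` whose first column
    is ``x`` itself and whose remaining columns are the restricted
    truncated-power terms.  ``x`` must be finite.
    """
    x = np.atleast_1d(np.asarray(x, dtype=float))
    if not np.all(np.isfinite(x)):
        raise ValueError("spline predictor contains non-finite values")
    t = np.asarray(spec.knots)
    k = t.size
    denom = t[-1] - t[-2]

    def cube(v):
        return np.where(v > 0.0, v, 0.0) ** 3

    cols = [x]
    for j in range(k - 2):
        cols.append(
            cube(x - t[j])
            - cube(x - t[-2]) * (t[-1] - t[j]) / denom
            + cube(x - t[-1]) * (t[-2] - t[j]) / denom
        )
    return np.column_stack(cols)
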