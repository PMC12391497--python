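"""Design-matrix construction shared by the mediator and outcome models.

A :class:`DesignSpec` is an ordered list of terms — splined continuous
variables, linear continuous variables, and categorical variables expanded
into treatment-coded dummies against a fixed reference level.  The same spec
builds the observed design, and counterfactual designs in which one variable
(BMI, or the mediator) is overridden while every other column keeps its
observed value.  No intercept column is emitted: the linear mediator model
adds one explicitly and the Gompertz baseline level plays that role in the
outcome model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .splines import SplineSpec, rcs_basis

__all__ = ["Term", "DesignSpec", "CATEGORICAL_LEVELS"]

#: Fixed level order per categorical variable; the first level is the reference.
CATEGORICAL_LEVELS: dict[str, tuple[str, ...]] = {
    "sex": ("male", "female"),
    "ethnicity": ("white", "black", "other"),
    "education": ("below", "college+"),
    "smoking": ("never", "former", "current"),
}


@dataclass(frozen=True)
class Term:
    """One design term: ``kind`` is 'linear', 'spline' or 'categorical'."""

    var: str
    kind: str = "linear"
    spline: SplineSpec | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("linear", "spline", "categorical"):
            raise ValueError(f"unknown term kind {self.kind!r}")
        if self.kind == "spline" and self.spline is None:
            raise ValueError(f"spline term {self.var!r} needs a SplineSpec")

    def column_names(self) -> list[str]:
        if self.kind == "linear":
            return [self.var]
        if self.kind == "spline":
            # Harrell-style primes for the nonlinear columns.
            return [self.var + "'" * j for j in range(self.spline.n_basis)]
        levels = CATEGORICAL_LEVELS[self.var]
        return [f"{self.var}[{lev}]" for lev in levels[1:]]

    def to_dict(self) -> dict:
        d = {"var": self.var, "kind": self.kind}
        if self.spline is not None:
            d["spline"] = self.spline.to_dict()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "Term":
        spline = SplineSpec.from_dict(d["spline"]) if "spline" in d else None
        return cls(var=d["var"], kind=d["kind"], spline=spline)


@dataclass(frozen=True)
class DesignSpec:
    terms: tuple[Term, ...]

    def __post_init__(self) -> None:
        vars_ = [t.var for t in self.terms]
        if len(set(vars_)) != len(vars_):
            raise ValueError(f"duplicate design variables: {vars_}")

    @property
    def column_names(self) -> list[str]:
        names: list[str] = []
        for t in self.terms:
            names.extend(t.column_names())
        return names

    @property
    def n_columns(self) -> int:
        return len(self.column_names)

    def term(self, var: str) -> Term:
        for t in self.terms:
            if t.var == var:
                return t
        raise KeyError(f"variable {var!r} not in design")

    def has(self, var: str) -> bool:
        return any(t.var == var for t in self.terms)

    def slices(self) -> dict[str, slice]:
        """Mapping variable -> slice of its columns in the built matrix."""
        out, start = {}, 0
        for t in self.terms:
            width = len(t.column_names())
            out[t.var] = slice(start, start + width)
            start += width
        return out

    def build(
        self,
        data: pd.DataFrame,
        overrides: dict[str, float | np.ndarray] | None = None,
    ) -> np.ndarray:
        """Build the (n, n_columns) design matrix.

        ``overrides`` replaces a variable's values (scalar broadcast or
        per-row array) before basis expansion — the counterfactual hook.
        """
        overrides = overrides or {}
        n = len(data)
        blocks: list[np.ndarray] = []
        for t in self.terms:
            if t.var in overrides:
                vals = np.broadcast_to(
                    np.asarray(overrides[t.var], dtype=float), (n,)
                ).copy() if t.kind != "categorical" else overrides[t.var]
            else:
                vals = data[t.var].to_numpy()
            if t.kind == "linear":
                blocks.append(np.asarray(vals, dtype=float).reshape(n, 1))
            elif t.kind == "spline":
                blocks.append(rcs_basis(np.asarray(vals, dtype=float), t.spline))
            else:
                levels = CATEGORICAL_LEVELS[t.var]
                vals = np.asarray(vals)
                bad = ~np.isin(vals, levels)
                if bad.any():
                    raise ValueError(
                        f"{t.var!r} has levels outside {levels}: "
                        f"{sorted(set(vals[bad]))}"
                    )
                blocks.append(
                    np.column_stack([(vals == lev).astype(float) for lev in levels[1:]])
                )
        if not blocks:
            return np.empty((n, 0))
        return np.hstack(blocks)

    def to_dict(self) -> dict:
        return {"terms": [t.to_dict() for t in self.terms]}

    @classmethod
    def from_dict(cls, d: dict) -> "DesignSpec":
        return cls(terms=tuple(Term.from_dict(t) for t in d["terms"]))


def check_full_rank(X: np.ndarray, names: list[str]) -> None:
    """Raise naming the offending columns if ``X`` is rank deficient."""
    if X.shape[1] == 0:
        return
    r = np.linalg.matrix_rank(X)
    if r < X.shape[1]:
        # QR with pivoting points at the dependent columns.
        _, R, piv = __import__("scipy.linalg", fromlist=["qr"]).qr(
            X, mode="economic", pivoting=True
        )
        diag = np.abs(np.diag(R))
        tol = diag.max() * max(X.shape) * np.finfo(float).eps
        bad = [names[piv[i]] for i in range(len(diag)) if diag[i] < tol]
        raise np.linalg.LinAlgError(
            f"design is collinear (rank {r} < {X.shape[1]}); "
            f"dependent columns: {bad}"
        )
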