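"""Penalized cubic B-spline bases for nonparametric covariate effects.

Each smooth covariate effect f(x) is a linear combination of ``q`` B-spline
basis functions with interior knots at empirical quantiles of the observed
covariate. Roughness is penalized through the integrated squared second
derivative, the quadratic form theta' Omega theta with
Omega_ij = integral B_i''(u) B_j''(u) du.

Identifiability: the intercepts must absorb the level of every smooth term,
so each fitted curve is constrained to empirical mean zero on the fitting
data (curves cross zero at the covariate mean). Because B-splines form a
partition of unity, simply mean-centering the columns leaves an exact flat
direction (all-equal coefficients represent the zero function with zero
penalty), so the constraint c'theta = 0 — with c the vector of basis column
means — is absorbed into the basis instead: coefficients live in the
(q-1)-dimensional null space of c', reached through an orthonormal map Z.
This is the standard sum-to-zero reparameterization for penalized additive
models and removes the rank deficiency entirely.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import BSpline
from scipy.linalg import null_space

from .exceptions import DesignError

# 3-point Gauss-Legendre nodes/weights on [0, 1]; exact for polynomials up to
# degree 5, more than enough for products of piecewise-linear B'' (degree 2).
_GL_NODES = (np.array([-np.sqrt(0.6), 0.0, np.sqrt(0.6)]) + 1.0) / 2.0
_GL_WEIGHTS = np.array([5.0, 8.0, 5.0]) / 18.0


@dataclass
class SplineBasis:
    """Constrained B-spline basis for one covariate.

    Attributes
    ----------
    name : covariate name.
    knots : full knot vector (boundary knots repeated ``degree + 1`` times).
    degree : spline degree (3 = cubic).
    center : empirical column means of the raw basis on the fitting data; the
        centering constraint is ``center @ theta = 0``.
    constraint_map : orthonormal ``(q, q-1)`` map Z from constrained
        coefficients to raw B-spline coefficients.
    """

    name: str
    knots: np.ndarray
    degree: int
    center: np.ndarray = field(default=None)
    constraint_map: np.ndarray = field(default=None)

    @property
    def q(self) -> int:
        """Number of raw B-spline basis functions."""
        return len(self.knots) - self.degree - 1

    @property
    def dim(self) -> int:
        """Number of free (constrained) coefficients = q - 1."""
        return self.q - 1

    @property
    def lower(self) -> float:
        return float(self.knots[self.degree])

    @property
    def upper(self) -> float:
        return float(self.knots[-self.degree - 1])

    # -- construction -------------------------------------------------------
    @classmethod
    def from_data(cls, x, name: str, q: int = 10, degree: int = 3) -> "SplineBasis":
        """Build a basis with interior knots at empirical quantiles of ``x``.

        ``q`` basis functions need ``q - degree - 1`` distinct interior knots;
        a :class:`DesignError` is raised when the covariate has too few
        distinct values to place them.
        """
        x = np.asarray(x, dtype=float)
        n_interior = q - degree - 1
        if n_interior < 0 or q < degree + 1 or q < 2:
            raise DesignError(f"q={q} incompatible with degree={degree}")
        lo, hi = float(np.min(x)), float(np.max(x))
        if lo == hi:
            raise DesignError(f"covariate {name!r} is constant; cannot build a spline basis")
        if n_interior > 0:
            probs = np.linspace(0, 1, n_interior + 2)[1:-1]
            interior = np.quantile(x, probs)
            if len(np.unique(interior)) < n_interior or interior[0] <= lo or interior[-1] >= hi:
                raise DesignError(
                    f"covariate {name!r} has too few distinct values for "
                    f"{n_interior} interior knots"
                )
        else:
            interior = np.array([])
        knots = np.concatenate([[lo] * (degree + 1), interior, [hi] * (degree + 1)])
        basis = cls(name=name, knots=knots, degree=degree)
        basis.center = basis.evaluate(x).mean(axis=0)
        Z = null_space(basis.center[None, :])
        if Z.shape[1] != basis.q - 1:  # pragma: no cover - c is never the zero vector
            raise DesignError(f"degenerate centering constraint for {name!r}")
        # fix signs for reproducibility (null_space columns are sign-arbitrary)
        signs = np.sign(Z[np.argmax(np.abs(Z), axis=0), np.arange(Z.shape[1])])
        basis.constraint_map = Z * signs
        return basis

    # -- evaluation ---------------------------------------------------------
    def _spline(self, nu: int = 0) -> BSpline:
        coef = np.eye(self.q)
        sp = BSpline(self.knots, coef, self.degree, extrapolate=False)
        return sp.derivative(nu) if nu else sp

    def evaluate(self, x, nu: int = 0, clamp: bool = True) -> np.ndarray:
        """Raw basis functions (or ``nu``-th derivatives) at ``x``; points
        outside the knot range are clamped to the boundary (the documented
        extrapolation policy for prediction on new subjects)."""
        x = np.asarray(x, dtype=float)
        if clamp:
            x = np.clip(x, self.lower, self.upper)
        out = self._spline(nu)(x)
        return np.nan_to_num(out, nan=0.0)

    def evaluate_centered(self, x, clamp: bool = True) -> np.ndarray:
        """Constrained basis columns: empirical mean zero on the fitting data
        by construction, ``dim = q - 1`` of them."""
        if self.constraint_map is None:
            raise DesignError("basis has no constraint map; build it with from_data")
        return self.evaluate(x, clamp=clamp) @ self.constraint_map

    def greville(self) -> np.ndarray:
        """Greville abscissae: raw coefficients ``a + b * greville()``
        represent the affine function ``a + b x`` exactly."""
        k, t = self.degree, self.knots
        return np.array([t[i + 1 : i + k + 1].mean() for i in range(self.q)])

    def affine_coefs(self, slope: float) -> np.ndarray:
        """Constrained coefficients representing ``slope * x`` minus its
        empirical mean (used for warm starts and penalty-limit checks)."""
        theta = slope * self.greville()
        theta = theta - (self.center @ theta) * np.ones(self.q)  # c'1 = 1
        return self.constraint_map.T @ theta

    # -- curvature penalty --------------------------------------------------
    @property
    def penalty_raw(self) -> np.ndarray:
        """Exact Omega_ij = integral B_i'' B_j'' du over the knot range.

        Computed per knot interval with 3-point Gauss-Legendre quadrature,
        exact because products of second derivatives of degree-``d`` splines
        are piecewise polynomials of degree ``2(d-2)``. Symmetric PSD with
        the affine coefficient vectors in its null space.
        """
        if getattr(self, "_penalty_raw", None) is None:
            q = self.q
            omega = np.zeros((q, q))
            if self.degree >= 2:
                breaks = np.unique(self.knots)
                d2 = self._spline(nu=2)
                for a, b in zip(breaks[:-1], breaks[1:]):
                    if b <= a:
                        continue
                    pts = a + (b - a) * _GL_NODES
                    vals = np.nan_to_num(d2(pts), nan=0.0)  # (3, q)
                    omega += (b - a) * (vals * _GL_WEIGHTS[:, None]).T @ vals
                omega = 0.5 * (omega + omega.T)
            self._penalty_raw = omega
        return self._penalty_raw

    @property
    def penalty(self) -> np.ndarray:
        """Constrained penalty Z' Omega Z; its null space is the centered
        affine direction."""
        if getattr(self, "_penalty", None) is None:
            Z = self.constraint_map
            P = Z.T @ self.penalty_raw @ Z
            self._penalty = 0.5 * (P + P.T)
        return self._penalty

    def roughness(self, beta) -> float:
        """beta' (Z' Omega Z) beta = integrated squared second derivative."""
        beta = np.asarray(beta, dtype=float)
        return float(beta @ self.penalty @ beta)

    # -- serialization ------------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "knots": self.knots.tolist(),
            "degree": int(self.degree),
            "center": self.center.tolist() if self.center is not None else None,
            "constraint_map": (
                None if self.constraint_map is None else self.constraint_map.tolist()
            ),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SplineBasis":
        center = None if d.get("center") is None else np.asarray(d["center"], dtype=float)
        cmap = None if d.get("constraint_map") is None else np.asarray(
            d["constraint_map"], dtype=float
        )
        return cls(
            name=d["name"],
            knots=np.asarray(d["knots"], dtype=float),
            degree=int(d["degree"]),
            center=center,
            constraint_map=cmap,
        )
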