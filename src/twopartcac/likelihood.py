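"""Design construction and the (penalized) two-part log-likelihood.

The two-part model pairs a logistic regression for the zero / nonzero CAC
indicator z with a Normal linear model for t = log(1 + CAC) among the nonzero
scores:

    P(z = 1 | x)   = expit(eta1(x)),   eta1 = a0 + s1(x)
    t | z = 1, x  ~  Normal(eta2(x), sigma^2),   eta2 = b0 + s2(x)

Proportional variants constrain the two covariate indices to differ only by a
scale factor: s2 = tau * s1. The per-subject log-likelihood is

    l_i = (1 - z_i) log(1 - p_i)
        + z_i [ log p_i - log sigma - (t_i - eta2_i)^2 / (2 sigma^2)
                - log(2 pi) / 2 ]

The Normal constant is retained so likelihood values are directly comparable
across nested variants (it cancels in differences regardless). The penalized
criterion divides by n and subtracts lambda * sum_k theta_k' Omega_k theta_k
over every distinct spline coefficient block (both parts for nonproportional
specs, the shared block once for proportional specs).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from .exceptions import DesignError
from .specs import ModelSpec
from .splines import SplineBasis

_LOG_2PI = float(np.log(2.0 * np.pi))


# ---------------------------------------------------------------------------
# design bundle
# ---------------------------------------------------------------------------


@dataclass
class Design:
    """Maps a cohort's covariate columns to effect columns.

    One instance serves both model parts (they share the column layout).
    ``labels[j]`` names effect column j; ``spline_slices`` maps each smooth
    covariate to its block of columns; ``penalty_matrix`` is the block-diagonal
    curvature penalty (zero outside spline blocks).
    """

    spec: ModelSpec
    labels: list[str]
    bases: dict[str, SplineBasis] = field(default_factory=dict)
    spline_slices: dict[str, slice] = field(default_factory=dict)

    @property
    def p(self) -> int:
        return len(self.labels)

    @classmethod
    def from_data(cls, spec: ModelSpec, X: pd.DataFrame) -> "Design":
        labels: list[str] = []
        bases: dict[str, SplineBasis] = {}
        slices: dict[str, slice] = {}
        for cov, kind in spec.effects.items():
            if cov not in X.columns:
                raise DesignError(f"spec covariate {cov!r} not found in the cohort")
            x = X[cov].to_numpy(dtype=float)
            if kind == "linear":
                labels.append(cov)
            elif kind == "quadratic":
                labels.extend([cov, f"{cov}^2"])
            else:
                basis = SplineBasis.from_data(x, cov, q=spec.basis_dim, degree=spec.degree)
                start = len(labels)
                labels.extend(f"{cov}:s{j + 1}" for j in range(basis.dim))
                bases[cov] = basis
                slices[cov] = slice(start, start + basis.dim)
        return cls(spec=spec, labels=labels, bases=bases, spline_slices=slices)

    def matrix(self, X: pd.DataFrame) -> np.ndarray:
        """Evaluate the effect columns on (new) data; spline covariates outside
        the training range are clamped to the boundary."""
        cols = np.empty((len(X), self.p))
        j = 0
        for cov, kind in self.spec.effects.items():
            x = X[cov].to_numpy(dtype=float)
            if kind == "linear":
                cols[:, j] = x
                j += 1
            elif kind == "quadratic":
                cols[:, j] = x
                cols[:, j + 1] = x * x
                j += 2
            else:
                basis = self.bases[cov]
                cols[:, j : j + basis.dim] = basis.evaluate_centered(x)
                j += basis.dim
        return cols

    def penalty_matrix(self) -> np.ndarray:
        P = np.zeros((self.p, self.p))
        for cov, sl in self.spline_slices.items():
            P[sl, sl] = self.bases[cov].penalty
        return P

    def roughness(self, theta: np.ndarray) -> float:
        """sum over smooth terms of theta_k' Omega_k theta_k for one part."""
        total = 0.0
        for cov, sl in self.spline_slices.items():
            total += self.bases[cov].roughness(theta[sl])
        return total

    def to_dict(self) -> dict:
        return {
            "spec": self.spec.to_dict(),
            "labels": list(self.labels),
            "bases": {k: b.to_dict() for k, b in self.bases.items()},
            "spline_slices": {k: [sl.start, sl.stop] for k, sl in self.spline_slices.items()},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Design":
        return cls(
            spec=ModelSpec.from_dict(d["spec"]),
            labels=list(d["labels"]),
            bases={k: SplineBasis.from_dict(b) for k, b in d["bases"].items()},
            spline_slices={k: slice(a, b) for k, (a, b) in d["spline_slices"].items()},
        )


def build_design(spec: ModelSpec, cohort: pd.DataFrame) -> Design:
    """Build the effect-column bundle for ``spec`` on a cohort table."""
    return Design.from_data(spec, cohort)


# ---------------------------------------------------------------------------
# parameters
# ---------------------------------------------------------------------------


@dataclass
class TwoPartParams:
    """Point in the parameter space of one model variant.

    ``theta1`` holds the logistic-part effect coefficients (the shared index
    for proportional variants, which is anchored in the logistic part with
    ``tau`` scaling it into the continuous part); ``theta2`` holds the free
    continuous-part coefficients of nonproportional variants.
    """

    a0: float
    b0: float
    theta1: np.ndarray
    sigma: float
    tau: float | None = None
    theta2: np.ndarray | None = None
    anchor: str = "logistic"

    def __post_init__(self):
        self.theta1 = np.asarray(self.theta1, dtype=float)
        if self.theta2 is not None:
            self.theta2 = np.asarray(self.theta2, dtype=float)
        if self.sigma <= 0:
            raise ValueError(f"sigma must be > 0, got {self.sigma}")
        if (self.tau is None) == (self.theta2 is None):
            raise ValueError("exactly one of tau (proportional) or theta2 must be given")
        if self.anchor not in ("logistic", "continuous"):
            raise ValueError(f"unknown anchor {self.anchor!r}")

    @property
    def part_scales(self) -> tuple[float, float]:
        """(s1, s2) with eta1 = a0 + s1*u and eta2 = b0 + s2*u, u the shared
        index; the anchored part has scale 1, tau multiplies the other."""
        if self.anchor == "logistic":
            return 1.0, self.tau
        return self.tau, 1.0

    @property
    def proportional(self) -> bool:
        return self.tau is not None

    def flat_labels(self, design: Design) -> list[str]:
        labels = ["a0", "b0"]
        labels += [f"logistic:{l}" for l in design.labels]
        if self.proportional:
            labels.append("tau")
        else:
            labels += [f"linear:{l}" for l in design.labels]
        labels.append("sigma")
        return labels

    def flatten(self) -> np.ndarray:
        tail = [self.tau] if self.proportional else list(self.theta2)
        return np.array([self.a0, self.b0, *self.theta1, *tail, self.sigma])


def linear_predictors(params: TwoPartParams, design: Design,
                      X: "pd.DataFrame | np.ndarray") -> tuple[np.ndarray, np.ndarray]:
    """(eta1, eta2) for every row; proportional variants satisfy
    eta2 - b0 = tau * (eta1 - a0) exactly, row-wise."""
    M = X if isinstance(X, np.ndarray) else design.matrix(X)
    if M.shape[1] != design.p:
        raise DesignError(f"design matrix has {M.shape[1]} columns, expected {design.p}")
    u = M @ params.theta1
    if params.proportional:
        s1, s2 = params.part_scales
        eta1 = params.a0 + s1 * u
        eta2 = params.b0 + s2 * u
    else:
        eta1 = params.a0 + u
        eta2 = params.b0 + M @ params.theta2
    return eta1, eta2


# ---------------------------------------------------------------------------
# log-likelihood
# ---------------------------------------------------------------------------


def bernoulli_loglik(eta1: np.ndarray, z: np.ndarray) -> float:
    """sum_i z_i log p_i + (1 - z_i) log(1 - p_i), via the stable log-sigmoid
    identity z*eta - log(1 + e^eta) (no probability clipping)."""
    return float(np.sum(z * eta1 - np.logaddexp(0.0, eta1)))


def normal_loglik(eta2: np.ndarray, t: np.ndarray, z: np.ndarray, sigma: float) -> float:
    """Conditional Normal log-density of t over the z = 1 subjects."""
    pos = z == 1
    r = t[pos] - eta2[pos]
    n1 = int(pos.sum())
    return float(-n1 * np.log(sigma) - 0.5 * np.sum(r * r) / sigma**2 - 0.5 * n1 * _LOG_2PI)


def log_likelihood(params: TwoPartParams, design: Design, cohort: pd.DataFrame,
                   M: np.ndarray | None = None) -> float:
    """Total two-part log-likelihood (full Normal constant included)."""
    if params.sigma <= 0:
        raise ValueError("sigma must be > 0")
    t = cohort["t"].to_numpy(dtype=float)
    z = cohort["z"].to_numpy()
    eta1, eta2 = linear_predictors(params, design, M if M is not None else cohort)
    return bernoulli_loglik(eta1, z) + normal_loglik(eta2, t, z, params.sigma)


def roughness_penalty(params: TwoPartParams, design: Design) -> float:
    """sum of theta' Omega theta over every distinct spline coefficient block."""
    pen = design.roughness(params.theta1)
    if not params.proportional and params.theta2 is not None:
        pen += design.roughness(params.theta2)
    return pen


def penalized_log_likelihood(params: TwoPartParams, design: Design,
                             cohort: pd.DataFrame, lam: float,
                             M: np.ndarray | None = None) -> float:
    """(1/n) log-likelihood minus lambda times the total roughness penalty."""
    if lam < 0:
        raise ValueError(f"penalty tuning parameter must be >= 0, got {lam}")
    n = len(cohort)
    return log_likelihood(params, design, cohort, M=M) / n - lam * roughness_penalty(
        params, design
    )


def probability_nonzero(params: TwoPartParams, design: Design, X) -> np.ndarray:
    eta1, _ = linear_predictors(params, design, X)
    return expit(eta1)
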