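"""Parametric-bootstrap inference for the two-part models.

Standard errors for every parameter (parametric coefficients, scale factor
tau, error SD sigma, and pointwise curves for smooth effects) come from
refitting the model to responses regenerated from the fitted model at the
observed covariate values. Nested model comparisons use the likelihood-ratio
statistic calibrated against its parametric-bootstrap distribution under the
fitted null model; semiparametric refits reuse the tuning parameter selected
on the original data rather than re-tuning per replicate.

Per-replicate random streams are derived from the master seed with a counter
scheme, so any replicate can be reproduced in isolation and a parallel run
would be bit-identical to the serial one.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import simulate_two_part
from .estimators import TwoPartModel
from .exceptions import ConvergenceError, DegenerateModelError, DesignError
from .likelihood import linear_predictors
from .specs import is_nested, load_spec


def _replicate_rng(master_seed: int, b: int) -> np.random.Generator:
    """Independent, reproducible stream for replicate ``b``."""
    return np.random.default_rng(np.random.SeedSequence([int(master_seed), int(b)]))


def simulate_from_fit(model: TwoPartModel, X: pd.DataFrame,
                      rng: np.random.Generator) -> np.ndarray:
    """Regenerate CAC responses from the fitted model at the observed
    covariates: z from the fitted logistic part, then t | z=1 from
    Normal(eta2, sigma^2) truncated to t > 0, cac = exp(t) - 1."""
    eta1, eta2 = linear_predictors(model.params_, model.design_, X)
    z, t = simulate_two_part(eta1, eta2, model.sigma_, rng)
    return np.where(z == 1, np.expm1(t), 0.0)


# ---------------------------------------------------------------------------
# bootstrap standard errors
# ---------------------------------------------------------------------------


@dataclass
class BootstrapResult:
    """Replicate estimates and derived standard errors.

    ``estimates`` is a (B_ok x p) frame of flat parameter vectors (columns
    labelled like ``logistic:age``, ``tau``, ``sigma``); ``se`` are the
    replicate standard deviations; ``smooth_sd`` maps each smooth covariate to
    a (grid, sd) frame of pointwise SDs per part.
    """

    B: int
    seed: int
    estimates: pd.DataFrame
    se: pd.Series
    smooth_sd: dict[str, pd.DataFrame] = field(default_factory=dict)
    n_failed: int = 0

    def to_dict(self) -> dict:
        # labels stored explicitly so column order survives key-sorting writers
        return {
            "B": int(self.B),
            "seed": int(self.seed),
            "labels": list(self.estimates.columns),
            "estimates": self.estimates.to_numpy().tolist(),
            "se": [float(self.se[k]) for k in self.estimates.columns],
            "smooth_sd": {k: v.to_dict(orient="list") for k, v in self.smooth_sd.items()},
            "n_failed": int(self.n_failed),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "BootstrapResult":
        labels = list(d["labels"])
        return cls(
            B=d["B"], seed=d["seed"],
            estimates=pd.DataFrame(np.asarray(d["estimates"]), columns=labels),
            se=pd.Series(dict(zip(labels, d["se"]))).reindex(labels),
            smooth_sd={
                k: pd.DataFrame(v)[[c for c in (k.split(":")[0], "sd")]]
                for k, v in d["smooth_sd"].items()
            },
            n_failed=d["n_failed"],
        )


def parametric_bootstrap(model: TwoPartModel, X: pd.DataFrame, B: int,
                         seed: int, smooth_grid_size: int = 101) -> BootstrapResult:
    """Bootstrap SEs for all parameters of a fitted model.

    Covariates are held fixed; responses are regenerated from the fit and the
    same spec is refitted with the same tuning parameter, warm-started at the
    point estimates. Replicates that fail to converge are dropped and logged;
    more than 10% failures aborts.
    """
    model._check_fitted()
    if B < 2:
        raise DesignError(f"B must be >= 2, got {B}")
    if B < 10:
        warnings.warn(f"bootstrap with B={B} replicates gives very noisy SEs",
                      RuntimeWarning)
    labels = model.labels_
    rows = []
    smooth_curves: dict[str, list] = {}
    grids: dict[str, np.ndarray] = {}
    for cov, basis in model.design_.bases.items():
        grids[cov] = np.linspace(basis.lower, basis.upper, smooth_grid_size)
        parts = ["logistic"] if model.params_.proportional else ["logistic", "linear"]
        for part in parts:
            smooth_curves[f"{cov}:{part}"] = []

    n_failed = 0
    for b in range(B):
        rng = _replicate_rng(seed, b)
        y_b = simulate_from_fit(model, X, rng)
        refit = TwoPartModel(spec=model.spec_, lam=model.lambda_, anchor=model.anchor,
                             random_state=model.random_state)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                refit.fit(X, y_b, starts=model.params_)
        except (ConvergenceError, DegenerateModelError):
            n_failed += 1
            continue
        rows.append(refit.flat_params())
        for key, store in smooth_curves.items():
            cov, part = key.split(":")
            store.append(refit.smooth_frame(cov, grid=grids[cov], part=part)["effect"].to_numpy())

    if n_failed > 0.1 * B:
        raise ConvergenceError(
            f"{n_failed}/{B} bootstrap replicates failed to converge; results would "
            "be biased"
        )
    estimates = pd.DataFrame(np.asarray(rows), columns=labels)
    se = estimates.std(axis=0, ddof=1)
    smooth_sd = {}
    for key, store in smooth_curves.items():
        cov, _ = key.split(":")
        arr = np.asarray(store)
        smooth_sd[key] = pd.DataFrame({cov: grids[cov], "sd": arr.std(axis=0, ddof=1)})
    return BootstrapResult(B=B, seed=seed, estimates=estimates, se=se,
                           smooth_sd=smooth_sd, n_failed=n_failed)


# ---------------------------------------------------------------------------
# bootstrap likelihood-ratio test
# ---------------------------------------------------------------------------


@dataclass
class LRTResult:
    """Bootstrap-calibrated likelihood-ratio comparison of nested variants."""

    null_spec: str
    alt_spec: str
    statistic: float  # 2 * (loglik_alt - loglik_null) on the data
    null_statistics: np.ndarray
    p_value: float
    B: int
    seed: int
    n_failed: int = 0

    def to_dict(self) -> dict:
        return {
            "null_spec": self.null_spec,
            "alt_spec": self.alt_spec,
            "statistic": float(self.statistic),
            "null_statistics": np.asarray(self.null_statistics).tolist(),
            "p_value": float(self.p_value),
            "B": int(self.B),
            "seed": int(self.seed),
            "n_failed": int(self.n_failed),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "LRTResult":
        return cls(null_spec=d["null_spec"], alt_spec=d["alt_spec"],
                   statistic=d["statistic"],
                   null_statistics=np.asarray(d["null_statistics"], dtype=float),
                   p_value=d["p_value"], B=d["B"], seed=d["seed"],
                   n_failed=d["n_failed"])


def bootstrap_lrt(null_spec, alt_spec, cohort: pd.DataFrame, B: int, seed: int,
                  lam_null: float | None = None, lam_alt: float | None = None) -> LRTResult:
    """Test H0: the null variant suffices, against a strictly larger variant.

    Fits both models to the data, forms Lambda = 2 (ll_alt - ll_null), then
    regenerates B cohorts from the fitted null (observed covariates fixed),
    refits both models to each, and reports the empirical p-value with the
    finite-B (+1) correction: p = (1 + #{Lambda_b >= Lambda}) / (B + 1).
    """
    nspec, aspec = load_spec(null_spec), load_spec(alt_spec)
    if nspec.name == aspec.name:
        raise DesignError("null and alternative specs are identical; not strictly nested")
    if not is_nested(nspec, aspec):
        raise DesignError(f"{nspec.name!r} is not nested in {aspec.name!r}")
    if B < 19:
        raise DesignError(f"B must be >= 19 for a meaningful p-value, got {B}")

    from .estimators import fit as _fit

    X = cohort[nspec.covariates]
    null_fit = _fit(nspec, cohort, lam=lam_null, seed=seed)
    alt_fit = _fit(aspec, cohort, lam=lam_alt, seed=seed)
    lam_n = null_fit.lambda_
    lam_a = alt_fit.lambda_
    stat = 2.0 * (alt_fit.loglik_ - null_fit.loglik_)

    stats = []
    n_failed = 0
    for b in range(B):
        rng = _replicate_rng(seed, b)
        y_b = simulate_from_fit(null_fit, X, rng)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                nb = TwoPartModel(spec=nspec, lam=lam_n).fit(X, y_b, starts=null_fit.params_)
                ab = TwoPartModel(spec=aspec, lam=lam_a).fit(X, y_b, starts=alt_fit.params_)
            stats.append(2.0 * (ab.loglik_ - nb.loglik_))
        except (ConvergenceError, DegenerateModelError):
            n_failed += 1
    if n_failed > 0.1 * B:
        raise ConvergenceError(f"{n_failed}/{B} LRT bootstrap replicates failed")
    stats = np.asarray(stats)
    p = (1.0 + np.sum(stats >= stat)) / (len(stats) + 1.0)
    return LRTResult(null_spec=nspec.name, alt_spec=aspec.name, statistic=float(stat),
                     null_statistics=stats, p_value=float(p), B=B, seed=seed,
                     n_failed=n_failed)


def bonferroni_adjust(p_values) -> np.ndarray:
    """Multiply each p-value by the number of comparisons, capping at 1."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    return np.minimum(p * p.size, 1.0)
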