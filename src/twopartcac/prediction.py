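"""Monte-Carlo split-sample evaluation of prediction performance.

The protocol: randomly split the cohort into equal train/test halves, fit
each candidate model variant on the training half only (semiparametric
tuning included, so no information leaks from the test half), then for every
test subject predict the probability of a nonzero CAC, dichotomize at 0.5,
and — if a nonzero status is predicted — predict log(1 + CAC) from the
continuous part. Repeating over many random splits averages out extreme
partitions. Two metrics are reported per variant: the binary error rate for
zero vs nonzero status, and the overall mean squared error on the
t = log(1 + CAC) scale with zeros included (predicted t is 0 whenever the
predicted status is zero).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .estimators import DEFAULT_LAMBDA_GRID, TwoPartModel, select_tuning
from .exceptions import DegenerateModelError, DesignError
from .specs import load_spec


@dataclass(frozen=True)
class SplitPlan:
    """Monte-Carlo split schedule: equal halves (train gets the extra subject
    for odd n), ``n_splits`` deterministic sub-seeds from the master seed."""

    n_splits: int = 500
    train_fraction: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if self.n_splits < 1:
            raise DesignError("n_splits must be >= 1")
        if not (0.0 < self.train_fraction < 1.0):
            raise DesignError("train_fraction must lie in (0, 1)")


@dataclass
class PredictionSummary:
    """Per-variant mean (SD) of error rate and overall MSE across splits."""

    table: pd.DataFrame  # spec, mean_error, sd_error, mean_mse, sd_mse
    raw: pd.DataFrame    # long format: split, spec, error_rate, mse
    plan: SplitPlan = field(default=None)

    def __str__(self) -> str:
        lines = []
        for _, row in self.table.iterrows():
            lines.append(
                f"{row['spec']:>5}: error rate {row['mean_error']:.4f} "
                f"({row['sd_error']:.4f})   MSE {row['mean_mse']:.4f} ({row['sd_mse']:.4f})"
            )
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "table": self.table.to_dict(orient="list"),
            "raw": self.raw.to_dict(orient="list"),
            "plan": None if self.plan is None else vars(self.plan).copy(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PredictionSummary":
        plan = None if d.get("plan") is None else SplitPlan(**d["plan"])
        return cls(table=pd.DataFrame(d["table"]), raw=pd.DataFrame(d["raw"]), plan=plan)


def predict_subject(model: TwoPartModel, row: pd.Series | pd.DataFrame):
    """(p_hat, z_hat, t_hat) for a single subject.

    p_hat = expit(eta1); z_hat = 1{p_hat > 0.5} (ties predict zero); t_hat is
    the continuous-part prediction floored at 0 when z_hat = 1, else 0.
    Covariates outside the training spline range are clamped to the boundary.
    """
    if isinstance(row, pd.Series):
        row = row.to_frame().T
    p, zhat, that = model.predict_parts(row)
    return float(p[0]), int(zhat[0]), float(that[0])


def _split_indices(n: int, seed, train_fraction: float = 0.5):
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    n_train = int(np.ceil(n * train_fraction))
    return perm[:n_train], perm[n_train:]


def evaluate_split(specs, cohort: pd.DataFrame, seed, lam: dict | None = None,
                   lambda_grid=DEFAULT_LAMBDA_GRID, cv: int = 5,
                   train_fraction: float = 0.5) -> pd.DataFrame:
    """One random train/test split, every spec fitted on train only.

    ``lam`` optionally maps spec names to fixed tuning parameters; otherwise
    semiparametric specs are tuned by cross-validation within the training
    half. Returns a frame with one row per spec: error_rate and mse.
    """
    specs = [load_spec(s) for s in specs]
    if len(cohort) < 40:
        raise DesignError("cohort too small for a meaningful split evaluation")
    train_idx, test_idx = _split_indices(len(cohort), seed, train_fraction)
    train = cohort.iloc[train_idx]
    test = cohort.iloc[test_idx]
    ztr = (train["cac"] > 0).to_numpy()
    if ztr.all() or not ztr.any():
        raise DegenerateModelError("training half has no zero (or no nonzero) CAC scores")

    t_test = np.log1p(test["cac"].to_numpy(dtype=float))
    z_test = (test["cac"] > 0).astype(int).to_numpy()
    rows = []
    for spec in specs:
        X_tr, y_tr = train[spec.covariates], train["cac"].to_numpy(dtype=float)
        lam_s = None if lam is None else lam.get(spec.name)
        if spec.family == "semiparametric" and lam_s is None:
            lam_s = select_tuning(spec, X_tr, y_tr, grid=lambda_grid, folds=cv, seed=0)
        model = TwoPartModel(spec=spec, lam=lam_s).fit(X_tr, y_tr)
        _, zhat, that = model.predict_parts(test[spec.covariates])
        rows.append({
            "spec": spec.name,
            "error_rate": float(np.mean(zhat != z_test)),
            "mse": float(np.mean((that - t_test) ** 2)),
        })
    return pd.DataFrame(rows)


def monte_carlo_evaluation(specs, cohort: pd.DataFrame, plan: SplitPlan | None = None,
                           lam: dict | None = None, lambda_grid=DEFAULT_LAMBDA_GRID,
                           cv: int = 5) -> PredictionSummary:
    """Repeat :func:`evaluate_split` over ``plan.n_splits`` deterministic
    sub-seeds and summarize mean (SD) per spec."""
    plan = plan or SplitPlan()
    frames = []
    for s in range(plan.n_splits):
        try:
            res = evaluate_split(specs, cohort, seed=[plan.seed, s], lam=lam,
                                 lambda_grid=lambda_grid, cv=cv,
                                 train_fraction=plan.train_fraction)
        except (DegenerateModelError, DesignError) as exc:
            raise type(exc)(f"split {s}: {exc}") from exc
        res.insert(0, "split", s)
        frames.append(res)
    raw = pd.concat(frames, ignore_index=True)
    grouped = raw.groupby("spec", sort=False)
    table = pd.DataFrame({
        "spec": list(grouped.groups),
        "mean_error": grouped["error_rate"].mean().to_numpy(),
        "sd_error": grouped["error_rate"].std(ddof=0).fillna(0.0).to_numpy(),
        "mean_mse": grouped["mse"].mean().to_numpy(),
        "sd_mse": grouped["mse"].std(ddof=0).fillna(0.0).to_numpy(),
    })
    return PredictionSummary(table=table, raw=raw, plan=plan)
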