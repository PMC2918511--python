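"""Cohort and result I/O with provenance.

Cohorts travel as comma-separated UTF-8 text with a header ("." decimal, no
locale inference). Fitted models, bootstrap results, LRT results and
prediction summaries round-trip through JSON losslessly (floats use the
shortest exact repr); every artifact embeds the package version, the seed(s)
used, and a hash of the model spec so tampering is detectable on read.
"""

from __future__ import annotations

import hashlib
import json
import os
import warnings

import numpy as np
import pandas as pd

from . import __version__
from .cohort import CovariateConfig
from .estimators import TwoPartModel
from .exceptions import CohortValidationError
from .inference import BootstrapResult, LRTResult
from .prediction import PredictionSummary


# ---------------------------------------------------------------------------
# cohort tables
# ---------------------------------------------------------------------------


def read_cohort(path, config: CovariateConfig | None = None,
                require_covariates: list[str] | None = None) -> pd.DataFrame:
    """Read and validate a cohort CSV; adds t = log(1+cac) and z = 1{cac>0}.

    Rejects missing or non-numeric cells and negative CAC values with
    row-indexed messages (rows counted from 0 in file order).
    """
    df = pd.read_csv(path)
    if "cac" not in df.columns:
        raise CohortValidationError(f"{path}: no 'cac' column")
    required = list(require_covariates or [])
    if config is not None:
        required = config.names
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise CohortValidationError(f"{path}: missing covariate columns {missing}")
    check_cols = (required or [c for c in df.columns if c != "subject_id"]) + ["cac"]
    for col in dict.fromkeys(check_cols):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[vals.isna()].tolist()
        if bad:
            raise CohortValidationError(
                f"{path}: column {col!r} has missing/non-numeric values at rows {bad[:10]}"
            )
        df[col] = vals.astype(float)
    neg = df.index[df["cac"] < 0].tolist()
    if neg:
        raise CohortValidationError(f"{path}: negative CAC at rows {neg[:10]}")
    if config is not None:
        for c in config.covariates:
            if c.kind == "binary":
                col = df[c.name]
                if not col.isin([0.0, 1.0]).all():
                    bad = df.index[~col.isin([0.0, 1.0])].tolist()
                    raise CohortValidationError(
                        f"{path}: binary covariate {c.name!r} has non-0/1 values at "
                        f"rows {bad[:10]}"
                    )
    df["t"] = np.log1p(df["cac"])
    df["z"] = (df["cac"] > 0).astype(int)
    return df


def write_cohort(cohort: pd.DataFrame, path) -> None:
    """Write the cohort as CSV (derived t/z columns are not persisted)."""
    drop = [c for c in ("t", "z") if c in cohort.columns]
    cohort.drop(columns=drop).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# result artifacts
# ---------------------------------------------------------------------------

_KINDS = {
    "fitted_model": (TwoPartModel, "to_dict", "from_dict"),
    "bootstrap_result": (BootstrapResult, "to_dict", "from_dict"),
    "lrt_result": (LRTResult, "to_dict", "from_dict"),
    "prediction_summary": (PredictionSummary, "to_dict", "from_dict"),
}


def spec_hash(spec_dict: dict) -> str:
    return hashlib.sha256(
        json.dumps(spec_dict, sort_keys=True).encode()
    ).hexdigest()[:16]


def _kind_of(obj) -> str:
    for kind, (cls, *_rest) in _KINDS.items():
        if isinstance(obj, cls):
            return kind
    raise TypeError(f"don't know how to serialize {type(obj).__name__}")


def _embedded_spec(kind: str, payload: dict):
    if kind == "fitted_model":
        return payload["design"]["spec"]
    return None


def write_results(obj, path, seed: int | None = None) -> None:
    """Serialize a result artifact to JSON with provenance metadata."""
    kind = _kind_of(obj)
    payload = obj.to_dict()
    doc = {"kind": kind, "version": __version__, "seed": seed, "payload": payload}
    spec_dict = _embedded_spec(kind, payload)
    if spec_dict is not None:
        doc["spec_hash"] = spec_hash(spec_dict)
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_results(path):
    """Load a result artifact; warns on version mismatch or a tampered spec."""
    with open(path) as fh:
        doc = json.load(fh)
    kind = doc.get("kind")
    if kind not in _KINDS:
        raise CohortValidationError(f"{path}: unknown artifact kind {kind!r}")
    if doc.get("version") != __version__:
        warnings.warn(
            f"{path}: written by version {doc.get('version')}, reading with "
            f"{__version__}", RuntimeWarning,
        )
    payload = doc["payload"]
    spec_dict = _embedded_spec(kind, payload)
    if spec_dict is not None and doc.get("spec_hash") is not None:
        if spec_hash(spec_dict) != doc["spec_hash"]:
            warnings.warn(f"{path}: spec hash mismatch; artifact may have been edited",
                          RuntimeWarning)
    cls = _KINDS[kind][0]
    return getattr(cls, "from_dict")(payload)


# ---------------------------------------------------------------------------
# report-style exports
# ---------------------------------------------------------------------------


def export_smooths(model: TwoPartModel, outdir, boot: BootstrapResult | None = None,
                   grid_size: int = 101) -> list[str]:
    """One (grid, value[, sd]) CSV per smooth effect and part."""
    os.makedirs(outdir, exist_ok=True)
    paths = []
    parts = ["logistic"] if model.params_.proportional else ["logistic", "linear"]
    for cov in model.design_.bases:
        for part in parts:
            frame = model.smooth_frame(cov, part=part)
            if boot is not None and f"{cov}:{part}" in boot.smooth_sd:
                sd = boot.smooth_sd[f"{cov}:{part}"]
                if len(sd) == len(frame):
                    frame = frame.assign(sd=sd["sd"].to_numpy())
            path = os.path.join(outdir, f"smooth_{cov}_{part}.csv")
            frame.to_csv(path, index=False)
            paths.append(path)
    return paths


def estimate_se_table(model: TwoPartModel, boot: BootstrapResult | None = None) -> pd.DataFrame:
    """Estimate (SE) table shaped like the usual two-column-per-model report:
    one row per parametric coefficient, logistic and linear parts side by side."""
    p = model.params_
    design = model.design_
    rows = []
    spline_cols = set()
    for sl in design.spline_slices.values():
        spline_cols.update(range(sl.start, sl.stop))

    def se_of(label):
        if boot is None or label not in boot.se.index:
            return None
        return float(boot.se[label])

    def fmt(est, se):
        return f"{est:.3f}" if se is None else f"{est:.3f} ({se:.3f})"

    for j, lab in enumerate(design.labels):
        if j in spline_cols:
            continue
        log_est = p.theta1[j]
        lin_est = p.tau * p.theta1[j] if p.proportional else p.theta2[j]
        lin_se = se_of(f"linear:{lab}") if not p.proportional else None
        rows.append({
            "covariate": lab,
            "logistic": fmt(log_est, se_of(f"logistic:{lab}")),
            "linear": fmt(lin_est, lin_se),
        })
    rows.append({"covariate": "sigma", "logistic": "", "linear": fmt(p.sigma, se_of("sigma"))})
    if p.proportional:
        rows.append({"covariate": "tau", "logistic": "", "linear": fmt(p.tau, se_of("tau"))})
    return pd.DataFrame(rows)
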