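"""Model specifications for the two-part CAC model family.

A :class:`ModelSpec` declares, for each covariate, how it enters the two
linear predictors (``linear``, ``quadratic`` = linear + squared term, or
``smooth`` = penalized cubic spline) and whether the two parts share a single
covariate index up to a scale factor (``proportional=True``) or carry free,
part-specific coefficients.

Six presets are shipped, named after the variants commonly fitted to
coronary-artery-calcium cohorts:

========  ============  ===========================================
name      proportional  covariate effects
========  ============  ===========================================
``i.1``   yes           linear for all 13 covariates
``i.2``   yes           linear, plus quadratic LDL and HDL
``ii.1``  no            linear for all 13 covariates
``ii.2``  no            linear, plus quadratic LDL and HDL
``iii``   yes           smooth age/BMI/LDL/HDL, linear otherwise
``iv``    no            smooth age/BMI/LDL/HDL, linear otherwise
========  ============  ===========================================

The link is fixed to logistic and the positive-part error to Normal.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from importlib import resources

import yaml

from .exceptions import DesignError

#: canonical covariate order for the MESA-like cohort
COVARIATE_NAMES = [
    "gender_male",
    "race_chinese",
    "race_african_american",
    "race_hispanic",
    "smoker_former",
    "smoker_current",
    "diabetes",
    "sbp",
    "dbp",
    "age",
    "bmi",
    "ldl",
    "hdl",
]

BINARY_COVARIATES = COVARIATE_NAMES[:7]
CONTINUOUS_COVARIATES = COVARIATE_NAMES[7:]

#: covariates given nonparametric (smooth) effects in the semiparametric presets
SMOOTH_COVARIATES = ["age", "bmi", "ldl", "hdl"]

EFFECT_KINDS = ("linear", "quadratic", "smooth")

PRESET_NAMES = ("i.1", "i.2", "ii.1", "ii.2", "iii", "iv")


@dataclass(frozen=True)
class ModelSpec:
    """Declarative description of one two-part model variant."""

    name: str
    proportional: bool
    effects: dict[str, str] = field(default_factory=dict)
    basis_dim: int = 10
    degree: int = 3

    def __post_init__(self):
        for cov, kind in self.effects.items():
            if kind not in EFFECT_KINDS:
                raise DesignError(f"unknown effect kind {kind!r} for covariate {cov!r}")
        if self.basis_dim < self.degree + 1:
            raise DesignError(
                f"basis_dim={self.basis_dim} too small for degree {self.degree} splines"
            )

    @property
    def family(self) -> str:
        return "semiparametric" if self.smooth_covariates else "parametric"

    @property
    def covariates(self) -> list[str]:
        return list(self.effects)

    @property
    def smooth_covariates(self) -> list[str]:
        return [c for c, k in self.effects.items() if k == "smooth"]

    def to_dict(self) -> dict:
        # effects as an ordered list of pairs: column order must survive
        # JSON round-trips even under key-sorting serializers
        return {
            "name": self.name,
            "proportional": self.proportional,
            "effects": [[c, k] for c, k in self.effects.items()],
            "basis_dim": self.basis_dim,
            "degree": self.degree,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ModelSpec":
        eff = d["effects"]
        effects = dict(eff) if isinstance(eff, dict) else {c: k for c, k in eff}
        return cls(
            name=d["name"],
            proportional=bool(d["proportional"]),
            effects=effects,
            basis_dim=int(d.get("basis_dim", 10)),
            degree=int(d.get("degree", 3)),
        )

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "ModelSpec":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def with_basis(self, basis_dim: int | None = None, degree: int | None = None) -> "ModelSpec":
        return replace(
            self,
            basis_dim=self.basis_dim if basis_dim is None else basis_dim,
            degree=self.degree if degree is None else degree,
        )


def _preset_effects(quadratic: bool, smooth: bool) -> dict[str, str]:
    effects = {c: "linear" for c in COVARIATE_NAMES}
    if quadratic:
        effects["ldl"] = "quadratic"
        effects["hdl"] = "quadratic"
    if smooth:
        for c in SMOOTH_COVARIATES:
            effects[c] = "smooth"
    return effects


def _builtin_presets() -> dict[str, ModelSpec]:
    return {
        "i.1": ModelSpec("i.1", True, _preset_effects(False, False)),
        "i.2": ModelSpec("i.2", True, _preset_effects(True, False)),
        "ii.1": ModelSpec("ii.1", False, _preset_effects(False, False)),
        "ii.2": ModelSpec("ii.2", False, _preset_effects(True, False)),
        "iii": ModelSpec("iii", True, _preset_effects(False, True)),
        "iv": ModelSpec("iv", False, _preset_effects(False, True)),
    }


def _normalize(name: str) -> str:
    return name.lower().replace("(", "").replace(")", "").replace(".", "").strip()


def load_spec(spec: "str | ModelSpec | dict") -> ModelSpec:
    """Resolve a spec given as preset name, dict, YAML file path, or ModelSpec."""
    if isinstance(spec, ModelSpec):
        return spec
    if isinstance(spec, dict):
        return ModelSpec.from_dict(spec)
    key = _normalize(spec)
    presets = {_normalize(k): v for k, v in _builtin_presets().items()}
    if key in presets:
        return presets[key]
    try:
        return ModelSpec.from_yaml(spec)
    except (OSError, yaml.YAMLError) as exc:
        raise DesignError(
            f"unknown model spec {spec!r}; presets are {PRESET_NAMES}"
        ) from exc


# ---------------------------------------------------------------------------
# nesting lattice among the presets (null, alternative) pairs
# ---------------------------------------------------------------------------
# Quadratic and linear effects lie in the span of the cubic-spline bases, and
# proportional models are constrained versions of their nonproportional
# counterparts, so the lattice is
#   i.1 < {i.2, ii.1, iii} ;  i.2 < {ii.2, iii} ;  ii.1 < ii.2 ;
#   everything < iv (smooths at lambda=0 contain polynomial effects).
NESTED_PAIRS = frozenset(
    {
        ("i.1", "i.2"),
        ("i.1", "ii.1"),
        ("i.1", "ii.2"),
        ("i.1", "iii"),
        ("i.1", "iv"),
        ("i.2", "ii.2"),
        ("i.2", "iii"),
        ("i.2", "iv"),
        ("ii.1", "ii.2"),
        ("ii.1", "iv"),
        ("ii.2", "iv"),
        ("iii", "iv"),
    }
)


def is_nested(null: "str | ModelSpec", alternative: "str | ModelSpec") -> bool:
    """True if *null* is a strict submodel of *alternative* in the preset lattice."""
    n = load_spec(null).name
    a = load_spec(alternative).name
    if n not in PRESET_NAMES or a not in PRESET_NAMES:
        raise DesignError(
            "nesting is only defined for the shipped presets; "
            f"got {n!r} vs {a!r}"
        )
    return (n, a) in NESTED_PAIRS


def write_preset_files(outdir) -> list[str]:
    """Write the six preset specs as YAML files (i1.yaml ... iv.yaml)."""
    import os

    paths = []
    for name, spec in _builtin_presets().items():
        path = os.path.join(outdir, name.replace(".", "") + ".yaml")
        spec.to_yaml(path)
        paths.append(path)
    return paths


def packaged_preset(name: str) -> ModelSpec:
    """Load a preset from the YAML files shipped inside the package."""
    fname = _normalize(name) + ".yaml"
    ref = resources.files("twopartcac").joinpath("presets", fname)
    with resources.as_file(ref) as path:
        return ModelSpec.from_yaml(path)
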