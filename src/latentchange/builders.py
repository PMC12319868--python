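"""Builders for the study's model family.

Constructs ModelSpecs for:

* a two-wave longitudinal CFA of the positive-social-experiences (PSE)
  factor at four invariance levels (configural / weak / strong / partial),
* the bivariate latent change score model (LCSM) coupling the PSE factor
  with an observed brain variable (mean cortical thickness),
* univariate ("separate indicator") LCSMs of two observed variables,
* multi-group expansions with cross-group equality-constraint toggles.

The latent metric follows the marker-variable convention: the marker
indicator's loading is fixed to 1 and its intercept to 0, so the factor
inherits the 0-100 indicator scale and latent means are free.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .model import ModelError, ModelSpec, ParamMatrices

__all__ = [
    "DEFAULT_INDICATORS",
    "STRUCTURAL_LABELS",
    "MeasurementSchema",
    "build_longitudinal_cfa",
    "build_bivariate_lcsm",
    "build_univariate_lcsm",
    "expand_multigroup",
    "saturated_spec",
]

DEFAULT_INDICATORS = (
    "prosocial",
    "friends",
    "school_env",
    "school_inv",
    "caregiver_mon",
    "family_coh",
    "neigh_safety",
)

INVARIANCE_LEVELS = ("configural", "weak", "strong", "partial")

#: The structural free parameters of the bivariate LCSM, one per reported row.
STRUCTURAL_LABELS = (
    "mean_pse_t1",
    "var_pse_t1",
    "intercept_delta_pse",
    "var_delta_pse",
    "self_feedback_pse",
    "mean_ct_t1",
    "var_ct_t1",
    "intercept_delta_ct",
    "var_delta_ct",
    "self_feedback_ct",
    "coupling_pse_ct",
    "change_covariance",
    "baseline_covariance",
)


@dataclass
class MeasurementSchema:
    """Names and conventions of the two-wave measurement model."""

    indicators: tuple[str, ...] = DEFAULT_INDICATORS
    waves: tuple[str, str] = ("t1", "t2")
    marker: str = "school_env"
    freed_intercepts: tuple[str, ...] = ("family_coh", "friends")

    def __post_init__(self) -> None:
        if self.marker not in self.indicators:
            raise ModelError(f"marker {self.marker!r} not among indicators")
        if self.marker in self.freed_intercepts:
            raise ModelError("marker intercept anchors the latent mean and cannot be freed")
        unknown = set(self.freed_intercepts) - set(self.indicators)
        if unknown:
            raise ModelError(f"freed_intercepts not among indicators: {sorted(unknown)}")

    def column(self, indicator: str, wave: str) -> str:
        return f"{indicator}_{wave}"

    def indicator_columns(self) -> list[str]:
        return [self.column(i, w) for w in self.waves for i in self.indicators]

    @classmethod
    def from_dict(cls, d: dict) -> "MeasurementSchema":
        return cls(
            indicators=tuple(d.get("indicators", DEFAULT_INDICATORS)),
            waves=tuple(d.get("waves", ("t1", "t2"))),
            marker=d.get("marker", "school_env"),
            freed_intercepts=tuple(d.get("freed_intercepts", ("family_coh", "friends"))),
        )

    def to_dict(self) -> dict:
        return {
            "indicators": list(self.indicators),
            "waves": list(self.waves),
            "marker": self.marker,
            "freed_intercepts": list(self.freed_intercepts),
        }


def _add_measurement(
    mats: ParamMatrices,
    schema: MeasurementSchema,
    level: str,
    obs_index: dict[str, int],
    factor_index: dict[str, int],
) -> None:
    """Install the two-wave indicator block (loadings, intercepts, residuals)."""
    w1, w2 = schema.waves
    for w in schema.waves:
        fac = factor_index[w]
        for ind in schema.indicators:
            i = obs_index[schema.column(ind, w)]
            if ind == schema.marker:
                mats.set_fixed("lam", (i, fac), 1.0)
                mats.set_fixed("nu", (i,), 0.0)
            else:
                lam_lab = f"lam_{ind}" if level != "configural" else f"lam_{ind}_{w}"
                mats.set_free("lam", (i, fac), lam_lab, 1.0)
                if level in ("configural", "weak"):
                    nu_lab = f"nu_{ind}_{w}"
                elif level == "partial" and ind in schema.freed_intercepts and w == w2:
                    nu_lab = f"nu_{ind}_{w2}"
                else:
                    nu_lab = f"nu_{ind}"
                mats.set_free("nu", (i,), nu_lab, 0.0)
            mats.set_free("theta", (i, i), f"th_{ind}_{w}", 50.0)
    for ind in schema.indicators:
        i1 = obs_index[schema.column(ind, w1)]
        i2 = obs_index[schema.column(ind, w2)]
        mats.set_free("theta", (i2, i1), f"th_{ind}_cross", 5.0)


def build_longitudinal_cfa(schema: MeasurementSchema, level: str = "configural") -> ModelSpec:
    """Two-wave one-factor CFA with across-wave residual covariances.

    ``level`` controls measurement-parameter equality across waves:
    configural (none), weak (loadings), strong (loadings + intercepts),
    partial (strong with ``schema.freed_intercepts`` released at wave 2).
    """
    if level not in INVARIANCE_LEVELS:
        raise ModelError(f"unknown invariance level {level!r}")
    w1, w2 = schema.waves
    observed = schema.indicator_columns()
    latent = [f"pse_{w1}", f"pse_{w2}"]
    obs_index = {name: i for i, name in enumerate(observed)}
    factor_index = {w1: 0, w2: 1}
    mats = ParamMatrices(len(observed), len(latent))
    _add_measurement(mats, schema, level, obs_index, factor_index)
    mats.set_free("psi", (0, 0), f"var_pse_{w1}", 20.0)
    mats.set_free("psi", (1, 1), f"var_pse_{w2}", 20.0)
    mats.set_free("psi", (1, 0), "cov_pse_waves", 10.0)
    mats.set_free("alpha", (0,), f"mean_pse_{w1}", 50.0)
    mats.set_free("alpha", (1,), f"mean_pse_{w2}", 50.0)
    spec = ModelSpec(observed_names=observed, latent_names=latent, matrices=[mats])
    spec.validate()
    return spec


def build_bivariate_lcsm(
    schema: MeasurementSchema,
    observed_name: str = "ct",
    measurement_level: str = "strong",
    reverse_coupling: bool = False,
) -> ModelSpec:
    """Bivariate LCSM: latent PSE factor coupled with an observed variable.

    Both constructs follow the change-score identity wave2 = wave1 + change
    (unit-weight fixed paths, zero wave-2 residuals).  The free structural
    set comprises baseline means/variances, change intercepts/variances,
    the two self-feedback paths, the unidirectional coupling from baseline
    PSE to the brain change score, the change-change covariance, and the
    baseline covariance.  The reverse coupling (brain baseline -> PSE
    change) is available behind a flag and off by default.
    """
    w1, w2 = schema.waves
    observed = schema.indicator_columns() + [f"{observed_name}_{w1}", f"{observed_name}_{w2}"]
    latent = [f"pse_{w1}", f"pse_{w2}", "delta_pse", f"ct_{w1}", f"ct_{w2}", "delta_ct"]
    P1, P2, DP, C1, C2, DC = range(6)
    obs_index = {name: i for i, name in enumerate(observed)}
    mats = ParamMatrices(len(observed), len(latent))
    _add_measurement(mats, schema, measurement_level, obs_index, {w1: P1, w2: P2})
    # observed brain variable: unit-loading latent proxies, zero residuals
    for w, fac in ((w1, C1), (w2, C2)):
        i = obs_index[f"{observed_name}_{w}"]
        mats.set_fixed("lam", (i, fac), 1.0)
        mats.set_fixed("nu", (i,), 0.0)
        mats.set_fixed("theta", (i, i), 0.0)
    # change-score identities: wave2 = wave1 + change, fixed unit paths
    for head, base, change in ((P2, P1, DP), (C2, C1, DC)):
        mats.set_fixed("beta", (head, base), 1.0)
        mats.set_fixed("beta", (head, change), 1.0)
    mats.set_free("beta", (DP, P1), "self_feedback_pse", -0.2)
    mats.set_free("beta", (DC, C1), "self_feedback_ct", -0.2)
    mats.set_free("beta", (DC, P1), "coupling_pse_ct", 0.0)
    if reverse_coupling:
        mats.set_free("beta", (DP, C1), "coupling_ct_pse", 0.0)
    mats.set_free("psi", (P1, P1), "var_pse_t1", 20.0)
    mats.set_free("psi", (C1, C1), "var_ct_t1", 60.0)
    mats.set_free("psi", (C1, P1), "baseline_covariance", 0.0)
    mats.set_free("psi", (DP, DP), "var_delta_pse", 20.0)
    mats.set_free("psi", (DC, DC), "var_delta_ct", 20.0)
    mats.set_free("psi", (DC, DP), "change_covariance", 0.0)
    mats.set_free("alpha", (P1,), "mean_pse_t1", 50.0)
    mats.set_free("alpha", (C1,), "mean_ct_t1", 50.0)
    mats.set_free("alpha", (DP,), "intercept_delta_pse", 0.0)
    mats.set_free("alpha", (DC,), "intercept_delta_ct", 0.0)
    spec = ModelSpec(observed_names=observed, latent_names=latent, matrices=[mats])
    spec.validate()
    return spec


def build_univariate_lcsm(
    x_name: str,
    y_name: str,
    waves: tuple[str, str] = ("t1", "t2"),
    coupling: bool = True,
    change_covariance: bool = True,
) -> ModelSpec:
    """Separate-indicator LCSM: both constructs observed, no factor model.

    ``x`` plays the role of the predictor construct (its baseline couples
    into the change of ``y``).  13 free parameters when coupling and the
    change covariance are free, giving df = 1.
    """
    w1, w2 = waves
    observed = [f"{x_name}_{w1}", f"{x_name}_{w2}", f"{y_name}_{w1}", f"{y_name}_{w2}"]
    latent = ["x_t1", "x_t2", "delta_x", "y_t1", "y_t2", "delta_y"]
    X1, X2, DX, Y1, Y2, DY = range(6)
    if len(set(observed)) < 4:
        raise ModelError("univariate LCSM needs four distinct observed columns")
    mats = ParamMatrices(4, 6)
    for i, fac in ((0, X1), (1, X2), (2, Y1), (3, Y2)):
        mats.set_fixed("lam", (i, fac), 1.0)
        mats.set_fixed("nu", (i,), 0.0)
        mats.set_fixed("theta", (i, i), 0.0)
    for head, base, change in ((X2, X1, DX), (Y2, Y1, DY)):
        mats.set_fixed("beta", (head, base), 1.0)
        mats.set_fixed("beta", (head, change), 1.0)
    mats.set_free("beta", (DX, X1), "self_feedback_x", -0.2)
    mats.set_free("beta", (DY, Y1), "self_feedback_y", -0.2)
    if coupling:
        mats.set_free("beta", (DY, X1), "coupling_x_to_delta_y", 0.0)
    mats.set_free("psi", (X1, X1), "var_x_t1", 50.0)
    mats.set_free("psi", (Y1, Y1), "var_y_t1", 50.0)
    mats.set_free("psi", (Y1, X1), "baseline_covariance", 0.0)
    mats.set_free("psi", (DX, DX), "var_delta_x", 20.0)
    mats.set_free("psi", (DY, DY), "var_delta_y", 20.0)
    if change_covariance:
        mats.set_free("psi", (DY, DX), "change_covariance", 0.0)
    mats.set_free("alpha", (X1,), "mean_x_t1", 50.0)
    mats.set_free("alpha", (Y1,), "mean_y_t1", 50.0)
    mats.set_free("alpha", (DX,), "intercept_delta_x", 0.0)
    mats.set_free("alpha", (DY,), "intercept_delta_y", 0.0)
    spec = ModelSpec(observed_names=observed, latent_names=latent, matrices=[mats])
    spec.validate()
    return spec


def expand_multigroup(
    spec: ModelSpec,
    group_labels: list[str],
    constrained_labels: set[str] | frozenset[str] = frozenset(),
    invariance_level: str = "weak",
    group_column: str = "group",
) -> ModelSpec:
    """Per-group copies of a single-group spec with equality toggles.

    Free labels are suffixed ``@<group>`` per group, except labels held
    equal across groups: measurement parameters per ``invariance_level``
    (weak shares loadings, strong also intercepts, configural none) and
    every label in ``constrained_labels``.  Toggling one label between
    shared and split changes the free-parameter count by (#groups - 1).
    """
    if spec.group_names is not None:
        raise ModelError("spec is already multi-group")
    if not group_labels:
        raise ModelError("group_labels must be non-empty")
    if len(set(group_labels)) != len(group_labels):
        raise ModelError("duplicate group labels")
    free = set(spec.free_labels())
    unknown = set(constrained_labels) - free
    if unknown:
        raise ModelError(f"constrained_labels not free in spec: {sorted(unknown)}")
    shared_prefixes = {"configural": (), "weak": ("lam_",), "strong": ("lam_", "nu_")}
    if invariance_level not in shared_prefixes:
        raise ModelError(f"unknown cross-group invariance level {invariance_level!r}")
    prefixes = shared_prefixes[invariance_level]

    def shared(label: str) -> bool:
        return label in constrained_labels or any(label.startswith(p) for p in prefixes)

    template = spec.matrices[0]
    matrices = []
    for gname in group_labels:
        mats = template.copy()
        for name, idx, lab in list(mats.iter_free_cells()):
            if not shared(lab):
                mats.set_free(name, idx, f"{lab}@{gname}", float(mats.values[name][idx]))
        matrices.append(mats)
    out = ModelSpec(
        observed_names=list(spec.observed_names),
        latent_names=list(spec.latent_names),
        matrices=matrices,
        group_names=list(group_labels),
        group_column=group_column,
    )
    out.validate()
    return out


def saturated_spec(names: list[str]) -> ModelSpec:
    """Unrestricted mean/covariance model: all moments free, no latents."""
    p = len(names)
    mats = ParamMatrices(p, 0)
    for i in range(p):
        mats.set_free("nu", (i,), f"mu_{names[i]}", 0.0)
        for j in range(i + 1):
            mats.set_free("theta", (i, j), f"s_{names[i]}_{names[j]}", 1.0 if i == j else 0.0)
    spec = ModelSpec(observed_names=list(names), latent_names=[], matrices=[mats])
    spec.validate()
    return spec
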