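"""Synthetic two-wave cohort generator.

Forward model of the bivariate latent change score system: baseline
positive-social-experiences (PSE) factor and mean cortical thickness (CT)
are drawn jointly, change scores follow their self-feedback / coupling
regressions with correlated residuals, wave 2 equals wave 1 plus change,
and seven indicators measure the PSE factor at each wave with
across-wave-correlated residuals.  Everything is generated in the scaled
0-100 metric the models see; a reverse-scaling utility emits native-scale
tables for end-to-end preprocessing runs.

The canonical parameterization anchors the structural truth to the
published two-wave adolescent-cohort estimates (see ``canonical_params``),
with measurement defaults calibrated so the fully standardized wave-1
loadings of the number-of-friends, neighborhood-safety and
family-cohesion indicators equal .10, .20 and .26, and the remaining
indicators .50.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit, logit

from .builders import MeasurementSchema, build_bivariate_lcsm
from .model import ModelError, implied_moments

__all__ = [
    "StructuralParams",
    "IndicatorParams",
    "MissingnessParams",
    "GeneratingParams",
    "canonical_params",
    "params_to_values",
    "implied_moments_from_params",
    "simulate_dataset",
    "inject_missingness",
    "to_native_scale",
]

#: fully standardized wave-1 loading targets used by the canonical calibration
CANONICAL_STD_LOADINGS = {
    "prosocial": 0.50,
    "friends": 0.10,
    "school_env": 0.50,     # marker
    "school_inv": 0.50,
    "caregiver_mon": 0.50,
    "family_coh": 0.26,
    "neigh_safety": 0.20,
}


@dataclass
class StructuralParams:
    """Structural truth of the bivariate LCSM, named as in the fitted model."""

    mean_pse_t1: float = 80.74
    var_pse_t1: float = 42.0
    intercept_delta_pse: float = 43.38
    var_delta_pse: float = 31.26
    self_feedback_pse: float = -0.51
    mean_ct_t1: float = 57.14
    var_ct_t1: float = 136.0
    intercept_delta_ct: float = 5.16
    var_delta_ct: float = 35.28
    self_feedback_ct: float = -0.16
    coupling_pse_ct: float = -0.01
    change_covariance: float = 2.62
    baseline_covariance: float = -0.18

    def as_dict(self) -> dict[str, float]:
        return dict(self.__dict__)


@dataclass
class IndicatorParams:
    loading: float          # unstandardized, on the marker-metric factor
    intercept: float
    resid_var: float        # same at both waves
    cross_cov: float        # across-wave residual covariance
    loading_t2: float | None = None    # wave-2 override (invariance violations)
    intercept_t2: float | None = None

    def at_wave(self, second: bool) -> tuple[float, float]:
        if not second:
            return self.loading, self.intercept
        lam = self.loading if self.loading_t2 is None else self.loading_t2
        nu = self.intercept if self.intercept_t2 is None else self.intercept_t2
        return lam, nu


@dataclass
class MissingnessParams:
    ct_t2_rate: float = 0.20
    indicator_t2_rate: float = 0.10
    wave1_rate: float = 0.0
    mar_slope: float = 0.5   # logistic dependence of CT_t2 missingness on baseline PSE

    def validate(self) -> None:
        for name in ("ct_t2_rate", "indicator_t2_rate", "wave1_rate"):
            r = getattr(self, name)
            if not 0.0 <= r <= 1.0:
                raise ModelError(f"{name}={r} outside [0, 1]")


@dataclass
class GeneratingParams:
    """Complete generating truth for a two-wave synthetic cohort."""

    structural: StructuralParams = field(default_factory=StructuralParams)
    measurement: dict[str, IndicatorParams] = field(default_factory=dict)
    missingness: MissingnessParams = field(default_factory=MissingnessParams)
    schema: MeasurementSchema = field(default_factory=MeasurementSchema)

    def __post_init__(self) -> None:
        if not self.measurement:
            self.measurement = _calibrate_measurement(self.structural, self.schema)
        self.missingness.validate()
        # the implied covariance must be positive definite, never silently not
        _, sigma = implied_moments_from_params(self)
        try:
            np.linalg.cholesky(sigma)
        except np.linalg.LinAlgError as err:
            raise ModelError("implied covariance matrix is not positive definite") from err

    def to_dict(self) -> dict:
        return {
            "structural": dict(self.structural.__dict__),
            "measurement": {k: dict(v.__dict__) for k, v in self.measurement.items()},
            "missingness": dict(self.missingness.__dict__),
            "schema": self.schema.to_dict(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GeneratingParams":
        from .builders import MeasurementSchema

        return cls(
            structural=StructuralParams(**d.get("structural", {})),
            measurement={k: IndicatorParams(**v) for k, v in d.get("measurement", {}).items()},
            missingness=MissingnessParams(**d.get("missingness", {})),
            schema=MeasurementSchema.from_dict(d.get("schema", {})),
        )

    def to_yaml(self, path) -> None:
        import yaml

        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "GeneratingParams":
        import yaml

        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def _total_change_variances(s: StructuralParams) -> tuple[float, float]:
    v_dpse = (
        s.self_feedback_pse**2 * s.var_pse_t1 + s.var_delta_pse
    )
    v_dct = (
        s.self_feedback_ct**2 * s.var_ct_t1
        + s.coupling_pse_ct**2 * s.var_pse_t1
        + 2 * s.self_feedback_ct * s.coupling_pse_ct * s.baseline_covariance
        + s.var_delta_ct
    )
    return v_dpse, v_dct


def canonical_params(schema: MeasurementSchema | None = None) -> GeneratingParams:
    """The canonical generating truth anchored to the published estimates.

    Baseline variances are back-solved so the standardized change-variance
    proportions equal .74 (PSE) and .91 (CT): the total change variance is
    the residual change variance divided by its standardized proportion,
    and the baseline variance absorbs the remainder through the
    self-feedback and coupling paths.
    """
    schema = schema or MeasurementSchema()
    s = StructuralParams()
    std_prop_pse, std_prop_ct = 0.74, 0.91
    total_dpse = s.var_delta_pse / std_prop_pse
    s.var_pse_t1 = (total_dpse - s.var_delta_pse) / s.self_feedback_pse**2
    total_dct = s.var_delta_ct / std_prop_ct
    s.var_ct_t1 = (
        total_dct
        - s.var_delta_ct
        - s.coupling_pse_ct**2 * s.var_pse_t1
        - 2 * s.self_feedback_ct * s.coupling_pse_ct * s.baseline_covariance
    ) / s.self_feedback_ct**2
    return GeneratingParams(structural=s, schema=schema)


def _calibrate_measurement(
    s: StructuralParams, schema: MeasurementSchema
) -> dict[str, IndicatorParams]:
    """Back-solve loadings/residuals from standardized wave-1 loading targets.

    Every indicator is given the same total observed variance as the
    marker (whose unit loading and the marker-loading target fix it at
    var_pse_t1 / s_marker^2); the cross-wave residual correlation defaults
    to .3.
    """
    std = {ind: CANONICAL_STD_LOADINGS.get(ind, 0.50) for ind in schema.indicators}
    s_marker = std[schema.marker]
    var_obs = s.var_pse_t1 / s_marker**2
    sd_pse, sd_obs = np.sqrt(s.var_pse_t1), np.sqrt(var_obs)
    out = {}
    for ind in schema.indicators:
        lam = std[ind] * sd_obs / sd_pse
        resid = var_obs * (1.0 - std[ind] ** 2)
        out[ind] = IndicatorParams(
            loading=float(lam), intercept=0.0, resid_var=float(resid),
            cross_cov=float(0.3 * resid),
        )
    marker = out[schema.marker]
    assert abs(marker.loading - 1.0) < 1e-9
    return out


def params_to_values(params: GeneratingParams) -> dict[str, float]:
    """Map generating truth onto the free labels of the strong-invariance LCSM."""
    schema = params.schema
    w1, w2 = schema.waves
    values = dict(params.structural.as_dict())
    for ind in schema.indicators:
        mp = params.measurement[ind]
        if ind != schema.marker:
            values[f"lam_{ind}"] = mp.loading
            values[f"nu_{ind}"] = mp.intercept
        values[f"th_{ind}_{w1}"] = mp.resid_var
        values[f"th_{ind}_{w2}"] = mp.resid_var
        values[f"th_{ind}_cross"] = mp.cross_cov
    return values


def implied_moments_from_params(
    params: GeneratingParams,
) -> tuple[np.ndarray, np.ndarray]:
    """Population mean and covariance of the 16 observed columns."""
    spec = build_bivariate_lcsm(params.schema, measurement_level="strong")
    return implied_moments(spec, params_to_values(params))


# ---------------------------------------------------------------------------
# simulation


def _simulate_block(params: GeneratingParams, n: int, rng: np.random.Generator) -> pd.DataFrame:
    s = params.structural
    schema = params.schema
    w1, w2 = schema.waves
    base_cov = np.array(
        [[s.var_pse_t1, s.baseline_covariance], [s.baseline_covariance, s.var_ct_t1]]
    )
    base = rng.multivariate_normal([s.mean_pse_t1, s.mean_ct_t1], base_cov, size=n)
    pse1, ct1 = base[:, 0], base[:, 1]
    e_cov = np.array(
        [[s.var_delta_pse, s.change_covariance], [s.change_covariance, s.var_delta_ct]]
    )
    e = rng.multivariate_normal([0.0, 0.0], e_cov, size=n)
    d_pse = s.intercept_delta_pse + s.self_feedback_pse * pse1 + e[:, 0]
    d_ct = s.intercept_delta_ct + s.self_feedback_ct * ct1 + s.coupling_pse_ct * pse1 + e[:, 1]
    pse2, ct2 = pse1 + d_pse, ct1 + d_ct
    cols: dict[str, np.ndarray] = {}
    factor = {w1: pse1, w2: pse2}
    resid_draws = {}
    for ind in schema.indicators:
        mp = params.measurement[ind]
        rcov = np.array([[mp.resid_var, mp.cross_cov], [mp.cross_cov, mp.resid_var]])
        resid_draws[ind] = rng.multivariate_normal([0.0, 0.0], rcov, size=n)
    for iw, w in enumerate(schema.waves):
        for ind in schema.indicators:
            lam, nu = params.measurement[ind].at_wave(iw == 1)
            cols[schema.column(ind, w)] = nu + lam * factor[w] + resid_draws[ind][:, iw]
    cols[f"ct_{w1}"], cols[f"ct_{w2}"] = ct1, ct2
    return pd.DataFrame(cols)


_PUBERTY_STAGES = ("pre", "early", "mid", "late", "post", "missing")
# within-sex stage probabilities; early fractions follow the cohort's
# reported group sizes, the non-early mass is spread over its four stages
_SEX_P = {"F": 0.48, "M": 0.52}
_STAGE_P = {
    "F": {"early": 1025 / 4524, "nonearly": 3331 / 4524, "missing": 168 / 4524},
    "M": {"early": 1143 / 4944, "nonearly": 3625 / 4944, "missing": 176 / 4944},
}
_NONEARLY_SPLIT = {"pre": 0.35, "mid": 0.45, "late": 0.15, "post": 0.05}
_EDU_YEARS = np.array([8, 10, 12, 13, 14, 16, 18, 21])
_EDU_P = np.array([0.03, 0.05, 0.20, 0.08, 0.12, 0.28, 0.16, 0.08])


def _simulate_demographics(n: int, rng: np.random.Generator) -> pd.DataFrame:
    sex = rng.choice(["F", "M"], size=n, p=[_SEX_P["F"], _SEX_P["M"]])
    stage = np.empty(n, dtype=object)
    for sx in ("F", "M"):
        idx = np.flatnonzero(sex == sx)
        pr = _STAGE_P[sx]
        stage_p = [pr["nonearly"] * _NONEARLY_SPLIT["pre"], pr["early"],
                   pr["nonearly"] * _NONEARLY_SPLIT["mid"],
                   pr["nonearly"] * _NONEARLY_SPLIT["late"],
                   pr["nonearly"] * _NONEARLY_SPLIT["post"], pr["missing"]]
        stage[idx] = rng.choice(list(_PUBERTY_STAGES), size=len(idx), p=stage_p)
    edu = rng.choice(_EDU_YEARS, size=n, p=_EDU_P)
    return pd.DataFrame({
        "sex": sex,
        "puberty_stage": stage,
        "parent_education_years": edu,
        "qc_exclude_flag_t1": rng.binomial(1, 0.09, n),
        "qc_exclude_flag_t2": rng.binomial(1, 0.043, n),
        "qc_clinical_score_t1": rng.choice([1, 2, 3, 4], size=n, p=[0.80, 0.16, 0.03, 0.01]),
        "qc_clinical_score_t2": rng.choice([1, 2, 3, 4], size=n, p=[0.81, 0.16, 0.02, 0.01]),
    })


def simulate_dataset(
    params: GeneratingParams,
    n: int,
    seed: int,
    include_demographics: bool = False,
    group_overrides: dict[str, StructuralParams] | None = None,
) -> pd.DataFrame:
    """Draw a complete wide-format synthetic cohort of size ``n``.

    Deterministic under a fixed seed.  ``group_overrides`` maps
    sex-by-puberty group labels (e.g. ``"female_early"``) to alternative
    structural truths, enabling multi-group true-positive/negative tests;
    demographics are generated whenever overrides are requested.
    """
    if n < 1:
        raise ModelError("n must be >= 1")
    rng = np.random.default_rng(seed)
    if group_overrides:
        include_demographics = True
    demo = _simulate_demographics(n, rng) if include_demographics else None
    if not group_overrides:
        df = _simulate_block(params, n, rng)
    else:
        from .preprocess import puberty_group_label

        labels = np.array([
            puberty_group_label(sx, st, "early_vs_nonearly")
            for sx, st in zip(demo["sex"], demo["puberty_stage"])
        ], dtype=object)
        df = pd.DataFrame(index=range(n))
        parts = []
        for lab in pd.unique(labels):
            idx = np.flatnonzero(labels == lab)
            p_g = params
            if lab in group_overrides:
                p_g = replace(params, structural=group_overrides[lab], measurement=params.measurement)
            block = _simulate_block(p_g, len(idx), rng)
            block.index = idx
            parts.append(block)
        df = pd.concat(parts).sort_index()
    df.insert(0, "subject_id", [f"S{i:06d}" for i in range(n)])
    if demo is not None:
        df = pd.concat([df, demo], axis=1)
    return df


def inject_missingness(
    table: pd.DataFrame,
    params: GeneratingParams,
    seed: int,
) -> pd.DataFrame:
    """Apply the MAR missingness mechanism to a complete scaled table.

    Wave-2 CT goes missing with the target marginal rate, modulated
    logistically by the observed baseline indicator mean (a factor-score
    proxy), so missingness depends on observed wave-1 data only.  Wave-2
    indicators are deleted completely at random at their own rate.  The
    logistic intercept is solved so the expected marginal rate matches the
    target exactly.
    """
    miss = params.missingness
    miss.validate()
    schema = params.schema
    rng = np.random.default_rng(seed)
    out = table.copy()
    w1, w2 = schema.waves
    wave1_cols = [schema.column(i, w1) for i in schema.indicators]
    score = out[wave1_cols].mean(axis=1).to_numpy(float)
    z = (score - score.mean()) / max(score.std(), 1e-12)

    def mar_mask(rate: float, slope: float) -> np.ndarray:
        if rate <= 0.0:
            return np.zeros(len(out), dtype=bool)
        if rate >= 1.0:
            return np.ones(len(out), dtype=bool)
        if slope == 0.0:
            p = np.full(len(out), rate)
        else:
            def mean_rate(c: float) -> float:
                return float(np.mean(expit(c + slope * z))) - rate
            c = brentq(mean_rate, logit(rate) - 10 * abs(slope) - 5, logit(rate) + 10 * abs(slope) + 5)
            p = expit(c + slope * z)
        return rng.random(len(out)) < p

    out.loc[mar_mask(miss.ct_t2_rate, -miss.mar_slope), f"ct_{w2}"] = np.nan
    for ind in schema.indicators:
        out.loc[mar_mask(miss.indicator_t2_rate, 0.0), schema.column(ind, w2)] = np.nan
    if miss.wave1_rate > 0:
        for col in wave1_cols + [f"ct_{w1}"]:
            out.loc[mar_mask(miss.wave1_rate, 0.0), col] = np.nan
    return out


def to_native_scale(table: pd.DataFrame, ranges: dict[str, tuple[float, float]] | None = None) -> pd.DataFrame:
    """Reverse the 0-100 scaling, emitting a native-scale table.

    Friends counts are rounded and clipped at zero to respect their native
    support; other variables are mapped linearly back to their scale range.
    """
    from .preprocess import DEFAULT_RANGES

    ranges = ranges or DEFAULT_RANGES
    out = table.copy()
    for col in out.columns:
        base = col.rsplit("_", 1)[0]
        if base in ranges:
            lo, hi = ranges[base]
            out[col] = lo + out[col] * (hi - lo) / 100.0
            if base == "friends":
                out[col] = out[col].round().clip(lower=0)
    return out
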