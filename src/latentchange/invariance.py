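"""Longitudinal measurement-invariance testing.

Fits the two-wave CFA at increasingly stringent equality levels
(configural -> weak -> strong, with a partial fallback that frees named
wave-2 intercepts) and walks the ladder with the decision rule: retain the
more constrained model when the chi-square difference is non-significant
(p > .05), or the RMSEA increase is < .015, or the CFI decrease is < .010.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .builders import MeasurementSchema, build_longitudinal_cfa
from .fit import FitOptions, FitResult, fit_model
from .indices import ComparisonResult, FitIndices, chi_square_difference, compute_fit_indices
from .model import ModelError

__all__ = ["LadderStep", "LadderResult", "invariance_ladder"]

_ORDER = ["configural", "weak", "strong", "partial"]


@dataclass
class LadderStep:
    level: str
    fit: FitResult
    indices: FitIndices
    comparison: ComparisonResult | None   # vs the previously retained level
    accepted: bool


@dataclass
class LadderResult:
    steps: list[LadderStep]
    retained: str

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for s in self.steps:
            row = {
                "level": s.level,
                "chi2": s.indices.chi2,
                "df": s.indices.df,
                "p": s.indices.p,
                "cfi": s.indices.cfi,
                "rmsea": s.indices.rmsea,
                "rmsea_lo": s.indices.rmsea_ci[0],
                "rmsea_hi": s.indices.rmsea_ci[1],
                "srmr": s.indices.srmr,
                "accepted": s.accepted,
                "retained": s.level == self.retained,
            }
            if s.comparison is not None:
                row.update(
                    delta_chi2=s.comparison.delta_chi2,
                    delta_df=s.comparison.delta_df,
                    delta_p=s.comparison.p,
                    delta_cfi=s.comparison.delta_cfi,
                    delta_rmsea=s.comparison.delta_rmsea,
                    decision=s.comparison.decision,
                )
            rows.append(row)
        return pd.DataFrame(rows)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def invariance_ladder(
    data: pd.DataFrame,
    schema: MeasurementSchema,
    levels: list[str] | None = None,
    freed_intercepts: tuple[str, ...] | None = None,
    options: FitOptions | None = None,
) -> LadderResult:
    """Fit the invariance ladder and return the trail plus retained level.

    Escalation stops when the decision rule rejects the more stringent
    model, except that a rejected ``strong`` model falls through to
    ``partial`` (if requested) which frees the schema's named wave-2
    intercepts.  Raises if the configural model does not converge.
    """
    levels = list(levels) if levels is not None else ["configural", "weak", "strong"]
    unknown = set(levels) - set(_ORDER)
    if unknown:
        raise ModelError(f"unknown ladder levels: {sorted(unknown)}")
    levels.sort(key=_ORDER.index)
    if freed_intercepts is not None:
        schema = MeasurementSchema(
            indicators=schema.indicators, waves=schema.waves,
            marker=schema.marker, freed_intercepts=tuple(freed_intercepts),
        )
    if "partial" in levels and not schema.freed_intercepts:
        raise ModelError("partial invariance requires freed_intercepts")

    steps: list[LadderStep] = []
    retained_fit: FitResult | None = None
    retained = None
    for i, level in enumerate(levels):
        if level == "partial" and retained == "strong":
            break    # partial is only a fallback for a rejected strong model
        fit = fit_model(build_longitudinal_cfa(schema, level), data, options)
        if retained_fit is None and not fit.converged:
            raise RuntimeError(
                f"{level} model did not converge (gradient max-norm {fit.grad_max:.3g}); "
                "ladder aborted"
            )
        indices = compute_fit_indices(fit)
        if retained_fit is None:
            steps.append(LadderStep(level, fit, indices, None, True))
            retained_fit, retained = fit, level
            continue
        comp = chi_square_difference(fit, retained_fit)
        accepted = comp.decision == "retain_constrained" and fit.converged
        steps.append(LadderStep(level, fit, indices, comp, accepted))
        if accepted:
            retained_fit, retained = fit, level
        elif level == "strong" and "partial" in levels[i + 1:]:
            continue    # strong rejected: fall through to the partial model
        else:
            break
    return LadderResult(steps=steps, retained=retained)
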