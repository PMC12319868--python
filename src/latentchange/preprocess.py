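"""Deterministic data hygiene for the wide two-wave table.

Order of operations: truncate extreme friend counts at 100, blank brain
values failing MRI quality control, then apply the cell-wise +/-5 z-score
outlier rule per variable and wave.  Scaling to 0-100 uses theoretical
scale ranges (percent of maximum possible), keeping the metric comparable
across waves and samples.  Every exclusion is logged, one row per applied
rule instance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import ModelError

__all__ = [
    "DEFAULT_RANGES",
    "ExclusionLog",
    "apply_exclusions",
    "scale_0_100",
    "assign_groups",
    "puberty_group_label",
    "split_exploratory",
]

#: theoretical scale ranges (min, max) per variable base name
DEFAULT_RANGES: dict[str, tuple[float, float]] = {
    "prosocial": (0.0, 2.0),
    "friends": (0.0, 100.0),
    "school_env": (1.0, 4.0),
    "school_inv": (1.0, 4.0),
    "caregiver_mon": (1.0, 5.0),
    "family_coh": (0.0, 2.0),
    "neigh_safety": (1.0, 5.0),
    "ct": (1.0, 4.5),
}

_WAVES = ("t1", "t2")
_Z_CUT = 5.0


@dataclass
class ExclusionLog:
    """Append-only record of applied exclusion-rule instances."""

    rows: list[dict] = field(default_factory=list)

    def add(self, subject_id, variable: str, wave: str, rule: str, original) -> None:
        self.rows.append({
            "subject_id": subject_id, "variable": variable, "wave": wave,
            "rule": rule, "original_value": original,
        })

    def to_frame(self) -> pd.DataFrame:
        cols = ["subject_id", "variable", "wave", "rule", "original_value"]
        return pd.DataFrame(self.rows, columns=cols)

    def count(self, rule: str | None = None) -> int:
        if rule is None:
            return len(self.rows)
        return sum(r["rule"] == rule for r in self.rows)


def _wave_cols(df: pd.DataFrame, base: str) -> list[tuple[str, str]]:
    return [(w, f"{base}_{w}") for w in _WAVES if f"{base}_{w}" in df.columns]


def apply_exclusions(
    raw: pd.DataFrame,
    variables: tuple[str, ...] | None = None,
    id_column: str = "subject_id",
) -> tuple[pd.DataFrame, ExclusionLog]:
    """Truncation, QC blanking and cell-wise z-score exclusion.

    * friend counts above 100 are truncated at 100 (logged ``truncate100``),
    * ``ct`` is blanked where the per-wave QC recommendation flag is set
      (``qc_recommend``) or the clinical-review score exceeds 2
      (``qc_clinical``),
    * each modeled variable is z-scored per wave on the post-truncation
      column and cells strictly beyond +/-5 are blanked (``zscore5``);
      cells exactly at |z| = 5 are retained.
    """
    df = raw.copy()
    log = ExclusionLog()
    ids = df[id_column] if id_column in df.columns else pd.Series(df.index, index=df.index)
    if variables is None:
        variables = tuple(DEFAULT_RANGES)

    if "friends" in variables:
        for w, col in _wave_cols(df, "friends"):
            over = df.index[df[col] > 100]
            for i in over:
                log.add(ids[i], "friends", w, "truncate100", df.at[i, col])
            df.loc[over, col] = 100.0

    if "ct" in variables:
        for w, col in _wave_cols(df, "ct"):
            flag, score = f"qc_exclude_flag_{w}", f"qc_clinical_score_{w}"
            if flag in df.columns:
                bad = df.index[(df[flag] == 1) & df[col].notna()]
                for i in bad:
                    log.add(ids[i], "ct", w, "qc_recommend", df.at[i, col])
                df.loc[bad, col] = np.nan
            if score in df.columns:
                bad = df.index[(df[score] > 2) & df[col].notna()]
                for i in bad:
                    log.add(ids[i], "ct", w, "qc_clinical", df.at[i, col])
                df.loc[bad, col] = np.nan

    for base in variables:
        for w, col in _wave_cols(df, base):
            vals = df[col]
            if vals.notna().sum() < 2 or vals.std(ddof=0) == 0:
                continue
            z = (vals - vals.mean()) / vals.std(ddof=0)
            bad = df.index[z.abs() > _Z_CUT]
            for i in bad:
                log.add(ids[i], base, w, "zscore5", df.at[i, col])
            df.loc[bad, col] = np.nan
    return df, log


def scale_0_100(
    table: pd.DataFrame, ranges: dict[str, tuple[float, float]] | None = None
) -> pd.DataFrame:
    """POMP-scale modeled variables: x -> 100 (x - min) / (max - min)."""
    ranges = ranges or DEFAULT_RANGES
    out = table.copy()
    for base, (lo, hi) in ranges.items():
        if hi == lo:
            raise ModelError(f"degenerate range for {base!r}: ({lo}, {hi})")
        for _, col in _wave_cols(out, base):
            out[col] = 100.0 * (out[col] - lo) / (hi - lo)
    return out


_EARLY = {"early"}
_CONSECUTIVE_EARLY = {"pre", "early"}


def puberty_group_label(sex: str, stage: str, grouping: str) -> str | None:
    """Group label for one participant, or None when stage is missing."""
    if stage in (None, "missing") or (isinstance(stage, float) and np.isnan(stage)):
        return None
    sex_name = {"F": "female", "M": "male"}.get(sex, str(sex).lower())
    if grouping == "early_vs_nonearly":
        return f"{sex_name}_early" if stage in _EARLY else f"{sex_name}_nonearly"
    if grouping == "consecutive":
        return f"{sex_name}_early" if stage in _CONSECUTIVE_EARLY else f"{sex_name}_late"
    raise ModelError(f"unknown grouping {grouping!r}")


def assign_groups(table: pd.DataFrame, grouping: str = "early_vs_nonearly") -> pd.Series:
    """Group labels per row: sex-by-puberty stratification or SES median split.

    ``early_vs_nonearly``: four labels contrasting the early puberty stage
    against all other stages, per sex.  ``consecutive``: early = pre+early,
    late = mid+late+post, per sex.  ``ses_median``: high/low split of
    parental education years at the sample median, ties assigned high.
    Rows with a missing puberty stage get ``None`` (excluded from
    multi-group fits).
    """
    if grouping == "ses_median":
        edu = pd.to_numeric(table["parent_education_years"], errors="coerce")
        med = edu.median()
        labels = pd.Series(
            np.where(edu.isna(), None, np.where(edu >= med, "high", "low")),
            index=table.index, dtype=object,
        )
        return labels
    if grouping not in ("early_vs_nonearly", "consecutive"):
        raise ModelError(f"unknown grouping {grouping!r}")
    return pd.Series(
        [puberty_group_label(sx, st, grouping)
         for sx, st in zip(table["sex"], table["puberty_stage"])],
        index=table.index, dtype=object,
    )


def split_exploratory(
    table: pd.DataFrame, fraction: float = 0.20, seed: int = 0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Seeded disjoint exhaustive split; the first part gets floor(fraction n)."""
    if not 0.0 < fraction < 1.0:
        raise ModelError("fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(table))
    k = int(np.floor(fraction * len(table)))
    expl = table.iloc[np.sort(perm[:k])]
    conf = table.iloc[np.sort(perm[k:])]
    return expl, conf
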