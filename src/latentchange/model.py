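"""Parameter-matrix representation of structural equation models.

A model is held in six LISREL-style all-latent matrices:

* ``lam``   — loadings of observed variables on latents (p x m),
* ``beta``  — directed paths among latents (m x m); houses self-feedback
  and coupling regressions of change-score models,
* ``psi``   — latent (residual) covariance matrix (m x m, symmetric),
* ``theta`` — observed residual covariance matrix (p x p, symmetric),
* ``nu``    — observed intercepts (p,),
* ``alpha`` — latent intercepts / means (m,).

Each cell is either *fixed* at a numeric value or *free* and tagged with a
string label.  Cells sharing a label share a value — that is how equality
constraints (across waves or across groups) are expressed.  The
model-implied moments are

    Sigma = Lam (I - B)^-1 Psi (I - B)^-T Lam^T + Theta
    mu    = nu + Lam (I - B)^-1 alpha
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import yaml

__all__ = [
    "ModelError",
    "StructuralCycleError",
    "ParamMatrices",
    "ModelSpec",
    "implied_moments",
]

MATRIX_NAMES = ("lam", "beta", "psi", "theta", "nu", "alpha")
SYMMETRIC = frozenset({"psi", "theta"})


class ModelError(ValueError):
    """Invalid model specification."""


class StructuralCycleError(ModelError):
    """(I - Beta) is singular: the directed part of the model has a cycle."""


def _shapes(p: int, m: int) -> dict[str, tuple[int, ...]]:
    return {
        "lam": (p, m),
        "beta": (m, m),
        "psi": (m, m),
        "theta": (p, p),
        "nu": (p,),
        "alpha": (m,),
    }


@dataclass
class ParamMatrices:
    """One group's parameter matrices: fixed values plus free-cell labels.

    ``values`` holds the current (or starting) numeric value of every cell;
    ``labels`` holds, per cell, either ``None`` (fixed) or a parameter
    label (free).  Symmetric matrices are kept mirrored at all times.
    """

    n_observed: int
    n_latent: int
    values: dict[str, np.ndarray] = field(default_factory=dict)
    labels: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        shapes = _shapes(self.n_observed, self.n_latent)
        for name, shape in shapes.items():
            self.values.setdefault(name, np.zeros(shape))
            self.labels.setdefault(name, np.full(shape, None, dtype=object))
            if self.values[name].shape != shape:
                raise ModelError(f"{name} has shape {self.values[name].shape}, expected {shape}")

    # -- cell editing ------------------------------------------------------
    def set_fixed(self, mat: str, idx, value: float) -> None:
        self._set(mat, idx, value, None)

    def set_free(self, mat: str, idx, label: str, start: float = 0.0) -> None:
        if not label:
            raise ModelError("free cells need a non-empty label")
        self._set(mat, idx, start, label)

    def _set(self, mat: str, idx, value: float, label) -> None:
        if mat not in MATRIX_NAMES:
            raise ModelError(f"unknown matrix {mat!r}")
        self.values[mat][idx] = value
        self.labels[mat][idx] = label
        if mat in SYMMETRIC and isinstance(idx, tuple) and idx[0] != idx[1]:
            self.values[mat][idx[::-1]] = value
            self.labels[mat][idx[::-1]] = label

    # -- free-cell bookkeeping --------------------------------------------
    def iter_free_cells(self):
        """Yield ``(matrix, (i, j) or (i,), label)`` in deterministic order.

        Symmetric matrices yield only the lower triangle (i >= j); the
        mirror cell is implied.
        """
        for name in MATRIX_NAMES:
            lab = self.labels[name]
            if lab.ndim == 1:
                for i in range(lab.shape[0]):
                    if lab[i] is not None:
                        yield name, (i,), lab[i]
            else:
                for i in range(lab.shape[0]):
                    cols = range(i + 1) if name in SYMMETRIC else range(lab.shape[1])
                    for j in cols:
                        if lab[i, j] is not None:
                            yield name, (i, j), lab[i, j]

    def set_values(self, values: dict[str, float]) -> None:
        """Write labelled parameter values into the numeric arrays."""
        for name, idx, label in self.iter_free_cells():
            self._set(name, idx, values[label], label)

    def copy(self) -> "ParamMatrices":
        return ParamMatrices(
            self.n_observed,
            self.n_latent,
            {k: v.copy() for k, v in self.values.items()},
            {k: v.copy() for k, v in self.labels.items()},
        )


@dataclass
class ModelSpec:
    """A SEM: observed/latent names plus one ParamMatrices per group.

    Single-group models have ``group_names is None`` and exactly one entry
    in ``matrices``.  Labels shared across groups are cross-group equality
    constraints.
    """

    observed_names: list[str]
    latent_names: list[str]
    matrices: list[ParamMatrices]
    group_names: list[str] | None = None
    group_column: str | None = None

    @property
    def n_groups(self) -> int:
        return len(self.matrices)

    @property
    def n_observed(self) -> int:
        return len(self.observed_names)

    def free_labels(self) -> list[str]:
        """Distinct parameter labels in deterministic (first-seen) order."""
        seen: dict[str, None] = {}
        for mats in self.matrices:
            for _, _, label in mats.iter_free_cells():
                seen.setdefault(label, None)
        return list(seen)

    @property
    def n_free(self) -> int:
        return len(self.free_labels())

    @property
    def n_moments(self) -> int:
        p = self.n_observed
        return self.n_groups * p * (p + 3) // 2

    @property
    def df(self) -> int:
        return self.n_moments - self.n_free

    def start_values(self) -> dict[str, float]:
        out: dict[str, float] = {}
        for mats in self.matrices:
            for name, idx, label in mats.iter_free_cells():
                out.setdefault(label, float(mats.values[name][idx]))
        return out

    def validate(self) -> None:
        p, m = self.n_observed, len(self.latent_names)
        if len(set(self.observed_names)) != p:
            raise ModelError("duplicate observed names")
        if self.group_names is not None and len(self.group_names) != len(self.matrices):
            raise ModelError("group_names and matrices length mismatch")
        for mats in self.matrices:
            if (mats.n_observed, mats.n_latent) != (p, m):
                raise ModelError("matrix dimensions do not match name lists")
            for name in SYMMETRIC:
                if not np.array_equal(mats.values[name], mats.values[name].T):
                    raise ModelError(f"{name} values not symmetric")
                if not np.array_equal(mats.labels[name], mats.labels[name].T):
                    raise ModelError(f"{name} labels not symmetric")
        if self.n_free > self.n_moments:
            raise ModelError(
                f"model not identified: {self.n_free} free parameters exceed "
                f"{self.n_moments} observed moments"
            )

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        groups = []
        for g, mats in enumerate(self.matrices):
            cells = []
            for name in MATRIX_NAMES:
                lab, val = mats.labels[name], mats.values[name]
                it = np.ndindex(*val.shape)
                for idx in it:
                    if name in SYMMETRIC and idx[0] < idx[1]:
                        continue
                    if lab[idx] is not None:
                        cells.append([name, list(idx), {"free": str(lab[idx]), "start": float(val[idx])}])
                    elif val[idx] != 0.0:
                        cells.append([name, list(idx), {"fix": float(val[idx])}])
            groups.append(cells)
        return {
            "observed": list(self.observed_names),
            "latent": list(self.latent_names),
            "group_names": list(self.group_names) if self.group_names else None,
            "group_column": self.group_column,
            "groups": groups,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ModelSpec":
        p, m = len(d["observed"]), len(d["latent"])
        matrices = []
        for cells in d["groups"]:
            mats = ParamMatrices(p, m)
            for name, idx, cell in cells:
                idx = tuple(idx)
                if "fix" in cell:
                    mats.set_fixed(name, idx, cell["fix"])
                else:
                    mats.set_free(name, idx, cell["free"], cell.get("start", 0.0))
            matrices.append(mats)
        spec = cls(
            observed_names=list(d["observed"]),
            latent_names=list(d["latent"]),
            matrices=matrices,
            group_names=d.get("group_names"),
            group_column=d.get("group_column"),
        )
        spec.validate()
        return spec

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "ModelSpec":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def _moments_from_matrices(mats: ParamMatrices) -> tuple[np.ndarray, np.ndarray]:
    m = mats.n_latent
    i_b = np.eye(m) - mats.values["beta"]
    # a singular (I - B) means the directed paths contain a cycle
    if abs(np.linalg.det(i_b)) < 1e-12:
        raise StructuralCycleError("(I - Beta) is singular")
    a = np.linalg.inv(i_b)
    e = mats.values["lam"] @ a
    sigma = e @ mats.values["psi"] @ e.T + mats.values["theta"]
    sigma = (sigma + sigma.T) / 2.0
    mu = mats.values["nu"] + e @ mats.values["alpha"]
    return mu, sigma


def implied_moments(
    spec: ModelSpec, values: dict[str, float] | None = None, group: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Model-implied mean vector and covariance matrix for one group.

    ``values`` maps every free label to a number; ``None`` uses the values
    currently stored in the matrices.
    """
    mats = spec.matrices[group]
    if values is not None:
        missing = [lab for lab in spec.free_labels() if lab not in values]
        if missing:
            raise ModelError(f"values missing labels: {missing[:5]}")
        mats = mats.copy()
        mats.set_values(values)
    return _moments_from_matrices(mats)
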