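"""Model fitting: FIML optimization, standard errors, standardization.

The FIML log-likelihood is maximized with L-BFGS using an analytic
(adjoint-propagated) gradient, followed where needed by Newton polishing
with a finite-difference Hessian of that gradient.  "Robust" standard
errors are sandwich estimates built from casewise score contributions;
observed-information standard errors are also available.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dataclass_field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .fiml import PatternData, independence_loglik, pattern_split, saturated_loglik
from .model import SYMMETRIC, ModelError, ModelSpec

__all__ = ["FitOptions", "FitResult", "fit_model", "standard_errors", "standardize_solution"]


@dataclass
class FitOptions:
    se: str = "sandwich"              # 'sandwich' | 'observed_information' | 'none'
    gtol: float = 1e-6                # max-norm tolerance on the mean-loglik gradient
    max_iter: int = 300               # L-BFGS iterations before scoring polish
    restarts: int = 2                 # extra jittered starts if not converged
    newton_steps: int = 50
    compute_baselines: bool = True    # saturated + independence log-likelihoods
    data_informed_starts: bool = True


@dataclass
class FitResult:
    """A fitted SEM: estimates, uncertainty, likelihoods, diagnostics."""

    spec: ModelSpec
    labels: list[str]
    estimates: dict[str, float]
    se: dict[str, float]
    z: dict[str, float]
    p: dict[str, float]
    std_all: dict[str, float]
    loglik: float
    loglik_saturated: float | None
    loglik_independence: float | None
    q_independence: int | None
    converged: bool
    grad_max: float
    n_used: dict[str, int]
    n_total: int
    vcov: np.ndarray | None
    se_flavor: str
    warnings: list[str] = dataclass_field(default_factory=list)
    std_cells: list[tuple] = dataclass_field(default_factory=list)
    objective: object | None = dataclass_field(default=None, repr=False)

    @property
    def df(self) -> int:
        return self.spec.df

    @property
    def chi_square(self) -> float:
        if self.loglik_saturated is None:
            raise ValueError("saturated log-likelihood not computed")
        return 2.0 * (self.loglik_saturated - self.loglik)

    def parameter_table(self) -> pd.DataFrame:
        rows = [
            {
                "label": lab,
                "estimate": self.estimates[lab],
                "se": self.se.get(lab, np.nan),
                "z": self.z.get(lab, np.nan),
                "p": self.p.get(lab, np.nan),
                "std_all": self.std_all.get(lab, np.nan),
            }
            for lab in self.labels
        ]
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# objective machinery


class _Objective:
    """FIML negative mean log-likelihood with analytic gradient."""

    def __init__(self, spec: ModelSpec, pattern_data: list[PatternData]):
        self.spec = spec
        self.data = pattern_data
        self.labels = spec.free_labels()
        self.index = {lab: k for k, lab in enumerate(self.labels)}
        self.mats = [m.copy() for m in spec.matrices]
        # per-group list of (matrix name, cell index, param index, mirrored)
        self.cells: list[list[tuple]] = []
        for mats in self.mats:
            cells = []
            for name, idx, lab in mats.iter_free_cells():
                mirrored = name in SYMMETRIC and len(idx) == 2 and idx[0] != idx[1]
                cells.append((name, idx, self.index[lab], mirrored))
            self.cells.append(cells)
        self.n_total = sum(pd_.n_used for pd_ in pattern_data)
        self.q = len(self.labels)

    def _set_theta(self, th: np.ndarray) -> None:
        for mats, cells in zip(self.mats, self.cells):
            for name, idx, k, mirrored in cells:
                mats.values[name][idx] = th[k]
                if mirrored:
                    mats.values[name][idx[::-1]] = th[k]

    def _group_moments(self, g: int):
        mats = self.mats[g]
        m = mats.n_latent
        i_b = np.eye(m) - mats.values["beta"]
        a = np.linalg.inv(i_b)
        e = mats.values["lam"] @ a
        sigma = e @ mats.values["psi"] @ e.T + mats.values["theta"]
        sigma = (sigma + sigma.T) / 2.0
        mu = mats.values["nu"] + e @ mats.values["alpha"]
        return a, e, mu, sigma

    def value_and_grad(self, th: np.ndarray) -> tuple[float, np.ndarray]:
        """Negative mean log-likelihood and its gradient; (+inf, 0) if non-PD."""
        self._set_theta(th)
        total = 0.0
        grad = np.zeros(self.q)
        for g, pdata in enumerate(self.data):
            mats = self.mats[g]
            try:
                a, e, mu, sigma = self._group_moments(g)
            except np.linalg.LinAlgError:
                return np.inf, np.zeros(self.q)
            p = pdata.p
            g_sig = np.zeros((p, p))
            g_mu = np.zeros(p)
            for pat in pdata.patterns:
                o = np.flatnonzero(pat.mask)
                sub = sigma[np.ix_(o, o)]
                try:
                    chol = np.linalg.cholesky(sub)
                except np.linalg.LinAlgError:
                    return np.inf, np.zeros(self.q)
                inv = np.linalg.inv(sub)
                logdet = 2.0 * np.log(np.diag(chol)).sum()
                d = pat.mean - mu[o]
                w = pat.scatter + pat.count * np.outer(d, d)
                total += -0.5 * (
                    pat.count * (len(o) * np.log(2 * np.pi) + logdet) + float(np.sum(inv * w))
                )
                gs = -0.5 * pat.count * inv + 0.5 * inv @ w @ inv
                g_sig[np.ix_(o, o)] += gs
                g_mu[o] += pat.count * inv @ d
            # adjoint propagation through Sigma = E Psi E^T + Theta, mu = nu + E alpha
            psi, lam, alpha = mats.values["psi"], mats.values["lam"], mats.values["alpha"]
            e_adj = 2.0 * g_sig @ e @ psi + np.outer(g_mu, alpha)
            adj = {
                "theta": g_sig,
                "psi": e.T @ g_sig @ e,
                "lam": e_adj @ a.T,
                "beta": a.T @ (lam.T @ e_adj) @ a.T,
                "nu": g_mu,
                "alpha": e.T @ g_mu,
            }
            for name, idx, k, mirrored in self.cells[g]:
                val = adj[name][idx]
                if mirrored:
                    val = val + adj[name][idx[::-1]]
                grad[k] += val
        scale = -1.0 / self.n_total
        return scale * total, scale * grad

    def loglik(self, th: np.ndarray) -> float:
        f, _ = self.value_and_grad(th)
        return -f * self.n_total

    # -- derivative matrices of (Sigma, mu) w.r.t. each parameter ----------
    def forward_derivs(self, g: int):
        """d(Sigma)/d(theta_k) and d(mu)/d(theta_k) for group g, all k."""
        mats = self.mats[g]
        a, e, mu, sigma = self._group_moments(g)
        psi, alpha = mats.values["psi"], mats.values["alpha"]
        p = mats.n_observed
        d_sig = np.zeros((self.q, p, p))
        d_mu = np.zeros((self.q, p))
        epsi = e @ psi
        for name, idx, k, mirrored in self.cells[g]:
            if name == "lam":
                i, j = idx
                w = epsi @ a[j, :]
                u = np.zeros(p)
                u[i] = 1.0
                d_sig[k] += np.outer(u, w) + np.outer(w, u)
                d_mu[k][i] += float(a[j, :] @ alpha)
            elif name == "beta":
                i, j = idx
                u = e[:, i]
                w = epsi @ a[j, :]
                d_sig[k] += np.outer(u, w) + np.outer(w, u)
                d_mu[k] += u * float(a[j, :] @ alpha)
            elif name == "psi":
                i, j = idx
                if i == j:
                    d_sig[k] += np.outer(e[:, i], e[:, i])
                else:
                    d_sig[k] += np.outer(e[:, i], e[:, j]) + np.outer(e[:, j], e[:, i])
            elif name == "theta":
                i, j = idx
                d_sig[k][i, j] += 1.0
                if i != j:
                    d_sig[k][j, i] += 1.0
            elif name == "nu":
                d_mu[k][idx[0]] += 1.0
            elif name == "alpha":
                d_mu[k] += e[:, idx[0]]
        return d_sig, d_mu, mu, sigma


def _numeric_hessian(obj: _Objective, th: np.ndarray) -> np.ndarray:
    """Central finite differences of the analytic gradient (mean loglik)."""
    q = len(th)
    h = 1e-5 * np.maximum(1.0, np.abs(th))
    hess = np.zeros((q, q))
    for k in range(q):
        up, dn = th.copy(), th.copy()
        up[k] += h[k]
        dn[k] -= h[k]
        _, g_up = obj.value_and_grad(up)
        _, g_dn = obj.value_and_grad(dn)
        hess[k] = (g_up - g_dn) / (2 * h[k])
    return (hess + hess.T) / 2.0


def _newton_polish(obj: _Objective, th: np.ndarray, gtol: float, max_steps: int):
    """Fisher-scoring iterations with ridge fallback and backtracking.

    The expected information is analytic and positive semi-definite, so the
    scoring direction is a reliable ascent direction near the optimum.
    """
    f, g = obj.value_and_grad(th)
    for _ in range(max_steps):
        if np.max(np.abs(g)) <= gtol:
            break
        try:
            hess = _expected_information(obj, th) / obj.n_total
        except np.linalg.LinAlgError:
            break
        ridge = 0.0
        for _try in range(8):
            try:
                step = np.linalg.solve(hess + ridge * np.eye(len(th)), -g)
                if np.dot(step, g) < 0:
                    break
            except np.linalg.LinAlgError:
                pass
            ridge = max(ridge * 10.0, 1e-6 * (1 + np.abs(np.diag(hess)).max()))
        else:
            break
        t = 1.0
        for _ls in range(40):
            f_new, g_new = obj.value_and_grad(th + t * step)
            if np.isfinite(f_new) and f_new <= f + 1e-12 * abs(f):
                break
            t *= 0.5
        else:
            break
        if np.max(np.abs(g_new)) >= np.max(np.abs(g)) and f_new >= f - 1e-14 * abs(f):
            break
        th = th + t * step
        f, g = f_new, g_new
    return th, f, g


def _data_informed_starts(spec: ModelSpec, pattern_data: list[PatternData], th: np.ndarray,
                          labels: list[str]) -> np.ndarray:
    """Moments-informed defaults: means at sample means, variances at half
    the sample variance, latent means/variances taken from marker columns."""
    index = {lab: k for k, lab in enumerate(labels)}
    th = th.copy()
    for g, mats in enumerate(spec.matrices):
        p = mats.n_observed
        mbar = np.full(p, np.nan)
        s2 = np.full(p, np.nan)
        cnt = np.zeros(p)
        for pat in pattern_data[g].patterns:
            o = np.flatnonzero(pat.mask)
            cnt[o] += pat.count
        for j in range(p):
            vals = np.concatenate(
                [pat.rows[:, list(np.flatnonzero(pat.mask)).index(j)]
                 for pat in pattern_data[g].patterns if pat.mask[j]]
                or [np.array([])]
            )
            if vals.size:
                mbar[j], s2[j] = vals.mean(), max(vals.var(), 1e-3)
        lam_val, lam_lab = mats.values["lam"], mats.labels["lam"]
        # marker column per latent: fixed unit loading, if any
        marker = {}
        for j in range(mats.n_latent):
            for i in range(p):
                if lam_lab[i, j] is None and lam_val[i, j] == 1.0:
                    marker[j] = i
                    break
        alpha_start = np.zeros(mats.n_latent)
        for name, idx, lab in mats.iter_free_cells():
            k = index[lab]
            if name == "theta" and idx[0] == idx[1] and np.isfinite(s2[idx[0]]):
                th[k] = s2[idx[0]] / 2.0
            elif name == "psi" and idx[0] == idx[1]:
                j = idx[0]
                base = s2[marker[j]] if j in marker and np.isfinite(s2[marker[j]]) else np.nanmedian(s2)
                th[k] = max(base / 2.0, 1e-2)
            elif name == "alpha":
                j = idx[0]
                if j in marker and np.isfinite(mbar[marker[j]]):
                    th[k] = mbar[marker[j]]
                    alpha_start[j] = th[k]
            elif name == "lam":
                th[k] = 1.0
        for name, idx, lab in mats.iter_free_cells():
            if name == "nu" and np.isfinite(mbar[idx[0]]):
                i = idx[0]
                lam_row = np.where(np.array([l is not None for l in lam_lab[i]]), 1.0, lam_val[i])
                th[index[lab]] = mbar[i] - float(lam_row @ alpha_start)
    return th


def fit_model(
    spec: ModelSpec,
    data: pd.DataFrame | np.ndarray,
    options: FitOptions | None = None,
) -> FitResult:
    """Fit a ModelSpec to wide-format data by FIML.

    ``data`` must contain the spec's observed columns (NaN = missing) and,
    for multi-group specs, the spec's ``group_column``.  Non-convergence is
    flagged on the result rather than raised; Heywood cases (negative
    variance estimates) are recorded as warnings.
    """
    options = options or FitOptions()
    spec.validate()
    pattern_data, n_used = _split_data(spec, data)
    obj = _Objective(spec, pattern_data)
    warns: list[str] = []

    th0 = np.array([spec.start_values()[lab] for lab in obj.labels])
    if options.data_informed_starts:
        th0 = _data_informed_starts(spec, pattern_data, th0, obj.labels)

    rng = np.random.default_rng(0)
    best = None
    for attempt in range(1 + options.restarts):
        start = th0 if attempt == 0 else th0 * (1 + 0.1 * rng.standard_normal(obj.q)) + 0.01 * rng.standard_normal(obj.q)
        res = optimize.minimize(
            obj.value_and_grad, start, jac=True, method="L-BFGS-B",
            options={"maxiter": options.max_iter, "ftol": 1e-10, "gtol": 1e-5},
        )
        th, f, g = _newton_polish(obj, res.x, options.gtol, options.newton_steps)
        gmax = float(np.max(np.abs(g)))
        if best is None or f < best[1]:
            best = (th, f, g, gmax)
        if gmax <= options.gtol:
            best = (th, f, g, gmax)
            break
    th, f, g, gmax = best
    converged = bool(np.isfinite(f) and gmax <= options.gtol)
    if not converged:
        warns.append(f"non-convergence: gradient max-norm {gmax:.3g} > {options.gtol:g}")
    loglik = -f * obj.n_total

    estimates = {lab: float(v) for lab, v in zip(obj.labels, th)}
    # Heywood screen: negative free variance estimates
    obj._set_theta(th)
    for g_i, mats in enumerate(obj.mats):
        for name, idx, lab in mats.iter_free_cells():
            if name in ("psi", "theta") and len(idx) == 2 and idx[0] == idx[1] and estimates[lab] < 0:
                msg = f"Heywood case: variance parameter {lab!r} = {estimates[lab]:.4g} < 0"
                if msg not in warns:
                    warns.append(msg)

    se, z, pvals, vcov = {}, {}, {}, None
    if options.se != "none" and converged:
        try:
            se, vcov = standard_errors(obj, th, options.se)
            for lab in obj.labels:
                s = se.get(lab, np.nan)
                z[lab] = estimates[lab] / s if s and np.isfinite(s) and s > 0 else np.nan
                pvals[lab] = 2 * stats.norm.sf(abs(z[lab])) if np.isfinite(z[lab]) else np.nan
        except np.linalg.LinAlgError:
            warns.append("singular information matrix: standard errors undefined")

    l_sat = l_ind = q_ind = None
    if options.compute_baselines:
        l_sat = sum(saturated_loglik(pd_) for pd_ in pattern_data)
        pairs = [independence_loglik(pd_) for pd_ in pattern_data]
        l_ind = sum(v for v, _ in pairs)
        q_ind = sum(q for _, q in pairs)

    result = FitResult(
        spec=spec, labels=obj.labels, estimates=estimates,
        se=se, z=z, p=pvals, std_all={},
        loglik=loglik, loglik_saturated=l_sat, loglik_independence=l_ind,
        q_independence=q_ind, converged=converged, grad_max=gmax,
        n_used=n_used, n_total=obj.n_total, vcov=vcov, se_flavor=options.se,
        warnings=warns, objective=obj,
    )
    if converged:
        try:
            result.std_all, result.std_cells = standardize_solution(result)
        except (np.linalg.LinAlgError, ValueError):
            result.warnings.append("standardization failed")
    return result


def _split_data(spec: ModelSpec, data) -> tuple[list[PatternData], dict[str, int]]:
    if isinstance(data, np.ndarray):
        df = pd.DataFrame(data, columns=spec.observed_names)
    else:
        df = data
    missing_cols = [c for c in spec.observed_names if c not in df.columns]
    if missing_cols:
        raise ModelError(f"data lacks observed columns: {missing_cols}")
    pattern_data, n_used = [], {}
    if spec.group_names is None:
        pd_ = pattern_split(df[spec.observed_names].to_numpy(float))
        pattern_data.append(pd_)
        n_used["all"] = pd_.n_used
    else:
        if spec.group_column is None or spec.group_column not in df.columns:
            raise ModelError("multi-group spec requires a group column in the data")
        for gname in spec.group_names:
            sub = df[df[spec.group_column] == gname]
            if len(sub) == 0:
                raise ModelError(f"group {gname!r} has no rows")
            pd_ = pattern_split(sub[spec.observed_names].to_numpy(float))
            pattern_data.append(pd_)
            n_used[gname] = pd_.n_used
    for pd_, n in zip(pattern_data, n_used.values()):
        if n <= spec.n_observed:
            warnings.warn("fewer rows than observed variables in a group", stacklevel=2)
    return pattern_data, n_used


def standard_errors(obj_or_fit, th: np.ndarray | None = None, flavor: str = "sandwich"):
    """Standard errors at the optimum.

    ``observed_information`` inverts the negative Hessian of the total
    log-likelihood; ``sandwich`` combines it with the outer product of
    casewise score contributions (robust to non-normality).
    """
    if isinstance(obj_or_fit, FitResult):
        fit = obj_or_fit
        if fit.objective is None:
            raise ValueError("FitResult carries no objective; refit with fit_model first")
        if not fit.converged:
            raise ValueError("standard errors require a converged fit")
        obj = fit.objective
        th = np.array([fit.estimates[lab] for lab in obj.labels])
    else:
        obj = obj_or_fit
    hess_mean = _numeric_hessian(obj, th)       # of negative mean loglik
    info = hess_mean * obj.n_total              # observed information of total loglik
    bread = np.linalg.inv(info)
    if flavor == "observed_information":
        vcov = bread
    elif flavor == "sandwich":
        meat = _score_outer_product(obj, th)
        vcov = bread @ meat @ bread
    else:
        raise ValueError(f"unknown SE flavor {flavor!r}")
    diag = np.diag(vcov).copy()
    se = {}
    for k, lab in enumerate(obj.labels):
        if diag[k] > 0:
            se[lab] = float(np.sqrt(diag[k]))
        else:
            warnings.warn(f"non-positive variance for {lab!r}: SE undefined", stacklevel=2)
            se[lab] = np.nan
    return se, vcov


def _score_outer_product(obj: _Objective, th: np.ndarray) -> np.ndarray:
    """Sum over rows of the outer product of casewise score vectors."""
    obj._set_theta(th)
    meat = np.zeros((obj.q, obj.q))
    for g, pdata in enumerate(obj.data):
        d_sig, d_mu, mu, sigma = obj.forward_derivs(g)
        for pat in pdata.patterns:
            o = np.flatnonzero(pat.mask)
            inv = np.linalg.inv(sigma[np.ix_(o, o)])
            b = (pat.rows - mu[o]) @ inv                     # (n_p, k)
            scores = np.empty((pat.count, obj.q))
            for k in range(obj.q):
                ds = d_sig[k][np.ix_(o, o)]
                dm = d_mu[k][o]
                tr_term = -0.5 * float(np.sum(inv * ds))
                scores[:, k] = tr_term + 0.5 * np.einsum("ij,jk,ik->i", b, ds, b) + b @ dm
            meat += scores.T @ scores
    return meat


def _expected_information(obj: _Objective, th: np.ndarray) -> np.ndarray:
    """Fisher information of the total log-likelihood at ``th``.

    Per pattern: I_jk = n [ dmu_j' P dmu_k + tr(P dSigma_j P dSigma_k)/2 ]
    on the observed sub-block, summed over patterns and groups.
    """
    obj._set_theta(th)
    info = np.zeros((obj.q, obj.q))
    for g, pdata in enumerate(obj.data):
        d_sig, d_mu, mu, sigma = obj.forward_derivs(g)
        for pat in pdata.patterns:
            o = np.flatnonzero(pat.mask)
            inv = np.linalg.inv(sigma[np.ix_(o, o)])
            ds = d_sig[:, o[:, None], o[None, :]]          # (q, k, k)
            dm = d_mu[:, o]                                # (q, k)
            pds = np.einsum("ab,jbc->jac", inv, ds)        # (q, k, k)
            tr_part = 0.5 * np.einsum("jab,kba->jk", pds, pds)
            mu_part = np.einsum("ja,ab,kb->jk", dm, inv, dm)
            info += pat.count * (mu_part + tr_part)
    return (info + info.T) / 2.0


def standardize_solution(fit: FitResult) -> tuple[dict[str, float], list[tuple]]:
    """Fully standardized solution.

    Loadings, directed paths, and intercepts are rescaled by model-implied
    total standard deviations of the connected variables.  Variance
    parameters are reported as proportions of the implied total variance of
    their variable; covariance parameters as the correlation of the
    corresponding (residual) terms, guaranteeing values in [-1, 1].

    Returns ``(by_label, cells)`` where ``by_label`` maps each label to the
    standardized value of its first cell and ``cells`` lists
    ``(group, matrix, index, label, estimate, standardized)`` per free cell.
    """
    spec = fit.spec
    by_label: dict[str, float] = {}
    cells: list[tuple] = []
    for g, template in enumerate(spec.matrices):
        mats = template.copy()
        mats.set_values(fit.estimates)
        m = mats.n_latent
        a = np.linalg.inv(np.eye(m) - mats.values["beta"])
        e = mats.values["lam"] @ a
        psi, theta = mats.values["psi"], mats.values["theta"]
        v_eta = a @ psi @ a.T
        sigma = e @ psi @ e.T + theta
        sd_eta = np.sqrt(np.maximum(np.diag(v_eta), 0.0))
        sd_obs = np.sqrt(np.maximum(np.diag(sigma), 0.0))
        for name, idx, lab in mats.iter_free_cells():
            est = float(mats.values[name][idx])
            val = np.nan
            if name == "lam":
                i, j = idx
                val = est * sd_eta[j] / sd_obs[i] if sd_obs[i] > 0 else np.nan
            elif name == "beta":
                i, j = idx
                val = est * sd_eta[j] / sd_eta[i] if sd_eta[i] > 0 else np.nan
            elif name == "psi":
                i, j = idx
                if i == j:
                    val = est / v_eta[i, i] if v_eta[i, i] > 0 else np.nan
                else:
                    denom = psi[i, i] * psi[j, j]
                    val = est / np.sqrt(denom) if denom > 0 else np.nan
            elif name == "theta":
                i, j = idx
                if i == j:
                    val = est / sigma[i, i] if sigma[i, i] > 0 else np.nan
                else:
                    denom = theta[i, i] * theta[j, j]
                    val = est / np.sqrt(denom) if denom > 0 else np.nan
            elif name == "nu":
                i = idx[0]
                val = est / sd_obs[i] if sd_obs[i] > 0 else np.nan
            elif name == "alpha":
                j = idx[0]
                val = est / sd_eta[j] if sd_eta[j] > 0 else np.nan
            cells.append((g, name, idx, lab, est, float(val)))
            if lab not in by_label:
                by_label[lab] = float(val)
    return by_label, cells
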