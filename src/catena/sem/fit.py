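"""FIML estimation: quasi-Newton optimisation, standard errors, df."""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from .likelihood import ObservedDataset, loglik_and_grad
from .model import ModelError, ModelSpec, ParameterTable
from .moments import group_moments

_BIG = 1e12


class ConvergenceError(RuntimeError):
    pass


@dataclass
class FitResult:
    spec: ModelSpec
    labels: list[str]
    estimates: dict[str, float]
    std_errors: dict[str, float]
    loglik: float
    df: int
    n_free: int
    n_moments: int
    converged: bool
    n_iter: int
    grad_norm: float
    group_ns: dict[str, int]
    implied: list[tuple[np.ndarray, np.ndarray]] = field(repr=False, default=None)
    message: str = ""

    @property
    def n_total(self) -> int:
        return sum(self.group_ns.values())

    @property
    def n_groups(self) -> int:
        return len(self.group_ns)

    def require_converged(self) -> "FitResult":
        if not self.converged:
            raise ConvergenceError(f"fit did not converge: {self.message}")
        return self

    def to_dict(self) -> dict:
        return {
            "estimates": self.estimates,
            "std_errors": self.std_errors,
            "loglik": self.loglik,
            "df": self.df,
            "n_free": self.n_free,
            "converged": self.converged,
            "n_iter": self.n_iter,
            "group_ns": self.group_ns,
            "message": self.message,
        }

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def count_sample_moments(spec: ModelSpec) -> int:
    p = len(spec.observed)
    return len(spec.groups) * (p + p * (p + 1) // 2)


def default_starts(table: ParameterTable, data: ObservedDataset) -> np.ndarray:
    """Data-driven starting values: observed moments seed the scale."""
    spec = table.spec
    col_mean = np.nanmean(data.data, axis=0)
    col_var = np.nanvar(data.data, axis=0)
    col_mean = np.where(np.isfinite(col_mean), col_mean, 0.0)
    col_var = np.where(np.isfinite(col_var) & (col_var > 0), col_var, 1.0)
    obs_index = {v: i for i, v in enumerate(spec.observed)}
    theta = np.zeros(table.n_free())
    for k, label in enumerate(table.labels):
        if label in table.starts:
            theta[k] = table.starts[label]
            continue
        gi, mat, i, j = table.placements[label][0]
        name = spec.variables[i]
        if mat == "m":
            theta[k] = col_mean[obs_index[name]] if name in obs_index else 0.0
        elif mat == "S" and i == j:
            if name in obs_index:
                theta[k] = 0.5 * col_var[obs_index[name]]
            else:
                theta[k] = 0.5 * float(np.mean(col_var))
        elif mat == "S":
            theta[k] = 0.0
        else:  # A: loading or regression
            theta[k] = 0.7 if spec.variables[j] in spec.latent else 0.0
            if spec.variables[j] in spec.latent and name in spec.latent:
                theta[k] = 0.3  # higher-order loading / latent regression
    return theta


def fit_model(
    spec: ModelSpec,
    data: ObservedDataset,
    starts: int = 3,
    seed: int = 11,
    max_iter: int = 1000,
    start_values: dict[str, float] | None = None,
) -> FitResult:
    """Maximise the FIML log-likelihood.

    Variance parameters are kept nonnegative by box bounds; points where
    the implied covariance loses positive definiteness return a smooth
    penalty so the line search backs off rather than raising.
    """
    spec.validate()
    if data.variables != spec.observed or data.groups != spec.groups:
        data = ObservedDataset(
            data.data, data.variables, data.group_labels, data.groups
        ).reorder(spec.observed)
        if data.groups != spec.groups:
            raise ModelError(
                f"data groups {data.groups} do not match model groups {spec.groups}"
            )
    table = spec.parameter_table()
    theta0 = default_starts(table, data)
    if start_values:
        for k, lab in enumerate(table.labels):
            if lab in start_values:
                theta0[k] = start_values[lab]
    bounds = [
        (0.0, None) if table.is_variance[lab] else (None, None)
        for lab in table.labels
    ]

    def objective(theta: np.ndarray):
        ll, grad = loglik_and_grad(table, theta, data)
        if not np.isfinite(ll):
            # flat plateau: the line search backs off into the feasible region
            return _BIG, np.zeros_like(theta)
        return -ll, -grad

    def solve(t0):
        res = minimize(
            objective,
            t0,
            jac=True,
            method="L-BFGS-B",
            bounds=bounds,
            options={"maxiter": max_iter, "ftol": 1e-13, "gtol": 3e-8},
        )
        # warm restart clears stale curvature after boundary-induced aborts
        for _ in range(2):
            if res.success or res.fun >= _BIG / 2:
                break
            res2 = minimize(
                objective, res.x, jac=True, method="L-BFGS-B", bounds=bounds,
                options={"maxiter": max_iter, "ftol": 1e-13, "gtol": 3e-8},
            )
            if res2.fun <= res.fun:
                res2.nit += res.nit
                res = res2
            else:
                break
        return res

    rng = np.random.default_rng(seed)
    best = None
    for s in range(max(1, starts)):
        t0 = theta0 if s == 0 else _disperse(theta0, table, rng)
        res = solve(t0)
        if best is None or res.fun < best.fun - 1e-9:
            best = res
    theta = best.x
    ll, grad = loglik_and_grad(table, theta, data)
    gnorm = float(np.max(np.abs(grad))) if grad is not None else np.inf
    converged = bool(np.isfinite(ll)) and best.fun < _BIG / 2 and (
        best.success or gnorm < 1e-3 * max(1.0, abs(ll))
    )
    estimates = {lab: float(v) for lab, v in zip(table.labels, theta)}
    ses = _standard_errors(table, theta, data, bounds) if converged else {}
    n_moments = count_sample_moments(spec)
    moms = group_moments(table, theta) if np.isfinite(ll) else None
    return FitResult(
        spec=spec,
        labels=list(table.labels),
        estimates=estimates,
        std_errors=ses,
        loglik=float(ll),
        df=n_moments - table.n_free(),
        n_free=table.n_free(),
        n_moments=n_moments,
        converged=converged,
        n_iter=int(best.nit),
        grad_norm=gnorm,
        group_ns=data.group_sizes(),
        implied=[(mu, sig) for mu, sig, _, _ in moms] if moms else None,
        message=str(best.message),
    )


def _disperse(theta0, table: ParameterTable, rng) -> np.ndarray:
    t = theta0 + rng.normal(0.0, 0.25, size=theta0.shape) * (
        1.0 + np.abs(theta0)
    )
    for k, lab in enumerate(table.labels):
        if table.is_variance[lab]:
            t[k] = abs(t[k]) + 1e-3
    return t


def _standard_errors(table, theta, data, bounds) -> dict[str, float]:
    """Inverse observed information; finite differences of the analytic grad."""
    k = len(theta)
    H = np.zeros((k, k))
    h = 1e-5 * (1.0 + np.abs(theta))
    for i in range(k):
        tp = theta.copy()
        tp[i] += h[i]
        tm = theta.copy()
        tm[i] -= h[i]
        if bounds[i][0] is not None and tm[i] < bounds[i][0]:
            tm[i] = bounds[i][0]
        _, gp = loglik_and_grad(table, tp, data)
        _, gm = loglik_and_grad(table, tm, data)
        if gp is None or gm is None:
            return {lab: float("nan") for lab in table.labels}
        H[i] = -(gp - gm) / (tp[i] - tm[i])
    H = 0.5 * (H + H.T)
    try:
        cov = np.linalg.pinv(H)
        se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    except np.linalg.LinAlgError:
        se = np.full(k, np.nan)
    return {lab: float(s) for lab, s in zip(table.labels, se)}


# -- saturated / baseline helper models --------------------------------------


def saturated_spec(observed: list[str], groups: list[str]) -> ModelSpec:
    spec = ModelSpec(observed=list(observed), latent=[], groups=list(groups))
    for i, a in enumerate(observed):
        spec.add("variance", a, a)
        spec.add("mean", a)
        for b in observed[i + 1:]:
            spec.add("covariance", a, b)
    return spec


def baseline_spec(observed: list[str], groups: list[str]) -> ModelSpec:
    spec = ModelSpec(observed=list(observed), latent=[], groups=list(groups))
    for a in observed:
        spec.add("variance", a, a)
        spec.add("mean", a)
    return spec


def fit_saturated(data: ObservedDataset) -> FitResult:
    """FIML fit of the unrestricted mean/covariance model.

    Estimated by EM on the multivariate-normal sufficient statistics,
    which maximises exactly the same likelihood as the optimiser but is
    far faster for the p(p+3)/2-parameter saturated model.
    """
    spec = saturated_spec(data.variables, data.groups)
    table = spec.parameter_table()
    p = len(data.variables)
    estimates: dict[str, float] = {}
    total_ll = 0.0
    for g, pats in zip(data.groups, data.patterns()):
        mu, sigma, ll = _em_mvnorm(pats, p)
        total_ll += ll
        for i, a in enumerate(data.variables):
            estimates[f"mean:{a}@{g}"] = float(mu[i])
            estimates[f"variance:{a}~{a}@{g}"] = float(sigma[i, i])
            for j in range(i + 1, p):
                b = data.variables[j]
                estimates[f"covariance:{a}~{b}@{g}"] = float(sigma[i, j])
    theta = np.array([estimates[lab] for lab in table.labels])
    ll, grad = loglik_and_grad(table, theta, data)
    return FitResult(
        spec=spec,
        labels=list(table.labels),
        estimates=estimates,
        std_errors={},
        loglik=float(ll),
        df=0,
        n_free=table.n_free(),
        n_moments=count_sample_moments(spec),
        converged=True,
        n_iter=0,
        grad_norm=float(np.max(np.abs(grad))) if grad is not None else np.nan,
        group_ns=data.group_sizes(),
        implied=None,
        message="saturated model (EM)",
    )


def _em_mvnorm(pats, p, tol=1e-10, max_iter=2000):
    """EM for MVN mean/covariance from pattern sufficient statistics."""
    n = sum(pat.n for pat in pats)
    # start from available-case moments
    mu = np.zeros(p)
    cnt = np.zeros(p)
    for pat in pats:
        mu[pat.idx] += pat.n * pat.mean
        cnt[pat.idx] += pat.n
    mu = np.where(cnt > 0, mu / np.maximum(cnt, 1), 0.0)
    sigma = np.eye(p)
    var = np.zeros(p)
    for pat in pats:
        var[pat.idx] += pat.n * (np.diag(pat.scatter) + (pat.mean - mu[pat.idx]) ** 2)
    var = np.where(cnt > 0, var / np.maximum(cnt, 1), 1.0)
    sigma = np.diag(np.maximum(var, 1e-8))
    last = -np.inf
    for _ in range(max_iter):
        ll = 0.0
        sum_x = np.zeros(p)
        sum_xx = np.zeros((p, p))
        for pat in pats:
            o = pat.idx
            m = np.setdiff1d(np.arange(p), o, assume_unique=True)
            Soo = sigma[np.ix_(o, o)]
            try:
                inv = np.linalg.inv(Soo)
            except np.linalg.LinAlgError:
                inv = np.linalg.pinv(Soo)
            d = pat.mean - mu[o]
            sign, logdet = np.linalg.slogdet(Soo)
            ll += -0.5 * pat.n * (
                o.size * np.log(2 * np.pi) + logdet
                + float(np.sum(inv * pat.scatter)) + d @ inv @ d
            )
            # expected sufficient statistics
            Exo = np.zeros((p,))
            Exo[o] = pat.mean
            C = np.zeros((p, p))
            C[np.ix_(o, o)] = pat.scatter + np.outer(pat.mean, pat.mean)
            if m.size:
                Smo = sigma[np.ix_(m, o)]
                B = Smo @ inv
                mm = mu[m] + B @ d
                Exo[m] = mm
                cond = sigma[np.ix_(m, m)] - B @ Smo.T
                # E[x_m x_o'] and E[x_m x_m'] given observed-pattern stats
                cross = np.outer(mm, pat.mean) + B @ pat.scatter
                C[np.ix_(m, o)] = cross
                C[np.ix_(o, m)] = cross.T
                C[np.ix_(m, m)] = (
                    cond + np.outer(mm, mm)
                    + B @ pat.scatter @ B.T
                )
            sum_x += pat.n * Exo
            sum_xx += pat.n * C
        mu = sum_x / n
        sigma = sum_xx / n - np.outer(mu, mu)
        sigma = 0.5 * (sigma + sigma.T)
        if abs(ll - last) < tol * (1 + abs(ll)):
            break
        last = ll
    return mu, sigma, ll
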