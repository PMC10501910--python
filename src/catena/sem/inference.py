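"""Nested-model tests, fit indices, invariance ladder, standardization."""

from __future__ import annotations

import re
from dataclasses import dataclass, replace

import numpy as np
from scipy.stats import chi2 as chi2_dist

from .fit import FitResult, count_sample_moments, fit_model, fit_saturated
from .likelihood import ObservedDataset, loglik_and_grad
from .model import Entry, ModelError, ModelSpec
from .moments import group_moments

ALPHA = 0.05
TREND = 0.1


class NestingError(ValueError):
    pass


def format_p(p: float) -> str:
    return "< 0.001" if p < 0.001 else f"{p:.3f}"


def verdict(p: float) -> str:
    if p <= ALPHA:
        return "significant"
    if p <= TREND:
        return "trend"
    return "ns"


@dataclass
class LRTResult:
    delta_chi2: float
    delta_df: int
    p: float
    constrained_labels: list[str]

    @property
    def significant(self) -> bool:
        return self.p <= ALPHA

    @property
    def verdict(self) -> str:
        return verdict(self.p)

    def to_dict(self) -> dict:
        return {
            "delta_chi2": self.delta_chi2,
            "delta_df": self.delta_df,
            "p": self.p,
            "p_display": format_p(self.p),
            "verdict": self.verdict,
            "constrained_labels": self.constrained_labels,
        }


def likelihood_ratio_test(
    fit_free: FitResult, fit_constrained: FitResult, labels: list[str] | None = None
) -> LRTResult:
    """Chi-square difference test of two nested FIML fits."""
    fit_free.require_converged()
    fit_constrained.require_converged()
    ddf = fit_constrained.df - fit_free.df
    if ddf < 1:
        raise NestingError(
            f"constrained model must have larger df (got Δdf = {ddf})"
        )
    delta = 2.0 * (fit_free.loglik - fit_constrained.loglik)
    if delta < -1e-4:
        raise NestingError(
            f"constrained log-likelihood exceeds free log-likelihood by {-delta/2:.2e}; "
            "models are not nested or the free fit is at a worse optimum"
        )
    delta = max(delta, 0.0)
    p = float(chi2_dist.sf(delta, ddf)) if delta > 0 else 1.0
    return LRTResult(delta, ddf, p, labels or [])


@dataclass
class FitIndices:
    chi_square: float
    df: int
    p: float
    rmsea: float
    cfi: float
    note: str = ""

    def to_dict(self) -> dict:
        return {
            "chi_square": self.chi_square,
            "df": self.df,
            "p": self.p,
            "p_display": format_p(self.p),
            "rmsea": self.rmsea,
            "cfi": self.cfi,
            "note": self.note,
        }


def _baseline_loglik_and_df(data: ObservedDataset) -> tuple[float, int]:
    """Independence model (free means/variances, zero covariances).

    With a diagonal covariance the FIML likelihood factorises per
    variable, so the MLE is the available-case mean and variance.
    """
    ll = 0.0
    p = len(data.variables)
    for g in data.groups:
        rows = data.data[data.group_labels == g]
        for j in range(p):
            col = rows[:, j]
            col = col[~np.isnan(col)]
            if col.size == 0:
                continue
            v = max(float(np.var(col)), 1e-12)
            ll += -0.5 * col.size * (np.log(2 * np.pi * v) + 1.0)
    n_moments = len(data.groups) * (p + p * (p + 1) // 2)
    df = n_moments - len(data.groups) * 2 * p
    return ll, df


def fit_indices(fit: FitResult, data: ObservedDataset) -> FitIndices:
    """Chi-square against the FIML-estimated saturated model, RMSEA, CFI."""
    fit.require_converged()
    data = data.reorder(fit.spec.observed)
    sat = fit_saturated(data)
    if not np.isfinite(sat.loglik):
        from .likelihood import DataError

        raise DataError(
            "saturated model is degenerate (fewer cases than variables in "
            "some group?); fit indices are undefined"
        )
    chi2 = 2.0 * (sat.loglik - fit.loglik)
    if chi2 < -1e-6:
        raise NestingError(
            f"model log-likelihood exceeds saturated log-likelihood by {-chi2/2:.2e}"
        )
    chi2 = max(chi2, 0.0)
    if chi2 < 1e-6:  # numerical zero per the chi-square invariant tolerance
        chi2 = 0.0
    df = fit.df
    note = ""
    if df == 0:
        p = 1.0
        rmsea = 0.0
        note = "saturated (df = 0); RMSEA reported as 0"
    else:
        p = float(chi2_dist.sf(chi2, df))
        n_total = fit.n_total
        g = fit.n_groups
        rmsea = float(np.sqrt(g) * np.sqrt(max(chi2 - df, 0.0) / (df * n_total)))
    ll_b, df_b = _baseline_loglik_and_df(data)
    chi2_b = max(2.0 * (sat.loglik - ll_b), 0.0)
    denom = max(chi2_b - df_b, chi2 - df, 0.0)
    cfi = 1.0 if denom == 0 else 1.0 - max(chi2 - df, 0.0) / denom
    cfi = float(np.clip(cfi, 0.0, 1.0))
    return FitIndices(float(chi2), int(df), p, rmsea, cfi, note)


# -- measurement invariance ladder -------------------------------------------

_TP_SUFFIX = re.compile(r"_tp\d+$")


def _tie_across_groups(spec: ModelSpec, kinds: tuple[str, ...]) -> ModelSpec:
    """Share each free measurement parameter of the given kinds across groups."""
    out = spec.copy()
    new_entries = []
    for e in out.entries:
        if e.free and e.kind in kinds and e.lhs in spec.observed:
            label = f"eq.{e.kind}.{e.lhs}" + (f".{e.rhs}" if e.rhs else "")
            e = replace(e, label=label)
        new_entries.append(e)
    out.entries = new_entries
    return out


def _tie_across_time(spec: ModelSpec, kinds: tuple[str, ...]) -> ModelSpec:
    """Share parameters across timepoint-suffixed variables (``*_tp<k>``)."""
    out = spec.copy()
    new_entries = []
    for e in out.entries:
        if e.free and e.kind in kinds and e.lhs in spec.observed:
            base_l = _TP_SUFFIX.sub("", e.lhs)
            base_r = _TP_SUFFIX.sub("", e.rhs) if e.rhs else ""
            label = f"eqt.{e.kind}.{base_l}" + (f".{base_r}" if base_r else "")
            e = replace(e, label=label)
        new_entries.append(e)
    out.entries = new_entries
    return out


def _free_latent_means(spec: ModelSpec) -> ModelSpec:
    """Free exogenous-latent means in all but the reference group."""
    out = spec.copy()
    endogenous = {
        e.lhs for e in spec.entries if e.kind == "regression"
    }
    has_mean = {(e.lhs, e.group) for e in spec.entries if e.kind == "mean"}
    for lv in spec.latent:
        if lv in endogenous:
            continue
        for g in spec.groups[1:]:
            if (lv, g) in has_mean or (lv, None) in has_mean:
                continue
            out.entries.append(Entry("mean", lv, free=True, group=g))
    return out


LADDER_STEPS = ("configural", "weak", "strong", "strict")


def invariance_ladder(
    spec: ModelSpec,
    data: ObservedDataset,
    grouping: str = "groups",
    steps: tuple[str, ...] = LADDER_STEPS,
    **fit_kw,
):
    """Configural → weak → strong → strict sequence of constrained fits.

    Each step is compared to the previous one with a likelihood-ratio
    test.  Returns a list of (step name, FitResult, LRTResult | None).
    """
    if grouping == "groups":
        if len(spec.groups) < 2:
            raise ModelError("invariance ladder requires at least two groups")
        tie = _tie_across_groups
    elif grouping == "timepoints":
        tie = _tie_across_time
    else:
        raise ModelError(f"unknown grouping {grouping!r}")

    ladder = []
    previous = None
    for step in steps:
        if step == "configural":
            mspec = spec
        elif step == "weak":
            mspec = tie(spec, ("loading",))
        elif step == "strong":
            mspec = tie(spec, ("loading", "mean"))
            if grouping == "groups":
                mspec = _free_latent_means(mspec)
        elif step == "strict":
            mspec = tie(spec, ("loading", "mean", "variance"))
            if grouping == "groups":
                mspec = _free_latent_means(mspec)
        else:
            raise ModelError(f"unknown ladder step {step!r}")
        fit = fit_model(mspec, data, **fit_kw)
        lrt = None
        if previous is not None:
            lrt = likelihood_ratio_test(previous, fit, labels=[step])
        ladder.append((step, fit, lrt))
        previous = fit
    return ladder


# -- standardized solution ----------------------------------------------------


class StandardizationError(ValueError):
    pass


@dataclass
class StandardizedSolution:
    by_group: dict[str, dict[str, float]]

    def value(self, label: str, group: str | None = None) -> float:
        g = group or next(iter(self.by_group))
        return self.by_group[g][label]

    def to_dict(self) -> dict:
        return {"by_group": self.by_group}


def standardize(fit: FitResult) -> StandardizedSolution:
    """Correlations and standardized regression weights.

    Covariances are divided by the product of model-implied standard
    deviations of the two variables; regression weights and loadings are
    rescaled by sd(predictor) / sd(outcome).
    """
    fit.require_converged()
    spec = fit.spec
    table = spec.parameter_table()
    theta = np.array([fit.estimates[lab] for lab in table.labels])
    by_group: dict[str, dict[str, float]] = {}
    for gi, (g, (mu, sigma, B, mats)) in enumerate(
        zip(spec.groups, group_moments(table, theta))
    ):
        Cfull = B @ mats["S"] @ B.T
        sd = np.sqrt(np.clip(np.diag(Cfull), 0.0, None))
        vals: dict[str, float] = {}
        idx = table.var_index
        for e in spec._group_entries(g):
            if not e.free or e.kind == "mean":
                continue
            label = e.label or table._auto_label(e, g)
            i, j = idx[e.lhs], idx[e.rhs]
            if sd[i] == 0 or (e.kind != "mean" and sd[j] == 0):
                raise StandardizationError(
                    f"zero model-implied variance for "
                    f"{e.lhs if sd[i] == 0 else e.rhs!r}"
                )
            if e.kind in ("covariance",):
                vals[label] = float(mats["S"][i, j] / (sd[i] * sd[j]))
            elif e.kind == "variance":
                vals[label] = float(mats["S"][i, i] / Cfull[i, i])
            else:  # loading / regression: lhs ~ rhs, beta * sd(rhs)/sd(lhs)
                vals[label] = float(mats["A"][i, j] * sd[j] / sd[i])
        by_group[g] = vals
    return StandardizedSolution(by_group)
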