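"""Logistic excess-odds-ratio (EOR) prevalence model.

The odds of being a prevalent case for subject *i* are

    odds_i = exp(beta0 + beta_age[cat(a_i)] + beta_sex * male_i) * (1 + EOR_i)

with the excess odds ratio modelled as a linear or linear-exponential
function of thyroid dose D (Gy), optionally modified by age at exposure
``e``, age at screening ``a``, time since exposure ``a - e`` or sex:

    form 1: EOR = alpha * D
    form 2: EOR = alpha * D * exp(gamma * D)
    form 3: EOR = alpha * D * exp(gamma * D + kappa * (e - 8))
    form 4: EOR = alpha * D * exp(gamma * D + tau * (a - 22))
    form 5: EOR = alpha * D * exp(gamma * D + psi * (a - e - 14))
    form 6: EOR = alpha * D * exp(gamma * D + eta * 1{male})

Ages are centred at 8 (exposure) and 22 (screening) years, the approximate
cohort means, which also makes forms 2-6 nest cleanly.  All parameters are
estimated by maximum likelihood; confidence intervals are profile-likelihood
based and hypothesis tests are likelihood-ratio tests.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

logger = logging.getLogger(__name__)

AGE_EXPOSURE_CENTER = 8.0
AGE_SCREEN_CENTER = 22.0
TIME_SINCE_CENTER = 14.0

# modifier parameters that multiply inside the exponential, per form
_FORM_EXTRAS: dict[str, tuple[str, ...]] = {
    "null": (),
    "linear": (),
    "linexp": ("gamma",),
    "linexp_agex": ("gamma", "kappa"),
    "linexp_agescr": ("gamma", "tau"),
    "linexp_tse": ("gamma", "psi"),
    "linexp_sex": ("gamma", "eta"),
}
_FORM_BY_NUMBER = {
    1: "linear",
    2: "linexp",
    3: "linexp_agex",
    4: "linexp_agescr",
    5: "linexp_tse",
    6: "linexp_sex",
}

_FEAS_FLOOR = 1e-10  # 1 + EOR must stay above this during optimisation
_PENALTY = 1e10


class ModelViolationError(ValueError):
    """Raised when 1 + EOR <= 0 at the requested parameter values."""


def canonical_form(form: int | str) -> str:
    """Resolve a form given by number (1-6) or name to its canonical name."""
    if isinstance(form, (int, np.integer)):
        try:
            return _FORM_BY_NUMBER[int(form)]
        except KeyError:
            raise ValueError(f"unknown EOR form number {form}") from None
    if form not in _FORM_EXTRAS:
        raise ValueError(f"unknown EOR form {form!r}")
    return form


def form_parameters(form: int | str) -> tuple[str, ...]:
    """Names of the free dose-response parameters of a form."""
    name = canonical_form(form)
    if name == "null":
        return ()
    return ("alpha",) + _FORM_EXTRAS[name]


@dataclass
class RiskParams:
    """Parameters of the EOR-logistic prevalence model.

    ``beta_age`` holds log-odds offsets for age-at-screening categories
    1..k relative to the reference category 0; categories are defined by
    the interior ``age_edges`` via ``searchsorted``.
    """

    beta0: float = 0.0
    beta_age: tuple[float, ...] = ()
    age_edges: tuple[float, ...] = ()
    beta_sex: float = 0.0  # male offset on baseline log-odds
    alpha: float = 0.0  # linear EOR slope, Gy^-1
    gamma: float = 0.0  # exponential curvature, Gy^-1
    kappa: float = 0.0  # age-at-exposure modifier, years^-1
    tau: float = 0.0  # age-at-screening modifier, years^-1
    psi: float = 0.0  # time-since-exposure modifier, years^-1
    eta: float = 0.0  # male modifier of the EOR

    def age_category(self, a):
        return np.searchsorted(np.asarray(self.age_edges), np.asarray(a), side="right")

    def baseline_logodds(self, a, male):
        a = np.asarray(a, dtype=float)
        male = np.asarray(male)
        out = np.full(np.broadcast(a, male).shape, self.beta0, dtype=float)
        if len(self.age_edges):
            coefs = np.concatenate([[0.0], np.asarray(self.beta_age, dtype=float)])
            out = out + coefs[self.age_category(a)]
        out = out + self.beta_sex * male.astype(float)
        return out


def _modifier_covariates(form: str, D, e, a, male) -> list[np.ndarray]:
    """Covariates multiplying the extra parameters inside exp(...)."""
    cols = {
        "gamma": lambda: np.asarray(D, dtype=float),
        "kappa": lambda: np.asarray(e, dtype=float) - AGE_EXPOSURE_CENTER,
        "tau": lambda: np.asarray(a, dtype=float) - AGE_SCREEN_CENTER,
        "psi": lambda: np.asarray(a, dtype=float)
        - np.asarray(e, dtype=float)
        - TIME_SINCE_CENTER,
        "eta": lambda: np.asarray(male, dtype=float),
    }
    return [cols[name]() for name in _FORM_EXTRAS[form]]


def excess_odds_ratio(D, e=None, a=None, male=None, params: RiskParams | None = None,
                      form: int | str = "linear"):
    """Evaluate EOR(D) for the given form; EOR(0) = 0 for every form."""
    form = canonical_form(form)
    D = np.asarray(D, dtype=float)
    if form == "null":
        return np.zeros_like(D)
    if np.any(D < 0):
        raise ValueError("dose must be non-negative")
    mod = np.zeros_like(D)
    for name, z in zip(_FORM_EXTRAS[form], _modifier_covariates(form, D, e, a, male)):
        mod = mod + getattr(params, name) * z
    return params.alpha * D * np.exp(mod)


def prevalence_prob(D, e, a, male, params: RiskParams, form: int | str = "linear"):
    """Probability of being a prevalent case under the EOR-logistic model."""
    eor = excess_odds_ratio(D, e, a, male, params, form)
    total = 1.0 + eor
    if np.any(total <= 0):
        raise ModelViolationError("1 + EOR <= 0 for at least one subject")
    logodds = params.baseline_logodds(a, male) + np.log(total)
    return special.expit(logodds)


def log_likelihood(y, p) -> float:
    """Bernoulli log-likelihood sum y*ln p + (1-y)*ln(1-p)."""
    y = np.asarray(y, dtype=float)
    p = np.asarray(p, dtype=float)
    if y.shape != p.shape:
        raise ValueError("case-status and probability vectors differ in length")
    return float(np.sum(y * np.log(p) + (1.0 - y) * np.log1p(-p)))


# ---------------------------------------------------------------------------
# ML fitting machinery
# ---------------------------------------------------------------------------

@dataclass
class ModelData:
    """Design matrices for fitting: baseline X, dose D, modifier columns Z."""

    X: np.ndarray  # n x nb baseline design (intercept, age dummies, sex, extras)
    y: np.ndarray
    D: np.ndarray
    Z: np.ndarray  # n x nextras modifier covariates
    form: str
    baseline_names: tuple[str, ...]
    age_edges: tuple[float, ...]

    @property
    def param_names(self) -> tuple[str, ...]:
        dose = () if self.form == "null" else ("alpha",) + _FORM_EXTRAS[self.form]
        return self.baseline_names + dose

    @property
    def n_baseline(self) -> int:
        return self.X.shape[1]


def build_model_data(cohort: pd.DataFrame, doses, form: int | str,
                     n_age_categories: int = 5,
                     age_edges: tuple[float, ...] | None = None,
                     extra_baseline: tuple[str, ...] = ()) -> ModelData:
    """Assemble design matrices from a cohort table and a dose vector.

    The baseline always contains an intercept, categorical age-at-screening
    (quantile bins unless explicit interior edges are given) and a male
    indicator; ``extra_baseline`` names additional cohort columns entered
    linearly (background-covariate sensitivity analyses).
    """
    form = canonical_form(form)
    D = np.asarray(doses, dtype=float)
    if len(D) != len(cohort):
        raise ValueError("doses not aligned with cohort")
    y = cohort["y"].to_numpy(dtype=float)
    a = cohort["a"].to_numpy(dtype=float)
    e = cohort["e"].to_numpy(dtype=float)
    male = (cohort["sex"].to_numpy() == "male").astype(float)
    if form != "null" and np.all(D == 0):
        raise ValueError("all doses are zero: dose-response parameters unidentifiable")

    if age_edges is None:
        qs = np.quantile(a, np.linspace(0, 1, n_age_categories + 1)[1:-1])
        age_edges = tuple(np.unique(qs))
    cat = np.searchsorted(np.asarray(age_edges), a, side="right")
    ncat = len(age_edges) + 1
    cols = [np.ones_like(a)]
    names = ["beta0"]
    for j in range(1, ncat):
        cols.append((cat == j).astype(float))
        names.append(f"beta_age{j}")
    cols.append(male)
    names.append("beta_sex")
    for name in extra_baseline:
        cols.append(cohort[name].to_numpy(dtype=float))
        names.append(f"beta_{name}")
    X = np.column_stack(cols)
    Z = (np.column_stack(_modifier_covariates(form, D, e, a, male))
         if _FORM_EXTRAS[form] else np.empty((len(D), 0)))
    return ModelData(X=X, y=y, D=D, Z=Z, form=form,
                     baseline_names=tuple(names), age_edges=tuple(age_edges))


def _nll_grad(theta: np.ndarray, data: ModelData, free: np.ndarray,
              fixed_full: np.ndarray):
    """Penalised negative log-likelihood and gradient w.r.t. free params."""
    full = fixed_full.copy()
    full[free] = theta
    nb = data.n_baseline
    beta = full[:nb]
    b = data.X @ beta
    if data.form == "null":
        eta = b
        ll = data.y @ eta - np.sum(np.logaddexp(0.0, eta))
        resid = data.y - special.expit(eta)
        grad = np.concatenate([data.X.T @ resid])
        return -ll, -grad[free]

    alpha = full[nb]
    extras = full[nb + 1:]
    mod = data.Z @ extras if extras.size else np.zeros_like(data.D)
    np.clip(mod, -60.0, 60.0, out=mod)
    u = data.D * np.exp(mod)
    eor = alpha * u
    R = 1.0 + eor
    bad = R <= _FEAS_FLOOR
    if np.any(bad):
        # smooth penalty pushing back into the feasible region
        viol = np.where(bad, _FEAS_FLOOR - R, 0.0)
        val = _PENALTY * (1.0 + viol.sum())
        dR = np.zeros(full.size)
        dR[nb] = -np.sum(np.where(bad, u, 0.0))
        if extras.size:
            dR[nb + 1:] = -(data.Z.T @ np.where(bad, eor, 0.0))
        return val, (_PENALTY * dR)[free]

    eta = b + np.log(R)
    ll = data.y @ eta - np.sum(np.logaddexp(0.0, eta))
    resid = data.y - special.expit(eta)
    grad = np.empty(full.size)
    grad[:nb] = data.X.T @ resid
    w = resid / R
    grad[nb] = w @ u
    if extras.size:
        grad[nb + 1:] = data.Z.T @ (w * eor)
    return -ll, -grad[free]


@dataclass
class FitResult:
    """Maximum-likelihood fit of one EOR form on one dose treatment."""

    form: str
    param_names: tuple[str, ...]
    estimates: dict[str, float]
    loglik: float
    converged: bool
    grad_norm: float
    n: int
    cases: int
    age_edges: tuple[float, ...]
    profile_cis: dict[str, tuple[float, float]] = field(default_factory=dict)
    ci_flags: dict[str, str] = field(default_factory=dict)
    theta: np.ndarray = field(default=None, repr=False)
    data: ModelData = field(default=None, repr=False)

    @property
    def n_free(self) -> int:
        return len(self.param_names)

    def __getitem__(self, name: str) -> float:
        return self.estimates[name]


def _optimize(data: ModelData, start: np.ndarray, free: np.ndarray,
              fixed_full: np.ndarray, maxiter: int = 500):
    res = optimize.minimize(
        _nll_grad, start[free], args=(data, free, fixed_full), jac=True,
        method="L-BFGS-B", options={"maxiter": maxiter, "ftol": 1e-12, "gtol": 1e-8},
    )
    full = fixed_full.copy()
    full[free] = res.x
    return -res.fun, full, res


def fit_ml(cohort: pd.DataFrame, doses, form: int | str = "linear", *,
           n_age_categories: int = 5, age_edges=None, extra_baseline=(),
           fixed: dict[str, float] | None = None, start: dict[str, float] | None = None,
           n_starts: int = 5, seed: int = 0, data: ModelData | None = None) -> FitResult:
    """Fit the EOR-logistic model by maximum likelihood with multi-starts.

    ``fixed`` pins named parameters (used by the profiler); ``start`` seeds
    the first optimisation start.  Additional random starts perturb the
    dose-response parameters to guard against the non-convexity of the
    linear-exponential forms.
    """
    if data is None:
        data = build_model_data(cohort, doses, form,
                                n_age_categories=n_age_categories,
                                age_edges=age_edges, extra_baseline=extra_baseline)
    y = data.y
    ncase = int(y.sum())
    if ncase == 0 or ncase == len(y):
        raise ValueError("need at least one case and one non-case")

    names = list(data.param_names)
    npar = len(names)
    fixed = dict(fixed or {})
    free = np.array([nm not in fixed for nm in names])
    fixed_full = np.zeros(npar)
    for nm, v in fixed.items():
        fixed_full[names.index(nm)] = v

    p0 = np.clip(ncase / len(y), 1e-6, 1 - 1e-6)
    # typical dose magnitude: makes starts (and hence the fit) equivariant
    # under a rescaling of the dose axis
    pos = data.D[data.D > 0]
    dscale = float(pos.mean()) if pos.size else 1.0
    base = np.zeros(npar)
    base[0] = special.logit(p0)
    if "alpha" in names and "alpha" not in fixed:
        base[names.index("alpha")] = 1.0 / dscale
    if start:
        for nm, v in start.items():
            base[names.index(nm)] = v

    rng = np.random.default_rng(seed)
    starts = [base]
    has_dose = data.form != "null" and "alpha" not in fixed
    for _ in range(n_starts - 1):
        s = base.copy()
        if has_dose:
            ia = names.index("alpha")
            s[ia] = np.exp(rng.normal(np.log(max(abs(base[ia]), 1.0 / dscale)), 1.0))
        for extra in _FORM_EXTRAS[data.form]:
            if extra in names and extra not in fixed:
                # gamma multiplies dose, so its natural scale is 1/dscale
                sd = 0.05 / dscale if extra == "gamma" else 0.05
                s[names.index(extra)] += rng.normal(0.0, sd)
        starts.append(s)

    best = None
    for s in starts:
        ll, full, res = _optimize(data, s, free, fixed_full)
        if best is None or ll > best[0]:
            best = (ll, full, res)
    ll, full, res = best
    # polish from the best point
    ll2, full2, res2 = _optimize(data, full, free, fixed_full)
    if ll2 > ll:
        ll, full, res = ll2, full2, res2

    _, g = _nll_grad(full[free], data, free, fixed_full)
    gnorm = float(np.linalg.norm(g, np.inf))
    converged = gnorm < 1e-3 * (1.0 + abs(ll))
    if not converged:
        logger.warning("fit_ml: gradient norm %.3g at reported optimum (form=%s)",
                       gnorm, data.form)
    estimates = dict(zip(names, full))
    return FitResult(form=data.form, param_names=tuple(n for n in names if n not in fixed),
                     estimates=estimates, loglik=ll, converged=converged,
                     grad_norm=gnorm, n=len(y), cases=ncase,
                     age_edges=data.age_edges, theta=full, data=data)


def _profile_ll(fit: FitResult, param: str, value: float,
                warm: np.ndarray | None = None) -> tuple[float, np.ndarray]:
    """Log-likelihood maximised over all parameters except ``param``."""
    data = fit.data
    names = list(data.param_names)
    npar = len(names)
    idx = names.index(param)
    free = np.ones(npar, dtype=bool)
    free[idx] = False
    fixed_full = np.zeros(npar)
    fixed_full[idx] = value
    start = (warm if warm is not None else fit.theta).copy()
    start[idx] = value
    ll, full, _ = _optimize(data, start, free, fixed_full)
    return ll, full


def profile_ci(fit: FitResult, param: str, level: float = 0.95,
               max_expand: int = 60) -> tuple[float, float]:
    """Profile-likelihood confidence interval for one parameter.

    Endpoints are where the profile log-likelihood drops by
    chi2_1(level)/2 (1.9207 at 95%) below the maximum.  Bounds that run
    into the feasibility boundary (1 + EOR -> 0) or fail to drop within
    the search range are flagged in ``fit.ci_flags``.
    """
    if level <= 0:
        return (fit.estimates[param], fit.estimates[param])
    drop = stats.chi2.ppf(level, 1) / 2.0
    target = fit.loglik - drop
    est = fit.estimates[param]
    step0 = max(0.25 * abs(est), 0.1)
    flags = []

    def search(direction: int) -> float:
        step = step0
        prev = est
        warm = fit.theta
        for _ in range(max_expand):
            cand = est + direction * step
            ll, warm = _profile_ll(fit, param, cand, warm)
            if ll < target:
                try:
                    root = optimize.brentq(
                        lambda v: _profile_ll(fit, param, v, warm)[0] - target,
                        min(prev, cand), max(prev, cand), xtol=1e-6 * (1 + abs(est)))
                except ValueError:
                    root = cand
                return root
            if ll <= -0.5 * _PENALTY:  # hit the feasibility boundary
                flags.append(f"{'lower' if direction < 0 else 'upper'}:boundary")
                return cand
            prev = cand
            step *= 2.0
        flags.append(f"{'lower' if direction < 0 else 'upper'}:open")
        return est + direction * step

    lo = search(-1)
    hi = search(+1)
    fit.profile_cis[param] = (lo, hi)
    if flags:
        fit.ci_flags[param] = ";".join(flags)
    return lo, hi


def lrt(fit_nested: FitResult, fit_full: FitResult) -> tuple[float, int, float]:
    """Likelihood-ratio test of a nested form against a richer one."""
    nested_names = set(fit_nested.param_names)
    full_names = set(fit_full.param_names)
    if not nested_names <= full_names:
        raise ValueError(f"{fit_nested.form} is not nested in {fit_full.form}")
    if fit_nested.n != fit_full.n or fit_nested.cases != fit_full.cases:
        raise ValueError("fits are not on the same cohort")
    df = len(full_names) - len(nested_names)
    statistic = max(0.0, 2.0 * (fit_full.loglik - fit_nested.loglik))
    p = float(stats.chi2.sf(statistic, df)) if df > 0 else 1.0
    return statistic, df, p
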