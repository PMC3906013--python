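"""Lognormal latent-variable fits and regression-calibration doses.

Measured doses (or activities) are modelled per stratum as

    ln V_i ~ Normal(mu_X[stratum(i)], sigma_X[stratum(i)]^2 + sigma_eps_i^2)

where sigma_eps_i = ln(GSD_i) is the subject's classical (instrument) error
log-SD and (mu_X, sigma_X) describe the latent lognormal distribution of the
true quantity.  (mu_X, sigma_X) are estimated by maximum likelihood per
stratum; this is a deconvolution, so sigma_X^2 is floored at zero.

Regression calibration replaces each measured dose with the conditional
expectation of the true dose given the measurements:

* method 1 (dose scale): the latent log dose given assigned mass has the
  conjugate Normal shrinkage posterior

      mu_c    = (sigma_eps^2 mu_X + sigma_X^2 ln D_mes) / (sigma_X^2 + sigma_eps^2)
      sigma_c^2 = sigma_X^2 sigma_eps^2 / (sigma_X^2 + sigma_eps^2)

  and E[D_true | D_mes] = exp(mu_c + sigma_c^2/2) * exp(sigma_delta^2/2),
  the last factor being the Berkson mass term E[1/delta] with
  delta = M_true / M_assigned ~ LogNormal(0, sigma_delta^2);

* method 2 (activity scale): assuming true activity independent of the
  assigned mass, E[D | A_mes, M_mes] = c * E[A | A_mes] * exp(sigma_delta^2/2)
  / M_mes with the same shrinkage form applied to ln A_mes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

logger = logging.getLogger(__name__)

DOSE_BINS: tuple[float, ...] = (0.0, 0.5, 1.0, 5.0, 10.0, np.inf)


@dataclass
class ErrorModelParams:
    """Per-stratum lognormal latent parameters on the dose or activity scale."""

    target: str  # "dose" or "activity"
    mu: dict[str, float]
    sigma: dict[str, float]
    loglik: float = np.nan
    pooled_strata: tuple[str, ...] = ()

    def lookup(self, strata) -> tuple[np.ndarray, np.ndarray]:
        strata = np.asarray(strata)
        mu = np.array([self.mu[s] for s in strata])
        sigma = np.array([self.sigma[s] for s in strata])
        return mu, sigma


def fit_latent_lognormal(values, sigma_eps, strata=None, target: str = "dose",
                         min_stratum: int = 10) -> ErrorModelParams:
    """ML fit of the stratum-wise latent lognormal model.

    Strata with fewer than ``min_stratum`` subjects fall back to pooled
    (all-subject) estimates with a logged warning.
    """
    values = np.asarray(values, dtype=float)
    if np.any(values <= 0):
        raise ValueError("measured values must be positive")
    sigma_eps = np.broadcast_to(np.asarray(sigma_eps, dtype=float), values.shape)
    if np.any(sigma_eps < 0):
        raise ValueError("classical log-SDs must be non-negative")
    if strata is None:
        strata = np.full(values.shape, "all")
    strata = np.asarray(strata)
    logv = np.log(values)

    def fit_group(lv, se):
        v2 = se ** 2

        def nll_grad(theta):
            mu, s = theta  # s = sigma_X^2
            var = s + v2
            r = lv - mu
            val = 0.5 * np.sum(np.log(2 * np.pi * var) + r ** 2 / var)
            gmu = -np.sum(r / var)
            gs = 0.5 * np.sum(1.0 / var - r ** 2 / var ** 2)
            return val, np.array([gmu, gs])

        start_s = max(float(np.var(lv) - np.mean(v2)), 1e-8)
        res = optimize.minimize(nll_grad, np.array([float(np.mean(lv)), start_s]),
                                jac=True, method="L-BFGS-B",
                                bounds=[(None, None), (0.0, None)],
                                options={"ftol": 1e-14, "gtol": 1e-10})
        mu, s = res.x
        if s <= 0:
            logger.warning("latent log-variance floored at 0 for a stratum")
        return float(mu), float(np.sqrt(max(s, 0.0))), -float(res.fun)

    mu_pool, sd_pool, _ = fit_group(logv, sigma_eps)
    mus, sds, pooled = {}, {}, []
    total_ll = 0.0
    for s in np.unique(strata):
        mask = strata == s
        if mask.sum() < min_stratum:
            logger.warning("stratum %r has %d subjects (<%d): using pooled estimates",
                           s, int(mask.sum()), min_stratum)
            mus[s], sds[s] = mu_pool, sd_pool
            pooled.append(str(s))
            var = sds[s] ** 2 + sigma_eps[mask] ** 2
            total_ll += -0.5 * float(np.sum(np.log(2 * np.pi * var)
                                            + (logv[mask] - mus[s]) ** 2 / var))
        else:
            mus[s], sds[s], ll = fit_group(logv[mask], sigma_eps[mask])
            total_ll += ll
    return ErrorModelParams(target=target, mu=mus, sigma=sds, loglik=total_ll,
                            pooled_strata=tuple(pooled))


def _shrinkage_mean(log_meas, mu_x, sigma_x, sigma_eps):
    """E[exp(X) | measurement] under the conjugate Normal shrinkage posterior."""
    s2 = sigma_x ** 2
    e2 = sigma_eps ** 2
    tot = s2 + e2
    with np.errstate(invalid="ignore", divide="ignore"):
        mu_c = np.where(tot > 0, (e2 * mu_x + s2 * log_meas) / np.where(tot > 0, tot, 1.0),
                        log_meas)
        var_c = np.where(tot > 0, s2 * e2 / np.where(tot > 0, tot, 1.0), 0.0)
    return np.exp(mu_c + 0.5 * var_c)


def expected_dose_rc1(D_mes, params: ErrorModelParams, sigma_eps, sigma_delta,
                      strata=None) -> np.ndarray:
    """Regression-calibration method 1: E[true dose | measured dose]."""
    if params.target != "dose":
        raise ValueError("method 1 requires parameters fitted on the dose scale")
    D_mes = np.asarray(D_mes, dtype=float)
    if np.any(D_mes <= 0):
        raise ValueError("measured dose must be positive")
    if strata is None:
        strata = np.full(D_mes.shape, next(iter(params.mu)))
    mu_x, sigma_x = params.lookup(strata)
    sigma_eps = np.broadcast_to(np.asarray(sigma_eps, dtype=float), D_mes.shape)
    sigma_delta = np.broadcast_to(np.asarray(sigma_delta, dtype=float), D_mes.shape)
    berkson = np.exp(0.5 * sigma_delta ** 2)  # E[1/delta]
    return _shrinkage_mean(np.log(D_mes), mu_x, sigma_x, sigma_eps) * berkson


def expected_dose_rc2(A_mes, M_mes, params: ErrorModelParams, sigma_eps, sigma_delta,
                      c: float = 1.0, strata=None) -> np.ndarray:
    """Regression-calibration method 2: c * E[A|A_mes] * E[1/M|M_mes].

    Relies on independence of true activity and assigned mass; the dose is
    linear in 1/M, so the Berkson mass factor is E[1/delta] = exp(sigma_delta^2/2).
    """
    if params.target != "activity":
        raise ValueError("method 2 requires parameters fitted on the activity scale")
    A_mes = np.asarray(A_mes, dtype=float)
    M_mes = np.asarray(M_mes, dtype=float)
    if np.any(A_mes <= 0) or np.any(M_mes <= 0):
        raise ValueError("measured activity and assigned mass must be positive")
    if strata is None:
        strata = np.full(A_mes.shape, next(iter(params.mu)))
    mu_x, sigma_x = params.lookup(strata)
    sigma_eps = np.broadcast_to(np.asarray(sigma_eps, dtype=float), A_mes.shape)
    sigma_delta = np.broadcast_to(np.asarray(sigma_delta, dtype=float), A_mes.shape)
    ea = _shrinkage_mean(np.log(A_mes), mu_x, sigma_x, sigma_eps)
    return c * ea * np.exp(0.5 * sigma_delta ** 2) / M_mes


@dataclass
class CalibratedDoses:
    """Per-subject conditional-expectation doses from one RC method."""

    method: str  # "RC1" or "RC2"
    doses: np.ndarray
    params: ErrorModelParams

    def __post_init__(self):
        if np.any(self.doses <= 0):
            raise ValueError("calibrated doses must be positive")


def calibrate_cohort(cohort: pd.DataFrame, c: float = 1.0,
                     min_stratum: int = 10) -> dict[str, CalibratedDoses]:
    """Fit both latent models on a cohort and return RC1 and RC2 doses."""
    strata = cohort["stratum"].to_numpy()
    se = np.log(cohort["gsd_A"].to_numpy(dtype=float))
    sd = np.log(cohort["gsd_M"].to_numpy(dtype=float))
    p_dose = fit_latent_lognormal(cohort["D_mes"], se, strata, target="dose",
                                  min_stratum=min_stratum)
    p_act = fit_latent_lognormal(cohort["A_mes"], se, strata, target="activity",
                                 min_stratum=min_stratum)
    rc1 = expected_dose_rc1(cohort["D_mes"], p_dose, se, sd, strata)
    rc2 = expected_dose_rc2(cohort["A_mes"], cohort["M_mes"], p_act, se, sd, c, strata)
    return {"RC1": CalibratedDoses("RC1", rc1, p_dose),
            "RC2": CalibratedDoses("RC2", rc2, p_act)}


def gsd_table(cohort: pd.DataFrame, dose_bins=DOSE_BINS) -> pd.DataFrame:
    """Summary of activity/mass error GSDs by measured-dose bin.

    Bins are half-open [lo, hi) partitioning (0, inf); the last row pools
    the whole cohort.  Empty bins yield NA statistics with a warning.
    """
    if len(cohort) == 0:
        raise ValueError("cohort is empty")
    edges = np.asarray(dose_bins, dtype=float)
    d = cohort["D_mes"].to_numpy(dtype=float)
    idx = np.clip(np.searchsorted(edges, d, side="right") - 1, 0, len(edges) - 2)
    rows = []
    labels = [f"{lo:g}-{hi:g}" if np.isfinite(hi) else f">{lo:g}"
              for lo, hi in zip(edges[:-1], edges[1:])] + ["total"]
    for k, label in enumerate(labels):
        sub = cohort if label == "total" else cohort[idx == k]
        row = {"dose_bin": label, "n": len(sub)}
        for col, tag in (("gsd_A", "activity"), ("gsd_M", "mass")):
            if len(sub) == 0:
                row.update({f"{tag}_{s}": np.nan for s in
                            ("min", "max", "mean", "median", "p10", "p90")})
                continue
            g = sub[col].to_numpy(dtype=float)
            row[f"{tag}_min"] = g.min()
            row[f"{tag}_max"] = g.max()
            row[f"{tag}_mean"] = g.mean()
            row[f"{tag}_median"] = float(np.median(g))
            row[f"{tag}_p10"] = float(np.percentile(g, 10))
            row[f"{tag}_p90"] = float(np.percentile(g, 90))
        if row["n"] == 0:
            logger.warning("empty dose bin %s in GSD table", label)
        rows.append(row)
    return pd.DataFrame(rows)


def lognormality_qq(doses) -> tuple[pd.DataFrame, float]:
    """QQ diagnostic of ln(dose) against the normal (Blom positions).

    Returns the ordered (theoretical, observed) pairs and their Pearson
    correlation; values near 1 indicate near-lognormal doses.
    """
    doses = np.asarray(doses, dtype=float)
    if doses.size < 3:
        raise ValueError("need at least 3 doses")
    if np.any(doses <= 0):
        raise ValueError("doses must be positive")
    ln = np.sort(np.log(doses))
    n = ln.size
    pos = (np.arange(1, n + 1) - 0.375) / (n + 0.25)
    theo = stats.norm.ppf(pos)
    r = float(np.corrcoef(theo, ln)[0, 1])
    return pd.DataFrame({"theoretical": theo, "observed": ln}), r
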