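"""Synthetic screening-cohort generator with mixed Berkson/classical dose error.

The generator reproduces the statistical structure the downstream analysis
assumes for a thyroid-screening prevalence cohort:

* each subject's thyroid mass is *assigned* from a population growth table
  (age x sex median), so the true mass scatters around the assignment --
  a multiplicative lognormal **Berkson** error;
* thyroid activity is *measured* by an instrument, so the measurement
  scatters around the true activity -- a multiplicative lognormal
  **classical** error with a per-subject geometric standard deviation (GSD);
* measured dose is ``D_mes = c * A_mes / M_assigned`` while the true dose is
  ``D_true = c * A_true / M_true``;
* prevalent case status is Bernoulli with probability given by the
  EOR-logistic risk model evaluated at the TRUE dose, with the baseline
  intercept calibrated so the expected case count matches a target
  (45 cases among 13,127 subjects by default).

Activity-error GSDs are drawn from a shifted truncated lognormal spanning
1.11-10.13 with overall mean ~1.35 and heavier values below 0.5 Gy;
mass-error GSDs from a left-skewed distribution on [1.28, 1.41] with mean
1.39 and median ~1.40.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .growth import DEFAULT_GROWTH_TABLE, MASS_FLOOR_G, assign_mass
from .risk import RiskParams, excess_odds_ratio, prevalence_prob

logger = logging.getLogger(__name__)

OBSERVED_COLUMNS = ["id", "e", "a", "sex", "stratum", "A_mes", "gsd_A",
                    "M_mes", "gsd_M", "D_mes", "y"]
LATENT_COLUMNS = ["A_true", "M_true", "D_true"]


@dataclass
class ActivityGsdSpec:
    """Per-subject activity-error GSD distribution (classical error size).

    ``gsd = offset + Z`` with Z shifted-lognormal truncated so that gsd
    stays in [lo, hi]; measurements at error-free dose below
    ``dose_threshold`` use the heavier low-dose parameters (instrument
    counting error grows at low activity).
    """

    constant: float | None = None
    offset: float = 1.10
    lo: float = 1.11
    hi: float = 10.13
    dose_threshold: float = 0.5
    low_dose: tuple[float, float] = (math.log(0.20), 0.85)
    high_dose: tuple[float, float] = (math.log(0.115), 0.45)


@dataclass
class MassGsdSpec:
    """Per-subject mass-error GSD distribution (Berkson error size).

    ``gsd = hi - (hi - lo) * Beta(a, b)``: range [lo, hi], mean
    ``hi - (hi-lo) * a/(a+b)`` = 1.39 and median ~1.40 at the defaults.
    """

    constant: float | None = None
    lo: float = 1.28
    hi: float = 1.41
    beta_a: float = 1.0
    beta_b: float = 5.5


def _default_risk() -> RiskParams:
    # linear-exponential truth with downward curvature; female excess in
    # baseline; beta0 is recalibrated to the target case count at run time
    return RiskParams(beta0=-6.0, beta_age=(0.3, 0.6), age_edges=(20.0, 24.0),
                      beta_sex=-0.7, alpha=9.0, gamma=-0.10)


@dataclass
class CohortConfig:
    """Study conditions for cohort simulation."""

    n: int = 13127
    oblasts: tuple[str, ...] = ("kyiv", "zhytomyr", "chernihiv")
    oblast_probs: tuple[float, ...] = (0.40, 0.32, 0.28)
    dose_median: dict[str, float] = field(
        default_factory=lambda: {"kyiv": 0.15, "zhytomyr": 0.20, "chernihiv": 0.30})
    log_dose_sigma: float = 1.4
    age_bands: tuple[tuple[float, float], ...] = ((0.0, 5.0), (5.0, 12.0), (12.0, 18.0))
    male_fraction: float = 0.5
    time_since_range: tuple[float, float] = (12.0, 14.0)
    growth_table: dict | None = None
    mass_floor: float = MASS_FLOOR_G
    activity_spec: dict[str, tuple[float, float]] | None = None
    c: float = 1.0  # Gy * g / kBq scaling of activity/mass ratio to dose
    gsd_activity: ActivityGsdSpec = field(default_factory=ActivityGsdSpec)
    gsd_mass: MassGsdSpec = field(default_factory=MassGsdSpec)
    risk: RiskParams = field(default_factory=_default_risk)
    risk_form: str = "linexp"
    target_cases: int | None = 45
    shared_error_logsd: float = 0.0
    n_missing: int = 0

    def __post_init__(self):
        if self.n < 1:
            raise ValueError("n must be >= 1")
        for spec in (self.gsd_activity, self.gsd_mass):
            if spec.constant is not None and spec.constant < 1:
                raise ValueError("GSDs must be >= 1")
        if self.gsd_activity.lo < 1 or self.gsd_mass.lo < 1:
            raise ValueError("GSD ranges must lie in [1, inf)")

    def stratum_label(self, oblast: str, band: tuple[float, float]) -> str:
        return f"{oblast}:{band[0]:g}-{band[1]:g}"

    def band_of(self, e: np.ndarray) -> np.ndarray:
        edges = np.array([b[0] for b in self.age_bands[1:]])
        return np.searchsorted(edges, e, side="right")

    def build_activity_spec(self) -> dict[str, tuple[float, float]]:
        """Per-stratum (log-mean, log-SD) of true activity, chosen so the
        implied error-free dose has the configured per-oblast median and
        log-SD (activity median = dose median x band-median mass)."""
        if self.activity_spec is not None:
            return self.activity_spec
        table = self.growth_table or DEFAULT_GROWTH_TABLE
        spec = {}
        for ob in self.oblasts:
            for band in self.age_bands:
                mid = 0.5 * (band[0] + band[1])
                m_mid = float(np.mean(assign_mass([mid, mid], ["male", "female"],
                                                  table, self.mass_floor)))
                mu_a = math.log(self.dose_median[ob] / self.c) + math.log(m_mid)
                spec[self.stratum_label(ob, band)] = (mu_a, self.log_dose_sigma)
        return spec

    @classmethod
    def simple(cls, n: int, *, dose_median: float = 0.2, log_dose_sigma: float = 1.2,
               gsd_a: float = 1.0, gsd_m: float = 1.0, alpha: float = 5.0,
               gamma: float = 0.0, target_cases: int | None = None,
               beta_sex: float = 0.0, risk_form: str | None = None) -> "CohortConfig":
        """Single-stratum, constant-mass, constant-GSD configuration.

        With one stratum and a constant assigned mass the lognormal latent
        models of both regression-calibration methods are exactly
        well-specified, which is the regime parameter-recovery studies use.
        """
        table = {s: {a: 10.0 for a in range(5, 17)} for s in ("male", "female")}
        form = risk_form if risk_form is not None else ("linexp" if gamma else "linear")
        return cls(
            n=n, oblasts=("all",), oblast_probs=(1.0,),
            dose_median={"all": dose_median}, log_dose_sigma=log_dose_sigma,
            age_bands=((0.0, 18.0),), growth_table=table,
            gsd_activity=ActivityGsdSpec(constant=gsd_a),
            gsd_mass=MassGsdSpec(constant=gsd_m),
            risk=RiskParams(beta0=-4.0, beta_sex=beta_sex, alpha=alpha, gamma=gamma),
            risk_form=form, target_cases=target_cases,
        )


# ---------------------------------------------------------------------------
# Component samplers
# ---------------------------------------------------------------------------

def sample_true_mass(assigned, gsd_m, rng) -> np.ndarray:
    """Berkson draw: true mass = assigned x LogNormal(0, ln gsd_m)."""
    assigned = np.asarray(assigned, dtype=float)
    gsd_m = np.asarray(gsd_m, dtype=float)
    if np.any(assigned <= 0):
        raise ValueError("assigned mass must be positive")
    if np.any(gsd_m < 1):
        raise ValueError("mass GSD must be >= 1")
    return assigned * np.exp(np.log(gsd_m) * rng.standard_normal(assigned.shape))


def sample_measured_activity(true_activity, gsd_a, rng) -> np.ndarray:
    """Classical draw: measured = true x LogNormal(0, ln gsd_a)."""
    true_activity = np.asarray(true_activity, dtype=float)
    gsd_a = np.asarray(gsd_a, dtype=float)
    if np.any(true_activity <= 0):
        raise ValueError("true activity must be positive")
    if np.any(gsd_a < 1):
        raise ValueError("activity GSD must be >= 1")
    return true_activity * np.exp(np.log(gsd_a) * rng.standard_normal(true_activity.shape))


def compute_dose(activity, mass, c: float = 1.0) -> np.ndarray:
    """Dose (Gy) = c x activity (kBq) / mass (g)."""
    activity = np.asarray(activity, dtype=float)
    mass = np.asarray(mass, dtype=float)
    if c <= 0:
        raise ValueError("scaling constant c must be positive")
    if np.any(mass <= 0):
        raise ValueError("mass must be positive")
    if np.any(activity <= 0):
        raise ValueError("activity must be positive")
    return c * activity / mass


def sample_case_status(D_true, e, a, male, params: RiskParams, form, rng) -> np.ndarray:
    """Bernoulli case status at the TRUE dose under the EOR-logistic model."""
    p = prevalence_prob(D_true, e, a, male, params, form)
    return (rng.uniform(size=np.shape(p)) < p).astype(np.int64)


def calibrate_intercept(D_true, e, a, male, params: RiskParams, form,
                        target_cases: float) -> RiskParams:
    """Solve for beta0 so the expected case count equals ``target_cases``."""

    def expected(beta0):
        p = prevalence_prob(D_true, e, a, male, replace(params, beta0=beta0), form)
        return float(np.sum(p)) - target_cases

    beta0 = optimize.brentq(expected, -30.0, 10.0, xtol=1e-10)
    return replace(params, beta0=beta0)


def _truncated_shifted_lognormal(rng, m, s, lo, hi, offset, size):
    """offset + LogNormal(m, s) truncated so the sum lies in [lo, hi]."""
    za = (math.log(max(lo - offset, 1e-300)) - m) / s
    zb = (math.log(hi - offset) - m) / s
    u = rng.uniform(stats.norm.cdf(za), stats.norm.cdf(zb), size)
    return offset + np.exp(m + s * stats.norm.ppf(u))


def _sample_gsd_activity(spec: ActivityGsdSpec, dose0: np.ndarray, rng) -> np.ndarray:
    if spec.constant is not None:
        return np.full(dose0.shape, float(spec.constant))
    low = dose0 < spec.dose_threshold
    out = np.empty_like(dose0)
    for mask, (m, s) in ((low, spec.low_dose), (~low, spec.high_dose)):
        k = int(mask.sum())
        if k:
            out[mask] = _truncated_shifted_lognormal(rng, m, s, spec.lo, spec.hi,
                                                     spec.offset, k)
    return out


def _sample_gsd_mass(spec: MassGsdSpec, n: int, rng) -> np.ndarray:
    if spec.constant is not None:
        return np.full(n, float(spec.constant))
    return spec.hi - (spec.hi - spec.lo) * rng.beta(spec.beta_a, spec.beta_b, n)


# ---------------------------------------------------------------------------
# Cohort generation and IO
# ---------------------------------------------------------------------------

def generate_cohort(config: CohortConfig, seed: int) -> pd.DataFrame:
    """Generate one cohort; truth columns (A_true, M_true, D_true) retained.

    The measured dose uses the ASSIGNED mass (Berkson), the true dose the
    true mass; case status is drawn at the true dose.  The calibrated
    baseline intercept is stored in ``df.attrs['risk_params']``.
    """
    rng = np.random.default_rng(seed)
    n = config.n

    oblast = rng.choice(np.array(config.oblasts), size=n, p=np.array(config.oblast_probs))
    e = 18.0 * rng.beta(1.6, 2.0, n)
    sex = np.where(rng.uniform(size=n) < config.male_fraction, "male", "female")
    a = e + rng.uniform(*config.time_since_range, size=n)
    band_idx = config.band_of(e)
    stratum = np.array([config.stratum_label(ob, config.age_bands[b])
                        for ob, b in zip(oblast, band_idx)])

    table = config.growth_table or DEFAULT_GROWTH_TABLE
    M_assigned = assign_mass(e, sex, table, config.mass_floor)
    gsd_M = _sample_gsd_mass(config.gsd_mass, n, rng)
    M_true = sample_true_mass(M_assigned, gsd_M, rng)

    spec = config.build_activity_spec()
    mu_a = np.array([spec[s][0] for s in stratum])
    sd_a = np.array([spec[s][1] for s in stratum])
    A_true = np.exp(mu_a + sd_a * rng.standard_normal(n))

    dose0 = compute_dose(A_true, M_assigned, config.c)  # error-free dose
    gsd_A = _sample_gsd_activity(config.gsd_activity, dose0, rng)
    A_mes = sample_measured_activity(A_true, gsd_A, rng)
    if config.shared_error_logsd > 0:
        strata = sorted(set(stratum))
        factors = dict(zip(strata, np.exp(
            config.shared_error_logsd * rng.standard_normal(len(strata)))))
        A_mes = A_mes * np.array([factors[s] for s in stratum])

    D_mes = compute_dose(A_mes, M_assigned, config.c)
    D_true = compute_dose(A_true, M_true, config.c)

    male = (sex == "male").astype(float)
    params = config.risk
    if config.target_cases is not None:
        params = calibrate_intercept(D_true, e, a, male, params, config.risk_form,
                                     config.target_cases)
    y = sample_case_status(D_true, e, a, male, params, config.risk_form, rng)

    df = pd.DataFrame({
        "id": np.arange(n), "e": e, "a": a, "sex": sex, "stratum": stratum,
        "A_mes": A_mes, "gsd_A": gsd_A, "M_mes": M_assigned, "gsd_M": gsd_M,
        "D_mes": D_mes, "y": y,
        "A_true": A_true, "M_true": M_true, "D_true": D_true,
    })
    if config.n_missing > 0:
        miss = rng.choice(n, size=config.n_missing, replace=False)
        df.loc[miss, "D_mes"] = np.nan
    df.attrs["risk_params"] = params
    df.attrs["risk_form"] = config.risk_form
    return df


def save_cohort(df: pd.DataFrame, path, observed_only: bool = False) -> None:
    cols = OBSERVED_COLUMNS if observed_only else OBSERVED_COLUMNS + [
        c for c in LATENT_COLUMNS if c in df.columns]
    # %.17g guarantees binary64 round-trips exactly through the CSV
    df[cols].to_csv(path, index=False, float_format="%.17g")


def load_cohort(path) -> pd.DataFrame:
    """Read a cohort CSV; subjects without a measured dose are dropped."""
    df = pd.read_csv(path, float_precision="round_trip")
    missing = df["D_mes"].isna()
    if missing.any():
        logger.info("dropping %d subjects with missing measured dose", int(missing.sum()))
        df = df[~missing].reset_index(drop=True)
    return df
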