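"""End-to-end orchestration: simulate -> calibrate -> fit/MCML -> report.

The report bundle mirrors the shape of a dose-error analysis write-up on
synthetic data: a GSD summary table, a fit-comparison table across the four
dose treatments (naive measured dose, the two regression-calibration
methods, MCML) x two EOR forms, a modifier-model table, dose-response curve
data with a profile-CI band, GSD-vs-dose scatter data, and a machine-
readable run log.  Plot *data* (CSV) is the contract; rendering is left to
the caller.  All artifacts carry the configuration hash and are
byte-reproducible for a fixed config and seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .calibration import calibrate_cohort, gsd_table, lognormality_qq
from .cohort import CohortConfig, generate_cohort, save_cohort
from .mcml import fit_mcml, profile_ci_mcml, sample_dose_posterior
from .risk import FitResult, fit_ml, lrt, profile_ci

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Reproducible pipeline run configuration."""

    seed: int = 0
    outdir: str = "thyrocal_out"
    cohort: CohortConfig = field(default_factory=CohortConfig)
    K: int = 1000  # posterior dose draws per subject for MCML
    ci_level: float = 0.95
    compute_cis: bool = True
    mcml_cis: bool = False  # profile CIs on the integrated likelihood are costly
    n_age_categories: int = 5

    def config_hash(self) -> str:
        payload = dataclasses.asdict(self)
        payload.pop("outdir")  # output location is not scientific configuration
        blob = json.dumps(_to_jsonable(payload), sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _to_jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer, np.bool_)):
        return obj.item()
    return obj


def compare_eor(fits: dict[str, FitResult], baseline: str = "naive") -> pd.DataFrame:
    """Percentage change of the linear EOR slope per method vs a baseline."""
    ref = fits[baseline]
    rows = []
    for method, fit in fits.items():
        if (fit.n, fit.cases) != (ref.n, ref.cases):
            raise ValueError("fits are not on the same cohort")
        rows.append({"method": method, "alpha": fit["alpha"],
                     "pct_change": 100.0 * (fit["alpha"] / ref["alpha"] - 1.0)})
    return pd.DataFrame(rows)


def _fit_row(fit: FitResult, treatment: str, form_label: str, p_value: float,
             ci_level: float, with_cis: bool, mcml_cohort=None) -> dict:
    row = {"dose_treatment": treatment, "form": form_label,
           "alpha": fit["alpha"], "loglik": fit.loglik, "p_improvement": p_value,
           "converged": fit.converged}
    if fit.form != "linear":
        row["gamma"] = fit.estimates.get("gamma", np.nan)
    params = ["alpha"] + (["gamma"] if fit.form != "linear" else [])
    for p in params:
        if with_cis:
            if mcml_cohort is not None:
                lo, hi = profile_ci_mcml(mcml_cohort, fit, p, ci_level)
            else:
                lo, hi = profile_ci(fit, p, ci_level)
            row[f"{p}_lo"], row[f"{p}_hi"] = lo, hi
        else:
            row[f"{p}_lo"] = row[f"{p}_hi"] = np.nan
    return row


def run_pipeline(config: RunConfig) -> dict:
    """Run the configured stages and write the report bundle to ``outdir``."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    chash = config.config_hash()
    artifacts: dict = {"config_hash": chash}
    ncat = config.n_age_categories

    cohort = generate_cohort(config.cohort, config.seed)
    save_cohort(cohort, out / "cohort.csv")
    n_missing = int(cohort["D_mes"].isna().sum())
    if n_missing:
        logger.info("dropping %d subjects with missing measured dose", n_missing)
        cohort = cohort[cohort["D_mes"].notna()].reset_index(drop=True)
    artifacts["cohort"] = cohort

    cal = calibrate_cohort(cohort, c=config.cohort.c)
    doses = {"naive": cohort["D_mes"].to_numpy(dtype=float),
             "rc1": cal["RC1"].doses, "rc2": cal["RC2"].doses}
    pd.DataFrame({"id": cohort["id"], "dose_rc1": doses["rc1"],
                  "dose_rc2": doses["rc2"]}).to_csv(out / "doses.csv", index=False)
    params_payload = {
        "config_hash": chash,
        "dose": {"mu": cal["RC1"].params.mu, "sigma": cal["RC1"].params.sigma},
        "activity": {"mu": cal["RC2"].params.mu, "sigma": cal["RC2"].params.sigma},
    }
    (out / "error_params.json").write_text(json.dumps(_to_jsonable(params_payload),
                                                      indent=2, sort_keys=True))
    gsd = gsd_table(cohort)
    gsd.insert(0, "config_hash", chash)
    gsd.to_csv(out / "gsd_table.csv", index=False)
    qq, qq_r = lognormality_qq(cohort["D_mes"])
    qq.to_csv(out / "qq.csv", index=False)
    artifacts.update(gsd_table=gsd, qq_correlation=qq_r, calibration=cal)

    rng = np.random.default_rng(config.seed + 1)
    se = np.log(cohort["gsd_A"].to_numpy(dtype=float))
    sd = np.log(cohort["gsd_M"].to_numpy(dtype=float))
    realizations = sample_dose_posterior(
        cohort["D_mes"].to_numpy(dtype=float), cal["RC1"].params, se, sd,
        config.K, rng, cohort["stratum"].to_numpy())

    # fit-comparison table: 4 dose treatments x {linear, linear-exponential}
    fits: dict[tuple[str, str], FitResult] = {}
    null_fits: dict[str, FitResult] = {}
    rows = []
    for treatment in ("naive", "rc1", "rc2", "mcml"):
        if treatment == "mcml":
            null_fit = fit_mcml(cohort, realizations, "null", n_age_categories=ncat)
            f1 = fit_mcml(cohort, realizations, "linear", n_age_categories=ncat)
            f2 = fit_mcml(cohort, realizations, "linexp", n_age_categories=ncat)
            with_cis = config.compute_cis and config.mcml_cis
            ctx = cohort
        else:
            d = doses[treatment]
            null_fit = fit_ml(cohort, d, "null", n_age_categories=ncat)
            f1 = fit_ml(cohort, d, "linear", n_age_categories=ncat)
            f2 = fit_ml(cohort, d, "linexp", n_age_categories=ncat)
            with_cis = config.compute_cis
            ctx = None
        null_fits[treatment] = null_fit
        fits[(treatment, "linear")] = f1
        fits[(treatment, "linexp")] = f2
        _, _, p1 = lrt(null_fit, f1)
        _, _, p2 = lrt(f1, f2)
        rows.append(_fit_row(f1, treatment, "alpha*D", p1, config.ci_level,
                             with_cis, ctx))
        rows.append(_fit_row(f2, treatment, "alpha*D*exp(gamma*D)", p2,
                             config.ci_level, with_cis, ctx))
    table2 = pd.DataFrame(rows)
    table2.insert(0, "config_hash", chash)
    table2.to_csv(out / "fit_comparison.csv", index=False)
    artifacts.update(fits=fits, table2=table2)

    linear_fits = {t: fits[(t, "linear")] for t in ("naive", "rc1", "rc2", "mcml")}
    eor_change = compare_eor(linear_fits)
    eor_change.insert(0, "config_hash", chash)
    eor_change.to_csv(out / "eor_change.csv", index=False)
    artifacts["eor_change"] = eor_change

    # modifier models 1-6 on RC1-calibrated doses; model 1 is tested against
    # the no-dose null, model 2 against model 1, models 3-6 against model 2
    mod_rows = []
    d1 = doses["rc1"]
    mfits = {}
    for num in range(1, 7):
        mfit = (fits[("rc1", "linear")] if num == 1
                else fits[("rc1", "linexp")] if num == 2
                else fit_ml(cohort, d1, num, n_age_categories=ncat))
        mfits[num] = mfit
        ref = null_fits["rc1"] if num == 1 else mfits[1] if num == 2 else mfits[2]
        _, _, p = lrt(ref, mfit)
        for pname in mfit.param_names:
            if pname.startswith("beta"):
                continue
            if config.compute_cis:
                lo, hi = mfit.profile_cis.get(pname) or profile_ci(
                    mfit, pname, config.ci_level)
            else:
                lo, hi = np.nan, np.nan
            mod_rows.append({"model": num, "parameter": pname,
                             "estimate": mfit[pname], "lo": lo, "hi": hi,
                             "p_improvement": p})
    table3 = pd.DataFrame(mod_rows)
    table3.insert(0, "config_hash", chash)
    table3.to_csv(out / "modifier_models.csv", index=False)
    artifacts["table3"] = table3

    # dose-response curve data (odds ratio vs dose, linear form, naive vs RC1)
    grid = np.linspace(0.0, float(np.quantile(doses["rc1"], 0.999)), 101)
    curve = pd.DataFrame({"dose": grid})
    for t in ("naive", "rc1"):
        f = linear_fits[t]
        curve[f"or_{t}"] = 1.0 + f["alpha"] * grid
        ci = f.profile_cis.get("alpha")
        if ci:
            curve[f"or_{t}_lo"] = 1.0 + ci[0] * grid
            curve[f"or_{t}_hi"] = 1.0 + ci[1] * grid
    curve.to_csv(out / "dose_response_curve.csv", index=False)
    artifacts["curve"] = curve

    scatter = cohort[["D_mes", "gsd_A", "gsd_M"]]
    scatter.to_csv(out / "gsd_scatter.csv", index=False)

    run_log = {
        "config_hash": chash,
        "seed": config.seed,
        "package_version": __version__,
        "n_subjects": int(len(cohort)),
        "n_missing_dose_dropped": n_missing,
        "n_cases": int(cohort["y"].sum()),
        "K": config.K,
        "qq_correlation": qq_r,
    }
    (out / "run_log.json").write_text(json.dumps(_to_jsonable(run_log), indent=2,
                                                 sort_keys=True))
    artifacts["run_log"] = run_log
    return artifacts
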