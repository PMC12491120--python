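"""Longitudinal statistics: fold changes, descriptives, mixed-effects
trajectory models and method-agreement measures.

The study design is a small repeated-measures cohort: each patient (and
lesion) is measured at treatment days 0, 7, 21 and 28, and every imaging or
serum metric is analysed as a percent fold change from its own baseline.
Trajectories are modelled with linear mixed-effects (LME) models — fixed
polynomial time terms (up to cubic, capturing the biphasic binding-potential
course) plus per-patient or per-lesion random intercepts — fitted by REML.
Method agreement between static (dSUV%) and dynamic (dBP_ND%) PET readouts
uses a mixed-model Bland-Altman analysis and a concordance correlation
coefficient for repeated measures.

Conventions
-----------
* Fold change is 100 * (follow-up - baseline) / baseline, so declines are
  negative (consistent with how such studies report PSA and SUV responses).
* Quartiles use midpoint plotting positions (k - 1/2)/n with linear
  interpolation (the "Hazen" rule).
* Confidence intervals and p-values for LME fixed effects use t statistics
  on residual degrees of freedom (n_obs - n_fixed) — the classical default
  of mixed-model tooling of the study's era, documented as a convention.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

import statsmodels.formula.api as smf

#: formula fragment per supported fixed term
_TERM_FORMULA = {
    "day": "day",
    "day2": "I(day**2)",
    "day3": "I(day**3)",
    "adc_pct": "adc_pct",
}

_EXACT_FIT_RTOL = 1e-10  # residual SS below this fraction of total SS => degenerate


def fold_change(baseline, followup):
    """Percent change from baseline: 100 (followup - baseline) / baseline."""
    b = np.asarray(baseline, dtype=float)
    if np.any(b == 0):
        raise ValueError("baseline value of 0 has no defined fold change")
    return 100.0 * (np.asarray(followup, dtype=float) - b) / b


def median_iqr(values) -> tuple[float, float, float]:
    """(median, Q1, Q3) under midpoint plotting positions with linear interpolation."""
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if v.size == 0:
        raise ValueError("no finite values")
    q1, med, q3 = np.quantile(v, [0.25, 0.5, 0.75], method="hazen")
    return float(med), float(q1), float(q3)


def compute_fold_changes(
    visits: pd.DataFrame, exclude_patients: tuple[str, ...] = (),
) -> pd.DataFrame:
    """Long visit table -> trajectory table of percent changes from baseline.

    ``visits`` columns: patient_id, lesion_id, day, metric, value.  Each
    (patient, lesion, metric) series must have a non-zero day-0 baseline;
    missing values are dropped.  ``exclude_patients`` removes patients from
    the output entirely (e.g. PET-negative patients from imaging summaries)
    — exclusions are explicit configuration, never inferred.
    """
    df = visits[~visits["patient_id"].isin(exclude_patients)].copy()
    df = df.dropna(subset=["value"])
    out = []
    for (pid, lid, metric), g in df.groupby(["patient_id", "lesion_id", "metric"], dropna=False):
        base_rows = g[g["day"] == 0]
        if base_rows.empty:
            raise ValueError(f"no baseline (day 0) for {pid}/{lid}/{metric}")
        b = float(base_rows["value"].iloc[0])
        for _, r in g.iterrows():
            out.append((pid, lid, int(r["day"]), metric, fold_change(b, r["value"])))
    res = pd.DataFrame(out, columns=["patient_id", "lesion_id", "day", "metric", "pct_change"])
    return res.sort_values(["metric", "patient_id", "lesion_id", "day"]).reset_index(drop=True)


@dataclass
class LMEFit:
    """Fixed effects and variance components of a fitted mixed model."""

    fixed_effects: pd.DataFrame  # index: term; columns: estimate, se, ci_low, ci_high, p
    variance_components: dict
    reml: bool
    n_obs: int
    n_groups: int
    df_resid: int
    n_dropped: int = 0
    converged: bool = True
    degenerate: bool = False

    @property
    def params(self) -> pd.Series:
        return self.fixed_effects["estimate"]


def _formula(response: str, fixed_terms) -> str:
    parts = []
    for t in fixed_terms:
        if t in ("1", "intercept"):
            continue
        if t not in _TERM_FORMULA:
            raise ValueError(f"unsupported fixed term {t!r}")
        parts.append(_TERM_FORMULA[t])
    rhs = " + ".join(parts) if parts else "1"
    return f"{response} ~ {rhs}"


def _check_design(ols_model) -> None:
    x = ols_model.exog
    rank = np.linalg.matrix_rank(x)
    if rank < x.shape[1]:
        names = ols_model.exog_names
        # name the dependent columns via QR pivoting
        _, r = np.linalg.qr(x)
        bad = [names[j] for j in range(x.shape[1]) if abs(r[j, j] if j < r.shape[0] else 0) < 1e-10]
        raise ValueError(f"singular fixed-effect design; collinear terms: {bad or names}")


def fit_lme(
    data: pd.DataFrame,
    response: str = "pct_change",
    fixed_terms=("day",),
    group: str = "patient_id",
    reml: bool = True,
) -> LMEFit:
    """REML linear mixed-effects fit with a random intercept per group.

    Rows with missing response/predictors are dropped (count reported in
    ``n_dropped``).  Exact-fit data (zero residual variance) make the REML
    likelihood singular; such fits short-circuit to the ordinary
    least-squares closed form with zero variance components, which is the
    analytic limit.
    """
    needed_col = {"day": "day", "day2": "day", "day3": "day", "adc_pct": "adc_pct"}
    cols = [response, group] + [needed_col[t] for t in fixed_terms if t not in ("1", "intercept")]
    cols = list(dict.fromkeys(cols))
    missing = [c for c in cols if c not in data.columns]
    if missing:
        raise ValueError(f"data lacks required columns: {missing}")
    d = data[cols].copy()
    n0 = len(d)
    d = d.dropna()
    n_dropped = n0 - len(d)
    if d[group].nunique() < 2:
        raise ValueError("need at least 2 groups for a random intercept")

    formula = _formula(response, fixed_terms)
    ols = smf.ols(formula, data=d)
    _check_design(ols)
    ols_res = ols.fit()
    k_fe = ols.exog.shape[1]
    n_obs = len(d)
    df_resid = max(n_obs - k_fe, 1)

    y = d[response].to_numpy(dtype=float)
    tss = float(np.sum((y - y.mean()) ** 2)) if n_obs > 1 else 0.0
    degenerate = ols_res.ssr <= max(_EXACT_FIT_RTOL * max(tss, 1.0), 1e-18)

    if degenerate:
        est = ols_res.params
        se = pd.Series(0.0, index=est.index)
        vc = {"group_var": 0.0, "residual_var": 0.0}
        converged = True
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            md = smf.mixedlm(formula, data=d, groups=d[group])
            res = md.fit(reml=reml)
        est = res.fe_params
        se = res.bse_fe
        # statsmodels reports cov_re on the response scale already
        gv = float(res.cov_re.iloc[0, 0]) if res.cov_re.shape[0] else 0.0
        vc = {"group_var": gv, "residual_var": float(res.scale)}
        converged = bool(res.converged)

    tcrit = sps.t.ppf(0.975, df_resid)
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = np.where(se > 0, est / se, np.inf * np.sign(est))
        p = 2.0 * sps.t.sf(np.abs(tstat), df_resid)
    fe = pd.DataFrame(
        {
            "estimate": est,
            "se": se,
            "ci_low": est - tcrit * se,
            "ci_high": est + tcrit * se,
            "p": p,
        }
    )
    return LMEFit(fe, vc, reml, n_obs, int(d[group].nunique()), df_resid,
                  n_dropped, converged, degenerate)


def anova_fixed(fit: LMEFit) -> pd.DataFrame:
    """Marginal F-test per fixed term (F = t^2 for single-df terms)."""
    if not fit.converged:
        raise ValueError("cannot run ANOVA on a non-converged fit")
    fe = fit.fixed_effects
    with np.errstate(divide="ignore", invalid="ignore"):
        f = np.where(fe["se"] > 0, (fe["estimate"] / fe["se"]) ** 2, np.inf)
    p = sps.f.sf(f, 1, fit.df_resid)
    return pd.DataFrame({"F": f, "p": p}, index=fe.index)


@dataclass
class AgreementResult:
    """Mixed-model Bland-Altman bias / limits of agreement plus concordance."""

    bias: float
    loa_low: float
    loa_high: float
    ccc: float | None
    n_pairs: int
    variance_components: dict = field(default_factory=dict)
    ccc_estimator: str | None = None


def agreement_lme(
    pairs: pd.DataFrame,
    col_a: str = "suv_pct",
    col_b: str = "bpnd_pct",
    group: str = "lesion_id",
) -> AgreementResult:
    """Bias and limits of agreement between two repeated-measure series.

    Differences d = a - b are modelled as d ~ 1 + (1|group); bias is the
    intercept and the limits of agreement are bias +/- 1.96 sqrt(var_group +
    var_residual), so repeated visits of one lesion do not masquerade as
    independent pairs.
    """
    d = pairs.dropna(subset=[col_a, col_b]).copy()
    if d[group].nunique() < 2:
        raise ValueError("need at least 2 lesions")
    d["_diff"] = d[col_a] - d[col_b]
    n = len(d)
    diffs = d["_diff"].to_numpy(dtype=float)
    if np.allclose(diffs, diffs[0], rtol=0, atol=1e-12):
        bias = float(diffs[0])
        return AgreementResult(bias, bias, bias, None, n, {"group_var": 0.0, "residual_var": 0.0})
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = smf.mixedlm("_diff ~ 1", data=d, groups=d[group]).fit(reml=True)
        bias = float(res.fe_params.iloc[0])
        gv = float(res.cov_re.iloc[0, 0])
        rv = float(res.scale)
    except np.linalg.LinAlgError:
        # degenerate grouping (e.g. no between-lesion variation): classical
        # Bland-Altman on the pooled differences
        bias = float(diffs.mean())
        gv, rv = 0.0, float(diffs.var(ddof=1))
    half = 1.96 * np.sqrt(gv + rv)
    return AgreementResult(bias, bias - half, bias + half, None, n,
                           {"group_var": gv, "residual_var": rv})


def concordance_correlation(a, b) -> tuple[float, str]:
    """Concordance correlation coefficient for paired method readings.

    Variance-components estimator from the balanced two-way layout
    (value ~ method + subject): ccc = var_subject / (var_subject +
    s2_method + var_residual), with s2_method the squared method mean
    difference over 2 and var_subject left untruncated so systematic
    anticorrelation yields a negative coefficient.  For unreplicated pairs
    this closed form coincides with Lin's sample CCC, which is also the
    fallback reported when the two-way decomposition is degenerate.
    Returns (ccc, estimator_name).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    ok = np.isfinite(a) & np.isfinite(b)
    a, b = a[ok], b[ok]
    n = a.size
    if n < 3:
        raise ValueError("need at least 3 pairs")
    mean_diff = a.mean() - b.mean()
    s2_method = mean_diff**2 / 2.0
    subj_means = (a + b) / 2.0
    msb = 2.0 * np.var(subj_means, ddof=1)
    dvar = np.var(a - b, ddof=1)
    mse = dvar / 2.0
    var_subj = (msb - mse) / 2.0
    denom = var_subj + s2_method + mse
    if not np.isfinite(denom) or denom <= 0:
        # degenerate decomposition: report Lin's sample CCC directly
        s1, s2 = np.var(a, ddof=1), np.var(b, ddof=1)
        s12 = np.cov(a, b, ddof=1)[0, 1]
        denom_lin = s1 + s2 + mean_diff**2
        if denom_lin <= 0:
            raise ValueError("zero total variance: concordance undefined")
        return float(2.0 * s12 / denom_lin), "lin"
    return float(var_subj / denom), "variance-components"


def pivot_changes(traj: pd.DataFrame) -> pd.DataFrame:
    """Trajectory table -> one row per (patient, lesion, day) with columns
    bpnd_pct / adc_pct / suv_pct / psa_pct as available.

    PSA is recorded per patient; it is broadcast across that patient's
    lesions so lesion-level models can use it as a covariate.
    """
    name = {"BPND": "bpnd_pct", "ADC": "adc_pct", "SUVpeak": "suv_pct", "PSA": "psa_pct"}
    lesion = traj[traj["metric"] != "PSA"].copy()
    lesion["col"] = lesion["metric"].map(name)
    wide = lesion.pivot_table(index=["patient_id", "lesion_id", "day"],
                              columns="col", values="pct_change").reset_index()
    wide.columns.name = None
    psa = traj[traj["metric"] == "PSA"]
    if not psa.empty:
        p = psa[["patient_id", "day", "pct_change"]].rename(columns={"pct_change": "psa_pct"})
        wide = wide.merge(p, on=["patient_id", "day"], how="left") if not wide.empty else p
    return wide


def summarize_trajectories(traj: pd.DataFrame) -> pd.DataFrame:
    """Group-level median (IQR) of percent changes per metric and visit day.

    Baseline rows (day 0, identically zero) are excluded.  Output columns:
    metric, day, n, median, q1, q3.
    """
    if traj.empty:
        raise ValueError("empty trajectory table")
    rows = []
    for (metric, day), g in traj[traj["day"] != 0].groupby(["metric", "day"]):
        vals = g["pct_change"].dropna()
        if vals.empty:
            continue
        med, q1, q3 = median_iqr(vals)
        rows.append((metric, int(day), len(vals), med, q1, q3))
    return (pd.DataFrame(rows, columns=["metric", "day", "n", "median", "q1", "q3"])
            .sort_values(["metric", "day"]).reset_index(drop=True))
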