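"""Outlier handling and mixed-effects models for nap-level outcomes.

Each outcome (SWA, slow-wave density, sigma power, spindle density,
K-complex/spindle likelihood, arousal density, nap duration) is modelled
with a linear mixed model: fixed effects for stimulation (nap condition
baseline=0/stimulation=1, or stimulus window OFF=0/ON=1 for the likelihood
outcomes), sensory reactivity, sex and age, plus a per-subject random
intercept; the interaction model adds stimulation x reactivity.  Estimation
is by maximum likelihood with Satterthwaite degrees of freedom for the
fixed-effect t-tests.  Main effects are reported from the base model and the
interaction from the interaction model.  Sleep-stage proportions are fitted
with a zero-inflated beta GLMM (logit link) delegated to R's glmmTMB.
"""

from __future__ import annotations

import json
import subprocess
import tempfile
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import InsufficientDataError, ParameterError, ValidationError

FIXED_EFFECTS = ("stimulation", "reactivity", "sex", "age")


# ---------------------------------------------------------------------------
# Winsorization
# ---------------------------------------------------------------------------


def winsorize(values, sd_limit: float = 4.0, unit: float = 1.0):
    """Replace outliers beyond ``sd_limit`` SD of the mean.

    High outliers become (max of non-outliers) + ``unit``; low outliers
    become (min of non-outliers) - ``unit``.  ``unit`` is the variable's
    declared measurement granularity.  Returns (adjusted array, change log).
    """
    x = np.asarray(values, dtype=float)
    if x.size < 3:
        raise ParameterError("need at least 3 values to Winsorize")
    sd = x.std()
    if sd == 0:
        return x.copy(), []
    z = (x - x.mean()) / sd
    out_hi = z > sd_limit
    out_lo = z < -sd_limit
    keep = ~(out_hi | out_lo)
    if not keep.any():
        raise ParameterError("all values are outliers; Winsorization undefined")
    adj = x.copy()
    log = []
    if out_hi.any():
        repl = x[keep].max() + unit
        for i in np.flatnonzero(out_hi):
            log.append({"index": int(i), "original": float(x[i]), "replaced": repl})
            adj[i] = repl
    if out_lo.any():
        repl = x[keep].min() - unit
        for i in np.flatnonzero(out_lo):
            log.append({"index": int(i), "original": float(x[i]), "replaced": repl})
            adj[i] = repl
    return adj, log


# ---------------------------------------------------------------------------
# Linear mixed models
# ---------------------------------------------------------------------------


@dataclass
class ModelFit:
    terms: pd.DataFrame  # term, beta, se, df, stat, p, ci_low, ci_high (+ _std)
    n_obs: int
    n_subjects: int
    variant: str
    outcome: str
    sigma2: float = np.nan  # residual variance
    tau2: float = np.nan  # random-intercept variance
    converged: bool = True
    backend: str = "statsmodels.MixedLM(ML)"

    def term(self, name: str) -> pd.Series:
        rows = self.terms[self.terms["term"] == name]
        if len(rows) != 1:
            raise KeyError(f"term {name!r} not in model (have {list(self.terms['term'])})")
        return rows.iloc[0]


def _design(
    data: pd.DataFrame,
    stim_col: str,
    interaction: bool,
    sensitivity: bool,
    extra_covariates: tuple[str, ...],
) -> tuple[np.ndarray, list[str]]:
    terms = ["Intercept", stim_col, "reactivity", "sex", "age"]
    cols = [
        np.ones(len(data)),
        data[stim_col].to_numpy(float),
        data["reactivity"].to_numpy(float),
        data["sex"].to_numpy(float),
        data["age"].to_numpy(float),
    ]
    if sensitivity:
        terms.append("autism_likelihood")
        cols.append(data["autism_likelihood"].to_numpy(float))
    for cv in extra_covariates:
        terms.append(cv)
        cols.append(data[cv].to_numpy(float))
    if interaction:
        terms.append(f"{stim_col}:reactivity")
        cols.append(data[stim_col].to_numpy(float) * data["reactivity"].to_numpy(float))
    return np.column_stack(cols), terms


def _satterthwaite(X: np.ndarray, group_sizes: np.ndarray, sigma2: float, tau2: float):
    """Satterthwaite df per fixed effect for a random-intercept LMM.

    Uses the analytic expected information of (sigma2, tau2) under ML and the
    delta method on the coefficient sampling variances.  Also returns the
    model-based SEs (sqrt diag of (X' V^-1 X)^-1).
    """
    p = X.shape[1]
    M = np.zeros((p, p))
    B_s = np.zeros((p, p))  # d/dsigma2 pieces
    B_t = np.zeros((p, p))  # d/dtau2 pieces
    info = np.zeros((2, 2))
    pos = 0
    for ni in group_sizes:
        Xi = X[pos : pos + ni]
        pos += ni
        # V_i^-1 = (I - c J)/sigma2 with c = tau2/(sigma2 + ni tau2)
        c = tau2 / (sigma2 + ni * tau2)
        ones = np.ones(ni)
        XtX = Xi.T @ Xi
        xs = Xi.T @ ones  # column sums
        Vinv_X = (Xi - c * np.outer(ones, xs)) / sigma2
        M += Xi.T @ Vinv_X
        B_s += Vinv_X.T @ Vinv_X
        u = Vinv_X.T @ ones  # X' V^-1 1
        B_t += np.outer(u, u)
        # traces for the expected information (eigenvalues sigma2+ni*tau2, sigma2)
        one_Vinv_one = ni * (1 - c * ni) / sigma2
        tr_Vinv2 = (ni - 1) / sigma2**2 + (1 - c * ni) ** 2 / sigma2**2
        one_Vinv2_one = ni * (1 - c * ni) ** 2 / sigma2**2
        info[0, 0] += 0.5 * tr_Vinv2
        info[0, 1] += 0.5 * one_Vinv2_one
        info[1, 1] += 0.5 * one_Vinv_one**2
    info[1, 0] = info[0, 1]
    C = np.linalg.inv(M)
    se = np.sqrt(np.diag(C))
    try:
        A = np.linalg.inv(info)
    except np.linalg.LinAlgError:
        A = np.linalg.pinv(info)
    dC_s = C @ B_s @ C
    dC_t = C @ B_t @ C
    n, dfs = X.shape[0], []
    for j in range(p):
        g = np.array([dC_s[j, j], dC_t[j, j]])
        denom = g @ A @ g
        if denom <= 0:
            dfs.append(float(n - p))
            continue
        df = 2 * C[j, j] ** 2 / denom
        dfs.append(float(np.clip(df, 1.0, n - p)))
    return np.array(dfs), se


def _fit_mixedlm(y: np.ndarray, X: np.ndarray, groups: np.ndarray):
    """ML fit of a random-intercept model; returns (beta, sigma2, tau2, ok).

    Columns are standardized internally for optimizer conditioning and the
    coefficients mapped back to the original scale.
    """
    import statsmodels.api as sm

    scale_x = X.std(axis=0)
    scale_x[scale_x == 0] = 1.0
    scale_y = y.std() or 1.0
    Xs = X / scale_x
    ys = y / scale_y
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.MixedLM(ys, Xs, groups=groups)
        try:
            res = model.fit(reml=False, method=["lbfgs", "bfgs", "powell"])
        except np.linalg.LinAlgError:
            res = model.fit(reml=False, method="powell")
    beta = np.asarray(res.fe_params, dtype=float) * scale_y / scale_x
    sigma2 = float(res.scale) * scale_y**2
    tau2 = float(np.asarray(res.cov_re)[0, 0]) * scale_y**2
    converged = bool(getattr(res, "converged", True))
    return beta, sigma2, max(tau2, 0.0), converged


def fit_lmm(
    data: pd.DataFrame,
    outcome: str,
    variant: str = "base",
    stim_col: str = "condition",
    extra_covariates: tuple[str, ...] = (),
    group_col: str = "subject",
) -> ModelFit:
    """Fit one LMM variant for one outcome.

    ``variant``: base | interaction | sensitivity_base | sensitivity_interaction
    (the sensitivity variants add autism likelihood as a control covariate).
    Binary predictors stay 0/1; standardized coefficients are computed by
    refitting with the z-scored outcome and continuous predictors.
    """
    if variant not in ("base", "interaction", "sensitivity_base", "sensitivity_interaction"):
        raise ParameterError(f"unknown variant {variant!r}")
    interaction = variant.endswith("interaction")
    sensitivity = variant.startswith("sensitivity")

    needed = {outcome, stim_col, "reactivity", "sex", "age", group_col, *extra_covariates}
    if sensitivity:
        needed.add("autism_likelihood")
    missing = needed - set(data.columns)
    if missing:
        raise ParameterError(f"data missing columns: {sorted(missing)}")
    data = data.dropna(subset=sorted(needed)).reset_index(drop=True)
    data = data.sort_values(group_col, kind="stable").reset_index(drop=True)
    if data[group_col].nunique() < 2:
        raise InsufficientDataError("need at least 2 subjects")
    y = data[outcome].to_numpy(float)
    if np.ptp(y) == 0:
        raise InsufficientDataError(f"outcome {outcome} is constant")

    X, terms = _design(data, stim_col, interaction, sensitivity, tuple(extra_covariates))
    groups = data[group_col].to_numpy()
    beta, sigma2, tau2, converged = _fit_mixedlm(y, X, groups)
    sizes = data.groupby(group_col, sort=False).size().to_numpy()
    dfs, se = _satterthwaite(X, sizes, sigma2, tau2)

    from scipy import stats as sstats

    tstat = beta / se
    pvals = 2 * sstats.t.sf(np.abs(tstat), dfs)
    tcrit = sstats.t.ppf(0.975, dfs)

    # standardized coefficients: z-score outcome and continuous predictors
    zdata = data.copy()
    for col in (outcome, "reactivity", "age"):
        v = zdata[col].to_numpy(float)
        zdata[col] = (v - v.mean()) / (v.std(ddof=1) if v.std(ddof=1) > 0 else 1.0)
    Xz, _ = _design(zdata, stim_col, interaction, sensitivity, tuple(extra_covariates))
    betaz, s2z, t2z, _convz = _fit_mixedlm(zdata[outcome].to_numpy(float), Xz, groups)
    dfz, sez = _satterthwaite(Xz, sizes, s2z, t2z)
    tcritz = sstats.t.ppf(0.975, dfz)

    table = pd.DataFrame(
        {
            "term": terms,
            "beta": beta,
            "se": se,
            "df": dfs,
            "stat": tstat,
            "p": pvals,
            "ci_low": beta - tcrit * se,
            "ci_high": beta + tcrit * se,
            "beta_std": betaz,
            "se_std": sez,
            "std_ci_low": betaz - tcritz * sez,
            "std_ci_high": betaz + tcritz * sez,
        }
    )
    return ModelFit(
        terms=table,
        n_obs=len(data),
        n_subjects=int(data[group_col].nunique()),
        variant=variant,
        outcome=outcome,
        sigma2=sigma2,
        tau2=tau2,
        converged=converged,
    )


def lmm_report(
    data: pd.DataFrame,
    outcome: str,
    stim_col: str = "condition",
    extra_covariates: tuple[str, ...] = (),
    sensitivity: bool = False,
) -> pd.DataFrame:
    """Combined report: main effects from the base model, the interaction
    term from the interaction model (the convention the result tables use)."""
    prefix = "sensitivity_" if sensitivity else ""
    base = fit_lmm(data, outcome, prefix + "base", stim_col, extra_covariates)
    inter = fit_lmm(data, outcome, prefix + "interaction", stim_col, extra_covariates)
    inter_term = f"{stim_col}:reactivity"
    rows = base.terms[base.terms["term"] != "Intercept"].copy()
    rows = pd.concat(
        [rows, inter.terms[inter.terms["term"] == inter_term]], ignore_index=True
    )
    rows.insert(0, "outcome", outcome)
    rows["n_obs"] = base.n_obs
    rows["n_subjects"] = base.n_subjects
    return rows


# ---------------------------------------------------------------------------
# Zero-inflated beta stage-proportion model (R glmmTMB backend)
# ---------------------------------------------------------------------------

_R_STAGE_SCRIPT = r"""
suppressMessages({library(glmmTMB); library(jsonlite)})
args <- commandArgs(trailingOnly = TRUE)
d <- read.csv(args[1])
d$stage <- factor(d$stage, levels = c("N1", "N2", "N3", "REM"))
out <- list()
for (coh in unique(d$cohort)) {
  di <- d[d$cohort == coh, ]
  fit <- tryCatch({
    m <- glmmTMB(prop ~ stage * condition * reactivity + (1 | subject),
                 ziformula = ~1, family = beta_family(link = "logit"),
                 data = di,
                 control = glmmTMBControl(optCtrl = list(iter.max = 500, eval.max = 500)))
    co <- summary(m)$coefficients$cond
    list(ok = TRUE, term = rownames(co), estimate = unname(co[, 1]),
         se = unname(co[, 2]), z = unname(co[, 3]), p = unname(co[, 4]))
  }, error = function(e) list(ok = FALSE, message = conditionMessage(e)))
  out[[as.character(coh)]] <- fit
}
writeLines(toJSON(out, digits = 12, auto_unbox = TRUE), args[2])
"""


def _validate_stage_df(df: pd.DataFrame) -> pd.DataFrame:
    needed = {"subject", "condition", "reactivity", "stage", "prop"}
    missing = needed - set(df.columns)
    if missing:
        raise ParameterError(f"stage data missing columns: {sorted(missing)}")
    p = df["prop"].to_numpy(float)
    if ((p < 0) | (p > 1)).any():
        raise ValidationError("stage proportions must lie in [0, 1]")
    out = df.copy()
    # the beta likelihood excludes 1; exact ones are nudged inside the open interval
    out["prop"] = np.minimum(p, 1 - 1e-6)
    return out


def fit_stage_proportion_models(dfs: list[pd.DataFrame]) -> list[ModelFit]:
    """Fit the zero-inflated beta GLMM to each cohort (one R session for all).

    Model: prop ~ stage * condition * reactivity + (1 | subject), beta family
    with logit link and a zero-inflation intercept; reference stage N1.
    """
    frames = []
    for i, df in enumerate(dfs):
        d = _validate_stage_df(df)
        d["cohort"] = i
        frames.append(d)
    allofit = pd.concat(frames, ignore_index=True)
    with tempfile.TemporaryDirectory() as tmp:
        csv = Path(tmp) / "stage.csv"
        rfile = Path(tmp) / "fit.R"
        outjson = Path(tmp) / "out.json"
        allofit.to_csv(csv, index=False)
        rfile.write_text(_R_STAGE_SCRIPT)
        proc = subprocess.run(
            ["Rscript", "--vanilla", str(rfile), str(csv), str(outjson)],
            capture_output=True,
            text=True,
        )
        if proc.returncode != 0:
            raise RuntimeError(f"glmmTMB backend failed:\n{proc.stderr[-2000:]}")
        results = json.loads(outjson.read_text())

    fits: list[ModelFit] = []
    for i, df in enumerate(dfs):
        r = results[str(i)]
        if not r.get("ok", False):
            raise RuntimeError(f"glmmTMB did not converge: {r.get('message')}")
        terms = pd.DataFrame(
            {
                "term": r["term"],
                "beta": np.asarray(r["estimate"], float),
                "se": np.asarray(r["se"], float),
                "stat": np.asarray(r["z"], float),
                "p": np.asarray(r["p"], float),
            }
        )
        fits.append(
            ModelFit(
                terms=terms,
                n_obs=len(df),
                n_subjects=int(df["subject"].nunique()),
                variant="stage_proportion",
                outcome="stage_prop",
                backend="glmmTMB zero-inflated beta (logit)",
            )
        )
    return fits


def fit_stage_proportion_model(df: pd.DataFrame) -> ModelFit:
    return fit_stage_proportion_models([df])[0]
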