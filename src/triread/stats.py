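"""The inferential battery run on simulation output.

Covers the full analysis chain: preprocessing (misread/missing removal,
2 SD outlier trimming, z-scoring), linear mixed-effects models with
crossed random intercepts for item and model version, likelihood-ratio
model comparison, interaction OLS of the SR scores on oral-vocabulary
variables, a recursive path ("structural regression") model with ML fit
indices, and the factorial imageability x consistency x SR analysis.

Mixed models are fit with statsmodels ``MixedLM`` using variance
components for the crossed factors.  Significance bookkeeping follows the
normal approximation |t| > 1.96.  The structural model treats the
single-indicator latent SR as observed (loading fixed to 1, residual 0);
for recursive path models with free exogenous covariances, per-equation
OLS is exact maximum likelihood, and fit indices (CFI, TLI, RMSEA) come
from the ML discrepancy between the model-implied and sample covariance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm
import statsmodels.formula.api as smf

T_CRIT = 1.96
CLOSE_FIT = {"cfi": 0.95, "rmsea": 0.06, "tli": 0.95}


class StatsError(ValueError):
    pass


@dataclass
class ModelFit:
    """Coefficients and inferential summaries of one fitted model."""

    kind: str
    coefs: pd.Series
    tvalues: pd.Series
    conf_int: pd.DataFrame
    llf: float | None = None
    n_params: int | None = None
    n_obs: int | None = None
    reml: bool | None = None
    r2: float | None = None
    adj_r2: float | None = None
    extra: dict = field(default_factory=dict)

    @property
    def significant(self) -> pd.Series:
        return self.tvalues.abs() > T_CRIT

    def to_frame(self) -> pd.DataFrame:
        out = pd.DataFrame({"coef": self.coefs, "t": self.tvalues})
        out[["ci_low", "ci_high"]] = self.conf_int
        out["significant"] = self.significant
        return out


# --------------------------------------------------------------------------
# preprocessing
# --------------------------------------------------------------------------

def zscore_columns(df: pd.DataFrame, columns: list[str]) -> pd.DataFrame:
    out = df.copy()
    for col in columns:
        x = out[col].astype(float)
        sd = x.std(ddof=1)
        if sd == 0 or not np.isfinite(sd):
            raise StatsError(f"column {col!r} has zero variance")
        out[col] = (x - x.mean()) / sd
    return out


def preprocess(df: pd.DataFrame, dv: str,
               covariates: list[str] | None = None,
               correct_flag: str | None = "phon_correct",
               scale: bool = True) -> pd.DataFrame:
    """Single-pass cleaning before any regression/LMM.

    Drops misread items (where ``correct_flag`` is False), rows missing the
    DV or any covariate, and DV outliers beyond +/- 2 SD of the retained
    mean; then z-scores the DV and covariates.
    """
    covariates = covariates or []
    out = df.copy()
    if correct_flag is not None and correct_flag in out.columns:
        out = out[out[correct_flag].astype(bool)]
    out = out.dropna(subset=[dv] + covariates)
    if out.empty:
        raise StatsError("no rows left after removing misread/missing")
    x = out[dv].astype(float)
    mu, sd = x.mean(), x.std(ddof=1)
    if sd > 0:
        out = out[(x - mu).abs() <= 2 * sd]
    if out.empty:
        raise StatsError("no rows left after outlier trimming")
    if scale:
        out = zscore_columns(out, [dv] + covariates)
    return out.reset_index(drop=True)


# --------------------------------------------------------------------------
# mixed models
# --------------------------------------------------------------------------

def fit_lmm(df: pd.DataFrame, formula: str,
            random: tuple[str, ...] = ("item_id", "version"),
            reml: bool = True, maxiter: int = 200) -> ModelFit:
    """LMM with crossed random intercepts via variance components.

    ``formula`` is a fixed-effects patsy formula, e.g.
    ``"phon_sse ~ wf + rc + wf:rc"``.  Use ``reml=False`` when the fit
    will enter a likelihood-ratio comparison.
    """
    data = df.copy()
    data["_group"] = 1
    vc = {name: f"0 + C({name})" for name in random}
    model = smf.mixedlm(formula, data, groups="_group", vc_formula=vc,
                        re_formula="0")
    res = model.fit(reml=reml, maxiter=maxiter, method="lbfgs")
    if not res.converged:  # pragma: no cover - diagnostic path
        res = model.fit(reml=reml, maxiter=maxiter, method="powell")
    fe = res.fe_params
    tv = fe / res.bse_fe
    ci = pd.DataFrame(
        {"ci_low": fe - T_CRIT * res.bse_fe,
         "ci_high": fe + T_CRIT * res.bse_fe})
    try:
        vc_names = list(model.exog_vc.names)
    except AttributeError:  # statsmodels internals moved
        vc_names = [f"vc{i}" for i in range(len(res.vcomp))]
    extra = {"vc": dict(zip(vc_names, map(float, res.vcomp))),
             "converged": bool(res.converged)}
    return ModelFit(kind="lmm", coefs=fe, tvalues=tv, conf_int=ci,
                    llf=float(res.llf), n_params=len(fe),
                    n_obs=int(res.nobs), reml=reml, extra=extra)


def compare_lmm(base: ModelFit, extended: ModelFit):
    """Likelihood-ratio test between nested ML-fitted mixed models.

    Returns ``(chi2, df, p)`` with df = the number of added fixed effects.
    """
    if base.reml or extended.reml:
        raise StatsError("likelihood-ratio comparison requires ML fits "
                         "(reml=False)")
    if base.n_obs != extended.n_obs:
        raise StatsError("models were fit to different data")
    base_terms = set(base.coefs.index)
    ext_terms = set(extended.coefs.index)
    if not base_terms <= ext_terms:
        raise StatsError("models are not nested")
    df = extended.n_params - base.n_params
    if df <= 0:
        raise StatsError("extended model adds no parameters")
    chi2 = max(2.0 * (extended.llf - base.llf), 0.0)
    p = float(scipy.stats.chi2.sf(chi2, df))
    return chi2, df, p


# --------------------------------------------------------------------------
# per-simulation regressions
# --------------------------------------------------------------------------

def ols_interaction(df: pd.DataFrame, dv: str, x1: str = "ove",
                    x2: str = "ovs", min_rows: int = 10) -> ModelFit:
    """OLS of an SR score on OVE, OVS and their interaction.

    Main effects are z-scored first; the interaction is the product of the
    two z-scored main effects and is not re-scaled (re-scaling a product
    distorts the interaction).  The DV is z-scored.
    """
    if len(df) < min_rows:
        raise StatsError(f"need >= {min_rows} simulations, got {len(df)}")
    d = zscore_columns(df[[dv, x1, x2]].astype(float), [dv, x1, x2])
    d["interaction"] = d[x1] * d[x2]
    X = sm.add_constant(d[[x1, x2, "interaction"]])
    fit = sm.OLS(d[dv], X).fit()
    ci = fit.conf_int()
    ci.columns = ["ci_low", "ci_high"]
    return ModelFit(kind="ols", coefs=fit.params, tvalues=fit.tvalues,
                    conf_int=ci, n_obs=int(fit.nobs),
                    n_params=len(fit.params),
                    r2=float(fit.rsquared), adj_r2=float(fit.rsquared_adj),
                    extra={"pvalues": fit.pvalues.to_dict(),
                           "f_pvalue": float(fit.f_pvalue)})


# --------------------------------------------------------------------------
# recursive path analysis with ML fit indices
# --------------------------------------------------------------------------

@dataclass
class PathResult:
    paths: pd.DataFrame          # rows: (dv, predictor, coef, se, t, p)
    chi2: float
    df: int
    cfi: float
    tli: float
    rmsea: float
    n_obs: int
    close_fit: dict[str, bool]
    implied_cov: pd.DataFrame | None = None


def path_analysis(data: pd.DataFrame,
                  equations: dict[str, list[str]]) -> PathResult:
    """ML estimation of a recursive path model on standardized data.

    ``equations`` maps each endogenous variable to its predictors.
    Exogenous variables (never a dependent variable) covary freely.
    Estimation is per-equation OLS — exact ML for recursive models with
    uncorrelated equation residuals — and fit statistics come from the ML
    discrepancy between the implied and sample covariance matrices.
    """
    endo = list(equations.keys())
    allvars: list[str] = []
    for dv, preds in equations.items():
        for v in preds + [dv]:
            if v not in allvars:
                allvars.append(v)
    exo = [v for v in allvars if v not in endo]
    order = exo + endo
    n = len(data)
    if n <= len(allvars) + 1:
        raise StatsError("too few observations for path analysis")
    Y = data[order].astype(float).to_numpy()
    S = np.cov(Y, rowvar=False, bias=True)           # ML covariance
    p = len(order)
    idx = {v: i for i, v in enumerate(order)}

    B = np.zeros((p, p))
    psi = np.zeros((p, p))
    psi[:len(exo), :len(exo)] = S[:len(exo), :len(exo)]
    rows = []
    n_free = len(exo) * (len(exo) + 1) // 2
    for dv, preds in equations.items():
        X = sm.add_constant(data[preds].astype(float))
        fit = sm.OLS(data[dv].astype(float), X).fit()
        for pred in preds:
            B[idx[dv], idx[pred]] = fit.params[pred]
            rows.append({"dv": dv, "predictor": pred,
                         "coef": float(fit.params[pred]),
                         "se": float(fit.bse[pred]),
                         "t": float(fit.tvalues[pred]),
                         "p": float(fit.pvalues[pred])})
        psi[idx[dv], idx[dv]] = float(fit.resid @ fit.resid) / n  # ML variance
        n_free += len(preds) + 1

    Iminus = np.linalg.inv(np.eye(p) - B)
    sigma = Iminus @ psi @ Iminus.T

    sign, logdet_sigma = np.linalg.slogdet(sigma)
    if sign <= 0:
        raise StatsError("implied covariance not positive definite")
    _, logdet_s = np.linalg.slogdet(S)
    fml = logdet_sigma - logdet_s + float(np.trace(S @ np.linalg.inv(sigma))) - p
    fml = max(fml, 0.0)
    if fml < 1e-10:  # saturated / just-identified up to round-off
        fml = 0.0
    chi2 = (n - 1) * fml
    dof = p * (p + 1) // 2 - n_free

    # independence baseline: diagonal Sigma_b
    # F = log|Sigma_b| - log|S| + tr(S Sigma_b^-1) - p
    fml_b = float(np.sum(np.log(np.diag(S)))) - logdet_s + \
        float(np.trace(S @ np.diag(1.0 / np.diag(S)))) - p
    chi2_b = (n - 1) * max(fml_b, 0.0)
    df_b = p * (p - 1) // 2

    d_model = max(chi2 - dof, 0.0)
    d_base = max(chi2_b - df_b, 0.0)
    cfi = 1.0 if d_base == 0 else 1.0 - d_model / max(d_base, d_model)
    if dof == 0:
        tli, rmsea = 1.0, 0.0
    else:
        denom = chi2_b / df_b - 1.0
        tli = 1.0 if denom <= 0 else (chi2_b / df_b - chi2 / dof) / denom
        rmsea = float(np.sqrt(d_model / (dof * (n - 1))))
    close = {"cfi": cfi >= CLOSE_FIT["cfi"],
             "rmsea": rmsea <= CLOSE_FIT["rmsea"],
             "tli": tli >= CLOSE_FIT["tli"]}
    return PathResult(paths=pd.DataFrame(rows), chi2=float(chi2), df=int(dof),
                      cfi=float(cfi), tli=float(min(tli, 1.0)),
                      rmsea=float(rmsea), n_obs=n, close_fit=close,
                      implied_cov=pd.DataFrame(sigma, index=order,
                                               columns=order))


def structural_model(df: pd.DataFrame, sr_col: str,
                     dv: str = "mean_phon_sse") -> PathResult:
    """The oral-knowledge -> SR -> reading-performance structural model.

    OVE, OVS and their interaction predict the SR score, which in turn
    (alongside direct OVE/OVS/interaction paths) predicts mean phonological
    SSE in reading aloud.  All variables standardized; the interaction is
    the product of the z-scored main effects.  The single-indicator latent
    SR is identified by fixing its loading to 1 and its residual to 0,
    i.e. treated as observed.
    """
    d = zscore_columns(df[[sr_col, dv, "ove", "ovs"]].astype(float),
                       [sr_col, dv, "ove", "ovs"])
    d["interaction"] = d["ove"] * d["ovs"]
    equations = {sr_col: ["ove", "ovs", "interaction"],
                 dv: [sr_col, "ove", "ovs", "interaction"]}
    return path_analysis(d, equations)


# --------------------------------------------------------------------------
# factorial SR analysis
# --------------------------------------------------------------------------

def factorial_sr_analysis(word_df: pd.DataFrame, sr_col: str,
                          dv: str = "phon_sse") -> tuple[ModelFit, pd.DataFrame]:
    """LMM of reading SSE on imageability x consistency x SR.

    Expects a preprocessed table with ``img_class`` / ``cons_class``
    centred factor codes (+/- 0.5), a z-scored SR score per simulation,
    and ``item_id`` / ``version`` identifiers.  Returns the fit and the
    model-free cell means for plotting the three-way interaction.
    """
    for col in ("img_class", "cons_class", sr_col, dv, "item_id", "version"):
        if col not in word_df.columns:
            raise StatsError(f"missing column {col!r}")
    cells = (word_df.groupby(["img_class", "cons_class"])[dv]
             .agg(["mean", "size"]).reset_index())
    if (cells["size"] == 0).any() or len(cells) < 4:
        raise StatsError("empty factorial cells")
    formula = f"{dv} ~ img_class * cons_class * {sr_col}"
    fit = fit_lmm(word_df, formula)
    return fit, cells
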