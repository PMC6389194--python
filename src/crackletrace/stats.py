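"""Mixed-model validation of the acoustic parameters.

Two model families, both with a per-subject random intercept to absorb the
repeated-measures structure (each animal contributes one observation per
PEEP level and region):

* acoustic parameter ~ Δatelectasis, fitted per region; the figure of
  merit is the marginal R² — the share of total variance (fixed +
  random-intercept + residual) explained by the fixed effects alone
  (Nakagawa & Schielzeth's definition).
* dSC ~ region * PEEP, with pairwise region contrasts on the marginal
  means, Holm-adjusted.

Estimation is REML via ``statsmodels`` ``MixedLM`` with an ML fallback on
convergence failure.  Contrast tests use the normal approximation for the
Wald z statistic.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import patsy
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests
from statsmodels.tools.sm_exceptions import ConvergenceWarning


@dataclass
class Contrast:
    label: str
    estimate: float
    se: float
    p_raw: float
    p_holm: float | None = None


@dataclass
class LMMFit:
    """Fitted random-intercept model summary."""

    intercept: float
    slope: float | None
    se_intercept: float
    se_slope: float | None
    p_slope: float | None
    conf_int_slope: tuple[float, float] | None
    var_random_intercept: float
    var_residual: float
    r2_marginal: float
    r2_conditional: float
    method: str
    converged: bool
    singular: bool = False
    term_pvalues: dict[str, float] = field(default_factory=dict)
    contrasts: list[Contrast] = field(default_factory=list)
    fe_params: pd.Series | None = None


def holm_adjust(pvalues) -> np.ndarray:
    """Step-down Holm adjustment, order-preserving and monotone."""
    p = np.asarray(pvalues, dtype=float)
    if p.size and (np.any(p < 0) or np.any(p > 1) or np.any(~np.isfinite(p))):
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p
    return multipletests(p, method="holm")[1]


def _fit_mixedlm(model) -> tuple:
    """REML fit with ML fallback; returns (result, method, converged)."""
    for reml, name in ((True, "REML"), (False, "ML")):
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", ConvergenceWarning)
                warnings.simplefilter("ignore", RuntimeWarning)
                warnings.simplefilter("ignore", UserWarning)
                res = model.fit(reml=reml, method=["powell", "lbfgs"],
                                maxiter=2000)
            if res.converged:
                return res, name, True
        except Exception:
            continue
    # last resort: report the ML fit even if not flagged converged
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = model.fit(reml=False)
    return res, "ML", bool(res.converged)


def _variance_partition(res, exog: np.ndarray) -> tuple[float, float, float]:
    fixed_pred = exog @ np.asarray(res.fe_params)
    var_f = float(np.var(fixed_pred, ddof=0))
    var_u = float(np.asarray(res.cov_re)[0, 0]) if res.cov_re.size else 0.0
    var_e = float(res.scale)
    return var_f, var_u, var_e


def fit_lmm_regression(obs: pd.DataFrame, value: str = "dce",
                       predictor: str = "delta_atelectasis",
                       group: str = "subject",
                       random_intercept: bool = True) -> LMMFit:
    """Random-intercept regression of an acoustic parameter on Δatelectasis.

    ``obs`` must hold one row per subject x condition x PEEP (x region
    already filtered).  Requires >= 2 subjects with >= 2 observations each.
    A fit whose between-subject variance collapses to zero is returned with
    ``singular=True`` rather than raised.  With
    ``random_intercept=False`` the between-subject variance is pinned at
    zero and the model reduces to ordinary least squares.
    """
    df = obs[[group, predictor, value]].dropna()
    counts = df.groupby(group).size()
    if len(counts) < 2 or (counts < 2).any():
        raise ValueError("need >= 2 subjects with >= 2 observations each")

    # standardise internally for optimiser stability; estimates are
    # back-transformed exactly, so results are invariant to affine
    # rescaling of either variable
    x = df[predictor].to_numpy(dtype=float)
    y = df[value].to_numpy(dtype=float)
    mx, sx = x.mean(), x.std()
    my, sy = y.mean(), y.std()
    if sx == 0:
        raise ValueError("predictor has zero variance")
    if sy == 0:
        sy = 1.0
    exog_std = sm.add_constant((x - mx)[:, None] / sx)
    if not random_intercept:
        res = sm.OLS((y - my) / sy, exog_std).fit()
        method, converged = "OLS", True
        res.fe_params = pd.Series(res.params)
        res.bse_fe = pd.Series(res.bse)
        res.cov_re = np.zeros((0, 0))
        res.scale = float(res.mse_resid)
    else:
        model = sm.MixedLM((y - my) / sy, exog_std,
                           groups=df[group].to_numpy())
        res, method, converged = _fit_mixedlm(model)
    var_f, var_u, var_e = _variance_partition(res, exog_std)
    var_u *= sy ** 2
    var_e *= sy ** 2
    denom = var_f * sy ** 2 + var_u + var_e
    var_f *= sy ** 2
    fe = np.asarray(res.fe_params)
    with warnings.catch_warnings():
        # perfect fits make cov_params marginally negative on the diagonal
        warnings.simplefilter("ignore", RuntimeWarning)
        bse = np.nan_to_num(np.asarray(res.bse_fe), nan=0.0)
    slope = float(fe[1]) * sy / sx
    se_slope = float(bse[1]) * sy / sx
    intercept = my + sy * float(fe[0]) - slope * mx
    # se(intercept) on the original scale via the delta of the affine map
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        cov_fe = np.asarray(res.cov_params())[:2, :2]
    J = np.array([sy, -sy * mx / sx])
    # degenerate (perfect) fits can yield a tiny negative quadratic form
    se_intercept = float(np.sqrt(max(J @ cov_fe @ J, 0.0)))
    z = slope / se_slope if se_slope > 0 else np.inf * np.sign(slope)
    p_slope = float(2 * sps.norm.sf(abs(z)))
    ci = (slope - 1.959963984540054 * se_slope,
          slope + 1.959963984540054 * se_slope)
    return LMMFit(
        intercept=intercept,
        slope=slope,
        se_intercept=se_intercept,
        se_slope=se_slope,
        p_slope=p_slope,
        conf_int_slope=ci,
        var_random_intercept=var_u,
        var_residual=var_e,
        r2_marginal=var_f / denom if denom > 0 else 0.0,
        r2_conditional=(var_f + var_u) / denom if denom > 0 else 0.0,
        method=method,
        converged=converged,
        singular=var_u <= 1e-12 * max(denom, 1.0),
        fe_params=pd.Series({"intercept": intercept, "slope": slope}),
    )


def fit_lmm_dsc(obs: pd.DataFrame, value: str = "dsc",
                region: str = "roi", peep: str = "peep",
                group: str = "subject") -> LMMFit:
    """Region x PEEP mixed ANOVA for dSC with pairwise region contrasts.

    Fixed effects for region, PEEP (both categorical) and their
    interaction; per-subject random intercept.  Pairwise region contrasts
    are differences of marginal means (averaged over PEEP levels), tested
    with Wald z and Holm-adjusted within the three-contrast family.
    Missing region x PEEP cells raise with the offending cells listed.
    """
    df = obs[[group, region, peep, value]].dropna().copy()
    regions = sorted(df[region].unique())
    peeps = sorted(df[peep].unique())
    if len(regions) < 2 or len(peeps) < 2:
        raise ValueError("need >= 2 regions and >= 2 PEEP levels")
    present = set(map(tuple, df[[region, peep]].drop_duplicates().to_numpy()))
    missing = [c for c in itertools.product(regions, peeps) if c not in present]
    if missing:
        raise ValueError(f"missing region x PEEP cells: {missing}")

    df["_peep"] = df[peep].astype(str)
    formula = f"{value} ~ C({region}) * C(_peep)"
    model = smf.mixedlm(formula, df, groups=df[group])
    res, method, converged = _fit_mixedlm(model)

    design_info = model.data.design_info
    exog = np.asarray(model.exog)
    var_f, var_u, var_e = _variance_partition(res, exog)
    denom = var_f + var_u + var_e
    beta = res.fe_params.to_numpy()
    cov = np.asarray(res.cov_params())[:len(beta), :len(beta)]

    # marginal-mean design row per region (uniform average over PEEP levels)
    grid = pd.DataFrame([{region: r, "_peep": str(p)}
                         for r in regions for p in peeps])
    rows = np.asarray(patsy.build_design_matrices([design_info], grid)[0])
    mm_rows = {r: rows[[i for i, (rr, _) in
                        enumerate(itertools.product(regions, peeps))
                        if rr == r]].mean(axis=0)
               for r in regions}

    contrasts = []
    for a, b in itertools.combinations(regions, 2):
        L = mm_rows[b] - mm_rows[a]
        est = float(L @ beta)
        se = float(np.sqrt(L @ cov @ L))
        z = est / se if se > 0 else np.inf * np.sign(est)
        contrasts.append(Contrast(label=f"{b} - {a}", estimate=est, se=se,
                                  p_raw=float(2 * sps.norm.sf(abs(z)))))
    adj = holm_adjust([c.p_raw for c in contrasts])
    for c, p in zip(contrasts, adj):
        c.p_holm = float(p)

    term_p = {}
    for term, name in ((f"C({region})", "region"), ("C(_peep)", "peep"),
                       (f"C({region}):C(_peep)", "interaction")):
        sl = design_info.term_name_slices[term]
        idx = np.arange(len(beta))[sl]
        R = np.zeros((len(idx), len(beta)))
        R[np.arange(len(idx)), idx] = 1.0
        est = R @ beta
        covR = R @ cov @ R.T
        stat = float(est @ np.linalg.solve(covR, est))
        term_p[name] = float(sps.chi2.sf(stat, len(idx)))

    return LMMFit(
        intercept=float(beta[0]), slope=None,
        se_intercept=float(res.bse_fe.iloc[0]),
        se_slope=None, p_slope=None, conf_int_slope=None,
        var_random_intercept=var_u, var_residual=var_e,
        r2_marginal=var_f / denom if denom > 0 else 0.0,
        r2_conditional=(var_f + var_u) / denom if denom > 0 else 0.0,
        method=method, converged=converged,
        singular=var_u <= 1e-12 * max(denom, 1.0),
        term_pvalues=term_p, contrasts=contrasts,
        fe_params=res.fe_params,
    )
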