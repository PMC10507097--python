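"""Growth and development statistics for multi-environment phenotype series.

The analysis chain implemented here:

1. per-measurement-date BLUEs of each genotype from a linear mixed model with
   genotype fixed and the trial design's positional factors random (REML);
2. a logistic growth model over time with environment-level fixed parameters
   and genotype-level random deviations, estimated by a precision-weighted
   two-stage procedure (per-group nonlinear fits, then a random-effects
   meta-model per parameter);
3. derivative/inflection analytics of the fitted curves and hierarchical
   clustering of the genotype × environment height matrix at a common
   inflection time;
4. a fixed-effect logistic model for population tasseling percentages with a
   two-way ANOVA on residuals and fitted values;
5. repeatability of the genotype signal across environments, variance
   decomposition of positional effects with parametric-bootstrap intervals,
   and yield-component BLUPs with Tukey-adjusted environment contrasts.

The two-stage logistic estimator deliberately replaces a joint nonlinear
mixed-model maximisation with an ARMA residual covariance: the inferential
targets (environment fixed parameters, genotype deviations) are recoverable
two-stage, and residual autocorrelation is reported as a portmanteau
(Ljung–Box, 10 lags) diagnostic instead of being folded into the likelihood.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from scipy import optimize, stats
from scipy.cluster.hierarchy import fcluster, leaves_list, linkage
from statsmodels.stats.anova import anova_lm
from statsmodels.stats.diagnostic import acorr_ljungbox

BOUNDARY_SD = 1e-6  # random-effect sd below this × response scale is dropped


class DesignError(ValueError):
    pass


class FitError(RuntimeError):
    pass


# -- design specifications ----------------------------------------------------


@dataclass(frozen=True)
class DesignSpec:
    """Fixed and random terms of one trial design's mixed model."""

    design_id: str
    fixed_terms: tuple
    random_terms: tuple  # patsy-style terms over table columns


DESIGNS = {
    # chamber container trials: replicate, container row/column, plant position
    # and the replicate interactions random
    "chamber_container": DesignSpec(
        "chamber_container",
        ("genotype",),
        (
            "C(replicate):C(row)",
            "C(replicate):C(position)",
            "C(replicate):C(column)",
            "C(column)",
            "C(row)",
            "C(position)",
            "C(replicate)",
        ),
    ),
    "glasshouse": DesignSpec(
        "glasshouse", ("genotype",), ("C(replicate)", "C(row)")
    ),
    "field": DesignSpec(
        "field",
        ("genotype",),
        ("C(replicate):C(position)", "C(position)", "C(replicate)"),
    ),
    # across-environment repeatability model
    "repeatability": DesignSpec(
        "repeatability",
        ("experiment", "experiment_time"),
        (
            "C(genotype):C(experiment_time)",
            "C(genotype):C(experiment)",
            "C(genotype)",
        ),
    ),
    # spatial-homogeneity trial
    "homogeneity": DesignSpec(
        "homogeneity",
        ("genotype",),
        ("C(preculture)", "C(column)", "C(row)", "C(replicate)", "C(soil)"),
    ),
}


def _term_columns(term: str) -> list[str]:
    return re.findall(r"C\((\w+)\)", term) or [term]


def validate_design(design: DesignSpec, table: pd.DataFrame) -> None:
    for term in design.random_terms:
        for col in _term_columns(term):
            if col not in table.columns:
                raise DesignError(
                    f"{design.design_id}: random term {term!r} references "
                    f"missing column {col!r}"
                )
    # a positional factor whose levels map 1:1 onto genotypes is confounded
    if "genotype" in table.columns:
        for term in design.random_terms:
            cols = _term_columns(term)
            if len(cols) != 1 or cols[0] == "genotype":
                continue
            ct = pd.crosstab(table[cols[0]], table["genotype"])
            if (
                ct.shape[0] == ct.shape[1]
                and ((ct > 0).sum(axis=1) == 1).all()
                and ((ct > 0).sum(axis=0) == 1).all()
            ):
                raise DesignError(
                    f"{design.design_id}: factor {cols[0]!r} is confounded "
                    "with genotype"
                )


# -- mixed-model plumbing -----------------------------------------------------


def _fit_vc_model(df: pd.DataFrame, fixed_formula: str, vc_terms: dict, reml=True):
    """REML linear mixed model with crossed variance components.

    ``vc_terms`` maps a component name to a patsy term; all components are
    crossed (one technical grouping spans the whole table).
    """
    work = df.copy()
    work["_all"] = 1
    vcf = {name: f"0 + {term}" for name, term in vc_terms.items()}
    model = smf.mixedlm(
        fixed_formula, work, groups="_all", vc_formula=vcf, re_formula="0"
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        # derivative-free search: boundary (zero) variance components leave
        # the REML surface non-smooth and defeat the gradient-based methods
        result = model.fit(reml=reml, method="powell", maxiter=2000)
    return result


def _vc_variances(result, vc_terms: dict) -> dict:
    names = list(vc_terms)
    return {name: float(result.vcomp[i]) for i, name in enumerate(names)}


# -- BLUEs --------------------------------------------------------------------


@dataclass
class BlueResult:
    trait: str
    date: object
    blues: pd.Series  # genotype -> estimate
    se: pd.Series
    variance_components: dict
    residual_variance: float
    boundary: list  # components estimated at the zero boundary
    flagged: list  # genotypes with <2 observations


def estimate_blues(
    table: pd.DataFrame,
    design: DesignSpec,
    trait: str = "plant_height",
    date=None,
    date_col: str = "das",
) -> BlueResult:
    """Per-genotype BLUEs at one measurement date.

    Genotype is fixed, the design's positional terms random; fitted by REML.
    Zero (boundary) variance components are permitted and reported.
    """
    validate_design(design, table)
    df = table if date is None else table[table[date_col] == date]
    if df.empty:
        raise DesignError(f"no observations at {date_col} == {date}")
    counts = df.groupby("genotype")[trait].count()
    flagged = list(counts.index[counts < 2])
    vc_terms = {f"vc{i}": t for i, t in enumerate(design.random_terms)}
    df = df[[c for c in df.columns]].dropna(subset=[trait])
    formula = f"{trait} ~ 0 + C(genotype)"
    try:
        result = _fit_vc_model(df, formula, vc_terms)
        params = result.fe_params
        ses = result.bse_fe
        vcomp = {
            design.random_terms[i]: v
            for i, v in enumerate(result.vcomp.astype(float))
        }
        resid_var = float(result.scale)
    except Exception:
        # boundary/singular designs: all variance components at zero -> OLS
        ols = smf.ols(formula, df).fit()
        params, ses = ols.params, ols.bse
        vcomp = {t: 0.0 for t in design.random_terms}
        resid_var = float(ols.scale)
    labels = [re.match(r"C\(genotype\)\[(.+)\]", p).group(1) for p in params.index]
    blues = pd.Series(params.to_numpy(float), index=labels, name="blue")
    se = pd.Series(ses.to_numpy(float), index=labels, name="se")
    scale = max(np.nanstd(df[trait].to_numpy(float)), 1e-12)
    boundary = [t for t, v in vcomp.items() if np.sqrt(max(v, 0.0)) < BOUNDARY_SD * scale]
    return BlueResult(trait, date, blues, se, vcomp, resid_var, boundary, flagged)


def blues_over_time(
    table: pd.DataFrame,
    designs: dict,
    trait: str = "plant_height",
    date_col: str = "das",
) -> pd.DataFrame:
    """BLUEs for every environment × measurement date, long format.

    ``designs`` maps environment label -> DesignSpec (or one spec for all).
    """
    rows = []
    for env, df_env in table.groupby("environment"):
        design = designs[env] if isinstance(designs, dict) else designs
        for date in sorted(df_env[date_col].unique()):
            res = estimate_blues(df_env, design, trait, date, date_col)
            for geno, val in res.blues.items():
                rows.append(
                    {
                        "environment": env,
                        "genotype": geno,
                        date_col: date,
                        "value": val,
                        "se": res.se[geno],
                    }
                )
    return pd.DataFrame(rows)


# -- logistic curves ----------------------------------------------------------


def logistic3(x, asym, xmid, scal):
    return asym / (1.0 + np.exp((xmid - np.asarray(x, float)) / scal))


def logistic4(x, a, b, xmid, scal):
    return a + (b - a) / (1.0 + np.exp((xmid - np.asarray(x, float)) / scal))


def _selfstart(t, y, n_params: int):
    """Starting values: Asym₀ = 1.05·max(y); xmid₀ = first crossing of
    Asym₀/2 (linear interpolation); scal₀ = (t₇₅ − t₂₅)/2.2."""
    t = np.asarray(t, float)
    y = np.asarray(y, float)
    asym0 = 1.05 * np.max(y)
    lo = np.min(y)

    def crossing(level):
        above = y >= level
        if not above.any():
            return t[-1]
        i = int(np.argmax(above))
        if i == 0:
            return t[0]
        f = (level - y[i - 1]) / (y[i] - y[i - 1]) if y[i] != y[i - 1] else 0.5
        return t[i - 1] + f * (t[i] - t[i - 1])

    if n_params == 3:
        xmid0 = crossing(asym0 / 2.0)
        t25, t75 = crossing(0.25 * asym0), crossing(0.75 * asym0)
    else:
        xmid0 = crossing(lo + (asym0 - lo) / 2.0)
        t25 = crossing(lo + 0.25 * (asym0 - lo))
        t75 = crossing(lo + 0.75 * (asym0 - lo))
    scal0 = max((t75 - t25) / 2.2, (t[-1] - t[0]) / 50.0)
    if n_params == 3:
        return [asym0, xmid0, scal0]
    return [lo, asym0, xmid0, scal0]


def fit_logistic_curve(t, y, n_params: int = 3):
    """Least-squares logistic fit for one genotype × environment series."""
    t = np.asarray(t, float)
    y = np.asarray(y, float)
    p0 = _selfstart(t, y, n_params)
    fun = logistic3 if n_params == 3 else logistic4
    span = t[-1] - t[0]
    if n_params == 3:
        bounds = ([1e-8, t[0] - span, 1e-3], [np.inf, t[-1] + span, span])
    else:
        bounds = (
            [-np.inf, 1e-8, t[0] - span, 1e-3],
            [np.inf, np.inf, t[-1] + span, span],
        )
    p0 = np.clip(p0, bounds[0], bounds[1])
    popt, pcov = optimize.curve_fit(fun, t, y, p0=p0, bounds=bounds, maxfev=20000)
    resid = y - fun(t, *popt)
    return popt, pcov, resid


# -- stage 2: precision-weighted random-effects meta-model --------------------


def _meta_mixed_reml(y, v, env_idx, n_env, geno_idx=None, n_geno=0):
    """REML meta-model  y = β_env + u_geno + e,  u ~ N(0, σ²_g),
    e ~ N(0, v + σ²); returns β, cov(β), BLUPs, (σ²_g, σ²)."""
    y = np.asarray(y, float)
    v = np.asarray(v, float)
    n = len(y)
    X = np.zeros((n, n_env))
    X[np.arange(n), env_idx] = 1.0
    G = None
    if geno_idx is not None and n_geno > 1:
        G = np.zeros((n, n_geno))
        G[np.arange(n), geno_idx] = 1.0

    scale0 = max(np.var(y), 1e-8)

    def neg_reml(theta):
        s2 = np.exp(theta[0])
        V = np.diag(v + s2)
        if G is not None:
            sg2 = np.exp(theta[1])
            V = V + sg2 * (G @ G.T)
        try:
            L = np.linalg.cholesky(V)
        except np.linalg.LinAlgError:
            return 1e12
        Vi_y = np.linalg.solve(V, y)
        Vi_X = np.linalg.solve(V, X)
        XtViX = X.T @ Vi_X
        beta = np.linalg.solve(XtViX, X.T @ Vi_y)
        r = y - X @ beta
        Vi_r = np.linalg.solve(V, r)
        logdetV = 2.0 * np.sum(np.log(np.diag(L)))
        sign, logdetX = np.linalg.slogdet(XtViX)
        return 0.5 * (logdetV + logdetX + r @ Vi_r)

    if G is not None:
        x0 = [np.log(scale0 * 0.5), np.log(scale0 * 0.5)]
    else:
        x0 = [np.log(scale0 * 0.5)]
    res = optimize.minimize(neg_reml, x0, method="Nelder-Mead",
                            options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 2000})
    s2 = float(np.exp(res.x[0]))
    sg2 = float(np.exp(res.x[1])) if G is not None else 0.0
    V = np.diag(v + s2)
    if G is not None:
        V = V + sg2 * (G @ G.T)
    Vi_X = np.linalg.solve(V, X)
    XtViX = X.T @ Vi_X
    cov_beta = np.linalg.inv(XtViX)
    beta = cov_beta @ (X.T @ np.linalg.solve(V, y))
    blups = np.zeros(n_geno)
    if G is not None:
        blups = sg2 * (G.T @ np.linalg.solve(V, y - X @ beta))
    return beta, cov_beta, blups, (sg2, s2)


PARAM_NAMES = {3: ("Asym", "xmid", "scal"), 4: ("A", "B", "xmid", "scal")}
#: parameters carrying a genotype random deviation (scal is shared; the left
#: asymptote of the 4-parameter curve is near zero and also shared)
RANDOM_PARAMS = {3: ("Asym", "xmid"), 4: ("B", "xmid")}


@dataclass
class LogisticFitResult:
    n_params: int
    time_axis: str
    environments: list
    genotypes: list
    fixed: dict  # param -> {env: value}
    fixed_cov: dict  # param -> (n_env × n_env) covariance of fixed params
    random: dict  # param -> {genotype: deviation}
    variance_components: dict  # param -> (sigma2_genotype, sigma2_stage2)
    residual_sd: dict  # env -> stage-1 residual sd
    stage1: pd.DataFrame
    diagnostics: dict
    log: list = field(default_factory=list)

    def params_for(self, genotype: str, environment: str) -> tuple:
        out = []
        for p in PARAM_NAMES[self.n_params]:
            val = self.fixed[p][environment]
            if p in self.random and genotype in self.random[p]:
                val += self.random[p][genotype]
            out.append(val)
        return tuple(out)

    def curve(self, environment: str, x):
        fun = logistic3 if self.n_params == 3 else logistic4
        pars = [self.fixed[p][environment] for p in PARAM_NAMES[self.n_params]]
        return fun(x, *pars)


def fit_logistic_population(
    blues: pd.DataFrame,
    n_params: int = 3,
    time_axis: str = "das",
    value_col: str = "value",
) -> LogisticFitResult:
    """Two-stage logistic mixed fit over genotype × environment BLUE series.

    Stage 1 fits one logistic curve per genotype × environment with
    self-starting values.  Stage 2 fits, per parameter, a precision-weighted
    random-effects meta-model with environment fixed effects; the asymptote
    and xmid carry genotype random deviations, scal is shared across
    genotypes.  A genotype random term whose estimated sd falls below
    1e-6 × the response scale is removed and the model refit (logged).
    """
    envs = sorted(blues["environment"].unique())
    genos = sorted(blues["genotype"].unique())
    log: list[str] = []
    names = PARAM_NAMES[n_params]
    stage1_rows = []
    resid_by_env: dict = {e: [] for e in envs}
    lb_stats = []
    for (env, geno), grp in blues.groupby(["environment", "genotype"]):
        grp = grp.sort_values(time_axis)
        t = grp[time_axis].to_numpy(float)
        y = grp[value_col].to_numpy(float)
        if len(t) < max(6, n_params + 1):
            log.append(f"{env}/{geno}: only {len(t)} time points; excluded")
            continue
        try:
            popt, pcov, resid = fit_logistic_curve(t, y, n_params)
        except (RuntimeError, ValueError) as exc:
            log.append(f"{env}/{geno}: stage-1 fit failed ({exc}); excluded")
            continue
        var = np.diag(pcov)
        if not np.all(np.isfinite(var)):
            log.append(f"{env}/{geno}: singular stage-1 covariance; excluded")
            continue
        rec = {"environment": env, "genotype": geno, "n_points": len(t)}
        for j, p in enumerate(names):
            rec[p] = popt[j]
            rec[f"var_{p}"] = max(var[j], 1e-12)
        stage1_rows.append(rec)
        resid_by_env[env].append(resid)
        if len(resid) > 12:
            lb = acorr_ljungbox(resid, lags=[10], return_df=True)
            lb_stats.append(
                (float(lb["lb_stat"].iloc[0]), float(lb["lb_pvalue"].iloc[0]))
            )
    if not stage1_rows:
        raise FitError("all genotype × environment groups failed to fit")
    stage1 = pd.DataFrame(stage1_rows)
    env_index = {e: i for i, e in enumerate(envs)}
    geno_index = {g: i for i, g in enumerate(genos)}
    ei = stage1["environment"].map(env_index).to_numpy()
    gi = stage1["genotype"].map(geno_index).to_numpy()

    fixed, fixed_cov, random_eff, vc = {}, {}, {}, {}
    for p in names:
        y = stage1[p].to_numpy(float)
        v = stage1[f"var_{p}"].to_numpy(float)
        with_random = p in RANDOM_PARAMS[n_params]
        if with_random:
            beta, cov, blups, (sg2, s2) = _meta_mixed_reml(
                y, v, ei, len(envs), gi, len(genos)
            )
            scale = max(np.std(y), 1e-12)
            if np.sqrt(sg2) < BOUNDARY_SD * scale:
                log.append(
                    f"random effect for {p!r} at boundary (sd "
                    f"{np.sqrt(sg2):.3g}); removed and refit"
                )
                beta, cov, blups, (sg2, s2) = _meta_mixed_reml(y, v, ei, len(envs))
                blups = np.zeros(len(genos))
                with_random = False
        else:
            beta, cov, blups, (sg2, s2) = _meta_mixed_reml(y, v, ei, len(envs))
            blups = np.zeros(len(genos))
        fixed[p] = {e: float(beta[env_index[e]]) for e in envs}
        fixed_cov[p] = cov
        random_eff[p] = (
            {g: float(blups[geno_index[g]]) for g in genos} if with_random else {}
        )
        vc[p] = (sg2, s2)

    residual_sd = {
        e: float(np.std(np.concatenate(r))) if r else np.nan
        for e, r in resid_by_env.items()
    }
    # determination coefficients on the xmid meta-model (representative scale)
    diag = {}
    if lb_stats:
        arr = np.array(lb_stats)
        diag["ljung_box_stat_mean"] = float(arr[:, 0].mean())
        diag["ljung_box_p_median"] = float(np.median(arr[:, 1]))
        diag["ljung_box_lags"] = 10
    r2 = {}
    for p in names:
        beta = np.array([fixed[p][e] for e in envs])
        yhat_fixed = beta[ei]
        var_f = float(np.var(yhat_fixed))
        sg2, s2 = vc[p]
        mean_v = float(np.mean(stage1[f"var_{p}"]))
        total = var_f + sg2 + s2 + mean_v
        r2[p] = {
            "marginal": var_f / total,
            "conditional": (var_f + sg2) / total,
        }
    diag["determination"] = r2
    return LogisticFitResult(
        n_params=n_params,
        time_axis=time_axis,
        environments=envs,
        genotypes=genos,
        fixed=fixed,
        fixed_cov=fixed_cov,
        random=random_eff,
        variance_components=vc,
        residual_sd=residual_sd,
        stage1=stage1,
        diagnostics=diag,
        log=log,
    )


def growth_speed_curve(fit: LogisticFitResult, environment: str, x) -> np.ndarray:
    """First derivative of the fitted curve in percent of the asymptote per
    time unit; maximal at xmid where it equals 25/scal."""
    x = np.asarray(x, float)
    if fit.n_params == 3:
        xmid = fit.fixed["xmid"][environment]
        scal = fit.fixed["scal"][environment]
    else:
        xmid = fit.fixed["xmid"][environment]
        scal = fit.fixed["scal"][environment]
    p = 1.0 / (1.0 + np.exp((xmid - x) / scal))
    return 100.0 * p * (1.0 - p) / scal


def height_at_time(
    fit: LogisticFitResult, genotype: str, environment: str, x
) -> float | np.ndarray:
    """Genotype-specific curve (fixed + random effects) evaluated at x."""
    pars = fit.params_for(genotype, environment)
    fun = logistic3 if fit.n_params == 3 else logistic4
    out = fun(x, *pars)
    return float(out) if np.ndim(out) == 0 else out


def height_matrix_at(fit: LogisticFitResult, x: float) -> pd.DataFrame:
    """Genotype × environment matrix of modeled trait values at time x."""
    data = {
        env: [height_at_time(fit, g, env, x) for g in fit.genotypes]
        for env in fit.environments
    }
    return pd.DataFrame(data, index=fit.genotypes)


# -- environment clustering ---------------------------------------------------


@dataclass
class ClusterResult:
    environments: list
    linkage: np.ndarray
    leaf_order: list
    merge_heights: np.ndarray
    standardized: pd.DataFrame
    dropped_rows: list

    def cut(self, k: int) -> dict:
        labels = fcluster(self.linkage, k, criterion="maxclust")
        return dict(zip(self.environments, labels.tolist()))


def cluster_environments(height_matrix: pd.DataFrame) -> ClusterResult:
    """Complete-linkage / Manhattan clustering of environments.

    Rows (genotypes) are standardized to mean 0 and sd 1; columns
    (environments) are clustered on the Manhattan distance between their
    standardized profiles.  Constant rows are dropped with a warning.
    """
    if height_matrix.isna().any().any():
        raise ValueError("height matrix must be complete (no missing cells)")
    sd = height_matrix.std(axis=1, ddof=1)
    dropped = list(height_matrix.index[sd == 0.0])
    if dropped:
        warnings.warn(f"dropping constant rows: {dropped}", stacklevel=2)
    mat = height_matrix.loc[sd > 0.0]
    z = mat.sub(mat.mean(axis=1), axis=0).div(mat.std(axis=1, ddof=1), axis=0)
    envs = list(z.columns)
    if len(envs) < 2:
        raise ValueError("need at least two environments to cluster")
    Z = linkage(z.T.to_numpy(), method="complete", metric="cityblock")
    order = [envs[i] for i in leaves_list(Z)]
    return ClusterResult(envs, Z, order, Z[:, 2].copy(), z, dropped)


# -- tasseling ----------------------------------------------------------------


@dataclass
class TasselFitResult:
    params: pd.DataFrame  # per environment: Asym, xmid, scal
    anova_residuals: pd.DataFrame
    anova_fitted: pd.DataFrame
    excluded: list
    log: list


def fit_tassel_model(tassel: pd.DataFrame) -> TasselFitResult:
    """Fixed-effect logistic model of percent tasseling per environment.

    Least-squares logistic per environment (time and cultivation are the fixed
    factors); residuals and fitted values are each analyzed in a two-way ANOVA
    with factors time and cultivation.  Environments with fewer than 4 time
    points are excluded.
    """
    pct = tassel["percent"].to_numpy(float)
    if np.any(pct < 0) or np.any(pct > 100):
        raise ValueError("percentages must lie in [0, 100]")
    log, excluded, rows = [], [], []
    fitted = np.full(len(tassel), np.nan)
    for env, grp in tassel.groupby("environment"):
        grp = grp.sort_values("das")
        if grp["percent"].diff().min() < -1e-9:
            log.append(f"{env}: tassel percentages decrease at some time point")
        if len(grp) < 4:
            excluded.append(env)
            log.append(f"{env}: fewer than 4 time points; excluded")
            continue
        t = grp["das"].to_numpy(float)
        y = grp["percent"].to_numpy(float)
        popt, _, resid = fit_logistic_curve(t, y, n_params=3)
        rows.append(
            {"environment": env, "Asym": popt[0], "xmid": popt[1], "scal": popt[2]}
        )
        fitted[grp.index.to_numpy()] = y - resid
    if not rows:
        raise FitError("no environment could be fit")
    work = tassel.copy()
    work["fitted"] = fitted
    work["resid"] = work["percent"] - work["fitted"]
    work = work[work["fitted"].notna()]
    n_env_fit = work["environment"].nunique()
    df_resid = len(work) - work["das"].nunique() - n_env_fit + 1
    if n_env_fit >= 2 and df_resid > 0:
        an_res = anova_lm(smf.ols("resid ~ C(das) + C(environment)", work).fit(), typ=2)
        an_fit = anova_lm(smf.ols("fitted ~ C(das) + C(environment)", work).fit(), typ=2)
    else:
        an_res = an_fit = pd.DataFrame()
        log.append("two-way ANOVA skipped: saturated design (one cell per factor combination)")
    return TasselFitResult(
        pd.DataFrame(rows).set_index("environment"), an_res, an_fit, excluded, log
    )


# -- repeatability ------------------------------------------------------------


@dataclass
class RepeatabilityResult:
    repeatability: float
    r2_marginal: float
    r2_conditional: float
    variance_components: dict
    residual_variance: float
    boundary: list


def repeatability(
    table: pd.DataFrame, trait: str = "plant_height", transform: str = "sqrt"
) -> RepeatabilityResult:
    """Genotype repeatability across environments.

    REML mixed model on the (square-root-transformed) trait with experiment
    and experiment-time fixed; genotype, genotype × experiment and genotype ×
    experiment-time random.  R_genotype = σ²_genotype / (σ²_genotype + σ²_ε).
    Marginal and conditional determination coefficients follow the standard
    fixed vs fixed+random variance partition.
    """
    if table["experiment"].nunique() < 2 or table["genotype"].nunique() < 2:
        raise DesignError("need at least 2 experiments and 2 genotypes")
    design = DESIGNS["repeatability"]
    validate_design(design, table)
    work = table.copy()
    work["_y"] = np.sqrt(work[trait]) if transform == "sqrt" else work[trait]
    vc_terms = {f"vc{i}": t for i, t in enumerate(design.random_terms)}
    # measurement dates nested within experiments alias the experiment factor;
    # the nested time factor alone spans the same fixed-effect space
    nested = (work.groupby("experiment_time")["experiment"].nunique() == 1).all()
    fixed = (
        "_y ~ C(experiment_time)"
        if nested
        else "_y ~ C(experiment) + C(experiment_time)"
    )
    result = _fit_vc_model(work, fixed, vc_terms)
    vcomp = {
        design.random_terms[i]: float(v) for i, v in enumerate(result.vcomp)
    }
    sigma_g = vcomp["C(genotype)"]
    sigma_e = float(result.scale)
    r = sigma_g / (sigma_g + sigma_e)
    fixed_part = result.model.exog @ result.fe_params
    var_f = float(np.var(fixed_part))
    total = var_f + sum(vcomp.values()) + sigma_e
    scale = max(np.std(work["_y"]), 1e-12)
    boundary = [
        t for t, v in vcomp.items() if np.sqrt(max(v, 0.0)) < BOUNDARY_SD * scale
    ]
    return RepeatabilityResult(
        repeatability=float(r),
        r2_marginal=var_f / total,
        r2_conditional=(var_f + sum(vcomp.values())) / total,
        variance_components=vcomp,
        residual_variance=sigma_e,
        boundary=boundary,
    )


# -- variance decomposition ---------------------------------------------------


@dataclass
class VarianceDecomposition:
    date: object
    shares: dict  # factor -> share of total variance
    ci: dict  # factor -> (lo, hi) bootstrap interval
    n_boot: int
    variance_components: dict

    def total(self) -> float:
        return sum(self.shares.values())


FACTOR_LABELS = {
    "C(preculture)": "preculture",
    "C(column)": "column",
    "C(row)": "row",
    "C(replicate)": "replicate",
    "C(soil)": "soil",
}


def _decomposition_shares(work, vc_terms, design):
    result = _fit_vc_model(work, "_y ~ C(genotype)", vc_terms)
    vcomp = {design.random_terms[i]: float(v) for i, v in enumerate(result.vcomp)}
    fixed_part = result.model.exog @ result.fe_params
    var_g = float(np.var(fixed_part))
    resid = float(result.scale)
    total = var_g + sum(vcomp.values()) + resid
    shares = {"genotype": var_g / total}
    for term, label in FACTOR_LABELS.items():
        shares[label] = vcomp.get(term, 0.0) / total
    shares["residual"] = resid / total
    return shares, vcomp, resid, fixed_part

def variance_decomposition(
    table: pd.DataFrame,
    trait: str = "plant_height",
    date=None,
    date_col: str = "das",
    n_boot: int = 1000,
    seed: int = 0,
) -> VarianceDecomposition:
    """Per-factor variance shares in the homogeneity trial at one date.

    Agreement-repeatability shares: the genotype (fixed-effect) share is the
    variance of the fixed predictions, each positional factor contributes its
    REML variance component, all over the total including the residual; the
    trait is square-root transformed first.  Percentile confidence intervals
    come from a parametric bootstrap (``n_boot`` refits).
    """
    design = DESIGNS["homogeneity"]
    df = table if date is None else table[table[date_col] == date]
    if df.empty:
        raise DesignError(f"no observations at {date_col} == {date}")
    validate_design(design, df)
    work = df.copy().reset_index(drop=True)
    work["_y"] = np.sqrt(work[trait])
    vc_terms = {f"vc{i}": t for i, t in enumerate(design.random_terms)}
    shares, vcomp, resid, fixed_part = _decomposition_shares(work, vc_terms, design)

    rng = np.random.default_rng(np.random.SeedSequence(seed))
    boots: dict = {k: [] for k in shares}
    Zs = {}
    for term in design.random_terms:
        cols = _term_columns(term)
        key = work[cols[0]].astype(str)
        for c in cols[1:]:
            key = key + ":" + work[c].astype(str)
        Zs[term] = pd.get_dummies(key).to_numpy(float)
    for _ in range(n_boot):
        y_star = fixed_part.copy()
        for term, Z in Zs.items():
            sd = np.sqrt(max(vcomp[term], 0.0))
            y_star = y_star + Z @ rng.normal(0.0, sd, Z.shape[1])
        y_star = y_star + rng.normal(0.0, np.sqrt(resid), len(work))
        wb = work.copy()
        wb["_y"] = y_star
        try:
            s, _, _, _ = _decomposition_shares(wb, vc_terms, design)
        except Exception:
            continue
        for k in boots:
            boots[k].append(s[k])
    ci = {
        k: (float(np.percentile(v, 2.5)), float(np.percentile(v, 97.5)))
        if v
        else (np.nan, np.nan)
        for k, v in boots.items()
    }
    return VarianceDecomposition(
        date=date,
        shares=shares,
        ci=ci,
        n_boot=n_boot,
        variance_components={**vcomp, "residual": resid},
    )


# -- yield components ---------------------------------------------------------


@dataclass
class YieldResult:
    trait: str
    blups: pd.DataFrame  # genotype × environment BLUPs (+ grand means)
    env_means: pd.Series
    contrasts: pd.DataFrame  # pairwise Tukey-adjusted environment contrasts
    genotype_variance: dict
    log: list


def _blups_single_env(df, trait, design, log):
    """Genotype BLUPs within one environment: genotype random (+ design terms)."""
    y = df[trait].to_numpy(float)
    vc_terms = {"genotype": "C(genotype)"}
    for i, t in enumerate(design.random_terms):
        vc_terms[f"vc{i}"] = t
    try:
        result = _fit_vc_model(df, f"{trait} ~ 1", vc_terms)
        variances = _vc_variances(result, vc_terms)
        sg2 = variances["genotype"]
        resid = float(result.scale)
    except Exception as exc:
        log.append(f"BLUP fit fell back to genotype means ({exc})")
        means = df.groupby("genotype")[trait].mean()
        return means - means.mean() + means.mean(), 0.0, float(np.var(y))
    # manual BLUP: u = σ²_g Z' V⁻¹ (y − μ̂)
    Z = pd.get_dummies(df["genotype"]).to_numpy(float)
    genos = list(pd.get_dummies(df["genotype"]).columns)
    V = resid * np.eye(len(df)) + sg2 * (Z @ Z.T)
    for i, t in enumerate(design.random_terms):
        cols = _term_columns(t)
        key = df[cols[0]].astype(str)
        for c in cols[1:]:
            key = key + ":" + df[c].astype(str)
        Zf = pd.get_dummies(key).to_numpy(float)
        V += variances[f"vc{i}"] * (Zf @ Zf.T)
    mu = float(result.fe_params.iloc[0])
    u = sg2 * (Z.T @ np.linalg.solve(V, y - mu))
    return pd.Series(mu + u, index=genos), sg2, resid


def yield_components(
    table: pd.DataFrame,
    trait: str,
    designs: dict | DesignSpec,
    tukey_alpha: float = 0.05,
) -> YieldResult:
    """Per-genotype yield BLUPs and Tukey-adjusted environment contrasts.

    BLUPs come from the per-environment design models with genotype random
    (full shrinkage to the grand mean when genotype variance is zero).
    Environment estimated means come from a model with cultivation fixed and
    genotype random; all-pairs contrasts use the studentized-range
    distribution with residual-based degrees of freedom (logged).
    """
    log: list[str] = []
    blup_cols = {}
    gvar = {}
    for env, df_env in table.groupby("environment"):
        df_env = df_env.dropna(subset=[trait])
        if df_env.empty:
            log.append(f"{env}: trait all-missing; environment dropped")
            continue
        design = designs[env] if isinstance(designs, dict) else designs
        blups, sg2, resid = _blups_single_env(
            df_env.reset_index(drop=True), trait, design, log
        )
        blup_cols[env] = blups
        gvar[env] = sg2
    blups = pd.DataFrame(blup_cols)

    # environment means: cultivation fixed, genotype random
    work = table.dropna(subset=[trait]).copy()
    result = _fit_vc_model(
        work, f"{trait} ~ 0 + C(environment)", {"genotype": "C(genotype)"}
    )
    envs = [
        re.match(r"C\(environment\)\[(.+)\]", p).group(1)
        for p in result.fe_params.index
    ]
    means = pd.Series(result.fe_params.to_numpy(float), index=envs)
    cov = np.asarray(result.cov_params())[: len(envs), : len(envs)]
    n_env = len(envs)
    df_resid = len(work) - n_env - work["genotype"].nunique() + 1
    log.append(f"Tukey df = n - n_env - n_genotypes + 1 = {df_resid}")
    rows = []
    for i in range(n_env):
        for j in range(i + 1, n_env):
            diff = means.iloc[i] - means.iloc[j]
            se = float(np.sqrt(cov[i, i] + cov[j, j] - 2 * cov[i, j]))
            q = abs(diff) / (se / np.sqrt(2.0))
            p = float(stats.studentized_range.sf(q, n_env, df_resid))
            qc = stats.studentized_range.ppf(1 - tukey_alpha, n_env, df_resid)
            half = qc * se / np.sqrt(2.0)
            rows.append(
                {
                    "a": envs[i],
                    "b": envs[j],
                    "difference": float(diff),
                    "se": se,
                    "p_tukey": min(p, 1.0),
                    "ci_low": float(diff - half),
                    "ci_high": float(diff + half),
                }
            )
    return YieldResult(trait, blups, means, pd.DataFrame(rows), gvar, log)


# -- parameter contrasts ------------------------------------------------------


def parameter_contrasts(fit: LogisticFitResult, alpha: float = 0.05) -> pd.DataFrame:
    """All pairwise environment differences per logistic parameter.

    Bonferroni correction over the pairs within each parameter family:
    adjusted p = min(1, p × m) and (1 − α/m) confidence intervals.
    """
    envs = fit.environments
    m = len(envs) * (len(envs) - 1) // 2
    if m == 0:
        raise ValueError("need at least 2 environments")
    zcrit = stats.norm.ppf(1 - alpha / (2 * m))
    rows = []
    for p_name in PARAM_NAMES[fit.n_params]:
        beta = np.array([fit.fixed[p_name][e] for e in envs])
        cov = fit.fixed_cov[p_name]
        for i in range(len(envs)):
            for j in range(i + 1, len(envs)):
                diff = beta[i] - beta[j]
                se = float(np.sqrt(cov[i, i] + cov[j, j] - 2 * cov[i, j]))
                z = diff / se if se > 0 else np.inf
                p_raw = 2.0 * stats.norm.sf(abs(z))
                rows.append(
                    {
                        "parameter": p_name,
                        "a": envs[i],
                        "b": envs[j],
                        "difference": float(diff),
                        "se": se,
                        "p_raw": float(p_raw),
                        "p_bonferroni": float(min(1.0, p_raw * m)),
                        "ci_low": float(diff - zcrit * se),
                        "ci_high": float(diff + zcrit * se),
                        "significant": bool(p_raw * m < alpha),
                    }
                )
    return pd.DataFrame(rows)
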