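"""Statistical layer: GLMs for counts and proportions, fit diagnostics,
marginal means with adjusted pairwise contrasts, agreement limits,
variance-component repeatability, within-group dispersion, and PCA.

Model fitting is delegated to statsmodels; this module owns the model
formulas, the link-selection rule, the diagnostics the pipeline reports
(Hosmer-Lemeshow, Nagelkerke pseudo-R^2, likelihood-ratio tests), and the
variance-component arithmetic behind repeatability.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats as sps
from statsmodels.regression.mixed_linear_model import MixedLM

COUNT_FORMULA = (
    "total_objects ~ C(variety) + C(processing_method) "
    "+ legume_fruit_pod_mass_g + C(variety):C(processing_method)"
)


@dataclass
class GLMFit:
    """A fitted GLM plus the quantities the pipeline reports."""

    link: str
    coefficients: pd.Series
    log_likelihood: float
    null_log_likelihood: float
    fitted: np.ndarray
    n_observations: int
    result: object  # underlying statsmodels results
    rmse: float | None = None
    mae: float | None = None
    extra: dict = field(default_factory=dict)


def _check_rank(model) -> None:
    X = np.asarray(model.exog)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # name the aliased columns: those whose removal does not drop the rank
        names = list(model.exog_names)
        aliased = []
        for j in range(X.shape[1]):
            Xj = np.delete(X, j, axis=1)
            if np.linalg.matrix_rank(Xj) == rank:
                aliased.append(names[j])
        raise ValueError(f"rank-deficient design; aliased terms: {aliased}")


def fit_count_model(
    data: pd.DataFrame,
    link: str,
    holdout: np.ndarray | None = None,
    formula: str = COUNT_FORMULA,
) -> GLMFit:
    """Fit the total-object-count GLM with a Gaussian-identity or Poisson-log
    link; report holdout RMSE and MAE when a holdout mask is given.

    ``holdout`` is a boolean mask over rows: True rows are held out of the
    fit and used only for the error metrics. Without a mask the model is
    fit on all rows (the refit step after link selection).
    """
    if link == "gaussian_identity":
        family = sm.families.Gaussian()
    elif link == "poisson_log":
        family = sm.families.Poisson()
    else:
        raise ValueError(f"unknown link {link!r}")

    train = data if holdout is None else data.loc[~holdout]
    model = smf.glm(formula, data=train, family=family)
    _check_rank(model)
    res = model.fit()
    null_res = smf.glm("total_objects ~ 1", data=train, family=family).fit()

    rmse = mae = None
    if holdout is not None and holdout.any():
        test = data.loc[holdout]
        pred = res.predict(test)
        err = np.asarray(test["total_objects"] - pred, dtype=float)
        rmse = float(np.sqrt(np.mean(err**2)))
        mae = float(np.mean(np.abs(err)))

    return GLMFit(
        link=link,
        coefficients=res.params,
        log_likelihood=float(res.llf),
        null_log_likelihood=float(null_res.llf),
        fitted=np.asarray(res.fittedvalues),
        n_observations=int(res.nobs),
        result=res,
        rmse=rmse,
        mae=mae,
    )


def select_count_model(
    data: pd.DataFrame,
    holdout: np.ndarray,
    formula: str = COUNT_FORMULA,
) -> tuple[GLMFit, pd.DataFrame]:
    """Fit Gaussian and Poisson count models, pick the better on holdout
    error, and refit the winner on all rows.

    Selection rule: prefer the link that is no worse on both RMSE and MAE;
    if the metrics disagree, RMSE decides. Returns the refit winner and the
    per-link comparison table.
    """
    fits = {
        link: fit_count_model(data, link, holdout, formula)
        for link in ("gaussian_identity", "poisson_log")
    }
    g, p = fits["gaussian_identity"], fits["poisson_log"]
    winner = "gaussian_identity" if g.rmse <= p.rmse else "poisson_log"
    comparison = pd.DataFrame(
        {
            "link": [g.link, p.link],
            "rmse": [g.rmse, p.rmse],
            "mae": [g.mae, p.mae],
            "selected": [winner == g.link, winner == p.link],
        }
    )
    refit = fit_count_model(data, winner, holdout=None, formula=formula)
    refit.rmse, refit.mae = fits[winner].rmse, fits[winner].mae
    refit.extra["comparison"] = comparison
    return refit, comparison


def anova_type1(data: pd.DataFrame, formula: str = COUNT_FORMULA) -> pd.DataFrame:
    """Sequential (type I) ANOVA table for the Gaussian count model."""
    ols_res = smf.ols(formula, data=data).fit()
    return sm.stats.anova_lm(ols_res, typ=1)


def fit_proportion_model(
    data: pd.DataFrame,
    response: str,
    total_col: str = "total_objects",
    formula_rhs: str = "C(variety) + C(processing_method) + legume_fruit_pod_mass_g",
) -> GLMFit:
    """Binomial-logit GLM for a class proportion, weighted by sample totals.

    ``response`` is a proportion column in [0,1]; each observation is
    weighted by its total object count (fractional totals from the SS/2
    rule are allowed). Reports the likelihood-ratio test against the
    intercept-only null and a complete-separation diagnostic.
    """
    y = np.asarray(data[response], dtype=float)
    if np.any((y < 0) | (y > 1)):
        raise ValueError(f"{response} must lie in [0,1]")
    w = np.asarray(data[total_col], dtype=float)
    model = smf.glm(
        f"{response} ~ {formula_rhs}",
        data=data,
        family=sm.families.Binomial(),
        var_weights=w,
    )
    _check_rank(model)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = model.fit()
        null_res = smf.glm(
            f"{response} ~ 1", data=data, family=sm.families.Binomial(), var_weights=w
        ).fit()

    lr = float(null_res.deviance - res.deviance)
    df = int(res.df_model)
    lrt_p = float(sps.chi2.sf(lr, df))

    mu = np.asarray(res.fittedvalues)
    separated = bool(
        np.all(y == 1) or np.all(y == 0)
        or np.any(np.abs(res.params) > 15)
        or np.any((mu < 1e-10) | (mu > 1 - 1e-10))
    )
    if separated:
        warnings.warn(
            f"proportion model for {response!r}: possible complete separation "
            "(coefficients or fitted probabilities at the boundary)",
            stacklevel=2,
        )

    fit = GLMFit(
        link="binomial_logit",
        coefficients=res.params,
        log_likelihood=float(res.llf),
        null_log_likelihood=float(null_res.llf),
        fitted=mu,
        n_observations=int(res.nobs),
        result=res,
    )
    fit.extra.update(
        lrt_stat=lr, lrt_df=df, lrt_p=lrt_p, separation=separated,
        nagelkerke_r2=nagelkerke_r2(fit.log_likelihood, fit.null_log_likelihood,
                                    fit.n_observations),
    )
    return fit


def hosmer_lemeshow(
    observed: np.ndarray,
    totals: np.ndarray,
    fitted_probs: np.ndarray,
    g: int = 10,
) -> tuple[float, int, float]:
    """Hosmer-Lemeshow goodness-of-fit test with deciles-of-risk grouping.

    Observations are sorted by fitted probability and split into ``g``
    near-equal groups; within each, O = observed successes, E = expected
    successes, n = trials, and the statistic is
    sum (O - E)^2 / (E * (1 - E/n)) with g - 2 degrees of freedom. When
    there are fewer distinct fitted values than groups, g is reduced with a
    warning.
    """
    observed = np.asarray(observed, dtype=float)
    totals = np.asarray(totals, dtype=float)
    fitted_probs = np.asarray(fitted_probs, dtype=float)
    if g < 3:
        raise ValueError("need at least 3 groups")
    if np.any((fitted_probs <= 0) | (fitted_probs >= 1)):
        raise ValueError("fitted probabilities must lie in (0,1)")
    n_distinct = len(np.unique(fitted_probs))
    if n_distinct < g:
        warnings.warn(
            f"only {n_distinct} distinct fitted values; reducing g from {g}",
            stacklevel=2,
        )
        g = max(3, n_distinct)

    order = np.argsort(fitted_probs, kind="stable")
    groups = np.array_split(order, g)
    chi2 = 0.0
    for idx in groups:
        O = observed[idx].sum()
        E = (totals[idx] * fitted_probs[idx]).sum()
        n_g = totals[idx].sum()
        denom = E * (1.0 - E / n_g)
        if denom > 0:
            chi2 += (O - E) ** 2 / denom
    df = g - 2
    return float(chi2), df, float(sps.chi2.sf(chi2, df))


def nagelkerke_r2(ll_model: float, ll_null: float, n: int) -> float:
    """Nagelkerke's pseudo-R^2: Cox-Snell R^2 rescaled to a [0,1] maximum."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if ll_model < ll_null:
        raise ValueError("ll_model must be >= ll_null for a nested null")
    if ll_null == 0:
        raise ValueError("undefined for a saturated null (ll_null = 0)")
    cox_snell = 1.0 - np.exp((2.0 / n) * (ll_null - ll_model))
    return float(cox_snell / (1.0 - np.exp((2.0 / n) * ll_null)))


# ---------------------------------------------------------------------------
# Estimated marginal means and adjusted pairwise contrasts
# ---------------------------------------------------------------------------

def emm_pairwise(
    fit: GLMFit,
    data: pd.DataFrame,
    factor: str,
    adjust: str = "single-step",
    n_mc: int = 40_000,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Estimated marginal means for one factor, plus adjusted all-pairs
    contrasts.

    Means are model predictions averaged over the reference grid (the
    observed combinations of the other model variables), computed on the
    link scale and back-transformed to the response scale with delta-method
    SEs. Contrasts are tested on the link scale; the single-step
    multiplicity adjustment uses the joint distribution of the contrast
    statistics (multivariate t for Gaussian fits, normal limit otherwise),
    evaluated by seeded Monte Carlo; ``adjust="bonferroni"`` is the labeled
    fallback.
    """
    res = fit.result
    levels = list(pd.unique(data[factor]))
    other_cols = [c for c in data.columns if c != factor]

    import patsy

    L_rows = []
    for lev in levels:
        grid = data[other_cols].copy()
        grid[factor] = lev
        X = patsy.dmatrix(res.model.data.design_info, grid, return_type="dataframe")
        L_rows.append(np.asarray(X).mean(axis=0))
    L = np.vstack(L_rows)

    beta = np.asarray(res.params)
    cov = np.asarray(res.cov_params())
    eta = L @ beta
    eta_se = np.sqrt(np.einsum("ij,jk,ik->i", L, cov, L))

    if fit.link == "binomial_logit":
        mean = 1.0 / (1.0 + np.exp(-eta))
        mean_se = mean * (1.0 - mean) * eta_se  # delta method
    else:
        mean, mean_se = eta, eta_se
    emm = pd.DataFrame(
        {factor: levels, "emmean": mean, "se": mean_se,
         "link_estimate": eta, "link_se": eta_se}
    )

    # all pairwise contrasts on the link scale
    pairs = [(i, j) for i in range(len(levels)) for j in range(i + 1, len(levels))]
    if not pairs:
        return emm, pd.DataFrame()
    C = np.array([L[i] - L[j] for i, j in pairs])
    est = C @ beta
    vcc = C @ cov @ C.T
    se = np.sqrt(np.diag(vcc))
    t_stat = est / se

    df_resid = getattr(res, "df_resid", np.inf)
    use_t = fit.link == "gaussian_identity" and np.isfinite(df_resid)

    if adjust == "bonferroni":
        if use_t:
            p_raw = 2 * sps.t.sf(np.abs(t_stat), df_resid)
        else:
            p_raw = 2 * sps.norm.sf(np.abs(t_stat))
        p_adj = np.minimum(1.0, p_raw * len(pairs))
        method = "bonferroni"
    elif adjust == "single-step":
        corr = vcc / np.outer(se, se)
        rng = np.random.default_rng(seed)
        # sample the joint null distribution of the contrast statistics
        w, V = np.linalg.eigh(corr)
        A = V @ np.diag(np.sqrt(np.clip(w, 0.0, None)))
        Z = rng.standard_normal((n_mc, len(pairs))) @ A.T
        if use_t:
            Z = Z / np.sqrt(rng.chisquare(df_resid, size=(n_mc, 1)) / df_resid)
        max_abs = np.max(np.abs(Z), axis=1)
        p_adj = np.array([np.mean(max_abs >= abs(t)) for t in t_stat])
        method = "single-step (mvt)" if use_t else "single-step (mvn)"
    else:
        raise ValueError(f"unknown adjustment {adjust!r}")

    contrasts = pd.DataFrame(
        {
            "level_1": [levels[i] for i, _ in pairs],
            "level_2": [levels[j] for _, j in pairs],
            "estimate": est,
            "se": se,
            "statistic": t_stat,
            "p_adjusted": p_adj,
            "adjustment": method,
        }
    )
    return emm, contrasts


def bland_altman(truth, prediction) -> tuple[float, float, float]:
    """Bland-Altman agreement: mean difference and 95% limits of agreement.

    Differences are prediction - truth; limits are mean +/- 1.96 * sample
    SD of the differences.
    """
    truth = np.asarray(truth, dtype=float)
    prediction = np.asarray(prediction, dtype=float)
    if truth.shape != prediction.shape or truth.size < 2:
        raise ValueError("need two equal-length vectors of length >= 2")
    d = prediction - truth
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    return mean, mean - 1.96 * sd, mean + 1.96 * sd


# ---------------------------------------------------------------------------
# Variance components and repeatability
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class VarianceComponents:
    """Genotype / environment / GxE / residual variances with replication."""

    sigma2_g: float
    sigma2_e: float
    sigma2_gxe: float
    sigma2_resid: float
    r: int  # replicates per genotype-environment cell
    e: int  # number of environments

    def __post_init__(self) -> None:
        if min(self.sigma2_g, self.sigma2_e, self.sigma2_gxe, self.sigma2_resid) < 0:
            raise ValueError("variance components must be non-negative")
        if self.r < 1 or self.e < 1:
            raise ValueError("r and e must be >= 1")


def repeatability(vc: VarianceComponents) -> float:
    """R = s2_G / (s2_G + s2_E/e + s2_GxE/e + s2_resid/(r*e)).

    The entry-mean repeatability of a genotype across e environments with r
    replicates per cell; an upper bound on broad-sense heritability here.
    """
    denom = (
        vc.sigma2_g
        + vc.sigma2_e / vc.e
        + vc.sigma2_gxe / vc.e
        + vc.sigma2_resid / (vc.r * vc.e)
    )
    if denom == 0:
        raise ValueError("all variance components are zero")
    return vc.sigma2_g / denom


def estimate_variance_components(
    data: pd.DataFrame,
    response: str,
    genotype_col: str = "variety",
    env_col: str = "environment",
    method: str = "reml",
) -> VarianceComponents:
    """Estimate (s2_G, s2_E, s2_GxE, s2_resid) from a genotype x environment
    table with replication.

    ``method="reml"`` fits a mixed model with genotype, environment and
    their interaction as crossed random effects (statsmodels MixedLM
    variance components). ``method="moments"`` uses the expected-mean-squares
    solution, exact for balanced designs; negative estimates are truncated
    at zero with a warning. For exactly balanced data the two agree.
    """
    g_levels = data[genotype_col].nunique()
    e_levels = data[env_col].nunique()
    if e_levels < 2 or g_levels < 2:
        raise ValueError(
            f"need >=2 genotypes and >=2 environments, got {g_levels} x {e_levels}"
        )
    cell_sizes = data.groupby([genotype_col, env_col], observed=True).size()
    r = int(round(cell_sizes.mean()))

    if method == "moments":
        s2 = _vc_moments(data, response, genotype_col, env_col)
    elif method == "reml":
        df = data[[response, genotype_col, env_col]].copy()
        df["_one"] = 1
        vcf = {
            "G": f"0 + C({genotype_col})",
            "E": f"0 + C({env_col})",
            "GxE": f"0 + C({genotype_col}):C({env_col})",
        }
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = MixedLM.from_formula(
                f"{response} ~ 1", groups="_one", vc_formula=vcf, re_formula="0",
                data=df,
            )
            res = model.fit(reml=True, method="lbfgs", maxiter=500)
        names = list(model.exog_vc.names)
        vcomp = dict(zip(names, np.asarray(res.vcomp)))
        s2 = (
            float(vcomp["G"]), float(vcomp["E"]), float(vcomp["GxE"]),
            float(res.scale),
        )
    else:
        raise ValueError(f"unknown method {method!r}")

    return VarianceComponents(
        sigma2_g=s2[0], sigma2_e=s2[1], sigma2_gxe=s2[2], sigma2_resid=s2[3],
        r=r, e=e_levels,
    )


def _vc_moments(data, response, genotype_col, env_col):
    """Expected-mean-squares solution for the balanced two-way random model."""
    y = data[response]
    G = data[genotype_col].nunique()
    E = data[env_col].nunique()
    cell = data.groupby([genotype_col, env_col], observed=True)[response]
    sizes = cell.size()
    if sizes.nunique() != 1:
        warnings.warn(
            "design not exactly balanced; method-of-moments estimates are "
            "approximate (using the mean cell size)", stacklevel=2,
        )
    r = float(sizes.mean())
    grand = y.mean()
    g_means = data.groupby(genotype_col, observed=True)[response].mean()
    e_means = data.groupby(env_col, observed=True)[response].mean()
    cell_means = cell.mean()

    ss_g = r * E * ((g_means - grand) ** 2).sum()
    ss_e = r * G * ((e_means - grand) ** 2).sum()
    interaction = (
        cell_means
        - g_means.reindex(cell_means.index.get_level_values(0)).to_numpy()
        - e_means.reindex(cell_means.index.get_level_values(1)).to_numpy()
        + grand
    )
    ss_gxe = r * (interaction**2).sum()
    fitted_cell = cell_means.reindex(
        pd.MultiIndex.from_arrays([data[genotype_col], data[env_col]])
    ).to_numpy()
    ss_resid = ((y.to_numpy() - fitted_cell) ** 2).sum()

    ms_g = ss_g / (G - 1)
    ms_e = ss_e / (E - 1)
    ms_gxe = ss_gxe / ((G - 1) * (E - 1))
    df_resid = len(y) - G * E
    ms_resid = ss_resid / df_resid if df_resid > 0 else 0.0

    s2_resid = ms_resid
    s2_gxe = (ms_gxe - ms_resid) / r
    s2_g = (ms_g - ms_gxe) / (r * E)
    s2_e = (ms_e - ms_gxe) / (r * G)
    out = []
    for name, v in (("G", s2_g), ("E", s2_e), ("GxE", s2_gxe), ("resid", s2_resid)):
        if v < 0:
            warnings.warn(
                f"negative moment estimate for sigma2_{name} truncated to 0",
                stacklevel=3,
            )
            v = 0.0
        out.append(float(v))
    return tuple(out)


# ---------------------------------------------------------------------------
# Dispersion and ordination
# ---------------------------------------------------------------------------

def twgss(points: np.ndarray, labels: np.ndarray) -> float:
    """Total within-group sum of squares: sum of squared distances of each
    point to its group centroid (the k-means objective)."""
    points = np.atleast_2d(np.asarray(points, dtype=float))
    labels = np.asarray(labels)
    if len(labels) != points.shape[0]:
        raise ValueError("one label per point required")
    if len(labels) == 0:
        raise ValueError("empty input")
    total = 0.0
    for lab in np.unique(labels):
        grp = points[labels == lab]
        total += float(((grp - grp.mean(axis=0)) ** 2).sum())
    return total


@dataclass
class PCAResult:
    scores: pd.DataFrame
    loadings: pd.DataFrame
    variance_explained: np.ndarray
    dropped_columns: list


def pca_biplot(traits: pd.DataFrame) -> PCAResult:
    """PCA of a trait matrix: centre, scale to unit variance, SVD.

    Zero-variance columns are dropped with a warning. Signs are fixed by
    forcing the largest-magnitude loading of each component positive.
    """
    X = traits.astype(float)
    if X.isna().any().any():
        raise ValueError("missing values; exclude degenerate samples upstream")
    sd = X.std(ddof=1)
    dropped = list(sd.index[sd == 0])
    if dropped:
        warnings.warn(f"dropping zero-variance column(s) {dropped}", stacklevel=2)
        X = X.drop(columns=dropped)
    if X.shape[1] < 2 or X.shape[0] < 3:
        raise ValueError("need >= 2 variables and >= 3 observations")
    Z = (X - X.mean()) / X.std(ddof=1)
    U, S, Vt = np.linalg.svd(Z.to_numpy(), full_matrices=False)
    # deterministic sign: largest-|loading| entry of each component positive
    for k in range(Vt.shape[0]):
        j = np.argmax(np.abs(Vt[k]))
        if Vt[k, j] < 0:
            Vt[k] *= -1.0
            U[:, k] *= -1.0
    scores = U * S
    var = S**2 / (S**2).sum()
    comp = [f"PC{k + 1}" for k in range(len(S))]
    return PCAResult(
        scores=pd.DataFrame(scores, index=X.index, columns=comp),
        loadings=pd.DataFrame(Vt.T, index=X.columns, columns=comp),
        variance_explained=var,
        dropped_columns=dropped,
    )
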