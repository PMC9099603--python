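"""Inferential layer: reliability, mixed models, and the within-/between-bird
decomposition of effort-mass associations.

Three tools cover the study's inference needs:

* **ICC(2,1)** — intraclass correlation from a two-way random-effects model,
  single measurement, absolute agreement, with an F-based 95% CI. Used to
  quantify between-day reliability of per-bird measurements (birds are
  subjects, days are "raters").
* **Random-intercept linear mixed models** fitted by REML, with sex as a
  fixed covariate (female reference) and Satterthwaite denominator degrees
  of freedom for fixed-effect F tests. Fitting is delegated to statsmodels
  ``MixedLM``; the Satterthwaite df are computed here from the analytic
  random-intercept covariance structure.
* **Within-subject centring** (van de Pol & Wright): a predictor is split
  into a within-bird component (observation minus bird mean) and a
  between-bird component (bird mean). Model 2 regresses on both components;
  model 3 keeps the raw predictor plus the between component, whose
  coefficient then equals the between-within difference — a direct test of
  whether plastic and stable effects differ.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.formula.api as smf
from statsmodels.tools.sm_exceptions import ConvergenceWarning

__all__ = [
    "IccResult",
    "FixedEffect",
    "MixedModelResult",
    "ThreeModelResult",
    "PearsonResult",
    "icc_single_absolute",
    "reliability_matrix",
    "fit_random_intercept_model",
    "within_between_decompose",
    "fit_three_model_sequence",
    "pearson_corr",
]


# ---------------------------------------------------------------------------
# ICC

@dataclass
class IccResult:
    icc: float
    ci_low: float
    ci_high: float
    n_subjects: int
    k_raters: int


def reliability_matrix(data: pd.DataFrame, value: str, *,
                       subject: str = "bird_id",
                       rater: str = "day") -> pd.DataFrame:
    """Pivot a long table to the subjects x raters matrix ICC expects."""
    return data.pivot_table(index=subject, columns=rater, values=value,
                            aggfunc="mean")


def icc_single_absolute(matrix: pd.DataFrame | np.ndarray, *,
                        alpha: float = 0.05) -> IccResult:
    """ICC(2,1): two-way random effects, single measurement, absolute agreement.

    Rows are subjects (birds), columns raters (days). Rows containing missing
    values are dropped (listwise complete cases). The point estimate comes
    from the two-way ANOVA mean squares,

        ICC = (MSR - MSE) / (MSR + (k-1) MSE + (k/n)(MSC - MSE)),

    and the CI follows the standard F-based construction for this form.
    Raises ``ValueError`` for matrices smaller than 2x2 after missing-data
    handling or with zero total variance (ICC undefined).
    """
    X = np.asarray(matrix, dtype=float)
    X = X[~np.isnan(X).any(axis=1)]
    n, k = X.shape if X.ndim == 2 else (0, 0)
    if n < 2 or k < 2:
        raise ValueError("ICC needs a complete-case matrix of at least 2x2")
    grand = X.mean()
    if np.allclose(X, grand):
        raise ValueError("ICC undefined: zero total variance")
    row_means = X.mean(axis=1)
    col_means = X.mean(axis=0)
    ssr = k * ((row_means - grand) ** 2).sum()
    ssc = n * ((col_means - grand) ** 2).sum()
    sst = ((X - grand) ** 2).sum()
    sse = sst - ssr - ssc
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))

    icc = (msr - mse) / (msr + (k - 1) * mse + k / n * (msc - mse))

    # F-based CI (two-way random, absolute agreement, single measure)
    a = k * icc / (n * (1.0 - icc)) if icc < 1.0 else np.inf
    b = 1.0 + k * icc * (n - 1) / (n * (1.0 - icc)) if icc < 1.0 else np.inf
    if np.isfinite(a):
        v_num = (a * msc + b * mse) ** 2
        v_den = ((a * msc) ** 2 / (k - 1)
                 + (b * mse) ** 2 / ((n - 1) * (k - 1)))
        v = v_num / v_den
    else:
        v = (n - 1) * (k - 1)
    f_l = scipy.stats.f.ppf(1 - alpha / 2, n - 1, v)
    f_u = scipy.stats.f.ppf(1 - alpha / 2, v, n - 1)
    lower = (n * (msr - f_l * mse)
             / (f_l * (k * msc + (k * n - k - n) * mse) + n * msr))
    upper = (n * (f_u * msr - mse)
             / (k * msc + (k * n - k - n) * mse + n * f_u * msr))
    return IccResult(icc=float(icc), ci_low=float(lower),
                     ci_high=float(upper), n_subjects=n, k_raters=k)


# ---------------------------------------------------------------------------
# Mixed models

@dataclass
class FixedEffect:
    name: str
    beta: float
    se: float
    F: float
    df_num: int
    df_den: float
    p: float


@dataclass
class MixedModelResult:
    fixed_effects: list[FixedEffect]
    var_bird: float       # random-intercept variance
    var_resid: float
    method: str           # "REML"
    df_method: str        # "satterthwaite"
    n_obs: int
    n_groups: int

    def effect(self, name: str) -> FixedEffect:
        for fe in self.fixed_effects:
            if fe.name == name:
                return fe
        raise KeyError(name)

    def beta(self, name: str) -> float:
        return self.effect(name).beta


def _term_to_patsy(term: str) -> str:
    # Sex enters with female as the reference level so betas report the
    # male-female contrast.
    if term == "sex":
        return "C(sex, Treatment('F'))"
    return f"Q('{term}')"


def _clean_name(name: str) -> str:
    if name.startswith("C(sex"):
        return "sex_M"
    if name.startswith("Q('") and name.endswith("')"):
        return name[3:-2]
    return name


def _satterthwaite_dfs(X: np.ndarray, y: np.ndarray,
                       group_codes: np.ndarray,
                       sb2: float, se2: float) -> np.ndarray:
    """Satterthwaite denominator df for each coefficient of a random-intercept LMM.

    Uses the analytic marginal covariance Sigma = se2*I + sb2*Z Z' (Z the
    group indicator), the GLS coefficient covariance C = (X' Sigma^-1 X)^-1,
    the gradient of each c'Cc with respect to theta = (sb2, se2), and the
    observed REML information of theta (the negative Hessian of the
    restricted log-likelihood, the convention lmerTest uses):

        df_j = 2 (c'Cc)^2 / (g_j' O^-1 g_j).

    Dense linear algebra; intended for cohort-scale data (n up to a few
    thousand observations).
    """
    n, p = X.shape
    Z = np.zeros((n, group_codes.max() + 1))
    Z[np.arange(n), group_codes] = 1.0
    ZZt = Z @ Z.T
    sigma = se2 * np.eye(n) + sb2 * ZZt
    sigma_inv = np.linalg.inv(sigma)
    XtSi = X.T @ sigma_inv
    C = np.linalg.inv(XtSi @ X)
    P = sigma_inv - XtSi.T @ C @ XtSi

    sigma_dots = [ZZt, np.eye(n)]
    # gradient of c'Cc wrt each variance parameter, per coefficient
    grads = np.empty((p, 2))
    for k, Sd in enumerate(sigma_dots):
        M = XtSi @ Sd @ XtSi.T        # X' Si Sd Si X
        CMC = C @ M @ C
        grads[:, k] = np.diag(CMC)
    # observed REML information of (sb2, se2); Sigma is linear in theta so
    # second derivatives of Sigma vanish
    Py = P @ y
    PSd = [P @ Sd for Sd in sigma_dots]
    info = np.empty((2, 2))
    for j in range(2):
        for k in range(2):
            quad = Py @ sigma_dots[j] @ P @ sigma_dots[k] @ Py
            info[j, k] = quad - 0.5 * np.trace(PSd[j] @ PSd[k])
    info = 0.5 * (info + info.T)
    cov_theta = np.linalg.pinv(info)
    dfs = np.empty(p)
    for j in range(p):
        var_c = C[j, j]
        denom = grads[j] @ cov_theta @ grads[j]
        dfs[j] = 2.0 * var_c ** 2 / denom if denom > 0 else n - p
    return dfs


def fit_random_intercept_model(data: pd.DataFrame, response: str,
                               fixed: tuple[str, ...] | list[str], *,
                               group: str = "bird_id") -> MixedModelResult:
    """REML random-intercept LMM with Satterthwaite fixed-effect inference.

    ``fixed`` is a list of column names; ``"sex"`` is coded with female as
    the reference level. Rows with missing response or predictors are
    dropped. Singular fits (zero bird variance) are floored at zero with a
    warning rather than failing.
    """
    cols = [response, group] + [t for t in fixed]
    df = data[cols].dropna().reset_index(drop=True)
    if df[group].nunique() < 2:
        raise ValueError("need at least 2 subjects")
    rhs = " + ".join(_term_to_patsy(t) for t in fixed) if fixed else "1"
    formula = f"Q('{response}') ~ {rhs}"
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        warnings.simplefilter("ignore", RuntimeWarning)
        warnings.simplefilter("ignore", UserWarning)
        model = smf.mixedlm(formula, df, groups=df[group])
        res = model.fit(reml=True)
    sb2 = max(float(np.asarray(res.cov_re)[0, 0]), 0.0)
    se2 = max(float(res.scale), 1e-12)

    X = np.asarray(model.exog, dtype=float)
    y = np.asarray(model.endog, dtype=float)
    codes = pd.Categorical(df[group]).codes.astype(int)
    dfs_satt = _satterthwaite_dfs(X, y, codes, sb2, se2)

    # GLS covariance at the fitted variances (consistent with the df calc)
    n = len(df)
    Z = np.zeros((n, codes.max() + 1))
    Z[np.arange(n), codes] = 1.0
    sigma = se2 * np.eye(n) + sb2 * (Z @ Z.T)
    C = np.linalg.inv(X.T @ np.linalg.solve(sigma, X))

    effects = []
    for j, name in enumerate(model.exog_names):
        beta = float(res.fe_params.iloc[j])
        se = float(np.sqrt(C[j, j]))
        df_den = float(dfs_satt[j])
        fstat = (beta / se) ** 2 if se > 0 else 0.0
        pval = float(scipy.stats.f.sf(fstat, 1, df_den)) if se > 0 else 1.0
        effects.append(FixedEffect(name=_clean_name(name), beta=beta, se=se,
                                   F=float(fstat), df_num=1, df_den=df_den,
                                   p=pval))
    return MixedModelResult(fixed_effects=effects, var_bird=sb2,
                            var_resid=se2, method="REML",
                            df_method="satterthwaite", n_obs=n,
                            n_groups=int(df[group].nunique()))


# ---------------------------------------------------------------------------
# Within/between decomposition

def within_between_decompose(data: pd.DataFrame, predictor: str, *,
                             subject: str = "bird_id") -> pd.DataFrame:
    """Split ``predictor`` into within- and between-subject components.

    Adds ``{predictor}_within`` (observation minus subject mean) and
    ``{predictor}_between`` (subject mean, repeated per observation). The
    two sum to the original predictor exactly, row by row, and the within
    component has mean zero for every subject.
    """
    out = data.copy()
    means = out.groupby(subject)[predictor].transform("mean")
    out[f"{predictor}_between"] = means
    out[f"{predictor}_within"] = out[predictor] - means
    return out


@dataclass
class ThreeModelResult:
    """Raw, decomposed, and difference-parameterised mixed models.

    ``raw`` regresses the response on the raw predictor; ``decomposed`` on
    the within and between components; ``difference`` on the raw predictor
    plus the between component, whose coefficient equals the between-within
    difference. ``identity_max_abs_diff`` records how closely the two
    algebraic identities linking model 3 to model 2 hold on this fit.
    """

    raw: MixedModelResult
    decomposed: MixedModelResult
    difference: MixedModelResult
    predictor: str
    identity_max_abs_diff: float


def fit_three_model_sequence(data: pd.DataFrame, response: str,
                             predictor: str, *,
                             covariates: tuple[str, ...] = ("sex",),
                             group: str = "bird_id") -> ThreeModelResult:
    """Fit the three-model within/between sequence for one predictor.

    Model 1: response ~ predictor (+ covariates); model 2 replaces the
    predictor by its within- and between-subject components; model 3 keeps
    the raw predictor and adds the between component. Because models 2 and 3
    span the same column space, model 3's raw-predictor coefficient must
    equal model 2's within coefficient and model 3's between coefficient
    must equal model 2's (between - within); the realised maximum deviation
    is reported so callers can verify the fits agree numerically.
    """
    dec = within_between_decompose(data, predictor, subject=group)
    w, b = f"{predictor}_within", f"{predictor}_between"
    m1 = fit_random_intercept_model(dec, response, [predictor, *covariates],
                                    group=group)
    # With no between-subject variance the between component is collinear
    # with the intercept: drop it (models 2 and 3 then coincide with the
    # within-only parameterisation and model 1 respectively).
    subject_means = dec.groupby(group)[predictor].mean()
    if float(subject_means.var(ddof=0)) < 1e-12:
        warnings.warn("between-subject component has zero variance; "
                      "dropped from models 2 and 3", stacklevel=2)
        m2 = fit_random_intercept_model(dec, response, [w, *covariates],
                                        group=group)
        m3 = m1
        d = abs(m3.beta(predictor) - m2.beta(w))
        return ThreeModelResult(raw=m1, decomposed=m2, difference=m3,
                                predictor=predictor,
                                identity_max_abs_diff=float(d))
    m2 = fit_random_intercept_model(dec, response, [w, b, *covariates],
                                    group=group)
    m3 = fit_random_intercept_model(dec, response, [predictor, b, *covariates],
                                    group=group)
    d1 = abs(m3.beta(predictor) - m2.beta(w))
    d2 = abs(m3.beta(b) - (m2.beta(b) - m2.beta(w)))
    return ThreeModelResult(raw=m1, decomposed=m2, difference=m3,
                            predictor=predictor,
                            identity_max_abs_diff=float(max(d1, d2)))


# ---------------------------------------------------------------------------
# Correlation

@dataclass
class PearsonResult:
    r: float
    df: int
    p: float


def pearson_corr(x: np.ndarray | pd.Series,
                 y: np.ndarray | pd.Series) -> PearsonResult:
    """Product-moment correlation with df = n - 2.

    Raises ``ValueError`` for fewer than 3 pairs or zero variance in either
    input (r undefined).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need equal-length inputs with n >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("correlation undefined: zero variance")
    r, p = scipy.stats.pearsonr(x, y)
    return PearsonResult(r=float(r), df=len(x) - 2, p=float(p))
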