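"""Statistical models on the association pipeline outputs.

Three fits:

* a Gaussian linear mixed model of z-standardized association with
  kin category, six-month age bin and their interaction as fixed
  effects and crossed random intercepts for father, mother and infant
  identity (one fit per comparison approach, within- or between-period);
* single-step-adjusted father-vs-non-kin contrasts within each age
  bin (the family is the seven within-bin comparisons);
* a binomial (logit) model of whether the same male sired the mother's
  next offspring, with the father's 18-month standardized association
  and his ordinal rank at conception as predictors and mother/father
  random intercepts.

Estimation is delegated to statsmodels (REML via ``MixedLM`` for the
Gaussian model; a Laplace/MAP fit of ``BinomialBayesMixedGLM`` with a
diffuse prior for the binomial model).  This module owns model
construction, filters, contrasts and reporting, not the optimizers.
Wald F statistics use a residual-type denominator degrees of freedom
(n minus the number of fixed-effect columns); with the sample sizes
this pipeline produces the F and chi-square scales are practically
indistinguishable.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
import numpy as np
import pandas as pd
import patsy
from scipy import stats

logger = logging.getLogger(__name__)

ASSOCIATION_FORMULA = "z ~ C(kin, Treatment('NON_KIN')) * C(age_bin)"
PATERNITY_FORMULA = "same_sire ~ z + rank"

_ADJUST_DRAWS = 100_000
_ADJUST_SEED = 20_401  # fixed: the adjustment must be deterministic


@dataclass
class AssociationFit:
    """Summary of the Gaussian mixed model of standardized association."""

    formula: str
    backend: str  # "mixedlm" or "ols"
    n_obs: int
    fe_params: pd.Series
    fe_cov: pd.DataFrame
    anova: pd.DataFrame  # term, F, df_num, df_den, p_value
    vc: dict[str, float]
    design_info: object
    converged: bool
    ddf: float
    table: pd.DataFrame = field(repr=False, default=None)

    def to_dict(self) -> dict:
        return {
            "formula": self.formula,
            "backend": self.backend,
            "n_obs": self.n_obs,
            "converged": self.converged,
            "variance_components": self.vc,
            "anova": self.anova.to_dict(orient="records"),
            "coefficients": {k: float(v) for k, v in self.fe_params.items()},
        }


def _term_ftests(design_info, fe, cov, n_obs) -> pd.DataFrame:
    """Wald F-test per model term from the fixed-effect covariance."""
    k = len(fe)
    ddf = max(n_obs - k, 1)
    rows = []
    for term, sl in design_info.term_name_slices.items():
        if term == "Intercept":
            continue
        idx = np.arange(k)[sl]
        if idx.size == 0:  # single-level factor contributes no columns
            continue
        b = fe.values[idx]
        V = cov.values[np.ix_(idx, idx)]
        try:
            stat = float(b @ np.linalg.solve(V, b))
        except np.linalg.LinAlgError:  # rank-deficient cell structure
            stat, idx = np.nan, idx
        q = len(idx)
        F = stat / q
        rows.append(
            dict(
                term=term,
                F=F,
                df_num=q,
                df_den=float(ddf),
                p_value=float(stats.f.sf(F, q, ddf)) if np.isfinite(F) else np.nan,
            )
        )
    return pd.DataFrame(rows, columns=["term", "F", "df_num", "df_den", "p_value"])


def fit_association_lmm(
    table: pd.DataFrame,
    backend: str = "mixedlm",
    reml: bool = True,
    include_sex: bool = False,
    force_zero_vc: bool = False,
) -> AssociationFit:
    """Fit the kin x age-bin mixed model on an analysis table.

    ``table`` needs columns ``z``, ``kin`` (FATHER / NON_KIN),
    ``age_bin``, ``male_id``, ``mother_id``, ``infant_id`` (and
    ``infant_sex`` when ``include_sex``).  ``backend='ols'`` drops the
    random effects entirely (the degenerate reference fit).  A random
    factor with fewer than two levels is dropped with a warning; a
    singular fit is returned with its variance component pinned near 0.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    data = table.copy()
    data["age_bin"] = data["age_bin"].astype(int)
    formula = ASSOCIATION_FORMULA + (" + C(infant_sex)" if include_sex else "")

    y, X = patsy.dmatrices(formula, data, return_type="dataframe")
    design_info = X.design_info
    n = len(data)

    if backend == "ols":
        res = sm.OLS(np.asarray(y).ravel(), X).fit()
        fe = pd.Series(res.params.values, index=X.columns)
        cov = pd.DataFrame(res.cov_params().values, index=X.columns, columns=X.columns)
        anova = _term_ftests(design_info, fe, cov, n)
        return AssociationFit(
            formula, "ols", n, fe, cov, anova, {}, design_info, True,
            float(n - len(fe)), data,
        )
    if backend != "mixedlm":
        raise ValueError(f"unknown backend {backend!r}")

    vc = {}
    for name, col in (("father", "male_id"), ("mother", "mother_id"), ("infant", "infant_id")):
        if data[col].nunique() >= 2:
            vc[name] = f"0 + C({col})"
        else:
            logger.warning("random factor %s has one level; dropped", col)
    if not vc:
        return fit_association_lmm(table, backend="ols", include_sex=include_sex)

    model = smf.mixedlm(
        formula, data, groups=np.ones(n), vc_formula=vc, re_formula="0"
    )
    fit_kwargs = {}
    if force_zero_vc:
        # pin every variance component (numerically) at zero: the fit
        # must then agree with plain OLS
        from statsmodels.regression.mixed_linear_model import MixedLMParams

        k_fe = X.shape[1]
        fit_kwargs["free"] = MixedLMParams.from_components(
            fe_params=np.ones(k_fe), cov_re=np.zeros((0, 0)), vcomp=np.zeros(len(vc))
        )
        fit_kwargs["start_params"] = MixedLMParams.from_components(
            fe_params=np.zeros(k_fe), cov_re=np.zeros((0, 0)),
            vcomp=np.full(len(vc), 1e-10),
        )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = model.fit(reml=reml, **fit_kwargs)
    k = len(res.fe_params)
    fe = pd.Series(np.asarray(res.fe_params), index=X.columns)
    cov = pd.DataFrame(
        np.asarray(res.cov_params())[:k, :k], index=X.columns, columns=X.columns
    )
    anova = _term_ftests(design_info, fe, cov, n)
    vcomp = {name: float(v) for name, v in zip(vc, np.asarray(res.vcomp))}
    vcomp["residual"] = float(res.scale)
    return AssociationFit(
        formula, "mixedlm", n, fe, cov, anova,
        vcomp, design_info, bool(res.converged), float(n - k), data,
    )


def tukey_within_bin(fit: AssociationFit, seed: int = _ADJUST_SEED) -> pd.DataFrame:
    """FATHER - NON_KIN contrast within each observed age bin.

    The family-wise adjustment is single-step over the (up to seven)
    within-bin contrasts: adjusted p is the probability that the
    maximum absolute component of a multivariate normal draw with the
    contrasts' correlation exceeds the observed |t| (the same
    construction multcomp-style software uses), floored at the
    unadjusted p so the adjustment can only be conservative.
    """
    bins = sorted(fit.table["age_bin"].unique())
    L = []
    for b in bins:
        new = pd.DataFrame(
            {"kin": ["FATHER", "NON_KIN"], "age_bin": [b, b],
             "infant_sex": ["F", "F"]}
        )
        (X,) = patsy.build_design_matrices([fit.design_info], new)
        L.append(np.asarray(X)[0] - np.asarray(X)[1])
    L = np.array(L)
    est = L @ fit.fe_params.values
    V = L @ fit.fe_cov.values @ L.T
    se = np.sqrt(np.diag(V))
    tvals = est / se
    p_unadj = 2.0 * stats.t.sf(np.abs(tvals), fit.ddf)

    corr = V / np.outer(se, se)
    rng = np.random.default_rng(seed)
    chol = np.linalg.cholesky(corr + 1e-10 * np.eye(len(bins)))
    draws = rng.standard_normal((_ADJUST_DRAWS, len(bins))) @ chol.T
    maxabs = np.abs(draws).max(axis=1)
    p_adj = np.array([float(np.mean(maxabs >= abs(t))) for t in tvals])
    p_adj = np.clip(np.maximum(p_adj, p_unadj), 0.0, 1.0)

    return pd.DataFrame(
        {
            "age_bin": bins,
            "estimate": est,
            "se": se,
            "t": tvals,
            "p_unadjusted": p_unadj,
            "p_adjusted": p_adj,
        }
    )


@dataclass
class PaternityFit:
    """Summary of the binomial same-sire model."""

    formula: str
    backend: str  # "bayes_mixed_map", "glm", or "firth"
    n_cases: int
    n_cases_total: int  # before the observation-time filter
    n_same_sire: int
    coef: pd.Series
    se: pd.Series
    wald: pd.DataFrame  # term, chi2, df, p_value
    vcp: dict[str, float]
    warnings: list[str]

    def to_dict(self) -> dict:
        return {
            "formula": self.formula,
            "backend": self.backend,
            "n_cases": self.n_cases,
            "n_cases_total": self.n_cases_total,
            "n_same_sire": self.n_same_sire,
            "coefficients": {k: float(v) for k, v in self.coef.items()},
            "wald": self.wald.to_dict(orient="records"),
            "variance_components": self.vcp,
            "warnings": self.warnings,
        }


def paternity_case_summary(cases: pd.DataFrame) -> dict:
    """Case bookkeeping: counts before/after the observation-time filter.

    ``same_sire_percent`` is the nearest-integer percentage of known
    cases in which the same male sired the mother's next offspring.
    """
    n_known = int(len(cases))
    n_same = int(cases["same_sire"].sum()) if n_known else 0
    n_passing = int(cases["passes_filter"].sum()) if n_known else 0
    n_same_passing = (
        int(cases.loc[cases["passes_filter"], "same_sire"].sum()) if n_known else 0
    )
    return {
        "n_cases_known": n_known,
        "n_same_sire_known": n_same,
        "same_sire_percent": int(round(100.0 * n_same / n_known)) if n_known else None,
        "n_cases_passing_filter": n_passing,
        "n_same_sire_passing": n_same_passing,
    }


def _wald_table(coef: pd.Series, se: pd.Series) -> pd.DataFrame:
    rows = []
    for name in coef.index:
        if name.lower() in ("intercept", "const"):
            continue
        s = float(se[name])
        if not np.isfinite(s) or s <= 0:  # unestimable (e.g. collinear) term
            rows.append(dict(term=name, chi2=np.nan, df=1, p_value=np.nan))
            continue
        chi2 = float((coef[name] / s) ** 2)
        rows.append(
            dict(term=name, chi2=chi2, df=1, p_value=float(stats.chi2.sf(chi2, 1)))
        )
    return pd.DataFrame(rows, columns=["term", "chi2", "df", "p_value"])


def firth_logistic(X: np.ndarray, y: np.ndarray, max_iter: int = 200, tol: float = 1e-8):
    """Bias-reduced (Jeffreys-penalized) logistic regression.

    Used as the fallback when maximum likelihood separates.  Returns
    ``(beta, cov)`` with the covariance from the penalized information.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    beta = np.zeros(X.shape[1])
    for _ in range(max_iter):
        eta = X @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = mu * (1.0 - mu)
        XW = X * w[:, None]
        info = X.T @ XW
        info_inv = np.linalg.pinv(info)
        h = np.einsum("ij,jk,ik->i", XW, info_inv, X)
        score = X.T @ (y - mu + h * (0.5 - mu))
        step = info_inv @ score
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            break
    eta = X @ beta
    mu = 1.0 / (1.0 + np.exp(-eta))
    info = X.T @ (X * (mu * (1 - mu))[:, None])
    return beta, np.linalg.pinv(info)


def fit_paternity_model(
    cases: pd.DataFrame,
    apply_filter: bool = True,
    random_effects: bool = True,
    prior_sd: float = 100.0,
) -> PaternityFit:
    """Fit the same-sire binomial model on paternity cases.

    ``cases`` comes from :func:`kinbias.association.build_paternity_cases`
    merged with an ordinal ``rank`` column; rows failing the 90-hour
    filter are dropped when ``apply_filter``.  With a degenerate
    response (all 0 or all 1) or detected separation, the fit falls
    back to bias-reduced penalized likelihood with a warning recorded
    in the summary.
    """
    import statsmodels.api as sm
    from statsmodels.genmod.bayes_mixed_glm import BinomialBayesMixedGLM

    notes: list[str] = []
    total = len(cases)
    data = cases[cases["passes_filter"]].copy() if apply_filter else cases.copy()
    data["same_sire"] = data["same_sire"].astype(int)
    n = len(data)
    n_same = int(data["same_sire"].sum())
    if n == 0:
        raise ValueError("no paternity cases pass the observation-time filter")

    y, X = patsy.dmatrices(PATERNITY_FORMULA, data, return_type="dataframe")
    yv = np.asarray(y).ravel()

    def finish(coef, se, backend, vcp):
        return PaternityFit(
            PATERNITY_FORMULA, backend, n, total, n_same,
            coef, se, _wald_table(coef, se), vcp, notes,
        )

    degenerate = n_same in (0, n)
    if degenerate:
        notes.append("degenerate response (all same or all different sires); penalized fit")
    if not degenerate and random_effects:
        use_re = data["mother_id"].nunique() >= 2 and data["father_id"].nunique() >= 2
        if use_re:
            try:
                md = BinomialBayesMixedGLM.from_formula(
                    PATERNITY_FORMULA,
                    vc_formulas={"mother": "0 + C(mother_id)", "father": "0 + C(father_id)"},
                    data=data,
                    fe_p=prior_sd,
                )
                # the backend draws random starting values from the
                # global RNG; pin them so fits are reproducible
                state = np.random.get_state()
                np.random.seed(_ADJUST_SEED)
                try:
                    with warnings.catch_warnings():
                        warnings.simplefilter("ignore")
                        res = md.fit_map()
                finally:
                    np.random.set_state(state)
                k = X.shape[1]
                coef = pd.Series(res.fe_mean[:k], index=X.columns)
                se = pd.Series(res.fe_sd[:k], index=X.columns)
                if np.all(np.isfinite(se)) and np.all(se.values > 0) and np.max(
                    np.abs(coef.values)
                ) < 30:
                    vcp = {
                        name: float(np.exp(v))
                        for name, v in zip(["mother", "father"], res.vcp_mean)
                    }
                    return finish(coef, se, "bayes_mixed_map", vcp)
                notes.append("mixed fit unstable; falling back to fixed-effects logit")
            except Exception as exc:  # pragma: no cover - backend edge
                notes.append(f"mixed fit failed ({exc}); falling back to fixed-effects logit")
        else:
            notes.append("a random factor has one level; fixed-effects logit used")

    if not degenerate:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = sm.GLM(yv, X, family=sm.families.Binomial()).fit()
            coef = pd.Series(res.params.values, index=X.columns)
            se = pd.Series(res.bse.values, index=X.columns)
            if np.max(np.abs(coef.values)) < 30 and np.all(np.isfinite(se.values)):
                return finish(coef, se, "glm", {})
            notes.append("separation detected; bias-reduced refit")
        except Exception:
            notes.append("GLM failed; bias-reduced refit")

    beta, cov = firth_logistic(np.asarray(X), yv)
    coef = pd.Series(beta, index=X.columns)
    se = pd.Series(np.sqrt(np.diag(cov)), index=X.columns)
    return finish(coef, se, "firth", {})
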