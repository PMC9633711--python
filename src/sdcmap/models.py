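"""Outcome modelling and model-comparison statistics.

Logistic regressions (crude and covariate-adjusted models for the SDC
score, and the basic vs enhanced prediction models of the split-half
analysis) are maximum-likelihood fits via statsmodels with Wald
confidence intervals on the log-odds scale.  Model comparison uses the
rank-based AUC, the category-free (continuous) net reclassification
improvement, the integrated discrimination improvement, and dominance
analysis with McFadden's pseudo-R^2 as the fit statistic.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ModelFit",
    "ReclassificationResult",
    "DominanceResult",
    "fit_logistic",
    "model_specs",
    "vif",
    "auc",
    "category_free_nri",
    "idi",
    "dominance_general",
    "group_tests",
    "rank_sum_test",
    "chi_square_test",
    "fdr_correct",
]


# --------------------------------------------------------------- containers


@dataclass
class ModelFit:
    names: list[str]
    intercept: float
    coefficients: pd.Series
    odds_ratios: pd.DataFrame  # columns: or, ci_low, ci_high
    p_values: pd.Series
    predicted: np.ndarray
    llf: float
    llnull: float
    mcfadden_r2: float
    auc: float
    vifs: pd.Series | None
    epv: float

    def summary_dict(self) -> dict:
        return {
            "predictors": {
                name: {
                    "coef": float(self.coefficients[name]),
                    "or": float(self.odds_ratios.loc[name, "or"]),
                    "or_ci": [
                        float(self.odds_ratios.loc[name, "ci_low"]),
                        float(self.odds_ratios.loc[name, "ci_high"]),
                    ],
                    "p": float(self.p_values[name]),
                }
                for name in self.names
            },
            "mcfadden_r2": float(self.mcfadden_r2),
            "auc": float(self.auc),
            "epv": float(self.epv),
            "vif_max": (
                float(np.max(self.vifs)) if self.vifs is not None else None
            ),
        }


@dataclass
class ReclassificationResult:
    nri: float
    nri_ci: tuple[float, float]
    nri_p: float
    idi: float
    idi_ci: tuple[float, float]
    idi_p: float


@dataclass
class DominanceResult:
    general_dominance: pd.Series
    ranking: list[str]
    fit_statistic: str = field(default="mcfadden_r2")
    full_model_fit: float = 0.0


# ------------------------------------------------------------- logistic fit


def _check_design(design: pd.DataFrame) -> pd.DataFrame:
    if not isinstance(design, pd.DataFrame):
        design = pd.DataFrame(np.asarray(design, float))
        design.columns = [f"x{j}" for j in range(design.shape[1])]
    design = design.astype(float)
    arr = design.to_numpy()
    spans = arr.max(axis=0) - arr.min(axis=0)
    for col, span in zip(design.columns, spans):
        if span == 0.0:
            raise ValueError(f"predictor '{col}' has zero variance")
    return design


def _separating_predictor(design: pd.DataFrame, y: np.ndarray) -> str | None:
    for col in design.columns:
        v = design[col].to_numpy()
        if v[y == 1].min() > v[y == 0].max() or v[y == 1].max() < v[y == 0].min():
            return col
    return None


def _log_likelihood(y: np.ndarray, mu: np.ndarray) -> float:
    mu = np.clip(mu, 1e-12, 1.0 - 1e-12)
    return float(np.sum(y * np.log(mu) + (1.0 - y) * np.log1p(-mu)))


def _irls_logit(X: np.ndarray, y: np.ndarray, tol: float = 1e-10,
                maxiter: int = 100):
    """Newton/IRLS maximum-likelihood fit of a logistic model.

    ``X`` includes the intercept column.  Returns (beta, cov, llf).
    Raises on divergence (separation) or a singular information matrix.
    """
    n, p = X.shape
    beta = np.zeros(p)
    pbar = y.mean()
    beta[0] = np.log(pbar / (1.0 - pbar))  # start at the null model
    ll = _log_likelihood(y, np.full(n, pbar))
    for _ in range(maxiter):
        eta = X @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = mu * (1.0 - mu)
        grad = X.T @ (y - mu)
        H = (X * w[:, None]).T @ X
        try:
            full_step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError as exc:
            raise np.linalg.LinAlgError(
                "singular information matrix"
            ) from exc
        # step-halving keeps the likelihood monotone
        step = full_step
        for _ in range(30):
            cand = beta + step
            ll_new = _log_likelihood(y, 1.0 / (1.0 + np.exp(-(X @ cand))))
            if ll_new >= ll - 1e-14:
                break
            step = step / 2.0
        beta = beta + step
        if np.max(np.abs(beta)) > 40.0:
            raise FloatingPointError("diverging coefficients (separation)")
        converged = ll_new - ll < tol and np.max(np.abs(full_step)) < 1e-6
        ll = ll_new
        if converged:
            break
    else:
        raise RuntimeError("logistic fit did not converge")
    mu = 1.0 / (1.0 + np.exp(-(X @ beta)))
    w = mu * (1.0 - mu)
    cov = np.linalg.inv((X * w[:, None]).T @ X)
    return beta, cov, ll


def fit_logistic(design, outcome, compute_vif: bool = True) -> ModelFit:
    """Maximum-likelihood logistic regression with Wald 95% CIs.

    The fit is Newton/IRLS with step-halving; ``design`` is a named
    predictor matrix (no intercept column; one is added).  Raises on
    perfect separation, naming the offending predictor where one can
    be identified.
    """
    design = _check_design(design)
    y = np.asarray(outcome).astype(float).ravel()
    if set(np.unique(y)) != {0.0, 1.0}:
        raise ValueError("outcome must contain both classes, coded 0/1")
    X = np.column_stack([np.ones(len(y)), design.to_numpy(float)])
    try:
        beta, cov, llf = _irls_logit(X, y)
    except (FloatingPointError, np.linalg.LinAlgError, RuntimeError) as exc:
        offender = _separating_predictor(design, y.astype(int))
        if offender is not None:
            raise ValueError(
                f"perfect separation by predictor '{offender}'"
            ) from exc
        raise RuntimeError(f"logistic fit failed: {exc}") from exc
    names = list(design.columns)
    b, s = beta[1:], np.sqrt(np.diag(cov))[1:]
    params = pd.Series(b, index=names)
    ors = pd.DataFrame(
        {
            "or": np.exp(b),
            "ci_low": np.exp(b - 1.96 * s),
            "ci_high": np.exp(b + 1.96 * s),
        },
        index=names,
    )
    from scipy.special import ndtr

    pvalues = pd.Series(2.0 * ndtr(-np.abs(b / s)), index=names)
    predicted = 1.0 / (1.0 + np.exp(-(X @ beta)))
    pbar = y.mean()
    llnull = float(len(y) * (pbar * np.log(pbar) + (1 - pbar) * np.log1p(-pbar)))
    n_events = float(y.sum())
    vifs = (
        vif(design) if compute_vif and design.shape[1] >= 2 else None
    )
    return ModelFit(
        names=names,
        intercept=float(beta[0]),
        coefficients=params,
        odds_ratios=ors,
        p_values=pvalues,
        predicted=predicted,
        llf=float(llf),
        llnull=llnull,
        mcfadden_r2=float(1.0 - llf / llnull),
        auc=auc(predicted, y),
        vifs=vifs,
        epv=n_events / design.shape[1],
    )


# ------------------------------------------------------------- model specs

BASIC_PREDICTORS = [
    "nihss",            # stroke severity
    "bi",               # level of disability
    "moca",             # cognitive impairment
    "age",
    "sex_female",
    "education_years",
    "neuroticism",
    "extraversion",
]

LOCALIZATION_LEVELS = ["left", "right", "bihemispheric", "infratentorial"]


def _localization_dummies(series: pd.Series) -> pd.DataFrame:
    cat = pd.Categorical(series, categories=LOCALIZATION_LEVELS)
    if cat.isna().any():
        raise ValueError("unknown lesion_localization level")
    dummies = pd.get_dummies(cat, prefix="localization").astype(float)
    return dummies.drop(columns="localization_left")  # reference: left


def model_specs(cohort: pd.DataFrame, sdc_scores) -> dict[str, pd.DataFrame]:
    """Design matrices for Models 1-3 and the basic/enhanced models.

    Model 1: SDC score (log-transformed) only.  Model 2: + imaging
    covariates (timing of imaging, lesion localization, lesion volume).
    Model 3: + all sociodemographic, clinical and psychological
    covariates.  basic: the 8 pre-selected literature predictors.
    enhanced: basic + SDC score.
    """
    cohort = cohort.reset_index(drop=True)
    scores = np.asarray(sdc_scores, float)
    if scores.shape[0] != len(cohort):
        raise ValueError("scores are not aligned with the cohort")
    needed = {
        "timing_of_imaging_days", "lesion_localization", "lesion_volume_cm3",
        "age", "sex", "education_years", "nihss", "bi", "moca",
        "neuroticism", "extraversion",
    }
    missing = needed - set(cohort.columns)
    if missing:
        raise ValueError(f"cohort is missing columns: {sorted(missing)}")

    base = pd.DataFrame({"sdc_score_log": scores})
    imaging = pd.concat(
        [
            cohort[["timing_of_imaging_days", "lesion_volume_cm3"]].astype(float),
            _localization_dummies(cohort["lesion_localization"]),
        ],
        axis=1,
    )
    sex_female = (
        cohort["sex"].map({"female": 1.0, "male": 0.0})
        if cohort["sex"].dtype == object
        else cohort["sex"].astype(float)
    )
    covars = pd.DataFrame(
        {
            "age": cohort["age"].astype(float),
            "sex_female": sex_female,
            "education_years": cohort["education_years"].astype(float),
            "nihss": cohort["nihss"].astype(float),
            "bi": cohort["bi"].astype(float),
            "moca": cohort["moca"].astype(float),
            "neuroticism": cohort["neuroticism"].astype(float),
            "extraversion": cohort["extraversion"].astype(float),
        }
    )
    basic = covars[BASIC_PREDICTORS].copy()
    specs = {
        "model1": base.copy(),
        "model2": pd.concat([base, imaging], axis=1),
        "model3": pd.concat([base, imaging, covars], axis=1),
        "basic": basic,
        "enhanced": pd.concat([basic, base], axis=1),
    }
    n_events = int(cohort["psd"].sum()) if "psd" in cohort else None
    if n_events is not None:
        for name, X in specs.items():
            epv = n_events / X.shape[1]
            if epv <= 10:
                warnings.warn(
                    f"model '{name}' has events-per-variable {epv:.1f} <= 10"
                )
    return specs


# -------------------------------------------------------------------- VIF


def vif(design: pd.DataFrame) -> pd.Series:
    """Variance inflation factors from per-column auxiliary regressions."""
    design = _check_design(design)
    if design.shape[1] < 2:
        raise ValueError("VIF requires at least 2 predictors")
    out = {}
    for col in design.columns:
        others = sm.add_constant(design.drop(columns=col), has_constant="add")
        r2 = sm.OLS(design[col], others).fit().rsquared
        out[col] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return pd.Series(out)


# -------------------------------------------------------------------- AUC


def auc(predicted, outcome) -> float:
    """Rank-based AUC (concordance); ties count one half."""
    p = np.asarray(predicted, float).ravel()
    y = np.asarray(outcome).astype(int).ravel()
    n1, n0 = int(y.sum()), int((1 - y).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("both outcome classes required")
    ranks = stats.rankdata(p)
    return float((ranks[y == 1].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0))


# ----------------------------------------------------------------- NRI/IDI


def category_free_nri(p_base, p_new, outcome) -> tuple[float, tuple, float]:
    """Continuous (category-free) NRI with asymptotic CI and p.

    NRI = [P(up|event) - P(down|event)] + [P(down|nonevent) -
    P(up|nonevent)]; exact ties contribute to neither direction.
    """
    pb = np.asarray(p_base, float).ravel()
    pn = np.asarray(p_new, float).ravel()
    y = np.asarray(outcome).astype(int).ravel()
    if pb.shape != pn.shape or pb.shape != y.shape:
        raise ValueError("probability vectors and outcome must align")
    up, down = pn > pb, pn < pb
    ev, ne = y == 1, y == 0
    n_e, n_ne = int(ev.sum()), int(ne.sum())
    if n_e == 0 or n_ne == 0:
        raise ValueError("both outcome classes required")
    pup_e, pdown_e = up[ev].mean(), down[ev].mean()
    pup_ne, pdown_ne = up[ne].mean(), down[ne].mean()
    nri_e = pup_e - pdown_e
    nri_ne = pdown_ne - pup_ne
    nri = float(nri_e + nri_ne)
    var = (pup_e + pdown_e - nri_e**2) / n_e + (
        pup_ne + pdown_ne - nri_ne**2
    ) / n_ne
    se = float(np.sqrt(var))
    if se == 0.0:
        p = 1.0 if nri == 0.0 else 0.0
    else:
        p = float(2.0 * stats.norm.sf(abs(nri) / se))
    return nri, (nri - 1.96 * se, nri + 1.96 * se), p


def idi(p_base, p_new, outcome) -> tuple[float, tuple, float]:
    """Integrated discrimination improvement with asymptotic CI and p."""
    pb = np.asarray(p_base, float).ravel()
    pn = np.asarray(p_new, float).ravel()
    y = np.asarray(outcome).astype(int).ravel()
    ev, ne = y == 1, y == 0
    n_e, n_ne = int(ev.sum()), int(ne.sum())
    if n_e == 0 or n_ne == 0:
        raise ValueError("both outcome classes required")
    d = pn - pb
    value = float(d[ev].mean() - d[ne].mean())
    se = float(
        np.sqrt(d[ev].var(ddof=1) / n_e + d[ne].var(ddof=1) / n_ne)
    )
    if se == 0.0:
        p = 1.0 if value == 0.0 else 0.0
    else:
        p = float(2.0 * stats.norm.sf(abs(value) / se))
    return value, (value - 1.96 * se, value + 1.96 * se), p


def compare_models(base: ModelFit, new: ModelFit, outcome) -> ReclassificationResult:
    """NRI and IDI for an enhanced model against a base model."""
    nri, nri_ci, nri_p = category_free_nri(base.predicted, new.predicted, outcome)
    idi_v, idi_ci, idi_p = idi(base.predicted, new.predicted, outcome)
    return ReclassificationResult(
        nri=nri, nri_ci=tuple(nri_ci), nri_p=nri_p,
        idi=idi_v, idi_ci=tuple(idi_ci), idi_p=idi_p,
    )


# ---------------------------------------------------------------- dominance


def _mcfadden_subsets(design: pd.DataFrame, y: np.ndarray) -> dict:
    """McFadden R^2 of every predictor subset (with intercept)."""
    cols = list(design.columns)
    arr = design.to_numpy(float)
    ones = np.ones((len(y), 1))
    pbar = y.mean()
    ll0 = float(len(y) * (pbar * np.log(pbar) + (1 - pbar) * np.log1p(-pbar)))
    r2: dict[frozenset, float] = {frozenset(): 0.0}
    col_idx = {c: j for j, c in enumerate(cols)}
    for size in range(1, len(cols) + 1):
        for subset in itertools.combinations(cols, size):
            X = np.hstack([ones, arr[:, [col_idx[c] for c in subset]]])
            try:
                _, _, llf = _irls_logit(X, y)
            except Exception as exc:
                raise RuntimeError(
                    f"subset fit failed for predictors {subset}: {exc}"
                ) from exc
            r2[frozenset(subset)] = float(1.0 - llf / ll0)
    return r2


def dominance_general(design, outcome) -> DominanceResult:
    """General dominance via full subset enumeration (2^p logistic fits).

    For each predictor the incremental McFadden R^2 from adding it to
    every subset not containing it is averaged within subset sizes and
    then across sizes.  The general dominance values sum to the full
    model's McFadden R^2.
    """
    design = _check_design(design)
    y = np.asarray(outcome).astype(float).ravel()
    cols = list(design.columns)
    p = len(cols)
    if p > 15:
        raise ValueError("dominance analysis limited to 15 predictors (2^p fits)")
    r2 = _mcfadden_subsets(design, y)
    values = {}
    for j in cols:
        others = [c for c in cols if c != j]
        by_size = []
        for size in range(0, p):
            incs = [
                r2[frozenset(S) | {j}] - r2[frozenset(S)]
                for S in itertools.combinations(others, size)
            ]
            by_size.append(np.mean(incs))
        values[j] = float(np.mean(by_size))
    series = pd.Series(values)
    ranking = list(series.sort_values(ascending=False).index)
    return DominanceResult(
        general_dominance=series,
        ranking=ranking,
        fit_statistic="mcfadden_r2",
        full_model_fit=r2[frozenset(cols)],
    )


# --------------------------------------------------------------- group tests


def rank_sum_test(x, y) -> tuple[float, float]:
    """Two-sample rank-sum test, tie-corrected normal approximation."""
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    return float(res.statistic), float(res.pvalue)


def chi_square_test(table) -> tuple[float, float]:
    """Pearson chi-square on an r x c contingency table (no correction)."""
    table = np.asarray(table, float)
    if table.min() < 0:
        raise ValueError("negative cell count")
    expected = stats.contingency.expected_freq(table)
    if np.any(expected == 0):
        raise ValueError("expected count of zero in a cell")
    stat, p, _, _ = stats.chi2_contingency(table, correction=False)
    return float(stat), float(p)


def group_tests(values, groups, kind: str = "auto") -> tuple[float, float]:
    """Compare a variable across groups.

    Continuous data: two-group rank-sum test (tie-corrected normal
    approximation) or Kruskal-Wallis for three or more groups.
    Categorical data (``kind='categorical'``): r x c chi-square from the
    cross-tabulation.
    """
    values = np.asarray(values)
    groups = np.asarray(groups)
    levels = np.unique(groups)
    if levels.size < 2:
        raise ValueError("at least 2 groups required")
    if kind == "categorical":
        table = pd.crosstab(pd.Series(groups), pd.Series(values)).to_numpy()
        return chi_square_test(table)
    samples = [values[groups == g].astype(float) for g in levels]
    if levels.size == 2:
        return rank_sum_test(samples[0], samples[1])
    res = stats.kruskal(*samples)
    return float(res.statistic), float(res.pvalue)


def fdr_correct(p_values) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (step-up, capped at 1)."""
    p = np.asarray(p_values, float).ravel()
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]
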