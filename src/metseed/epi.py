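"""Cohort ingestion and association models for cLNM occurrence.

Covers the association toolkit applied to the cohort: crosstabs with row
percentages, sex/age-adjusted logistic regression with likelihood-ratio
tests (LRT) and driver-heterogeneity tests, and excess-odds-ratio (EOR)
dose-response models.

The EOR model is the radiation-epidemiology convention for a dose effect
that is linear on the odds-ratio scale rather than log-linear::

    odds(y=1 | x, d) = exp(x'beta) * (1 + theta1*d + theta2*d^2)

with ``d`` the thyroid dose in Gy (doses above 1000 mGy truncated to
1000 mGy before conversion).  ``theta1`` is the EOR per Gy.  The model
is fitted by maximum likelihood under the positivity constraint
``1 + theta1*d + theta2*d^2 > 0`` at every observed dose, and
uncertainty in ``theta1`` is reported as a profile-likelihood 95%
interval.  The ``theta = 0`` submodel is an ordinary logistic
regression, which anchors the dose-trend LRT.

Modelling objects follow the statsmodels idiom: build a model from
data, call :meth:`ExcessOddsRatioLogit.fit`, inspect the returned
:class:`EORResults` (params, loglik, profile CI, ``summary()``).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize, stats

__all__ = [
    "ingest_cohort",
    "crosstab",
    "fit_logistic",
    "LogisticFit",
    "lrt",
    "LRTResult",
    "heterogeneity_test",
    "ExcessOddsRatioLogit",
    "EORResults",
    "fit_eor",
    "DOSE_TRUNCATION_MGY",
    "DOSE_BINS_MGY",
]

DOSE_TRUNCATION_MGY = 1000.0
#: categorical dose bins (mGy): 0, 1-99, 100-199, >=200
DOSE_BINS_MGY = (0.0, 1.0, 100.0, 200.0)

REQUIRED_COLUMNS = ("id", "sex", "age_at_ptc")


def ingest_cohort(
    table: pd.DataFrame, dose_truncation_mGy: float = DOSE_TRUNCATION_MGY
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Validate and normalize a clinical cohort table.

    Recodes unknown nodal/metastasis stages (Nx, Mx/Mm) to N0/M0, derives
    the cLNM outcome from nodal stage when absent, and adds a modelling
    dose column ``dose_Gy_trunc`` = min(dose, truncation)/1000.  Rows
    missing sex, age, or outcome are rejected; returns
    ``(subjects, rejected)`` where ``rejected`` carries a reason column.
    """
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"cohort table missing required columns: {missing}")
    df = table.copy()

    if "n_stage" in df.columns:
        df["n_stage"] = (
            df["n_stage"].astype(str).str.upper().replace({"NX": "N0", "NAN": "N0"})
        )
    if "m_stage" in df.columns:
        df["m_stage"] = (
            df["m_stage"].astype(str).str.upper().replace({"MX": "M0", "MM": "M0", "NAN": "M0"})
        )
    if "clnm" not in df.columns:
        if "n_stage" not in df.columns:
            raise ValueError("cohort table needs a clnm outcome or an n_stage column")
        df["clnm"] = df["n_stage"].isin(["N1", "N1A", "N1B", "N1a", "N1b"])

    reasons = pd.Series("", index=df.index, dtype=object)
    reasons[df["sex"].isna()] = "missing_sex"
    reasons[df["age_at_ptc"].isna() & (reasons == "")] = "missing_age"
    reasons[df["clnm"].isna() & (reasons == "")] = "missing_outcome"

    if "dose_mGy" in df.columns:
        dose = df["dose_mGy"].fillna(0.0).astype(float)
    else:
        dose = pd.Series(0.0, index=df.index)
    df["dose_mGy"] = dose
    df["dose_Gy_trunc"] = np.minimum(dose, dose_truncation_mGy) / 1000.0

    rejected = df[reasons != ""].copy()
    rejected["reject_reason"] = reasons[reasons != ""]
    subjects = df[reasons == ""].copy()
    subjects["clnm"] = subjects["clnm"].astype(bool)
    return subjects, rejected


def crosstab(
    subjects: pd.DataFrame,
    row: str = "driver_category",
    col: str = "clnm",
    split_col: str | None = None,
    row_order: list | None = None,
) -> pd.DataFrame:
    """Counts and row percentages of a binary outcome by category.

    Returns one row per category with ``n_total``, ``n_event``, ``pct``
    (100*n_event/n_total rounded to one decimal).  ``split_col`` (for
    instance nodal substage) adds per-level event counts and percentages.
    """
    if subjects[row].isna().all() or len(subjects) == 0:
        raise ValueError("no categories to tabulate")
    df = subjects[subjects[row].notna()]
    rows = []
    groups = df.groupby(row, sort=True)
    for cat, grp in groups:
        n_tot = len(grp)
        n_ev = int(grp[col].astype(bool).sum())
        rec = {
            row: cat,
            "n_total": n_tot,
            "n_event": n_ev,
            "pct": round(100.0 * n_ev / n_tot, 1),
        }
        if split_col is not None:
            for level, sub in grp[grp[col].astype(bool)].groupby(split_col):
                rec[f"n_{level}"] = len(sub)
                rec[f"pct_{level}"] = round(100.0 * len(sub) / n_tot, 1)
        rows.append(rec)
    out = pd.DataFrame(rows).set_index(row)
    if row_order is not None:
        out = out.reindex(row_order)
    return out


@dataclass
class LogisticFit:
    """Logistic-regression fit: coefficients, SEs, ORs with Wald 95% CIs."""

    params: pd.Series
    bse: pd.Series
    loglik: float
    nobs: int
    result: object = field(repr=False, default=None)

    @property
    def odds_ratios(self) -> pd.DataFrame:
        z = stats.norm.ppf(0.975)
        return pd.DataFrame(
            {
                "OR": np.exp(self.params),
                "ci_low": np.exp(self.params - z * self.bse),
                "ci_high": np.exp(self.params + z * self.bse),
            }
        )


def _check_separation(endog: np.ndarray, exog: pd.DataFrame) -> None:
    # Complete/quasi-separation: a binary column perfectly aligned with the
    # outcome.  (Heuristic; statsmodels' own convergence checks back this up.)
    y = endog.astype(bool)
    for col in exog.columns:
        x = np.asarray(exog[col], dtype=float)
        uniq = np.unique(x)
        if len(uniq) == 2:
            hi = x == uniq.max()
            if (y[hi].all() and not y[~hi].any()) or ((~y[hi]).all() and y[~hi].all()):
                raise ValueError(f"complete separation on covariate {col!r}; fit aborted")


def fit_logistic(outcome, design: pd.DataFrame, add_intercept: bool = True) -> LogisticFit:
    """Maximum-likelihood logistic regression (IRLS via statsmodels).

    ``design`` holds the covariates; an intercept column is prepended
    unless already present.  Complete separation aborts the fit with an
    explanatory error.
    """
    y = np.asarray(outcome, dtype=float)
    X = design.copy().astype(float)
    if add_intercept and "const" not in X.columns:
        X = sm.add_constant(X, has_constant="add")
    _check_separation(y, X.drop(columns=["const"], errors="ignore"))
    res = sm.Logit(y, X).fit(disp=0, maxiter=200)
    if not res.mle_retvals.get("converged", True):
        raise RuntimeError("logistic fit did not converge")
    return LogisticFit(
        params=res.params, bse=res.bse, loglik=float(res.llf), nobs=int(res.nobs), result=res
    )


@dataclass(frozen=True)
class LRTResult:
    statistic: float
    df: int
    p: float


def lrt(loglik_full: float, loglik_reduced: float, df: int) -> LRTResult:
    """Likelihood-ratio test of nested models; statistic clamped at zero."""
    if df <= 0:
        raise ValueError("LRT requires df >= 1 (models must be strictly nested)")
    stat = max(0.0, 2.0 * (loglik_full - loglik_reduced))
    p = float(stats.chi2.sf(stat, df)) if stat > 0 else 1.0
    return LRTResult(stat, df, p)


def heterogeneity_test(
    subjects: pd.DataFrame,
    category: str = "driver_category",
    outcome: str = "clnm",
    adjust: tuple[str, ...] = ("sex", "age_at_ptc"),
) -> LRTResult:
    """LRT for outcome heterogeneity across categories, sex/age adjusted.

    Compares the adjusted logistic model with and without the category
    factor; df = number of categories - 1.  Categories whose outcome is
    entirely missing are dropped.
    """
    df = subjects[subjects[category].notna() & subjects[outcome].notna()].copy()
    cats = sorted(df[category].unique())
    if len(cats) < 2:
        raise ValueError("heterogeneity test needs >= 2 categories")
    base = pd.DataFrame(index=df.index)
    for col in adjust:
        if col == "sex":
            base["male"] = (df["sex"] == "M").astype(float)
        else:
            base[col] = df[col].astype(float)
    dummies = pd.get_dummies(df[category], drop_first=True, dtype=float)
    full = fit_logistic(df[outcome], pd.concat([base, dummies], axis=1))
    reduced = fit_logistic(df[outcome], base)
    return lrt(full.loglik, reduced.loglik, df=len(cats) - 1)


# ---------------------------------------------------------------------------
# Excess odds ratio dose-response model
# ---------------------------------------------------------------------------

_CHI2_1_HALF_95 = stats.chi2.ppf(0.95, 1) / 2.0  # 1.9207...
_EPS_POS = 1e-6


class ExcessOddsRatioLogit:
    """Binary-outcome model with a dose effect linear on the odds scale.

    Parameters
    ----------
    endog : array-like of 0/1
        Outcome indicator.
    exog : DataFrame
        Log-linear covariates; an intercept is added unless present.
    dose : array-like
        Dose in Gy (non-negative; truncation applied upstream).
    dose_terms : {"linear", "linear_quadratic", "quadratic"}
        Which dose parameters enter ``1 + theta1*d + theta2*d^2``.
    """

    def __init__(self, endog, exog: pd.DataFrame, dose, dose_terms: str = "linear"):
        if dose_terms not in ("linear", "linear_quadratic", "quadratic"):
            raise ValueError(f"unknown dose_terms {dose_terms!r}")
        self.y = np.asarray(endog, dtype=float)
        X = exog.copy().astype(float)
        if "const" not in X.columns:
            X = sm.add_constant(X, has_constant="add")
        self.exog_names = list(X.columns)
        self.X = X.to_numpy()
        self.d = np.asarray(dose, dtype=float)
        if np.any(self.d < 0):
            raise ValueError("doses must be non-negative")
        if np.all(self.d == 0):
            raise ValueError("all doses are zero; theta is unidentifiable")
        self.dose_terms = dose_terms
        self.n_beta = self.X.shape[1]
        self.theta_names = {
            "linear": ["theta1"],
            "linear_quadratic": ["theta1", "theta2"],
            "quadratic": ["theta2"],
        }[dose_terms]
        self.n_theta = len(self.theta_names)
        self.d_max = float(self.d.max())

    # -- likelihood machinery ------------------------------------------------

    def _dose_factor(self, theta: np.ndarray) -> np.ndarray:
        f = np.ones_like(self.d)
        if self.dose_terms == "linear":
            f = 1.0 + theta[0] * self.d
        elif self.dose_terms == "quadratic":
            f = 1.0 + theta[0] * self.d ** 2
        else:
            f = 1.0 + theta[0] * self.d + theta[1] * self.d ** 2
        return f

    def loglike(self, params: np.ndarray) -> float:
        beta = params[: self.n_beta]
        theta = params[self.n_beta :]
        f = self._dose_factor(theta)
        if np.any(f <= 0):
            return -np.inf
        eta = self.X @ beta + np.log(f)
        # loglik = sum y*eta - log(1+exp(eta))
        return float(np.sum(self.y * eta - np.logaddexp(0.0, eta)))

    def _neg_loglike_grad(self, params: np.ndarray):
        beta = params[: self.n_beta]
        theta = params[self.n_beta :]
        f = self._dose_factor(theta)
        if np.any(f <= _EPS_POS):
            # barrier: steeply penalize infeasible dose factors
            viol = np.clip(_EPS_POS - f, 0.0, None)
            pen = 1e6 * float(np.sum(viol ** 2)) + 1e3
            grad = np.zeros_like(params)
            df_dtheta = self._dose_factor_jac()
            grad[self.n_beta :] = -2e6 * (viol @ df_dtheta)
            return pen, grad
        eta = self.X @ beta + np.log(f)
        pi = 1.0 / (1.0 + np.exp(-eta))
        ll = float(np.sum(self.y * eta - np.logaddexp(0.0, eta)))
        resid = self.y - pi
        g_beta = self.X.T @ resid
        df_dtheta = self._dose_factor_jac()
        g_theta = df_dtheta.T @ (resid / f)
        return -ll, -np.concatenate([g_beta, g_theta])

    def _dose_factor_jac(self) -> np.ndarray:
        cols = []
        if "theta1" in self.theta_names:
            cols.append(self.d)
        if "theta2" in self.theta_names:
            cols.append(self.d ** 2)
        return np.column_stack(cols)

    def _theta_bounds(self) -> list[tuple[float | None, float | None]]:
        # For a single dose term the positivity constraint is a box bound:
        # the factor is minimized at d_max, so theta > -1/d_max^k + eps.
        if self.dose_terms == "linear":
            return [(-1.0 / self.d_max + _EPS_POS, None)]
        if self.dose_terms == "quadratic":
            return [(-1.0 / self.d_max ** 2 + _EPS_POS, None)]
        return [(None, None), (None, None)]  # handled by the barrier

    def _optimize(
        self, start: np.ndarray, fixed_theta1: float | None = None
    ) -> tuple[np.ndarray, float, bool]:
        """Maximize the likelihood, optionally with theta1 held fixed."""
        free_theta = list(self.theta_names)
        if fixed_theta1 is not None:
            free_theta.remove("theta1")

        def pack(p_free):
            if fixed_theta1 is None:
                return p_free
            beta = p_free[: self.n_beta]
            rest = p_free[self.n_beta :]
            theta = []
            j = 0
            for name in self.theta_names:
                if name == "theta1":
                    theta.append(fixed_theta1)
                else:
                    theta.append(rest[j])
                    j += 1
            return np.concatenate([beta, theta])

        def fun(p_free):
            return self._neg_loglike_grad(pack(p_free))[0]

        def jac(p_free):
            full_grad = self._neg_loglike_grad(pack(p_free))[1]
            if fixed_theta1 is None:
                return full_grad
            keep = list(range(self.n_beta)) + [
                self.n_beta + i
                for i, name in enumerate(self.theta_names)
                if name != "theta1"
            ]
            return full_grad[keep]

        bounds = [(None, None)] * self.n_beta
        tb = self._theta_bounds()
        for name, b in zip(self.theta_names, tb):
            if fixed_theta1 is not None and name == "theta1":
                continue
            bounds.append(b)

        if fixed_theta1 is None:
            x0 = start
        else:
            keep = list(range(self.n_beta)) + [
                self.n_beta + i
                for i, name in enumerate(self.theta_names)
                if name != "theta1"
            ]
            x0 = start[keep]

        res = optimize.minimize(
            fun, x0, jac=jac, method="L-BFGS-B", bounds=bounds,
            options={"maxiter": 500, "ftol": 1e-12, "gtol": 1e-9},
        )
        return pack(res.x), -float(res.fun), bool(res.success)

    # -- public fitting API --------------------------------------------------

    def fit(self, profile_ci: bool = True, ci_tol: float = 1e-4) -> "EORResults":
        """Maximize the likelihood; optionally profile a 95% CI for theta1."""
        # Warm start: logistic fit with theta = 0.
        logit0 = sm.Logit(self.y, self.X).fit(disp=0, maxiter=200)
        start = np.concatenate([np.asarray(logit0.params), np.zeros(self.n_theta)])
        params, llf, ok = self._optimize(start)
        loglik_null = float(logit0.llf)
        if llf < loglik_null - 1e-8:
            # theta = 0 must never fit worse than the submodel it nests.
            params, llf, ok = start, loglik_null, ok
        ci = (np.nan, np.nan)
        if profile_ci and "theta1" in self.theta_names:
            ci = self._profile_ci_theta1(params, llf, tol=ci_tol)
        named = pd.Series(params, index=self.exog_names + self.theta_names)
        return EORResults(
            model=self,
            params=named,
            loglik=llf,
            loglik_theta0=loglik_null,
            theta1_ci=ci,
            converged=ok,
        )

    def _profile_theta1(self, theta1: float, start: np.ndarray) -> float:
        _, llf, _ = self._optimize(start, fixed_theta1=theta1)
        return llf

    def _profile_ci_theta1(
        self, params: np.ndarray, llf_max: float, tol: float = 1e-4
    ) -> tuple[float, float]:
        """95% profile-likelihood bounds for theta1 by bisection.

        Each bound solves ``profile(theta1) = llf_max - chi2_1(0.95)/2``.
        The lower search is bracketed by the positivity bound when the
        drop is never reached (the bound is then reported at the
        constraint edge).
        """
        i_t1 = self.n_beta + self.theta_names.index("theta1")
        hat = params[i_t1]
        target = llf_max - _CHI2_1_HALF_95

        def prof(t1):
            return self._profile_theta1(t1, params.copy())

        # Upper bound: expand until profile drops below target.
        step = max(0.5, abs(hat))
        hi = hat + step
        for _ in range(60):
            if prof(hi) < target:
                break
            hi = hat + (hi - hat) * 2.0
        else:
            return (np.nan, np.inf)
        lo_br, hi_br = hat, hi
        while hi_br - lo_br > tol:
            mid = 0.5 * (lo_br + hi_br)
            if prof(mid) >= target:
                lo_br = mid
            else:
                hi_br = mid
        upper = 0.5 * (lo_br + hi_br)

        # Lower bound: bracket between the positivity constraint and hat.
        floor = (
            -1.0 / self.d_max + 2 * _EPS_POS
            if self.dose_terms in ("linear", "linear_quadratic")
            else hat - 10 * max(1.0, abs(hat))
        )
        if prof(floor) >= target:
            lower = floor  # drop not reached inside the feasible region
        else:
            lo_br, hi_br = floor, hat
            while hi_br - lo_br > tol:
                mid = 0.5 * (lo_br + hi_br)
                if prof(mid) >= target:
                    hi_br = mid
                else:
                    lo_br = mid
            lower = 0.5 * (lo_br + hi_br)
        return (float(lower), float(upper))


@dataclass
class EORResults:
    """Fitted excess-odds-ratio model.

    ``params`` holds the log-linear coefficients followed by the dose
    parameters (theta1 per Gy, theta2 per Gy^2 as applicable);
    ``loglik_theta0`` is the nested plain-logistic log-likelihood, so
    ``lrt(loglik, loglik_theta0, df=n_theta)`` is the dose-trend test.
    """

    model: ExcessOddsRatioLogit
    params: pd.Series
    loglik: float
    loglik_theta0: float
    theta1_ci: tuple[float, float]
    converged: bool

    @property
    def theta1(self) -> float:
        return float(self.params.get("theta1", np.nan))

    @property
    def theta2(self) -> float:
        return float(self.params.get("theta2", np.nan))

    def dose_trend_lrt(self) -> LRTResult:
        return lrt(self.loglik, self.loglik_theta0, df=self.model.n_theta)

    def summary(self) -> str:
        lines = [
            "Excess odds ratio dose-response model",
            f"  dose terms: {self.model.dose_terms}   n = {len(self.model.y)}",
            f"  loglik = {self.loglik:.4f}   (theta=0 submodel: {self.loglik_theta0:.4f})",
            f"  converged: {self.converged}",
            "  parameters:",
        ]
        for name, val in self.params.items():
            lines.append(f"    {name:>12s} = {val: .4f}")
        if "theta1" in self.params.index:
            lo, hi = self.theta1_ci
            lines.append(
                f"  EOR per Gy (theta1) = {self.theta1:.3f}, "
                f"95% profile CI ({lo:.3f}, {hi:.3f})"
            )
            t = self.dose_trend_lrt()
            lines.append(
                f"  dose trend LRT: chi2({t.df}) = {t.statistic:.3f}, p = {t.p:.3g}"
            )
        return "\n".join(lines)


def fit_eor(
    outcome,
    dose_Gy,
    design: pd.DataFrame | None = None,
    dose_terms: str = "linear",
    profile_ci: bool = True,
) -> EORResults:
    """Convenience wrapper: build and fit an :class:`ExcessOddsRatioLogit`."""
    y = np.asarray(outcome, dtype=float)
    if design is None:
        design = pd.DataFrame(index=pd.RangeIndex(len(y)))
    model = ExcessOddsRatioLogit(y, design, dose_Gy, dose_terms=dose_terms)
    return model.fit(profile_ci=profile_ci)
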