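"""The five estimation strategies and the multiple-imputation engine.

Every strategy answers the same question — what is the slope of an
unadjusted linear regression of the participant-level outcome on delirium
duration? — but resolves missing daily assessments differently:

``complete_case``
    drop every participant with at least one missing day.
``adhoc_worst`` / ``adhoc_best``
    deterministically substitute missing assessments with delirium present
    (worst) or absent (best), then recompute durations.
``passive_mi``
    "impute then transform": multiply impute the *daily* statuses from a
    logistic model on daily SOFA and the outcome, recompute the duration in
    each completed dataset, fit the analysis model per completion, and pool
    with Rubin's rules.
``active_mi``
    "just another variable": collapse to a participant-level table
    (duration, mean SOFA over the stay, outcome), multiply impute the
    *summary* itself with Bayesian normal linear regression (or predictive
    mean matching), fit per completion, and pool.  Observed daily
    assessments of participants with an undefined duration are deliberately
    ignored — that is the defining property of the approach.

Both MI strategies draw imputation-model parameters from their approximate
posterior before drawing values ("proper" imputation), so the
between-imputation variance reflects model uncertainty.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from scipy.special import expit

from .cohort import Cohort, _as_rng

__all__ = [
    "NonEstimableError",
    "StrategyEstimate",
    "PoolingResult",
    "fit_analysis_model",
    "complete_case",
    "adhoc_impute",
    "impute_binary_daily",
    "passive_mi",
    "active_mi",
    "rubins_pool",
    "STRATEGIES",
    "ALL_STRATEGIES",
]

#: minimum observed participant-days for fitting the daily imputation model
MIN_OBSERVED_DAYS = 20


class NonEstimableError(RuntimeError):
    """A strategy could not produce an estimate on this dataset.

    Raised, for example, when fewer than three participants survive
    complete-case exclusion or when the retained durations are constant.
    The simulation loop tallies these rather than crashing: non-estimable
    replicates are a finding, not a failure.
    """


@dataclasses.dataclass
class StrategyEstimate:
    """Slope estimate from one strategy on one dataset."""

    strategy_name: str
    beta_hat: float
    se: float
    df: float
    n_used: int
    b_imputations: int = 0

    def conf_int(self, level: float = 0.95) -> tuple[float, float]:
        """t-based confidence interval (normal when df is infinite)."""
        crit = stats.t.ppf(0.5 + level / 2.0, self.df)
        return (self.beta_hat - crit * self.se, self.beta_hat + crit * self.se)

    def covers(self, value: float, level: float = 0.95) -> bool:
        lo, hi = self.conf_int(level)
        return bool(lo <= value <= hi)


@dataclasses.dataclass
class PoolingResult:
    """Rubin's-rules combination of B imputation-specific estimates."""

    q_bar: float
    w: float
    b_var: float
    t_var: float
    df: float

    @property
    def se(self) -> float:
        return float(np.sqrt(self.t_var))


# ----------------------------------------------------------------------
# analysis model
# ----------------------------------------------------------------------
def fit_analysis_model(
    durations,
    outcomes,
    strategy_name: str = "ols",
    b_imputations: int = 0,
) -> StrategyEstimate:
    """Unadjusted OLS of the outcome on delirium duration.

    Returns the duration slope, its standard error and the residual degrees
    of freedom ``n - 2``.  The model deliberately contains no confounders:
    the point of the design is to isolate the missing-data strategy.
    """
    x = np.asarray(durations, dtype=float)
    y = np.asarray(outcomes, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("durations and outcomes must be 1-d and aligned")
    if np.isnan(x).any() or np.isnan(y).any():
        raise ValueError("analysis model requires defined durations and outcomes")
    n = len(x)
    if n < 3:
        raise NonEstimableError(f"need at least 3 participants, got {n}")
    if np.ptp(x) == 0:
        raise NonEstimableError("duration is constant: slope not identifiable")
    res = sm.OLS(y, sm.add_constant(x)).fit()
    se = float(res.bse[1])
    tss = float(((y - y.mean()) ** 2).sum())
    if res.ssr <= 1e-24 * max(tss, 1.0):  # numerically perfect fit
        se = 0.0
        warnings.warn(
            "outcome is an exact linear function of duration; "
            "standard error is zero",
            stacklevel=2,
        )
    return StrategyEstimate(
        strategy_name=strategy_name,
        beta_hat=float(res.params[1]),
        se=se,
        df=float(res.df_resid),
        n_used=n,
        b_imputations=b_imputations,
    )


# ----------------------------------------------------------------------
# non-MI strategies
# ----------------------------------------------------------------------
def complete_case(cohort: Cohort) -> StrategyEstimate:
    """Exclude every participant with one or more missing daily assessments."""
    keep = ~cohort.has_missing_days().to_numpy(bool)
    n_used = int(keep.sum())
    if n_used < 3:
        raise NonEstimableError(
            f"only {n_used} participants have complete assessments"
        )
    dur = cohort.durations().to_numpy(float)[keep]
    y = cohort.outcomes().to_numpy(float)[keep]
    return fit_analysis_model(dur, y, strategy_name="complete_case")


def adhoc_impute(cohort: Cohort, fill: str) -> StrategyEstimate:
    """Deterministic single substitution of missing assessments.

    ``fill='worst'`` treats every missing day as delirium present (the
    summary can only grow); ``fill='best'`` as absent.  Every duration
    becomes defined, so the full sample size is retained — at the price of
    systematically over- or understating the exposure.
    """
    if fill not in ("worst", "best"):
        raise ValueError("fill must be 'worst' or 'best'")
    deli = cohort.days["delirium"]
    pid = cohort.days["participant_id"]
    present = deli.fillna(0.0).groupby(pid, sort=False).sum()
    dur = present.reindex(cohort.participants.index).to_numpy(float)
    if fill == "worst":
        n_miss = deli.isna().groupby(pid, sort=False).sum()
        dur = dur + n_miss.reindex(cohort.participants.index).to_numpy(float)
    y = cohort.outcomes().to_numpy(float)
    return fit_analysis_model(dur, y, strategy_name=f"adhoc_{fill}")


# ----------------------------------------------------------------------
# daily-level (passive) imputation engine
# ----------------------------------------------------------------------
def _ridge_logit(
    X: np.ndarray, y: np.ndarray, penalty: float = 1e-4, max_iter: int = 50
) -> tuple[np.ndarray, np.ndarray]:
    """Ridge-penalised logistic MLE by Newton iterations.

    Fallback when the unpenalised fit fails (complete separation or a
    singular information matrix); the small penalty keeps the Hessian
    invertible without materially shrinking well-identified coefficients.
    """
    k = X.shape[1]
    beta = np.zeros(k)
    eye = penalty * np.eye(k)
    for _ in range(max_iter):
        p = expit(X @ beta)
        w = p * (1.0 - p)
        hess = (X * w[:, None]).T @ X + eye
        grad = X.T @ (y - p) - penalty * beta
        step = np.linalg.solve(hess, grad)
        beta = beta + step
        if np.max(np.abs(step)) < 1e-10:
            break
    p = expit(X @ beta)
    w = np.clip(p * (1.0 - p), 1e-12, None)
    cov = np.linalg.inv((X * w[:, None]).T @ X + eye)
    return beta, cov


class _DailyImputer:
    """Fitted daily-level imputation model, reusable across B draws.

    Fits the logistic regression of observed delirium on the predictors
    once; each draw then samples a coefficient vector from the approximate
    posterior N(MLE, inverse observed information) and Bernoulli values for
    the missing days.
    """

    def __init__(self, cohort: Cohort, predictors=("sofa", "outcome")):
        days = cohort.days
        deli = days["delirium"].to_numpy(float)
        obs = ~np.isnan(deli)
        self.n_missing = int((~obs).sum())
        self.n_participants = cohort.n_participants

        cols = [np.ones(len(days))]
        for name in predictors:
            if name == "sofa":
                cols.append(days["sofa"].to_numpy(float))
            elif name == "outcome":
                cols.append(cohort.day_outcomes())
            else:
                raise ValueError(f"unknown predictor {name!r}")
        X = np.column_stack(cols)
        if np.isnan(X).any():
            raise ValueError("imputation predictors must be fully observed")

        codes = cohort.participant_codes()
        self.mis_X = X[~obs]
        self.mis_codes = codes[~obs]
        self.obs_present = np.bincount(
            codes[obs], weights=deli[obs], minlength=self.n_participants
        )
        self._miss_row_mask = ~obs

        y = deli[obs]
        n_obs = len(y)
        if self.n_missing and n_obs < MIN_OBSERVED_DAYS:
            raise NonEstimableError(
                f"only {n_obs} observed assessments: too few to fit the "
                "daily imputation model"
            )
        self.const_prob: float | None = None
        self.beta = None
        self.chol = None
        if self.n_missing == 0:
            return
        if y.min() == y.max():
            warnings.warn(
                "all observed assessments are a single class; imputing the "
                "observed class",
                stacklevel=3,
            )
            self.const_prob = float(y[0])
            return
        beta, cov = self._fit(X[obs], y)
        self.beta = beta
        self.chol = self._safe_cholesky(cov)

    @staticmethod
    def _fit(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = sm.Logit(y, X).fit(disp=0, maxiter=100)
            beta = np.asarray(res.params, float)
            cov = np.asarray(res.cov_params(), float)
            converged = bool(res.mle_retvals.get("converged", False))
            if (
                not converged
                or not np.all(np.isfinite(beta))
                or not np.all(np.isfinite(cov))
                or np.max(np.abs(beta)) > 50.0
            ):
                raise np.linalg.LinAlgError("unstable logistic fit")
            return beta, cov
        except Exception:
            warnings.warn(
                "logistic imputation model unstable (separation or "
                "non-convergence); using ridge-penalised fit",
                stacklevel=4,
            )
            return _ridge_logit(X, y)

    @staticmethod
    def _safe_cholesky(cov: np.ndarray) -> np.ndarray:
        jitter = 0.0
        for _ in range(6):
            try:
                return np.linalg.cholesky(cov + jitter * np.eye(cov.shape[0]))
            except np.linalg.LinAlgError:
                jitter = max(jitter * 10.0, 1e-12)
        raise np.linalg.LinAlgError("imputation-model covariance not PSD")

    def draw_missing(self, rng: np.random.Generator) -> np.ndarray:
        """One stochastic completion of the missing statuses (0/1 array)."""
        if self.const_prob is not None:
            p = np.full(self.n_missing, self.const_prob)
        else:
            beta = self.beta + self.chol @ rng.standard_normal(len(self.beta))
            p = expit(self.mis_X @ beta)
        return (rng.random(self.n_missing) < p).astype(float)

    def draw_durations(self, rng: np.random.Generator) -> np.ndarray:
        imputed = self.draw_missing(rng)
        filled = np.bincount(
            self.mis_codes, weights=imputed, minlength=self.n_participants
        )
        return self.obs_present + filled


def impute_binary_daily(
    cohort: Cohort,
    predictors=("sofa", "outcome"),
    rng: np.random.Generator | int | None = None,
) -> Cohort:
    """One proper stochastic completion of the daily delirium statuses.

    Building block of :func:`passive_mi`; exposed for inspection of single
    completed datasets.  A cohort without missing days is returned as a
    copy, unchanged.
    """
    rng = _as_rng(rng)
    imputer = _DailyImputer(cohort, predictors=predictors)
    out = cohort.copy()
    if imputer.n_missing == 0:
        return out
    values = imputer.draw_missing(rng)
    deli = out.days["delirium"].to_numpy(float)
    deli[imputer._miss_row_mask] = values
    out.days["delirium"] = deli
    return out


def passive_mi(
    cohort: Cohort,
    b: int = 10,
    rng: np.random.Generator | int | None = None,
    predictors=("sofa", "outcome"),
) -> StrategyEstimate:
    """Passive multiple imputation: impute daily, then summarise.

    B independent completions of the daily statuses; in each, durations are
    recomputed and the analysis model refit; estimates are pooled with
    Rubin's rules.  Preserves every observed assessment.
    """
    if b < 2:
        raise ValueError("multiple imputation needs B >= 2")
    rng = _as_rng(rng)
    y = cohort.outcomes().to_numpy(float)
    imputer = _DailyImputer(cohort, predictors=predictors)
    if imputer.n_missing == 0:
        est = fit_analysis_model(
            cohort.durations(), y, strategy_name="passive_mi", b_imputations=b
        )
        est.df = np.inf  # between-imputation variance is exactly zero
        return est
    pairs = []
    for _ in range(b):
        dur = imputer.draw_durations(rng)
        fit = fit_analysis_model(dur, y)
        pairs.append((fit.beta_hat, fit.se))
    pooled = rubins_pool(pairs)
    return StrategyEstimate(
        strategy_name="passive_mi",
        beta_hat=pooled.q_bar,
        se=pooled.se,
        df=pooled.df,
        n_used=cohort.n_participants,
        b_imputations=b,
    )


# ----------------------------------------------------------------------
# summary-level (active) imputation
# ----------------------------------------------------------------------
def active_mi(
    cohort: Cohort,
    b: int = 10,
    rng: np.random.Generator | int | None = None,
    method: str = "bayes",
    pmm_k: int = 5,
) -> StrategyEstimate:
    """Active multiple imputation: treat the summary as just another variable.

    The cohort collapses to one row per participant — duration (undefined
    where any day is missing), mean SOFA over the whole stay, outcome.  The
    undefined durations are multiply imputed from a Bayesian normal linear
    regression on mean SOFA and outcome (coefficients and residual variance
    drawn from the standard conjugate posterior; predictive draws rounded
    and clipped to [0, length of stay]), or by predictive mean matching
    when ``method='pmm'``.  Partially observed daily assessments contribute
    nothing beyond whether the duration is defined.
    """
    if b < 2:
        raise ValueError("multiple imputation needs B >= 2")
    if method not in ("bayes", "pmm"):
        raise ValueError("method must be 'bayes' or 'pmm'")
    rng = _as_rng(rng)

    dur = cohort.durations().to_numpy(float)
    y = cohort.outcomes().to_numpy(float)
    mean_sofa = (
        cohort.days.groupby("participant_id", sort=False)["sofa"]
        .mean()
        .reindex(cohort.participants.index)
        .to_numpy(float)
    )
    los = cohort.length_of_stay().to_numpy(float)

    observed = ~np.isnan(dur)
    n_obs = int(observed.sum())
    if not (~observed).any():
        est = fit_analysis_model(
            dur, y, strategy_name="active_mi", b_imputations=b
        )
        est.df = np.inf
        return est
    if n_obs < 3:
        raise NonEstimableError(
            f"only {n_obs} participants have a defined duration"
        )

    X = np.column_stack([np.ones(len(dur)), mean_sofa, y])
    X_obs, X_mis = X[observed], X[~observed]
    y_obs = dur[observed]
    k = X.shape[1]
    nu = n_obs - k
    if nu < 1:
        raise NonEstimableError(
            f"{n_obs} observed durations cannot identify the {k}-parameter "
            "imputation model"
        )
    gram = X_obs.T @ X_obs
    try:
        gram_inv = np.linalg.inv(gram)
        chol = np.linalg.cholesky(gram_inv)
    except np.linalg.LinAlgError as err:
        raise NonEstimableError(
            "imputation design is singular (collinear predictors)"
        ) from err
    beta_hat = gram_inv @ (X_obs.T @ y_obs)
    resid = y_obs - X_obs @ beta_hat
    rss = float(resid @ resid)

    pairs = []
    for _ in range(b):
        sigma2 = rss / rng.chisquare(nu) if rss > 0 else 0.0
        sigma = np.sqrt(sigma2)
        beta_draw = beta_hat + sigma * (chol @ rng.standard_normal(k))
        mu_mis = X_mis @ beta_draw
        if method == "bayes":
            draw = mu_mis + sigma * rng.standard_normal(len(mu_mis))
            imputed = np.clip(np.rint(draw), 0.0, los[~observed])
        else:
            imputed = _pmm_draw(
                X_obs @ beta_draw, mu_mis, y_obs, k_donors=pmm_k, rng=rng
            )
        completed = dur.copy()
        completed[~observed] = imputed
        fit = fit_analysis_model(completed, y)
        pairs.append((fit.beta_hat, fit.se))
    pooled = rubins_pool(pairs)
    return StrategyEstimate(
        strategy_name="active_mi",
        beta_hat=pooled.q_bar,
        se=pooled.se,
        df=pooled.df,
        n_used=cohort.n_participants,
        b_imputations=b,
    )


def _pmm_draw(
    pred_obs: np.ndarray,
    pred_mis: np.ndarray,
    y_obs: np.ndarray,
    k_donors: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Predictive mean matching: donate an observed duration from the
    k nearest observed cases by predicted mean, ties broken at random."""
    k_donors = min(k_donors, len(y_obs))
    out = np.empty(len(pred_mis))
    for i, mu in enumerate(pred_mis):
        dist = np.abs(pred_obs - mu)
        # random tie-break: jitter the argpartition order
        order = np.argsort(dist + rng.random(len(dist)) * 1e-9, kind="stable")
        out[i] = y_obs[order[rng.integers(k_donors)]]
    return out


# ----------------------------------------------------------------------
# Rubin's rules
# ----------------------------------------------------------------------
def rubins_pool(estimates) -> PoolingResult:
    """Pool B (estimate, standard error) pairs with Rubin's rules.

    q_bar = mean estimate; W = mean squared SE (within-imputation
    variance); B_var = sample variance of the estimates; total variance
    T = W + (1 + 1/B) B_var; degrees of freedom
    df = (B - 1) (1 + W / ((1 + 1/B) B_var))^2, infinite when B_var = 0.
    """
    arr = np.asarray(list(estimates), dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("estimates must be (beta_hat, se) pairs")
    n_imp = arr.shape[0]
    if n_imp < 2:
        raise ValueError("pooling needs at least 2 imputations")
    betas, ses = arr[:, 0], arr[:, 1]
    if (ses < 0).any():
        raise ValueError("standard errors must be non-negative")
    q_bar = float(betas.mean())
    w = float((ses**2).mean())
    b_var = float(betas.var(ddof=1))
    t_var = w + (1.0 + 1.0 / n_imp) * b_var
    if b_var == 0.0:
        df = np.inf
    else:
        df = (n_imp - 1) * (1.0 + w / ((1.0 + 1.0 / n_imp) * b_var)) ** 2
    return PoolingResult(q_bar=q_bar, w=w, b_var=b_var, t_var=t_var, df=float(df))


# ----------------------------------------------------------------------
# registry
# ----------------------------------------------------------------------
def _run_complete_case(cohort, rng=None, b=10, **kw):
    return complete_case(cohort)


def _run_adhoc_worst(cohort, rng=None, b=10, **kw):
    return adhoc_impute(cohort, "worst")


def _run_adhoc_best(cohort, rng=None, b=10, **kw):
    return adhoc_impute(cohort, "best")


def _run_passive(cohort, rng=None, b=10, **kw):
    return passive_mi(cohort, b=b, rng=rng, **kw)


def _run_active(cohort, rng=None, b=10, **kw):
    return active_mi(cohort, b=b, rng=rng, **kw)


STRATEGIES = {
    "complete_case": _run_complete_case,
    "adhoc_worst": _run_adhoc_worst,
    "adhoc_best": _run_adhoc_best,
    "passive_mi": _run_passive,
    "active_mi": _run_active,
}

ALL_STRATEGIES = tuple(STRATEGIES)
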