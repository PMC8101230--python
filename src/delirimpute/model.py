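"""Model/Results facade for fitting one dataset under a chosen strategy.

`DurationOutcomeModel` wraps a participant-day cohort and exposes the
unadjusted linear association between delirium duration and the outcome
under any of the five missing-data strategies; `fit()` returns a
`DurationOutcomeResults` carrying the slope, its standard error, degrees of
freedom, confidence interval and a text `summary()`.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import Cohort, read_cohort_csv
from .strategies import ALL_STRATEGIES, STRATEGIES, NonEstimableError, StrategyEstimate

__all__ = ["DurationOutcomeModel", "DurationOutcomeResults"]


class DurationOutcomeModel:
    """Outcome ~ delirium duration, estimated under a missing-data strategy.

    Parameters
    ----------
    cohort
        A :class:`~delirimpute.cohort.Cohort` whose participants carry an
        outcome.  Daily delirium assessments may be partially missing; how
        they are handled is decided at :meth:`fit` time.
    """

    def __init__(self, cohort: Cohort):
        if cohort.outcomes().isna().any():
            raise ValueError("every participant needs an observed outcome")
        self.cohort = cohort

    @classmethod
    def from_dataframe(
        cls, days: pd.DataFrame, outcomes: pd.Series | dict | None = None
    ) -> "DurationOutcomeModel":
        """Build from a long participant-day frame plus per-participant outcomes.

        ``days`` needs columns ``participant_id, day, delirium, sofa`` with
        delirium coded 1/0/NaN.  ``outcomes`` maps participant id to the
        outcome; alternatively an ``outcome`` column repeated per row may be
        included in ``days``.
        """
        days = pd.DataFrame(days)
        participants = None
        if outcomes is not None:
            participants = pd.Series(outcomes, name="outcome").to_frame()
            participants.index.name = "participant_id"
        elif "outcome" in days.columns:
            participants = (
                days.groupby("participant_id", sort=False)["outcome"].first().to_frame()
            )
            days = days.drop(columns="outcome")
        return cls(Cohort(days, participants))

    @classmethod
    def from_csv(cls, path) -> "DurationOutcomeModel":
        return cls(read_cohort_csv(path))

    def fit(
        self,
        strategy: str = "passive_mi",
        b: int = 10,
        seed: int | np.random.Generator | None = None,
        **kwargs,
    ) -> "DurationOutcomeResults":
        """Estimate the duration slope under one strategy.

        ``b`` and ``seed`` only matter for the MI strategies; extra keyword
        arguments are forwarded (e.g. ``predictors`` for passive MI,
        ``method='pmm'`` for active MI).
        """
        if strategy not in STRATEGIES:
            raise ValueError(
                f"unknown strategy {strategy!r}; choose from {ALL_STRATEGIES}"
            )
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        estimate = STRATEGIES[strategy](self.cohort, rng=rng, b=b, **kwargs)
        return DurationOutcomeResults(self, estimate)

    def fit_all(
        self, b: int = 10, seed: int | None = None, **kwargs
    ) -> dict[str, "DurationOutcomeResults | None"]:
        """Fit every strategy; ``None`` marks a non-estimable one."""
        out: dict[str, DurationOutcomeResults | None] = {}
        ss = np.random.SeedSequence(seed)
        for name, child in zip(ALL_STRATEGIES, ss.spawn(len(ALL_STRATEGIES))):
            try:
                out[name] = self.fit(
                    strategy=name, b=b, seed=np.random.default_rng(child), **kwargs
                )
            except NonEstimableError:
                out[name] = None
        return out


class DurationOutcomeResults:
    """Estimate container with statsmodels-flavoured accessors."""

    def __init__(self, model: DurationOutcomeModel, estimate: StrategyEstimate):
        self.model = model
        self.estimate = estimate

    # -- scalar accessors ------------------------------------------------
    @property
    def strategy(self) -> str:
        return self.estimate.strategy_name

    @property
    def params(self) -> float:
        """Estimated change in outcome per additional delirium day."""
        return self.estimate.beta_hat

    @property
    def bse(self) -> float:
        return self.estimate.se

    @property
    def df_resid(self) -> float:
        return self.estimate.df

    @property
    def nobs(self) -> int:
        return self.estimate.n_used

    @property
    def tvalues(self) -> float:
        return self.estimate.beta_hat / self.estimate.se

    @property
    def pvalues(self) -> float:
        return 2.0 * stats.t.sf(abs(self.tvalues), self.estimate.df)

    def conf_int(self, alpha: float = 0.05) -> tuple[float, float]:
        return self.estimate.conf_int(level=1.0 - alpha)

    def summary(self, alpha: float = 0.05) -> str:
        lo, hi = self.conf_int(alpha)
        e = self.estimate
        df_txt = "inf" if np.isinf(e.df) else f"{e.df:.1f}"
        lines = [
            "Delirium duration vs. outcome (unadjusted linear model)",
            "=" * 56,
            f"strategy:            {e.strategy_name}",
            f"participants used:   {e.n_used}",
            f"imputations (B):     {e.b_imputations if e.b_imputations else '-'}",
            f"duration slope:      {e.beta_hat:.4f}",
            f"std. error:          {e.se:.4f}",
            f"df:                  {df_txt}",
            f"{100 * (1 - alpha):.0f}% CI:              [{lo:.4f}, {hi:.4f}]",
            f"t:                   {self.tvalues:.3f}   p: {self.pvalues:.4g}",
            "=" * 56,
        ]
        return "\n".join(lines)

    def __repr__(self) -> str:
        e = self.estimate
        return (
            f"<DurationOutcomeResults {e.strategy_name}: "
            f"beta={e.beta_hat:.4f} se={e.se:.4f} n={e.n_used}>"
        )
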