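"""Synthetic base cohort with the structure of ICU participant-day data.

The simulation design calls for cluster resampling from a real critical-care
base sample whose daily delirium statuses are serially correlated and whose
daily SOFA severity score is elevated on delirious days.  No such sample is
distributable, so this module generates a synthetic one with the same
statistical structure:

* length of stay drawn from a truncated geometric (right-skewed, ICU-like)
  or truncated Poisson distribution on ``[los_min, los_max]``, calibrated to
  a target mean stay;
* daily delirium following a two-state Markov chain with initial probability
  ``p_init``, persistence ``p_stay_del`` = P(delirious tomorrow | delirious
  today) and incidence ``p_new_del`` = P(delirious tomorrow | not delirious
  today);
* SOFA built from a participant-level severity anchor plus an additive shift
  on delirious days plus day-level noise, rounded and clipped to the
  clinical [0, 24] integer range.

The positive SOFA-delirium association induced by ``sofa_del_shift`` is what
makes SOFA a useful auxiliary for MAR missingness and for the imputation
models.  Defaults give a participant-day delirium prevalence near 0.40 and a
mean stay of 7 days, i.e. a mean duration of 2-3 delirious days.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .cohort import Cohort, _as_rng

__all__ = ["BaseCohortParams", "generate_base_cohort", "summarize_base"]


@dataclasses.dataclass
class BaseCohortParams:
    """Parameters of the synthetic base-cohort generator.

    All defaults live here so that sensitivity sweeps can vary them in one
    place.  ``los_dist`` is ``"geometric"`` (default) or ``"poisson"``.
    """

    n_base: int = 1000
    los_min: int = 2
    los_max: int = 30
    los_mean: float = 7.0
    los_dist: str = "geometric"
    p_init: float = 0.4
    p_stay_del: float = 0.7
    p_new_del: float = 0.2
    sofa_base_mean: float = 6.0
    sofa_base_sd: float = 3.0
    sofa_del_shift: float = 3.0
    sofa_noise_sd: float = 2.0

    def validate(self) -> None:
        if self.n_base < 1:
            raise ValueError("n_base must be positive")
        if not (1 <= self.los_min <= self.los_max <= 30):
            raise ValueError("need 1 <= los_min <= los_max <= 30")
        if not (self.los_min <= self.los_mean <= self.los_max):
            raise ValueError("los_mean must lie within [los_min, los_max]")
        for name in ("p_init", "p_stay_del", "p_new_del"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be a probability, got {v}")
        if self.p_stay_del < self.p_new_del:
            raise ValueError("delirium must persist: p_stay_del >= p_new_del")
        if self.los_dist not in ("geometric", "poisson"):
            raise ValueError(f"unknown los_dist {self.los_dist!r}")
        if self.sofa_base_sd < 0 or self.sofa_noise_sd < 0:
            raise ValueError("SOFA standard deviations must be non-negative")

    def stationary_prevalence(self) -> float:
        """Long-run delirium prevalence of the two-state chain."""
        denom = self.p_new_del + 1.0 - self.p_stay_del
        if denom == 0.0:  # absorbing in both states: prevalence set by p_init
            return self.p_init
        return self.p_new_del / denom


def _los_pmf(params: BaseCohortParams) -> tuple[np.ndarray, np.ndarray]:
    """Support and probabilities of the LOS distribution, mean-calibrated."""
    k = np.arange(params.los_min, params.los_max + 1)
    if params.los_min == params.los_max:
        return k, np.ones(1)

    if params.los_dist == "geometric":
        # weights (1-q)^(k - los_min); mean decreases from midpoint (q->0)
        # to los_min (q->1)
        def mean_at(q: float) -> float:
            w = (1.0 - q) ** (k - params.los_min)
            return float((k * w).sum() / w.sum())

        midpoint = (params.los_min + params.los_max) / 2.0
        if params.los_mean >= midpoint:
            raise ValueError(
                f"truncated geometric mean must be below the support midpoint "
                f"{midpoint}; got los_mean={params.los_mean}"
            )
        q = optimize.brentq(
            lambda q: mean_at(q) - params.los_mean, 1e-12, 1 - 1e-12, xtol=1e-13
        )
        w = (1.0 - q) ** (k - params.los_min)
    else:  # truncated Poisson: mean increases with the rate
        def mean_at(lam: float) -> float:
            w = stats.poisson.pmf(k, lam)
            return float((k * w).sum() / w.sum())

        lam = optimize.brentq(
            lambda lam: mean_at(lam) - params.los_mean, 1e-9, 500.0, xtol=1e-10
        )
        w = stats.poisson.pmf(k, lam)
    return k, w / w.sum()


def generate_base_cohort(
    params: BaseCohortParams | None = None,
    rng: np.random.Generator | int | None = None,
) -> Cohort:
    """Generate a fully observed synthetic base cohort.

    Every daily status is observed (no missingness); missingness is imposed
    downstream by :mod:`delirimpute.missingness`.
    """
    params = params or BaseCohortParams()
    params.validate()
    rng = _as_rng(rng)

    support, probs = _los_pmf(params)
    los = rng.choice(support, size=params.n_base, p=probs)
    t_max = int(los.max())

    status = np.empty((params.n_base, t_max), dtype=bool)
    status[:, 0] = rng.random(params.n_base) < params.p_init
    for t in range(1, t_max):
        u = rng.random(params.n_base)
        status[:, t] = np.where(
            status[:, t - 1], u < params.p_stay_del, u < params.p_new_del
        )

    anchor = rng.normal(params.sofa_base_mean, params.sofa_base_sd, params.n_base)
    noise = rng.normal(0.0, params.sofa_noise_sd, (params.n_base, t_max))
    sofa = np.rint(
        np.clip(anchor[:, None] + params.sofa_del_shift * status + noise, 0, 24)
    ).astype(np.int64)

    alive = np.arange(t_max)[None, :] < los[:, None]
    pid = np.repeat(np.arange(params.n_base), los)
    day = np.concatenate([np.arange(1, stay + 1) for stay in los])
    days = pd.DataFrame(
        {
            "participant_id": pid,
            "day": day,
            "delirium": status[alive].astype(float),
            "sofa": sofa[alive],
        }
    )
    return Cohort(
        days,
        provenance={"generator": dataclasses.asdict(params)},
        validate=False,
    )


def summarize_base(cohort: Cohort) -> pd.Series:
    """Descriptive summary used to check the generator's calibration."""
    if cohort.n_participants == 0:
        raise ValueError("cohort is empty")
    deli = cohort.days["delirium"]
    dur = cohort.durations().to_numpy(float)
    on = cohort.days.loc[deli == 1.0, "sofa"]
    off = cohort.days.loc[deli == 0.0, "sofa"]
    quantiles = np.nanquantile(dur, [0.0, 0.25, 0.5, 0.75, 1.0])
    return pd.Series(
        {
            "n_participants": cohort.n_participants,
            "n_days": cohort.n_days,
            "mean_los": cohort.length_of_stay().mean(),
            "delirium_prevalence": deli.mean(),
            "mean_duration": np.nanmean(dur),
            "duration_q0": quantiles[0],
            "duration_q25": quantiles[1],
            "duration_q50": quantiles[2],
            "duration_q75": quantiles[3],
            "duration_q100": quantiles[4],
            "sofa_mean_delirium": on.mean() if len(on) else np.nan,
            "sofa_mean_no_delirium": off.mean() if len(off) else np.nan,
        }
    )
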