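"""Impose MCAR / MAR / MNAR missingness on daily delirium assessments.

Missingness targets the exposure assessment only: each participant-day's
delirium status is independently set to missing with a probability given by
the mechanism, while SOFA and the outcome stay fully observed.

* **MCAR** — constant probability ``p`` for every participant-day.
* **MAR** — ``P(missing) = expit(alpha_miss + beta_sofa * SOFA_ij)``:
  missingness depends on the observed auxiliary severity score.
* **MNAR** — ``P(missing) = expit(alpha_miss + beta_del_miss * delirium_ij)``:
  missingness depends on the (to-be-masked) delirium status itself.

For MAR and MNAR the intercept ``alpha_miss`` is not user-set: it is
calibrated by monotone root finding so that the *expected* missing fraction
over the cohort's realised covariate distribution equals the target
proportion; Bernoulli draws then produce the usual sampling variation
around it.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy.optimize import brentq
from scipy.special import expit, logit

from .cohort import Cohort, _as_rng

__all__ = [
    "MECHANISMS",
    "MissingnessSpec",
    "missing_probability",
    "calibrate_alpha",
    "calibrated",
    "impose_missingness",
]

MECHANISMS = ("MCAR", "MAR", "MNAR")

#: tolerance on |expected missing fraction - target| after calibration
CALIBRATION_TOL = 1e-8


@dataclasses.dataclass(frozen=True)
class MissingnessSpec:
    """One missingness configuration: mechanism, target proportion, strength.

    ``strength`` is the logistic slope on the mechanism's covariate (SOFA
    for MAR, the delirium indicator for MNAR); it is unused for MCAR.
    ``alpha_miss`` is the calibrated logistic intercept, derived from a
    cohort by :func:`calibrate_alpha`, never set directly by the user.
    """

    mechanism: str
    proportion: float
    strength: float = 0.0
    alpha_miss: float | None = None

    def __post_init__(self):
        if self.mechanism not in MECHANISMS:
            raise ValueError(f"mechanism must be one of {MECHANISMS}")
        if not 0.0 < self.proportion < 1.0:
            raise ValueError("proportion must lie in (0, 1)")
        if self.strength < 0:
            raise ValueError("strength must be non-negative")
        if self.mechanism == "MCAR" and self.strength != 0.0:
            raise ValueError("MCAR takes no strength parameter")

    @property
    def requires_calibration(self) -> bool:
        return self.mechanism != "MCAR"

    @property
    def label(self) -> str:
        if self.mechanism == "MCAR":
            return "MCAR"
        return f"{self.mechanism}(b={self.strength:g})"


def _covariate(spec: MissingnessSpec, cohort: Cohort) -> np.ndarray:
    if spec.mechanism == "MAR":
        x = cohort.days["sofa"].to_numpy(float)
        if np.isnan(x).any():
            raise ValueError("MAR missingness requires fully observed SOFA")
    else:  # MNAR conditions on the true (pre-masking) delirium status
        x = cohort.days["delirium"].to_numpy(float)
        if np.isnan(x).any():
            raise ValueError(
                "MNAR missingness requires the true delirium status: "
                "impose missingness on a fully observed cohort"
            )
    return x


def calibrate_alpha(spec: MissingnessSpec, cohort: Cohort) -> float:
    """Intercept making the expected missing fraction equal the target.

    The mean of ``expit(alpha + strength * x)`` over the cohort's
    participant-days is continuous and strictly increasing in ``alpha``, so
    the root is found by bracketed bisection (Brent) to within
    ``CALIBRATION_TOL``.
    """
    if not spec.requires_calibration:
        raise ValueError("MCAR needs no intercept calibration")
    x = _covariate(spec, cohort)
    p, s = spec.proportion, spec.strength
    if s == 0.0:
        return float(logit(p))

    def gap(alpha: float) -> float:
        return float(expit(alpha + s * x).mean() - p)

    # expit(logit(p) + s*(x - max)) <= p termwise, so the bracket is exact
    lo = float(logit(p) - s * x.max()) - 1.0
    hi = float(logit(p) - s * x.min()) + 1.0
    alpha = brentq(gap, lo, hi, xtol=1e-13, rtol=8.9e-16)
    if abs(gap(alpha)) > CALIBRATION_TOL:
        raise RuntimeError(
            f"intercept calibration failed for {spec.label} at p={p}: "
            f"residual {gap(alpha):.3e} on bracket [{lo:.3f}, {hi:.3f}]"
        )
    return float(alpha)


def calibrated(spec: MissingnessSpec, cohort: Cohort) -> MissingnessSpec:
    """Return a copy of ``spec`` with ``alpha_miss`` calibrated to ``cohort``."""
    if not spec.requires_calibration:
        return spec
    return dataclasses.replace(spec, alpha_miss=calibrate_alpha(spec, cohort))


def missing_probability(
    spec: MissingnessSpec,
    sofa=None,
    delirium=None,
):
    """Per-day missingness probability under ``spec`` (scalar or vectorised)."""
    if spec.mechanism == "MCAR":
        base = sofa if sofa is not None else delirium
        if base is None:
            return spec.proportion
        return np.full(np.shape(base), spec.proportion, dtype=float)
    if spec.alpha_miss is None:
        raise ValueError(
            f"{spec.mechanism} spec must be calibrated before computing probabilities"
        )
    if spec.mechanism == "MAR":
        if sofa is None:
            raise ValueError("MAR probability needs the SOFA score")
        return expit(spec.alpha_miss + spec.strength * np.asarray(sofa, float))
    if delirium is None:
        raise ValueError("MNAR probability needs the delirium status")
    return expit(spec.alpha_miss + spec.strength * np.asarray(delirium, float))


def impose_missingness(
    cohort: Cohort,
    spec: MissingnessSpec,
    rng: np.random.Generator | int | None = None,
) -> Cohort:
    """Mask delirium assessments according to ``spec``.

    The cohort must be fully observed.  For MAR/MNAR an uncalibrated spec is
    calibrated against this cohort first (deterministic given the cohort).
    The pre-masking status is retained in a ``delirium_true`` column for
    oracle checks only.
    """
    deli = cohort.days["delirium"].to_numpy(float)
    if np.isnan(deli).any():
        raise ValueError("cohort already contains missing assessments")
    rng = _as_rng(rng)
    if spec.requires_calibration and spec.alpha_miss is None:
        spec = calibrated(spec, cohort)

    probs = missing_probability(
        spec,
        sofa=cohort.days["sofa"].to_numpy(float),
        delirium=deli,
    )
    mask = rng.random(cohort.n_days) < probs

    out = cohort.copy()
    out.days["delirium_true"] = deli
    masked = deli.copy()
    masked[mask] = np.nan
    out.days["delirium"] = masked
    out.provenance["missingness"] = {
        "mechanism": spec.mechanism,
        "proportion": spec.proportion,
        "strength": spec.strength,
        "alpha_miss": spec.alpha_miss,
        "n_masked": int(mask.sum()),
    }
    return out
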