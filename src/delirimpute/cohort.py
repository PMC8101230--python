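"""Participant-day data model for ICU-style longitudinal cohorts.

A cohort is a collection of participants, each assessed daily for delirium
(a yes/no status) for the duration of their stay, together with a daily
integer SOFA severity score and a single participant-level continuous
outcome.  The summary exposure of interest is the *delirium duration*: the
number of days a participant was delirious.  A single missing daily
assessment leaves that summary undefined, which is precisely the problem the
estimation strategies in :mod:`delirimpute.strategies` address.

Internally a cohort is held as two aligned pandas frames:

``days``
    long format, one row per participant-day, columns ``participant_id``,
    ``day`` (1-based, consecutive within participant), ``delirium``
    (``1.0`` present / ``0.0`` absent / ``NaN`` missing) and ``sofa``
    (integer in [0, 24]).  After missingness has been imposed an extra
    ``delirium_true`` column retains the pre-masking status for oracle
    checks; it is never consulted by any estimation strategy.

``participants``
    indexed by ``participant_id``, columns ``outcome`` (continuous score,
    ``NaN`` until generated) and ``true_duration`` (populated alongside the
    outcome in synthetic data).

The object API (:class:`Participant`, :class:`ParticipantDay`,
:func:`compute_duration`) mirrors the row-level semantics and is what the
unit-level contracts are written against; the frame-backed accessors are the
vectorised equivalents used by the strategies and the simulation loop.
"""

from __future__ import annotations

import dataclasses
from typing import Hashable, Iterator

import numpy as np
import pandas as pd

__all__ = [
    "ParticipantDay",
    "Participant",
    "Cohort",
    "compute_duration",
    "cluster_resample",
    "generate_outcome",
    "read_cohort_csv",
    "write_cohort_csv",
]

DAY_COLUMNS = ["participant_id", "day", "delirium", "sofa"]
MAX_LOS = 30  # participants are followed to study day 30 at most


def _as_rng(rng: np.random.Generator | int | None) -> np.random.Generator:
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)


@dataclasses.dataclass
class ParticipantDay:
    """One daily assessment: the unit that missingness acts on.

    ``delirium`` is ternary: ``True`` (present), ``False`` (absent) or
    ``None`` (assessment missing).  ``sofa`` is an integer severity score in
    [0, 24]; it is treated as always observed by the strategies but may be
    ``None`` in externally supplied data.
    """

    participant_id: Hashable
    day: int
    delirium: bool | None
    sofa: int | None = None


@dataclasses.dataclass
class Participant:
    participant_id: Hashable
    days: list[ParticipantDay]
    outcome: float | None = None
    true_duration: int | None = None

    @property
    def length_of_stay(self) -> int:
        return len(self.days)


def compute_duration(participant: Participant) -> int | None:
    """Delirium duration, or ``None`` when any daily status is missing.

    Complete-case semantics: one missing assessment leaves the summary
    undefined even if every other day is observed.  The estimation
    strategies each override this in their own way (substitution,
    imputation, exclusion).  ``None`` is a deliberate typed sentinel:
    arithmetic on it raises rather than silently propagating.
    """
    if not participant.days:
        raise ValueError("participant has no days")
    statuses = [d.delirium for d in participant.days]
    if any(s is None for s in statuses):
        return None
    return int(sum(bool(s) for s in statuses))


class Cohort:
    """Long-format participant-day table plus participant-level attributes."""

    def __init__(
        self,
        days: pd.DataFrame,
        participants: pd.DataFrame | None = None,
        provenance: dict | None = None,
        validate: bool = True,
    ):
        days = pd.DataFrame(days).copy()
        missing_cols = [c for c in DAY_COLUMNS if c not in days.columns]
        if missing_cols:
            raise ValueError(f"day table lacks columns {missing_cols}")
        days = days.sort_values(["participant_id", "day"], kind="mergesort")
        days = days.reset_index(drop=True)
        days["day"] = days["day"].astype(np.int64)
        days["delirium"] = days["delirium"].astype(float)
        if days["sofa"].isna().any():
            days["sofa"] = days["sofa"].astype(float)
        else:
            days["sofa"] = days["sofa"].astype(np.int64)

        if participants is None:
            pids = days["participant_id"].drop_duplicates()
            participants = pd.DataFrame(
                {"outcome": np.nan, "true_duration": np.nan},
                index=pd.Index(pids, name="participant_id"),
            )
        else:
            participants = pd.DataFrame(participants).copy()
            if participants.index.name != "participant_id":
                if "participant_id" in participants.columns:
                    participants = participants.set_index("participant_id")
                else:
                    participants.index.name = "participant_id"
            for col in ("outcome", "true_duration"):
                if col not in participants.columns:
                    participants[col] = np.nan
            participants["outcome"] = participants["outcome"].astype(float)
            participants["true_duration"] = participants["true_duration"].astype(float)

        self.days = days
        self.participants = participants
        self.provenance = dict(provenance or {})
        self._day_index_cache: dict | None = None
        if validate:
            self.validate()

    # ------------------------------------------------------------------
    # invariants
    # ------------------------------------------------------------------
    def validate(self) -> None:
        if self.participants.index.has_duplicates:
            raise ValueError("participant ids are not unique")
        day_pids = pd.Index(self.days["participant_id"].unique())
        if not day_pids.isin(self.participants.index).all():
            raise ValueError("day table contains participants absent from the participant table")
        if not self.participants.index.isin(day_pids).all():
            raise ValueError("participant table contains participants with no days")
        # days consecutive from 1 within each participant (table is sorted)
        expected = self.days.groupby("participant_id", sort=False).cumcount() + 1
        if not (self.days["day"].to_numpy() == expected.to_numpy()).all():
            raise ValueError("days must be consecutive starting at 1 within each participant")
        los = self.length_of_stay()
        if (los < 1).any() or (los > MAX_LOS).any():
            raise ValueError(f"length of stay must lie in [1, {MAX_LOS}]")
        sofa = self.days["sofa"]
        observed = sofa.dropna()
        if len(observed) and (
            (observed < 0).any() or (observed > 24).any() or (observed % 1 != 0).any()
        ):
            raise ValueError("SOFA scores must be integers in [0, 24]")
        deli = self.days["delirium"]
        if not deli.dropna().isin([0.0, 1.0]).all():
            raise ValueError("delirium must be 0, 1 or missing")

    # ------------------------------------------------------------------
    # basic accessors
    # ------------------------------------------------------------------
    @property
    def n_participants(self) -> int:
        return len(self.participants)

    @property
    def n_days(self) -> int:
        return len(self.days)

    def length_of_stay(self) -> pd.Series:
        los = self.days.groupby("participant_id", sort=False).size()
        return los.reindex(self.participants.index)

    def durations(self) -> pd.Series:
        """Delirium duration per participant; ``NaN`` where any day is missing."""
        deli = self.days["delirium"]
        pid = self.days["participant_id"]
        has_na = deli.isna().groupby(pid, sort=False).any()
        total = deli.fillna(0.0).groupby(pid, sort=False).sum()
        return total.where(~has_na).reindex(self.participants.index)

    def has_missing_days(self) -> pd.Series:
        pid = self.days["participant_id"]
        return (
            self.days["delirium"].isna().groupby(pid, sort=False).any()
            .reindex(self.participants.index)
        )

    def outcomes(self) -> pd.Series:
        return self.participants["outcome"]

    def day_outcomes(self) -> np.ndarray:
        """Participant outcome broadcast to one value per day row."""
        return (
            self.days["participant_id"].map(self.participants["outcome"]).to_numpy(float)
        )

    def participant_codes(self) -> np.ndarray:
        """Integer position (0..n-1) of each day row's participant."""
        pos = pd.Series(
            np.arange(self.n_participants), index=self.participants.index
        )
        return self.days["participant_id"].map(pos).to_numpy(np.int64)

    def copy(self) -> "Cohort":
        return Cohort(
            self.days.copy(),
            self.participants.copy(),
            provenance=dict(self.provenance),
            validate=False,
        )

    # ------------------------------------------------------------------
    # object API
    # ------------------------------------------------------------------
    def participant(self, pid: Hashable) -> Participant:
        rows = self.days.iloc[self._day_indices()[pid]]
        days = [
            ParticipantDay(
                participant_id=pid,
                day=int(r.day),
                delirium=None if np.isnan(r.delirium) else bool(r.delirium),
                sofa=None if pd.isna(r.sofa) else int(r.sofa),
            )
            for r in rows.itertuples()
        ]
        meta = self.participants.loc[pid]
        outcome = None if pd.isna(meta["outcome"]) else float(meta["outcome"])
        true_dur = (
            None if pd.isna(meta["true_duration"]) else int(meta["true_duration"])
        )
        return Participant(pid, days, outcome=outcome, true_duration=true_dur)

    def iter_participants(self) -> Iterator[Participant]:
        for pid in self.participants.index:
            yield self.participant(pid)

    @classmethod
    def from_participants(
        cls, participants: list[Participant], provenance: dict | None = None
    ) -> "Cohort":
        rows = []
        meta = {}
        for p in participants:
            for d in p.days:
                rows.append(
                    {
                        "participant_id": p.participant_id,
                        "day": d.day,
                        "delirium": np.nan if d.delirium is None else float(d.delirium),
                        "sofa": np.nan if d.sofa is None else d.sofa,
                    }
                )
            meta[p.participant_id] = {
                "outcome": np.nan if p.outcome is None else p.outcome,
                "true_duration": np.nan if p.true_duration is None else p.true_duration,
            }
        part = pd.DataFrame.from_dict(meta, orient="index")
        part.index.name = "participant_id"
        return cls(pd.DataFrame(rows), part, provenance=provenance)

    def _day_indices(self) -> dict:
        if self._day_index_cache is None:
            self._day_index_cache = self.days.groupby(
                "participant_id", sort=False
            ).indices
        return self._day_index_cache


# ----------------------------------------------------------------------
# cohort-level operations
# ----------------------------------------------------------------------
def cluster_resample(
    base: Cohort,
    n_participants: int,
    rng: np.random.Generator | int | None = None,
    replace: bool = False,
) -> Cohort:
    """Single-stage cluster sample with the participant as the sampling unit.

    Whole participants are drawn so that each sampled participant carries
    *all* of its days intact, preserving the within-participant serial
    correlation.  Sampled participants are renumbered ``0..n-1`` so that
    repeated draws (with ``replace=True``) remain distinguishable.
    """
    rng = _as_rng(rng)
    if n_participants < 1:
        raise ValueError("n_participants must be positive")
    ids = base.participants.index.to_numpy()
    if not replace and n_participants > len(ids):
        raise ValueError(
            f"cannot sample {n_participants} participants without replacement "
            f"from a base of {len(ids)}"
        )
    chosen = rng.choice(ids, size=n_participants, replace=replace)

    idx_map = base._day_indices()
    blocks = [idx_map[pid] for pid in chosen]
    lens = np.array([len(b) for b in blocks])
    rows = np.concatenate(blocks)

    new_days = base.days.iloc[rows].copy().reset_index(drop=True)
    new_days["participant_id"] = np.repeat(np.arange(n_participants), lens)

    new_part = base.participants.loc[chosen].copy()
    new_part.index = pd.Index(np.arange(n_participants), name="participant_id")

    prov = dict(base.provenance)
    prov["resampled"] = {"n_participants": n_participants, "replace": replace}
    return Cohort(new_days, new_part, provenance=prov, validate=False)


def generate_outcome(
    cohort: Cohort,
    intercept: float = 80.0,
    beta_del: float = -1.0,
    resid_sd: float = 12.0,
    rng: np.random.Generator | int | None = None,
) -> Cohort:
    """Generate the cognitive outcome as a linear function of delirium duration.

    ``outcome_i = intercept + beta_del * duration_i + eps_i`` with
    ``eps_i ~ N(0, resid_sd^2)``.  Must be called while delirium is fully
    observed (before any missingness is imposed); the true duration is
    recorded alongside for oracle checks.
    """
    if resid_sd < 0:
        raise ValueError("resid_sd must be non-negative")
    dur = cohort.durations()
    if dur.isna().any():
        raise ValueError(
            "all durations must be defined: generate outcomes before imposing missingness"
        )
    rng = _as_rng(rng)
    d = dur.to_numpy(float)
    eps = rng.normal(0.0, resid_sd, size=len(d)) if resid_sd > 0 else np.zeros(len(d))
    out = cohort.copy()
    out.participants["outcome"] = intercept + beta_del * d + eps
    out.participants["true_duration"] = d
    out.provenance["outcome_model"] = {
        "intercept": intercept,
        "beta_del": beta_del,
        "resid_sd": resid_sd,
    }
    return out


# ----------------------------------------------------------------------
# CSV round trip (long table, Y/N/empty delirium, outcome repeated per row)
# ----------------------------------------------------------------------
def write_cohort_csv(cohort: Cohort, path) -> None:
    df = cohort.days[DAY_COLUMNS].copy()
    df["delirium"] = df["delirium"].map({1.0: "Y", 0.0: "N"})
    df["outcome"] = df["participant_id"].map(cohort.participants["outcome"])
    df.to_csv(path, index=False)


def read_cohort_csv(path) -> Cohort:
    df = pd.read_csv(path)
    missing_cols = [c for c in DAY_COLUMNS if c not in df.columns]
    if missing_cols:
        raise ValueError(f"cohort CSV lacks columns {missing_cols}")
    deli = df["delirium"].astype("string").str.strip().str.upper()
    mapped = deli.map({"Y": 1.0, "N": 0.0})
    bad = deli.notna() & (deli != "") & mapped.isna()
    if bad.any():
        raise ValueError(
            f"unrecognised delirium codes: {sorted(deli[bad].unique())} (expected Y/N/empty)"
        )
    days = df[["participant_id", "day", "sofa"]].copy()
    days["delirium"] = mapped.astype(float)
    participants = None
    if "outcome" in df.columns:
        participants = (
            df.groupby("participant_id", sort=False)["outcome"].first().to_frame()
        )
    return Cohort(days, participants, provenance={"source": str(path)})
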