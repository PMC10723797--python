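"""Trial-validity screening and comparison-force binning.

A 2AFC trial is kept only if the response was recorded, the test force landed
inside its hardware tolerance (strictly between 1.85 and 2.15 N), the test
force was actually triggered by the movement, the finger did not move more
than 10 mm on a NOGO trial, the force did not arrive after the vertical
movement endpoint, and (in the unexpected-no-contact design) the finger did
not contact the distance sensor.  Trials failing several rules are counted
once, under the first failing rule in a fixed precedence order, so exclusion
ledgers are reproducible.  Surviving trials get their measured comparison
force binned to the nearest nominal level before psychometric fitting.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .observer import COMPARISON_LEVELS, TRIAL_COLUMNS, ExperimentDesign

__all__ = [
    "EXCLUSION_REASONS",
    "ExclusionRules",
    "ExclusionReport",
    "MalformedTrialError",
    "bin_comparison_force",
    "apply_exclusions",
    "kinematic_summaries",
    "rules_for_design",
]

#: Fixed precedence of exclusion reasons (first failing rule wins).
EXCLUSION_REASONS: tuple[str, ...] = (
    "missing_response",
    "test_force_out_of_tolerance",
    "not_triggered",
    "moved_on_nogo",
    "force_after_endpoint",
    "contacted_distance_sensor",
)


class MalformedTrialError(ValueError):
    """Raised for rows violating the trial-table schema; carries row indices."""

    def __init__(self, message: str, rows: Sequence[int]):
        super().__init__(f"{message} (rows: {list(rows)})")
        self.rows = list(rows)


@dataclass(frozen=True)
class ExclusionRules:
    """Which validity rules are active and with what thresholds."""

    test_force_bounds: tuple[float, float] = (1.85, 2.15)  # open interval, N
    require_response: bool = True
    require_triggered: bool = True
    nogo_movement_limit_mm: float = 10.0
    reject_force_after_endpoint: bool = True
    reject_distance_sensor_contact: bool = False  # active for exp3 only


def rules_for_design(design: ExperimentDesign | str) -> ExclusionRules:
    """Default rule activation per experiment preset.

    The distance-sensor-contact rule exists only in the retracting-platform
    design (exp3); all other rules are universal (the NOGO-movement rule is
    vacuous without NOGO trials).
    """
    exp = design if isinstance(design, str) else design.experiment_id
    return ExclusionRules(reject_distance_sensor_contact=(exp == "exp3"))


@dataclass
class ExclusionReport:
    """Full accounting of which trials were dropped and why."""

    total_trials: int
    excluded_by_reason: dict[str, int]
    per_participant: dict[str, dict[str, int]] = field(default_factory=dict)

    @property
    def excluded_total(self) -> int:
        return int(sum(self.excluded_by_reason.values()))

    @property
    def excluded_fraction(self) -> float:
        if self.total_trials == 0:
            return 0.0
        return self.excluded_total / self.total_trials

    def excluded_percent(self, ndigits: int = 1) -> float:
        """Percentage of excluded trials, rounded for display."""
        return round(100.0 * self.excluded_fraction, ndigits)

    def to_dict(self) -> dict:
        return {
            "total_trials": self.total_trials,
            "excluded_by_reason": dict(self.excluded_by_reason),
            "excluded_total": self.excluded_total,
            "excluded_percent": self.excluded_percent(1),
            "per_participant": {k: dict(v) for k, v in self.per_participant.items()},
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)

    @classmethod
    def from_counts(
        cls, total_trials: int, excluded_by_reason: Mapping[str, int]
    ) -> "ExclusionReport":
        """Build a ledger directly from per-reason counts (e.g. a published
        preprocessing table) without the underlying trials."""
        return cls(
            total_trials=int(total_trials),
            excluded_by_reason={k: int(v) for k, v in excluded_by_reason.items()},
        )


# ---------------------------------------------------------------------------
# Binning
# ---------------------------------------------------------------------------

def bin_comparison_force(
    measured: float | np.ndarray,
    levels: Sequence[float] = COMPARISON_LEVELS,
) -> float | np.ndarray:
    """Snap a measured comparison force to the nearest nominal level.

    Ties at the exact midpoint of two levels break toward the lower level;
    values beyond the extremes clamp to the nearest extreme.
    """
    lv = np.asarray(levels, dtype=float)
    if lv.size == 0:
        raise ValueError("levels must be non-empty")
    if not np.all(np.diff(lv) > 0):
        raise ValueError("levels must be strictly increasing")
    x = np.asarray(measured, dtype=float)
    # searchsorted against midpoints; side="left" sends exact midpoints down
    mids = (lv[:-1] + lv[1:]) / 2.0
    idx = np.searchsorted(mids, x, side="left")
    out = lv[idx]
    if np.isscalar(measured):
        return float(out)
    return out


# ---------------------------------------------------------------------------
# Exclusion screening
# ---------------------------------------------------------------------------

def _validate_schema(trials: pd.DataFrame) -> None:
    missing_cols = [c for c in TRIAL_COLUMNS if c not in trials.columns]
    if missing_cols:
        raise MalformedTrialError(
            f"trial table missing columns {missing_cols}", rows=[]
        )
    bad = trials.index[
        trials["measured_comparison_N"].isna()
        | (trials["measured_comparison_N"] <= 0)
        | trials["measured_test_N"].isna()
        | (trials["measured_test_N"] <= 0)
    ]
    if len(bad):
        raise MalformedTrialError("non-positive or missing measured force", bad)
    valid_resp = trials["response"].isin(
        ["comparison_stronger", "test_stronger"]
    ) | trials["response"].isna()
    bad = trials.index[~valid_resp]
    if len(bad):
        raise MalformedTrialError("unrecognised response code", bad)


def apply_exclusions(
    trials: pd.DataFrame,
    rules: ExclusionRules,
    bin_levels: Sequence[float] | None = COMPARISON_LEVELS,
) -> tuple[pd.DataFrame, ExclusionReport]:
    """Screen a trial table, returning surviving trials and the full ledger.

    The clean table carries an appended ``comparison_level`` column (the
    binned measured comparison force) ready for psychometric fitting.  Every
    input trial lands in exactly one of: the clean table, or one exclusion
    reason (first failing rule in :data:`EXCLUSION_REASONS` order).
    """
    _validate_schema(trials)
    lo, hi = rules.test_force_bounds
    fails: dict[str, pd.Series] = {
        "missing_response": (
            trials["response"].isna()
            if rules.require_response
            else pd.Series(False, index=trials.index)
        ),
        "test_force_out_of_tolerance": ~(
            (trials["measured_test_N"] > lo) & (trials["measured_test_N"] < hi)
        ),
        "not_triggered": (
            ~trials["triggered"].astype(bool)
            if rules.require_triggered
            else pd.Series(False, index=trials.index)
        ),
        "moved_on_nogo": trials["nogo"].astype(bool)
        & (trials["moved_on_nogo_mm"] > rules.nogo_movement_limit_mm),
        "force_after_endpoint": (
            trials["force_after_endpoint"].astype(bool)
            if rules.reject_force_after_endpoint
            else pd.Series(False, index=trials.index)
        ),
        "contacted_distance_sensor": (
            trials["contacted_distance_sensor"].astype(bool)
            if rules.reject_distance_sensor_contact
            else pd.Series(False, index=trials.index)
        ),
    }
    reason = pd.Series(pd.NA, index=trials.index, dtype=object)
    for r in EXCLUSION_REASONS:
        reason = reason.where(reason.notna() | ~fails[r].fillna(False), r)
    excluded_by_reason = {
        r: int((reason == r).sum()) for r in EXCLUSION_REASONS if (reason == r).any()
    }
    per_participant: dict[str, dict[str, int]] = {}
    excl = reason.notna()
    if excl.any():
        grouped = (
            pd.DataFrame(
                {"participant_id": trials["participant_id"], "reason": reason}
            )
            .dropna(subset=["reason"])
            .groupby(["participant_id", "reason"])
            .size()
        )
        for (pid, r), n in grouped.items():
            per_participant.setdefault(str(pid), {})[str(r)] = int(n)
    clean = trials.loc[~excl].copy()
    if bin_levels is not None:
        clean["comparison_level"] = bin_comparison_force(
            clean["measured_comparison_N"].to_numpy(), bin_levels
        )
    report = ExclusionReport(
        total_trials=int(len(trials)),
        excluded_by_reason=excluded_by_reason,
        per_participant=per_participant,
    )
    return clean, report


# ---------------------------------------------------------------------------
# Kinematic summaries
# ---------------------------------------------------------------------------

def kinematic_summaries(trials: pd.DataFrame) -> pd.DataFrame:
    """Per-participant, per-condition mean kinematic summaries.

    Returns a wide table indexed by participant with one column per
    (quantity, condition) pair — endpoint offset in mm, force lead time in ms
    — plus contact-minus-no-contact paired differences for downstream tests.
    Cells with no trials for a condition come back as NaN rather than being
    fabricated.
    """
    for col in ("endpoint_offset_mm", "force_lead_time_ms"):
        if col not in trials.columns:
            raise MalformedTrialError(f"kinematic column {col!r} absent", rows=[])
    means = (
        trials.groupby(["participant_id", "condition"], sort=True)[
            ["endpoint_offset_mm", "force_lead_time_ms"]
        ]
        .mean()
        .unstack("condition")
    )
    means.columns = [f"{q}:{c}" for q, c in means.columns]
    for q in ("endpoint_offset_mm", "force_lead_time_ms"):
        a, b = f"{q}:contact", f"{q}:no_contact"
        if a in means.columns and b in means.columns:
            means[f"{q}:contact_minus_no_contact"] = means[a] - means[b]
    return means
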