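"""Synthetic 2AFC force-discrimination observers.

Simulates trial-level data for a somatosensory-attenuation force-discrimination
task: on every trial a fixed 2 N *test* force and a variable *comparison* force
are delivered to the passive left index finger, and the observer reports which
felt stronger.  Observers are logistic: the probability of reporting the
comparison as stronger is a sigmoid in comparison magnitude, parameterised by a
point of subjective equality (PSE) and a just noticeable difference (JND).
A lower PSE in an action condition than in the passive baseline encodes
attenuation of the perceived test force.

Three experiment presets reproduce the trial structure of the three designs:

``exp1``
    baseline / contact / no-contact, one 70-trial block each (210 trials).
``exp2``
    as exp1 plus NOGO (movement-inhibition) trials pseudo-randomly intermixed
    at 50% within the contact and no-contact blocks (350 trials).
``exp3``
    80% contact / 20% no-contact intermixed in one block (224 + 56 trials)
    plus a 56-trial baseline block (336 trials).

The module also injects controlled anomalies (missing responses, out-of-
tolerance test forces, untriggered forces, movement on NOGO trials, ...) so
that every downstream trial-exclusion rule can be exercised.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Sequence, Union

import numpy as np
import pandas as pd

__all__ = [
    "COMPARISON_LEVELS",
    "TEST_FORCE",
    "TRIAL_COLUMNS",
    "KINEMATIC_COLUMNS",
    "ExperimentDesign",
    "KinematicParams",
    "ObserverParams",
    "ConditionSpec",
    "PopulationSpec",
    "UnknownPresetError",
    "MissingConditionError",
    "InvalidParameterError",
    "UnknownAnomalyError",
    "make_design",
    "default_population",
    "simulate_participant",
    "simulate_cohort",
    "inject_anomalies",
    "choice_probability",
    "write_trials",
    "read_trials",
]

#: The seven nominal comparison-force magnitudes (N).
COMPARISON_LEVELS: tuple[float, ...] = (1.0, 1.5, 1.75, 2.0, 2.25, 2.5, 3.0)

#: The fixed test-force magnitude (N).
TEST_FORCE: float = 2.0

#: Canonical trial-table CSV columns, in order.
TRIAL_COLUMNS: tuple[str, ...] = (
    "participant_id",
    "experiment",
    "block",
    "condition",
    "trial_index",
    "nominal_comparison_N",
    "measured_comparison_N",
    "measured_test_N",
    "response",
    "nogo",
    "moved_on_nogo_mm",
    "force_after_endpoint",
    "triggered",
    "contacted_distance_sensor",
)

#: Extra in-memory kinematic summary columns carried by simulated tables.
KINEMATIC_COLUMNS: tuple[str, ...] = ("endpoint_offset_mm", "force_lead_time_ms")

RESPONSE_COMPARISON = "comparison_stronger"
RESPONSE_TEST = "test_stronger"

#: Anomaly keys understood by :func:`inject_anomalies`.
ANOMALY_KEYS: tuple[str, ...] = (
    "missing_response",
    "test_force_out_of_tolerance",
    "not_triggered",
    "moved_on_nogo",
    "force_after_endpoint",
    "contacted_distance_sensor",
)


class UnknownPresetError(ValueError):
    """Raised for an experiment preset that is not exp1/exp2/exp3."""


class MissingConditionError(KeyError):
    """Raised when an observer lacks parameters for a design condition."""


class InvalidParameterError(ValueError):
    """Raised for non-positive JNDs or standard deviations."""


class UnknownAnomalyError(KeyError):
    """Raised for an anomaly key outside the supported taxonomy."""


# ---------------------------------------------------------------------------
# Designs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BlockSpec:
    """One block of trials: which conditions it mixes and how."""

    label: str
    composition: Mapping[str, int]  # condition -> trial count
    mixing: str = "blocked"  # "blocked" (single condition) or "intermixed"


@dataclass(frozen=True)
class ExperimentDesign:
    """Condition structure, trial counts, force levels and timing of a preset."""

    experiment_id: str
    conditions: tuple[str, ...]
    trials_per_condition: Mapping[str, int]
    comparison_levels: tuple[float, ...] = COMPARISON_LEVELS
    test_force: float = TEST_FORCE
    isi_range_ms: tuple[float, float] = (800.0, 1200.0)
    block_structure: tuple[BlockSpec, ...] = ()
    nogo_fraction: float = 0.0
    counterbalance: bool = True

    def __post_init__(self) -> None:
        levels = np.asarray(self.comparison_levels, dtype=float)
        if not (np.all(np.diff(levels) > 0) and np.all(levels > 0)):
            raise InvalidParameterError(
                "comparison levels must be strictly increasing and positive"
            )

    @property
    def total_trials(self) -> int:
        """Trials per participant."""
        return int(sum(self.trials_per_condition.values()))


def make_design(preset: str) -> ExperimentDesign:
    """Return the fully populated design for one of the three experiments.

    Parameters
    ----------
    preset
        ``"exp1"``, ``"exp2"`` or ``"exp3"``.

    Raises
    ------
    UnknownPresetError
        For any other preset name.
    """
    if preset == "exp1":
        counts = {"baseline": 70, "contact": 70, "no_contact": 70}
        blocks = tuple(
            BlockSpec(label=c, composition={c: 70}) for c in counts
        )
        return ExperimentDesign(
            experiment_id="exp1",
            conditions=tuple(counts),
            trials_per_condition=counts,
            block_structure=blocks,
            nogo_fraction=0.0,
        )
    if preset == "exp2":
        counts = {
            "baseline": 70,
            "contact": 70,
            "no_contact": 70,
            "nogo_contact": 70,
            "nogo_no_contact": 70,
        }
        blocks = (
            BlockSpec("baseline", {"baseline": 70}),
            BlockSpec(
                "contact", {"contact": 70, "nogo_contact": 70}, mixing="intermixed"
            ),
            BlockSpec(
                "no_contact",
                {"no_contact": 70, "nogo_no_contact": 70},
                mixing="intermixed",
            ),
        )
        return ExperimentDesign(
            experiment_id="exp2",
            conditions=tuple(counts),
            trials_per_condition=counts,
            block_structure=blocks,
            nogo_fraction=0.5,
        )
    if preset == "exp3":
        counts = {"baseline": 56, "contact": 224, "no_contact": 56}
        blocks = (
            BlockSpec("baseline", {"baseline": 56}),
            BlockSpec(
                "mixed", {"contact": 224, "no_contact": 56}, mixing="intermixed"
            ),
        )
        return ExperimentDesign(
            experiment_id="exp3",
            conditions=tuple(counts),
            trials_per_condition=counts,
            block_structure=blocks,
            nogo_fraction=0.0,
        )
    raise UnknownPresetError(f"unknown experiment preset: {preset!r}")


# ---------------------------------------------------------------------------
# Observer parameters
# ---------------------------------------------------------------------------

CondValue = Union[float, Mapping[str, float]]


def _per_condition(value: CondValue, condition: str, default: float = 0.0) -> float:
    if isinstance(value, Mapping):
        return float(value.get(condition, default))
    return float(value)


@dataclass(frozen=True)
class KinematicParams:
    """Per-trial kinematic summary generators (scalars, not trajectories).

    ``endpoint_offset_mm`` and ``force_lead_time_ms`` may be a single value or
    a mapping condition -> value, so that condition differences (e.g. the
    active finger sitting closer to the passive one on contact trials) can be
    simulated.  ``force_lead_time_ms`` is test-force onset minus movement
    endpoint time; negative means the force arrived before the endpoint.
    """

    movement_duration_ms: float = 300.0
    endpoint_offset_mm: CondValue = 10.0
    force_lead_time_ms: CondValue = -10.0
    trigger_delay_ms: float = 36.0  # intrinsic contact-trigger delay
    nogo_twitch_amplitude_mm: float = 2.0
    endpoint_offset_sd_mm: float = 4.0
    force_lead_sd_ms: float = 20.0


@dataclass(frozen=True)
class ObserverParams:
    """Generative PSE/JND per condition for one simulated participant."""

    participant_id: str
    per_condition: Mapping[str, tuple[float, float]]  # condition -> (pse, jnd)
    lapse_rate: float = 0.0
    response_missing_rate: float = 0.0
    kinematic_profile: KinematicParams = field(default_factory=KinematicParams)

    def __post_init__(self) -> None:
        if not 0.0 <= self.lapse_rate < 0.5:
            raise InvalidParameterError("lapse_rate must lie in [0, 0.5)")
        for cond, (_, jnd) in self.per_condition.items():
            if jnd <= 0:
                raise InvalidParameterError(f"jnd must be > 0 (condition {cond!r})")


def choice_probability(
    x: np.ndarray | float, pse: float, jnd: float, lapse: float = 0.0
) -> np.ndarray | float:
    """P(report comparison stronger) at comparison magnitude ``x``.

    The slope is ``beta1 = ln(3)/jnd`` so the 50%-to-75% distance on the
    logistic equals one JND, and ``beta0 = -beta1 * pse`` so the 50% point
    sits at the PSE.  A lapse floor/ceiling compresses the curve into
    ``[lapse/2, 1 - lapse/2]``.
    """
    if jnd <= 0:
        raise InvalidParameterError("jnd must be > 0")
    beta1 = np.log(3.0) / jnd
    z = beta1 * (np.asarray(x, dtype=float) - pse)
    p = lapse / 2.0 + (1.0 - lapse) / (1.0 + np.exp(-z))
    if np.isscalar(x):
        return float(p)
    return p


# ---------------------------------------------------------------------------
# Trial simulation
# ---------------------------------------------------------------------------

def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def _level_sequence(
    count: int, levels: Sequence[float], rng: np.random.Generator
) -> np.ndarray:
    """Equal repetitions of each level, in randomized order."""
    n_levels = len(levels)
    reps, rem = divmod(count, n_levels)
    seq = np.repeat(np.asarray(levels, dtype=float), reps)
    if rem:  # uneven counts never arise from the presets but stay valid
        seq = np.concatenate([seq, rng.choice(levels, size=rem, replace=False)])
    rng.shuffle(seq)
    return seq


def simulate_participant(
    params: ObserverParams,
    design: ExperimentDesign,
    seed,
    force_jitter_sd: float = 0.01,
) -> pd.DataFrame:
    """Simulate every trial of ``design`` for one logistic observer.

    Measured forces are the nominal forces plus Gaussian jitter (sd
    ``force_jitter_sd`` N, truncated at zero).  Responses are Bernoulli draws
    from :func:`choice_probability` evaluated at the *measured* comparison
    force.  Kinematic summary columns are drawn from the observer's
    :class:`KinematicParams`.  Identical ``(params, design, seed)`` reproduce
    the table bit-for-bit.
    """
    for cond in design.conditions:
        if cond not in params.per_condition:
            raise MissingConditionError(
                f"observer {params.participant_id!r} has no parameters for "
                f"condition {cond!r}"
            )
    rng = _as_rng(seed)
    kin = params.kinematic_profile
    rows: list[dict] = []
    for block in design.block_structure:
        cond_labels = np.concatenate(
            [np.repeat(c, n) for c, n in block.composition.items()]
        )
        level_by_cond = {
            c: iter(_level_sequence(n, design.comparison_levels, rng))
            for c, n in block.composition.items()
        }
        if block.mixing == "intermixed":
            rng.shuffle(cond_labels)
        for idx, cond in enumerate(cond_labels):
            nominal = float(next(level_by_cond[cond]))
            measured_cmp = max(1e-6, nominal + rng.normal(0.0, force_jitter_sd))
            measured_test = max(
                1e-6, design.test_force + rng.normal(0.0, force_jitter_sd)
            )
            pse, jnd = params.per_condition[cond]
            p = choice_probability(measured_cmp, pse, jnd, params.lapse_rate)
            response = (
                RESPONSE_COMPARISON if rng.random() < p else RESPONSE_TEST
            )
            if params.response_missing_rate and (
                rng.random() < params.response_missing_rate
            ):
                response = None
            nogo = cond.startswith("nogo")
            is_movement = cond in ("contact", "no_contact")
            rows.append(
                {
                    "participant_id": params.participant_id,
                    "experiment": design.experiment_id,
                    "block": block.label,
                    "condition": cond,
                    "trial_index": idx,
                    "nominal_comparison_N": nominal,
                    "measured_comparison_N": measured_cmp,
                    "measured_test_N": measured_test,
                    "response": response,
                    "nogo": nogo,
                    "moved_on_nogo_mm": (
                        abs(rng.normal(0.0, kin.nogo_twitch_amplitude_mm))
                        if nogo
                        else np.nan
                    ),
                    "force_after_endpoint": False,
                    "triggered": True,
                    "contacted_distance_sensor": False,
                    "endpoint_offset_mm": (
                        rng.normal(
                            _per_condition(kin.endpoint_offset_mm, cond),
                            kin.endpoint_offset_sd_mm,
                        )
                        if is_movement
                        else np.nan
                    ),
                    "force_lead_time_ms": (
                        rng.normal(
                            _per_condition(kin.force_lead_time_ms, cond),
                            kin.force_lead_sd_ms,
                        )
                        if is_movement
                        else np.nan
                    ),
                }
            )
    df = pd.DataFrame(rows, columns=list(TRIAL_COLUMNS) + list(KINEMATIC_COLUMNS))
    df["response"] = df["response"].astype(object)
    return df


# ---------------------------------------------------------------------------
# Cohorts
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ConditionSpec:
    """Population-level generative parameters for one condition."""

    pse_mean: float
    pse_sd: float
    jnd_mean: float
    jnd_sd: float

    def __post_init__(self) -> None:
        if self.pse_sd <= 0 or self.jnd_sd <= 0:
            raise InvalidParameterError("population SDs must be > 0")
        if self.jnd_mean <= 0:
            raise InvalidParameterError("population jnd mean must be > 0")


@dataclass(frozen=True)
class PopulationSpec:
    """Between-participant distribution of observer parameters.

    A participant's PSE in each condition is the condition mean, plus a
    shared Gaussian participant offset (``participant_pse_sd``) capturing the
    stable individual perceptual scale that makes within-subject contrasts
    powerful, plus an independent condition-specific Gaussian deviation
    (``pse_sd``).  JNDs are log-Gaussian (moment matched to the requested
    mean and SD) so that every drawn JND is positive.
    """

    per_condition: Mapping[str, ConditionSpec]
    participant_pse_sd: float = 0.0
    lapse_rate: float = 0.0
    response_missing_rate: float = 0.0
    kinematics: KinematicParams = field(default_factory=KinematicParams)

    def __post_init__(self) -> None:
        if self.participant_pse_sd < 0:
            raise InvalidParameterError("participant_pse_sd must be >= 0")

    def draw(self, participant_id: str, rng: np.random.Generator) -> ObserverParams:
        offset = (
            rng.normal(0.0, self.participant_pse_sd)
            if self.participant_pse_sd > 0
            else 0.0
        )
        per_cond: dict[str, tuple[float, float]] = {}
        for cond, spec in self.per_condition.items():
            pse = offset + rng.normal(spec.pse_mean, spec.pse_sd)
            sigma2 = np.log1p((spec.jnd_sd / spec.jnd_mean) ** 2)
            mu = np.log(spec.jnd_mean) - sigma2 / 2.0
            jnd = float(np.exp(rng.normal(mu, np.sqrt(sigma2))))
            per_cond[cond] = (float(pse), jnd)
        return ObserverParams(
            participant_id=participant_id,
            per_condition=per_cond,
            lapse_rate=self.lapse_rate,
            response_missing_rate=self.response_missing_rate,
            kinematic_profile=self.kinematics,
        )


def default_population(experiment: str) -> PopulationSpec:
    """Arbitrary-but-plausible generative population for each preset.

    Group means place a 0.2 N attenuation in the contact condition (and, for
    exp3, a 0.13 N attenuation of no-contact; for exp2, ~0.06/0.09 N
    suppression on NOGO trials).  Between-participant PSE spread is mostly a
    shared perceptual offset (0.13 N) with a small condition-specific
    component (0.05 N) — the correlated structure a within-subject design
    exploits, sized so a 0.2 N shift yields paired effect sizes around
    d ~ 1.2 at 70 trials/condition.  Mean JND is 0.4 N.  These are
    simulation defaults at realistic magnitudes, not estimates of any real
    cohort.
    """
    base = dict(pse_sd=0.05, jnd_mean=0.4, jnd_sd=0.1)
    cond_specs = {
        "exp1": {
            "baseline": ConditionSpec(pse_mean=2.0, **base),
            "contact": ConditionSpec(pse_mean=1.8, **base),
            "no_contact": ConditionSpec(pse_mean=2.0, **base),
        },
        "exp2": {
            "baseline": ConditionSpec(pse_mean=2.0, **base),
            "contact": ConditionSpec(pse_mean=1.8, **base),
            "no_contact": ConditionSpec(pse_mean=2.0, **base),
            "nogo_contact": ConditionSpec(pse_mean=1.94, **base),
            "nogo_no_contact": ConditionSpec(pse_mean=1.91, **base),
        },
        "exp3": {
            "baseline": ConditionSpec(pse_mean=2.0, **base),
            "contact": ConditionSpec(pse_mean=1.8, **base),
            "no_contact": ConditionSpec(pse_mean=1.87, **base),
        },
    }
    if experiment not in cond_specs:
        raise UnknownPresetError(f"unknown experiment preset: {experiment!r}")
    kin = {
        # contact endpoint sits closer to the passive finger; the no-contact
        # force leads the endpoint by more than the contact force does
        "exp1": KinematicParams(
            endpoint_offset_mm={"contact": 8.0, "no_contact": 10.32},
            force_lead_time_ms={"contact": -10.0, "no_contact": -34.0},
        ),
        "exp2": KinematicParams(
            endpoint_offset_mm={"contact": 8.0, "no_contact": 12.0},
            force_lead_time_ms={"contact": -10.0, "no_contact": -21.0},
        ),
        "exp3": KinematicParams(
            endpoint_offset_mm={"contact": 30.0, "no_contact": 4.3},
            force_lead_time_ms={"contact": -10.0, "no_contact": -25.0},
        ),
    }
    return PopulationSpec(
        per_condition=cond_specs[experiment],
        participant_pse_sd=0.13,
        kinematics=kin[experiment],
    )


def cohort_seed_sequences(
    seed: int, n_participants: int
) -> tuple[np.random.SeedSequence, list[np.random.SeedSequence]]:
    """Deterministic split of one seed into (population draw, per-participant)."""
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(n_participants + 1)
    return children[0], children[1:]


def simulate_cohort(
    n_participants: int,
    design: ExperimentDesign,
    population: PopulationSpec,
    seed: int,
    force_jitter_sd: float = 0.01,
) -> pd.DataFrame:
    """Simulate a cohort: draw observers from ``population``, run each through
    ``design``, and concatenate the per-participant trial tables."""
    if n_participants < 1:
        raise InvalidParameterError("n_participants must be >= 1")
    pop_ss, part_ss = cohort_seed_sequences(seed, n_participants)
    pop_rng = np.random.default_rng(pop_ss)
    tables = []
    for i, child in enumerate(part_ss):
        params = population.draw(f"P{i + 1:03d}", pop_rng)
        tables.append(
            simulate_participant(
                params, design, np.random.default_rng(child), force_jitter_sd
            )
        )
    return pd.concat(tables, ignore_index=True)


# ---------------------------------------------------------------------------
# Anomaly injection
# ---------------------------------------------------------------------------

def inject_anomalies(
    trials: pd.DataFrame,
    rates: Mapping[str, float],
    seed: int,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Flip validity flags/values on a reproducible random subset of trials.

    Each anomaly applies only to the trial types on which it can physically
    occur (e.g. NOGO movement only on NOGO trials, untriggered forces only on
    no-contact movement trials).  Returns the modified copy of the table and
    the exact count of injections per anomaly.
    """
    for key in rates:
        if key not in ANOMALY_KEYS:
            raise UnknownAnomalyError(f"unknown anomaly key: {key!r}")
    out = trials.copy()
    counts: dict[str, int] = {}
    rng = np.random.default_rng(seed)
    eligibility = {
        "missing_response": out["response"].notna(),
        "test_force_out_of_tolerance": pd.Series(True, index=out.index),
        "not_triggered": (out["condition"] == "no_contact") & ~out["nogo"],
        "moved_on_nogo": out["nogo"].astype(bool),
        "force_after_endpoint": out["condition"].isin(["contact", "no_contact"])
        & ~out["nogo"],
        "contacted_distance_sensor": (out["condition"] == "no_contact")
        & ~out["nogo"],
    }
    for key in ANOMALY_KEYS:  # fixed iteration order keeps draws reproducible
        rate = float(rates.get(key, 0.0))
        if not 0.0 <= rate <= 1.0:
            raise InvalidParameterError(f"anomaly rate for {key!r} must be in [0, 1]")
        if rate == 0.0:
            counts[key] = 0
            continue
        eligible = out.index[eligibility[key]]
        hit = eligible[rng.random(len(eligible)) < rate]
        counts[key] = int(len(hit))
        if len(hit) == 0:
            continue
        if key == "missing_response":
            out.loc[hit, "response"] = None
        elif key == "test_force_out_of_tolerance":
            # push the measured test force outside the open (1.85, 2.15) band
            low = rng.random(len(hit)) < 0.5
            delta = rng.uniform(0.0, 0.10, size=len(hit))
            out.loc[hit, "measured_test_N"] = np.where(
                low, 1.85 - delta, 2.15 + delta
            )
        elif key == "not_triggered":
            out.loc[hit, "triggered"] = False
        elif key == "moved_on_nogo":
            out.loc[hit, "moved_on_nogo_mm"] = 10.0 + rng.uniform(
                1.0, 20.0, size=len(hit)
            )
        elif key == "force_after_endpoint":
            out.loc[hit, "force_after_endpoint"] = True
        elif key == "contacted_distance_sensor":
            out.loc[hit, "contacted_distance_sensor"] = True
    return out, counts


# ---------------------------------------------------------------------------
# Trial-table CSV I/O
# ---------------------------------------------------------------------------

def write_trials(trials: pd.DataFrame, path) -> None:
    """Write the canonical trial CSV (missing response as an empty field)."""
    out = trials.loc[:, list(TRIAL_COLUMNS)].copy()
    out.to_csv(path, index=False)


def read_trials(path) -> pd.DataFrame:
    """Read a trial CSV written by :func:`write_trials` (or hand-built)."""
    df = pd.read_csv(
        path,
        dtype={"participant_id": str, "experiment": str, "block": str,
               "condition": str},
    )
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"trial table missing columns: {missing}")
    df["response"] = df["response"].where(df["response"].notna(), None).astype(object)
    for col in ("nogo", "force_after_endpoint", "triggered",
                "contacted_distance_sensor"):
        df[col] = df[col].astype(bool)
    return df
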