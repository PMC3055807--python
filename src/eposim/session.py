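"""Orchestration of one 32-week prescription session.

A session is a 12-week equilibration phase followed by a 20-week
maintenance phase (224 daily engine steps).  Every week the true
haemoglobin is logged; the prescriber sees a noisy observation
(±noise_amplitude g/dL, reported to 0.1 g/dL) and only on *visible* weeks.
In the weekly arm every week is a dosing opportunity and visible; in the
monthly arm the first 8 weeks are a weekly titration window, after which
dosing and visibility fall on every fourth week (9, 13, 17, 21, 25, 29).
Study mode A inserts one random acute bleeding episode (0–30% of blood
volume) in weeks 18–24; mode B has none.

Randomness is split into independent named streams (patient, noise, bleed)
spawned from the session seed, so toggling one feature never shifts
another's draws.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DomainError, PolicyError, SessionAbortedError
from .kinetics import (
    DoseEvent,
    apply_bleed,
    hb_true,
    initial_state,
    mean_rbc_lifespan,
    step_day,
)
from .patient import ModelConstants, VirtualPatient

__all__ = [
    "SessionConfig",
    "SessionRecord",
    "dosing_weeks",
    "observe_hb",
    "schedule_bleed",
    "visible",
    "run_session",
]

DAYS_PER_WEEK = 7
INTERVALS = ("weekly", "monthly")
MODES = ("A", "B")

#: Length of the initial titration window during which the monthly arm may
#: still dose (and observe) weekly.
TITRATION_WEEKS = 8
#: Weeks between administrations in the monthly arm after titration.
MONTHLY_STRIDE = 4


@dataclass(frozen=True)
class SessionConfig:
    """Half-life (hours), administration interval, study mode and seed."""

    half_life: float
    interval: str
    mode: str
    seed: int
    constants: ModelConstants = field(default_factory=ModelConstants)

    def validate(self) -> "SessionConfig":
        self.constants.validate()
        if self.half_life not in self.constants.allowed_half_lives:
            raise ConfigurationError(
                f"half_life {self.half_life} not in {self.constants.allowed_half_lives}"
            )
        if self.interval not in INTERVALS:
            raise ConfigurationError(f"interval must be one of {INTERVALS}")
        if self.mode not in MODES:
            raise ConfigurationError(f"mode must be one of {MODES}")
        return self

    def to_dict(self) -> dict:
        return {
            "half_life": self.half_life,
            "interval": self.interval,
            "mode": self.mode,
            "seed": self.seed,
        }


@dataclass
class SessionRecord:
    """Complete weekly log of a session plus its config and patient.

    ``data`` has one row per week with columns: week, phase, visible,
    true_hb, observed_hb, dose (NaN on non-dosing weeks), bleed_fraction
    (NaN unless a bleed happened that week) and rbc_lifespan (the turnover
    read-out at the week's start).
    """

    config: SessionConfig
    patient: VirtualPatient
    data: pd.DataFrame

    def doses(self) -> pd.Series:
        """Doses actually entered, indexed by week."""
        d = self.data.set_index("week")["dose"]
        return d[d.notna()]


def dosing_weeks(interval: str, constants: ModelConstants) -> List[int]:
    """Week indices (1-based) on which a dose may be entered.

    Weekly arm: every week.  Monthly arm: weekly during the titration
    window, then every ``MONTHLY_STRIDE`` weeks.
    """
    if interval not in INTERVALS:
        raise ConfigurationError(f"interval must be one of {INTERVALS}")
    total = constants.total_weeks
    if interval == "weekly":
        return list(range(1, total + 1))
    weeks = list(range(1, TITRATION_WEEKS + 1))
    weeks += list(range(TITRATION_WEEKS + 1, total + 1, MONTHLY_STRIDE))
    return weeks


def observe_hb(
    true_hb: float, rng: np.random.Generator, constants: ModelConstants
) -> float:
    """Observed haemoglobin: truth plus an incidental fluctuation drawn
    uniform on [-noise_amplitude, +noise_amplitude] g/dL.

    The fluctuation is quantised to the 0.1 g/dL reporting grid (and clipped
    back into the amplitude bound, relevant only for non-multiple-of-0.1
    amplitudes), so the reported deviation from the true value never exceeds
    the stated amplitude.  Noise is observation-level only — it never feeds
    back into the cell population.
    """
    if true_hb < 0:
        raise DomainError(f"true_hb must be >= 0, got {true_hb}")
    amp = constants.noise_amplitude
    noise = float(np.clip(round(float(rng.uniform(-amp, amp)), 1), -amp, amp))
    return true_hb + noise


def schedule_bleed(
    mode: str, rng: np.random.Generator, constants: ModelConstants
) -> Optional[Tuple[int, float]]:
    """Mode A: one (week, fraction) bleed, week uniform on the bleed window,
    fraction uniform on [0, bleed_max_fraction].  Mode B: ``None``."""
    if mode not in MODES:
        raise ConfigurationError(f"mode must be one of {MODES}")
    if mode == "B":
        return None
    lo, hi = constants.bleed_window
    week = int(rng.integers(lo, hi + 1))
    fraction = float(rng.uniform(0.0, constants.bleed_max_fraction))
    return week, fraction


def visible(interval: str, week: int, constants: ModelConstants) -> bool:
    """Whether the prescriber sees this week's haemoglobin.

    Weekly arm: always.  Monthly arm: during titration and on the
    every-fourth-week calendar thereafter.  True haemoglobin is logged
    regardless, for analysis.
    """
    if interval not in INTERVALS:
        raise ConfigurationError(f"interval must be one of {INTERVALS}")
    if not (1 <= week <= constants.total_weeks):
        raise DomainError(f"week must be in [1, {constants.total_weeks}], got {week}")
    if interval == "weekly":
        return True
    if week <= TITRATION_WEEKS:
        return True
    return (week - (TITRATION_WEEKS + 1)) % MONTHLY_STRIDE == 0


def _phase(week: int, constants: ModelConstants) -> str:
    return "equilibration" if week <= constants.equilibration_weeks else "maintenance"


def run_session(
    config: SessionConfig,
    patient: VirtualPatient,
    policy,
) -> SessionRecord:
    """Simulate 32 weeks of prescribing and return the complete record.

    ``policy`` is queried only on dosing weeks, with the visible
    observation history ``[(week, observed_hb), ...]`` and its own current
    dose, via ``policy.decide(week, history, current_dose)``; it must
    return a finite non-negative dose.  Deterministic given the seeds and a
    deterministic policy.
    """
    config.validate()
    patient.validate()
    constants = config.constants
    ss = np.random.SeedSequence(config.seed)
    noise_rng, bleed_rng = (np.random.default_rng(s) for s in ss.spawn(2))

    state = initial_state(patient, constants, config.half_life)
    bleed = schedule_bleed(config.mode, bleed_rng, constants)
    dose_calendar = set(dosing_weeks(config.interval, constants))

    rows: List[dict] = []
    history: List[Tuple[int, float]] = []
    current_dose: Optional[float] = None
    try:
        for week in range(1, constants.total_weeks + 1):
            bleed_fraction = np.nan
            if bleed is not None and week == bleed[0]:
                apply_bleed(state, bleed[1], constants)
                bleed_fraction = bleed[1]
            true = hb_true(state, constants)
            observed = observe_hb(true, noise_rng, constants)
            lifespan = mean_rbc_lifespan(state)
            vis = visible(config.interval, week, constants)
            if vis:
                history.append((week, observed))
            dose = np.nan
            todays_doses: List[DoseEvent] = []
            if week in dose_calendar:
                proposed = policy.decide(week, list(history), current_dose)
                if proposed is None or not np.isfinite(proposed) or proposed < 0:
                    raise PolicyError(
                        f"policy returned invalid dose {proposed!r} for week {week}"
                    )
                dose = float(proposed)
                current_dose = dose
                if dose > 0:
                    todays_doses.append(DoseEvent(day=state.day, amount=dose))
            rows.append(
                {
                    "week": week,
                    "phase": _phase(week, constants),
                    "visible": vis,
                    "true_hb": true,
                    "observed_hb": observed,
                    "dose": dose,
                    "bleed_fraction": bleed_fraction,
                    "rbc_lifespan": lifespan,
                }
            )
            for day_in_week in range(DAYS_PER_WEEK):
                step_day(state, todays_doses if day_in_week == 0 else (), patient, constants)
                todays_doses = []
    except (EOFError, KeyboardInterrupt) as exc:
        raise SessionAbortedError(
            f"session aborted during week {len(rows) + 1}", partial_rows=rows
        ) from exc

    data = pd.DataFrame(rows)
    return SessionRecord(config=config, patient=patient, data=data)
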