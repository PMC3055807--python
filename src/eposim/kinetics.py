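"""Daily-step erythropoiesis engine.

Drug model
    ESA concentration decays mono-exponentially; a dose train superposes:
    C(t) = sum over doses d with d.day <= t of
           d.amount * 2**(-24 * (t - d.day) / half_life_hours).
    Concentration carries dose units (U-equivalents); only the product of
    sensitivity and the stimulus function is observable, so no absolute
    volume-of-distribution model is attached.

Effect model
    Red-cell production on day t is the endogenous baseline plus a
    saturating Emax term driven by the concentration felt one maturation
    delay tau earlier (precursor kinetics collapsed to a fixed lag):
    production(t) = P0 + s * Emax * C(t - tau) / (C(t - tau) + C50).

Cell population
    Cells born on the same day form a cohort.  Individual cell lifespans
    are uniform on [L - spread, L + spread]; a cohort, being a large
    population of cells, therefore retires *deterministically* along the
    survival schedule of that law, including fractional presence on a
    cell's final day, so the expected circulating lifetime of a cohort is
    exactly the mean lifespan L.  Haemoglobin is kappa times total
    circulating mass; the reported "mean RBC lifespan" is the turnover
    read-out: circulating mass divided by the expected daily senescence
    loss smoothed over a 7-day window.  At the untreated steady state this
    equals L exactly (for any spread with L - spread >= 7 days, i.e. no
    cell dies younger than the smoothing window) and it fluctuates with
    the age distribution whenever production has been uneven.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import numpy as np

from .errors import DomainError, SchedulingError, UndefinedStateError
from .patient import ModelConstants, VirtualPatient

__all__ = [
    "DoseEvent",
    "ErythroState",
    "survival_weights",
    "epo_concentration",
    "production_stimulus",
    "initial_state",
    "step_day",
    "apply_bleed",
    "hb_true",
    "total_mass",
    "mean_rbc_lifespan",
]

#: Width (days) of the smoothing window for the turnover lifespan read-out.
LIFESPAN_WINDOW = 7


@dataclass(frozen=True)
class DoseEvent:
    """A single ESA administration: ``amount`` units given on ``day``."""

    day: int
    amount: float

    def __post_init__(self):
        if self.day < 0:
            raise DomainError(f"dose day must be >= 0, got {self.day}")
        if not math.isfinite(self.amount) or self.amount < 0:
            raise DomainError(f"dose amount must be finite and >= 0, got {self.amount}")


def _clamp_antiderivative(y: float) -> float:
    # G(y) = integral_0^y clip(t, 0, 1) dt
    if y <= 0.0:
        return 0.0
    if y <= 1.0:
        return 0.5 * y * y
    return y - 0.5


def survival_weights(mean_lifespan: float, spread: float) -> np.ndarray:
    """Expected presence weight of a cohort at each integer age.

    ``w[a]`` is the expected fraction of a day that a cell with lifespan
    uniform on ``[L - spread, L + spread]`` spends in circulation during
    the day of age ``a`` (1 while surely alive, a fraction across the death
    day, 0 after).  The array ends at the last strictly positive weight and
    satisfies ``sum(w) == mean_lifespan`` exactly (expected lifetime-days).
    """
    if mean_lifespan <= 0 or not (0 <= spread < mean_lifespan):
        raise DomainError("need mean_lifespan > 0 and 0 <= spread < mean_lifespan")
    lo, hi = mean_lifespan - spread, mean_lifespan + spread
    n = int(math.ceil(hi))
    ages = np.arange(n + 1, dtype=float)
    if spread == 0.0:
        w = np.clip(mean_lifespan - ages, 0.0, 1.0)
    else:
        g_hi = np.array([_clamp_antiderivative(hi - a) for a in ages])
        g_lo = np.array([_clamp_antiderivative(lo - a) for a in ages])
        w = (g_hi - g_lo) / (hi - lo)
    # trim trailing zeros so len(w) is the first dead age
    nz = np.nonzero(w)[0]
    return w[: nz[-1] + 1].copy()


@dataclass
class ErythroState:
    """Ledger of RBC cohorts plus the dose history.

    ``births[i]`` is the birth day of cohort ``i`` (ascending), ``masses[i]``
    its birth mass (already scaled by any bleeding since); the current
    circulating mass of a cohort is ``masses[i] * w[day - births[i]]`` with
    ``w`` the survival-weight table.  Cohorts are pruned once their weight
    reaches zero.
    """

    day: int
    births: List[int]
    masses: List[float]
    doses: List[DoseEvent]
    half_life: float
    weights: np.ndarray = field(repr=False)

    def n_cohorts(self) -> int:
        return len(self.births)

    def ages(self) -> np.ndarray:
        return self.day - np.asarray(self.births, dtype=np.int64)

    def cohort_masses(self) -> np.ndarray:
        """Current circulating mass of every cohort."""
        if not self.births:
            return np.empty(0)
        return np.asarray(self.masses) * self.weights[self.ages()]


def epo_concentration(
    doses: Sequence[DoseEvent], half_life: float, t: float
) -> float:
    """Superposed mono-exponential concentration at time ``t`` (days).

    Each past dose contributes ``amount * 2**(-24 * (t - day) / half_life)``
    with ``half_life`` in hours; doses dated after ``t`` contribute nothing.
    """
    if half_life <= 0:
        raise DomainError(f"half_life must be > 0, got {half_life}")
    if t < 0:
        raise DomainError(f"time must be >= 0, got {t}")
    c = 0.0
    for d in doses:
        if d.amount < 0:
            raise DomainError("dose amounts must be >= 0")
        if d.day <= t:
            c += d.amount * 2.0 ** (-24.0 * (t - d.day) / half_life)
    return c


def production_stimulus(
    concentration: float, patient: VirtualPatient, constants: ModelConstants
) -> float:
    """Red-cell production rate (mass-units/day) at a given ESA concentration.

    Saturating Emax form: ``P0 + s * Emax * C / (C + C50)``.  Equals the
    endogenous baseline at C = 0 and is monotone non-decreasing in C.
    """
    if concentration < 0 or not math.isfinite(concentration):
        raise DomainError(f"concentration must be finite and >= 0, got {concentration}")
    drive = concentration / (concentration + constants.c50) if concentration > 0 else 0.0
    return patient.baseline_production + patient.sensitivity * constants.emax * drive


def initial_state(
    patient: VirtualPatient, constants: ModelConstants, half_life: float
) -> ErythroState:
    """Pre-treatment steady state: the stationary age distribution under P0.

    One cohort of birth mass P0 per day of age, so total circulating mass
    is ``P0 * mean_lifespan`` and the noise-free haemoglobin equals the
    patient's starting value exactly.
    """
    constants.validate()
    if half_life not in constants.allowed_half_lives:
        raise DomainError(
            f"half_life {half_life} not in allowed set {constants.allowed_half_lives}"
        )
    w = survival_weights(constants.mean_lifespan, constants.lifespan_spread)
    n = len(w)
    births = list(range(-(n - 1), 1))  # ages n-1 ... 0 at day 0
    masses = [patient.baseline_production] * n
    return ErythroState(
        day=0, births=births, masses=masses, doses=[], half_life=half_life, weights=w
    )


def step_day(
    state: ErythroState,
    new_doses: Sequence[DoseEvent],
    patient: VirtualPatient,
    constants: ModelConstants,
) -> ErythroState:
    """Advance the state by one day (in place; also returned).

    Appends today's doses, then creates tomorrow's cohort with mass equal
    to the production rate driven by the concentration one maturation delay
    before tomorrow, advances the clock, and prunes cohorts whose survival
    weight has reached zero.
    """
    for d in new_doses:
        if d.day != state.day:
            raise SchedulingError(
                f"dose dated day {d.day} submitted on simulation day {state.day}"
            )
    state.doses.extend(new_doses)
    new_day = state.day + 1
    t_felt = new_day - constants.maturation_delay
    if t_felt >= 0:
        c = epo_concentration(state.doses, state.half_life, t_felt)
    else:
        c = 0.0
    prod = production_stimulus(c, patient, constants)
    state.births.append(new_day)
    state.masses.append(prod)
    state.day = new_day
    n_w = len(state.weights)
    while state.births and new_day - state.births[0] >= n_w:
        state.births.pop(0)
        state.masses.pop(0)
    return state


def apply_bleed(
    state: ErythroState,
    fraction: float,
    constants: Optional[ModelConstants] = None,
) -> ErythroState:
    """Acute bleeding: remove ``fraction`` of every cohort's mass (in place).

    Proportional removal leaves the normalised age distribution untouched
    and scales total mass by exactly ``1 - fraction``.  Plasma-volume refill
    is treated as immediate, so the haemoglobin drop equals the volume
    fraction lost.
    """
    max_frac = constants.bleed_max_fraction if constants is not None else 0.30
    if not (0.0 <= fraction <= max_frac + 1e-12):
        raise DomainError(
            f"bleed fraction must be in [0, {max_frac}], got {fraction}"
        )
    if fraction == 0.0:
        return state
    keep = 1.0 - fraction
    state.masses = [m * keep for m in state.masses]
    return state


def total_mass(state: ErythroState) -> float:
    """Total circulating RBC mass (mass units)."""
    if not state.births:
        return 0.0
    return float(np.dot(state.masses, state.weights[state.ages()]))


def hb_true(state: ErythroState, constants: ModelConstants) -> float:
    """Noise-free haemoglobin: kappa times total circulating mass."""
    return constants.hb_per_mass * total_mass(state)


def mean_rbc_lifespan(state: ErythroState) -> float:
    """Turnover lifespan (days): mass over smoothed expected senescence loss.

    The denominator is the mean, over the next ``LIFESPAN_WINDOW`` days, of
    the expected mass lost to senescence from the cohorts currently in
    circulation — by telescoping, ``sum_i m_i * (w[a_i] - w[a_i + W]) / W``.
    At a stationary age distribution this is exactly the production rate,
    so the read-out reproduces the configured mean lifespan; uneven past
    production perturbs the age distribution and makes it fluctuate.
    """
    if not state.births:
        raise UndefinedStateError("mean RBC lifespan is undefined for an empty state")
    w = state.weights
    ages = state.ages()
    m = np.asarray(state.masses)
    wp = np.concatenate([w, np.zeros(LIFESPAN_WINDOW)])
    mass = float(np.dot(m, w[ages]))
    loss = float(np.dot(m, w[ages] - wp[ages + LIFESPAN_WINDOW])) / LIFESPAN_WINDOW
    if mass <= 0.0:
        raise UndefinedStateError("mean RBC lifespan is undefined for zero mass")
    if loss <= 0.0:
        raise UndefinedStateError("no senescence within the smoothing window")
    return mass / loss
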