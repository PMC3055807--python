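"""Model constants and virtual patient generation.

The simulated subject is an ESA-naive haemodialysis patient.  Three numbers
define them: the starting haemoglobin (a random multiple of 0.1 g/dL in
[7.0, 8.0]), a dimensionless ESA sensitivity ``s`` (log-normal, median 1)
that scales drug-driven red-cell production, and an endogenous baseline
production rate ``P0`` chosen so that, untreated and noise-free, the patient
sits exactly at their starting haemoglobin: with haemoglobin-per-mass
calibration constant kappa and mean red-cell lifespan L,

    Hb = kappa * (total circulating RBC mass) = kappa * P0 * L  at steady state,

hence ``P0 = starting_hb / (kappa * L)``.  Imposing this pre-treatment
steady state means week-0 dynamics are driven purely by prescriptions.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .errors import ConfigurationError, DomainError

__all__ = [
    "ModelConstants",
    "VirtualPatient",
    "baseline_production",
    "generate_patient",
    "patient_from_seed",
]

#: Number of points on the starting-haemoglobin grid 7.0, 7.1, ..., 8.0.
_N_HB_GRID = 11


@dataclass(frozen=True)
class ModelConstants:
    """All fixed parameters of the simulator.

    Defaults reproduce the study configuration: haemoglobin target
    11–12 g/dL with a 13 g/dL safety threshold, mean RBC lifespan 61.2 days,
    observation noise of ±0.5 g/dL, ESA half-lives restricted to
    {24, 48, 138} hours, a 12-week equilibration phase followed by a 20-week
    maintenance phase, bleeding of at most 30% of blood volume in weeks
    18–24, and a dose–response scale calibrated so the population's mean
    weekly epoetin need at target is about 6,000 U.

    Units: haemoglobin in g/dL, times in days (half-lives in hours), doses
    in units of epoetin (U), RBC mass in arbitrary mass units with
    ``hb_per_mass`` (kappa) converting total mass to g/dL.
    """

    target_low: float = 11.0
    target_high: float = 12.0
    safety_threshold: float = 13.0
    mean_lifespan: float = 61.2
    lifespan_spread: float = 15.0
    maturation_delay: int = 7
    hb_per_mass: float = 1.0
    # Saturating dose-response g(C) = emax * C / (C + c50), in RBC-mass-units/day.
    # emax is set so a fully saturated stimulus could sustain 25 g/dL of
    # ESA-driven haemoglobin in a median-sensitivity patient (dosing in the
    # study regime sits well below saturation); c50 is the calibrated
    # half-saturation concentration in dose units (see prescribers module).
    emax: float = 25.0 / 61.2
    c50: float = 6203.851456021526
    sensitivity_sigma: float = 0.3
    noise_amplitude: float = 0.5
    allowed_half_lives: tuple = (24.0, 48.0, 138.0)
    equilibration_weeks: int = 12
    maintenance_weeks: int = 20
    bleed_window: tuple = (18, 24)
    bleed_max_fraction: float = 0.30
    mean_weekly_need: float = 6000.0

    @property
    def target_mid(self) -> float:
        return 0.5 * (self.target_low + self.target_high)

    @property
    def total_weeks(self) -> int:
        return self.equilibration_weeks + self.maintenance_weeks

    def validate(self) -> "ModelConstants":
        """Check every structural invariant; return self for chaining."""
        if not (self.target_low < self.target_high < self.safety_threshold):
            raise ConfigurationError(
                "require target_low < target_high < safety_threshold, got "
                f"{self.target_low}, {self.target_high}, {self.safety_threshold}"
            )
        if self.mean_lifespan <= 0:
            raise ConfigurationError("mean_lifespan must be positive")
        if not (0 <= self.lifespan_spread < self.mean_lifespan):
            raise ConfigurationError(
                "lifespan_spread must satisfy 0 <= spread < mean_lifespan"
            )
        if self.maturation_delay < 0:
            raise ConfigurationError("maturation_delay must be >= 0")
        if self.hb_per_mass <= 0:
            raise ConfigurationError("hb_per_mass must be positive")
        if self.emax <= 0 or self.c50 <= 0:
            raise ConfigurationError("dose-response parameters must be positive")
        if self.sensitivity_sigma < 0:
            raise ConfigurationError("sensitivity_sigma must be >= 0")
        if self.noise_amplitude < 0:
            raise ConfigurationError("noise_amplitude must be >= 0")
        if not self.allowed_half_lives or any(h <= 0 for h in self.allowed_half_lives):
            raise ConfigurationError("allowed_half_lives must be positive")
        if not (0 < self.bleed_max_fraction <= 1):
            raise ConfigurationError("bleed_max_fraction must be in (0, 1]")
        if self.equilibration_weeks <= 0 or self.maintenance_weeks <= 0:
            raise ConfigurationError("phase lengths must be positive")
        lo, hi = self.bleed_window
        if not (1 <= lo <= hi <= self.total_weeks):
            raise ConfigurationError("bleed_window must lie within the session")
        if self.mean_weekly_need <= 0:
            raise ConfigurationError("mean_weekly_need must be positive")
        return self

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["allowed_half_lives"] = list(self.allowed_half_lives)
        d["bleed_window"] = list(self.bleed_window)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConstants":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigurationError(
                f"unknown constants key(s): {', '.join(sorted(unknown))}"
            )
        kwargs = dict(d)
        if "allowed_half_lives" in kwargs:
            kwargs["allowed_half_lives"] = tuple(kwargs["allowed_half_lives"])
        if "bleed_window" in kwargs:
            kwargs["bleed_window"] = tuple(kwargs["bleed_window"])
        return cls(**kwargs).validate()


@dataclass(frozen=True)
class VirtualPatient:
    """One randomised ESA-naive subject.

    ``baseline_production`` sustains ``starting_hb`` with zero ESA on board;
    ``sensitivity`` multiplies the drug-driven part of red-cell production.
    """

    starting_hb: float
    sensitivity: float
    baseline_production: float
    seed: Optional[int] = None

    def validate(self, constants: Optional[ModelConstants] = None) -> "VirtualPatient":
        if not (7.0 - 1e-9 <= self.starting_hb <= 8.0 + 1e-9):
            raise ConfigurationError("starting_hb must be in [7.0, 8.0]")
        if abs(round(self.starting_hb * 10) - self.starting_hb * 10) > 1e-9:
            raise ConfigurationError("starting_hb must be a multiple of 0.1 g/dL")
        if self.sensitivity <= 0 or self.baseline_production <= 0:
            raise ConfigurationError("sensitivity and baseline_production must be > 0")
        return self

    def to_dict(self) -> dict:
        return {
            "starting_hb": self.starting_hb,
            "sensitivity": self.sensitivity,
            "baseline_production": self.baseline_production,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "VirtualPatient":
        return cls(**d)


def baseline_production(starting_hb: float, constants: ModelConstants) -> float:
    """Endogenous RBC production rate P0 (mass-units/day) sustaining ``starting_hb``.

    Solves ``kappa * P0 * mean_lifespan = starting_hb``, i.e. the untreated
    steady state of the cohort engine.  Linear in the starting haemoglobin.
    """
    if starting_hb < 0 or not math.isfinite(starting_hb):
        raise DomainError(f"starting_hb must be finite and >= 0, got {starting_hb}")
    return starting_hb / (constants.hb_per_mass * constants.mean_lifespan)


def generate_patient(
    rng: np.random.Generator,
    constants: ModelConstants,
    seed: Optional[int] = None,
) -> VirtualPatient:
    """Draw one virtual patient from a seeded stream.

    Starting haemoglobin is uniform over the 11 grid points
    {7.0, 7.1, ..., 8.0}; sensitivity is log-normal with median 1 and
    log-scale dispersion ``constants.sensitivity_sigma``.  Deterministic
    given the generator state.  ``seed`` is recorded on the patient for
    provenance only; the draw uses ``rng``.
    """
    constants.validate()
    idx = int(rng.integers(0, _N_HB_GRID))
    starting_hb = round(7.0 + 0.1 * idx, 1)
    sensitivity = float(rng.lognormal(mean=0.0, sigma=constants.sensitivity_sigma))
    p0 = baseline_production(starting_hb, constants)
    return VirtualPatient(
        starting_hb=starting_hb,
        sensitivity=sensitivity,
        baseline_production=p0,
        seed=seed,
    ).validate()


def patient_from_seed(seed: int, constants: ModelConstants) -> VirtualPatient:
    """Convenience wrapper: a fresh patient from an integer seed."""
    rng = np.random.default_rng(seed)
    return generate_patient(rng, constants, seed=seed)
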