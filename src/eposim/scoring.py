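"""Session statistics: central tendency, variability, target occupancy,
ability score, dose-adjustment count and trapezoidal AUC.

Two variability metrics are computed.  The standard deviation measures
dispersion around the mean; the *delta Hb* — the mean absolute difference
between consecutive values — is sensitive to week-to-week alternation that
the SD cannot see (an alternating series and its sorted copy share an SD
but not a delta Hb).

The ability score summarises target-keeping over a series of values with
target range [11, 12] g/dL and safety threshold 13 g/dL: each value below
11 or above 12 costs one error point and a value above 13 costs a second
one (double error); with E points over N values the score is ``2 - E/N``,
so a fully in-target series scores 2, a series entirely outside the target
(but never above 13) scores 1, and overshooting can push it below 1.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .errors import InsufficientDataError
from .patient import ModelConstants
from .session import SessionRecord

__all__ = [
    "SessionStats",
    "delta_hb",
    "ability_score",
    "target_percentages",
    "count_dose_changes",
    "trapezoid_auc",
    "summarize",
]


@dataclass(frozen=True)
class SessionStats:
    """Summary of one session (or one phase / sampling grid of it)."""

    mean_hb: float
    sd_hb: float
    delta_hb: float
    pct_below_11: float
    pct_in_target: float
    pct_above_12: float
    pct_above_13: float
    ability_score: float
    mean_rbc_lifespan: float
    sd_rbc_lifespan: float
    n_dose_changes: int
    auc: float
    n_obs: int

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


def _as_series(series: Sequence[float]) -> np.ndarray:
    x = np.asarray(series, dtype=float)
    if x.ndim != 1:
        raise InsufficientDataError("expected a 1-D series of haemoglobin values")
    return x


def delta_hb(series: Sequence[float]) -> float:
    """Mean absolute difference between consecutive values (g/dL)."""
    x = _as_series(series)
    if x.size < 2:
        raise InsufficientDataError("delta Hb needs at least 2 values")
    return float(np.mean(np.abs(np.diff(x))))


def ability_score(series: Sequence[float], constants: ModelConstants) -> float:
    """Target-keeping score 2 - E/N; see module docstring.

    Boundary convention: values exactly at 11.0 or 12.0 g/dL are in target
    and 13.0 is not "above 13" (strict inequalities).
    """
    x = _as_series(series)
    if x.size == 0:
        raise InsufficientDataError("ability score needs at least 1 value")
    errors = (
        np.count_nonzero(x < constants.target_low)
        + np.count_nonzero(x > constants.target_high)
        + np.count_nonzero(x > constants.safety_threshold)
    )
    return float(2.0 - errors / x.size)


def target_percentages(
    series: Sequence[float], constants: ModelConstants
) -> tuple:
    """(% below 11, % in [11, 12], % above 12, % above 13).

    The first three partition the series (boundaries count as in-target);
    the above-13 percentage is a subset of above-12.
    """
    x = _as_series(series)
    if x.size == 0:
        raise InsufficientDataError("target percentages need at least 1 value")
    n = x.size
    below = 100.0 * int(np.count_nonzero(x < constants.target_low)) / n
    in_target = 100.0 * int(
        np.count_nonzero((x >= constants.target_low) & (x <= constants.target_high))
    ) / n
    above12 = 100.0 * int(np.count_nonzero(x > constants.target_high)) / n
    above13 = 100.0 * int(np.count_nonzero(x > constants.safety_threshold)) / n
    return (below, in_target, above12, above13)


def count_dose_changes(doses: Sequence[float]) -> int:
    """Number of dose adjustments: positions where the dose differs from the
    previous one (the first prescription is not a change)."""
    d = np.asarray(doses, dtype=float)
    if d.size == 0:
        return 0
    return int(np.count_nonzero(d[1:] != d[:-1]))


def trapezoid_auc(
    series: Sequence[float],
    baseline: float = 0.0,
    x: Optional[Sequence[float]] = None,
) -> float:
    """Composite trapezoid area under (series - baseline).

    ``x`` gives the abscissae in weeks (defaults to a uniform weekly grid),
    so the result is in g/dL * weeks.
    """
    y = _as_series(series) - baseline
    if y.size < 2:
        raise InsufficientDataError("AUC needs at least 2 values")
    if x is None:
        return float(np.trapezoid(y, dx=1.0))
    return float(np.trapezoid(y, x=np.asarray(x, dtype=float)))


def summarize(
    record: SessionRecord,
    constants: Optional[ModelConstants] = None,
    phase: str = "all",
    sampling: str = "weekly",
) -> SessionStats:
    """Compute every statistic of ``SessionStats`` on a phase/grid selection.

    ``phase`` is 'all', 'equilibration' or 'maintenance'; ``sampling`` is
    'weekly' (true haemoglobin, every selected week) or 'visible' (the
    observed values the prescriber actually saw, on visible weeks only —
    the AUC then uses the actual week positions as abscissae).  Delta Hb is
    taken over consecutive values of the selected grid; dose changes are
    counted over the doses entered within the selected weeks.
    """
    if constants is None:
        constants = record.config.constants
    if phase not in ("all", "equilibration", "maintenance"):
        raise InsufficientDataError(f"unknown phase filter {phase!r}")
    if sampling not in ("weekly", "visible"):
        raise InsufficientDataError(f"unknown sampling grid {sampling!r}")
    df = record.data
    if phase != "all":
        df = df[df["phase"] == phase]
    if sampling == "visible":
        df = df[df["visible"]]
        hb = df["observed_hb"].to_numpy(dtype=float)
    else:
        hb = df["true_hb"].to_numpy(dtype=float)
    if hb.size == 0:
        raise InsufficientDataError(
            f"no observations for phase={phase!r}, sampling={sampling!r}"
        )
    weeks = df["week"].to_numpy(dtype=float)
    below, in_tgt, above12, above13 = target_percentages(hb, constants)
    doses = df["dose"].to_numpy(dtype=float)
    doses = doses[~np.isnan(doses)]
    lifespan = df["rbc_lifespan"].to_numpy(dtype=float)
    return SessionStats(
        mean_hb=float(np.mean(hb)),
        sd_hb=float(np.std(hb, ddof=1)) if hb.size > 1 else 0.0,
        delta_hb=delta_hb(hb) if hb.size > 1 else 0.0,
        pct_below_11=below,
        pct_in_target=in_tgt,
        pct_above_12=above12,
        pct_above_13=above13,
        ability_score=ability_score(hb, constants),
        mean_rbc_lifespan=float(np.mean(lifespan)),
        sd_rbc_lifespan=float(np.std(lifespan, ddof=1)) if lifespan.size > 1 else 0.0,
        n_dose_changes=count_dose_changes(doses),
        auc=trapezoid_auc(hb, baseline=0.0, x=weeks) if hb.size > 1 else 0.0,
        n_obs=int(hb.size),
    )
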