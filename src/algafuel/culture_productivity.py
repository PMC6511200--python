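"""Steady-state productivity analysis of semi-continuous cultures.

A strain is run at several dilution rates D (medium replacements per day);
at steady state the specific growth rate equals D, so the biomass
productivity is P_b = D * X_ss with X_ss the steady-state biomass
concentration.  Lipid and FAME (saponifiable-lipid) productivities follow by
multiplying with the corresponding dry-weight mass fractions measured at
steady state:

    P_lip [mg/L/day] = 10 * P_b [g/L/day] * w_lip [% d.wt.]

Steady state is operationalized as: at least three reactor-volume turnovers
(3/D days) elapsed since the switch to semi-continuous operation, after
which the last three sampled days are averaged.  Light-limited sweeps show
X_ss decreasing with D, a unimodal P_b, and washout at high D; the optimum
dilution rate maximizes the productivity criterion of interest.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

__all__ = [
    "DailyRecord",
    "CultureTimeSeries",
    "SteadyStateWindow",
    "SteadyStateRecord",
    "DilutionSweep",
    "detect_steady_state",
    "productivities",
    "select_optimum",
    "flag_washout",
    "SteadyStateWarning",
]

Mode = Literal["batch", "semicontinuous"]


class SteadyStateWarning(UserWarning):
    """Raised (as a warning) when a steady-state window looks unconverged."""


@dataclass(frozen=True)
class DailyRecord:
    """One daily sample of a culture."""

    day: float
    mode: Mode
    biomass_g_per_l: float
    fv_fm: float | None = None

    def __post_init__(self) -> None:
        if self.biomass_g_per_l < 0:
            raise ValueError("biomass concentration must be >= 0")
        if self.fv_fm is not None and not 0.0 <= self.fv_fm <= 1.0:
            raise ValueError("Fv/Fm must lie in [0, 1]")
        if self.mode not in ("batch", "semicontinuous"):
            raise ValueError(f"unknown mode {self.mode!r}")


@dataclass
class CultureTimeSeries:
    """Daily biomass (and optionally Fv/Fm) records for one strain at one D."""

    strain: str
    dilution_rate: float
    records: list[DailyRecord]
    reactor_volume_l: float | None = None

    def __post_init__(self) -> None:
        days = [r.day for r in self.records]
        if any(b >= a for a, b in zip(days[1:], days[:-1])):
            raise ValueError("days must be strictly increasing")

    @property
    def semicontinuous(self) -> list[DailyRecord]:
        return [r for r in self.records if r.mode == "semicontinuous"]


@dataclass(frozen=True)
class SteadyStateWindow:
    """The qualifying averaging window of a time series."""

    days: tuple[float, ...]
    mean_biomass: float
    cv_biomass: float
    converged: bool  # CV within the convergence warning threshold


def detect_steady_state(
    ts: CultureTimeSeries,
    n_days: int = 3,
    turnovers: float = 3.0,
    cv_warn: float = 0.10,
) -> SteadyStateWindow:
    """Locate the steady-state averaging window of a semi-continuous series.

    The window is the last ``n_days`` sampled semi-continuous days, each of
    which must fall at least ``turnovers / D`` days after the switch to
    semi-continuous mode (i.e. after three reactor-volume turnovers by
    default).  The window is unaffected by any batch-phase days preceding
    the switch.  A coefficient of variation of biomass above ``cv_warn``
    triggers a :class:`SteadyStateWarning` but is not an error.

    Raises
    ------
    ValueError
        If D <= 0, or fewer than ``n_days`` qualifying days exist
        ("insufficient steady-state data").
    """
    if ts.dilution_rate <= 0:
        raise ValueError("steady-state detection requires D > 0")
    semi = ts.semicontinuous
    if not semi:
        raise ValueError("insufficient steady-state data: no semi-continuous days")
    switch_day = semi[0].day
    earliest = switch_day + turnovers / ts.dilution_rate
    qualifying = [r for r in semi if r.day >= earliest]
    if len(qualifying) < n_days:
        raise ValueError(
            f"insufficient steady-state data: {len(qualifying)} qualifying "
            f"days after {earliest:g} (need {n_days})"
        )
    window = qualifying[-n_days:]
    x = np.array([r.biomass_g_per_l for r in window])
    mean = float(x.mean())
    cv = float(x.std(ddof=0) / mean) if mean > 0 else math.inf
    converged = cv <= cv_warn
    if not converged:
        warnings.warn(
            f"steady-state window CV(X) = {cv:.1%} exceeds {cv_warn:.0%}; "
            f"the culture may not have converged",
            SteadyStateWarning,
            stacklevel=2,
        )
    return SteadyStateWindow(
        days=tuple(r.day for r in window),
        mean_biomass=mean,
        cv_biomass=cv,
        converged=converged,
    )


def productivities(
    x_ss: float, d: float, w_lip: float = 0.0, w_fame: float = 0.0
) -> tuple[float, float, float]:
    """Biomass, lipid and FAME productivities at steady state.

    Parameters are the steady-state biomass concentration (g/L), the
    dilution rate (1/day) and the lipid / FAME dry-weight percentages.
    Returns ``(P_b, P_lip, P_fame)`` with P_b in g/L/day and the mass-
    fraction productivities in mg/L/day.
    """
    if min(x_ss, d, w_lip, w_fame) < 0:
        raise ValueError("productivity inputs must be >= 0")
    if max(w_lip, w_fame) > 100:
        raise ValueError("mass fractions are percentages and must be <= 100")
    p_b = d * x_ss
    return p_b, 10.0 * p_b * w_lip, 10.0 * p_b * w_fame


@dataclass(frozen=True)
class SteadyStateRecord:
    """Steady-state characterization of one strain at one dilution rate."""

    strain: str
    dilution_rate: float
    x_ss: float  # g/L
    lipid_fraction: float = 0.0  # % d.wt.
    fame_fraction: float = 0.0  # % d.wt.
    protein_fraction: float = 0.0  # % d.wt.

    def __post_init__(self) -> None:
        # delegates range validation; also derives nothing mutable
        productivities(self.x_ss, self.dilution_rate,
                       self.lipid_fraction, self.fame_fraction)

    @property
    def biomass_productivity(self) -> float:
        """P_b = D * X_ss, g/L/day."""
        return self.dilution_rate * self.x_ss

    @property
    def lipid_productivity(self) -> float:
        """P_lip = 10 * P_b * w_lip, mg/L/day."""
        return 10.0 * self.biomass_productivity * self.lipid_fraction

    @property
    def fame_productivity(self) -> float:
        """P_fame = 10 * P_b * w_fame, mg/L/day."""
        return 10.0 * self.biomass_productivity * self.fame_fraction


@dataclass
class DilutionSweep:
    """Steady-state records of one strain over increasing dilution rates."""

    strain: str
    records: list[SteadyStateRecord]

    def __post_init__(self) -> None:
        rates = [r.dilution_rate for r in self.records]
        if any(b <= a for a, b in zip(rates, rates[1:])):
            raise ValueError("dilution rates must be strictly increasing and unique")

    @property
    def dilution_rates(self) -> list[float]:
        return [r.dilution_rate for r in self.records]


Criterion = Literal["lipid", "fame", "biomass", "combined"]


def _criterion_values(sweep: DilutionSweep, criterion: Criterion) -> np.ndarray:
    if criterion == "lipid":
        return np.array([r.lipid_productivity for r in sweep.records])
    if criterion == "fame":
        return np.array([r.fame_productivity for r in sweep.records])
    if criterion == "biomass":
        return np.array([r.biomass_productivity for r in sweep.records])
    if criterion == "combined":
        # best compromise of biomass and lipid productivity: sum of the
        # min-max normalized curves
        p_b = np.array([r.biomass_productivity for r in sweep.records])
        p_lip = np.array([r.lipid_productivity for r in sweep.records])

        def norm(v: np.ndarray) -> np.ndarray:
            span = v.max() - v.min()
            return np.zeros_like(v) if span == 0 else (v - v.min()) / span

        return norm(p_b) + norm(p_lip)
    raise ValueError(f"unknown criterion {criterion!r}")


def select_optimum(
    sweep: DilutionSweep, criterion: Criterion = "lipid"
) -> tuple[float, SteadyStateRecord]:
    """The dilution rate maximizing the chosen productivity criterion.

    Ties are broken toward the smaller dilution rate (cheaper medium
    turnover).  Raises on an empty sweep.
    """
    if not sweep.records:
        raise ValueError("cannot select an optimum from an empty sweep")
    values = _criterion_values(sweep, criterion)
    best = int(np.argmax(values))  # argmax returns the first (smallest-D) max
    record = sweep.records[best]
    return record.dilution_rate, record


def flag_washout(
    sweep: DilutionSweep, threshold_fraction: float = 0.15
) -> float | None:
    """Smallest D whose X_ss collapsed below a fraction of the sweep maximum.

    Returns ``None`` when no record falls below
    ``threshold_fraction * max(X_ss)``.
    """
    if len(sweep.records) < 2:
        raise ValueError("washout detection needs at least two records")
    x = np.array([r.x_ss for r in sweep.records])
    cutoff = threshold_fraction * x.max()
    for record, x_ss in zip(sweep.records, x):
        if x_ss < cutoff:
            return record.dilution_rate
    return None
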