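"""Seeded generators emulating the study's measurement types.

Three kinds of synthetic input are produced, each with its generating
ground truth stored alongside so recovery tests are well posed:

* **Chemostat sweeps** — steady states of a light-limited bubble-column
  culture across dilution rates.  Growth follows a Hill curve of the
  column-averaged irradiance (Beer-Lambert attenuation through the light
  path); the steady-state biomass at each D solves mu(Iav(X)) = D by
  bisection, giving the qualitative light-limited signature: X_ss
  decreasing with D, unimodal biomass productivity, and washout once D
  exceeds mu at full irradiance.  Daily time series relax toward X_ss with
  multiplicative lognormal noise (positivity-preserving).
* **Rapid light curves** — rETR from the Platt photoinhibition model on a
  12-step PAR ladder with multiplicative Gaussian noise, together with
  fluorescence (F, Fm') pairs realizing the implied quantum yields.
* **Stress time-courses** — templated trajectories of Fv/Fm, alpha and Ik
  under heat (38 C), cold (10 C) or high light (1600 umol/m2/s), with the
  ground-truth change-points stored.
* **FAME profiles** — Dirichlet draws over the 15-species fatty-acid
  alphabet of the packaged reference table, scaled to a sub-100 total.

Identical configurations and seeds give bit-identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .culture_productivity import (
    CultureTimeSeries,
    DailyRecord,
    DilutionSweep,
    SteadyStateRecord,
)
from .fame_profile import FameProfile, FattyAcid, parse_fatty_acid, saturation_summary
from .photosynthesis import RapidLightCurve, platt_retr

__all__ = [
    "ChemostatConfig",
    "RLCConfig",
    "StressConfig",
    "FameConfig",
    "SimulationConfig",
    "SyntheticSweep",
    "SyntheticRLC",
    "SyntheticStressCourse",
    "SyntheticProfile",
    "average_irradiance",
    "growth_rate",
    "steady_state_biomass",
    "simulate_chemostat_sweep",
    "simulate_rlc",
    "simulate_stress_course",
    "simulate_fame_profile",
]


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ChemostatConfig:
    """Light-limited chemostat parameters.

    Defaults emulate the study's indoor bubble columns: 7 cm light path,
    1000 umol/m2/s incident irradiance, steady states spanning ~2 g/L down
    to washout within a 0.05-0.9 1/day dilution-rate range.
    """

    mu_max: float = 0.9  # 1/day
    ka: float = 200.0  # biomass absorption coefficient, m2/kg
    light_path: float = 0.07  # m (column diameter)
    i0: float = 1000.0  # incident irradiance, umol/m2/s
    ik_growth: float = 250.0  # half-saturation irradiance of growth
    hill_n: float = 1.4  # Hill exponent of the growth-irradiance curve
    noise_cv: float = 0.05  # CV of daily biomass observations

    def __post_init__(self) -> None:
        if min(self.mu_max, self.ka, self.light_path, self.i0,
               self.ik_growth, self.hill_n) <= 0:
            raise ValueError("chemostat rates and irradiances must be > 0")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")


#: Typical 12-step actinic ladder (plus the dark step) of a rapid light
#: curve protocol, umol/m2/s.
DEFAULT_PAR_STEPS: tuple[float, ...] = (
    0, 25, 45, 66, 90, 125, 190, 285, 420, 625, 820, 1150, 1500,
)


@dataclass(frozen=True)
class RLCConfig:
    """Ground-truth Platt parameters and noise of a synthetic RLC."""

    alpha: float = 0.30
    ps: float = 80.0
    beta: float = 0.01
    par_steps: tuple[float, ...] = DEFAULT_PAR_STEPS
    noise_sd: float = 0.05  # multiplicative Gaussian noise on rETR
    absorptance_factor: float = 1.0
    fm_dark: float = 1000.0  # arbitrary fluorescence scale

    def __post_init__(self) -> None:
        if self.alpha <= 0 or self.ps <= 0 or self.beta < 0:
            raise ValueError("need alpha > 0, Ps > 0, beta >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


StressKind = Literal["heat38", "cold10", "highlight1600"]


@dataclass(frozen=True)
class StressConfig:
    """Stress time-course template parameters (times in minutes)."""

    duration_min: float = 240.0
    step_min: float = 5.0
    noise_sd: float = 0.0  # additive Gaussian, relative to initial value
    fv_fm_initial: float = 0.69
    alpha_initial: float = 0.15
    ik_initial: float = 250.0
    dip_time_min: float = 60.0  # heat template: time of the Fv/Fm minimum
    recovery_time_min: float = 155.0  # heat template: Fv/Fm recovery time
    cold_min_time_min: float = 215.0  # cold template: time of the alpha minimum

    def __post_init__(self) -> None:
        if self.duration_min > 240.0:
            raise ValueError("stress exposures are at most 4 h (240 min)")
        if not 0 < self.dip_time_min < self.recovery_time_min <= self.duration_min:
            raise ValueError("need 0 < dip time < recovery time <= duration")


@dataclass(frozen=True)
class FameConfig:
    """Dirichlet generator over the reference fatty-acid alphabet.

    ``class_weights`` set the expected mass split between SFA, MUFA and
    PUFA (they may sum below 1; the remainder spreads uniformly); the
    concentration parameter controls draw-to-draw variability (higher =
    tighter around the mixture mean).  Totals are drawn uniformly from
    ``total_range`` — profiles legitimately sum below 100 %.
    """

    class_weights: tuple[float, float, float] = (0.25, 0.25, 0.50)
    concentration: float = 50.0
    total_range: tuple[float, float] = (80.0, 100.0)

    def __post_init__(self) -> None:
        if sum(self.class_weights) > 1.0 + 1e-9:
            raise ValueError("class mixture weights must sum to <= 1")
        if self.concentration <= 0:
            raise ValueError("concentration must be > 0")


@dataclass(frozen=True)
class SimulationConfig:
    """Bundle of all generator parameters plus the master seed."""

    seed: int = 0
    chemostat: ChemostatConfig = field(default_factory=ChemostatConfig)
    rlc: RLCConfig = field(default_factory=RLCConfig)
    stress: StressConfig = field(default_factory=StressConfig)
    fame: FameConfig = field(default_factory=FameConfig)


# ---------------------------------------------------------------------------
# Chemostat model
# ---------------------------------------------------------------------------


def average_irradiance(x: float, cfg: ChemostatConfig) -> float:
    """Column-averaged Beer-Lambert irradiance at biomass x (g/L).

    Iav(X) = I0 * (1 - exp(-Ka X L)) / (Ka X L), with the X -> 0 limit I0.
    (g/L equals kg/m3, so Ka [m2/kg] * X * L is dimensionless.)
    """
    tau = cfg.ka * x * cfg.light_path
    if tau < 1e-12:
        return cfg.i0
    return cfg.i0 * (1.0 - math.exp(-tau)) / tau


def growth_rate(i: float, cfg: ChemostatConfig) -> float:
    """Hill growth-irradiance curve mu(I) = mu_max I^n / (Ik^n + I^n)."""
    if i <= 0:
        return 0.0
    ratio = (i / cfg.ik_growth) ** cfg.hill_n
    return cfg.mu_max * ratio / (1.0 + ratio)


def steady_state_biomass(
    d: float, cfg: ChemostatConfig, x_max: float = 100.0
) -> float:
    """Solve mu(Iav(X)) = D for the steady-state biomass (g/L).

    Returns 0.0 (washout) when D is at or above the growth rate achievable
    at full incident irradiance.  The left-hand side is strictly decreasing
    in X, so bisection on [~0, x_max] brackets the unique root.
    """
    if d <= 0:
        raise ValueError("dilution rate must be > 0")
    eps = 1e-9
    if d >= growth_rate(average_irradiance(eps, cfg), cfg):
        return 0.0

    def excess(x: float) -> float:
        return growth_rate(average_irradiance(x, cfg), cfg) - d

    if excess(x_max) > 0:  # pragma: no cover - pathological parameters
        raise ValueError(f"steady state exceeds the {x_max} g/L search bracket")
    return float(brentq(excess, eps, x_max, xtol=1e-12, rtol=8.9e-16))


@dataclass
class SyntheticSweep:
    """A generated dilution sweep plus its ground truth."""

    strain: str
    config: ChemostatConfig
    seed: int
    d_grid: tuple[float, ...]
    true_x_ss: tuple[float, ...]  # noise-free solver output per D
    timeseries: list[CultureTimeSeries]  # noisy daily series per D

    def true_records(self) -> DilutionSweep:
        """Sweep built from the noise-free steady states."""
        return DilutionSweep(
            strain=self.strain,
            records=[
                SteadyStateRecord(self.strain, d, x)
                for d, x in zip(self.d_grid, self.true_x_ss)
            ],
        )

    def timeseries_frame(self) -> pd.DataFrame:
        """All daily records in the culture time-series CSV schema."""
        rows = [
            {
                "strain": ts.strain,
                "day": r.day,
                "mode": r.mode,
                "dilution_rate": ts.dilution_rate,
                "biomass_gL": r.biomass_g_per_l,
                "fv_fm": r.fv_fm,
            }
            for ts in self.timeseries
            for r in ts.records
        ]
        return pd.DataFrame(rows)


def _lognormal_factor(rng: np.random.Generator, cv: float, size=None):
    """Unit-mean multiplicative lognormal noise with the given CV."""
    if cv == 0:
        return np.ones(size) if size is not None else 1.0
    sigma = math.sqrt(math.log1p(cv * cv))
    return rng.lognormal(mean=-0.5 * sigma * sigma, sigma=sigma, size=size)


def simulate_chemostat_sweep(
    cfg: ChemostatConfig,
    d_grid: Sequence[float],
    seed: int = 0,
    strain: str = "synthetic",
    batch_days: int = 10,
) -> SyntheticSweep:
    """Generate steady states and daily series over a dilution-rate grid.

    Each series starts with a ``batch_days`` batch phase rising toward the
    zero-dilution carrying capacity, then relaxes exponentially to the
    steady state of its D; the series extends past three reactor-volume
    turnovers so steady-state detection has a qualifying window.  Daily
    observations carry unit-mean lognormal noise of CV ``noise_cv``.
    """
    d_grid = tuple(float(d) for d in d_grid)
    if not d_grid or any(d <= 0 for d in d_grid):
        raise ValueError("dilution grid must be positive")
    if any(b <= a for a, b in zip(d_grid, d_grid[1:])):
        raise ValueError("dilution grid must be strictly increasing")
    rng = np.random.default_rng(seed)
    # batch phase approaches the densest achievable culture
    x_batch = steady_state_biomass(min(0.05, min(d_grid)), cfg)
    true_x = tuple(steady_state_biomass(d, cfg) for d in d_grid)
    series = []
    for d, x_ss in zip(d_grid, true_x):
        n_semi = max(int(math.ceil(3.0 / d)) + 10, 12)
        days = np.arange(1, batch_days + n_semi + 1, dtype=float)
        x_true = np.empty_like(days)
        # logistic-ish batch rise from a dilute inoculum
        x0 = 0.05 * x_batch
        for i in range(batch_days):
            x_true[i] = x_batch * x0 / (x0 + (x_batch - x0)
                                        * math.exp(-cfg.mu_max * days[i]))
        # semi-continuous relaxation toward the steady state of this D
        x = x_true[batch_days - 1]
        # relaxation toward steady state with a time constant of at most
        # 2.5 days so the averaging window samples a converged culture
        rate = max(d, 0.4)
        for i in range(batch_days, len(days)):
            x = x_ss + (x - x_ss) * math.exp(-rate)
            x_true[i] = x
        noise = _lognormal_factor(rng, cfg.noise_cv, size=len(days))
        records = [
            DailyRecord(
                day=float(day),
                mode="batch" if day <= batch_days else "semicontinuous",
                biomass_g_per_l=float(xv * nv),
            )
            for day, xv, nv in zip(days, x_true, noise)
        ]
        series.append(CultureTimeSeries(strain=strain, dilution_rate=d,
                                        records=records))
    return SyntheticSweep(
        strain=strain, config=cfg, seed=seed, d_grid=d_grid,
        true_x_ss=true_x, timeseries=series,
    )


# ---------------------------------------------------------------------------
# Rapid light curves
# ---------------------------------------------------------------------------


@dataclass
class SyntheticRLC:
    """A generated rapid light curve plus its ground truth."""

    config: RLCConfig
    seed: int
    par: np.ndarray
    retr: np.ndarray  # noisy rETR per step
    qy: np.ndarray  # implied quantum yields
    f: np.ndarray  # fluorescence realizations
    fm_prime: np.ndarray

    def curve(self) -> RapidLightCurve:
        return RapidLightCurve(par=self.par, qy=self.qy,
                               absorptance_factor=self.config.absorptance_factor)

    def frame(self, sample_id: str = "rlc-0") -> pd.DataFrame:
        """Steps in the RLC CSV schema (the PAR=0 row carries F0/Fm)."""
        return pd.DataFrame({
            "sample_id": sample_id,
            "step": np.arange(len(self.par)),
            "par": self.par,
            "f": self.f,
            "fm_prime": self.fm_prime,
        })


def simulate_rlc(cfg: RLCConfig, seed: int = 0) -> SyntheticRLC:
    """Generate one noisy RLC from ground-truth Platt parameters.

    rETR at each ladder step is the Platt curve value times multiplicative
    Gaussian noise ``(1 + noise_sd * z)``; the implied quantum yield
    QY = 2 rETR / (PAR * absorptance) is realized as an (F, Fm') pair on a
    smoothly declining Fm' envelope.  The dark step's yield is the model's
    low-light limit 2 * alpha (the maximal quantum yield).  Parameters whose
    implied yield exceeds 1 are rejected.
    """
    rng = np.random.default_rng(seed)
    par = np.asarray(cfg.par_steps, dtype=float)
    clean = platt_retr(par, cfg.alpha, cfg.ps, cfg.beta)
    noise = 1.0 + cfg.noise_sd * rng.standard_normal(len(par))
    retr = np.clip(clean * noise, 0.0, None)
    qy = np.empty_like(retr)
    lit = par > 0
    qy[lit] = 2.0 * retr[lit] / (par[lit] * cfg.absorptance_factor)
    qy[~lit] = 2.0 * cfg.alpha / cfg.absorptance_factor  # low-light limit = MQY
    if np.any(qy > 1.0):
        raise ValueError("parameters inconsistent with fluorescence bounds "
                         "(implied QY > 1)")
    retr[~lit] = 0.0
    # realize yields as fluorescence pairs on a declining Fm' envelope
    fm_prime = cfg.fm_dark * (1.0 + par / 300.0) ** -0.3
    f = fm_prime * (1.0 - qy)
    return SyntheticRLC(config=cfg, seed=seed, par=par, retr=retr, qy=qy,
                        f=f, fm_prime=fm_prime)


# ---------------------------------------------------------------------------
# Stress time-courses
# ---------------------------------------------------------------------------


@dataclass
class SyntheticStressCourse:
    """A templated stress trajectory plus its ground-truth change-points."""

    kind: StressKind
    config: StressConfig
    seed: int
    course: pd.DataFrame  # columns: time_min, fv_fm, alpha, ik
    truth: dict[str, float | None]


#: Relative band within which a trajectory counts as recovered; matches the
#: default of :func:`algafuel.photosynthesis.stress_course_summary`.
RECOVERY_BAND = 0.05


def _dip_and_recover(t, t0, t_min, t1, depth):
    """Piecewise-linear dip to ``1 - depth`` at ``t_min``, recovering so the
    trajectory first re-enters the 5 % band of its initial value exactly at
    ``t1``."""
    down = np.clip((t - t0) / (t_min - t0), 0.0, 1.0)
    up = np.clip((t - t_min) / (t1 - t_min), 0.0, 1.0)
    return np.where(
        t <= t_min,
        1.0 - depth * down,
        (1.0 - depth) + (depth - 0.98 * RECOVERY_BAND) * up,
    )


def simulate_stress_course(
    cfg: StressConfig, kind: StressKind, seed: int = 0
) -> SyntheticStressCourse:
    """Generate a 4-h stress trajectory of Fv/Fm, alpha and Ik.

    Templates (relative to the initial values):

    * ``heat38`` — Fv/Fm dips to a minimum at ``dip_time_min`` and recovers
      to its initial band at ``recovery_time_min``; Ik declines from
      125 min on.
    * ``cold10`` — alpha declines steadily to a minimum at
      ``cold_min_time_min`` then rebounds; Fv/Fm sags mildly.
    * ``highlight1600`` — Fv/Fm drops sharply within the first 5 min and
      alpha from 35 min on; no recovery within the exposure.
    """
    if kind not in ("heat38", "cold10", "highlight1600"):
        raise ValueError(f"unknown stress kind {kind!r}")
    rng = np.random.default_rng(seed)
    t = np.arange(0.0, cfg.duration_min + cfg.step_min / 2, cfg.step_min)
    ones = np.ones_like(t)
    truth: dict[str, float | None]
    if kind == "heat38":
        fv_fm = _dip_and_recover(t, 10.0, cfg.dip_time_min,
                                 cfg.recovery_time_min, 0.35)
        alpha = _dip_and_recover(t, 10.0, cfg.dip_time_min,
                                 cfg.recovery_time_min, 0.15)
        ik = np.where(t < 125.0, 1.0, 1.0 - 0.4 * (t - 125.0) / (t[-1] - 125.0))
        truth = {"fv_fm_min_time": cfg.dip_time_min,
                 "fv_fm_recovery_time": cfg.recovery_time_min}
    elif kind == "cold10":
        t_min = cfg.cold_min_time_min
        alpha = np.where(
            t <= t_min,
            1.0 - 0.40 * t / t_min,  # 0.15 -> 0.09 is a 40 % decline
            0.60 + 0.30 * (t - t_min) / max(t[-1] - t_min, cfg.step_min),
        )
        fv_fm = 1.0 - 0.10 * t / t[-1]
        ik = 1.0 + 0.15 * np.sin(2.0 * math.pi * t / t[-1])
        truth = {"alpha_min_time": t_min, "alpha_recovery_time": None}
    else:  # highlight1600
        fv_fm = np.where(t < 5.0, 1.0, 0.55 - 0.05 * t / t[-1])
        alpha = np.where(t < 35.0, 1.0, 0.60 - 0.10 * (t - 35.0) / t[-1])
        ik = ones * (1.0 - 0.05 * t / t[-1])
        truth = {"fv_fm_drop_by": 5.0, "fv_fm_recovery_time": None}
    frame = pd.DataFrame({
        "time_min": t,
        "fv_fm": cfg.fv_fm_initial * fv_fm,
        "alpha": cfg.alpha_initial * alpha,
        "ik": cfg.ik_initial * ik,
    })
    if cfg.noise_sd > 0:
        for col, scale in (("fv_fm", cfg.fv_fm_initial),
                           ("alpha", cfg.alpha_initial),
                           ("ik", cfg.ik_initial)):
            frame[col] += cfg.noise_sd * scale * rng.standard_normal(len(t))
    return SyntheticStressCourse(kind=kind, config=cfg, seed=seed,
                                 course=frame, truth=truth)


# ---------------------------------------------------------------------------
# FAME profiles
# ---------------------------------------------------------------------------

#: The fatty-acid alphabet of the packaged reference composition table.
REFERENCE_FATTY_ACIDS: tuple[FattyAcid, ...] = tuple(
    parse_fatty_acid(name)
    for name in (
        "14:0", "16:0", "16:1n7", "16:2n4", "16:3n4", "16:4n1",
        "18:0", "18:1n9", "18:1n7", "18:2n6", "18:3n3", "18:4n3",
        "20:4n6", "20:1n9", "22:5n3",
    )
)


@dataclass
class SyntheticProfile:
    """A generated FAME profile plus its ground truth."""

    config: FameConfig
    seed: int
    profile: FameProfile
    truth: dict[str, float]  # includes the generating ACU and total


def simulate_fame_profile(
    cfg: FameConfig, seed: int = 0, strain: str = "synthetic",
    dilution_rate: float = 0.2,
) -> SyntheticProfile:
    """Draw a compositional FAME profile over the reference alphabet.

    Fractions are a Dirichlet draw with mean set by the SFA/MUFA/PUFA
    mixture weights (species within a class share its weight equally,
    left-over weight spreads uniformly), scaled to a total drawn from
    ``total_range``.  The realized ACU and total are stored as ground
    truth.
    """
    rng = np.random.default_rng(seed)
    fas = REFERENCE_FATTY_ACIDS
    classes = np.array([min(fa.double_bonds, 2) for fa in fas])
    w_sfa, w_mufa, w_pufa = cfg.class_weights
    leftover = max(1.0 - (w_sfa + w_mufa + w_pufa), 0.0)
    mean = np.empty(len(fas))
    for cls, weight in enumerate((w_sfa, w_mufa, w_pufa)):
        members = classes == cls
        mean[members] = weight / members.sum()
    mean += leftover / len(fas)
    mean /= mean.sum()
    fractions = rng.dirichlet(cfg.concentration * mean)
    total = rng.uniform(*cfg.total_range)
    pct = fractions * total
    profile = FameProfile(
        strain=strain,
        dilution_rate=dilution_rate,
        fractions={fa: float(p) for fa, p in zip(fas, pct) if p > 0},
        provenance=f"synthetic (seed={seed})",
    )
    acu = float(sum(fa.double_bonds * p for fa, p in zip(fas, pct)) / 100.0)
    return SyntheticProfile(
        config=cfg, seed=seed, profile=profile,
        truth={"acu": acu, "total": float(total)},
    )
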