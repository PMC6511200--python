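"""PAM chlorophyll-fluorescence parameters and rapid-light-curve fitting.

Fluorescence quantities
-----------------------
From a dark-adapted sample the minimal and maximal fluorescence F0 and Fm
give the maximum quantum efficiency of photosystem II,

    Fv/Fm = (Fm - F0) / Fm.

Under actinic light, the steady-state fluorescence F and the saturating-
pulse maximum Fm' give the effective quantum yield QY = (Fm' - F)/Fm', and
the relative electron transport rate

    rETR = PAR * a * QY * 0.5,

where 0.5 partitions absorbed photons between the two photosystems and
``a`` is the absorptance factor (1.0 by default; 0.84 is a common
instrument convention — the choice rescales rETRmax and Ik but not ratios
of alpha).

Rapid light curves
------------------
An RLC steps the actinic irradiance E through a ladder and records rETR(E),
which shows light-limited, saturated and photoinhibited regions.  The curve
is fitted with the Platt photoinhibition model

    rETR(E) = Ps * (1 - exp(-alpha E / Ps)) * exp(-beta E / Ps),

whose maximum is rETRmax = Ps * [alpha/(alpha+beta)] * [beta/(alpha+beta)]^(beta/alpha)
for beta > 0 (and Ps for beta = 0).  The light-saturation irradiance is
Ik = rETRmax / alpha.  The maximal quantum yield MQY is taken from the
measured yield of the first (lowest-light) RLC step, not from the fit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

__all__ = [
    "FluorescenceState",
    "QuenchingResult",
    "RapidLightCurve",
    "PlattFit",
    "max_quantum_yield",
    "effective_qy",
    "quenching",
    "rel_etr",
    "platt_retr",
    "platt_retr_max",
    "fit_platt",
    "StressSummary",
    "ParameterCourse",
    "stress_course_summary",
]


@dataclass(frozen=True)
class FluorescenceState:
    """One complete set of fluorescence levels (arbitrary units)."""

    f0: float
    fm: float
    f: float
    fm_prime: float
    f0_prime: float | None = None

    def __post_init__(self) -> None:
        if not self.fm > self.f0 > 0:
            raise ValueError("need Fm > F0 > 0")
        if not self.fm_prime >= self.f > 0:
            raise ValueError("need Fm' >= F > 0")
        if self.fm < self.fm_prime:
            raise ValueError("need Fm >= Fm'")


def max_quantum_yield(f0: float, fm: float) -> float:
    """Fv/Fm = (Fm - F0)/Fm, the dark-adapted maximum PSII efficiency."""
    if f0 <= 0 or fm <= f0:
        raise ValueError("need Fm > F0 > 0 (nonzero variable fluorescence)")
    return (fm - f0) / fm


def effective_qy(f: float, fm_prime: float) -> float:
    """QY = (Fm' - F)/Fm', the effective PSII yield under actinic light."""
    if f <= 0 or fm_prime < f:
        raise ValueError("need Fm' >= F > 0")
    return (fm_prime - f) / fm_prime


@dataclass(frozen=True)
class QuenchingResult:
    qp: float
    npq: float
    f0_prime_estimated: bool


def quenching(
    f0: float,
    fm: float,
    f: float,
    fm_prime: float,
    f0_prime: float | None = None,
) -> QuenchingResult:
    """Photochemical (qP) and non-photochemical (NPQ) quenching.

    NPQ = (Fm - Fm')/Fm' and qP = (Fm' - F)/(Fm' - F0').  When F0' was not
    measured it is estimated with the Oxborough-Baker relation
    F0' = F0 / (Fv/Fm + F0/Fm'); the result is flagged as estimated.
    """
    state = FluorescenceState(f0=f0, fm=fm, f=f, fm_prime=fm_prime,
                              f0_prime=f0_prime)
    estimated = f0_prime is None
    if estimated:
        f0_prime = f0 / (max_quantum_yield(f0, fm) + f0 / fm_prime)
    if fm_prime <= f0_prime:
        raise ValueError("need Fm' > F0'")
    npq = (fm - fm_prime) / fm_prime
    qp = (fm_prime - f) / (fm_prime - f0_prime)
    return QuenchingResult(qp=qp, npq=npq, f0_prime_estimated=estimated)


def rel_etr(
    par: float, qy: float, absorptance_factor: float = 1.0,
    psii_fraction: float = 0.5,
) -> float:
    """rETR = PAR * absorptance * QY * 0.5."""
    if par < 0:
        raise ValueError("PAR must be >= 0")
    if not 0.0 <= qy <= 1.0:
        raise ValueError("QY must lie in [0, 1]")
    return par * absorptance_factor * qy * psii_fraction


@dataclass
class RapidLightCurve:
    """An ordered rapid light curve: (PAR, QY, rETR) per step.

    Steps must have strictly increasing PAR starting from the dark (or
    lowest-light) level.  Constructed either directly from yields or, via
    :meth:`from_fluorescence`, from raw (F, Fm') pairs — a PAR = 0 row then
    carries the dark-adapted (F0, Fm) pair and its QY is Fv/Fm.
    """

    par: np.ndarray
    qy: np.ndarray
    absorptance_factor: float = 1.0
    psii_fraction: float = 0.5

    def __post_init__(self) -> None:
        self.par = np.asarray(self.par, dtype=float)
        self.qy = np.asarray(self.qy, dtype=float)
        if self.par.shape != self.qy.shape:
            raise ValueError("PAR and QY must have the same length")
        if np.any(self.par < 0) or np.any(np.diff(self.par) <= 0):
            raise ValueError("PAR must be >= 0 and strictly increasing")
        if np.any((self.qy < 0) | (self.qy > 1)):
            raise ValueError("QY must lie in [0, 1]")

    @classmethod
    def from_fluorescence(
        cls,
        par: Sequence[float],
        f: Sequence[float],
        fm_prime: Sequence[float],
        absorptance_factor: float = 1.0,
    ) -> "RapidLightCurve":
        qy = [effective_qy(fi, fmi) for fi, fmi in zip(f, fm_prime)]
        return cls(par=np.asarray(par, dtype=float), qy=np.asarray(qy),
                   absorptance_factor=absorptance_factor)

    @property
    def retr(self) -> np.ndarray:
        return (self.par * self.absorptance_factor * self.qy
                * self.psii_fraction)

    @property
    def mqy(self) -> float:
        """Maximal quantum yield: the measured yield of the first step."""
        return float(self.qy[0])

    def __len__(self) -> int:
        return len(self.par)


def platt_retr(par, alpha: float, ps: float, beta: float):
    """The Platt photoinhibition curve rETR(E)."""
    e = np.asarray(par, dtype=float)
    return ps * (1.0 - np.exp(-alpha * e / ps)) * np.exp(-beta * e / ps)


def platt_retr_max(alpha: float, ps: float, beta: float) -> float:
    """Peak rETR of the Platt curve (equals Ps when beta = 0)."""
    if beta == 0:
        return ps
    s = alpha + beta
    return ps * (alpha / s) * (beta / s) ** (beta / alpha)


@dataclass(frozen=True)
class PlattFit:
    """Fitted Platt parameters and the quantities derived from them.

    ``ik * alpha == retr_max`` holds exactly by construction.
    """

    alpha: float
    beta: float
    ps: float
    retr_max: float
    ik: float
    mqy: float
    rss: float
    converged: bool
    n_steps: int
    message: str = ""


def fit_platt(rlc: RapidLightCurve) -> PlattFit:
    """Fit the Platt photoinhibition model to a rapid light curve.

    Bounded nonlinear least squares on (alpha, Ps, beta) with alpha, Ps > 0
    and beta >= 0.  Initial guesses: alpha from the slope of the first two
    nonzero-PAR points, Ps from the maximum observed rETR, beta = 0.01 *
    alpha0.  Non-convergence is reported through the ``converged`` flag and
    optimizer message, not as an exception.  Fewer than 5 steps is an error.
    """
    if len(rlc) < 5:
        raise ValueError("need at least 5 RLC steps to fit the Platt model")
    par = rlc.par
    retr = rlc.retr
    nonzero = np.nonzero(par)[0]
    if len(nonzero) < 2:
        raise ValueError("need at least two nonzero-PAR steps")
    i, j = nonzero[0], nonzero[1]
    alpha0 = max((retr[j] - retr[i]) / (par[j] - par[i]), 1e-6)
    # fall back on the secant through the first lit point when the curve is
    # already bending between the first two lit steps
    alpha0 = max(alpha0, retr[i] / par[i] if par[i] > 0 else 0.0)
    ps0 = max(retr.max(), 1e-6)
    beta0 = 0.01 * alpha0

    def residuals(theta):
        alpha, ps, beta = theta
        return platt_retr(par, alpha, ps, beta) - retr

    tiny = 1e-12
    result = least_squares(
        residuals,
        x0=[alpha0, ps0, beta0],
        bounds=([tiny, tiny, 0.0], [np.inf, np.inf, np.inf]),
        method="trf",
        xtol=1e-12,
        ftol=1e-12,
        gtol=1e-12,
        max_nfev=2000,
    )
    alpha, ps, beta = result.x
    retr_max = platt_retr_max(alpha, ps, beta)
    return PlattFit(
        alpha=float(alpha),
        beta=float(beta),
        ps=float(ps),
        retr_max=float(retr_max),
        ik=float(retr_max / alpha),
        mqy=rlc.mqy,
        rss=float(2.0 * result.cost),
        converged=bool(result.success),
        n_steps=len(rlc),
        message=result.message,
    )


# ---------------------------------------------------------------------------
# Stress time-courses
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ParameterCourse:
    """Trajectory summary of one photosynthetic parameter under stress."""

    times: tuple[float, ...]
    values: tuple[float, ...]
    initial: float
    time_of_min: float | None
    recovery_time: float | None


@dataclass(frozen=True)
class StressSummary:
    courses: dict[str, ParameterCourse]


def _summarize_course(
    times: np.ndarray, values: np.ndarray, band: float
) -> ParameterCourse:
    initial = float(values[0])
    within = np.abs(values - initial) <= band * abs(initial)
    if within.all():
        # flat trajectory: no change-point, nothing to recover from
        return ParameterCourse(tuple(times), tuple(values), initial, None, None)
    imin = int(np.argmin(values))
    recovery = None
    for t, v, ok in zip(times[imin + 1:], values[imin + 1:], within[imin + 1:]):
        if ok:
            recovery = float(t)
            break
    return ParameterCourse(
        tuple(times), tuple(values), initial,
        time_of_min=float(times[imin]), recovery_time=recovery,
    )


def stress_course_summary(
    course: pd.DataFrame, time_column: str = "time_min", band: float = 0.05
) -> StressSummary:
    """Summarize per-parameter stress trajectories.

    ``course`` holds a time column plus one column per photosynthetic
    parameter (e.g. ``fv_fm``, ``alpha``, ``ik``, ``retr_max``).  For each
    parameter the summary reports the time of its minimum and the recovery
    time — the first time after the minimum at which the value returns to
    within ``band`` (default 5 %) of its initial value.  A trajectory that
    never leaves the band has no change-point.
    """
    if time_column not in course.columns:
        raise ValueError(f"missing time column {time_column!r}")
    if len(course) < 3:
        raise ValueError("need at least 3 time points")
    times = course[time_column].to_numpy(dtype=float)
    if np.any(np.diff(times) <= 0):
        raise ValueError("times must be strictly increasing")
    courses = {
        name: _summarize_course(times, course[name].to_numpy(dtype=float), band)
        for name in course.columns
        if name != time_column
    }
    return StressSummary(courses=courses)
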