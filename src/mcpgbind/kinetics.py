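"""1:1 Langmuir kinetic analysis of label-free binding sensorgrams.

A sensorgram records surface binding signal while protein at concentration
C flows over immobilized DNA (association) and after a buffer wash
(dissociation).  Under the 1:1 Langmuir model,

    association:   S(t) = S_eq * (1 - exp(-(k_on*C + k_off) * t)),
                   S_eq = S_max * C / (C + K_D)
    dissociation:  S(t_w + t) = S_0 * exp(-k_off * t)

with K_D = k_off / k_on.  Fitting is two-stage for identifiability: k_off
comes from the wash phase alone, then k_on and S_max from the association
phase with k_off held fixed.  Affinities are reported per concentration and
averaged over the (typically two) concentrations measured.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

logger = logging.getLogger(__name__)


@dataclass
class Sensorgram:
    """One binding/dissociation time course at a single protein concentration."""

    times: np.ndarray  # seconds, strictly increasing
    signals: np.ndarray  # arbitrary reflectivity units
    concentration: float  # molar
    t_wash: float  # dissociation onset, seconds

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.signals = np.asarray(self.signals, dtype=float)
        if self.times.shape != self.signals.shape:
            raise ValueError("times and signals differ in length")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if not self.times[0] <= self.t_wash <= self.times[-1]:
            raise ValueError("t_wash outside the recorded time range")
        if self.association_mask().sum() < 5 or self.dissociation_mask().sum() < 5:
            raise ValueError("need >= 5 points in each phase")

    def association_mask(self) -> np.ndarray:
        return self.times < self.t_wash

    def dissociation_mask(self) -> np.ndarray:
        return self.times >= self.t_wash


@dataclass
class KineticFit:
    """Fitted 1:1 kinetics for one sensorgram."""

    k_on: float  # 1/(M*s)
    k_off: float  # 1/s
    s_max: float  # signal units
    residual_rms: float
    concentration: float
    converged: bool = True
    reason: str | None = None

    @property
    def k_d(self) -> float:
        return self.k_off / self.k_on


@dataclass
class AveragedKD:
    """K_D averaged over per-concentration fits."""

    k_d: float
    fits: list[KineticFit] = field(default_factory=list)
    discordance: float = 1.0  # max/min ratio of per-concentration K_D
    single_concentration: bool = False
    discordant: bool = False


class FitFailure(RuntimeError):
    """Raised internally; surfaced as a non-converged KineticFit."""


def model_association(t, k_on: float, k_off: float, C: float,
                      s_max: float) -> np.ndarray:
    """Association-phase signal of the 1:1 Langmuir model."""
    if k_on < 0 or k_off < 0:
        raise ValueError("rate constants must be non-negative")
    t = np.asarray(t, dtype=float)
    k_obs = k_on * C + k_off
    s_eq = s_max * k_on * C / k_obs if k_obs > 0 else 0.0
    return s_eq * (1.0 - np.exp(-k_obs * t))


def model_dissociation(t, s_0: float, k_off: float) -> np.ndarray:
    """Exponential decay after the wash: S = S_0 * exp(-k_off * t)."""
    if k_off < 0:
        raise ValueError("k_off must be non-negative")
    return s_0 * np.exp(-k_off * np.asarray(t, dtype=float))


def _fit_dissociation(t: np.ndarray, s: np.ndarray) -> tuple[float, float]:
    """(s_0, k_off) by NLS, initialized from log-linear regression."""
    pos = s > 0
    if pos.sum() >= 2:
        slope, intercept = np.polyfit(t[pos], np.log(s[pos]), 1)
        k0 = max(-slope, 1e-8)
        s0 = float(np.exp(intercept))
    else:
        k0, s0 = 1e-3, max(float(s[0]), 1e-12)
    popt, _ = curve_fit(model_dissociation, t, s, p0=[s0, k0],
                        bounds=([0, 0], [np.inf, np.inf]), maxfev=10000)
    return float(popt[0]), float(popt[1])


def fit_sensorgram(data: Sensorgram, min_signal: float = 1e-9,
                   joint: bool = False) -> KineticFit:
    """Fit a sensorgram with the 1:1 model; never returns a silent number.

    Two-stage by default (k_off from the wash phase, then k_on and S_max
    from the association phase with k_off fixed); ``joint=True`` refines
    all three parameters simultaneously afterwards.  A flat trace (no
    binding) yields a non-converged fit with a diagnostic reason.
    """
    am, dm = data.association_mask(), data.dissociation_mask()
    t_a, s_a = data.times[am], data.signals[am]
    t_d = data.times[dm] - data.t_wash
    s_d = data.signals[dm]
    C = data.concentration

    if np.ptp(data.signals) <= min_signal or np.max(s_a) <= min_signal:
        return KineticFit(k_on=np.nan, k_off=np.nan, s_max=np.nan,
                          residual_rms=np.nan, concentration=C,
                          converged=False, reason="no observed binding signal")
    try:
        _, k_off = _fit_dissociation(t_d, s_d)

        plateau = float(np.median(s_a[-max(3, len(s_a) // 10):]))
        s_max0 = max(2.0 * plateau, 1e-9)
        # crude k_obs from time to half-plateau
        half_idx = np.searchsorted(s_a, plateau / 2.0)
        t_half = t_a[min(half_idx, len(t_a) - 1)] or t_a[1]
        k_on0 = max((np.log(2.0) / t_half - k_off) / C, 1e-3)

        def assoc(t, k_on, s_max):
            return model_association(t, k_on, k_off, C, s_max)

        popt, _ = curve_fit(assoc, t_a, s_a, p0=[k_on0, s_max0],
                            bounds=([0, 0], [np.inf, np.inf]), maxfev=10000)
        k_on, s_max = float(popt[0]), float(popt[1])

        if joint:
            def full(t, k_on, k_off_, s_max):
                out = np.empty_like(t)
                a = t < data.t_wash
                out[a] = model_association(t[a], k_on, k_off_, C, s_max)
                s_w = model_association(data.t_wash, k_on, k_off_, C, s_max)
                out[~a] = model_dissociation(t[~a] - data.t_wash, s_w, k_off_)
                return out

            popt, _ = curve_fit(full, data.times, data.signals,
                                p0=[k_on, k_off, s_max],
                                bounds=([0, 0, 0], [np.inf] * 3), maxfev=20000)
            k_on, k_off, s_max = map(float, popt)

        pred = np.concatenate([
            model_association(t_a, k_on, k_off, C, s_max),
            model_dissociation(
                t_d, model_association(data.t_wash, k_on, k_off, C, s_max),
                k_off),
        ])
        rms = float(np.sqrt(np.mean((np.concatenate([s_a, s_d]) - pred) ** 2)))
    except (RuntimeError, ValueError) as exc:
        return KineticFit(k_on=np.nan, k_off=np.nan, s_max=np.nan,
                          residual_rms=np.nan, concentration=C,
                          converged=False, reason=f"fit failed: {exc}")
    if k_on <= 0:
        return KineticFit(k_on=k_on, k_off=k_off, s_max=s_max,
                          residual_rms=rms, concentration=C,
                          converged=False, reason="non-positive k_on")
    return KineticFit(k_on=k_on, k_off=k_off, s_max=s_max, residual_rms=rms,
                      concentration=C)


def average_kd(fits: list[KineticFit],
               discordance_limit: float = 3.0) -> AveragedKD:
    """Arithmetic-mean K_D over converged per-concentration fits.

    Flags the result when only one fit converged or when the per-
    concentration estimates disagree by more than ``discordance_limit``x.
    """
    good = [f for f in fits if f.converged]
    if not good:
        raise FitFailure("no converged fits to average")
    kds = [f.k_d for f in good]
    discordance = max(kds) / min(kds) if min(kds) > 0 else np.inf
    if discordance > discordance_limit:
        logger.warning("discordant K_D estimates (ratio %.2f)", discordance)
    return AveragedKD(
        k_d=float(np.mean(kds)),
        fits=good,
        discordance=float(discordance),
        single_concentration=len(good) < len(fits) or len(good) == 1,
        discordant=discordance > discordance_limit,
    )
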