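"""Synthetic heart-rate series emulating a four-phase outdoor running protocol.

The generator mimics a wearable 1 Hz HR stream recorded on a run with an
initial flat phase, an uphill (~6.8% slope), a downhill (~7.2% slope) and a
final flat phase.  Each phase drives a target HR plateau; the physiological
onset delay is modelled as a first-order exponential response with time
constant ``tau_s`` (the body does not adapt to load instantly).  Optional
periodic components and one of three serially dependent noise models are
added, and the result is clipped to the physiological amplitude range
(25-240 bpm by default).

The phase plateau levels are documented generator constants chosen to look
like a recreational runner; they are not estimates of any real subject.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .copulas import make_copula
from .series import TimeSeries

__all__ = [
    "Phase",
    "PeriodicComponent",
    "NoiseModel",
    "ProtocolProfile",
    "default_running_profile",
    "generate_hr",
]


@dataclass(frozen=True)
class Phase:
    name: str
    duration_s: float
    plateau_bpm: float


@dataclass(frozen=True)
class PeriodicComponent:
    amplitude_bpm: float
    period_s: float
    phase_rad: float = 0.0


@dataclass(frozen=True)
class NoiseModel:
    """Residual noise model: white, AR(1), or copula-chained.

    ``sigma`` is the stationary (marginal) standard deviation in bpm for all
    three kinds; for ``ar1`` the innovation sd is ``sigma * sqrt(1 - phi^2)``.
    The ``copula`` kind chains draws through the conditional CDF of the given
    Archimedean family and maps them to bpm through a normal marginal.
    """

    kind: str = "ar1"  # white | ar1 | copula
    sigma: float = 2.0
    phi: float = 0.8
    family: str = "clayton"
    theta: float = 2.0

    def __post_init__(self):
        if self.kind not in ("white", "ar1", "copula"):
            raise ValueError(f"unknown noise kind {self.kind!r}")
        if self.sigma < 0:
            raise ValueError(f"sigma must be >= 0, got {self.sigma}")
        if self.kind == "ar1" and not (-1.0 < self.phi < 1.0):
            raise ValueError(f"ar1 phi must lie in (-1, 1), got {self.phi}")


@dataclass(frozen=True)
class ProtocolProfile:
    """Full description of a synthetic running session."""

    phases: tuple
    tau_s: float = 30.0
    periodic: tuple = ()
    noise: NoiseModel = field(default_factory=NoiseModel)
    amplitude_bounds: tuple = (25.0, 240.0)
    sampling_interval: float = 1.0

    def __post_init__(self):
        problems = []
        if not self.phases:
            problems.append("profile needs at least one phase")
        for ph in self.phases:
            if ph.duration_s <= 0:
                problems.append(f"phase {ph.name!r} has non-positive duration")
        if self.tau_s <= 0:
            problems.append("tau_s must be > 0")
        lo, hi = self.amplitude_bounds
        if not lo < hi:
            problems.append("amplitude_bounds must be ordered (low, high)")
        if self.sampling_interval <= 0:
            problems.append("sampling_interval must be > 0")
        for pc in self.periodic:
            if pc.period_s <= 0:
                problems.append("periodic component period must be > 0")
        if problems:
            raise ValueError("invalid profile: " + "; ".join(problems))

    @property
    def total_duration_s(self) -> float:
        return float(sum(ph.duration_s for ph in self.phases))


def default_running_profile(
    noise: NoiseModel | None = None, periodic: tuple | None = None
) -> ProtocolProfile:
    """The default four-phase running session.

    Phase boundaries fall at 465 s, 1112 s and 1547 s with a total of
    2634 s (i.e. 0:07:45 / 0:18:32 / 0:25:47 / 0:43:54), matching the
    reference running route; plateau levels are plausible defaults
    (rest ~90 bpm, uphill peak 165, downhill 150, final flat 155).
    """
    phases = (
        Phase("initial_flat", 465.0, 90.0),
        Phase("uphill", 1112.0 - 465.0, 165.0),
        Phase("downhill", 1547.0 - 1112.0, 150.0),
        Phase("final_flat", 2634.0 - 1547.0, 155.0),
    )
    if periodic is None:
        periodic = (PeriodicComponent(amplitude_bpm=3.0, period_s=300.0),)
    return ProtocolProfile(
        phases=phases,
        periodic=periodic,
        noise=noise if noise is not None else NoiseModel(),
    )


def _smoothed_trend(profile: ProtocolProfile, n: int) -> np.ndarray:
    dt = profile.sampling_interval
    t = np.arange(n) * dt
    edges = np.cumsum([ph.duration_s for ph in profile.phases])
    targets = np.array([ph.plateau_bpm for ph in profile.phases])
    target_t = targets[np.searchsorted(edges, t, side="right").clip(max=len(targets) - 1)]
    # first-order exponential response toward the current target plateau
    alpha = -np.expm1(-dt / profile.tau_s)
    trend = np.empty(n)
    trend[0] = targets[0]
    for i in range(1, n):
        trend[i] = trend[i - 1] + alpha * (target_t[i] - trend[i - 1])
    for pc in profile.periodic:
        trend += pc.amplitude_bpm * np.sin(2.0 * np.pi * t / pc.period_s + pc.phase_rad)
    return trend


def _noise(profile: ProtocolProfile, n: int, rng: np.random.Generator) -> np.ndarray:
    nm = profile.noise
    if nm.sigma == 0.0:
        return np.zeros(n)
    if nm.kind == "white":
        return rng.normal(0.0, nm.sigma, n)
    if nm.kind == "ar1":
        innov_sd = nm.sigma * np.sqrt(1.0 - nm.phi**2)
        eps = rng.normal(0.0, innov_sd, n)
        out = np.empty(n)
        out[0] = rng.normal(0.0, nm.sigma)
        for i in range(1, n):
            out[i] = nm.phi * out[i - 1] + eps[i]
        return out
    # copula chain: u_t | u_{t-1} via the conditional CDF, normal marginal
    cop = make_copula(nm.family, nm.theta)
    u = np.empty(n)
    u[0] = rng.random()
    for i in range(1, n):
        u[i] = float(cop.conditional_sample(u[i - 1], 1, rng)[0])
    return stats.norm.ppf(u) * nm.sigma


def generate_hr(profile: ProtocolProfile | None = None, seed: int = 0) -> TimeSeries:
    """Generate one synthetic HR session: smoothed phase trend + periodic
    components + serially dependent noise, clipped to the amplitude bounds.

    Deterministic for a fixed seed; different seeds share the identical
    trend and differ only in the noise.
    """
    if profile is None:
        profile = default_running_profile()
    n = int(round(profile.total_duration_s / profile.sampling_interval))
    rng = np.random.default_rng(seed)
    values = _smoothed_trend(profile, n) + _noise(profile, n, rng)
    values = np.clip(values, *profile.amplitude_bounds)
    return TimeSeries(values, sampling_interval=profile.sampling_interval)
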