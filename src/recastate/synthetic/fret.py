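"""Synthetic two-state smFRET trajectories and titration datasets.

Emulates an immobilized DNA substrate whose FRET efficiency reports RecA
filament occupancy: a continuous-time two-state (bound/unbound) process
with Gaussian emission around the bound (~0.20) and unbound (~0.43) state
means, heterogeneous unbinding (a fast and a slow off-rate mixed per
binding event), donor-to-acceptor crosstalk, and intensity noise on the
summed signal.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from ..fret import FretTrajectory, compute_fret

__all__ = [
    "TwoStateKineticModel",
    "TrueSegment",
    "SimulatedTrajectory",
    "simulate_fret_trajectory",
    "sample_biexponential_dwells",
    "simulate_titration",
    "TitrationData",
]

BOUND, UNBOUND = "bound", "unbound"


@dataclass(frozen=True)
class TwoStateKineticModel:
    """Generative model of a two-state FRET trajectory.

    Parameters
    ----------
    k_bind : float
        Pseudo-first-order binding rate (s⁻¹).
    k_off_fast, k_off_slow : float
        Unbinding rates (s⁻¹) of the two dissociation classes; defaults
        0.23 and 0.044 s⁻¹.
    f_slow : float
        Probability that a binding event belongs to the slow-unbinding
        class (static per-event mixture).
    fret_bound_mean, fret_bound_sd : float
        Observed FRET distribution of the bound state (0.20 ± 0.07).
    fret_unbound_mean, fret_unbound_sd : float
        Observed FRET distribution of the unbound state (0.43 ± 0.07).
    total_intensity : float
        Mean summed donor+acceptor counts per frame (au).
    crosstalk : float
        Donor→acceptor leakage coefficient in [0, 1).
    intensity_noise : float
        Shot-like noise scale: the summed intensity is drawn as
        N(total, intensity_noise * sqrt(total)). Noise on the sum leaves
        the acceptor/total ratio — hence the FRET value — untouched, so
        the configured state sds describe the *observed* FRET widths.
    frame_interval : float
        Seconds per camera frame.
    seed : int
        RNG seed used when no generator is passed explicitly.
    """

    k_bind: float = 0.2
    k_off_fast: float = 0.23
    k_off_slow: float = 0.044
    f_slow: float = 0.91
    fret_bound_mean: float = 0.20
    fret_bound_sd: float = 0.07
    fret_unbound_mean: float = 0.43
    fret_unbound_sd: float = 0.07
    total_intensity: float = 400.0
    crosstalk: float = 0.0
    intensity_noise: float = 1.0
    frame_interval: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k_bind < 0 or self.k_off_fast <= 0 or self.k_off_slow <= 0:
            raise ValueError("rates must be positive (k_bind may be 0)")
        if not 0.0 <= self.f_slow <= 1.0:
            raise ValueError("f_slow must be in [0, 1]")
        for m in (self.fret_bound_mean, self.fret_unbound_mean):
            if not 0.0 < m < 1.0:
                raise ValueError("FRET state means must lie in (0, 1)")
        if self.fret_bound_sd <= 0 or self.fret_unbound_sd <= 0:
            raise ValueError("FRET state sds must be positive")
        if not 0.0 <= self.crosstalk < 1.0:
            raise ValueError("crosstalk must be in [0, 1)")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")
        if self.total_intensity <= 0:
            raise ValueError("total_intensity must be positive")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)

    def with_(self, **kwargs) -> "TwoStateKineticModel":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class TrueSegment:
    """Ground-truth continuous-time state episode."""

    state: str
    start: float
    duration: float
    rate_class: str | None  # "fast" | "slow" for bound episodes
    censored: bool


@dataclass
class SimulatedTrajectory:
    """A simulated trajectory plus its generating ground truth."""

    trajectory: FretTrajectory
    segments: list[TrueSegment]
    frame_states: np.ndarray  # per-frame true majority-occupancy state labels


def _gillespie(model: TwoStateKineticModel, duration: float, rng) -> list[TrueSegment]:
    segments: list[TrueSegment] = []
    t = 0.0
    state = UNBOUND  # traces start with the substrate unbound
    while t < duration:
        if state == UNBOUND:
            dwell = rng.exponential(1.0 / model.k_bind) if model.k_bind > 0 else np.inf
            cls = None
        else:
            cls = "slow" if rng.random() < model.f_slow else "fast"
            k = model.k_off_slow if cls == "slow" else model.k_off_fast
            dwell = rng.exponential(1.0 / k)
        end = min(t + dwell, duration)
        segments.append(
            TrueSegment(state, t, end - t, cls, censored=(t + dwell > duration) or t == 0.0)
        )
        t += dwell
        state = BOUND if state == UNBOUND else UNBOUND
    return segments


def simulate_fret_trajectory(
    model: TwoStateKineticModel,
    duration: float,
    rng: np.random.Generator | None = None,
) -> SimulatedTrajectory:
    """Simulate a single-molecule FRET trajectory of the two-state model.

    A continuous-time state sequence is generated by the Gillespie
    algorithm (each bound episode drawn from the fast or slow unbinding
    class with probability ``1 - f_slow`` / ``f_slow``) and discretized at
    the frame interval by majority occupancy, mimicking camera
    integration. Per-frame FRET values are drawn from the occupied
    state's Gaussian; donor and acceptor intensities are reconstructed
    from the drawn efficiency and the (noisy) summed intensity, with
    crosstalk leaking a fraction of the donor signal into the acceptor
    channel.

    Returns the trajectory together with the ground-truth episode list
    and per-frame state labels.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    if duration < 10 * model.frame_interval:
        raise ValueError("duration must cover at least 10 frames")
    if rng is None:
        rng = model.rng()

    segments = _gillespie(model, duration, rng)
    dt = model.frame_interval
    n_frames = int(np.floor(duration / dt))
    edges = np.arange(n_frames + 1) * dt

    # bound occupancy per frame from overlap with bound episodes
    occupancy = np.zeros(n_frames)
    for seg in segments:
        if seg.state != BOUND:
            continue
        lo = np.clip(seg.start, edges[:-1], edges[1:])
        hi = np.clip(seg.start + seg.duration, edges[:-1], edges[1:])
        occupancy += np.maximum(hi - lo, 0.0)
    bound_frame = occupancy >= 0.5 * dt

    means = np.where(bound_frame, model.fret_bound_mean, model.fret_unbound_mean)
    sds = np.where(bound_frame, model.fret_bound_sd, model.fret_unbound_sd)
    efficiency = rng.normal(means, sds)
    total = model.total_intensity + rng.normal(
        0.0, model.intensity_noise * np.sqrt(model.total_intensity), n_frames
    )
    total = np.maximum(total, 1.0)
    donor = (1.0 - efficiency) * total
    acceptor = efficiency * total + model.crosstalk * donor

    traj = compute_fret(
        donor, acceptor, crosstalk=model.crosstalk, frame_interval=dt
    )
    states = np.where(bound_frame, BOUND, UNBOUND)
    return SimulatedTrajectory(traj, segments, states)


def sample_biexponential_dwells(
    n: int,
    k_fast: float = 0.23,
    k_slow: float = 0.044,
    f_slow: float = 0.91,
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """Draw bound dwell times from the two-class unbinding mixture.

    Each event is assigned to the slow class with probability ``f_slow``
    and its duration drawn from the corresponding exponential; the
    survival function of the sample is
    ``(1 - f_slow) e^{-k_fast t} + f_slow e^{-k_slow t}``.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    slow = rng.random(n) < f_slow
    rates = np.where(slow, k_slow, k_fast)
    return rng.exponential(1.0 / rates)


@dataclass
class TitrationData:
    """Per-concentration FRET samples with ground-truth bound labels."""

    concentrations: np.ndarray  # nM
    fret_values: list[np.ndarray]
    bound_labels: list[np.ndarray]
    kd: float
    hill_n: float

    def true_bound_probability(self) -> np.ndarray:
        c, kd, n = self.concentrations, self.kd, self.hill_n
        return np.where(c > 0, c ** n / (c ** n + kd ** n), 0.0)


def simulate_titration(
    kd: float,
    hill_n: float,
    concentrations,
    molecules_per_point,
    model: TwoStateKineticModel | None = None,
    rng: np.random.Generator | int | None = None,
) -> TitrationData:
    """Simulate per-molecule FRET values across a probe titration.

    At concentration ``c`` each molecule is bound with Hill probability
    ``p = c^n / (c^n + K_D^n)`` and its FRET value drawn from the
    corresponding state Gaussian of ``model``.
    """
    if kd <= 0:
        raise ValueError("kd must be positive")
    if hill_n <= 0:
        raise ValueError("hill_n must be positive")
    c = np.asarray(concentrations, dtype=float)
    counts = np.asarray(molecules_per_point, dtype=int)
    if np.any(c < 0):
        raise ValueError("concentrations must be non-negative")
    if np.any(counts <= 0):
        raise ValueError("molecule counts must be positive")
    if c.shape != counts.shape:
        raise ValueError("concentrations and molecule counts must align")
    if model is None:
        model = TwoStateKineticModel()
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(model.seed if rng is None else rng)

    p = np.where(c > 0, c ** hill_n / (c ** hill_n + kd ** hill_n), 0.0)
    values, labels = [], []
    for pi, ni in zip(p, counts):
        bound = rng.random(ni) < pi
        means = np.where(bound, model.fret_bound_mean, model.fret_unbound_mean)
        sds = np.where(bound, model.fret_bound_sd, model.fret_unbound_sd)
        values.append(rng.normal(means, sds))
        labels.append(bound)
    return TitrationData(c, values, labels, kd, hill_n)
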