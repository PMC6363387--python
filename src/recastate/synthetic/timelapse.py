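"""Synthetic time-lapse stacks: SOS-like induction and storage-structure events.

Generates a GFP-channel image stack over a synthetic cell field in which
cytosolic fluorescence follows a logistic SOS-induction-like fold-increase
curve, and polar storage structures dissolve (intensity drops to cytosol
level within one frame) and/or new structures appear at sampled event
times. Ground-truth event times are recorded at frame resolution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from .cellfield import CellField, CellFieldConfig, SimStructure, simulate_cell_field

__all__ = [
    "InductionCurve",
    "EventTimeDistribution",
    "TimelapseConfig",
    "TimelapseResult",
    "simulate_timelapse",
]


@dataclass(frozen=True)
class InductionCurve:
    """Logistic fold-increase curve ``FI(t) = baseline + amplitude * s(t)``
    with ``s`` a logistic sigmoid of midpoint ``t_mid_min`` and width
    ``width_min``. ``amplitude = 0`` gives a flat curve at baseline.
    """

    baseline: float = 1.0
    amplitude: float = 1.0
    t_mid_min: float = 60.0
    width_min: float = 15.0

    def __call__(self, t_min) -> np.ndarray:
        t = np.asarray(t_min, dtype=float)
        return self.baseline + self.amplitude / (
            1.0 + np.exp(-(t - self.t_mid_min) / self.width_min)
        )

    def peak(self, t_max_min: float) -> float:
        return float(self(t_max_min))


@dataclass(frozen=True)
class EventTimeDistribution:
    """Parametric distribution of event times in minutes.

    ``kind="lognormal"`` draws lognormal times with the given median and
    log-sd; ``kind="fixed"`` returns the median for every event.
    """

    median_min: float = 45.0
    sigma_log: float = 0.5
    kind: str = "lognormal"

    def __post_init__(self) -> None:
        if self.median_min < 0:
            raise ValueError("median must be non-negative")
        if self.kind not in ("lognormal", "fixed"):
            raise ValueError(f"unknown distribution kind {self.kind!r}")

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        if self.kind == "fixed":
            return np.full(n, self.median_min)
        return self.median_min * np.exp(rng.normal(0.0, self.sigma_log, n))


@dataclass(frozen=True)
class TimelapseConfig:
    """Time-lapse generation parameters (5-min frames over 3 h by default)."""

    n_frames: int = 37
    frame_interval_min: float = 5.0
    induction_curve: InductionCurve = InductionCurve()
    dissolution_time_distribution: EventTimeDistribution = EventTimeDistribution(45.0)
    appearance_time_distribution: EventTimeDistribution = EventTimeDistribution(
        90.0, 0.3
    )
    dissolving_fraction: float = 0.56
    appearance_probability: float = 0.9
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_frames < 2:
            raise ValueError("need at least 2 frames")
        if self.frame_interval_min <= 0:
            raise ValueError("frame interval must be positive")
        if not 0.0 <= self.dissolving_fraction <= 1.0:
            raise ValueError("dissolving_fraction must be in [0, 1]")

    @property
    def times_min(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.frame_interval_min


@dataclass
class TimelapseResult:
    """Rendered stack plus per-structure ground-truth events."""

    stack: np.ndarray  # (T, Y, X) GFP channel
    field: CellField
    events: pd.DataFrame  # structure_id, cell_id, kind, event, event_time_min, event_frame
    config: TimelapseConfig
    structures: list[SimStructure]


def _quantize_frame(t_min: float, dt: float, n_frames: int) -> int:
    """First frame index at or after the event time."""
    return int(min(np.ceil(t_min / dt - 1e-9), n_frames))


def simulate_timelapse(
    config: TimelapseConfig,
    field_config: CellFieldConfig,
    rng: np.random.Generator | None = None,
) -> TimelapseResult:
    """Render a GFP-channel time-lapse with structure dissolution/appearance.

    Structures present in the base field dissolve with probability
    ``dissolving_fraction`` at a time drawn from the dissolution
    distribution (their intensity drops to the cytosol level at the event
    frame); each cell additionally gains a new structure at the opposite
    pole with probability ``appearance_probability`` at a time drawn from
    the appearance distribution. Cytosolic intensity follows
    ``cytosol_level * induction_curve(t)``.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    field = simulate_cell_field(field_config, rng)
    shape = field.shape
    dt = config.frame_interval_min
    n = config.n_frames

    cells_by_id = {c.cell_id: c for c in field.cells}
    records = []
    render: list[tuple[SimStructure, int, int]] = []  # structure, first, last frame
    all_structures = list(field.structures)
    next_sid = max((s.structure_id for s in all_structures), default=-1) + 1

    for s in field.structures:
        if rng.random() < config.dissolving_fraction:
            t_ev = config.dissolution_time_distribution.sample(1, rng)[0]
            fr = _quantize_frame(max(t_ev, dt), dt, n)
            if fr >= n:  # dissolves after observation ends
                records.append((s.structure_id, s.cell_id, "initial", "persistent",
                                np.nan, -1))
                render.append((s, 0, n))
                continue
            records.append((s.structure_id, s.cell_id, "initial", "dissolved",
                            fr * dt, fr))
            render.append((s, 0, fr))
        else:
            records.append((s.structure_id, s.cell_id, "initial", "persistent",
                            np.nan, -1))
            render.append((s, 0, n))

    for cell in field.cells:
        if rng.random() >= config.appearance_probability:
            continue
        t_ev = config.appearance_time_distribution.sample(1, rng)[0]
        fr = _quantize_frame(max(t_ev, dt), dt, n)
        if fr >= n:
            continue
        existing = [s for s in field.structures if s.cell_id == cell.cell_id]
        pole = cell.p0 if not existing else (
            cell.p1
            if np.hypot(*(existing[0].center_px - cell.p0))
            < np.hypot(*(existing[0].center_px - cell.p1))
            else cell.p0
        )
        direction = cell.centroid_px - pole
        direction = direction / np.hypot(*direction)
        major_px = 0.8 / field_config.pixel_size
        if existing:
            # a structure appearing fused to an existing one is not a
            # countable new object: require a clear gap between ellipses
            center_new = pole + direction * (major_px / 2 + 1.0)
            gap = (
                np.hypot(*(existing[0].center_px - center_new))
                - existing[0].major_px / 2
                - major_px / 2
            )
            if gap < 3.0:
                continue
        params = field_config.storage_structure_params
        intensity = params.intensity_mean if params else 8615.0
        axis = cell.p1 - cell.p0
        new = SimStructure(
            structure_id=next_sid,
            cell_id=cell.cell_id,
            center_px=pole + direction * (major_px / 2 + 1.0),
            major_px=major_px,
            minor_px=min(major_px * 0.6, 2 * cell.radius_px - 2.0),
            angle=np.arctan2(axis[1], axis[0]),
            intensity=intensity,
            target_feret_um=major_px * field_config.pixel_size,
        )
        next_sid += 1
        all_structures.append(new)
        records.append((new.structure_id, new.cell_id, "appeared", "appeared",
                        fr * dt, fr))
        render.append((new, fr, n))

    events = pd.DataFrame(
        records,
        columns=["structure_id", "cell_id", "kind", "event", "event_time_min",
                 "event_frame"],
    )

    from .cellfield import _render_cell_mask  # shared rendering helper

    cell_mask = (
        _render_cell_mask(field.cells, shape) if field.cells else np.zeros(shape)
    )
    fi = config.induction_curve(config.times_min)
    bg = field_config.background_level
    cyto0 = field_config.cytosol_level
    psf = field_config.psf_sigma_px

    stack = np.empty((n,) + shape, dtype=np.float32)
    for t in range(n):
        cyto_t = cyto0 * fi[t]
        raw = bg + (cyto_t - bg) * cell_mask
        for s, first, last in render:
            if first <= t < last:
                r, c = s.mask_indices(shape)
                raw[r, c] = s.intensity
        frame = ndi.gaussian_filter(raw, psf) + rng.normal(
            0, field_config.noise_sd, shape
        )
        stack[t] = frame.astype(np.float32)

    return TimelapseResult(
        stack=stack,
        field=field,
        events=events,
        config=config,
        structures=all_structures,
    )
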