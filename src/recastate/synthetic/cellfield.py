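"""Synthetic multi-channel images of rod-shaped bacteria.

Renders fields of spherocylindrical *E. coli*-like cells on a regular
grid with random orientation: a brightfield-like channel (dark cell body
on a brighter background, suitable for the bandpass → edge → ridge
outline-detection chain), two fluorescence channels carrying
diffraction-limited foci with a controllable colocalized fraction, and a
GFP-like channel carrying cytosolic fluorescence plus bright polar
storage structures. Every rendered object is recorded in ground-truth
tables.

Default intensity levels follow the measured calibration of the imaging
regime being emulated: slide background 479 au, cytosolic RecA-GFP
1576 au, storage structures 8615 au.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from shapely.geometry import LineString, Polygon

__all__ = [
    "StorageStructureParams",
    "CellFieldConfig",
    "SimCell",
    "SimStructure",
    "CellField",
    "PlacementError",
    "simulate_cell_field",
]

#: camera calibration: 25 px² = 0.28462 μm² -> 0.1067 μm per pixel
DEFAULT_PIXEL_SIZE = 0.1067


class PlacementError(RuntimeError):
    """Raised when an object cannot be placed under its constraints."""


@dataclass(frozen=True)
class StorageStructureParams:
    """Storage-structure rendering parameters.

    Structures are elliptical polar aggregates; ``feret_um_mean/sd``
    parametrize a normal draw of the target maximum Feret diameter
    (truncated at ``feret_um_min``), and intensity a normal draw of the
    plateau intensity (au).
    """

    probability: float = 1.0
    intensity_mean: float = 8615.0
    intensity_sd: float = 1000.0
    feret_um_mean: float = 1.0
    feret_um_sd: float = 0.2
    feret_um_min: float = 0.5
    aspect: float = 0.6  # minor/major axis ratio


@dataclass(frozen=True)
class CellFieldConfig:
    """Configuration of a synthetic cell field.

    Lengths are in μm; intensities in arbitrary camera units. Foci counts
    per cell are Poisson-distributed around the configured means.
    ``colocalized_fraction`` is the probability that a channel-b focus in
    a cell containing at least one channel-a focus is placed within the
    colocalization radius of one (non-colocalized foci are kept at least
    1.5x the radius away, so the configured fraction is exact ground
    truth).
    """

    n_cells: int = 50
    cell_length_range: tuple[float, float] = (2.2, 4.0)
    cell_width_range: tuple[float, float] = (0.9, 1.1)
    pixel_size: float = DEFAULT_PIXEL_SIZE
    foci_per_cell_channel_a: float = 2.0
    foci_per_cell_channel_b: float = 1.5
    colocalized_fraction: float = 0.0
    colocalization_radius: float = 0.2
    focus_amplitude: float = 3000.0
    focus_sigma_px: float = 1.3
    noise_sd: float = 30.0
    background_level: float = 479.0
    cytosol_level: float = 1576.0
    storage_structure_params: StorageStructureParams | None = None
    # brightfield rendering
    bf_background: float = 1000.0
    bf_depth: float = 400.0
    bf_noise_sd: float = 8.0
    psf_sigma_px: float = 1.0
    margin_px: int = 12
    box_px: int | None = None  # grid-box side; derived from lengths if None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        if not 0.0 <= self.colocalized_fraction <= 1.0:
            raise ValueError("colocalized_fraction must be in [0, 1]")
        if self.n_cells < 0:
            raise ValueError("n_cells must be >= 0")
        if min(self.foci_per_cell_channel_a, self.foci_per_cell_channel_b) < 0:
            raise ValueError("foci counts must be >= 0")
        if self.colocalization_radius <= 0:
            raise ValueError("colocalization_radius must be positive")

    def with_(self, **kwargs) -> "CellFieldConfig":
        return replace(self, **kwargs)


@dataclass
class SimCell:
    """Ground-truth cell: spherocylinder axis segment plus radius."""

    cell_id: int
    p0: np.ndarray  # axis endpoints, px coordinates (x, y)
    p1: np.ndarray
    width_um: float
    length_um: float
    pixel_size: float

    @property
    def radius_px(self) -> float:
        return 0.5 * self.width_um / self.pixel_size

    @property
    def centroid_px(self) -> np.ndarray:
        return 0.5 * (self.p0 + self.p1)

    @property
    def polygon_px(self) -> Polygon:
        return LineString([self.p0, self.p1]).buffer(self.radius_px, quad_segs=32)

    @property
    def area_um2(self) -> float:
        w, l = self.width_um, self.length_um
        return (l - w) * w + np.pi * (w / 2) ** 2

    def distance_to_axis_px(self, x, y) -> np.ndarray:
        return _dist_point_segment(x, y, self.p0, self.p1)

    def contains_px(self, x, y, margin_px: float = 0.0) -> np.ndarray:
        return self.distance_to_axis_px(x, y) <= self.radius_px - margin_px


@dataclass
class SimStructure:
    """Ground-truth storage structure (ellipse) with its pixel mask."""

    structure_id: int
    cell_id: int
    center_px: np.ndarray
    major_px: float  # full major axis length, px
    minor_px: float
    angle: float  # radians, major axis orientation
    intensity: float
    target_feret_um: float

    def mask_indices(self, shape) -> tuple[np.ndarray, np.ndarray]:
        """(rows, cols) of pixels whose centers fall inside the ellipse."""
        cx, cy = self.center_px
        a, b = self.major_px / 2, self.minor_px / 2
        r0 = max(int(cy - a - 2), 0)
        r1 = min(int(cy + a + 3), shape[0])
        c0 = max(int(cx - a - 2), 0)
        c1 = min(int(cx + a + 3), shape[1])
        rr, cc = np.mgrid[r0:r1, c0:c1]
        dx, dy = cc - cx, rr - cy
        ca, sa = np.cos(self.angle), np.sin(self.angle)
        u = dx * ca + dy * sa
        v = -dx * sa + dy * ca
        inside = (u / a) ** 2 + (v / b) ** 2 <= 1.0
        return rr[inside], cc[inside]


@dataclass
class CellField:
    """Rendered field plus full ground truth."""

    brightfield: np.ndarray
    channels: dict[str, np.ndarray]
    cells: list[SimCell]
    foci: pd.DataFrame
    structures: list[SimStructure]
    config: CellFieldConfig

    @property
    def shape(self) -> tuple[int, int]:
        return self.brightfield.shape

    def cells_frame(self) -> pd.DataFrame:
        rows = [
            {
                "cell_id": c.cell_id,
                "centroid_x_px": c.centroid_px[0],
                "centroid_y_px": c.centroid_px[1],
                "length_um": c.length_um,
                "width_um": c.width_um,
                "area_um2": c.area_um2,
            }
            for c in self.cells
        ]
        return pd.DataFrame(
            rows,
            columns=[
                "cell_id",
                "centroid_x_px",
                "centroid_y_px",
                "length_um",
                "width_um",
                "area_um2",
            ],
        )

    def structures_frame(self) -> pd.DataFrame:
        rows = [
            {
                "structure_id": s.structure_id,
                "cell_id": s.cell_id,
                "center_x_px": s.center_px[0],
                "center_y_px": s.center_px[1],
                "target_feret_um": s.target_feret_um,
                "intensity": s.intensity,
            }
            for s in self.structures
        ]
        return pd.DataFrame(
            rows,
            columns=[
                "structure_id",
                "cell_id",
                "center_x_px",
                "center_y_px",
                "target_feret_um",
                "intensity",
            ],
        )


def _dist_point_segment(x, y, p0, p1):
    d = p1 - p0
    l2 = float(d @ d)
    if l2 == 0:
        return np.hypot(x - p0[0], y - p0[1])
    t = np.clip(((x - p0[0]) * d[0] + (y - p0[1]) * d[1]) / l2, 0.0, 1.0)
    return np.hypot(x - (p0[0] + t * d[0]), y - (p0[1] + t * d[1]))


def _layout(config: CellFieldConfig) -> tuple[int, int, int]:
    max_len_px = config.cell_length_range[1] / config.pixel_size
    box = config.box_px or int(np.ceil(max_len_px + 2 * config.margin_px))
    ncol = max(int(np.ceil(np.sqrt(max(config.n_cells, 1)))), 1)
    nrow = max(int(np.ceil(max(config.n_cells, 1) / ncol)), 1)
    return box, nrow, ncol


def _place_cells(config: CellFieldConfig, rng) -> tuple[list[SimCell], tuple[int, int]]:
    box, nrow, ncol = _layout(config)
    shape = (nrow * box, ncol * box)
    cells = []
    for i in range(config.n_cells):
        r, c = divmod(i, ncol)
        center = np.array([(c + 0.5) * box, (r + 0.5) * box]) + rng.uniform(-2, 2, 2)
        length = rng.uniform(*config.cell_length_range)
        width = rng.uniform(*config.cell_width_range)
        angle = rng.uniform(0, np.pi)
        half_axis = 0.5 * (length - width) / config.pixel_size
        if half_axis + width / config.pixel_size / 2 + 3 > box / 2:
            raise PlacementError(
                f"cell length {length:.2f} um exceeds its {box} px grid box; "
                "increase margin or canvas"
            )
        direction = np.array([np.cos(angle), np.sin(angle)])
        cells.append(
            SimCell(
                cell_id=i,
                p0=center - half_axis * direction,
                p1=center + half_axis * direction,
                width_um=width,
                length_um=length,
                pixel_size=config.pixel_size,
            )
        )
    return cells, shape


def _sample_point_in_cell(cell: SimCell, rng, margin_px: float, max_tries=200):
    lo = np.minimum(cell.p0, cell.p1) - cell.radius_px
    hi = np.maximum(cell.p0, cell.p1) + cell.radius_px
    for _ in range(max_tries):
        p = rng.uniform(lo, hi)
        if cell.contains_px(p[0], p[1], margin_px=margin_px):
            return p
    raise PlacementError("could not sample a point inside the cell body")


def _place_foci(config: CellFieldConfig, cells, rng) -> pd.DataFrame:
    px = config.pixel_size
    radius_px = config.colocalization_radius / px
    # within-channel separation: foci are countable as distinct objects
    min_sep_px = 0.45 / px
    margin = 1.5  # keep foci off the membrane so they render inside
    rows = []
    fid = 0
    # Poisson focus counts per cell; colocalization labels are assigned by
    # a stratified permutation over all eligible channel-b foci (those in
    # cells with at least one channel-a focus) so the configured
    # colocalized fraction is realized exactly, not just in expectation.
    counts = {
        cell.cell_id: (
            rng.poisson(config.foci_per_cell_channel_a),
            rng.poisson(config.foci_per_cell_channel_b),
        )
        for cell in cells
    }
    eligible = [
        (cid, j)
        for cid, (na, nb) in counts.items()
        if na > 0
        for j in range(nb)
    ]
    n_coloc = int(round(config.colocalized_fraction * len(eligible)))
    chosen = set(
        tuple(eligible[i]) for i in rng.permutation(len(eligible))[:n_coloc]
    )
    b_labels = {
        cid: [(cid, j) in chosen for j in range(nb)] if na > 0 else [False] * nb
        for cid, (na, nb) in counts.items()
    }
    for cell in cells:
        n_a, n_b = counts[cell.cell_id]
        a_pos = []
        for _ in range(n_a):
            for attempt in range(200):
                p = _sample_point_in_cell(cell, rng, margin)
                if all(np.hypot(*(p - q)) >= min_sep_px for q in a_pos):
                    break
            a_pos.append(p)
        for p in a_pos:
            rows.append((fid, cell.cell_id, "a", p[0], p[1], False))
            fid += 1
        b_pos: list[np.ndarray] = []
        for coloc in b_labels.pop(cell.cell_id, []):
            if coloc:
                anchor = a_pos[rng.integers(len(a_pos))]
                p = anchor.copy()
                for attempt in range(100):
                    ang = rng.uniform(0, 2 * np.pi)
                    rad = 0.5 * radius_px * np.sqrt(rng.random())
                    q = anchor + rad * np.array([np.cos(ang), np.sin(ang)])
                    if cell.contains_px(q[0], q[1], margin_px=margin) and all(
                        np.hypot(*(q - b)) >= min_sep_px for b in b_pos
                    ):
                        p = q
                        break
            else:
                # the anti-colocalization clearance is the label-critical
                # constraint; the within-channel separation is best-effort
                p = None
                for attempt in range(600):
                    q = _sample_point_in_cell(cell, rng, margin)
                    if all(np.hypot(*(q - a)) >= 1.5 * radius_px for a in a_pos):
                        if all(np.hypot(*(q - b)) >= min_sep_px for b in b_pos):
                            p = q
                            break
                        if p is None or attempt >= 300:
                            p = q
                            if attempt >= 300:
                                break
                if p is None:
                    raise PlacementError(
                        "could not place a non-colocalized focus at least "
                        f"{1.5 * config.colocalization_radius:.2f} um from "
                        "channel-a foci; cell too crowded"
                    )
            b_pos.append(p)
            rows.append((fid, cell.cell_id, "b", p[0], p[1], coloc))
            fid += 1
    df = pd.DataFrame(
        rows, columns=["focus_id", "cell_id", "channel", "x_px", "y_px", "colocalized"]
    )
    df["x_um"] = df["x_px"] * px
    df["y_um"] = df["y_px"] * px
    return df


def _place_structures(config: CellFieldConfig, cells, rng) -> list[SimStructure]:
    params = config.storage_structure_params
    if params is None:
        return []
    px = config.pixel_size
    out = []
    sid = 0
    for cell in cells:
        if rng.random() >= params.probability:
            continue
        feret = max(
            rng.normal(params.feret_um_mean, params.feret_um_sd), params.feret_um_min
        )
        # keep the ellipse inside the cell body
        feret = min(feret, cell.length_um - cell.width_um)
        intensity = max(rng.normal(params.intensity_mean, params.intensity_sd), 3000.0)
        axis = cell.p1 - cell.p0
        axis = axis / np.hypot(*axis)
        # polar placement, pole chosen at random
        pole = cell.p0 if rng.random() < 0.5 else cell.p1
        direction = cell.centroid_px - pole
        direction = direction / np.hypot(*direction)
        major_px = feret / px
        center = pole + direction * (major_px / 2 + 1.0)
        minor_px = min(major_px * params.aspect, 2 * cell.radius_px - 2.0)
        angle = np.arctan2(axis[1], axis[0])
        out.append(
            SimStructure(
                structure_id=sid,
                cell_id=cell.cell_id,
                center_px=center,
                major_px=major_px,
                minor_px=minor_px,
                angle=angle,
                intensity=intensity,
                target_feret_um=feret,
            )
        )
        sid += 1
    return out


def _render_cell_mask(cells, shape) -> np.ndarray:
    mask = np.zeros(shape, dtype=float)
    for cell in cells:
        r = cell.radius_px
        lo = np.floor(np.minimum(cell.p0, cell.p1) - r - 2).astype(int)
        hi = np.ceil(np.maximum(cell.p0, cell.p1) + r + 3).astype(int)
        lo = np.maximum(lo, 0)
        hi = np.minimum(hi, [shape[1], shape[0]])
        cc, rr = np.meshgrid(np.arange(lo[0], hi[0]), np.arange(lo[1], hi[1]))
        inside = cell.contains_px(cc.astype(float), rr.astype(float))
        mask[rr[inside], cc[inside]] = 1.0
    return mask


def _add_gaussian_spots(img, xs, ys, amplitudes, sigma):
    half = int(np.ceil(4 * sigma))
    for x, y, a in zip(xs, ys, amplitudes):
        r0, c0 = int(round(y)) - half, int(round(x)) - half
        r1, c1 = r0 + 2 * half + 1, c0 + 2 * half + 1
        rr, cc = np.mgrid[max(r0, 0) : min(r1, img.shape[0]),
                          max(c0, 0) : min(c1, img.shape[1])]
        img[rr, cc] += a * np.exp(
            -((cc - x) ** 2 + (rr - y) ** 2) / (2 * sigma ** 2)
        )


def simulate_cell_field(
    config: CellFieldConfig, rng: np.random.Generator | None = None
) -> CellField:
    """Render a synthetic multi-channel cell field with ground truth.

    Returns a :class:`CellField` holding the brightfield channel, the two
    focus channels (``"a"``, ``"b"``), a GFP-like channel (``"gfp"``)
    carrying cytosolic fluorescence and storage structures, and tables of
    every placed cell, focus and structure.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    cells, shape = _place_cells(config, rng)
    if not cells:
        shape = (_layout(config)[0],) * 2
    cell_mask = _render_cell_mask(cells, shape) if cells else np.zeros(shape)

    psf = config.psf_sigma_px
    bf = (
        config.bf_background
        - config.bf_depth * ndi.gaussian_filter(cell_mask, psf)
        + rng.normal(0, config.bf_noise_sd, shape)
    )

    foci = _place_foci(config, cells, rng) if cells else pd.DataFrame(
        columns=["focus_id", "cell_id", "channel", "x_px", "y_px", "colocalized",
                 "x_um", "y_um"]
    )
    cyto = config.cytosol_level - config.background_level
    channels = {}
    for ch in ("a", "b"):
        # foci are PSF-sized images of point emitters: drawn at their own
        # width on top of the blurred cytosol, not re-blurred
        img = ndi.gaussian_filter(config.background_level + cyto * cell_mask, psf)
        sel = foci[foci["channel"] == ch] if len(foci) else foci
        if len(sel):
            _add_gaussian_spots(
                img,
                sel["x_px"].to_numpy(),
                sel["y_px"].to_numpy(),
                np.full(len(sel), config.focus_amplitude),
                config.focus_sigma_px,
            )
        channels[ch] = img + rng.normal(0, config.noise_sd, shape)

    structures = _place_structures(config, cells, rng) if cells else []
    gfp_raw = config.background_level + cyto * cell_mask
    for s in structures:
        r, c = s.mask_indices(shape)
        gfp_raw[r, c] = s.intensity
    channels["gfp"] = ndi.gaussian_filter(gfp_raw, psf) + rng.normal(
        0, config.noise_sd, shape
    )

    return CellField(
        brightfield=bf,
        channels=channels,
        cells=cells,
        foci=foci,
        structures=structures,
        config=config,
    )
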