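"""Brightfield cell-outline detection: bandpass -> edge -> ridge chain.

Cell outlines are detected by (1) a Gaussian bandpass that suppresses
structures larger/smaller than configured cutoffs, (2) a Gaussian-
derivative gradient-magnitude edge map rescaled to 8-bit, and (3) a
Steger-style curvilinear ridge detector applied to the edge map: line
points from Hessian eigen-analysis at scale ``ridge_sigma`` with
sub-pixel localization, hysteresis linking into chains, and emission of
chains that close on themselves as cell-outline polygons.

The default parameters (bandpass 2/0 px, edge smoothing 2 px, line width
2 px, sigma 0.8, hysteresis thresholds 1.7/5 on the 8-bit edge map) are
the calibrated values for the brightfield imaging regime this chain was
developed for.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from shapely.geometry import Polygon

__all__ = [
    "SegmentationConfig",
    "CellOutline",
    "bandpass_filter",
    "edge_map",
    "detect_ridge_points",
    "link_ridge_chains",
    "extract_outlines",
    "segment_cells",
    "match_outlines_to_polygons",
]


@dataclass(frozen=True)
class SegmentationConfig:
    """Parameters of the bandpass -> edge -> ridge detection chain."""

    bandpass_large: float = 2.0  # suppress structures larger than this (px)
    bandpass_small: float = 0.0  # suppress structures smaller than this (px)
    edge_smoothing: float = 2.0  # Gaussian-derivative scale (px)
    ridge_line_width: float = 2.0
    ridge_sigma: float = 0.8
    ridge_low_threshold: float = 1.7
    ridge_high_threshold: float = 5.0
    ridge_high_contrast: float = 230.0
    ridge_low_contrast: float = 87.0
    min_chain_length: int = 10  # px; shorter chains are noise fragments
    closure_gap: float = 2.0  # px; endpoint gap below which a chain closes

    def __post_init__(self) -> None:
        if self.bandpass_large <= 0 or self.bandpass_small < 0:
            raise ValueError("bandpass cutoffs must be positive (small may be 0)")
        if self.edge_smoothing <= 0 or self.ridge_sigma <= 0:
            raise ValueError("scales must be positive")
        if self.ridge_low_threshold >= self.ridge_high_threshold:
            raise ValueError("ridge low threshold must be below high threshold")


@dataclass
class CellOutline:
    """Closed cell contour with sub-pixel vertices.

    Vertices are in pixel coordinates (x = column, y = row, origin
    top-left, pixel centers at integer coordinates). Area is computed by
    the shoelace formula on the sub-pixel polygon.
    """

    vertices: np.ndarray  # (n, 2) array of (x, y)
    closed: bool = True
    pixel_size: float | None = None

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 2:
            raise ValueError("vertices must be an (n, 2) array")

    @property
    def polygon(self) -> Polygon:
        poly = Polygon(self.vertices)
        if not poly.is_valid:
            poly = poly.buffer(0)
        return poly

    @property
    def area_px2(self) -> float:
        return float(self.polygon.area)

    @property
    def area_um2(self) -> float:
        if self.pixel_size is None:
            raise ValueError("pixel_size not set")
        return self.area_px2 * self.pixel_size ** 2

    @property
    def centroid_px(self) -> np.ndarray:
        c = self.polygon.centroid
        return np.array([c.x, c.y])


# ---------------------------------------------------------------------------
# Stage 1: Fourier-domain Gaussian bandpass
# ---------------------------------------------------------------------------


def bandpass_filter(
    image: np.ndarray, config: SegmentationConfig | None = None
) -> np.ndarray:
    """Gaussian bandpass: suppress structures larger than ``bandpass_large``
    px and smaller than ``bandpass_small`` px.

    Implemented as a difference of Gaussians (sigma = cutoff / 2), which
    is the Fourier-domain Gaussian band; the DC component is removed
    whenever the large-structure cutoff is active.
    """
    if config is None:
        config = SegmentationConfig()
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ValueError(f"expected a 2-D image, got {img.ndim}-D")
    small = (
        ndi.gaussian_filter(img, config.bandpass_small / 2.0)
        if config.bandpass_small > 0
        else img
    )
    large = ndi.gaussian_filter(img, config.bandpass_large / 2.0)
    return small - large


# ---------------------------------------------------------------------------
# Stage 2: Gaussian-derivative edge magnitude, rescaled to 8-bit
# ---------------------------------------------------------------------------


def edge_map(image: np.ndarray, smoothing: float = 2.0) -> np.ndarray:
    """Gradient magnitude of the Gaussian-smoothed image, rescaled to [0, 255].

    The gradient is computed with Gaussian-derivative kernels at scale
    ``smoothing``; the output is linearly rescaled so its maximum maps to
    255 (8-bit edge image convention expected by the ridge thresholds).
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ValueError(f"expected a 2-D image, got {img.ndim}-D")
    if smoothing <= 0:
        raise ValueError("smoothing must be positive")
    gx = ndi.gaussian_filter(img, smoothing, order=(0, 1))
    gy = ndi.gaussian_filter(img, smoothing, order=(1, 0))
    mag = np.hypot(gx, gy)
    peak = mag.max()
    if peak > 0:
        mag = mag * (255.0 / peak)
    return mag


# ---------------------------------------------------------------------------
# Stage 3: Steger-style ridge detection
# ---------------------------------------------------------------------------


@dataclass
class RidgePoints:
    """Grid of detected line points with sub-pixel positions."""

    mask: np.ndarray  # bool, accepted line points
    x: np.ndarray  # sub-pixel x per pixel
    y: np.ndarray
    strength: np.ndarray  # |second directional derivative|
    nx: np.ndarray  # unit normal (across the line)
    ny: np.ndarray


def detect_ridge_points(
    image: np.ndarray, sigma: float = 0.8, dark_lines: bool = False
) -> RidgePoints:
    """Detect curvilinear line points by Hessian eigen-analysis.

    At each pixel the Hessian of the Gaussian-smoothed image is
    eigen-decomposed; the eigenvector of the largest-magnitude eigenvalue
    gives the direction across the line, and the first derivative along
    it locates the ridge to sub-pixel accuracy. A pixel is a line point
    when the sub-pixel offset falls within the pixel and the second
    derivative has the sign of a bright (or dark) line.
    """
    img = np.asarray(image, dtype=float)
    rx = ndi.gaussian_filter(img, sigma, order=(0, 1))
    ry = ndi.gaussian_filter(img, sigma, order=(1, 0))
    rxx = ndi.gaussian_filter(img, sigma, order=(0, 2))
    ryy = ndi.gaussian_filter(img, sigma, order=(2, 0))
    rxy = ndi.gaussian_filter(img, sigma, order=(1, 1))

    half_tr = 0.5 * (rxx + ryy)
    disc = np.sqrt(np.maximum(0.25 * (rxx - ryy) ** 2 + rxy ** 2, 0.0))
    l1 = half_tr + disc
    l2 = half_tr - disc
    lam = np.where(np.abs(l1) >= np.abs(l2), l1, l2)

    # eigenvector of lam: (rxy, lam - rxx) or (lam - ryy, rxy), pick stabler
    v1x, v1y = rxy, lam - rxx
    v2x, v2y = lam - ryy, rxy
    use2 = np.hypot(v1x, v1y) < np.hypot(v2x, v2y)
    nx = np.where(use2, v2x, v1x)
    ny = np.where(use2, v2y, v1y)
    norm = np.hypot(nx, ny)
    norm = np.where(norm > 0, norm, 1.0)
    nx, ny = nx / norm, ny / norm

    sign_ok = lam > 0 if dark_lines else lam < 0
    strength = np.abs(lam)

    denom = rxx * nx ** 2 + 2 * rxy * nx * ny + ryy * ny ** 2
    denom = np.where(np.abs(denom) > 1e-12, denom, np.inf)
    t = -(rx * nx + ry * ny) / denom
    tx, ty = t * nx, t * ny
    within = (np.abs(tx) <= 0.55) & (np.abs(ty) <= 0.55)

    cols, rows = np.meshgrid(np.arange(img.shape[1]), np.arange(img.shape[0]))
    return RidgePoints(
        mask=sign_ok & within,
        x=cols + tx,
        y=rows + ty,
        strength=strength,
        nx=nx,
        ny=ny,
    )


def _hysteresis(mask, strength, low, high):
    strong = mask & (strength >= high)
    weak = mask & (strength >= low)
    lab, n = ndi.label(weak, structure=np.ones((3, 3), dtype=int))
    if n == 0:
        return np.zeros_like(mask)
    keep = np.unique(lab[strong])
    keep = keep[keep > 0]
    return np.isin(lab, keep)


def _thin_across(accepted, points: RidgePoints):
    """Drop line points whose across-line neighbor is stronger."""
    out = accepted.copy()
    rows, cols = np.nonzero(accepted)
    for r, c in zip(rows, cols):
        dx = int(round(points.nx[r, c]))
        dy = int(round(points.ny[r, c]))
        if dx == 0 and dy == 0:
            continue
        for s in (1, -1):
            rr, cc = r + s * dy, c + s * dx
            if 0 <= rr < accepted.shape[0] and 0 <= cc < accepted.shape[1]:
                if accepted[rr, cc] and points.strength[rr, cc] > points.strength[r, c]:
                    out[r, c] = False
                    break
    return out


_NEIGHBORS = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


def link_ridge_chains(points: RidgePoints, low: float, high: float) -> list[np.ndarray]:
    """Link accepted line points into ordered sub-pixel chains.

    Hysteresis keeps weak points only when connected to a strong point.
    Chains are traced greedily: from an endpoint (or an arbitrary point of
    a cycle), the walk continues to the unvisited 8-neighbor that
    minimizes the direction change of the path — the continuation-by-
    slope junction rule.
    """
    accepted = _hysteresis(points.mask, points.strength, low, high)
    accepted = _thin_across(accepted, points)
    coords = {(r, c) for r, c in zip(*np.nonzero(accepted))}

    def neighbors(rc):
        r, c = rc
        return [
            (r + dr, c + dc) for dr, dc in _NEIGHBORS if (r + dr, c + dc) in coords
        ]

    visited: set[tuple[int, int]] = set()
    chains: list[np.ndarray] = []

    def tangent_align(rc, v):
        """|cos| between a step vector and the line tangent at a point."""
        tx, ty = -points.ny[rc], points.nx[rc]  # tangent = normal rotated 90°
        num = abs(v[1] * tx + v[0] * ty)  # v is (dr, dc) = (dy, dx)
        return num / np.hypot(*v)

    def walk(start, first_step):
        chain = [start]
        visited.add(start)
        prev, cur = start, first_step
        closed = False
        while True:
            chain.append(cur)
            visited.add(cur)
            # loop closure: the walk returned to the start's neighborhood
            if len(chain) > 12 and max(
                abs(cur[0] - start[0]), abs(cur[1] - start[1])
            ) <= 2:
                chain.append(start)  # close the loop explicitly
                closed = True
                break
            dvec = (cur[0] - prev[0], cur[1] - prev[1])
            # candidates must continue roughly along the local line tangent;
            # junction spurs (crossing lines) fail this and are not entered
            cands = [
                n
                for n in neighbors(cur)
                if n not in visited
                and tangent_align(n, (n[0] - cur[0], n[1] - cur[1])) >= 0.35
            ]
            if not cands:
                # junction hole: look ahead up to 3 px along the travel
                # direction for a compatible line point and jump the gap
                jump = None
                dn = np.hypot(*dvec)
                for dr in range(-3, 4):
                    for dc in range(-3, 4):
                        n = (cur[0] + dr, cur[1] + dc)
                        if n == cur or n not in coords or n in visited:
                            continue
                        dist = np.hypot(dr, dc)
                        if dist > 2.5:
                            continue
                        ahead = (dr * dvec[0] + dc * dvec[1]) / (dist * dn)
                        if ahead < 0.9:
                            continue
                        if tangent_align(n, (dr, dc)) < 0.6:
                            continue
                        if jump is None or dist < jump[0]:
                            jump = (dist, n)
                if jump is not None:
                    prev, cur = cur, jump[1]
                    continue
                break

            def cost(n):
                v = (n[0] - cur[0], n[1] - cur[1])
                dot = v[0] * dvec[0] + v[1] * dvec[1]
                turn = -dot / (np.hypot(*v) * np.hypot(*dvec))
                return turn + (1.0 - tangent_align(n, v))

            nxt = min(cands, key=cost)
            v = (nxt[0] - cur[0], nxt[1] - cur[1])
            dot = v[0] * dvec[0] + v[1] * dvec[1]
            if -dot / (np.hypot(*v) * np.hypot(*dvec)) > 0.5:
                break  # > ~120 degree turn: stop rather than fold back
            prev, cur = cur, nxt
        return chain, closed

    def trace_from(start):
        nbrs = [n for n in neighbors(start) if n not in visited]
        if not nbrs:
            visited.add(start)
            return [start]
        fwd, closed = walk(start, nbrs[0])
        if closed:
            return fwd
        # extend backwards from the start if another branch exists
        back_nbrs = [n for n in neighbors(start) if n not in visited]
        if back_nbrs:
            back, _ = walk(start, back_nbrs[0])
            fwd = list(reversed(back[1:])) + fwd
        return fwd

    # strongest points first: salient lines claim their pixels before
    # weaker crossing spurs can consume them at junctions
    order = sorted(coords, key=lambda rc: -points.strength[rc])
    for rc in order:
        if rc in visited:
            continue
        chain = trace_from(rc)
        if len(chain) >= 2:
            chains.append(
                np.array([[points.x[r, c], points.y[r, c]] for r, c in chain])
            )
    return _stitch_chains(chains)


def _end_direction(chain, head: bool):
    """Outward unit direction at a chain end."""
    k = min(3, len(chain) - 1)
    v = chain[0] - chain[k] if head else chain[-1] - chain[-1 - k]
    n = np.hypot(*v)
    return v / n if n > 0 else v


def _stitch_chains(chains: list[np.ndarray]) -> list[np.ndarray]:
    """Two-pass endpoint stitching of traced chains.

    Approximates the line-extension behavior of the original detector:
    tracing breaks at junctions are bridged first at short range (3 px,
    loose direction test), then at long range (12 px) for long fragments
    with strictly continuing end directions (which excludes stitching
    across parallel neighboring lines). Short chains are never stitched
    (they are noise fragments).
    """
    return _stitch_pass(chains, radius=3.0, min_len=6, align=0.0)


def _stitch_pass(
    chains: list[np.ndarray],
    radius: float,
    min_len: int,
    align: float,
    max_passes: int = 10,
) -> list[np.ndarray]:
    chains = list(chains)
    for _ in range(max_passes):
        merged = False
        long_idx = [i for i, c in enumerate(chains) if len(c) >= min_len]
        i = 0
        while i < len(long_idx):
            a = long_idx[i]
            ca = chains[a]
            best = None
            for j in long_idx:
                if j == a:
                    continue
                cb = chains[j]
                for a_head in (False, True):
                    for b_head in (True, False):
                        pa = ca[0] if a_head else ca[-1]
                        pb = cb[0] if b_head else cb[-1]
                        gap = np.hypot(*(pa - pb))
                        if gap > radius:
                            continue
                        da = _end_direction(ca, a_head)
                        db = _end_direction(cb, b_head)
                        # db points outward from cb's end: continuation means
                        # da and db roughly opposite
                        if float(da @ db) > -(0.1 + align):
                            continue
                        if gap > 1e-9:
                            conn = (pb - pa) / gap
                            if float(conn @ da) < align:
                                continue
                        if best is None or gap < best[0]:
                            best = (gap, j, a_head, b_head)
            if best is not None:
                _, j, a_head, b_head = best
                ca2 = chains[a][::-1] if a_head else chains[a]
                cb2 = chains[j] if b_head else chains[j][::-1]
                chains[a] = np.vstack([ca2, cb2])
                chains.pop(j)
                merged = True
                long_idx = [i2 for i2, c in enumerate(chains) if len(c) >= min_len]
                i = 0
                continue
            i += 1
        if not merged:
            break
    return chains


def extract_outlines(
    edge_image: np.ndarray,
    config: SegmentationConfig | None = None,
    pixel_size: float | None = None,
) -> tuple[list[CellOutline], list[np.ndarray]]:
    """Extract closed cell outlines from an edge-strength image.

    Runs the ridge detector on the edge image, links line points into
    chains, and emits chains whose endpoints close (gap <= ``closure_gap``
    px) as :class:`CellOutline` polygons; open chains are returned
    separately.
    """
    if config is None:
        config = SegmentationConfig()
    points = detect_ridge_points(edge_image, sigma=config.ridge_sigma)
    chains = link_ridge_chains(
        points, config.ridge_low_threshold, config.ridge_high_threshold
    )
    outlines: list[CellOutline] = []
    open_chains: list[np.ndarray] = []
    for chain in chains:
        if len(chain) < config.min_chain_length:
            continue
        gap = np.hypot(*(chain[0] - chain[-1]))
        if gap <= config.closure_gap and len(chain) >= 8:
            poly_chain = chain
        elif len(chain) >= 30 and gap <= 12.0 and gap < 0.25 * len(chain):
            # line extension: bridge a junction-induced hole with a
            # tangent-following arc between the two chain ends
            poly_chain = np.vstack([chain, _closure_arc(chain)])
        else:
            open_chains.append(chain)
            continue
        outline = CellOutline(poly_chain, closed=True, pixel_size=pixel_size)
        if outline.polygon.area > 0:
            outlines.append(outline)
        else:
            open_chains.append(chain)
    return outlines, open_chains


def _closure_arc(chain: np.ndarray) -> np.ndarray:
    """Quadratic Bezier bridging the gap from chain end back to its start.

    The control point sits at the intersection of the end-tangent rays,
    so the bridge continues both ends smoothly (falling back to the chord
    midpoint for near-parallel tangents or distant intersections).
    """
    p0, p1 = chain[-1], chain[0]
    gap = np.hypot(*(p1 - p0))
    k = min(4, len(chain) - 1)
    t0 = chain[-1] - chain[-1 - k]
    t1 = chain[0] - chain[k]  # outward at the head
    n0 = np.hypot(*t0)
    n1 = np.hypot(*t1)
    ctrl = 0.5 * (p0 + p1)
    if n0 > 0 and n1 > 0:
        d0, d1 = t0 / n0, t1 / n1
        # solve p0 + a*d0 == p1 + b*d1
        det = d0[0] * (-d1[1]) - (-d1[0]) * d0[1]
        if abs(det) > 1e-6:
            rhs = p1 - p0
            a = (rhs[0] * (-d1[1]) - (-d1[0]) * rhs[1]) / det
            cand = p0 + a * d0
            if 0 < a < 2.0 * gap:
                ctrl = cand
    ts = np.linspace(0, 1, max(int(gap), 3) + 2)[1:-1]
    return np.array(
        [(1 - t) ** 2 * p0 + 2 * t * (1 - t) * ctrl + t ** 2 * p1 for t in ts]
    )


def segment_cells(
    brightfield: np.ndarray,
    config: SegmentationConfig | None = None,
    pixel_size: float | None = None,
) -> tuple[list[CellOutline], list[np.ndarray]]:
    """Full outline-detection chain on a brightfield image.

    Applies :func:`bandpass_filter`, :func:`edge_map` and
    :func:`extract_outlines` in sequence and returns (closed outlines,
    open chains).
    """
    if config is None:
        config = SegmentationConfig()
    bp = bandpass_filter(brightfield, config)
    edges = edge_map(bp, config.edge_smoothing)
    return extract_outlines(edges, config, pixel_size=pixel_size)


def match_outlines_to_polygons(
    outlines: list[CellOutline], truth: list[Polygon]
) -> list[tuple[int, int, float]]:
    """Greedy best-IoU matching of detected outlines to truth polygons.

    Returns (truth_index, outline_index, iou) triples for pairs with
    IoU > 0; each outline and each truth polygon is used at most once.
    """
    pairs = []
    for i, t in enumerate(truth):
        for j, o in enumerate(outlines):
            p = o.polygon
            if not p.intersects(t):
                continue
            inter = p.intersection(t).area
            union = p.union(t).area
            if union > 0 and inter > 0:
                pairs.append((inter / union, i, j))
    pairs.sort(reverse=True)
    used_t, used_o, out = set(), set(), []
    for iou, i, j in pairs:
        if i in used_t or j in used_o:
            continue
        used_t.add(i)
        used_o.add(j)
        out.append((i, j, iou))
    return out
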