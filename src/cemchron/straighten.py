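"""Straightening of the curved cementum band along a user-drawn midline.

The tooth-root cementum runs circumferentially in a transverse CT slice.
A user supplies a polyline roughly following the middle of the band; a
natural cubic spline through those control points is resampled at unit arc
length, and pixel profiles are interpolated along the local normals,
producing a rectangular image in which growth increments run horizontally:
row 0 is the outer cementum surface, the last row faces the cemento-dentine
junction, and the middle row is the midline itself. Pixels sampled outside
the tissue stay at the background fill value 0, so the radial tissue extent
of a transect can later be measured as the span of non-zero values.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.ndimage import map_coordinates

log = logging.getLogger("cemchron")


@dataclasses.dataclass
class MidlinePath:
    """User-drawn midline: ordered control points plus sampling half-width."""

    control_points: np.ndarray  # (n, 2) array of (x, y) pixel coordinates
    half_width_px: int = 10

    def __post_init__(self) -> None:
        pts = np.atleast_2d(np.asarray(self.control_points, float))
        if pts.shape[0] < 2 or pts.shape[1] != 2:
            raise ValueError("midline needs >= 2 (x, y) control points")
        if np.any(np.all(np.diff(pts, axis=0) == 0, axis=1)):
            raise ValueError("consecutive control points must be distinct")
        if self.half_width_px < 1:
            raise ValueError("half_width_px must be >= 1")
        self.control_points = pts


@dataclasses.dataclass
class StraightenedImage:
    """Rectangular resampling of the cementum band.

    ``pixels`` has height 2*half_width+1 and width equal to the arc length
    of the midline in pixels; row 0 is the outer surface side.
    """

    pixels: np.ndarray
    half_width_px: int
    voxel_size_um: float | None = None

    def __post_init__(self) -> None:
        if self.pixels.shape[0] != 2 * self.half_width_px + 1:
            raise ValueError("height must equal 2*half_width_px + 1")

    @property
    def coverage(self) -> float:
        """Fraction of non-background (non-zero) pixels."""
        return float(np.count_nonzero(self.pixels)) / self.pixels.size


def _segments_intersect(p, q, r, s) -> bool:
    def cross(o, a, b):
        return (a[0] - o[0]) * (b[1] - o[1]) - (a[1] - o[1]) * (b[0] - o[0])
    d1, d2 = cross(r, s, p), cross(r, s, q)
    d3, d4 = cross(p, q, r), cross(p, q, s)
    return ((d1 > 0) != (d2 > 0)) and ((d3 > 0) != (d4 > 0))


def fit_midline(control_points: np.ndarray) -> np.ndarray:
    """Interpolate control points with a natural cubic spline and resample
    at unit arc-length steps.

    Returns an (m, 2) array of sub-pixel (x, y) samples spaced one pixel
    apart along the curve. A self-intersecting path triggers a warning but
    is still returned.
    """
    pts = np.atleast_2d(np.asarray(control_points, float))
    if pts.shape[0] < 2:
        raise ValueError("need >= 2 control points")
    chord = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    if np.any(chord == 0):
        raise ValueError("consecutive control points must be distinct")
    t = np.concatenate([[0.0], np.cumsum(chord)])
    spline = CubicSpline(t, pts, bc_type="natural")
    # dense evaluation for an accurate arc-length parameterisation
    dense_t = np.linspace(0, t[-1], max(20 * len(pts), int(np.ceil(t[-1])) * 8 + 1))
    dense = spline(dense_t)
    seg = np.linalg.norm(np.diff(dense, axis=0), axis=1)
    arc = np.concatenate([[0.0], np.cumsum(seg)])
    total = arc[-1]
    n_samples = int(np.floor(total + 1e-9)) + 1
    targets = np.arange(n_samples, dtype=float)
    path = np.column_stack([
        np.interp(targets, arc, dense[:, 0]),
        np.interp(targets, arc, dense[:, 1]),
    ])
    # coarse self-intersection check on the resampled polyline
    step = max(1, len(path) // 200)
    poly = path[::step]
    for i in range(len(poly) - 1):
        for j in range(i + 2, len(poly) - 1):
            if _segments_intersect(poly[i], poly[i + 1], poly[j], poly[j + 1]):
                warnings.warn("midline path self-intersects", stacklevel=2)
                return path
    return path


def _normals(path: np.ndarray, image_shape: tuple[int, int]) -> np.ndarray:
    """Unit normals oriented away from the image centroid (outward)."""
    tangent = np.gradient(path, axis=0)
    norm = np.linalg.norm(tangent, axis=1, keepdims=True)
    norm[norm == 0] = 1.0
    tangent /= norm
    normal = np.column_stack([-tangent[:, 1], tangent[:, 0]])
    centroid = np.array([(image_shape[1] - 1) / 2.0, (image_shape[0] - 1) / 2.0])
    outward = path - centroid
    flip = np.sum(normal * outward, axis=1) < 0
    normal[flip] *= -1
    return normal


def straighten(slice_px: np.ndarray, midline: MidlinePath) -> StraightenedImage:
    """Resample a slice along the midline's normals into a rectangle.

    For each unit-arc-length path sample a profile of ``2*half_width+1``
    bilinearly interpolated values is taken along the local normal; row 0
    is the outward (outer cementum surface) side.
    """
    h = midline.half_width_px
    path = fit_midline(midline.control_points)
    normal = _normals(path, slice_px.shape)
    offsets = np.arange(h, -h - 1, -1, dtype=float)  # +h (outward) .. -h
    # sample coordinates: (rows, cols) for map_coordinates
    xs = path[None, :, 0] + offsets[:, None] * normal[None, :, 0]
    ys = path[None, :, 1] + offsets[:, None] * normal[None, :, 1]
    out_of_bounds = ((xs < 0) | (xs > slice_px.shape[1] - 1)
                     | (ys < 0) | (ys > slice_px.shape[0] - 1))
    if np.any(out_of_bounds):
        r, c = np.argwhere(out_of_bounds)[0]
        raise ValueError(
            f"normal sampling leaves image bounds at path sample {c}, "
            f"offset {offsets[r]:+g} px")
    pixels = map_coordinates(slice_px.astype(float), [ys, xs], order=1,
                             mode="constant", cval=0.0)
    return StraightenedImage(pixels=pixels, half_width_px=h)


def propagate_midline(stack, midline: MidlinePath,
                      slice_range: range | None = None
                      ) -> dict[int, StraightenedImage]:
    """Apply one midline to a range of slices.

    The same control points and half-width are reused for every slice in
    ``slice_range`` (default: the whole stack). Slices for which the
    sampling leaves the image bounds are skipped with a warning. Per-slice
    tissue coverage (fraction of non-zero output pixels) is logged so the
    user can decide where the midline needs re-annotation.
    """
    if slice_range is None:
        slice_range = range(len(stack))
    out: dict[int, StraightenedImage] = {}
    for i in slice_range:
        if not 0 <= i < len(stack):
            raise IndexError(f"slice index {i} outside stack of {len(stack)}")
        try:
            img = straighten(stack.slices[i], midline)
        except ValueError as exc:
            warnings.warn(f"slice {i} skipped: {exc}", stacklevel=2)
            continue
        img.voxel_size_um = stack.voxel_size_um
        out[i] = img
        log.info("slice %d: straightened, coverage %.3f", i, img.coverage)
    return out
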