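"""Field geometry: buffered plots, back-projection into views, plot-frame resampling.

Each breeding plot is a polygon in world coordinates (metric, planar).  A
drone view observes it obliquely; projecting the plot corners through the
camera's pinhole model gives a per-view image mask, and an affine transform
fitted to the corner correspondences maps a common *plot coordinate frame*
(axes parallel to the plot borders, threefold oversampled relative to the
nominal ground sampling distance) into each view.  Resampling every
segmented view into this frame is what makes pixel-wise aggregation into a
multiview image possible.

Plots are shrunk by a buffer ``B`` before sampling so that tall plants from
a neighbouring plot, seen obliquely, cannot leak in:

    B = tan(AOV/2) · h_canopy + E_ref

where ``AOV`` is the camera's maximum angle of view, ``h_canopy`` the canopy
height and ``E_ref`` the georeferencing precision.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from shapely.geometry import Polygon

__all__ = [
    "PlotPolygon",
    "CameraView",
    "PlotImageMask",
    "FlatElevation",
    "ElevationRaster",
    "min_buffer",
    "max_canopy_height",
    "backproject_polygon",
    "resample_to_plot",
    "nadir_rotation",
    "MASK_SENTINEL",
]

#: sentinel for pixels outside the buffered plot polygon in plot-frame rasters
MASK_SENTINEL = -1

#: affine corner-fit residual (px) above which a coregistration warning is issued
_RESIDUAL_WARN_PX = 2.0


def min_buffer(aov_deg: float, h_canopy: float, e_ref: float) -> float:
    """Minimum plot-polygon buffer in metres.

    ``B = tan(AOV/2)·h_canopy + E_ref``: the horizontal offset at which the
    top of a canopy of height ``h_canopy`` appears under the worst viewing
    angle, plus the georeferencing precision.
    """
    if not 0 <= aov_deg < 180:
        raise ValueError(f"angle of view must be in [0, 180) degrees, got {aov_deg}")
    if h_canopy < 0 or e_ref < 0:
        raise ValueError("canopy height and georeferencing precision must be >= 0")
    return math.tan(math.radians(aov_deg) / 2.0) * h_canopy + e_ref


def max_canopy_height(buffer_m: float, aov_deg: float, e_ref: float) -> float:
    """Tallest canopy monitorable with a given buffer (inverse of :func:`min_buffer`)."""
    if not 0 < aov_deg < 180:
        raise ValueError("angle of view must be in (0, 180) degrees")
    if buffer_m < e_ref:
        raise ValueError("buffer smaller than georeferencing precision leaves no margin")
    return (buffer_m - e_ref) / math.tan(math.radians(aov_deg) / 2.0)


@dataclass(frozen=True)
class PlotPolygon:
    """A plot's world-coordinate outline plus experimental-design metadata.

    ``corners`` are 4+ XY(Z) points in metres, ordered along the boundary.
    The plot frame has its origin at the corner nearest the field origin and
    its x axis along the plot length (sowing-row direction).
    """

    plot_id: str
    corners: np.ndarray
    buffer_m: float = 0.25
    row: int | None = None
    range_: int | None = None
    genotype: str | None = None

    def __post_init__(self) -> None:
        c = np.atleast_2d(np.asarray(self.corners, dtype=float))
        if c.shape[0] < 4 or c.shape[1] not in (2, 3):
            raise ValueError("corners must be >= 4 points of XY or XYZ")
        if not Polygon(c[:, :2]).is_valid:
            raise ValueError(f"plot {self.plot_id}: polygon is self-intersecting")
        if self.buffer_m < 0:
            raise ValueError("buffer must be >= 0")
        object.__setattr__(self, "corners", c)

    @property
    def polygon(self) -> Polygon:
        return Polygon(self.corners[:, :2])

    @property
    def buffered(self) -> Polygon:
        """Polygon shrunk inward by ``buffer_m``; must remain nonempty."""
        inner = self.polygon.buffer(-self.buffer_m, join_style="mitre")
        if inner.is_empty:
            raise ValueError(
                f"plot {self.plot_id}: buffer {self.buffer_m} m erases the polygon"
            )
        return inner

    def plot_frame(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Return (origin, x-axis unit, y-axis unit) of the plot frame in world XY."""
        xy = self.corners[:, :2]
        origin = xy[np.argmin(np.hypot(xy[:, 0], xy[:, 1]))]
        others = xy[~np.all(xy == origin, axis=1)]
        # x axis along the longer adjacent edge (plot length, sowing-row direction)
        d = others - origin
        edges = d[np.argsort(np.hypot(d[:, 0], d[:, 1]))[:2]]
        lengths = np.hypot(edges[:, 0], edges[:, 1])
        ex = edges[np.argmax(lengths)] / lengths.max()
        ey = np.array([-ex[1], ex[0]])
        if np.cross(np.append(ex, 0), np.append(ey, 0))[2] < 0:
            ey = -ey
        return origin, ex, ey

    def to_plot_mm(self, world_xy: np.ndarray) -> np.ndarray:
        """World XY metres -> plot-frame millimetres."""
        origin, ex, ey = self.plot_frame()
        rel = np.atleast_2d(world_xy) - origin
        return np.column_stack([rel @ ex, rel @ ey]) * 1000.0


def nadir_rotation() -> np.ndarray:
    """World->camera rotation for a camera looking straight down.

    Camera x follows world x, camera y is flipped (image rows grow southward),
    camera z points along the view direction (downward).
    """
    return np.diag([1.0, -1.0, -1.0])


@dataclass(frozen=True)
class CameraView:
    """Pinhole camera: pose in world coordinates plus intrinsics.

    ``rotation`` maps world-frame vectors into the camera frame (z forward
    along the optical axis).  Lens distortion is assumed already corrected.
    """

    image_id: str
    position: np.ndarray
    rotation: np.ndarray
    focal_px: float
    principal_point: tuple[float, float]
    image_size: tuple[int, int]  # (width, height) px
    gsd_mm: float = 3.0

    def __post_init__(self) -> None:
        pos = np.asarray(self.position, dtype=float).reshape(3)
        rot = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        if np.linalg.norm(rot.T @ rot - np.eye(3)) > 1e-8:
            raise ValueError(f"view {self.image_id}: rotation is not orthonormal")
        if self.focal_px <= 0:
            raise ValueError("focal length must be > 0")
        object.__setattr__(self, "position", pos)
        object.__setattr__(self, "rotation", rot)

    def project(self, world_xyz: np.ndarray) -> np.ndarray:
        """Project world XYZ points (m) to image pixel coordinates (u, v).

        Raises ``ValueError`` if any point lies on or behind the camera plane.
        """
        pts = np.atleast_2d(np.asarray(world_xyz, dtype=float))
        cam = (pts - self.position) @ self.rotation.T
        if np.any(cam[:, 2] <= 0):
            raise ValueError(f"view {self.image_id}: point behind camera plane")
        u = self.focal_px * cam[:, 0] / cam[:, 2] + self.principal_point[0]
        v = self.focal_px * cam[:, 1] / cam[:, 2] + self.principal_point[1]
        return np.column_stack([u, v])

    def pixel_to_ground(self, uv: np.ndarray, ground_z: float) -> np.ndarray:
        """Intersect the ray through pixel (u, v) with the plane z = ground_z."""
        uv = np.atleast_2d(np.asarray(uv, dtype=float))
        d_cam = np.column_stack(
            [
                (uv[:, 0] - self.principal_point[0]) / self.focal_px,
                (uv[:, 1] - self.principal_point[1]) / self.focal_px,
                np.ones(len(uv)),
            ]
        )
        d_world = d_cam @ self.rotation  # R^T rows applied
        t = (ground_z - self.position[2]) / d_world[:, 2]
        return self.position + t[:, None] * d_world


class FlatElevation:
    """Constant ground elevation (flat plane at height z metres)."""

    def __init__(self, z: float = 0.0):
        self.z = float(z)

    def lookup(self, xy: np.ndarray) -> np.ndarray:
        return np.full(len(np.atleast_2d(xy)), self.z)


class ElevationRaster:
    """Regular-grid ground elevation with nearest-cell lookup.

    An optional 5x5 moving-median smoothing (reflect borders) is offered for
    terrain models that still carry vegetation spikes.
    """

    def __init__(self, values: np.ndarray, x0: float, y0: float, dx: float, dy: float,
                 median_filter: bool = False):
        values = np.asarray(values, dtype=float)
        if median_filter:
            values = ndimage.median_filter(values, size=5, mode="reflect")
        self.values = values
        self.x0, self.y0, self.dx, self.dy = x0, y0, dx, dy

    def lookup(self, xy: np.ndarray) -> np.ndarray:
        xy = np.atleast_2d(np.asarray(xy, dtype=float))
        col = np.round((xy[:, 0] - self.x0) / self.dx).astype(int)
        row = np.round((xy[:, 1] - self.y0) / self.dy).astype(int)
        ny, nx = self.values.shape
        if np.any(col < 0) or np.any(col >= nx) or np.any(row < 0) or np.any(row >= ny):
            raise ValueError("elevation lookup outside raster extent")
        return self.values[row, col]


@dataclass
class PlotImageMask:
    """One plot's outline in one view, plus the plot-frame -> image affine.

    ``affine_mm`` is the 2x3 matrix mapping plot-frame millimetre coordinates
    to image pixel coordinates, fitted by least squares to the projected
    corners.
    """

    image_id: str
    plot_id: str
    polygon_px: np.ndarray
    affine_mm: np.ndarray
    fully_visible: bool
    fit_residual_px: float = 0.0

    @property
    def invertible(self) -> bool:
        return abs(np.linalg.det(self.affine_mm[:, :2])) > 1e-12


def backproject_polygon(plot: PlotPolygon, elevation, view: CameraView) -> PlotImageMask:
    """Project a plot's corners into a view and fit the plot->image affine.

    Corner Z is taken from ``elevation`` unless the corners already carry Z.
    Returns a mask flagged ``fully_visible`` only when every projected corner
    lies inside the image bounds; a corner behind the camera raises.
    """
    xy = plot.corners[:, :2]
    if plot.corners.shape[1] == 3 and np.all(np.isfinite(plot.corners[:, 2])):
        z = plot.corners[:, 2]
    else:
        z = elevation.lookup(xy)
    if not np.all(np.isfinite(z)):
        raise ValueError(f"plot {plot.plot_id}: non-finite corner elevation")
    world = np.column_stack([xy, z])
    px = view.project(world)

    plot_mm = plot.to_plot_mm(xy)
    # least-squares affine fit: [x_mm y_mm 1] @ A.T = [u v]
    design = np.column_stack([plot_mm, np.ones(len(plot_mm))])
    coef, *_ = np.linalg.lstsq(design, px, rcond=None)
    affine = coef.T  # 2x3
    resid = float(np.sqrt(np.mean(np.sum((design @ coef - px) ** 2, axis=1))))
    if resid > _RESIDUAL_WARN_PX:
        warnings.warn(
            f"plot {plot.plot_id} in view {view.image_id}: affine corner residual "
            f"{resid:.2f} px exceeds {_RESIDUAL_WARN_PX} px coregistration precision",
            stacklevel=2,
        )
    w, h = view.image_size
    visible = bool(
        np.all((px[:, 0] >= 0) & (px[:, 0] <= w - 1) & (px[:, 1] >= 0) & (px[:, 1] <= h - 1))
    )
    return PlotImageMask(
        image_id=view.image_id,
        plot_id=plot.plot_id,
        polygon_px=px,
        affine_mm=affine,
        fully_visible=visible,
        fit_residual_px=resid,
    )


def resample_to_plot(
    seg_img: np.ndarray,
    mask: PlotImageMask,
    gsd_mm: float,
    plot_l_mm: float,
    plot_w_mm: float,
    buffered_polygon_mm: np.ndarray | None = None,
) -> np.ndarray:
    """Resample a segmented view into the plot frame at threefold resolution.

    The output grid has ``3·plot_l/GSD × 3·plot_w/GSD`` pixels (effective GSD
    of GSD/3); each output pixel centre is mapped through the plot->image
    affine and sampled nearest-neighbour from ``seg_img`` (oversampling exists
    precisely to absorb the round-off of nearest-neighbour sampling of binary
    masks).  Pixels outside the buffered polygon, or mapping outside the
    source image, carry :data:`MASK_SENTINEL`.

    Parameters
    ----------
    seg_img
        Binary {0, 1} raster in image coordinates.
    mask
        Correspondence produced by :func:`backproject_polygon`.
    gsd_mm
        Nominal ground sampling distance, mm/px.
    plot_l_mm, plot_w_mm
        Plot length (x, sowing-row direction) and width (y) in millimetres.
    buffered_polygon_mm
        Optional buffered-polygon vertices in plot-frame mm; pixels outside
        it are masked.
    """
    if not mask.invertible:
        raise ValueError("plot->image affine is singular")
    nx = int(round(3 * plot_l_mm / gsd_mm))
    ny = int(round(3 * plot_w_mm / gsd_mm))
    if nx <= 0 or ny <= 0:
        raise ValueError("plot-frame output dimensions must be positive")
    step = gsd_mm / 3.0
    x_mm = (np.arange(nx) + 0.5) * step
    y_mm = (np.arange(ny) + 0.5) * step
    gx, gy = np.meshgrid(x_mm, y_mm)
    pts = np.column_stack([gx.ravel(), gy.ravel(), np.ones(gx.size)])
    uv = pts @ mask.affine_mm.T
    col = np.round(uv[:, 0]).astype(int)
    row = np.round(uv[:, 1]).astype(int)
    h, w = seg_img.shape
    inside = (col >= 0) & (col < w) & (row >= 0) & (row < h)

    out = np.full(gx.size, MASK_SENTINEL, dtype=np.int8)
    out[inside] = np.asarray(seg_img, dtype=np.int8)[row[inside], col[inside]]
    out = out.reshape(ny, nx)

    if buffered_polygon_mm is not None:
        import shapely

        poly = Polygon(np.asarray(buffered_polygon_mm, dtype=float))
        keep = shapely.contains_xy(poly, gx.ravel(), gy.ravel())
        out[~keep.reshape(ny, nx)] = MASK_SENTINEL
    return out
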