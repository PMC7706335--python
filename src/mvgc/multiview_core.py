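"""Multiview ground-cover images and their scalar descriptors.

The central product: for each plot, all plot-frame binary segmentations from
overlapping views are averaged pixel-wise,

    mvImg(x, y) = (1 / n_Img) Σ_i segImg_res,i(x, y),

so each pixel carries the *fraction of views* in which it was classified as
plant.  Fractions near 1 mark dense canopy or plant parts close to the
ground; intermediate fractions mark erect or sparse plant parts whose
apparent position moves with the viewing angle.  Two families of scalar
descriptors are derived:

* ground-cover percentiles ``mvGC_i`` — the fraction of pixels whose value
  strictly exceeds a threshold ``i`` (percent of the [0, 1] fraction scale);
* apparent leaf area ``LA = Σ_j mvImg_j²`` — squaring compensates for the
  skew of zenith angles towards off-nadir views typical of drone surveys.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .plot_geometry import MASK_SENTINEL

__all__ = [
    "MultiviewImage",
    "GroundCoverPercentiles",
    "ApparentLeafArea",
    "aggregate",
    "gc_percentiles",
    "apparent_leaf_area",
    "DEFAULT_THRESHOLDS",
    "write_multiview_tiff",
    "read_multiview_tiff",
]

#: ten equally distributed percentile thresholds, percent of full fraction
DEFAULT_THRESHOLDS = tuple(range(10, 101, 10))


@dataclass
class MultiviewImage:
    """Per-plot raster of plant-pixel fractions in the plot frame.

    ``values`` holds fractions in [0, 1]; masked pixels (outside the buffered
    plot polygon) are NaN.  ``effective_gsd_mm`` is the nominal GSD divided
    by the threefold plot-frame oversampling.
    """

    values: np.ndarray
    n_views: int
    plot_id: str | None = None
    campaign: str | None = None
    effective_gsd_mm: float | None = None

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        unmasked = v[np.isfinite(v)]
        if unmasked.size and (unmasked.min() < 0 or unmasked.max() > 1):
            raise ValueError("multiview fractions must lie in [0, 1]")
        if self.n_views < 1:
            raise ValueError("n_views must be >= 1")
        self.values = v

    @property
    def unmasked(self) -> np.ndarray:
        return self.values[np.isfinite(self.values)]


@dataclass(frozen=True)
class GroundCoverPercentiles:
    """mvGC_i values for a set of percent thresholds; nonincreasing in i."""

    thresholds: tuple
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if len(self.thresholds) != len(v):
            raise ValueError("thresholds and values length mismatch")
        if np.any(np.diff(v) > 1e-12):
            raise ValueError("mvGC must be nonincreasing in the threshold")
        object.__setattr__(self, "values", v)

    def as_dict(self) -> dict:
        return {f"mvGC{int(t)}": float(v) for t, v in zip(self.thresholds, self.values)}


@dataclass(frozen=True)
class ApparentLeafArea:
    """Sum of squared fractions, in (effective) pixel² units; optional mm²."""

    la_px: float
    la_mm2: float | None = None


def aggregate(
    masks: list[np.ndarray],
    image_ids: list[str] | None = None,
    per_pixel_denominator: bool = False,
    **meta,
) -> MultiviewImage:
    """Average plot-frame binary masks into a multiview ground-cover image.

    Each mask holds {0, 1} with :data:`~mvgc.plot_geometry.MASK_SENTINEL` for
    pixels outside the buffered polygon.  By default the denominator is the
    single number of views and a pixel is masked if it is masked in *any*
    view (the paper's single-``n_Img`` division; partially visible plots
    should be excluded upstream).  With ``per_pixel_denominator=True`` each
    pixel is averaged over the views in which it is unmasked.
    """
    if not masks:
        raise ValueError("need at least one mask")
    shapes = {m.shape for m in masks}
    if len(shapes) > 1:
        ids = image_ids or [str(i) for i in range(len(masks))]
        bad = [i for i, m in zip(ids, masks) if m.shape != masks[0].shape]
        raise ValueError(f"mask dimension mismatch for images: {bad}")

    stack = np.stack([np.asarray(m) for m in masks])
    valid = stack != MASK_SENTINEL
    # 64-bit accumulation keeps the sums exact
    s = np.where(valid, stack, 0).astype(np.int64).sum(axis=0)
    if per_pixel_denominator:
        n = valid.sum(axis=0)
        with np.errstate(invalid="ignore"):
            out = np.where(n > 0, s / np.maximum(n, 1), np.nan)
    else:
        out = np.where(valid.all(axis=0), s / len(masks), np.nan)
    return MultiviewImage(values=out, n_views=len(masks), **meta)


def gc_percentiles(
    mv: MultiviewImage, thresholds=DEFAULT_THRESHOLDS
) -> GroundCoverPercentiles:
    """Fraction of unmasked pixels strictly above each threshold.

    ``mvGC_i = (1/n) Σ_j [mvImg_j > i/100]`` with ``i`` in percent of the
    [0, 1] fraction scale.  The strict inequality means ``i = 100`` always
    yields 0 — a degenerate but faithful endpoint.
    """
    t = np.asarray(thresholds, dtype=float)
    if np.any(t <= 0) or np.any(t > 100):
        raise ValueError("thresholds must lie in (0, 100]")
    px = mv.unmasked
    if px.size == 0:
        raise ValueError("empty unmasked region")
    vals = np.array([(px > ti / 100.0).mean() for ti in t])
    return GroundCoverPercentiles(thresholds=tuple(thresholds), values=vals)


def apparent_leaf_area(
    mv: MultiviewImage, exponent: float = 2.0
) -> ApparentLeafArea:
    """Apparent leaf area ``LA = Σ_j mvImg_j²`` over unmasked pixels.

    The exponent is configurable for flight plans with other zenith-angle
    distributions; 2 is the default.  When the image records its effective
    GSD the area is also reported in mm².
    """
    px = mv.unmasked
    if px.size == 0:
        raise ValueError("empty unmasked region")
    la = float(np.sum(px**exponent))
    la_mm2 = la * mv.effective_gsd_mm**2 if mv.effective_gsd_mm else None
    return ApparentLeafArea(la_px=la, la_mm2=la_mm2)


def write_multiview_tiff(mv: MultiviewImage, path) -> None:
    """Persist as single-band float TIFF plus a JSON sidecar with metadata."""
    import json
    from pathlib import Path

    import tifffile

    path = Path(path)
    tifffile.imwrite(path, mv.values.astype(np.float32))
    sidecar = {
        "plot_id": mv.plot_id,
        "campaign": mv.campaign,
        "n_views": mv.n_views,
        "effective_gsd_mm": mv.effective_gsd_mm,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def read_multiview_tiff(path) -> MultiviewImage:
    import json
    from pathlib import Path

    import tifffile

    path = Path(path)
    values = tifffile.imread(path).astype(float)
    meta = json.loads(path.with_suffix(".json").read_text())
    return MultiviewImage(values=values, **meta)
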