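"""Plant/soil pixel classification with Bayer-aware colour features.

Seedling-stage wheat leaves are only a few millimetres wide; at a ground
sampling distance of ~3 mm most plant pixels are mixed pixels, and the
camera's Bayer mosaic means only half the sensor sites measured green
directly.  The classifier therefore works only at green Bayer positions:
red and blue are interpolated there from the two adjacent same-channel
sites, and each green position carries 17 predictors — R, G, B plus four
derived colour spaces (XYZ, nonlinear sRGB, HSV, CIE L*a*b*) and the
plant-sensitive indices ExG and ExR.  An ensemble (random-forest)
classifier predicts plant vs. soil per green position; missing red/blue
positions are filled and speckle noise removed with a 3x3 morphological
opening, yielding a full-resolution binary segmentation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import joblib
import numpy as np
from scipy import ndimage
from skimage import color, morphology

__all__ = [
    "BAYER_PATTERNS",
    "ColorFeatureStack",
    "PixelClassifier",
    "SegmentedImage",
    "extract_color_features",
    "train_classifier",
    "segment_image",
    "excess_green",
    "excess_red",
    "DEFAULT_HYPERPARAMS",
]

BAYER_PATTERNS = ("RGGB", "BGGR", "GRBG", "GBRG")

FEATURE_NAMES = [
    "R", "G", "B",
    "X", "Y", "Z",
    "sR", "sG", "sB",
    "H", "S", "V",
    "L*", "a*", "b*",
    "ExR", "ExG",
]

#: hyperparameters of the plant/soil ensemble
DEFAULT_HYPERPARAMS = {
    "n_estimators": 55,
    "min_samples_split": 4,
    "min_samples_leaf": 6,
    "max_features": 6,
    "max_depth": 95,
}


def excess_green(rgb01: np.ndarray) -> np.ndarray:
    """ExG = 2g − r − b on sum-normalised chromatic coordinates."""
    s = rgb01.sum(axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        chrom = np.where(s[..., None] > 0, rgb01 / np.maximum(s[..., None], 1e-12), 1 / 3)
    return 2 * chrom[..., 1] - chrom[..., 0] - chrom[..., 2]


def excess_red(rgb01: np.ndarray) -> np.ndarray:
    """ExR = 1.4r − g on sum-normalised chromatic coordinates."""
    s = rgb01.sum(axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        chrom = np.where(s[..., None] > 0, rgb01 / np.maximum(s[..., None], 1e-12), 1 / 3)
    return 1.4 * chrom[..., 0] - chrom[..., 1]


@dataclass
class ColorFeatureStack:
    """Per-green-Bayer-position feature matrix plus placement indices."""

    features: np.ndarray  # (n_green, 17)
    rows: np.ndarray
    cols: np.ndarray
    image_shape: tuple[int, int]
    bit_depth: int = 12

    def __post_init__(self) -> None:
        if self.features.shape[1] != len(FEATURE_NAMES):
            raise ValueError(f"expected {len(FEATURE_NAMES)} features")
        if not np.all(np.isfinite(self.features)):
            raise ValueError("non-finite colour features")


def _pattern_grid(bayer_pattern: str) -> np.ndarray:
    if bayer_pattern not in BAYER_PATTERNS:
        raise ValueError(f"unknown Bayer pattern {bayer_pattern!r}; expected one of {BAYER_PATTERNS}")
    return np.array(list(bayer_pattern)).reshape(2, 2)


def _interpolate_rb(mosaic: np.ndarray, bayer_pattern: str):
    """Return (R, G, B) at green positions of a single-channel Bayer mosaic.

    At each green site the missing red (blue) value is the mean of the two
    adjacent red (blue) sites, which lie either horizontally or vertically
    depending on the green site's row within the 2x2 pattern.  Borders are
    edge-padded.
    """
    grid = _pattern_grid(bayer_pattern)
    h, w = mosaic.shape
    pad = np.pad(mosaic.astype(float), 1, mode="edge")
    rows_g, cols_g = [], []
    r_vals, g_vals, b_vals = [], [], []
    for pr in range(2):
        for pc in range(2):
            if grid[pr, pc] != "G":
                continue
            horiz_channel = grid[pr, 1 - pc]   # neighbour in the same pattern row
            rr = np.arange(pr, h, 2)
            cc = np.arange(pc, w, 2)
            R, C = np.meshgrid(rr, cc, indexing="ij")
            g = mosaic[R, C].astype(float)
            horiz = 0.5 * (pad[R + 1, C] + pad[R + 1, C + 2])
            vert = 0.5 * (pad[R, C + 1] + pad[R + 2, C + 1])
            if horiz_channel == "R":
                r, b = horiz, vert
            else:
                r, b = vert, horiz
            rows_g.append(R.ravel())
            cols_g.append(C.ravel())
            r_vals.append(r.ravel())
            g_vals.append(g.ravel())
            b_vals.append(b.ravel())
    rows = np.concatenate(rows_g)
    cols = np.concatenate(cols_g)
    order = np.lexsort((cols, rows))
    return (
        np.concatenate(r_vals)[order],
        np.concatenate(g_vals)[order],
        np.concatenate(b_vals)[order],
        rows[order],
        cols[order],
    )


def extract_color_features(
    rgb: np.ndarray, bayer_pattern: str = "RGGB", bit_depth: int = 12
) -> ColorFeatureStack:
    """Compute the 17 colour predictors at green Bayer positions.

    ``rgb`` may be a raw single-channel Bayer mosaic (H, W) or an already
    demosaiced 3-channel image (H, W, 3); in the latter case the declared
    pattern acts as a virtual mosaic, preserving the green-position
    subsampling semantics.  8-bit input is accepted and rescaled.
    """
    rgb = np.asarray(rgb)
    if bit_depth not in (8, 12, 16):
        raise ValueError("bit_depth must be 8, 12 or 16")
    scale = float(2**bit_depth - 1)

    if rgb.ndim == 3:
        grid = _pattern_grid(bayer_pattern)
        chan = {"R": 0, "G": 1, "B": 2}
        mosaic = np.empty(rgb.shape[:2], dtype=float)
        for pr in range(2):
            for pc in range(2):
                mosaic[pr::2, pc::2] = rgb[pr::2, pc::2, chan[grid[pr, pc]]]
    elif rgb.ndim == 2:
        mosaic = rgb.astype(float)
    else:
        raise ValueError("rgb must be (H, W) mosaic or (H, W, 3) image")

    r, g, b, rows, cols = _interpolate_rb(mosaic, bayer_pattern)
    rgb01 = np.column_stack([r, g, b]) / scale

    px = rgb01[None, :, :]  # (1, n, 3) pseudo-image for skimage conversions
    xyz = color.rgb2xyz(px)[0]
    srgb_nonlinear = _linear_to_srgb(rgb01)
    hsv = color.rgb2hsv(px)[0]
    lab = color.rgb2lab(px)[0]

    feats = np.column_stack(
        [
            rgb01,
            xyz,
            srgb_nonlinear,
            hsv,
            lab,
            excess_red(rgb01),
            excess_green(rgb01),
        ]
    )
    return ColorFeatureStack(
        features=feats, rows=rows, cols=cols, image_shape=mosaic.shape, bit_depth=bit_depth
    )


def _linear_to_srgb(rgb01: np.ndarray) -> np.ndarray:
    """Gamma-encode linear camera RGB to nonlinear sRGB (D65)."""
    a = 0.055
    return np.where(rgb01 <= 0.0031308, 12.92 * rgb01, (1 + a) * np.power(np.maximum(rgb01, 0), 1 / 2.4) - a)


@dataclass
class PixelClassifier:
    """Trained plant/soil ensemble plus its provenance."""

    model: Any
    hyperparams: dict
    n_samples: int
    class_balance: dict
    oob_score: float | None = None
    feature_names: tuple = tuple(FEATURE_NAMES)

    def save(self, path) -> None:
        joblib.dump(
            {
                "model": self.model,
                "hyperparams": self.hyperparams,
                "n_samples": self.n_samples,
                "class_balance": self.class_balance,
                "oob_score": self.oob_score,
                "feature_names": self.feature_names,
            },
            path,
        )

    @classmethod
    def load(cls, path) -> "PixelClassifier":
        d = joblib.load(path)
        return cls(**d)


def train_classifier(
    features: np.ndarray,
    labels: np.ndarray,
    hyperparams: dict | None = None,
    seed: int = 17,
) -> PixelClassifier:
    """Train the plant/soil random forest.

    Labels are {0 soil, 1 plant}; both classes must be present.  Out-of-bag
    accuracy is recorded as a built-in validation estimate.
    """
    from sklearn.ensemble import RandomForestClassifier

    features = np.asarray(features, dtype=float)
    labels = np.asarray(labels).astype(int)
    classes, counts = np.unique(labels, return_counts=True)
    if len(classes) < 2:
        raise ValueError("training set contains a single class; need plant and soil samples")
    hp = dict(DEFAULT_HYPERPARAMS)
    if hyperparams:
        hp.update(hyperparams)
    hp["max_features"] = min(hp["max_features"], features.shape[1])
    rf = RandomForestClassifier(random_state=seed, oob_score=True, bootstrap=True, **hp)
    rf.fit(features, labels)
    return PixelClassifier(
        model=rf,
        hyperparams=hp,
        n_samples=len(labels),
        class_balance={int(c): int(n) for c, n in zip(classes, counts)},
        oob_score=float(rf.oob_score_),
    )


def segment_image(
    rgb: np.ndarray,
    model: PixelClassifier,
    bayer_pattern: str = "RGGB",
    bit_depth: int = 12,
) -> "SegmentedImage":
    """Segment an image into a full-resolution binary plant/soil raster.

    Predictions are made at green Bayer positions only; the missing red/blue
    positions are filled from their 3x3 neighbourhood and one binary opening
    with a 3x3 structuring element removes isolated speckle.
    """
    stack = extract_color_features(rgb, bayer_pattern=bayer_pattern, bit_depth=bit_depth)
    pred = model.model.predict(stack.features).astype(np.uint8)

    sparse = np.zeros(stack.image_shape, dtype=np.uint8)
    sparse[stack.rows, stack.cols] = pred
    green_mask = np.zeros(stack.image_shape, dtype=bool)
    green_mask[stack.rows, stack.cols] = True

    # fill non-green positions from the neighbourhood maximum of green predictions
    filled = ndimage.maximum_filter(sparse, size=3)
    full = np.where(green_mask, sparse, filled)

    opened = morphology.opening(full.astype(bool), footprint=np.ones((3, 3), bool))
    return SegmentedImage(binary=opened.astype(np.uint8), image_id=None, classifier_meta=model.hyperparams)


@dataclass
class SegmentedImage:
    """Binary {0 soil, 1 plant} raster aligned to its source image."""

    binary: np.ndarray
    image_id: str | None = None
    classifier_meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        vals = np.unique(self.binary)
        if not np.all(np.isin(vals, [0, 1])):
            raise ValueError("segmented image must be binary {0, 1}")
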