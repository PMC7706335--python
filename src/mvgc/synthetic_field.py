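"""Synthetic wheat-nursery simulator: the ground-truth oracle for the pipeline.

Simulates a seedling-stage winter-wheat trial from first principles of
cereal ontogeny:

* main-stem leaf number grows linearly in thermal time,
  ``N_l,MS = (GDD − t0) / P`` with phyllochron ``P`` (°C·day per leaf) and
  emergence thermal time ``t0``;
* the n-th tiller carries ``N_l,Ti_n = a·N_l,MS − b·n`` leaves and exists
  only while that number is positive — tillering starts once the main stem
  has enough leaves and later tillers appear successively;
* assuming equal single-leaf area ``A_l`` before stem elongation, plot leaf
  area is ``LA = Σ_plants A_l · (N_l,MS + Σ_n N_l,Ti_n)``.

Plants are placed along sowing rows (default 0.125 m spacing) by a
Poisson process with optional clumping.  Rendering stamps each plant as a
flat-top disk whose area matches its current leaf area; per-view the disk
centre is jittered by a view-dependent offset emulating the parallax of
erect leaves, so that averaging many views produces the fractional-cover
signature the multiview method exploits.  Trials add genotype effects,
replication structure and a smooth spatial trend, and export the truth
tables every pipeline stage is validated against.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .multiview_core import MultiviewImage, aggregate
from .plot_geometry import MASK_SENTINEL

__all__ = [
    "GenotypeParams",
    "SimPlant",
    "FieldTruth",
    "single_leaf_area",
    "leaves_main_stem",
    "tiller_leaves",
    "shoots_and_leaf_area",
    "simulate_canopy",
    "render_views",
    "render_plot_views",
    "make_trial",
    "percentile_trajectories",
]

#: leaf-shape factor for LA = length × width × factor
LEAF_SHAPE_FACTOR = 0.835

#: default sowing-row spacing, metres
ROW_SPACING_M = 0.125


def single_leaf_area(length_mm: float, width_mm: float) -> float:
    """Single-leaf area from length and maximum width: ``L × W × 0.835`` mm²."""
    if length_mm <= 0 or width_mm <= 0:
        raise ValueError("leaf length and width must be > 0")
    return length_mm * width_mm * LEAF_SHAPE_FACTOR


@dataclass(frozen=True)
class GenotypeParams:
    """Genotype-specific ontogeny parameters.

    ``tiller_a``/``tiller_b`` govern tiller appearance (the n-th tiller
    exists while ``a·N_l,MS − b·n > 0``); they are treated as
    genotype-independent constants by default.
    """

    name: str
    phyllochron: float          # °C·day per leaf
    t0: float                   # emergence, °C·day
    leaf_area_mm2: float        # single-leaf area A_l
    gs30_gdd: float             # thermal time at beginning of stem elongation
    tiller_a: float = 1.0
    tiller_b: float = 2.5
    max_shoots: int | None = None

    def __post_init__(self) -> None:
        if self.phyllochron <= 0:
            raise ValueError("phyllochron must be > 0")
        if self.t0 < 0:
            raise ValueError("emergence thermal time must be >= 0")
        if self.leaf_area_mm2 <= 0:
            raise ValueError("single-leaf area must be > 0")
        if self.gs30_gdd <= self.t0:
            raise ValueError("GS30 must come after emergence")


def leaves_main_stem(gdd, params: GenotypeParams):
    """Main-stem leaf number ``(GDD − t0)/P``, clamped at 0 before emergence."""
    g = np.asarray(gdd, dtype=float)
    return np.maximum((g - params.t0) / params.phyllochron, 0.0)


def tiller_leaves(n_l_ms, params: GenotypeParams, max_tillers: int = 40):
    """Leaves per existing tiller at a given main-stem leaf number.

    Tiller n carries ``a·N_l,MS − b·n`` leaves and exists only while that is
    positive.  Returns an array of per-tiller leaf counts (may be empty).
    """
    counts = []
    for n in range(1, max_tillers + 1):
        leaves = params.tiller_a * float(n_l_ms) - params.tiller_b * n
        if leaves <= 0:
            break
        counts.append(leaves)
    return np.asarray(counts)


def shoots_and_leaf_area(gdd, params: GenotypeParams) -> tuple[int, float]:
    """(shoot count, plant leaf area mm²) of one plant at thermal time ``gdd``."""
    n_ms = float(leaves_main_stem(gdd, params))
    if n_ms <= 0:
        return 0, 0.0
    tl = tiller_leaves(n_ms, params)
    n_shoots = 1 + len(tl)
    if params.max_shoots is not None and n_shoots > params.max_shoots:
        tl = tl[: params.max_shoots - 1]
        n_shoots = params.max_shoots
    la = params.leaf_area_mm2 * (n_ms + float(tl.sum()))
    return n_shoots, la


@dataclass
class SimPlant:
    """A simulated plant: position in the plot frame plus its genotype."""

    plot_id: str
    x_mm: float
    y_mm: float
    genotype: GenotypeParams
    emergence_jitter_gdd: float = 0.0

    def state(self, gdd: float) -> tuple[int, float]:
        shifted = replace(self.genotype, t0=self.genotype.t0 + self.emergence_jitter_gdd) \
            if self.emergence_jitter_gdd else self.genotype
        return shoots_and_leaf_area(gdd, shifted)


@dataclass
class FieldTruth:
    """Ground truth for a simulated trial (the acceptance oracle)."""

    plants: pd.DataFrame          # plot_id, x_mm, y_mm, genotype
    plots: pd.DataFrame           # plot_id, genotype, rep, year_site, row, range, x, y, n_plants, gs30_gdd
    shoot_series: pd.DataFrame    # plot_id, gdd, delta_gdd, shoots, leaf_area_mm2
    genotype_params: dict
    spatial_trend: pd.DataFrame | None = None


def _place_plants(
    rng: np.random.Generator,
    plot_l_mm: float,
    plot_w_mm: float,
    n_rows: int,
    density_per_m: float,
    clumping: float,
) -> np.ndarray:
    """Plant positions along sowing rows, Poisson with optional clumping.

    ``clumping`` in [0, 1): fraction of plants placed as close satellites of
    another plant (emulating double seeds / clustered emergence).
    """
    rows_y = (np.arange(n_rows) + 0.5) * plot_w_mm / n_rows
    pts = []
    for y in rows_y:
        n = rng.poisson(density_per_m * plot_l_mm / 1000.0)
        x = rng.uniform(0, plot_l_mm, size=n)
        pts.append(np.column_stack([x, np.full(n, y)]))
    pts = np.vstack(pts) if pts else np.empty((0, 2))
    if clumping > 0 and len(pts) > 0:
        n_extra = rng.binomial(len(pts), clumping)
        parents = pts[rng.integers(0, len(pts), size=n_extra)]
        offsets = rng.normal(0, 12.0, size=(n_extra, 2))  # ~12 mm satellite spread
        extra = parents + offsets
        extra[:, 0] = np.clip(extra[:, 0], 0, plot_l_mm)
        extra[:, 1] = np.clip(extra[:, 1], 0, plot_w_mm)
        pts = np.vstack([pts, extra])
    return pts


def simulate_canopy(
    genotype: GenotypeParams,
    gdd_grid: np.ndarray,
    seed: int,
    plot_id: str = "plot",
    plot_l_mm: float = 1000.0,
    plot_w_mm: float = 375.0,
    n_rows: int = 3,
    density_per_m: float = 35.0,
    clumping: float = 0.2,
    emergence_jitter_sd: float = 15.0,
) -> tuple[list[SimPlant], pd.DataFrame]:
    """Simulate one plot: plant placement plus per-GDD shoot and leaf-area truth.

    Returns the plant list and a truth frame with per-campaign plot totals.
    Doubling ``leaf_area_mm2`` doubles plot leaf area exactly (leaf area is
    linear in ``A_l``); shoot counts are nondecreasing in GDD before GS30.
    """
    rng = np.random.default_rng(seed)
    pts = _place_plants(rng, plot_l_mm, plot_w_mm, n_rows, density_per_m, clumping)
    plants = [
        SimPlant(
            plot_id=plot_id,
            x_mm=float(x),
            y_mm=float(y),
            genotype=genotype,
            emergence_jitter_gdd=float(rng.normal(0, emergence_jitter_sd)),
        )
        for x, y in pts
    ]
    rows = []
    for gdd in np.asarray(gdd_grid, dtype=float):
        shoots = 0
        la = 0.0
        for p in plants:
            s, a = p.state(gdd)
            shoots += s
            la += a
        rows.append((plot_id, gdd, gdd - genotype.gs30_gdd, shoots, la, len(plants)))
    truth = pd.DataFrame(
        rows, columns=["plot_id", "gdd", "delta_gdd", "shoots", "leaf_area_mm2", "n_plants"]
    )
    return plants, truth


def _stamp_disk(img: np.ndarray, cx: float, cy: float, radius_px: float) -> None:
    """Set pixels within ``radius_px`` of (cx, cy) to 1, truncated at borders."""
    h, w = img.shape
    r = int(np.ceil(radius_px))
    x0, x1 = max(int(cx) - r, 0), min(int(cx) + r + 1, w)
    y0, y1 = max(int(cy) - r, 0), min(int(cy) + r + 1, h)
    if x0 >= x1 or y0 >= y1:
        return
    yy, xx = np.mgrid[y0:y1, x0:x1]
    img[y0:y1, x0:x1] |= ((xx - cx) ** 2 + (yy - cy) ** 2 <= radius_px**2)


def render_plot_views(
    plants: list[SimPlant],
    gdd: float,
    n_views: int,
    seed: int,
    plot_l_mm: float = 1000.0,
    plot_w_mm: float = 375.0,
    effective_gsd_mm: float = 1.0,
    erectness_jitter_px: float = 2.0,
) -> list[np.ndarray]:
    """Render one plot at one campaign as per-view binary plot-frame masks.

    Each plant becomes a flat-top disk whose area equals its current leaf
    area; per view the disk centre is offset by a zero-mean jitter whose
    magnitude models leaf erectness under the view's zenith angle.  With
    zero jitter all views are identical and the multiview aggregate is
    binary; with jitter the aggregate develops the fractional annulus
    characteristic of erect plant parts.
    """
    rng = np.random.default_rng(seed)
    nx = int(round(plot_l_mm / effective_gsd_mm))
    ny = int(round(plot_w_mm / effective_gsd_mm))
    states = [p.state(gdd) for p in plants]
    masks = []
    for _ in range(n_views):
        img = np.zeros((ny, nx), dtype=bool)
        for p, (shoots, la) in zip(plants, states):
            if la <= 0:
                continue
            radius_mm = np.sqrt(la / np.pi)
            jitter = rng.normal(0, erectness_jitter_px, size=2) if erectness_jitter_px > 0 else (0, 0)
            _stamp_disk(
                img,
                p.x_mm / effective_gsd_mm + jitter[0],
                p.y_mm / effective_gsd_mm + jitter[1],
                radius_mm / effective_gsd_mm,
            )
        masks.append(img.astype(np.int8))
    return masks


def render_views(
    plants: list[SimPlant],
    gdd: float,
    n_views: int = 40,
    seed: int = 0,
    **kwargs,
) -> tuple[MultiviewImage, list[np.ndarray]]:
    """Render per-view masks and return their multiview aggregate plus the masks."""
    masks = render_plot_views(plants, gdd, n_views, seed, **kwargs)
    mv = aggregate(masks, effective_gsd_mm=kwargs.get("effective_gsd_mm", 1.0))
    return mv, masks


# ---------------------------------------------------------------------------
# Trial-level generator
# ---------------------------------------------------------------------------

#: Parameter spreads of the elite genotype set emulated by default:
#: phyllochron central band 70–80 °C·day per leaf, emergence 75–140 °C·day,
#: single-leaf area 300–380 mm²; GS30 spread defaults to 20 days.
DEFAULT_PARAM_RANGES = {
    "phyllochron": (70.0, 80.0),
    "t0": (75.0, 140.0),
    "leaf_area_mm2": (300.0, 380.0),
}

#: mean thermal-time accumulation per calendar day in early spring, °C·day
#: (daily means of 5-8 °C during the tillering window of temperate sites)
GDD_PER_DAY = 6.0


def make_trial(
    n_genotypes: int = 4,
    n_reps: int = 2,
    year_sites: tuple = ("Y1",),
    n_campaigns: int = 6,
    gs30_mean_gdd: float = 612.0,
    gs30_spread_days: float = 20.0,
    spatial_trend_sd: float = 0.0,
    seed: int = 1,
    param_ranges: dict | None = None,
) -> FieldTruth:
    """Generate a full trial: design, genotype parameters, truth tables, schedule.

    Genotype parameters are drawn once per genotype from the configured
    ranges; each plot inherits its genotype's parameters. Campaigns are
    scheduled at two per week (every 3.5 days, ``GDD_PER_DAY`` °C·day per
    day) covering the tillering window up to shortly after the latest GS30.
    The same seed reproduces the trial bit-identically.
    """
    rng = np.random.default_rng(seed)
    pr = dict(DEFAULT_PARAM_RANGES)
    if param_ranges:
        pr.update(param_ranges)
    spread_gdd = gs30_spread_days * GDD_PER_DAY

    genos = {}
    for i in range(n_genotypes):
        name = f"G{i + 1:02d}"
        genos[name] = GenotypeParams(
            name=name,
            phyllochron=rng.uniform(*pr["phyllochron"]),
            t0=rng.uniform(*pr["t0"]),
            leaf_area_mm2=rng.uniform(*pr["leaf_area_mm2"]),
            gs30_gdd=gs30_mean_gdd + rng.uniform(-0.5, 0.5) * spread_gdd,
        )

    # campaign schedule: two flights per week, ending shortly after the last
    # genotype reaches stem elongation and reaching back through tillering
    last_gs30 = max(g.gs30_gdd for g in genos.values())
    step = 3.5 * GDD_PER_DAY
    gdd_grid = last_gs30 + 30.0 - step * np.arange(max(n_campaigns, 2))[::-1]
    gdd_grid = gdd_grid[gdd_grid > 100.0]

    plot_rows, plant_rows, series_rows = [], [], []
    plants_by_plot = {}
    for ys in year_sites:
        order = []
        for rep in range(1, n_reps + 1):
            perm = rng.permutation(sorted(genos))
            order.extend((rep, g) for g in perm)
        for k, (rep, gname) in enumerate(order):
            rng_idx = k % n_genotypes  # position within the rep block
            plot_id = f"{ys}_r{rep}_{gname}"
            plants, truth = simulate_canopy(
                genos[gname],
                gdd_grid,
                seed=int(rng.integers(0, 2**31 - 1)),
                plot_id=plot_id,
                # emergence success varies plot to plot (seed lots, seedbed)
                density_per_m=rng.uniform(18.0, 50.0),
            )
            plants_by_plot[plot_id] = plants
            x = rng_idx * 1.1
            y = (rep - 1) * 0.45
            plot_rows.append(
                (plot_id, gname, rep, ys, rep, rng_idx + 1, x, y,
                 len(plants), genos[gname].gs30_gdd)
            )
            for p in plants:
                plant_rows.append((plot_id, p.x_mm, p.y_mm, gname))
            series_rows.append(truth)

    plots = pd.DataFrame(
        plot_rows,
        columns=["plot_id", "genotype", "rep", "year_site", "row", "range",
                 "x", "y", "n_plants", "gs30_gdd"],
    )
    spatial = None
    if spatial_trend_sd > 0:
        span = max(plots["x"].max() - plots["x"].min(), 1e-9)
        trend = spatial_trend_sd * (plots["x"] - plots["x"].mean()) / span * 2.0
        spatial = plots[["plot_id"]].assign(trend=trend.to_numpy())
    truth = FieldTruth(
        plants=pd.DataFrame(plant_rows, columns=["plot_id", "x_mm", "y_mm", "genotype"]),
        plots=plots,
        shoot_series=pd.concat(series_rows, ignore_index=True),
        genotype_params=genos,
        spatial_trend=spatial,
    )
    truth.plants_by_plot = plants_by_plot  # runtime handle for rendering
    truth.gdd_grid = gdd_grid
    return truth


def percentile_trajectories(
    delta_gdd: np.ndarray,
    noise_sd: float = 0.0,
    seed: int = 0,
    thresholds=tuple(range(10, 101, 10)),
) -> pd.DataFrame:
    """Deterministic ground-cover percentile curves on a ΔGDD_GS30 axis.

    Emulates the structural signal the GS30 regressor learns: each
    percentile follows a smooth monotone curve of ΔGDD (cover rises and its
    upper percentiles lag the lower ones through pseudostem erection), with
    optional i.i.d. Gaussian noise.  Values are clipped to [0, 1]; columns
    are ``mvGC10..mvGC100``.
    """
    rng = np.random.default_rng(seed)
    dg = np.asarray(delta_gdd, dtype=float)
    out = {}
    for t in thresholds:
        # pseudostem erection: percentile distribution shifts rapidly around
        # GS30, the higher thresholds responding later and less strongly
        amp = 0.55 * (1.0 - (t / 100.0) ** 1.3)
        center = (t / 100.0 - 0.5) * 30.0
        curve = amp / (1.0 + np.exp(-(dg - center) / 8.0))
        noisy = curve + rng.normal(0, noise_sd, size=dg.shape)
        out[f"mvGC{int(t)}"] = np.clip(noisy, 0.0, 1.0)
    return pd.DataFrame(out)
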