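"""Time-point and intermediate-level traits from multiview descriptors.

Three trait families are extracted from multiview ground-cover images:

* **GS30 index** — a support-vector regressor maps the ten ground-cover
  percentiles of a plot/campaign to its thermal time relative to stem
  elongation (ΔGDD_GS30); per plot, a linear fit of the index against
  campaign GDD is intersected with zero to date GS30.
* **Plant count** — local maxima of the multiview image seed a watershed on
  the inverted fraction landscape; region areas are converted to plant
  counts through a calibrated linear relation, N̂ = Σ_j (a_W·A_j + b_W).
* **Shoot count** — apparent leaf area relates to shoot number through a
  logistic curve whose midpoint and scale drift linearly with ΔGDD_GS30;
  inverting the curve turns per-campaign leaf areas into shoot counts, and
  an inverse-exponential model N_S,t = N_S − exp(−a·ΔGDD) fitted over
  −200 ≤ ΔGDD < 0 summarises them into a final shoot count and a tillering
  rate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .multiview_core import DEFAULT_THRESHOLDS, MultiviewImage

__all__ = [
    "Gs30Model",
    "WatershedConfig",
    "LAShootModel",
    "ShootDynamics",
    "train_gs30",
    "predict_gs30_index",
    "gs30_timepoint",
    "watershed_labels",
    "watershed_regions",
    "calibrate_watershed",
    "predict_plant_count",
    "fit_la_shoot_model",
    "logistic_la",
    "shoots_from_la",
    "fit_shoot_dynamics",
    "plant_count_trait",
    "error_metrics",
]

_RNG_OFFSET_FITS = 9221  # substream offset for multi-start initial values


# ---------------------------------------------------------------------------
# GS30 index
# ---------------------------------------------------------------------------

@dataclass
class Gs30Model:
    """RBF support-vector regressor from percentile vectors to ΔGDD_GS30."""

    svr: object
    cost: float
    gamma: float
    window: float
    feature_schema: tuple
    response_range: tuple
    cv_report: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.cost <= 0 or self.gamma <= 0:
            raise ValueError("cost and gamma must be > 0")
        if len(self.feature_schema) != 10:
            raise ValueError("feature schema must list the 10 percentile features")


def _schema_names(thresholds=DEFAULT_THRESHOLDS) -> tuple:
    return tuple(f"mvGC{int(t)}" for t in thresholds)


def train_gs30(
    features: pd.DataFrame,
    response: np.ndarray,
    window: float = 20.0,
    cost: float = 32.0,
    gamma: float = 0.125,
    genotype: np.ndarray | None = None,
    year_site: np.ndarray | None = None,
    min_samples: int = 20,
) -> Gs30Model:
    """Train the GS30 support-vector regressor on percentile/ΔGDD pairs.

    Pairs are filtered to ``|ΔGDD_GS30| <= window`` (default ±20 °C·day, the
    band where the pseudostem-erection signal is informative).  When grouping
    labels are given, grouped cross-validation reports RMSE/rRMSE for unseen
    genotypes (10-fold) and unseen year-sites (3-fold).
    """
    from sklearn.model_selection import GroupKFold
    from sklearn.svm import SVR

    schema = _schema_names()
    if list(features.columns) != list(schema):
        raise ValueError(f"feature columns must be exactly {schema}")
    y = np.asarray(response, dtype=float)
    keep = np.abs(y) <= window
    if keep.sum() == 0:
        raise ValueError(
            f"no samples inside ±{window} GDD window "
            f"(response range {y.min():.1f}..{y.max():.1f})"
        )
    if keep.sum() < min_samples:
        raise ValueError(f"only {keep.sum()} samples inside ±{window} GDD; need >= {min_samples}")
    X, y = features.to_numpy(dtype=float)[keep], y[keep]

    svr = SVR(kernel="rbf", C=cost, gamma=gamma)
    svr.fit(X, y)

    cv_report = {}
    span = max(np.ptp(y), 1e-9)
    for label, groups, k in (("genotype", genotype, 10), ("year_site", year_site, 3)):
        if groups is None:
            continue
        g = np.asarray(groups)[keep]
        k_eff = min(k, len(np.unique(g)))
        if k_eff < 2:
            continue
        preds = np.full(len(y), np.nan)
        for tr, te in GroupKFold(n_splits=k_eff).split(X, y, groups=g):
            m = SVR(kernel="rbf", C=cost, gamma=gamma).fit(X[tr], y[tr])
            preds[te] = m.predict(X[te])
        rmse = float(np.sqrt(np.mean((y - preds) ** 2)))
        cv_report[label] = {"k": k_eff, "rmse": rmse, "rrmse": rmse / span}

    return Gs30Model(
        svr=svr,
        cost=cost,
        gamma=gamma,
        window=window,
        feature_schema=schema,
        response_range=(float(y.min()), float(y.max())),
        cv_report=cv_report,
    )


def predict_gs30_index(model: Gs30Model, features: pd.DataFrame) -> np.ndarray:
    """Predict ΔGDD_GS30 per plot/campaign from percentile features.

    Predictions are clamped to the training response range: percentile
    vectors far from the training manifold (e.g. bare soil) must not
    extrapolate beyond thermal times the model has seen.
    """
    if list(features.columns) != list(model.feature_schema):
        raise ValueError(
            f"feature schema mismatch: expected {model.feature_schema}, "
            f"got {tuple(features.columns)}"
        )
    raw = model.svr.predict(features.to_numpy(dtype=float))
    lo, hi = model.response_range
    return np.clip(raw, lo, hi)


def gs30_timepoint(
    estimates: pd.DataFrame,
    repeatability_by_campaign: dict | None = None,
    min_repeatability: float = 0.5,
    window: float | None = 20.0,
    plateau_tol: float | None = None,
) -> pd.DataFrame:
    """Date GS30 per plot by intersecting the index trajectory with zero.

    ``estimates`` needs columns ``plot_id``, ``campaign``, ``gdd``,
    ``estimate`` (the ΔGDD_GS30 index).  Campaigns whose repeatability falls
    below ``min_repeatability`` are dropped, estimates outside ``±window``
    are dropped, and per plot a line ``estimate = a·GDD + b`` is fitted;
    GS30 = −b/a.  Plots with a nonpositive slope are flagged unresolvable,
    plots with fewer than two retained campaigns are returned missing.

    Because the regressor is trained inside a ±window band, its index
    saturates for campaigns far outside it; saturated campaigns carry no
    timing information and would flatten the fitted line.  Campaigns on such
    plateaus — where the index changes by less than ``plateau_tol`` (default
    2% of the plot's index range, so the rule is invariant to the index
    amplitude) against both neighbouring campaigns — are excluded, and the
    line is fitted locally, within ±2 windows of the campaign whose index is
    nearest zero.

    Returns a frame with columns ``plot_id, gs30_gdd, r2, n_campaigns, flag``.
    """
    df = estimates.copy()
    if repeatability_by_campaign is not None:
        ok = df["campaign"].map(lambda c: repeatability_by_campaign.get(c, 1.0))
        df = df[ok >= min_repeatability]
    if window is not None:
        df = df[np.abs(df["estimate"]) <= window]

    halfwidth = 2.0 * (window if window is not None else 25.0)

    def _responsive(grp: pd.DataFrame) -> pd.DataFrame:
        grp = grp.sort_values("gdd")
        # drop plateau campaigns: the index no longer responds to thermal time
        est = grp["estimate"].to_numpy()
        tol = plateau_tol if plateau_tol is not None else 0.02 * np.ptp(est)
        d = np.abs(np.diff(est))
        live = np.zeros(len(grp), dtype=bool)
        live[:-1] |= d > tol
        live[1:] |= d > tol
        grp = grp[live] if live.any() else grp.iloc[:0]
        if len(grp) < 2:
            return grp
        # localise the fit around the campaign nearest the zero crossing
        t_star = grp["gdd"].to_numpy()[np.argmin(np.abs(grp["estimate"].to_numpy()))]
        return grp[np.abs(grp["gdd"] - t_star) <= halfwidth]

    rows = []
    for plot_id, grp in df.groupby("plot_id", sort=True):
        grp = _responsive(grp)
        if len(grp) < 2 or grp["gdd"].nunique() < 2:
            rows.append((plot_id, np.nan, np.nan, len(grp), "too_few_campaigns"))
            continue
        fit = stats.linregress(grp["gdd"], grp["estimate"])
        if fit.slope <= 0:
            rows.append((plot_id, np.nan, fit.rvalue**2, len(grp), "nonpositive_slope"))
            continue
        rows.append((plot_id, -fit.intercept / fit.slope, fit.rvalue**2, len(grp), "ok"))
    return pd.DataFrame(rows, columns=["plot_id", "gs30_gdd", "r2", "n_campaigns", "flag"])


# ---------------------------------------------------------------------------
# Plant count (watershed)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class WatershedConfig:
    """Thresholds for peak detection and watershed support plus calibration."""

    i_thresh: float = 0.10
    i_peak: float = 0.30
    d_min: int = 8
    a_w: float | None = None
    b_w: float | None = None

    def __post_init__(self) -> None:
        if not 0 < self.i_thresh <= self.i_peak <= 1:
            raise ValueError("need 0 < i_thresh <= i_peak <= 1")
        if self.d_min < 1:
            raise ValueError("d_min must be >= 1 pixel")


def watershed_labels(mv: MultiviewImage, cfg: WatershedConfig) -> np.ndarray:
    """Label image of watershed regions (0 = background).

    Peaks are local maxima with fraction > ``i_peak`` separated by at least
    ``d_min`` pixels (a connected plateau counts once); the watershed floods
    the inverted fraction landscape restricted to pixels above ``i_thresh``.
    """
    from skimage.feature import peak_local_max
    from skimage.segmentation import watershed

    img = np.nan_to_num(mv.values, nan=0.0)
    support = img > cfg.i_thresh
    peaks = peak_local_max(
        img,
        min_distance=int(cfg.d_min),
        threshold_abs=np.nextafter(cfg.i_peak, np.inf),
        exclude_border=False,
    )
    if len(peaks) == 0:
        return np.zeros(img.shape, dtype=int)
    markers = np.zeros(img.shape, dtype=int)
    markers[tuple(peaks.T)] = np.arange(1, len(peaks) + 1)
    return watershed(-img, markers=markers, mask=support)


def watershed_regions(mv: MultiviewImage, cfg: WatershedConfig) -> np.ndarray:
    """Region areas (pixels) of the watershed partition of plant cover.

    An image with no peaks yields an empty list — a valid zero-plant plot.
    """
    labels = watershed_labels(mv, cfg)
    _, counts = np.unique(labels[labels > 0], return_counts=True)
    return counts


def calibrate_watershed(
    areas: np.ndarray, plants_in_region: np.ndarray
) -> tuple[float, float, dict]:
    """OLS of manual per-region plant counts on watershed region areas.

    Returns ``(a_w, b_w, diagnostics)``; diagnostics carry R² and standard
    errors.  At least 10 regions with truth counts are required, and areas
    must vary.
    """
    import statsmodels.api as sm

    A = np.asarray(areas, dtype=float)
    y = np.asarray(plants_in_region, dtype=float)
    if len(A) < 10:
        raise ValueError(f"need >= 10 calibration regions, got {len(A)}")
    if np.ptp(A) == 0:
        raise ValueError("zero variance in region areas; cannot calibrate")
    res = sm.OLS(y, sm.add_constant(A)).fit()
    b_w, a_w = res.params
    diag = {
        "r2": float(res.rsquared),
        "se_a": float(res.bse[1]),
        "se_b": float(res.bse[0]),
        "n": len(A),
    }
    return float(a_w), float(b_w), diag


def predict_plant_count(
    areas: np.ndarray, a_w: float, b_w: float, intercept_once: bool = False
) -> float:
    """Plant count from region areas: ``Σ_j (a_W·A_j + b_W)``, floored at 0.

    ``intercept_once=True`` is a diagnostic variant applying the intercept a
    single time instead of per region.
    """
    A = np.asarray(areas, dtype=float)
    if A.size == 0:
        return 0.0
    if intercept_once:
        total = a_w * A.sum() + b_w
    else:
        total = float(np.sum(a_w * A + b_w))
    return max(total, 0.0)


# ---------------------------------------------------------------------------
# Shoot count (logistic LA <-> shoots)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LAShootModel:
    """GDD-anchored logistic LA↔shoots model.

    ``LA = asym / (1 + exp((xmid(Δ) − log1p(N_S)) / scal(Δ)))`` with
    ``xmid(Δ) = a_xmid·Δ + b_xmid`` and ``scal(Δ) = a_scal·Δ + b_scal`` in
    ΔGDD_GS30.  ``asym`` is the leaf area at the assumed 90% maximum cover.
    """

    asym: float
    a_xmid: float
    b_xmid: float
    a_scal: float
    b_scal: float
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.asym <= 0:
            raise ValueError("asym must be > 0")

    def xmid(self, delta_gdd):
        return self.a_xmid * np.asarray(delta_gdd, dtype=float) + self.b_xmid

    def scal(self, delta_gdd):
        return self.a_scal * np.asarray(delta_gdd, dtype=float) + self.b_scal


def logistic_la(n_s, delta_gdd, model: LAShootModel):
    """Forward model: apparent leaf area for a shoot count at a growth stage."""
    x = np.log1p(np.asarray(n_s, dtype=float))
    return model.asym / (1.0 + np.exp((model.xmid(delta_gdd) - x) / model.scal(delta_gdd)))


def shoots_from_la(la, delta_gdd, model: LAShootModel):
    """Invert the logistic: ``N̂_S = expm1(xmid − scal·ln(asym/LA − 1))``.

    ``la >= asym`` is clamped to 0.999·asym with a warning; ``la <= 0``
    yields zero shoots.
    """
    la = np.asarray(la, dtype=float)
    scalar = la.ndim == 0
    la = np.atleast_1d(la).astype(float)
    if np.any(la >= model.asym):
        warnings.warn("leaf area at or above asymptote; clamping to 0.999·asym", stacklevel=2)
        la = np.minimum(la, 0.999 * model.asym)
    out = np.zeros_like(la)
    pos = la > 0
    xm = np.broadcast_to(model.xmid(delta_gdd), la.shape)
    sc = np.broadcast_to(model.scal(delta_gdd), la.shape)
    if np.any(sc[pos] <= 0):
        raise ValueError("scal(ΔGDD) <= 0 outside the fitted growth-stage range")
    exponent = np.clip(xm[pos] - sc[pos] * np.log(model.asym / la[pos] - 1.0), -745.0, 700.0)
    out[pos] = np.expm1(exponent)
    out = np.maximum(out, 0.0)
    return float(out[0]) if scalar else out


def _multistart_curve_fit(f, x, y, p0_ranges, seed, n_starts=5, **kwargs):
    """Levenberg–Marquardt least squares from several data-driven starts."""
    rng = np.random.default_rng(seed)
    best = None
    starts = [np.array([(lo + hi) / 2 for lo, hi in p0_ranges])]
    starts += [np.array([rng.uniform(lo, hi) for lo, hi in p0_ranges]) for _ in range(n_starts - 1)]
    for p0 in starts:
        try:
            popt, pcov = optimize.curve_fit(
                f, x, y, p0=p0, maxfev=20000, xtol=1e-10, ftol=1e-10, **kwargs
            )
        except (RuntimeError, ValueError):
            continue
        sse = float(np.sum((f(x, *popt) - y) ** 2))
        if best is None or sse < best[2]:
            best = (popt, pcov, sse)
    if best is None:
        raise RuntimeError("nonlinear fit failed from all starts")
    return best


def fit_la_shoot_model(
    la: np.ndarray,
    n_s: np.ndarray,
    delta_gdd: np.ndarray,
    asym: float,
    window: float = 12.5,
    min_group_size: int = 5,
    seed: int = 17,
) -> LAShootModel:
    """Fit the growth-stage-anchored logistic from (LA, N_S, ΔGDD) triplets.

    Triplets are grouped into ΔGDD bins of half-width ``window`` (±12.5 GDD);
    each group gets a two-parameter logistic fit (``asym`` fixed), and the
    per-group midpoints and scales are regressed linearly on the group-centre
    ΔGDD.  An ANOVA-style F test reports whether the ΔGDD dependence of each
    parameter is significant.
    """
    import statsmodels.api as sm

    la = np.asarray(la, dtype=float)
    n_s = np.asarray(n_s, dtype=float)
    dg = np.asarray(delta_gdd, dtype=float)
    bin_w = 2 * window
    centers = np.round(dg / bin_w) * bin_w

    groups = []
    for c in np.unique(centers):
        m = centers == c
        if m.sum() < min_group_size:
            continue
        x = np.log1p(n_s[m])
        if np.ptp(x) < 0.05:
            warnings.warn(f"ΔGDD group {c:+.0f}: shoot counts nearly constant, "
                          "scal unidentifiable; dropped", stacklevel=2)
            continue

        def f(x_, xmid, scal):
            return asym / (1.0 + np.exp((xmid - x_) / scal))

        try:
            popt, _, _ = _multistart_curve_fit(
                f, x, la[m],
                p0_ranges=[(x.min(), x.max()), (0.1, 3.0)],
                seed=seed + int(abs(c)),
                bounds=([x.min() - 10.0, 1e-3], [x.max() + 10.0, 20.0]),
            )
        except RuntimeError:
            warnings.warn(f"ΔGDD group {c:+.0f}: logistic fit did not converge; dropped",
                          stacklevel=2)
            continue
        if popt[1] <= 0:
            continue
        groups.append((float(c), float(popt[0]), float(popt[1]), int(m.sum())))

    if len(groups) < 3:
        raise ValueError(f"only {len(groups)} usable ΔGDD groups; need >= 3")
    gdf = pd.DataFrame(groups, columns=["delta_gdd", "xmid", "scal", "n"])

    X = sm.add_constant(gdf["delta_gdd"].to_numpy())
    fit_xmid = sm.OLS(gdf["xmid"].to_numpy(), X).fit()
    fit_scal = sm.OLS(gdf["scal"].to_numpy(), X).fit()

    diagnostics = {
        "groups": gdf,
        "xmid_r2": float(fit_xmid.rsquared),
        "scal_r2": float(fit_scal.rsquared),
        "xmid_slope_p": float(fit_xmid.pvalues[1]),
        "scal_slope_p": float(fit_scal.pvalues[1]),
    }
    return LAShootModel(
        asym=asym,
        a_xmid=float(fit_xmid.params[1]),
        b_xmid=float(fit_xmid.params[0]),
        a_scal=float(fit_scal.params[1]),
        b_scal=float(fit_scal.params[0]),
        diagnostics=diagnostics,
    )


# ---------------------------------------------------------------------------
# Shoot dynamics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ShootDynamics:
    """Inverse-exponential tillering summary: final shoots and tillering rate."""

    n_s: float
    a: float | None
    se_n_s: float | None = None
    se_a: float | None = None
    fallback: bool = False
    n_points: int = 0


def fit_shoot_dynamics(
    n_s_t: np.ndarray,
    delta_gdd: np.ndarray,
    seed: int = 17,
    gdd_range: tuple = (-200.0, 0.0),
) -> ShootDynamics:
    """Fit ``N_S,t = N_S − exp(−a·ΔGDD)`` over the pre-GS30 tillering window.

    Points outside ``−200 <= ΔGDD < 0`` are filtered to prevent
    extrapolation.  With fewer than three remaining points the final shoot
    count falls back to the median of the series and the rate is reported
    missing — the behaviour used when a site has too few early campaigns.
    The fitted curve may be negative early in the season; values are never
    clamped during fitting.
    """
    y = np.asarray(n_s_t, dtype=float)
    x = np.asarray(delta_gdd, dtype=float)
    m = (x >= gdd_range[0]) & (x < gdd_range[1]) & np.isfinite(y)
    if m.sum() < 3:
        med = float(np.median(y[np.isfinite(y)])) if np.isfinite(y).any() else np.nan
        return ShootDynamics(n_s=med, a=None, fallback=True, n_points=int(m.sum()))
    x, y = x[m], y[m]

    def f(x_, n_s, a):
        return n_s - np.exp(-a * x_)

    y_max = max(y.max(), 1.0)
    try:
        popt, pcov, _ = _multistart_curve_fit(
            f, x, y, p0_ranges=[(0.5 * y_max, 2.0 * y_max), (0.001, 0.1)], seed=seed,
            bounds=([1e-6, 1e-6], [20.0 * y_max, 1.0]),
        )
    except RuntimeError:
        return ShootDynamics(n_s=float(np.median(y)), a=None, fallback=True, n_points=len(y))
    se = np.sqrt(np.diag(pcov)) if np.all(np.isfinite(pcov)) else (None, None)
    return ShootDynamics(
        n_s=float(popt[0]),
        a=float(popt[1]),
        se_n_s=float(se[0]) if se[0] is not None else None,
        se_a=float(se[1]) if se[1] is not None else None,
        fallback=False,
        n_points=len(y),
    )


# ---------------------------------------------------------------------------
# Dynamic summaries & error metrics
# ---------------------------------------------------------------------------

def plant_count_trait(corrected_counts: np.ndarray) -> float:
    """Intermediate-level plant count: median of corrected time-point counts."""
    c = np.asarray(corrected_counts, dtype=float)
    c = c[np.isfinite(c)]
    if c.size == 0:
        raise ValueError("no corrected time points available")
    return float(np.median(c))


def error_metrics(reference: np.ndarray, estimate: np.ndarray) -> dict:
    """Prediction-error summary with the reference-minus-estimate convention.

    Returns bias (mean of reference − estimate), RMSE, rRMSE (RMSE over the
    reference mean; NaN with a flag when that mean is zero), R² from OLS of
    estimate on reference, and Pearson r.
    """
    ref = np.asarray(reference, dtype=float)
    est = np.asarray(estimate, dtype=float)
    ok = np.isfinite(ref) & np.isfinite(est)
    ref, est = ref[ok], est[ok]
    if len(ref) < 2:
        raise ValueError("need >= 2 paired finite values")
    err = ref - est
    rmse = float(np.sqrt(np.mean(err**2)))
    mean_ref = float(np.mean(ref))
    rrmse = rmse / mean_ref if mean_ref != 0 else np.nan
    if np.ptp(ref) > 0 and np.ptp(est) > 0:
        r = float(stats.pearsonr(ref, est).statistic)
        r2 = r**2
    else:
        r, r2 = np.nan, np.nan
    return {
        "bias": float(np.mean(err)),
        "rmse": rmse,
        "rrmse": rrmse,
        "rrmse_flag": "undefined_zero_reference_mean" if mean_ref == 0 else "",
        "r2": r2,
        "pearson_r": r,
        "n": int(len(ref)),
    }
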