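"""Spatial correction, repeatability, heritability and relative efficiency.

Plot values from a field trial confound genotype effects with smooth spatial
field trends (soil, moisture) and row/range artefacts.  Spatial correction
fits

    value ~ f(x, y) + random(row) + random(range) + random(genotype)

with ``f`` a tensor-product P-spline surface (second-order difference
penalties, knots per direction = ceil(2/3 · plots-in-direction)) and returns
corrected plot values as genotype BLUE + residual.

Repeatability and heritability are *generalized heritabilities* in the
Cullis form

    H² = 1 − v̄_ΔBLUP / (2 σ̂²_g),

the mean variance of pairwise genotype-BLUP differences relative to twice
the genotypic variance — a variance-ratio measure that remains valid for
unbalanced mixed models and reduces to σ²_g/(σ²_g + σ²_e/r) for balanced
designs.  The value of switching from hand measurements to an imaging proxy
is summarised by the relative efficiency of indirect selection,
``RE = h_HTFP · r_G / h_manual``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

__all__ = [
    "CorrectionResult",
    "HeritabilityResult",
    "validate_design",
    "spatial_correct",
    "repeatability_simple",
    "heritability_multi",
    "relative_efficiency",
]

DESIGN_COLUMNS = ("plot_id", "x", "y", "row", "range", "genotype", "rep")


def validate_design(design: pd.DataFrame, require_year_site: bool = False) -> pd.DataFrame:
    need = list(DESIGN_COLUMNS) + (["year_site"] if require_year_site else [])
    missing = [c for c in need if c not in design.columns]
    if missing:
        raise ValueError(f"design is missing columns: {missing}")
    if not np.all(np.isfinite(design[["x", "y"]].to_numpy(dtype=float))):
        raise ValueError("design coordinates must be finite")
    key = ["row", "range"] + (["year_site"] if "year_site" in design.columns else [])
    if design.duplicated(subset=key).any():
        raise ValueError("(row, range) must be unique within a year_site")
    return design


# ---------------------------------------------------------------------------
# One-random-effect REML (genotype intercepts) with exact Cullis PEVs
# ---------------------------------------------------------------------------

def _reml_genotype(y: np.ndarray, X: np.ndarray, genotype: np.ndarray) -> dict:
    """REML for ``y = Xβ + Z_g u + e`` with ``u ~ N(0, σ²_g I)``.

    The variance ratio λ = σ²_g/σ²_e is profiled by 1-D optimisation of the
    REML criterion; the full prediction-error-variance matrix of the
    genotype BLUPs is returned for the Cullis generalized heritability.
    """
    y = np.asarray(y, dtype=float)
    genos, gidx = np.unique(np.asarray(genotype), return_inverse=True)
    n, q = len(y), len(genos)
    Z = np.zeros((n, q))
    Z[np.arange(n), gidx] = 1.0
    p = np.linalg.matrix_rank(X)

    def crit(log_lam):
        lam = np.exp(log_lam)
        V = np.eye(n) + lam * (Z @ Z.T)
        try:
            L = np.linalg.cholesky(V)
        except np.linalg.LinAlgError:
            return 1e12
        Vi_y = np.linalg.solve(V, y)
        Vi_X = np.linalg.solve(V, X)
        XtViX = X.T @ Vi_X
        beta = np.linalg.lstsq(XtViX, X.T @ Vi_y, rcond=None)[0]
        r = y - X @ beta
        Vi_r = np.linalg.solve(V, r)
        quad = float(r @ Vi_r)
        if quad <= 0:
            return 1e12
        logdet_V = 2.0 * float(np.sum(np.log(np.diag(L))))
        sign, logdet_XVX = np.linalg.slogdet(XtViX)
        if sign <= 0:
            # rank-deficient fixed part; use pseudo-determinant
            ev = np.linalg.eigvalsh(XtViX)
            logdet_XVX = float(np.sum(np.log(ev[ev > 1e-10 * ev.max()])))
        return logdet_V + logdet_XVX + (n - p) * np.log(quad)

    res = optimize.minimize_scalar(crit, bounds=(-12.0, 12.0), method="bounded",
                                   options={"xatol": 1e-8})
    lam = float(np.exp(res.x))
    V = np.eye(n) + lam * (Z @ Z.T)
    Vi = np.linalg.inv(V)
    XtViX = X.T @ Vi @ X
    XtViX_inv = np.linalg.pinv(XtViX)
    P = Vi - Vi @ X @ XtViX_inv @ X.T @ Vi
    sigma2_e = float(y @ P @ y) / (n - p)
    sigma2_g = lam * sigma2_e
    blup = lam * (Z.T @ P @ y)  # û = σ²_g Z'Σ⁻¹(y − Xβ̂) with Σ = σ²_e·V
    # PEV = Var(u − û) = σ²_g I − σ²_g² Z' PΣ Z, with PΣ = P/σ²_e
    pev = sigma2_g * np.eye(q) - (sigma2_g**2 / max(sigma2_e, 1e-300)) * (Z.T @ P @ Z)
    return {
        "genotypes": genos,
        "sigma2_g": sigma2_g,
        "sigma2_e": sigma2_e,
        "lambda": lam,
        "blup": blup,
        "pev": pev,
    }


def _cullis_h2(sigma2_g: float, pev: np.ndarray) -> float:
    """Generalized heritability 1 − v̄_ΔBLUP/(2σ²_g), clipped to [0, 1]."""
    if sigma2_g <= 0:
        return 0.0
    q = pev.shape[0]
    d = np.diag(pev)
    # mean over unordered pairs of Var(û_i − û_j) = PEV_ii + PEV_jj − 2 PEV_ij
    n_pairs = q * (q - 1)
    vbar = (2 * (q - 1) * d.sum() - 4 * np.triu(pev, 1).sum()) / n_pairs
    return float(np.clip(1.0 - vbar / (2.0 * sigma2_g), 0.0, 1.0))


@dataclass
class HeritabilityResult:
    """Generalized heritability plus the variance components behind it."""

    h2: float
    sigma2_g: float
    sigma2_e: float
    model: str
    n_genotypes: int
    n_obs: int

    def __post_init__(self) -> None:
        if not 0 <= self.h2 <= 1:
            raise ValueError("heritability must lie in [0, 1]")


def repeatability_simple(values: np.ndarray, design: pd.DataFrame) -> HeritabilityResult:
    """Within-environment repeatability: ``Y = R | G`` (replication fixed,
    genotype random), generalized heritability in the Cullis form."""
    design = validate_design(design)
    if design["rep"].nunique() < 2:
        raise ValueError("repeatability requires >= 2 replications")
    y = np.asarray(values, dtype=float)
    X = pd.get_dummies(design["rep"].astype(str), drop_first=False).to_numpy(dtype=float)
    fit = _reml_genotype(y, X, design["genotype"].to_numpy())
    return HeritabilityResult(
        h2=_cullis_h2(fit["sigma2_g"], fit["pev"]),
        sigma2_g=fit["sigma2_g"],
        sigma2_e=fit["sigma2_e"],
        model="R | G",
        n_genotypes=len(fit["genotypes"]),
        n_obs=len(y),
    )


def heritability_multi(
    values: np.ndarray,
    design: pd.DataFrame,
    reps_to_use: int | None = None,
    seed: int = 0,
) -> HeritabilityResult:
    """Multi-environment generalized heritability.

    Model ``Y = Yr/R | G`` (year and replication-within-year fixed, genotype
    random) when at least two replications remain, else ``Y = Yr | G``.
    Genotypes not present in every year-site are filtered out first;
    ``reps_to_use`` subsamples replications (e.g. to 1 or 2) so heritability
    is comparable with a lower-throughput manual protocol.
    """
    design = validate_design(design, require_year_site=True)
    df = design.copy()
    df["_value"] = np.asarray(values, dtype=float)

    year_sites = df["year_site"].unique()
    if len(year_sites) < 2:
        raise ValueError("multi-environment heritability requires >= 2 year_sites")
    common = set(df["genotype"].unique())
    for ys in year_sites:
        common &= set(df.loc[df["year_site"] == ys, "genotype"])
    if not common:
        raise ValueError("no genotype common to all year_sites")
    df = df[df["genotype"].isin(common)]

    if reps_to_use is not None:
        rng = np.random.default_rng(seed)
        kept = []
        for ys, grp in df.groupby("year_site"):
            reps = np.sort(grp["rep"].unique())
            chosen = reps[: min(reps_to_use, len(reps))]
            kept.append(grp[grp["rep"].isin(chosen)])
        df = pd.concat(kept)

    n_reps = df.groupby("year_site")["rep"].nunique().min()
    if n_reps >= 2:
        fixed = pd.get_dummies(
            df["year_site"].astype(str) + "/" + df["rep"].astype(str)
        ).to_numpy(dtype=float)
        model = "Yr/R | G"
    else:
        fixed = pd.get_dummies(df["year_site"].astype(str)).to_numpy(dtype=float)
        model = "Yr | G"
    fit = _reml_genotype(df["_value"].to_numpy(), fixed, df["genotype"].to_numpy())
    return HeritabilityResult(
        h2=_cullis_h2(fit["sigma2_g"], fit["pev"]),
        sigma2_g=fit["sigma2_g"],
        sigma2_e=fit["sigma2_e"],
        model=model,
        n_genotypes=len(fit["genotypes"]),
        n_obs=len(df),
    )


# ---------------------------------------------------------------------------
# Spatial correction (tensor P-spline surface)
# ---------------------------------------------------------------------------

def _bspline_basis(coords: np.ndarray, n_segments: int, degree: int = 3) -> np.ndarray:
    from scipy.interpolate import BSpline

    lo, hi = float(np.min(coords)), float(np.max(coords))
    if hi == lo:
        hi = lo + 1.0
    n_segments = max(int(n_segments), 1)
    inner = np.linspace(lo, hi, n_segments + 1)
    knots = np.concatenate([[lo] * degree, inner, [hi] * degree])
    t = np.clip(coords, lo, hi - 1e-12 * (hi - lo))
    return BSpline.design_matrix(t, knots, degree).toarray()


def _second_diff_penalty(k: int) -> np.ndarray:
    if k < 3:
        return np.zeros((max(k - 2, 0), k))
    D = np.diff(np.eye(k), n=2, axis=0)
    return D


@dataclass
class CorrectionResult:
    """Spatially corrected plot values plus the fitted surface and repeatability."""

    corrected: pd.DataFrame          # plot_id, value, corrected, genotype
    surface: np.ndarray              # fitted spatial trend per plot
    genotype_blue: pd.Series
    repeatability: float
    sigma2_g: float
    sigma2_e: float
    smoothing: dict = field(default_factory=dict)


def spatial_correct(
    values: np.ndarray,
    design: pd.DataFrame,
    knots_factor: float = 2.0 / 3.0,
) -> CorrectionResult:
    """Remove smooth spatial trends and row/range artefacts from plot values.

    A tensor-product P-spline surface over (x, y) with second-order
    difference penalties absorbs the field trend; row and range dummies are
    ridge-penalised (random-effect-like) and genotype enters as fixed dummies
    (BLUEs).  Knots per direction follow ceil(knots_factor · plots in that
    direction).  The smoothing parameters are selected by generalized
    cross-validation on a log grid.  Corrected values are genotype BLUE +
    residual; repeatability is the Cullis generalized heritability of the
    corrected values under ``R | G``.
    """
    design = validate_design(design)
    y = np.asarray(values, dtype=float)
    if design["genotype"].nunique() < 2:
        raise ValueError("spatial correction requires >= 2 genotypes")
    if design["rep"].nunique() < 2:
        raise ValueError("spatial correction requires >= 2 replications")
    for factor in ("row", "range"):
        # genotype must not be locked to a single row/range, or the genotype
        # BLUEs are inseparable from that design effect
        per_geno = design.groupby("genotype")[factor].nunique()
        if design[factor].nunique() >= 2 and (per_geno == 1).all() \
                and design.groupby(factor)["genotype"].nunique().max() == 1:
            raise ValueError(f"genotypes are confounded with {factor}")

    n_row = design["row"].nunique()
    n_rng = design["range"].nunique()
    Bx = _bspline_basis(design["x"].to_numpy(dtype=float), int(np.ceil(knots_factor * n_rng)))
    By = _bspline_basis(design["y"].to_numpy(dtype=float), int(np.ceil(knots_factor * n_row)))
    # row-wise tensor product
    B = (Bx[:, :, None] * By[:, None, :]).reshape(len(y), -1)
    kx, ky = Bx.shape[1], By.shape[1]
    Dx = np.kron(_second_diff_penalty(kx), np.eye(ky))
    Dy = np.kron(np.eye(kx), _second_diff_penalty(ky))

    G = pd.get_dummies(design["genotype"]).to_numpy(dtype=float)
    Zr = pd.get_dummies(design["row"]).to_numpy(dtype=float)
    Zc = pd.get_dummies(design["range"]).to_numpy(dtype=float)

    n = len(y)
    M = np.hstack([G, B, Zr, Zc])
    slices = {
        "G": slice(0, G.shape[1]),
        "B": slice(G.shape[1], G.shape[1] + B.shape[1]),
        "Zr": slice(G.shape[1] + B.shape[1], G.shape[1] + B.shape[1] + Zr.shape[1]),
        "Zc": slice(G.shape[1] + B.shape[1] + Zr.shape[1], M.shape[1]),
    }

    best = None
    gcv_gamma = 1.4  # inflate dof cost to guard against undersmoothing
    for lam_s in np.logspace(0, 6, 7):
        for lam_z in (1e0, 1e2, 1e4):
            pen_rows = []
            pen_rows.append(np.sqrt(lam_s) * np.hstack([
                np.zeros((Dx.shape[0], G.shape[1])), Dx,
                np.zeros((Dx.shape[0], Zr.shape[1] + Zc.shape[1]))]))
            pen_rows.append(np.sqrt(lam_s) * np.hstack([
                np.zeros((Dy.shape[0], G.shape[1])), Dy,
                np.zeros((Dy.shape[0], Zr.shape[1] + Zc.shape[1]))]))
            Zpen = np.zeros((Zr.shape[1] + Zc.shape[1], M.shape[1]))
            Zpen[:, slices["Zr"].start:] = np.sqrt(lam_z) * np.eye(Zr.shape[1] + Zc.shape[1])
            pen_rows.append(Zpen)
            P = np.vstack(pen_rows)

            MtM = M.T @ M + P.T @ P
            Mty = M.T @ y
            theta = np.linalg.lstsq(MtM, Mty, rcond=None)[0]
            fitted = M @ theta
            # effective dof: trace of the hat matrix
            S = np.linalg.lstsq(MtM, M.T @ M, rcond=None)[0]
            edf = float(np.trace(S))
            sse = float(np.sum((y - fitted) ** 2))
            denom = max(n - gcv_gamma * edf, 1e-6)
            gcv = n * sse / denom**2
            if best is None or gcv < best["gcv"]:
                best = {"gcv": gcv, "lam_s": lam_s, "lam_z": lam_z,
                        "theta": theta, "edf": edf}

    theta = best["theta"]
    surface = B @ theta[slices["B"]]
    rowrange = Zr @ theta[slices["Zr"]] + Zc @ theta[slices["Zc"]]
    geno_eff = G @ theta[slices["G"]]
    residual = y - geno_eff - surface - rowrange
    corrected = geno_eff + residual

    blue = pd.Series(theta[slices["G"]], index=pd.get_dummies(design["genotype"]).columns)
    rep_fit = repeatability_simple(corrected, design)
    if not np.all(np.isfinite(corrected)):
        raise ValueError("non-finite corrected values")
    out = design[["plot_id", "genotype"]].copy()
    out["value"] = y
    out["corrected"] = corrected
    return CorrectionResult(
        corrected=out,
        surface=surface,
        genotype_blue=blue,
        repeatability=rep_fit.h2,
        sigma2_g=rep_fit.sigma2_g,
        sigma2_e=rep_fit.sigma2_e,
        smoothing={"lambda_surface": best["lam_s"], "lambda_rowrange": best["lam_z"],
                   "edf": best["edf"], "gcv": best["gcv"]},
    )


# ---------------------------------------------------------------------------
# Relative efficiency of indirect selection
# ---------------------------------------------------------------------------

def relative_efficiency(h2_htfp: float, h2_manual: float, r_g: float) -> dict:
    """``RE = sqrt(h²_HTFP) · r_G / sqrt(h²_manual)``.

    A zero manual heritability makes direct selection impossible; RE is then
    reported infinite with a flag rather than raising.
    """
    for name, v in (("h2_htfp", h2_htfp), ("h2_manual", h2_manual)):
        if not 0 <= v <= 1:
            raise ValueError(f"{name} must lie in [0, 1]")
    if not -1 <= r_g <= 1:
        raise ValueError("r_g must lie in [-1, 1]")
    if h2_manual == 0:
        return {"re": np.inf, "flag": "infinite_re_zero_manual_heritability"}
    return {"re": float(np.sqrt(h2_htfp) * r_g / np.sqrt(h2_manual)), "flag": ""}
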