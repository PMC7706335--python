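import numpy as np
import pandas as pd
import pytest

from mvgc.stat_genetics import (
    heritability_multi,
    relative_efficiency,
    repeatability_simple,
    spatial_correct,
    validate_design,
)


def make_design(ng=36, r=2, seed=0, year_site=None):
    """Randomised 6-column layout: rep blocks stacked along y."""
    rng = np.random.default_rng(seed)
    rows = []
    genos = [f"g{i:02d}" for i in range(ng)]
    for rep in range(r):
        perm = rng.permutation(genos)
        for k, g in enumerate(perm):
            row_i = k // 6 + rep * (ng // 6)
            col_i = k % 6
            rows.append(
                (f"p{rep}_{k}", col_i * 1.5, row_i * 0.4, row_i + 1, col_i + 1, g, rep + 1)
            )
    df = pd.DataFrame(rows, columns=["plot_id", "x", "y", "row", "range", "genotype", "rep"])
    if year_site is not None:
        df["year_site"] = year_site
    return df


def simulate_values(design, sigma_g, sigma_e, seed, trend=None):
    rng = np.random.default_rng(seed)
    genos = sorted(design["genotype"].unique())
    u = dict(zip(genos, rng.normal(0, sigma_g, len(genos))))
    y = design["genotype"].map(u).to_numpy() + rng.normal(0, sigma_e, len(design))
    if trend is not None:
        y = y + trend
    return y


class TestRepeatabilitySimple:
    def test_balanced_closed_form(self):
        """σ²_g=4, σ²_e=1, 2 reps: H² ≈ 4/(4 + 1/2) = 0.889 (±0.05 over sims)."""
        h = [
            repeatability_simple(
                simulate_values(make_design(seed=s), 2.0, 1.0, 300 + s), make_design(seed=s)
            ).h2
            for s in range(8)
        ]
        assert np.mean(h) == pytest.approx(8.0 / 9.0, abs=0.05)

    def test_permuted_genotypes_near_zero(self):
        d = make_design(seed=1)
        y = simulate_values(d, 2.0, 1.0, 11)
        d_perm = d.assign(genotype=np.random.default_rng(0).permutation(d["genotype"]))
        assert repeatability_simple(y, d_perm).h2 < 0.25

    def test_duplicated_plots_approach_one(self):
        d = make_design(seed=2)
        y = simulate_values(d, 2.0, 1.0, 12)
        d2 = pd.concat(
            [d, d.assign(plot_id=d.plot_id + "_dup", rep=d.rep + 2, row=d.row + 20)]
        )
        h = repeatability_simple(np.r_[y, y], d2).h2
        assert h > repeatability_simple(y, d).h2 - 1e-9

    def test_single_rep_rejected(self):
        d = make_design(r=1)
        with pytest.raises(ValueError, match="replication"):
            repeatability_simple(np.zeros(len(d)), d)

    def test_bounded_in_unit_interval(self, rng):
        d = make_design(seed=3)
        h = repeatability_simple(rng.normal(0, 1, len(d)), d).h2
        assert 0.0 <= h <= 1.0


class TestSpatialCorrect:
    def test_trend_free_matches_closed_form(self):
        """No trend, σ²_g=σ²_e=1, 2 reps: repeatability ≈ 1/(1+0.5) = 0.667
        within ±0.1 over simulations."""
        vals = []
        for s in range(8):
            d = make_design(seed=s)
            vals.append(spatial_correct(simulate_values(d, 1.0, 1.0, 100 + s), d).repeatability)
        assert np.mean(vals) == pytest.approx(2.0 / 3.0, abs=0.1)

    def test_planar_trend_absorbed(self):
        """Adding a strong planar trend changes repeatability by < 0.05 on
        average: the surface absorbs it."""
        shifts = []
        for s in range(6):
            d = make_design(seed=s)
            base = simulate_values(d, 1.0, 1.0, 200 + s)
            trend = 0.8 * d["x"].to_numpy() + 0.5 * d["y"].to_numpy()
            r0 = spatial_correct(base, d).repeatability
            r1 = spatial_correct(base + trend, d).repeatability
            shifts.append(r1 - r0)
        assert abs(np.mean(shifts)) < 0.05

    def test_zero_genotype_variance_near_zero(self):
        d = make_design(seed=3)
        y = np.random.default_rng(7).normal(0, 1, len(d))
        assert spatial_correct(y, d).repeatability < 0.1

    def test_ranking_preserved_under_additive_trend(self):
        from scipy.stats import spearmanr

        d = make_design(seed=4)
        y = simulate_values(d, 2.0, 0.5, 44)
        trend = 1.2 * d["x"].to_numpy()
        b0 = spatial_correct(y, d).genotype_blue
        b1 = spatial_correct(y + trend, d).genotype_blue
        rho = spearmanr(b0.sort_index(), b1.sort_index()).statistic
        assert rho >= 0.95

    def test_single_genotype_rejected(self):
        d = make_design(seed=5).assign(genotype="g00")
        with pytest.raises(ValueError, match="genotype"):
            spatial_correct(np.zeros(len(d)), d)


class TestHeritabilityMulti:
    def _two_year_data(self, sigma_g, sigma_yr, sigma_e, seed, r=2, ng=36):
        rng = np.random.default_rng(seed)
        genos = [f"g{i:02d}" for i in range(ng)]
        u = dict(zip(genos, rng.normal(0, sigma_g, ng)))
        parts = []
        for ys in ("Y1", "Y2"):
            d = make_design(ng=ng, r=r, seed=seed, year_site=ys)
            y = d["genotype"].map(u).to_numpy() + rng.normal(0, sigma_yr) \
                + rng.normal(0, sigma_e, len(d))
            parts.append(d.assign(val=y))
        return pd.concat(parts, ignore_index=True)

    def test_balanced_multi_environment_closed_form(self):
        """σ²_g=σ²_yr=σ²_e=1, 2 years × 2 reps: H² ≈ 1/(1+1/4) = 0.8 ± 0.1."""
        h = []
        for s in range(8):
            df = self._two_year_data(1.0, 1.0, 1.0, 400 + s)
            h.append(heritability_multi(df["val"].to_numpy(), df).h2)
        assert np.mean(h) == pytest.approx(0.8, abs=0.1)

    def test_pure_year_effect_no_genetics(self):
        df = self._two_year_data(0.0, 2.0, 1.0, 9)
        assert heritability_multi(df["val"].to_numpy(), df).h2 < 0.15

    def test_h2_nondecreasing_in_replication_on_average(self):
        diffs = []
        for s in range(6):
            df = self._two_year_data(1.0, 1.0, 1.0, 500 + s, r=4)
            h1 = heritability_multi(df["val"].to_numpy(), df, reps_to_use=1, seed=s).h2
            h4 = heritability_multi(df["val"].to_numpy(), df, reps_to_use=4, seed=s).h2
            diffs.append(h4 - h1)
        assert np.mean(diffs) >= 0.0

    def test_model_label_follows_replication(self):
        df = self._two_year_data(1.0, 1.0, 1.0, 5)
        assert heritability_multi(df["val"].to_numpy(), df).model == "Yr/R | G"
        assert heritability_multi(df["val"].to_numpy(), df, reps_to_use=1).model == "Yr | G"

    def test_noncommon_genotypes_filtered(self):
        df = self._two_year_data(1.0, 1.0, 1.0, 6)
        extra = make_design(ng=6, r=2, seed=99, year_site="Y1")
        extra["genotype"] = extra["genotype"].str.replace("g", "x")
        extra["val"] = 0.0
        extra["row"] += 100
        both = pd.concat([df, extra], ignore_index=True)
        res = heritability_multi(both["val"].to_numpy(), both)
        assert res.n_genotypes == 36

    def test_disjoint_genotype_sets_rejected(self):
        a = make_design(ng=6, r=2, seed=1, year_site="Y1").assign(val=0.0)
        b = make_design(ng=6, r=2, seed=2, year_site="Y2").assign(val=0.0)
        b["genotype"] = b["genotype"].str.replace("g", "z")
        both = pd.concat([a, b], ignore_index=True)
        with pytest.raises(ValueError, match="common"):
            heritability_multi(both["val"].to_numpy(), both)


class TestRelativeEfficiency:
    def test_identical_methods(self):
        assert relative_efficiency(0.5, 0.5, 1.0)["re"] == pytest.approx(1.0)

    def test_worked_arithmetic(self):
        assert relative_efficiency(0.64, 0.16, 0.5)["re"] == pytest.approx(1.0)

    def test_zero_genetic_correlation(self):
        assert relative_efficiency(0.7, 0.5, 0.0)["re"] == 0.0

    def test_infinite_when_manual_heritability_zero(self):
        res = relative_efficiency(0.5, 0.0, 0.8)
        assert np.isinf(res["re"]) and res["flag"]

    def test_monotonicity(self):
        base = relative_efficiency(0.5, 0.5, 0.5)["re"]
        assert relative_efficiency(0.7, 0.5, 0.5)["re"] > base
        assert relative_efficiency(0.5, 0.7, 0.5)["re"] < base
        assert relative_efficiency(0.5, 0.5, 0.7)["re"] > base

    def test_out_of_range_inputs_rejected(self):
        with pytest.raises(ValueError):
            relative_efficiency(1.5, 0.5, 0.5)
        with pytest.raises(ValueError):
            relative_efficiency(0.5, 0.5, 1.5)


def test_validate_design_catches_duplicates_and_missing():
    d = make_design(ng=6, r=2, seed=0)
    with pytest.raises(ValueError, match="missing"):
        validate_design(d.drop(columns=["x"]))
    dup = pd.concat([d, d.iloc[[0]]], ignore_index=True)
    with pytest.raises(ValueError, match="unique"):
        validate_design(dup)
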