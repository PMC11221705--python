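import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy.signal import lfilter

from physeter import models, synth
from physeter.models import CyclicBasis, ModelSpec


def ar1(phi, n, seed):
    rng = np.random.default_rng(seed)
    return lfilter([1.0], [1.0, -phi], rng.normal(size=n))


class TestCyclicBasis:
    def test_periodic_values(self):
        B = models.cyclic_basis(np.array([1.0, 366.0]), df=2)
        assert np.abs(B[0] - B[1]).max() < 1e-10

    def test_periodic_first_derivative(self):
        cb = CyclicBasis(df=3)
        eps = 1e-5
        d_lo = (cb.transform([1 + eps]) - cb.transform([1.0])) / eps
        d_hi = (cb.transform([366.0]) - cb.transform([366 - eps])) / eps
        assert np.abs(d_lo - d_hi).max() < 1e-4

    def test_df_columns(self):
        for df in (2, 3, 5):
            assert CyclicBasis(df=df).transform(np.linspace(1, 366, 50)).shape == (50, df)

    def test_constant_projection(self):
        # the constant lives entirely in the intercept: regressing a constant
        # response on [1 | basis] returns zero basis coefficients
        x = np.linspace(1, 366, 500)
        B = models.cyclic_basis(x, df=2)
        X = np.column_stack([np.ones(500), B])
        beta, *_ = np.linalg.lstsq(X, np.full(500, 3.7), rcond=None)
        assert beta[0] == pytest.approx(3.7, abs=1e-8)
        assert np.abs(beta[1:]).max() < 1e-8

    def test_reproducible(self):
        x = np.linspace(1, 366, 100)
        assert np.array_equal(CyclicBasis(df=2).transform(x), CyclicBasis(df=2).transform(x))

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            CyclicBasis(df=2).transform([0.5])


class TestBlockSizeFromAcf:
    def test_white_noise(self):
        rng = np.random.default_rng(0)
        assert models.block_size_from_acf(rng.normal(size=100_000)) == 1

    @pytest.mark.parametrize("phi,analytic", [(0.9, 22), (0.5, 4)])
    def test_ar1_matches_analytic(self, phi, analytic):
        # analytic limit: ceil(ln 0.1 / ln phi)
        tol = 2 if phi == 0.9 else 1
        for seed in range(3):
            k = models.block_size_from_acf(ar1(phi, 100_000, seed))
            assert abs(k - analytic) <= tol, (phi, seed, k)

    def test_short_series_rejected(self):
        with pytest.raises(ValueError):
            models.block_size_from_acf(np.zeros(5))


class TestVifScreen:
    def test_orthogonal(self):
        rng = np.random.default_rng(0)
        X = pd.DataFrame({"a": rng.normal(size=5000), "b": rng.normal(size=5000)})
        out = models.vif_screen(X)
        assert np.allclose(out["vif"], 1.0, atol=0.05)
        assert not out["flag"].any()

    def test_duplicated_covariate_flagged(self):
        rng = np.random.default_rng(1)
        a = rng.normal(size=100)
        out = models.vif_screen(pd.DataFrame({"a": a, "b": a}))
        assert (out["vif"] > 100).all() and out["flag"].all()

    def test_correlated_pair_closed_form(self):
        rng = np.random.default_rng(2)
        n = 200_000
        a = rng.normal(size=n)
        b = 0.7 * a + np.sqrt(1 - 0.49) * rng.normal(size=n)
        out = models.vif_screen(pd.DataFrame({"a": a, "b": b}))
        assert out["vif"].iloc[0] == pytest.approx(1 / (1 - 0.49), abs=0.05)
        assert not out["flag"].any()

    def test_single_covariate_rejected(self):
        with pytest.raises(ValueError):
            models.vif_screen(pd.DataFrame({"a": [1.0, 2.0]}))


class TestFitGee:
    def test_independence_limit_equals_glm(self):
        sim = synth.simulate_presence(
            synth.PresenceSimConfig(n_years=1, amplitude=1.0, seed=3)
        )
        fit = models.fit_gee(sim, ModelSpec("presence", ["julian_day"], corstr="independence"))
        glm = sm.GLM(fit.y, fit.X, family=sm.families.Binomial()).fit()
        assert np.abs(np.asarray(fit.params) - np.asarray(glm.params)).max() < 1e-6

    def test_seasonal_peak_recovery(self):
        sim = synth.simulate_presence(
            synth.PresenceSimConfig(
                n_years=2, peak_day=182, amplitude=1.5, baseline=-1.0,
                ar1_phi=0.8, ar1_sd=1.0, seed=7,
            )
        )
        fit = models.fit_gee(sim, ModelSpec("presence", ["julian_day"], block_len_h=24))
        assert abs(fit.seasonal_peak_day() - 182) <= 15

    def test_robust_se_exceeds_naive_under_autocorrelation(self):
        wins = 0
        reps = 8
        for seed in range(reps):
            sim = synth.simulate_presence(
                synth.PresenceSimConfig(
                    n_years=1, peak_day=182, amplitude=1.0, baseline=-1.0,
                    ar1_phi=0.8, ar1_sd=1.0, seed=seed,
                )
            )
            gee = models.fit_gee(sim, ModelSpec("presence", ["julian_day"], block_len_h=48))
            glm = sm.GLM(gee.y, gee.X, family=sm.families.Binomial()).fit()
            jd = [i for i, c in enumerate(gee.X.columns) if c.startswith("jd_")]
            robust = np.sqrt(np.diag(gee.cov_robust))[jd]
            naive = np.asarray(glm.bse)[jd]
            wins += int((robust >= naive).all())
        assert wins >= int(np.ceil(0.95 * reps))

    def test_partial_fit_shape_and_ci(self):
        sim = synth.simulate_presence(
            synth.PresenceSimConfig(n_years=1, amplitude=1.5, seed=11)
        )
        fit = models.fit_gee(sim, ModelSpec("presence", ["julian_day"], block_len_h=24))
        pf = fit.partial_fit("julian_day", seed=0)
        assert {"x", "eta", "fit", "lo", "hi"} <= set(pf.columns)
        assert ((pf["lo"] <= pf["fit"]) & (pf["fit"] <= pf["hi"])).all()

    def test_nonbinary_response_rejected(self):
        sim = synth.simulate_presence(synth.PresenceSimConfig(n_years=1, seed=0))
        sim["presence"] = sim["presence"] * 2.0
        with pytest.raises(ValueError, match="binary"):
            models.fit_gee(sim, ModelSpec("presence", ["julian_day"]))


class TestSelection:
    def test_single_covariate_single_step(self):
        sim = synth.simulate_presence(synth.PresenceSimConfig(n_years=1, amplitude=1.0, seed=5))
        trace = models.backward_select(sim, ModelSpec("presence", ["julian_day"], block_len_h=24))
        assert len(trace.steps) == 1
        assert trace.final_covariates == ["julian_day"]

    def test_noise_covariate_dropped(self):
        # selection + Wald pruning together (the published workflow) discards
        # a pure-noise year factor in the vast majority of seeds
        dropped = 0
        reps = 10
        for seed in range(reps):
            sim = synth.simulate_presence(
                synth.PresenceSimConfig(
                    n_years=2, peak_day=182, amplitude=1.5, baseline=-1.0, seed=seed
                )
            )
            trace = models.backward_select(
                sim, ModelSpec("presence", ["julian_day", "year"], block_len_h=24)
            )
            final = models.wald_prune(trace.final_fit)
            if "year" not in final.terms and "julian_day" in final.terms:
                dropped += 1
        assert dropped >= int(np.ceil(0.9 * reps))

    def test_qica_monotone_along_path(self):
        sim = synth.simulate_presence(
            synth.PresenceSimConfig(n_years=2, amplitude=1.5, peak_day=100, seed=2)
        )
        trace = models.backward_select(
            sim, ModelSpec("presence", ["julian_day", "year"], block_len_h=24)
        )
        qs = [s["qica"] for s in trace.steps]
        assert all(b <= a for a, b in zip(qs, qs[1:]))

    def test_tie_break_by_declaration_order(self, monkeypatch):
        sim = synth.simulate_presence(synth.PresenceSimConfig(n_years=2, amplitude=1.0, seed=4))
        monkeypatch.setattr(models, "qica", lambda fit: 0.0)  # force exact ties
        trace = models.backward_select(
            sim, ModelSpec("presence", ["julian_day", "year"], block_len_h=24)
        )
        # exact ties: current model wins, nothing dropped, order = declaration
        assert trace.final_covariates == ["julian_day", "year"]
        assert trace.final_order == ["julian_day", "year"]

    def test_selection_deterministic(self):
        sim = synth.simulate_presence(synth.PresenceSimConfig(n_years=2, amplitude=1.0, seed=6))
        spec = ModelSpec("presence", ["julian_day", "year"], block_len_h=24)
        a = models.backward_select(sim, spec)
        b = models.backward_select(sim, spec)
        assert a.final_covariates == b.final_covariates
        assert a.final_order == b.final_order


class TestWaldPrune:
    def test_significant_model_unchanged(self):
        sim = synth.simulate_presence(
            synth.PresenceSimConfig(n_years=2, amplitude=2.0, seed=8)
        )
        fit = models.fit_gee(sim, ModelSpec("presence", ["julian_day"], block_len_h=24))
        pruned = models.wald_prune(fit)
        assert pruned.terms.keys() == fit.terms.keys()

    def test_null_factor_removed(self):
        sim = synth.simulate_presence(
            synth.PresenceSimConfig(n_years=2, amplitude=1.5, peak_day=182, seed=12)
        )
        fit = models.fit_gee(
            sim, ModelSpec("presence", ["julian_day", "year"], block_len_h=24)
        )
        pruned = models.wald_prune(fit)
        assert "year" not in pruned.terms
        assert "julian_day" in pruned.terms

    def test_nothing_significant_gives_intercept_only(self):
        sim = synth.simulate_presence(
            synth.PresenceSimConfig(n_years=1, amplitude=0.0, baseline=-1.0, seed=13)
        )
        fit = models.fit_gee(sim, ModelSpec("presence", ["julian_day"], block_len_h=24))
        pruned = models.wald_prune(fit)
        assert pruned.terms == {}
        assert list(pruned.X.columns) == ["Intercept"]


class TestDiagnostics:
    def test_tjur_perfect(self):
        assert models.tjur_r2([1, 0, 1], [1.0, 0.0, 1.0]) == 1.0

    def test_tjur_constant(self):
        assert models.tjur_r2([1, 0], [0.5, 0.5]) == 0.0

    def test_tjur_two_point(self):
        assert models.tjur_r2([1, 0], [0.8, 0.2]) == pytest.approx(0.6)

    def test_tjur_requires_both_classes(self):
        with pytest.raises(ValueError):
            models.tjur_r2([1, 1], [0.5, 0.5])

    def test_binned_residual_coverage_well_specified(self):
        rng = np.random.default_rng(0)
        n = 10_000
        x = rng.normal(size=n)
        p = 1 / (1 + np.exp(-(0.3 + 0.8 * x)))
        y = (rng.uniform(size=n) < p).astype(float)
        res = sm.GLM(y, sm.add_constant(x), family=sm.families.Binomial()).fit()
        br = models.binned_residuals(y, np.asarray(res.fittedvalues))
        assert br["inside"].mean() >= 0.85

    def test_diagnostics_on_fit(self):
        sim = synth.simulate_presence(
            synth.PresenceSimConfig(n_years=1, amplitude=1.5, seed=14)
        )
        fit = models.fit_gee(sim, ModelSpec("presence", ["julian_day"], block_len_h=24))
        d = models.diagnostics(fit)
        assert 0 <= d["tjur_r2"] <= 1
        assert 0 <= d["binned_residual_coverage"] <= 1
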