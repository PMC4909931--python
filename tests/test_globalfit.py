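import numpy as np
import pytest

from spinex import (
    ExchangeParams,
    RDProfile,
    SpinExchangeModel,
    detect_dispersion,
    fit_two_state_global,
    fit_two_state_individual,
    mc_fit_errors,
    r1rho_laguerre,
)
from spinex.decay import R1rhoPoint

from conftest import make_condition


def small_design(n_onres=8, offres_powers=(100.0, 300.0), n_off=6):
    conds = [make_condition(float(p), 0.0) for p in np.geomspace(100, 2000, n_onres)]
    for p in offres_powers:
        for frac in np.linspace(0.8, 3.5, n_off // 2):
            for sign in (1.0, -1.0):
                conds.append(make_condition(p, sign * frac * p))
    return conds


def profile_from_model(model, fieldctx, conds, sigma=0.2, noise_seed=None):
    rng = np.random.default_rng(noise_seed) if noise_seed is not None else None
    pts = []
    for c in conds:
        r = r1rho_laguerre(model, c, fieldctx)
        if rng is not None:
            r = r + rng.normal(0.0, sigma)
        pts.append(R1rhoPoint(condition=c, r1rho=r, sigma=sigma, i0=100.0))
    return RDProfile(residue_label=model.residue_label, points=tuple(pts))


def make_model(label, dw, exchange):
    return SpinExchangeModel(label, 2.0, 16.0, 145.0, dw, exchange)


class TestSelfConsistency:
    def test_noiseless_single_residue_exact_recovery(self, fieldctx, exchange):
        model = make_model("G174", 4.3, exchange)
        prof = profile_from_model(model, fieldctx, small_design())
        res = fit_two_state_individual(prof, fieldctx)
        assert res.chi2 == pytest.approx(0.0, abs=1e-6)
        assert res.exchange.k_ex == pytest.approx(423.0, rel=1e-3)
        assert res.exchange.p_minor == pytest.approx(0.029, rel=1e-3)
        assert res.per_residue["G174"]["dw_ppm"] == pytest.approx(4.3, rel=1e-3)
        assert res.per_residue["G174"]["r2"] == pytest.approx(16.0, rel=1e-3)

    def test_global_fit_matches_individual_on_truly_shared_data(self, fieldctx, exchange):
        models = [make_model("G174", 4.3, exchange), make_model("G176", -2.0, exchange)]
        conds = small_design()
        profs = [profile_from_model(m, fieldctx, conds) for m in models]
        glob = fit_two_state_global(profs, fieldctx)
        indiv = [fit_two_state_individual(p, fieldctx) for p in profs]
        # noiseless shared truth: global minimum equals the individual minima
        assert glob.chi2 == pytest.approx(sum(r.chi2 for r in indiv), abs=1e-5)
        assert glob.chi2 == pytest.approx(0.0, abs=1e-5)
        assert glob.n_free_params == 2 + 3 * 2

    def test_recovery_with_noise_within_uncertainty(self, fieldctx, exchange):
        model = make_model("G174", 4.3, exchange)
        prof = profile_from_model(model, fieldctx, small_design(), sigma=0.3, noise_seed=4)
        res = fit_two_state_individual(prof, fieldctx)
        res = mc_fit_errors(res, [prof], fieldctx, n_iter=50, seed=0)
        assert abs(res.exchange.k_ex - 423.0) < 3 * res.exchange_sigma["k_ex"]
        assert abs(res.per_residue["G174"]["dw_ppm"] - 4.3) < 3 * res.per_residue_sigma["G174"]["dw_ppm"]


class TestSignIdentifiability:
    def test_on_resonance_only_flags_indeterminate_sign(self, fieldctx, exchange):
        model = make_model("G174", 4.3, exchange)
        conds = [make_condition(float(p), 0.0) for p in np.geomspace(100, 2000, 10)]
        prof = profile_from_model(model, fieldctx, conds)
        res = fit_two_state_individual(prof, fieldctx)
        assert "sign_indeterminate" in res.flags

    def test_off_resonance_data_resolves_sign(self, fieldctx, exchange):
        conds = small_design()
        for dw in (4.3, -4.3):
            model = make_model("G174", dw, exchange)
            prof = profile_from_model(model, fieldctx, conds)
            res = fit_two_state_individual(prof, fieldctx)
            assert "sign_indeterminate" not in res.flags
            assert np.sign(res.per_residue["G174"]["dw_ppm"]) == np.sign(dw)
            assert res.per_residue["G174"]["dw_ppm"] == pytest.approx(dw, rel=0.01)


class TestMonteCarloFitErrors:
    def test_zero_point_sigma_gives_zero_parameter_sigma(self, fieldctx, exchange):
        model = make_model("G174", 4.3, exchange)
        prof = profile_from_model(model, fieldctx, small_design(), sigma=0.0)
        with pytest.warns(UserWarning, match="unit weights"):
            res = fit_two_state_individual(prof, fieldctx)
        with pytest.warns(UserWarning, match="unit weights"):
            res = mc_fit_errors(res, [prof], fieldctx, n_iter=20, seed=0)
        assert res.exchange_sigma["k_ex"] == pytest.approx(0.0, abs=1e-6)

    def test_seed_determinism(self, fieldctx, exchange):
        model = make_model("G174", 4.3, exchange)
        prof = profile_from_model(model, fieldctx, small_design(), sigma=0.3, noise_seed=9)
        res = fit_two_state_individual(prof, fieldctx)
        a = mc_fit_errors(res, [prof], fieldctx, n_iter=20, seed=5).exchange_sigma["k_ex"]
        b = mc_fit_errors(res, [prof], fieldctx, n_iter=20, seed=5).exchange_sigma["k_ex"]
        assert a == b
        assert res.seed_used == 5


class TestDispersionScreen:
    def test_noiseless_flat_profile_is_flat_with_p_one(self, fieldctx):
        model = make_model("U162", 0.0, ExchangeParams(p_minor=0.0, k_ex=100.0))
        prof = profile_from_model(model, fieldctx, small_design())
        out = detect_dispersion(prof, fieldctx)
        assert out.classification == "flat"
        assert out.p_value == 1.0

    def test_strong_exchange_is_dispersive(self, fieldctx, exchange):
        model = make_model("G174", 4.3, exchange)
        prof = profile_from_model(model, fieldctx, small_design(), sigma=0.3, noise_seed=2)
        out = detect_dispersion(prof, fieldctx)
        assert out.classification == "dispersive"
        assert out.p_value < 1e-6
        assert out.chi2_flat > out.chi2_exchange

    def test_too_few_points_is_insufficient(self, fieldctx, exchange):
        model = make_model("G174", 4.3, exchange)
        conds = [make_condition(float(p), 0.0) for p in (100, 200, 400, 800, 1600, 2000)]
        prof = profile_from_model(model, fieldctx, conds, sigma=0.3, noise_seed=0)
        out = detect_dispersion(prof, fieldctx)
        assert out.classification == "insufficient_data"

    def test_profile_needs_six_points(self, exchange, fieldctx):
        model = make_model("G174", 4.3, exchange)
        conds = [make_condition(float(p), 0.0) for p in (100, 400, 2000)]
        with pytest.raises(ValueError, match=">= 6"):
            profile_from_model(model, fieldctx, conds)
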