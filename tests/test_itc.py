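import math

import numpy as np
import pytest

from phnmr.exceptions import ParameterError
from phnmr.itc import (
    BindingParams,
    ITCExperiment,
    OneSiteBindingModel,
    fit_single_site,
    simulate_isotherm,
    thermodynamics,
)
from phnmr.synthetic import make_itc

M0 = 30e-6  # default cell concentration, M


class TestSimulateIsotherm:
    def test_zero_enthalpy_gives_only_offset(self):
        exp = ITCExperiment()
        heats = simulate_isotherm(exp, BindingParams(dh=0.0, q_offset=1.5))
        np.testing.assert_allclose(heats, 1.5)

    def test_empty_syringe_gives_only_offset(self):
        exp = ITCExperiment(syringe_conc_uM=0.0)
        heats = simulate_isotherm(exp, BindingParams(q_offset=-0.3))
        np.testing.assert_allclose(heats, -0.3)

    def test_stoichiometric_limit_steps_at_n(self):
        # c >> 1000: every injected ligand binds until sites saturate, so
        # pre-step injections each release the full molar heat and the
        # cumulative curve steps at molar ratio = n
        exp = ITCExperiment()
        n_sites = 0.8
        params = BindingParams(n=n_sites, ka=1e12, dh=-10.0)
        heats = simulate_isotherm(exp, params)
        ratios = exp.molar_ratios()
        per_mole = -10.0 * 300e-6 * 20e-6 * 1e9  # dH * ligand moles/injection
        pre = ratios < n_sites * 0.9
        post = ratios > n_sites * 1.1
        np.testing.assert_allclose(heats[pre], per_mole, rtol=0.02)
        assert np.all(np.abs(heats[post]) < 0.02 * abs(per_mole))

    def test_heat_conservation_in_saturating_limit(self):
        # fine injections, saturating syringe: cumulative heat approaches
        # n * M0 * V0 * dH across a c grid
        expected = 1.0 * M0 * 0.002 * -10.0 * 1e9
        for c in (5, 20, 100, 500):
            exp = ITCExperiment(syringe_conc_uM=30000.0,
                                injection_volumes_ul=tuple([1.0] * 500))
            heats = simulate_isotherm(exp, BindingParams(ka=c / M0, dh=-10.0))
            assert heats.sum() == pytest.approx(expected, rel=5e-3)

    def test_rejects_nonphysical_params(self):
        with pytest.raises(ParameterError):
            BindingParams(ka=-1.0)
        with pytest.raises(ParameterError):
            BindingParams(n=0.0)


class TestFit:
    @pytest.mark.parametrize("c", [5, 20, 100, 500])
    def test_noiseless_round_trip_recovers_parameters(self, c):
        truth = BindingParams(n=0.95, ka=c / M0, dh=-8.5, q_offset=0.2)
        exp = ITCExperiment().with_heats(
            simulate_isotherm(ITCExperiment(), truth))
        fit = fit_single_site(exp)
        assert fit.converged
        assert fit.params.n == pytest.approx(truth.n, rel=1e-3)
        assert fit.params.ka == pytest.approx(truth.ka, rel=1e-3)
        assert fit.params.dh == pytest.approx(truth.dh, rel=1e-3)
        assert fit.kd_nM == pytest.approx(truth.kd_nM, rel=1e-3)

    def test_noisy_replicates_bracket_generating_kd(self):
        kd_true = 52.1
        fits = [
            fit_single_site(make_itc(
                params=BindingParams(ka=1e9 / kd_true, dh=-10.0),
                noise_fraction=0.02, seed=400 + i)[0]).kd_nM
            for i in range(30)
        ]
        fits = np.asarray(fits)
        assert fits.min() < kd_true < fits.max()
        assert fits.mean() == pytest.approx(kd_true, rel=0.15)

    def test_all_zero_heats_flagged_degenerate(self):
        exp = ITCExperiment().with_heats([0.0] * 25)
        fit = fit_single_site(exp)
        assert abs(fit.params.dh) < 1e-3
        # Ka unidentifiable -> c-value warning fires or stderr blows up
        assert not fit.c_value_ok or not np.isfinite(fit.stderr["log10_ka"]) \
            or fit.kd_stderr_nM > fit.kd_nM

    def test_drop_first_excludes_first_injection(self):
        exp, _ = make_itc(params=BindingParams(ka=1e7, dh=-10.0), seed=2)
        spiked = list(exp.heats_ucal)
        spiked[0] = 0.0  # simulate a degraded first injection
        exp_bad = exp.with_heats(spiked)
        clean_fit = OneSiteBindingModel(exp_bad, drop_first=True).fit()
        dirty_fit = OneSiteBindingModel(exp_bad, drop_first=False).fit()
        assert clean_fit.n_obs == 24
        assert abs(clean_fit.kd_nM - 100.0) < abs(dirty_fit.kd_nM - 100.0)

    def test_needs_heats_and_enough_injections(self):
        with pytest.raises(ValueError):
            OneSiteBindingModel(ITCExperiment())
        short = ITCExperiment(injection_volumes_ul=(20.0,) * 4,
                              heats_ucal=(1.0,) * 4)
        with pytest.raises(ValueError):
            OneSiteBindingModel(short)

    def test_summary_reports_key_quantities(self):
        exp, _ = make_itc(params=BindingParams(ka=1e7, dh=-10.0), seed=3)
        text = fit_single_site(exp).summary()
        for token in ("Kd (nM)", "dH (kcal/mol)", "dG (kcal/mol)",
                      "TdS (kcal/mol)", "c value"):
            assert token in text

    def test_from_dataframe_constructor(self):
        pd = pytest.importorskip("pandas")
        exp, _ = make_itc(params=BindingParams(ka=1e7, dh=-10.0), seed=4)
        frame = pd.DataFrame({
            "volume_ul": exp.injection_volumes_ul,
            "heat_ucal": exp.heats_ucal,
        })
        model = OneSiteBindingModel.from_dataframe(
            frame, cell_conc_uM=30.0, syringe_conc_uM=300.0)
        # constructor equivalence: same data, same fit as the direct path
        direct = fit_single_site(exp)
        assert model.fit().kd_nM == pytest.approx(direct.kd_nM, rel=1e-6)


class TestThermodynamics:
    def test_unit_ka_gives_zero_dg(self):
        dg, tds = thermodynamics(1.0, -5.0)
        assert dg == 0.0
        assert tds == -5.0

    def test_dh_equal_dg_gives_zero_tds(self):
        ka = 1e7
        dg, _ = thermodynamics(ka, 0.0)
        _, tds = thermodynamics(ka, dg)
        assert tds == pytest.approx(0.0, abs=1e-12)

    def test_52nM_kd_gives_minus_9_8_kcal(self):
        # Kd = 52.1 nM at 293.15 K
        ka = 1.0 / 52.1e-9
        dg, _ = thermodynamics(ka, -10.0, 293.15)
        assert dg == pytest.approx(-1.9872e-3 * 293.15 * math.log(ka), abs=1e-12)
        assert dg == pytest.approx(-9.77, abs=0.05)

    def test_rejects_nonpositive_inputs(self):
        with pytest.raises(ParameterError):
            thermodynamics(0.0, -10.0)
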