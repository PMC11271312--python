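"""Extinction ladder, GuHCl conversion, two-state model and global CD fit."""

import numpy as np
import pytest
from scipy.optimize import curve_fit

from chainsplit.denaturation import (
    CDDataset,
    RT_KJ_PER_MOL,
    TwoStateParams,
    concentration_from_absorbance,
    extinction_coefficient,
    fraction_unfolded,
    global_fit_unfolding,
    guhcl_from_refractive_index,
    two_state_signal,
)
from chainsplit.synthdata import SimulationConfig, simulate_cd_unfolding


class TestExtinction:
    @pytest.mark.parametrize(
        "n_tyr,expected", [(4, 6.20e3), (3, 4.65e3), (2, 3.10e3), (1, 1.55e3)]
    )
    def test_ladder_proportional_to_tyrosines(self, n_tyr, expected):
        assert extinction_coefficient(n_tyr) == pytest.approx(expected, rel=1e-12)

    @pytest.mark.parametrize("n_tyr", [0, 5])
    def test_out_of_range_rejected(self, n_tyr):
        with pytest.raises(ValueError):
            extinction_coefficient(n_tyr)

    def test_beer_lambert_concentration(self):
        # A276 = 0.31 with 4 Tyr over 0.5 cm -> 100 uM
        c = concentration_from_absorbance(0.31, n_tyr=4, pathlength_cm=0.5)
        assert c == pytest.approx(100e-6, rel=1e-12)


class TestGuHClConversion:
    def test_pure_buffer_is_zero(self):
        assert guhcl_from_refractive_index(1.3330, 1.3330) == 0.0

    def test_polynomial_value(self):
        # independent evaluation of 57.147 x + 38.68 x^2 - 91.60 x^3 at 0.1
        expected = float(np.polyval([-91.60, 38.68, 57.147, 0.0], 0.1))
        assert expected == pytest.approx(6.0099, abs=1e-4)
        assert guhcl_from_refractive_index(1.4330, 1.3330) == pytest.approx(expected)

    def test_monotone_increasing_over_working_range(self):
        dn = np.linspace(0.0, 0.15, 301)
        c = np.array([guhcl_from_refractive_index(1.333 + x, 1.333) for x in dn])
        assert np.all(np.diff(c) > 0)

    def test_negative_increment_rejected(self):
        with pytest.raises(ValueError):
            guhcl_from_refractive_index(1.3329, 1.3330)


class TestTwoStateModel:
    def _params(self, cm=4.5, m=4.0):
        return TwoStateParams(
            cm_M=cm, m_value=m, baselines={222.0: (-10.0, 0.1, -3.0, -0.05)}
        )

    def test_signal_at_midpoint_is_baseline_average(self):
        p = self._params()
        yn = -10.0 + 0.1 * 4.5
        yu = -3.0 - 0.05 * 4.5
        assert two_state_signal(p, 222.0, 4.5) == pytest.approx((yn + yu) / 2)

    def test_fully_folded_limit_at_zero_denaturant(self):
        p = self._params(cm=4.5, m=40.0)  # m*cm >> RT
        assert two_state_signal(p, 222.0, 0.0) == pytest.approx(-10.0, abs=1e-9)

    def test_fraction_matches_boltzmann_oracle(self):
        # direct formula evaluation at D = 8.3, cm = 4.5, m = 4
        dg = 4.0 * (4.5 - 8.3)
        expected = 1.0 / (1.0 + np.exp(dg / RT_KJ_PER_MOL))
        assert fraction_unfolded(8.3, 4.5, 4.0) == pytest.approx(expected, rel=1e-14)

    def test_fraction_is_half_at_midpoint_and_increasing(self):
        d = np.linspace(0, 8.3, 100)
        f = fraction_unfolded(d, 4.5, 4.0)
        assert fraction_unfolded(4.5, 4.5, 4.0) == pytest.approx(0.5, abs=1e-15)
        assert np.all(np.diff(f) > 0)

    def test_unknown_wavelength_rejected(self):
        with pytest.raises(KeyError):
            two_state_signal(self._params(), 999.0, 1.0)


class TestGlobalFit:
    def test_noiseless_dataset_recovered_exactly(self):
        data = simulate_cd_unfolding(4.50, 4.0, SimulationConfig(seed=0, noise_sd=0.0))
        fit = global_fit_unfolding(data)
        assert fit.converged
        assert fit.sse < 1e-10
        assert fit.cm_M == pytest.approx(4.50, abs=1e-8)
        assert fit.m_value == pytest.approx(4.0, abs=1e-6)
        assert fit.n_params == 2 + 4 * 21

    def test_recovery_at_2pct_noise(self):
        data = simulate_cd_unfolding(4.50, 4.0, SimulationConfig(seed=5, noise_sd=0.02))
        fit = global_fit_unfolding(data)
        assert fit.cm_M == pytest.approx(4.50, abs=0.05)

    def test_translation_equivariance(self):
        cfg = SimulationConfig(seed=9, noise_sd=0.02)
        data = simulate_cd_unfolding(4.50, 4.0, cfg)
        shifted = CDDataset(
            wavelengths_nm=data.wavelengths_nm,
            denaturant_M=tuple(d + 0.5 for d in data.denaturant_M),
            signal=data.signal,
        )
        fit = global_fit_unfolding(data)
        fit_shifted = global_fit_unfolding(shifted)
        assert fit_shifted.cm_M == pytest.approx(fit.cm_M + 0.5, abs=1e-6)
        assert fit_shifted.m_value == pytest.approx(fit.m_value, abs=1e-6)

    def test_single_wavelength_equals_per_curve_fit(self):
        """With one wavelength the global fit degenerates to the standard
        6-parameter single-curve fit (independent curve_fit route)."""
        cfg = SimulationConfig(seed=13, noise_sd=0.01)
        data = simulate_cd_unfolding(4.50, 4.0, cfg)
        wl = data.wavelengths_nm[10]
        single = CDDataset(
            wavelengths_nm=(wl,),
            denaturant_M=data.denaturant_M,
            signal=data.signal[10:11],
        )
        fit = global_fit_unfolding(single)

        def model(d, cm, m, yn, sn, yu, su):
            f = 1.0 / (1.0 + np.exp(m * (cm - d) / RT_KJ_PER_MOL))
            return (1 - f) * (yn + sn * d) + f * (yu + su * d)

        d = np.asarray(single.denaturant_M)
        popt, _ = curve_fit(
            model, d, single.signal[0], p0=[4.0, 4.0, -10, 0, -3, 0], maxfev=20000
        )
        assert fit.cm_M == pytest.approx(popt[0], abs=1e-4)
        assert fit.m_value == pytest.approx(popt[1], rel=1e-3)

    def test_midpoint_series_recovered_in_order(self):
        """The analogue series' midpoints (4.50-5.42 M) come back in rank
        order and each within 0.05 M; median error across seeds stays small."""
        midpoints = [4.50, 4.91, 5.01, 5.10, 5.42]
        errors = []
        for seed in range(10):
            fitted = [
                global_fit_unfolding(
                    simulate_cd_unfolding(cm, 4.0, SimulationConfig(seed=seed, noise_sd=0.02))
                ).cm_M
                for cm in midpoints
            ]
            assert fitted == sorted(fitted)
            errors += [abs(f - c) for f, c in zip(fitted, midpoints)]
        assert np.median(errors) < 0.05

    def test_unbracketed_transition_flagged(self):
        d = tuple(np.linspace(0.0, 2.0, 12))
        wl = (222.0,)
        params = TwoStateParams(cm_M=6.0, m_value=6.0, baselines={222.0: (-10, 0, -3, 0)})
        sig = np.array([two_state_signal(params, 222.0, np.array(d))])
        fit = global_fit_unfolding(CDDataset(wavelengths_nm=wl, denaturant_M=d, signal=sig))
        assert not fit.converged
        assert "not bracketed" in fit.message

    def test_too_few_denaturant_points_rejected(self):
        with pytest.raises(ValueError, match="denaturant"):
            global_fit_unfolding(
                CDDataset(
                    wavelengths_nm=(222.0,),
                    denaturant_M=tuple(np.linspace(0, 8, 5)),
                    signal=np.zeros((1, 5)),
                )
            )
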