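import numpy as np
import pandas as pd
import pytest

from sersquant import (
    SUDAN_DILUTION_LEVELS_M,
    ComponentLibrary,
    DesignTable,
    PeakModel,
    SimulationConfig,
    build_component_spectrum,
    saturating_library,
    simulate_dilution_series,
    simulate_mixtures,
    sudan_mixture_design,
)

AXIS = SimulationConfig().axis()


class TestComponentSpectrum:
    def test_empty_peak_list_gives_zero(self):
        np.testing.assert_array_equal(build_component_spectrum([], AXIS), 0.0)

    def test_lorentzian_apex_on_grid(self):
        spec = build_component_spectrum(
            [PeakModel(center=1000.0, width=5.0, height=1.0)], AXIS
        )
        assert AXIS[np.argmax(spec)] == 1000.0
        assert spec.max() == pytest.approx(1.0)

    def test_gaussian_apex_and_hwhm(self):
        spec = build_component_spectrum(
            [PeakModel(center=1000.0, width=10.0, height=2.0, shape="gaussian")], AXIS
        )
        assert spec.max() == pytest.approx(2.0)
        assert spec[AXIS == 1010.0][0] == pytest.approx(1.0, rel=1e-10)

    def test_sudan_i_local_maxima_at_reported_bands(self, library):
        spec = build_component_spectrum(library.analyte_peaks["sudan_i"], AXIS)
        for center in (722.0, 753.0, 1000.0, 1198.0, 1258.0, 1506.0):
            i = int(np.argmin(np.abs(AXIS - center)))
            assert spec[i] > spec[i - 2] and spec[i] > spec[i + 2]

    def test_out_of_axis_peak_warns_but_contributes(self, caplog):
        import logging

        with caplog.at_level(logging.WARNING, logger="sersquant.simulate"):
            spec = build_component_spectrum(
                [PeakModel(center=3000.0, width=50.0, height=1.0)], AXIS
            )
        assert "outside the axis" in caplog.text
        assert spec[-1] > 0

    def test_axis_must_increase(self):
        with pytest.raises(ValueError):
            build_component_spectrum([], AXIS[::-1])


class TestSimulateMixtures:
    def _noiseless(self, seed=0, replicates=1):
        return SimulationConfig(
            additive_noise_sd=0.0,
            multiplicative_noise_sd=0.0,
            drift_amplitude=0.0,
            replicates=replicates,
            seed=seed,
        )

    def test_zero_concentration_row_is_pure_matrix(self, library):
        design = DesignTable(
            pd.DataFrame({name: [0.0] for name in library.analytes}), unit="molar"
        )
        out = simulate_mixtures(design, library, self._noiseless())
        matrix = build_component_spectrum(library.matrix_peaks, AXIS)
        np.testing.assert_array_equal(out.intensities[0], matrix)

    def test_linearity_in_concentration(self, library):
        c = 1.0e-5
        design = DesignTable(
            pd.DataFrame({"sudan_ii": [c, 2 * c]}), unit="molar"
        )
        out = simulate_mixtures(design, library, self._noiseless())
        matrix = build_component_spectrum(library.matrix_peaks, AXIS)
        np.testing.assert_allclose(
            out.intensities[1] - matrix,
            2 * (out.intensities[0] - matrix),
            atol=1e-12,
        )

    def test_90_row_design_gives_270_spectra_90_ids(self, library):
        design = sudan_mixture_design(m=90, n_levels=21, seed=0)
        out = simulate_mixtures(design, library, SimulationConfig(seed=1))
        assert out.n_spectra == 270
        assert out.metadata["sample_id"].nunique() == 90
        assert out.metadata.groupby("sample_id").size().eq(3).all()

    def test_negative_concentration_rejected(self, library):
        with pytest.raises(ValueError):
            DesignTable(pd.DataFrame({"sudan_i": [-1e-6]}), unit="molar")

    def test_unknown_design_column_rejected(self, library):
        design = DesignTable(pd.DataFrame({"not_a_dye": [1e-6]}), unit="molar")
        with pytest.raises(ValueError, match="not_a_dye"):
            simulate_mixtures(design, library, self._noiseless())

    def test_saturation_bounds_analyte_contribution(self):
        lib = saturating_library(c_sat=2.0e-5)
        matrix = build_component_spectrum(lib.matrix_peaks, AXIS)
        big = 1.0  # vastly above c_sat
        design = DesignTable(pd.DataFrame({"sudan_i": [big]}), unit="molar")
        out = simulate_mixtures(design, lib, self._noiseless())
        component = build_component_spectrum(lib.analyte_peaks["sudan_i"], AXIS)
        bound = lib.gains["sudan_i"] * 2.0e-5 * component
        excess = out.intensities[0] - matrix
        assert np.all(excess <= bound + 1e-9)
        # approaches the bound to within c_sat/c relative error
        assert excess.max() == pytest.approx(bound.max(), rel=3e-5)


class TestDilutionSeries:
    def test_seven_levels_three_replicates(self, library, noiseless_config):
        out = simulate_dilution_series(
            "sudan_i", SUDAN_DILUTION_LEVELS_M, library, noiseless_config
        )
        assert out.n_spectra == 21
        assert out.metadata["conc_sudan_i_M"].nunique() == 7

    def test_replicates_identical_without_noise(self, noiseless_series):
        reps = noiseless_series.intensities[:3]
        np.testing.assert_array_equal(reps[0], reps[1])
        np.testing.assert_array_equal(reps[0], reps[2])

    def test_seeded_determinism_with_noise(self, library):
        cfg = SimulationConfig(seed=99)
        a = simulate_dilution_series("sudan_iii", SUDAN_DILUTION_LEVELS_M, library, cfg)
        b = simulate_dilution_series("sudan_iii", SUDAN_DILUTION_LEVELS_M, library, cfg)
        np.testing.assert_array_equal(a.intensities, b.intensities)
        assert a.metadata.equals(b.metadata)

    def test_unknown_analyte_lists_library(self, library, noiseless_config):
        with pytest.raises(ValueError, match="sudan_i"):
            simulate_dilution_series(
                "sudan_v", SUDAN_DILUTION_LEVELS_M, library, noiseless_config
            )

    def test_peak_apex_monotone_in_concentration(self, library, noiseless_config):
        out = simulate_dilution_series(
            "sudan_iv", SUDAN_DILUTION_LEVELS_M, library, noiseless_config
        )
        conc = out.metadata["conc_sudan_iv_M"].to_numpy()
        apex_channel = int(np.argmin(np.abs(AXIS - 1310.0)))
        order = np.argsort(conc[::3])
        apex = out.intensities[::3, apex_channel][order]
        assert np.all(np.diff(apex) > 0)


class TestValidatedTypes:
    def test_peak_invariants(self):
        with pytest.raises(ValueError):
            PeakModel(center=1000, width=0.0, height=1.0)
        with pytest.raises(ValueError):
            PeakModel(center=1000, width=5.0, height=-0.1)
        with pytest.raises(ValueError):
            PeakModel(center=1000, width=5.0, height=1.0, shape="voigt")

    def test_library_invariants(self):
        with pytest.raises(ValueError):
            ComponentLibrary(analyte_peaks={"a": []}, gains={"a": -1.0})

    def test_config_invariants(self):
        with pytest.raises(ValueError):
            SimulationConfig(axis_start=2000, axis_stop=400)
        with pytest.raises(ValueError):
            SimulationConfig(replicates=0)
        with pytest.raises(ValueError):
            SimulationConfig(additive_noise_sd=-0.1)

    def test_default_axis_801_channels(self):
        assert AXIS.size == 801
        assert AXIS[0] == 400.0 and AXIS[-1] == 2000.0
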