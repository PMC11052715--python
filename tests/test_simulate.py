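"""Synthetic-experiment generator: skin geometry, GTT dynamics,
absorption profiles, transients and protocol bookkeeping."""

import numpy as np
import pytest

from glucogate.bands import ChromophoreLibrary, ChromophoreSpectrum, Band
from glucogate.errors import ResolutionError
from glucogate.gtt import GTTParams, gtt_curve, blood_curve
from glucogate.signals import hilbert_envelope
from glucogate.simulate import (
    AcquisitionConfig,
    ProtocolConfig,
    absorption_profile,
    raster_positions,
    simulate_experiment,
    simulate_transient,
)
from glucogate.skin import Layer, SkinModel, make_default_skin


class TestSkinGeometry:
    def test_capillary_span_convention(self):
        skin = make_default_skin(capillary_depth_um=97.5, capillary_thickness_um=20.0)
        cap = next(la for la in skin.layers if la.name == "capillary")
        assert (cap.z_top_um, cap.z_bottom_um) == (87.5, 107.5)
        assert cap.glucose_pool == "blood"

    def test_zero_thickness_rejected(self):
        with pytest.raises(ValueError):
            make_default_skin(capillary_depth_um=97.5, capillary_thickness_um=0.0)

    def test_layers_contiguous_and_span_total_depth(self, skin):
        total = sum(la.thickness_um for la in skin.layers)
        assert total == pytest.approx(skin.total_depth_um)
        for a, b in zip(skin.layers, skin.layers[1:]):
            assert a.z_bottom_um == pytest.approx(b.z_top_um)

    def test_overlapping_layers_rejected(self):
        with pytest.raises(ValueError, match="contiguous"):
            SkinModel(
                layers=[
                    Layer(name="a", z_top_um=0, z_bottom_um=30, chromophores={}),
                    Layer(name="b", z_top_um=20, z_bottom_um=60, chromophores={}),
                ]
            )

    def test_negative_concentration_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            Layer(name="a", z_top_um=0, z_bottom_um=30, chromophores={"water": -0.1})


class TestGTT:
    def test_zero_dose_stays_at_baseline(self):
        params = GTTParams(dose_g_kg=0.0)
        curve = gtt_curve(params, np.linspace(-10, 150, 161))
        assert np.allclose(curve.blood_mgdl, params.baseline_mgdl)
        assert np.allclose(curve.isf_mgdl, params.isf_dilution * params.baseline_mgdl)

    def test_tiny_lag_limit_is_diluted_blood(self):
        params = GTTParams(isf_lag_min=1e-3)
        t = np.linspace(-5, 150, 311)
        curve = gtt_curve(params, t)
        assert np.allclose(
            curve.isf_mgdl, params.isf_dilution * curve.blood_mgdl, rtol=2e-3
        )

    def test_isf_matches_convolution_oracle(self):
        # exact solution of the first-order lag as a convolution integral
        params = GTTParams(isf_lag_min=12.0)
        t = np.linspace(0, 180, 1801)
        curve = gtt_curve(params, t)
        lag = params.isf_lag_min
        s = np.linspace(0, t[-1], 20001)
        b = blood_curve(params, s)
        oracle = np.empty_like(t)
        for i, ti in enumerate(t):
            m = s <= ti
            kern = np.exp(-(ti - s[m]) / lag) / lag
            oracle[i] = params.baseline_mgdl * np.exp(-ti / lag) + np.trapezoid(
                b[m] * kern, s[m]
            )
        oracle *= params.isf_dilution
        assert np.allclose(curve.isf_mgdl, oracle, rtol=2e-3, atol=0.2)
        assert np.argmax(curve.isf_mgdl) > np.argmax(curve.blood_mgdl)

    def test_isf_delay_monotone_in_lag(self):
        t = np.linspace(-10, 180, 1901)
        delays = []
        for lag in (5.0, 10.0, 20.0):
            curve = gtt_curve(GTTParams(isf_lag_min=lag), t)
            delays.append(
                t[np.argmax(curve.isf_mgdl)] - t[np.argmax(curve.blood_mgdl)]
            )
        assert delays[0] < delays[1] < delays[2]

    def test_nonfinite_params_rejected(self):
        with pytest.raises(ValueError):
            GTTParams(baseline_mgdl=float("nan"))


class TestAbsorptionProfile:
    def test_zero_concentrations_give_zero(self, library):
        empty = SkinModel(
            layers=[Layer(name="a", z_top_um=0, z_bottom_um=100, chromophores={"water": 0.0})]
        )
        z = np.linspace(0, 99, 100)
        mu = absorption_profile(empty, library, 1080.0, {}, z)
        assert np.allclose(mu, 0.0)

    def test_glucose_term_linear_in_blood_concentration(self, skin, library):
        z = np.linspace(0, 299, 300)
        base = absorption_profile(skin, library, 1080.0, {"blood_mgdl": 0.0, "isf_mgdl": 0.0}, z)
        g1 = absorption_profile(skin, library, 1080.0, {"blood_mgdl": 100.0, "isf_mgdl": 0.0}, z)
        g2 = absorption_profile(skin, library, 1080.0, {"blood_mgdl": 200.0, "isf_mgdl": 0.0}, z)
        assert np.allclose(g2 - base, 2.0 * (g1 - base), rtol=1e-12, atol=1e-12)

    def test_glucose_contribution_larger_at_994_than_1200(self, skin, library):
        z = np.linspace(85, 110, 50)
        state0 = {"blood_mgdl": 0.0, "isf_mgdl": 0.0}
        state1 = {"blood_mgdl": 200.0, "isf_mgdl": 0.0}
        d994 = absorption_profile(skin, library, 994.0, state1, z) - absorption_profile(
            skin, library, 994.0, state0, z
        )
        d1200 = absorption_profile(skin, library, 1200.0, state1, z) - absorption_profile(
            skin, library, 1200.0, state0, z
        )
        assert d994.max() > d1200.max()

    def test_unknown_chromophore_raises(self, library):
        weird = SkinModel(
            layers=[Layer(name="a", z_top_um=0, z_bottom_um=50, chromophores={"unobtainium": 1.0})]
        )
        with pytest.raises(KeyError, match="unobtainium"):
            absorption_profile(weird, library, 1080.0, {}, np.linspace(0, 49, 50))

    def test_out_of_support_wavenumber_raises(self, skin, library):
        with pytest.raises(ValueError, match="support"):
            absorption_profile(skin, library, 2000.0, {}, np.linspace(0, 10, 5))


class TestTransient:
    state = {"blood_mgdl": 100.0, "isf_mgdl": 80.0}

    def test_zero_absorption_gives_zero_trace(self, library):
        empty = SkinModel(
            layers=[Layer(name="a", z_top_um=0, z_bottom_um=100, chromophores={})]
        )
        tr = simulate_transient(empty, library, 1080.0, {}, noise_frac=0.0)
        assert np.allclose(tr.samples, 0.0)

    def test_thin_layer_time_of_flight(self, library):
        # absorbing sliver centred 75 um deep -> envelope max at
        # surface_offset + 75 um / c, within one sample
        thin = SkinModel(
            layers=[
                Layer(name="a", z_top_um=0, z_bottom_um=73.5, chromophores={}),
                Layer(name="b", z_top_um=73.5, z_bottom_um=76.5, chromophores={"water": 0.9}),
                Layer(name="c", z_top_um=76.5, z_bottom_um=300, chromophores={}),
            ],
            boundary_smoothing_um=0.0,
        )
        tr = simulate_transient(thin, library, 1080.0, self.state, noise_frac=0.0)
        env = hilbert_envelope(tr)
        t_max = env.times[np.argmax(env.values)]
        expected = thin.surface_offset_time_s + 75e-6 / thin.speed_of_sound_m_s
        assert abs(t_max - expected) <= tr.dt * 1.0001

    def test_explicit_averaging_matches_clt_prediction(self, skin, library):
        acq = AcquisitionConfig(n_samples=256)
        clean = simulate_transient(skin, library, 1080.0, self.state, acq, noise_frac=0.0)
        resid = []
        for s in range(30):
            tr = simulate_transient(
                skin, library, 1080.0, self.state, acq,
                noise_frac=0.014, seed=s, n_averages=1000, explicit_averaging=True,
            )
            resid.append(tr.samples - clean.samples)
        sd = np.std(np.concatenate(resid))
        predicted = 0.014 * np.abs(clean.samples).max() / np.sqrt(1000)
        assert sd == pytest.approx(predicted, rel=0.15)

    def test_seed_determinism(self, skin, library):
        a = simulate_transient(skin, library, 1080.0, self.state, seed=7)
        b = simulate_transient(skin, library, 1080.0, self.state, seed=7)
        assert np.array_equal(a.samples, b.samples)

    def test_negative_noise_rejected(self, skin, library):
        with pytest.raises(ValueError, match="noise_frac"):
            simulate_transient(skin, library, 1080.0, self.state, noise_frac=-0.1)

    def test_coarse_dt_rejected(self, skin, library):
        with pytest.raises(ResolutionError):
            simulate_transient(
                skin, library, 1080.0, self.state,
                AcquisitionConfig(dt_s=5e-9, n_samples=64), noise_frac=0.0,
            )

    def test_beer_lambert_linearity_regime(self, library):
        # with mu_a * z << 1 the gated glucose response is linear in
        # blood glucose to within 1% of the exact Beer-Lambert value
        weak = ChromophoreLibrary(
            entries={
                "water": ChromophoreSpectrum(baseline=(1.0, 0.0)),
                "glucose": ChromophoreSpectrum(
                    bands=(
                        Band(994.0, 25.0, 2e-4),
                        Band(1036.0, 25.0, 2e-4),
                        Band(1080.0, 25.0, 2e-4),
                        Band(1109.0, 25.0, 2e-4),
                    )
                ),
                "lactate": ChromophoreSpectrum(
                    bands=(Band(1040.0, 25.0, 0.0), Band(1125.0, 25.0, 0.0))
                ),
            }
        )
        skin = SkinModel(
            layers=[
                Layer(name="above", z_top_um=0, z_bottom_um=90, chromophores={"water": 0.1}),
                Layer(
                    name="cap", z_top_um=90, z_bottom_um=105,
                    chromophores={"water": 0.1}, glucose_pool="blood",
                ),
                Layer(name="below", z_top_um=105, z_bottom_um=300, chromophores={"water": 0.1}),
            ],
            boundary_smoothing_um=0.0,
        )
        peaks = []
        doses = (50.0, 150.0, 250.0)
        for g in doses:
            tr = simulate_transient(
                skin, weak, 1080.0, {"blood_mgdl": g, "isf_mgdl": 0.0}, noise_frac=0.0
            )
            env = hilbert_envelope(tr)
            t = env.times
            lo = 50e-9 + 90e-6 / 1500.0
            hi = 50e-9 + 105e-6 / 1500.0
            peaks.append(env.values[(t >= lo) & (t < hi)].max())
        peaks = np.asarray(peaks)
        slope = (peaks[-1] - peaks[0]) / (doses[-1] - doses[0])
        linear = peaks[0] + slope * (np.asarray(doses) - doses[0])
        assert np.allclose(peaks, linear, rtol=0.01)


class TestExperiment:
    def test_protocol_counts_match_defaults(self, dataset):
        protocol = ProtocolConfig()
        assert protocol.wavenumber_grid.size == 100
        for loc in ("P1", "P2"):
            recs = dataset.records[loc]
            assert len(recs) == 50
            assert all(r.wavenumbers.size == 100 for r in recs)
        assert dataset.reference.times_min.size == 50

    def test_same_seed_regenerates_identically(self):
        a = simulate_experiment(seed=42)
        b = simulate_experiment(seed=42)
        assert np.array_equal(a.reference.glucose_mgdl, b.reference.glucose_mgdl)
        assert np.array_equal(
            a.records["P1"][10].transients, b.records["P1"][10].transients
        )
        assert np.array_equal(
            a.records["P2"][49].transients, b.records["P2"][49].transients
        )

    def test_reference_strictly_increasing_and_alternating_offsets(self, dataset):
        assert np.all(np.diff(dataset.reference.times_min) > 0)
        t1 = dataset.records["P1"][0].timestamp_min
        t2 = dataset.records["P2"][0].timestamp_min
        assert t2 - t1 == pytest.approx(1.5)

    def test_avascular_location_has_no_blood_pool_truth(self, dataset):
        # both locations share the blood curve truth; the avascular point's
        # ISF lags it further
        r1 = dataset.records["P1"][30]
        r2 = dataset.records["P2"][30]
        assert r1.blood_mgdl != r1.isf_mgdl
        assert r2.isf_mgdl < r2.blood_mgdl


class TestRaster:
    def test_paper_grid_has_4900_points(self):
        assert len(raster_positions(70, 70)) == 4900

    def test_single_point(self):
        assert raster_positions(1, 1) == [(0, 0)]

    def test_row_major_order(self):
        got = raster_positions(3, 4)
        expected = [(x, y) for y in range(4) for x in range(3)]
        assert got == expected
        assert len(got) == 12

    @pytest.mark.parametrize("nx,ny", [(0, 5), (5, 0), (-1, 2)])
    def test_nonpositive_dimensions_rejected(self, nx, ny):
        with pytest.raises(ValueError):
            raster_positions(nx, ny)
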