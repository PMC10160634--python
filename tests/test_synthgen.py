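import numpy as np
import pandas as pd
import pytest
from scipy.integrate import trapezoid

from chlorokin.errors import LayoutCapacityError
from chlorokin.synthgen import (
    DESTRUCTIVE_TIMEPOINTS_MIN,
    KineticParams,
    NoiseConfig,
    PchlideParams,
    SpectralComponent,
    SpectrumModel,
    chl_kinetics,
    default_spectrum_model,
    make_layout,
    pchlide_kinetics,
    render_stack,
    sample_virtual_pigments,
    synth_spectrum,
)


class TestLayout:
    def test_default_grid_fills_five_variants(self):
        layout = make_layout([f"v{i}" for i in range(5)], rng_seed=1)
        assert layout.n_cells == 15
        for v in layout.variants:
            assert len(layout.cells_for_variant(v)) == 3

    def test_single_variant_can_fill_plate(self):
        layout = make_layout(["only"], rng_seed=0, replicate_cells_per_variant=15)
        assert len(layout.cells_for_variant("only")) == 15

    def test_capacity_error(self):
        with pytest.raises(LayoutCapacityError):
            make_layout([f"v{i}" for i in range(6)], rng_seed=0)

    def test_same_seed_identical_assignment(self):
        a = make_layout(["x", "y"], rng_seed=42)
        b = make_layout(["x", "y"], rng_seed=42)
        assert a.assignment == b.assignment
        c = make_layout(["x", "y"], rng_seed=43)
        assert a.assignment != c.assignment

    def test_seedlings_per_genotype(self):
        # 3 replicate cells × ~30 seedlings per cell = 90 per genotype
        layout = make_layout([f"v{i}" for i in range(5)], rng_seed=1)
        per_genotype = layout.replicate_cells_per_variant * layout.seedlings_per_cell
        assert per_genotype == 90


class TestChlKinetics:
    def test_starts_at_baseline(self):
        p = KineticParams()
        assert chl_kinetics(0.0, p) == pytest.approx(p.f_base)

    def test_limit(self):
        p = KineticParams()
        expected = (
            p.f_base
            + p.burst_amplitude
            + p.plateau * (1.0 - 1.0 / (1.0 + np.exp(p.exp_rate * p.exp_onset)))
        )
        assert chl_kinetics(1e6, p) == pytest.approx(expected)

    def test_monotone_non_decreasing(self):
        t = np.linspace(0, 240, 2000)
        f = chl_kinetics(t)
        assert np.all(np.diff(f) >= -1e-12)

    def test_lag_slower_than_exponential_onset(self):
        # numeric derivative: mid-lag rate is below the rate at exp_onset
        p = KineticParams()
        eps = 1e-4
        def rate(t):
            return (chl_kinetics(t + eps, p) - chl_kinetics(t - eps, p)) / (2 * eps)
        assert rate(50.0) < rate(p.exp_onset)

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            chl_kinetics(-1.0)


class TestPchlideKinetics:
    def test_starts_at_p0(self):
        p = PchlideParams()
        assert pchlide_kinetics(0.0, p) == pytest.approx(p.p0)

    def test_minimum_near_60_min(self):
        # grid-search oracle over the protocol span
        t = np.linspace(0, 240, 4801)
        argmin = t[np.argmin(pchlide_kinetics(t))]
        assert 50 <= argmin <= 70

    def test_resynthesis_exceeds_minimum(self):
        assert pchlide_kinetics(240.0) > pchlide_kinetics(60.0)


class TestRenderStack:
    def test_noiseless_means_match_truth(self, noiseless_sim):
        stack, truth = noiseless_sim
        zone = truth.pixel_labels
        cot = zone == 3
        cell = truth.cell_labels
        for c in np.unique(cell[cell > 0])[:2]:
            sel = cot & (cell == c)
            expected = truth.true_zone_traces.query("cell == @c and zone == 'cotyledon'")
            for k in (0, 60, 119):
                got = stack.data[k][sel].mean()
                want = expected.loc[expected["round"] == k, "true_mean"].iloc[0]
                # uint16 rounding is the only discrepancy allowed
                assert got == pytest.approx(want, abs=0.5)

    def test_pixel_ceiling(self, noisy_sim):
        stack, _ = noisy_sim
        assert stack.data.max() <= 65535

    def test_determinism(self, tiny_layout, default_protocol, tiny_kinetics):
        kw = dict(noise=NoiseConfig(), rng_seed=5, image_shape=(64, 64))
        s1, _ = render_stack(tiny_layout, default_protocol, tiny_kinetics, **kw)
        s2, _ = render_stack(tiny_layout, default_protocol, tiny_kinetics, **kw)
        assert np.array_equal(s1.data, s2.data)
        s3, _ = render_stack(
            tiny_layout, default_protocol, tiny_kinetics,
            noise=NoiseConfig(), rng_seed=6, image_shape=(64, 64),
        )
        assert not np.array_equal(s1.data, s3.data)

    def test_noise_sd_calibration(self, tiny_layout, default_protocol, tiny_kinetics):
        # background pixels carry read noise + shot noise on the pedestal
        noise = NoiseConfig(read_sd=6.0, shot_coeff=0.5, cell_cv=0.0, background_level=100.0)
        stack, truth = render_stack(
            tiny_layout, default_protocol, tiny_kinetics,
            noise=noise, rng_seed=3, image_shape=(64, 64),
        )
        bg = truth.pixel_labels == 0
        sample = stack.data[:, bg][:200].astype(float).ravel()
        expected_sd = np.hypot(noise.read_sd, noise.shot_coeff * np.sqrt(100.0))
        assert abs(sample.std() - expected_sd) / expected_sd < 0.2

    def test_zone_ordering(self, noiseless_sim):
        stack, truth = noiseless_sim
        tr = truth.true_zone_traces.pivot_table(
            index=["cell", "round"], columns="zone", values="true_mean"
        )
        assert (tr["cotyledon"] >= tr["hypocotyl"]).all()
        assert (tr["hypocotyl"] >= tr["root"]).all()

    def test_too_small_image_rejected(self, tiny_layout, default_protocol, tiny_kinetics):
        from chlorokin.errors import GeometryError

        with pytest.raises(GeometryError):
            render_stack(
                tiny_layout, default_protocol, tiny_kinetics,
                noise=NoiseConfig.zero(), rng_seed=0, image_shape=(10, 10),
            )


class TestVirtualPigments:
    def test_normalized_to_t8(self):
        df = sample_virtual_pigments({"wt": KineticParams()})
        t8 = df[df["timepoint"] == "T8"]
        for col in ("chl_a", "chl_b", "pchlide"):
            assert t8[col].iloc[0] == pytest.approx(1.0)

    def test_noiseless_tracks_fluorescence_exactly(self):
        kp = KineticParams()
        df = sample_virtual_pigments({"wt": kp})
        f = chl_kinetics(df["time_min"].to_numpy(), kp)
        r = np.corrcoef(df["chl_a"], f)[0, 1]
        assert r == pytest.approx(1.0, abs=1e-12)

    def test_timepoint_outside_span_rejected(self):
        with pytest.raises(ValueError):
            sample_virtual_pigments({"wt": KineticParams()}, timepoints_min=[0, 100, 300])

    def test_nine_timepoints(self):
        df = sample_virtual_pigments({"wt": KineticParams()})
        assert list(df["timepoint"]) == [f"T{i}" for i in range(9)]
        assert df["time_min"].iloc[3] == 60.0  # pchlide-minimum collection point
        assert df["time_min"].iloc[5] == 120.0  # resynthesis-onset collection point


class TestSynthSpectrum:
    def test_t0_only_pchlide_bands(self):
        model = default_spectrum_model()
        s = synth_spectrum(0.0, model)
        by_name = {c.name: c.amplitude(0.0) for c in model.components}
        assert by_name["free_pchlide"] > 0 and by_name["photoactive_pchlide"] > 0
        for name in ("chl_unbound", "psii_core", "lhc_broad"):
            assert by_name[name] == pytest.approx(0.0, abs=1e-12)
        # consequently the two spectral maxima sit at 630 and 654 nm
        wl = s["wavelength_nm"].to_numpy()
        peak = wl[s["intensity"].to_numpy().argmax()]
        assert peak == pytest.approx(654.0, abs=1.0)

    def test_single_component_peak_at_center(self):
        comp = SpectralComponent("one", 700.0, 10.0, lambda t: 2.0)
        model = SpectrumModel(components=(comp,), wavelength_grid_nm=np.arange(600.0, 801.0))
        s = synth_spectrum(5.0, model)
        assert s["wavelength_nm"][s["intensity"].idxmax()] == 700.0

    def test_integral_matches_quadrature(self):
        model = default_spectrum_model()
        t = 120.0
        s = synth_spectrum(t, model)
        integral = trapezoid(s["intensity"], s["wavelength_nm"])
        expected = sum(
            c.amplitude(t) * c.width_nm * np.sqrt(2 * np.pi) for c in model.components
        )
        assert integral == pytest.approx(expected, rel=1e-4)

    def test_grid_not_covering_rejected(self):
        model = default_spectrum_model(wavelength_grid_nm=np.arange(640.0, 700.0))
        with pytest.raises(ValueError):
            synth_spectrum(0.0, model)
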