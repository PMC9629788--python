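import io

import numpy as np
import pytest

from conftest import make_params
from cropsail.errors import ForwardModelError, SchemaError
from cropsail.rtm import (
    MICASENSE_LIMITS,
    N_WAVELENGTHS,
    WAVELENGTHS,
    PlateSailModel,
    SpectralBand,
    Spectrum,
    builtin_micasense_bands,
    forward_reflectance,
    load_response_csv,
    resample_bands,
    soil_spectrum,
)

MODEL = PlateSailModel()


def at(nm, arr):
    return arr[int(nm - 400)]


class TestForwardModel:
    def test_output_length_and_bounds(self):
        s = MODEL.reflectance(make_params())
        assert s.reflectance.shape == (2101,)
        assert s.reflectance.min() >= 0.0 and s.reflectance.max() <= 1.0

    def test_deterministic(self):
        p = make_params()
        a = MODEL.reflectance(p).reflectance
        b = MODEL.reflectance(p).reflectance
        assert np.array_equal(a, b)

    def test_nir_increases_with_lai(self):
        lo = MODEL.reflectance(make_params(LAI=0.5)).reflectance
        hi = MODEL.reflectance(make_params(LAI=6.0)).reflectance
        assert at(800, hi) > at(800, lo)

    def test_red_decreases_with_chlorophyll(self):
        lo = MODEL.reflectance(make_params(Cab=10.0, Car=2.16)).reflectance
        hi = MODEL.reflectance(make_params(Cab=60.0, Car=12.96)).reflectance
        assert at(670, hi) < at(670, lo)

    def test_swir_decreases_with_water(self):
        lo = MODEL.reflectance(make_params(Cw=0.005)).reflectance
        hi = MODEL.reflectance(make_params(Cw=0.03)).reflectance
        for nm in (1450, 1940):
            assert at(nm, hi) < at(nm, lo)

    def test_bare_canopy_returns_soil(self):
        s = MODEL.reflectance(make_params(LAI=0.0))
        assert np.allclose(s.reflectance, soil_spectrum(1.0))

    def test_hotspot_brightens_backscatter(self):
        # off-nadir sun: a larger hot-spot parameter keeps the sunlit and
        # viewed gap fractions correlated deeper into the canopy -> brighter
        small = MODEL.reflectance(make_params(SZA=30.0, hspot=0.05)).reflectance
        large = MODEL.reflectance(make_params(SZA=30.0, hspot=1.0)).reflectance
        assert at(800, large) > at(800, small)

    def test_batch_equals_loop(self):
        params = [make_params(LAI=v) for v in (0.5, 2.0, 5.0)]
        batch = MODEL.reflectance_batch(params)
        for i, p in enumerate(params):
            assert np.array_equal(batch[i], MODEL.reflectance(p).reflectance)

    @pytest.mark.parametrize("kw,msg", [
        (dict(LAI=-1.0), "LAI"),
        (dict(Cab=-5.0), "Cab"),
        (dict(SZA=95.0), "SZA"),
        (dict(VZA=10.0), "nadir"),
        (dict(Ns=0.0), "Ns"),
    ])
    def test_inadmissible_parameters_named(self, kw, msg):
        with pytest.raises(ForwardModelError, match=msg):
            MODEL.reflectance(make_params(**kw))

    def test_bounds_hold_over_random_sweep(self, rng):
        for _ in range(50):
            p = make_params(
                Ns=rng.uniform(1.0, 3.0), Cab=rng.uniform(5, 80),
                Car=rng.uniform(1, 18), Cw=rng.uniform(0.004, 0.03),
                Cm=rng.uniform(0.002, 0.012), LAI=rng.uniform(0.1, 8),
                hspot=rng.uniform(0.05, 1.0), SZA=rng.uniform(0, 70),
                RAA=rng.uniform(-90, 90),
            )
            r = MODEL.reflectance(p).reflectance
            assert r.shape == (N_WAVELENGTHS,)
            assert r.min() >= 0.0 and r.max() <= 1.0


class TestSpectrumInvariants:
    def test_wrong_length_rejected(self):
        with pytest.raises(ForwardModelError):
            Spectrum(np.zeros(100))

    def test_out_of_range_rejected(self):
        bad = np.zeros(N_WAVELENGTHS)
        bad[5] = 1.5
        with pytest.raises(ForwardModelError):
            Spectrum(bad)


class TestResampleBands:
    def test_constant_spectrum_any_band(self):
        s = Spectrum(np.full(N_WAVELENGTHS, 0.3))
        vals = resample_bands(s, builtin_micasense_bands())
        assert np.allclose(vals, 0.3)

    def test_uniform_response_is_plain_mean(self):
        r = np.linspace(0.1, 0.6, N_WAVELENGTHS)
        band = SpectralBand("red", 663, 673)
        expected = r[663 - 400:674 - 400].mean()
        assert resample_bands(Spectrum(r), [band])[0] == pytest.approx(expected, rel=1e-12)

    def test_triangular_response_matches_brute_force(self):
        r = np.linspace(0.0, 1.0, N_WAVELENGTHS)
        phi = np.concatenate([np.arange(1, 7), np.arange(5, 0, -1)]).astype(float)
        band = SpectralBand("tri", 700, 710, phi)
        num = sum(phi[j] * r[700 - 400 + j] for j in range(11))
        assert resample_bands(Spectrum(r), [band])[0] == pytest.approx(
            num / phi.sum(), rel=1e-12)

    def test_rescaling_response_invariance(self):
        r = np.linspace(0.05, 0.8, N_WAVELENGTHS)
        phi = np.abs(np.sin(np.arange(41) / 3.0)) + 0.1
        a = resample_bands(Spectrum(r), [SpectralBand("b", 820, 860, phi)])[0]
        b = resample_bands(Spectrum(r), [SpectralBand("b", 820, 860, 7.3 * phi)])[0]
        assert a == pytest.approx(b, rel=1e-12)

    def test_band_value_within_spectrum_range(self, rng):
        r = rng.uniform(0, 1, N_WAVELENGTHS)
        for band in builtin_micasense_bands():
            v = resample_bands(Spectrum(r), [band])[0]
            seg = r[band.lambda_min - 400:band.lambda_max - 400 + 1]
            assert seg.min() - 1e-12 <= v <= seg.max() + 1e-12

    def test_band_outside_grid_rejected(self):
        with pytest.raises(SchemaError):
            resample_bands(Spectrum(np.full(N_WAVELENGTHS, 0.2)),
                           [SpectralBand("uv", 300, 410)])

    def test_all_zero_response_rejected(self):
        with pytest.raises(SchemaError):
            SpectralBand("dead", 500, 510, np.zeros(11))


class TestMicasenseBands:
    def test_five_bands_with_printed_limits(self):
        bands = builtin_micasense_bands()
        assert len(bands) == 5
        limits = {b.name: (b.lambda_min, b.lambda_max) for b in bands}
        assert limits["blue"] == (465, 485)
        assert limits["green"] == (550, 570)
        assert limits["red"] == (663, 673)
        assert limits["nir"] == (820, 860)
        assert limits["red_edge"] == (712, 722)
        assert limits == MICASENSE_LIMITS


def test_response_csv_loader_round_trip(tmp_path):
    lines = ["band,wavelength_nm,response"]
    for wl in range(663, 674):
        lines.append(f"red,{wl},{1.0 if wl != 668 else 2.0}")
    path = tmp_path / "resp.csv"
    path.write_text("\n".join(lines))
    bands = load_response_csv(path)
    assert len(bands) == 1
    assert bands[0].lambda_min == 663 and bands[0].lambda_max == 673
    assert bands[0].response[5] == 2.0
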