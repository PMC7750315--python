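import numpy as np
import pandas as pd
import pytest

from pollicolor.errors import SpectrumError
from pollicolor.spectra import (
    ReflectanceSpectrum,
    SpectrumCollection,
    aggregate,
    center_and_bin,
    read_spectra,
    smooth,
    trim,
)


def make_spec(wl, refl, species="sp", individual="i1", **kw):
    return ReflectanceSpectrum(
        wavelengths=np.asarray(wl, float), reflectance=np.asarray(refl, float),
        species=species, individual=individual, **kw
    )


class TestReadSpectra:
    def test_identity_ingestion_two_column_long(self, tmp_path):
        wl = np.arange(300, 701)
        df = pd.DataFrame(
            {"wl": wl, "reflectance": 50.0, "species": "a", "individual": "a1",
             "tissue": "corolla"}
        )
        path = tmp_path / "s.csv"
        df.to_csv(path, index=False)
        coll = read_spectra(path, layout="long")
        assert len(coll) == 1
        s = coll.spectra[0]
        assert s.wavelengths.size == 401
        assert np.allclose(s.reflectance, 50.0)

    def test_wide_fan_out(self, tmp_path):
        wl = np.arange(300, 701)
        df = pd.DataFrame({"wl": wl, "s1": 10.0, "s2": 20.0, "s3": 30.0})
        path = tmp_path / "w.csv"
        df.to_csv(path, index=False)
        coll = read_spectra(path, layout="wide")
        assert len(coll) == 3
        grids = {tuple(s.wavelengths) for s in coll}
        assert len(grids) == 1

    def test_descending_wavelengths_error(self, tmp_path):
        df = pd.DataFrame({"wl": [700, 500, 300], "s1": [1.0, 2.0, 3.0]})
        path = tmp_path / "bad.csv"
        df.to_csv(path, index=False)
        with pytest.raises(SpectrumError, match="non-monotone"):
            read_spectra(path, layout="wide")

    def test_missing_metadata_error(self, tmp_path):
        df = pd.DataFrame({"wl": [300, 400], "reflectance": [1.0, 2.0]})
        path = tmp_path / "m.csv"
        df.to_csv(path, index=False)
        with pytest.raises(SpectrumError, match="missing metadata"):
            read_spectra(path, layout="long")

    def test_common_grid_is_range_intersection(self, tmp_path):
        rows = []
        for sp, lo, hi in (("a", 250, 800), ("b", 320, 750)):
            wl = np.arange(lo, hi + 1)
            rows.append(pd.DataFrame({"wl": wl, "reflectance": 5.0, "species": sp,
                                      "individual": sp, "tissue": "corolla"}))
        path = tmp_path / "two.csv"
        pd.concat(rows).to_csv(path, index=False)
        coll = read_spectra(path, layout="long")
        assert coll.wavelengths[0] == 320
        assert coll.wavelengths[-1] == 750


class TestTrim:
    def test_trim_to_insect_range(self):
        wl = np.arange(250, 1101)
        s = make_spec(wl, np.linspace(0, 100, wl.size))
        out = trim(s, 300, 700)
        assert out.wavelengths[0] == 300 and out.wavelengths[-1] == 700

    def test_trim_identity(self, flat_spectrum):
        out = trim(flat_spectrum, 300, 700)
        assert np.array_equal(out.wavelengths, flat_spectrum.wavelengths)
        assert np.array_equal(out.reflectance, flat_spectrum.reflectance)

    def test_trim_idempotent(self):
        wl = np.arange(250, 801)
        s = make_spec(wl, np.linspace(0, 100, wl.size))
        once = trim(s, 300, 700)
        twice = trim(once, 300, 700)
        assert np.array_equal(once.reflectance, twice.reflectance)

    def test_inverted_window_error(self, flat_spectrum):
        with pytest.raises(SpectrumError, match="invalid trim window"):
            trim(flat_spectrum, 400, 350)

    def test_window_outside_range_error(self, flat_spectrum):
        with pytest.raises(SpectrumError, match="outside measured range"):
            trim(flat_spectrum, 250, 700)


class TestSmooth:
    def test_constant_invariance(self, grid):
        s = make_spec(grid, np.full(grid.size, 30.0))
        out = smooth(s, span=0.25)
        assert np.allclose(out.reflectance, 30.0, atol=1e-8)

    def test_line_reproduction(self, grid):
        line = 2.0 + 0.05 * grid
        s = make_spec(grid, line)
        out = smooth(s, span=0.25)
        assert np.allclose(out.reflectance, line, atol=1e-6)

    def test_noise_variance_reduced(self, grid):
        rng = np.random.default_rng(42)
        noise = 50.0 + rng.normal(0, 5.0, grid.size)
        s = make_spec(grid, noise)
        out = smooth(s, span=0.25)
        assert out.reflectance.var() < s.reflectance.var()

    def test_negative_clipped(self, grid):
        rng = np.random.default_rng(0)
        s = make_spec(grid, rng.normal(0.0, 1.0, grid.size))
        out = smooth(s, span=0.25)
        assert np.all(out.reflectance >= 0)

    def test_too_few_points_error(self):
        s = make_spec(np.arange(5.0) + 300, np.ones(5))
        with pytest.raises(SpectrumError, match="too few points"):
            smooth(s)

    def test_bad_span_error(self, flat_spectrum):
        with pytest.raises(SpectrumError, match="span"):
            smooth(flat_spectrum, span=0.0)


class TestAggregate:
    def test_mean_of_equals(self, grid):
        a = make_spec(grid, np.full(grid.size, 12.0), individual="i1")
        b = make_spec(grid, np.full(grid.size, 12.0), individual="i1")
        out = aggregate(SpectrumCollection([a, b]), level="individual")
        assert len(out) == 1
        assert np.allclose(out.spectra[0].reflectance, 12.0)
        assert out.spectra[0].n_averaged == 2

    def test_midpoint(self, grid):
        a = make_spec(grid, np.full(grid.size, 10.0))
        b = make_spec(grid, np.full(grid.size, 30.0))
        out = aggregate(SpectrumCollection([a, b]), level="species")
        assert np.allclose(out.spectra[0].reflectance, 20.0)

    def test_individual_count_contract(self, grid):
        spectra = []
        for ind in range(3):
            for rep in range(2):
                spectra.append(
                    make_spec(grid, np.full(grid.size, float(ind)), individual=f"i{ind}")
                )
        out = aggregate(SpectrumCollection(spectra), level="individual")
        assert len(out) == 3

    def test_species_keeps_morphs_separate(self, grid):
        a = make_spec(grid, np.full(grid.size, 5.0), morph="green")
        b = make_spec(grid, np.full(grid.size, 50.0), morph="maroon")
        out = aggregate(SpectrumCollection([a, b]), level="species+morph")
        assert len(out) == 2

    def test_commutes_with_linear_maps(self, grid):
        rng = np.random.default_rng(3)
        specs = [make_spec(grid, rng.uniform(0, 100, grid.size)) for _ in range(4)]
        agg_then_map = aggregate(SpectrumCollection(specs), "species").spectra[0].reflectance * 2 + 1
        mapped = [s.with_values(s.reflectance * 2 + 1) for s in specs]
        map_then_agg = aggregate(SpectrumCollection(mapped), "species").spectra[0].reflectance
        assert np.allclose(agg_then_map, map_then_agg)

    def test_empty_error(self):
        with pytest.raises(SpectrumError, match="empty"):
            aggregate(SpectrumCollection([]), level="species")


class TestCenterAndBin:
    def test_constant_gives_zeros(self, flat_spectrum):
        out = center_and_bin(flat_spectrum, n_bins=10)
        assert np.allclose(out, 0.0)

    def test_step_spectrum_oracle(self, grid):
        # oracle: 1-nm grid 300..700 has 401 points, 201 of them >= 500
        refl = np.where(grid < 500, 0.0, 100.0)
        s = make_spec(grid, refl)
        out = center_and_bin(s, n_bins=10)
        mean = 100.0 * 201 / 401
        expected = np.array([-mean] * 5 + [100.0 - mean] * 5)
        assert np.allclose(out, expected)

    def test_bin_edges_are_40nm(self, flat_spectrum):
        # 10 bins over [300, 700] -> first bin covers [300, 340)
        refl = np.where(flat_spectrum.wavelengths < 340, 100.0, 0.0)
        s = flat_spectrum.with_values(refl)
        out = center_and_bin(s, n_bins=10)
        mean = 100.0 * 40 / 401
        assert out[0] == pytest.approx(100.0 - mean)
        assert np.allclose(out[1:], -mean)

    def test_constant_shift_invariance(self, grid):
        rng = np.random.default_rng(7)
        refl = rng.uniform(0, 80, grid.size)
        s = make_spec(grid, refl)
        shifted = s.with_values(refl + 13.5)
        assert np.allclose(center_and_bin(s), center_and_bin(shifted))

    def test_wrong_span_error(self):
        wl = np.arange(350, 701)
        s = make_spec(wl, np.ones(wl.size))
        with pytest.raises(SpectrumError, match="expected exactly"):
            center_and_bin(s)


def test_monotone_wavelength_invariant_enforced():
    with pytest.raises(SpectrumError, match="non-monotone"):
        make_spec([300, 299, 301], [1, 2, 3])
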