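import numpy as np
import pytest

from pollicolor.errors import VisionError
from pollicolor.spectra import ReflectanceSpectrum
from pollicolor.vision import (
    ColorLocus,
    Illuminant,
    NoiseModel,
    achromatic_contrast,
    energy_to_photon_flux,
    fly_distance,
    fly_locus,
    load_illuminant,
    load_receptor_set,
    maxwell_locus,
    quantum_catch,
    receptor_template,
    rnl_chromatic_distance,
)


def spec_of(grid, refl, species="x", individual="x1", tissue="corolla"):
    return ReflectanceSpectrum(
        wavelengths=grid, reflectance=np.broadcast_to(refl, grid.shape).copy(),
        species=species, individual=individual, tissue=tissue,
    )


def tri_locus(q, viewer="hawkmoth"):
    q = np.asarray(q, float)
    return ColorLocus(
        viewer=viewer, receptor_names=("UV", "B", "G"), Q=q, q=q, r=q / q.sum()
    )


def tetra_locus(q, viewer="blowfly"):
    q = np.asarray(q, float)
    return ColorLocus(
        viewer=viewer, receptor_names=("R7p", "R8p", "R7y", "R8y"),
        Q=q, q=q, r=q / q.sum(),
    )


class TestReceptorTemplate:
    def test_peak_location(self, grid):
        s = receptor_template(520.0, grid)
        assert abs(grid[np.argmax(s)] - 520.0) <= 1.0

    def test_peak_normalized(self, grid):
        s = receptor_template(450.0, grid)
        assert s.max() == pytest.approx(1.0)

    def test_uv_template_far_tail_small(self, grid):
        s = receptor_template(357.0, grid)
        assert s[grid == 520.0][0] < 0.05

    def test_outside_grid_error(self, grid):
        with pytest.raises(VisionError):
            receptor_template(250.0, grid)


class TestQuantumCatch:
    def test_background_maps_to_unit_catches(self, grid):
        recs = load_receptor_set("hawkmoth", grid=grid)
        illum = load_illuminant("D65")
        leaf = spec_of(grid, 30.0, tissue="leaf")
        locus = quantum_catch(leaf, recs, illum, leaf)
        assert np.allclose(locus.q, 1.0)
        assert np.allclose(locus.r, 1.0 / 3.0)

    def test_von_kries_illuminant_scale_invariance(self, grid):
        recs = load_receptor_set("hawkmoth", grid=grid)
        illum = load_illuminant("D65")
        doubled = Illuminant(illum.wavelengths, illum.irradiance * 2.0, "2xD65")
        stim = spec_of(grid, np.linspace(10, 80, grid.size))
        bkg = spec_of(grid, 30.0, tissue="leaf")
        a = quantum_catch(stim, recs, illum, bkg)
        b = quantum_catch(stim, recs, doubled, bkg)
        assert np.allclose(a.q, b.q)

    def test_toy_grid_matches_hand_integration(self):
        # 3-point grid: trapezoid rule by hand for one receptor
        g = np.array([400.0, 500.0, 600.0])
        sens = np.array([[0.2, 1.0, 0.1]])
        from pollicolor.vision import ReceptorSet

        recs = ReceptorSet(
            viewer="toy", names=("X",), lambda_max=(500.0,),
            sensitivities=sens, densities=(1.0,), grid=g,
        )
        illum = Illuminant(g, np.array([1.0, 2.0, 3.0]))
        refl = np.array([50.0, 25.0, 10.0])
        stim = spec_of(g, refl)
        bkg = spec_of(g, np.array([10.0, 10.0, 10.0]), tissue="leaf")
        locus = quantum_catch(stim, recs, illum, bkg)
        integrand = (refl / 100.0) * sens[0] * np.array([1.0, 2.0, 3.0])
        expected = 0.5 * (integrand[0] + integrand[1]) * 100 + 0.5 * (
            integrand[1] + integrand[2]
        ) * 100
        assert locus.Q[0] == pytest.approx(expected, abs=1e-9)

    def test_zero_background_catch_error(self, grid):
        recs = load_receptor_set("hawkmoth", grid=grid)
        illum = load_illuminant("D65")
        stim = spec_of(grid, 50.0)
        bkg = spec_of(grid, 0.0, tissue="leaf")
        with pytest.raises(VisionError, match="background quantum catch"):
            quantum_catch(stim, recs, illum, bkg)

    def test_refinement_grid_halving(self):
        # halving the step changes Q by < 0.1% for smooth spectra
        coarse = np.arange(300.0, 701.0, 2.0)
        fine = np.arange(300.0, 701.0, 1.0)
        illum = load_illuminant("D65")
        qs = []
        for g in (coarse, fine):
            recs = load_receptor_set("hawkmoth", grid=g)
            stim = spec_of(g, 20.0 + 50.0 / (1.0 + np.exp(-(g - 450) / 30.0)))
            bkg = spec_of(g, 30.0, tissue="leaf")
            qs.append(quantum_catch(stim, recs, illum, bkg).Q)
        assert np.all(np.abs(qs[0] - qs[1]) / qs[1] < 1e-3)


class TestMaxwell:
    def test_achromatic_center(self):
        xy = maxwell_locus(tri_locus([1.0, 1.0, 1.0]))
        assert np.allclose(xy, 0.0)

    def test_vertex_distance(self):
        xy = maxwell_locus(tri_locus([1.0, 1e-12, 1e-12]))
        assert np.linalg.norm(xy) == pytest.approx(np.sqrt(2.0 / 3.0), abs=1e-6)

    def test_uv_green_swap_reflects_x(self):
        a = maxwell_locus(tri_locus([0.5, 0.2, 0.3]))
        b = maxwell_locus(tri_locus([0.3, 0.2, 0.5]))
        assert a[0] == pytest.approx(-b[0])
        assert a[1] == pytest.approx(b[1])

    def test_physical_spectra_stay_inside_triangle(self, grid):
        recs = load_receptor_set("hawkmoth", grid=grid)
        illum = load_illuminant("sunset")
        bkg = spec_of(grid, 30.0, tissue="leaf")
        rng = np.random.default_rng(5)
        vmax = np.sqrt(2.0 / 3.0) + 1e-9
        for _ in range(10):
            stim = spec_of(grid, rng.uniform(1.0, 100.0, grid.size))
            xy = maxwell_locus(quantum_catch(stim, recs, illum, bkg))
            assert np.linalg.norm(xy) <= vmax

    def test_tetrachromat_error(self):
        with pytest.raises(VisionError):
            maxwell_locus(tetra_locus([1, 1, 1, 1]))


class TestFlyCategorical:
    def test_adaptation_point_is_boundary(self):
        cat, uv = fly_locus(tetra_locus([1.0, 1.0, 1.0, 1.0]))
        assert cat == "boundary"
        assert np.allclose(uv, 0.0)

    def test_fly_uv_quadrant(self):
        cat, uv = fly_locus(tetra_locus([2.0, 1.0, 2.0, 1.0]))
        assert uv[0] > 0 and uv[1] > 0
        assert cat == "fly-UV"

    def test_fly_blue_quadrant(self):
        cat, uv = fly_locus(tetra_locus([1.0, 2.0, 2.0, 1.0]))
        assert uv[0] < 0 and uv[1] > 0
        assert cat == "fly-blue"

    def test_fly_yellow_and_purple(self):
        assert fly_locus(tetra_locus([1.0, 2.0, 1.0, 2.0]))[0] == "fly-yellow"
        assert fly_locus(tetra_locus([2.0, 1.0, 1.0, 2.0]))[0] == "fly-purple"

    def test_category_scale_invariant(self):
        q = np.array([1.7, 0.8, 1.1, 0.4])
        base_cat, base_uv = fly_locus(tetra_locus(q))
        for c in (0.1, 3.0, 42.0):
            cat, uv = fly_locus(tetra_locus(c * q))
            assert cat == base_cat
            assert uv == pytest.approx(base_uv)

    def test_trichromat_error(self):
        with pytest.raises(VisionError):
            fly_locus(tri_locus([1, 1, 1]))


class TestFlyDistance:
    def test_identity(self):
        a = tetra_locus([2.0, 1.0, 1.5, 0.5])
        assert fly_distance(a, a) == 0.0

    def test_3_4_5(self):
        # construct loci with (u,v)=(0,0) and (0.3,0.4)
        a = tetra_locus([1.0, 1.0, 1.0, 1.0])
        b = tetra_locus([1.3, 0.7, 1.4, 0.6])
        assert fly_distance(a, b) == pytest.approx(0.5)

    def test_symmetry(self):
        rng = np.random.default_rng(11)
        for _ in range(5):
            a = tetra_locus(rng.uniform(0.2, 3.0, 4))
            b = tetra_locus(rng.uniform(0.2, 3.0, 4))
            assert fly_distance(a, b) == pytest.approx(fly_distance(b, a))

    def test_mixed_viewer_error(self):
        a = tetra_locus([1, 1, 1, 1], viewer="blowfly")
        b = tetra_locus([1, 1, 1, 1], viewer="hoverfly")
        with pytest.raises(VisionError, match="mixed viewers"):
            fly_distance(a, b)


class TestNoiseAndRnl:
    def test_noise_values_from_printed_densities(self):
        noise = NoiseModel(weber=0.1, densities=(0.1, 0.23, 0.67))
        e = noise.e
        assert e[2] == pytest.approx(0.1)
        assert e[1] == pytest.approx(0.1 * np.sqrt(0.67 / 0.23), abs=1e-4)
        assert e[0] == pytest.approx(0.1 * np.sqrt(0.67 / 0.1), abs=1e-4)
        assert e[1] == pytest.approx(0.1707, abs=1e-4)
        assert e[0] == pytest.approx(0.2588, abs=1e-4)

    def test_identical_stimuli_zero(self):
        noise = NoiseModel()
        a = tri_locus([1.2, 0.8, 1.5])
        assert rnl_chromatic_distance(a, a, noise) == 0.0

    def test_achromatic_scaling_zero(self):
        noise = NoiseModel()
        a = tri_locus([1.2, 0.8, 1.5])
        b = tri_locus(np.array([1.2, 0.8, 1.5]) * 3.7)
        # ColorLocus q stored unnormalized; scaling all catches equally
        assert rnl_chromatic_distance(a, b, noise) == pytest.approx(0.0, abs=1e-12)

    def test_symmetry_and_nonnegativity(self):
        noise = NoiseModel()
        rng = np.random.default_rng(2)
        for _ in range(5):
            a = tri_locus(rng.uniform(0.3, 2.0, 3))
            b = tri_locus(rng.uniform(0.3, 2.0, 3))
            d1 = rnl_chromatic_distance(a, b, noise)
            d2 = rnl_chromatic_distance(b, a, noise)
            assert d1 >= 0
            assert d1 == pytest.approx(d2)

    def test_receptor_permutation_invariance(self):
        # permuting receptors together with their noises leaves the distance fixed
        qa, qb = np.array([1.2, 0.7, 1.9]), np.array([0.5, 1.4, 1.1])
        e = np.array([0.25, 0.17, 0.1])
        from pollicolor.vision import rnl_contrast_from_df

        df = np.log(qa / qb)
        base = rnl_contrast_from_df(df, e)
        perm = [2, 0, 1]
        assert rnl_contrast_from_df(df[perm], e[perm]) == pytest.approx(base)

    def test_nonpositive_catch_error(self):
        noise = NoiseModel()
        a = tri_locus([1.0, 1.0, 1.0])
        bad = ColorLocus(
            viewer="hawkmoth", receptor_names=("UV", "B", "G"),
            Q=np.array([0.0, 1.0, 1.0]), q=np.array([0.0, 1.0, 1.0]),
            r=np.array([0.0, 0.5, 0.5]),
        )
        with pytest.raises(VisionError):
            rnl_chromatic_distance(a, bad, noise)


class TestAchromatic:
    def test_background_zero_both_forms(self):
        noise = NoiseModel()
        a = tri_locus([1.0, 1.0, 1.0])
        for form in ("michelson", "log_jnd"):
            assert achromatic_contrast(a, a, noise, form=form)["value"] == 0.0

    def test_michelson_oracle(self):
        noise = NoiseModel()
        a = tri_locus([1.0, 1.0, 3.0])
        bkg = tri_locus([1.0, 1.0, 1.0])
        out = achromatic_contrast(a, bkg, noise, form="michelson")
        assert out["value"] == pytest.approx(0.5)
        assert out["form"] == "michelson"

    def test_log_jnd_oracle(self):
        noise = NoiseModel(weber=0.1)
        a = tri_locus([1.0, 1.0, np.e])
        bkg = tri_locus([1.0, 1.0, 1.0])
        out = achromatic_contrast(a, bkg, noise, form="log_jnd")
        assert out["value"] == pytest.approx(10.0, abs=1e-9)


def test_energy_to_photon_flux_weights_long_wavelengths():
    wl = np.array([300.0, 600.0])
    flux = energy_to_photon_flux(wl, np.array([1.0, 1.0]))
    assert flux[1] == pytest.approx(1.0)
    assert flux[0] == pytest.approx(0.5)


def test_bundled_illuminants_positive(grid):
    for name in ("D65", "sunset"):
        ill = load_illuminant(name)
        assert np.all(ill.on_grid(grid) > 0)
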