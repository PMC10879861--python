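import numpy as np
import pytest

from oracles import (
    lasso_active_set_oracle,
    lasso_objective,
    lasso_projected_gradient_oracle,
    nnls_oracle,
)
from srh import (
    ChannelSubset,
    HyperspectralCube,
    MixtureModel,
    PixelSpectrum,
    ReferenceLibrary,
    UnmixParams,
    WavenumberAxis,
    derive_protein_reference,
    lasso_unmix_pixel,
    restrict_to_channels,
    unmix_cube,
)
from srh.phantom import COMPONENT_NAMES, default_band_models
from srh.unmix import lasso_cd


def random_library(rng, k, m):
    ax = WavenumberAxis(np.sort(rng.uniform(2820, 3030, size=m)))
    spectra = rng.uniform(0.05, 1.0, size=(k, m))
    return ReferenceLibrary.from_raw([f"c{i}" for i in range(k)], spectra, ax)


class TestLassoPixel:
    def test_zero_spectrum_gives_zero(self, library):
        y = PixelSpectrum(np.zeros(45), library.axis)
        for lam in (0.0, 0.01, 0.5):
            c = lasso_unmix_pixel(y, library, UnmixParams(lam=lam))
            assert np.all(c == 0)

    def test_single_component_exact_least_squares(self, axis45):
        lib = ReferenceLibrary.from_raw(["s"], np.ones((1, 45)), axis45)
        y = PixelSpectrum(2.0 * lib.spectra[0], axis45)
        c = lasso_unmix_pixel(y, lib, UnmixParams(lam=0.0))
        assert c[0] == pytest.approx(2.0, abs=1e-9)

    def test_axis_mismatch_raises(self, library):
        other = WavenumberAxis(np.linspace(2825, 3025, 45))
        y = PixelSpectrum(np.ones(45), other)
        with pytest.raises(ValueError):
            lasso_unmix_pixel(y, library)

    def test_matches_oracles_on_restricted_library(self, library):
        rng = np.random.default_rng(11)
        idx = [2, 10, 19, 28, 36, 44]
        sub = ChannelSubset.from_axis(library.axis, idx)
        lib6 = restrict_to_channels(library, sub)
        for _ in range(20):
            y = rng.uniform(0, 2, size=6)
            c = lasso_unmix_pixel(PixelSpectrum(y, lib6.axis), lib6,
                                  UnmixParams(lam=0.01))
            _, obj_star = lasso_active_set_oracle(y, lib6.spectra, 0.01)
            obj = lasso_objective(y, lib6.spectra, c, 0.01)
            assert obj == pytest.approx(obj_star, abs=1e-6)

    def test_orthonormal_soft_threshold_closed_form(self):
        # orthonormal rows: solution is the one-sided soft threshold
        ax = WavenumberAxis([2850.0, 2900.0, 2950.0, 3000.0])
        A = np.eye(3, 4)
        lib = ReferenceLibrary(("a", "b", "c"), A, ax, normalization="none")
        rng = np.random.default_rng(5)
        lam = 0.2
        for _ in range(10):
            y = rng.uniform(-1, 2, size=4)
            c = lasso_cd(y[None], A, lam, nonneg=True)[0][0]
            closed = np.maximum(A @ y - lam / 2, 0.0)
            np.testing.assert_allclose(c, closed, atol=1e-9)

    def test_nnls_limit_matches_scipy(self, library):
        rng = np.random.default_rng(7)
        for _ in range(20):
            c_true = rng.uniform(0, 2, size=5)
            y = c_true @ library.spectra + rng.normal(0, 0.05, size=45)
            c = lasso_unmix_pixel(PixelSpectrum(np.abs(y), library.axis), library,
                                  UnmixParams(lam=0.0))
            ref = nnls_oracle(np.abs(y), library.spectra)
            np.testing.assert_allclose(c, ref, atol=1e-8)

    def test_unconstrained_lasso_matches_projected_gradient(self):
        rng = np.random.default_rng(3)
        lib = random_library(rng, 4, 8)
        for _ in range(10):
            y = rng.normal(0, 1, size=8)
            c = lasso_cd(y[None], lib.spectra, 0.05, nonneg=False)[0][0]
            ref = lasso_projected_gradient_oracle(y, lib.spectra, 0.05, nonneg=False)
            obj = lasso_objective(y, lib.spectra, c, 0.05)
            obj_ref = lasso_objective(y, lib.spectra, ref, 0.05)
            assert obj <= obj_ref + 1e-8

    def test_monotone_sparsity_in_lambda(self, library):
        rng = np.random.default_rng(19)
        y = rng.uniform(0.2, 1.5, size=5) @ library.spectra
        nnz_prev = None
        for lam in (0.0, 0.003, 0.01, 0.03, 0.1, 0.3, 1.0, 3.0):
            c = lasso_unmix_pixel(PixelSpectrum(y, library.axis), library,
                                  UnmixParams(lam=lam))
            nnz = int(np.sum(c > 1e-12))
            if nnz_prev is not None:
                assert nnz <= nnz_prev
            nnz_prev = nnz


class TestOracleEquivalenceProperty:
    def test_random_triples_match_active_set_oracle(self):
        """Coordinate descent agrees with exhaustive support enumeration."""
        rng = np.random.default_rng(42)
        n_checked = 0
        for _ in range(70):
            k = int(rng.integers(1, 6))
            m = int(rng.integers(k, 11))
            lib = random_library(rng, k, m)
            y = np.abs(rng.normal(0.5, 0.5, size=m))
            for lam in (0.0, 0.01, 0.1):
                c = lasso_cd(y[None], lib.spectra, lam, nonneg=True)[0][0]
                _, obj_star = lasso_active_set_oracle(y, lib.spectra, lam)
                obj = lasso_objective(y, lib.spectra, c, lam)
                assert obj == pytest.approx(obj_star, abs=1e-6)
                n_checked += 1
        assert n_checked >= 200


class TestUnmixCube:
    def test_single_pixel_cube_equals_pixel_op(self, library):
        rng = np.random.default_rng(2)
        y = rng.uniform(0, 1, size=45)
        cube = HyperspectralCube(y.reshape(1, 1, 45), library.axis)
        maps = unmix_cube(cube, library)
        c = lasso_unmix_pixel(PixelSpectrum(y, library.axis), library)
        np.testing.assert_allclose(maps.data[0, 0], c, atol=1e-12)

    def test_names_and_meta_recorded(self, noisy_full_maps):
        assert noisy_full_maps.names == COMPONENT_NAMES
        assert noisy_full_maps.meta["lam"] == 0.01
        assert noisy_full_maps.meta["normalization"] == "unit_l2"

    def test_rmse_monotone_in_noise(self, library):
        import srh

        rmses = []
        for sd in (0.0, 0.01, 0.05):
            cube, truth = srh.generate_phantom(
                srh.default_phantom_spec(noise_sd=sd, seed=17))
            maps = unmix_cube(cube, library)
            rmses.append(float(np.sqrt(np.mean((maps.data - truth.data) ** 2))))
        assert rmses[0] <= rmses[1] <= rmses[2]


class TestDeriveProteinReference:
    def _spectrum(self, name, axis):
        return default_band_models()[name].evaluate(axis.as_array())

    def test_identical_inputs_degenerate(self, axis45):
        lipid = PixelSpectrum(self._spectrum("unsaturated_lipid", axis45), axis45)
        with pytest.raises(ValueError):
            derive_protein_reference(lipid, lipid)

    def test_disjoint_support_passthrough(self):
        ax = WavenumberAxis(np.linspace(2820, 3030, 45))
        cell = np.zeros(45)
        cell[:20] = 1.0
        lipid = np.zeros(45)
        lipid[-5:] = 1.0  # only near the 3009 marker
        out = derive_protein_reference(PixelSpectrum(cell, ax), PixelSpectrum(lipid, ax))
        np.testing.assert_allclose(out.values, cell / np.linalg.norm(cell), atol=1e-12)

    def test_recovers_protein_from_mixture(self, axis45):
        protein = self._spectrum("cellular_protein", axis45)
        lipid = self._spectrum("unsaturated_lipid", axis45)
        cell = 0.7 * protein + 0.3 * lipid
        out = derive_protein_reference(PixelSpectrum(cell, axis45),
                                       PixelSpectrum(lipid, axis45))
        p = protein / np.linalg.norm(protein)
        cosine = float(out.values @ p)
        assert cosine > 0.99


class TestModelResults:
    def test_summary_reports_fit(self, noisy_phantom, library):
        cube, _ = noisy_phantom
        res = MixtureModel(cube, library).fit()
        text = res.summary()
        assert "lambda: 0.01" in text
        for name in COMPONENT_NAMES:
            assert name in text
        assert res.rss >= 0
        assert res.maps.data.shape == (64, 64, 5)

    def test_from_phantom_constructor(self):
        model = MixtureModel.from_phantom()
        res = model.fit()
        assert res.maps.n_components == 5
        assert model.truth.data.shape == res.maps.data.shape
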