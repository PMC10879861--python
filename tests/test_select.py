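import itertools

import numpy as np
import pytest

from srh import (
    ChannelSubset,
    ReferenceLibrary,
    SamplerParams,
    UnmixParams,
    WavenumberAxis,
    acquisition_cost,
    evaluate_subset,
    rfe_select,
    sample_balanced_pixels,
    speedup_factor,
)
from srh.select import PixelSample
from srh.unmix import lasso_cd


class TestBalancedSampler:
    def test_default_quota_420_per_component(self, noisy_phantom, noisy_full_maps):
        cube, _ = noisy_phantom
        sample = sample_balanced_pixels(cube, noisy_full_maps, SamplerParams())
        assert sample.coordinates.shape == (2100, 2)
        counts = np.bincount(sample.dominant_labels, minlength=5)
        assert np.all(counts == 420)

    def test_same_seed_same_coordinates(self, noisy_phantom, noisy_full_maps):
        cube, _ = noisy_phantom
        a = sample_balanced_pixels(cube, noisy_full_maps, SamplerParams(seed=99))
        b = sample_balanced_pixels(cube, noisy_full_maps, SamplerParams(seed=99))
        assert np.array_equal(a.coordinates, b.coordinates)

    def test_missing_dominant_component_names_it(self, noisy_phantom, noisy_full_maps):
        from srh import ConcentrationMaps

        cube, _ = noisy_phantom
        data = noisy_full_maps.data.copy()
        data[:, :, -1] = 0.0  # no pixel can be water-dominant now
        maps = ConcentrationMaps(data, noisy_full_maps.names)
        with pytest.raises(ValueError, match="water"):
            sample_balanced_pixels(cube, maps, SamplerParams())

    def test_invalid_budget_rejected(self):
        with pytest.raises(ValueError):
            SamplerParams(n_total=2100, n_subsets=8)

    def test_unbalanced_sample_rejected(self):
        with pytest.raises(ValueError):
            PixelSample(np.array([[0, 0], [0, 1], [1, 0]]),
                        np.array([0, 0, 1]),
                        np.zeros((3, 4)), np.zeros((3, 2)))


def planted_library():
    """8-channel library where exactly channels 5,6,7 separate the components.

    All three spectra share the same values on channels 0–4 and have
    equal-norm, orthogonal patterns on 5–7, so after unit normalization the
    non-contrast channels remain identical across components.
    """
    ax = WavenumberAxis(np.linspace(2820, 3030, 8))
    common = np.full(5, 0.3)
    spectra = np.zeros((3, 8))
    for k in range(3):
        spectra[k, :5] = common
        spectra[k, 5 + k] = 0.8
    return ReferenceLibrary.from_raw(("a", "b", "c"), spectra, ax)


def planted_sample(lib, n_pixels=60, seed=0):
    rng = np.random.default_rng(seed)
    C_true = rng.uniform(0.2, 2.0, size=(n_pixels, 3))
    Y = C_true @ lib.spectra
    params = UnmixParams()
    full, _, _ = lasso_cd(Y, lib.spectra, params.lam, params.nonneg,
                          params.max_iters, params.tol)
    coords = np.stack([np.arange(n_pixels), np.zeros(n_pixels, dtype=int)], axis=1)
    labels = np.argmax(full, axis=1)
    # balance is irrelevant for the planted instance; use a uniform label
    return PixelSample(coords, np.zeros(n_pixels, dtype=int), Y, full)


def exhaustive_best_subset(sample, lib, k, params):
    best = None
    m = lib.spectra.shape[1]
    for keep in itertools.combinations(range(m), k):
        A = lib.spectra[:, list(keep)]
        C, _, _ = lasso_cd(sample.spectra[:, list(keep)], A, params.lam,
                           params.nonneg, params.max_iters, params.tol)
        mse = float(np.mean((C - sample.full_abundances) ** 2))
        if best is None or mse < best[0]:
            best = (mse, keep)
    return best


class TestRfeSelect:
    def test_target_equals_m_is_identity(self, library, noisy_phantom, noisy_full_maps):
        cube, _ = noisy_phantom
        sample = sample_balanced_pixels(cube, noisy_full_maps,
                                        SamplerParams(n_total=100, n_subsets=5, seed=1))
        subset = rfe_select(sample, library, UnmixParams(), target_k=45)
        assert subset.indices == tuple(range(45))
        assert subset.trace == ()

    def test_invalid_target_rejected(self, library, noisy_phantom, noisy_full_maps):
        cube, _ = noisy_phantom
        sample = sample_balanced_pixels(cube, noisy_full_maps,
                                        SamplerParams(n_total=100, n_subsets=5, seed=1))
        with pytest.raises(ValueError):
            rfe_select(sample, library, UnmixParams(), target_k=0)
        with pytest.raises(ValueError):
            rfe_select(sample, library, UnmixParams(), target_k=46)

    def test_planted_contrast_channels_recovered_and_match_exhaustive(self):
        lib = planted_library()
        sample = planted_sample(lib)
        params = UnmixParams()
        subset = rfe_select(sample, lib, params, target_k=3)
        assert subset.indices == (5, 6, 7)
        assert len(subset.trace) == 5
        _, best_keep = exhaustive_best_subset(sample, lib, 3, params)
        assert tuple(best_keep) == subset.indices

    def test_determinism(self):
        lib = planted_library()
        sample = planted_sample(lib)
        s1 = rfe_select(sample, lib, UnmixParams(), target_k=4)
        s2 = rfe_select(sample, lib, UnmixParams(), target_k=4)
        assert s1.indices == s2.indices
        assert s1.trace == s2.trace

    def test_full_rank_at_k_equals_components(self, library, noisy_phantom,
                                              noisy_full_maps):
        cube, _ = noisy_phantom
        sample = sample_balanced_pixels(cube, noisy_full_maps,
                                        SamplerParams(n_total=250, n_subsets=5, seed=3))
        subset = rfe_select(sample, library, UnmixParams(), target_k=5)
        A = library.spectra[:, list(subset.indices)]
        assert np.linalg.matrix_rank(A) == 5


class TestTraceMonotonicity:
    def test_mse_trace_nondecreasing_over_seeds(self, library):
        """Greedy removal of the least-informative channel first: the recorded
        MSE should (statistically) not decrease along the elimination path."""
        import srh

        good = 0
        n_seeds = 10
        for seed in range(n_seeds):
            cube, _ = srh.generate_phantom(
                srh.default_phantom_spec(noise_sd=0.02, seed=seed))
            full = srh.unmix_cube(cube, library)
            sample = sample_balanced_pixels(
                cube, full, SamplerParams(n_total=250, n_subsets=5, seed=seed))
            subset = rfe_select(sample, library, UnmixParams(), target_k=10)
            mses = [m for _, m in subset.trace]
            if all(b >= a - 1e-12 for a, b in zip(mses, mses[1:])):
                good += 1
        assert good >= 0.95 * n_seeds


class TestEvaluateSubset:
    def test_full_subset_gives_ssim_one(self, library, noisy_phantom, noisy_full_maps):
        cube, _ = noisy_phantom
        subset = ChannelSubset.from_axis(library.axis, range(45))
        rep = evaluate_subset(cube, library, UnmixParams(), subset, noisy_full_maps)
        assert rep.mean_ssim == pytest.approx(1.0, abs=1e-9)


class TestCostModel:
    def test_nine_fold_speedup_45_to_5(self):
        assert speedup_factor(45, 5) == pytest.approx(9.0)
        full = acquisition_cost(45, 1024 * 1024, 10.0)
        sub = acquisition_cost(5, 1024 * 1024, 10.0)
        assert full / sub == pytest.approx(9.0)

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            acquisition_cost(0, 10, 10.0)
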