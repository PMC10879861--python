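"""Sparsity-penalized spectral unmixing — the computational heart of HC-SRH.

Each pixel spectrum y (length M) is modeled as a non-negative linear mixture
of K reference spectra (the rows a_k of the library matrix A), and the
per-pixel concentrations c are estimated by the non-negative LASSO

    c* = argmin_{c ≥ 0}  ‖y − Aᵀc‖₂²  +  λ‖c‖₁ .

Convention (important — common libraries differ): the objective is exactly
the residual sum of squares plus λ‖c‖₁ — no 1/(2M) factor — with the pixel
spectrum y NOT normalized and the reference spectra unit-L2-norm at
construction.  Under this convention λ = 0.01 is the default sparsity
penalty.  Non-negativity is on by default (negative concentrations are
physically meaningless); ``nonneg=False`` gives the unconstrained LASSO.

The solver is cyclic coordinate descent started from c = 0 with a fixed
component order, which together with convexity makes the output
deterministic.  For an orthonormal library it reduces to the closed form
c_k = max(a_kᵀy − λ/2, 0).

The module exposes both a functional surface (:func:`lasso_unmix_pixel`,
:func:`unmix_cube`) and a model/results pair (:class:`MixtureModel`,
:class:`UnmixResults`) carrying estimates, diagnostics and a summary table.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import (
    ChannelSubset,
    ConcentrationMaps,
    HyperspectralCube,
    ReferenceLibrary,
    WavenumberAxis,
)

__all__ = [
    "UnmixParams",
    "PixelSpectrum",
    "lasso_unmix_pixel",
    "unmix_cube",
    "derive_protein_reference",
    "MixtureModel",
    "UnmixResults",
]


@dataclass
class UnmixParams:
    """Solver settings for the non-negative LASSO.

    lam : sparsity penalty λ ≥ 0 (default 0.01 under the declared
        normalization convention).
    nonneg : enforce c ≥ 0 (default True).
    max_iters : coordinate-descent sweep budget.
    tol : stop when the largest coefficient change in a sweep, relative to
        max(1, ‖c‖∞), falls below this.
    """

    lam: float = 0.01
    nonneg: bool = True
    max_iters: int = 2000
    tol: float = 1e-10

    def __post_init__(self):
        if self.lam < 0:
            raise ValueError("lam must be non-negative")
        if self.max_iters < 1:
            raise ValueError("max_iters must be positive")
        if self.tol <= 0:
            raise ValueError("tol must be positive")


@dataclass
class PixelSpectrum:
    """A single length-M intensity vector on a wavenumber axis."""

    values: np.ndarray
    axis: WavenumberAxis

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or self.values.size != len(self.axis):
            raise ValueError("spectrum length must match axis")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite spectrum value")


def _soft_threshold(z: np.ndarray, t: float) -> np.ndarray:
    return np.sign(z) * np.maximum(np.abs(z) - t, 0.0)


def lasso_cd(Y: np.ndarray, A: np.ndarray, lam: float, nonneg: bool = True,
             max_iters: int = 2000, tol: float = 1e-10,
             C0: np.ndarray | None = None) -> tuple[np.ndarray, int, bool]:
    """Cyclic coordinate descent on a batch of pixels.

    Y : (N, M) pixel spectra;  A : (K, M) reference spectra (rows).
    Returns ``(C, n_iters, converged)`` with C of shape (N, K).

    Uses the Gram matrix G = AAᵀ so each sweep costs O(N·K²); the coordinate
    update for component k is the (optionally one-sided) soft threshold
    ``c_k ← S(z_k, λ/2) / G_kk`` with ``z_k = a_kᵀy − Σ_{j≠k} c_j G_jk``.
    """
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    A = np.asarray(A, dtype=float)
    n, m = Y.shape
    k = A.shape[0]
    if A.shape[1] != m:
        raise ValueError(f"library has {A.shape[1]} channels, spectra have {m}")
    G = A @ A.T
    diag = np.diag(G).copy()
    if np.any(diag <= 0):
        raise ValueError("library contains an all-zero spectrum on these channels")
    B = Y @ A.T  # (N, K): a_k·y per pixel
    C = np.zeros((n, k)) if C0 is None else np.array(C0, dtype=float, copy=True)
    half_lam = 0.5 * lam
    converged = False
    it = 0
    for it in range(1, max_iters + 1):
        delta = 0.0
        for j in range(k):
            z = B[:, j] - C @ G[:, j] + C[:, j] * diag[j]
            if nonneg:
                new = np.maximum((z - half_lam) / diag[j], 0.0)
            else:
                new = _soft_threshold(z, half_lam) / diag[j]
            step = np.max(np.abs(new - C[:, j])) if n else 0.0
            if step > delta:
                delta = step
            C[:, j] = new
        scale = max(1.0, float(np.max(np.abs(C)))) if C.size else 1.0
        if delta / scale < tol:
            converged = True
            break
    return C, it, converged


def lasso_objective(Y: np.ndarray, A: np.ndarray, C: np.ndarray, lam: float) -> np.ndarray:
    """Per-pixel objective ‖y − Aᵀc‖² + λ‖c‖₁."""
    Y = np.atleast_2d(Y)
    C = np.atleast_2d(C)
    resid = Y - C @ A
    return np.sum(resid**2, axis=1) + lam * np.sum(np.abs(C), axis=1)


def lasso_unmix_pixel(y: PixelSpectrum, library: ReferenceLibrary,
                      params: UnmixParams | None = None) -> np.ndarray:
    """Abundance vector for one pixel; see module docstring for the objective."""
    params = params or UnmixParams()
    if y.axis != library.axis:
        raise ValueError("pixel spectrum and library are on different axes")
    C, _, _ = lasso_cd(y.values[None, :], library.spectra, params.lam,
                       params.nonneg, params.max_iters, params.tol)
    return C[0]


def unmix_cube(cube: HyperspectralCube, library: ReferenceLibrary,
               params: UnmixParams | None = None,
               subset: ChannelSubset | None = None) -> ConcentrationMaps:
    """Unmix every pixel of a cube independently.

    ``subset`` is recorded in the output metadata when the cube/library were
    channel-restricted; it does not re-slice anything here.
    """
    params = params or UnmixParams()
    if cube.axis != library.axis:
        raise ValueError("cube and library are on different axes")
    h, w, _ = cube.shape
    C, iters, converged = lasso_cd(cube.pixels(), library.spectra, params.lam,
                                   params.nonneg, params.max_iters, params.tol)
    if params.nonneg:
        C = np.maximum(C, 0.0)
    meta = {
        "lam": params.lam,
        "nonneg": params.nonneg,
        "normalization": library.normalization,
        "channel_subset_cm1": list(subset.shifts) if subset else None,
        "n_iters": iters,
        "converged": converged,
    }
    data = C.reshape(h, w, library.n_components)
    if not params.nonneg:
        # the container enforces c >= 0; unconstrained fits clip for storage
        meta["clipped_negative_fraction"] = float(np.mean(C < 0))
        data = np.maximum(data, 0.0)
    return ConcentrationMaps(data, library.names, subset, meta)


def derive_protein_reference(cell_spectrum: PixelSpectrum,
                             lipid_spectrum: PixelSpectrum,
                             marker_cm1: float = 3009.0,
                             window_cm1: float = 10.0) -> PixelSpectrum:
    """Cellular-protein reference by lipid subtraction.

    A measured cancer-cell spectrum is a protein/lipid mixture; the protein
    reference is obtained by removing an α-scaled unsaturated-lipid spectrum.
    α ≥ 0 is fit by least squares restricted to the channels within
    ``±window_cm1`` of the lipid-specific =C-H marker band (≈3009 cm⁻¹),
    where protein contributes least, then the clipped residual
    ``max(cell − α·lipid, 0)`` is renormalized to unit L2 norm.
    """
    if cell_spectrum.axis != lipid_spectrum.axis:
        raise ValueError("spectra are on different axes")
    cell = cell_spectrum.values
    lipid = lipid_spectrum.values
    if np.any(cell < 0) or np.any(lipid < 0):
        raise ValueError("input spectra must be non-negative")
    shifts = cell_spectrum.axis.as_array()
    sel = np.abs(shifts - marker_cm1) <= window_cm1
    if not np.any(sel) or not np.any(lipid[sel] > 0):
        raise ValueError("no usable lipid-marker channels in the window")
    alpha = max(float(cell[sel] @ lipid[sel]) / float(lipid[sel] @ lipid[sel]), 0.0)
    resid = np.maximum(cell - alpha * lipid, 0.0)
    norm = float(np.linalg.norm(resid))
    if norm < 1e-12 * max(1.0, float(np.linalg.norm(cell))):
        raise ValueError("degenerate input: subtraction leaves an all-zero spectrum")
    return PixelSpectrum(resid / norm, cell_spectrum.axis)


# ---------------------------------------------------------------------------
# Model / Results surface


class MixtureModel:
    """Linear mixing model of a hyperspectral cube against a reference library.

    Parameters
    ----------
    cube : HyperspectralCube
        The observation; each pixel spectrum is one sample.
    library : ReferenceLibrary
        Endmember matrix A (rows unit-norm at construction).
    params : UnmixParams, optional
        Penalty and solver settings (λ = 0.01 by default).
    subset : ChannelSubset, optional
        Recorded when the inputs are channel-restricted.

    ``fit()`` estimates the per-pixel concentrations by non-negative LASSO
    and returns an :class:`UnmixResults`.
    """

    def __init__(self, cube: HyperspectralCube, library: ReferenceLibrary,
                 params: UnmixParams | None = None,
                 subset: ChannelSubset | None = None):
        if cube.axis != library.axis:
            raise ValueError("cube and library are on different axes")
        self.cube = cube
        self.library = library
        self.params = params or UnmixParams()
        self.subset = subset

    @classmethod
    def from_phantom(cls, spec=None, params: UnmixParams | None = None):
        """Convenience constructor: fit the default synthetic scene."""
        from .phantom import default_phantom_spec, generate_phantom, make_default_library

        spec = spec or default_phantom_spec()
        cube, truth = generate_phantom(spec)
        library = make_default_library(cube.axis)
        model = cls(cube, library, params)
        model.truth = truth
        return model

    def fit(self) -> "UnmixResults":
        maps = unmix_cube(self.cube, self.library, self.params, self.subset)
        return UnmixResults(self, maps)


class UnmixResults:
    """Fitted concentration maps plus diagnostics.

    Attributes
    ----------
    maps : ConcentrationMaps
        H×W×K abundance volume in library component order.
    """

    def __init__(self, model: MixtureModel, maps: ConcentrationMaps):
        self.model = model
        self.maps = maps
        C = maps.data.reshape(-1, maps.n_components)
        Y = model.cube.pixels()
        resid = Y - C @ model.library.spectra
        self._rss = float(np.sum(resid**2))
        self._n_pixels = Y.shape[0]

    @property
    def rss(self) -> float:
        """Total residual sum of squares over all pixels."""
        return self._rss

    @property
    def mean_rss_per_pixel(self) -> float:
        return self._rss / self._n_pixels

    @property
    def sparsity(self) -> np.ndarray:
        """Fraction of pixels with zero abundance, per component."""
        C = self.maps.data.reshape(-1, self.maps.n_components)
        return np.mean(C == 0.0, axis=0)

    def mean_abundance(self) -> np.ndarray:
        return self.maps.data.reshape(-1, self.maps.n_components).mean(axis=0)

    def render(self, scheme=None, **kwargs) -> np.ndarray:
        from .render import DEFAULT_SCHEME, render_merged

        return render_merged(self.maps, scheme or DEFAULT_SCHEME, **kwargs)

    def save(self, out_dir) -> None:
        from .io import write_maps

        write_maps(self.maps, out_dir)

    def summary(self) -> str:
        """Plain-text fit report (components, mean abundance, sparsity, fit)."""
        m = self.maps
        lines = [
            "Non-negative LASSO spectral unmixing",
            "=" * 52,
            f"pixels: {self._n_pixels}   channels: {self.model.cube.n_channels}"
            f"   components: {m.n_components}",
            f"lambda: {self.model.params.lam:g}   nonneg: {self.model.params.nonneg}"
            f"   converged: {m.meta.get('converged')}"
            f" ({m.meta.get('n_iters')} sweeps)",
            f"mean RSS / pixel: {self.mean_rss_per_pixel:.4e}",
            "-" * 52,
            f"{'component':<20}{'mean abund.':>14}{'zero frac.':>14}",
        ]
        means = self.mean_abundance()
        zeros = self.sparsity
        for i, name in enumerate(m.names):
            lines.append(f"{name:<20}{means[i]:>14.4f}{zeros[i]:>14.3f}")
        sub = m.meta.get("channel_subset_cm1")
        if sub:
            lines.append("-" * 52)
            lines.append("channels (cm⁻¹): " + ", ".join(f"{s:.0f}" for s in sub))
        return "\n".join(lines)
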