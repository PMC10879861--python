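"""Synthetic tissue-phantom generator with known ground truth.

Real HC-SRH operates on hyperspectral SRS cubes of unstained tissue in the
C-H stretch window (≈2820–3030 cm⁻¹), where the spectra of saturated lipid,
unsaturated lipid, cellular protein, extracellular matrix (ECM) and water
overlap heavily.  This module emulates that setting: component spectra are
sums of Gaussian bands placed near the canonical C-H features (≈2850 CH₂
symmetric, ≈2880 CH₂ asymmetric, ≈2930 CH₃, ≈3009 =C-H, and the broad O-H
shoulder above 3050 cm⁻¹), and scenes are built from spatial primitives
(ducts, ECM fibers and annuli, adipocyte rings, necrotic cores) over a water
background.  The cube is the exact linear mixture of the truth maps with the
library spectra plus additive white Gaussian noise, clipped at zero — so the
generator returns both the observation and the noise-free ground truth that
every downstream stage can be scored against.

Truth maps may sum to more than one per pixel: water coexists with every
other component, so no simplex constraint is imposed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .core import ConcentrationMaps, HyperspectralCube, ReferenceLibrary, WavenumberAxis

__all__ = [
    "BandModel",
    "Disk",
    "Annulus",
    "Fiber",
    "Background",
    "PhantomSpec",
    "default_axis",
    "default_band_models",
    "make_default_library",
    "default_scene",
    "default_phantom_spec",
    "generate_phantom",
    "split_into_tiles",
]

COMPONENT_NAMES = (
    "unsaturated_lipid",
    "cellular_protein",
    "ecm",
    "saturated_lipid",
    "water",
)


@dataclass(frozen=True)
class BandModel:
    """One component spectrum as a sum of Gaussian bands.

    Each band is a ``(center_cm1, width_cm1, amplitude)`` triple; ``width``
    is the Gaussian sigma.
    """

    bands: tuple[tuple[float, float, float], ...]

    def __post_init__(self):
        if len(self.bands) < 1:
            raise ValueError("band model needs at least one band")
        for c, w, a in self.bands:
            if w <= 0:
                raise ValueError("band width must be positive")
            if a < 0:
                raise ValueError("band amplitude must be non-negative")

    def evaluate(self, shifts: np.ndarray) -> np.ndarray:
        shifts = np.asarray(shifts, dtype=float)
        out = np.zeros_like(shifts)
        for center, width, amp in self.bands:
            out += amp * np.exp(-0.5 * ((shifts - center) / width) ** 2)
        return out


# ---------------------------------------------------------------------------
# Scene primitives


@dataclass(frozen=True)
class Disk:
    component: str
    level: float
    center: tuple[float, float]  # (row, col)
    radius: float

    def mask(self, h: int, w: int) -> np.ndarray:
        rr, cc = np.mgrid[0:h, 0:w]
        return (rr - self.center[0]) ** 2 + (cc - self.center[1]) ** 2 <= self.radius**2


@dataclass(frozen=True)
class Annulus:
    component: str
    level: float
    center: tuple[float, float]
    r_inner: float
    r_outer: float

    def mask(self, h: int, w: int) -> np.ndarray:
        rr, cc = np.mgrid[0:h, 0:w]
        d2 = (rr - self.center[0]) ** 2 + (cc - self.center[1]) ** 2
        return (d2 >= self.r_inner**2) & (d2 <= self.r_outer**2)


@dataclass(frozen=True)
class Fiber:
    """Polyline of given half-thickness, e.g. an ECM/collagen fiber."""

    component: str
    level: float
    points: tuple[tuple[float, float], ...]
    thickness: float

    def mask(self, h: int, w: int) -> np.ndarray:
        rr, cc = np.mgrid[0:h, 0:w]
        out = np.zeros((h, w), dtype=bool)
        pts = np.asarray(self.points, dtype=float)
        for p, q in zip(pts[:-1], pts[1:]):
            v = q - p
            vv = float(v @ v)
            if vv == 0:
                d2 = (rr - p[0]) ** 2 + (cc - p[1]) ** 2
            else:
                t = np.clip(((rr - p[0]) * v[0] + (cc - p[1]) * v[1]) / vv, 0.0, 1.0)
                d2 = (rr - (p[0] + t * v[0])) ** 2 + (cc - (p[1] + t * v[1])) ** 2
            out |= d2 <= self.thickness**2
        return out


@dataclass(frozen=True)
class Background:
    """Whole-field level, used for the ubiquitous water signal."""

    component: str
    level: float

    def mask(self, h: int, w: int) -> np.ndarray:
        return np.ones((h, w), dtype=bool)


ScenePrimitive = Disk | Annulus | Fiber | Background


@dataclass
class PhantomSpec:
    """Full description of a synthetic scene.

    ``noise_sd`` is the additive Gaussian sigma relative to the peak clean
    signal of the cube.  Same spec + same seed ⇒ bit-identical output.
    """

    height: int = 64
    width: int = 64
    axis: WavenumberAxis = field(default_factory=lambda: default_axis())
    components: dict[str, BandModel] = field(default_factory=lambda: default_band_models())
    scene: tuple[ScenePrimitive, ...] = field(default_factory=lambda: default_scene())
    noise_sd: float = 0.02
    seed: int = 17

    def __post_init__(self):
        if self.height < 1 or self.width < 1:
            raise ValueError("phantom must have positive extent")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        for prim in self.scene:
            if prim.component not in self.components:
                raise ValueError(f"scene references undeclared component {prim.component!r}")


def default_axis(n_channels: int = 45, lo: float = 2820.0, hi: float = 3030.0) -> WavenumberAxis:
    """The 45-channel C-H window grid, 2820–3030 cm⁻¹."""
    return WavenumberAxis(np.linspace(lo, hi, n_channels))


def default_band_models() -> dict[str, BandModel]:
    """Band models for the five components of the C-H window.

    Protein and ECM share band structure with the ECM spectrum uniformly
    blue-shifted by 8 cm⁻¹, emulating the hydrogen-bond/fibril shift that is
    the main spectral difference between the two in tissue.  Water appears
    only as the low-energy tail of the broad O-H band centered above the
    window.
    """
    shift = 8.0  # ECM blue shift vs cellular protein, cm⁻¹
    protein_bands = ((2930.0, 22.0, 1.0), (2880.0, 20.0, 0.35), (2960.0, 16.0, 0.45))
    return {
        "unsaturated_lipid": BandModel(
            ((2850.0, 14.0, 1.0), (2885.0, 16.0, 0.55), (2930.0, 18.0, 0.30),
             (3009.0, 12.0, 0.45))
        ),
        "cellular_protein": BandModel(protein_bands),
        "ecm": BandModel(tuple((c + shift, w, a) for c, w, a in protein_bands)),
        "saturated_lipid": BandModel(
            ((2850.0, 12.0, 1.0), (2880.0, 14.0, 0.80), (2905.0, 14.0, 0.30),
             (2935.0, 16.0, 0.25))
        ),
        "water": BandModel(((3090.0, 70.0, 1.0),)),
    }


def make_default_library(axis: WavenumberAxis) -> ReferenceLibrary:
    """Evaluate the default band models on ``axis`` as a unit-norm library.

    The axis must lie inside the supported C-H range (2800–3100 cm⁻¹); the
    shipped band models are meaningless outside it.
    """
    arr = axis.as_array()
    if arr.min() < 2800.0 or arr.max() > 3100.0:
        raise ValueError("default library supports only the 2800–3100 cm⁻¹ C-H window")
    models = default_band_models()
    spectra = np.stack([models[name].evaluate(arr) for name in COMPONENT_NAMES])
    return ReferenceLibrary.from_raw(COMPONENT_NAMES, spectra, axis)


def default_scene() -> tuple[ScenePrimitive, ...]:
    """A 64×64 breast-tissue-like scene.

    Duct of tumor cells with a denser necrotic core, ringed by ECM; two ECM
    fibers; an adipocyte with an unsaturated-lipid membrane ring around a
    saturated-lipid core; a cytoplasm patch and a second saturated-fat
    deposit; water everywhere.  Every component dominates (argmax abundance)
    a region large enough for the balanced channel-selection sampler.
    """
    return (
        Background("water", 1.0),
        # duct with necrotic core, ringed by stretched ECM
        Disk("cellular_protein", 2.0, (21.0, 21.0), 13.0),
        Disk("cellular_protein", 3.0, (21.0, 21.0), 5.0),
        Annulus("ecm", 2.0, (21.0, 21.0), 13.5, 19.0),
        # stromal collagen fibers
        Fiber("ecm", 1.8, ((44.0, 2.0), (52.0, 26.0), (60.0, 50.0)), 2.0),
        Fiber("ecm", 1.8, ((2.0, 46.0), (18.0, 56.0), (34.0, 63.0)), 1.6),
        # adipocyte: unsaturated-lipid membrane ring, saturated-lipid core
        Annulus("unsaturated_lipid", 2.5, (46.0, 14.0), 5.0, 9.5),
        Disk("saturated_lipid", 2.5, (46.0, 14.0), 4.5),
        # cytoplasm-rich patch and a solid-fat deposit
        Disk("unsaturated_lipid", 2.0, (44.0, 46.0), 9.0),
        Disk("saturated_lipid", 2.2, (14.0, 50.0), 11.5),
    )


def default_phantom_spec(noise_sd: float = 0.02, seed: int = 17,
                         height: int = 64, width: int = 64) -> PhantomSpec:
    return PhantomSpec(height=height, width=width, noise_sd=noise_sd, seed=seed)


def generate_phantom(spec: PhantomSpec) -> tuple[HyperspectralCube, ConcentrationMaps]:
    """Render a phantom cube and its noise-free ground-truth maps.

    The cube is ``Σ_k truth_k ⊗ spectrum_k + noise`` clipped at zero, with
    spectra taken from the unit-norm default library of ``spec.components``.
    Overlapping primitives of the same component combine by maximum.
    """
    h, w = spec.height, spec.width
    names = tuple(spec.components.keys())
    arr = spec.axis.as_array()
    spectra = np.stack([spec.components[n].evaluate(arr) for n in names])
    library = ReferenceLibrary.from_raw(names, spectra, spec.axis)

    truth = np.zeros((h, w, len(names)), dtype=float)
    for prim in spec.scene:
        k = names.index(prim.component)
        mask = prim.mask(h, w)
        truth[:, :, k] = np.where(mask, np.maximum(truth[:, :, k], prim.level),
                                  truth[:, :, k])

    clean = np.einsum("hwk,km->hwm", truth, library.spectra)
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        noise = rng.normal(0.0, spec.noise_sd * clean.max(), size=clean.shape)
        data = np.clip(clean + noise, 0.0, None)
    else:
        data = clean
    prov = {
        "source": "phantom",
        "seed": spec.seed,
        "noise_sd": spec.noise_sd,
        "components": list(names),
    }
    cube = HyperspectralCube(data, spec.axis, provenance=prov)
    maps = ConcentrationMaps(truth, names, None, {"source": "phantom_truth"})
    return cube, maps


def split_into_tiles(cube: HyperspectralCube, rows: int, cols: int, overlap: int,
                     jitter: np.ndarray | None = None):
    """Cut a cube into an overlapping tile grid (testing/simulation aid).

    Nominal tile origins are spaced ``tile − overlap`` apart; ``jitter`` is an
    optional ``rows×cols×2`` integer array of per-tile origin offsets (the
    anchor tile (0,0) is never jittered).  Returns ``(tiles, origins)`` where
    ``tiles[r][c]`` is a cube and ``origins`` the actual (row, col) origins.
    """
    h, w, _ = cube.shape
    if (h + (rows - 1) * overlap) % rows or (w + (cols - 1) * overlap) % cols:
        raise ValueError("cube extent incompatible with requested grid/overlap")
    th = (h + (rows - 1) * overlap) // rows
    tw = (w + (cols - 1) * overlap) // cols
    origins = np.zeros((rows, cols, 2), dtype=int)
    tiles: list[list[HyperspectralCube]] = []
    for r in range(rows):
        row_tiles = []
        for c in range(cols):
            oy, ox = r * (th - overlap), c * (tw - overlap)
            if jitter is not None and (r, c) != (0, 0):
                oy += int(jitter[r, c, 0])
                ox += int(jitter[r, c, 1])
            oy = int(np.clip(oy, 0, h - th))
            ox = int(np.clip(ox, 0, w - tw))
            origins[r, c] = (oy, ox)
            row_tiles.append(
                HyperspectralCube(cube.data[oy:oy + th, ox:ox + tw].copy(),
                                  cube.axis, cube.pixel_size_um)
            )
        tiles.append(row_tiles)
    return tiles, origins
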