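"""Domain types shared by every stage of the HC-SRH pipeline.

The pipeline operates on three in-memory containers: a hyperspectral cube
(two spatial axes plus a Raman-shift axis), a reference-spectra library (the
endmember matrix of the linear mixing model), and the concentration maps the
unmixing stage produces.  A :class:`ChannelSubset` records which spectral
channels survive selective sampling, together with the elimination trace.

Conventions
-----------
* Cube memory layout is ``(row, column, channel)``, image origin top-left,
  matching the page order of multi-page TIFF stacks.
* Channel indices are 0-based internally; user-facing output prints cm⁻¹
  values, never indices.
* Reference spectra are scaled to unit Euclidean norm at construction and the
  applied normalization is recorded on the library.  After channel
  restriction the sliced spectra are *not* renormalized, so reduced-channel
  abundances stay on the same concentration scale as full-spectrum ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "WavenumberAxis",
    "HyperspectralCube",
    "ReferenceLibrary",
    "ConcentrationMaps",
    "ChannelSubset",
    "validate_cube",
    "restrict_to_channels",
]


@dataclass(frozen=True)
class WavenumberAxis:
    """Ordered grid of Raman shifts (cm⁻¹) shared by cubes and spectra."""

    shifts: tuple[float, ...]

    def __init__(self, shifts: Sequence[float]):
        arr = np.asarray(shifts, dtype=float)
        if arr.ndim != 1 or arr.size < 1:
            raise ValueError("axis must be a 1-D sequence with at least one shift")
        if not np.all(np.isfinite(arr)) or np.any(arr <= 0):
            raise ValueError("Raman shifts must be finite and positive")
        if arr.size > 1 and np.any(np.diff(arr) <= 0):
            raise ValueError("Raman shifts must be strictly increasing")
        object.__setattr__(self, "shifts", tuple(arr.tolist()))

    def __len__(self) -> int:
        return len(self.shifts)

    def as_array(self) -> np.ndarray:
        return np.asarray(self.shifts, dtype=float)

    def __eq__(self, other) -> bool:
        return isinstance(other, WavenumberAxis) and self.shifts == other.shifts


@dataclass
class HyperspectralCube:
    """H×W×M non-negative SRS intensity volume on a wavenumber axis.

    ``pixel_size_um`` defaults to 0.5 µm (500 nm), the acquisition pixel
    pitch; dwell time and other acquisition metadata live in ``provenance``.
    """

    data: np.ndarray
    axis: WavenumberAxis
    pixel_size_um: float = 0.5
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("cube data must be H×W×M")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        violations = validate_cube(self)
        if violations:
            raise ValueError("invalid cube: " + "; ".join(violations))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def n_channels(self) -> int:
        return self.data.shape[2]

    def pixels(self) -> np.ndarray:
        """Flattened (H·W)×M view of the pixel spectra (row-major)."""
        h, w, m = self.data.shape
        return self.data.reshape(h * w, m)


@dataclass
class ReferenceLibrary:
    """K named endmember spectra on a shared axis — the matrix A of the model.

    Spectra are stored row-wise (K×M).  ``normalization`` records the scaling
    applied at construction (``"unit_l2"`` by default, or ``"none"`` for
    already-scaled spectra, e.g. after channel restriction).
    """

    names: tuple[str, ...]
    spectra: np.ndarray
    axis: WavenumberAxis
    normalization: str = "unit_l2"

    def __post_init__(self):
        self.names = tuple(self.names)
        self.spectra = np.asarray(self.spectra, dtype=float)
        if len(self.names) < 1:
            raise ValueError("library needs at least one component")
        if len(set(self.names)) != len(self.names):
            raise ValueError("duplicate component names")
        if self.spectra.ndim != 2 or self.spectra.shape != (len(self.names), len(self.axis)):
            raise ValueError("spectra must be K×M matching names and axis")
        if not np.all(np.isfinite(self.spectra)):
            raise ValueError("non-finite reference intensity")
        if np.any(self.spectra < 0):
            raise ValueError("negative reference intensity")
        if self.normalization == "unit_l2":
            norms = np.linalg.norm(self.spectra, axis=1)
            if np.any(norms == 0):
                raise ValueError("cannot normalize an all-zero spectrum")
            self.spectra = self.spectra / norms[:, None]

    @property
    def n_components(self) -> int:
        return len(self.names)

    @classmethod
    def from_raw(cls, names, spectra, axis) -> "ReferenceLibrary":
        """Build a unit-norm library from raw non-negative spectra."""
        return cls(tuple(names), np.asarray(spectra, dtype=float), axis, "unit_l2")


@dataclass
class ConcentrationMaps:
    """H×W×K abundance volume produced by unmixing.

    ``axis_used`` records the channel subset the maps were computed from
    (``None`` means the full spectrum); ``meta`` carries λ, normalization tag
    and solver diagnostics so any map is reproducible from its inputs.
    """

    data: np.ndarray
    names: tuple[str, ...]
    axis_used: "ChannelSubset | None" = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.names = tuple(self.names)
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3 or self.data.shape[2] != len(self.names):
            raise ValueError("maps must be H×W×K matching names")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("non-finite abundance")
        if np.any(self.data < 0):
            raise ValueError("negative abundance")

    @property
    def n_components(self) -> int:
        return len(self.names)

    def plane(self, name: str) -> np.ndarray:
        """Single component abundance image."""
        return self.data[:, :, self.names.index(name)]


@dataclass
class ChannelSubset:
    """Selected channel positions into a parent axis, with the RFE trace.

    ``trace`` is the ordered list of ``(eliminated_index, mse_at_elimination)``
    pairs recorded while channels were discarded; its length always equals
    ``parent M − subset size``.
    """

    indices: tuple[int, ...]
    shifts: tuple[float, ...]
    trace: tuple[tuple[int, float], ...] = ()

    def __post_init__(self):
        self.indices = tuple(int(i) for i in self.indices)
        self.shifts = tuple(float(s) for s in self.shifts)
        self.trace = tuple((int(i), float(m)) for i, m in self.trace)
        if len(self.indices) < 1:
            raise ValueError("subset must keep at least one channel")
        if len(set(self.indices)) != len(self.indices):
            raise ValueError("duplicate channel indices")
        if list(self.indices) != sorted(self.indices):
            raise ValueError("channel indices must be sorted ascending")
        if len(self.shifts) != len(self.indices):
            raise ValueError("shifts must pair with indices")

    def __len__(self) -> int:
        return len(self.indices)

    @classmethod
    def from_axis(cls, axis: WavenumberAxis, indices: Sequence[int],
                  trace: Sequence[tuple[int, float]] = ()) -> "ChannelSubset":
        idx = sorted(int(i) for i in indices)
        m = len(axis)
        for i in idx:
            if not 0 <= i < m:
                raise IndexError(f"channel index {i} out of range for {m}-channel axis")
        shifts = [axis.shifts[i] for i in idx]
        return cls(tuple(idx), tuple(shifts), tuple(trace))


def validate_cube(cube: HyperspectralCube) -> list[str]:
    """Report-only invariant check; returns a list of violations (empty = valid)."""
    violations: list[str] = []
    data = np.asarray(cube.data)
    if data.ndim != 3:
        violations.append("data is not H×W×M")
        return violations
    h, w, m = data.shape
    if h < 1 or w < 1:
        violations.append("empty spatial extent")
    if m != len(cube.axis):
        violations.append(
            f"axis length mismatch: {m} channels vs {len(cube.axis)} shifts"
        )
    if not np.all(np.isfinite(data)):
        violations.append("non-finite intensity")
    if cube.pixel_size_um <= 0:
        violations.append("non-positive pixel size")
    return violations


def restrict_to_channels(obj, subset: ChannelSubset):
    """Slice a cube or library down to the channels of ``subset``.

    The returned object's axis is exactly the subset shifts.  For a library
    the sliced spectra keep their full-spectrum scaling (no renormalization),
    so abundances computed on the subset remain comparable to full-spectrum
    abundances.
    """
    idx = np.asarray(subset.indices, dtype=int)
    if isinstance(obj, HyperspectralCube):
        m = obj.n_channels
        if np.any(idx < 0) or np.any(idx >= m):
            raise IndexError(f"subset index out of range for {m}-channel cube")
        sub_axis = WavenumberAxis([obj.axis.shifts[i] for i in idx])
        if tuple(sub_axis.shifts) != subset.shifts:
            raise ValueError("subset shifts do not match the cube axis")
        prov = dict(obj.provenance)
        prov["channel_subset_cm1"] = list(subset.shifts)
        return HyperspectralCube(obj.data[:, :, idx].copy(), sub_axis,
                                 obj.pixel_size_um, prov)
    if isinstance(obj, ReferenceLibrary):
        m = len(obj.axis)
        if np.any(idx < 0) or np.any(idx >= m):
            raise IndexError(f"subset index out of range for {m}-channel library")
        sub_axis = WavenumberAxis([obj.axis.shifts[i] for i in idx])
        # sliced, not renormalized: abundances keep the full-spectrum scale
        return ReferenceLibrary(obj.names, obj.spectra[:, idx].copy(), sub_axis,
                                normalization="none")
    raise TypeError(f"cannot restrict object of type {type(obj).__name__}")
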