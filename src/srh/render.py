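"""Pseudo-color histology rendering of concentration maps.

The display convention mirrors the standard HC-SRH presentation: yellow for
unsaturated lipids, red for cellular protein, blue for ECM, cyan for
saturated lipids, grey for water.  Each component map is normalized by its
own maximum, multiplied by its RGB triple, and the contributions are summed
and clipped to [0, 1] — additive blending, so overlaps brighten and mix
(protein over ECM → magenta).  Water is blended at half weight by default so
the ubiquitous grey background does not wash out tissue structure; the water
channel is typically also percentile contrast-enhanced before display.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import ConcentrationMaps

__all__ = ["ColorScheme", "DEFAULT_SCHEME", "enhance_contrast", "render_merged"]


@dataclass(frozen=True)
class ColorScheme:
    """Component name → RGB triple (components in [0, 1])."""

    colors: dict[str, tuple[float, float, float]]
    weights: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        for name, rgb in self.colors.items():
            if len(rgb) != 3 or any(not (0.0 <= v <= 1.0) for v in rgb):
                raise ValueError(f"invalid RGB for {name!r}")

    def color(self, name: str) -> np.ndarray:
        if name not in self.colors:
            raise KeyError(f"no color assigned for component {name!r}")
        return np.asarray(self.colors[name], dtype=float)

    def weight(self, name: str) -> float:
        return float(self.weights.get(name, 1.0))


DEFAULT_SCHEME = ColorScheme(
    colors={
        "unsaturated_lipid": (1.0, 1.0, 0.0),  # yellow
        "cellular_protein": (1.0, 0.0, 0.0),   # red
        "ecm": (0.0, 0.0, 1.0),                # blue
        "saturated_lipid": (0.0, 1.0, 1.0),    # cyan
        "water": (0.7, 0.7, 0.7),              # grey
    },
    weights={"water": 0.5},
)


def enhance_contrast(plane: np.ndarray, method: str = "percentile",
                     percentiles: tuple[float, float] = (1.0, 99.0)) -> np.ndarray:
    """Percentile contrast stretch mapping [p_lo, p_hi] → [0, 1], clipped.

    A constant plane (degenerate stretch) maps to all zeros.
    """
    if method != "percentile":
        raise ValueError(f"unknown contrast method {method!r}")
    p_lo, p_hi = percentiles
    if p_lo >= p_hi:
        raise ValueError("lower percentile must be below the upper one")
    plane = np.asarray(plane, dtype=float)
    if np.any(plane < 0):
        raise ValueError("plane must be non-negative")
    lo, hi = np.percentile(plane, [p_lo, p_hi])
    if hi <= lo:
        return np.zeros_like(plane)
    return np.clip((plane - lo) / (hi - lo), 0.0, 1.0)


def render_merged(maps: ConcentrationMaps, scheme: ColorScheme = DEFAULT_SCHEME,
                  enhance: dict[str, tuple[float, float]] | None = None,
                  use_weights: bool = True) -> np.ndarray:
    """Merge concentration maps into an H×W×3 RGB image in [0, 1].

    Each component is scaled by its own maximum (so rendering is invariant
    to a global rescale of any map), optionally contrast-stretched
    (``enhance = {"water": (1, 99)}`` reproduces the enhanced water channel),
    colored, weighted, summed and clipped.
    """
    h, w, _ = maps.data.shape
    rgb = np.zeros((h, w, 3))
    enhance = enhance or {}
    for i, name in enumerate(maps.names):
        color = scheme.color(name)
        plane = maps.data[:, :, i]
        if name in enhance:
            norm = enhance_contrast(plane, "percentile", enhance[name])
        else:
            peak = float(plane.max())
            norm = plane / peak if peak > 0 else np.zeros_like(plane)
        weight = scheme.weight(name) if use_weights else 1.0
        rgb += weight * norm[:, :, None] * color[None, None, :]
    return np.clip(rgb, 0.0, 1.0)
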