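"""Image-quality metrics quantifying channel-reduction degradation.

Reduced-channel concentration maps are scored against the full-spectrum
result per component with SSIM (mean local structural similarity, 7×7
uniform window, stabilizers C1 = (0.01·R)² and C2 = (0.03·R)²) and PSNR
(10·log₁₀(R²/MSE), in dB).  The dynamic range R for each component is the
maximum of the *reference* (full-spectrum) map, which keeps PSNR comparable
across different channel counts; identical planes get a +inf PSNR sentinel.
Aggregate numbers are unweighted means over components, and the choice is
recorded on the report.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from skimage.metrics import structural_similarity

from .core import ConcentrationMaps

__all__ = ["QualityReport", "ssim", "psnr", "compare_maps"]


def ssim(a: np.ndarray, b: np.ndarray, data_range: float) -> float:
    """Mean local SSIM with a 7×7 uniform window; symmetric in (a, b)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    if data_range <= 0:
        raise ValueError("data_range must be positive")
    return float(structural_similarity(a, b, win_size=7, gaussian_weights=False,
                                       data_range=data_range))


def psnr(a: np.ndarray, b: np.ndarray, data_range: float) -> float:
    """Peak signal-to-noise ratio in dB; identical planes → +inf."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    if data_range <= 0:
        raise ValueError("data_range must be positive")
    mse = float(np.mean((a - b) ** 2))
    if mse == 0:
        return math.inf
    return 10.0 * math.log10(data_range**2 / mse)


@dataclass
class QualityReport:
    """Per-component and aggregate SSIM/PSNR of a map set vs a reference."""

    per_component: dict[str, tuple[float, float]]  # name -> (ssim, psnr_db)
    mean_ssim: float
    mean_psnr_db: float
    data_range: dict[str, float]
    notes: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {
            "per_component": {k: {"ssim": v[0], "psnr_db": v[1]}
                              for k, v in self.per_component.items()},
            "mean_ssim": self.mean_ssim,
            "mean_psnr_db": self.mean_psnr_db,
            "data_range": self.data_range,
            "notes": self.notes,
        }


def compare_maps(candidate: ConcentrationMaps, reference: ConcentrationMaps) -> QualityReport:
    """Score ``candidate`` concentration maps against ``reference``.

    The reference is the full-spectrum result; its per-component maximum sets
    the dynamic range (an all-zero reference plane falls back to the
    candidate's maximum, or 1 if both are empty).
    """
    if candidate.names != reference.names:
        raise ValueError("component names/order differ between map sets")
    if candidate.data.shape != reference.data.shape:
        raise ValueError("map shapes differ")
    per: dict[str, tuple[float, float]] = {}
    ranges: dict[str, float] = {}
    for i, name in enumerate(reference.names):
        ref_plane = reference.data[:, :, i]
        cand_plane = candidate.data[:, :, i]
        r = float(ref_plane.max())
        if r == 0:
            r = float(cand_plane.max()) or 1.0
        ranges[name] = r
        per[name] = (ssim(cand_plane, ref_plane, r), psnr(cand_plane, ref_plane, r))
    ssims = [v[0] for v in per.values()]
    psnrs = [v[1] for v in per.values()]
    mean_psnr = math.inf if any(math.isinf(p) for p in psnrs) else float(np.mean(psnrs))
    return QualityReport(per, float(np.mean(ssims)), mean_psnr, ranges,
                         {"aggregation": "unweighted mean over components",
                          "data_range": "max of reference map per component"})
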