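"""Beer-Lambert stain model: optical density, unmixing, forward mixing.

Chromogenic IHC tiles are a mixture of two absorbing dyes on a bright-field
scanner: hematoxylin (bluish, all nuclei) and DAB (brown, receptor-positive
nuclei).  In optical-density space absorbances add linearly, so an RGB pixel
can be unmixed into per-stain concentrations with the inverse of a 3x3 stain
matrix (Ruifrok-Johnston colour deconvolution).  The same matrix, run
forward, turns known per-stain od rasters into an 8-bit RGB image, which is
how the synthetic generator produces tiles with known ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigError, ParameterError, ShapeError

__all__ = [
    "StainModel",
    "DABMap",
    "rgb_to_od",
    "deconvolve",
    "normalize_dab",
    "forward_mix",
]

# Ruifrok & Johnston H-DAB optical-density vectors; the residual channel is
# the normalized cross product of the two (same construction as skimage's
# hdx basis, so it may carry a negative component).
_H = np.array([0.650, 0.704, 0.286])
_DAB = np.array([0.269, 0.568, 0.778])

#: Small additive constant in the log transform; keeps od finite at rgb=0.
LOG_EPS = 1.0


def _default_vectors() -> np.ndarray:
    h = _H / np.linalg.norm(_H)
    d = _DAB / np.linalg.norm(_DAB)
    r = np.cross(h, d)
    r = r / np.linalg.norm(r)
    return np.vstack([h, d, r])


@dataclass(frozen=True)
class StainModel:
    """3-stain od basis (rows: hematoxylin, DAB, residual) plus scanner I0.

    Parameters
    ----------
    vectors
        3x3 matrix whose rows are unit od vectors.  Channel od of a pixel
        with concentrations ``c`` is ``c @ vectors``.
    background_intensity
        Transmitted light level I0 per channel (scalar or length 3).
    od_reference
        Optical density mapped to DAB value 1.0 by :func:`normalize_dab`.
    """

    vectors: np.ndarray = field(default_factory=_default_vectors)
    background_intensity: float = 255.0
    od_reference: float = 1.0

    def __post_init__(self) -> None:
        v = np.asarray(self.vectors, dtype=float)
        if v.shape != (3, 3):
            raise ConfigError(f"stain matrix must be 3x3, got {v.shape}")
        norms = np.linalg.norm(v, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-6):
            raise ConfigError(f"stain vectors must be unit norm, got norms {norms}")
        # physical non-negativity applies to the dye vectors themselves;
        # the residual (cross product) may dip below zero
        if np.any(v[:2] < -1e-9):
            raise ConfigError("hematoxylin/DAB vectors must be non-negative")
        cos = abs(float(v[0] @ v[1]))
        if cos > 1.0 - 1e-6:
            raise ConfigError("hematoxylin and DAB vectors are collinear")
        if np.linalg.cond(v) > 1e8:
            raise ConfigError("stain matrix is numerically singular")
        if np.any(np.asarray(self.background_intensity) <= 0):
            raise ConfigError("background_intensity must be positive")
        if self.od_reference <= 0:
            raise ConfigError("od_reference must be positive")
        object.__setattr__(self, "vectors", v)

    @property
    def inverse(self) -> np.ndarray:
        return np.linalg.inv(self.vectors)


@dataclass(frozen=True)
class DABMap:
    """Normalized DAB channel in [0, 1]; input to the mean-intensity statistic."""

    values: np.ndarray
    od_reference: float = 1.0

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.min(initial=0.0) < 0.0 or v.max(initial=0.0) > 1.0:
            raise ParameterError("DABMap values must lie in [0, 1]")
        object.__setattr__(self, "values", v)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.values.shape


def rgb_to_od(rgb: np.ndarray, background_intensity: float | np.ndarray = 255.0) -> np.ndarray:
    """Convert an 8-bit RGB raster to optical density.

    od = -log10((rgb + eps) / I0) with eps = 1, per channel.  Strictly
    decreasing in rgb; ~0 for background (white) pixels.
    """
    rgb = np.asarray(rgb)
    if rgb.ndim != 3 or rgb.shape[-1] != 3:
        raise ShapeError(f"expected an (H, W, 3) raster, got shape {rgb.shape}")
    i0 = np.asarray(background_intensity, dtype=float)
    if np.any(i0 <= 0):
        raise ParameterError("background_intensity must be positive")
    return -np.log10((rgb.astype(float) + LOG_EPS) / i0)


def deconvolve(rgb: np.ndarray, model: StainModel | None = None) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Unmix an RGB tile into (hematoxylin, DAB, residual) od rasters.

    Solves od = c @ M per pixel with the inverse stain matrix; negative
    concentrations are clipped to 0 (physical non-negativity).
    """
    if model is None:
        model = StainModel()
    od = rgb_to_od(rgb, model.background_intensity)
    conc = od @ model.inverse
    conc = np.clip(conc, 0.0, None)
    return conc[..., 0], conc[..., 1], conc[..., 2]


def normalize_dab(dab_od: np.ndarray, od_reference: float = 1.0) -> DABMap:
    """Rescale a DAB od raster to [0, 1] with ``od_reference`` mapping to 1."""
    if od_reference <= 0:
        raise ParameterError("od_reference must be positive")
    values = np.clip(np.asarray(dab_od, dtype=float) / od_reference, 0.0, 1.0)
    return DABMap(values=values, od_reference=od_reference)


def forward_mix(
    hematoxylin_od: np.ndarray,
    dab_od: np.ndarray,
    model: StainModel | None = None,
    residual_od: np.ndarray | None = None,
) -> np.ndarray:
    """Render per-stain od rasters to an 8-bit RGB image (Beer-Lambert).

    rgb = round(I0 * 10^-(c @ M)), clipped to [0, 255].  Inverse of
    :func:`deconvolve` up to 8-bit quantization.
    """
    if model is None:
        model = StainModel()
    h = np.asarray(hematoxylin_od, dtype=float)
    d = np.asarray(dab_od, dtype=float)
    if h.shape != d.shape:
        raise ShapeError(f"od raster shapes differ: {h.shape} vs {d.shape}")
    r = np.zeros_like(h) if residual_od is None else np.asarray(residual_od, dtype=float)
    if r.shape != h.shape:
        raise ShapeError(f"residual shape {r.shape} != {h.shape}")
    conc = np.stack([h, d, r], axis=-1)
    channel_od = conc @ model.vectors
    i0 = np.asarray(model.background_intensity, dtype=float)
    rgb = np.round(i0 * np.power(10.0, -channel_od))
    return np.clip(rgb, 0, 255).astype(np.uint8)
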