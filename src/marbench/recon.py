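"""Filtered backprojection with a Ram-Lak filter, and HU conversion.

Classic parallel-beam FBP: each view is convolved with the band-limited
ramp (Ram-Lak) kernel sampled at the detector pitch, then backprojected
with linear interpolation.  No apodization window is applied.  The output
is a linear attenuation image in 1/cm on a square grid whose extent
defaults to the detector field of view.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

from .projector import LogSinogram, ProjectionGeometry
from ._kernels import backproject

__all__ = ["ReconImage", "ramp_filter", "fbp", "mu_to_hu"]


@dataclass(frozen=True)
class ReconImage:
    """Reconstructed attenuation image (1/cm) with provenance metadata."""

    pixels: np.ndarray
    pixel_size: float
    provenance: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        p = np.asarray(self.pixels)
        if p.ndim != 2 or p.shape[0] != p.shape[1]:
            raise ValueError("image must be square")
        if not np.all(np.isfinite(p)):
            raise ValueError("image must be finite")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


def _ramp_kernel_fft(n_bins: int, spacing: float) -> np.ndarray:
    """FFT of the discrete band-limited ramp kernel (Ram-Lak).

    Spatial samples: h[0] = 1/(4 d^2), h[k] = -1/(pi k d)^2 for odd k,
    0 for even k; zero-padded to the next power of two above 2 n_bins.
    """
    size = 1 << int(np.ceil(np.log2(2 * n_bins)))
    h = np.zeros(size)
    h[0] = 1.0 / (4.0 * spacing**2)
    k = np.arange(1, n_bins)
    odd = k[k % 2 == 1]
    vals = -1.0 / (np.pi * odd * spacing) ** 2
    h[odd] = vals
    h[-odd] = vals
    return np.fft.rfft(h)


def ramp_filter(sino: np.ndarray, spacing: float) -> np.ndarray:
    """Apply the Ram-Lak filter along the detector axis of (views, bins)."""
    n_views, n_bins = sino.shape
    H = _ramp_kernel_fft(n_bins, spacing)
    size = 2 * (H.shape[0] - 1)
    padded = np.fft.rfft(sino, n=size, axis=1)
    filtered = np.fft.irfft(padded * H[None, :], n=size, axis=1)[:, :n_bins]
    return filtered * spacing


def fbp(
    sino: LogSinogram | np.ndarray,
    out_size: int = 512,
    geometry: ProjectionGeometry | None = None,
    fov: float | None = None,
    provenance: dict[str, Any] | None = None,
) -> ReconImage:
    """Reconstruct a log sinogram into a ``out_size``-square mu image.

    ``fov`` sets the reconstructed extent (default: detector field of
    view); the operator is linear in the sinogram values.
    """
    if isinstance(sino, LogSinogram):
        geometry = sino.geometry
        values = sino.values
    else:
        if geometry is None:
            raise ValueError("geometry required when passing a bare array")
        values = np.asarray(sino, float)
    fov = geometry.fov if fov is None else fov
    pixel_size = fov / out_size
    filtered = ramp_filter(values, geometry.detector_spacing)
    th = geometry.thetas
    img = backproject(
        np.ascontiguousarray(filtered),
        np.cos(th),
        np.sin(th),
        geometry.detector_spacing,
        int(out_size),
        float(pixel_size),
    )
    prov = {"pipeline": "FBP"}
    if provenance:
        prov.update(provenance)
    return ReconImage(pixels=img, pixel_size=pixel_size, provenance=prov)


def mu_to_hu(image: ReconImage | np.ndarray, mu_water_eff: float) -> np.ndarray:
    """Hounsfield units: 1000 (mu - mu_water) / mu_water."""
    if mu_water_eff <= 0:
        raise ValueError("mu_water_eff must be positive")
    pixels = image.pixels if isinstance(image, ReconImage) else np.asarray(image)
    return 1000.0 * (pixels - mu_water_eff) / mu_water_eff
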