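"""Sinogram-inpainting metal artifact reduction.

Two classical variants are implemented:

* **MAR 1** — sinogram-domain segmentation: bins whose log-attenuation
  exceeds a fixed threshold are declared metal-corrupted and replaced by
  linear interpolation along the detector axis, then the repaired sinogram
  is reconstructed with FBP.
* **MAR 2** — image-domain segmentation: the uncorrected FBP image is
  thresholded in HU to find metal pixels, the (slightly dilated) metal mask
  is forward projected to locate the corrupted sinogram bins, and those
  bins are inpainted before the final FBP.

Both thresholds are calibrated once, at mid-range imaging parameters, and
then *frozen* — deliberately.  A frozen sinogram threshold is fragile
against dose changes (the scatter floor compresses log values at low dose
until the metal trace falls below the threshold and the mask comes out
empty), and detecting that failure mode is precisely what the assessment
framework is for.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .projector import LogSinogram, ProjectionGeometry, project_image
from .recon import ReconImage, fbp, mu_to_hu

__all__ = [
    "MetalTraceMask",
    "MetalImageMask",
    "MARThresholds",
    "segment_sinogram_metal",
    "inpaint_trace",
    "mar1",
    "segment_image_metal",
    "metal_trace_from_image_mask",
    "mar2",
]


@dataclass(frozen=True)
class MetalTraceMask:
    """Boolean sinogram mask; True = corrupted by metal."""

    mask: np.ndarray
    geometry: ProjectionGeometry

    def __post_init__(self) -> None:
        if self.mask.shape != self.geometry.shape:
            raise ValueError("trace mask shape does not match geometry")


@dataclass(frozen=True)
class MetalImageMask:
    """Boolean image mask; True = metal pixel."""

    mask: np.ndarray
    pixel_size: float


@dataclass(frozen=True)
class MARThresholds:
    """Frozen calibration products: MAR 1 log-attenuation threshold and
    MAR 2 HU threshold (plus the effective water mu used for HU)."""

    log_threshold: float
    hu_threshold: float
    mu_water_eff: float


def segment_sinogram_metal(
    sino: LogSinogram, threshold: float
) -> MetalTraceMask:
    """MAR 1 segmentation: mask = (log value > threshold)."""
    return MetalTraceMask(mask=sino.values > threshold, geometry=sino.geometry)


def inpaint_trace(sino: LogSinogram, mask: MetalTraceMask) -> LogSinogram:
    """Replace masked bins by 1-D linear interpolation along each view.

    Maximal masked runs are bridged linearly between the nearest unmasked
    neighbors; runs touching a detector edge take the nearest unmasked
    value.  Unmasked bins are bit-identical to the input.
    """
    m = mask.mask
    if m.shape != sino.values.shape:
        raise ValueError("mask shape does not match sinogram")
    out = sino.values.copy()
    bins = np.arange(sino.geometry.n_bins)
    for v in range(sino.geometry.n_views):
        row_mask = m[v]
        if not row_mask.any():
            continue
        if row_mask.all():
            raise ValueError(
                f"view {v} fully masked: metal segmentation is catastrophic"
            )
        good = ~row_mask
        out[v, row_mask] = np.interp(bins[row_mask], bins[good], out[v, good])
    return LogSinogram(
        values=out, geometry=sino.geometry, I0=sino.I0, s0=sino.s0
    )


def mar1(
    sino: LogSinogram, threshold: float, out_size: int = 512, fov: float | None = None
) -> ReconImage:
    """Sinogram-domain MAR: segment, inpaint, reconstruct."""
    mask = segment_sinogram_metal(sino, threshold)
    repaired = inpaint_trace(sino, mask)
    img = fbp(repaired, out_size=out_size, fov=fov)
    return ReconImage(
        pixels=img.pixels,
        pixel_size=img.pixel_size,
        provenance={**img.provenance, "pipeline": "MAR1", "log_threshold": threshold},
    )


def segment_image_metal(
    image: ReconImage, hu_threshold: float, mu_water_eff: float
) -> MetalImageMask:
    """MAR 2 segmentation: mask = (HU(image) > hu_threshold)."""
    hu = mu_to_hu(image, mu_water_eff)
    return MetalImageMask(mask=hu > hu_threshold, pixel_size=image.pixel_size)


def metal_trace_from_image_mask(
    mask: MetalImageMask,
    geometry: ProjectionGeometry,
    dilate_px: int = 1,
    tau: float | None = None,
) -> MetalTraceMask:
    """Forward project a metal image mask into a sinogram trace.

    The mask is dilated by ``dilate_px`` pixels first (standard safety
    margin against partial-volume erosion of the segmented metal), then
    projected; bins whose metal path length exceeds ``tau`` (default: half
    a pixel) are flagged.
    """
    m = mask.mask
    if dilate_px > 0 and m.any():
        m = ndimage.binary_dilation(m, iterations=dilate_px)
    if tau is None:
        tau = 0.5 * mask.pixel_size
    n = m.shape[0]
    path = project_image(
        m.astype(np.float64),
        geometry,
        mask.pixel_size,
        support_radius=0.5 * n * mask.pixel_size * 1.5,
    )
    return MetalTraceMask(mask=path > tau, geometry=geometry)


def mar2(
    sino: LogSinogram,
    hu_threshold: float,
    mu_water_eff: float,
    out_size: int = 512,
    fov: float | None = None,
    dilate_px: int = 1,
    reinsert_metal: bool = False,
    initial_image: ReconImage | None = None,
) -> ReconImage:
    """Image-domain MAR: FBP, segment metal in HU, forward project the
    mask, inpaint the trace, reconstruct.

    ``initial_image`` may pass in an already-computed plain FBP of the same
    sinogram to avoid reconstructing it twice.  With ``reinsert_metal`` the
    segmented metal pixels are copied back into the corrected image.
    """
    image0 = initial_image if initial_image is not None else fbp(
        sino, out_size=out_size, fov=fov
    )
    img_mask = segment_image_metal(image0, hu_threshold, mu_water_eff)
    if not img_mask.mask.any():
        out = image0.pixels.copy()
    else:
        trace = metal_trace_from_image_mask(
            img_mask, sino.geometry, dilate_px=dilate_px
        )
        repaired = inpaint_trace(sino, trace)
        out = fbp(repaired, out_size=out_size, fov=fov).pixels
        if reinsert_metal:
            out[img_mask.mask] = image0.pixels[img_mask.mask]
    return ReconImage(
        pixels=out,
        pixel_size=image0.pixel_size,
        provenance={
            **image0.provenance,
            "pipeline": "MAR2",
            "hu_threshold": hu_threshold,
            "dilate_px": dilate_px,
            "reinsert_metal": reinsert_metal,
        },
    )
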