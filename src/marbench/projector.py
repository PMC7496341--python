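"""Polychromatic projection simulation on a fixed parallel-beam geometry.

The chain is: per-material path-length sinograms (cm) -> expected detected
counts under the tube spectrum (Beer-Lambert per energy bin, summed with
spectral weights) -> Poisson counting noise + constant Poisson scatter +
Gaussian electronic readout noise -> negative-log sinogram normalized to
the flat field ``I0 + s0``.

Beam hardening is inherent to the polychromatic sum: the effective
attenuation per cm falls as the path grows, which (together with photon
starvation behind metal and the scatter floor) is the physical driver of
the metal artifacts this framework is built to study.

Scatter is modelled as a *constant* background: a fixed
Poisson mean ``s0`` per bin per view, independent of the tube output
``I0``.  At low dose the scatter floor dominates the detected counts and
compresses the log values toward ``ln(1 + I0/s0)`` — this is exactly what
defeats a frozen sinogram-domain metal threshold (see `marbench.mar`).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .materials import AttenuationTable, Spectrum, interpolate_mu
from .phantom import PhantomInstance, rasterize
from ._kernels import forward_project

__all__ = [
    "ProjectionGeometry",
    "CountsSinogram",
    "LogSinogram",
    "project_image",
    "material_line_integrals",
    "expected_counts",
    "detect_counts",
    "counts_to_log_sinogram",
]

PHANTOM_DIAMETER = 24.0  # cm, outer disk
LOG_CLIP_COUNTS = 1.0  # photon-starvation clip before the log


@dataclass(frozen=True)
class ProjectionGeometry:
    """Parallel-beam sampling: ``n_views`` over [0, pi), ``n_bins`` detector
    bins of ``detector_spacing`` cm with the center bin on the rotation axis."""

    n_views: int = 720
    n_bins: int = 729
    fov: float = 26.0

    def __post_init__(self) -> None:
        if self.n_views < 180:
            raise ValueError("need at least 180 views over [0, pi)")
        if self.n_bins % 2 == 0:
            raise ValueError("n_bins must be odd (center bin on the rotation axis)")
        if self.fov < PHANTOM_DIAMETER:
            raise ValueError(f"detector extent must cover {PHANTOM_DIAMETER} cm")

    @property
    def detector_spacing(self) -> float:
        return self.fov / self.n_bins

    @property
    def thetas(self) -> np.ndarray:
        return np.arange(self.n_views) * np.pi / self.n_views

    @property
    def s_coords(self) -> np.ndarray:
        return (np.arange(self.n_bins) - (self.n_bins - 1) / 2.0) * self.detector_spacing

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_views, self.n_bins)


@dataclass(frozen=True)
class CountsSinogram:
    """Detected photons per bin per view (non-integer after readout noise)."""

    counts: np.ndarray
    geometry: ProjectionGeometry
    I0: float
    s0: float
    readout_sigma: float
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.counts.shape != self.geometry.shape:
            raise ValueError("counts shape does not match geometry")
        if self.I0 <= 0:
            raise ValueError("I0 must be positive")
        if self.s0 < 0:
            raise ValueError("s0 must be non-negative")


@dataclass(frozen=True)
class LogSinogram:
    """Negative-log projection data, ``-ln(counts / (I0 + s0))``."""

    values: np.ndarray
    geometry: ProjectionGeometry
    I0: float = 1.0
    s0: float = 0.0

    def __post_init__(self) -> None:
        if self.values.shape != self.geometry.shape:
            raise ValueError("log sinogram shape does not match geometry")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("log sinogram must be finite everywhere")


def project_image(
    image: np.ndarray,
    geometry: ProjectionGeometry,
    pixel_size: float,
    support_radius: float = 0.0,
) -> np.ndarray:
    """Discrete line integrals (value-weighted cm) of one pixel map.

    ``support_radius`` (cm, optional) bounds the ray marching to a circle
    known to contain all nonzero pixels; 0 integrates the full grid.
    """
    image = np.ascontiguousarray(image, dtype=np.float64)
    th = geometry.thetas
    return forward_project(
        image,
        float(pixel_size),
        np.cos(th),
        np.sin(th),
        geometry.n_bins,
        geometry.detector_spacing,
        float(support_radius),
    )


def material_line_integrals(
    phantom: PhantomInstance,
    geometry: ProjectionGeometry,
    grid_size: int = 729,
    fov: float | None = None,
    precomputed_fixed: dict[str, np.ndarray] | None = None,
) -> dict[str, np.ndarray]:
    """Per-material path-length sinograms of a phantom instance.

    The phantom is rasterized at ``grid_size`` and each material map is
    forward projected; the operation is linear in the maps.  ``fov``
    defaults to the detector extent.  ``precomputed_fixed`` may carry
    sinograms of the angle-independent bone and iron maps (they are
    identical across acquisitions that share ``teeth_material``), in which
    case only the water map — the only one touched by the rotating inset
    and the signal — is projected.
    """
    fov = geometry.fov if fov is None else fov
    if grid_size < geometry.n_bins // 2:
        raise ValueError("rasterization grid too coarse for the detector sampling")
    pixel = fov / grid_size
    maps = rasterize(phantom, grid_size, fov)
    support = 12.0 + 3.0 * pixel  # outer disk radius plus sampling margin
    sinos: dict[str, np.ndarray] = {}
    for mat, m in maps.items():
        if precomputed_fixed is not None and mat in precomputed_fixed:
            sinos[mat] = precomputed_fixed[mat]
        else:
            sinos[mat] = project_image(m, geometry, pixel, support_radius=support)
    return sinos


def _polychromatic_transmission(
    mats: dict[str, np.ndarray],
    spectrum: Spectrum,
    tables: dict[str, AttenuationTable],
) -> np.ndarray:
    """sum_E S(E) exp(-sum_m mu_m(E) L_m), per sinogram bin."""
    first = next(iter(mats.values()))
    out = np.zeros_like(first)
    names = [m for m in mats if np.any(mats[m])]
    mus = {m: interpolate_mu(tables[m], spectrum.energies) for m in names}
    for k, w in enumerate(spectrum.weights):
        if w == 0.0:
            continue
        path = np.zeros_like(first)
        for m in names:
            path += mus[m][k] * mats[m]
        out += w * np.exp(-path)
    return out


def expected_counts(
    mats: dict[str, np.ndarray],
    spectrum: Spectrum,
    tables: dict[str, AttenuationTable],
    I0: float,
    s0: float = 0.0,
) -> np.ndarray:
    """Noise-free mean detected counts ``I0 * T + s0`` per bin."""
    return I0 * _polychromatic_transmission(mats, spectrum, tables) + s0


def detect_counts(
    mats: dict[str, np.ndarray],
    spectrum: Spectrum,
    tables: dict[str, AttenuationTable],
    geometry: ProjectionGeometry,
    I0: float,
    s0: float = 100.0,
    readout_sigma: float = 5.0,
    seed: int | None = 0,
) -> CountsSinogram:
    """Simulate one noisy acquisition.

    Detected counts are a Poisson sample of the spectrally integrated
    primary beam, plus an independent Poisson scatter sample of constant
    mean ``s0``, plus zero-mean Gaussian readout noise.  ``seed=None``
    returns the noiseless expectation (useful for calibration).
    """
    primary = I0 * _polychromatic_transmission(mats, spectrum, tables)
    if seed is None:
        counts = primary + s0
    else:
        rng = np.random.default_rng(seed)
        counts = rng.poisson(primary).astype(np.float64)
        if s0 > 0:
            counts += rng.poisson(s0, size=primary.shape)
        if readout_sigma > 0:
            counts += rng.normal(0.0, readout_sigma, size=primary.shape)
    return CountsSinogram(
        counts=counts,
        geometry=geometry,
        I0=float(I0),
        s0=float(s0),
        readout_sigma=float(readout_sigma),
        seed=seed,
    )


def counts_to_log_sinogram(counts: CountsSinogram) -> LogSinogram:
    """Negative-log transform with a photon-starvation clip at 1 count."""
    flat = counts.I0 + counts.s0
    values = -np.log(np.clip(counts.counts, LOG_CLIP_COUNTS, None) / flat)
    return LogSinogram(
        values=values, geometry=counts.geometry, I0=counts.I0, s0=counts.s0
    )
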