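"""HDF5 / TIFF persistence for sinograms and reconstructed images."""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np
import tifffile

from .projector import CountsSinogram, LogSinogram, ProjectionGeometry
from .recon import ReconImage

__all__ = [
    "save_log_sinogram",
    "load_log_sinogram",
    "save_counts_sinogram",
    "save_image_tiff",
    "load_image_tiff",
    "save_image_h5",
]


def _write_geometry(group: h5py.Group, geometry: ProjectionGeometry) -> None:
    group.attrs["n_views"] = geometry.n_views
    group.attrs["n_bins"] = geometry.n_bins
    group.attrs["fov"] = geometry.fov
    group.attrs["detector_spacing"] = geometry.detector_spacing


def _read_geometry(group: h5py.Group) -> ProjectionGeometry:
    return ProjectionGeometry(
        n_views=int(group.attrs["n_views"]),
        n_bins=int(group.attrs["n_bins"]),
        fov=float(group.attrs["fov"]),
    )


def save_log_sinogram(path: str | Path, sino: LogSinogram) -> None:
    with h5py.File(path, "w") as f:
        d = f.create_dataset("log_sinogram", data=sino.values)
        _write_geometry(d, sino.geometry)
        d.attrs["I0"] = sino.I0
        d.attrs["s0"] = sino.s0


def load_log_sinogram(path: str | Path) -> LogSinogram:
    with h5py.File(path, "r") as f:
        d = f["log_sinogram"]
        return LogSinogram(
            values=d[()],
            geometry=_read_geometry(d),
            I0=float(d.attrs["I0"]),
            s0=float(d.attrs["s0"]),
        )


def save_counts_sinogram(path: str | Path, counts: CountsSinogram) -> None:
    with h5py.File(path, "w") as f:
        d = f.create_dataset("counts", data=counts.counts)
        _write_geometry(d, counts.geometry)
        d.attrs["I0"] = counts.I0
        d.attrs["s0"] = counts.s0
        d.attrs["readout_sigma"] = counts.readout_sigma
        if counts.seed is not None and np.isscalar(counts.seed):
            d.attrs["seed"] = counts.seed


def save_image_tiff(path: str | Path, image: ReconImage) -> None:
    tifffile.imwrite(
        path,
        image.pixels.astype(np.float32),
        metadata={"pixel_size_cm": image.pixel_size, **{
            k: str(v) for k, v in image.provenance.items()
        }},
    )


def load_image_tiff(path: str | Path, pixel_size: float) -> ReconImage:
    return ReconImage(pixels=tifffile.imread(path).astype(float), pixel_size=pixel_size)


def save_image_h5(path: str | Path, image: ReconImage) -> None:
    with h5py.File(path, "w") as f:
        d = f.create_dataset("image", data=image.pixels)
        d.attrs["pixel_size_cm"] = image.pixel_size
        for k, v in image.provenance.items():
            d.attrs[f"prov_{k}"] = str(v)


def save_channel_bank(path: str | Path, bank) -> None:
    """Export a DDOG channel matrix (q x p) with its parameters."""
    with h5py.File(path, "w") as f:
        d = f.create_dataset("U", data=bank.U)
        d.attrs["roi_side"] = bank.roi_side
        d.attrs["sigma0"] = bank.sigma0
        d.attrs["alpha"] = bank.alpha
        d.attrs["Q"] = bank.Q
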