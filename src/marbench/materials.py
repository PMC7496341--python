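"""Energy-dependent attenuation data and the x-ray tube spectrum.

The simulation needs linear attenuation coefficients :math:`\\mu(E)` for the
three phantom materials (water, cortical bone, iron) and a 120 kVp tube
spectrum.  Both are shipped as small plain-text tables under
``marbench/data`` so that runs are fully self-contained and deterministic.

Attenuation values are interpolated log-log linearly, the standard scheme
for photon cross sections, which vary smoothly on a log-log scale away from
absorption edges (none of the three materials has an edge above 10 keV).
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass

import numpy as np

__all__ = [
    "AttenuationTable",
    "Spectrum",
    "load_attenuation_table",
    "load_spectrum",
    "interpolate_mu",
    "effective_mu",
]

_MATERIAL_FILES = {
    "water": "mu_water.txt",
    "bone": "mu_bone.txt",
    "iron": "mu_iron.txt",
}

_SPECTRUM_FILES = {
    "120kvp": "spectrum_120kvp.txt",
}


def _read_two_column(name: str) -> tuple[np.ndarray, np.ndarray]:
    ref = importlib.resources.files("marbench.data").joinpath(name)
    data = np.loadtxt(str(ref))
    return data[:, 0], data[:, 1]


@dataclass(frozen=True)
class AttenuationTable:
    """Linear attenuation coefficient of one material on a keV grid.

    Attributes
    ----------
    material_name : str
    energies : ndarray
        Strictly increasing photon energies, keV.
    mu_values : ndarray
        Linear attenuation coefficients, 1/cm, all positive.
    """

    material_name: str
    energies: np.ndarray
    mu_values: np.ndarray

    def __post_init__(self) -> None:
        e = np.asarray(self.energies, float)
        m = np.asarray(self.mu_values, float)
        if e.ndim != 1 or e.shape != m.shape:
            raise ValueError("energies and mu_values must be matching 1-D arrays")
        if not np.all(np.diff(e) > 0):
            raise ValueError("energies must be strictly increasing")
        if not np.all(m > 0):
            raise ValueError("all attenuation values must be positive")
        if e[0] > 10.0 or e[-1] < 120.0:
            raise ValueError("table must span at least [10, 120] keV")
        object.__setattr__(self, "energies", e)
        object.__setattr__(self, "mu_values", m)

    def __call__(self, energy) -> np.ndarray:
        return interpolate_mu(self, energy)


@dataclass(frozen=True)
class Spectrum:
    """Relative photon fluence per energy bin, normalized to unit sum."""

    energies: np.ndarray
    weights: np.ndarray

    def __post_init__(self) -> None:
        e = np.asarray(self.energies, float)
        w = np.asarray(self.weights, float)
        if e.shape != w.shape or e.ndim != 1:
            raise ValueError("energies and weights must be matching 1-D arrays")
        if np.any(w < 0):
            raise ValueError("spectrum weights must be non-negative")
        s = w.sum()
        if s <= 0:
            raise ValueError("spectrum has no fluence")
        object.__setattr__(self, "energies", e)
        object.__setattr__(self, "weights", w / s)

    @property
    def mean_energy(self) -> float:
        """Fluence-weighted mean energy, keV."""
        return float(np.sum(self.energies * self.weights))


def load_attenuation_table(material: str) -> AttenuationTable:
    """Load the bundled attenuation table for ``water``, ``bone`` or ``iron``."""
    try:
        fname = _MATERIAL_FILES[material]
    except KeyError:
        raise KeyError(
            f"unknown material {material!r}; available: {sorted(_MATERIAL_FILES)}"
        ) from None
    e, mu = _read_two_column(fname)
    return AttenuationTable(material, e, mu)


def load_attenuation_tables() -> dict[str, AttenuationTable]:
    """All three bundled material tables, keyed by material name."""
    return {m: load_attenuation_table(m) for m in _MATERIAL_FILES}


def load_spectrum(fixture_id: str = "120kvp") -> Spectrum:
    """Load a bundled tube spectrum, normalized, on a 1 keV grid."""
    try:
        fname = _SPECTRUM_FILES[fixture_id]
    except KeyError:
        raise KeyError(
            f"unknown spectrum fixture {fixture_id!r}; available: {sorted(_SPECTRUM_FILES)}"
        ) from None
    e, w = _read_two_column(fname)
    return Spectrum(e, w)


def interpolate_mu(table: AttenuationTable, energy) -> np.ndarray:
    """Log-log linear interpolation of :math:`\\mu(E)`; exact at grid knots.

    Parameters
    ----------
    energy : float or array
        Photon energy in keV; must lie within the table range.
    """
    e = np.asarray(energy, float)
    if np.any(e < table.energies[0]) or np.any(e > table.energies[-1]):
        raise ValueError(
            f"energy outside table range "
            f"[{table.energies[0]}, {table.energies[-1]}] keV for "
            f"{table.material_name}"
        )
    out = np.exp(
        np.interp(np.log(e), np.log(table.energies), np.log(table.mu_values))
    )
    return out if out.ndim else float(out)


def effective_mu(table: AttenuationTable, spectrum: Spectrum) -> float:
    """Spectrum-weighted mean attenuation coefficient, 1/cm.

    Used as the effective monochromatic surrogate, e.g. for the HU
    conversion of reconstructed images.
    """
    return float(np.sum(spectrum.weights * interpolate_mu(table, spectrum.energies)))
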