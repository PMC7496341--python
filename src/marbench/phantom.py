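"""Randomized head phantom with metal implants and a lumpy rotatable inset.

The phantom is a 2-D stack of geometric primitives (disks and Gaussian
"lumps") laid down painter-style:

* outer disk, r = 12 cm, cortical bone (the skull);
* inner disk, r = 10 cm, water (brain);
* rotatable inset, r = 5.9 cm, at 1.05 x water, carrying a lumpy random
  texture and two deep-brain iron implants that rotate with it;
* 12 teeth (r = 0.7 cm, bone by default) on an arc, each with an iron
  filling (r = 0.2 cm);
* two cochlear iron implants (r = 0.6 cm) at (+-11, 0);
* an optional low-contrast disk signal (r = 0.5 cm) at the origin whose
  attenuation is ``a x 1.05 x water``; the signal *replaces* the local
  lumpy background (a removable rod in a physical phantom).

All coordinates are cm, phantom center at (0, 0), x right, y up, inset
rotation counter-clockwise.  Every primitive has an analytic Radon
transform, which serves as the oracle for the discrete projector; the
production path rasterizes per-material maps and projects them discretely,
because the signal's background replacement and the inset-edge truncation
of the lump texture have no closed form.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "DiskPrimitive",
    "GaussianLump",
    "LumpField",
    "PhantomInstance",
    "N_LUMPS",
    "INSET_BASE_SCALE",
    "sample_lump_field",
    "build_phantom",
    "rasterize",
    "pixel_grid",
    "tooth_centers",
    "lump_field_map",
    "analytic_disk_sinogram",
    "analytic_lump_sinogram",
    "analytic_primitive_sinogram",
    "analytic_iron_path_sinogram",
]

N_LUMPS = 20
INSET_BASE_SCALE = 1.05  # inset base material, multiple of water
LUMP_AMPLITUDE_SCALE = 0.015  # peak lump amplitude, multiple of mu_water
LUMP_CONFINEMENT_RADIUS = 4.9  # cm, |r_i| constraint
LUMP_WIDTH_MIN = 0.2  # cm, clamp floor for w_i

OUTER_RADIUS = 12.0
INNER_RADIUS = 10.0
INSET_RADIUS = 5.9
SIGNAL_RADIUS = 0.5
TOOTH_RADIUS = 0.7
FILLING_RADIUS = 0.2
COCHLEAR_RADIUS = 0.6
DBS_RADIUS = 0.3
DBS_CENTERS = ((1.0, -5.1), (-1.0, -5.1))
COCHLEAR_CENTERS = ((11.0, 0.0), (-11.0, 0.0))


def tooth_centers() -> np.ndarray:
    """Centers of the 12 teeth: (7 cos(n pi/11), 9 sin(n pi/11)), n = 0..11."""
    n = np.arange(12)
    return np.column_stack([7.0 * np.cos(n * np.pi / 11), 9.0 * np.sin(n * np.pi / 11)])


@dataclass(frozen=True)
class DiskPrimitive:
    """Homogeneous disk; ``scale`` multiplies the material's mu(E)."""

    center: tuple[float, float]
    radius: float
    material: str
    scale: float = 1.0

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("disk radius must be positive")


@dataclass(frozen=True)
class GaussianLump:
    """One lump of the inset texture: mu_scale * mu_water * exp(-pi |r-c|^2 / w^2)."""

    center: tuple[float, float]
    width: float
    mu_scale: float  # amplitude as a multiple of mu_water

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ValueError("lump width must be positive")
        if float(np.hypot(*self.center)) >= LUMP_CONFINEMENT_RADIUS:
            raise ValueError("lump center must satisfy |r_i| < 4.9 cm")


@dataclass(frozen=True)
class LumpField:
    """A fixed realization of N = 20 lumps, reproducible from its seed."""

    lumps: tuple[GaussianLump, ...]
    seed: int

    def __post_init__(self) -> None:
        if len(self.lumps) != N_LUMPS:
            raise ValueError(f"lump field must contain exactly {N_LUMPS} lumps")


def sample_lump_field(seed: int) -> LumpField:
    """Draw the 20-lump inset texture.

    Per lump: width ``w_i = 1.3 + 2 R`` with R standard normal, clamped to
    >= 0.2 cm; center uniform in the disk ``|r_i| < 4.9`` cm; amplitude
    ``mu_i = 1.5% x mu_water x R'`` with R' uniform on (-1, 1) — percent-scale
    texture, commensurate with the 0-6% contrast of the disk signal it
    provides the background variability for.
    """
    rng = np.random.default_rng(seed)
    lumps = []
    for _ in range(N_LUMPS):
        w = max(1.3 + 2.0 * rng.standard_normal(), LUMP_WIDTH_MIN)
        radius = LUMP_CONFINEMENT_RADIUS * np.sqrt(rng.uniform())
        phi = rng.uniform(0.0, 2.0 * np.pi)
        center = (radius * np.cos(phi), radius * np.sin(phi))
        amp = LUMP_AMPLITUDE_SCALE * rng.uniform(-1.0, 1.0)
        lumps.append(GaussianLump(center, w, amp))
    return LumpField(tuple(lumps), seed)


@dataclass(frozen=True)
class PhantomInstance:
    """One realized phantom: geometry + lump texture + inset angle + signal state."""

    lump_field: LumpField
    inset_angle: float = 0.0
    signal_present: bool = False
    signal_amplitude: float = 1.0
    teeth_material: str = "bone"

    def __post_init__(self) -> None:
        if self.signal_present and not (1.0 <= self.signal_amplitude <= 1.06):
            raise ValueError("signal amplitude must lie in [1.00, 1.06]")

    # --- primitive inventory ---------------------------------------------

    def fixed_primitives(self) -> list[DiskPrimitive]:
        """Angle-independent disks, in painter order."""
        prims = [
            DiskPrimitive((0.0, 0.0), OUTER_RADIUS, "bone"),
            DiskPrimitive((0.0, 0.0), INNER_RADIUS, "water"),
            DiskPrimitive((0.0, 0.0), INSET_RADIUS, "water", INSET_BASE_SCALE),
        ]
        for c in tooth_centers():
            prims.append(DiskPrimitive(tuple(c), TOOTH_RADIUS, self.teeth_material))
        for c in tooth_centers():
            prims.append(DiskPrimitive(tuple(c), FILLING_RADIUS, "iron"))
        for c in COCHLEAR_CENTERS:
            prims.append(DiskPrimitive(c, COCHLEAR_RADIUS, "iron"))
        return prims

    def rotating_primitives(self) -> list[DiskPrimitive]:
        """Deep-brain implants, rotated rigidly with the inset."""
        return [
            DiskPrimitive(_rotate(c, self.inset_angle), DBS_RADIUS, "iron")
            for c in DBS_CENTERS
        ]

    def primitives(self) -> list[DiskPrimitive]:
        prims = self.fixed_primitives() + self.rotating_primitives()
        if self.signal_present:
            prims.append(
                DiskPrimitive(
                    (0.0, 0.0),
                    SIGNAL_RADIUS,
                    "water",
                    self.signal_amplitude * INSET_BASE_SCALE,
                )
            )
        return prims

    def iron_primitives(self) -> list[DiskPrimitive]:
        return [p for p in self.primitives() if p.material == "iron"]


def _rotate(c, angle: float) -> tuple[float, float]:
    ca, sa = np.cos(angle), np.sin(angle)
    return (ca * c[0] - sa * c[1], sa * c[0] + ca * c[1])


def build_phantom(
    inset_angle: float = 0.0,
    signal_present: bool = False,
    signal_amplitude: float = 1.0,
    lump_seed: int = 0,
    lump_field: LumpField | None = None,
    teeth_material: str = "bone",
) -> PhantomInstance:
    """Assemble a phantom instance; the lump field may be passed in to reuse
    one texture across acquisitions (the physical-phantom convention)."""
    if lump_field is None:
        lump_field = sample_lump_field(lump_seed)
    return PhantomInstance(
        lump_field=lump_field,
        inset_angle=float(inset_angle),
        signal_present=bool(signal_present),
        signal_amplitude=float(signal_amplitude),
        teeth_material=teeth_material,
    )


# --- rasterization --------------------------------------------------------


def pixel_grid(grid_size: int, fov: float) -> tuple[np.ndarray, np.ndarray]:
    """Pixel-center coordinates (cm) of a square grid covering ``fov``."""
    d = fov / grid_size
    c = (np.arange(grid_size) - (grid_size - 1) / 2.0) * d
    x, y = np.meshgrid(c, -c)  # row 0 at top (y up)
    return x, y


def lump_field_map(
    field: LumpField,
    grid_size: int,
    fov: float,
    angle: float = 0.0,
    mask_to_inset: bool = False,
) -> np.ndarray:
    """Water-equivalent amplitude map of the (rotated) lump texture."""
    x, y = pixel_grid(grid_size, fov)
    out = np.zeros_like(x)
    for lump in field.lumps:
        cx, cy = _rotate(lump.center, angle)
        r2 = (x - cx) ** 2 + (y - cy) ** 2
        out += lump.mu_scale * np.exp(-np.pi * r2 / lump.width**2)
    if mask_to_inset:
        out[x**2 + y**2 >= INSET_RADIUS**2] = 0.0
    return out


def rasterize(
    phantom: PhantomInstance, grid_size: int, fov: float
) -> dict[str, np.ndarray]:
    """Per-material thickness-weight maps on a ``grid_size``-square grid.

    Returns maps keyed ``water``/``bone``/``iron``; the attenuation map at
    energy E is ``sum_m maps[m] * mu_m(E)``.  The water map carries the
    continuous inset texture (clamped at 0 to stay physical) and the signal
    override; pixel-center sampling with strict Euclidean inside tests.
    """
    if grid_size < 128:
        raise ValueError("grid_size must be >= 128")
    if fov < 2 * OUTER_RADIUS:
        raise ValueError(f"fov must be >= {2 * OUTER_RADIUS} cm to contain the phantom")
    x, y = pixel_grid(grid_size, fov)
    r2 = x**2 + y**2

    maps = {m: np.zeros_like(x) for m in ("water", "bone", "iron")}
    # painter regions, innermost last
    in_outer = r2 < OUTER_RADIUS**2
    in_inner = r2 < INNER_RADIUS**2
    in_inset = r2 < INSET_RADIUS**2

    maps["bone"][in_outer & ~in_inner] = 1.0
    maps["water"][in_inner & ~in_inset] = 1.0
    texture = lump_field_map(phantom.lump_field, grid_size, fov, phantom.inset_angle)
    maps["water"][in_inset] = np.clip(INSET_BASE_SCALE + texture[in_inset], 0.0, None)

    for c in tooth_centers():
        m = (x - c[0]) ** 2 + (y - c[1]) ** 2 < TOOTH_RADIUS**2
        maps["water"][m] = 0.0
        maps["bone"][m] = 0.0
        maps["iron"][m] = 0.0
        maps[phantom.teeth_material][m] = 1.0
    for c in tooth_centers():
        m = (x - c[0]) ** 2 + (y - c[1]) ** 2 < FILLING_RADIUS**2
        maps["bone"][m] = 0.0
        maps["water"][m] = 0.0
        maps["iron"][m] = 1.0
    for c in COCHLEAR_CENTERS:
        m = (x - c[0]) ** 2 + (y - c[1]) ** 2 < COCHLEAR_RADIUS**2
        maps["bone"][m] = 0.0
        maps["iron"][m] = 1.0
    for p in phantom.rotating_primitives():
        m = (x - p.center[0]) ** 2 + (y - p.center[1]) ** 2 < DBS_RADIUS**2
        maps["water"][m] = 0.0
        maps["iron"][m] = 1.0
    if phantom.signal_present:
        m = r2 < SIGNAL_RADIUS**2
        # signal replaces the local background: no lumps, homogeneous disk
        maps["water"][m] = phantom.signal_amplitude * INSET_BASE_SCALE
    return maps


# --- analytic Radon transforms -------------------------------------------


def _signed_distances(geometry, center) -> np.ndarray:
    """d[view, bin] = s - c . (cos theta, sin theta) for the geometry rays."""
    th = geometry.thetas[:, None]
    s = geometry.s_coords[None, :]
    return s - (center[0] * np.cos(th) + center[1] * np.sin(th))


def analytic_disk_sinogram(disk: DiskPrimitive, geometry) -> np.ndarray:
    """Exact chord lengths 2 sqrt(R^2 - d^2) of a disk, cm."""
    d = _signed_distances(geometry, disk.center)
    return 2.0 * np.sqrt(np.clip(disk.radius**2 - d**2, 0.0, None))


def analytic_lump_sinogram(lump: GaussianLump, geometry) -> np.ndarray:
    """Exact Radon transform of one Gaussian lump (water-equivalent cm)."""
    d = _signed_distances(geometry, lump.center)
    return lump.mu_scale * lump.width * np.exp(-np.pi * d**2 / lump.width**2)


def analytic_primitive_sinogram(primitive, geometry) -> np.ndarray:
    """Dispatch on primitive type; disks give path length, lumps give
    water-equivalent amplitude-weighted path."""
    if isinstance(primitive, DiskPrimitive):
        return analytic_disk_sinogram(primitive, geometry)
    if isinstance(primitive, GaussianLump):
        return analytic_lump_sinogram(primitive, geometry)
    raise TypeError(f"no analytic Radon transform for {type(primitive).__name__}")


def analytic_iron_path_sinogram(phantom: PhantomInstance, geometry) -> np.ndarray:
    """Exact total iron path length (cm) per ray; iron disks are disjoint so
    chords add.  This is the ground-truth metal trace used to validate MAR
    segmentation."""
    out = np.zeros((geometry.n_views, geometry.n_bins))
    for p in phantom.iron_primitives():
        out += analytic_disk_sinogram(p, geometry)
    return out
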