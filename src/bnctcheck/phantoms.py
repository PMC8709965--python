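"""Voxel phantoms: water QA tank and a synthetic layered head stand-in.

Conventions: 0-based voxel indices, grid positions are voxel centres,
beam axis is +z entering the phantom front face (water tank) or the
vertex (head). All lengths in mm except densities (g/cm^3) and boron
concentration (µg of 10B per g of tissue).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .materials import MATERIAL_INDEX, MATERIAL_ORDER, TISSUES

AIR = MATERIAL_INDEX["air"]


class PhantomParameterError(ValueError):
    """Invalid phantom construction parameter."""


@dataclass(frozen=True)
class VoxelPhantom:
    """Regular 3D voxel grid with material, density and boron loading.

    Attributes
    ----------
    voxel_size : tuple of 3 floats, mm per axis
    origin : tuple of 3 floats, mm — position of the centre of voxel (0,0,0)
    material_index : int array (nx, ny, nz), indices into MATERIAL_ORDER
    density : float array, g/cm^3 per voxel
    boron_conc : float array, µg 10B per g tissue per voxel (0 in air)
    """

    voxel_size: tuple[float, float, float]
    origin: tuple[float, float, float]
    material_index: np.ndarray
    density: np.ndarray
    boron_conc: np.ndarray

    def __post_init__(self) -> None:
        m = self.material_index
        if m.ndim != 3:
            raise PhantomParameterError("material grid must be 3D")
        if self.density.shape != m.shape or self.boron_conc.shape != m.shape:
            raise PhantomParameterError("grid shapes must match")
        if m.min() < 0 or m.max() >= len(MATERIAL_ORDER):
            raise PhantomParameterError("voxel references undefined material")
        if np.any(self.boron_conc < 0):
            raise PhantomParameterError("negative boron concentration")
        if np.any(self.boron_conc[m == AIR] != 0):
            raise PhantomParameterError("boron concentration must be 0 in air")

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.material_index.shape

    @property
    def voxel_volume_cm3(self) -> float:
        sx, sy, sz = self.voxel_size
        return sx * sy * sz * 1e-3  # mm^3 -> cm^3

    def voxel_centres(self, axis: int) -> np.ndarray:
        """Physical centre coordinates (mm) along one axis."""
        n = self.grid_shape[axis]
        return self.origin[axis] + self.voxel_size[axis] * np.arange(n)

    def extent_mm(self) -> np.ndarray:
        """(3, 2) array of outer grid bounds in mm."""
        lo = np.asarray(self.origin) - 0.5 * np.asarray(self.voxel_size)
        hi = lo + np.asarray(self.grid_shape) * np.asarray(self.voxel_size)
        return np.stack([lo, hi], axis=1)


@dataclass(frozen=True)
class ROIMask:
    """Named boolean region on a phantom grid."""

    name: str
    mask: np.ndarray

    def __post_init__(self) -> None:
        if self.mask.dtype != bool:
            object.__setattr__(self, "mask", self.mask.astype(bool))

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())


def _fill_material(material: np.ndarray, name: str, region: np.ndarray) -> None:
    material[region] = MATERIAL_INDEX[name]


def _densities_for(material: np.ndarray) -> np.ndarray:
    lookup = np.array([TISSUES[n].mass_density for n in MATERIAL_ORDER])
    return lookup[material]


def build_water_qa_phantom(
    voxel_size: float,
    *,
    height_mm: float = 280.0,
    length_mm: float = 210.0,
    width_mm: float = 210.0,
    wall_mm: float = 10.0,
    front_wall_mm: float = 2.0,
    air_margin_mm: float = 0.0,
) -> VoxelPhantom:
    """Rectangular water tank for routine QA.

    The tank is 21 cm x 21 cm in cross section (x, y) and 28 cm deep
    along the beam axis (+z), with 1 cm acrylic walls except a 2 mm
    entrance window. Interior is water; any margin outside is air.

    Parameters
    ----------
    voxel_size : float
        Isotropic voxel edge in mm. Must divide the tank dimensions to
        within one voxel.
    """
    if voxel_size <= 0:
        raise PhantomParameterError("voxel_size must be positive")
    dims = np.array([length_mm, width_mm, height_mm])
    n_inner = dims / voxel_size
    if np.any(np.abs(n_inner - np.round(n_inner)) > 1e-6):
        raise PhantomParameterError(
            f"voxel_size {voxel_size} mm does not divide tank dimensions {dims}"
        )
    margin_vox = int(np.ceil(air_margin_mm / voxel_size))
    shape = tuple(int(np.round(d / voxel_size)) + 2 * margin_vox for d in dims)
    material = np.full(shape, AIR, dtype=np.int16)

    # physical coordinates: beam axis through x = y = 0, tank front at z = 0
    half = (length_mm / 2.0, width_mm / 2.0)
    origin = (
        -half[0] - margin_vox * voxel_size + 0.5 * voxel_size,
        -half[1] - margin_vox * voxel_size + 0.5 * voxel_size,
        -margin_vox * voxel_size + 0.5 * voxel_size,
    )
    centres = [
        origin[a] + voxel_size * np.arange(shape[a]) for a in range(3)
    ]
    X, Y, Z = np.meshgrid(*centres, indexing="ij")

    in_tank = (
        (np.abs(X) < half[0]) & (np.abs(Y) < half[1])
        & (Z > 0) & (Z < height_mm)
    )
    _fill_material(material, "acrylic", in_tank)

    interior = (
        (np.abs(X) < half[0] - wall_mm) & (np.abs(Y) < half[1] - wall_mm)
        & (Z > front_wall_mm) & (Z < height_mm - wall_mm)
    )
    _fill_material(material, "water", interior)

    density = _densities_for(material)
    boron = np.zeros(shape)
    return VoxelPhantom(
        (voxel_size,) * 3, origin, material, density, boron
    )


def build_head_phantom(
    voxel_size: float,
    *,
    outer_radius_mm: float = 80.0,
    skin_mm: float = 3.0,
    skull_mm: float = 7.0,
    brain_shell_mm: float = 45.0,
    tumour_diameter_mm: float = 10.0,
    tumour_depth_mm: float = 40.0,
    air_margin_mm: float = 6.0,
) -> tuple[VoxelPhantom, list[ROIMask]]:
    """Concentric spherical head stand-in with tumour, brain and skin ROIs.

    Layers, outside in: 3 mm skin shell, skull shell, brain shell, soft
    tissue core. A spherical tumour of 1 cm diameter is centred at 4 cm
    depth below the skin surface along the beam axis (+z through the
    vertex, the lowest-z pole). Outer radius, skull and brain shell
    thicknesses are synthetic free parameters, not anatomical claims.

    Returns the phantom plus ROI masks for tumour, brain and skin
    (pairwise disjoint; brain excludes the tumour volume).
    """
    if voxel_size <= 0:
        raise PhantomParameterError("voxel_size must be positive")
    if voxel_size > skin_mm:
        raise PhantomParameterError(
            f"voxel_size {voxel_size} mm too coarse to resolve the "
            f"{skin_mm} mm skin shell"
        )
    R = outer_radius_mm
    half = R + air_margin_mm
    n = int(np.ceil(2 * half / voxel_size))
    shape = (n, n, n)
    origin = (-half + 0.5 * voxel_size,) * 3
    centres = origin[0] + voxel_size * np.arange(n)
    X, Y, Z = np.meshgrid(centres, centres, centres, indexing="ij")
    r = np.sqrt(X**2 + Y**2 + Z**2)

    material = np.full(shape, AIR, dtype=np.int16)
    _fill_material(material, "soft_tissue", r < R)
    _fill_material(material, "brain", r < R - skin_mm - skull_mm)
    _fill_material(
        material, "soft_tissue", r < R - skin_mm - skull_mm - brain_shell_mm
    )
    # shells written after the interior so they are not overwritten
    _fill_material(material, "skin", (r < R) & (r >= R - skin_mm))
    _fill_material(
        material, "bone", (r < R - skin_mm) & (r >= R - skin_mm - skull_mm)
    )

    # tumour centre on the beam axis, tumour_depth_mm below the vertex
    # (the z = -R pole where the beam enters)
    tc = np.array([0.0, 0.0, -R + tumour_depth_mm])
    rt = np.sqrt(X**2 + Y**2 + (Z - tc[2]) ** 2)
    tumour = rt < tumour_diameter_mm / 2
    brain = material == MATERIAL_INDEX["brain"]
    if not np.all(brain[tumour]):
        raise PhantomParameterError(
            "tumour sphere does not fit inside the brain shell"
        )
    _fill_material(material, "tumour", tumour)

    skin = material == MATERIAL_INDEX["skin"]
    brain = material == MATERIAL_INDEX["brain"]

    density = _densities_for(material)
    boron = np.zeros(shape)
    phantom = VoxelPhantom((voxel_size,) * 3, origin, material, density, boron)
    rois = [
        ROIMask("tumour", tumour),
        ROIMask("brain", brain),
        ROIMask("skin", skin),
    ]
    return phantom, rois


def set_boron(phantom: VoxelPhantom, blood_conc: float) -> VoxelPhantom:
    """Load every non-air voxel with a uniform blood-level 10B concentration.

    The tumour/tissue-to-blood concentration ratio is *not* applied here;
    it is a weighting-stage parameter so the stored value is the blood
    level everywhere (µg/g).
    """
    if blood_conc < 0:
        raise PhantomParameterError("boron concentration must be >= 0")
    boron = np.where(phantom.material_index == AIR, 0.0, float(blood_conc))
    return replace(phantom, boron_conc=boron)
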