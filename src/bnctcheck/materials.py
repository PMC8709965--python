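"""Tissue material compositions for voxel-phantom dosimetry.

Compositions are elemental weight fractions per tissue type, the standard
input for multigroup macroscopic cross sections and KERMA factors. The
set covers the tissues of a layered head stand-in (soft tissue, bone,
brain, skin), water for the QA tank, air, and an acrylic tank wall.
"""

from __future__ import annotations

from dataclasses import dataclass
from types import MappingProxyType
from typing import Mapping

_SUM_TOL = 1e-3


class CompositionError(ValueError):
    """Weight fractions invalid (negative or not summing to one)."""


@dataclass(frozen=True)
class MaterialComposition:
    """Elemental composition by mass fraction plus bulk density.

    Attributes
    ----------
    name : str
        Tissue label.
    weight_fractions : Mapping[str, float]
        Element symbol -> mass fraction; residual trace elements may be
        lumped under ``"other"``. Fractions sum to 1 within 1e-3.
    mass_density : float
        Bulk density in g/cm^3.
    """

    name: str
    weight_fractions: Mapping[str, float]
    mass_density: float

    def __post_init__(self) -> None:
        for el, f in self.weight_fractions.items():
            if not (0.0 <= f <= 1.0):
                raise CompositionError(
                    f"material {self.name!r}: fraction of {el} = {f} not in [0, 1]"
                )
        total = sum(self.weight_fractions.values())
        if abs(total - 1.0) > _SUM_TOL:
            raise CompositionError(
                f"material {self.name!r}: weight fractions sum to {total:.4f}, "
                f"deviating from 1 by more than {_SUM_TOL}"
            )
        if self.mass_density < 0:
            raise CompositionError(
                f"material {self.name!r}: negative density {self.mass_density}"
            )
        object.__setattr__(
            self, "weight_fractions", MappingProxyType(dict(self.weight_fractions))
        )

    def fraction(self, element: str) -> float:
        return self.weight_fractions.get(element, 0.0)


def make_material(
    name: str, weight_fractions: Mapping[str, float], mass_density: float
) -> MaterialComposition:
    """Validate and construct a :class:`MaterialComposition`."""
    return MaterialComposition(name, weight_fractions, mass_density)


# Densities: water 1.00 by definition; air 1.205e-3 (20 C); cortical-bone
# class 1.85, brain 1.04, skin 1.09, soft tissue 1.00 (standard reference
# tissue values); PMMA 1.19 for the acrylic tank wall.
TISSUES: dict[str, MaterialComposition] = {
    m.name: m
    for m in (
        make_material(
            "soft_tissue",
            {"H": 0.101, "C": 0.111, "N": 0.026, "O": 0.762},
            1.00,
        ),
        make_material(
            "air",
            {"C": 0.0001, "N": 0.755, "O": 0.232, "other": 0.013},
            1.205e-3,
        ),
        make_material(
            "bone",
            {"H": 0.047, "C": 0.144, "N": 0.042, "O": 0.446, "other": 0.320},
            1.85,
        ),
        make_material(
            "brain",
            {"H": 0.107, "C": 0.145, "N": 0.022, "O": 0.712, "other": 0.014},
            1.04,
        ),
        make_material(
            "skin",
            {"H": 0.100, "C": 0.204, "N": 0.042, "O": 0.645, "other": 0.009},
            1.09,
        ),
        make_material("water", {"H": 0.112, "O": 0.888}, 1.00),
        # PMMA (C5H8O2) tank wall
        make_material(
            "acrylic", {"H": 0.0805, "C": 0.5998, "O": 0.3196}, 1.19
        ),
        # boron-free tumour surrogate: soft-tissue composition, unit density
        make_material(
            "tumour",
            {"H": 0.101, "C": 0.111, "N": 0.026, "O": 0.762},
            1.00,
        ),
    )
}

#: Stable material index used by phantoms (0 is always air).
MATERIAL_ORDER: tuple[str, ...] = (
    "air",
    "water",
    "acrylic",
    "soft_tissue",
    "brain",
    "bone",
    "skin",
    "tumour",
)

MATERIAL_INDEX: dict[str, int] = {name: i for i, name in enumerate(MATERIAL_ORDER)}


def material_by_index(idx: int) -> MaterialComposition:
    return TISSUES[MATERIAL_ORDER[idx]]
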