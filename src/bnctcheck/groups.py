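"""Neutron energy-group structure and thermal/epithermal/fast classification.

BNCT dose reporting partitions the neutron spectrum at 0.53 eV
(thermal/epithermal, the cadmium-cutoff region) and 40 keV
(epithermal/fast), with an upper transport limit of 30 MeV for an
accelerator source. Both band boundaries are inclusive upper bounds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

THERMAL_EPI_BOUNDARY_MEV = 5.3e-7
EPI_FAST_BOUNDARY_MEV = 4e-2
E_MIN_MEV = 1e-20
E_MAX_MEV = 30.0

#: kT at 293 K in MeV, used to split the thermal band into two groups so
#: 1/v behaviour across the thermal range is resolved.
THERMAL_KT_MEV = 2.53e-8

#: Default 5-group boundaries (MeV). Thermal = groups 0-1, epithermal =
#: group 2, fast = groups 3-4, so band reporting is a partition of groups.
DEFAULT_BOUNDARIES = (
    E_MIN_MEV,
    THERMAL_KT_MEV,
    THERMAL_EPI_BOUNDARY_MEV,
    EPI_FAST_BOUNDARY_MEV,
    1.0,
    E_MAX_MEV,
)


class EnergyRangeError(ValueError):
    """Energy outside the supported (0, 30] MeV transport range."""


def classify_energy(energy_mev: float) -> str:
    """Classify a neutron energy into the thermal/epithermal/fast band.

    Upper bounds are inclusive: E = 0.53 eV is thermal, E = 40 keV is
    epithermal.

    Parameters
    ----------
    energy_mev : float
        Neutron energy in MeV; must lie in (0, 30].
    """
    if not (0.0 < energy_mev <= E_MAX_MEV):
        raise EnergyRangeError(
            f"neutron energy {energy_mev!r} MeV outside (0, {E_MAX_MEV}] MeV"
        )
    if energy_mev <= THERMAL_EPI_BOUNDARY_MEV:
        return "thermal"
    if energy_mev <= EPI_FAST_BOUNDARY_MEV:
        return "epithermal"
    return "fast"


@dataclass(frozen=True)
class EnergyGroupStructure:
    """Ordered multigroup structure with band labels per group.

    Groups are indexed from lowest energy upward; group ``g`` spans
    ``(boundaries[g], boundaries[g+1]]``.
    """

    boundaries: tuple[float, ...] = DEFAULT_BOUNDARIES
    #: representative energy per group used to evaluate 1/v cross sections;
    #: defaults to kT for the lowest thermal group, geometric midpoints above.
    representative_energies: tuple[float, ...] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        b = np.asarray(self.boundaries, dtype=float)
        if b.ndim != 1 or b.size < 2:
            raise ValueError("need at least two group boundaries")
        if not np.all(np.diff(b) > 0):
            raise ValueError("group boundaries must be strictly increasing")
        if not (b[0] <= 1e-12 and abs(b[-1] - E_MAX_MEV) < 1e-9):
            raise ValueError(
                "group structure must span 1e-20 to 30 MeV"
            )
        for edge in (THERMAL_EPI_BOUNDARY_MEV, EPI_FAST_BOUNDARY_MEV):
            if not np.any(np.isclose(b, edge, rtol=1e-9)):
                raise ValueError(
                    f"band boundary {edge} MeV must be a group boundary"
                )
        if self.representative_energies is None:
            reps = []
            for lo, hi in zip(b[:-1], b[1:]):
                if lo <= 1e-12:
                    # lowest group: kT rather than the meaningless geometric
                    # midpoint of (1e-20, kT]
                    reps.append(min(hi, THERMAL_KT_MEV) * 0.5)
                else:
                    reps.append(float(np.sqrt(lo * hi)))
            object.__setattr__(self, "representative_energies", tuple(reps))
        elif len(self.representative_energies) != b.size - 1:
            raise ValueError("one representative energy per group required")

    @property
    def n_groups(self) -> int:
        return len(self.boundaries) - 1

    @property
    def labels(self) -> tuple[str, ...]:
        """Band label of each group, by its upper boundary."""
        return tuple(classify_energy(hi) for hi in self.boundaries[1:])

    def group_of(self, energy_mev: float) -> int:
        """Index of the group containing ``energy_mev`` (upper-inclusive)."""
        if not (self.boundaries[0] < energy_mev <= self.boundaries[-1]):
            raise EnergyRangeError(
                f"energy {energy_mev} MeV outside group structure"
            )
        idx = int(np.searchsorted(self.boundaries, energy_mev, side="left")) - 1
        return max(idx, 0)

    def band_groups(self, label: str) -> list[int]:
        """Group indices belonging to a thermal/epithermal/fast band."""
        if label not in ("thermal", "epithermal", "fast"):
            raise ValueError(f"unknown band label {label!r}")
        return [g for g, lab in enumerate(self.labels) if lab == label]


DEFAULT_GROUPS = EnergyGroupStructure()
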