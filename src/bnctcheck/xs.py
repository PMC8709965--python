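"""Embedded few-group cross-section library.

Macroscopic cross sections are computed from elemental compositions and
standard 2200 m/s microscopic constants (1/v absorption for 10B and
14N(n,p), hydrogen-dominated scattering, H(n,gamma) -> 2.22 MeV capture
photon). Group transfer uses a free-gas downscatter approximation driven
by the mean logarithmic energy decrement, so thermalization in hydrogenous
media is qualitatively right without an evaluated-data file. Full
continuous-energy libraries and bound thermal-scattering laws are out of
scope; this library exists to exercise the transport/dosimetry chain, not
to replace an evaluated library.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .groups import DEFAULT_GROUPS, EnergyGroupStructure
from .materials import MATERIAL_ORDER, TISSUES
from .phantoms import VoxelPhantom

AVOGADRO = 6.02214076e23
BARN = 1e-24  # cm^2
EV_REF_MEV = 2.53e-8  # 2200 m/s reference energy
MEV_TO_J = 1.602176634e-13

#: 10B(n,alpha)7Li: 2200 m/s cross section (barns) and mean charged-particle
#: kinetic energy deposited locally per capture (MeV, 94% branch to the
#: 478 keV excited state).
SIGMA_B10_TH = 3837.0
E_B10_MEV = 2.33

#: 14N(n,p)14C: 2200 m/s cross section and Q-value carried by the proton
#: and recoil (MeV).
SIGMA_N14_NP_TH = 1.83
E_N14_MEV = 0.626

#: H(n,gamma)D thermal capture and its photon line.
SIGMA_H_CAPTURE_TH = 0.332
H_CAPTURE_PHOTON_MEV = 2.22

#: micrograms of 10B per gram -> atoms per gram
B10_ATOMS_PER_UG = 1e-6 / 10.013 * AVOGADRO

# Elemental data: atomic mass, thermal (2200 m/s) absorption (barns, 1/v
# scaled to other groups), and per-group elastic scattering (barns) on the
# default 5-group structure (thermal, thermal, epithermal, 0.04-1 MeV,
# 1-30 MeV). Scattering values are representative free-atom magnitudes;
# the thermal H value is raised toward the bound value so hydrogenous
# moderation is not badly underestimated.
_ELEMENTS: dict[str, dict] = {
    "H": {"A": 1.008, "sigma_a_th": SIGMA_H_CAPTURE_TH,
          "sigma_s": (30.0, 25.0, 20.0, 6.0, 1.8)},
    "C": {"A": 12.011, "sigma_a_th": 0.0035,
          "sigma_s": (4.7, 4.7, 4.7, 3.5, 1.6)},
    "N": {"A": 14.007, "sigma_a_th": SIGMA_N14_NP_TH + 0.08,
          "sigma_s": (10.0, 10.0, 9.0, 3.0, 1.5)},
    "O": {"A": 15.999, "sigma_a_th": 0.00019,
          "sigma_s": (4.2, 4.2, 3.8, 3.0, 1.5)},
    # lumped trace constituents (Na/P/S/Cl/K/Ca/Ar...): generic medium-Z
    "other": {"A": 31.0, "sigma_a_th": 0.5,
              "sigma_s": (3.0, 3.0, 3.0, 2.5, 1.5)},
}

#: photon mass attenuation (cm^2/g) near the 2.22 MeV capture line; bone
#: slightly lower per gram, air close to water.
_PHOTON_MU_RHO = {"default": 0.0464, "bone": 0.0445, "air": 0.0437}


def _one_over_v(sigma_th: float, e_mev: float) -> float:
    return sigma_th * np.sqrt(EV_REF_MEV / e_mev)


def _xi(A: float) -> float:
    """Mean logarithmic energy decrement for elastic scattering off mass A."""
    if A <= 1.0001:
        return 1.0
    a = ((A - 1.0) / (A + 1.0)) ** 2
    return 1.0 + a * np.log(a) / (1.0 - a)


@dataclass(frozen=True)
class CrossSectionLibrary:
    """Per-material, per-group macroscopic data (normalized to unit density).

    All neutron arrays are cm^2/g (multiply by voxel density for cm^-1);
    ``transfer[m, g]`` is the conditional outgoing-group distribution given
    a scattering event in group ``g`` (rows sum to 1); ``capture_gamma[m, g]``
    is the H-capture macroscopic cross section (cm^2/g), i.e. the part of
    absorption that emits a 2.22 MeV photon.
    """

    groups: EnergyGroupStructure
    material_names: tuple[str, ...]
    sigma_a: np.ndarray      # (M, G) cm^2/g, boron-free
    sigma_s: np.ndarray      # (M, G) cm^2/g
    transfer: np.ndarray     # (M, G, G) conditional on scattering
    capture_gamma: np.ndarray  # (M, G) cm^2/g subset of sigma_a
    sigma_b_unit: np.ndarray   # (G,) cm^2/g per (µg 10B / g)
    photon_mu: np.ndarray      # (M,) cm^2/g attenuation at the capture line
    photon_energy_mev: float = H_CAPTURE_PHOTON_MEV

    def __post_init__(self) -> None:
        if np.any(self.sigma_a < 0) or np.any(self.sigma_s < 0):
            raise ValueError("negative cross section")
        if np.any(self.capture_gamma - self.sigma_a > 1e-12):
            raise ValueError("capture-photon channel exceeds absorption")
        rows = self.transfer.sum(axis=2)
        scat = self.sigma_s > 0
        if np.any(np.abs(rows[scat] - 1.0) > 1e-9):
            raise ValueError("transfer rows must sum to 1 where scattering > 0")

    @property
    def sigma_t(self) -> np.ndarray:
        return self.sigma_a + self.sigma_s

    # ---- voxel-grid expansion -------------------------------------------
    def macroscopic_grids(self, phantom: VoxelPhantom) -> dict[str, np.ndarray]:
        """Expand to per-voxel macroscopic grids (cm^-1) including boron."""
        m = phantom.material_index
        rho = phantom.density
        sig_a = (self.sigma_a[m] + phantom.boron_conc[..., None]
                 * self.sigma_b_unit) * rho[..., None]
        sig_s = self.sigma_s[m] * rho[..., None]
        cap_g = self.capture_gamma[m] * rho[..., None]
        with np.errstate(invalid="ignore", divide="ignore"):
            p_gamma = np.where(sig_a > 0, cap_g / np.maximum(sig_a, 1e-300), 0.0)
        return {
            "sigma_a": sig_a,
            "sigma_s": sig_s,
            "sigma_t": sig_a + sig_s,
            "p_capture_gamma": p_gamma,
            "photon_mu": self.photon_mu[m] * rho,
        }


def _downscatter_transfer(groups: EnergyGroupStructure, xi_mat: float) -> np.ndarray:
    """Adjacent-group downscatter from the mean lethargy gain per collision.

    The probability of leaving group g toward the next lower-energy group
    is xi / delta_u(g) (capped at 1); the lowest group scatters in-group
    (no upscatter — a free-gas simplification).
    """
    G = groups.n_groups
    T = np.zeros((G, G))
    b = np.asarray(groups.boundaries)
    for g in range(G):
        if g == 0:
            T[0, 0] = 1.0
            continue
        du = np.log(b[g + 1] / max(b[g], 1e-30))
        p_down = min(1.0, xi_mat / du) if du > 0 else 1.0
        T[g, g - 1] = p_down
        T[g, g] = 1.0 - p_down
    return T


def standard_library(
    groups: EnergyGroupStructure = DEFAULT_GROUPS,
) -> CrossSectionLibrary:
    """Build the default library for all defined tissue materials."""
    G = groups.n_groups
    reps = np.asarray(groups.representative_energies)
    names = MATERIAL_ORDER
    M = len(names)
    sigma_a = np.zeros((M, G))
    sigma_s = np.zeros((M, G))
    capture_gamma = np.zeros((M, G))
    transfer = np.zeros((M, G, G))
    photon_mu = np.zeros(M)

    for mi, name in enumerate(names):
        comp = TISSUES[name]
        xi_num = xi_den = 0.0
        for el, w in comp.weight_fractions.items():
            data = _ELEMENTS[el if el in _ELEMENTS else "other"]
            n_per_g = w / data["A"] * AVOGADRO
            for g in range(G):
                sa = _one_over_v(data["sigma_a_th"], reps[g]) * BARN * n_per_g
                ss = data["sigma_s"][g] * BARN * n_per_g
                sigma_a[mi, g] += sa
                sigma_s[mi, g] += ss
                if el == "H":
                    capture_gamma[mi, g] += (
                        _one_over_v(SIGMA_H_CAPTURE_TH, reps[g]) * BARN * n_per_g
                    )
            xi_num += n_per_g * data["sigma_s"][2] * _xi(data["A"])
            xi_den += n_per_g * data["sigma_s"][2]
        xi_mat = xi_num / xi_den if xi_den > 0 else 0.1
        transfer[mi] = _downscatter_transfer(groups, xi_mat)
        photon_mu[mi] = _PHOTON_MU_RHO.get(name, _PHOTON_MU_RHO["default"])

    sigma_b_unit = np.array(
        [_one_over_v(SIGMA_B10_TH, e) * BARN * B10_ATOMS_PER_UG for e in reps]
    )
    return CrossSectionLibrary(
        groups=groups,
        material_names=names,
        sigma_a=sigma_a,
        sigma_s=sigma_s,
        transfer=transfer,
        capture_gamma=capture_gamma,
        sigma_b_unit=sigma_b_unit,
        photon_mu=photon_mu,
    )


def uniform_library(
    sigma_a_cm2_per_g: float,
    sigma_s_cm2_per_g: float = 0.0,
    *,
    groups: EnergyGroupStructure = DEFAULT_GROUPS,
    in_group_scatter: bool = True,
    capture_photon: bool = False,
) -> CrossSectionLibrary:
    """Material- and group-independent library for analytic benchmarks.

    Every material gets the same absorption/scattering per unit density,
    no boron sensitivity, and (by default) in-group isotropic scattering —
    the configuration for which closed-form slab and infinite-medium
    solutions exist.
    """
    G = groups.n_groups
    M = len(MATERIAL_ORDER)
    sigma_a = np.full((M, G), float(sigma_a_cm2_per_g))
    sigma_s = np.full((M, G), float(sigma_s_cm2_per_g))
    transfer = np.zeros((M, G, G))
    if in_group_scatter:
        for g in range(G):
            transfer[:, g, g] = 1.0
    else:
        for mi in range(M):
            transfer[mi] = _downscatter_transfer(groups, 1.0)
    cap = sigma_a.copy() if capture_photon else np.zeros((M, G))
    return CrossSectionLibrary(
        groups=groups,
        material_names=MATERIAL_ORDER,
        sigma_a=sigma_a,
        sigma_s=sigma_s,
        transfer=transfer,
        capture_gamma=cap,
        sigma_b_unit=np.zeros(G),
        photon_mu=np.full(M, 0.05),
    )
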