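"""Parametric planar neutron/photon source with circular collimation.

Stands in for an accelerator beam-shaping assembly: instead of modelling
moderation physics, the source emits from a plane with a prescribed
multigroup spectrum (Maxwellian thermal + 1/E epithermal + exponential
fast tail), a binned forward-peaked angular distribution, and an optional
photon contamination fraction. The collimator is treated as a perfect
aperture of 10, 12 or 15 cm diameter (the clinical set).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import integrate

from .groups import DEFAULT_GROUPS, EnergyGroupStructure

_NORM_TOL = 1e-9


class BeamParameterError(ValueError):
    pass


@dataclass(frozen=True)
class CollimatorField:
    """Circular field on the source plane. Diameter in cm, centre in mm."""

    diameter_cm: float
    centre_mm: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if self.diameter_cm <= 0:
            raise BeamParameterError("collimator diameter must be positive")

    @property
    def radius_mm(self) -> float:
        return self.diameter_cm * 10.0 / 2.0


@dataclass(frozen=True)
class BeamSpectrum:
    """Discretized emission spectrum on an energy-group structure.

    ``group_probabilities`` are neutron emission probabilities per group
    (sum to 1); ``angular_bins``/``angular_probabilities`` give the
    cosine-binned direction distribution; photons are emitted with
    probability ``gamma_fraction`` (per emitted particle) at a single
    contamination line energy.
    """

    groups: EnergyGroupStructure
    group_probabilities: np.ndarray
    angular_cosine_edges: np.ndarray
    angular_probabilities: np.ndarray
    gamma_fraction: float = 0.0
    gamma_energy_mev: float = 2.2

    def __post_init__(self) -> None:
        p = np.asarray(self.group_probabilities, dtype=float)
        a = np.asarray(self.angular_probabilities, dtype=float)
        if p.size != self.groups.n_groups:
            raise BeamParameterError("one probability per energy group required")
        if np.any(p < 0) or abs(p.sum() - 1.0) > _NORM_TOL:
            raise BeamParameterError("group probabilities must sum to 1")
        if np.any(a < 0) or abs(a.sum() - 1.0) > _NORM_TOL:
            raise BeamParameterError("angular probabilities must sum to 1")
        edges = np.asarray(self.angular_cosine_edges, dtype=float)
        if edges.size != a.size + 1 or not np.all(np.diff(edges) > 0):
            raise BeamParameterError("cosine bin edges must be increasing, n+1")
        if not (0.0 <= self.gamma_fraction < 1.0):
            raise BeamParameterError("gamma_fraction must be in [0, 1)")
        object.__setattr__(self, "group_probabilities", p)
        object.__setattr__(self, "angular_probabilities", a)
        object.__setattr__(self, "angular_cosine_edges", edges)


def _maxwellian_group_weights(groups: EnergyGroupStructure, kT: float) -> np.ndarray:
    """Integrate the thermal Maxwellian flux density over each group."""

    def pdf(e: float) -> float:
        return np.sqrt(e) * np.exp(-e / kT)

    w = np.zeros(groups.n_groups)
    for g, (lo, hi) in enumerate(
        zip(groups.boundaries[:-1], groups.boundaries[1:])
    ):
        if groups.labels[g] != "thermal":
            continue
        val, _ = integrate.quad(pdf, max(lo, 1e-12), min(hi, 40 * kT))
        w[g] = val
    return w


def forward_peaked_cosine_bins(n_bins: int = 51) -> tuple[np.ndarray, np.ndarray]:
    """Equal-cosine bins on [0, 1] weighted by cos^2 (forward-peaked)."""
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    mids = 0.5 * (edges[:-1] + edges[1:])
    w = mids**2
    return edges, w / w.sum()


def build_reference_spectrum(
    thermal_frac: float,
    epi_frac: float,
    fast_frac: float,
    gamma_fraction: float = 0.0,
    *,
    groups: EnergyGroupStructure = DEFAULT_GROUPS,
    kT_mev: float = 2.53e-8,
    fast_tail_mev: float = 1.0,
    n_angular_bins: int = 51,
) -> BeamSpectrum:
    """Build the parametric source spectrum from band fractions.

    The thermal component is a Maxwellian at 293 K, the epithermal
    component follows 1/E within its band (so its group weights are
    proportional to the lethargy width), and the fast component is a
    decaying exponential tail exp(-E / fast_tail_mev). Neutron band
    fractions must sum to 1.
    """
    fracs = np.array([thermal_frac, epi_frac, fast_frac], dtype=float)
    if np.any(fracs < 0):
        raise BeamParameterError("band fractions must be non-negative")
    if abs(fracs.sum() - 1.0) > _NORM_TOL:
        raise BeamParameterError(
            f"neutron band fractions sum to {fracs.sum()}, expected 1"
        )

    p = np.zeros(groups.n_groups)
    th = _maxwellian_group_weights(groups, kT_mev)
    if th.sum() > 0:
        p += thermal_frac * th / th.sum()

    epi = np.zeros(groups.n_groups)
    for g in groups.band_groups("epithermal"):
        lo, hi = groups.boundaries[g], groups.boundaries[g + 1]
        epi[g] = np.log(hi / lo)  # integral of 1/E
    if epi.sum() > 0:
        p += epi_frac * epi / epi.sum()

    fast = np.zeros(groups.n_groups)
    for g in groups.band_groups("fast"):
        lo, hi = groups.boundaries[g], groups.boundaries[g + 1]
        fast[g] = np.exp(-lo / fast_tail_mev) - np.exp(-hi / fast_tail_mev)
    if fast.sum() > 0:
        p += fast_frac * fast / fast.sum()

    p = p / p.sum()
    edges, w = forward_peaked_cosine_bins(n_angular_bins)
    return BeamSpectrum(
        groups=groups,
        group_probabilities=p,
        angular_cosine_edges=edges,
        angular_probabilities=w,
        gamma_fraction=gamma_fraction,
    )


def sample_particles(
    spectrum: BeamSpectrum,
    field: CollimatorField,
    n: int,
    rng: np.random.Generator,
    z_mm: float = 0.0,
) -> dict[str, np.ndarray]:
    """Sample ``n`` source particles from the planar collimated source.

    Positions are uniform on the collimator disk at plane z = ``z_mm``;
    the polar cosine is drawn from the binned angular distribution
    (uniform within a bin), azimuth uniform; neutron energies are sampled
    log-uniformly within their group (exactly 1/E inside a group, which
    matches the epithermal shape). Photons carry the contamination line
    energy and a group index of -1.

    Returns arrays: position (n, 3) mm, direction (n, 3) unit vectors,
    energy_mev (n,), group (n,), is_photon (n,) bool.
    """
    # uniform on disk: r = R sqrt(u)
    u = rng.random(n)
    r = field.radius_mm * np.sqrt(u)
    phi = rng.uniform(0, 2 * np.pi, n)
    pos = np.empty((n, 3))
    pos[:, 0] = field.centre_mm[0] + r * np.cos(phi)
    pos[:, 1] = field.centre_mm[1] + r * np.sin(phi)
    pos[:, 2] = z_mm

    bins = rng.choice(
        spectrum.angular_probabilities.size, size=n, p=spectrum.angular_probabilities
    )
    lo = spectrum.angular_cosine_edges[bins]
    hi = spectrum.angular_cosine_edges[bins + 1]
    mu = lo + (hi - lo) * rng.random(n)
    psi = rng.uniform(0, 2 * np.pi, n)
    s = np.sqrt(np.maximum(0.0, 1.0 - mu**2))
    direction = np.column_stack([s * np.cos(psi), s * np.sin(psi), mu])

    is_photon = rng.random(n) < spectrum.gamma_fraction
    group = rng.choice(
        spectrum.groups.n_groups, size=n, p=spectrum.group_probabilities
    )
    b = np.asarray(spectrum.groups.boundaries)
    elo, ehi = b[group], b[group + 1]
    energy = np.exp(
        np.log(elo) + (np.log(ehi) - np.log(elo)) * rng.random(n)
    )
    energy[is_photon] = spectrum.gamma_energy_mev
    group = group.astype(np.int64)
    group[is_photon] = -1
    return {
        "position": pos,
        "direction": direction,
        "energy_mev": energy,
        "group": group,
        "is_photon": is_photon,
    }


def sample_particle(
    spectrum: BeamSpectrum, field: CollimatorField, rng: np.random.Generator
) -> dict[str, np.ndarray]:
    """Single-particle convenience wrapper around :func:`sample_particles`."""
    batch = sample_particles(spectrum, field, 1, rng)
    return {k: v[0] for k, v in batch.items()}
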