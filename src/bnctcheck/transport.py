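"""Multigroup Monte Carlo neutron/photon transport in voxel phantoms.

Neutrons are tracked with Woodcock (delta) tracking against a per-group
majorant cross section, so no voxel-boundary geometry code is needed:
flights are sampled against the majorant, collisions are accepted as real
with probability sigma_t(voxel)/sigma_majorant, real collisions scatter
isotropically with multigroup transfer or absorb (optionally emitting a
2.22 MeV hydrogen-capture photon), and photons are transported with
attenuation-only physics. Flux is scored with the collision-at-majorant
estimator — a score of 1/sigma_majorant at every (real or virtual)
collision — which is the standard unbiased estimator of track-length flux
under delta tracking. Statistics are batch based: the relative error of a
tally is the standard deviation of the batch means divided by
(grand mean * sqrt(n_batches)).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .beam import BeamSpectrum, CollimatorField, sample_particles
from .phantoms import VoxelPhantom
from .xs import CrossSectionLibrary, standard_library

_MM_PER_CM = 10.0


def _majorant_floor(phantom: VoxelPhantom) -> float:
    """Scoring floor for the delta-tracking majorant (cm^-1).

    Extra virtual collisions are physically inert but set the spatial
    scoring density of the collision-at-majorant estimator, so the floor
    targets about one score per two voxel widths even in void/air.
    """
    return 0.5 / (min(phantom.voxel_size) / _MM_PER_CM)


class TransportParameterError(ValueError):
    pass


@dataclass
class FluxTally:
    """Per-voxel, per-group track-length flux with batch statistics.

    ``flux`` is neutron flux (cm^-2 per source particle) of shape
    (nx, ny, nz, n_groups); ``photon_flux`` is the capture/contamination
    photon flux on the same grid. ``relative_error`` entries where the
    mean is zero are NaN (flagged undefined, never silently zero).
    """

    phantom: VoxelPhantom
    groups: "object"
    flux: np.ndarray
    photon_flux: np.ndarray
    relative_error: np.ndarray
    photon_relative_error: np.ndarray
    n_histories: int
    n_batches: int
    seed: int
    balance: dict[str, int] = field(default_factory=dict)

    def band_flux(self, label: str) -> np.ndarray:
        """Sum neutron flux over the groups of one reporting band."""
        idx = self.groups.band_groups(label)
        return self.flux[..., idx].sum(axis=-1)


def relative_error(batch_means: np.ndarray, axis: int = 0) -> np.ndarray:
    """Relative error of a tally: sd of batch means / (mean * sqrt(n)).

    Entries with zero mean are undefined and returned as NaN.
    """
    bm = np.asarray(batch_means, dtype=float)
    n = bm.shape[axis]
    if n < 2:
        raise TransportParameterError("need at least 2 batches")
    mean = bm.mean(axis=axis)
    sd = bm.std(axis=axis, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        rel = sd / (mean * np.sqrt(n))
    return np.where(mean == 0, np.nan, rel)


def _rel_err_from_moments(s1: np.ndarray, s2: np.ndarray, n: int) -> np.ndarray:
    """Relative error from running sum/sum-of-squares of batch means."""
    mean = s1 / n
    var = np.maximum(s2 / n - mean**2, 0.0) * n / (n - 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        rel = np.sqrt(var) / (mean * np.sqrt(n))
    return np.where(mean == 0, np.nan, rel)


def _voxel_indices(
    pos: np.ndarray, phantom: VoxelPhantom
) -> tuple[np.ndarray, np.ndarray]:
    """Map positions (mm) to voxel indices; second return is in-grid mask."""
    origin = np.asarray(phantom.origin)
    size = np.asarray(phantom.voxel_size)
    idx = np.floor((pos - origin + 0.5 * size) / size).astype(np.int64)
    shape = np.asarray(phantom.grid_shape)
    inside = np.all((idx >= 0) & (idx < shape), axis=1)
    return idx, inside


def _isotropic_directions(n: int, rng: np.random.Generator) -> np.ndarray:
    mu = rng.uniform(-1.0, 1.0, n)
    phi = rng.uniform(0.0, 2 * np.pi, n)
    s = np.sqrt(1.0 - mu**2)
    return np.column_stack([s * np.cos(phi), s * np.sin(phi), mu])


def _track_photons(
    pos: np.ndarray,
    direction: np.ndarray,
    phantom: VoxelPhantom,
    mu_grid: np.ndarray,
    tally: np.ndarray,
    rng: np.random.Generator,
) -> int:
    """Attenuation-only photon transport with delta tracking; returns #absorbed."""
    if pos.shape[0] == 0:
        return 0
    mu_maj = max(float(mu_grid.max()), _majorant_floor(phantom))
    absorbed = 0
    pos = pos.copy()
    direction = direction.copy()
    while pos.shape[0] > 0:
        d_mm = rng.exponential(1.0, pos.shape[0]) / mu_maj * _MM_PER_CM
        pos += d_mm[:, None] * direction
        idx, inside = _voxel_indices(pos, phantom)
        pos, direction, idx = pos[inside], direction[inside], idx[inside]
        if pos.shape[0] == 0:
            break
        ix, iy, iz = idx.T
        np.add.at(tally, (ix, iy, iz), 1.0 / mu_maj)
        real = rng.random(pos.shape[0]) < mu_grid[ix, iy, iz] / mu_maj
        absorbed += int(real.sum())
        keep = ~real
        pos, direction = pos[keep], direction[keep]
    return absorbed


def run_transport(
    phantom: VoxelPhantom,
    spectrum: BeamSpectrum,
    field_: CollimatorField | None,
    n_histories: int,
    n_batches: int = 10,
    seed: int = 0,
    *,
    library: CrossSectionLibrary | None = None,
    source: str = "planar",
    max_collisions: int = 10_000,
) -> FluxTally:
    """Run the multigroup Monte Carlo simulation and tally per-voxel flux.

    Parameters
    ----------
    field_ : CollimatorField or None
        Circular field on the z = grid-entry plane for the planar source;
        ignored (may be None) for ``source="volume"``.
    source : {"planar", "volume"}
        "planar" emits from the collimated plane in front of the grid;
        "volume" emits uniformly over the grid volume with isotropic
        directions (for infinite-medium benchmarks).

    Every launched neutron terminates by absorption or leakage; the
    balance counts are recorded per run in ``FluxTally.balance``.
    """
    if n_histories < n_batches or n_batches < 2:
        raise TransportParameterError("need n_histories >= n_batches >= 2")
    if phantom.material_index.size == 0:
        raise TransportParameterError("empty phantom")
    if source == "planar" and field_ is None:
        raise TransportParameterError("planar source requires a collimator field")
    library = library or standard_library(spectrum.groups)
    if library.groups.n_groups != spectrum.groups.n_groups:
        raise TransportParameterError("library/spectrum group mismatch")

    grids = library.macroscopic_grids(phantom)
    sig_t, sig_a = grids["sigma_t"], grids["sigma_a"]
    p_cap_gamma = grids["p_capture_gamma"]
    mu_grid = grids["photon_mu"]
    G = spectrum.groups.n_groups
    sig_maj = np.maximum(sig_t.reshape(-1, G).max(axis=0), _majorant_floor(phantom))
    transfer_cum = np.cumsum(library.transfer, axis=2)
    mats = phantom.material_index

    shape = phantom.grid_shape
    vol = phantom.voxel_volume_cm3
    s1 = np.zeros(shape + (G,))
    s2 = np.zeros(shape + (G,))
    p1 = np.zeros(shape)
    p2 = np.zeros(shape)
    rng = np.random.default_rng(seed)
    n_launched = n_absorbed = n_leaked = 0
    entry_z = phantom.extent_mm()[2, 0]

    per_batch = n_histories // n_batches
    for _ in range(n_batches):
        tally = np.zeros(shape + (G,))
        ptally = np.zeros(shape)

        if source == "planar":
            src = sample_particles(spectrum, field_, per_batch, rng, z_mm=entry_z)
            pos, direction = src["position"], src["direction"]
            group, is_photon = src["group"], src["is_photon"]
        elif source == "volume":
            lo, hi = phantom.extent_mm().T
            pos = rng.uniform(lo, hi, size=(per_batch, 3))
            direction = _isotropic_directions(per_batch, rng)
            group = rng.choice(G, size=per_batch, p=spectrum.group_probabilities)
            is_photon = np.zeros(per_batch, dtype=bool)
        else:
            raise TransportParameterError(f"unknown source mode {source!r}")

        photon_bank_pos = [pos[is_photon]]
        photon_bank_dir = [direction[is_photon]]
        pos, direction, group = pos[~is_photon], direction[~is_photon], group[~is_photon]
        n_neutrons = pos.shape[0]
        n_launched += n_neutrons
        batch_absorbed = batch_leaked = 0

        for _step in range(max_collisions):
            n_alive = pos.shape[0]
            if n_alive == 0:
                break
            d_mm = rng.exponential(1.0, n_alive) / sig_maj[group] * _MM_PER_CM
            pos += d_mm[:, None] * direction
            idx, inside = _voxel_indices(pos, phantom)
            batch_leaked += int((~inside).sum())
            pos, direction, group, idx = (
                pos[inside], direction[inside], group[inside], idx[inside]
            )
            if pos.shape[0] == 0:
                break
            ix, iy, iz = idx.T
            np.add.at(tally, (ix, iy, iz, group), 1.0 / sig_maj[group])

            u = rng.random(pos.shape[0])
            st = sig_t[ix, iy, iz, group]
            real = u * sig_maj[group] < st
            if not np.any(real):
                continue
            sa = sig_a[ix, iy, iz, group]
            absorb = real & (rng.random(pos.shape[0]) * np.maximum(st, 1e-300) < sa)
            scatter = real & ~absorb

            if np.any(absorb):
                batch_absorbed += int(absorb.sum())
                pg = p_cap_gamma[ix[absorb], iy[absorb], iz[absorb], group[absorb]]
                emit = rng.random(pg.size) < pg
                if np.any(emit):
                    photon_bank_pos.append(pos[absorb][emit].copy())
                    photon_bank_dir.append(
                        _isotropic_directions(int(emit.sum()), rng)
                    )

            if np.any(scatter):
                rows = transfer_cum[mats[ix[scatter], iy[scatter], iz[scatter]],
                                    group[scatter]]
                group[scatter] = (
                    rows < rng.random(int(scatter.sum()))[:, None]
                ).sum(axis=1)
                direction[scatter] = _isotropic_directions(int(scatter.sum()), rng)

            keep = ~absorb
            pos, direction, group = pos[keep], direction[keep], group[keep]
        else:
            # histories exceeding the collision cap are counted as lost
            batch_leaked += pos.shape[0]

        n_absorbed += batch_absorbed
        n_leaked += batch_leaked

        ppos = np.concatenate(photon_bank_pos, axis=0)
        pdir = np.concatenate(photon_bank_dir, axis=0)
        _track_photons(ppos, pdir, phantom, mu_grid, ptally, rng)

        bm = tally / (per_batch * vol)
        s1 += bm
        s2 += bm**2
        pbm = ptally / (per_batch * vol)
        p1 += pbm
        p2 += pbm**2

    nb = n_batches
    tally_obj = FluxTally(
        phantom=phantom,
        groups=spectrum.groups,
        flux=s1 / nb,
        photon_flux=p1 / nb,
        relative_error=_rel_err_from_moments(s1, s2, nb),
        photon_relative_error=_rel_err_from_moments(p1, p2, nb),
        n_histories=per_batch * nb,
        n_batches=nb,
        seed=seed,
        balance={
            "launched": n_launched,
            "absorbed": n_absorbed,
            "leaked": n_leaked,
        },
    )
    return tally_obj


def depth_profile(
    tally: FluxTally, group_label: str, axis: int = 2
) -> dict[str, np.ndarray]:
    """Central-column flux vs depth for a reporting band or the photon field.

    Returns depth coordinates (mm), the flux profile and its propagated
    relative error along the voxel column through the beam axis.
    """
    if group_label == "photon":
        f = tally.photon_flux
        r = tally.photon_relative_error
    elif group_label in ("thermal", "epithermal", "fast"):
        idx = tally.groups.band_groups(group_label)
        f = tally.flux[..., idx].sum(axis=-1)
        # combine group relative errors in quadrature, flux weighted
        var = np.zeros_like(f)
        for g in idx:
            re = np.nan_to_num(tally.relative_error[..., g])
            var += (tally.flux[..., g] * re) ** 2
        with np.errstate(invalid="ignore", divide="ignore"):
            r = np.where(f > 0, np.sqrt(var) / np.maximum(f, 1e-300), np.nan)
    else:
        raise TransportParameterError(f"unknown group label {group_label!r}")

    shape = tally.phantom.grid_shape
    centre = [s // 2 for s in shape]
    sl = [centre[0], centre[1], centre[2]]
    sl[axis] = slice(None)
    profile = f[tuple(sl)]
    rel = r[tuple(sl)]
    depth = tally.phantom.voxel_centres(axis)
    return {"depth_mm": depth, "flux": profile, "relative_error": rel}
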