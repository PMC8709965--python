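"""Shared fixtures: small phantoms, beams and independent oracles."""

from __future__ import annotations

import numpy as np
import pytest

import bnctcheck as bc
from bnctcheck.groups import DEFAULT_GROUPS


@pytest.fixture(scope="session")
def water_phantom_coarse():
    return bc.build_water_qa_phantom(10.0)


@pytest.fixture(scope="session")
def head_phantom_2mm():
    return bc.build_head_phantom(2.0)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def axial_monogroup_spectrum():
    """Pencil beam: all emission in the epithermal group, cosine = 1."""
    return bc.BeamSpectrum(
        DEFAULT_GROUPS,
        np.array([0.0, 0.0, 1.0, 0.0, 0.0]),
        np.array([1.0 - 1e-9, 1.0]),
        np.array([1.0]),
    )


@pytest.fixture(scope="session")
def reference_spectrum():
    return bc.build_reference_spectrum(0.05, 0.85, 0.10, 0.0)


def brute_force_gamma(reference, evaluated, criteria, spacing_mm):
    """Independent exhaustive gamma evaluation on small grids.

    Direct per-voxel loop minimizing over the dense candidate lattice
    (step DTA/10, radius 2*DTA) with scipy's RegularGridInterpolator —
    no shell ordering, no early termination, separate interpolation code.
    """
    from scipy.interpolate import RegularGridInterpolator

    ref = np.asarray(reference, float)
    ev = np.asarray(evaluated, float)
    spacing = np.asarray(spacing_mm, float)
    axes = [spacing[a] * np.arange(ref.shape[a]) for a in range(3)]
    interp = RegularGridInterpolator(
        axes, ev, method="linear", bounds_error=False, fill_value=None
    )
    dta = criteria.dta_mm
    step = dta / 10.0
    n = int(np.floor(2.0 * dta / step))
    ax = step * np.arange(-n, n + 1)
    ox, oy, oz = np.meshgrid(ax, ax, ax, indexing="ij")
    offs = np.column_stack([ox.ravel(), oy.ravel(), oz.ravel()])
    offs = offs[(offs**2).sum(axis=1) <= (2.0 * dta) ** 2 + 1e-12]

    ref_max = ref.max()
    thr = criteria.threshold_pct / 100.0 * ref_max
    out = np.full(ref.shape, np.nan)
    for idx in np.argwhere(ref > thr):
        p0 = idx * spacing
        if criteria.normalization == "global":
            dd = criteria.dose_diff_pct / 100.0 * ref_max
        else:
            dd = criteria.dose_diff_pct / 100.0 * ref[tuple(idx)]
        pts = p0 + offs
        # clamp to the grid to mirror nearest-edge extension
        lim = (np.asarray(ref.shape) - 1) * spacing
        pts_c = np.clip(pts, 0.0, lim)
        vals = interp(pts_c)
        g2 = ((offs / dta) ** 2).sum(axis=1) + (
            (vals - ref[tuple(idx)]) / dd
        ) ** 2
        out[tuple(idx)] = np.sqrt(g2.min())
    return out


def ode_expected_counts(true_rate, history, measurement, n_atoms,
                        steps_per_interval=4000):
    """Independent ODE oracle for the activation/decay/counting chain.

    Integrates dN/dt = R * n_atoms * q(t) - lambda * N with fixed-step
    RK4 through every irradiation interval, then through the cooling
    period, then accumulates eps * gamma * lambda * N over the counting
    window. Shares no code with the closed form.
    """
    lam = measurement.decay_const

    def rk4(n0, source, t_total, steps):
        h = t_total / steps
        n = n0
        for _ in range(steps):
            k1 = source - lam * n
            k2 = source - lam * (n + 0.5 * h * k1)
            k3 = source - lam * (n + 0.5 * h * k2)
            k4 = source - lam * (n + h * k3)
            n = n + h / 6.0 * (k1 + 2 * k2 + 2 * k3 + k4)
        return n

    n_act = 0.0
    for q, dt in history.intervals:
        n_act = rk4(n_act, true_rate * n_atoms * q / dt, dt,
                    steps_per_interval)
    n_act = rk4(n_act, 0.0, measurement.t_cool, steps_per_interval)

    # counts: integrate eps*gamma*lam*N over the counting window
    h = measurement.t_meas / steps_per_interval
    counts = 0.0
    n = n_act
    for _ in range(steps_per_interval):
        n_mid = rk4(n, 0.0, h / 2.0, 1)
        counts += lam * n_mid * h
        n = rk4(n, 0.0, h, 1)
    return measurement.efficiency * measurement.emission_prob * counts
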