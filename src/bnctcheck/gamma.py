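"""3D gamma-index comparison of co-registered dose grids.

For each reference voxel above the dose threshold the gamma index is the
minimum over evaluated-grid positions r of

    sqrt( (|r - r_ref| / DTA)^2 + ((D_eval(r) - D_ref) / dD)^2 )

with dD the dose-difference criterion (global: % of the reference
maximum; local: % of the local reference dose). A voxel passes when
gamma <= 1 (the boundary passes). The search minimizes over a subvoxel
candidate lattice (trilinear interpolation, step DTA/10, radius 2*DTA),
processed in shells of increasing distance with early termination once
the distance term alone exceeds the running minimum.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage


class GammaStructureError(ValueError):
    pass


@dataclass(frozen=True)
class GammaCriteria:
    """Dose-difference (%), DTA (mm), low-dose threshold (%), normalization."""

    dose_diff_pct: float
    dta_mm: float
    threshold_pct: float = 10.0
    normalization: str = "global"

    def __post_init__(self) -> None:
        if self.dose_diff_pct <= 0 or self.dta_mm <= 0:
            raise GammaStructureError("criteria must be positive")
        if not (0 <= self.threshold_pct < 100):
            raise GammaStructureError("threshold must be in [0, 100)")
        if self.normalization not in ("global", "local"):
            raise GammaStructureError("normalization must be global or local")


@dataclass
class GammaResult:
    """Gamma map (NaN below threshold), pass rate in %, evaluated count."""

    gamma_map: np.ndarray
    pass_rate: float
    n_evaluated: int
    criteria: GammaCriteria


def _search_offsets(dta_mm: float, spacing: np.ndarray) -> np.ndarray:
    """Candidate offsets (mm) within 2*DTA, step DTA/10, sorted by radius."""
    step = dta_mm / 10.0
    radius = 2.0 * dta_mm
    n = int(np.floor(radius / step))
    ax = step * np.arange(-n, n + 1)
    ox, oy, oz = np.meshgrid(ax, ax, ax, indexing="ij")
    offsets = np.column_stack([ox.ravel(), oy.ravel(), oz.ravel()])
    d2 = (offsets**2).sum(axis=1)
    keep = d2 <= radius**2 + 1e-12
    offsets, d2 = offsets[keep], d2[keep]
    order = np.argsort(d2, kind="stable")
    return offsets[order]


def gamma_index(
    reference: np.ndarray,
    evaluated: np.ndarray,
    criteria: GammaCriteria,
    spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0),
) -> GammaResult:
    """Compute the per-voxel gamma map and pass rate.

    Both grids must share shape and spacing (resampling is the caller's
    job). Voxels at or below ``threshold_pct`` of the reference maximum
    are excluded from both the map (NaN) and the pass rate.
    """
    ref = np.asarray(reference, dtype=float)
    ev = np.asarray(evaluated, dtype=float)
    if ref.shape != ev.shape:
        raise GammaStructureError(
            f"grid shapes differ: {ref.shape} vs {ev.shape}"
        )
    ref_max = ref.max()
    if ref_max <= 0:
        raise GammaStructureError("reference maximum must be positive")
    spacing = np.asarray(spacing_mm, dtype=float)

    above = ref > criteria.threshold_pct / 100.0 * ref_max
    n_eval = int(above.sum())
    gamma_map = np.full(ref.shape, np.nan)
    if n_eval == 0:
        return GammaResult(gamma_map, 100.0, 0, criteria)

    if criteria.normalization == "global":
        dd = criteria.dose_diff_pct / 100.0 * ref_max
        dd_per_voxel = np.full(n_eval, dd)
    else:
        dd_per_voxel = criteria.dose_diff_pct / 100.0 * ref[above]

    vox = np.argwhere(above).astype(float)  # index coordinates
    ref_vals = ref[above]
    dta = criteria.dta_mm

    offsets = _search_offsets(dta, spacing)
    best = np.full(n_eval, np.inf)
    active = np.arange(n_eval)
    i = 0
    chunk = 32
    while i < offsets.shape[0] and active.size > 0:
        block = offsets[i : i + chunk]
        i += chunk
        # distance term of the first (smallest) offset in the block: once it
        # exceeds the running minimum for a voxel, no later offset can win
        d2_min = (block[0] ** 2).sum() / dta**2
        still = best[active] > d2_min
        active = active[still]
        if active.size == 0:
            break
        coords_base = vox[active]
        for off in block:
            d2 = (off**2).sum() / dta**2
            pts = (coords_base * spacing + off) / spacing
            vals = ndimage.map_coordinates(
                ev, pts.T, order=1, mode="nearest"
            )
            g2 = d2 + ((vals - ref_vals[active]) / dd_per_voxel[active]) ** 2
            np.minimum.at(best, active, g2)

    gamma_vals = np.sqrt(best)
    gamma_map[above] = gamma_vals
    pass_rate = 100.0 * float((gamma_vals <= 1.0 + 1e-12).sum()) / n_eval
    return GammaResult(gamma_map, pass_rate, n_eval, criteria)


def criteria_sweep(
    reference: np.ndarray,
    evaluated: np.ndarray,
    fixed_axis: str,
    fixed_value: float,
    values: list[float],
    *,
    threshold_pct: float = 10.0,
    spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0),
) -> list[dict]:
    """Pass-rate table varying one criterion while the other is fixed.

    ``fixed_axis`` names the criterion held fixed ("dose_diff_pct" or
    "dta_mm"); ``values`` sweep the other one (positive, ascending).
    """
    if len(values) == 0:
        raise GammaStructureError("empty sweep value list")
    vals = np.asarray(values, dtype=float)
    if np.any(vals <= 0) or np.any(np.diff(vals) <= 0):
        raise GammaStructureError("sweep values must be positive and ascending")
    if fixed_axis not in ("dose_diff_pct", "dta_mm"):
        raise GammaStructureError(f"unknown fixed axis {fixed_axis!r}")

    rows = []
    for v in vals:
        kwargs = {fixed_axis: fixed_value,
                  ("dta_mm" if fixed_axis == "dose_diff_pct" else "dose_diff_pct"): v}
        crit = GammaCriteria(threshold_pct=threshold_pct, **kwargs)
        res = gamma_index(reference, evaluated, crit, spacing_mm)
        rows.append(
            {
                "dose_diff_pct": crit.dose_diff_pct,
                "dta_mm": crit.dta_mm,
                "pass_rate": res.pass_rate,
                "n_evaluated": res.n_evaluated,
            }
        )
    return rows
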