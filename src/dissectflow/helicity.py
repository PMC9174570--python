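"""Vorticity, helicity density, and false-lumen helicity profiles.

Helicity density H = v . (curl v) measures the alignment of velocity
with vorticity; its sign encodes the handedness of rotation about the
flow axis.  Elevated |H| in the false lumen marks the rotational flow
that entry-tear jets drive.  Profiles report the per-cross-section mean
helicity density (m/s^2) along the shared TL+FL centerline, false lumen
only — the mean (not the area integral) so values are comparable across
grid resolutions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .centerline import Centerline
from .errors import DataError, ParameterError
from .fields import LABELS, LumenMask, VelocityField4D

log = logging.getLogger(__name__)


def _masked_derivative(f: np.ndarray, in_mask: np.ndarray, axis: int,
                       spacing_m: float) -> np.ndarray:
    """d f / d axis with mask awareness.

    Central differences where both neighbors are in the mask, one-sided
    where only one is, NaN where neither (single-voxel-thick regions).
    """
    fp = np.roll(f, -1, axis=axis)
    fm = np.roll(f, 1, axis=axis)
    mp = np.roll(in_mask, -1, axis=axis)
    mm = np.roll(in_mask, 1, axis=axis)
    # roll wraps around; kill the wrapped faces
    sl_hi = [slice(None)] * f.ndim
    sl_hi[axis] = slice(-1, None)
    sl_lo = [slice(None)] * f.ndim
    sl_lo[axis] = slice(0, 1)
    mp = mp.copy(); mp[tuple(sl_hi)] = False
    mm = mm.copy(); mm[tuple(sl_lo)] = False

    out = np.full_like(f, np.nan, dtype=float)
    both = mp & mm
    only_p = mp & ~mm
    only_m = mm & ~mp
    out[both] = (fp[both] - fm[both]) / (2 * spacing_m)
    out[only_p] = (fp[only_p] - f[only_p]) / spacing_m
    out[only_m] = (f[only_m] - fm[only_m]) / spacing_m
    return out


def curl(fld: VelocityField4D, mask=None) -> np.ndarray:
    """Vorticity omega = curl v per voxel per phase, in 1/s.

    Spacing-aware differences restricted to the mask (one-sided at mask
    boundaries; NaN where no in-mask neighbor exists along an axis —
    flagged via a log message).

    Returns
    -------
    ndarray, shape (nx, ny, nz, 3, n_phases), NaN outside the mask.
    """
    if isinstance(mask, LumenMask):
        in_mask = mask.lumen()
    elif mask is None:
        in_mask = np.ones(fld.grid_shape, dtype=bool)
    else:
        in_mask = np.asarray(mask, dtype=bool)
    if in_mask.shape != fld.grid_shape:
        raise DataError("mask grid does not match the velocity grid")
    sp_m = fld.spacing / 1000.0  # mm -> m so derivatives are 1/s
    T = fld.n_phases
    omega = np.full(fld.grid_shape + (3, T), np.nan)
    for t in range(T):
        d = {}
        for c in range(3):
            v = np.where(in_mask, fld.values[:, :, :, c, t], np.nan)
            for a in range(3):
                if (c, a) in ((0, 0), (1, 1), (2, 2)):
                    continue
                d[(c, a)] = _masked_derivative(v, in_mask, a, sp_m[a])
        omega[..., 0, t] = d[(2, 1)] - d[(1, 2)]
        omega[..., 1, t] = d[(0, 2)] - d[(2, 0)]
        omega[..., 2, t] = d[(1, 0)] - d[(0, 1)]
    n_missing = int(np.sum(in_mask & ~np.isfinite(omega[..., 0, 0])))
    if n_missing:
        log.info("curl: %d in-mask voxels have undefined vorticity "
                 "(single-voxel-thick geometry)", n_missing)
    omega[~in_mask] = np.nan
    return omega


def helicity_density(v: np.ndarray, omega: np.ndarray) -> np.ndarray:
    """Pointwise H = v . omega (m/s^2), sign preserved.

    Accepts a :class:`VelocityField4D` or the raw (..., 3, T) array for
    ``v``; shapes must match ``omega``.
    """
    if isinstance(v, VelocityField4D):
        v = v.values
    v = np.asarray(v, dtype=float)
    omega = np.asarray(omega, dtype=float)
    if v.shape != omega.shape:
        raise DataError(f"shape mismatch: v {v.shape} vs omega {omega.shape}")
    return np.einsum("...ct,...ct->...t", v, omega)


def nanmean_quiet(a: np.ndarray, axis=None) -> np.ndarray:
    """nanmean that stays silent on all-NaN slices (returns NaN there)."""
    import warnings as _w
    with _w.catch_warnings():
        _w.simplefilter("ignore", category=RuntimeWarning)
        return np.nanmean(a, axis=axis)


def boundary_voxels(in_mask: np.ndarray) -> np.ndarray:
    """Voxels with any 6-neighbor outside the mask (curl least accurate)."""
    eroded = ndimage.binary_erosion(in_mask,
                                    structure=ndimage.generate_binary_structure(3, 1))
    return in_mask & ~eroded


@dataclass
class HelicityProfile:
    """Per-section mean helicity along the centerline, false lumen only.

    ``h_mean`` is the cycle-averaged mean helicity density per section
    (m/s^2), ``abs_h_mean`` the same for |H|; sections without false-
    lumen samples hold NaN.  |h_mean| <= abs_h_mean per section, with
    equality iff H is single-signed there.
    """

    arclength_mm: np.ndarray
    h_mean: np.ndarray
    abs_h_mean: np.ndarray
    n_samples: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "arclength_mm": self.arclength_mm,
            "h_mean_ms2": self.h_mean,
            "abs_h_mean_ms2": self.abs_h_mean,
            "n_samples": self.n_samples,
        })


def helicity_profile(h_field: np.ndarray, mask: LumenMask, cl: Centerline,
                     fl_label: int = LABELS["false_lumen"],
                     include_boundary: bool = False) -> HelicityProfile:
    """Mean H and |H| per centerline section over false-lumen voxels.

    Voxels are assigned to the nearest centerline point (1 mm spacing in
    the standard pipeline, so bands are the 1 mm cross-sections); the
    cycle average is the uniform mean over phases.  Mask-boundary voxels
    are excluded from the means by default — the curl there relies on
    one-sided differences and is the least accurate.
    """
    from scipy.spatial import cKDTree
    h_field = np.asarray(h_field, dtype=float)
    if h_field.ndim != 4:
        raise DataError("helicity field must be (nx, ny, nz, n_phases)")
    fl = mask.region(fl_label)
    n_pts = len(cl)
    out = HelicityProfile(
        arclength_mm=cl.arclength.copy(),
        h_mean=np.full(n_pts, np.nan),
        abs_h_mean=np.full(n_pts, np.nan),
        n_samples=np.zeros(n_pts, dtype=int),
    )
    if not np.any(fl):
        log.warning("false-lumen label %d absent: empty helicity profile",
                    fl_label)
        return out
    use = fl.copy()
    if not include_boundary:
        interior = fl & ~boundary_voxels(mask.lumen())
        if np.any(interior):
            use = interior
    idxs = np.argwhere(use)
    world = idxs @ mask.affine[:3, :3].T + mask.affine[:3, 3]
    _, band = cKDTree(cl.points).query(world)
    h_cyc = nanmean_quiet(h_field, axis=3)[use]
    abs_cyc = nanmean_quiet(np.abs(h_field), axis=3)[use]
    ok = np.isfinite(h_cyc)
    for i in range(n_pts):
        sel = (band == i) & ok
        n = int(np.sum(sel))
        out.n_samples[i] = n
        if n:
            out.h_mean[i] = float(np.mean(h_cyc[sel]))
            out.abs_h_mean[i] = float(np.mean(abs_cyc[sel]))
    return out


def project_map(values: np.ndarray, axis: str | int = "x") -> np.ndarray:
    """2-D average intensity projection of a parameter map.

    NaN-aware mean along one axis; columns with no masked voxels stay
    NaN (transparent background).
    """
    from .flowquant import ParametricMap
    if isinstance(values, ParametricMap):
        values = values.values
    values = np.asarray(values, dtype=float)
    axis_map = {"x": 0, "y": 1, "z": 2}
    if isinstance(axis, str):
        if axis not in axis_map:
            raise ParameterError(f"axis must be one of x/y/z, got {axis!r}")
        axis = axis_map[axis]
    if axis not in (0, 1, 2):
        raise ParameterError("projection axis must be 0, 1 or 2")
    return nanmean_quiet(values, axis=axis)
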