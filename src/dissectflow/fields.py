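"""In-memory containers for 4D phase-contrast velocity data.

Conventions used throughout the package:

* velocity values are stored in m/s; geometry (spacing, coordinates,
  radii) in mm; flow rates in mL/s; per-cycle volumes in mL.  With those
  units a flux integral ``sum(v * dA)`` over a plane (v in m/s, dA in mm^2)
  is numerically in mL/s, so no conversion factors appear in the
  quantification code.
* voxel indices are 0-based; world coordinates come from the NIfTI affine
  and all geometric reasoning happens in world mm.
* the velocity-component axis order is anatomical (RL, AP, FH); the
  mapping of components to world axes is declared explicitly
  (``component_axes``), never inferred from headers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
from scipy.ndimage import map_coordinates

from .errors import DataError, FormatError

#: Canonical integer label codes for the lumen segmentation.
LABELS: Mapping[str, int] = {
    "background": 0,
    "true_lumen": 1,
    "false_lumen": 2,
    "ascending": 3,
    "branch_1": 4,
    "branch_2": 5,
    "branch_3": 6,
    "excluded": 7,
}

#: Labels that count as lumen for quantification purposes.
LUMEN_LABELS = (1, 2, 3, 4, 5, 6)

COMPONENT_NAMES = ("RL", "AP", "FH")


def _check_affine(affine: np.ndarray) -> np.ndarray:
    affine = np.asarray(affine, dtype=float)
    if affine.shape != (4, 4):
        raise DataError(f"affine must be 4x4, got {affine.shape}")
    return affine


@dataclass
class VelocityField4D:
    """Gridded 3-component velocity over space and cardiac phase.

    Parameters
    ----------
    values : ndarray, shape (nx, ny, nz, 3, n_phases)
        Velocity in m/s. Component axis follows ``component_axes``.
    affine : ndarray (4, 4)
        Voxel-index -> world-mm transform (NIfTI convention).
    phase_duration_ms : float
        Duration of one reconstructed cardiac phase (uniform, retrospective
        gating assumed).
    venc_cms : float or sequence of 3 floats, optional
        Velocity-encoding limit per component in cm/s. Velocities beyond
        it would alias in an acquisition; the phantom warns when it
        generates such speeds.
    component_axes : tuple of int
        World axis index each velocity component points along; default
        (0, 1, 2) i.e. component 0 is the world-x (RL) velocity and
        component 2 the world-z (FH, foot-head) velocity.
    """

    values: np.ndarray
    affine: np.ndarray
    phase_duration_ms: float
    venc_cms: np.ndarray | float | None = None
    component_axes: tuple = (0, 1, 2)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 5 or self.values.shape[3] != 3:
            raise DataError(
                "velocity values must have shape (nx, ny, nz, 3, n_phases), "
                f"got {self.values.shape}"
            )
        if self.values.shape[4] < 1:
            raise DataError("at least one cardiac phase required")
        self.affine = _check_affine(self.affine)
        if np.any(self.spacing <= 0):
            raise DataError("voxel spacing must be strictly positive")
        if self.phase_duration_ms <= 0:
            raise DataError("phase duration must be positive")
        if self.venc_cms is not None:
            self.venc_cms = np.broadcast_to(
                np.asarray(self.venc_cms, dtype=float), (3,)
            ).copy()

    # -- geometry -----------------------------------------------------
    @property
    def grid_shape(self) -> tuple:
        return self.values.shape[:3]

    @property
    def n_phases(self) -> int:
        return self.values.shape[4]

    @property
    def spacing(self) -> np.ndarray:
        """Voxel spacing in mm per world axis (from the affine)."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    @property
    def phase_duration_s(self) -> float:
        return self.phase_duration_ms / 1000.0

    @property
    def voxel_volume_mm3(self) -> float:
        return float(abs(np.linalg.det(self.affine[:3, :3])))

    def world_coordinates(self) -> tuple:
        """Meshgrid world coordinates (mm) of all voxel centers."""
        idx = np.meshgrid(*[np.arange(n) for n in self.grid_shape], indexing="ij")
        ijk = np.stack([a.ravel() for a in idx], axis=1)
        xyz = ijk @ self.affine[:3, :3].T + self.affine[:3, 3]
        return tuple(xyz[:, a].reshape(self.grid_shape) for a in range(3))

    def world_to_voxel(self, points_mm: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points_mm, dtype=float))
        inv = np.linalg.inv(self.affine)
        return pts @ inv[:3, :3].T + inv[:3, 3]

    def voxel_to_world(self, ijk: np.ndarray) -> np.ndarray:
        ijk = np.atleast_2d(np.asarray(ijk, dtype=float))
        return ijk @ self.affine[:3, :3].T + self.affine[:3, 3]

    # -- sampling -----------------------------------------------------
    def sample(self, points_mm: np.ndarray, order: int = 1) -> np.ndarray:
        """Interpolate the velocity at world points.

        Trilinear by default (``order=1``). Points outside the grid get
        zero velocity (constant extension), which matches the phantom's
        zero background.

        Returns
        -------
        ndarray, shape (n_points, 3, n_phases)
        """
        vox = self.world_to_voxel(points_mm).T  # (3, M)
        out = np.empty((vox.shape[1], 3, self.n_phases))
        for c in range(3):
            for t in range(self.n_phases):
                out[:, c, t] = map_coordinates(
                    self.values[:, :, :, c, t], vox, order=order,
                    mode="constant", cval=0.0,
                )
        return out

    def speed(self) -> np.ndarray:
        """Voxel-wise velocity magnitude, shape (nx, ny, nz, n_phases)."""
        return np.sqrt(np.sum(self.values ** 2, axis=3))

    def copy(self) -> "VelocityField4D":
        return replace(self, values=self.values.copy(),
                       affine=self.affine.copy())


@dataclass
class LumenMask:
    """Integer-labeled voxel mask on the same grid as its velocity field.

    Codes follow :data:`LABELS`: 0 background, 1 true lumen, 2 false
    lumen, 3 ascending aorta, 4-6 branches, 7 excluded-by-stent-artifact.
    Excluded voxels never contribute to any quantification.
    """

    labels: np.ndarray
    affine: np.ndarray

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise DataError(f"mask must be 3-D, got shape {self.labels.shape}")
        if not np.issubdtype(self.labels.dtype, np.integer):
            self.labels = self.labels.astype(np.int16)
        self.affine = _check_affine(self.affine)

    @property
    def grid_shape(self) -> tuple:
        return self.labels.shape

    @property
    def spacing(self) -> np.ndarray:
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    def region(self, label) -> np.ndarray:
        """Boolean mask of one label code (or of a tuple of codes)."""
        if np.isscalar(label):
            return self.labels == label
        return np.isin(self.labels, np.asarray(label))

    def lumen(self, include_branches: bool = True) -> np.ndarray:
        """All quantifiable lumen voxels (never the excluded code)."""
        codes = LUMEN_LABELS if include_branches else (1, 2, 3)
        return self.region(codes)

    def aorta(self) -> np.ndarray:
        """Combined TL + FL (+ ascending) mask used for the centerline."""
        return self.region((LABELS["true_lumen"], LABELS["false_lumen"],
                            LABELS["ascending"]))

    def counts(self) -> dict:
        vals, cnts = np.unique(self.labels, return_counts=True)
        inv = {v: k for k, v in LABELS.items()}
        return {inv.get(int(v), f"label_{int(v)}"): int(c)
                for v, c in zip(vals, cnts)}

    def world_to_voxel(self, points_mm):
        pts = np.atleast_2d(np.asarray(points_mm, dtype=float))
        inv = np.linalg.inv(self.affine)
        return pts @ inv[:3, :3].T + inv[:3, 3]

    def label_at(self, points_mm: np.ndarray) -> np.ndarray:
        """Nearest-neighbor label lookup at world points (0 outside grid)."""
        vox = np.rint(self.world_to_voxel(points_mm)).astype(int)
        inside = np.all((vox >= 0) & (vox < np.array(self.grid_shape)), axis=1)
        out = np.zeros(len(vox), dtype=self.labels.dtype)
        v = vox[inside]
        out[inside] = self.labels[v[:, 0], v[:, 1], v[:, 2]]
        return out

    def copy(self) -> "LumenMask":
        return LumenMask(self.labels.copy(), self.affine.copy())


@dataclass
class LandmarkSet:
    """Named anatomical points in world mm.

    Canonical names: ``seed`` (proximal centerline seed),
    ``left_subclavian``, ``celiac_trunk``, ``ascending_reference``
    (plane 5 cm above the aortic sinus used to normalize flows).
    """

    points: dict = field(default_factory=dict)

    def __getitem__(self, name: str) -> np.ndarray:
        try:
            return np.asarray(self.points[name], dtype=float)
        except KeyError:
            raise DataError(f"landmark {name!r} not defined") from None

    def __contains__(self, name: str) -> bool:
        return name in self.points

    def names(self):
        return list(self.points)

    def validate_in_grid(self, grid_shape, affine) -> None:
        affine = _check_affine(affine)
        inv = np.linalg.inv(affine)
        lo = -0.5
        hi = np.asarray(grid_shape) - 0.5
        for name, p in self.points.items():
            vox = np.asarray(p, float) @ inv[:3, :3].T + inv[:3, 3]
            if np.any(vox < lo) or np.any(vox >= hi):
                raise DataError(
                    f"landmark {name!r} at {p} lies outside the grid bounds")


# ----------------------------------------------------------------------
# simple derived quantities


def phase_to_velocity(phase, venc_cms, return_alias_mask: bool = False):
    """Convert raw phase (radians) to velocity in m/s.

    The standard phase-contrast relation ``v = phase / pi * VENC``. Phase
    outside [-pi, pi] indicates velocity aliasing; such samples are
    flagged (warning plus optional boolean mask), never silently clamped.
    """
    phase = np.asarray(phase, dtype=float)
    venc_ms = float(venc_cms) / 100.0
    aliased = np.abs(phase) > np.pi + 1e-12
    if np.any(aliased):
        warnings.warn(
            f"{int(np.sum(aliased))} phase sample(s) outside [-pi, pi]: "
            "velocity aliasing suspected", stacklevel=2)
    v = phase / np.pi * venc_ms
    if return_alias_mask:
        return v, aliased
    return v


def compute_pcmra(fld: VelocityField4D) -> np.ndarray:
    """Phase-contrast MR angiogram: time-averaged speed per voxel.

    The mean over cardiac phases of the velocity *magnitude* (so flow
    that alternates sign still lights up); this is the image that is
    segmented to obtain the lumen mask.
    """
    if fld.n_phases < 1:
        raise FormatError("PCMRA needs at least one phase")
    return fld.speed().mean(axis=3)
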