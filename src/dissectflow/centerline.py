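"""Aortic centerline extraction and cross-section placement.

The centerline is computed on the *combined* true + false lumen mask by
topology-preserving iterative 3-D thinning, ordered from a proximal seed
landmark, smoothed, and resampled at 1 mm arclength spacing; one
quantification plane (cross-section) is placed per centerline point,
normal to the local tangent.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field as dc_field

import networkx as nx
import numpy as np
from scipy import ndimage
from scipy.interpolate import interp1d
from skimage.morphology import ball, skeletonize

from .errors import DataError, LandmarkError, ParameterError
from .fields import LandmarkSet, LumenMask

log = logging.getLogger(__name__)


@dataclass
class Centerline:
    """Ordered 3-D polyline in world mm with tangents and landmarks."""

    points: np.ndarray  # (N, 3) mm
    landmarks: dict = dc_field(default_factory=dict)  # name -> point index

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 3:
            raise DataError("centerline points must be (N, 3)")
        if len(self.points) < 2:
            raise DataError("centerline needs at least two points")

    def __len__(self):
        return len(self.points)

    @property
    def arclength(self) -> np.ndarray:
        steps = np.linalg.norm(np.diff(self.points, axis=0), axis=1)
        return np.concatenate([[0.0], np.cumsum(steps)])

    @property
    def length(self) -> float:
        return float(self.arclength[-1])

    @property
    def tangents(self) -> np.ndarray:
        """Unit tangents from central differences (one-sided at the ends)."""
        t = np.gradient(self.points, axis=0)
        n = np.linalg.norm(t, axis=1, keepdims=True)
        n[n == 0] = 1.0
        return t / n

    def reverse(self) -> "Centerline":
        n = len(self.points)
        lm = {k: n - 1 - v for k, v in self.landmarks.items()}
        return Centerline(self.points[::-1].copy(), lm)

    def locate(self, point_mm) -> int:
        """Index of the centerline point nearest a world point."""
        d = np.linalg.norm(self.points - np.asarray(point_mm, float), axis=1)
        return int(np.argmin(d))


@dataclass
class CrossSection:
    """Quantification plane: origin + unit normal + in-plane sample lattice.

    ``coords`` are the world positions of the lattice samples (all on
    the plane), ``labels`` the lumen label at each sample (nearest
    voxel), ``dA`` the per-sample area element in mm^2.
    """

    origin: np.ndarray
    normal: np.ndarray
    coords: np.ndarray  # (M, 3)
    labels: np.ndarray  # (M,)
    dA: float
    index: int = 0
    arclength: float = 0.0

    @property
    def is_empty(self) -> bool:
        return not np.any(self.labels > 0)

    def lumen_samples(self, label=None) -> np.ndarray:
        """Boolean selector of the samples with a (specific) lumen label."""
        from .fields import LUMEN_LABELS
        if label is None:
            return np.isin(self.labels, LUMEN_LABELS)
        if np.isscalar(label):
            return self.labels == label
        return np.isin(self.labels, np.asarray(label))


# ----------------------------------------------------------------------


def extract_skeleton(mask, close_radius_vox: int = 0) -> np.ndarray:
    """Topology-preserving 3-D thinning of the combined lumen mask.

    Parameters
    ----------
    mask : LumenMask or bool array
        A :class:`LumenMask` contributes its TL + FL (+ ascending)
        union. ``close_radius_vox`` applies a morphological closing
        first — needed on dissections, where the zero-velocity septum
        otherwise splits the union into two components.

    Returns
    -------
    bool array — one-voxel-wide curve skeleton.

    Raises
    ------
    DataError if the (closed) union is not a single 26-connected
    component; the message lists the component sizes.
    """
    if isinstance(mask, LumenMask):
        union = mask.aorta()
    else:
        union = np.asarray(mask, dtype=bool)
    if union.ndim != 3:
        raise DataError("skeletonization expects a 3-D mask")
    if close_radius_vox > 0:
        union = ndimage.binary_closing(union, structure=ball(close_radius_vox))
    labeled, n = ndimage.label(union, structure=np.ones((3, 3, 3)))
    if n == 0:
        raise DataError("empty lumen mask: nothing to skeletonize")
    if n > 1:
        sizes = sorted(np.bincount(labeled.ravel())[1:], reverse=True)
        raise DataError(
            f"combined lumen mask has {n} 26-connected components "
            f"(sizes {sizes}); expected one — consider closing the septum "
            "(close_radius_vox > 0)")
    skel = skeletonize(union, method="lee").astype(bool)
    if not np.any(skel):
        raise DataError("thinning produced an empty skeleton (degenerate "
                        "mask geometry)")
    return skel


def _skeleton_graph(skeleton: np.ndarray, spacing: np.ndarray) -> nx.Graph:
    vox = np.argwhere(skeleton)
    index = {tuple(v): i for i, v in enumerate(vox)}
    g = nx.Graph()
    g.add_nodes_from(range(len(vox)))
    offsets = np.array([(i, j, k) for i in (-1, 0, 1) for j in (-1, 0, 1)
                        for k in (-1, 0, 1) if (i, j, k) != (0, 0, 0)])
    for a, v in enumerate(vox):
        for off in offsets:
            nb = tuple(v + off)
            b = index.get(nb)
            if b is not None and b > a:
                w = float(np.linalg.norm(off * spacing))
                g.add_edge(a, b, weight=w)
    return g, vox


def order_and_prune(skeleton: np.ndarray, seed_mm, affine,
                    prune_mm: float = 5.0,
                    seed_tolerance_mm: float = 10.0) -> Centerline:
    """Order the skeleton into a single proximal-to-distal polyline.

    The skeleton voxel nearest the proximal seed landmark anchors the
    curve; the geodesically farthest voxel from it defines the distal
    end, and the shortest skeleton path between the two is the
    centerline.  Side branches fall off this main path; branches longer
    than ``prune_mm`` are logged (arch-vessel stubs), shorter ones are
    spurs and vanish silently.  Ties for the distal end break
    deterministically on the lexicographically smallest voxel index.
    """
    affine = np.asarray(affine, dtype=float)
    spacing = np.linalg.norm(affine[:3, :3], axis=0)
    if not np.any(skeleton):
        raise DataError("empty skeleton")
    g, vox = _skeleton_graph(skeleton, spacing)
    world = vox @ affine[:3, :3].T + affine[:3, 3]

    seed = np.asarray(seed_mm, dtype=float)
    d_seed = np.linalg.norm(world - seed, axis=1)
    start = int(np.argmin(d_seed))
    if d_seed[start] > seed_tolerance_mm:
        raise LandmarkError(
            f"seed landmark {seed} is {d_seed[start]:.1f} mm from the "
            f"nearest skeleton voxel (tolerance {seed_tolerance_mm} mm)")

    # geodesic distances from the seed end; farthest node = distal end
    dist = nx.single_source_dijkstra_path_length(g, start, weight="weight")
    if len(dist) < len(vox):
        missing = len(vox) - len(dist)
        log.warning("%d skeleton voxels unreachable from the seed; ignored",
                    missing)
    dmax = max(dist.values())
    candidates = [n for n, d in dist.items() if d == dmax]
    end = min(candidates, key=lambda n: tuple(vox[n]))
    path = nx.dijkstra_path(g, start, end, weight="weight")

    n_off = len(dist) - len(path)
    if n_off:
        off_world = world[[n for n in dist if n not in set(path)]]
        log.info("order_and_prune: %d skeleton voxels off the main path "
                 "(side branches/spurs) removed", n_off)
        del off_world
    points = world[path]
    # collapse accidental duplicates
    keep = np.concatenate([[True],
                           np.linalg.norm(np.diff(points, axis=0), axis=1) > 1e-9])
    return Centerline(points[keep])


def resample(cl: Centerline, spacing_mm: float = 1.0,
             smooth_mm: float = 5.0) -> Centerline:
    """Smooth and resample the centerline at uniform arclength spacing.

    A moving average over a ``smooth_mm`` window precedes the
    resampling — voxel-level jaggedness otherwise corrupts the tangents
    and with them the forward/reverse flux classification.
    """
    if spacing_mm <= 0:
        raise ParameterError("resample spacing must be > 0")
    pts = cl.points
    if len(pts) < 2:
        raise DataError("cannot resample a centerline with < 2 points")
    step = float(np.mean(np.linalg.norm(np.diff(pts, axis=0), axis=1)))
    if smooth_mm > 0 and step > 0:
        half = max(1, int(round(smooth_mm / (2 * step))))
        kernel = np.ones(2 * half + 1) / (2 * half + 1)
        # odd reflection about the endpoints preserves them (a straight
        # line stays exactly itself, ends included)
        head = 2 * pts[0] - pts[half:0:-1]
        tail = 2 * pts[-1] - pts[-2:-half - 2:-1]
        padded = np.vstack([head, pts, tail])
        pts = np.column_stack([
            np.convolve(padded[:, a], kernel, mode="valid") for a in range(3)])
    s = np.concatenate([[0.0],
                        np.cumsum(np.linalg.norm(np.diff(pts, axis=0), axis=1))])
    total = s[-1]
    if total < spacing_mm:
        raise DataError(
            f"centerline length {total:.2f} mm shorter than the resample "
            f"spacing {spacing_mm} mm")
    n = int(np.floor(total / spacing_mm)) + 1
    s_new = np.arange(n) * spacing_mm
    interp = interp1d(s, pts, axis=0, kind="linear")
    new_pts = interp(s_new)
    lm = {k: int(np.argmin(np.linalg.norm(new_pts - cl.points[v], axis=1)))
          for k, v in cl.landmarks.items()}
    return Centerline(new_pts, lm)


def map_landmarks(cl: Centerline, landmarks: LandmarkSet,
                  names=("ascending_reference", "left_subclavian",
                         "celiac_trunk")) -> Centerline:
    """Attach landmark indices (nearest centerline point) to the curve."""
    for name in names:
        if name in landmarks:
            cl.landmarks[name] = cl.locate(landmarks[name])
    return cl


def place_cross_sections(cl: Centerline, mask: LumenMask,
                         max_radius_mm: float = 30.0,
                         lattice_spacing_mm: float | None = None) -> list:
    """One quantification plane per centerline point.

    The in-plane sample lattice runs at the voxel resolution by default;
    samples farther than ``max_radius_mm`` from the centerline point are
    dropped so a section cannot capture the false-lumen limb a second
    time where it wraps around the true lumen.  Labels are looked up
    nearest-neighbor (categorical); empty sections are kept but flagged.
    """
    if max_radius_mm <= 0:
        raise ParameterError("section radius must be > 0")
    h = float(lattice_spacing_mm or np.min(mask.spacing))
    n_half = int(np.ceil(max_radius_mm / h))
    offs = (np.arange(-n_half, n_half + 1)) * h
    A, B = np.meshgrid(offs, offs, indexing="ij")
    in_disk = (A ** 2 + B ** 2) <= max_radius_mm ** 2
    alpha, beta = A[in_disk], B[in_disk]

    tangents = cl.tangents
    arclen = cl.arclength
    sections = []
    for i, (o, t) in enumerate(zip(cl.points, tangents)):
        # deterministic in-plane basis: pair t with its least-aligned axis
        a = np.zeros(3)
        a[int(np.argmin(np.abs(t)))] = 1.0
        u = np.cross(t, a)
        u /= np.linalg.norm(u)
        v = np.cross(t, u)
        coords = o[None, :] + alpha[:, None] * u[None, :] + beta[:, None] * v[None, :]
        labels = mask.label_at(coords)
        sec = CrossSection(origin=o.copy(), normal=t.copy(), coords=coords,
                           labels=labels, dA=h * h, index=i,
                           arclength=float(arclen[i]))
        if sec.is_empty:
            log.debug("cross-section %d at s=%.1f mm has no lumen samples",
                      i, arclen[i])
        sections.append(sec)
    return sections
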