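"""Flow quantification: per-section flux, parametric maps, summaries.

Flow direction is defined with respect to the centerline: the
through-plane velocity s = v . t-hat is *forward* (proximal to distal)
when positive and *reverse* when negative.  Per cross-section, net /
forward / reverse flow rates are flux integrals over the in-plane lumen
samples; per-cycle volumes are phase-duration-weighted sums (rectangle
rule, uniform phase duration under retrospective gating).  Voxel-wise
forward-flow (FF) and reverse-flow (RF) maps accumulate through-plane
*volume* over the cycle so that sums over a centerline band reconcile
with the section volumes; the stasis map is the percentage of the cycle
a voxel's speed stays below a threshold (0.1 m/s default).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .centerline import Centerline, CrossSection
from .errors import DataError, ParameterError
from .fields import LumenMask, VelocityField4D

log = logging.getLogger(__name__)

STASIS_THRESHOLD_MS = 0.1  # m/s


def classify_direction(velocity, tangent) -> np.ndarray:
    """Signed through-plane speed s = v . t-hat (forward > 0, reverse < 0).

    Purely in-plane (swirl) velocity has s = 0 and contributes no
    through-plane flow.
    """
    v = np.asarray(velocity, dtype=float)
    t = np.asarray(tangent, dtype=float)
    if not np.isclose(np.linalg.norm(t), 1.0, atol=1e-6):
        raise ParameterError("tangent must be unit-norm")
    return v @ t


@dataclass
class FlowCurve:
    """Net/forward/reverse flow rates per phase plus per-cycle volumes.

    Invariants: forward(t) >= 0, reverse(t) <= 0 and
    net(t) = forward(t) + reverse(t) exactly per phase.
    """

    net_mls: np.ndarray
    forward_mls: np.ndarray
    reverse_mls: np.ndarray
    phase_duration_s: float
    label: object = None
    section_index: int = 0
    arclength: float = 0.0
    n_samples: int = 0

    @property
    def is_empty(self) -> bool:
        return self.n_samples == 0

    @property
    def net_ml(self) -> float:
        return float(np.sum(self.net_mls) * self.phase_duration_s)

    @property
    def forward_ml(self) -> float:
        return float(np.sum(self.forward_mls) * self.phase_duration_s)

    @property
    def reverse_ml(self) -> float:
        return float(np.sum(self.reverse_mls) * self.phase_duration_s)


def section_flow(fld: VelocityField4D, section: CrossSection,
                 label=None, compensate_excluded: bool = True) -> FlowCurve:
    """Flux integral of one cross-section, restricted to a lumen label.

    net(t) = sum s dA, forward(t) = sum max(s, 0) dA, reverse(t) =
    sum min(s, 0) dA over the section's lumen samples; with velocity in
    m/s and dA in mm^2 the results are in mL/s.

    Samples carrying the excluded (stent-artifact) code are lumen whose
    velocity measurement was discarded: by default the flux is rescaled
    by the sampled-area fraction (1 + n_excluded / n_valid), which is
    unbiased when exclusion is unrelated to the local velocity.  Pass
    ``compensate_excluded=False`` for the raw valid-sample integral.
    """
    from .fields import LABELS
    sel = section.lumen_samples(label)
    dt = fld.phase_duration_s
    if not np.any(sel):
        log.debug("empty section %d for label %r", section.index, label)
        z = np.zeros(fld.n_phases)
        return FlowCurve(z, z.copy(), z.copy(), dt, label=label,
                         section_index=section.index,
                         arclength=section.arclength, n_samples=0)
    v = fld.sample(section.coords[sel])  # (M, 3, T)
    s = np.einsum("mct,c->mt", v, section.normal)  # signed speed per sample
    factor = 1.0
    if compensate_excluded:
        n_excl = int(np.sum(section.labels == LABELS["excluded"]))
        if n_excl:
            n_valid = int(section.lumen_samples().sum())
            factor = 1.0 + n_excl / n_valid
    net = s.sum(axis=0) * section.dA * factor
    fwd = np.maximum(s, 0.0).sum(axis=0) * section.dA * factor
    rev = np.minimum(s, 0.0).sum(axis=0) * section.dA * factor
    return FlowCurve(net, fwd, rev, dt, label=label,
                     section_index=section.index,
                     arclength=section.arclength,
                     n_samples=int(np.sum(sel)))


def flow_profile(fld: VelocityField4D, sections, label=None) -> pd.DataFrame:
    """Tidy table: one row per cross-section per phase."""
    rows = []
    for sec in sections:
        fc = section_flow(fld, sec, label)
        for t in range(fld.n_phases):
            rows.append({
                "section": sec.index, "arclength_mm": sec.arclength,
                "phase": t, "net_mls": fc.net_mls[t],
                "forward_mls": fc.forward_mls[t],
                "reverse_mls": fc.reverse_mls[t],
                "n_samples": fc.n_samples,
            })
    return pd.DataFrame(rows)


@dataclass
class ParametricMap:
    """Voxel-wise scalar on the field grid, NaN outside the lumen."""

    values: np.ndarray
    affine: np.ndarray
    name: str
    units: str

    def masked_mean(self, region: np.ndarray) -> float:
        vals = self.values[region]
        vals = vals[np.isfinite(vals)]
        return float(np.mean(vals)) if vals.size else float("nan")


def _nearest_tangents(cl: Centerline, points_mm: np.ndarray):
    """Nearest-centerline-point assignment (ties to lower arclength)."""
    tree = cKDTree(cl.points)
    _, idx = tree.query(points_mm)
    return idx, cl.tangents[idx]


def ff_rf_maps(fld: VelocityField4D, mask: LumenMask, cl: Centerline):
    """Voxel-wise forward/reverse flow maps (mL per cycle per voxel).

    Each lumen voxel gets the tangent of its nearest centerline point;
    the through-plane flux s . A_eff is accumulated over the cycle with
    A_eff = voxel volume / centerline spacing, so summing the map over
    the voxels nearest one centerline point approximates that section's
    forward (resp. reverse) per-cycle volume.
    """
    lumen = mask.lumen()
    idxs = np.argwhere(lumen)
    world = idxs @ mask.affine[:3, :3].T + mask.affine[:3, 3]
    _, tangents = _nearest_tangents(cl, world)
    v = fld.values[lumen]  # (M, 3, T)
    s = np.einsum("mct,mc->mt", v, tangents)
    ds = cl.length / (len(cl) - 1)
    a_eff = fld.voxel_volume_mm3 / ds  # mm^2
    dt = fld.phase_duration_s
    ff_vals = np.maximum(s, 0.0).sum(axis=1) * dt * a_eff
    rf_vals = np.minimum(s, 0.0).sum(axis=1) * dt * a_eff
    ff = np.full(mask.grid_shape, np.nan)
    rf = np.full(mask.grid_shape, np.nan)
    ff[lumen] = ff_vals
    rf[lumen] = rf_vals
    return (ParametricMap(ff, mask.affine, "FF", "mL"),
            ParametricMap(rf, mask.affine, "RF", "mL"))


def stasis_map(fld: VelocityField4D, mask: LumenMask,
               threshold_ms: float = STASIS_THRESHOLD_MS) -> ParametricMap:
    """Percentage of the cardiac cycle each voxel's speed is below threshold."""
    if threshold_ms <= 0:
        raise ParameterError("stasis threshold must be > 0")
    lumen = mask.lumen()
    speed = fld.speed()  # (nx, ny, nz, T)
    pct = 100.0 * np.mean(speed < threshold_ms, axis=3)
    out = np.full(mask.grid_shape, np.nan)
    out[lumen] = pct[lumen]
    return ParametricMap(out, mask.affine, "stasis", "%")


def band_sums(pmap: ParametricMap, mask: LumenMask, cl: Centerline,
              window_mm: float = 10.0) -> np.ndarray:
    """Per-section volume estimates from an FF/RF map.

    Sums the map over arclength windows of ``window_mm`` centered on
    each centerline point and rescales by (centerline spacing / window)
    so the result is comparable to the per-cycle section volume.  The
    window must span at least a few voxels — the voxel grid is usually
    coarser than the 1 mm centerline spacing.
    """
    lumen = mask.lumen()
    idxs = np.argwhere(lumen)
    world = idxs @ mask.affine[:3, :3].T + mask.affine[:3, 3]
    band, _ = _nearest_tangents(cl, world)
    vals = np.nan_to_num(pmap.values[lumen])
    per_point = np.zeros(len(cl))
    np.add.at(per_point, band, vals)
    s = cl.arclength
    ds = cl.length / (len(cl) - 1)
    h = float(np.mean(mask.spacing))  # voxel extent along the tangent
    s_vox = s[band]
    out = np.zeros(len(cl))
    for i in range(len(cl)):
        sel = np.abs(s - s[i]) <= window_mm / 2
        vsel = sel[band]
        if not np.any(vsel):
            continue
        # width from the voxel slabs actually captured: the voxel grid
        # is coarser than the centerline sampling
        n_slabs = np.unique(np.round(s_vox[vsel] / h)).size
        width = max(n_slabs, 1) * h
        out[i] = per_point[sel].sum() * ds / width
    return out


def segment_average(per_section_values, cl: Centerline,
                    from_landmark: str, to_landmark: str) -> float:
    """Unweighted mean of per-section values over a closed landmark range."""
    vals = np.asarray(per_section_values, dtype=float)
    for name in (from_landmark, to_landmark):
        if name not in cl.landmarks:
            raise DataError(f"landmark {name!r} not mapped onto the centerline")
    i, j = cl.landmarks[from_landmark], cl.landmarks[to_landmark]
    if i > j:
        i, j = j, i
    if j >= len(vals):
        raise DataError("landmark index beyond the per-section values")
    seg = vals[i:j + 1]
    seg = seg[np.isfinite(seg)]
    if seg.size == 0:
        return float("nan")
    return float(np.mean(seg))


@dataclass
class FlowSummary:
    """Per-region flow volumes, raw and normalized to ascending net flow.

    ``regions`` maps region name -> dict with ``net_ml``, ``forward_ml``,
    ``reverse_ml`` (mL/cycle) and optionally ``stasis_pct``.  Normalized
    values are percentages of the ascending-aorta net per-cycle volume;
    the reference region's normalized net flow is 100 by construction.
    """

    regions: dict
    reference: str = "ascending"
    extras: dict = dc_field(default_factory=dict)

    def normalized(self) -> dict:
        if self.reference not in self.regions:
            raise DataError(f"reference region {self.reference!r} missing")
        ref = self.regions[self.reference]["net_ml"]
        if ref == 0:
            raise DataError("reference net flow is zero: cannot normalize")
        out = {}
        for name, vals in self.regions.items():
            out[name] = {
                k.replace("_ml", "_norm_pct"): 100.0 * v / ref
                for k, v in vals.items() if k.endswith("_ml")
            }
        return out

    def to_dict(self) -> dict:
        try:
            norm = self.normalized()
        except DataError:
            norm = None  # single-lumen phantoms have no reference region
        return {"reference": self.reference, "regions": self.regions,
                "normalized": norm, "extras": self.extras}


def normalize_and_compare(pre: FlowSummary, post: FlowSummary) -> pd.DataFrame:
    """Pre/post comparison of normalized flows with relative changes.

    Relative change = 100 (post_norm - pre_norm) / pre_norm, per region
    and quantity; undefined (NaN, reported missing) when the pre value
    is zero.
    """
    pre_n, post_n = pre.normalized(), post.normalized()
    common = [r for r in pre_n if r in post_n]
    if not common:
        raise DataError("pre and post summaries share no region labels")
    rows = []
    for region in common:
        for key in pre_n[region]:
            if key not in post_n[region]:
                continue
            a, b = pre_n[region][key], post_n[region][key]
            if a == 0:
                # unchanged zero is a zero change; a change from zero
                # has no defined relative scale -> missing, never inf
                rel = 0.0 if b == 0 else float("nan")
            else:
                rel = 100.0 * (b - a) / a
            rows.append({"region": region, "quantity": key,
                         "pre": a, "post": b, "relative_change_pct": rel})
    return pd.DataFrame(rows)


def branch_plane_flow(fld: VelocityField4D, mask: LumenMask, origin_mm,
                      normal, radius_mm: float = 15.0,
                      label=None) -> FlowCurve:
    """Net flow through a manually placed plane (branch measurement).

    Same flux integral as :func:`section_flow`, restricted to the given
    branch label (any lumen label if None) within ``radius_mm`` of the
    plane origin.  A plane that misses the branch yields an empty,
    flagged curve.
    """
    normal = np.asarray(normal, dtype=float)
    nn = np.linalg.norm(normal)
    if nn == 0:
        raise ParameterError("plane normal must be nonzero")
    normal = normal / nn
    origin = np.asarray(origin_mm, dtype=float)
    h = float(np.min(mask.spacing))
    n_half = int(np.ceil(radius_mm / h))
    offs = np.arange(-n_half, n_half + 1) * h
    A, B = np.meshgrid(offs, offs, indexing="ij")
    keep = (A ** 2 + B ** 2) <= radius_mm ** 2
    a = np.zeros(3)
    a[int(np.argmin(np.abs(normal)))] = 1.0
    u = np.cross(normal, a)
    u /= np.linalg.norm(u)
    v = np.cross(normal, u)
    coords = origin[None, :] + A[keep][:, None] * u + B[keep][:, None] * v
    labels = mask.label_at(coords)
    sec = CrossSection(origin=origin, normal=normal, coords=coords,
                       labels=labels, dA=h * h, index=-1, arclength=0.0)
    fc = section_flow(fld, sec, label)
    if fc.is_empty:
        log.warning("branch plane at %s misses label %r", origin, label)
    return fc


def summarize_regions(fld: VelocityField4D, mask: LumenMask, cl: Centerline,
                      sections, stasis_threshold_ms: float = STASIS_THRESHOLD_MS,
                      region_labels=None) -> FlowSummary:
    """Region-level FlowSummary from per-section flux curves.

    Per region, the per-cycle volumes are averaged over the sections
    that contain samples of that region's label (unweighted mean along
    the centerline); FL stasis is the mean stasis-map value over the
    false-lumen voxels.
    """
    from .fields import LABELS
    if region_labels is None:
        region_labels = {"ascending": LABELS["ascending"],
                         "true_lumen": LABELS["true_lumen"],
                         "false_lumen": LABELS["false_lumen"]}
    smap = stasis_map(fld, mask, stasis_threshold_ms)
    regions = {}
    for name, code in region_labels.items():
        nets, fwds, revs = [], [], []
        for sec in sections:
            fc = section_flow(fld, sec, code)
            if fc.is_empty:
                continue
            nets.append(fc.net_ml)
            fwds.append(fc.forward_ml)
            revs.append(fc.reverse_ml)
        if not nets:
            continue
        regions[name] = {
            "net_ml": float(np.mean(nets)),
            "forward_ml": float(np.mean(fwds)),
            "reverse_ml": float(np.mean(revs)),
            "stasis_pct": smap.masked_mean(mask.region(code)),
            "n_sections": len(nets),
        }
    return FlowSummary(regions=regions)
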