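"""Synthetic 4D flow phantoms with analytic ground truth.

The phantoms emulate the statistical and physical structure the analysis
assumes in dissected-aorta 4D Flow data: pulsatile laminar flow with a
known flow-rate waveform, a two-lumen dissection geometry with an
entry-tear jet, a helical (rigid-rotation) flow component with known
helicity, low-velocity stasis pockets, additive Gaussian velocity noise,
and localized high-spatial-gradient "stent" noise.  Every generated
field ships with closed-form ground truth so the quantification modules
can be validated without patient data.

Units follow the package convention: velocities m/s, geometry mm, flows
mL/s, per-cycle volumes mL.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dc_field
from typing import Optional

import numpy as np
from scipy import stats as sps

from .errors import ParameterError, SizingError
from .fields import LABELS, LumenMask, VelocityField4D

GEOMETRIES = ("straight-tube", "u-bend", "two-lumen-dissection")
WAVEFORMS = ("steady", "sinusoid", "systolic-pulse")

# systolic-pulse shape coefficients: sin^2 systolic lobe over the first
# SYSTOLE_FRACTION of the RR interval, small constant diastolic runoff.
SYSTOLE_FRACTION = 0.35
DIASTOLIC_LEVEL = 0.05


@dataclass
class PhantomSpec:
    """Parameters of a synthetic phantom.

    Defaults mirror a typical aortic 4D Flow acquisition: 2.5 mm
    isotropic voxels, 20 reconstructed cardiac phases, VENC 150 cm/s.
    """

    geometry: str = "straight-tube"
    radius_mm: float = 10.0
    bend_radius_mm: float = 40.0
    septum_voxels: int = 1
    spacing_mm: float = 2.5
    n_phases: int = 20
    rr_ms: float = 1000.0
    peak_velocity_ms: float = 1.0
    waveform: str = "steady"
    angular_velocity_rads: float = 0.0
    axial_profile: str = "parabolic"
    noise_sd_ms: float = 0.0
    venc_cms: float = 150.0
    length_mm: float = 160.0
    margin_mm: float = 6.0
    seed: int = 0

    def validate(self) -> None:
        if self.geometry not in GEOMETRIES:
            raise ParameterError(f"unknown geometry {self.geometry!r}")
        if self.waveform not in WAVEFORMS:
            raise ParameterError(f"unknown waveform {self.waveform!r}")
        if self.spacing_mm <= 0:
            raise ParameterError("spacing must be > 0")
        if self.n_phases < 1:
            raise ParameterError("need at least one cardiac phase")
        if self.waveform != "steady" and self.n_phases < 2:
            raise ParameterError("pulsatile waveforms need >= 2 phases")
        if self.radius_mm < 2 * self.spacing_mm:
            raise SizingError(
                f"lumen radius {self.radius_mm} mm under-resolved at "
                f"{self.spacing_mm} mm spacing (need radius >= 2*spacing)")
        if self.noise_sd_ms < 0:
            raise ParameterError("noise SD must be >= 0")

    @property
    def phase_duration_ms(self) -> float:
        return self.rr_ms / self.n_phases

    def waveform_samples(self) -> np.ndarray:
        """Waveform values at phase centers over one RR interval."""
        t = (np.arange(self.n_phases) + 0.5) / self.n_phases
        return waveform_function(self.waveform)(t)


def waveform_function(kind: str):
    """Return w(t_norm) on [0, 1): dimensionless flow-rate shape."""
    if kind == "steady":
        return lambda t: np.ones_like(np.asarray(t, dtype=float))
    if kind == "sinusoid":
        return lambda t: np.sin(2 * np.pi * np.asarray(t, dtype=float))
    if kind == "systolic-pulse":
        def w(t):
            t = np.asarray(t, dtype=float)
            out = np.full_like(t, DIASTOLIC_LEVEL)
            sys = t < SYSTOLE_FRACTION
            out[sys] = np.sin(np.pi * t[sys] / SYSTOLE_FRACTION) ** 2
            return out
        return w
    raise ParameterError(f"unknown waveform {kind!r}")


@dataclass
class GroundTruth:
    """Analytic truth accompanying a phantom.

    ``flow_mls`` holds the per-region flow-rate waveform (mL/s per
    phase); ``forward_ml``/``reverse_ml``/``net_ml`` the per-cycle
    volumes (reverse carried as a negative number so net = forward +
    reverse); ``stasis_pct`` the expected stasis percentage per region
    *under the generator's own noise model* (the noise-free value is in
    ``stasis_pct_noiseless``); ``helicity_density_ms2`` the mean
    helicity density v.(curl v) where the phantom defines one.
    """

    flow_mls: dict = dc_field(default_factory=dict)
    forward_ml: dict = dc_field(default_factory=dict)
    reverse_ml: dict = dc_field(default_factory=dict)
    net_ml: dict = dc_field(default_factory=dict)
    fractions: dict = dc_field(default_factory=dict)
    stasis_pct: dict = dc_field(default_factory=dict)
    stasis_pct_noiseless: dict = dc_field(default_factory=dict)
    helicity_density_ms2: Optional[float] = None
    stent_voxels: Optional[np.ndarray] = None
    meta: dict = dc_field(default_factory=dict)

    def check_consistency(self, atol: float = 1e-9) -> None:
        for region in self.net_ml:
            if not np.isclose(self.net_ml[region],
                              self.forward_ml[region] + self.reverse_ml[region],
                              atol=atol):
                raise AssertionError(
                    f"ground truth inconsistent for {region}: net != fwd+rev")

    def to_dict(self) -> dict:
        d = {
            "flow_mls": {k: np.asarray(v).tolist() for k, v in self.flow_mls.items()},
            "forward_ml": self.forward_ml,
            "reverse_ml": self.reverse_ml,
            "net_ml": self.net_ml,
            "fractions": self.fractions,
            "stasis_pct": self.stasis_pct,
            "stasis_pct_noiseless": self.stasis_pct_noiseless,
            "helicity_density_ms2": self.helicity_density_ms2,
            "stent_voxels": (None if self.stent_voxels is None
                             else np.asarray(self.stent_voxels).tolist()),
            "meta": self.meta,
        }
        return d


def expected_stasis_pct(true_speeds: np.ndarray, noise_sd: float,
                        threshold: float = 0.1) -> float:
    """Expected percentage of (voxel, phase) samples with speed < threshold.

    With isotropic Gaussian noise of SD sigma on each component, the
    measured squared speed given true speed s follows sigma^2 times a
    noncentral chi-square with 3 dof and noncentrality (s/sigma)^2, so
    the per-sample stasis probability has a closed form. sigma = 0
    degenerates to the indicator.
    """
    s = np.asarray(true_speeds, dtype=float)
    if s.size == 0:
        return float("nan")
    if noise_sd <= 0:
        return float(np.mean(s < threshold) * 100.0)
    q = (threshold / noise_sd) ** 2
    nc = (s / noise_sd) ** 2
    return float(np.mean(sps.ncx2.cdf(q, 3, nc)) * 100.0)


# ----------------------------------------------------------------------
# grid helpers

def _straight_grid(spec: PhantomSpec, half_width_mm: float):
    sp = spec.spacing_mm
    n_xy = int(np.ceil(2 * half_width_mm / sp)) + 1
    if n_xy % 2 == 0:
        n_xy += 1  # odd count puts the tube axis on voxel centers
    nz = int(np.ceil(spec.length_mm / sp)) + 1
    x = (np.arange(n_xy) - (n_xy - 1) / 2) * sp
    z = np.arange(nz) * sp
    affine = np.diag([sp, sp, sp, 1.0])
    affine[0, 3] = x[0]
    affine[1, 3] = x[0]
    affine[2, 3] = 0.0
    X, Y, Z = np.meshgrid(x, x, z, indexing="ij")
    return X, Y, Z, affine


def _assemble_field(vx, vy, vz, spec: PhantomSpec, affine, rng) -> VelocityField4D:
    values = np.stack([vx, vy, vz], axis=3)  # (nx,ny,nz,3,T)
    if spec.noise_sd_ms > 0:
        values = values + rng.normal(0.0, spec.noise_sd_ms, size=values.shape)
    return VelocityField4D(values=values, affine=affine,
                           phase_duration_ms=spec.phase_duration_ms,
                           venc_cms=spec.venc_cms)


def _default_landmarks(length_mm: float, z_asc_end: float | None = None) -> dict:
    z1 = z_asc_end if z_asc_end is not None else 0.25 * length_mm
    return {
        "seed": [0.0, 0.0, 0.0],
        "ascending_reference": [0.0, 0.0, round(0.5 * z1, 3)],
        "left_subclavian": [0.0, 0.0, round(min(z1 + 5.0, length_mm), 3)],
        "celiac_trunk": [0.0, 0.0, round(0.9 * length_mm, 3)],
    }


# ----------------------------------------------------------------------
# phantom builders

def make_tube_phantom(spec: PhantomSpec):
    """Pulsatile parabolic (Poiseuille) flow in a straight or U-bend tube.

    The axial velocity is v(r, t) = v_peak (1 - r^2/R^2) w(t); the
    analytic flow rate is Q(t) = w(t) v_peak pi R^2 / 2 (in mL/s for
    v_peak in m/s, R in mm).

    Returns
    -------
    (VelocityField4D, LumenMask, GroundTruth)
    """
    spec.validate()
    if spec.geometry not in ("straight-tube", "u-bend"):
        raise ParameterError("make_tube_phantom handles straight-tube/u-bend")
    rng = np.random.default_rng(spec.seed)
    R = spec.radius_mm
    w = spec.waveform_samples()
    T = spec.n_phases

    if spec.geometry == "straight-tube":
        X, Y, Z, affine = _straight_grid(spec, R + spec.margin_mm)
        r2 = X ** 2 + Y ** 2
        inside = r2 <= R ** 2
        profile = np.where(inside, spec.peak_velocity_ms * (1 - r2 / R ** 2), 0.0)
        vz = profile[..., None] * w  # (nx, ny, nz, T)
        zeros = np.zeros(inside.shape + (T,))
        fld = _assemble_field(zeros, zeros.copy(), vz, spec, affine, rng)
        axis_info = {"kind": "straight", "axis_point": [0.0, 0.0, 0.0],
                     "axis_direction": [0.0, 0.0, 1.0],
                     "length_mm": float(Z.max())}
        landmarks = _default_landmarks(float(Z.max()))
    else:  # u-bend: half-torus in the x-z plane with straight legs below
        Rb = spec.bend_radius_mm
        if Rb <= R:
            raise ParameterError("bend radius must exceed lumen radius")
        sp = spec.spacing_mm
        leg = 2 * R  # straight inflow/outflow legs keep thinning end
        # erosion away from the bend itself
        half = Rb + R + spec.margin_mm
        n_x = int(np.ceil(2 * half / sp)) + 1
        n_y = int(np.ceil(2 * (R + spec.margin_mm) / sp)) + 1
        n_z = int(np.ceil((Rb + R + leg + 2 * spec.margin_mm) / sp)) + 1
        n_x += 1 - n_x % 2  # tube plane y=0 and bend center on voxel centers
        n_y += 1 - n_y % 2
        xs = (np.arange(n_x) - (n_x - 1) / 2) * sp
        ys = (np.arange(n_y) - (n_y - 1) / 2) * sp
        zs = np.arange(n_z) * sp - (leg + spec.margin_mm)
        affine = np.diag([sp, sp, sp, 1.0])
        affine[:3, 3] = [xs[0], ys[0], zs[0]]
        X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij")
        rho = np.sqrt(X ** 2 + Z ** 2)
        d2_bend = (rho - Rb) ** 2 + Y ** 2
        in_bend = (d2_bend <= R ** 2) & (Z >= 0)
        d2_in = (X - Rb) ** 2 + Y ** 2  # inflow leg at x=+Rb, flow +z
        d2_out = (X + Rb) ** 2 + Y ** 2  # outflow leg at x=-Rb, flow -z
        in_leg_in = (d2_in <= R ** 2) & (Z < 0)
        in_leg_out = (d2_out <= R ** 2) & (Z < 0)
        inside = in_bend | in_leg_in | in_leg_out
        d2 = np.where(in_bend, d2_bend,
                      np.where(in_leg_in, d2_in,
                               np.where(in_leg_out, d2_out, R ** 2)))
        profile = np.where(inside, spec.peak_velocity_ms * (1 - d2 / R ** 2), 0.0)
        theta = np.arctan2(Z, X)
        tx = np.where(in_bend, -np.sin(theta), 0.0)
        tz = np.where(in_bend, np.cos(theta),
                      np.where(in_leg_in, 1.0,
                               np.where(in_leg_out, -1.0, 0.0)))
        vx = (profile * tx)[..., None] * w
        vz = (profile * tz)[..., None] * w
        vy = np.zeros_like(vx)
        fld = _assemble_field(vx, vy, vz, spec, affine, rng)
        axis_info = {"kind": "u-bend", "bend_radius_mm": Rb,
                     "bend_center": [0.0, 0.0, 0.0],
                     "bend_arclength_mm": float(np.pi * Rb),
                     "leg_length_mm": float(leg)}
        landmarks = {"seed": [Rb, 0.0, float(zs[0])]}

    labels = np.where(inside, LABELS["true_lumen"], 0).astype(np.int16)
    mask = LumenMask(labels, affine)

    q = w * spec.peak_velocity_ms * np.pi * R ** 2 / 2.0  # mL/s
    dt = spec.phase_duration_ms / 1000.0
    fwd = float(np.sum(np.maximum(q, 0.0)) * dt)
    rev = float(np.sum(np.minimum(q, 0.0)) * dt)

    speeds = np.abs(profile[inside][:, None] * np.abs(w)[None, :])
    gt = GroundTruth(
        flow_mls={"true_lumen": q},
        forward_ml={"true_lumen": fwd},
        reverse_ml={"true_lumen": rev},
        net_ml={"true_lumen": fwd + rev},
        stasis_pct={"true_lumen": expected_stasis_pct(speeds, spec.noise_sd_ms)},
        stasis_pct_noiseless={"true_lumen": expected_stasis_pct(speeds, 0.0)},
        helicity_density_ms2=None,
        meta={"spec": vars(spec).copy(), "geometry": axis_info,
              "landmarks": landmarks},
    )
    gt.check_consistency()
    return fld, mask, gt


def make_helical_phantom(spec: PhantomSpec, axial_profile: str | None = None):
    """Rigid rotation about the tube axis superposed on axial flow.

    In-plane velocity is Omega x r; the vorticity of that component is
    exactly 2 Omega along the axis.  With a *uniform* axial velocity
    v_z the helicity density is 2 Omega v_z everywhere; with a
    *parabolic* axial profile v_z(r) = v0 (1 - r^2/R^2) the in-plane
    vorticity contributes Omega r . grad v_z and the helicity density is
    again the constant 2 Omega v0 (the radial terms cancel), but the
    velocity field is quadratic, so finite-difference errors at the mask
    boundary are genuine — that variant is the discretization-
    convergence workhorse.
    """
    spec.validate()
    if spec.geometry != "straight-tube":
        raise ParameterError("helical phantom is defined on a straight tube")
    profile_kind = axial_profile or "uniform"
    if profile_kind not in ("uniform", "parabolic"):
        raise ParameterError(f"unknown axial profile {profile_kind!r}")
    rng = np.random.default_rng(spec.seed)
    R = spec.radius_mm
    omega = spec.angular_velocity_rads
    w = spec.waveform_samples()
    T = spec.n_phases

    if spec.venc_cms is not None and abs(omega) * R / 1000.0 * 100.0 > spec.venc_cms:
        warnings.warn("in-plane rotational speed exceeds VENC: such a field "
                      "would alias in a real acquisition", stacklevel=2)

    X, Y, Z, affine = _straight_grid(spec, R + spec.margin_mm)
    r2 = X ** 2 + Y ** 2
    inside = r2 <= R ** 2
    if profile_kind == "uniform":
        axial = np.where(inside, spec.peak_velocity_ms, 0.0)
        q0 = spec.peak_velocity_ms * np.pi * R ** 2
    else:
        axial = np.where(inside, spec.peak_velocity_ms * (1 - r2 / R ** 2), 0.0)
        q0 = spec.peak_velocity_ms * np.pi * R ** 2 / 2.0
    # in-plane rigid rotation: Omega (rad/s) x r (m)
    vx0 = np.where(inside, -omega * Y / 1000.0, 0.0)
    vy0 = np.where(inside, omega * X / 1000.0, 0.0)
    vx = vx0[..., None] * w
    vy = vy0[..., None] * w
    vz = axial[..., None] * w
    fld = _assemble_field(vx, vy, vz, spec, affine, rng)
    labels = np.where(inside, LABELS["true_lumen"], 0).astype(np.int16)
    mask = LumenMask(labels, affine)

    q = w * q0
    dt = spec.phase_duration_ms / 1000.0
    fwd = float(np.sum(np.maximum(q, 0.0)) * dt)
    rev = float(np.sum(np.minimum(q, 0.0)) * dt)
    h_mean = 2.0 * omega * spec.peak_velocity_ms * float(np.mean(w ** 2))

    speeds = np.sqrt(vx0 ** 2 + vy0 ** 2 + axial ** 2)[inside][:, None] * np.abs(w)
    gt = GroundTruth(
        flow_mls={"true_lumen": q},
        forward_ml={"true_lumen": fwd},
        reverse_ml={"true_lumen": rev},
        net_ml={"true_lumen": fwd + rev},
        stasis_pct={"true_lumen": expected_stasis_pct(speeds, spec.noise_sd_ms)},
        stasis_pct_noiseless={"true_lumen": expected_stasis_pct(speeds, 0.0)},
        helicity_density_ms2=h_mean,
        meta={"spec": vars(spec).copy(),
              "axial_profile": profile_kind,
              "landmarks": _default_landmarks(float(Z.max()))},
    )
    gt.check_consistency()
    return fld, mask, gt


def make_dissection_phantom(spec: PhantomSpec, tl_fraction: float,
                            fl_reverse_fraction: float,
                            total_volume_ml: float = 70.0,
                            jet_velocity_ms: float = 0.0,
                            pocket_fraction: float = 0.25,
                            pocket_scale: float = 0.05,
                            branch_fraction: float = 0.0):
    """Two-lumen dissection: TL and FL separated by a zero-velocity septum.

    A proximal segment (first quarter of the vessel) is a single lumen
    labeled as ascending aorta carrying the summed inflow; distal to it
    the disk is split by a planar septum into true lumen (x < 0) and
    false lumen (x > 0).

    Flow split: the true lumen carries ``tl_fraction`` of the per-cycle
    inflow ``total_volume_ml`` forward (shaped by the spec waveform); the
    false lumen carries the remainder, of which ``fl_reverse_fraction``
    flows retrograde: FL forward volume = (1-tl)(1-r) V, FL reverse
    volume = (1-tl) r V (the FL waveform is piecewise constant, forward
    over the first phases and reverse over the rest, so the volumes are
    met exactly).

    Options: an entry-tear jet (``jet_velocity_ms`` > 0, transverse flow
    through a mid-vessel septum gap), a distal low-velocity FL stasis
    pocket (velocities scaled by ``pocket_scale`` over the distal
    ``pocket_fraction`` of the dissected segment), and a side branch
    carrying ``branch_fraction`` of the inflow.
    """
    spec.validate()
    if not (0.0 < tl_fraction <= 1.0):
        raise ParameterError("tl_fraction must be in (0, 1]")
    if not (0.0 <= fl_reverse_fraction <= 1.0):
        raise ParameterError("fl_reverse_fraction must be in [0, 1]")
    if total_volume_ml <= 0:
        raise ParameterError("total_volume_ml must be > 0")
    rng = np.random.default_rng(spec.seed)
    R = spec.radius_mm
    sp = spec.spacing_mm
    T = spec.n_phases
    dt = spec.phase_duration_ms / 1000.0

    half_width = R + spec.margin_mm
    if branch_fraction > 0:
        half_width = R + 25.0 + spec.margin_mm  # room for the side branch
    X, Y, Z, affine = _straight_grid(spec, half_width)
    r2 = X ** 2 + Y ** 2
    disk = r2 <= R ** 2
    length = float(Z.max())
    z_asc = 0.25 * length
    sept_half = spec.septum_voxels * sp / 2.0

    asc = disk & (Z < z_asc)
    dissected = disk & (Z >= z_asc)
    septum = dissected & (np.abs(X) < sept_half)
    tl = dissected & (X <= -sept_half)
    fl = dissected & (X >= sept_half)

    labels = np.zeros(X.shape, dtype=np.int16)
    labels[asc] = LABELS["ascending"]
    labels[tl] = LABELS["true_lumen"]
    labels[fl] = LABELS["false_lumen"]

    # entry tear: transverse gap through the septum, mid-dissected segment
    tear = np.zeros_like(disk)
    if jet_velocity_ms > 0:
        z_t0 = z_asc + 0.3 * (length - z_asc)
        tear = septum & (Z >= z_t0) & (Z < z_t0 + 10.0) & (r2 <= (0.6 * R) ** 2)
        labels[tear] = LABELS["false_lumen"]

    voxel_area = sp * sp  # mm^2 per voxel in a z-normal plane
    nz_ref = labels.shape[2] // 2  # any dissected, non-pocket slice
    a_tl = float(np.sum(tl[:, :, nz_ref]) * voxel_area)
    a_fl = float(np.sum(fl[:, :, nz_ref]) * voxel_area)
    a_asc = float(np.sum(asc[:, :, labels.shape[2] // 8]) * voxel_area)
    if a_tl == 0 or a_fl == 0:
        raise SizingError("lumen halves unresolved: enlarge radius or "
                          "reduce septum thickness")

    # Smooth in-plane profiles, zero at the walls and at the septum, so
    # trilinear flux sampling sees no jump discontinuity; each profile
    # is normalized by its *discrete* slice integral, which makes the
    # target flow waveforms exact for the rasterized field.
    f_disk = np.clip(1.0 - r2 / R ** 2, 0.0, None)
    ramp = np.clip((np.abs(X) - sept_half) / (2 * sp), 0.0, 1.0)
    f_half = f_disk * ramp
    F_tl = float(np.sum(np.where(tl, f_half, 0.0)[:, :, nz_ref]) * voxel_area)
    F_fl = float(np.sum(np.where(fl, f_half, 0.0)[:, :, nz_ref]) * voxel_area)
    F_asc = float(np.sum(np.where(asc, f_disk, 0.0)
                         [:, :, labels.shape[2] // 8]) * voxel_area)

    # true-lumen waveform: spec waveform shape, scaled to the volume target
    w = spec.waveform_samples()
    if spec.waveform == "steady":
        w = np.ones(T)
    denom = float(np.sum(w) * dt)
    if denom <= 0:
        raise ParameterError("waveform must carry net forward volume for "
                             "the true lumen")
    u_tl = (tl_fraction * total_volume_ml / (F_tl * denom)) * w  # m/s scale

    # false-lumen piecewise-constant waveform meeting the volume targets:
    # forward over the first phases, retrograde over the rest
    fl_total = (1.0 - tl_fraction) * total_volume_ml
    fwd_target = fl_total * (1.0 - fl_reverse_fraction)
    rev_target = fl_total * fl_reverse_fraction
    k_fwd = int(round(T * (1.0 - fl_reverse_fraction)))
    if fwd_target > 0 and k_fwd == 0:
        k_fwd = 1
    if rev_target > 0 and k_fwd == T:
        k_fwd = T - 1
    u_fl = np.zeros(T)
    if fwd_target > 0:
        u_fl[:k_fwd] = fwd_target / (F_fl * k_fwd * dt)
    if rev_target > 0:
        u_fl[k_fwd:] = -rev_target / (F_fl * (T - k_fwd) * dt)

    q_tl = u_tl * F_tl
    q_fl = u_fl * F_fl
    u_asc = (q_tl + q_fl) / F_asc

    vz = np.zeros(X.shape + (T,))
    vz[asc] = f_disk[asc][:, None] * u_asc
    vz[tl] = f_half[tl][:, None] * u_tl
    vz[fl] = f_half[fl][:, None] * u_fl
    vx = np.zeros_like(vz)
    vy = np.zeros_like(vz)

    # distal FL stasis pocket: velocities scaled toward zero
    pocket = np.zeros_like(disk)
    z_pocket = length
    if pocket_fraction > 0:
        z_pocket = z_asc + (1.0 - pocket_fraction) * (length - z_asc)
        pocket = fl & (Z >= z_pocket)
        vz[pocket] *= pocket_scale

    if jet_velocity_ms > 0:
        vx[tear] = jet_velocity_ms * (w / max(float(np.max(np.abs(w))), 1e-12))

    # optional side branch along +x off the descending segment
    branch = np.zeros_like(disk)
    q_branch = np.zeros(T)
    if branch_fraction > 0:
        rb = max(5.0, 2 * sp)
        z_b = z_asc + 10.0
        branch = ((Z - z_b) ** 2 + Y ** 2 <= rb ** 2) & (X > 0) & \
                 (X <= R + 25.0) & ~disk
        labels[branch] = LABELS["branch_1"]
        # parabolic branch profile normalized on a complete x-slice
        # (slices with x > R are not clipped by the main vessel)
        f_b = np.clip(1.0 - ((Z - z_b) ** 2 + Y ** 2) / rb ** 2, 0.0, None)
        xs = np.unique(X[branch & (X > R + sp)])
        mid_x = xs[len(xs) // 2]
        F_b = float(np.sum(np.where(branch & np.isclose(X, mid_x), f_b, 0.0))
                    * voxel_area)
        q_branch = branch_fraction * (q_tl + q_fl)
        vx[branch] = f_b[branch][:, None] * (q_branch / F_b)

    fld = _assemble_field(vx, vy, vz, spec, affine, rng)
    mask = LumenMask(labels, affine)

    def _vols(q):
        f = float(np.sum(np.maximum(q, 0.0)) * dt)
        r = float(np.sum(np.minimum(q, 0.0)) * dt)
        return f, r

    regions = {"ascending": q_tl + q_fl, "true_lumen": q_tl,
               "false_lumen": q_fl}
    if branch_fraction > 0:
        regions["branch_1"] = q_branch
    fwd_ml, rev_ml, net_ml = {}, {}, {}
    for name, q in regions.items():
        f, r = _vols(q)
        fwd_ml[name], rev_ml[name], net_ml[name] = f, r, f + r

    sigma = spec.noise_sd_ms
    speed_nf = np.sqrt(vx ** 2 + vy ** 2 + vz ** 2)  # noise-free speeds
    speed_sets = {
        "ascending": speed_nf[asc],
        "true_lumen": speed_nf[tl],
        "false_lumen": speed_nf[fl | tear],
        "fl_pocket": speed_nf[pocket] if np.any(pocket) else np.zeros((0, T)),
    }
    stasis = {k: expected_stasis_pct(v, sigma) for k, v in speed_sets.items()}
    stasis0 = {k: expected_stasis_pct(v, 0.0) for k, v in speed_sets.items()}

    gt = GroundTruth(
        flow_mls={k: v for k, v in regions.items()},
        forward_ml=fwd_ml, reverse_ml=rev_ml, net_ml=net_ml,
        fractions={
            "tl_forward": fwd_ml["true_lumen"] / total_volume_ml,
            "tl_reverse": -rev_ml["true_lumen"] / total_volume_ml,
            "fl_forward": fwd_ml["false_lumen"] / total_volume_ml,
            "fl_reverse": -rev_ml["false_lumen"] / total_volume_ml,
        },
        stasis_pct=stasis, stasis_pct_noiseless=stasis0,
        helicity_density_ms2=None,
        meta={
            "spec": vars(spec).copy(),
            "tl_fraction": tl_fraction,
            "fl_reverse_fraction": fl_reverse_fraction,
            "total_volume_ml": total_volume_ml,
            "areas_mm2": {"ascending": a_asc, "true_lumen": a_tl,
                          "false_lumen": a_fl},
            "z_ascending_end_mm": z_asc,
            "z_pocket_start_mm": z_pocket,
            "pocket_scale": pocket_scale,
            "n_pocket_voxels": int(np.sum(pocket)),
            "jet_velocity_ms": jet_velocity_ms,
            "landmarks": _default_landmarks(length, z_asc_end=z_asc),
        },
    )
    gt.check_consistency()
    return fld, mask, gt


def inject_stent_noise(fld: VelocityField4D, region, amplitude_ms: float,
                       seed: int = 0,
                       ground_truth: GroundTruth | None = None) -> VelocityField4D:
    """Corrupt the FH velocity in a voxel region with stent-like noise.

    The perturbation alternates sign on the voxel parity checkerboard
    and from phase to phase, producing the high spatial gradients
    (summed over time) that the stent-artifact detector looks for.  All
    voxels outside ``region`` are bit-identical to the input; the
    corrupted voxel list is recorded on ``ground_truth`` when given.

    ``region`` is either an (N, 3) integer index array or a boolean
    grid mask.
    """
    region = np.asarray(region)
    if region.dtype == bool:
        idx = np.argwhere(region)
    else:
        idx = np.atleast_2d(region).astype(int)
    out = fld.copy()
    if idx.size == 0:
        warnings.warn("empty stent-noise region: returning unmodified copy",
                      stacklevel=2)
        return out
    if np.any(idx < 0) or np.any(idx >= np.array(fld.grid_shape)):
        raise ParameterError("stent-noise region extends outside the grid")
    if amplitude_ms < 0:
        raise ParameterError("amplitude must be >= 0")
    if amplitude_ms == 0:
        return out

    rng = np.random.default_rng(seed)
    T = fld.n_phases
    parity = (-1.0) ** (idx.sum(axis=1))  # (N,)
    phase_sign = (-1.0) ** np.arange(T)  # (T,)
    jitter = 1.0 + 0.25 * np.abs(rng.standard_normal((len(idx), T)))
    delta = amplitude_ms * parity[:, None] * phase_sign[None, :] * jitter
    out.values[idx[:, 0], idx[:, 1], idx[:, 2], 2, :] += delta
    if ground_truth is not None:
        ground_truth.stent_voxels = idx.copy()
    return out
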