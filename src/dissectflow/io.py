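"""NIfTI / JSON / CSV input-output.

Velocity fields travel either as three 4-D NIfTI files (one per
anatomical component, RL / AP / FH) or as a single 5-D file with the
component on the last axis. Acquisition metadata that NIfTI cannot carry
(VENC, component-to-axis mapping) lives in a JSON sidecar written next
to the images.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .errors import FormatError
from .fields import COMPONENT_NAMES, LandmarkSet, LumenMask, VelocityField4D

_SIDECAR_SUFFIX = ".json"


def _load_nifti(path):
    path = Path(path)
    if not path.exists():
        raise FormatError(f"file not found: {path}")
    return nib.load(str(path))


def write_velocity(fld: VelocityField4D, out_dir, basename="velocity",
                   single_file: bool = False) -> list:
    """Write a velocity field as NIfTI plus a JSON metadata sidecar.

    Returns the list of paths written. ``single_file=True`` writes one
    5-D image (x, y, z, phase, component); otherwise one 4-D image per
    component named ``<basename>_RL/_AP/_FH``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    data = np.moveaxis(fld.values, 3, 4).astype(np.float32)  # (x,y,z,t,c)
    if single_file:
        img = nib.Nifti1Image(data, fld.affine)
        img.header["pixdim"][4] = fld.phase_duration_ms
        p = out_dir / f"{basename}.nii.gz"
        img.to_filename(str(p))
        paths.append(p)
    else:
        for c, name in enumerate(COMPONENT_NAMES):
            img = nib.Nifti1Image(data[..., c], fld.affine)
            img.header["pixdim"][4] = fld.phase_duration_ms
            p = out_dir / f"{basename}_{name}.nii.gz"
            img.to_filename(str(p))
            paths.append(p)
    meta = {
        "phase_duration_ms": fld.phase_duration_ms,
        "venc_cms": None if fld.venc_cms is None else list(np.asarray(fld.venc_cms)),
        "component_axes": list(fld.component_axes),
        "component_order": list(COMPONENT_NAMES),
    }
    sidecar = out_dir / f"{basename}{_SIDECAR_SUFFIX}"
    sidecar.write_text(json.dumps(meta, indent=2, sort_keys=True) + "\n")
    paths.append(sidecar)
    return paths


def read_velocity(paths, metadata=None) -> VelocityField4D:
    """Assemble a :class:`VelocityField4D` from NIfTI file(s).

    Parameters
    ----------
    paths : path or sequence of 3 paths
        A single 5-D file, or the three per-component 4-D files in
        RL, AP, FH order.
    metadata : dict or path, optional
        Sidecar metadata (``phase_duration_ms``, ``venc_cms``,
        ``component_axes``). If omitted, a ``<basename>.json`` sidecar
        next to the (first) image is used when present.
    """
    if isinstance(paths, (str, Path)):
        paths = [paths]
    paths = [Path(p) for p in paths]

    if metadata is None:
        guess = paths[0].parent / (paths[0].name.split("_")[0].split(".")[0]
                                   + _SIDECAR_SUFFIX)
        metadata = guess if guess.exists() else {}
    if isinstance(metadata, (str, Path)):
        metadata = json.loads(Path(metadata).read_text())

    if len(paths) == 1:
        img = _load_nifti(paths[0])
        data = np.asanyarray(img.dataobj)
        if data.ndim != 5 or data.shape[4] != 3:
            raise FormatError(
                f"{paths[0]}: expected 5-D (x,y,z,t,component) data, "
                f"got shape {data.shape}")
        values = np.moveaxis(data, 4, 3).astype(float)
        affine = img.affine
        header_dt = float(img.header["pixdim"][4])
    elif len(paths) == 3:
        comps, affine, header_dt = [], None, 0.0
        shape = None
        for p in paths:
            img = _load_nifti(p)
            d = np.asanyarray(img.dataobj)
            if d.ndim != 4:
                raise FormatError(f"{p}: expected 4-D component data, "
                                  f"got shape {d.shape}")
            if shape is None:
                shape, affine = d.shape, img.affine
                header_dt = float(img.header["pixdim"][4])
            elif d.shape != shape:
                raise FormatError(
                    f"{p}: grid/phase mismatch {d.shape} vs {shape}")
            elif not np.allclose(img.affine, affine, atol=1e-4):
                raise FormatError(f"{p}: affine differs from first component")
            comps.append(d.astype(float))
        values = np.stack(comps, axis=3)
    else:
        raise FormatError("expected one 5-D file or three component files, "
                          f"got {len(paths)} paths")

    dt = float(metadata.get("phase_duration_ms", header_dt) or header_dt)
    if dt <= 0:
        raise FormatError(
            f"{paths[0]}: phase duration missing from header and metadata")
    venc = metadata.get("venc_cms")
    axes = tuple(metadata.get("component_axes", (0, 1, 2)))
    return VelocityField4D(values=values, affine=affine,
                           phase_duration_ms=dt, venc_cms=venc,
                           component_axes=axes)


def write_mask(mask: LumenMask, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    nib.Nifti1Image(mask.labels.astype(np.int16), mask.affine).to_filename(str(path))
    return path


def read_mask(path) -> LumenMask:
    img = _load_nifti(path)
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise FormatError(f"{path}: mask must be 3-D, got shape {data.shape}")
    return LumenMask(np.rint(data).astype(np.int16), img.affine)


def write_map(values: np.ndarray, affine: np.ndarray, path) -> Path:
    """Write a scalar parametric map (NaN background) as float32 NIfTI."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    nib.Nifti1Image(np.asarray(values, dtype=np.float32), affine).to_filename(str(path))
    return path


def write_landmarks(landmarks: LandmarkSet, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    payload = {k: [float(x) for x in np.asarray(v, float)]
               for k, v in landmarks.points.items()}
    path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
    return path


def read_landmarks(path) -> LandmarkSet:
    path = Path(path)
    if not path.exists():
        raise FormatError(f"file not found: {path}")
    raw = json.loads(path.read_text())
    return LandmarkSet({k: np.asarray(v, float) for k, v in raw.items()})


def write_json(obj, path) -> Path:
    """Serialize a plain dict (numbers/str/lists) deterministically."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)

    def _default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        raise TypeError(f"not JSON-serializable: {type(o)}")

    path.write_text(json.dumps(obj, indent=2, sort_keys=True,
                               default=_default, allow_nan=True) + "\n")
    return path


def read_json(path) -> dict:
    return json.loads(Path(path).read_text())


def write_table(df: pd.DataFrame, path) -> Path:
    """Tidy CSV output (one row per cross-section per phase and friends)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format="%.9g")
    return path
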