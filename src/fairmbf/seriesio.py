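"""NIfTI + JSON-sidecar interchange for FAIR series and derived maps.

A series is stored as one 3-D NIfTI volume of 13 frames (six control, six
tagged, M0 last, frames along the third axis) with the in-plane affine set
from the protocol's pixel size.  Timing and protocol metadata live in a
JSON sidecar next to the volume — transparent and diffable, unlike NIfTI
header extensions.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path
from typing import Optional, Tuple

import nibabel as nib
import numpy as np

from ._imageops import RigidTransform
from .phantom import GroundTruth
from .protocols import AcquisitionProtocol, FairSeries, ImageFrame
from .quantify import MBFMap

__all__ = ["write_series", "read_series", "write_ground_truth",
           "read_ground_truth", "write_mbf_map"]

_SIDE_FIELDS = ("protocol", "heart_rate_bpm", "blood_t1_ms", "frames")


def _affine(pixel_mm: Tuple[float, float], slice_mm: float) -> np.ndarray:
    return np.diag([pixel_mm[1], pixel_mm[0], slice_mm, 1.0])


def write_series(series: FairSeries, path: str, seed: Optional[int] = None) -> Path:
    """Write a FAIR series as ``<path>.nii`` plus ``<path>.json``."""
    path = Path(path)
    frames = series.frames()
    # nibabel stores (x, y, frame); pixels are (row=y, col=x)
    vol = np.stack([f.pixels.T for f in frames], axis=2)
    img = nib.Nifti1Image(vol, _affine(series.protocol.pixel_mm,
                                       series.protocol.slice_mm))
    nii_path = path.with_suffix(".nii")
    nib.save(img, str(nii_path))

    sidecar = {
        "protocol": json.loads(series.protocol.to_json()),
        "heart_rate_bpm": series.heart_rate_bpm,
        "blood_t1_ms": series.blood_t1_ms,
        "frames": [
            {"frame_type": f.frame_type, "index": f.index,
             "actual_ti_ms": f.actual_ti_ms}
            for f in frames
        ],
    }
    if seed is not None:
        sidecar["seed"] = int(seed)
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))
    return nii_path


def read_series(path: str) -> FairSeries:
    """Read a series written by :func:`write_series`, validating the sidecar."""
    path = Path(path)
    nii_path = path.with_suffix(".nii")
    json_path = path.with_suffix(".json")
    if not json_path.exists():
        raise FileNotFoundError(f"missing sidecar {json_path}")
    sidecar = json.loads(json_path.read_text())
    missing = [k for k in _SIDE_FIELDS if k not in sidecar]
    if missing:
        raise ValueError(f"sidecar missing required fields: {missing}")

    vol = np.asarray(nib.load(str(nii_path)).dataobj, dtype=float)
    if vol.ndim != 3 or vol.shape[2] != len(sidecar["frames"]):
        raise ValueError(
            f"volume has {vol.shape[2] if vol.ndim == 3 else '?'} frames but "
            f"sidecar lists {len(sidecar['frames'])}")

    protocol = AcquisitionProtocol.from_dict(sidecar["protocol"])
    frames = {"control": [], "tagged": [], "m0": []}
    for k, meta in enumerate(sidecar["frames"]):
        ftype = meta.get("frame_type")
        if ftype not in frames:
            raise ValueError(f"frame {k + 1}: unknown frame_type {ftype!r}")
        if ftype != "m0" and meta.get("actual_ti_ms") is None:
            raise ValueError(f"frame {k + 1}: actual_ti_ms missing")
        frames[ftype].append(ImageFrame(vol[:, :, k].T, ftype,
                                        meta.get("index"),
                                        meta.get("actual_ti_ms")))
    for name, want in (("control", 6), ("tagged", 6), ("m0", 1)):
        if len(frames[name]) != want:
            raise ValueError(
                f"expected {want} {name} frame(s), sidecar lists {len(frames[name])}")
    return FairSeries(protocol=protocol, controls=frames["control"],
                      taggeds=frames["tagged"], m0=frames["m0"][0],
                      heart_rate_bpm=float(sidecar["heart_rate_bpm"]),
                      blood_t1_ms=float(sidecar["blood_t1_ms"]))


def write_ground_truth(truth: GroundTruth, path: str,
                       pixel_mm=(2.0, 2.0), slice_mm=10.0) -> None:
    """Save truth as ``<path>_mbf.nii``, ``<path>_mask.nii`` and ``<path>.json``."""
    path = Path(path)
    aff = _affine(pixel_mm, slice_mm)
    nib.save(nib.Nifti1Image(truth.mbf_map.T[..., None], aff),
             str(path.parent / (path.name + "_mbf.nii")))
    nib.save(nib.Nifti1Image(truth.myo_mask.T[..., None].astype(np.uint8), aff),
             str(path.parent / (path.name + "_mask.nii")))
    log = {
        "injected_transforms": [asdict(t) for t in truth.injected_transforms],
        "actual_tis": truth.actual_tis,
        "mean_ti_control_ms": truth.mean_ti_control_ms,
        "mean_ti_tagged_ms": truth.mean_ti_tagged_ms,
    }
    (path.parent / (path.name + ".json")).write_text(json.dumps(log, indent=2))


def read_ground_truth(path: str) -> GroundTruth:
    path = Path(path)
    mbf = np.asarray(nib.load(str(path.parent / (path.name + "_mbf.nii"))).dataobj,
                     dtype=float)[:, :, 0].T
    mask = np.asarray(nib.load(str(path.parent / (path.name + "_mask.nii"))).dataobj
                      ).astype(bool)[:, :, 0].T
    log = json.loads((path.parent / (path.name + ".json")).read_text())
    return GroundTruth(
        mbf_map=mbf, myo_mask=mask,
        injected_transforms=[RigidTransform(**t) for t in log["injected_transforms"]],
        actual_tis=log["actual_tis"],
        mean_ti_control_ms=log["mean_ti_control_ms"],
        mean_ti_tagged_ms=log["mean_ti_tagged_ms"],
    )


def write_mbf_map(mbf: MBFMap, path: str, pixel_mm=(2.0, 2.0), slice_mm=10.0) -> Path:
    """Write an MBF map (NaN outside validity) as a single-slice NIfTI."""
    path = Path(path).with_suffix(".nii")
    nib.save(nib.Nifti1Image(mbf.values.T[..., None],
                             _affine(pixel_mm, slice_mm)), str(path))
    return path
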