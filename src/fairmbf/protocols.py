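"""Acquisition protocols and cardiac timing arithmetic.

A FAIR (flow-sensitive alternating inversion recovery) perfusion scan is
described here by the parameters of its single-shot bSSFP readout: cardiac
phase, acceleration method and factor, matrix/FOV geometry and the basic
sequence timings.  Three presets ship with the package:

* ``FAIR-PI2_D`` — diastolic acquisition, parallel imaging (SENSE) factor 2
* ``FAIR-PI2_S`` — systolic acquisition, parallel imaging factor 2
* ``FAIR-CS3_S`` — systolic acquisition, compressed sensing factor 3

The acquisition window (duration of the single-shot readout) follows from
TR x (phase-encode lines / acceleration factor); shortening it below the
cardiac rest period is what suppresses physiological noise in the
simulation model.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field, asdict
from enum import Enum
from pathlib import Path
from typing import Optional, Tuple

import numpy as np

__all__ = [
    "CardiacPhase",
    "AccelMethod",
    "AcquisitionProtocol",
    "ImageFrame",
    "FairSeries",
    "acquisition_window",
    "pair_duration",
    "get_protocol",
    "PROTOCOL_PRESETS",
    "BLOOD_T1_MS",
]

#: Longitudinal relaxation time of arterial blood at 3 T, in ms.
BLOOD_T1_MS = 1700.0


class CardiacPhase(str, Enum):
    DIASTOLE = "diastole"
    SYSTOLE = "systole"


class AccelMethod(str, Enum):
    PARALLEL_IMAGING = "parallel_imaging"
    COMPRESSED_SENSING = "compressed_sensing"
    NONE = "none"


@dataclass(frozen=True)
class AcquisitionProtocol:
    """One imaging strategy (phase, acceleration, geometry, timings).

    Times are in ms, lengths in mm, the flip angle in degrees.
    ``rest_period_ms`` is the duration of the quiescent cardiac window the
    readout is triggered into; it is a simulation parameter (the scanner
    determines it from cine images) and defaults per cardiac phase.
    """

    name: str
    cardiac_phase: CardiacPhase
    accel_method: AccelMethod
    accel_factor: float
    fov_mm: Tuple[float, float] = (300.0, 300.0)
    matrix: Tuple[int, int] = (150, 150)
    slice_mm: float = 10.0
    tr_ms: float = 2.2
    te_ms: float = 1.1
    flip_deg: float = 50.0
    nominal_ti_ms: float = 1000.0
    control_slab_mm: float = 30.0
    rest_period_ms: Optional[float] = None

    def __post_init__(self):
        if self.accel_factor < 1:
            raise ValueError(f"accel_factor must be >= 1, got {self.accel_factor}")
        for attr in ("tr_ms", "te_ms", "nominal_ti_ms", "slice_mm", "control_slab_mm"):
            if getattr(self, attr) <= 0:
                raise ValueError(f"{attr} must be > 0")
        if self.rest_period_ms is None:
            # End-systolic rest period ~80-100 ms; mid-diastolic longer at rest.
            default = 90.0 if self.cardiac_phase == CardiacPhase.SYSTOLE else 180.0
            object.__setattr__(self, "rest_period_ms", default)

    @property
    def pixel_mm(self) -> Tuple[float, float]:
        return (self.fov_mm[0] / self.matrix[0], self.fov_mm[1] / self.matrix[1])

    def to_json(self, path=None) -> str:
        doc = asdict(self)
        doc["cardiac_phase"] = self.cardiac_phase.value
        doc["accel_method"] = self.accel_method.value
        text = json.dumps(doc, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_dict(cls, doc: dict) -> "AcquisitionProtocol":
        doc = dict(doc)
        doc["cardiac_phase"] = CardiacPhase(doc["cardiac_phase"])
        doc["accel_method"] = AccelMethod(doc["accel_method"])
        doc["fov_mm"] = tuple(doc["fov_mm"])
        doc["matrix"] = tuple(doc["matrix"])
        return cls(**doc)

    @classmethod
    def from_json(cls, source) -> "AcquisitionProtocol":
        if isinstance(source, Path) or (
                isinstance(source, str) and not source.lstrip().startswith("{")):
            text = Path(source).read_text()
        else:
            text = source
        return cls.from_dict(json.loads(text))


@dataclass
class ImageFrame:
    """A single 2-D image with its type and actual inversion time.

    ``pixels`` holds signed signal intensities (arbitrary units); inverted
    magnetization is represented by negative values.  ``actual_ti_ms`` is the
    per-frame inversion delay realised by the cardiac gating and is ``None``
    for the unprepared M0 frame.
    """

    pixels: np.ndarray
    frame_type: str  # "control" | "tagged" | "m0"
    index: Optional[int] = None
    actual_ti_ms: Optional[float] = None

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2:
            raise ValueError("ImageFrame expects a 2-D pixel grid")
        if self.frame_type not in ("control", "tagged", "m0"):
            raise ValueError(f"unknown frame_type {self.frame_type!r}")
        if self.frame_type != "m0":
            if self.actual_ti_ms is None or self.actual_ti_ms <= 0:
                raise ValueError("control/tagged frames need actual_ti_ms > 0")

    @property
    def shape(self):
        return self.pixels.shape

    def copy(self) -> "ImageFrame":
        return ImageFrame(self.pixels.copy(), self.frame_type, self.index, self.actual_ti_ms)


@dataclass
class FairSeries:
    """Six control frames, six tagged frames and one M0 frame."""

    protocol: AcquisitionProtocol
    controls: list
    taggeds: list
    m0: ImageFrame
    heart_rate_bpm: float = 60.0
    blood_t1_ms: float = BLOOD_T1_MS

    def __post_init__(self):
        if len(self.controls) != 6 or len(self.taggeds) != 6:
            raise ValueError(
                f"a FAIR series needs 6 control and 6 tagged frames, "
                f"got {len(self.controls)} and {len(self.taggeds)}"
            )
        shapes = {f.shape for f in self.frames()}
        if len(shapes) != 1:
            raise ValueError(f"all frames must share one grid, got shapes {shapes}")

    def frames(self):
        return [*self.controls, *self.taggeds, self.m0]

    @property
    def shape(self):
        return self.m0.shape


def acquisition_window(protocol: AcquisitionProtocol) -> float:
    """Duration of the single-shot readout in ms: TR x lines / acceleration.

    The phase-encode direction is the second matrix dimension.  If the line
    count does not divide evenly by the acceleration factor the fractional
    value is returned with a warning rather than silently rounded.
    """
    lines = protocol.matrix[1] / protocol.accel_factor
    if abs(lines - round(lines)) > 1e-9:
        warnings.warn(
            f"phase-encode line count {protocol.matrix[1]}/{protocol.accel_factor} "
            f"= {lines:.4g} is fractional; using it unrounded",
            stacklevel=2,
        )
    return protocol.tr_ms * lines


def pair_duration(protocol: AcquisitionProtocol, heart_rate_bpm: float,
                  rest_gap_s: float = 8.0) -> float:
    """Wall-clock time in seconds to acquire one tagged/control pair.

    Each double-gated image spans two cardiac cycles: the inversion pulse is
    played in one cycle and the readout in the next, both at the same trigger
    delay.  A pair is two such images plus a rest gap for Mz recovery.
    """
    if heart_rate_bpm <= 0:
        raise ValueError("heart_rate_bpm must be > 0")
    return 2 * 2 * (60.0 / heart_rate_bpm) + rest_gap_s


def _preset(name, phase, method, factor):
    return AcquisitionProtocol(
        name=name, cardiac_phase=phase, accel_method=method, accel_factor=factor
    )


PROTOCOL_PRESETS = {
    "FAIR-PI2_D": _preset("FAIR-PI2_D", CardiacPhase.DIASTOLE,
                          AccelMethod.PARALLEL_IMAGING, 2),
    "FAIR-PI2_S": _preset("FAIR-PI2_S", CardiacPhase.SYSTOLE,
                          AccelMethod.PARALLEL_IMAGING, 2),
    "FAIR-CS3_S": _preset("FAIR-CS3_S", CardiacPhase.SYSTOLE,
                          AccelMethod.COMPRESSED_SENSING, 3),
}


def get_protocol(name: str, **overrides) -> AcquisitionProtocol:
    """Return a shipped preset by name, optionally overriding fields."""
    try:
        base = PROTOCOL_PRESETS[name]
    except KeyError:
        raise KeyError(
            f"unknown protocol {name!r}; available: {sorted(PROTOCOL_PRESETS)}"
        ) from None
    if not overrides:
        return base
    doc = asdict(base)
    doc["cardiac_phase"] = base.cardiac_phase
    doc["accel_method"] = base.accel_method
    doc.update(overrides)
    return AcquisitionProtocol(**doc)
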