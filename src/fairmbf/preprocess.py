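"""Pipeline stages upstream of quantification.

The processing order mirrors the acquisition logic: (1) crop a region of
interest around the left ventricle in the M0 image and propagate it to all
frames; (2) register frames 2-6 of each time series to frame 1 of the same
series with a mean-squares metric (same contrast, so the simple metric is
reliable); (3) correct each frame's signal for the difference between its
actual and nominal inversion time with the inversion-recovery model

    I_corr = M0 + (I - M0) e^(dTI / T1),  dTI = actual - nominal,

using the blood T1 (~1700 ms); (4) average each series into a single
control and a single tagged image; (5) register both averages to the M0
image with a mutual-information metric (robust to their different
contrasts).

Registration is rigid (in-plane translation + rotation), bilinear,
two-level multi-resolution, initialised at identity with no random metric
sampling, so results are deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple, Union

import numpy as np
import SimpleITK as sitk

from ._imageops import (RigidTransform, euler2d, from_sitk,
                        rigid_from_euler2d, to_sitk)
from .protocols import FairSeries, ImageFrame

__all__ = ["RigidTransform", "RegistrationResult", "PreparedPair", "crop_roi",
           "register_rigid", "correct_inversion_time", "average_series",
           "preprocess_series"]

#: joint-histogram bins for the mutual-information metric
MI_BINS = 32
#: optimiser cap; hitting it marks the result as not converged
MAX_ITERATIONS = 200


@dataclass
class RegistrationResult:
    """Aligned frame plus the rigid transform that produced it.

    ``converged`` is False when the optimiser stopped at the iteration cap;
    the best-found transform is still returned rather than failing.
    """

    aligned: ImageFrame
    transform: RigidTransform
    converged: bool = True
    metric_value: float = float("nan")
    iterations: int = 0

    def __iter__(self):
        return iter((self.aligned, self.transform))


@dataclass
class PreparedPair:
    """Averaged, motion- and TI-corrected control/tagged images on the M0 grid."""

    control_avg: ImageFrame
    tagged_avg: ImageFrame
    m0: ImageFrame
    ti_control_ms: float
    ti_tagged_ms: float
    transform_log: Dict[str, List[RigidTransform]] = field(default_factory=dict)


def crop_roi(series: FairSeries, center_px: Optional[Tuple[int, int]] = None,
             size_px: int = 64) -> FairSeries:
    """Apply one square crop window identically to all 13 frames.

    ``center_px`` is the (row, col) window center, default the grid center;
    a window extending past the image bounds is an error.
    """
    ny, nx = series.shape
    if center_px is None:
        center_px = (ny // 2, nx // 2)
    r0 = int(center_px[0]) - size_px // 2
    c0 = int(center_px[1]) - size_px // 2
    if r0 < 0 or c0 < 0 or r0 + size_px > ny or c0 + size_px > nx:
        raise ValueError(
            f"crop window [{r0}:{r0 + size_px}, {c0}:{c0 + size_px}] exceeds "
            f"the {ny} x {nx} grid")

    def cut(fr: ImageFrame) -> ImageFrame:
        return ImageFrame(fr.pixels[r0:r0 + size_px, c0:c0 + size_px].copy(),
                          fr.frame_type, fr.index, fr.actual_ti_ms)

    return FairSeries(protocol=series.protocol,
                      controls=[cut(f) for f in series.controls],
                      taggeds=[cut(f) for f in series.taggeds],
                      m0=cut(series.m0),
                      heart_rate_bpm=series.heart_rate_bpm,
                      blood_t1_ms=series.blood_t1_ms)


def register_rigid(moving: ImageFrame, fixed: ImageFrame,
                   metric: str = "mean_squares",
                   spacing_mm: Tuple[float, float] = (2.0, 2.0),
                   center_px: Optional[Tuple[float, float]] = None
                   ) -> RegistrationResult:
    """Rigidly align ``moving`` to ``fixed`` and resample it (bilinear).

    ``metric`` is ``"mean_squares"`` (within-series, same contrast) or
    ``"mutual_information"`` (across contrasts, 32-bin joint histogram with
    dense sampling).  The transform rotates about ``center_px`` (default:
    image center).  Deterministic: identity initialisation, dense metric,
    regular-step gradient descent with a fixed iteration cap.
    """
    if moving.shape != fixed.shape:
        raise ValueError(f"frame grids differ: {moving.shape} vs {fixed.shape}")
    if center_px is None:
        center_px = ((moving.shape[0] - 1) / 2.0, (moving.shape[1] - 1) / 2.0)

    f_img = to_sitk(fixed.pixels, spacing_mm)
    m_img = to_sitk(moving.pixels, spacing_mm)

    reg = sitk.ImageRegistrationMethod()
    if metric == "mean_squares":
        reg.SetMetricAsMeanSquares()
    elif metric == "mutual_information":
        reg.SetMetricAsMattesMutualInformation(MI_BINS)
    else:
        raise ValueError(f"unknown metric {metric!r}")
    reg.SetMetricSamplingStrategy(reg.NONE)
    reg.SetInterpolator(sitk.sitkLinear)
    reg.SetOptimizerAsRegularStepGradientDescent(
        learningRate=1.0, minStep=1e-4, numberOfIterations=MAX_ITERATIONS,
        gradientMagnitudeTolerance=1e-8)
    reg.SetOptimizerScalesFromPhysicalShift()
    tx = euler2d(RigidTransform(), spacing_mm, center_px)
    reg.SetInitialTransform(tx, inPlace=True)
    # 3-level pyramid: the coarse, heavily smoothed level is what lets the
    # optimiser pick up rotations whose capture range is small at full scale
    reg.SetShrinkFactorsPerLevel([4, 2, 1])
    reg.SetSmoothingSigmasPerLevel([2.0, 1.0, 0.0])

    final = reg.Execute(f_img, m_img)
    iterations = reg.GetOptimizerIteration()
    fill = float(moving.pixels[0, 0])
    out = sitk.Resample(m_img, f_img, final, sitk.sitkLinear, fill)
    aligned = ImageFrame(from_sitk(out), moving.frame_type, moving.index,
                         moving.actual_ti_ms)
    return RegistrationResult(
        aligned=aligned,
        transform=rigid_from_euler2d(sitk.Euler2DTransform(final), spacing_mm),
        converged=iterations < MAX_ITERATIONS,
        metric_value=float(reg.GetMetricValue()),
        iterations=int(iterations),
    )


def apply_transform(frame: ImageFrame, transform: RigidTransform,
                    spacing_mm=(2.0, 2.0), center_px=None) -> ImageFrame:
    """Resample a frame under an already-known rigid transform."""
    if center_px is None:
        center_px = ((frame.shape[0] - 1) / 2.0, (frame.shape[1] - 1) / 2.0)
    img = to_sitk(frame.pixels, spacing_mm)
    out = sitk.Resample(img, img, euler2d(transform, spacing_mm, center_px),
                        sitk.sitkLinear, float(frame.pixels[0, 0]))
    return ImageFrame(from_sitk(out), frame.frame_type, frame.index,
                      frame.actual_ti_ms)


def correct_inversion_time(frame: ImageFrame, m0: ImageFrame,
                           nominal_ti_ms: float, t1_ms: float) -> ImageFrame:
    """Shift a frame's signal to the nominal TI along inversion recovery.

    I_corr = M0 + (I - M0) e^(dTI/T1) with dTI = actual - nominal.  The
    corrected frame's actual TI is set to the nominal value.
    """
    if t1_ms <= 0:
        raise ValueError("t1_ms must be positive")
    if frame.actual_ti_ms is None:
        raise ValueError("frame has no actual inversion time")
    if frame.shape != m0.shape:
        raise ValueError("frame and M0 grids differ")
    dti = frame.actual_ti_ms - nominal_ti_ms
    corrected = m0.pixels + (frame.pixels - m0.pixels) * np.exp(dti / t1_ms)
    return ImageFrame(corrected, frame.frame_type, frame.index,
                      actual_ti_ms=float(nominal_ti_ms))


def average_series(frames: List[ImageFrame]) -> Tuple[ImageFrame, float]:
    """Pixelwise mean of one frame series; TI is the mean of the frames' TIs."""
    if not frames:
        raise ValueError("cannot average an empty series")
    types = {f.frame_type for f in frames}
    if len(types) != 1:
        raise ValueError(f"mixed frame types in series: {types}")
    shapes = {f.shape for f in frames}
    if len(shapes) != 1:
        raise ValueError(f"mixed grids in series: {shapes}")
    mean_px = np.mean([f.pixels for f in frames], axis=0)
    mean_ti = float(np.mean([f.actual_ti_ms for f in frames]))
    return ImageFrame(mean_px, frames[0].frame_type,
                      actual_ti_ms=mean_ti), mean_ti


def preprocess_series(series: FairSeries,
                      center_px: Optional[Tuple[int, int]] = None,
                      size_px: int = 64,
                      register: bool = True) -> PreparedPair:
    """Run the full preprocessing chain on one FAIR series.

    Order: crop -> within-series registration (mean squares, frames 2-6 to
    frame 1) -> TI correction of all 12 frames against the cropped M0 (the
    nominal TI is the per-type mean of the actual TIs) -> averaging ->
    registration of both averages to the cropped M0 (mutual information).
    ``register=False`` skips both registration stages (motion-correction
    ablation).
    """
    spacing = series.protocol.pixel_mm
    cropped = crop_roi(series, center_px, size_px)
    log: Dict[str, List[RigidTransform]] = {"control": [], "tagged": [], "to_m0": []}

    aligned = {}
    for name, frames in (("control", cropped.controls), ("tagged", cropped.taggeds)):
        out = [frames[0]]
        log[name].append(RigidTransform())  # frame 1 is the reference
        for fr in frames[1:]:
            if register:
                res = register_rigid(fr, frames[0], "mean_squares", spacing)
                out.append(res.aligned)
                log[name].append(res.transform)
            else:
                out.append(fr)
                log[name].append(RigidTransform())
        aligned[name] = out

    t1 = series.blood_t1_ms
    prepared = {}
    mean_tis = {}
    for name in ("control", "tagged"):
        nominal = float(np.mean([f.actual_ti_ms for f in aligned[name]]))
        corrected = [correct_inversion_time(f, cropped.m0, nominal, t1)
                     for f in aligned[name]]
        avg, mean_ti = average_series(corrected)
        mean_tis[name] = mean_ti
        if register:
            res = register_rigid(avg, cropped.m0, "mutual_information", spacing)
            prepared[name] = res.aligned
            log["to_m0"].append(res.transform)
        else:
            prepared[name] = avg
            log["to_m0"].append(RigidTransform())

    return PreparedPair(control_avg=prepared["control"],
                        tagged_avg=prepared["tagged"],
                        m0=cropped.m0,
                        ti_control_ms=mean_tis["control"],
                        ti_tagged_ms=mean_tis["tagged"],
                        transform_log=log)
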