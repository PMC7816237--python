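"""Synthetic short-axis cardiac phantom with known perfusion ground truth.

The phantom is a left-ventricular annulus (myocardium) around a blood-pool
disk on a 150 x 150 grid of 2 x 2 mm pixels.  Wall thickness depends on the
cardiac phase: contracted systolic walls are thicker and contain more
pixels than diastolic ones, which is the geometric effect the systolic
protocols exploit.

The noiseless signal model is constructed as the exact algebraic inverse of
the double-gated FAIR quantification formula

    MBF = 1/(2 M0) * [ (C/TI_C) e^(-TI_C/T1) - (T/TI_T) e^(-TI_T/T1) ],

so that quantifying the noiseless frames returns the configured true MBF to
machine precision.  The tagged image follows signed inversion recovery of
the tissue (T = M0 (1 - 2 e^(-TI/T1_tissue))); the control image is then
solved from the formula above.  Signals are signed throughout: inverted
magnetization is negative, no magnitude operation is applied.

On top of the clean signals, :func:`simulate_series` applies, in order,
per-frame inversion-time jitter (re-expressed through the inversion-recovery
signal model so that the pipeline's TI correction is exact on noiseless
data), one rigid motion per breath-hold pair, physiological noise whose
amplitude grows with the excess of the readout window over the cardiac rest
period, and thermal Gaussian noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Tuple, Union

import numpy as np

from ._imageops import RigidTransform, apply_rigid
from .protocols import (
    AcquisitionProtocol,
    CardiacPhase,
    FairSeries,
    ImageFrame,
    acquisition_window,
)

__all__ = ["PhantomSpec", "GroundTruth", "make_geometry", "forward_signals",
           "simulate_series", "MS_PER_MIN"]

#: conversion between perfusion in 1/ms and ml/g/min at unit tissue density
MS_PER_MIN = 60000.0


@dataclass
class PhantomSpec:
    """Parameters of the synthetic LV phantom.

    Radii are in mm; ``true_mbf`` (ml/g/min) may be a scalar or a full-grid
    map and applies inside the myocardium only.  Noise parameters:
    ``thermal_sigma`` is the additive Gaussian SD as a fraction of the
    myocardial M0; ``physio_k`` scales physiological noise per ms of excess
    of the acquisition window over the protocol's cardiac rest period;
    ``ti_jitter_frac`` is the relative half-width of the uniform per-frame
    inversion-time jitter.
    """

    matrix: Tuple[int, int] = (150, 150)
    pixel_mm: Tuple[float, float] = (2.0, 2.0)
    diastole_radii_mm: Tuple[float, float] = (25.0, 34.0)
    systole_radii_mm: Tuple[float, float] = (16.0, 31.0)
    center_mm: Optional[Tuple[float, float]] = None  # (y, x); default = grid center
    rv_direction_deg: float = 180.0  # septum toward image left
    rv_radius_mm: float = 0.0        # optional RV blood pool; > 0 breaks the
    rv_offset_mm: float = 10.0       # rotational symmetry (center beyond outer radius)
    true_mbf: Union[float, np.ndarray] = 1.5
    m0_myo: float = 1000.0
    m0_blood: float = 1300.0
    m0_background: float = 20.0
    t1_blood_ms: float = 1700.0
    t1_myo_ms: float = 1500.0
    ti_jitter_frac: float = 0.05
    motion_shift_px: float = 3.0
    motion_rot_deg: float = 3.0
    thermal_sigma: float = 0.02
    physio_k: float = 0.004
    seed: int = 0

    def __post_init__(self):
        for radii in (self.diastole_radii_mm, self.systole_radii_mm):
            if radii[0] > radii[1]:
                raise ValueError(f"inner radius exceeds outer radius: {radii}")
        for attr in ("ti_jitter_frac", "motion_shift_px", "motion_rot_deg",
                     "thermal_sigma", "physio_k"):
            if getattr(self, attr) < 0:
                raise ValueError(f"{attr} must be >= 0")

    @property
    def center(self) -> Tuple[float, float]:
        if self.center_mm is not None:
            return self.center_mm
        return (self.matrix[0] * self.pixel_mm[0] / 2.0,
                self.matrix[1] * self.pixel_mm[1] / 2.0)

    @property
    def center_px(self) -> Tuple[float, float]:
        """Phantom center in 0-based pixel-index coordinates."""
        cy, cx = self.center
        return (cy / self.pixel_mm[0] - 0.5, cx / self.pixel_mm[1] - 0.5)

    def radii(self, phase: CardiacPhase) -> Tuple[float, float]:
        phase = CardiacPhase(phase)
        return (self.diastole_radii_mm if phase == CardiacPhase.DIASTOLE
                else self.systole_radii_mm)

    def noiseless(self) -> "PhantomSpec":
        """Copy with all corruption switched off (for oracle round trips)."""
        return replace(self, ti_jitter_frac=0.0, motion_shift_px=0.0,
                       motion_rot_deg=0.0, thermal_sigma=0.0, physio_k=0.0)


@dataclass
class GroundTruth:
    """What the generator knows and the pipeline must recover."""

    mbf_map: np.ndarray          # ml/g/min, zero outside the myocardium
    myo_mask: np.ndarray         # boolean
    injected_transforms: List[RigidTransform]  # series order: controls 1-6, taggeds 1-6
    actual_tis: List[float]      # same order, ms
    mean_ti_control_ms: float = float("nan")
    mean_ti_tagged_ms: float = float("nan")

    def __post_init__(self):
        if np.any(self.mbf_map[~self.myo_mask] != 0):
            raise ValueError("ground-truth MBF must be zero outside the myocardium")


def make_geometry(spec: PhantomSpec, phase: CardiacPhase) -> Dict[str, np.ndarray]:
    """Rasterize the annular LV geometry for one cardiac phase.

    A pixel belongs to a compartment iff its center lies inside it
    (pixel-center convention: pixel (i, j) has center ((i+0.5) dy, (j+0.5) dx),
    x increasing rightward, y downward, 0-based indices).  The right
    ventricle is a blood-pool disk abutting the LV along ``rv_direction_deg``
    (it never overwrites myocardial pixels); besides anatomical realism it
    breaks the rotational symmetry of the annulus, making in-plane rotation
    observable to registration.
    Returns boolean masks ``myocardium``, ``lv_cavity``, ``rv_cavity`` and
    ``background``.
    """
    inner, outer = spec.radii(phase)
    ny, nx = spec.matrix
    dy, dx = spec.pixel_mm
    cy, cx = spec.center
    extent = outer + (spec.rv_offset_mm + spec.rv_radius_mm
                      if spec.rv_radius_mm > 0 else 0.0)
    if (cy - extent < 0 or cy + extent > ny * dy
            or cx - extent < 0 or cx + extent > nx * dx):
        raise ValueError(
            f"phantom of extent {extent} mm at center {(cy, cx)} "
            f"exceeds the {ny * dy} x {nx * dx} mm field of view")
    yy = (np.arange(ny) + 0.5) * dy
    xx = (np.arange(nx) + 0.5) * dx
    r = np.hypot(yy[:, None] - cy, xx[None, :] - cx)
    myo = (r >= inner) & (r < outer)
    cavity = r < inner
    rv = np.zeros_like(myo)
    if spec.rv_radius_mm > 0:
        ang = np.deg2rad(spec.rv_direction_deg)
        d = outer + spec.rv_offset_mm
        rv_c = (cy + d * np.sin(ang), cx + d * np.cos(ang))
        r_rv = np.hypot(yy[:, None] - rv_c[0], xx[None, :] - rv_c[1])
        rv = (r_rv < spec.rv_radius_mm) & ~myo & ~cavity
    return {"myocardium": myo, "lv_cavity": cavity, "rv_cavity": rv,
            "background": ~(myo | cavity | rv)}


def _mbf_map_per_ms(spec: PhantomSpec, myo_mask: np.ndarray) -> np.ndarray:
    f = np.zeros(spec.matrix, dtype=float)
    mbf = np.asarray(spec.true_mbf, dtype=float)
    if mbf.ndim == 0:
        f[myo_mask] = float(mbf)
    else:
        f[myo_mask] = np.broadcast_to(mbf, spec.matrix)[myo_mask]
    if not np.all(np.isfinite(f)):
        raise ValueError("true_mbf must be finite")
    return f / MS_PER_MIN


def forward_signals(spec: PhantomSpec, protocol: AcquisitionProtocol,
                    ti_c_ms: Optional[float] = None,
                    ti_t_ms: Optional[float] = None):
    """Noiseless (control, tagged, m0) frames consistent with the MBF formula.

    By default both inversion times equal the protocol's nominal TI; separate
    control/tagged TIs may be given (the simulator anchors the signals at the
    per-type mean of the jittered actual TIs so that TI correction followed by
    quantification is exact).
    """
    if spec.m0_myo <= 0:
        raise ValueError("myocardial M0 must be positive")
    ti_c = float(protocol.nominal_ti_ms if ti_c_ms is None else ti_c_ms)
    ti_t = float(protocol.nominal_ti_ms if ti_t_ms is None else ti_t_ms)
    if ti_c <= 0 or ti_t <= 0:
        raise ValueError("inversion times must be positive")
    t1b = spec.t1_blood_ms

    masks = make_geometry(spec, protocol.cardiac_phase)
    myo = masks["myocardium"]
    blood = masks["lv_cavity"] | masks["rv_cavity"]

    m0_map = np.full(spec.matrix, spec.m0_background, dtype=float)
    m0_map[myo] = spec.m0_myo
    m0_map[blood] = spec.m0_blood

    # tagged image: signed inversion recovery per compartment
    tagged = np.full(spec.matrix, spec.m0_background, dtype=float)
    tagged[myo] = spec.m0_myo * (1.0 - 2.0 * np.exp(-ti_t / spec.t1_myo_ms))
    tagged[blood] = spec.m0_blood * (1.0 - 2.0 * np.exp(-ti_t / t1b))

    # control image: exact inverse of the quantification formula,
    # C = TI_C e^{+TI_C/T1} (2 M0 f + (T/TI_T) e^{-TI_T/T1}), f in 1/ms
    f = _mbf_map_per_ms(spec, myo)
    control = ti_c * np.exp(ti_c / t1b) * (
        2.0 * m0_map * f + (tagged / ti_t) * np.exp(-ti_t / t1b))

    return (ImageFrame(control, "control", actual_ti_ms=ti_c),
            ImageFrame(tagged, "tagged", actual_ti_ms=ti_t),
            ImageFrame(m0_map, "m0"))


def _roll_ti(pixels: np.ndarray, m0_map: np.ndarray, ti_from: float,
             ti_to: float, t1_ms: float) -> np.ndarray:
    """Move a frame from one inversion time to another along the IR model."""
    if ti_from == ti_to:
        return pixels.copy()
    return m0_map + (pixels - m0_map) * np.exp((ti_from - ti_to) / t1_ms)


def simulate_series(spec: PhantomSpec, protocol: AcquisitionProtocol,
                    heart_rate_bpm: float = 60.0):
    """Simulate one FAIR series (6 control + 6 tagged + M0) with ground truth.

    Frames are generated in acquisition order — six breath-hold pairs, the
    within-pair order alternating tagged/control, control/tagged — with all
    randomness drawn from ``spec.seed``:

    1. each frame's actual TI ~ Uniform(nominal * (1 +/- ti_jitter_frac));
       the clean signals are anchored at the per-type mean TI and each frame
       is rolled to its actual TI along the blood-T1 inversion-recovery
       model, so the pipeline's TI correction (back to the mean) is exact
       in the absence of noise;
    2. one rigid transform per breath-hold pair, applied to both frames
       (translation ~ U(+/- motion_shift_px), rotation ~ U(+/- motion_rot_deg));
       the separately acquired M0 frame is not moved;
    3. physiological noise on myocardial pixels of each frame, SD =
       physio_k * max(0, T_acq - rest_period) * local M0 — zero whenever the
       readout fits inside the rest period;
    4. thermal noise on every pixel of all 13 frames,
       SD = thermal_sigma * myocardial M0.
    """
    if tuple(spec.matrix) != tuple(protocol.matrix):
        raise ValueError(
            f"phantom grid {spec.matrix} != protocol matrix {protocol.matrix}")
    rng = np.random.default_rng(spec.seed)
    nominal = protocol.nominal_ti_ms
    jit = spec.ti_jitter_frac

    # (1) actual TIs in acquisition order: pair p is tagged-first when p is even
    order = []  # (frame_type, pair_index)
    for p in range(6):
        first, second = (("tagged", "control") if p % 2 == 0
                         else ("control", "tagged"))
        order += [(first, p), (second, p)]
    tis = {"control": np.zeros(6), "tagged": np.zeros(6)}
    for ftype, p in order:
        tis[ftype][p] = nominal * (1.0 + rng.uniform(-jit, jit))
    mean_ti_c = float(np.mean(tis["control"]))
    mean_ti_t = float(np.mean(tis["tagged"]))

    control0, tagged0, m0_frame = forward_signals(
        spec, protocol, ti_c_ms=mean_ti_c, ti_t_ms=mean_ti_t)
    masks = make_geometry(spec, protocol.cardiac_phase)
    myo = masks["myocardium"]
    m0_map = m0_frame.pixels
    anchor = {"control": (control0.pixels, mean_ti_c),
              "tagged": (tagged0.pixels, mean_ti_t)}

    frames = {"control": [], "tagged": []}
    for ftype in ("control", "tagged"):
        base, mean_ti = anchor[ftype]
        for i in range(6):
            px = _roll_ti(base, m0_map, mean_ti, tis[ftype][i], spec.t1_blood_ms)
            frames[ftype].append(
                ImageFrame(px, ftype, index=i + 1, actual_ti_ms=float(tis[ftype][i])))

    # (2) rigid motion per breath-hold pair
    move = spec.motion_shift_px > 0 or spec.motion_rot_deg > 0
    pair_tx: List[RigidTransform] = []
    for p in range(6):
        if move:
            dx, dy = rng.uniform(-spec.motion_shift_px, spec.motion_shift_px, 2)
            th = rng.uniform(-spec.motion_rot_deg, spec.motion_rot_deg)
            pair_tx.append(RigidTransform(float(dx), float(dy), float(th)))
        else:
            pair_tx.append(RigidTransform())
    if move:
        for ftype in ("control", "tagged"):
            for p in range(6):
                fr = frames[ftype][p]
                fill = float(fr.pixels[0, 0])
                fr.pixels = apply_rigid(fr.pixels, pair_tx[p], spec.pixel_mm,
                                        spec.center_px, fill=fill)

    # (3) physiological noise, proportional to the excess readout window
    excess = max(0.0, acquisition_window(protocol) - protocol.rest_period_ms)
    if excess > 0 and spec.physio_k > 0:
        for p in range(6):
            if pair_tx[p].is_near_identity(0.0, 0.0):
                local_m0, local_myo = m0_map, myo
            else:
                local_m0 = apply_rigid(m0_map, pair_tx[p], spec.pixel_mm,
                                       spec.center_px, fill=spec.m0_background)
                local_myo = apply_rigid(myo.astype(float), pair_tx[p],
                                        spec.pixel_mm, spec.center_px,
                                        fill=0.0, nearest=True) > 0.5
            sd_field = spec.physio_k * excess * local_m0
            for ftype, pp in order[2 * p:2 * p + 2]:
                noise = rng.standard_normal(spec.matrix)
                frames[ftype][pp].pixels = frames[ftype][pp].pixels + \
                    np.where(local_myo, sd_field * noise, 0.0)

    # (4) thermal noise on every frame including M0
    if spec.thermal_sigma > 0:
        sd = spec.thermal_sigma * spec.m0_myo
        for ftype, p in order:
            frames[ftype][p].pixels = frames[ftype][p].pixels + \
                rng.normal(0.0, sd, spec.matrix)
        m0_frame = ImageFrame(m0_map + rng.normal(0.0, sd, spec.matrix), "m0")

    series = FairSeries(protocol=protocol, controls=frames["control"],
                        taggeds=frames["tagged"], m0=m0_frame,
                        heart_rate_bpm=heart_rate_bpm,
                        blood_t1_ms=spec.t1_blood_ms)
    truth = GroundTruth(
        mbf_map=_mbf_map_per_ms(spec, myo) * MS_PER_MIN,
        myo_mask=myo,
        injected_transforms=[pair_tx[p] for p in range(6)] * 2,
        actual_tis=[float(t) for t in tis["control"]] + [float(t) for t in tis["tagged"]],
        mean_ti_control_ms=mean_ti_c,
        mean_ti_tagged_ms=mean_ti_t,
    )
    return series, truth
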