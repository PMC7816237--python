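# Methods

## Signal model and quantification

A FAIR series consists of six control images (slice-selective inversion,
30 mm slab), six tagged images (nonselective inversion) and one unprepared
M0 image, all double-gated: inversion in one cardiac cycle, single-shot
bSSFP readout at the same trigger delay in the next, so the nominal
inversion time TI equals one R-R interval (60000/HR ms). Myocardial blood
flow is computed pixelwise as

    MBF = 1/(2·M0) · [ (C/TI_C)·e^(−TI_C/T1) − (T/TI_T)·e^(−TI_T/T1) ] · 60000

with C, T the (averaged) control and tagged intensities, TI_C/TI_T their
inversion times in ms, T1 the blood longitudinal relaxation time (1700 ms
at 3 T), the factor 60000 converting 1/ms to 1/min, and a tissue density of
1 g/ml so that 1/min reads as ml/g/min. Both exponential terms attenuate
with TI as printed in the double-gated ASL literature this formula comes
from; no blood–tissue partition coefficient is introduced. Signals are
*signed* throughout (inverted magnetization is negative) — no magnitude
operation — which keeps the forward model exactly invertible. Pixels with
M0 below 5% of the M0 maximum are flagged invalid rather than zeroed,
because 1/M0 amplifies noise without bound in air; negative MBF values are
retained in maps and statistics.

Beat-to-beat TI variation is corrected with the inversion-recovery model

    I_corr = M0 + (I − M0)·e^(ΔTI/T1),   ΔTI = TI_actual − TI_nominal,

where the nominal TI is the per-series mean of the six recorded actual TIs,
computed separately for controls and taggeds; the two resulting mean TIs
enter the quantification formula as TI_C and TI_T. Blood T1 is used even on
myocardial pixels, matching practice; the residual tissue-T1 mismatch is a
known approximation.

## Processing order

The pipeline runs: (1) crop a 64×64-pixel ROI around the LV in the M0
frame, propagated to all 13 frames; (2) register frames 2–6 of each series
to frame 1 with a mean-squares metric (same contrast within a series);
(3) TI-correct all 12 frames against the cropped M0; (4) average each
series; (5) register the two averages to M0 with a 32-bin Mattes mutual
information metric (robust across contrasts). Registration is rigid
(Euler 2-D about the ROI center), bilinear, initialised at identity, dense
metric (no random sampling), regular-step gradient descent capped at 200
iterations, three-level multi-resolution (shrink 4/2/1, smoothing σ
2/1/0 px). The coarse level is what gives rotations a usable capture range
on 64×64 images. All settings are fixed, so registration is deterministic;
non-convergence returns the best transform with a flag rather than failing.

Temporal SNR uses per-pair MBF maps: each control/tagged pair is registered
internally (mean squares), brought onto the M0 grid (mutual information on
the control, transform applied to both), then both frames are TI-corrected
to the *pair-mean* TI and quantified at that common TI. Equalising the TIs
inside a pair is essential: the quantification formula's two terms each
carry the full M0 baseline divided by TI, which cancels only when
TI_C = TI_T. Feeding raw beat-to-beat TIs (several percent apart) directly
into the formula injects a first-order baseline error of ~0.4 ml/g/min SD
per pair — an artifact of TI bookkeeping, not of physiology — which would
cap TSNR near 4 for every protocol and mask the motion-noise differences
TSNR exists to measure. TSNR is the mean of the six ROI-mean MBF values
divided by their sample SD (n−1); it is reported as NaN when the SD is zero.
A per-pixel TSNR map (temporal mean/SD per pixel, median-summarised) is
available as a secondary output (`tsnr_mode="pixel"`).

## Phantom

The phantom is an annulus (myocardium) around a disk (LV blood pool) on a
150×150 grid of 2×2 mm pixels, pixel-center rasterization. Default radii:
diastole 25/34 mm (≈417 pixels), systole 16/31 mm (≈532 pixels), giving a
systolic/diastolic pixel ratio ≈1.3 — the wall-thickening effect that
motivates systolic acquisition. Compartment baselines: myocardium M0 1000,
blood 1300, background 20 (below the 5% validity floor). Tagged signals
follow signed inversion recovery (T1 1500 ms myocardium, 1700 ms blood);
the control image is then solved from the quantification formula so that
quantifying the noiseless frames returns the configured true MBF (default
uniform 1.5 ml/g/min; a map may be supplied) to machine precision.
Perfusion is zero in the blood pools and background by construction, so the
control equals the tagged signal there — physically the LV cavity control
would be refilled, uninverted blood, but the algebraically closed form is
preferred so that zero-flow regions quantify to exactly zero.

An optional right-ventricular blood-pool disk (`rv_radius_mm`, default off)
abuts the annulus on the septal side. The pure annulus is rotationally
symmetric, making in-plane rotation a gauge freedom that no registration
metric can observe (and that costs nothing when uncorrected); tests of
rotation recovery therefore use the asymmetric RV configuration, while the
default geometry keeps the symmetric annulus. On the symmetric phantom the
registration metrics' gradients vanish at identity by symmetry, so
registration is exactly neutral on aligned data; with the RV present the
mean-squares/mutual-information optima under residual contrast differences
sit a few 10⁻³ px off identity — a real property of intensity metrics, which
is why the machine-precision round-trip tests use the symmetric geometry.

Corruption, per simulated scan (all randomness from one seed, frames drawn
in acquisition order with the tagged/control order alternating between
breath-holds):

1. **TI jitter** — each frame's actual TI ~ Uniform(nominal ± 5%). The
   noiseless signals are anchored at the per-type mean of the drawn TIs and
   each frame is rolled to its actual TI along the blood-T1
   inversion-recovery model, so the pipeline's TI correction (which
   corrects to the per-type mean) is exact on noiseless data by
   construction: the correction step is tested with a sharp pass/fail.
2. **Bulk motion** — one rigid transform per breath-hold pair (both frames
   of a pair share a breath-hold), translation ~ U(±3 px), rotation
   ~ U(±3°); the separately acquired M0 frame stays fixed.
3. **Physiological noise** — zero-mean Gaussian on myocardial pixels with
   SD = k · max(0, T_acq − rest period) · local M0, k = 0.004 per ms. The
   linear-in-excess-window form is a modelling invention; it encodes the
   qualitative mechanism (readout spilling out of the quiescent window
   picks up cardiac motion) and is zero whenever the readout fits the rest
   period. Rest periods are simulation parameters: 180 ms diastole, 90 ms
   systole. Hence PI2_D is physio-noise-free (165 ≤ 180), PI2_S has 75 ms
   excess, CS3_S 20 ms (ratio 3.75).
4. **Thermal noise** — Gaussian, SD = 2% of myocardial M0, on every pixel
   of all 13 frames.

## Cohort experiment

`run_experiment` simulates n subjects (default 12) and runs each through
all three protocols. Per subject: heart rate ~ Normal(64, 10) bpm truncated
at 40 (nominal TI = one R-R interval); anatomical size via a radius scale
factor ~ Normal(1, 0.06) clipped to [0.8, 1.2]; global true MBF ~
Normal(1.5, 0.25) ml/g/min truncated at 0.5. Size and MBF variation are
shared across a subject's three scans (paired design) and exist so that
pixel counts and MBF have realistic between-subject spread — without them
the pixel-count comparison would have zero within-group variance and the
test statistics would degenerate. The analysis mask is the phantom's own
truth mask for the matching cardiac phase (manual segmentation stands
outside the simulated pipeline). Group comparisons use a plain one-way
ANOVA per metric (mean MBF, TSNR, pixel count), followed — only when
p < 0.05 — by paired two-tailed t-tests for the three protocol pairs at the
same α, without multiplicity correction. Post-hoc tests are paired because
every subject undergoes all three protocols.

Typical cohort output (n = 12, master seed 1): pixel counts 412/541/541
(systolic/diastolic ratio 1.31, p < 10⁻⁴), TSNR ≈ 26/5/14 for
PI2_D/PI2_S/CS3_S with the systolic parallel-imaging protocol significantly
below both alternatives, and no significant mean-MBF difference — the
directional pattern the three-protocol design predicts. TSNR magnitudes
depend directly on the invented physiological-noise coefficient and should
be read as ordinal, not calibrated, values.

## Problem sizes and runtime

Default problem sizes were chosen to keep a laptop run comfortable: 64×64
ROI registration (~40 ms per call), a 12-subject cohort in ~2 minutes, and
the 50-repetition null control (physiological noise and motion switched
off) with the motion-correction stage disabled — on motion-free data
registration is a no-op by construction and dominates runtime otherwise.

## Known limitations

* No through-plane motion, coil maps, k-space undersampling artifacts or
  fat signal; acceleration enters only through the readout-window duration
  and the physiological-noise scaling. Compressed sensing's intrinsic
  denoising is not modelled.
* The phantom's signals are signed; magnitude-reconstructed data would need
  polarity restoration before this pipeline.
* Physiological noise is spatially white within the myocardium; real
  cardiac-motion noise is structured (edges, banding), so registration-based
  pipelines may fare somewhat better here than on real scans.
* TI jitter is drawn i.i.d. per frame; real R-R series are autocorrelated,
  and within-breath-hold variation is smaller than between-breath-hold
  variation.
* Passing tests demonstrate correctness of the algebra, the registration
  machinery and the statistical workflow on data generated by this model —
  not fidelity of any particular noise magnitude to a given scanner.
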