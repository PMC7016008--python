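# Methods

This note documents the models, numerical choices and design decisions
behind `atriasim`, and what its synthetic-data tests do and do not show
about clinical data.

## Cell model

The membrane model is the Courtemanche–Ramirez–Nattel (CRN) human atrial
myocyte: 21 states (vm; 15 gates m, h, j, oa, oi, ua, ui, xr, xs, d, f,
f_Ca, u, v, w; Na+, K+, Ca2+ and two sarcoplasmic-reticulum Ca2+ pools),
with constants and initial resting state taken from the curated public
encoding of the original formulation.  Electrical remodeling is purely
multiplicative on six targeted currents (`IonChannelScaling`):

| profile | I_K1 | I_NCX | I_Na | I_to | I_CaL | I_Kur |
|---|---|---|---|---|---|---|
| chronic AF | ×2.0 | ×1.4 | ×0.9 | ×0.3 | ×0.5 | ×0.5 |
| fibrotic (on top) | ×0.5 | — | ×0.6 | — | ×0.5 | — |

Profiles compose multiplicatively, so a fibrotic node inside
AF-remodeled tissue carries, e.g., I_K1 ×1.0 and I_CaL ×0.25.  The NCX
factor scales the CRN Na+/Ca2+-exchanger current formulation directly.

**Integration.** Gates use the Rush–Larsen exponential update (exact for
frozen rate coefficients); vm and concentrations use forward Euler.  The
global step is adaptive: 0.01 ms while any node's |dvm/dt| exceeds
1 mV/ms (upstrokes), 0.1 ms otherwise, and steps never straddle a
stimulus edge.  Removable singularities in the rate expressions (α_m at
−47.13 mV, the d-gate and w-gate time constants, x_r/x_s rates) are
patched with their analytic limits.  The single-cell stimulus default is
a −2000 pA, 2 ms rectangle (≈2× diastolic threshold); tissue pacing uses
−4000 pA because the stimulated disk also charges its neighbors through
diffusion.

**APD90** is measured from the instant of maximum dvm/dt within a beat
to recovery of 90 % of the beat amplitude toward the pre-beat diastolic
level, with linear interpolation between samples.  Characterization
values produced by this implementation: neutral profile 306 ms (first
beat at 1 Hz) / 297 ms (steady state); AF profile 201 ms (single beat
from rest), 180 ms (1-Hz steady state), 165 ms (steady state at the
500-ms clinical pacing cycle length).  The AF-remodeled APD is strongly
rate-dependent; any published single number for it is meaningful only
together with its pacing protocol, which is why the acceptance suite
pins the protocol explicitly (20 beats at CL 500 ms, last beat).

**Verification.** An independently coded plain-ODE transcription of the
same equations, integrated with LSODA at rtol 1e-8, agrees with the
Rush–Larsen path within 0.7 mV everywhere outside the ~2-ms
stimulus/upstroke transient, within 0.5 ms in activation time and within
0.7 ms in APD90.  During the upstroke itself a ~0.02-ms phase lag of the
first-order scheme translates into a few mV at ~200 mV/ms; no
first-order scheme at a 0.01-ms floor can do better, and the morphology
and APD comparisons are the meaningful checks.

## Tissue model

Monodomain reaction–diffusion on a triangulated surface,
∂t v = −I_ion/C_m + ∇·(D∇v), discretized with linear-triangle stiffness
assembly and a lumped (barycentric) mass matrix; boundaries are natural
zero-flux.  The per-element tensor is
D = κ_L σ_L f fᵀ + κ_T σ_T (P − f fᵀ) with f the mean node fiber
projected into the element plane and P the in-plane projector.  An
element is fibrotic by majority vote of its three nodes (fibrosis is
assigned per node, conduction acts per element).

**Operator splitting.** Each global step advances the reaction (the numba
cell kernel) and then the diffusion term explicitly, sub-cycled to 80 %
of its Gershgorin stability bound so the 0.1-ms relaxed step remains
usable during diastole.  Runs are bitwise deterministic for fixed
inputs.

**Conductivity → diffusion calibration.** The published tissue
conductivities (S/m) do not determine a surface diffusion coefficient
(mm²/ms): no surface-to-volume ratio or membrane capacitance per area is
given, and the printed CV anisotropy (0.707/0.486 ≈ 1.45) is
inconsistent with the continuum prediction from the conductivity ratio
(√(0.1264/0.0252) ≈ 2.24).  The conduction velocities are therefore
treated as the authoritative observables: two planar-wave experiments on
a 30 × 10 mm sheet at 235 µm (fibers along, then across, the propagation
axis) fix κ_L and κ_T so the measured CV hits each target, iterating the
continuum law CV ∝ √D (convergence in 3–4 runs to <1 %).  The calibrated
values are κ_L ≈ 1.93 and κ_T ≈ 4.07 (diffusion 0.244 and 0.103 mm²/ms).
Patient-level tuning then multiplies both κ by one common factor —
longitudinal and transverse adjusted at the same rate — via the
T ∝ 1/√scale fixed point until the mean virtual conduction time to the
target points matches the clinical mean within 2 %.

At the 235-µm reference density the solver is in the continuum regime:
CV tracks √κ within 5 % over a 4× range and changes by 2.4 % when the
spacing is halved.  On coarser test meshes (≥500 µm) discrete
propagation slows the low-diffusion end below the √D law; tests that
probe the law therefore run at 235 µm.

**Activation and CV.** Local activation time is the first upward
crossing of −40 mV after a stimulus (a standard upstroke marker; the
printed source does not state its rule), interpolated between output
frames.  CV between two points is their on-surface (geodesic) distance
over their activation-time difference.  Geodesics use Dijkstra on the
edge graph augmented with unfolded two-triangle shortcuts (error well
under 5 % at the densities used; 1.1 % on a flat 500-µm sheet, 0.2 % on
an icosphere).

**Ramp pacing.** Cycle length steps 200 → 120 ms in 10-ms decrements,
4 beats per step, then continues at 120 ms with the remainder absorbed
in that final step so the overall pacing duration is 6,530 ms.  Only the
endpoints and the total are published; the decrement and beats-per-step
are this package's choice, both configurable.  Induction is declared
when activity continues for the full 6-s post-pacing window with no
silent gap above 500 ms.

## Map processing

Sparse map samples spread onto mesh nodes by inverse-distance weighting
within a 10-mm radius.  The exponent (2) and the exact-hit epsilon
(1e-6 mm) are package choices — the source states the method and the
radius only.  Nodes with no sample in radius are flagged uncovered,
treated as healthy (5 mV) for fibrosis purposes and excluded from
agreement statistics; this avoids fabricating low-voltage tissue where
the catheter never sampled.

The voltage-to-fibrosis cubic is published on the percent scale
(99.8 at 0 mV) while its piecewise neighbors are probabilities; the only
commensurable reading divides the polynomial by 100 and clamps to
[0, 1].  Each node draws independently against one seeded generator
(spatial correlation of fibrosis is not modeled; the source compares
each node "against a random number").

Map agreement reports Pearson r, RMSE and %RMSE per region and overall;
%RMSE is normalized by the region mean of the reference (first) field,
which reproduces the pattern that low-voltage regions show high %RMSE at
similar absolute RMSE.

## Wave-dynamics analysis

Dominant frequency: de-mean, Hann taper, FFT periodogram per node over
the trailing 6-s window; DF is the in-band (1–20 Hz, excluding DC/drift)
argmax; frequency resolution is 1/window ≈ 0.17 Hz.  Phase is the
analytic-signal (Hilbert) angle of the de-meaned vm — the phase
construction is not specified by the source; the Hilbert phase is the
standard parameter-free choice.  Phase singularities are faces whose
oriented cycle winds the phase by ±2π ("the phase is undefined" inside),
with the winding sign as chirality — validated against a brute-force
winding oracle and against constructed spirals (tip localized within one
edge length).  Trajectories link events greedily to the nearest
same-chirality open tip within 5 mm per frame (configurable).  The
mother-rotor criterion uses the exact (Welzl) minimal enclosing circle
of the tip path: lifespan > 5 s and diameter ≤ wavelength/2, with the
wavelength measured from a 600-ms-cycle-length planar wave (CV × 600 ms).

## Forward electrograms

The extracellular potential is the current-source volume integral
φ_e(r′) = −(σ_i/4πσ_e) Σ_elements ∇V_m·∇(1/|r′−c|)·(area × thickness),
with the exact per-element gradient of the linear interpolant and the
kernel at the element centroid.  The monolayer surface model has no wall
thickness; a nominal 2 mm enters only as a uniform amplitude factor and
leaves morphology — the validated quantity — untouched.  σ_i/σ_e
defaults to 0.4; only the ratio matters up to scale.  The singular
self-element is avoided by a 0.5-mm electrode clearance (electrodes sit
off-wall in mapping practice) rather than analytic regularization.
Bipolar signals subtract two poles 1 mm apart.  Morphology similarity is
the inner product of unit-normalized signals, averaged over beat
segments when a segmentation is supplied (segments are resampled to a
common length first); with a single segment it is plain cosine
similarity.

## Synthetic data: what it shows and what it does not

The fixture factory generates sheets/spheres, smooth voltage truths
(sums of Gaussian bumps rescaled to the clinical 0.1–3.5 mV range),
activation truths radiating geodesically from one earliest-activation
site, sparse noisy acquisitions of >500 points (0.05 mV voltage noise,
1 ms LAT noise, ≤0.5 mm off-surface jitter), and kinematic
membrane-potential movies (plane waves and Archimedean spirals built
from a stereotyped AP template parameterized by APD90).  Fixtures are
pure functions of (spec, seed).

Passing tests on these fixtures demonstrates that the operators are
correct (interpolation recovers known fields, PS detection finds known
tips, tuning recovers hidden diffusion scales) — not that the pipeline
reproduces clinical correlations: real maps have registration error,
breathing artifacts, non-Gaussian noise and anatomy far from a sheet,
and sustained AF cannot exist on desk-scale geometry at all, because the
reentrant wavelength (CV × APD ≈ 100 mm) exceeds the sheets used here.
The fibrosis↔rotor association test therefore places kinematic spiral
cores by substrate (sampling proportional to regional fibrosis) and
checks the analysis chain, not the emergence of rotors from fibrosis.

## Problem sizes

The test suite and the acceptance script run at deliberately modest
sizes chosen as the smallest that sit in the asymptotic regime of each
check: calibration and CV measurements on 30 × 10 mm sheets at 235 µm
(~6,450 nodes, ~35–65-ms effective runs with early stopping), tuning
recovery on 15 × 6 mm sheets at 500 µm, analysis fixtures on 30 × 30 mm
sheets at 600 µm with 6-s movies at 10–20-ms frames, and the end-to-end
pipeline exercise on a 12 × 6 mm sheet with a shortened ramp.  Full-scale
runs (hundreds of thousands of nodes, 6.5-s ramp plus 6-s analysis) use
the same code paths unchanged.

## Known limitations

* Monolayer surface model: no wall thickness, no transmural
  heterogeneity, no bidomain effects or bath loading.
* The AF-remodeled APD90 measured here at the 500-ms clinical cycle
  length (165 ms) is below some published single-number reports; see the
  rate-dependence table above — the discrepancy is a protocol question,
  not a kinetics one, since the neutral model reproduces the canonical
  ~300-ms APD90 and an independent transcription agrees to sub-ms.
* Fiber fields are synthetic rules (uniform, circular, activation-
  gradient) rather than atlas-derived anatomy.
* Fibrosis draws are spatially independent; clustered/patchy fibrosis is
  not modeled.
* Trajectory linking is greedy nearest-neighbor with no gap tolerance; a
  one-frame detection dropout splits a trajectory.
* `rigid_align` is the only registration primitive; no deformable or
  field-scaling registration of clinical geometry.
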