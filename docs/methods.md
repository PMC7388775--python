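# Methods

This note records the models, conventions, and design choices behind each
stage of the pipeline, including what the synthetic generators do and do
not emulate.

## Pacemaker-cell simulation

**Integrator.** Fixed-step explicit (forward) Euler with dt = 0.1 ms and a
default duration of 10 s, matching the stated simulation protocol for this
class of study; no adaptive solver is offered, so that convergence behavior
is exactly the first-order behavior the tests assert (halving dt halves the
error on the linear relaxation model). Currents are capacitance-normalized
(pA/pF), so dV/dt = −ΣI needs no cell-capacitance constant; the printed
per-pF conductance units are taken at face value. A non-finite state aborts
with the offending step index rather than propagating NaNs.

**Stretch-activated current.** I_SAC,NS = g_SAC,NS·(V_m − E_SAC,NS), linear,
instantly activating, non-inactivating, with defaults g = 0.000248 nS/pF and
E = −10 mV. `calibrate_g_sac` operationalizes "conductance causing an X%
reduction in |MDP|" as a bisection on g: the upper bracket is doubled until
the reduction is exceeded; if oscillation is lost first, a distinct
`BracketingError` is raised (vs plain non-convergence). Steady state is
operationalized as the last 10 complete cycles of the run, with a warning
if their cycle-length CV exceeds 1%.

**Cell-model plug-in contract.** A model names its gating states and its
currents; the integrator owns the voltage update and applies per-current
multiplicative scales (the pharmacology hook; the 4-AP preset is
{I_to: 0, I_K_delayed: 0.75}). Published SAN models are deliberately not
transcribed here: they are external plug-ins through
`load_cell_model("pkg.module:factory")`, and every in-repo workflow runs on
the demo model below. Consequences for interpretation: quantitative BR/APD
percentages obtained on the demo model are properties of the demo model,
not reproductions of any published model's numbers.

**Demo pacemaker.** Five capacitance-normalized currents — I_Ca_L (upstroke),
I_K_delayed (repolarization), I_to (early repolarization), I_f and a small
background Na leak (diastolic depolarization) — with first-order
Hodgkin-Huxley gates. Parameters were tuned, before any acceptance testing,
to a functional specification: cycle length 130–170 ms (mouse-like,
~438 beats·min⁻¹ at default settings), MDP in [−65, −55] mV, peak in
[0, +30] mV, and a 4-AP response that prolongs APD20 by ≥15% while moving
cycle length by <3%. Two tuning decisions matter for that last property:
the delayed rectifier's activation sits relatively positive (midpoint
−20 mV) and deactivates within ~5 ms at diastolic potentials, so scaling it
barely touches diastole; and the L-type window current is kept small
(activation midpoint −28 mV, slope 4 mV), so diastolic depolarization is
carried by I_f plus the leak rather than by a Ca²⁺ window that pharmacology
would perturb. The demo cell's aiding fraction at E_SAC = −10 mV is ~0.79
(long diastolic depolarization), so sustained stretch *accelerates* it —
the rabbit-like pattern, not the mouse-like one; this is a feature for
exercising the phase-alignment machinery, not a defect.

## AP features and phase alignment

Cycle boundaries are local voltage minima (MDP times) found in two passes:
an unconstrained pass estimates the median inter-minimum interval, then a
refractory distance of 40% of that interval plus a prominence filter (25%
of the robust amplitude) rejects double detections; edge-truncated minima
whose prominence is clipped by the trace boundary may be discarded — by
construction these belong to partial cycles.

Feature conventions (the common ones, stated because several are not
standardized in the literature): upstroke time is the maximum of dV/dt;
APD20 runs from the upstroke time to the first interpolated crossing below
peak − 0.20·(peak − following MDP); the diastolic-depolarization rate is
the least-squares slope of V(t) over 10–60% of the MDP→upstroke-onset
interval, with onset defined as dV/dt first exceeding 5% of its maximum.
Reported rates use BR = 60000/CL in beats·min⁻¹ throughout.

Phase alignment labels time *aiding* where sign(dV/dt)·sign(E_SAC − V) > 0
and *opposing* where negative. Because the trace is piecewise linear
between samples, the label can only switch within a step where V crosses
E_SAC; that crossing is located by exact interpolation, so the aiding
fraction of analytic test waveforms (ramps, triangles) is exact rather than
sample-quantized. Zero-measure boundaries (dV/dt = 0 or V = E_SAC) join the
preceding interval — a tie-break with no effect on any integral quantity.

## Chronotropy pipeline

Beat times are peaks of the ECG/force signal with prominence ≥ 30% (default)
of the robust 5th–95th percentile amplitude range and a refractory interval
of 60/max_rate; when the percentile range collapses (sparse spikes on a
flat baseline), the full amplitude range is used instead. The stretch
response at one strain is the signed largest-magnitude deviation of a
3-beat median-smoothed instantaneous-BR series inside the 30 s stretch
window, as a percent of the mean BR in the preceding 10 s baseline window;
a window-mean variant is provided (`mode="mean"`) since either reading of
"change in BR during stretch" is defensible, with peak as default. Repeats
at equal strain are averaged (two expected); the per-preparation summary is
the largest absolute response across strains, ties broken toward lower
strain; and responsiveness-vs-stiffness uses plain OLS with Pearson r and a
two-sided p for the slope. A configurable QC flag marks baselines below
290 beats·min⁻¹ (a mouse-specific exclusion rule); it flags, not filters.

## Tissue mechanics

Stress = force·9.80665/area (gram-force over mm² gives kPa — stress units
are fixed at kPa since source reports leave them unnamed); strain =
(L − L0)/L0, with negative strains returned under a warning rather than
rejected. The stiffness index β is estimated by nonlinear least squares on
stress = α·e^(β·strain) in linear stress space, initialized from the OLS
line through log(stress) vs strain; linear-space NLS is the primary
estimator because it weights the high-stress end the way published visual
fits suggest, and the log-space fit is retained as initializer/diagnostic.
Two points yield the exact interpolating exponential, flagged as such.
Non-positive stresses are excluded with a warning. Under 5% multiplicative
noise on a 0–0.5 strain grid the estimator recovers β with <0.1% mean bias
over 1000 replicates (empirical SD ~0.29 at β = 6).

## Fiber morphometrics

Direction is the largest-eigenvalue eigenvector of the centered coordinate
covariance, projected to the imaging plane and folded to [0, 180)° against
a configurable reference axis (the crista terminalis / stretch direction;
x by default) — folding resolves the eigenvector sign ambiguity.
Orientation histograms use 15° bins (binning is not standardized; 12 bins
over the half-circle is a common choice), per-sample normalized fractions,
and an unweighted cross-sample mean; an alignment fraction within ±20° of
the reference axis quantifies "alignment increase" reproducibly.

Tortuosity is polyline arc length over endpoint chord (≥1, equal to 1 iff
collinear; invariant to rigid motions and uniform scaling). Crimp
wavelength is measured on the lateral-deviation signal (signed in-plane
distance from the principal axis, ordered along it) after removing the bow
— modeled as one half-period sinusoid over the whole fiber plus an affine
trend, fitted by linear least squares — because bow and crimp are distinct
phenomena that stretch affects in sequence. Peaks need prominence ≥20% of
the detrended deviation range, with an absolute floor (10⁻⁹ of the chord)
so float residue of the detrend never counts as crimp; wavelengths are
straight-line distances between consecutive peaks, read as one full period
(peak-to-peak, not peak-to-trough). Fewer than two peaks yields an empty
list with a warning.

## Membrane ultrastructure

The convolution index is (arc/chord − 1)·100 for 2-D tomographic-slice
contours; the mesh form (area/footprint − 1)·100 is the same formula one
dimension up, not a separate algorithm. Membrane area for density
normalization is arc length × slice thickness (275 nm default). Caveola
markers count as sub-sarcolemmal within 150 nm of the contour
(point-to-segment distance; the cutoff is configurable because no standard
exists). The caveolar membrane *fraction* of total sarcolemma follows from
the caveolar *excess* k (membrane added relative to a smooth outline) as
k/(1+k). The composite spare-membrane reserve compounds convolution c and
caveolar excess k multiplicatively, (1+c)(1+k) − 1: caveolae decorate the
already-folded surface, and the multiplicative form is the one consistent
with composing the published component values (10.9% and 117% give 141%;
an additive model gives 127.9%). It is symmetric and reduces exactly to
either component when the other is zero.

## Synthetic-data generators

All generators draw from one explicit `numpy` Generator seeded per call; no
global RNG state. Noise-free outputs are exactly invertible by the
corresponding analysis operation up to stated discretization error, and
ground truth for curved geometry always comes from dense quadrature of the
jitter-free analytic curve, never from the sampled points.

* **AP trains** are four C¹-joined cosine ramps per cycle — diastolic
  depolarization (dd_fraction of the cycle, MDP to a takeoff at 15% of the
  MDP→peak range), upstroke (upstroke_ms), plateau shoulder
  (plateau_fraction, peak down to the 20%-repolarization level), and final
  repolarization. Cosine ramps give monotone phases and analytic phase
  boundaries (so APD20 truth is upstroke_ms/2 + plateau duration exactly);
  they are not splines and carry no stochastic beat-to-beat variability.
  The trace starts half a diastolic interval before the first MDP so all
  n_cycles minima are interior.
* **Beat trains** are unit Gaussian bumps (4 ms FWHM) at beat times laid
  down by stepping each interval from the instantaneous rate (baseline
  plus a signed step inside the stretch window), plus white noise and
  linear drift, sampled at 1 kHz by default. ECG morphology is reduced to
  positive spikes since only peak times enter the analysis; no QRS realism,
  no rate variability beyond the commanded step.
* **Stress–strain** points are α·e^(β·strain)·(1+ε) with multiplicative
  Gaussian ε — matching how measurement error scales with load — on a
  caller-supplied strain grid.
* **Fibers** run along a commanded in-plane direction with sinusoidal
  in-plane crimp, an optional half-period bow, and isotropic Gaussian
  per-point jitter. Planar crimp (no helical component) is a simplification;
  jitter-free truth is used for tortuosity.
* **Membrane profiles** are sinusoids y = A·sin(2πx/λ) with caveola markers
  at Poisson positions along the contour (mean = density × arc × slice
  thickness), kept two radii apart (resampled up to a retry limit, then an
  error), offset one radius beneath the membrane. The generator's caveolar
  excess truth uses a 2-D flask model (one circle circumference of extra
  membrane per caveola).

**What passing tests therefore show** — that each estimator inverts its
generating model at the stated tolerance, that the phase-alignment argument
holds across the synthetic AP family (aiding fraction strictly increases
with plateau fraction), and that the full cohort pipeline recovers a known
responsiveness–stiffness slope. They do not certify performance on real
recordings with baseline wander, ectopy, tracing errors, or non-sinusoidal
crimp, nor do they reproduce published simulation percentages, which
require the external cell model.

## Problem sizes and determinism

Default analysis sizes were chosen as the smallest that leave comfortable
statistical margin: 10 s simulations (≥50 cycles of the demo cell, last 10
analyzed), 1000-replicate stiffness Monte-Carlo, 9-preparation cohorts with
two repeats, 50 fibers × 3 samples per condition, 20 membrane profiles per
phenotype. Every stochastic stage takes an explicit integer seed, and equal
seeds give bit-identical outputs.

## Known limitations

Single-cell only (no tissue-level electrotonic coupling); sustained stretch
only (no diastole-gated cyclic protocols); the demo cell is a functional
stand-in with a rabbit-like phase balance, so mouse-specific simulation
percentages are out of reach without an external mouse SAN model; fiber
analysis starts at traced polylines (no image segmentation); membrane
analysis starts at segmented contours and caveola inventories (no automatic
caveola detection).
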