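# sanstretch

Tools for studying stretch-induced chronotropy of the sinoatrial node
(SAN), the heart's natural pacemaker. In most species, stretching the SAN
raises its beating rate (BR, the Bainbridge response); in mouse the response
is variable and often negative. The leading explanation is geometric: the
current through cation non-selective stretch-activated channels,

    I_SAC,NS = g_SAC,NS · (V_m − E_SAC,NS),      E_SAC,NS ≈ −10 mV,

pulls the membrane potential toward its reversal potential, so it
*accelerates* the intrinsic voltage change during phases when V_m is already
moving toward E_SAC,NS (diastolic depolarization, early repolarization) and
*opposes* it otherwise (late upstroke, final repolarization). The net
chronotropic effect of sustained stretch is set by the balance of these
"aiding" and "opposing" phases — a balance that depends on action-potential
(AP) shape, and hence on species. Tissue-level context matters too: the
chronotropic responsiveness correlates with tissue stiffness (exponential
stress–strain index β), and stretch remodels both the collagen network
(fiber rotation, bow straightening, crimp) and the sarcolemma (unfolding of
membrane undulations and flask-shaped caveolae — the "spare membrane"
reserve).

The package implements that entire computational pipeline, exercisable end
to end on synthetic data with known ground truth:

| module | what it does |
| --- | --- |
| `sanstretch.synthetic` | generators for AP trains, ECG-like beat trains, stress–strain curves, crimped/bowed 3-D fibers, membrane profiles with caveolae — all seeded, all with analytic ground truth |
| `sanstretch.sim` | forward-Euler pacemaker-cell simulation (dt = 0.1 ms, 10 s runs) on a pluggable cell-model contract, with I_SAC,NS, conductance calibration to a target \|MDP\| reduction, and multiplicative pharmacology (4-AP preset: I_to × 0, I_K,delayed × 0.75) |
| `sanstretch.ap` | cycle detection, AP features (MDP, peak, cycle length, APD20, diastolic-depolarization rate), and the aiding/opposing phase segmentation for a given E_SAC |
| `sanstretch.chronotropy` | beat detection from ECG/force peaks, instantaneous BR, per-strain stretch responses with repeat averaging, largest absolute response, OLS regression of responsiveness on stiffness β |
| `sanstretch.mechanics` | gram-force → kPa stress, strain, and the exponential fit stress = α·e^(β·strain) (nonlinear LS, log-linear initialized) |
| `sanstretch.fibers` | PCA fiber direction folded to [0,180)°, polar orientation histograms, tortuosity (arc/chord), crimp wavelength after bow detrending; SWC and CSV I/O |
| `sanstretch.membrane` | convolution index (arc/chord or area/footprint excess), caveolar density, caveolar membrane fraction, and the multiplicative spare-membrane composite |

A published mouse SAN AP model is *not* bundled; `sanstretch.sim.load_cell_model`
accepts any externally supplied model conforming to the `CellModel`
contract. A tunable five-current `DemoPacemakerModel` (mouse-like rate,
~438 beats·min⁻¹) ships in its place so that every workflow runs
self-contained.

## Worked example

Calibrate the stretch current to a 10% reduction in |MDP| on the demo cell,
then compare conditions (this is `analysis/01_simulate_stretch.py`):

```python
from sanstretch.sim import (DemoPacemakerModel, SACParams, FOUR_AP,
                            apply_pharmacology, calibrate_g_sac, integrate)
from sanstretch.ap import detect_cycles, features

model = DemoPacemakerModel()
g = calibrate_g_sac(model, 0.10, tolerance=0.01, duration_ms=4000.0)
res = integrate(model, 10000.0, 0.1, sac=SACParams(g_sac=g, e_sac=-10.0))
```

prints (abridged):

```
calibrated g_SAC = 0.01680 nS/pF (E_SAC = -10 mV)
             cycle_length_ms   br_bpm  mdp_mv  peak_mv  apd20_ms  dd_rate_mv_per_s
control               136.94   438.15  -64.24    15.46      9.45            189.44
stretch                58.86  1019.37  -57.88    12.89      8.92            435.42
4ap                   134.29   446.79  -62.89    30.86     11.70            181.52

aiding fraction of the control cycle (E_SAC = -10 mV): 0.79
4-AP vs control:  BR +2.0%, APD20 +23.8%
```

Reading this: the calibrated stretch current depolarizes the MDP by 10%
(−64.2 → −57.9 mV) and, because aiding phases occupy 79% of this cell's
cycle, sustained stretch *accelerates* it — the rabbit-like pattern. The
4-AP preset prolongs APD20 by ~24% while leaving baseline rate essentially
unchanged (+2%), reproducing the pharmacology's signature separation of AP
shape from rate.

The numbered scripts under `analysis/` run the other stages — the
responsiveness-vs-stiffness cohort regression (fitted slope −2.55 per unit β
against a generating slope of −2.5, r = −0.99, p = 4×10⁻⁷, n = 9), the
stiffness Monte-Carlo (β recovered with <0.1% bias over 1000 noisy
replicates), collagen morphometrics (2.8-fold alignment increase with
stretch at unchanged crimp wavelength), and the membrane reserve — writing
their tables to `results/`.

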