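# lvdose

How far can the x-ray dose of a cardiac CT scan be reduced before
automatically derived left-ventricular (LV) function metrics stop being
trustworthy?  `lvdose` answers this question *in silico*, end to end:

1. **Phantom** — synthetic beating-LV phantoms (truncated prolate-spheroid
   shells with an apex-anchored systolic deformation) with closed-form
   ground truth for ejection fraction (EF), global longitudinal strain
   (GLS), circumferential strain (CS) and wall thickening (WT);
2. **Scanner** — a parallel-beam CT simulator that inserts Poisson quantum
   noise and Gaussian electronic noise in the projection domain and
   emulates reduced tube currents (mA) from a single standard-dose scan by
   incremental noise injection, then reconstructs with Hann-filtered FBP;
3. **Observers** — a residual 3D U-Net segmenter (background / myocardium /
   LV blood pool) trained with the generalized Dice loss, in two arms
   (*Standard*: standard-dose data only; *Noise-Robust*: warm-started from
   Standard and tuned on the emulated low-dose ladder), plus a
   deterministic rule-based observer;
4. **Measurement** — reformatting into two long-axis views (2-CH, PLAX) and
   three short-axis views (basal/middle/apical), then EF, GLS, CS per SAX
   level, and 16-spoke WT;
5. **Study** — the dose-ladder experiment: every observer segments every
   rung (500, 100, 50, 25, 10 mA), each low-dose result is compared with
   the same observer's standard-dose result (Dice overlap and metric
   deltas, in percentage points), and an explicit rule detects the lowest
   acceptable tube current (90th-percentile |Δ| ≤ 2.5 pp for EF, GLS, CS).

The intended audience is researchers prototyping dose-reduction studies or
validating functional-measurement pipelines who want exact ground truth
and a fully reproducible, CPU-sized testbed.

## Core quantities

With ED as the reference phase (shortening negative):

- EF = 100·(EDV − ESV)/EDV from blood-pool voxel volumes;
- GLS = 100·(L_ES − L_ED)/L_ED, L the apex-to-basal-plane cavity length,
  averaged over the 2-CH and PLAX views;
- CS = 100·(P_ES − P_ED)/P_ED, P the endocardial perimeter traced by 360
  radial rays in a SAX view;
- WT_k = 100·(t_ES,k − t_ED,k)/t_ED,k along 16 spokes equally spaced over
  360°, averaged per SAX level;
- observer agreement: Dice = 2|A∩B|/(|A|+|B|), Pearson ρ.

For the phantom all of these have closed forms (e.g. EF = 100·(1 −
s_r²·s_l) for endocardial ES scale factors s_r, s_l), which is what makes
the pipeline testable to fractions of a percentage point.  See
`docs/methods.md` for the model, its assumptions and all numerical
choices.

## Worked example

```python
import numpy as np
from lvdose import phantom, ct_sim, metrics
from lvdose.segmenter import RuleBasedObserver
from lvdose.volumes import Grid

spec = phantom.build_phantom_spec(target_ef_pct=60.0)
gt = phantom.analytic_ground_truth(spec)

grid = Grid.centered(64, 2.25)
geom = ct_sim.ScanGeometry(n_detectors=96, detector_pitch_mm=1.6, n_angles=96)
acq = ct_sim.AcquisitionSpec(tube_current_mA=500.0)

observer = RuleBasedObserver()
segs = {}
for phase in ("ED", "ES"):
    labels, image = phantom.voxelize_phase(spec, phase, grid)
    ladder = ct_sim.emulate_dose_ladder(image, geom, acq, [500.0, 25.0], seed=7)
    segs[phase] = {mA: observer.segment(vol) for mA, vol in ladder.items()}

for mA in (500.0, 25.0):
    fm = metrics.compute_all(segs["ED"][mA], segs["ES"][mA])
    print(f"{mA:5.0f} mA: EF {fm.ef_pct:5.2f}%  GLS {fm.gls_pct:6.2f}%  "
          f"CS_mid {fm.cs_pct['middle']:6.2f}%")
print(f"truth   : EF {gt.ef_pct:5.2f}%  GLS {gt.gls_pct:6.2f}%  "
      f"CS_mid {gt.cs_pct['middle']:6.2f}%")
```

prints

```
  500 mA: EF 60.32%  GLS -13.63%  CS_mid -29.79%
   25 mA: EF 60.47%  GLS -15.48%  CS_mid -28.43%
truth   : EF 60.00%  GLS -15.00%  CS_mid -29.00%
```

i.e. even at a 20× dose reduction the simulated-scan metrics stay within
a couple of percentage points of the analytic truth and within ~1.9 pp of
their own standard-dose values (EF moves by 0.15 pp), while the
segmentation itself visibly roughens — Dice of the 25 mA myocardium
segmentation against the standard-dose one is 0.916 here.  (The residual
standard-dose biases, e.g. GLS −13.6 vs −15.0, come from the coarse
2.25 mm simulation grid and the threshold observer, not from the
measurement chain: on generator labels at 0.75 mm every metric recovers
its closed-form value to well under a percentage point — see the test
suite.)

A command-line surface wraps the same stages (`lvdose phantom`, `lvdose
ctsim`, `lvdose segment`, `lvdose metrics`, `lvdose study`); every run
writes a manifest with the resolved configuration and seeds.

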