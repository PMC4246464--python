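# cinedense

Contour-based post-processing of **cine DENSE** (Displacement ENcoding with
Stimulated Echoes) cardiovascular MR: from wrapped displacement-encoded
phase images and myocardial contours to circumferential/radial/longitudinal
strain curves, left-ventricular twist, and torsion — including the
**three-contour simplified workflow** and the agreement statistics used to
validate it against full manual contouring.

DENSE stores the in-plane displacement **u** of the tissue at each pixel in
the signal phase, φ = 2π·k_e·u (k_e is the displacement-encoding frequency,
e.g. 1.0 cycles/mm in mice, 0.1 in humans).  Contours only *mask* which
pixels carry tissue displacement; they never enter the strain computation
directly.  That is what makes the simplification work: instead of drawing
endo+epi boundaries on every one of 20–30 frames (40–60 contours per
slice), the user draws **three** — the end-diastolic endocardium and
epicardium (the resting configuration) and the end-systolic endocardium —
and the package propagates them: ED epicardium to every frame, ES
endocardium to every frame but the reference, for a ~94% reduction in
contouring workload.

The processing chain (identical for full and simplified contour sets):

1. pixel-center rasterization of the myocardial annulus per frame;
2. seeded, quality-guided path-following 2D phase unwrapping per frame and
   encoding direction;
3. u = φ/(2π·k_e); noise-pixel rejection by phase-difference variance;
   thin-plate scattered interpolation of (reference position → displacement)
   to invert the Eulerian sampling;
4. mesh of the resting configuration (128 circumferential × 5 radial
   elements), deformed along node trajectories smoothed by a 10th-order
   polynomial in time pinned to the resting position;
5. per-element Green–Lagrange strain **E** = ½(FᵀF − I), expressed in
   rest-frame circumferential/radial directions as percentages; segment
   averages from the anterior RV insertion; twist = mean node rotation;
   torsion = OLS slope of twist vs slice location (deg/cm);
6. agreement between two analyses: modified coefficient of variation
   CoV = Σ StDev(x_o, x_s) / |Σ (x_o+x_s)/2| × 100, curve RMSE, and
   Bland–Altman bias ± 1.96·SD limits of agreement.

An analytic phantom — an incompressible contracting, twisting annulus with
exact DENSE phase encoding — provides ground truth (closed-form strains and
torsion) for every stage.  See `docs/methods.md` for the model details.

## Worked example

Simulate a mouse-like phantom slice (128×128, 0.25 mm pixels, 20 frames,
20% peak endocardial contraction, 4° peak twist, 0.05 rad phase noise),
then analyze it with the full per-frame truth contours and with the
three-contour simplification, and compare:

```
$ cinedense simulate --frames 20 --seed 1 --out phantom.h5
wrote phantom.h5 (1 slice(s))

$ cinedense analyze --container phantom.h5 \
    --contours phantom_slice00_contours.json --mode full --out run_full
[    0.05s] slice00: mode=full, contours consumed: 40
[    3.17s] slice00: peak mid-wall tangential strain -11.50%

$ cinedense analyze --container phantom.h5 \
    --contours phantom_slice00_contours.json --mode simplified --out run_simple
[    0.06s] slice00: simplified contours (ES frame 9)
[    0.06s] slice00: mode=simplified, contours consumed: 3
[    3.51s] slice00: peak mid-wall tangential strain -11.50%

$ cinedense compare --a run_full --b run_simple --out agreement.csv
$ head -3 agreement.csv
measure,n,bias,loa_halfwidth,cov_percent,rmse
peak_Ecc_percent,6,0.0046,0.0271,0.0694,0.0135
peak_Err_percent,6,-0.6687,0.7793,3.1425,0.7608
```

Reading the numbers: the closed-form peak mid-wall circumferential strain
of this phantom is ½(λ_c²−1) = −11.52%, and both analysis arms recover
−11.50%.  The full run consumed 40 contours (2 × 20 frames), the
simplified run 3.  Comparing the two arms over the six segments, peak Ecc
agrees with a bias of 0.005% strain, 95% limits of agreement ±0.03%, and a
modified CoV of 0.07%; radial strain, computed from only a few pixels
across the wall, is the least robust measure (CoV 3.1%) — both orderings
expected for this kind of data.  Each run directory contains the per-frame
segmental curves (`slice00_curves.csv`), signed peaks
(`slice00_peaks.csv`), the fully resolved configuration (`config.toml`),
and a log; multi-slice runs (`simulate --slices 3 --torsion 1.5`) add a
per-frame `torsion.csv`.

The same operations are available as a library:

```python
from cinedense import PhantomSpec, render_slice, analyze_slice

dense, truth = render_slice(PhantomSpec(seed=1))
result = analyze_slice(dense, truth.contour_set)
print(result.peak_midwall_ecc_percent)   # -11.504
print(truth.peak_midwall_ecc_percent)    # -11.52 (closed form)
```

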