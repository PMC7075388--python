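# flatbeam

Sliding-window leaf trajectory optimization for delivering **conventional
flat beams with a flattening-filter-free (FFF) photon beam**.

Modern linacs can run without the flattening filter: the dose rate more
than doubles and head scatter drops, but the raw fluence is strongly
forward-peaked, so conventional 2D/3D treatments that expect a flat field
can no longer be delivered as open fields. `flatbeam` plans dynamic MLC
deliveries that *modulate the FFF beam into a flat one*: both leaves of
every pair sweep across the field while the beam is on, and the per-bixel
exposure times are chosen so the delivered planar dose matches the flat
reference of the filtered beam.

The core is a single convex program over the leaf trajectories — the
direct-trajectory alternative to the usual two-step "optimize a fluence
map, then sequence leaves" pipeline, which can destroy flatness at the
sequencing step. For leaf pair *n* and bixel boundary *j*, the variables
are the boundary arrival/departure times of the leading and trailing
leaf, `r_in/r_out` and `l_in/l_out`; the exposure of bixel *(n,j)* is

    t_nj = ½[(l_out,nj − r_out,nj) + (l_in,n,j+1 − r_in,n,j+1)],

fluence is `x_nj = DR·t_nj` at constant dose rate, dose is
`d_i = Σ_nj D_nij x_nj`, and the objective

    λ₁ Σ_i (d_i − d_iᴰ)² + λ₂ T + λ₃ Σ_nj (|x_nj^LTG| + |x_nj^RTG|)

balances dose fidelity against total beam-on time `T` and
tongue-and-groove (T&G) strip fluence between adjacent leaves. Every
dynamic MLC limit — 6 mm minimum gap at every instant, 6 cm/s leaf speed,
15 cm overtravel, 20 cm same-bank carriage span, synchronized beam-off —
enters as a linear constraint, so the program is convex and the returned
trajectories are globally optimal *and* deliverable by construction. The
solver is an in-package Mehrotra predictor–corrector interior-point
method (matrix-free for large fields). Machine defaults describe an
Agility-class 160-leaf MLC; the beam model is a documented synthetic
stand-in (radial FFF falloff ≈ 0.70 at 10 cm off-axis; double-Gaussian
penumbra/scatter kernel), not commissioned data.

## Worked example

```python
from flatbeam import LeafTrajectoryModel

model = LeafTrajectoryModel.from_field("square", side=10.0)
results = model.fit()
print(results.summary())
```

prints (abridged):

```
Leaf Trajectory Optimization Results
====================================================
field                       square_10
active rows                 20
variables / constraints     3761 / 5681
solver status               optimal (8 iterations, 1.2 s)
weights l1/l2/l3            1 / 0.001 / 0
beam-on time T              16.012 s
total MU                    373.6
objective (dose/time/T&G)   3.73 / 0.01601 / 0
deliverable                 yes

family                   worst slack  units pass
ordering                   1.073e-02  s     yes
speed                      1.292e-02  s     yes
min_gap                   -3.331e-16  cm    yes
overtravel                 1.060e+01  cm    yes
bank_span                  1.960e+01  cm    yes
beam_off_sync             -0.000e+00  s     yes
```

A 10×10 cm² flat field is delivered in ~16 s of beam-on time at
1400 MU/min; the constraint report certifies the trajectory against every
machine limit on the reconstructed leaf motion (negative slack would be a
violation). Downstream:

```python
dose = results.dose(normalized=True)       # planar dose, CAX = 1.0
cps  = results.control_points(50)          # equidistant-MU control points
from flatbeam import write_plan
write_plan(cps, "plan.json")               # RT-plan-like JSON (or CSV)
```

The same pipeline is scriptable from the shell:

```
flatbeam plan --field square --size-cm 10 --out runs/sq10
flatbeam sweep --field mantle_like --which lambda3 --ratios 0.01,0.1,1,10
flatbeam fixtures --out fixtures/
flatbeam validate runs/sq10/plan.json
```

`run_field` writes a metrics report per field — IEC flatness of the
crossline/inline profiles (100·(Dmax−Dmin)/(Dmax+Dmin) over the central
80 % of the field), the 3 %/3 mm local-gamma pass rate against the flat
reference with a 10 % dose threshold, delivery time, total MU and the
T&G fluence sum. Optimized square fields from 10×10 to 30×30 cm² come
out with sub-percent-to-~2 % flatness and 100 % gamma pass rates against
their flat references; enabling the λ₃ term on the concave mantle-like
field cuts the worst T&G underdose dip in the inline profile from ≈8 %
to ≈1.6 % of the CAX dose. See `docs/methods.md` for the model,
assumptions, and what the synthetic world does and does not establish.

## Acceptance script

```
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

re-runs the headline computation from scratch: it rasterizes the 10×10,
20×20 and 30×30 cm² square fields at 0.2 cm bixels, solves the trajectory
program at the default weights against the flat reference on a 0.2 cm
dose grid, computes the dose of the optimized fluence, scores IEC
flatness on the crossline and inline central-axis profiles of each field,
and writes the median of the six values (in percent) as JSON.
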