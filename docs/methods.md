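# Methods

`flatbeam` plans sliding-window dynamic MLC deliveries that reproduce a
conventional *flat* dose map using the forward-peaked fluence of a
flattening-filter-free (FFF) photon beam. The entire planning problem —
dose fidelity, delivery efficiency, tongue-and-groove (T&G) control and
every dynamic MLC limit — is a single convex program over the leaf
trajectories, so the solution returned is the global optimum.

## The trajectory model

Leaves sweep unidirectionally in +x. For leaf pair *n* and bixel
boundary *j*, four times describe the delivery: the arrival/departure
times `r_in/r_out` of the leading (right-bank) leaf and `l_in/l_out` of
the trailing (left-bank) leaf. With linear motion between boundaries,
the exposure of bixel *(n, j)* is exactly the trapezoid average

    t_nj = 1/2 [ (l_out[n,j] - r_out[n,j]) + (l_in[n,j+1] - r_in[n,j+1]) ]

and fluence is `x_nj = DR * t_nj` at the constant nominal dose rate
`DR` (1400 MU/min for the unflattened beam; dose-rate modulation is not
modeled). The dose at plane voxel *i* is `d_i = sum_nj D_nij x_nj`
through the influence operator below, and the objective is

    lambda1 * sum_i (d_i - d_i^D)^2  +  lambda2 * T
        +  lambda3 * sum_nj ( |x_nj^LTG| + |x_nj^RTG| )

subject to, per row: time ordering (`in <= out`), leaf speed
(`in[j+1] - out[j] >= bixel_width / v_max`), the minimum dynamic gap,
overtravel bounds (applied as clamps on each leaf's reachable boundary
range), same-bank carriage-span constraints generated only for flagged
pairs, and a shared beam-off time `T` equal to every trailing leaf's
final departure. All constraints are linear; the objective is convex
(the T&G magnitudes enter through epigraph auxiliaries `s >= ±expr`).

Defaults follow the published operating point: `lambda1 : lambda2 =
1000 : 1`, and `lambda1 : lambda3 = 0.1` (i.e. `lambda3 = 10 lambda1`)
when T&G control is enabled; T&G control is off by default and enabled
per field, mirroring its selective clinical use for concave apertures.

### Gap enforcement in continuous time

The index-shifted family `r_out[n,j] <= l_out[n, j-G]` (with
`G = min_gap / bixel_width`, integral by construction) keeps the
trailing leaf at least `G` bixels behind — but only *at boundary
crossings*; between crossings the piecewise-linear tips can close the
gap by up to one bixel. The model therefore adds the symmetric arrival
family `r_in[n,j] <= l_in[n, j-G]`. For piecewise-linear motion the
instantaneous gap is piecewise linear in time with extrema at crossing
events, so the two families together are *exactly* equivalent to
`gap >= min_gap` at every instant. The deliverability validator checks
this on the reconstructed position-time curves at the union of all
breakpoints, which is exhaustive for the same reason.

### Parking convention and its consequences

The trailing leaf parks at the row's left edge `x_start`, the leading
leaf at `x_start + min_gap`; delivery ends with the trailing leaf at
`x_end - min_gap` and the leading leaf at `x_end` (clamped by
overtravel for very wide rows, in which case the uncovered bixels stay
exposed from beam-on or until beam-off and the parked crossing times
are the constants 0 / T). Two structural facts follow:

- The `G` window-opening bixels of each row are exposed from t = 0, and
  the leaf-speed limit forces their exposure times to *increase* by at
  least `bixel_width / v_max` per bixel (each is a sum from a monotone
  time chain). A perfectly uniform fluence profile is therefore
  unreachable in the outermost `G` bixels — a kinematic staircase of
  `~0.78 MU` per bixel at the default machine. Its dose signature is
  confined to the penumbra region and is invisible to the central-80%
  flatness and 3%/3 mm gamma scores.
- Properties like "optimal fluence scales linearly with the desired
  dose" hold exactly in the window interior but not in the staircase
  bixels (the staircase step is kinematic and does not scale).

### Carriage constraints at scale

Preprocessing flags a same-bank pair when its start/start, start/end or
end/end tip positions differ by more than the 20 cm carriage span. For
wide sweeps (30x30 cm^2 and beyond) the start-vs-end test flags *every*
pair, and the pairwise constraint family would reach ~10^6 rows. The
model then swaps in the equivalent envelope form: one variable `u_g`
per boundary with `f(n, g) <= u_g <= f(m, g + S)` over the involved
rows, which has the same feasible set — unflagged pairs cannot violate
the span, by the same preprocessing argument — at O(rows x boundaries)
size. For small flag sets the pairwise form is generated as such. In
both forms, constraints are generated only between genuine trajectory
variables: a comparison against a *parked* boundary (a leaf that never
visits it; crossing time 0 or T by convention) is either trivially
slack or not a statement about real motion, and pinning envelope
variables against such constants makes the program dual-degenerate.
The positional span itself is always re-verified on the delivered
motion by the constraint validator.

## Beam and dose model

The dose engine is a deliberately simple, documented stand-in for a
commissioned pencil-beam system; no depth physics is modeled and the
"10 cm depth / 100 cm SAD" plane is geometry labeling only.

- **Off-axis intensity** (fff mode): `1 - 0.0325 r + 0.00025 r^2`,
  clipped below at 0.2 — 1.0 on axis, ~0.70 at r = 10 cm, ~0.45 at
  r = 20 cm, the typical published falloff of a 6 MV FFF beam. A
  measured two-column radius/intensity table can be substituted. Flat
  mode is identically 1.0 and generates the reference.
- **Kernel**: two isotropic Gaussians — penumbra core sigma 0.25 cm,
  weight 0.85; scatter tail sigma 1.5 cm, weight 0.15 — normalized to
  unit integral. The tail makes small fields measurably non-flat: a
  10x10 cm^2 flat-reference field loses ~4% of its dose 1 cm inside the
  edge, so its central-80% flatness is ~1.9% (20x20 and larger are
  <1%). This is a property of the stated beam model, mirrored equally
  in the reference and in the optimized dose, so difference metrics are
  unaffected.
- **Influence operator**: `D_nij = off_axis(bixel center) x` (kernel
  integrated over the 0.2 x 0.5 cm bixel footprint, sampled at voxel
  centers). Because the kernel is a Gaussian mixture this factorizes
  exactly into per-component 1D edge-response operators (a Kronecker
  structure); the operator is stored and applied in that form, and a
  sparse materialization (entries < 1e-6 of the peak dropped) is
  available for small problems and cross-checks.

### Prescription scale

The flat reference is CAX-normalized; before optimization it is scaled
to a prescription fluence, default **35 MU at the CAX**. The scale is
physically load-bearing: a sliding window can deliver no less than
`min_gap / v_max * DR = 2.33 MU` to any bixel it crosses, so a target
near 1 MU would be unreachable. 35 MU clears that floor ~15x and puts
delivery times near the clinically reported range (about 20 s for a
10x10 cm^2; about 72 s for a 30x30 cm^2, where compensating the
off-axis falloff demands up to 2.3x corner fluence). Flatness and gamma are invariant to
this scale.

## Solver

The program is a convex QP with ~4 variables per bixel boundary (about
35,000 for a 30x30 cm^2 field at 0.2 cm bixels) and a similar number of
linear inequalities. It is solved by an in-package Mehrotra
predictor-corrector primal-dual interior-point method. The Newton
systems `(P + A' W A + delta I) dx = rhs` are solved:

- **directly** (sparse LU) when the field is small enough for an exact
  sparse Hessian (<= 400 bixels), or
- **matrix-free** with preconditioned CG: the Hessian is applied
  through the Kronecker-factorized influence Gram (a few small dense
  multiplications), and the preconditioner is a sparse LU of a banded
  Gram truncation filtered to within-row blocks plus the shared-time
  arrowhead, added to the exact barrier term A'WA. Carriage-envelope
  rows are excluded from the preconditioner (they couple every row and
  cause heavy factorization fill) but remain in the exact operator —
  they are far from active at the optimum, so CG absorbs the
  difference.

Default tolerances: primal feasibility 1e-9 (relative), duality-gap
1e-8, inner CG tolerance adaptive in the barrier parameter with floor
1e-9. These deliver dose residuals at the 1e-3 relative level and
constraint satisfaction many orders below the validation tolerances
(1e-5 s / 1e-4 cm). The method is deterministic; repeated fits
reproduce objectives bit-for-bit. Relative weight magnitudes are
normalized away internally, so the published weight ratios can be used
directly at any lambda1.

## Delivery conversion

Control points sample the trajectories at equidistant cumulative MU
(equivalently time), endpoints included; positions invert the
piecewise-linear crossing times, with dwells mapping to constant
position. Reconstruction accumulates, per bixel center, the time the
center lies strictly between the two tips assuming linear motion
between control points. Exposure of a bixel center under the exact
trajectories equals the trapezoid `t_nj` identically, so the
reconstruction error is purely a sampling effect; on a 20x20 cm^2
field the worst bixel error decays from 0.20 s at 100 control points to
0.019 s at 400 — faster than the nominal 1/n, because the worst bixels
are the opening-staircase ones whose trajectories become exactly
representable once samples are dense enough.

## Tongue-and-groove evaluation

The optimizer penalizes the linear strip-time expressions (adjacent-row
differences of trailing/leading crossing-time sums, as magnitudes via
epigraph variables). The *evaluation* of T&G dose damage is deliberately
independent of that approximation: sliding-window motion makes each
row's open interval at a point a single time interval, so the 1 mm strip
between adjacent leaves carries the exact intersection of the two rows'
open intervals. A fine-row (0.5 mm) fluence image with these strip times
is convolved with the beam kernel to produce the T&G-aware dose map.
Strips bordering closed or inactive rows are treated as fully blocked by
the neighbor's tongue — a binary worst case; partial transmission
through the tongue is not modeled.

The dip score of a profile is its deficit against a local-maxima
envelope (grey closing, 3 cm window), ignoring features narrower than
0.5 cm (grid noise) and regions where the envelope is below 20% of the
CAX (the out-of-field tail, where morphological closing produces
boundary artifacts, carries no meaningful dips). On the mantle-like
fixture the *inline* CAX profile is the sensitive one: the corner scoop
staggers row starts, so each leaf-edge strip is nearly uniformly
darkened along x (no local crossline dips) while the inline profile
shows one dip per strip. Enabling the T&G term cuts the worst inline
dip from ~8.3% to ~1.6% of the CAX dose.

## Synthetic fields

Built-in parametric contours stand in for the published study set:
squares (10-40 cm), the 15x6 cm^2 spine rectangle, an offset
`spine_asym`, a smooth-waisted `hourglass`, a superelliptic
`whole_brain_like`, and `mantle_like` — a box with a concave
inferior-corner scoop. A centered inferior notch would split leaf rows
into two disjoint apertures (out of scope by design); the corner scoop
keeps one interval per row while still forcing the adjacent-row
trajectory mismatch that provokes T&G stripes. The published study's
exact contour coordinates are not available, so no coordinate-level
agreement is claimed; the fixtures reproduce the *class* of geometry
(convexity features, aspect ratios).

## What a green test does and does not establish

The synthetic world shares one kernel between the reference and the
optimized beam, has no measurement noise, no head-scatter dependence on
aperture (the published discussion identifies in-air scatter as the
main residual discrepancy source — explicitly not modeled here), no
rounded leaf tips, no interleaf transmission, and no absolute MU
calibration. Green flatness/gamma tests therefore establish that the
*optimization and conversion machinery* reproduces a reachable target
through a deliverable trajectory set — not that a physical accelerator
delivery would measure the same numbers. Conversely, the constraint
certificate (gap/speed/overtravel/span/sync at 1e-5 s, 1e-4 cm on the
reconstructed motion) is machine-meaningful as stated.

## Known limitations

- Single aperture per leaf row; no islands, no interdigitation
  restrictions (the modeled MLC interdigitates).
- Constant dose rate; no jaw tracking; 2D evaluation plane only.
- The T&G strip model is binary (blocked/open) at the strip level.
- The interior-point method's matrix-free path assumes the influence
  operator is a Gaussian mixture; exotic kernels require the exact
  sparse path (small fields) or a new preconditioner.
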