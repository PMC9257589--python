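# Methods

## Scope and data flow

The package estimates iris sphincter muscle traction relative to stromal
stiffness from pupillary light reflex (PLR) imaging. The measurement
chain is: NIR frame sequence → pupil/limbus tracking → margin Lagrangian
strain → (optionally) full-field strain by digital image correlation →
inverse finite-element identification of the traction-to-stiffness
ratio `T_s : E` and its dependence on the assumed sphincter width `a_s`.
Real recordings are supplied as frame directories; a synthetic generator
with closed-form kinematics stands in for them everywhere in the test
suite.

## Synthetic PLR sequences

The generator emulates a 30 s, 25 Hz NIR recording at 768x576 px and
39 um/px: 15 s dark acclimation, 5 s light stimulus, 10 s darkness.
The pupil-to-limbus radius ratio `beta` is 0.566 dark-adapted and falls
to 0.262 at maximum constriction (cohort means of the reference
protocol); the constriction and recovery follow exponentials with
defaults of 0.5 s and 4 s. No published time constants exist for this
protocol; the defaults qualitatively match the published radius traces
and are not estimates. Recovery is asymptotic, hence never complete
within the recording, as observed.

Material points move by a kinematic map that is linear in reference
radius between the moving pupil margin and the fixed limbus. The radial
stretch is then spatially uniform, matching the empirical observation
that the radial strain is nearly constant across the iris, and every
Lagrangian strain component is available in closed form as ground truth
(`render_sequence` also accepts an arbitrary monotone radial map, used
to drive the renderer with the FE model's own equilibrium kinematics in
the closed-loop test).

The iris texture is a sum of three band-passed seeded noise octaves on a
polar lookup grid with feature sizes fixed in physical units (0.12-0.7 mm)
and mild (~1.5:1) radial elongation, mimicking crypts and furrows.
Stronger elongation is realistic but starves subsets of circumferential
gradient content: with a 3:1 texture the DIC stage underestimates radial
displacement systematically by ~10-15%, reproducing the known weakness
of subset correlation on radially oriented iris features. The default
keeps the generator in the regime where DIC is validatable against the
closed form; the anisotropic failure mode is thereby documented but not
exercised by the tests. Corneal glints are rendered as saturated discs
fixed in image coordinates (they are reflections, not tissue, and do not
advect); eyelid occlusion is an optional intensity band. Rendering is
pure: (config, seed) determines every frame bit-for-bit, with per-frame
noise streams derived from (seed, frame index).

What the generator does not emulate: corneal refraction and its
radially varying distortion, iris curvature and out-of-plane motion,
gaze drift, hippus, blinks (excluded frames are instead injected
explicitly in tests). Passing tests therefore demonstrate correctness
of the algorithms on ideal-optics data, not robustness to every
confound of real recordings.

## Tracking

Pupil: 3x3 median filter, binarisation of pixels darker than 0.1
(normalised intensity; an Otsu fallback is available), a 2-px square
erosion/dilation pass, hole filling, largest connected component,
`r_p = sqrt(area/pi)`. Components hugging the image border are
rejected. Limbus: Daugman's integro-differential operator — the centre
and radius maximising the Gaussian-smoothed (sigma 2 px) radial
derivative of the mean intensity on circular arcs restricted to lateral
±45° sectors (eyelid avoidance); saturated pixels are excluded from the
arc means (glint rejection). Because lateral-arc integration has a
degenerate off-centre/small-radius valley, the search first scans
radius at the hinted centre, then refines centre and radius locally,
visiting candidate centres outward from the hint. Sequences are
analysed every 10th frame (2.5 Hz effective); each frame's limbus
search is seeded by the previous frame within ±6 px.

Margin strains use `eps_i = ((r_i/rbar_i0)^2 - 1)/2` with the reference
radius averaged over the acclimation phase; the maximum-constriction
strain averages the pupil strain over 17-20 s. QC excludes scans more
than 3 sd from the cohort mean (single pass); cohort statistics average
test-retest scans per eye first and use a normal-theory 95% CI
(z = 1.96, configurable; the reference cohorts have n of order 40).

## Digital image correlation

Incremental subset correlation between consecutive analysed frames from
light onset: 31 px subsets on a 4 px grid (defaults; tests use 17 px
subsets on half-scale images), NSSD criterion with affine subset shape
functions, integer-pixel coarse search (visited outward from zero so
featureless subsets keep the null hypothesis) followed by batched
Gauss-Newton refinement on cubic-spline interpolated intensities.
Cumulative displacement advects each point; an increment's match is
rejected — permanently, matching practice — if the final update exceeds
the 0.1 px matchability threshold or the final NSSD cost exceeds 0.05.

Strain is post-processed by local least-squares affine fits of the
cumulative displacement over a square window of grid points (window
size in grid units, the convention of commercial subset-DIC software;
15 at full scale), giving F and `E = (F^T F - I)/2`, rotated into polar
components about the reference pupil centre. Profiles take per-bin
medians/IQRs over a box through the pupil centre of total height half
the reference pupil radius and width the limbus diameter, against the
normalised coordinate `x_bar` (0 pupil margin, 1 limbus), pooling the
nasal and temporal arms. Outlier curves are screened by symmetric
Hausdorff distance to the pointwise median curve (exclude beyond
mean + 2 sd; threshold configurable — the reference procedure does not
state one). A virtual tensometer evaluates the chord between the two
tracked points nearest the nasal-temporal axis just outside the margin.

## Forward model

The iris is a thin annular disc: compressible neo-Hookean stroma

    Psi = mu [ (I1 - 3)/2 - ln J ] + (lambda_L/2) (ln J)^2,
    mu = E/(2(1+nu)),  lambda_L = E nu/((1+nu)(1-2nu)),

with principal Cauchy stresses
`sigma_i = (mu (lambda_i^2 - 1) + lambda_L ln J)/J`. The sphincter is an
active circumferential fiber stress of magnitude `T_s` prescribed in the
reference configuration on the material ring `R in [R_in, R_in + a_s]`;
its push-forward contributes `(T_s/J) lambda_theta^p` to the hoop Cauchy
stress with `p = 2`, the convention of standard active-contraction
implementations in nonlinear FE codes (the deformed fiber `F a0` enters
unnormalised). `p` is configurable; `p = 0` prescribes the Cauchy
magnitude directly and yields a much more compliant response (fitted
ratios roughly half), outside the published range.

Geometry: `R_in = 3.4 mm` (dark-adapted pupil), `R_out = 6 mm` (limbus),
thickness 0.17 mm. Boundary conditions: traction-free inner edge,
fully fixed outer edge (the measured limbus strain is negligible).
Through-thickness stretch is eliminated pointwise by the plane-stress
root `sigma_zz = 0` (scalar Newton, monotone residual, unique root).
Equilibrium is enforced in the thin-limit membrane form

    d(r N_rr)/dr = N_tt,   N = lambda_z sigma,

i.e. on thickness-weighted stress resultants — the consistent reduction
of a thin 3D disc whose thickness changes with deformation. At small
strain this coincides with the pointwise radial equilibrium ODE, which
is what the independent linear oracle in the tests discretises.

Discretisation: 1D Galerkin, linear elements (default 100, with a node
placed exactly at the sphincter outer edge to avoid the active-region
boundary cutting an element), 2-point Gauss quadrature, analytic-free
banded Jacobian by element-level finite differences, Newton with
damped positivity-guarded updates, tolerance 1e-9 on the scaled
residual norm, load ramped in 10 increments with adaptive halving.
A warm-start entry point solves directly at full load from a nearby
converged state (used heavily by the inverse stage; verified to agree
with the cold ramp to 1e-10). The pupil-margin strain is converged to
~1e-5 at 50 elements; 100 is comfortable margin at ~35 ms per solve.

Properties the implementation guarantees (all under test): stress-free
reference, exact `(E, T_s)` scale invariance of the deformation, strict
monotonicity of `|eps_p|` in `T_s/E`, `J > 0` and monotone `r(R)`,
zero hoop strain at the fixed limbus, peak radial strain at the
sphincter's outer edge, small-strain agreement with an independent
linear finite-difference oracle to <1%. Because the active stress
scales with `lambda_theta^2`, constriction is self-limiting: extreme
tractions drive the pupil towards, but never through, full closure.

## Inverse identification

The objective is `|eps_p(model) - eps_p(measured)|`. `fit_single` runs
25 Nelder-Mead starts (gradient-free: the FE objective has noisy
numerical derivatives) from a deterministic unscrambled-Halton layout
over the box `0 < E < 1000 kPa, 0 < nu < 0.5, 0 < T_s < 1000 kPa`,
accepting fits below 1e-3 strain. Only `T_s/E` is identifiable; the
reported ratio is the through-origin least-squares slope of `T_s` on
`E` over accepted fits (scale invariance forces a zero intercept; the
free-intercept slope and the median per-fit ratio are reported as
diagnostics). `ratio_root` is the independent cross-check: with `E = 1`
and `nu` fixed, Brent root-solving of `eps_p(rho) = target`.

Poisson's ratio is unidentifiable — every `nu` in the box fits the
target equally well — but the fitted ratio is not independent of `nu`:
at `a_s = 1 mm` the fixed-`nu` ratio spans 5.06 (nu = 0.49) to 6.65
(nu = 0.05), and more at narrower widths, because the through-thickness
stretch couples `nu` into the membrane equilibrium. The multi-start
slope therefore effectively marginalises `nu` over its search range,
which is also what the reference identification procedure does; the
width sweep uses it by default, with the fixed-`nu` root solve always
reported alongside. The power law `T_s:E = (A/a_s)^B` is fitted by
nonlinear least squares started from the exact log-linear solution,
with 95% CIs from the linearised covariance and t-quantiles at n-2 df.

Default identification target: -0.386, the cohort mean maximum
pupil-margin strain of the reference protocol, so the inverse stage
runs with no image input.

## Problem sizes used in tests

Rendering and DIC tests run at half resolution (384x288 px, 78 um/px)
with 17 px subsets, and the validation contraction stops at
`beta = 0.40`; these sizes keep full-chain validation able to resolve
subpixel accuracy while the whole suite stays within minutes. The
inverse and acceptance computations run at full fidelity (25 starts,
100 elements, all four widths).

## Known limitations

- The 1D membrane reduction assumes exact axisymmetry and a flat,
  uniform-thickness disc; iris curvature, regional thickness variation
  and the dilator muscle are not modelled.
- The stroma is elastic and isotropic; viscoelasticity and fibrous
  anisotropy are out of scope, so the identified ratio is an effective,
  rate-free quantity.
- The fitted ratio inherits an `a_s`-dependence (the power law) and a
  residual `nu`-dependence (~10% at the baseline width); neither
  quantity is identifiable from a single pupil-strain scalar.
- Subset DIC on strongly radially-elongated texture underestimates
  radial motion; profiles within half a subset of the pupil margin or
  limbus are unreliable and the virtual tensometer can fail there when
  too few points survive, as on real data.
- The Hausdorff screen's exclusion threshold and the strain-filter
  semantics of commercial DIC software are conventions, not published
  values; both are configurable and documented above.
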