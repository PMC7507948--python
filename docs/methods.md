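# Methods

## The estimation problem

Invasive free portal pressure (FPP) is the reference standard for staging
portal hypertension, but requires catheterising the portal vein.  The
non-invasive alternative modelled here combines three routinely available
inputs — the geometry of the portal venous tree, per-vessel Doppler
ultrasound (inner diameter, maximum velocity), and blood properties — into
a hemodynamic simulation whose output, the virtual free portal pressure
(vFPP), is read at the centre of the portal trunk and compared with the
invasive measurement.

`portoflow` implements this as a one-dimensional resistance-network
reduction of the governing equations rather than a 3-D finite-volume CFD
simulation.  The reduction is deliberate: at canine portal scale
(diameters 2–10 mm, mean velocities 7–25 cm/s, Re ≈ 100–400) flow is
steady and laminar, fully developed profiles are a reasonable closure, and
the network form is analytically verifiable term by term — every solver
answer can be checked against `128 μ L Q/(π d⁴)` and junction continuity.
What the reduction discards is documented under *Limitations*.

## Vessel tree

The tree is a graph of circular segments with linear taper between
proximal and distal diameters.  The canonical canine template has the six
named vessels — splenic, superior and inferior mesenteric veins joining at
a confluence, the portal trunk, and the left/right portal branches leaving
the bifurcation — with control-group diameters (PV 4.5, LPV 3.4, RPV 4.2,
SV 1.8, SMV 3.1, IMV 2.0 mm).  Segment lengths are not published anywhere
we know of; the defaults (trunk 45 mm, branches 30–70 mm) are package
choices at beagle anatomical plausibility and only scale the (sub-mmHg)
viscous drops.

Boundary faces must sit on degree-1 nodes.  Velocity conditions occupy all
five branch faces, which leaves the trunk without a free cross-section for
the pressure reference; the template therefore carries a short (2 mm) stub
segment at the trunk's hepatic end whose face is the gauge-0 pressure
outlet.  Because the velocity set is reconciled to zero net flow, the stub
carries exactly zero flow and does not perturb the solution — it is purely
the gauge anchor.  This is why the canonical template has seven segments:
six named vessels plus the reference stub.

Junctions are shared-pressure nodes with no junction volume or loss model.
The triangulated tube surface (target edge 0.2–1.0 mm, enforced with an
explicit override) exists for export (binary STL, legacy-ASCII VTK) and
area cross-checks; the solver never uses it.

## Boundary conditions

Doppler maxima become means through a fixed factor of 0.7 — the envelope
average of a portal venous waveform is roughly 70% of peak.  The factor is
configuration, not a constant baked into code, because it is an
approximation.  Flow is conserved from measurement site to model face by
`v_b = (d_us²/d_b²) v_us`.

Imposing measured velocities on all five branches over-determines mass
balance, since measurement error guarantees Σ inflow ≠ Σ outflow.  We
reconcile by scaling both hepatic outflows by the single factor
Σ inflow / Σ outflow, keeping the three splanchnic inflows untouched: the
splanchnic supply is the physiological driver, and anchoring inflows makes
the trunk flow equal to the measured supply.  The reconciliation is
idempotent and reported (factor, pre-balance imbalance).  Hepatofugal
(reversed) flow is accepted with a sign flip and a logged warning.

## Network solve and vFPP

Nodal continuity with conductances 1/R yields a symmetric sparse linear
system; the reference node is pinned to the gauge pressure and the system
is solved by a direct sparse factorisation, so identical inputs give
bit-identical outputs.  Post-solve, the junction imbalance is checked
against 1e-10 × max |Q| and per-segment Reynolds numbers against a
laminar threshold of 2000 (warning only — the closure is still applied).

vFPP is the trunk midpoint pressure (mean of its end-node pressures, i.e.
the linear interpolant of the Poiseuille profile), converted at
1 mmHg = 133.322 Pa, plus a configurable absolute reference `p_ref`.

### The absolute-calibration question

With a gauge-0 outlet, pure viscous drops at the published diameters and
velocities are of order 0.1–0.5 mmHg — two orders of magnitude below
invasive FPP values of 6–19 mmHg.  A gauge-referenced viscous network (and
equally a gauge-referenced CFD solution) therefore cannot produce absolute
vFPP values on the invasive scale by itself; some absolute calibration
must bridge the gap, and no published procedure for it is available to
us.  The package makes this explicit instead of guessing: `p_ref` is an
exposed parameter (default 0), `table_emulation` mode shows the raw gap,
and the validation surface uses `forward_consistent` mode (below), which
is independent of how the offset is obtained.

## Synthetic cohorts

The generator emulates the five-group design (control plus 1–4 months of
CCl₄-induced fibrosis, default five animals per group) from the published
group summaries: FPP in mmHg, six vessel diameters in mm, six maximum
velocities in cm/s, each as mean ± SD.  Blood density and viscosity are
not published; defaults are typical mammalian whole blood, 1050 ± 15 kg/m³
and 3.5 ± 0.3 mPa·s.

Draws are independent Normal(mean, SD) truncated below at zero (rejection
sampling), with the bound exposed as `truncate_frac` (fraction of the
mean).  Positivity-only truncation was chosen over a higher floor because
the largest published coefficient of variation (splenic-vein velocity in
the 3-month group, 6.5/18.5 ≈ 35%) puts any floor much above zero close
enough to the mean to bias that cell's moments measurably; at zero the
worst-case mean shift is +0.045 cm/s and the SD shrinkage 0.065 cm/s,
both inside three standard errors at n = 10⁴, which is the generator's
calibration requirement.  No covariances are published, so quantities are
independent within animal and the disease-stage correlation is carried by
group membership alone.

Reproducibility: each animal draws from a child generator keyed by
(seed, group index, animal index), so enlarging a cohort never perturbs
existing animals.

Two truth modes:

- **table_emulation** — invasive FPP is drawn from its own published
  distribution; truth and Doppler measurements are linked only through
  group.  This mirrors the real study design, including the calibration
  gap.
- **forward_consistent** — the animal's FPP draw becomes its `p_ref`, and
  `fpp_true = p_ref +` the forward model's gauge trunk pressure computed
  from the noise-free measurements.  The pipeline applied to noise-free
  data then recovers truth exactly, making parameter-recovery experiments
  well-posed: any recovery error is attributable to the injected
  measurement noise, not to an unknown offset.

Observer noise multiplies each diameter and velocity by independent
Normal(1, cv) factors (truncated positive); reported observer variability
bounds realistic CVs at ≤ 10%.  The bench protocol for blood density —
weighing a 1 mL aliquot at least three times and averaging — is modelled
with additive balance noise, and its output variance follows the standard
error of the mean.

## Statistics

- **Bland–Altman**: bias = mean(vFPP − FPP), LoA = bias ± 1.96 SD.  LoA
  confidence intervals use the variance `s²(1/n + 1.96²/(2(n−1)))` with
  t(n−1) quantiles; from published summary statistics (bias −0.220, LoAs
  2.24/−2.68, n = 25) this arithmetic reproduces all six published CI
  bounds to printed precision, which is the evidence for the variance-form
  choice.  A summary-statistics entry point exists so published numbers
  can be checked without raw data.
- **ICC**: ICC(2,1), two-way random effects, absolute agreement, single
  measures, from the ANOVA mean squares with McGraw–Wong F-based bounds.
  No ICC model is named in the source material; absolute agreement is the
  form that matches a method-comparison question.  Cross-checked in tests
  against a loop-based ANOVA oracle and against `pingouin`.
- **Lin's CCC** with 1/n moments and a Fisher-z interval.
- **AUC** by Mann–Whitney pair counting (ties ½) with a DeLong interval —
  chosen because it reproduces the common commercial-package default; the
  AUC interval is the one choice not verifiable against published bounds
  (the underlying 25 real pairs are unavailable).
- **Threshold diagnostics** at strictly `score > 12 mmHg`:
  Clopper–Pearson exact intervals for sensitivity/specificity (these
  reproduce the published 64.0/99.8 and 61.5/99.8 bounds from 12/13 and
  11/12), Simel log-method intervals for the likelihood ratios (reproduce
  1.7–72.8 and 0.01–0.6).  Degenerate ratios (zero cells) are reported as
  point values with the interval flagged undefined.
- **Group tables** follow the source's test-selection rule: Shapiro–Wilk
  per group, Student's t-test when normal, Mann–Whitney U otherwise, with
  `*` flags at P < 0.05 vs control and `mean ± SD` formatting at one
  decimal.

Report JSON carries full precision; display strings apply the published
rounding (one decimal for percentages and likelihood ratios, two–three for
coefficients).

## Problem sizes used by the shipped experiments

Generator calibration runs at n = 10,000 per group; the noise-response
experiment uses 200 replicates of 25 animals at 5% CV and 60 replicates
per CV level for the monotonicity check; random-network solver checks use
100 trees of up to 50 segments.  These sizes give three-standard-error
resolution on every calibrated quantity while keeping the whole suite in
the tens of seconds on a laptop core.

## Limitations

- Convective momentum, junction losses, vessel compliance, pulsatility and
  non-Newtonian rheology are all outside the Poiseuille network reduction.
  At Re ≈ 300 with steady venous flow these are secondary, but the model
  should not be pushed to stenotic or arterial regimes.
- The absolute-pressure calibration is unresolved (see above); only
  gauge-relative and forward-consistent statements are validated.
- Synthetic cohorts carry no within-animal covariance between vessels, no
  measurement-site geometry mismatch, and group-wise normality by
  construction; passing recovery tests demonstrates correctness of the
  computational chain under the stated noise model, not clinical accuracy
  on real animals.
- The canonical template's lengths and planar layout are package defaults;
  only diameters are data-driven.
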