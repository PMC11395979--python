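# Methods

This note documents the models, the synthetic data they are exercised on,
and the numerical choices, in enough detail to reproduce or audit any
number the package computes. Units are fixed throughout: diameters in mm,
velocities in m/s, pressures in kPa; the only conversion is
1 mmHg = 0.133322 kPa, chosen so the conventional 20 mmHg surgical
threshold prints as 2.67 kPa at two decimals.

## Synthetic cohort generator

The generator is a first-class model, not a test fixture: it defines the
study conditions under which every sampling property in the test suite is
evaluated. It emulates a two-class pediatric cohort of 60 records (30
normal, 30 coarctation) in three coupled layers.

**Morphometry.** Each record draws nine landmark diameters from
class-conditional truncated normals (rejection at zero). The default
parameters are synthetic — *not* patient-derived — and encode the
qualitative class differences of such cohorts: in CoA the minimal
descending diameter D0 is markedly smaller and less spread (2.5 ± 0.5 mm
vs 8.5 ± 1.0 mm; critical infant coarctations narrow the isthmus to a
fraction of the normal caliber, and the wider normal population carries
more anatomical variation), D3 and D1 are somewhat smaller, while DBCA
(with more spread) and D5 are larger. Within every record D0 is
constrained not to exceed D3 or D4 — it is by definition the descending
minimum — by whole-record rejection (at most 100 attempts, then a
generation error naming the class). The within-class separation is chosen
so that the five-diameter classifier can reach a perfect 12-record test
set in the vast majority of cohorts, mirroring a cohort whose D0
distributions separate cleanly.

**Hemodynamics (`balance` mode, default).** An inlet velocity
v(P1) ~ N(0.9, 0.10) m/s is drawn; outlet velocities follow volume-flow
continuity exactly, v(P1)·D1² = Σ_k v(Ω_k)·D_k², with a fixed flow split
(15% BCA, 7% LCCA, 8% LSCA, 70% descending). Interior stations use the
local diameter (D2 for M1, D3 for M2, D4 for M3, the D4–D5 mean for M4).
Pressures decrease downstream from a fixed distal level (10.5 kPa at O5)
with a per-station viscous drop of 0.10 kPa and a stenosis loss

    Δp_sten = 0.03 · ((D3/D0)⁴ − 1)  kPa

placed between the two post-arch stations, so the peak-to-peak gradient
γ = p(M3) − p(M4) picks it up. The fourth power is the leading-order
velocity-head scaling of an orifice-type loss (velocity through the
throat scales as (D3/D0)², the head as its square); the 0.03 kPa scale
puts the median CoA gradient near the 20 mmHg decision threshold, with
zero excess loss when D0 = D3. Independent Gaussian noise is added last.

**Noise calibration.** The per-response noise levels were calibrated
once, before any classifier development, against the determination
coefficients that linear ratio-feature regressions reach on CFD-derived
data of this kind: velocity noise 0.8 m/s for v(OBCA) (the branch
velocity carries rare variations no diameter regression captures),
0.38 m/s for v(M4), 0.5 m/s for the remaining velocities, and 0.35 kPa
for pressures. Under these defaults the refitted forms average
R² ≈ 0.26 / 0.39 / 0.55 for v(OBCA) / v(M4) / v(O5) over 50 cohorts while
remaining statistically significant (model F-test p < 0.05) in well over
80% of cohorts — low-ish R² with clear significance, and v(O5) the
best-predicted, v(OBCA) the worst.

**`equation` mode.** For identifiability and coverage studies the
generator can instead produce the five surrogate-covered responses
*exactly* from the published regression forms (plus noise). Fitting the
same forms on a noise-free equation-mode cohort must — and does — recover
the generating coefficients to 1e-6; with noise, the normal-theory 95%
confidence intervals cover the truth at the nominal rate. For the chained
velocity models the coverage study conditions on the generator's own
pressure chain (the predicted-pressure regressor is computed from the
generating pressure model, not re-estimated), so the model is correctly
specified and nominal coverage is the right benchmark.

**Geometry.** `SyntheticAorta` is a planar "candy-cane": straight
ascending segment (15 mm), half-circle arch (radius 12 mm), straight
descending segment (45 mm), with a linear proximal-to-distal radius taper
(6.0 → 4.5 mm) that completes by mid-vessel, so the descending segment
has uniform caliber unless a Gaussian-shaped narrowing
r(s)·(1 − depth·exp(−(s−s₀)²/2w²)) is present. Meshes are swept tubes:
parallel-transported frames (no ring twist), triangulated side wall,
triangle-fan end caps; watertight by construction. Branches are separate
cylindrical stubs attached at conventional arch positions. Measuring
branches on stub meshes rather than on a merged junction mesh is a
deliberate scope decision: a merged mesh would require vascular-tree
splitting, which none of the downstream models need.

**Spherical sampling.** Field values at a landmark are taken on a regular
grid of spacing 0.084 mm strictly inside a 1 mm-diameter sphere; that
spacing puts the in-sphere count at 850–900 points (895 at the default).
The grid is symmetric about the center, so the sample mean of any affine
field equals the field at the center — the basis of the averaging tests.

### What the generator does *not* emulate

Real aortas are not planar tubes with circular sections; real CFD fields
have pulsatile structure, recirculation and wall effects that no additive
Gaussian noise reproduces; diameter correlations within a patient are
richer than the single D0 ≤ min(D3, D4) constraint. Consequently, passing
tests demonstrate that the *pipeline* — measurement, regression,
classification, comparison protocol — behaves correctly under controlled
conditions with known truth; they do not certify clinical accuracy on
patient data.

## Automatic morphometry

The centerline is traced by marching cross-section centroids: slice the
mesh perpendicular to the current direction, take the centroid of the
connected section polygon containing the current point, advance one step
(default 1 mm), update the direction from the last two centroids. The
initial direction at the inlet is inferred from the mesh itself: among
deduplicated face normals near the inlet hint, candidates whose plane
bounds the local vertex patch (end caps do; wall facets on curved
vessels do not) are trial-marched four steps, and the stable candidate
with the smallest section area wins — this distinguishes the cap from
lengthwise slabs on straight vessels and from convex-rim tangent lenses
on curved ones. Both vessel ends are approached by bisection, so the
recovered arc length matches the true vessel length to a fraction of a
step (0.5% on a quarter-torus benchmark). The per-station centroid fixed
point converges to 1e-6 mm; all operations are purely geometric, hence
rigid-motion equivariant.

A diameter is always the equivalent-circle diameter 2√(area/π) of the
connected plane-section polygon containing the centerline point —
robust to elliptic sections, and exact for them (semi-axes 4 and 9 give
12.0 mm). Section polygons are built by projecting the section curves
onto an orthonormal in-plane basis; open section curves are an error.

D0 and D4 are located by a dense scan (step ≤ 0.5 mm) over the
configured descending range followed by bounded golden-section
refinement (tolerance 1e-3 mm), and the refined minimum is accepted only
if it does not exceed the scanned one — so the search can never do worse
than the scan oracle. Landmark stations are configurable fractional arc
lengths; D1 applies the literal "1 cm above the inlet" anatomical rule.
Branch diameters are measured 2 mm distal to the origin along the stub's
principal axis ("at the origin" is not a point; 2 mm clears the weld
region). On generator fixtures all nine diameters land within 2% of the
analytic truth (typically 0.2–0.6%).

The manual-vs-automatic agreement report computes one Pearson r per
diameter; a constant column yields NaN with a warning rather than a
fabricated value.

## Surrogate regressions

The five regression forms (two pressures, three chained velocities) are
fixed; coefficients come either from the published sets (default) or
from OLS on a cohort. OLS goes through a QR decomposition
(`numpy.linalg.lstsq`) with an explicit intercept; diagnostics are
R² = 1 − SSR/SST, the overall-F p-level, and normal-theory standard
errors — all verified against an independent statistical package in the
tests. Rank-deficient designs are rejected with the collinear term names
(identified by pivoted QR). Chaining is strictly feed-forward: the inlet
pressure model is fitted first and its in-sample predictions enter the
velocity fits; at prediction time the same composition is applied, so a
perturbation of D1 reaches v̂(O5) both directly and through p̂(P1).

In the full pipeline the surrogates are fitted on the training split
only. The alternative (fitting on all records) would leak test
information into the metamodel comparison; nothing in the protocol
requires it, so the conservative choice is the default.

## Logistic classification

Maximum likelihood by explicitly written IRLS: each iteration solves the
weighted normal equations with weights μ(1−μ) on the working response;
convergence when the log-likelihood moves less than 1e-8, cap 100
iterations. Features are z-scored by default (stored in the classifier),
which makes coefficient magnitudes comparable across mm- and kPa-scaled
features; a raw mode exists. Perfect or quasi-perfect separation — the
expected regime when D0 splits the classes cleanly — is detected
(training set classified perfectly with diverging scores) and reported
via a warning and a flag; the fit at the cap is returned because its
decision boundary is exactly what the protocol needs. Classification is
strict: CoA if and only if the probability exceeds the threshold, so a
record sitting exactly at P = 0.5 is called normal. Probabilities are
clamped into the open unit interval at the float boundary.

The published coefficient tables are shipped verbatim with their
caveats exposed as configuration rather than silently patched: the
morphometric table prints no intercept (default 0, settable), and in the
metamodel table the three identical velocity coefficients (−1.05) look
like a typesetting artifact.

**Feature sets.** The literal hemodynamic classifier uses
{v(OBCA), v(M3), v(O5), p(P1), p(M1)}. The surrogate chain, however,
predicts {v(OBCA), v(M4), v(O5), p(P1), p(M2)} — the equations' own
response set. A metamodel classifier can only use predictable features,
and comparing it against a direct classifier with a *different* feature
set would confound the comparison. `run_pipeline` therefore defaults both
the direct and the metamodel classifier to the predictable set; the
literal set remains the default for the standalone published-table
classifier, and both are configurable. Relatedly, the landmark naming
ambiguity (documents of this kind describe "three points Mi" but use
M1–M4 throughout) is resolved by always emitting all four M stations.

**Split.** Stratified: round(0.2·n) per class held out (never emptying a
class's training side), reproducible from a seed; 60 records give exactly
12 test records, so one, two or three errors give 0.92, 0.83, 0.75 at two
decimals.

## Pipeline and provenance

One seed drives everything; per-stage substreams are derived by hashing
the stage name into a seed sequence, so adding or reordering stages never
shifts another stage's stream. The same split serves all three
classifiers (asserted at evaluation, not assumed). Results carry the seed
and a SHA-256 hash of the full configuration; rerunning from the same
seed and configuration reproduces every number bit-identically. The
comparison report recomputes accuracies from the stored confusion
matrices and fails loudly on any inconsistency. An ablation switch
(`all_features_ablation`) trains the direct classifier on all 18
hemodynamic columns instead of the five-feature set — the regime where
extra noisy features tend to *lower* held-out accuracy.

## Problem sizes

Default study scale everywhere: 60-record cohorts; 100-seed sampling
studies for classifier properties; 200 cohorts for interval coverage; 50
for R² calibration checks. Meshes use 48 circumferential × 300 axial
samples (test fixtures) — enough for sub-percent diameter accuracy —
with finer sweeps only where a convergence statement is itself under
test. The complete test suite runs in about a minute on one CPU; the
acceptance script in a few seconds.

## Known limitations

* The generator's hemodynamics are steady-state and noise-driven; no
  pulsatility, no wall shear stress or oscillatory shear index.
* The mesh machinery targets tube-like, capped, single-component vessels;
  heavily trabeculated or branching-junction meshes are out of scope
  (branches are measured as separate stubs).
* Published-coefficient mode evaluates the printed models as given; on
  synthetic cohorts their *absolute* predictions are only as good as the
  printed forms transfer, which is why the pipeline defaults to fitted
  mode.
* The morphometric published table lacks an intercept; any choice is a
  guess, so it is configuration, and the default of 0 makes its raw
  scores comparable only up to a shift.
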