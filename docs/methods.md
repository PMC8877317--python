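# Methods

## Constrained mixture design

A q-component mixture with proportions x₁…x_q summing to a constant total
and per-component bounds Lᵢ ≤ xᵢ ≤ Uᵢ defines a convex polytope inside the
simplex. Candidate design points are built McLean–Anderson style: all
extreme vertices (enumerate bound assignments of q−1 components, solve the
last from the sum constraint, keep the feasible ones), the centroid of every
constraint facet holding at least two vertices (edges, for three
components), the overall centroid, and axial check blends. Axial blends are
taken as midpoints between the overall centroid and *every* vertex and edge
centroid — not vertices only — because lower-bounded three-component
regions published in the formulation literature use centroid–edge blends as
check points as well; for the bundled study region this candidate set
contains all ten distinct compositions of the published 16-run design.

D-optimal selection maximizes det(XᵀX) of the Scheffé model matrix over
n-run subsets drawn **with replacement** from the candidates (replication is
how mixture DoE buys pure-error degrees of freedom). The optimizer is
Fedorov point exchange: from a random initial design, repeatedly replace a
design point with the candidate that increases the determinant, until a full
pass yields no improvement; the determinant is non-decreasing by
construction and passes are capped (default 50). Ten seeded random starts
guard against local optima. The model matrix is built in pseudo coding
purely for conditioning; the arg-max is unaffected because the coding is a
fixed affine reparametrization on the constant-sum slice. With six runs on
the unconstrained simplex the algorithm recovers the known quadratic
D-optimum ({3 vertices, 3 binary midpoints}), verified in the tests against
an exhaustive grid search.

## Scheffé response surfaces

Mixture polynomials carry no intercept — the constant is absorbed by
Σxᵢ = total. The quadratic three-component model is

y = β₁x₁ + β₂x₂ + β₃x₃ + β₁₂x₁x₂ + β₁₃x₁x₃ + β₂₃x₂x₃.

With active lower bounds the fit uses **L-pseudo components**,
x′ᵢ = (xᵢ − Lᵢ)/(1 − ΣL), mapping the bounded region onto the unit simplex.
This coding choice is pinned down by an internal consistency check: the
bundled study's published coefficient vectors, evaluated at its reported
optimum under this coding, reproduce the reported predictions (37.53 nm,
80.55%) to one unit in the last printed digit, whereas raw-fraction coding
does not. The check is a permanent test.

Estimation is ordinary least squares on the six terms. ANOVA follows
mixture convention: total SS corrected for the mean, model df = p − 1 (the
constant-sum constraint absorbs one), residual df = n − p. Diagnostics:

- R² = 1 − SS_res/SS_tot; adjusted R² = 1 − (SS_res/df_res)/(SS_tot/(n−1)).
- PRESS via the hat-matrix shortcut Σ(eᵢ/(1−hᵢᵢ))², equal to the explicit
  n-refit leave-one-out sum (tested to 1e-8 relative); predicted
  R² = 1 − PRESS/SS_tot. A run with leverage 1 (saturated designs) raises a
  leverage error naming the run, since its LOO prediction is undefined.
- Adequate precision, the response-surface signal-to-noise ratio
  (max ŷ − min ŷ)/√(p·MSE/n); values above 4 indicate the model
  discriminates across the design space. Residual sums below 1e-12 of the
  total SS are treated as a perfect fit and reported as +∞ rather than a
  floating-point-noise ratio.

`select_model` fits linear and quadratic, keeps models whose adjusted-minus-
predicted R² gap is below 0.2, picks the lowest PRESS, and prefers the
quadratic on ties. All six quadratic terms are always retained — no
backward elimination — matching the structure of the published equations.

Percent prediction error in verification blocks is
|experimental − predicted|/experimental × 100; this denominator reproduces
both published verification errors (4.38%, 1.94%).

Entrapment bookkeeping: EE% = 100·(drug loaded)/(drug added),
DL% = 100·(drug loaded)/(carrier mass).

## Desirability optimization

Each response prediction maps to d ∈ [0, 1] by a one-sided linear ramp
between limits L < U (direction by goal, weight as exponent); overall
D = (Π dᵢ^{wᵢ})^{1/Σwᵢ}, zero as soon as any d is zero. Ramp limits default
to the observed response range of the design (size 37.5–47.55 nm,
EE 68.22–86.84%); the source study does not state its limits, and this
default reproduces its reported optimum desirability D = 0.812 (computed
0.8123), so it is the package default while remaining configurable.
Weights and importances default to 1.

The search runs Nelder–Mead in the q−1 free pseudo coordinates from every
candidate point plus 16 random feasible starts, with a linear feasibility
penalty dominating any attainable D; the returned D is recomputed at the
returned composition. A 0.001-step grid oracle in the tests confirms no
feasible point beats the optimizer by more than 1e-3 in D. The design-space
map classifies a pseudo-simplex grid (default resolution 60) against hard
thresholds ("≤"/"≥" per response) and is emitted as a plottable table;
tightening a threshold provably never enlarges the accepted set.

## Release kinetics

Cumulative release Q(t) (% of dose) is fitted under three linearized laws:
Q on t (zero order, k in %/h), ln(100 − Q) on t (first order, k in 1/h) and
Q on √t (Higuchi, k in %/√h), each by least squares **with** intercept — a
free intercept quantifies any burst release instead of assuming it away.
Points at Q = 100 are excluded from the log transform only, with a note on
the fit. The best model maximizes R² in its own regression space (adjusted
R² is reported alongside; the models share parameter count, so the ranking
is unchanged). T50 solves the best model for Q = 50 — for Higuchi
T50 = ((50 − b)/k)² — and reports a not-reached marker (None) beyond 10×
the observed horizon. At 2% noise the generating law is re-identified in
≥ 90% of 50 seeded replicates for Higuchi (k = 20 %/√h), zero order
(k = 4 %/h) and first order (k = 0.05 1/h, ≈70% released at 24 h); slower
or faster first-order truths blur into the neighbouring laws because the
log transform amplifies noise as Q → 100.

## CMC breakpoint detection

Absorbance vs log₁₀(concentration) is modelled as two joined line segments
via the continuous hinge basis {1, x, max(0, x − knot)}; the knot minimizing
total SSE over interior candidates is the breakpoint and CMC = 10^knot.
Candidates are the midpoints between consecutive data abscissae (keeping at
least two points strictly on each side), then a 50-point linear refinement
plus a bounded scalar minimization between the neighbours of the best
candidate — noiseless synthetic breakpoints are recovered to machine
precision. The hinge coefficient must be positive (right slope steeper than
left, the micellization signature) by a scale-aware tolerance, and the
two-segment SSE must genuinely improve on the single-line fit; otherwise a
no-breakpoint error is raised. Fits with fewer than three points on either
side are flagged unstable. Log base 10 is a display convention only — the
recovered CMC is base-invariant, and rescaling all concentrations by a
constant shifts the estimate by exactly that constant.

## Non-compartmental pharmacokinetics

Times are minutes internally; AUC is reported in ng·min/mL and, because
published tables in this area conventionally print ng·h/mL even over
minute-denominated windows, also in ng·h/mL (factor 1/60). All targeting
quantities are AUC ratios and therefore unit-invariant.

AUC and AUMC use the linear trapezoid over observed times (the log-linear
rule on declining segments is available behind `auc_method="log-linear"`).
The terminal constant Ke is the negative slope of ln C against t over the
last three samples by default (configurable); non-positive terminal
concentrations or a non-declining tail raise a terminal-phase error.
AUC_∞ = AUC_last + C_last/Ke; AUMC_∞ adds t_last·C_last/Ke + C_last/Ke²;
MRT = AUMC_∞/AUC_∞. `extrapolate=False` returns observed-window quantities
only, for short profiles with no usable elimination phase. Profiles are
treated as one mean curve per group, matching destructive sparse sampling
designs that publish one parameter set per arm.

F% = 100·(AUC_IN/AUC_IV)·(dose ratio); DTE% and DTP% as in the README, with
the algebraic identity DTP% = 100·(1 − 100/DTE%) asserted to 1e-10 in a
property test over random positive AUC quadruples.

## Synthetic-data generators

All generators take a seed and are byte-deterministic; noiseless truths are
exactly recoverable by the downstream estimators (round-trip suite).

- **Mixture responses**: y = Xβ + N(0, σ²) at the design's pseudo-coded
  points; the default β vectors are the published size and EE coefficient
  sets, so the noiseless surface emits ≈47.5 nm at the replicated
  (70, 20, 10)% vertex, next to the observed 47.44/47.55 nm.
- **Release**: the chosen law evaluated on a 0.5–24 h sampling grid,
  additive Gaussian noise in percentage points, clipped to [0, 100] and made
  non-decreasing by a running maximum.
- **Absorbance**: piecewise-linear in log₁₀ concentration over a
  17-point 10⁻⁵–10⁻¹% w/v grid, default breakpoint 0.001326% w/v, slopes
  0.02 → 0.55 absorbance/decade, additive Gaussian noise.
- **PK profiles**: IV plasma C₀e^(−Ke·t) (C₀ = 525.7 ng/mL, Ke = 0.26/h);
  intranasal plasma a Bateman curve (ka = 7.5/h for a ≈30 min Tmax,
  Ke = 0.19/h) whose amplitude is set from the closed-form Bateman integral
  so the analytic AUC(0–480 min) ratio equals the bioavailable fraction
  0.7653 exactly. Brain curves are route-specific scalings of the plasma
  curves (partition 0.284, the IV brain/plasma AUC ratio) — the systemic,
  BBB-crossing contribution — and the intranasal brain curve adds a direct
  olfactory Bateman term calibrated to 1681 ng·h/mL, the published
  brain-IN AUC minus the systemic share. Noise is multiplicative
  log-normal (mean-one) so concentrations stay positive. Sampling follows a
  conventional 5–480 min schedule.

This calibration is inferred: the study published only summary parameters,
not curves, and a one-compartment shape cannot match its Cmax, Tmax and both
AUC windows simultaneously. The generator therefore targets the AUC(0–480)
summaries — which determine every targeting statistic — and accepts
approximate Cmax/MRT/Ke agreement. Because brain curves are plasma
scalings, brain terminal slopes equal plasma ones (0.26/0.19 per h) rather
than the published brain values (0.215/0.168 per h). Consequences for
interpretation: passing tests demonstrate estimator correctness under
first-order absorption/elimination with log-normal assay noise, not under
real-data features such as enterohepatic recirculation, nonlinear efflux,
inter-animal variability or below-quantification censoring, none of which
the generator emulates.

## Problem sizes and numerical choices

Simulation-based tests use 50–500 replicates (50 for model-recovery
confusion rates, 100 for noisy CMC recovery, 500 for coefficient
unbiasedness and the DTP/DTE identity), sizes at which the whole suite runs
in seconds while Monte-Carlo error stays well inside the asserted margins.
Numeric tie-breaks and tolerances: candidate deduplication at 1e-8;
feasibility checks at 1e-8 with boundary clipping; determinant improvements
accepted above 1e-12 in log units; model selection defaults to the
quadratic on PRESS ties; desirability at exactly L or U evaluates to the
ramp's closed endpoint (1 or 0). Degenerate inputs fail fast with typed
errors: infeasible mixture regions, rank-deficient model matrices, leverage-1
runs, non-monotone release profiles, all-zero concentration profiles,
breakpoint-free absorbance curves.

## Known limitations

- Design-space mapping is implemented for three-component mixtures (the
  grid is a 2-simplex); the algebraic machinery above it is q-general.
- Release-model discrimination by R² inherits the usual caveat that the
  three laws are nearly collinear over short horizons; profiles should span
  a substantial release fraction before the winner is trusted.
- NCA assumes the profile's last samples lie on a log-linear decline;
  flip-flop kinetics (absorption slower than elimination) will report the
  absorption constant as the terminal slope, as any NCA does.
- The desirability optimum is a point estimate; no uncertainty is
  propagated from the Scheffé fits into D.
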