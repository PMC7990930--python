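# Methods

This note documents the statistical model behind `dropsig`, the
numerical choices in its solvers, what the synthetic-data generator
does and does not emulate, and the known limitations.

## Signature encoding

A gene signature over M markers is a presence/absence bit pattern.
Marker 1 is the least-significant bit and signatures are indexed
1..2^M, so index 1 is all-negative and index 2^M all-positive.  This
convention is load-bearing: it makes signature combination equal to
bitwise OR on (index − 1), which is what gives the forward model its
pair structure (signatures 2 and 3 combine to 4; 2 and 7, 3 and 6, or
4 and 5 combine to 8).  Profiles are stored dense (length 2^M), which
caps M at 16; the assay itself is a 3–4 plex, so this is not a
practical limit.

## Occupancy model

Cell encapsulation is Poisson.  λ (mean cells per droplet,
dimensionless; typical operating range 0.1–1) is estimated as
−ln(empty fraction).  The deconvolution conditions on a droplet
holding exactly one or two cells: p1 = 2/(2+λ), p2 = λ/(2+λ).
Droplets with more than two cells are deliberately unmodeled in the
inversion; their analytic frequency (0.11% at λ = 0.2, 1.44% at
λ = 0.5, ≈8.03% at λ = 1) is exposed as `multiplet_fraction`, and the
simulator quantifies the resulting bias (below).  The same Poisson
inversion applied per target gene gives limiting-dilution
quantification of transcript concentrations: copies/nL =
−ln(fraction negative)/droplet volume.  A zero negative fraction is
reported as "above quantifiable range" rather than a number.

## Forward model and its two variants

With ambient profile n, single-cell profile s, and signature
combination = OR, the probability of observing signature g in a
cell-containing droplet is

    d_g = p1 Σ_{a∨c=g} n_a s_c + p2 Σ_{a, c1≤c2 : a∨c1∨c2=g} coeff · n_a s_{c1} s_{c2}

built generically for any M by enumeration.  The implementation
factors this as d = p1·L·s + p2·L·q(s), where L[g,u] = Σ_{a∨u=g} n_a
is the ambient-combination matrix and q(s) accumulates unordered cell
pair products by their combined mask — O(G²) per evaluation.

The `coeff` of heterotypic pairs (c1 ≠ c2) is where the two shipped
variants differ.  Under `verbatim` (default) every unordered pair
carries coefficient 1.  This exactly reproduces the 3-marker equation
system the pipeline is specified by (an independent hard-coded
transcription of those eight equations is the anti-regression oracle
in the test suite), but it does not conserve probability: summing over
g gives Σd = p1 + p2(1 + Σs²)/2 < 1 whenever p2 > 0.  Under
`multinomial`, heterotypic pairs carry coefficient 2 — the probability
of drawing an unordered pair of i.i.d. cells — and Σd = 1 exactly.
Both are available because the choice is a genuine modeling fork; the
default favors fidelity to the published system, and no silent
"correction" is applied.  An observed d (which always sums to one) is
therefore fit in a least-squares sense under `verbatim`, never
rescaled.

## Step-2 inversion

The polynomial system d = F(s) is solved on the probability simplex by
damped fixed-point iteration: the coefficient of s_g's own linear term
in equation g is p1·Σ_{a⊆g} n_a (the diagonal of L), and each sweep
updates s ← Π(s + η·(d − F(s))/(p1·diag L)) with damping η = 0.5,
where Π clamps at zero and renormalizes.  Stopping: L∞ step < 1e-10 or
10,000 sweeps.

Two failure modes are handled explicitly.  First, the projection can
create spurious fixed points: the step converges while the equation
residual stays large.  A residual is accepted only if it is explained
by the verbatim model's mass deficit (L∞ residual ≤ 1.5 × |Σd −
ΣF(s)|); otherwise the iterate is treated as a stall.  Second, on a
stall or iteration exhaustion, the solver falls back to bounded least
squares (`scipy.optimize.least_squares`, bounds [0,1], the sum-to-one
constraint folded in as a penalty residual) from multiple starts (best
iterate, projected d, uniform).  Plain least squares is *not* used
unconditionally: on an empirical d the mass deficit acts as a
systematic residual that least squares redistributes across
components, which wipes out per-mill-level populations, whereas the
renormalizing fixed point absorbs the deficit in the overall scale.
The returned s always satisfies s ≥ 0, Σs = 1, with convergence
status, iterations and residual reported.

## Step-3 composition

s is modeled as a non-negative combination of reference profiles
(s = Σ w_k r_k) and solved by Lawson–Hanson NNLS
(`scipy.optimize.nnls`), so the KKT conditions hold at the solution:
zero weights have non-negative gradient components, positive weights
near-zero ones.  Weights are normalized to proportions by default
(raw weights retained).  Nearly collinear references trigger a
conditioning warning but still return the NNLS solution.  A reference
set missing a true constituent shows up as a markedly larger fit
residual, which is surfaced in the diagnostics.

## Step-1 classification

Droplets are first gated by area to discard broken-up or coalesced
droplets; the gate bounds are user-set (upstream image analysis
determines the units).  Each channel — the cell-tracking dye and one
probe channel per marker — is clustered independently on
log10(intensity + 1) (fluorescence spans decades; the transform is
configurable off).  The default clusterer is a variational Bayesian
Gaussian mixture with a Dirichlet-process prior (≤10 components, so
the effective cluster count is inferred); DBSCAN (for
arbitrary-shaped clusters; droplets labeled noise are excluded from
d/n with a logged count) and a fixed threshold are alternatives.
Joint multi-channel clustering is supported by passing a 2-D array.

Cluster polarity is automatic by default: the lowest-center cluster
anchors the negative population, and clusters exceeding the anchor by
a 3× fold-change are positive.  Two refinements make this robust in
practice: centers are geometric means (a log-normal mode split into
sub-clusters by the mixture differs in arithmetic mean through tail
weight alone), and clusters holding < 1% of droplets cannot anchor (a
handful of low outliers must not drag the reference down).  An
explicit cluster→polarity map always overrides, mirroring manual
labeling.  d is then the signature distribution over cell-positive
droplets, n over empty ones, λ = −ln(empty fraction), all by direct
counting.  A per-channel silhouette-style separation score is reported
as a diagnostic — e.g. elevated dye background degrades it — rather
than any attempt at background correction.

## Simulator

Each trial draws, per droplet: a Poisson(λ) cell count (uncapped),
i.i.d. cell types from the composition c, each cell's signature from
its type's reference profile r_k, and exactly one ambient signature
from the mixture ambient profile m = Σ c_k n_k (the all-negative
signature represents "no ambient RNA"); the droplet displays the OR of
all draws.  Trials use independent counter-derived streams
(`SeedSequence(base_seed, trial_index)`), so runs are bit-reproducible
and order-insensitive.  Classification on simulated signature tables
reduces to counting, because the signatures are already discrete; the
fluorescence-level generator exists to exercise the Step-1 clustering
path separately.

Default scenario parameters are the study conditions of interest:
200,000 droplets per trial, λ = 0.2, composition (90%, 9.9%, 0.1%),
100 trials.  The default reference profiles are synthetic stand-ins
(no tabulated empirical profiles exist to import): each of three types
puts 0.85 on its own single-marker signature, 0.09 on all-negative
dropout, 0.02 on each other single-marker signature, and 0.01 on each
double involving its own marker; ambient profiles put 0.85 on
all-negative, 0.12 on the type's own marker, 0.015 on each other.
These numbers were chosen once to give well-separated but
realistically imperfect populations — marker dropout and a little
cross-signature mass are what real endpoint RT-PCR profiles show, and
the cross mass is also what makes the uncorrected analysis lose rare
populations (the majority reference over-explains the rare signature
once ambient/doublet smearing shrinks it, so NNLS clamps the rare
weight at zero).  All profiles are fully overridable.

The fluorescence generator draws per-channel log-normal intensities
with ~2 decades (≈13σ in log10) between the negative and positive
modes by default, a dye signal scaling with cell count plus a
configurable background, and Gaussian droplet areas inflated
multiplicatively per extra cell.  It emulates separation quality and
dye background, not PCR kinetics, droplet coalescence dynamics, or
imaging optics — so passing end-to-end tests demonstrate the analysis
logic under clean-to-moderate separation, not robustness to every
instrument artifact.

## What the simulations show

With the default scenario the corrected pipeline recovers the 0.1%
population with mean ≈0.09–0.10% and a 95% CI (of the mean over 100
trials) covering the truth, while the uncorrected analysis estimates
it at zero in essentially every trial.  Raising λ to 0.5 and 1.0 at
fixed droplet count shrinks the confidence intervals (more cells
sampled) but degrades rare-population accuracy — at λ = 1 about 8% of
droplets hold >2 cells, violating the inversion's doublet truncation —
so accuracy is best at λ ≤ 0.2.  The residual bias of the corrected
estimates at λ = 0.2 is at the few-×10⁻⁴ level, visible only because
the trial CIs are tight; it stems from the ≤2-cell truncation and the
nonlinearity of the inversion under multinomial sampling noise, and it
is why distribution-level bands, not CIs of the mean, are the stable
accuracy statement at small population frequencies.

## Numerical and interface choices

- Profile validation: entries ≥ 0, Σ = 1 within 1e-9; empirical
  estimates use an explicit renormalize option.
- The verbatim/multinomial fork, the fixed-point damping (0.5),
  tolerance (1e-10 L∞), iteration cap (10,000) and the stall test are
  all exposed as parameters.
- The solver is deterministic; no randomness anywhere in Steps 1–3.
- CSV formats: comma-separated with header, UTF-8; profile CSVs are
  `signature,probability` with signatures in "+-+" string form;
  droplet CSVs follow the CellProfiler column convention, rebindable.
- Machine outputs (JSON) carry full precision; rounding happens only
  in human-facing summaries.

## Limitations

- The inversion stops at doublets; above λ ≈ 0.5 multiplet bias
  dominates and the tool should be used for design-time warnings, not
  correction.
- Composition estimation assumes every constituent population appears
  in the references (violations are flagged via residual, not fixed).
- One ambient draw per droplet; per-gene independent ambient sampling
  is a plausible alternative reading that is not implemented.
- Marker calls are binary; no transcript-count quantification per
  cell beyond the limiting-dilution utilities.
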