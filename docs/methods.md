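# Methods

## Model

Misfolded, hyperphosphorylated tau is assumed to propagate through the
brain's axonal wiring in a prion-like fashion: proteopathic seeds travel
along white-matter tracts and replicate locally. On a weighted, undirected
connectome graph with `N` regions this is the graph-discretized
Fisher–Kolmogorov (FKPP) equation for nodal concentrations `c_i ∈ [0, 1]`:

    dc_i/dt = −κ Σ_j L_ij c_j + α c_i (1 − c_i)

* `A_ij = n_ij / l_ij` — adjacency from tractography fiber count `n_ij`
  divided by mean fiber length `l_ij` (fibers per unit length);
* `D_ii = Σ_{j≠i} A_ij`, `L = D − A` — weighted graph Laplacian;
* `κ` (nominally μm/yr) — per-subject transport rate along edges. The
  Laplacian carries its own connectivity units, so `κ` acts operationally
  as a scale factor on the given `L`; we report it in its nominal units
  without attempting a unit conversion, and the same convention must be
  used when comparing values across connectomes;
* `α` (1/yr) — per-subject net production rate (production + conversion −
  clearance); negative values mean clearance dominates.

`c ≡ 0` and `c ≡ 1` are fixed points; for `α ≥ 0` the unit hypercube is
invariant; for `α = 0` total concentration is conserved and diffusion
relaxes each connected component to its mean.

## Data scale

Regional tau-PET SUVR values (uptake normalized to inferior cerebellar
gray) are mapped to the model's [0, 1] scale: a two-component Gaussian
mixture fitted to the pooled values across subjects, time points and
regions separates the tau-negative bulk from the tau-positive tail. The
positivity threshold is the point between the component means where
posterior membership in the upper component reaches 0.5 (root-found with
Brent's method; a grid-searched crossing agrees to <1e−3). Values at or
below the threshold become 0; values above are rescaled affinely against a
ceiling and capped at 1.

Choices the upstream description leaves open, fixed here:

* **Ceiling** — the cohort-wide maximum raw value, applied globally (not
  per subject), so normalized concentrations are comparable across
  subjects. Configurable.
* **Degenerate mixtures** — the fit errors out (rather than returning an
  arbitrary number) when a component collapses (< 1% weight) or the mean
  gap is smaller than the summed component SDs; a fixed threshold override
  (e.g. 1.1 SUVR) is then accepted.
* **Observed regions** — only cortical regions enter the likelihood;
  subcortical regions and the hippocampus are excluded because of known
  off-target binding, but the dynamics always run on the full graph.

## Hierarchical Bayesian calibration

Per subject `s`, the baseline scan is the initial condition (not data);
follow-up scans at the exact acquisition offsets enter a Gaussian
likelihood around the simulated values with width `σ_err`. Priors:

| parameter | prior |
|---|---|
| μ^κ | Normal(1, 20) bounded > 0 |
| σ^κ, σ^α±, σ_err | Half-Cauchy(β = 1) |
| κ_s | Normal(μ^κ, σ^κ) bounded > 0 |
| μ^α± | Normal(0, 2) |
| α_s | Normal(μ^α_g, σ^α_g), g = amyloid status |

Production-rate hyperdistributions are separate for amyloid-positive and
amyloid-negative subjects; the structure does not force a group difference,
so a detected gap is data-driven.

### Sampling

The posterior is explored with an affine-invariant ensemble MCMC (emcee),
using a mixture of differential-evolution and snooker moves. Gradient-based
samplers need derivatives through the ODE solver; the ensemble sampler
needs none, at the cost of being more sensitive to posterior geometry. Three
choices matter:

* **Unconstrained parameterization.** All positive parameters are sampled
  on the log scale with Jacobian corrections. Subject parameters are
  non-centered (`κ_s = μ^κ + σ^κ z_s`, `z_s` standard normal truncated
  below so `κ_s > 0`): in centered form, weakly identified subjects drag
  the ensemble into the small-σ funnel neck, which affine moves cannot
  escape (observed as collapsed per-subject posteriors); non-centering
  removes the funnel.
* **Initialization.** The joint mode of a hierarchical posterior is
  degenerate (density unbounded as a group scale → 0), so MAP-centered
  starts fail. Walkers instead start from independent ridge-penalized
  least-squares fits of each subject's (κ, α), with group-level
  coordinates at the empirical moments of those fits and deliberately
  overdispersed scale coordinates.
* **Likelihood determinism.** Inside the likelihood all subjects are
  integrated jointly with a fixed-step RK4 scheme (step 0.1 yr), vectorized
  over walkers and subjects, so the likelihood is a smooth deterministic
  function of the parameters. Against the adaptive reference solver the
  fixed-step error is ~1e−6, orders of magnitude below `σ_err`.

`chains` independent ensembles are run (default 2), each with
max(2·ndim + 2, 48) walkers, 1,600 discarded adaptation steps and 2,000
kept steps by default. Every walker is one chain for split-R̂/ESS purposes;
R̂ > 1.1 raises a prominent warning and a machine-readable flag, never an
exception. Divergences do not exist for this sampler and are reported
as 0. `target_accept` is accepted for config compatibility but inert.
Identical seeds reproduce runs bit-exactly.

Elsewhere (public `integrate`, forecasts) the ODE is solved with adaptive
LSODA at rtol 1e−9 / atol 1e−12 — tolerances tightened well beyond the
usual 1e−6 defaults so that the κ = 0 analytic-logistic contract (≤ 1e−6
absolute error) and the fixed-point contract (≤ 1e−9 drift over 50 years)
hold with margin at negligible cost for N ≤ 83.

### Summaries and group comparison

Per-subject posterior means (medians also emitted) are summarized as
mean/SD/min/max across subjects — diffusion over all subjects, production
rates split by amyloid group. The group contrast is an independent
two-sample t-test on per-subject posterior-mean production rates
(pooled-variance by default, Welch optional). Using posterior means as the
per-subject point estimates is an assumption; the upstream analysis does
not state its choice.

## Forecasting

For each posterior draw of (κ_s, α_s) the dynamics are integrated from the
subject's baseline scan over a 30-year horizon (0.25-yr grid); pointwise
medians and equal-tailed 95% bands summarize 4,000 draws. Equal-tailed
percentile bands were chosen over HPD intervals for stability under
monotone transforms. Observation noise is *not* added by default — bands
quantify parameter uncertainty propagated through the dynamics — and can
be enabled by flag. Default monitored regions: entorhinal cortex, middle
temporal gyrus, superior temporal gyrus, both hemispheres (Braak stages
II/IV/V).

The scan-scheduling rule reports the earliest grid time at which the band
width exceeds a threshold (default 0.2), aggregated as the maximum over
monitored regions; per-region first crossings are reported alongside. A
band that never crosses is flagged "beyond horizon".

## Synthetic cohorts

The generator emulates the structure of a longitudinal tau-PET cohort:
76 subjects (46 amyloid-positive / 30 negative) by default; baseline plus
2–4 follow-ups spaced Normal(1.07, 0.31) years (truncated at 0.1 yr);
baseline tau seeded in entorhinal and neighboring temporal regions at
0.1–0.5 with near-zero background (Braak-early topography); per-subject
(κ_s, α_s) drawn from the hierarchical law; Gaussian observation noise
(σ = 0.05) on the normalized scale, clipped to [0, 1]. Default group-level
parameters follow the reference posterior summary (κ: 1.304 ± 0.69;
α: 0.019 ± 0.27 positive, −0.143 ± 0.21 negative).

Two generator decisions deserve emphasis:

* **Baseline noise** (`noise_on_baseline`, default False). The calibration
  model conditions on the baseline scan as an *exact* initial condition.
  If the generator also adds noise to the baseline observation, that IC
  error biases the fitted parameters beyond what the posterior width can
  express, and interval coverage degrades by construction (measured:
  ~70–90% instead of ~95%). The default therefore generates from the model
  actually being fitted — baseline exact, follow-ups noisy — which is the
  correct setup for calibration experiments; setting the flag True
  emulates the additional unmodeled acquisition error of real data.
* **Designed contrasts** (`exact_group_moments`, default False). For
  recovery experiments that test whether a known group gap is detected,
  drawn production rates can be standardized within group so the realized
  means/SDs equal the configured ones exactly, removing finite-sample draw
  luck from the designed contrast.

What the generator does **not** emulate: PET image formation, off-target
binding, scanner/session effects, spatially correlated noise, and
censoring-aware observation models (values are clipped at the scale
boundaries but the likelihood treats them as Gaussian). Passing recovery
tests therefore demonstrate correctness of the estimation machinery under
the model's own assumptions, not robustness to these real-data effects.

## Reduced-scale verification

The reference cohort is access-controlled, so the quantitative checks run
on synthetic data at desk scale (the package's own choice of problem
sizes): a 10-node random graph (edge probability 0.5, weights 0.05–0.5 so
the diffusion time scale matches the ~3-year observation window), 12
subjects (6 per amyloid group), 3 follow-ups, σ_err = 0.05, and a designed
group gap of 0.16/yr — the reported contrast (0.019 − (−0.143)) — with
within-group SD 0.08/yr, small enough that the contrast is identifiable
with six subjects per group. Baselines seed all regions at 0.2–0.6, away
from the [0, 1] censoring boundaries the Gaussian likelihood ignores.
Recovery fits use 2 ensembles × 80 walkers × (3,500 + 3,500) steps.

## Known limitations

* κ is only weakly identified when diffusion saturates within the
  observation window (strongly coupled graphs or large κ); its posterior
  then has a long flat upper tail and the hierarchy shrinks it toward the
  group mean. This mirrors the weak identifiability expected at short
  follow-up horizons.
* The ensemble sampler's R̂ on hierarchical scale parameters converges
  slowly; runs report convergence flags and should be lengthened when
  R̂ > 1.1 matters for the question at hand.
* One shared connectome for all subjects; per-subject κ partially absorbs
  individual connectivity differences.
* Regionally constant κ and α; no atrophy coupling; no censoring-aware
  likelihood at the scale boundaries.
* The packaged 83-region connectome is synthetic (lobe-block structure,
  sparse interhemispheric edges) — a stand-in that lets the pipeline run
  end-to-end without restricted downloads, not real tractography.
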