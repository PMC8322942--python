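# tauspread

Physics-based modeling of misfolded-tau propagation on the brain
connectome, with hierarchical Bayesian calibration to longitudinal tau-PET
data and posterior-predictive forecasting.

Tau pathology in Alzheimer's disease spreads along axonal connections in a
stereotyped spatiotemporal pattern. `tauspread` models this as a
reaction–diffusion process on a weighted brain graph — the graph-discretized
Fisher–Kolmogorov equation

    dc_i/dt = −κ Σ_j L_ij c_j + α c_i (1 − c_i),

where `c_i ∈ [0, 1]` is the normalized tau burden of region `i`,
`L = D − A` the weighted graph Laplacian of the connectome
(`A_ij = n_ij / l_ij`: fiber count over mean fiber length), `κ` a
per-subject diffusion coefficient and `α` a per-subject net production
rate (negative when clearance dominates). Per-subject parameters are
calibrated to longitudinal regional SUVR tables with a hierarchical
Bayesian model whose production-rate hyperdistributions are stratified by
amyloid-β status, so the package can ask: *do amyloid-positive subjects
produce misfolded tau faster?* — and answer with posterior distributions,
credible intervals and a group-level test. Posterior-predictive forecasts
with 95% credible bands turn the calibrated model into a scan-scheduling
tool: the time at which a subject's band becomes wider than a chosen
threshold is a sensible moment for the next confirmatory scan.

The package is for computational neuroscientists and imaging statisticians
working with regional tau-PET SUVR tables (image registration and
segmentation are upstream; amyloid status is an input label). Because real
longitudinal tau-PET cohorts are access-controlled, a first-class
synthetic-cohort generator reproduces the statistical structure of such
data, and a packaged **synthetic** 83-region connectome (Desikan–Killiany
style labels, lobe-block connectivity, sparse interhemispheric edges) lets
the whole pipeline run with no external downloads.

## Worked example

Simulate a small cohort on a toy graph, calibrate it, and forecast:

```python
import numpy as np
from tauspread import (
    BrainNetwork, RegionTable, CohortConfig, HyperParams, ModelSpec,
    SamplerConfig, build_model, sample_posterior, summarize_posterior,
    compare_groups, simulate_cohort, posterior_predict, recommend_scan_time,
)

rng = np.random.default_rng(5)
n = 10
regions = RegionTable(
    tuple(f"lh-r{i}" if i < 5 else f"rh-r{i}" for i in range(n)),
    tuple("left" if i < 5 else "right" for i in range(n)),
    np.ones(n, bool),
)
A = np.zeros((n, n))
for i in range(n):
    for j in range(i + 1, n):
        if rng.random() < 0.5:
            A[i, j] = A[j, i] = rng.uniform(0.05, 0.5)
net = BrainNetwork.from_adjacency(regions, A)

truth = HyperParams(mu_kappa=1.0, sigma_kappa=0.3,
                    mu_alpha_pos=0.08, sigma_alpha_pos=0.08,
                    mu_alpha_neg=-0.08, sigma_alpha_neg=0.08, sigma_err=0.05)
cfg = CohortConfig(n_positive=6, n_negative=6, true_hyperparams=truth,
                   followup_range=(3, 3), seed_regions=tuple(range(n)),
                   seed_level=(0.2, 0.6), exact_group_moments=True, rng_seed=0)
cohort = simulate_cohort(cfg, net)

spec = ModelSpec(network=net, cohort=cohort.scan_series,
                 sampler_config=SamplerConfig(chains=2, tune=1000, draws=1000,
                                              walkers=80, seed=0))
samples = sample_posterior(build_model(spec), spec.sampler_config)
summary = summarize_posterior(samples)
print(summary.table.round(3))
res = compare_groups(summary.subjects)
print(f"amyloid+ vs amyloid-: t = {res.t_statistic:.2f}, p = {res.p_value:.4f}")

fc = posterior_predict(samples, cohort.scan_series[0], net,
                       horizon=15, n_draws=2000, regions=("lh-r0",), seed=0)
rec = recommend_scan_time(fc, width_threshold=0.1)
print("next scan recommended at", rec.recommended_time, "years")
```

Output (exact numbers depend on seeds):

```
      kappa  alpha_neg  alpha_pos
Mean  1.084     -0.077      0.077
Std   0.531      0.084      0.082
Min   0.225     -0.203     -0.070
Max   2.024      0.022      0.153
amyloid+ vs amyloid-: t = 3.24, p = 0.0089
next scan recommended at 10.5 years
```

The group table mirrors the standard posterior-summary layout: per-subject
posterior means summarized across subjects — diffusion coefficients pooled,
production rates split by amyloid status. Here the fitted group means
(+0.077 vs −0.077 per year) recover the generating gap of 0.16/yr, and the
t-test on per-subject posterior means flags the group difference. The scan
recommendation is the first time the subject's 95% credible band grows
wider than the chosen 0.1 threshold.

The same workflow is available from the shell:

```bash
tauspread simulate --n-positive 6 --n-negative 6 --seed 0 --out runs/sim
tauspread fit --cohort runs/sim/cohort.csv --threshold 0 --ceiling 1 \
              --out runs/fit
tauspread forecast --posterior runs/fit --subject sub-000 --out runs/fc
```

(omitting `--network` uses the packaged synthetic 83-region connectome).

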