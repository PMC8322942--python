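"""Hierarchical Bayesian calibration of per-subject FKPP parameters.

Each subject s contributes a diffusion coefficient ``kappa_s`` (positive)
and a production rate ``alpha_s`` (signed). Partial pooling ties subjects
together: ``kappa_s ~ BoundNormal(>0, mu_k, sigma_k)`` with common
hyperpriors for all subjects, and ``alpha_s ~ Normal(mu_a[g], sigma_a[g])``
where the group g is the subject's amyloid status, so amyloid-positive and
amyloid-negative subjects share separate production-rate hyperdistributions.
Weakly informative priors: ``mu_k ~ BoundNormal(>0, 1, 20)``,
``mu_a ~ Normal(0, 2)``, all scale parameters ``~ HalfCauchy(beta=1)``.

The likelihood compares model trajectories, started from each subject's
baseline scan, to the follow-up scans on the observed (cortical) regions:
observations are Normal around the simulated values with width
``sigma_err``. The dynamics run on the full graph; only cortical regions
enter the likelihood.

Sampling uses an affine-invariant ensemble MCMC (emcee) on an unconstrained
parameterization: positive parameters are sampled on the log scale with the
Jacobian correction, and subject-level parameters are non-centered
(``kappa_s = mu_k + sigma_k z_s`` with truncated standard-normal ``z_s``),
which avoids the funnel geometry typical of hierarchical posteriors. The
"chains" setting maps to independent ensembles; within an ensemble each
walker is reported as one chain for split-R-hat / ESS diagnostics.
"""

from __future__ import annotations

import logging
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import arviz as az
import emcee
import numpy as np
import pandas as pd
from scipy.special import log_ndtr
from scipy.stats import truncnorm, halfcauchy, ttest_ind  # truncnorm: prior sampling

from .connectome import BrainNetwork
from .dynamics import integrate_batch
from .errors import DataError
from .preprocess import ScanSeries, select_observed_regions

__all__ = [
    "HyperParams",
    "PriorConfig",
    "SamplerConfig",
    "ModelSpec",
    "HierarchicalModel",
    "PosteriorSamples",
    "PosteriorSummary",
    "GroupComparison",
    "build_model",
    "sample_posterior",
    "summarize_posterior",
    "compare_groups",
    "sample_prior",
]

log = logging.getLogger(__name__)

_LOG_2PI = float(np.log(2.0 * np.pi))
RHAT_WARN = 1.1


@dataclass(frozen=True)
class HyperParams:
    """Group-level parameters of the hierarchical model."""

    mu_kappa: float
    sigma_kappa: float
    mu_alpha_pos: float
    sigma_alpha_pos: float
    mu_alpha_neg: float
    sigma_alpha_neg: float
    sigma_err: float

    def __post_init__(self) -> None:
        for name in ("sigma_kappa", "sigma_alpha_pos", "sigma_alpha_neg", "sigma_err"):
            if not getattr(self, name) >= 0:
                raise DataError(f"{name} must be nonnegative")


@dataclass(frozen=True)
class PriorConfig:
    """Constants of the weakly informative priors.

    ``mu_kappa ~ BoundNormal(>0, loc, scale)``; ``mu_alpha ~ Normal(loc,
    scale)``; every scale parameter has a HalfCauchy(beta) prior.
    """

    mu_kappa_loc: float = 1.0
    mu_kappa_scale: float = 20.0
    mu_alpha_loc: float = 0.0
    mu_alpha_scale: float = 2.0
    halfcauchy_beta: float = 1.0

    def __post_init__(self) -> None:
        if self.mu_kappa_scale <= 0 or self.mu_alpha_scale <= 0 or self.halfcauchy_beta <= 0:
            raise DataError("prior scale constants must be positive")


@dataclass(frozen=True)
class SamplerConfig:
    """Ensemble-sampler settings.

    ``chains`` independent ensembles are run, each with ``walkers`` walkers
    (default: max(2*ndim + 2, 48)), for ``tune`` discarded adaptation steps
    followed by ``draws`` kept steps. ``target_accept`` is recorded for
    interface compatibility with step-size-adapting samplers but has no
    effect on the ensemble moves. ``ode_dt`` is the fixed RK4 step used
    inside the likelihood so that it is a deterministic function of the
    parameters.
    """

    chains: int = 2
    tune: int = 1600
    draws: int = 2000
    walkers: int | None = None
    target_accept: float = 0.9
    seed: int = 0
    ode_dt: float = 0.1


@dataclass
class ModelSpec:
    """Everything needed to build the hierarchical model."""

    network: BrainNetwork
    cohort: list[ScanSeries]
    observed_region_indices: np.ndarray | None = None
    prior_config: PriorConfig = field(default_factory=PriorConfig)
    sampler_config: SamplerConfig = field(default_factory=SamplerConfig)


class HierarchicalModel:
    """Explicit log-posterior of the hierarchical FKPP model.

    Unconstrained sampling vector (dimension ``7 + 2 S``)::

        [log mu_k, log sigma_k, mu_a+, log sigma_a+, mu_a-, log sigma_a-,
         log sigma_err, z_kappa (S), z_alpha (S)]

    Hyper-scales are sampled on the log scale with the Jacobian correction.
    Subject-level parameters are non-centered, ``kappa_s = mu_k + sigma_k *
    z_s`` and ``alpha_s = mu_a[g] + sigma_a[g] * z_s`` with standard-normal
    ``z`` (truncated below for kappa so that ``kappa_s > 0``): when the data
    constrain a subject weakly, its ``z`` reverts to an isotropic normal
    instead of coupling to the group scale, which removes the funnel
    geometry that otherwise traps the ensemble in the small-sigma neck.
    All log-density evaluations are vectorized over a batch of parameter
    vectors.
    """

    def __init__(self, spec: ModelSpec) -> None:
        if not spec.cohort:
            raise DataError("empty cohort")
        cohort = []
        for s in spec.cohort:
            if s.normalized is None:
                raise DataError(
                    f"subject {s.subject_id}: cohort must be normalized before fitting"
                )
            if s.n_followups < 1:
                log.warning(
                    "subject %s has no follow-up scans; excluded from fit", s.subject_id
                )
                continue
            cohort.append(s)
        if not cohort:
            raise DataError("no subject has follow-up scans")
        self.spec = spec
        self.cohort = cohort
        self.network = spec.network
        self.prior = spec.prior_config
        self.subject_ids = tuple(s.subject_id for s in cohort)
        self.amyloid = np.array([s.amyloid_positive for s in cohort], dtype=bool)
        self.n_subjects = len(cohort)
        if spec.observed_region_indices is None:
            self.obs_regions = select_observed_regions(spec.network.regions)
        else:
            self.obs_regions = np.asarray(spec.observed_region_indices, dtype=int)
        self.ode_dt = spec.sampler_config.ode_dt

        # Baseline scans are initial conditions (full graph); follow-ups are
        # data (observed regions only). All subjects are integrated jointly
        # on the union grid of follow-up times.
        self.baselines = np.stack([s.normalized[0] for s in cohort])  # (S, N)
        all_times = np.unique(np.concatenate([s.scan_times[1:] for s in cohort]))
        self.eval_times = all_times
        self._time_index = {t: m for m, t in enumerate(all_times)}
        self._sub_time_idx = [
            np.array([self._time_index[t] for t in s.scan_times[1:]], dtype=int)
            for s in cohort
        ]
        self._sub_obs = [s.normalized[1:][:, self.obs_regions] for s in cohort]
        self.n_obs = int(sum(o.size for o in self._sub_obs))
        # flat (scan, subject) index pairs for a single vectorized gather
        self._flat_t = np.concatenate(self._sub_time_idx) if self._sub_time_idx else np.empty(0, int)
        self._flat_s = np.concatenate(
            [np.full(len(idx), s, dtype=int) for s, idx in enumerate(self._sub_time_idx)]
        ) if self._sub_time_idx else np.empty(0, int)
        self._flat_obs = (
            np.concatenate(self._sub_obs, axis=0) if self._sub_obs
            else np.empty((0, self.obs_regions.size))
        )

        self.param_names = (
            ["mu_kappa", "sigma_kappa", "mu_alpha_pos", "sigma_alpha_pos",
             "mu_alpha_neg", "sigma_alpha_neg", "sigma_err"]
            + [f"kappa[{sid}]" for sid in self.subject_ids]
            + [f"alpha[{sid}]" for sid in self.subject_ids]
        )
        self.ndim = 7 + 2 * self.n_subjects

    # -- parameter transforms ------------------------------------------------

    def _unpack(self, theta: np.ndarray):
        """Map unconstrained vectors (K, ndim) to natural-scale parameters."""
        theta = np.atleast_2d(theta)
        S = self.n_subjects
        with np.errstate(over="ignore"):
            mu_k = np.exp(theta[:, 0])
            sig_k = np.exp(theta[:, 1])
            mu_ap = theta[:, 2]
            sig_ap = np.exp(theta[:, 3])
            mu_an = theta[:, 4]
            sig_an = np.exp(theta[:, 5])
            sig_err = np.exp(theta[:, 6])
            z_k = theta[:, 7 : 7 + S]
            z_a = theta[:, 7 + S : 7 + 2 * S]
            kappa = mu_k[:, None] + sig_k[:, None] * z_k
            mu_a = np.where(self.amyloid[None, :], mu_ap[:, None], mu_an[:, None])
            sig_a = np.where(self.amyloid[None, :], sig_ap[:, None], sig_an[:, None])
            alpha = mu_a + sig_a * z_a
        return mu_k, sig_k, mu_ap, sig_ap, mu_an, sig_an, sig_err, z_k, z_a, kappa, alpha

    def pack_natural(self, hyper: HyperParams, kappas: np.ndarray, alphas: np.ndarray) -> np.ndarray:
        """Build one unconstrained vector from natural-scale parameters."""
        z_k = (np.asarray(kappas, dtype=float) - hyper.mu_kappa) / hyper.sigma_kappa
        mu_a = np.where(self.amyloid, hyper.mu_alpha_pos, hyper.mu_alpha_neg)
        sig_a = np.where(self.amyloid, hyper.sigma_alpha_pos, hyper.sigma_alpha_neg)
        z_a = (np.asarray(alphas, dtype=float) - mu_a) / sig_a
        return np.concatenate(
            [
                [np.log(hyper.mu_kappa), np.log(hyper.sigma_kappa),
                 hyper.mu_alpha_pos, np.log(hyper.sigma_alpha_pos),
                 hyper.mu_alpha_neg, np.log(hyper.sigma_alpha_neg),
                 np.log(hyper.sigma_err)],
                z_k,
                z_a,
            ]
        )

    # -- densities -----------------------------------------------------------

    @staticmethod
    def _log_halfcauchy(x: np.ndarray, beta: float) -> np.ndarray:
        return np.log(2.0 / (np.pi * beta)) - np.log1p((x / beta) ** 2)

    def log_prior(self, theta: np.ndarray) -> np.ndarray:
        """Joint log prior density on the unconstrained scale (with Jacobians)."""
        theta = np.atleast_2d(theta)
        p = self.prior
        (mu_k, sig_k, mu_ap, sig_ap, mu_an, sig_an, sig_err,
         z_k, z_a, kappa, _alpha) = self._unpack(theta)
        beta = p.halfcauchy_beta

        # mu_kappa ~ BoundNormal(>0, loc, scale); sampled as log mu_kappa.
        # Written out manually (normal logpdf minus the >0 normalization).
        zm = (mu_k - p.mu_kappa_loc) / p.mu_kappa_scale
        lp = (
            -0.5 * zm**2 - np.log(p.mu_kappa_scale) - 0.5 * _LOG_2PI
            - log_ndtr(p.mu_kappa_loc / p.mu_kappa_scale)
        )
        lp = lp + theta[:, 0]  # Jacobian d mu_k / d log mu_k
        for sig, col in ((sig_k, 1), (sig_ap, 3), (sig_an, 5), (sig_err, 6)):
            lp += self._log_halfcauchy(sig, beta) + theta[:, col]
        for mu in (mu_ap, mu_an):
            lp += (
                -0.5 * ((mu - p.mu_alpha_loc) / p.mu_alpha_scale) ** 2
                - np.log(p.mu_alpha_scale) - 0.5 * _LOG_2PI
            )
        # z_kappa: standard normal truncated below at -mu_k/sig_k so that
        # kappa_s > 0; the truncation normalization is Phi(mu_k/sig_k).
        with np.errstate(over="ignore", invalid="ignore"):
            valid = np.all(kappa > 0, axis=1)
            lp += (
                -0.5 * (z_k**2).sum(axis=1)
                - self.n_subjects * log_ndtr(mu_k / sig_k)
                - 0.5 * self.n_subjects * _LOG_2PI
            )
            lp += -0.5 * (z_a**2).sum(axis=1) - 0.5 * self.n_subjects * _LOG_2PI
        return np.where(valid & np.isfinite(lp), lp, -np.inf)

    def _predict(self, kappa: np.ndarray, alpha: np.ndarray) -> np.ndarray:
        """Trajectories at the union follow-up grid; shape (T, K, S, N)."""
        with np.errstate(over="ignore", invalid="ignore", under="ignore"):
            return integrate_batch(
                self.baselines, kappa, alpha, self.network.laplacian,
                self.eval_times, dt=self.ode_dt,
            )

    def log_likelihood(self, theta: np.ndarray) -> np.ndarray:
        """Gaussian log likelihood of all follow-up observations."""
        theta = np.atleast_2d(theta)
        *_, sig_err, _zk, _za, kappa, alpha = self._unpack(theta)
        if self.n_obs == 0:
            return np.zeros(theta.shape[0])
        try:
            traj = self._predict(kappa, alpha)
        except Exception:  # non-finite blow-up for extreme walkers
            return np.full(theta.shape[0], -np.inf)
        with np.errstate(over="ignore", invalid="ignore"):
            pred = traj[self._flat_t, :, self._flat_s, :][:, :, self.obs_regions]
            ss = np.square(pred - self._flat_obs[:, None, :]).sum(axis=(0, 2))
            ll = (
                -0.5 * ss / sig_err**2
                - self.n_obs * np.log(sig_err)
                - 0.5 * self.n_obs * _LOG_2PI
            )
        return np.where(np.isfinite(ll), ll, -np.inf)

    def log_posterior(self, theta: np.ndarray) -> np.ndarray:
        theta = np.atleast_2d(theta)
        lp = self.log_prior(theta)
        out = np.full(theta.shape[0], -np.inf)
        ok = np.isfinite(lp)
        if np.any(ok):
            out[ok] = lp[ok] + self.log_likelihood(theta[ok])
        return out

    # -- initialization ------------------------------------------------------

    def _sse(self, kappa: np.ndarray, alpha: np.ndarray) -> np.ndarray:
        """Per-subject sum of squared residuals; shapes (K, S) -> (K, S)."""
        traj = self._predict(np.atleast_2d(kappa), np.atleast_2d(alpha))
        out = np.empty((traj.shape[1], self.n_subjects))
        for s in range(self.n_subjects):
            pred = traj[self._sub_time_idx[s], :, s, :][:, :, self.obs_regions]
            out[:, s] = np.square(pred - self._sub_obs[s][:, None, :]).sum(axis=(0, 2))
        return out

    def empirical_start(self, maxiter: int = 300) -> np.ndarray:
        """Starting point from independent per-subject least-squares fits.

        The joint posterior mode of a hierarchical model is degenerate (the
        density grows without bound as a group scale shrinks onto its
        subjects), so it is useless for initialization. Instead each
        subject's (kappa, alpha) is fitted independently by ridge-penalized
        least squares, and the group-level coordinates are set to the
        empirical moments of those fits, with floors keeping the start away
        from the funnel neck.
        """
        from scipy.optimize import minimize

        S = self.n_subjects

        def objective(x: np.ndarray) -> float:
            kap = np.exp(x[:S])
            ss = self._sse(kap[None, :], x[None, S:])[0]
            ridge = 0.5 * np.sum((x[:S] / 2.0) ** 2) + 0.5 * np.sum((x[S:] / 1.0) ** 2)
            val = ss.sum() / (2 * 0.05**2) + ridge
            return float(val) if np.isfinite(val) else 1e10

        x0 = np.zeros(2 * S)
        res = minimize(objective, x0, method="L-BFGS-B", options={"maxiter": maxiter})
        log_kap, alp = res.x[:S], res.x[S:]
        kap = np.exp(log_kap)
        mu_k = max(float(kap.mean()), 0.05)
        sig_k = max(float(kap.std()), 0.1 * mu_k, 0.05)
        pos, neg = self.amyloid, ~self.amyloid
        mu_ap = float(alp[pos].mean()) if pos.any() else 0.0
        mu_an = float(alp[neg].mean()) if neg.any() else 0.0
        sig_ap = max(float(alp[pos].std()) if pos.any() else 0.1, 0.03)
        sig_an = max(float(alp[neg].std()) if neg.any() else 0.1, 0.03)
        sig_err = max(np.sqrt(self._sse(kap[None], alp[None])[0].sum()
                              / max(self.n_obs, 1)), 0.01)
        hyper = HyperParams(
            mu_kappa=mu_k, sigma_kappa=sig_k,
            mu_alpha_pos=mu_ap, sigma_alpha_pos=sig_ap,
            mu_alpha_neg=mu_an, sigma_alpha_neg=sig_an,
            sigma_err=float(sig_err),
        )
        return self.pack_natural(hyper, kap, alp)

    def initial_points(
        self, rng: np.random.Generator, nwalkers: int, center: np.ndarray | None = None
    ) -> np.ndarray:
        """Walker start positions around the empirical start.

        Location coordinates get a tight jitter; the log-scale coordinates
        are deliberately overdispersed so the ensemble straddles the
        hierarchy's funnel instead of starting inside its neck. Walkers
        with non-finite posterior are re-jittered.
        """
        if center is None:
            center = self.empirical_start()
        S = self.n_subjects
        scale = np.full(self.ndim, 0.1)
        scale[[1, 3, 5]] = 0.5  # group log-scales: overdisperse
        scale[6] = 0.2
        scale[7:] = 0.3  # subject-level z coordinates
        p0 = center[None, :] + scale * rng.standard_normal((nwalkers, self.ndim))
        lp = self.log_posterior(p0)
        for _ in range(50):
            bad = ~np.isfinite(lp)
            if not np.any(bad):
                break
            p0[bad] = center[None, :] + 0.5 * scale * rng.standard_normal(
                (int(bad.sum()), self.ndim)
            )
            lp = self.log_posterior(p0)
        return p0

    def dispersed_points(self, rng: np.random.Generator, nwalkers: int) -> np.ndarray:
        """Overdispersed but numerically safe starting points."""
        S = self.n_subjects
        p0 = np.empty((nwalkers, self.ndim))
        p0[:, 0] = rng.normal(0.0, 0.5, nwalkers)          # log mu_kappa ~ around 1
        p0[:, 1] = np.log(np.abs(rng.normal(0.3, 0.15, nwalkers)) + 0.05)
        p0[:, 2] = rng.normal(0.0, 0.15, nwalkers)
        p0[:, 3] = np.log(np.abs(rng.normal(0.1, 0.05, nwalkers)) + 0.02)
        p0[:, 4] = rng.normal(0.0, 0.15, nwalkers)
        p0[:, 5] = np.log(np.abs(rng.normal(0.1, 0.05, nwalkers)) + 0.02)
        p0[:, 6] = np.log(np.abs(rng.normal(0.08, 0.04, nwalkers)) + 0.01)
        p0[:, 7 : 7 + S] = rng.normal(0.0, 0.5, (nwalkers, S))   # log kappa_s
        p0[:, 7 + S :] = rng.normal(0.0, 0.2, (nwalkers, S))     # alpha_s
        return p0


def build_model(spec: ModelSpec) -> HierarchicalModel:
    """Assemble the hierarchical probabilistic model from its specification."""
    return HierarchicalModel(spec)


# ---------------------------------------------------------------------------
# Posterior container and sampling
# ---------------------------------------------------------------------------


@dataclass
class PosteriorSamples:
    """Posterior draws (chain x draw x parameter) plus diagnostics."""

    idata: az.InferenceData
    subject_ids: tuple[str, ...]
    amyloid_positive: np.ndarray
    diagnostics: pd.DataFrame
    divergences: int = 0
    acceptance_fraction: float = float("nan")
    converged: bool = True
    warnings: list[str] = field(default_factory=list)

    @property
    def n_chains(self) -> int:
        return self.idata.posterior.sizes["chain"]

    @property
    def n_draws(self) -> int:
        return self.idata.posterior.sizes["draw"]

    def hyper_draws(self, name: str) -> np.ndarray:
        """Flattened draws of one scalar hyperparameter."""
        return self.idata.posterior[name].to_numpy().ravel()

    def subject_draws(self, name: str) -> np.ndarray:
        """Flattened draws of 'kappa' or 'alpha'; shape (draws, subjects)."""
        arr = self.idata.posterior[name].to_numpy()  # (chain, draw, subject)
        return arr.reshape(-1, arr.shape[-1])

    def subject_posterior_means(self) -> pd.DataFrame:
        """Per-subject posterior means, medians and 95% credible intervals."""
        kap = self.subject_draws("kappa")
        alp = self.subject_draws("alpha")
        q = lambda x, p: np.quantile(x, p, axis=0)
        return pd.DataFrame(
            {
                "subject_id": self.subject_ids,
                "amyloid_positive": self.amyloid_positive.astype(int),
                "kappa_mean": kap.mean(axis=0),
                "kappa_median": np.median(kap, axis=0),
                "kappa_lo95": q(kap, 0.025),
                "kappa_hi95": q(kap, 0.975),
                "alpha_mean": alp.mean(axis=0),
                "alpha_median": np.median(alp, axis=0),
                "alpha_lo95": q(alp, 0.025),
                "alpha_hi95": q(alp, 0.975),
            }
        )

    def draws_frame(self, thin: int = 1) -> pd.DataFrame:
        """Long-format draws table (chain, draw, parameter, value)."""
        rows = []
        post = self.idata.posterior
        for name in ("mu_kappa", "sigma_kappa", "mu_alpha_pos", "sigma_alpha_pos",
                     "mu_alpha_neg", "sigma_alpha_neg", "sigma_err"):
            arr = post[name].to_numpy()[:, ::thin]
            c, d = np.indices(arr.shape)
            rows.append(pd.DataFrame({
                "chain": c.ravel(), "draw": d.ravel(),
                "parameter": name, "value": arr.ravel(),
            }))
        for name in ("kappa", "alpha"):
            arr = post[name].to_numpy()[:, ::thin]
            for s, sid in enumerate(self.subject_ids):
                sl = arr[:, :, s]
                c, d = np.indices(sl.shape)
                rows.append(pd.DataFrame({
                    "chain": c.ravel(), "draw": d.ravel(),
                    "parameter": f"{name}[{sid}]", "value": sl.ravel(),
                }))
        return pd.concat(rows, ignore_index=True)

    def save(self, out_dir: str | Path, thin: int = 1) -> None:
        """Persist draws (columnar CSV) and metadata/diagnostics (JSON)."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.draws_frame(thin=thin).to_csv(out / "posterior_draws.csv", index=False)
        meta = {
            "subject_ids": list(self.subject_ids),
            "amyloid_positive": [int(x) for x in self.amyloid_positive],
            "divergences": self.divergences,
            "acceptance_fraction": self.acceptance_fraction,
            "converged": bool(self.converged),
            "warnings": self.warnings,
            "diagnostics": self.diagnostics.to_dict(orient="records"),
        }
        (out / "posterior_meta.json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def load(cls, out_dir: str | Path) -> "PosteriorSamples":
        out = Path(out_dir)
        meta = json.loads((out / "posterior_meta.json").read_text())
        df = pd.read_csv(out / "posterior_draws.csv")
        subject_ids = tuple(meta["subject_ids"])
        n_chain = int(df["chain"].max()) + 1
        n_draw = int(df["draw"].max()) + 1
        post: dict[str, np.ndarray] = {}
        scalars = ("mu_kappa", "sigma_kappa", "mu_alpha_pos", "sigma_alpha_pos",
                   "mu_alpha_neg", "sigma_alpha_neg", "sigma_err")
        for name in scalars:
            sub = df[df["parameter"] == name]
            arr = np.empty((n_chain, n_draw))
            arr[sub["chain"], sub["draw"]] = sub["value"]
            post[name] = arr
        for name in ("kappa", "alpha"):
            arr = np.empty((n_chain, n_draw, len(subject_ids)))
            for s, sid in enumerate(subject_ids):
                sub = df[df["parameter"] == f"{name}[{sid}]"]
                arr[sub["chain"], sub["draw"], s] = sub["value"]
            post[name] = arr
        idata = az.from_dict(posterior=post, dims={"kappa": ["subject"], "alpha": ["subject"]},
                             coords={"subject": list(subject_ids)})
        return cls(
            idata=idata,
            subject_ids=subject_ids,
            amyloid_positive=np.array(meta["amyloid_positive"], dtype=bool),
            diagnostics=pd.DataFrame(meta["diagnostics"]),
            divergences=meta["divergences"],
            acceptance_fraction=meta["acceptance_fraction"],
            converged=meta["converged"],
            warnings=list(meta["warnings"]),
        )


def _walker_count(config: SamplerConfig, ndim: int) -> int:
    n = config.walkers or max(2 * ndim + 2, 48)
    return n + (n % 2)


def sample_posterior(
    model: HierarchicalModel, config: SamplerConfig | None = None
) -> PosteriorSamples:
    """Sample the posterior with independent affine-invariant ensembles.

    Each of ``config.chains`` ensembles runs ``tune`` discarded adaptation
    steps then ``draws`` kept steps; every walker is one chain in the output
    (so the chain dimension is ``chains * walkers``). Runs with the same
    seed are bit-reproducible. Poor convergence (split-R-hat > 1.1) is
    reported via ``converged=False`` and a warning, not an exception.
    """
    config = config or model.spec.sampler_config
    ndim = model.ndim
    nwalkers = _walker_count(config, ndim)
    moves = [(emcee.moves.DEMove(), 0.8), (emcee.moves.DESnookerMove(), 0.2)]
    chains = []
    acc = []
    seeds = np.random.SeedSequence(config.seed).generate_state(config.chains)
    center = model.empirical_start()
    for c in range(config.chains):
        seed_c = int(seeds[c] % (2**31 - 1))
        rng = np.random.default_rng(seed_c)
        sampler = emcee.EnsembleSampler(
            nwalkers, ndim, model.log_posterior, vectorize=True, moves=moves
        )
        p0 = model.initial_points(rng, nwalkers, center=center)
        state = emcee.State(p0, random_state=np.random.RandomState(seed_c).get_state())
        state = sampler.run_mcmc(state, config.tune, progress=False)
        sampler.reset()
        sampler.run_mcmc(state, config.draws, progress=False)
        chains.append(sampler.get_chain())  # (draws, walkers, ndim)
        acc.append(float(np.mean(sampler.acceptance_fraction)))
    raw = np.concatenate(chains, axis=1)  # (draws, chains*walkers, ndim)
    theta = np.moveaxis(raw, 0, 1)  # (chain, draw, ndim)

    C, T, _ = theta.shape
    flat = theta.reshape(-1, ndim)
    (mu_k, sig_k, mu_ap, sig_ap, mu_an, sig_an, sig_err,
     _zk, _za, kappa, alpha) = model._unpack(flat)
    S = model.n_subjects
    post = {
        "mu_kappa": mu_k.reshape(C, T),
        "sigma_kappa": sig_k.reshape(C, T),
        "mu_alpha_pos": mu_ap.reshape(C, T),
        "sigma_alpha_pos": sig_ap.reshape(C, T),
        "mu_alpha_neg": mu_an.reshape(C, T),
        "sigma_alpha_neg": sig_an.reshape(C, T),
        "sigma_err": sig_err.reshape(C, T),
        "kappa": kappa.reshape(C, T, S),
        "alpha": alpha.reshape(C, T, S),
    }
    idata = az.from_dict(
        posterior=post,
        dims={"kappa": ["subject"], "alpha": ["subject"]},
        coords={"subject": list(model.subject_ids)},
    )
    rhat = az.rhat(idata)
    ess = az.ess(idata)
    rows = []
    for name in post:
        r = np.atleast_1d(rhat[name].to_numpy())
        e = np.atleast_1d(ess[name].to_numpy())
        if r.size == 1:
            rows.append({"parameter": name, "rhat": float(r[0]), "ess_bulk": float(e[0])})
        else:
            for s, sid in enumerate(model.subject_ids):
                rows.append({"parameter": f"{name}[{sid}]", "rhat": float(r[s]),
                             "ess_bulk": float(e[s])})
    diagnostics = pd.DataFrame(rows)
    max_rhat = float(diagnostics["rhat"].max())
    warnings: list[str] = []
    converged = max_rhat <= RHAT_WARN
    if not converged:
        msg = (
            f"convergence warning: max split-R-hat {max_rhat:.3f} > {RHAT_WARN}; "
            "treat posterior summaries with caution"
        )
        warnings.append(msg)
        log.warning(msg)
    return PosteriorSamples(
        idata=idata,
        subject_ids=model.subject_ids,
        amyloid_positive=model.amyloid,
        diagnostics=diagnostics,
        divergences=0,  # not defined for the ensemble sampler
        acceptance_fraction=float(np.mean(acc)),
        converged=converged,
        warnings=warnings,
    )


# ---------------------------------------------------------------------------
# Summaries and group comparison
# ---------------------------------------------------------------------------


@dataclass
class PosteriorSummary:
    """Per-subject posterior means plus the group-level summary table."""

    subjects: pd.DataFrame
    table: pd.DataFrame  # rows Mean/Std/Min/Max, columns kappa / alpha_neg / alpha_pos


def summarize_posterior(samples: PosteriorSamples) -> PosteriorSummary:
    """Summarize per-subject posterior means in the standard group layout.

    The group table reports mean, standard deviation, minimum and maximum of
    the per-subject posterior means: diffusion coefficients across all
    subjects, production rates split by amyloid status.
    """
    subjects = samples.subject_posterior_means()
    pos = subjects["amyloid_positive"].astype(bool).to_numpy()
    kap = subjects["kappa_mean"].to_numpy()
    alp = subjects["alpha_mean"].to_numpy()

    def col(values: np.ndarray) -> list[float]:
        if values.size == 0:
            return [np.nan] * 4
        return [float(values.mean()),
                float(values.std(ddof=1)) if values.size > 1 else 0.0,
                float(values.min()), float(values.max())]

    table = pd.DataFrame(
        {
            "kappa": col(kap),
            "alpha_neg": col(alp[~pos]),
            "alpha_pos": col(alp[pos]),
        },
        index=["Mean", "Std", "Min", "Max"],
    )
    return PosteriorSummary(subjects=subjects, table=table)


@dataclass(frozen=True)
class GroupComparison:
    """Two-sample t-test on per-subject posterior-mean production rates."""

    t_statistic: float
    p_value: float
    n_positive: int
    n_negative: int
    mean_positive: float
    mean_negative: float
    welch: bool

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)


def compare_groups(
    subjects: pd.DataFrame, value: str = "alpha_mean", welch: bool = False
) -> GroupComparison:
    """Independent t-test of production rates between amyloid groups.

    ``subjects`` is the per-subject table from :func:`summarize_posterior`
    (columns ``amyloid_positive`` and ``value``). The classic pooled-variance
    test is the default; set ``welch=True`` for unequal variances.
    """
    pos_mask = subjects["amyloid_positive"].astype(bool).to_numpy()
    x_pos = subjects.loc[pos_mask, value].to_numpy()
    x_neg = subjects.loc[~pos_mask, value].to_numpy()
    if x_pos.size < 2 or x_neg.size < 2:
        raise DataError("need at least 2 subjects per amyloid group for the t-test")
    res = ttest_ind(x_pos, x_neg, equal_var=not welch)
    return GroupComparison(
        t_statistic=float(res.statistic),
        p_value=float(res.pvalue),
        n_positive=int(x_pos.size),
        n_negative=int(x_neg.size),
        mean_positive=float(x_pos.mean()),
        mean_negative=float(x_neg.mean()),
        welch=welch,
    )


def sample_prior(
    prior: PriorConfig, n: int, rng: np.random.Generator
) -> dict[str, np.ndarray]:
    """Direct draws from the hyperprior marginals (for prior checks)."""
    a = (0.0 - prior.mu_kappa_loc) / prior.mu_kappa_scale
    return {
        "mu_kappa": truncnorm.rvs(a, np.inf, loc=prior.mu_kappa_loc,
                                  scale=prior.mu_kappa_scale, size=n, random_state=rng),
        "sigma_kappa": halfcauchy.rvs(scale=prior.halfcauchy_beta, size=n, random_state=rng),
        "mu_alpha_pos": rng.normal(prior.mu_alpha_loc, prior.mu_alpha_scale, n),
        "mu_alpha_neg": rng.normal(prior.mu_alpha_loc, prior.mu_alpha_scale, n),
        "sigma_alpha_pos": halfcauchy.rvs(scale=prior.halfcauchy_beta, size=n, random_state=rng),
        "sigma_alpha_neg": halfcauchy.rvs(scale=prior.halfcauchy_beta, size=n, random_state=rng),
        "sigma_err": halfcauchy.rvs(scale=prior.halfcauchy_beta, size=n, random_state=rng),
    }
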