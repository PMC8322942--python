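"""Posterior-predictive regional forecasts and scan-scheduling rules.

For each posterior draw of a subject's (kappa, alpha) the FKPP dynamics are
integrated forward from the subject's baseline scan; pointwise medians and
equal-tailed credible bands across draws quantify how parameter uncertainty
propagates into the projected tau burden. The band width feeds a simple
scheduling rule: the first time the credible band in any monitored region
grows wider than a critical threshold (default 0.2) is a sensible moment
for the next confirmatory scan.

Default monitored regions are the entorhinal cortex, middle temporal gyrus
and superior temporal gyrus in both hemispheres - areas hit at distinct
Braak stages, so their trajectories stage the disease.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .connectome import BrainNetwork
from .dynamics import integrate_batch
from .errors import DataError
from .inference import PosteriorSamples
from .preprocess import ScanSeries

__all__ = [
    "Forecast",
    "ScanRecommendation",
    "DEFAULT_FORECAST_REGIONS",
    "resolve_regions",
    "posterior_predict",
    "recommend_scan_time",
    "plot_forecast",
]

DEFAULT_FORECAST_REGIONS = ("entorhinal", "middletemporal", "superiortemporal")
DEFAULT_HORIZON_YEARS = 30.0
DEFAULT_N_DRAWS = 4000
DEFAULT_TIME_STEP = 0.25


@dataclass(frozen=True)
class Forecast:
    """Posterior-predictive trajectories for one subject.

    ``median``, ``lower`` and ``upper`` have shape (time, region); the band
    is equal-tailed at the stated credible level.
    """

    subject_id: str
    region_names: tuple[str, ...]
    times: np.ndarray
    median: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    n_draws: int
    level: float = 0.95

    def __post_init__(self) -> None:
        if np.any(self.lower > self.median + 1e-12) or np.any(
            self.median > self.upper + 1e-12
        ):
            raise DataError("forecast band must satisfy lower <= median <= upper")

    @property
    def width(self) -> np.ndarray:
        """Pointwise credible-band width, shape (time, region)."""
        return self.upper - self.lower

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r, name in enumerate(self.region_names):
            rows.append(
                pd.DataFrame(
                    {
                        "time_years": self.times,
                        "region": name,
                        "median": self.median[:, r],
                        "lower": self.lower[:, r],
                        "upper": self.upper[:, r],
                    }
                )
            )
        return pd.concat(rows, ignore_index=True)

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


@dataclass(frozen=True)
class ScanRecommendation:
    """First time the credible band exceeds the width threshold."""

    subject_id: str
    region_names: tuple[str, ...]
    recommended_time: float | None  # None when the band never exceeds it
    beyond_horizon: bool
    width_threshold: float
    per_region_times: dict[str, float | None]

    def to_json(self) -> str:
        d = asdict(self)
        d["region_names"] = list(self.region_names)
        return json.dumps(d, indent=2)


def resolve_regions(
    network: BrainNetwork, specs: tuple[str | int, ...]
) -> tuple[np.ndarray, tuple[str, ...]]:
    """Resolve region specs (substring, exact name or id) to graph indices.

    A bare substring like ``"entorhinal"`` matches the region in both
    hemispheres.
    """
    idx: list[int] = []
    for spec in specs:
        if isinstance(spec, (int, np.integer)):
            idx.append(network.regions.index(int(spec)))
            continue
        text = str(spec)
        if text in network.regions.names:
            idx.append(network.regions.names.index(text))
            continue
        hits = [i for i, nm in enumerate(network.regions.names) if text in nm]
        if not hits:
            raise DataError(f"region {spec!r} not found in network")
        idx.extend(hits)
    idx = sorted(dict.fromkeys(idx))
    return np.array(idx, dtype=int), tuple(network.regions.names[i] for i in idx)


def posterior_predict(
    samples: PosteriorSamples,
    subject: ScanSeries,
    network: BrainNetwork,
    horizon: float = DEFAULT_HORIZON_YEARS,
    n_draws: int = DEFAULT_N_DRAWS,
    regions: tuple[str | int, ...] = DEFAULT_FORECAST_REGIONS,
    time_step: float = DEFAULT_TIME_STEP,
    level: float = 0.95,
    seed: int = 0,
    include_observation_noise: bool = False,
) -> Forecast:
    """Posterior-predictive forecast from the subject's baseline scan.

    Draws ``n_draws`` (kappa, alpha) pairs from the subject's posterior,
    integrates each over ``horizon`` years on the full graph, and summarizes
    the monitored regions with the pointwise median and the equal-tailed
    ``level`` credible band. Observation noise is excluded by default: the
    band reflects parameter uncertainty propagated through the dynamics.
    """
    if subject.subject_id not in samples.subject_ids:
        raise DataError(f"subject {subject.subject_id!r} not in posterior samples")
    if subject.normalized is None:
        raise DataError(f"subject {subject.subject_id}: normalize scans first")
    s = samples.subject_ids.index(subject.subject_id)
    region_idx, region_names = resolve_regions(network, regions)

    kap = samples.subject_draws("kappa")[:, s]
    alp = samples.subject_draws("alpha")[:, s]
    rng = np.random.default_rng(seed)
    pick = rng.integers(0, kap.size, size=n_draws)
    kap, alp = kap[pick], alp[pick]

    times = np.arange(0.0, horizon + time_step / 2, time_step)
    c0 = subject.normalized[0]
    states = integrate_batch(c0, kap, alp, network.laplacian, times)  # (T, K, N)
    sel = states[:, :, region_idx]
    if include_observation_noise:
        sig = samples.hyper_draws("sigma_err")[pick]
        sel = sel + rng.normal(0.0, 1.0, size=sel.shape) * sig[None, :, None]
    tail = (1.0 - level) / 2.0
    lower, median, upper = np.quantile(sel, [tail, 0.5, 1.0 - tail], axis=1)
    return Forecast(
        subject_id=subject.subject_id,
        region_names=region_names,
        times=times,
        median=median,
        lower=lower,
        upper=upper,
        n_draws=n_draws,
        level=level,
    )


def recommend_scan_time(
    forecast: Forecast, width_threshold: float = 0.2
) -> ScanRecommendation:
    """Earliest forecast time at which the credible band exceeds the threshold.

    The trigger is evaluated on the maximum band width across the monitored
    regions; per-region first-crossing times are reported alongside. When
    the band never exceeds the threshold inside the horizon the
    recommendation is flagged as beyond the horizon.
    """
    width = forecast.width
    exceeded = width.max(axis=1) > width_threshold
    per_region: dict[str, float | None] = {}
    for r, name in enumerate(forecast.region_names):
        hits = np.flatnonzero(width[:, r] > width_threshold)
        per_region[name] = float(forecast.times[hits[0]]) if hits.size else None
    hits = np.flatnonzero(exceeded)
    if hits.size:
        return ScanRecommendation(
            subject_id=forecast.subject_id,
            region_names=forecast.region_names,
            recommended_time=float(forecast.times[hits[0]]),
            beyond_horizon=False,
            width_threshold=width_threshold,
            per_region_times=per_region,
        )
    return ScanRecommendation(
        subject_id=forecast.subject_id,
        region_names=forecast.region_names,
        recommended_time=None,
        beyond_horizon=True,
        width_threshold=width_threshold,
        per_region_times=per_region,
    )


def plot_forecast(
    forecast: Forecast,
    recommendation: ScanRecommendation | None = None,
    path: str | Path | None = None,
):
    """Median curves with shaded credible bands, one panel per region."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    n = len(forecast.region_names)
    fig, axes = plt.subplots(1, n, figsize=(3.2 * n, 3.0), sharey=True, squeeze=False)
    for r, (ax, name) in enumerate(zip(axes[0], forecast.region_names)):
        ax.fill_between(
            forecast.times, forecast.lower[:, r], forecast.upper[:, r],
            alpha=0.3, label=f"{int(forecast.level * 100)}% credible band",
        )
        ax.plot(forecast.times, forecast.median[:, r], lw=1.5, label="median")
        if recommendation and recommendation.recommended_time is not None:
            ax.axvline(recommendation.recommended_time, color="gray", ls="--", lw=1)
        ax.set_title(name, fontsize=9)
        ax.set_xlabel("years after baseline scan")
        ax.set_ylim(-0.02, 1.02)
    axes[0][0].set_ylabel("normalized tau concentration")
    axes[0][0].legend(fontsize=7)
    fig.suptitle(forecast.subject_id, fontsize=10)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
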