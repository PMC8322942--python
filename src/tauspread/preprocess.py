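"""Mapping regional tau-PET SUVR onto the model's [0,1] concentration scale.

Raw regional standardized uptake value ratios (SUVR, reference-normalized
tracer uptake) are converted to normalized concentrations ``c_pet`` in two
steps: (1) a two-component Gaussian mixture fitted to the pooled SUVR values
across all subjects, time points and regions separates the tau-negative bulk
from the tau-positive tail and defines a positivity threshold (the crossing
point where posterior membership in the upper component reaches 0.5);
(2) values at or below the threshold map to zero and suprathreshold values
are rescaled affinely to [0,1] against a global ceiling.

Model calibration is restricted to cortical regions; subcortical regions and
the hippocampus are excluded because their PET signal is contaminated by
off-target binding in the choroid plexus and nearby vascular structures.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.stats import norm
from sklearn.mixture import GaussianMixture

from .connectome import RegionTable
from .errors import DataError, DegenerateMixtureError

__all__ = [
    "ScanSeries",
    "MixtureFit",
    "fit_positivity_threshold",
    "normalize_suvr",
    "select_observed_regions",
    "normalize_cohort",
    "read_cohort_table",
    "write_cohort_table",
]

log = logging.getLogger(__name__)

MIN_POOL_SIZE = 100
MIN_CALIBRATION_SCANS = 3  # baseline + >= 2 follow-ups


@dataclass
class ScanSeries:
    """One subject's longitudinal regional tau observations.

    ``raw_suvr`` has one row per scan (baseline first) and one column per
    atlas region; ``normalized`` is filled by :func:`normalize_cohort` (or
    directly when data are already on the [0,1] scale).
    """

    subject_id: str
    amyloid_positive: bool
    scan_times: np.ndarray  # years from baseline, first entry 0
    raw_suvr: np.ndarray  # (n_scans, n_regions)
    normalized: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        t = np.asarray(self.scan_times, dtype=float)
        x = np.asarray(self.raw_suvr, dtype=float)
        if t.ndim != 1 or x.ndim != 2 or x.shape[0] != t.size:
            raise DataError(
                f"subject {self.subject_id}: scan_times/raw_suvr shape mismatch"
            )
        if t.size == 0 or not np.isclose(t[0], 0.0):
            raise DataError(f"subject {self.subject_id}: first scan time must be 0")
        if np.any(np.diff(t) < 0):
            raise DataError(f"subject {self.subject_id}: scan times decrease")
        self.scan_times = t
        self.raw_suvr = x
        if self.normalized is not None:
            z = np.asarray(self.normalized, dtype=float)
            if z.shape != x.shape:
                raise DataError(f"subject {self.subject_id}: normalized shape mismatch")
            if np.any(z < 0) or np.any(z > 1):
                raise DataError(
                    f"subject {self.subject_id}: normalized values outside [0,1]"
                )
            self.normalized = z

    @property
    def n_scans(self) -> int:
        return self.scan_times.size

    @property
    def n_followups(self) -> int:
        return self.n_scans - 1

    @property
    def calibration_eligible(self) -> bool:
        return self.n_scans >= MIN_CALIBRATION_SCANS


@dataclass(frozen=True)
class MixtureFit:
    """Two-component univariate Gaussian mixture and the derived threshold."""

    weights: tuple[float, float]
    means: tuple[float, float]  # ordered, lower first
    sds: tuple[float, float]
    positivity_threshold: float

    def membership_upper(self, x: np.ndarray) -> np.ndarray:
        """Posterior probability that ``x`` belongs to the upper component."""
        x = np.asarray(x, dtype=float)
        lo = self.weights[0] * norm.pdf(x, self.means[0], self.sds[0])
        hi = self.weights[1] * norm.pdf(x, self.means[1], self.sds[1])
        return hi / (lo + hi)

    def report(self) -> str:
        return (
            "Two-component Gaussian mixture fit\n"
            f"  lower component: weight={self.weights[0]:.3f} "
            f"mean={self.means[0]:.4f} sd={self.sds[0]:.4f}\n"
            f"  upper component: weight={self.weights[1]:.3f} "
            f"mean={self.means[1]:.4f} sd={self.sds[1]:.4f}\n"
            f"  positivity threshold (membership 0.5): "
            f"{self.positivity_threshold:.4f}\n"
        )


def fit_positivity_threshold(
    pooled_values: np.ndarray,
    random_state: int = 0,
    n_init: int = 5,
) -> MixtureFit:
    """Fit a two-component Gaussian mixture to pooled raw SUVR values.

    The positivity threshold is the point between the component means where
    the posterior membership probability of the upper (tau-positive)
    component crosses 0.5. Raises :class:`DegenerateMixtureError` when the
    fit collapses (vanishing weight, coincident means, or no crossing), in
    which case a fixed threshold override should be used instead.
    """
    x = np.asarray(pooled_values, dtype=float).ravel()
    x = x[np.isfinite(x)]
    if x.size < MIN_POOL_SIZE:
        raise DataError(
            f"need >= {MIN_POOL_SIZE} pooled values to fit the mixture, got {x.size}"
        )
    if np.any(x <= 0):
        raise DataError("pooled SUVR values must be positive")
    gm = GaussianMixture(
        n_components=2, covariance_type="full", n_init=n_init,
        random_state=random_state,
    ).fit(x[:, None])
    order = np.argsort(gm.means_.ravel())
    means = gm.means_.ravel()[order]
    sds = np.sqrt(gm.covariances_.ravel()[order])
    weights = gm.weights_.ravel()[order]

    # degenerate when a component vanishes or the modes are not separated
    # (mean gap below the summed component spreads: effectively unimodal)
    if min(weights) < 0.01 or (means[1] - means[0]) < (sds[0] + sds[1]):
        raise DegenerateMixtureError(
            "mixture fit collapsed (single mode); supply a fixed positivity "
            f"threshold instead. Fitted means {means[0]:.4f}/{means[1]:.4f}, "
            f"weights {weights[0]:.3f}/{weights[1]:.3f}"
        )
    fit = MixtureFit(
        weights=(float(weights[0]), float(weights[1])),
        means=(float(means[0]), float(means[1])),
        sds=(float(sds[0]), float(sds[1])),
        positivity_threshold=np.nan,
    )

    def g(v: float) -> float:
        return float(fit.membership_upper(np.array([v]))[0]) - 0.5

    lo, hi = fit.means
    if g(lo) >= 0 or g(hi) <= 0:
        raise DegenerateMixtureError(
            "no membership-0.5 crossing between the component means; "
            "supply a fixed positivity threshold instead"
        )
    threshold = brentq(g, lo, hi, xtol=1e-10)
    return replace(fit, positivity_threshold=float(threshold))


def normalize_suvr(
    raw: np.ndarray, threshold: float, ceiling: float
) -> np.ndarray:
    """Map raw SUVR to normalized concentrations ``c_pet`` in [0,1].

    Values at or below ``threshold`` become 0; values above are mapped
    affinely, ``(raw - threshold) / (ceiling - threshold)``, capped at 1.
    """
    if not ceiling > threshold:
        raise DataError(
            f"ceiling ({ceiling}) must exceed threshold ({threshold})"
        )
    raw = np.asarray(raw, dtype=float)
    scaled = (raw - threshold) / (ceiling - threshold)
    return np.clip(scaled, 0.0, 1.0)


def select_observed_regions(regions: RegionTable) -> np.ndarray:
    """Indices of the cortical regions used in the likelihood.

    Subcortical regions (including the hippocampus) are excluded from
    calibration; the dynamics still run on the full graph.
    """
    idx = regions.cortical_indices
    if idx.size == 0:
        log.warning("region table flags no cortical regions; observed set empty")
    return idx


def normalize_cohort(
    cohort: list[ScanSeries],
    threshold: float | None = None,
    ceiling: float | None = None,
    random_state: int = 0,
) -> tuple[list[ScanSeries], MixtureFit | None]:
    """Normalize a cohort's raw SUVR in place and return the mixture fit.

    When ``threshold`` is None it is estimated by
    :func:`fit_positivity_threshold` on the pooled raw values; a provided
    value (e.g. a fixed 1.1) overrides the fit. The ceiling defaults to the
    cohort-wide maximum raw value, applied globally so concentrations remain
    comparable across subjects.
    """
    if not cohort:
        raise DataError("empty cohort")
    pooled = np.concatenate([s.raw_suvr.ravel() for s in cohort])
    fit: MixtureFit | None = None
    if threshold is None:
        fit = fit_positivity_threshold(pooled, random_state=random_state)
        threshold = fit.positivity_threshold
    if ceiling is None:
        ceiling = float(np.max(pooled))
        if ceiling <= threshold:
            ceiling = threshold + 1.0  # degenerate all-negative cohort
    for s in cohort:
        s.normalized = normalize_suvr(s.raw_suvr, threshold, ceiling)
    return cohort, fit


# ---------------------------------------------------------------------------
# Cohort table I/O (long format)
# ---------------------------------------------------------------------------
# Schema: one row per (subject, scan, region) with columns
#   subject_id, amyloid_positive (0/1), time_years, region, suvr


def read_cohort_table(path: str | Path, regions: RegionTable) -> list[ScanSeries]:
    """Read a long-format cohort table into per-subject scan series."""
    df = pd.read_csv(path, sep=None, engine="python")
    required = {"subject_id", "amyloid_positive", "time_years", "region", "suvr"}
    missing = required - set(df.columns)
    if missing:
        raise DataError(f"cohort table missing columns: {sorted(missing)}")
    out: list[ScanSeries] = []
    for sid, g in df.groupby("subject_id", sort=True):
        amyloid = bool(g["amyloid_positive"].iloc[0])
        times = np.sort(g["time_years"].unique())
        mat = np.zeros((times.size, regions.n))
        seen = np.zeros((times.size, regions.n), dtype=bool)
        t_index = {t: m for m, t in enumerate(times)}
        for row in g.itertuples(index=False):
            m = t_index[row.time_years]
            r = regions.index(row.region)
            mat[m, r] = float(row.suvr)
            seen[m, r] = True
        if not seen.all():
            raise DataError(
                f"subject {sid}: missing SUVR entries for some (scan, region) pairs"
            )
        out.append(
            ScanSeries(
                subject_id=str(sid),
                amyloid_positive=amyloid,
                scan_times=times - times[0],
                raw_suvr=mat,
            )
        )
    if not out:
        raise DataError("cohort table contains no subjects")
    return out


def write_cohort_table(
    cohort: list[ScanSeries],
    regions: RegionTable,
    path: str | Path,
    normalized: bool = False,
) -> None:
    """Write a cohort in the long format read by :func:`read_cohort_table`."""
    rows = []
    for s in cohort:
        values = s.normalized if normalized else s.raw_suvr
        if values is None:
            raise DataError(f"subject {s.subject_id}: no normalized values to write")
        for m, t in enumerate(s.scan_times):
            for r, name in enumerate(regions.names):
                rows.append(
                    (s.subject_id, int(s.amyloid_positive), t, name, values[m, r])
                )
    pd.DataFrame(
        rows, columns=["subject_id", "amyloid_positive", "time_years", "region", "suvr"]
    ).to_csv(path, index=False)
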