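"""Timeline post-processing: anchoring, change points, nonlinearity, CAG strata.

A fitted progression model lives on an arbitrary (mean-centred) latent time
axis. Anchoring re-points ``t = 0`` at the disease time where the reference
region's posterior-mean trajectory equals the manifest-HD group's baseline
mean, defining a common abnormality threshold. Regions are then ordered by
their *change point* — the time of maximal gradient of each sampled posterior
curve — and characterised by the magnitude of change (percent of control mean)
and by a nonlinearity index (RMS distance between the fitted trajectory and
the best straight line through the staged data).
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .model import ModelConfig, PosteriorSampleSet, ProgressionModel, fit

__all__ = [
    "ChangePointSummary",
    "anchor_timeline",
    "hd_baseline_means",
    "change_points",
    "nonlinearity_index",
    "nonlinearity_table",
    "refit_by_cag",
]


def hd_baseline_means(adjusted) -> dict:
    """Per-region mean adjusted value of the manifest-HD group at baseline."""
    df = adjusted.data
    hd = df[(df["group"] == "HD") & (df["visit_index"] == 0)]
    if len(hd) == 0:
        raise ValueError("no manifest-HD baseline rows to anchor on")
    return {r: float(hd[r].mean()) for r in adjusted.regions}


def _crossing_time(model: ProgressionModel, region: str, target: float) -> float | None:
    """User-frame time where the posterior-mean curve crosses ``target``."""
    lo, hi = model.domain
    grid = np.linspace(lo, hi, 2001)
    mu = model.predict_mean(region, grid)
    if not (mu.min() - 1e-9 <= target <= mu.max() + 1e-9):
        return None
    idx = np.nonzero(np.diff(np.sign(mu - target)) != 0)[0]
    if len(idx) == 0:
        # target equals an endpoint value
        return float(grid[int(np.argmin(np.abs(mu - target)))])
    i = idx[0]
    f = lambda t: model.predict_mean(region, np.array([t]))[0] - target
    return float(brentq(f, grid[i], grid[i + 1], xtol=1e-10))


def _steepest_crossing_region(model: ProgressionModel, hd_means: dict) -> str:
    """Region whose posterior-mean curve crosses its HD baseline mean with the
    largest gradient (most sharply localized crossing)."""
    best, best_grad = None, -np.inf
    for r in model.regions:
        if r not in hd_means:
            continue
        t = _crossing_time(model, r, hd_means[r])
        if t is None:
            continue
        eps = 0.05
        lo, hi = model.domain
        t0, t1 = max(t - eps, lo), min(t + eps, hi)
        g = abs(
            (model.predict_mean(r, np.array([t1]))[0]
             - model.predict_mean(r, np.array([t0]))[0]) / (t1 - t0)
        )
        if g > best_grad:
            best, best_grad = r, g
    if best is None:
        raise ValueError(
            "no region's HD baseline mean lies within its fitted trajectory "
            "range; cannot anchor"
        )
    return best


def anchor_timeline(
    model: ProgressionModel, hd_means: dict, reference: str | None = None
) -> ProgressionModel:
    """Return a copy of the model re-anchored so ``t = 0`` is the abnormality
    threshold.

    A single global time offset is applied such that the reference region's
    posterior-mean trajectory passes through its manifest-HD baseline mean at
    ``t = 0``. By default the reference is the region whose trajectory crosses
    its HD mean most steeply — a saturated trajectory (e.g. striatum, already
    at plateau in manifest HD) pins the crossing poorly, whereas a region
    still mid-rise localizes it sharply. Per-region anchor times (each
    region's own crossing of its HD mean, on the new axis) are stored for
    querying. Anchoring an already anchored model yields an additional offset
    of ~0 (idempotence). Raises if the HD mean lies outside the trajectory's
    range.
    """
    if reference is None:
        reference = _steepest_crossing_region(model, hd_means)
    if reference not in hd_means:
        raise ValueError(f"no HD baseline mean for reference region {reference!r}")
    t_star = _crossing_time(model, reference, hd_means[reference])
    if t_star is None:
        raise ValueError(
            f"HD baseline mean {hd_means[reference]:.3f} for {reference!r} is outside "
            "the fitted trajectory range; cannot anchor"
        )
    anchored = dataclasses.replace(
        model,
        origin=model.origin + t_star,
        hd_baseline_means={k: float(v) for k, v in hd_means.items()},
    )
    anchored.anchor_times = {
        r: (None if (c := _crossing_time(anchored, r, hd_means[r])) is None else c)
        for r in anchored.regions
        if r in hd_means
    }
    return anchored


@dataclass
class ChangePointSummary:
    """Boxplot statistics of per-sample maximum-gradient times per region."""

    table: pd.DataFrame  # region, mean, median, q1, q3, min, max, magnitude, counts
    n_samples: int

    def ordering(self) -> list[str]:
        """Regions ordered from earliest to latest mean change time."""
        return list(self.table.sort_values("mean_time")["region"])


def change_points(
    samples,
    control_stats: dict | None = None,
    gradient_tol: float = 1e-4,
) -> ChangePointSummary:
    """Change-point times and magnitudes from posterior sample sets.

    ``samples`` maps region -> :class:`PosteriorSampleSet` (a single set is
    also accepted). For each sampled curve the change point is the grid time
    maximizing the discrete first difference (ties break to the earliest
    time); curves whose maximal gradient falls below ``gradient_tol`` per
    grid step, or that are gradient-ties across the whole grid (e.g. exactly
    linear), are flagged undefined and excluded, with the exclusion count
    reported. Magnitude per curve is ``max - min``, converted to percent of
    the control mean when ``control_stats`` provides per-region
    ``(hc_raw_mean, hc_resid_sd)``; otherwise it stays in standardized units.
    """
    if isinstance(samples, PosteriorSampleSet):
        samples = {samples.region: samples}
    rows = []
    n_samples = 0
    for region, ss in samples.items():
        grid = ss.grid
        if len(grid) < 3:
            raise ValueError("grid too coarse to resolve gradients (need >= 3 points)")
        diffs = np.diff(ss.curves, axis=1)  # (S, n-1)
        max_d = diffs.max(axis=1)
        tie = (diffs.max(axis=1) - diffs.min(axis=1)) <= 1e-9 * np.maximum(
            np.abs(max_d), 1e-12
        )
        defined = (max_d > gradient_tol) & ~tie
        n_excluded = int((~defined).sum())
        times = grid[np.argmax(diffs, axis=1)]  # left edge of steepest step
        times = times[defined]
        mags = ss.curves.max(axis=1) - ss.curves.min(axis=1)
        if control_stats is not None:
            mean_raw, sd_raw = control_stats[region]
            mags = mags * sd_raw / abs(mean_raw) * 100.0
        n_samples = max(n_samples, ss.curves.shape[0])
        rows.append(
            {
                "region": region,
                "mean_time": float(times.mean()) if times.size else np.nan,
                "median_time": float(np.median(times)) if times.size else np.nan,
                "q1_time": float(np.percentile(times, 25)) if times.size else np.nan,
                "q3_time": float(np.percentile(times, 75)) if times.size else np.nan,
                "min_time": float(times.min()) if times.size else np.nan,
                "max_time": float(times.max()) if times.size else np.nan,
                "mean_magnitude": float(mags.mean()),
                "n_used": int(defined.sum()),
                "n_excluded": n_excluded,
            }
        )
    return ChangePointSummary(table=pd.DataFrame(rows), n_samples=n_samples)


def _rms_curve_vs_line(times, values, curve_fn, domain, n_grid: int = 200) -> float:
    """RMS distance between a trajectory and the LS line through the data."""
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    ok = ~np.isnan(values)
    times, values = times[ok], values[ok]
    if len(np.unique(times)) < 3:
        raise ValueError("need at least 3 distinct staged times for a linear fit")
    slope, intercept = np.polyfit(times, values, 1)
    grid = np.linspace(domain[0], domain[1], n_grid)
    curve = np.asarray(curve_fn(grid), dtype=float)
    line = intercept + slope * grid
    return float(np.sqrt(np.mean((curve - line) ** 2)))


def nonlinearity_index(model: ProgressionModel, data, region: str) -> float:
    """Degree of trajectory nonlinearity for one region.

    Fits a least-squares line to the posterior-mean trajectory evaluated at
    the staged observation times (disease time from the fitted shifts), and
    returns the RMS difference between trajectory and line over the central
    staged-time range (2nd-98th percentile; outside it the trajectory is
    prior- rather than data-determined). Staging the line on the observed
    time distribution keeps the comparison weighted the way the data weight
    the fit, while comparing curve-to-line (rather than line-to-noisy-data)
    makes the index a pure curvature measure: exactly linear trajectories
    yield an index near zero, and the index is invariant to adding a
    constant to all values.
    """
    shift_by_id = dict(zip(model.subject_ids, model.shifts))
    df = data.data
    known = df["subject_id"].map(shift_by_id)
    if known.isna().any():
        df = df[~known.isna()]
        known = known.dropna()
    times = known.to_numpy(dtype=float) + df["time_offset"].to_numpy(dtype=float)
    ok = ~np.isnan(df[region].to_numpy(dtype=float))
    times = times[ok]
    if len(np.unique(times)) < 3:
        raise ValueError("need at least 3 distinct staged times for a linear fit")
    lo, hi = np.quantile(times, [0.02, 0.98])
    curve_at_obs = model.predict_mean(region, times)
    return _rms_curve_vs_line(
        times, curve_at_obs, lambda g: model.predict_mean(region, g), (lo, hi)
    )


def nonlinearity_table(model: ProgressionModel, data) -> pd.DataFrame:
    """Nonlinearity index for every region, ranked (1 = most nonlinear)."""
    idx = {r: nonlinearity_index(model, data, r) for r in model.regions}
    tab = pd.DataFrame(
        {"region": list(idx), "nonlinearity": [idx[r] for r in idx]}
    ).sort_values("nonlinearity", ascending=False, ignore_index=True)
    tab["rank"] = np.arange(1, len(tab) + 1)
    return tab


def refit_by_cag(
    data,
    cag_groups: dict,
    config: ModelConfig | None = None,
    hd_means: dict | None = None,
    min_subjects: int = 5,
):
    """Fit independent progression models on CAG-repeat strata.

    ``cag_groups`` maps stratum label -> iterable of CAG values. Strata
    smaller than ``min_subjects`` are skipped with a warning (small strata
    support only qualitative comparison); an empty stratum raises. When
    ``hd_means`` is given every stratum model is anchored by the same rule.
    Returns ``(models, sizes)`` dicts keyed by stratum label, with ``None``
    for skipped strata.
    """
    df = data.data
    per_subject_cag = df.groupby("subject_id")["cag"].first()
    models, sizes = {}, {}
    for label, cags in cag_groups.items():
        cagset = set(int(c) for c in cags)
        ids = [s for s, c in per_subject_cag.items() if not pd.isna(c) and int(c) in cagset]
        sizes[label] = len(ids)
        if len(ids) == 0:
            raise ValueError(f"CAG stratum {label!r} is empty")
        if len(ids) < min_subjects:
            warnings.warn(
                f"CAG stratum {label!r} has only {len(ids)} subjects (< {min_subjects}); "
                "fit skipped — qualitative use only",
                RuntimeWarning,
            )
            models[label] = None
            continue
        m = fit(data.subset(ids), config)
        if hd_means is not None:
            m = anchor_timeline(m, hd_means)
        models[label] = m
    return models, sizes
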