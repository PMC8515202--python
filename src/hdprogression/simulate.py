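"""Synthetic longitudinal cohorts of regional brain volumes in Huntington disease.

The generator emulates the study design the progression model assumes: three
diagnostic groups (healthy controls HC, premanifest gene carriers PreHD, and
manifest HD), each subject observed at three visits 12 months apart, with ten
regional volumes per visit. Gene-positive subjects sit at an unknown point of a
common disease timeline, encoded by a per-subject *time-shift* ``d_j`` (their
disease time at the baseline visit; ``t = 0`` is clinical onset). Group-level
trajectories are four-parameter logistics per region — region-specific change
times spread over roughly eleven years, magnitudes of 7–22 % of the control
mean, with the striatum (caudate, putamen, pallidum) earliest and largest and
the lateral ventricles the single region that *grows* with disease. On top of
the group curve each subject carries a Gaussian random intercept, i.i.d.
measurement noise, and linear covariate effects (age, sex, site, total
intracranial volume, field strength) that the preprocessing step must undo.

Ground-truth parameters (shifts, intercepts, curves) are returned alongside the
cohort table so that recovery of latent quantities can be tested exactly.
All randomness flows from a single seed through one ``numpy`` generator.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.special import expit

from .exceptions import ConfigurationError

__all__ = [
    "RegionSpec",
    "SubjectTruth",
    "GeneratorConfig",
    "DEFAULT_REGIONS",
    "logistic_curve",
    "generate_cohort",
    "assign_onsets",
    "censored_time_to_onset",
    "write_cohort",
    "read_cohort",
    "write_truths",
    "read_truths",
]


@dataclass(frozen=True)
class RegionSpec:
    """Ground-truth trajectory parameters for one regional volume.

    Parameters
    ----------
    name : str
        Region label (e.g. ``"caudate"``).
    direction : int
        +1 if the volume increases with disease (lateral ventricles),
        -1 if it atrophies.
    change_time : float
        Disease time (years relative to onset, ``t = 0``) at which the
        trajectory's gradient is maximal — the logistic midpoint.
    magnitude : float
        Total change over the timeline, as a fraction of the control mean
        (e.g. 0.20 for a 20 % change). Must be positive.
    steepness : float
        Logistic rate in 1/years. Must be positive.
    floor : float
        Pre-disease baseline offset, as a fraction of the control mean.
    mean_volume : float
        Healthy-control mean raw volume in mL (sets the raw scale).
    hc_cv : float
        Coefficient of variation of covariate-adjusted HC volumes; sets the
        raw-scale spread of the random intercept plus noise.
    """

    name: str
    direction: int
    change_time: float
    magnitude: float
    steepness: float
    floor: float = 0.0
    mean_volume: float = 10.0
    hc_cv: float = 0.05

    def __post_init__(self) -> None:
        if self.magnitude <= 0:
            raise ConfigurationError(f"magnitude must be > 0 for region {self.name!r}")
        if self.steepness <= 0:
            raise ConfigurationError(f"steepness must be > 0 for region {self.name!r}")
        if self.direction not in (-1, 1):
            raise ConfigurationError(f"direction must be +1 or -1 for region {self.name!r}")
        if self.mean_volume <= 0:
            raise ConfigurationError(f"mean_volume must be > 0 for region {self.name!r}")
        if self.hc_cv <= 0:
            raise ConfigurationError(f"hc_cv must be > 0 for region {self.name!r}")


#: Default ten-region fixture. Change times span ~[-7, +4] years with the
#: striatum earliest and largest; the lateral ventricles are the one enlarging
#: region with a late, sharp acceleration. Magnitudes span 7-22 % of control
#: mean. These are fixture defaults with the qualitative structure of HD
#: atrophy, not estimates of any real cohort.
DEFAULT_REGIONS: tuple[RegionSpec, ...] = (
    RegionSpec("caudate", -1, -6.0, 0.20, 0.70, mean_volume=7.6),
    RegionSpec("putamen", -1, -5.0, 0.22, 0.60, mean_volume=9.8),
    RegionSpec("pallidum", -1, -4.0, 0.18, 0.85, mean_volume=3.6),
    RegionSpec("temporal", -1, -2.5, 0.12, 0.60, mean_volume=110.0),
    RegionSpec("frontal", -1, -1.5, 0.10, 0.55, mean_volume=150.0),
    RegionSpec("occipital", -1, -0.5, 0.16, 0.60, mean_volume=62.0),
    RegionSpec("lateral_ventricles", +1, 1.0, 0.22, 1.10, mean_volume=28.0),
    RegionSpec("sensory_motor", -1, 2.5, 0.14, 0.70, mean_volume=58.0),
    RegionSpec("thalamus_proper", -1, 3.5, 0.09, 0.75, mean_volume=14.5),
    RegionSpec("parietal", -1, 5.0, 0.07, 0.80, mean_volume=100.0),
)


def logistic_curve(t, spec: RegionSpec):
    """Group-level trajectory value at disease time ``t`` (years from onset).

    Returns ``floor + direction * magnitude / (1 + exp(-steepness*(t - change_time)))``
    in units of fraction-of-control-mean. Total function: accepts scalars or
    arrays, never raises.
    """
    t = np.asarray(t, dtype=float)
    val = spec.floor + spec.direction * spec.magnitude * expit(
        spec.steepness * (t - spec.change_time)
    )
    return val if val.ndim else float(val)


@dataclass
class SubjectTruth:
    """Ground-truth latent state for one simulated subject."""

    subject_id: str
    group: str  # HC | PreHD | HD
    time_shift: float  # d_j: disease time (years from onset) at baseline visit
    random_intercept: float  # nu_j, generator-standardized units
    baseline_age: float
    sex: str
    site: str
    field_strength: str
    tiv: float  # total intracranial volume, mL
    cag: int | None = None  # gene-positive only
    onset_age: float | None = None  # present iff the subject converts in-window


@dataclass(frozen=True)
class GeneratorConfig:
    """Settings for :func:`generate_cohort`.

    Defaults mirror the scale of the larger HD cohort imaging studies: three
    annual visits, ~100/104/80 HC/PreHD/HD subjects, gene-positive time-shifts
    spread over an 11-year window with the manifest group drawn from the
    post-onset tail, measurement noise SD 0.3 and between-subject random
    intercept SD 0.95 in generator-standardized units. The intercept/noise
    split gives a test-retest ICC of ~0.91 — the reliability regime of
    longitudinally registered volumetry — and makes the HC residual SD ~1, so
    covariate adjustment passes generator units through unchanged.
    """

    n_per_group: dict = field(
        default_factory=lambda: {"HC": 100, "PreHD": 104, "HD": 80}
    )
    regions: tuple[RegionSpec, ...] = DEFAULT_REGIONS
    noise_sd: float = 0.3
    intercept_sd: float = 0.95
    # gene-positive time-shift (baseline disease time) ranges spanning ~11
    # years in total; manifest HD is drawn from the late half of the span
    # (clinical diagnosis is a noisy threshold, so the groups overlap a little
    # around onset)
    pre_shift_range: tuple[float, float] = (-7.0, 0.0)
    hd_shift_range: tuple[float, float] = (-1.5, 4.0)
    n_visits: int = 3
    visit_interval: float = 1.0  # years; 12-month spacing
    conversion_window: float = 2.0  # follow-up span used to label converters
    baseline_age_mean: float = 42.0
    baseline_age_sd: float = 8.0
    tiv_mean: float = 1450.0
    tiv_sd: float = 110.0
    sexes: tuple[str, ...] = ("F", "M")
    sites: tuple[str, ...] = ("siteA", "siteB", "siteC")
    field_strengths: tuple[str, ...] = ("3T",)
    cag_range: tuple[int, int] = (41, 50)
    # linear covariate effects injected into raw volumes, as fraction of the
    # region's control mean (so the preprocessing regression has work to undo)
    age_effect: float = -0.003  # per year, centred at age_center
    sex_effect: float = 0.04  # male offset
    site_effects: dict = field(
        default_factory=lambda: {"siteA": 0.0, "siteB": 0.01, "siteC": -0.015}
    )
    tiv_effect: float = 0.0004  # per mL, centred at tiv_center
    field_strength_effects: dict = field(default_factory=lambda: {"3T": 0.0})
    age_center: float = 45.0
    tiv_center: float = 1450.0
    missing_rate: float = 0.0  # optional missingness simulation, default off
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.regions:
            raise ConfigurationError("regions must be non-empty")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")
        if self.intercept_sd < 0:
            raise ConfigurationError("intercept_sd must be >= 0")
        if self.n_visits < 1:
            raise ConfigurationError("n_visits must be >= 1")
        if self.visit_interval <= 0:
            raise ConfigurationError("visit_interval must be > 0")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ConfigurationError("missing_rate must be in [0, 1)")
        counts = dict(self.n_per_group)
        if any(v < 0 for v in counts.values()):
            raise ConfigurationError("n_per_group counts must be >= 0")
        if sum(counts.values()) < 1:
            raise ConfigurationError("n_per_group must include at least one subject")
        names = [r.name for r in self.regions]
        if len(set(names)) != len(names):
            raise ConfigurationError("regions must have unique names")

    @property
    def region_names(self) -> list[str]:
        return [r.name for r in self.regions]


def _covariate_offset(cfg: GeneratorConfig, age, sex, site, fs, tiv):
    """Linear covariate effect as a fraction of the region's control mean."""
    return (
        cfg.age_effect * (age - cfg.age_center)
        + (cfg.sex_effect if sex == "M" else 0.0)
        + cfg.site_effects.get(site, 0.0)
        + cfg.tiv_effect * (tiv - cfg.tiv_center)
        + cfg.field_strength_effects.get(fs, 0.0)
    )


def generate_cohort(config: GeneratorConfig) -> tuple[pd.DataFrame, list[SubjectTruth]]:
    """Simulate a longitudinal cohort and return (cohort table, truths).

    The cohort table is long format, one row per subject-visit, with columns
    ``subject_id, group, visit_index, age, sex, site, field_strength, tiv,
    cag, onset_age`` followed by one raw-volume column per region (mL).

    Gene-positive raw values at disease time ``t = (age - baseline_age) + d_j``
    follow ``mean_volume * (1 + logistic_curve(t))`` plus the scaled random
    intercept, noise and covariate terms; HC subjects follow a flat curve at
    the floor. Identical config (including its seed) reproduces the table
    bit-for-bit.
    """
    rng = np.random.default_rng(config.seed)
    sigma_tot = math.hypot(config.noise_sd, config.intercept_sd)
    denom = sigma_tot if sigma_tot > 0 else 1.0

    truths: list[SubjectTruth] = []
    sid = 0
    for group in ("HC", "PreHD", "HD"):
        for _ in range(int(config.n_per_group.get(group, 0))):
            sid += 1
            subject_id = f"S{sid:04d}"
            if group == "HC":
                d = 0.0
                cag = None
            elif group == "PreHD":
                d = float(rng.uniform(*config.pre_shift_range))
                cag = int(rng.integers(config.cag_range[0], config.cag_range[1] + 1))
            else:
                d = float(rng.uniform(*config.hd_shift_range))
                cag = int(rng.integers(config.cag_range[0], config.cag_range[1] + 1))
            truths.append(
                SubjectTruth(
                    subject_id=subject_id,
                    group=group,
                    time_shift=d,
                    random_intercept=float(rng.normal(0.0, config.intercept_sd)),
                    baseline_age=float(
                        rng.normal(config.baseline_age_mean, config.baseline_age_sd)
                    ),
                    sex=str(rng.choice(config.sexes)),
                    site=str(rng.choice(config.sites)),
                    field_strength=str(rng.choice(config.field_strengths)),
                    tiv=float(rng.normal(config.tiv_mean, config.tiv_sd)),
                    cag=cag,
                )
            )

    truths = assign_onsets(truths, window=config.conversion_window)

    rows = []
    for tr in truths:
        gene_positive = tr.group != "HC"
        for v in range(config.n_visits):
            t_offset = v * config.visit_interval
            age = tr.baseline_age + t_offset
            row = {
                "subject_id": tr.subject_id,
                "group": tr.group,
                "visit_index": v,
                "age": age,
                "sex": tr.sex,
                "site": tr.site,
                "field_strength": tr.field_strength,
                "tiv": tr.tiv,
                "cag": tr.cag if tr.cag is not None else np.nan,
                "onset_age": tr.onset_age if tr.onset_age is not None else np.nan,
            }
            cov = _covariate_offset(
                config, age, tr.sex, tr.site, tr.field_strength, tr.tiv
            )
            for spec in config.regions:
                if gene_positive:
                    signal = logistic_curve(tr.time_shift + t_offset, spec)
                else:
                    signal = spec.floor
                scale = spec.mean_volume * spec.hc_cv / denom
                eps = float(rng.normal(0.0, config.noise_sd))
                raw = (
                    spec.mean_volume * (1.0 + signal + cov)
                    + scale * (tr.random_intercept + eps)
                )
                if config.missing_rate > 0 and rng.uniform() < config.missing_rate:
                    raw = np.nan
                row[spec.name] = raw
            rows.append(row)

    cohort = pd.DataFrame(rows)
    return cohort, truths


def assign_onsets(truths: Sequence[SubjectTruth], window: float = 2.0) -> list[SubjectTruth]:
    """Fill ``onset_age`` for subjects whose follow-up window reaches onset.

    Under the anchored-timeline convention (``t = 0`` is onset, baseline
    disease time is ``d_j``) the subject crosses onset at
    ``onset_age = baseline_age - d_j``. Converters are gene-positive subjects
    whose simulated window of ``window`` years reaches ``t >= 0``, i.e.
    ``d_j + window >= 0``; others keep ``onset_age = None``.
    """
    out = []
    for tr in truths:
        tr = dataclasses.replace(tr)
        if tr.group != "HC" and tr.time_shift + window >= 0:
            tr.onset_age = tr.baseline_age - tr.time_shift
        else:
            tr.onset_age = None
        out.append(tr)
    return out


def censored_time_to_onset(
    truth: SubjectTruth, visit_interval: float = 1.0, horizon: float = 15.0
) -> float | None:
    """Interval-censored observed time to onset, in years from baseline.

    Conversion is detected only at discrete visits every ``visit_interval``
    years: the recorded onset is the first visit at which the subject's disease
    time has reached 0, so the measured time is ``ceil(-d_j / interval)``
    visits — at or after the true crossing. Returns ``None`` for HC subjects
    and for gene carriers who do not convert within ``horizon`` years.
    """
    if truth.group == "HC":
        return None
    if truth.time_shift >= 0:
        return 0.0  # already manifest at the baseline visit
    k = math.ceil(-truth.time_shift / visit_interval - 1e-12)
    t_obs = k * visit_interval
    return t_obs if t_obs <= horizon else None


# ---------------------------------------------------------------------------
# Plain-text I/O


def write_cohort(cohort: pd.DataFrame, path) -> None:
    cohort.to_csv(path, index=False)


def read_cohort(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_truths(truths: Sequence[SubjectTruth], path) -> None:
    pd.DataFrame([dataclasses.asdict(t) for t in truths]).to_csv(path, index=False)


def read_truths(path) -> list[SubjectTruth]:
    df = pd.read_csv(path)
    out = []
    for rec in df.to_dict("records"):
        cag = rec.get("cag")
        onset = rec.get("onset_age")
        out.append(
            SubjectTruth(
                subject_id=str(rec["subject_id"]),
                group=str(rec["group"]),
                time_shift=float(rec["time_shift"]),
                random_intercept=float(rec["random_intercept"]),
                baseline_age=float(rec["baseline_age"]),
                sex=str(rec["sex"]),
                site=str(rec["site"]),
                field_strength=str(rec["field_strength"]),
                tiv=float(rec["tiv"]),
                cag=None if pd.isna(cag) else int(cag),
                onset_age=None if pd.isna(onset) else float(onset),
            )
        )
    return out


def config_to_yaml(config: GeneratorConfig, path) -> None:
    d = dataclasses.asdict(config)
    d["regions"] = [dataclasses.asdict(r) for r in config.regions]
    with open(path, "w") as fh:
        yaml.safe_dump(d, fh, sort_keys=False)


def config_from_yaml(path) -> GeneratorConfig:
    with open(path) as fh:
        d = yaml.safe_load(fh)
    d["regions"] = tuple(RegionSpec(**r) for r in d["regions"])
    for key in ("pre_shift_range", "hd_shift_range", "cag_range", "sexes", "sites",
                "field_strengths"):
        if key in d:
            d[key] = tuple(d[key])
    return GeneratorConfig(**d)
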