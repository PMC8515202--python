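"""Gaussian-process progression model with latent individual time-shifts.

The generative model for subject ``j``, region ``r`` at observation time ``t``
(years from that subject's baseline visit) is::

    y_jr(t) = f_r(t + d_j) + s_r * nu_j + eps,   eps ~ N(0, sigma_r^2)

where ``f_r`` is a monotone (nondecreasing) group-level trajectory shared by
all subjects, ``d_j`` is a per-subject time-shift placing the subject on a
common disease timeline (one latent disease time per subject, shared across
regions), and ``nu_j`` is a shared anatomical random intercept loading on
each region with the sign ``s_r`` that direction normalization applied to it
(a per-region intercept variant is available via the config).

``f_r`` is represented by a finite Gaussian (RBF) basis expansion with an
isotropic Gaussian prior on the weights — a fixed-feature approximation to a
GP — and a mean-field Gaussian variational posterior over the weights.
Monotonicity is enforced softly at a dense grid of virtual derivative points
by penalizing the *expected rectified negative derivative*
``E[max(0, -f'(u))]`` under the variational posterior (closed form for a
Gaussian). This pushes the posterior-mean derivative nonnegative and squeezes
the derivative's posterior spread wherever the trajectory is flat — so
plateaus stay admissible (unlike a hard positive-slope margin) while the mean
and almost all posterior samples are nondecreasing; sampled curves are
additionally projected onto the monotone cone when they violate the
tolerance.

Inference maximizes the evidence lower bound by block-coordinate ascent:
L-BFGS updates of each region's variational parameters, closed-form updates of
the intercepts and noise scales, and an exhaustive grid update of each
subject's shift (jointly with its intercepts). Every block update cannot
decrease the objective, so the recorded ELBO trace is nondecreasing.

Identifiability: the training shifts are constrained to mean zero by carrying
a global ``origin`` offset between the user-facing timeline and the internal
basis coordinate; the anchoring step (see :mod:`hdprogression.timeline`) later
re-points ``t = 0`` at the manifest-group baseline mean by moving the same
offset, which leaves the likelihood untouched.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field

import numpy as np
import yaml
from scipy.optimize import minimize
from scipy.special import erfc

from .exceptions import ConfigurationError, FitError
from .preprocess import AdjustedMatrix

__all__ = [
    "ModelConfig",
    "ProgressionModel",
    "PosteriorSampleSet",
    "fit",
    "predict_mean",
    "sample_posterior",
    "sample_all_regions",
    "cross_validate",
    "save_model",
    "load_model",
]

MONOTONE_TOL = 1e-3  # allowed violation per grid step, standardized units


@dataclass(frozen=True)
class ModelConfig:
    """Hyperparameters and optimizer settings for :func:`fit`."""

    n_basis: int = 14
    domain: tuple[float, float] = (-12.0, 8.0)  # basis-coordinate time bounds, years
    lengthscale: float | None = None  # RBF kernel lengthscale; default 1.2 * spacing
    n_constraint_points: int = 80  # virtual derivative points for monotonicity
    constraint_strength: float = 200.0  # weight on E[relu(-f')] at those points
    prior_scale: float = 3.0  # prior SD of basis weights, standardized units
    intercept_scale: float = 1.0  # prior SD of random intercepts (data z-scale)
    noise_floor: float = 1e-3
    n_outer: int = 30  # block-coordinate ascent iterations
    shift_grid_step: float = 0.1  # years, shift-update grid resolution
    max_lbfgs_iter: int = 60
    tol: float = 1e-8  # relative ELBO change for early stopping
    intercept_structure: str = "shared"  # "shared" nu_j or "per_region" nu_jr
    score_curve_variance: bool = True  # include var(f) in shift scoring
    marginalize_shifts: int = 4  # final EM sweeps with q(d) on the grid
    learn_intercept_scale: bool = False  # optional empirical-Bayes update of eta
    posterior_mean_shifts: bool = True  # final shifts = grid-posterior means
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_basis < 4:
            raise ConfigurationError("n_basis must be >= 4")
        if self.n_constraint_points < self.n_basis:
            raise ConfigurationError("n_constraint_points must be >= n_basis")
        if self.domain[1] <= self.domain[0]:
            raise ConfigurationError("domain must be an increasing interval")
        if self.intercept_structure not in ("shared", "per_region"):
            raise ConfigurationError(
                "intercept_structure must be 'shared' or 'per_region'"
            )

    @property
    def resolved_lengthscale(self) -> float:
        if self.lengthscale is not None:
            return float(self.lengthscale)
        spacing = (self.domain[1] - self.domain[0]) / (self.n_basis - 1)
        return 1.6 * spacing


class _RBFBasis:
    """Gaussian bumps on regular centres plus constant and linear trend terms.

    The trend columns make straight lines exactly representable (a decaying
    RBF span cannot hold a line near the domain edges), so nearly-linear
    trajectories do not get spuriously flattened or curved; the linear column
    is scaled by the domain half-width so all weights share one prior scale.
    """

    def __init__(self, domain, n_basis, lengthscale):
        self.centers = np.linspace(domain[0], domain[1], n_basis)
        self.ell = float(lengthscale)

    @property
    def _trend_scale(self):
        c = self.centers
        return (c[0] + c[-1]) / 2.0, max((c[-1] - c[0]) / 2.0, 1e-9)

    @property
    def n_features(self) -> int:
        return len(self.centers) + 2

    def design(self, t):
        t = np.asarray(t, dtype=float)
        c0, half = self._trend_scale
        rbf = np.exp(-((t[..., None] - self.centers) ** 2) / (2 * self.ell**2))
        ones = np.ones(t.shape + (1,))
        lin = ((t - c0) / half)[..., None]
        return np.concatenate([ones, lin, rbf], axis=-1)

    def ddesign(self, t):
        t = np.asarray(t, dtype=float)
        _, half = self._trend_scale
        diff = t[..., None] - self.centers
        drbf = np.exp(-(diff**2) / (2 * self.ell**2)) * (-diff / self.ell**2)
        zeros = np.zeros(t.shape + (1,))
        dlin = np.full(t.shape + (1,), 1.0 / half)
        return np.concatenate([zeros, dlin, drbf], axis=-1)


@dataclass
class PosteriorSampleSet:
    """Sampled trajectory curves for one region on a common time grid."""

    region: str
    grid: np.ndarray  # (n,) user-frame times, years
    curves: np.ndarray  # (S, n) sampled trajectories, standardized units
    seed: int
    n_projected: int = 0  # samples projected onto the monotone cone


@dataclass
class ProgressionModel:
    """Fitted posterior over group trajectories, shifts and intercepts.

    The user-facing timeline ``t`` maps to the internal basis coordinate
    ``u = t + origin``; subject ``j``'s estimated disease time at baseline is
    ``shifts[j] = d_internal[j] - origin``. Before anchoring, ``origin`` equals
    the mean internal shift so the training shifts average exactly zero.
    """

    config: ModelConfig
    regions: list[str]
    basis_centers: np.ndarray  # (M,)
    lengthscale: float
    weight_mean: np.ndarray  # (R, M) variational means
    weight_sd: np.ndarray  # (R, M) variational SDs (mean-field)
    sigma: np.ndarray  # (R,) noise SDs
    subject_ids: list[str]
    d_internal: np.ndarray  # (J,) shifts in basis coordinates
    nu: np.ndarray  # (J, R) random intercepts
    origin: float
    directions: dict = field(default_factory=dict)  # region -> +-1 flip applied
    support_internal: tuple = (0.0, 0.0)  # basis-coordinate span of observed times
    elbo_trace: list = field(default_factory=list)
    converged: bool = True
    anchor_times: dict = field(default_factory=dict)  # region -> own abnormality time
    hd_baseline_means: dict = field(default_factory=dict)

    # -- geometry -----------------------------------------------------------

    @property
    def basis(self) -> _RBFBasis:
        b = _RBFBasis.__new__(_RBFBasis)
        b.centers = self.basis_centers
        b.ell = self.lengthscale
        return b

    @property
    def shifts(self) -> np.ndarray:
        """Per-subject disease time at the baseline visit, user frame (years)."""
        return self.d_internal - self.origin

    @property
    def domain(self) -> tuple[float, float]:
        """User-frame time bounds of the fitted model."""
        lo, hi = self.config.domain
        return (lo - self.origin, hi - self.origin)

    @property
    def support(self) -> tuple[float, float]:
        """User-frame span actually covered by (shifted) observations.

        Outside this span the trajectory is prior-dominated; change-point and
        nonlinearity summaries should be evaluated within it.
        """
        lo, hi = self.support_internal
        return (lo - self.origin, hi - self.origin)

    def support_grid(self, step: float = 0.05) -> np.ndarray:
        """Uniform grid over the data-supported span (default 0.05-year step)."""
        lo, hi = self.support
        n = int(np.floor((hi - lo) / step + 1e-9)) + 1
        return lo + step * np.arange(n)

    def _check_domain(self, t):
        lo, hi = self.domain
        t = np.asarray(t, dtype=float)
        pad = 1e-9
        if t.size and (t.min() < lo - pad or t.max() > hi + pad):
            raise ValueError(
                f"time grid [{t.min():.3f}, {t.max():.3f}] outside fitted domain "
                f"[{lo:.3f}, {hi:.3f}]"
            )
        return t

    def _region_index(self, region: str) -> int:
        try:
            return self.regions.index(region)
        except ValueError:
            raise KeyError(f"unknown region {region!r}; have {self.regions}") from None

    # -- prediction ---------------------------------------------------------

    def predict_mean(self, region: str, t_grid) -> np.ndarray:
        """Posterior-mean trajectory of ``region`` on user-frame times."""
        r = self._region_index(region)
        t = self._check_domain(t_grid)
        return self.basis.design(t + self.origin) @ self.weight_mean[r]

    def predict_sd(self, region: str, t_grid) -> np.ndarray:
        """Pointwise posterior SD of the trajectory (mean-field)."""
        r = self._region_index(region)
        t = self._check_domain(t_grid)
        Phi = self.basis.design(t + self.origin)
        return np.sqrt((Phi**2) @ (self.weight_sd[r] ** 2))

    def predict_all(self, t_grid) -> np.ndarray:
        """(n_times, R) posterior means for all regions."""
        t = self._check_domain(t_grid)
        return self.basis.design(t + self.origin) @ self.weight_mean.T

    def sample_posterior(self, region, t_grid, n_samples, seed) -> PosteriorSampleSet:
        return sample_posterior(self, region, t_grid, n_samples, seed)

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "config": dataclasses.asdict(self.config),
            "regions": list(self.regions),
            "basis_centers": self.basis_centers.tolist(),
            "lengthscale": float(self.lengthscale),
            "weight_mean": self.weight_mean.tolist(),
            "weight_sd": self.weight_sd.tolist(),
            "sigma": self.sigma.tolist(),
            "subject_ids": list(self.subject_ids),
            "d_internal": self.d_internal.tolist(),
            "nu": self.nu.tolist(),
            "origin": float(self.origin),
            "directions": {k: int(v) for k, v in self.directions.items()},
            "support_internal": [float(v) for v in self.support_internal],
            "elbo_trace": [float(v) for v in self.elbo_trace],
            "converged": bool(self.converged),
            "anchor_times": {k: (None if v is None else float(v))
                             for k, v in self.anchor_times.items()},
            "hd_baseline_means": {k: float(v) for k, v in self.hd_baseline_means.items()},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ProgressionModel":
        cfg = d["config"].copy()
        cfg["domain"] = tuple(cfg["domain"])
        return cls(
            config=ModelConfig(**cfg),
            regions=list(d["regions"]),
            basis_centers=np.asarray(d["basis_centers"], dtype=float),
            lengthscale=float(d["lengthscale"]),
            weight_mean=np.asarray(d["weight_mean"], dtype=float),
            weight_sd=np.asarray(d["weight_sd"], dtype=float),
            sigma=np.asarray(d["sigma"], dtype=float),
            subject_ids=list(d["subject_ids"]),
            d_internal=np.asarray(d["d_internal"], dtype=float),
            nu=np.asarray(d["nu"], dtype=float),
            origin=float(d["origin"]),
            directions=dict(d.get("directions", {})),
            support_internal=tuple(d.get("support_internal", (0.0, 0.0))),
            elbo_trace=list(d["elbo_trace"]),
            converged=bool(d["converged"]),
            anchor_times=dict(d.get("anchor_times", {})),
            hd_baseline_means=dict(d.get("hd_baseline_means", {})),
        )


def save_model(model: ProgressionModel, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(model.to_dict(), fh, sort_keys=False)


def load_model(path) -> ProgressionModel:
    with open(path) as fh:
        return ProgressionModel.from_dict(yaml.safe_load(fh))


# ---------------------------------------------------------------------------
# Fitting internals


def _extract_arrays(data: AdjustedMatrix):
    """Long table -> (ids, times (J,V), Y (J,V,R)) with NaN padding."""
    df = data.data
    ids = list(dict.fromkeys(df["subject_id"]))
    vmax = int(df.groupby("subject_id").size().max())
    J, R = len(ids), len(data.regions)
    times = np.full((J, vmax), np.nan)
    Y = np.full((J, vmax, R), np.nan)
    idx = {s: j for j, s in enumerate(ids)}
    counters = {s: 0 for s in ids}
    vals = df[data.regions].to_numpy(dtype=float)
    toff = df["time_offset"].to_numpy(dtype=float)
    sids = df["subject_id"].to_numpy()
    for n in range(len(df)):
        j = idx[sids[n]]
        v = counters[sids[n]]
        counters[sids[n]] = v + 1
        times[j, v] = toff[n]
        Y[j, v] = vals[n]
    return ids, times, Y


_SQRT_2PI = float(np.sqrt(2.0 * np.pi))


def _expected_neg_gradient(mu, sd):
    """E[max(0, -G)] for G ~ N(mu, sd^2): the expected monotonicity violation."""
    alpha = mu / sd
    phi = np.exp(-0.5 * alpha**2) / _SQRT_2PI
    return sd * phi - mu * 0.5 * erfc(alpha / np.sqrt(2.0))


def fit(
    data: AdjustedMatrix,
    config: ModelConfig | None = None,
    initial_shifts: dict | None = None,
) -> ProgressionModel:
    """Fit the progression model to an adjusted biomarker matrix.

    Maximizes the evidence lower bound jointly over the variational posterior
    of each region's trajectory weights, the per-subject shifts and
    intercepts, and the noise scales. Deterministic given data + config (the
    config seed fixes any tie-breaking); emits a warning with the final ELBO
    trace if the relative objective change has not levelled off within the
    iteration budget.
    """
    cfg = config or ModelConfig()
    ids, times, Y = _extract_arrays(data)
    J, V, R = Y.shape
    if J < 2:
        raise FitError("need at least 2 subjects")
    n_visits = np.sum(~np.isnan(times), axis=1)
    if np.max(n_visits) < 2:
        raise FitError(
            "all subjects have a single visit: time-shifts are identified from "
            "within-subject change and cannot be estimated"
        )

    basis = _RBFBasis(cfg.domain, cfg.n_basis, cfg.resolved_lengthscale)
    M = basis.n_features
    alpha2 = cfg.prior_scale**2
    hp = {"eta2": cfg.intercept_scale**2}  # mutable: empirical-Bayes update
    u_c = np.linspace(cfg.domain[0], cfg.domain[1], cfg.n_constraint_points)
    dPhi_c = basis.ddesign(u_c)

    mask = ~np.isnan(Y)  # (J,V,R)
    Y0 = np.where(mask, Y, 0.0)
    tmask = ~np.isnan(times)
    t0 = np.where(tmask, times, 0.0)
    vspan = np.nanmax(times)
    # direction-normalization flips each region's sign, so a shared anatomical
    # size intercept loads onto region r with the region's direction sign
    sg = np.array([float(data.directions.get(r, 1)) for r in data.regions])

    # --- initialization ---------------------------------------------------
    # severity ordering: standardized subject mean level across regions/visits
    sev = np.array([np.nanmean(Y[j][mask[j].any(axis=1)]) if mask[j].any() else 0.0
                    for j in range(J)])
    sev_sd = sev.std()
    z = (sev - sev.mean()) / (sev_sd if sev_sd > 0 else 1.0)
    lo_d, hi_d = cfg.domain[0] + 0.5, cfg.domain[1] - 0.5 - vspan
    if initial_shifts is not None:
        d = np.clip(np.array([initial_shifts[s] for s in ids]), lo_d, hi_d)
    else:
        d = np.clip(z * 3.3, lo_d, hi_d)

    # weights: least-squares ramp from low to high data quantiles over domain
    grid0 = np.linspace(cfg.domain[0], cfg.domain[1], 200)
    Phi0 = basis.design(grid0)
    m_w = np.zeros((R, M))
    s_w = np.full((R, M), 0.05)
    for r in range(R):
        yr = Y[..., r][mask[..., r]]
        qlo, qhi = np.quantile(yr, [0.05, 0.95]) if yr.size else (0.0, 1.0)
        ramp = qlo + (qhi - qlo) * (grid0 - grid0[0]) / (grid0[-1] - grid0[0])
        m_w[r], *_ = np.linalg.lstsq(
            Phi0.T @ Phi0 + 1e-3 * np.eye(M), Phi0.T @ ramp, rcond=None
        )
    sigma2 = np.full(R, 0.5)
    nu = np.zeros((J, R))

    cand = np.arange(lo_d, hi_d + 1e-9, cfg.shift_grid_step)

    def region_nll_terms(r, d_vec, nu_r):
        """Expected NLL pieces for one region at given shifts/intercepts."""
        tau = t0 + d_vec[:, None]
        Phi = basis.design(tau.ravel()).reshape(J, V, M)
        mu = Phi @ m_w[r]
        var = (Phi**2) @ (s_w[r] ** 2)
        e = np.where(mask[..., r], Y0[..., r] - mu - nu_r[:, None], 0.0)
        var = np.where(mask[..., r], var, 0.0)
        return e, var

    def total_elbo():
        total = 0.0
        for r in range(R):
            e, var = region_nll_terms(r, d, nu[:, r])
            n_r = mask[..., r].sum()
            total -= ((e**2).sum() + var.sum()) / (2 * sigma2[r])
            total -= 0.5 * n_r * np.log(2 * np.pi * sigma2[r])
            s2 = s_w[r] ** 2
            total -= 0.5 * np.sum(
                s2 / alpha2 + m_w[r] ** 2 / alpha2 - 1.0 - np.log(s2 / alpha2)
            )
            mu_d = dPhi_c @ m_w[r]
            sd_d = np.sqrt((dPhi_c**2) @ s2 + 1e-12)
            total -= cfg.constraint_strength * _expected_neg_gradient(mu_d, sd_d).sum()
        if cfg.intercept_structure == "shared":
            total -= (nu[:, 0] ** 2).sum() / (2 * hp["eta2"])
            total -= 0.5 * J * np.log(2 * np.pi * hp["eta2"])
        else:
            total -= (nu**2).sum() / (2 * hp["eta2"])
            total -= 0.5 * nu.size * np.log(2 * np.pi * hp["eta2"])
        return float(total)

    def update_region(r):
        tau = t0 + d[:, None]
        obs = mask[..., r]
        Phi = basis.design(tau[tmask])  # rows align with tmask flattening
        # align observation mask within tmask rows
        obs_flat = obs[tmask]
        Phi = Phi[obs_flat]
        y = (Y0[..., r] - nu[:, r][:, None])[obs]
        _update_region_stats(r, Phi.T @ Phi, Phi.T @ y, float(y @ y),
                             (Phi**2).sum(axis=0))

    def _update_region_stats(r, Hq, gq, yy, PhiSq):
        """Penalized variational update of one region's weights given the
        (possibly expectation-weighted) quadratic sufficient statistics."""
        x0 = np.concatenate([m_w[r], np.log(s_w[r])])

        def fg(x):
            m, rho = x[:M], x[M:]
            s2 = np.exp(2 * rho)
            val = (m @ Hq @ m - 2 * gq @ m + yy + PhiSq @ s2) / (2 * sigma2[r])
            gm = (Hq @ m - gq) / sigma2[r]
            grho = (PhiSq * s2) / sigma2[r]
            val += 0.5 * np.sum(s2 / alpha2 + m**2 / alpha2 - 1.0 - 2 * rho
                                + np.log(alpha2))
            gm += m / alpha2
            grho += s2 / alpha2 - 1.0
            mu_d = dPhi_c @ m
            sd_d = np.sqrt((dPhi_c**2) @ s2 + 1e-12)
            alpha = mu_d / sd_d
            phi = np.exp(-0.5 * alpha**2) / _SQRT_2PI
            Phi_neg = 0.5 * erfc(alpha / np.sqrt(2.0))  # P(f' < 0)
            val += cfg.constraint_strength * float(
                (sd_d * phi - mu_d * Phi_neg).sum()
            )
            gm -= cfg.constraint_strength * (dPhi_c.T @ Phi_neg)
            grho += cfg.constraint_strength * ((phi / sd_d) @ (dPhi_c**2)) * s2
            return val, np.concatenate([gm, grho])

        f0, _ = fg(x0)
        res = minimize(fg, x0, jac=True, method="L-BFGS-B",
                       options={"maxiter": cfg.max_lbfgs_iter})
        if np.isfinite(res.fun) and res.fun <= f0:
            m_w[r] = res.x[:M]
            s_w[r] = np.exp(res.x[M:])

    def update_nu_sigma():
        tau = t0 + d[:, None]
        Phi = basis.design(tau.ravel()).reshape(J, V, M)
        e0s, vars_ = [], []
        for r in range(R):
            mu = Phi @ m_w[r]
            vars_.append(np.where(mask[..., r], (Phi**2) @ (s_w[r] ** 2), 0.0))
            e0s.append(np.where(mask[..., r], Y0[..., r] - mu, 0.0))
        if cfg.intercept_structure == "shared":
            # one scalar intercept per subject with signed loadings,
            # precision-weighted across regions
            A = sum(sg[r] * e0s[r].sum(axis=1) / sigma2[r] for r in range(R))
            B = sum(mask[..., r].sum(axis=1) / sigma2[r] for r in range(R))
            nu_shared = A / np.maximum(B + 1.0 / hp["eta2"], 1e-12)
            nu[:] = nu_shared[:, None] * sg[None, :]
        else:
            for r in range(R):
                n_jr = mask[..., r].sum(axis=1)
                lam = sigma2[r] / hp["eta2"]
                nu[:, r] = e0s[r].sum(axis=1) / np.maximum(n_jr + lam, 1e-12)
        for r in range(R):
            e = np.where(mask[..., r], e0s[r] - nu[:, r][:, None], 0.0)
            n_r = max(mask[..., r].sum(), 1)
            sigma2[r] = max(((e**2).sum() + vars_[r].sum()) / n_r, cfg.noise_floor**2)
        if cfg.learn_intercept_scale:
            # nu[:, r] = sg_r * nu_shared, so nu**2 is structure-agnostic here
            if cfg.intercept_structure == "shared":
                hp["eta2"] = max(float(np.mean(nu[:, 0] ** 2)), 1e-4)
            else:
                hp["eta2"] = max(float(np.mean(nu**2)), 1e-4)

    def regauge_intercepts():
        # a constant splits between the intercepts' mean and the basis
        # constant term; coordinate ascent equilibrates that split slowly, so
        # move the mean into the constant weight whenever it raises the ELBO
        # (likelihood is invariant; only the two prior terms change)
        if cfg.intercept_structure == "shared":
            nu_sh = nu[:, 0] * sg[0]
            c = float(nu_sh.mean())
            d_prior = (
                (np.sum(nu_sh**2) - np.sum((nu_sh - c) ** 2)) / (2 * hp["eta2"])
                - np.sum((m_w[:, 0] + sg * c) ** 2 - m_w[:, 0] ** 2) / (2 * alpha2)
            )
            if d_prior > 0:
                m_w[:, 0] += sg * c
                nu[:] = (nu_sh - c)[:, None] * sg[None, :]
        else:
            for r in range(R):
                c = float(nu[:, r].mean())
                d_prior = (
                    (np.sum(nu[:, r] ** 2) - np.sum((nu[:, r] - c) ** 2))
                    / (2 * hp["eta2"])
                    - ((m_w[r, 0] + c) ** 2 - m_w[r, 0] ** 2) / (2 * alpha2)
                )
                if d_prior > 0:
                    m_w[r, 0] += c
                    nu[:, r] -= c

    def shift_scores(include_current: bool):
        """Joint (d, nu) scores on the candidate grid; nu profiled out."""
        C = len(cand)
        ncol = C + 1 if include_current else C
        score = np.zeros((J, ncol))
        best_nu = np.zeros((J, ncol, R))
        cand_all = np.broadcast_to(cand, (J, C))
        if include_current:
            cand_all = np.concatenate([cand_all, d[:, None]], axis=1)
        tau = t0[:, None, :] + cand_all[:, :, None]  # (J, ncol, V)
        Phi = basis.design(tau.reshape(-1)).reshape(J, ncol, V, M)
        shared = cfg.intercept_structure == "shared"
        A = np.zeros((J, ncol)) if shared else None  # sum_r S1_r / sigma_r^2
        B = np.zeros(J) if shared else None  # sum_r n_jr / sigma_r^2
        for r in range(R):
            n_jr = mask[..., r].sum(axis=1)  # (J,)
            mu = Phi @ m_w[r]
            if cfg.score_curve_variance:
                var = np.where(mask[..., r][:, None, :], (Phi**2) @ (s_w[r] ** 2), 0.0)
            else:
                var = np.zeros_like(mu)
            e0 = np.where(mask[..., r][:, None, :], Y0[..., r][:, None, :] - mu, 0.0)
            S1 = e0.sum(axis=2)  # (J, ncol)
            SS = (e0**2).sum(axis=2)
            if shared:
                score += (SS + var.sum(axis=2)) / (2 * sigma2[r])
                A += sg[r] * S1 / sigma2[r]
                B += n_jr / sigma2[r]
            else:
                lam = sigma2[r] / hp["eta2"]
                nopt = S1 / np.maximum(n_jr[:, None] + lam, 1e-12)
                sse = SS - 2 * nopt * S1 + n_jr[:, None] * nopt**2
                score += (sse + var.sum(axis=2)) / (2 * sigma2[r]) \
                    + nopt**2 / (2 * hp["eta2"])
                best_nu[..., r] = nopt
        if shared:
            # score(nu) = base - A*nu + (B + 1/eta2)*nu^2/2, minimized at
            # nu* = A/(B + 1/eta2) with reduction -A^2 / (2*(B + 1/eta2))
            prec = np.maximum(B + 1.0 / hp["eta2"], 1e-12)[:, None]
            score -= (A**2) / (2 * prec)
            best_nu[:] = (A / prec)[..., None] * sg[None, None, :]
        return cand_all, score, best_nu

    def update_shifts():
        # exhaustive grid argmin (plus each subject's current shift) with
        # intercepts re-optimized per candidate; joint (d_j, nu_j) block update
        cand_all, score, best_nu = shift_scores(include_current=True)
        pick = np.argmin(score, axis=1)
        d[:] = cand_all[np.arange(J), pick]
        nu[:] = best_nu[np.arange(J), pick]

    def posterior_mean_shifts():
        # final E-step: per-subject posterior over the shift grid (flat prior
        # over the domain); shifts become posterior means, intercepts follow
        _, score, _ = shift_scores(include_current=False)
        w = np.exp(-(score - score.min(axis=1, keepdims=True)))
        w /= w.sum(axis=1, keepdims=True)
        d[:] = w @ cand

    def snapshot():
        return (d.copy(), m_w.copy(), s_w.copy(), nu.copy(), sigma2.copy(),
                dict(hp))

    def restore(state):
        d[:], m_w[:], s_w[:], nu[:], sigma2[:] = (
            state[0], state[1], state[2], state[3], state[4]
        )
        hp.clear()
        hp.update(state[5])

    def refit_given_shifts():
        for r in range(R):
            update_region(r)
        update_nu_sigma()
        regauge_intercepts()

    def try_timescale_rescale():
        # the alternation corrects a global error in the shift dispersion only
        # geometrically slowly (curve steepness and shift spread trade off
        # almost freely), so line-search the scale directly: stretch or shrink
        # the shifts about their mean, refit everything else, keep the best
        best_state = snapshot()
        best_elbo = total_elbo()
        center = d.mean()
        for s in (0.75, 0.85, 1.15, 1.3):
            restore(best_state)
            d[:] = np.clip(center + s * (d - center), lo_d, hi_d)
            refit_given_shifts()
            update_shifts()
            update_nu_sigma()
            regauge_intercepts()
            e = total_elbo()
            if e > best_elbo:
                best_elbo = e
                best_state = snapshot()
        restore(best_state)

    # --- block-coordinate ascent -----------------------------------------
    elbo_trace = []
    converged = False
    for it in range(cfg.n_outer):
        for r in range(R):
            update_region(r)
        update_nu_sigma()
        regauge_intercepts()
        update_shifts()
        update_nu_sigma()
        regauge_intercepts()
        if it in (2, 6, 12, 20):
            try_timescale_rescale()
        elbo_trace.append(total_elbo())
        if it >= 2:
            prev, cur = elbo_trace[-2], elbo_trace[-1]
            if abs(cur - prev) < cfg.tol * (abs(cur) + 1.0):
                converged = True
                break
    if not converged and len(elbo_trace) >= 2:
        rel = abs(elbo_trace[-1] - elbo_trace[-2]) / (abs(elbo_trace[-1]) + 1.0)
        if rel > 1e-3:
            warnings.warn(
                "progression-model fit did not converge within the iteration "
                f"budget (final relative ELBO change {rel:.2e}); ELBO trace tail: "
                f"{[round(v, 3) for v in elbo_trace[-5:]]}",
                RuntimeWarning,
            )
        else:  # levelled off to within the coordinate-ascent tail tolerance
            converged = True

    def em_refine(n_sweeps):
        # Final refinement with the shift treated as a latent variable on the
        # candidate grid: E-step computes q(d_j) (intercept profiled), M-step
        # re-solves each region's penalized variational update under the
        # expected design. Fitting curves through *point* shifts attenuates
        # their slope (staging error blurs the time axis); marginalizing
        # removes that bias. Shared-intercept structure only.
        q = None
        nu_c = None
        for _ in range(n_sweeps):
            tau = t0[:, None, :] + cand[None, :, None]  # (J, C, V)
            Phi = basis.design(tau.reshape(-1)).reshape(J, len(cand), V, M)
            score = np.zeros((J, len(cand)))
            A = np.zeros((J, len(cand)))
            B = np.zeros(J)
            mus = []
            for r in range(R):
                mu = Phi @ m_w[r]
                mus.append(mu)
                e0 = np.where(mask[..., r][:, None, :],
                              Y0[..., r][:, None, :] - mu, 0.0)
                score += (e0**2).sum(axis=2) / (2 * sigma2[r])
                A += sg[r] * e0.sum(axis=2) / sigma2[r]
                B += mask[..., r].sum(axis=1) / sigma2[r]
            prec = np.maximum(B[:, None] + 1.0 / hp["eta2"], 1e-12)
            score -= A**2 / (2 * prec)
            q = np.exp(-(score - score.min(axis=1, keepdims=True)))
            q /= q.sum(axis=1, keepdims=True)
            nu_c = A / prec  # profiled shared intercept per candidate
            for r in range(R):
                obs = mask[..., r][:, None, :]  # (J,1,V)
                w = np.where(obs, q[:, :, None], 0.0).reshape(-1)  # (J*C*V,)
                Pf = Phi.reshape(-1, M)
                ye = np.where(obs, Y0[..., r][:, None, :] - sg[r] * nu_c[:, :, None],
                              0.0).reshape(-1)
                Pw = Pf * w[:, None]
                Hq = Pw.T @ Pf
                gq = Pw.T @ ye
                yy = float((w * ye**2).sum())
                PhiSq = (Pw * Pf).sum(axis=0)
                _update_region_stats(r, Hq, gq, yy, PhiSq)
                resid = ye - Pf @ m_w[r]
                n_r = max(mask[..., r].sum(), 1)
                sigma2[r] = max(
                    (float(w @ resid**2) + PhiSq @ (s_w[r] ** 2)) / n_r,
                    cfg.noise_floor**2,
                )
        d[:] = q @ cand  # posterior-mean shifts under the final q
        if cfg.intercept_structure == "shared":
            nu[:] = ((q * nu_c).sum(axis=1))[:, None] * sg[None, :]

    if cfg.marginalize_shifts > 0 and cfg.intercept_structure == "shared":
        em_refine(cfg.marginalize_shifts)
    elif cfg.posterior_mean_shifts:
        posterior_mean_shifts()
        update_nu_sigma()

    origin = float(d.mean())  # zero-mean gauge for training shifts
    # data-supported span: central 98 % of observed (shifted) times, so a
    # single extreme subject does not stretch it into prior-dominated territory
    tau_obs = np.quantile((t0 + d[:, None])[tmask], [0.01, 0.99])
    return ProgressionModel(
        config=cfg,
        regions=list(data.regions),
        basis_centers=basis.centers,
        lengthscale=basis.ell,
        weight_mean=m_w,
        weight_sd=s_w,
        sigma=np.sqrt(sigma2),
        subject_ids=ids,
        d_internal=d,
        nu=nu,
        origin=origin,
        directions={r: int(data.directions.get(r, 1)) for r in data.regions},
        support_internal=(float(tau_obs[0]), float(tau_obs[1])),
        elbo_trace=elbo_trace,
        converged=converged,
    )


# ---------------------------------------------------------------------------
# Posterior prediction and sampling


def predict_mean(model: ProgressionModel, region: str, t_grid) -> np.ndarray:
    """Posterior-mean trajectory on a user-frame time grid (module-level alias)."""
    return model.predict_mean(region, t_grid)


def sample_posterior(
    model: ProgressionModel, region: str, t_grid, n_samples: int, seed: int
) -> PosteriorSampleSet:
    """Draw ``n_samples`` trajectory curves from the variational posterior.

    Curves violating the monotonicity tolerance (1e-3 standardized units per
    grid step) are projected onto the nondecreasing cone by isotonic
    regression; the number of projected curves is recorded. Seeded and
    reproducible.
    """
    from scipy.optimize import isotonic_regression

    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    r = model._region_index(region)
    t = model._check_domain(t_grid)
    Phi = model.basis.design(t + model.origin)
    rng = np.random.default_rng(seed)
    W = model.weight_mean[r] + rng.standard_normal(
        (n_samples, model.weight_mean.shape[1])
    ) * model.weight_sd[r]
    curves = W @ Phi.T
    n_projected = 0
    for i in range(n_samples):
        if np.min(np.diff(curves[i]), initial=0.0) < -MONOTONE_TOL:
            curves[i] = isotonic_regression(curves[i]).x
            n_projected += 1
    return PosteriorSampleSet(
        region=region, grid=t, curves=curves, seed=seed, n_projected=n_projected
    )


def sample_all_regions(
    model: ProgressionModel, t_grid, n_samples: int, seed: int
) -> dict[str, PosteriorSampleSet]:
    """Posterior sample sets for every region (distinct derived sub-seeds)."""
    return {
        region: sample_posterior(model, region, t_grid, n_samples, (seed + 7 * i) % (2**31))
        for i, region in enumerate(model.regions)
    }


# ---------------------------------------------------------------------------
# Cross-validation


@dataclass
class CVResult:
    rho: float  # mean held-out residual / full-fit residual
    full_residual: float
    fold_residuals: list


def _rms_residual(model: ProgressionModel, data: AdjustedMatrix, shifts, nus) -> float:
    """RMS residual of observations around the shifted trajectories."""
    ids, times, Y = _extract_arrays(data)
    mask = ~np.isnan(Y)
    total, count = 0.0, 0
    for j, sid in enumerate(ids):
        tj = times[j][~np.isnan(times[j])]
        mu = model.predict_all(tj + shifts[sid])  # (V, R)
        e = Y[j, : len(tj)] - mu - nus[sid]
        e = e[mask[j, : len(tj)]]
        total += float((e**2).sum())
        count += e.size
    return np.sqrt(total / max(count, 1))


def _stage_and_intercepts(model: ProgressionModel, data: AdjustedMatrix, grid_step=0.05):
    """Stage each subject (rigid slide of its visit series) and estimate its
    intercepts, mirroring the training-time estimators."""
    from .staging import stage_series

    eta2 = model.config.intercept_scale**2
    shared = model.config.intercept_structure == "shared"
    sg = np.array([float(model.directions.get(r, 1)) for r in data.regions])
    shifts, nus = {}, {}
    df = data.data
    for sid, g in df.groupby("subject_id", sort=False):
        offs = g["time_offset"].to_numpy(dtype=float)
        vals = g[data.regions].to_numpy(dtype=float)
        est = stage_series(
            model, offs, vals, grid_step=grid_step,
            intercept="shared" if shared else "none",
            intercept_scale=model.config.intercept_scale,
        )
        shifts[sid] = est.stage
        mu = model.predict_all(offs + est.stage)
        e0 = vals - mu
        if shared:
            ok = ~np.isnan(e0)
            w = 1.0 / model.sigma**2
            A = np.nansum(e0 * (sg * w)[None, :])
            B = float((ok * w[None, :]).sum())
            nus[sid] = sg * (A / max(B + 1.0 / eta2, 1e-12))
        else:
            nu = np.zeros(len(data.regions))
            for r in range(len(data.regions)):
                ok = ~np.isnan(e0[:, r])
                lam = model.sigma[r] ** 2 / eta2
                nu[r] = e0[ok, r].sum() / max(ok.sum() + lam, 1e-12)
            nus[sid] = nu
    return shifts, nus


def cross_validate(
    data: AdjustedMatrix,
    config: ModelConfig | None = None,
    k: int = 10,
    folds: list | None = None,
) -> CVResult:
    """Subject-level k-fold cross-validation residual ratio.

    rho = (mean held-out RMS residual across folds) / (RMS residual of the
    full-data fit); held-out subjects are staged with the staging rule and
    given shrunk intercepts before their residual is measured. Values near 1
    indicate stable hyperparameters. Folds always split subjects, never
    visits; pass ``folds`` (lists of subject ids) to control the split.
    """
    cfg = config or ModelConfig()
    subjects = list(dict.fromkeys(data.data["subject_id"]))
    if folds is not None:
        folds = [[subjects.index(s) for s in f] for f in folds]
        k = len(folds)
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > len(subjects):
        raise ValueError(f"k={k} exceeds the number of subjects ({len(subjects)})")
    if folds is None:
        rng = np.random.default_rng(cfg.seed)
        order = list(rng.permutation(len(subjects)))
        folds = [sorted(order[i::k]) for i in range(k)]
    if any(len(f) == 0 for f in folds):
        raise ValueError("empty cross-validation fold")

    full_model = fit(data, cfg)
    full_shifts = {s: sh for s, sh in zip(full_model.subject_ids, full_model.shifts)}
    full_nus = {s: full_model.nu[j] for j, s in enumerate(full_model.subject_ids)}
    full_res = _rms_residual(full_model, data, full_shifts, full_nus)

    fold_res = []
    for f in folds:
        test_ids = {subjects[i] for i in f}
        train = data.subset([s for s in subjects if s not in test_ids])
        test = data.subset(sorted(test_ids))
        m = fit(train, cfg)
        shifts, nus = _stage_and_intercepts(m, test)
        fold_res.append(_rms_residual(m, test, shifts, nus))
    rho = float(np.mean(fold_res) / full_res)
    return CVResult(rho=rho, full_residual=float(full_res), fold_residuals=fold_res)
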