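"""Covariate adjustment and standardization of raw regional volumes.

Raw volumes are regressed on nuisance covariates (age, sex, site, total
intracranial volume, optionally field strength) using ordinary least squares
fitted on the healthy-control group only; residuals are z-scored against the
HC residual distribution and direction-normalized so that every region's
expected disease trend is increasing. The resulting standardized values are
what the progression model consumes. The full inverse transform (coefficients,
HC statistics, direction map) is retained so results can be reported on the
raw scale.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .exceptions import ConfigurationError

__all__ = [
    "AdjustmentModel",
    "AdjustedMatrix",
    "fit_adjustment",
    "apply_adjustment",
    "invert_adjustment",
]

CATEGORICAL = ("sex", "site", "field_strength")


@dataclass
class AdjustmentModel:
    """Per-region OLS covariate model plus HC standardization statistics."""

    covariates: list[str]
    levels: dict  # categorical covariate -> ordered levels (first = reference)
    regions: list[str]
    coef: pd.DataFrame  # rows: const + predictors; columns: regions
    hc_resid_sd: dict  # region -> SD of HC residuals (raw units)
    hc_raw_mean: dict  # region -> mean raw HC volume (denominator for % change)
    scale: str = "zscore"  # or "percent" (percent of control mean)

    def design(self, cohort: pd.DataFrame) -> pd.DataFrame:
        return _design_matrix(cohort, self.covariates, self.levels)

    def predict(self, cohort: pd.DataFrame) -> pd.DataFrame:
        """Covariate-predicted raw volume per region for each row."""
        X = self.design(cohort)
        X = X[self.coef.index]  # enforce column order
        return pd.DataFrame(
            X.to_numpy() @ self.coef.to_numpy(),
            columns=self.regions,
            index=cohort.index,
        )

    def save(self, path, directions: dict | None = None) -> None:
        d = {
            "covariates": self.covariates,
            "levels": self.levels,
            "regions": self.regions,
            "coef": {c: self.coef[c].tolist() for c in self.coef.columns},
            "coef_index": self.coef.index.tolist(),
            "hc_resid_sd": self.hc_resid_sd,
            "hc_raw_mean": self.hc_raw_mean,
            "scale": self.scale,
        }
        if directions is not None:
            d["directions"] = directions
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def load(cls, path) -> "AdjustmentModel":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        coef = pd.DataFrame(
            {c: d["coef"][c] for c in d["regions"]}, index=d["coef_index"]
        )
        return cls(
            covariates=d["covariates"],
            levels=d["levels"],
            regions=d["regions"],
            coef=coef,
            hc_resid_sd=d["hc_resid_sd"],
            hc_raw_mean=d["hc_raw_mean"],
            scale=d.get("scale", "zscore"),
        )


@dataclass
class AdjustedMatrix:
    """Model-ready standardized biomarker values, one row per subject-visit.

    ``data`` carries ``subject_id, group, visit_index, time_offset`` (years
    from that subject's baseline visit), passthrough columns (``age, cag,
    onset_age``) and one adjusted column per region. ``directions`` records the
    direction map applied so the transform can be inverted.
    """

    data: pd.DataFrame
    regions: list[str]
    directions: dict
    scale: str = "zscore"

    def subset(self, subject_ids) -> "AdjustedMatrix":
        ids = set(subject_ids)
        return AdjustedMatrix(
            data=self.data[self.data["subject_id"].isin(ids)].reset_index(drop=True),
            regions=list(self.regions),
            directions=dict(self.directions),
            scale=self.scale,
        )

    def values(self) -> np.ndarray:
        return self.data[self.regions].to_numpy(dtype=float)

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, regions, directions, scale: str = "zscore"):
        """Load a previously written matrix; region/direction metadata come
        from the adjustment-model sidecar."""
        return cls(
            data=pd.read_csv(path),
            regions=list(regions),
            directions={r: int(directions[r]) for r in regions},
            scale=scale,
        )


def _design_matrix(df: pd.DataFrame, covariates, levels) -> pd.DataFrame:
    missing = [c for c in covariates if c not in df.columns]
    if missing:
        raise ConfigurationError(f"covariate columns missing from cohort: {missing}")
    cols = {"const": np.ones(len(df))}
    for cov in covariates:
        if cov in CATEGORICAL:
            lv = levels[cov]
            observed = set(df[cov].astype(str))
            unseen = observed - set(lv)
            if unseen:
                raise ConfigurationError(
                    f"unseen level(s) {sorted(unseen)} for covariate {cov!r}"
                )
            for level in lv[1:]:  # first level is the reference
                cols[f"{cov}[{level}]"] = (df[cov].astype(str) == level).astype(float)
        else:
            cols[cov] = df[cov].to_numpy(dtype=float)
    return pd.DataFrame(cols, index=df.index)


def fit_adjustment(
    cohort: pd.DataFrame,
    covariates=("age", "sex", "site", "tiv"),
    regions=None,
    scale: str = "zscore",
) -> AdjustmentModel:
    """Fit per-region OLS covariate models on the HC rows of a cohort.

    Raises on absent HC rows, degenerate one-level categorical covariates and
    rank-deficient designs (naming the offending columns).
    """
    covariates = list(covariates)
    if regions is None:
        reserved = {
            "subject_id", "group", "visit_index", "age", "sex", "site",
            "field_strength", "tiv", "cag", "onset_age",
        }
        regions = [c for c in cohort.columns if c not in reserved]
    if not regions:
        raise ConfigurationError("no region columns found in cohort")
    hc = cohort[cohort["group"] == "HC"]
    if len(hc) == 0:
        raise ConfigurationError("no HC rows: adjustment must be fitted on controls")
    if hc["subject_id"].nunique() < 2:
        raise ConfigurationError("need at least 2 HC subjects to fit adjustment")

    levels = {}
    for cov in covariates:
        if cov in CATEGORICAL:
            lv = sorted(hc[cov].astype(str).unique())
            if len(lv) < 2:
                raise ConfigurationError(
                    f"covariate {cov!r} has a single level ({lv[0]!r}) in HC rows; "
                    "drop it or provide data with >= 2 levels"
                )
            levels[cov] = lv

    X = _design_matrix(hc, covariates, levels)
    Xv = X.to_numpy(dtype=float)
    rank = np.linalg.matrix_rank(Xv)
    if rank < Xv.shape[1]:
        # flag columns whose removal restores full column rank
        bad = [
            X.columns[i]
            for i in range(1, Xv.shape[1])
            if np.linalg.matrix_rank(np.delete(Xv, i, axis=1)) == rank
        ]
        raise ConfigurationError(f"design matrix is rank-deficient; collinear columns: {bad}")

    coef = {}
    resid_sd = {}
    raw_mean = {}
    for r in regions:
        y = hc[r].to_numpy(dtype=float)
        ok = ~np.isnan(y)
        beta, *_ = np.linalg.lstsq(Xv[ok], y[ok], rcond=None)
        resid = y[ok] - Xv[ok] @ beta
        dof = max(ok.sum() - Xv.shape[1], 1)
        coef[r] = beta
        resid_sd[r] = float(np.sqrt((resid**2).sum() / dof))
        raw_mean[r] = float(np.nanmean(y))
    coef_df = pd.DataFrame(coef, index=X.columns)[regions]
    return AdjustmentModel(
        covariates=covariates,
        levels=levels,
        regions=list(regions),
        coef=coef_df,
        hc_resid_sd=resid_sd,
        hc_raw_mean=raw_mean,
        scale=scale,
    )


def apply_adjustment(
    cohort: pd.DataFrame, model: AdjustmentModel, direction_map: dict
) -> AdjustedMatrix:
    """Covariate-adjust, standardize and direction-normalize a cohort.

    ``adjusted = direction * (raw - covariate prediction) / HC residual SD``
    (z-score scale) or ``direction * 100 * (raw - prediction) / HC raw mean``
    (percent scale). Multiplying by the region's direction (-1 for atrophying
    regions, +1 for the enlarging ventricles) makes every region's expected
    disease trend increasing, which is what the model's positive-derivative
    constraint assumes.
    """
    missing = [r for r in model.regions if r not in direction_map]
    if missing:
        raise ConfigurationError(f"direction_map missing regions: {missing}")
    pred = model.predict(cohort)
    out = cohort[["subject_id", "group", "visit_index"]].copy()
    baseline_age = cohort.groupby("subject_id")["age"].transform("min")
    out["time_offset"] = cohort["age"] - baseline_age
    for col in ("age", "cag", "onset_age"):
        if col in cohort.columns:
            out[col] = cohort[col]
    for r in model.regions:
        resid = cohort[r].to_numpy(dtype=float) - pred[r].to_numpy()
        if model.scale == "percent":
            std = 100.0 * resid / model.hc_raw_mean[r]
        else:
            std = resid / model.hc_resid_sd[r]
        out[r] = direction_map[r] * std
    return AdjustedMatrix(
        data=out,
        regions=list(model.regions),
        directions={r: int(direction_map[r]) for r in model.regions},
        scale=model.scale,
    )


def invert_adjustment(
    adjusted: AdjustedMatrix, cohort: pd.DataFrame, model: AdjustmentModel
) -> pd.DataFrame:
    """Reconstruct raw volumes from adjusted values (round-trip inverse).

    ``cohort`` supplies the covariate columns row-aligned with
    ``adjusted.data``.
    """
    pred = model.predict(cohort)
    out = adjusted.data[["subject_id", "visit_index"]].copy()
    for r in model.regions:
        z = adjusted.data[r].to_numpy(dtype=float) * adjusted.directions[r]
        if model.scale == "percent":
            resid = z * model.hc_raw_mean[r] / 100.0
        else:
            resid = z * model.hc_resid_sd[r]
        out[r] = resid + pred[r].to_numpy()
    return out
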