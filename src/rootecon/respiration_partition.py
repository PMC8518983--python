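"""Partitioning total root respiration among root tissue classes.

Whole-root-system respiration cannot be dissected physically at throughput,
so it is partitioned statistically: total respiration (TRR, nmol s^-1) is
regressed on the volumes of three tissue classes —

* axial root volume (diameter > 0.3 mm),
* lateral root axis volume (lateral volume minus tip volume),
* lateral root tip volume (tip count minus the assumed number of seminal
  roots, times a nominal 0.01 mm3 per tip).

The fitted slopes are volume-specific respiration rates (nmol s^-1 mm^-3)
per tissue class; their ratios quantify how much more active tips are than
axial or lateral axis tissue.  The residual of the model — respiration not
explained by tissue-class abundance — is retained as the trait ``SRR_R``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

log = logging.getLogger(__name__)

PREDICTORS = ["axial_volume_mm3", "lateral_axis_volume_mm3", "tip_volume_mm3"]


def partition_volumes(
    features: pd.DataFrame,
    seminal_count: int = 4,
    tip_unit_volume_mm3: float = 0.01,
) -> pd.DataFrame:
    """Split per-sample root volume into tissue classes.

    ``n_lateral_tips = max(tips - seminal_count, 0)`` (seedlings are assumed
    to carry ``seminal_count`` seminal root tips that are not lateral tips);
    ``tip_volume = n_lateral_tips * tip_unit_volume_mm3``;
    ``lateral_axis_volume = max(lateral_volume - tip_volume, 0)``.
    Clamping to zero is flagged, never fatal.
    """
    tips = features["tips"].to_numpy(float)
    lrv = features["lrv_mm3"].to_numpy(float)
    n_lat = np.maximum(tips - seminal_count, 0.0)
    tip_vol = n_lat * tip_unit_volume_mm3
    lat_axis = lrv - tip_vol
    clamped = lat_axis < 0
    lat_axis = np.maximum(lat_axis, 0.0)
    out = pd.DataFrame(
        {
            "sample_id": features["sample_id"],
            "axial_volume_mm3": features["arv_mm3"].to_numpy(float),
            "lateral_axis_volume_mm3": lat_axis,
            "tip_volume_mm3": tip_vol,
            "n_lateral_tips": n_lat,
            "clamped": clamped | (tips < seminal_count),
        }
    )
    n_clamped = int(out["clamped"].sum())
    if n_clamped:
        log.warning("partition_volumes: %d samples required clamping", n_clamped)
    return out


@dataclass
class PartitionModel:
    """OLS fit of TRR on the three tissue-class volumes (with intercept)."""

    params: pd.Series           # intercept + three slopes, nmol s-1 mm-3
    bse: pd.Series
    pvalues: pd.Series
    r_squared: float
    f_pvalue: float
    n_obs: int
    n_clamped: int = 0

    @property
    def ratio_tip_axial(self) -> float:
        a = self.params["axial_volume_mm3"]
        return self.params["tip_volume_mm3"] / a if a > 0 else np.nan

    @property
    def ratio_tip_lateral(self) -> float:
        l = self.params["lateral_axis_volume_mm3"]
        return self.params["tip_volume_mm3"] / l if l > 0 else np.nan

    def predict(self, volumes: pd.DataFrame) -> pd.Series:
        X = volumes[PREDICTORS].to_numpy(float)
        pred = self.params["const"] + X @ self.params[PREDICTORS].to_numpy()
        return pd.Series(pred, index=volumes.index, name="predicted_trr")

    def to_dict(self) -> dict:
        return {
            "coefficients": self.params.to_dict(),
            "standard_errors": self.bse.to_dict(),
            "p_values": self.pvalues.to_dict(),
            "r_squared": self.r_squared,
            "f_pvalue": self.f_pvalue,
            "n_obs": self.n_obs,
            "n_clamped": self.n_clamped,
            "ratio_tip_axial": self.ratio_tip_axial,
            "ratio_tip_lateral": self.ratio_tip_lateral,
        }


def _merged(volumes: pd.DataFrame, respiration: pd.DataFrame) -> pd.DataFrame:
    resp = respiration.rename(columns={"flux_nmol_s": "trr", "TRR": "trr"})
    d = volumes.merge(resp[["sample_id", "trr"]], on="sample_id", how="inner")
    return d.dropna(subset=PREDICTORS + ["trr"])


def fit_partition_model(
    volumes: pd.DataFrame, respiration: pd.DataFrame
) -> PartitionModel:
    """Fit ``TRR ~ axial_volume + lateral_axis_volume + tip_volume``.

    ``respiration`` needs ``sample_id`` and a ``flux_nmol_s`` (or ``TRR``)
    column.  Raises on fewer than 5 complete cases or a rank-deficient
    design (collinear volume columns are named in the error).
    """
    d = _merged(volumes, respiration)
    if len(d) < 5:
        raise ValueError(f"need >= 5 complete cases, got {len(d)}")
    X = sm.add_constant(d[PREDICTORS].astype(float), has_constant="add")
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        corr = d[PREDICTORS].corr().abs()
        np.fill_diagonal(corr.values, 0.0)
        pair = np.unravel_index(np.argmax(corr.values), corr.shape)
        raise ValueError(
            "rank-deficient design; most collinear columns: "
            f"{PREDICTORS[pair[0]]} ~ {PREDICTORS[pair[1]]}"
        )
    fit = sm.OLS(d["trr"].astype(float), X).fit()
    n_clamped = int(d["clamped"].sum()) if "clamped" in d.columns else 0
    return PartitionModel(
        params=fit.params,
        bse=fit.bse,
        pvalues=fit.pvalues,
        r_squared=float(fit.rsquared),
        f_pvalue=float(fit.f_pvalue),
        n_obs=int(fit.nobs),
        n_clamped=n_clamped,
    )


def _aic(y: np.ndarray, X: np.ndarray) -> float:
    """AIC = n·ln(RSS/n) + 2k for an OLS fit with k fitted parameters."""
    n = len(y)
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    rss = float(np.sum((y - X @ beta) ** 2))
    rss = max(rss, 1e-300)  # guard exact fits
    return n * np.log(rss / n) + 2 * X.shape[1]


def stepwise_aic(
    data: pd.DataFrame,
    response: str,
    terms: list[str] | None = None,
) -> tuple[list[str], list[dict]]:
    """Bidirectional stepwise OLS term selection minimising AIC.

    Starts from the full model (all ``terms``) and repeatedly applies the
    single term addition or removal that most reduces
    ``AIC = n·ln(RSS/n) + 2k`` until no move improves it.  The intercept is
    always included.  Returns ``(selected_terms, trace)`` where the trace
    records every accepted step.
    """
    terms = list(terms) if terms is not None else [c for c in PREDICTORS if c in data.columns]
    d = data.dropna(subset=terms + [response])
    y = d[response].to_numpy(float)
    n = len(y)

    def design(sel: list[str]) -> np.ndarray:
        cols = [np.ones(n)] + [d[t].to_numpy(float) for t in sel]
        return np.column_stack(cols)

    current = sorted(terms)
    current_aic = _aic(y, design(current))
    trace = [dict(action="start", terms=list(current), aic=current_aic)]
    while True:
        candidates: list[tuple[float, str, list[str]]] = []
        for t in current:  # drops
            sel = [x for x in current if x != t]
            candidates.append((_aic(y, design(sel)), f"- {t}", sel))
        for t in terms:  # adds
            if t not in current:
                sel = sorted(current + [t])
                candidates.append((_aic(y, design(sel)), f"+ {t}", sel))
        if not candidates:
            break
        best_aic, action, best_sel = min(candidates, key=lambda c: c[0])
        if best_aic < current_aic - 1e-10:
            current, current_aic = best_sel, best_aic
            trace.append(dict(action=action, terms=list(current), aic=current_aic))
        else:
            break
    return current, trace


def residual_trait(
    model: PartitionModel,
    volumes: pd.DataFrame,
    respiration: pd.DataFrame,
) -> pd.DataFrame:
    """Per-sample residual respiration ``SRR_R = observed - predicted`` (nmol s^-1).

    On the fitting population the mean residual is zero by construction
    (OLS with intercept).
    """
    d = _merged(volumes, respiration)
    pred = model.predict(d)
    return pd.DataFrame({"sample_id": d["sample_id"], "SRR_R": d["trr"] - pred})
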