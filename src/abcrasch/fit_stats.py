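"""Residual fit statistics and separation/reliability summaries.

Quality control for a Rasch calibration rests on standardized residuals
z_pi = (x_pi - P_pi)/sqrt(P_pi(1-P_pi)).  Outfit is the plain mean of z²
(outlier-sensitive); infit weights each z² by the binomial information
W_pi = P_pi(1-P_pi), emphasising responses near an entity's own level.  Both
have expectation ≈ 1 under the model.  The standardized form (Zstd) maps the
mean-square to an approximate unit normal through the Wilson-Hilferty
cube-root transformation using the statistic's model variance; displayed
values are clamped to ±9.9, the convention of the classic calibration
software printouts.

Separation G = sqrt(true variance / error variance) and reliability
R = G²/(1+G²) summarise how many statistically distinct strata of measures
the instrument resolves.  All quantities here are model-based ("model"
error); the misfit-inflated "real" variants of some software are not
computed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_io import ResponseMatrix
from .rasch import RaschFit

__all__ = [
    "FitReport",
    "standardized_residuals",
    "infit_outfit",
    "flag_misfit",
    "separation_reliability",
    "point_measure_corr",
]

#: default acceptance windows for item fit
MNSQ_RANGE = (0.75, 1.33)
ZSTD_RANGE = (-2.0, 2.0)
ZSTD_CLAMP = 9.9


@dataclass
class FitReport:
    """Per-item and per-person fit tables plus separation/reliability summary."""

    per_item: pd.DataFrame
    per_person: pd.DataFrame
    summary: dict

    def export_items(self, path) -> None:
        self.per_item.to_csv(path, index=False)


def standardized_residuals(fit: RaschFit, data: ResponseMatrix) -> pd.DataFrame:
    """z_pi = (x_pi - P_pi)/sqrt(P_pi(1-P_pi)); missing cells stay NaN."""
    values = data.values()
    P = fit.prob_matrix().to_numpy()
    if np.any((P <= 0.0) | (P >= 1.0)):
        raise FloatingPointError(
            "model probability hit 0 or 1; data were not screened for extremes"
        )
    z = (values - P) / np.sqrt(P * (1.0 - P))
    return pd.DataFrame(z, index=data.X.index, columns=data.X.columns)


def _mnsq_zstd(values, obs, P, axis):
    """Mean-squares and Wilson-Hilferty Zstd along one margin.

    axis=0 aggregates over persons (item statistics); axis=1 over items.
    """
    W = np.where(obs, P * (1.0 - P), 0.0)
    # fourth central moment of a Bernoulli cell: C = W(1-3W)
    C = W * (1.0 - 3.0 * W)
    sq = np.where(obs, (values - P) ** 2, 0.0)
    z2 = np.where(obs, sq / np.where(W > 0, W, 1.0), 0.0)
    N = obs.sum(axis=axis)
    sumW = W.sum(axis=axis)

    with np.errstate(divide="ignore", invalid="ignore"):
        outfit = z2.sum(axis=axis) / N
        infit = sq.sum(axis=axis) / sumW
        var_out = (C / np.where(W > 0, W, 1.0) ** 2).sum(axis=axis) / N**2 - 1.0 / N
        var_in = (C - W**2).sum(axis=axis) / sumW**2

    def wilson_hilferty(mnsq, var):
        q = np.sqrt(np.maximum(var, 1e-12))
        z = (np.cbrt(mnsq) - 1.0) * 3.0 / q + q / 3.0
        return np.clip(z, -ZSTD_CLAMP, ZSTD_CLAMP)

    enough = N >= 2
    out = {
        "infit_mnsq": np.where(enough, infit, np.nan),
        "infit_zstd": np.where(enough, wilson_hilferty(infit, var_in), np.nan),
        "outfit_mnsq": np.where(enough, outfit, np.nan),
        "outfit_zstd": np.where(enough, wilson_hilferty(outfit, var_out), np.nan),
    }
    return out


def separation_reliability(measures, ses) -> dict:
    """Separation G and reliability R = G²/(1+G²) from measures and their SEs.

    Error variance is the mean squared SE; true variance is the observed
    variance of the measures minus the error variance, floored at zero.
    """
    measures = np.asarray(measures, dtype=float)
    ses = np.asarray(ses, dtype=float)
    keep = np.isfinite(measures) & np.isfinite(ses)
    measures, ses = measures[keep], ses[keep]
    if measures.size < 2:
        raise ValueError("separation_reliability needs at least 2 entities")
    err_var = float(np.mean(ses**2))
    obs_var = float(np.var(measures, ddof=1))
    true_var = max(obs_var - err_var, 0.0)
    if obs_var == 0.0 or true_var == 0.0:
        return {"separation": 0.0, "reliability": 0.0}
    G = np.sqrt(true_var / err_var)
    return {"separation": float(G), "reliability": float(G**2 / (1.0 + G**2))}


def point_measure_corr(data: ResponseMatrix, fit: RaschFit) -> pd.Series:
    """Pearson correlation of each item column with the person measures."""
    beta = fit.beta.to_numpy()
    values = data.values()
    out = {}
    for j, iid in enumerate(data.X.columns):
        x = values[:, j]
        keep = ~np.isnan(x)
        xj, bj = x[keep], beta[keep]
        if xj.size < 2 or np.std(xj) == 0.0 or np.std(bj) == 0.0:
            out[iid] = np.nan
            continue
        out[iid] = float(np.corrcoef(xj, bj)[0, 1])
    return pd.Series(out, name="point_measure_corr")


def infit_outfit(fit: RaschFit, data: ResponseMatrix) -> FitReport:
    """Full fit report: MNSQ/Zstd per item and person, correlations, summary."""
    values = data.values()
    obs = ~np.isnan(values)
    P = fit.prob_matrix().to_numpy()

    item_stats = _mnsq_zstd(values, obs, P, axis=0)
    person_stats = _mnsq_zstd(values, obs, P, axis=1)
    X0 = np.where(obs, values, 0.0)

    per_item = pd.DataFrame(
        {
            "id": data.X.columns,
            "total_score": X0.sum(axis=0).astype(int),
            "count": obs.sum(axis=0).astype(int),
            "measure": fit.delta.to_numpy(),
            "se": fit.se_delta.to_numpy(),
            **item_stats,
            "point_measure_corr": point_measure_corr(data, fit).to_numpy(),
        }
    )
    per_person = pd.DataFrame(
        {
            "id": data.X.index,
            "total_score": X0.sum(axis=1).astype(int),
            "count": obs.sum(axis=1).astype(int),
            "measure": fit.beta.to_numpy(),
            "se": fit.se_beta.to_numpy(),
            **person_stats,
        }
    )
    summary = {}
    for label, tbl in (("person", per_person), ("item", per_item)):
        sr = separation_reliability(tbl["measure"], tbl["se"])
        summary[f"{label}_separation"] = sr["separation"]
        summary[f"{label}_reliability"] = sr["reliability"]
    return FitReport(per_item=per_item, per_person=per_person, summary=summary)


def flag_misfit(
    report: FitReport | pd.DataFrame,
    mnsq_range: tuple[float, float] = MNSQ_RANGE,
    zstd_range: tuple[float, float] = ZSTD_RANGE,
) -> pd.DataFrame:
    """Flag items whose infit statistics leave the acceptance windows.

    Accepts a full :class:`FitReport` or any table with ``infit_mnsq`` and
    ``infit_zstd`` columns; returns per-item booleans ``mnsq_violation``,
    ``zstd_violation``, ``any`` and ``both``.
    """
    tbl = report.per_item if isinstance(report, FitReport) else report
    mnsq = tbl["infit_mnsq"].to_numpy(dtype=float)
    zstd = tbl["infit_zstd"].to_numpy(dtype=float)
    mnsq_bad = (mnsq < mnsq_range[0]) | (mnsq > mnsq_range[1])
    zstd_bad = (zstd < zstd_range[0]) | (zstd > zstd_range[1])
    return pd.DataFrame(
        {
            "id": tbl["id"] if "id" in tbl else tbl.index,
            "mnsq_violation": mnsq_bad,
            "zstd_violation": zstd_bad,
            "any": mnsq_bad | zstd_bad,
            "both": mnsq_bad & zstd_bad,
        }
    ).reset_index(drop=True)
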