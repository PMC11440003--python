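"""Unidimensionality assessment by PCA of standardized Rasch residuals.

If a single latent trait drives the responses, the standardized residuals
left after removing the Rasch-modelled part should be unstructured noise:
every eigenvalue of their item × item correlation matrix near 1.  A leading
residual component ("first contrast") with eigenvalue ≥ 2 — i.e. the strength
of two or more items — signals a secondary dimension, and items loading on it
with opposite signs mark the opposing clusters.  The scale passes when the
Rasch measures explain at least 40% of total variance and the first contrast
stays below 2.0 item-units.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_io import ResponseMatrix
from .fit_stats import standardized_residuals
from .rasch import RaschFit

__all__ = ["ContrastResult", "residual_pca", "contrast_loadings"]

VARIANCE_EXPLAINED_MIN = 40.0  # percent
CONTRAST_EIGENVALUE_MAX = 2.0  # item units
LOADING_THRESHOLD = 0.4
MIN_PAIR_OVERLAP = 30


@dataclass
class ContrastResult:
    """Residual-PCA summary: variance split, contrast eigenvalues, loadings."""

    variance_explained_by_measure: float  # percent of total variance
    contrast_eigenvalues: np.ndarray  # descending, item units
    contrast_percents: np.ndarray  # percent of total variance per contrast
    loadings: pd.DataFrame  # items × contrasts
    unidimensional: bool
    measure_contrast_ratios: np.ndarray = field(default=None)  # type: ignore[assignment]
    low_overlap_pairs: list = field(default_factory=list)

    def export(self, eig_path, loading_path, threshold: float = LOADING_THRESHOLD) -> None:
        pd.DataFrame(
            {
                "contrast": np.arange(1, len(self.contrast_eigenvalues) + 1),
                "eigenvalue": self.contrast_eigenvalues,
                "percent": self.contrast_percents,
            }
        ).to_csv(eig_path, index=False)
        rows = []
        for c in self.loadings.columns:
            for iid, val in self.loadings[c].items():
                rows.append((iid, c, val, abs(val) >= threshold))
        pd.DataFrame(
            rows, columns=["item", "contrast", "loading", "above_threshold"]
        ).to_csv(loading_path, index=False)


def _measure_variance(fit: RaschFit, data: ResponseMatrix) -> float:
    """Rasch-explained variance in residual-eigenvalue (item) units.

    The raw variance a cell's measures explain is W_pi(beta_p - delta_i)²
    with W_pi = P_pi(1 - P_pi); the cell's raw residual variance is W_pi.
    The residual pool maps to L eigenvalue units (the trace of the residual
    correlation matrix), so the explained variance on that same scale is
    L * sum(W * spread) / sum(W) over observed cells.
    """
    values = data.values()
    obs = ~np.isnan(values)
    P = fit.prob_matrix().to_numpy()
    W = np.where(obs, P * (1.0 - P), 0.0)
    spread = (fit.beta.to_numpy()[:, None] - fit.delta.to_numpy()[None, :]) ** 2
    L = data.n_items
    return float(L * (W * spread).sum() / W.sum())


def residual_pca(fit: RaschFit, data: ResponseMatrix, n_contrasts: int = 5) -> ContrastResult:
    """PCA of the pairwise-complete correlation matrix of standardized residuals.

    Loadings are reported for the leading ``n_contrasts`` components as
    eigenvector × sqrt(eigenvalue), with the sign of each contrast fixed so
    its largest-|loading| item is positive.
    """
    if data.n_items < 3:
        raise ValueError("residual PCA needs at least 3 items")
    Z = standardized_residuals(fit, data)
    obs = Z.notna().to_numpy()
    overlap = obs.T.astype(int) @ obs.astype(int)
    low = []
    items = list(Z.columns)
    for a in range(len(items)):
        for b in range(a + 1, len(items)):
            if overlap[a, b] < MIN_PAIR_OVERLAP:
                low.append((items[a], items[b]))
    R = Z.corr(min_periods=2).to_numpy()
    if np.isnan(R).any():
        bad = [items[j] for j in np.where(np.isnan(R).any(axis=0))[0]]
        raise np.linalg.LinAlgError(
            f"residual correlation undefined for items {bad} (constant or disjoint residuals)"
        )
    off = R - np.eye(len(items))
    if np.any(np.abs(off) > 1.0 - 1e-12):
        a, b = np.argwhere(np.abs(off) > 1.0 - 1e-12)[0]
        raise np.linalg.LinAlgError(
            f"residual correlation matrix is singular: items {items[a]} and {items[b]} "
            "are collinear"
        )
    eigval, eigvec = np.linalg.eigh(R)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    eigval = np.clip(eigval, 0.0, None)

    k = min(n_contrasts, len(items))
    load = eigvec[:, :k] * np.sqrt(eigval[:k])[None, :]
    for c in range(k):
        top = np.argmax(np.abs(load[:, c]))
        if load[top, c] < 0:
            load[:, c] = -load[:, c]
    loadings = pd.DataFrame(
        load, index=items, columns=[f"contrast_{c + 1}" for c in range(k)]
    )

    v_measure = _measure_variance(fit, data)
    total = v_measure + len(items)
    pct_measure = 100.0 * v_measure / total
    pct_contrasts = 100.0 * eigval / total
    first = float(eigval[0])
    return ContrastResult(
        variance_explained_by_measure=pct_measure,
        contrast_eigenvalues=eigval,
        contrast_percents=pct_contrasts,
        loadings=loadings,
        unidimensional=(pct_measure >= VARIANCE_EXPLAINED_MIN)
        and (first < CONTRAST_EIGENVALUE_MAX),
        measure_contrast_ratios=v_measure / np.maximum(eigval[:k], 1e-12),
        low_overlap_pairs=low,
    )


def contrast_loadings(
    result: ContrastResult, threshold: float = LOADING_THRESHOLD
) -> dict[str, pd.Series]:
    """Items with |loading| ≥ threshold per contrast, ordered by |loading|."""
    out = {}
    for c in result.loadings.columns:
        col = result.loadings[c]
        sel = col[col.abs() >= threshold]
        out[c] = sel.reindex(sel.abs().sort_values(ascending=False).index)
    return out
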