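"""Pipeline driver, Wright map rendering, and provenance-carrying exports.

`run_pipeline` chains the full analysis in its canonical order — extreme
screening, JML calibration, fit diagnostics, residual PCA, penalized DIF path
with BIC selection — writing every stage's export plus a run log into an
output directory and returning an :class:`AnalysisBundle`.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

from . import data_io, dif, dimensionality, fit_stats, rasch

logger = logging.getLogger("abcrasch")

__all__ = ["AnalysisBundle", "PipelineError", "wright_map", "run_pipeline", "DEFAULT_CONFIG"]

#: every tunable threshold of the analysis, with the study's conventions
DEFAULT_CONFIG = {
    "screen_extremes": True,
    "jml": {"max_iter": 100, "tol": 1e-6, "bias_correction": False},
    "fit": {"mnsq_range": [0.75, 1.33], "zstd_range": [-2.0, 2.0]},
    "dimensionality": {
        "variance_explained_min": 40.0,
        "contrast_eigenvalue_max": 2.0,
        "loading_threshold": 0.4,
    },
    "dif": {
        "n_lambda": 50,
        "quadrature_nodes": 21,
        "zero_threshold": 1e-4,
        "rasch_constrained": False,
        "lambda_min_ratio": 1e-3,
        "references": dict(dif.DEFAULT_REFERENCES),
    },
    "instrument": {"cutoff_score": 68},
}


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline failed at stage {stage!r}: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class AnalysisBundle:
    """Everything one analysis run produced, plus its provenance."""

    fit: rasch.RaschFit
    fit_report: fit_stats.FitReport
    contrasts: dimensionality.ContrastResult
    dif_path: dif.DIFPath
    screened: data_io.ResponseMatrix
    extreme_persons: list = field(default_factory=list)
    extreme_items: list = field(default_factory=list)
    provenance: dict = field(default_factory=dict)


def wright_map(fit: rasch.RaschFit, bins: int = 30, width: int = 30) -> str:
    """Two-column text histogram of persons (left) and items (right).

    Shares one logit axis with mean item difficulty pinned at 0; one person
    glyph ``#`` stands for ceil(n/rows) persons (stated in the legend), and
    ``.`` marks a non-empty remainder below one glyph.
    """
    beta = fit.beta.to_numpy()
    delta = fit.delta.to_numpy()
    lo = math.floor(min(beta.min(), delta.min()) * 2) / 2
    hi = math.ceil(max(beta.max(), delta.max()) * 2) / 2
    edges = np.linspace(lo, hi, bins + 1)
    p_counts, _ = np.histogram(beta, bins=edges)
    per_glyph = max(1, math.ceil(p_counts.max() / width))
    lines = [
        "  logit | persons" + " " * (width - 7) + "| items",
        "-" * (10 + width + 10),
    ]
    item_ids = list(fit.delta.index)
    for b in range(bins - 1, -1, -1):
        center = (edges[b] + edges[b + 1]) / 2
        n_full, rem = divmod(p_counts[b], per_glyph)
        glyphs = "#" * n_full + ("." if rem else "")
        in_bin = [
            str(item_ids[j])
            for j in range(len(delta))
            if edges[b] <= delta[j] < edges[b + 1]
            or (b == bins - 1 and delta[j] == edges[-1])
        ]
        lines.append(
            f"{center:7.2f} | {glyphs:<{width}}| {' '.join(in_bin)}"
        )
    lines.append(f"each '#' represents {per_glyph} persons; '.' is 1-{per_glyph - 1} persons"
                 if per_glyph > 1 else "each '#' represents 1 person")
    lines.append("mean item difficulty set to 0 logits")
    return "\n".join(lines)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def run_pipeline(
    responses_path,
    covariates_path,
    instrument_path=None,
    config: dict | None = None,
    out_dir=None,
) -> AnalysisBundle:
    """Run screen → JML → fit statistics → residual PCA → DIF path → BIC.

    ``config`` overrides :data:`DEFAULT_CONFIG` entries (shallow, per block).
    When ``out_dir`` is given, every stage writes its CSV export there along
    with ``provenance.json``; on a stage failure a FAILED marker naming the
    stage is left next to any partial outputs.
    """
    cfg = {k: (dict(v) if isinstance(v, dict) else v) for k, v in DEFAULT_CONFIG.items()}
    for key, val in (config or {}).items():
        if isinstance(val, dict) and isinstance(cfg.get(key), dict):
            cfg[key].update(val)
        else:
            cfg[key] = val
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    def fail(stage: str, exc: Exception):
        logger.error("stage %s failed: %s", stage, exc)
        if out is not None:
            (out / "FAILED").write_text(f"stage: {stage}\nerror: {exc}\n")
        raise PipelineError(stage, exc)

    try:
        provenance = {
            "started": datetime.now(timezone.utc).isoformat(),
            "inputs": {
                "responses": {
                    "path": str(responses_path),
                    "sha256": _sha256(Path(responses_path)),
                },
                "covariates": {
                    "path": str(covariates_path),
                    "sha256": _sha256(Path(covariates_path)),
                },
            },
            "config": cfg,
        }
        if instrument_path is not None:
            provenance["inputs"]["instrument"] = {
                "path": str(instrument_path),
                "sha256": _sha256(Path(instrument_path)),
            }
        data = data_io.read_responses(responses_path, covariates_path)
    except Exception as exc:
        fail("data_io", exc)
    logger.info("loaded %d persons x %d items", *data.shape)

    try:
        screened, ex_p, ex_i = data_io.screen_extremes(data)
    except Exception as exc:
        fail("screen_extremes", exc)
    if ex_p or ex_i:
        logger.warning("screened out %d persons, %d items", len(ex_p), len(ex_i))

    try:
        fit = rasch.estimate_jml(screened, **cfg["jml"])
    except Exception as exc:
        fail("rasch_calibration", exc)
    logger.info(
        "JML %s in %d cycles, loglik %.2f",
        "converged" if fit.converged else "DID NOT CONVERGE",
        fit.n_iter,
        fit.loglik,
    )

    try:
        report = fit_stats.infit_outfit(fit, screened)
        flags = fit_stats.flag_misfit(
            report,
            tuple(cfg["fit"]["mnsq_range"]),
            tuple(cfg["fit"]["zstd_range"]),
        )
    except Exception as exc:
        fail("fit_diagnostics", exc)
    logger.info("misfit flags: %d items", int(flags["any"].sum()))

    try:
        contrasts = dimensionality.residual_pca(fit, screened)
    except Exception as exc:
        fail("dimensionality", exc)
    logger.info(
        "variance by measure %.1f%%, first contrast %.2f",
        contrasts.variance_explained_by_measure,
        contrasts.contrast_eigenvalues[0],
    )

    try:
        design = dif.build_design(
            screened.covariates, cfg["dif"].get("references")
        )
        path = dif.fit_dif_path(
            screened,
            design,
            n_lambda=cfg["dif"]["n_lambda"],
            quadrature_nodes=cfg["dif"]["quadrature_nodes"],
            rasch_constrained=cfg["dif"]["rasch_constrained"],
            zero_threshold=cfg["dif"]["zero_threshold"],
            lambda_min_ratio=cfg["dif"]["lambda_min_ratio"],
        )
    except Exception as exc:
        fail("dif_lasso", exc)
    sel = path.selected
    logger.info(
        "DIF path: selected lambda %.4f, %d nonzero gamma",
        sel.lambda_,
        int((sel.nonzero_gamma().to_numpy() != 0).sum()),
    )

    provenance["finished"] = datetime.now(timezone.utc).isoformat()
    bundle = AnalysisBundle(
        fit=fit,
        fit_report=report,
        contrasts=contrasts,
        dif_path=path,
        screened=screened,
        extreme_persons=ex_p,
        extreme_items=ex_i,
        provenance=provenance,
    )
    if out is not None:
        rasch.export_fit(fit, screened, out / "measures.csv")
        report.export_items(out / "item_fit.csv")
        flags.to_csv(out / "misfit_flags.csv", index=False)
        contrasts.export(out / "contrast_eigenvalues.csv", out / "contrast_loadings.csv",
                         cfg["dimensionality"]["loading_threshold"])
        path.export(out / "dif_path.csv")
        dif.dif_table(sel, design, cfg["dif"]["zero_threshold"]).to_csv(
            out / "dif_table.csv"
        )
        (out / "wright_map.txt").write_text(wright_map(fit))
        (out / "provenance.json").write_text(json.dumps(provenance, indent=1, default=str))
    return bundle
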