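"""Published reference tables from the large-sample ABC calibration study.

Two tables from the published Rasch/DIF analysis of the ABC in a clinical
sample of 3,319 children ship with the package as plain CSV: the fit
statistics of the 29 items flagged as misfitting, and the BIC-selected lasso
DIF coefficients for all 57 items (rows absent from the published table are
zero; the published layout omits the symptom-level columns, reported in the
text as all zero, so they are carried here explicitly as zeros).  They serve
as worked-example inputs for the screening and tabulation operations — the
raw response data behind them were never deposited.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = ["reference_fit_statistics", "reference_dif_coefficients"]


def _read(name: str) -> pd.DataFrame:
    ref = resources.files("abcrasch.data").joinpath(name)
    with resources.as_file(ref) as path:
        return pd.read_csv(path)


def reference_fit_statistics() -> pd.DataFrame:
    """Fit statistics of the 29 published misfitting items.

    Columns: item, total_score, total_count, measure, se, infit_mnsq,
    infit_zstd, outfit_mnsq, outfit_zstd, corr.  Zstd values of ±9.9 are the
    display clamp of the calibration software.
    """
    return _read("reference_fit_statistics.csv")


def reference_dif_coefficients() -> pd.DataFrame:
    """Published BIC-selected uniform-DIF coefficients, one row per item.

    Columns: item, gender, infant, kindergarten, primary, junior_high,
    non_autism, mild_moderate.  Nonzero entries mark uniform DIF; negative
    values make the item easier for that group.
    """
    return _read("reference_dif_coefficients.csv")
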