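"""Instrument definition, weighted scoring, and dichotomization for the ABC.

The Autism Behavior Checklist (ABC) is a 57-item caregiver-reported checklist
of autistic behaviors organised in five subscales.  Each rated item contributes
a fixed frequency-derived weight of 1-4 points to a weighted total; a total
above 67 points (cut-off 68) flags severe symptoms.  Rasch analysis of the
checklist operates on the dichotomous rated/not-rated form, so this module
also converts weighted scoring sheets to 0/1 responses.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ItemDef",
    "Instrument",
    "InstrumentError",
    "ScoringError",
    "load_instrument",
    "packaged_abc",
    "dichotomize",
    "weighted_total",
]

VALID_SUBSCALES = frozenset(
    {"relating", "sensory", "language", "body_object_use", "social_self_help"}
)


class InstrumentError(ValueError):
    """Raised when an instrument definition violates the schema."""


class ScoringError(ValueError):
    """Raised when a raw scoring sheet contains an impossible value."""


@dataclass(frozen=True)
class ItemDef:
    """One checklist item: identifier, wording, subscale and weight (1-4 points)."""

    id: int
    text: str
    subscale: str
    weight: int
    text_source: str = "published"
    subscale_source: str = "published"

    def __post_init__(self) -> None:
        if self.weight not in (1, 2, 3, 4):
            raise InstrumentError(
                f"item {self.id}: weight must be in 1..4, got {self.weight!r}"
            )
        if self.subscale not in VALID_SUBSCALES:
            raise InstrumentError(
                f"item {self.id}: unknown subscale {self.subscale!r}; "
                f"allowed: {sorted(VALID_SUBSCALES)}"
            )


@dataclass(frozen=True)
class Instrument:
    """An ordered item catalogue plus the weighted-total cut-off score."""

    name: str
    items: tuple[ItemDef, ...]
    cutoff_score: int
    notes: str = field(default="", compare=False)

    def __post_init__(self) -> None:
        ids = [it.id for it in self.items]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise InstrumentError(f"duplicate item ids: {dupes}")
        if ids != list(range(1, len(ids) + 1)):
            raise InstrumentError("item ids must be contiguous 1..n in order")

    def __len__(self) -> int:
        return len(self.items)

    @property
    def item_ids(self) -> list[int]:
        return [it.id for it in self.items]

    @property
    def weights(self) -> np.ndarray:
        return np.array([it.weight for it in self.items], dtype=float)

    @property
    def subscales(self) -> set[str]:
        return {it.subscale for it in self.items}

    @property
    def max_score(self) -> int:
        return int(sum(it.weight for it in self.items))


def _item_from_record(rec: dict) -> ItemDef:
    for key in ("id", "text", "subscale", "weight"):
        if key not in rec:
            raise InstrumentError(f"item record missing field {key!r}: {rec}")
    return ItemDef(
        id=int(rec["id"]),
        text=str(rec["text"]),
        subscale=str(rec["subscale"]),
        weight=int(rec["weight"]),
        text_source=str(rec.get("text_source", "published")),
        subscale_source=str(rec.get("subscale_source", "published")),
    )


def load_instrument(path: str | Path) -> Instrument:
    """Load an instrument definition from its JSON schema.

    The schema is ``{name, cutoff_score, items: [{id, text, subscale, weight}]}``.
    Raises :class:`InstrumentError` naming the offending field on any schema or
    invariant violation.
    """
    with open(path, "r", encoding="utf-8") as fh:
        try:
            doc = json.load(fh)
        except json.JSONDecodeError as exc:
            raise InstrumentError(f"{path}: not valid JSON: {exc}") from exc
    for key in ("name", "cutoff_score", "items"):
        if key not in doc:
            raise InstrumentError(f"{path}: missing top-level field {key!r}")
    items = tuple(_item_from_record(rec) for rec in doc["items"])
    return Instrument(
        name=str(doc["name"]),
        items=items,
        cutoff_score=int(doc["cutoff_score"]),
        notes=str(doc.get("notes", "")),
    )


def packaged_abc() -> Instrument:
    """The packaged 57-item ABC definition (item texts where published)."""
    ref = resources.files("abcrasch.data").joinpath("abc_instrument.json")
    with resources.as_file(ref) as path:
        inst = load_instrument(path)
    if len(inst) != 57:
        raise InstrumentError("packaged ABC definition must have 57 items")
    return inst


def _as_frame(raw: pd.DataFrame | np.ndarray, instrument: Instrument) -> pd.DataFrame:
    if isinstance(raw, pd.DataFrame):
        frame = raw.astype(float)
    else:
        arr = np.asarray(raw, dtype=float)
        if arr.ndim == 1:
            arr = arr[None, :]
        frame = pd.DataFrame(arr)
    if frame.shape[1] != len(instrument):
        raise ScoringError(
            f"scoring sheet has {frame.shape[1]} columns but instrument "
            f"defines {len(instrument)} items"
        )
    return frame


def _validate_raw(frame: pd.DataFrame, instrument: Instrument) -> None:
    weights = instrument.weights
    values = frame.to_numpy(dtype=float)
    bad = np.zeros_like(values, dtype=bool)
    observed = ~np.isnan(values)
    bad[observed] = (values[observed] != 0) & (values[observed] != np.broadcast_to(weights, values.shape)[observed])
    if bad.any():
        p, i = np.argwhere(bad)[0]
        raise ScoringError(
            f"person {frame.index[p]!r}, item {instrument.item_ids[i]}: raw score "
            f"{values[p, i]:g} is neither 0 nor the item weight {int(weights[i])}"
        )


def dichotomize(raw_scores: pd.DataFrame | np.ndarray, instrument: Instrument) -> pd.DataFrame:
    """Rescore a weighted sheet to 0/1: any positive rated score becomes 1.

    Each cell must be 0 or exactly the item's weight; missing cells (NaN) stay
    missing.  Idempotent on data already scored with weight-1 items.
    """
    frame = _as_frame(raw_scores, instrument)
    _validate_raw(frame, instrument)
    out = frame.where(frame.isna(), (frame > 0).astype(float))
    return out


def weighted_total(
    raw_scores: Sequence[float] | np.ndarray | pd.Series, instrument: Instrument
) -> tuple[int, bool]:
    """Weighted total for one person's sheet and the severe-symptom flag.

    The classification rule is strict: totals at or above the instrument
    cut-off (68 for the ABC, i.e. "above 67") are positive.
    """
    row = pd.Series(np.asarray(raw_scores, dtype=float))
    frame = _as_frame(row.to_frame().T, instrument)
    _validate_raw(frame, instrument)
    total = int(np.nansum(frame.to_numpy()))
    return total, total >= instrument.cutoff_score
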