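"""Synthetic dichotomous response data with the structure the analysis assumes.

The generator draws per-person covariates from categorical margins, latent
traits from a normal distribution (optionally shifted per group to create
impact — true trait differences — as opposed to DIF), and responses from the
two-parameter logistic model with per-item uniform-DIF shifts:

    P(x_pi = 1) = logistic(alpha_i * (theta_p - diff_i - x_p @ gamma_i))

The default configuration emulates the published ABC calibration sample:
3,319 children, 79.69% male, age-group margins dominated by under-3s and
kindergarteners, a CARS severity split of roughly 34/44/22%, 57 items with
difficulties spread over the logit range the calibration reported (a near
continuum in [-2, 2] plus two very common behaviors near -4.2 logits and one
rare one near +1.1), unit discriminations, and no DIF.

Draw order within one `simulate` call is fixed (covariates, then traits, then
responses item-major) from a single seeded generator, so equal seeds give
byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .data_io import AGE_LEVELS, GENDER_LEVELS, SYMPTOM_LEVELS, ResponseMatrix
from .dif import build_design

__all__ = ["SimConfig", "default_abc_config", "simulate"]

DEFAULT_SEED = 20240916


@dataclass
class SimConfig:
    """Generating parameters for one synthetic sample."""

    n_persons: int
    item_difficulties: np.ndarray
    item_discriminations: np.ndarray
    theta_dist: dict = field(default_factory=lambda: {"mean": 0.0, "sd": 1.0})
    group_proportions: dict = field(default_factory=dict)
    gamma: np.ndarray = None  # type: ignore[assignment]  # items × design columns
    theta_shift_by_group: np.ndarray | None = None  # impact, per design column
    missing_rate: float = 0.0
    seed: int = DEFAULT_SEED
    n_traits: int = 1
    item_trait: np.ndarray | None = None  # trait index per item, default all 0
    generator: str = "numpy.random.PCG64"

    def __post_init__(self) -> None:
        self.item_difficulties = np.asarray(self.item_difficulties, dtype=float)
        self.item_discriminations = np.asarray(self.item_discriminations, dtype=float)
        ni = len(self.item_difficulties)
        if len(self.item_discriminations) != ni:
            raise ValueError("difficulties and discriminations lengths differ")
        if (self.item_discriminations <= 0).any():
            raise ValueError("discriminations must be positive")
        if self.gamma is None:
            self.gamma = np.zeros((ni, 7))
        self.gamma = np.asarray(self.gamma, dtype=float)
        if self.gamma.shape[0] != ni:
            raise ValueError("gamma must have one row per item")
        for factor, props in self.group_proportions.items():
            total = sum(props.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"{factor} proportions sum to {total}, not 1")
        if self.item_trait is not None:
            self.item_trait = np.asarray(self.item_trait, dtype=int)
            if len(self.item_trait) != ni:
                raise ValueError("item_trait must have one entry per item")
            if self.item_trait.max() >= self.n_traits:
                raise ValueError("item_trait index exceeds n_traits")

    @property
    def n_items(self) -> int:
        return len(self.item_difficulties)


def default_abc_config(seed: int = DEFAULT_SEED) -> SimConfig:
    """The study-emulating default: 57 items, n = 3,319, published margins."""
    diffs = np.empty(57)
    body = np.linspace(-2.0, 2.0, 54)
    others = [i for i in range(57) if i not in (9, 18, 37)]  # 0-based 9→item 10 etc.
    diffs[others] = body
    diffs[9] = -4.22  # near-universal behavior (item 10 analogue)
    diffs[37] = -4.27  # item 38 analogue
    diffs[18] = 1.1  # rare behavior (item 19 analogue)
    return SimConfig(
        n_persons=3319,
        item_difficulties=diffs,
        item_discriminations=np.ones(57),
        theta_dist={"mean": 0.0, "sd": 1.0},
        group_proportions={
            "gender": {"male": 0.7969, "female": 0.2031},
            "age_group": {
                "infant": 0.4260,
                "kindergarten": 0.4528,
                "primary": 0.1145,
                "junior_high": 0.006,
                "high": 0.0007,
            },
            "symptom_level": {
                "non_autism": 0.3420,
                "mild_moderate": 0.4357,
                "severe": 0.2223,
            },
        },
        gamma=np.zeros((57, 7)),
        seed=seed,
    )


def _draw_factor(rng, levels, props, n):
    p = np.array([props[lev] for lev in levels], dtype=float)
    p = p / p.sum()
    return rng.choice(len(levels), size=n, p=p)


def simulate(config: SimConfig) -> tuple[ResponseMatrix, dict]:
    """Draw one sample; returns the response matrix and the generating truth."""
    rng = np.random.default_rng(config.seed)
    n, ni = config.n_persons, config.n_items

    props = {
        "gender": config.group_proportions.get(
            "gender", {"male": 0.5, "female": 0.5}
        ),
        "age_group": config.group_proportions.get(
            "age_group", {lev: 1.0 / len(AGE_LEVELS) for lev in AGE_LEVELS}
        ),
        "symptom_level": config.group_proportions.get(
            "symptom_level", {lev: 1.0 / len(SYMPTOM_LEVELS) for lev in SYMPTOM_LEVELS}
        ),
    }
    gender = _draw_factor(rng, GENDER_LEVELS, props["gender"], n)
    age = _draw_factor(rng, AGE_LEVELS, props["age_group"], n)
    sym = _draw_factor(rng, SYMPTOM_LEVELS, props["symptom_level"], n)
    person_ids = [f"p{k + 1:05d}" for k in range(n)]
    covariates = pd.DataFrame(
        {
            "gender": [GENDER_LEVELS[g] for g in gender],
            "age_group": [AGE_LEVELS[a] for a in age],
            "symptom_level": [SYMPTOM_LEVELS[s] for s in sym],
        },
        index=pd.Index(person_ids, name="person_id"),
    )
    design = build_design(covariates)
    Xd = design.matrix.to_numpy()

    mean, sd = config.theta_dist["mean"], config.theta_dist["sd"]
    theta = mean + sd * rng.standard_normal((n, config.n_traits))
    if config.theta_shift_by_group is not None:
        shift = Xd @ np.asarray(config.theta_shift_by_group, dtype=float)
        theta = theta + shift[:, None]
    item_trait = (
        config.item_trait if config.item_trait is not None else np.zeros(ni, dtype=int)
    )

    gamma = config.gamma
    if gamma.shape[1] != Xd.shape[1]:
        raise ValueError(
            f"gamma has {gamma.shape[1]} columns; design has {Xd.shape[1]}"
        )
    X = np.empty((n, ni))
    for i in range(ni):  # item-major response draws, fixed order
        eff = config.item_difficulties[i] + Xd @ gamma[i]
        eta = config.item_discriminations[i] * (theta[:, item_trait[i]] - eff)
        p = 1.0 / (1.0 + np.exp(-eta))
        X[:, i] = (rng.random(n) < p).astype(float)
    if config.missing_rate > 0:
        mask = rng.random((n, ni)) < config.missing_rate
        X[mask] = np.nan

    frame = pd.DataFrame(
        X, index=covariates.index, columns=[f"item_{i + 1}" for i in range(ni)]
    )
    data = ResponseMatrix(X=frame, covariates=covariates)
    truth = {
        "theta": theta[:, 0] if config.n_traits == 1 else theta,
        "covariates": covariates,
        "design_columns": design.columns,
        "config": config,
    }
    return data, truth


def write_truth(truth: dict, path) -> None:
    """Dump generating parameters (not the raw draws) as JSON."""
    import json

    cfg = truth["config"]
    payload = asdict(cfg)
    for key, val in payload.items():
        if isinstance(val, np.ndarray):
            payload[key] = val.tolist()
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=1)
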