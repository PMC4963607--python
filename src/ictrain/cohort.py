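"""Synthetic randomized waitlist-control cohorts and instrument scoring.

Generates two-arm cohorts (training vs waitlist) with demographics drawn
from an overweight/obese adult population (BMI truncated below 25) and
per-outcome (time 1, time 2) scores drawn bivariate-normal per participant,
so the paired structure the mixed ANOVA assumes is present by construction.
Default cell means and SDs are calibrated to the outcome pattern of such a
trial: healthy-eating score and cognitive restraint rise after training,
laboratory consumption of unhealthy food falls, and the waitlist arm drifts
slightly the other way.

Also scores the food-consumption taste test (grams consumed x configurable
energy density, summed into healthy and unhealthy kcal) and provides keyed
summation scaffolds for the HEQ (70-item food-frequency quiz, 8 subgroups)
and TFEQ (51 items; cognitive restraint, disinhibition, hunger).  The
instruments' proprietary item keys are not public, so the shipped keys are
editable placeholders with uniform weights.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

TRAINING = "training"
WAITLIST = "waitlist"
TIMES = (1, 2)

#: outcome -> {(condition, time): (mean, sd)} — study-condition defaults
DEFAULT_CELLS: dict[str, dict[tuple[str, int], tuple[float, float]]] = {
    "heq_total": {
        (TRAINING, 1): (36.96, 8.45),
        (TRAINING, 2): (42.42, 9.98),
        (WAITLIST, 1): (39.58, 9.68),
        (WAITLIST, 2): (35.88, 11.24),
    },
    "fct_healthy_kcal": {
        (TRAINING, 1): (31.59, 9.47),
        (TRAINING, 2): (63.17, 19.08),
        (WAITLIST, 1): (32.0, 10.0),
        (WAITLIST, 2): (33.0, 10.0),
    },
    "fct_unhealthy_kcal": {
        (TRAINING, 1): (234.68, 74.40),
        (TRAINING, 2): (76.50, 25.15),
        (WAITLIST, 1): (230.0, 70.0),
        (WAITLIST, 2): (225.0, 70.0),
    },
    "tfeq_restraint": {
        (TRAINING, 1): (9.27, 3.38),
        (TRAINING, 2): (11.50, 4.25),
        (WAITLIST, 1): (9.5, 3.4),
        (WAITLIST, 2): (9.3, 3.4),
    },
    "tfeq_disinhibition": {
        (TRAINING, 1): (8.0, 3.5),
        (TRAINING, 2): (8.0, 3.5),
        (WAITLIST, 1): (8.0, 3.5),
        (WAITLIST, 2): (8.3, 3.5),
    },
    "tfeq_hunger": {
        (TRAINING, 1): (5.6, 3.4),
        (TRAINING, 2): (5.5, 3.4),
        (WAITLIST, 1): (5.58, 3.46),
        (WAITLIST, 2): (6.88, 3.56),
    },
}


@dataclass(frozen=True)
class CohortSpec:
    """Cohort composition and per-outcome cell means/SDs."""

    n_per_condition: int = 26
    age_mean: float = 36.48
    age_sd: float = 14.22
    age_min: float = 18.0
    bmi_mean: float = 29.54
    bmi_sd: float = 4.05
    bmi_min: float = 25.0
    test_retest_corr: float = 0.6
    cells: dict = field(default_factory=lambda: DEFAULT_CELLS)

    def __post_init__(self) -> None:
        if self.n_per_condition < 2:
            raise ValueError("need at least 2 participants per condition")
        if not -1.0 < self.test_retest_corr < 1.0:
            raise ValueError("test-retest correlation must lie in (-1, 1)")
        for outcome, cellmap in self.cells.items():
            for key, (_, sd) in cellmap.items():
                if sd <= 0:
                    raise ValueError(f"non-positive SD for {outcome} cell {key}")


def _truncated_normal(
    rng: np.random.Generator, mean: float, sd: float, lo: float, size: int
) -> np.ndarray:
    # resampling rejection is fine here: the truncation point is well within
    # a few sd of the mean for the supported demographics
    out = rng.normal(mean, sd, size)
    while (bad := out < lo).any():
        out[bad] = rng.normal(mean, sd, bad.sum())
    return out


def generate_cohort(spec: CohortSpec, rng: np.random.Generator) -> pd.DataFrame:
    """Balanced two-condition cohort, one row per participant x time.

    Each outcome's (time 1, time 2) pair is bivariate normal with the
    specified cell means/SDs and within-participant correlation.
    Reproducible under a fixed generator.
    """
    n = spec.n_per_condition
    participants = []
    for c, condition in enumerate((TRAINING, WAITLIST)):
        for i in range(n):
            participants.append((f"P{c * n + i + 1:03d}", condition))
    ages = _truncated_normal(rng, spec.age_mean, spec.age_sd, spec.age_min, 2 * n)
    bmis = _truncated_normal(rng, spec.bmi_mean, spec.bmi_sd, spec.bmi_min, 2 * n)

    rows = []
    for (pid, condition), age, bmi in zip(participants, ages, bmis):
        scores = {t: {} for t in TIMES}
        for outcome, cellmap in spec.cells.items():
            m1, s1 = cellmap[(condition, 1)]
            m2, s2 = cellmap[(condition, 2)]
            r = spec.test_retest_corr
            cov = [[s1**2, r * s1 * s2], [r * s1 * s2, s2**2]]
            y1, y2 = rng.multivariate_normal([m1, m2], cov)
            scores[1][outcome] = y1
            scores[2][outcome] = y2
        for t in TIMES:
            rows.append(
                {
                    "participant_id": pid,
                    "condition": condition,
                    "time": t,
                    "age": float(age),
                    "bmi": float(bmi),
                    **{k: float(v) for k, v in scores[t].items()},
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# food consumption test scoring

#: offered snack portions in grams
DEFAULT_OFFERED_G = {"nuts": 156.0, "grapes": 216.0, "chips": 60.0, "candy": 161.0}
#: configurable energy densities, kcal per gram (typical nutrition-table
#: values for unsalted mixed nuts, grapes, plain chips and chocolate candy)
DEFAULT_DENSITY_KCAL_PER_G = {
    "nuts": 6.07,
    "grapes": 0.69,
    "chips": 5.36,
    "candy": 4.92,
}
HEALTHY_FOODS = ("nuts", "grapes")
UNHEALTHY_FOODS = ("chips", "candy")


@dataclass(frozen=True)
class FCTItems:
    """Grams offered/consumed per snack food plus energy densities."""

    consumed_g: dict
    offered_g: dict = field(default_factory=lambda: dict(DEFAULT_OFFERED_G))
    density_kcal_per_g: dict = field(
        default_factory=lambda: dict(DEFAULT_DENSITY_KCAL_PER_G)
    )

    def __post_init__(self) -> None:
        for food in HEALTHY_FOODS + UNHEALTHY_FOODS:
            consumed = self.consumed_g.get(food, 0.0)
            offered = self.offered_g[food]
            if not 0.0 <= consumed <= offered:
                raise ValueError(
                    f"weighing error: consumed {consumed} g of {food} "
                    f"with only {offered} g offered"
                )
            if self.density_kcal_per_g[food] <= 0:
                raise ValueError("energy densities must be positive")


def score_fct(items: FCTItems) -> tuple[float, float]:
    """(healthy_kcal, unhealthy_kcal): grams consumed x energy density, summed.

    Linear in consumed grams — doubling consumption doubles kcal exactly.
    """
    healthy = sum(
        items.consumed_g.get(f, 0.0) * items.density_kcal_per_g[f]
        for f in HEALTHY_FOODS
    )
    unhealthy = sum(
        items.consumed_g.get(f, 0.0) * items.density_kcal_per_g[f]
        for f in UNHEALTHY_FOODS
    )
    return float(healthy), float(unhealthy)


# ---------------------------------------------------------------------------
# questionnaire scoring scaffolds

@dataclass(frozen=True)
class ScoringKey:
    """Keyed summation: subscale -> list of (item_index, reverse, max_level)."""

    name: str
    n_items: int
    subscales: dict  # subscale -> tuple of (index, reverse: bool, max_level: int)

    def __post_init__(self) -> None:
        seen = [i for items in self.subscales.values() for (i, _, _) in items]
        if any(not 0 <= i < self.n_items for i in seen):
            raise ValueError("item index outside the instrument")


def placeholder_heq_key() -> ScoringKey:
    """70 items assigned round-robin to the 8 food subgroups, 0-5 Likert."""
    subgroups = (
        "fruits", "vegetables", "meat_proteins", "vegetarian_proteins",
        "grains", "water", "dairy", "extras",
    )
    subscales = {s: [] for s in subgroups}
    for i in range(70):
        subscales[subgroups[i % 8]].append((i, False, 5))
    return ScoringKey(
        name="HEQ",
        n_items=70,
        subscales={s: tuple(v) for s, v in subscales.items()},
    )


def placeholder_tfeq_key() -> ScoringKey:
    """51 items: 21 restraint, 16 disinhibition, 14 hunger; binary/4-point mix."""
    subscales = {
        "cognitive_restraint": tuple((i, False, 1 if i % 3 else 3) for i in range(21)),
        "disinhibition": tuple((i, False, 1 if i % 2 else 3) for i in range(21, 37)),
        "hunger": tuple((i, i % 7 == 0, 1 if i % 2 else 3) for i in range(37, 51)),
    }
    return ScoringKey(name="TFEQ", n_items=51, subscales=subscales)


@dataclass(frozen=True)
class InstrumentScores:
    heq_subgroups: dict
    heq_total: float
    tfeq: dict  # cognitive_restraint, disinhibition, hunger


def score_key(responses, key: ScoringKey) -> dict:
    """Keyed sums per subscale, honoring reverse-keyed items."""
    responses = np.asarray(responses)
    if len(responses) != key.n_items:
        raise ValueError(
            f"{key.name} expects {key.n_items} responses, got {len(responses)}"
        )
    out = {}
    for subscale, items in key.subscales.items():
        total = 0.0
        for idx, reverse, max_level in items:
            r = responses[idx]
            if not 0 <= r <= max_level:
                raise ValueError(
                    f"response {r} out of range [0, {max_level}] at item {idx}"
                )
            total += (max_level - r) if reverse else r
        out[subscale] = float(total)
    return out


def score_instruments(
    heq_responses,
    tfeq_responses,
    heq_key: ScoringKey | None = None,
    tfeq_key: ScoringKey | None = None,
) -> InstrumentScores:
    """Score both questionnaires; HEQ total is the sum of subgroup scores."""
    heq_key = placeholder_heq_key() if heq_key is None else heq_key
    tfeq_key = placeholder_tfeq_key() if tfeq_key is None else tfeq_key
    heq = score_key(heq_responses, heq_key)
    tfeq = score_key(tfeq_responses, tfeq_key)
    return InstrumentScores(
        heq_subgroups=heq, heq_total=float(sum(heq.values())), tfeq=tfeq
    )
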