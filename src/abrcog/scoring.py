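"""Hearing and cognition summary variables.

Hearing level is the pure-tone average (PTA) over 0.5/1/2/4 kHz in the
better ear (smaller PTA = better hearing). Cognition is summarised by
z-scoring each of the ten raw measures against the analyzed sample
(n−1 SD), flipping the sign of time-based measures so that higher always
means better, and averaging the ten z-scores into a composite. Categorical
groupings: age groups young (<31 y) / middle-aged (31–59 y) / elderly
(≥60 y), and hearing loss defined as PTA ≥ 20 dB HL.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .schema import (
    COGNITIVE_MEASURES,
    COMPOSITE_COLUMN,
    LOWER_IS_BETTER,
    DataError,
    InputError,
    z_column,
)

logger = logging.getLogger(__name__)

PTA_FREQUENCIES_KHZ = (0.5, 1.0, 2.0, 4.0)
HEARING_LOSS_CUTOFF_DB = 20.0
AGE_GROUP_EDGES = (31.0, 60.0)  # young < 31 <= middle < 60 <= elderly
AGE_GROUP_LABELS = ("young", "middle-aged", "elderly")


@dataclass(frozen=True)
class Audiogram:
    """Per-ear thresholds in dB HL keyed by frequency in kHz."""

    left: Mapping[float, float] | None = None
    right: Mapping[float, float] | None = None

    def __post_init__(self) -> None:
        for ear_name, ear in (("left", self.left), ("right", self.right)):
            if ear is None:
                continue
            for freq, thr in ear.items():
                if not -10.0 <= thr <= 120.0:
                    raise InputError(
                        f"{ear_name} ear threshold {thr} dB HL at {freq} kHz outside [-10, 120]"
                    )


@dataclass(frozen=True)
class CognitiveBattery:
    """Named measures with direction flags (True = higher is better)."""

    measures: tuple[str, ...] = COGNITIVE_MEASURES
    higher_is_better: Mapping[str, bool] = field(
        default_factory=lambda: {m: m not in LOWER_IS_BETTER for m in COGNITIVE_MEASURES}
    )

    def __post_init__(self) -> None:
        missing = [m for m in self.measures if m not in self.higher_is_better]
        if missing:
            raise InputError(f"direction flags missing for measures: {missing}")


DEFAULT_BATTERY = CognitiveBattery()


def compute_pta_better_ear(audiogram: Audiogram) -> tuple[float, str]:
    """PTA (dB HL) of the better ear and which ear that is.

    PTA = arithmetic mean of the 0.5/1/2/4 kHz thresholds per ear; the
    better ear has the smaller PTA. Ties resolve to the right ear (logged).
    """
    ptas: dict[str, float] = {}
    problems: dict[str, list[float]] = {}
    for ear_name, ear in (("left", audiogram.left), ("right", audiogram.right)):
        if ear is None:
            continue
        missing = [f for f in PTA_FREQUENCIES_KHZ if f not in ear]
        if missing:
            problems[ear_name] = missing
            continue
        ptas[ear_name] = float(np.mean([ear[f] for f in PTA_FREQUENCIES_KHZ]))
    if not ptas:
        raise InputError(
            f"no ear has thresholds at all PTA frequencies {PTA_FREQUENCIES_KHZ} kHz; "
            f"missing: {problems or 'no ears provided'}"
        )
    if len(ptas) == 1:
        ear_name, pta = next(iter(ptas.items()))
        return pta, ear_name
    if ptas["left"] < ptas["right"]:
        return ptas["left"], "left"
    if ptas["left"] == ptas["right"]:
        logger.info("PTA tie between ears (%.2f dB HL); choosing right ear", ptas["right"])
    return ptas["right"], "right"


def categorize_participant(age: float, pta: float) -> tuple[str, str]:
    """(age group, hearing category) for one participant."""
    if age < 18:
        raise InputError(f"age {age} < 18 years is outside the adult cohort definition")
    if age < AGE_GROUP_EDGES[0]:
        group = AGE_GROUP_LABELS[0]
    elif age < AGE_GROUP_EDGES[1]:
        group = AGE_GROUP_LABELS[1]
    else:
        group = AGE_GROUP_LABELS[2]
    hearing = "hearing loss" if pta >= HEARING_LOSS_CUTOFF_DB else "normal hearing"
    return group, hearing


def build_cognitive_scores(
    cohort: pd.DataFrame,
    battery: CognitiveBattery = DEFAULT_BATTERY,
    min_measures: int | None = None,
) -> pd.DataFrame:
    """Scored cohort: z columns, composite, age group, hearing category.

    Each measure is z-scored against the sample (mean 0, SD 1, n−1
    denominator) and sign-flipped where lower raw values mean better
    performance. The composite is the mean over available z-scores when at
    least ``min_measures`` are present (default: all but two, i.e. 8 of the
    10-measure battery); otherwise the participant is flagged
    ``excluded_low_coverage`` and the composite is NaN.
    """
    if len(cohort) < 2:
        raise InputError("scoring requires at least 2 participants")
    if min_measures is None:
        min_measures = max(len(battery.measures) - 2, 1)
    missing_cols = [m for m in battery.measures if m not in cohort.columns]
    if missing_cols:
        raise InputError(f"cohort table lacks cognitive measures: {missing_cols}")

    scored = cohort.copy()
    z_cols = []
    for measure in battery.measures:
        x = pd.to_numeric(scored[measure], errors="coerce")
        sd = x.std(ddof=1)
        if not np.isfinite(sd) or sd == 0:
            raise DataError(f"measure '{measure}' has zero variance; cannot z-score")
        z = (x - x.mean()) / sd
        if not battery.higher_is_better[measure]:
            z = -z
        col = z_column(measure)
        scored[col] = z
        z_cols.append(col)

    available = scored[z_cols].notna().sum(axis=1)
    scored[COMPOSITE_COLUMN] = scored[z_cols].mean(axis=1, skipna=True)
    excluded = available < min_measures
    scored.loc[excluded, COMPOSITE_COLUMN] = np.nan
    scored["excluded_low_coverage"] = excluded

    if "age" in scored.columns:
        edges = (-np.inf, *AGE_GROUP_EDGES, np.inf)
        scored["age_group"] = pd.cut(
            scored["age"], bins=edges, right=False, labels=AGE_GROUP_LABELS
        ).astype(str)
    if "pta" in scored.columns:
        scored["hearing_category"] = np.where(
            scored["pta"] >= HEARING_LOSS_CUTOFF_DB, "hearing loss", "normal hearing"
        )
    return scored
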