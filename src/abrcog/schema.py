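"""Canonical cohort-table schema shared by every pipeline stage.

The cohort CSV is the single interchange format: one row per participant,
demographics + hearing + ABR wave features + the ten raw cognitive measures.
Column metadata below drives validation in :mod:`abrcog.io`.
"""

from __future__ import annotations

from dataclasses import dataclass

#: The ten cognitive outcome measures, in battery order.
#: Time-based measures (trail making, four-mountains reaction time) are
#: lower-is-better; every other measure is higher-is-better.
COGNITIVE_MEASURES: tuple[str, ...] = (
    "word_learning",
    "delayed_recall",
    "word_recognition",
    "animal_fluency",
    "tmt_a_seconds",
    "tmt_b_seconds",
    "four_mountains_accuracy",
    "four_mountains_rt_ms",
    "visual_discrimination",
    "sdmt",
)

LOWER_IS_BETTER: frozenset[str] = frozenset(
    {"tmt_a_seconds", "tmt_b_seconds", "four_mountains_rt_ms"}
)

#: ABR feature columns of the cohort table (units in the schema entries).
ABR_COLUMNS: tuple[str, ...] = (
    "wave_i_latency",
    "wave_i_amplitude",
    "wave_v_latency",
    "wave_v_amplitude",
    "iv_latency_difference",
    "log_vi_amplitude_ratio",
)

#: z-score column name for a raw measure.
def z_column(measure: str) -> str:
    return f"z_{measure}"


COMPOSITE_COLUMN = "composite_z"


@dataclass(frozen=True)
class ColumnSpec:
    """Validation metadata for one cohort column."""

    name: str
    unit: str
    required: bool = False
    numeric: bool = True
    # hard bounds: values outside are errors; soft bounds: warnings only
    hard_range: tuple[float, float] | None = None
    warn_range: tuple[float, float] | None = None


COHORT_SCHEMA: dict[str, ColumnSpec] = {
    spec.name: spec
    for spec in [
        ColumnSpec("participant_id", "", required=True, numeric=False),
        ColumnSpec("age", "years", required=True, hard_range=(18.0, 120.0)),
        ColumnSpec("sex", "", numeric=False),
        ColumnSpec("pta", "dB HL", hard_range=(-10.0, 120.0)),
        ColumnSpec("wave_i_latency", "ms", warn_range=(0.5, 3.5)),
        ColumnSpec("wave_i_amplitude", "uV", warn_range=(0.0, 2.0)),
        # warn outside the analysis search window 5.1-6.4 ms (with margin)
        ColumnSpec("wave_v_latency", "ms", warn_range=(4.5, 7.5)),
        ColumnSpec("wave_v_amplitude", "uV", warn_range=(0.0, 2.0)),
        ColumnSpec("iv_latency_difference", "ms", warn_range=(2.0, 6.5)),
        ColumnSpec("log_vi_amplitude_ratio", "ln(uV/uV)"),
        ColumnSpec("word_learning", "words", hard_range=(0, 30)),
        ColumnSpec("delayed_recall", "words", hard_range=(0, 10)),
        ColumnSpec("word_recognition", "words", hard_range=(0, 20)),
        ColumnSpec("animal_fluency", "animals/min", hard_range=(0, 80)),
        ColumnSpec("tmt_a_seconds", "s", hard_range=(0, 600)),
        ColumnSpec("tmt_b_seconds", "s", hard_range=(0, 600)),
        ColumnSpec("four_mountains_accuracy", "correct", hard_range=(0, 15)),
        ColumnSpec("four_mountains_rt_ms", "ms", hard_range=(0, 60000)),
        ColumnSpec("visual_discrimination", "correct", hard_range=(0, 18)),
        ColumnSpec("sdmt", "pairs", hard_range=(0, 120)),
    ]
}

#: Column order used when writing the canonical cohort CSV.
COHORT_COLUMN_ORDER: tuple[str, ...] = tuple(COHORT_SCHEMA)


class AbrcogError(Exception):
    """Base class for package errors."""


class ParameterError(AbrcogError, ValueError):
    """Invalid generator or analysis parameters; names the offending field."""


class InputError(AbrcogError, ValueError):
    """Structurally invalid input data."""


class DataError(AbrcogError, ValueError):
    """Input data that is well-formed but unusable (e.g. zero variance)."""


class DegenerateInputError(DataError):
    """A computation whose inputs admit no answer (single class, ties only)."""


class ModelError(AbrcogError, ValueError):
    """A regression model that cannot be fit (rank deficiency, tiny n)."""


class MappingError(AbrcogError, KeyError):
    """Source-data column map does not cover a required canonical column."""


class PipelineError(AbrcogError, RuntimeError):
    """A pipeline stage failed; the message names the stage."""
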