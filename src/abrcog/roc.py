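"""Percentile-criterion ROC/AUC sweep for a single biomarker.

For each percentile criterion p in 1..99, participants at or above the
empirical p-th percentile of the cognitive composite are "good" performers,
the rest "poor". The biomarker (wave V amplitude or latency), oriented so
that higher oriented values indicate better cognition (amplitude up = good,
latency up = poor), is scored against the labels by the empirical AUC — the
Mann–Whitney probability that a random good performer out-scores a random
poor one, ties counted 1/2. The Youden-optimal cutoff (max sensitivity +
specificity − 1) is reported in original biomarker units at each criterion.
A chance band, obtained by replacing the biomarker with seeded independent
standard-normal draws, anchors AUC = 0.5; because AUC is invariant to any
strictly increasing transform of the scores, this null is distribution-free.
Optionally the composite is first residualized on age (OLS) so the sweep
targets the age-independent part of cognition.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .schema import COMPOSITE_COLUMN, DegenerateInputError, InputError, ParameterError

DEFAULT_PERCENTILES: tuple[int, ...] = tuple(range(1, 100))

#: a-priori biomarker orientations: +1 higher = better cognition
ORIENTATIONS = {
    "wave_v_amplitude": +1,
    "wave_v_latency": -1,
    "wave_i_amplitude": +1,
    "wave_i_latency": -1,
}


@dataclass(frozen=True)
class SweepConfig:
    predictor: str
    orientation: int = +1  # +1: higher predictor ~ better cognition
    percentiles: tuple[int, ...] = DEFAULT_PERCENTILES
    adjust_age: bool = False
    chance_replicates: int = 1000
    seed: int = 0
    outcome: str = COMPOSITE_COLUMN

    def __post_init__(self) -> None:
        if self.orientation not in (-1, 1):
            raise ParameterError("orientation must be +1 or -1")
        if any(not 0 < p < 100 for p in self.percentiles):
            raise ParameterError("percentiles must lie strictly inside (0, 100)")
        if self.chance_replicates < 1:
            raise ParameterError("chance_replicates must be >= 1")

    @classmethod
    def for_predictor(cls, predictor: str, **kwargs) -> "SweepConfig":
        """Config with the field's standard orientation for known predictors."""
        orientation = ORIENTATIONS.get(predictor, +1)
        return cls(predictor=predictor, orientation=orientation, **kwargs)


@dataclass
class SweepCurve:
    """Per-percentile sweep results plus grid summaries."""

    table: pd.DataFrame  # percentile, n_good, n_poor, auc, cutoff, ...
    predictor: str
    orientation: int
    adjust_age: bool

    @property
    def summary(self) -> dict:
        auc = self.table["auc"].to_numpy(dtype=float)
        valid = np.isfinite(auc)
        if not valid.any():
            return {"mean_auc": np.nan, "sd_auc": np.nan, "min_auc": np.nan,
                    "max_auc": np.nan, "argmax_percentile": np.nan}
        best = int(np.nanargmax(auc))
        return {
            "mean_auc": float(np.nanmean(auc)),
            "sd_auc": float(np.nanstd(auc, ddof=1)),
            "min_auc": float(np.nanmin(auc)),
            "max_auc": float(np.nanmax(auc)),
            "argmax_percentile": int(self.table["percentile"].iloc[best]),
        }


@dataclass
class ChanceBand:
    """Null AUC distribution from random predictors."""

    replicate_means: np.ndarray  # mean AUC over the grid, per replicate
    percentile_curve: np.ndarray  # replicate-averaged AUC per percentile
    percentiles: tuple[int, ...]

    @property
    def mean(self) -> float:
        return float(np.nanmean(self.replicate_means))

    @property
    def sd_between_replicates(self) -> float:
        return float(np.nanstd(self.replicate_means, ddof=1))

    @property
    def sd_across_percentiles(self) -> float:
        return float(np.nanstd(self.percentile_curve, ddof=1))


# ---------------------------------------------------------------------------
# primitives
# ---------------------------------------------------------------------------


def label_by_percentile(values: np.ndarray, percentile: float) -> np.ndarray:
    """Boolean good-performer labels: value >= empirical p-th percentile.

    The percentile is the linear-interpolation empirical quantile
    (``numpy.quantile`` default).
    """
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise InputError("need at least 2 values to label")
    if not 0 < percentile < 100:
        raise ParameterError("percentile must lie strictly inside (0, 100)")
    if np.ptp(values) == 0:
        raise DegenerateInputError("all composite values identical; labels undefined")
    cutoff = np.quantile(values, percentile / 100.0)
    return values >= cutoff


def empirical_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Mann–Whitney AUC: P(good score > poor score) + P(tie)/2.

    Computed via midranks: AUC = (R_good − n_g(n_g+1)/2) / (n_g n_p), which
    equals all-pairs counting with ties worth 1/2.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    n_good = int(labels.sum())
    n_poor = int(labels.size - n_good)
    if n_good == 0 or n_poor == 0:
        raise DegenerateInputError("both classes must be non-empty for AUC")
    ranks = stats.rankdata(scores)
    r_good = ranks[labels].sum()
    return float((r_good - n_good * (n_good + 1) / 2.0) / (n_good * n_poor))


def youden_cutoff(scores: np.ndarray, labels: np.ndarray) -> tuple[float, float, float]:
    """Cutoff maximizing Youden's J = sensitivity + specificity − 1.

    Scores are oriented (higher = good); a participant is predicted good
    when score > cutoff. Candidates are midpoints between adjacent sorted
    unique scores plus ±inf. Ties on J break toward higher specificity,
    then toward the lower cutoff. Returns (cutoff, sensitivity, specificity).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    n_good = int(labels.sum())
    n_poor = int(labels.size - n_good)
    if n_good == 0 or n_poor == 0:
        raise DegenerateInputError("both classes must be non-empty for a Youden cutoff")
    uniq = np.unique(scores)
    candidates = np.concatenate(([-np.inf], (uniq[:-1] + uniq[1:]) / 2.0, [np.inf]))
    good_scores = scores[labels]
    poor_scores = scores[~labels]
    best = None
    for c in candidates:
        sens = float((good_scores > c).mean())
        spec = float((poor_scores <= c).mean())
        j = sens + spec - 1.0
        key = (j, spec, -c)  # maximize J, then specificity, then prefer lower cutoff
        if best is None or key > best[0]:
            best = (key, c, sens, spec)
    _, cutoff, sens, spec = best
    return float(cutoff), sens, spec


def age_adjust_cognition(composite: np.ndarray, age: np.ndarray) -> np.ndarray:
    """OLS residuals of composite on age (intercept included)."""
    composite = np.asarray(composite, dtype=float)
    age = np.asarray(age, dtype=float)
    if composite.size < 3:
        raise InputError("age adjustment needs at least 3 observations")
    if np.ptp(age) == 0:
        raise DegenerateInputError("constant age; residualization undefined")
    X = np.column_stack([np.ones_like(age), age])
    beta, *_ = np.linalg.lstsq(X, composite, rcond=None)
    return composite - X @ beta


# ---------------------------------------------------------------------------
# sweeps
# ---------------------------------------------------------------------------


def _auc_grid(
    scores_oriented: np.ndarray, good_masks: np.ndarray, counts_good: np.ndarray
) -> np.ndarray:
    """Vectorized AUC for many labelings of one fixed score vector.

    ``good_masks`` is (n_percentiles, n) boolean; returns AUC per row,
    NaN where a labeling is single-class.
    """
    n = scores_oriented.size
    ranks = stats.rankdata(scores_oriented)
    r_good = good_masks @ ranks
    n_good = counts_good.astype(float)
    n_poor = n - n_good
    with np.errstate(divide="ignore", invalid="ignore"):
        auc = (r_good - n_good * (n_good + 1) / 2.0) / (n_good * n_poor)
    auc[(n_good == 0) | (n_poor == 0)] = np.nan
    return auc


def _label_grid(values: np.ndarray, percentiles: Sequence[int]) -> tuple[np.ndarray, np.ndarray]:
    cutoffs = np.quantile(values, np.asarray(percentiles, dtype=float) / 100.0)
    masks = values[None, :] >= cutoffs[:, None]
    return masks, masks.sum(axis=1)


def run_sweep(scored: pd.DataFrame, config: SweepConfig) -> SweepCurve:
    """Full percentile sweep of one biomarker against the composite.

    Per grid percentile: good/poor labels, empirical AUC of the oriented
    biomarker, Youden-optimal cutoff mapped back to original units with its
    decision direction. Percentiles where a class is empty are recorded as
    missing rows, not failures.
    """
    if config.predictor not in scored.columns:
        raise InputError(f"predictor column '{config.predictor}' not in table")
    work = scored[[config.predictor, config.outcome] + (["age"] if config.adjust_age else [])].dropna()
    if len(work) < 10:
        raise InputError(f"sweep needs >= 10 complete rows, got {len(work)}")
    composite = work[config.outcome].to_numpy(dtype=float)
    predictor = work[config.predictor].to_numpy(dtype=float)
    if config.adjust_age:
        composite = age_adjust_cognition(composite, work["age"].to_numpy(dtype=float))
    oriented = config.orientation * predictor

    rows = []
    for p in config.percentiles:
        labels = label_by_percentile(composite, p)
        n_good = int(labels.sum())
        n_poor = int(labels.size - n_good)
        if n_good == 0 or n_poor == 0:
            rows.append(
                dict(percentile=p, n_good=n_good, n_poor=n_poor, auc=np.nan,
                     cutoff=np.nan, cutoff_direction="", sensitivity=np.nan,
                     specificity=np.nan)
            )
            continue
        auc = empirical_auc(oriented, labels)
        c_or, sens, spec = youden_cutoff(oriented, labels)
        if config.orientation == 1:
            cutoff, direction = c_or, "above_cutoff_good"
        else:
            cutoff, direction = -c_or, "above_cutoff_poor"
        rows.append(
            dict(percentile=p, n_good=n_good, n_poor=n_poor, auc=auc,
                 cutoff=cutoff, cutoff_direction=direction,
                 sensitivity=sens, specificity=spec)
        )
    return SweepCurve(
        table=pd.DataFrame(rows),
        predictor=config.predictor,
        orientation=config.orientation,
        adjust_age=config.adjust_age,
    )


def chance_band(scored: pd.DataFrame, config: SweepConfig) -> ChanceBand:
    """Null sweep: the biomarker replaced by independent N(0,1) draws.

    Seeded; each replicate reruns the full percentile sweep and contributes
    its grid-mean AUC. Reports variability both between replicates and
    across the (replicate-averaged) percentile curve, since the two spreads
    answer different questions.
    """
    work = scored[[config.outcome] + (["age"] if config.adjust_age else [])].dropna()
    composite = work[config.outcome].to_numpy(dtype=float)
    if config.adjust_age:
        composite = age_adjust_cognition(composite, work["age"].to_numpy(dtype=float))
    n = composite.size
    if n < 10:
        raise InputError("chance band needs >= 10 complete rows")
    good_masks, counts = _label_grid(composite, config.percentiles)

    rng = np.random.default_rng(config.seed)
    reps = config.chance_replicates
    replicate_means = np.empty(reps)
    curve_sum = np.zeros(len(config.percentiles))
    for r in range(reps):
        fake = rng.standard_normal(n)
        auc = _auc_grid(fake, good_masks, counts)
        replicate_means[r] = np.nanmean(auc)
        curve_sum += np.nan_to_num(auc, nan=0.0)
    # grid points that are single-class are NaN for every replicate
    valid = ~np.isnan(_auc_grid(np.arange(n, dtype=float), good_masks, counts))
    curve = np.where(valid, curve_sum / reps, np.nan)
    return ChanceBand(
        replicate_means=replicate_means,
        percentile_curve=curve,
        percentiles=tuple(config.percentiles),
    )


def compare_sweeps(curve_a: SweepCurve, curve_b: SweepCurve) -> dict:
    """Paired two-sided t-test of AUC across shared grid points.

    Used to compare, e.g., age-adjusted vs unadjusted curves. Caveat: grid
    points are highly dependent (nested labelings), so the p-value is
    descriptive rather than strictly valid.
    """
    merged = curve_a.table.merge(
        curve_b.table, on="percentile", suffixes=("_a", "_b")
    ).dropna(subset=["auc_a", "auc_b"])
    if len(merged) < 2:
        raise InputError("need >= 2 shared valid grid points")
    t, p = stats.ttest_rel(merged["auc_a"], merged["auc_b"])
    return {
        "mean_a": float(merged["auc_a"].mean()),
        "mean_b": float(merged["auc_b"].mean()),
        "t": float(t),
        "p": float(p),
        "n_points": int(len(merged)),
    }
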