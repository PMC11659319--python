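"""k-fold cross-validated single-feature LDA per percentile criterion.

At each percentile criterion the cohort is labeled good/poor on the
composite, the fixed k-fold partition splits it into train/validation sets,
a linear discriminant is fit on the training feature and its discriminant
score is evaluated on the validation fold by the empirical AUC. Folds whose
training *or* validation labels contain a single class are excluded from
the average (at extreme percentiles the minority class may fit inside a
single fold); a percentile where every fold is excluded is reported missing.

With one feature the LDA discriminant score is an affine function of the
feature, so the fold AUC must equal the AUC of the raw feature oriented by
the sign of the learned coefficient — an exact oracle used by the tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

from .roc import DEFAULT_PERCENTILES, age_adjust_cognition, empirical_auc, label_by_percentile
from .schema import COMPOSITE_COLUMN, DegenerateInputError, InputError, ParameterError

#: k values used by the study design; others require explicit opt-in
ALLOWED_K = (2, 5, 10)

EXCLUDED = "excluded"


@dataclass(frozen=True)
class CVConfig:
    k: int
    predictor: str
    orientation: int = +1
    percentiles: tuple[int, ...] = DEFAULT_PERCENTILES
    adjust_age: bool = False
    seed: int = 0
    outcome: str = COMPOSITE_COLUMN
    allow_any_k: bool = False

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ParameterError("k must be >= 2")
        if self.k not in ALLOWED_K and not self.allow_any_k:
            raise ParameterError(
                f"k={self.k} outside the study set {ALLOWED_K}; pass allow_any_k=True to override"
            )
        if self.orientation not in (-1, 1):
            raise ParameterError("orientation must be +1 or -1")


@dataclass
class CVResult:
    table: pd.DataFrame  # percentile, mean_auc, retained_folds, excluded_folds
    k: int
    seed: int

    @property
    def summary(self) -> dict:
        auc = self.table["mean_auc"].to_numpy(dtype=float)
        return {
            "mean_auc": float(np.nanmean(auc)),
            "sd_auc": float(np.nanstd(auc, ddof=1)),
            "n_missing_percentiles": int(np.isnan(auc).sum()),
        }


def make_folds(n: int, k: int, seed: int) -> np.ndarray:
    """Random non-stratified partition into k folds of sizes differing by <= 1.

    Returns an integer fold id per observation; seeded and reproducible.
    """
    if k > n:
        raise ParameterError(f"k={k} exceeds n={n}")
    if k < 2:
        raise ParameterError("k must be >= 2")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    fold_ids = np.empty(n, dtype=int)
    for fid, chunk in enumerate(np.array_split(order, k)):
        fold_ids[chunk] = fid
    return fold_ids


def lda_fold_auc(
    x_train: np.ndarray,
    y_train: np.ndarray,
    x_val: np.ndarray,
    y_val: np.ndarray,
) -> float | str:
    """Validation AUC of a one-feature LDA, or ``"excluded"``.

    LDA uses pooled within-class variance and empirical priors. A fold is
    excluded when its training or validation labels are single-class
    (undefined discriminant or undefined sensitivity/specificity).
    """
    x_train = np.asarray(x_train, dtype=float)
    x_val = np.asarray(x_val, dtype=float)
    y_train = np.asarray(y_train, dtype=bool)
    y_val = np.asarray(y_val, dtype=bool)
    if x_train.size == 0 or x_val.size == 0:
        raise InputError("empty train or validation partition")
    if len(np.unique(y_train)) < 2 or len(np.unique(y_val)) < 2:
        return EXCLUDED
    lda = LinearDiscriminantAnalysis(solver="lsqr")
    import warnings

    with warnings.catch_warnings():
        # single-member training classes are legitimate here (extreme
        # percentiles); sklearn's covariance helper warns about them
        warnings.filterwarnings("ignore", message="Only one sample available")
        lda.fit(x_train.reshape(-1, 1), y_train.astype(int))
    scores = lda.decision_function(x_val.reshape(-1, 1))
    return empirical_auc(scores, y_val)


def cv_sweep(scored: pd.DataFrame, config: CVConfig) -> CVResult:
    """Cross-validated AUC curve over the percentile grid.

    One seeded fold partition of the cohort is reused across all
    percentiles (the partition is a property of the dataset, not of the
    criterion). Per percentile: per-fold LDA AUC, exclusion bookkeeping,
    mean over retained folds; NaN when no fold is retained.
    """
    cols = [config.predictor, config.outcome] + (["age"] if config.adjust_age else [])
    if config.predictor not in scored.columns:
        raise InputError(f"predictor column '{config.predictor}' not in table")
    work = scored[cols].dropna()
    n = len(work)
    if n < 10:
        raise InputError(f"cv sweep needs >= 10 complete rows, got {n}")
    if config.k > n // 2:
        raise ParameterError(f"k={config.k} too large for n={n} (need k <= n/2)")

    composite = work[config.outcome].to_numpy(dtype=float)
    feature = config.orientation * work[config.predictor].to_numpy(dtype=float)
    if config.adjust_age:
        composite = age_adjust_cognition(composite, work["age"].to_numpy(dtype=float))

    fold_ids = make_folds(n, config.k, config.seed)

    rows = []
    for p in config.percentiles:
        try:
            labels = label_by_percentile(composite, p)
        except DegenerateInputError:
            rows.append(dict(percentile=p, mean_auc=np.nan, retained_folds=0,
                             excluded_folds=config.k))
            continue
        fold_aucs = []
        excluded = 0
        for fid in range(config.k):
            val = fold_ids == fid
            res = lda_fold_auc(feature[~val], labels[~val], feature[val], labels[val])
            if res == EXCLUDED:
                excluded += 1
            else:
                fold_aucs.append(res)
        rows.append(
            dict(
                percentile=p,
                mean_auc=float(np.mean(fold_aucs)) if fold_aucs else np.nan,
                retained_folds=len(fold_aucs),
                excluded_folds=excluded,
            )
        )
    return CVResult(table=pd.DataFrame(rows), k=config.k, seed=config.seed)
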