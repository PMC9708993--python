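"""Objective and subjective evaluation of synthesised nodules.

Objective arm: per-feature two-sample Kolmogorov-Smirnov comparison of
radiomic feature distributions between real and synthetic cohorts, and a
stratified fourfold cross-validated logistic-regression classifier whose
pooled ROC AUC measures how separable the cohorts are from radiomics alone.

Subjective arm: analytics for a visual Turing test in which readers rate
each nodule on a four-level scale (confidently fake, leaning fake, leaning
real, confidently real).  Ratings binarise to a real/fake call for the
confusion matrix and act as ordinal scores (0-3) for the reader ROC.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.preprocessing import StandardScaler

from .radiomics import FeatureVector

__all__ = [
    "ks_two_sample", "KSReport", "compare_cohorts", "reference_ks_table",
    "CVResult", "real_vs_fake_auc", "roc_auc",
    "VTTRecord", "VTTSummary", "vtt_summary", "read_vtt_csv",
    "RATING_LEVELS",
]

RATING_LEVELS = ("confidently fake", "leaning fake", "leaning real",
                 "confidently real")
_CALLED_REAL = {"leaning real", "confidently real"}


# --------------------------------------------------------------------------
# Kolmogorov-Smirnov
# --------------------------------------------------------------------------

def ks_two_sample(a, b, small_n: int = 10) -> tuple[float, float]:
    """Two-sample KS test: D = max |ECDF_a - ECDF_b| and its p-value.

    Uses the exact null distribution when both samples have at most
    ``small_n`` observations, the asymptotic Kolmogorov distribution
    otherwise.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    method = "exact" if max(a.size, b.size) <= small_n else "asymp"
    res = stats.ks_2samp(a, b, method=method)
    return float(res.statistic), float(res.pvalue)


@dataclass
class KSReport:
    """Per-feature KS outcomes sorted by descending p-value."""

    records: list[tuple[str, str, float, float]]  # (family, name, D, p)
    alpha: float = 0.05

    def __post_init__(self) -> None:
        self.records = sorted(self.records, key=lambda r: -r[3])

    @property
    def n_total(self) -> int:
        return len(self.records)

    @property
    def n_nonsignificant(self) -> int:
        return sum(1 for *_rest, p in self.records if p >= self.alpha)

    @property
    def fraction_nonsignificant(self) -> float:
        return self.n_nonsignificant / self.n_total

    def to_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["family", "feature", "D", "p_value"])
            writer.writerows(self.records)


def compare_cohorts(
    real: list[FeatureVector],
    synth: list[FeatureVector],
    alpha: float = 0.05,
) -> KSReport:
    """One KS test per radiomic feature between the two cohorts."""
    if len(real) < 2 or len(synth) < 2:
        raise ValueError("each cohort needs at least two feature vectors")
    keys = list(real[0].keys())
    for fv in [*real, *synth]:
        if set(fv.keys()) != set(keys):
            raise ValueError("cohorts must share identical feature keys")
    records = []
    for family, name in keys:
        a = np.array([fv[(family, name)] for fv in real])
        b = np.array([fv[(family, name)] for fv in synth])
        d, p = ks_two_sample(a, b)
        records.append((family, name, d, p))
    return KSReport(records=records, alpha=alpha)


def reference_ks_table() -> pd.DataFrame:
    """Published reference KS p-values for the 93 radiomic features
    comparing real and GAN-synthesised GGN cohorts (packaged data)."""
    with resources.files("ggnforge.data").joinpath(
        "reference_ks_pvalues.csv"
    ).open() as fh:
        return pd.read_csv(fh)


# --------------------------------------------------------------------------
# ROC / cross-validated classifier
# --------------------------------------------------------------------------

def roc_auc(scores, labels) -> float:
    """Trapezoidal ROC AUC with midrank tie handling (Mann-Whitney form)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must align")
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes must be present")
    return float(roc_auc_score(labels, scores))


@dataclass
class CVResult:
    fold_aucs: list[float]
    pooled_auc: float
    pooled_accuracy: float
    fold_assignment: dict[int, int]  # case index -> test fold


def real_vs_fake_auc(
    features: list[FeatureVector] | np.ndarray,
    labels,
    k: int = 4,
    seed: int = 0,
) -> CVResult:
    """Stratified k-fold logistic regression separating real from synthetic.

    Features are standardised on each training fold; held-out scores are
    pooled for the overall AUC and the accuracy at threshold 0.5.
    """
    if isinstance(features, list):
        keys = sorted(features[0].keys())
        X = np.array([[fv[key] for key in keys] for fv in features])
    else:
        X = np.asarray(features, dtype=float)
    y = np.asarray([1 if lab in (1, "synthetic", True) else 0 for lab in labels])
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    if np.bincount(y).min() < k:
        raise ValueError(f"need at least {k} cases of each class for {k} folds")

    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    pooled_scores = np.zeros(len(y))
    fold_aucs: list[float] = []
    fold_assignment: dict[int, int] = {}
    for fold, (train_idx, test_idx) in enumerate(skf.split(X, y)):
        scaler = StandardScaler().fit(X[train_idx])
        model = LogisticRegression(C=1e6, max_iter=5000)
        model.fit(scaler.transform(X[train_idx]), y[train_idx])
        s = model.predict_proba(scaler.transform(X[test_idx]))[:, 1]
        pooled_scores[test_idx] = s
        for i in test_idx:
            fold_assignment[int(i)] = fold
        if len(np.unique(y[test_idx])) == 2:
            fold_aucs.append(roc_auc(s, y[test_idx]))
    pooled_auc = roc_auc(pooled_scores, y)
    pooled_accuracy = float(np.mean((pooled_scores >= 0.5) == y))
    return CVResult(fold_aucs=fold_aucs, pooled_auc=pooled_auc,
                    pooled_accuracy=pooled_accuracy,
                    fold_assignment=fold_assignment)


# --------------------------------------------------------------------------
# Visual Turing test
# --------------------------------------------------------------------------

@dataclass
class VTTRecord:
    case_id: str
    truth: str            # "real" | "synthetic"
    rating: str           # one of RATING_LEVELS
    reader_id: str = ""

    def __post_init__(self) -> None:
        if self.truth not in ("real", "synthetic"):
            raise ValueError(f"unknown truth {self.truth!r}")
        if self.rating not in RATING_LEVELS:
            raise ValueError(f"unknown rating {self.rating!r}")

    @property
    def called_real(self) -> bool:
        return self.rating in _CALLED_REAL

    @property
    def score(self) -> int:
        return RATING_LEVELS.index(self.rating)


@dataclass
class VTTSummary:
    confusion: dict[tuple[str, str], int]     # (truth, call) -> count
    proportions: dict[str, dict[str, float]]  # truth -> rating -> fraction
    auc: float | None                         # None when one class only
    n_records: int

    def fraction_called_real(self, truth: str) -> float:
        called = sum(v for (t, call), v in self.confusion.items()
                     if t == truth and call == "real")
        total = sum(v for (t, _), v in self.confusion.items() if t == truth)
        return called / total if total else 0.0


def vtt_summary(records: list[VTTRecord]) -> VTTSummary:
    """Confusion counts, per-truth rating proportions, and reader ROC AUC.

    The ordinal rating (0 = confidently fake ... 3 = confidently real) is
    the reader's score; real is the positive class.  With only one truth
    class present the AUC is reported as None.
    """
    if not records:
        raise ValueError("no records")
    confusion: dict[tuple[str, str], int] = {}
    proportions: dict[str, dict[str, float]] = {}
    for truth in ("real", "synthetic"):
        subset = [r for r in records if r.truth == truth]
        if not subset:
            continue
        for call in ("real", "fake"):
            confusion[(truth, call)] = sum(
                1 for r in subset if r.called_real == (call == "real")
            )
        proportions[truth] = {
            level: sum(1 for r in subset if r.rating == level) / len(subset)
            for level in RATING_LEVELS
        }
    truths = {r.truth for r in records}
    if len(truths) == 2:
        auc = roc_auc([r.score for r in records],
                      [1 if r.truth == "real" else 0 for r in records])
    else:
        auc = None
    return VTTSummary(confusion=confusion, proportions=proportions,
                      auc=auc, n_records=len(records))


def read_vtt_csv(path: str | Path) -> list[VTTRecord]:
    """Ratings CSV with columns case_id, truth, rating, reader_id."""
    records = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            records.append(VTTRecord(
                case_id=row["case_id"], truth=row["truth"],
                rating=row["rating"], reader_id=row.get("reader_id", ""),
            ))
    return records
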