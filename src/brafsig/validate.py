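"""Performance estimation: LOOCV, threshold selection, confusion metrics,
pre-screen enrichment accounting.

LOOCV scores each sample with templates rebuilt on all other samples;
one global threshold is then chosen on the full LOOCV score vector by
maximizing overall accuracy under the strict-greater call rule.
Sensitivity and specificity are computed against sequenced BRAF status,
so "false positives" include wild-type tumors that genuinely belong to
the mutation-like expression subtype; :func:`expected_specificity`
encodes the enrichment-bias correction for cohorts whose collection was
pre-screened by signature score.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .centroid import (
    MUTATION_LIKE,
    WILDTYPE_LIKE,
    Metric,
    SignatureTemplatePair,
    _scores_matrix,
)
from .errors import ValidationError
from .io import ExpressionMatrix

__all__ = [
    "ConfusionSummary",
    "LoocvResult",
    "loocv_scores",
    "optimize_threshold",
    "confusion_metrics",
    "expected_specificity",
    "prescreen_select",
    "cohort_composition",
    "run_loocv",
]


@dataclass(frozen=True)
class ConfusionSummary:
    """2x2 confusion counts and derived rates.

    Positives are mutation-like calls; truth is sequenced BRAF status.
    """

    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @property
    def sensitivity(self) -> float:
        return self.tp / (self.tp + self.fn)

    @property
    def specificity(self) -> float:
        return self.tn / (self.tn + self.fp)

    @property
    def accuracy(self) -> float:
        return (self.tp + self.tn) / self.total

    @property
    def fraction_called_positive(self) -> float:
        return (self.tp + self.fp) / self.total

    def as_dict(self) -> dict:
        return {
            "tp": self.tp,
            "fp": self.fp,
            "fn": self.fn,
            "tn": self.tn,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "accuracy": self.accuracy,
            "fraction_called_positive": self.fraction_called_positive,
        }


@dataclass(frozen=True)
class LoocvResult:
    """Per-sample LOOCV scores, the accuracy-optimal threshold and the
    confusion table at that threshold."""

    scores: pd.Series  # index: sample ids
    threshold: float
    confusion: ConfusionSummary


def _check_labels(labels: Sequence[str]) -> np.ndarray:
    labels = np.asarray(labels, dtype=object)
    unknown = sorted(set(labels) - {"mutated", "wildtype"})
    if unknown:
        raise ValidationError(f"labels must be mutated/wildtype, got {unknown}")
    return labels


def loocv_scores(
    m: ExpressionMatrix, labels: Sequence[str], metric: Metric = "pearson"
) -> pd.Series:
    """Leave-one-out signature scores over a signature-aligned matrix.

    For each sample, both class templates are rebuilt from the remaining
    samples and the held-out sample is scored against them.  Class sums
    are precomputed so each fold is an O(genes) update, but the result is
    identical to an explicit per-fold rebuild.
    """
    labels = _check_labels(labels)
    if labels.shape[0] != m.shape[1]:
        raise ValidationError("one label per sample is required")
    values = m.values
    is_mut = labels == "mutated"
    n_mut, n_wt = int(is_mut.sum()), int((~is_mut).sum())
    if n_mut < 3 or n_wt < 3:
        raise ValidationError(
            "each class needs >= 3 samples so every fold keeps >= 2 per class"
        )
    sum_mut = values[:, is_mut].sum(axis=1)
    sum_wt = values[:, ~is_mut].sum(axis=1)

    out = np.empty(m.shape[1])
    for j, sid in enumerate(m.sample_ids):
        x = values[:, j]
        if is_mut[j]:
            mut_t = (sum_mut - x) / (n_mut - 1)
            wt_t = sum_wt / n_wt
        else:
            mut_t = sum_mut / n_mut
            wt_t = (sum_wt - x) / (n_wt - 1)
        try:
            templates = SignatureTemplatePair(tuple(m.gene_ids), mut_t, wt_t)
            out[j] = _scores_matrix(x[:, None], templates, metric)[0]
        except ValidationError as exc:
            raise ValidationError(f"sample {sid!r}: {exc}") from exc
    return pd.Series(out, index=m.sample_ids, name="score")


def _candidate_thresholds(scores: np.ndarray) -> np.ndarray:
    distinct = np.unique(scores)
    mids = (distinct[:-1] + distinct[1:]) / 2.0
    return np.concatenate(([distinct[0] - 1.0], mids, [distinct[-1] + 1.0]))


def optimize_threshold(scores: Sequence[float], labels: Sequence[str]) -> float:
    """Accuracy-optimal decision threshold under the strict-greater rule.

    Candidates are midpoints of adjacent distinct sorted scores plus one
    sentinel below the minimum and one above the maximum; among
    accuracy ties the lowest threshold is returned, making the search
    deterministic.
    """
    scores = np.asarray(scores, dtype=float)
    labels = _check_labels(labels)
    if scores.shape[0] != labels.shape[0]:
        raise ValidationError("scores and labels must have equal length")
    is_mut = labels == "mutated"
    if is_mut.sum() < 1 or (~is_mut).sum() < 1:
        raise ValidationError("at least one sample per class is required")
    best_thr, best_acc = np.nan, -1.0
    for thr in _candidate_thresholds(scores):
        acc = float(np.mean((scores > thr) == is_mut))
        if acc > best_acc:
            best_acc, best_thr = acc, thr
    return float(best_thr)


def confusion_metrics(calls: Sequence[str], labels: Sequence[str]) -> ConfusionSummary:
    """Tally a confusion table from class calls and sequenced labels."""
    calls = np.asarray(calls, dtype=object)
    labels = _check_labels(labels)
    if calls.shape[0] != labels.shape[0]:
        raise ValidationError("calls and labels must have equal length")
    bad = sorted(set(calls) - {MUTATION_LIKE, WILDTYPE_LIKE})
    if bad:
        raise ValidationError(f"calls must be {MUTATION_LIKE}/{WILDTYPE_LIKE}, got {bad}")
    pos = calls == MUTATION_LIKE
    mut = labels == "mutated"
    return ConfusionSummary(
        tp=int(np.sum(pos & mut)),
        fp=int(np.sum(pos & ~mut)),
        fn=int(np.sum(~pos & mut)),
        tn=int(np.sum(~pos & ~mut)),
    )


def expected_specificity(n_mut: int, n_wt: int) -> float:
    """Enrichment-bias specificity estimate, ``1 - n_mut / n_wt``.

    When a cohort is pre-screened by signature score, the wild-type
    mutation-like prevalence is assumed to rise to the same (enriched)
    level as the mutant prevalence; the expected specificity is then one
    minus the ratio of mutant to wild-type counts.
    """
    if n_wt <= 0:
        raise ValidationError("n_wt must be positive")
    return 1.0 - n_mut / n_wt


def run_loocv(
    m: ExpressionMatrix, labels: Sequence[str], metric: Metric = "pearson"
) -> LoocvResult:
    """LOOCV scores, accuracy-optimal threshold, and confusion at that threshold."""
    scores = loocv_scores(m, labels, metric)
    threshold = optimize_threshold(scores.to_numpy(), labels)
    calls = np.where(scores.to_numpy() > threshold, MUTATION_LIKE, WILDTYPE_LIKE)
    return LoocvResult(
        scores=scores,
        threshold=threshold,
        confusion=confusion_metrics(calls, labels),
    )


def prescreen_select(
    scores: pd.Series, k_top: int, k_random: int, seed: int
) -> list[str]:
    """Pre-screen cohort selection: score-ranked top plus a random rest.

    Takes the ``k_top`` samples with the highest scores (descending;
    ties broken by input order) and ``k_random`` samples drawn uniformly
    without replacement from the remainder.  Deterministic under
    ``seed``.  Returns the selected sample ids, top block first.
    """
    if k_top < 0 or k_random < 0:
        raise ValidationError("k_top and k_random must be >= 0")
    if k_top + k_random > len(scores):
        raise ValidationError(
            f"k_top + k_random = {k_top + k_random} exceeds pool size {len(scores)}"
        )
    vals = scores.to_numpy(dtype=float)
    if not np.all(np.isfinite(vals)):
        raise ValidationError("scores must be finite")
    order = np.argsort(-vals, kind="stable")
    top_ids = [str(scores.index[i]) for i in order[:k_top]]
    remainder = [str(scores.index[i]) for i in order[k_top:]]
    rng = np.random.default_rng(seed)
    random_ids = [remainder[i] for i in sorted(rng.choice(len(remainder), size=k_random, replace=False))]
    return top_ids + random_ids


def cohort_composition(annotations: pd.DataFrame) -> pd.DataFrame:
    """Mutant counts and fractions per cohort_tag plus an overall row.

    Returns a frame indexed by cohort tag (with a final ``total`` row)
    with columns ``n``, ``n_mutated`` and ``fraction_mutated``.
    """
    if "cohort_tag" not in annotations.columns or "braf_status" not in annotations.columns:
        raise ValidationError("annotations need cohort_tag and braf_status columns")
    rows = []
    for tag, grp in annotations.groupby("cohort_tag", sort=False):
        n_mut = int((grp["braf_status"] == "mutated").sum())
        rows.append({"cohort_tag": tag, "n": len(grp), "n_mutated": n_mut})
    n_mut_total = int((annotations["braf_status"] == "mutated").sum())
    rows.append({"cohort_tag": "total", "n": len(annotations), "n_mutated": n_mut_total})
    out = pd.DataFrame(rows).set_index("cohort_tag")
    out["fraction_mutated"] = out["n_mutated"] / out["n"]
    return out
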