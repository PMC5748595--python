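"""Two-template nearest-centroid scoring.

The classifier keeps one centroid (template) per class: the per-gene
mean log2 expression of the BRAF-mutated training samples and of the
wild-type training samples, over the signature genes.  A sample's
signature score is

    score(x) = cor(x, template_mut) - cor(x, template_wt)

with ``cor`` the Pearson correlation over the signature genes (cosine
similarity is available as an alternative metric).  Scores therefore lie
in [-2, 2]; a sample is called *mutation-like* when its score is
strictly greater than the decision threshold, *wildtype-like*
otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError
from .io import ExpressionMatrix

__all__ = [
    "SignatureTemplatePair",
    "ScoredCohort",
    "build_templates",
    "score_sample",
    "score_cohort",
    "read_templates",
    "write_templates",
    "MUTATION_LIKE",
    "WILDTYPE_LIKE",
]

MUTATION_LIKE = "mutation_like"
WILDTYPE_LIKE = "wildtype_like"

Metric = Literal["pearson", "cosine"]


@dataclass(frozen=True)
class SignatureTemplatePair:
    """Class centroids over the signature genes, in signature order."""

    gene_ids: tuple[str, ...]
    mut_template: np.ndarray
    wt_template: np.ndarray

    def __post_init__(self) -> None:
        mut = np.asarray(self.mut_template, dtype=float)
        wt = np.asarray(self.wt_template, dtype=float)
        n = len(self.gene_ids)
        if mut.shape != (n,) or wt.shape != (n,):
            raise ValidationError("template length must match the number of signature genes")
        if not (np.all(np.isfinite(mut)) and np.all(np.isfinite(wt))):
            raise ValidationError("templates must be finite")
        if np.allclose(mut, wt):
            raise ValidationError("mutation and wild-type templates are identical")
        object.__setattr__(self, "mut_template", mut)
        object.__setattr__(self, "wt_template", wt)


@dataclass(frozen=True)
class ScoredCohort:
    """Per-sample signature scores and class calls at a fixed threshold."""

    scores: pd.DataFrame  # columns: sample_id, score, call
    threshold: float

    @property
    def score_values(self) -> np.ndarray:
        return self.scores["score"].to_numpy()

    @property
    def calls(self) -> np.ndarray:
        return self.scores["call"].to_numpy()


def _center_norm(v: np.ndarray, metric: Metric, what: str) -> np.ndarray:
    if metric == "pearson":
        v = v - v.mean()
    norm = float(np.linalg.norm(v))
    if norm == 0.0:
        raise ValidationError(f"{what} has zero variance; correlation undefined")
    return v / norm


def build_templates(
    m: ExpressionMatrix, labels: Sequence[str]
) -> SignatureTemplatePair:
    """Per-gene class means over a signature-aligned training matrix.

    ``labels`` gives the sequenced BRAF status per sample, aligned to the
    matrix columns; every training label must be ``mutated`` or
    ``wildtype`` and each class needs at least 2 samples.  Templates are
    unweighted means; no gene standardization is applied.
    """
    labels = np.asarray(labels, dtype=object)
    if labels.shape[0] != m.shape[1]:
        raise ValidationError("one label per sample is required")
    unknown = sorted(set(labels) - {"mutated", "wildtype"})
    if unknown:
        raise ValidationError(f"training labels must be mutated/wildtype, got {unknown}")
    values = m.values
    templates: dict[str, np.ndarray] = {}
    for cls in ("mutated", "wildtype"):
        mask = labels == cls
        if mask.sum() < 2:
            raise ValidationError(f"class {cls!r} has fewer than 2 training samples")
        templates[cls] = values[:, mask].mean(axis=1)
    return SignatureTemplatePair(
        gene_ids=tuple(m.gene_ids),
        mut_template=templates["mutated"],
        wt_template=templates["wildtype"],
    )


def score_sample(
    x: np.ndarray | pd.Series, t: SignatureTemplatePair, metric: Metric = "pearson"
) -> float:
    """Correlation-difference score of one expression vector.

    Returns ``cor(x, mut_template) - cor(x, wt_template)``; the result
    lies in [-2, 2].  Raises if the vector or a template is constant
    (Pearson correlation undefined).
    """
    x = np.asarray(x, dtype=float)
    if x.shape != (len(t.gene_ids),):
        raise ValidationError(
            f"expression vector length {x.shape} does not match template length {len(t.gene_ids)}"
        )
    if not np.all(np.isfinite(x)):
        raise ValidationError("expression vector contains non-finite values")
    xn = _center_norm(x, metric, "expression vector")
    mutn = _center_norm(t.mut_template.copy(), metric, "mutation template")
    wtn = _center_norm(t.wt_template.copy(), metric, "wild-type template")
    return float(xn @ mutn - xn @ wtn)


def _scores_matrix(values: np.ndarray, t: SignatureTemplatePair, metric: Metric) -> np.ndarray:
    """Vectorized correlation-difference scores for a genes x samples array."""
    X = values.astype(float)
    if metric == "pearson":
        X = X - X.mean(axis=0, keepdims=True)
    norms = np.linalg.norm(X, axis=0)
    if np.any(norms == 0.0):
        raise ValidationError("sample with zero variance; correlation undefined")
    Xn = X / norms
    mutn = _center_norm(t.mut_template.copy(), metric, "mutation template")
    wtn = _center_norm(t.wt_template.copy(), metric, "wild-type template")
    return Xn.T @ (mutn - wtn)


def score_cohort(
    m: ExpressionMatrix,
    t: SignatureTemplatePair,
    threshold: float,
    metric: Metric = "pearson",
) -> ScoredCohort:
    """Score every sample of a signature-aligned matrix and call classes.

    The boundary rule is strict: call = mutation_like iff score >
    threshold.  Scoring errors are re-raised with the offending sample
    id attached.
    """
    if tuple(m.gene_ids) != tuple(t.gene_ids):
        raise ValidationError("matrix gene order does not match template gene order")
    try:
        scores = _scores_matrix(m.values, t, metric)
    except ValidationError:
        # fall back to the per-sample path to name the offending sample
        scores = np.empty(m.shape[1])
        for j, sid in enumerate(m.sample_ids):
            try:
                scores[j] = score_sample(m.values[:, j], t, metric)
            except ValidationError as exc:
                raise ValidationError(f"sample {sid!r}: {exc}") from exc
    calls = np.where(scores > threshold, MUTATION_LIKE, WILDTYPE_LIKE)
    df = pd.DataFrame({"sample_id": m.sample_ids, "score": scores, "call": calls})
    return ScoredCohort(scores=df, threshold=float(threshold))


def write_templates(t: SignatureTemplatePair, path: str | Path) -> None:
    pd.DataFrame(
        {"gene_id": t.gene_ids, "mut_template": t.mut_template, "wt_template": t.wt_template}
    ).to_csv(Path(path), sep="\t", index=False, lineterminator="\n")


def read_templates(path: str | Path) -> SignatureTemplatePair:
    df = pd.read_csv(Path(path), sep="\t")
    return SignatureTemplatePair(
        gene_ids=tuple(df["gene_id"].astype(str)),
        mut_template=df["mut_template"].to_numpy(dtype=float),
        wt_template=df["wt_template"].to_numpy(dtype=float),
    )
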