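"""Paired fresh-frozen / FFPE concordance analysis.

Pairs failing sample-quality criteria (low tumor-cell percentage, low
microarray signal) are excluded first.  FFPE scores falling inside the
borderline region around the FFPE threshold are then set aside, and
agreement is the fraction of remaining pairs whose fresh-frozen and
FFPE class calls coincide.  Pearson r between the paired scores is
reported over all kept (post-exclusion) pairs, before borderline
filtering.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .centroid import MUTATION_LIKE, WILDTYPE_LIKE
from .errors import ValidationError
from .stability import BorderlineRegion

__all__ = ["ConcordanceReport", "apply_exclusions", "concordance_report"]

PAIR_COLUMNS = ("sample_id", "ff_score", "ffpe_score")


@dataclass(frozen=True)
class ConcordanceReport:
    """Outcome of the paired fresh-frozen vs FFPE comparison."""

    n_pairs: int
    n_excluded_low_tumor: int
    n_excluded_low_signal: int
    n_outside_borderline: int
    n_switched: int
    agreement: float  # NaN when no pair lies outside the borderline region
    pearson_r: float
    pairs: pd.DataFrame  # per-pair scores, calls, in_borderline, switched

    @property
    def agreement_defined(self) -> bool:
        return self.n_outside_borderline > 0

    def as_dict(self) -> dict:
        return {
            "n_pairs": self.n_pairs,
            "n_excluded_low_tumor": self.n_excluded_low_tumor,
            "n_excluded_low_signal": self.n_excluded_low_signal,
            "n_outside_borderline": self.n_outside_borderline,
            "n_switched": self.n_switched,
            "agreement": self.agreement,
            "pearson_r": self.pearson_r,
        }


def _check_pairs(pairs: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in PAIR_COLUMNS if c not in pairs.columns]
    if missing:
        raise ValidationError(f"paired-score table missing column(s): {', '.join(missing)}")
    return pairs


def apply_exclusions(
    pairs: pd.DataFrame,
    annotations: pd.DataFrame,
    min_tumor_pct: float = 30.0,
    min_signal: float = float("-inf"),
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Drop pairs failing sample-quality criteria; tally by reason.

    Tumor percentage is checked first, so a sample failing both
    criteria is counted once, under low tumor.  ``annotations`` must
    carry ``tumor_pct`` for every paired sample and, when
    ``min_signal`` is finite, a ``signal`` column (e.g. mean log2
    intensity).  A missing tumor percentage (NaN) is treated as
    unknown and is not excluded.
    """
    pairs = _check_pairs(pairs)
    ann = annotations.set_index(annotations["sample_id"].astype(str))
    missing = [s for s in pairs["sample_id"].astype(str) if s not in ann.index]
    if missing:
        raise ValidationError(f"no annotation for sample(s): {', '.join(missing)}")
    use_signal = np.isfinite(min_signal)
    if use_signal and "signal" not in ann.columns:
        raise ValidationError("min_signal requires a 'signal' column in the annotations")

    keep_rows, n_low_tumor, n_low_signal = [], 0, 0
    for _, row in pairs.iterrows():
        meta = ann.loc[str(row["sample_id"])]
        tumor = meta["tumor_pct"]
        if pd.notna(tumor) and float(tumor) < min_tumor_pct:
            n_low_tumor += 1
            continue
        if use_signal and float(meta["signal"]) < min_signal:
            n_low_signal += 1
            continue
        keep_rows.append(row)
    kept = pd.DataFrame(keep_rows, columns=pairs.columns).reset_index(drop=True)
    return kept, {"low_tumor": n_low_tumor, "low_signal": n_low_signal}


def concordance_report(
    pairs: pd.DataFrame,
    ff_threshold: float,
    ffpe_threshold: float,
    region: BorderlineRegion,
    exclusions: dict[str, int] | None = None,
) -> ConcordanceReport:
    """Switch counting and agreement over non-borderline pairs.

    Class calls use the strict-greater rule against each channel's own
    threshold; the borderline region applies to the FFPE score only,
    with inclusive edges.  ``agreement = 1 - n_switched /
    n_outside_borderline`` and is NaN (flagged via
    ``agreement_defined``) when every pair is borderline.
    """
    pairs = _check_pairs(pairs).copy()
    if abs(region.threshold - ffpe_threshold) > 1e-12:
        raise ValidationError("borderline region must be centred on the FFPE threshold")
    ff = pairs["ff_score"].to_numpy(dtype=float)
    ffpe = pairs["ffpe_score"].to_numpy(dtype=float)
    pairs["ff_call"] = np.where(ff > ff_threshold, MUTATION_LIKE, WILDTYPE_LIKE)
    pairs["ffpe_call"] = np.where(ffpe > ffpe_threshold, MUTATION_LIKE, WILDTYPE_LIKE)
    pairs["in_borderline"] = region.contains(ffpe)
    outside = ~pairs["in_borderline"].to_numpy()
    switched = (pairs["ff_call"] != pairs["ffpe_call"]).to_numpy() & outside
    pairs["switched"] = switched
    n_outside = int(outside.sum())
    n_switched = int(switched.sum())
    agreement = 1.0 - n_switched / n_outside if n_outside > 0 else float("nan")
    if len(pairs) >= 2 and np.std(ff) > 0 and np.std(ffpe) > 0:
        r = float(stats.pearsonr(ff, ffpe).statistic)
    else:
        r = float("nan")
    exclusions = exclusions or {}
    return ConcordanceReport(
        n_pairs=len(pairs),
        n_excluded_low_tumor=int(exclusions.get("low_tumor", 0)),
        n_excluded_low_signal=int(exclusions.get("low_signal", 0)),
        n_outside_borderline=n_outside,
        n_switched=n_switched,
        agreement=agreement,
        pearson_r=r,
        pairs=pairs,
    )
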