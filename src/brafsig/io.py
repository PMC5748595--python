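"""Reading, writing and validation of the three tabular inputs.

The package works on three plain-text artifacts:

* an expression matrix — TSV/CSV, genes as rows, samples as columns,
  first column gene identifiers, header row sample identifiers.  Values
  are assumed to be log2-transformed, normalized intensities; no
  normalization or imputation is performed here and missing values are
  rejected.
* a signature gene list — two-column TSV ``gene_id<TAB>direction`` with
  direction ``up`` or ``down`` (the direction of regulation in the
  mutation-like subtype).
* a sample annotation table — TSV with columns ``sample_id``,
  ``braf_status`` (mutated / wildtype / unknown), ``tumor_pct``,
  ``cohort_tag``, ``msi_status`` and optionally extra numeric columns
  such as ``signal``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from .errors import ParseError, ValidationError

__all__ = [
    "ExpressionMatrix",
    "SignatureGeneSet",
    "read_matrix",
    "write_matrix",
    "read_signature",
    "write_signature",
    "read_annotations",
    "write_annotations",
    "validate_annotations",
    "align_to_signature",
    "BRAF_STATUSES",
    "MSI_STATUSES",
]

BRAF_STATUSES = ("mutated", "wildtype", "unknown")
MSI_STATUSES = ("MSI", "MSS", "unknown")

ANNOTATION_COLUMNS = ("sample_id", "braf_status", "tumor_pct", "cohort_tag", "msi_status")


def _find_duplicates(ids: Sequence[str]) -> list[str]:
    seen: set[str] = set()
    dups: list[str] = []
    for x in ids:
        if x in seen and x not in dups:
            dups.append(x)
        seen.add(x)
    return dups


@dataclass(frozen=True)
class ExpressionMatrix:
    """Log2 expression values, genes as rows and samples as columns.

    Wraps a :class:`pandas.DataFrame` whose index holds gene identifiers
    and whose columns hold sample identifiers.  Construction validates
    uniqueness of identifiers and finiteness of every value.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        if df.shape[0] < 1 or df.shape[1] < 1:
            raise ValidationError("expression matrix must have at least one gene and one sample")
        dup_genes = _find_duplicates(list(df.index))
        if dup_genes:
            raise ValidationError(f"duplicate gene identifier(s): {', '.join(dup_genes)}")
        dup_samples = _find_duplicates(list(df.columns))
        if dup_samples:
            raise ValidationError(f"duplicate sample identifier(s): {', '.join(dup_samples)}")
        values = df.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise ValidationError("expression matrix contains non-numeric values")
        if not np.all(np.isfinite(values)):
            bad = np.argwhere(~np.isfinite(values))[0]
            raise ValidationError(
                f"non-finite value at gene {df.index[bad[0]]!r}, sample {df.columns[bad[1]]!r}"
            )

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        """Dense float array, shape (n_genes, n_samples)."""
        return self.data.to_numpy(dtype=float)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def subset_samples(self, sample_ids: Sequence[str]) -> "ExpressionMatrix":
        missing = [s for s in sample_ids if s not in self.data.columns]
        if missing:
            raise ValidationError(f"unknown sample identifier(s): {', '.join(missing)}")
        return ExpressionMatrix(self.data.loc[:, list(sample_ids)])


@dataclass(frozen=True)
class SignatureGeneSet:
    """Ordered signature gene list with per-gene regulation direction.

    ``entries`` is a sequence of ``(gene_id, direction)`` pairs where
    direction is ``"up"`` (higher in the mutation-like subtype) or
    ``"down"``.  Any length >= 2 is accepted; the canonical signature
    has 58 genes.
    """

    entries: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        if len(self.entries) < 2:
            raise ValidationError("signature must contain at least 2 genes")
        genes = [g for g, _ in self.entries]
        dups = _find_duplicates(genes)
        if dups:
            raise ValidationError(f"duplicate signature gene(s): {', '.join(dups)}")
        for g, d in self.entries:
            if d not in ("up", "down"):
                raise ValidationError(f"invalid direction {d!r} for gene {g!r} (expected up/down)")

    @property
    def gene_ids(self) -> list[str]:
        return [g for g, _ in self.entries]

    @property
    def directions(self) -> np.ndarray:
        """+1 for up-regulated genes, -1 for down-regulated, in signature order."""
        return np.array([1.0 if d == "up" else -1.0 for _, d in self.entries])

    def __len__(self) -> int:
        return len(self.entries)

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[str, str]]) -> "SignatureGeneSet":
        return cls(tuple((str(g), str(d)) for g, d in pairs))


def _sep_for(dialect: str) -> str:
    if dialect not in ("tsv", "csv"):
        raise ValueError(f"unknown dialect {dialect!r} (expected 'tsv' or 'csv')")
    return "\t" if dialect == "tsv" else ","


def read_matrix(path: str | Path, dialect: Literal["tsv", "csv"] = "tsv") -> ExpressionMatrix:
    """Read an expression matrix; first column gene ids, header sample ids.

    Row and column order are preserved from the file.  Duplicated
    identifiers and non-numeric cells raise with the offending
    coordinate named.
    """
    path = Path(path)
    sep = _sep_for(dialect)
    try:
        df = pd.read_csv(path, sep=sep, index_col=0, dtype=str)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise ParseError(f"cannot parse {path}: {exc}") from exc
    if df.shape[1] == 0:
        raise ParseError(f"{path}: no sample columns found")
    numeric = pd.DataFrame(index=df.index, columns=df.columns, dtype=float)
    for col in df.columns:
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna() & df[col].notna()
        if bad.any():
            gene = df.index[bad.to_numpy().argmax()]
            raise ParseError(f"{path}: non-numeric value at gene {gene!r}, sample {col!r}")
        numeric[col] = converted
    numeric.index = numeric.index.astype(str)
    numeric.columns = numeric.columns.astype(str)
    return ExpressionMatrix(numeric)


def write_matrix(m: ExpressionMatrix, path: str | Path, dialect: Literal["tsv", "csv"] = "tsv") -> None:
    """Write a matrix in the canonical form read back by :func:`read_matrix`."""
    sep = _sep_for(dialect)
    m.data.to_csv(Path(path), sep=sep, index_label="gene_id", lineterminator="\n")


def read_signature(path: str | Path) -> SignatureGeneSet:
    """Read a two-column (gene_id, direction) TSV, no header."""
    path = Path(path)
    pairs: list[tuple[str, str]] = []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise ParseError(f"{path}:{lineno}: expected 'gene_id<TAB>direction', got {line!r}")
        pairs.append((parts[0], parts[1]))
    return SignatureGeneSet.from_pairs(pairs)


def write_signature(s: SignatureGeneSet, path: str | Path) -> None:
    Path(path).write_text("".join(f"{g}\t{d}\n" for g, d in s.entries))


def validate_annotations(df: pd.DataFrame) -> pd.DataFrame:
    """Validate a sample annotation table; returns the (typed) table.

    Requires the columns of the annotation schema, unique sample ids,
    braf_status / msi_status from their enumerated sets and tumor_pct in
    [0, 100] or missing (NaN).
    """
    missing_cols = [c for c in ANNOTATION_COLUMNS if c not in df.columns]
    if missing_cols:
        raise ValidationError(f"annotation table missing column(s): {', '.join(missing_cols)}")
    dups = _find_duplicates(list(df["sample_id"].astype(str)))
    if dups:
        raise ValidationError(f"duplicate sample_id(s) in annotations: {', '.join(dups)}")
    bad_braf = sorted(set(df["braf_status"]) - set(BRAF_STATUSES))
    if bad_braf:
        raise ValidationError(f"invalid braf_status value(s): {bad_braf}")
    bad_msi = sorted(set(df["msi_status"]) - set(MSI_STATUSES))
    if bad_msi:
        raise ValidationError(f"invalid msi_status value(s): {bad_msi}")
    tumor = pd.to_numeric(df["tumor_pct"], errors="coerce")
    known = tumor.notna()
    if ((tumor[known] < 0) | (tumor[known] > 100)).any():
        raise ValidationError("tumor_pct values must lie in [0, 100]")
    out = df.copy()
    out["sample_id"] = out["sample_id"].astype(str)
    out["tumor_pct"] = tumor
    return out


def read_annotations(path: str | Path, dialect: Literal["tsv", "csv"] = "tsv") -> pd.DataFrame:
    sep = _sep_for(dialect)
    try:
        df = pd.read_csv(Path(path), sep=sep)
    except Exception as exc:  # pragma: no cover
        raise ParseError(f"cannot parse {path}: {exc}") from exc
    return validate_annotations(df)


def write_annotations(df: pd.DataFrame, path: str | Path, dialect: Literal["tsv", "csv"] = "tsv") -> None:
    sep = _sep_for(dialect)
    df.to_csv(Path(path), sep=sep, index=False, lineterminator="\n")


def align_to_signature(
    m: ExpressionMatrix, s: SignatureGeneSet, max_missing: int = 0
) -> ExpressionMatrix:
    """Restrict a matrix to the signature genes, rows in signature order.

    In strict mode (``max_missing=0``, the default) every signature gene
    must be present; otherwise up to ``max_missing`` absent genes are
    tolerated and silently dropped from the output.
    """
    present = set(m.data.index)
    missing = [g for g in s.gene_ids if g not in present]
    if len(missing) > max_missing:
        raise ValidationError(
            f"{len(missing)} signature gene(s) absent from matrix: {', '.join(missing)}"
        )
    keep = [g for g in s.gene_ids if g in present]
    return ExpressionMatrix(m.data.loc[keep])
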