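"""Shared domain types, file readers/writers and correlation primitives.

The whole pipeline operates on three tabular objects:

* :class:`ExpressionMatrix` — transcript × sample TPM values, with a
  transcript → gene map derived from the alternative-transcript suffix
  convention (``GeneName-1``, ``GeneName-2`` or ``GeneName_1`` …).
* :class:`TraitTable` — sample × metabolite contents.  For ginseng roots the
  traits are the nine mono-ginsenosides (Rg1, Re, Rf, Rb1, Rg2, Rc, Rb2, Rb3,
  Rd) plus the total ``TS``, which must equal the row-wise sum of the monos.
* correlation results linking the two.

Significance of a Pearson correlation is computed through the classical
t transform ``t = r * sqrt((n - 2) / (1 - r**2))`` referred to Student's t
with ``n - 2`` degrees of freedom, two-tailed.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

#: The nine mono-ginsenoside trait names, in conventional report order.
MONO_TRAITS: tuple[str, ...] = (
    "Rg1", "Re", "Rf", "Rb1", "Rg2", "Rc", "Rb2", "Rb3", "Rd",
)
#: Name of the total-ginsenoside column (sum of the nine monos).
TOTAL_TRAIT = "TS"
#: Full default trait order.
DEFAULT_TRAITS: tuple[str, ...] = MONO_TRAITS + (TOTAL_TRAIT,)

#: Relative tolerance for the "total equals sum of monos" check.
TS_SUM_RTOL = 1e-9


class ValidationError(ValueError):
    """Raised when an input table violates a structural invariant."""


class DegenerateInputError(ValueError):
    """Raised for inputs on which a statistic is undefined (e.g. zero variance)."""


_SUFFIX_RE = re.compile(r"^(?P<gene>.+?)[-_](?P<k>\d+)$")


def gene_of_transcript(transcript_id: str) -> str:
    """Map a transcript id to its gene id by the suffix convention.

    ``PgCYP274-1`` and ``PgCYP274-2`` both map to ``PgCYP274``; an id without
    a trailing ``-<int>`` / ``_<int>`` suffix is its own gene.
    """
    m = _SUFFIX_RE.match(transcript_id)
    return m.group("gene") if m else transcript_id


def _check_numeric_frame(df: pd.DataFrame, what: str) -> None:
    arr = df.to_numpy()
    if not np.issubdtype(arr.dtype, np.number):
        raise ValidationError(f"{what} contains non-numeric values")
    if np.isnan(arr).any():
        r, c = np.argwhere(np.isnan(arr))[0]
        raise ValidationError(
            f"{what} contains a missing value at row {df.index[r]!r}, "
            f"column {df.columns[c]!r}; missing data are not supported"
        )
    if (arr < 0).any():
        r, c = np.argwhere(arr < 0)[0]
        raise ValidationError(
            f"{what} contains a negative value ({arr[r, c]!r}) at "
            f"row {df.index[r]!r}, column {df.columns[c]!r}"
        )


@dataclass
class ExpressionMatrix:
    """Transcript × sample TPM matrix with a transcript → gene map.

    Parameters
    ----------
    data
        DataFrame indexed by transcript id, one column per sample, values
        non-negative TPM.
    gene_of
        Mapping from every transcript id to its gene id.  If omitted it is
        derived from the transcript-id suffix convention.
    """

    data: pd.DataFrame
    gene_of: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            dup = self.data.index[self.data.index.duplicated()][0]
            raise ValidationError(f"duplicate transcript id {dup!r}")
        self.data = self.data.astype(float)
        self.data.index.name = None
        self.data.columns.name = None
        _check_numeric_frame(self.data, "expression matrix")
        if not self.gene_of:
            self.gene_of = {t: gene_of_transcript(t) for t in self.data.index}
        missing = set(self.data.index) - set(self.gene_of)
        if missing:
            raise ValidationError(
                f"no gene mapping for transcripts: {sorted(missing)[:5]}"
            )

    # -- accessors ---------------------------------------------------------
    @property
    def transcript_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def samples(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def genes(self) -> list[str]:
        """Distinct gene ids, in first-appearance order."""
        seen: dict[str, None] = {}
        for t in self.data.index:
            seen.setdefault(self.gene_of[t], None)
        return list(seen)

    def transcripts_of_gene(self, gene_id: str) -> list[str]:
        return [t for t in self.data.index if self.gene_of[t] == gene_id]

    def subset(self, transcript_ids: Sequence[str]) -> "ExpressionMatrix":
        missing = [t for t in transcript_ids if t not in self.data.index]
        if missing:
            raise ValidationError(f"unknown transcripts: {missing[:5]}")
        return ExpressionMatrix(
            self.data.loc[list(transcript_ids)].copy(),
            {t: self.gene_of[t] for t in transcript_ids},
        )

    # -- IO ----------------------------------------------------------------
    @classmethod
    def from_tsv(
        cls, path: str | Path, gene_map_path: str | Path | None = None
    ) -> "ExpressionMatrix":
        """Read a TSV with transcript ids in the first column and a sample
        header row; an optional two-column sidecar maps transcript → gene."""
        df = pd.read_csv(path, sep="\t", index_col=0)
        df.index = df.index.astype(str)
        gene_of: dict[str, str] = {}
        if gene_map_path is not None:
            gm = pd.read_csv(gene_map_path, sep="\t", header=None, dtype=str)
            gene_of = dict(zip(gm.iloc[:, 0], gm.iloc[:, 1]))
        return cls(df, gene_of)

    def to_tsv(self, path: str | Path) -> None:
        self.data.to_csv(path, sep="\t", index_label="transcript_id")


@dataclass
class TraitTable:
    """Sample × trait metabolite contents.

    If a total column (``TS``) is present it must equal the row-wise sum of
    the remaining trait columns to within relative tolerance ``1e-9``; if it
    is absent it can be appended with :meth:`with_total`.
    """

    data: pd.DataFrame
    total_column: str = TOTAL_TRAIT

    def __post_init__(self) -> None:
        self.data = self.data.astype(float)
        self.data.index.name = None
        self.data.columns.name = None
        if self.data.index.has_duplicates:
            dup = self.data.index[self.data.index.duplicated()][0]
            raise ValidationError(f"duplicate sample id {dup!r}")
        _check_numeric_frame(self.data, "trait table")
        if self.total_column in self.data.columns:
            monos = self.data.drop(columns=[self.total_column])
            expected = monos.sum(axis=1).to_numpy()
            got = self.data[self.total_column].to_numpy()
            if not np.allclose(got, expected, rtol=TS_SUM_RTOL, atol=0.0):
                bad = self.data.index[
                    ~np.isclose(got, expected, rtol=TS_SUM_RTOL, atol=0.0)
                ][0]
                raise ValidationError(
                    f"total column {self.total_column!r} is not the sum of the "
                    f"mono traits for sample {bad!r}"
                )

    @property
    def samples(self) -> list[str]:
        return list(self.data.index)

    @property
    def traits(self) -> list[str]:
        return list(self.data.columns)

    @property
    def mono_traits(self) -> list[str]:
        return [c for c in self.data.columns if c != self.total_column]

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    def with_total(self) -> "TraitTable":
        """Return a table that includes the total column (computed if absent)."""
        if self.total_column in self.data.columns:
            return self
        df = self.data.copy()
        df[self.total_column] = df.sum(axis=1)
        return TraitTable(df, self.total_column)

    @classmethod
    def from_tsv(cls, path: str | Path, compute_total: bool = True) -> "TraitTable":
        df = pd.read_csv(path, sep="\t", index_col=0)
        df.index = df.index.astype(str)
        tt = cls(df)
        return tt.with_total() if compute_total else tt

    def to_tsv(self, path: str | Path) -> None:
        self.data.to_csv(path, sep="\t", index_label="sample_id")


@dataclass(frozen=True)
class CorrelationResult:
    """A single transcript–trait correlation with its two-tailed p-value."""

    transcript_id: str
    gene_id: str
    trait: str
    r: float
    n: int
    p: float


def check_matched_samples(expr: ExpressionMatrix, traits: TraitTable) -> list[str]:
    """Validate that both tables describe the same samples; return the order
    used downstream (the expression-matrix order)."""
    a, b = set(expr.samples), set(traits.samples)
    if a != b:
        diff = sorted(a.symmetric_difference(b))
        raise ValidationError(
            f"sample sets differ between expression and trait tables; "
            f"symmetric difference: {diff}"
        )
    return expr.samples


# ---------------------------------------------------------------------------
# correlation primitives
# ---------------------------------------------------------------------------

def pearson_r(x: Sequence[float], y: Sequence[float]) -> float:
    """Sample Pearson correlation of two equal-length vectors (n >= 3)."""
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.shape != ya.shape or xa.ndim != 1:
        raise ValidationError("pearson_r requires two equal-length 1-D vectors")
    if xa.size < 3:
        raise ValidationError("pearson_r requires n >= 3")
    xc = xa - xa.mean()
    yc = ya - ya.mean()
    nx = float(np.sqrt(np.dot(xc, xc)))
    ny = float(np.sqrt(np.dot(yc, yc)))
    if nx == 0.0 or ny == 0.0:
        raise DegenerateInputError("zero-variance vector has no defined correlation")
    r = float(np.dot(xc, yc) / (nx * ny))
    return max(-1.0, min(1.0, r))


def correlation_p(r: float, n: int) -> float:
    """Two-tailed p-value of a Pearson correlation via the t transform.

    ``t = r * sqrt((n - 2) / (1 - r**2))`` with ``n - 2`` degrees of freedom.
    ``|r| == 1`` returns the smallest positive float (perfect correlation).
    """
    if n < 3:
        raise ValidationError("correlation_p requires n >= 3")
    if abs(r) > 1.0:
        raise ValidationError("|r| must be <= 1")
    if abs(r) == 1.0:
        logger.info("correlation_p: |r| == 1, returning p-value floor")
        return float(np.nextafter(0.0, 1.0))
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    return float(2.0 * stats.t.sf(abs(t), n - 2))


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Bonferroni-corrected per-test threshold ``alpha / m``."""
    if not 0.0 < alpha < 1.0:
        raise ValidationError("alpha must lie in (0, 1)")
    if m < 1:
        raise ValidationError("m must be >= 1")
    return alpha / m


def pairwise_correlations(
    X: np.ndarray, Y: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Pearson r and two-tailed p for every row of ``X`` against every row of
    ``Y`` (both shaped features × samples, same sample count n >= 3).

    Zero-variance rows yield ``nan`` r and p; callers decide the skip policy.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if X.shape[1] != Y.shape[1]:
        raise ValidationError("sample counts differ")
    n = X.shape[1]
    if n < 3:
        raise ValidationError("need at least 3 samples")
    Xc = X - X.mean(axis=1, keepdims=True)
    Yc = Y - Y.mean(axis=1, keepdims=True)
    xn = np.sqrt((Xc * Xc).sum(axis=1))
    yn = np.sqrt((Yc * Yc).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (Xc @ Yc.T) / np.outer(xn, yn)
    r = np.clip(r, -1.0, 1.0)
    r[xn == 0.0, :] = np.nan
    r[:, yn == 0.0] = np.nan
    with np.errstate(invalid="ignore", divide="ignore"):
        t = r * np.sqrt((n - 2) / (1.0 - r * r))
    p = 2.0 * stats.t.sf(np.abs(t), n - 2)
    # perfect correlations: the t transform overflows; clamp to the floor
    p = np.where(np.abs(r) >= 1.0, np.nextafter(0.0, 1.0), p)
    p[np.isnan(r)] = np.nan
    return r, p


def format_p(p: float) -> str:
    """Serialize a p-value in scientific notation with 3 significant digits."""
    return f"{p:.2E}"
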