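"""Expression matrices: container, TSV I/O, and stage normalizations.

An :class:`ExpressionMatrix` is a genes-in-rows real matrix with ordered,
unique gene and sample identifiers and a free-text ``stage_tag`` recording
its provenance (``"counts"``, ``"tpm"``, ``"log2_tpm"``, ``"scaled"``, ...).
Normalizations return new matrices and never modify their input.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from coexnet.errors import (
    DomainError,
    EmptyMatrixError,
    IdentifierCollisionError,
    MissingLengthError,
    ParseError,
    ZeroLibraryError,
    ZeroVarianceError,
)


@dataclass
class ExpressionMatrix:
    """Gene x sample expression values with identifier bookkeeping.

    Parameters
    ----------
    gene_ids : list of str
        Row identifiers, unique, order-preserving.
    sample_ids : list of str
        Column identifiers, unique, order-preserving.
    values : ndarray of shape (n_genes, n_samples)
        Real-valued expression; units depend on ``stage_tag``.
    stage_tag : str
        Provenance label for the normalization stage.
    """

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    stage_tag: str = "raw"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise IdentifierCollisionError("duplicate gene identifiers")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise IdentifierCollisionError("duplicate sample identifiers")
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ParseError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if not np.all(np.isfinite(self.values)):
            raise ParseError("expression values must be finite (no NaN/inf)")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.gene_ids, columns=self.sample_ids
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, stage_tag: str = "raw") -> "ExpressionMatrix":
        return cls(
            gene_ids=[str(g) for g in frame.index],
            sample_ids=[str(s) for s in frame.columns],
            values=frame.to_numpy(dtype=float),
            stage_tag=stage_tag,
        )


def read_expression(path, *, transpose: bool = False,
                    stage_tag: str = "raw") -> ExpressionMatrix:
    """Read a TSV expression matrix (first column gene ids, header samples).

    ``transpose=True`` accepts samples-in-rows files and flips them.
    Raises :class:`IdentifierCollisionError` on duplicated identifiers and
    :class:`ParseError` on non-numeric cells (with row/column location).
    """
    frame = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if frame.index.duplicated().any():
        dups = frame.index[frame.index.duplicated()].unique().tolist()
        raise IdentifierCollisionError(f"duplicated row identifiers: {dups}")
    if frame.columns.duplicated().any():
        dups = frame.columns[frame.columns.duplicated()].unique().tolist()
        raise IdentifierCollisionError(f"duplicated column identifiers: {dups}")
    numeric = frame.apply(pd.to_numeric, errors="coerce")
    if numeric.isna().any().any():
        bad = np.argwhere(numeric.isna().to_numpy())
        r, c = bad[0]
        raise ParseError(
            f"non-numeric value {frame.iat[r, c]!r} at row "
            f"{frame.index[r]!r}, column {frame.columns[c]!r}"
        )
    if transpose:
        numeric = numeric.T
    return ExpressionMatrix.from_frame(numeric, stage_tag=stage_tag)


def write_expression(mat: ExpressionMatrix, path) -> None:
    """Write the matrix as TSV with a ``gene_id`` index column."""
    frame = mat.to_frame()
    frame.index.name = "gene_id"
    frame.to_csv(path, sep="\t", float_format="%.10g")


def filter_zero_variance(mat: ExpressionMatrix) -> ExpressionMatrix:
    """Drop genes whose expression is constant across samples.

    Zero-variance genes carry no correlation signal and break the Pearson
    denominator; they are discarded before any distance calculation.
    """
    var = mat.values.var(axis=1)
    keep = var > 0.0
    if not keep.any():
        raise EmptyMatrixError("all genes have zero variance")
    return ExpressionMatrix(
        gene_ids=[g for g, k in zip(mat.gene_ids, keep) if k],
        sample_ids=list(mat.sample_ids),
        values=mat.values[keep],
        stage_tag=mat.stage_tag,
    )


def tpm_normalize(counts: ExpressionMatrix,
                  lengths: dict[str, float]) -> ExpressionMatrix:
    """Convert raw counts to Transcripts Per Million.

    Per sample: rate_g = count_g / length_g, TPM_g = rate_g / sum(rate) * 1e6,
    so every sample column sums to one million, correcting for sequencing
    depth and transcript length.
    """
    missing = [g for g in counts.gene_ids if g not in lengths]
    if missing:
        raise MissingLengthError(f"no transcript length for: {missing[:5]}")
    lens = np.array([float(lengths[g]) for g in counts.gene_ids])
    if np.any(lens <= 0):
        raise MissingLengthError("transcript lengths must be positive")
    if np.any(counts.values < 0):
        raise DomainError("counts must be non-negative")
    rate = counts.values / lens[:, None]
    colsum = rate.sum(axis=0)
    zero = colsum <= 0
    if zero.any():
        bad = [s for s, z in zip(counts.sample_ids, zero) if z]
        raise ZeroLibraryError(f"all-zero sample(s): {bad}")
    return replace(counts, values=rate / colsum * 1e6, stage_tag="tpm")


def log2_transform(mat: ExpressionMatrix,
                   pseudocount: float = 1.0) -> ExpressionMatrix:
    """Elementwise log2(value + pseudocount); requires non-negative input."""
    if pseudocount <= 0:
        raise DomainError("pseudocount must be positive")
    if np.any(mat.values < 0):
        raise DomainError("log2 transform requires non-negative values")
    return replace(
        mat,
        values=np.log2(mat.values + pseudocount),
        stage_tag=f"log2(pc={pseudocount:g})_{mat.stage_tag}",
    )


def scale_samples(mat: ExpressionMatrix) -> ExpressionMatrix:
    """Center and scale each sample column to mean 0, sd 1.

    The sample (n-1 denominator) standard deviation is used throughout the
    toolkit. Idempotent up to floating-point error.
    """
    mean = mat.values.mean(axis=0)
    sd = mat.values.std(axis=0, ddof=1)
    if np.any(sd == 0):
        bad = [s for s, z in zip(mat.sample_ids, sd == 0) if z]
        raise ZeroVarianceError(f"constant sample(s): {bad}")
    return replace(
        mat,
        values=(mat.values - mean) / sd,
        stage_tag=f"scaled_{mat.stage_tag}",
    )
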