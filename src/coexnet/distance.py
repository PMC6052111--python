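"""Gene-gene association measures and highest-reciprocal-rank ranking.

Six measures are supported: Pearson correlation (PCC), Spearman correlation
(SCC), their highest-reciprocal-rank ranked forms (PCC-HRR, SCC-HRR),
k-nearest-neighbor mutual information (MI, Kraskov estimator) and
shrinkage-regularized partial correlation (PC, Schäfer–Strimmer).

HRR converts a correlation matrix into ranks: for every gene A, the
correlations CC(A, ·) are ranked decreasingly with rank 0 reserved for the
gene itself (so the best partner has rank 1), and
``HRR(A, B) = max(rank_A(B), rank_B(A))``. A pair scores well only if each
gene is among the other's top correlates, which integrates the whole
transcriptional neighborhood of both genes and is robust to global biases in
the correlation distribution introduced by normalization. HRR is
lower-better; all other measures are higher-better.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial import cKDTree
from scipy.special import digamma

from coexnet.errors import (
    ConditioningError,
    DomainError,
    InsufficientSamplesError,
    KindMismatchError,
    ParameterError,
    ZeroVarianceError,
)
from coexnet.expression import ExpressionMatrix

#: ScoreMatrix kinds that hold ranks rather than similarities.
_HRR_KINDS = frozenset({"hrr_pcc", "hrr_scc"})
_CC_KINDS = frozenset({"pcc", "scc"})


@dataclass
class ScoreMatrix:
    """Symmetric gene x gene association scores.

    ``orientation`` is ``"lower_better"`` exactly for HRR kinds (ranks) and
    ``"higher_better"`` otherwise. The diagonal convention is 1 for
    correlation kinds, 0 for HRR (self-rank) and +inf for MI (sentinel,
    excluded from thresholding).
    """

    gene_ids: list[str]
    values: np.ndarray
    kind: str

    @property
    def orientation(self) -> str:
        return "lower_better" if self.kind in _HRR_KINDS else "higher_better"

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids,
                            columns=self.gene_ids)

    def write(self, path) -> None:
        frame = self.to_frame()
        frame.index.name = "gene_id"
        frame.to_csv(path, sep="\t", float_format="%.10g")


def _check_samples(mat: ExpressionMatrix, minimum: int = 3) -> None:
    if mat.n_samples < minimum:
        raise InsufficientSamplesError(
            f"need >= {minimum} samples, got {mat.n_samples}"
        )


def _check_variance(mat: ExpressionMatrix) -> None:
    var = mat.values.var(axis=1)
    if np.any(var == 0):
        bad = [g for g, v in zip(mat.gene_ids, var) if v == 0]
        raise ZeroVarianceError(
            f"zero-variance gene(s) {bad[:5]}; run filter_zero_variance first"
        )


def pearson_matrix(mat: ExpressionMatrix,
                   block_size: int = 2048) -> ScoreMatrix:
    """All-pairs Pearson correlation.

    Computed blockwise on standardized rows so peak memory beyond the output
    is O(block_size x n_genes).
    """
    _check_samples(mat)
    _check_variance(mat)
    x = mat.values
    x = x - x.mean(axis=1, keepdims=True)
    x = x / np.sqrt((x * x).sum(axis=1, keepdims=True))
    n = x.shape[0]
    out = np.empty((n, n))
    for start in range(0, n, block_size):
        stop = min(start + block_size, n)
        out[start:stop] = x[start:stop] @ x.T
    np.clip(out, -1.0, 1.0, out=out)
    np.fill_diagonal(out, 1.0)
    out = (out + out.T) / 2.0
    return ScoreMatrix(list(mat.gene_ids), out, "pcc")


def spearman_matrix(mat: ExpressionMatrix,
                    block_size: int = 2048) -> ScoreMatrix:
    """All-pairs Spearman correlation: Pearson on within-gene sample ranks
    (average ranks for ties)."""
    _check_samples(mat)
    _check_variance(mat)
    ranked = ExpressionMatrix(
        gene_ids=list(mat.gene_ids),
        sample_ids=list(mat.sample_ids),
        values=stats.rankdata(mat.values, axis=1),
        stage_tag=f"ranked_{mat.stage_tag}",
    )
    sm = pearson_matrix(ranked, block_size=block_size)
    return ScoreMatrix(sm.gene_ids, sm.values, "scc")


def hrr_matrix(cc: ScoreMatrix) -> ScoreMatrix:
    """Highest reciprocal rank of a correlation matrix.

    Per gene, correlations are ranked decreasingly (rank 0 = the gene
    itself, rank 1 = best partner); ties are broken deterministically by
    ascending partner index so each row's off-diagonal ranks are exactly the
    permutation {1, ..., N-1}. ``HRR = max(rank_A(B), rank_B(A))``, diagonal
    0, lower-better.
    """
    if cc.kind not in _CC_KINDS:
        raise KindMismatchError(
            f"HRR requires a pcc or scc matrix, got kind {cc.kind!r}"
        )
    n = cc.n_genes
    if n < 2:
        raise ParameterError("HRR needs at least 2 genes")
    ranks = np.empty((n, n), dtype=np.int64)
    idx = np.arange(n)
    for i in range(n):
        row = cc.values[i].copy()
        row[i] = np.inf  # self sorts first -> rank 0
        order = np.lexsort((idx, -row))
        ranks[i, order] = idx
    hrr = np.maximum(ranks, ranks.T)
    np.fill_diagonal(hrr, 0)
    kind = "hrr_pcc" if cc.kind == "pcc" else "hrr_scc"
    return ScoreMatrix(list(cc.gene_ids), hrr.astype(float), kind)


def _ksg_pair_mi(x: np.ndarray, y: np.ndarray, k: int) -> float:
    # Kraskov-Stögbauer-Grassberger estimator 1, Chebyshev joint metric.
    n = len(x)
    pts = np.column_stack([x, y])
    tree = cKDTree(pts)
    dist, _ = tree.query(pts, k=k + 1, p=np.inf)
    eps = dist[:, -1]
    xs = np.sort(x)
    ys = np.sort(y)
    nx = (np.searchsorted(xs, x + eps, side="left")
          - np.searchsorted(xs, x - eps, side="right")) - 1
    ny = (np.searchsorted(ys, y + eps, side="left")
          - np.searchsorted(ys, y - eps, side="right")) - 1
    mi = (digamma(k) + digamma(n)
          - np.mean(digamma(nx + 1) + digamma(ny + 1)))
    return float(max(mi, 0.0))


def mutual_information_matrix(mat: ExpressionMatrix, k: int = 3, *,
                              jitter: bool = True,
                              seed: int = 0) -> ScoreMatrix:
    """k-nearest-neighbor (Kraskov) mutual information for every gene pair.

    Values are in nats, clipped at 0. The estimator assumes continuous data;
    when ``jitter`` is set, a deterministic seeded perturbation of relative
    scale 1e-10 breaks exact ties. The diagonal holds a +inf sentinel (the
    self-MI of a continuous variable is unbounded) and must be excluded from
    any thresholding.
    """
    if k < 1 or k >= mat.n_samples - 1:
        raise ParameterError(
            f"k must satisfy 1 <= k <= n_samples-2, got k={k}, "
            f"n_samples={mat.n_samples}"
        )
    x = np.asarray(mat.values, dtype=float)
    if jitter:
        rng = np.random.default_rng(seed)
        scale = np.maximum(np.abs(x).max(axis=1, keepdims=True), 1.0)
        x = x + rng.standard_normal(x.shape) * 1e-10 * scale
    n = x.shape[0]
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            out[i, j] = out[j, i] = _ksg_pair_mi(x[i], x[j], k)
    np.fill_diagonal(out, np.inf)
    return ScoreMatrix(list(mat.gene_ids), out, "mi")


def _shrinkage_lambda(x: np.ndarray) -> float:
    """Analytic optimal shrinkage intensity toward the identity correlation
    target (Schäfer–Strimmer): lambda* = sum Var(r_ij) / sum r_ij^2 over
    off-diagonal entries."""
    n, p = x.shape[1], x.shape[0]
    xs = (x - x.mean(axis=1, keepdims=True)) / x.std(axis=1, ddof=1,
                                                     keepdims=True)
    r = (xs @ xs.T) / (n - 1)
    # Var(r_ij) = n / (n-1)^3 * sum_k (w_kij - wbar_ij)^2 with
    # w_kij = xs_ik * xs_jk; computed via moment matrices to stay O(p^2 n).
    wbar = r * (n - 1) / n
    sum_w2 = (xs ** 2) @ (xs ** 2).T
    var_r = n / (n - 1) ** 3 * (sum_w2 - n * wbar ** 2)
    off = ~np.eye(p, dtype=bool)
    denom = np.sum(r[off] ** 2)
    if denom == 0:
        return 1.0
    lam = np.sum(var_r[off]) / denom
    return float(min(1.0, max(0.0, lam)))


def partial_correlation_shrinkage(mat: ExpressionMatrix, *,
                                  lambda_floor: float = 0.01
                                  ) -> ScoreMatrix:
    """Partial correlations from a shrunken correlation matrix.

    The sample correlation matrix is shrunk toward the identity with the
    analytic Schäfer–Strimmer intensity (clamped to
    ``[lambda_floor, 1]`` so the shrunken matrix is positive definite even
    when genes outnumber samples), inverted to a precision matrix Ω, and
    standardized: ``PC(i, j) = -Ω_ij / sqrt(Ω_ii Ω_jj)``, diagonal 1.
    """
    _check_samples(mat)
    _check_variance(mat)
    x = mat.values
    n = x.shape[1]
    xs = (x - x.mean(axis=1, keepdims=True)) / x.std(axis=1, ddof=1,
                                                     keepdims=True)
    r = (xs @ xs.T) / (n - 1)
    np.fill_diagonal(r, 1.0)
    lam = max(_shrinkage_lambda(x), lambda_floor)
    shrunk = (1.0 - lam) * r
    np.fill_diagonal(shrunk, 1.0)
    try:
        omega = np.linalg.inv(shrunk)
    except np.linalg.LinAlgError as exc:
        raise ConditioningError(
            f"shrunken correlation matrix is singular (lambda={lam:.4g}); "
            "raise lambda_floor"
        ) from exc
    d = np.sqrt(np.diag(omega))
    pc = -omega / np.outer(d, d)
    np.fill_diagonal(pc, 1.0)
    pc = (pc + pc.T) / 2.0
    return ScoreMatrix(list(mat.gene_ids), pc, "pc")


def first_order_pc(r_xy: float, r_yz: float, r_xz: float) -> float:
    """First-order partial correlation of x and y conditioning on z:

        R_xy.z = (R_xy - R_yz R_xz) / sqrt((1 - R_yz^2)(1 - R_xz^2))

    with the three simple correlation coefficients as inputs.
    """
    for name, r in (("r_xy", r_xy), ("r_yz", r_yz), ("r_xz", r_xz)):
        if not -1.0 <= r <= 1.0:
            raise DomainError(f"{name}={r} outside [-1, 1]")
    if abs(r_yz) == 1.0 or abs(r_xz) == 1.0:
        raise DomainError(
            "conditioning correlation of magnitude 1: denominator vanishes"
        )
    return (r_xy - r_yz * r_xz) / np.sqrt((1 - r_yz ** 2) * (1 - r_xz ** 2))
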