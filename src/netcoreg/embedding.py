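"""Expression standardization, network penalty matrix, and SVD embeddings.

The network-regularized objective

    f(c) = 1/(2M) ||y - Xc||^2 + alpha ||c||_1
         + beta/2 * sum_{i<j} w_ij (c_i/sqrt(d_i) - c_j/sqrt(d_j))^2

is rewritten with the penalty in quadratic form ``beta/2 c'Ac`` where
``A_ij = -w_ij / sqrt(d_i d_j)`` off the diagonal and ``A_ii = 1`` (a
degree-normalized graph-Laplacian variant). Collecting quadratic terms gives
``E = X'X/M + beta*A``, a symmetric PSD matrix whose eigendecomposition
``E = U S U'`` defines embeddings

    X~ = sqrt(N) S^(1/2) U'        (column i = TF i's embedding)
    y~ = sqrt(N)/M S^(-1/2) U' X'y

so that 1/N X~'X~ = E and 1/N y~'X~ = 1/M y'X, and the original objective
equals a plain Lasso on (X~, y~) up to an additive constant. Small singular
values (s_i < tol * s_max) are truncated to zero for stability, with the
corresponding entries of the inverse square root zeroed as well.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from netcoreg.ppin import PreprocessedPPIN

logger = logging.getLogger(__name__)

BETA_FLOOR = 1e-6
DEFAULT_SVD_TOL = 1e-6
PSD_CLAMP = 0.0  # eigenvalues below zero (round-off) are clamped here


@dataclass
class ExpressionMatrix:
    """Standardized TF expression: columns have mean 0, population sd 1.

    The training means and sds are stored so the same affine transform can be
    applied to held-out data.
    """

    X: np.ndarray
    tf_order: tuple[str, ...]
    col_means: np.ndarray
    col_sds: np.ndarray

    @property
    def m(self) -> int:
        return self.X.shape[0]

    @property
    def n(self) -> int:
        return self.X.shape[1]

    def transform(self, X_new: np.ndarray) -> np.ndarray:
        """Apply the stored training transform to new data."""
        return (np.asarray(X_new, dtype=float) - self.col_means) / self.col_sds


@dataclass
class TargetVector:
    """Standardized TG expression with stored training mean/sd."""

    y: np.ndarray
    mu: float
    sd: float

    def transform(self, y_new: np.ndarray) -> np.ndarray:
        return (np.asarray(y_new, dtype=float) - self.mu) / self.sd


@dataclass
class PenaltyMatrix:
    """Degree-normalized network penalty ``A`` with unit diagonal."""

    A: np.ndarray
    d: np.ndarray
    tf_order: tuple[str, ...]


@dataclass
class EmbeddingSpace:
    """Eigendecomposition of ``E`` and the transformed system (X~, y~)."""

    E: np.ndarray
    beta: float
    U: np.ndarray
    S: np.ndarray          # all eigenvalues, descending, clamped at 0
    S_trunc: np.ndarray    # truncated eigenvalues (small ones zeroed)
    X_tilde: np.ndarray
    y_tilde: np.ndarray
    rank_retained: int
    tf_order: tuple[str, ...]
    m: int

    @property
    def n(self) -> int:
        return self.E.shape[0]


def standardize(
    X_raw: np.ndarray,
    y_raw: np.ndarray,
    tf_order: tuple[str, ...] | list[str] | None = None,
) -> tuple[ExpressionMatrix, TargetVector]:
    """Center and scale columns of ``X_raw`` and ``y_raw``.

    Uses the population standard deviation (divisor M) so that
    ``diag(X'X / M) = 1`` exactly, which the identity ``E_ii = 1 + beta``
    relies on. Pairwise Pearson correlations are unchanged by this affine map.
    """
    X_raw = np.asarray(X_raw, dtype=float)
    y_raw = np.asarray(y_raw, dtype=float).ravel()
    if X_raw.ndim != 2:
        raise ValueError("X_raw must be 2-dimensional (samples x TFs)")
    m, n = X_raw.shape
    if m < 2:
        raise ValueError(f"need at least 2 samples, got {m}")
    if y_raw.shape[0] != m:
        raise ValueError("X_raw and y_raw disagree on sample count")
    if tf_order is None:
        tf_order = tuple(f"TF{i + 1}" for i in range(n))
    tf_order = tuple(tf_order)

    mu = X_raw.mean(axis=0)
    sd = X_raw.std(axis=0)  # population sd, ddof=0
    zero = np.where(sd == 0)[0]
    if zero.size:
        raise ValueError(f"zero-variance expression column for TF {tf_order[zero[0]]!r}")
    mu_y = float(y_raw.mean())
    sd_y = float(y_raw.std())
    if sd_y == 0:
        raise ValueError("target gene expression is constant")

    return (
        ExpressionMatrix(X=(X_raw - mu) / sd, tf_order=tf_order, col_means=mu, col_sds=sd),
        TargetVector(y=(y_raw - mu_y) / sd_y, mu=mu_y, sd=sd_y),
    )


def build_A(ppin: PreprocessedPPIN) -> PenaltyMatrix:
    """Build ``A_ij = -w_ij / sqrt(d_i d_j)`` (i != j), ``A_ii = 1``.

    Equivalent to ``D (W o V) D`` with ``D = diag(1/sqrt(d))`` and
    ``V = N*I - 11'``: the Hadamard product puts ``d_i`` on the diagonal and
    ``-w_ij`` off it. ``A`` is symmetric PSD and annihilates ``sqrt(d)``.
    """
    if ppin.n < 2:
        raise ValueError("penalty matrix requires at least 2 TFs")
    d = ppin.d
    if np.any(d <= 0):
        bad = ppin.tf_order[int(np.argmin(d))]
        raise ValueError(f"nonpositive degree for TF {bad!r}; network is not fully connected")
    inv_sqrt = 1.0 / np.sqrt(d)
    A = -(ppin.W * np.outer(inv_sqrt, inv_sqrt))
    np.fill_diagonal(A, 1.0)
    return PenaltyMatrix(A=A, d=d.copy(), tf_order=ppin.tf_order)


def build_E(X: ExpressionMatrix, A: PenaltyMatrix, beta: float) -> np.ndarray:
    """Combine expression and network prior: ``E = X'X/M + beta*A``.

    ``beta`` must be positive; nonpositive requests are replaced by a small
    documented floor (``1e-6``) so the no-network limit remains solvable.
    """
    if X.n != A.A.shape[0]:
        raise ValueError(
            f"dimension mismatch: X has {X.n} TF columns, A is {A.A.shape[0]}x{A.A.shape[1]}"
        )
    if beta <= 0:
        logger.info("beta=%s replaced by floor %s", beta, BETA_FLOOR)
        beta = BETA_FLOOR
    return X.X.T @ X.X / X.m + beta * A.A


def svd_embed(
    E: np.ndarray,
    X: ExpressionMatrix,
    y: TargetVector,
    beta: float,
    tol: float = DEFAULT_SVD_TOL,
) -> EmbeddingSpace:
    """Eigendecompose ``E`` and construct the embedded system (X~, y~).

    ``E`` is symmetric PSD, so its eigendecomposition coincides with its SVD;
    tiny negative eigenvalues from round-off are clamped to zero. Eigenvalues
    below ``tol * s_max`` are truncated, and the pseudo-inverse square root
    used for ``y~`` zeroes those directions. The sign of each eigenvector is
    fixed by making its largest-magnitude entry positive, for reproducibility
    of intermediates (downstream quantities are invariant to this choice).
    """
    if not 0 < tol < 1:
        raise ValueError(f"tol must be in (0, 1), got {tol}")
    E = np.asarray(E, dtype=float)
    if E.shape[0] != E.shape[1]:
        raise ValueError("E must be square")
    if not np.allclose(E, E.T, atol=1e-10):
        raise ValueError("E must be symmetric")

    vals, vecs = np.linalg.eigh(E)
    vals = np.clip(vals, PSD_CLAMP, None)
    order = np.argsort(vals)[::-1]
    vals = vals[order]
    vecs = vecs[:, order]
    # deterministic sign convention
    flip = np.sign(vecs[np.argmax(np.abs(vecs), axis=0), np.arange(vecs.shape[1])])
    flip[flip == 0] = 1.0
    vecs = vecs * flip

    s_max = vals[0]
    if s_max <= 0:
        raise ValueError("degenerate E: all singular values are zero")
    keep = vals >= tol * s_max
    if not keep.any():
        raise ValueError("degenerate E: all singular values truncated")
    s_trunc = np.where(keep, vals, 0.0)
    rank = int(keep.sum())

    n = E.shape[0]
    sqrt_s = np.sqrt(s_trunc)
    inv_sqrt_s = np.divide(1.0, sqrt_s, out=np.zeros_like(sqrt_s), where=sqrt_s > 0)
    X_tilde = np.sqrt(n) * (sqrt_s[:, None] * vecs.T)
    y_tilde = (np.sqrt(n) / X.m) * (inv_sqrt_s[:, None] * vecs.T) @ (X.X.T @ y.y)

    return EmbeddingSpace(
        E=E,
        beta=beta,
        U=vecs,
        S=vals,
        S_trunc=s_trunc,
        X_tilde=X_tilde,
        y_tilde=y_tilde,
        rank_retained=rank,
        tf_order=X.tf_order,
        m=X.m,
    )
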