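"""Canonical correlation analysis (CCA) for blind source separation, with a
Gaussian-elimination (left matrix division) solver variant.

The separation pairs the multichannel input ``X`` with a temporally delayed
copy ``Y`` built by a valid convolution with the mask ``[1 0 1]``, so the
canonical variates of ``X`` are ordered by autocorrelation: broadband,
white-noise-like artifact activity ends up in the weakly autocorrelated
trailing components, which is the premise for separating muscle artifact
from EEG.

Two interchangeable solvers are provided for the eigenproblem
``G a = rho^2 a`` with ``G = Cxx^-1 Cxy Cyy^-1 Cyx``:

``solve_cca_inverse``
    the textbook route through explicit matrix inverses;
``solve_cca_leftdiv``
    the left-division (backslash) route that solves ``Cxx A = Cxy`` and
    ``Cyy B = Cyx`` by LU factorisation, falling back to a
    pivoted-QR least-squares solve on rank-deficient blocks.

Both produce identical canonical correlations on well-conditioned input;
the left-division route avoids forming inverses and degrades gracefully
when a covariance block is singular.

Inside this module channels are rows and time is columns; the samples ×
channels orientation of the I/O layer is transposed at the boundary.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.linalg

__all__ = [
    "CovarianceBlocks",
    "CanonicalModel",
    "SourceSet",
    "build_delayed",
    "build_covariance",
    "solve_cca_inverse",
    "solve_cca_leftdiv",
    "estimate_sources",
    "remix",
]

#: imaginary parts of eigenvalues/-vectors below this (relative) size are
#: numerical noise and clipped; larger ones signal ill-conditioning.
_IMAG_TOL = 1e-8

#: eigenvalues closer than this (relative) are treated as a degenerate
#: cluster and given a canonical subspace basis.  Differences in rho^2 at
#: this scale are far below the sampling error of the covariance estimates,
#: so the within-cluster directions carry no statistical meaning.
_CLUSTER_RTOL = 1e-6


@dataclass
class CovarianceBlocks:
    """Regularised auto/cross covariance blocks of the stacked ``[X; Y]``.

    ``Cxx`` and ``Cyy`` carry ``beta`` added to their diagonals so they stay
    positive definite even for (near-)constant channels; ``Cyx`` is exactly
    the transpose of ``Cxy``.
    """

    Cxx: np.ndarray
    Cyy: np.ndarray
    Cxy: np.ndarray
    Cyx: np.ndarray
    beta: float = 1e-8

    @property
    def sx(self) -> int:
        return self.Cxx.shape[0]

    @property
    def sy(self) -> int:
        return self.Cyy.shape[0]


@dataclass
class CanonicalModel:
    """Result of a CCA solve.

    ``rho_sq`` holds the squared canonical correlations sorted descending;
    rows of ``a`` and ``b`` are the unit-norm weight vectors for ``X`` and
    ``Y`` (largest-magnitude entry positive).  ``W`` is the mixing map back
    from canonical variates to channels — the inverse of the weight matrix
    ``a`` — or ``None`` if ``a`` is not invertible, in which case remixing
    uses a least-squares solve.
    """

    rho_sq: np.ndarray
    a: np.ndarray
    b: np.ndarray
    W: np.ndarray | None
    solver: str


@dataclass
class SourceSet:
    """Canonical variates ``p = a @ X`` (components × samples) plus model."""

    sources: np.ndarray
    model: CanonicalModel

    @property
    def n_components(self) -> int:
        return self.sources.shape[0]


def build_delayed(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Build the delayed companion ``Y`` of ``X`` and align the pair.

    ``Y`` is the per-channel valid convolution of ``X`` with ``[1 0 1]``:
    ``Y[c, i] = X[c, i-1] + X[c, i+1]``, two samples shorter than ``X``.
    ``X`` is trimmed of its first and last column so both matrices are
    conformable for stacking ``Z = [X; Y]``.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] < 3:
        raise ValueError("need at least 3 samples to build a delayed copy")
    Y = X[:, :-2] + X[:, 2:]
    return X[:, 1:-1], Y


def build_covariance(
    X_aligned: np.ndarray, Y: np.ndarray, beta: float = 1e-8
) -> CovarianceBlocks:
    """Sample covariance of the stacked ``Z = [X; Y]``, cut into blocks.

    ``beta`` (default 1e-8) is added to the diagonals of both auto-blocks to
    keep them nonsingular; it is small enough not to perturb well-scaled
    covariances measurably.
    """
    X_aligned = np.atleast_2d(np.asarray(X_aligned, dtype=float))
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    if X_aligned.shape[1] != Y.shape[1]:
        raise ValueError("X_aligned and Y must have the same number of samples")
    if X_aligned.shape[1] < 2:
        raise ValueError("need at least 2 samples for a covariance")
    sx, sy = X_aligned.shape[0], Y.shape[0]
    Z = np.vstack([X_aligned, Y])
    C = np.cov(Z)  # rows are variables, ddof=1
    C = np.atleast_2d(C)
    Cxx = C[:sx, :sx] + beta * np.eye(sx)
    Cyy = C[sx:, sx:] + beta * np.eye(sy)
    Cxy = C[:sx, sx:]
    return CovarianceBlocks(Cxx=Cxx, Cyy=Cyy, Cxy=Cxy, Cyx=Cxy.T.copy(), beta=beta)


def _real_clip(arr: np.ndarray, scale: float) -> np.ndarray:
    imax = float(np.max(np.abs(arr.imag))) if np.iscomplexobj(arr) else 0.0
    if imax > _IMAG_TOL * max(scale, 1.0):
        raise np.linalg.LinAlgError(
            f"eigen solve produced imaginary parts of size {imax:.2e}; "
            "the covariance blocks are too ill-conditioned"
        )
    return np.asarray(arr).real


def _normalize_vectors(V: np.ndarray) -> np.ndarray:
    """Columns to unit Euclidean norm, largest-magnitude entry positive."""
    V = V.copy()
    norms = np.linalg.norm(V, axis=0)
    norms[norms == 0] = 1.0
    V /= norms
    lead = np.abs(V).argmax(axis=0)
    signs = np.sign(V[lead, np.arange(V.shape[1])])
    signs[signs == 0] = 1.0
    return V * signs


def _canonical_cluster_basis(Vc: np.ndarray, metric: np.ndarray) -> np.ndarray:
    """Deterministic orthonormal basis of a near-degenerate eigenspace.

    Within a cluster of (numerically) equal canonical correlations the
    individual eigenvectors are not identified — any basis of the invariant
    subspace is an equally valid solution, and tiny perturbations of ``G``
    rotate LAPACK's choice arbitrarily.  The subspace itself, however, is
    stable.  We orthonormalise the cluster and diagonalise the projection
    of the auto-covariance ``metric`` onto it: the within-cluster
    components become mutually uncorrelated, variance-ordered variates.
    The result depends only on the subspace, so different solver routes
    agree, and an arbitrary rotation that would hide genuine signal in a
    variance-cancelling combination is avoided.
    """
    Q, _ = np.linalg.qr(Vc)
    S = Q.T @ metric @ Q
    evals, R = np.linalg.eigh(S)
    return Q @ R[:, ::-1]  # descending within-cluster variance


def _eig_sorted(G: np.ndarray, metric: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Eigen-decompose the (nonsymmetric) CCA product matrix.

    Returns eigenvalues sorted descending and the matching unit-norm,
    sign-fixed eigenvectors as rows.  Clusters of eigenvalues equal to
    within ``_CLUSTER_RTOL`` (relative) are given a canonical subspace basis and ordered
    by the index of each vector's largest entry, making the output
    deterministic under (near-)degeneracy.
    """
    w, V = np.linalg.eig(G)
    if w.size == 0:
        return w.real, V.real.T
    scale = float(np.max(np.abs(w)))
    w = _real_clip(w, scale)
    V = _real_clip(V, 1.0)
    order = np.argsort(-w, kind="stable")
    w, V = w[order], V[:, order]
    tol = _CLUSTER_RTOL * max(scale, 1.0)
    i = 0
    while i < w.size:
        j = i + 1
        while j < w.size and w[j - 1] - w[j] <= tol:
            j += 1
        if j - i > 1:
            V[:, i:j] = _canonical_cluster_basis(V[:, i:j], metric)
        i = j
    V = _normalize_vectors(V)
    # within each cluster, order by the index of the largest-magnitude entry
    lead = np.abs(V).argmax(axis=0)
    i = 0
    while i < w.size:
        j = i + 1
        while j < w.size and w[j - 1] - w[j] <= tol:
            j += 1
        if j - i > 1:
            # vectors in a cluster share one (numerically equal) eigenvalue,
            # so only the vectors are permuted and w stays sorted
            sub = i + np.argsort(lead[i:j], kind="stable")
            V[:, i:j] = V[:, sub]
        i = j
    return w, V.T


def _finish_model(
    blocks: CovarianceBlocks, Ga: np.ndarray, Gb: np.ndarray, solver: str
) -> CanonicalModel:
    rho_sq, a = _eig_sorted(Ga, blocks.Cxx)
    _, b = _eig_sorted(Gb, blocks.Cyy)
    try:
        W = np.linalg.inv(a)
    except np.linalg.LinAlgError:
        W = None
    return CanonicalModel(rho_sq=rho_sq, a=a, b=b, W=W, solver=solver)


def solve_cca_inverse(blocks: CovarianceBlocks) -> CanonicalModel:
    """Standard CCA through explicit inverses of the auto-covariances.

    Solves the eigenproblems of ``Cxx^-1 Cxy Cyy^-1 Cyx`` (weights for X)
    and its role-swapped partner (weights for Y).
    """
    try:
        iCxx = np.linalg.inv(blocks.Cxx)
        iCyy = np.linalg.inv(blocks.Cyy)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            f"singular covariance block despite beta={blocks.beta}: {exc}"
        ) from exc
    Ga = iCxx @ blocks.Cxy @ iCyy @ blocks.Cyx
    Gb = iCyy @ blocks.Cyx @ iCxx @ blocks.Cxy
    return _finish_model(blocks, Ga, Gb, "inverse")


def _left_divide(M: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Solve ``M @ A = B`` by LU; pivoted-QR least squares if M is singular.

    The fallback mirrors backslash semantics on rank-deficient systems: the
    effective rank is determined by QR with column pivoting (LAPACK gelsy)
    and the solution has at most that many independent components.
    """
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error", scipy.linalg.LinAlgWarning)
            return scipy.linalg.solve(M, B)
    except (np.linalg.LinAlgError, scipy.linalg.LinAlgError,
            scipy.linalg.LinAlgWarning):
        sol, _, rank, _ = scipy.linalg.lstsq(M, B, lapack_driver="gelsy")
        return sol


def solve_cca_leftdiv(blocks: CovarianceBlocks) -> CanonicalModel:
    """CCA through left matrix division (Gaussian elimination).

    ``A`` solves ``Cxx @ A = Cxy`` and ``B`` solves ``Cyy @ B = Cyx`` by LU
    factorisation — no inverse is ever formed — then ``G = A @ B`` is
    eigen-decomposed exactly as in :func:`solve_cca_inverse`.  Because
    ``Gb = B @ A`` shares its nonzero spectrum with ``Ga = A @ B``, the
    Y-side weights come for free.  Rank-deficient blocks are handled by a
    pivoted-QR least-squares solve instead of failing.
    """
    A = _left_divide(blocks.Cxx, blocks.Cxy)
    B = _left_divide(blocks.Cyy, blocks.Cyx)
    return _finish_model(blocks, A @ B, B @ A, "leftdiv")


def estimate_sources(model: CanonicalModel, X_aligned: np.ndarray) -> SourceSet:
    """Project channels onto the canonical variates: ``p = a @ X_aligned``."""
    X_aligned = np.atleast_2d(np.asarray(X_aligned, dtype=float))
    if model.a.shape[1] != X_aligned.shape[0]:
        raise ValueError(
            f"model expects {model.a.shape[1]} channels, got {X_aligned.shape[0]}"
        )
    return SourceSet(sources=model.a @ X_aligned, model=model)


def remix(
    model: CanonicalModel,
    sources: SourceSet,
    zero_mask: np.ndarray | None = None,
) -> np.ndarray:
    """Map sources back to channel space, zeroing the masked components.

    ``zero_mask[i] = True`` suppresses component ``i`` before the inverse
    weight map is applied.  If the weight matrix is not invertible the
    reconstruction is the least-squares solution of ``a @ X = p`` (with a
    warning).
    """
    p = np.array(sources.sources, dtype=float, copy=True)
    if zero_mask is None:
        zero_mask = np.zeros(p.shape[0], dtype=bool)
    zero_mask = np.asarray(zero_mask, dtype=bool)
    if zero_mask.size != p.shape[0]:
        raise ValueError(
            f"mask length {zero_mask.size} != component count {p.shape[0]}"
        )
    p[zero_mask] = 0.0
    if model.W is not None:
        return model.W @ p
    warnings.warn(
        "weight matrix is not invertible; remixing by least squares",
        RuntimeWarning,
        stacklevel=2,
    )
    sol, _, _, _ = scipy.linalg.lstsq(model.a, p, lapack_driver="gelsy")
    return sol
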