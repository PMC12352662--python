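"""Affine-invariant geometry of symmetric positive-definite matrices.

Covariance matrices live on the SPD cone.  Under the affine-invariant
metric, the exponential/logarithmic maps at a base point ``B`` are

    Log_B(S) = B^{1/2} log(B^{-1/2} S B^{-1/2}) B^{1/2}
    Exp_B(T) = B^{1/2} exp(B^{-1/2} T B^{-1/2}) B^{1/2}

and the geometric (Karcher/Fréchet) mean of a set {S_k} is the point M
minimizing the summed squared geodesic distances, found here by the
standard fixed-point iteration on the whitened tangent mean.

All matrix functions go through symmetric eigendecompositions with an
eigenvalue clip at ``EIG_CLIP`` for numerical safety on near-singular
shrinkage outputs.
"""

from __future__ import annotations

import numpy as np

EIG_CLIP = 1e-12
SYM_TOL = 1e-8


class ConvergenceError(RuntimeError):
    """Karcher-mean fixed point failed to converge; carries the residual."""

    def __init__(self, residual: float, max_iter: int):
        self.residual = residual
        super().__init__(
            f"geometric mean did not converge in {max_iter} iterations "
            f"(tangent-mean norm {residual:.3e})"
        )


def _check_sym(M: np.ndarray, tol: float = SYM_TOL, name: str = "matrix") -> np.ndarray:
    M = np.asarray(M, dtype=float)
    if M.ndim != 2 or M.shape[0] != M.shape[1]:
        raise ValueError(f"{name} must be square, got shape {M.shape}")
    if not np.allclose(M, M.T, atol=tol * max(1.0, float(np.abs(M).max()))):
        raise ValueError(f"{name} is not symmetric within tolerance")
    return 0.5 * (M + M.T)


def is_spd(M: np.ndarray, tol: float = SYM_TOL) -> bool:
    """True if ``M`` is symmetric with strictly positive eigenvalues."""
    M = np.asarray(M, dtype=float)
    if M.ndim != 2 or M.shape[0] != M.shape[1]:
        return False
    if not np.allclose(M, M.T, atol=tol * max(1.0, float(np.abs(M).max()))):
        return False
    return float(np.linalg.eigvalsh(M)[0]) > 0.0


def _check_spd(M: np.ndarray, name: str = "matrix") -> np.ndarray:
    M = _check_sym(M, name=name)
    if float(np.linalg.eigvalsh(M)[0]) <= 0.0:
        raise ValueError(f"{name} is not positive definite")
    return M


def _eig_fun(M: np.ndarray, fun) -> np.ndarray:
    """Apply a scalar function to the eigenvalues of a symmetric matrix."""
    w, V = np.linalg.eigh(0.5 * (M + M.T))
    return (V * fun(w)) @ V.T


def sqrtm(M: np.ndarray) -> np.ndarray:
    return _eig_fun(M, lambda w: np.sqrt(np.clip(w, EIG_CLIP, None)))


def invsqrtm(M: np.ndarray) -> np.ndarray:
    return _eig_fun(M, lambda w: 1.0 / np.sqrt(np.clip(w, EIG_CLIP, None)))


def logm(M: np.ndarray) -> np.ndarray:
    return _eig_fun(M, lambda w: np.log(np.clip(w, EIG_CLIP, None)))


def expm(M: np.ndarray) -> np.ndarray:
    return _eig_fun(M, np.exp)


def tangent_log(S: np.ndarray, base: np.ndarray) -> np.ndarray:
    """Log map of SPD matrix ``S`` at SPD base point ``base``.

    Returns the symmetric tangent vector
    ``base^{1/2} log(base^{-1/2} S base^{-1/2}) base^{1/2}``.
    """
    S = _check_spd(S, "S")
    base = _check_spd(base, "base")
    ib = invsqrtm(base)
    b = sqrtm(base)
    T = b @ logm(ib @ S @ ib) @ b
    return 0.5 * (T + T.T)


def tangent_exp(T: np.ndarray, base: np.ndarray) -> np.ndarray:
    """Exp map of symmetric tangent vector ``T`` at SPD base point ``base``.

    Inverse of :func:`tangent_log` at the same base; the result is SPD.
    """
    T = _check_sym(T, name="T")
    base = _check_spd(base, "base")
    ib = invsqrtm(base)
    b = sqrtm(base)
    S = b @ expm(ib @ T @ ib) @ b
    return 0.5 * (S + S.T)


def geodesic_distance(A: np.ndarray, B: np.ndarray) -> float:
    """Affine-invariant distance ``||log(A^{-1/2} B A^{-1/2})||_F``."""
    ia = invsqrtm(_check_spd(A, "A"))
    return float(np.linalg.norm(logm(ia @ _check_spd(B, "B") @ ia)))


def geometric_mean(
    mats, tol: float = 1e-10, max_iter: int = 50, init: np.ndarray | None = None
) -> np.ndarray:
    """Karcher mean of a list of SPD matrices (affine-invariant metric).

    Fixed-point iteration: whiten every matrix at the current estimate M,
    average the matrix logs, and move M along that tangent mean.  Converged
    when the Frobenius norm of the tangent mean drops below ``tol``.

    Raises
    ------
    ConvergenceError
        If the residual is still above ``tol`` after ``max_iter`` steps.
    """
    mats = [np.asarray(M, dtype=float) for M in mats]
    if not mats:
        raise ValueError("need at least one matrix")
    n = mats[0].shape[0]
    for M in mats:
        if M.shape != (n, n):
            raise ValueError("all matrices must have the same shape")
    if len(mats) == 1:
        return _check_spd(mats[0])
    M = np.mean(mats, axis=0) if init is None else np.asarray(init, dtype=float)
    residual = np.inf
    for _ in range(max_iter):
        im = invsqrtm(M)
        A = np.mean([logm(im @ S @ im) for S in mats], axis=0)
        residual = float(np.linalg.norm(A))
        if residual < tol:
            return 0.5 * (M + M.T)
        s = sqrtm(M)
        M = s @ expm(A) @ s
        M = 0.5 * (M + M.T)
    # accept late convergence if the final update landed inside tol
    im = invsqrtm(M)
    A = np.mean([logm(im @ S @ im) for S in mats], axis=0)
    residual = float(np.linalg.norm(A))
    if residual < tol:
        return 0.5 * (M + M.T)
    raise ConvergenceError(residual, max_iter)


def eigenvalue_floor(M: np.ndarray, floor: float = 1e-6) -> np.ndarray:
    """Project a symmetric matrix onto the SPD cone by flooring eigenvalues."""
    M = 0.5 * (np.asarray(M, dtype=float) + np.asarray(M, dtype=float).T)
    w, V = np.linalg.eigh(M)
    return (V * np.clip(w, floor, None)) @ V.T
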