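"""Element-wise weighted low-rank approximation (maximum-likelihood PCA).

Minimizes S² = ‖W ∘ (X − c − T Pᵀ)‖²_F by alternating exact weighted
least-squares updates of scores (per row) and loadings (per column), after a
weighted-column-mean centering step. Each half-step is an exact WLS solve, so
the objective is non-increasing by construction. Used both to denoise single
blocks before scaling (the filtering route) and to fit the fused component
model itself with weights (the modelling route).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["WpcaModel", "weighted_pca", "project", "mals_filter", "filter_rows"]


@dataclass
class WpcaModel:
    centers: np.ndarray          # weighted column means, frozen for projection
    loadings: np.ndarray         # J × R, orthonormal columns
    scores: np.ndarray           # I × R, weighted LS against the loadings
    n_components: int
    converged: bool
    objective: float             # final S²
    n_iter: int
    objective_history: np.ndarray = field(default_factory=lambda: np.array([]))
    zero_weight_rows: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))
    zero_weight_cols: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))


def _solve_wls_rows(Y: np.ndarray, W2: np.ndarray, P: np.ndarray, ridge: float = 0.0) -> np.ndarray:
    """Per-row WLS: t_i = argmin ‖w_i ∘ (y_i − P t)‖²; batched normal equations."""
    R = P.shape[1]
    A = np.einsum("ij,jr,js->irs", W2, P, P, optimize=True)
    b = np.einsum("ij,jr->ir", W2 * Y, P, optimize=True)
    diag = np.einsum("irr->ir", A)
    eps = ridge + 1e-12 * np.maximum(diag.max(axis=1, keepdims=True), 1e-300)
    A = A + eps[:, :, None] * np.eye(R)
    try:
        return np.linalg.solve(A, b[..., None])[..., 0]
    except np.linalg.LinAlgError:  # pragma: no cover - degenerate fallback
        out = np.empty((Y.shape[0], R))
        for i in range(Y.shape[0]):
            out[i], *_ = np.linalg.lstsq(A[i], b[i], rcond=None)
        return out


def _objective(Y: np.ndarray, W: np.ndarray, T: np.ndarray, P: np.ndarray) -> float:
    resid = W * (Y - T @ P.T)
    return float(np.sum(resid * resid))


def weighted_pca(X: np.ndarray, W: np.ndarray, R: int, tol: float = 1e-9,
                 max_iter: int = 500, center: bool = True, seed: int = 0) -> WpcaModel:
    """Alternating weighted least squares for the rank-R weighted approximation.

    Initialization is the (deterministic) SVD of the centered matrix, so
    ``seed`` only matters if random restarts are ever layered on top. Rows or
    columns whose weights are all zero are flagged and handled by unweighted
    projection. On exit the loadings are orthonormalized and the scores
    re-derived by one more row-wise WLS pass against them.
    """
    X = np.asarray(X, dtype=float)
    W = np.asarray(W, dtype=float)
    if X.shape != W.shape:
        raise ValueError("X and W must have the same shape")
    if np.any(W < 0) or not np.all(np.isfinite(W)):
        raise ValueError("weights must be finite and non-negative")
    I, J = X.shape
    if not 1 <= R <= min(I, J):
        raise ValueError(f"R={R} out of range for a {I}×{J} matrix")
    W2 = W * W
    zero_rows = np.flatnonzero(W2.sum(axis=1) == 0)
    zero_cols = np.flatnonzero(W2.sum(axis=0) == 0)
    # All-zero-weight rows/columns contribute nothing to the objective; their
    # scores (resp. loadings) are set by the unweighted projection. The unit
    # stand-in weights enter only the solve for that row/column itself.
    W2_rows = W2
    if zero_rows.size:
        W2_rows = W2.copy()
        W2_rows[zero_rows, :] = 1.0
    W2_cols = W2
    if zero_cols.size:
        W2_cols = W2.copy()
        W2_cols[:, zero_cols] = 1.0

    if center:
        colw = W2_cols.sum(axis=0)
        centers = np.einsum("ij,ij->j", W2_cols, np.nan_to_num(X)) / np.maximum(colw, 1e-300)
    else:
        centers = np.zeros(J)
    Y = X - centers
    Y = np.nan_to_num(Y, nan=0.0)  # NaN only allowed where the weight is 0

    _, _, Vt = np.linalg.svd(Y, full_matrices=False)
    P = Vt[:R].T
    T = _solve_wls_rows(Y, W2_rows, P)
    history = [_objective(Y, W, T, P)]
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        P = _solve_wls_rows(Y.T, W2_cols.T, T)
        T = _solve_wls_rows(Y, W2_rows, P)
        obj = _objective(Y, W, T, P)
        history.append(obj)
        prev = history[-2]
        if prev - obj <= tol * max(prev, 1e-300):
            converged = True
            break
    # Rotational indeterminacy: orthonormalize via SVD of the fitted matrix,
    # then one exact WLS pass so stored training scores equal their projection.
    Xhat = T @ P.T
    U, s, Vt = np.linalg.svd(Xhat, full_matrices=False)
    P = Vt[:R].T
    T = _solve_wls_rows(Y, W2_rows, P)
    history.append(_objective(Y, W, T, P))
    return WpcaModel(centers=centers, loadings=P, scores=T, n_components=R,
                     converged=converged, objective=history[-1], n_iter=it,
                     objective_history=np.array(history),
                     zero_weight_rows=zero_rows, zero_weight_cols=zero_cols)


def project(model: WpcaModel, x_new: np.ndarray, w_new: np.ndarray | None = None) -> np.ndarray:
    """Scores for new rows: WLS against the frozen loadings after frozen centering."""
    x_new = np.atleast_2d(np.asarray(x_new, dtype=float))
    if w_new is None:
        w_new = np.ones_like(x_new)
    w_new = np.atleast_2d(np.asarray(w_new, dtype=float))
    if x_new.shape != w_new.shape:
        raise ValueError("new rows and weights must have the same shape")
    W2 = w_new * w_new
    dead = W2.sum(axis=1) == 0
    if np.any(dead):
        W2 = W2.copy()
        W2[dead, :] = 1.0
    Y = x_new - model.centers
    Y = np.where(np.isfinite(Y), Y, 0.0)
    return _solve_wls_rows(Y, W2, model.loadings)


def mals_filter(X: np.ndarray, W: np.ndarray, R: int, **kwargs) -> tuple[np.ndarray, WpcaModel]:
    """Denoise one block: rank-R weighted reconstruction centers + T Pᵀ."""
    model = weighted_pca(X, W, R, **kwargs)
    return model.centers + model.scores @ model.loadings.T, model


def filter_rows(model: WpcaModel, x_new: np.ndarray, w_new: np.ndarray | None = None) -> np.ndarray:
    """Apply a frozen filter model to new rows (project, then reconstruct)."""
    t = project(model, x_new, w_new)
    return model.centers + t @ model.loadings.T
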