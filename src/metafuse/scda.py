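"""Simultaneous component analysis of fused blocks and LDA on its scores.

SCA-P fits one shared score matrix T and per-block loadings P_k by an ordinary
SVD of the column-concatenated (pre-processed) blocks X_c = [X_1 … X_K]. A
two-class Fisher discriminant is then fitted on the leading R scores (PCDA for
K=1, SCDA for fused blocks). In the weighted variant the concatenated blocks
are fitted with element-wise weights (maximum-likelihood fusion) and the LDA
runs on the weighted scores.

Variable-level importance is recovered by pushing the discriminant direction
back through the loadings, b = P_c β, and splitting b per block.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import wpca as _wpca
from .datamodel import FusedBlocks

__all__ = ["ScaModel", "DiscriminantModel", "sca_fit", "lda_fit", "scda_predict",
           "variable_weights", "weighted_scda_fit"]


@dataclass
class ScaModel:
    """Shared scores and stacked per-block loadings of an SCA-P fit."""

    scores: np.ndarray              # I × R
    loadings: np.ndarray            # (Σ J_k) × R, orthonormal columns (unweighted mode)
    n_components: int
    block_sizes: list[int]
    singular_values: np.ndarray | None = None
    mode: str = "unweighted"        # or "weighted"
    wpca_model: "_wpca.WpcaModel | None" = None

    def block_loadings(self) -> list[np.ndarray]:
        edges = np.cumsum(self.block_sizes)[:-1]
        return np.split(self.loadings, edges, axis=0)

    def project(self, x_new: np.ndarray, w_new: np.ndarray | None = None) -> np.ndarray:
        """Scores for new (pre-processed) concatenated rows with frozen loadings."""
        x_new = np.atleast_2d(np.asarray(x_new, dtype=float))
        if self.mode == "weighted":
            assert self.wpca_model is not None
            return _wpca.project(self.wpca_model, x_new, w_new)
        return x_new @ self.loadings


@dataclass
class DiscriminantModel:
    """Two-class Fisher discriminant on component scores.

    β maximizes the between/within scatter quotient (for two classes
    β ∝ Σ_W⁻¹(T̄₁−T̄₂), stored unit-length); the offset is
    β₀ = −½(T̄₁+T̄₂)ᵀβ so the decision value d = tᵀβ + β₀ is zero exactly at
    the class-mean midpoint. d > 0 predicts the first class; the boundary
    itself goes to the second class (strict inequality).
    """

    beta: np.ndarray
    beta0: float
    class_means: tuple[np.ndarray, np.ndarray]
    classes: tuple[str, str]
    sigma_between: np.ndarray = field(repr=False, default=None)
    sigma_within: np.ndarray = field(repr=False, default=None)

    def decision_values(self, scores: np.ndarray) -> np.ndarray:
        return np.atleast_2d(scores) @ self.beta + self.beta0

    def rayleigh_quotient(self, direction: np.ndarray) -> float:
        d = np.asarray(direction, dtype=float)
        return float((d @ self.sigma_between @ d) / (d @ self.sigma_within @ d))


def sca_fit(values: np.ndarray | FusedBlocks, R: int,
            block_sizes: list[int] | None = None) -> ScaModel:
    """SCA-P: top-R SVD of the concatenated pre-processed blocks; T = X_c P_c."""
    if isinstance(values, FusedBlocks):
        block_sizes = [b.n_metabolites for b in values.blocks]
        X = values.values
    else:
        X = np.asarray(values, dtype=float)
        if block_sizes is None:
            block_sizes = [X.shape[1]]
    if sum(block_sizes) != X.shape[1]:
        raise ValueError("block sizes do not sum to the concatenated column count")
    if not 1 <= R <= min(X.shape):
        raise ValueError(f"R={R} out of range for a {X.shape[0]}×{X.shape[1]} matrix")
    _, s, Vt = np.linalg.svd(X, full_matrices=False)
    P = Vt[:R].T
    return ScaModel(scores=X @ P, loadings=P, n_components=R,
                    block_sizes=list(block_sizes), singular_values=s[:R])


def lda_fit(scores: np.ndarray, labels, classes: tuple[str, str] | None = None,
            ridge: float = 1e-8) -> DiscriminantModel:
    """Fisher LDA on component scores with unnormalized scatter matrices.

    Scatters are plain sums (no n−1 division); β is scale-invariant to that
    convention. A ridge of ``ridge``·trace(Σ_W)/R is added to Σ_W only when it
    is numerically singular.
    """
    T = np.asarray(scores, dtype=float)
    labels = np.asarray([str(l) for l in labels])
    uniq = sorted(set(labels.tolist()))
    if classes is None:
        if len(uniq) != 2:
            raise ValueError(f"exactly two classes required, got {uniq}")
        classes = (uniq[0], uniq[1])
    m1 = labels == classes[0]
    m2 = labels == classes[1]
    if m1.sum() < 2 or m2.sum() < 2:
        raise ValueError("each class needs at least 2 samples")
    if not np.all(m1 | m2):
        raise ValueError("labels outside the two declared classes")
    t1, t2 = T[m1], T[m2]
    mean1, mean2 = t1.mean(axis=0), t2.mean(axis=0)
    diff = mean1 - mean2
    sb = np.outer(diff, diff)
    sw = (t1 - mean1).T @ (t1 - mean1) + (t2 - mean2).T @ (t2 - mean2)
    R = T.shape[1]
    try:
        beta = np.linalg.solve(sw, diff)
        if not np.all(np.isfinite(beta)):
            raise np.linalg.LinAlgError
    except np.linalg.LinAlgError:
        sw_r = sw + ridge * np.trace(sw) / R * np.eye(R)
        beta = np.linalg.solve(sw_r, diff)
    nrm = np.linalg.norm(beta)
    if nrm == 0:
        raise ValueError("degenerate discriminant: identical class means")
    beta = beta / nrm
    beta0 = float(-0.5 * (mean1 + mean2) @ beta)
    return DiscriminantModel(beta=beta, beta0=beta0, class_means=(mean1, mean2),
                             classes=classes, sigma_between=sb, sigma_within=sw)


def scda_predict(sca: ScaModel, dm: DiscriminantModel, new_rows: np.ndarray,
                 w_new: np.ndarray | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Class labels and decision values for new pre-processed concatenated rows."""
    t = sca.project(new_rows, w_new)
    d = dm.decision_values(t)
    labels = np.where(d > 0, dm.classes[0], dm.classes[1])
    return labels, d


def variable_weights(sca: ScaModel, dm: DiscriminantModel) -> tuple[np.ndarray, list[np.ndarray]]:
    """Metabolite-level discriminant weights b = P_c β and their per-block split."""
    b = sca.loadings @ dm.beta
    edges = np.cumsum(sca.block_sizes)[:-1]
    return b, np.split(b, edges)


def weighted_scda_fit(values: np.ndarray, weights: np.ndarray, labels, R: int,
                      block_sizes: list[int] | None = None,
                      classes: tuple[str, str] | None = None,
                      **wpca_kwargs) -> tuple[ScaModel, DiscriminantModel]:
    """Maximum-likelihood fusion: weighted PCA of the concatenated blocks, then
    LDA on the weighted scores.

    ``values``/``weights`` are the concatenated pre-processed blocks (autoscaled
    and blockscaled) with weights expressed in the same scaled units.
    """
    X = np.asarray(values, dtype=float)
    if block_sizes is None:
        block_sizes = [X.shape[1]]
    model = _wpca.weighted_pca(X, np.asarray(weights, dtype=float), R, **wpca_kwargs)
    sca = ScaModel(scores=model.scores, loadings=model.loadings, n_components=R,
                   block_sizes=list(block_sizes), mode="weighted", wpca_model=model)
    dm = lda_fit(model.scores, labels, classes=classes)
    return sca, dm
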