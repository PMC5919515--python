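"""Variance-stabilizing transformations.

sqrt and log need no training information. The generalized logarithm
``g(x) = ln(x + sqrt(x² + λ))`` interpolates between a shifted linear map for
x² ≪ λ (where measurement error is additive and should be left alone) and
ln(2x) for x² ≫ λ (where error is multiplicative and needs log compression).
λ is tuned by maximum likelihood from duplicate work-ups of the same samples:
the right λ makes the transformed replicate deviations homoscedastic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar


@dataclass
class GlogParams:
    """Fitted glog tuning parameter, one per block or optionally per metabolite.

    ``lam`` is in squared-intensity units; for the two-component error model
    x = μ·e^η + ε the variance-stabilizing value is approximately
    var(ε)/var(η).
    """

    lam: float
    per_metabolite: np.ndarray | None = None  # NaN entries fall back to ``lam``

    def __post_init__(self) -> None:
        if self.lam < 0:
            raise ValueError("glog lambda must be non-negative")
        if self.per_metabolite is not None:
            self.per_metabolite = np.asarray(self.per_metabolite, dtype=float)
            if np.any(self.per_metabolite[np.isfinite(self.per_metabolite)] < 0):
                raise ValueError("per-metabolite lambdas must be non-negative")

    def lambda_for_columns(self, n_columns: int) -> np.ndarray:
        lam = np.full(n_columns, self.lam, dtype=float)
        if self.per_metabolite is not None:
            if self.per_metabolite.shape[0] != n_columns:
                raise ValueError("per-metabolite lambda length mismatch")
            ok = np.isfinite(self.per_metabolite)
            lam[ok] = self.per_metabolite[ok]
        return lam


def sqrt_transform(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if np.any(x[np.isfinite(x)] < 0):
        raise ValueError("sqrt transform requires non-negative intensities")
    return np.sqrt(x)


def log_transform(x: np.ndarray, floor: float | None = None) -> np.ndarray:
    """Natural log with a positive floor guarding zeros.

    Default floor: 1e-12 of the largest finite value (intensity ratios have no
    natural unit, so the floor is taken relative to the block's own scale).
    """
    x = np.asarray(x, dtype=float)
    if np.any(x[np.isfinite(x)] < 0):
        raise ValueError("log transform requires non-negative intensities")
    if floor is None:
        mx = np.nanmax(x) if np.isfinite(x).any() else 1.0
        floor = 1e-12 * (mx if mx > 0 else 1.0)
    if floor <= 0:
        raise ValueError("log floor must be positive")
    return np.log(np.maximum(x, floor))


def glog_transform(x: np.ndarray, params: GlogParams | float) -> np.ndarray:
    """g(x) = ln(x + sqrt(x² + λ)); strictly increasing, defined for all x when λ>0.

    For negative x the equivalent form ln λ − ln(−x + sqrt(x² + λ)) is used:
    it avoids the catastrophic cancellation of the naive expression and makes
    the symmetry identity g(x) + g(−x) = ln λ hold to machine precision.
    """
    x = np.asarray(x, dtype=float)
    if isinstance(params, GlogParams):
        lam = params.lambda_for_columns(x.shape[-1]) if x.ndim > 0 and params.per_metabolite is not None else params.lam
    else:
        lam = float(params)
        if lam < 0:
            raise ValueError("glog lambda must be non-negative")
    ax = np.abs(x)
    pos = np.log(ax + np.sqrt(ax * ax + lam))
    with np.errstate(divide="ignore"):
        return np.where(x >= 0, pos, np.log(lam) - pos)


def glog_derivative(x: np.ndarray, lam) -> np.ndarray:
    return 1.0 / np.sqrt(np.asarray(x, dtype=float) ** 2 + lam)


def apply_glog_to_test(x_new: np.ndarray, params: GlogParams) -> np.ndarray:
    """Transform new rows with the frozen training λ (never refit on test data)."""
    return glog_transform(x_new, params)


# ---------------------------------------------------------------------------
# Maximum-likelihood λ tuning from replicate pairs


def _pair_negloglik(log_lam: float, x1: np.ndarray, x2: np.ndarray) -> float:
    """Profile negative log-likelihood of a constant-variance normal on the
    transformed replicate deviations, with the change-of-variables Jacobian.

    For each pair the two deviations from the (profiled-out) pair mean are
    ±(g(x1)−g(x2))/2, contributing (g1−g2)²/2 to the deviation sum of squares;
    the full-ML variance counts all 2N observations. ln g'(x) = −½ ln(x² + λ).
    """
    lam = np.exp(log_lam)
    g1 = np.log(x1 + np.sqrt(x1 * x1 + lam))
    g2 = np.log(x2 + np.sqrt(x2 * x2 + lam))
    d2 = 0.5 * (g1 - g2) ** 2
    n = x1.size + x2.size
    s2 = d2.sum() / n
    if s2 <= 0:
        return np.inf
    jacobian = -0.5 * (np.log(x1 * x1 + lam).sum() + np.log(x2 * x2 + lam).sum())
    return 0.5 * n * np.log(s2) - jacobian


def fit_glog_lambda(replicates, mode: str = "block",
                    min_pairs_per_metabolite: int = 3) -> GlogParams:
    """Tune λ by maximum likelihood on duplicate work-ups.

    ``replicates`` provides the raw paired values (``x1``, ``x2`` arrays of
    shape D × J and ``pair_var``), e.g. an ``errormodel.ReplicateSet``.
    ``mode='block'`` fits a single λ; ``mode='metabolite'`` fits one per
    column, falling back to the block λ when a column has fewer than
    ``min_pairs_per_metabolite`` usable pairs.

    The search runs over ln λ on scale-free bounds [ln(1e−8·s²), ln(1e4·s²)],
    s² being the global mean replicate variance.
    """
    x1 = np.asarray(replicates.x1, dtype=float)
    x2 = np.asarray(replicates.x2, dtype=float)
    ok = np.isfinite(x1) & np.isfinite(x2)
    if ok.sum() < 2:
        raise ValueError("glog fitting needs at least 2 replicate pairs")
    s2 = float(np.nanmean(0.5 * (x1[ok] - x2[ok]) ** 2))
    if s2 <= 0:
        raise ValueError("replicates are all identical; lambda is unidentifiable")
    lo, hi = np.log(1e-8 * s2), np.log(1e4 * s2)

    def _fit(a1: np.ndarray, a2: np.ndarray) -> float:
        res = minimize_scalar(_pair_negloglik, bounds=(lo, hi), args=(a1, a2),
                              method="bounded", options={"xatol": 1e-6})
        return float(np.exp(res.x))

    block_lam = _fit(x1[ok], x2[ok])
    if mode == "block":
        return GlogParams(lam=block_lam)
    if mode != "metabolite":
        raise ValueError(f"unknown lambda mode {mode!r}")
    n_col = x1.shape[1]
    per = np.full(n_col, np.nan)
    for j in range(n_col):
        mask = ok[:, j]
        if mask.sum() >= min_pairs_per_metabolite and np.any(x1[mask, j] != x2[mask, j]):
            per[j] = _fit(x1[mask, j], x2[mask, j])
    return GlogParams(lam=block_lam, per_metabolite=per)
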