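"""Measurement-error variance models estimated from duplicate work-ups.

Each duplicated sample yields, per metabolite, a level estimate
μ = (x₁+x₂)/2 and a one-degree-of-freedom variance estimate σ² = (x₁−x₂)²/2.
Two error structures are fitted to these (μ, σ²) clouds:

* a two-component (additive + multiplicative) piecewise model per metabolite
  *group* — constant variance σ_Add² below a cutoff α, growing as
  σ_Add² + σ_Mult²(μ−α)² above it — fitted by a two-step robust (Huber)
  procedure over a grid of cutoffs;
* a constant median variance per *metabolite*, robust to outlying pairs and
  independent of the measured level.

Either model converts intensities into element-wise weights w = 1/σ for the
weighted component analyses.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .datamodel import MetaboliteBlock, SampleTable

__all__ = [
    "ReplicateSet", "RockeLorenzatoFit", "RockeLorenzatoModel", "MedianErrorModel",
    "pair_stats", "fit_rocke_lorenzato", "fit_rocke_lorenzato_all",
    "fit_median_model", "predict_sigma", "build_weights",
    "huber_regress", "huber_location",
]


@dataclass
class ReplicateSet:
    """Paired duplicate measurements and their per-pair (mean, variance) stats.

    Arrays are D × J (pairs × metabolites); NaN marks pairs where either
    work-up is missing for that metabolite.
    """

    x1: np.ndarray
    x2: np.ndarray
    metabolite_ids: list[str]
    metabolite_group: list[str]
    pair_ids: list[tuple[str, str, str]]  # (sample_id_1, sample_id_2, replicate_group)

    def __post_init__(self) -> None:
        self.x1 = np.asarray(self.x1, dtype=float)
        self.x2 = np.asarray(self.x2, dtype=float)
        if self.x1.shape != self.x2.shape:
            raise ValueError("replicate arrays must have equal shape")

    @property
    def n_pairs(self) -> int:
        return self.x1.shape[0]

    @property
    def pair_mean(self) -> np.ndarray:
        return 0.5 * (self.x1 + self.x2)

    @property
    def pair_var(self) -> np.ndarray:
        return 0.5 * (self.x1 - self.x2) ** 2

    def pooled_group_points(self, group: str) -> tuple[np.ndarray, np.ndarray]:
        """All finite (μ, σ²) points of the metabolites belonging to ``group``."""
        cols = [j for j, g in enumerate(self.metabolite_group) if g == group]
        if not cols:
            raise KeyError(f"no metabolites in group {group!r}")
        mu = self.pair_mean[:, cols].ravel()
        s2 = self.pair_var[:, cols].ravel()
        ok = np.isfinite(mu) & np.isfinite(s2)
        return mu[ok], s2[ok]


def pair_stats(block: MetaboliteBlock, sample_table: SampleTable) -> ReplicateSet:
    """Collect the duplicate pairs annotated in the sample table from a block."""
    pairs = sample_table.replicate_pairs()
    if not pairs:
        raise ValueError("sample table contains no replicate pairs")
    row_of = {s: i for i, s in enumerate(block.sample_ids)}
    x1, x2, ids = [], [], []
    for i1, i2, g in pairs:
        s1, s2_ = sample_table.sample_ids[i1], sample_table.sample_ids[i2]
        if s1 not in row_of or s2_ not in row_of:
            raise ValueError(f"replicate pair {g!r}: samples {s1!r}/{s2_!r} missing from block")
        x1.append(block.values[row_of[s1]])
        x2.append(block.values[row_of[s2_]])
        ids.append((s1, s2_, g))
    return ReplicateSet(np.array(x1), np.array(x2), list(block.metabolite_ids),
                        list(block.metabolite_group), ids)


def merge_replicates(sets: list[ReplicateSet]) -> ReplicateSet:
    """Column-concatenate replicate sets from blocks sharing the same pairs."""
    ref = sets[0].pair_ids
    for s in sets[1:]:
        if s.pair_ids != ref:
            raise ValueError("replicate sets do not share the same pairs")
    return ReplicateSet(
        np.hstack([s.x1 for s in sets]), np.hstack([s.x2 for s in sets]),
        [m for s in sets for m in s.metabolite_ids],
        [g for s in sets for g in s.metabolite_group], ref,
    )


# ---------------------------------------------------------------------------
# Huber robust fitting (IRLS, MATLAB-robustfit conventions)

_HUBER_C = 1.345


def huber_regress(X: np.ndarray, y: np.ndarray, c: float = _HUBER_C,
                  max_iter: int = 100, tol: float = 1e-10) -> np.ndarray:
    """Huber M-regression by IRLS; residual scale = MAD/0.6745 each iteration.

    Falls back to the least-squares solution when residual scale collapses
    (perfect fits). No intercept is added; pass a column of ones for one.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != np.asarray(y).shape[0]:
        X = X.T
    y = np.asarray(y, dtype=float)
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    yscale = max(float(np.max(np.abs(y))), 1e-300)
    for _ in range(max_iter):
        r = y - X @ beta
        s = np.median(np.abs(r)) / 0.6745
        if s <= 1e-12 * yscale:
            break
        u = np.abs(r) / (c * s)
        w = np.where(u <= 1.0, 1.0, 1.0 / np.maximum(u, 1e-300))
        Xw = X * w[:, None]
        beta_new, *_ = np.linalg.lstsq(Xw.T @ X, Xw.T @ y, rcond=None)
        if np.max(np.abs(beta_new - beta)) <= tol * (1.0 + np.max(np.abs(beta))):
            beta = beta_new
            break
        beta = beta_new
    return beta


def huber_location(y: np.ndarray, c: float = _HUBER_C) -> float:
    """Robust location (constant-only Huber regression)."""
    y = np.asarray(y, dtype=float)
    if y.size == 0:
        raise ValueError("empty sample")
    return float(huber_regress(np.ones((y.size, 1)), y, c=c)[0])


# ---------------------------------------------------------------------------
# Two-component piecewise model per metabolite group


@dataclass
class RockeLorenzatoFit:
    """Fitted parameters of the piecewise error-variance law for one group."""

    sigma_add: float
    sigma_mult: float
    alpha: float
    objective: float
    n_points: int

    def predict_var(self, mu: np.ndarray) -> np.ndarray:
        mu = np.asarray(mu, dtype=float)
        extra = np.where(mu > self.alpha, (self.sigma_mult * (mu - self.alpha)) ** 2, 0.0)
        return self.sigma_add ** 2 + extra


@dataclass
class RockeLorenzatoModel:
    """One piecewise fit per metabolite group (amines + lipid classes)."""

    fits: dict[str, RockeLorenzatoFit]
    group_of_metabolite: dict[str, str] = field(default_factory=dict)

    def fit_for(self, group: str) -> RockeLorenzatoFit:
        if group not in self.fits:
            raise KeyError(f"no error model fitted for group {group!r}")
        return self.fits[group]


def _piecewise_objective(mu, s2, alpha, sig_add2, sig_mult2):
    pred = sig_add2 + np.where(mu > alpha, sig_mult2 * (mu - alpha) ** 2, 0.0)
    return float(np.sum((s2 - pred) ** 2))


def fit_rocke_lorenzato(replicates: ReplicateSet, group: str, n_alpha: int = 25,
                        step1: str = "huber", step2: str = "huber") -> RockeLorenzatoFit:
    """Two-step fit of the piecewise variance law on the pooled group cloud.

    For each candidate cutoff α (empirical 2.5%…97.5% quantiles of the pooled
    levels, plus 0): step 1 estimates σ_Add² as a robust location of the
    variances at levels ≤ α; step 2 regresses the excess variance on (μ−α)²
    without intercept (Huber weights) over levels > α. The candidate with the
    smallest plain sum of squared variance residuals wins; negative estimates
    are clipped to zero.

    ``step1`` selects the location estimator below the cutoff: 'huber'
    (default), 'mean' or 'median'. ``step2`` selects the slope estimator above
    it: 'huber' (default) or 'ls'. Because the per-pair variances are strongly
    right-skewed (1 degree of freedom), the robust slope is biased low, which
    the cutoff selection partially compensates by drifting upward; the 'ls'
    slope is the consistent choice when unbiased parameter recovery matters
    more than outlier resistance.
    """
    mu, s2 = replicates.pooled_group_points(group)
    if mu.size < 4:
        raise ValueError(f"group {group!r}: need ≥4 (mean, variance) points, got {mu.size}")
    qs = np.quantile(mu, np.linspace(0.025, 0.975, n_alpha))
    candidates = np.unique(np.concatenate([[0.0], qs]))
    locate = {"huber": huber_location, "mean": np.mean, "median": np.median}[step1]
    best: RockeLorenzatoFit | None = None
    for alpha in candidates:
        below = s2[mu <= alpha]
        above = mu > alpha
        sig_add2 = max(float(locate(below)), 0.0) if below.size else 0.0
        if np.any(above):
            x = (mu[above] - alpha) ** 2
            y = s2[above] - sig_add2
            if step2 == "huber":
                slope = float(huber_regress(x[:, None], y)[0])
            elif step2 == "ls":
                slope = float((x @ y) / (x @ x))
            else:
                raise ValueError(f"unknown step2 estimator {step2!r}")
            sig_mult2 = max(slope, 0.0)
        else:
            sig_mult2 = 0.0
        obj = _piecewise_objective(mu, s2, alpha, sig_add2, sig_mult2)
        if best is None or obj < best.objective:
            best = RockeLorenzatoFit(np.sqrt(sig_add2), np.sqrt(sig_mult2),
                                     float(alpha), obj, mu.size)
    assert best is not None
    return best


def fit_rocke_lorenzato_all(replicates: ReplicateSet, **kwargs) -> RockeLorenzatoModel:
    groups = sorted(set(replicates.metabolite_group))
    fits = {g: fit_rocke_lorenzato(replicates, g, **kwargs) for g in groups}
    gmap = dict(zip(replicates.metabolite_ids, replicates.metabolite_group))
    return RockeLorenzatoModel(fits, gmap)


# ---------------------------------------------------------------------------
# Median (constant-per-metabolite) model


@dataclass
class MedianErrorModel:
    """Median pair variance per metabolite; error independent of the level."""

    sigma2: np.ndarray
    metabolite_ids: list[str]

    def __post_init__(self) -> None:
        self.sigma2 = np.asarray(self.sigma2, dtype=float)
        if np.any(self.sigma2[np.isfinite(self.sigma2)] < 0):
            raise ValueError("median variances must be non-negative")

    def sigma2_for(self, metabolite: str) -> float:
        try:
            return float(self.sigma2[self.metabolite_ids.index(metabolite)])
        except ValueError as exc:
            raise KeyError(f"unknown metabolite {metabolite!r}") from exc


def fit_median_model(replicates: ReplicateSet) -> MedianErrorModel:
    pv = replicates.pair_var
    n_valid = np.isfinite(pv).sum(axis=0)
    if np.any(n_valid == 0):
        bad = [replicates.metabolite_ids[j] for j in np.flatnonzero(n_valid == 0)]
        raise ValueError(f"metabolite(s) with no replicate pair: {bad[:5]}")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        med = np.nanmedian(pv, axis=0)
    if np.any(med == 0):
        warnings.warn("some metabolites have zero median replicate variance; "
                      "their weights will be capped", stacklevel=2)
    return MedianErrorModel(med, list(replicates.metabolite_ids))


# ---------------------------------------------------------------------------
# Prediction and weight construction


def predict_sigma(model, mu, metabolite: str | None = None, group: str | None = None) -> np.ndarray:
    """Error SD at level ``mu`` under either fitted model.

    For the piecewise group model pass ``group`` (or ``metabolite`` if the model
    knows its group); the median model ignores ``mu`` and needs ``metabolite``.
    """
    mu = np.asarray(mu, dtype=float)
    if isinstance(model, RockeLorenzatoModel):
        if group is None:
            if metabolite is None:
                raise ValueError("piecewise model prediction needs a group or metabolite")
            if metabolite not in model.group_of_metabolite:
                raise KeyError(f"unknown metabolite {metabolite!r}")
            group = model.group_of_metabolite[metabolite]
        return np.sqrt(model.fit_for(group).predict_var(mu))
    if isinstance(model, MedianErrorModel):
        if metabolite is None:
            raise ValueError("median model prediction needs a metabolite id")
        return np.sqrt(model.sigma2_for(metabolite)) * np.ones_like(mu)
    raise TypeError(f"unsupported error model {type(model).__name__}")


def sigma_matrix(block: MetaboliteBlock, model) -> np.ndarray:
    """Per-element error SD for a block, using measured values as level proxy."""
    if isinstance(model, MedianErrorModel):
        idx = [model.metabolite_ids.index(m) for m in block.metabolite_ids]
        sig = np.sqrt(model.sigma2[idx])
        return np.broadcast_to(sig, block.values.shape).copy()
    if isinstance(model, RockeLorenzatoModel):
        out = np.empty_like(block.values)
        for j, g in enumerate(block.metabolite_group):
            out[:, j] = np.sqrt(model.fit_for(g).predict_var(block.values[:, j]))
        return out
    raise TypeError(f"unsupported error model {type(model).__name__}")


def build_weights(block: MetaboliteBlock, model, cap_factor: float = 1e3) -> np.ndarray:
    """Element-wise weights w = 1/σ, with missing entries weighted 0.

    The measured value stands in for the unobserved true level. Weights above
    ``cap_factor`` times the block's median positive weight are capped so that
    near-zero variance estimates cannot dominate the weighted fits.
    """
    sig = sigma_matrix(block, model)
    missing = ~np.isfinite(block.values)
    with np.errstate(divide="ignore"):
        w = np.where(sig > 0, 1.0 / np.where(sig > 0, sig, 1.0), np.inf)
    finite_pos = w[np.isfinite(w) & (w > 0)]
    if finite_pos.size == 0:
        raise ValueError("all weights are infinite; configure a cap or refit the model")
    if cap_factor is None and np.any(~np.isfinite(w)):
        raise ValueError("zero predicted error SD encountered and no weight cap configured")
    cap = cap_factor * float(np.median(finite_pos))
    w = np.minimum(w, cap)
    w[missing] = 0.0
    return w
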