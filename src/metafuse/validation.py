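"""Cross-model validation of the fusion classifiers, and univariate screening.

The harness splits the analysis samples into 8 class-stratified parts, trains
every data-dependent step (transform parameters, centering/scaling, filter
models, component models, LDA) on 7 parts and predicts the held-out part, so
test samples never influence any fitted parameter. The split is redrawn 25
times (configurable) and the per-repeat misclassification counts are averaged.
Component counts are fixed per run (3/5/7 by default), never optimized inside
a fold. Metabolite importance is the mean |b| of the discriminant's
variable-level weights over all parts × repeats models.

The glog λ and the measurement-error models are estimated from the duplicate
work-ups, which are separate samples from the 31 analysis samples; those fits
are therefore fold-invariant and computed once per run.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import errormodel as _em
from . import scda as _scda
from . import transforms as _tf
from . import wpca as _wpca
from .datamodel import FusedBlocks, MetaboliteBlock, SampleTable, ScalingParams, apply_scaling, fit_scaling

__all__ = [
    "TRANSFORM_METHODS", "MALS_METHODS", "WEIGHTED_METHODS", "valid_configurations",
    "FoldPlan", "make_fold_plan", "FoldModel", "fit_fold", "predict_fold",
    "CvResult", "run_cv", "importance_table", "TtestResult", "ttest_screen",
]

TRANSFORM_METHODS = ("raw", "sqrt", "log", "glog")
MALS_METHODS = ("mals_rl", "mals_med")
WEIGHTED_METHODS = ("weighted_rl", "weighted_med")
ALL_METHODS = TRANSFORM_METHODS + MALS_METHODS + WEIGHTED_METHODS


def valid_configurations() -> list[tuple[str, str]]:
    """The 14 supported (method, scaling) configurations."""
    combos = [(m, s) for m in TRANSFORM_METHODS + MALS_METHODS for s in ("center", "auto")]
    combos += [(m, "auto") for m in WEIGHTED_METHODS]
    return combos


# ---------------------------------------------------------------------------
# Fold plans


@dataclass
class FoldPlan:
    """One stratified partition of the analysis samples into parts."""

    parts: list[np.ndarray]
    repeat_index: int = 0

    def __post_init__(self) -> None:
        allidx = np.concatenate(self.parts)
        if len(np.unique(allidx)) != allidx.size:
            raise ValueError("fold parts overlap")


def make_fold_plan(labels, classes: tuple[str, str], rng: np.random.Generator,
                   n_parts: int = 8, repeat_index: int = 0) -> FoldPlan:
    """Random stratified split: each class spread as evenly as possible over the
    parts, surplus going to the earlier parts (so with 16+15 samples in 8 parts
    the first 7 parts hold 2+2 and the last 2+1)."""
    labels = np.asarray([str(l) for l in labels])
    per_part: list[list[int]] = [[] for _ in range(n_parts)]
    for cls in classes:
        idx = np.flatnonzero(labels == cls)
        if idx.size < n_parts:
            warnings.warn(
                f"class {cls!r} has {idx.size} samples for {n_parts} parts; "
                "some parts will lack this class", stacklevel=2)
        idx = rng.permutation(idx)
        base, extra = divmod(idx.size, n_parts)
        start = 0
        for p in range(n_parts):
            size = base + (1 if p < extra else 0)
            per_part[p].extend(idx[start:start + size].tolist())
            start += size
    return FoldPlan([np.array(sorted(p), dtype=int) for p in per_part], repeat_index)


# ---------------------------------------------------------------------------
# Per-fold fitting (training rows only — structural leakage guard)


@dataclass
class FoldModel:
    """Everything fitted on one training fold, frozen for test prediction."""

    method: str
    scaling: str
    classes: tuple[str, str]
    components: tuple[int, ...]
    scaling_params: list[ScalingParams]
    per_component: dict[int, tuple[_scda.ScaModel, _scda.DiscriminantModel, np.ndarray]]
    mals_models: list[_wpca.WpcaModel] | None = None
    error_model: object | None = None
    weight_cap: float = 1e3


def _scaled_weights(block: MetaboliteBlock, model, params: ScalingParams,
                    cap_factor: float) -> np.ndarray:
    """Weights 1/σ in the units of the scaled data: the error SD propagates
    through the affine scaling, σ_scaled = σ / (scale · block_factor)."""
    sig = _em.sigma_matrix(block, model)
    denom = (params.scale if params.scale is not None else 1.0) * params.block_factor
    sig = sig / denom
    missing = ~np.isfinite(block.values)
    with np.errstate(divide="ignore"):
        w = np.where(sig > 0, 1.0 / np.where(sig > 0, sig, 1.0), np.inf)
    pos = w[np.isfinite(w) & (w > 0)]
    if pos.size == 0:
        raise ValueError("all scaled weights are infinite")
    w = np.minimum(w, cap_factor * float(np.median(pos)))
    w[missing] = 0.0
    return w


def fit_fold(train: FusedBlocks, train_features: list[np.ndarray], train_labels,
             method: str, scaling: str, classes: tuple[str, str],
             components: tuple[int, ...] = (3, 5, 7), error_model=None,
             mals_components: int = 7, weight_cap: float = 1e3) -> FoldModel:
    """Fit one training fold. ``train_features`` are the (already transformed)
    per-block matrices for the transformation route; the filter and modelling
    routes work from the raw block values and the replicate-derived error model."""
    if method not in ALL_METHODS:
        raise ValueError(f"unknown method {method!r}")
    labels = np.asarray([str(l) for l in train_labels])
    per_component: dict[int, tuple] = {}
    mals_models = None

    if method in TRANSFORM_METHODS + MALS_METHODS:
        if method in MALS_METHODS:
            if error_model is None:
                raise ValueError(f"{method} requires a fitted error model")
            feats, mals_models = [], []
            for blk in train.blocks:
                w = _em.build_weights(blk, error_model, cap_factor=weight_cap)
                r_f = min(mals_components, blk.n_samples - 1, blk.n_metabolites)
                filt, wm = _wpca.mals_filter(blk.values, w, r_f)
                feats.append(filt)
                mals_models.append(wm)
        else:
            feats = [np.asarray(f, dtype=float) for f in train_features]
        scaled, sparams = [], []
        for f in feats:
            z, p = fit_scaling(f, scaling)
            scaled.append(z)
            sparams.append(p)
        Xc = np.hstack(scaled)
        block_sizes = [b.n_metabolites for b in train.blocks]
        r_max = min(max(components), min(Xc.shape))
        full = _scda.sca_fit(Xc, r_max, block_sizes=block_sizes)
        for R in components:
            r = min(R, r_max)
            P = full.loadings[:, :r]
            sca = _scda.ScaModel(scores=full.scores[:, :r], loadings=P, n_components=r,
                                 block_sizes=block_sizes)
            dm = _scda.lda_fit(sca.scores, labels, classes=classes)
            b, _ = _scda.variable_weights(sca, dm)
            per_component[R] = (sca, dm, b)
    else:  # weighted fusion: autoscale + blockscale, then weighted component fit
        if error_model is None:
            raise ValueError(f"{method} requires a fitted error model")
        scaled, sparams, wts = [], [], []
        for blk in train.blocks:
            z, p = fit_scaling(blk.values, "auto")
            scaled.append(np.nan_to_num(z, nan=0.0))
            sparams.append(p)
            wts.append(_scaled_weights(blk, error_model, p, weight_cap))
        Xc, Wc = np.hstack(scaled), np.hstack(wts)
        block_sizes = [b.n_metabolites for b in train.blocks]
        for R in components:
            r = min(R, min(Xc.shape))
            sca, dm = _scda.weighted_scda_fit(Xc, Wc, labels, r,
                                              block_sizes=block_sizes, classes=classes)
            b, _ = _scda.variable_weights(sca, dm)
            per_component[R] = (sca, dm, b)
    return FoldModel(method=method, scaling=scaling, classes=classes,
                     components=tuple(components), scaling_params=sparams,
                     per_component=per_component, mals_models=mals_models,
                     error_model=error_model, weight_cap=weight_cap)


def predict_fold(fm: FoldModel, test: FusedBlocks,
                 test_features: list[np.ndarray]) -> dict[int, np.ndarray]:
    """Predict class labels of test rows with every parameter frozen."""
    if fm.method in TRANSFORM_METHODS + MALS_METHODS:
        if fm.method in MALS_METHODS:
            feats = []
            for blk, wm in zip(test.blocks, fm.mals_models):
                w = _em.build_weights(blk, fm.error_model, cap_factor=fm.weight_cap)
                feats.append(_wpca.filter_rows(wm, blk.values, w))
        else:
            feats = test_features
        Xc = np.hstack([apply_scaling(f, p) for f, p in zip(feats, fm.scaling_params)])
        out = {}
        for R, (sca, dm, _) in fm.per_component.items():
            labels, _d = _scda.scda_predict(sca, dm, Xc)
            out[R] = labels
        return out
    zc, wc = [], []
    for blk, p in zip(test.blocks, fm.scaling_params):
        zc.append(np.nan_to_num(apply_scaling(blk.values, p), nan=0.0))
        wc.append(_scaled_weights(blk, fm.error_model, p, fm.weight_cap))
    Xc, Wc = np.hstack(zc), np.hstack(wc)
    out = {}
    for R, (sca, dm, _) in fm.per_component.items():
        labels, _d = _scda.scda_predict(sca, dm, Xc, w_new=Wc)
        out[R] = labels
    return out


# ---------------------------------------------------------------------------
# The repeated cross-validation harness


@dataclass
class CvResult:
    """Misclassification counts and variable importance of one configuration."""

    method: str
    scaling: str
    components: tuple[int, ...]
    repeats: int
    n_parts: int
    seed: int
    n_samples: int
    counts: dict[int, np.ndarray]          # per component count: length-``repeats``
    importance: dict[int, np.ndarray]      # mean |b| over parts × repeats models
    metabolite_ids: list[str]
    metabolite_group: list[str]
    repeat_seeds: list[int] = field(default_factory=list)

    @property
    def averages(self) -> dict[int, float]:
        return {R: float(np.mean(c)) for R, c in self.counts.items()}


def _prepare_error_model(method: str, blocks: FusedBlocks, sample_table: SampleTable,
                         replicates: _em.ReplicateSet | None, error_model):
    if method not in MALS_METHODS + WEIGHTED_METHODS:
        return None
    if error_model is not None:
        return error_model
    if replicates is None:
        replicates = _em.merge_replicates([_em.pair_stats(b, sample_table) for b in blocks.blocks])
    if method.endswith("_rl"):
        return _em.fit_rocke_lorenzato_all(replicates)
    return _em.fit_median_model(replicates)


def _transform_features(method: str, blocks: FusedBlocks, replicates, glog_params,
                        log_floor) -> tuple[list[np.ndarray], _tf.GlogParams | None]:
    if method == "raw" or method in MALS_METHODS + WEIGHTED_METHODS:
        # filter/modelling routes work from the raw values (weights do the rest)
        return [b.values for b in blocks.blocks], None
    if method == "sqrt":
        return [_tf.sqrt_transform(b.values) for b in blocks.blocks], None
    if method == "log":
        return [_tf.log_transform(b.values, floor=log_floor) for b in blocks.blocks], None
    if method == "glog":
        if glog_params is None:
            if replicates is None:
                raise ValueError("glog needs fitted GlogParams or a replicate set")
            if isinstance(replicates, _em.ReplicateSet):
                glog_params = [_tf.fit_glog_lambda(
                    _subset_replicates(replicates, b.metabolite_ids)) for b in blocks.blocks]
            else:
                glog_params = replicates
        if isinstance(glog_params, _tf.GlogParams):
            glog_params = [glog_params] * len(blocks.blocks)
        feats = [_tf.glog_transform(b.values, p) for b, p in zip(blocks.blocks, glog_params)]
        return feats, glog_params
    raise ValueError(method)


def _subset_replicates(replicates: _em.ReplicateSet, metabolite_ids: list[str]) -> _em.ReplicateSet:
    cols = [replicates.metabolite_ids.index(m) for m in metabolite_ids]
    return _em.ReplicateSet(replicates.x1[:, cols], replicates.x2[:, cols],
                            [replicates.metabolite_ids[c] for c in cols],
                            [replicates.metabolite_group[c] for c in cols],
                            replicates.pair_ids)


def run_cv(blocks: FusedBlocks, sample_table: SampleTable, method: str, scaling: str,
           classes: tuple[str, str] | None = None, components: tuple[int, ...] = (3, 5, 7),
           repeats: int = 25, n_parts: int = 8, seed: int = 0,
           replicates: _em.ReplicateSet | None = None, error_model=None,
           glog_params=None, mals_components: int = 7, weight_cap: float = 1e3,
           log_floor: float | None = None) -> CvResult:
    """Repeated stratified cross-model validation of one configuration.

    ``blocks`` may contain replicate/other samples; only rows whose class label
    is one of the two analysis classes enter the folds. Duplicate-derived fits
    (error model, glog λ) are computed once; everything else is refit per fold.
    """
    if (method, scaling) not in valid_configurations():
        raise ValueError(f"configuration ({method!r}, {scaling!r}) is not one of the "
                         f"supported combinations: {valid_configurations()}")
    if classes is None:
        labs = [c for c in sample_table.class_label if c not in ("", "other")]
        uniq = sorted(set(labs), key=labs.index)
        if len(uniq) != 2:
            raise ValueError("cannot infer the two analysis classes; pass classes=")
        classes = (uniq[0], uniq[1])
    label_of = dict(zip(sample_table.sample_ids, sample_table.class_label))
    rows = np.array([i for i, s in enumerate(blocks.sample_ids)
                     if label_of.get(s) in classes], dtype=int)
    if rows.size < 2 * n_parts // 2:
        raise ValueError("too few analysis samples")
    analysis = blocks.subset_samples(rows)
    labels = np.asarray([label_of[s] for s in analysis.sample_ids])

    if replicates is None and (method in MALS_METHODS + WEIGHTED_METHODS
                               or (method == "glog" and glog_params is None)):
        replicates = _em.merge_replicates(
            [_em.pair_stats(b, sample_table) for b in blocks.blocks])
    emodel = _prepare_error_model(method, blocks, sample_table, replicates, error_model)
    features, _ = _transform_features(method, analysis, replicates, glog_params, log_floor)

    counts = {R: np.zeros(repeats) for R in components}
    imp_sum = {R: np.zeros(analysis.n_columns) for R in components}
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(repeats)
    repeat_seeds = [int(c.generate_state(1)[0] % (2**31)) for c in children]
    n_models = 0
    for r, child in enumerate(children):
        rng = np.random.default_rng(child)
        plan = make_fold_plan(labels, classes, rng, n_parts=n_parts, repeat_index=r)
        for part in plan.parts:
            if part.size == 0:
                continue
            train_idx = np.setdiff1d(np.arange(analysis.n_samples), part)
            train = analysis.subset_samples(train_idx)
            test = analysis.subset_samples(part)
            f_train = [f[train_idx] for f in features]
            f_test = [f[part] for f in features]
            fm = fit_fold(train, f_train, labels[train_idx], method, scaling, classes,
                          components=components, error_model=emodel,
                          mals_components=mals_components, weight_cap=weight_cap)
            preds = predict_fold(fm, test, f_test)
            for R in components:
                counts[R][r] += int(np.sum(preds[R] != labels[part]))
                imp_sum[R] += np.abs(fm.per_component[R][2])
            n_models += 1
    models_each = n_models if n_models else 1  # parts × repeats models per component count
    importance = {R: imp_sum[R] / models_each for R in components}
    return CvResult(method=method, scaling=scaling, components=tuple(components),
                    repeats=repeats, n_parts=n_parts, seed=seed,
                    n_samples=analysis.n_samples, counts=counts, importance=importance,
                    metabolite_ids=analysis.metabolite_ids,
                    metabolite_group=analysis.metabolite_group,
                    repeat_seeds=repeat_seeds)


def importance_table(result: CvResult, R: int, top: int | None = 10) -> pd.DataFrame:
    """Metabolites ranked by mean |b| over all fold models for R components."""
    if R not in result.importance:
        raise KeyError(f"no importance for R={R}; available: {list(result.importance)}")
    df = pd.DataFrame({
        "metabolite": result.metabolite_ids,
        "group": result.metabolite_group,
        "importance": result.importance[R],
    }).sort_values("importance", ascending=False, kind="mergesort").reset_index(drop=True)
    df.index = df.index + 1
    df.index.name = "rank"
    return df.head(top) if top else df


# ---------------------------------------------------------------------------
# Univariate screening


@dataclass
class TtestResult:
    pvalues: np.ndarray
    n_significant: int
    n_bonferroni: int
    alpha: float
    bonferroni_alpha: float
    metabolite_ids: list[str]
    significant_mask: np.ndarray
    bonferroni_mask: np.ndarray


def ttest_screen(values: np.ndarray | FusedBlocks, labels, classes: tuple[str, str] | None = None,
                 alpha: float = 0.05, n_tests: int | None = None,
                 metabolite_ids: list[str] | None = None) -> TtestResult:
    """Pooled-variance two-sided two-sample t-test per metabolite, with counts
    at ``alpha`` and at the Bonferroni limit ``alpha / n_tests``."""
    if isinstance(values, FusedBlocks):
        metabolite_ids = values.metabolite_ids
        values = values.values
    X = np.asarray(values, dtype=float)
    labels = np.asarray([str(l) for l in labels])
    uniq = sorted(set(labels.tolist()))
    if classes is None:
        if len(uniq) != 2:
            raise ValueError(f"exactly two classes required, got {uniq}")
        classes = (uniq[0], uniq[1])
    a, b = X[labels == classes[0]], X[labels == classes[1]]
    if a.shape[0] < 2 or b.shape[0] < 2:
        raise ValueError("each class needs at least 2 samples for a t-test")
    _t, p = stats.ttest_ind(a, b, axis=0, equal_var=True, nan_policy="omit")
    p = np.asarray(p)
    if n_tests is None:
        n_tests = X.shape[1]
    bonf = alpha / n_tests
    sig = p < alpha
    sigb = p < bonf
    return TtestResult(pvalues=p, n_significant=int(np.nansum(sig)),
                       n_bonferroni=int(np.nansum(sigb)), alpha=alpha,
                       bonferroni_alpha=bonf,
                       metabolite_ids=metabolite_ids or [str(j) for j in range(X.shape[1])],
                       significant_mask=sig, bonferroni_mask=sigb)
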