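"""Synthetic two-platform, two-class datasets with level-dependent noise.

The generator emulates the structure of a small human cohort measured on an
amine and a lipid LC-MS platform: two blocks sharing samples, a low-rank
between-class mean shift on latent components, baselines spanning several
orders of magnitude (log-uniform), two-component measurement noise
x = μ·e^η + ε applied per metabolite group, and duplicate work-ups of extra
samples from which error models and the glog λ are estimated. Every stage of
the pipeline is testable against the returned ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.linalg import subspace_angles

from .datamodel import (AMINE_GROUP, LIPID_CLASSES, FusedBlocks, MetaboliteBlock,
                        SampleTable, write_block)

__all__ = ["SyntheticSpec", "generate", "recovery_report", "write_dataset",
           "DEFAULT_LIPID_SPLIT"]

# Lipid-class sizes for the default 165-lipid block (TG- and PC-heavy, as is
# typical of plasma lipidomics panels).
DEFAULT_LIPID_SPLIT = {"TG": 55, "PC": 30, "SM": 15, "CE": 12, "DG": 10,
                       "Cer": 10, "PE": 12, "LPC": 13, "LPE": 8}


@dataclass
class SyntheticSpec:
    """Study conditions for one synthetic dataset.

    Defaults mirror the gastric-bypass cohort layout: 16 + 15 analysis samples,
    43 amines + 165 lipids in the nine lipid classes, 15 duplicate pairs.
    ``effect_size`` is the between-class mean shift on the first latent
    component in latent-SD units (1.5 ⇒ substantially overlapping classes, the
    regime where misclassification counts are informative). ``sigma_mult`` is
    the multiplicative error SD (≈ relative SD, 10% is a typical LC-MS value),
    ``sigma_add`` the additive error SD in intensity-ratio units.
    """

    n_per_class: tuple[int, int] = (16, 15)
    classes: tuple[str, str] = ("healthy_obese", "diabetic_obese")
    n_metabolites: tuple[int, ...] = (43, 165)
    block_names: tuple[str, ...] = ("amines", "lipids")
    n_components: int = 3
    effect_size: float = 1.5
    loading_sparsity: float = 0.5
    rel_loading_scale: float = 0.15
    baseline_range: tuple[float, float] = (0.05, 20.0)
    sigma_add: float | dict = 0.02
    sigma_mult: float | dict = 0.1
    alpha_mult: float | dict = 0.2
    n_duplicate_pairs: int = 15
    noise: str = "lognormal"  # Eq-4-style; "piecewise" draws directly from the fitted law
    lipid_split: dict | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if any(n <= 0 for n in self.n_per_class + self.n_metabolites):
            raise ValueError("sample and metabolite counts must be positive")
        if self.n_duplicate_pairs < 0 or self.n_components < 1:
            raise ValueError("invalid duplicate or component count")
        if self.noise not in ("lognormal", "piecewise"):
            raise ValueError(f"unknown noise mode {self.noise!r}")
        for v in (self.sigma_add, self.sigma_mult, self.alpha_mult):
            vals = v.values() if isinstance(v, dict) else [v]
            if any(x < 0 for x in vals):
                raise ValueError("noise parameters must be non-negative")


def _group_param(param, group: str) -> float:
    return float(param[group]) if isinstance(param, dict) else float(param)


def _make_groups(spec: SyntheticSpec) -> list[list[str]]:
    groups: list[list[str]] = []
    for k, j in enumerate(spec.n_metabolites):
        if k == 0:
            groups.append([AMINE_GROUP] * j)
            continue
        split = dict(spec.lipid_split or DEFAULT_LIPID_SPLIT)
        total = sum(split.values())
        g: list[str] = []
        for cls in LIPID_CLASSES:
            g.extend([cls] * int(round(split.get(cls, 0) * j / total)))
        while len(g) < j:
            g.append("TG")
        groups.append(g[:j])
    return groups


def generate(spec: SyntheticSpec) -> tuple[FusedBlocks, SampleTable, dict]:
    """Draw one dataset; bit-identical for identical specs (seed included)."""
    rng = np.random.default_rng(spec.seed)
    n1, n2 = spec.n_per_class
    n_analysis = n1 + n2
    d = spec.n_duplicate_pairs
    R = spec.n_components
    groups = _make_groups(spec)

    # latent scores: class mean shift on component 1
    scores = rng.standard_normal((n_analysis + d, R))
    scores[:n1, 0] += spec.effect_size / 2.0
    scores[n1:n_analysis, 0] -= spec.effect_size / 2.0

    sample_ids = [f"S{i + 1:02d}" for i in range(n_analysis)]
    labels = [spec.classes[0]] * n1 + [spec.classes[1]] * n2
    rep_groups = [""] * n_analysis
    for p in range(d):
        for suffix in ("a", "b"):
            sample_ids.append(f"rep{p + 1:02d}_{suffix}")
            labels.append("other")
            rep_groups.append(f"rep{p + 1:02d}")

    blocks, truth_loadings, truth_mu, truth_base = [], [], [], []
    lo, hi = spec.baseline_range
    for k, (j_k, name) in enumerate(zip(spec.n_metabolites, spec.block_names)):
        baseline = np.exp(rng.uniform(np.log(lo), np.log(hi), size=j_k))
        load = rng.standard_normal((j_k, R))
        load[rng.random((j_k, R)) < spec.loading_sparsity] = 0.0
        load *= spec.rel_loading_scale * baseline[:, None]
        mu = np.maximum(baseline + scores @ load.T, 0.0)  # (n_analysis + d) × j_k

        sig_add = np.array([_group_param(spec.sigma_add, g) for g in groups[k]])
        sig_mult = np.array([_group_param(spec.sigma_mult, g) for g in groups[k]])
        alpha = np.array([_group_param(spec.alpha_mult, g) for g in groups[k]])

        def observe(m: np.ndarray) -> np.ndarray:
            if spec.noise == "lognormal":
                eta = rng.standard_normal(m.shape) * sig_mult
                eps = rng.standard_normal(m.shape) * sig_add
                x = m * np.exp(eta) + eps
            else:
                sd = np.sqrt(sig_add ** 2
                             + np.where(m > alpha, (sig_mult * (m - alpha)) ** 2, 0.0))
                x = m + rng.standard_normal(m.shape) * sd
            return np.maximum(x, 0.0)

        x_analysis = observe(mu[:n_analysis])
        rep_rows = []
        for p in range(d):
            m_row = mu[n_analysis + p][None, :]
            rep_rows.append(observe(m_row)[0])
            rep_rows.append(observe(m_row)[0])
        values = np.vstack([x_analysis] + ([np.array(rep_rows)] if d else []))
        mets = [f"{g}.{j + 1:03d}" if g != AMINE_GROUP else f"A{j + 1:03d}"
                for j, g in enumerate(groups[k])]
        blocks.append(MetaboliteBlock(values, sample_ids, mets, groups[k], block_name=name))
        truth_loadings.append(load)
        truth_mu.append(mu)
        truth_base.append(baseline)

    table = SampleTable(sample_ids, labels, rep_groups)
    truth = {
        "scores": scores,
        "loadings": truth_loadings,
        "mu": truth_mu,
        "baselines": truth_base,
        "sigma_add": {g: _group_param(spec.sigma_add, g) for gs in groups for g in set(gs)},
        "sigma_mult": {g: _group_param(spec.sigma_mult, g) for gs in groups for g in set(gs)},
        "alpha_mult": {g: _group_param(spec.alpha_mult, g) for gs in groups for g in set(gs)},
        "classes": spec.classes,
        "spec": spec,
    }
    return FusedBlocks(blocks), table, truth


def recovery_report(data: FusedBlocks, truth: dict, rl_model=None,
                    sca_model=None, cv_result=None) -> dict:
    """Relative/absolute recovery errors of the fitted stages vs ground truth.

    Error-model errors are relative where the true value is nonzero, absolute
    otherwise. The loading-subspace error is the largest principal angle (rad)
    between the true concatenated loading subspace and the fitted one.
    """
    report: dict = {}
    if rl_model is not None:
        errs_add, errs_mult = {}, {}
        for g, fit in rl_model.fits.items():
            ta, tm = truth["sigma_add"].get(g, 0.0), truth["sigma_mult"].get(g, 0.0)
            errs_add[g] = abs(fit.sigma_add - ta) / ta if ta else abs(fit.sigma_add)
            errs_mult[g] = abs(fit.sigma_mult - tm) / tm if tm else abs(fit.sigma_mult)
        report["sigma_add_error"] = errs_add
        report["sigma_mult_error"] = errs_mult
        report["sigma_add_error_median"] = float(np.median(list(errs_add.values())))
        report["sigma_mult_error_median"] = float(np.median(list(errs_mult.values())))
    if sca_model is not None:
        true_p = np.vstack(truth["loadings"])
        r = min(true_p.shape[1], sca_model.loadings.shape[1])
        ang = subspace_angles(true_p[:, :r], sca_model.loadings[:, :r])
        report["max_principal_angle_rad"] = float(np.max(ang)) if ang.size else 0.0
    if cv_result is not None:
        report["cv_average_misclassifications"] = cv_result.averages
    return report


def write_dataset(blocks: FusedBlocks, table: SampleTable, out_dir) -> list[Path]:
    """Write the dataset in the same CSV layout the readers expect."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = []
    for b in blocks.blocks:
        p = out / f"{b.block_name}.csv"
        write_block(b, p)
        paths.append(p)
    p = out / "samples.csv"
    table.to_csv(p)
    paths.append(p)
    return paths
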