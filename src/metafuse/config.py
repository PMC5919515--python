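"""Pipeline configuration schema and model-archive (de)serialization."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import errormodel as _em
from . import scda as _scda
from . import transforms as _tf
from . import wpca as _wpca
from .datamodel import (AMINE_GROUP, FusedBlocks, SampleTable, ScalingParams,
                        infer_lipid_class, lod_filter, read_block)
from .validation import FoldModel, valid_configurations


@dataclass
class BlockConfig:
    path: str
    name: str = "block"
    group: str = "amine"  # 'amine', 'lipid' (infer class from name) or a CSV map path


@dataclass
class PipelineConfig:
    """Validated configuration for one end-to-end run.

    ``method``/``scaling`` must be one of the 14 supported combinations
    (transforms × center/auto, filter variants × center/auto, and the two
    weighted-fusion variants which are always autoscaled).
    """

    blocks: list[BlockConfig]
    sample_table: str
    method: str = "raw"
    scaling: str = "auto"
    components: list[int] = field(default_factory=lambda: [3, 5, 7])
    repeats: int = 25
    seed: int = 0
    output_dir: str = "results"
    classes: list[str] | None = None
    apply_lod_filter: bool = False
    lod_threshold: float = 0.8
    mals_components: int = 7
    weight_cap: float = 1e3
    lambda_mode: str = "block"

    def __post_init__(self) -> None:
        self.blocks = [b if isinstance(b, BlockConfig) else BlockConfig(**b) for b in self.blocks]
        if (self.method, self.scaling) not in valid_configurations():
            raise ValueError(
                f"({self.method!r}, {self.scaling!r}) is not a supported configuration; "
                f"choose one of {valid_configurations()}")
        if self.repeats < 1 or not self.components:
            raise ValueError("repeats must be ≥1 and components non-empty")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)

    def to_dict(self) -> dict:
        return asdict(self)

    def digest(self) -> str:
        """Stable hash of the configuration, stamped into every output file."""
        payload = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def _group_resolver(bc: BlockConfig):
    if bc.group == "amine":
        return lambda m: AMINE_GROUP
    if bc.group == "lipid":
        return infer_lipid_class
    import pandas as pd

    df = pd.read_csv(bc.group)
    return dict(zip(df.iloc[:, 0].astype(str), df.iloc[:, 1].astype(str)))


def load_data(config: PipelineConfig) -> tuple[FusedBlocks, SampleTable]:
    table = SampleTable.from_csv(config.sample_table)
    blocks = [read_block(bc.path, _group_resolver(bc), block_name=bc.name)
              for bc in config.blocks]
    if config.apply_lod_filter:
        classes = tuple(config.classes) if config.classes else None
        blocks = [lod_filter(b, table, config.lod_threshold, group_labels=classes)
                  for b in blocks]
    return FusedBlocks(blocks), table


# ---------------------------------------------------------------------------
# Model archive: a frozen FoldModel plus block metadata, as JSON


def _arr(a):
    return None if a is None else np.asarray(a).tolist()


def _ser_error_model(model) -> dict | None:
    if model is None:
        return None
    if isinstance(model, _em.RockeLorenzatoModel):
        return {"type": "rl",
                "fits": {g: {"sigma_add": f.sigma_add, "sigma_mult": f.sigma_mult,
                             "alpha": f.alpha, "objective": f.objective,
                             "n_points": f.n_points} for g, f in model.fits.items()},
                "group_of_metabolite": model.group_of_metabolite}
    if isinstance(model, _em.MedianErrorModel):
        return {"type": "median", "sigma2": _arr(model.sigma2),
                "metabolite_ids": model.metabolite_ids}
    raise TypeError(type(model).__name__)


def deserialize_error_model(d: dict | None):
    if d is None:
        return None
    if d["type"] == "rl":
        fits = {g: _em.RockeLorenzatoFit(**f) for g, f in d["fits"].items()}
        return _em.RockeLorenzatoModel(fits, dict(d["group_of_metabolite"]))
    return _em.MedianErrorModel(np.asarray(d["sigma2"]), list(d["metabolite_ids"]))


def save_model_archive(fm: FoldModel, blocks: FusedBlocks, path,
                       glog_params: _tf.GlogParams | list | None = None,
                       seed: int | None = None, config_digest: str | None = None) -> None:
    per_comp = {}
    for R, (sca, dm, b) in fm.per_component.items():
        entry = {"loadings": _arr(sca.loadings), "mode": sca.mode,
                 "beta": _arr(dm.beta), "beta0": dm.beta0,
                 "class_means": [_arr(dm.class_means[0]), _arr(dm.class_means[1])],
                 "b": _arr(b)}
        if sca.mode == "weighted":
            entry["wpca_centers"] = _arr(sca.wpca_model.centers)
        per_comp[str(R)] = entry
    mals = None
    if fm.mals_models is not None:
        mals = [{"centers": _arr(m.centers), "loadings": _arr(m.loadings)}
                for m in fm.mals_models]
    if isinstance(glog_params, _tf.GlogParams):
        glog_params = [glog_params] * len(blocks.blocks)
    doc = {
        "method": fm.method, "scaling": fm.scaling, "classes": list(fm.classes),
        "components": list(fm.components), "weight_cap": fm.weight_cap,
        "seed": seed, "config_digest": config_digest,
        "blocks": [{
            "name": blk.block_name,
            "metabolite_ids": blk.metabolite_ids,
            "metabolite_group": blk.metabolite_group,
            "scaling": {"center": _arr(p.center), "scale": _arr(p.scale),
                        "block_factor": p.block_factor},
            "glog": None if glog_params is None else
                    {"lam": glog_params[k].lam,
                     "per_metabolite": _arr(glog_params[k].per_metabolite)},
        } for k, (blk, p) in enumerate(zip(blocks.blocks, fm.scaling_params))],
        "mals_models": mals,
        "error_model": _ser_error_model(fm.error_model),
        "per_component": per_comp,
    }
    Path(path).write_text(json.dumps(doc))


def load_model_archive(path) -> tuple[FoldModel, dict]:
    """Rebuild a frozen FoldModel (usable with ``validation.predict_fold``)."""
    doc = json.loads(Path(path).read_text())
    sparams = []
    for bd in doc["blocks"]:
        s = bd["scaling"]
        sparams.append(ScalingParams(
            center=np.asarray(s["center"]),
            scale=None if s["scale"] is None else np.asarray(s["scale"]),
            block_factor=s["block_factor"], metabolite_ids=bd["metabolite_ids"]))
    mals = None
    if doc["mals_models"] is not None:
        mals = []
        for md in doc["mals_models"]:
            P = np.asarray(md["loadings"])
            mals.append(_wpca.WpcaModel(
                centers=np.asarray(md["centers"]), loadings=P,
                scores=np.zeros((0, P.shape[1])), n_components=P.shape[1],
                converged=True, objective=np.nan, n_iter=0))
    emodel = deserialize_error_model(doc["error_model"])
    block_sizes = [len(bd["metabolite_ids"]) for bd in doc["blocks"]]
    per_comp = {}
    for R, e in doc["per_component"].items():
        P = np.asarray(e["loadings"])
        wm = None
        if e["mode"] == "weighted":
            wm = _wpca.WpcaModel(centers=np.asarray(e["wpca_centers"]), loadings=P,
                                 scores=np.zeros((0, P.shape[1])),
                                 n_components=P.shape[1], converged=True,
                                 objective=np.nan, n_iter=0)
        sca = _scda.ScaModel(scores=np.zeros((0, P.shape[1])), loadings=P,
                             n_components=P.shape[1], block_sizes=block_sizes,
                             mode=e["mode"], wpca_model=wm)
        dm = _scda.DiscriminantModel(
            beta=np.asarray(e["beta"]), beta0=float(e["beta0"]),
            class_means=(np.asarray(e["class_means"][0]), np.asarray(e["class_means"][1])),
            classes=tuple(doc["classes"]))
        per_comp[int(R)] = (sca, dm, np.asarray(e["b"]))
    fm = FoldModel(method=doc["method"], scaling=doc["scaling"],
                   classes=tuple(doc["classes"]), components=tuple(doc["components"]),
                   scaling_params=sparams, per_component=per_comp,
                   mals_models=mals, error_model=emodel,
                   weight_cap=doc.get("weight_cap", 1e3))
    return fm, doc
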