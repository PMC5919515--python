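"""Domain containers and pre-processing bookkeeping for multi-platform intensity data.

A *block* is one platform's samples × metabolites matrix of internal-standard
ratios (unitless, non-negative). Blocks measured on the same samples are fused
by column concatenation; all centering/scaling parameters are estimated on
training rows only and replayed verbatim on new rows.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

AMINE_GROUP = "amine"
LIPID_CLASSES = ("TG", "DG", "Cer", "SM", "PC", "PE", "LPE", "LPC", "CE")
KNOWN_GROUPS = (AMINE_GROUP,) + LIPID_CLASSES


@dataclass
class MetaboliteBlock:
    """One platform's I × J intensity matrix plus sample/metabolite metadata.

    ``values`` holds floats with NaN marking missing (e.g. below-detection)
    entries. ``metabolite_group`` assigns each column to one of the error-model
    groups (the amine group or one of the nine lipid classes by default).
    """

    values: np.ndarray
    sample_ids: list[str]
    metabolite_ids: list[str]
    metabolite_group: list[str]
    block_name: str = "block"
    allowed_groups: tuple[str, ...] = KNOWN_GROUPS

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.metabolite_ids = [str(m) for m in self.metabolite_ids]
        self.metabolite_group = [str(g) for g in self.metabolite_group]
        if self.values.ndim != 2:
            raise ValueError(f"block '{self.block_name}': values must be 2-D")
        i, j = self.values.shape
        if len(self.sample_ids) != i:
            raise ValueError(f"block '{self.block_name}': {len(self.sample_ids)} sample ids for {i} rows")
        if len(self.metabolite_ids) != j:
            raise ValueError(f"block '{self.block_name}': {len(self.metabolite_ids)} metabolite ids for {j} columns")
        if len(self.metabolite_group) != j:
            raise ValueError(f"block '{self.block_name}': group labels must match column count")
        seen: set[str] = set()
        for m in self.metabolite_ids:
            if m in seen:
                raise ValueError(f"block '{self.block_name}': duplicated metabolite id {m!r}")
            seen.add(m)
        if self.allowed_groups is not None:
            bad = sorted(set(self.metabolite_group) - set(self.allowed_groups))
            if bad:
                raise ValueError(
                    f"block '{self.block_name}': unknown metabolite group(s) {bad}; "
                    f"allowed: {list(self.allowed_groups)}"
                )

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_metabolites(self) -> int:
        return self.values.shape[1]

    def subset_metabolites(self, keep: np.ndarray) -> "MetaboliteBlock":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        return MetaboliteBlock(
            values=self.values[:, keep],
            sample_ids=list(self.sample_ids),
            metabolite_ids=[self.metabolite_ids[j] for j in keep],
            metabolite_group=[self.metabolite_group[j] for j in keep],
            block_name=self.block_name,
            allowed_groups=self.allowed_groups,
        )

    def subset_samples(self, rows: np.ndarray) -> "MetaboliteBlock":
        rows = np.asarray(rows)
        if rows.dtype == bool:
            rows = np.flatnonzero(rows)
        return MetaboliteBlock(
            values=self.values[rows],
            sample_ids=[self.sample_ids[i] for i in rows],
            metabolite_ids=list(self.metabolite_ids),
            metabolite_group=list(self.metabolite_group),
            block_name=self.block_name,
            allowed_groups=self.allowed_groups,
        )


@dataclass
class SampleTable:
    """Sample metadata: class label and replicate-pair linkage.

    ``replicate_group`` links the two duplicate work-ups of one sample; it is
    the empty string for unreplicated samples. Classification uses only the
    samples whose ``class_label`` is one of the two analysis classes.
    """

    sample_ids: list[str]
    class_label: list[str]
    replicate_group: list[str]

    def __post_init__(self) -> None:
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.class_label = [str(c) for c in self.class_label]
        self.replicate_group = [str(r) if r not in (None, "nan") else "" for r in self.replicate_group]
        n = len(self.sample_ids)
        if len(self.class_label) != n or len(self.replicate_group) != n:
            raise ValueError("sample table columns must have equal length")

    def class_indices(self, label: str) -> np.ndarray:
        return np.array([i for i, c in enumerate(self.class_label) if c == label], dtype=int)

    def replicate_pairs(self) -> list[tuple[int, int, str]]:
        """Row-index pairs (i1, i2, group_id); every group must have exactly 2 rows."""
        groups: dict[str, list[int]] = {}
        for i, g in enumerate(self.replicate_group):
            if g:
                groups.setdefault(g, []).append(i)
        pairs = []
        for g in sorted(groups):
            rows = groups[g]
            if len(rows) != 2:
                raise ValueError(f"replicate group {g!r} has {len(rows)} rows; duplicates must come in pairs")
            pairs.append((rows[0], rows[1], g))
        return pairs

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"sample_id": self.sample_ids, "class": self.class_label, "replicate_group": self.replicate_group}
        )

    @classmethod
    def from_csv(cls, path) -> "SampleTable":
        df = pd.read_csv(path, dtype=str).fillna("")
        cols = {c.lower(): c for c in df.columns}
        try:
            sid = df[cols.get("sample_id", df.columns[0])]
            cl = df[cols.get("class", df.columns[1])]
        except IndexError as exc:  # pragma: no cover - malformed input
            raise ValueError(f"sample table {path}: need sample_id and class columns") from exc
        rep = df[cols["replicate_group"]] if "replicate_group" in cols else [""] * len(df)
        return cls(list(sid), list(cl), list(rep))

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


@dataclass
class FusedBlocks:
    """Ordered blocks sharing the sample mode; concatenated column-wise for SCA."""

    blocks: list[MetaboliteBlock]

    def __post_init__(self) -> None:
        if not self.blocks:
            raise ValueError("need at least one block")
        ref = self.blocks[0].sample_ids
        for b in self.blocks[1:]:
            if b.sample_ids != ref:
                raise ValueError(
                    f"block '{b.block_name}' does not share sample ids with '{self.blocks[0].block_name}'"
                )

    @property
    def sample_ids(self) -> list[str]:
        return self.blocks[0].sample_ids

    @property
    def n_samples(self) -> int:
        return self.blocks[0].n_samples

    @property
    def n_columns(self) -> int:
        return sum(b.n_metabolites for b in self.blocks)

    @property
    def values(self) -> np.ndarray:
        return np.hstack([b.values for b in self.blocks])

    @property
    def metabolite_ids(self) -> list[str]:
        return [m for b in self.blocks for m in b.metabolite_ids]

    @property
    def metabolite_group(self) -> list[str]:
        return [g for b in self.blocks for g in b.metabolite_group]

    @property
    def block_names(self) -> list[str]:
        return [b.block_name for b in self.blocks]

    def column_map(self) -> list[tuple[int, int]]:
        """Bijection: concatenated column index -> (block index, within-block column)."""
        out = []
        for k, b in enumerate(self.blocks):
            out.extend((k, j) for j in range(b.n_metabolites))
        return out

    def split_columns(self, v: np.ndarray) -> list[np.ndarray]:
        """Split a length-ΣJ_k vector (or matrix with that many columns) back per block."""
        sizes = [b.n_metabolites for b in self.blocks]
        edges = np.cumsum(sizes)[:-1]
        return np.split(np.asarray(v), edges, axis=-1)

    def subset_samples(self, rows) -> "FusedBlocks":
        return FusedBlocks([b.subset_samples(rows) for b in self.blocks])


# ---------------------------------------------------------------------------
# CSV I/O


def read_block(csv_path, metabolite_group_map, block_name: str | None = None,
               allowed_groups: tuple[str, ...] = KNOWN_GROUPS) -> MetaboliteBlock:
    """Read a block CSV: header row of metabolite ids, first column sample ids.

    ``metabolite_group_map`` is a dict ``metabolite_id -> group`` or a callable
    of the metabolite id. Non-numeric cells become NaN (missing).
    """
    df = pd.read_csv(csv_path, index_col=0)
    if df.shape[1] == 0:
        raise ValueError(f"{csv_path}: no metabolite columns found")
    values = df.apply(pd.to_numeric, errors="coerce").to_numpy(dtype=float)
    mets = [str(c) for c in df.columns]
    if callable(metabolite_group_map):
        groups = [metabolite_group_map(m) for m in mets]
    else:
        missing = [m for m in mets if m not in metabolite_group_map]
        if missing:
            raise KeyError(f"{csv_path}: metabolite(s) without group annotation: {missing[:5]}")
        groups = [metabolite_group_map[m] for m in mets]
    name = block_name if block_name is not None else str(csv_path)
    return MetaboliteBlock(values, list(df.index), mets, groups, block_name=name,
                           allowed_groups=allowed_groups)


def write_block(block: MetaboliteBlock, csv_path) -> None:
    pd.DataFrame(block.values, index=block.sample_ids, columns=block.metabolite_ids).to_csv(csv_path)


def infer_lipid_class(metabolite_id: str) -> str:
    """Map a lipid name like 'TG.52.2' or 'SM.d18.1.16.0' to its class label."""
    for cls in sorted(LIPID_CLASSES, key=len, reverse=True):
        if metabolite_id.startswith(cls + ".") or metabolite_id == cls:
            return cls
    raise KeyError(f"cannot infer lipid class of {metabolite_id!r}")


# ---------------------------------------------------------------------------
# Detection-limit filter


def lod_filter(block: MetaboliteBlock, sample_table: SampleTable,
               threshold_fraction: float = 0.8,
               group_labels: tuple[str, str] | None = None,
               lod_mask: np.ndarray | None = None) -> MetaboliteBlock:
    """Keep metabolites with ≥ ``threshold_fraction`` above-detection values in
    at least one of the two designated sample groups.

    ``lod_mask`` (same shape as the block, True = above detection) overrides the
    default rule that missing or non-positive entries are below detection.
    """
    if not 0.0 < threshold_fraction <= 1.0:
        raise ValueError("threshold_fraction must be in (0, 1]")
    if group_labels is None:
        labels = [c for c in sample_table.class_label if c not in ("", "other")]
        uniq = sorted(set(labels), key=labels.index)
        if len(uniq) < 2:
            raise ValueError("cannot infer the two comparison groups from the sample table")
        group_labels = (uniq[0], uniq[1])
    id_to_row = {s: i for i, s in enumerate(sample_table.sample_ids)}
    try:
        rows_by_group = []
        for lab in group_labels:
            idx = sample_table.class_indices(lab)
            if idx.size == 0:
                raise KeyError(lab)
            sids = [sample_table.sample_ids[i] for i in idx]
            rows_by_group.append(np.array([block.sample_ids.index(s) for s in sids if s in set(block.sample_ids)]))
    except KeyError as exc:
        raise ValueError(f"group {exc} absent from the sample table") from exc
    del id_to_row
    if lod_mask is None:
        above = np.isfinite(block.values) & (block.values > 0)
    else:
        above = np.asarray(lod_mask, dtype=bool)
        if above.shape != block.values.shape:
            raise ValueError("lod_mask shape must match block values")
    keep = np.zeros(block.n_metabolites, dtype=bool)
    for rows in rows_by_group:
        if rows.size == 0:
            raise ValueError("a comparison group has no rows in this block")
        frac = above[rows].mean(axis=0)
        keep |= frac >= threshold_fraction
    return block.subset_metabolites(keep)


# ---------------------------------------------------------------------------
# Centering / scaling


@dataclass
class ScalingParams:
    """Frozen per-metabolite center/scale and per-block Frobenius factor.

    Applying the params to new rows replays exactly the training transform:
    ``(x − center) / scale / block_factor`` (scale omitted when centering only).
    """

    center: np.ndarray
    scale: np.ndarray | None = None
    block_factor: float = 1.0
    metabolite_ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.center = np.asarray(self.center, dtype=float)
        if self.scale is not None:
            self.scale = np.asarray(self.scale, dtype=float)
            if np.any(self.scale <= 0):
                raise ValueError("scales must be strictly positive")
        if not self.block_factor > 0:
            raise ValueError("block factor must be strictly positive")


def center(values: np.ndarray) -> tuple[np.ndarray, ScalingParams]:
    values = np.asarray(values, dtype=float)
    c = values.mean(axis=0)
    return values - c, ScalingParams(center=c)


def autoscale(values: np.ndarray, ddof: int = 1) -> tuple[np.ndarray, ScalingParams]:
    values = np.asarray(values, dtype=float)
    c = values.mean(axis=0)
    s = values.std(axis=0, ddof=ddof)
    bad = np.flatnonzero(s == 0)
    if bad.size:
        raise ValueError(f"autoscale: zero-variance column(s) at index {bad.tolist()}")
    return (values - c) / s, ScalingParams(center=c, scale=s)


def blockscale(values_list: list[np.ndarray]) -> tuple[list[np.ndarray], list[float]]:
    """Divide each (already centered/scaled) block by its Frobenius norm."""
    out, factors = [], []
    for v in values_list:
        f = float(np.linalg.norm(v))
        if f == 0:
            raise ValueError("blockscale: zero matrix")
        out.append(v / f)
        factors.append(f)
    return out, factors


def fit_scaling(values: np.ndarray, mode: str) -> tuple[np.ndarray, ScalingParams]:
    """Center or autoscale a block, then scale it to unit Frobenius norm."""
    if mode == "center":
        z, params = center(values)
    elif mode in ("auto", "autoscale"):
        z, params = autoscale(values)
    else:
        raise ValueError(f"unknown scaling mode {mode!r}; use 'center' or 'auto'")
    f = float(np.linalg.norm(z))
    if f == 0:
        raise ValueError("block is identically zero after centering")
    params.block_factor = f
    return z / f, params


def apply_scaling(new_values: np.ndarray, params: ScalingParams) -> np.ndarray:
    """Replay frozen training centering/scaling/block factor on new rows."""
    x = np.asarray(new_values, dtype=float)
    if x.shape[-1] != params.center.shape[0]:
        raise ValueError(
            f"apply_scaling: {x.shape[-1]} columns vs {params.center.shape[0]} stored parameters"
        )
    z = x - params.center
    if params.scale is not None:
        z = z / params.scale
    return z / params.block_factor
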