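"""Turn paired IP/input FPKM tables into the matrices the block search consumes.

MeRIP-seq profiles the m6A epi-transcriptome with two libraries per
condition: an antibody-enriched IP sample and an input (background
expression) sample.  From the two FPKM matrices this module derives

* a methylation-level matrix ``P`` — per site *i* and condition *j*,
  ``p_ij = (t_ij + a) / (t_ij + h_ij + 2a)`` with ``t`` the IP FPKM, ``h``
  the input FPKM and ``a`` a pseudo-count that keeps zero-coverage cells
  finite (they resolve to exactly 0.5);
* an expression-weight matrix ``W`` — ``w_ij = log(t_ij + h_ij + 1)`` —
  which acts as a confidence level for ``p_ij``: methylation ratios backed
  by deep coverage are trusted more than ratios computed on a handful of
  fragments.

``P`` is then passed through a whole/row/column centering-scaling cascade
(subtract the mean, divide by the range, in that order of axes) and a final
global min-max step, producing ``P^t`` in [0, 1]; ``W`` is min-max
normalised to ``W^t``.  The cascade removes global, per-site and
per-condition level effects so that the downstream search responds to
*local* hyper-methylation rather than to globally hot sites or conditions.

Homology side-information — which sites share a gene, which conditions
share a cell line — is loaded here as well, as self-inclusive equivalence
classes.
"""

from __future__ import annotations

import json

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "FpkmPair",
    "PreprocessConfig",
    "HomologyMap",
    "MethylationDataset",
    "read_fpkm_pair",
    "read_homology_maps",
    "compute_methylation_level",
    "compute_expression_weight",
    "normalize_methylation",
    "normalize_expression",
    "preprocess_pair",
    "write_dataset",
    "read_dataset",
]

_LOG_FNS = {"natural": np.log, "base2": np.log2, "base10": np.log10}

Degenerate = Literal["error", "zero"]


@dataclass(frozen=True)
class PreprocessConfig:
    """Tunables of the FPKM -> (P^t, W^t) conversion.

    alpha
        Pseudo-count added to IP and input FPKM so that zero/zero cells
        resolve to 0.5 instead of NaN.  Must be positive.
    log_base
        Base of the logarithm in the expression weight; "natural",
        "base2" or "base10".  The final min-max step removes global scale,
        so the base only reshapes the weight curve; it is recorded in run
        metadata.
    degenerate
        What to do when a centering-scaling step meets a zero range:
        "error" (default) raises naming the axis and index, "zero" maps
        the offending slice to all zeros.
    """

    alpha: float = 1e-6
    log_base: Literal["natural", "base2", "base10"] = "natural"
    degenerate: Degenerate = "error"

    def __post_init__(self) -> None:
        if not (self.alpha > 0):
            raise ValueError(f"alpha must be > 0, got {self.alpha}")
        if self.log_base not in _LOG_FNS:
            raise ValueError(f"unknown log_base {self.log_base!r}")
        if self.degenerate not in ("error", "zero"):
            raise ValueError(f"unknown degenerate policy {self.degenerate!r}")

    def to_dict(self) -> dict:
        return {"alpha": self.alpha, "log_base": self.log_base,
                "degenerate": self.degenerate}


@dataclass(frozen=True)
class FpkmPair:
    """Aligned IP/input FPKM matrices (sites x conditions)."""

    ip: np.ndarray
    input: np.ndarray
    site_ids: tuple[str, ...]
    condition_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        ip = np.asarray(self.ip, dtype=float)
        inp = np.asarray(self.input, dtype=float)
        object.__setattr__(self, "ip", ip)
        object.__setattr__(self, "input", inp)
        object.__setattr__(self, "site_ids", tuple(self.site_ids))
        object.__setattr__(self, "condition_ids", tuple(self.condition_ids))
        if ip.shape != inp.shape:
            raise ValueError(f"IP shape {ip.shape} != input shape {inp.shape}")
        if ip.shape != (len(self.site_ids), len(self.condition_ids)):
            raise ValueError("matrix shape does not match identifier counts")
        if len(set(self.site_ids)) != len(self.site_ids):
            raise ValueError("duplicate site IDs")
        if len(set(self.condition_ids)) != len(self.condition_ids):
            raise ValueError("duplicate condition IDs")
        for name, mat in (("ip", ip), ("input", inp)):
            if not np.all(np.isfinite(mat)):
                raise ValueError(f"{name} matrix contains non-finite values")
            if np.any(mat < 0):
                i, j = np.argwhere(mat < 0)[0]
                raise ValueError(
                    f"{name} matrix has a negative FPKM at site "
                    f"{self.site_ids[i]!r}, condition {self.condition_ids[j]!r}"
                )

    @property
    def shape(self) -> tuple[int, int]:
        return self.ip.shape


@dataclass(frozen=True)
class HomologyMap:
    """Self-inclusive equivalence classes of sites (by gene) and conditions
    (by cell line)."""

    site_groups: Mapping[str, frozenset[str]]
    condition_groups: Mapping[str, frozenset[str]]

    def __post_init__(self) -> None:
        for label, groups in (("site", self.site_groups),
                              ("condition", self.condition_groups)):
            for key, grp in groups.items():
                if key not in grp:
                    raise ValueError(
                        f"{label} group for {key!r} is not self-inclusive")
                for member in grp:
                    if groups.get(member) != grp:
                        raise ValueError(
                            f"{label} groups are not equivalence classes "
                            f"({key!r} vs {member!r})")

    @staticmethod
    def from_labels(site_labels: Mapping[str, str],
                    condition_labels: Mapping[str, str]) -> "HomologyMap":
        """Build equivalence classes from ID -> group-label maps."""
        return HomologyMap(_classes(site_labels), _classes(condition_labels))

    @staticmethod
    def singleton(site_ids: Iterable[str],
                  condition_ids: Iterable[str]) -> "HomologyMap":
        """Every ID in its own group (no homology information)."""
        return HomologyMap({s: frozenset([s]) for s in site_ids},
                           {c: frozenset([c]) for c in condition_ids})

    def to_dict(self) -> dict:
        return {
            "site_groups": {k: sorted(v) for k, v in self.site_groups.items()},
            "condition_groups": {k: sorted(v)
                                 for k, v in self.condition_groups.items()},
        }


def _classes(labels: Mapping[str, str]) -> dict[str, frozenset[str]]:
    by_label: dict[str, set[str]] = {}
    for ident, lab in labels.items():
        by_label.setdefault(lab, set()).add(ident)
    out: dict[str, frozenset[str]] = {}
    for members in by_label.values():
        grp = frozenset(members)
        for ident in members:
            out[ident] = grp
    return out


@dataclass(frozen=True)
class MethylationDataset:
    """Normalised methylation (P^t) and expression-weight (W^t) matrices,
    both in [0, 1], plus identifiers and homology classes."""

    p_t: np.ndarray
    w_t: np.ndarray
    site_ids: tuple[str, ...]
    condition_ids: tuple[str, ...]
    homology: HomologyMap

    def __post_init__(self) -> None:
        p = np.asarray(self.p_t, dtype=float)
        w = np.asarray(self.w_t, dtype=float)
        object.__setattr__(self, "p_t", p)
        object.__setattr__(self, "w_t", w)
        object.__setattr__(self, "site_ids", tuple(self.site_ids))
        object.__setattr__(self, "condition_ids", tuple(self.condition_ids))
        if p.shape != w.shape:
            raise ValueError("p_t and w_t shapes differ")
        if p.shape != (len(self.site_ids), len(self.condition_ids)):
            raise ValueError("matrix shape does not match identifier counts")
        for name, mat in (("p_t", p), ("w_t", w)):
            if np.any(~np.isfinite(mat)):
                raise ValueError(f"{name} contains NaN/inf")
            if mat.min() < -1e-12 or mat.max() > 1 + 1e-12:
                raise ValueError(f"{name} has entries outside [0, 1]")
        missing_s = set(self.site_ids) - set(self.homology.site_groups)
        missing_c = set(self.condition_ids) - set(self.homology.condition_groups)
        if missing_s or missing_c:
            raise ValueError(
                f"homology map missing sites {sorted(missing_s)[:5]} / "
                f"conditions {sorted(missing_c)[:5]}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.p_t.shape


# ---------------------------------------------------------------------------
# readers

def _read_matrix(path: str | Path, sep: str = "\t") -> pd.DataFrame:
    df = pd.read_csv(path, sep=sep, index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    bad = df.columns[~df.dtypes.map(lambda d: np.issubdtype(d, np.number))]
    if len(bad):
        for col in bad:
            for ridx, val in df[col].items():
                try:
                    float(val)
                except (TypeError, ValueError):
                    raise ValueError(
                        f"{path}: non-numeric cell at row {ridx!r}, "
                        f"column {col!r}: {val!r}") from None
        df = df.astype(float)
    return df


def read_fpkm_pair(ip_path: str | Path, input_path: str | Path,
                   sep: str = "\t") -> FpkmPair:
    """Read aligned IP/input FPKM tables (header row of condition IDs,
    first column of site IDs); the input table is reordered to the IP
    table's row/column order.
    """
    ip = _read_matrix(ip_path, sep)
    inp = _read_matrix(input_path, sep)
    for axis, a, b in (("site", ip.index, inp.index),
                       ("condition", ip.columns, inp.columns)):
        only_ip = sorted(set(a) - set(b))
        only_in = sorted(set(b) - set(a))
        if only_ip or only_in:
            raise ValueError(
                f"{axis} IDs differ between IP and input tables: "
                f"missing from input {only_ip[:10]}, "
                f"missing from IP {only_in[:10]}")
    inp = inp.loc[ip.index, ip.columns]
    return FpkmPair(ip.to_numpy(float), inp.to_numpy(float),
                    tuple(ip.index), tuple(ip.columns))


def _read_two_col(path: str | Path, sep: str = "\t") -> dict[str, str]:
    df = pd.read_csv(path, sep=sep, dtype=str)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected two columns (ID, group label)")
    labels: dict[str, str] = {}
    for ident, lab in zip(df.iloc[:, 0], df.iloc[:, 1]):
        if ident in labels and labels[ident] != lab:
            raise ValueError(
                f"{path}: ID {ident!r} mapped to both "
                f"{labels[ident]!r} and {lab!r}")
        labels[ident] = lab
    return labels


def read_homology_maps(site_gene_path: str | Path,
                       condition_cellline_path: str | Path,
                       site_ids: Iterable[str],
                       condition_ids: Iterable[str],
                       sep: str = "\t") -> HomologyMap:
    """Load site->gene and condition->cell-line maps and build the
    homology equivalence classes for the given dataset IDs."""
    site_labels = _read_two_col(site_gene_path, sep)
    cond_labels = _read_two_col(condition_cellline_path, sep)
    missing = sorted(set(site_ids) - set(site_labels))
    if missing:
        raise ValueError(f"site->gene map is missing IDs {missing[:10]}")
    missing = sorted(set(condition_ids) - set(cond_labels))
    if missing:
        raise ValueError(
            f"condition->cell-line map is missing IDs {missing[:10]}")
    return HomologyMap.from_labels(
        {s: site_labels[s] for s in site_ids},
        {c: cond_labels[c] for c in condition_ids})


# ---------------------------------------------------------------------------
# the arithmetic

def compute_methylation_level(pair: FpkmPair,
                              cfg: PreprocessConfig | None = None) -> np.ndarray:
    """Methylation level p = (t + a) / (t + h + 2a); entries in (0, 1)."""
    cfg = cfg or PreprocessConfig()
    a = cfg.alpha
    return (pair.ip + a) / (pair.ip + pair.input + 2 * a)


def compute_expression_weight(pair: FpkmPair,
                              cfg: PreprocessConfig | None = None) -> np.ndarray:
    """Expression weight w = log(t + h + 1) in the configured base."""
    cfg = cfg or PreprocessConfig()
    return _LOG_FNS[cfg.log_base](pair.ip + pair.input + 1.0)


def _center_scale(x: np.ndarray, axis: int | None,
                  degenerate: Degenerate, stage: str) -> np.ndarray:
    """(x - mean) / (max - min) along `axis` (None = whole matrix)."""
    mean = x.mean(axis=axis, keepdims=axis is not None)
    rng = (x.max(axis=axis, keepdims=axis is not None)
           - x.min(axis=axis, keepdims=axis is not None))
    flat = np.atleast_1d(np.squeeze(rng)) == 0 if axis is not None else rng == 0
    if axis is None:
        if rng == 0:
            raise ValueError(f"{stage}: matrix is constant (zero range)")
        return (x - mean) / rng
    if np.any(flat):
        if degenerate == "error":
            which = "row" if axis == 1 else "column"
            idx = int(np.flatnonzero(flat)[0])
            raise ValueError(
                f"{stage}: zero-range {which} at index {idx}; "
                "set degenerate='zero' to map it to zeros")
        safe = np.where(rng == 0, 1.0, rng)
        out = (x - mean) / safe
        mask = np.broadcast_to(rng == 0, x.shape)
        return np.where(mask, 0.0, out)
    return (x - mean) / rng


def _minmax(x: np.ndarray, stage: str) -> np.ndarray:
    lo, hi = x.min(), x.max()
    if hi == lo:
        raise ValueError(f"{stage}: matrix is constant (zero range)")
    return (x - lo) / (hi - lo)


def normalize_methylation(P: np.ndarray,
                          degenerate: Degenerate = "error") -> np.ndarray:
    """Whole -> row -> column centering-scaling, then global min-max.

    Each centering-scaling step subtracts the mean and divides by the
    range (max - min) of the indicated axis; the final min-max pins the
    output to span [0, 1] exactly.  A zero range at any stage raises by
    default; with ``degenerate="zero"`` the flat row/column is mapped to
    zeros (a flat overall matrix always raises).
    """
    P = np.asarray(P, dtype=float)
    nw = _center_scale(P, None, degenerate, "whole normalization")
    nr = _center_scale(nw, 1, degenerate, "row normalization")
    nc = _center_scale(nr, 0, degenerate, "column normalization")
    return _minmax(nc, "final min-max")


def normalize_expression(W: np.ndarray) -> np.ndarray:
    """Global min-max of the expression weights to [0, 1]."""
    return _minmax(np.asarray(W, dtype=float), "expression min-max")


def preprocess_pair(pair: FpkmPair, homology: HomologyMap | None = None,
                    cfg: PreprocessConfig | None = None) -> MethylationDataset:
    """Full chain: FPKM pair -> MethylationDataset (P^t, W^t in [0, 1]).

    With no homology map, singleton groups are used (every site/condition
    its own group), which disables the homology weighting downstream.
    """
    cfg = cfg or PreprocessConfig()
    if homology is None:
        homology = HomologyMap.singleton(pair.site_ids, pair.condition_ids)
    p_t = normalize_methylation(compute_methylation_level(pair, cfg),
                                degenerate=cfg.degenerate)
    w_t = normalize_expression(compute_expression_weight(pair, cfg))
    return MethylationDataset(p_t, w_t, pair.site_ids, pair.condition_ids,
                              homology)


# ---------------------------------------------------------------------------
# dataset persistence (TSV matrices + JSON sidecar)

def write_dataset(ds: MethylationDataset, out_dir: str | Path,
                  cfg: PreprocessConfig | None = None) -> dict[str, Path]:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {"p_t": out / "p_t.tsv", "w_t": out / "w_t.tsv",
             "meta": out / "dataset.json"}
    for key, mat in (("p_t", ds.p_t), ("w_t", ds.w_t)):
        df = pd.DataFrame(mat, index=list(ds.site_ids),
                          columns=list(ds.condition_ids))
        df.to_csv(paths[key], sep="\t", index_label="id")
    meta = {"config": (cfg or PreprocessConfig()).to_dict(),
            "homology": ds.homology.to_dict()}
    paths["meta"].write_text(json.dumps(meta, indent=1, sort_keys=True))
    return paths


def read_dataset(in_dir: str | Path) -> MethylationDataset:
    d = Path(in_dir)
    p = _read_matrix(d / "p_t.tsv")
    w = _read_matrix(d / "w_t.tsv")
    meta = json.loads((d / "dataset.json").read_text())
    hom = HomologyMap(
        {k: frozenset(v) for k, v in meta["homology"]["site_groups"].items()},
        {k: frozenset(v)
         for k, v in meta["homology"]["condition_groups"].items()})
    return MethylationDataset(p.to_numpy(float), w.to_numpy(float),
                              tuple(p.index), tuple(p.columns), hom)
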