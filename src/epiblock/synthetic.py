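"""MeRIP-seq-like simulator with planted hyper-methylated blocks.

The generator emulates the data model the search consumes: per-site,
per-condition IP/input FPKM pairs whose implied methylation ratio
``t / (t + h)`` equals a target level ``pi``.  Background cells sit at a
baseline level; cells inside planted blocks are raised to a block level.
Total coverage ``t + h`` is drawn log-normally, giving the realistic
heavy-tailed FPKM distribution and hence informative expression weights.

Noise enters on the methylation (proportion) scale through four
channels:

* ``block_pattern_sd`` — one shared per-condition modulation of each
  block's level, common to every site of the block: the co-methylation
  pattern itself.
* ``noise_sd`` — a Gaussian perturbation drawn **once per (gene,
  condition)** and shared by all sites of the gene.  This is the
  statistical structure the homology similarity term rewards: sites of
  one gene co-vary across conditions.
* ``site_noise_sd`` — an independent Gaussian per cell, representing
  site-level measurement noise that homology information can average
  away.
* ``dropout`` — per planted cell, the probability that the block signal
  is lost and the cell reverts to baseline (signal dropout of individual
  sites under individual conditions).

Sites are assigned to genes and conditions to cell lines round-robin;
planted blocks may overlap (a cell in several blocks takes the maximum
planted level).  Alongside the FPKM pair the simulator emits the ground
truth and a synthetic annotation in which each planted block's genes
form one term, plus random filler terms, so the enrichment-constraint
tuner has a signal to find.

What the generator does *not* emulate: read-level sampling noise,
transcript-length and GC biases, peak-calling uncertainty, or antibody
efficiency differences between experiments.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .engine import LFB, jaccard
from .enrichment import AnnotationSet, write_gmt
from .preprocess import FpkmPair, HomologyMap, MethylationDataset

__all__ = [
    "PlantedBlock",
    "SimulationSpec",
    "GroundTruth",
    "RecoveryReport",
    "simulate",
    "planted_dataset",
    "recovery_score",
    "write_fixture",
]


@dataclass(frozen=True)
class PlantedBlock:
    """Site/condition index sets (0-based) of one planted block."""

    sites: frozenset[int]
    conditions: frozenset[int]

    def __post_init__(self) -> None:
        if not self.sites or not self.conditions:
            raise ValueError("planted blocks must be non-empty")


@dataclass(frozen=True)
class SimulationSpec:
    """Study conditions of one simulated dataset.

    Defaults describe the canonical benchmark: a 500-site x 30-condition
    matrix with one planted hyper-methylated block covering all sites of
    the first 10 genes and all conditions of the first 2 cell lines
    (50 x 6), baseline methylation 0.3, planted level 0.85 modulated by
    a shared per-condition co-methylation pattern (sd 0.05), and
    gene-shared methylation noise sd 0.05.  Coverage is log-normal with
    median ~20 FPKM: a per-(gene, condition) expression draw (log-sd
    0.5) shared by the gene's sites — FPKM is a transcript-level
    quantity — plus per-site jitter (log-sd 0.2); ``depth_gene_sd``
    optionally adds a gene main effect retained across conditions.
    100 genes and 10 cell lines mirror a multi-dataset compendium in
    which each gene carries a handful of sites and each cell line a few
    conditions.
    """

    n_sites: int = 500
    n_conditions: int = 30
    n_genes: int = 100
    n_cell_lines: int = 10
    blocks: tuple[PlantedBlock, ...] = ()
    baseline_p: float = 0.3
    block_p: float = 0.85
    noise_sd: float = 0.05
    block_pattern_sd: float = 0.05
    site_noise_sd: float = 0.0
    dropout: float = 0.0
    depth_log_mean: float = 3.0
    depth_gene_sd: float = 0.0
    depth_log_sd: float = 0.5
    depth_site_sd: float = 0.2
    n_filler_terms: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.baseline_p < self.block_p < 1):
            raise ValueError("need 0 < baseline_p < block_p < 1")
        if self.noise_sd < 0 or self.site_noise_sd < 0:
            raise ValueError("noise sds must be >= 0")
        if not (0 <= self.dropout < 1):
            raise ValueError("dropout must be in [0, 1)")
        if not (1 <= self.n_genes <= self.n_sites
                and 1 <= self.n_cell_lines <= self.n_conditions):
            raise ValueError("group counts must be in [1, axis size]")
        if self.blocks:
            blocks = tuple(self.blocks)
        else:
            # one default block aligned with the homology structure:
            # all sites of the first genes (~50 sites), all conditions of
            # the first cell lines (~6 conditions)
            n_b_genes = max(1, round(min(50, self.n_sites)
                                     * self.n_genes / self.n_sites))
            n_b_cells = max(1, round(min(6, self.n_conditions)
                                     * self.n_cell_lines / self.n_conditions))
            sites = frozenset(i for i in range(self.n_sites)
                              if i % self.n_genes < n_b_genes)
            conds = frozenset(j for j in range(self.n_conditions)
                              if j % self.n_cell_lines < n_b_cells)
            blocks = (PlantedBlock(sites, conds),)
        object.__setattr__(self, "blocks", blocks)
        for b in blocks:
            if max(b.sites) >= self.n_sites or max(b.conditions) >= self.n_conditions:
                raise ValueError("planted block exceeds matrix bounds")


@dataclass(frozen=True)
class GroundTruth:
    """Planted blocks (as ID sets) and the homology label maps."""

    blocks: tuple[PlantedBlock, ...]
    site_ids: tuple[str, ...]
    condition_ids: tuple[str, ...]
    site_gene: Mapping[str, str]
    condition_cellline: Mapping[str, str]

    def block_ids(self, k: int) -> tuple[frozenset[str], frozenset[str]]:
        b = self.blocks[k]
        return (frozenset(self.site_ids[i] for i in b.sites),
                frozenset(self.condition_ids[j] for j in b.conditions))

    def homology(self) -> HomologyMap:
        return HomologyMap.from_labels(dict(self.site_gene),
                                       dict(self.condition_cellline))


@dataclass(frozen=True)
class RecoveryReport:
    """Planted-block recovery of a found block list.

    ``per_block[k]`` is the best match score of true block k over the
    found blocks, where a match score is the product of the site-set and
    condition-set Jaccard indices.  ``recovery`` averages over true
    blocks (how much truth was found); ``relevance`` averages the mirror
    direction over found blocks (how much of what was found is true).
    """

    per_block: tuple[float, ...]
    recovery: float
    relevance: float


def _ids(prefix: str, n: int) -> tuple[str, ...]:
    width = max(3, len(str(n)))
    return tuple(f"{prefix}{i:0{width}d}" for i in range(n))


def simulate(spec: SimulationSpec) -> tuple[FpkmPair, GroundTruth,
                                            AnnotationSet]:
    """Draw one dataset; fully determined by ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    m, n = spec.n_sites, spec.n_conditions
    site_ids = _ids("site_", m)
    cond_ids = _ids("cond_", n)
    genes = _ids("gene_", spec.n_genes)
    cells = _ids("cl_", spec.n_cell_lines)
    gene_of = np.arange(m) % spec.n_genes          # round-robin
    cell_of = np.arange(n) % spec.n_cell_lines

    # planted levels; overlaps take the maximum level, dropout reverts
    # individual planted cells to baseline
    pi = np.full((m, n), spec.baseline_p)
    level = np.full((m, n), -np.inf)
    for b in spec.blocks:
        # co-methylation: one shared per-condition modulation of the
        # block level, common to every site of the block
        wiggle = (rng.normal(0.0, spec.block_pattern_sd, size=n)
                  if spec.block_pattern_sd > 0 else np.zeros(n))
        cell_level = spec.block_p + wiggle
        blk = np.ix_(sorted(b.sites), sorted(b.conditions))
        level[blk] = np.maximum(level[blk],
                                cell_level[sorted(b.conditions)])
    planted = np.isfinite(level)
    keep = planted
    if spec.dropout > 0:
        keep = planted & (rng.random((m, n)) >= spec.dropout)
    pi[keep] = np.maximum(pi[keep], level[keep])

    if spec.noise_sd > 0:
        shared = rng.normal(0.0, spec.noise_sd, size=(spec.n_genes, n))
        pi = pi + shared[gene_of]
    if spec.site_noise_sd > 0:
        pi = pi + rng.normal(0.0, spec.site_noise_sd, size=(m, n))
    pi = np.clip(pi, 0.01, 0.99)

    # FPKM is a transcript-level quantity: a gene keeps its characteristic
    # expression across conditions (gene main effect), modulated per
    # condition, and sites of one gene share it up to per-site jitter
    log_expr = (spec.depth_log_mean
                + rng.normal(0.0, spec.depth_gene_sd, size=(spec.n_genes, 1))
                + rng.normal(0.0, spec.depth_log_sd, size=(spec.n_genes, n)))
    log_cov = log_expr[gene_of]
    if spec.depth_site_sd > 0:
        log_cov = log_cov + rng.normal(0.0, spec.depth_site_sd, size=(m, n))
    coverage = np.exp(log_cov)
    pair = FpkmPair(ip=pi * coverage, input=(1.0 - pi) * coverage,
                    site_ids=site_ids, condition_ids=cond_ids)
    truth = GroundTruth(
        blocks=spec.blocks, site_ids=site_ids, condition_ids=cond_ids,
        site_gene={site_ids[i]: genes[gene_of[i]] for i in range(m)},
        condition_cellline={cond_ids[j]: cells[cell_of[j]]
                            for j in range(n)})

    terms: dict[str, frozenset[str]] = {}
    for k, b in enumerate(spec.blocks):
        terms[f"block_term_{k}"] = frozenset(
            genes[gene_of[i]] for i in b.sites)
    for k in range(spec.n_filler_terms):
        size = int(rng.integers(5, max(6, min(30, spec.n_genes) + 1)))
        size = min(size, spec.n_genes)
        draw = rng.choice(spec.n_genes, size=size, replace=False)
        terms[f"filler_term_{k}"] = frozenset(genes[i] for i in draw)
    ann = AnnotationSet(terms=terms, universe=frozenset(genes))
    return pair, truth, ann


def planted_dataset(n_sites: int = 500, n_conditions: int = 30,
                    blocks: Sequence[PlantedBlock] | None = None,
                    background_p: float = 0.1, block_p: float = 0.9,
                    noise_sd: float = 0.0, pattern_sd: float = 0.0,
                    gene_shared_sd: float = 0.0, dropout: float = 0.0,
                    sites_per_gene: int = 1,
                    conditions_per_cell_line: int = 1,
                    w_range: tuple[float, float] = (0.4, 0.6),
                    seed: int = 0) -> tuple[MethylationDataset, GroundTruth]:
    """Planted-block benchmark built directly on the normalised scale.

    Unlike :func:`simulate`, which emits raw FPKM pairs for the full
    preprocessing chain, this constructs a :class:`MethylationDataset`
    whose methylation matrix is ``background_p`` outside the planted
    blocks and ``block_p`` inside, with expression weights drawn
    uniformly mid-range.  It is the canonical construction for
    benchmarking the block search in isolation.

    Noise channels: ``pattern_sd`` draws one shared per-condition
    modulation of each block's level (the co-methylation pattern);
    ``dropout`` reverts individual planted cells to background;
    ``gene_shared_sd`` adds a per-(gene, condition) Gaussian shared by
    all sites of a gene; ``noise_sd`` adds independent cell noise.
    ``sites_per_gene`` / ``conditions_per_cell_line`` of 1 give
    singleton homology groups; larger values group contiguous IDs.
    """
    rng = np.random.default_rng(seed)
    m, n = n_sites, n_conditions
    if blocks is None:
        blocks = (PlantedBlock(frozenset(range(min(50, m))),
                               frozenset(range(min(6, n)))),)
    blocks = tuple(blocks)
    P = np.full((m, n), float(background_p))
    level = np.full((m, n), -np.inf)
    for b in blocks:
        wiggle = (rng.normal(0.0, pattern_sd, size=n)
                  if pattern_sd > 0 else np.zeros(n))
        cols = sorted(b.conditions)
        blk = np.ix_(sorted(b.sites), cols)
        level[blk] = np.maximum(level[blk], block_p + wiggle[cols])
    planted = np.isfinite(level)
    keep = planted
    if dropout > 0:
        keep = planted & (rng.random((m, n)) >= dropout)
    P[keep] = np.maximum(P[keep], level[keep])
    gene_of = np.arange(m) // sites_per_gene
    if gene_shared_sd > 0:
        shared = rng.normal(0.0, gene_shared_sd,
                            size=(int(gene_of.max()) + 1, n))
        P = P + shared[gene_of]
    if noise_sd > 0:
        P = P + rng.normal(0.0, noise_sd, size=(m, n))
    P = np.clip(P, 0.0, 1.0)
    W = rng.uniform(*w_range, size=(m, n))

    site_ids = _ids("site_", m)
    cond_ids = _ids("cond_", n)
    cell_of = np.arange(n) // conditions_per_cell_line
    site_gene = {site_ids[i]: f"gene_{gene_of[i]:04d}" for i in range(m)}
    cond_cl = {cond_ids[j]: f"cl_{cell_of[j]:03d}" for j in range(n)}
    hom = HomologyMap.from_labels(site_gene, cond_cl)
    ds = MethylationDataset(P, W, site_ids, cond_ids, hom)
    truth = GroundTruth(blocks=blocks, site_ids=site_ids,
                        condition_ids=cond_ids, site_gene=site_gene,
                        condition_cellline=cond_cl)
    return ds, truth


def recovery_score(found: Sequence[LFB],
                   truth: GroundTruth) -> RecoveryReport:
    """Match found blocks against the planted truth (Jaccard products)."""
    true_sets = [truth.block_ids(k) for k in range(len(truth.blocks))]
    found_sets = [(set(f.sites), set(f.conditions)) for f in found]

    def match(a: tuple, b: tuple) -> float:
        return jaccard(a[0], b[0]) * jaccard(a[1], b[1])

    per_block = tuple(
        max((match(t, f) for f in found_sets), default=0.0)
        for t in true_sets)
    recovery = float(np.mean(per_block)) if per_block else 0.0
    relevance = (float(np.mean([
        max((match(t, f) for t in true_sets), default=0.0)
        for f in found_sets])) if found_sets else 0.0)
    return RecoveryReport(per_block=per_block, recovery=recovery,
                          relevance=relevance)


def write_fixture(spec: SimulationSpec, out_dir: str | Path) -> dict[str, Path]:
    """Materialise one simulated dataset in the on-disk dialects the
    readers consume: IP/input TSVs, homology map TSVs, a GMT annotation
    and a ground-truth JSON."""
    pair, truth, ann = simulate(spec)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {k: out / f"{k}.tsv" for k in
             ("ip", "input", "site_genes", "condition_celllines")}
    paths["annotation"] = out / "annotation.gmt"
    paths["truth"] = out / "truth.json"
    for key, mat in (("ip", pair.ip), ("input", pair.input)):
        pd.DataFrame(mat, index=list(pair.site_ids),
                     columns=list(pair.condition_ids)).to_csv(
            paths[key], sep="\t", index_label="id")
    pd.DataFrame({"id": list(truth.site_ids),
                  "gene": [truth.site_gene[s] for s in truth.site_ids]}
                 ).to_csv(paths["site_genes"], sep="\t", index=False)
    pd.DataFrame({"id": list(truth.condition_ids),
                  "cell_line": [truth.condition_cellline[c]
                                for c in truth.condition_ids]}
                 ).to_csv(paths["condition_celllines"], sep="\t", index=False)
    write_gmt(ann, paths["annotation"])
    paths["truth"].write_text(json.dumps({
        "blocks": [{"sites": sorted(b.sites),
                    "conditions": sorted(b.conditions)}
                   for b in truth.blocks],
        "site_ids": list(truth.site_ids),
        "condition_ids": list(truth.condition_ids),
    }, indent=1))
    return paths
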