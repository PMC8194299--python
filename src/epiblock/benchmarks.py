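"""Planted-block benchmark studies for the block search.

Each function defines one reproducible study on synthetic data — the
canonical 500-site x 30-condition geometry with one 50 x 6 planted
hyper-methylated block (background level 0.1, block level 0.9,
mid-range expression weights), or a variant of it — runs the search
with the package defaults, and reports recovery statistics.  A match
score between a found and a planted block is the product of the
site-set and condition-set Jaccard indices; a planted block's score is
its best match over all found blocks.

These studies benchmark the search engine on directly constructed
normalised datasets; the full FPKM pipeline (simulation, preprocessing,
enrichment-constrained threshold tuning) is exercised by
:func:`tuning_benchmark`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .engine import EngineConfig, ThresholdPair, run
from .enrichment import GridSearchResult, grid_search
from .preprocess import PreprocessConfig, preprocess_pair
from .synthetic import (PlantedBlock, SimulationSpec, planted_dataset,
                        recovery_score, simulate)

__all__ = [
    "RecoveryStudy",
    "single_block_recovery",
    "overlap_recovery",
    "homology_ablation",
    "null_control",
    "tuning_benchmark",
]

_GEOMETRY = dict(n_sites=500, n_conditions=30)
_BLOCK = PlantedBlock(frozenset(range(50)), frozenset(range(6)))


@dataclass(frozen=True)
class RecoveryStudy:
    """Per-seed outcomes of a planted-recovery study."""

    match_scores: tuple[float, ...]      # best match per seed (one block)
    exact: tuple[bool, ...]              # sets equal to truth, per seed

    @property
    def mean_match(self) -> float:
        return float(np.mean(self.match_scores))

    @property
    def n_exact(self) -> int:
        return int(sum(self.exact))


def _engine(seed: int, **overrides) -> EngineConfig:
    return EngineConfig(seed=seed, max_lfbs=10, **overrides)


def single_block_recovery(noise_sd: float, n_seeds: int = 10,
                          seed0: int = 0,
                          thresholds: ThresholdPair | None = None
                          ) -> RecoveryStudy:
    """Recover one planted 50 x 6 block at T_R = T_C = 1, with singleton
    homology groups and the given methylation noise level."""
    thresholds = thresholds or ThresholdPair(1.0, 1.0)
    scores, exact = [], []
    for k in range(n_seeds):
        ds, truth = planted_dataset(blocks=[_BLOCK], noise_sd=noise_sd,
                                    seed=seed0 + k, **_GEOMETRY)
        lfbs = run(ds, thresholds, _engine(seed0 + 100 + k))
        rep = recovery_score(lfbs, truth)
        scores.append(rep.per_block[0])
        ts, tc = truth.block_ids(0)
        exact.append(any(b.sites == ts and b.conditions == tc
                         for b in lfbs))
    return RecoveryStudy(tuple(scores), tuple(exact))


def overlap_recovery(n_seeds: int = 10, seed0: int = 0,
                     noise_sd: float = 0.05) -> list[tuple[float, float]]:
    """Two 40 x 6 blocks sharing 20% of their sites (8 of 40), disjoint
    condition sets; returns per-seed best match scores for each block."""
    blocks = [PlantedBlock(frozenset(range(40)), frozenset(range(6))),
              PlantedBlock(frozenset(range(32, 72)),
                           frozenset(range(6, 12)))]
    out = []
    for k in range(n_seeds):
        ds, truth = planted_dataset(blocks=blocks, noise_sd=noise_sd,
                                    seed=seed0 + k, **_GEOMETRY)
        lfbs = run(ds, ThresholdPair(1.0, 1.0), _engine(seed0 + 100 + k))
        rep = recovery_score(lfbs, truth)
        out.append((rep.per_block[0], rep.per_block[1]))
    return out


def homology_ablation(n_seeds: int = 20, seed0: int = 0,
                      dropout: float = 0.3, gene_shared_sd: float = 0.05,
                      noise_sd: float = 0.05,
                      pattern_sd: float = 0.05) -> dict:
    """Site recovery with and without homology weighting.

    The planted block covers whole genes (5 sites per gene); gene-mates
    share a per-condition methylation perturbation, while per-site
    dropout erases the planted signal from individual cells.  Reports
    the per-seed best site-set Jaccard under both settings and the
    paired difference (weighted minus unweighted).
    """
    on, off = [], []
    for k in range(n_seeds):
        ds, truth = planted_dataset(
            blocks=[_BLOCK], sites_per_gene=5, noise_sd=noise_sd,
            gene_shared_sd=gene_shared_sd, dropout=dropout,
            pattern_sd=pattern_sd, seed=seed0 + k, **_GEOMETRY)
        ts, _ = truth.block_ids(0)
        for weighted, acc in ((True, on), (False, off)):
            lfbs = run(ds, ThresholdPair(1.0, 1.0),
                       _engine(seed0 + 100 + k,
                               homology_weighting=weighted))
            best = max((len(b.sites & ts) / len(b.sites | ts)
                        for b in lfbs), default=0.0)
            acc.append(best)
    diffs = np.array(on) - np.array(off)
    return {"with_homology": on, "without_homology": off,
            "mean_with": float(np.mean(on)),
            "mean_without": float(np.mean(off)),
            "paired_difference": float(diffs.mean())}


def null_control(n_seeds: int = 10, seed0: int = 0,
                 thresholds: ThresholdPair | None = None) -> list[int]:
    """Block counts on pure-noise data (no planted structure) at the
    strict thresholds T_R = T_C = 3."""
    thresholds = thresholds or ThresholdPair(3.0, 3.0)
    counts = []
    for k in range(n_seeds):
        ds, _ = planted_dataset(blocks=[], background_p=0.3,
                                noise_sd=0.05, seed=seed0 + k,
                                **_GEOMETRY)
        counts.append(len(run(ds, thresholds, _engine(seed0 + 100 + k))))
    return counts


def tuning_benchmark(seed: int = 0, repeats: int = 3,
                     grid: Sequence[float] = (0.5, 1.0, 3.0)
                     ) -> GridSearchResult:
    """Full pipeline: simulate FPKM data with a planted block whose
    genes form one annotation term, preprocess, and tune (T_R, T_C) by
    the enrichment-constrained grid search."""
    spec = SimulationSpec(seed=seed)
    pair, truth, ann = simulate(spec)
    ds = preprocess_pair(pair, truth.homology(),
                         PreprocessConfig(degenerate="zero"))
    return grid_search(ds, ann, dict(truth.site_gene), list(grid),
                       list(grid), repeats=repeats,
                       cfg=EngineConfig(seed=seed))
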