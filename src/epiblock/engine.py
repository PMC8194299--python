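"""Sequential extraction of locally hyper-methylated blocks (LFBs).

The search is an iterative signature algorithm over the normalised
methylation matrix ``P^t`` with two extra ingredients:

* **expression weighting** — every methylation score is multiplied by the
  (residualised) expression weight ``W``, so low-coverage cells contribute
  little evidence;
* **homology weighting** — every candidate row/column score is further
  multiplied by ``t``, the absolute Pearson correlation between the
  candidate's weighted profile ``P^t ⊙ W^t`` and the mean profile of its
  homology group (sites sharing a gene, conditions sharing a cell line).
  Coherent members of a group are rewarded; rows/columns that disagree
  with their relatives are damped.

One block search alternates a condition step and a site step.  The
condition step scores every condition ``v`` as

    e_v = (1/|U'|) * sum_{u in U'} w_uv * pR_uv,        (residual evidence)
    t_v = |corr(profile_v, mean profile of v's cell-line group)|,

where ``pR`` is the per-row min-max of the residual methylation matrix and
``U'`` the current site subset, and keeps ``V' = {v : |e_v t_v - mean| >
T_C * sigma}`` (population sigma over all conditions).  The site step is
the mirror image with the per-column min-max ``pC`` and threshold ``T_R``.
Iteration stops when the Jaccard similarity between successive site
subsets reaches ``epsilon``.

After a block converges, its mean methylation and mean weight are
subtracted from the residual matrices on its cells (residual masking), and
the search restarts from a fresh random site subset.  Masking lets
overlapping blocks be discovered one after another instead of the search
re-finding the strongest block forever.  The run terminates at the first
search that fails to converge (or selects an empty subset), or at the
``max_lfbs`` cap.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np

from .preprocess import Degenerate, MethylationDataset

__all__ = [
    "ThresholdPair",
    "EngineConfig",
    "LFB",
    "SearchFailure",
    "SearchState",
    "StepScores",
    "block_means",
    "subtract_lfbs",
    "homology_similarity",
    "condition_step",
    "site_step",
    "jaccard",
    "search_lfb",
    "run",
]


@dataclass(frozen=True)
class ThresholdPair:
    """Row (site) and column (condition) selection thresholds."""

    t_r: float
    t_c: float

    def __post_init__(self) -> None:
        if self.t_r < 0 or self.t_c < 0:
            raise ValueError("thresholds must be non-negative")


@dataclass(frozen=True)
class EngineConfig:
    """Search parameters.

    epsilon
        Jaccard convergence criterion on successive site subsets; close
        to 1 (default 0.99) means near-identical subsets are required.
    max_iterations
        Iteration cap per block search; a search that has not converged
        by then is a failure and ends the run.
    max_lfbs
        Cap on the number of blocks extracted in one run.
    init_fraction
        The initial site subset is a uniform random sample of
        ``ceil(init_fraction * n_sites)`` sites.  Small seed subsets
        (default 5%) break the symmetry between overlapping blocks; a
        large start tends to straddle them and converge on their union.
    seed
        Seed for the random initialisation; fixed seed + fixed inputs
        gives a bit-identical block sequence.
    deviation_mode
        "signed" (default) keeps only scores above the mean, targeting
        hyper-methylated blocks directly; "absolute" selects deviations
        in either direction, which also sweeps in hypo-methylated rows
        and columns and tends to merge overlapping blocks.
    threshold_scale
        "sigma" compares the deviation against T * population-sigma of
        the scores (default); "raw" compares against T directly.
    homology_weighting
        When False all t-scores are 1 and the engine reduces to a plain
        expression-weighted iterative signature search (ablation).
    degenerate
        Policy for flat rows/columns in the residual min-max; "zero"
        (default) maps them to zeros, "error" raises.  Residual matrices
        routinely contain flat slices, so "zero" is the working default
        here even though the preprocess chain errors by default.
    """

    epsilon: float = 0.99
    max_iterations: int = 50
    max_lfbs: int = 50
    init_fraction: float = 0.05
    seed: int = 0
    deviation_mode: Literal["absolute", "signed"] = "signed"
    threshold_scale: Literal["sigma", "raw"] = "sigma"
    homology_weighting: bool = True
    degenerate: Degenerate = "zero"

    def __post_init__(self) -> None:
        if not (0 < self.epsilon <= 1):
            raise ValueError("epsilon must be in (0, 1]")
        if self.max_iterations < 1 or self.max_lfbs < 1:
            raise ValueError("iteration/block caps must be >= 1")
        if not (0 < self.init_fraction <= 1):
            raise ValueError("init_fraction must be in (0, 1]")

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in (
            "epsilon", "max_iterations", "max_lfbs", "init_fraction",
            "seed", "deviation_mode", "threshold_scale",
            "homology_weighting", "degenerate")}


@dataclass(frozen=True)
class LFB:
    """One converged block: a site subset hyper-methylated across a
    condition subset, with its block means on P^t / W^t."""

    sites: frozenset[str]
    conditions: frozenset[str]
    mu_p: float
    mu_w: float
    iterations_used: int
    converged: bool
    jaccard_trace: tuple[float, ...]

    def __post_init__(self) -> None:
        if not self.sites or not self.conditions:
            raise ValueError("an LFB must have non-empty site and "
                             "condition sets")
        if not (np.isfinite(self.mu_p) and np.isfinite(self.mu_w)):
            raise ValueError("block means must be finite")

    def to_dict(self) -> dict:
        return {"sites": sorted(self.sites),
                "conditions": sorted(self.conditions),
                "mu_p": self.mu_p, "mu_w": self.mu_w,
                "iterations_used": self.iterations_used,
                "converged": self.converged,
                "jaccard_trace": list(self.jaccard_trace)}


@dataclass(frozen=True)
class SearchFailure:
    """Typed non-exceptional outcome of a block search."""

    reason: str
    iterations_used: int = 0


@dataclass
class SearchState:
    """Residual matrices and the evolving row/column subsets of one search."""

    p_resid: np.ndarray
    w_resid: np.ndarray
    p_row_norm: np.ndarray
    p_col_norm: np.ndarray
    current_sites: set[str] = field(default_factory=set)
    current_conditions: set[str] = field(default_factory=set)
    previous_sites: set[str] = field(default_factory=set)


@dataclass(frozen=True)
class StepScores:
    """Diagnostic scores of one condition/site step."""

    e_scores: Mapping[str, float]
    t_scores: Mapping[str, float]
    combined: Mapping[str, float]
    threshold_value: float


# ---------------------------------------------------------------------------
# primitives

def jaccard(a: Iterable, b: Iterable) -> float:
    """|a & b| / |a | b|; 0 when both are empty."""
    a, b = set(a), set(b)
    union = a | b
    if not union:
        return 0.0
    return len(a & b) / len(union)


def block_means(dataset: MethylationDataset, sites: Iterable[str],
                conditions: Iterable[str]) -> tuple[float, float]:
    """Mean of P^t and of W^t over the sites x conditions block."""
    rows = _indices(dataset.site_ids, sites, "site")
    cols = _indices(dataset.condition_ids, conditions, "condition")
    if rows.size == 0 or cols.size == 0:
        raise ValueError("block_means requires non-empty site and "
                         "condition sets")
    block = np.ix_(rows, cols)
    return float(dataset.p_t[block].mean()), float(dataset.w_t[block].mean())


def _indices(ordered: Sequence[str], wanted: Iterable[str],
             label: str) -> np.ndarray:
    pos = {ident: i for i, ident in enumerate(ordered)}
    try:
        return np.array(sorted(pos[w] for w in wanted), dtype=int)
    except KeyError as exc:
        raise KeyError(f"unknown {label} ID {exc.args[0]!r}") from None


def _axis_minmax(x: np.ndarray, axis: int, degenerate: Degenerate) -> np.ndarray:
    """Per-row (axis=1) or per-column (axis=0) min-max to [0, 1]."""
    lo = x.min(axis=axis, keepdims=True)
    hi = x.max(axis=axis, keepdims=True)
    rng = hi - lo
    if np.any(rng == 0):
        if degenerate == "error":
            which = "row" if axis == 1 else "column"
            idx = int(np.flatnonzero(np.squeeze(rng) == 0)[0])
            raise ValueError(f"zero-range {which} {idx} in residual min-max")
        out = (x - lo) / np.where(rng == 0, 1.0, rng)
        return np.where(np.broadcast_to(rng == 0, x.shape), 0.0, out)
    return (x - lo) / rng


def subtract_lfbs(dataset: MethylationDataset, found: Sequence[LFB],
                  degenerate: Degenerate = "zero") -> SearchState:
    """Residual matrices after masking the already-found blocks.

    Each found block's mean methylation (resp. mean weight) is subtracted
    from every cell it covers; the per-row and per-column min-max of the
    methylation residual are precomputed for the step scores.
    """
    p = dataset.p_t.copy()
    w = dataset.w_t.copy()
    for lfb in found:
        rows = _indices(dataset.site_ids, lfb.sites, "site")
        cols = _indices(dataset.condition_ids, lfb.conditions, "condition")
        p[np.ix_(rows, cols)] -= lfb.mu_p
        w[np.ix_(rows, cols)] -= lfb.mu_w
    return SearchState(
        p_resid=p, w_resid=w,
        p_row_norm=_axis_minmax(p, 1, degenerate),
        p_col_norm=_axis_minmax(p, 0, degenerate),
    )


def homology_similarity(profiles: np.ndarray, index: int,
                        group: np.ndarray) -> float:
    """Absolute Pearson correlation between one profile and the mean
    profile of its (self-inclusive) homology group.

    ``profiles`` holds the weighted profiles P^t ⊙ W^t restricted to the
    active opposite-axis subset, one row per candidate.  Profiles shorter
    than 2 or with zero variance on either side give t = 0: an undefined
    correlation must not fabricate homologous support.  A singleton group
    compares a profile with itself and scores 1 when non-constant.
    """
    x = np.asarray(profiles[index], dtype=float)
    if x.size < 2:
        return 0.0
    g = np.asarray(profiles[group], dtype=float).mean(axis=0)
    xc = x - x.mean()
    gc = g - g.mean()
    denom = np.sqrt((xc @ xc) * (gc @ gc))
    if denom == 0:
        return 0.0
    return float(min(abs(xc @ gc) / denom, 1.0))


def _t_scores(weighted: np.ndarray, group_ids: np.ndarray,
              n_groups: int) -> np.ndarray:
    """Vectorised |Pearson| of each row of `weighted` against its group
    mean row; zero-variance or length<2 profiles score 0."""
    n, width = weighted.shape
    if width < 2:
        return np.zeros(n)
    counts = np.bincount(group_ids, minlength=n_groups).astype(float)
    sums = np.zeros((n_groups, width))
    np.add.at(sums, group_ids, weighted)
    gmean = sums[group_ids] / counts[group_ids, None]
    xc = weighted - weighted.mean(axis=1, keepdims=True)
    gc = gmean - gmean.mean(axis=1, keepdims=True)
    num = np.abs((xc * gc).sum(axis=1))
    den = np.sqrt((xc * xc).sum(axis=1) * (gc * gc).sum(axis=1))
    t = np.zeros(n)
    ok = den > 0
    t[ok] = np.minimum(num[ok] / den[ok], 1.0)
    return t


def _group_codes(ordered: Sequence[str],
                 groups: Mapping[str, frozenset[str]]) -> tuple[np.ndarray, int]:
    """Integer group label per ID, groups restricted to the dataset IDs."""
    code_of: dict[frozenset, int] = {}
    codes = np.empty(len(ordered), dtype=int)
    for i, ident in enumerate(ordered):
        grp = groups[ident]
        codes[i] = code_of.setdefault(grp, len(code_of))
    return codes, len(code_of)


def _select(combined: np.ndarray, threshold: float,
            cfg: EngineConfig) -> np.ndarray:
    mean = combined.mean()
    dev = combined - mean
    if cfg.deviation_mode == "absolute":
        dev = np.abs(dev)
    if cfg.threshold_scale == "sigma":
        cut = threshold * combined.std()  # population sigma
    else:
        cut = threshold
    return np.flatnonzero(dev > cut)


def condition_step(state: SearchState, dataset: MethylationDataset,
                   thresholds: ThresholdPair,
                   cfg: EngineConfig) -> tuple[StepScores, set[str]]:
    """Score every condition against the current site subset and keep the
    outliers; returns the scores and the new condition subset (empty on a
    search-failure signal)."""
    rows = _indices(dataset.site_ids, state.current_sites, "site")
    if rows.size == 0:
        raise ValueError("condition_step requires a non-empty site subset")
    e = (state.w_resid[rows] * state.p_row_norm[rows]).mean(axis=0)
    if cfg.homology_weighting:
        weighted = (dataset.p_t * dataset.w_t)[rows].T  # conditions x |U'|
        codes, n_groups = _group_codes(dataset.condition_ids,
                                       dataset.homology.condition_groups)
        t = _t_scores(weighted, codes, n_groups)
    else:
        t = np.ones_like(e)
    combined = e * t
    keep = _select(combined, thresholds.t_c, cfg)
    ids = dataset.condition_ids
    scores = StepScores(
        e_scores=dict(zip(ids, e.tolist())),
        t_scores=dict(zip(ids, t.tolist())),
        combined=dict(zip(ids, combined.tolist())),
        threshold_value=float(thresholds.t_c * combined.std()
                              if cfg.threshold_scale == "sigma"
                              else thresholds.t_c),
    )
    return scores, {ids[j] for j in keep}


def site_step(state: SearchState, dataset: MethylationDataset,
              thresholds: ThresholdPair,
              cfg: EngineConfig) -> tuple[StepScores, set[str]]:
    """Mirror of :func:`condition_step` over sites, using the per-column
    residual min-max and the site (gene) homology groups."""
    cols = _indices(dataset.condition_ids, state.current_conditions,
                    "condition")
    if cols.size == 0:
        raise ValueError("site_step requires a non-empty condition subset")
    e = (state.w_resid[:, cols] * state.p_col_norm[:, cols]).mean(axis=1)
    if cfg.homology_weighting:
        weighted = (dataset.p_t * dataset.w_t)[:, cols]  # sites x |V'|
        codes, n_groups = _group_codes(dataset.site_ids,
                                       dataset.homology.site_groups)
        t = _t_scores(weighted, codes, n_groups)
    else:
        t = np.ones_like(e)
    combined = e * t
    keep = _select(combined, thresholds.t_r, cfg)
    ids = dataset.site_ids
    scores = StepScores(
        e_scores=dict(zip(ids, e.tolist())),
        t_scores=dict(zip(ids, t.tolist())),
        combined=dict(zip(ids, combined.tolist())),
        threshold_value=float(thresholds.t_r * combined.std()
                              if cfg.threshold_scale == "sigma"
                              else thresholds.t_r),
    )
    return scores, {ids[i] for i in keep}


# ---------------------------------------------------------------------------
# search loop

def search_lfb(dataset: MethylationDataset, found: Sequence[LFB],
               thresholds: ThresholdPair, cfg: EngineConfig,
               rng: np.random.Generator | None = None) -> LFB | SearchFailure:
    """One block search: residualise, random site-subset start, alternate
    condition/site steps until the site subset stabilises.

    Returns a converged :class:`LFB`, or a :class:`SearchFailure` when a
    step selects nothing or the iteration cap is reached.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    state = subtract_lfbs(dataset, found, degenerate=cfg.degenerate)
    m = len(dataset.site_ids)
    n_init = max(1, int(np.ceil(cfg.init_fraction * m)))
    init = rng.choice(m, size=n_init, replace=False)
    state.current_sites = {dataset.site_ids[i] for i in np.sort(init)}

    trace: list[float] = []
    for iteration in range(1, cfg.max_iterations + 1):
        _, new_conditions = condition_step(state, dataset, thresholds, cfg)
        if not new_conditions:
            return SearchFailure("empty condition selection", iteration)
        state.current_conditions = new_conditions
        _, new_sites = site_step(state, dataset, thresholds, cfg)
        if not new_sites:
            return SearchFailure("empty site selection", iteration)
        state.previous_sites = state.current_sites
        state.current_sites = new_sites
        jac = jaccard(state.current_sites, state.previous_sites)
        trace.append(jac)
        if jac >= cfg.epsilon:
            mu_p, mu_w = block_means(dataset, state.current_sites,
                                     state.current_conditions)
            return LFB(sites=frozenset(state.current_sites),
                       conditions=frozenset(state.current_conditions),
                       mu_p=mu_p, mu_w=mu_w,
                       iterations_used=iteration, converged=True,
                       jaccard_trace=tuple(trace))
    return SearchFailure("no convergence within max_iterations",
                         cfg.max_iterations)


def run(dataset: MethylationDataset, thresholds: ThresholdPair,
        cfg: EngineConfig | None = None) -> list[LFB]:
    """Extract blocks sequentially until a search fails or the cap is hit.

    Each converged block is masked out of the residual before the next
    search; overlapping blocks are permitted and recovered separately.
    The returned list is in discovery order.
    """
    cfg = cfg or EngineConfig()
    rng = np.random.default_rng(cfg.seed)
    found: list[LFB] = []
    while len(found) < cfg.max_lfbs:
        outcome = search_lfb(dataset, found, thresholds, cfg, rng=rng)
        if isinstance(outcome, SearchFailure):
            break
        found.append(outcome)
    return found
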