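# Methods and design notes

## The model

The object being mined is a *locally hyper-methylated block* (LFB): a
set of m⁶A sites whose methylation level is jointly elevated across a
set of experimental conditions.  The biological premise is that the few
writer/eraser enzymes each regulate many sites, so sites under common
regulation share a methylation pattern — and that this sharing is
structured by homology: sites of one gene tend to co-vary, as do
conditions derived from one cell line.

The search is an iterative signature algorithm (ISA) over the
normalised methylation matrix *Pᵗ*, with two modifications relative to
a plain ISA: every evidence score is multiplied by the (residualised)
expression weight — methylation ratios estimated from deep coverage
count for more — and by the homology similarity term, the absolute
Pearson correlation of a candidate row/column's weighted profile with
its homology group's mean profile.  Found blocks are masked by
subtracting their mean methylation and weight from the residual
matrices, and the search restarts from a fresh random site subset, so
overlapping blocks can be extracted sequentially.  The run terminates
at the first search that either fails the Jaccard convergence test
within the iteration cap or selects an empty row/column set.

Assumptions worth keeping in mind:

* Hyper-methylation is *relative*: thresholds compare each score to the
  mean and population standard deviation of its axis, so a block is
  whatever stands out from the current residual background, not
  whatever exceeds a fixed methylation value.
* The normalisation cascade removes global, per-site and per-condition
  level effects.  In particular the column step removes each column's
  mean — a planted block's column-mean elevation is gone after
  preprocessing, and the search detects blocks through within-column
  contrast, amplified over iterations.
* Masking assumes blocks combine additively in the residual; cells
  covered by several blocks accumulate all their subtractions.

## Parameters

| parameter | default | meaning / rationale |
|---|---|---|
| `alpha` | 1e-6 | pseudo-count in the methylation ratio; zero-coverage cells resolve to exactly 0.5 (no evidence either way) |
| `log_base` | natural | base of the expression weight log; min–max removes scale but not curve shape, so it is recorded in run metadata |
| `degenerate` | `error` (preprocess), `zero` (engine) | zero-range rows/columns in a min–max step; the preprocessing chain refuses them loudly, while the engine maps them to zeros because residual matrices generically contain flat slices |
| `t_r`, `t_c` | — | selection thresholds, in units of population standard deviations of the combined scores; the tuning framework searches 0–3 |
| `epsilon` | 0.99 | Jaccard convergence on successive site subsets |
| `max_iterations` | 50 | per-search cap; non-convergence ends the run |
| `max_lfbs` | 50 | run-level cap guarding pathological inputs |
| `init_fraction` | 0.05 | the initial site subset is a uniform random 5% sample.  Small seeds follow ISA practice and break the symmetry between overlapping blocks — a half-matrix start straddles them and converges on their union |
| `deviation_mode` | `signed` | keep scores above mean + T·σ.  The target is *hyper*-methylation; the two-sided `absolute` variant also sweeps in hypo-methylated rows/columns and tends to merge overlapping blocks, so it is provided as an option, not the default |
| `threshold_scale` | `sigma` | `raw` compares deviations against T directly instead of T·σ |
| `homology_weighting` | `true` | multiply evidence by the homology similarity; `false` gives the plain expression-weighted ISA (ablation) |

Enrichment: p-values are one-sided hypergeometric over the annotation
universe, floored at 1e-300; `−log₁₀` is used for the term scores
(configurable); Benjamini–Hochberg q-values are reported alongside but
never enter the WE score, matching its definition on raw p-values.  The
random baseline uses 100 seeded draws by default (50 inside the grid
search).  Grid selection ties break to the smaller *T_R*, then *T_C*.

## The synthetic data

`synthetic.simulate` emulates the data model the method consumes:
per-cell coverage is log-normal (median ≈ 20 FPKM) with the
per-(gene, condition) expression draw shared by a gene's sites — FPKM
is a transcript-level quantity — plus per-site jitter; target
methylation is a baseline (0.3) with planted blocks raised to 0.85,
modulated by a shared per-condition *co-methylation pattern*
(`block_pattern_sd`), with gene-shared perturbations
(homologous sites of one gene share one draw per condition), optional
per-site noise and per-cell signal dropout.  IP and input FPKM are then
`π·c` and `(1−π)·c`, so the methylation ratio inverts to the target
level exactly as the pseudo-count vanishes.  The default planted block
covers whole genes and whole cell lines, the alignment the homology
terms are designed for, and the emitted annotation gives each block's
genes one term plus random filler terms.

`synthetic.planted_dataset` constructs the normalised dataset directly
(background 0.1, block 0.9, mid-range weights) and is the canonical
benchmark for the search engine in isolation; `epiblock.benchmarks`
defines the recovery studies on it.

What the generator does **not** emulate: read-level sampling noise,
transcript length and GC biases, peak-calling uncertainty, antibody
efficiency differences, and real annotation structure (term overlap
hierarchies).  Passing recovery benchmarks therefore demonstrates the
search mechanics — bootstrap, masking, convergence, thresholds — not
performance on real compendia, where background sites are not
exchangeable and annotation signal is far sparser.

## Numerical choices

* Centering–scaling steps divide by the range (max − min), exactly as
  the method defines them, not by the standard deviation.
* A constant overall matrix is always an error; flat rows/columns
  follow the `degenerate` policy.  Note that the pseudo-count leaves
  "flat" background rows microscopically varied, and the row step then
  amplifies that variation to full range — cell-level order is *not*
  preserved through the cascade, only aggregate contrast (the test
  suite asserts exactly this).
* Homology similarity of a zero-variance or length-<2 profile is 0: an
  undefined correlation must not fabricate homologous support.
  Singleton groups give t = 1 by self-correlation.
* Selection uses strict inequality; with exactly half an axis planted,
  deviations equal σ and nothing is selected — benchmark constructions
  keep planted structure a proper minority.
* Block means are computed on *Pᵗ*/*Wᵗ*, not on residuals; e-scores use
  the residual weight matrix while t-scores use the un-residualised
  weighted profiles, preserving the distinction the score definitions
  draw.
* Convergence is tested on the site subset only; the conditions
  reported with a block are those that produced its final site set.
* All randomness flows from explicit integer seeds through numpy
  Generators; a fixed seed gives a bit-identical block sequence, and
  the grid search derives per-repeat seeds from its master seed.

## Known limitations

* **The homology similarity term is a double-edged sword.**  On short
  profiles (a block search typically restricts to ~6 conditions) the
  absolute Pearson correlation is a high-variance statistic, and
  multiplying it into well-separated evidence scores adds noise.
  Worse, any noise process that decouples an individual site from its
  gene-mates (e.g. per-site signal dropout) lowers exactly the true
  sites' similarity scores, while background gene-mates sharing their
  per-gene noise score high.  The ablation benchmark
  (`benchmarks.homology_ablation`, reported by the acceptance script)
  measures this directly, and on planted data the weighted search
  recovers *fewer* true sites than the unweighted one.  The term can
  help only where gene-mates share signal variation that individual
  noise does not destroy; treat `homology_weighting=false` as a
  serious candidate configuration.
* After the genuine hyper-methylated signal is masked, searches can
  still converge on residual background structure, so runs often end
  at the block cap with background-level blocks in the tail.  Filter
  by block mean methylation (see the first example).
* The termination rule (first failed search) makes the *number* of
  blocks sensitive to noise; the recovery benchmarks therefore score
  block sets against planted truth rather than counting.
* The enrichment baseline errors when random draws show no enrichment
  at all (WE_random = 0, RPR undefined); annotations with very few
  terms may need a larger `alpha_filter` or more draws.
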