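# epiblock

Homology-weighted biclustering of MeRIP-seq epi-transcriptome data:
mining **locally hyper-methylated blocks** (LFBs) — subsets of m⁶A sites
that are jointly hyper-methylated across subsets of experimental
conditions — together with an enrichment-constraint framework for tuning
the search thresholds.

The package is written for computational epigenomics: you have per-site
FPKM matrices from the IP (methylation-enriched) and input (expression
background) libraries of a MeRIP-seq compendium, and you want the
co-methylation modules hiding in them — groups of sites that a common
writer/eraser enzyme plausibly regulates together under specific
conditions or cell lines.

## The method

From the paired FPKM matrices *t* (IP) and *h* (input), each site *i*
and condition *j* gets a methylation level and an expression confidence
weight

```
p_ij = (t_ij + α) / (t_ij + h_ij + 2α),      w_ij = log(t_ij + h_ij + 1)
```

*P* is passed through whole → row → column centering–scaling
((x − mean)/range along each axis in turn) and a global min–max, giving
*Pᵗ* ∈ [0, 1]; *W* is min–max normalised to *Wᵗ*.

The search is an iterative signature algorithm: starting from a small
random site subset *U′*, it alternates a condition step and a site step.
The condition step scores every condition *v* by the expression-weighted
evidence over the current sites,

```
e_v = (1/|U′|) Σ_{u∈U′} w⁽ᵏ⁾_uv · p^{R(k)}_uv
```

(*p^{R(k)}* is the per-row min–max of the residual methylation matrix),
multiplied by the **homology similarity** *t_v* — the absolute Pearson
correlation between *v*'s weighted profile *Pᵗ⊙Wᵗ* and the mean profile
of the conditions sharing its cell line.  Conditions whose combined
score stands out from the mean by more than *T_C* population standard
deviations are kept; the site step mirrors this with per-column
normalisation, gene-homology groups and threshold *T_R*.  Iteration
stops when the Jaccard similarity of successive site subsets reaches
ε (default 0.99).  Each converged block's mean methylation and weight
are subtracted from its cells (residual masking), and the search
restarts — which is how overlapping blocks are recovered one by one.
The run ends at the first search that fails to converge.

To choose (*T_R*, *T_C*), each block's gene set is scored by a one-sided
hypergeometric test against an annotation (GMT) file, aggregated into a
weighted enrichment score `WE = Σ(-log10 p_i)·m_i/M / (Σ m_i/M + m_non/M)`
and compared against random gene sets of the same size through the
relative promotion rate `RPR = M(WE − WE_random) / (M_all · WE_random)`.
A grid search keeps the threshold pairs yielding the most blocks and,
among those, picks the pair with the best mean RPR.

## A worked example

```sh
python examples/01_mine_planted_blocks.py
```

builds a 500 × 30 benchmark with two planted blocks that share 20% of
their sites, runs the search at *T_R* = *T_C* = 1 and prints:

```
found 50 converged block(s); 2 hyper-methylated:
  LFB 0: 40 sites x 6 conditions, mean methylation 0.905, converged in 2 iterations
  LFB 1: 40 sites x 6 conditions, mean methylation 0.899, converged in 3 iterations
recovery 1.000  relevance 1.000
```

Both overlapping planted blocks are recovered exactly (match score 1.0 =
site-Jaccard × condition-Jaccard against the planted truth); the
converged blocks whose mean methylation sits at background level are
residual artifacts of the masking and are filtered by their block mean.
`examples/02_full_fpkm_pipeline.py` runs the same search on simulated
raw IP/input FPKM tables through the full preprocessing chain, and
`examples/03_threshold_tuning.py` demonstrates the enrichment-based
grid search (it prints the grid of mean block counts and RPRs and the
selected pair).

There is also a thin command line:

```sh
epiblock simulate --out fixture/
epiblock preprocess --ip fixture/ip.tsv --input fixture/input.tsv \
    --site-genes fixture/site_genes.tsv \
    --condition-celllines fixture/condition_celllines.tsv \
    --degenerate zero --out dataset/
epiblock run --dataset dataset/ --tr 1.0 --tc 1.0 --seed 1 --out lfbs/
epiblock tune --dataset dataset/ --gmt fixture/annotation.gmt \
    --site-genes fixture/site_genes.tsv --out tuned/
```

Every command writes a `metadata.json` (config, seed, version) from
which its outputs are reproducible byte for byte.

## Layout

```
src/epiblock/preprocess.py   FPKM pair -> normalised dataset, homology maps
src/epiblock/engine.py       the block search (scores, steps, masking)
src/epiblock/enrichment.py   hypergeometric tests, WE score, RPR, grid search
src/epiblock/synthetic.py    simulator + planted benchmark constructors
src/epiblock/benchmarks.py   the reproducible recovery studies
src/epiblock/cli.py          the command-line front end
docs/methods.md              modelling and design notes
```
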