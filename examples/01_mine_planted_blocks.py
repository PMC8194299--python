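"""Mine hyper-methylated blocks from a planted benchmark matrix.

Builds a 500-site x 30-condition normalised methylation dataset with two
overlapping planted blocks, runs the block search, and scores the result
against the planted truth.
"""

from epiblock import EngineConfig, ThresholdPair, run
from epiblock.synthetic import PlantedBlock, planted_dataset, recovery_score

blocks = [
    PlantedBlock(frozenset(range(40)), frozenset(range(6))),
    PlantedBlock(frozenset(range(32, 72)), frozenset(range(6, 12))),
]
dataset, truth = planted_dataset(n_sites=500, n_conditions=30,
                                 blocks=blocks, noise_sd=0.05, seed=1)

lfbs = run(dataset, ThresholdPair(t_r=1.0, t_c=1.0), EngineConfig(seed=1))

# Blocks are extracted until a search fails to converge.  Once the real
# hyper-methylated signal is masked out, the search can still converge
# on residual background structure, so filter by block mean methylation:
# genuine hyper-methylated blocks sit far above the matrix average.
hyper = [b for b in lfbs if b.mu_p > dataset.p_t.mean() + 0.2]
print(f"found {len(lfbs)} converged block(s); "
      f"{len(hyper)} hyper-methylated:")
for k, b in enumerate(hyper):
    print(f"  LFB {k}: {len(b.sites)} sites x {len(b.conditions)} "
          f"conditions, mean methylation {b.mu_p:.3f}, "
          f"converged in {b.iterations_used} iterations")

report = recovery_score(hyper, truth)
print(f"recovery {report.recovery:.3f}  relevance {report.relevance:.3f}")
print("(1.0 = every planted block matched exactly; the match score of a "
      "block is the product of its site-set and condition-set Jaccard "
      "indices)")
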