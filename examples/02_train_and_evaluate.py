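"""Race the multi-QMS encoding against binary mutation status.

Generates a small synthetic cell-line cohort with a planted threshold
driver (only high-impact driver mutations confer sensitivity), runs
repeated nested cross-validation for both encodings and compares the
pooled held-out Pearson correlations with Fisher's r-to-z test.
"""

from qmsdr import GeneratorConfig
from qmsdr.benchmarks import multi_vs_binary

config = GeneratorConfig(n_samples=400, n_genes=40, seed=5)
result = multi_vs_binary(config, n_repeats=3)

print(f"pooled test Pearson r, multi-QMS : {result.multi.pooled_r:.3f} "
      f"(n={result.multi.n_pooled})")
print(f"pooled test Pearson r, binary    : {result.binary.pooled_r:.3f} "
      f"(n={result.binary.n_pooled})")
print(f"difference                       : {result.margin:.3f}")
print(f"Fisher r-to-z                    : z={result.fisher_z:.2f}, "
      f"p={result.fisher_p:.2e}")
# The score-based encoding separates high-impact from low-impact driver
# mutations, which the mutated/unmutated flag cannot do by construction,
# so the multi-QMS model correlates substantially better with the
# measured AUDRC on held-out samples.
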