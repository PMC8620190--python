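"""Score all methods over replicated simulations.

Each replicate simulates a community, infers an association network, applies
every single method plus the intersection combination, and scores removals
against the known interactions. The summary reports per-method medians: the
removed fraction and the precision (PPV - fraction of removed edges that
really were false associations).
"""

from ended import run_benchmark, summarize_benchmark

table = run_benchmark(n_datasets=5, seed=0)
summary = summarize_benchmark(table)
cols = ["approach", "removed_fraction_median", "PPV_median", "TPR_median",
        "TNR_median"]
print(summary[cols].to_string(index=False))
# Single methods remove more edges (higher TPR) but also more true
# interactions; the intersection is conservative: fewest removals, best
# precision.
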