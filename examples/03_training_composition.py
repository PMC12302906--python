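"""Does the training pool determine whether the true driver is identified?

Per gene, models are trained on subsamples drawn from three pools — chamber
data only, field data only, or a half-and-half mixture — and for each
subsample the better of the temperature- and radiation-driven models is
chosen by BIC.  In chamber data the two variables decouple, so the choice
is consistent; in field data they share the solar cycle and the choice is
ambiguous.  Held-out error is always measured on field samples never seen
in training.

This is a small, fast version (6 genes, n=96, 6 replicates); the full
experiment runs via ``scripts/acceptance.py`` or the pipeline CLI.
"""

import pandas as pd

from fieldfit import (build_pool, enumerate_conditions, run_selection_experiment,
                      selection_accuracy, summarize_mae)
from fieldfit.synthdata import (make_truth_genes, simulate_field_study,
                                simulate_gc_study)

conditions = enumerate_conditions()
probe = simulate_gc_study(conditions, [], seed=10)
truth = make_truth_genes(3, 3, 0, reference=probe.samples, seed=10)
gc = simulate_gc_study(conditions, truth, seed=11)
fd = simulate_field_study(truth, n_samples=300, seed=12)
test = simulate_field_study(truth, n_samples=200, seed=13)

pools = [build_pool("gc", [gc]), build_pool("field", [fd]),
         build_pool("mixed", [gc, fd])]
result = run_selection_experiment(
    [t.gene_id for t in truth], pools, sizes=(96,), reps=6,
    test=(test.expr, test.samples), seed=14,
)

drivers = {t.gene_id: t.driver for t in truth}
print("fraction of (gene, replicate) choices matching the true driver:")
for pool in ("gc", "field", "mixed"):
    acc = selection_accuracy(result, drivers, pool, 96)
    print(f"  {pool:6s} {acc:.2f}")

med = summarize_mae(result.summaries, "per_rep_median")
print("\nmedian held-out field MAE (log2 units), by pool:")
print(med.groupby("pool")["median_mae"].median().round(3).to_string())
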