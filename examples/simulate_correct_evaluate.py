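"""The full workflow at small scale: simulate reads with known errors,
correct them, and score every base against the ground truth.

Recall is the fraction of injected errors restored to the true base;
precision is the fraction of changes that were real errors. Recall is
expected to drop on low-expression transcripts, whose k-mers are too
rare to distinguish from errors.
"""

import warnings

from readfix import (CorrectionParams, ThresholdConfig, build_table,
                     correct_read, resolve_alpha)
from readfix.evaluate import evaluate_run, metrics
from readfix.simulate import SimConfig, simulate_dataset

config = SimConfig(n_transcripts=12, n_reads=4000, read_length=100,
                   error_rate=0.005, seed=7)
transcripts, clean, mutated, truths, origins = simulate_dataset(config)
n_errors = sum(len(t.positions) for t in truths)
print(f"simulated {len(mutated)} reads from {len(transcripts)} transcripts "
      f"({n_errors} injected errors)")

table = build_table(mutated, k=23)
tc = ThresholdConfig()
with warnings.catch_warnings():
    warnings.simplefilter("ignore")  # tiny dataset: alpha falls back
    alpha = resolve_alpha(table, tc, seed=7)
params = CorrectionParams(k=23, alpha=alpha, threshold_config=tc)
print(f"k-mer table: {len(table)} multi-occurrence 23-mers; alpha = {alpha}")

results = [correct_read(r, table, params) for r in mutated]
truth_map = {t.read_id: t for t in truths}
overall, by_tier = evaluate_run(mutated, results, truth_map)
m = metrics(overall)
print(f"overall: TP={overall.tp} FP={overall.fp} FN={overall.fn}  "
      f"recall={m.recall:.3f} precision={m.precision:.3f} F={m.f_score:.3f}")
for tier in ("high", "medium", "low"):
    if tier in by_tier:
        mt = metrics(by_tier[tier])
        print(f"  {tier:<7} recall={mt.recall:.3f} precision={mt.precision:.3f}")
# TP + FN always equals the number of injected errors (conservation).
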