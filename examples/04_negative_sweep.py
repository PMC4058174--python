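"""How many training negatives are worth using?

Protocol: hold out the first positives/negatives as a fixed validation
set, then train on all remaining positives plus the first n remaining
negatives for increasing n, and watch the validation metrics. On real
benchmarks performance rises with n and then plateaus.
"""

from dnabind import (
    SyntheticConfig,
    TrainingSet,
    feature_matrix,
    generate,
    split_validation,
    sweep_negatives,
)

# A weak compositional shift keeps the task hard enough that the
# benefit of extra negatives is visible.
records, labels = generate(SyntheticConfig(n_pos=80, n_neg=900, delta=0.05, seed=5))
data = TrainingSet(feature_matrix(records), labels, ids=[r.id for r in records])

validation, remainder = split_validation(data, n_pos_val=40, n_neg_val=150)
table = sweep_negatives(remainder, validation, [50, 150, 400, 750], rounds=10, seed=5)
print(table.to_string(index=False))
# One row per negative count n; ACC/SE/SP/F1 in percent, MCC in [-1, 1],
# all measured on the same fixed validation set.
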