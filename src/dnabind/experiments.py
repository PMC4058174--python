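"""Negative-sample-count experiment: fixed validation split, sweep of n.

Protocol: hold out the FIRST ``n_pos_val`` positives and FIRST
``n_neg_val`` negatives (in dataset row order) as a validation set; for
each requested negative count n, train on all remaining positives plus
the first n remaining negatives and evaluate on the validation set.
Negative subsets are therefore nested prefixes (smaller training sets
are contained in larger ones), making the sweep a clean measurement of
the effect of adding negatives.
"""

from __future__ import annotations

from os import PathLike
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from dnabind.ensemble import BaseLearnerSpec, TrainingSet, train
from dnabind.evaluation import evaluate_model


def split_validation(
    data: TrainingSet, n_pos_val: int, n_neg_val: int
) -> tuple[TrainingSet, TrainingSet]:
    """Split off the first ``n_pos_val`` positives and ``n_neg_val`` negatives.

    Both partitions preserve the input row order; they are disjoint and
    together exhaust the input.
    """
    pos_rows = np.flatnonzero(data.y == 1)
    neg_rows = np.flatnonzero(data.y == -1)
    if n_pos_val < 0 or n_neg_val < 0:
        raise ValueError("validation counts must be non-negative")
    if n_pos_val > len(pos_rows):
        raise ValueError(
            f"requested {n_pos_val} validation positives but only "
            f"{len(pos_rows)} available"
        )
    if n_neg_val > len(neg_rows):
        raise ValueError(
            f"requested {n_neg_val} validation negatives but only "
            f"{len(neg_rows)} available"
        )
    val_rows = np.sort(
        np.concatenate([pos_rows[:n_pos_val], neg_rows[:n_neg_val]])
    ).astype(int)
    mask = np.zeros(len(data), dtype=bool)
    mask[val_rows] = True
    rest_rows = np.flatnonzero(~mask)
    return data.subset(val_rows), data.subset(rest_rows)


def sweep_negatives(
    remainder: TrainingSet,
    validation: TrainingSet,
    n_values: Sequence[int],
    registry: Optional[Sequence[BaseLearnerSpec]] = None,
    rounds: Optional[int] = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Train with increasing negative counts and tabulate validation metrics.

    Returns one row per requested n, in request order, with columns
    ``n, ACC, MCC, SE, SP, F1`` (ACC/SE/SP/F1 in percent). Identical
    seeds give identical rows for duplicated n.
    """
    pos_rows = np.flatnonzero(remainder.y == 1)
    neg_rows = np.flatnonzero(remainder.y == -1)
    n_values = [int(n) for n in n_values]
    for n in n_values:
        if n < 1 or n > len(neg_rows):
            raise ValueError(
                f"sweep value n={n} out of range (remainder holds "
                f"{len(neg_rows)} negatives)"
            )
    rows = []
    for n in n_values:
        take = np.sort(np.concatenate([pos_rows, neg_rows[:n]])).astype(int)
        subset = remainder.subset(take)
        model = train(subset, registry=registry, rounds=rounds, seed=seed)
        report, _ = evaluate_model(model, validation)
        rows.append(
            {
                "n": n,
                "ACC": report.acc,
                "MCC": report.mcc,
                "SE": report.se,
                "SP": report.sp,
                "F1": 100.0 * report.f1,
            }
        )
    return pd.DataFrame(rows, columns=["n", "ACC", "MCC", "SE", "SP", "F1"])


def plot_sweep(table: pd.DataFrame, path: Union[str, PathLike]) -> None:
    """Save a metric-vs-n line plot for a sweep table."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    for column in ("ACC", "SE", "SP", "F1"):
        ax.plot(table["n"], table[column], marker="o", label=column)
    ax.plot(table["n"], 100 * table["MCC"], marker="s", label="MCC x100")
    ax.set_xlabel("training negatives n")
    ax.set_ylabel("metric (%)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
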