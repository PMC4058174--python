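"""Independent brute-force reference for the feature definitions.

Pure-Python, loop-based, written directly from the defining formulas:
per-letter composition o_a / L; per-group content, position-quantile
distribution with 1-based index k = ceil(q * n); cross-group adjacent
dipeptide counts over the L - 1 pairs. Kept deliberately separate from
the package implementation it checks.
"""

import math

ALPHABET = "ACDEFGHIKLMNPQRSTVWY"


def brute_force_features(seq, grouping_rows, normalizer="L"):
    """Feature list for ``seq`` given ``grouping_rows`` of (g1, g2, g3) strings."""
    L = len(seq)
    feats = [seq.count(aa) / L for aa in ALPHABET]
    for row in grouping_rows:
        groups = [set(g) for g in row]

        def group_index(c):
            for gi, g in enumerate(groups):
                if c in g:
                    return gi
            raise ValueError(c)

        # content
        counts = [sum(1 for c in seq if c in g) for g in groups]
        feats += [c / L for c in counts]
        # distribution
        for g in groups:
            positions = [i + 1 for i, c in enumerate(seq) if c in g]
            n = len(positions)
            if n == 0:
                feats += [0.0] * 5
                continue
            picks = [positions[0]]
            picks += [positions[math.ceil(q * n) - 1] for q in (0.25, 0.5, 0.75)]
            picks.append(positions[-1])
            feats += [p / L for p in picks]
        # dipeptide composition across distinct groups
        pair_counts = {frozenset((0, 1)): 0, frozenset((0, 2)): 0, frozenset((1, 2)): 0}
        for a, b in zip(seq, seq[1:]):
            key = frozenset((group_index(a), group_index(b)))
            if len(key) == 2:
                pair_counts[key] += 1
        denom = L if normalizer == "L" else max(L - 1, 1)
        feats += [
            pair_counts[frozenset((0, 1))] / denom,
            pair_counts[frozenset((0, 2))] / denom,
            pair_counts[frozenset((1, 2))] / denom,
        ]
    return feats
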