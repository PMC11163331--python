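"""Independent reference implementations used only to check the package.

These deliberately avoid the library's own alignment primitives: edit
distance is a numpy dynamic program, and the greedy clustering oracle is a
from-scratch restatement of the 97% rule.
"""

import numpy as np


def levenshtein_oracle(a: str, b: str) -> int:
    """Row-wise DP; the insertion recurrence is closed with a running-min
    trick: min_k (cand[k] + (j - k)) = accumulate(cand - j) + j."""
    if a == b:
        return 0
    bn = np.frombuffer(b.encode(), dtype=np.uint8)
    prev = np.arange(len(b) + 1)
    for ca in a.encode():
        cand = np.empty(len(b) + 1, dtype=int)
        cand[0] = prev[0] + 1
        cand[1:] = np.minimum(prev[1:] + 1, prev[:-1] + (bn != ca))
        idx = np.arange(len(b) + 1)
        prev = np.minimum.accumulate(cand - idx) + idx
    return int(prev[-1])


def identity_oracle(a: str, b: str) -> float:
    n = max(len(a), len(b))
    return 1.0 if n == 0 else 1.0 - levenshtein_oracle(a, b) / n


def greedy_cluster_oracle(seqs: list, min_identity: float = 0.97) -> list:
    """Greedy centroid clustering over sequences already in priority order.

    Returns a list of clusters, each a list of member sequences, in
    founding order.
    """
    clusters: list[list[str]] = []
    for s in seqs:
        for cl in clusters:
            if identity_oracle(s, cl[0]) >= min_identity:
                cl.append(s)
                break
        else:
            clusters.append([s])
    return clusters
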