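"""ReliefF feature relevance (multi-class, k nearest neighbors).

Every instance serves as a reference point (m = n). For each reference, the
k nearest same-class hits pull a feature's weight down by their normalized
value difference; the k nearest misses of every other class, weighted by
that class's prior renormalized over the complement of the reference class,
push the weight up. Distances are Manhattan on range-normalized features.
"""

from __future__ import annotations

import numpy as np


def relieff_scores(X: np.ndarray, y_codes: np.ndarray, k: int = 10) -> np.ndarray:
    n, p = X.shape
    span = X.max(axis=0) - X.min(axis=0)
    span[span == 0] = 1.0  # constant feature: all diffs 0 regardless
    Z = X / span

    classes = np.unique(y_codes)
    priors = {c: float((y_codes == c).mean()) for c in classes}

    # pairwise Manhattan distances on normalized features, computed in row
    # chunks to bound memory at ~chunk * n * p floats
    D = np.empty((n, n))
    chunk = max(1, int(2e7 // max(n * p, 1)))
    for start in range(0, n, chunk):
        stop = min(start + chunk, n)
        D[start:stop] = np.abs(
            Z[start:stop, None, :] - Z[None, :, :]
        ).sum(axis=2)
    np.fill_diagonal(D, np.inf)

    W = np.zeros(p)
    for i in range(n):
        ci = y_codes[i]
        for c in classes:
            members = np.flatnonzero(y_codes == c)
            members = members[members != i]
            if len(members) == 0:
                continue
            kk = min(k, len(members))
            # nearest kk, ties broken by index for determinism
            order = members[np.lexsort((members, D[i, members]))][:kk]
            diffs = np.abs(Z[i] - Z[order]).sum(axis=0) / kk
            if c == ci:
                W -= diffs
            else:
                W += priors[c] / (1.0 - priors[ci]) * diffs
    return W / n
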