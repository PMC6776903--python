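"""Independent reference implementations used as test oracles."""

import itertools

import numpy as np
from scipy.stats import rankdata


def brute_force_insulation(values, w, mode):
    """Double-loop reference for the raw insulation score."""
    n = values.shape[0]
    raw = np.full(n, np.nan)
    for i in range(w, n - w):
        square = []
        for a in range(i - w, i):
            for b in range(i + 1, i + w + 1):
                if np.isfinite(values[a, b]):
                    square.append(values[a, b])
        if not square:
            continue
        square = np.array(square)
        if mode == "mean":
            raw[i] = square.mean()
        else:
            q1, q3 = np.percentile(square, [25, 75])
            iqr = q3 - q1
            keep = square[(square >= q1 - 1.5 * iqr) & (square <= q3 + 1.5 * iqr)]
            raw[i] = keep.mean()
    return raw


def exact_rank_sum_p(x, y):
    """Brute-force enumeration of the two-sided rank-sum null."""
    combined = np.concatenate([x, y])
    ranks = rankdata(combined)
    n = len(x)
    w_obs = ranks[:n].sum()
    ws = np.array([ranks[list(idx)].sum()
                   for idx in itertools.combinations(range(len(combined)), n)])
    mu = ws.mean()
    return float(np.mean(np.abs(ws - mu) >= abs(w_obs - mu) - 1e-9))
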