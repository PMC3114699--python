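"""Brute-force SAM oracle: plain-loop reimplementation of the permutation
FDR machinery, enumerating every distinct label assignment itself.  Kept
deliberately naive (python loops, no shared code with the package) so it can
serve as an independent cross-check."""

import itertools

import numpy as np


def two_class_d(values, labels, treat, ref, s0):
    d = []
    for row in values:
        x1 = [v for v, l in zip(row, labels) if l == treat and np.isfinite(v)]
        x2 = [v for v, l in zip(row, labels) if l == ref and np.isfinite(v)]
        if len(x1) < 2 or len(x2) < 2:
            d.append(np.nan)
            continue
        m1 = sum(x1) / len(x1)
        m2 = sum(x2) / len(x2)
        ss = sum((v - m1) ** 2 for v in x1) + sum((v - m2) ** 2 for v in x2)
        pooled = ss / (len(x1) + len(x2) - 2)
        s = ((1 / len(x1) + 1 / len(x2)) * pooled) ** 0.5
        d.append((m1 - m2) / (s + s0))
    return np.array(d)


def exhaustive_sam_fdr(values, labels, treat, ref, s0, n_delta=60):
    """Full enumeration of label assignments; returns delta table + q-values.

    Follows the standard SAM definitions: expected order statistics from the
    permutation null, cut points as the least extreme observed statistic at
    least delta away from its expectation, called counts, pi0-scaled median
    null counts beyond the cuts, and per-gene q = minimum FDR over the
    deltas at which the gene is called, monotonized along |d|.
    """
    labels = list(labels)
    d_obs = two_class_d(values, labels, treat, ref, s0)
    perms = sorted(set(itertools.permutations(labels)))
    d_perm = np.array([two_class_d(values, list(p), treat, ref, s0) for p in perms])

    d_sorted = np.sort(d_obs)
    dbar = np.sort(d_perm, axis=1).mean(axis=0)
    q25, q75 = np.percentile(d_perm.ravel(), [25, 75])
    pi0 = min(1.0, np.sum((d_obs > q25) & (d_obs < q75)) / (0.5 * len(d_obs)))

    diff = d_sorted - dbar
    deltas = np.linspace(0.0, np.abs(diff).max(), n_delta)
    table = []
    q = np.full(len(d_obs), 1.0)
    for delta in deltas:
        ups = [d_sorted[i] for i in range(len(d_sorted)) if diff[i] >= delta]
        lows = [d_sorted[i] for i in range(len(d_sorted)) if -diff[i] >= delta]
        cutup = min(ups) if ups else np.inf
        cutlow = max(lows) if lows else -np.inf
        called_mask = (d_obs >= cutup) | (d_obs <= cutlow)
        called = int(called_mask.sum())
        false_counts = [
            int(np.sum(row >= cutup) + np.sum(row <= cutlow)) for row in d_perm
        ]
        median_false = pi0 * float(np.median(false_counts))
        fdr = min(1.0, median_false / called) if called else 0.0
        table.append((delta, cutlow, cutup, called, median_false, fdr))
        if called:
            q[called_mask] = np.minimum(q[called_mask], fdr)
    rank = np.argsort(-np.abs(d_obs), kind="stable")
    q_desc = q[rank]
    q_desc = np.minimum.accumulate(q_desc[::-1])[::-1]
    q[rank] = q_desc
    return d_obs, table, q, pi0, len(perms)
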