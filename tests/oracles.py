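"""Independent brute-force oracles used by unit and acceptance tests.

These deliberately re-derive the definitions with plain loops and exhaustive
enumeration so they share no code with the implementations they check.
"""

from itertools import product

import numpy as np


def brute_wcss_two_clusters(values):
    """Minimal Σ(Xi − Yi)² over every assignment of values to 2 groups."""
    x = list(map(float, values))
    n = len(x)
    best = float("inf")
    for assignment in product([0, 1], repeat=n):
        groups = {0: [], 1: []}
        for v, g in zip(x, assignment):
            groups[g].append(v)
        cost = 0.0
        for vals in groups.values():
            if vals:
                mu = sum(vals) / len(vals)
                cost += sum((v - mu) ** 2 for v in vals)
        best = min(best, cost)
    return best


def brute_kmeans_best_inertia(X):
    """Global minimum inertia over every non-trivial 2-partition of the rows."""
    X = np.asarray(X, float)
    n = X.shape[0]
    best = float("inf")
    for assignment in product([0, 1], repeat=n):
        if len(set(assignment)) < 2:
            continue
        cost = 0.0
        for g in (0, 1):
            rows = X[[a == g for a in assignment]]
            centre = rows.mean(axis=0)
            cost += ((rows - centre) ** 2).sum()
        best = min(best, cost)
    return best


def _plateau_local_max(a, i):
    """Is position i the first sample of an interior (plateau) local maximum?"""
    if i < 1 or a[i] <= a[i - 1]:
        return False
    j = i + 1
    while j < len(a) and a[j] == a[i]:
        j += 1
    return j < len(a) and a[j] < a[i]


def brute_gsr_scan(phasic, sig_threshold=1.5):
    """Exhaustive scan for GSR events: (trigger, peak, amplitude, significant).

    Triggers are positive interior local maxima of the first difference;
    the peak is the first following local maximum of the trace, or the last
    sample when none exists; non-positive amplitudes are dropped.
    """
    x = list(map(float, phasic))
    d = [x[i + 1] - x[i] for i in range(len(x) - 1)]
    events = []
    for i in range(len(d)):
        if d[i] > 0 and _plateau_local_max(d, i):
            peak = len(x) - 1
            for j in range(i + 1, len(x)):
                if _plateau_local_max(x, j):
                    peak = j
                    break
            if x[peak] > 0:
                events.append((i, peak, x[peak], x[peak] > sig_threshold))
    return events
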