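"""Independent reference implementations used only by the tests.

Each oracle takes a deliberately different route from the package code:
explicit Python loops, two-pass formulas, or brute-force enumeration.
"""

from __future__ import annotations

import math

import numpy as np


def isocontour_bruteforce(values, voi, fraction):
    """Brute-force enumeration of the per-VOI isocontour voxel set."""
    vmax = -math.inf
    shape = values.shape
    for i in range(shape[0]):
        for j in range(shape[1]):
            for k in range(shape[2]):
                if voi[i, j, k] and values[i, j, k] > vmax:
                    vmax = values[i, j, k]
    out = np.zeros(shape, dtype=bool)
    for i in range(shape[0]):
        for j in range(shape[1]):
            for k in range(shape[2]):
                if voi[i, j, k] and values[i, j, k] >= fraction * vmax:
                    out[i, j, k] = True
    return out


def region_metrics_tripleloop(values, voi, spacing_mm, factor, fraction):
    """Naive triple-loop region quantification.

    Returns (mean, max, volume_ml, burden, n_anatomical, n_thresholded) with
    uptake already scaled by *factor* (decay correction x SUV).
    """
    seg = isocontour_bruteforce(values, voi, fraction)
    collected = []
    vmax = -math.inf
    n_anat = 0
    shape = values.shape
    for i in range(shape[0]):
        for j in range(shape[1]):
            for k in range(shape[2]):
                if voi[i, j, k]:
                    n_anat += 1
                if seg[i, j, k]:
                    v = values[i, j, k]
                    collected.append(v)
                    if v > vmax:
                        vmax = v
    n_thr = len(collected)
    mean = math.fsum(collected) / n_thr * factor
    vmax *= factor
    vol_ml = n_thr * (spacing_mm[0] * spacing_mm[1] * spacing_mm[2] / 1000.0)
    return mean, vmax, vol_ml, mean * vol_ml, n_anat, n_thr


def pearson_twopass(x, y):
    """Two-pass covariance Pearson r (no vectorised shortcuts)."""
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    sxy = sum((a - mx) * (b - my) for a, b in zip(x, y))
    sxx = sum((a - mx) ** 2 for a in x)
    syy = sum((b - my) ** 2 for b in y)
    return sxy / math.sqrt(sxx * syy)


def _midranks(pooled):
    order = sorted(range(len(pooled)), key=lambda i: pooled[i])
    ranks = [0.0] * len(pooled)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and pooled[order[j + 1]] == pooled[order[i]]:
            j += 1
        avg = (i + j) / 2.0 + 1.0
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks


def kruskal_wallis_reference(groups):
    """Naive rank-sum H with tie correction, written from the definition."""
    pooled = [v for g in groups for v in g]
    n = len(pooled)
    ranks = _midranks(pooled)
    h = 0.0
    start = 0
    for g in groups:
        r = sum(ranks[start : start + len(g)])
        h += r * r / len(g)
        start += len(g)
    h = 12.0 / (n * (n + 1)) * h - 3 * (n + 1)
    tie = 0.0
    for v in set(pooled):
        t = pooled.count(v)
        tie += t**3 - t
    denom = 1.0 - tie / (n**3 - n)
    if denom == 0.0:
        return 0.0
    return h / denom
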