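"""Independent brute-force reference implementations used only by tests.

These deliberately avoid the package's vectorised code paths: plain loops
and explicit formulas, so that agreement is evidence rather than tautology.
"""

from __future__ import annotations

import math

import numpy as np


def bh_stepup(pvalues):
    """Benjamini-Hochberg q-values by literal step-up enumeration."""
    p = list(pvalues)
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    q = [None] * m
    running_min = math.inf
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        running_min = min(running_min, m * p[i] / rank_from_top)
        q[i] = min(running_min, 1.0)
    return q


def knn_impute(values, K):
    """Exhaustive KNN mean imputation (O(G^2 p) loops).

    Distance between genes = sum of squared differences over features
    present in both; no co-present features => infinite distance.  For a
    missing cell (g, k): average feature k over the K nearest genes that
    carry feature k, ties broken by gene index.
    """
    values = np.asarray(values, dtype=float)
    G, p = values.shape
    present = ~np.isnan(values)
    dist = np.full((G, G), np.inf)
    for i in range(G):
        for j in range(G):
            if i == j:
                continue
            s = 0.0
            any_shared = False
            for l in range(p):
                if present[i, l] and present[j, l]:
                    s += (values[i, l] - values[j, l]) ** 2
                    any_shared = True
            if any_shared:
                dist[i, j] = s
    out = values.copy()
    for g in range(G):
        for k in range(p):
            if present[g, k]:
                continue
            candidates = [(dist[g, t], t) for t in range(G)
                          if present[t, k] and math.isfinite(dist[g, t])]
            candidates.sort()
            chosen = [t for _, t in candidates[:K]]
            out[g, k] = float(np.mean([values[t, k] for t in chosen]))
    return out


def coverage_scan(gene_set, mutations):
    """Patient-by-patient scan for the covered fraction."""
    patients = sorted({m.sample for m in mutations})
    covered = 0
    for patient in patients:
        if any(m.sample == patient and m.gene in gene_set
               for m in mutations):
            covered += 1
    return covered / len(patients)


def gamma_loglik(x, shape, rate):
    """Log-likelihood of the gamma density (shape/rate form)."""
    x = np.asarray(x, dtype=float)
    return float(
        np.sum(shape * math.log(rate) - math.lgamma(shape)
               + (shape - 1) * np.log(x) - rate * x)
    )
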