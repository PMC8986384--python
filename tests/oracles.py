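"""Independent brute-force reference implementations used as test oracles.

Everything here is written as plainly as possible (explicit loops over
samples and cluster pairs) and never calls into habitatkit, so agreement is
evidence rather than tautology.
"""

import math

import numpy as np


def dist(a, b):
    return math.sqrt(sum((x - y) ** 2 for x, y in zip(a, b)))


def brute_inertia(X, labels):
    total = 0.0
    for j in sorted(set(labels)):
        members = [X[i] for i in range(len(X)) if labels[i] == j]
        c = [sum(col) / len(members) for col in zip(*members)]
        for m in members:
            total += dist(m, c) ** 2
    return total


def brute_calinski_harabasz(X, labels):
    n = len(X)
    ids = sorted(set(labels))
    k = len(ids)
    grand = [sum(col) / n for col in zip(*X)]
    B = 0.0
    W = 0.0
    for j in ids:
        members = [X[i] for i in range(n) if labels[i] == j]
        c = [sum(col) / len(members) for col in zip(*members)]
        B += len(members) * dist(c, grand) ** 2
        for m in members:
            W += dist(m, c) ** 2
    if W == 0.0:
        return math.inf
    return (B / (k - 1)) / (W / (n - k))


def brute_silhouette(X, labels):
    n = len(X)
    ids = sorted(set(labels))
    s_total = 0.0
    for i in range(n):
        same = [p for p in range(n) if labels[p] == labels[i] and p != i]
        if not same:
            continue  # singleton contributes 0
        a = sum(dist(X[i], X[p]) for p in same) / len(same)
        b = math.inf
        for j in ids:
            if j == labels[i]:
                continue
            other = [p for p in range(n) if labels[p] == j]
            b = min(b, sum(dist(X[i], X[p]) for p in other) / len(other))
        denom = max(a, b)
        s_total += 0.0 if denom == 0.0 else (b - a) / denom
    return s_total / n


def brute_separation(centroids):
    k = len(centroids)
    pairs = [(p, q) for p in range(k) for q in range(p + 1, k)]
    return sum(dist(centroids[p], centroids[q]) for p, q in pairs) / len(pairs)


def brute_davies_bouldin(X, labels):
    ids = sorted(set(labels))
    k = len(ids)
    centroids = []
    scatters = []
    for j in ids:
        members = [X[i] for i in range(len(X)) if labels[i] == j]
        c = [sum(col) / len(members) for col in zip(*members)]
        centroids.append(c)
        scatters.append(sum(dist(m, c) for m in members) / len(members))
    total = 0.0
    for p in range(k):
        worst = 0.0
        for q in range(k):
            if p == q:
                continue
            d = dist(centroids[p], centroids[q])
            num = scatters[p] + scatters[q]
            if d == 0.0:
                r = 0.0 if num == 0.0 else math.inf
            else:
                r = num / d
            worst = max(worst, r)
        total += worst
    return total / k


def brute_cluster_means(X, labels):
    return np.array([
        np.mean([X[i] for i in range(len(X)) if labels[i] == j], axis=0)
        for j in sorted(set(labels))
    ])


def brute_auc(scores, labels):
    """AUC by explicit positive-negative pair enumeration; ties count 1/2."""
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                total += 1.0
            elif p == q:
                total += 0.5
    return total / (len(pos) * len(neg))
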