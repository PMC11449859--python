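"""Independent brute-force oracles used to cross-check the implementation.

Everything here is written as plain, obviously-correct loops, deliberately
sharing no code with the package under test.
"""

import math


def brute_run_events(xs, kind):
    """All maximal strictly-monotone runs of a sequence, by direct scan."""
    xs = list(xs)
    n = len(xs)
    good = (lambda d: d > 0) if kind == "increasing" else (lambda d: d < 0)
    out = []
    i = 0
    while i < n - 1:
        if good(xs[i + 1] - xs[i]):
            j = i
            while j < n - 1 and good(xs[j + 1] - xs[j]):
                j += 1
            diffs = [xs[t + 1] - xs[t] for t in range(i, j)]
            out.append((i, j - i, sum(diffs) / len(diffs)))
            i = j
        else:
            i += 1
    return out


def brute_extremum_events(xs, kind):
    """All interior extrema (plateaus anchored at their first index)."""
    xs = list(xs)
    n = len(xs)
    out = []
    for i in range(1, n - 1):
        if xs[i] == xs[i - 1]:
            continue  # not a plateau onset
        j = i
        while j + 1 < n and xs[j + 1] == xs[i]:
            j += 1
        if j == n - 1:
            continue  # plateau runs into the endpoint: no flanking value
        if kind == "local_max" and xs[i - 1] < xs[i] > xs[j + 1]:
            out.append((i, xs[i]))
        elif kind == "local_min" and xs[i - 1] > xs[i] < xs[j + 1]:
            out.append((i, xs[i]))
    return out


def _dist(p, q):
    return math.sqrt(sum((a - b) ** 2 for a, b in zip(p, q)))


def brute_mean_silhouette(points, labels):
    """Textbook silhouette, pairwise loops; singleton clusters score 0."""
    points = [list(p) for p in points]
    labels = list(labels)
    n = len(points)
    clusters = sorted(set(labels), key=repr)
    scores = []
    for i in range(n):
        own = [j for j in range(n) if labels[j] == labels[i] and j != i]
        if not own:
            scores.append(0.0)
            continue
        a = sum(_dist(points[i], points[j]) for j in own) / len(own)
        b = math.inf
        for c in clusters:
            if c == labels[i]:
                continue
            other = [j for j in range(n) if labels[j] == c]
            b = min(b, sum(_dist(points[i], points[j]) for j in other) / len(other))
        scores.append((b - a) / max(a, b))
    return sum(scores) / n


def brute_nearest_centroid(point, centroids):
    """Index of the nearest centroid, smallest index on ties."""
    best_j, best_d = 0, math.inf
    for j, c in enumerate(centroids):
        d = _dist(point, c)
        if d < best_d:
            best_j, best_d = j, d
    return best_j
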