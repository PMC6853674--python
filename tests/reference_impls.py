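"""Naive, loop-based reference implementations used as independent oracles.

These stay deliberately simple (plain Python lists, explicit scans) and are
never imported by the package: they re-derive the same quantities through a
different code path so the tests can compare.
"""
from __future__ import annotations


def naive_smooth(length, positions, w_smooth):
    """Double-loop kernel smoothing with edge clipping."""
    h = (w_smooth - 1) // 2
    kernel = [(1 - (d / (h + 1)) ** 2) ** 2 for d in range(-h, h + 1)]
    total = sum(kernel)
    kernel = [k / total for k in kernel]
    curve = [0.0] * length
    for pos in positions:
        for d in range(-h, h + 1):
            if 0 <= pos + d < length:
                curve[pos + d] += kernel[d + h]
    return curve


def naive_clusters(curve, w_cluster):
    """Exhaustive-scan cluster detection + merging.

    Returns merged spans [(left, right, peak)] under the shared definitions:
    values compared after rounding to 1e-10; a plateau is one extremum with
    leftmost representative; raw spans partition the element, splitting each
    separating minimum plateau at its midpoint; merging closes transitively
    over consecutive raw peaks within w_cluster.
    """
    values = [round(float(v), 10) for v in curve]
    length = len(values)
    # maximal runs of equal value
    runs = []  # (first, last, value), inclusive
    start = 0
    for i in range(1, length + 1):
        if i == length or values[i] != values[start]:
            runs.append((start, i - 1, values[start]))
            start = i
    # local-maximum runs with positive value
    peak_runs = []
    for r, (_a, _b, v) in enumerate(runs):
        higher_left = r > 0 and runs[r - 1][2] > v
        higher_right = r < len(runs) - 1 and runs[r + 1][2] > v
        if v > 0 and not higher_left and not higher_right:
            peak_runs.append(r)
    if not peak_runs:
        return []
    # raw spans: split the minimum plateau between consecutive peaks
    lefts = [0]
    rights = []
    for r1, r2 in zip(peak_runs, peak_runs[1:]):
        lowest = None
        for r in range(r1 + 1, r2):
            if lowest is None or runs[r][2] < runs[lowest][2]:
                lowest = r
        a, b, _ = runs[lowest]
        cut = a + (b - a) // 2
        rights.append(cut)
        lefts.append(cut + 1)
    rights.append(length - 1)
    raw = [
        (left, right, runs[r][0], runs[r][2])
        for left, right, r in zip(lefts, rights, peak_runs)
    ]
    # transitive merge over consecutive raw peaks
    groups = [[raw[0]]]
    for span in raw[1:]:
        if span[2] - groups[-1][-1][2] <= w_cluster:
            groups[-1].append(span)
        else:
            groups.append([span])
    merged = []
    for group in groups:
        best = group[0]
        for span in group[1:]:
            if span[3] > best[3]:
                best = span
        merged.append((group[0][0], group[-1][1], best[2]))
    return merged


def naive_empirical_pvalue(observed, simulated):
    """Brute-force rank count with pseudocount."""
    count = 0
    for s in simulated:
        if s >= observed:
            count += 1
    return (1 + count) / (len(simulated) + 1)


def naive_bh(p_values):
    """Step-up Benjamini-Hochberg by explicit rank scan, in input order."""
    n = len(p_values)
    order = sorted(range(n), key=lambda i: p_values[i])
    q = [0.0] * n
    running = 1.0
    for rank in range(n, 0, -1):
        i = order[rank - 1]
        running = min(running, p_values[i] * n / rank)
        q[i] = running
    return q


def naive_interval_union(intervals):
    """Union of half-open intervals by membership enumeration."""
    covered = set()
    for start, end in intervals:
        covered.update(range(start, end))
    merged = []
    for point in sorted(covered):
        if merged and point == merged[-1][1]:
            merged[-1][1] = point + 1
        else:
            merged.append([point, point + 1])
    return [(a, b) for a, b in merged]
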