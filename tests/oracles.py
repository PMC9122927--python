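"""Independent brute-force reference implementations used as test oracles.

Deliberately naive and written without reference to the package internals:
the PUL oracle tests every contiguous window for rule satisfaction and
maximality instead of growing chains.
"""

from __future__ import annotations

SUBSTRATE = frozenset({"GH", "PL", "CE", "CBM", "SULFATASE", "SUSC", "SUSD"})
DEGRADATIVE = frozenset({"GH", "PL", "CE"})


def brute_force_puls(labels, max_gap=6, min_chain=3, min_degradative=2):
    """All maximal windows satisfying the locus rules, classified.

    ``labels`` is a sequence of sets of (category, family) pairs. Returns
    (first, last, pul_class, n_pairs, n_degradative) tuples in index order.
    """
    n = len(labels)
    cats = [{c for c, _ in l} for l in labels]
    sub = [bool(c & SUBSTRATE) for c in cats]
    deg = [bool(c & DEGRADATIVE) for c in cats]
    susc = ["SUSC" in c for c in cats]
    susd = ["SUSD" in c for c in cats]
    sub_pos = [i for i in range(n) if sub[i]]

    def window_valid(i, j):
        inside = [p for p in sub_pos if i <= p <= j]
        if not inside or inside[0] != i or inside[-1] != j:
            return False
        return all(b - a - 1 <= max_gap for a, b in zip(inside, inside[1:]))

    def window_maximal(i, j):
        left = [p for p in sub_pos if p < i]
        if left and i - left[-1] - 1 <= max_gap:
            return False
        right = [p for p in sub_pos if p > j]
        if right and right[0] - j - 1 <= max_gap:
            return False
        return True

    calls = []
    for ii, i in enumerate(sub_pos):
        for j in sub_pos[ii:]:
            if not (window_valid(i, j) and window_maximal(i, j)):
                continue
            # independent greedy left-to-right SusC/SusD pairing
            pairs = 0
            k = i
            while k < j:
                if (susc[k] and susd[k + 1]) or (susd[k] and susc[k + 1]):
                    pairs += 1
                    k += 2
                else:
                    k += 1
            n_deg = sum(deg[i:j + 1])
            n_sub = sum(sub[i:j + 1])
            if pairs >= 1 and n_deg >= min_degradative:
                calls.append((i, j, "canonical", pairs, n_deg))
            elif n_sub >= min_chain:
                calls.append((i, j, "noncanonical", pairs, n_deg))
    return calls


def naive_upgma(dist, ids):
    """Average-linkage agglomeration by direct recomputation of cluster
    means; returns the sorted list of merge heights."""
    clusters = [frozenset([i]) for i in range(len(ids))]
    heights = []
    while len(clusters) > 1:
        best = None
        for a in range(len(clusters)):
            for b in range(a + 1, len(clusters)):
                vals = [dist[x][y] for x in clusters[a] for y in clusters[b]]
                d = sum(vals) / len(vals)
                if best is None or d < best[0]:
                    best = (d, a, b)
        d, a, b = best
        heights.append(d)
        merged = clusters[a] | clusters[b]
        clusters = [c for k, c in enumerate(clusters) if k not in (a, b)]
        clusters.append(merged)
    return heights
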