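"""Independent brute-force oracles used only by the test suite.

Each oracle recomputes a quantity by enumeration or direct summation,
sharing no code with the implementation it checks.
"""

import itertools
from math import comb, inf


def fisher_p_enumeration(a, b, c, d):
    """Two-sided Fisher p by full enumeration of tables with fixed margins."""
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def table_prob(x):  # x = top-left cell
        return comb(r1, x) * comb(r2, c1 - x) / comb(n, c1)

    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    p_obs = table_prob(a)
    total = 0.0
    for x in range(lo, hi + 1):
        px = table_prob(x)
        # relative slack on the tie comparison, as in R's fisher.test
        if px <= p_obs * (1 + 1e-7):
            total += px
    return min(total, 1.0)


def binomial_tail_summation(n, k, p):
    """P(X >= k) by direct pmf summation."""
    return sum(comb(n, i) * p**i * (1 - p) ** (n - i) for i in range(k, n + 1))


def discovery_curve_enumeration(keysets):
    """Average recovered fraction over all size-m subsets, m = 1..k."""
    k = len(keysets)
    total = set().union(*keysets)
    curve = []
    for m in range(1, k + 1):
        vals = []
        for combo in itertools.combinations(range(k), m):
            u = set()
            for i in combo:
                u |= keysets[i]
            vals.append(len(u) / len(total))
        curve.append(sum(vals) / len(vals))
    return curve


def transitive_closure_clusters(junctions, window):
    """Connected components by repeated all-pairs closure (no graph library)."""

    def linked(j1, j2):
        for c1, p1 in j1.breakends:
            for c2, p2 in j2.breakends:
                if c1 == c2 and abs(p1 - p2) <= window:
                    return True
        return False

    n = len(junctions)
    label = list(range(n))
    changed = True
    while changed:
        changed = False
        for i in range(n):
            for j in range(n):
                if i != j and linked(junctions[i], junctions[j]):
                    m = min(label[i], label[j])
                    if label[i] != m or label[j] != m:
                        label[i] = label[j] = m
                        changed = True
    groups = {}
    for i, lab in enumerate(label):
        groups.setdefault(lab, set()).add(i)
    return {frozenset(g) for g in groups.values()}


def best_pair_exhaustive(pairs):
    """Argmin over (mut_median, ratio, peptide) by linear scan."""
    best = None
    best_key = (inf, inf, "")
    for p in pairs:
        r = p.ratio
        key = (p.mut_median, r if r == r else inf, p.mut_peptide)
        if key < best_key:
            best, best_key = p, key
    return best


def _quartet_topologies():
    # the three unrooted 4-leaf topologies as sister-pair splits
    return [((0, 1), (2, 3)), ((0, 2), (1, 3)), ((0, 3), (1, 2))]


def least_squares_quartet(dist):
    """Best 4-leaf topology by least-squares branch-length fit.

    ``dist`` is a 4x4 distance matrix. For split (AB)(CD) with internal
    edge, solve the 5-branch least-squares problem and return the split
    with minimal residual sum of squares.
    """
    import numpy as np

    best_split, best_rss = None, inf
    for (i, j), (k, l) in _quartet_topologies():
        # design matrix over pairs for branches (ei, ej, ek, el, em)
        pairs = [(i, j), (i, k), (i, l), (j, k), (j, l), (k, l)]
        rows = []
        y = []
        for a, b in pairs:
            row = [0.0] * 5
            row[[i, j, k, l].index(a)] = 1.0
            row[[i, j, k, l].index(b)] = 1.0
            same_side = {a, b} in ({i, j}, {k, l})
            row[4] = 0.0 if same_side else 1.0
            rows.append(row)
            y.append(dist[a][b])
        A = np.array(rows)
        yv = np.array(y)
        coef, *_ = np.linalg.lstsq(A, yv, rcond=None)
        rss = float(np.sum((A @ coef - yv) ** 2))
        if rss < best_rss - 1e-12:
            best_rss, best_split = rss, ((i, j), (k, l))
    return best_split
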