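"""Independent brute-force reference implementations used as test oracles.

These deliberately share no code with the package: plain-Python enumeration
over every candidate, kept slow and obvious.
"""

from itertools import combinations

_COMP = {"A": "T", "T": "A", "C": "G", "G": "C"}


def _pair_mismatch(seq, p, q, n, circular):
    """1 if bases at p and q do not form a Watson-Crick pair (N never pairs),
    None if either index is out of bounds (linear sequences)."""
    if circular:
        p %= n
        q %= n
    elif not (0 <= p < n and 0 <= q < n):
        return None
    a, b = seq[p], seq[q]
    if a == "N" or b == "N":
        return 1
    return 0 if _COMP[a] == b else 1


def brute_force_palindromes(seq, min_stem=6, max_stem=100, max_loop=10,
                            max_mismatch=1, circular=False):
    """All maximal inverted repeats by exhaustive enumeration.

    Enumerates every (left-arm-end, loop, stem) triple, keeps triples that
    satisfy the parameter budgets, then filters to maximal hits by explicitly
    testing the outward and inward one-pair extensions.

    Returns a sorted list of (left_start, stem, loop, mismatches), with
    left_start modulo the length for circular sequences.
    """
    seq = seq.upper()
    n = len(seq)
    valid = {}  # (a, g, s) -> mismatches ; a = left arm end (loop start)
    a_range = range(n) if circular else range(1, n)
    for a in a_range:
        for g in range(max_loop + 1):
            cum = 0
            for k in range(max_stem):
                m = _pair_mismatch(seq, a - 1 - k, a + g + k, n, circular)
                if m is None:
                    break
                cum += m
                if cum > max_mismatch:
                    break
                s = k + 1
                if circular and 2 * s + g > n:
                    break
                valid[(a, g, s)] = cum

    def extension_valid(a, g, s, mism, da, dg, ds):
        """Can the hit be extended to (a+da, g+dg, s+ds) within budgets?"""
        a2, g2, s2 = a + da, g + dg, s + ds
        if g2 < 0 or s2 > max_stem:
            return False
        if dg == 0:   # outward: new pair beyond the arms
            extra = _pair_mismatch(seq, a - 1 - s, a + g + s, n, circular)
        else:         # inward: new pair at the loop ends
            extra = _pair_mismatch(seq, a2 - 1, a2 + g2, n, circular)
        if extra is None:
            return False
        if circular and 2 * s2 + g2 > n:
            return False
        return mism + extra <= max_mismatch

    out = set()
    for (a, g, s), mism in valid.items():
        if s < min_stem:
            continue
        if extension_valid(a, g, s, mism, 0, 0, 1):          # outward
            continue
        if extension_valid(a, g, s, mism, +1, -2, 1):        # inward
            continue
        left_start = (a - s) % n if circular else a - s
        out.add((left_start, s, g, mism))
    return sorted(out)


def brute_force_gc_windows(seq, window, step, circular):
    """Naive per-window GC recount."""
    n = len(seq)
    vals = []
    starts = range(0, n, step) if circular else range(0, n - window + 1, step)
    for start in starts:
        if circular:
            w = (seq * 2)[start:start + window]
        else:
            w = seq[start:start + window]
        denom = sum(w.count(b) for b in "ACGT")
        gc = w.count("G") + w.count("C")
        vals.append((start, gc / denom if denom else None))
    return vals


def brute_force_dotplot(a, b, window=50, threshold=100, match=5, mismatch=-4):
    """Exhaustive window scoring over every (i, j)."""
    pts = set()
    for i in range(len(a) - window + 1):
        for j in range(len(b) - window + 1):
            score = 0
            for k in range(window):
                x, y = a[i + k], b[j + k]
                score += match if (x == y and x != "N") else mismatch
            if score >= threshold:
                pts.add((i, j))
    return pts


def brute_force_p_distance(row_a, row_b, missing="-.?N"):
    """Column-by-column recount under pairwise deletion."""
    compared = diff = 0
    for x, y in zip(row_a.upper(), row_b.upper()):
        if x in missing or y in missing:
            continue
        compared += 1
        if x != y:
            diff += 1
    return (diff / compared if compared else None), compared


def circular_adjacencies(units):
    """Canonical signed adjacency set of a circular signed gene order.

    ``units`` is a list of (label, sign). Each adjacency ((u,su),(v,sv)) is
    identified with its reading on the other strand ((v,-sv),(u,-su)).
    """
    adjs = set()
    k = len(units)
    for i in range(k):
        u, su = units[i]
        v, sv = units[(i + 1) % k]
        fwd = ((u, su), (v, sv))
        rev = ((v, -sv), (u, -su))
        adjs.add(min(fwd, rev))
    return adjs


def brute_force_breakpoints(units_a, units_b):
    """Adjacency-set difference between two circular signed orders."""
    shared = {u for u, _ in units_a} & {u for u, _ in units_b}
    ra = [(u, s) for u, s in units_a if u in shared]
    rb = [(u, s) for u, s in units_b if u in shared]
    return len(circular_adjacencies(ra) - circular_adjacencies(rb))


def exact_mannwhitney_p(a, b, alternative="less"):
    """Exact one-tailed Mann-Whitney p by enumerating every assignment of
    the pooled values to the two groups (mid-p not used; ties share ranks)."""
    pooled = list(a) + list(b)
    na = len(a)

    def u_stat(group_a, group_b):
        u = 0.0
        for x in group_a:
            for y in group_b:
                u += 1.0 if x > y else (0.5 if x == y else 0.0)
        return u

    obs = u_stat(a, b)
    count = total = 0
    idx = range(len(pooled))
    for comb in combinations(idx, na):
        ga = [pooled[i] for i in comb]
        gb = [pooled[i] for i in idx if i not in comb]
        u = u_stat(ga, gb)
        total += 1
        if alternative == "less" and u <= obs:
            count += 1
        elif alternative == "greater" and u >= obs:
            count += 1
    return count / total
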