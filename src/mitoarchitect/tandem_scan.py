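"""Tandem-repeat detection by k-mer period seeding and wraparound scoring.

A simplified detector sharing the classic Tandem Repeats Finder scoring
weights (match +2, mismatch -7, indel -7, minimum score 50, maximum period
500). Candidate periods are seeded by exact k-mer recurrences at distance
d <= max_period; each candidate array is scored by aligning the sequence
against itself offset by the period (so every position beyond the first
copy scores against the corresponding position one period earlier — for a
perfect array of length n and period p the score is 2*(n - p)). The
probabilistic model of the original tool is not reproduced; the match
probability is used only to accept a consensus period.
"""

from __future__ import annotations

from dataclasses import dataclass
from collections import Counter, defaultdict

import numpy as np

from .genome_io import CircularGenome

_SEED_K = 8


@dataclass(frozen=True)
class TandemParams:
    match: int = 2
    mismatch: int = -7
    indel: int = -7
    min_score: int = 50
    max_period: int = 500
    match_probability: float = 0.80
    indel_probability: float = 0.10

    def __post_init__(self):
        if self.min_score <= 0:
            raise ValueError("min_score must be positive")
        if self.max_period < 1:
            raise ValueError("max_period must be >= 1")


@dataclass(frozen=True)
class TandemRepeat:
    genome_id: str
    span: tuple[int, int]     # end may exceed genome length on wrap
    period: int
    copy_number: float
    consensus: str
    score: int

    @property
    def span_len(self) -> int:
        return self.span[1] - self.span[0]


def _align_offset_score(seq: str, start: int, end: int, period: int,
                        params: TandemParams, band: int = 8) -> int:
    """Banded global alignment score of seq[start+period:end] against
    seq[start:end-period] (the array against itself shifted by one period)."""
    a = seq[start + period:end]
    b = seq[start:end - period]
    n, m = len(a), len(b)
    if n == 0 or m == 0:
        return 0
    band = max(band, abs(n - m) + 2)
    NEG = -(10 ** 9)
    prev = np.full(2 * band + 1, NEG, dtype=np.int64)
    prev[band] = 0  # diagonal offset j - i in [-band, band]
    for i in range(1, n + 1):
        cur = np.full(2 * band + 1, NEG, dtype=np.int64)
        for off in range(-band, band + 1):
            j = i + off
            if not (0 <= j <= m):
                continue
            best = NEG
            if j > 0 and prev[off + band] > NEG:  # diagonal: a[i-1] vs b[j-1]
                x, y = a[i - 1], b[j - 1]
                sub = params.match if (x == y and x != "N") else params.mismatch
                best = prev[off + band] + sub
            if off + 1 <= band and prev[off + band + 1] > NEG:  # gap in b
                best = max(best, prev[off + band + 1] + params.indel)
            if off - 1 >= -band and cur[off - 1 + band] > NEG:  # gap in a
                best = max(best, cur[off - 1 + band] + params.indel)
            cur[off + band] = best
        prev = cur
    return int(prev[m - n + band])


def _extend_bounds(seq: str, pos: int, period: int, limit_lo: int, limit_hi: int,
                   params: TandemParams, max_errors_run: int = 3) -> tuple[int, int]:
    """Boundaries of the array supported by offset-``period`` self-similarity.

    Extends greedily around ``pos`` tolerating short error runs, then trims
    to the maximum-scoring contiguous stretch of the offset comparison
    (match/mismatch weights), i.e. local-alignment boundary semantics.
    Returned span covers the whole array including its first copy.
    """
    n = len(seq)
    lo = pos
    run = 0
    while lo - 1 >= limit_lo and lo - 1 + period < n:
        if seq[lo - 1] == seq[lo - 1 + period] and seq[lo - 1] != "N":
            lo -= 1
            run = 0
        elif run < max_errors_run:
            lo -= 1
            run += 1
        else:
            break
    lo += run
    hi = pos
    run = 0
    while hi < limit_hi and hi - period >= 0:
        if seq[hi] == seq[hi - period] and seq[hi] != "N":
            hi += 1
            run = 0
        elif run < max_errors_run:
            hi += 1
            run += 1
        else:
            break
    hi -= run
    if hi <= lo:
        return pos, pos
    # Kadane trim: best-scoring window of per-position contributions
    best = cur = 0
    best_lo = best_hi = cur_lo = lo
    for i in range(lo, hi):
        c = params.match if (seq[i] == seq[i - period] and seq[i] != "N") \
            else params.mismatch
        if cur <= 0:
            cur, cur_lo = c, i
        else:
            cur += c
        if cur > best:
            best, best_lo, best_hi = cur, cur_lo, i + 1
    return best_lo - period, best_hi


def _consensus(seq: str, start: int, end: int, period: int) -> tuple[str, float]:
    """Majority consensus per phase and its identity to the array."""
    cols: list[Counter] = [Counter() for _ in range(period)]
    for i in range(start, end):
        b = seq[i]
        if b != "N":
            cols[(i - start) % period][b] += 1
    cons = "".join(c.most_common(1)[0][0] if c else "A" for c in cols)
    matches = sum(1 for i in range(start, end) if seq[i] == cons[(i - start) % period])
    return cons, matches / (end - start)


def find_tandem_repeats(genome: CircularGenome,
                        params: TandemParams = TandemParams()) -> list[TandemRepeat]:
    """Tandem arrays with alignment score >= min_score and period <= max_period.

    Overlapping reports of one array are merged to the highest-scoring
    period (smallest period on ties, provided its consensus explains the
    array at >= match_probability identity). Circular genomes are scanned
    across the origin.
    """
    n = len(genome)
    if genome.is_circular:
        seq = genome.sequence * 2
        scan_len = min(2 * n, n + params.max_period * 4 + 200)
        seq = seq[:scan_len]
    else:
        seq = genome.sequence
        scan_len = n

    # seed: exact k-mer recurrences at distance <= max_period
    positions: dict[str, int] = {}
    seed_dists: dict[int, list[int]] = defaultdict(list)
    k = _SEED_K
    for i in range(scan_len - k + 1):
        kmer = seq[i:i + k]
        if "N" in kmer:
            continue
        j = positions.get(kmer)
        if j is not None and 1 <= i - j <= params.max_period:
            seed_dists[i - j].append(i)
        positions[kmer] = i

    candidates: list[TandemRepeat] = []
    for period, pos_list in seed_dists.items():
        # group seed positions into runs supporting the same array
        pos_list.sort()
        groups: list[list[int]] = [[pos_list[0]]]
        for p in pos_list[1:]:
            if p - groups[-1][-1] <= 2 * period:
                groups[-1].append(p)
            else:
                groups.append([p])
        for grp in groups:
            anchor = grp[0]
            lo, hi = _extend_bounds(seq, anchor, period,
                                    limit_lo=period, limit_hi=scan_len,
                                    params=params)
            if hi - lo < 2 * period - period // 2:
                continue
            cons, ident = _consensus(seq, lo, hi, period)
            if ident < params.match_probability:
                continue
            score = _align_offset_score(seq, lo, hi, period, params)
            if score < params.min_score:
                continue
            copies = (hi - lo) / period
            if copies < 1.9:
                continue
            candidates.append(TandemRepeat(genome.id, (lo, hi), period,
                                           round(copies, 1), cons, score))

    # deduplicate wrapped copies and merge overlapping reports
    if genome.is_circular:
        norm = {}
        for r in candidates:
            s = r.span[0] % n
            key = (s, r.span_len, r.period)
            if key not in norm and r.span_len <= n:
                norm[key] = TandemRepeat(r.genome_id, (s, s + r.span_len),
                                         r.period, r.copy_number, r.consensus, r.score)
        candidates = list(norm.values())

    candidates.sort(key=lambda r: (-r.score, r.period, r.span))
    kept: list[TandemRepeat] = []
    for r in candidates:
        overlapping = False
        for q in kept:
            if _spans_overlap(r.span, q.span, n, genome.is_circular):
                overlapping = True
                break
        if not overlapping:
            kept.append(r)
    kept.sort(key=lambda r: r.span)
    return kept


def _spans_overlap(a: tuple[int, int], b: tuple[int, int], n: int,
                   circular: bool) -> bool:
    if not circular:
        return a[0] < b[1] and b[0] < a[1]
    pa = {i % n for i in range(a[0], a[1])}
    pb = {i % n for i in range(b[0], b[1])}
    return bool(pa & pb)


def tandem_to_tsv(repeats, path) -> None:
    with open(path, "w") as fh:
        fh.write("genome\tstart\tend\tperiod\tcopies\tscore\tconsensus\n")
        for r in repeats:
            fh.write(f"{r.genome_id}\t{r.span[0]}\t{r.span[1]}\t{r.period}\t"
                     f"{r.copy_number}\t{r.score}\t{r.consensus}\n")
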