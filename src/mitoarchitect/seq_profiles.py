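"""Sliding-window GC profiles, dotplot point sets and p-distances.

GC is profiled in a 100-bp window with a 10-bp step, windows anchored at
position 0 of the deposited sequence and wrapping the origin on circular
genomes. Dotplots follow the classic EMBOSS dotmatcher scheme: a point at
(i, j) whenever the ungapped window of length ``window`` scores at least
``threshold`` under the standard DNA +5/-4 matrix. p-distances use
pairwise deletion: each pair of aligned rows is compared only over columns
where neither row carries a gap or missing character.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genome_io import CircularGenome

MISSING_CHARS = set("-.?N")


@dataclass(frozen=True)
class GcProfile:
    genome_id: str
    window: int
    step: int
    values: tuple[tuple[int, float], ...]  # (window start, GC fraction), NaN = undefined

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, columns=["start", "gc"])


@dataclass(frozen=True)
class DotplotParams:
    window: int = 50
    threshold: int = 100
    match: int = 5
    mismatch: int = -4

    def __post_init__(self):
        if self.threshold > self.window * self.match:
            raise ValueError("threshold unreachable: exceeds window * match score")


@dataclass(frozen=True)
class DistanceMatrix:
    labels: tuple[str, ...]
    distances: np.ndarray       # symmetric, zero diagonal, NaN where undefined
    compared_sites: np.ndarray  # per-pair non-missing column counts

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.distances, index=self.labels, columns=self.labels)


def gc_profile(genome: CircularGenome, window: int = 100, step: int = 10) -> GcProfile:
    """Per-window GC fraction (G+C over non-N bases).

    Circular genomes wrap, giving ceil(length/step) windows; linear genomes
    take every full window. An all-N window is emitted as NaN.
    """
    n = len(genome)
    if genome.is_circular:
        starts = range(0, n, step)
        seq = genome.sequence * (2 if window <= n else (window // n + 2))
    else:
        if window > n:
            raise ValueError("window exceeds linear genome length")
        starts = range(0, n - window + 1, step)
        seq = genome.sequence
    arr = np.frombuffer(seq.encode(), dtype="S1")
    is_gc = np.isin(arr, [b"G", b"C"]).astype(np.int32)
    is_acgt = np.isin(arr, [b"A", b"C", b"G", b"T"]).astype(np.int32)
    cg = np.concatenate([[0], np.cumsum(is_gc)])
    ca = np.concatenate([[0], np.cumsum(is_acgt)])
    vals = []
    for s in starts:
        denom = ca[s + window] - ca[s]
        gc = cg[s + window] - cg[s]
        vals.append((s, gc / denom if denom else float("nan")))
    return GcProfile(genome.id, window, step, tuple(vals))


def dotplot(seq_a: str, seq_b: str,
             params: DotplotParams = DotplotParams()) -> set[tuple[int, int]]:
    """Point set {(i, j)} of window matches between two sequences.

    Scored per diagonal with a sliding window sum; N never matches.
    """
    a = np.frombuffer(seq_a.upper().encode(), dtype="S1")
    b = np.frombuffer(seq_b.upper().encode(), dtype="S1")
    w = params.window
    if len(a) < w or len(b) < w:
        raise ValueError("both sequences must be at least one window long")
    pts: set[tuple[int, int]] = set()
    for off in range(-(len(a) - w), len(b) - w + 1):
        if off >= 0:
            length = min(len(a), len(b) - off)
            av, bv = a[:length], b[off:off + length]
            i0 = 0
        else:
            length = min(len(b), len(a) + off)
            av, bv = a[-off:-off + length], b[:length]
            i0 = -off
        m = ((av == bv) & (av != b"N")).astype(np.int32)
        score = np.convolve(m, np.ones(w, dtype=np.int32), mode="valid")
        score = score * params.match + (w - score) * params.mismatch
        for k in np.nonzero(score >= params.threshold)[0]:
            pts.add((i0 + int(k), i0 + int(k) + off))
    return pts


def p_distance(alignment: list[tuple[str, str]]) -> DistanceMatrix:
    """Pairwise p-distances of an alignment under pairwise deletion.

    ``alignment`` is a list of (label, aligned sequence); rows must have
    equal length. A pair with zero comparable sites gets distance NaN.
    """
    labels = tuple(lab for lab, _ in alignment)
    rows = [seq.upper() for _, seq in alignment]
    if len({len(r) for r in rows}) > 1:
        raise ValueError("aligned rows must have equal length")
    mat = np.array([np.frombuffer(r.encode(), dtype="S1") for r in rows])
    ok = ~np.isin(mat, [c.encode() for c in MISSING_CHARS])
    k = len(rows)
    d = np.zeros((k, k))
    counts = np.zeros((k, k), dtype=int)
    for i in range(k):
        for j in range(i + 1, k):
            both = ok[i] & ok[j]
            ns = int(both.sum())
            counts[i, j] = counts[j, i] = ns
            if ns == 0:
                d[i, j] = d[j, i] = float("nan")
            else:
                diff = int((mat[i][both] != mat[j][both]).sum())
                d[i, j] = d[j, i] = diff / ns
    np.fill_diagonal(counts, mat.shape[1])
    return DistanceMatrix(labels, d, counts)
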