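"""Detection and classification of small inverted repeats (SIRs).

A hit is a hairpin-forming inverted repeat: a left stem arm, a loop of
``loop_len`` unpaired bases, and a right arm that is the reverse complement
of the left arm up to ``max_mismatch`` mismatched base pairs. Only
*maximal* hits are reported: neither growing both arms outward by one base
nor growing them inward into the loop (shrinking it by two) yields another
hit within the mismatch, loop and stem-length budgets. N bases never pair;
a pair involving N counts as a mismatch.

The scan walks antidiagonals of the (implicit) self-comparison matrix:
every hit with loop midpoint at center ``c`` consists of consecutive base
pairs ``(c-1-d, c+d)`` (even loops) or ``(c-1-d, c+1+d)`` (odd loops), so
for each center and each admissible innermost depth the unique maximal
outward extension is found with one cumulative-sum pass.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from collections import Counter
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .genome_io import CircularGenome, RegionPartition

log = logging.getLogger(__name__)

_BLOCKED = 1000  # pseudo-mismatch count marking out-of-bounds pairs

_ENC = np.full(256, 4, dtype=np.int8)
for i, b in enumerate(b"ACGT"):
    _ENC[b] = i
_COMP = np.array([3, 2, 1, 0, 5], dtype=np.int8)  # A<->T, C<->G, N never pairs


@dataclass(frozen=True)
class PalindromeParams:
    """Detection parameters (defaults follow EMBOSS-palindrome conventions:
    stem length 6–100, loop up to 10, at most one mismatched pair)."""

    min_stem: int = 6
    max_stem: int = 100
    max_loop: int = 10
    max_mismatch: int = 1
    require_stem_gt_loop: bool = True

    def __post_init__(self):
        if not (1 <= self.min_stem <= self.max_stem):
            raise ValueError("need 1 <= min_stem <= max_stem")
        if self.max_loop < 0 or self.max_mismatch < 0:
            raise ValueError("max_loop and max_mismatch must be >= 0")


@dataclass(frozen=True)
class PalindromeHit:
    """One maximal inverted repeat. Intervals are 0-based half-open on the
    deposited strand; on circular genomes the right arm end may exceed the
    genome length to denote wrapping (coordinates are taken modulo length).
    """

    genome_id: str
    left_arm: tuple[int, int]
    right_arm: tuple[int, int]
    loop_len: int
    stem_len: int
    mismatches: int
    hexamer: str = ""
    region: str = ""

    @property
    def span(self) -> tuple[int, int]:
        return (self.left_arm[0], self.right_arm[1])

    @property
    def span_len(self) -> int:
        return 2 * self.stem_len + self.loop_len


def _encode(seq: str) -> np.ndarray:
    return _ENC[np.frombuffer(seq.encode(), dtype=np.uint8)]


def _family_hits(W: np.ndarray, parity: int, c_lo: int, c_hi: int,
                 params: PalindromeParams) -> list[tuple[int, int, int, int]]:
    """Maximal hits of one loop-parity family on encoded sequence W.

    Returns tuples (loop_start, stem, loop, mismatches) with coordinates in W.
    """
    if parity == 1 and params.max_loop < 1:
        return []
    depth = (params.max_loop - parity) // 2 + params.max_stem
    centers = np.arange(c_lo, c_hi)
    if centers.size == 0:
        return []
    d = np.arange(depth)
    left = centers[:, None] - 1 - d[None, :]
    right = centers[:, None] + parity + d[None, :]
    inb = (left >= 0) & (right < len(W))
    mis = np.full(left.shape, _BLOCKED, dtype=np.int32)
    li = np.clip(left, 0, len(W) - 1)
    ri = np.clip(right, 0, len(W) - 1)
    pair_ok = _COMP[W[li]] == W[ri]
    mis[inb] = np.where(pair_ok[inb], 0, 1)

    out: list[tuple[int, int, int, int]] = []
    mm = params.max_mismatch
    for d_in in range((params.max_loop - parity) // 2 + 1):
        g = 2 * d_in + parity
        B = mis[:, d_in:d_in + params.max_stem]
        G = np.cumsum(B, axis=1)
        s = (G <= mm).sum(axis=1)
        valid = s >= params.min_stem
        if not valid.any():
            continue
        m_used = np.take_along_axis(G, np.maximum(s - 1, 0)[:, None], 1)[:, 0]
        if d_in >= 1:
            inward_ok = (s + 1 <= params.max_stem) & (m_used + mis[:, d_in - 1] <= mm)
        else:
            inward_ok = np.zeros_like(valid)
        emit = valid & ~inward_ok
        for ci in np.nonzero(emit)[0]:
            stem = int(s[ci])
            loop_start = int(centers[ci]) - d_in
            out.append((loop_start, stem, g, int(m_used[ci])))
    return out


def find_palindromes(genome: CircularGenome,
                     params: PalindromeParams = PalindromeParams()) -> list[PalindromeHit]:
    """All maximal inverted-repeat hits of a genome (pre stem>loop filter).

    Circular genomes are scanned across the origin; duplicate wrapped copies
    are removed and hits whose total span would exceed the genome length are
    dropped. Hits are sorted by left-arm start, then stem length descending.
    """
    n = len(genome)
    if genome.is_circular:
        span_max = 2 * params.max_stem + params.max_loop
        reps = max(3, -(-(2 * n + 2 * span_max + 4) // n))
        W = _encode(genome.sequence * reps)
        c_lo, c_hi = n, 2 * n
    else:
        W = _encode(genome.sequence)
        c_lo, c_hi = 0, n + 1

    raw: list[tuple[int, int, int, int]] = []
    for parity in (0, 1):
        raw.extend(_family_hits(W, parity, c_lo, c_hi, params))

    hits: list[PalindromeHit] = []
    seen: set[tuple[int, int, int]] = set()
    for loop_start, stem, loop, mism in raw:
        a0 = loop_start - stem           # left arm start
        if genome.is_circular:
            if 2 * stem + loop > n:
                continue
            a0_mod = a0 % n
            key = (a0_mod, stem, loop)
            if key in seen:
                continue
            seen.add(key)
            left = (a0_mod, a0_mod + stem)
            right_start = a0_mod + stem + loop
        else:
            left = (a0, a0 + stem)
            right_start = a0 + stem + loop
        hits.append(PalindromeHit(
            genome_id=genome.id,
            left_arm=left,
            right_arm=(right_start, right_start + stem),
            loop_len=loop,
            stem_len=stem,
            mismatches=mism,
            hexamer=classify_hexamer_raw(genome, left[1]) if stem >= 6 else "",
        ))
    hits.sort(key=lambda h: (h.left_arm[0], -h.stem_len, h.loop_len))
    return hits


def filter_stem_gt_loop(hits: Iterable[PalindromeHit]) -> list[PalindromeHit]:
    """Keep hits whose stem is strictly longer than the loop."""
    return [h for h in hits if h.stem_len > h.loop_len]


def classify_hexamer_raw(genome: CircularGenome, left_arm_end: int) -> str:
    """Six loop-adjacent bases of the left (5') arm on the deposited strand."""
    hexamer = genome.fetch(left_arm_end - 6, left_arm_end)
    return "ambiguous" if "N" in hexamer else hexamer


def classify_hexamer(hit: PalindromeHit, genome: CircularGenome) -> str:
    """Hexamer family of a hit: the last six bases of the left arm (those
    adjacent to the loop), read 5'->3' on the deposited strand. Stems whose
    classifying window contains N are labelled ``ambiguous`` and excluded
    from type tables."""
    if hit.stem_len < 6:
        raise ValueError("hexamer classification needs stem_len >= 6")
    label = classify_hexamer_raw(genome, hit.left_arm[1])
    if label == "ambiguous":
        log.info("%s: hit at %s has N in classifying window", genome.id, hit.left_arm)
    return label


def call_repeat_types(hits: Sequence[PalindromeHit], threshold: int = 10) -> set[str]:
    """Hexamer classes occurring at least ``threshold`` times in one genome
    (the "repeat"-type roster). Expects post-filter hits of a single genome."""
    counts = Counter(h.hexamer for h in hits if h.hexamer and h.hexamer != "ambiguous")
    return {hx for hx, c in counts.items() if c >= threshold}


@dataclass
class SirTypeTable:
    """Per-genome SIR counts by hexamer class plus per-region statistics."""

    counts: pd.DataFrame                      # classes x genomes
    roster: dict[str, set[str]]               # repeat types called per genome
    region_stats: pd.DataFrame                # genomes x (n/bp x total/CR/IGR)
    scope: str = "union"


def assign_region(hit: PalindromeHit, partition: RegionPartition,
                  circular: bool = True) -> str:
    """coding / intergenic / spanning for the full hit span (arms + loop)."""
    return partition.region_of(hit.span[0], hit.span[0] + hit.span_len, circular)


def build_sir_tables(hits_by_genome: Mapping[str, Sequence[PalindromeHit]],
                     partitions: Mapping[str, RegionPartition] | None = None,
                     threshold: int = 10,
                     roster_scope: str = "union") -> SirTypeTable:
    """Tabulate SIR counts per hexamer class and per region.

    ``roster_scope='union'`` pools repeat types called in any genome (each
    column then reports that genome's count for every pooled class, repeat-
    level or not); ``'per_genome'`` restricts each genome's statistics to its
    own roster. Hits spanning a region boundary are tallied to the class of
    their midpoint base for the CR/IGR split.
    """
    if roster_scope not in ("union", "per_genome"):
        raise ValueError("roster_scope must be 'union' or 'per_genome'")
    partitions = partitions or {}
    roster = {gid: call_repeat_types(hits, threshold)
              for gid, hits in hits_by_genome.items()}
    union_roster = sorted(set().union(*roster.values())) if roster else []

    genomes = list(hits_by_genome)
    counts = pd.DataFrame(0, index=union_roster, columns=genomes, dtype=int)
    rows = []
    for gid, hits in hits_by_genome.items():
        per_class = Counter(h.hexamer for h in hits
                            if h.hexamer and h.hexamer != "ambiguous")
        keep = union_roster if roster_scope == "union" else sorted(roster[gid])
        for hx in keep:
            if hx in counts.index:
                counts.loc[hx, gid] = per_class.get(hx, 0)
        tallied = [h for h in hits if h.hexamer in set(keep)]
        part = partitions.get(gid)
        stat = {"n_total": len(tallied), "bp_total": sum(h.span_len for h in tallied)}
        if part is None:
            if tallied:
                log.info("%s: no region partition; total-only SIR statistics", gid)
            stat.update({k: np.nan for k in
                         ("n_coding", "n_intergenic", "bp_coding", "bp_intergenic")})
        else:
            for cls in ("coding", "intergenic"):
                sel = [h for h in tallied
                       if part.midpoint_class(h.span[0], h.span[0] + h.span_len) == cls]
                stat[f"n_{cls}"] = len(sel)
                stat[f"bp_{cls}"] = sum(h.span_len for h in sel)
        rows.append(pd.Series(stat, name=gid))
    region_stats = pd.DataFrame(rows) if rows else pd.DataFrame()
    return SirTypeTable(counts=counts, roster=roster,
                        region_stats=region_stats, scope=roster_scope)


def hits_to_bed(hits: Iterable[PalindromeHit], path) -> None:
    """BED6 of hits: name = hexamer class, score = stem length."""
    with open(path, "w") as fh:
        for h in hits:
            fh.write(f"{h.genome_id}\t{h.span[0]}\t{h.span[0] + h.span_len}\t"
                     f"{h.hexamer or '.'}\t{h.stem_len}\t+\n")
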