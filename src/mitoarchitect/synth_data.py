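"""Synthetic annotated mitogenome fixtures with planted ground truth.

Generates circular mitogenome-like sequences (20–45 kb, configurable GC)
carrying a placozoan-style gene complement (12 protein-coding genes, two
rRNAs with a fragmented large subunit, 24 tRNAs, optional unknown ORFs and
group I / II introns), with planted inverted-repeat hairpins, planted
tandem arrays and, via :func:`evolve_along_tree`, section-level
rearrangements (inversions, translocations) applied along a given tree.
Every planted element is recorded in a :class:`TruthSet` for recovery
testing.

Background sequence is i.i.d. per base at the configured GC — no codon or
dinucleotide structure. Planted elements are spaced at least
``min_spacing`` apart so detected hits cannot interact or merge.

Hairpin maximality guarantee: a planted hairpin is constructed with
non-pairing flanking bases and non-pairing loop ends, so when it carries
exactly the detector's mismatch budget it is recovered at its exact
coordinates. Hairpins planted with fewer mismatches leave extension
budget, so the detector reports a (possibly longer) containing hit of the
same loop-adjacent hexamer family.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import dendropy
import numpy as np

from .gene_order import GeneOrder, canonical_adjacency
from .genome_io import (CircularGenome, Feature, FeatureSet, revcomp,
                        write_genbank, write_fasta, DEFAULT_DROP_KINDS)

_BASES = np.frombuffer(b"ACGT", dtype="S1")
_COMP = {"A": "T", "T": "A", "C": "G", "G": "C"}


# ---------------------------------------------------------------------------
# configuration and truth containers

@dataclass(frozen=True)
class SirPlan:
    """A family of hairpins to plant: ``count`` copies with the given
    loop-adjacent stem hexamer."""
    hexamer: str
    count: int
    stem_range: tuple[int, int] = (6, 20)
    loop_range: tuple[int, int] = (0, 10)
    mismatches: int = 1
    region: str = "intergenic"        # intergenic | coding

    def __post_init__(self):
        if len(self.hexamer) != 6 or set(self.hexamer) - set("ACGT"):
            raise ValueError("hexamer must be six of A/C/G/T")
        if not (1 <= self.stem_range[0] <= self.stem_range[1] <= 100):
            raise ValueError("stem range must lie in [1, 100]")
        if self.mismatches not in (0, 1):
            raise ValueError("planted mismatches must be 0 or 1")


@dataclass(frozen=True)
class TandemPlan:
    period: int
    copies: float
    identity: float = 1.0
    region: str = "intergenic"


@dataclass(frozen=True)
class SynthConfig:
    length: int = 30000
    gc: float = 0.41
    genome_id: str = "synth"
    sir_plan: tuple[SirPlan, ...] = ()
    tandem_plan: tuple[TandemPlan, ...] = ()
    n_orfs: int = 3
    with_introns: bool = True
    min_spacing: int = 150
    seed: int = 0

    def __post_init__(self):
        if not (1000 <= self.length <= 100000):
            raise ValueError("genome length out of supported range")
        if not (0.0 < self.gc < 1.0):
            raise ValueError("gc must be a fraction in (0, 1)")


@dataclass(frozen=True)
class PlantedSir:
    left_arm: tuple[int, int]
    right_arm: tuple[int, int]
    stem_len: int
    loop_len: int
    mismatches: int
    hexamer: str
    region: str


@dataclass(frozen=True)
class PlantedTandem:
    span: tuple[int, int]
    period: int
    copies: float
    region: str


@dataclass(frozen=True)
class RearrangementEvent:
    """One event on the edge above the named node (tip or internal label)."""
    edge: str
    kind: str                      # inversion | translocation
    span: tuple[str, str]          # first and last gene unit of the block
    dest: str | None = None        # translocation: insert after this unit
    inverted: bool = False         # translocation with inversion


@dataclass
class TruthSet:
    genome_id: str
    planted_sirs: list[PlantedSir] = field(default_factory=list)
    planted_tandems: list[PlantedTandem] = field(default_factory=list)
    gene_orders: dict[str, GeneOrder] = field(default_factory=dict)
    events: list[RearrangementEvent] = field(default_factory=list)
    lost_adjacencies: dict[str, list] = field(default_factory=dict)
    gained_adjacencies: dict[str, list] = field(default_factory=dict)
    section_partition: list[tuple[str, ...]] = field(default_factory=list)


# ---------------------------------------------------------------------------
# gene layout template

_PROTEIN_GENES = {
    "nad5": 2000, "cox1": 1700, "nad4": 1450, "cob": 1150, "nad2": 1100,
    "nad1": 1000, "cox3": 850, "cox2": 800, "atp6": 750, "nad6": 600,
    "nad3": 400, "nad4L": 300,
}
_TRNAS = ("trnA", "trnR", "trnN", "trnD", "trnC", "trnQ", "trnE", "trnG",
          "trnH", "trnI", "trnL1", "trnL2", "trnK", "trnM", "trnF", "trnP",
          "trnS1", "trnS2", "trnT", "trnW", "trnY", "trnV", "trnG2", "trnM2")


def default_template(with_introns: bool = True, n_orfs: int = 3):
    """Placozoan-style block layout: (label, kind, length, strand) tuples.

    cox1 is fragmented by two group I introns, 16S into an 'a' fragment and
    an intron-split 'b' fragment (group II), mirroring the fragmentation
    patterns typical of these genomes.
    """
    blocks: list[tuple[str, str, int, str]] = []
    for i, (gene, size) in enumerate(_PROTEIN_GENES.items()):
        strand = "+" if i % 3 else "-"
        if gene == "cox1" and with_introns:
            blocks += [("cox1_e1", "protein_gene", 500, strand),
                       ("cox1_i1", "intron_groupI", 350, strand),
                       ("cox1_e2", "protein_gene", 700, strand),
                       ("cox1_i2", "intron_groupI", 300, strand),
                       ("cox1_e3", "protein_gene", 500, strand)]
        else:
            blocks.append((gene, "protein_gene", size, strand))
    blocks.append(("12S", "rRNA", 900, "+"))
    blocks.append(("16Sa", "rRNA", 1500, "+"))
    if with_introns:
        blocks += [("16Sb", "rRNA", 500, "+"),
                   ("16Sb_i1", "intron_groupII", 250, "+"),
                   ("16Sc", "rRNA", 400, "+")]
    else:
        blocks.append(("16Sb", "rRNA", 900, "+"))
    for j, t in enumerate(_TRNAS):
        blocks.append((t, "tRNA", 70, "+" if j % 2 else "-"))
    for k in range(n_orfs):
        blocks.append((f"orf{k + 1}", "orf_unknown", 350, "+"))
    return blocks


# ---------------------------------------------------------------------------
# generation

def _draw_background(rng: np.random.Generator, n: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return _BASES[rng.choice(4, size=n, p=p)]


def _non_complement(rng: np.random.Generator, base: str) -> str:
    choices = [b for b in "ACGT" if b != _COMP[base]]
    return choices[rng.integers(len(choices))]


def _other_base(rng: np.random.Generator, base: str) -> str:
    choices = [b for b in "ACGT" if b != base]
    return choices[rng.integers(len(choices))]


class _SlotPool:
    """Free placement slots per region class, enforcing minimum spacing."""

    def __init__(self, slots: dict[str, list[tuple[int, int]]], spacing: int):
        self.slots = {k: sorted(v) for k, v in slots.items()}
        self.spacing = spacing

    def place(self, rng: np.random.Generator, region: str, length: int) -> int:
        cands = [(i, s, e) for i, (s, e) in enumerate(self.slots.get(region, []))
                 if e - s >= length]
        if not cands:
            raise ValueError(
                f"overcrowded plan: no {region} slot of {length} bp available")
        i, s, e = cands[rng.integers(len(cands))]
        pos = int(rng.integers(s, e - length + 1))
        del self.slots[region][i]
        lo, hi = pos - self.spacing, pos + length + self.spacing
        keep = []
        if s < lo:
            keep.append((s, min(lo, e)))
        if hi < e:
            keep.append((hi, e))
        self.slots[region].extend(k for k in keep if k[1] - k[0] > 0)
        return pos


def _plant_hairpin(rng: np.random.Generator, arr: np.ndarray, pos: int,
                   plan: SirPlan) -> PlantedSir:
    s_lo, s_hi = plan.stem_range
    stem = int(rng.integers(s_lo, s_hi + 1))
    l_lo, l_hi = plan.loop_range
    loop_len = int(rng.integers(l_lo, min(l_hi, stem - 1) + 1))
    left = ("".join(rng.choice(list("ACGT"), size=stem - 6)) + plan.hexamer) \
        if stem > 6 else plan.hexamer
    right = list(revcomp(left))
    if plan.mismatches:
        # substitute one right-arm base to a non-pairing one
        k = int(rng.integers(stem))
        paired_left = left[stem - 1 - k]
        right[k] = _non_complement(rng, paired_left)
    loop = [str(b) for b in rng.choice(list("ACGT"), size=loop_len)]
    if loop_len >= 2 and loop[-1] == _COMP[loop[0]]:
        loop[-1] = _non_complement(rng, loop[0])
    element = left + "".join(loop) + "".join(right)
    n = len(arr)
    arr[pos:pos + len(element)] = np.frombuffer(element.encode(), dtype="S1")
    # non-pairing flanks block outward extension past the planted arms
    pre, post = (pos - 1) % n, (pos + len(element)) % n
    if arr[post] == _COMP[arr[pre].decode()].encode():
        arr[post] = _non_complement(rng, arr[pre].decode()).encode()
    return PlantedSir(
        left_arm=(pos, pos + stem),
        right_arm=(pos + stem + loop_len, pos + 2 * stem + loop_len),
        stem_len=stem, loop_len=loop_len, mismatches=plan.mismatches,
        hexamer=plan.hexamer, region=plan.region)


def _plant_tandem(rng: np.random.Generator, arr: np.ndarray, pos: int,
                  plan: TandemPlan) -> PlantedTandem:
    unit = "".join(rng.choice(list("ACGT"), size=plan.period))
    total = int(round(plan.period * plan.copies))
    text = (unit * (total // plan.period + 1))[:total]
    chars = list(text)
    n_mut = int(round((1 - plan.identity) * total))
    # never mutate the first copy so the consensus stays anchored
    if n_mut and total > plan.period:
        sites = rng.choice(np.arange(plan.period, total), size=min(n_mut, total - plan.period),
                           replace=False)
        for i in sites:
            chars[i] = _non_complement(rng, _COMP[chars[i]])  # any base != original
    arr[pos:pos + total] = np.frombuffer("".join(chars).encode(), dtype="S1")
    # boundary guards: flanking bases must not continue the period phase
    n = len(arr)
    left_phase = chars[plan.period - 1]
    if arr[(pos - 1) % n].decode() == left_phase:
        arr[(pos - 1) % n] = _other_base(rng, left_phase).encode()
    right_phase = chars[total - plan.period]
    if arr[(pos + total) % n].decode() == right_phase:
        arr[(pos + total) % n] = _other_base(rng, right_phase).encode()
    return PlantedTandem((pos, pos + total), plan.period,
                         round(total / plan.period, 1), plan.region)


def generate_genome(config: SynthConfig) -> tuple[CircularGenome, FeatureSet, TruthSet]:
    """One annotated synthetic genome plus its planted truth.

    Deterministic for a fixed config (byte-identical sequence and truth).
    Raises when the plant plan does not fit the genome with the required
    spacing, naming the first unplaceable element.
    """
    rng = np.random.default_rng(config.seed)
    arr = _draw_background(rng, config.length, config.gc)

    blocks = default_template(config.with_introns, config.n_orfs)
    gene_total = sum(b[2] for b in blocks)
    n_gaps = len(blocks)
    free = config.length - gene_total
    if free < n_gaps * 20:
        raise ValueError("genome length too small for the gene template")
    gap_sizes = _random_partition(rng, free, n_gaps, minimum=20)

    features: list[Feature] = []
    pos = 0
    coding_slots: list[tuple[int, int]] = []
    inter_slots: list[tuple[int, int]] = []
    # 75-bp slot margins guarantee >= 150 bp between plants in different
    # slots even across the shortest (70 bp tRNA) genes
    margin = max(75, config.min_spacing // 2)
    for (label, kind, size, strand), gap in zip(blocks, gap_sizes):
        if gap > 2 * margin:
            inter_slots.append((pos + margin, pos + gap - margin))
        pos += gap
        features.append(Feature(label, kind, [(pos, pos + size)], strand))
        if kind in ("protein_gene", "rRNA") and size > 2 * margin + 100:
            coding_slots.append((pos + margin, pos + size - margin))
        pos += size
    assert pos == config.length

    pool = _SlotPool({"intergenic": inter_slots, "coding": coding_slots},
                     config.min_spacing)
    truth = TruthSet(genome_id=config.genome_id)
    jobs: list[tuple[int, str, object]] = []
    for plan in config.sir_plan:
        reserved = 2 * plan.stem_range[1] + plan.loop_range[1]
        jobs.extend((reserved, "sir", plan) for _ in range(plan.count))
    for plan in config.tandem_plan:
        jobs.append((int(round(plan.period * plan.copies)), "tandem", plan))
    # place the largest elements first so big arrays get the big slots
    jobs.sort(key=lambda j: -j[0])
    for length, kind, plan in jobs:
        p = pool.place(rng, plan.region, length)
        if kind == "sir":
            truth.planted_sirs.append(_plant_hairpin(rng, arr, p, plan))
        else:
            truth.planted_tandems.append(_plant_tandem(rng, arr, p, plan))
    truth.planted_sirs.sort(key=lambda s: s.left_arm)
    truth.planted_tandems.sort(key=lambda t: t.span)

    genome = CircularGenome(config.genome_id, arr.tobytes().decode(), "circular")
    fset = FeatureSet(config.genome_id, features)
    from .genome_io import extract_gene_order
    truth.gene_orders[config.genome_id] = extract_gene_order(fset)
    return genome, fset, truth


def _random_partition(rng: np.random.Generator, total: int, parts: int,
                      minimum: int) -> list[int]:
    """Split ``total`` into ``parts`` integers >= minimum (Dirichlet-ish)."""
    spare = total - parts * minimum
    w = rng.dirichlet(np.ones(parts))
    sizes = (w * spare).astype(int)
    sizes[-1] += spare - sizes.sum()
    return [minimum + int(s) for s in sizes]


# ---------------------------------------------------------------------------
# tree-guided rearrangement

def _segments(genome: CircularGenome, features: FeatureSet):
    """Alternating (sequence, feature-or-None) segments covering the genome."""
    feats = sorted(features, key=lambda f: f.start)
    segs = []
    cursor = 0
    for f in feats:
        s, e = f.intervals[0]
        if s > cursor:
            segs.append((genome.sequence[cursor:s], None))
        segs.append((genome.sequence[s:e], f))
        cursor = e
    if cursor < len(genome):
        segs.append((genome.sequence[cursor:], None))
    return segs


def _rebuild(genome_id: str, segs) -> tuple[CircularGenome, FeatureSet]:
    seq_parts = []
    feats = []
    pos = 0
    for text, f in segs:
        if f is not None:
            feats.append(Feature(f.label, f.kind, [(pos, pos + len(text))], f.strand))
        seq_parts.append(text)
        pos += len(text)
    return (CircularGenome(genome_id, "".join(seq_parts), "circular"),
            FeatureSet(genome_id, feats))


def _unit_index(segs, drop_kinds) -> dict[str, int]:
    return {f.label: i for i, (_, f) in enumerate(segs)
            if f is not None and f.kind not in drop_kinds}


def _apply_event(segs, event: RearrangementEvent, drop_kinds):
    """Apply one event to a segment list; returns (segs, lost, gained)
    with unit-level canonical adjacency changes."""
    idx = _unit_index(segs, drop_kinds)
    for u in event.span + ((event.dest,) if event.dest else ()):
        if u is not None and u not in idx:
            raise ValueError(f"event references unknown unit {u!r}")
    i, j = idx[event.span[0]], idx[event.span[1]]
    if i > j:
        raise ValueError(f"span {event.span} is not forward-contiguous")
    block = segs[i:j + 1]

    def unit_sign(f):
        return 1 if f.strand == "+" else -1

    units = [(f.label, unit_sign(f)) for _, f in segs
             if f is not None and f.kind not in drop_kinds]
    order = GeneOrder("tmp", units)
    upos = {u: k for k, (u, _) in enumerate(units)}
    a, b = upos[event.span[0]], upos[event.span[1]]
    n = len(units)
    prev_u, next_u = units[(a - 1) % n], units[(b + 1) % n]
    first_u, last_u = units[a], units[b]

    def flip(u):
        return (u[0], -u[1])

    lost = {canonical_adjacency(prev_u, first_u),
            canonical_adjacency(last_u, next_u)}
    inv_block = [(revcomp(t), None if f is None else
                  Feature(f.label, f.kind, f.intervals,
                          "-" if f.strand == "+" else "+"))
                 for t, f in reversed(block)]
    if event.kind == "inversion":
        new_segs = segs[:i] + inv_block + segs[j + 1:]
        gained = {canonical_adjacency(prev_u, flip(last_u)),
                  canonical_adjacency(flip(first_u), next_u)}
    elif event.kind == "translocation":
        remaining = segs[:i] + segs[j + 1:]
        moved = inv_block if event.inverted else block
        ridx = _unit_index(remaining, drop_kinds)
        d = ridx[event.dest]
        new_segs = remaining[:d + 1] + moved + remaining[d + 1:]
        # the destination's old forward adjacency is broken too
        runits = [(f.label, unit_sign(f)) for _, f in remaining
                  if f is not None and f.kind not in drop_kinds]
        rpos = {u: k for k, (u, _) in enumerate(runits)}
        dpos = rpos[event.dest]
        dest_u, after_u = runits[dpos], runits[(dpos + 1) % len(runits)]
        lost = {canonical_adjacency(prev_u, first_u),
                canonical_adjacency(last_u, next_u),
                canonical_adjacency(dest_u, after_u)}
        head = flip(last_u) if event.inverted else first_u
        tail = flip(first_u) if event.inverted else last_u
        gained = {canonical_adjacency(prev_u, next_u),
                  canonical_adjacency(dest_u, head),
                  canonical_adjacency(tail, after_u)}
    else:
        raise ValueError(f"unknown event kind {event.kind!r}")
    return new_segs, lost, gained


def evolve_along_tree(genome: CircularGenome, features: FeatureSet,
                      tree: str | dendropy.Tree,
                      plan: list[RearrangementEvent],
                      drop_kinds=DEFAULT_DROP_KINDS):
    """Apply rearrangement events along a tree; returns tip genomes + truth.

    Each tip carries the composition of the events on its root-to-tip path
    (sequence segments move and flip together with their annotations).
    Event plans must be non-interacting: every broken adjacency must still
    be a root adjacency and no created adjacency may recreate one, so the
    expected conserved-section partition is the root order cut at every
    broken adjacency. Multiple events on one edge apply in plan order.

    Returns ``(cohort, truth)`` where cohort maps tip label ->
    (CircularGenome, FeatureSet).
    """
    if isinstance(tree, dendropy.Tree):
        t = tree
    else:
        t = dendropy.Tree.get(data=tree, schema="newick")
    by_edge: dict[str, list[RearrangementEvent]] = {}
    for ev in plan:
        by_edge.setdefault(ev.edge, []).append(ev)

    from .genome_io import extract_gene_order
    root_order = extract_gene_order(features, drop_kinds)
    root_adjs = root_order.adjacencies()
    truth = TruthSet(genome_id=genome.id, events=list(plan))
    all_lost: set = set()

    def node_name(node):
        if node.taxon is not None:
            return node.taxon.label
        return node.label

    cohort: dict[str, tuple[CircularGenome, FeatureSet]] = {}

    def walk(node, segs):
        name = node_name(node)
        lost_here: set = set()
        gained_here: set = set()
        for ev in by_edge.get(name, []) if name else []:
            segs, lost, gained = _apply_event(segs, ev, drop_kinds)
            lost_here |= lost
            gained_here |= gained
        if name and (lost_here or gained_here):
            bad = lost_here - root_adjs
            if bad:
                raise ValueError(f"interacting plan: {bad} not root adjacencies")
            if gained_here & root_adjs:
                raise ValueError("interacting plan: event recreates a root adjacency")
            truth.lost_adjacencies[name] = sorted(lost_here)
            truth.gained_adjacencies[name] = sorted(gained_here)
            all_lost.update(lost_here)
        if node.is_leaf():
            g, fs = _rebuild(name, segs)
            cohort[name] = (g, fs)
            truth.gene_orders[name] = extract_gene_order(fs, drop_kinds)
        else:
            for child in node.child_nodes():
                walk(child, list(segs))

    walk(t.seed_node, _segments(genome, features))

    # expected section partition: root circular order cut at broken adjacencies
    units = list(root_order.units)
    n = len(units)
    cut_after = []
    for i in range(n):
        adj = canonical_adjacency(units[i], units[(i + 1) % n])
        if adj in all_lost:
            cut_after.append(i)
    if not cut_after:
        truth.section_partition = [tuple(u for u, _ in units)]
    else:
        parts = []
        starts = [(i + 1) % n for i in cut_after]
        for k, s in enumerate(sorted(starts)):
            e = sorted(starts)[(k + 1) % len(starts)]
            block = []
            i = s
            while True:
                block.append(units[i][0])
                if i == (e - 1) % n:
                    break
                i = (i + 1) % n
            parts.append(tuple(block))
        truth.section_partition = parts
    return cohort, truth


# ---------------------------------------------------------------------------
# truth writers / readers (plain-text round trip)

def write_truth(truth: TruthSet, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    with open(outdir / "sirs.bed", "w") as fh:
        for p in truth.planted_sirs:
            fh.write(f"{truth.genome_id}\t{p.left_arm[0]}\t{p.right_arm[1]}\t"
                     f"{p.hexamer}\t{p.stem_len}\t{p.loop_len}\t{p.mismatches}\t"
                     f"{p.region}\n")
    with open(outdir / "tandems.tsv", "w") as fh:
        fh.write("genome\tstart\tend\tperiod\tcopies\tregion\n")
        for p in truth.planted_tandems:
            fh.write(f"{truth.genome_id}\t{p.span[0]}\t{p.span[1]}\t{p.period}\t"
                     f"{p.copies}\t{p.region}\n")
    with open(outdir / "orders.tsv", "w") as fh:
        fh.write("genome\tposition\tlabel\tstrand\n")
        for gid, order in truth.gene_orders.items():
            for i, (u, s) in enumerate(order.units):
                fh.write(f"{gid}\t{i}\t{u}\t{'+' if s > 0 else '-'}\n")
    with open(outdir / "events.json", "w") as fh:
        json.dump([{"edge": e.edge, "kind": e.kind, "span": list(e.span),
                    "dest": e.dest, "inverted": e.inverted}
                   for e in truth.events], fh, indent=1)


def read_truth(genome_id: str, outdir: str | Path) -> TruthSet:
    outdir = Path(outdir)
    truth = TruthSet(genome_id=genome_id)
    with open(outdir / "sirs.bed") as fh:
        for line in fh:
            gid, s, e, hexamer, stem, loop, mism, region = line.split("\t")
            s, e, stem, loop, mism = map(int, (s, e, stem, loop, mism))
            truth.planted_sirs.append(PlantedSir(
                (s, s + stem), (e - stem, e), stem, loop, mism,
                hexamer, region.strip()))
    with open(outdir / "tandems.tsv") as fh:
        next(fh)
        for line in fh:
            gid, s, e, period, copies, region = line.split("\t")
            truth.planted_tandems.append(PlantedTandem(
                (int(s), int(e)), int(period), float(copies), region.strip()))
    orders: dict[str, list] = {}
    with open(outdir / "orders.tsv") as fh:
        next(fh)
        for line in fh:
            gid, _pos, label, strand = line.split("\t")
            orders.setdefault(gid, []).append((label, 1 if strand.strip() == "+" else -1))
    for gid, units in orders.items():
        truth.gene_orders[gid] = GeneOrder(gid, units)
    with open(outdir / "events.json") as fh:
        truth.events = [RearrangementEvent(d["edge"], d["kind"], tuple(d["span"]),
                                           d["dest"], d["inverted"])
                        for d in json.load(fh)]
    return truth


def write_cohort(cohort, outdir: str | Path) -> None:
    """GenBank + FASTA per genome for a cohort mapping id -> (genome, features)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for gid, (g, fs) in cohort.items():
        write_genbank(g, fs, outdir / f"{gid}.gb")
        write_fasta([g], outdir / f"{gid}.fasta")
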