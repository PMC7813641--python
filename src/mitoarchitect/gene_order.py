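"""Signed circular gene orders, conserved-section merging and breakpoints.

Two gene units are merged into one section when they are adjacent with the
same relative orientation in *every* analysed genome that contains both
(signed-reversal equivalence: ``+a,+b`` in one genome matches ``-b,-a`` in
another). Connected components of that conservation relation are the
sections; units private to a single genome become singleton sections.
Breakpoint distance counts canonical signed adjacencies of one circular
order that are absent from another. Rearrangement events are mapped onto a
given tree by Fitch-style presence sets of adjacencies — a descriptive
change list per edge, not an ancestral-genome reconstruction.
"""

from __future__ import annotations

import logging
import string
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import dendropy

log = logging.getLogger(__name__)

SignedUnit = tuple[str, int]           # (label, +1/-1)
Adjacency = tuple[SignedUnit, SignedUnit]


@dataclass(frozen=True)
class GeneOrder:
    """A circular signed arrangement of gene units."""

    genome_id: str
    units: tuple[SignedUnit, ...]

    def __init__(self, genome_id: str, units: Iterable[SignedUnit]):
        units = tuple((str(u), int(s)) for u, s in units)
        labels = [u for u, _ in units]
        if len(set(labels)) != len(labels):
            raise ValueError(f"{genome_id}: duplicate unit labels in gene order")
        if any(s not in (1, -1) for _, s in units):
            raise ValueError("orientations must be +1 or -1")
        object.__setattr__(self, "genome_id", genome_id)
        object.__setattr__(self, "units", units)

    def __len__(self) -> int:
        return len(self.units)

    @property
    def labels(self) -> set[str]:
        return {u for u, _ in self.units}

    def restrict(self, keep: set[str]) -> "GeneOrder":
        return GeneOrder(self.genome_id,
                         [(u, s) for u, s in self.units if u in keep])

    def rotate(self, k: int) -> "GeneOrder":
        n = len(self.units)
        k %= n
        return GeneOrder(self.genome_id, self.units[k:] + self.units[:k])

    def reflect(self) -> "GeneOrder":
        """The same circle read on the opposite strand."""
        return GeneOrder(self.genome_id, [(u, -s) for u, s in reversed(self.units)])

    def adjacencies(self) -> set[Adjacency]:
        """Canonical signed circular adjacency set."""
        out = set()
        n = len(self.units)
        for i in range(n):
            out.add(canonical_adjacency(self.units[i], self.units[(i + 1) % n]))
        return out

    def neighbor_map(self) -> dict[str, list[tuple[str, Adjacency]]]:
        nb: dict[str, list[tuple[str, Adjacency]]] = {u: [] for u, _ in self.units}
        n = len(self.units)
        for i in range(n):
            u, v = self.units[i], self.units[(i + 1) % n]
            adj = canonical_adjacency(u, v)
            nb[u[0]].append((v[0], adj))
            nb[v[0]].append((u[0], adj))
        return nb


def canonical_adjacency(u: SignedUnit, v: SignedUnit) -> Adjacency:
    """Identify an oriented adjacency with its opposite-strand reading."""
    fwd = (u, v)
    rev = ((v[0], -v[1]), (u[0], -u[1]))
    return min(fwd, rev)


def cyclic_signed_equal(a: GeneOrder, b: GeneOrder) -> bool:
    """Equality up to rotation and whole-circle reflection with sign flip."""
    if len(a) != len(b) or a.labels != b.labels:
        return False
    n = len(a)
    if n == 0:
        return True
    for cand in (b, b.reflect()):
        for k in range(n):
            if cand.rotate(k).units == a.units:
                return True
    return False


@dataclass
class Section:
    """A maximal conserved run of gene units across the analysed cohort."""

    id: str
    members: tuple[SignedUnit, ...]            # reference orientation
    presence: set[str] = field(default_factory=set)
    orientation: dict[str, int] = field(default_factory=dict)
    broken_cycle: bool = False                 # fully conserved circle, arbitrary break

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(u for u, _ in self.members)


def _section_label(i: int) -> str:
    letters = string.ascii_uppercase
    out = ""
    i += 1
    while i:
        i, r = divmod(i - 1, 26)
        out = letters[r] + out
    return out


def merge_sections(orders: Sequence[GeneOrder]) -> list[Section]:
    """Merge units adjacent with conserved orientation in every genome.

    Requires at least two orders. Sections are labelled A, B, C, ... by the
    genomic position of their first member in the first input genome (units
    absent from it follow, in input order of the genome introducing them).
    """
    if len(orders) < 2:
        raise ValueError("need at least two gene orders")
    containing: dict[str, list[GeneOrder]] = {}
    for o in orders:
        for u in o.labels:
            containing.setdefault(u, []).append(o)

    neighbor_maps = {o.genome_id: o.neighbor_map() for o in orders}

    def conserved_link(u: str, v: str) -> Adjacency | None:
        # units private to a single genome are singleton sections by fiat
        if len(containing[u]) < 2 or len(containing[v]) < 2:
            return None
        shared = [o for o in containing[u] if v in o.labels]
        if not shared:
            return None
        adjs = []
        for o in shared:
            cand = [adj for w, adj in neighbor_maps[o.genome_id][u] if w == v]
            if not cand:
                return None
            adjs.append(cand[0])
        first = adjs[0]
        if all(a == first for a in adjs):
            return first
        log.info("inconsistent orientation between %s and %s; left unmerged", u, v)
        return None

    links: dict[str, list[tuple[str, Adjacency]]] = {u: [] for u in containing}
    seen_pairs = set()
    for o in orders:
        n = len(o.units)
        for i in range(n):
            u, v = o.units[i][0], o.units[(i + 1) % n][0]
            if u == v:
                continue
            key = frozenset((u, v))
            if key in seen_pairs:
                continue
            seen_pairs.add(key)
            adj = conserved_link(u, v)
            if adj is not None:
                links[u].append((v, adj))
                links[v].append((u, adj))

    # components of the link graph
    comps: list[list[str]] = []
    unvisited = set(containing)
    while unvisited:
        start = unvisited.pop()
        comp = [start]
        stack = [start]
        while stack:
            x = stack.pop()
            for y, _ in links[x]:
                if y in unvisited:
                    unvisited.remove(y)
                    comp.append(y)
                    stack.append(y)
        comps.append(comp)

    sections: list[Section] = []
    for comp in comps:
        sec = _build_section(comp, links, orders)
        if sec is not None:
            sections.append(sec)
        else:  # malformed component: demote to singletons
            for u in comp:
                sections.append(_build_section([u], {u: []}, orders))

    # deterministic labelling by position in the first genome, then input order
    first = orders[0]
    pos_in_first = {u: i for i, (u, _) in enumerate(first.units)}
    intro_order = {}
    for rank_g, o in enumerate(orders):
        for i, (u, _) in enumerate(o.units):
            intro_order.setdefault(u, (rank_g, i))

    def sort_key(sec: Section):
        anchors = [pos_in_first[u] for u in sec.labels if u in pos_in_first]
        if anchors:
            return (0, min(anchors))
        return (1,) + min(intro_order[u] for u in sec.labels)

    sections.sort(key=sort_key)
    for i, sec in enumerate(sections):
        sec.id = _section_label(i)
    return sections


def _build_section(comp: list[str], links, orders: Sequence[GeneOrder]) -> Section | None:
    degrees = {u: len(links.get(u, [])) for u in comp}
    if any(d > 2 for d in degrees.values()):
        log.warning("ambiguous linkage in component %s", comp)
        return None
    ends = sorted(u for u, d in degrees.items() if d <= 1)
    broken_cycle = not ends
    if broken_cycle:
        # fully conserved circle: break at the member earliest in the first
        # genome containing any member (declared arbitrary break)
        anchor = next(o for o in orders if set(comp) & o.labels)
        start = next(u for u, _ in anchor.units if u in comp)
    else:
        start = ends[0]

    # walk the chain, propagating signs through the canonical adjacencies
    chain: list[SignedUnit] = [(start, 1)]
    prev = None
    cur, cur_sign = start, 1
    while True:
        nxt = [(v, adj) for v, adj in links.get(cur, []) if v != prev]
        if broken_cycle and len(chain) == len(comp):
            break
        if not nxt:
            break
        v, adj = nxt[0]
        matched = False
        for reading in (adj, ((adj[1][0], -adj[1][1]), (adj[0][0], -adj[0][1]))):
            (x, sx), (y, sy) = reading
            if x == cur and (len(chain) == 1 or sx == cur_sign):
                if len(chain) == 1:
                    chain[0] = (cur, sx)  # start sign comes from the adjacency
                chain.append((v, sy))
                matched = True
                break
        if not matched:
            log.warning("sign-inconsistent walk in component %s", comp)
            return None
        prev, cur = cur, v
        cur_sign = chain[-1][1]
        if len(chain) > len(comp):
            log.warning("cyclic walk overrun in component %s", comp)
            return None

    if len(chain) != len(comp):
        log.warning("component %s is not a simple chain", comp)
        return None

    presence = {o.genome_id for o in orders if set(comp) & o.labels}

    # orient the reference so the first genome containing the section reads +
    anchor = next(o for o in orders if set(comp) & o.labels)
    orient_anchor = _orientation_in(anchor, chain)
    if orient_anchor == -1:
        chain = [(u, -s) for u, s in reversed(chain)]
    members = tuple(chain)

    sec = Section("?", members, presence=presence, broken_cycle=broken_cycle)
    for o in orders:
        if o.genome_id in presence:
            sec.orientation[o.genome_id] = _orientation_in(o, list(members))
    return sec


def _orientation_in(order: GeneOrder, chain: list[SignedUnit]) -> int:
    """+1 / -1: does the genome carry the chain forward or signed-reversed?"""
    sub = [u for u in chain if u[0] in order.labels]
    if not sub:
        return 1
    if len(sub) == 1:
        sign_in_genome = dict(order.units)[sub[0][0]]
        return 1 if sign_in_genome == sub[0][1] else -1
    # find the first chain member in the genome and check its oriented sign
    genome_signs = dict(order.units)
    u, s_ref = sub[0]
    return 1 if genome_signs[u] == s_ref else -1


def section_order(order: GeneOrder, sections: Sequence[Section]) -> list[tuple[str, int]]:
    """Rewrite a genome as a signed circular sequence of section ids.

    Raises if a section's members are not contiguous in this genome (which
    would violate the merge invariant).
    """
    unit_to_sec: dict[str, Section] = {}
    for sec in sections:
        for u, _ in sec.members:
            unit_to_sec[u] = sec
    units = [u for u in order.units if u[0] in unit_to_sec]
    if not units:
        return []
    n = len(units)
    sec_ids = [unit_to_sec[u[0]].id for u in units]
    # rotate so index 0 starts a new section run
    start = 0
    if n > 1 and all(s == sec_ids[0] for s in sec_ids):
        start = 0
    else:
        for i in range(n):
            if sec_ids[i] != sec_ids[i - 1]:
                start = i
                break
    units = units[start:] + units[:start]
    sec_ids = sec_ids[start:] + sec_ids[:start]

    out: list[tuple[str, int]] = []
    i = 0
    seen_ids = set()
    while i < n:
        j = i
        while j < n and sec_ids[j] == sec_ids[i]:
            j += 1
        sec = unit_to_sec[units[i][0]]
        if sec.id in seen_ids:
            raise ValueError(
                f"{order.genome_id}: section {sec.id} members are not contiguous")
        seen_ids.add(sec.id)
        run = units[i:j]
        expected = [m for m in sec.members if m[0] in order.labels]
        rev = [(u, -s) for u, s in reversed(expected)]
        if run == expected:
            out.append((sec.id, 1))
        elif run == rev:
            out.append((sec.id, -1))
        else:
            raise ValueError(
                f"{order.genome_id}: section {sec.id} order {run} matches neither "
                f"{expected} nor its signed reversal")
        i = j
    return out


def breakpoint_distance(order_a: GeneOrder, order_b: GeneOrder) -> int:
    """Number of signed circular adjacencies of A absent from B (restricted
    to the shared unit set)."""
    shared = order_a.labels & order_b.labels
    if len(shared) < 2:
        raise ValueError("breakpoint distance needs at least two shared units")
    a = order_a.restrict(shared)
    b = order_b.restrict(shared)
    return len(a.adjacencies() - b.adjacencies())


@dataclass(frozen=True)
class EdgeChanges:
    """Adjacency changes assigned to one tree edge (descendant-side clade)."""

    clade: frozenset[str]
    gained: frozenset[Adjacency]
    lost: frozenset[Adjacency]
    at_polytomy: bool = False


def map_events_on_tree(orders: Mapping[str, GeneOrder] | Sequence[GeneOrder],
                       tree: str | dendropy.Tree) -> list[EdgeChanges]:
    """Assign adjacency gains/losses to tree edges by all-or-none consensus.

    For each edge, an adjacency is *gained* if present in every descendant
    tip and absent from every other tip, *lost* in the converse case. This
    is a descriptive change list (Fitch-style presence sets), not an
    ancestral reconstruction; with non-overlapping single events per edge it
    recovers each event's breakpoints on the true edge.
    """
    if not isinstance(orders, Mapping):
        orders = {o.genome_id: o for o in orders}
    if isinstance(tree, dendropy.Tree):
        t = tree
    else:
        src = {"data": tree, "schema": "newick"}
        t = dendropy.Tree.get(**src)
    tip_ids = {leaf.taxon.label for leaf in t.leaf_node_iter()}
    missing = tip_ids - set(orders)
    if missing:
        raise ValueError(f"tree tips without gene orders: {sorted(missing)}")

    adj = {gid: orders[gid].adjacencies() for gid in tip_ids}
    out: list[EdgeChanges] = []
    for node in t.preorder_node_iter():
        if node.parent_node is None or node.is_leaf() and node.taxon is None:
            continue
        clade = frozenset(leaf.taxon.label for leaf in node.leaf_iter())
        rest = tip_ids - clade
        if not rest:
            continue
        inter_d = set.intersection(*(adj[g] for g in clade))
        union_d = set.union(*(adj[g] for g in clade))
        inter_r = set.intersection(*(adj[g] for g in rest))
        union_r = set.union(*(adj[g] for g in rest))
        gained = frozenset(inter_d - union_r)
        lost = frozenset(inter_r - union_d)
        if gained or lost:
            poly = node.parent_node is not None and len(node.parent_node.child_nodes()) > 2
            out.append(EdgeChanges(clade, gained, lost, at_polytomy=poly))
    return out
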