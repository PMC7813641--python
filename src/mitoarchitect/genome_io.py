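"""Genome and annotation I/O with circular-coordinate support.

Internal convention: 0-based half-open intervals on the deposited strand.
GenBank locations (1-based inclusive) are converted on read and write.
Features that wrap the origin of a circular genome are represented as one
feature holding two intervals, ``[(start, L), (0, end)]``, kept in
transcription-independent genomic wrapping order.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import CompoundLocation, SeqFeature, SimpleLocation
from Bio.SeqRecord import SeqRecord

log = logging.getLogger(__name__)

ALPHABET = set("ACGTN")

#: feature kinds recognised downstream
KINDS = (
    "protein_gene",
    "rRNA",
    "tRNA",
    "orf_unknown",
    "intron_groupI",
    "intron_groupII",
    "exon",
    "other",
)

#: kinds counted as coding in region partitions
CODING_KINDS = frozenset({"protein_gene", "rRNA", "tRNA", "orf_unknown", "exon"})

#: kinds excluded from gene orders by default
DEFAULT_DROP_KINDS = frozenset({"orf_unknown", "intron_groupI", "intron_groupII"})

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement over the {A,C,G,T,N} alphabet."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class CircularGenome:
    """A DNA sequence with declared topology.

    Coordinates on circular genomes wrap modulo ``len(genome)``.
    """

    id: str
    sequence: str
    topology: str = "circular"

    def __post_init__(self):
        seq = self.sequence.upper()
        if len(seq) < 1:
            raise ValueError(f"{self.id}: empty sequence")
        bad = set(seq) - ALPHABET
        if bad:
            raise ValueError(f"{self.id}: characters outside A/C/G/T/N: {sorted(bad)}")
        if self.topology not in ("circular", "linear"):
            raise ValueError(f"{self.id}: topology must be circular or linear")
        object.__setattr__(self, "sequence", seq)

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def is_circular(self) -> bool:
        return self.topology == "circular"

    def fetch(self, start: int, end: int) -> str:
        """Sequence of [start, end); wraps the origin on circular genomes."""
        n = len(self.sequence)
        if self.is_circular:
            length = end - start
            start %= n
            end = start + length
            if end <= n:
                return self.sequence[start:end]
            return (self.sequence * ((end // n) + 1))[start:end]
        if not (0 <= start <= end <= n):
            raise IndexError(f"[{start},{end}) outside linear genome of length {n}")
        return self.sequence[start:end]

    def gc_fraction(self) -> float:
        """G+C over non-N bases of the whole genome."""
        counts = {b: self.sequence.count(b) for b in "ACGT"}
        denom = sum(counts.values())
        return (counts["G"] + counts["C"]) / denom if denom else float("nan")


@dataclass
class Feature:
    """A typed, stranded (possibly multi-interval) annotation."""

    label: str
    kind: str
    intervals: list[tuple[int, int]]
    strand: str = "+"

    def __post_init__(self):
        if self.kind not in KINDS:
            raise ValueError(f"unknown feature kind {self.kind!r}")
        if self.strand not in "+-":
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        for s, e in self.intervals:
            if not (0 <= s < e):
                raise ValueError(f"{self.label}: bad interval ({s},{e})")

    @property
    def length(self) -> int:
        return sum(e - s for s, e in self.intervals)

    @property
    def start(self) -> int:
        """Genomic anchor: start of the first interval in wrapping order."""
        return self.intervals[0][0]

    @property
    def wraps(self) -> bool:
        return len(self.intervals) == 2 and self.intervals[0][1] > self.intervals[1][0] \
            and self.intervals[1][0] == 0


@dataclass
class FeatureSet:
    genome_id: str
    features: list[Feature] = field(default_factory=list)

    def __iter__(self):
        return iter(self.features)

    def __len__(self):
        return len(self.features)

    def of_kind(self, *kinds: str) -> list[Feature]:
        ks = set(kinds)
        return [f for f in self.features if f.kind in ks]


@dataclass
class RegionPartition:
    """Coding / intergenic / intron classification of every base.

    Introns are reported separately but counted inside the intergenic total,
    so ``coding + intergenic == genome length`` always holds.
    ``labels`` holds one code per base: 0 intergenic, 1 coding, 2 group I
    intron, 3 group II intron (introns are a sub-class of intergenic).
    """

    genome_id: str
    labels: np.ndarray
    sizes: dict[str, int]
    gc: dict[str, float]

    CODES = {"intergenic": 0, "coding": 1, "intronI": 2, "intronII": 3}

    def region_of(self, start: int, end: int, circular: bool = True) -> str:
        """Coarse class of a span: coding, intergenic or spanning."""
        n = len(self.labels)
        idx = np.arange(start, end) % n if circular else np.arange(start, end)
        coding = self.labels[idx] == 1
        if coding.all():
            return "coding"
        if not coding.any():
            return "intergenic"
        return "spanning"

    def midpoint_class(self, start: int, end: int) -> str:
        """CR/IGR class of the midpoint base (used for spanning elements)."""
        mid = (start + (end - start) // 2) % len(self.labels)
        return "coding" if self.labels[mid] == 1 else "intergenic"


# ---------------------------------------------------------------------------
# GenBank / FASTA reading

_GB_KIND_MAP = {"rRNA": "rRNA", "tRNA": "tRNA"}


def _classify_gb_feature(feat: SeqFeature) -> str | None:
    qual = feat.qualifiers
    note = " ".join(qual.get("note", [])).lower()
    if feat.type in _GB_KIND_MAP:
        return _GB_KIND_MAP[feat.type]
    if feat.type == "CDS":
        label = _gb_label(feat).lower()
        product = " ".join(qual.get("product", [])).lower()
        if label.startswith("orf") or "orf_unknown" in note or "hypothetical" in product:
            return "orf_unknown"
        return "protein_gene"
    if feat.type == "intron":
        if "group ii" in note or "group_ii" in note:
            return "intron_groupII"
        if "group i" in note or "group_i" in note:
            return "intron_groupI"
        return "other"
    if feat.type == "exon":
        return "exon"
    if feat.type in ("gene", "source", "misc_feature", "D-loop", "repeat_region"):
        return None  # container / non-typed features are skipped silently
    return "other"


def _gb_label(feat: SeqFeature) -> str:
    for key in ("gene", "label", "standard_name", "product", "locus_tag"):
        if key in feat.qualifiers:
            return str(feat.qualifiers[key][0]).replace(" ", "_")
    return feat.type


def _location_to_intervals(feat: SeqFeature) -> tuple[list[tuple[int, int]], str]:
    loc = feat.location
    strand = "-" if (loc.strand or 1) < 0 else "+"
    parts = loc.parts if isinstance(loc, CompoundLocation) else [loc]
    ivals = [(int(p.start), int(p.end)) for p in parts]
    # Biopython lists parts in transcription order; store genomic wrapping order
    if strand == "-":
        ivals = ivals[::-1]
    return ivals, strand


def read_genbank(path: str | Path) -> tuple[CircularGenome, FeatureSet]:
    """Read one GenBank flat file into internal coordinates.

    Missing sequence is a hard error; an unparseable feature is skipped with
    a warning.
    """
    record = SeqIO.read(str(path), "genbank")
    seq = str(record.seq).upper()
    if not seq or set(seq) == {"N"} and len(seq) == 0:
        raise ValueError(f"{path}: record has no sequence")
    topology = record.annotations.get("topology", "linear")
    genome = CircularGenome(record.id or record.name, seq, topology)
    features: list[Feature] = []
    for feat in record.features:
        kind = _classify_gb_feature(feat)
        if kind is None:
            continue
        try:
            ivals, strand = _location_to_intervals(feat)
            features.append(Feature(_gb_label(feat), kind, ivals, strand))
        except Exception as exc:  # malformed location: warn and skip
            warnings.warn(f"{path}: skipping feature {feat.type}: {exc}")
            log.warning("skipping feature %s in %s: %s", feat.type, path, exc)
    return genome, FeatureSet(genome.id, features)


def read_fasta(path: str | Path, topology: str = "circular") -> list[CircularGenome]:
    return [
        CircularGenome(rec.id, str(rec.seq).upper(), topology)
        for rec in SeqIO.parse(str(path), "fasta")
    ]


def write_fasta(genomes: Iterable[CircularGenome], path: str | Path) -> None:
    records = [SeqRecord(Seq(g.sequence), id=g.id, description=g.topology) for g in genomes]
    SeqIO.write(records, str(path), "fasta")


_KIND_TO_GB = {
    "protein_gene": "CDS",
    "orf_unknown": "CDS",
    "rRNA": "rRNA",
    "tRNA": "tRNA",
    "intron_groupI": "intron",
    "intron_groupII": "intron",
    "exon": "exon",
    "other": "misc_feature",
}


def write_genbank(genome: CircularGenome, features: FeatureSet, path: str | Path) -> None:
    """Write internal objects as a GenBank flat file (round-trips with read_genbank)."""
    record = SeqRecord(Seq(genome.sequence), id=genome.id, name=genome.id[:16],
                       description="synthetic mitogenome",
                       annotations={"topology": genome.topology,
                                    "molecule_type": "DNA"})
    for f in features:
        strand = -1 if f.strand == "-" else 1
        ivals = f.intervals if strand == 1 else f.intervals[::-1]
        parts = [SimpleLocation(s, e, strand) for s, e in ivals]
        loc = parts[0] if len(parts) == 1 else CompoundLocation(parts)
        qual = {"gene": [f.label]}
        if f.kind == "orf_unknown":
            qual["note"] = ["orf_unknown"]
            qual["product"] = ["hypothetical protein"]
        elif f.kind == "intron_groupI":
            qual["note"] = ["group I intron"]
        elif f.kind == "intron_groupII":
            qual["note"] = ["group II intron"]
        record.features.append(SeqFeature(loc, type=_KIND_TO_GB[f.kind], qualifiers=qual))
    SeqIO.write([record], str(path), "genbank")


# ---------------------------------------------------------------------------
# Region partitioning

def partition_regions(genome: CircularGenome, features: FeatureSet) -> RegionPartition:
    """Classify every base as coding / intergenic, introns sub-classified.

    Precedence: coding > intron > intergenic. Intron bases are carved out of
    the intergenic class for reporting but remain inside its total, so that
    coding + intergenic sizes sum to the genome length.
    """
    n = len(genome)
    labels = np.zeros(n, dtype=np.int8)
    arr = np.frombuffer(genome.sequence.encode(), dtype="S1")

    def mark(feats: Sequence[Feature], code: int, only_if: int | None = 0):
        for f in feats:
            for s, e in f.intervals:
                if e > n:
                    raise ValueError(f"{f.label}: interval ({s},{e}) beyond genome")
                span = labels[s:e]
                if only_if is None:
                    span[:] = code
                else:
                    span[span == only_if] = code

    mark(features.of_kind(*CODING_KINDS), 1, only_if=None)
    mark(features.of_kind("intron_groupI"), 2, only_if=0)
    mark(features.of_kind("intron_groupII"), 3, only_if=0)
    overl = sum(
        int((labels[s:e] == 1).sum())
        for f in features.of_kind("intron_groupI", "intron_groupII")
        for s, e in f.intervals
    )
    if overl:
        log.info("%s: %d intron bases overlap coding features (coding wins)", genome.id, overl)

    def gc_of(mask: np.ndarray) -> float:
        sel = arr[mask]
        denom = int(np.isin(sel, [b"A", b"C", b"G", b"T"]).sum())
        if denom == 0:
            return float("nan")
        gc = int(np.isin(sel, [b"G", b"C"]).sum())
        return gc / denom

    coding_mask = labels == 1
    inter_mask = ~coding_mask  # introns included
    sizes = {
        "coding": int(coding_mask.sum()),
        "intergenic": int(inter_mask.sum()),
        "intronI": int((labels == 2).sum()),
        "intronII": int((labels == 3).sum()),
    }
    gc = {
        "coding": gc_of(coding_mask),
        "intergenic": gc_of(inter_mask),
        "intronI": gc_of(labels == 2),
        "intronII": gc_of(labels == 3),
        "total": genome.gc_fraction(),
    }
    return RegionPartition(genome.id, labels, sizes, gc)


def write_partition_bed(partition: RegionPartition, path: str | Path) -> None:
    """BED (0-based half-open) runs of each region class."""
    labels = partition.labels
    names = {v: k for k, v in RegionPartition.CODES.items()}
    with open(path, "w") as fh:
        start = 0
        for i in range(1, len(labels) + 1):
            if i == len(labels) or labels[i] != labels[start]:
                fh.write(f"{partition.genome_id}\t{start}\t{i}\t{names[int(labels[start])]}\n")
                start = i


# ---------------------------------------------------------------------------
# Gene orders

def extract_gene_order(features: FeatureSet,
                       drop_kinds: frozenset[str] | set[str] = DEFAULT_DROP_KINDS):
    """Signed circular list of gene units in genomic order.

    Features of ``drop_kinds`` are excluded; duplicate labels are suffixed
    ``_1, _2, ...`` deterministically in genomic order. Returns a
    :class:`mitoarchitect.gene_order.GeneOrder`.
    """
    from .gene_order import GeneOrder  # local import avoids a cycle

    kept = sorted((f for f in features if f.kind not in drop_kinds),
                  key=lambda f: (f.start, f.label))
    labels = [f.label for f in kept]
    counts: dict[str, int] = {}
    units = []
    for f in kept:
        lab = f.label
        if labels.count(lab) > 1:
            counts[lab] = counts.get(lab, 0) + 1
            new = f"{lab}_{counts[lab]}"
            log.info("%s: duplicate label %s -> %s", features.genome_id, lab, new)
            lab = new
        units.append((lab, 1 if f.strand == "+" else -1))
    return GeneOrder(features.genome_id, units)
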