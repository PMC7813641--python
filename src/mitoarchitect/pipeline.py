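"""One-command cohort analysis: scan, partition, merge, summarize.

``run_cohort`` chains the stages — genome/annotation reading, SIR and
tandem scans, GC profiling, gene-order section merging (for cohorts of at
least two genomes) and the per-genome summary table with Average / S.D.
footer rows — and writes every table plus a JSON run manifest recording
parameters and input checksums. The analysis path is fully deterministic,
so reruns on identical inputs produce byte-identical tables.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .gene_order import map_events_on_tree, merge_sections, section_order
from .genome_io import (partition_regions, extract_gene_order, read_genbank,
                        write_partition_bed)
from .seq_profiles import gc_profile
from .sir_scan import (PalindromeParams, build_sir_tables, filter_stem_gt_loop,
                       find_palindromes, hits_to_bed)
from .summary_stats import cohort_stats, summarize_genome, summary_table
from .tandem_scan import TandemParams, find_tandem_repeats, tandem_to_tsv

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    genomes: list[str]
    outdir: str = "mitoarchitect_out"
    tree: str | None = None
    sir_params: PalindromeParams = field(default_factory=PalindromeParams)
    tandem_params: TandemParams = field(default_factory=TandemParams)
    sir_threshold: int = 10
    roster_scope: str = "union"
    gc_window: int = 100
    gc_step: int = 10
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {"genomes", "outdir", "tree", "sir_threshold", "roster_scope",
                 "gc_window", "gc_step", "seed"}
        kwargs = {k: v for k, v in raw.items() if k in known}
        if "sir_params" in raw:
            kwargs["sir_params"] = PalindromeParams(**raw["sir_params"])
        if "tandem_params" in raw:
            kwargs["tandem_params"] = TandemParams(**raw["tandem_params"])
        cfg = cls(**kwargs)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        if not self.genomes:
            raise ValueError("at least one genome is required")
        for p in self.genomes:
            if not Path(p).exists():
                raise FileNotFoundError(p)
        if self.tree and not Path(self.tree).exists():
            raise FileNotFoundError(self.tree)


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def run_cohort(config: RunConfig) -> Path:
    """Execute the full analysis; returns the output directory.

    Any stage failure aborts with an exception naming the stage and input.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)

    genomes, featuresets, partitions = {}, {}, {}
    for path in config.genomes:
        try:
            g, fs = read_genbank(path)
        except Exception as exc:
            raise RuntimeError(f"genome_io failed on {path}: {exc}") from exc
        genomes[g.id] = g
        featuresets[g.id] = fs
        partitions[g.id] = partition_regions(g, fs)
        write_partition_bed(partitions[g.id], out / f"{g.id}.regions.bed")

    hits_by_genome = {}
    for gid, g in genomes.items():
        try:
            hits = filter_stem_gt_loop(find_palindromes(g, config.sir_params))
        except Exception as exc:
            raise RuntimeError(f"sir_scan failed on {gid}: {exc}") from exc
        hits_by_genome[gid] = hits
        hits_to_bed(hits, out / f"{gid}.sirs.bed")
    sir_table = build_sir_tables(hits_by_genome, partitions,
                                 threshold=config.sir_threshold,
                                 roster_scope=config.roster_scope)
    sir_table.counts.to_csv(out / "sir_type_counts.tsv", sep="\t")

    tandems = {}
    for gid, g in genomes.items():
        try:
            tandems[gid] = find_tandem_repeats(g, config.tandem_params)
        except Exception as exc:
            raise RuntimeError(f"tandem_scan failed on {gid}: {exc}") from exc
        tandem_to_tsv(tandems[gid], out / f"{gid}.tandems.tsv")

    for gid, g in genomes.items():
        prof = gc_profile(g, config.gc_window, config.gc_step)
        prof.to_frame().to_csv(out / f"{gid}.gc.tsv", sep="\t", index=False)

    if len(genomes) >= 2:
        orders = [extract_gene_order(featuresets[gid]) for gid in genomes]
        try:
            sections = merge_sections(orders)
        except Exception as exc:
            raise RuntimeError(f"gene_order failed: {exc}") from exc
        with open(out / "sections.tsv", "w") as fh:
            fh.write("section\tmembers\tpresence\n")
            for sec in sections:
                members = ",".join(f"{'+' if s > 0 else '-'}{u}" for u, s in sec.members)
                fh.write(f"{sec.id}\t{members}\t{','.join(sorted(sec.presence))}\n")
        with open(out / "section_orders.tsv", "w") as fh:
            for o in orders:
                so = section_order(o, sections)
                fh.write(o.genome_id + "\t" +
                         " ".join(f"{'+' if s > 0 else '-'}{sid}" for sid, s in so) + "\n")
        if config.tree:
            tree_text = Path(config.tree).read_text()
            changes = map_events_on_tree({o.genome_id: o for o in orders}, tree_text)
            with open(out / "edge_changes.json", "w") as fh:
                json.dump([{"clade": sorted(c.clade),
                            "gained": [repr(a) for a in sorted(c.gained)],
                            "lost": [repr(a) for a in sorted(c.lost)],
                            "at_polytomy": c.at_polytomy} for c in changes],
                          fh, indent=1)
    else:
        log.info("single genome: gene_order stage skipped")

    roster_hits = {
        gid: [h for h in hits
              if h.hexamer in (set().union(*sir_table.roster.values())
                               if config.roster_scope == "union"
                               else sir_table.roster[gid])]
        for gid, hits in hits_by_genome.items()
    }
    summaries = [summarize_genome(genomes[gid], partitions[gid],
                                  roster_hits[gid], tandems[gid])
                 for gid in genomes]
    table = summary_table(summaries)
    stats = cohort_stats(table)
    footer = stats.rename(index={"mean": "Average", "sd": "S.D."})
    pd.concat([table, footer]).to_csv(out / "summary.tsv", sep="\t",
                                      float_format="%.2f")

    manifest = {
        "version": __version__,
        "parameters": {
            "sir": vars(config.sir_params).copy(),
            "tandem": vars(config.tandem_params).copy(),
            "sir_threshold": config.sir_threshold,
            "roster_scope": config.roster_scope,
            "gc_window": config.gc_window,
            "gc_step": config.gc_step,
            "seed": config.seed,
        },
        "inputs": {str(p): _sha256(p) for p in config.genomes},
        "genomes": sorted(genomes),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return out
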