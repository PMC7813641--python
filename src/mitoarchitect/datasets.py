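"""Bundled reference tables.

``placozoan_characteristics`` returns the published per-genome summary of
the 14 placozoan mitogenomes (three genera: *Polyplacotoma*, *Trichoplax*
and *Hoilungia*; GenBank accessions in the ``accession`` column): whole-
genome, coding-region and intergenic-region sizes and GC percentages,
intron totals, and small-inverted-repeat / tandem-repeat counts and sizes
split by region. Useful as the reference input for cohort descriptive
statistics without downloading the records.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

SIZE_COLUMNS = ["genome_bp", "coding_bp", "igr_bp", "intronI_bp", "intronII_bp"]
GC_COLUMNS = ["genome_gc", "coding_gc", "igr_gc"]


def placozoan_characteristics() -> pd.DataFrame:
    """The 14-row placozoan mitogenome characteristics table."""
    ref = resources.files("mitoarchitect").joinpath("data/placozoan_mitogenomes.tsv")
    with resources.as_file(ref) as path:
        df = pd.read_csv(path, sep="\t")
    return df.set_index("haplotype")
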