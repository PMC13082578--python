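"""CAGE 5'-tag counting inside the predefined promoter windows.

CAGE (Cap Analysis of Gene Expression) reads mark capped transcript 5' ends,
so tag positions measure initiation directly.  To keep coordinates matched
with the RNA-seq-derived quantifications, tags are counted inside the same
promoter windows built by the annotation module — no de-novo TSS clustering.
Counting is strand-matched by default because CAGE libraries are stranded
and bidirectional promoters would otherwise be conflated.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import pandas as pd
from intervaltree import IntervalTree

from .annotation import PromoterMap
from .quantify import PromoterCountMatrix, TableFormatError


@dataclass
class CageTag:
    """One TSS position with its aggregated tag count."""

    chrom: str
    pos: int  # 1-based position of the read 5' end
    strand: str
    count: int

    def __post_init__(self) -> None:
        if self.count < 1:
            raise ValueError("tag count must be >= 1")


def parse_cage_table(path: str | Path) -> list[CageTag]:
    """Read tags from a 4-column TSV (chrom, pos, strand, count) or BED6.

    BED6 rows are single-base intervals with the score column holding the
    tag count; the 1-based position is the interval end.
    """
    tags: list[CageTag] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track")):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) == 4:
                chrom, pos, strand, count = f[0], int(f[1]), f[2], int(f[3])
            elif len(f) >= 6:
                chrom, strand, count = f[0], f[5], int(float(f[4]))
                start, end = int(f[1]), int(f[2])
                if end - start != 1:
                    raise TableFormatError(
                        f"line {lineno}: CAGE BED intervals must be single-base"
                    )
                pos = end
            else:
                raise TableFormatError(f"line {lineno}: expected 4 (TSV) or 6 (BED) columns")
            tags.append(CageTag(chrom=chrom, pos=pos, strand=strand, count=count))
    return tags


def count_cage(
    pmap: PromoterMap,
    tags: dict[str, Sequence[CageTag]],
    stranded: bool = True,
) -> PromoterCountMatrix:
    """Sum tag counts falling inside each retained promoter's window.

    A tag inside overlapping windows of several promoters counts toward each
    (windows of internal/overlapping-flagged promoters are ignored).  Library
    size is the total tag count of the sample.
    """
    promoters = pmap.quantifiable()
    trees: dict[str, IntervalTree] = {}
    for p in promoters:
        tree = trees.setdefault(p.chrom, IntervalTree())
        tree.addi(p.window[0], p.window[1] + 1, p)
    pids = [p.promoter_id for p in promoters]
    samples = list(tags)
    counts = pd.DataFrame(0.0, index=pids, columns=samples)
    library = pd.Series(0.0, index=samples)
    for sample, sample_tags in tags.items():
        for tag in sample_tags:
            library[sample] += tag.count
            tree = trees.get(tag.chrom)
            if tree is None:
                continue
            for hit in tree[tag.pos]:
                p = hit.data
                if stranded and tag.strand != p.strand:
                    continue
                counts.at[p.promoter_id, sample] += tag.count
    return PromoterCountMatrix(
        method="cage",
        counts=counts,
        library_size=library,
        metadata={
            "library_size_definition": "total tag count",
            "stranded": stranded,
        },
    )
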