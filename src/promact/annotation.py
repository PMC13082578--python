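"""Promoter annotation: build a promoter–transcript–gene map from a GTF.

A *promoter* here is a group of transcript first exons of one gene merged by
single-linkage overlap, anchored at the 5'-most transcription start site (TSS)
of the group.  Promoters whose TSS falls inside a non-first exon of another
transcript are flagged *internal* (elongation signal from an upstream promoter
would be misread as initiation); promoters whose first-exon footprint overlaps
a different gene's promoter on the same strand are flagged *overlapping*.
Flagged promoters are kept in the map for auditing but excluded from
downstream quantification.

All coordinates are 1-based inclusive genomic positions, as in GTF.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from intervaltree import IntervalTree

logger = logging.getLogger(__name__)

Interval = tuple[int, int]

_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')


class GtfFormatError(ValueError):
    """A GTF line violates the format contract (bad coordinates, mixed strands...)."""


@dataclass
class TranscriptModel:
    """One transcript with exons ordered in transcription direction.

    ``exons[0]`` is the 5'-most exon in transcript orientation: for "-" strand
    transcripts it is the exon with the *largest* genomic coordinates.
    """

    transcript_id: str
    gene_id: str
    gene_biotype: str
    chrom: str
    strand: str
    exons: list[Interval]

    @property
    def tss(self) -> int:
        """First transcribed base: start of the first exon in transcription direction."""
        first = self.exons[0]
        return first[0] if self.strand == "+" else first[1]

    @property
    def first_exon(self) -> Interval:
        return self.exons[0]

    @property
    def first_intron(self) -> Interval | None:
        """First intron (1-based first/last intronic base), or None if single-exon."""
        if len(self.exons) < 2:
            return None
        e1, e2 = self.exons[0], self.exons[1]
        if self.strand == "+":
            return (e1[1] + 1, e2[0] - 1)
        return (e2[1] + 1, e1[0] - 1)

    @property
    def length(self) -> int:
        """Annotated transcript length: sum of exon widths in bp."""
        return sum(e - s + 1 for s, e in self.exons)


@dataclass
class Promoter:
    promoter_id: int
    gene_id: str
    chrom: str
    strand: str
    tss: int
    rank_5to3: int
    transcript_ids: set[str]
    first_exon_union: list[Interval]
    member_first_exons: list[Interval]
    first_introns: set[Interval]
    internal: bool = False
    overlapping: bool = False
    window: Interval = (0, 0)

    @property
    def intronless(self) -> bool:
        return not self.first_introns

    @property
    def excluded(self) -> bool:
        """True when the promoter must not be quantified (internal or overlapping)."""
        return self.internal or self.overlapping


@dataclass
class PromoterMap:
    """The unified promoter–transcript–gene map reused by every downstream step."""

    promoters: list[Promoter]
    transcript_to_promoter: dict[str, int]
    gene_to_promoters: dict[str, list[int]]
    transcript_length: dict[str, int] = field(default_factory=dict)
    window_up: int = 500
    window_down: int = 500

    def __post_init__(self) -> None:
        self._by_id = {p.promoter_id: p for p in self.promoters}

    def promoter(self, promoter_id: int) -> Promoter:
        return self._by_id[promoter_id]

    def quantifiable(self) -> list[Promoter]:
        """Promoters retained for quantification (neither internal nor overlapping)."""
        return [p for p in self.promoters if not p.excluded]

    def intron_index(self) -> dict[tuple[str, int, int], list[Promoter]]:
        """(chrom, first intronic base, last intronic base) -> promoters owning it."""
        index: dict[tuple[str, int, int], list[Promoter]] = {}
        for p in self.promoters:
            for s, e in p.first_introns:
                index.setdefault((p.chrom, s, e), []).append(p)
        return index

    # ------------------------------------------------------------------ I/O
    def to_tsv(self, path: str | Path) -> None:
        cols = (
            "promoter_id\tgene_id\tchrom\tstrand\ttss\trank_5to3\tn_transcripts"
            "\ttranscript_ids\tintronless\tinternal\toverlapping\twindow_start\twindow_end\n"
        )
        with open(path, "w") as fh:
            fh.write(cols)
            for p in sorted(self.promoters, key=lambda q: q.promoter_id):
                fh.write(
                    f"{p.promoter_id}\t{p.gene_id}\t{p.chrom}\t{p.strand}\t{p.tss}"
                    f"\t{p.rank_5to3}\t{len(p.transcript_ids)}"
                    f"\t{','.join(sorted(p.transcript_ids))}"
                    f"\t{p.intronless}\t{p.internal}\t{p.overlapping}"
                    f"\t{p.window[0]}\t{p.window[1]}\n"
                )

    def windows_to_bed(self, path: str | Path) -> None:
        """Promoter windows as BED6 (0-based half-open per the BED standard)."""
        with open(path, "w") as fh:
            for p in sorted(self.promoters, key=lambda q: q.promoter_id):
                fh.write(
                    f"{p.chrom}\t{p.window[0] - 1}\t{p.window[1]}"
                    f"\tpromoter_{p.promoter_id}\t0\t{p.strand}\n"
                )

    def to_json_dict(self) -> dict:
        """Full lossless serialisation (used by the CLI to chain stages)."""
        return {
            "window_up": self.window_up,
            "window_down": self.window_down,
            "transcript_length": self.transcript_length,
            "transcript_to_promoter": self.transcript_to_promoter,
            "promoters": [
                {
                    "promoter_id": p.promoter_id,
                    "gene_id": p.gene_id,
                    "chrom": p.chrom,
                    "strand": p.strand,
                    "tss": p.tss,
                    "rank_5to3": p.rank_5to3,
                    "transcript_ids": sorted(p.transcript_ids),
                    "first_exon_union": [list(iv) for iv in p.first_exon_union],
                    "member_first_exons": [list(iv) for iv in p.member_first_exons],
                    "first_introns": sorted([list(iv) for iv in p.first_introns]),
                    "internal": p.internal,
                    "overlapping": p.overlapping,
                    "window": list(p.window),
                }
                for p in self.promoters
            ],
        }

    @classmethod
    def from_json_dict(cls, d: dict) -> "PromoterMap":
        promoters = [
            Promoter(
                promoter_id=q["promoter_id"],
                gene_id=q["gene_id"],
                chrom=q["chrom"],
                strand=q["strand"],
                tss=q["tss"],
                rank_5to3=q["rank_5to3"],
                transcript_ids=set(q["transcript_ids"]),
                first_exon_union=[tuple(iv) for iv in q["first_exon_union"]],
                member_first_exons=[tuple(iv) for iv in q["member_first_exons"]],
                first_introns={tuple(iv) for iv in q["first_introns"]},
                internal=q["internal"],
                overlapping=q["overlapping"],
                window=tuple(q["window"]),
            )
            for q in d["promoters"]
        ]
        gene_to_promoters: dict[str, list[int]] = {}
        for p in promoters:
            gene_to_promoters.setdefault(p.gene_id, []).append(p.promoter_id)
        return cls(
            promoters=promoters,
            transcript_to_promoter=dict(d["transcript_to_promoter"]),
            gene_to_promoters=gene_to_promoters,
            transcript_length=dict(d["transcript_length"]),
            window_up=d["window_up"],
            window_down=d["window_down"],
        )


# --------------------------------------------------------------------- parse


def _parse_attributes(raw: str) -> dict[str, str]:
    return dict(_ATTR_RE.findall(raw))


def parse_gtf(
    path: str | Path,
    feature_filter: set[str] | None = frozenset({"protein_coding"}),
    primary_chroms: set[str] | None = None,
) -> list[TranscriptModel]:
    """Parse a GTF into transcript models, keeping one model per transcript.

    Parameters
    ----------
    path
        GTF file (Ensembl or GENCODE attribute dialect; both ``gene_biotype``
        and ``gene_type`` attribute keys are accepted).
    feature_filter
        Gene biotypes to keep; ``None`` keeps everything.  Default keeps only
        protein-coding genes, which have the most reliably annotated
        transcript structures.
    primary_chroms
        Optional whitelist of chromosome names (drops unplaced scaffolds).
    """
    per_transcript: dict[str, TranscriptModel] = {}
    n_dropped = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 9:
                raise GtfFormatError(f"line {lineno}: expected 9 tab-separated fields")
            chrom, _source, feature, start_s, end_s, _score, strand, _frame, attrs = fields
            if feature != "exon":
                continue
            start, end = int(start_s), int(end_s)
            if end < start:
                raise GtfFormatError(f"line {lineno}: exon end {end} < start {start}")
            a = _parse_attributes(attrs)
            biotype = a.get("gene_biotype", a.get("gene_type", ""))
            tid = a.get("transcript_id")
            gid = a.get("gene_id")
            if tid is None or gid is None:
                raise GtfFormatError(f"line {lineno}: missing gene_id/transcript_id")
            if feature_filter is not None and biotype not in feature_filter:
                n_dropped += 1
                continue
            if primary_chroms is not None and chrom not in primary_chroms:
                n_dropped += 1
                continue
            model = per_transcript.get(tid)
            if model is None:
                per_transcript[tid] = TranscriptModel(
                    transcript_id=tid, gene_id=gid, gene_biotype=biotype,
                    chrom=chrom, strand=strand, exons=[(start, end)],
                )
            else:
                if model.chrom != chrom or model.strand != strand:
                    raise GtfFormatError(
                        f"line {lineno}: transcript {tid} has exons on mixed "
                        "chromosomes or strands"
                    )
                model.exons.append((start, end))
    if n_dropped:
        logger.info("parse_gtf: dropped %d exon records failing filters", n_dropped)
    out = []
    for model in per_transcript.values():
        model.exons.sort(key=lambda iv: iv[0], reverse=(model.strand == "-"))
        out.append(model)
    return out


# ------------------------------------------------------------ promoter map


def _merge_overlapping(intervals: Iterable[Interval]) -> list[Interval]:
    """Union of 1-based inclusive intervals as disjoint sorted intervals."""
    ivs = sorted(intervals)
    merged: list[list[int]] = []
    for s, e in ivs:
        if merged and s <= merged[-1][1] + 1:  # overlapping or base-adjacent
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def build_promoter_map(
    transcripts: Sequence[TranscriptModel],
    window_up: int = 500,
    window_down: int = 500,
) -> PromoterMap:
    """Group transcripts into promoters by single-linkage first-exon overlap.

    Within a gene (and strand), transcripts whose first exons share at least
    one base are merged transitively into one promoter.  The promoter TSS is
    the 5'-most transcript start of the group; ranks number the gene's
    promoters 1..k in transcription direction (5' to 3').  The counting
    window is ``[tss - window_up, tss + window_down]`` in transcription
    orientation, clipped at position 1.
    """
    if window_up < 0 or window_down < 0:
        raise ValueError("window_up and window_down must be >= 0")
    if not transcripts:
        logger.warning("build_promoter_map: empty transcript list")
        return PromoterMap([], {}, {}, {}, window_up, window_down)

    by_gene: dict[tuple[str, str, str], list[TranscriptModel]] = {}
    for t in transcripts:
        by_gene.setdefault((t.gene_id, t.chrom, t.strand), []).append(t)

    promoters: list[Promoter] = []
    transcript_to_promoter: dict[str, int] = {}
    gene_to_promoters: dict[str, list[int]] = {}
    transcript_length = {t.transcript_id: t.length for t in transcripts}
    next_id = 1

    for (gene_id, chrom, strand), members in sorted(by_gene.items()):
        # single-linkage: sort first exons by start; a chain extends while the
        # next start is inside the running envelope
        members = sorted(members, key=lambda t: t.first_exon)
        groups: list[list[TranscriptModel]] = []
        envelope_end = None
        for t in members:
            s, e = t.first_exon
            if envelope_end is not None and s <= envelope_end:
                groups[-1].append(t)
                envelope_end = max(envelope_end, e)
            else:
                groups.append([t])
                envelope_end = e
        group_infos = []
        for g in groups:
            if strand == "+":
                tss = min(t.first_exon[0] for t in g)
            else:
                tss = max(t.first_exon[1] for t in g)
            group_infos.append((tss, g))
        # rank 5'->3' in transcription direction
        group_infos.sort(key=lambda x: x[0], reverse=(strand == "-"))
        for rank, (tss, g) in enumerate(group_infos, start=1):
            if strand == "+":
                window = (max(1, tss - window_up), tss + window_down)
            else:
                window = (max(1, tss - window_down), tss + window_up)
            introns = {t.first_intron for t in g if t.first_intron is not None}
            p = Promoter(
                promoter_id=next_id,
                gene_id=gene_id,
                chrom=chrom,
                strand=strand,
                tss=tss,
                rank_5to3=rank,
                transcript_ids={t.transcript_id for t in g},
                first_exon_union=_merge_overlapping(t.first_exon for t in g),
                member_first_exons=sorted({t.first_exon for t in g}),
                first_introns=introns,
                window=window,
            )
            promoters.append(p)
            gene_to_promoters.setdefault(gene_id, []).append(next_id)
            for t in g:
                transcript_to_promoter[t.transcript_id] = next_id
            next_id += 1

    return PromoterMap(
        promoters, transcript_to_promoter, gene_to_promoters,
        transcript_length, window_up, window_down,
    )


def flag_internal(pmap: PromoterMap, transcripts: Sequence[TranscriptModel]) -> PromoterMap:
    """Flag promoters whose TSS falls inside a downstream (non-first) exon.

    A promoter is internal when its TSS position lies within any exon that is
    not the first exon of its own transcript, for any transcript that is not a
    member of the promoter.  Reads from elongation of the upstream promoter
    would otherwise be misattributed to initiation here.  Flags are set
    in place; flagged promoters stay in the map.
    """
    trees: dict[str, IntervalTree] = {}
    for t in transcripts:
        tree = trees.setdefault(t.chrom, IntervalTree())
        for s, e in t.exons[1:]:  # exon index >= 2 in transcription order
            tree.addi(s, e + 1, t.transcript_id)
    for p in pmap.promoters:
        tree = trees.get(p.chrom)
        if tree is None:
            p.internal = False
            continue
        hits = tree[p.tss]
        p.internal = any(hit.data not in p.transcript_ids for hit in hits)
    return pmap


def flag_overlapping(pmap: PromoterMap) -> PromoterMap:
    """Flag promoter pairs of *different* genes whose first-exon unions overlap.

    Overlap requires the same strand and at least one shared base; both
    members of a pair are flagged.
    """
    trees: dict[tuple[str, str], IntervalTree] = {}
    for p in pmap.promoters:
        tree = trees.setdefault((p.chrom, p.strand), IntervalTree())
        for s, e in p.first_exon_union:
            tree.addi(s, e + 1, p)
    for p in pmap.promoters:
        p.overlapping = False
    for p in pmap.promoters:
        tree = trees[(p.chrom, p.strand)]
        for s, e in p.first_exon_union:
            for hit in tree.overlap(s, e + 1):
                other: Promoter = hit.data
                if other.gene_id != p.gene_id:
                    p.overlapping = True
                    other.overlapping = True
    return pmap
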