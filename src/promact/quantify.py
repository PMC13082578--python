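"""Promoter quantification: junction-, transcript- and first-exon-based counting.

Three complementary strategies produce promoter x sample raw-count matrices
over the same promoter universe:

* ``junction`` — sums uniquely mapped split reads whose intron coordinates
  exactly match a promoter's first introns (initiation evidence; blind to
  intronless promoters, which are marked not-quantifiable rather than zero).
* ``transcript`` — sums estimated transcript read counts over the promoter's
  member transcripts.
* ``first_exon`` — counts aligned reads overlapping the promoter's first-exon
  bins, after removing bins shared between promoters.

Normalisation helpers: DESeq2-style median-of-ratios size factors, log2
activity, and RPKM.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .annotation import Interval, PromoterMap

logger = logging.getLogger(__name__)


class TableFormatError(ValueError):
    """An input table violates its dialect contract."""


@dataclass
class JunctionRecord:
    """One splice junction (STAR SJ.out.tab dialect), intron coordinates 1-based."""

    chrom: str
    intron_first: int
    intron_last: int
    strand_code: int  # 0 undefined, 1 "+", 2 "-"
    unique_reads: int
    multi_reads: int


@dataclass
class TranscriptQuant:
    transcript_id: str
    length: int
    effective_length: float
    tpm: float
    num_reads: float


@dataclass
class ReadInterval:
    """One aligned read segment, half-open is NOT used: start/end 1-based inclusive."""

    chrom: str
    start: int
    end: int
    strand: str  # "+", "-" or "." (unstranded)
    read_id: str


@dataclass
class PromoterCountMatrix:
    """Promoters x samples raw counts for one quantification method.

    Rows that the method cannot measure (e.g. intronless promoters under the
    junction method) carry NaN and ``quantifiable`` False — distinct from an
    observed zero.
    """

    method: str
    counts: pd.DataFrame  # index promoter_id, columns sample ids, float
    library_size: pd.Series  # per sample
    promoter_length: pd.Series | None = None  # bp, for RPKM; None for junction/cage
    quantifiable: pd.Series = field(default=None)  # type: ignore[assignment]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.quantifiable is None:
            self.quantifiable = pd.Series(True, index=self.counts.index)
        if (self.counts.to_numpy()[np.isfinite(self.counts.to_numpy())] < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def promoter_ids(self) -> list[int]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    def to_tsv(self, path: str | Path, sidecar: str | Path | None = None) -> None:
        out = self.counts.copy()
        out.insert(0, "promoter_id", out.index)
        out.to_csv(path, sep="\t", index=False)
        if sidecar is not None:
            meta = {
                "method": self.method,
                "library_size": {k: float(v) for k, v in self.library_size.items()},
                "promoter_length": (
                    None
                    if self.promoter_length is None
                    else {int(k): float(v) for k, v in self.promoter_length.items()}
                ),
                "quantifiable": {int(k): bool(v) for k, v in self.quantifiable.items()},
                **self.metadata,
            }
            Path(sidecar).write_text(json.dumps(meta, indent=1, sort_keys=True))

    @classmethod
    def from_tsv(cls, path: str | Path, sidecar: str | Path) -> "PromoterCountMatrix":
        df = pd.read_csv(path, sep="\t").set_index("promoter_id")
        meta = json.loads(Path(sidecar).read_text())
        length = meta.get("promoter_length")
        return cls(
            method=meta["method"],
            counts=df,
            library_size=pd.Series(meta["library_size"]),
            promoter_length=None if length is None else pd.Series(
                {int(k): v for k, v in length.items()}
            ).reindex(df.index),
            quantifiable=pd.Series(
                {int(k): v for k, v in meta["quantifiable"].items()}
            ).reindex(df.index),
            metadata={
                k: v
                for k, v in meta.items()
                if k not in {"method", "library_size", "promoter_length", "quantifiable"}
            },
        )


# ------------------------------------------------------------------ parsing


def parse_sj_table(path: str | Path) -> list[JunctionRecord]:
    """Parse a STAR ``SJ.out.tab``-style file (9 whitespace-separated columns).

    Columns used: 1 chrom, 2 intron first base, 3 intron last base, 4 strand
    code (0/1/2), 7 uniquely mapped reads, 8 multi-mapped reads.
    """
    records: list[JunctionRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = line.split()
            if len(fields) != 9:
                raise TableFormatError(
                    f"line {lineno}: expected 9 columns, got {len(fields)}"
                )
            try:
                rec = JunctionRecord(
                    chrom=fields[0],
                    intron_first=int(fields[1]),
                    intron_last=int(fields[2]),
                    strand_code=int(fields[3]),
                    unique_reads=int(fields[6]),
                    multi_reads=int(fields[7]),
                )
            except ValueError as err:
                raise TableFormatError(f"line {lineno}: unparsable field ({err})")
            if rec.intron_first > rec.intron_last:
                raise TableFormatError(f"line {lineno}: intron end before start")
            if rec.unique_reads < 0 or rec.multi_reads < 0:
                raise TableFormatError(f"line {lineno}: negative read count")
            records.append(rec)
    return records


_QUANT_HEADER = ["Name", "Length", "EffectiveLength", "TPM", "NumReads"]


def parse_quant_table(path: str | Path) -> list[TranscriptQuant]:
    """Parse a Salmon ``quant.sf``-style table (tab-separated, fixed header)."""
    df = pd.read_csv(path, sep="\t")
    if list(df.columns) != _QUANT_HEADER:
        raise TableFormatError(
            f"expected header {' '.join(_QUANT_HEADER)}, got {' '.join(map(str, df.columns))}"
        )
    if df["Name"].duplicated().any():
        dup = df.loc[df["Name"].duplicated(), "Name"].iloc[0]
        raise TableFormatError(f"duplicated transcript_id {dup!r}")
    if (df["NumReads"] < 0).any():
        raise TableFormatError("negative NumReads")
    return [
        TranscriptQuant(r.Name, int(r.Length), float(r.EffectiveLength),
                        float(r.TPM), float(r.NumReads))
        for r in df.itertuples(index=False)
    ]


def parse_read_bed(path: str | Path) -> list[ReadInterval]:
    """Read aligned-segment intervals from BED6 (0-based half-open on disk)."""
    reads: list[ReadInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 4:
                raise TableFormatError(f"line {lineno}: BED needs >= 4 columns")
            strand = f[5] if len(f) >= 6 else "."
            reads.append(
                ReadInterval(chrom=f[0], start=int(f[1]) + 1, end=int(f[2]),
                             strand=strand, read_id=f[3])
            )
    return reads


# ----------------------------------------------------------------- counting


def _strand_ok(code_or_strand: int | str, promoter_strand: str) -> bool:
    if code_or_strand in (0, "."):
        return True
    if isinstance(code_or_strand, int):
        return {1: "+", 2: "-"}[code_or_strand] == promoter_strand
    return code_or_strand == promoter_strand


def quantify_junctions(
    pmap: PromoterMap,
    sj_tables: dict[str, Sequence[JunctionRecord]],
) -> PromoterCountMatrix:
    """Count uniquely mapped first-intron junction reads per promoter.

    A junction record contributes its ``unique_reads`` to every retained
    promoter owning a first intron with exactly matching coordinates and a
    compatible strand (STAR strand code 0 matches either).  Intronless
    promoters are not measurable by this method and are marked
    not-quantifiable.  The per-sample library size is the total of unique
    reads over the whole junction table.
    """
    promoters = pmap.quantifiable()
    index = {}
    for p in promoters:
        for s, e in p.first_introns:
            index.setdefault((p.chrom, s, e), []).append(p)
    # log promoter pairs sharing a first intron (counted toward each)
    for key, plist in index.items():
        if len(plist) > 1:
            logger.info(
                "junction-ambiguous intron %s shared by promoters %s",
                key, [p.promoter_id for p in plist],
            )
    pids = [p.promoter_id for p in promoters]
    samples = list(sj_tables)
    counts = pd.DataFrame(0.0, index=pids, columns=samples)
    library = pd.Series(0.0, index=samples)
    for sample, records in sj_tables.items():
        if not records:
            logger.warning("sample %s has zero junction records", sample)
        for rec in records:
            library[sample] += rec.unique_reads
            for p in index.get((rec.chrom, rec.intron_first, rec.intron_last), ()):
                if _strand_ok(rec.strand_code, p.strand):
                    counts.at[p.promoter_id, sample] += rec.unique_reads
    quantifiable = pd.Series([not p.intronless for p in promoters], index=pids)
    counts.loc[~quantifiable] = np.nan
    return PromoterCountMatrix(
        method="junction", counts=counts, library_size=library,
        quantifiable=quantifiable,
        metadata={"library_size_definition": "total unique junction reads"},
    )


def quantify_transcripts(
    pmap: PromoterMap,
    quants: dict[str, Sequence[TranscriptQuant]],
) -> PromoterCountMatrix:
    """Aggregate transcript-level read counts to promoters.

    ``count(promoter, sample)`` is the sum of ``NumReads`` over the promoter's
    member transcripts; ids missing from a table count as zero with a warning.
    The promoter length used for RPKM is the unweighted mean of the member
    transcripts' annotated (exonic) lengths.
    """
    promoters = pmap.quantifiable()
    pids = [p.promoter_id for p in promoters]
    samples = list(quants)
    counts = pd.DataFrame(0.0, index=pids, columns=samples)
    library = pd.Series(0.0, index=samples)
    for sample, table in quants.items():
        reads = {q.transcript_id: q.num_reads for q in table}
        library[sample] = float(sum(reads.values()))
        for p in promoters:
            total = 0.0
            for tid in p.transcript_ids:
                if tid in reads:
                    total += reads[tid]
                else:
                    logger.warning(
                        "transcript %s of promoter %d missing from sample %s; "
                        "treated as 0", tid, p.promoter_id, sample,
                    )
            counts.at[p.promoter_id, sample] = total
    lengths = pd.Series(
        [
            float(np.mean([pmap.transcript_length[t] for t in sorted(p.transcript_ids)]))
            for p in promoters
        ],
        index=pids,
    )
    return PromoterCountMatrix(
        method="transcript", counts=counts, library_size=library,
        promoter_length=lengths,
        metadata={"library_size_definition": "total NumReads over the quant table"},
    )


def flatten_first_exons(pmap: PromoterMap) -> dict[int, list[Interval]]:
    """Split each promoter's first-exon union into disjoint counting bins.

    Bin boundaries are contributed by every member first exon's start/end, so
    each bin is either wholly inside or wholly outside any member exon.  Bins
    overlapping a bin of another promoter (any gene, same strand) are removed
    from both and reported as ambiguous; a promoter left with no bins is
    marked not-quantifiable for the first-exon method.
    """
    promoters = pmap.quantifiable()
    bins: dict[int, list[Interval]] = {}
    for p in promoters:
        # every member first-exon start/end contributes a cut point
        cuts: set[int] = set()
        for s, e in p.member_first_exons:
            cuts.add(s)
            cuts.add(e + 1)
        pbins: list[Interval] = []
        for us, ue in p.first_exon_union:
            inner = sorted(c for c in cuts if us < c <= ue)
            lo = us
            for c in inner:
                pbins.append((lo, c - 1))
                lo = c
            pbins.append((lo, ue))
        bins[p.promoter_id] = pbins

    # cross-promoter ambiguity: drop whole bins that overlap another promoter's bin
    trees: dict[tuple[str, str], IntervalTree] = {}
    by_id = {p.promoter_id: p for p in promoters}
    for pid, pbins in bins.items():
        p = by_id[pid]
        tree = trees.setdefault((p.chrom, p.strand), IntervalTree())
        for s, e in pbins:
            tree.addi(s, e + 1, pid)
    for pid, pbins in bins.items():
        p = by_id[pid]
        tree = trees[(p.chrom, p.strand)]
        kept = []
        for s, e in pbins:
            others = {h.data for h in tree.overlap(s, e + 1)} - {pid}
            if others:
                logger.info(
                    "ambiguous first-exon bin %s:%d-%d shared by promoters %s",
                    p.chrom, s, e, sorted({pid} | others),
                )
            else:
                kept.append((s, e))
        bins[pid] = kept
        if not kept:
            logger.warning(
                "promoter %d has no unambiguous first-exon bins; "
                "not quantifiable by the first-exon method", pid,
            )
    return bins


def quantify_first_exons(
    pmap: PromoterMap,
    bins: dict[int, list[Interval]],
    reads: dict[str, Sequence[ReadInterval]],
) -> PromoterCountMatrix:
    """Count reads overlapping first-exon bins, one count per read per promoter.

    A read contributes 1 to a promoter when any of its aligned segments
    overlaps any of the promoter's bins by >= 1 bp with a compatible strand
    ("." matches either); multiple overlapping segments or bins still count
    once.  Library size is the number of distinct read ids in the sample.
    """
    by_id = {p.promoter_id: p for p in pmap.quantifiable()}
    trees: dict[tuple[str, str], IntervalTree] = {}
    for pid, pbins in bins.items():
        p = by_id[pid]
        tree = trees.setdefault((p.chrom, p.strand), IntervalTree())
        for s, e in pbins:
            tree.addi(s, e + 1, pid)
    pids = list(bins)
    samples = list(reads)
    counts = pd.DataFrame(0.0, index=pids, columns=samples)
    library = pd.Series(0.0, index=samples)
    for sample, segs in reads.items():
        seen: set[tuple[str, int]] = set()
        read_ids: set[str] = set()
        for seg in segs:
            read_ids.add(seg.read_id)
            for (chrom, strand), tree in trees.items():
                if chrom != seg.chrom or not _strand_ok(seg.strand, strand):
                    continue
                for hit in tree.overlap(seg.start, seg.end + 1):
                    key = (seg.read_id, hit.data)
                    if key not in seen:
                        seen.add(key)
                        counts.at[hit.data, sample] += 1
        library[sample] = float(len(read_ids))
    lengths = pd.Series(
        {pid: float(sum(e - s + 1 for s, e in pbins)) for pid, pbins in bins.items()}
    ).reindex(pids)
    quantifiable = pd.Series({pid: bool(bins[pid]) for pid in pids}).reindex(pids)
    counts.loc[~quantifiable] = np.nan
    return PromoterCountMatrix(
        method="first_exon", counts=counts, library_size=library,
        promoter_length=lengths, quantifiable=quantifiable,
        metadata={"library_size_definition": "distinct read ids in the sample"},
    )


# ------------------------------------------------------------ normalisation


def size_factors(matrix: PromoterCountMatrix) -> pd.Series:
    """Median-of-ratios size factors (DESeq2-style), geometric mean 1.

    The per-promoter reference is the geometric mean across samples over
    promoters with all-positive counts; each sample's factor is the median
    ratio of its counts to the reference, rescaled so the factors have
    geometric mean 1.
    """
    counts = matrix.counts.loc[matrix.quantifiable]
    arr = counts.to_numpy(dtype=float)
    positive = np.all(arr > 0, axis=1) & np.all(np.isfinite(arr), axis=1)
    if not positive.any():
        raise ValueError(
            "no promoter with positive counts in every sample; "
            "median-of-ratios undefined — consider a library-size fallback"
        )
    sub = arr[positive]
    ref = np.exp(np.mean(np.log(sub), axis=1))
    ratios = sub / ref[:, None]
    factors = np.median(ratios, axis=0)
    factors = factors / np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=counts.columns)


def normalize_activity(
    matrix: PromoterCountMatrix,
    factors: pd.Series,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Promoter activity: ``log2(count / size_factor + pseudocount)``.

    Not-quantifiable entries stay missing (NaN).
    """
    if (factors <= 0).any():
        raise ValueError("size factors must be positive")
    return np.log2(matrix.counts.div(factors, axis=1) + pseudocount)


def rpkm(matrix: PromoterCountMatrix) -> pd.DataFrame:
    """Reads per kilobase per million: ``count * 1e9 / (length * library_size)``."""
    if matrix.promoter_length is None:
        raise ValueError(
            f"method {matrix.method!r} has no promoter lengths; RPKM unsupported"
        )
    if (matrix.promoter_length < 1).any():
        raise ValueError("promoter lengths must be >= 1 bp")
    if (matrix.library_size <= 0).any():
        raise ValueError("library sizes must be positive")
    scaled = matrix.counts.div(matrix.promoter_length, axis=0)
    return scaled.div(matrix.library_size, axis=1) * 1e9
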