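"""Shared fixtures and brute-force oracle helpers."""

from __future__ import annotations

import numpy as np
import pytest

from promact import (
    PromoterMap,
    TranscriptModel,
    build_promoter_map,
    flag_internal,
    flag_overlapping,
)


def make_tx(tid, exons, gene="G1", strand="+", chrom="chr1", biotype="protein_coding"):
    """Transcript from genomic-order exon tuples; reorders for '-' strand."""
    exons = sorted(exons)
    if strand == "-":
        exons = exons[::-1]
    return TranscriptModel(
        transcript_id=tid, gene_id=gene, gene_biotype=biotype,
        chrom=chrom, strand=strand, exons=list(exons),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


def random_annotation(rng, n_genes=60):
    """Random toy annotation with overlap chains, internal and cross-gene cases."""
    transcripts = []
    for gi in range(n_genes):
        gene = f"G{gi}"
        chrom = f"chr{1 + gi % 3}"
        strand = "+" if rng.random() < 0.5 else "-"
        base = int(rng.integers(1, 50_000))
        n_tx = int(rng.integers(1, 5))
        for ti in range(n_tx):
            fe_start = base + int(rng.integers(0, 600))
            fe_len = int(rng.integers(50, 300))
            exons = [(fe_start, fe_start + fe_len)]
            if rng.random() < 0.8:  # add downstream exons
                pos = exons[-1][1] + int(rng.integers(50, 800))
                for _ in range(int(rng.integers(1, 3))):
                    ln = int(rng.integers(50, 300))
                    exons.append((pos, pos + ln))
                    pos = exons[-1][1] + int(rng.integers(50, 800))
            transcripts.append(make_tx(f"{gene}.T{ti}", exons, gene, strand, chrom))
    return transcripts


def built_map(transcripts, **kw) -> PromoterMap:
    pmap = build_promoter_map(transcripts, **kw)
    flag_internal(pmap, transcripts)
    flag_overlapping(pmap)
    return pmap


# ------------------------------------------------------------ brute oracles


def overlap_1based(a, b) -> bool:
    return a[0] <= b[1] and b[0] <= a[1]


def brute_grouping(transcripts):
    """Union-find over pairwise first-exon overlap within (gene, strand, chrom)."""
    groups = {}
    by_key = {}
    for t in transcripts:
        by_key.setdefault((t.gene_id, t.chrom, t.strand), []).append(t)
    out = set()
    for key, members in by_key.items():
        parent = {t.transcript_id: t.transcript_id for t in members}

        def find(x):
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        for a in members:
            for b in members:
                if a is not b and overlap_1based(a.first_exon, b.first_exon):
                    parent[find(a.transcript_id)] = find(b.transcript_id)
        clusters = {}
        for t in members:
            clusters.setdefault(find(t.transcript_id), set()).add(t.transcript_id)
        for c in clusters.values():
            out.add(frozenset(c))
    return out


def brute_internal_flags(pmap, transcripts):
    """Triple loop: promoter x transcript x non-first exon containing the TSS."""
    flags = {}
    for p in pmap.promoters:
        flag = False
        for t in transcripts:
            if t.transcript_id in p.transcript_ids or t.chrom != p.chrom:
                continue
            for s, e in t.exons[1:]:
                if s <= p.tss <= e:
                    flag = True
        flags[p.promoter_id] = flag
    return flags


def brute_overlap_flags(pmap):
    """All-pairs cross-gene same-strand first-exon-union intersection."""
    flags = {p.promoter_id: False for p in pmap.promoters}
    ps = pmap.promoters
    for i, a in enumerate(ps):
        for b in ps[i + 1:]:
            if a.gene_id == b.gene_id or a.chrom != b.chrom or a.strand != b.strand:
                continue
            if any(overlap_1based(x, y) for x in a.first_exon_union for y in b.first_exon_union):
                flags[a.promoter_id] = True
                flags[b.promoter_id] = True
    return flags
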