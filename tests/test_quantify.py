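"""Counting strategies, parsers and normalisation."""

import numpy as np
import pandas as pd
import pytest

from promact import (
    JunctionRecord,
    PromoterCountMatrix,
    ReadInterval,
    TableFormatError,
    TranscriptQuant,
    build_promoter_map,
    flatten_first_exons,
    normalize_activity,
    parse_quant_table,
    parse_sj_table,
    quantify_first_exons,
    quantify_junctions,
    quantify_transcripts,
    rpkm,
    size_factors,
)

from conftest import built_map, make_tx, overlap_1based


# ------------------------------------------------------------------ parsers


class TestParseSj:
    def test_column_mapping(self, tmp_path):
        p = tmp_path / "sj.tab"
        p.write_text("chr1 201 400 1 1 0 12 3 20\n")
        (rec,) = parse_sj_table(p)
        assert (rec.chrom, rec.intron_first, rec.intron_last) == ("chr1", 201, 400)
        assert (rec.strand_code, rec.unique_reads, rec.multi_reads) == (1, 12, 3)

    def test_empty_file(self, tmp_path):
        p = tmp_path / "sj.tab"
        p.write_text("")
        assert parse_sj_table(p) == []

    def test_strand_code_two_is_minus(self, tmp_path):
        p = tmp_path / "sj.tab"
        p.write_text("chr1 201 400 2 1 0 5 0 20\n")
        assert parse_sj_table(p)[0].strand_code == 2

    def test_wrong_column_count_names_line(self, tmp_path):
        p = tmp_path / "sj.tab"
        p.write_text("chr1 201 400 1 1 0 12 3 20\nchr1 201 400\n")
        with pytest.raises(TableFormatError, match="line 2"):
            parse_sj_table(p)


class TestParseQuant:
    HEADER = "Name\tLength\tEffectiveLength\tTPM\tNumReads\n"

    def test_row_parse(self, tmp_path):
        p = tmp_path / "quant.sf"
        p.write_text(self.HEADER + "T1\t1500\t1320.5\t10.2\t250.0\n")
        (q,) = parse_quant_table(p)
        assert (q.transcript_id, q.length, q.effective_length, q.tpm, q.num_reads) == \
               ("T1", 1500, 1320.5, 10.2, 250.0)

    def test_header_only_is_empty(self, tmp_path):
        p = tmp_path / "quant.sf"
        p.write_text(self.HEADER)
        assert parse_quant_table(p) == []

    def test_duplicate_id_names_offender(self, tmp_path):
        p = tmp_path / "quant.sf"
        p.write_text(self.HEADER + "T1\t100\t50\t1\t1\nT1\t100\t50\t1\t1\n")
        with pytest.raises(TableFormatError, match="T1"):
            parse_quant_table(p)

    def test_missing_header_rejected(self, tmp_path):
        p = tmp_path / "quant.sf"
        p.write_text("T1\t100\t50\t1\t1\n")
        with pytest.raises(TableFormatError, match="header"):
            parse_quant_table(p)


# ----------------------------------------------------------------- junction


def two_promoter_map():
    tx = [make_tx("T1", [(100, 200), (401, 500)]),
          make_tx("T1b", [(100, 180), (401, 500)]),
          make_tx("T2", [(1000, 1100), (1500, 1600)])]
    return built_map(tx)


class TestQuantifyJunctions:
    def test_exact_intron_match(self):
        pmap = two_promoter_map()
        sj = [JunctionRecord("chr1", 201, 400, 1, 12, 0)]
        m = quantify_junctions(pmap, {"s1": sj})
        p1 = next(p for p in pmap.promoters if "T1" in p.transcript_ids)
        assert m.counts.at[p1.promoter_id, "s1"] == 12

    def test_two_first_introns_sum(self):
        pmap = two_promoter_map()
        p1 = next(p for p in pmap.promoters if "T1" in p.transcript_ids)
        assert p1.first_introns == {(201, 400), (181, 400)}
        sj = [JunctionRecord("chr1", 201, 400, 1, 12, 0),
              JunctionRecord("chr1", 181, 400, 1, 5, 0)]
        m = quantify_junctions(pmap, {"s1": sj})
        assert m.counts.at[p1.promoter_id, "s1"] == 17

    def test_strand_code_zero_matches_either(self):
        pmap = two_promoter_map()
        sj = [JunctionRecord("chr1", 201, 400, 0, 7, 0)]
        m = quantify_junctions(pmap, {"s1": sj})
        p1 = next(p for p in pmap.promoters if "T1" in p.transcript_ids)
        assert m.counts.at[p1.promoter_id, "s1"] == 7

    def test_wrong_strand_not_counted_but_in_library(self):
        pmap = two_promoter_map()
        sj = [JunctionRecord("chr1", 201, 400, 2, 9, 0)]
        m = quantify_junctions(pmap, {"s1": sj})
        assert m.counts.drop(index=[]).fillna(0).to_numpy().sum() == 0
        assert m.library_size["s1"] == 9

    def test_intronless_promoter_marked_not_quantifiable(self):
        tx = [make_tx("T1", [(100, 200)]),
              make_tx("T2", [(1000, 1100), (1500, 1600)])]
        pmap = built_map(tx)
        m = quantify_junctions(pmap, {"s1": []})
        p1 = next(p for p in pmap.promoters if "T1" in p.transcript_ids)
        assert not m.quantifiable[p1.promoter_id]
        assert np.isnan(m.counts.at[p1.promoter_id, "s1"])

    def test_random_fixture_matches_nested_loop_oracle(self, rng):
        # 20 promoters / 200 junctions
        tx = []
        for i in range(20):
            base = 1 + i * 3000
            strand = "+" if i % 2 == 0 else "-"
            tx.append(make_tx(f"T{i}", [(base, base + 100), (base + 500, base + 700)],
                              gene=f"G{i}", strand=strand))
        pmap = built_map(tx)
        introns = [iv for p in pmap.promoters for iv in p.first_introns]
        records = []
        for _ in range(200):
            if rng.random() < 0.5:
                s, e = introns[int(rng.integers(len(introns)))]
            else:
                s = int(rng.integers(1, 60_000)); e = s + int(rng.integers(50, 400))
            records.append(JunctionRecord("chr1", s, e, int(rng.integers(0, 3)),
                                          int(rng.integers(0, 50)), 0))
        m = quantify_junctions(pmap, {"s1": records})
        for p in pmap.quantifiable():
            expected = 0
            for r in records:
                strand = {0: None, 1: "+", 2: "-"}[r.strand_code]
                if (r.intron_first, r.intron_last) in p.first_introns and \
                        (strand is None or strand == p.strand):
                    expected += r.unique_reads
            if p.intronless:
                continue
            assert m.counts.at[p.promoter_id, "s1"] == expected

    def test_counts_bounded_by_library_size(self, rng):
        pmap = two_promoter_map()
        sj = [JunctionRecord("chr1", 201, 400, 1, 12, 0),
              JunctionRecord("chr1", 1101, 1499, 1, 4, 0)]
        m = quantify_junctions(pmap, {"s1": sj})
        assert np.nansum(m.counts["s1"].to_numpy()) <= m.library_size["s1"]


# --------------------------------------------------------------- transcript


class TestQuantifyTranscripts:
    def test_sum_over_members_and_mean_length(self):
        tx = [make_tx("T1", [(1, 1000)]), make_tx("T2", [(500, 2499)])]
        pmap = built_map(tx)
        quants = {"s1": [TranscriptQuant("T1", 1000, 900, 1, 250.0),
                         TranscriptQuant("T2", 2000, 1900, 1, 100.0)]}
        m = quantify_transcripts(pmap, quants)
        pid = pmap.promoters[0].promoter_id
        assert m.counts.at[pid, "s1"] == 350.0
        assert m.promoter_length[pid] == 1500.0

    def test_missing_transcript_counts_zero_with_warning(self, caplog):
        pmap = built_map([make_tx("T1", [(1, 100)])])
        m = quantify_transcripts(pmap, {"s1": []})
        assert m.counts.iloc[0, 0] == 0.0

    def test_random_fixture_matches_brute_aggregation(self, rng):
        tx = []
        for i in range(30):
            base = 1 + i * 5000
            tx.append(make_tx(f"T{i}a", [(base, base + 400)], gene=f"G{i}"))
            tx.append(make_tx(f"T{i}b", [(base + 100, base + 600)], gene=f"G{i}"))
        pmap = built_map(tx)
        table = [TranscriptQuant(t.transcript_id, t.length, t.length - 50, 1.0,
                                 float(rng.integers(0, 500)))
                 for t in tx]
        m = quantify_transcripts(pmap, {"s1": table})
        reads = {q.transcript_id: q.num_reads for q in table}
        for p in pmap.quantifiable():
            assert m.counts.at[p.promoter_id, "s1"] == \
                pytest.approx(sum(reads[t] for t in p.transcript_ids))
        assert m.library_size["s1"] == pytest.approx(sum(reads.values()))


# ---------------------------------------------------------------- first exon


class TestFirstExonBins:
    def test_single_exon_single_bin_inclusive_width(self):
        pmap = built_map([make_tx("T1", [(100, 200)])])
        bins = flatten_first_exons(pmap)
        (pid, pbins), = bins.items()
        assert pbins == [(100, 200)]
        assert sum(e - s + 1 for s, e in pbins) == 101

    def test_overlapping_members_split_at_boundaries(self):
        tx = [make_tx("T1", [(100, 200), (900, 1000)]),
              make_tx("T2", [(150, 250), (900, 1000)])]
        pmap = built_map(tx)
        (pbins,) = flatten_first_exons(pmap).values()
        assert pbins == [(100, 149), (150, 200), (201, 250)]

    def test_boundary_construction_covers_union_exactly(self, rng):
        tx = [make_tx("T1", [(100, 200), (900, 1000)]),
              make_tx("T2", [(150, 250), (900, 1000)])]
        pmap = built_map(tx)
        (pbins,) = flatten_first_exons(pmap).values()
        covered = set()
        for s, e in pbins:
            seg = set(range(s, e + 1))
            assert not covered & seg  # disjoint
            covered |= seg
        assert covered == set(range(100, 251))

    def test_cross_promoter_shared_bins_removed_from_both(self):
        # same-strand different genes sharing 150-200 (flagging is skipped by
        # building the map without the overlap flag step)
        tx = [make_tx("A.T1", [(100, 200)], gene="A"),
              make_tx("B.T1", [(150, 250)], gene="B")]
        pmap = build_promoter_map(tx)
        bins = flatten_first_exons(pmap)
        for pbins in bins.values():
            for b in pbins:
                assert not overlap_1based(b, (150, 200))


class TestQuantifyFirstExons:
    def make(self):
        tx = [make_tx("T1", [(100, 200), (900, 1000)]),
              make_tx("T2", [(150, 250), (900, 1000)])]
        pmap = built_map(tx)
        return pmap, flatten_first_exons(pmap)

    def test_one_bp_overlap_counts(self):
        pmap, bins = self.make()
        reads = {"s1": [ReadInterval("chr1", 180, 220, "+", "r1")]}
        m = quantify_first_exons(pmap, bins, reads)
        assert m.counts.iloc[0, 0] == 1

    def test_read_spanning_two_bins_counted_once(self):
        pmap, bins = self.make()
        reads = {"s1": [ReadInterval("chr1", 140, 160, "+", "r1")]}
        m = quantify_first_exons(pmap, bins, reads)
        assert m.counts.iloc[0, 0] == 1

    def test_strand_mismatch_not_counted(self):
        pmap, bins = self.make()
        reads = {"s1": [ReadInterval("chr1", 180, 220, "-", "r1"),
                        ReadInterval("chr1", 180, 220, ".", "r2")]}
        m = quantify_first_exons(pmap, bins, reads)
        assert m.counts.iloc[0, 0] == 1  # "." matches, "-" does not
        assert m.library_size["s1"] == 2

    def test_random_reads_match_membership_oracle(self, rng):
        tx = []
        for i in range(10):
            base = 1 + i * 2000
            strand = "+" if i % 2 == 0 else "-"
            tx.append(make_tx(f"T{i}", [(base, base + 300)], gene=f"G{i}", strand=strand))
        pmap = built_map(tx)
        bins = flatten_first_exons(pmap)
        reads = []
        for j in range(1000):
            s = int(rng.integers(1, 21_000))
            strand = [".", "+", "-"][int(rng.integers(3))]
            reads.append(ReadInterval("chr1", s, s + 80, strand, f"r{j}"))
        m = quantify_first_exons(pmap, bins, {"s1": reads})
        for p in pmap.quantifiable():
            expected = sum(
                1 for r in reads
                if r.strand in (".", p.strand)
                and any(overlap_1based((r.start, r.end), b) for b in bins[p.promoter_id])
            )
            assert m.counts.at[p.promoter_id, "s1"] == expected


# ------------------------------------------------------------ normalisation


def matrix_of(arr, columns=None) -> PromoterCountMatrix:
    df = pd.DataFrame(np.asarray(arr, dtype=float),
                      columns=columns or [f"s{i}" for i in range(np.shape(arr)[1])])
    return PromoterCountMatrix("junction", df, library_size=df.sum())


class TestSizeFactors:
    def test_identical_samples_unit_factors(self):
        m = matrix_of([[10, 10], [5, 5], [3, 3]])
        assert np.allclose(size_factors(m), [1.0, 1.0])

    def test_doubled_sample_factors_proportional_one_two(self):
        m = matrix_of([[10, 20], [5, 10], [3, 6]])
        f = size_factors(m)
        assert f["s1"] / f["s0"] == pytest.approx(2.0)
        assert np.exp(np.mean(np.log(f))) == pytest.approx(1.0)

    def test_single_sample_factor_one(self):
        m = matrix_of([[10], [5], [3]])
        assert np.allclose(size_factors(m), [1.0])

    def test_no_all_positive_promoter_raises(self):
        m = matrix_of([[0, 5], [5, 0]])
        with pytest.raises(ValueError, match="positive"):
            size_factors(m)

    def test_scaling_inputs_scales_factors(self):
        m1 = matrix_of([[10, 20], [6, 9], [3, 7]])
        m2 = matrix_of(m1.counts.to_numpy() * 5)
        # factors are scale-free after geometric-mean centering, so activities agree
        a1 = normalize_activity(m1, size_factors(m1))
        np.testing.assert_allclose(size_factors(m1), size_factors(m2))
        assert a1.notna().all().all()


class TestActivityAndRpkm:
    def test_activity_values(self):
        m = matrix_of([[0], [3], [7]])
        act = normalize_activity(m, pd.Series([1.0], index=["s0"]))
        assert act.iloc[0, 0] == 0.0
        assert act.iloc[1, 0] == pytest.approx(2.0)
        m2 = matrix_of([[7]])
        act2 = normalize_activity(m2, pd.Series([2.0], index=["s0"]))
        assert act2.iloc[0, 0] == pytest.approx(np.log2(4.5))

    def test_not_quantifiable_propagates_as_missing(self):
        df = pd.DataFrame([[np.nan], [4.0]], columns=["s0"])
        m = PromoterCountMatrix("junction", df, library_size=pd.Series({"s0": 4.0}),
                               quantifiable=pd.Series([False, True]))
        act = normalize_activity(m, pd.Series({"s0": 1.0}))
        assert np.isnan(act.iloc[0, 0]) and act.iloc[1, 0] == pytest.approx(np.log2(5))

    def test_rpkm_values(self):
        df = pd.DataFrame([[100.0], [0.0], [37.0]], columns=["s0"])
        m = PromoterCountMatrix(
            "transcript", df, library_size=pd.Series({"s0": 1e6}),
            promoter_length=pd.Series([1000.0, 500.0, 1530.0]),
        )
        r = rpkm(m)
        assert r.iloc[0, 0] == pytest.approx(100.0)
        assert r.iloc[1, 0] == 0.0
        m.library_size["s0"] = 2.4e7
        assert rpkm(m).iloc[2, 0] == pytest.approx(37 * 1e9 / (1530 * 2.4e7))

    def test_rpkm_invariant_under_joint_scaling(self):
        df = pd.DataFrame([[100.0]], columns=["s0"])
        m = PromoterCountMatrix("transcript", df, library_size=pd.Series({"s0": 1e6}),
                                promoter_length=pd.Series([1000.0]))
        m2 = PromoterCountMatrix("transcript", df * 7, library_size=pd.Series({"s0": 7e6}),
                                 promoter_length=pd.Series([1000.0]))
        assert rpkm(m).iloc[0, 0] == pytest.approx(rpkm(m2).iloc[0, 0])

    def test_rpkm_unsupported_without_lengths(self):
        m = matrix_of([[1, 2]])
        with pytest.raises(ValueError, match="RPKM"):
            rpkm(m)
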