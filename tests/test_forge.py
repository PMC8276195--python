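"""Annotation forging: each stage against planted truth and hand oracles."""

import numpy as np
import pandas as pd
import pytest

from pirnakit.forge import (
    SeqRecord,
    annotate_embedded,
    collapse_sequences,
    exclude_coding_overlap,
    find_genomic_regions,
    forge,
    integrate_databases,
    intersect_te,
    length_filter,
    reclassify_biotypes,
    write_forge_outputs,
)
from pirnakit.io import GenomicHit, GtfFeature, TeInterval, read_gtf
from tests.conftest import db_records


def rec(rid, seq, biotype="piRNA", db=None):
    return SeqRecord(
        primary_id=rid, alias_ids={rid}, sequence=seq, biotype=biotype,
        source_db=set() if db is None else {db},
    )


def hit(chrom="chr1", start=100, length=28, strand="+"):
    return GenomicHit(chrom, start, start + length, strand, 0, length)


class TestCollapse:
    def test_empty_input(self):
        assert collapse_sequences([]) == []

    def test_same_sequence_merges_aliases(self):
        out = collapse_sequences([rec("hsa_piR_1", "ACGTACGT"), rec("hsa_piR_2", "ACGTACGT")])
        assert len(out) == 1
        assert out[0].alias_ids == {"hsa_piR_1", "hsa_piR_2"}
        assert out[0].primary_id == "hsa_piR_1"

    def test_seeded_redundant_collection_collapses_to_distinct(self):
        rng = np.random.default_rng(0)
        bases = np.array(list("ACGT"))
        distinct = ["".join(bases[rng.integers(0, 4, 26)]) for _ in range(400)]
        records = [
            rec(f"id{i}", distinct[rng.integers(0, 400)]) for i in range(1000)
        ]
        out = collapse_sequences(records)
        # hash-set oracle
        assert len(out) == len({r.sequence for r in records})

    def test_idempotent(self):
        records = [rec(f"id{i}", "ACGT" * (2 + i % 3)) for i in range(10)]
        once = collapse_sequences(records)
        twice = collapse_sequences(once)
        assert [(r.primary_id, r.sequence, r.alias_ids) for r in once] == [
            (r.primary_id, r.sequence, r.alias_ids) for r in twice
        ]


class TestLengthFilter:
    def test_boundary_is_exclusive(self):
        records = [rec("a", "A" * 100), rec("b", "A" * 98 + "C")]
        kept = length_filter(records, 100)
        assert [r.primary_id for r in kept] == ["b"]

    def test_all_short_is_identity(self):
        records = [rec(f"r{i}", "ACGTACGTACGTACGTACGTACGT") for i in range(5)]
        assert length_filter(records, 100) == records


class TestReclassify:
    def test_matching_snorna_takes_its_biotype(self):
        pb = [rec("p1", "ACGTACGTACGTACGTACGTACGTAC")]
        rc = [rec("u1", "ACGTACGTACGTACGTACGTACGTAC", biotype="snoRNA")]
        out, log = reclassify_biotypes(collapse_sequences(pb), collapse_sequences(rc))
        assert out[0].biotype == "snoRNA"
        assert log.iloc[0]["status"] == "reclassified"

    def test_no_match_stays_pirna(self):
        pb = [rec("p1", "ACGTACGTACGTACGTACGTACGTAC")]
        out, log = reclassify_biotypes(pb, [])
        assert out[0].biotype == "piRNA" and log.empty

    def test_ambiguous_double_biotype_flagged_not_changed(self):
        seq = "ACGTACGTACGTACGTACGTACGTAC"
        pb = [rec("p1", seq)]
        rc = collapse_sequences([rec("u1", seq, "snoRNA"), rec("u2", seq, "snRNA")])
        out, log = reclassify_biotypes(pb, rc)
        assert out[0].biotype == "piRNA" and out[0].reclass_ambiguous
        assert log.iloc[0]["status"] == "ambiguous"

    def test_sequences_never_altered(self, fixture):
        pb, rc = db_records(fixture)
        pb_c, rc_c = collapse_sequences(pb), collapse_sequences(rc)
        out, _ = reclassify_biotypes(pb_c, rc_c)
        assert sorted(r.sequence for r in out) == sorted(r.sequence for r in pb_c)

    def test_planted_conflicts_all_logged(self, fixture):
        pb, rc = db_records(fixture)
        _, log = reclassify_biotypes(collapse_sequences(pb), collapse_sequences(rc))
        n_conflict = (fixture.truth["category"] == "conflict").sum()
        assert (log["status"] == "reclassified").sum() == n_conflict


class TestIntegrate:
    def test_long_pirnabank_only_record_excluded(self):
        pb = [rec("p1", "A" * 70, db="pirnabank")]
        merged, counts = integrate_databases(pb, [rec("u1", "ACGT" * 7, db="rnacentral")], 69)
        assert [r.primary_id for r in merged] == ["u1"]
        assert counts == {"common": 0, "rnacentral_only": 1, "pirnabank_only": 0}

    def test_shared_sequence_merges_provenance_and_primary_id(self):
        seq = "ACGTACGTACGTACGTACGTACGTACGT"  # 28 nt
        merged, counts = integrate_databases(
            [rec("p1", seq, db="pirnabank")], [rec("u1", seq, db="rnacentral")], 69
        )
        (m,) = merged
        assert m.primary_id == "u1"  # completing database id wins
        assert m.source_db == {"pirnabank", "rnacentral"}
        assert "p1" in m.alias_ids
        assert counts["common"] == 1

    def test_disjoint_sets_concatenate(self):
        pb = [rec(f"p{i}", f"ACGTACGTACGTACGTACGTACGT{'A' * i}C", db="pirnabank") for i in range(5)]
        rc = [rec(f"u{i}", f"TTGTACGTACGTACGTACGTACGT{'G' * i}C", db="rnacentral") for i in range(3)]
        merged, _ = integrate_databases(pb, rc, 69)
        assert len(merged) == 8

    def test_id_collision_with_different_sequences_is_error(self):
        with pytest.raises(ValueError, match="reused"):
            integrate_databases(
                [rec("x", "ACGTACGTACGTACGTACGTACGTA", db="pirnabank")],
                [rec("x", "TGCATGCATGCATGCATGCATGCAT", db="rnacentral")],
                69,
            )


class TestCodingOverlap:
    GENES = [
        GtfFeature("chr1", "t", "gene", 1000, 6000, "+", {"gene_id": "G1", "gene_type": "protein_coding"}),
        GtfFeature("chr1", "t", "exon", 1000, 1300, "+", {"gene_id": "G1", "gene_type": "protein_coding"}),
        GtfFeature("chr1", "t", "CDS", 1100, 1300, "+", {"gene_id": "G1", "gene_type": "protein_coding"}),
    ]

    def test_feature_in_cds_removed_when_stringent(self):
        feats = [(rec("a", "A" * 28), hit(start=1150))]
        kept, flags = exclude_coding_overlap(feats, self.GENES, stringent=True)
        assert kept == [] and flags == {"a": True}

    def test_lenient_keeps_and_flags(self):
        feats = [(rec("a", "A" * 28), hit(start=1150))]
        kept, flags = exclude_coding_overlap(feats, self.GENES, stringent=False)
        assert len(kept) == 1 and flags == {"a": True}

    def test_intergenic_kept_in_both_modes(self):
        feats = [(rec("a", "A" * 28), hit(start=9000))]
        for stringent in (True, False):
            kept, flags = exclude_coding_overlap(feats, self.GENES, stringent=stringent)
            assert len(kept) == 1 and flags == {}

    def test_intronic_feature_survives_stringent(self):
        feats = [(rec("a", "A" * 28), hit(start=3000))]
        kept, _ = exclude_coding_overlap(feats, self.GENES, stringent=True)
        assert len(kept) == 1


class TestEmbedded:
    HOSTS = [
        GtfFeature("chr1", "t", "gene", 2000, 4000, "+", {"gene_id": "H1", "gene_type": "lncRNA"}),
    ]

    def test_contained_same_strand_reported(self):
        feats = [(rec("p", "A" * 28), hit(start=2500, strand="+"))]
        assert annotate_embedded(feats, self.HOSTS) == [("p", "H1", "lncRNA")]

    def test_opposite_strand_not_reported(self):
        feats = [(rec("p", "A" * 28), hit(start=2500, strand="-"))]
        assert annotate_embedded(feats, self.HOSTS) == []

    def test_partial_overlap_not_reported(self):
        feats = [(rec("p", "A" * 28), hit(start=1990, strand="+"))]
        assert annotate_embedded(feats, self.HOSTS) == []

    def test_non_pirna_features_ignored(self):
        feats = [(rec("p", "A" * 28, biotype="miRNA"), hit(start=2500, strand="+"))]
        assert annotate_embedded(feats, self.HOSTS) == []

    def test_planted_containments_recovered(self, fixture):
        expected = fixture.truth.loc[fixture.truth["embedded_host"] != ""]
        feats = []
        for f in fixture.features:
            for chrom, start, strand in f.surviving_placements:
                feats.append(
                    (rec(f.uid, f.sequence), hit(chrom, start, f.length, strand))
                )
        rows = annotate_embedded(feats, fixture.gene_features)
        assert sorted((r[0], r[1]) for r in rows) == sorted(
            map(tuple, expected[["uid", "embedded_host"]].values)
        )


class TestRegions:
    def test_isolated_feature_one_region(self):
        labels, regions = find_genomic_regions([(rec("a", "A" * 28), hit(start=100))], 1000, [])
        assert labels == {"a": "cluster"} and len(regions) == 1
        assert regions.iloc[0][["start", "end"]].tolist() == [100, 128]

    def test_features_beyond_gap_split(self):
        feats = [(rec("a", "A" * 28), hit(start=0)), (rec("b", "A" * 28), hit(start=10_000))]
        labels, regions = find_genomic_regions(feats, 1000, [])
        assert len(regions) == 2

    def test_features_within_gap_merge(self):
        feats = [(rec("a", "A" * 28), hit(start=0)), (rec("b", "A" * 28), hit(start=500))]
        _, regions = find_genomic_regions(feats, 1000, [])
        assert len(regions) == 1 and regions.iloc[0]["n_placements"] == 2

    def test_gene_overlap_labels_genic(self):
        gene = [GtfFeature("chr1", "t", "gene", 0, 5000, "+", {"gene_id": "G", "gene_type": "x"})]
        feats = [(rec(f"f{i}", "A" * 28), hit(start=100 + i * 200)) for i in range(5)]
        labels, regions = find_genomic_regions(feats, 1000, gene)
        assert len(regions) == 1 and regions.iloc[0]["label"] == "genic"
        assert set(labels.values()) == {"genic"}

    def test_hits_in_both_region_kinds_label_both(self):
        gene = [GtfFeature("chr1", "t", "gene", 0, 1000, "+", {"gene_id": "G", "gene_type": "x"})]
        feats = [
            (rec("m", "A" * 28), hit(start=100)),
            (rec("m", "A" * 28), hit(start=50_000)),
        ]
        labels, _ = find_genomic_regions(feats, 1000, gene)
        assert labels == {"m": "both"}


class TestTeIntersect:
    def test_overlapping_te_reported_with_class(self):
        te = [TeInterval("chr1", 90, 140, "TE1", "+", "LINE", "L1", "L1HS")]
        out = intersect_te([(rec("a", "A" * 28), hit(start=100))], te)
        assert len(out) == 1
        row = out.iloc[0]
        assert row["te_class"] == "LINE" and row["overlap_bp"] == 28

    def test_no_overlap_no_rows(self):
        te = [TeInterval("chr1", 500, 600, "TE1", "+", "LINE", "L1", "L1HS")]
        assert intersect_te([(rec("a", "A" * 28), hit(start=100))], te).empty

    def test_feature_spanning_two_tes_two_rows(self):
        tes = [
            TeInterval("chr1", 90, 110, "TE1", "+", "LINE", "L1", "L1HS"),
            TeInterval("chr1", 115, 150, "TE2", "+", "SINE", "Alu", "AluY"),
        ]
        out = intersect_te([(rec("a", "A" * 28), hit(start=100))], tes)
        assert len(out) == 2
        # interval oracle: overlap lengths computed by hand
        assert sorted(out["overlap_bp"]) == [10, 13]


class TestForgePipeline:
    def test_planted_truth_equivalence(self, fixture, forge_result):
        """The forged track equals the generator's expected placements exactly."""
        got = (
            pd.DataFrame(
                [
                    {
                        "chrom": h.chrom,
                        "start": h.start,
                        "end": h.end,
                        "strand": h.strand,
                        "gene_id": r.primary_id,
                        "gene_biotype": r.biotype,
                    }
                    for r, h in forge_result.track.features
                ]
            )
            .sort_values(["chrom", "start", "end", "gene_id"])
            .reset_index(drop=True)
        )
        pd.testing.assert_frame_equal(got, fixture.expected_gtf, check_like=True)

    def test_region_labels_match_truth(self, fixture, forge_result):
        expected = fixture.truth.set_index("uid")["expected_region"]
        for sid, label in forge_result.track.region_info.items():
            assert expected.loc[sid] == label

    def test_multimap_info_matches_truth(self, fixture, forge_result):
        expected = fixture.truth.set_index("uid")
        for sid, n in forge_result.track.multimap_info.items():
            assert n == expected.loc[sid, "n_surviving_placements"]

    def test_stage_counts_monotone_through_filters(self, forge_result):
        frame = forge_result.stats.to_frame()
        pb_counts = frame[
            frame["metric"].isin(["pirnabank_records", "pirnabank_unique", "pirnabank_mapped", "pirnabank_kept"])
        ]["value"].tolist()
        assert pb_counts == sorted(pb_counts, reverse=True)

    def test_written_gtf_round_trips(self, tmp_path, forge_result):
        paths = write_forge_outputs(forge_result, tmp_path)
        feats = read_gtf(paths["gtf"])
        assert len(feats) == len(forge_result.track.features)
        # re-scan the written GTF against the rules: lengths and chromosomes
        for f in feats:
            assert f.end - f.start < 100
            assert f.chrom.startswith("chr") and "Un" not in f.chrom

    def test_rerun_is_byte_identical(self, tmp_path, fixture, run_config):
        pb, rc = db_records(fixture)
        outs = []
        for d in ("a", "b"):
            res = forge(
                run_config, pb, rc, fixture.genome, fixture.gene_features, fixture.te_intervals
            )
            paths = write_forge_outputs(res, tmp_path / d)
            outs.append(paths)
        for key in ("gtf", "fasta", "regions", "multimap", "te", "reclass"):
            assert outs[0][key].read_bytes() == outs[1][key].read_bytes(), key

    def test_lenient_mode_keeps_flagged_coding_overlaps(self, fixture, run_config):
        import dataclasses

        cfg = dataclasses.replace(run_config, forge=dataclasses.replace(
            run_config.forge, stringent_coding_filter=False))
        pb, rc = db_records(fixture)
        res = forge(cfg, pb, rc, fixture.genome, fixture.gene_features, fixture.te_intervals)
        in_cds = set(fixture.truth.loc[fixture.truth["category"] == "in_cds", "uid"])
        track_ids = {r.primary_id for r, _ in res.track.features}
        assert in_cds <= track_ids
        assert all(res.track.coding_overlap_flags.get(u) for u in in_cds)
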