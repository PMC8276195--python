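"""Trimming, read alignment, feature counting and the EM quantifier."""

import numpy as np
import pandas as pd
import pytest

from pirnakit.align import UngappedIndex
from pirnakit.config import QuantParams
from pirnakit.forge import AnnotationTrack, SeqRecord
from pirnakit.io import GenomeRef, GenomicHit
from pirnakit.quantify import (
    ReadAlignment,
    align_reads,
    build_equivalence_classes,
    consensus_expressed,
    count_features,
    quantify_transcripts,
    trim_adapter,
    trim_reads,
)

ADAPTER = "TGGAATTCTCGGGTGCCAAGG"


class TestTrim:
    def test_full_adapter_removed(self):
        insert = "ACGTACGTACGTACGTACGTACGTA"  # 25 nt
        t = trim_adapter(("r", insert + ADAPTER, "I" * (25 + len(ADAPTER))), ADAPTER)
        assert t.sequence == insert and t.trimmed_bases == len(ADAPTER)

    def test_no_adapter_unchanged(self):
        seq = "ACGTACGTACGTACGTACGTACGTA"
        t = trim_adapter(("r", seq, "I" * len(seq)), ADAPTER)
        assert t.sequence == seq and t.trimmed_bases == 0

    def test_short_insert_discarded(self):
        seq = "ACGTACGTAC" + ADAPTER  # 10 nt insert < 15
        assert trim_adapter(("r", seq, "I" * len(seq)), ADAPTER) is None

    def test_adapter_prefix_at_read_end(self):
        insert = "ACGTACGTACGTACGTACGTACGT"  # 24 nt
        seq = insert + ADAPTER[:5]
        t = trim_adapter(("r", seq, "I" * len(seq)), ADAPTER)
        assert t.sequence == insert

    def test_one_error_tolerated_in_long_overlap(self):
        insert = "ACGTACGTACGTACGTACGTACGT"
        bad = "A" + ADAPTER[1:]  # 1 mismatch in 21 bases: rate < 0.1
        t = trim_adapter(("r", insert + bad, "I" * (24 + 21)), ADAPTER)
        assert t.sequence == insert

    def test_simulated_inserts_recovered_exactly(self):
        """>=99% exact insert recovery at zero sequencing error."""
        rng = np.random.default_rng(1)
        bases = np.array(list("ACGT"))
        params = QuantParams(adapter=ADAPTER)
        n_ok = n = 0
        reads = []
        inserts = []
        for i in range(10_000):
            L = int(rng.integers(18, 35))
            insert = "".join(bases[rng.integers(0, 4, L)])
            read = (insert + ADAPTER)[:50]
            inserts.append(insert)
            reads.append((f"r{i}", read, "I" * len(read)))
        trimmed = trim_reads(reads, params)
        by_id = {t.id: t.sequence for t in trimmed}
        for i, insert in enumerate(inserts):
            n += 1
            if by_id.get(f"r{i}") == insert:
                n_ok += 1
        assert n_ok / n >= 0.99


def _toy_genome(seed=3, n=4000):
    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))
    return GenomeRef(
        chrom_names=["c1"],
        sequences={"c1": "".join(bases[rng.integers(0, 4, n)])},
        standard_set={"c1"},
    )


class TestAlignReads:
    def mk_read(self, seq, rid="r1"):
        from pirnakit.quantify import TrimmedRead

        return TrimmedRead(rid, seq, "I" * len(seq), 0)

    def test_unique_22mer_single_hit(self):
        genome = _toy_genome()
        idx = UngappedIndex(genome)
        read = self.mk_read(genome.sequences["c1"][1000:1022])
        (aln,) = align_reads([read], idx, QuantParams())
        assert aln.n_hits == 1 and aln.hits[0].start == 1000

    def test_one_mismatch_still_aligns(self):
        genome = _toy_genome()
        idx = UngappedIndex(genome)
        seq = list(genome.sequences["c1"][2000:2024])
        seq[10] = {"A": "C", "C": "A", "G": "T", "T": "G"}[seq[10]]
        (aln,) = align_reads([self.mk_read("".join(seq))], idx, QuantParams())
        assert aln.n_hits == 1 and aln.hits[0].mismatches == 1

    def test_over_multimapped_read_reported_unaligned(self):
        seq = "ACGTTGCAGGATCCAT"
        genome = GenomeRef(
            chrom_names=["c1"],
            sequences={"c1": ("TT" + seq) * 101 + "TTTT"},
            standard_set={"c1"},
        )
        params = QuantParams(max_loci=100)
        (aln,) = align_reads([self.mk_read(seq)], UngappedIndex(genome), params)
        assert aln.n_hits == 0

    def test_non_acgtn_read_skipped(self):
        genome = _toy_genome()
        out = align_reads([self.mk_read("ACGTXACGTACGTACGTAC")], UngappedIndex(genome), QuantParams())
        assert out == []


def _track_with(features):
    """features: list of (id, biotype, chrom, start, length, strand)."""
    pairs = []
    recs = {}
    for fid, biotype, chrom, start, length, strand in features:
        r = recs.setdefault(
            fid,
            SeqRecord(primary_id=fid, alias_ids={fid}, sequence="A" * length, biotype=biotype),
        )
        pairs.append((r, GenomicHit(chrom, start, start + length, strand, 0, length)))
    return AnnotationTrack(features=pairs)


def _aln(rid, placements):
    hits = [GenomicHit(c, s, e, strand, 0, e - s) for c, s, e, strand in placements]
    return ReadAlignment(rid, "", hits, len(hits))


class TestCountFeatures:
    TRACK = _track_with(
        [
            ("f1", "piRNA", "c1", 100, 30, "+"),
            ("f2", "piRNA", "c1", 500, 30, "+"),
            ("multi", "piRNA", "c1", 900, 30, "+"),
            ("multi", "piRNA", "c1", 1300, 30, "+"),
            ("ov1", "piRNA", "c1", 2000, 30, "+"),
            ("ov2", "miRNA", "c1", 2010, 30, "+"),
        ]
    )

    def test_unique_read_counts_one(self):
        res = count_features([_aln("r", [("c1", 105, 127, "+")])], self.TRACK, "fractional")
        assert res.counts["f1"] == 1.0 and res.assigned == 1.0

    def test_antisense_read_not_assigned(self):
        res = count_features([_aln("r", [("c1", 105, 127, "-")])], self.TRACK, "fractional")
        assert res.counts.sum() == 0 and res.unassigned == 1

    def test_two_copy_feature_fractional_sums_to_one(self):
        aln = _aln("r", [("c1", 905, 927, "+"), ("c1", 1305, 1327, "+")])
        res = count_features([aln], self.TRACK, "fractional")
        assert res.counts["multi"] == pytest.approx(1.0)

    def test_ambiguous_overlap_dropped(self):
        res = count_features([_aln("r", [("c1", 2012, 2034, "+")])], self.TRACK, "fractional")
        assert res.counts.sum() == 0 and res.ambiguous == 1

    def test_unique_mode_drops_multimappers(self):
        aln = _aln("r", [("c1", 905, 927, "+"), ("c1", 1305, 1327, "+")])
        res = count_features([aln], self.TRACK, "unique")
        assert res.counts.sum() == 0

    def test_mode_ordering_all_ge_fractional_ge_unique(self):
        rng = np.random.default_rng(4)
        alns = []
        spots = [(100, "f1"), (500, "f2"), (900, "multi"), (1300, "multi")]
        for i in range(200):
            k = int(rng.integers(1, 3))
            chosen = rng.choice(len(spots), size=k, replace=False)
            placements = [("c1", spots[j][0] + 2, spots[j][0] + 26, "+") for j in chosen]
            alns.append(_aln(f"r{i}", placements))
        res = {m: count_features(alns, self.TRACK, m).counts for m in ("all", "fractional", "unique")}
        assert (res["all"] >= res["fractional"] - 1e-9).all()
        assert (res["fractional"] >= res["unique"] - 1e-9).all()


def _mk_trimmed(seqs):
    from pirnakit.quantify import TrimmedRead

    return [TrimmedRead(f"r{i}", s, "I" * len(s), 0) for i, s in enumerate(seqs)]


class TestTranscriptEM:
    def test_reads_unique_to_one_transcript(self):
        rng = np.random.default_rng(0)
        bases = np.array(list("ACGT"))
        tx = [("t1", "".join(bases[rng.integers(0, 4, 60)])), ("t2", "".join(bases[rng.integers(0, 4, 60)]))]
        reads = _mk_trimmed([tx[0][1][5:35]] * 10)
        q = quantify_transcripts(reads, tx, QuantParams(n_bootstraps=5), seed=0)
        assert q.counts["t1"] == pytest.approx(10.0) and q.counts["t2"] == pytest.approx(0.0)

    def test_identical_transcripts_split_evenly(self):
        seq = "ACGTTGCAGGATCCATACGTTGCAGGATCCATAAACCC"
        tx = [("a", seq), ("b", seq)]
        reads = _mk_trimmed([seq[2:30]] * 10)
        q = quantify_transcripts(reads, tx, QuantParams(n_bootstraps=5), seed=0)
        assert q.counts["a"] == pytest.approx(5.0, abs=1e-6)
        assert q.counts["b"] == pytest.approx(5.0, abs=1e-6)

    def test_mass_conserved_and_loglik_monotone(self, fixture, sample_reads):
        reads, _ = sample_reads
        trimmed = trim_reads(reads[:4000], QuantParams(adapter=fixture.spec.adapter))
        tx = [
            (f.uid, f.sequence)
            for f in fixture.features
            if f.drop_reason == "" and f.surviving_placements
        ]
        q = quantify_transcripts(trimmed, tx, QuantParams(n_bootstraps=3), seed=1)
        assert q.counts.sum() == pytest.approx(q.eq_classes.n_mapped, rel=1e-6)
        ll = q.loglik_trace
        assert all(b >= a - 1e-9 for a, b in zip(ll, ll[1:]))

    def test_planted_mixture_recovered_within_bootstrap_error(self):
        """60/30/10 mixture of three transcripts, 5,000 seeded reads."""
        rng = np.random.default_rng(11)
        bases = np.array(list("ACGT"))
        tx = [(f"t{i}", "".join(bases[rng.integers(0, 4, 80)])) for i in range(3)]
        props = np.array([0.6, 0.3, 0.1])
        n = 5000
        seqs = []
        for i, k in enumerate(rng.multinomial(n, props)):
            for _ in range(k):
                s = int(rng.integers(0, 50))
                seqs.append(tx[i][1][s : s + 30])
        q = quantify_transcripts(_mk_trimmed(seqs), tx, QuantParams(n_bootstraps=50), seed=2)
        for i in range(3):
            sd = max(q.bootstrap_sd[f"t{i}"], 1.0)
            assert abs(q.counts[f"t{i}"] - props[i] * n) <= 3 * sd + 3

    def test_small_instance_agrees_with_likelihood_grid(self):
        """Two transcripts sharing reads: EM vs a brute-force likelihood grid."""
        seqA = "ACGTTGCAGGATCCATACGAAGGTTCCAAGGTTAA"
        seqB = "TTTACGTTGCAGGATCCATACGCCGGAATTCCGGA"
        shared = "ACGTTGCAGGATCCATACG"  # occurs in both
        tx = [("A", seqA), ("B", seqB)]
        reads = _mk_trimmed([shared] * 6 + [seqA[10:32]] * 3 + [seqB[20:40]] * 1)
        q = quantify_transcripts(reads, tx, QuantParams(n_bootstraps=2, em_tol=1e-12), seed=0)
        # grid oracle over theta = P(read from A)
        thetas = np.linspace(1e-6, 1 - 1e-6, 20_001)
        ll = 6 * np.log(1.0) + 3 * np.log(thetas) + 1 * np.log(1 - thetas)
        best = thetas[np.argmax(ll)]
        assert q.counts["A"] / 10 == pytest.approx(best, abs=5e-3)

    def test_empty_transcript_set_is_error(self):
        with pytest.raises(ValueError):
            build_equivalence_classes(_mk_trimmed(["ACGT" * 8]), [])


class TestConsensus:
    def test_union_and_intersection_planted(self):
        both = {f"b{i}" for i in range(30)}
        g_only = {f"g{i}" for i in range(10)}
        t_only = {f"t{i}" for i in range(5)}
        g, t = both | g_only, both | t_only
        assert len(consensus_expressed(g, t, "union")) == 45
        assert len(consensus_expressed(g, t, "intersection")) == 30

    def test_intersection_subset_union(self):
        g, t = {"a", "b"}, {"b", "c"}
        inter = consensus_expressed(g, t, "intersection")
        union = consensus_expressed(g, t, "union")
        assert inter <= g <= union and inter <= t <= union
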