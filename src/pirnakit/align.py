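"""Ungapped, splice-free placement of short sequences on a reference.

This is the alignment contract shared by the annotation-forging realignment
(>=16 matched bases, 0 mismatches) and read quantification (>=14 matched
bases, <=1 mismatch): every end-to-end ungapped placement of the query on
either strand is reported, and a query with more placements than ``max_loci``
is treated as unmapped (mirroring how a short-read aligner reports reads that
exceed its multimap cap).

Candidate loci come from exact k-mer seeds.  With at most one mismatch the
query is split into two disjoint seeds (pigeonhole: the mismatch can ruin at
most one), each looked up in a sorted k-mer table of the concatenated
reference; candidates are then verified by a vectorised Hamming comparison.
``search_brute_force`` is the deliberately naive sliding-window oracle used
by the test-suite; it shares no code with the indexed path.
"""

from __future__ import annotations

import numpy as np

from pirnakit.io import GenomeRef, GenomicHit, revcomp

_CODE = np.full(256, 255, dtype=np.uint8)
for i, base in enumerate("ACGT"):
    _CODE[ord(base)] = i
_CODE[ord("N")] = 4


def encode_seq(seq: str) -> np.ndarray:
    arr = _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    if (arr == 255).any():
        bad = sorted(set(seq) - set("ACGTN"))
        raise ValueError(f"sequence contains non-ACGTN symbols: {bad}")
    return arr


class UngappedIndex:
    """K-mer index over a reference for exact-seed candidate generation."""

    def __init__(self, genome: GenomeRef):
        self.genome = genome
        self.chrom_names = list(genome.chrom_names)
        lengths = np.array([genome.chrom_length(c) for c in self.chrom_names], dtype=np.int64)
        # chromosome c occupies [offsets[c], offsets[c+1]) in the concatenation
        self.offsets = np.concatenate([[0], np.cumsum(lengths)])
        self.codes = np.concatenate(
            [encode_seq(genome.sequences[c]) for c in self.chrom_names]
        )
        self._kmer_cache: dict[int, tuple[np.ndarray, np.ndarray]] = {}

    # -- k-mer table ---------------------------------------------------------

    def _kmer_table(self, k: int) -> tuple[np.ndarray, np.ndarray]:
        if k in self._kmer_cache:
            return self._kmer_cache[k]
        n = self.codes.size
        if n < k:
            empty = np.empty(0, dtype=np.int64)
            self._kmer_cache[k] = (empty, empty)
            return self._kmer_cache[k]
        vals = np.zeros(n - k + 1, dtype=np.int64)
        invalid = np.zeros(n - k + 1, dtype=bool)
        for j in range(k):
            col = self.codes[j : n - k + 1 + j]
            vals = vals * 4 + np.minimum(col, 3)
            invalid |= col >= 4  # windows containing N never seed
        # windows crossing a chromosome boundary are not real loci
        starts = np.arange(n - k + 1)
        chrom_of_start = np.searchsorted(self.offsets, starts, side="right") - 1
        chrom_of_end = np.searchsorted(self.offsets, starts + k - 1, side="right") - 1
        invalid |= chrom_of_start != chrom_of_end
        vals[invalid] = -1
        order = np.argsort(vals, kind="stable")
        self._kmer_cache[k] = (vals[order], order.astype(np.int64))
        return self._kmer_cache[k]

    def _seed_hits(self, query_codes: np.ndarray, k: int, offset: int) -> np.ndarray:
        """Concatenation positions where the k-mer at ``offset`` occurs exactly."""
        sub = query_codes[offset : offset + k]
        if (sub >= 4).any():
            return np.empty(0, dtype=np.int64)
        val = 0
        for c in sub:
            val = val * 4 + int(c)
        sorted_vals, order = self._kmer_table(k)
        lo = np.searchsorted(sorted_vals, val, side="left")
        hi = np.searchsorted(sorted_vals, val, side="right")
        return order[lo:hi] - offset

    # -- search --------------------------------------------------------------

    def _strand_hits(
        self, query: str, max_mismatch: int
    ) -> tuple[np.ndarray, np.ndarray]:
        """Candidate start positions (concatenation coords) and mismatch counts."""
        q = encode_seq(query)
        L = q.size
        if max_mismatch == 0:
            k = min(16, L)
            cands = self._seed_hits(q, k, 0)
        else:
            # two disjoint seeds; one of them is exact under <=1 mismatch
            k = min(16, L // 2)
            cands = np.union1d(self._seed_hits(q, k, 0), self._seed_hits(q, k, L - k))
        if cands.size == 0:
            return cands, cands
        n = self.codes.size
        cands = cands[(cands >= 0) & (cands + L <= n)]
        # placements must sit inside a single chromosome
        chrom_s = np.searchsorted(self.offsets, cands, side="right") - 1
        chrom_e = np.searchsorted(self.offsets, cands + L - 1, side="right") - 1
        cands = cands[chrom_s == chrom_e]
        if cands.size == 0:
            return cands, cands
        windows = self.codes[cands[:, None] + np.arange(L)[None, :]]
        # N never matches anything, including another N
        mism = ((windows != q[None, :]) | (windows == 4) | (q[None, :] == 4)).sum(axis=1)
        keep = mism <= max_mismatch
        return cands[keep], mism[keep]

    def search(
        self,
        seq: str,
        min_match: int,
        max_mismatch: int,
        max_loci: int,
    ) -> tuple[list[GenomicHit], int, bool]:
        """All end-to-end ungapped placements of ``seq`` on either strand.

        Returns (hits, n_loci, exceeds_max_loci).  When the locus count
        exceeds ``max_loci`` the hit list is empty and the flag is set; the
        caller drops the sequence, as the aligner contract prescribes.
        A placement needs ``len(seq) - mismatches >= min_match`` and
        ``mismatches <= max_mismatch``.
        """
        L = len(seq)
        eff_mismatch = min(max_mismatch, L - min_match)
        if eff_mismatch < 0:  # too short to ever reach min_match
            return [], 0, False
        hits: list[GenomicHit] = []
        for strand, query in (("+", seq), ("-", revcomp(seq))):
            pos, mism = self._strand_hits(query, eff_mismatch)
            chrom_idx = np.searchsorted(self.offsets, pos, side="right") - 1
            for p, m, ci in zip(pos.tolist(), mism.tolist(), chrom_idx.tolist()):
                start = p - int(self.offsets[ci])
                hits.append(
                    GenomicHit(
                        chrom=self.chrom_names[ci],
                        start=start,
                        end=start + L,
                        strand=strand,
                        mismatches=int(m),
                        matched_bases=L - int(m),
                    )
                )
        hits.sort(key=lambda h: (h.chrom, h.start, h.strand))
        n_loci = len(hits)
        if n_loci > max_loci:
            return [], n_loci, True
        return hits, n_loci, False


def search_brute_force(
    seq: str,
    genome: GenomeRef,
    min_match: int,
    max_mismatch: int,
    max_loci: int,
) -> tuple[list[GenomicHit], int, bool]:
    """Naive sliding-window scan over every position and both strands.

    Independent oracle for :meth:`UngappedIndex.search`: no seeding, no
    candidate generation — every window of every chromosome is compared in
    full (vectorised over positions so megabase references stay testable).
    """
    L = len(seq)
    eff_mismatch = min(max_mismatch, L - min_match)
    if eff_mismatch < 0:
        return [], 0, False
    hits: list[GenomicHit] = []
    queries = {"+": seq, "-": revcomp(seq)}
    n_code = ord("N")
    for strand, query in queries.items():
        q = np.frombuffer(query.encode("ascii"), dtype=np.uint8)
        q_is_n = q == n_code
        for chrom in genome.chrom_names:
            ref = np.frombuffer(genome.sequences[chrom].encode("ascii"), dtype=np.uint8)
            if ref.size < L:
                continue
            windows = np.lib.stride_tricks.sliding_window_view(ref, L)
            mism_counts = (
                (windows != q[None, :]) | (windows == n_code) | q_is_n[None, :]
            ).sum(axis=1)
            for start in np.nonzero(mism_counts <= eff_mismatch)[0].tolist():
                mism = int(mism_counts[start])
                hits.append(
                    GenomicHit(
                        chrom=chrom,
                        start=start,
                        end=start + L,
                        strand=strand,
                        mismatches=mism,
                        matched_bases=L - mism,
                    )
                )
    hits.sort(key=lambda h: (h.chrom, h.start, h.strand))
    n_loci = len(hits)
    if n_loci > max_loci:
        return [], n_loci, True
    return hits, n_loci, False
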