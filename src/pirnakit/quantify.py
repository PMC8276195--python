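"""Read pre-processing and the two quantification tracks.

Genomic track: 3' adapter trimming, ungapped genome alignment (>=14 matched
bases, <=1 mismatch, <=100 loci, no splicing) and strand-aware feature
counting with a choice of multimapper policy (unique / all / fractional).

Transcriptomic track: reads are matched to the annotation FASTA as ungapped
substrings (<=1 mismatch), grouped into transcript equivalence classes, and
abundances are estimated by expectation-maximisation with multinomial
bootstrap resampling of class counts for a per-transcript count SD.

The consensus operation combines the "expressed" feature sets of the two
tracks as union or intersection.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from pirnakit.align import UngappedIndex, encode_seq
from pirnakit.config import QuantParams
from pirnakit.forge import AnnotationTrack
from pirnakit.io import GenomeRef, GenomicHit, StageStats, logger

# ---------------------------------------------------------------------------
# Adapter trimming
# ---------------------------------------------------------------------------


@dataclass
class TrimmedRead:
    id: str
    sequence: str
    quality: str
    trimmed_bases: int


def _find_adapter(seq: str, adapter: str, max_error_rate: float, min_overlap: int = 3) -> int:
    """Leftmost 3' adapter start, or -1.

    Every position j is tested against the adapter prefix that fits in the
    remaining read (a full internal occurrence or a prefix hanging off the
    read end); a hit needs overlap >= min_overlap and mismatches <=
    floor(max_error_rate * overlap).  The leftmost acceptable j wins.
    """
    L = len(seq)
    for j in range(L - min_overlap + 1):
        m = min(len(adapter), L - j)
        allowed = int(max_error_rate * m)
        mism = 0
        for a, b in zip(seq[j : j + m], adapter[:m]):
            if a != b:
                mism += 1
                if mism > allowed:
                    break
        else:
            return j
    return -1


def trim_adapter(
    read: tuple[str, str, str],
    adapter: str,
    max_error_rate: float = 0.1,
    min_read_len: int = 15,
) -> TrimmedRead | None:
    """Trim the 3' adapter from one read; None when the insert is too short."""
    rid, seq, qual = read
    if not adapter:
        raise ValueError("adapter must be non-empty")
    j = _find_adapter(seq, adapter, max_error_rate)
    if j < 0:
        trimmed = TrimmedRead(rid, seq, qual, 0)
    else:
        trimmed = TrimmedRead(rid, seq[:j], qual[:j], len(seq) - j)
    if len(trimmed.sequence) < min_read_len:
        return None
    return trimmed


def trim_reads(
    reads: Iterable[tuple[str, str, str]],
    params: QuantParams,
    stats: StageStats | None = None,
    sample: str = "sample",
) -> list[TrimmedRead]:
    """Trim a whole library; discarded-too-short reads are counted."""
    kept: list[TrimmedRead] = []
    n_in = n_discarded = n_trimmed = 0
    for read in reads:
        n_in += 1
        t = trim_adapter(read, params.adapter, params.max_error_rate, params.min_read_len)
        if t is None:
            n_discarded += 1
            continue
        if t.trimmed_bases:
            n_trimmed += 1
        kept.append(t)
    if stats is not None:
        stats.log(f"trim[{sample}]", "input_reads", n_in)
        stats.log(f"trim[{sample}]", "adapter_trimmed", n_trimmed)
        stats.log(f"trim[{sample}]", "discarded_too_short", n_discarded)
        stats.log(f"trim[{sample}]", "kept", len(kept))
    return kept


# ---------------------------------------------------------------------------
# Genomic alignment
# ---------------------------------------------------------------------------


@dataclass
class ReadAlignment:
    read_id: str
    sequence: str
    hits: list[GenomicHit]
    n_hits: int
    clipped_3p: int = 0


def search_with_clip(
    index: UngappedIndex,
    seq: str,
    min_match: int,
    max_mismatch: int,
    max_loci: int,
    max_clip_3p: int = 2,
) -> tuple[list[GenomicHit], int, bool, int]:
    """Placement search with a bounded 3'-end soft clip fallback.

    A 3' adapter remnant shorter than the trimmer's minimum overlap (so at
    most min_overlap - 1 = 2 bases) survives trimming and breaks end-to-end
    placement; clipping up to that many 3' bases recovers it, mirroring how
    spliced aligners soft-clip read ends.  Clipping stops at the first clip
    depth that yields placements.
    """
    for clip in range(0, max_clip_3p + 1):
        q = seq[: len(seq) - clip] if clip else seq
        if len(q) < min_match:
            break
        hits, n_loci, too_many = index.search(q, min_match, max_mismatch, max_loci)
        if hits or too_many:
            return hits, n_loci, too_many, clip
    return [], 0, False, 0


def align_reads(
    reads: Sequence[TrimmedRead],
    index: UngappedIndex,
    params: QuantParams,
    stats: StageStats | None = None,
    sample: str = "sample",
) -> list[ReadAlignment]:
    """Align trimmed reads: ungapped, splice-free, both strands.

    Reads exceeding the multimap cap are reported unaligned; reads with
    non-ACGTN symbols are skipped and logged.  Identical read sequences are
    aligned once and the placements shared.
    """
    cache: dict[str, tuple[list[GenomicHit], int, bool, int]] = {}
    out: list[ReadAlignment] = []
    n_unique = n_multi = n_unaligned = n_bad = 0
    for read in reads:
        seq = read.sequence
        if seq not in cache:
            try:
                cache[seq] = search_with_clip(
                    index, seq, params.min_match, params.max_mismatch, params.max_loci
                )
            except ValueError:
                cache[seq] = ([], -1, False, 0)
        hits, n_loci, too_many, clip = cache[seq]
        if n_loci == -1:
            n_bad += 1
            continue
        if too_many or not hits:
            n_unaligned += 1
            out.append(ReadAlignment(read.id, seq, [], 0))
            continue
        if n_loci == 1:
            n_unique += 1
        else:
            n_multi += 1
        out.append(ReadAlignment(read.id, seq, hits, n_loci, clipped_3p=clip))
    if n_bad:
        logger.warning("align[%s]: skipped %d reads with non-ACGTN symbols", sample, n_bad)
    if stats is not None:
        stats.log(f"align[{sample}]", "input_reads", len(reads))
        stats.log(f"align[{sample}]", "uniquely_aligned", n_unique)
        stats.log(f"align[{sample}]", "multi_aligned", n_multi)
        stats.log(f"align[{sample}]", "unaligned", n_unaligned)
    return out


# ---------------------------------------------------------------------------
# Feature counting (genomic track)
# ---------------------------------------------------------------------------


@dataclass
class CountResult:
    counts: pd.Series  # indexed by feature id
    assigned: float
    ambiguous: int
    unassigned: int


def _feature_trees(track: AnnotationTrack) -> dict[tuple[str, str], IntervalTree]:
    trees: dict[tuple[str, str], IntervalTree] = {}
    for rec, hit in track.features:
        trees.setdefault((hit.chrom, hit.strand), IntervalTree()).addi(
            hit.start, hit.end, rec.primary_id
        )
    return trees


def count_features(
    read_alignments: Sequence[ReadAlignment],
    track: AnnotationTrack,
    mode: str = "fractional",
) -> CountResult:
    """Assign read placements to features and count them.

    A placement is assigned to a feature when their intervals overlap by at
    least one base on the same strand; a placement overlapping more than one
    distinct feature is ambiguous and dropped.  Multi-placed reads follow the
    ``mode`` policy: unique -> dropped, all -> +1 per assigned placement,
    fractional -> +1/n_hits per assigned placement.
    """
    if mode not in ("unique", "all", "fractional"):
        raise ValueError(f"unknown counting mode {mode!r}")
    trees = _feature_trees(track)
    feature_ids = sorted({rec.primary_id for rec, _ in track.features})
    counts: dict[str, float] = dict.fromkeys(feature_ids, 0.0)
    assigned = 0.0
    ambiguous = unassigned = 0
    for aln in read_alignments:
        if aln.n_hits == 0:
            continue
        if mode == "unique" and aln.n_hits > 1:
            continue
        placements: list[str] = []
        amb = False
        for hit in aln.hits:
            tree = trees.get((hit.chrom, hit.strand))
            overlaps = {iv.data for iv in tree.overlap(hit.start, hit.end)} if tree else set()
            if len(overlaps) > 1:
                amb = True
            elif len(overlaps) == 1:
                placements.append(next(iter(overlaps)))
        if amb:
            ambiguous += 1
            continue
        if not placements:
            unassigned += 1
            continue
        weight = 1.0 if mode != "fractional" else 1.0 / aln.n_hits
        for fid in placements:
            counts[fid] += weight
            assigned += weight
    return CountResult(
        counts=pd.Series(counts, name="count"),
        assigned=assigned,
        ambiguous=ambiguous,
        unassigned=unassigned,
    )


# ---------------------------------------------------------------------------
# Transcriptomic track: equivalence classes + EM
# ---------------------------------------------------------------------------


@dataclass
class EquivalenceClasses:
    transcript_ids: list[str]
    classes: list[tuple[tuple[int, ...], int]]  # (sorted transcript indices, read count)
    n_mapped: int
    n_unmapped: int


def build_equivalence_classes(
    reads: Sequence[TrimmedRead],
    transcripts: Sequence[tuple[str, str]],
    max_mismatch: int = 1,
) -> EquivalenceClasses:
    """Group reads by the set of transcripts containing them as a substring.

    Matching is ungapped, sense-strand, with <= ``max_mismatch`` mismatches
    (the libraries are stranded and reads are the mature molecules).
    """
    if not transcripts:
        raise ValueError("empty transcript set")
    tx_ids = [tid for tid, _ in transcripts]
    genome = GenomeRef(
        chrom_names=list(tx_ids),
        sequences={tid: seq for tid, seq in transcripts},
        standard_set=set(tx_ids),
    )
    index = UngappedIndex(genome)
    tx_pos = {tid: i for i, tid in enumerate(tx_ids)}
    cache: dict[str, tuple[int, ...]] = {}
    class_counts: dict[tuple[int, ...], int] = {}
    n_mapped = n_unmapped = 0
    for read in reads:
        seq = read.sequence
        if seq not in cache:
            hits: list[GenomicHit] = []
            try:
                for clip in range(0, 3):  # same bounded 3' clip as the genomic track
                    q = seq[: len(seq) - clip] if clip else seq
                    hits, _, _ = index.search(q, len(q) - max_mismatch, max_mismatch, 10**9)
                    if hits:
                        break
            except ValueError:
                hits = []
            members = tuple(sorted({tx_pos[h.chrom] for h in hits if h.strand == "+"}))
            cache[seq] = members
        members = cache[seq]
        if not members:
            n_unmapped += 1
            continue
        n_mapped += 1
        class_counts[members] = class_counts.get(members, 0) + 1
    classes = sorted(class_counts.items())
    return EquivalenceClasses(
        transcript_ids=list(tx_ids), classes=classes, n_mapped=n_mapped, n_unmapped=n_unmapped
    )


def _em_run(
    n_tx: int,
    class_members: list[np.ndarray],
    class_counts: np.ndarray,
    tol: float,
    max_iter: int,
) -> tuple[np.ndarray, list[float]]:
    """EM over equivalence classes; returns expected counts and log-likelihoods."""
    total = class_counts.sum()
    flat = np.concatenate(class_members) if class_members else np.empty(0, dtype=np.int64)
    class_of = np.concatenate(
        [np.full(len(m), i, dtype=np.int64) for i, m in enumerate(class_members)]
    ) if class_members else np.empty(0, dtype=np.int64)
    alpha = np.full(n_tx, total / n_tx, dtype=float)
    loglik: list[float] = []
    for _ in range(max_iter):
        class_sums = np.zeros(len(class_members))
        np.add.at(class_sums, class_of, alpha[flat])
        with np.errstate(divide="ignore"):
            loglik.append(float(np.sum(class_counts * (np.log(class_sums) - np.log(total)))))
        shares = alpha[flat] / class_sums[class_of] * class_counts[class_of]
        new_alpha = np.zeros(n_tx)
        np.add.at(new_alpha, flat, shares)
        delta = np.max(np.abs(new_alpha - alpha)) / total
        alpha = new_alpha
        if delta < tol:
            break
    return alpha, loglik


@dataclass
class TranscriptQuant:
    counts: pd.Series  # expected counts per transcript
    bootstrap_sd: pd.Series
    loglik_trace: list[float] = field(repr=False, default_factory=list)
    eq_classes: EquivalenceClasses | None = None


def quantify_transcripts(
    reads: Sequence[TrimmedRead],
    transcripts: Sequence[tuple[str, str]],
    params: QuantParams,
    seed: int = 0,
) -> TranscriptQuant:
    """Equivalence-class EM abundance estimation with bootstrap SDs.

    Expected counts sum to the number of mapped reads; the bootstrap
    resamples class counts multinomially (seeded) and reruns EM.
    """
    eq = build_equivalence_classes(reads, transcripts, params.max_mismatch)
    n_tx = len(eq.transcript_ids)
    members = [np.array(m, dtype=np.int64) for m, _ in eq.classes]
    counts = np.array([c for _, c in eq.classes], dtype=float)
    if counts.size == 0 or counts.sum() == 0:
        zero = pd.Series(0.0, index=eq.transcript_ids)
        return TranscriptQuant(counts=zero, bootstrap_sd=zero.copy(), eq_classes=eq)
    alpha, loglik = _em_run(n_tx, members, counts, params.em_tol, params.em_max_iter)
    rng = np.random.default_rng(seed)
    total = int(counts.sum())
    boots = np.empty((params.n_bootstraps, n_tx))
    probs = counts / counts.sum()
    for b in range(params.n_bootstraps):
        resampled = rng.multinomial(total, probs).astype(float)
        nonzero = resampled > 0
        boots[b], _ = _em_run(
            n_tx,
            [m for m, keep in zip(members, nonzero) if keep],
            resampled[nonzero],
            params.em_tol,
            params.em_max_iter,
        )
    sd = boots.std(axis=0, ddof=1) if params.n_bootstraps > 1 else np.zeros(n_tx)
    return TranscriptQuant(
        counts=pd.Series(alpha, index=eq.transcript_ids, name="count"),
        bootstrap_sd=pd.Series(sd, index=eq.transcript_ids, name="bootstrap_sd"),
        loglik_trace=loglik,
        eq_classes=eq,
    )


# ---------------------------------------------------------------------------
# Consensus
# ---------------------------------------------------------------------------


def consensus_expressed(
    genomic_expressed: set[str],
    transcriptomic_expressed: set[str],
    mode: str = "union",
    stats: StageStats | None = None,
) -> set[str]:
    """Union or intersection of the two tracks' expressed feature sets."""
    if mode == "union":
        result = genomic_expressed | transcriptomic_expressed
    elif mode == "intersection":
        result = genomic_expressed & transcriptomic_expressed
    else:
        raise ValueError(f"unknown consensus mode {mode!r}")
    if stats is not None:
        stats.log("consensus", "genomic_expressed", len(genomic_expressed))
        stats.log("consensus", "transcriptomic_expressed", len(transcriptomic_expressed))
        stats.log("consensus", mode, len(result))
    return result


def count_matrix(
    per_sample: dict[str, pd.Series], method: str
) -> pd.DataFrame:
    """Assemble per-sample count columns into a features x samples matrix."""
    df = pd.DataFrame(per_sample).fillna(0.0)
    df.attrs["method"] = method
    return df
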