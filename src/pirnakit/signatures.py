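"""piRNA sequence signatures: positional base bias and the ping-pong overlap.

Mature piRNAs carry a 5' uridine bias (1U) and — when produced by the
ping-pong amplification cycle — an adenine at position 10 (10A), because the
responder piRNA's 5' end sits exactly 10 nt inside the initiator.  The
module computes position 1-15 base-frequency matrices (logos drawn with T,
as sequencing reports thymine), exact binomial bias tests, per-group read
length distributions, per-base strand coverage, and the ping-pong profile:
a histogram of 5'-5' overlaps between opposite-strand read pairs with a
z-score of the 10-nt bin against the rest.

Overlap convention: an overlap of k means the plus-strand read's 5' end and
the minus-strand read's 5' end span k bases, i.e. the minus read's 5' end
(its rightmost genomic base) lies k-1 bases downstream of the plus read's
5' end::

    plus   5'-P=========>
    minus        <=========M-5'
               |--k--|          k = M - P + 1; ping-pong hallmark: k = 10
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import binomtest

from pirnakit.quantify import ReadAlignment

BASES = ("A", "C", "G", "T")


# ---------------------------------------------------------------------------
# Position frequency matrix and bias tests
# ---------------------------------------------------------------------------


@dataclass
class PositionFrequencyMatrix:
    freq: pd.DataFrame  # positions (1-based index) x bases
    coverage: pd.Series  # sequences covering each position
    n_sequences: int
    pseudocount: float

    def information_content(self) -> pd.Series:
        """Per-position information content in bits (0..2)."""
        p = self.freq.to_numpy(dtype=float)
        with np.errstate(divide="ignore", invalid="ignore"):
            ent = -np.nansum(np.where(p > 0, p * np.log2(p), 0.0), axis=1)
        return pd.Series(2.0 - ent, index=self.freq.index, name="bits")


def pfm(
    sequences: Sequence[str], positions: int = 15, pseudocount: float = 0.0
) -> PositionFrequencyMatrix:
    """Base frequencies over the first ``positions`` bases.

    Sequences shorter than ``positions`` contribute only to the positions
    they cover; each position is normalised by its own coverage (plus
    pseudocounts).
    """
    if not sequences:
        raise ValueError("pfm needs at least one sequence")
    counts = np.zeros((positions, 4))
    coverage = np.zeros(positions)
    base_idx = {b: i for i, b in enumerate(BASES)}
    for seq in sequences:
        for i, base in enumerate(seq[:positions].upper().replace("U", "T")):
            if base in base_idx:
                counts[i, base_idx[base]] += 1
                coverage[i] += 1
    counts += pseudocount
    denom = counts.sum(axis=1)
    denom[denom == 0] = np.nan
    freq = counts / denom[:, None]
    return PositionFrequencyMatrix(
        freq=pd.DataFrame(freq, index=range(1, positions + 1), columns=BASES),
        coverage=pd.Series(coverage, index=range(1, positions + 1)),
        n_sequences=len(sequences),
        pseudocount=pseudocount,
    )


def bias_test(
    matrix: PositionFrequencyMatrix, position: int, base: str, background: float = 0.25
) -> tuple[float, float]:
    """Observed base fraction at a position + exact two-sided binomial p."""
    if position not in matrix.freq.index:
        raise ValueError(f"position {position} outside the matrix")
    n = int(matrix.coverage.loc[position])
    if n == 0:
        raise ValueError(f"no sequence covers position {position}")
    frac = float(matrix.freq.loc[position, base.upper().replace("U", "T")])
    k = int(round(frac * n))
    p = binomtest(k, n, background, alternative="two-sided").pvalue
    return frac, float(p)


def bias_scan(
    matrix: PositionFrequencyMatrix, base: str, background: float = 0.25
) -> pd.DataFrame:
    """Bias test for one base at every position of the matrix."""
    rows = []
    for pos in matrix.freq.index:
        frac, p = bias_test(matrix, pos, base, background)
        rows.append({"position": pos, "base": base, "fraction": frac, "p_value": p})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Ping-pong signature
# ---------------------------------------------------------------------------


@dataclass
class PingPongProfile:
    overlap_counts: pd.Series  # index 1..20
    z10: float  # NaN when undefined

    @property
    def defined(self) -> bool:
        return np.isfinite(self.z10)


def pingpong(
    read_alignments: Iterable[ReadAlignment], max_overlap: int = 20
) -> PingPongProfile:
    """5'-5' overlap histogram of opposite-strand read pairs + 10-nt z-score.

    Multi-mapped reads contribute 1/n_hits per placement (consistent with
    fractional counting), so a pair's weight is the product of its reads'
    placement weights.  z10 compares the 10-nt bin against the mean and SD of
    the other bins; with fewer than two nonzero bins it is undefined (NaN).
    """
    plus_w: dict[str, dict[int, float]] = {}
    minus_w: dict[str, dict[int, float]] = {}
    for aln in read_alignments:
        if aln.n_hits == 0:
            continue
        w = 1.0 / aln.n_hits
        for hit in aln.hits:
            if hit.strand == "+":
                d = plus_w.setdefault(hit.chrom, {})
                d[hit.start] = d.get(hit.start, 0.0) + w  # 5' end of a + read
            else:
                d = minus_w.setdefault(hit.chrom, {})
                five = hit.end - 1  # 5' end of a - read is its rightmost base
                d[five] = d.get(five, 0.0) + w
    counts = np.zeros(max_overlap)
    for chrom, pw in plus_w.items():
        mw = minus_w.get(chrom)
        if not mw:
            continue
        for p5, wp in pw.items():
            for k in range(1, max_overlap + 1):
                wm = mw.get(p5 + k - 1)
                if wm:
                    counts[k - 1] += wp * wm
    series = pd.Series(counts, index=range(1, max_overlap + 1), name="pairs")
    others = np.delete(counts, 9)
    if np.count_nonzero(counts) >= 2 and others.std(ddof=1) > 0:
        z10 = float((counts[9] - others.mean()) / others.std(ddof=1))
    else:
        z10 = float("nan")
    return PingPongProfile(overlap_counts=series, z10=z10)


# ---------------------------------------------------------------------------
# Length distributions and strand coverage
# ---------------------------------------------------------------------------


def length_distribution(
    expressed: Mapping[str, Mapping[str, set[str]]],
    feature_lengths: Mapping[str, int],
) -> pd.DataFrame:
    """Feature-length barplot table per group per quantification method.

    ``expressed[method][group]`` is the set of expressed feature ids.
    """
    rows = []
    for method, by_group in sorted(expressed.items()):
        for group, feats in sorted(by_group.items()):
            lengths = pd.Series([feature_lengths[f] for f in feats if f in feature_lengths])
            for length, n in lengths.value_counts().sort_index().items():
                rows.append({"method": method, "group": group, "length": int(length), "n_features": int(n)})
    return pd.DataFrame(rows, columns=["method", "group", "length", "n_features"])


def strand_coverage(
    read_alignments: Iterable[ReadAlignment],
    chrom: str,
    start: int,
    end: int,
    chrom_length: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-base plus/minus coverage over [start, end), 1/n_hits weighted."""
    if start < 0 or end <= start or (chrom_length is not None and end > chrom_length):
        raise ValueError(f"region {chrom}:{start}-{end} outside genome bounds")
    n = end - start
    plus = np.zeros(n)
    minus = np.zeros(n)
    for aln in read_alignments:
        if aln.n_hits == 0:
            continue
        w = 1.0 / aln.n_hits
        for hit in aln.hits:
            if hit.chrom != chrom:
                continue
            lo = max(hit.start, start)
            hi = min(hit.end, end)
            if lo < hi:
                target = plus if hit.strand == "+" else minus
                target[lo - start : hi - start] += w
    return plus, minus
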