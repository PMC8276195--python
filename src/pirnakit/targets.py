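"""Complementarity-based mRNA target prediction for piRNAs.

A piRNA can guide cleavage or repression of a transcript it pairs with in
antisense.  The scanner slides each piRNA along every transcript region
(5UTR / CDS / 3UTR) looking for antisense duplexes in which the seed span
(piRNA positions 2-11) is perfectly complementary, total mismatches stay
within a budget, and G:U wobble pairs are tolerated outside the seed.  The
score is matched + 0.5 * wobbles; hit lists are sorted by score.

The scoring scheme is this module's own (versioned in output headers so runs
stay comparable); it deliberately ignores duplex thermodynamics.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from pirnakit.io import revcomp

SCORING_VERSION = "pirnakit-seedmatch-1"

REGIONS = ("5UTR", "CDS", "3UTR")


@dataclass
class TargetParams:
    seed_start: int = 2  # 1-based, inclusive
    seed_end: int = 11  # inclusive
    max_mismatches: int = 4
    max_wobbles: int = 4

    def validate(self) -> None:
        if not 1 <= self.seed_start <= self.seed_end:
            raise ValueError("bad seed span")
        if self.max_mismatches < 0 or self.max_wobbles < 0:
            raise ValueError("negative budgets")


@dataclass(frozen=True)
class TargetHit:
    pirna_id: str
    transcript_id: str
    region: str
    start: int  # 1-based position of the site in the region sequence
    matched: int
    wobbles: int
    mismatches: int
    score: float


def _classify_pair(pirna_base: str, target_base: str) -> str:
    """Pair type of a piRNA base with the target base it faces in the duplex."""
    complement = {"A": "T", "C": "G", "G": "C", "T": "A"}
    if complement.get(pirna_base) == target_base:
        return "match"
    if (pirna_base == "G" and target_base == "T") or (pirna_base == "T" and target_base == "G"):
        # G:U and U:G wobbles (T stands for the transcript's U)
        return "wobble"
    return "mismatch"


def scan_site(pirna: str, window: str, params: TargetParams) -> tuple[int, int, int] | None:
    """Evaluate one candidate site; returns (matched, wobbles, mismatches) or None.

    ``window`` is the target-region slice, same length as the piRNA, in its
    own 5'->3' orientation.  piRNA position j (1-based) faces window base
    L - j (0-based), because the duplex is antiparallel.
    """
    L = len(pirna)
    if len(window) != L:
        return None
    matched = wobbles = mismatches = 0
    for j in range(1, L + 1):
        kind = _classify_pair(pirna[j - 1], window[L - j])
        in_seed = params.seed_start <= j <= params.seed_end
        if kind == "match":
            matched += 1
        elif kind == "wobble" and not in_seed:
            wobbles += 1
        elif in_seed:
            return None  # seed must be perfectly complementary
        else:
            mismatches += 1
        if mismatches > params.max_mismatches or wobbles > params.max_wobbles:
            return None
    return matched, wobbles, mismatches


def predict_targets(
    pirna_seqs: Mapping[str, str],
    transcript_regions: Mapping[str, Mapping[str, str]] | Sequence[tuple[str, str, str]],
    params: TargetParams | None = None,
) -> list[TargetHit]:
    """Scan every (piRNA, transcript region) combination for antisense sites.

    ``transcript_regions`` maps transcript id -> {region: sequence} (or is a
    list of (transcript_id, region, sequence) triples).  Hits are returned
    sorted by decreasing score, then by (piRNA, transcript, region, start)
    so the output is order-invariant in its inputs.
    """
    if params is None:
        params = TargetParams()
    params.validate()
    if not pirna_seqs:
        raise ValueError("empty piRNA set")
    if not isinstance(transcript_regions, Mapping):
        mapping: dict[str, dict[str, str]] = {}
        for tid, region, seq in transcript_regions:
            mapping.setdefault(tid, {})[region] = seq
        transcript_regions = mapping
    hits: list[TargetHit] = []
    for pid in sorted(pirna_seqs):
        pirna = pirna_seqs[pid].upper().replace("U", "T")
        L = len(pirna)
        for tid in sorted(transcript_regions):
            for region in sorted(transcript_regions[tid]):
                seq = transcript_regions[tid][region].upper().replace("U", "T")
                for start in range(0, len(seq) - L + 1):
                    res = scan_site(pirna, seq[start : start + L], params)
                    if res is None:
                        continue
                    matched, wobbles, mismatches = res
                    hits.append(
                        TargetHit(
                            pirna_id=pid,
                            transcript_id=tid,
                            region=region,
                            start=start + 1,
                            matched=matched,
                            wobbles=wobbles,
                            mismatches=mismatches,
                            score=matched + 0.5 * wobbles,
                        )
                    )
    hits.sort(key=lambda h: (-h.score, h.pirna_id, h.transcript_id, h.region, h.start))
    return hits


def hits_table(hits: Sequence[TargetHit]) -> pd.DataFrame:
    """Tabular form of the hit list, with per-region tallies in ``attrs``."""
    df = pd.DataFrame([h.__dict__ for h in hits])
    if df.empty:
        df = pd.DataFrame(
            columns=[
                "pirna_id",
                "transcript_id",
                "region",
                "start",
                "matched",
                "wobbles",
                "mismatches",
                "score",
            ]
        )
    df.attrs["scoring_version"] = SCORING_VERSION
    df.attrs["per_region"] = df["region"].value_counts().to_dict() if len(df) else {}
    return df
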