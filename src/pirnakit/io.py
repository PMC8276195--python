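"""Readers and writers for the standard formats the toolkit touches.

External coordinates follow each format's convention (GTF: 1-based closed;
BED: 0-based half-open; SAM: 1-based).  Internally everything is 0-based
half-open; conversion happens only here, at the I/O boundary.

FASTA/FASTQ parsing is delegated to Bio.SeqIO; GTF/BED/TSV go through
pandas; SAM emission goes through pysam.  All writers are deterministic:
fixed ordering and fixed float formatting, so identical inputs give
byte-identical files.
"""

from __future__ import annotations

import gzip
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import pandas as pd
import pysam
from Bio import SeqIO

logger = logging.getLogger("pirnakit")
if not logger.handlers:
    _h = logging.StreamHandler(sys.stderr)
    _h.setFormatter(logging.Formatter("[pirnakit] %(levelname)s %(message)s"))
    logger.addHandler(_h)
    logger.setLevel(logging.INFO)

VALID_ALPHABET = set("ACGTN")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement of an upper-case DNA string."""
    return seq.translate(_COMPLEMENT)[::-1]


class ParseError(ValueError):
    """Raised when an input file violates its format contract."""


# ---------------------------------------------------------------------------
# Core containers
# ---------------------------------------------------------------------------


@dataclass
class GenomeRef:
    """A reference genome held in memory.

    chrom_names preserves file order; sequences are upper-case DNA;
    standard_set flags the chromosomes considered "standard" (autosomes +
    X/Y/MT by default).
    """

    chrom_names: list[str]
    sequences: dict[str, str]
    standard_set: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        for name in self.chrom_names:
            seq = self.sequences.get(name, "")
            if not seq:
                raise ValueError(f"chromosome {name!r} has an empty sequence")
            bad = set(seq) - VALID_ALPHABET
            if bad:
                raise ValueError(f"chromosome {name!r} contains invalid symbols {sorted(bad)}")
        if not self.standard_set <= set(self.chrom_names):
            raise ValueError("standard_set must be a subset of chrom_names")

    def __len__(self) -> int:
        return len(self.chrom_names)

    def chrom_length(self, name: str) -> int:
        return len(self.sequences[name])

    @classmethod
    def from_fasta(cls, path: str | Path, config=None) -> "GenomeRef":
        records = read_fasta(path)
        names = [rid for rid, _ in records]
        seqs = {rid: seq for rid, seq in records}
        if config is not None:
            std = {n for n in names if config.is_standard_chromosome(n)}
        else:
            std = set(names)
        return cls(chrom_names=names, sequences=seqs, standard_set=std)


@dataclass
class SampleSheet:
    """The sample table: sample_id, group, optional batch, FASTQ path."""

    table: pd.DataFrame  # columns: sample, group, batch (optional), fastq_path

    def __post_init__(self) -> None:
        required = {"sample", "group"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"sample sheet missing columns: {sorted(missing)}")
        if self.table["sample"].duplicated().any():
            dup = self.table.loc[self.table["sample"].duplicated(), "sample"].tolist()
            raise ValueError(f"duplicate sample ids: {dup}")
        if (self.table.groupby("group").size() < 1).any():  # pragma: no cover - groupby drops empties
            raise ValueError("every group needs at least one sample")

    @property
    def samples(self) -> list[str]:
        return self.table["sample"].tolist()

    @property
    def groups(self) -> pd.Series:
        return self.table.set_index("sample")["group"]

    def group_sizes(self) -> dict[str, int]:
        return self.table.groupby("group").size().to_dict()

    @classmethod
    def from_tsv(cls, path: str | Path) -> "SampleSheet":
        return cls(pd.read_csv(path, sep="\t", dtype=str))

    def to_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


@dataclass(frozen=True)
class GenomicHit:
    """One ungapped placement of a sequence or read on the genome.

    start/end are 0-based half-open; matched_bases = span length - mismatches.
    """

    chrom: str
    start: int
    end: int
    strand: str
    mismatches: int
    matched_bases: int

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("GenomicHit requires end > start")
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")


@dataclass
class GtfFeature:
    """One GTF line held internally in 0-based half-open coordinates."""

    chrom: str
    source: str
    feature_type: str
    start: int  # 0-based
    end: int  # half-open
    strand: str
    attributes: dict[str, str]

    @property
    def gene_id(self) -> str:
        return self.attributes.get("gene_id", "")


# ---------------------------------------------------------------------------
# FASTA / FASTQ
# ---------------------------------------------------------------------------


def _open_maybe_gzip(path: str | Path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read FASTA into (id, sequence) tuples, preserving file order.

    Sequences are upper-cased and RNA U is mapped to DNA T.  A record with an
    empty sequence or a file without any record is a parse error.
    """
    out: list[tuple[str, str]] = []
    with _open_maybe_gzip(path) as fh:
        for i, rec in enumerate(SeqIO.parse(fh, "fasta")):
            seq = str(rec.seq).upper().replace("U", "T")
            if not seq:
                raise ParseError(f"{path}: record {i + 1} ({rec.id!r}) has a blank sequence")
            out.append((rec.description.strip() or rec.id, seq))
    if not out:
        raise ParseError(f"{path}: no FASTA records found")
    return out


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for rid, seq in records:
            fh.write(f">{rid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fastq(path: str | Path) -> Iterator[tuple[str, str, str]]:
    """Iterate (id, sequence, quality-string) over plain or gzipped FASTQ."""
    with _open_maybe_gzip(path) as fh:
        n = 0
        while True:
            header = fh.readline()
            if not header:
                return
            seq_line = fh.readline()
            plus = fh.readline()
            qual_line = fh.readline()
            n += 1
            if not seq_line or not plus or not qual_line:
                raise ParseError(f"{path}: truncated FASTQ record {n}")
            seq = seq_line.rstrip("\n")
            qual = qual_line.rstrip("\n")
            if not header.startswith("@") or not plus.startswith("+"):
                raise ParseError(f"{path}: malformed FASTQ record {n}")
            if len(seq) != len(qual):
                raise ParseError(
                    f"{path}: record {n}: sequence length {len(seq)} != quality length {len(qual)}"
                )
            yield header[1:].split()[0], seq.upper().replace("U", "T"), qual


def write_fastq(records: Iterable[tuple[str, str, str]], path: str | Path) -> None:
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "wt") as fh:
        for rid, seq, qual in records:
            fh.write(f"@{rid}\n{seq}\n+\n{qual}\n")


# ---------------------------------------------------------------------------
# GTF
# ---------------------------------------------------------------------------

_GTF_COLUMNS = [
    "chrom",
    "source",
    "feature_type",
    "start",
    "end",
    "score",
    "strand",
    "frame",
    "attributes",
]


def _format_attributes(attrs: dict[str, str]) -> str:
    return " ".join(f'{k} "{v}";' for k, v in attrs.items())


def _parse_attributes(text: str) -> dict[str, str]:
    attrs: dict[str, str] = {}
    for chunk in text.strip().split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        if " " not in chunk:
            raise ParseError(f"malformed GTF attribute {chunk!r}")
        key, value = chunk.split(" ", 1)
        attrs[key] = value.strip().strip('"')
    return attrs


def write_gtf_features(features: Sequence[GtfFeature], path: str | Path) -> None:
    """Write GTF2.2 (attribute style `key "value";`), 1-based closed coordinates.

    Lines are ordered deterministically by (chrom, start, end, gene_id).
    Features with an empty interval are refused.
    """
    for f in features:
        if f.end <= f.start:
            raise ValueError(f"feature {f.gene_id!r}: end <= start in half-open coordinates")
    ordered = sorted(features, key=lambda f: (f.chrom, f.start, f.end, f.gene_id))
    with open(path, "w") as fh:
        for f in ordered:
            fh.write(
                "\t".join(
                    [
                        f.chrom,
                        f.source,
                        f.feature_type,
                        str(f.start + 1),
                        str(f.end),
                        ".",
                        f.strand,
                        ".",
                        _format_attributes(f.attributes),
                    ]
                )
                + "\n"
            )


def read_gtf(path: str | Path) -> list[GtfFeature]:
    """Parse a GTF file into internal 0-based half-open features."""
    out: list[GtfFeature] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 9:
                raise ParseError(f"{path}:{lineno}: expected 9 GTF columns, got {len(fields)}")
            chrom, source, ftype, start, end, _score, strand, _frame, attrs = fields
            out.append(
                GtfFeature(
                    chrom=chrom,
                    source=source,
                    feature_type=ftype,
                    start=int(start) - 1,
                    end=int(end),
                    strand=strand,
                    attributes=_parse_attributes(attrs),
                )
            )
    return out


# ---------------------------------------------------------------------------
# BED (TE track): 0-based half-open, 6 standard columns + class/family/gene
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TeInterval:
    chrom: str
    start: int
    end: int
    name: str
    strand: str
    te_class: str
    te_family: str
    te_gene: str


def read_te_bed(path: str | Path) -> list[TeInterval]:
    """Read a transposable-element BED file with class/family/gene extra columns.

    Malformed rows are skipped with a warning rather than aborting the run.
    """
    out: list[TeInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.rstrip("\n").split("\t")
            try:
                if len(fields) < 9:
                    raise ValueError(f"expected >=9 columns, got {len(fields)}")
                chrom, start, end, name, _score, strand = fields[:6]
                te_class, te_family, te_gene = fields[6:9]
                start_i, end_i = int(start), int(end)
                if end_i <= start_i:
                    raise ValueError("end <= start")
                out.append(
                    TeInterval(chrom, start_i, end_i, name, strand, te_class, te_family, te_gene)
                )
            except ValueError as exc:
                logger.warning("%s:%d: skipping malformed TE row (%s)", path, lineno, exc)
    return out


# ---------------------------------------------------------------------------
# SAM
# ---------------------------------------------------------------------------


def write_sam(
    alignments: Iterable[tuple[str, str, Sequence[GenomicHit]]],
    genome_ref: GenomeRef,
    path: str | Path,
) -> None:
    """Write read placements as SAM text.

    ``alignments`` yields (read_id, read_sequence, hits); one SAM line is
    emitted per placement with FLAG bit 16 on the minus strand and an NH tag
    carrying the placement count.  Placements on chromosomes absent from the
    reference are an error.
    """
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [
            {"SN": name, "LN": genome_ref.chrom_length(name)} for name in genome_ref.chrom_names
        ],
    }
    chrom_index = {name: i for i, name in enumerate(genome_ref.chrom_names)}
    with pysam.AlignmentFile(str(path), "w", header=header) as sam:
        for read_id, seq, hits in alignments:
            n = len(hits)
            for hit in hits:
                if hit.chrom not in chrom_index:
                    raise ValueError(f"alignment on unknown chromosome {hit.chrom!r}")
                a = pysam.AlignedSegment(sam.header)
                a.query_name = read_id
                a.reference_id = chrom_index[hit.chrom]
                a.reference_start = hit.start
                a.flag = 16 if hit.strand == "-" else 0
                a.mapping_quality = 255
                span = hit.end - hit.start
                a.cigarstring = f"{span}M"
                a.query_sequence = revcomp(seq) if hit.strand == "-" else seq
                a.set_tags([("NH", n, "i"), ("NM", hit.mismatches, "i")])
                sam.write(a)


# ---------------------------------------------------------------------------
# TSV count tables and stage statistics
# ---------------------------------------------------------------------------


def write_counts_tsv(counts: pd.DataFrame, path: str | Path) -> None:
    """Write a features x samples count table with stable ordering/formatting."""
    counts.sort_index().to_csv(path, sep="\t", float_format="%.6g", index_label="feature_id")


def read_counts_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="feature_id")


class StageStats:
    """Collects per-stage record counts; mirrors a pipeline statistics TSV.

    Every pipeline stage logs its input/output counts here and to stderr.
    """

    def __init__(self) -> None:
        self.rows: list[tuple[str, str, float]] = []

    def log(self, stage: str, key: str, value: float) -> None:
        self.rows.append((stage, key, value))
        logger.info("%s: %s = %s", stage, key, value)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows, columns=["stage", "metric", "value"])

    def write(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.6g")
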