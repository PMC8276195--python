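"""Annotation forging: build one harmonised sncRNA annotation track.

Two sequence databases — a piRNA-dedicated one (piRNABank-like; many ids per
molecule) and a general sncRNA one (RNAcentral-like; headers carry
``id|biotype``) — are collapsed to unique sequences, realigned ungapped to
the reference genome, length-filtered, biotype-reclassified, merged, and
annotated with genomic-region, multimapping, embedded-host and
transposable-element metadata.  The result is a GTF + FASTA pair plus three
metadata side-tables, with per-stage counts in a statistics TSV.

Stage order::

    collapse -> realign -> length_filter -> reclassify -> integrate
      -> standard-chromosome filter -> exclude_coding_overlap
      -> annotate_embedded -> find_genomic_regions -> intersect_te -> write
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from intervaltree import IntervalTree

from pirnakit.align import UngappedIndex
from pirnakit.config import RunConfig
from pirnakit.io import (
    GenomeRef,
    GenomicHit,
    GtfFeature,
    StageStats,
    TeInterval,
    logger,
    read_fasta,
    write_fasta,
    write_gtf_features,
)

BIOTYPES = {
    "piRNA",
    "miRNA",
    "rRNA",
    "tRNA",
    "snRNA",
    "snoRNA",
    "YRNA",
    "lncRNA_fragment",
    "other",
}


@dataclass
class SeqRecord:
    """A database sequence after collapsing: one record per distinct sequence."""

    primary_id: str
    alias_ids: set[str]
    sequence: str
    biotype: str = "piRNA"
    source_db: set[str] = field(default_factory=set)
    biotype_votes: set[str] = field(default_factory=set)
    reclass_ambiguous: bool = False

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class AnnotationTrack:
    """Merged feature set: (sequence record, genomic hit) pairs + metadata."""

    features: list[tuple[SeqRecord, GenomicHit]]
    region_info: dict[str, str] = field(default_factory=dict)  # seq id -> cluster|genic|both
    multimap_info: dict[str, int] = field(default_factory=dict)  # seq id -> locus count
    embedded_info: list[tuple[str, str, str]] = field(default_factory=list)
    te_info: pd.DataFrame | None = None
    coding_overlap_flags: dict[str, bool] = field(default_factory=dict)  # lenient mode

    @property
    def records(self) -> list[SeqRecord]:
        seen: dict[str, SeqRecord] = {}
        for rec, _ in self.features:
            seen.setdefault(rec.primary_id, rec)
        return list(seen.values())

    def to_gtf_features(self) -> list[GtfFeature]:
        out = []
        for rec, hit in self.features:
            attrs = {
                "gene_id": rec.primary_id,
                "gene_biotype": rec.biotype,
                "provenance": ",".join(sorted(rec.source_db)),
                "alias_ids": ",".join(sorted(rec.alias_ids)),
            }
            if rec.primary_id in self.region_info:
                attrs["genomic_region"] = self.region_info[rec.primary_id]
            if self.coding_overlap_flags.get(rec.primary_id):
                attrs["coding_overlap"] = "yes"
            out.append(
                GtfFeature(
                    chrom=hit.chrom,
                    source="pirnakit",
                    feature_type="sncRNA",
                    start=hit.start,
                    end=hit.end,
                    strand=hit.strand,
                    attributes=attrs,
                )
            )
        return out


# ---------------------------------------------------------------------------
# Parsing database FASTA headers
# ---------------------------------------------------------------------------


def load_database_fasta(path: str | Path, default_biotype: str = "piRNA") -> list[SeqRecord]:
    """Load a database dump: headers ``id`` or ``id|biotype``; one record each."""
    out = []
    for header, seq in read_fasta(path):
        first = header.split()[0]
        if "|" in first:
            rid, biotype = first.split("|", 1)
        else:
            rid, biotype = first, default_biotype
        out.append(SeqRecord(primary_id=rid, alias_ids={rid}, sequence=seq, biotype=biotype))
    return out


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------


def collapse_sequences(records: Iterable[SeqRecord]) -> list[SeqRecord]:
    """Collapse duplicate and multi-mapped ids: one record per distinct sequence.

    Alias ids are unioned; biotype votes of the merged inputs are retained so
    later reclassification can detect within-database ambiguity.  Output is
    ordered by first appearance of each sequence, which makes the operation
    deterministic and idempotent.
    """
    by_seq: dict[str, SeqRecord] = {}
    for rec in records:
        if rec.sequence in by_seq:
            tgt = by_seq[rec.sequence]
            tgt.alias_ids |= rec.alias_ids
            tgt.biotype_votes |= rec.biotype_votes or {rec.biotype}
            tgt.source_db |= rec.source_db
        else:
            by_seq[rec.sequence] = SeqRecord(
                primary_id=rec.primary_id,
                alias_ids=set(rec.alias_ids),
                sequence=rec.sequence,
                biotype=rec.biotype,
                source_db=set(rec.source_db),
                biotype_votes=set(rec.biotype_votes) or {rec.biotype},
            )
    return list(by_seq.values())


def realign_ungapped(
    records: Sequence[SeqRecord],
    index: UngappedIndex,
    min_match: int,
    max_mismatch: int,
    max_loci: int,
    hit_cache: dict[str, tuple[list[GenomicHit], int, bool]] | None = None,
) -> tuple[list[tuple[SeqRecord, list[GenomicHit]]], dict[str, int], list[str]]:
    """Realign each record to the genome; drop unmapped and over-multimapped ones.

    Returns (mapped records with hits, locus counts, dropped-as-exceeding ids).
    """
    mapped: list[tuple[SeqRecord, list[GenomicHit]]] = []
    loci: dict[str, int] = {}
    exceeded: list[str] = []
    cache = hit_cache if hit_cache is not None else {}
    for rec in records:
        key = rec.sequence
        if key not in cache:
            cache[key] = index.search(rec.sequence, min_match, max_mismatch, max_loci)
        hits, n_loci, too_many = cache[key]
        if too_many:
            exceeded.append(rec.primary_id)
            continue
        if hits:
            mapped.append((rec, hits))
            loci[rec.primary_id] = n_loci
    return mapped, loci, exceeded


def length_filter(records: Iterable[SeqRecord], max_len: int) -> list[SeqRecord]:
    """Keep sequences strictly shorter than ``max_len`` (default <100 nt)."""
    return [r for r in records if r.length < max_len]


def reclassify_biotypes(
    pirnabank_records: Sequence[SeqRecord],
    rnacentral_records: Sequence[SeqRecord],
) -> tuple[list[SeqRecord], pd.DataFrame]:
    """Re-categorise piRNA-database sequences using the general database.

    A piRNA-database sequence identical to a general-database sequence whose
    biotype is not piRNA takes that biotype.  If the matching sequence has
    two or more distinct non-piRNA biotypes the record is flagged ambiguous
    and stays piRNA.  A log table (old -> new biotype, matched id) is returned.
    """
    by_seq = {r.sequence: r for r in rnacentral_records}
    log_rows = []
    out = []
    for rec in pirnabank_records:
        match = by_seq.get(rec.sequence)
        new = SeqRecord(
            primary_id=rec.primary_id,
            alias_ids=set(rec.alias_ids),
            sequence=rec.sequence,
            biotype=rec.biotype,
            source_db=set(rec.source_db),
            biotype_votes=set(rec.biotype_votes),
        )
        if match is not None:
            non_pirna = {b for b in (match.biotype_votes or {match.biotype}) if b != "piRNA"}
            if len(non_pirna) == 1:
                new_biotype = next(iter(non_pirna))
                if new_biotype != rec.biotype:
                    log_rows.append(
                        {
                            "sequence_id": rec.primary_id,
                            "old_biotype": rec.biotype,
                            "new_biotype": new_biotype,
                            "matched_id": match.primary_id,
                            "status": "reclassified",
                        }
                    )
                    new.biotype = new_biotype
            elif len(non_pirna) > 1:
                new.reclass_ambiguous = True
                log_rows.append(
                    {
                        "sequence_id": rec.primary_id,
                        "old_biotype": rec.biotype,
                        "new_biotype": rec.biotype,
                        "matched_id": match.primary_id,
                        "status": "ambiguous",
                    }
                )
        out.append(new)
    log = pd.DataFrame(
        log_rows, columns=["sequence_id", "old_biotype", "new_biotype", "matched_id", "status"]
    )
    return out, log


def integrate_databases(
    pirnabank_records: Sequence[SeqRecord],
    rnacentral_records: Sequence[SeqRecord],
    pirnabank_max_len: int,
) -> tuple[list[SeqRecord], dict[str, int]]:
    """Merge the two databases into one feature set.

    All general-database records are kept; piRNA-database records enter only
    when strictly shorter than ``pirnabank_max_len`` (<69 nt).  Records whose
    sequences coincide become one feature with both provenance tags; the
    general database supplies the primary id, the piRNA-database ids stay as
    aliases.  Counts (common / each-only) are returned for the stats table.
    """
    merged: dict[str, SeqRecord] = {}
    seen_ids: dict[str, str] = {}
    for rec in rnacentral_records:
        if rec.primary_id in seen_ids and seen_ids[rec.primary_id] != rec.sequence:
            raise ValueError(f"id {rec.primary_id!r} reused for a different sequence")
        seen_ids[rec.primary_id] = rec.sequence
        merged[rec.sequence] = SeqRecord(
            primary_id=rec.primary_id,
            alias_ids=set(rec.alias_ids),
            sequence=rec.sequence,
            biotype=rec.biotype,
            source_db=set(rec.source_db) or {"rnacentral"},
            biotype_votes=set(rec.biotype_votes),
            reclass_ambiguous=rec.reclass_ambiguous,
        )
    counts = {"common": 0, "rnacentral_only": len(merged), "pirnabank_only": 0}
    for rec in pirnabank_records:
        if rec.length >= pirnabank_max_len:
            continue
        if rec.sequence in merged:
            tgt = merged[rec.sequence]
            tgt.alias_ids |= rec.alias_ids
            tgt.source_db |= set(rec.source_db) or {"pirnabank"}
            counts["common"] += 1
            counts["rnacentral_only"] -= 1
        else:
            if rec.primary_id in seen_ids and seen_ids[rec.primary_id] != rec.sequence:
                raise ValueError(f"id {rec.primary_id!r} reused for a different sequence")
            seen_ids[rec.primary_id] = rec.sequence
            merged[rec.sequence] = SeqRecord(
                primary_id=rec.primary_id,
                alias_ids=set(rec.alias_ids),
                sequence=rec.sequence,
                biotype=rec.biotype,
                source_db=set(rec.source_db) or {"pirnabank"},
                biotype_votes=set(rec.biotype_votes),
                reclass_ambiguous=rec.reclass_ambiguous,
            )
            counts["pirnabank_only"] += 1
    return list(merged.values()), counts


# -- gene-annotation interval helpers ---------------------------------------


def _build_trees(
    gene_features: Sequence[GtfFeature], predicate
) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for f in gene_features:
        if predicate(f):
            trees.setdefault(f.chrom, IntervalTree()).addi(f.start, f.end, f)
    return trees


def _gene_type(f: GtfFeature) -> str:
    return f.attributes.get("gene_type", f.attributes.get("gene_biotype", ""))


def exclude_coding_overlap(
    features: Sequence[tuple[SeqRecord, GenomicHit]],
    gene_annotation: Sequence[GtfFeature],
    stringent: bool,
) -> tuple[list[tuple[SeqRecord, GenomicHit]], dict[str, bool]]:
    """Remove (stringent) or flag (lenient) placements in protein-coding space.

    A placement is coding-overlapping when it intersects, by at least one
    base and on either strand, an exon or CDS of a protein-coding gene, or
    any CDS interval at all.
    """
    trees = _build_trees(
        gene_annotation,
        lambda f: (
            f.feature_type == "CDS"
            or (f.feature_type in ("exon", "CDS") and _gene_type(f) == "protein_coding")
        ),
    )
    kept: list[tuple[SeqRecord, GenomicHit]] = []
    flags: dict[str, bool] = {}
    for rec, hit in features:
        tree = trees.get(hit.chrom)
        overlapping = bool(tree is not None and tree.overlap(hit.start, hit.end))
        if overlapping:
            flags[rec.primary_id] = True
        if stringent and overlapping:
            continue
        kept.append((rec, hit))
    return kept, flags


def annotate_embedded(
    features: Sequence[tuple[SeqRecord, GenomicHit]],
    host_annotation: Sequence[GtfFeature],
    same_strand: bool = True,
) -> list[tuple[str, str, str]]:
    """piRNAs fully contained in a host sncRNA/lncRNA interval.

    Hosts are gene-level intervals of non-coding gene types.  Containment
    must be full and (by default) sense to the host.  Features themselves are
    untouched; only metadata rows are produced.
    """
    host_types = {"lncRNA", "snoRNA", "snRNA", "miRNA", "rRNA", "tRNA", "YRNA", "misc_RNA"}
    trees = _build_trees(
        host_annotation,
        lambda f: f.feature_type == "gene" and _gene_type(f) in host_types,
    )
    rows: list[tuple[str, str, str]] = []
    seen = set()
    for rec, hit in features:
        if rec.biotype != "piRNA":
            continue
        tree = trees.get(hit.chrom)
        if tree is None:
            continue
        for iv in sorted(tree.overlap(hit.start, hit.end)):
            host: GtfFeature = iv.data
            if not (host.start <= hit.start and hit.end <= host.end):
                continue
            if same_strand and host.strand != hit.strand:
                continue
            key = (rec.primary_id, host.gene_id)
            if key not in seen:
                seen.add(key)
                rows.append((rec.primary_id, host.gene_id, _gene_type(host)))
    return rows


def find_genomic_regions(
    features: Sequence[tuple[SeqRecord, GenomicHit]],
    max_gap: int,
    gene_annotation: Sequence[GtfFeature],
) -> tuple[dict[str, str], pd.DataFrame]:
    """Merge placements into regions and label each sequence's genomic origin.

    Placements within ``max_gap`` on the same chromosome (strand-agnostic)
    single-linkage-merge into a region.  A region overlapping any gene
    interval is "genic", otherwise a "cluster".  A sequence is labelled by
    the union of its regions' labels ("both" when mixed).
    """
    gene_trees = _build_trees(gene_annotation, lambda f: f.feature_type == "gene")
    by_chrom: dict[str, list[tuple[int, int, str]]] = {}
    for rec, hit in features:
        by_chrom.setdefault(hit.chrom, []).append((hit.start, hit.end, rec.primary_id))
    seq_labels: dict[str, set[str]] = {}
    region_rows = []
    for chrom in sorted(by_chrom):
        ivs = sorted(by_chrom[chrom])
        i = 0
        while i < len(ivs):
            r_start, r_end = ivs[i][0], ivs[i][1]
            members = [ivs[i][2]]
            j = i + 1
            while j < len(ivs) and ivs[j][0] - r_end <= max_gap:
                r_end = max(r_end, ivs[j][1])
                members.append(ivs[j][2])
                j += 1
            tree = gene_trees.get(chrom)
            label = "genic" if tree is not None and tree.overlap(r_start, r_end) else "cluster"
            region_rows.append(
                {
                    "chrom": chrom,
                    "start": r_start,
                    "end": r_end,
                    "label": label,
                    "n_placements": len(members),
                }
            )
            for m in members:
                seq_labels.setdefault(m, set()).add(label)
            i = j
    labels = {
        sid: ("both" if len(lbls) > 1 else next(iter(lbls))) for sid, lbls in seq_labels.items()
    }
    regions = pd.DataFrame(region_rows, columns=["chrom", "start", "end", "label", "n_placements"])
    return labels, regions


def intersect_te(
    features: Sequence[tuple[SeqRecord, GenomicHit]],
    te_intervals: Sequence[TeInterval],
) -> pd.DataFrame:
    """One metadata row per (placement, overlapping TE) with overlap length."""
    trees: dict[str, IntervalTree] = {}
    for te in te_intervals:
        trees.setdefault(te.chrom, IntervalTree()).addi(te.start, te.end, te)
    rows = []
    for rec, hit in features:
        tree = trees.get(hit.chrom)
        if tree is None:
            continue
        for iv in sorted(tree.overlap(hit.start, hit.end)):
            te: TeInterval = iv.data
            overlap = min(hit.end, te.end) - max(hit.start, te.start)
            rows.append(
                {
                    "sequence_id": rec.primary_id,
                    "chrom": hit.chrom,
                    "start": hit.start,
                    "end": hit.end,
                    "te_name": te.name,
                    "te_class": te.te_class,
                    "te_family": te.te_family,
                    "te_gene": te.te_gene,
                    "overlap_bp": overlap,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "sequence_id",
            "chrom",
            "start",
            "end",
            "te_name",
            "te_class",
            "te_family",
            "te_gene",
            "overlap_bp",
        ],
    )


# ---------------------------------------------------------------------------
# Full composition
# ---------------------------------------------------------------------------


@dataclass
class ForgeResult:
    track: AnnotationTrack
    reclassification_log: pd.DataFrame
    regions: pd.DataFrame
    stats: StageStats
    integrate_counts: dict[str, int]


def forge(
    config: RunConfig,
    pirna_db: Sequence[SeqRecord] | str | Path,
    sncrna_db: Sequence[SeqRecord] | str | Path,
    genome: GenomeRef,
    gene_annotation: Sequence[GtfFeature],
    te_intervals: Sequence[TeInterval],
) -> ForgeResult:
    """Run the full annotation-forging pipeline and return the track + logs."""
    p = config.forge
    stats = StageStats()
    if isinstance(pirna_db, (str, Path)):
        pirna_db = load_database_fasta(pirna_db, default_biotype="piRNA")
    if isinstance(sncrna_db, (str, Path)):
        sncrna_db = load_database_fasta(sncrna_db, default_biotype="other")
    for rec in pirna_db:
        rec.source_db = {"pirnabank"}
    for rec in sncrna_db:
        rec.source_db = {"rnacentral"}
    stats.log("input", "pirnabank_records", len(pirna_db))
    stats.log("input", "rnacentral_records", len(sncrna_db))

    pb = collapse_sequences(pirna_db)
    rc = collapse_sequences(sncrna_db)
    stats.log("collapse", "pirnabank_unique", len(pb))
    stats.log("collapse", "rnacentral_unique", len(rc))

    index = UngappedIndex(genome)
    cache: dict = {}
    pb_mapped, pb_loci, pb_exceeded = realign_ungapped(
        pb, index, p.min_match, p.max_mismatch, p.max_loci, hit_cache=cache
    )
    rc_mapped, rc_loci, rc_exceeded = realign_ungapped(
        rc, index, p.min_match, p.max_mismatch, p.max_loci, hit_cache=cache
    )
    for sid in pb_exceeded + rc_exceeded:
        logger.info("realign: %s exceeds max_loci, dropped", sid)
    stats.log("realign", "pirnabank_mapped", len(pb_mapped))
    stats.log("realign", "rnacentral_mapped", len(rc_mapped))
    stats.log("realign", "exceeds_max_loci", len(pb_exceeded) + len(rc_exceeded))

    hits_by_seq = {rec.sequence: hits for rec, hits in pb_mapped + rc_mapped}
    pb2 = length_filter([rec for rec, _ in pb_mapped], p.max_seq_len)
    rc2 = length_filter([rec for rec, _ in rc_mapped], p.max_seq_len)
    stats.log("length_filter", "pirnabank_kept", len(pb2))
    stats.log("length_filter", "rnacentral_kept", len(rc2))

    pb3, reclass_log = reclassify_biotypes(pb2, rc2)
    stats.log("reclassify", "reclassified", int((reclass_log["status"] == "reclassified").sum()))

    merged, integrate_counts = integrate_databases(pb3, rc2, p.pirnabank_max_len)
    for key, value in integrate_counts.items():
        stats.log("integrate", key, value)

    features: list[tuple[SeqRecord, GenomicHit]] = []
    multimap: dict[str, int] = {}
    for rec in merged:
        std_hits = [h for h in hits_by_seq[rec.sequence] if h.chrom in genome.standard_set]
        if not std_hits:
            continue
        multimap[rec.primary_id] = len(std_hits)
        for h in std_hits:
            features.append((rec, h))
    stats.log("standard_chromosomes", "sequences", len(multimap))
    stats.log("standard_chromosomes", "placements", len(features))

    features, coding_flags = exclude_coding_overlap(
        features, gene_annotation, stringent=p.stringent_coding_filter
    )
    if p.stringent_coding_filter:
        kept_ids = {rec.primary_id for rec, _ in features}
        multimap = {
            sid: sum(1 for rec, _ in features if rec.primary_id == sid) for sid in kept_ids
        }
    stats.log("coding_filter", "placements", len(features))
    stats.log("coding_filter", "sequences", len({rec.primary_id for rec, _ in features}))

    embedded = annotate_embedded(features, gene_annotation, same_strand=p.embedded_same_strand)
    stats.log("embedded", "pairs", len(embedded))

    region_labels, regions = find_genomic_regions(features, p.region_max_gap, gene_annotation)
    stats.log("regions", "n_regions", len(regions))

    te_info = intersect_te(features, te_intervals)
    stats.log("te", "overlap_rows", len(te_info))

    track = AnnotationTrack(
        features=features,
        region_info=region_labels,
        multimap_info=multimap,
        embedded_info=embedded,
        te_info=te_info,
        coding_overlap_flags=coding_flags,
    )
    return ForgeResult(
        track=track,
        reclassification_log=reclass_log,
        regions=regions,
        stats=stats,
        integrate_counts=integrate_counts,
    )


def write_forge_outputs(result: ForgeResult, out_dir: str | Path) -> dict[str, Path]:
    """Write GTF, FASTA and the three metadata side-files + stats TSV."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "gtf": out / "annotation.gtf",
        "fasta": out / "annotation.fasta",
        "regions": out / "Genomic_Region_info.tsv",
        "multimap": out / "Multimapping_piRNA_info.tsv",
        "te": out / "Transposable_Elements_info.tsv",
        "reclass": out / "reclassification_log.tsv",
        "stats": out / "forge_stats.tsv",
    }
    track = result.track
    write_gtf_features(track.to_gtf_features(), paths["gtf"])
    records = sorted(track.records, key=lambda r: r.primary_id)
    write_fasta(
        [(f"{r.primary_id}|{r.biotype}", r.sequence) for r in records], paths["fasta"]
    )
    pd.DataFrame(
        sorted(track.region_info.items()), columns=["sequence_id", "genomic_region"]
    ).to_csv(paths["regions"], sep="\t", index=False)
    pd.DataFrame(
        sorted(track.multimap_info.items()), columns=["sequence_id", "n_loci"]
    ).to_csv(paths["multimap"], sep="\t", index=False)
    track.te_info.to_csv(paths["te"], sep="\t", index=False)
    result.reclassification_log.to_csv(paths["reclass"], sep="\t", index=False)
    result.stats.write(paths["stats"])
    return paths
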