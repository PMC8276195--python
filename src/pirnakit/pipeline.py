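"""High-level pipeline runners used by the command-line interface.

Each runner wires the low-level operations of one pipeline stage together,
writes the stage's output files, and returns the in-memory results so that
the stages compose programmatically as well.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from pirnakit import de as de_mod
from pirnakit import quantify as qt
from pirnakit import stats as st
from pirnakit.align import UngappedIndex
from pirnakit.config import RunConfig
from pirnakit.forge import AnnotationTrack
from pirnakit.io import (
    GenomeRef,
    SampleSheet,
    StageStats,
    read_fastq,
    write_counts_tsv,
    write_sam,
)


def quant_genomic(
    config: RunConfig,
    genome: GenomeRef,
    track: AnnotationTrack,
    sheet: SampleSheet,
    out_dir: str | Path | None = None,
    reads_by_sample: dict[str, list[tuple[str, str, str]]] | None = None,
) -> tuple[pd.DataFrame, StageStats]:
    """Trim, align and count every library against the forged annotation."""
    stats = StageStats()
    index = UngappedIndex(genome)
    columns: dict[str, pd.Series] = {}
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
    for _, row in sheet.table.iterrows():
        sample = row["sample"]
        if reads_by_sample is not None:
            raw = reads_by_sample[sample]
        else:
            raw = list(read_fastq(row["fastq_path"]))
        trimmed = qt.trim_reads(raw, config.quant, stats, sample)
        alignments = qt.align_reads(trimmed, index, config.quant, stats, sample)
        result = qt.count_features(alignments, track, mode=config.quant.count_mode)
        stats.log(f"count[{sample}]", "assigned", result.assigned)
        stats.log(f"count[{sample}]", "ambiguous", result.ambiguous)
        stats.log(f"count[{sample}]", "unassigned", result.unassigned)
        columns[sample] = result.counts
        if out is not None:
            aligned = [
                (a.read_id, a.sequence, a.hits) for a in alignments if a.n_hits > 0
            ]
            write_sam(aligned, genome, out / f"{sample}.genomic.sam")
    matrix = qt.count_matrix(columns, method="genomic")
    if out is not None:
        write_counts_tsv(matrix, out / "counts_genomic.tsv")
        stats.write(out / "quant_genomic_stats.tsv")
    return matrix, stats


def quant_transcriptomic(
    config: RunConfig,
    transcripts: list[tuple[str, str]],
    sheet: SampleSheet,
    out_dir: str | Path | None = None,
    reads_by_sample: dict[str, list[tuple[str, str, str]]] | None = None,
    seed: int | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, StageStats]:
    """Equivalence-class EM quantification of every library."""
    stats = StageStats()
    seed = config.seed if seed is None else seed
    columns: dict[str, pd.Series] = {}
    sds: dict[str, pd.Series] = {}
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
    for i, (_, row) in enumerate(sheet.table.iterrows()):
        sample = row["sample"]
        if reads_by_sample is not None:
            raw = reads_by_sample[sample]
        else:
            raw = list(read_fastq(row["fastq_path"]))
        trimmed = qt.trim_reads(raw, config.quant, stats, sample)
        quant = qt.quantify_transcripts(
            trimmed, transcripts, config.quant, seed=(seed * 7919 + i) % (2**31)
        )
        if quant.eq_classes is not None:
            stats.log(f"em[{sample}]", "mapped", quant.eq_classes.n_mapped)
            stats.log(f"em[{sample}]", "unmapped", quant.eq_classes.n_unmapped)
            stats.log(f"em[{sample}]", "n_classes", len(quant.eq_classes.classes))
        columns[sample] = quant.counts
        sds[sample] = quant.bootstrap_sd
    matrix = qt.count_matrix(columns, method="transcriptomic")
    sd_matrix = pd.DataFrame(sds).fillna(0.0)
    if out is not None:
        write_counts_tsv(matrix, out / "counts_transcriptomic.tsv")
        write_counts_tsv(sd_matrix, out / "bootstrap_sd.tsv")
        stats.write(out / "quant_tx_stats.tsv")
    return matrix, sd_matrix, stats


def expressed_sets(
    config: RunConfig,
    genomic: pd.DataFrame,
    transcriptomic: pd.DataFrame,
    sheet: SampleSheet,
) -> tuple[set[str], set[str]]:
    """Per-track "expressed" feature sets under the shared low-count filter."""
    if set(genomic.columns) != set(transcriptomic.columns):
        raise ValueError("genomic and transcriptomic matrices cover different samples")
    sizes = sheet.group_sizes()
    kw = dict(
        cpm_threshold=config.stats.cpm_threshold,
        min_samples=config.stats.min_samples,
        group_sizes=sizes,
    )
    return (
        set(st.filter_low(genomic, **kw).kept),
        set(st.filter_low(transcriptomic, **kw).kept),
    )


def run_eda(
    config: RunConfig,
    counts: pd.DataFrame,
    sheet: SampleSheet,
    biotype_map: pd.Series | None = None,
    out_dir: str | Path | None = None,
    label: str = "genomic",
) -> dict:
    """Filter + normalise one matrix and emit the exploratory summaries."""
    filt = st.filter_low(
        counts,
        cpm_threshold=config.stats.cpm_threshold,
        min_samples=config.stats.min_samples,
        group_sizes=sheet.group_sizes(),
    )
    factors = {
        "TMM": st.tmm_factors(filt.counts, "TMM"),
        "TMMwsp": st.tmm_factors(filt.counts, "TMMwsp"),
        "RLE": st.rle_factors(filt.counts),
    }
    log_expr = st.cpm(filt.counts, factors["TMM"], log=True)
    results = {
        "filtered": filt,
        "factors": factors,
        "log_expr": log_expr,
        "rle_stats": st.rle_plot_stats(log_expr),
        "pca": st.ordination(log_expr, "PCA"),
        "mds": st.ordination(log_expr, "MDS", top=config.stats.mds_top_features),
        "clustering": st.cluster_samples(log_expr, "average"),
    }
    if biotype_map is not None:
        results["biodetection"] = st.biodetection(counts, biotype_map)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_counts_tsv(filt.counts, out / f"filtered_{label}.tsv")
        pd.DataFrame(factors).to_csv(out / f"size_factors_{label}.tsv", sep="\t")
        write_counts_tsv(log_expr, out / f"log2cpm_tmm_{label}.tsv")
        results["rle_stats"].to_csv(out / f"rle_stats_{label}.tsv", sep="\t")
        results["pca"][0].to_csv(out / f"pca_{label}.tsv", sep="\t")
        results["mds"][0].to_csv(out / f"mds_{label}.tsv", sep="\t")
        results["clustering"].correlation.to_csv(out / f"correlation_{label}.tsv", sep="\t")
        if biotype_map is not None:
            bio = results["biodetection"]
            bio.within_sample_pct.to_csv(out / f"biodetection_within_{label}.tsv", sep="\t")
            bio.detected_pct_of_biotype.to_csv(out / f"biodetection_detected_{label}.tsv", sep="\t")
            bio.count_quartiles.to_csv(out / f"countsbio_{label}.tsv", sep="\t", index=False)
    return results


def run_differential(
    config: RunConfig,
    genomic: pd.DataFrame,
    transcriptomic: pd.DataFrame,
    sheet: SampleSheet,
    out_dir: str | Path | None = None,
) -> dict:
    """Voom + moderated-t DE on both matrices, merged with consensus labels."""
    groups = sheet.groups
    batch = (
        sheet.table.set_index("sample")["batch"]
        if "batch" in sheet.table.columns and sheet.table["batch"].nunique() > 1
        else None
    )
    tables = {}
    for label, counts in (("genomic", genomic), ("transcriptomic", transcriptomic)):
        filt = st.filter_low(
            counts,
            cpm_threshold=config.stats.cpm_threshold,
            min_samples=config.stats.min_samples,
            group_sizes=sheet.group_sizes(),
        )
        factors = st.tmm_factors(filt.counts, "TMM")
        tables[label] = de_mod.run_de(filt.counts, groups, factors, batch=batch)
    merged = de_mod.merge_de(
        tables["genomic"],
        tables["transcriptomic"],
        mode=config.de.merge_mode,
        alpha=config.de.alpha,
    )
    updown = de_mod.classify_updown(merged, alpha=config.de.alpha)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for label, table in tables.items():
            table.to_csv(out / f"de_{label}.tsv", sep="\t", float_format="%.6g")
        merged.to_csv(out / "de_merged.tsv", sep="\t", float_format="%.6g")
        pd.Series(
            {k: updown[k] for k in ("n_up", "n_down", "n_discordant")}
        ).to_csv(out / "de_updown_summary.tsv", sep="\t", header=False)
    return {"per_method": tables, "merged": merged, "updown": updown}
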