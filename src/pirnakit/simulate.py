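"""Seeded generators for every input the toolkit consumes, with planted truth.

The generator emulates the study conditions end to end at toy scale: two
sequence databases with duplicate ids, biotype conflicts and over-long
entries; a random genome carrying planted single- and multi-locus sncRNAs,
piRNA clusters, protein-coding genes (for the coding-overlap filter),
non-coding host genes (for embedded-piRNA metadata), transposable elements
and a non-standard chromosome; and small RNA-seq libraries with negative
binomial feature expression, four spike-in piRNA-like species at known input
ratios (two 2'-O-methylated, two not), optional periodate treatment that
depletes non-methylated molecules by a factor delta, 3' adapters and
per-base sequencing errors.

Every generator is a pure function of (spec, seed): the same spec yields
byte-identical files.  Truth tables are rich enough to score every
downstream module without re-deriving anything by hand.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from pirnakit.config import RunConfig
from pirnakit.io import GenomeRef, GenomicHit, GtfFeature, TeInterval, revcomp, write_fasta, write_fastq, write_gtf_features
from pirnakit.quantify import ReadAlignment

BASES = np.array(list("ACGT"))

SPIKE_SPECIES = (
    # (name, length, methylated) — two unmethylated and two methylated, 22/28 nt
    ("SS-22", 22, False),
    ("SS-28", 28, False),
    ("mSS-22", 22, True),
    ("mSS-28", 28, True),
)


@dataclass
class SampleDesign:
    name: str
    group: str
    batch: str = "b1"
    spike_scale: float = 1.0  # relative spike-in input (dilution series: 1, 10, 100)
    periodate_delta: float = 1.0  # depletion factor for non-methylated species (1 = untreated)


def default_samples() -> list[SampleDesign]:
    return [SampleDesign(f"{g}{i + 1}", g) for g in ("A", "B") for i in range(3)]


def dilution_samples(scales: tuple[float, ...] = (1.0, 10.0, 100.0)) -> list[SampleDesign]:
    names = ["dil_A", "dil_B", "dil_C"]
    return [SampleDesign(n, "dilution", spike_scale=s) for n, s in zip(names, scales)]


def periodate_samples(delta: float = 0.05, n_pairs: int = 1) -> list[SampleDesign]:
    out = []
    for i in range(n_pairs):
        out.append(SampleDesign(f"untreated_{i + 1}", "untreated"))
        out.append(SampleDesign(f"treated_{i + 1}", "treated", periodate_delta=delta))
    return out


@dataclass
class FixtureSpec:
    """Layout and expression model of the synthetic study."""

    seed: int = 0
    # genome
    n_chroms: int = 2
    chrom_len: int = 500_000
    nonstandard_chrom_len: int = 20_000
    # planted sncRNAs
    n_cluster_pirnas: int = 80  # in n_clusters piRNA clusters
    n_clusters: int = 8
    n_intergenic_pirnas: int = 60
    n_genic_pirnas: int = 12  # intronic in protein-coding genes
    n_multilocus: int = 10  # extra piRNAs planted at 2-4 loci
    n_exceed_loci: int = 2  # planted at > max_loci copies -> dropped
    n_in_cds: int = 8  # inside CDS -> removed in stringent mode
    n_embedded: int = 3  # inside non-coding hosts, same strand
    n_embedded_antisense: int = 1  # inside a host, opposite strand -> no metadata row
    n_nonstandard: int = 5  # on the non-standard chromosome -> dropped
    n_other: dict = field(
        default_factory=lambda: {
            "miRNA": 25,
            "tRNA": 15,
            "snoRNA": 15,
            "snRNA": 10,
            "rRNA": 8,
            "YRNA": 5,
        }
    )
    n_conflicts: int = 10  # in both DBs, general DB says non-piRNA -> reclassified
    n_ambiguous: int = 2  # general DB lists the sequence under 2 non-piRNA biotypes
    n_long_db: int = 5  # >=100 nt -> length-filtered
    n_pirnabank_long: int = 5  # 69..98 nt, piRNA-DB only -> dropped at integration
    pirnabank_common_fraction: float = 0.6  # piRNAs present in BOTH databases
    pirnabank_dup_ids: int = 3  # ids per sequence in the piRNA DB (collapse fodder)
    pirna_len: tuple[int, int] = (26, 33)  # half-open
    pirna_u1_bias: float = 0.9  # 5' uridine bias
    pirna_a10_bias: float = 0.6  # position-10 adenine bias
    other_len: dict = field(
        default_factory=lambda: {
            "miRNA": (21, 24),
            "tRNA": (70, 90),
            "snoRNA": (60, 90),
            "snRNA": (55, 90),
            "rRNA": (30, 60),
            "YRNA": (30, 50),
        }
    )
    max_loci: int = 100
    # genes / TEs
    n_coding_genes: int = 10
    n_host_genes: int = 6
    n_te: int = 12
    # expression + sequencing
    samples: list[SampleDesign] = field(default_factory=default_samples)
    reads_per_sample: int = 50_000
    nb_dispersion: float = 0.2
    n_de_up: int = 20
    n_de_down: int = 10
    de_logfc: float = 2.0
    spike_base_mean: float = 200.0
    adapter: str = "TGGAATTCTCGGGTGCCAAGG"
    read_len: int = 50
    error_rate: float = 0.001

    def validate(self) -> None:
        if self.n_cluster_pirnas % self.n_clusters:
            raise ValueError("n_cluster_pirnas must divide evenly into n_clusters")
        for s in self.samples:
            if not 0 < s.periodate_delta <= 1:
                raise ValueError("periodate delta must be in (0, 1]")


# ---------------------------------------------------------------------------


@dataclass
class PlantedFeature:
    uid: str  # final primary id expected after forging
    sequence: str
    biotype: str  # expected final biotype
    methylated: bool
    in_pirnabank: bool
    in_rnacentral: bool
    pb_ids: list[str] = field(default_factory=list)
    rc_entries: list[tuple[str, str]] = field(default_factory=list)  # (id, listed biotype)
    placements: list[tuple[str, int, str]] = field(default_factory=list)  # chrom, start, strand
    category: str = "intergenic"
    expected_region: str = ""  # cluster | genic | both | "" (not in track)
    drop_reason: str = ""  # "" = survives stringent forging
    surviving_placements: list[tuple[str, int, str]] = field(default_factory=list)
    embedded_host: str = ""

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class Fixture:
    spec: FixtureSpec
    genome: GenomeRef
    gene_features: list[GtfFeature]
    te_intervals: list[TeInterval]
    pirna_db: list[tuple[str, str]]  # FASTA records (id, seq)
    sncrna_db: list[tuple[str, str]]  # headers id|biotype
    features: list[PlantedFeature]
    truth: pd.DataFrame  # one row per planted feature
    expected_gtf: pd.DataFrame  # expected stringent-forge placements
    expression: pd.DataFrame | None = None  # per-feature per-group NB means + logFC

    def expressed_feature_ids(self) -> list[str]:
        return self.truth.loc[self.truth["drop_reason"] == "", "uid"].tolist()


class _Allocator:
    """Hands out non-overlapping genome intervals with safety gaps.

    The inter-allocation gap exceeds the region-merge distance, so features
    from different allocations never coalesce into one region by accident.
    """

    def __init__(self, rng: np.random.Generator, chrom_lens: dict[str, int], gap: int = 2000):
        self.rng = rng
        self.cursors = {c: 100 for c in chrom_lens}
        self.lens = chrom_lens
        self.gap = gap

    def take(self, length: int, chrom: str | None = None, gap: int | None = None) -> tuple[str, int]:
        gap = self.gap if gap is None else gap
        if chrom is None:
            chrom = min(self.cursors, key=lambda c: self.cursors[c] / self.lens[c])
        start = self.cursors[chrom]
        if start + length + gap > self.lens[chrom]:
            raise ValueError(f"fixture layout overflow on {chrom}")
        self.cursors[chrom] = start + length + gap + int(self.rng.integers(0, 500))
        return chrom, start


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(BASES[rng.integers(0, 4, size=length)])


def _biased_base(rng: np.random.Generator, base: str, prob: float) -> str:
    """Draw ``base`` with exactly ``prob``, else uniformly from the other three."""
    if rng.random() < prob:
        return base
    others = [b for b in "ACGT" if b != base]
    return others[rng.integers(0, 3)]


def _pirna_seq(rng: np.random.Generator, spec: FixtureSpec, length: int) -> str:
    seq = list(_random_seq(rng, length))
    seq[0] = _biased_base(rng, "T", spec.pirna_u1_bias)
    if length > 10:
        seq[9] = _biased_base(rng, "A", spec.pirna_a10_bias)
    return "".join(seq)


def make_genome_and_databases(spec: FixtureSpec) -> Fixture:
    """Build genome FASTA, gene GTF, TE BED, both database FASTAs and truth."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    std_chroms = [f"chr{i + 1}" for i in range(spec.n_chroms)]
    ns_chrom = "chrUn_random1"
    chrom_lens = {c: spec.chrom_len for c in std_chroms}
    chrom_lens[ns_chrom] = spec.nonstandard_chrom_len
    genome_arr = {c: BASES[rng.integers(0, 4, size=n)] for c, n in chrom_lens.items()}
    alloc = _Allocator(rng, {c: spec.chrom_len for c in std_chroms})
    ns_alloc = _Allocator(rng, {ns_chrom: spec.nonstandard_chrom_len}, gap=500)

    features: list[PlantedFeature] = []
    used_seqs: set[str] = set()
    serial = {"pb": 0, "rc": 0, "f": 0}

    def fresh_seq(maker, *args) -> str:
        for _ in range(100):
            s = maker(*args)
            if s not in used_seqs and revcomp(s) not in used_seqs:
                used_seqs.add(s)
                return s
        raise RuntimeError("could not draw a fresh sequence")

    def plant(seq: str, chrom: str, start: int, strand: str, arr=None) -> None:
        target = genome_arr[chrom] if arr is None else arr
        payload = seq if strand == "+" else revcomp(seq)
        target[start : start + len(seq)] = list(payload)

    def new_feature(seq: str, biotype: str, *, in_pb: bool, in_rc: bool, methylated=None,
                    category="intergenic", rc_biotypes=None) -> PlantedFeature:
        serial["f"] += 1
        pb_ids = []
        rc_entries = []
        if in_pb:
            n_ids = spec.pirnabank_dup_ids
            for _ in range(n_ids):
                serial["pb"] += 1
                pb_ids.append(f"hsa_piR_{serial['pb']:06d}")
        if in_rc:
            for bt in rc_biotypes or [biotype]:
                serial["rc"] += 1
                rc_entries.append((f"URS{serial['rc']:07d}", bt))
        uid = rc_entries[0][0] if rc_entries else (pb_ids[0] if pb_ids else f"f{serial['f']}")
        if methylated is None:
            methylated = biotype == "piRNA"
        feat = PlantedFeature(
            uid=uid,
            sequence=seq,
            biotype=biotype,
            methylated=methylated,
            in_pirnabank=in_pb,
            in_rnacentral=in_rc,
            pb_ids=pb_ids,
            rc_entries=rc_entries,
            category=category,
        )
        features.append(feat)
        return feat

    def in_both() -> bool:
        return bool(rng.random() < spec.pirnabank_common_fraction)

    def pirna_feature(category: str, **kw) -> PlantedFeature:
        length = int(rng.integers(*spec.pirna_len))
        seq = fresh_seq(_pirna_seq, rng, spec, length)
        if in_both():
            in_pb = in_rc = True
        elif rng.random() < 0.5:  # piRNA-database only (length < 69 keeps it at merge)
            in_pb, in_rc = True, False
        else:
            in_pb, in_rc = False, True
        return new_feature(seq, "piRNA", in_pb=in_pb, in_rc=in_rc, category=category, **kw)

    # -- protein-coding genes: exon1+CDS / intron / exon2+CDS ----------------
    gene_features: list[GtfFeature] = []
    gene_layouts = []
    for gi in range(spec.n_coding_genes):
        span = 5000
        chrom, start = alloc.take(span)
        strand = "+" if rng.random() < 0.5 else "-"
        gid = f"GENE{gi + 1:03d}"
        attrs = {"gene_id": gid, "gene_type": "protein_coding"}
        parts = [
            ("gene", start, start + span),
            ("exon", start, start + 300),
            ("CDS", start + 100, start + 300),
            ("exon", start + 4700, start + 5000),
            ("CDS", start + 4700, start + 4900),
        ]
        for ftype, s, e in parts:
            gene_features.append(GtfFeature(chrom, "sim", ftype, s, e, strand, dict(attrs)))
        gene_layouts.append((gid, chrom, start, span, strand))

    # -- non-coding host genes ----------------------------------------------
    host_layouts = []
    for hi in range(spec.n_host_genes):
        span = 2000
        chrom, start = alloc.take(span)
        strand = "+" if rng.random() < 0.5 else "-"
        host_type = "lncRNA" if hi % 2 == 0 else "snoRNA"
        gid = f"HOST{hi + 1:03d}"
        gene_features.append(
            GtfFeature(chrom, "sim", "gene", start, start + span, strand,
                       {"gene_id": gid, "gene_type": host_type})
        )
        host_layouts.append((gid, chrom, start, span, strand, host_type))

    # -- piRNA clusters ------------------------------------------------------
    per_cluster = spec.n_cluster_pirnas // spec.n_clusters
    for ci in range(spec.n_clusters):
        members = []
        total = 0
        for _ in range(per_cluster):
            f = pirna_feature("cluster")
            members.append(f)
            total += f.length + 150
        chrom, start = alloc.take(total + 200)
        pos = start
        for f in members:
            strand = "+" if rng.random() < 0.5 else "-"
            plant(f.sequence, chrom, pos, strand)
            f.placements.append((chrom, pos, strand))
            f.expected_region = "cluster"
            pos += f.length + 50 + int(rng.integers(0, 100))

    # -- isolated intergenic piRNAs and other sncRNAs ------------------------
    def plant_single(f: PlantedFeature, region_label: str = "cluster") -> None:
        chrom, start = alloc.take(f.length)
        strand = "+" if rng.random() < 0.5 else "-"
        plant(f.sequence, chrom, start, strand)
        f.placements.append((chrom, start, strand))
        f.expected_region = region_label

    for _ in range(spec.n_intergenic_pirnas):
        plant_single(pirna_feature("intergenic"))
    for biotype, n in spec.n_other.items():
        lo, hi = spec.other_len[biotype]
        for _ in range(n):
            seq = fresh_seq(_random_seq, rng, int(rng.integers(lo, hi)))
            f = new_feature(seq, biotype, in_pb=False, in_rc=True, category="other_sncRNA")
            plant_single(f)

    # -- intronic (genic) piRNAs --------------------------------------------
    for i in range(spec.n_genic_pirnas):
        gid, chrom, gstart, span, gstrand = gene_layouts[i % len(gene_layouts)]
        f = pirna_feature("genic_intronic")
        offset = 600 + (i // len(gene_layouts)) * 400 + int(rng.integers(0, 200))
        pos = gstart + offset  # inside the intron (300..4700)
        strand = "+" if rng.random() < 0.5 else "-"
        plant(f.sequence, chrom, pos, strand)
        f.placements.append((chrom, pos, strand))
        f.expected_region = "genic"

    # -- piRNAs inside CDS: removed by the stringent filter ------------------
    for i in range(spec.n_in_cds):
        gid, chrom, gstart, span, gstrand = gene_layouts[i % len(gene_layouts)]
        f = pirna_feature("in_cds")
        pos = gstart + 120 + (i // len(gene_layouts)) * 40  # inside CDS1 (100..300)
        strand = "+" if rng.random() < 0.5 else "-"
        plant(f.sequence, chrom, pos, strand)
        f.placements.append((chrom, pos, strand))
        f.drop_reason = "coding_overlap"

    # -- embedded piRNAs inside hosts ----------------------------------------
    for i in range(spec.n_embedded + spec.n_embedded_antisense):
        gid, chrom, hstart, span, hstrand, htype = host_layouts[i % len(host_layouts)]
        f = pirna_feature("embedded" if i < spec.n_embedded else "embedded_antisense")
        pos = hstart + 400 + (i // len(host_layouts)) * 300
        strand = hstrand if i < spec.n_embedded else ("-" if hstrand == "+" else "+")
        plant(f.sequence, chrom, pos, strand)
        f.placements.append((chrom, pos, strand))
        f.expected_region = "genic"
        if i < spec.n_embedded:
            f.embedded_host = gid

    # -- multi-locus piRNAs --------------------------------------------------
    for i in range(spec.n_multilocus):
        f = pirna_feature("multilocus")
        n_copies = int(rng.integers(2, 5))
        labels = set()
        for c in range(n_copies):
            if i == 0 and c == 0:  # one sequence spans cluster AND genic space -> "both"
                gid, chrom, gstart, span, gstrand = gene_layouts[-1]
                pos = gstart + 3000
                strand = "+"
                labels.add("genic")
            else:
                chrom, pos = alloc.take(f.length)
                strand = "+" if rng.random() < 0.5 else "-"
                labels.add("cluster")
            plant(f.sequence, chrom, pos, strand)
            f.placements.append((chrom, pos, strand))
        f.expected_region = "both" if len(labels) > 1 else labels.pop()

    # -- over-multimapped sequences: dropped by the aligner cap --------------
    for _ in range(spec.n_exceed_loci):
        length = int(rng.integers(*spec.pirna_len))
        seq = fresh_seq(_pirna_seq, rng, spec, length)
        f = new_feature(seq, "piRNA", in_pb=True, in_rc=False, category="exceeds_loci")
        n_copies = spec.max_loci + 1
        chrom, start = alloc.take(n_copies * (length + 10))
        pos = start
        for _ in range(n_copies):
            plant(f.sequence, chrom, pos, "+")
            f.placements.append((chrom, pos, "+"))
            pos += length + 10
        f.drop_reason = "exceeds_max_loci"

    # -- non-standard chromosome features ------------------------------------
    for _ in range(spec.n_nonstandard):
        f = pirna_feature("nonstandard")
        chrom, start = ns_alloc.take(f.length)
        plant(f.sequence, chrom, start, "+")
        f.placements.append((chrom, start, "+"))
        f.drop_reason = "nonstandard_chromosome"

    # -- biotype conflicts: both DBs, general DB disagrees -------------------
    conflict_biotypes = ["snoRNA", "snRNA", "miRNA", "rRNA", "YRNA"]
    for i in range(spec.n_conflicts):
        bt = conflict_biotypes[i % len(conflict_biotypes)]
        length = int(rng.integers(*spec.pirna_len))
        seq = fresh_seq(_pirna_seq, rng, spec, length)
        f = new_feature(seq, bt, in_pb=True, in_rc=True, category="conflict", rc_biotypes=[bt])
        plant_single(f)
    for _ in range(spec.n_ambiguous):
        length = int(rng.integers(*spec.pirna_len))
        seq = fresh_seq(_pirna_seq, rng, spec, length)
        f = new_feature(
            seq, "snoRNA", in_pb=True, in_rc=True, category="ambiguous_conflict",
            rc_biotypes=["snoRNA", "snRNA"],
        )
        plant_single(f)

    # -- length-filter fodder -------------------------------------------------
    for _ in range(spec.n_long_db):
        seq = fresh_seq(_random_seq, rng, int(rng.integers(100, 120)))
        f = new_feature(seq, "piRNA", in_pb=True, in_rc=True, category="too_long")
        chrom, start = alloc.take(f.length)
        plant(f.sequence, chrom, start, "+")
        f.placements.append((chrom, start, "+"))
        f.drop_reason = "length_filter"
    for _ in range(spec.n_pirnabank_long):
        seq = fresh_seq(_random_seq, rng, int(rng.integers(69, 99)))
        f = new_feature(seq, "piRNA", in_pb=True, in_rc=False, category="pirnabank_long")
        chrom, start = alloc.take(f.length)
        plant(f.sequence, chrom, start, "+")
        f.placements.append((chrom, start, "+"))
        f.drop_reason = "pirnabank_length_rule"

    # -- spike-ins: planted in the genome and present in both databases ------
    for name, length, methylated in SPIKE_SPECIES:
        seq = fresh_seq(_random_seq, rng, length)
        f = new_feature(seq, "piRNA", in_pb=True, in_rc=True, methylated=methylated,
                        category="spike_in")
        f.uid = name  # spike-ins keep their species name as the feature id
        f.rc_entries = [(name, "piRNA")]
        f.pb_ids = [f"{name}_pb"]
        plant_single(f)

    # -- transposable elements ------------------------------------------------
    te_intervals: list[TeInterval] = []
    te_classes = [("LINE", "L1", "L1HS"), ("SINE", "Alu", "AluY"), ("LTR", "ERVL", "ERVL-E")]
    te_targets = [f for f in features if f.category in ("intergenic", "cluster") and f.placements]
    for ti in range(spec.n_te):
        cls = te_classes[ti % len(te_classes)]
        if ti < min(6, len(te_targets)):  # TEs overlapping planted features
            f = te_targets[ti]
            chrom, pos, strand = f.placements[0]
            s = max(0, pos - 20)
            e = pos + f.length + int(rng.integers(10, 60))
        else:  # background TEs in unallocated space
            chrom, s = alloc.take(300)
            e = s + 300
            strand = "+"
        te_intervals.append(
            TeInterval(chrom, s, e, f"TE{ti + 1:03d}", strand, cls[0], cls[1], cls[2])
        )

    # -- assemble database FASTA records (deterministic order) ---------------
    pirna_db: list[tuple[str, str]] = []
    sncrna_db: list[tuple[str, str]] = []
    for f in features:
        for pid in f.pb_ids:
            pirna_db.append((pid, f.sequence))
        for rid, bt in f.rc_entries:
            sncrna_db.append((f"{rid}|{bt}", f.sequence))

    genome = GenomeRef(
        chrom_names=std_chroms + [ns_chrom],
        sequences={c: "".join(arr) for c, arr in genome_arr.items()},
        standard_set=set(std_chroms),
    )

    # -- expected forge outcome ----------------------------------------------
    for f in features:
        if f.drop_reason in ("", "coding_overlap"):
            std = [p for p in f.placements if p[0] != ns_chrom]
            if f.drop_reason == "coding_overlap":
                f.surviving_placements = []
            else:
                f.surviving_placements = std
        else:
            f.surviving_placements = []
    truth = pd.DataFrame(
        [
            {
                "uid": f.uid,
                "sequence": f.sequence,
                "length": f.length,
                "biotype": f.biotype,
                "methylated": f.methylated,
                "in_pirnabank": f.in_pirnabank,
                "in_rnacentral": f.in_rnacentral,
                "category": f.category,
                "n_loci": len(f.placements),
                "expected_region": f.expected_region if not f.drop_reason else "",
                "embedded_host": f.embedded_host,
                "drop_reason": f.drop_reason,
                "n_surviving_placements": len(f.surviving_placements),
            }
            for f in features
        ]
    )
    gtf_rows = []
    for f in features:
        for chrom, pos, strand in f.surviving_placements:
            gtf_rows.append(
                {
                    "chrom": chrom,
                    "start": pos,
                    "end": pos + f.length,
                    "strand": strand,
                    "gene_id": f.uid,
                    "gene_biotype": f.biotype,
                }
            )
    expected_gtf = (
        pd.DataFrame(gtf_rows)
        .sort_values(["chrom", "start", "end", "gene_id"])
        .reset_index(drop=True)
    )

    fixture = Fixture(
        spec=spec,
        genome=genome,
        gene_features=gene_features,
        te_intervals=te_intervals,
        pirna_db=pirna_db,
        sncrna_db=sncrna_db,
        features=features,
        truth=truth,
        expected_gtf=expected_gtf,
    )
    _attach_expression(fixture, rng)
    return fixture


def _attach_expression(fixture: Fixture, rng: np.random.Generator) -> None:
    """NB expression model over surviving features, with planted DE truth."""
    spec = fixture.spec
    expressed = [f for f in fixture.features if f.surviving_placements]
    n = len(expressed)
    base = rng.lognormal(mean=np.log(60.0), sigma=1.0, size=n)
    spikes = np.array([f.category == "spike_in" for f in expressed])
    base[spikes] = spec.spike_base_mean
    # scale the non-spike features to roughly hit the per-sample read budget
    non_spike_total = base[~spikes].sum()
    budget = max(spec.reads_per_sample - base[spikes].sum(), 1.0)
    base[~spikes] *= budget / max(non_spike_total, 1.0)
    de_candidates = [i for i, f in enumerate(expressed)
                     if f.category != "spike_in" and base[i] >= 5.0]
    rng.shuffle(de_candidates)
    n_up, n_down = spec.n_de_up, spec.n_de_down
    up_idx = de_candidates[:n_up]
    down_idx = de_candidates[n_up : n_up + n_down]
    logfc = np.zeros(n)
    logfc[up_idx] = spec.de_logfc
    logfc[down_idx] = -spec.de_logfc
    fixture.expression = pd.DataFrame(
        {
            "uid": [f.uid for f in expressed],
            "sequence": [f.sequence for f in expressed],
            "methylated": [f.methylated for f in expressed],
            "is_spike": spikes,
            "mean_A": base,
            "mean_B": base * 2.0**logfc,
            "true_logfc": logfc,
        }
    ).set_index("uid")


def simulate_reads(
    fixture: Fixture, sample: SampleDesign, seed: int
) -> tuple[list[tuple[str, str, str]], pd.Series]:
    """One library: (id, sequence, quality) reads + true fragment counts.

    Fragment counts are negative binomial around the group mean (Poisson for
    spike-ins, whose input is controlled); spike-in means scale with the
    sample's dilution factor and non-methylated species are multiplied by the
    periodate depletion factor delta.  Reads are insert + adapter, truncated
    to the machine read length, with iid per-base errors.
    """
    spec = fixture.spec
    expr = fixture.expression
    if expr is None:
        raise ValueError("fixture has no expression model")
    rng = np.random.default_rng(seed)
    # the second group level in sorted order carries the planted fold changes,
    # matching the contrast of a two-group design matrix (second over first);
    # single-group designs use the baseline means
    levels = sorted({s.group for s in spec.samples})
    mean_col = "mean_B" if len(levels) > 1 and sample.group == levels[1] else "mean_A"
    mu = expr[mean_col].to_numpy().copy()
    mu[expr["is_spike"].to_numpy()] *= sample.spike_scale
    if sample.periodate_delta < 1.0:
        mu[~expr["methylated"].to_numpy()] *= sample.periodate_delta
    disp = spec.nb_dispersion
    is_spike = expr["is_spike"].to_numpy()
    counts = np.zeros(len(mu), dtype=int)
    # NB as gamma-Poisson; spike-ins pure Poisson (their input is pipetted, not biological)
    nb_mask = ~is_spike
    shape = 1.0 / disp
    lam = rng.gamma(shape, mu[nb_mask] * disp)
    counts[nb_mask] = rng.poisson(lam)
    counts[is_spike] = rng.poisson(mu[is_spike])
    reads: list[tuple[str, str, str]] = []
    serial = 0
    seqs = expr["sequence"].tolist()
    for i, c in enumerate(counts):
        insert = seqs[i]
        for _ in range(c):
            serial += 1
            full = (insert + spec.adapter)[: spec.read_len]
            arr = np.frombuffer(full.encode(), dtype=np.uint8).copy()
            errs = np.nonzero(rng.random(arr.size) < spec.error_rate)[0]
            for e in errs:
                choices = [b for b in b"ACGT" if b != arr[e]]
                arr[e] = choices[rng.integers(0, 3)]
            seq = arr.tobytes().decode()
            reads.append((f"{sample.name}_r{serial:06d}", seq, "I" * len(seq)))
    order = rng.permutation(len(reads))
    reads = [reads[i] for i in order]
    truth = pd.Series(counts, index=expr.index, name=sample.name)
    return reads, truth


def simulate_all_reads(
    fixture: Fixture,
) -> tuple[dict[str, list[tuple[str, str, str]]], pd.DataFrame]:
    """All libraries of the design; per-sample seeds derive from the spec seed."""
    libs = {}
    truths = {}
    for i, s in enumerate(fixture.spec.samples):
        reads, truth = simulate_reads(fixture, s, seed=(fixture.spec.seed * 1009 + i) % (2**31))
        libs[s.name] = reads
        truths[s.name] = truth
    return libs, pd.DataFrame(truths)


# ---------------------------------------------------------------------------
# Ping-pong placement simulator
# ---------------------------------------------------------------------------


def simulate_pingpong(
    n_pairs: int = 200,
    n_background: int = 200,
    overlap: int = 10,
    read_len: int = 28,
    genome_len: int = 100_000,
    chrom: str = "pp1",
    seed: int = 0,
) -> list[ReadAlignment]:
    """Opposite-strand read pairs with an exact k-nt 5' overlap plus uniform noise.

    Each signal pair contributes a plus read whose 5' end is at p and a minus
    read whose 5' end is at p + overlap - 1; background reads fall uniformly
    on both strands.  Setting ``n_pairs=0`` gives pure noise.
    """
    rng = np.random.default_rng(seed)
    out: list[ReadAlignment] = []
    serial = 0

    def add(start: int, strand: str) -> None:
        nonlocal serial
        serial += 1
        hit = GenomicHit(chrom, start, start + read_len, strand, 0, read_len)
        out.append(ReadAlignment(f"pp_r{serial}", "", [hit], 1))

    for _ in range(n_pairs):
        p = int(rng.integers(read_len, genome_len - 2 * read_len))
        add(p, "+")
        m5 = p + overlap - 1  # 5' end of the minus read
        add(m5 - read_len + 1, "-")
    for _ in range(n_background):
        add(int(rng.integers(0, genome_len - read_len)), "+" if rng.random() < 0.5 else "-")
    return out


# ---------------------------------------------------------------------------
# File emission
# ---------------------------------------------------------------------------


def write_fixture(fixture: Fixture, out_dir: str | Path, write_reads: bool = True) -> dict[str, Path]:
    """Write the complete input bundle + truth/ tables for a fixture."""
    out = Path(out_dir)
    (out / "truth").mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    paths["genome"] = out / "genome.fasta"
    write_fasta(
        [(c, fixture.genome.sequences[c]) for c in fixture.genome.chrom_names], paths["genome"]
    )
    paths["gene_gtf"] = out / "genes.gtf"
    write_gtf_features(fixture.gene_features, paths["gene_gtf"])
    paths["te_bed"] = out / "te.bed"
    with open(paths["te_bed"], "w") as fh:
        for te in fixture.te_intervals:
            fh.write(
                f"{te.chrom}\t{te.start}\t{te.end}\t{te.name}\t0\t{te.strand}\t"
                f"{te.te_class}\t{te.te_family}\t{te.te_gene}\n"
            )
    paths["pirna_db"] = out / "pirna_db.fasta"
    write_fasta(fixture.pirna_db, paths["pirna_db"])
    paths["sncrna_db"] = out / "sncrna_db.fasta"
    write_fasta(fixture.sncrna_db, paths["sncrna_db"])
    paths["truth_features"] = out / "truth" / "features.tsv"
    fixture.truth.to_csv(paths["truth_features"], sep="\t", index=False)
    paths["truth_gtf"] = out / "truth" / "expected_gtf.tsv"
    fixture.expected_gtf.to_csv(paths["truth_gtf"], sep="\t", index=False)
    if fixture.expression is not None:
        paths["truth_expression"] = out / "truth" / "expression.tsv"
        fixture.expression.to_csv(paths["truth_expression"], sep="\t")
    rows = []
    if write_reads:
        libs, truth_counts = simulate_all_reads(fixture)
        paths["truth_counts"] = out / "truth" / "counts.tsv"
        truth_counts.to_csv(paths["truth_counts"], sep="\t", index_label="feature_id")
        for s in fixture.spec.samples:
            fq = out / f"{s.name}.fastq.gz"
            write_fastq(libs[s.name], fq)
            rows.append(
                {"sample": s.name, "group": s.group, "batch": s.batch, "fastq_path": str(fq)}
            )
    else:
        for s in fixture.spec.samples:
            rows.append({"sample": s.name, "group": s.group, "batch": s.batch, "fastq_path": ""})
    paths["samples"] = out / "samples.tsv"
    pd.DataFrame(rows).to_csv(paths["samples"], sep="\t", index=False)
    return paths


def default_run_config(spec: FixtureSpec) -> RunConfig:
    """A RunConfig matched to a fixture's adapter and seed."""
    cfg = RunConfig()
    cfg.quant = replace(cfg.quant, adapter=spec.adapter)
    cfg.seed = spec.seed
    return cfg
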