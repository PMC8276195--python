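"""Shared fixtures: a small planted study generated once per session."""

from __future__ import annotations

import logging

import pytest

from pirnakit.config import RunConfig
from pirnakit.forge import SeqRecord, forge
from pirnakit.simulate import (
    FixtureSpec,
    default_run_config,
    make_genome_and_databases,
    simulate_reads,
)

logging.getLogger("pirnakit").setLevel(logging.WARNING)


def small_spec(seed: int = 2, **overrides) -> FixtureSpec:
    """A compact study layout: every forge rule exercised, quick to align."""
    base = dict(
        seed=seed,
        chrom_len=250_000,
        n_cluster_pirnas=40,
        n_clusters=4,
        n_intergenic_pirnas=20,
        n_genic_pirnas=6,
        n_multilocus=4,
        n_exceed_loci=1,
        n_in_cds=4,
        n_other={"miRNA": 8, "tRNA": 5, "snoRNA": 5, "snRNA": 3, "rRNA": 3, "YRNA": 2},
        reads_per_sample=5_000,
    )
    base.update(overrides)
    return FixtureSpec(**base)


def db_records(fixture):
    """The two database FASTA payloads as SeqRecord lists."""
    pb = [
        SeqRecord(primary_id=rid, alias_ids={rid}, sequence=seq)
        for rid, seq in fixture.pirna_db
    ]
    rc = []
    for header, seq in fixture.sncrna_db:
        rid, biotype = header.split("|")
        rc.append(SeqRecord(primary_id=rid, alias_ids={rid}, sequence=seq, biotype=biotype))
    return pb, rc


@pytest.fixture(scope="session")
def fixture():
    return make_genome_and_databases(small_spec())


@pytest.fixture(scope="session")
def run_config(fixture) -> RunConfig:
    return default_run_config(fixture.spec)


@pytest.fixture(scope="session")
def forge_result(fixture, run_config):
    pb, rc = db_records(fixture)
    return forge(
        run_config, pb, rc, fixture.genome, fixture.gene_features, fixture.te_intervals
    )


@pytest.fixture(scope="session")
def sample_reads(fixture):
    """One simulated library (group A, sample 1) with its true counts."""
    return simulate_reads(fixture, fixture.spec.samples[0], seed=11)
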