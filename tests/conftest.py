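import numpy as np
import pandas as pd
import pytest

from promcore import SimConfig, simulate
from promcore.clustering import TSC


def make_fragments(rows):
    """Fragment table from (chrom, strand, cap, insert_end, sig, lib) tuples."""
    return pd.DataFrame(
        rows,
        columns=["chrom", "strand", "cap_pos", "insert_end", "splice_signature", "library_id"],
    )


def make_tsc(
    positions,
    counts,
    chrom="chr1",
    strand="+",
    tsc_id="T1",
    libraries=("lib1",),
    total_tpm=100.0,
):
    """One-library TSC with boundaries computed from the counts."""
    from promcore.clustering import tsc_boundaries

    positions = np.asarray(positions, dtype=np.int64)
    counts = np.asarray(counts, dtype=np.int64).reshape(len(positions), -1)
    lo, hi, dom = tsc_boundaries(positions, counts.sum(axis=1), strand)
    return TSC(
        id=tsc_id,
        chrom=chrom,
        strand=strand,
        positions=positions,
        counts=counts,
        libraries=list(libraries),
        boundary_start=lo,
        boundary_end=hi,
        dominant_pos=dom,
        total_tpm=total_tpm,
    )


@pytest.fixture(scope="session")
def small_sim():
    """A modest synthetic experiment shared across tests (300 genes,
    3 libraries, default 10%/10% artifact rates)."""
    config = SimConfig(
        genome_length=2_500_000,
        n_genes=300,
        n_libraries=3,
        reads_per_library=15_000,
        seed=11,
    )
    genome, genes, truth, fragments = simulate(config)
    return {
        "config": config,
        "genome": genome,
        "genes": genes,
        "truth": truth,
        "fragments": fragments,
    }


@pytest.fixture(scope="session")
def small_pipeline(small_sim):
    """Full pipeline (cluster -> filters -> assignment) on small_sim."""
    from promcore import (
        assign_tsc,
        classify_adjacency,
        run_clustering,
        tgag_enrichment_filter,
        truncation_filter,
    )

    tscs, totals = run_clustering(small_sim["fragments"])
    kept, _, _ = tgag_enrichment_filter(
        tscs, small_sim["genome"], small_sim["genes"], seed=0
    )
    kept, _, _ = truncation_filter(kept, small_sim["fragments"], small_sim["genes"])
    assignments = classify_adjacency(
        assign_tsc(kept, small_sim["fragments"], small_sim["genes"])
    )
    return {
        "tscs": tscs,
        "filtered": kept,
        "totals": totals,
        "assignments": assignments,
    }


@pytest.fixture(scope="session")
def clean_sim():
    """Artifact-free synthetic experiment (null behaviour checks)."""
    config = SimConfig(
        genome_length=2_000_000,
        n_genes=250,
        n_libraries=2,
        reads_per_library=15_000,
        artifact_tgag_rate=0.0,
        artifact_truncation_rate=0.0,
        seed=7,
    )
    genome, genes, truth, fragments = simulate(config)
    return {
        "config": config,
        "genome": genome,
        "genes": genes,
        "truth": truth,
        "fragments": fragments,
    }
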