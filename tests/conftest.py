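from __future__ import annotations

import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from rrbsdiff import meth_quant, rrbs_sim, synth_genome
from rrbsdiff.io import PipelineConfig
from rrbsdiff.pipeline import run_pipeline


@pytest.fixture(scope="session")
def small_genome():
    """Compact genome + catalogue shared by read-only tests."""
    return synth_genome.generate_genome(
        n_contigs=1, contig_length=80_000, n_promoters=6, n_repeats=9,
        n_imprinted_clusters=1, cpg_island_fraction=0.5, seed=11,
    )


@pytest.fixture(scope="session")
def small_states(small_genome):
    genome, catalogue = small_genome
    return synth_genome.assign_methylation_states(
        genome, catalogue, synth_genome.default_profiles(), seed=12
    )


@pytest.fixture(scope="session")
def small_counts(small_genome, small_states):
    genome, _ = small_genome
    fragments = rrbs_sim.size_select(rrbs_sim.digest_mspi(genome))
    plan = {f"{ct}_rep{r}": ct for ct in small_states.columns for r in (1, 2)}
    return rrbs_sim.simulate_counts(
        fragments, small_states, mean_coverage=30.0, sample_plan=plan, seed=13
    )


@pytest.fixture(scope="session")
def small_gated(small_counts, small_states):
    wide = meth_quant.to_wide(small_counts)
    groups = {ct: [f"{ct}_rep1", f"{ct}_rep2"] for ct in small_states.columns}
    return meth_quant.filter_coverage(meth_quant.merge_replicates(wide, groups))


@pytest.fixture(scope="session")
def demo_config():
    """Reduced end-to-end configuration used by pipeline-level tests."""
    return PipelineConfig(seed=7, n_contigs=2, contig_length=100_000,
                          n_promoters=16, n_repeats=24,
                          n_imprinted_clusters=2)


@pytest.fixture(scope="session")
def demo_run(demo_config, tmp_path_factory):
    outdir = tmp_path_factory.mktemp("demo_run")
    manifest = run_pipeline(demo_config, outdir)
    return demo_config, outdir, manifest
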