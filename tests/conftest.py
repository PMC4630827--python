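import dataclasses

import pytest

from multicnv import AnchorSet, synthetic_data as sd, pipeline as pl


@pytest.fixture(scope="session")
def default_cohort():
    """Two-batch, 170-samples-per-batch cohort at generator defaults."""
    return sd.simulate_cohort(sd.SimConfig(seed=7))


@pytest.fixture(scope="session")
def default_cohort_results(default_cohort):
    """Per-batch pipeline results (anchored k selection) on the default cohort."""
    cohort = default_cohort
    anchor_sets = {b: AnchorSet(lst)
                   for b, lst in cohort.truth.anchors.items()}
    results, discarded = pl.call_copy_number(
        cohort.depth, cohort.gene_map, cohort.block_genes,
        pl.PipelineConfig(seed=11), anchor_sets)
    return results, discarded


@pytest.fixture(scope="session")
def merged_batch_results(default_cohort):
    """Same cohort analysed as one pooled batch (centres collapsed)."""
    from multicnv import targets_io

    cohort = default_cohort
    merged_samples = [dataclasses.replace(s, centre="MERGED")
                      for s in cohort.depth.samples]
    depth = targets_io.DepthMatrix(
        cohort.depth.targets, merged_samples, cohort.depth.counts,
        cohort.depth.total_mapped_reads)
    anchors = {"MERGED:EUR": AnchorSet(
        [a for lst in cohort.truth.anchors.values() for a in lst])}
    results, _ = pl.call_copy_number(
        depth, cohort.gene_map, cohort.block_genes,
        pl.PipelineConfig(seed=11), anchors)
    return results


@pytest.fixture(scope="session")
def clone_counts_path():
    from importlib.resources import files

    return str(files("multicnv") / "data" / "clone_counts_validation.tsv")
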