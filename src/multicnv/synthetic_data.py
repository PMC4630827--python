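"""Synthetic cohorts with the statistical structure the pipeline assumes.

The generator emulates a multi-centre exome cohort over a multiallelic
CNV locus:

* integer copy-number states 2..8 with continental-group-specific
  frequencies (mode 4; mode 5 for the African-like group);
* a block of genes whose targets scale with the sample's copy number,
  surrounded by diploid genes;
* centre-specific systematics: per-(centre, target) gain factors and a
  low-rank multiplicative artifact field exp(strength * u_t * v_s),
  which is approximately additive after per-target standardization —
  exactly the structure SVD component removal targets;
* negative-binomial count noise (Poisson in the zero-dispersion limit)
  plus a continuous per-sample dosage jitter in copy-number units;
* allele-read sampling for multicopy genotypes and clone-count sampling
  with a background cut-failure rate.

Everything is deterministic given the master seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .targets_io import (DepthMatrix, SampleMeta, TargetRegion,
                         build_flanked_targets, ExonTarget)
from .validation_stats import CloneCounts

CN_STATES = (2, 3, 4, 5, 6, 7, 8)

#: default copy-number frequencies per continental-group archetype;
#: mode 4 everywhere except the African-like group (mode 5), range 2-8
DEFAULT_CN_FREQUENCIES: dict[str, tuple[float, ...]] = {
    "AFR": (0.005, 0.12, 0.28, 0.32, 0.18, 0.075, 0.02),
    "EAS": (0.03, 0.20, 0.38, 0.28, 0.08, 0.025, 0.005),
    "SAS": (0.04, 0.17, 0.39, 0.27, 0.12, 0.01, 0.0),
    "EUR": (0.02, 0.14, 0.41, 0.31, 0.10, 0.02, 0.0),
    "AMR": (0.02, 0.20, 0.46, 0.26, 0.05, 0.01, 0.0),
}

DEFAULT_BLOCK_GENES = ("DEFB4", "DEFB103", "DEFB104", "DEFB105", "DEFB106",
                       "DEFB107")


@dataclasses.dataclass
class SimConfig:
    """Study conditions for the simulated cohort."""

    batches: tuple[tuple[str, str, int], ...] = (("BGI", "EUR", 170),
                                                 ("WUGSC", "EUR", 170))
    cn_frequencies: Mapping[str, tuple[float, ...]] = dataclasses.field(
        default_factory=lambda: dict(DEFAULT_CN_FREQUENCIES))
    block_genes: tuple[str, ...] = DEFAULT_BLOCK_GENES
    n_non_block_genes: int = 30
    targets_per_gene: int = 4
    non_block_targets_per_gene: int = 5
    target_length_bp: int = 800
    depth_scale: float = 100.0       # expected RPKM of a diploid target
    total_reads_mean: float = 5e6
    artifact_rank: int = 1
    artifact_strength: float = 0.25  # sd of the low-rank log-depth field
    centre_gain_sd: float = 0.15     # per-(centre, target) log-gain sd
    nb_dispersion: float = 0.005     # NB variance = mu + dispersion * mu^2
    cn_signal_sd: float = 0.15       # per-sample dosage jitter, CN units
    low_coverage_fraction: float = 0.03
    n_anchors_per_batch: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        for group, freqs in self.cn_frequencies.items():
            if len(freqs) != len(CN_STATES):
                raise ValueError(f"{group}: need {len(CN_STATES)} frequencies")
            if not np.isclose(sum(freqs), 1.0, atol=1e-6):
                raise ValueError(f"{group}: frequencies sum to {sum(freqs)}")
        for _, _, n in self.batches:
            if n <= 0:
                raise ValueError("batch sizes must be positive")
        if self.depth_scale <= 0:
            raise ValueError("depth_scale must be positive")


@dataclasses.dataclass
class TruthTable:
    true_cn: pd.Series                    # per sample
    artifact_loadings: pd.DataFrame       # samples x rank, per-centre fields
    anchors: dict[str, list[tuple[str, int]]]   # batch_id -> (sample, CN)
    discarded_truth: list[str]            # samples simulated as low coverage


@dataclasses.dataclass
class SimulatedCohort:
    depth: DepthMatrix
    gene_map: dict[str, list[int]]
    block_genes: tuple[str, ...]
    truth: TruthTable
    config: SimConfig


def _make_targets(cfg: SimConfig) -> tuple[list[TargetRegion],
                                           dict[str, list[int]], np.ndarray]:
    """Lay genes along one chromosome; returns regions, gene map, block mask."""
    genes = list(cfg.block_genes) + [f"GENE{i:02d}"
                                     for i in range(cfg.n_non_block_genes)]
    per_gene = ([cfg.targets_per_gene] * len(cfg.block_genes)
                + [cfg.non_block_targets_per_gene] * cfg.n_non_block_genes)
    exons = []
    pos = 10_000
    for gene, n_t in zip(genes, per_gene):
        for _ in range(n_t):
            exons.append(ExonTarget("chr8", pos, pos + cfg.target_length_bp,
                                    gene))
            pos += cfg.target_length_bp + 2_000   # gaps wide enough not to merge
        pos += 10_000
    regions = build_flanked_targets(exons, flank=300, merge_gap=600)
    gene_map: dict[str, list[int]] = {g: [] for g in genes}
    for i, r in enumerate(regions):
        for g in r.genes:
            gene_map[g].append(i)
    block = np.zeros(len(regions), dtype=bool)
    for g in cfg.block_genes:
        block[gene_map[g]] = True
    return regions, gene_map, block


def _nb_counts(rng: np.random.Generator, mu: np.ndarray,
               dispersion: float) -> np.ndarray:
    if dispersion <= 0:
        return rng.poisson(mu)
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, mu * dispersion)
    return rng.poisson(lam)


def simulate_cohort(cfg: SimConfig) -> SimulatedCohort:
    """Draw a full cohort: counts, metadata, and the generating truth."""
    rng = np.random.default_rng(cfg.seed)
    regions, gene_map, block_mask = _make_targets(cfg)
    n_targets = len(regions)
    lengths_kb = np.array([r.length_bp for r in regions]) / 1e3

    samples: list[SampleMeta] = []
    columns: dict[str, np.ndarray] = {}
    totals: dict[str, float] = {}
    true_cn: dict[str, int] = {}
    anchors: dict[str, list[tuple[str, int]]] = {}
    loadings_rows = []
    discarded_truth: list[str] = []
    cn_values = np.array(CN_STATES)

    for b_idx, (centre, group, n_samples) in enumerate(cfg.batches):
        freqs = np.asarray(cfg.cn_frequencies[group], dtype=float)
        # centre systematics: per-target gain, shared by the whole batch
        gain = np.exp(rng.normal(0.0, cfg.centre_gain_sd, size=n_targets))
        u = rng.normal(size=(n_targets, cfg.artifact_rank))
        u /= np.linalg.norm(u, axis=0, keepdims=True)
        u *= np.sqrt(n_targets)       # unit sd per target on average
        batch_id = f"{centre}:{group}"
        anchors[batch_id] = []
        for i in range(n_samples):
            sid = f"S{b_idx}_{i:04d}"
            samples.append(SampleMeta(sid, f"{group}-POP", group, centre))
            cn = int(rng.choice(cn_values, p=freqs))
            true_cn[sid] = cn
            v = rng.normal(size=cfg.artifact_rank)
            loadings_rows.append((sid, batch_id, *v))
            dosage = cn + rng.normal(0.0, cfg.cn_signal_sd)
            total_reads = rng.normal(cfg.total_reads_mean,
                                     0.1 * cfg.total_reads_mean)
            total_reads = max(total_reads, 1e5)
            coverage = 1.0
            if rng.random() < cfg.low_coverage_fraction:
                coverage = rng.uniform(0.05, 0.3)   # falls below the QC cut
                discarded_truth.append(sid)
            artifact = np.exp(cfg.artifact_strength * (u @ v))
            rel_cn = np.where(block_mask, dosage / 2.0, 1.0)
            mu = (cfg.depth_scale * lengths_kb * (total_reads / 1e6)
                  * coverage * rel_cn * gain * artifact)
            counts = _nb_counts(rng, mu, cfg.nb_dispersion).astype(float)
            columns[sid] = counts
            totals[sid] = max(float(total_reads), float(counts.sum()))
        # anchors: spread over the batch, known CN = truth
        batch_ids = [s.sample_id for s in samples
                     if s.batch_id == batch_id and s.sample_id not in
                     set(discarded_truth)]
        step = max(1, len(batch_ids) // max(cfg.n_anchors_per_batch, 1))
        chosen = batch_ids[::step][:cfg.n_anchors_per_batch]
        anchors[batch_id] = [(sid, true_cn[sid]) for sid in chosen]

    counts_df = pd.DataFrame(columns, index=[r.region_id for r in regions])
    depth = DepthMatrix(regions, samples, counts_df,
                        pd.Series(totals).reindex(counts_df.columns))
    loadings = pd.DataFrame(
        loadings_rows,
        columns=["sample_id", "batch_id",
                 *[f"loading_{r}" for r in range(cfg.artifact_rank)]]
    ).set_index("sample_id")
    truth = TruthTable(pd.Series(true_cn), loadings, anchors, discarded_truth)
    return SimulatedCohort(depth, gene_map, cfg.block_genes, truth, cfg)


def simulate_site_reads(
    genotype: tuple[int, int], depth: int, base_error: float = 0.005,
    seed: int | np.random.Generator = 0,
) -> tuple[int, int]:
    """Draw (n_ref, n_alt) for a multicopy genotype at given depth."""
    j, n = genotype
    if not 0 <= j <= n:
        raise ValueError(f"invalid genotype (j={j}, N={n})")
    if depth < 0:
        raise ValueError("depth must be non-negative")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    p = (j / n) * (1 - base_error) + (1 - j / n) * base_error
    n_alt = int(rng.binomial(depth, p)) if depth else 0
    return depth - n_alt, n_alt


def simulate_clone_counts(
    true_fraction: float, n_clones: int, background_failure: float = 0.03,
    seed: int | np.random.Generator = 0,
    sample_id: str = "SIM", variant_id: str = "simvar",
) -> CloneCounts:
    """Clone tallies with digest failures counted as uncut.

    P(uncut clone) = fraction + (1 - fraction) * background.
    """
    if not 0 <= true_fraction <= 1 or not 0 <= background_failure <= 1:
        raise ValueError("fraction and background must lie in [0, 1]")
    if n_clones <= 0:
        raise ValueError("n_clones must be positive")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    p_uncut = true_fraction + (1 - true_fraction) * background_failure
    n_uncut = int(rng.binomial(n_clones, p_uncut))
    return CloneCounts(sample_id, variant_id, n_uncut, n_clones - n_uncut)


# ---------------------------------------------------------------------------
# on-disk emission in the dialects the pipeline consumes

def write_cohort(cohort: SimulatedCohort, outdir: str | Path) -> dict[str, str]:
    """Write counts/metadata/annotation/anchors/truth TSVs plus a manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    depth = cohort.depth
    paths = {
        "annotation": outdir / "targets.bed",
        "counts": outdir / "counts.tsv",
        "metadata": outdir / "samples.tsv",
        "totals": outdir / "totals.tsv",
        "anchors": outdir / "anchors.tsv",
        "truth_cn": outdir / "truth_cn.tsv",
        "manifest": outdir / "manifest.json",
    }
    with open(paths["annotation"], "w") as fh:
        for r in depth.targets:
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t"
                     f"{';'.join(sorted(r.genes))}\n")
    depth.counts.to_csv(paths["counts"], sep="\t", index_label="target_id")
    depth.meta_frame().reset_index().to_csv(paths["metadata"], sep="\t",
                                            index=False)
    depth.total_mapped_reads.rename("total_mapped_reads").rename_axis(
        "sample_id").reset_index().to_csv(paths["totals"], sep="\t",
                                          index=False)
    anchor_rows = [(b, sid, cn) for b, lst in cohort.truth.anchors.items()
                   for sid, cn in lst]
    pd.DataFrame(anchor_rows, columns=["batch_id", "sample_id", "known_cn"]
                 ).to_csv(paths["anchors"], sep="\t", index=False)
    cohort.truth.true_cn.rename("true_cn").rename_axis("sample_id"
                                                       ).reset_index().to_csv(
        paths["truth_cn"], sep="\t", index=False)
    cfg_dict = dataclasses.asdict(cohort.config)
    cfg_dict["cn_frequencies"] = {k: list(v) for k, v in
                                  cohort.config.cn_frequencies.items()}
    manifest = {
        "config": cfg_dict,
        "config_sha1": hashlib.sha1(
            json.dumps(cfg_dict, sort_keys=True, default=list).encode()
        ).hexdigest(),
        "files": {k: str(v.name) for k, v in paths.items()},
    }
    with open(paths["manifest"], "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return {k: str(v) for k, v in paths.items()}
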