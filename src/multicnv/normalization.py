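"""RPKM, coverage QC, per-batch standardization, and SVD denoising.

The normalization chain turns raw target read counts into a dosage signal:

1. RPKM: reads per kilobase of target per million mapped reads.
2. Sample QC: samples whose mean RPKM over all targets is below 50 are
   discarded (background-dominated libraries).
3. ZRPKM: per-target robust z-score within one batch (centre x continental
   group), location = median, scale = standard deviation across the
   batch's samples.
4. SVD-ZRPKM: the leading singular-value components — which capture
   systematic, centre-specific enrichment structure rather than copy
   number — are zeroed and the matrix reconstructed from the remainder.

The number of components to drop is chosen from the scree of singular
values (largest relative drop), and can be overridden per batch.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .targets_io import DepthMatrix

logger = logging.getLogger(__name__)

RPKM_MIN_MEAN = 50.0


@dataclasses.dataclass
class RpkmMatrix:
    """RPKM values with the same axes as the source DepthMatrix."""

    values: pd.DataFrame          # targets x samples
    target_lengths_bp: np.ndarray

    @property
    def mean_rpkm(self) -> pd.Series:
        return self.values.mean(axis=0)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)


@dataclasses.dataclass
class ZrpkmMatrix:
    """Standardized RPKM for one batch, with the per-target location/scale used."""

    values: pd.DataFrame
    location: pd.Series
    scale: pd.Series
    excluded_targets: list[str]   # zero-scale targets dropped before SVD


@dataclasses.dataclass
class SvdDecomposition:
    singular_values: np.ndarray
    u: np.ndarray
    vt: np.ndarray
    k_removed: int

    def __post_init__(self) -> None:
        s = self.singular_values
        if np.any(np.diff(s) > 1e-9 * max(1.0, abs(s[0]) if len(s) else 1.0)):
            raise ValueError("singular values must be non-increasing")
        if not 0 <= self.k_removed <= len(s):
            raise ValueError("k_removed out of range")


def compute_rpkm(depth: DepthMatrix) -> RpkmMatrix:
    """RPKM(t, s) = counts(t, s) / (length_kb(t) * total_reads(s)/1e6)."""
    lengths = depth.target_lengths_bp
    if (lengths <= 0).any():
        raise ValueError("target lengths must be positive")
    totals = depth.total_mapped_reads
    zero = totals.index[totals <= 0].tolist()
    if zero:
        raise ValueError(f"zero total mapped reads for samples {zero}")
    denom = np.outer(lengths / 1e3, totals.values / 1e6)
    values = pd.DataFrame(depth.counts.values / denom,
                          index=depth.counts.index,
                          columns=depth.counts.columns)
    return RpkmMatrix(values, lengths)


def filter_low_coverage_samples(
    rpkm: RpkmMatrix, min_mean: float = RPKM_MIN_MEAN
) -> tuple[RpkmMatrix, list[str]]:
    """Drop samples with mean RPKM strictly below ``min_mean``."""
    means = rpkm.mean_rpkm
    discarded = means.index[means < min_mean].tolist()
    kept_cols = [s for s in rpkm.values.columns if s not in set(discarded)]
    if not kept_cols:
        raise ValueError(
            f"all {len(discarded)} samples fall below mean RPKM {min_mean}")
    return RpkmMatrix(rpkm.values[kept_cols], rpkm.target_lengths_bp), discarded


def qc_report(rpkm: RpkmMatrix, min_mean: float = RPKM_MIN_MEAN) -> pd.DataFrame:
    means = rpkm.mean_rpkm
    return pd.DataFrame({
        "sample_id": means.index,
        "mean_rpkm": means.values,
        "status": np.where(means.values < min_mean, "discarded", "kept"),
    })


def zrpkm(rpkm_batch: RpkmMatrix, ddof: int = 1) -> ZrpkmMatrix:
    """Per-target robust standardization across one batch's samples.

    location = median, scale = standard deviation (sample sd). Targets
    with zero scale carry no dosage information and are excluded with a
    warning rather than imputed.
    """
    vals = rpkm_batch.values
    if vals.shape[1] < 3:
        raise ValueError(
            f"batch has {vals.shape[1]} samples; need at least 3")
    location = vals.median(axis=1)
    scale = vals.std(axis=1, ddof=ddof)
    keep = scale > 0
    excluded = vals.index[~keep].tolist()
    if excluded:
        logger.warning("excluding %d zero-scale targets from SVD: %s",
                       len(excluded), excluded[:5])
    z = vals.loc[keep].sub(location[keep], axis=0).div(scale[keep], axis=0)
    return ZrpkmMatrix(z, location[keep], scale[keep], excluded)


def scree(z: ZrpkmMatrix | pd.DataFrame | np.ndarray,
          max_k: int = 5) -> tuple[np.ndarray, int]:
    """Singular values and a suggested number of components to remove.

    suggested_k is the index of the largest relative drop
    (sigma_i - sigma_{i+1}) / sigma_1 — a reproducible proxy for reading
    the shoulder of the scree plot by eye — capped at ``max_k``.
    """
    m = _as_array(z)
    if min(m.shape) < 2:
        raise ValueError("need at least 2 targets and 2 samples")
    s = np.linalg.svd(m, compute_uv=False)
    if s[0] <= 0:
        return s, 0
    drops = -np.diff(s) / s[0]
    suggested = int(np.argmax(drops)) + 1 if len(drops) else 1
    return s, min(suggested, max_k)


def remove_components(
    z: ZrpkmMatrix | pd.DataFrame | np.ndarray, k: int
) -> tuple[pd.DataFrame | np.ndarray, SvdDecomposition]:
    """Zero the ``k`` largest singular values and reconstruct (SVD-ZRPKM)."""
    m = _as_array(z)
    if not 0 <= k <= min(m.shape):
        raise ValueError(f"k={k} out of range for shape {m.shape}")
    u, s, vt = np.linalg.svd(m, full_matrices=False)
    # sign convention: each left singular vector's largest-|.| entry positive
    for i in range(u.shape[1]):
        j = np.argmax(np.abs(u[:, i]))
        if u[j, i] < 0:
            u[:, i] *= -1
            vt[i, :] *= -1
    s_kept = s.copy()
    s_kept[:k] = 0.0
    recon = (u * s_kept) @ vt
    decomp = SvdDecomposition(s, u, vt, k)
    if isinstance(z, ZrpkmMatrix):
        out = pd.DataFrame(recon, index=z.values.index, columns=z.values.columns)
    elif isinstance(z, pd.DataFrame):
        out = pd.DataFrame(recon, index=z.index, columns=z.columns)
    else:
        out = recon
    return out, decomp


def gene_mean_signal(
    svd_zrpkm: pd.DataFrame,
    gene_map: Mapping[str, Sequence[str] | Sequence[int]],
    genes: Sequence[str],
) -> tuple[pd.DataFrame, pd.Series]:
    """Mean normalized signal per gene and over a gene set, per sample.

    ``gene_map`` maps gene symbol to the target row labels (or positional
    indices) of its targets. The gene-set signal is the mean over *all*
    targets of all listed genes (targets counted once each), not the mean
    of per-gene means — genes with more exons weigh more, matching their
    larger share of the depth evidence.
    """
    per_gene = {}
    all_rows: list = []
    for gene in genes:
        if gene not in gene_map:
            raise KeyError(f"gene {gene!r} not present in gene map")
        rows = list(gene_map[gene])
        if not rows:
            raise KeyError(f"gene {gene!r} has no targets")
        sub = (svd_zrpkm.iloc[rows] if all(isinstance(r, (int, np.integer))
                                           for r in rows)
               else svd_zrpkm.loc[rows])
        per_gene[gene] = sub.mean(axis=0)
        all_rows.append(sub)
    pooled = pd.concat(all_rows)
    pooled = pooled[~pooled.index.duplicated()]
    gene_table = pd.DataFrame(per_gene).T  # genes x samples
    return gene_table, pooled.mean(axis=0)


def _as_array(z) -> np.ndarray:
    if isinstance(z, ZrpkmMatrix):
        return z.values.values
    if isinstance(z, pd.DataFrame):
        return z.values
    return np.asarray(z, dtype=float)
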