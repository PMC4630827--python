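"""CNV block delineation from between-gene signal correlation.

Genes lying on the same copy-number-variable block rise and fall together
in normalized read depth across samples, so the squared Pearson
correlation (r^2) of their per-gene mean signals is high; genes outside
the block correlate only at noise level. The block is read off the
gene x gene r^2 matrix: a gene is in-block when its mean r^2 against a
set of seed genes (genes known a priori to sit on the block) reaches a
threshold. The full matrix is always emitted so the call can be checked
visually, mirroring how such matrices are usually inspected as a shaded
heatmap.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd


@dataclasses.dataclass
class CorrelationMatrix:
    """genes x genes r^2 values in genomic order; NaN for zero-variance genes."""

    r2: pd.DataFrame
    zero_variance_genes: list[str]

    def __post_init__(self) -> None:
        m = self.r2.values
        finite = ~np.isnan(m)
        if not np.allclose(m[finite & finite.T], m.T[finite & finite.T]):
            raise ValueError("r^2 matrix not symmetric")


def pairwise_gene_r2(table: pd.DataFrame) -> CorrelationMatrix:
    """Squared Pearson correlation between all gene pairs.

    ``table`` is genes x samples in genomic order. Genes with zero
    variance across samples are flagged and their entries left missing
    (NaN) rather than set to 0.
    """
    if table.shape[1] < 3:
        raise ValueError(f"need >= 3 samples, got {table.shape[1]}")
    variances = table.var(axis=1, ddof=1)
    zero_var = variances.index[variances == 0].tolist()
    r = table.T.corr(method="pearson")  # pandas leaves NaN for zero variance
    r2 = r ** 2
    np.fill_diagonal(r2.values, 1.0)
    r2.loc[zero_var, :] = np.nan
    r2.loc[:, zero_var] = np.nan
    return CorrelationMatrix(r2, zero_var)


def contiguous_block(
    corr: CorrelationMatrix,
    seed_genes: list[str],
    r2_threshold: float = 0.5,
) -> pd.DataFrame:
    """Block membership by mean r^2 against the seed genes.

    A gene is in-block iff its mean r^2 to the seed genes (self-pairs and
    missing entries excluded from the mean) is >= ``r2_threshold``. Seed
    genes are always in-block. The result keeps genomic order so
    contiguity of the called block can be inspected directly.
    """
    unknown = [g for g in seed_genes if g not in corr.r2.index]
    if unknown:
        raise KeyError(f"seed genes not in matrix: {unknown}")
    rows = []
    for gene in corr.r2.index:
        others = [s for s in seed_genes if s != gene]
        vals = corr.r2.loc[gene, others].dropna() if others else pd.Series(dtype=float)
        mean_r2 = float(vals.mean()) if len(vals) else np.nan
        in_block = gene in seed_genes or (
            not np.isnan(mean_r2) and mean_r2 >= r2_threshold)
        rows.append((gene, mean_r2, bool(in_block)))
    return pd.DataFrame(rows, columns=["gene", "mean_r2_to_seed", "in_block"]
                        ).set_index("gene")
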