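"""Stage orchestration: wire the modules into the end-to-end analysis.

Order of operations per batch (centre x continental group):
counts -> RPKM -> low-coverage filter -> ZRPKM -> scree / component
removal -> gene-set mean signal -> mixture fit -> absolute copy-number
assignment -> confidence filter. Downstream stages (boundary, variant
calling, clone validation, selection) consume the per-sample calls.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import boundary, cn_calling, normalization, targets_io
from .cn_calling import AnchorSet, CopyNumberCall
from .normalization import RPKM_MIN_MEAN

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class PipelineConfig:
    annotation_path: str = ""
    counts_path: str = ""
    metadata_path: str = ""
    totals_path: str = ""
    anchors_path: str | None = None
    flank: int = 300
    merge_gap: int = 600
    rpkm_min_mean: float = RPKM_MIN_MEAN
    #: "anchored": choose k in 0..max_components by anchor agreement
    #: (falls back to the scree heuristic without anchors); "auto": scree
    #: heuristic; an integer or per-batch {batch_id: k} mapping: fixed.
    components_removed: int | str = "anchored"
    max_components: int = 5
    c_min: int = 2
    c_max: int = 8
    modal_cn: int = 4
    posterior_threshold: float = 0.95
    n_restarts: int = 10
    min_batch_size: int = 10
    seed: int = 0
    outdir: str = "results"

    def config_hash(self) -> str:
        return hashlib.sha1(json.dumps(
            dataclasses.asdict(self), sort_keys=True, default=str
        ).encode()).hexdigest()[:12]


@dataclasses.dataclass
class BatchResult:
    batch_id: str
    model: cn_calling.MixtureModel | None
    calls: list[CopyNumberCall]
    singular_values: np.ndarray
    k_removed: int
    suggested_k: int
    signal: pd.Series          # gene-set mean SVD-ZRPKM per sample
    gene_signal: pd.DataFrame  # per-gene mean per sample
    error: str | None = None


def load_anchor_sets(path: str | Path) -> dict[str, AnchorSet]:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    sets: dict[str, AnchorSet] = {}
    for batch_id, grp in df.groupby("batch_id"):
        sets[str(batch_id)] = AnchorSet(
            [(r["sample_id"], int(r["known_cn"])) for _, r in grp.iterrows()],
            source=str(path))
    return sets


def call_copy_number(
    depth: targets_io.DepthMatrix,
    gene_map: Mapping[str, Sequence[int]],
    signal_genes: Sequence[str],
    cfg: PipelineConfig,
    anchor_sets: Mapping[str, AnchorSet] | None = None,
) -> tuple[list[BatchResult], list[str]]:
    """Run the full depth -> copy-number chain batch by batch.

    Returns per-batch results (batches whose mixture fit or anchoring
    fails carry an error string instead of crashing the run) and the
    low-coverage samples discarded cohort-wide.
    """
    rpkm = normalization.compute_rpkm(depth)
    rpkm, discarded = normalization.filter_low_coverage_samples(
        rpkm, cfg.rpkm_min_mean)
    logger.info("discarded %d low-coverage samples", len(discarded))
    meta = depth.meta_frame()
    # gene_map holds positional target indices; convert to row labels once
    row_labels = list(depth.counts.index)
    label_map = {g: [row_labels[i] for i in idx]
                 for g, idx in gene_map.items()}
    results: list[BatchResult] = []
    batch_of = meta["batch_id"]
    for batch_id in batch_of.loc[rpkm.sample_ids].unique():
        batch_samples = [s for s in rpkm.sample_ids
                         if batch_of[s] == batch_id]
        batch_rpkm = normalization.RpkmMatrix(
            rpkm.values[batch_samples], rpkm.target_lengths_bp)
        try:
            result = _call_batch(batch_id, batch_rpkm, label_map,
                                 signal_genes, cfg,
                                 (anchor_sets or {}).get(batch_id))
        except (cn_calling.FitError, ValueError) as exc:
            logger.warning("batch %s failed: %s", batch_id, exc)
            result = BatchResult(batch_id, None, [], np.array([]), 0, 0,
                                 pd.Series(dtype=float), pd.DataFrame(),
                                 error=str(exc))
        results.append(result)
    return results, discarded


def _batch_signals(z, label_map, signal_genes, cfg, k):
    denoised, _ = normalization.remove_components(z, k)
    # excluded zero-scale targets are absent from the denoised matrix
    present = set(denoised.index)
    usable_map = {g: [r for r in rows if r in present]
                  for g, rows in label_map.items()}
    return normalization.gene_mean_signal(denoised, usable_map,
                                          list(signal_genes))


def _call_batch(batch_id, batch_rpkm, label_map, signal_genes, cfg,
                anchors) -> BatchResult:
    z = normalization.zrpkm(batch_rpkm)
    sv, suggested_k = normalization.scree(z, max_k=cfg.max_components)
    candidates = _candidate_ks(cfg.components_removed, batch_id, suggested_k,
                               cfg.max_components, anchors)
    seed = _child_seed(cfg.seed, batch_id)
    attempts: list[tuple[float, float, int, object, object, object, list]] = []
    last_error: Exception | None = None
    fallback_signals = None
    for k in candidates:
        gene_signal, set_signal = _batch_signals(z, label_map, signal_genes,
                                                 cfg, k)
        if fallback_signals is None:
            fallback_signals = (k, gene_signal, set_signal)
        try:
            model = cn_calling.fit_mixture(
                set_signal.values, cfg.c_min, cfg.c_max, cfg.n_restarts,
                seed=seed, min_batch_size=cfg.min_batch_size)
            calls = cn_calling.assign_copy_number(
                model, set_signal.values, list(set_signal.index), batch_id,
                anchors=anchors, modal_cn=cfg.modal_cn,
                posterior_threshold=cfg.posterior_threshold)
        except (cn_calling.FitError, ValueError) as exc:
            last_error = exc
            continue
        agreement, _ = _anchor_score(calls, anchors)
        prop_conf = sum(c.confident for c in calls) / len(calls)
        attempts.append((agreement, prop_conf, k, model, gene_signal,
                         set_signal, calls))
    if not attempts:
        result = BatchResult(batch_id, None, [], sv, 0, suggested_k,
                             pd.Series(dtype=float), pd.DataFrame(),
                             error=str(last_error))
        if fallback_signals is not None:
            result.k_removed, result.gene_signal, result.signal = \
                fallback_signals[0], fallback_signals[1], fallback_signals[2]
        return result
    # best anchor agreement, then sharpest clustering, then small k
    agreement, _, k, model, gene_signal, set_signal, calls = max(
        attempts, key=lambda a: (a[0], a[1], -a[2]))
    if len(candidates) > 1:
        logger.info("batch %s: k=%d chosen by anchors (agreement %.0f%%)",
                    batch_id, k, 100 * agreement)
    return BatchResult(batch_id, model, calls, sv, k, suggested_k,
                       set_signal, gene_signal)


def _anchor_score(calls, anchors) -> tuple[float, float]:
    if anchors is None or not anchors.anchors:
        return 1.0, 0.0
    by_id = {c.sample_id: c for c in calls}
    known = [(by_id[s], cn) for s, cn in anchors.anchors if s in by_id]
    if not known:
        return 0.0, 0.0
    hits = sum(1 for c, cn in known if c.copy_number == cn)
    mean_post = sum(c.posterior for c, _ in known) / len(known)
    return hits / len(known), mean_post


def _candidate_ks(spec_k, batch_id: str, suggested: int, max_k: int,
                  anchors) -> list[int]:
    if isinstance(spec_k, Mapping):
        return [int(spec_k.get(batch_id, suggested))]
    if spec_k == "auto":
        return [suggested]
    if spec_k == "anchored":
        if anchors is not None and anchors.anchors:
            # at least one component is always removed: the normalization
            # is defined by zeroing the leading systematic component(s)
            return list(range(1, max_k + 1))
        return [suggested]
    return [int(spec_k)]


def _child_seed(master: int, batch_id: str) -> int:
    h = hashlib.sha256(f"{master}:{batch_id}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


def gene_signal_table(results: Sequence[BatchResult],
                      gene_order: Sequence[str]) -> pd.DataFrame:
    """Concatenate per-batch per-gene signals into one genes x samples table."""
    frames = [r.gene_signal for r in results if not r.gene_signal.empty]
    if not frames:
        raise ValueError("no batch produced gene signals")
    table = pd.concat(frames, axis=1)
    return table.loc[[g for g in gene_order if g in table.index]]


def run_boundary(results: Sequence[BatchResult], gene_order: Sequence[str],
                 seed_genes: Sequence[str], r2_threshold: float = 0.5
                 ) -> tuple[boundary.CorrelationMatrix, pd.DataFrame]:
    table = gene_signal_table(results, gene_order)
    corr = boundary.pairwise_gene_r2(table)
    membership = boundary.contiguous_block(corr, list(seed_genes),
                                           r2_threshold)
    return corr, membership


def write_batch_outputs(results: Sequence[BatchResult],
                        cfg: PipelineConfig) -> dict[str, str]:
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    header = f"# config_hash={cfg.config_hash()} seed={cfg.seed}\n"
    all_calls = [c for r in results for c in r.calls]
    calls_path = outdir / "copy_number_calls.tsv"
    with open(calls_path, "w") as fh:
        fh.write(header)
        cn_calling.calls_frame(all_calls).to_csv(fh, sep="\t", index=False)
    models_path = outdir / "mixture_models.json"
    models = {r.batch_id: (r.model.to_dict() if r.model else
                           {"error": r.error}) for r in results}
    models_path.write_text(json.dumps(models, indent=1, sort_keys=True))
    scree_path = outdir / "scree.tsv"
    with open(scree_path, "w") as fh:
        fh.write(header)
        fh.write("batch_id\tcomponent\tsingular_value\tk_removed\n")
        for r in results:
            for i, s in enumerate(r.singular_values, start=1):
                fh.write(f"{r.batch_id}\t{i}\t{s:.6g}\t{r.k_removed}\n")
    return {"calls": str(calls_path), "models": str(models_path),
            "scree": str(scree_path)}


def plot_batch(result: BatchResult, path: str | Path) -> None:
    """Histogram of the batch signal with the fitted mixture overlaid."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    x = result.signal.values
    ax.hist(x, bins=40, density=True, alpha=0.6, color="steelblue")
    if result.model is not None:
        grid = np.linspace(x.min() - 0.5, x.max() + 0.5, 400)
        dens = np.zeros_like(grid)
        m = result.model
        for w, mu in zip(m.weights, m.means):
            comp = w * np.exp(-0.5 * ((grid - mu) / m.sigma) ** 2) / (
                m.sigma * np.sqrt(2 * np.pi))
            ax.plot(grid, comp, color="gray", lw=0.8)
            dens += comp
        ax.plot(grid, dens, color="firebrick", lw=1.5)
    ax.set_xlabel("gene-set mean SVD-ZRPKM")
    ax.set_ylabel("density")
    ax.set_title(result.batch_id)
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)
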