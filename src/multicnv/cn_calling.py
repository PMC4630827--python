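"""Integer copy-number calling from a one-dimensional dosage signal.

Each batch (sequencing centre x continental group) is fitted with a
constrained one-dimensional Gaussian mixture: one component per candidate
integer copy number c in [c_min, c_max], component means linear in c
(mu_c = beta0 + beta1 * c, beta1 > 0), a shared standard deviation sigma,
and free mixing weights. The linear-mean / shared-sigma parameterization
keeps seven components identifiable on batches of a few hundred samples.

Component indices are relative; absolute copy number is pinned either by
anchor samples with known copy number (e.g. from a paralogue ratio test)
or by asserting which copy number is modal in the batch. A call's
posterior is the responsibility of its assigned component; calls with
posterior strictly above 0.95 are treated as confident.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import logsumexp

logger = logging.getLogger(__name__)

POSTERIOR_THRESHOLD = 0.95
DEFAULT_MODAL_CN = 4


class FitError(RuntimeError):
    """Mixture fitting or anchoring failed; carries diagnostics."""


@dataclasses.dataclass
class MixtureModel:
    c_min: int
    c_max: int
    beta0: float
    beta1: float
    sigma: float
    weights: np.ndarray
    log_likelihood: float
    n_iterations: int
    seed: int

    def __post_init__(self) -> None:
        if self.beta1 <= 0:
            raise FitError(f"beta1={self.beta1:.4g} not positive")
        if self.sigma <= 0:
            raise FitError("sigma must be positive")
        if not np.isclose(self.weights.sum(), 1.0, atol=1e-6):
            raise FitError("weights do not sum to 1")

    @property
    def components(self) -> np.ndarray:
        return np.arange(self.c_min, self.c_max + 1)

    @property
    def means(self) -> np.ndarray:
        return self.beta0 + self.beta1 * self.components

    def responsibilities(self, signal: np.ndarray) -> np.ndarray:
        """Posterior over components for each point; rows sum to 1."""
        x = np.asarray(signal, dtype=float)[:, None]
        log_w = np.log(np.maximum(self.weights, 1e-300))
        log_pdf = (-0.5 * ((x - self.means[None, :]) / self.sigma) ** 2
                   - np.log(self.sigma) - 0.5 * np.log(2 * np.pi))
        log_post = log_w[None, :] + log_pdf
        return np.exp(log_post - logsumexp(log_post, axis=1, keepdims=True))

    def to_dict(self) -> dict:
        return {
            "c_min": self.c_min, "c_max": self.c_max,
            "beta0": self.beta0, "beta1": self.beta1, "sigma": self.sigma,
            "weights": self.weights.tolist(),
            "log_likelihood": self.log_likelihood,
            "n_iterations": self.n_iterations, "seed": self.seed,
            "variance_structure": "shared-sigma, means linear in copy number",
        }


@dataclasses.dataclass
class CopyNumberCall:
    sample_id: str
    batch_id: str
    raw_signal: float
    copy_number: int
    posterior: float
    confident: bool


@dataclasses.dataclass
class AnchorSet:
    """Control samples with copy number known from an orthogonal assay."""

    anchors: list[tuple[str, int]]
    source: str = "external assay"

    def __post_init__(self) -> None:
        for sid, cn in self.anchors:
            if not 1 <= cn <= 12:
                raise ValueError(
                    f"anchor {sid}: copy number {cn} outside plausible [1, 12]")


def _log_likelihood(x, means, sigma, weights) -> float:
    log_pdf = (-0.5 * ((x[:, None] - means[None, :]) / sigma) ** 2
               - np.log(sigma) - 0.5 * np.log(2 * np.pi))
    return float(logsumexp(np.log(np.maximum(weights, 1e-300))[None, :]
                           + log_pdf, axis=1).sum())


def fit_mixture(
    signal: Sequence[float],
    c_min: int = 2,
    c_max: int = 8,
    n_restarts: int = 10,
    seed: int = 0,
    min_batch_size: int = 10,
    max_iter: int = 500,
    tol: float = 1e-8,
) -> MixtureModel:
    """EM fit of the constrained mixture; best of ``n_restarts`` by log-likelihood.

    Restart r uses a child seed derived from ``seed``; the fit is
    deterministic given (signal, seed). A restart is discarded when it
    collapses (sigma below 1e-6 of the data spread) or fits a
    non-increasing dosage (beta1 <= 0).
    """
    x = np.asarray(list(signal), dtype=float)
    if len(x) < min_batch_size:
        raise FitError(f"batch of {len(x)} below minimum {min_batch_size}")
    if c_max <= c_min:
        raise ValueError("c_max must exceed c_min")
    spread = float(x.max() - x.min())
    if spread == 0:
        raise FitError("all signal values identical; degenerate batch")
    comps = np.arange(c_min, c_max + 1)
    m = len(comps)
    rng_master = np.random.default_rng(seed)
    best: MixtureModel | None = None
    failures: list[str] = []
    for r in range(n_restarts):
        rng = np.random.default_rng(rng_master.integers(2**31))
        beta1 = spread / (c_max - c_min) * rng.uniform(0.7, 1.3)
        beta0 = x.min() - beta1 * c_min + rng.normal(0, 0.1 * spread)
        sigma = spread / (2.0 * m) * rng.uniform(0.5, 1.5)
        weights = rng.dirichlet(np.full(m, 5.0))
        prev_ll = -np.inf
        n_iter = 0
        ok = True
        for n_iter in range(1, max_iter + 1):
            means = beta0 + beta1 * comps
            log_pdf = (-0.5 * ((x[:, None] - means[None, :]) / sigma) ** 2
                       - np.log(sigma) - 0.5 * np.log(2 * np.pi))
            log_post = (np.log(np.maximum(weights, 1e-300))[None, :] + log_pdf)
            ll = float(logsumexp(log_post, axis=1).sum())
            resp = np.exp(log_post - logsumexp(log_post, axis=1,
                                               keepdims=True))
            # M-step
            weights = resp.mean(axis=0)
            w_tot = resp.sum()
            sw_c = resp.sum(axis=0)
            mean_c = float(sw_c @ comps) / w_tot
            mean_x = float(x.mean())
            cov_xc = float((resp * x[:, None] * comps[None, :]).sum()) / w_tot \
                - mean_x * mean_c
            var_c = float(sw_c @ comps**2) / w_tot - mean_c**2
            if var_c <= 0:
                ok = False
                failures.append(f"restart {r}: weight collapse on one component")
                break
            beta1_new = cov_xc / var_c
            beta0_new = mean_x - beta1_new * mean_c
            means_new = beta0_new + beta1_new * comps
            sigma2 = float((resp * (x[:, None] - means_new[None, :]) ** 2
                            ).sum()) / w_tot
            if sigma2 < (1e-6 * spread) ** 2:
                ok = False
                failures.append(f"restart {r}: sigma collapsed")
                break
            beta0, beta1, sigma = beta0_new, beta1_new, float(np.sqrt(sigma2))
            if abs(ll - prev_ll) < tol * (1 + abs(ll)):
                break
            prev_ll = ll
        if not ok:
            continue
        if beta1 <= 0:
            failures.append(f"restart {r}: beta1={beta1:.4g} <= 0")
            continue
        means = beta0 + beta1 * comps
        ll = _log_likelihood(x, means, sigma, weights)
        if best is None or ll > best.log_likelihood:
            best = MixtureModel(c_min, c_max, float(beta0), float(beta1),
                                float(sigma), weights, ll, n_iter, seed)
    if best is None:
        raise FitError("no restart converged to a valid fit: "
                       + "; ".join(failures[:5]))
    return best


def assign_copy_number(
    model: MixtureModel,
    signal: Sequence[float],
    sample_ids: Sequence[str],
    batch_id: str = "",
    anchors: AnchorSet | None = None,
    modal_cn: int | None = None,
    posterior_threshold: float = POSTERIOR_THRESHOLD,
) -> list[CopyNumberCall]:
    """Assign integer copy numbers with posteriors, pinned to absolute CN.

    With ``anchors``, the integer offset applied to component indices is
    the one maximizing agreement with the anchors' known copy numbers
    (offset 0 means the fitted component index IS the copy number);
    agreement below 50% raises "anchoring failed". Without anchors, the
    highest-weight component is aligned to ``modal_cn``. Posterior ties
    break toward the lower copy number.
    """
    x = np.asarray(list(signal), dtype=float)
    ids = list(sample_ids)
    if len(x) != len(ids):
        raise ValueError("signal and sample_ids length mismatch")
    resp = model.responsibilities(x)
    comps = model.components
    # argmax with ties toward lower copy number: argmax takes first max
    comp_idx = np.argmax(resp, axis=1)
    if anchors is not None and anchors.anchors:
        id_pos = {s: i for i, s in enumerate(ids)}
        missing = [s for s, _ in anchors.anchors if s not in id_pos]
        if missing:
            raise ValueError(f"anchor samples not in batch: {missing}")
        best_offset, best_agree = None, -1.0
        for offset in range(-model.c_max, 13):
            hits = sum(
                1 for sid, known in anchors.anchors
                if comps[comp_idx[id_pos[sid]]] + offset == known)
            agree = hits / len(anchors.anchors)
            if agree > best_agree:
                best_offset, best_agree = offset, agree
        if best_agree < 0.5:
            raise FitError(
                f"anchoring failed: best agreement {best_agree:.0%} "
                f"(< 50%) at offset {best_offset}")
        offset = best_offset
    else:
        target_modal = DEFAULT_MODAL_CN if modal_cn is None else modal_cn
        offset = target_modal - comps[int(np.argmax(model.weights))]
    calls = []
    for i, sid in enumerate(ids):
        post = float(resp[i, comp_idx[i]])
        cn = int(comps[comp_idx[i]] + offset)
        calls.append(CopyNumberCall(sid, batch_id, float(x[i]), cn, post,
                                    post > posterior_threshold))
    return calls


def filter_confident_calls(
    calls: Sequence[CopyNumberCall],
    min_posterior: float = POSTERIOR_THRESHOLD,
) -> tuple[list[CopyNumberCall], list[CopyNumberCall], float | None]:
    """Partition calls by posterior strictly greater than ``min_posterior``.

    Returns (confident, flagged, proportion confident); the proportion is
    None for empty input.
    """
    confident = [c for c in calls if c.posterior > min_posterior]
    flagged = [c for c in calls if not c.posterior > min_posterior]
    prop = len(confident) / len(calls) if calls else None
    return confident, flagged, prop


def concordance(
    calls_a: dict[str, int] | Sequence[CopyNumberCall],
    calls_b: dict[str, int] | Sequence[CopyNumberCall],
) -> tuple[pd.DataFrame, int, float]:
    """Contingency table and discrepancy rate over shared samples."""
    a = _as_call_dict(calls_a)
    b = _as_call_dict(calls_b)
    shared = sorted(set(a) & set(b))
    if not shared:
        raise ValueError("no shared samples between call sets")
    pairs = pd.DataFrame({"cn_a": [a[s] for s in shared],
                          "cn_b": [b[s] for s in shared]}, index=shared)
    table = pd.crosstab(pairs["cn_a"], pairs["cn_b"])
    n_concordant = int((pairs["cn_a"] == pairs["cn_b"]).sum())
    return table, n_concordant, 1.0 - n_concordant / len(shared)


def pc1_consensus(probe_matrix: pd.DataFrame | np.ndarray) -> np.ndarray:
    """Per-sample consensus score: first principal component across probes.

    ``probe_matrix`` is probes x samples. Probes are centred, samples are
    the observations; the returned score is the PC1 coordinate of each
    sample, sign-fixed to correlate positively with the per-sample mean
    probe value.
    """
    m = np.asarray(probe_matrix, dtype=float)
    if m.shape[0] < 2 or m.shape[1] < 3:
        raise ValueError("need >= 2 probes and >= 3 samples")
    centred = m - m.mean(axis=1, keepdims=True)
    if not np.any(centred):
        raise ValueError("zero-variance probe matrix")
    u, s, vt = np.linalg.svd(centred, full_matrices=False)
    score = s[0] * vt[0]          # per-sample PC1 coordinate
    mean_probe = m.mean(axis=0)
    if np.corrcoef(score, mean_probe)[0, 1] < 0:
        score = -score
    return score


def calls_frame(calls: Sequence[CopyNumberCall]) -> pd.DataFrame:
    return pd.DataFrame([
        (c.sample_id, c.batch_id, c.raw_signal, c.copy_number, c.posterior,
         c.confident) for c in calls],
        columns=["sample_id", "batch_id", "raw_signal", "copy_number",
                 "posterior", "confident"])


def _as_call_dict(calls) -> dict[str, int]:
    if isinstance(calls, dict):
        return calls
    return {c.sample_id: c.copy_number for c in calls}
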