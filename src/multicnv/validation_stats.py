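"""Clone-count validation statistics for multicopy genotypes.

Cloning a PCR product that spans a variant site and scoring individual
clones by restriction digest gives a direct count of how many amplified
molecules carried each allele. If the exome-called genotype (j alternate
copies out of N) is right, the uncut (variant) allele should appear in a
fraction j/N of clones. Each sample/variant pair therefore yields a
binomial proportion with an exact (Clopper-Pearson, also reported in the
literature as "Pearson-Klopper") confidence interval, and consistency is
judged by whether j/N lies inside that interval. Samples homozygous for
the cut allele estimate the background rate at which the digest fails.
"""

from __future__ import annotations

import dataclasses
import math
from pathlib import Path
from typing import Sequence

import pandas as pd
from scipy.stats import beta


@dataclasses.dataclass(frozen=True)
class CloneCounts:
    sample_id: str
    variant_id: str
    n_uncut: int    # clones showing the undigested (variant) allele
    n_cut: int      # clones showing the digested allele

    def __post_init__(self) -> None:
        if self.n_uncut < 0 or self.n_cut < 0:
            raise ValueError("clone counts must be non-negative")

    @property
    def n_total(self) -> int:
        return self.n_uncut + self.n_cut


@dataclasses.dataclass(frozen=True)
class ProportionEstimate:
    p_hat: float
    ci_low: float
    ci_high: float
    confidence: float = 0.95
    method: str = "clopper-pearson"

    def rounded(self, ndigits: int = 2) -> tuple[float, float, float]:
        """(p_hat, ci_low, ci_high) rounded half-away-from-zero."""
        return (round_half_away(self.p_hat, ndigits),
                round_half_away(self.ci_low, ndigits),
                round_half_away(self.ci_high, ndigits))


@dataclasses.dataclass
class ConsistencyVerdict:
    sample_id: str
    variant_id: str
    alt_copies: int
    copy_number: int
    expected_fraction: float
    estimate: ProportionEstimate
    in_ci: bool
    best_supported_n: int | None


def round_half_away(x: float, ndigits: int = 2) -> float:
    """Round with halves away from zero (the convention of printed tables)."""
    factor = 10 ** ndigits
    return math.floor(abs(x) * factor + 0.5) / factor * (1 if x >= 0 else -1)


def clopper_pearson(x: int, n: int, conf: float = 0.95) -> ProportionEstimate:
    """Exact binomial proportion CI from beta quantiles.

    ci_low = 0 when x = 0 and ci_high = 1 when x = n; otherwise the
    equal-tailed beta-quantile bounds at level ``conf``.
    """
    if n <= 0:
        raise ValueError("need at least one trial")
    if not 0 <= x <= n:
        raise ValueError(f"successes {x} outside [0, {n}]")
    alpha = 1.0 - conf
    low = 0.0 if x == 0 else float(beta.ppf(alpha / 2, x, n - x + 1))
    high = 1.0 if x == n else float(beta.ppf(1 - alpha / 2, x + 1, n - x))
    return ProportionEstimate(x / n, low, high, conf)


def estimate_background_failure(
    controls: Sequence[CloneCounts], conf: float = 0.95
) -> ProportionEstimate:
    """Pooled cut-failure rate across homozygous-cut control samples."""
    if not controls:
        raise ValueError("need at least one control sample")
    uncut = sum(c.n_uncut for c in controls)
    total = sum(c.n_total for c in controls)
    if total == 0:
        raise ValueError("controls have zero clones")
    return clopper_pearson(uncut, total, conf)


def clone_consistency(
    counts: CloneCounts,
    exome_genotype: tuple[int, int],
    candidate_ns: Sequence[int],
    conf: float = 0.95,
    background: float = 0.0,
) -> ConsistencyVerdict:
    """Judge agreement between clone proportion and the exome genotype.

    ``in_ci`` tests whether the expected fraction j/N lies in the
    *unrounded* CI of the uncut-clone proportion; when a background
    cut-failure rate is supplied, the expected fraction is floored at it
    (an all-cut genotype still shows background uncut clones).
    ``best_supported_n`` is the candidate copy number whose nearest
    attainable fraction j'/N (j' = 1..N-1) is closest to the observed
    proportion — the reasoning used when clone counts disagree with the
    exome copy number but agree with an orthogonal assay's.
    """
    j, n = exome_genotype
    if not 0 <= j <= n:
        raise ValueError(f"invalid genotype (j={j}, N={n})")
    if not candidate_ns:
        raise ValueError("candidate copy-number list is empty")
    est = clopper_pearson(counts.n_uncut, counts.n_total, conf)
    expected = j / n
    expected_adj = max(expected, background)
    in_ci = est.ci_low <= expected_adj <= est.ci_high
    best_n, best_dist = None, float("inf")
    for cand in candidate_ns:
        for jp in range(1, cand):
            d = abs(est.p_hat - jp / cand)
            if d < best_dist:
                best_n, best_dist = cand, d
    return ConsistencyVerdict(counts.sample_id, counts.variant_id, j, n,
                              expected, est, bool(in_ci), best_n)


# ---------------------------------------------------------------------------
# table I/O

def load_clone_counts(path: str | Path) -> pd.DataFrame:
    """Read a clone-count TSV.

    Columns: sample_id, variant_id, n_uncut, n_cut, exome_genotype
    (string like AGGG), exome_cn, uncut_allele, and an optional
    orthogonal_cn column carrying a copy number from an independent
    assay when one disagrees with the exome call.
    """
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str,
                                            "variant_id": str})
    required = {"sample_id", "variant_id", "n_uncut", "n_cut",
                "exome_genotype", "exome_cn", "uncut_allele"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return df


def validation_table(
    clone_df: pd.DataFrame,
    conf: float = 0.95,
    apply_background_floor: bool = True,
) -> pd.DataFrame:
    """Per-row proportion estimates, CIs, and consistency verdicts.

    The alternate copy count j is read off the exome genotype string as
    the number of ``uncut_allele`` letters it contains. Rows with j = 0
    are the homozygous-cut controls: per variant, their pooled uncut
    proportion estimates the background digest-failure rate, which
    (when ``apply_background_floor``) floors every row's expected
    fraction so a control's own residual uncut clones do not count
    against it. Candidate copy numbers for ``best_supported_n`` are the
    exome call plus any orthogonal-assay call recorded for the row.
    """
    js = [str(r["exome_genotype"]).count(str(r["uncut_allele"]))
          for _, r in clone_df.iterrows()]
    background: dict[str, float] = {}
    if apply_background_floor:
        for variant, grp in clone_df.groupby("variant_id"):
            ctrl = [CloneCounts(r["sample_id"], variant, int(r["n_uncut"]),
                                int(r["n_cut"]))
                    for (_, r), j in zip(clone_df.iterrows(), js)
                    if r["variant_id"] == variant and j == 0]
            if ctrl:
                background[variant] = estimate_background_failure(ctrl).p_hat
    rows = []
    for (_, r), j in zip(clone_df.iterrows(), js):
        counts = CloneCounts(r["sample_id"], r["variant_id"],
                             int(r["n_uncut"]), int(r["n_cut"]))
        n = int(r["exome_cn"])
        candidates = {n}
        ortho = r.get("orthogonal_cn")
        if ortho is not None and not pd.isna(ortho) and str(ortho).strip():
            candidates.add(int(float(ortho)))
        verdict = clone_consistency(
            counts, (j, n), sorted(candidates), conf,
            background=background.get(r["variant_id"], 0.0))
        p, lo, hi = verdict.estimate.rounded(2)
        rows.append({
            "sample_id": counts.sample_id,
            "variant_id": counts.variant_id,
            "n_uncut": counts.n_uncut,
            "n_cut": counts.n_cut,
            "p_hat": p, "ci_low": lo, "ci_high": hi,
            "p_hat_raw": verdict.estimate.p_hat,
            "ci_low_raw": verdict.estimate.ci_low,
            "ci_high_raw": verdict.estimate.ci_high,
            "exome_genotype": r["exome_genotype"],
            "expected_fraction": verdict.expected_fraction,
            "in_ci": verdict.in_ci,
            "best_supported_n": verdict.best_supported_n,
        })
    return pd.DataFrame(rows)
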