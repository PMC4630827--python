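"""Frequency-spectrum comparison of variant classes (selection screen).

Under neutrality, non-synonymous (NS) and synonymous (S) variants should
share one frequency distribution; negative selection depletes NS
variants at appreciable frequency (spectrum shifted toward 0) while
balancing selection enriches intermediate frequencies. The comparison is
the k-sample Anderson-Darling test in its tie-adjusted (midrank)
version, computed from the statistic's definition: frequencies of rare
variants tie heavily, so the midrank form is essential.

For a pooled sample of N observations in k groups of sizes n_i with L
distinct values z_j of multiplicity l_j, with M_ij the midrank count of
group i at z_j and B_j the pooled midrank count,

    A2akN = (N - 1)/N * sum_i 1/n_i * sum_j l_j/N *
            (N*M_ij - n_i*B_j)^2 / (B_j*(N - B_j) - N*l_j/4)

standardized as T = (A2akN - (k - 1)) / sigma_N with the published
variance formula. The default p-value is from label permutations
(exactly enumerated when the number of distinct assignments is small),
which is reliable at the small per-class variant counts typical of
single-gene-family scans; an asymptotic interpolation of the published
percentile table is also available.
"""

from __future__ import annotations

import dataclasses
import itertools
import math
from typing import Sequence

import numpy as np
import pandas as pd

EFFECT_CLASSES = ("synonymous", "non-synonymous", "other")


@dataclasses.dataclass(frozen=True)
class VariantFrequencyRecord:
    variant_id: str
    gene: str
    continental_group: str
    effect: str
    frequency: float

    def __post_init__(self) -> None:
        if self.effect not in EFFECT_CLASSES:
            raise ValueError(f"unknown effect class {self.effect!r}")
        if not 0 <= self.frequency <= 1:
            raise ValueError(f"frequency {self.frequency} outside [0, 1]")


@dataclasses.dataclass
class AdTestResult:
    statistic: float           # A2akN
    standardized: float        # (A2akN - (k-1)) / sigma_N
    p_value: float | None
    p_method: str              # "permutation", "exact", "asymptotic"
    group_sizes: tuple[int, ...]
    untestable: bool = False
    note: str = ""


def variant_frequency(alt_copies: Sequence[int], copy_numbers: Sequence[int]
                      ) -> float:
    """Copy-weighted alternate frequency: sum_s j_s / sum_s N_s."""
    j = np.asarray(alt_copies, dtype=float)
    n = np.asarray(copy_numbers, dtype=float)
    if len(j) != len(n) or len(j) == 0:
        raise ValueError("need matching, non-empty j and N vectors")
    if np.any(j > n) or np.any(j < 0):
        raise ValueError("alt copies must lie in [0, N] per sample")
    total = n.sum()
    if total <= 0:
        raise ValueError("total copies is zero")
    return float(j.sum() / total)


def _a2akn(value_idx: np.ndarray, group_sizes: Sequence[int],
           l_j: np.ndarray) -> float:
    """Midrank statistic from pooled distinct-value indices.

    ``value_idx`` holds, for each observation laid out group after group,
    the index of its value among the L sorted distinct pooled values;
    ``l_j`` the pooled multiplicities.
    """
    n_total = len(value_idx)
    n_l = len(l_j)
    b_j = np.cumsum(l_j) - 0.5 * l_j      # pooled midrank counts
    denom = b_j * (n_total - b_j) - n_total * l_j / 4.0
    valid = denom > 0                      # last distinct value contributes 0
    a2 = 0.0
    start = 0
    for n_i in group_sizes:
        f_ij = np.bincount(value_idx[start:start + n_i], minlength=n_l
                           ).astype(float)
        start += n_i
        m_ij = np.cumsum(f_ij) - 0.5 * f_ij
        num = (n_total * m_ij - n_i * b_j) ** 2
        a2 += (l_j[valid] / n_total * num[valid] / denom[valid]).sum() / n_i
    return (n_total - 1) / n_total * a2


def _sigma_n(n_total: int, k: int, group_sizes: Sequence[int]) -> float:
    """Standard deviation of A2akN under H0 (published variance formula)."""
    big_h = sum(1.0 / n_i for n_i in group_sizes)
    small_h = sum(1.0 / i for i in range(1, n_total))
    g = sum(1.0 / ((n_total - i) * j)
            for i in range(1, n_total - 1)
            for j in range(i + 1, n_total))
    a = (4 * g - 6) * (k - 1) + (10 - 6 * g) * big_h
    b = (2 * g - 4) * k**2 + 8 * small_h * k + \
        (2 * g - 14 * small_h - 4) * big_h - 8 * small_h + 4 * g - 6
    c = (6 * small_h + 2 * g - 2) * k**2 + \
        (4 * small_h - 4 * g + 6) * k + (2 * small_h - 6) * big_h + 4 * small_h
    d = (2 * small_h + 6) * k**2 - 4 * small_h * k
    var = (a * n_total**3 + b * n_total**2 + c * n_total + d) / \
        ((n_total - 1) * (n_total - 2) * (n_total - 3))
    return math.sqrt(max(var, 0.0))


# percentile table of the standardized statistic: rows = significance
# levels, tm = b0 + b1/sqrt(m) + b2/m at m = k - 1
_SIG = np.array([0.25, 0.10, 0.05, 0.025, 0.01, 0.005, 0.001])
_B0 = np.array([0.675, 1.281, 1.645, 1.960, 2.326, 2.573, 3.085])
_B1 = np.array([-0.245, 0.250, 0.678, 1.149, 1.822, 2.364, 3.615])
_B2 = np.array([-0.105, -0.305, -0.481, -0.687, -0.914, -1.282, -2.288])


def _asymptotic_p(standardized: float, k: int) -> float:
    m = k - 1
    tm = _B0 + _B1 / math.sqrt(m) + _B2 / m
    coefs = np.polyfit(tm, np.log(_SIG), 2)
    p = math.exp(np.polyval(coefs, standardized))
    return float(min(max(p, 0.0), 1.0))


def ad_ksample(
    samples: Sequence[Sequence[float]],
    p_method: str = "permutation",
    n_permutations: int = 10_000,
    seed: int = 0,
) -> AdTestResult:
    """Tie-adjusted k-sample Anderson-Darling test.

    ``p_method`` one of "permutation" (default; switches to exact
    enumeration of all distinct label assignments when there are no more
    of them than ``n_permutations``), "exact" (always enumerate), or
    "asymptotic" (interpolated percentile table). Permutation p-values
    include the observed statistic in the numerator and denominator and
    are deterministic given ``seed``.
    """
    groups = [np.asarray(list(s), dtype=float) for s in samples]
    k = len(groups)
    if k < 2:
        raise ValueError(f"need k >= 2 samples, got {k}")
    if any(len(g) == 0 for g in groups):
        raise ValueError("every sample must be non-empty")
    sizes = tuple(len(g) for g in groups)
    pooled = np.concatenate(groups)
    n_total = len(pooled)
    if n_total < 4:
        raise ValueError("pooled sample size must be at least 4")
    zstar, value_idx_pooled = np.unique(pooled, return_inverse=True)
    l_j = np.bincount(value_idx_pooled).astype(float)
    if len(zstar) < 2:
        return AdTestResult(0.0, 0.0, None, p_method, sizes, untestable=True,
                            note="all pooled values identical")
    stat = _a2akn(value_idx_pooled, sizes, l_j)
    sigma = _sigma_n(n_total, k, sizes)
    standardized = (stat - (k - 1)) / sigma if sigma > 0 else 0.0

    if p_method == "asymptotic":
        return AdTestResult(stat, standardized, _asymptotic_p(standardized, k),
                            "asymptotic", sizes)
    if p_method not in ("permutation", "exact"):
        raise ValueError(f"unknown p_method {p_method!r}")

    n_exact = _n_assignments(sizes)
    if p_method == "exact" or n_exact <= n_permutations:
        ge = total = 0
        for perm_idx in _enumerate_assignments(n_total, sizes):
            s = _a2akn(value_idx_pooled[perm_idx], sizes, l_j)
            total += 1
            if s >= stat - 1e-12:
                ge += 1
        return AdTestResult(stat, standardized, ge / total, "exact", sizes)

    rng = np.random.default_rng(seed)
    ge = 0
    idx = value_idx_pooled.copy()
    for _ in range(n_permutations):
        rng.shuffle(idx)
        if _a2akn(idx, sizes, l_j) >= stat - 1e-12:
            ge += 1
    p = (ge + 1) / (n_permutations + 1)
    return AdTestResult(stat, standardized, p, "permutation", sizes)


def _n_assignments(sizes: Sequence[int]) -> int:
    n = sum(sizes)
    total = 1
    remaining = n
    for s in sizes[:-1]:
        total *= math.comb(remaining, s)
        remaining -= s
    return total


def _enumerate_assignments(n_total: int, sizes: Sequence[int]):
    """Yield index arrays for every distinct assignment of positions to groups."""
    def rec(avail: tuple[int, ...], remaining_sizes: tuple[int, ...]):
        if len(remaining_sizes) == 1:
            yield list(avail)
            return
        s = remaining_sizes[0]
        for chosen in itertools.combinations(avail, s):
            rest = tuple(a for a in avail if a not in set(chosen))
            for tail in rec(rest, remaining_sizes[1:]):
                yield list(chosen) + tail
    for assignment in rec(tuple(range(n_total)), tuple(sizes)):
        yield np.array(assignment, dtype=int)


def compare_ns_s(
    records: Sequence[VariantFrequencyRecord],
    group: str,
    p_method: str = "permutation",
    n_permutations: int = 10_000,
    seed: int = 0,
) -> AdTestResult:
    """NS-vs-S frequency-spectrum test for one continental group.

    Pools variants across genes within the group. With fewer than 2
    variants in either class the result is flagged untestable rather
    than raising.
    """
    ns = [r.frequency for r in records
          if r.continental_group == group and r.effect == "non-synonymous"]
    s = [r.frequency for r in records
         if r.continental_group == group and r.effect == "synonymous"]
    if len(ns) < 2 or len(s) < 2:
        return AdTestResult(float("nan"), float("nan"), None, p_method,
                            (len(ns), len(s)), untestable=True,
                            note="fewer than 2 variants in a class")
    return ad_ksample([ns, s], p_method, n_permutations, seed)


def results_frame(results: dict[str, AdTestResult]) -> pd.DataFrame:
    rows = []
    for group, r in results.items():
        rows.append({
            "group": group, "k": len(r.group_sizes),
            "sizes": "/".join(map(str, r.group_sizes)),
            "A2akN": r.statistic, "standardized": r.standardized,
            "p_value": r.p_value, "p_method": r.p_method,
            "untestable": r.untestable,
        })
    return pd.DataFrame(rows)
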