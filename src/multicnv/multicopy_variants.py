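"""Ploidy-aware site-level variant calling in a multicopy region.

A sample carrying N copies of the region (N = its integer copy-number
call) can hold j = 0..N alternate copies at a paralogous site, so the
expected alternate-read fraction is j/N rather than the diploid 0, 1/2,
1. Genotypes are called from filtered allele counts with a binomial
likelihood over j:

    L(j) = Binom(n_alt; n_alt + n_ref, p_j),
    p_j  = (j/N)(1 - eps) + (1 - j/N) eps,

where eps is the residual per-read error rate after quality filtering.
A flat prior over j gives the posterior; the maximum-posterior j is the
call (ties to the lower j). Evidence filters mirror common practice for
multicopy loci: a variant is only reported when the alternate allele has
at least ``min_alt_count`` supporting reads and at least
``min_alt_fraction`` of the filtered depth.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy.stats import binom


@dataclasses.dataclass(frozen=True)
class Site:
    chrom: str
    pos: int          # 1-based position, VCF convention
    ref: str
    alt: str


@dataclasses.dataclass(frozen=True)
class CallerConfig:
    min_base_quality: int = 30
    min_mapping_quality: int = 50
    min_alt_fraction: float = 0.10
    min_alt_count: int = 10
    base_error: float = 0.005

    def __post_init__(self) -> None:
        if not 0 < self.base_error < 0.5:
            raise ValueError("base_error must lie in (0, 0.5)")
        if min(self.min_base_quality, self.min_mapping_quality,
               self.min_alt_count) < 0 or self.min_alt_fraction < 0:
            raise ValueError("thresholds must be non-negative")


@dataclasses.dataclass
class SiteObservation:
    sample_id: str
    site: Site
    n_ref: int
    n_alt: int
    total_depth: int
    copy_number: int

    def __post_init__(self) -> None:
        if self.n_ref + self.n_alt > self.total_depth:
            raise ValueError("allele counts exceed total depth")
        if self.copy_number < 1:
            raise ValueError("copy number must be >= 1")


@dataclasses.dataclass
class MulticopyGenotype:
    sample_id: str
    site: Site
    copy_number: int                  # N
    alt_copies: int                   # j
    genotype: str                     # e.g. "AGGG" for j=1, N=4, sorted
    posterior: np.ndarray             # over j = 0..N
    no_call: bool = False
    no_call_reason: str = ""

    def __post_init__(self) -> None:
        if not 0 <= self.alt_copies <= self.copy_number:
            raise ValueError("alt copies outside [0, N]")
        if len(self.genotype) != self.copy_number:
            raise ValueError("genotype string length must equal N")


def genotype_string(ref: str, alt: str, j: int, n: int) -> str:
    """Alphabetically sorted string of j alt and N - j ref bases."""
    return "".join(sorted(alt * j + ref * (n - j)))


def filter_reads(
    reads: Iterable[tuple[str, int, int]],
    ref: str,
    alt: str,
    cfg: CallerConfig = CallerConfig(),
) -> tuple[int, int, int]:
    """Tally (n_ref, n_alt, n_discarded) from (base, base_q, map_q) reads.

    A read is kept iff base quality >= min_base_quality AND mapping
    quality >= min_mapping_quality (both inclusive). Kept reads carrying
    neither the ref nor the alt base are discarded and counted.
    """
    n_ref = n_alt = n_discarded = 0
    for base, base_q, map_q in reads:
        if base_q < cfg.min_base_quality or map_q < cfg.min_mapping_quality:
            n_discarded += 1
        elif base == ref:
            n_ref += 1
        elif base == alt:
            n_alt += 1
        else:
            n_discarded += 1
    return n_ref, n_alt, n_discarded


def genotype_likelihoods(
    n_alt: int, n_ref: int, copy_number: int, base_error: float = 0.005
) -> tuple[np.ndarray, np.ndarray, int | None]:
    """Likelihood and flat-prior posterior over j = 0..N; MAP j (ties low).

    Returns (likelihood, posterior, map_j); map_j is None when there is
    no coverage.
    """
    n = copy_number
    if n < 1:
        raise ValueError("copy number must be >= 1")
    depth = n_alt + n_ref
    j = np.arange(n + 1)
    p_j = (j / n) * (1 - base_error) + (1 - j / n) * base_error
    if depth == 0:
        flat = np.full(n + 1, 1.0 / (n + 1))
        return np.ones(n + 1), flat, None
    lik = binom.pmf(n_alt, depth, p_j)
    total = lik.sum()
    if total == 0:
        # numerically underflowed; fall back to log-space comparison
        loglik = binom.logpmf(n_alt, depth, p_j)
        post = np.exp(loglik - loglik.max())
        post /= post.sum()
    else:
        post = lik / total
    return lik, post, int(np.argmax(post))


def call_site(
    obs: SiteObservation, cfg: CallerConfig = CallerConfig()
) -> MulticopyGenotype:
    """Call the multicopy genotype at one site for one sample.

    The alternate allele must clear both evidence filters
    (n_alt >= min_alt_count and alt fraction >= min_alt_fraction);
    otherwise the genotype is forced to j = 0 and flagged no_call with
    reason "evidence filters". Zero filtered coverage yields no_call
    "no coverage".
    """
    n = obs.copy_number
    depth = obs.n_alt + obs.n_ref
    site = obs.site
    if depth == 0:
        return MulticopyGenotype(
            obs.sample_id, site, n, 0, genotype_string(site.ref, site.alt, 0, n),
            np.full(n + 1, 1.0 / (n + 1)), no_call=True,
            no_call_reason="no coverage")
    frac = obs.n_alt / depth
    if obs.n_alt < cfg.min_alt_count or frac < cfg.min_alt_fraction:
        _, post, _ = genotype_likelihoods(obs.n_alt, obs.n_ref, n,
                                          cfg.base_error)
        return MulticopyGenotype(
            obs.sample_id, site, n, 0, genotype_string(site.ref, site.alt, 0, n),
            post, no_call=obs.n_alt > 0,
            no_call_reason="evidence filters" if obs.n_alt > 0 else "")
    _, post, map_j = genotype_likelihoods(obs.n_alt, obs.n_ref, n,
                                          cfg.base_error)
    return MulticopyGenotype(
        obs.sample_id, site, n, map_j,
        genotype_string(site.ref, site.alt, map_j, n), post)


def expected_alt_fraction(genotype: MulticopyGenotype | tuple[int, int]) -> float:
    """Expected alternate-read fraction of a genotype: j / N.

    A genotype with one alternate copy out of four (e.g. AGGG with alt A)
    is expected to show the alternate in a quarter of the reads.
    """
    if isinstance(genotype, MulticopyGenotype):
        j, n = genotype.alt_copies, genotype.copy_number
    else:
        j, n = genotype
    if not 0 <= j <= n or n < 1:
        raise ValueError(f"invalid genotype (j={j}, N={n})")
    return j / n


# ---------------------------------------------------------------------------
# VCF output

VCF_HEADER = """\
##fileformat=VCFv4.2
##source=multicnv
##INFO=<ID=NS,Number=1,Type=Integer,Description="Number of samples with data">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype (unphased, one allele index per copy)">
##FORMAT=<ID=CN,Number=1,Type=Integer,Description="Integer copy number of the region (ploidy at this site)">
##FORMAT=<ID=ACN,Number=1,Type=Integer,Description="Alternate copy count j out of CN">
"""


def write_variant_calls(
    genotypes: Sequence[MulticopyGenotype], path: str | Path
) -> None:
    """Write calls as VCF 4.2 with per-sample CN and ACN FORMAT fields.

    Sites are sorted on write; one record per site with one genotype
    column per sample. Two conflicting records (same chrom/pos but
    different ref or alt) raise an error.
    """
    by_site: dict[Site, dict[str, MulticopyGenotype]] = {}
    samples: list[str] = []
    for g in genotypes:
        by_site.setdefault(g.site, {})[g.sample_id] = g
        if g.sample_id not in samples:
            samples.append(g.sample_id)
    positions: dict[tuple[str, int], Site] = {}
    for site in by_site:
        key = (site.chrom, site.pos)
        if key in positions and positions[key] != site:
            raise ValueError(f"conflicting records at {site.chrom}:{site.pos}")
        positions[key] = site
    with open(path, "w") as fh:
        fh.write(VCF_HEADER)
        # FORMAT and genotype columns appear only when there are samples
        cols = "\tFORMAT" + "".join(f"\t{s}" for s in samples) if samples \
            else ""
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO"
                 + cols + "\n")
        for site in sorted(by_site, key=lambda s: (s.chrom, s.pos)):
            calls = by_site[site]
            cols = []
            for s in samples:
                g = calls.get(s)
                if g is None:
                    cols.append("./.")
                    continue
                gt = "/".join(["1"] * g.alt_copies
                              + ["0"] * (g.copy_number - g.alt_copies)) or "."
                cols.append(f"{gt}:{g.copy_number}:{g.alt_copies}")
            fh.write(f"{site.chrom}\t{site.pos}\t.\t{site.ref}\t{site.alt}"
                     f"\t.\tPASS\tNS={len(calls)}\tGT:CN:ACN\t"
                     + "\t".join(cols) + "\n")


def read_variant_calls(path: str | Path) -> list[MulticopyGenotype]:
    """Read back a VCF written by :func:`write_variant_calls` (cyvcf2)."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = vcf.samples
    out: list[MulticopyGenotype] = []
    for rec in vcf:
        site = Site(rec.CHROM, rec.POS, rec.REF, rec.ALT[0])
        cns = rec.format("CN")
        acns = rec.format("ACN")
        if cns is None:
            continue
        for i, s in enumerate(samples):
            cn, acn = int(cns[i][0]), int(acns[i][0])
            if cn < 0:   # missing sample in this record
                continue
            out.append(MulticopyGenotype(
                s, site, cn, acn, genotype_string(site.ref, site.alt, acn, cn),
                np.full(cn + 1, np.nan)))
    return out
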