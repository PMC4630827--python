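"""Target construction and depth-matrix I/O.

The unit of depth counting is a *target region*: an exon extended by a
fixed flank on both sides, with nearby exons merged into one contiguous
region when the genomic gap between them is smaller than a threshold.
Coordinates are 0-based half-open (BED convention) throughout; GFF-style
1-based inclusive input is converted on load.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

DEFAULT_FLANK = 300
DEFAULT_MERGE_GAP = 600


class ValidationError(ValueError):
    """Raised when an input file or record violates a contract."""


@dataclasses.dataclass(frozen=True, order=True)
class ExonTarget:
    """One exon interval (0-based, half-open) attributed to a gene."""

    chrom: str
    start: int
    end: int
    gene: str

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValidationError("exon with empty chromosome name")
        if self.start < 0:
            raise ValidationError(
                f"negative coordinate {self.start} for {self.gene}")
        if self.end <= self.start:
            raise ValidationError(
                f"degenerate interval [{self.start}, {self.end}) for {self.gene}")


@dataclasses.dataclass(frozen=True)
class TargetRegion:
    """A flank-extended, merge-resolved interval; the unit of depth counting."""

    chrom: str
    start: int
    end: int
    genes: frozenset[str]

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValidationError(
                f"degenerate region [{self.start}, {self.end})")

    @property
    def length_bp(self) -> int:
        return self.end - self.start

    @property
    def region_id(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}"


@dataclasses.dataclass(frozen=True)
class SampleMeta:
    """Sample provenance; batch = (sequencing centre, continental group)."""

    sample_id: str
    population: str
    continental_group: str
    centre: str

    @property
    def batch_id(self) -> str:
        return f"{self.centre}:{self.continental_group}"


@dataclasses.dataclass
class DepthMatrix:
    """Read counts per (target, sample) plus per-sample library sizes.

    ``counts`` is a DataFrame indexed by target region id with one column
    per sample; ``total_mapped_reads`` is a Series over the same samples.
    """

    targets: list[TargetRegion]
    samples: list[SampleMeta]
    counts: pd.DataFrame
    total_mapped_reads: pd.Series

    def __post_init__(self) -> None:
        sample_ids = [s.sample_id for s in self.samples]
        if len(set(sample_ids)) != len(sample_ids):
            dupes = sorted({s for s in sample_ids if sample_ids.count(s) > 1})
            raise ValidationError(f"duplicate sample ids: {dupes}")
        if self.counts.shape != (len(self.targets), len(self.samples)):
            raise ValidationError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.targets)} targets x {len(self.samples)} samples")
        if (self.counts.values < 0).any():
            raise ValidationError("negative read counts")
        colsum = self.counts.sum(axis=0)
        short = self.total_mapped_reads.reindex(sample_ids)
        if short.isna().any():
            missing = sorted(short.index[short.isna()])
            raise ValidationError(f"missing total read counts for {missing}")
        if (short < colsum).any():
            bad = sorted(colsum.index[short < colsum])
            raise ValidationError(
                f"total_mapped_reads below on-target counts for {bad}")

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    @property
    def target_lengths_bp(self) -> np.ndarray:
        return np.array([t.length_bp for t in self.targets], dtype=float)

    def meta_frame(self) -> pd.DataFrame:
        rows = [
            (s.sample_id, s.population, s.continental_group, s.centre, s.batch_id)
            for s in self.samples
        ]
        return pd.DataFrame(
            rows,
            columns=["sample_id", "population", "continental_group", "centre",
                     "batch_id"],
        ).set_index("sample_id")


# ---------------------------------------------------------------------------
# annotation loading

def load_exon_annotation(path: str | Path, dialect: str = "bed") -> list[ExonTarget]:
    """Read exon intervals from a BED4 file or a gff-like TSV.

    dialect "bed": whitespace-separated chrom/start/end/gene, 0-based
    half-open. dialect "tsv": header with named columns chrom, start, end,
    gene and an optional one_based column; rows flagged one_based (or all
    rows, when the column is absent and one_based semantics are requested
    via the column) are converted from 1-based inclusive coordinates.
    Identical intervals (same chrom/start/end/gene) are deduplicated.
    """
    path = Path(path)
    exons: list[ExonTarget] = []
    if dialect == "bed":
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.strip()
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                fields = line.split()
                if len(fields) < 4:
                    raise ValidationError(
                        f"{path}:{lineno}: expected 4 BED columns, got "
                        f"{len(fields)}")
                chrom, start_s, end_s, gene = fields[:4]
                try:
                    start, end = int(start_s), int(end_s)
                except ValueError as exc:
                    raise ValidationError(
                        f"{path}:{lineno}: non-integer coordinate") from exc
                try:
                    exons.append(ExonTarget(chrom, start, end, gene))
                except ValidationError as exc:
                    raise ValidationError(f"{path}:{lineno}: {exc}") from exc
    elif dialect in ("tsv", "gff-like", "gff"):
        df = pd.read_csv(path, sep="\t")
        required = {"chrom", "start", "end", "gene"}
        if not required.issubset(df.columns):
            raise ValidationError(
                f"{path}: missing columns {sorted(required - set(df.columns))}")
        one_based = df["one_based"].astype(bool) if "one_based" in df.columns \
            else pd.Series(True, index=df.index)
        for i, row in df.iterrows():
            start, end = int(row["start"]), int(row["end"])
            if one_based.loc[i]:
                start -= 1  # 1-based inclusive -> 0-based half-open
            try:
                exons.append(ExonTarget(str(row["chrom"]), start, end,
                                        str(row["gene"])))
            except ValidationError as exc:
                raise ValidationError(f"{path}: row {i + 2}: {exc}") from exc
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    return sorted(set(exons))


def build_flanked_targets(
    exons: Sequence[ExonTarget],
    flank: int = DEFAULT_FLANK,
    merge_gap: int = DEFAULT_MERGE_GAP,
) -> list[TargetRegion]:
    """Extend each exon by ``flank`` bp and merge exons closer than ``merge_gap``.

    Two same-chromosome exons whose inter-exon gap is *strictly* less than
    ``merge_gap`` contribute to one contiguous region covering both (plus
    flanks); abutting flank-extended intervals at gap exactly ``merge_gap``
    stay separate. Gene attributions of merged exons are unioned. Flanks
    clip at coordinate 0.
    """
    if flank < 0 or merge_gap < 0:
        raise ValueError("flank and merge_gap must be non-negative")
    regions: list[TargetRegion] = []
    for exon in sorted(set(exons)):
        start = max(0, exon.start - flank)
        end = exon.end + flank
        if regions and regions[-1].chrom == exon.chrom and (
                exon.start - (regions[-1].end - flank) < merge_gap
                or start < regions[-1].end):
            prev = regions[-1]
            regions[-1] = TargetRegion(
                prev.chrom, prev.start, max(prev.end, end),
                prev.genes | {exon.gene})
        else:
            regions.append(TargetRegion(exon.chrom, start, end,
                                        frozenset({exon.gene})))
    return regions


def write_targets_bed(regions: Iterable[TargetRegion], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in regions:
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t"
                     f"{';'.join(sorted(r.genes))}\n")


def gene_to_targets(regions: Sequence[TargetRegion]) -> dict[str, list[int]]:
    """Map each gene symbol to the indices of regions it contributed exons to."""
    out: dict[str, list[int]] = {}
    for i, r in enumerate(regions):
        for g in r.genes:
            out.setdefault(g, []).append(i)
    return out


# ---------------------------------------------------------------------------
# depth matrix loading

def load_sample_metadata(path: str | Path) -> dict[str, SampleMeta]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample_id", "population", "continental_group", "centre"}
    if not required.issubset(df.columns):
        raise ValidationError(
            f"{path}: missing columns {sorted(required - set(df.columns))}")
    metas: dict[str, SampleMeta] = {}
    for _, row in df.iterrows():
        sid = row["sample_id"]
        if sid in metas:
            raise ValidationError(f"{path}: duplicate sample_id {sid}")
        metas[sid] = SampleMeta(sid, row["population"],
                                row["continental_group"], row["centre"])
    return metas


def load_depth_matrix(
    counts_path: str | Path,
    meta_path: str | Path,
    totals_path: str | Path,
    targets: Sequence[TargetRegion],
) -> DepthMatrix:
    """Assemble a validated DepthMatrix from its three on-disk tables.

    ``counts_path``: TSV, first column target_id, one column per sample.
    ``totals_path``: TSV with columns sample_id, total_mapped_reads.
    Samples present in the counts header but absent from the metadata are
    rejected by name.
    """
    counts = pd.read_csv(counts_path, sep="\t", index_col=0)
    metas = load_sample_metadata(meta_path)
    totals_df = pd.read_csv(totals_path, sep="\t")
    if not {"sample_id", "total_mapped_reads"}.issubset(totals_df.columns):
        raise ValidationError(f"{totals_path}: need sample_id and "
                              "total_mapped_reads columns")
    totals = totals_df.set_index("sample_id")["total_mapped_reads"].astype(float)

    missing = [s for s in counts.columns if s not in metas]
    if missing:
        raise ValidationError(f"samples without metadata: {missing}")
    expected_ids = [t.region_id for t in targets]
    if list(counts.index) != expected_ids:
        raise ValidationError(
            f"counts rows do not match the {len(expected_ids)} expected "
            "target regions (order and ids must agree)")
    samples = [metas[s] for s in counts.columns]
    return DepthMatrix(list(targets), samples, counts.astype(float),
                       totals.reindex(counts.columns))
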