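"""Genomic-interval engine: union merge, peak annotation, region enrichment.

Coordinates are 0-based half-open throughout (BED convention); any 1-based
input must be converted at the boundary. A gene's TSS is ``start`` on the
plus strand and ``end - 1`` on the minus strand.

Annotation assigns each peak exactly one category by priority:
promoter > exon > intron > downstream > distal intergenic, where the
promoter window spans ``promoter_upstream`` bases upstream through
``promoter_downstream`` bases downstream of the TSS in transcription
orientation, "overlap" means at least one shared base, and "downstream"
is a window past the gene's 3' end. 5'/3' UTRs are folded into "exon".

Region enrichment scores a query peak set against a labeled catalog with a
shuffle null: each query peak is uniformly re-placed on its own chromosome
(length preserved) ``n_shuffles`` times; the observed count of query peaks
touching the catalog is compared to the null via a z-score and an add-one
empirical p-value, (1 + #{null >= obs}) / (n_shuffles + 1), which can never
be zero. BH correction is applied across catalog labels.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import false_discovery_control

__all__ = [
    "GenomicInterval",
    "GeneModel",
    "AnnotationParams",
    "EnrichmentResult",
    "CATEGORIES",
    "merge_union",
    "annotate_peak",
    "genomic_distribution",
    "region_enrichment",
    "read_bed",
    "write_bed",
    "read_chrom_sizes",
    "read_gene_models",
    "write_gene_models",
]

CATEGORIES = ("promoter", "exon", "intron", "downstream", "distal intergenic")


@dataclass(frozen=True, order=True)
class GenomicInterval:
    chrom: str
    start: int
    end: int
    name: str | None = None
    score: float | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, start: int, end: int) -> bool:
        return self.start < end and start < self.end


@dataclass(frozen=True)
class GeneModel:
    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    exons: tuple[tuple[int, int], ...] = ()

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id!r}: strand must be + or -")
        if not 0 <= self.start < self.end:
            raise ValueError(f"gene {self.gene_id!r}: invalid interval")
        prev_end = self.start
        for s, e in self.exons:
            if s < self.start or e > self.end or s >= e or s < prev_end:
                raise ValueError(
                    f"gene {self.gene_id!r}: exons must be sorted, disjoint and "
                    "within the gene interval"
                )
            prev_end = e

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end - 1


@dataclass(frozen=True)
class AnnotationParams:
    promoter_upstream: int = 3000
    promoter_downstream: int = 3000
    downstream_window: int = 3000

    def __post_init__(self) -> None:
        if min(self.promoter_upstream, self.promoter_downstream, self.downstream_window) < 0:
            raise ValueError("annotation windows must be >= 0")


@dataclass
class EnrichmentResult:
    label: str
    observed: int
    null_mean: float
    null_sd: float
    z: float | None  # None when the null is degenerate (SD = 0)
    p: float
    q: float | None = None


def merge_union(*interval_lists: Iterable[GenomicInterval]) -> list[GenomicInterval]:
    """Per-chromosome union of all intervals, sorted and non-overlapping.

    Touching intervals (end == next start) are merged into one.
    """
    pooled = [iv for lst in interval_lists for iv in lst]
    merged: list[GenomicInterval] = []
    for chrom in sorted({iv.chrom for iv in pooled}):
        spans = sorted((iv.start, iv.end) for iv in pooled if iv.chrom == chrom)
        cur_s, cur_e = spans[0]
        for s, e in spans[1:]:
            if s <= cur_e:
                cur_e = max(cur_e, e)
            else:
                merged.append(GenomicInterval(chrom, cur_s, cur_e))
                cur_s, cur_e = s, e
        merged.append(GenomicInterval(chrom, cur_s, cur_e))
    return merged


def _promoter_window(gene: GeneModel, params: AnnotationParams) -> tuple[int, int]:
    if gene.strand == "+":
        lo = gene.tss - params.promoter_upstream
        hi = gene.tss + params.promoter_downstream
    else:  # upstream is to the right of the TSS
        lo = gene.tss - params.promoter_downstream + 1
        hi = gene.tss + params.promoter_upstream + 1
    return max(lo, 0), hi


def _downstream_window(gene: GeneModel, params: AnnotationParams) -> tuple[int, int]:
    if gene.strand == "+":
        return gene.end, gene.end + params.downstream_window
    return max(gene.start - params.downstream_window, 0), gene.start


def annotate_peak(
    peak: GenomicInterval,
    genes: Sequence[GeneModel],
    params: AnnotationParams = AnnotationParams(),
) -> str:
    """Assign one category, testing all genes per category in priority order."""
    same_chrom = [g for g in genes if g.chrom == peak.chrom]
    for lo, hi in (_promoter_window(g, params) for g in same_chrom):
        if lo < peak.end and peak.start < hi:
            return "promoter"
    for g in same_chrom:
        for s, e in g.exons:
            if s < peak.end and peak.start < e:
                return "exon"
    for g in same_chrom:
        if g.start < peak.end and peak.start < g.end:
            return "intron"
    for lo, hi in (_downstream_window(g, params) for g in same_chrom):
        if lo < hi and lo < peak.end and peak.start < hi:
            return "downstream"
    return "distal intergenic"


def genomic_distribution(
    peaks: Sequence[GenomicInterval],
    genes: Sequence[GeneModel],
    params: AnnotationParams = AnnotationParams(),
) -> dict[str, float]:
    """Fraction of peaks per category; fractions sum to 1."""
    if not peaks:
        raise ValueError("empty peak set")
    counts = dict.fromkeys(CATEGORIES, 0)
    for peak in peaks:
        counts[annotate_peak(peak, genes, params)] += 1
    total = len(peaks)
    return {cat: counts[cat] / total for cat in CATEGORIES}


def _overlap_counts(
    starts: np.ndarray,
    lengths: np.ndarray,
    cat_starts: np.ndarray,
    cat_ends: np.ndarray,
) -> np.ndarray:
    """Count peaks (rows of ``starts``) overlapping a merged catalog.

    ``starts`` is (n_rows, n_peaks); catalog arrays are sorted, disjoint.
    A peak [s, s+len) overlaps iff the last catalog interval starting before
    its end extends past its start.
    """
    ends = starts + lengths
    idx = np.searchsorted(cat_starts, ends, side="left")
    hit = idx > 0
    prev_end = np.where(hit, cat_ends[np.maximum(idx - 1, 0)], 0)
    return np.sum(hit & (prev_end > starts), axis=1)


def region_enrichment(
    query: Sequence[GenomicInterval],
    catalog: Mapping[str, Sequence[GenomicInterval]],
    chrom_sizes: Mapping[str, int],
    n_shuffles: int = 1000,
    seed: int = 0,
) -> list[EnrichmentResult]:
    """Shuffle-null enrichment of a query peak set against each catalog label.

    Each shuffle re-places every query peak uniformly on its own chromosome,
    preserving its length. ``z`` is reported as ``None`` when the null has
    zero spread; the empirical p uses the add-one rule so it is never 0.
    """
    if n_shuffles < 1:
        raise ValueError("n_shuffles must be >= 1")
    for iv in query:
        if iv.chrom not in chrom_sizes or iv.end > chrom_sizes[iv.chrom]:
            raise ValueError(f"query interval {iv} exceeds chromosome bounds")
    for label, ivs in catalog.items():
        for iv in ivs:
            if iv.chrom not in chrom_sizes or iv.end > chrom_sizes[iv.chrom]:
                raise ValueError(f"catalog {label!r}: interval {iv} exceeds bounds")

    rng = np.random.default_rng(seed)
    chroms = sorted({iv.chrom for iv in query})
    # Pre-draw shuffled starts once per chromosome; reused across labels so
    # all labels share the same null placements (and the seed fixes them).
    placements: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    for chrom in chroms:
        lengths = np.array([len(iv) for iv in query if iv.chrom == chrom])
        obs_starts = np.array([iv.start for iv in query if iv.chrom == chrom])
        max_start = chrom_sizes[chrom] - lengths  # inclusive upper bound
        null_starts = rng.integers(
            0, max_start + 1, size=(n_shuffles, len(lengths))
        )
        placements[chrom] = (obs_starts, lengths, null_starts)

    results: list[EnrichmentResult] = []
    for label in catalog:
        merged = merge_union(catalog[label])
        observed = 0
        null = np.zeros(n_shuffles, dtype=int)
        for chrom in chroms:
            obs_starts, lengths, null_starts = placements[chrom]
            spans = [(iv.start, iv.end) for iv in merged if iv.chrom == chrom]
            if not spans:
                continue
            cat_s = np.array([s for s, _ in spans])
            cat_e = np.array([e for _, e in spans])
            observed += int(
                _overlap_counts(obs_starts[None, :], lengths, cat_s, cat_e)[0]
            )
            null += _overlap_counts(null_starts, lengths, cat_s, cat_e)
        mean = float(null.mean())
        sd = float(null.std(ddof=0))
        z = (observed - mean) / sd if sd > 0 else None
        p = (1 + int(np.sum(null >= observed))) / (n_shuffles + 1)
        results.append(
            EnrichmentResult(label, observed, mean, sd, z, p)
        )

    qvals = false_discovery_control([r.p for r in results], method="bh")
    for r, q in zip(results, qvals):
        r.q = float(q)
    return results


# ---------------------------------------------------------------------------
# text-format IO


def read_bed(path: str | Path) -> list[GenomicInterval]:
    """BED3/BED6 reader (track/browser/# lines skipped)."""
    out: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}: line {lineno}: BED needs >=3 columns")
            name = fields[3] if len(fields) > 3 and fields[3] != "." else None
            score = (
                float(fields[4]) if len(fields) > 4 and fields[4] != "." else None
            )
            out.append(
                GenomicInterval(fields[0], int(fields[1]), int(fields[2]), name, score)
            )
    return out


def write_bed(intervals: Iterable[GenomicInterval], path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            name = iv.name if iv.name is not None else "."
            score = f"{iv.score:g}" if iv.score is not None else "."
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t{score}\t.\n")


def read_chrom_sizes(path: str | Path) -> dict[str, int]:
    sizes: dict[str, int] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            chrom, size = line.split("\t")[:2]
            sizes[chrom] = int(size)
    return sizes


def read_gene_models(path: str | Path) -> list[GeneModel]:
    """Gene models TSV: chrom, start, end, strand, gene_id, exon blocks.

    Exon blocks mimic BED12: comma-separated ``offset:length`` pairs
    relative to the gene start.
    """
    genes: list[GeneModel] = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            chrom, start_s, end_s, strand, gene_id, blocks = line.rstrip("\n").split("\t")[:6]
            start = int(start_s)
            exons = tuple(
                (start + int(off), start + int(off) + int(ln))
                for off, ln in (b.split(":") for b in blocks.split(",") if b)
            )
            genes.append(GeneModel(gene_id, chrom, start, int(end_s), strand, exons))
    return genes


def write_gene_models(genes: Iterable[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("#chrom\tstart\tend\tstrand\tgene_id\texon_blocks\n")
        for g in genes:
            blocks = ",".join(f"{s - g.start}:{e - s}" for s, e in g.exons)
            fh.write(f"{g.chrom}\t{g.start}\t{g.end}\t{g.strand}\t{g.gene_id}\t{blocks}\n")


def enrichment_table(results: Sequence[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "label": [r.label for r in results],
            "observed": [r.observed for r in results],
            "null_mean": [r.null_mean for r in results],
            "null_sd": [r.null_sd for r in results],
            "z": [r.z if r.z is not None else np.nan for r in results],
            "p": [r.p for r in results],
            "q": [r.q for r in results],
        }
    )
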