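"""Synthetic inputs with the statistical structure the pipeline assumes.

Four generators cover the four analysis substrates:

* ``simulate_cohort`` — a multi-subgroup expression cohort in which each
  subgroup activates its own marker gene sets (a +delta mean shift on log2
  scale) on top of per-gene log-normal baselines, with samples assigned to
  platforms that apply strictly monotone per-sample distortions. This
  emulates training corpora that mix array platforms, where gene-set scores
  are robust to platform differences even though individual genes are not.
* ``simulate_xenograft_alignments`` — read pairs of known graft (human) or
  host (mouse) origin whose alignment scores favor the true genome by a
  configurable gap, plus exactly tied ambiguous pairs.
* ``simulate_de_tables`` — per-contrast DE tables with planted exclusive-up,
  exclusive-down and shared-but-direction-mixed genes, background-contrast
  confounders, and low-count genes; every non-planted gene fails at least
  one significance threshold.
* ``simulate_genome`` / ``plant_peaks`` — non-overlapping gene models on
  synthetic chromosomes and peaks guaranteed (by round-trip through the
  annotation rules) to fall in a requested genomic category.

All generators are deterministic given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .disambiguate import AlignedReadPair
from .genesets import GeneSet, GeneSetCollection
from .peaks import AnnotationParams, GeneModel, GenomicInterval, annotate_peak

__all__ = [
    "PlatformDistortion",
    "CohortSpec",
    "SimulatedCohort",
    "XenograftSpec",
    "DESimulation",
    "simulate_cohort",
    "simulate_xenograft_alignments",
    "simulate_de_tables",
    "simulate_genome",
    "plant_peaks",
    "write_ortholog_map",
    "write_pairs_tsv",
]


@dataclass(frozen=True)
class PlatformDistortion:
    """Strictly increasing per-sample transform: intercept + slope * x^power.

    The power is applied through the odd extension sign(x)*|x|^power so the
    transform is strictly increasing over the whole real line.
    """

    name: str
    slope: float = 1.0
    intercept: float = 0.0
    power: float = 1.0

    def __post_init__(self) -> None:
        if self.slope <= 0 or self.power <= 0:
            raise ValueError("slope and power must be > 0 for a strictly increasing map")

    def apply(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        return self.intercept + self.slope * np.sign(x) * np.abs(x) ** self.power


DEFAULT_PLATFORMS = (
    PlatformDistortion("arrayA"),
    PlatformDistortion("arrayB", slope=1.4, intercept=2.0, power=1.15),
)


@dataclass(frozen=True)
class CohortSpec:
    """Study conditions for the planted multi-subgroup expression cohort.

    Defaults are the conditions the classifier is evaluated under: four
    subgroups of 40 samples, 2000 genes, 200 gene sets of 30 genes of which
    4 per subgroup are markers, a +2 log2 mean shift on marker-set genes,
    residual noise SD 0.5, and two platforms with monotone distortions.
    """

    n_subgroups: int = 4
    samples_per_subgroup: int = 40
    n_genes: int = 2000
    marker_sets_per_subgroup: int = 4
    effect_size_delta: float = 2.0
    noise_sd: float = 0.5
    platforms: tuple[PlatformDistortion, ...] = DEFAULT_PLATFORMS
    seed: int = 0
    n_gene_sets: int = 200
    genes_per_set: int = 30
    baseline_mean: float = 6.0
    baseline_sd: float = 2.0

    def __post_init__(self) -> None:
        for name in ("n_subgroups", "samples_per_subgroup", "n_genes",
                     "marker_sets_per_subgroup", "n_gene_sets", "genes_per_set"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not self.platforms:
            raise ValueError("need at least one platform")
        n_marker_sets = self.n_subgroups * self.marker_sets_per_subgroup
        if n_marker_sets > self.n_gene_sets:
            raise ValueError("marker sets exceed n_gene_sets")
        if n_marker_sets * self.genes_per_set > self.n_genes:
            raise ValueError("marker-set genes exceed n_genes")


@dataclass
class SimulatedCohort:
    expression: pd.DataFrame          # genes x samples, after platform distortion
    undistorted: pd.DataFrame         # genes x samples, before platform distortion
    labels: pd.Series                 # sample -> subgroup
    sample_platform: pd.Series        # sample -> platform name
    gene_sets: GeneSetCollection
    marker_map: dict[str, list[str]]  # subgroup -> marker set names


def simulate_cohort(spec: CohortSpec) -> SimulatedCohort:
    """Generate the planted cohort; reproducible given ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    genes = np.array([f"G{i:05d}" for i in range(spec.n_genes)], dtype=object)
    subgroups = [f"SG{k + 1}" for k in range(spec.n_subgroups)]
    samples = [
        f"{sg}_s{i:03d}" for sg in subgroups for i in range(spec.samples_per_subgroup)
    ]
    labels = pd.Series(
        [sg for sg in subgroups for _ in range(spec.samples_per_subgroup)],
        index=samples,
        name="subgroup",
    )

    # Disjoint marker-gene blocks per marker set, drawn from a permutation.
    perm = rng.permutation(spec.n_genes)
    n_marker_sets = spec.n_subgroups * spec.marker_sets_per_subgroup
    marker_map: dict[str, list[str]] = {sg: [] for sg in subgroups}
    sets: list[GeneSet] = []
    marker_genes_by_subgroup: dict[str, np.ndarray] = {}
    cursor = 0
    for k, sg in enumerate(subgroups):
        block_idx: list[int] = []
        for j in range(spec.marker_sets_per_subgroup):
            idx = perm[cursor: cursor + spec.genes_per_set]
            cursor += spec.genes_per_set
            set_name = f"GS{len(sets):04d}"
            sets.append(GeneSet(set_name, frozenset(genes[idx]), f"marker:{sg}"))
            marker_map[sg].append(set_name)
            block_idx.extend(idx)
        marker_genes_by_subgroup[sg] = np.array(block_idx)
    for _ in range(spec.n_gene_sets - n_marker_sets):
        idx = rng.choice(spec.n_genes, size=spec.genes_per_set, replace=False)
        sets.append(GeneSet(f"GS{len(sets):04d}", frozenset(genes[idx]), "random"))
    collection = GeneSetCollection(sets)

    baseline = rng.normal(spec.baseline_mean, spec.baseline_sd, size=spec.n_genes)
    expr = np.tile(baseline[:, None], (1, len(samples)))
    for k, sg in enumerate(subgroups):
        cols = np.arange(
            k * spec.samples_per_subgroup, (k + 1) * spec.samples_per_subgroup
        )
        expr[np.ix_(marker_genes_by_subgroup[sg], cols)] += spec.effect_size_delta
    expr += rng.normal(0.0, spec.noise_sd, size=expr.shape)
    undistorted = pd.DataFrame(expr, index=genes, columns=samples)

    # Balanced round-robin platform assignment within each subgroup.
    platform_names = [
        spec.platforms[i % len(spec.platforms)].name
        for sg in subgroups
        for i in range(spec.samples_per_subgroup)
    ]
    sample_platform = pd.Series(platform_names, index=samples, name="platform")
    by_name = {p.name: p for p in spec.platforms}
    distorted = undistorted.copy()
    for s in samples:
        distorted[s] = by_name[sample_platform[s]].apply(distorted[s].to_numpy())

    return SimulatedCohort(
        expression=distorted,
        undistorted=undistorted,
        labels=labels,
        sample_platform=sample_platform,
        gene_sets=collection,
        marker_map=marker_map,
    )


@dataclass(frozen=True)
class XenograftSpec:
    """Mixture of graft/host/ambiguous read pairs with a score gap.

    ``score_gap_mean`` is the mean alignment-score advantage of the true
    genome; drawn gaps are clipped below at 1 so a non-ambiguous pair never
    ties.
    """

    n_pairs: int = 1000
    graft_fraction: float = 0.8
    ambiguous_fraction: float = 0.05
    score_gap_mean: float = 15.0
    score_gap_sd: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pairs <= 0:
            raise ValueError("n_pairs must be > 0")
        for f in (self.graft_fraction, self.ambiguous_fraction):
            if not 0.0 <= f <= 1.0:
                raise ValueError("fractions must be in [0, 1]")
        if self.graft_fraction + self.ambiguous_fraction > 1.0:
            raise ValueError("graft_fraction + ambiguous_fraction must be <= 1")
        if self.score_gap_mean <= 0:
            raise ValueError("score_gap_mean must be > 0")


def simulate_xenograft_alignments(
    spec: XenograftSpec,
) -> tuple[list[AlignedReadPair], list[str]]:
    """Read pairs plus their true origin labels (graft/host/ambiguous)."""
    rng = np.random.default_rng(spec.seed)
    n_graft = int(round(spec.graft_fraction * spec.n_pairs))
    n_amb = int(round(spec.ambiguous_fraction * spec.n_pairs))
    n_graft = min(n_graft, spec.n_pairs)
    n_amb = min(n_amb, spec.n_pairs - n_graft)
    origins = (
        ["graft"] * n_graft
        + ["host"] * (spec.n_pairs - n_graft - n_amb)
        + ["ambiguous"] * n_amb
    )
    rng.shuffle(origins)

    pairs: list[AlignedReadPair] = []
    for i, origin in enumerate(origins):
        base = int(round(rng.normal(120.0, 10.0)))
        gap = int(np.ceil(max(1.0, rng.normal(spec.score_gap_mean, spec.score_gap_sd))))
        hi, lo = base + gap, base
        hi_mapq, lo_mapq = 60, max(0, 60 - gap)
        read_id = f"read{i:06d}"
        if origin == "graft":
            pairs.append(AlignedReadPair(read_id, float(hi), float(lo), hi_mapq, lo_mapq))
        elif origin == "host":
            pairs.append(AlignedReadPair(read_id, float(lo), float(hi), lo_mapq, hi_mapq))
        else:
            pairs.append(AlignedReadPair(read_id, float(base), float(base), 30, 30))
    return pairs, origins


@dataclass
class DESimulation:
    foreground: list[pd.DataFrame]
    background: list[pd.DataFrame]
    truth: dict[str, frozenset[str]]  # shared / exclusive_up / exclusive_down


def _planted_stats(rng: np.random.Generator, n: int, direction: int) -> pd.DataFrame:
    l2fc = direction * (1.5 + np.abs(rng.normal(0.8, 0.4, size=n)))
    padj = rng.uniform(1e-8, 0.049, size=n)
    return pd.DataFrame(
        {"log2FoldChange": l2fc, "pvalue": padj * rng.uniform(0.1, 1.0, size=n), "padj": padj}
    )


def _null_stats(rng: np.random.Generator, n: int) -> pd.DataFrame:
    # Every null gene fails at least one threshold: either |l2fc| < 1 or
    # padj >= 0.05.
    small_fc = rng.random(size=n) < 0.5
    l2fc = np.where(
        small_fc, rng.uniform(-0.9, 0.9, size=n), rng.normal(0.0, 1.2, size=n)
    )
    padj = np.where(small_fc, rng.uniform(0.0, 1.0, size=n), rng.uniform(0.05, 1.0, size=n))
    return pd.DataFrame(
        {"log2FoldChange": l2fc, "pvalue": padj * rng.uniform(0.1, 1.0, size=n), "padj": padj}
    )


def simulate_de_tables(
    n_genes: int = 2000,
    n_foreground: int = 3,
    n_background: int = 2,
    n_exclusive_up: int = 30,
    n_exclusive_down: int = 30,
    n_shared_mixed: int = 20,
    n_shared_with_background: int = 15,
    n_low_count: int = 25,
    seed: int = 0,
) -> DESimulation:
    """DE tables with planted signature structure.

    Roles are carved from disjoint gene blocks: exclusive-up/-down genes are
    significant in that direction in every foreground contrast and in no
    background contrast; shared-mixed genes are significant in every
    foreground contrast with inconsistent direction; shared-with-background
    genes are up in every foreground *and* in every background contrast (so
    they survive the shared intersection but are subtracted from the
    exclusives); low-count genes have baseCount < 10. All other genes fail
    at least one threshold everywhere.
    """
    if n_foreground < 1:
        raise ValueError("need at least one foreground contrast")
    planted = (
        n_exclusive_up + n_exclusive_down + n_shared_mixed
        + n_shared_with_background + n_low_count
    )
    if planted > n_genes:
        raise ValueError("planted roles exceed n_genes (roles must be disjoint)")

    rng = np.random.default_rng(seed)
    genes = np.array([f"g{i:05d}" for i in range(n_genes)], dtype=object)
    perm = rng.permutation(n_genes)
    cursor = 0

    def take(n: int) -> np.ndarray:
        nonlocal cursor
        idx = perm[cursor: cursor + n]
        cursor += n
        return idx

    idx_up = take(n_exclusive_up)
    idx_down = take(n_exclusive_down)
    idx_mixed = take(n_shared_mixed)
    idx_shared_bg = take(n_shared_with_background)
    idx_low = take(n_low_count)

    base_counts = rng.integers(10, 5000, size=n_genes)
    base_counts[idx_low] = rng.integers(0, 10, size=n_low_count)

    def build(contrast: int, is_background: bool) -> pd.DataFrame:
        stats = _null_stats(rng, n_genes)
        if not is_background:
            stats.iloc[idx_up] = _planted_stats(rng, n_exclusive_up, +1).to_numpy()
            stats.iloc[idx_down] = _planted_stats(rng, n_exclusive_down, -1).to_numpy()
            mixed_dir = +1 if contrast == 0 else -1
            stats.iloc[idx_mixed] = _planted_stats(rng, n_shared_mixed, mixed_dir).to_numpy()
        # shared-with-background genes are up everywhere, fg and bg alike
        stats.iloc[idx_shared_bg] = _planted_stats(
            rng, n_shared_with_background, +1
        ).to_numpy()
        table = pd.DataFrame(
            {
                "gene": genes,
                "log2FoldChange": stats["log2FoldChange"].to_numpy(),
                "pvalue": stats["pvalue"].to_numpy(),
                "padj": stats["padj"].to_numpy(),
                "baseCount": base_counts,
            }
        )
        return table

    foreground = [build(c, False) for c in range(n_foreground)]
    background = [build(c, True) for c in range(n_background)]

    shared = frozenset(genes[np.concatenate([idx_up, idx_down, idx_mixed, idx_shared_bg])])
    excl_up = set(genes[idx_up])
    if n_background == 0:
        # nothing subtracts the everywhere-up confounders
        excl_up |= set(genes[idx_shared_bg])
    if n_foreground == 1:
        # a single contrast makes the "mixed" genes directionally consistent (up)
        excl_up |= set(genes[idx_mixed])
    truth = {
        "shared": shared,
        "exclusive_up": frozenset(excl_up),
        "exclusive_down": frozenset(genes[idx_down]),
    }
    return DESimulation(foreground=foreground, background=background, truth=truth)


def simulate_genome(
    n_chroms: int = 2,
    chrom_length: int = 5_000_000,
    n_genes: int = 60,
    seed: int = 0,
    min_gene_length: int = 12_000,
    max_gene_length: int = 30_000,
    margin: int = 12_000,
) -> tuple[list[GeneModel], dict[str, int]]:
    """Non-overlapping gene models on synthetic chromosomes.

    Genes are distributed round-robin across chromosomes and placed with at
    least ``margin`` bases between neighbours (and from chromosome ends), so
    promoter and downstream windows of adjacent genes cannot collide.
    Raises on infeasible packing. Strands alternate; each gene gets three
    exons (two introns) sized so intronic space well clear of the promoter
    window exists.
    """
    if n_chroms <= 0 or chrom_length <= 0 or n_genes < 0:
        raise ValueError("n_chroms, chrom_length must be > 0 and n_genes >= 0")
    rng = np.random.default_rng(seed)
    chrom_sizes = {f"chr{i + 1}": chrom_length for i in range(n_chroms)}
    per_chrom: dict[str, int] = {c: 0 for c in chrom_sizes}
    for i in range(n_genes):
        per_chrom[f"chr{i % n_chroms + 1}"] += 1

    genes: list[GeneModel] = []
    gene_no = 0
    for chrom, count in per_chrom.items():
        if count == 0:
            continue
        lengths = rng.integers(min_gene_length, max_gene_length + 1, size=count)
        slack = chrom_length - int(lengths.sum()) - margin * (count + 1)
        if slack < 0:
            raise ValueError(
                f"infeasible packing: {count} genes do not fit on {chrom} "
                f"with margin {margin}"
            )
        # Distribute the slack over the count+1 gaps.
        cuts = np.sort(rng.integers(0, slack + 1, size=count))
        extra = np.diff(np.concatenate(([0], cuts)))
        pos = margin + int(extra[0]) if count else 0
        for j in range(count):
            start = pos
            end = start + int(lengths[j])
            strand = "+" if gene_no % 2 == 0 else "-"
            length = end - start
            # three exons: both ends plus a middle sliver; introns flank it
            e1 = (start, start + 400)
            mid = start + length // 2
            e2 = (mid, mid + 400)
            e3 = (end - 400, end)
            genes.append(
                GeneModel(f"gene{gene_no:04d}", chrom, start, end, strand, (e1, e2, e3))
            )
            gene_no += 1
            pos = end + margin + (int(extra[j + 1]) if j + 1 < count else 0)
    return genes, chrom_sizes


def plant_peaks(
    genes: Sequence[GeneModel],
    chrom_sizes: dict[str, int],
    category: str,
    n_peaks: int,
    width: int = 200,
    params: AnnotationParams = AnnotationParams(),
    seed: int = 0,
    max_tries: int = 20_000,
) -> list[GenomicInterval]:
    """Peaks guaranteed to annotate as ``category`` (round-trip verified).

    Candidate positions are proposed near the relevant gene feature (or
    uniformly for "distal intergenic") and accepted only when
    ``annotate_peak`` returns the requested category; raises when placement
    keeps failing.
    """
    if category not in ("promoter", "exon", "intron", "downstream", "distal intergenic"):
        raise ValueError(f"unknown category {category!r}")
    if category != "distal intergenic" and not genes:
        raise ValueError(f"cannot plant {category!r} peaks without genes")
    rng = np.random.default_rng(seed)
    chroms = sorted(chrom_sizes)
    peaks: list[GenomicInterval] = []
    tries = 0
    while len(peaks) < n_peaks:
        tries += 1
        if tries > max_tries:
            raise RuntimeError(f"could not place {n_peaks} {category!r} peaks")
        if category == "distal intergenic":
            chrom = chroms[rng.integers(len(chroms))]
            start = int(rng.integers(0, chrom_sizes[chrom] - width))
        else:
            g = genes[rng.integers(len(genes))]
            chrom = g.chrom
            if category == "promoter":
                center = g.tss + int(rng.integers(-params.promoter_upstream // 2,
                                                  params.promoter_downstream // 2))
            elif category == "exon":
                s, e = g.exons[rng.integers(len(g.exons))]
                center = int(rng.integers(s, e))
            elif category == "intron":
                center = int(rng.integers(g.start, g.end))
            else:  # downstream
                if g.strand == "+":
                    center = g.end + int(rng.integers(1, max(params.downstream_window, 2)))
                else:
                    center = g.start - int(rng.integers(1, max(params.downstream_window, 2)))
            start = max(0, center - width // 2)
        if start + width > chrom_sizes[chrom]:
            continue
        peak = GenomicInterval(chrom, start, start + width, f"{category}_{len(peaks)}")
        if annotate_peak(peak, genes, params) == category:
            peaks.append(peak)
    return peaks


def write_ortholog_map(
    genes: Sequence[str], path: str | Path, ortholog_fraction: float = 0.9, seed: int = 0
) -> dict[str, bool]:
    """Write a synthetic human->mouse ortholog flag table for given genes."""
    rng = np.random.default_rng(seed)
    flags = rng.random(len(genes)) < ortholog_fraction
    mapping = {g: bool(f) for g, f in zip(genes, flags)}
    with open(path, "w") as fh:
        fh.write("#human_symbol\thas_mouse_ortholog\n")
        for g, f in mapping.items():
            fh.write(f"{g}\t{1 if f else 0}\n")
    return mapping


def write_pairs_tsv(
    pairs: Sequence[AlignedReadPair], path: str | Path
) -> None:
    """Write pairs as the SAM-derived tabular input the disambiguator reads."""
    with open(path, "w") as fh:
        fh.write("#read_id\tgenome\tflag\tmapq\tAS\n")
        for p in pairs:
            if p.human_score is not None or p.human_mapq is not None:
                fh.write(
                    f"{p.read_id}\thuman\t0\t{p.human_mapq if p.human_mapq is not None else ''}"
                    f"\t{p.human_score if p.human_score is not None else ''}\n"
                )
            if p.mouse_score is not None or p.mouse_mapq is not None:
                fh.write(
                    f"{p.read_id}\tmouse\t0\t{p.mouse_mapq if p.mouse_mapq is not None else ''}"
                    f"\t{p.mouse_score if p.mouse_score is not None else ''}\n"
                )
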