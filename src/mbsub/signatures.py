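"""Differential-expression thresholds, signature set algebra, overlap test.

The pipeline consumes DE result tables (gene, log2 fold change, p, BH-
adjusted p, optional total count) produced upstream, removes genes with
fewer than ``min_total_count`` (10) total counts, and calls a gene
significant when adjusted p < 0.05 and |log2FC| > 1 — both strict, so a
gene sitting exactly on a boundary is not significant.

Signatures are derived by set algebra over several contrasts: the *shared*
signature is the genes differential (either direction) in every foreground
contrast; the *exclusive* up/down signatures are the genes consistently
up (down) in every foreground contrast and differential in no background
contrast. This isolates what the co-driven tumors do that the single-driver
tumors do not. Exclusive signatures are then intersected with peak-derived
bound-gene lists under an upper-tail hypergeometric test.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from scipy.stats import hypergeom

__all__ = [
    "SignatureThresholds",
    "SignatureSets",
    "read_de_table",
    "write_de_table",
    "filter_low_count",
    "threshold_de",
    "shared_and_exclusive",
    "overlap_test",
]

REQUIRED_COLUMNS = ("gene", "log2FoldChange", "pvalue", "padj")


@dataclass(frozen=True)
class SignatureThresholds:
    max_padj: float = 0.05
    min_abs_l2fc: float = 1.0
    min_total_count: int = 10

    def __post_init__(self) -> None:
        if not 0.0 < self.max_padj <= 1.0:
            raise ValueError("max_padj must be in (0, 1]")
        if self.min_abs_l2fc < 0:
            raise ValueError("min_abs_l2fc must be >= 0")


@dataclass
class SignatureSets:
    """Per-contrast up/down calls plus the derived shared/exclusive sets."""

    foreground: list[tuple[frozenset[str], frozenset[str]]]
    background: list[tuple[frozenset[str], frozenset[str]]]
    shared: frozenset[str]
    exclusive_up: frozenset[str]
    exclusive_down: frozenset[str]

    def summary(self) -> dict[str, int]:
        return {
            "n_shared": len(self.shared),
            "n_exclusive_up": len(self.exclusive_up),
            "n_exclusive_down": len(self.exclusive_down),
        }


def _validate(table: pd.DataFrame) -> None:
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"DE table missing columns: {missing}")
    if table["gene"].duplicated().any():
        dupes = table.loc[table["gene"].duplicated(), "gene"].unique()[:5]
        raise ValueError(f"DE table has duplicate genes, e.g. {list(dupes)}")
    for col in ("pvalue", "padj"):
        vals = table[col].dropna()
        if ((vals < 0) | (vals > 1)).any():
            raise ValueError(f"{col} outside [0, 1]")


def read_de_table(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t")
    _validate(table)
    return table


def write_de_table(table: pd.DataFrame, path: str | Path) -> None:
    _validate(table)
    table.to_csv(path, sep="\t", index=False)


def filter_low_count(table: pd.DataFrame, min_total_count: int = 10) -> pd.DataFrame:
    """Drop genes whose total count across sample groups is below the floor.

    Keeps genes with ``baseCount >= min_total_count`` ("fewer than N" are
    excluded, so exactly N survives). Requires a ``baseCount`` column.
    """
    _validate(table)
    if "baseCount" not in table.columns:
        raise ValueError("filter_low_count requires a 'baseCount' column")
    return table[table["baseCount"] >= min_total_count].reset_index(drop=True)


def threshold_de(
    table: pd.DataFrame, thresholds: SignatureThresholds = SignatureThresholds()
) -> tuple[frozenset[str], frozenset[str]]:
    """(up, down) gene sets under strict padj and |log2FC| thresholds."""
    _validate(table)
    sig = table["padj"] < thresholds.max_padj
    up = table.loc[sig & (table["log2FoldChange"] > thresholds.min_abs_l2fc), "gene"]
    down = table.loc[sig & (table["log2FoldChange"] < -thresholds.min_abs_l2fc), "gene"]
    return frozenset(up), frozenset(down)


def shared_and_exclusive(
    foreground: Sequence[tuple[Iterable[str], Iterable[str]]],
    background: Sequence[tuple[Iterable[str], Iterable[str]]] = (),
    direction_consistent_shared: bool = False,
) -> SignatureSets:
    """Derive shared and exclusive signatures from per-contrast (up, down).

    shared = intersection over foreground contrasts of (up | down) —
    direction-agnostic by default; ``direction_consistent_shared`` instead
    takes (intersection of ups) | (intersection of downs).
    exclusive_up = (intersection of foreground ups) minus every gene
    differential in any background contrast; exclusive_down analogous.
    """
    if not foreground:
        raise ValueError("need at least one foreground contrast")
    fg = [(frozenset(u), frozenset(d)) for u, d in foreground]
    bg = [(frozenset(u), frozenset(d)) for u, d in background]

    inter_up = frozenset.intersection(*(u for u, _ in fg))
    inter_down = frozenset.intersection(*(d for _, d in fg))
    if direction_consistent_shared:
        shared = inter_up | inter_down
    else:
        any_dir = [u | d for u, d in fg]
        shared = frozenset.intersection(*any_dir)

    bg_all = frozenset().union(*(u | d for u, d in bg)) if bg else frozenset()
    return SignatureSets(
        foreground=fg,
        background=bg,
        shared=shared,
        exclusive_up=inter_up - bg_all,
        exclusive_down=inter_down - bg_all,
    )


def overlap_test(
    signature: Iterable[str],
    bound_genes: Iterable[str],
    universe: Iterable[str],
) -> tuple[frozenset[str], float]:
    """Intersection of two gene sets plus its hypergeometric tail probability.

    p = P(X >= |overlap|) drawing |signature| genes without replacement from
    a universe containing |bound_genes| successes. Both sets must be subsets
    of the universe. An empty signature gives p = 1.
    """
    sig = frozenset(signature)
    bound = frozenset(bound_genes)
    uni = frozenset(universe)
    stray = (sig | bound) - uni
    if stray:
        raise ValueError(f"genes outside the universe, e.g. {sorted(stray)[:5]}")
    overlap = sig & bound
    k = len(overlap)
    if k == 0:
        return overlap, 1.0
    p = float(hypergeom.sf(k - 1, len(uni), len(bound), len(sig)))
    return overlap, min(p, 1.0)


def write_signature_sets(sets: SignatureSets, outdir: str | Path) -> None:
    """One-gene-per-line text files plus a JSON count summary."""
    import json

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for name, genes in (
        ("shared", sets.shared),
        ("exclusive_up", sets.exclusive_up),
        ("exclusive_down", sets.exclusive_down),
    ):
        (outdir / f"{name}_genes.txt").write_text(
            "".join(g + "\n" for g in sorted(genes))
        )
    (outdir / "signature_summary.json").write_text(json.dumps(sets.summary(), indent=2))
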