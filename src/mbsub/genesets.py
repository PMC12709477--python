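"""Gene-set collections (GMT), ortholog maps and the ortholog/size filter.

Feature selection for the subgroup classifier starts from a large gene-set
collection (MSigDB-style) restricted to sets that translate across species:
a set is kept when at least ``min_ortholog_fraction`` of its members have a
mouse ortholog and its size lies within ``[min_size, max_size]`` (defaults
0.80 / 15 / 400, all boundaries inclusive).

Gene symbols are compared case-sensitively after whitespace stripping.
Set size is measured on the full GMT membership; pass a gene universe via
``filter_genesets(..., restrict_to=...)`` to measure it after intersecting
with an expression matrix instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

__all__ = [
    "GeneSet",
    "GeneSetCollection",
    "GeneSetFilterParams",
    "read_gmt",
    "write_gmt",
    "read_ortholog_map",
    "ortholog_fraction",
    "filter_genesets",
]

_FALSY = {"", "0", "false", "no", "na", "n", "-", "none"}


@dataclass(frozen=True)
class GeneSet:
    """A named set of gene symbols with an optional free-text description."""

    name: str
    genes: frozenset[str]
    description: str = ""

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("gene set name must be non-empty")
        if not self.genes:
            raise ValueError(f"gene set {self.name!r} has no genes")

    def __len__(self) -> int:
        return len(self.genes)


@dataclass
class GeneSetCollection:
    """Ordered collection of uniquely named gene sets."""

    sets: list[GeneSet] = field(default_factory=list)

    def __post_init__(self) -> None:
        names = [s.name for s in self.sets]
        if len(names) != len(set(names)):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ValueError(f"duplicate gene set names: {dupes}")
        self._by_name = {s.name: s for s in self.sets}

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self) -> Iterator[GeneSet]:
        return iter(self.sets)

    def __getitem__(self, name: str) -> GeneSet:
        return self._by_name[name]

    def __contains__(self, name: str) -> bool:
        return name in self._by_name

    @property
    def names(self) -> list[str]:
        return [s.name for s in self.sets]


@dataclass(frozen=True)
class GeneSetFilterParams:
    """Thresholds for the ortholog-fraction and size filter (all inclusive)."""

    min_ortholog_fraction: float = 0.80
    min_size: int = 15
    max_size: int = 400

    def __post_init__(self) -> None:
        if not 0.0 <= self.min_ortholog_fraction <= 1.0:
            raise ValueError("min_ortholog_fraction must be in [0, 1]")
        if not 0 < self.min_size <= self.max_size:
            raise ValueError("require 0 < min_size <= max_size")


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT file (name, description, genes... per tab-separated line).

    Duplicate genes within a line are deduplicated; a duplicate set name or a
    line with fewer than three fields raises ``ValueError`` naming the line.
    """
    sets: list[GeneSet] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}: line {lineno}: GMT line needs >=3 tab-separated "
                    f"fields, got {len(fields)}"
                )
            name, description, *genes = fields
            members = frozenset(g.strip() for g in genes if g.strip())
            if not members:
                raise ValueError(f"{path}: line {lineno}: set {name!r} has no genes")
            sets.append(GeneSet(name=name.strip(), genes=members, description=description))
    return GeneSetCollection(sets)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for s in collection:
            genes = "\t".join(sorted(s.genes))
            fh.write(f"{s.name}\t{s.description}\t{genes}\n")


def read_ortholog_map(path: str | Path) -> dict[str, bool]:
    """Read a two-column TSV mapping human symbol -> ortholog flag.

    The second column may be a boolean-ish flag (1/0, true/false, yes/no) or a
    mouse symbol; any non-empty, non-falsy value counts as "has ortholog".
    A header line starting with '#' is skipped. Duplicate keys are an error.
    """
    mapping: dict[str, bool] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ValueError(f"{path}: line {lineno}: need 2 tab-separated columns")
            human = fields[0].strip()
            if human in mapping:
                raise ValueError(f"{path}: line {lineno}: duplicate symbol {human!r}")
            mapping[human] = fields[1].strip().lower() not in _FALSY
    return mapping


def ortholog_fraction(gene_set: GeneSet, orthologs: Mapping[str, bool]) -> float:
    """Fraction of member genes with a mouse ortholog.

    Genes absent from the map count as non-orthologous.
    """
    if not gene_set.genes:
        raise ValueError("gene set is empty")
    n_orth = sum(1 for g in gene_set.genes if orthologs.get(g, False))
    return n_orth / len(gene_set.genes)


def filter_genesets(
    collection: GeneSetCollection,
    orthologs: Mapping[str, bool],
    params: GeneSetFilterParams = GeneSetFilterParams(),
    restrict_to: Iterable[str] | None = None,
) -> GeneSetCollection:
    """Keep sets passing the ortholog-fraction and size thresholds (inclusive).

    ``restrict_to``: optionally intersect each set with a gene universe (e.g.
    the expression matrix index) before measuring size and ortholog fraction.
    Order of surviving sets is preserved.
    """
    universe = None if restrict_to is None else frozenset(restrict_to)
    survivors: list[GeneSet] = []
    for s in collection:
        genes = s.genes if universe is None else s.genes & universe
        if not genes:
            continue
        candidate = GeneSet(s.name, frozenset(genes), s.description)
        size_ok = params.min_size <= len(candidate) <= params.max_size
        frac_ok = ortholog_fraction(candidate, orthologs) >= params.min_ortholog_fraction
        if size_ok and frac_ok:
            survivors.append(s)
    return GeneSetCollection(survivors)
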