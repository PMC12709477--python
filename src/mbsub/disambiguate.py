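"""Graft/host assignment of xenograft read pairs aligned to two genomes.

Xenograft sequencing mixes human tumor (graft) and mouse brain (host)
fragments. Each read pair is aligned to both references and assigned to the
genome with the better evidence: graft when the combined human score beats
the mouse score, host for the reverse, ambiguous on a tie. A genome with no
alignment at all scores -infinity.

Comparison key: summed alignment scores (AS tags) when both genomes carry
them, falling back to summed mapping quality otherwise; ``key="mapq"``
forces the MAPQ comparison. An unaligned mate contributes 0 to its genome's
pair sum. Comparison is per pair, not per mate.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Iterable, Literal

__all__ = [
    "AlignedReadPair",
    "DisambiguationSummary",
    "assign_read_pair",
    "disambiguate_pairs",
    "read_pairs_tsv",
    "read_pairs_sam",
    "write_assignments",
]

Assignment = Literal["graft", "host", "ambiguous"]


@dataclass(frozen=True)
class AlignedReadPair:
    """Pair-level alignment evidence against the human and mouse genomes.

    ``None`` means "no alignment to that genome"; scores are pair sums.
    """

    read_id: str
    human_score: float | None = None
    mouse_score: float | None = None
    human_mapq: int | None = None
    mouse_mapq: int | None = None

    def __post_init__(self) -> None:
        has_human = self.human_score is not None or self.human_mapq is not None
        has_mouse = self.mouse_score is not None or self.mouse_mapq is not None
        if not (has_human or has_mouse):
            raise ValueError(f"read {self.read_id!r}: no alignment to either genome")
        for mapq in (self.human_mapq, self.mouse_mapq):
            if mapq is not None and not 0 <= mapq <= 255:
                raise ValueError(f"read {self.read_id!r}: MAPQ {mapq} outside 0-255")

    def swapped(self) -> "AlignedReadPair":
        """The same evidence with human and mouse genomes exchanged."""
        return AlignedReadPair(
            read_id=self.read_id,
            human_score=self.mouse_score,
            mouse_score=self.human_score,
            human_mapq=self.mouse_mapq,
            mouse_mapq=self.human_mapq,
        )


@dataclass(frozen=True)
class DisambiguationSummary:
    n_graft: int
    n_host: int
    n_ambiguous: int

    @property
    def total(self) -> int:
        return self.n_graft + self.n_host + self.n_ambiguous


def _comparison_key(pair: AlignedReadPair, key: str) -> tuple[float, float]:
    neg_inf = float("-inf")
    has_human = pair.human_score is not None or pair.human_mapq is not None
    has_mouse = pair.mouse_score is not None or pair.mouse_mapq is not None

    def pick(score: float | None, mapq: int | None, use_scores: bool) -> float:
        if use_scores and score is not None:
            return float(score)
        if mapq is not None:
            return float(mapq)
        if score is not None:  # aligned but only a score available
            return float(score)
        return neg_inf

    if key == "mapq":
        use_scores = False
    else:  # score_then_mapq: AS when every aligned genome carries one
        use_scores = (not has_human or pair.human_score is not None) and (
            not has_mouse or pair.mouse_score is not None
        )
    return (
        pick(pair.human_score, pair.human_mapq, use_scores),
        pick(pair.mouse_score, pair.mouse_mapq, use_scores),
    )


def assign_read_pair(
    pair: AlignedReadPair, key: str = "score_then_mapq"
) -> Assignment:
    """graft / host / ambiguous by comparing the pair's two genome scores."""
    human, mouse = _comparison_key(pair, key)
    if human > mouse:
        return "graft"
    if mouse > human:
        return "host"
    return "ambiguous"


def disambiguate_pairs(
    pairs: Iterable[AlignedReadPair], key: str = "score_then_mapq"
) -> tuple[
    list[AlignedReadPair],
    list[AlignedReadPair],
    list[AlignedReadPair],
    DisambiguationSummary,
]:
    """Partition pairs into graft/host/ambiguous lists plus counts.

    Read ids must be unique; a duplicate is an error.
    """
    seen: set[str] = set()
    graft: list[AlignedReadPair] = []
    host: list[AlignedReadPair] = []
    ambiguous: list[AlignedReadPair] = []
    buckets = {"graft": graft, "host": host, "ambiguous": ambiguous}
    for pair in pairs:
        if pair.read_id in seen:
            raise ValueError(f"duplicate read id {pair.read_id!r}")
        seen.add(pair.read_id)
        buckets[assign_read_pair(pair, key)].append(pair)
    summary = DisambiguationSummary(len(graft), len(host), len(ambiguous))
    return graft, host, ambiguous, summary


def read_pairs_tsv(path: str | Path) -> list[AlignedReadPair]:
    """Read SAM-derived tabular records: read_id, genome, flag, mapq, AS.

    One row per aligned mate; rows are aggregated per (read_id, genome) by
    summing AS and MAPQ over mates. ``genome`` must be ``human`` or
    ``mouse``; AS may be empty/NA. Lines starting with '#' are skipped.
    """
    acc: dict[str, dict[str, dict[str, float | None]]] = {}
    order: list[str] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 5:
                raise ValueError(f"{path}: line {lineno}: need 5 columns")
            read_id, genome, _flag, mapq_s, as_s = fields[:5]
            genome = genome.strip().lower()
            if genome not in ("human", "mouse"):
                raise ValueError(f"{path}: line {lineno}: genome must be human/mouse")
            if read_id not in acc:
                acc[read_id] = {}
                order.append(read_id)
            slot = acc[read_id].setdefault(genome, {"score": None, "mapq": None})
            if mapq_s.strip():
                slot["mapq"] = (slot["mapq"] or 0) + int(mapq_s)
            if as_s.strip() and as_s.strip().upper() not in ("NA", "."):
                slot["score"] = (slot["score"] or 0.0) + float(as_s)
    pairs = []
    for read_id in order:
        h = acc[read_id].get("human", {"score": None, "mapq": None})
        m = acc[read_id].get("mouse", {"score": None, "mapq": None})
        pairs.append(
            AlignedReadPair(
                read_id=read_id,
                human_score=h["score"],
                mouse_score=m["score"],
                human_mapq=None if h["mapq"] is None else int(h["mapq"]),
                mouse_mapq=None if m["mapq"] is None else int(m["mapq"]),
            )
        )
    return pairs


def _collect_sam(path: str | Path) -> dict[str, dict[str, float | None]]:
    import pysam

    per_read: dict[str, dict[str, float | None]] = {}
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as fh:
        for rec in fh:
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                continue
            slot = per_read.setdefault(rec.query_name, {"score": None, "mapq": None})
            slot["mapq"] = (slot["mapq"] or 0) + rec.mapping_quality
            if rec.has_tag("AS"):
                slot["score"] = (slot["score"] or 0.0) + float(rec.get_tag("AS"))
    return per_read


def read_pairs_sam(human_sam: str | Path, mouse_sam: str | Path) -> list[AlignedReadPair]:
    """Build pairs from two name-matched SAM text files (one per genome)."""
    human = _collect_sam(human_sam)
    mouse = _collect_sam(mouse_sam)
    pairs = []
    for read_id in sorted(set(human) | set(mouse)):
        h = human.get(read_id, {"score": None, "mapq": None})
        m = mouse.get(read_id, {"score": None, "mapq": None})
        pairs.append(
            AlignedReadPair(
                read_id=read_id,
                human_score=h["score"],
                mouse_score=m["score"],
                human_mapq=None if h["mapq"] is None else int(h["mapq"]),
                mouse_mapq=None if m["mapq"] is None else int(m["mapq"]),
            )
        )
    return pairs


def write_assignments(
    graft: list[AlignedReadPair],
    host: list[AlignedReadPair],
    ambiguous: list[AlignedReadPair],
    summary: DisambiguationSummary,
    outdir: str | Path,
) -> None:
    """Write three read-id lists plus a JSON count summary."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for name, bucket in (("graft", graft), ("host", host), ("ambiguous", ambiguous)):
        (outdir / f"{name}_reads.txt").write_text(
            "".join(p.read_id + "\n" for p in bucket)
        )
    (outdir / "summary.json").write_text(json.dumps(asdict(summary), indent=2))
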