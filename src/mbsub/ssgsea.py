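"""Single-sample gene-set enrichment (ssGSEA) scoring.

For one sample, genes are ranked by decreasing expression (ties broken by
gene name for determinism). With ``N`` genes and set ``S``, position
``i`` (1-based) carries rank weight ``v_i = (N - i + 1) ** alpha`` when the
gene is in ``S``. The score is the integral (sum over all positions ``k``)
of the difference between the weighted in-set ECDF and the unweighted
out-of-set ECDF::

    score = sum_k [ P_in(k) - P_out(k) ]
    P_in(k)  = sum_{i<=k, i in S} v_i / sum_{i in S} v_i
    P_out(k) = |{ i<=k, i not in S }| / (N - |S|)

This sum-of-differences form is the single-sample variant's defining choice
(as opposed to the maximum-deviation statistic of two-group GSEA). Because
the statistic depends on expression only through within-sample ranks, any
strictly increasing per-sample transformation — e.g. a platform-specific
monotone distortion — leaves unnormalized scores unchanged; that robustness
is why gene-set scores, not genes, feed the cross-platform classifier.

``alpha`` defaults to 0.25 and, when ``normalize`` is on, all scores are
divided by the global (max - min) of the unnormalized matrix. Neither
convention is universal, so both are recorded alongside every profile.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .genesets import GeneSet, GeneSetCollection

__all__ = [
    "SsgseaParams",
    "EnrichmentProfile",
    "enrichment_score",
    "ssgsea_matrix",
    "read_expression",
    "write_expression",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SsgseaParams:
    alpha: float = 0.25
    normalize: bool = True

    def __post_init__(self) -> None:
        if self.alpha < 0:
            raise ValueError("alpha must be >= 0")


@dataclass
class EnrichmentProfile:
    """Samples x gene-sets score matrix plus the parameters that produced it."""

    scores: pd.DataFrame  # rows = samples, columns = gene sets
    params: SsgseaParams
    dropped_sets: list[str]

    def __post_init__(self) -> None:
        if self.scores.isna().any().any():
            raise ValueError("enrichment profile contains missing values")
        if self.scores.columns.duplicated().any():
            raise ValueError("duplicate gene-set columns in profile")

    @property
    def set_names(self) -> list[str]:
        return list(self.scores.columns)

    def write(self, path: str | Path) -> None:
        """Write scores as TSV with a JSON sidecar recording the parameters."""
        path = Path(path)
        self.scores.to_csv(path, sep="\t", index_label="sample")
        sidecar = {"params": asdict(self.params), "dropped_sets": self.dropped_sets}
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=2))


def _rank_order(values: np.ndarray, names: np.ndarray) -> np.ndarray:
    # Decreasing value, ties broken by gene name (lexsort: last key primary).
    return np.lexsort((names, -values))


def enrichment_score(
    sample_values: Mapping[str, float] | pd.Series,
    gene_set: GeneSet | frozenset[str] | set[str],
    alpha: float = 0.25,
) -> float:
    """ssGSEA score of one gene set in one sample (unnormalized).

    Raises ``ValueError`` when the set does not intersect the gene universe,
    when it covers the whole universe, or when fewer than two genes are given.
    """
    series = pd.Series(sample_values, dtype=float)
    if len(series) < 2:
        raise ValueError("need at least 2 genes to rank")
    members = gene_set.genes if isinstance(gene_set, GeneSet) else frozenset(gene_set)
    names = series.index.to_numpy(dtype=object)
    in_set = np.isin(names, list(members))
    n_in = int(in_set.sum())
    if n_in == 0:
        raise ValueError("gene set does not intersect the gene universe")
    if n_in == len(series):
        raise ValueError("gene set equals the gene universe; score undefined")

    order = _rank_order(series.to_numpy(), names.astype(str))
    in_ordered = in_set[order]
    n = len(series)
    weights = (n - np.arange(n)).astype(float) ** alpha  # position i -> (N-i+1)^alpha
    p_in = np.cumsum(np.where(in_ordered, weights, 0.0))
    p_in /= p_in[-1]
    p_out = np.cumsum(~in_ordered) / (n - n_in)
    return float(np.sum(p_in - p_out))


def ssgsea_matrix(
    expression: pd.DataFrame,
    collection: GeneSetCollection,
    params: SsgseaParams = SsgseaParams(),
) -> EnrichmentProfile:
    """Score every gene set in every sample of a genes x samples matrix.

    Sets with no gene in the matrix index are dropped with a warning; an
    empty surviving collection is an error. With ``params.normalize`` the
    whole matrix is divided by its global (max - min) before being returned.
    """
    if expression.isna().any().any():
        raise ValueError("expression matrix contains missing values")
    genes = expression.index.to_numpy(dtype=object)
    gene_pos = {g: i for i, g in enumerate(genes)}
    n = len(genes)
    if n < 2:
        raise ValueError("need at least 2 genes")

    kept: list[GeneSet] = []
    dropped: list[str] = []
    for s in collection:
        n_in = sum(1 for g in s.genes if g in gene_pos)
        if n_in == 0 or n_in == n:
            dropped.append(s.name)
        else:
            kept.append(s)
    if dropped:
        msg = f"dropping {len(dropped)} gene set(s) with empty or full intersection"
        logger.warning("%s: %s", msg, dropped[:10])
        warnings.warn(msg, stacklevel=2)
    if not kept:
        raise ValueError("no gene set intersects the expression matrix")

    membership = np.zeros((len(kept), n), dtype=bool)  # sets x genes
    for row, s in enumerate(kept):
        idx = [gene_pos[g] for g in s.genes if g in gene_pos]
        membership[row, idx] = True
    set_sizes = membership.sum(axis=1)

    name_keys = genes.astype(str)
    weights = (n - np.arange(n)).astype(float) ** params.alpha
    values = expression.to_numpy(dtype=float)
    scores = np.empty((expression.shape[1], len(kept)))
    for j in range(expression.shape[1]):
        order = _rank_order(values[:, j], name_keys)
        in_ordered = membership[:, order]  # sets x positions
        win = np.where(in_ordered, weights[None, :], 0.0)
        p_in = np.cumsum(win, axis=1)
        p_in /= p_in[:, -1:]
        p_out = np.cumsum(~in_ordered, axis=1) / (n - set_sizes)[:, None]
        scores[j] = np.sum(p_in - p_out, axis=1)

    if params.normalize:
        span = scores.max() - scores.min()
        if span > 0:
            scores = scores / span

    frame = pd.DataFrame(
        scores, index=expression.columns, columns=[s.name for s in kept]
    )
    return EnrichmentProfile(scores=frame, params=params, dropped_sets=dropped)


def read_expression(path: str | Path) -> pd.DataFrame:
    """Read a genes x samples TSV (first column = gene id, header = samples)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.duplicated().any():
        raise ValueError(f"{path}: duplicate gene ids")
    return df


def write_expression(expression: pd.DataFrame, path: str | Path) -> None:
    expression.to_csv(path, sep="\t", index_label="gene")
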