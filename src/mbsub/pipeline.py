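"""Config-driven orchestration of the analysis stages.

A single YAML/JSON config holds the input paths and parameter blocks for
every stage; every run writes a ``manifest.json`` that materializes all
parameters actually applied (including paper-silent defaults), the seed and
the package version, so a run is reproducible from its manifest alone.

Error model: ``ConfigError`` for invalid/missing configuration (CLI exit
code 2), ``DataError`` for malformed inputs discovered during compute
(exit 3). Stage failures are re-raised with the stage name attached.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict
from pathlib import Path
from typing import Any, Mapping

import pandas as pd
import yaml

from . import __version__
from .classifier import TrainConfig, predict_proba, save_model, train_model
from .disambiguate import disambiguate_pairs, read_pairs_tsv, write_assignments
from .genesets import GeneSetFilterParams, filter_genesets, read_gmt, read_ortholog_map
from .peaks import (
    AnnotationParams,
    enrichment_table,
    genomic_distribution,
    merge_union,
    read_bed,
    read_chrom_sizes,
    read_gene_models,
    region_enrichment,
    write_bed,
)
from .signatures import (
    SignatureThresholds,
    filter_low_count,
    overlap_test,
    read_de_table,
    shared_and_exclusive,
    threshold_de,
    write_signature_sets,
)
from .ssgsea import SsgseaParams, read_expression, ssgsea_matrix, write_expression
from .synthetic import (
    CohortSpec,
    XenograftSpec,
    simulate_cohort,
    simulate_de_tables,
    simulate_genome,
    simulate_xenograft_alignments,
    plant_peaks,
    write_ortholog_map,
    write_pairs_tsv,
)
from .genesets import write_gmt
from .peaks import write_gene_models

logger = logging.getLogger(__name__)

__all__ = [
    "ConfigError",
    "DataError",
    "load_config",
    "run_simulate",
    "run_disambiguate",
    "run_classify",
    "run_integrate",
]


class ConfigError(Exception):
    """Invalid or incomplete pipeline configuration."""


class DataError(Exception):
    """Well-formed configuration but malformed or inconsistent data."""


def load_config(path: str | Path) -> dict[str, Any]:
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    try:
        cfg = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise ConfigError(f"cannot parse config {path}: {exc}") from exc
    if not isinstance(cfg, dict):
        raise ConfigError(f"config {path} must be a mapping")
    cfg.setdefault("_config_dir", str(path.parent))
    return cfg


def _resolve(cfg: Mapping[str, Any], key_path: str, value: str) -> Path:
    p = Path(value)
    if not p.is_absolute():
        p = Path(cfg.get("_config_dir", ".")) / p
    if not p.exists():
        raise ConfigError(f"{key_path}: file not found: {p}")
    return p


def _require(section: Mapping[str, Any] | None, stage: str, *keys: str) -> None:
    if section is None:
        raise ConfigError(f"config has no '{stage}' section")
    missing = [k for k in keys if k not in section]
    if missing:
        raise ConfigError(f"{stage}: missing keys {missing}")


def _write_manifest(outdir: Path, stage: str, payload: dict[str, Any]) -> None:
    payload = {"stage": stage, "mbsub_version": __version__, **payload}
    (outdir / "manifest.json").write_text(json.dumps(payload, indent=2, default=str))


def _seed(config: Mapping[str, Any], override: int | None) -> int:
    if override is not None:
        return int(override)
    return int(config.get("seed", 0))


def run_simulate(
    config: Mapping[str, Any], outdir: str | Path, seed: int | None = None
) -> dict[str, Path]:
    """Generate a complete synthetic input bundle for the other stages."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    s = _seed(config, seed)
    section = dict(config.get("simulate") or {})

    cohort_kwargs = dict(section.get("cohort") or {})
    cohort = simulate_cohort(CohortSpec(seed=s, **cohort_kwargs))
    xeno_kwargs = dict(section.get("xenograft") or {})
    pairs, origins = simulate_xenograft_alignments(XenograftSpec(seed=s + 1, **xeno_kwargs))
    de_kwargs = dict(section.get("de") or {})
    de = simulate_de_tables(seed=s + 2, **de_kwargs)
    genome_kwargs = dict(section.get("genome") or {})
    genes, chrom_sizes = simulate_genome(seed=s + 3, **genome_kwargs)

    paths: dict[str, Path] = {}

    def out(name: str) -> Path:
        paths[name] = outdir / name
        return paths[name]

    write_expression(cohort.expression, out("expression.tsv"))
    cohort.labels.to_frame().to_csv(out("labels.tsv"), sep="\t", index_label="sample")
    write_gmt(cohort.gene_sets, out("gene_sets.gmt"))
    write_ortholog_map(
        list(cohort.expression.index), out("ortholog_map.tsv"), seed=s + 4
    )
    (out("marker_map.json")).write_text(json.dumps(cohort.marker_map, indent=2))
    write_pairs_tsv(pairs, out("xenograft_pairs.tsv"))
    (out("xenograft_origins.tsv")).write_text(
        "".join(f"{p.read_id}\t{o}\n" for p, o in zip(pairs, origins))
    )
    for i, table in enumerate(de.foreground, start=1):
        table.to_csv(out(f"de_foreground_{i}.tsv"), sep="\t", index=False)
    for i, table in enumerate(de.background, start=1):
        table.to_csv(out(f"de_background_{i}.tsv"), sep="\t", index=False)
    (out("de_truth.json")).write_text(
        json.dumps({k: sorted(v) for k, v in de.truth.items()}, indent=2)
    )
    write_gene_models(genes, out("gene_models.tsv"))
    with open(out("chrom_sizes.tsv"), "w") as fh:
        for chrom, size in chrom_sizes.items():
            fh.write(f"{chrom}\t{size}\n")
    promoter_peaks = plant_peaks(genes, chrom_sizes, "promoter", 30, seed=s + 5)
    write_bed(promoter_peaks, out("promoter_peaks.bed"))
    # two-label region catalog: the planted promoter peaks themselves
    # (maximally enriched) vs random placements (null)
    import numpy as _np

    rng = _np.random.default_rng(s + 6)
    from .peaks import GenomicInterval as _GI

    catalog = [
        _GI(p.chrom, p.start, p.end, "planted_promoters") for p in promoter_peaks
    ]
    chroms = sorted(chrom_sizes)
    for _ in range(60):
        chrom = chroms[int(rng.integers(len(chroms)))]
        start = int(rng.integers(0, chrom_sizes[chrom] - 400))
        catalog.append(_GI(chrom, start, start + 400, "random_background"))
    write_bed(catalog, out("region_catalog.bed"))

    _write_manifest(
        outdir,
        "simulate",
        {
            "seed": s,
            "cohort_spec": cohort_kwargs,
            "xenograft_spec": xeno_kwargs,
            "de_spec": de_kwargs,
            "genome_spec": genome_kwargs,
            "outputs": {k: str(v) for k, v in paths.items()},
        },
    )
    return paths


def run_disambiguate(
    config: Mapping[str, Any], outdir: str | Path, seed: int | None = None
) -> dict[str, int]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    section = config.get("disambiguate")
    _require(section, "disambiguate", "pairs_tsv")
    pairs_path = _resolve(config, "disambiguate.pairs_tsv", section["pairs_tsv"])
    key = section.get("key", "score_then_mapq")
    try:
        pairs = read_pairs_tsv(pairs_path)
        graft, host, amb, summary = disambiguate_pairs(pairs, key=key)
    except ValueError as exc:
        raise DataError(f"disambiguate: {exc}") from exc
    write_assignments(graft, host, amb, summary, outdir)
    _write_manifest(
        outdir,
        "disambiguate",
        {
            "seed": _seed(config, seed),
            "pairs_tsv": str(pairs_path),
            "key": key,
            "summary": asdict(summary),
        },
    )
    return asdict(summary)


def run_classify(
    config: Mapping[str, Any], outdir: str | Path, seed: int | None = None
):
    """filter_genesets -> ssgsea_matrix -> train_model -> predict_proba."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    s = _seed(config, seed)
    section = config.get("classify")
    _require(section, "classify", "expression", "labels", "gmt", "ortholog_map")

    expr_path = _resolve(config, "classify.expression", section["expression"])
    labels_path = _resolve(config, "classify.labels", section["labels"])
    gmt_path = _resolve(config, "classify.gmt", section["gmt"])
    orth_path = _resolve(config, "classify.ortholog_map", section["ortholog_map"])
    query_path = (
        _resolve(config, "classify.query_expression", section["query_expression"])
        if section.get("query_expression")
        else None
    )

    filter_params = GeneSetFilterParams(**(section.get("geneset_filter") or {}))
    ssgsea_params = SsgseaParams(**(section.get("ssgsea") or {}))
    train_kwargs = dict(section.get("train") or {})
    train_kwargs.setdefault("seed", s)
    train_config = TrainConfig(**train_kwargs)

    try:
        expr = read_expression(expr_path)
        labels = pd.read_csv(labels_path, sep="\t", index_col=0).iloc[:, 0]
        collection = read_gmt(gmt_path)
        orthologs = read_ortholog_map(orth_path)
        labels = labels.reindex(expr.columns)
        if labels.isna().any():
            raise DataError("classify: labels missing for some expression samples")

        kept = filter_genesets(collection, orthologs, filter_params)
        if len(kept) == 0:
            raise DataError("classify: no gene set survives the ortholog/size filter")
        profile = ssgsea_matrix(expr, kept, ssgsea_params)
        model = train_model(profile, labels, train_config)
        query_profile = profile
        if query_path is not None:
            query = read_expression(query_path)
            query_profile = ssgsea_matrix(query, kept, ssgsea_params)
        probs = predict_proba(model, query_profile)
    except DataError:
        raise
    except ValueError as exc:
        raise DataError(f"classify: {exc}") from exc

    save_model(model, outdir / "model")
    profile.write(outdir / "enrichment_profile.tsv")
    calls = probs.idxmax(axis=1)
    pred = probs.copy()
    pred["predicted_label"] = calls
    pred.to_csv(outdir / "predictions.tsv", sep="\t", index_label="sample")
    _write_manifest(
        outdir,
        "classify",
        {
            "seed": s,
            "inputs": {
                "expression": str(expr_path),
                "labels": str(labels_path),
                "gmt": str(gmt_path),
                "ortholog_map": str(orth_path),
                "query_expression": str(query_path) if query_path else None,
            },
            "geneset_filter": asdict(filter_params),
            "n_sets_after_filter": len(kept),
            "ssgsea": asdict(ssgsea_params),
            "train": asdict(train_config),
            "n_selected_features": len(model.selected_features),
            "test_accuracy": model.test_accuracy,
        },
    )
    return model, probs


def run_integrate(
    config: Mapping[str, Any], outdir: str | Path, seed: int | None = None
) -> dict[str, Any]:
    """Signature algebra + overlap test + peak annotation + region enrichment."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    s = _seed(config, seed)
    section = config.get("integrate")
    _require(section, "integrate", "foreground_de")

    thresholds = SignatureThresholds(**(section.get("thresholds") or {}))
    ann_params = AnnotationParams(**(section.get("annotation") or {}))
    n_shuffles = int(section.get("n_shuffles", 1000))

    fg_paths = [
        _resolve(config, "integrate.foreground_de", p) for p in section["foreground_de"]
    ]
    bg_paths = [
        _resolve(config, "integrate.background_de", p)
        for p in section.get("background_de", [])
    ]

    summary: dict[str, Any] = {"thresholds": asdict(thresholds)}
    try:
        fg_tables = [
            filter_low_count(read_de_table(p), thresholds.min_total_count)
            for p in fg_paths
        ]
        bg_tables = [
            filter_low_count(read_de_table(p), thresholds.min_total_count)
            for p in bg_paths
        ]
        sets = shared_and_exclusive(
            [threshold_de(t, thresholds) for t in fg_tables],
            [threshold_de(t, thresholds) for t in bg_tables],
        )
        write_signature_sets(sets, outdir)
        summary["signatures"] = sets.summary()
        logger.info(
            "thresholds applied: padj < %g, |log2FC| > %g, total count >= %d",
            thresholds.max_padj, thresholds.min_abs_l2fc, thresholds.min_total_count,
        )

        if section.get("bound_genes"):
            bound_path = _resolve(config, "integrate.bound_genes", section["bound_genes"])
            bound = frozenset(
                g.strip() for g in bound_path.read_text().splitlines() if g.strip()
            )
            universe = frozenset(fg_tables[0]["gene"])
            overlap, p = overlap_test(
                sets.exclusive_down & universe, bound & universe, universe
            )
            (outdir / "overlap_genes.txt").write_text(
                "".join(g + "\n" for g in sorted(overlap))
            )
            summary["overlap_test"] = {
                "n_overlap": len(overlap),
                "hypergeometric_p": p,
                "universe_size": len(universe),
            }

        if section.get("peaks"):
            peak_paths = [
                _resolve(config, "integrate.peaks", p) for p in section["peaks"]
            ]
            gene_models = read_gene_models(
                _resolve(config, "integrate.gene_models", section["gene_models"])
            )
            merged = merge_union(*(read_bed(p) for p in peak_paths))
            write_bed(merged, outdir / "merged_peaks.bed")
            dist = genomic_distribution(merged, gene_models, ann_params)
            summary["genomic_distribution"] = dist
            summary["annotation"] = asdict(ann_params)

            if section.get("catalog"):
                catalog_bed = read_bed(
                    _resolve(config, "integrate.catalog", section["catalog"])
                )
                chrom_sizes = read_chrom_sizes(
                    _resolve(config, "integrate.chrom_sizes", section["chrom_sizes"])
                )
                catalog: dict[str, list] = {}
                for iv in catalog_bed:
                    catalog.setdefault(iv.name or "catalog", []).append(iv)
                results = region_enrichment(
                    merged, catalog, chrom_sizes, n_shuffles=n_shuffles, seed=s
                )
                enrichment_table(results).to_csv(
                    outdir / "region_enrichment.tsv", sep="\t", index=False
                )
                summary["region_enrichment"] = {
                    "n_shuffles": n_shuffles,
                    "n_labels": len(results),
                }
    except (ConfigError, DataError):
        raise
    except ValueError as exc:
        raise DataError(f"integrate: {exc}") from exc

    (outdir / "integrate_summary.json").write_text(json.dumps(summary, indent=2))
    _write_manifest(outdir, "integrate", {"seed": s, **summary})
    return summary
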