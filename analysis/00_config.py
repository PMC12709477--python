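"""Shared configuration for the numbered analysis drivers.

All drivers read and write below ``results/`` at the repository root and
share one seed, so the whole analysis is reproducible end to end by running
the scripts in order:

    python analysis/01_simulate_inputs.py
    python analysis/02_disambiguate_reads.py
    python analysis/03_classify_subgroups.py
    python analysis/04_integrate_signatures_and_peaks.py
"""

from pathlib import Path

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"
INPUTS = RESULTS / "inputs"
SEED = 7

CONFIG = {
    "seed": SEED,
    # study conditions: defaults of CohortSpec / XenograftSpec / the DE and
    # genome generators; listed explicitly nowhere so the library defaults
    # stay the single source of truth
    "simulate": {},
    "classify": {
        "expression": str(INPUTS / "expression.tsv"),
        "labels": str(INPUTS / "labels.tsv"),
        "gmt": str(INPUTS / "gene_sets.gmt"),
        "ortholog_map": str(INPUTS / "ortholog_map.tsv"),
        # synthetic sets hold 30 genes each, below the 15-400 window's
        # MSigDB-scale upper bound; the ortholog threshold stays at 0.80
        "geneset_filter": {"min_ortholog_fraction": 0.80, "min_size": 15, "max_size": 400},
        "ssgsea": {"alpha": 0.25, "normalize": True},
        "train": {"train_fraction": 0.70, "importance_threshold": 8, "n_trees": 500},
    },
    "disambiguate": {"pairs_tsv": str(INPUTS / "xenograft_pairs.tsv")},
    "integrate": {
        "foreground_de": [str(INPUTS / f"de_foreground_{i}.tsv") for i in (1, 2, 3)],
        "background_de": [str(INPUTS / f"de_background_{i}.tsv") for i in (1, 2)],
        "thresholds": {"max_padj": 0.05, "min_abs_l2fc": 1.0, "min_total_count": 10},
        "peaks": [str(INPUTS / "promoter_peaks.bed")],
        "gene_models": str(INPUTS / "gene_models.tsv"),
        "catalog": str(INPUTS / "region_catalog.bed"),
        "chrom_sizes": str(INPUTS / "chrom_sizes.tsv"),
        "n_shuffles": 1000,
    },
}
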