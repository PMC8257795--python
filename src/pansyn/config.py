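"""Flat key-value configuration mirroring every named pipeline threshold.

Config files are plain ``key = value`` lines (``#`` comments allowed);
values are parsed as int, float, bool or string.  :data:`DEFAULTS` is the
single source of the pipeline's default thresholds.
"""

from __future__ import annotations

from pathlib import Path

DEFAULTS: dict[str, object] = {
    # hit pruning / orthogroups
    "prune_n_top": 2,
    "pangenome_hits_per_gene_per_genome": 1,
    # collinear chaining (paralog / homeolog runs)
    "paralog_max_gap": 50,
    "paralog_min_size": 10,
    "dbscan_radius": 50.0,
    "dbscan_min_hits": 10,
    # collinear chaining (pan-genome runs)
    "pangenome_max_gap": 20,
    "pangenome_min_size": 10,
    # rearrangement clock
    "wgd_age_myr": 60.0,
    # pan-genome / PAV
    "absence_min_run": 5,
    "very_similar_min_coverage": 99.0,
    "very_similar_min_identity": 95.0,
    "diverged_min_coverage": 75.0,
    "diverged_min_identity": 75.0,
    "haplotype_identity_threshold": 98.0,
    # molecular evolution
    "kaks_min_codons": 10,
    "sliding_window_genes": 100,
    # introgression
    "prune_min_minor_allele_count": 3,
    "prune_max_r2": 0.999,
    "prune_window_snps": 100,
    "hmm_n_sources": 4,
    "hmm_genotyping_error": 1e-3,
    "hmm_switch_rate": 5.0,
    "min_block_markers": 500,
    # documentation of the multi-pulse admixture model this HMM condenses:
    # pulses at 2-5 generations with proportions .5/.25/.125, ne 1000,
    # tmax 5, tolerance .01
    "ancestry_hmm_cmdline": (
        "-p 0 5 1 -p 1 5 1 -p 2 5 1 -p 3 5 1 -p 3 4 .5 -p 3 3 0.25 "
        "-p 3 2 0.125 --ne 1000 --tmax 5 -e 1e-3 --tolerance .01 -g"
    ),
    # QTL mapping
    "marker_min_maf": 0.05,
    "marker_max_het_freq": 0.8,
    "marker_max_missing": 0.1,
    "marker_max_alleles": 2,
    "marker_depth_trim_fraction": 0.01,
    "bin_size_bp": 25_000,
    "bin_local_window_snps": 10,
    "map_function": "kosambi",
    "map_error_prob": 0.0165,
    "scan_step_cm": 0.1,
    "n_permutations": 10_000,
    "bayes_prob": 0.95,
    # quantile transform convention for the Ks landscape
    "quantile_definition": "midrank_minus_half_over_n",
    "window_aggregation": "mean",
}


def _parse_value(raw: str) -> object:
    raw = raw.strip()
    low = raw.lower()
    if low in ("true", "false"):
        return low == "true"
    for cast in (int, float):
        try:
            return cast(raw)
        except ValueError:
            pass
    return raw


def load_config(path: str | Path | None = None) -> dict[str, object]:
    """Defaults overlaid with an optional flat key-value file."""
    cfg = dict(DEFAULTS)
    if path is None:
        return cfg
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected 'key = value'")
            key, raw = line.split("=", 1)
            cfg[key.strip()] = _parse_value(raw)
    return cfg


def write_config(cfg: dict[str, object], path: str | Path) -> None:
    with open(path, "w") as fh:
        for key, value in cfg.items():
            fh.write(f"{key} = {value}\n")
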