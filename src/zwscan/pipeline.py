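"""End-to-end pipeline: simulate -> qc -> grm -> gwas -> interaction -> haplotype.

Every stage is a pure function of its inputs plus the seed; rerunning with
the same configuration is bit-identical.  A run-manifest JSON records the
seed, parameters and per-stage record counts.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .epistasis import build_table, offspring_ratio_test, records_from_truth
from .haplotype import HAP1, HAP2, count_haplotypes, default_panel
from .io import GenotypeData, read_genotypes_tsv, read_phenotypes, write_genotypes_tsv
from .qc import filter_markers, impute_missing
from .relatedness import build_grm
from .scan import manhattan_plot, run_gwas, ztw_condition
from .simdata import SimConfig, causal_marker_ids, simulate_population, write_population

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Pipeline configuration (YAML-loadable; CLI flags override)."""

    out_dir: str = "zwscan_run"
    seed: int = 0
    alpha: float = 0.05
    ci_level: float = 0.95
    maf_min: float = 0.05
    callrate_min: float = 0.80
    n_neighbors: int = 10
    sim: dict = field(default_factory=dict)  # SimConfig overrides
    stages: list[str] = field(
        default_factory=lambda: [
            "simulate", "qc", "grm", "gwas", "interaction", "haplotype",
        ]
    )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {k: v for k, v in raw.items() if k in cls.__dataclass_fields__}
        unknown = set(raw) - set(known)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**known)
        if not 0 < cfg.alpha < 1:
            raise ValueError("alpha must be in (0,1)")
        return cfg


def run_pipeline(config: RunConfig) -> dict:
    """Run the configured stages; returns (and writes) the run manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "alpha": config.alpha,
        "stages": {},
    }
    t_all = time.time()

    sim_cfg = SimConfig(**{**config.sim, "seed": config.seed})
    geno = pheno = truth = None
    if "simulate" in config.stages:
        t0 = time.time()
        geno, pheno, truth = simulate_population(sim_cfg)
        write_population(geno, pheno, out / "population")
        truth.to_csv(out / "population.truth.tsv", sep="\t", index=False)
        manifest["stages"]["simulate"] = {
            "n_individuals": geno.n_individuals,
            "n_markers": geno.n_markers,
            "seconds": round(time.time() - t0, 3),
        }
        logger.info("simulate: %s individuals x %s markers",
                    geno.n_individuals, geno.n_markers)
    else:
        geno = read_genotypes_tsv(out / "population.geno.tsv",
                                  out / "population.map.tsv")
        pheno = read_phenotypes(out / "population.pheno.tsv")
        truth = pd.read_csv(out / "population.truth.tsv", sep="\t")

    locus1_id, locus2_id = causal_marker_ids(sim_cfg)
    cohort_rule = ztw_condition(locus1_id)
    qced = None
    if "qc" in config.stages:
        t0 = time.time()
        qced, report = filter_markers(
            geno, maf_min=config.maf_min, callrate_min=config.callrate_min
        )
        if np.isnan(qced.values).any():
            qced = impute_missing(qced, n_neighbors=config.n_neighbors)
        report.to_csv(out / "qc_report.tsv", sep="\t", index=False)
        write_genotypes_tsv(qced, out / "imputed.geno.tsv", out / "imputed.map.tsv")
        manifest["stages"]["qc"] = {
            "n_markers_in": geno.n_markers,
            "n_markers_kept": qced.n_markers,
            "n_removed": len(report),
            "seconds": round(time.time() - t0, 3),
        }

    if "grm" in config.stages:
        t0 = time.time()
        src = qced if qced is not None else geno
        kin = build_grm(src)
        pd.DataFrame(
            kin.K, index=kin.individual_ids, columns=kin.individual_ids
        ).to_csv(out / "K.tsv", sep="\t")
        manifest["stages"]["grm"] = {
            "n": kin.n, "n_markers": kin.n_markers,
            "seconds": round(time.time() - t0, 3),
        }

    if "gwas" in config.stages:
        t0 = time.time()
        result = run_gwas(
            geno, pheno, condition=cohort_rule,
            alpha=config.alpha, ci_level=config.ci_level,
            maf_min=config.maf_min, callrate_min=config.callrate_min,
            n_neighbors=config.n_neighbors,
            chrom_lengths=sim_cfg.resolved_lengths(),
        )
        result.table.to_csv(out / "scan.tsv", sep="\t", index=False,
                            float_format="%.6g")
        with open(out / "scan_summary.json", "w") as fh:
            json.dump(result.summary(), fh, indent=2)
        manhattan_plot(result, out / "manhattan.png",
                       chrom_lengths=sim_cfg.resolved_lengths())
        manifest["stages"]["gwas"] = {
            "n_markers": int(len(result.table)),
            "peak_marker": result.peak_marker,
            "threshold": result.threshold,
            "seconds": round(time.time() - t0, 3),
        }

    if "interaction" in config.stages:
        t0 = time.time()
        records = records_from_truth(truth, pheno)
        table = build_table(records)
        table.counts.to_csv(out / "interaction.tsv", sep="\t")
        manifest["stages"]["interaction"] = {
            "n_records": table.total,
            "misclassified": table.misclassified,
            "seconds": round(time.time() - t0, 3),
        }

    if "haplotype" in config.stages:
        t0 = time.time()
        panel = default_panel()
        hap_of = {"A": panel.haplotype_alleles(HAP1),
                  "G": panel.haplotype_alleles(HAP2)}
        zw = truth[truth["g2_genotype"].isin(["GG", "AA"])]
        vectors = [
            hap_of["A" if g2 == "AA" else "G"]
            for g2 in zw["g2_genotype"]
        ]
        n_classes = count_haplotypes(vectors, panel) if vectors else 0
        manifest["stages"]["haplotype"] = {
            "panel_sites": len(panel),
            "n_vectors": len(vectors),
            "n_classes": n_classes,
            "seconds": round(time.time() - t0, 3),
        }

    manifest["seconds_total"] = round(time.time() - t_all, 3)
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
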