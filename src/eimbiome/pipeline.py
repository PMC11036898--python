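"""End-to-end orchestration: synthetic (or on-disk) data through
preprocessing, diversity, PERMANOVA, differential abundance and
SparCC modules, with every result written as TSV plus a JSON run log.
"""

from __future__ import annotations

import json
import logging
import sys
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .containers import GROUP_CASE, GROUP_CONTROL, CountTable, validate_metadata
from .da import differential_abundance, effect_filter
from .diversity import alpha_diversity, beta_distance_matrix, permanova, rank_compare
from .io import (
    read_count_table,
    read_metadata,
    read_taxonomy,
    read_tree,
    write_count_table,
    write_distance_matrix,
    write_metadata,
    write_tree,
)
from .preprocess import filter_low_frequency, prevalence_filter, remove_control_artifacts
from .sparcc import associate_modules, detect_modules, module_abundance, sparcc
from .synthetic import (
    SimulationParams,
    apply_contaminant_carryover,
    generate_community,
    generate_negative_controls,
    generate_random_tree,
)

__all__ = ["PipelineConfig", "run_pipeline"]

log = logging.getLogger("eimbiome")


@dataclass
class PipelineConfig:
    """All paths and thresholds of a pipeline run.

    Threshold defaults are the analysis settings of the source study:
    pooled low-frequency cutoff 0.001% (1e-5), decontamination
    prevalence 15%/15%, DA & SparCC prevalence 10%, module correlation
    threshold 0.5, significance q < 0.05 with |log2 FC| > 1.
    """

    counts: str | None = None
    metadata: str | None = None
    taxonomy: str | None = None
    tree: str | None = None
    output_dir: str = "results"
    low_freq: float = 1e-5
    control_prevalence: float = 0.15
    sample_prevalence: float = 0.15
    min_prevalence: float = 0.10
    module_threshold: float = 0.5
    exclusion_threshold: float = 0.1
    max_exclusions: int = 10
    q_threshold: float = 0.05
    lfc_threshold: float = 1.0
    beta_metric: str = "weighted_unifrac"
    permanova_terms: list[str] = field(default_factory=lambda: ["group"])
    da_covariates: list[str] = field(default_factory=lambda: ["subtype", "surgery"])
    n_permutations: int = 999
    seed: int = 0
    # synthetic-cohort sizes used when no counts path is configured;
    # defaults mirror the study population (86 EIM / 45 control)
    sim_n_case: int = 86
    sim_n_control: int = 45
    sim_n_asvs: int = 300

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**raw)

    def thresholds(self) -> dict:
        d = asdict(self)
        for k in ("counts", "metadata", "taxonomy", "tree", "output_dir"):
            d.pop(k)
        return d


def _load_or_simulate(config: PipelineConfig):
    if config.counts is not None:
        counts = read_count_table(config.counts)
        if config.metadata is None:
            raise ValueError("metadata path required when counts are given")
        meta = validate_metadata(read_metadata(config.metadata), counts)
        tree = read_tree(config.tree) if config.tree else None
        return counts, meta, tree

    log.info("no input counts given: simulating a synthetic cohort (seed=%d)", config.seed)
    params = SimulationParams(
        n_samples_per_group=(config.sim_n_case, config.sim_n_control),
        n_asvs=config.sim_n_asvs,
        module_spec=[(16, 0.8), (6, 0.8), (2, 0.8)],
        effect_spec=[(40, -3.0, (0.3, 0.05)), (41, 2.5, 0.0), (42, -2.0, 0.0)],
        contaminant_spec=[(50, 25.0, 0.05), (51, 40.0, 0.08)],
        seed=config.seed,
    )
    counts, meta, truth = generate_community(params)
    counts = apply_contaminant_carryover(counts, params)
    controls = generate_negative_controls(truth, params)
    full = CountTable(pd.concat([counts.data, controls.data]))
    ctrl_meta = pd.DataFrame(
        {
            "group": pd.NA,
            "subtype": pd.NA,
            "surgery": False,
            "is_negative_control": True,
        },
        index=controls.data.index,
    )
    meta = pd.concat([meta, ctrl_meta])
    tree = generate_random_tree(full.asv_ids, seed=config.seed)
    return full, meta, tree


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and write the result bundle to ``output_dir``.

    Returns a dict of in-memory results keyed by stage.  Reruns with
    the same config (and seed) are bit-identical.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle: dict = {}

    def stage(name):
        log.info("stage: %s", name)

    try:
        stage("load")
        counts, meta, tree = _load_or_simulate(config)
        if config.counts is None:
            write_count_table(counts, out / "counts_raw.tsv")
            write_metadata(meta, out / "metadata.csv")
            if tree is not None:
                write_tree(tree, out / "tree.nwk")

        stage("preprocess")
        filtered = filter_low_frequency(counts, config.low_freq)
        clean = remove_control_artifacts(
            filtered, meta, config.control_prevalence, config.sample_prevalence
        )
        write_count_table(clean, out / "counts_clean.tsv")
        bundle["counts_clean"] = clean
        bio_meta = meta.loc[clean.sample_ids]

        stage("alpha diversity")
        alpha = alpha_diversity(clean)
        alpha.to_csv(out / "alpha_diversity.tsv", sep="\t")
        groups = bio_meta["group"]
        alpha_tests = {}
        for metric in ("observed_richness", "shannon", "pielou_evenness"):
            vals = alpha[metric].dropna()
            g = groups.loc[vals.index]
            u, p = rank_compare(
                vals[g == GROUP_CASE].to_numpy(), vals[g == GROUP_CONTROL].to_numpy()
            )
            alpha_tests[metric] = {"U": u, "p": p}
        bundle["alpha"] = alpha
        bundle["alpha_tests"] = alpha_tests

        stage("beta diversity + PERMANOVA")
        dm = beta_distance_matrix(clean, config.beta_metric, tree=tree)
        write_distance_matrix(dm, out / f"distance_{config.beta_metric}.tsv")
        perma = permanova(
            dm,
            bio_meta,
            config.permanova_terms,
            n_permutations=config.n_permutations,
            seed=config.seed,
        )
        perma_df = pd.DataFrame([asdict(r) for r in perma])
        perma_df.to_csv(out / "permanova.tsv", sep="\t", index=False)
        bundle["permanova"] = perma

        stage("differential abundance")
        da_input = prevalence_filter(clean, config.min_prevalence)
        da_table = differential_abundance(da_input, bio_meta, config.da_covariates)
        if config.taxonomy:
            tax = read_taxonomy(config.taxonomy)
            keep = [c for c in ("Phylum", "Family", "Genus", "Species") if c in tax.columns]
            da_table = da_table.join(tax[keep], how="left")
        da_table.to_csv(out / "da_table.tsv", sep="\t")
        significant = effect_filter(da_table, config.q_threshold, config.lfc_threshold)
        significant.to_csv(out / "da_significant.tsv", sep="\t")
        bundle["da_table"] = da_table
        bundle["da_significant"] = significant

        stage("SparCC modules")
        rho = sparcc(
            da_input,
            exclusion_threshold=config.exclusion_threshold,
            max_exclusions=config.max_exclusions,
        )
        rho.to_csv(out / "sparcc_correlations.tsv", sep="\t")
        modules = detect_modules(rho, config.module_threshold)
        abund = module_abundance(da_input, modules)
        abund.attrs["module_sizes"] = {
            f"module_{k + 1}": len(m) for k, m in enumerate(modules.modules)
        }
        assoc = associate_modules(abund, bio_meta)
        members = pd.DataFrame(
            [
                {"module_id": f"module_{k + 1}", "size": len(m), "members": ";".join(sorted(m))}
                for k, m in enumerate(modules.modules)
            ]
        )
        members.to_csv(out / "modules.tsv", sep="\t", index=False)
        assoc_df = pd.DataFrame([asdict(a) for a in assoc])
        assoc_df.to_csv(out / "module_associations.tsv", sep="\t", index=False)
        bundle["modules"] = modules
        bundle["associations"] = assoc
    except Exception as exc:
        raise RuntimeError(f"pipeline failed: {exc}") from exc

    run_log = {
        "package_version": __version__,
        "python": sys.version.split()[0],
        "seed": config.seed,
        "thresholds": config.thresholds(),
        "n_samples": counts.n_samples,
        "n_asvs_raw": counts.n_asvs,
        "n_asvs_clean": clean.n_asvs,
        "n_significant_asvs": int(len(significant)),
        "n_modules": len(modules),
    }
    (out / "run_log.json").write_text(json.dumps(run_log, indent=2))
    bundle["run_log"] = run_log
    return bundle
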