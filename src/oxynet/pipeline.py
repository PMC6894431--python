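"""End-to-end orchestration: read -> growth -> networks -> nulls ->
rank/abundance -> associations -> JSON reports."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

from . import __version__
from .association_analysis import (
    growth_infestation_ancova,
    habitat_summaries,
    individual_network_models,
)
from .data_model import (
    StudyDataset,
    drop_uninfected_hosts,
    read_host_table,
    read_interaction_matrix,
    write_metrics_report,
)
from .growth import GrowthModelParams, estimate_growth_rate, params_for_sex
from .network_metrics import host_metrics, network_metrics
from .null_models import nestedness_test
from .rank_abundance import compare_slopes, fit_slope, rank_table

log = logging.getLogger("oxynet")

__all__ = ["PipelineConfig", "run_pipeline", "add_growth_rates"]


@dataclass
class PipelineConfig:
    """Inputs, growth parameters, replication and output location."""

    matrix_paths: dict[str, str]            # habitat -> CSV path
    trait_path: str | None = None
    output_dir: str = "oxynet_out"
    n_replicates: int = 1000
    seed: int = 20100315
    subset: str = "all"                     # all | adults for summaries
    networks_only: bool = False
    transposed_matrices: bool = False
    growth_params: GrowthModelParams | None = None  # None = sex-specific defaults
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")


def add_growth_rates(hosts, params: GrowthModelParams | None = None):
    """Fill ``growth_rate_k`` from carapace length and age where missing."""
    for h in hosts:
        if h.growth_rate_k is None:
            p = params if params is not None else params_for_sex(h.sex)
            h.growth_rate_k = estimate_growth_rate(h.carapace_mm, h.age_years, p)
    return hosts


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run every stage and write one JSON report per habitat plus a
    study-level report.  Deterministic for a fixed (config, seed)."""
    logging.basicConfig(level=cfg.log_level)
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    matrices = {}
    for habitat, path in cfg.matrix_paths.items():
        try:
            matrices[habitat] = read_interaction_matrix(
                path, habitat, transposed=cfg.transposed_matrices
            )
        except Exception as exc:
            raise RuntimeError(f"stage read_matrix[{habitat}] on {path}: {exc}") from exc

    report: dict = {"habitats": {}, "study": {}}
    tables = {}
    for habitat, m in matrices.items():
        log.info("network stage: habitat=%s %dx%d", habitat, m.n_species, m.n_hosts)
        infected = drop_uninfected_hosts(m)
        block = {
            "n_hosts_sampled": m.n_hosts,
            "n_hosts_infected": infected.n_hosts,
            "metrics": network_metrics(infected).as_dict(),
            "host_metrics": host_metrics(infected).as_dict(),
        }
        ens = nestedness_test(
            infected, n_replicates=cfg.n_replicates, seed=cfg.seed
        )
        block["null_model"] = ens.as_dict()
        t = rank_table(m)
        slope, intercept = fit_slope(t)
        tables[habitat] = t
        block["rank_abundance"] = {"slope": slope, "intercept": intercept,
                                   "species": list(t.species)}
        report["habitats"][habitat] = block

    if len(tables) >= 2:
        report["study"]["rank_abundance_ancova"] = compare_slopes(tables).to_dict(
            orient="records"
        )

    if cfg.trait_path and not cfg.networks_only:
        hosts = read_host_table(cfg.trait_path)
        add_growth_rates(hosts, cfg.growth_params)
        ds = StudyDataset(hosts=hosts, matrices=matrices)
        for subset in ("all", "adults"):
            report["study"][f"summary_{subset}"] = habitat_summaries(
                ds, subset
            ).to_dict(orient="records")
        for covariate in ("richness", "abundance"):
            for subset in ("all", "adults"):
                res = growth_infestation_ancova(ds, covariate=covariate, subset=subset)
                report["study"][f"ancova_{covariate}_{subset}"] = res.as_dict()
        report["study"]["individual_models"] = individual_network_models(ds).to_dict(
            orient="records"
        )
    elif not cfg.trait_path and not cfg.networks_only:
        log.warning("no trait table given: association stages skipped")

    report["config"] = {
        "n_replicates": cfg.n_replicates,
        "seed": cfg.seed,
        "subset": cfg.subset,
        "version": __version__,
    }
    write_metrics_report(
        report, out / "report.json", seed=cfg.seed, n_replicates=cfg.n_replicates
    )
    for habitat in matrices:
        write_metrics_report(
            report["habitats"][habitat], out / f"report_{habitat}.json",
            seed=cfg.seed, n_replicates=cfg.n_replicates,
        )
    return report
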