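"""End-to-end pipeline orchestration.

Stages: DMR classification into LMG/HMG percentile tails -> per-class
mutual-information network -> topology statistics -> top-k candidate ranking
-> gene-phenotype correlation network -> enlarged-cohort validation.  Every
intermediate artifact is written as TSV (edge lists additionally as SIF), and
a JSON manifest records the configuration, realized thresholds, per-stage
counts and SHA-256 hashes of every output, so that identical config + seed
reproduce byte-identical results.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import association, candidates, classify, minet, topology, validation
from .synthetic import (
    CohortSpec,
    ValidationCohortSpec,
    simulate_discovery_cohort,
    simulate_phenotypes,
    simulate_validation_cohort,
)

__all__ = ["PipelineConfig", "run_pipeline", "load_config", "write_tsv", "read_matrix_tsv"]

logger = logging.getLogger(__name__)

_FLOAT_FMT = "%.10g"


@dataclass
class PipelineConfig:
    """All thresholds and knobs of the pipeline in one place."""

    seed: int = 0
    percentile_low: float = 5.0
    percentile_high: float = 95.0
    mi_bins: int | None = None  # None = ceil(sqrt(n_samples))
    mi_tau: float = 0.0
    top_k: int = 10
    alpha_assoc: float = 0.05
    alpha_validation: float = 0.05
    n_sites: int = 841
    n_case: int = 6
    n_ctrl: int = 6
    n_case_validation: int = 48
    n_ctrl_validation: int = 24
    supplementary: tuple[str, ...] = candidates.DEFAULT_SUPPLEMENTARY

    def __post_init__(self) -> None:
        if self.percentile_low >= self.percentile_high:
            raise ValueError("percentile_low must be below percentile_high")
        for a in (self.alpha_assoc, self.alpha_validation):
            if not 0 < a < 1:
                raise ValueError("significance levels must lie in (0, 1)")
        if self.top_k < 1:
            raise ValueError("top_k must be at least 1")


def load_config(path) -> PipelineConfig:
    """Read a YAML config; unknown keys are rejected."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    if "supplementary" in raw:
        raw["supplementary"] = tuple(raw["supplementary"])
    return PipelineConfig(**raw)


def write_tsv(df: pd.DataFrame, path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index, float_format=_FLOAT_FMT)


def read_matrix_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig, out_dir) -> dict:
    """Run every stage on a synthetic cohort and return the manifest dict.

    All outputs land under ``out_dir``; the manifest is also written there
    as ``manifest.json``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sub = np.random.SeedSequence(config.seed).generate_state(4) % (2**31)
    manifest: dict = {"config": dataclasses.asdict(config), "stages": {}}

    # stage 1: discovery cohort
    spec = CohortSpec(
        n_sites=config.n_sites, n_case=config.n_case, n_ctrl=config.n_ctrl,
        seed=int(sub[0]),
    )
    matrix, dmrs = simulate_discovery_cohort(spec)
    write_tsv(matrix.values, out / "methylation_matrix.tsv", index=True)
    write_tsv(dmrs, out / "dmr_table.tsv")
    manifest["stages"]["simulate"] = {
        "n_sites": int(len(dmrs)), "n_samples": int(matrix.values.shape[1]),
    }

    # stage 2: percentile classification
    classes = classify.classify_lmg_hmg(
        dmrs, config.percentile_low, config.percentile_high
    )
    classify.write_class_file(classes, out / "gene_classes.tsv")
    manifest["stages"]["classify"] = {
        "n_lmg": int(len(classes.lmg)), "n_hmg": int(len(classes.hmg)),
        "threshold_low": classes.threshold_low,
        "threshold_high": classes.threshold_high,
    }

    # stages 3-5 per gene class: MI network, topology, candidates
    cand_lists: dict[str, candidates.CandidateList] = {}
    for label, members in (("LMG", classes.lmg), ("HMG", classes.hmg)):
        sub_matrix = matrix.restrict(members["node_id"])
        mi = minet.build_mi_matrix(sub_matrix, config.mi_bins)
        net = minet.threshold_network(mi, tau=config.mi_tau)
        minet.write_edge_list(net, out / f"network_{label.lower()}.tsv")
        minet.write_sif(net, out / f"network_{label.lower()}.sif")
        nodes = topology.node_metrics(net)
        write_tsv(nodes, out / f"node_metrics_{label.lower()}.tsv")
        nm = topology.network_metrics(net)
        write_tsv(nm.as_row(), out / f"network_metrics_{label.lower()}.tsv")
        cand = candidates.rank_candidates(nodes, config.top_k, network_class=label)
        write_tsv(cand.ranked, out / f"candidates_{label.lower()}.tsv")
        cand_lists[label] = cand
        try:
            avg_mi = minet.average_mi(net)
        except ValueError:
            avg_mi = None
        manifest["stages"][f"network_{label}"] = {
            "n_nodes": int(net.number_of_nodes()),
            "n_edges": int(net.number_of_edges()),
            "density": nm.density,
            "average_mi": avg_mi,
            "connected": nm.connected,
            "estimator": mi.estimator_tag,
        }

    panel = candidates.merge_candidates(
        cand_lists["LMG"], cand_lists["HMG"], config.supplementary
    )
    write_tsv(panel, out / "candidate_panel.tsv")
    manifest["stages"]["candidates"] = {"panel_size": int(len(panel))}

    # stage 6: phenotype associations on the discovery samples
    disc_pheno = simulate_phenotypes(config.n_case, config.n_ctrl, seed=int(sub[1]))
    cand_nodes = pd.concat(
        [cand_lists["LMG"].ranked["node_id"], cand_lists["HMG"].ranked["node_id"]]
    )
    cand_levels = matrix.values.loc[cand_nodes]
    assoc = association.build_association_network(
        cand_levels, disc_pheno, alpha=config.alpha_assoc
    )
    write_tsv(disc_pheno.reset_index(), out / "phenotypes_discovery.tsv")
    write_tsv(assoc, out / "association_network.tsv")
    manifest["stages"]["associate"] = {"n_edges": int(len(assoc))}

    # stage 7: enlarged-cohort validation
    vspec = ValidationCohortSpec(
        n_case=config.n_case_validation, n_ctrl=config.n_ctrl_validation,
        seed=int(sub[2]),
    )
    cohort = simulate_validation_cohort(vspec)
    val_pheno = simulate_phenotypes(
        config.n_case_validation, config.n_ctrl_validation, seed=int(sub[3])
    )
    results = validation.validate_panel(
        cohort, val_pheno, alpha=config.alpha_validation
    )
    write_tsv(cohort.reset_index(), out / "validation_cohort.tsv")
    write_tsv(val_pheno.reset_index(), out / "phenotypes_validation.tsv")
    write_tsv(results, out / "validation_results.tsv")
    manifest["stages"]["validate"] = {
        "n_loci": int(len(results)),
        "n_significant": int(results["significant"].sum()),
        "significant_loci": sorted(results.loc[results["significant"], "locus"]),
    }

    manifest["outputs"] = {
        p.name: _sha256(p) for p in sorted(out.glob("*.tsv")) if p.name != "manifest.json"
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    logger.info("pipeline complete: %s", out / "manifest.json")
    return manifest
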