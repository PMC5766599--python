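"""End-to-end orchestration: simulate/load -> DE -> confirm -> enrich ->
network -> qPCR, with a reproducibility manifest.

Every stage writes its artifacts into the run's output directory and
nothing mutates its inputs; the manifest records parameters, input and
output checksums and per-stage row counts, enough to re-run the analysis
bit-identically. All randomness flows from the single configured seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .config import SimulationConfig
from .confirm import annotate_novelty, confirm, partition_by_direction, write_confirmed
from .de import (
    lrt_group_test,
    lrt_paired_test,
    read_de_results,
    tmm_normalize,
    write_de_results,
)
from .enrichment import correlate_target_vs_all, rank_set_enrichment
from .errors import ConfigurationError, LnckitError, ValidationError
from .io import (
    read_annotation,
    read_counts,
    read_gene_sets,
    read_id_list,
    read_sample_sheet,
    write_annotation,
    write_counts,
    write_gene_sets,
    write_sample_sheet,
)
from .network import (
    build_network,
    hub_report,
    select_vertices,
    write_edge_list,
    write_graphml,
    write_hub_report,
    write_sif,
)
from .qpcr import paired_tumor_normal_test, qpcr_records, stagewise_analysis
from .simulate import (
    PLANTED_SET_ID,
    planted_gene_set,
    simulate_confirmation_cohort,
    simulate_discovery_cohort,
    simulate_qpcr_cohort,
    target_lncrna,
    write_truth,
)

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Everything `run_all` needs.

    Either ``simulation`` is set (synthetic mode: all inputs are
    generated) or the input paths are; thresholds default to the
    pipeline's standard operating point (discovery FDR < 0.2,
    confirmation FDR < 0.05, 0.5% edge tails, alpha = 0.05).
    """

    outdir: str = "lnckit_run"
    seed: int = 0
    simulation: SimulationConfig | None = None
    # user-data mode paths (ignored in synthetic mode)
    counts_discovery: str | None = None
    samples_discovery: str | None = None
    counts_confirmation: str | None = None
    samples_confirmation: str | None = None
    annotation: str | None = None
    gene_sets: str | None = None
    known_lncrnas: str | None = None
    qpcr_table: str | None = None
    target: str | None = None
    set_id: str | None = None
    # thresholds
    fdr_disc: float = 0.2
    fdr_conf: float = 0.05
    edge_fraction: float = 0.005
    alpha: float = 0.05
    min_expressed_samples: int = 2
    sample_subset: str = "tumor"
    # synthetic qPCR conditions
    qpcr_n_pairs: int = 139
    qpcr_effect_delta_ct: float = 1.0
    qpcr_noise_sd: float = 0.5

    def __post_init__(self):
        for name, lo, hi in (
            ("fdr_disc", 0.0, 1.0),
            ("fdr_conf", 0.0, 1.0),
            ("alpha", 0.0, 1.0),
        ):
            v = getattr(self, name)
            if not lo < v <= hi:
                raise ConfigurationError(f"PipelineConfig.{name}: must lie in ({lo}, {hi}]")
        if not 0.0 < self.edge_fraction <= 0.5:
            raise ConfigurationError("PipelineConfig.edge_fraction: must lie in (0, 0.5]")
        if self.sample_subset not in ("tumor", "normal", "all"):
            raise ConfigurationError("PipelineConfig.sample_subset: tumor|normal|all")

    @property
    def synthetic(self) -> bool:
        return self.simulation is not None

    @classmethod
    def from_yaml(cls, path, **overrides) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        sim = raw.pop("simulation", None)
        raw.update(overrides)
        cfg = cls(**raw)
        if sim is not None:
            cfg.simulation = SimulationConfig.from_dict(sim)
        return cfg

    def validate_paths(self) -> None:
        if self.synthetic:
            return
        required = (
            "counts_discovery",
            "samples_discovery",
            "counts_confirmation",
            "samples_confirmation",
            "annotation",
        )
        for name in required:
            p = getattr(self, name)
            if p is None:
                raise ValidationError(f"input path {name!r} is required (or set simulation)")
            if not Path(p).exists():
                raise ValidationError(f"input path {name!r} does not exist: {p}")
        for name in ("gene_sets", "known_lncrnas", "qpcr_table"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise ValidationError(f"input path {name!r} does not exist: {p}")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_all(cfg: PipelineConfig) -> dict:
    """Execute every stage in order and return the run manifest.

    A stage failure aborts the run with the failing stage named; partial
    outputs are left on disk for inspection.
    """
    cfg.validate_paths()
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": cfg.seed,
        "parameters": {
            "fdr_disc": cfg.fdr_disc,
            "fdr_conf": cfg.fdr_conf,
            "edge_fraction": cfg.edge_fraction,
            "alpha": cfg.alpha,
            "min_expressed_samples": cfg.min_expressed_samples,
            "sample_subset": cfg.sample_subset,
        },
        "stages": {},
    }
    logger.info("run-all: outdir=%s seed=%d synthetic=%s", outdir, cfg.seed, cfg.synthetic)
    for key, val in manifest["parameters"].items():
        logger.info("parameter %s = %r (defaults are logged deliberately)", key, val)

    stage = "simulate/load"
    try:
        if cfg.synthetic:
            sim = cfg.simulation.replace(seed=cfg.seed)
            counts_d, sheet_d, annotation, truth = simulate_discovery_cohort(sim)
            counts_c, sheet_c = simulate_confirmation_cohort(sim, truth)
            sets = planted_gene_set(truth)
            known = set()
            target = target_lncrna(truth)
            set_id = PLANTED_SET_ID
            qpcr_raw = simulate_qpcr_cohort(
                n_pairs=cfg.qpcr_n_pairs,
                effect_delta_ct=cfg.qpcr_effect_delta_ct,
                noise_sd=cfg.qpcr_noise_sd,
                seed=cfg.seed,
            )
            inputs = outdir / "inputs"
            inputs.mkdir(exist_ok=True)
            write_counts(counts_d, inputs / "counts_discovery.tsv")
            write_sample_sheet(sheet_d, inputs / "samples_discovery.tsv")
            write_counts(counts_c, inputs / "counts_confirmation.tsv")
            write_sample_sheet(sheet_c, inputs / "samples_confirmation.tsv")
            write_annotation(annotation, inputs / "annotation.tsv")
            write_gene_sets(sets, inputs / "gene_sets.tsv")
            write_truth(truth, inputs / "truth.tsv")
            qpcr_raw.to_csv(inputs / "qpcr.tsv", sep="\t", index=False, float_format="%.6g")
        else:
            counts_d = read_counts(cfg.counts_discovery)
            sheet_d = read_sample_sheet(cfg.samples_discovery, counts_d)
            counts_c = read_counts(cfg.counts_confirmation)
            sheet_c = read_sample_sheet(cfg.samples_confirmation, counts_c)
            annotation = read_annotation(cfg.annotation)
            sets = read_gene_sets(cfg.gene_sets) if cfg.gene_sets else None
            known = read_id_list(cfg.known_lncrnas) if cfg.known_lncrnas else set()
            target = cfg.target
            set_id = cfg.set_id
            qpcr_raw = (
                pd.read_csv(cfg.qpcr_table, sep="\t") if cfg.qpcr_table else None
            )
            truth = None
        manifest["stages"][stage] = {
            "n_features": counts_d.shape[0],
            "n_samples_discovery": counts_d.shape[1],
            "n_samples_confirmation": counts_c.shape[1],
        }

        stage = "de-discovery"
        norm_d = tmm_normalize(counts_d)
        de_d = lrt_paired_test(
            counts_d, sheet_d, norm_d, min_expressed_samples=cfg.min_expressed_samples
        )
        write_de_results(de_d, outdir / "discovery_de.tsv")
        manifest["stages"][stage] = {
            "n_tested": int(de_d["tested"].sum()),
            "n_fdr_pass": int((de_d["fdr"] < cfg.fdr_disc).sum()),
        }

        stage = "de-confirmation"
        norm_c = tmm_normalize(counts_c)
        de_c = lrt_group_test(
            counts_c, sheet_c, norm_c, min_expressed_samples=cfg.min_expressed_samples
        )
        write_de_results(de_c, outdir / "confirmation_de.tsv")
        manifest["stages"][stage] = {
            "n_tested": int(de_c["tested"].sum()),
            "n_fdr_pass": int((de_c["fdr"] < cfg.fdr_conf).sum()),
        }

        stage = "confirm"
        hits = confirm(
            de_d,
            de_c,
            fdr_disc=cfg.fdr_disc,
            fdr_conf=cfg.fdr_conf,
            annotation=annotation,
        )
        hits = annotate_novelty(hits, known)
        up, down = partition_by_direction(hits)
        write_confirmed(hits, outdir / "confirmed.tsv")
        manifest["stages"][stage] = {
            "n_confirmed": len(hits),
            "n_up": len(up),
            "n_down": len(down),
            "n_novel": int(hits["novel"].sum()),
        }

        stage = "enrich"
        if target is not None and sets is not None and set_id in sets:
            ranking = correlate_target_vs_all(
                counts_c, target, sheet=sheet_c, sample_subset=cfg.sample_subset
            )
            enr = rank_set_enrichment(ranking, sets.members(set_id), set_id)
            pd.DataFrame([enr.__dict__]).to_csv(
                outdir / "enrichment.tsv", sep="\t", index=False, float_format="%.6g"
            )
            manifest["stages"][stage] = {
                "target": target,
                "set_id": set_id,
                "p_one_sided": enr.p_one_sided,
            }
        else:
            logger.info("enrich: no target/gene set configured; skipped")
            manifest["stages"][stage] = {"skipped": True}

        stage = "network"
        vertices = select_vertices(
            de_d, de_c, annotation, fdr_disc=cfg.fdr_disc, fdr_conf=cfg.fdr_conf
        )
        net = build_network(
            counts_c,
            sheet_c,
            vertices,
            edge_fraction=cfg.edge_fraction,
            sample_subset=cfg.sample_subset,
        )
        write_edge_list(net, outdir / "network_edges.tsv")
        write_sif(net, outdir / "network.sif")
        write_graphml(net, outdir / "network.graphml")
        hubs = hub_report(net)
        write_hub_report(hubs, outdir / "network_hubs.tsv")
        manifest["stages"][stage] = {
            "n_vertices": net.graph.number_of_nodes(),
            "n_edges": net.graph.number_of_edges(),
            "top_hub": hubs["feature_id"].iloc[0] if len(hubs) else None,
        }

        stage = "qpcr"
        if qpcr_raw is not None:
            records = qpcr_records(qpcr_raw)
            rows = []
            for tgt, grp in records.groupby("target"):
                paired = paired_tumor_normal_test(grp)
                stagewise = stagewise_analysis(grp, alpha=cfg.alpha)
                rows.append(
                    {
                        "target": tgt,
                        "paired_statistic": paired.statistic,
                        "paired_p": paired.p_value,
                        "kruskal_h": stagewise.kruskal.statistic,
                        "kruskal_p": stagewise.kruskal.p_value,
                        "n_stage_pairs_flagged": 0
                        if stagewise.pairwise is None
                        else int((stagewise.pairwise["p_value"] < cfg.alpha).sum()),
                    }
                )
            summary = pd.DataFrame(rows)
            summary.to_csv(
                outdir / "qpcr_summary.tsv", sep="\t", index=False, float_format="%.6g"
            )
            manifest["stages"][stage] = {"n_targets": len(summary)}
        else:
            manifest["stages"][stage] = {"skipped": True}
    except LnckitError as exc:
        raise LnckitError(f"stage {stage!r} failed: {exc}") from exc

    if truth is not None:
        confirmed = set(hits["feature_id"])
        true_de = set(truth.loc[truth["is_de"], "feature_id"])
        strong = set(
            truth.loc[truth["is_de"] & (truth["true_log2fc"].abs() >= 3.0), "feature_id"]
        )
        manifest["recovery"] = {
            "sensitivity": len(confirmed & true_de) / len(true_de) if true_de else None,
            "sensitivity_strong_effects": (
                len(confirmed & strong) / len(strong) if strong else None
            ),
            "false_confirmed": len(confirmed - true_de),
        }

    manifest["outputs"] = {
        p.name: _sha256(p) for p in sorted(outdir.rglob("*")) if p.is_file() and p.name != "manifest.json"
    }
    with open(outdir / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
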