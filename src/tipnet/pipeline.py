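"""End-to-end orchestration: data -> FPKM -> filter -> DEG / WGCNA / DNB ->
overlap report, with a manifest for reproducibility.

Inputs are either a simulated study (when no counts path is given) or
counts + gene lengths + sample sheet TSVs. Every stage writes its artifact
under ``outdir`` in the formats the owning module defines; the manifest
records the configuration hash, the seed and the package version, so a rerun
with the same config and seed is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .deg import differential_expression
from .dnb import select_dnb
from .expression import (
    CountMatrix,
    ExpressionMatrix,
    compute_fpkm,
    filter_expressed,
)
from .integration import overlap_report
from .simulate import SimulationConfig, simulate_study
from . import wgcna as wg

__all__ = ["PipelineConfig", "run_pipeline"]

log = logging.getLogger("tipnet")


@dataclass
class PipelineConfig:
    # input paths; when counts_path is None a study is simulated
    counts_path: str | None = None
    gene_lengths_path: str | None = None
    sample_sheet_path: str | None = None
    outdir: str = "tipnet_run"
    stage_order: list[str] = field(default_factory=list)
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    # expression filter
    min_nonzero_samples: int = 8
    # DEG thresholds
    fc_up: float = 1.5
    fc_down: float = 0.67
    alpha: float = 0.05
    # WGCNA parameters
    powers: list[int] = field(default_factory=lambda: list(range(1, 21)))
    fit_threshold: float = 0.85
    min_module_size: int = 30
    merge_cut_height: float = 0.25
    mm_threshold: float = 0.8
    gs_threshold: float = 0.2
    n_hub_modules: int = 2
    # DNB parameters
    dnb_min_size: int = 30
    dnb_cut_height: tuple = (0.3, 0.4, 0.5, 0.6)
    dnb_log2: bool = False
    seed: int = 0

    def validate(self) -> None:
        if not (self.fc_up >= 1 and 0 < self.fc_down <= 1):
            raise ValueError("fold-change thresholds out of range")
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must be in (0, 1)")
        if self.min_module_size < 1 or self.dnb_min_size < 2:
            raise ValueError("module size thresholds out of range")
        if not (0 < self.mm_threshold <= 1 and 0 <= self.gs_threshold < 1):
            raise ValueError("hub thresholds out of range")

    def content_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _load_inputs(config: PipelineConfig) -> tuple[ExpressionMatrix, object]:
    if config.counts_path is None:
        sim = config.simulation
        sim.seed = config.seed
        study = simulate_study(sim)
        return study.expression, study.truth
    for name, p in [
        ("counts", config.counts_path),
        ("gene lengths", config.gene_lengths_path),
        ("sample sheet", config.sample_sheet_path),
    ]:
        if p is None or not Path(p).exists():
            raise FileNotFoundError(f"missing {name} file: {p}")
    counts = pd.read_csv(config.counts_path, sep="\t", index_col=0)
    lengths = pd.read_csv(config.gene_lengths_path, sep="\t", index_col=0).iloc[:, 0]
    sheet = pd.read_csv(config.sample_sheet_path, sep="\t", index_col=0)
    lib = pd.Series(counts.sum(axis=0), index=counts.columns)
    cm = CountMatrix(counts=counts, gene_lengths=lengths, library_sizes=lib)
    expr = compute_fpkm(cm)
    expr.stages = sheet["stage"].reindex(counts.columns)
    expr.stage_order = config.stage_order or sorted(expr.stages.unique().tolist())
    expr.__post_init__()
    return expr, None


def _stage_contrasts(stage_order: list[str]) -> list[tuple[str, str]]:
    # every later stage against every earlier one (b over a)
    return [
        (stage_order[i], stage_order[j])
        for i in range(len(stage_order))
        for j in range(i + 1, len(stage_order))
    ]


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full staged analysis; returns the report dict and writes every
    artifact plus a manifest under ``config.outdir``."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    t0 = time.time()

    expr_raw, truth = _load_inputs(config)
    log.info("input: %d genes x %d samples", *expr_raw.values.shape)

    expr = filter_expressed(expr_raw, config.min_nonzero_samples)
    log.info("expression filter: %d genes kept", expr.values.shape[0])

    # --- differential expression, all pairwise later-vs-earlier contrasts
    deg_sets: dict[str, set[str]] = {}
    deg_counts = {}
    for a, b in _stage_contrasts(expr.stage_order):
        table = differential_expression(
            expr, a, b, fc_up=config.fc_up, fc_down=config.fc_down,
            alpha=config.alpha,
        )
        name = f"{b}_vs_{a}"
        table.to_csv(outdir / f"deg_{name}.tsv", sep="\t")
        deg_sets[name] = set(table.index[table["is_deg"]])
        deg_counts[name] = int(table["is_deg"].sum())
        log.info("DEG %s: %d genes", name, deg_counts[name])
    all_deg = set().union(*deg_sets.values()) if deg_sets else set()

    # --- coexpression network
    values = expr.values.to_numpy(dtype=float)
    scan = wg.soft_threshold_scan(
        values, config.powers, fit_threshold=config.fit_threshold
    )
    log.info("soft threshold: %s", scan.chosen_power)
    adj = wg.adjacency(values, scan.chosen_power)
    tom = wg.tom_similarity(adj)
    labels = wg.cluster_modules(1.0 - tom, min_module_size=config.min_module_size)
    labels = wg.merge_close_modules(values, labels, config.merge_cut_height)
    colors = wg.assign_colors(labels)
    eig, ve = wg.module_eigengenes(values, labels)
    stage_code = expr.stage_codes().to_numpy(dtype=float)
    mm = wg.module_membership(values, eig)
    gs = wg.gene_significance(values, stage_code)
    traits = pd.DataFrame({"stage": stage_code}, index=expr.sample_ids)
    mt = wg.module_trait_correlation(eig, traits)
    log.info("modules: %d (+grey)", len(set(labels) - {0}))

    # hub genes from the modules most positively associated with stage
    stage_rows = mt[mt["trait"] == "stage"].dropna()
    positive = stage_rows[(stage_rows["r"] > 0) & (stage_rows["p"] < 0.05)]
    hub_modules = (
        positive.sort_values("r", ascending=False)["module"]
        .head(config.n_hub_modules)
        .tolist()
    )
    hub_mask = wg.select_hub_genes(
        mm, gs, labels, config.mm_threshold, config.gs_threshold, hub_modules
    )
    hub_genes = set(expr.gene_ids[hub_mask])
    log.info("hub genes: %d (modules %s)", len(hub_genes), hub_modules)

    assignment = pd.DataFrame(
        {
            "module": labels,
            "color": colors,
            "mm_own": [
                mm.loc[i, labels[i]] if labels[i] in mm.columns else np.nan
                for i in range(len(labels))
            ],
            "gs": gs,
            "hub": hub_mask,
        },
        index=expr.gene_ids,
    )
    assignment.to_csv(outdir / "modules.tsv", sep="\t")
    eig.to_csv(outdir / "eigengenes.tsv", sep="\t")
    (outdir / "module_trait.json").write_text(
        mt.to_json(orient="records", indent=1)
    )

    # --- dynamic network biomarker
    dnb_result = select_dnb(
        expr, min_size=config.dnb_min_size, cut_height=config.dnb_cut_height,
        log2=config.dnb_log2,
    )
    (outdir / "dnb.json").write_text(json.dumps(dnb_result.as_dict(), indent=1))
    log.info(
        "DNB: %d genes, tipping at %s",
        len(dnb_result.dnb_genes),
        dnb_result.tipping_stage,
    )

    # --- integration
    report_sets = {
        "DEG": all_deg,
        "hub": hub_genes,
        "DNB": dnb_result.dnb_genes,
    }
    overlaps = overlap_report(report_sets)
    (outdir / "overlap.json").write_text(json.dumps(overlaps.as_dict(), indent=1))

    report = {
        "n_genes_input": int(expr_raw.values.shape[0]),
        "n_genes_filtered": int(expr.values.shape[0]),
        "deg_counts": deg_counts,
        "soft_threshold": scan.chosen_power,
        "n_modules": int(len(set(labels) - {0})),
        "module_sizes": {
            c: int((colors == c).sum()) for c in pd.unique(colors)
        },
        "hub_modules": [int(m) for m in hub_modules],
        "n_hub_genes": len(hub_genes),
        "dnb_size": len(dnb_result.dnb_genes),
        "tipping_stage": dnb_result.tipping_stage,
        "dnb_ci_profile": dnb_result.ci_profile(),
        "overlap_sizes": overlaps.sizes(),
        "key_genes": overlaps.union_of_overlaps,
    }
    (outdir / "report.json").write_text(json.dumps(report, indent=1))
    manifest = {
        "config_hash": config.content_hash(),
        "seed": config.seed,
        "version": __version__,
        "elapsed_s": round(time.time() - t0, 2),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    if truth is not None:
        report["truth_tipping_stage"] = expr.stage_order[truth.tipping_stage]
        report["truth_dnb_jaccard"] = _jaccard(
            dnb_result.dnb_genes, truth.dnb_genes
        )
    return report


def _jaccard(a: set, b: set) -> float:
    if not a and not b:
        return 1.0
    return len(a & b) / len(a | b)
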