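"""Synthetic staged expression studies with planted, recoverable structure.

The generator emulates a three-stage observational transcriptome design
(e.g. normal coronary angiography -> intermediate lesion -> acute myocardial
infarction, 8 monocyte samples per stage): coexpression modules whose shared
factor tracks the ordinal disease stage, and a dynamic-network-biomarker (DNB)
group whose within-group standard deviation and intra-correlation spike at one
planted stage while its coupling to the rest of the transcriptome drops.

Genes are generated on the log2 scale as

    x_gs = mu_g + signal_gs + noise_sd * eps_gs

and exponentiated to FPKM-like positives; fragment counts are obtained by
inverting the FPKM formula and rounding, so both the count and the FPKM code
paths downstream see realistic, mutually consistent inputs.

Signals:

* module m: a per-sample factor ``lambda_m * stage_z + sqrt(1-lambda_m^2) *
  (w*G + sqrt(1-w^2)*eta_m)`` where ``stage_z`` is the standardized ordinal
  stage, ``G`` a global per-sample factor that couples modules to each other
  (and to DNB genes) within a stage, and ``eta_m`` module-private.
* DNB gene, outside the planted stage: ``a * G`` plus noise — a mild, shared
  coupling to the rest of the network.
* DNB gene, at the planted stage: the coupling to ``G`` is scaled by
  ``1 - dnb_cross_corr_drop`` and replaced by a DNB-private factor with
  inflated scale, so that the within-stage SD equals ``dnb_sd_inflation``
  times its value elsewhere and the expected intra-DNB correlation is
  ``dnb_intra_corr``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import ContingencyTable, GroupSummary
from .expression import CountMatrix, ExpressionMatrix, compute_fpkm

__all__ = [
    "SimulationConfig",
    "PlantedTruth",
    "SimulatedStudy",
    "simulate_study",
    "simulate_cohort_table",
    "write_study",
]

_STAGE_NAMES_3 = ["NCA", "IML", "AMI"]


@dataclass
class SimulationConfig:
    """Design of a synthetic staged study.

    Defaults mirror the motivating monocyte study: 3 stages x 8 samples,
    2000 genes, eight planted modules with the published module sizes and a
    103-gene DNB group tipping at the middle (pre-disease) stage.
    """

    n_genes: int = 2000
    n_stages: int = 3
    samples_per_stage: int = 8
    module_sizes: list[int] = field(
        default_factory=lambda: [575, 367, 330, 118, 77, 57, 50, 40]
    )
    module_trait_loadings: list[float] = field(
        default_factory=lambda: [0.64, 0.55, -0.45, 0.4, -0.35, 0.3, -0.25, 0.2]
    )
    dnb_size: int = 103
    dnb_stage_index: int = 1
    dnb_sd_inflation: float = 3.0
    dnb_intra_corr: float = 0.8
    dnb_cross_corr_drop: float = 1.0
    dnb_base_loading: float = 0.4
    shared_factor_weight: float = 0.5
    noise_sd: float = 0.5
    silent_fraction: float = 0.1
    gene_length_range: tuple[int, int] = (200, 10000)
    library_size: int = 20_000_000
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes <= 0:
            raise ValueError("n_genes must be positive")
        if self.n_stages <= 0:
            raise ValueError("n_stages must be positive")
        if self.samples_per_stage <= 0:
            raise ValueError("samples_per_stage must be positive")
        if len(self.module_sizes) != len(self.module_trait_loadings):
            raise ValueError(
                "module_sizes and module_trait_loadings must have equal length"
            )
        if any(s <= 0 for s in self.module_sizes):
            raise ValueError("module sizes must be positive")
        if any(not np.isfinite(l) or abs(l) > 1 for l in self.module_trait_loadings):
            raise ValueError("module trait loadings must be finite and in [-1, 1]")
        if self.dnb_size < 0:
            raise ValueError("dnb_size must be non-negative")
        if sum(self.module_sizes) + self.dnb_size > self.n_genes:
            raise ValueError(
                f"sum(module_sizes) + dnb_size = "
                f"{sum(self.module_sizes) + self.dnb_size} exceeds n_genes = "
                f"{self.n_genes}"
            )
        if not (0 <= self.dnb_stage_index < self.n_stages):
            raise ValueError(
                f"dnb_stage_index {self.dnb_stage_index} outside "
                f"[0, {self.n_stages})"
            )
        if self.dnb_sd_inflation < 1:
            raise ValueError("dnb_sd_inflation must be >= 1")
        if not (0 < self.dnb_intra_corr < 1):
            raise ValueError("dnb_intra_corr must be in (0, 1)")
        if not (0 <= self.dnb_cross_corr_drop <= 1):
            raise ValueError("dnb_cross_corr_drop must be in [0, 1]")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if not (0 <= self.silent_fraction < 1):
            raise ValueError("silent_fraction must be in [0, 1)")
        lo, hi = self.gene_length_range
        if lo <= 0 or hi < lo:
            raise ValueError("gene_length_range must be a positive (low, high) pair")
        if self.library_size <= 0:
            raise ValueError("library_size must be positive")

    def stage_names(self) -> list[str]:
        if self.n_stages == 3:
            return list(_STAGE_NAMES_3)
        return [f"stage{i}" for i in range(self.n_stages)]


@dataclass
class PlantedTruth:
    """Ground truth of a simulated study: module labels (0 = background),
    the planted DNB gene set, and the planted tipping stage index."""

    module_assignment: pd.Series
    dnb_genes: set[str]
    tipping_stage: int


@dataclass
class SimulatedStudy:
    counts: CountMatrix
    expression: ExpressionMatrix
    sample_sheet: pd.DataFrame
    truth: PlantedTruth


def simulate_study(config: SimulationConfig) -> SimulatedStudy:
    """Draw one study. Identical config + seed gives bit-identical output."""
    config.validate()
    rng = np.random.default_rng(config.seed)

    n_samples = config.n_stages * config.samples_per_stage
    stage_names = config.stage_names()
    stage_idx = np.repeat(np.arange(config.n_stages), config.samples_per_stage)
    sample_ids = [
        f"{stage_names[t]}_{i + 1}"
        for t in range(config.n_stages)
        for i in range(config.samples_per_stage)
    ]
    gene_ids = [f"G{i:05d}" for i in range(config.n_genes)]

    stage_z = (stage_idx - stage_idx.mean()) / stage_idx.std()

    # gene -> structure assignment: modules first, then the DNB block
    labels = np.zeros(config.n_genes, dtype=int)
    pos = 0
    for m, size in enumerate(config.module_sizes, start=1):
        labels[pos : pos + size] = m
        pos += size
    dnb_mask = np.zeros(config.n_genes, dtype=bool)
    dnb_mask[pos : pos + config.dnb_size] = True
    planted = (labels > 0) | dnb_mask

    mu = np.where(
        planted,
        rng.normal(4.0, 1.0, config.n_genes),
        rng.normal(2.5, 1.5, config.n_genes),
    )
    # a tenth of the background is essentially silent, so the downstream
    # detection filter (FPKM > 0 in enough samples) has genuine work to do
    silent = (~planted) & (rng.random(config.n_genes) < config.silent_fraction)
    mu[silent] = rng.normal(-12.0, 2.0, int(silent.sum()))

    G = rng.standard_normal(n_samples)  # global per-sample factor
    w = config.shared_factor_weight

    x = mu[:, None] + config.noise_sd * rng.standard_normal(
        (config.n_genes, n_samples)
    )
    for m, lam in enumerate(config.module_trait_loadings, start=1):
        eta = rng.standard_normal(n_samples)
        factor = lam * stage_z + np.sqrt(1 - lam**2) * (
            w * G + np.sqrt(1 - w**2) * eta
        )
        x[labels == m] += factor[None, :]

    if config.dnb_size:
        a = config.dnb_base_loading
        s0 = np.hypot(a, config.noise_sd)  # baseline within-stage SD
        at_tip = stage_idx == config.dnb_stage_index
        n_tip = int(at_tip.sum())
        n_dnb = config.dnb_size
        # outside the planted stage: coupled to the global factor
        x[np.ix_(dnb_mask, ~at_tip)] += a * G[~at_tip][None, :]
        # at the planted stage: rebuild the fluctuation term entirely
        a_res = (1 - config.dnb_cross_corr_drop) * a
        c2 = (config.dnb_sd_inflation * s0) ** 2 - a_res**2
        c = np.sqrt(max(c2, 0.0))
        r = config.dnb_intra_corr
        # DNB-private shared factor, standardized over the stage's samples so
        # the planted SD inflation holds in every realization, not merely in
        # expectation — with one shared factor and few samples the realized
        # spike would otherwise vary by a factor ~2 across seeds, making the
        # planted truth label unreliable
        F = rng.standard_normal(n_tip)
        F = (F - F.mean()) / F.std()
        eps = rng.standard_normal((n_dnb, n_tip))
        x[np.ix_(dnb_mask, at_tip)] = (
            mu[dnb_mask][:, None]
            + a_res * G[at_tip][None, :]
            + c * (np.sqrt(r) * F[None, :] + np.sqrt(1 - r) * eps)
        )

    fpkm_latent = np.power(2.0, x)
    lengths = rng.integers(
        config.gene_length_range[0], config.gene_length_range[1] + 1, config.n_genes
    )
    lib = float(config.library_size)
    counts_values = np.rint(fpkm_latent * lengths[:, None] * lib / 1e9)

    counts = CountMatrix(
        counts=pd.DataFrame(counts_values, index=gene_ids, columns=sample_ids),
        gene_lengths=pd.Series(lengths, index=gene_ids, name="length"),
        library_sizes=pd.Series(lib, index=sample_ids, name="library_size"),
    )

    stages = pd.Series(
        [stage_names[t] for t in stage_idx], index=sample_ids, name="stage"
    )
    expression = compute_fpkm(counts)
    expression.stages = stages
    expression.stage_order = stage_names
    expression.__post_init__()

    sample_sheet = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "stage": stages.values,
            "age": np.round(rng.normal(62.0, 9.0, n_samples), 1),
            "sex": np.where(rng.random(n_samples) < 0.7, "M", "F"),
            "bmi": np.round(rng.normal(24.5, 2.6, n_samples), 2),
            "lvef": np.round(rng.normal(63.0, 7.0, n_samples), 2),
        }
    ).set_index("sample_id")

    truth = PlantedTruth(
        module_assignment=pd.Series(labels, index=gene_ids, name="module"),
        dnb_genes={g for g, is_dnb in zip(gene_ids, dnb_mask) if is_dnb},
        tipping_stage=config.dnb_stage_index,
    )
    return SimulatedStudy(
        counts=counts, expression=expression, sample_sheet=sample_sheet, truth=truth
    )


_DEFAULT_CONTINUOUS = {
    # per-group (mean, sd) cycled over stages; magnitudes follow a typical
    # staged-CAD baseline table
    "age": [(60.0, 9.0), (63.0, 9.0), (63.0, 8.0)],
    "bmi": [(24.8, 2.1), (22.7, 2.3), (26.0, 3.3)],
    "lvef": [(65.0, 6.7), (65.0, 4.4), (58.4, 9.8)],
}
_DEFAULT_CATEGORICAL = {
    # per-group Bernoulli probability of the first category
    "male": [0.625, 0.75, 0.75],
    "diabetes": [0.25, 0.125, 0.375],
    "hypertension": [0.75, 0.625, 0.5],
}


def simulate_cohort_table(
    config: SimulationConfig,
    continuous: dict[str, list[tuple[float, float]]] | None = None,
    categorical: dict[str, list[float]] | None = None,
) -> tuple[dict[str, list[GroupSummary]], dict[str, ContingencyTable]]:
    """Draw a baseline-characteristics fixture: per-stage mean/SD/n summaries
    for continuous covariates and group x category contingency tables for
    binary covariates.

    Parameter lists are cycled when shorter than ``n_stages``. Deterministic
    in ``config.seed``.
    """
    config.validate()
    if config.n_stages < 2:
        raise ValueError("cohort tables need at least 2 groups")
    rng = np.random.default_rng(config.seed)
    continuous = continuous if continuous is not None else _DEFAULT_CONTINUOUS
    categorical = categorical if categorical is not None else _DEFAULT_CATEGORICAL
    n = config.samples_per_stage
    groups = config.stage_names()

    summaries: dict[str, list[GroupSummary]] = {}
    for var, params in continuous.items():
        per_group = []
        for g in range(config.n_stages):
            mean, sd = params[g % len(params)]
            draws = rng.normal(mean, sd, n)
            per_group.append(
                GroupSummary(
                    mean=float(draws.mean()), sd=float(draws.std(ddof=1)), n=n
                )
            )
        summaries[var] = per_group

    tables: dict[str, ContingencyTable] = {}
    for var, probs in categorical.items():
        counts = np.empty((config.n_stages, 2), dtype=int)
        for g in range(config.n_stages):
            p = probs[g % len(probs)]
            k = int((rng.random(n) < p).sum())
            counts[g] = (k, n - k)
        tables[var] = ContingencyTable(
            counts=counts,
            row_labels=groups,
            col_labels=["yes", "no"],
        )
    return summaries, tables


def demo_config(n_genes: int, seed: int = 0) -> SimulationConfig:
    """A two-module demo layout scaled to any gene count: 30% + 20% of the
    genes in stage-correlated modules, 15% in the planted DNB group."""
    if n_genes < 20:
        raise ValueError("demo layout needs at least 20 genes")
    return SimulationConfig(
        n_genes=n_genes,
        module_sizes=[int(0.3 * n_genes), int(0.2 * n_genes)],
        module_trait_loadings=[0.7, -0.6],
        dnb_size=max(4, int(0.15 * n_genes)),
        seed=seed,
    )


def write_study(study: SimulatedStudy, outdir) -> None:
    """Write counts/FPKM TSVs, the sample sheet, and the truth JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    study.counts.counts.to_csv(outdir / "counts.tsv", sep="\t")
    study.expression.values.to_csv(outdir / "fpkm.tsv", sep="\t")
    meta = study.counts.gene_lengths.to_frame()
    meta.to_csv(outdir / "gene_lengths.tsv", sep="\t")
    study.sample_sheet.to_csv(outdir / "sample_sheet.tsv", sep="\t")
    truth = {
        "module_assignment": study.truth.module_assignment.to_dict(),
        "dnb_genes": sorted(study.truth.dnb_genes),
        "tipping_stage": study.truth.tipping_stage,
    }
    (outdir / "truth.json").write_text(json.dumps(truth, indent=1))
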