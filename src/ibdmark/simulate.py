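"""Synthetic IBD cohort generator.

Emulates the data substrate of a whole-blood prognostic-biomarker study:
a training cohort with two latent patient subgroups (IBD1 = poor prognosis,
IBD2 = good prognosis) visible in CD8 T cell transcriptomes, an attenuated
echo of the same structure in whole blood, triplicate qPCR Ct measurements
with stable reference genes, and clinical follow-up with subgroup-dependent
treatment-escalation hazards.

Expression model: Gaussian on the log2 scale. Genes are organised in
equicorrelated blocks (shared latent factor per block) to reproduce the
multicollinearity of real transcriptomes. Informative genes receive a mean
shift of ``effect_size`` log2 units in the IBD1 subgroup; the whole-blood
matrix carries the same shift scaled by ``wholeblood_attenuation``.

Clinical model: time to first treatment escalation is exponential with rate
``hazard_rate_good`` (IBD2) or ``hazard_rate_good * hazard_ratio`` (IBD1),
administratively censored at ``censor_time``; escalation counts within the
18-month horizon are Poisson with a rate ratio of ``escalation_rate_ratio``
between subgroups.

qPCR model: Ct = offset - slope * log2(expression) + noise, in triplicate,
ideal amplification efficiency (slope = 1 cycle per doubling) by default.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "SimulationConfig",
    "SyntheticCohort",
    "simulate_cohort",
    "simulate_escalations",
    "simulate_qpcr",
    "write_cohort",
]

#: Ordered therapy tiers, least to most aggressive.
THERAPY_TIERS = (
    "none",
    "immunomodulator",
    "anti-TNFa",
    "second-line biological",
    "surgery/colectomy",
)

HORIZON_18M_YEARS = 1.5


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic cohort.

    Defaults mirror the study conditions: 69 training samples split
    35 IBD1 / 34 IBD2, a few hundred measured genes of which a correlated
    minority separate the subgroups, a whole-blood signal attenuated to
    half the CD8 T cell effect, and an escalation hazard ratio of 2.65
    between subgroups with administrative censoring.
    """

    n_samples: int = 69
    n_genes: int = 500
    n_informative: int = 50
    n_blocks: int = 10
    effect_size: float = 1.0          # log2-units IBD1-vs-IBD2 shift (CD8 scale)
    wholeblood_attenuation: float = 0.5
    noise_sd: float = 0.5             # log2-units residual SD
    block_rho: float = 0.7            # within-block equicorrelation
    subgroup_proportion: float = 35 / 69   # fraction of samples in IBD1
    hazard_rate_good: float = 0.25    # escalations / year, IBD2
    hazard_ratio: float = 2.65
    censor_time: float = 3.0          # years
    escalation_rate_good: float = 0.6   # expected escalations in 18 m, IBD2
    escalation_rate_ratio: float = 3.0
    n_reference_genes: int = 3
    qpcr_noise_sd: float = 0.2        # cycles, replicate-level
    qpcr_slope: float = 1.0           # cycles per log2 unit
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_informative > self.n_genes:
            raise ValueError(
                f"n_informative ({self.n_informative}) exceeds n_genes ({self.n_genes})"
            )
        if not 0.0 < self.subgroup_proportion < 1.0:
            raise ValueError("subgroup_proportion must lie in (0, 1)")
        if self.hazard_ratio <= 0:
            raise ValueError("hazard_ratio must be > 0")
        for name in ("hazard_rate_good", "escalation_rate_good", "escalation_rate_ratio"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        for name in ("effect_size", "wholeblood_attenuation", "noise_sd",
                     "block_rho", "censor_time", "qpcr_noise_sd", "qpcr_slope"):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")
        if not 0.0 <= self.wholeblood_attenuation <= 1.0:
            raise ValueError("wholeblood_attenuation must lie in [0, 1]")


@dataclass
class SyntheticCohort:
    """All components share the same ordered sample identifiers."""

    cd8_expression: pd.DataFrame        # genes x samples, log2 scale
    wholeblood_expression: pd.DataFrame
    ct_table: pd.DataFrame              # long: sample_id, gene, replicate, ct
    clinical: pd.DataFrame              # per-sample follow-up
    true_labels: pd.Series              # "IBD1"/"IBD2" per sample
    informative_genes: list[str] = field(default_factory=list)
    reference_genes: list[str] = field(default_factory=list)
    config: SimulationConfig | None = None

    @property
    def sample_ids(self) -> list[str]:
        return list(self.cd8_expression.columns)


def _draw_labels(rng: np.random.Generator, cfg: SimulationConfig) -> np.ndarray:
    """Binary subgroup indicator (1 = IBD1) with expected fraction subgroup_proportion.

    Uses a randomised round of n * proportion so the realised split matches
    the configured cohort composition (e.g. 35/34 at n=69, p=35/69) while
    remaining binomial-consistent as n grows.
    """
    n1 = cfg.n_samples * cfg.subgroup_proportion
    n1_int = int(np.floor(n1))
    if rng.random() < (n1 - n1_int):
        n1_int += 1
    n1_int = min(max(n1_int, 0), cfg.n_samples)
    labels = np.zeros(cfg.n_samples, dtype=np.int64)
    labels[rng.choice(cfg.n_samples, size=n1_int, replace=False)] = 1
    return labels


def _expression_matrix(
    rng: np.random.Generator,
    cfg: SimulationConfig,
    labels: np.ndarray,
    effect: float,
    gene_ids: list[str],
    sample_ids: list[str],
) -> pd.DataFrame:
    """Gaussian expression with a planted subgroup shift and correlated
    informative blocks.

    Informative genes (the first ``n_informative``) are organised in
    ``n_blocks`` equicorrelated blocks — a shared latent factor per block —
    reproducing the multicollinearity among co-regulated signature genes
    that the penalised classifier must cope with:

        x_gj = baseline_g + effect * label_j
               + noise_sd * (sqrt(rho) * z_block(g),j + sqrt(1-rho) * eps_gj)

    Background genes are independent unit-variance noise around their
    baselines.
    """
    n, p = cfg.n_samples, cfg.n_genes
    # baseline abundance is a property of the gene, shared across cohorts:
    # drawn from a fixed stream so independently simulated cohorts agree
    baseline = np.random.default_rng(777).uniform(4.0, 12.0, size=p)
    z = rng.standard_normal((cfg.n_blocks, n))
    eps = rng.standard_normal((p, n))
    rho = cfg.block_rho
    values = baseline[:, None] + cfg.noise_sd * eps
    m = cfg.n_informative
    block_of = np.arange(m) % cfg.n_blocks
    values[:m] = (
        baseline[:m, None]
        + cfg.noise_sd * (math.sqrt(rho) * z[block_of] + math.sqrt(1.0 - rho) * eps[:m])
    )
    values[:m] += effect * labels[None, :]
    return pd.DataFrame(values, index=gene_ids, columns=sample_ids)


def simulate_escalations(
    labels: pd.Series, config: SimulationConfig, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """Simulate per-patient clinical course from subgroup labels.

    Time to first escalation is exponential; the IBD1 rate is
    ``hazard_rate_good * hazard_ratio``. Observations are censored at
    ``censor_time``. Escalation counts within 18 months are Poisson with
    rate ``escalation_rate_good`` (IBD2) scaled by ``escalation_rate_ratio``
    for IBD1. Therapy tier is the count truncated into the tier ladder;
    colectomy is confined to multiply-escalating IBD1 patients.
    """
    if len(labels) == 0:
        raise ValueError("empty label vector")
    levels = pd.unique(labels)
    if len(levels) > 2:
        raise ValueError(f"labels must have at most two levels, got {list(levels)}")
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)

    is_bad = np.asarray(labels == "IBD1", dtype=bool)
    n = len(labels)
    rate = np.where(is_bad, config.hazard_rate_good * config.hazard_ratio,
                    config.hazard_rate_good)
    latent_t = rng.exponential(1.0 / rate)
    event = (latent_t <= config.censor_time).astype(np.int64)
    time_years = np.minimum(latent_t, config.censor_time)

    count_rate = np.where(
        is_bad,
        config.escalation_rate_good * config.escalation_rate_ratio,
        config.escalation_rate_good,
    )
    n_esc = rng.poisson(count_rate)

    tier_idx = np.minimum(n_esc, len(THERAPY_TIERS) - 2)
    colectomy = (is_bad & (n_esc >= 2) & (rng.random(n) < 0.3)).astype(np.int64)
    tier_idx = np.where(colectomy == 1, len(THERAPY_TIERS) - 1, tier_idx)

    followup = np.full(n, config.censor_time, dtype=float)
    return pd.DataFrame(
        {
            "sample_id": labels.index,
            "time_years": time_years,
            "event": event,
            "n_escalations_18m": n_esc,
            "therapy_tier": [THERAPY_TIERS[i] for i in tier_idx],
            "colectomy": colectomy,
            "followup_years": followup,
        }
    ).set_index("sample_id", drop=False)


def simulate_qpcr(
    expression: pd.DataFrame,
    panel: list[str],
    plate_noise_sd: float = 0.2,
    slope: float = 1.0,
    offset: float = 40.0,
    n_replicates: int = 3,
    rng: np.random.Generator | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate triplicate qPCR Ct values for ``panel`` genes.

    Ct = offset - slope * log2(expression) + N(0, plate_noise_sd), so higher
    expression yields lower Ct and a doubling of linear expression lowers the
    mean Ct by ``slope`` cycles.
    """
    missing = [g for g in panel if g not in expression.index]
    if missing:
        raise KeyError(f"panel genes absent from expression matrix: {missing}")
    if rng is None:
        rng = np.random.default_rng(seed)
    sub = expression.loc[panel]
    records = []
    for gene, row in sub.iterrows():
        mean_ct = offset - slope * row.to_numpy()
        noise = rng.normal(0.0, plate_noise_sd, size=(n_replicates, len(row)))
        cts = mean_ct[None, :] + noise
        for rep in range(n_replicates):
            for s, ct in zip(row.index, cts[rep]):
                records.append((s, gene, rep + 1, ct))
    out = pd.DataFrame(records, columns=["sample_id", "gene", "replicate", "ct"])
    return out


def simulate_cohort(config: SimulationConfig) -> SyntheticCohort:
    """Generate a full synthetic cohort; deterministic for a fixed seed."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)

    sample_ids = [f"S{i + 1:03d}" for i in range(cfg.n_samples)]
    gene_ids = [f"G{i + 1:04d}" for i in range(cfg.n_genes)]
    ref_ids = [f"REF{i + 1}" for i in range(cfg.n_reference_genes)]

    labels01 = _draw_labels(rng, cfg)
    labels = pd.Series(
        np.where(labels01 == 1, "IBD1", "IBD2"), index=sample_ids, name="subgroup"
    )

    cd8 = _expression_matrix(rng, cfg, labels01, cfg.effect_size, gene_ids, sample_ids)
    wb = _expression_matrix(
        rng, cfg, labels01, cfg.effect_size * cfg.wholeblood_attenuation,
        gene_ids, sample_ids,
    )

    # stable reference genes: high, nearly constant expression on both
    # platforms; baselines fixed per gene (shared across cohorts)
    ref_base = np.random.default_rng(778).uniform(9.0, 11.0, size=cfg.n_reference_genes)
    ref_vals = ref_base[:, None] + 0.05 * rng.standard_normal(
        (cfg.n_reference_genes, cfg.n_samples)
    )
    ref_df = pd.DataFrame(ref_vals, index=ref_ids, columns=sample_ids)
    wb = pd.concat([wb, ref_df])
    cd8 = pd.concat([cd8, ref_df])

    clinical = simulate_escalations(labels, cfg, rng=rng)

    informative = gene_ids[: cfg.n_informative]
    default_panel = informative[: min(len(informative), 39)] + ref_ids
    ct = simulate_qpcr(
        wb, default_panel, plate_noise_sd=cfg.qpcr_noise_sd,
        slope=cfg.qpcr_slope, rng=rng,
    )

    return SyntheticCohort(
        cd8_expression=cd8,
        wholeblood_expression=wb,
        ct_table=ct,
        clinical=clinical,
        true_labels=labels,
        informative_genes=informative,
        reference_genes=ref_ids,
        config=cfg,
    )


def write_cohort(cohort: SyntheticCohort, out_dir: str | Path) -> None:
    """Write the cohort in the pipeline's on-disk dialects.

    Expression: TSV, rows = genes (first column gene ID), columns = samples.
    Clinical: CSV. Ct table: long-format CSV.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cohort.cd8_expression.to_csv(out / "cd8.tsv", sep="\t", index_label="gene")
    cohort.wholeblood_expression.to_csv(
        out / "wholeblood.tsv", sep="\t", index_label="gene"
    )
    cohort.ct_table.to_csv(out / "ct.csv", index=False)
    cohort.clinical.to_csv(out / "clinical.csv", index=False)
    cohort.true_labels.rename("subgroup").to_csv(out / "true_labels.csv", index_label="sample_id")
    if cohort.config is not None:
        import json

        (out / "config.json").write_text(json.dumps(asdict(cohort.config), indent=2))


def read_expression(path: str | Path) -> pd.DataFrame:
    """Read a genes-by-samples TSV written by :func:`write_cohort`."""
    return pd.read_csv(path, sep="\t", index_col=0)
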