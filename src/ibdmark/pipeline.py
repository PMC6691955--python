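"""End-to-end synthetic pipeline: simulate -> discover -> train -> translate
-> lock -> classify -> validate.

Runs the whole biomarker-development procedure on a synthetic training
cohort, locks the resulting qPCR classifier, then scores an independently
simulated validation cohort and quantifies prognostic separation there.
Everything is deterministic given (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score

from .consensus import ConsensusResult, assign_subgroup_names, consensus_cluster
from .lockdown import (
    CandidatePanel,
    LockedClassifier,
    classify_table,
    refit_on_qpcr,
    regularize_unscaled,
    select_candidate_panel,
)
from .loocv import LoocvReport, nested_loocv
from .penalized import (
    ModelGrid,
    PenalizedLogitResults,
    default_grid,
    fit_adaptive_grid,
    select_best_model,
)
from .quantify import correlation_filter, delta_ct_matrix, delta_delta_ct, standardize_features
from .simulate import SimulationConfig, SyntheticCohort, simulate_cohort, simulate_qpcr
from .survival import ConfusionAtHorizon, SurvivalComparison, compare_survival, confusion_at_horizon

__all__ = ["PipelineResult", "run_pipeline"]


@dataclass
class PipelineResult:
    cohort: SyntheticCohort
    discovery: ConsensusResult
    discovered_labels: pd.Series       # "IBD1"/"IBD2" from consensus clustering
    discovery_ari: float               # vs planted labels
    microarray_optimal: PenalizedLogitResults
    panel: CandidatePanel
    retained_panel: list[str]          # after microarray-qPCR correlation filter
    qpcr_optimal: PenalizedLogitResults
    classifier: LockedClassifier
    training_calls: pd.DataFrame
    validation_cohort: SyntheticCohort
    validation_calls: pd.DataFrame
    validation_survival: SurvivalComparison
    validation_confusion: ConfusionAtHorizon
    validation_agreement: float        # locked calls vs planted labels

    def summary(self) -> str:
        clf = self.classifier
        return "\n".join(
            [
                "End-to-end synthetic pipeline",
                "=" * 46,
                f"Discovery ARI vs planted subgroups: {self.discovery_ari:.3f}",
                f"Microarray optimal model: k={self.microarray_optimal.k}, "
                f"BIC={self.microarray_optimal.bic('standard'):.1f}",
                f"Candidate panel: {len(self.panel.informative)} informative + "
                f"{len(self.panel.reference_genes)} reference "
                f"({len(self.retained_panel)} retained after correlation filter)",
                f"qPCR optimal model: k={self.qpcr_optimal.k}",
                f"Locked classifier: {len(clf.informative_genes)} informative + "
                f"{len(clf.reference_genes)} reference genes",
                f"Validation: {self.validation_survival.summary()}",
                f"Validation confusion: {self.validation_confusion.summary()}",
                f"Validation call/planted-label agreement: "
                f"{self.validation_agreement:.3f}",
            ]
        )


def _calls_to_subgroups(calls: pd.DataFrame) -> pd.Series:
    s = calls.set_index("sample_id")["label"]
    return s.map({"IBDhi": "IBD1", "IBDlo": "IBD2"}).rename("subgroup")


def run_pipeline(
    config: SimulationConfig | None = None,
    seed: int = 0,
    grid: ModelGrid | None = None,
    n_lambda1: int = 14,
    n_lambda2: int = 5,
    consensus_resamples: int = 100,
    consensus_k_range: tuple[int, ...] = (2, 3, 4),
    panel_quotas: tuple[int, int, int] = (12, 6, 21),
    r_min: float = 0.5,
    run_loocv: bool = False,
) -> PipelineResult:
    """Run the full development-and-validation procedure on synthetic data.

    ``seed`` drives the training cohort; the validation cohort uses an
    offset seed so its patients are independent draws from the same
    population. The default hyperparameter grid is a reduced
    14 x 5 x 3 = 210-model grid; pass ``grid`` explicitly (e.g. the full
    2100-model ``default_grid``) to override.
    """
    if config is None:
        config = SimulationConfig()
    config = replace(config, seed=seed)
    cohort = simulate_cohort(config)

    # --- subgroup discovery on CD8 T cell transcriptomes ------------------
    cd8 = cohort.cd8_expression.drop(index=cohort.reference_genes)
    discovery = consensus_cluster(
        cd8,
        k_range=consensus_k_range,
        n_resamples=consensus_resamples,
        seed=seed + 101,
    )
    if discovery.chosen_k == 2:
        labels = assign_subgroup_names(discovery, cd8, cohort.informative_genes)
    else:
        # force a two-group cut for downstream training when PAC prefers k != 2
        forced = replace_k2(discovery)
        labels = assign_subgroup_names(forced, cd8, cohort.informative_genes)
    ari = float(adjusted_rand_score(cohort.true_labels, labels))

    # --- whole-blood microarray classifier --------------------------------
    wb = cohort.wholeblood_expression.drop(index=cohort.reference_genes)
    Xwb = wb.T  # samples x genes
    y = (labels == "IBD1").astype(float).reindex(Xwb.index)
    Xwb_std, _ = standardize_features(wb)
    Xwb_std = Xwb_std.T
    if grid is None:
        lambda2_values = tuple(np.geomspace(1e-3, 10.0, n_lambda2))
        grid = default_grid(
            Xwb_std.to_numpy(), y.to_numpy(),
            n_lambda1=n_lambda1, lambda2_values=lambda2_values,
        )
    models = fit_adaptive_grid(
        Xwb_std.to_numpy(), y.to_numpy(), grid, feature_names=list(Xwb_std.columns)
    )
    optimal = select_best_model(models)

    loocv_report: LoocvReport | None = None
    if run_loocv:
        loocv_report = nested_loocv(Xwb, y, grid)

    # --- qPCR candidate panel and measurement ------------------------------
    panel = select_candidate_panel(
        models, optimal, wb, cohort.reference_genes, quotas=panel_quotas
    )
    qpcr_rng = np.random.default_rng(seed + 202)
    ct = simulate_qpcr(
        cohort.wholeblood_expression, panel.all_genes,
        plate_noise_sd=config.qpcr_noise_sd, slope=config.qpcr_slope,
        rng=qpcr_rng,
    )
    rel = delta_delta_ct(ct, panel.reference_genes)
    retained, _report = correlation_filter(wb, rel, panel.informative, r_min=r_min)

    # --- qPCR-scale refit and unscaled lock-down ---------------------------
    dct = delta_ct_matrix(rel).loc[retained]
    dct_std, _ = standardize_features(dct)
    qpcr_optimal = refit_on_qpcr(dct_std.T, y.reindex(dct_std.columns), grid)
    active = qpcr_optimal.active_features
    if not active:  # fully shrunk null model: fall back to the retained panel
        active = retained
    classifier = regularize_unscaled(
        dct.loc[active].T, y.reindex(dct.columns), panel.reference_genes,
        seed=seed + 303,
    )

    training_calls = classify_table(classifier, ct)

    # --- independent validation cohort -------------------------------------
    vconfig = replace(config, seed=seed + 10_007)
    vcohort = simulate_cohort(vconfig)
    vct = simulate_qpcr(
        vcohort.wholeblood_expression,
        classifier.informative_genes + classifier.reference_genes,
        plate_noise_sd=config.qpcr_noise_sd, slope=config.qpcr_slope,
        rng=np.random.default_rng(seed + 404),
    )
    vcalls = classify_table(classifier, vct)
    vsub = _calls_to_subgroups(vcalls)
    surv = compare_survival(vcohort.clinical, vsub)
    conf = confusion_at_horizon(vcalls, vcohort.clinical)
    truth = vcohort.true_labels.reindex(vsub.index)
    agreement = float((vsub == truth).mean())

    result = PipelineResult(
        cohort=cohort,
        discovery=discovery,
        discovered_labels=labels,
        discovery_ari=ari,
        microarray_optimal=optimal,
        panel=panel,
        retained_panel=retained,
        qpcr_optimal=qpcr_optimal,
        classifier=classifier,
        training_calls=training_calls,
        validation_cohort=vcohort,
        validation_calls=vcalls,
        validation_survival=surv,
        validation_confusion=conf,
        validation_agreement=agreement,
    )
    if loocv_report is not None:
        result.loocv_report = loocv_report  # type: ignore[attr-defined]
    return result


def replace_k2(result: ConsensusResult) -> ConsensusResult:
    """Re-cut a consensus result at k=2 (used when PAC chose a different k)."""
    from scipy.cluster.hierarchy import fcluster, linkage
    from scipy.spatial.distance import squareform

    M = result.consensus_by_k.get(2)
    if M is None:
        M = result.consensus_matrix.to_numpy()
    dist = 1.0 - M
    np.fill_diagonal(dist, 0.0)
    Z = linkage(squareform(dist, checks=False), method="average")
    labels = fcluster(Z, t=2, criterion="maxclust")
    sample_ids = list(result.consensus_matrix.columns)
    return ConsensusResult(
        consensus_matrix=pd.DataFrame(M, index=sample_ids, columns=sample_ids),
        chosen_k=2,
        labels=pd.Series(labels, index=sample_ids, name="cluster"),
        k_scores=result.k_scores,
        consensus_by_k=result.consensus_by_k,
    )
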