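"""Translation of a microarray-selected signature to a locked qPCR classifier.

Stages mirror a clinical-assay development path:

1. ``select_candidate_panel`` — assemble a qPCR candidate panel from the
   BIC-optimal microarray model (all its genes), genes highly correlated
   with them, and recurrent genes from lower-ranked candidate models.
2. ``refit_on_qpcr`` — rerun the full adaptive elastic-net + BIC strategy
   on standardised ΔCt features.
3. ``regularize_unscaled`` — a final round of cross-validated penalised
   logistic regression on *unscaled* ΔCt features (a prerequisite for
   clinical deployment, where per-cohort standardisation is unavailable),
   selecting the most-regularised model within one standard error of the
   minimum mean CV misclassification error, then locking the refitted
   model with a tamper-evident checksum.
4. ``classify_sample`` — score new samples with the locked model at the
   0.5 probability cut-off; boundary probability is assigned to the
   high-risk side (conservative: flags the patient for closer monitoring).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .penalized import (
    ModelGrid,
    PenalizedLogit,
    PenalizedLogitResults,
    fit_adaptive_grid,
    lambda1_max,
    select_best_model,
)
from .quantify import delta_ct_matrix, delta_delta_ct

__all__ = [
    "CandidatePanel",
    "select_candidate_panel",
    "refit_on_qpcr",
    "regularize_unscaled",
    "LockedClassifier",
    "classify_sample",
    "classify_table",
]


@dataclass
class CandidatePanel:
    """qPCR candidate panel, partitioned by provenance; lists are disjoint."""

    from_optimal: list[str]
    correlated_additions: list[str]
    from_suboptimal_models: list[str]
    reference_genes: list[str]

    @property
    def informative(self) -> list[str]:
        return self.from_optimal + self.correlated_additions + self.from_suboptimal_models

    @property
    def all_genes(self) -> list[str]:
        return self.informative + self.reference_genes


def select_candidate_panel(
    models: list[PenalizedLogitResults],
    optimal: PenalizedLogitResults,
    microarray: pd.DataFrame,
    reference_genes: list[str],
    quotas: tuple[int, int, int] = (12, 6, 21),
    r_corr_min: float = 0.8,
    convention: str = "standard",
) -> CandidatePanel:
    """Assemble the candidate panel for qPCR optimisation.

    Category 1: every nonzero gene of the optimal model (capped at the first
    quota in coefficient-magnitude order). Category 2: genes most correlated
    (|r| >= ``r_corr_min``) with category-1 genes, best first. Category 3:
    most-frequent nonzero genes among the remaining candidate models, best
    first. A shortfall in one category is filled from the next; the panel is
    deterministic given its inputs.
    """
    n_opt, n_corr, n_sub = quotas
    coef = optimal.coef_series()
    opt_genes = coef[coef != 0].abs().sort_values(ascending=False).index.tolist()
    from_optimal = opt_genes[:n_opt]
    shortfall = max(0, n_opt - len(from_optimal))

    taken = set(from_optimal) | set(reference_genes)

    # category 2: correlation with optimal-model genes on the microarray
    corr_candidates: list[tuple[float, str]] = []
    pool = [g for g in microarray.index if g not in taken]
    if from_optimal and pool:
        sub = microarray.loc[from_optimal].to_numpy(dtype=float)
        rest = microarray.loc[pool].to_numpy(dtype=float)
        sub_c = sub - sub.mean(axis=1, keepdims=True)
        rest_c = rest - rest.mean(axis=1, keepdims=True)
        sub_n = sub_c / np.linalg.norm(sub_c, axis=1, keepdims=True)
        denom = np.linalg.norm(rest_c, axis=1, keepdims=True)
        denom[denom == 0] = np.inf
        rest_n = rest_c / denom
        r = rest_n @ sub_n.T  # pool x optimal
        best_r = np.max(np.abs(r), axis=1)
        for g, v in zip(pool, best_r):
            if v >= r_corr_min:
                corr_candidates.append((float(v), g))
    corr_candidates.sort(key=lambda t: (-t[0], t[1]))
    correlated = [g for _, g in corr_candidates[: n_corr + shortfall]]
    taken |= set(correlated)
    shortfall = max(0, n_corr + shortfall - len(correlated))

    # category 3: nonzero frequency among lower-ranked models (ties: mean |coef|)
    freq: dict[str, int] = {}
    mag: dict[str, float] = {}
    for m in models:
        if m is optimal:
            continue
        for g, b in zip(m.model.feature_names, m.params):
            if b != 0.0 and g not in taken:
                freq[g] = freq.get(g, 0) + 1
                mag[g] = mag.get(g, 0.0) + abs(float(b))
    ranked = sorted(freq, key=lambda g: (-freq[g], -mag[g], g))
    from_sub = ranked[: n_sub + shortfall]

    return CandidatePanel(
        from_optimal=from_optimal,
        correlated_additions=correlated,
        from_suboptimal_models=from_sub,
        reference_genes=list(reference_genes),
    )


def refit_on_qpcr(
    qpcr_features: pd.DataFrame,
    labels: pd.Series,
    grid: ModelGrid,
    convention: str = "standard",
) -> PenalizedLogitResults:
    """Adaptive elastic-net grid + BIC selection on standardised ΔCt features.

    ``qpcr_features``: samples x genes, already standardised. Identical
    machinery to the microarray stage, applied to the qPCR scale.
    """
    models = fit_adaptive_grid(
        qpcr_features, labels, grid, feature_names=list(qpcr_features.columns)
    )
    return select_best_model(models, convention=convention)


def _stratified_folds(y: np.ndarray, n_folds: int, rng: np.random.Generator) -> list[np.ndarray]:
    """Deterministic stratified fold assignment; returns test-index arrays."""
    folds: list[list[int]] = [[] for _ in range(n_folds)]
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        rng.shuffle(idx)
        for pos, i in enumerate(idx):
            folds[pos % n_folds].append(int(i))
    return [np.array(sorted(f), dtype=int) for f in folds]


def regularize_unscaled(
    qpcr_features_unscaled: pd.DataFrame,
    labels: pd.Series,
    reference_genes: list[str],
    n_folds: int = 10,
    n_lambda: int = 30,
    lambda_min_ratio: float = 1e-2,
    lambda2: float = 1e-4,
    seed: int = 0,
    label_hi: str = "IBDhi",
    label_lo: str = "IBDlo",
) -> "LockedClassifier":
    """Cross-validated re-regularisation on unscaled ΔCt features; 1-SE rule.

    A lasso-dominated path (small fixed ridge term for uniqueness) is fit on
    the raw ΔCt matrix; mean misclassification error is estimated by
    stratified ``n_folds``-fold CV; the largest penalty whose mean CV error
    is within one standard error of the minimum is chosen; the model is
    refit on all data at that penalty and locked.
    """
    X = qpcr_features_unscaled.to_numpy(dtype=float)
    y = np.asarray(labels, dtype=float).ravel()
    n = len(y)
    names = list(qpcr_features_unscaled.columns)

    lmax = lambda1_max(X, y)
    path = np.geomspace(lmax, lmax * lambda_min_ratio, n_lambda)

    rng = np.random.default_rng(seed)
    folds = _stratified_folds(y, n_folds, rng)
    for f in folds:
        tr_y = np.delete(y, f)
        if len(np.unique(tr_y)) < 2 or len(f) == 0:
            raise ValueError("degenerate CV fold (single class or empty)")

    err = np.zeros((n_folds, n_lambda))
    for fi, test_idx in enumerate(folds):
        mask = np.ones(n, dtype=bool)
        mask[test_idx] = False
        model = PenalizedLogit(y[mask], X[mask], feature_names=names)
        warm = None
        for li, l1 in enumerate(path):
            # CV only needs the misclassification decision; a looser
            # tolerance here does not affect the selected penalty
            res = model.fit(
                l1, lambda2, tol=1e-6, max_iter=20_000,
                start_params=None if warm is None else warm[0],
                start_intercept=None if warm is None else warm[1],
            )
            warm = (res.params, res.intercept)
            prob = res.predict(X[test_idx])
            calls = (prob >= 0.5).astype(float)
            err[fi, li] = float(np.mean(calls != y[test_idx]))

    mean_err = err.mean(axis=0)
    se_err = err.std(axis=0, ddof=1) / np.sqrt(n_folds)
    i_min = int(np.argmin(mean_err))
    cutoff = mean_err[i_min] + se_err[i_min]
    # path is descending in penalty; the smallest index within 1 SE is the
    # most-regularised admissible model
    i_1se = int(np.flatnonzero(mean_err <= cutoff)[0])

    full = PenalizedLogit(y, X, feature_names=names)
    warm = None
    final = None
    k_at_min = None
    for li, l1 in enumerate(path):
        res = full.fit(
            l1, lambda2,
            start_params=None if warm is None else warm[0],
            start_intercept=None if warm is None else warm[1],
        )
        warm = (res.params, res.intercept)
        if li == i_1se:
            final = res
        if li == i_min:
            k_at_min = res.k
        if li >= max(i_1se, i_min):
            break
    assert final is not None

    coef = final.coef_series()
    active = coef[coef != 0]
    return LockedClassifier(
        informative_genes=list(active.index),
        reference_genes=list(reference_genes),
        beta=[float(b) for b in active.values],
        intercept=float(final.intercept),
        threshold=0.5,
        label_hi=label_hi,
        label_lo=label_lo,
        version="1.0",
        provenance={
            "lambda1": float(path[i_1se]),
            "lambda2": float(lambda2),
            "n_folds": n_folds,
            "seed": seed,
            "cv_mean_error_at_lambda": float(mean_err[i_1se]),
            "cv_min_mean_error": float(mean_err[i_min]),
            "k_at_cv_min": k_at_min,
            "one_se_cutoff": float(cutoff),
            "n_training_samples": int(n),
        },
    )


def _checksum(payload: dict) -> str:
    body = json.dumps(payload, sort_keys=True, separators=(",", ":"))
    return hashlib.sha256(body.encode()).hexdigest()


@dataclass(frozen=True)
class LockedClassifier:
    """Immutable final qPCR classifier on unscaled ΔCt features.

    ``beta`` is ordered like ``informative_genes``; the decision threshold
    is fixed at probability 0.5 with the boundary assigned to ``label_hi``.
    The checksum covers every numeric and naming field, so any mutation of
    a serialised classifier is detected on load.
    """

    informative_genes: list[str]
    reference_genes: list[str]
    beta: list[float]
    intercept: float
    threshold: float
    label_hi: str
    label_lo: str
    version: str
    provenance: dict = field(default_factory=dict)

    def _payload(self) -> dict:
        return {
            "informative_genes": list(self.informative_genes),
            "reference_genes": list(self.reference_genes),
            "beta": [float(b) for b in self.beta],
            "intercept": float(self.intercept),
            "threshold": float(self.threshold),
            "label_hi": self.label_hi,
            "label_lo": self.label_lo,
            "version": self.version,
        }

    @property
    def checksum(self) -> str:
        return _checksum(self._payload())

    @property
    def n_genes(self) -> int:
        """Total panel size (informative + reference genes)."""
        return len(self.informative_genes) + len(self.reference_genes)

    def to_json(self, path=None) -> str:
        doc = self._payload()
        doc["checksum"] = self.checksum
        doc["provenance"] = self.provenance
        text = json.dumps(doc, indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, source: str) -> "LockedClassifier":
        """Load and verify; raises ValueError if the checksum does not match."""
        try:
            doc = json.loads(source)
        except json.JSONDecodeError:
            with open(source) as fh:
                doc = json.load(fh)
        stored = doc.pop("checksum", None)
        provenance = doc.pop("provenance", {})
        clf = cls(provenance=provenance, **doc)
        if stored != clf.checksum:
            raise ValueError(
                "locked-classifier checksum mismatch: content was modified"
            )
        return clf

    def decision_scores(self, delta_ct: pd.DataFrame) -> pd.Series:
        """Linear score per sample from a genes x samples ΔCt matrix."""
        missing = [g for g in self.informative_genes if g not in delta_ct.index]
        if missing:
            raise KeyError(f"classifier gene(s) missing from ΔCt features: {missing}")
        Xm = delta_ct.loc[self.informative_genes].to_numpy(dtype=float)
        return pd.Series(
            np.asarray(self.beta) @ Xm + self.intercept, index=delta_ct.columns
        )


def classify_table(clf: LockedClassifier, ct: pd.DataFrame) -> pd.DataFrame:
    """Score every sample in a long-format Ct table with a locked classifier.

    Returns columns sample_id, probability, label, no_call_reason. A sample
    missing any classifier gene gets a no-call naming the gene rather than a
    silent default.
    """
    results = []
    present = ct.groupby("sample_id")["gene"].apply(set)
    needed = set(clf.informative_genes) | set(clf.reference_genes)
    callable_samples = []
    for s, genes in present.items():
        missing = needed - genes
        if missing:
            results.append((s, np.nan, "no-call", f"missing gene(s): {sorted(missing)}"))
        else:
            callable_samples.append(s)
    if callable_samples:
        sub = ct[ct["sample_id"].isin(callable_samples)]
        rel = delta_delta_ct(sub, clf.reference_genes)
        dct = delta_ct_matrix(rel)
        score = clf.decision_scores(dct)
        prob = 1.0 / (1.0 + np.exp(-score))
        for s in callable_samples:
            p = float(prob[s])
            lab = clf.label_hi if p >= clf.threshold else clf.label_lo
            results.append((s, p, lab, ""))
    out = pd.DataFrame(
        results, columns=["sample_id", "probability", "label", "no_call_reason"]
    )
    return out.sort_values("sample_id").reset_index(drop=True)


def classify_sample(clf: LockedClassifier, ct_one_sample: pd.DataFrame) -> dict:
    """Risk call for a single sample's Ct measurements.

    Returns {"sample_id", "probability", "label"}; raises KeyError naming
    the gene if any classifier gene is absent.
    """
    samples = ct_one_sample["sample_id"].unique()
    if len(samples) != 1:
        raise ValueError("classify_sample expects exactly one sample")
    needed = set(clf.informative_genes) | set(clf.reference_genes)
    missing = needed - set(ct_one_sample["gene"])
    if missing:
        raise KeyError(f"no-call: missing gene(s) {sorted(missing)}")
    row = classify_table(clf, ct_one_sample).iloc[0]
    return {
        "sample_id": row["sample_id"],
        "probability": float(row["probability"]),
        "label": row["label"],
    }
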