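"""Candidate-panel assembly, 1-SE re-regularisation, lock-down and scoring."""

import json

import numpy as np
import pandas as pd
import pytest

from ibdmark import (
    LockedClassifier,
    ModelGrid,
    PenalizedLogit,
    classify_sample,
    classify_table,
    refit_on_qpcr,
    regularize_unscaled,
    select_candidate_panel,
    simulate_qpcr,
    standardize_features,
)
from ibdmark.quantify import delta_ct_matrix, delta_delta_ct
from conftest import make_ct_table


def _result_with(model, coefs):
    """A PenalizedLogitResults with prescribed coefficients (panel logic
    reads only the coefficient pattern, so the fit itself is irrelevant)."""
    from ibdmark import PenalizedLogitResults

    params = np.zeros(len(model.feature_names))
    for name, b in coefs.items():
        params[model.feature_names.index(name)] = b
    return PenalizedLogitResults(
        model=model, params=params, intercept=0.0,
        lambda1=0.1, lambda2=0.1, gamma=1.0,
        l1_weights=np.ones(len(params)), llf=-10.0, objective=0.5,
        n_iter=10, converged=True,
    )


def _panel_inputs(seed=0, n=30):
    """Handcrafted model stack: 3 optimal genes, 2 genes correlated with
    them (r ~ 0.99), and recurrent genes in lower-ranked models."""
    rng = np.random.default_rng(seed)
    names = ["o1", "o2", "o3", "c1", "c2"] + [f"s{j}" for j in range(7)]
    data = {nm: rng.standard_normal(n) for nm in names}
    data["c1"] = data["o1"] + 0.05 * rng.standard_normal(n)
    data["c2"] = data["o2"] + 0.05 * rng.standard_normal(n)
    micro = pd.DataFrame(data).T
    micro.columns = [f"smp{i}" for i in range(n)]

    X = micro.T.to_numpy()
    y = np.array([0.0, 1.0] * (n // 2))
    base = PenalizedLogit(y, (X - X.mean(0)) / X.std(0, ddof=1),
                          feature_names=names)
    optimal = _result_with(base, {"o1": 1.0, "o2": -0.8, "o3": 0.5})
    subs = [
        _result_with(base, {"o1": 0.9, "s0": 0.4, "s1": 0.3}),
        _result_with(base, {"s0": 0.5, "s2": 0.2}),
        _result_with(base, {"s0": 0.1, "s1": 0.2, "s3": 0.3}),
    ]
    return [optimal] + subs, optimal, micro


class TestCandidatePanel:
    def test_quota_partition(self):
        models, optimal, micro = _panel_inputs()
        panel = select_candidate_panel(models, optimal, micro, ["REF1"],
                                       quotas=(3, 2, 4), r_corr_min=0.8)
        assert set(panel.from_optimal) == {"o1", "o2", "o3"}
        assert set(panel.correlated_additions) == {"c1", "c2"}
        assert len(panel.from_suboptimal_models) == 4
        assert panel.from_suboptimal_models[0] == "s0"  # most recurrent first
        # the three informative lists are disjoint
        lists = [set(panel.from_optimal), set(panel.correlated_additions),
                 set(panel.from_suboptimal_models)]
        assert not (lists[0] & lists[1] or lists[0] & lists[2] or lists[1] & lists[2])
        assert len(panel.informative) == 3 + 2 + 4

    def test_unattainable_correlation_falls_through_to_suboptimal(self):
        models, optimal, micro = _panel_inputs()
        panel = select_candidate_panel(models, optimal, micro, ["REF1"],
                                       quotas=(3, 2, 2), r_corr_min=1.0)
        assert panel.correlated_additions == []
        assert len(panel.from_suboptimal_models) == 4  # shortfall absorbed

    def test_deterministic(self):
        models, optimal, micro = _panel_inputs()
        p1 = select_candidate_panel(models, optimal, micro, ["REF1"],
                                    quotas=(3, 2, 4), r_corr_min=0.8)
        p2 = select_candidate_panel(models, optimal, micro, ["REF1"],
                                    quotas=(3, 2, 4), r_corr_min=0.8)
        assert p1.informative == p2.informative
        assert p1.reference_genes == p2.reference_genes


class TestRefitOnQpcr:
    def test_null_labels_select_empty_model(self, rng):
        n, p = 40, 12
        X = rng.standard_normal((n, p))
        feats = pd.DataFrame((X - X.mean(0)) / X.std(0, ddof=1),
                             columns=[f"g{j}" for j in range(p)])
        y = pd.Series([0.0, 1.0] * (n // 2))
        grid = ModelGrid(triples=tuple((l1, 0.1, 1.0)
                                       for l1 in (0.5, 0.25, 0.12)))
        best = refit_on_qpcr(feats, y, grid)
        assert best.k == 0
        assert best.llf <= 0
        assert np.isfinite(best.bic("standard"))


class TestRegularizeUnscaled:
    def _signal_features(self, seed=1, n=60, p=10):
        rng = np.random.default_rng(seed)
        y = np.array([0.0, 1.0] * (n // 2))
        X = rng.standard_normal((n, p)) + 2.0 * y[:, None] * (np.arange(p) < 4)
        return pd.DataFrame(X, columns=[f"g{j}" for j in range(p)]), pd.Series(y)

    def test_one_se_model_is_sparser_than_cv_minimum(self):
        feats, y = self._signal_features()
        clf = regularize_unscaled(feats, y, ["REF1"], n_folds=5, seed=2)
        k_lock = len(clf.informative_genes)
        assert 0 < k_lock <= feats.shape[1]
        assert k_lock <= clf.provenance["k_at_cv_min"]
        assert clf.provenance["cv_mean_error_at_lambda"] <= (
            clf.provenance["one_se_cutoff"] + 1e-12
        )

    def test_lock_is_deterministic(self):
        feats, y = self._signal_features()
        a = regularize_unscaled(feats, y, ["REF1"], n_folds=5, seed=2)
        b = regularize_unscaled(feats, y, ["REF1"], n_folds=5, seed=2)
        assert a.checksum == b.checksum


class TestLockedClassifier:
    def _toy_classifier(self):
        return LockedClassifier(
            informative_genes=["gA", "gB", "gC"],
            reference_genes=["ref1"],
            beta=[0.8, -1.2, 0.4],
            intercept=0.3,
            threshold=0.5,
            label_hi="IBDhi",
            label_lo="IBDlo",
            version="1.0",
        )

    def test_checksum_round_trip(self, tmp_path):
        clf = self._toy_classifier()
        path = tmp_path / "clf.json"
        clf.to_json(path)
        loaded = LockedClassifier.from_json(str(path))
        assert loaded == clf

    def test_tampered_coefficient_detected(self, tmp_path):
        clf = self._toy_classifier()
        path = tmp_path / "clf.json"
        clf.to_json(path)
        doc = json.loads(path.read_text())
        doc["beta"][0] = 0.9
        path.write_text(json.dumps(doc))
        with pytest.raises(ValueError, match="checksum"):
            LockedClassifier.from_json(str(path))

    def test_hand_computed_logistic_score(self):
        """Three-gene toy coefficients match the closed-form logistic."""
        clf = self._toy_classifier()
        ct = make_ct_table([
            ("s1", "gA", [26.0] * 3),   # dCt = 1
            ("s1", "gB", [27.0] * 3),   # dCt = 2
            ("s1", "gC", [24.0] * 3),   # dCt = -1
            ("s1", "ref1", [25.0] * 3),
        ])
        call = classify_sample(clf, ct)
        score = 0.3 + 0.8 * 1 + (-1.2) * 2 + 0.4 * (-1)
        expected = 1 / (1 + np.exp(-score))
        assert call["probability"] == pytest.approx(expected, abs=1e-12)
        assert call["label"] == ("IBDhi" if expected >= 0.5 else "IBDlo")

    def test_boundary_probability_is_high_risk(self):
        clf = LockedClassifier(
            informative_genes=["gA"], reference_genes=["ref1"],
            beta=[0.0], intercept=0.0, threshold=0.5,
            label_hi="IBDhi", label_lo="IBDlo", version="1.0",
        )
        ct = make_ct_table([("s1", "gA", [25.0] * 3),
                            ("s1", "ref1", [25.0] * 3)])
        call = classify_sample(clf, ct)
        assert call["probability"] == pytest.approx(0.5)
        assert call["label"] == "IBDhi"

    def test_intercept_only_probability(self):
        clf = LockedClassifier(
            informative_genes=["gA"], reference_genes=["ref1"],
            beta=[0.0], intercept=1.0, threshold=0.5,
            label_hi="IBDhi", label_lo="IBDlo", version="1.0",
        )
        ct = make_ct_table([("s1", "gA", [21.0] * 3),
                            ("s1", "ref1", [25.0] * 3)])
        call = classify_sample(clf, ct)
        assert call["probability"] == pytest.approx(1 / (1 + np.exp(-1.0)), abs=1e-12)

    def test_plate_shift_invariance_of_calls(self):
        clf = self._toy_classifier()
        records = [("s1", "gA", [26.0, 26.1, 25.9]),
                   ("s1", "gB", [27.0] * 3),
                   ("s1", "gC", [24.0] * 3),
                   ("s1", "ref1", [25.0] * 3)]
        ct = make_ct_table(records)
        shifted = ct.copy()
        shifted["ct"] += 3.7
        a = classify_sample(clf, ct)
        b = classify_sample(clf, shifted)
        assert b["probability"] == pytest.approx(a["probability"], abs=1e-9)

    def test_missing_gene_is_named_no_call(self):
        clf = self._toy_classifier()
        ct = make_ct_table([("s1", "gA", [26.0] * 3),
                            ("s1", "ref1", [25.0] * 3)])
        with pytest.raises(KeyError, match="gB"):
            classify_sample(clf, ct)
        table = classify_table(clf, ct)
        assert table.iloc[0]["label"] == "no-call"
        assert "gB" in table.iloc[0]["no_call_reason"]
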