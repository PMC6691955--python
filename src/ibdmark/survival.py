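"""Prognostic validation: survival separation, escalation counts, confusion
matrices at a clinical horizon, and risk-ratio statistics.

Kaplan-Meier estimation, the log-rank test and the Cox proportional-hazards
model (Efron tie handling, Wald intervals) are provided by lifelines;
Fisher's exact test and the Mann-Whitney test by scipy — each wrapped here
with the contracts the pipeline relies on (shapes, error handling, exact
small-sample behaviour) and cross-checked against independent oracles in
the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import sqrt

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank
from scipy import stats

__all__ = [
    "kaplan_meier",
    "logrank_test",
    "cox_hr",
    "SurvivalComparison",
    "compare_survival",
    "ConfusionAtHorizon",
    "confusion_at_horizon",
    "relative_risk",
    "fisher_exact_2x2",
    "mann_whitney",
]


def kaplan_meier(times, events) -> pd.DataFrame:
    """Product-limit survival estimate.

    Returns a step function as a frame with columns time, at_risk, survival.
    Censored observations leave the curve flat and only reduce the risk set.
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    if t.shape != e.shape:
        raise ValueError("times and events must have equal length")
    if np.any(t < 0):
        raise ValueError("negative survival time")
    kmf = KaplanMeierFitter()
    kmf.fit(t, event_observed=e)
    surv = kmf.survival_function_["KM_estimate"]
    at_risk = kmf.event_table["at_risk"].reindex(surv.index)
    return pd.DataFrame(
        {"time": surv.index.to_numpy(), "at_risk": at_risk.to_numpy(),
         "survival": surv.to_numpy()}
    ).reset_index(drop=True)


def logrank_test(times, events, groups) -> tuple[float, float]:
    """Two-group one-degree-of-freedom log-rank test -> (chi2, p)."""
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    g = np.asarray(groups)
    levels = np.unique(g)
    if len(levels) != 2:
        raise ValueError(f"log-rank test requires exactly two groups, got {len(levels)}")
    a = g == levels[0]
    res = _ll_logrank(t[a], t[~a], event_observed_A=e[a], event_observed_B=e[~a])
    return float(res.test_statistic), float(res.p_value)


def cox_hr(times, events, group_indicator) -> tuple[float, float, float, float]:
    """Cox proportional-hazards fit for a single binary covariate.

    Partial-likelihood maximisation with Efron tie handling; returns
    (hr, ci_low, ci_high, p) with a Wald 95% interval on the log scale.
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    x = np.asarray(group_indicator, dtype=float)
    if set(np.unique(x)) - {0.0, 1.0}:
        raise ValueError("group_indicator must be binary 0/1")
    for v in (0.0, 1.0):
        if e[x == v].sum() < 1:
            raise ValueError("each group needs at least one event")
    df = pd.DataFrame({"time": t, "event": e, "group": x})
    cph = CoxPHFitter()
    cph.fit(df, duration_col="time", event_col="event")
    beta = float(cph.params_["group"])
    se = float(cph.standard_errors_["group"])
    p = float(cph.summary.loc["group", "p"])
    z = stats.norm.ppf(0.975)
    return float(np.exp(beta)), float(np.exp(beta - z * se)), float(np.exp(beta + z * se)), p


@dataclass
class SurvivalComparison:
    km_curves: dict[str, pd.DataFrame]
    logrank_chi2: float
    logrank_p: float
    hr: float
    hr_ci: tuple[float, float]
    hr_p: float
    groups: tuple[str, str]  # (reference, comparison); hr is comparison vs reference

    def summary(self) -> str:
        lo, hi = self.hr_ci
        return (
            f"{self.groups[1]} vs {self.groups[0]}: HR={self.hr:.2f} "
            f"(95% CI {lo:.2f} to {hi:.2f}; p={self.hr_p:.3g}); "
            f"log-rank chi2={self.logrank_chi2:.2f}, p={self.logrank_p:.3g}"
        )

    def plot_km(self, ax=None, censor_at: float | None = 1.5):
        """Step plot of escalation-free survival per group.

        ``censor_at`` truncates the *display* at the given horizon
        (administrative censoring for presentation only; tests always use
        the full follow-up). Returns the matplotlib axes.
        """
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        for name, curve in self.km_curves.items():
            t = np.concatenate([[0.0], curve["time"].to_numpy()])
            s = np.concatenate([[1.0], curve["survival"].to_numpy()])
            if censor_at is not None:
                keep = t <= censor_at
                t, s = t[keep], s[keep]
                t = np.append(t, censor_at)
                s = np.append(s, s[-1])
            ax.step(t, s, where="post", label=str(name))
        ax.set_xlabel("years since enrolment")
        ax.set_ylabel("escalation-free survival")
        ax.set_ylim(0, 1.02)
        ax.legend()
        return ax


def compare_survival(
    clinical: pd.DataFrame, labels: pd.Series, reference_label: str | None = None
) -> SurvivalComparison:
    """KM curves, log-rank test and Cox HR between two labelled groups.

    ``clinical`` needs columns time_years and event, indexed by sample;
    ``labels`` assigns each sample to one of two groups. The hazard ratio is
    for the non-reference group relative to ``reference_label`` (default:
    lexicographically last label, so IBDhi-vs-IBDlo and IBD1-vs-IBD2 come
    out with the poor-prognosis group in the numerator).
    """
    lab = labels.reindex(clinical.index)
    levels = sorted(pd.unique(lab.dropna()))
    if len(levels) != 2:
        raise ValueError("compare_survival requires exactly two groups")
    if reference_label is None:
        reference_label = levels[-1]
    other = [l for l in levels if l != reference_label][0]

    t = clinical["time_years"].to_numpy(dtype=float)
    e = clinical["event"].to_numpy(dtype=int)
    chi2, p = logrank_test(t, e, lab.to_numpy())
    x = (lab == other).to_numpy(dtype=float)
    hr, lo, hi, hr_p = cox_hr(t, e, x)
    curves = {
        lev: kaplan_meier(t[(lab == lev).to_numpy()], e[(lab == lev).to_numpy()])
        for lev in levels
    }
    return SurvivalComparison(
        km_curves=curves, logrank_chi2=chi2, logrank_p=p,
        hr=hr, hr_ci=(lo, hi), hr_p=hr_p,
        groups=(reference_label, other),
    )


@dataclass
class ConfusionAtHorizon:
    horizon: float
    min_escalations: int
    tp: int
    fp: int
    tn: int
    fn: int
    n_excluded: int

    @property
    def n_evaluable(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    def _ratio(self, num: int, den: int) -> float:
        return num / den if den > 0 else float("nan")

    @property
    def sensitivity(self) -> float:
        return self._ratio(self.tp, self.tp + self.fn)

    @property
    def specificity(self) -> float:
        return self._ratio(self.tn, self.tn + self.fp)

    @property
    def ppv(self) -> float:
        return self._ratio(self.tp, self.tp + self.fp)

    @property
    def npv(self) -> float:
        return self._ratio(self.tn, self.tn + self.fn)

    def summary(self) -> str:
        def fmt(v, den):
            return f"{100 * v:.1f}% (n={den})" if den > 0 else f"undefined (n=0)"

        return (
            f"Horizon {self.horizon} y, >= {self.min_escalations} escalations: "
            f"sensitivity {fmt(self.sensitivity, self.tp + self.fn)}, "
            f"specificity {fmt(self.specificity, self.tn + self.fp)}, "
            f"PPV {fmt(self.ppv, self.tp + self.fp)}, "
            f"NPV {fmt(self.npv, self.tn + self.fn)}; "
            f"{self.n_excluded} excluded"
        )


def confusion_at_horizon(
    calls: pd.DataFrame,
    clinical: pd.DataFrame,
    horizon: float = 1.5,
    min_escalations: int = 2,
    positive_label: str = "IBDhi",
) -> ConfusionAtHorizon:
    """Confusion matrix of classifier calls against multiple escalations.

    Positive call = ``positive_label``; condition = at least
    ``min_escalations`` escalations within the horizon. Samples are
    evaluable if followed for at least the horizon or already meeting the
    condition; the rest are excluded and counted.
    """
    clin = clinical[["sample_id", "n_escalations_18m", "followup_years"]].reset_index(
        drop=True
    )
    merged = calls.merge(clin, on="sample_id")
    merged = merged[merged["label"] != "no-call"]
    cond = merged["n_escalations_18m"] >= min_escalations
    evaluable = (merged["followup_years"] >= horizon) | cond
    n_excluded = int((~evaluable).sum())
    ev = merged[evaluable]
    pos = ev["label"] == positive_label
    cond = ev["n_escalations_18m"] >= min_escalations
    tp = int((pos & cond).sum())
    fp = int((pos & ~cond).sum())
    fn = int((~pos & cond).sum())
    tn = int((~pos & ~cond).sum())
    if tp + fp + tn + fn == 0:
        raise ValueError("no evaluable samples at this horizon")
    return ConfusionAtHorizon(
        horizon=horizon, min_escalations=min_escalations,
        tp=tp, fp=fp, tn=tn, fn=fn, n_excluded=n_excluded,
    )


def relative_risk(a: int, n1: int, b: int, n2: int) -> tuple[float, float, float]:
    """Relative risk (a/n1)/(b/n2) with a log-normal 95% CI.

    b = 0 makes the RR infinite and the CI undefined (returned as NaN).
    """
    if n1 <= 0 or n2 <= 0 or not (0 <= a <= n1) or not (0 <= b <= n2):
        raise ValueError("invalid counts")
    if b == 0:
        return float("inf"), float("nan"), float("nan")
    rr = (a / n1) / (b / n2)
    if a == 0:
        return 0.0, float("nan"), float("nan")
    se = sqrt(1 / a - 1 / n1 + 1 / b - 1 / n2)
    z = stats.norm.ppf(0.975)
    return rr, rr * np.exp(-z * se), rr * np.exp(z * se)


def fisher_exact_2x2(a: int, b: int, c: int, d: int) -> float:
    """Two-tailed Fisher's exact test p-value for the table [[a, b], [c, d]].

    Sums hypergeometric probabilities of all tables with the same margins
    whose probability does not exceed the observed table's.
    """
    for v in (a, b, c, d):
        if v < 0 or int(v) != v:
            raise ValueError("cells must be non-negative integers")
    if (a + b == 0) or (c + d == 0) or (a + c == 0) or (b + d == 0):
        raise ValueError("empty margin")
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    return float(p)


def mann_whitney(x, y, alternative: str = "two-sided") -> tuple[float, float]:
    """Mann-Whitney U test -> (U, p).

    Exact enumeration when n1*n2 <= 400 and the pooled data are tie-free;
    otherwise the tie-corrected normal approximation with continuity
    correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("empty sample")
    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (len(x) * len(y) <= 400 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative=alternative, method=method)
    return float(res.statistic), float(res.pvalue)
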