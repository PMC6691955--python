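"""Quantification: ΔΔCt relative expression, feature standardisation and the
microarray-qPCR correlation filter.

The ΔΔCt method converts triplicate cycle-threshold (Ct) measurements into
relative expression: per sample, ΔCt(gene) = mean replicate Ct of the gene
minus the mean over reference genes of their mean replicate Cts; ΔΔCt
subtracts a per-gene calibrator constant; relative expression is 2^(−ΔΔCt).
Because target and reference genes shift together, ΔΔCt is invariant to a
constant Ct offset applied to a whole sample (plate shift).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "replicate_means",
    "delta_delta_ct",
    "delta_ct_matrix",
    "Standardizer",
    "standardize_features",
    "correlation_filter",
]

#: replicate-consistency QC bound, cycles
DEFAULT_QC_SD = 0.5


def replicate_means(ct: pd.DataFrame, qc_sd: float = DEFAULT_QC_SD) -> pd.DataFrame:
    """Collapse technical replicates to per-sample/gene mean Ct.

    Returns a frame with columns sample_id, gene, ct_mean, ct_sd, n_reps,
    qc_pass. Replicate SD above ``qc_sd`` flags the record; flagged records
    are retained (exclusion is the caller's decision).
    """
    g = ct.groupby(["sample_id", "gene"])["ct"]
    out = g.agg(ct_mean="mean", ct_sd="std", n_reps="size").reset_index()
    out["ct_sd"] = out["ct_sd"].fillna(0.0)
    out["qc_pass"] = out["ct_sd"] <= qc_sd
    return out


def delta_delta_ct(
    ct: pd.DataFrame,
    reference_genes: list[str],
    calibrator_delta_ct: dict[str, float] | float = 0.0,
    qc_sd: float = DEFAULT_QC_SD,
    drop_failed_qc: bool = False,
) -> pd.DataFrame:
    """Relative expression by the ΔΔCt method from a long-format Ct table.

    Per sample: ΔCt(gene) = mean replicate Ct(gene) − mean over reference
    genes of their mean replicate Ct; ΔΔCt = ΔCt − calibrator(gene);
    rel_expr = 2^(−ΔΔCt). The default calibrator of 0 yields pure ΔCt —
    any fixed calibrator is a per-gene constant absorbed downstream by the
    classifier's coefficients and intercept.

    Returns a frame with columns sample_id, gene, delta_ct, delta_delta_ct,
    rel_expr (reference genes excluded from the output).
    """
    means = replicate_means(ct, qc_sd=qc_sd)
    if drop_failed_qc:
        means = means[means["qc_pass"]]

    ref = means[means["gene"].isin(reference_genes)]
    ref_counts = ref.groupby("sample_id")["gene"].nunique()
    all_samples = means["sample_id"].unique()
    for s in all_samples:
        if ref_counts.get(s, 0) < len(reference_genes):
            missing = set(reference_genes) - set(ref.loc[ref["sample_id"] == s, "gene"])
            raise ValueError(
                f"sample {s!r} is missing reference gene(s) {sorted(missing)}"
            )
    ref_mean = ref.groupby("sample_id")["ct_mean"].mean()

    tgt = means[~means["gene"].isin(reference_genes)].copy()
    tgt["delta_ct"] = tgt["ct_mean"] - tgt["sample_id"].map(ref_mean)
    if isinstance(calibrator_delta_ct, dict):
        cal = tgt["gene"].map(calibrator_delta_ct).fillna(0.0)
    else:
        cal = float(calibrator_delta_ct)
    tgt["delta_delta_ct"] = tgt["delta_ct"] - cal
    tgt["rel_expr"] = np.exp2(-tgt["delta_delta_ct"])
    return tgt[["sample_id", "gene", "delta_ct", "delta_delta_ct", "rel_expr"]].reset_index(
        drop=True
    )


def delta_ct_matrix(rel: pd.DataFrame) -> pd.DataFrame:
    """Pivot a ΔΔCt result into a genes-by-samples ΔCt matrix (classifier features)."""
    return rel.pivot(index="gene", columns="sample_id", values="delta_ct")


@dataclass
class Standardizer:
    """Per-gene centre/scale of a standardisation, invertible."""

    center: pd.Series
    scale: pd.Series

    def transform(self, matrix: pd.DataFrame) -> pd.DataFrame:
        return matrix.sub(self.center, axis=0).div(self.scale, axis=0)

    def inverse_transform(self, matrix: pd.DataFrame) -> pd.DataFrame:
        return matrix.mul(self.scale, axis=0).add(self.center, axis=0)


def standardize_features(
    matrix: pd.DataFrame,
) -> tuple[pd.DataFrame, Standardizer]:
    """Standardise each gene row to mean 0, sample SD 1 (n−1 denominator).

    Returns the standardised matrix and the fitted :class:`Standardizer`
    so the transform can be inverted or applied to held-out samples.
    Zero-variance genes are a hard error (they carry no information and
    would produce non-finite features).
    """
    center = matrix.mean(axis=1)
    scale = matrix.std(axis=1, ddof=1)
    bad = scale[~(scale > 0)].index.tolist()
    if bad:
        raise ValueError(f"zero-variance gene(s): {bad}")
    sc = Standardizer(center=center, scale=scale)
    return sc.transform(matrix), sc


def correlation_filter(
    microarray: pd.DataFrame,
    qpcr_rel: pd.DataFrame,
    candidates: list[str],
    r_min: float = 0.5,
) -> tuple[list[str], pd.DataFrame]:
    """Filter candidate genes by microarray-vs-qPCR agreement.

    Pearson r is computed per gene between the microarray log2 values and
    −ΔCt (= log2 relative expression) over the shared samples. Genes with
    r ≥ ``r_min`` are retained in input order. A zero-variance vector on
    either platform leaves the correlation undefined; the gene is excluded
    with reason "undefined correlation".

    Returns (retained gene list, report frame with columns gene, r,
    retained, reason).
    """
    dct = delta_ct_matrix(qpcr_rel)
    rows = []
    retained: list[str] = []
    for gene in candidates:
        if gene not in microarray.index or gene not in dct.index:
            rows.append((gene, np.nan, False, "missing on a platform"))
            continue
        shared = [s for s in microarray.columns if s in dct.columns]
        x = microarray.loc[gene, shared].to_numpy(dtype=float)
        y = -dct.loc[gene, shared].to_numpy(dtype=float)
        if np.std(x) == 0 or np.std(y) == 0:
            rows.append((gene, np.nan, False, "undefined correlation"))
            continue
        r = float(np.corrcoef(x, y)[0, 1])
        keep = r >= r_min
        rows.append((gene, r, keep, "" if keep else f"r < {r_min}"))
        if keep:
            retained.append(gene)
    report = pd.DataFrame(rows, columns=["gene", "r", "retained", "reason"])
    return retained, report
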