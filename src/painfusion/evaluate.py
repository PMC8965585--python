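"""Performance metrics and model comparison statistics.

The primary metric is the Pearson correlation (PCC) between predicted
and measured thresholds across subjects; mean absolute error (MAE,
reported as mean +- sd of per-subject absolute errors) measures overall
distance. Paired t-tests compare per-subject absolute errors between
models. Because every model's PCC shares the same measured thresholds,
PCCs of two models are dependent; they are compared with the
Meng-Rosenthal-Rubin z-test for two dependent correlations sharing one
variable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import PredictionResult

__all__ = [
    "pcc",
    "mae",
    "paired_t_abs_errors",
    "compare_dependent_correlations",
    "EvaluationReport",
    "build_report",
]


def pcc(pred: np.ndarray, true: np.ndarray) -> tuple[float, float]:
    """Pearson r and its two-sided p-value (t with n-2 df)."""
    pred = np.asarray(pred, dtype=float)
    true = np.asarray(true, dtype=float)
    if pred.shape != true.shape:
        raise ValueError("length mismatch")
    n = pred.size
    if n < 3:
        raise ValueError("correlation needs at least 3 subjects")
    if np.ptp(pred) == 0 or np.ptp(true) == 0:
        raise ValueError("constant input: correlation undefined")
    res = stats.pearsonr(pred, true)
    return float(res.statistic), float(res.pvalue)


def mae(pred: np.ndarray, true: np.ndarray, ddof: int = 1) -> tuple[float, float]:
    """Mean and sd of per-subject absolute errors |yhat_n - y_n|.

    The sd is the sample standard deviation across subjects by default
    (``ddof=1``), matching the mean +- std reporting convention;
    population sd is available via ``ddof=0``.
    """
    pred = np.asarray(pred, dtype=float)
    true = np.asarray(true, dtype=float)
    if pred.shape != true.shape:
        raise ValueError("length mismatch")
    if pred.size == 0:
        raise ValueError("empty input")
    err = np.abs(pred - true)
    sd = float(err.std(ddof=ddof)) if err.size > ddof else 0.0
    return float(err.mean()), sd


def paired_t_abs_errors(
    res_a: PredictionResult, res_b: PredictionResult
) -> tuple[float, float]:
    """Paired t-test on the per-subject absolute-error differences."""
    if res_a.subject_ids != res_b.subject_ids or not np.array_equal(
        res_a.true, res_b.true
    ):
        raise ValueError("results must share subjects and true thresholds")
    if res_a.n_subjects < 3:
        raise ValueError("paired t-test needs at least 3 subjects")
    d = np.abs(res_a.predicted - res_a.true) - np.abs(res_b.predicted - res_b.true)
    if np.ptp(d) == 0:
        if np.any(d != 0):
            warnings.warn(
                "absolute-error differences are a non-zero constant; "
                "paired t-test is degenerate (p set to 1)",
                stacklevel=2,
            )
        return 0.0, 1.0
    t, p = stats.ttest_rel(
        np.abs(res_a.predicted - res_a.true), np.abs(res_b.predicted - res_b.true)
    )
    return float(t), float(p)


def compare_dependent_correlations(
    y: np.ndarray, pred_a: np.ndarray, pred_b: np.ndarray
) -> tuple[float, float]:
    """Meng-Rosenthal-Rubin z-test for two correlations sharing y.

    With Fisher transforms z_A, z_B of r(y, A) and r(y, B),
    rbar2 = (r_Ay^2 + r_By^2)/2, f = min(1, (1 - r_AB)/(2 (1 - rbar2)))
    and h = (1 - f rbar2)/(1 - rbar2):

        z = (z_A - z_B) sqrt((n - 3) / (2 (1 - r_AB) h)),

    referred to the standard normal (two-sided). Antisymmetric in
    (A, B).
    """
    y = np.asarray(y, dtype=float)
    a = np.asarray(pred_a, dtype=float)
    b = np.asarray(pred_b, dtype=float)
    n = y.size
    if a.size != n or b.size != n:
        raise ValueError("length mismatch")
    if n < 10:
        raise ValueError("dependent-correlation test needs at least 10 subjects")
    if np.array_equal(a, b):
        return 0.0, 1.0
    r_ay = np.corrcoef(y, a)[0, 1]
    r_by = np.corrcoef(y, b)[0, 1]
    r_ab = np.corrcoef(a, b)[0, 1]
    for name, r in (("r_Ay", r_ay), ("r_By", r_by), ("r_AB", r_ab)):
        if not np.isfinite(r):
            raise ValueError(f"{name} is undefined (constant input?)")
        if abs(r) >= 1.0 - 1e-12:
            raise ValueError(f"{name} is at +-1: test degenerate")
    za, zb = np.arctanh(r_ay), np.arctanh(r_by)
    rbar2 = (r_ay**2 + r_by**2) / 2.0
    f = min(1.0, (1.0 - r_ab) / (2.0 * (1.0 - rbar2)))
    h = (1.0 - f * rbar2) / (1.0 - rbar2)
    z = (za - zb) * np.sqrt((n - 3) / (2.0 * (1.0 - r_ab) * h))
    p = 2.0 * stats.norm.sf(abs(z))
    return float(z), float(p)


@dataclass
class EvaluationReport:
    """Per-model metrics plus the pairwise comparison matrices."""

    per_model: pd.DataFrame
    mae_ttest_p: pd.DataFrame
    pcc_z: pd.DataFrame
    pcc_p: pd.DataFrame

    def to_json_dict(self) -> dict:
        return {
            "per_model": self.per_model.to_dict(orient="index"),
            "mae_ttest_p": self.mae_ttest_p.to_dict(orient="index"),
            "pcc_z": self.pcc_z.to_dict(orient="index"),
            "pcc_p": self.pcc_p.to_dict(orient="index"),
        }


def build_report(suite_results: dict[str, PredictionResult]) -> EvaluationReport:
    """Model-comparison table and all pairwise tests.

    One row per model (MAE mean +- sd, PCC r and p); pairwise matrices
    hold the paired-t p-values on absolute errors and the dependent-
    correlation z/p for every model pair.
    """
    if not suite_results:
        raise ValueError("no results to report")
    names = list(suite_results)
    rows = []
    for name in names:
        r = suite_results[name]
        m, sd = mae(r.predicted, r.true)
        cc, p = pcc(r.predicted, r.true)
        rows.append(
            {"model": name, "mae_mean": m, "mae_sd": sd, "pcc_r": cc, "pcc_p": p}
        )
    per_model = pd.DataFrame(rows).set_index("model")

    k = len(names)
    tmat = pd.DataFrame(np.full((k, k), np.nan), index=names, columns=names)
    zmat = tmat.copy()
    pmat = tmat.copy()
    for i, a in enumerate(names):
        for j, b in enumerate(names):
            if i >= j:
                continue
            _, tp = paired_t_abs_errors(suite_results[a], suite_results[b])
            z, zp = compare_dependent_correlations(
                suite_results[a].true,
                suite_results[a].predicted,
                suite_results[b].predicted,
            )
            tmat.loc[a, b] = tmat.loc[b, a] = tp
            zmat.loc[a, b] = z
            zmat.loc[b, a] = -z
            pmat.loc[a, b] = pmat.loc[b, a] = zp
    return EvaluationReport(per_model=per_model, mae_ttest_p=tmat, pcc_z=zmat, pcc_p=pmat)
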