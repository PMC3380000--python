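"""Differential-expression filtering that seeds network inference.

Each probeset is tested with a two-way ANOVA (condition and time as
main-effect factors, fitted on the treated samples), p-values are adjusted
with the Benjamini-Hochberg step-up rule, and a probeset is selected when
the adjusted p is below ``alpha`` and the largest absolute mean log2
difference of any condition x time group versus the baseline controls
reaches ``log2(fc_threshold)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .expr_data import ExpressionMatrix, SampleDesign


class DegenerateDesignError(ValueError):
    """The design cannot support the requested model."""


@dataclass(frozen=True)
class DiffExprResult:
    probe_id: str
    p_value: float
    p_adjusted: float
    max_abs_log2_fc: float
    selected: bool


def _anova_design_matrix(conditions: np.ndarray, times: np.ndarray) -> np.ndarray:
    """Main-effects design matrix: intercept + condition dummies + time dummies."""
    cond_levels = sorted(set(conditions))
    time_levels = sorted(set(times))
    if len(cond_levels) < 2 or len(time_levels) < 2:
        raise DegenerateDesignError(
            "two-way ANOVA needs >=2 levels in both condition and time "
            f"(got {len(cond_levels)} and {len(time_levels)})"
        )
    n = len(conditions)
    cols = [np.ones(n)]
    for lev in cond_levels[1:]:
        cols.append((conditions == lev).astype(float))
    for lev in time_levels[1:]:
        cols.append((times == lev).astype(float))
    return np.column_stack(cols)


def _model_f_pvalues(Y: np.ndarray, X: np.ndarray) -> np.ndarray:
    """Omnibus regression F-test p-values, one per row of Y.

    F = ((TSS - RSS)/df_model) / (RSS/df_resid) against the intercept-only
    model. Rows with (numerically) zero total variance carry no evidence and
    get p = 1; rows fitted exactly (zero residual variance but real effect)
    get p = 0.
    """
    n, k = X.shape
    df_model = k - 1
    df_resid = n - k
    if df_resid < 1:
        raise DegenerateDesignError("not enough samples for residual degrees of freedom")
    # hat-matrix-free residuals via one QR shared by all probes
    Q, _ = np.linalg.qr(X)
    fitted = Y @ Q @ Q.T
    rss = np.sum((Y - fitted) ** 2, axis=1)
    tss = np.sum((Y - Y.mean(axis=1, keepdims=True)) ** 2, axis=1)
    scale = np.maximum(tss, 1.0)
    p = np.ones(len(Y))
    informative = tss > 1e-12 * scale
    exact = informative & (rss <= 1e-12 * tss)
    regular = informative & ~exact
    with np.errstate(divide="ignore", invalid="ignore"):
        f = ((tss[regular] - rss[regular]) / df_model) / (rss[regular] / df_resid)
    p[regular] = stats.f.sf(f, df_model, df_resid)
    p[exact] = 0.0
    return p


def two_way_anova(values: np.ndarray, design: SampleDesign) -> float:
    """Omnibus p-value for one probe under the condition+time main-effects model.

    Baseline-control samples are excluded: they occupy no condition x time
    factorial cell. When a factor collapses to a single level among treated
    samples the model degenerates to one-way ANOVA on the remaining factor.
    """
    values = np.asarray(values, dtype=float)
    tab = design.table
    treated = ~tab["is_baseline_control"].astype(bool).to_numpy()
    if treated.sum() < 3:
        raise DegenerateDesignError("need >=3 treated samples")
    conditions = tab["condition"].to_numpy()[treated]
    times = tab["time"].to_numpy()[treated]
    y = values[treated][None, :]
    try:
        X = _anova_design_matrix(conditions, times)
    except DegenerateDesignError:
        # single-level factor: collapse to one-way on the multi-level one
        factor = conditions if len(set(conditions)) > 1 else times
        if len(set(factor)) < 2:
            raise
        levels = sorted(set(factor))
        n = len(factor)
        cols = [np.ones(n)] + [(factor == lev).astype(float) for lev in levels[1:]]
        X = np.column_stack(cols)
    return float(_model_f_pvalues(y, X)[0])


def adjust_pvalues(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (order-preserving, <=1)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def max_abs_log2_fold_changes(
    matrix: ExpressionMatrix, design: SampleDesign
) -> np.ndarray:
    """Largest |mean log2 difference| of any condition x time group vs baseline."""
    tab = design.table.loc[list(matrix.sample_ids)]
    baseline = tab["is_baseline_control"].astype(bool).to_numpy()
    if not baseline.any():
        raise ValueError("no baseline-control samples in design")
    base_mean = matrix.values[:, baseline].mean(axis=1)
    treated = ~baseline
    groups = pd.Series(
        tab["condition"].astype(str) + "|" + tab["time"].astype(str)
    ).to_numpy()
    max_fc = np.zeros(matrix.n_probes)
    for g in np.unique(groups[treated]):
        mask = treated & (groups == g)
        diff = np.abs(matrix.values[:, mask].mean(axis=1) - base_mean)
        np.maximum(max_fc, diff, out=max_fc)
    return max_fc


def select_differential(
    matrix: ExpressionMatrix,
    design: SampleDesign,
    alpha: float = 0.05,
    fc_threshold: float = 2.0,
) -> list[DiffExprResult]:
    """Run the full differential filter; one result per probe, in matrix order."""
    design.check_matches(matrix)
    tab = design.table.loc[list(matrix.sample_ids)]
    treated = ~tab["is_baseline_control"].astype(bool).to_numpy()
    conditions = tab["condition"].to_numpy()[treated]
    times = tab["time"].to_numpy()[treated]
    X = _anova_design_matrix(conditions, times)
    p = _model_f_pvalues(matrix.values[:, treated], X)
    p_adj = adjust_pvalues(p)
    fc = max_abs_log2_fold_changes(matrix, design)
    log2_fc_min = np.log2(fc_threshold)
    results = []
    for i, probe in enumerate(matrix.probe_ids):
        sel = bool((p_adj[i] < alpha) and (fc[i] >= log2_fc_min))
        results.append(DiffExprResult(probe, float(p[i]), float(p_adj[i]), float(fc[i]), sel))
    return results


def results_to_frame(results: list[DiffExprResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "probe_id": [r.probe_id for r in results],
            "p_value": [r.p_value for r in results],
            "p_adjusted": [r.p_adjusted for r in results],
            "max_abs_log2_fc": [r.max_abs_log2_fc for r in results],
            "selected": [r.selected for r in results],
        }
    )


def selected_probes(results: list[DiffExprResult]) -> list[str]:
    return [r.probe_id for r in results if r.selected]
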