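"""Time-resolved group comparison and imaging-vs-destructive correlation.

Two variants are compared round by round on their normalized fluorescence:
either a mixed model with a random intercept per replicate unit (plate /
experiment) or a Welch two-sample test when too few units exist for a random
effect. Raw p-values across the rounds of one comparison form the
Benjamini-Hochberg family; maximal runs of adjusted significance are reported
as time intervals, the display convention for genotype/treatment contrasts.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from chlorokin.errors import AlignmentError, InsufficientDataError

logger = logging.getLogger(__name__)


@dataclass
class SignificanceTrack:
    """Per-round p-values and the derived significant time intervals."""

    time_min: np.ndarray
    p_raw: np.ndarray
    p_adj: np.ndarray
    significant: np.ndarray
    intervals: list[tuple[float, float]]
    alpha: float


@dataclass
class CorrelationResult:
    """Pearson correlation between imaging kinetics and a destructive pigment."""

    r: float
    n_points: int
    matched_time_min: np.ndarray
    note: str


def _roi_matrix(traces: pd.DataFrame, value_col: str) -> tuple[np.ndarray, np.ndarray, list]:
    """Pivot a long trace table into (n_roi × n_round) values + time grid."""
    pivot = traces.pivot_table(
        index=["cell", "zone"], columns="round", values=value_col, dropna=False
    )
    rounds = pivot.columns.to_numpy()
    tm = traces.drop_duplicates("round").sort_values("round")["time_min"].to_numpy()
    return pivot.to_numpy(), tm[np.argsort(rounds)], list(pivot.index)


def pointwise_test(
    traces_a: pd.DataFrame,
    traces_b: pd.DataFrame,
    model: str = "welch",
    value_col: str = "norm",
    unit_col: str | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-round two-sided test of the group difference.

    Returns ``(time_min, p_raw)``. ``model='mixed'`` fits, per round,
    ``value ~ group`` with a random intercept per replicate unit (column
    ``unit_col``) and reports the Wald p-value of the group effect; with
    fewer than 3 distinct units it falls back to Welch with a logged
    warning, as does any singular fit. ``model='welch'`` is the plain
    unequal-variance two-sample test across replicate ROIs.
    """
    a_mat, t_a, _ = _roi_matrix(traces_a, value_col)
    b_mat, t_b, _ = _roi_matrix(traces_b, value_col)
    if a_mat.shape[1] != b_mat.shape[1] or not np.allclose(t_a, t_b):
        raise AlignmentError("groups are not on a common time grid")
    if a_mat.shape[0] < 2 or b_mat.shape[0] < 2:
        raise InsufficientDataError("need at least 2 replicate ROIs per group")
    if model == "mixed":
        units_a = _units(traces_a, unit_col, a_mat.shape[0])
        units_b = _units(traces_b, unit_col, b_mat.shape[0])
        n_units = len(set(units_a) | set(units_b))
        if n_units < 3:
            logger.warning(
                "mixed model requested but only %d replicate unit(s); falling back to welch",
                n_units,
            )
            model = "welch"
    if model == "welch":
        with np.errstate(divide="ignore", invalid="ignore"), warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            p = sps.ttest_ind(a_mat, b_mat, axis=0, equal_var=False).pvalue
        p = np.where(np.isfinite(p), p, 1.0)
        return t_a, np.asarray(p, dtype=float)
    if model != "mixed":
        raise ValueError(f"unknown model {model!r}")

    import statsmodels.formula.api as smf

    p_out = np.ones(a_mat.shape[1])
    for k in range(a_mat.shape[1]):
        df = pd.DataFrame(
            {
                "value": np.concatenate([a_mat[:, k], b_mat[:, k]]),
                "group": ["a"] * a_mat.shape[0] + ["b"] * b_mat.shape[0],
                "unit": list(units_a) + list(units_b),
            }
        ).dropna()
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = smf.mixedlm("value ~ group", df, groups=df["unit"]).fit(reml=True)
            pk = float(fit.pvalues["group[T.b]"])
            if not np.isfinite(pk):
                raise ValueError("non-finite p-value")
        except Exception:  # singular fit: documented welch fallback
            logger.warning("singular mixed fit at round %d; welch fallback", k)
            pk = float(
                sps.ttest_ind(a_mat[:, k], b_mat[:, k], equal_var=False).pvalue
            )
        p_out[k] = pk if np.isfinite(pk) else 1.0
    return t_a, p_out


def _units(traces: pd.DataFrame, unit_col: str | None, n_roi: int) -> list:
    if unit_col is None or unit_col not in traces.columns:
        return ["unit0"] * n_roi
    pivot = traces.drop_duplicates(["cell", "zone"]).set_index(["cell", "zone"])
    return list(pivot[unit_col])


def adjust_bh(p_raw) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1, tie-safe)."""
    p = np.asarray(p_raw, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def significant_intervals(
    p_adj, time_min, alpha: float = 0.05
) -> list[tuple[float, float]]:
    """Maximal runs of consecutive rounds with p_adj < alpha, as time intervals."""
    p = np.asarray(p_adj, dtype=float)
    t = np.asarray(time_min, dtype=float)
    if p.shape != t.shape:
        raise AlignmentError("p_adj and time_min must align")
    sig = p < alpha
    intervals = []
    start = None
    for i, s in enumerate(sig):
        if s and start is None:
            start = i
        elif not s and start is not None:
            intervals.append((float(t[start]), float(t[i - 1])))
            start = None
    if start is not None:
        intervals.append((float(t[start]), float(t[-1])))
    return intervals


def compare_groups(
    traces_a: pd.DataFrame,
    traces_b: pd.DataFrame,
    alpha: float = 0.05,
    model: str = "welch",
    value_col: str = "norm",
    unit_col: str | None = None,
) -> SignificanceTrack:
    """pointwise test → BH adjustment → interval extraction, one call."""
    t, p_raw = pointwise_test(traces_a, traces_b, model=model, value_col=value_col, unit_col=unit_col)
    p_adj = adjust_bh(p_raw)
    sig = p_adj < alpha
    return SignificanceTrack(
        time_min=t,
        p_raw=p_raw,
        p_adj=p_adj,
        significant=sig,
        intervals=significant_intervals(p_adj, t, alpha),
        alpha=alpha,
    )


def correlate_destructive(
    fluor_time_min,
    fluor_values,
    pigment_table: pd.DataFrame,
    pigment: str = "chl_a",
    tolerance_min: float = 1.0,
) -> CorrelationResult:
    """Pearson correlation between a fluorescence trace and destructive pigments.

    The fluorescence trace is renormalized to its value at the final (4-h)
    timepoint; the pigment column is already normalized to T8. Each pigment
    timepoint is matched to the nearest frame within ``tolerance_min``;
    unmatched timepoints are dropped. At least 3 matches are required.
    """
    t = np.asarray(fluor_time_min, dtype=float)
    v = np.asarray(fluor_values, dtype=float)
    end_val = v[-1]
    if end_val == 0 or not np.isfinite(end_val):
        raise InsufficientDataError("fluorescence endpoint value is degenerate")
    v_norm = v / end_val
    matched_f, matched_p, matched_t = [], [], []
    for _, row in pigment_table.iterrows():
        j = int(np.argmin(np.abs(t - row["time_min"])))
        if abs(t[j] - row["time_min"]) <= tolerance_min:
            matched_f.append(v_norm[j])
            matched_p.append(float(row[pigment]))
            matched_t.append(t[j])
    if len(matched_f) < 3:
        raise InsufficientDataError(
            f"only {len(matched_f)} pigment timepoints matched within ±{tolerance_min} min"
        )
    r = float(sps.pearsonr(matched_f, matched_p).statistic)
    return CorrelationResult(
        r=r,
        n_points=len(matched_f),
        matched_time_min=np.asarray(matched_t),
        note=f"fluorescence normalized to its final-frame value; pigment '{pigment}' normalized to T8",
    )
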