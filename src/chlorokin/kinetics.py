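"""Normalization, replicate aggregation and phase annotation of ROI traces.

Traces are normalized per ROI to the mean fluorescence of the first round
(F/F0), which cancels multiplicative camera gain, before being aggregated
across the replicate ROIs of a variant. Phase annotation locates the end of
the initial burst and the end of the lag phase (exponential onset) from the
smoothed derivative of a mean trace.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from chlorokin.errors import AlignmentError, DegenerateInputError

logger = logging.getLogger(__name__)


def normalize_f0(traces: pd.DataFrame) -> pd.DataFrame:
    """Add a ``norm`` column: mean fluorescence divided by the round-0 mean.

    Expects the long-format trace table (``cell, zone, round, time_min, mean``).
    ROIs whose F0 is non-positive or missing are dropped with a logged
    warning rather than producing infinities.
    """
    df = traces.copy()
    df["norm"] = np.nan
    keep = []
    for key, sub in df.groupby(["cell", "zone"], dropna=False, sort=False):
        sub = sub.sort_values("round")
        f0 = sub.loc[sub["round"] == 0, "mean"]
        if f0.empty or not np.isfinite(f0.iloc[0]) or f0.iloc[0] <= 0:
            logger.warning("ROI %s has degenerate baseline F0; excluded", (key,))
            continue
        sub = sub.assign(norm=sub["mean"] / f0.iloc[0])
        keep.append(sub)
    if not keep:
        raise DegenerateInputError("no ROI with a positive F0 baseline")
    return pd.concat(keep, ignore_index=True)


def aggregate_replicates(traces: pd.DataFrame, value_col: str = "norm") -> pd.DataFrame:
    """Pointwise mean ± sample SD (n−1) across replicate ROIs.

    All ROIs must share the same time grid. Returns columns
    ``round, time_min, n, mean_<value_col>, sd_<value_col>``.
    """
    grids = traces.groupby(["cell", "zone"], dropna=False, sort=False)["round"].apply(
        lambda s: tuple(sorted(s))
    )
    if grids.nunique() != 1:
        raise AlignmentError("replicate traces are not on a common round grid")
    n_rois = len(grids)
    if n_rois < 2:
        raise AlignmentError(f"need at least 2 replicate traces, got {n_rois}")
    g = traces.groupby(["round", "time_min"], as_index=False)[value_col].agg(
        ["mean", "std", "count"]
    )
    g = g.rename(
        columns={"mean": f"mean_{value_col}", "std": f"sd_{value_col}", "count": "n"}
    )
    return g[["round", "time_min", "n", f"mean_{value_col}", f"sd_{value_col}"]]


@dataclass
class PhaseAnnotation:
    """Kinetic phase landmarks of one mean trace (minutes).

    ``burst_end_min`` — where the fast initial rise has decayed to half of
    its early maximum rate; ``lag_end_min`` — last pre-maximum time at which
    the rise rate is at most a quarter of its global maximum, i.e. the onset
    of the exponential phase; ``max_rate_min``/``max_rate`` — location and
    value of the global derivative maximum. Landmarks the rules cannot locate
    are None (flagged, never raised).
    """

    burst_end_min: float | None
    lag_end_min: float | None
    max_rate_min: float
    max_rate: float


def annotate_phases(
    time_min: np.ndarray,
    values: np.ndarray,
    smoothing_window: int = 5,
    burst_fraction: float = 0.5,
    lag_fraction: float = 0.25,
) -> PhaseAnnotation:
    """Locate burst end and lag end on a mean fluorescence trace.

    The trace is smoothed with a centered moving average (window in rounds,
    shrunk at the edges), differentiated on its time grid, and thresholded:
    the burst ends where the derivative first drops below ``burst_fraction``
    of its early maximum (maximum over the first window); the lag ends at the
    last time before the global derivative maximum at which the derivative is
    at most ``lag_fraction`` of that maximum. Missing values are linearly
    interpolated for annotation only. Deterministic; invariant to
    multiplicative rescaling of the trace.
    """
    t = np.asarray(time_min, dtype=float)
    v = np.asarray(values, dtype=float)
    if len(t) < 20:
        raise ValueError(f"need at least 20 timepoints for phase annotation, got {len(t)}")
    if np.any(~np.isfinite(v)):
        v = pd.Series(v).interpolate(limit_direction="both").to_numpy()
    s = pd.Series(v).rolling(smoothing_window, center=True, min_periods=1).mean().to_numpy()
    d = np.gradient(s, t)

    w = max(2, smoothing_window)
    init_max = d[:w].max()
    init_arg = int(np.argmax(d[:w]))
    burst_end = None
    if init_max > 0:
        below = np.nonzero(d[init_arg:] < burst_fraction * init_max)[0]
        if below.size:
            cand = t[init_arg + below[0]]
            # a trace with no initial fast phase has its global rate maximum
            # well after the early window: only call a burst if the early rate
            # actually dominates the first part of the record
            if init_max >= burst_fraction * d.max() or cand < t[int(np.argmax(d))]:
                burst_end = float(cand)
    gmax_i = int(np.argmax(d))
    max_rate = float(d[gmax_i])
    lag_end = None
    if max_rate > 0 and gmax_i > 0:
        pre = np.nonzero(d[:gmax_i] <= lag_fraction * max_rate)[0]
        if pre.size:
            lag_end = float(t[pre[-1]])
    if burst_end is not None and lag_end is not None and burst_end > lag_end:
        burst_end = None  # early window rate never dominated: no burst phase
    return PhaseAnnotation(
        burst_end_min=burst_end,
        lag_end_min=lag_end,
        max_rate_min=float(t[gmax_i]),
        max_rate=max_rate,
    )
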