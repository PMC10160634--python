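"""Gaussian decomposition of 77 K chlorophyll fluorescence emission spectra.

At liquid-nitrogen temperature the emission spectrum of a greening seedling
resolves into pigment-protein pools with characteristic bands: free
protochlorophyllide near 630 nm, the photoactive protochlorophyllide:POR:NADPH
complex near 654 nm, unbound chlorophyll at 675–683 nm (its maximum drifts
red as chlorophyll accumulates), the PSII core (CP43/CP47) shoulder near
695 nm, and a broad LHC antenna band between 720 and 760 nm. Spectra are
reference-corrected, fitted as a bounded sum of Gaussians, and the fitted
amplitudes are tracked over the de-etiolation series.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.stats import spearmanr

from chlorokin.errors import AlignmentError

#: fitted centers may move this far from the template center (nm)
DEFAULT_CENTER_TOL = 6.0
#: the broad LHC band drifts more; identified by name
BROAD_CENTER_TOL = 20.0
MAX_WIDTH = 25.0


@dataclass(frozen=True)
class ComponentTemplate:
    """Initial guess and bounds for one Gaussian band."""

    name: str
    center_nm: float
    width_nm: float
    center_tol_nm: float = DEFAULT_CENTER_TOL


def default_component_template() -> tuple[ComponentTemplate, ...]:
    """The five canonical 77 K bands of a de-etiolating seedling."""
    return (
        ComponentTemplate("free_pchlide", 630.0, 9.0),
        ComponentTemplate("photoactive_pchlide", 654.0, 8.0),
        ComponentTemplate("chl_unbound", 679.0, 9.0),  # drifts 675 → 683 nm
        ComponentTemplate("psii_core", 695.0, 7.0),
        ComponentTemplate("lhc_broad", 740.0, 16.0, center_tol_nm=BROAD_CENTER_TOL),
    )


@dataclass
class ComponentFit:
    """Result of one spectrum decomposition."""

    components: pd.DataFrame  # name, center_nm, width_nm, amplitude
    residual_rms: float
    converged: bool
    fitted: np.ndarray = field(repr=False, default=None)


def baseline_correct(
    spectrum: pd.DataFrame, reference: pd.DataFrame | None
) -> tuple[pd.DataFrame, float]:
    """Subtract a blank reference spectrum, flooring negatives at zero.

    Both tables need identical, strictly increasing wavelength grids. Returns
    the corrected spectrum and the fraction of samples floored.
    """
    wl = spectrum["wavelength_nm"].to_numpy()
    if np.any(np.diff(wl) <= 0):
        raise AlignmentError("wavelength grid must be strictly increasing")
    if reference is None:
        return spectrum.copy(), 0.0
    if not np.array_equal(wl, reference["wavelength_nm"].to_numpy()):
        raise AlignmentError("spectrum and reference are on different wavelength grids")
    diff = spectrum["intensity"].to_numpy() - reference["intensity"].to_numpy()
    floored = float(np.mean(diff < 0))
    return pd.DataFrame({"wavelength_nm": wl, "intensity": np.clip(diff, 0.0, None)}), floored


def _gauss_sum(wl: np.ndarray, params: np.ndarray) -> np.ndarray:
    out = np.zeros_like(wl)
    for i in range(0, len(params), 3):
        a, c, w = params[i : i + 3]
        out = out + a * np.exp(-((wl - c) ** 2) / (2.0 * w**2))
    return out


def fit_components(
    spectrum: pd.DataFrame,
    template: tuple[ComponentTemplate, ...] | None = None,
) -> ComponentFit:
    """Bounded nonlinear least-squares fit of a Gaussian sum.

    Parameters per component: amplitude ≥ 0, center within its template
    tolerance, width in [2, 25] nm. Initialization is fixed at the template
    centers/widths with unit amplitudes, so the fit is deterministic.
    Non-convergence is reported through ``converged`` with the residual, not
    raised.
    """
    if template is None:
        template = default_component_template()
    wl = spectrum["wavelength_nm"].to_numpy(dtype=float)
    y = spectrum["intensity"].to_numpy(dtype=float)
    for comp in template:
        lo, hi = comp.center_nm - comp.center_tol_nm, comp.center_nm + comp.center_tol_nm
        if lo < wl[0] or hi > wl[-1]:
            raise AlignmentError(
                f"grid [{wl[0]}, {wl[-1]}] nm does not cover component {comp.name} bounds"
            )
    x0, lower, upper = [], [], []
    for comp in template:
        x0 += [1.0, comp.center_nm, comp.width_nm]
        lower += [0.0, comp.center_nm - comp.center_tol_nm, 2.0]
        upper += [np.inf, comp.center_nm + comp.center_tol_nm, MAX_WIDTH]
    res = optimize.least_squares(
        lambda p: _gauss_sum(wl, p) - y,
        x0=np.array(x0),
        bounds=(np.array(lower), np.array(upper)),
        method="trf",
        xtol=1e-12,
        ftol=1e-12,
        gtol=1e-12,
    )
    fitted = _gauss_sum(wl, res.x)
    rms = float(np.sqrt(np.mean((fitted - y) ** 2)))
    table = pd.DataFrame(
        {
            "name": [c.name for c in template],
            "center_nm": res.x[1::3],
            "width_nm": res.x[2::3],
            "amplitude": res.x[0::3],
        }
    )
    return ComponentFit(
        components=table, residual_rms=rms, converged=bool(res.success), fitted=fitted
    )


def track_pools(
    fits: dict[float, ComponentFit], spearman_threshold: float = 0.8
) -> pd.DataFrame:
    """Amplitude trajectories of each pool across a timepoint series.

    ``fits`` maps acquisition time (minutes) to a :class:`ComponentFit`.
    Returns a long table ``time_min, name, amplitude, center_nm`` plus a
    ``trend`` column per component: 'increasing' / 'decreasing' when the
    Spearman correlation of amplitude vs time passes the threshold in
    magnitude, otherwise 'none' (constant series have no trend).
    """
    if len(fits) < 2:
        raise ValueError("need at least 2 timepoints to track pools")
    rows = []
    for t in sorted(fits):
        tab = fits[t].components
        for _, r in tab.iterrows():
            rows.append(
                {
                    "time_min": t,
                    "name": r["name"],
                    "amplitude": r["amplitude"],
                    "center_nm": r["center_nm"],
                }
            )
    df = pd.DataFrame(rows)
    trends = {}
    for name, sub in df.groupby("name"):
        amps = sub.sort_values("time_min")["amplitude"].to_numpy()
        if np.allclose(amps, amps[0]):
            trends[name] = "none"
            continue
        rho = spearmanr(sub.sort_values("time_min")["time_min"], amps).statistic
        if np.isnan(rho):
            trends[name] = "none"
        elif rho >= spearman_threshold:
            trends[name] = "increasing"
        elif rho <= -spearman_threshold:
            trends[name] = "decreasing"
        else:
            trends[name] = "none"
    df["trend"] = df["name"].map(trends)
    return df
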