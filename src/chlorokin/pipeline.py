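"""End-to-end runs: simulate a plate, analyze a stack, compare variants.

This is the library surface behind the command-line interface; every step is
also callable on its own. The analysis order is fixed: reference frame →
threshold mask → zone partition → trace extraction → F/F0 normalization →
replicate aggregation → pointwise tests → BH adjustment → interval calls.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from chlorokin import kinetics as kin
from chlorokin import segmentation as seg
from chlorokin import stats as st
from chlorokin.config import RunConfig
from chlorokin.synthgen import (
    DESTRUCTIVE_TIMEPOINTS_MIN,
    FrameStack,
    GroundTruth,
    PlateLayout,
    default_spectrum_model,
    make_layout,
    render_stack,
    sample_virtual_pigments,
    synth_spectrum,
)


@dataclass
class SimulationResult:
    stack: FrameStack
    truth: GroundTruth
    layout: PlateLayout
    pigments: pd.DataFrame
    spectra: dict[float, pd.DataFrame]


@dataclass
class AnalysisResult:
    mask: seg.PlantMask
    traces: pd.DataFrame
    normalized: pd.DataFrame
    aggregates: dict[str, pd.DataFrame]
    comparison: st.SignificanceTrack | None


def simulate_run(config: RunConfig, spectra_timepoints: tuple[float, ...] | None = None) -> SimulationResult:
    """Render a full synthetic experiment from a config and its seed."""
    layout = make_layout(
        variants=list(config.variants),
        rng_seed=config.rng_seed,
        grid_rows=config.layout["grid_rows"],
        areas_per_row=config.layout["areas_per_row"],
        replicate_cells_per_variant=config.layout["replicate_cells_per_variant"],
        seeds_per_area=config.layout.get("seeds_per_area", 40),
        seedlings_per_cell=config.layout.get("seedlings_per_cell", 30),
        plate_size_mm=tuple(config.layout.get("plate_size_mm", (120.0, 120.0))),
    )
    kinetics = config.kinetics_per_variant()
    stack, truth = render_stack(
        layout,
        config.protocol,
        kinetics,
        noise=config.noise,
        rng_seed=config.rng_seed,
        image_shape=config.image_shape,
    )
    # a shortened protocol samples only the collection timepoints it covers
    span = config.protocol.total_duration_min
    timepoints = tuple(t for t in DESTRUCTIVE_TIMEPOINTS_MIN if t <= span)
    pigments = sample_virtual_pigments(
        kinetics,
        config.pchlide_per_variant(),
        timepoints_min=timepoints,
        noise_cv=0.05,
        rng_seed=config.rng_seed,
        total_duration_min=config.protocol.total_duration_min,
    )
    truth.virtual_pigments = pigments
    if spectra_timepoints is None:
        spectra_timepoints = timepoints
    first = next(iter(kinetics.values()))
    model = default_spectrum_model(chl_params=first)
    spectra = {float(t): synth_spectrum(float(t), model) for t in spectra_timepoints}
    return SimulationResult(stack=stack, truth=truth, layout=layout, pigments=pigments, spectra=spectra)


def analyze_run(
    stack: FrameStack,
    layout: PlateLayout,
    config: RunConfig,
) -> AnalysisResult:
    """Run the mask pipeline and variant comparison on one stack."""
    s = config.segmentation
    mask = seg.build_mask(
        stack,
        layout,
        method=s.get("method", "otsu"),
        manual_threshold=s.get("manual_threshold"),
        saturation_fraction_max=s.get("saturation_fraction_max", 0.001),
        target_time_min=s.get("target_time_min", 180.0),
        band_fractions=tuple(s.get("band_fractions", seg.DEFAULT_BAND_FRACTIONS)),
    )
    traces = seg.extract_traces(stack, mask, grouping="cell_zone")
    traces = traces.dropna(subset=["mean"])
    normalized = kin.normalize_f0(traces)
    normalized = normalized.merge(
        pd.Series(dict(layout.assignment), name="variant").rename_axis("cell").reset_index(),
        on="cell",
        how="left",
    )
    zone = config.stats.get("zone", "cotyledon")
    aggregates = {}
    for variant in layout.variants:
        sub = normalized[(normalized["variant"] == variant) & (normalized["zone"] == zone)]
        if sub["cell"].nunique() >= 2:
            aggregates[variant] = kin.aggregate_replicates(sub)
    comparison = None
    if len(layout.variants) >= 2:
        va, vb = layout.variants[:2]
        sub_a = normalized[(normalized["variant"] == va) & (normalized["zone"] == zone)]
        sub_b = normalized[(normalized["variant"] == vb) & (normalized["zone"] == zone)]
        if sub_a["cell"].nunique() >= 2 and sub_b["cell"].nunique() >= 2:
            comparison = st.compare_groups(
                sub_a,
                sub_b,
                alpha=config.stats.get("alpha", 0.05),
                model=config.stats.get("model", "welch"),
            )
    return AnalysisResult(
        mask=mask,
        traces=traces,
        normalized=normalized,
        aggregates=aggregates,
        comparison=comparison,
    )


def small_test_config(
    rng_seed: int = 0,
    exp_onset_shift: float = 0.0,
    n_rounds: int = 120,
    image_shape: tuple[int, int] = (64, 64),
) -> RunConfig:
    """Reduced-scale two-variant config for simulation studies.

    A 3×6 grid giving the standard 9 replicate ROIs per variant, small cells
    on a 64×64 frame, 3 seedlings per cell; the second variant's exponential
    onset is shifted by ``exp_onset_shift`` minutes. Full protocol timing is
    kept.
    """
    cfg = RunConfig(rng_seed=rng_seed)
    cfg.layout = {
        "grid_rows": 3,
        "areas_per_row": 6,
        "replicate_cells_per_variant": 9,
        "seeds_per_area": 4,
        "seedlings_per_cell": 3,
        "plate_size_mm": [120.0, 120.0],
    }
    cfg.variants = {
        "groupA": {},
        "groupB": {"exp_onset": 120.0 + exp_onset_shift},
    }
    cfg.image_shape = image_shape
    if n_rounds != 120:
        from chlorokin.protocol import build_protocol

        cfg.protocol = build_protocol(total_duration_min=n_rounds * 2.0)
    return cfg
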