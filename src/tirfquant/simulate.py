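"""Forward generator of ground-truthed synthetic TIRF cohorts.

Every stage of the quantification chain is testable without external data:
per-cell recruitment kinetics produce a membrane-recruitment trajectory
``delta_m(t)``, the layered-optics forward model turns it into a
ground-truth fluorescence fold-change ``F(t)``, and the renderer draws
noisy camera frames whose ROI-extracted, background-subtracted,
baseline-normalized trace has expectation ``F(t)``.

The recruitment time course is a delayed exponential rise with optional
partial exponential relaxation,

    delta_m(t) = A * (1 - exp(-(t - t0)/tau_rise))
                   * (p + (1 - p) * exp(-(t - t0)/tau_decay))    for t > t0,

zero before the delay ``t0``.  This is the simplest shape consistent with
the observed phenomenology: lipid-biosensor signals rise within a minute or
two of growth-factor application and partially relax while the stimulus is
still present (receptor internalization, lipid phosphatases), whereas
channel-trafficking signals rise and plateau without reversal
(``p = 1``).  The generator makes no kinetic claim beyond that shape.

Cohort templates encode the three canonical experimental conditions:

- **responder** — right-skewed (log-normal) response amplitudes, calibrated
  so the cohort-mean window fold-change is ~1.5;
- **vehicle** — zero amplitude, fold-change 1 plus noise;
- **inhibitor** — a small decline below baseline (kinase inhibition
  depletes the resting lipid pool), window mean ~0.88.

All randomness flows from explicit seeds through ``numpy.random.Generator``;
identical spec + seed gives bit-identical output.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from skimage.draw import ellipse as _draw_ellipse

from .optics import LayerGrid, illumination_profile
from .traces import (
    ImageStack,
    RoiSet,
    TreatmentWindow,
    WINDOW_PRESETS,
    normalize_baseline,
    process_stack,
    window_summary,
)
from .translocation import (
    FIXED_TOTAL,
    RestingState,
    fold_change_curve,
    membrane_ratio,
    solve_delta_m,
    solve_resting_density,
)

__all__ = [
    "KineticParams",
    "NoiseParams",
    "CellGeometry",
    "CohortSpec",
    "ExperimentSpec",
    "GroundTruth",
    "recruitment_curve",
    "render_stack",
    "generate_cohorts",
    "responder_spec",
    "vehicle_spec",
    "inhibitor_spec",
    "default_experiment",
]


@dataclass(frozen=True)
class KineticParams:
    """Single-cell recruitment kinetics.

    Attributes
    ----------
    amplitude : float
        Recruitment scale ``A`` (peak delta_m), molecules per the
        normalized units of the resting state; >= 0.
    delay : float
        Onset delay after treatment application, s.
    rise_tau : float
        Rise time constant, s.
    decay_tau : float
        Relaxation time constant, s (``inf`` for no relaxation).
    plateau_fraction : float
        Fraction of the peak retained at steady state, in (0, 1].
    """

    amplitude: float
    delay: float = 30.0
    rise_tau: float = 60.0
    decay_tau: float = math.inf
    plateau_fraction: float = 1.0

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")
        if self.delay < 0:
            raise ValueError("delay must be >= 0")
        if self.rise_tau <= 0 or self.decay_tau <= 0:
            raise ValueError("time constants must be positive")
        if not (0 < self.plateau_fraction <= 1):
            raise ValueError("plateau_fraction must be in (0, 1]")


def recruitment_curve(params: KineticParams, time: np.ndarray) -> np.ndarray:
    """Evaluate ``delta_m(t)`` for one cell; zero before the onset delay."""
    time = np.asarray(time, dtype=float)
    t = time - params.delay
    rise = -np.expm1(-np.clip(t, 0, None) / params.rise_tau)
    if math.isinf(params.decay_tau) or params.plateau_fraction == 1.0:
        relax = 1.0
    else:
        relax = params.plateau_fraction + (1 - params.plateau_fraction) * np.exp(
            -np.clip(t, 0, None) / params.decay_tau
        )
    curve = params.amplitude * rise * relax
    return np.where(t > 0, curve, 0.0)


@dataclass(frozen=True)
class NoiseParams:
    """Camera noise model: scaled-Poisson photon noise + Gaussian read noise.

    Pixel counts are ``offset + Poisson(photons) + N(0, read_noise_sd)``
    where the mean photon flux is ``background_photons`` everywhere plus
    ``baseline_photons * F(t)`` inside the footprint.  The defaults give a
    per-pixel SNR typical of camera-based TIRF (single-frame per-pixel CV
    ~9% at baseline, so the ~1000-pixel ROI mean is precise to a few
    tenths of a percent).  ``trace_cv`` is the per-frame fractional noise
    of the image-free fast path; it is deliberately larger (1.5%) because
    it stands in for everything the pixel model omits — baseline drift,
    focus fluctuations, cell movement — not just shot noise.  Setting
    ``photon_noise=False`` and ``read_noise_sd=0`` renders exact means.
    """

    baseline_photons: float = 150.0
    background_photons: float = 30.0
    read_noise_sd: float = 3.0
    offset: float = 100.0
    photon_noise: bool = True
    trace_cv: float = 0.015

    def __post_init__(self) -> None:
        if min(self.baseline_photons, self.background_photons, self.offset) < 0:
            raise ValueError("photon levels and offset must be >= 0")
        if self.read_noise_sd < 0 or self.trace_cv < 0:
            raise ValueError("noise magnitudes must be >= 0")

    @classmethod
    def off(cls) -> "NoiseParams":
        return cls(photon_noise=False, read_noise_sd=0.0, trace_cv=0.0)


@dataclass(frozen=True)
class CellGeometry:
    """Elliptical footprint plus a rectangular background region."""

    frame_shape: tuple[int, int] = (96, 96)
    center: tuple[int, int] = (40, 48)
    radii: tuple[int, int] = (16, 20)
    background_rows: tuple[int, int] = (74, 92)
    background_cols: tuple[int, int] = (6, 44)

    def masks(self) -> RoiSet:
        h, w = self.frame_shape
        cy, cx = self.center
        ry, rx = self.radii
        if cy + ry >= h or cx + rx >= w or cy - ry < 0 or cx - rx < 0:
            raise ValueError("cell geometry larger than frame")
        cell = np.zeros(self.frame_shape, dtype=bool)
        rr, cc = _draw_ellipse(cy, cx, ry, rx, shape=self.frame_shape)
        cell[rr, cc] = True
        bg = np.zeros(self.frame_shape, dtype=bool)
        r0, r1 = self.background_rows
        c0, c1 = self.background_cols
        if r1 > h or c1 > w:
            raise ValueError("background region larger than frame")
        bg[r0:r1, c0:c1] = True
        if (cell & bg).any():
            raise ValueError("cell geometry overlaps background region")
        return RoiSet(cell_mask=cell, background_mask=bg)


@dataclass(frozen=True)
class CohortSpec:
    """One experimental condition to simulate.

    Per-cell amplitudes are log-normal with the given median and log-scale
    sigma (right-skewed, matching observed response distributions); a
    median of 0 gives identically zero amplitudes (vehicle).
    ``response_sign = -1`` turns recruitment into depletion (inhibitor
    cohorts fall slightly below baseline).
    """

    condition: str
    n_cells: int
    amplitude_median: float
    amplitude_sigma: float = 1.0
    delay: float = 30.0
    rise_tau: float = 60.0
    decay_tau: float = math.inf
    plateau_fraction: float = 1.0
    response_sign: int = 1
    noise: NoiseParams = field(default_factory=NoiseParams)
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        if self.amplitude_median < 0 or self.amplitude_sigma < 0:
            raise ValueError("amplitude distribution parameters must be >= 0")
        if self.response_sign not in (1, -1):
            raise ValueError("response_sign must be +1 or -1")


def responder_spec(n_cells: int = 100, condition: str = "responder", **kw) -> CohortSpec:
    """Biosensor-responder template: skewed amplitudes, partial relaxation.

    Amplitude log-normal(median 0.56, sigma 1.0) with plateau fraction 0.7
    and 300-s relaxation puts the cohort-mean window fold-change near 1.5
    with pronounced right skew.
    """
    return CohortSpec(
        condition=condition,
        n_cells=n_cells,
        amplitude_median=0.56,
        amplitude_sigma=1.0,
        plateau_fraction=0.7,
        decay_tau=300.0,
        **kw,
    )


def vehicle_spec(n_cells: int = 20, condition: str = "vehicle", **kw) -> CohortSpec:
    """No-treatment template: zero amplitude, fold-change 1 plus noise."""
    return CohortSpec(
        condition=condition,
        n_cells=n_cells,
        amplitude_median=0.0,
        amplitude_sigma=0.0,
        **kw,
    )


def inhibitor_spec(n_cells: int = 60, condition: str = "inhibitor", **kw) -> CohortSpec:
    """Kinase-inhibitor template: slight decline below baseline (~0.88)."""
    return CohortSpec(
        condition=condition,
        n_cells=n_cells,
        amplitude_median=0.16,
        amplitude_sigma=0.1,
        response_sign=-1,
        **kw,
    )


@dataclass(frozen=True)
class GroundTruth:
    """Per-cell generator ground truth.

    ``fold_curve`` is the noiseless fluorescence fold-change trajectory
    ``F(t)`` implied by the kinetics and the layered forward model;
    ``window_fold`` its mean over the experiment's summary window;
    ``r_m`` the membrane ratio obtained by inverting ``window_fold`` under
    the experiment's scenario.
    """

    condition: str
    cell_id: str
    params: KineticParams
    time: np.ndarray
    fold_curve: np.ndarray
    window_fold: float
    r_m: float


@dataclass
class ExperimentSpec:
    """A full simulated experiment: cohorts plus shared optics and timing."""

    cohorts: list[CohortSpec]
    seed: int = 0
    scenario: str = FIXED_TOTAL
    decay: float = 0.008
    layer_thickness: float = 10.0
    n_layers: int = 50
    frame_interval: float = 10.0
    start_time: float = -120.0
    n_frames: int = 73
    baseline_duration: float = 60.0
    window: TreatmentWindow = field(
        default_factory=lambda: WINDOW_PRESETS["akt_ph_late"]
    )

    @property
    def times(self) -> np.ndarray:
        return self.start_time + self.frame_interval * np.arange(self.n_frames)

    def layer_grid(self) -> LayerGrid:
        return illumination_profile(self.decay, self.layer_thickness, self.n_layers)


def default_experiment(seed: int = 0) -> ExperimentSpec:
    """Responder / vehicle / inhibitor cohorts at canonical sizes."""
    return ExperimentSpec(
        cohorts=[responder_spec(100), vehicle_spec(20), inhibitor_spec(60)],
        seed=seed,
    )


def _cohort_rng(spec: CohortSpec, experiment_seed: int, index: int) -> np.random.Generator:
    if spec.seed is not None:
        return np.random.default_rng(spec.seed)
    return np.random.default_rng(np.random.SeedSequence(experiment_seed).spawn(
        index + 1
    )[index])


def _amplitude_ceiling(resting: RestingState, scenario: str, sign: int) -> float:
    # A cell cannot recruit more molecules than the evanescent-field pool
    # holds: under fixed_total the peak delta_m is capped just below N*m
    # (cytosol empty); depletion is capped at the resting layer density.
    if sign < 0:
        return 0.95 * resting.molecules_per_layer * resting.grid.n_layers
    if scenario == FIXED_TOTAL:
        return 0.95 * resting.molecules_per_layer * resting.grid.n_layers
    return math.inf


def _sample_kinetics(
    spec: CohortSpec,
    rng: np.random.Generator,
    max_amplitude: float = math.inf,
) -> list[KineticParams]:
    if spec.amplitude_median == 0:
        amplitudes = np.zeros(spec.n_cells)
    elif spec.amplitude_sigma == 0:
        amplitudes = np.full(spec.n_cells, spec.amplitude_median)
    else:
        amplitudes = rng.lognormal(
            mean=math.log(spec.amplitude_median),
            sigma=spec.amplitude_sigma,
            size=spec.n_cells,
        )
    amplitudes = np.minimum(amplitudes, max_amplitude)
    return [
        KineticParams(
            amplitude=float(a),
            delay=spec.delay,
            rise_tau=spec.rise_tau,
            decay_tau=spec.decay_tau,
            plateau_fraction=spec.plateau_fraction,
        )
        for a in amplitudes
    ]


def _cell_truth(
    condition: str,
    cell_id: str,
    params: KineticParams,
    sign: int,
    resting: RestingState,
    scenario: str,
    times: np.ndarray,
    window: TreatmentWindow,
) -> GroundTruth:
    delta_m_t = sign * recruitment_curve(params, times)
    fold = fold_change_curve(resting, delta_m_t, scenario=scenario)
    window_fold = window_summary(fold, times, window)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        delta_m_w = solve_delta_m(
            window_fold, resting, scenario=scenario, allow_depletion=True
        )
    return GroundTruth(
        condition=condition,
        cell_id=cell_id,
        params=params,
        time=times,
        fold_curve=fold,
        window_fold=window_fold,
        r_m=membrane_ratio(resting, delta_m_w),
    )


def _render_frames(
    fold_curve: np.ndarray,
    rois: RoiSet,
    noise: NoiseParams,
    rng: np.random.Generator,
) -> np.ndarray:
    shape = rois.cell_mask.shape
    n_frames = fold_curve.size
    mean = np.broadcast_to(
        noise.background_photons, (n_frames,) + shape
    ).astype(float).copy()
    mean[:, rois.cell_mask] += noise.baseline_photons * fold_curve[:, None]
    if noise.photon_noise:
        counts = rng.poisson(mean).astype(float)
    else:
        counts = mean
    if noise.read_noise_sd > 0:
        counts = counts + rng.normal(0.0, noise.read_noise_sd, size=counts.shape)
    frames = noise.offset + counts
    # camera ADC clips at zero; with the default offset this never binds
    return np.clip(frames, 0.0, None)


def render_stack(
    spec: CohortSpec,
    grid: LayerGrid | None = None,
    geometry: CellGeometry | None = None,
    scenario: str = FIXED_TOTAL,
    frame_interval: float = 10.0,
    start_time: float = -120.0,
    n_frames: int = 73,
    window: TreatmentWindow | None = None,
) -> list[tuple[ImageStack, RoiSet, GroundTruth]]:
    """Render noisy image stacks for every cell of a cohort.

    Returns one ``(ImageStack, RoiSet, GroundTruth)`` triple per cell.  The
    expectation of the pipeline-processed (ROI mean, background-subtracted,
    baseline-normalized) trace equals the ground-truth ``F(t)``.  The
    cohort seed fully determines the output.
    """
    if grid is None:
        grid = illumination_profile(0.008)
    if geometry is None:
        geometry = CellGeometry()
    if window is None:
        window = WINDOW_PRESETS["akt_ph_late"]
    resting = solve_resting_density(grid)
    rng = np.random.default_rng(spec.seed if spec.seed is not None else 0)
    times = start_time + frame_interval * np.arange(n_frames)
    rois = geometry.masks()
    ceiling = _amplitude_ceiling(resting, scenario, spec.response_sign)
    out = []
    for k, params in enumerate(_sample_kinetics(spec, rng, ceiling)):
        truth = _cell_truth(
            spec.condition,
            f"{spec.condition}_{k:03d}",
            params,
            spec.response_sign,
            resting,
            scenario,
            times,
            window,
        )
        frames = _render_frames(truth.fold_curve, rois, spec.noise, rng)
        stack = ImageStack(
            frames=frames,
            channel_label=spec.condition,
            frame_interval=frame_interval,
            start_time=start_time,
        )
        out.append((stack, rois, truth))
    return out


def generate_cohorts(
    experiment: ExperimentSpec,
    render: bool = False,
    geometry: CellGeometry | None = None,
) -> tuple[pd.DataFrame, list[GroundTruth]]:
    """Simulate an experiment and summarize it with the real pipeline.

    Parameters
    ----------
    experiment
        Cohorts plus shared optics/timing.
    render
        If True, render full image stacks per cell and push them through
        the image pipeline (slower, end-to-end).  If False (default), use
        the trace-level fast path: per-frame multiplicative Gaussian noise
        of CV ``noise.trace_cv`` applied directly to ``F(t)``, then the
        same baseline-normalization and window-summary operations.  The
        fast path bypasses image rendering and is flagged by the
        ``rendered`` column.

    Returns
    -------
    (summary, truths)
        ``summary``: DataFrame with cell_id, condition, summary_value,
        true_value, rendered.  ``truths``: per-cell :class:`GroundTruth`.
    """
    grid = experiment.layer_grid()
    resting = solve_resting_density(grid)
    times = experiment.times
    rows = []
    truths: list[GroundTruth] = []
    for index, spec in enumerate(experiment.cohorts):
        rng = _cohort_rng(spec, experiment.seed, index)
        if render:
            rendered = render_stack(
                replace(spec, seed=int(rng.integers(2**31 - 1))),
                grid=grid,
                geometry=geometry,
                scenario=experiment.scenario,
                frame_interval=experiment.frame_interval,
                start_time=experiment.start_time,
                n_frames=experiment.n_frames,
                window=experiment.window,
            )
            for stack, rois, truth in rendered:
                trace = process_stack(
                    stack, rois, baseline_duration=experiment.baseline_duration
                )
                rows.append(
                    {
                        "cell_id": truth.cell_id,
                        "condition": spec.condition,
                        "summary_value": trace.summary(experiment.window),
                        "true_value": truth.window_fold,
                        "rendered": True,
                    }
                )
                truths.append(truth)
        else:
            ceiling = _amplitude_ceiling(resting, experiment.scenario, spec.response_sign)
            for k, params in enumerate(_sample_kinetics(spec, rng, ceiling)):
                truth = _cell_truth(
                    spec.condition,
                    f"{spec.condition}_{k:03d}",
                    params,
                    spec.response_sign,
                    resting,
                    experiment.scenario,
                    times,
                    experiment.window,
                )
                measured = truth.fold_curve.copy()
                if spec.noise.trace_cv > 0:
                    measured = measured * (
                        1.0 + rng.normal(0.0, spec.noise.trace_cv, size=times.size)
                    )
                normalized = normalize_baseline(
                    measured, times, experiment.baseline_duration
                )
                rows.append(
                    {
                        "cell_id": truth.cell_id,
                        "condition": spec.condition,
                        "summary_value": window_summary(
                            normalized, times, experiment.window
                        ),
                        "true_value": truth.window_fold,
                        "rendered": False,
                    }
                )
                truths.append(truth)
    return pd.DataFrame(rows), truths
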