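"""Synthetic indicator-dilution experiment generator.

Produces gamma-variate bolus curves, frame stacks, and microsphere assay
tables for a one-vessel arcade with three ROIs (D1 distal, D2 middle, D3
proximal reference) across four hemodynamic states (T0-T3), with known
ground-truth regional flows for recovery testing.

Model assumptions (documented, configurable, not claims about any animal):
  * curve amplitude scales linearly with regional flow and time-to-peak
    inversely with it, relative to the D3 reference bolus;
  * bolus arrival is injection time + a systemic lag + a per-ROI arcade
    transit delay;
  * residual dye from repeated injections appears as an additive baseline
    offset that accumulates across successive states;
  * microsphere deposition is Poisson with mean proportional to
    flow x sample weight, the reference sample's mean proportional to the
    withdrawal rate with the same constant.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import defaults
from .errors import ConfigurationError, InvalidInputError
from .image_io_roi import FrameStack, ROIDefinition, TimeIntensityCurve
from .microsphere_flow import MicrosphereAssay, ReferenceSample, TissueSample

__all__ = [
    "BolusParams",
    "ROIPerfusionSpec",
    "AcquisitionConfig",
    "ExperimentConfig",
    "SimulatedExperiment",
    "gamma_variate",
    "simulate_curve",
    "simulate_experiment",
    "simulate_frame_stacks",
    "simulate_microsphere_assay",
    "default_experiment_config",
]


@dataclass(frozen=True)
class BolusParams:
    """Parametric first-passage bolus: gamma-variate kernel plus an optional
    delayed recirculation copy."""

    baseline_level: float = defaults.BOLUS_BASELINE
    amplitude: float = defaults.BOLUS_AMPLITUDE          # A, peak above baseline
    onset_time: float = 0.0                              # t0, arrival at the ROI
    time_to_peak: float = defaults.BOLUS_TIME_TO_PEAK    # t_p, onset -> peak
    shape: float = defaults.BOLUS_SHAPE                  # alpha > 0
    recirculation_fraction: float = defaults.RECIRCULATION_FRACTION
    recirculation_delay: float = defaults.RECIRCULATION_DELAY

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise InvalidInputError("amplitude must be >= 0")
        if self.time_to_peak <= 0:
            raise InvalidInputError("time_to_peak must be > 0")
        if self.shape <= 0:
            raise InvalidInputError("shape must be > 0")
        if self.onset_time < 0:
            raise InvalidInputError("onset_time must be >= 0")
        if not (0 <= self.recirculation_fraction < 1):
            raise InvalidInputError("recirculation_fraction must be in [0, 1)")


@dataclass(frozen=True)
class ROIPerfusionSpec:
    """Position of one ROI on the arcade's flow gradient."""

    roi_name: str
    relative_flow: float        # regional flow / reference (D3) flow
    arrival_delay: float = 0.0  # s, extra transit vs the reference ROI
    pooling_offset: float = 0.0  # a.u. residual-dye baseline per prior injection

    def __post_init__(self) -> None:
        if self.relative_flow <= 0:
            raise InvalidInputError("relative_flow must be > 0")
        if self.arrival_delay < 0:
            raise InvalidInputError("arrival_delay must be >= 0")
        if self.pooling_offset < 0:
            raise InvalidInputError("pooling_offset must be >= 0")


@dataclass(frozen=True)
class AcquisitionConfig:
    frame_rate: float = defaults.FRAME_RATE
    duration: float = defaults.DURATION
    injection_time: float = defaults.INJECTION_TIME
    bit_depth: int = defaults.BIT_DEPTH
    noise_sd: float = defaults.NOISE_SD
    seed: int = 0

    def __post_init__(self) -> None:
        if self.frame_rate <= 0:
            raise InvalidInputError("frame_rate must be > 0")
        if not (0 <= self.injection_time < self.duration):
            raise InvalidInputError("need 0 <= injection_time < duration")
        if self.bit_depth not in (8, 12, 16):
            raise InvalidInputError("bit_depth must be one of 8, 12, 16")
        if self.noise_sd < 0:
            raise InvalidInputError("noise_sd must be >= 0")

    @property
    def n_frames(self) -> int:
        return int(round(self.duration * self.frame_rate))

    @property
    def time_grid(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.frame_rate

    @property
    def ceiling(self) -> int:
        return 2 ** self.bit_depth - 1


@dataclass(frozen=True)
class ExperimentConfig:
    """Full generator configuration for one animal's experiment."""

    roi_specs: tuple[ROIPerfusionSpec, ...]
    state_flow_scales: dict[str, float]
    acquisition: AcquisitionConfig = field(default_factory=AcquisitionConfig)
    bolus: BolusParams = field(default_factory=BolusParams)
    systemic_lag: float = defaults.SYSTEMIC_LAG
    reference_flow: float = defaults.REFERENCE_FLOW  # ml/min/g at rel=scale=1
    seed: int = 0

    def __post_init__(self) -> None:
        names = [s.roi_name for s in self.roi_specs]
        if "D3" not in names:
            raise ConfigurationError("ROI set must include the reference ROI D3")
        if len(set(names)) != len(names):
            raise ConfigurationError(f"duplicate ROI names in {names}")
        for scale in self.state_flow_scales.values():
            if scale <= 0:
                raise ConfigurationError("state flow scales must be > 0")


@dataclass(frozen=True)
class SimulatedExperiment:
    """Curves plus ground truth for all ROIs x states of one experiment."""

    curves: dict[tuple[str, str], TimeIntensityCurve]
    true_flows: dict[tuple[str, str], float]           # ml/min/g
    true_onsets: dict[tuple[str, str], float]          # s, bolus arrival
    microsphere_truth: dict[tuple[str, str], float]    # expected counts
    seed: int
    config: ExperimentConfig

    def __post_init__(self) -> None:
        if set(self.curves) != set(self.true_flows):
            raise InvalidInputError("curves and true_flows must share keys")


def default_experiment_config(seed: int = 0) -> ExperimentConfig:
    """The stock 3-ROI x 4-state configuration with library defaults."""
    specs = tuple(
        ROIPerfusionSpec(roi_name=name, **params)
        for name, params in defaults.ROI_SPECS.items()
    )
    return ExperimentConfig(
        roi_specs=specs,
        state_flow_scales=dict(defaults.STATE_FLOW_SCALES),
        acquisition=AcquisitionConfig(seed=seed),
        seed=seed,
    )


# -------------------------------------------------------------------- kernel


def gamma_variate(t: np.ndarray, p: BolusParams) -> np.ndarray:
    """Evaluate the bolus model on a time grid.

    For ``u = (t - onset_time) / time_to_peak``:

        baseline                                   for u < 0
        baseline + A * u**alpha * exp(alpha*(1-u)) for u >= 0

    normalized so the primary kernel peaks at exactly ``baseline + A`` at
    ``u = 1``.  A recirculation copy (same kernel, scaled by
    ``recirculation_fraction``, delayed by ``recirculation_delay``) is added.
    """
    t = np.asarray(t, dtype=float)
    if t.ndim != 1 or np.any(np.diff(t) <= 0):
        raise InvalidInputError("time grid must be 1-D and monotone increasing")

    def kernel(onset: float) -> np.ndarray:
        u = (t - onset) / p.time_to_peak
        out = np.zeros_like(t)
        pos = u > 0
        up = u[pos]
        out[pos] = p.amplitude * up ** p.shape * np.exp(p.shape * (1.0 - up))
        return out

    y = p.baseline_level + kernel(p.onset_time)
    if p.recirculation_fraction > 0:
        y += p.recirculation_fraction * kernel(p.onset_time + p.recirculation_delay)
    return y


# -------------------------------------------------------------------- curves


def simulate_curve(
    spec: ROIPerfusionSpec,
    state_flow_scale: float,
    acq: AcquisitionConfig,
    bolus: BolusParams | None = None,
    systemic_lag: float = defaults.SYSTEMIC_LAG,
    state_label: str = "",
    pooling_offset: float | None = None,
    rng: np.random.Generator | None = None,
) -> TimeIntensityCurve:
    """Render one ROI's acquired curve for one hemodynamic state.

    Flow (``relative_flow * state_flow_scale``) maps onto the reference bolus
    by amplitude ~ flow and time-to-peak ~ 1/flow; arrival is
    ``injection_time + systemic_lag + arrival_delay``.  Gaussian sensor noise
    is added, then the signal is clipped to the bit-depth range and quantized
    to the integer grid (round half to even, like a frame grabber).
    """
    if state_flow_scale <= 0:
        raise InvalidInputError("state_flow_scale must be > 0")
    bolus = bolus or BolusParams()
    if pooling_offset is None:
        pooling_offset = spec.pooling_offset
    flow = spec.relative_flow * state_flow_scale
    p = BolusParams(
        baseline_level=bolus.baseline_level + pooling_offset,
        amplitude=bolus.amplitude * flow,
        onset_time=acq.injection_time + systemic_lag + spec.arrival_delay,
        time_to_peak=bolus.time_to_peak / flow,
        shape=bolus.shape,
        recirculation_fraction=bolus.recirculation_fraction,
        recirculation_delay=bolus.recirculation_delay,
    )
    y = gamma_variate(acq.time_grid, p)
    if acq.noise_sd > 0:
        if rng is None:
            rng = np.random.default_rng(acq.seed)
        y = y + rng.normal(0.0, acq.noise_sd, size=y.size)
    y = np.clip(y, 0.0, float(acq.ceiling))
    y = np.rint(y)  # round half to even onto the integer grid
    return TimeIntensityCurve(
        times=acq.time_grid,
        intensities=y,
        injection_time=acq.injection_time,
        roi_name=spec.roi_name,
        state_label=state_label,
        ceiling=float(acq.ceiling),
    )


def true_onset_time(
    spec: ROIPerfusionSpec,
    acq: AcquisitionConfig,
    systemic_lag: float = defaults.SYSTEMIC_LAG,
) -> float:
    return acq.injection_time + systemic_lag + spec.arrival_delay


# ---------------------------------------------------------------- experiment


def simulate_experiment(
    config: ExperimentConfig, seed: int | None = None
) -> SimulatedExperiment:
    """All ROIs x states for one animal, with ground truth.

    The residual-dye pooling offset accumulates across successive states
    (state k carries k times the per-injection offset).  Each (roi, state)
    curve draws from its own seed substream, so regeneration with the same
    seed and config is bit-identical.
    """
    if seed is None:
        seed = config.seed
    states = list(config.state_flow_scales)
    n_streams = len(config.roi_specs) * len(states)
    children = np.random.SeedSequence(seed).spawn(n_streams)

    curves: dict[tuple[str, str], TimeIntensityCurve] = {}
    true_flows: dict[tuple[str, str], float] = {}
    true_onsets: dict[tuple[str, str], float] = {}
    microsphere_truth: dict[tuple[str, str], float] = {}
    stream = 0
    for spec in config.roi_specs:
        for k, state in enumerate(states):
            scale = config.state_flow_scales[state]
            rng = np.random.default_rng(children[stream])
            stream += 1
            curves[(spec.roi_name, state)] = simulate_curve(
                spec,
                scale,
                config.acquisition,
                bolus=config.bolus,
                systemic_lag=config.systemic_lag,
                state_label=state,
                pooling_offset=spec.pooling_offset * k,
                rng=rng,
            )
            flow = config.reference_flow * spec.relative_flow * scale
            true_flows[(spec.roi_name, state)] = flow
            true_onsets[(spec.roi_name, state)] = true_onset_time(
                spec, config.acquisition, config.systemic_lag
            )
            microsphere_truth[(spec.roi_name, state)] = (
                defaults.REFERENCE_COUNT_SCALE
                * flow
                * defaults.SAMPLE_WEIGHT
                / defaults.WITHDRAWAL_RATE
            )
    return SimulatedExperiment(
        curves=curves,
        true_flows=true_flows,
        true_onsets=true_onsets,
        microsphere_truth=microsphere_truth,
        seed=seed,
        config=config,
    )


# -------------------------------------------------------------- frame stacks


def simulate_frame_stacks(
    experiment: SimulatedExperiment,
    geometry: dict[str, tuple[int, int, int, int]],
    canvas_shape: tuple[int, int],
    background_level: float = 2.0,
    pixel_noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[dict[str, FrameStack], list[ROIDefinition]]:
    """Render the experiment's curves onto image stacks, one per state.

    ``geometry`` maps ROI name -> half-open rectangle on the canvas; the
    rectangles must be disjoint and inside the canvas.  Every ROI pixel
    follows its ROI's curve plus iid Gaussian pixel noise; background pixels
    sit at a constant dim level.  With ``pixel_noise_sd=0`` the ROI mean of
    the output reproduces the input curve exactly.
    """
    height, width = canvas_shape
    occupancy = np.zeros((height, width), dtype=int)
    rois = []
    for name, rect in geometry.items():
        roi = ROIDefinition(name=name, rect=rect, is_reference=(name == "D3"))
        mask = roi.to_mask(height, width)  # bounds-checked here
        occupancy += mask
        rois.append(roi)
    if occupancy.max() > 1:
        raise ConfigurationError("ROI rectangles overlap")

    acq = experiment.config.acquisition
    states = list(experiment.config.state_flow_scales)
    children = np.random.SeedSequence(seed).spawn(len(states))
    stacks: dict[str, FrameStack] = {}
    for state, child in zip(states, children):
        rng = np.random.default_rng(child)
        frames = np.full(
            (acq.n_frames, height, width), float(background_level)
        )
        for roi in rois:
            curve = experiment.curves[(roi.name, state)]
            mask = roi.to_mask(height, width)
            values = np.repeat(
                curve.intensities[:, None], int(mask.sum()), axis=1
            )
            if pixel_noise_sd > 0:
                values = values + rng.normal(0.0, pixel_noise_sd, values.shape)
            frames[:, mask] = values
        frames = np.rint(np.clip(frames, 0, acq.ceiling)).astype(
            np.uint8 if acq.bit_depth == 8 else np.uint16
        )
        stacks[state] = FrameStack(
            frames=frames,
            frame_rate=acq.frame_rate,
            bit_depth=acq.bit_depth,
            origin_timestamp=0.0,
        )
    return stacks, rois


# ------------------------------------------------------------- microspheres


def simulate_microsphere_assay(
    true_flows: dict[str, float],
    weights: dict[str, float],
    withdrawal_rate: float = defaults.WITHDRAWAL_RATE,
    reference_count_scale: float = defaults.REFERENCE_COUNT_SCALE,
    regions: dict[str, str] | None = None,
    color: str = "crimson",
    poisson_noise: bool = True,
    seed: int = 0,
) -> MicrosphereAssay:
    """Generate one assay table from per-sample ground-truth flows.

    Expected tissue signal is ``reference_count_scale * flow * weight /
    withdrawal_rate`` so that the reference-sample formula inverts exactly on
    noiseless expectations; realized signals are Poisson draws when
    ``poisson_noise`` is set.
    """
    if withdrawal_rate <= 0:
        raise InvalidInputError("withdrawal_rate must be > 0")
    if set(true_flows) != set(weights):
        raise InvalidInputError("true_flows and weights must share sample ids")
    for sid, flow in true_flows.items():
        if flow <= 0 or weights[sid] <= 0:
            raise InvalidInputError(f"sample {sid}: flows and weights must be > 0")

    rng = np.random.default_rng(seed)
    scale = reference_count_scale / withdrawal_rate
    tissue = []
    for sid in sorted(true_flows):
        expected = scale * true_flows[sid] * weights[sid]
        signal = float(rng.poisson(expected)) if poisson_noise else expected
        tissue.append(
            TissueSample(
                sample_id=sid,
                region=(regions or {}).get(sid, sid),
                weight=weights[sid],
                signal=signal,
                color=color,
            )
        )
    ref_expected = reference_count_scale
    ref_signal = float(rng.poisson(ref_expected)) if poisson_noise else ref_expected
    reference = ReferenceSample(
        withdrawal_rate=withdrawal_rate, signal=ref_signal, color=color
    )
    return MicrosphereAssay(tissue=tuple(tissue), reference=reference)
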