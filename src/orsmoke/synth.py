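"""Synthetic operating-room air: cautery plumes with known ground truth.

The generator emulates the measurement context of a real-time PTR-MS
campaign in a laminar-flow operating room so that every downstream stage
(blank subtraction, calibration, summaries, exposure, design statistics) can
be tested against a known truth:

* cautery activations are a homogeneous Poisson process over the operation
  segment; each activation releases a log-normally distributed amplitude per
  compound (heavy-tailed maxima, as observed in OR air);
* each plume decays exponentially with a first-order ventilation clearance
  constant ``k`` (the laminar-flow room, no spatial modelling);
* smoke-evacuation use, measurement location and surgical approach act as
  multiplicative factors on emission amplitude;
* a constant background (anesthetic gases, instrument background) is present
  in every segment; the pre/post blank windows contain background only and
  the calibration window additionally contains a known standard-gas
  concentration;
* the instrument multiplies the true concentration by a per-channel
  sensitivity (``calib_true_factor``) and adds white Gaussian noise.

Identical ``(design, config, seed)`` triples reproduce bit-identical output.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .design import OperationDesign
from .errors import ParameterError
from .registry import CompoundTable
from .signal import IonTimeSeries

__all__ = [
    "SimConfig",
    "SimTruth",
    "randomize_operations",
    "assign_designs",
    "simulate_operation",
    "simulate_breath_pair",
    "config_from_registry",
]

PerChannel = float | Mapping[str, float]


def _resolve(value: PerChannel, channels: Sequence[str], name: str) -> dict[str, float]:
    """Broadcast a scalar, or validate a per-channel mapping, over channels."""
    if isinstance(value, Mapping):
        missing = [c for c in channels if c not in value]
        if missing:
            raise ParameterError(f"{name}: missing channels {missing}")
        return {c: float(value[c]) for c in channels}
    return {c: float(value) for c in channels}


@dataclass(frozen=True)
class SimConfig:
    """Generator parameters; per-compound fields take a scalar or a mapping.

    ``event_rate`` is cautery activations per minute; ``ventilation_rate_k``
    the first-order clearance constant (1/s); ``ses_attenuation``,
    ``room_dilution`` multiply emissions in ``[0, 1]`` when the design says
    ``with_ses`` / ``room_air``; ``open_vs_mis_factor`` multiplies emissions
    for open surgery.  ``calib_true_factor`` is the instrument sensitivity
    (observed = true × factor + noise); ``calib_standard_ppb`` the known
    standard-gas concentration present in the calibration window.
    """

    event_rate: float = 1.0
    emission_mean_ppb: PerChannel = 30.0
    emission_sd_ppb: PerChannel = 30.0
    ventilation_rate_k: float = 0.05
    ses_attenuation: float = 0.5
    room_dilution: float = 0.8
    open_vs_mis_factor: float = 1.3
    background_ppb: PerChannel = 5.0
    noise_sd_ppb: float = 0.5
    calib_true_factor: PerChannel = 1.0
    calib_standard_ppb: PerChannel = 100.0
    sample_period: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.event_rate < 0:
            raise ParameterError("event_rate must be >= 0")
        if self.ventilation_rate_k < 0:
            raise ParameterError("ventilation_rate_k must be >= 0")
        for nm in ("ses_attenuation", "room_dilution"):
            v = getattr(self, nm)
            if not 0.0 <= v <= 1.0:
                raise ParameterError(f"{nm} must lie in [0, 1], got {v}")
        if self.open_vs_mis_factor < 0:
            raise ParameterError("open_vs_mis_factor must be >= 0")
        if self.noise_sd_ppb < 0:
            raise ParameterError("noise_sd_ppb must be >= 0")
        if self.sample_period <= 0:
            raise ParameterError("sample_period must be > 0")


@dataclass
class SimTruth:
    """Ground truth for one simulated record.

    Expected statistics are on the calibrated (true-concentration) scale,
    noise-free, conditional on the realized events, over the operation
    segment.
    """

    op_id: str
    event_times: np.ndarray
    amplitudes: pd.DataFrame
    design_factor: float
    expected_mean_ppb: dict[str, float]
    expected_max_ppb: dict[str, float]
    background_ppb: dict[str, float]
    calib_true_factor: dict[str, float]
    seed: int
    uptake_fractions: dict[str, float] | None = None


def randomize_operations(n: int, block_size: int = 4, seed: int = 0) -> list[str]:
    """Blocked 1:1 randomization of smoke-evacuation use.

    Within every complete block of ``block_size`` operations exactly half
    are assigned ``with_ses``; a trailing partial block is a truncated
    random balanced block.  Reproducible from ``seed``.
    """
    if n < 0:
        raise ParameterError("n must be >= 0")
    if block_size <= 0 or block_size % 2:
        raise ParameterError(f"block_size must be a positive even count, got {block_size}")
    rng = np.random.default_rng(seed)
    out: list[str] = []
    while len(out) < n:
        block = ["with_ses"] * (block_size // 2) + ["without_ses"] * (block_size // 2)
        out.extend(rng.permutation(block).tolist())
    return out[:n]


def assign_designs(
    n: int,
    duration: float,
    block_size: int = 4,
    seed: int = 0,
    room_air_fraction: float = 0.3,
) -> list[OperationDesign]:
    """Designs for ``n`` operations: blocked SES randomization, alternating
    approach (decided before randomization), and a fraction of records
    measured in room air rather than at surgeon level."""
    ses = randomize_operations(n, block_size=block_size, seed=seed)
    rng = np.random.default_rng([seed, 1])
    room = rng.random(n) < room_air_fraction
    return [
        OperationDesign(
            op_id=f"op{i:03d}",
            approach="open" if i % 2 == 0 else "minimally_invasive",
            ses=ses[i],
            location="room_air" if room[i] else "surgeon_level",
            duration=duration,
        )
        for i in range(n)
    ]


def design_factor(design: OperationDesign, config: SimConfig) -> float:
    """Multiplicative emission factor implied by the design's factor levels."""
    f = 1.0
    if design.ses == "with_ses":
        f *= config.ses_attenuation
    if design.location == "room_air":
        f *= config.room_dilution
    if design.approach == "open":
        f *= config.open_vs_mis_factor
    return f


def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    """(mu, sigma) of a log-normal with the given arithmetic mean and sd."""
    if mean <= 0:
        return -np.inf, 0.0
    sigma2 = np.log1p((sd / mean) ** 2)
    return np.log(mean) - sigma2 / 2.0, np.sqrt(sigma2)


def _op_rng(config_seed: int, op_id: str, salt: int = 0) -> np.random.Generator:
    return np.random.default_rng([config_seed & 0x7FFFFFFF, zlib.crc32(op_id.encode()), salt])


def simulate_operation(
    design: OperationDesign,
    config: SimConfig,
    registry: CompoundTable | Sequence[str],
    event_times_override: np.ndarray | None = None,
    amplitudes_override: Mapping[str, Sequence[float]] | None = None,
) -> tuple[IonTimeSeries, SimTruth]:
    """Simulate one operation's observed record and its ground truth.

    The observed concentration at time ``t`` in the operation segment is

    ``(background + f · Σ_{e: t_e ≤ t} A_e · exp(−k (t − t_e))) · s + ε``

    where ``f`` is the design's multiplicative factor, ``s`` the instrument
    sensitivity and ``ε`` white Gaussian noise; blank windows contain
    background only and the calibration window background plus the standard.

    ``event_times_override`` / ``amplitudes_override`` replace the random
    Poisson event times and log-normal amplitudes with fixed values (useful
    for closed-form checks); both must be given together.
    """
    channels = list(registry.names) if isinstance(registry, CompoundTable) else list(registry)
    if not channels:
        raise ParameterError("at least one compound channel required")
    mean = _resolve(config.emission_mean_ppb, channels, "emission_mean_ppb")
    sd = _resolve(config.emission_sd_ppb, channels, "emission_sd_ppb")
    background = _resolve(config.background_ppb, channels, "background_ppb")
    sens = _resolve(config.calib_true_factor, channels, "calib_true_factor")
    standard = _resolve(config.calib_standard_ppb, channels, "calib_standard_ppb")

    rng = _op_rng(config.seed, design.op_id)
    t = np.arange(0.0, design.record_end, config.sample_period)
    op_start, op_end = design.operation_start, design.operation_end
    in_op = (t >= op_start) & (t < op_end)

    if (event_times_override is None) != (amplitudes_override is None):
        raise ParameterError("event_times_override and amplitudes_override go together")
    if event_times_override is not None:
        event_times = np.asarray(event_times_override, dtype=float)
        n_events = event_times.size
        if np.any(event_times < op_start) or np.any(event_times >= op_end):
            raise ParameterError("override event times must fall in the operation segment")
    else:
        n_events = rng.poisson(config.event_rate * design.duration / 60.0)
        event_times = np.sort(rng.uniform(op_start, op_end, size=n_events))
    f = design_factor(design, config)
    k = config.ventilation_rate_k

    # (events × time) first-order decay kernel, zero before each event
    if n_events:
        dt = t[None, :] - event_times[:, None]
        kernel = np.where(dt >= 0.0, np.exp(-k * np.maximum(dt, 0.0)), 0.0)
    else:
        kernel = np.zeros((0, t.size))

    amplitudes = {}
    truth = pd.DataFrame(0.0, index=pd.Index(t, name="time_s"), columns=channels)
    for c in channels:
        if amplitudes_override is not None:
            amps = np.asarray(amplitudes_override[c], dtype=float)
            if amps.size != n_events:
                raise ParameterError(f"{c}: {amps.size} amplitudes for {n_events} events")
        else:
            mu, sigma = _lognormal_params(mean[c], sd[c])
            amps = rng.lognormal(mu, sigma, size=n_events) if np.isfinite(mu) else np.zeros(n_events)
        amplitudes[c] = amps
        plume = amps @ kernel if n_events else np.zeros(t.size)
        truth[c] = background[c] + f * plume

    cal_lo, cal_hi = design.calib_window
    in_cal = (t >= cal_lo) & (t < cal_hi)
    observed = truth.copy()
    for c in channels:
        chan = truth[c].to_numpy().copy()
        chan[~in_op] = background[c]          # blanks: background only
        chan[in_cal] = background[c] + standard[c]
        observed[c] = chan * sens[c]
    if config.noise_sd_ppb > 0:
        observed += rng.normal(0.0, config.noise_sd_ppb, size=observed.shape)

    series = IonTimeSeries(op_id=design.op_id, data=observed, segments=design.segments())
    op_truth = truth.loc[in_op]
    sim_truth = SimTruth(
        op_id=design.op_id,
        event_times=event_times,
        amplitudes=pd.DataFrame(amplitudes),
        design_factor=f,
        expected_mean_ppb={c: float(op_truth[c].mean()) for c in channels},
        expected_max_ppb={c: float(op_truth[c].max()) for c in channels},
        background_ppb=background,
        calib_true_factor=sens,
        seed=config.seed,
    )
    return series, sim_truth


def simulate_breath_pair(
    config: SimConfig,
    uptake_fraction: PerChannel,
    seed: int = 0,
    channels: Sequence[str] = ("Acetaldehyde",),
    duration: float = 600.0,
) -> tuple[IonTimeSeries, IonTimeSeries, SimTruth]:
    """Paired inhale/exhale breath series with known uptake fractions.

    The inhaled expectation per compound is the ambient level at the mask
    (background plus mean emission); the exhaled expectation is the inhaled
    expectation times ``1 − uptake_fraction``, with independent instrument
    noise on both channels.
    """
    channels = list(channels)
    uptake = _resolve(uptake_fraction, channels, "uptake_fraction")
    for c, u in uptake.items():
        if not 0.0 <= u <= 1.0:
            raise ParameterError(f"uptake fraction for {c} must lie in [0, 1], got {u}")
    mean = _resolve(config.emission_mean_ppb, channels, "emission_mean_ppb")
    background = _resolve(config.background_ppb, channels, "background_ppb")

    rng = np.random.default_rng([seed & 0x7FFFFFFF, 0xB12EA7])
    t = np.arange(0.0, duration, config.sample_period)
    segments = {"operation": (0.0, float(duration))}
    inhale_level = {c: background[c] + mean[c] for c in channels}

    def make(levels: Mapping[str, float], op_id: str) -> IonTimeSeries:
        data = pd.DataFrame(
            {c: np.full(t.size, levels[c]) for c in channels},
            index=pd.Index(t, name="time_s"),
        )
        if config.noise_sd_ppb > 0:
            data += rng.normal(0.0, config.noise_sd_ppb, size=data.shape)
        return IonTimeSeries(op_id=op_id, data=data, segments=dict(segments))

    inhale = make(inhale_level, "breath-in")
    exhale = make({c: inhale_level[c] * (1.0 - uptake[c]) for c in channels}, "breath-ex")
    truth = SimTruth(
        op_id="breath",
        event_times=np.empty(0),
        amplitudes=pd.DataFrame(),
        design_factor=1.0,
        expected_mean_ppb=inhale_level,
        expected_max_ppb=inhale_level,
        background_ppb=background,
        calib_true_factor={c: 1.0 for c in channels},
        seed=seed,
        uptake_fractions=uptake,
    )
    return inhale, exhale, truth


def config_from_registry(
    registry: CompoundTable,
    base: SimConfig | None = None,
    amplitude_cv: float = 1.0,
    anesthetics: Sequence[str] = ("Desflurane", "Sevoflurane"),
) -> SimConfig:
    """A :class:`SimConfig` whose stationary plume means track the panel.

    For a homogeneous Poisson process at rate λ (1/s) with mean amplitude Ā
    and clearance ``k``, the stationary plume mean is ``λ·Ā/k``; emission
    means are therefore set to ``avg_ppb · k/λ`` so that simulated
    operation-segment means resemble the panel's average column.  Anesthetic
    carrier gases are treated as pure background (no cautery emission).
    """
    from dataclasses import replace as dc_replace

    base = base or SimConfig()
    lam = base.event_rate / 60.0
    if lam <= 0:
        raise ParameterError("config_from_registry requires a positive event_rate")
    scale = base.ventilation_rate_k / lam
    emission, background = {}, {}
    for rec in registry:
        if rec.name in anesthetics:
            emission[rec.name] = 0.0
            background[rec.name] = rec.avg_ppb_paper
        else:
            emission[rec.name] = rec.avg_ppb_paper * scale
            background[rec.name] = 0.0
    sdmap = {c: amplitude_cv * emission[c] for c in emission}
    return dc_replace(
        base,
        emission_mean_ppb=emission,
        emission_sd_ppb=sdmap,
        background_ppb=background,
    )
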