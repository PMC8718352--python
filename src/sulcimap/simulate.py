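"""Forward simulator for median-nerve SSEP sessions on an ECoG grid.

Generates continuous multichannel recordings with a bipolar-EMG trigger
channel and full ground truth, so every downstream stage (trigger
detection, epoching, Fisher analysis, clustering) is testable without
patient data.

Model
-----
Each stimulation trial adds, per channel, a regional template scaled by a
spatial gain that decays exponentially with distance from a hand-knob-like
source posterior-lateral of the central sulcus (CS):

* posterior (S1):  ``-A_N20 g(t; N20) + A_P25 g(t; P25) + A_P30 g(t; P30)``
* anterior  (M1):  ``+A_P20 g(t; P20) - A_late g(t; P30 + delta)``

with ``g`` a unit-peak Gaussian bump.  The opposite polarity at ~20 ms is
the classical phase reversal across the CS.  An optional broad far-field
bump common to both regions models the shared slow activity that can make
raw anterior/posterior amplitudes overlap; it is weak in the derivative
trace (a bump of width sigma differentiates to amplitude ~A/sigma).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .geometry import GridGeometry, cs_line_x, make_grid_geometry

__all__ = [
    "SimulationParams",
    "GroundTruth",
    "ssep_template",
    "spatial_gain",
    "channel_templates",
    "simulate_session",
]

_COMPONENTS = ("N20", "P20", "P25", "P30")


@dataclass
class SimulationParams:
    """Knobs of the forward model; defaults are the package's reference
    acquisition conditions (0.6 Hz stimulation, 2.4 kHz sampling, 4x8 grid
    at 5 mm pitch crossing the CS)."""

    grid_rows: int = 4
    grid_cols: int = 8
    spacing_mm: float = 5.0
    cs_offset_mm: float = 16.5
    cs_angle_deg: float = 8.0
    source_position: tuple[float, float] = (24.0, 12.0)
    component_latencies_ms: dict = field(
        default_factory=lambda: {"N20": 20.0, "P20": 20.0, "P25": 25.0, "P30": 30.0}
    )
    component_amplitudes_uV: dict = field(
        default_factory=lambda: {"N20": 10.0, "P20": 6.0, "P25": 3.0, "P30": 8.0}
    )
    component_width_ms: float = 2.0
    anterior_late_amp_uV: float = 4.0
    anterior_late_delay_ms: float = 3.0
    shared_amp_uV: float = 10.0
    shared_latency_ms: float = 28.0
    shared_width_ms: float = 5.0
    spatial_decay_mm: float = 15.0
    cs_mixing_mm: float = 0.0
    n_trials: int = 100
    stim_rate_hz: float = 0.6
    noise_sd_uV: float = 1.0
    latency_jitter_ms: float = 0.5
    corrupted_channel_fraction: float = 0.0
    emg_noise_sd_uV: float = 5.0
    sample_rate_hz: float = 2400.0
    seed: int = 0
    expect_crossing: bool = False

    def validate(self) -> None:
        lat = self.component_latencies_ms
        amp = self.component_amplitudes_uV
        missing = set(_COMPONENTS) - set(lat) | set(_COMPONENTS) - set(amp)
        if missing:
            raise ValueError(f"missing component parameters: {sorted(missing)}")
        vals = list(amp.values()) + [self.anterior_late_amp_uV, self.shared_amp_uV]
        if not all(np.isfinite(v) for v in vals):
            raise ValueError("all amplitudes must be finite")
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")
        if not (17.0 <= lat["N20"] <= 25.0):
            raise ValueError("N20 latency must lie in the 17-25 ms search window")
        if not (27.0 <= lat["P30"] <= 40.0):
            raise ValueError("P30 latency must lie in the 27-40 ms search window")
        if self.spatial_decay_mm <= 0:
            raise ValueError("spatial_decay_mm must be > 0")
        if self.stim_rate_hz <= 0 or self.sample_rate_hz <= 0:
            raise ValueError("rates must be > 0")
        if not (0.0 <= self.corrupted_channel_fraction < 1.0):
            raise ValueError("corrupted_channel_fraction must be in [0, 1)")

    def copy(self, **changes) -> "SimulationParams":
        return replace(self, **changes)


@dataclass
class GroundTruth:
    """Per-channel truth of a simulated session."""

    region_labels: np.ndarray                # anterior|posterior|excluded
    cs_line: np.ndarray
    corrupted_channels: np.ndarray           # int indices
    true_latencies_ms: dict
    trigger_samples: np.ndarray = field(default_factory=lambda: np.array([], int))

    def __post_init__(self) -> None:
        self.region_labels = np.asarray(self.region_labels, dtype=object)
        self.corrupted_channels = np.asarray(self.corrupted_channels, dtype=int)
        n = len(self.region_labels)
        if self.corrupted_channels.size and (
            self.corrupted_channels.min() < 0 or self.corrupted_channels.max() >= n
        ):
            raise ValueError("corrupted_channels outside the channel set")


def _bump(t_ms: np.ndarray, center_ms: float, width_ms: float) -> np.ndarray:
    """Unit-peak Gaussian bump."""
    return np.exp(-0.5 * ((t_ms - center_ms) / width_ms) ** 2)


def ssep_template(region: str, params: SimulationParams,
                  time_axis_ms: np.ndarray) -> np.ndarray:
    """Noise-free SSEP waveform (uV) for one cortical region.

    ``time_axis_ms`` is post-stimulus time; it should cover at least
    0-50 ms for the full morphology.  The posterior template carries the
    physiological N20-P25-P30 sequence; the anterior template is the
    phase-reversed P20 followed by a late negativity.
    """
    t = np.asarray(time_axis_ms, dtype=float)
    lat = params.component_latencies_ms
    amp = params.component_amplitudes_uV
    w = params.component_width_ms
    if region == "posterior":
        wave = (
            -amp["N20"] * _bump(t, lat["N20"], w)
            + amp["P25"] * _bump(t, lat["P25"], w)
            + amp["P30"] * _bump(t, lat["P30"], w)
        )
    elif region == "anterior":
        wave = (
            +amp["P20"] * _bump(t, lat["P20"], w)
            - params.anterior_late_amp_uV
            * _bump(t, lat["P30"] + params.anterior_late_delay_ms, w)
        )
    else:
        raise ValueError(f"unknown region label: {region!r}")
    return wave


def _shared_wave(params: SimulationParams, t_ms: np.ndarray) -> np.ndarray:
    """Stimulus-locked slow far-field component, spatially uniform.

    Volume-conducted far-field activity reaches every contact with similar
    amplitude, unlike the regional components that decay away from the
    source; being broad (``shared_width_ms``), it dominates raw traces but
    is ~width-fold weaker in the derivative."""
    if not params.shared_amp_uV:
        return np.zeros_like(np.asarray(t_ms, dtype=float))
    return params.shared_amp_uV * _bump(
        np.asarray(t_ms, dtype=float), params.shared_latency_ms,
        params.shared_width_ms,
    )


def spatial_gain(channel_pos, source_position, spatial_decay_mm: float) -> float:
    """Amplitude gain in (0, 1]: exp(-d / decay) with d the Euclidean
    distance from the channel to the source."""
    if spatial_decay_mm <= 0:
        raise ValueError("spatial_decay_mm must be > 0")
    d = math.dist(tuple(channel_pos), tuple(source_position))
    return math.exp(-d / spatial_decay_mm)


def _channel_gains(params: SimulationParams, geometry: GridGeometry) -> np.ndarray:
    return np.array(
        [
            spatial_gain(pos, params.source_position, params.spatial_decay_mm)
            for pos in geometry.positions_mm
        ]
    )


def _posterior_weights(params: SimulationParams,
                       geometry: GridGeometry) -> np.ndarray:
    """Per-channel posterior mixture weight: a hard switch at the CS line
    when ``cs_mixing_mm`` = 0, otherwise a sigmoid blend in the signed
    distance to the line (volume conduction blurring the morphology
    transition across the sulcus)."""
    y_center = (params.grid_rows - 1) * params.spacing_mm / 2.0
    x_at = cs_line_x(geometry.positions_mm[:, 1], params.cs_offset_mm,
                     params.cs_angle_deg, y_center)
    signed_d = (geometry.positions_mm[:, 0] - x_at) * math.cos(
        math.radians(params.cs_angle_deg)
    )
    if params.cs_mixing_mm > 0:
        return 1.0 / (1.0 + np.exp(-signed_d / params.cs_mixing_mm))
    return (signed_d >= 0).astype(float)


def channel_templates(params: SimulationParams,
                      time_axis_ms: np.ndarray) -> np.ndarray:
    """Expected noiseless per-channel waveform (uV), jitter-free.

    ``gain * (w_post * posterior + (1 - w_post) * anterior) + far-field``;
    this is what trial averaging converges to, and equals
    ``ssep_template(region) * spatial_gain`` channel-wise when mixing and
    the shared far-field are disabled.
    """
    params.validate()
    geometry = make_grid_geometry(
        params.grid_rows, params.grid_cols, params.spacing_mm,
        params.cs_offset_mm, params.cs_angle_deg,
    )
    gains = _channel_gains(params, geometry)
    w_post = _posterior_weights(params, geometry)
    t = np.asarray(time_axis_ms, dtype=float)
    ta = ssep_template("anterior", params, t)
    tp = ssep_template("posterior", params, t)
    sh = _shared_wave(params, t)
    return (
        w_post[:, None] * tp[None, :] + (1.0 - w_post)[:, None] * ta[None, :]
    ) * gains[:, None] + sh[None, :]


def simulate_session(params: SimulationParams):
    """Generate one full stimulation session.

    Returns
    -------
    (TrialRecording, GridGeometry, GroundTruth)
        Continuous grid recording (uV) with an EMG trigger channel,
        the grid geometry with CS annotations, and the ground truth.

    Notes
    -----
    Fully reproducible given ``params.seed``.  Corrupted channels are
    replaced by white noise whose averaged-trace SD is ~20x the clean
    noise floor (continuous SD ``20 * noise_sd * sqrt(n_trials)``), so
    they stay conspicuous after trial averaging.
    """
    from .preprocess import TrialRecording

    params.validate()
    rng = np.random.default_rng(params.seed)

    geometry = make_grid_geometry(
        params.grid_rows, params.grid_cols, params.spacing_mm,
        params.cs_offset_mm, params.cs_angle_deg,
    )
    labels = geometry.region_labels
    if params.expect_crossing and (
        np.all(labels == "anterior") or np.all(labels == "posterior")
    ):
        raise ValueError(
            "CS line does not cross the grid but a crossing was requested"
        )

    fs = params.sample_rate_hz
    n_ch = geometry.n_channels
    pre_s = 0.5
    onsets_s = pre_s + np.arange(params.n_trials) / params.stim_rate_hz
    n_samples = int(round((onsets_s[-1] + 1.0) * fs))
    onset_samples = np.round(onsets_s * fs).astype(int)

    gains = _channel_gains(params, geometry)

    tmpl_len = int(round(0.065 * fs))
    t_rel_ms = np.arange(tmpl_len) / fs * 1000.0

    if params.noise_sd_uV > 0:
        data = rng.normal(0.0, params.noise_sd_uV, size=(n_ch, n_samples))
    else:
        data = np.zeros((n_ch, n_samples))

    jitter = (
        rng.normal(0.0, params.latency_jitter_ms, size=params.n_trials)
        if params.latency_jitter_ms > 0
        else np.zeros(params.n_trials)
    )
    w_post = _posterior_weights(params, geometry)
    for k, s0 in enumerate(onset_samples):
        ta = ssep_template("anterior", params, t_rel_ms - jitter[k])
        tp = ssep_template("posterior", params, t_rel_ms - jitter[k])
        sh = _shared_wave(params, t_rel_ms - jitter[k])
        trial = (
            w_post[:, None] * tp[None, :] + (1.0 - w_post)[:, None] * ta[None, :]
        ) * gains[:, None] + sh[None, :]
        data[:, s0:s0 + tmpl_len] += trial

    # corrupted channels: high-variance noise replacing the signal
    n_bad = int(math.floor(params.corrupted_channel_fraction * n_ch))
    bad = rng.choice(n_ch, size=n_bad, replace=False) if n_bad else np.array([], int)
    if n_bad:
        sd_bad = 20.0 * params.noise_sd_uV * math.sqrt(params.n_trials)
        data[np.sort(bad)] = rng.normal(0.0, sd_bad, size=(n_bad, n_samples))

    emg = (
        rng.normal(0.0, params.emg_noise_sd_uV, size=n_samples)
        if params.emg_noise_sd_uV > 0
        else np.zeros(n_samples)
    )
    emg[onset_samples] += 50.0 * max(params.emg_noise_sd_uV, 1.0)

    recording = TrialRecording(
        data=data,
        emg=emg,
        sample_rate_hz=fs,
        triggers=onset_samples,
        channel_ids=list(geometry.channel_ids),
    )
    truth = GroundTruth(
        region_labels=labels.copy(),
        cs_line=geometry.cs_line.copy(),
        corrupted_channels=np.sort(bad),
        true_latencies_ms=dict(params.component_latencies_ms),
        trigger_samples=onset_samples,
    )
    return recording, geometry, truth
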