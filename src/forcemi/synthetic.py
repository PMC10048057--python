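"""Synthetic ERD-EEG sessions for a three-level-force motor-imagery paradigm.

The generator emulates the session structure of the force-level MI
experiment the package targets: 16 s trials (2 s preparation, 4 s cue,
6 s motor imagery, 4 s rest), nine rounds of 24 trials per session, and
three force classes whose event-related desynchronization (ERD) in the
alpha (13-14 Hz) and beta (24-28 Hz) bands over the contralateral
sensorimotor focus (C3 for right-limb imagery) deepens and spatially
widens with force level.

Signal model per scalp channel, in microvolts:

* 1/f-colored background noise plus a white-noise floor,
* a 50 Hz power-line sinusoid,
* ongoing narrowband oscillations (band-pass-filtered Gaussian noise)
  in each ERD band.

During the MI period the oscillation amplitude on channels near the
focus is multiplied by ``10**(-depth_db/20)`` where the effective depth
ramps up after MI onset, deepens mildly across the MI period (so band
power decreases over time, as ERSP curves of force MI show), and falls
off as a Gaussian of montage distance with a class-specific extent.
Oscillations dominate band power in their own bands, so measured
band-power suppression closely tracks the injected depth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import montage as _montage
from .containers import CLASS_NAMES, RawRecording

__all__ = [
    "TrialTimeline", "ERDSpec", "NoiseSpec", "SessionConfig",
    "generate_trial", "generate_session",
]


@dataclass(frozen=True)
class TrialTimeline:
    """Durations (s) of the four trial periods: prep, cue, MI, rest."""

    prep_s: float = 2.0
    cue_s: float = 4.0
    mi_s: float = 6.0
    rest_s: float = 4.0

    def __post_init__(self) -> None:
        for name in ("prep_s", "cue_s", "mi_s", "rest_s"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")

    @property
    def total_s(self) -> float:
        return self.prep_s + self.cue_s + self.mi_s + self.rest_s

    @property
    def mi_onset_s(self) -> float:
        """Time of MI onset from trial start."""
        return self.prep_s + self.cue_s


@dataclass(frozen=True)
class ERDSpec:
    """Class-dependent ERD structure injected during the MI period.

    ``depth_db_by_class`` are suppression depths in dB (positive numbers;
    class k's band amplitude is scaled by ``10**(-depth/20)`` at the
    focus).  ``spatial_extent_by_class`` are Gaussian falloff scales in
    montage head-radius units.  Both must be non-decreasing across
    classes small -> medium -> large.  ``deepen_frac`` linearly modulates
    the depth from (1-f) to (1+f) of nominal across the MI period, so
    the MI-mean depth stays at nominal while band power decreases with
    time.
    """

    bands: tuple[tuple[float, float], ...] = ((13.0, 14.0), (24.0, 28.0))
    depth_db_by_class: tuple[float, ...] = (2.0, 4.0, 6.0)
    focal_channels: tuple[str, ...] = ("C3",)
    spatial_extent_by_class: tuple[float, ...] = (0.2, 0.35, 0.5)
    onset_ramp_s: float = 0.5
    deepen_frac: float = 0.15
    coherence_extent: float = 0.0

    def __post_init__(self) -> None:
        for lo, hi in self.bands:
            if not (8.0 <= lo < hi <= 30.0):
                raise ValueError("ERD bands must lie within 8-30 Hz")
        depths = np.abs(self.depth_db_by_class)
        if np.any(np.diff(depths) < 0):
            raise ValueError("ERD depth must be non-decreasing with force level")
        if np.any(np.diff(self.spatial_extent_by_class) < 0):
            raise ValueError("spatial extent must be non-decreasing with force level")
        if self.onset_ramp_s < 0 or not (0 <= self.deepen_frac < 1):
            raise ValueError("invalid ramp or deepening parameters")


@dataclass(frozen=True)
class NoiseSpec:
    """Background noise: 1/f exponent and scale, white floor, 50 Hz line,
    and per-band ongoing oscillation amplitudes (all scales are standard
    deviations in microvolts; ``line_amp`` is a sinusoid amplitude)."""

    pink_exponent: float = 1.0
    pink_std: float = 3.0
    white_std: float = 1.0
    line_freq: float = 50.0
    line_amp: float = 2.0
    osc_std: tuple[float, ...] = (3.0, 2.0)


@dataclass(frozen=True)
class SessionConfig:
    """One recording session: rounds x trials with a fixed class per round."""

    channels: tuple[str, ...] = _montage.ALL_CHANNELS
    fs: float = 1000.0
    n_rounds: int = 9
    trials_per_round: int = 24
    round_class_order: tuple[int, ...] = (0, 1, 2, 0, 1, 2, 0, 1, 2)
    noise: NoiseSpec = field(default_factory=NoiseSpec)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fs <= 100:
            raise ValueError("fs must exceed 100 Hz to carry the 50 Hz line and EEG bands")
        if self.n_rounds < 1 or self.trials_per_round < 1:
            raise ValueError("n_rounds and trials_per_round must be positive")
        if len(self.round_class_order) != self.n_rounds:
            raise ValueError("round_class_order must give one class per round")
        if not set(self.round_class_order) <= {0, 1, 2}:
            raise ValueError("classes must be in {0, 1, 2}")

    @property
    def n_channels(self) -> int:
        return len(self.channels)

    @property
    def n_trials(self) -> int:
        return self.n_rounds * self.trials_per_round

    @property
    def scalp_channels(self) -> tuple[str, ...]:
        return tuple(c for c in self.channels if c.upper() not in _montage.EOG_CHANNELS)

    @property
    def eog_channels(self) -> tuple[str, ...]:
        return tuple(c for c in self.channels if c.upper() in _montage.EOG_CHANNELS)


# ---------------------------------------------------------------------------
# noise primitives

def _colored_noise(rng, n_ch, n_samp, fs, exponent, std):
    """Gaussian noise with power spectrum ~ 1/f**exponent, unit-free std."""
    spec = rng.standard_normal((n_ch, n_samp // 2 + 1)) + \
        1j * rng.standard_normal((n_ch, n_samp // 2 + 1))
    freqs = np.fft.rfftfreq(n_samp, 1.0 / fs)
    shape = np.zeros_like(freqs)
    shape[1:] = freqs[1:] ** (-exponent / 2.0)
    x = np.fft.irfft(spec * shape, n=n_samp, axis=-1)
    sd = x.std(axis=-1, keepdims=True)
    sd[sd == 0] = 1.0
    return x / sd * std


def _narrowband_noise(rng, n_ch, n_samp, fs, band, std):
    """Band-limited Gaussian noise (brick-wall in the FFT domain)."""
    spec = rng.standard_normal((n_ch, n_samp // 2 + 1)) + \
        1j * rng.standard_normal((n_ch, n_samp // 2 + 1))
    freqs = np.fft.rfftfreq(n_samp, 1.0 / fs)
    mask = (freqs >= band[0]) & (freqs <= band[1])
    if not mask.any():
        raise ValueError(f"band {band} resolves to no FFT bins at this length")
    x = np.fft.irfft(spec * mask, n=n_samp, axis=-1)
    sd = x.std(axis=-1, keepdims=True)
    sd[sd == 0] = 1.0
    return x / sd * std


def _erd_depth_profile(times, timeline: TrialTimeline, erd: ERDSpec):
    """Fraction of nominal depth at each sample (0 outside the MI period)."""
    t0 = timeline.mi_onset_s
    rel = times - t0
    in_mi = (rel >= 0) & (rel < timeline.mi_s)
    shape = np.zeros_like(times)
    ramp = np.ones_like(times)
    if erd.onset_ramp_s > 0:
        ramp = np.clip(rel / erd.onset_ramp_s, 0.0, 1.0)
    deepen = 1.0 + erd.deepen_frac * (2.0 * rel / timeline.mi_s - 1.0)
    shape[in_mi] = (ramp * deepen)[in_mi]
    # unit mean over MI: the nominal depth is the MI-average suppression (dB)
    mean = shape[in_mi].mean()
    if mean > 0:
        shape[in_mi] /= mean
    return shape


def generate_trial(timeline: TrialTimeline, erd: ERDSpec, klass: int,
                   channels=None, noise: NoiseSpec | None = None,
                   rng: np.random.Generator | None = None,
                   fs: float = 1000.0) -> np.ndarray:
    """Generate one scalp-channel trial, shape (n_channels, n_samples).

    ``channels`` is an ordered list of scalp channel labels (defaults to
    the full 30-channel montage); each must have a montage position.
    ``klass`` is the force class (0=small, 1=medium, 2=large).
    """
    if klass not in (0, 1, 2):
        raise ValueError(f"unknown class {klass!r}; expected 0/1/2 "
                         f"({'/'.join(CLASS_NAMES)})")
    channels = tuple(channels) if channels is not None else _montage.SCALP_CHANNELS
    noise = noise or NoiseSpec()
    rng = rng if rng is not None else np.random.default_rng()

    for foc in erd.focal_channels:
        if foc.upper() not in {c.upper() for c in channels}:
            raise ValueError(f"focal channel {foc!r} absent from montage")

    n_ch = len(channels)
    n_samp = int(round(timeline.total_s * fs))
    times = np.arange(n_samp) / fs

    x = _colored_noise(rng, n_ch, n_samp, fs, noise.pink_exponent, noise.pink_std)
    x += rng.standard_normal((n_ch, n_samp)) * noise.white_std
    if noise.line_amp > 0 and noise.line_freq < fs / 2:
        phase = rng.uniform(0, 2 * np.pi)
        x += noise.line_amp * np.sin(2 * np.pi * noise.line_freq * times + phase)

    # Gaussian spatial falloff from the nearest focal channel
    dists = np.min(
        [_montage.distances_from(foc, channels) for foc in erd.focal_channels],
        axis=0,
    )
    depth = abs(erd.depth_db_by_class[klass])
    sigma = erd.spatial_extent_by_class[klass]
    falloff = np.exp(-dists ** 2 / (2.0 * sigma ** 2))
    profile = _erd_depth_profile(times, timeline, erd)  # (n_samp,)
    # per-channel, per-sample amplitude gain for the oscillatory component
    gain = 10.0 ** (-(depth * falloff[:, None] * profile[None, :]) / 20.0)

    osc_stds = noise.osc_std
    if len(osc_stds) < len(erd.bands):
        osc_stds = tuple(osc_stds) + (osc_stds[-1],) * (len(erd.bands) - len(osc_stds))
    # volume conduction makes neighbouring channels partially coherent:
    # mix a focal source into each channel's own oscillation so that
    # per-channel band power stays std**2 while cross-channel coherence
    # falls off with montage distance
    if erd.coherence_extent > 0:
        coh = np.exp(-dists ** 2 / (2.0 * erd.coherence_extent ** 2))
    else:
        coh = np.zeros(n_ch)
    for band, std in zip(erd.bands, osc_stds):
        source = _narrowband_noise(rng, 1, n_samp, fs, band, 1.0)
        own = _narrowband_noise(rng, n_ch, n_samp, fs, band, 1.0)
        osc = (coh[:, None] * source +
               np.sqrt(1.0 - coh ** 2)[:, None] * own) * std
        x += osc * gain
    return x


def _eog_signals(rng, n_ch, n_samp, fs):
    """Slow, high-amplitude ocular-artifact-like noise for HEOG/VEOG."""
    slow = _colored_noise(rng, n_ch, n_samp, fs, 2.5, 40.0)
    return slow + rng.standard_normal((n_ch, n_samp)) * 2.0


def generate_session(cfg: SessionConfig, timeline: TrialTimeline | None = None,
                     erd: ERDSpec | None = None) -> RawRecording:
    """Generate a continuous session recording with one marker per trial.

    Trials are contiguous 16 s blocks (rest period included), rounds run
    back-to-back, and each event marker sits at the MI-period onset of
    its trial and carries the round's force class.
    """
    timeline = timeline or TrialTimeline()
    erd = erd or ERDSpec()
    rng = np.random.default_rng(cfg.seed)

    scalp = cfg.scalp_channels
    eog = cfg.eog_channels
    n_samp_trial = int(round(timeline.total_s * cfg.fs))
    onset_offset = int(round(timeline.mi_onset_s * cfg.fs))

    blocks, events = [], []
    pos = 0
    for klass in cfg.round_class_order:
        for _ in range(cfg.trials_per_round):
            trial = generate_trial(timeline, erd, int(klass), scalp,
                                   cfg.noise, rng, cfg.fs)
            if eog:
                trial = np.vstack([trial, _eog_signals(rng, len(eog),
                                                       n_samp_trial, cfg.fs)])
            blocks.append(trial.astype(np.float32))
            events.append((pos + onset_offset, int(klass)))
            pos += n_samp_trial

    order = list(scalp) + list(eog)
    # restore the configured channel order (EOG may be interleaved in cfg)
    perm = [order.index(c) for c in cfg.channels]
    signals = np.concatenate(blocks, axis=1)[perm]
    return RawRecording(
        signals=signals,
        fs=cfg.fs,
        channel_labels=list(cfg.channels),
        events=np.array(events, dtype=np.int64),
    )
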