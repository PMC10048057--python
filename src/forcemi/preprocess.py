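"""Preprocessing chain for force-MI EEG.

Stages, in the order applied by :func:`preprocess_recording`:

1. bilateral-mastoid re-reference (skipped with a warning if the mastoid
   channels are not in the recording),
2. 0.5-100 Hz band-pass and 50 Hz notch,
3. common average reference (CAR) over scalp channels,
4. 8-30 Hz FIR band-pass (the sensorimotor mu/beta range),
5. downsampling to 128 Hz,
6. removal of the HEOG/VEOG ocular channels,
7. epoching around the MI-period onset,
8. per-trial z-normalization.

All filters are odd-length Hamming-windowed-sinc FIR kernels applied by
centered FFT convolution; a symmetric kernel aligned on its center tap
has exactly zero phase, so filtering introduces no time shift relative
to the event markers.
"""

from __future__ import annotations

import warnings
from fractions import Fraction

import numpy as np
from scipy import signal as sps

from .containers import RawRecording, TrialSet
from .montage import EOG_CHANNELS

DEFAULT_MASTOIDS = ("M1", "M2")
TARGET_FS = 128.0


# ---------------------------------------------------------------------------
# FIR helpers

def _odd_numtaps(fs: float, transition_hz: float) -> int:
    """Hamming-window FIR length for a given transition width (~3.3/Δf)."""
    n = int(np.ceil(3.3 * fs / transition_hz))
    return n + 1 if n % 2 == 0 else n


def _fir_zero_phase(x: np.ndarray, taps: np.ndarray) -> np.ndarray:
    """Apply a symmetric odd-length FIR with zero phase ('same' alignment)."""
    assert len(taps) % 2 == 1
    return sps.fftconvolve(x, taps[None, :], mode="same", axes=-1)


def rereference_mastoid(rec: RawRecording,
                        mastoid_labels=DEFAULT_MASTOIDS) -> RawRecording:
    """Subtract the mean of the two mastoid channels from every channel.

    The mastoid channels themselves are retained (they become
    half-difference signals carrying no common reference information).
    """
    idx = []
    for lab in mastoid_labels:
        if lab not in rec.channel_labels:
            raise KeyError(f"mastoid channel {lab!r} not in recording")
        idx.append(rec.channel_index(lab))
    ref = rec.signals[idx].mean(axis=0)
    return rec.copy_with(signals=rec.signals - ref[None, :])


def filter_chain(rec: RawRecording) -> RawRecording:
    """0.5-100 Hz band-pass followed by a 50 Hz notch, both zero-phase.

    The band-pass is realized as a 0.5 Hz high-pass (0.5 Hz transition)
    cascaded with a 100 Hz low-pass (5 Hz transition); the notch is a
    49-51 Hz band-stop.
    """
    fs = rec.fs
    if fs <= 200:
        raise ValueError(f"fs={fs} too low for a 100 Hz band edge")
    hp = sps.firwin(_odd_numtaps(fs, 0.5), 0.5, pass_zero=False, fs=fs,
                    window="hamming")
    lp = sps.firwin(_odd_numtaps(fs, 5.0), 100.0, pass_zero=True, fs=fs,
                    window="hamming")
    notch = sps.firwin(_odd_numtaps(fs, 2.0), [49.0, 51.0], pass_zero=True,
                       fs=fs, window="hamming")
    x = _fir_zero_phase(rec.signals, hp)
    x = _fir_zero_phase(x, lp)
    x = _fir_zero_phase(x, notch)
    return rec.copy_with(signals=x)


def car(rec: RawRecording, exclude=()) -> RawRecording:
    """Common average reference over all channels not in ``exclude``.

    Excluded channels (ocular, mastoid) neither contribute to nor
    receive the average.
    """
    excl = {e.upper() for e in exclude}
    included = [i for i, lab in enumerate(rec.channel_labels)
                if lab.upper() not in excl]
    if len(included) < 2:
        raise ValueError("CAR needs at least two included channels")
    x = rec.signals.copy()
    mean = x[included].mean(axis=0)
    x[included] -= mean[None, :]
    return rec.copy_with(signals=x)


def mi_bandpass(rec: RawRecording) -> RawRecording:
    """Zero-phase 8-30 Hz FIR band-pass (5 Hz transition width)."""
    fs = rec.fs
    if fs <= 60:
        raise ValueError(f"fs={fs} too low for a 30 Hz band edge")
    bp = sps.firwin(_odd_numtaps(fs, 5.0), [8.0, 30.0], pass_zero=False,
                    fs=fs, window="hamming")
    return rec.copy_with(signals=_fir_zero_phase(rec.signals, bp))


def downsample(rec: RawRecording, target_fs: float = TARGET_FS) -> RawRecording:
    """Polyphase resampling to ``target_fs``; event onsets are rescaled."""
    if target_fs >= rec.fs:
        raise ValueError("target_fs must be below the current rate")
    frac = Fraction(target_fs / rec.fs).limit_denominator(10000)
    x = sps.resample_poly(rec.signals, frac.numerator, frac.denominator, axis=-1)
    events = rec.events.copy()
    if events.size:
        events[:, 0] = np.rint(events[:, 0] * (target_fs / rec.fs)).astype(np.int64)
    return rec.copy_with(signals=x, fs=float(target_fs), events=events)


def drop_eog(rec: RawRecording, eog_labels=EOG_CHANNELS) -> RawRecording:
    """Remove ocular channels, preserving the order of the rest."""
    eog = {e.upper() for e in eog_labels}
    keep = [i for i, lab in enumerate(rec.channel_labels)
            if lab.upper() not in eog]
    if len(keep) == rec.n_channels:
        warnings.warn("no EOG channels found; recording unchanged",
                      stacklevel=2)
        return rec.copy_with(signals=rec.signals.copy())
    return rec.copy_with(
        signals=rec.signals[keep],
        channel_labels=[rec.channel_labels[i] for i in keep],
    )


def epoch(rec: RawRecording, window: tuple[float, float] = (0.0, 6.0)) -> TrialSet:
    """Cut one epoch per event, ``window`` in seconds around MI onset."""
    start_s, end_s = window
    if end_s <= start_s:
        raise ValueError("epoch window must have positive length")
    n_t = int(round((end_s - start_s) * rec.fs))
    offset = int(round(start_s * rec.fs))
    trials, labels = [], []
    for i, (onset, klass) in enumerate(rec.events):
        a = onset + offset
        b = a + n_t
        if a < 0 or b > rec.n_samples:
            raise ValueError(
                f"epoch window {window} for trial {i} (onset sample {onset}) "
                f"exceeds recording bounds")
        trials.append(rec.signals[:, a:b])
        labels.append(klass)
    return TrialSet(
        data=np.stack(trials) if trials else
        np.empty((0, rec.n_channels, n_t)),
        labels=np.asarray(labels, dtype=np.int64),
        fs=rec.fs,
        window=(float(start_s), float(end_s)),
        channel_labels=list(rec.channel_labels),
    )


def normalize(trials: TrialSet, per_channel: bool = False) -> TrialSet:
    """Per-trial z-normalization: x* = (x - mu) / sigma.

    By default a single scalar mean and (population) standard deviation
    is computed over all channels and time points of each trial; with
    ``per_channel=True`` each channel is standardized separately.
    """
    x = trials.data.astype(np.float64, copy=True)
    axes = (2,) if per_channel else (1, 2)
    mu = x.mean(axis=axes, keepdims=True)
    sigma = x.std(axis=axes, keepdims=True)  # population (ddof=0)
    if np.any(sigma <= 0):
        bad = int(np.argwhere(~(sigma > 0))[0][0])
        raise ValueError(f"trial {bad} has zero variance; cannot normalize")
    return TrialSet((x - mu) / sigma, trials.labels, trials.fs,
                    trials.window, list(trials.channel_labels))


def preprocess_recording(rec: RawRecording,
                         window: tuple[float, float] = (0.0, 6.0),
                         mastoid_labels=DEFAULT_MASTOIDS,
                         target_fs: float = TARGET_FS,
                         do_normalize: bool = True,
                         per_channel_norm: bool = False) -> TrialSet:
    """Run the full chain from continuous recording to model-ready trials."""
    if all(m in rec.channel_labels for m in mastoid_labels):
        rec = rereference_mastoid(rec, mastoid_labels)
    else:
        warnings.warn("mastoid channels absent; skipping re-reference",
                      stacklevel=2)
    rec = filter_chain(rec)
    rec = car(rec, exclude=tuple(EOG_CHANNELS) + tuple(mastoid_labels))
    rec = mi_bandpass(rec)
    rec = downsample(rec, target_fs)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # EOG-free input is fine here
        rec = drop_eog(rec)
    trials = epoch(rec, window)
    if do_normalize:
        trials = normalize(trials, per_channel=per_channel_norm)
    return trials
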