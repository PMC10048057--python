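"""Event-related spectral perturbation (ERSP) via the short-time FFT.

The ERSP of a channel is the trial-average of the magnitude-squared
STFT, expressed in dB relative to the pre-MI baseline: with trial
spectrograms ``|F_k(f,t)|^2`` averaged to ``P(f,t)``,

    ERSP_db(f, t) = 10 * log10( P(f, t) / B(f) ),

where ``B(f)`` summarizes ``P`` over the baseline second before MI
onset (-1..0 s).  ``baseline_stat`` selects the arithmetic time-mean of
baseline power (classical divisive baseline, default) or the geometric
mean, which makes the baseline columns average to exactly 0 dB.

Negative dB during the MI period is event-related desynchronization
(ERD); the defaults (1 s Hann window, 16-sample hop at 128 Hz) give
1 Hz frequency resolution, enough to resolve the 13-14 Hz band.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal.windows import hann

from .containers import TrialSet

DEFAULT_WINDOW_S = 1.0
DEFAULT_OVERLAP = 0.875
BASELINE_WINDOW = (-1.0, 0.0)


@dataclass
class Spectrogram:
    """Magnitude-squared STFT of one signal: power (freq x time), PSD scale."""

    power: np.ndarray
    freqs: np.ndarray
    times: np.ndarray
    edge_flags: np.ndarray  # True where the window support crossed an edge

    def __post_init__(self) -> None:
        assert self.power.shape == (len(self.freqs), len(self.times))


@dataclass
class ERSPMap:
    """Baseline-relative dB power for one channel (freq x time)."""

    db: np.ndarray
    freqs: np.ndarray
    times: np.ndarray
    n_trials: int
    channel: str
    baseline_window: tuple[float, float] = BASELINE_WINDOW
    edge_flags: np.ndarray | None = None

    def to_long_frame(self, klass: int | None = None) -> pd.DataFrame:
        """Long-format table (channel, class, freq, time, db) for export."""
        ff, tt = np.meshgrid(self.freqs, self.times, indexing="ij")
        return pd.DataFrame({
            "channel": self.channel,
            "class": -1 if klass is None else int(klass),
            "freq": ff.ravel(),
            "time": tt.ravel(),
            "db": self.db.ravel(),
        })


def stft(x: np.ndarray, fs: float, window_s: float = DEFAULT_WINDOW_S,
         overlap_frac: float = DEFAULT_OVERLAP,
         t0: float = 0.0) -> Spectrogram:
    """Hann-windowed magnitude-squared STFT of a 1-D signal.

    Columns are centered every ``hop = window*(1-overlap)`` samples over
    the whole signal; edge columns use reflection padding and are
    flagged.  ``t0`` is the time of sample 0 (s).  Power is scaled as a
    one-sided power spectral density.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValueError("stft expects a single-channel 1-D signal")
    nw = int(round(window_s * fs))
    if nw < 8:
        raise ValueError("window too short: need at least 8 samples")
    if x.size < nw:
        raise ValueError(f"signal ({x.size}) shorter than window ({nw})")
    if not 0 <= overlap_frac < 1:
        raise ValueError("overlap_frac must lie in [0, 1)")
    hop = max(1, int(round(nw * (1.0 - overlap_frac))))

    win = hann(nw, sym=False)
    half = nw // 2
    xp = np.pad(x, half, mode="reflect")
    centers = np.arange(0, x.size, hop)
    segs = np.stack([xp[c:c + nw] for c in centers])
    spec = np.fft.rfft(segs * win[None, :], axis=1)
    power = (np.abs(spec) ** 2).T / (fs * np.sum(win ** 2))
    if nw % 2 == 0:
        power[1:-1] *= 2.0  # one-sided PSD
    else:
        power[1:] *= 2.0
    freqs = np.fft.rfftfreq(nw, 1.0 / fs)
    times = t0 + centers / fs
    edge = (centers - half < 0) | (centers + (nw - half) > x.size)
    return Spectrogram(power=power, freqs=freqs, times=times, edge_flags=edge)


def ersp_map(trials: TrialSet, channel: str,
             window_s: float = DEFAULT_WINDOW_S,
             overlap_frac: float = DEFAULT_OVERLAP,
             baseline: tuple[float, float] = BASELINE_WINDOW,
             baseline_stat: str = "mean") -> ERSPMap:
    """Trial-averaged ERSP (dB) of one channel.

    The epoch window of ``trials`` must contain the baseline interval;
    restrict ``trials`` to a single class first if a per-class map is
    wanted.
    """
    if trials.n_trials < 1:
        raise ValueError("need at least one trial")
    if trials.window[0] > baseline[0] or trials.window[1] < baseline[1]:
        raise ValueError(
            f"epoch window {trials.window} does not contain baseline {baseline}")
    if baseline_stat not in ("mean", "gmean"):
        raise ValueError("baseline_stat must be 'mean' or 'gmean'")
    ci = trials.channel_index(channel)

    mean_power = None
    ref = None
    for k in range(trials.n_trials):
        spec = stft(trials.data[k, ci], trials.fs, window_s, overlap_frac,
                    t0=trials.window[0])
        if mean_power is None:
            mean_power = np.zeros_like(spec.power)
            ref = spec
        mean_power += spec.power
    mean_power /= trials.n_trials

    in_base = (ref.times >= baseline[0]) & (ref.times < baseline[1])
    # edge columns mix reflection-padded samples whose mirror correlation
    # biases narrowband power; keep them out of the baseline statistic
    if (in_base & ~ref.edge_flags).any():
        in_base &= ~ref.edge_flags
    if not in_base.any():
        raise ValueError("no STFT columns fall inside the baseline window")
    base_cols = mean_power[:, in_base]
    if np.any(base_cols <= 0):
        raise ValueError("zero baseline power at some frequency")
    if baseline_stat == "mean":
        b = base_cols.mean(axis=1)
    else:
        b = np.exp(np.log(base_cols).mean(axis=1))
    with np.errstate(divide="raise"):
        db = 10.0 * np.log10(mean_power / b[:, None])
    return ERSPMap(db=db, freqs=ref.freqs, times=ref.times,
                   n_trials=trials.n_trials, channel=channel,
                   baseline_window=tuple(baseline), edge_flags=ref.edge_flags)


def band_curve(emap: ERSPMap, band: tuple[float, float]) -> np.ndarray:
    """Time series of dB averaged over the rows with lo <= f <= hi."""
    lo, hi = band
    rows = (emap.freqs >= lo) & (emap.freqs <= hi)
    if not rows.any():
        raise ValueError(f"band {band} selects no frequency rows")
    return emap.db[rows].mean(axis=0)


def band_window_mean(emap: ERSPMap, band: tuple[float, float],
                     time_window: tuple[float, float] = (0.0, 6.0)) -> float:
    """Scalar mean dB over a band and time window (e.g. the MI period)."""
    cols = (emap.times >= time_window[0]) & (emap.times < time_window[1])
    if not cols.any():
        raise ValueError(f"time window {time_window} selects no columns")
    return float(band_curve(emap, band)[cols].mean())


def channel_band_power(trials: TrialSet, band: tuple[float, float],
                       time_window: tuple[float, float] = (0.0, 6.0),
                       **stft_kwargs) -> pd.Series:
    """Per-channel mean ERSP (dB) in a band over a time window.

    Returns a Series indexed by channel label, ready for topographic
    display: the most negative entries mark the ERD focus.
    """
    values = {}
    for lab in trials.channel_labels:
        emap = ersp_map(trials, lab, **stft_kwargs)
        values[lab] = band_window_mean(emap, band, time_window)
    return pd.Series(values, name=f"ersp_db_{band[0]}-{band[1]}Hz")


def plot_ersp_map(emap: ERSPMap, ax=None, vmin=None, vmax=None):
    """Minimal time-frequency image of an ERSP map (requires matplotlib)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    limit = vmax if vmax is not None else np.abs(emap.db).max()
    im = ax.pcolormesh(emap.times, emap.freqs, emap.db, cmap="RdBu_r",
                       vmin=vmin if vmin is not None else -limit, vmax=limit)
    ax.set_xlabel("time (s, MI onset = 0)")
    ax.set_ylabel("frequency (Hz)")
    ax.figure.colorbar(im, ax=ax, label="ERSP (dB)")
    return ax
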