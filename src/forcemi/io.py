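"""Reading and writing recordings as EDF+ and HDF5.

EDF reading is delegated to MNE.  Writing uses a small built-in EDF+
serializer (16-bit samples, one annotation channel carrying the trial
markers) so simulated sessions can be exchanged with standard EEG tools;
the writer is intentionally minimal: integer sampling rates, continuous
recordings ('EDF+C') only.
"""

from __future__ import annotations

import datetime
import math

import numpy as np

from .containers import RawRecording

_HEADER_DATE = "01.01.00"  # fixed date: simulated data carry no real clock


def _pad(text: str, width: int) -> bytes:
    b = text.encode("ascii")
    if len(b) > width:
        raise ValueError(f"EDF header field too long: {text!r} > {width}")
    return b.ljust(width)


def _annotation_payloads(rec: RawRecording, n_records: int) -> list[bytes]:
    """Per-record EDF+ TAL byte strings (timekeeping TAL + event TALs)."""
    by_record: dict[int, list[bytes]] = {}
    for onset, label in rec.events:
        t = onset / rec.fs
        r = min(int(t), n_records - 1)
        tal = f"+{t:.4f}\x15{0:.4f}\x14class{int(label)}\x14\x00".encode("ascii")
        by_record.setdefault(r, []).append(tal)
    payloads = []
    for r in range(n_records):
        keep = b"".join(by_record.get(r, []))
        payloads.append(f"+{r}\x14\x14\x00".encode("ascii") + keep)
    return payloads


def write_edf(rec: RawRecording, path) -> None:
    """Write a recording to EDF+ with events as annotations.

    Samples are quantized to 16 bits over each channel's observed range;
    the sampling rate must be an integer number of Hz.
    """
    fs = rec.fs
    if abs(fs - round(fs)) > 1e-9:
        raise ValueError("EDF writer requires an integer sampling rate")
    spr = int(round(fs))  # samples per 1 s data record, per signal
    n_records = max(1, math.ceil(rec.n_samples / spr))

    sig = np.asarray(rec.signals, dtype=float)
    pad = n_records * spr - rec.n_samples
    if pad:
        sig = np.pad(sig, ((0, 0), (0, pad)))

    # per-channel physical scaling onto the full 16-bit digital range
    phys_min = sig.min(axis=1)
    phys_max = sig.max(axis=1)
    span = phys_max - phys_min
    flat = span <= 0
    phys_min[flat] -= 1.0
    phys_max[flat] += 1.0
    dig_min, dig_max = -32768, 32767
    gain = (dig_max - dig_min) / (phys_max - phys_min)
    digital = np.rint((sig - phys_min[:, None]) * gain[:, None] + dig_min)
    digital = np.clip(digital, dig_min, dig_max).astype("<i2")

    tals = _annotation_payloads(rec, n_records)
    ann_bytes = max(max(len(t) for t in tals), 2 * spr)
    ann_bytes += ann_bytes % 2  # even byte count = whole 2-byte samples
    ann_spr = ann_bytes // 2

    ns = rec.n_channels + 1
    header_bytes = 256 * (1 + ns)
    record_bytes = 2 * (rec.n_channels * spr + ann_spr)

    with open(path, "wb") as f:
        f.write(_pad("0", 8))
        f.write(_pad("X X X X", 80))                      # local patient id
        f.write(_pad("Startdate X X X X", 80))            # local recording id
        f.write(_pad(_HEADER_DATE, 8))
        f.write(_pad("00.00.00", 8))
        f.write(_pad(str(header_bytes), 8))
        f.write(_pad("EDF+C", 44))
        f.write(_pad(str(n_records), 8))
        f.write(_pad("1", 8))                             # record duration s
        f.write(_pad(str(ns), 4))

        labels = list(rec.channel_labels) + ["EDF Annotations"]
        for lab in labels:
            f.write(_pad(lab, 16))
        for _ in labels:
            f.write(_pad("", 80))                         # transducer
        for i in range(ns):
            f.write(_pad("uV" if i < rec.n_channels else "", 8))
        for i in range(ns):
            f.write(_pad(f"{phys_min[i]:.6g}" if i < rec.n_channels else "-1", 8))
        for i in range(ns):
            f.write(_pad(f"{phys_max[i]:.6g}" if i < rec.n_channels else "1", 8))
        for i in range(ns):
            f.write(_pad(str(dig_min), 8))
        for i in range(ns):
            f.write(_pad(str(dig_max), 8))
        for _ in labels:
            f.write(_pad("", 80))                         # prefiltering
        for i in range(ns):
            f.write(_pad(str(spr if i < rec.n_channels else ann_spr), 8))
        for _ in labels:
            f.write(_pad("", 32))                         # reserved

        for r in range(n_records):
            block = digital[:, r * spr:(r + 1) * spr].tobytes()
            ann = tals[r].ljust(ann_bytes, b"\x00")
            f.write(block)
            f.write(ann)
            assert len(block) + len(ann) == record_bytes


def read_edf(path) -> RawRecording:
    """Read an EDF/EDF+ file into a :class:`RawRecording` (microvolts)."""
    import mne

    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    signals = raw.get_data() * 1e6  # MNE returns volts
    events = []
    for onset, desc in zip(raw.annotations.onset, raw.annotations.description):
        if desc.startswith("class"):
            events.append((int(round(onset * raw.info["sfreq"])),
                           int(desc.removeprefix("class"))))
    return RawRecording(
        signals=signals,
        fs=float(raw.info["sfreq"]),
        channel_labels=list(raw.ch_names),
        events=np.array(sorted(events), dtype=np.int64).reshape(-1, 2),
    )


def load_recording(path) -> RawRecording:
    """Load a recording from either EDF (.edf) or the HDF5 container."""
    p = str(path)
    if p.lower().endswith(".edf"):
        return read_edf(p)
    return RawRecording.from_hdf5(p)
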