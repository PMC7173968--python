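"""Recording and hypnogram I/O, band-pass filtering, and 4-s epoch segmentation.

Conventions used throughout the package:

* clock times are stored as seconds from midnight (float);
* epoch indices are 0-based and sample windows are half-open:
  epoch ``k`` covers samples ``[k*L, (k+1)*L)`` with ``L = epoch_len * fs``;
* the epoch grid is anchored at sample 0 of the recording.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.signal import butter, sosfiltfilt

logger = logging.getLogger(__name__)

STATES = ("W", "NR", "R", "C", "D")

#: fraction of Nyquist at which a requested band edge is capped
NYQUIST_CAP = 0.98

EEG_BAND = (1.5, 30.0)   # hardware EEG pass band, Hz
EMG_BAND = (15.0, 300.0)  # hardware EMG pass band, Hz (capped at Nyquist digitally)


def parse_clock(value) -> float:
    """Convert ``"HH:MM"``/``"HH:MM:SS"`` or a number to seconds from midnight."""
    if isinstance(value, str):
        parts = [float(p) for p in value.split(":")]
        while len(parts) < 3:
            parts.append(0.0)
        h, m, s = parts[:3]
        return h * 3600.0 + m * 60.0 + s
    return float(value)


def format_clock(seconds: float) -> str:
    s = int(round(seconds)) % 86400
    return f"{s // 3600:02d}:{(s // 60) % 60:02d}:{s % 60:02d}"


def is_light(clock_s, lights_on: float, lights_off: float):
    """True where a clock time (seconds from midnight) falls in the light phase.

    Handles schedules that wrap midnight (e.g. lights on 20:00-8:00).
    """
    t = np.asarray(clock_s) % 86400.0
    if lights_on <= lights_off:
        return (t >= lights_on) & (t < lights_off)
    return (t >= lights_on) | (t < lights_off)


@dataclass
class Recording:
    """Two-channel polysomnography recording (EEG + EMG), amplitudes in µV."""

    eeg: np.ndarray
    emg: np.ndarray
    fs: float = 128.0
    start_clock: float = 72000.0  # 20:00, dark onset
    lights_on: float = 28800.0    # 8:00
    lights_off: float = 72000.0   # 20:00

    def __post_init__(self):
        self.eeg = np.asarray(self.eeg, dtype=float)
        self.emg = np.asarray(self.emg, dtype=float)
        if self.eeg.shape != self.emg.shape:
            raise ValueError("EEG and EMG must have the same length")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if self.lights_on == self.lights_off:
            raise ValueError("lights_on and lights_off must differ")

    @property
    def n_samples(self) -> int:
        return self.eeg.shape[0]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs


@dataclass
class EpochSeries:
    """Contiguous non-overlapping fixed-length windows of a recording."""

    eeg_epochs: np.ndarray  # (n_epochs, L)
    emg_epochs: np.ndarray  # (n_epochs, L)
    epoch_len: float
    fs: float
    epoch_clock: np.ndarray  # clock time (s from midnight) of each epoch start
    phase: np.ndarray        # 'light' | 'dark' per epoch
    dropped_samples: int = 0

    @property
    def n_epochs(self) -> int:
        return self.eeg_epochs.shape[0]


def bandpass(signal, fs: float, low: float, high: float):
    """Zero-phase Butterworth band-pass (order 4, applied forward-backward).

    ``high`` is capped at ``0.98 * fs / 2`` when it reaches Nyquist, mirroring
    what happens when an analog front-end band exceeds the digital bandwidth.
    """
    x = np.asarray(signal, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("signal contains non-finite samples")
    nyq = fs / 2.0
    if not (0 < low < high):
        raise ValueError("need 0 < low < high")
    if low >= nyq:
        raise ValueError("low edge at or above Nyquist")
    eff_high = min(high, NYQUIST_CAP * nyq)
    if eff_high != high:
        logger.info("band edge %.6g Hz capped at %.6g Hz (fs=%g)", high, eff_high, fs)
    sos = butter(4, [low, eff_high], btype="bandpass", fs=fs, output="sos")
    return sosfiltfilt(sos, x)


def effective_band(fs: float, low: float, high: float) -> tuple[float, float]:
    """The digitally realizable band for a requested analog band."""
    return (low, min(high, NYQUIST_CAP * fs / 2.0))


def epoch_segment(rec: Recording, epoch_len: float = 4.0) -> EpochSeries:
    """Cut a recording into contiguous ``epoch_len``-second windows.

    The trailing remainder (if the duration is not a multiple of the epoch
    length) is dropped and logged.
    """
    L = epoch_len * rec.fs
    if abs(L - round(L)) > 1e-9:
        raise ValueError("epoch_len * fs must be an integer number of samples")
    L = int(round(L))
    n = rec.n_samples // L
    if n == 0:
        raise ValueError("recording shorter than one epoch")
    dropped = rec.n_samples - n * L
    if dropped:
        logger.info("dropped %d trailing samples (%.3g s)", dropped, dropped / rec.fs)
    eeg = rec.eeg[: n * L].reshape(n, L)
    emg = rec.emg[: n * L].reshape(n, L)
    clock = (rec.start_clock + np.arange(n) * epoch_len) % 86400.0
    phase = np.where(is_light(clock, rec.lights_on, rec.lights_off), "light", "dark")
    return EpochSeries(eeg, emg, epoch_len, rec.fs, clock, phase, dropped)


# ---------------------------------------------------------------------------
# EDF read/write
# ---------------------------------------------------------------------------

def _edf_field(values, width: int) -> bytes:
    out = b""
    for v in values:
        b = str(v).encode("ascii")[:width]
        out += b.ljust(width)
    return out


def write_edf(rec: Recording, path) -> None:
    """Write a recording as standard 16-bit EDF (two signals: EEG, EMG, µV).

    One-second data records; the duration must therefore be an integer number
    of seconds (always true for whole 4-s epochs).
    """
    path = Path(path)
    fs = rec.fs
    if abs(fs - round(fs)) > 1e-9:
        raise ValueError("EDF export requires an integer sampling rate")
    fs = int(round(fs))
    if rec.n_samples % fs:
        raise ValueError("EDF export requires a whole number of seconds")
    n_rec = rec.n_samples // fs
    sigs = [rec.eeg, rec.emg]
    labels = ["EEG", "EMG"]
    ns = len(sigs)

    start = int(round(rec.start_clock)) % 86400
    header = b"0".ljust(8)
    header += b"X".ljust(80)                      # patient id
    header += b"X".ljust(80)                      # recording id
    header += b"01.01.24"                         # nominal start date
    header += f"{start // 3600:02d}.{(start // 60) % 60:02d}.{start % 60:02d}".encode()
    header += str(256 * (1 + ns)).encode().ljust(8)
    header += b"".ljust(44)
    header += str(n_rec).encode().ljust(8)
    header += b"1".ljust(8)                       # record duration, s
    header += str(ns).encode().ljust(4)

    digitized = []
    pmins, pmaxs = [], []
    for s in sigs:
        amp = float(np.max(np.abs(s))) if s.size else 0.0
        amp = amp if amp > 0 else 1.0
        pmins.append(-amp)
        pmaxs.append(amp)
        d = np.clip(np.round(s / amp * 32767.0), -32768, 32767).astype("<i2")
        digitized.append(d)

    header += _edf_field(labels, 16)
    header += _edf_field([""] * ns, 80)           # transducer
    header += _edf_field(["uV"] * ns, 8)
    header += _edf_field([f"{v:.6g}" for v in pmins], 8)
    header += _edf_field([f"{v:.6g}" for v in pmaxs], 8)
    header += _edf_field([-32768] * ns, 8)
    header += _edf_field([32767] * ns, 8)
    header += _edf_field([""] * ns, 80)           # prefiltering
    header += _edf_field([fs] * ns, 8)
    header += _edf_field([""] * ns, 32)

    with open(path, "wb") as fh:
        fh.write(header)
        for r in range(n_rec):
            for d in digitized:
                fh.write(d[r * fs : (r + 1) * fs].tobytes())


def _read_edf(path, channel_map=None) -> tuple[np.ndarray, np.ndarray, float, float]:
    import mne

    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    names = {n.strip().upper(): i for i, n in enumerate(raw.ch_names)}
    cmap = {k.upper(): v for k, v in (channel_map or {}).items()}
    idx = {}
    for want in ("EEG", "EMG"):
        if want in cmap:
            label = cmap[want].strip().upper()
            if label not in names:
                raise ValueError(
                    f"channel override {cmap[want]!r} not found; file has {raw.ch_names}"
                )
            idx[want] = names[label]
        elif want in names:
            idx[want] = names[want]
        else:
            raise ValueError(
                f"no channel labeled {want!r} (case-insensitive) in {raw.ch_names}; "
                "pass channel_map to override"
            )
    data = raw.get_data(units="uV")
    meas = raw.info.get("meas_date")
    start = 0.0
    if meas is not None:
        start = meas.hour * 3600.0 + meas.minute * 60.0 + meas.second
    return data[idx["EEG"]], data[idx["EMG"]], float(raw.info["sfreq"]), start


# ---------------------------------------------------------------------------
# Raw-binary fallback: float32 interleaved [eeg, emg] + JSON sidecar
# ---------------------------------------------------------------------------

def write_raw(rec: Recording, path) -> None:
    path = Path(path)
    data = np.empty((rec.n_samples, 2), dtype="<f4")
    data[:, 0] = rec.eeg
    data[:, 1] = rec.emg
    data.tofile(path)
    sidecar = {
        "fs": rec.fs,
        "start_clock": rec.start_clock,
        "lights_on": rec.lights_on,
        "lights_off": rec.lights_off,
        "channels": ["EEG", "EMG"],
        "dtype": "<f4",
        "unit": "uV",
    }
    Path(str(path) + ".json").write_text(json.dumps(sidecar, indent=1))


def _read_raw_binary(path) -> tuple[np.ndarray, np.ndarray, float, float, float, float]:
    sidecar_path = Path(str(path) + ".json")
    if not sidecar_path.exists():
        raise FileNotFoundError(f"raw recording sidecar {sidecar_path} not found")
    meta = json.loads(sidecar_path.read_text())
    data = np.fromfile(path, dtype=meta.get("dtype", "<f4")).reshape(-1, 2)
    return (
        data[:, 0].astype(float),
        data[:, 1].astype(float),
        float(meta["fs"]),
        parse_clock(meta.get("start_clock", 72000.0)),
        parse_clock(meta.get("lights_on", 28800.0)),
        parse_clock(meta.get("lights_off", 72000.0)),
    )


def read_recording(
    path,
    format: str = "edf",
    channel_map: dict | None = None,
    lights_on=28800.0,
    lights_off=72000.0,
    start_clock=None,
) -> Recording:
    """Read a two-channel recording from EDF or the raw-binary fallback.

    EDF channel mapping is by label (case-insensitive ``EEG``/``EMG``) or via
    ``channel_map={"EEG": "label", "EMG": "label"}``. The light schedule is
    not stored in EDF and is supplied by the caller (defaults 8:00-20:00).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"recording {path} not found")
    if format == "edf":
        eeg, emg, fs, file_start = _read_edf(path, channel_map)
        lo, lf = parse_clock(lights_on), parse_clock(lights_off)
        start = file_start if start_clock is None else parse_clock(start_clock)
    elif format == "raw":
        eeg, emg, fs, file_start, lo, lf = _read_raw_binary(path)
        start = file_start if start_clock is None else parse_clock(start_clock)
    else:
        raise ValueError(f"unknown format {format!r} (expected 'edf' or 'raw')")
    return Recording(eeg, emg, fs, start, lo, lf)


# ---------------------------------------------------------------------------
# Hypnogram TSV
# ---------------------------------------------------------------------------

def write_hypnogram(labels, path, start_clock: float = 72000.0, epoch_len: float = 4.0) -> None:
    """Write per-epoch state labels as TSV: epoch_index, clock_time, state."""
    labels = np.asarray(labels, dtype=str)
    bad = set(labels.tolist()) - set(STATES)
    if bad:
        raise ValueError(f"unknown state tokens {sorted(bad)}")
    with open(path, "w") as fh:
        fh.write("epoch_index\tclock_time\tstate\n")
        for i, s in enumerate(labels):
            fh.write(f"{i}\t{format_clock(start_clock + i * epoch_len)}\t{s}\n")


def read_hypnogram(path) -> np.ndarray:
    """Read a hypnogram TSV back into a label array; strict token validation."""
    labels = []
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("epoch_index"):
            raise ValueError(f"{path}: not a hypnogram TSV (bad header)")
        for ln, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise ValueError(f"{path}:{ln}: expected 3 tab-separated columns")
            idx, _, state = parts
            if int(idx) != len(labels):
                raise ValueError(f"{path}:{ln}: non-contiguous epoch index {idx}")
            if state not in STATES:
                raise ValueError(
                    f"{path}:{ln}: unknown state token {state!r} (expected one of {STATES})"
                )
            labels.append(state)
    return np.asarray(labels, dtype="<U2")
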