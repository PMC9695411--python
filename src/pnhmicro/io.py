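"""Reading, writing and rate conversion for continuous LFP, annotations and spike times.

All analysis downstream runs on a common 1 kHz timeline; this module owns the
conversion. Two signal containers are supported on disk: EDF (16-bit, physical
unit microvolt) as the interchange format, and raw float32 binary with a JSON
sidecar as a lossless fast path. Event annotations and spike times travel as
TSV.

Time convention: seconds from recording start, 0-based sample indexing.
Annotation intervals are half-open ``[start_s, end_s)``.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal as sps

#: Closed annotation vocabulary: the three interictal patterns, the periodic
#: fast-activity variant, seizures and artifact periods.
LABELS = ("PD+F", "SD+F", "ES", "PF", "seizure", "artifact")

#: Labels whose periods are excluded from resting-state (baseline) estimates.
EXCLUSION_LABELS = frozenset(LABELS)

ANNOTATION_COLUMNS = ["label", "channel", "start_s", "end_s"]


class FormatError(ValueError):
    """A file failed to parse under the declared dialect."""


class VocabularyError(ValueError):
    """An annotation row carries a label outside the closed vocabulary."""


@dataclass
class SampledSignal:
    """One channel of continuous data in microvolts.

    Sample ``i`` sits at time ``t0_s + i / fs_hz``.
    """

    channel_id: str
    fs_hz: float
    samples: np.ndarray
    t0_s: float = 0.0

    def __post_init__(self) -> None:
        if self.fs_hz <= 0:
            raise ValueError(f"fs_hz must be positive, got {self.fs_hz}")
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples must be finite")

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.fs_hz

    @property
    def times(self) -> np.ndarray:
        return self.t0_s + np.arange(self.samples.size) / self.fs_hz


@dataclass
class AnnotationTable:
    """Labeled events (pattern, channel, onset/offset in seconds)."""

    df: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=ANNOTATION_COLUMNS)
    )

    def __post_init__(self) -> None:
        df = self.df.copy()
        missing = [c for c in ANNOTATION_COLUMNS if c not in df.columns]
        if missing:
            raise FormatError(f"annotation table missing columns: {missing}")
        df = df[ANNOTATION_COLUMNS]
        df["start_s"] = df["start_s"].astype(float)
        df["end_s"] = df["end_s"].astype(float)
        bad = df[~df["label"].isin(LABELS)]
        if len(bad):
            raise VocabularyError(
                f"unknown labels in rows {bad.index.tolist()}: "
                f"{sorted(bad['label'].unique())}; allowed: {list(LABELS)}"
            )
        inverted = df[df["end_s"] < df["start_s"]]
        if len(inverted):
            raise ValueError(
                f"end_s < start_s in rows {inverted.index.tolist()}"
            )
        self.df = df.sort_values("start_s", kind="stable").reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    def select(self, label: str, channel: str | None = None) -> pd.DataFrame:
        sel = self.df[self.df["label"] == label]
        if channel is not None:
            sel = sel[sel["channel"] == channel]
        return sel.reset_index(drop=True)

    def intervals(self, labels) -> np.ndarray:
        """(n, 2) array of [start, end) intervals for the given labels."""
        sel = self.df[self.df["label"].isin(set(labels))]
        return sel[["start_s", "end_s"]].to_numpy(dtype=float).reshape(-1, 2)

    def concat(self, other: "AnnotationTable") -> "AnnotationTable":
        return AnnotationTable(pd.concat([self.df, other.df], ignore_index=True))


def overlaps_any(intervals: np.ndarray, start: float, end: float) -> bool:
    """True if [start, end) intersects any half-open row of ``intervals``."""
    if intervals.size == 0:
        return False
    return bool(np.any((intervals[:, 0] < end) & (intervals[:, 1] > start)))


# ---------------------------------------------------------------------------
# Annotations and spike times (TSV)
# ---------------------------------------------------------------------------

def read_annotations(path) -> AnnotationTable:
    df = pd.read_csv(path, sep="\t", dtype={"label": str, "channel": str})
    return AnnotationTable(df)


def write_annotations(table: AnnotationTable, path) -> None:
    table.df.to_csv(path, sep="\t", index=False)


def read_spike_times(path) -> dict[str, np.ndarray]:
    """TSV with columns unit_id, time_s -> {unit_id: sorted times}."""
    df = pd.read_csv(path, sep="\t", dtype={"unit_id": str})
    out = {}
    for uid, grp in df.groupby("unit_id", sort=True):
        t = np.sort(grp["time_s"].to_numpy(dtype=float))
        out[uid] = t
    return out


def write_spike_times(trains: dict[str, np.ndarray], path) -> None:
    frames = [
        pd.DataFrame({"unit_id": uid, "time_s": np.asarray(t, dtype=float)})
        for uid, t in trains.items()
    ]
    df = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(columns=["unit_id", "time_s"])
    )
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Raw float32 + JSON sidecar
# ---------------------------------------------------------------------------

def write_raw(signals: list[SampledSignal], path) -> None:
    """Interleave channels as float32 with a ``.json`` sidecar next to the file."""
    path = Path(path)
    fs = {s.fs_hz for s in signals}
    n = {s.samples.size for s in signals}
    if len(fs) != 1 or len(n) != 1:
        raise ValueError("all channels must share fs and length")
    data = np.stack([s.samples for s in signals]).astype(np.float32)  # (ch, n)
    data.T.tofile(path)  # sample-major interleaving
    sidecar = {
        "fs_hz": signals[0].fs_hz,
        "n_channels": len(signals),
        "channel_names": [s.channel_id for s in signals],
        "t0_s": signals[0].t0_s,
        "dtype": "float32",
        "unit": "uV",
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=1))


def _read_raw(path) -> list[SampledSignal]:
    path = Path(path)
    sidecar_path = path.with_suffix(path.suffix + ".json")
    if not sidecar_path.exists():
        raise FormatError(f"missing sidecar {sidecar_path}")
    meta = json.loads(sidecar_path.read_text())
    for key in ("fs_hz", "n_channels", "channel_names"):
        if key not in meta:
            raise FormatError(f"sidecar missing field '{key}'")
    nch = int(meta["n_channels"])
    flat = np.fromfile(path, dtype=np.float32)
    if flat.size % nch:
        raise FormatError(
            f"raw file length {flat.size} not divisible by n_channels={nch}"
        )
    data = flat.reshape(-1, nch).T
    t0 = float(meta.get("t0_s", 0.0))
    return [
        SampledSignal(name, float(meta["fs_hz"]), data[i].astype(np.float64), t0)
        for i, name in enumerate(meta["channel_names"])
    ]


# ---------------------------------------------------------------------------
# EDF
# ---------------------------------------------------------------------------
# A minimal writer for the 16-bit EDF interchange format (no pre-installed
# package writes EDF). Reading goes through MNE. One data record per second;
# the sampling rate must therefore be an integer.

def write_edf(signals: list[SampledSignal], path) -> None:
    path = Path(path)
    fs = signals[0].fs_hz
    if any(s.fs_hz != fs for s in signals):
        raise ValueError("all channels must share a sampling rate")
    if fs != int(fs):
        raise ValueError("EDF writer requires an integer sampling rate")
    fs = int(fs)
    nch = len(signals)
    n = min(s.samples.size for s in signals)
    n_records = n // fs  # whole 1 s records only
    if n_records == 0:
        raise ValueError("signal shorter than one 1 s data record")

    def pad(text: str, width: int) -> bytes:
        b = text.encode("ascii")
        if len(b) > width:
            b = b[:width]
        return b.ljust(width)

    header = b"".join(
        [
            pad("0", 8),  # version
            pad("X X X X", 80),  # patient id (anonymous)
            pad("Startdate X X X X", 80),  # recording id
            pad("01.01.00", 8),
            pad("00.00.00", 8),
            pad(str(256 * (nch + 1)), 8),
            pad("", 44),
            pad(str(n_records), 8),
            pad("1", 8),  # record duration, s
            pad(str(nch), 4),
        ]
    )

    phys_min, phys_max, scaled = [], [], []
    for s in signals:
        x = s.samples[: n_records * fs]
        lo = float(np.min(x)) if x.size else -1.0
        hi = float(np.max(x)) if x.size else 1.0
        if hi <= lo:
            hi = lo + 1.0
        gain = (hi - lo) / (2**16 - 1)
        dig = np.round((x - lo) / gain) - 32768
        scaled.append(dig.astype(np.int16))
        phys_min.append(lo)
        phys_max.append(hi)

    def field_block(values, width):
        return b"".join(pad(v, width) for v in values)

    header += field_block([s.channel_id for s in signals], 16)
    header += field_block(["" for _ in signals], 80)  # transducer
    header += field_block(["uV" for _ in signals], 8)
    header += field_block([f"{v:.6g}" for v in phys_min], 8)
    header += field_block([f"{v:.6g}" for v in phys_max], 8)
    header += field_block(["-32768" for _ in signals], 8)
    header += field_block(["32767" for _ in signals], 8)
    header += field_block(["" for _ in signals], 80)  # prefiltering
    header += field_block([str(fs) for _ in signals], 8)
    header += field_block(["" for _ in signals], 32)  # reserved

    with open(path, "wb") as fh:
        fh.write(header)
        for r in range(n_records):
            for ch in range(nch):
                fh.write(scaled[ch][r * fs : (r + 1) * fs].tobytes())


def _validate_edf(path: Path) -> None:
    with open(path, "rb") as fh:
        head = fh.read(256)
        if len(head) < 256:
            raise FormatError("EDF header truncated (< 256 bytes)")
        try:
            header_bytes = int(head[184:192])
            n_records = int(head[236:244])
            nch = int(head[252:256])
        except ValueError as exc:
            raise FormatError(f"EDF header field unparsable: {exc}") from exc
        sig_head = fh.read(header_bytes - 256)
        if len(sig_head) < header_bytes - 256:
            raise FormatError("EDF signal header truncated")
        try:
            ns_start = 16 + 80 + 8 + 8 + 8 + 8 + 8 + 80
            samples_per_record = [
                int(sig_head[nch * ns_start + i * 8 : nch * ns_start + (i + 1) * 8])
                for i in range(nch)
            ]
        except ValueError as exc:
            raise FormatError(
                f"EDF samples-per-record field unparsable: {exc}"
            ) from exc
    expected = header_bytes + n_records * 2 * sum(samples_per_record)
    actual = path.stat().st_size
    if n_records >= 0 and actual < expected:
        raise FormatError(
            f"EDF data truncated: file has {actual} bytes, header implies {expected}"
        )


def _read_edf(path: Path) -> list[SampledSignal]:
    import mne

    _validate_edf(path)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    data = raw.get_data() * 1e6  # Volts -> microvolts
    fs = float(raw.info["sfreq"])
    return [
        SampledSignal(name, fs, data[i]) for i, name in enumerate(raw.ch_names)
    ]


def read_signal(path, format: str = "raw") -> list[SampledSignal]:
    """Read continuous data; ``format`` is ``"edf"`` or ``"raw"`` (+ sidecar)."""
    path = Path(path)
    if format == "edf":
        return _read_edf(path)
    if format == "raw":
        return _read_raw(path)
    raise ValueError(f"unknown format {format!r}")


# ---------------------------------------------------------------------------
# Rate conversion
# ---------------------------------------------------------------------------

TARGET_FS = 1000.0
#: Zero-phase anti-aliasing cutoff before decimation to 1 kHz. Keeps the
#: 60-200 Hz analysis band untouched while killing content above the new
#: Nyquist.
ANTIALIAS_CUTOFF_HZ = 400.0


def downsample_to_1khz(signal: SampledSignal) -> SampledSignal:
    """Resample a channel to the common 1 kHz analysis rate.

    A zero-phase Butterworth low-pass at 400 Hz precedes polyphase
    resampling, so band-limited content (< 400 Hz) survives without phase
    distortion. A 1 kHz input is returned unchanged.
    """
    from fractions import Fraction

    if signal.fs_hz < TARGET_FS:
        raise ValueError(
            f"cannot downsample {signal.fs_hz} Hz to 1 kHz (fs must be >= 1000)"
        )
    if signal.fs_hz == TARGET_FS:
        return signal
    sos = sps.butter(
        8, ANTIALIAS_CUTOFF_HZ, btype="low", fs=signal.fs_hz, output="sos"
    )
    filtered = sps.sosfiltfilt(sos, signal.samples)
    frac = Fraction(int(TARGET_FS), int(round(signal.fs_hz))).limit_denominator()
    out = sps.resample_poly(filtered, frac.numerator, frac.denominator)
    n_out = int(np.floor(signal.samples.size * TARGET_FS / signal.fs_hz))
    out = out[:n_out]
    return replace(signal, fs_hz=TARGET_FS, samples=out)
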