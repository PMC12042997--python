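"""Standard-format I/O: WAV audio, TSV tables, a raw binary EEG container
with JSON sidecar, and optional EDF/BDF reading for real recordings."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import wavfile

from cheechlab.audio import AudioTrack
from cheechlab.erp import EEGRecording


def write_wav(path, track: AudioTrack) -> None:
    """Write an audio track as 32-bit float WAV (lossless for float32 data)."""
    wavfile.write(str(path), int(round(track.rate_hz)), track.samples.astype(np.float32))


def read_wav(path) -> AudioTrack:
    """Read a WAV file; malformed/truncated files are rejected with the
    file size in the diagnostic."""
    path = Path(path)
    try:
        rate, data = wavfile.read(str(path))
    except Exception as exc:  # scipy raises mixed ValueError/struct.error
        size = path.stat().st_size if path.exists() else 0
        raise ValueError(f"malformed WAV {path} ({size} bytes): {exc}") from exc
    return AudioTrack(samples=np.asarray(data, dtype=np.float64), rate_hz=float(rate))


def write_events_tsv(path, frame: pd.DataFrame) -> None:
    frame.to_csv(path, sep="\t", index=False)


def read_events_tsv(path) -> pd.DataFrame:
    try:
        return pd.read_csv(path, sep="\t")
    except Exception as exc:
        raise ValueError(f"malformed event TSV {path}: {exc}") from exc


def write_cohort_tsv(path, cohort: pd.DataFrame) -> None:
    cohort.to_csv(path, sep="\t", index=False)


def read_cohort_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# Internal recording container: float64 raw samples + JSON sidecar


def write_recording(path, recording: EEGRecording) -> None:
    """Write a recording as ``<path>.raw`` (float64, channels × samples,
    C order) plus a ``<path>.json`` sidecar with channels, rate, and events."""
    path = Path(path)
    raw = path.with_suffix(".raw")
    sidecar = path.with_suffix(".json")
    recording.samples.astype(np.float64).tofile(raw)
    sidecar.write_text(
        json.dumps(
            {
                "channel_names": recording.channel_names,
                "rate_hz": recording.rate_hz,
                "n_samples": recording.n_samples,
                "events": recording.events.to_dict(orient="list"),
                "meta": {k: v for k, v in recording.meta.items() if _jsonable(v)},
            }
        )
    )


def read_recording(path) -> EEGRecording:
    path = Path(path)
    raw = path.with_suffix(".raw")
    sidecar = path.with_suffix(".json")
    if not sidecar.exists():
        raise ValueError(f"missing sidecar {sidecar}")
    info = json.loads(sidecar.read_text())
    n_ch, n_s = len(info["channel_names"]), info["n_samples"]
    data = np.fromfile(raw, dtype=np.float64)
    if data.size != n_ch * n_s:
        raise ValueError(
            f"container {raw} holds {data.size} samples at byte offset "
            f"{data.size * 8}, expected {n_ch * n_s}"
        )
    return EEGRecording(
        channel_names=info["channel_names"],
        rate_hz=info["rate_hz"],
        samples=data.reshape(n_ch, n_s),
        events=pd.DataFrame(info["events"]),
        meta=info.get("meta", {}),
    )


def _jsonable(v) -> bool:
    try:
        json.dumps(v)
        return True
    except TypeError:
        return False


def read_edf_bdf(path) -> EEGRecording:
    """Read a real EDF/BDF recording via MNE (read-only entry point)."""
    try:
        import mne
    except ImportError as exc:  # pragma: no cover - mne is an optional extra
        raise ImportError("reading EDF/BDF requires the 'mne' package") from exc
    path = str(path)
    reader = mne.io.read_raw_bdf if path.lower().endswith(".bdf") else mne.io.read_raw_edf
    raw = reader(path, preload=True, verbose="error")
    events = pd.DataFrame(
        {
            "onset_s": raw.annotations.onset,
            "code": list(raw.annotations.description),
        }
    )
    return EEGRecording(
        channel_names=list(raw.ch_names),
        rate_hz=float(raw.info["sfreq"]),
        samples=raw.get_data() * 1e6,  # volts → µV
        events=events,
    )
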