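"""Session and trace I/O.

Two on-disk session representations:

* **EDF+** — one signal per electrode plus the EMG channel, stimulation
  onsets as EDF+ annotations.  The writer is a minimal EDF+C implementation
  (16-bit, per-signal physical scaling); reading goes through
  :func:`mne.io.read_raw_edf`.
* **fixture bundle** — a directory with ``data.npy`` (channels x samples,
  uV), ``emg.npy`` and a JSON sidecar carrying sample rate, triggers,
  geometry, ground truth and the generating parameters.  This is the
  lossless format used by the pipeline and tests.

SSEP traces are written as CSV (rows = channels, columns = time in ms,
header row) with a JSON sidecar (flavor, excluded channels, trial count).
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .geometry import GridGeometry
from .preprocess import SSEPTrace, TrialRecording
from .simulate import GroundTruth, SimulationParams

__all__ = [
    "write_edf",
    "read_edf",
    "save_fixture",
    "load_fixture",
    "write_trace_csv",
    "read_trace_csv",
]


# ---------------------------------------------------------------------------
# EDF+


def _pad(text: str, width: int) -> bytes:
    b = text.encode("ascii")[:width]
    return b + b" " * (width - len(b))


def _fmt_float(x: float, width: int = 8) -> bytes:
    for prec in range(6, -1, -1):
        s = f"{x:.{prec}f}"
        if len(s) <= width:
            return _pad(s, width)
    return _pad(f"{x:.0e}", width)


def write_edf(path, recording: TrialRecording, annotations: str = "stim") -> None:
    """Write a recording as EDF+C.

    Electrode signals keep their channel ids, the EMG channel is labelled
    ``EMG``, and each trigger becomes an EDF+ annotation with text
    ``annotations``.  Record duration is 1 s; the trailing partial record
    is zero-padded.
    """
    fs = recording.sample_rate_hz
    if abs(fs - round(fs)) > 1e-9:
        raise ValueError("EDF writer requires an integer sample rate")
    fs = int(round(fs))
    signals = [recording.data[i] for i in range(recording.n_channels)]
    labels = list(recording.channel_ids)
    signals.append(recording.emg)
    labels.append("EMG")
    n_samp = len(recording.emg)
    n_records = int(np.ceil(n_samp / fs))

    onsets_s = (
        (np.asarray(recording.triggers, dtype=float) / fs).tolist()
        if recording.triggers is not None
        else []
    )
    # annotation channel: enough bytes per record for the timestamp TAL
    # plus any events falling in that record
    ann_records = []
    for r in range(n_records):
        tal = f"+{r}\x14\x14\x00"
        for t in onsets_s:
            if r <= t < r + 1:
                tal += f"+{t:.6f}\x14\x14{annotations}\x14\x00"
        ann_records.append(tal.encode("ascii"))
    ann_bytes = max(len(a) for a in ann_records)
    ann_samples = (ann_bytes + 1) // 2 + 1

    phys_min, phys_max, dig = [], [], []
    for sig in signals:
        lo, hi = float(np.min(sig)), float(np.max(sig))
        if hi <= lo:
            lo, hi = lo - 1.0, hi + 1.0
        phys_min.append(lo)
        phys_max.append(hi)
        scaled = (np.asarray(sig) - lo) / (hi - lo) * 65535.0 - 32768.0
        dig.append(np.round(scaled).astype("<i2"))

    n_signals = len(signals) + 1
    header_bytes = 256 * (1 + n_signals)
    with open(path, "wb") as fh:
        fh.write(_pad("0", 8))
        fh.write(_pad("X X X X", 80))
        fh.write(_pad("Startdate X X X X", 80))
        fh.write(_pad("01.01.00", 8))
        fh.write(_pad("00.00.00", 8))
        fh.write(_pad(str(header_bytes), 8))
        fh.write(_pad("EDF+C", 44))
        fh.write(_pad(str(n_records), 8))
        fh.write(_pad("1", 8))
        fh.write(_pad(str(n_signals), 4))
        for lab in labels + ["EDF Annotations"]:
            fh.write(_pad(lab, 16))
        for _ in range(n_signals):
            fh.write(_pad("", 80))                       # transducer
        for _ in range(len(signals)):
            fh.write(_pad("uV", 8))
        fh.write(_pad("", 8))
        for lo in phys_min:
            fh.write(_fmt_float(lo))
        fh.write(_pad("-1", 8))
        for hi in phys_max:
            fh.write(_fmt_float(hi))
        fh.write(_pad("1", 8))
        for _ in range(len(signals)):
            fh.write(_pad("-32768", 8))
        fh.write(_pad("-32768", 8))
        for _ in range(len(signals)):
            fh.write(_pad("32767", 8))
        fh.write(_pad("32767", 8))
        for _ in range(n_signals):
            fh.write(_pad("", 80))                       # prefilter
        for _ in range(len(signals)):
            fh.write(_pad(str(fs), 8))
        fh.write(_pad(str(ann_samples), 8))
        for _ in range(n_signals):
            fh.write(_pad("", 32))
        for r in range(n_records):
            lo_s, hi_s = r * fs, (r + 1) * fs
            for sig in dig:
                chunk = sig[lo_s:hi_s]
                if len(chunk) < fs:
                    chunk = np.concatenate(
                        [chunk, np.zeros(fs - len(chunk), dtype="<i2")]
                    )
                fh.write(chunk.tobytes())
            ann = ann_records[r]
            fh.write(ann + b"\x00" * (2 * ann_samples - len(ann)))


def read_edf(path) -> TrialRecording:
    """Read an EDF+ session (any EDF+ with an ``EMG`` channel works).

    Stimulation annotations become trigger sample indices.
    """
    import mne

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    fs = float(raw.info["sfreq"])
    names = raw.ch_names
    if "EMG" not in names:
        raise ValueError("EDF file has no EMG channel")
    emg_idx = names.index("EMG")
    data = raw.get_data() * 1e6      # mne returns volts
    ch_idx = [i for i in range(len(names)) if i != emg_idx]
    triggers = None
    if len(raw.annotations):
        onsets = [
            ann["onset"] for ann in raw.annotations
            if ann["description"] not in ("", None)
        ]
        if onsets:
            triggers = np.round(np.asarray(sorted(onsets)) * fs).astype(int)
    return TrialRecording(
        data=data[ch_idx],
        emg=data[emg_idx],
        sample_rate_hz=fs,
        triggers=triggers,
        channel_ids=[names[i] for i in ch_idx],
    )


# ---------------------------------------------------------------------------
# fixture bundle


def save_fixture(directory, recording: TrialRecording,
                 geometry: GridGeometry | None = None,
                 ground_truth: GroundTruth | None = None,
                 params: SimulationParams | None = None) -> Path:
    """Write a lossless session bundle (arrays + JSON sidecar)."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    np.save(d / "data.npy", recording.data)
    np.save(d / "emg.npy", recording.emg)
    sidecar: dict = {
        "sample_rate_hz": recording.sample_rate_hz,
        "channel_ids": list(recording.channel_ids),
        "triggers": (
            recording.triggers.tolist() if recording.triggers is not None else None
        ),
    }
    if geometry is not None:
        sidecar["geometry"] = geometry.to_dict()
    if ground_truth is not None:
        sidecar["ground_truth"] = {
            "region_labels": list(ground_truth.region_labels),
            "cs_line": ground_truth.cs_line.tolist(),
            "corrupted_channels": ground_truth.corrupted_channels.tolist(),
            "true_latencies_ms": ground_truth.true_latencies_ms,
            "trigger_samples": ground_truth.trigger_samples.tolist(),
        }
    if params is not None:
        sidecar["params"] = dataclasses.asdict(params)
        sidecar["seed"] = params.seed
    with open(d / "session.json", "w") as fh:
        json.dump(sidecar, fh, indent=1)
    return d


def load_fixture(directory):
    """Read a session bundle.

    Returns ``(recording, geometry, ground_truth, params)``; missing
    optional pieces come back as None.
    """
    d = Path(directory)
    with open(d / "session.json") as fh:
        sidecar = json.load(fh)
    recording = TrialRecording(
        data=np.load(d / "data.npy"),
        emg=np.load(d / "emg.npy"),
        sample_rate_hz=sidecar["sample_rate_hz"],
        triggers=(
            np.asarray(sidecar["triggers"], int)
            if sidecar.get("triggers") is not None else None
        ),
        channel_ids=sidecar.get("channel_ids", []),
    )
    geometry = (
        GridGeometry.from_dict(sidecar["geometry"])
        if "geometry" in sidecar else None
    )
    truth = None
    if "ground_truth" in sidecar:
        gt = sidecar["ground_truth"]
        truth = GroundTruth(
            region_labels=np.asarray(gt["region_labels"], dtype=object),
            cs_line=np.asarray(gt["cs_line"], float),
            corrupted_channels=np.asarray(gt["corrupted_channels"], int),
            true_latencies_ms=gt["true_latencies_ms"],
            trigger_samples=np.asarray(gt["trigger_samples"], int),
        )
    params = None
    if "params" in sidecar:
        p = dict(sidecar["params"])
        p["source_position"] = tuple(p["source_position"])
        params = SimulationParams(**p)
    return recording, geometry, truth, params


# ---------------------------------------------------------------------------
# trace CSV


def write_trace_csv(trace: SSEPTrace, path) -> None:
    path = Path(path)
    df = pd.DataFrame(
        trace.values,
        index=pd.Index(trace.channel_ids, name="channel"),
        columns=[f"{t:.6f}" for t in trace.time_axis_ms],
    )
    df.to_csv(path)
    sidecar = {
        "flavor": trace.flavor,
        "excluded_channels": trace.excluded_channels.tolist(),
        "n_trials_averaged": trace.n_trials_averaged,
    }
    with open(path.with_suffix(".json"), "w") as fh:
        json.dump(sidecar, fh, indent=1)


def read_trace_csv(path) -> SSEPTrace:
    path = Path(path)
    df = pd.read_csv(path, index_col=0)
    with open(path.with_suffix(".json")) as fh:
        sidecar = json.load(fh)
    return SSEPTrace(
        values=df.to_numpy(),
        time_axis_ms=np.asarray([float(c) for c in df.columns]),
        flavor=sidecar["flavor"],
        excluded_channels=np.asarray(sidecar["excluded_channels"], int),
        n_trials_averaged=sidecar["n_trials_averaged"],
        channel_ids=[str(c) for c in df.index],
    )
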