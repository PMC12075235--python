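"""Reading and writing recordings and label files.

Two on-disk recording formats are supported:

* **EDF** — read with MNE, written by the in-package writer
  (:func:`vigilscore.edf.write_edf`).
* **CSV** — first row ``time,<ch1>,<ch2>,...``, one sample per row, with an
  optional JSON sidecar ``<file>.json`` holding the sampling rate, channel
  roles and start time. Without a sidecar the rate is inferred from the time
  column and roles are guessed from channel names.

Label files are plain text: exactly one ASCII character per epoch from the
alphabet ``abclmnoNU``, no separators.
"""

from __future__ import annotations

import json
import logging
from datetime import datetime
from pathlib import Path

import numpy as np
import pandas as pd

from .edf import write_edf
from .recording import ChannelMeta, Recording
from .scorer import ALPHABET, LabelSequence

logger = logging.getLogger("vigilscore")

__all__ = [
    "FormatError",
    "HeaderError",
    "LabelError",
    "read_recording",
    "write_recording",
    "read_labels",
    "write_labels",
    "write_edf",
]


class FormatError(ValueError):
    """The file does not parse under the named standard."""


class HeaderError(FormatError):
    """Required header metadata (e.g. sampling rate) is missing."""


class LabelError(ValueError):
    """A label file contains characters outside the 9-letter alphabet."""


def _guess_role(name: str) -> str:
    lowered = name.lower()
    if "emg" in lowered:
        return "EMG"
    if "ref" in lowered:
        return "REF"
    return "EEG"


def _read_csv(path: Path) -> Recording:
    sidecar = path.with_suffix(path.suffix + ".json")
    meta = {}
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # pragma: no cover - pandas message varies
        raise FormatError(f"cannot parse {path} as CSV: {exc}") from exc
    if df.empty or df.shape[1] < 2:
        raise HeaderError(f"{path}: expected columns time,<ch1>,... with data rows")

    ch_names = [c for c in df.columns if c != "time"]
    fs = meta.get("fs")
    if fs is None:
        if "time" not in df.columns or len(df) < 2:
            raise HeaderError(f"{path}: no sampling rate in sidecar and no time column")
        dt = np.median(np.diff(df["time"].to_numpy()))
        if dt <= 0:
            raise HeaderError(f"{path}: time column is not increasing")
        fs = 1.0 / dt
        logger.info("inferred fs=%.6g Hz from time column of %s", fs, path)

    roles = {c["name"]: c for c in meta.get("channels", [])}
    channels = [
        ChannelMeta(
            name=name,
            role=roles.get(name, {}).get("role", _guess_role(name)),
            site=roles.get(name, {}).get("site", ""),
        )
        for name in ch_names
    ]
    start = meta.get("start_time")
    start_time = datetime.fromisoformat(start) if start else datetime(2000, 1, 1, 9, 0)
    signal = df[ch_names].to_numpy(dtype=float).T
    return Recording(signal=signal, fs=float(fs), channels=channels, start_time=start_time)


def _read_edf(path: Path) -> Recording:
    import mne

    try:
        raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    except Exception as exc:
        raise FormatError(f"cannot parse {path} as EDF: {exc}") from exc
    data = raw.get_data() * 1e6  # MNE returns SI volts; recordings are in uV
    channels = []
    for name in raw.ch_names:
        parts = name.split(" ", 1)
        if parts[0].upper() in ("EEG", "EMG", "REF") and len(parts) == 2:
            role, base = parts[0].upper(), parts[1]
        else:
            role, base = _guess_role(name), name
        channels.append(ChannelMeta(name=base, role=role))
    meas = raw.info.get("meas_date")
    start_time = meas.replace(tzinfo=None) if meas is not None else datetime(2000, 1, 1, 9, 0)
    return Recording(
        signal=data, fs=float(raw.info["sfreq"]), channels=channels, start_time=start_time
    )


def read_recording(path, fmt: str | None = None) -> Recording:
    """Read an EDF or CSV(+JSON sidecar) recording.

    ``fmt`` may be ``"EDF"`` or ``"CSV"``; by default it is taken from the
    file extension.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.stat().st_size == 0:
        raise HeaderError(f"{path} is empty")
    if fmt is None:
        fmt = "EDF" if path.suffix.lower() == ".edf" else "CSV"
    fmt = fmt.upper()
    if fmt == "EDF":
        return _read_edf(path)
    if fmt == "CSV":
        return _read_csv(path)
    raise ValueError(f"unknown format {fmt!r}")


def write_recording(path, rec: Recording, fmt: str | None = None) -> None:
    """Write a recording as EDF or as CSV with a JSON sidecar."""
    path = Path(path)
    if fmt is None:
        fmt = "EDF" if path.suffix.lower() == ".edf" else "CSV"
    fmt = fmt.upper()
    if fmt == "EDF":
        write_edf(path, rec)
        return
    if fmt != "CSV":
        raise ValueError(f"unknown format {fmt!r}")
    t = np.arange(rec.n_samples) / rec.fs
    df = pd.DataFrame({"time": t})
    for ch, row in zip(rec.channels, rec.signal):
        df[ch.name] = row
    df.to_csv(path, index=False)
    sidecar = {
        "fs": rec.fs,
        "start_time": rec.start_time.isoformat(),
        "channels": [
            {"name": ch.name, "role": ch.role, "site": ch.site} for ch in rec.channels
        ],
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=1))


def write_labels(labels: LabelSequence, path) -> None:
    """Write one byte per epoch; 'U' is legal on disk but warned about,
    since finished scorings should not contain unscored epochs."""
    if "U" in labels.labels:
        logger.warning("label sequence contains %d 'U' (unscored) epochs", labels.labels.count("U"))
    Path(path).write_text(labels.labels, encoding="ascii")


def read_labels(path, epoch_len: float = 1.0) -> LabelSequence:
    """Read a label file; any character outside the alphabet is an error."""
    payload = Path(path).read_text(encoding="ascii").rstrip("\n")
    bad = set(payload) - set(ALPHABET)
    if bad:
        raise LabelError(f"{path}: characters outside alphabet {ALPHABET!r}: {sorted(bad)}")
    return LabelSequence(labels=payload, epoch_len=epoch_len)
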