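"""Reading and writing the package's on-disk formats.

Datasets: npz container (full fidelity) or plain CSV — see
:class:`meghfo.data.SegmentDataset`. Recordings: npz container with channel
names and the ground-truth event list; EDF files are read through ``mne``
when it is installed (optional extra). Ground-truth event lists travel as a
BED-like tab-delimited text file with columns ``channel  onset_s
duration_s  freq_hz  amplitude``.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .data import SegmentDataset
from .synthetic import HFOEventParams, Recording

EVENT_COLUMNS = ("channel", "onset_s", "duration_s", "freq_hz", "amplitude")


def write_events(path, events) -> None:
    """Write a ground-truth event list as BED-like TSV.

    ``events`` is an iterable of (channel, onset_s, HFOEventParams).
    """
    rows = [
        {
            "channel": ch,
            "onset_s": onset,
            "duration_s": p.duration,
            "freq_hz": p.center_freq,
            "amplitude": p.amplitude,
        }
        for ch, onset, p in events
    ]
    pd.DataFrame(rows, columns=EVENT_COLUMNS).to_csv(path, sep="\t", index=False)


def read_events(path) -> list[tuple[str, float, HFOEventParams]]:
    df = pd.read_csv(path, sep="\t")
    out = []
    for _, r in df.iterrows():
        out.append(
            (
                str(r["channel"]),
                float(r["onset_s"]),
                HFOEventParams(
                    center_freq=float(r["freq_hz"]),
                    duration=float(r["duration_s"]),
                    amplitude=float(r.get("amplitude", 1.0)),
                    onset=float(r["onset_s"]),
                ),
            )
        )
    return out


def save_recording(path, rec: Recording) -> None:
    meta = {
        "fs": rec.fs,
        "channel_names": list(rec.channel_names),
        "events": [
            {
                "channel": ch,
                "onset_s": onset,
                "duration_s": p.duration,
                "freq_hz": p.center_freq,
                "amplitude": p.amplitude,
                "envelope": p.envelope,
            }
            for ch, onset, p in rec.event_truth
        ],
    }
    np.savez_compressed(
        path,
        data=rec.data,
        meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
    )


def load_recording(path) -> Recording:
    """Load a recording from the npz container or from an EDF file."""
    path = Path(path)
    if path.suffix.lower() == ".edf":
        return read_edf(path)
    with np.load(path, allow_pickle=False) as z:
        meta = json.loads(bytes(z["meta"].tobytes()).decode())
        events = [
            (
                e["channel"],
                e["onset_s"],
                HFOEventParams(
                    center_freq=e["freq_hz"],
                    duration=e["duration_s"],
                    amplitude=e["amplitude"],
                    envelope=e.get("envelope", "gaussian"),
                    onset=e["onset_s"],
                ),
            )
            for e in meta["events"]
        ]
        return Recording(z["data"], meta["fs"], meta["channel_names"], events)


def read_edf(path) -> Recording:
    """Read an EDF recording via mne (install the ``edf`` extra)."""
    try:
        import mne
    except ImportError as exc:  # pragma: no cover
        raise ImportError(
            "reading EDF requires mne: pip install meghfo[edf]"
        ) from exc
    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    return Recording(raw.get_data(), raw.info["sfreq"], list(raw.ch_names), [])


def load_dataset(path, fs: float = 2400.0) -> SegmentDataset:
    path = Path(path)
    if path.suffix.lower() == ".csv":
        return SegmentDataset.from_csv(path, fs)
    return SegmentDataset.from_npz(path)


def save_dataset(path, ds: SegmentDataset) -> None:
    path = Path(path)
    if path.suffix.lower() == ".csv":
        ds.to_csv(path)
    else:
        ds.to_npz(path)
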