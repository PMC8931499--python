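"""Shared containers for labeled 1-D signal segments.

The unit of analysis throughout the package is the *segment*: a fixed-length
window of a single channel (default 2000 samples at 2400 Hz), labeled HFO
(contains a high-frequency oscillation burst), NC (normal control background)
or UNLABELED (windows cut from a continuous recording, awaiting
classification). Segments carry a provenance tag so that virtual
(augmentation-generated) samples can never leak into an evaluation fold.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

#: Integer label codes used everywhere in the package.
HFO = 1
NC = 0
UNLABELED = -1

LABEL_NAMES = {HFO: "HFO", NC: "NC", UNLABELED: "UNLABELED"}
LABEL_CODES = {v: k for k, v in LABEL_NAMES.items()}

#: Allowed provenance tags. "real" = measured data, "synthetic" = simulator
#: output (ground-truthed, usable for evaluation), "virtual" = augmentation
#: output (training only).
SOURCES = ("real", "synthetic", "virtual")


@dataclass
class Segment:
    """One fixed-length 1-D signal window."""

    samples: np.ndarray
    label: int = UNLABELED
    fs: float = 2400.0
    source: str = "synthetic"
    channel_id: str = ""
    start_time: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ValueError("segment samples must be a 1-D vector")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("segment samples must be finite")
        if self.label not in LABEL_NAMES:
            raise ValueError(f"unknown label code {self.label!r}")
        if self.source not in SOURCES:
            raise ValueError(f"unknown source {self.source!r}")

    def __len__(self) -> int:
        return self.samples.size


class SegmentDataset:
    """A collection of equal-length segments with label/provenance bookkeeping.

    Thin wrapper over a dense ``(n_segments, T)`` float matrix plus parallel
    per-segment metadata arrays; all model and augmentation code works on the
    matrix directly.
    """

    def __init__(
        self,
        X: np.ndarray,
        y: np.ndarray,
        fs: float = 2400.0,
        source: Sequence[str] | None = None,
        channel_id: Sequence[str] | None = None,
        start_time: np.ndarray | None = None,
    ) -> None:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        y = np.asarray(y, dtype=int)
        if X.shape[0] != y.shape[0]:
            raise ValueError("X and y must have the same number of rows")
        if not np.all(np.isfinite(X)):
            raise ValueError("segment matrix must be finite")
        n = X.shape[0]
        self.X = X
        self.y = y
        self.fs = float(fs)
        self.source = np.asarray(
            ["synthetic"] * n if source is None else list(source), dtype=object
        )
        self.channel_id = np.asarray(
            [""] * n if channel_id is None else list(channel_id), dtype=object
        )
        self.start_time = (
            np.zeros(n) if start_time is None else np.asarray(start_time, dtype=float)
        )
        for arr, name in (
            (self.source, "source"),
            (self.channel_id, "channel_id"),
            (self.start_time, "start_time"),
        ):
            if len(arr) != n:
                raise ValueError(f"{name} length {len(arr)} != n segments {n}")
        bad = set(self.source) - set(SOURCES)
        if bad:
            raise ValueError(f"unknown source tags {bad}")

    # -- basic protocol ----------------------------------------------------
    def __len__(self) -> int:
        return self.X.shape[0]

    @property
    def n_segments(self) -> int:
        return self.X.shape[0]

    @property
    def segment_length(self) -> int:
        return self.X.shape[1] if self.X.size else 0

    def class_counts(self) -> dict[str, int]:
        return {
            name: int(np.sum(self.y == code))
            for code, name in LABEL_NAMES.items()
            if np.any(self.y == code) or code in (HFO, NC)
        }

    def segments(self) -> Iterable[Segment]:
        for i in range(len(self)):
            yield Segment(
                self.X[i],
                int(self.y[i]),
                self.fs,
                str(self.source[i]),
                str(self.channel_id[i]),
                float(self.start_time[i]),
            )

    def subset(self, idx: np.ndarray) -> "SegmentDataset":
        idx = np.asarray(idx)
        return SegmentDataset(
            self.X[idx],
            self.y[idx],
            self.fs,
            self.source[idx],
            self.channel_id[idx],
            self.start_time[idx],
        )

    @classmethod
    def from_segments(cls, segs: Sequence[Segment], fs: float | None = None) -> "SegmentDataset":
        if not segs:
            return cls(np.empty((0, 0)), np.empty(0, dtype=int), fs or 2400.0)
        lengths = {len(s) for s in segs}
        if len(lengths) != 1:
            raise ValueError(f"segments have mixed lengths {sorted(lengths)}")
        fs = fs if fs is not None else segs[0].fs
        return cls(
            np.stack([s.samples for s in segs]),
            np.array([s.label for s in segs], dtype=int),
            fs,
            [s.source for s in segs],
            [s.channel_id for s in segs],
            np.array([s.start_time for s in segs]),
        )

    @classmethod
    def concat(cls, parts: Sequence["SegmentDataset"]) -> "SegmentDataset":
        parts = [p for p in parts if len(p)]
        if not parts:
            return cls(np.empty((0, 0)), np.empty(0, dtype=int))
        T = {p.segment_length for p in parts}
        if len(T) != 1:
            raise ValueError("cannot concatenate datasets with different segment lengths")
        fs = {p.fs for p in parts}
        if len(fs) != 1:
            raise ValueError("cannot concatenate datasets with different sampling rates")
        return cls(
            np.vstack([p.X for p in parts]),
            np.concatenate([p.y for p in parts]),
            parts[0].fs,
            np.concatenate([p.source for p in parts]),
            np.concatenate([p.channel_id for p in parts]),
            np.concatenate([p.start_time for p in parts]),
        )

    # -- persistence -------------------------------------------------------
    def to_npz(self, path) -> None:
        """Binary array container: segment matrix + label vector + metadata."""
        meta = {
            "fs": self.fs,
            "source": list(map(str, self.source)),
            "channel_id": list(map(str, self.channel_id)),
        }
        np.savez_compressed(
            path,
            X=self.X,
            y=self.y,
            start_time=self.start_time,
            meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
        )

    @classmethod
    def from_npz(cls, path) -> "SegmentDataset":
        with np.load(path, allow_pickle=False) as z:
            meta = json.loads(bytes(z["meta"].tobytes()).decode())
            return cls(
                z["X"], z["y"], meta["fs"], meta["source"], meta["channel_id"], z["start_time"]
            )

    def to_csv(self, path) -> None:
        """Plain-text mirror: one row per segment, sample columns then label.

        Sampling rate and provenance are not representable here; use the npz
        container for full fidelity.
        """
        df = pd.DataFrame(self.X)
        df.columns = [f"s{i}" for i in range(self.segment_length)]
        df["label"] = self.y
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, fs: float = 2400.0) -> "SegmentDataset":
        df = pd.read_csv(path)
        y = df.iloc[:, -1].to_numpy(dtype=int)
        X = df.iloc[:, :-1].to_numpy(dtype=float)
        return cls(X, y, fs)

    def __repr__(self) -> str:  # pragma: no cover
        c = self.class_counts()
        return (
            f"SegmentDataset(n={len(self)}, T={self.segment_length}, fs={self.fs}, "
            f"counts={c})"
        )
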