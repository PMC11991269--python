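"""Reading, writing and aligning 1 Hz recordings, hypnograms and epoch scorings.

A :class:`Recording` holds the three smartwatch channels the stager consumes
(heart rate in bpm, RR intervals in ms, 3-axis acceleration in g), sampled at
exactly 1 Hz.  A :class:`Hypnogram` holds one stage label per second over the
four-stage alphabet WAKE / LIGHT / DEEP / REM, where LIGHT merges NREM1 and
NREM2 and DEEP is NREM3.  Medical scorings arrive at 30 s granularity as an
:class:`EpochScoring` and are upsampled to 1 Hz before any second-by-second
comparison.

Timestamps are integer epoch-seconds; a series of length ``n`` starting at
``start_time`` covers the half-open interval ``[start_time, start_time + n)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import AlignmentError, DataError, FormatError, GapError

STAGES: tuple[str, ...] = ("WAKE", "LIGHT", "DEEP", "REM")
STAGE_INDEX: dict[str, int] = {s: i for i, s in enumerate(STAGES)}
STAGE_DTYPE = "U5"

HYPNOGRAM_SOURCES = ("algorithm", "medical", "wearable")

HR_RANGE = (20.0, 250.0)  # bpm, exclusive bounds
RR_RANGE = (200.0, 3000.0)  # ms, exclusive bounds

#: Largest timestamp gap (s) that may be imputed by last-observation-carried-forward.
MAX_FILL_GAP = 5

RECORDING_COLUMNS = ("timestamp", "hr_bpm", "rr_ms", "acc_x", "acc_y", "acc_z")
HYPNOGRAM_COLUMNS = ("timestamp", "stage")
EPOCH_COLUMNS = ("epoch_index", "stage")


@dataclass
class Recording:
    """Synchronized 1 Hz multichannel recording of one night.

    Parameters
    ----------
    start_time
        Epoch-seconds of the first sample.
    hr
        Heart rate, bpm, one value per second, in the open interval (20, 250).
    rr
        RR interval, ms, one per-second representative of the beat-to-beat
        interval (the latest completed interval), in (200, 3000).
    acc
        ``(n, 3)`` array of 3-axis acceleration, g units.
    subject_id
        Opaque label.
    imputed
        Boolean flag per second marking values filled in over a timestamp gap.
    """

    start_time: int
    hr: np.ndarray
    rr: np.ndarray
    acc: np.ndarray
    subject_id: str = "unknown"
    imputed: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.hr = np.asarray(self.hr, dtype=float)
        self.rr = np.asarray(self.rr, dtype=float)
        self.acc = np.asarray(self.acc, dtype=float)
        n = self.hr.size
        if n < 1:
            raise DataError("a Recording must contain at least one sample")
        if self.rr.shape != (n,) or self.acc.shape != (n, 3):
            raise DataError(
                f"channel length mismatch: hr {n}, rr {self.rr.shape}, acc {self.acc.shape}"
            )
        if self.imputed is None:
            self.imputed = np.zeros(n, dtype=bool)
        else:
            self.imputed = np.asarray(self.imputed, dtype=bool)
            if self.imputed.shape != (n,):
                raise DataError("imputed flags must have one entry per sample")
        for name, values, (lo, hi) in (
            ("hr", self.hr, HR_RANGE),
            ("rr", self.rr, RR_RANGE),
        ):
            bad = np.flatnonzero(~((values > lo) & (values < hi)))
            if bad.size:
                raise DataError(
                    f"{name} value {values[bad[0]]!r} at row {int(bad[0])} outside ({lo}, {hi})"
                )
        self.start_time = int(self.start_time)

    def __len__(self) -> int:
        return int(self.hr.size)

    @property
    def end_time(self) -> int:
        """One past the timestamp of the last sample."""
        return self.start_time + len(self)

    @property
    def timestamps(self) -> np.ndarray:
        return self.start_time + np.arange(len(self), dtype=np.int64)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "timestamp": self.timestamps,
                "hr_bpm": self.hr,
                "rr_ms": self.rr,
                "acc_x": self.acc[:, 0],
                "acc_y": self.acc[:, 1],
                "acc_z": self.acc[:, 2],
            }
        )


@dataclass
class Hypnogram:
    """Per-second stage labels over a night."""

    start_time: int
    stages: np.ndarray
    source: str = "algorithm"

    def __post_init__(self) -> None:
        self.stages = np.asarray(self.stages, dtype=STAGE_DTYPE)
        if self.stages.size < 1:
            raise DataError("a Hypnogram must contain at least one label")
        bad = np.flatnonzero(~np.isin(self.stages, STAGES))
        if bad.size:
            raise DataError(
                f"unknown stage label {self.stages[bad[0]]!r} at second {int(bad[0])}"
            )
        if self.source not in HYPNOGRAM_SOURCES:
            raise DataError(
                f"source must be one of {HYPNOGRAM_SOURCES}, got {self.source!r}"
            )
        self.start_time = int(self.start_time)

    def __len__(self) -> int:
        return int(self.stages.size)

    @property
    def end_time(self) -> int:
        return self.start_time + len(self)

    @property
    def timestamps(self) -> np.ndarray:
        return self.start_time + np.arange(len(self), dtype=np.int64)

    def stage_fractions(self) -> dict[str, float]:
        n = len(self)
        return {s: float(np.count_nonzero(self.stages == s)) / n for s in STAGES}


@dataclass
class EpochScoring:
    """Stage labels at fixed epoch granularity (30 s in standard PSG scoring)."""

    stages: np.ndarray
    epoch_length: int = 30

    def __post_init__(self) -> None:
        self.stages = np.asarray(self.stages, dtype=STAGE_DTYPE)
        if self.stages.size < 1:
            raise DataError("an EpochScoring must contain at least one epoch")
        if int(self.epoch_length) < 1:
            raise DataError("epoch_length must be >= 1 s")
        self.epoch_length = int(self.epoch_length)
        bad = np.flatnonzero(~np.isin(self.stages, STAGES))
        if bad.size:
            raise DataError(
                f"unknown stage label {self.stages[bad[0]]!r} at epoch {int(bad[0])}"
            )

    def __len__(self) -> int:
        return int(self.stages.size)


# ---------------------------------------------------------------------------
# column mapping


def _apply_dialect(
    frame: pd.DataFrame, required: tuple[str, ...], dialect: dict[str, str] | None
) -> pd.DataFrame:
    """Rename foreign column names to the canonical ones and check presence."""
    if dialect:
        inverse = {v: k for k, v in dialect.items()}
        frame = frame.rename(columns=inverse)
    for col in required:
        if col not in frame.columns:
            raise FormatError(f"missing required column {col!r}")
    return frame


def _numeric_column(frame: pd.DataFrame, name: str) -> np.ndarray:
    values = pd.to_numeric(frame[name], errors="coerce")
    bad = np.flatnonzero(values.isna().to_numpy() & frame[name].notna().to_numpy())
    if bad.size == 0:
        bad = np.flatnonzero(values.isna().to_numpy())
    if bad.size:
        raise DataError(
            f"non-numeric value {frame[name].iloc[bad[0]]!r} in column {name!r} "
            f"at data row {int(bad[0])}"
        )
    return values.to_numpy(dtype=float)


def _checked_timestamps(ts: np.ndarray) -> np.ndarray:
    if np.any(ts != np.round(ts)):
        raise DataError("timestamps must be integer epoch-seconds")
    ts = ts.astype(np.int64)
    dt = np.diff(ts)
    dup = np.flatnonzero(dt == 0)
    if dup.size:
        raise DataError(f"duplicate timestamp {int(ts[dup[0] + 1])} at data row {int(dup[0] + 1)}")
    dec = np.flatnonzero(dt < 0)
    if dec.size:
        raise DataError(
            f"non-monotone timestamp {int(ts[dec[0] + 1])} at data row {int(dec[0] + 1)}"
        )
    return ts


# ---------------------------------------------------------------------------
# recordings


def _fill_gaps(
    ts: np.ndarray, channels: dict[str, np.ndarray], max_gap: int
) -> tuple[dict[str, np.ndarray], np.ndarray]:
    """LOCF-fill gaps of at most ``max_gap`` seconds; raise GapError on larger."""
    dt = np.diff(ts)
    big = np.flatnonzero(dt > max_gap)
    if big.size:
        i = big[0]
        raise GapError(
            f"timestamp gap of {int(dt[i])} s after {int(ts[i])} exceeds the "
            f"{max_gap} s imputation limit; use read_recording_segments() to split"
        )
    span = int(ts[-1] - ts[0] + 1)
    idx = (ts - ts[0]).astype(np.int64)
    present = np.zeros(span, dtype=bool)
    present[idx] = True
    # index of the most recent present sample at or before each second
    carry = np.maximum.accumulate(np.where(present, np.arange(span), -1))
    src = carry[carry >= 0]  # present[0] is True by construction
    pos_of = np.full(span, -1, dtype=np.int64)
    pos_of[idx] = np.arange(idx.size)
    filled = {name: vals[pos_of[src]] for name, vals in channels.items()}
    return filled, ~present


def read_recording(
    path,
    dialect: dict[str, str] | None = None,
    gap_policy: str = "fill",
    subject_id: str | None = None,
) -> Recording:
    """Read a 1 Hz recording from a delimited text file.

    Parameters
    ----------
    path
        CSV file with header columns ``timestamp,hr_bpm,rr_ms,acc_x,acc_y,acc_z``
        (or foreign names remapped through ``dialect``).
    dialect
        Mapping from canonical column names to the names used in the file,
        e.g. ``{"hr_bpm": "heart_rate"}``.
    gap_policy
        ``"fill"`` imputes timestamp gaps of at most 5 s by carrying the last
        observation forward (flagged per second); ``"error"`` rejects any gap.
        Gaps larger than 5 s always raise :class:`GapError`.
    """
    if gap_policy not in ("fill", "error"):
        raise ValueError(f"unknown gap_policy {gap_policy!r}")
    frame = pd.read_csv(path, float_precision="round_trip")
    frame = _apply_dialect(frame, RECORDING_COLUMNS, dialect)
    ts = _checked_timestamps(_numeric_column(frame, "timestamp"))
    channels = {name: _numeric_column(frame, name) for name in RECORDING_COLUMNS[1:]}
    if gap_policy == "error" and np.any(np.diff(ts) != 1):
        i = int(np.flatnonzero(np.diff(ts) != 1)[0])
        raise GapError(f"timestamp gap after {int(ts[i])} with gap_policy='error'")
    filled, imputed = _fill_gaps(ts, channels, MAX_FILL_GAP)
    return Recording(
        start_time=int(ts[0]),
        hr=filled["hr_bpm"],
        rr=filled["rr_ms"],
        acc=np.column_stack([filled["acc_x"], filled["acc_y"], filled["acc_z"]]),
        subject_id=subject_id if subject_id is not None else "unknown",
        imputed=imputed,
    )


def read_recording_segments(
    path, dialect: dict[str, str] | None = None, subject_id: str | None = None
) -> list[Recording]:
    """Read a recording, splitting at timestamp gaps larger than 5 s.

    Classification restarts on each returned segment; gaps of at most 5 s
    inside a segment are LOCF-imputed exactly as in :func:`read_recording`.
    """
    frame = pd.read_csv(path, float_precision="round_trip")
    frame = _apply_dialect(frame, RECORDING_COLUMNS, dialect)
    ts = _checked_timestamps(_numeric_column(frame, "timestamp"))
    channels = {name: _numeric_column(frame, name) for name in RECORDING_COLUMNS[1:]}
    breaks = np.flatnonzero(np.diff(ts) > MAX_FILL_GAP) + 1
    segments = []
    for lo, hi in zip(np.r_[0, breaks], np.r_[breaks, ts.size]):
        part = {name: vals[lo:hi] for name, vals in channels.items()}
        filled, imputed = _fill_gaps(ts[lo:hi], part, MAX_FILL_GAP)
        segments.append(
            Recording(
                start_time=int(ts[lo]),
                hr=filled["hr_bpm"],
                rr=filled["rr_ms"],
                acc=np.column_stack(
                    [filled["acc_x"], filled["acc_y"], filled["acc_z"]]
                ),
                subject_id=subject_id if subject_id is not None else "unknown",
                imputed=imputed,
            )
        )
    return segments


def write_recording(rec: Recording, path) -> None:
    """Write a recording as CSV; ``read_recording`` round-trips it exactly."""
    rec.to_frame().to_csv(path, index=False)


# ---------------------------------------------------------------------------
# hypnograms and epoch scorings


def read_hypnogram(path, source: str = "algorithm") -> Hypnogram:
    """Read a per-second hypnogram CSV with columns ``timestamp,stage``."""
    frame = pd.read_csv(path, float_precision="round_trip")
    frame = _apply_dialect(frame, HYPNOGRAM_COLUMNS, None)
    ts = _checked_timestamps(_numeric_column(frame, "timestamp"))
    if np.any(np.diff(ts) != 1):
        i = int(np.flatnonzero(np.diff(ts) != 1)[0])
        raise DataError(f"hypnogram timestamps must be contiguous; gap after {int(ts[i])}")
    return Hypnogram(start_time=int(ts[0]), stages=frame["stage"].to_numpy(), source=source)


def write_hypnogram(hyp: Hypnogram, path) -> None:
    pd.DataFrame({"timestamp": hyp.timestamps, "stage": hyp.stages}).to_csv(
        path, index=False
    )


def read_epoch_scoring(path, epoch_length: int = 30) -> EpochScoring:
    """Read a 30 s epoch scoring CSV with columns ``epoch_index,stage``."""
    frame = pd.read_csv(path, float_precision="round_trip")
    frame = _apply_dialect(frame, EPOCH_COLUMNS, None)
    idx = _numeric_column(frame, "epoch_index").astype(np.int64)
    if np.any(idx != np.arange(idx.size)):
        raise DataError("epoch_index must run 0, 1, 2, ... without gaps")
    return EpochScoring(stages=frame["stage"].to_numpy(), epoch_length=epoch_length)


def upsample_epochs(
    scoring: EpochScoring, start_time: int = 0, source: str = "medical"
) -> Hypnogram:
    """Expand an epoch scoring to 1 Hz by repeating each label epoch_length times."""
    stages = np.repeat(scoring.stages, scoring.epoch_length)
    return Hypnogram(start_time=start_time, stages=stages, source=source)


def align_hypnograms(a: Hypnogram, b: Hypnogram) -> tuple[Hypnogram, Hypnogram]:
    """Trim two hypnograms to their common time span, second-aligned.

    Raises :class:`AlignmentError` when the spans are disjoint.
    """
    lo = max(a.start_time, b.start_time)
    hi = min(a.end_time, b.end_time)
    if hi <= lo:
        raise AlignmentError(
            f"hypnogram spans [{a.start_time}, {a.end_time}) and "
            f"[{b.start_time}, {b.end_time}) do not overlap"
        )
    return (
        Hypnogram(lo, a.stages[lo - a.start_time : hi - a.start_time], a.source),
        Hypnogram(lo, b.stages[lo - b.start_time : hi - b.start_time], b.source),
    )
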