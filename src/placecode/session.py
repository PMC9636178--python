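"""Session data model and on-disk format.

A *session* is one animal's continuous recording: a frame-synchronized
behavior table (time, track position, velocity, licking, reward delivery,
condition label) plus a cells x frames ``dF/F`` matrix and optional pupil
channels.  On disk a session is a directory containing ``behavior.tsv``
(tab-separated, one row per frame) and ``traces.h5`` (HDF5), with an
optional ``ground_truth.json`` for synthetic sessions.

Global conventions live here too: the track is ``track_length`` cm
(default 200), positions are 0-based cm in ``[0, track_length)``, and the
standard spatial discretization is 40 half-open 5 cm bins whose centers
are used whenever a bin must map back to cm.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np

#: Fixed vocabulary of condition labels: Rewarded, UnRewarded, Re-Rewarded,
#: Novel (rewarded), and a cue-free dark environment.
CONDITIONS = ("R", "UR", "RR", "N", "DARK")

BEHAVIOR_FILE = "behavior.tsv"
TRACES_FILE = "traces.h5"
GROUND_TRUTH_FILE = "ground_truth.json"


class SessionFormatError(Exception):
    """A mandatory file is missing or malformed."""


class SessionValidationError(Exception):
    """Loaded data violate the session invariants."""


@dataclass
class BinningSpec:
    """Spatial discretization and the immobility filter.

    The 2 m track is divided into ``n_bins`` half-open bins of
    ``bin_width`` cm; frames with speed below ``speed_threshold`` cm/s are
    treated as immobile and excluded from rate maps and decoder training.
    """

    n_bins: int = 40
    bin_width: float = 5.0
    speed_threshold: float = 1.0

    @property
    def track_length(self) -> float:
        return self.n_bins * self.bin_width

    @property
    def centers(self) -> np.ndarray:
        """Bin centers in cm, ``(i + 0.5) * bin_width``."""
        return (np.arange(self.n_bins) + 0.5) * self.bin_width

    def bin_of(self, position: np.ndarray) -> np.ndarray:
        """Bin index of each position, clipped into ``[0, n_bins - 1]``."""
        idx = np.floor(np.asarray(position) / self.bin_width).astype(int)
        return np.clip(idx, 0, self.n_bins - 1)

    def bins_covering(self, start_cm: float, end_cm: float) -> np.ndarray:
        """Indices of bins fully covered by ``[start_cm, end_cm]``."""
        first = int(np.ceil(start_cm / self.bin_width - 1e-9))
        last = int(np.floor(end_cm / self.bin_width + 1e-9))
        return np.arange(first, min(last, self.n_bins))


@dataclass
class SessionRecord:
    """One animal-session: behavior channels plus the dF/F matrix.

    All per-frame channels share length ``T``; ``dff`` is cells x T.
    """

    time: np.ndarray
    position: np.ndarray
    velocity: np.ndarray
    lick: np.ndarray
    reward: np.ndarray
    condition: np.ndarray
    dff: np.ndarray
    frame_rate: float = 30.0
    track_length: float = 200.0
    pupil_area: np.ndarray | None = None
    blink_area: np.ndarray | None = None
    animal_id: str = ""

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.position = np.asarray(self.position, dtype=float)
        self.velocity = np.asarray(self.velocity, dtype=float)
        self.lick = np.asarray(self.lick, dtype=bool)
        self.reward = np.asarray(self.reward, dtype=bool)
        self.condition = np.asarray(self.condition, dtype=object)
        self.dff = np.atleast_2d(np.asarray(self.dff, dtype=float))
        if self.pupil_area is not None:
            self.pupil_area = np.asarray(self.pupil_area, dtype=float)
        if self.blink_area is not None:
            self.blink_area = np.asarray(self.blink_area, dtype=float)

    @property
    def n_frames(self) -> int:
        return self.time.shape[0]

    @property
    def n_cells(self) -> int:
        return self.dff.shape[0]

    @property
    def run_mask(self) -> np.ndarray:
        """Frames with speed >= 1 cm/s (active exploration)."""
        return self.velocity >= 1.0


def validate_session(session: SessionRecord) -> list[str]:
    """Check every session invariant; return one message per violation.

    Violations are reported, never raised, so a partially corrupt session
    can still be inspected.
    """
    report: list[str] = []
    T = session.n_frames
    for name in ("position", "velocity", "lick", "reward", "condition"):
        arr = getattr(session, name)
        if arr.shape[0] != T:
            report.append(f"channel {name!r} has length {arr.shape[0]}, expected {T}")
    if session.dff.size and session.dff.shape[1] != T:
        report.append(f"dff has {session.dff.shape[1]} columns, expected {T} frames")
    for name in ("pupil_area", "blink_area"):
        arr = getattr(session, name)
        if arr is not None and arr.shape[0] != T:
            report.append(f"channel {name!r} has length {arr.shape[0]}, expected {T}")

    if session.position.shape[0] == T:
        bad = np.flatnonzero(
            (session.position < 0) | (session.position >= session.track_length)
        )
        for i in bad[:10]:
            report.append(
                f"position {session.position[i]:g} outside [0, {session.track_length:g}) "
                f"at frame {i}"
            )
        if bad.size > 10:
            report.append(f"... {bad.size - 10} further position violations")
    if session.velocity.shape[0] == T:
        if not np.all(np.isfinite(session.velocity)):
            report.append("velocity contains non-finite values")
        elif np.any(session.velocity < 0):
            report.append("velocity contains negative values")

    unknown = sorted(set(session.condition) - set(CONDITIONS))
    if unknown:
        report.append(f"condition labels outside vocabulary {CONDITIONS}: {unknown}")

    if T >= 2:
        dt = np.diff(session.time)
        if np.any(dt <= 0):
            report.append("time is not strictly increasing")
        else:
            expected = 1.0 / session.frame_rate
            if abs(np.median(dt) - expected) > 0.5 * expected:
                report.append(
                    f"median frame spacing {np.median(dt):.4f}s inconsistent with "
                    f"frame rate {session.frame_rate:g} Hz"
                )
    return report


def save_session(session: SessionRecord, path: str | Path) -> None:
    """Write a session directory (``behavior.tsv`` + ``traces.h5``).

    Floats are stored as 32-bit; integer/boolean channels round-trip
    bit-exactly.
    """
    import pandas as pd

    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    frame = np.arange(session.n_frames)
    table = pd.DataFrame(
        {
            "frame": frame,
            "time_s": session.time.astype(np.float32),
            "position_cm": session.position.astype(np.float32),
            "velocity_cms": session.velocity.astype(np.float32),
            "lick": session.lick.astype(int),
            "reward": session.reward.astype(int),
            "condition": session.condition,
        }
    )
    table.to_csv(path / BEHAVIOR_FILE, sep="\t", index=False)

    with h5py.File(path / TRACES_FILE, "w") as f:
        f.create_dataset("dff", data=session.dff.astype(np.float32))
        if session.pupil_area is not None:
            f.create_dataset("pupil_area", data=session.pupil_area.astype(np.float32))
        if session.blink_area is not None:
            f.create_dataset("blink_area", data=session.blink_area.astype(np.float32))
        f.attrs["frame_rate_hz"] = session.frame_rate
        f.attrs["track_length_cm"] = session.track_length
        f.attrs["animal_id"] = session.animal_id


def load_session(path: str | Path) -> SessionRecord:
    """Load a session directory saved by :func:`save_session`.

    Raises :class:`SessionFormatError` if a mandatory file is missing and
    :class:`SessionValidationError` if behavior and traces disagree on the
    frame count.  Missing optional channels load as ``None``.
    """
    import pandas as pd

    path = Path(path)
    behavior_path = path / BEHAVIOR_FILE
    traces_path = path / TRACES_FILE
    if not behavior_path.exists():
        raise SessionFormatError(f"missing mandatory file {behavior_path}")
    if not traces_path.exists():
        raise SessionFormatError(f"missing mandatory file {traces_path}")

    table = pd.read_csv(behavior_path, sep="\t")
    with h5py.File(traces_path, "r") as f:
        dff = np.asarray(f["dff"], dtype=float)
        pupil = np.asarray(f["pupil_area"], dtype=float) if "pupil_area" in f else None
        blink = np.asarray(f["blink_area"], dtype=float) if "blink_area" in f else None
        frame_rate = float(f.attrs.get("frame_rate_hz", 30.0))
        track_length = float(f.attrs.get("track_length_cm", 200.0))
        animal_id = str(f.attrs.get("animal_id", ""))

    T = len(table)
    if dff.size and dff.ndim == 2 and dff.shape[1] != T:
        raise SessionValidationError(
            f"behavior has {T} frames but traces have {dff.shape[1]} columns"
        )
    return SessionRecord(
        time=table["time_s"].to_numpy(dtype=float),
        position=table["position_cm"].to_numpy(dtype=float),
        velocity=table["velocity_cms"].to_numpy(dtype=float),
        lick=table["lick"].to_numpy(dtype=bool),
        reward=table["reward"].to_numpy(dtype=bool),
        condition=table["condition"].to_numpy(dtype=object),
        dff=dff if dff.size else np.zeros((0, T)),
        frame_rate=frame_rate,
        track_length=track_length,
        pupil_area=pupil,
        blink_area=blink,
        animal_id=animal_id,
    )


def load_ground_truth(path: str | Path) -> dict:
    """Load ``ground_truth.json`` from a synthetic session directory."""
    with open(Path(path) / GROUND_TRUTH_FILE) as f:
        return json.load(f)
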