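"""Domain types and file I/O for fNIRS hyperscanning recordings.

A :class:`Recording` holds one participant's oxygenated-hemoglobin (HbO)
time series as a channels x samples matrix.  The native on-disk format is a
plain TSV (column 1 ``time_s``, columns 2+ ``CH<k>``) with a JSON sidecar
carrying the participant role, sampling rate and channel labels, so every
artifact is inspectable with standard tools.  An adapter for SNIRF-style
HDF5 containers (HbO channels only) is provided for interoperability.

A :class:`SessionLayout` encodes the condition / block / turn-taking
timeline of one session in seconds; an :class:`INSTable` holds the
long-format interpersonal-neural-synchronization results
(dyad x channel pair x frequency scale x time lag).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Recording",
    "Phase",
    "SessionLayout",
    "INSTable",
    "CONDITIONS",
    "REST_FOR_CONDITION",
    "DEFAULT_REGION_LABELS",
    "read_recording",
    "write_recording",
    "read_layout",
    "write_layout",
    "read_ins_table",
    "write_ins_table",
]

#: Conditions of the communication paradigm: consecutive dialogue
#: interpreting (CI), simultaneous interpreting (SI), mother-tongue
#: retelling (CC), and the two resting baselines (silent rest and rest
#: while listening to rain sounds).
CONDITIONS = ("CI", "SI", "CC", "rest", "rest_rain")

#: Which resting baseline each task condition is subtracted against.
#: CI is recorded with rain-sound masking in the earphones, so its
#: baseline is the rest-with-rain-sounds recording; SI and CC use the
#: silent rest.
REST_FOR_CONDITION = {"CI": "rest_rain", "SI": "rest", "CC": "rest"}


class MalformedInputError(ValueError):
    """Raised when an input file violates the format contract."""


def _synthetic_region_labels() -> dict:
    """Synthetic channel -> cortical-region map for the 26-channel montage.

    This is a stand-in lookup table, not a product of anatomical
    registration: optode digitization and MNI/Brodmann labeling are out of
    scope, so channels are tagged with plausible region names for a 3x5
    left fronto-temporo-parietal patch (CH1-CH22) plus a 2x2 right
    temporoparietal patch (CH23-CH26).  The channels that matter for the
    reported effects carry their conventional tags: CH15 left
    temporoparietal junction (lTPJ), CH24 right TPJ (rTPJ), CH17 and CH8
    left inferior frontal gyrus (lIFG).
    """
    labels = {}
    for k in range(1, 23):
        if k in (8, 17):
            labels[f"CH{k}"] = "lIFG"
        elif k == 15:
            labels[f"CH{k}"] = "lTPJ"
        elif k <= 7:
            labels[f"CH{k}"] = "lFrontal"
        elif k <= 14:
            labels[f"CH{k}"] = "lTemporal"
        else:
            labels[f"CH{k}"] = "lParietal"
    for k in range(23, 27):
        labels[f"CH{k}"] = "rTPJ"
    return labels


#: Synthetic default region tags (see :func:`_synthetic_region_labels`).
DEFAULT_REGION_LABELS = _synthetic_region_labels()


@dataclass
class Recording:
    """One participant's multichannel HbO time series.

    Parameters
    ----------
    participant_role:
        Which member of the triad the recording belongs to: ``"A"``
        (Chinese-speaking interlocutor), ``"C"`` (English-speaking
        interlocutor) or ``"B"`` (interpreter; unused by the analyses).
    sampling_rate:
        Samples per second (the ETG-class instrument records at 10 Hz).
    data:
        Real matrix of shape (n_channels, n_samples), HbO concentration
        change in arbitrary units.
    channel_labels:
        Ordered channel names, ``CH1`` ... ``CH26`` by convention.
    region_labels:
        Optional channel -> region-tag map (e.g. ``CH15 -> lTPJ``).
    """

    participant_role: str
    sampling_rate: float
    data: np.ndarray
    channel_labels: list
    region_labels: Optional[dict] = None

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if self.data.ndim != 2:
            raise ValueError("data must be a 2-D channels x samples matrix")
        if len(self.channel_labels) != self.data.shape[0]:
            raise ValueError(
                f"{len(self.channel_labels)} channel labels for "
                f"{self.data.shape[0]} data rows"
            )
        if not np.all(np.isfinite(self.data)):
            raise MalformedInputError("recording contains non-finite samples")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sampling_rate

    def times(self) -> np.ndarray:
        """Sample times in seconds, 0-based from recording start."""
        return np.arange(self.n_samples) / self.sampling_rate

    def channel(self, label: str) -> np.ndarray:
        """Return one channel's series by label."""
        try:
            idx = self.channel_labels.index(label)
        except ValueError:
            raise KeyError(f"no channel {label!r}") from None
        return self.data[idx]

    def copy(self) -> "Recording":
        return Recording(
            participant_role=self.participant_role,
            sampling_rate=self.sampling_rate,
            data=self.data.copy(),
            channel_labels=list(self.channel_labels),
            region_labels=dict(self.region_labels) if self.region_labels else None,
        )


@dataclass(frozen=True)
class Phase:
    """One speaking/listening phase inside a turn-taking.

    ``phase_tag`` is ``A_speak_C_listen`` or ``C_speak_A_listen``; the
    window is half-open, ``[start_s, start_s + duration_s)``.
    """

    start_s: float
    duration_s: float
    phase_tag: str
    turn_index: int

    @property
    def end_s(self) -> float:
        return self.start_s + self.duration_s


PHASE_TAGS = ("A_speak_C_listen", "C_speak_A_listen")

#: In consecutive interpreting the speaker/listener roles swap every 45 s,
#: so every CI phase lasts exactly 45 s.
CI_PHASE_S = 45.0


@dataclass
class SessionLayout:
    """Condition / block / phase timeline of one session, in seconds.

    Blocks are ``[start_s, end_s]`` task intervals; phases (turn-taking
    halves) must lie inside a block, be non-overlapping, and — for the CI
    condition — last exactly 45 s.  Rest sessions have no turns.
    """

    condition: str
    blocks: list = field(default_factory=list)
    turns: list = field(default_factory=list)

    def __post_init__(self):
        if self.condition not in CONDITIONS:
            raise ValueError(
                f"unknown condition {self.condition!r}; expected one of {CONDITIONS}"
            )
        self.blocks = [(float(a), float(b)) for a, b in self.blocks]
        for a, b in self.blocks:
            if b <= a:
                raise ValueError(f"block ({a}, {b}) has non-positive length")
        turns = []
        for t in self.turns:
            if isinstance(t, Phase):
                turns.append(t)
            else:
                turns.append(Phase(**t))
        turns.sort(key=lambda p: p.start_s)
        for p in turns:
            if p.phase_tag not in PHASE_TAGS:
                raise ValueError(f"unknown phase tag {p.phase_tag!r}")
            if p.duration_s <= 0:
                raise ValueError("phase duration must be positive")
            if self.condition == "CI" and abs(p.duration_s - CI_PHASE_S) > 1e-9:
                raise ValueError(
                    f"CI phases last {CI_PHASE_S} s (roles swap every 45 s); "
                    f"got {p.duration_s}"
                )
            if not any(a - 1e-9 <= p.start_s and p.end_s <= b + 1e-9
                       for a, b in self.blocks):
                raise ValueError(
                    f"phase [{p.start_s}, {p.end_s}) extends outside every block"
                )
        for prev, nxt in zip(turns, turns[1:]):
            if nxt.start_s < prev.end_s - 1e-9:
                raise ValueError(
                    f"phases overlap: [{prev.start_s}, {prev.end_s}) and "
                    f"[{nxt.start_s}, {nxt.end_s})"
                )
        self.turns = turns

    @property
    def n_phases(self) -> int:
        return len(self.turns)

    def span_s(self) -> float:
        """End of the last block."""
        return max(b for _, b in self.blocks) if self.blocks else 0.0

    def shifted(self, offset_s: float, max_s: Optional[float] = None) -> "SessionLayout":
        """Re-reference the timeline by ``-offset_s`` (e.g. after edge
        trimming), dropping blocks/phases that fall outside ``[0, max_s)``."""
        blocks = []
        for a, b in self.blocks:
            a2, b2 = a - offset_s, b - offset_s
            if max_s is not None:
                a2, b2 = max(a2, 0.0), min(b2, max_s)
            else:
                a2 = max(a2, 0.0)
            if b2 > a2:
                blocks.append((a2, b2))
        turns = []
        for p in self.turns:
            s2 = p.start_s - offset_s
            if s2 < 0 or (max_s is not None and s2 + p.duration_s > max_s + 1e-9):
                continue
            turns.append(Phase(s2, p.duration_s, p.phase_tag, p.turn_index))
        return SessionLayout(self.condition, blocks, turns)


INS_COLUMNS = ["dyad", "condition", "chA", "chC",
               "scale_index", "period_s", "lag_s", "value"]
_INS_KEY = ["dyad", "condition", "chA", "chC", "scale_index", "lag_s"]


@dataclass
class INSTable:
    """Long-format INS-increase table.

    One row per (dyad, condition, channel pair, frequency scale, lag);
    ``value`` is the Fisher-z INS increase (task coherence minus matched
    rest coherence), ``lag_s`` the integer shift of participant C's series
    relative to A's in seconds (positive = C delayed).
    """

    df: pd.DataFrame

    def __post_init__(self):
        missing = [c for c in INS_COLUMNS if c not in self.df.columns]
        if missing:
            raise ValueError(f"INSTable missing columns {missing}")
        self.df = self.df[INS_COLUMNS].reset_index(drop=True)
        lags = self.df["lag_s"].to_numpy()
        if not np.allclose(lags, np.round(lags)):
            raise ValueError("lag_s must be whole seconds")
        self.df = self.df.astype({"scale_index": "int64", "lag_s": "int64",
                                  "period_s": "float64", "value": "float64"})
        if self.df.duplicated(subset=_INS_KEY).any():
            raise ValueError("duplicate (dyad, condition, pair, scale, lag) keys")

    def __len__(self) -> int:
        return len(self.df)

    @staticmethod
    def concat(tables: Sequence["INSTable"]) -> "INSTable":
        return INSTable(pd.concat([t.df for t in tables], ignore_index=True))


# ---------------------------------------------------------------------------
# Recording I/O

def write_recording(recording: Recording, path) -> None:
    """Write a recording as TSV (``time_s`` + one column per channel)
    with a JSON sidecar ``<stem>.json`` holding the metadata."""
    path = Path(path)
    df = pd.DataFrame(
        {"time_s": recording.times(), **{
            lab: recording.data[i] for i, lab in enumerate(recording.channel_labels)
        }}
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")
    sidecar = {
        "participant_role": recording.participant_role,
        "sampling_rate": recording.sampling_rate,
        "channel_labels": list(recording.channel_labels),
        "region_labels": recording.region_labels,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def read_recording(path, format_hint: Optional[str] = None) -> Recording:
    """Read a recording from the native TSV+sidecar format or a
    SNIRF-style HDF5 container.

    The time column must be uniform to 1e-6 s and is cross-checked
    against the sidecar's sampling rate; missing cells are rejected.
    """
    path = Path(path)
    fmt = format_hint or ("snirf" if path.suffix == ".snirf" else "tsv")
    if fmt == "snirf":
        return _read_snirf(path)
    if fmt != "tsv":
        raise ValueError(f"unknown format hint {format_hint!r}")

    df = pd.read_csv(path, sep="\t")
    if "time_s" not in df.columns:
        raise MalformedInputError("first column must be 'time_s'")
    if df.isna().any().any():
        raise MalformedInputError("missing cells in recording table")
    t = df["time_s"].to_numpy(dtype=float)
    if len(t) < 2:
        raise MalformedInputError("need at least two samples")
    dt = np.diff(t)
    if np.max(np.abs(dt - dt[0])) > 1e-6:
        raise MalformedInputError("non-uniform time step beyond 1e-6 s")
    rate = 1.0 / dt[0]

    sidecar_path = path.with_suffix(".json")
    role, labels, regions = "A", [c for c in df.columns if c != "time_s"], None
    if sidecar_path.exists():
        meta = json.loads(sidecar_path.read_text())
        role = meta.get("participant_role", role)
        regions = meta.get("region_labels")
        side_rate = meta.get("sampling_rate")
        if side_rate is not None and abs(side_rate - rate) > 1e-6 * side_rate:
            raise MalformedInputError(
                f"sidecar sampling rate {side_rate} Hz disagrees with time "
                f"column ({rate:.6g} Hz)"
            )
        side_labels = meta.get("channel_labels")
        if side_labels is not None:
            if list(side_labels) != labels:
                raise MalformedInputError("sidecar channel labels disagree with table")
    data = df[labels].to_numpy(dtype=float).T
    return Recording(role, rate, data, labels, regions)


def _read_snirf(path) -> Recording:
    """Minimal SNIRF (HDF5) reader: HbO channels of ``/nirs/data1`` only."""
    import h5py

    with h5py.File(path, "r") as f:
        nirs = f["nirs"] if "nirs" in f else f["nirs1"]
        data1 = nirs["data1"]
        time = np.asarray(data1["time"])
        dd = np.asarray(data1["dataTimeSeries"])  # samples x channels
        if len(time) == 2:  # SNIRF allows [start, dt]
            dt = time[1]
        else:
            steps = np.diff(time)
            if np.max(np.abs(steps - steps[0])) > 1e-6:
                raise MalformedInputError("non-uniform SNIRF time vector")
            dt = steps[0]
        keep, labels = [], []
        for name in sorted(
            (k for k in data1.keys() if k.startswith("measurementList")),
            key=lambda s: int(s.replace("measurementList", "")),
        ):
            ml = data1[name]
            dtl = ml["dataTypeLabel"][()] if "dataTypeLabel" in ml else b""
            if isinstance(dtl, bytes):
                dtl = dtl.decode()
            if str(dtl) == "HbO":
                idx = int(name.replace("measurementList", "")) - 1
                keep.append(idx)
                labels.append(f"CH{len(keep)}")
        if not keep:
            raise MalformedInputError("no HbO channels in SNIRF file")
        meta = nirs.get("metaDataTags")
        role = "A"
        if meta is not None and "participant_role" in meta:
            role = meta["participant_role"][()]
            if isinstance(role, bytes):
                role = role.decode()
    if not np.all(np.isfinite(dd)):
        raise MalformedInputError("missing cells in SNIRF data")
    return Recording(role, 1.0 / float(dt), dd[:, keep].T, labels)


# ---------------------------------------------------------------------------
# Layout I/O

def write_layout(layout: SessionLayout, path) -> None:
    payload = {
        "condition": layout.condition,
        "blocks": [list(b) for b in layout.blocks],
        "turns": [
            {"start_s": p.start_s, "duration_s": p.duration_s,
             "phase_tag": p.phase_tag, "turn_index": p.turn_index}
            for p in layout.turns
        ],
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def read_layout(path) -> SessionLayout:
    """Read and validate a session layout from its JSON representation."""
    payload = json.loads(Path(path).read_text())
    return SessionLayout(
        condition=payload["condition"],
        blocks=payload.get("blocks", []),
        turns=payload.get("turns", []),
    )


# ---------------------------------------------------------------------------
# INS table I/O

def write_ins_table(table: INSTable, path) -> None:
    table.df.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_ins_table(path) -> INSTable:
    df = pd.read_csv(path, sep="\t")
    return INSTable(df)  # duplicate keys rejected by the constructor
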