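"""From coherence maps to channel-wise, baseline-corrected, time-lagged
INS values.

The interpersonal-neural-synchronization (INS) value of a channel pair
is the Fisher-z wavelet coherence averaged over the task period, minus
the same quantity computed on the condition-matched resting baseline
(rest with rain sounds for CI; silent rest for SI and CC).  Time-lagged
INS shifts participant C's series relative to A's in whole seconds,
truncates both to the overlap, and recomputes the whole coherence
pipeline on the shifted series; lag 0 reproduces the unlagged value
exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .io import INS_COLUMNS, INSTable, Recording, REST_FOR_CONDITION, SessionLayout
from .wavelet import CoherenceMap, MorletParams, ScaleGrid, fisher_z, wtc

__all__ = [
    "LagGrid",
    "RestPairingError",
    "channelwise_ins",
    "task_average",
    "ins_increase",
    "lagged_ins",
    "band_average",
    "phase_average",
    "pool_phases",
]


class RestPairingError(ValueError):
    """Raised when a task condition is paired with the wrong resting
    baseline (CI must be corrected against rest with rain sounds; SI and
    CC against silent rest)."""


@dataclass(frozen=True)
class LagGrid:
    """Integer-second lag grid, symmetric around zero.

    Positive lag = participant C's series delayed relative to A's.
    """

    max_lag_s: int = 26
    lags_s: np.ndarray = field(init=False, repr=False)

    def __post_init__(self):
        if self.max_lag_s < 0:
            raise ValueError("max_lag_s must be >= 0")
        object.__setattr__(
            self, "lags_s", np.arange(-self.max_lag_s, self.max_lag_s + 1))

    def __len__(self):
        return len(self.lags_s)


def channelwise_ins(rec_a: Recording, rec_c: Recording, grid: ScaleGrid,
                    params: MorletParams = MorletParams(),
                    pairs: Optional[Sequence[Tuple[str, str]]] = None,
                    ) -> Dict[Tuple[str, str], CoherenceMap]:
    """Wavelet coherence for every requested (chA, chC) channel pair.

    With ``pairs=None`` all combinations are computed — 26 x 26 = 676
    maps for the full montage.
    """
    if rec_a.n_samples != rec_c.n_samples:
        raise ValueError("recordings must have equal length")
    if rec_a.sampling_rate != rec_c.sampling_rate:
        raise ValueError("recordings must share a sampling rate")
    if pairs is None:
        pairs = [(la, lc) for la in rec_a.channel_labels
                 for lc in rec_c.channel_labels]
    else:
        for la, lc in pairs:
            if la not in rec_a.channel_labels or lc not in rec_c.channel_labels:
                raise ValueError(f"pair ({la}, {lc}) not in the montage")
    out = {}
    for la, lc in pairs:
        out[(la, lc)] = wtc(rec_a.channel(la), rec_c.channel(lc),
                            rec_a.sampling_rate, grid, params)
    return out


def _window_slices(layout: SessionLayout, rate: float, n_times: int):
    slices = []
    for a, b in layout.blocks:
        i0 = int(round(a * rate))
        i1 = min(int(round(b * rate)), n_times)
        if i1 > i0 >= 0:
            slices.append(slice(i0, i1))
    return slices


def task_average(coh_map: CoherenceMap, layout: SessionLayout,
                 square_root: bool = True) -> np.ndarray:
    """Per-scale mean Fisher-z coherence over the task period (the
    layout's blocks, half-open windows)."""
    slices = _window_slices(layout, coh_map.sampling_rate, coh_map.n_times)
    if not slices:
        raise ValueError("task period is empty within the coherence map")
    z = fisher_z(coh_map.values, square_root=square_root)
    chunks = [z[:, s] for s in slices]
    total = np.concatenate(chunks, axis=1)
    if total.shape[1] == 0:
        raise ValueError("task period is empty within the coherence map")
    return total.mean(axis=1)


def ins_increase(task_avg: np.ndarray, rest_avg: np.ndarray,
                 task_condition: Optional[str] = None,
                 rest_condition: Optional[str] = None) -> np.ndarray:
    """Per-scale INS increase: task minus matched rest.

    If condition labels are given, the pairing is checked: CI must be
    corrected against rest_rain, SI and CC against rest.
    """
    task_avg = np.asarray(task_avg, dtype=float)
    rest_avg = np.asarray(rest_avg, dtype=float)
    if task_avg.shape != rest_avg.shape:
        raise ValueError("task and rest averages must share the scale grid")
    if task_condition is not None and rest_condition is not None:
        expected = REST_FOR_CONDITION.get(task_condition)
        if expected is None:
            raise RestPairingError(f"{task_condition!r} is not a task condition")
        if rest_condition != expected:
            raise RestPairingError(
                f"{task_condition} must be baseline-corrected against "
                f"{expected}, not {rest_condition}"
            )
    return task_avg - rest_avg


def _shift_pair(a: np.ndarray, c: np.ndarray, lag_samples: int):
    """Align A and C for a given lag (positive = C delayed), truncating
    to the overlap rather than wrapping around."""
    if lag_samples > 0:
        return a[:-lag_samples or None], c[lag_samples:]
    if lag_samples < 0:
        return a[-lag_samples:], c[:lag_samples]
    return a, c


def _lagged_layout(layout: SessionLayout, abs_lag_s: float,
                   overlap_s: float) -> SessionLayout:
    """Task windows for a lag-truncated pair of series.

    In the truncated index frame, sample i corresponds to different
    session times for A and C; a sample is kept as "task" only when it
    lies inside a task block on both participants' timelines, which
    works out to trimming |lag| seconds off every block end.  The rule
    is symmetric in the sign of the lag, which is what makes lagged INS
    invariant (up to lag negation) under swapping the roles of A and C.
    """
    blocks = []
    for a, b in layout.blocks:
        b2 = min(b - abs_lag_s, overlap_s)
        if b2 > a:
            blocks.append((a, b2))
    return SessionLayout(layout.condition, blocks=blocks, turns=[])


def lagged_ins(rec_a: Recording, rec_c: Recording, layout: SessionLayout,
               rest_a: Recording, rest_c: Recording, rest_layout: SessionLayout,
               grid: ScaleGrid, lag_grid: LagGrid = LagGrid(),
               params: MorletParams = MorletParams(),
               pairs: Optional[Sequence[Tuple[str, str]]] = None,
               dyad_id: int = 0, lag_rest: bool = False,
               square_root: bool = True) -> INSTable:
    """Time-lagged INS increase for the requested channel pairs.

    For every lag, C's series is shifted by ``lag * rate`` samples, both
    series are truncated to the overlap, the full coherence pipeline is
    recomputed on the shifted series, and the matched rest baseline is
    subtracted.  By default the rest baseline is computed once, unlagged
    (rest has no lead-lag structure); ``lag_rest=True`` recomputes it at
    every lag.
    """
    rate = rec_a.sampling_rate
    if pairs is None:
        pairs = [(la, lc) for la in rec_a.channel_labels
                 for lc in rec_c.channel_labels]
    max_lag = int(np.max(np.abs(lag_grid.lags_s)))
    overlap_s = rec_a.duration_s - max_lag
    if overlap_s < 60.0:
        raise ValueError("lagged overlap shorter than 60 s")
    if overlap_s < 2 * grid.max_scale:
        warnings.warn("lagged overlap shorter than twice the maximum scale",
                      stacklevel=2)

    rest_cond = rest_layout.condition
    frames: List[pd.DataFrame] = []
    scale_idx = np.arange(grid.n_scales)
    for la, lc in pairs:
        xa, xc = rec_a.channel(la), rec_c.channel(lc)
        ra, rc = rest_a.channel(la), rest_c.channel(lc)
        rest_z = None
        if not lag_rest:
            rest_map = wtc(ra, rc, rate, grid, params)
            rest_z = task_average(rest_map, rest_layout, square_root)
        for lag in lag_grid.lags_s:
            lag_samples = float(lag) * rate
            if abs(lag_samples - round(lag_samples)) > 1e-9:
                raise ValueError(f"lag {lag} s is not a whole sample count")
            L = int(round(lag_samples))
            a_seg, c_seg = _shift_pair(xa, xc, L)
            coh = wtc(a_seg, c_seg, rate, grid, params)
            lay = _lagged_layout(layout, abs(L) / rate, len(a_seg) / rate)
            tz = task_average(coh, lay, square_root)
            if lag_rest:
                ra_seg, rc_seg = _shift_pair(ra, rc, L)
                rest_map = wtc(ra_seg, rc_seg, rate, grid, params)
                rlay = _lagged_layout(rest_layout, abs(L) / rate,
                                      len(ra_seg) / rate)
                rest_z = task_average(rest_map, rlay, square_root)
            inc = ins_increase(tz, rest_z, layout.condition, rest_cond)
            frames.append(pd.DataFrame({
                "dyad": dyad_id, "condition": layout.condition,
                "chA": la, "chC": lc, "scale_index": scale_idx,
                "period_s": grid.periods, "lag_s": int(lag), "value": inc,
            }))
    return INSTable(pd.concat(frames, ignore_index=True)[INS_COLUMNS])


def band_average(ins_by_scale: np.ndarray, grid: ScaleGrid,
                 band: Tuple[float, float]) -> float:
    """Mean INS over the scales whose frequency lies in
    ``[band[0], band[1]]`` Hz."""
    mask = grid.band_mask(*band)
    if not mask.any():
        raise ValueError(f"no grid scale falls in band {band} Hz")
    return float(np.asarray(ins_by_scale, dtype=float)[mask].mean())


def phase_average(coh_map: CoherenceMap, layout: SessionLayout,
                  delay_s: float = 6.0,
                  square_root: bool = True) -> pd.DataFrame:
    """Per-phase, per-scale mean Fisher-z coherence.

    Phase windows are shifted forward by ``delay_s`` (the ~6 s
    hemodynamic delay-to-peak), so neural responses to a phase are read
    out where the blood-flow response actually peaks.  Windows running
    past the record end are truncated with a warning; windows entirely
    outside raise.
    """
    if not layout.turns:
        raise ValueError("layout has no phases")
    rate = coh_map.sampling_rate
    z = fisher_z(coh_map.values, square_root=square_root)
    records = []
    for p in layout.turns:
        i0 = int(round((p.start_s + delay_s) * rate))
        i1 = int(round((p.start_s + p.duration_s + delay_s) * rate))
        if i0 >= coh_map.n_times:
            raise ValueError(
                f"shifted window of turn {p.turn_index} ({p.phase_tag}) lies "
                "entirely outside the record")
        if i1 > coh_map.n_times:
            warnings.warn(
                f"shifted window of turn {p.turn_index} truncated at the "
                "record end", stacklevel=2)
            i1 = coh_map.n_times
        records.append({
            "turn_index": p.turn_index,
            "phase_tag": p.phase_tag,
            "values": z[:, i0:i1].mean(axis=1),
        })
    df = pd.DataFrame(records)
    return df


def pool_phases(phase_df: pd.DataFrame) -> Dict[str, np.ndarray]:
    """Pool phase averages by tag across turns: one per-scale vector per
    phase type (A-speaking vs C-speaking), i.e. one value per dyad per
    direction once band-averaged."""
    out = {}
    for tag, group in phase_df.groupby("phase_tag"):
        out[tag] = np.mean(np.stack(group["values"].to_numpy()), axis=0)
    return out
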