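"""Benign/ectopic classification of paced traces by early afterdepolarizations.

A beat exhibits an EAD when, besides the primary (upstroke) peak, the
voltage shows a secondary local maximum that rose above -50 mV and is
separated from every other detected peak in the beat by at least 100 ms.
Four successive beats are analysed so that alternans (EADs on every second
beat) is not missed: the cell is ectopic if *any* of the four beats is
flagged. Beats are delimited by stimulus onsets (half-open windows), and
peak detection uses a small prominence floor (1 mV by default) to ignore
solver ripple.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks

from .cell_model import APTrace

#: Voltage a secondary peak must exceed (strict) to count as an EAD.
EAD_VOLTAGE_MV = -50.0
#: Minimum separation (inclusive) between an EAD peak and every other peak.
EAD_SEPARATION_MS = 100.0
#: Default peak prominence floor (mV); not a study value, suppresses ripple.
PEAK_PROMINENCE_MV = 1.0


@dataclass(frozen=True)
class Peak:
    """A local maximum of the voltage trace."""

    time: float  # ms
    voltage: float  # mV
    beat: int


@dataclass(frozen=True)
class CellLabel:
    """Classification outcome with per-beat detail."""

    ectopic: bool
    beat_flags: tuple[bool, ...]
    peaks: tuple[Peak, ...]

    @property
    def label(self) -> str:
        return "ectopic" if self.ectopic else "benign"


def detect_peaks(trace: APTrace, prominence: float = PEAK_PROMINENCE_MV) -> list[Peak]:
    """All local maxima with at least ``prominence`` mV, assigned to beats."""
    if len(trace.time) < 3:
        raise ValueError("trace too short for peak detection")
    if np.median(np.diff(trace.time)) > 1.0 + 1e-9:
        raise ValueError("trace must be sampled at <= 1 ms for peak detection")
    idx, _ = find_peaks(trace.vm, prominence=prominence)
    cl = trace.protocol.cycle_length
    return [
        Peak(
            time=float(trace.time[i]),
            voltage=float(trace.vm[i]),
            beat=int(trace.time[i] // cl),
        )
        for i in idx
    ]


def classify_beat(
    peaks: list[Peak],
    beat: int,
    voltage_mv: float = EAD_VOLTAGE_MV,
    separation_ms: float = EAD_SEPARATION_MS,
) -> bool:
    """EAD flag for one beat.

    True iff a non-primary peak rises above ``voltage_mv`` (strict) and its
    time differs by at least ``separation_ms`` (inclusive) from every other
    detected peak in the beat. The primary peak is the earliest peak of the
    beat (the upstroke).
    """
    in_beat = sorted((p for p in peaks if p.beat == beat), key=lambda p: p.time)
    if len(in_beat) < 2:
        return False
    for p in in_beat[1:]:
        if p.voltage <= voltage_mv:
            continue
        if all(
            abs(p.time - q.time) >= separation_ms for q in in_beat if q is not p
        ):
            return True
    return False


def classify_cell(
    trace: APTrace,
    prominence: float = PEAK_PROMINENCE_MV,
    voltage_mv: float = EAD_VOLTAGE_MV,
    separation_ms: float = EAD_SEPARATION_MS,
    min_beats: int = 4,
) -> CellLabel:
    """Benign/ectopic label from the recorded beats (any-beat rule)."""
    n_beats = trace.n_beats
    if n_beats < min_beats:
        raise ValueError(
            f"classification needs >= {min_beats} recorded beats, got {n_beats}"
        )
    peaks = detect_peaks(trace, prominence=prominence)
    flags = tuple(
        classify_beat(peaks, b, voltage_mv, separation_ms) for b in range(n_beats)
    )
    return CellLabel(ectopic=any(flags), beat_flags=flags, peaks=tuple(peaks))
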