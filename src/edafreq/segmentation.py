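"""Sliding-window segmentation into fixed-length, single-state segments.

Candidate windows start on the fixed grid 0, t_step, 2*t_step, ... over the
whole signal. A window is emitted only if every label inside it is identical
and not ``other``, so no segment ever mixes affective states; windows that
straddle a state transition are rejected, never emitted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .signal_io import LabeledSignal

PREPROCESS_MODES = ("mean-removal", "none")


@dataclass(frozen=True)
class SegmentationConfig:
    """Window length and overlap, both in samples.

    Defaults are 48-sample windows with 20-sample overlap: 12 s windows
    advancing by 7 s at the 4 Hz wrist-EDA rate.
    """

    t_length: int = 48
    t_overlap: int = 20

    def __post_init__(self) -> None:
        if not 0 <= self.t_overlap < self.t_length:
            raise ValueError(
                f"need 0 <= t_overlap < t_length, got "
                f"t_overlap={self.t_overlap}, t_length={self.t_length}"
            )

    @property
    def t_step(self) -> int:
        return self.t_length - self.t_overlap


@dataclass
class Segment:
    """One fixed-length window of a signal carrying a single state label."""

    subject_id: str
    label: str
    start: int
    values: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.label == "other":
            raise ValueError("segments never carry the 'other' label")


def segment(signal: LabeledSignal, config: SegmentationConfig = SegmentationConfig()) -> list[Segment]:
    """Cut a labeled signal into pure single-state segments.

    Returns segments in temporal order. A signal shorter than ``t_length``
    yields an empty list.
    """
    n = len(signal)
    out: list[Segment] = []
    labels = signal.labels
    for start in range(0, n - config.t_length + 1, config.t_step):
        window = labels[start : start + config.t_length]
        first = window[0]
        if first == "other":
            continue
        if all(lbl == first for lbl in window):
            out.append(
                Segment(
                    subject_id=signal.subject_id,
                    label=first,
                    start=start,
                    values=signal.samples[start : start + config.t_length].copy(),
                    fs=signal.fs,
                )
            )
    return out


def preprocess_segment(seg: Segment, mode: str = "mean-removal") -> Segment:
    """Per-segment preprocessing before spectral analysis.

    ``mean-removal`` subtracts the segment's own sample mean, which zeroes
    the DC bin of its DFT; raw skin conductance carries a large positive
    tonic offset that would otherwise dominate every energy-based feature.
    ``none`` returns the segment unchanged.
    """
    if mode not in PREPROCESS_MODES:
        raise ValueError(f"unknown preprocess mode {mode!r}; use one of {PREPROCESS_MODES}")
    if mode == "none":
        return seg
    return Segment(
        subject_id=seg.subject_id,
        label=seg.label,
        start=seg.start,
        values=seg.values - seg.values.mean(),
        fs=seg.fs,
    )
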