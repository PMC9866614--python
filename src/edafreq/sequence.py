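"""Sequence analysis: windowed mean and variance over w consecutive segments.

Stress episodes produce feature trajectories that are not only shifted but
also less variable than other states, so each per-segment base feature a is
augmented with its mean M_w and variance V_w over the w most recent
segments. The window uses exactly w terms with divisor w for the mean and
the population normalizer 1/w for the variance. With 3m + 1 base features
this triples the table to 3*(3m + 1) columns.

Windows never span a subject or state boundary: a training row mixing
states would have no defined class label. The first w - 1 segments of each
uniform run produce no output row (no padding).
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view

from .signal_io import METADATA_COLUMNS, feature_columns


def _windows(values: Sequence[float], w: int) -> np.ndarray:
    if w < 1:
        raise ValueError(f"window size must be >= 1, got {w}")
    values = np.asarray(values, dtype=float)
    if values.ndim != 1:
        raise ValueError("values must be one-dimensional")
    if len(values) < w:
        raise ValueError(f"need at least w={w} values, got {len(values)}")
    return sliding_window_view(values, w)


def windowed_mean(values: Sequence[float], w: int) -> np.ndarray:
    """Mean of each w-long trailing window; output length len(values) - w + 1."""
    return _windows(values, w).mean(axis=1)


def windowed_variance(values: Sequence[float], w: int) -> np.ndarray:
    """Population variance (1/w) of each w-long trailing window."""
    return _windows(values, w).var(axis=1)


def sequence_feature_names(base_names: Sequence[str]) -> list[str]:
    """Column names of the sequence table: a, mw_a, vw_a per base feature a."""
    names: list[str] = []
    for a in base_names:
        names += [a, f"mw_{a}", f"vw_{a}"]
    return names


def assemble_sequence_features(table: pd.DataFrame, w: int) -> pd.DataFrame:
    """Expand a per-segment feature table with windowed mean and variance.

    The input must hold one row per segment in temporal order within each
    subject, with columns ``subject_id``, ``label``, ``segment_start`` and
    the base features. Windows are formed only over w consecutive rows
    sharing one subject and one label; each output row carries the metadata
    of its most recent segment. Runs shorter than w contribute no rows.
    """
    if w < 1:
        raise ValueError(f"window size must be >= 1, got {w}")
    base = feature_columns(table)
    out_cols = list(METADATA_COLUMNS) + sequence_feature_names(base)
    pieces: list[pd.DataFrame] = []
    for _, subject_rows in table.groupby("subject_id", sort=False):
        run_id = (subject_rows["label"] != subject_rows["label"].shift()).cumsum()
        for _, run in subject_rows.groupby(run_id, sort=False):
            if len(run) < w:
                continue
            piece = {c: run[c].to_numpy()[w - 1 :] for c in METADATA_COLUMNS}
            for a in base:
                values = run[a].to_numpy(dtype=float)
                piece[a] = values[w - 1 :]
                piece[f"mw_{a}"] = windowed_mean(values, w)
                piece[f"vw_{a}"] = windowed_variance(values, w)
            pieces.append(pd.DataFrame(piece))
    if not pieces:
        return pd.DataFrame(columns=out_cols)
    return pd.concat(pieces, ignore_index=True)[out_cols]
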