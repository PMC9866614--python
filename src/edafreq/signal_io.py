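"""Labeled skin-conductance signals and their external representations.

The central container is :class:`LabeledSignal`: a subject's conductance
samples (microsiemens) with one affective-state label per sample. State
labels are restricted to the four codes ``baseline``, ``stress``,
``amusement`` and ``other``; ``other`` marks everything downstream stages
must ignore (transients, meditation, mixed label blocks).

The WESAD adapter reads the per-subject pickle records distributed with the
public WESAD dataset (wrist EDA at 4 Hz, labels at 700 Hz) and aligns the
high-rate labels to the EDA sampling grid. The rest of the package depends
only on :class:`LabeledSignal`, never on the adapter.
"""

from __future__ import annotations

import pickle
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import MalformedRecordError, SchemaError

#: The four state codes that may appear on a LabeledSignal.
STATE_CODES = ("baseline", "stress", "amusement", "other")

#: WESAD numeric protocol codes mapped to state names. Codes 0 (transient),
#: 4 (meditation) and 5-7 carry no affective condition used here and map to
#: "other", which excludes them from every experiment.
WESAD_CODE_MAP = {1: "baseline", 2: "stress", 3: "amusement"}

#: WESAD label rate (700 Hz) over wrist-EDA rate (4 Hz).
WESAD_LABEL_RATIO = 175

METADATA_COLUMNS = ("subject_id", "label", "segment_start")


@dataclass
class LabeledSignal:
    """A subject's conductance time series with per-sample state labels.

    Parameters
    ----------
    subject_id
        Opaque subject identifier.
    samples
        Conductance values in microsiemens, one per time step.
    labels
        State code per sample, each one of :data:`STATE_CODES`.
    fs
        Sampling rate in Hz (wrist EDA from the Empatica E4 is 4 Hz).
    """

    subject_id: str
    samples: np.ndarray
    labels: np.ndarray
    fs: float = 4.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        self.labels = np.asarray(self.labels, dtype=object)
        if self.samples.ndim != 1:
            raise ValueError("samples must be one-dimensional")
        if len(self.samples) != len(self.labels):
            raise ValueError(
                f"samples ({len(self.samples)}) and labels ({len(self.labels)}) "
                "must have equal length"
            )
        if not self.fs > 0:
            raise ValueError("sampling rate must be positive")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples must be finite")
        bad = set(self.labels) - set(STATE_CODES)
        if bad:
            raise ValueError(f"unknown state codes: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.samples)


def _canonical_label(value) -> str:
    """Map a raw label (WESAD numeric code or state name) to a state code."""
    if isinstance(value, (int, np.integer)):
        return WESAD_CODE_MAP.get(int(value), "other")
    if value in STATE_CODES:
        return value
    return "other"


def resample_labels(labels_hi: Sequence, ratio: int) -> np.ndarray:
    """Downsample a high-rate label stream by uniform-block reduction.

    Output element ``t`` summarises the block ``labels_hi[t*ratio:(t+1)*ratio]``:
    the block's (canonicalised) label when all entries agree, else ``"other"``.
    Mapping mixed blocks to ``other`` guarantees that samples spanning a state
    transition can never enter a single-state segment downstream.

    Parameters
    ----------
    labels_hi
        Label stream at the higher rate (WESAD numeric codes or state names).
    ratio
        Integer number of high-rate labels per output label (700/4 = 175 for
        WESAD wrist EDA).
    """
    if ratio < 1:
        raise ValueError(f"ratio must be >= 1, got {ratio}")
    labels_hi = np.asarray(labels_hi, dtype=object)
    n_out = len(labels_hi) // ratio
    blocks = labels_hi[: n_out * ratio].reshape(n_out, ratio)
    out = np.empty(n_out, dtype=object)
    for t, block in enumerate(blocks):
        first = block[0]
        out[t] = _canonical_label(first) if all(b == first for b in block) else "other"
    return out


def read_wesad_subject(path, ratio: int = WESAD_LABEL_RATIO) -> LabeledSignal:
    """Read one WESAD per-subject pickle record as a 4 Hz LabeledSignal.

    The record must contain a wrist-EDA channel (``signal/wrist/EDA``) and a
    700 Hz label channel (``label``). Chest channels are ignored if present.

    Raises
    ------
    MalformedRecordError
        If the EDA or label channel is absent.
    """
    path = Path(path)
    with open(path, "rb") as fh:
        record = pickle.load(fh, encoding="latin1")

    try:
        eda = record["signal"]["wrist"]["EDA"]
    except (KeyError, TypeError) as exc:
        raise MalformedRecordError(
            f"{path.name}: missing wrist EDA channel (signal/wrist/EDA)"
        ) from exc
    try:
        labels_hi = record["label"]
    except (KeyError, TypeError) as exc:
        raise MalformedRecordError(f"{path.name}: missing label channel") from exc

    eda = np.asarray(eda, dtype=float).ravel()
    labels = resample_labels(np.asarray(labels_hi).ravel(), ratio)
    n = min(len(eda), len(labels))
    subject_id = str(record.get("subject", path.stem))
    return LabeledSignal(subject_id=subject_id, samples=eda[:n], labels=labels[:n])


def write_feature_table(rows: Iterable[dict] | pd.DataFrame, path) -> None:
    """Write feature records to CSV (UTF-8, '.' decimal, header row).

    Every record must carry ``subject_id``, ``label`` and ``segment_start``
    plus an identical ordered set of feature names.

    Raises
    ------
    SchemaError
        If records disagree on their feature-name set or lack metadata.
    """
    if isinstance(rows, pd.DataFrame):
        table = rows
        missing = [c for c in METADATA_COLUMNS if c not in table.columns]
        if missing:
            raise SchemaError(f"missing metadata columns: {missing}")
    else:
        rows = list(rows)
        if rows:
            reference = list(rows[0].keys())
            missing = [c for c in METADATA_COLUMNS if c not in reference]
            if missing:
                raise SchemaError(f"missing metadata columns: {missing}")
            for i, row in enumerate(rows):
                if list(row.keys()) != reference:
                    raise SchemaError(
                        f"row {i} feature names differ from row 0: "
                        f"{list(row.keys())} vs {reference}"
                    )
            table = pd.DataFrame(rows, columns=reference)
        else:
            table = pd.DataFrame(columns=list(METADATA_COLUMNS))
    table.to_csv(path, index=False, encoding="utf-8")


def read_feature_table(path) -> pd.DataFrame:
    """Read a feature table written by :func:`write_feature_table`."""
    table = pd.read_csv(path, encoding="utf-8")
    missing = [c for c in METADATA_COLUMNS if c not in table.columns]
    if missing:
        raise SchemaError(f"feature table at {path} lacks columns: {missing}")
    return table


def feature_columns(table: pd.DataFrame) -> list[str]:
    """Names of the non-metadata (feature) columns, in table order."""
    return [c for c in table.columns if c not in METADATA_COLUMNS]
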