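"""Glue from labeled signals to the final sequence-feature table."""

from __future__ import annotations

import logging
from typing import Iterable, Sequence

import pandas as pd

from .errors import ZeroEnergySegmentError
from .segmentation import SegmentationConfig, preprocess_segment, segment
from .sequence import assemble_sequence_features
from .signal_io import METADATA_COLUMNS, LabeledSignal
from .spectral import DEFAULT_BANDS, FrequencyBand, extract_segment_features, feature_names

logger = logging.getLogger(__name__)


def extract_base_features(
    signals: Iterable[LabeledSignal],
    config: SegmentationConfig = SegmentationConfig(),
    bands: Sequence[FrequencyBand] = DEFAULT_BANDS,
    preprocess: str = "mean-removal",
    normalize: str = "none",
    include_dc: bool = False,
) -> pd.DataFrame:
    """Per-segment feature table over a cohort, one row per pure segment.

    Zero-energy segments (e.g. perfectly constant after mean removal) are
    dropped with a logged count; real conductance never produces them.
    """
    rows: list[dict] = []
    n_dropped = 0
    for signal in signals:
        for seg in segment(signal, config):
            seg = preprocess_segment(seg, preprocess)
            try:
                features = extract_segment_features(
                    seg, bands=bands, normalize=normalize, include_dc=include_dc
                )
            except ZeroEnergySegmentError:
                n_dropped += 1
                continue
            rows.append(
                {
                    "subject_id": seg.subject_id,
                    "label": seg.label,
                    "segment_start": seg.start,
                    **features,
                }
            )
    if n_dropped:
        logger.info("dropped %d zero-energy segment(s)", n_dropped)
    columns = list(METADATA_COLUMNS) + feature_names(bands)
    return pd.DataFrame(rows, columns=columns)


def extract_features(
    signals: Iterable[LabeledSignal],
    config: SegmentationConfig = SegmentationConfig(),
    bands: Sequence[FrequencyBand] = DEFAULT_BANDS,
    w: int = 7,
    preprocess: str = "mean-removal",
    normalize: str = "none",
    include_dc: bool = False,
) -> pd.DataFrame:
    """Full pipeline: segment, spectral features, then sequence expansion."""
    base = extract_base_features(
        signals, config, bands, preprocess=preprocess, normalize=normalize, include_dc=include_dc
    )
    return assemble_sequence_features(base, w)
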