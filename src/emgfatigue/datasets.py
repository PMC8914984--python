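"""Packaged study tables, hand-transcribed cell-by-cell from the printed source.

Four small CSV fixtures ship with the package:

- ``table6_segment_labels.csv`` — per-muscle segment classifications for the
  first three and last three windows of each fatigue session (the accounting
  table behind the confusion counts).
- ``table5_fatigue_indices.csv`` — first/last-segment fatigue indices and the
  time to reported fatigue per muscle.
- ``table4_iemg_slopes.csv`` — IEMG regression slopes per muscle in the
  non-fatigue and fatigue conditions.
- ``table3_spectral_frequencies.csv`` — first-segment MNF/MDF per muscle
  (the evidence for the 80 Hz low/high band boundary).

One muscle (subject 3, right) was excluded from the study and appears as
not-examined / missing throughout, leaving 75 usable muscles.
"""
from __future__ import annotations

from importlib.resources import files

import pandas as pd

from .io import LabelTable, read_label_table


def _fixture_path(name: str) -> str:
    return str(files("emgfatigue.data").joinpath(name))


def segment_labels_path() -> str:
    """Filesystem path of the packaged segment-label table."""
    return _fixture_path("table6_segment_labels.csv")


def load_segment_labels() -> LabelTable:
    """The per-muscle segment classification table (75 usable muscle rows)."""
    return read_label_table(segment_labels_path())


def load_fatigue_indices() -> pd.DataFrame:
    """First/last-segment fatigue indices and time-to-fatigue per muscle.

    The excluded muscle's numeric fields are NaN.
    """
    return pd.read_csv(_fixture_path("table5_fatigue_indices.csv"))


def load_iemg_slopes() -> pd.DataFrame:
    """Per-muscle IEMG regression slopes for non-fatigue and fatigue sessions."""
    return pd.read_csv(_fixture_path("table4_iemg_slopes.csv"))


def load_spectral_frequencies() -> pd.DataFrame:
    """First-segment MNF and MDF per muscle in the fatigue condition."""
    return pd.read_csv(_fixture_path("table3_spectral_frequencies.csv"))
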