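"""Band + threshold segment classifier.

A segment is labeled *tremor* exactly when its dominant frequency lies
inside the tremor bandwidth (inclusive bounds; the upper limit defaults to
12 Hz, covering the common tremor disorders) and the density amplitude at
the dominant frequency strictly exceeds the power threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .domfreq import DFResult, df_table
from .preprocess import SegmentSet

__all__ = ["DetectionParams", "classify_segment", "classify_table", "classify_set"]

#: Fixed upper limit of the tremor bandwidth (Hz).
BAND_UPPER_DEFAULT = 12.0


@dataclass(frozen=True)
class DetectionParams:
    """Classifier parameters: tremor band and power threshold.

    ``power_threshold`` is a one-sided density value in m^2/s^4 per Hz,
    compared against the DF amplitude.
    """

    band_lower: float
    band_upper: float = BAND_UPPER_DEFAULT
    power_threshold: float = 0.0

    def __post_init__(self) -> None:
        if not 0 <= self.band_lower <= self.band_upper:
            raise ValueError(
                f"need 0 <= band_lower <= band_upper, got "
                f"({self.band_lower:g}, {self.band_upper:g})"
            )
        if self.power_threshold < 0:
            raise ValueError("power_threshold must be >= 0")


def classify_segment(df: DFResult, params: DetectionParams) -> str:
    """Pure band + threshold decision for one dominant frequency."""
    in_band = params.band_lower <= df.freq <= params.band_upper
    loud = df.amplitude > params.power_threshold
    return "tremor" if (in_band and loud) else "no_tremor"


def classify_table(table: pd.DataFrame, params: DetectionParams) -> pd.DataFrame:
    """Apply the classifier to a dominant-frequency table.

    Vectorized counterpart of :func:`classify_segment`; the input frame is
    one produced by :func:`tremorkit.domfreq.df_table`.
    """
    pred = (
        (table["freq_hz"] >= params.band_lower)
        & (table["freq_hz"] <= params.band_upper)
        & (table["amplitude"] > params.power_threshold)
    )
    out = table[["patient_id", "segment_index", "method"]].copy()
    out["prediction"] = pd.Series(
        pred.map({True: "tremor", False: "no_tremor"}), index=table.index
    )
    return out


def classify_set(
    segset: SegmentSet,
    method: str,
    params: DetectionParams,
    include_discard: bool = False,
) -> pd.DataFrame:
    """Classify every (non-discard) segment of a set with one method.

    Dominant frequencies are computed once and cached on the set, so
    re-classifying under new parameters is a comparison-only pass.
    """
    table = df_table(segset, method)
    if not include_discard:
        table = table[table["ref_label"] != "discard"].reset_index(drop=True)
    return classify_table(table, params)
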