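"""Recording I/O, band-limiting filters, resampling and segmentation.

Raw uniaxial accelerometer recordings (m/s^2) are read from plain-text
CSV/TSV, band-limited with zero-phase Butterworth filters (high-pass to
remove gravity/drift, low-pass to suppress mains artifact), optionally
decimated to a working rate, and cut into non-overlapping fixed-length
segments that are the unit of all downstream classification.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal

__all__ = [
    "LABELS",
    "Recording",
    "Segment",
    "SegmentSet",
    "read_recording",
    "band_limit",
    "resample",
    "segment",
    "attach_labels",
]

#: Closed set of per-segment reference labels.
LABELS = ("tremor", "no_tremor", "discard", "unlabeled")

#: Labels allowed in an on-disk label table (``unlabeled`` is implicit).
TABLE_LABELS = ("tremor", "no_tremor", "discard")


@dataclass
class Recording:
    """A sampled acceleration signal.

    Parameters
    ----------
    samples : ndarray
        Acceleration in m/s^2.
    rate : float
        Sampling frequency in Hz.
    patient_id : str
        Opaque identifier used for per-patient stratification.
    label : str, optional
        Free-text diagnosis; carried as metadata only.
    """

    samples: np.ndarray
    rate: float
    patient_id: str
    label: str | None = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.rate <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.rate}")
        if self.samples.ndim != 1 or self.samples.size == 0:
            raise ValueError("samples must be a non-empty 1-D sequence")
        if not np.all(np.isfinite(self.samples)):
            bad = int(np.flatnonzero(~np.isfinite(self.samples))[0])
            raise ValueError(f"non-finite sample at index {bad}")

    @property
    def duration(self) -> float:
        """Duration in seconds."""
        return self.samples.size / self.rate


@dataclass
class Segment:
    """A fixed-duration window of a recording."""

    samples: np.ndarray
    rate: float
    patient_id: str
    index: int
    ref_label: str = "unlabeled"

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.ref_label not in LABELS:
            raise ValueError(
                f"ref_label {self.ref_label!r} not in {LABELS}"
            )

    @property
    def duration(self) -> float:
        return self.samples.size / self.rate

    @property
    def key(self) -> tuple[str, int]:
        return (self.patient_id, self.index)


@dataclass
class SegmentSet:
    """An ordered collection of equal-duration segments.

    All segments share the sampling rate and duration; ``patient_id``
    partitions the set for stratified cross-validation.  Dominant-frequency
    tables computed from the set are cached on the instance so that
    re-classification under new detection parameters never re-estimates
    spectra.
    """

    segments: list[Segment]
    provenance: dict = field(default_factory=dict)
    _df_cache: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        if self.segments:
            rates = {s.rate for s in self.segments}
            if len(rates) != 1:
                raise ValueError(f"segments have mixed rates: {sorted(rates)}")
            sizes = {s.samples.size for s in self.segments}
            if len(sizes) != 1:
                raise ValueError("segments have mixed durations")

    def __len__(self) -> int:
        return len(self.segments)

    def __iter__(self):
        return iter(self.segments)

    def __getitem__(self, i):
        return self.segments[i]

    @property
    def rate(self) -> float:
        return self.segments[0].rate

    def by_key(self) -> dict[tuple[str, int], Segment]:
        return {s.key: s for s in self.segments}

    def labeled(self, exclude_discard: bool = True) -> list[Segment]:
        """Segments carrying a tremor / no-tremor reference label."""
        keep = {"tremor", "no_tremor"}
        if not exclude_discard:
            keep.add("discard")
        return [s for s in self.segments if s.ref_label in keep]

    def invalidate_cache(self) -> None:
        self._df_cache.clear()


def _sniff(path: Path) -> tuple[str, bool]:
    """Detect the delimiter and whether the first line is a header."""
    with open(path) as fh:
        first = ""
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                first = line
                break
    if not first:
        raise ValueError(f"{path}: file contains no data")
    if "\t" in first:
        sep = "\t"
    elif "," in first:
        sep = ","
    else:
        sep = r"\s+"
    tokens = [t for t in first.replace("\t", ",").replace(" ", ",").split(",") if t]
    has_header = False
    for tok in tokens:
        try:
            float(tok)
        except ValueError:
            has_header = True
            break
    return sep, has_header


def read_recording(
    path: str | Path,
    rate: float,
    patient_id: str,
    label: str | None = None,
) -> Recording:
    """Read a single-axis acceleration recording from CSV/TSV.

    The file holds either one numeric column (acceleration) or a ``time``
    column followed by the acceleration; a header row is optional.  When a
    time column is present it must be uniformly spaced and consistent with
    the declared ``rate``.

    Raises
    ------
    FileNotFoundError
        If ``path`` does not exist.
    ValueError
        For non-numeric content, non-finite rows, or a time column that is
        non-uniform or contradicts ``rate``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"recording file not found: {path}")
    sep, has_header = _sniff(path)
    df = pd.read_csv(
        path, sep=sep, header=0 if has_header else None, comment="#",
        engine="python",
    )
    if has_header:
        df.columns = [str(c).strip().lower() for c in df.columns]
        if "acc" in df.columns:
            acc = df["acc"]
            time = df["time"] if "time" in df.columns else None
        elif df.shape[1] == 1:
            acc, time = df.iloc[:, 0], None
        elif df.shape[1] == 2:
            time, acc = df.iloc[:, 0], df.iloc[:, 1]
        else:
            raise ValueError(
                f"{path}: cannot identify acceleration column among "
                f"{list(df.columns)}; name it 'acc'"
            )
    else:
        if df.shape[1] == 1:
            acc, time = df.iloc[:, 0], None
        elif df.shape[1] == 2:
            time, acc = df.iloc[:, 0], df.iloc[:, 1]
        else:
            raise ValueError(
                f"{path}: headerless file must have 1 (acc) or 2 (time, acc) "
                f"columns, found {df.shape[1]}"
            )

    acc = pd.to_numeric(acc, errors="coerce").to_numpy(dtype=float)
    if not np.all(np.isfinite(acc)):
        row = int(np.flatnonzero(~np.isfinite(acc))[0])
        raise ValueError(
            f"{path}: non-finite or non-numeric acceleration at data row {row}"
        )
    if time is not None:
        t = pd.to_numeric(time, errors="coerce").to_numpy(dtype=float)
        if not np.all(np.isfinite(t)):
            row = int(np.flatnonzero(~np.isfinite(t))[0])
            raise ValueError(f"{path}: non-numeric time value at data row {row}")
        if t.size > 1:
            dt = np.diff(t)
            if dt.min() <= 0 or not np.allclose(dt, dt.mean(), rtol=1e-3,
                                                atol=1e-9 * max(1.0, abs(dt.mean()))):
                raise ValueError(f"{path}: time column is not uniformly spaced")
            implied = 1.0 / dt.mean()
            if abs(implied - rate) > 1e-3 * rate:
                raise ValueError(
                    f"{path}: time stamps imply {implied:.6g} Hz but rate="
                    f"{rate:g} Hz was declared"
                )
    return Recording(acc, rate, patient_id, label)


def band_limit(
    rec: Recording,
    hp_cutoff: float = 0.25,
    hp_order: int = 4,
    lp_cutoff: float = 45.0,
    lp_order: int = 2,
) -> Recording:
    """Apply zero-phase Butterworth high- and low-pass filters.

    The high-pass (default 4th order, 0.25 Hz) removes the gravity
    component and slow drift; the low-pass (default 2nd order, 45 Hz)
    suppresses mains artifact.  Filters are applied forward-backward
    (``sosfiltfilt``) so segment boundaries carry no phase lag; note that
    this squares each filter's magnitude response.
    """
    nyq = rec.rate / 2.0
    for name, c in (("high-pass", hp_cutoff), ("low-pass", lp_cutoff)):
        if not 0 < c < nyq:
            raise ValueError(
                f"{name} cutoff {c:g} Hz must lie in (0, Nyquist={nyq:g}) Hz"
            )
    sos_hp = signal.butter(hp_order, hp_cutoff, "highpass", fs=rec.rate,
                           output="sos")
    sos_lp = signal.butter(lp_order, lp_cutoff, "lowpass", fs=rec.rate,
                           output="sos")
    # Edge padding of ~3 filter time constants; the 0.25 Hz high-pass rings
    # for seconds, far beyond sosfiltfilt's default pad.
    n = rec.samples.size
    pad_hp = min(n - 1, int(3 * rec.rate / hp_cutoff))
    pad_lp = min(n - 1, max(24, int(3 * rec.rate / lp_cutoff)))
    x = signal.sosfiltfilt(sos_hp, rec.samples, padlen=pad_hp)
    x = signal.sosfiltfilt(sos_lp, x, padlen=pad_lp)
    return Recording(x, rec.rate, rec.patient_id, rec.label)


def resample(
    rec: Recording,
    target_rate: float = 100.0,
    lp_cutoff: float = 45.0,
) -> Recording:
    """Resample a band-limited recording to the working rate.

    ``target_rate`` must be at least twice the low-pass cutoff applied by
    :func:`band_limit` so no retained spectral content aliases.  Uses
    polyphase resampling; an identity rate returns a copy.
    """
    if target_rate < 2 * lp_cutoff:
        raise ValueError(
            f"target_rate {target_rate:g} Hz < 2 x low-pass cutoff "
            f"({lp_cutoff:g} Hz); retained band would alias"
        )
    if target_rate == rec.rate:
        return Recording(rec.samples.copy(), rec.rate, rec.patient_id, rec.label)
    frac = Fraction(target_rate / rec.rate).limit_denominator(10000)
    x = signal.resample_poly(rec.samples, frac.numerator, frac.denominator)
    return Recording(x, target_rate, rec.patient_id, rec.label)


def segment(rec: Recording, seg_len: float = 4.0) -> SegmentSet:
    """Cut a recording into non-overlapping ``seg_len``-second segments.

    A trailing remainder shorter than one segment is discarded; every
    segment starts with ``ref_label='unlabeled'``.
    """
    n_per = int(round(seg_len * rec.rate))
    if n_per <= 0:
        raise ValueError("seg_len too short for the sampling rate")
    if rec.samples.size < n_per:
        raise ValueError(
            f"recording of {rec.duration:.3g} s shorter than one segment "
            f"({seg_len:g} s)"
        )
    n_seg = rec.samples.size // n_per
    segs = [
        Segment(rec.samples[i * n_per:(i + 1) * n_per], rec.rate,
                rec.patient_id, i)
        for i in range(n_seg)
    ]
    return SegmentSet(segs, provenance={
        "rate": rec.rate, "seg_len": seg_len, "n_segments": n_seg,
    })


def merge(sets: list[SegmentSet]) -> SegmentSet:
    """Concatenate per-patient segment sets into one cohort-level set."""
    segs = [s for ss in sets for s in ss]
    prov = {"merged_from": [ss.provenance for ss in sets]}
    return SegmentSet(segs, provenance=prov)


def attach_labels(segset: SegmentSet, label_table: str | Path) -> SegmentSet:
    """Attach reference labels from a CSV table to a segment set.

    The table has columns ``patient_id,segment_index,label`` with labels
    from {tremor, no_tremor, discard}.  Segments labeled ``discard`` are
    retained but excluded from evaluation downstream.  Labels are attached
    in place; the (same) set is returned.
    """
    label_table = Path(label_table)
    if not label_table.exists():
        raise FileNotFoundError(f"label table not found: {label_table}")
    try:
        df = pd.read_csv(label_table)
    except pd.errors.EmptyDataError:
        return segset
    if df.empty:
        return segset
    required = {"patient_id", "segment_index", "label"}
    if not required.issubset(df.columns):
        raise ValueError(
            f"label table must have columns {sorted(required)}, "
            f"found {list(df.columns)}"
        )
    bad = set(df["label"]) - set(TABLE_LABELS)
    if bad:
        raise ValueError(
            f"unknown label token(s) {sorted(bad)}; allowed: {TABLE_LABELS}"
        )
    keys = list(zip(df["patient_id"].astype(str), df["segment_index"].astype(int)))
    seen: set[tuple[str, int]] = set()
    for k in keys:
        if k in seen:
            raise ValueError(f"duplicate label-table key {k}")
        seen.add(k)
    by_key = segset.by_key()
    for (pid, idx), lab in zip(keys, df["label"]):
        if (pid, idx) not in by_key:
            raise ValueError(
                f"label-table key ({pid!r}, {idx}) matches no segment"
            )
        by_key[(pid, idx)].ref_label = lab
    return segset
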