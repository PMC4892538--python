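"""Dominant-frequency extraction from PSDs and AR-model ensembles.

A segment's *dominant frequency* (DF) is the frequency carrying its
defining spectral peak, together with the density value at that frequency
(the DF *amplitude*).  Non-parametric estimates take the global argmax of
the PSD; the AR ensemble (orders 1..20) supports five selection criteria:

``akaike``
    Highest point of the spectrum of the AIC-selected model.
``high_amp``
    Globally highest point across all 20 spectra.
``high_freq``
    The interior peak with the highest frequency across all spectra,
    regardless of its height.
``mode_high_amp`` / ``mode_high_freq``
    The mode over models of the per-model DF (argmax, respectively
    highest-frequency peak), after quantizing to 0.05 Hz bins; the mode
    discards the few model orders that misrepresent the segment.

All criteria operate on the 0-20 Hz band and break ties deterministically
toward lower frequency / lower model order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as _scipy_signal

from .preprocess import Segment, SegmentSet
from .spectral import (
    DEFAULT_FGRID,
    MAX_ORDER,
    ARModel,
    PSDEstimate,
    aic,
    ar_spectrum_matrix,
    fit_all_orders,
    modified_periodogram,
    welch,
)

__all__ = [
    "MODE_BIN_HZ",
    "NONPARAM_METHODS",
    "ENSEMBLE_METHODS",
    "ALL_METHODS",
    "DFResult",
    "PeakList",
    "find_peaks",
    "df_nonparam",
    "df_akaike",
    "df_high_amp",
    "df_high_freq",
    "df_mode",
    "ensemble_dfs",
    "df_table",
]

#: Quantization width for the mode criteria.  AR dominant frequencies are
#: continuous, so the mode is undefined without binning; 0.05 Hz matches the
#: classifier's band-limit search step.
MODE_BIN_HZ = 0.05

NONPARAM_METHODS = ("periodogram", "welch2", "welch3", "welch8")
ENSEMBLE_METHODS = ("akaike", "high_amp", "high_freq",
                    "mode_high_amp", "mode_high_freq")
ALL_METHODS = NONPARAM_METHODS + ENSEMBLE_METHODS


@dataclass
class DFResult:
    """A dominant frequency with its density amplitude and provenance."""

    freq: float
    amplitude: float
    criterion: str
    source_order: int | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.freq <= 20:
            raise ValueError(f"dominant frequency {self.freq:g} outside [0, 20] Hz")
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")


@dataclass
class PeakList:
    """Interior local maxima of one PSD, ordered by frequency."""

    peaks: list[tuple[float, float]]

    def __len__(self) -> int:
        return len(self.peaks)


def _peak_indices(power: np.ndarray) -> np.ndarray:
    """Indices of strict interior local maxima (plateau centers)."""
    idx, _ = _scipy_signal.find_peaks(power)
    return idx


def find_peaks(psd: PSDEstimate) -> PeakList:
    """Interior peaks of a PSD.

    Grid endpoints are never peaks; flat plateaus report their center
    point (rounded down).
    """
    if psd.power.size < 3:
        raise ValueError("PSD must have at least 3 points")
    idx = _peak_indices(psd.power)
    return PeakList([(float(psd.freqs[i]), float(psd.power[i])) for i in idx])


def df_nonparam(psd: PSDEstimate, fmax: float = 20.0) -> DFResult:
    """Global argmax of a non-parametric PSD on [0, ``fmax``].

    Ties break toward the lower frequency (first argmax).
    """
    keep = psd.freqs <= fmax + 1e-9
    if not np.any(keep):
        raise ValueError("PSD restricted to [0, fmax] is empty")
    f, p = psd.freqs[keep], psd.power[keep]
    i = int(np.argmax(p))
    return DFResult(float(f[i]), float(p[i]), "nonparam")


class EnsembleSpectra:
    """Shared evaluation of a 20-model AR ensemble on a frequency grid.

    Computes the density matrix, per-model argmax and per-model interior
    peaks once, so that all five parametric criteria reuse the same work.
    """

    def __init__(self, models: list[ARModel],
                 fgrid: np.ndarray | None = None) -> None:
        if not models:
            raise ValueError("empty model ensemble")
        self.models = models
        self.fgrid = DEFAULT_FGRID if fgrid is None else np.asarray(fgrid, float)
        self.power = ar_spectrum_matrix(models, self.fgrid)
        self.orders = np.array([m.order for m in models])
        self.argmax = np.argmax(self.power, axis=1)
        self.peaks = [_peak_indices(row) for row in self.power]
        self.aics = np.array([aic(m) for m in models])

    def _result(self, model_i: int, freq_i: int, criterion: str) -> DFResult:
        return DFResult(
            float(self.fgrid[freq_i]),
            float(self.power[model_i, freq_i]),
            criterion,
            source_order=int(self.orders[model_i]),
        )


def _as_ensemble(models, fgrid) -> EnsembleSpectra:
    if isinstance(models, EnsembleSpectra):
        return models
    return EnsembleSpectra(models, fgrid)


def df_akaike(models, fgrid: np.ndarray | None = None) -> DFResult:
    """DF of the single AIC-selected model (ties to the lower order)."""
    ens = _as_ensemble(models, fgrid)
    best = int(np.argmin(ens.aics))
    return ens._result(best, int(ens.argmax[best]), "akaike")


def df_high_amp(models, fgrid: np.ndarray | None = None) -> DFResult:
    """Globally highest density point over all spectra jointly."""
    ens = _as_ensemble(models, fgrid)
    mi, fi = np.unravel_index(int(np.argmax(ens.power)), ens.power.shape)
    return ens._result(int(mi), int(fi), "high_amp")


def df_high_freq(models, fgrid: np.ndarray | None = None) -> DFResult:
    """Highest-frequency interior peak over the union of all spectra.

    The peak's amplitude is its density in the spectrum that produced it;
    when two spectra peak at exactly the same frequency the higher
    amplitude wins.  A fully peakless ensemble (monotone spectra) falls
    back to the global-argmax behavior.
    """
    ens = _as_ensemble(models, fgrid)
    best: tuple[int, float, int] | None = None  # (freq_i, amp, model_i)
    for mi, idx in enumerate(ens.peaks):
        if idx.size == 0:
            continue
        fi = int(idx[-1])
        amp = float(ens.power[mi, fi])
        if best is None or fi > best[0] or (fi == best[0] and amp > best[1]):
            best = (fi, amp, mi)
    if best is None:
        r = df_high_amp(ens)
        return DFResult(r.freq, r.amplitude, "high_freq", r.source_order)
    fi, _, mi = best
    return ens._result(mi, fi, "high_freq")


def _per_model_dfs(ens: EnsembleSpectra, inner: str) -> np.ndarray:
    """One DF index per model under the inner criterion."""
    if inner == "high_amp":
        return ens.argmax.copy()
    if inner == "high_freq":
        out = np.empty(len(ens.models), dtype=int)
        for mi, idx in enumerate(ens.peaks):
            out[mi] = int(idx[-1]) if idx.size else int(ens.argmax[mi])
        return out
    raise ValueError(f"inner criterion must be 'high_amp' or 'high_freq', got {inner!r}")


def df_mode(models, fgrid: np.ndarray | None = None,
            inner_criterion: str = "high_amp") -> DFResult:
    """Mode over models of the per-model DF, on a 0.05 Hz binning grid.

    The returned frequency is the winning bin's value; its amplitude is the
    maximal density at the DF across the models voting for that bin.  Mode
    ties break toward the lower frequency.
    """
    ens = _as_ensemble(models, fgrid)
    df_idx = _per_model_dfs(ens, inner_criterion)
    freqs = ens.fgrid[df_idx]
    bins = np.round(freqs / MODE_BIN_HZ).astype(int)
    values, counts = np.unique(bins, return_counts=True)
    mode_bin = int(values[np.argmax(counts)])  # first max = lowest frequency
    voters = np.flatnonzero(bins == mode_bin)
    amps = ens.power[voters, df_idx[voters]]
    w = int(voters[np.argmax(amps)])
    freq = min(mode_bin * MODE_BIN_HZ, 20.0)
    return DFResult(freq, float(amps.max()), f"mode_{inner_criterion}",
                    source_order=int(ens.orders[w]))


def ensemble_dfs(models, fgrid: np.ndarray | None = None) -> dict[str, DFResult]:
    """All five parametric DF criteria from one shared ensemble evaluation."""
    ens = _as_ensemble(models, fgrid)
    return {
        "akaike": df_akaike(ens),
        "high_amp": df_high_amp(ens),
        "high_freq": df_high_freq(ens),
        "mode_high_amp": df_mode(ens, inner_criterion="high_amp"),
        "mode_high_freq": df_mode(ens, inner_criterion="high_freq"),
    }


def _df_for_segment(seg: Segment, method: str, fmax: float,
                    fgrid: np.ndarray | None,
                    max_order: int) -> DFResult:
    if method == "periodogram":
        return df_nonparam(modified_periodogram(seg, fmax=fmax), fmax)
    if method.startswith("welch"):
        return df_nonparam(welch(seg, int(method[5:]), fmax=fmax), fmax)
    models = fit_all_orders(seg, max_order)
    return ensemble_dfs(models, fgrid)[method]


def df_table(
    segset: SegmentSet,
    methods: str | list[str] = "all",
    fmax: float = 20.0,
    fgrid: np.ndarray | None = None,
    max_order: int = MAX_ORDER,
) -> pd.DataFrame:
    """Dominant frequencies of every segment for the requested methods.

    Returns a frame with columns ``patient_id, segment_index, ref_label,
    method, freq_hz, amplitude, source_order``.  Results are cached on the
    segment set keyed by method, so spectra are estimated once no matter how
    often the set is re-classified; the AR ensemble is fitted once per
    segment and shared across all five parametric criteria.
    """
    if methods == "all":
        methods = list(ALL_METHODS)
    elif isinstance(methods, str):
        methods = [methods]
    unknown = set(methods) - set(ALL_METHODS)
    if unknown:
        raise ValueError(f"unknown method(s) {sorted(unknown)}; "
                         f"choose from {ALL_METHODS}")

    cache = segset._df_cache
    missing = [m for m in methods if m not in cache]
    missing_np = [m for m in missing if m in NONPARAM_METHODS]
    missing_ens = [m for m in missing if m in ENSEMBLE_METHODS]
    for m in missing_np:
        cache[m] = [_df_for_segment(s, m, fmax, fgrid, max_order)
                    for s in segset]
    if missing_ens:
        rows: dict[str, list[DFResult]] = {m: [] for m in ENSEMBLE_METHODS}
        for s in segset:
            dfs = ensemble_dfs(fit_all_orders(s, max_order), fgrid)
            for m in ENSEMBLE_METHODS:
                rows[m].append(dfs[m])
        for m in ENSEMBLE_METHODS:
            cache[m] = rows[m]

    records = []
    for m in methods:
        for s, r in zip(segset, cache[m]):
            records.append((s.patient_id, s.index, s.ref_label, m,
                            r.freq, r.amplitude, r.source_order))
    return pd.DataFrame(records, columns=[
        "patient_id", "segment_index", "ref_label", "method",
        "freq_hz", "amplitude", "source_order",
    ])
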