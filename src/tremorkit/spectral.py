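"""One-sided PSD estimation: modified periodogram, Welch, and Burg AR models.

Two families of estimators are provided for 4-s accelerometer segments:

* **Non-parametric** (FFT-based): the modified (Hamming-windowed)
  periodogram and Welch's method with 2, 3 or 8 windows at 50% overlap.
  Their frequency resolution is fixed by the segment duration.
* **Parametric**: autoregressive (AR) models fitted with Burg's method.
  An AR(k) model assumes ``x[n] = sum_i a_i x[n-i] + e[n]`` with white
  innovation ``e``; its power spectral density is the innovation variance
  shaped by the all-pole synthesis filter ``H(z) = 1 / (1 - sum a_i z^-i)``.
  Burg estimates the ``a_i`` by minimizing the summed forward and backward
  prediction-error energy through a lattice recursion over reflection
  coefficients, which guarantees a stable synthesis filter.  Model orders
  1..20 are fitted and kept as an ensemble; the Akaike information
  criterion scores each order.

All densities are one-sided, in (m/s^2)^2 per Hz, so that the integral of
the density over the full band equals the signal variance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .preprocess import Segment

__all__ = [
    "PSDEstimate",
    "ARModel",
    "DEFAULT_FGRID",
    "MAX_ORDER",
    "REFLECTION_LIMIT",
    "modified_periodogram",
    "welch",
    "welch_window_length",
    "burg_fit",
    "fit_all_orders",
    "ar_psd",
    "ar_spectrum_matrix",
    "aic",
]

#: Default evaluation grid for AR frequency responses: 0-20 Hz, 0.01 Hz step.
#: Voluntary movement and tremor both live well below 20 Hz, and 0.01 Hz is
#: far below any clinically meaningful frequency difference.
DEFAULT_FGRID = np.round(np.arange(0.0, 20.0 + 1e-9, 0.01), 10)

#: Highest AR order fitted for the ensemble criteria.
MAX_ORDER = 20

#: Magnitude clip for Burg reflection coefficients.  For numerically
#: noiseless periodic segments the optimal |k| reaches 1 within float
#: rounding, which collapses the spectral line to a width far below the
#: evaluation grid step; the clip imposes a minimum pole bandwidth
#: (~0.03 Hz at 100 Hz) so line spectra stay representable on the grid,
#: and makes the strict-stability invariant unconditional.
REFLECTION_LIMIT = 1.0 - 1e-3


@dataclass
class PSDEstimate:
    """A one-sided power spectral density on an explicit frequency grid."""

    freqs: np.ndarray
    power: np.ndarray
    method: str
    order: int | None = None

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.power = np.asarray(self.power, dtype=float)
        if self.freqs.shape != self.power.shape:
            raise ValueError("freqs and power must have equal length")
        if self.freqs.size and (np.any(np.diff(self.freqs) <= 0)
                                or self.freqs[0] < 0):
            raise ValueError("freqs must be strictly increasing and >= 0")
        if not np.all(np.isfinite(self.power)) or np.any(self.power < 0):
            raise ValueError("power must be finite and non-negative")

    def to_csv(self, path) -> None:
        """Write ``freq_hz,power`` rows with the method in a comment header."""
        with open(path, "w") as fh:
            fh.write(f"# method={self.method}"
                     + (f" order={self.order}" if self.order else "")
                     + "\n")
            fh.write("freq_hz,power\n")
            for f, p in zip(self.freqs, self.power):
                fh.write(f"{f:.6g},{p:.10g}\n")


@dataclass
class ARModel:
    """A Burg autoregressive fit of one segment.

    ``coeffs`` are predictor coefficients ``a_1..a_k`` in the convention
    ``x[n] = sum_i a_i x[n-i] + e[n]`` (note the plus sign: the monic
    polynomial of the synthesis filter is ``1 - sum a_i z^-i``).
    ``reflection`` holds the per-stage lattice coefficients; all magnitudes
    are strictly below 1, which places every pole of the synthesis filter
    strictly inside the unit circle.  ``resid_var`` is the prediction-error
    (innovation) variance.
    """

    order: int
    coeffs: np.ndarray
    reflection: np.ndarray
    resid_var: float
    n: int
    rate: float

    def __post_init__(self) -> None:
        self.coeffs = np.asarray(self.coeffs, dtype=float)
        self.reflection = np.asarray(self.reflection, dtype=float)
        if self.order < 1 or self.coeffs.size != self.order:
            raise ValueError("order must be >= 1 and match len(coeffs)")

    @property
    def poly(self) -> np.ndarray:
        """Monic denominator polynomial ``[1, -a_1, ..., -a_k]``."""
        return np.concatenate(([1.0], -self.coeffs))

    def poles(self) -> np.ndarray:
        """Roots of the synthesis-filter denominator."""
        return np.roots(self.poly)


def _validate_psd_inputs(seg: Segment, fmax: float) -> None:
    if seg.samples.size == 0:
        raise ValueError("segment is empty")
    if fmax > seg.rate / 2.0 + 1e-12:
        raise ValueError(
            f"fmax {fmax:g} Hz exceeds Nyquist ({seg.rate / 2:g} Hz)"
        )


def modified_periodogram(seg: Segment, fmax: float = 20.0) -> PSDEstimate:
    """Hamming-windowed periodogram, restricted to [0, ``fmax``] Hz.

    Scaled as a density with window power correction, so the full-band
    integral equals the (windowed) segment variance.
    """
    _validate_psd_inputs(seg, fmax)
    f, p = signal.periodogram(
        seg.samples, fs=seg.rate, window="hamming", detrend=False,
        scaling="density",
    )
    keep = f <= fmax + 1e-9
    return PSDEstimate(f[keep], p[keep], "periodogram")


def welch_window_length(n_samples: int, n_windows: int,
                        overlap: float = 0.5) -> int:
    """Maximal window length fitting ``n_windows`` at the given overlap.

    Solves ``L * (1 + (k - 1) * (1 - overlap)) = n`` and floors: with 50%
    overlap, 400 samples give L=200 for 3 windows and L=88 for 8.
    """
    return int(n_samples / (1 + (n_windows - 1) * (1 - overlap)))


def welch(seg: Segment, n_windows: int, overlap: float = 0.5,
          fmax: float = 20.0) -> PSDEstimate:
    """Welch PSD: averaged Hamming-windowed sub-periodograms.

    ``n_windows`` must be 2, 3 or 8 (the configurations under study);
    averaging trades frequency resolution for variance reduction.
    """
    if n_windows not in (2, 3, 8):
        raise ValueError(f"n_windows must be one of (2, 3, 8), got {n_windows}")
    _validate_psd_inputs(seg, fmax)
    L = welch_window_length(seg.samples.size, n_windows, overlap)
    if L < 8:
        raise ValueError(
            f"segment of {seg.samples.size} samples too short for "
            f"{n_windows} windows (implied length {L} < 8)"
        )
    f, p = signal.welch(
        seg.samples, fs=seg.rate, window="hamming", nperseg=L,
        noverlap=int(L * overlap), detrend=False, scaling="density",
    )
    keep = f <= fmax + 1e-9
    return PSDEstimate(f[keep], p[keep], f"welch{n_windows}")


def _burg_recursion(x: np.ndarray, max_order: int):
    """Run the Burg lattice recursion up to ``max_order``.

    Returns per-stage reflection coefficients, residual variances
    (stage 0..max_order) and the predictor-coefficient vector per order.
    At each stage the reflection coefficient is the closed-form minimizer
    of the summed forward+backward squared prediction error,
    ``k = -2 sum(f*b) / sum(f^2 + b^2)`` over the valid sample range.
    """
    n = x.size
    f = x.astype(float).copy()
    b = x.astype(float).copy()
    e0 = float(np.mean(x * x))
    if e0 == 0.0:
        raise ValueError("all-zero segment: prediction-error variance degenerate")
    tiny = n * e0 * 1e-30

    reflections = np.zeros(max_order)
    resid = np.empty(max_order + 1)
    resid[0] = e0
    # a_poly[m] holds [1, alpha_1..alpha_m] with synthesis denominator
    # A(z) = 1 + sum alpha_i z^-i; predictor coeffs are -alpha.
    a = np.array([1.0])
    coeffs_per_order: list[np.ndarray] = []
    frozen = False
    for m in range(1, max_order + 1):
        fa = f[m:]
        bb = b[m - 1:-1]
        den = float(np.dot(fa, fa) + np.dot(bb, bb))
        if frozen or den <= tiny:
            k = 0.0  # residual exhausted: freeze remaining stages
        else:
            k = -2.0 * float(np.dot(fa, bb)) / den
            if abs(k) > REFLECTION_LIMIT:
                # The stage saturated (a spectral line): what remains is
                # clamp misfit, not signal, so later stages must not model it.
                k = float(np.copysign(REFLECTION_LIMIT, k))
                frozen = True
        reflections[m - 1] = k
        a = np.concatenate((a, [0.0]))
        a = a + k * a[::-1]
        f_new = fa + k * bb
        b_new = bb + k * fa
        f[m:] = f_new
        b[m:] = b_new  # backward error shifts by one even when k == 0
        resid[m] = resid[m - 1] * (1.0 - k * k)
        coeffs_per_order.append(-a[1:].copy())
    return reflections, resid, coeffs_per_order


def burg_fit(seg: Segment, order: int) -> ARModel:
    """Fit an AR model of the given order with Burg's method.

    Raises for a degenerate (all-zero) segment or ``order >= n_samples``.
    """
    n = seg.samples.size
    if not 1 <= order < n:
        raise ValueError(f"order must satisfy 1 <= order < n_samples ({n})")
    refl, resid, coeffs = _burg_recursion(seg.samples, order)
    return ARModel(order, coeffs[-1], refl, float(resid[order]), n, seg.rate)


def fit_all_orders(seg: Segment, max_order: int = MAX_ORDER) -> list[ARModel]:
    """Fit AR models of orders 1..``max_order`` in one lattice pass.

    Residual variance is non-increasing with order (nested minimization).
    """
    n = seg.samples.size
    if not 1 <= max_order < n:
        raise ValueError(f"max_order must satisfy 1 <= max_order < {n}")
    refl, resid, coeffs = _burg_recursion(seg.samples, max_order)
    return [
        ARModel(m, coeffs[m - 1], refl[:m], float(resid[m]), n, seg.rate)
        for m in range(1, max_order + 1)
    ]


def ar_psd(model: ARModel, fgrid: np.ndarray | None = None) -> PSDEstimate:
    """One-sided AR spectral density on ``fgrid``.

    ``S(f) = 2 sigma^2 / (rate * |1 - sum a_i exp(-i 2 pi f i / rate)|^2)``.
    """
    if fgrid is None:
        fgrid = DEFAULT_FGRID
    fgrid = np.asarray(fgrid, dtype=float)
    if fgrid.size and (fgrid[0] < 0 or fgrid[-1] > model.rate / 2 + 1e-9):
        raise ValueError("fgrid must lie within [0, rate/2]")
    _, h = signal.freqz([1.0], model.poly, worN=fgrid, fs=model.rate)
    power = 2.0 * model.resid_var * np.abs(h) ** 2 / model.rate
    return PSDEstimate(fgrid, power, "ar", order=model.order)


def ar_spectrum_matrix(models: list[ARModel],
                       fgrid: np.ndarray | None = None) -> np.ndarray:
    """Stacked AR densities, shape ``(n_models, len(fgrid))``.

    Vectorized over models: evaluates every synthesis-filter denominator on
    the grid in one complex matrix product.
    """
    if fgrid is None:
        fgrid = DEFAULT_FGRID
    fgrid = np.asarray(fgrid, dtype=float)
    rate = models[0].rate
    kmax = max(m.order for m in models)
    A = np.zeros((len(models), kmax + 1))
    for i, m in enumerate(models):
        A[i, 0] = 1.0
        A[i, 1:m.order + 1] = -m.coeffs
    # E[j, i] = exp(-i 2 pi f_j i / rate)
    E = np.exp(-2j * np.pi * np.outer(fgrid / rate, np.arange(kmax + 1)))
    den = np.abs(E @ A.T) ** 2  # (n_freqs, n_models)
    sig = np.array([m.resid_var for m in models])
    return (2.0 * sig[None, :] / (rate * den)).T


def aic(model: ARModel) -> float:
    """Akaike information criterion ``N ln(sigma^2) + 2k``.

    Rewards fit through the log residual variance while penalizing model
    complexity; ties between orders are broken toward the lower order by
    the callers.
    """
    if model.resid_var <= 0:
        raise ValueError("AIC undefined for non-positive residual variance")
    return model.n * float(np.log(model.resid_var)) + 2.0 * model.order
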