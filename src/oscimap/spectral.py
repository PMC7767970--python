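"""Per-pixel band-limited spectral power: Welch PSD, band-power maps,
max-normalisation, quantile/z-score masking and radial PSD profiles.

Welch defaults (1 s Hann segments, 50 % overlap, per-segment linear
detrend) give 1 Hz resolution at every supported frame rate, enough to
resolve the 3-12 Hz band. Band integration is half-open ``[f_lo, f_hi)``
so that adjacent sub-bands add exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import signal, stats

from .errors import ConfigurationError, NumericalError
from .preprocess import Movie

__all__ = [
    "PSDImage",
    "welch_psd",
    "band_power_map",
    "normalize_to_max",
    "threshold_quantile",
    "zscore_filter",
    "psd_vs_distance",
    "RadialPSDResult",
]

DEFAULT_BAND = (3.0, 12.0)
DEFAULT_SEGMENT_S = 1.0
DEFAULT_OVERLAP = 0.5


@dataclass(frozen=True)
class PSDImage:
    """Per-pixel integrated band power with masking/normalisation state."""

    band_power: np.ndarray
    band: tuple[float, float]
    frame_rate: float
    pixel_pitch_um: float
    normalization: str = "raw"  # raw | max-normalized
    threshold_quantile_applied: float | None = None
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        bp = np.asarray(self.band_power, dtype=float)
        if bp.ndim != 2:
            raise ConfigurationError("band_power must be 2-D")
        if np.any(bp[np.isfinite(bp)] < 0):
            raise NumericalError("band power must be non-negative")
        object.__setattr__(self, "band_power", bp)
        if self.mask is None:
            object.__setattr__(self, "mask", np.isfinite(bp))
        elif self.mask.shape != bp.shape:
            raise ConfigurationError("mask shape must match band_power")

    @property
    def masked_values(self) -> np.ndarray:
        return self.band_power[self.mask]


def _welch_params(sample_rate: float, n_samples: int, segment_s: float,
                  overlap_fraction: float) -> tuple[int, int]:
    nperseg = int(round(segment_s * sample_rate))
    if nperseg < 4:
        raise ConfigurationError(
            f"segment of {segment_s} s is only {nperseg} samples at "
            f"{sample_rate} Hz")
    if n_samples < nperseg:
        raise ConfigurationError(
            f"trace of {n_samples} samples shorter than one Welch segment "
            f"({nperseg} samples = {segment_s} s at {sample_rate} Hz); record "
            f"at least {nperseg / sample_rate:.2f} s"
        )
    noverlap = int(round(overlap_fraction * nperseg))
    return nperseg, noverlap


def welch_psd(trace: np.ndarray, sample_rate: float,
              segment_s: float = DEFAULT_SEGMENT_S,
              overlap_fraction: float = DEFAULT_OVERLAP,
              axis: int = -1) -> tuple[np.ndarray, np.ndarray]:
    """One-sided Welch PSD (Hann window, linear per-segment detrend).

    Returns ``(frequencies, psd)`` with density scaling, so the PSD
    integrated over all frequencies approximates the trace variance
    (Parseval, within windowing tolerance).
    """
    trace = np.asarray(trace, dtype=float)
    nperseg, noverlap = _welch_params(
        sample_rate, trace.shape[axis], segment_s, overlap_fraction)
    return signal.welch(trace, fs=sample_rate, window="hann", nperseg=nperseg,
                        noverlap=noverlap, detrend="linear",
                        scaling="density", axis=axis)


def band_power(freqs: np.ndarray, psd: np.ndarray,
               band: tuple[float, float], axis: int = -1) -> np.ndarray:
    """Integrate a PSD over the half-open band ``[f_lo, f_hi)``."""
    f_lo, f_hi = band
    sel = (freqs >= f_lo) & (freqs < f_hi)
    df = freqs[1] - freqs[0]
    return np.take(psd, np.flatnonzero(sel), axis=axis).sum(axis=axis) * df


def band_power_map(movie: Movie, band: tuple[float, float] = DEFAULT_BAND,
                   segment_s: float = DEFAULT_SEGMENT_S,
                   overlap_fraction: float = DEFAULT_OVERLAP) -> PSDImage:
    """Integrated in-band Welch power for every pixel of a movie.

    The movie should carry a dimensionless signal (dF/F); NaN pixels (e.g.
    masked zero-baseline pixels) yield NaN band power and are excluded from
    the default mask.
    """
    nyquist = movie.frame_rate / 2
    if band[1] > nyquist or band[0] <= 0 or band[0] >= band[1]:
        raise ConfigurationError(
            f"band {band} Hz invalid for Nyquist {nyquist} Hz; need "
            f"0 < f_lo < f_hi <= {nyquist}"
        )
    freqs, psd = welch_psd(movie.data, movie.frame_rate, segment_s,
                           overlap_fraction, axis=0)
    bp = band_power(freqs, psd, band, axis=0)
    return PSDImage(band_power=bp, band=tuple(band),
                    frame_rate=movie.frame_rate,
                    pixel_pitch_um=movie.pixel_pitch_um)


def normalize_to_max(image: PSDImage) -> PSDImage:
    """Scale so the maximal unmasked pixel equals 1. Idempotent."""
    values = image.masked_values
    if values.size == 0 or not np.any(values > 0):
        raise NumericalError(
            "cannot normalise an all-zero/empty PSD image: no maximal pixel")
    return replace(image, band_power=image.band_power / values.max(),
                   normalization="max-normalized")


def threshold_quantile(image: PSDImage, q: float = 0.90) -> PSDImage:
    """Mask pixels strictly above the q-quantile of all in-frame values.

    Uses the linear-interpolation sample quantile; with distinct values
    the retained fraction is ~(1 - q). The new mask is intersected with
    any existing mask. A degenerate all-equal image yields an empty mask
    with a warning.
    """
    if not 0 < q < 1:
        raise ConfigurationError(f"quantile must be in (0, 1), got {q}")
    finite = np.isfinite(image.band_power)
    values = image.band_power[finite]
    thresh = np.quantile(values, q)
    above = np.zeros_like(finite)
    above[finite] = image.band_power[finite] > thresh
    if not above.any():
        warnings.warn(
            "quantile threshold retained no pixels (degenerate image?)",
            RuntimeWarning, stacklevel=2)
    return replace(image, mask=image.mask & above,
                   threshold_quantile_applied=q)


def zscore_filter(image: PSDImage, z_min: float = 2.0) -> PSDImage:
    """Mask pixels whose band-power z-score (over all in-frame pixels) is
    >= ``z_min``; intersects with any existing mask."""
    finite = np.isfinite(image.band_power)
    values = image.band_power[finite]
    sd = values.std()
    if sd == 0:
        warnings.warn("zero variance across pixels; z-score mask is empty",
                      RuntimeWarning, stacklevel=2)
        return replace(image, mask=np.zeros_like(image.mask))
    z = np.full(image.band_power.shape, -np.inf)
    z[finite] = (values - values.mean()) / sd
    return replace(image, mask=image.mask & (z >= z_min))


@dataclass(frozen=True)
class RadialPSDResult:
    """Radially binned normalized band power around a reference point."""

    table: pd.DataFrame  # columns: distance_um, mean_psd, n_pixels
    half_max_distance_um: float  # NaN if censored
    censored: bool
    correlation_r: float
    correlation_p: float


def psd_vs_distance(image: PSDImage, center: tuple[float, float],
                    bin_width_um: float | None = None) -> RadialPSDResult:
    """Mean max-normalised band power vs distance from ``center`` (pixel
    coordinates), the first half-max crossing distance, and the Pearson
    correlation between per-pixel distance and normalised power.

    A profile that never falls below half its peak within the field is
    reported censored (``half_max_distance_um = NaN``).
    """
    if not image.mask.any():
        raise ConfigurationError("all pixels masked out; nothing to profile")
    if bin_width_um is None:
        bin_width_um = image.pixel_pitch_um
    norm = image.band_power / np.nanmax(image.band_power[image.mask])

    rr, cc = np.nonzero(image.mask)
    dist = np.hypot(rr - center[0], cc - center[1]) * image.pixel_pitch_um
    vals = norm[rr, cc]

    n_bins = int(np.ceil((dist.max() + 1e-9) / bin_width_um)) or 1
    idx = np.minimum((dist / bin_width_um).astype(int), n_bins - 1)
    sums = np.bincount(idx, weights=vals, minlength=n_bins)
    counts = np.bincount(idx, minlength=n_bins)
    with np.errstate(invalid="ignore"):
        means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    centers = (np.arange(n_bins) + 0.5) * bin_width_um
    table = pd.DataFrame({"distance_um": centers, "mean_psd": means,
                          "n_pixels": counts})

    valid = counts > 0
    prof = means[valid]
    prof_r = centers[valid]
    peak_i = int(np.nanargmax(prof))
    half = prof[peak_i] / 2.0
    half_r, censored = np.nan, True
    for j in range(peak_i + 1, prof.size):
        if prof[j] < half:
            # linear interpolation between bins j-1 and j
            r0, r1 = prof_r[j - 1], prof_r[j]
            v0, v1 = prof[j - 1], prof[j]
            half_r = r0 + (v0 - half) / (v0 - v1) * (r1 - r0)
            censored = False
            break

    if vals.size >= 2 and np.ptp(vals) > 0 and np.ptp(dist) > 0:
        r, p = stats.pearsonr(dist, vals)
    else:
        r, p = np.nan, np.nan
    return RadialPSDResult(table=table, half_max_distance_um=half_r,
                           censored=censored, correlation_r=float(r),
                           correlation_p=float(p))
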