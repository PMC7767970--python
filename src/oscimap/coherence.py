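"""Temporal-structure analyses: sliding auto/cross-correlograms, shuffle
nulls, windowed pixel covariance and coherence images, cross-power spectral
density, pre/post-stimulation spectral ratios and trace correlation
matrices.

Lag convention: a positive lag ``d`` in a cross-correlogram of ``(a, b)``
means ``b`` lags ``a`` by ``d`` seconds, i.e. the peak sits at ``+T/4``
when ``b`` is ``a`` delayed by a quarter period.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal

from .errors import ConfigurationError
from .preprocess import Movie, detrend_trace
from .spectral import DEFAULT_OVERLAP, DEFAULT_SEGMENT_S, welch_psd

__all__ = [
    "Correlogram",
    "CovarianceAnalysis",
    "sliding_autocorrelogram",
    "shuffle_null",
    "sliding_crosscorrelogram",
    "windowed_covariance",
    "coherence_image",
    "cross_psd",
    "prepost_spectrum_ratio",
    "timepoint_correlation_matrix",
]


@dataclass(frozen=True)
class Correlogram:
    """Stack of per-window normalized correlograms and their mean."""

    lags_s: np.ndarray
    values: np.ndarray  # mean across windows
    window_stack: np.ndarray  # (n_windows, n_lags)
    window_s: float
    peak_lag_s: float
    peak_value: float
    dominant_period_s: float = np.nan

    @property
    def dispersion(self) -> np.ndarray:
        """Across-window standard deviation at each lag."""
        return self.window_stack.std(axis=0)


def _window_starts(n: int, n_win: int) -> np.ndarray:
    step = max(n_win // 2, 1)  # half-window overlap
    return np.arange(0, n - n_win + 1, step)


def _lagged_pearson(a: np.ndarray, b: np.ndarray, max_lag: int) -> np.ndarray | None:
    """Pearson correlation of the overlapping parts of ``a`` and ``b`` at
    every lag in ``[-max_lag, max_lag]`` (positive lag: b delayed behind a).

    Correlating only the overlap keeps every value in [-1, 1] exactly and
    makes a pure periodic signal reach ~1 again at its period. Returns None
    if the full windows have zero variance.
    """
    n = a.size
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        return None
    out = np.empty(2 * max_lag + 1)
    for i, k in enumerate(range(-max_lag, max_lag + 1)):
        if k >= 0:
            x, y = a[: n - k], b[k:]
        else:
            x, y = a[-k:], b[: n + k]
        xc = x - x.mean()
        yc = y - y.mean()
        denom = np.sqrt(np.dot(xc, xc) * np.dot(yc, yc))
        out[i] = np.dot(xc, yc) / denom if denom > 0 else 0.0
    return out


def sliding_autocorrelogram(trace: np.ndarray, sample_rate: float,
                            window_s: float = 1.0) -> Correlogram:
    """Normalized autocorrelation per sliding window (half-window step),
    averaged across windows.

    The dominant period is the lag of the first positive peak at non-zero
    lag of the mean correlogram; ``peak_value`` is its height. Zero-variance
    windows are skipped with a warning.
    """
    trace = np.asarray(trace, dtype=float)
    n_win = int(round(window_s * sample_rate))
    if trace.size < 2 * n_win:
        raise ConfigurationError(
            f"trace of {trace.size} samples needs >= 2 windows of "
            f"{n_win} samples")
    max_lag = n_win - 1
    rows, skipped = [], 0
    for start in _window_starts(trace.size, n_win):
        w = trace[start:start + n_win]
        c = _lagged_pearson(w, w, max_lag)
        if c is None:
            skipped += 1
            continue
        rows.append(c)
    if skipped:
        warnings.warn(f"skipped {skipped} zero-variance windows",
                      RuntimeWarning, stacklevel=2)
    if not rows:
        raise ConfigurationError("all windows had zero variance")
    stack = np.asarray(rows)
    mean = stack.mean(axis=0)
    lags = np.arange(-max_lag, max_lag + 1) / sample_rate

    # first positive-lag positive peak of the mean correlogram
    pos = mean[max_lag:]
    peaks, _ = signal.find_peaks(pos, height=0.0)
    if peaks.size:
        k = peaks[0]
        period = k / sample_rate
        peak_val = float(pos[k])
    else:
        period, peak_val, k = np.nan, np.nan, 0
    return Correlogram(lags_s=lags, values=mean, window_stack=stack,
                       window_s=window_s,
                       peak_lag_s=float(k / sample_rate),
                       peak_value=peak_val, dominant_period_s=period)


def shuffle_null(trace: np.ndarray, seed: int = 0) -> np.ndarray:
    """Random temporal permutation: the amplitude histogram is preserved
    exactly while autocorrelation structure is destroyed."""
    trace = np.asarray(trace)
    if trace.size == 0:
        raise ConfigurationError("cannot shuffle an empty trace")
    return np.random.default_rng(seed).permutation(trace)


def sliding_crosscorrelogram(trace_a: np.ndarray, trace_b: np.ndarray,
                             sample_rate: float,
                             window_s: float = 1.0) -> Correlogram:
    """Per-window normalized cross-correlation over lags up to +-window/2,
    averaged across windows; reports the mean correlogram's peak value and
    lag. Traces must share length and rate (downsample first)."""
    a = np.asarray(trace_a, dtype=float)
    b = np.asarray(trace_b, dtype=float)
    if a.size != b.size:
        raise ConfigurationError(
            f"trace lengths differ ({a.size} vs {b.size}); resample to a "
            "common rate first (see downsample_ephys)")
    n_win = int(round(window_s * sample_rate))
    if a.size < n_win:
        raise ConfigurationError("traces shorter than one window")
    max_lag = n_win // 2
    rows, skipped = [], 0
    for start in _window_starts(a.size, n_win):
        c = _lagged_pearson(a[start:start + n_win], b[start:start + n_win],
                            max_lag)
        if c is None:
            skipped += 1
            continue
        rows.append(c)
    if skipped:
        warnings.warn(f"skipped {skipped} zero-variance windows",
                      RuntimeWarning, stacklevel=2)
    if not rows:
        raise ConfigurationError("all windows had zero variance")
    stack = np.asarray(rows)
    mean = stack.mean(axis=0)
    lags = np.arange(-max_lag, max_lag + 1) / sample_rate
    # among near-maximal bins (0.01 correlation units) prefer the lag
    # closest to zero: a periodic signal repeats its peak at every multiple
    # of the period and noise jitters which replicate is largest
    near = np.flatnonzero(mean >= mean.max() - 0.01)
    k = int(near[np.argmin(np.abs(lags[near]))])
    return Correlogram(lags_s=lags, values=mean, window_stack=stack,
                       window_s=window_s, peak_lag_s=float(lags[k]),
                       peak_value=float(mean[k]))


@dataclass(frozen=True)
class CovarianceAnalysis:
    """Per-window pixel-by-pixel covariance matrices."""

    windows_s: tuple[tuple[float, float], ...]
    matrices: np.ndarray  # (n_windows, n_pixels, n_pixels), raw covariance
    pixels: np.ndarray  # (n_pixels, 2) row/col
    frame_shape: tuple[int, int]

    def normalized(self, mode: str = "joint") -> np.ndarray:
        """Display normalisation to the max absolute covariance, either
        jointly across all windows (default) or per window."""
        if mode == "joint":
            scale = np.abs(self.matrices).max() or 1.0
            return self.matrices / scale
        if mode == "per-window":
            scale = np.abs(self.matrices).max(axis=(1, 2), keepdims=True)
            return self.matrices / np.where(scale == 0, 1.0, scale)
        raise ConfigurationError(f"unknown normalisation mode {mode!r}")


def windowed_covariance(movie: Movie, pixels: np.ndarray,
                        windows_s, detrend_window_s: float = 0.25,
                        ) -> CovarianceAnalysis:
    """Covariance between the detrended traces of the given pixels in each
    time window (``windows_s`` = iterable of ``(t0, t1)`` in seconds)."""
    pixels = np.asarray(pixels)
    if pixels.shape[0] < 2:
        raise ConfigurationError("need >= 2 pixels for covariance analysis")
    traces = movie.data[:, pixels[:, 0], pixels[:, 1]].T.astype(float)
    traces = np.stack([
        detrend_trace(tr, movie.frame_rate, detrend_window_s) for tr in traces])
    mats = []
    for t0, t1 in windows_s:
        i0, i1 = int(round(t0 * movie.frame_rate)), int(round(t1 * movie.frame_rate))
        if not (0 <= i0 < i1 <= movie.n_frames):
            raise ConfigurationError(
                f"window ({t0}, {t1}) s outside the {movie.duration_s} s recording")
        if i1 - i0 < 2:
            raise ConfigurationError(f"window ({t0}, {t1}) s has < 2 frames")
        mats.append(np.cov(traces[:, i0:i1]))
    return CovarianceAnalysis(windows_s=tuple(tuple(w) for w in windows_s),
                              matrices=np.asarray(mats), pixels=pixels,
                              frame_shape=movie.frame_shape)


def coherence_image(analysis: CovarianceAnalysis) -> np.ndarray:
    """Per-pixel map of the across-window maximum of the mean absolute
    off-diagonal covariance with all other analysed pixels. Pixels outside
    the analysis are 0."""
    n_pix = analysis.pixels.shape[0]
    if n_pix < 2:
        raise ConfigurationError("coherence image needs >= 2 analysed pixels")
    abs_mats = np.abs(analysis.matrices.copy())
    idx = np.arange(n_pix)
    abs_mats[:, idx, idx] = 0.0
    per_window = abs_mats.sum(axis=2) / (n_pix - 1)  # (n_windows, n_pixels)
    values = per_window.max(axis=0)
    image = np.zeros(analysis.frame_shape)
    image[analysis.pixels[:, 0], analysis.pixels[:, 1]] = values
    return image


def cross_psd(trace_a: np.ndarray, trace_b: np.ndarray, sample_rate: float,
              segment_s: float = DEFAULT_SEGMENT_S,
              overlap_fraction: float = DEFAULT_OVERLAP,
              ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Welch cross-power spectral density: ``(frequencies, |CSD|, phase)``.

    Welch parameters match :func:`oscimap.spectral.welch_psd`, so
    ``cross_psd(a, a)`` equals the PSD of ``a`` bin-by-bin with zero phase.
    """
    a = np.asarray(trace_a, dtype=float)
    b = np.asarray(trace_b, dtype=float)
    if a.size != b.size:
        raise ConfigurationError(
            f"trace lengths differ ({a.size} vs {b.size})")
    nperseg = int(round(segment_s * sample_rate))
    if a.size < nperseg:
        raise ConfigurationError("traces shorter than one Welch segment")
    freqs, csd = signal.csd(a, b, fs=sample_rate, window="hann",
                            nperseg=nperseg,
                            noverlap=int(round(overlap_fraction * nperseg)),
                            detrend="linear", scaling="density")
    return freqs, np.abs(csd), np.angle(csd)


def prepost_spectrum_ratio(trace: np.ndarray, sample_rate: float,
                           stim_window_s: tuple[float, float],
                           epoch_s: float = 2.0,
                           segment_s: float = DEFAULT_SEGMENT_S,
                           peak_support: float = 0.5,
                           ) -> tuple[np.ndarray, np.ndarray, float, float]:
    """Per-bin PSD ratio of matched-duration epochs after vs before a
    stimulation window.

    Returns ``(frequencies, ratio, peak_ratio, peak_frequency)``. The pre
    epoch is the ``epoch_s`` seconds ending at stimulation onset; the post
    epoch the same duration starting at stimulation offset. The reported
    peak is the ratio argmax over spectrally dominant post bins (post PSD
    within ``peak_support`` of its maximum): the raw argmax can land on a
    window-leakage shoulder of a strong evoked tone where the pre spectrum
    is near-empty and the ratio therefore unstable. The full per-bin ratio
    is returned unrestricted.
    """
    trace = np.asarray(trace, dtype=float)
    n_epoch = int(round(epoch_s * sample_rate))
    i_on = int(round(stim_window_s[0] * sample_rate))
    i_off = int(round(stim_window_s[1] * sample_rate))
    if i_on - n_epoch < 0 or i_off + n_epoch > trace.size:
        raise ConfigurationError(
            f"need {epoch_s} s of data both before and after the stimulation "
            f"window {stim_window_s} s")
    pre = trace[i_on - n_epoch: i_on]
    post = trace[i_off: i_off + n_epoch]
    freqs, psd_pre = welch_psd(pre, sample_rate, segment_s)
    _, psd_post = welch_psd(post, sample_rate, segment_s)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(psd_pre > 0, psd_post / psd_pre, np.nan)
    # ignore DC and require spectrally dominant post bins for the peak
    valid = (np.isfinite(ratio) & (freqs > 0)
             & (psd_post >= peak_support * psd_post[freqs > 0].max()))
    if not valid.any():
        raise ConfigurationError("no valid frequency bins for the ratio")
    k = np.flatnonzero(valid)[int(np.argmax(ratio[valid]))]
    return freqs, ratio, float(ratio[k]), float(freqs[k])


def timepoint_correlation_matrix(traces, window_s=None,
                                 sample_rate: float | None = None) -> np.ndarray:
    """Pearson correlation between all pairs of traces within a window.

    Symmetric with unit diagonal; pairs involving a zero-variance trace are
    reported NaN (missing), not zero.
    """
    arr = np.asarray(traces, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 2:
        raise ConfigurationError("need >= 2 equal-length traces")
    if window_s is not None:
        if sample_rate is None:
            raise ConfigurationError("window_s requires sample_rate")
        i0 = int(round(window_s[0] * sample_rate))
        i1 = int(round(window_s[1] * sample_rate))
        if not (0 <= i0 < i1 <= arr.shape[1]):
            raise ConfigurationError(f"window {window_s} s outside traces")
        arr = arr[:, i0:i1]
    n = arr.shape[0]
    centered = arr - arr.mean(axis=1, keepdims=True)
    norms = np.sqrt((centered**2).sum(axis=1))
    out = np.full((n, n), np.nan)
    for i in range(n):
        for j in range(n):
            if i == j:
                out[i, j] = 1.0
            elif norms[i] > 0 and norms[j] > 0:
                out[i, j] = float(np.dot(centered[i], centered[j])
                                  / (norms[i] * norms[j]))
    return out
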