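"""Movie and trace conditioning: I/O, cropping, bleach correction, dF/F,
median-filter detrending and anti-aliased downsampling of electrophysiology.

Conventions
-----------
Arrays are ``(time, rows, cols)`` with 0-based, half-open pixel ranges.
All operations return new objects; inputs are never mutated.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import yaml
from scipy.ndimage import median_filter
from scipy.optimize import curve_fit

from .errors import ConfigurationError, DataFormatError

logger = logging.getLogger(__name__)

__all__ = [
    "Movie",
    "EphysTrace",
    "load_movie",
    "save_movie",
    "crop",
    "bleach_correct",
    "dff",
    "detrend_trace",
    "downsample_ephys",
]


@dataclass(frozen=True)
class Movie:
    """A fluorescence movie with acquisition metadata.

    Parameters
    ----------
    data : ndarray
        3-D array ``(time, rows, cols)``, fluorescence counts or a
        dimensionless derived signal (see ``origin``).
    frame_rate : float
        Acquisition rate in Hz.
    pixel_pitch_um : float
        Pixel size in micrometres.
    origin : str
        Processing provenance tag: ``raw``, ``bleach-corrected``, ``dff``
        or ``detrended``.
    """

    data: np.ndarray
    frame_rate: float
    pixel_pitch_um: float
    origin: str = "raw"

    def __post_init__(self) -> None:
        data = np.asarray(self.data)
        if data.ndim != 3:
            raise DataFormatError(
                f"movie data must be 3-D (time, rows, cols); got shape {data.shape}"
            )
        if not self.frame_rate > 0:
            raise ConfigurationError(f"frame_rate must be > 0, got {self.frame_rate}")
        if not self.pixel_pitch_um > 0:
            raise ConfigurationError(
                f"pixel_pitch_um must be > 0, got {self.pixel_pitch_um}"
            )
        object.__setattr__(self, "data", data)

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.data.shape[1:]

    @property
    def duration_s(self) -> float:
        """Recording duration in seconds."""
        return self.n_frames / self.frame_rate

    @property
    def times(self) -> np.ndarray:
        """Frame time stamps in seconds (frame 0 at t = 0)."""
        return np.arange(self.n_frames) / self.frame_rate


@dataclass(frozen=True)
class EphysTrace:
    """A membrane-voltage trace in mV at a fixed sample rate."""

    samples: np.ndarray
    sample_rate: float

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=float)
        if samples.ndim != 1:
            raise DataFormatError("ephys trace must be 1-D")
        if not self.sample_rate > 0:
            raise ConfigurationError(
                f"sample_rate must be > 0, got {self.sample_rate}"
            )
        object.__setattr__(self, "samples", samples)

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.sample_rate

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.samples.size) / self.sample_rate


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

_META_KEYS = ("frame_rate_hz", "pixel_pitch_um", "origin")


def save_movie(movie: Movie, path) -> None:
    """Write a movie as a multi-page TIFF (one page per frame).

    Acquisition metadata is stored as JSON in the TIFF description tag so
    that :func:`load_movie` can round-trip it without a sidecar file.
    """
    import tifffile

    meta = {
        "frame_rate_hz": movie.frame_rate,
        "pixel_pitch_um": movie.pixel_pitch_um,
        "origin": movie.origin,
    }
    tifffile.imwrite(str(path), movie.data, photometric="minisblack",
                     description=json.dumps(meta))


def load_movie(path, frame_rate=None, pixel_pitch_um=None) -> Movie:
    """Read a multi-page TIFF movie.

    Metadata precedence: explicit arguments, then JSON in the TIFF
    description tag, then a YAML sidecar ``<path>.meta.yaml`` with keys
    ``frame_rate_hz`` / ``pixel_pitch_um``. A missing frame rate is a
    configuration error — there is no silent default.
    """
    import tifffile

    try:
        with tifffile.TiffFile(str(path)) as tif:
            shapes = {page.shape for page in tif.pages}
            if len(shapes) > 1:
                raise DataFormatError(
                    f"TIFF pages have differing sizes {sorted(shapes)}; "
                    "movies must have one fixed frame size"
                )
            data = tif.asarray()
            description = tif.pages[0].description
    except DataFormatError:
        raise
    except Exception as exc:  # tifffile raises various classes
        raise DataFormatError(f"could not read TIFF movie {path}: {exc}") from exc

    if data.ndim == 2:
        data = data[None]

    meta = {}
    if description:
        try:
            parsed = json.loads(description)
            if isinstance(parsed, dict):
                meta.update(parsed)
        except (ValueError, TypeError):
            pass
    sidecar = str(path) + ".meta.yaml"
    try:
        with open(sidecar) as fh:
            side = yaml.safe_load(fh) or {}
        for key in _META_KEYS:
            meta.setdefault(key, side.get(key))
    except FileNotFoundError:
        pass

    if frame_rate is None:
        frame_rate = meta.get("frame_rate_hz")
    if pixel_pitch_um is None:
        pixel_pitch_um = meta.get("pixel_pitch_um")
    if frame_rate is None:
        raise ConfigurationError(
            f"frame rate for {path} not found in TIFF tags or sidecar "
            f"{sidecar}; pass frame_rate= explicitly or provide a sidecar "
            "with key frame_rate_hz"
        )
    if pixel_pitch_um is None:
        raise ConfigurationError(
            f"pixel pitch for {path} not found; pass pixel_pitch_um= or "
            f"provide sidecar key pixel_pitch_um in {sidecar}"
        )
    return Movie(
        data=data,
        frame_rate=float(frame_rate),
        pixel_pitch_um=float(pixel_pitch_um),
        origin=str(meta.get("origin", "raw")),
    )


# ---------------------------------------------------------------------------
# Spatial / temporal conditioning
# ---------------------------------------------------------------------------


def crop(movie: Movie, rows: tuple[int, int], cols: tuple[int, int]) -> Movie:
    """Crop to the half-open pixel ranges ``rows=[r0, r1)``, ``cols=[c0, c1)``."""
    r0, r1 = rows
    c0, c1 = cols
    nrows, ncols = movie.frame_shape
    if not (0 <= r0 < r1 <= nrows and 0 <= c0 < c1 <= ncols):
        raise ConfigurationError(
            f"crop ranges rows={rows} cols={cols} invalid for frame "
            f"{movie.frame_shape}; ranges are half-open and must be "
            "non-empty and in-bounds"
        )
    return replace(movie, data=movie.data[:, r0:r1, c0:c1].copy())


def _exp_model(t, a, tau, c):
    return a * np.exp(-t / tau) + c


def _fit_exponential(t: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Fit ``a*exp(-t/tau) + c`` and return the fitted trend.

    Raises on failure so callers can fall back.
    """
    y0, y1 = float(y[0]), float(y[-1])
    span = y0 - y1
    if abs(span) < 1e-12 * max(abs(y0), 1.0):
        # flat trace: trend is its mean
        return np.full_like(y, float(np.mean(y)), dtype=float)
    p0 = (span, max(t[-1], 1e-6) / 2.0, y1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        popt, _ = curve_fit(
            _exp_model, t, y, p0=p0,
            bounds=([-np.inf, 1e-9, -np.inf], [np.inf, np.inf, np.inf]),
            maxfev=2000,
        )
    trend = _exp_model(t, *popt)
    if np.any(trend <= 0) or not np.all(np.isfinite(trend)):
        raise RuntimeError("non-positive or non-finite fitted trend")
    return trend


def bleach_correct(movie: Movie, mode: str = "pixel") -> Movie:
    """Divide out a fitted mono-exponential-plus-offset bleaching trend.

    ``mode='pixel'`` fits every pixel independently (falling back to the
    global frame-mean trend where a pixel fit fails); ``mode='global'``
    fits the frame-mean trace once and rescales it per pixel. Output traces
    are dimensionless with per-pixel mean ~= 1.
    """
    if movie.n_frames < 10:
        raise ConfigurationError(
            f"bleach correction needs >= 10 frames, got {movie.n_frames}"
        )
    if mode not in ("pixel", "global"):
        raise ConfigurationError(f"unknown bleach correction mode {mode!r}")
    t = movie.times
    data = movie.data.astype(float)
    global_mean = data.mean(axis=(1, 2))
    try:
        global_trend = _fit_exponential(t, global_mean)
    except Exception:
        global_trend = np.full_like(t, float(global_mean.mean()))
        logger.warning("global bleach fit failed; using flat trend")
    rel_global = global_trend / global_trend.mean()

    out = np.empty_like(data)
    if mode == "global":
        # shared trend shape, per-pixel scale
        pixel_mean = data.mean(axis=0)
        trend = rel_global[:, None, None] * pixel_mean[None]
        with np.errstate(divide="ignore", invalid="ignore"):
            out = np.where(trend > 0, data / trend, 1.0)
    else:
        n_fallback = 0
        nrows, ncols = movie.frame_shape
        for r in range(nrows):
            for c in range(ncols):
                y = data[:, r, c]
                try:
                    trend = _fit_exponential(t, y)
                except Exception:
                    n_fallback += 1
                    m = y.mean()
                    trend = rel_global * (m if m > 0 else 1.0)
                out[:, r, c] = y / trend
        if n_fallback:
            logger.warning(
                "bleach_correct: %d/%d pixels fell back to the global trend",
                n_fallback, nrows * ncols,
            )
    return replace(movie, data=out, origin="bleach-corrected")


def dff(movie: Movie, baseline: str = "mean",
        baseline_window: tuple[float, float] | None = None) -> Movie:
    """Convert to fractional fluorescence change (F - F0) / F0.

    F0 is the per-pixel temporal mean (``baseline='mean'``) or the mean
    over a time window in seconds (``baseline='window'``, e.g. a
    pre-stimulus epoch). Pixels with zero baseline are masked to NaN with
    a warning rather than raising.
    """
    data = movie.data.astype(float)
    if baseline == "mean":
        f0 = data.mean(axis=0)
    elif baseline == "window":
        if baseline_window is None:
            raise ConfigurationError("baseline='window' requires baseline_window")
        i0 = int(round(baseline_window[0] * movie.frame_rate))
        i1 = int(round(baseline_window[1] * movie.frame_rate))
        if not (0 <= i0 < i1 <= movie.n_frames):
            raise ConfigurationError(
                f"baseline window {baseline_window} s outside recording"
            )
        f0 = data[i0:i1].mean(axis=0)
    else:
        raise ConfigurationError(f"unknown baseline definition {baseline!r}")

    zero = ~(f0 > 0)
    if np.any(zero):
        warnings.warn(
            f"dff: {int(zero.sum())} pixels have non-positive baseline; "
            "masked to NaN", RuntimeWarning, stacklevel=2,
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        out = (data - f0) / f0
    out[:, zero] = np.nan
    return replace(movie, data=out, origin="dff")


def detrend_trace(trace: np.ndarray, sample_rate: float,
                  window_s: float = 0.25) -> np.ndarray:
    """Subtract a running median (reflection-padded edges) from a 1-D trace.

    The default 0.25 s window passes oscillations faster than ~2 Hz while
    removing slow drift; output mean is ~0.
    """
    trace = np.asarray(trace, dtype=float)
    n_win = int(round(window_s * sample_rate))
    if n_win < 3:
        raise ConfigurationError(
            f"detrend window {window_s} s is only {n_win} samples at "
            f"{sample_rate} Hz; need >= 3"
        )
    if n_win > trace.size:
        raise ConfigurationError(
            f"detrend window ({n_win} samples) longer than trace "
            f"({trace.size} samples)"
        )
    med = median_filter(trace, size=n_win, mode="reflect")
    return trace - med


def downsample_ephys(trace: EphysTrace, target_rate: float) -> EphysTrace:
    """Downsample by consecutive bin-averaging (anti-aliasing by design).

    Output length is ``floor(n * target_rate / sample_rate)``; bin *i*
    averages source samples ``[floor(i*f), floor((i+1)*f))`` with
    ``f = sample_rate / target_rate``, so non-integer ratios are handled.
    """
    if target_rate > trace.sample_rate:
        raise ConfigurationError(
            f"target rate {target_rate} Hz above source rate "
            f"{trace.sample_rate} Hz; downsampling only"
        )
    n_out = int(np.floor(trace.samples.size * target_rate / trace.sample_rate))
    if n_out == 0:
        raise ConfigurationError("trace too short for requested target rate")
    f = trace.sample_rate / target_rate
    edges = np.floor(np.arange(n_out + 1) * f).astype(int)
    csum = np.concatenate([[0.0], np.cumsum(trace.samples)])
    sums = csum[edges[1:]] - csum[edges[:-1]]
    counts = np.diff(edges)
    out = sums / counts
    return EphysTrace(samples=out, sample_rate=target_rate)
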