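"""Staining quantification: azimuthal radial intensity profiles, half-max
spread radii, per-cell segment profiles with compartment statistics, and
segment-variability dispersion.

Compartment bounds follow fixed radial distances from the cell centre:
nucleus 0-3.5 um, cytosol 3.5-10 um, neuropil beyond 10 um.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigurationError, NumericalError

__all__ = [
    "RadialProfile",
    "CompartmentBounds",
    "CellProfileResult",
    "HalfMaxResult",
    "radial_profile",
    "half_max_radius",
    "cell_radial_profile",
    "compartment_stats",
    "segment_variability",
    "find_injection_center",
]


@dataclass(frozen=True)
class RadialProfile:
    """Mean intensity per annulus around a centre point."""

    radii_um: np.ndarray  # bin centres, strictly increasing
    intensity: np.ndarray  # NaN where an annulus contains no pixels
    center_um: tuple[float, float]
    normalization: str = "raw"

    def __post_init__(self) -> None:
        if np.any(np.diff(self.radii_um) <= 0):
            raise ConfigurationError("radii must be strictly increasing")


@dataclass(frozen=True)
class CompartmentBounds:
    """Radial compartment limits in micrometres (contiguous, ordered)."""

    nucleus_um: float = 3.5
    soma_um: float = 10.0

    def __post_init__(self) -> None:
        if not 0 < self.nucleus_um < self.soma_um:
            raise ConfigurationError(
                "compartment bounds must satisfy 0 < nucleus < soma")


@dataclass(frozen=True)
class HalfMaxResult:
    radius_um: float  # r_max if censored
    censored: bool


def _pixel_distances(shape, center_um, pixel_pitch_um):
    yy, xx = np.mgrid[: shape[0], : shape[1]].astype(float)
    return np.hypot(yy * pixel_pitch_um - center_um[0],
                    xx * pixel_pitch_um - center_um[1])


def radial_profile(image: np.ndarray, center_um: tuple[float, float],
                   r_max_um: float, pixel_pitch_um: float,
                   bin_width_um: float | None = None) -> RadialProfile:
    """Azimuthally averaged intensity per annulus ``[r, r + bin)``.

    Annulus membership is by pixel-centre distance; an annulus containing
    no pixels is recorded as NaN (missing), never zero. Default bin width
    is one pixel pitch.
    """
    image = np.asarray(image, dtype=float)
    if bin_width_um is None:
        bin_width_um = pixel_pitch_um
    if not r_max_um > bin_width_um:
        raise ConfigurationError("r_max must exceed the bin width")
    extent = ((image.shape[0] - 1) * pixel_pitch_um,
              (image.shape[1] - 1) * pixel_pitch_um)
    if not (0 <= center_um[0] <= extent[0] and 0 <= center_um[1] <= extent[1]):
        raise ConfigurationError(f"centre {center_um} um outside image {extent} um")
    r = _pixel_distances(image.shape, center_um, pixel_pitch_um)
    n_bins = int(np.ceil(r_max_um / bin_width_um))
    idx = (r / bin_width_um).astype(int)
    inside = idx < n_bins
    sums = np.bincount(idx[inside], weights=image[inside], minlength=n_bins)
    counts = np.bincount(idx[inside], minlength=n_bins)
    with np.errstate(invalid="ignore"):
        means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    centers = (np.arange(n_bins) + 0.5) * bin_width_um
    return RadialProfile(radii_um=centers, intensity=means,
                         center_um=tuple(center_um))


def half_max_radius(profile: RadialProfile,
                    baseline_fraction: float = 0.1) -> HalfMaxResult:
    """Smallest radius beyond the profile peak where intensity first falls
    below ``(peak + baseline) / 2``, linearly interpolated between bins.

    The baseline is the mean of the outermost ``baseline_fraction`` of
    bins. A profile that never crosses within range is censored at the
    outermost radius.
    """
    r = profile.radii_um
    y = profile.intensity
    valid = np.isfinite(y)
    if not valid.any() or np.nanmax(y) <= 0:
        raise NumericalError("profile has no positive peak")
    n_base = max(int(round(baseline_fraction * r.size)), 1)
    baseline = np.nanmean(y[-n_base:])
    peak_i = int(np.nanargmax(y))
    half = (y[peak_i] + baseline) / 2.0
    for j in range(peak_i + 1, r.size):
        if not np.isfinite(y[j]):
            continue
        if y[j] < half:
            # previous finite point for interpolation
            k = j - 1
            while k > peak_i and not np.isfinite(y[k]):
                k -= 1
            r0, v0 = r[k], y[k]
            r1, v1 = r[j], y[j]
            radius = r0 + (v0 - half) / (v0 - v1) * (r1 - r0)
            return HalfMaxResult(radius_um=float(radius), censored=False)
    return HalfMaxResult(radius_um=float(r[-1]), censored=True)


@dataclass(frozen=True)
class CellProfileResult:
    """360-degree average and angular-segment radial profiles of one cell,
    min-max normalised within the sampling disc."""

    average: RadialProfile
    segments: tuple[RadialProfile, ...]
    segment_edges_deg: np.ndarray


def cell_radial_profile(image: np.ndarray, cell_center_um: tuple[float, float],
                        pixel_pitch_um: float, radius_um: float = 20.0,
                        n_segments: int = 18,
                        bin_width_um: float | None = None) -> CellProfileResult:
    """Radial profiles on a disc around a cell centre, as a 360-degree
    average and ``n_segments`` angular segments (default 18 x 20 degrees,
    0 degrees along the image row axis, counterclockwise).

    The disc must lie fully inside the image; profiles are min-max
    normalised within the disc so the maximum is exactly 1.
    """
    image = np.asarray(image, dtype=float)
    if bin_width_um is None:
        bin_width_um = pixel_pitch_um
    extent = ((image.shape[0] - 1) * pixel_pitch_um,
              (image.shape[1] - 1) * pixel_pitch_um)
    cy, cx = cell_center_um
    if (cy - radius_um < 0 or cx - radius_um < 0
            or cy + radius_um > extent[0] or cx + radius_um > extent[1]):
        raise ConfigurationError(
            f"cell disc (centre {cell_center_um} um, radius {radius_um} um) "
            "clipped by the image border")

    yy, xx = np.mgrid[: image.shape[0], : image.shape[1]].astype(float)
    dy = yy * pixel_pitch_um - cy
    dx = xx * pixel_pitch_um - cx
    r = np.hypot(dy, dx)
    theta = np.mod(np.arctan2(dx, dy), 2 * np.pi)  # 0 = row axis, ccw

    inside = r < radius_um
    lo, hi = image[inside].min(), image[inside].max()
    span = hi - lo if hi > lo else 1.0
    norm_img = (image - lo) / span

    n_bins = int(np.ceil(radius_um / bin_width_um))
    centers = (np.arange(n_bins) + 0.5) * bin_width_um
    rbin = (r / bin_width_um).astype(int)

    def _profile(sel):
        sel = sel & inside
        sums = np.bincount(rbin[sel], weights=norm_img[sel], minlength=n_bins)
        counts = np.bincount(rbin[sel], minlength=n_bins)
        with np.errstate(invalid="ignore"):
            vals = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
        return RadialProfile(radii_um=centers, intensity=vals,
                             center_um=tuple(cell_center_um),
                             normalization="min-max")

    average = _profile(np.ones_like(inside))
    edges = np.linspace(0, 2 * np.pi, n_segments + 1)
    seg_idx = np.minimum((theta / (2 * np.pi) * n_segments).astype(int),
                         n_segments - 1)
    segments = tuple(_profile(seg_idx == s) for s in range(n_segments))
    return CellProfileResult(average=average, segments=segments,
                             segment_edges_deg=np.degrees(edges))


def compartment_stats(cell_profiles, bounds: CompartmentBounds | None = None,
                      ) -> pd.DataFrame:
    """Per-cell compartment means from averaged radial profiles.

    Accepts an iterable of :class:`RadialProfile` (or
    :class:`CellProfileResult`, whose average is used). Returns one row per
    cell with nucleus/cytosol/neuropil mean intensity, the
    cytosol-to-neuropil ratio, the peak-intensity radius, and a
    ``cytosol_dominant`` flag (> 50 % of the cytosol + neuropil signal in
    the cytosol); the fraction of flagged cells is the population statistic.
    """
    if bounds is None:
        bounds = CompartmentBounds()
    rows = []
    for i, prof in enumerate(cell_profiles):
        if isinstance(prof, CellProfileResult):
            prof = prof.average
        r, y = prof.radii_um, prof.intensity
        if r[-1] <= bounds.soma_um:
            raise ConfigurationError(
                f"profile {i} does not extend past the soma bound "
                f"({bounds.soma_um} um)")
        nuc = np.nanmean(y[r <= bounds.nucleus_um])
        cyt = np.nanmean(y[(r > bounds.nucleus_um) & (r <= bounds.soma_um)])
        npl = np.nanmean(y[r > bounds.soma_um])
        ratio = cyt / npl if npl > 0 else np.inf
        total = cyt + npl
        rows.append({
            "cell": i,
            "nucleus_mean": float(nuc),
            "cytosol_mean": float(cyt),
            "neuropil_mean": float(npl),
            "cytosol_neuropil_ratio": float(ratio),
            "peak_radius_um": float(r[int(np.nanargmax(y))]),
            "cytosol_dominant": bool(total > 0 and cyt / total > 0.5),
        })
    return pd.DataFrame(rows)


def segment_variability(result: CellProfileResult) -> float:
    """Standard deviation across angular segments of each segment's peak
    intensity (profiles already normalised). 0 for a rotationally
    symmetric cell; larger for punctate, inhomogeneous labelling."""
    peaks = [np.nanmax(seg.intensity) for seg in result.segments
             if np.isfinite(seg.intensity).any()]
    if len(peaks) < 2:
        raise ConfigurationError("need >= 2 segments with data")
    return float(np.std(peaks))


def find_injection_center(image: np.ndarray, pixel_pitch_um: float,
                          top_fraction: float = 0.001) -> tuple[float, float]:
    """Default injection-centre estimate: centroid (in um) of the brightest
    ``top_fraction`` of pixels."""
    image = np.asarray(image, dtype=float)
    n = max(int(round(top_fraction * image.size)), 1)
    flat = image.ravel()
    idx = np.argpartition(flat, -n)[-n:]
    rr, cc = np.unravel_index(idx, image.shape)
    w = flat[idx]
    if w.sum() <= 0:
        w = np.ones_like(w)
    return (float(np.average(rr, weights=w)) * pixel_pitch_um,
            float(np.average(cc, weights=w)) * pixel_pitch_um)
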