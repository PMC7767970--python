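"""Ground-truth generators: oscillating-cluster movies, paired voltage
traces, and dye-staining images with known radial structure.

The generative model is deliberately simple and fully parameterised so that
every downstream analysis can be validated against known ground truth:

* each cluster is a filled disk of pixels sharing one sinusoidal membrane
  voltage (mV), clusters superpose where they overlap;
* fluorescence is ``baseline * exp(-t/bleach_tau) * (1 + sensitivity * V)``
  plus sensor noise, so a depolarisation increases fluorescence and a
  1 mV swing moves the signal by ``sensitivity`` (default 0.5 %) of
  baseline;
* an optional stimulation train entrains every cluster to a common
  frequency (with per-cluster phases and an amplitude gain) once the train
  ends, and renders brief negative artifact deflections during the pulses.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .preprocess import EphysTrace, Movie

__all__ = [
    "ClusterSpec",
    "StimSpec",
    "SceneConfig",
    "MovieFixture",
    "CellSpec",
    "StainingFieldSpec",
    "generate_sto_movie",
    "generate_paired_ephys",
    "generate_staining_field",
    "random_scene",
    "dye_solution_molarity",
]


@dataclass(frozen=True)
class ClusterSpec:
    """One synchronously oscillating pixel group.

    ``amplitude_mv`` is peak-to-peak membrane-voltage swing in mV;
    physiological STOs run 3-12 Hz at 2-10 mV. ``onset_s``/``offset_s``
    gate the oscillation in time (``offset_s=None`` means until the end).
    """

    center: tuple[int, int]
    frequency_hz: float
    amplitude_mv: float = 5.0
    footprint_diameter_um: float = 110.0
    phase_rad: float = 0.0
    onset_s: float = 0.0
    offset_s: float | None = None
    allow_any_frequency: bool = False

    def __post_init__(self) -> None:
        if not self.allow_any_frequency and not (3.0 <= self.frequency_hz <= 12.0):
            raise ConfigurationError(
                f"cluster frequency {self.frequency_hz} Hz outside the 3-12 Hz "
                "band; pass allow_any_frequency=True to override"
            )
        if self.amplitude_mv < 0:
            raise ConfigurationError("amplitude must be >= 0")
        if self.footprint_diameter_um <= 0:
            raise ConfigurationError("footprint diameter must be > 0")


@dataclass(frozen=True)
class StimSpec:
    """An afferent stimulation train and its effect on the oscillators.

    After the last pulse every cluster oscillates at ``entrained_frequency_hz``
    with amplitude scaled by ``power_gain`` and phase taken from
    ``post_phases_rad`` (one entry per cluster; None keeps each cluster's
    own phase). During each pulse a brief negative artifact deflection of
    ``artifact_amplitude`` counts is applied frame-wide.
    """

    onset_s: float
    entrained_frequency_hz: float
    n_pulses: int = 10
    pulse_rate_hz: float = 10.0
    power_gain: float = 1.0
    post_phases_rad: tuple[float, ...] | None = None
    artifact_amplitude: float = 0.0

    @property
    def end_s(self) -> float:
        return self.onset_s + self.n_pulses / self.pulse_rate_hz


@dataclass(frozen=True)
class SceneConfig:
    """Full description of a synthetic recording."""

    frame_size: tuple[int, int] = (256, 256)
    frame_rate: float = 60.0
    pixel_pitch_um: float = 17.86
    duration_s: float = 10.0
    clusters: tuple[ClusterSpec, ...] = ()
    sensitivity: float = 0.005  # fractional dF/F per mV
    baseline_intensity: float = 1000.0
    bleach_tau_s: float = np.inf
    noise_sd: float = 2.0
    noise_model: str = "gaussian"  # or "poisson"
    stim: StimSpec | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("frame_rate", "pixel_pitch_um", "duration_s",
                     "baseline_intensity"):
            v = getattr(self, name)
            if not (np.isfinite(v) and v > 0):
                raise ConfigurationError(f"{name} must be finite and > 0, got {v}")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")
        if not self.bleach_tau_s > 0:
            raise ConfigurationError("bleach_tau_s must be > 0 (may be inf)")
        if self.noise_model not in ("gaussian", "poisson"):
            raise ConfigurationError(f"unknown noise model {self.noise_model!r}")
        freqs = [c.frequency_hz for c in self.clusters]
        if self.stim is not None:
            freqs.append(self.stim.entrained_frequency_hz)
            if self.stim.end_s >= self.duration_s:
                raise ConfigurationError(
                    f"stimulation train ends at {self.stim.end_s} s, at or "
                    f"beyond the {self.duration_s} s recording"
                )
        if freqs and self.frame_rate <= 2 * max(freqs):
            raise ConfigurationError(
                f"frame rate {self.frame_rate} Hz violates Nyquist for the "
                f"{max(freqs)} Hz oscillation; need frame_rate > "
                f"{2 * max(freqs)} Hz"
            )


@dataclass(frozen=True)
class MovieFixture:
    """A generated movie plus its ground truth.

    ``labels`` assigns each pixel to exactly one cluster (-1 = background;
    overlap resolved in favour of the earlier cluster). ``clusters`` is a
    table of per-cluster frequency/phase/amplitude/geometry.
    """

    movie: Movie
    labels: np.ndarray
    clusters: pd.DataFrame
    voltages_mv: np.ndarray  # (n_clusters, n_frames) ground-truth mV traces


def _disk_mask(shape: tuple[int, int], center: tuple[int, int],
               radius_px: float) -> np.ndarray:
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    return (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius_px**2


def _cluster_voltage(cluster: ClusterSpec, idx: int, t: np.ndarray,
                     stim: StimSpec | None) -> np.ndarray:
    """Ground-truth membrane voltage (mV) of one cluster over frame times."""
    amp = cluster.amplitude_mv / 2.0  # peak-to-peak -> amplitude
    offset = cluster.offset_s if cluster.offset_s is not None else np.inf
    active = (t >= cluster.onset_s) & (t < offset)
    v = amp * np.sin(2 * np.pi * cluster.frequency_hz * t + cluster.phase_rad)
    v = np.where(active, v, 0.0)
    if stim is not None:
        post = t >= stim.end_s
        phase = cluster.phase_rad
        if stim.post_phases_rad is not None:
            phase = stim.post_phases_rad[idx]
        v_post = (stim.power_gain * amp
                  * np.sin(2 * np.pi * stim.entrained_frequency_hz
                           * (t - stim.end_s) + phase))
        v = np.where(post, v_post, v)
    return v


def generate_sto_movie(config: SceneConfig) -> MovieFixture:
    """Render a movie of spatially clustered sinusoidal oscillations.

    Deterministic given ``config.seed``. Raises on Nyquist violations and
    on cluster footprints that do not fit inside the frame.
    """
    n_frames = int(round(config.duration_s * config.frame_rate))
    if n_frames < 1:
        raise ConfigurationError("duration too short for a single frame")
    shape = tuple(config.frame_size)
    t = np.arange(n_frames) / config.frame_rate

    labels = np.full(shape, -1, dtype=np.int32)
    voltage = np.zeros((n_frames,) + shape)
    volt_traces = np.zeros((len(config.clusters), n_frames))
    rows = []
    for idx, cluster in enumerate(config.clusters):
        radius_px = cluster.footprint_diameter_um / (2 * config.pixel_pitch_um)
        r0, c0 = cluster.center
        if (r0 - radius_px < -0.5 or c0 - radius_px < -0.5
                or r0 + radius_px > shape[0] - 0.5
                or c0 + radius_px > shape[1] - 0.5):
            raise ConfigurationError(
                f"cluster {idx} footprint (centre {cluster.center}, radius "
                f"{radius_px:.1f} px) extends outside the {shape} frame"
            )
        mask = _disk_mask(shape, cluster.center, radius_px)
        v = _cluster_voltage(cluster, idx, t, config.stim)
        volt_traces[idx] = v
        voltage[:, mask] += v[:, None]  # superposition on overlap
        labels[mask & (labels == -1)] = idx
        rows.append({
            "cluster_id": idx,
            "center_row": r0,
            "center_col": c0,
            "frequency_hz": cluster.frequency_hz,
            "amplitude_mv": cluster.amplitude_mv,
            "phase_rad": cluster.phase_rad,
            "footprint_diameter_um": cluster.footprint_diameter_um,
            "n_pixels": int(mask.sum()),
        })

    bleach = np.exp(-t / config.bleach_tau_s) if np.isfinite(config.bleach_tau_s) \
        else np.ones_like(t)
    data = (config.baseline_intensity * bleach[:, None, None]
            * (1.0 + config.sensitivity * voltage))

    if config.stim is not None and config.stim.artifact_amplitude > 0:
        pulse_times = (config.stim.onset_s
                       + np.arange(config.stim.n_pulses) / config.stim.pulse_rate_hz)
        pulse_frames = np.unique(
            np.round(pulse_times * config.frame_rate).astype(int))
        pulse_frames = pulse_frames[(pulse_frames >= 0) & (pulse_frames < n_frames)]
        data[pulse_frames] -= config.stim.artifact_amplitude

    rng = np.random.default_rng(config.seed)
    if config.noise_model == "poisson":
        data = rng.poisson(np.clip(data, 0, None)).astype(float)
        if config.noise_sd > 0:
            data += rng.normal(0.0, config.noise_sd, data.shape)
    elif config.noise_sd > 0:
        data = data + rng.normal(0.0, config.noise_sd, data.shape)

    movie = Movie(data=data, frame_rate=config.frame_rate,
                  pixel_pitch_um=config.pixel_pitch_um, origin="raw")
    table = pd.DataFrame(
        rows, columns=["cluster_id", "center_row", "center_col", "frequency_hz",
                       "amplitude_mv", "phase_rad", "footprint_diameter_um",
                       "n_pixels"])
    return MovieFixture(movie=movie, labels=labels, clusters=table,
                        voltages_mv=volt_traces)


def generate_paired_ephys(cluster: ClusterSpec, sample_rate: float,
                          duration_s: float, noise_sd_mv: float = 0.0,
                          seed: int = 0, stim: StimSpec | None = None,
                          cluster_index: int = 0) -> EphysTrace:
    """Current-clamp-like mV trace sharing a cluster's frequency and phase.

    Sharing the phase function with :func:`generate_sto_movie` guarantees
    that (after downsampling) the trace cross-correlates with the movie's
    cluster trace at zero lag.
    """
    if duration_s <= 0:
        raise ConfigurationError("duration must be > 0; empty traces are not valid")
    if sample_rate < 2 * cluster.frequency_hz:
        raise ConfigurationError(
            f"sample rate {sample_rate} Hz below Nyquist for "
            f"{cluster.frequency_hz} Hz"
        )
    n = int(round(duration_s * sample_rate))
    t = np.arange(n) / sample_rate
    v = _cluster_voltage(cluster, cluster_index, t, stim)
    if noise_sd_mv > 0:
        v = v + np.random.default_rng(seed).normal(0.0, noise_sd_mv, n)
    return EphysTrace(samples=v, sample_rate=sample_rate)


@dataclass(frozen=True)
class CellSpec:
    """A labelled cell rendered on top of the staining field.

    ``ratios`` are (nucleus, cytosol, neuropil) intensity multipliers of
    ``intensity``; the neuropil annulus extends from the soma radius to
    ``neuropil_radius_um``.
    """

    center_um: tuple[float, float]
    intensity: float = 100.0
    nucleus_radius_um: float = 3.5
    soma_radius_um: float = 10.0
    neuropil_radius_um: float = 20.0
    ratios: tuple[float, float, float] = (0.1, 1.0, 0.5)

    def __post_init__(self) -> None:
        if not self.nucleus_radius_um < self.soma_radius_um:
            raise ConfigurationError("nucleus radius must be < soma radius")
        if not self.soma_radius_um <= self.neuropil_radius_um:
            raise ConfigurationError("soma radius must be <= neuropil radius")


@dataclass(frozen=True)
class StainingFieldSpec:
    """A radially decaying dye field with optional compartmentalised cells."""

    frame_size: tuple[int, int] = (256, 256)
    pixel_pitch_um: float = 0.44
    injection_center_um: tuple[float, float] | None = None  # default: frame centre
    profile_shape: str = "gaussian"  # or "gaussian-with-tail"
    half_max_radius_um: float = 84.0
    peak_intensity: float = 1000.0
    tail_fraction: float = 0.15
    tail_scale_um: float = 200.0
    cells: tuple[CellSpec, ...] = ()
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.half_max_radius_um <= 0:
            raise ConfigurationError("half_max_radius_um must be > 0")
        if self.profile_shape not in ("gaussian", "gaussian-with-tail"):
            raise ConfigurationError(
                f"unknown profile shape {self.profile_shape!r}")

    @property
    def center_um(self) -> tuple[float, float]:
        if self.injection_center_um is not None:
            return self.injection_center_um
        return ((self.frame_size[0] - 1) / 2 * self.pixel_pitch_um,
                (self.frame_size[1] - 1) / 2 * self.pixel_pitch_um)


def generate_staining_field(spec: StainingFieldSpec) -> np.ndarray:
    """Render a 2-D staining image whose azimuthal profile has the
    configured half-maximal radius (a Gaussian with sigma = r_half /
    sqrt(2 ln 2), optionally with an exponential tail)."""
    shape = tuple(spec.frame_size)
    yy, xx = np.mgrid[: shape[0], : shape[1]].astype(float)
    yy *= spec.pixel_pitch_um
    xx *= spec.pixel_pitch_um
    cy, cx = spec.center_um
    r = np.hypot(yy - cy, xx - cx)

    sigma = spec.half_max_radius_um / np.sqrt(2 * np.log(2))
    image = spec.peak_intensity * np.exp(-(r**2) / (2 * sigma**2))
    if spec.profile_shape == "gaussian-with-tail":
        image = image + (spec.peak_intensity * spec.tail_fraction
                         * np.exp(-r / spec.tail_scale_um))

    extent_um = ((shape[0] - 1) * spec.pixel_pitch_um,
                 (shape[1] - 1) * spec.pixel_pitch_um)
    for i, cell in enumerate(spec.cells):
        ccy, ccx = cell.center_um
        rad = cell.neuropil_radius_um
        if (ccy - rad < 0 or ccx - rad < 0
                or ccy + rad > extent_um[0] or ccx + rad > extent_um[1]):
            raise ConfigurationError(
                f"cell {i} (centre {cell.center_um} um, outer radius {rad} um) "
                "overlaps the image border"
            )
        rc = np.hypot(yy - ccy, xx - ccx)
        nuc, cyt, npil = cell.ratios
        image = image + cell.intensity * (
            nuc * (rc <= cell.nucleus_radius_um)
            + cyt * ((rc > cell.nucleus_radius_um) & (rc <= cell.soma_radius_um))
            + npil * ((rc > cell.soma_radius_um) & (rc <= cell.neuropil_radius_um))
        )

    if spec.noise_sd > 0:
        image = image + np.random.default_rng(spec.seed).normal(
            0.0, spec.noise_sd, shape)
    return image


def random_scene(seed: int, n_clusters: int = 3,
                 frame_size: tuple[int, int] = (64, 64),
                 frame_rate: float = 40.0, duration_s: float = 5.0,
                 pixel_pitch_um: float = 17.86,
                 frequencies: tuple[float, ...] | None = None,
                 amplitude_mv: float = 6.0, noise_sd: float = 2.0,
                 footprint_diameter_um: float = 110.0,
                 baseline_intensity: float = 1000.0,
                 bleach_tau_s: float = np.inf,
                 stim: StimSpec | None = None) -> SceneConfig:
    """Build a scene with randomly placed, non-overlapping clusters.

    Cluster centres are rejection-sampled so footprints stay inside the
    frame and are separated by at least two footprint radii plus a guard
    band (so density clustering cannot merge them). Frequencies default to
    a random draw in 3.5-10 Hz; phases are uniform.
    """
    rng = np.random.default_rng(seed)
    radius_px = footprint_diameter_um / (2 * pixel_pitch_um)
    margin = int(np.ceil(radius_px)) + 1
    if frame_size[0] - 2 * margin <= 0 or frame_size[1] - 2 * margin <= 0:
        raise ConfigurationError("frame too small for the requested footprint")
    min_sep = 2 * radius_px + 7  # guard band in pixels
    centers: list[tuple[int, int]] = []
    for _ in range(10000):
        if len(centers) == n_clusters:
            break
        cand = (int(rng.integers(margin, frame_size[0] - margin)),
                int(rng.integers(margin, frame_size[1] - margin)))
        if all(np.hypot(cand[0] - c[0], cand[1] - c[1]) >= min_sep
               for c in centers):
            centers.append(cand)
    if len(centers) < n_clusters:
        raise ConfigurationError(
            f"could not place {n_clusters} non-overlapping clusters in a "
            f"{frame_size} frame")
    if frequencies is None:
        freqs = rng.uniform(3.5, 10.0, n_clusters)
    else:
        freqs = [frequencies[i % len(frequencies)] for i in range(n_clusters)]
    clusters = tuple(
        ClusterSpec(center=centers[i], frequency_hz=float(freqs[i]),
                    amplitude_mv=amplitude_mv,
                    footprint_diameter_um=footprint_diameter_um,
                    phase_rad=float(rng.uniform(0, 2 * np.pi)))
        for i in range(n_clusters))
    return SceneConfig(frame_size=frame_size, frame_rate=frame_rate,
                       pixel_pitch_um=pixel_pitch_um, duration_s=duration_s,
                       clusters=clusters, noise_sd=noise_sd,
                       baseline_intensity=baseline_intensity,
                       bleach_tau_s=bleach_tau_s, stim=stim, seed=seed)


def dye_solution_molarity(mass_concentration_ug_per_ml: float,
                          molecular_weight_g_per_mol: float) -> float:
    """Molar concentration in mM from mass concentration and MW.

    ug/ml divided by g/mol is mmol/l directly (ug/ml = mg/l; mg/l over
    g/mol = mmol/l).
    """
    if mass_concentration_ug_per_ml <= 0:
        raise ConfigurationError("mass concentration must be > 0")
    if molecular_weight_g_per_mol <= 0:
        raise ConfigurationError("molecular weight must be > 0")
    return mass_concentration_ug_per_ml / molecular_weight_g_per_mol
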