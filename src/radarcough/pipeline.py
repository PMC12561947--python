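"""Raw IF cube -> log-magnitude range-Doppler map (RDM) sequence.

Stages, in order:

1. range FFT along the ADC-sample axis (per chirp, per antenna);
2. slow-time clutter removal: subtract the per-(antenna, range-bin) mean
   over chirps, nulling static reflectors;
3. primary-bin selection: argmax over range bins of the chirp-averaged
   modulus of the antenna-averaged signal;
4. band extraction: a fixed-width window of range bins centered on the
   primary bin, clamped at the array edges;
5. sliding-window Doppler FFT (window W chirps, step S chirps), centered so
   the zero-velocity column sits at index W//2; targets moving away from
   the radar appear on the positive side;
6. magnitude, average over receive antennas, natural log with an additive
   floor.

At the default geometry (1500 chirps, W=125, S=40, 48-bin band) the output
is a (35, 1, 48, 125) real sequence.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.signal.windows import hann

from .config import PipelineConfig, RadarConfig
from .simulate import RawRadarCube


@dataclass
class RangeProfiles:
    """Complex range profiles, shape (chirps M, antennas R, range bins N)."""

    data: np.ndarray

    def __post_init__(self):
        if self.data.ndim != 3:
            raise ValueError("range profiles must be (chirps, antennas, bins)")


@dataclass
class RDMSequence:
    """Log-magnitude RDM sequence (frames T, 1, range bins B, Doppler bins W)."""

    data: np.ndarray
    primary_bin: int = -1
    frame_times: np.ndarray = field(default_factory=lambda: np.zeros(0))
    subject_id: str = ""
    scene: str = "bed"
    activity_class: str = "breathing"
    label: int = 0
    seed: int | None = None

    @property
    def num_frames(self) -> int:
        return self.data.shape[0]


def range_fft(cube: RawRadarCube) -> RangeProfiles:
    """DFT along fast time: (M, TX, R, N) cube -> (M, R, N) complex profiles.

    Rectangular window, no normalization; the single TX axis is dropped.
    """
    data = cube.data
    if data.ndim != 4:
        raise ValueError(f"expected 4-D cube, got shape {data.shape}")
    if not np.isfinite(data).all():
        raise ValueError("non-finite values in cube")
    profiles = np.fft.fft(data[:, 0, :, :], axis=-1)
    return RangeProfiles(profiles)


def remove_clutter(rp: RangeProfiles) -> RangeProfiles:
    """Subtract the slow-time mean per antenna and range bin.

    Static reflectors (walls, furniture, a motionless torso) contribute a
    chirp-independent component which this removes exactly; every output
    series has zero mean over chirps.
    """
    if not np.isfinite(rp.data).all():
        raise ValueError("non-finite values in range profiles")
    return RangeProfiles(rp.data - rp.data.mean(axis=0, keepdims=True))


def select_primary_bin(rp: RangeProfiles) -> int:
    """Range bin holding the strongest (clutter-removed) reflection.

    The complex signal is averaged over antennas, its modulus averaged over
    chirps, and the argmax over range bins returned; ties break toward the
    lowest index.
    """
    energy = np.abs(rp.data.mean(axis=1)).mean(axis=0)
    if not energy.any():
        raise ValueError("no signal energy in range profiles")
    return int(np.argmax(energy))


def extract_band(rp: RangeProfiles, primary: int, band_width: int) -> np.ndarray:
    """Keep ``band_width`` range bins centered on ``primary``.

    The window [primary - B//2, primary + ceil(B/2)) is shifted (clamped)
    to stay inside [0, N), so exactly B bins are always returned.
    Returns an (M, R, B) complex array.
    """
    n_bins = rp.data.shape[-1]
    if band_width > n_bins:
        raise ValueError(f"band_width {band_width} exceeds {n_bins} range bins")
    if not 0 <= primary < n_bins:
        raise ValueError(f"primary bin {primary} outside [0, {n_bins})")
    lo = primary - band_width // 2
    lo = min(max(lo, 0), n_bins - band_width)
    return rp.data[:, :, lo:lo + band_width]


def band_start(primary: int, band_width: int, n_bins: int) -> int:
    """First range bin of the extracted band (after edge clamping)."""
    lo = primary - band_width // 2
    return min(max(lo, 0), n_bins - band_width)


def count_frames(num_chirps: int, window: int, step: int) -> int:
    """Number of sliding Doppler windows: floor((M - W)/S) + 1."""
    if window > num_chirps:
        raise ValueError(f"window {window} exceeds {num_chirps} chirps")
    if step < 1 or window < 1:
        raise ValueError("window and step must be >= 1")
    return (num_chirps - window) // step + 1


def doppler_frames(band: np.ndarray, window: int, step: int,
                   window_fn: str | None = None) -> np.ndarray:
    """Sliding-window slow-time DFT: (M, R, B) -> (T, R, B, W) complex frames.

    Frame t covers chirps [t*step, t*step + window).  The spectrum is
    centered (zero Doppler at index window//2); positive indices above the
    center correspond to targets moving away from the radar.
    """
    num_chirps = band.shape[0]
    count_frames(num_chirps, window, step)  # validates
    windows = sliding_window_view(band, window, axis=0)[::step]  # (T, R, B, W)
    if window_fn == "hann":
        windows = windows * hann(window, sym=False)
    elif window_fn is not None:
        raise ValueError(f"unknown window_fn {window_fn!r}")
    spectra = np.fft.fft(windows, axis=-1)
    return np.fft.fftshift(spectra, axes=-1)


def to_rdm_sequence(frames: np.ndarray, log_offset: float = 1e-6,
                    **metadata) -> RDMSequence:
    """Magnitude, antenna average and log floor: (T, R, B, W) -> (T, 1, B, W)."""
    if not np.isfinite(frames).all():
        raise ValueError("non-finite values in Doppler frames")
    magnitude = np.abs(frames).mean(axis=1, keepdims=True)
    data = np.log(log_offset + magnitude)
    return RDMSequence(data=data, **metadata)


def preprocess(cube: RawRadarCube,
               pipeline_cfg: PipelineConfig | None = None,
               radar_cfg: RadarConfig | None = None) -> RDMSequence:
    """Full chain from raw cube to RDM sequence."""
    pcfg = pipeline_cfg or PipelineConfig()
    rcfg = radar_cfg or RadarConfig()
    rp = remove_clutter(range_fft(cube))
    try:
        primary = select_primary_bin(rp)
    except ValueError:
        # static/empty scene: keep a centered band of an all-zero signal
        primary = cube.data.shape[-1] // 2
    band = extract_band(rp, primary, pcfg.band_width)
    frames = doppler_frames(band, pcfg.doppler_window, pcfg.doppler_step,
                            pcfg.window_fn)
    n_frames = frames.shape[0]
    frame_times = (np.arange(n_frames) * pcfg.doppler_step
                   + pcfg.doppler_window / 2.0) / rcfg.chirp_rep_frequency
    return to_rdm_sequence(
        frames, log_offset=pcfg.log_offset, primary_bin=primary,
        frame_times=frame_times, subject_id=cube.subject_id, scene=cube.scene,
        activity_class=cube.activity_class, label=cube.label, seed=cube.seed,
    )


def standardize(data: np.ndarray) -> np.ndarray:
    """Zero-mean/unit-variance over a whole sequence (model input scaling).

    A constant sequence (e.g. a static scene at the log floor) maps to zeros.
    """
    mu = data.mean()
    sd = data.std()
    if sd == 0:
        return np.zeros_like(data)
    return (data - mu) / sd
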