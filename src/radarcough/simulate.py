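"""Synthetic FMCW radar scenes with parameterized human motion.

The simulator plays the role of the measurement campaign: it turns a
parameterized motion description (breathing chest excursion, cough
transients, limb movements) into the dechirped complex IF cube a radar
front-end would record, so the full preprocessing/classification stack can
be exercised and tested without access to hardware or private recordings.

Signal model (point scatterers, dechirped):

    s(i, r, n) = sum_k a_k * exp(j * (2*pi * f_b,k(t_i) * n / f_s
                                      + 4*pi * R_k(t_i) / lambda + phi_r))

with beat frequency ``f_b = 2 * slope * R / c``, chirp time
``t_i = i / chirp_rep_frequency``, fixed small per-antenna phase offsets
``phi_r`` and optional circular complex Gaussian noise scaled to a target
SNR.  Increasing range over time means "moving away" and lands on the
positive side of the Doppler axis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.constants import c as SPEED_OF_LIGHT

from .config import DatasetSpec, RadarConfig

#: activity inventory per scene; "cough" is the positive class everywhere.
SCENE_ACTIVITIES = {
    "bed": ("cough", "breathing", "arm_move", "turn_over", "lie_sit"),
    "sitting": ("cough", "breathing", "arm_move", "head_move", "sit_stand"),
}
ALL_ACTIVITIES = ("cough", "breathing", "arm_move", "head_move",
                  "turn_over", "sit_stand", "lie_sit")

#: fixed per-antenna phase offsets [rad]; geometry-free identical copies
ANTENNA_PHASES = np.array([0.0, 0.05, 0.10, 0.15])


@dataclass
class TransientEvent:
    """A smooth displacement transient riding on a scatterer's trajectory.

    Two kinematic shapes share this container:

    * monotonic pulse (``oscillation_frequency = 0``):
      d(t) = A * sin^2(pi * tau), tau = (t - onset)/duration — a limb or
      torso excursion that builds up and returns; peak radial speed
      ``pi*A/duration``.  Used for limb/posture movements, which move far
      (large A) but comparatively slowly.
    * oscillatory jerk (``oscillation_frequency = f > 0``):
      d(t) = A * sin(2*pi*f*(t-onset)) * sin^2(pi*tau) — the chest wall
      during a cough: several rapid back-and-forth cycles under a smooth
      envelope.  Displacement stays small (centimeters) while the peak
      radial speed ``~2*pi*f*A`` reaches the 0.3-1 m/s range, producing the
      short broadband micro-Doppler stripe characteristic of coughs.
    """

    onset: float                       # s
    duration: float                    # s
    peak_displacement: float           # m (signed; positive = away from radar)
    oscillation_frequency: float = 0.0  # Hz; 0 = monotonic pulse

    def displacement(self, t: np.ndarray) -> np.ndarray:
        tau = (t - self.onset) / self.duration
        active = (tau >= 0.0) & (tau <= 1.0)
        envelope = np.sin(np.pi * np.clip(tau, 0.0, 1.0)) ** 2
        if self.oscillation_frequency > 0:
            carrier = np.sin(
                2.0 * np.pi * self.oscillation_frequency * (t - self.onset))
            return np.where(active, self.peak_displacement * carrier * envelope,
                            0.0)
        return np.where(active, self.peak_displacement * envelope, 0.0)

    @property
    def peak_speed(self) -> float:
        if self.oscillation_frequency > 0:
            return abs(self.peak_displacement) * 2.0 * np.pi * \
                self.oscillation_frequency
        return abs(self.peak_displacement) * np.pi / self.duration


@dataclass
class Scatterer:
    base_range: float              # m
    amplitude: float = 1.0         # linear gain
    breathing_amplitude: float = 0.0   # m chest excursion
    breathing_frequency: float = 0.0   # Hz
    breathing_phase: float = 0.0       # rad
    radial_velocity: float = 0.0       # m/s, positive = away
    transient_events: list[TransientEvent] = field(default_factory=list)

    def trajectory(self, t: np.ndarray) -> np.ndarray:
        rng = self.base_range + self.radial_velocity * t
        if self.breathing_amplitude:
            rng = rng + self.breathing_amplitude * np.sin(
                2.0 * np.pi * self.breathing_frequency * t + self.breathing_phase
            )
        for ev in self.transient_events:
            rng = rng + ev.displacement(t)
        return rng


@dataclass
class MotionProfile:
    scatterers: list[Scatterer]
    activity_class: str
    scene: str

    @property
    def label(self) -> int:
        """1 for cough, 0 otherwise."""
        return int(self.activity_class == "cough")

    @property
    def transient_events(self):
        return [ev for sc in self.scatterers for ev in sc.transient_events]


@dataclass
class RawRadarCube:
    """One 3 s recording: complex IF data (chirps, TX, RX, ADC samples)."""

    data: np.ndarray
    subject_id: str = ""
    scene: str = "bed"
    activity_class: str = "breathing"
    label: int = 0
    seed: int | None = None


@dataclass
class ManifestRecord:
    sample_id: str
    subject_id: str
    scene: str
    activity_class: str
    label: int
    seed: int
    path: str = ""


@dataclass
class DatasetManifest:
    records: list[ManifestRecord]
    master_seed: int = 0

    def __post_init__(self):
        ids = [r.sample_id for r in self.records]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate sample_ids in manifest")

    def __len__(self):
        return len(self.records)

    def subjects(self) -> list[str]:
        return sorted({r.subject_id for r in self.records})

    def filter(self, **conditions) -> "DatasetManifest":
        recs = [
            r for r in self.records
            if all(getattr(r, k) == v for k, v in conditions.items())
        ]
        return DatasetManifest(recs, master_seed=self.master_seed)


# ---------------------------------------------------------------------------
# motion sampling
# ---------------------------------------------------------------------------

#: documented parameter ranges for each activity; all tunable per call.
#: Coughs are short chest transients on top of breathing; limb/posture
#: movements are longer and larger so classes are separable yet overlapping.
MOTION_RANGES = {
    "breathing_amplitude": (0.003, 0.008),   # m chest excursion
    "breathing_frequency": (0.2, 0.4),       # Hz
    "torso_amplitude": (0.8, 1.2),           # linear gain
    "limb_amplitude": (0.3, 0.8),
    "cough_speed": (0.3, 1.0),               # m/s peak radial speed
    "cough_duration": (0.3, 0.6),            # s
    "cough_oscillation": (3.0, 8.0),         # Hz chest-wall jerk rate
    "arm_move_speed": (0.2, 0.6),
    "arm_move_duration": (0.8, 2.0),
    "head_move_speed": (0.1, 0.3),
    "head_move_duration": (0.5, 1.5),
    "turn_over_speed": (0.3, 0.7),
    "turn_over_duration": (1.0, 2.0),
    "posture_speed": (0.4, 0.8),             # sit_stand / lie_sit
    "posture_duration": (0.8, 1.5),
    "bed_range": (0.7, 1.3),                 # m subject distance, bed scene
    "sitting_range": (0.9, 1.6),             # m, sitting scene
}


@dataclass
class SubjectTraits:
    """Per-subject habits that individualize recordings."""

    range_center: float
    breathing_frequency: float
    breathing_amplitude: float

    @classmethod
    def sample(cls, scene: str, rng: np.random.Generator,
               ranges: dict = MOTION_RANGES) -> "SubjectTraits":
        key = "bed_range" if scene == "bed" else "sitting_range"
        return cls(
            range_center=rng.uniform(*ranges[key]),
            breathing_frequency=rng.uniform(*ranges["breathing_frequency"]),
            breathing_amplitude=rng.uniform(*ranges["breathing_amplitude"]),
        )


def _transient(rng, speed_range, dur_range, duration_total=3.0, margin=0.2,
               oscillation_range=None):
    dur = rng.uniform(*dur_range)
    dur = min(dur, duration_total - 2 * margin)
    onset = rng.uniform(margin, duration_total - dur - margin)
    speed = rng.uniform(*speed_range)
    sign = rng.choice([-1.0, 1.0])
    if oscillation_range is not None:
        f_osc = rng.uniform(*oscillation_range)
        # oscillatory jerk: amplitude set so the peak speed matches the draw
        return TransientEvent(onset, dur, sign * speed / (2.0 * np.pi * f_osc),
                              oscillation_frequency=f_osc)
    return TransientEvent(onset, dur, sign * speed * dur / np.pi)


def sample_motion_profile(activity_class: str, scene: str,
                          rng: np.random.Generator,
                          traits: SubjectTraits | None = None,
                          ranges: dict = MOTION_RANGES,
                          duration: float = 3.0) -> MotionProfile:
    """Draw a randomized motion profile for one recording.

    Deterministic given the generator state.  Cough profiles always carry at
    least one short high-speed chest transient superimposed on breathing.
    """
    if scene not in SCENE_ACTIVITIES:
        raise ValueError(f"unknown scene {scene!r}")
    if activity_class not in SCENE_ACTIVITIES[scene]:
        raise ValueError(
            f"unknown activity class {activity_class!r} for scene {scene!r}; "
            f"valid: {SCENE_ACTIVITIES[scene]}"
        )
    if traits is None:
        traits = SubjectTraits.sample(scene, rng, ranges)

    torso = Scatterer(
        base_range=traits.range_center + rng.uniform(-0.05, 0.05),
        amplitude=rng.uniform(*ranges["torso_amplitude"]),
        breathing_amplitude=traits.breathing_amplitude * rng.uniform(0.8, 1.2),
        breathing_frequency=traits.breathing_frequency * rng.uniform(0.9, 1.1),
        breathing_phase=rng.uniform(0.0, 2.0 * np.pi),
    )
    scatterers = [torso]

    if activity_class == "cough":
        for _ in range(rng.integers(1, 3)):
            torso.transient_events.append(
                _transient(rng, ranges["cough_speed"], ranges["cough_duration"],
                           duration,
                           oscillation_range=ranges["cough_oscillation"])
            )
    elif activity_class in ("arm_move", "head_move"):
        limb = Scatterer(
            base_range=torso.base_range + rng.uniform(-0.25, 0.25),
            amplitude=rng.uniform(*ranges["limb_amplitude"]),
        )
        limb.transient_events.append(
            _transient(rng, ranges[f"{activity_class}_speed"],
                       ranges[f"{activity_class}_duration"], duration)
        )
        scatterers.append(limb)
    elif activity_class == "turn_over":
        torso.transient_events.append(
            _transient(rng, ranges["turn_over_speed"],
                       ranges["turn_over_duration"], duration)
        )
        limb = Scatterer(
            base_range=torso.base_range + rng.uniform(-0.2, 0.2),
            amplitude=rng.uniform(*ranges["limb_amplitude"]),
        )
        limb.transient_events.append(
            _transient(rng, ranges["turn_over_speed"],
                       ranges["turn_over_duration"], duration)
        )
        scatterers.append(limb)
    elif activity_class in ("sit_stand", "lie_sit"):
        torso.transient_events.append(
            _transient(rng, ranges["posture_speed"],
                       ranges["posture_duration"], duration)
        )
    # "breathing": torso only, no transients

    return MotionProfile(scatterers=scatterers, activity_class=activity_class,
                         scene=scene)


# ---------------------------------------------------------------------------
# cube synthesis
# ---------------------------------------------------------------------------

def synthesize_cube(profile: MotionProfile, cfg: RadarConfig | None = None,
                    snr_db: float | None = None,
                    rng: np.random.Generator | int | None = None,
                    subject_id: str = "") -> RawRadarCube:
    """Render a motion profile into a complex IF data cube.

    ``snr_db=None`` produces a noiseless cube; otherwise circular complex
    Gaussian noise is added per antenna with power set from the realized
    mean signal power, so the SNR matches ``snr_db`` in expectation.
    """
    cfg = cfg or RadarConfig()
    seed = None
    if isinstance(rng, (int, np.integer)):
        seed = int(rng)
        rng = np.random.default_rng(seed)
    elif rng is None:
        rng = np.random.default_rng(0)

    M, N, R = cfg.num_chirps, cfg.num_adc_samples, cfg.num_rx
    t = np.arange(M) / cfg.chirp_rep_frequency
    n = np.arange(N)

    base = np.zeros((M, N), dtype=np.complex128)
    for sc in profile.scatterers:
        if not np.isfinite([sc.base_range, sc.amplitude, sc.radial_velocity,
                            sc.breathing_amplitude]).all():
            raise ValueError("non-finite scatterer parameters")
        traj = sc.trajectory(t)
        if traj.min() <= 0 or traj.max() >= cfg.max_unambiguous_range:
            raise ValueError(
                f"scatterer trajectory [{traj.min():.2f}, {traj.max():.2f}] m "
                f"leaves the unambiguous range (0, {cfg.max_unambiguous_range:.2f}) m"
            )
        beat = 2.0 * cfg.slope * traj / SPEED_OF_LIGHT           # (M,)
        phase = (
            2.0 * np.pi * np.outer(beat, n / cfg.sample_rate)
            + (4.0 * np.pi * traj / cfg.wavelength)[:, None]
        )
        base += sc.amplitude * np.exp(1j * phase)

    phases = ANTENNA_PHASES[:R] if R <= len(ANTENNA_PHASES) else np.linspace(
        0.0, 0.05 * (R - 1), R
    )
    data = base[:, None, None, :] * np.exp(1j * phases)[None, None, :, None]
    data = np.ascontiguousarray(np.broadcast_to(data, (M, cfg.num_tx, R, N)))

    if snr_db is not None:
        if not np.isfinite(snr_db):
            raise ValueError("snr_db must be finite or None")
        p_signal = float(np.mean(np.abs(base) ** 2))
        if p_signal > 0:
            p_noise = p_signal / 10.0 ** (snr_db / 10.0)
            sigma = np.sqrt(p_noise / 2.0)
            noise = rng.normal(scale=sigma, size=(M, cfg.num_tx, R, N, 2))
            data = data + noise[..., 0] + 1j * noise[..., 1]

    return RawRadarCube(
        data=data, subject_id=subject_id, scene=profile.scene,
        activity_class=profile.activity_class, label=profile.label, seed=seed,
    )


# ---------------------------------------------------------------------------
# dataset generation
# ---------------------------------------------------------------------------

def _record_seed(master_seed: int, subject_index: int, sample_index: int) -> int:
    """Stable per-record seed derived from the master seed (stored for replay)."""
    ss = np.random.SeedSequence([master_seed, subject_index, sample_index])
    return int(ss.generate_state(1)[0])


def _noncough_activity(scene: str, index: int) -> str:
    inventory = [a for a in SCENE_ACTIVITIES[scene] if a != "cough"]
    return inventory[index % len(inventory)]


def generate_manifest(spec: DatasetSpec | None = None) -> DatasetManifest:
    """Enumerate every recording of the dataset (no signal synthesis).

    Non-cough recordings cycle through the scene's non-cough inventory so
    the class composition matches the requested counts exactly and the
    activity mix is balanced.
    """
    spec = spec or DatasetSpec()
    records: list[ManifestRecord] = []
    scene_counts = {
        "bed": (spec.bed_cough, spec.bed_noncough),
        "sitting": (spec.sitting_cough, spec.sitting_noncough),
    }
    for s_idx in range(spec.num_subjects):
        subject_id = f"S{s_idx + 1:02d}"
        sample_index = 0
        for scene, (n_cough, n_non) in scene_counts.items():
            plan = ["cough"] * n_cough + [
                _noncough_activity(scene, i) for i in range(n_non)
            ]
            for activity in plan:
                seed = _record_seed(spec.master_seed, s_idx, sample_index)
                records.append(ManifestRecord(
                    sample_id=f"{subject_id}_{scene}_{sample_index:04d}",
                    subject_id=subject_id,
                    scene=scene,
                    activity_class=activity,
                    label=int(activity == "cough"),
                    seed=seed,
                ))
                sample_index += 1
    return DatasetManifest(records, master_seed=spec.master_seed)


def subject_traits_for(subject_id: str, scene: str, master_seed: int,
                       ranges: dict = MOTION_RANGES) -> SubjectTraits:
    """Deterministic per-subject traits shared by all of a subject's recordings."""
    idx = int(subject_id.lstrip("S"))
    ss = np.random.SeedSequence([master_seed, 10_000 + idx,
                                 0 if scene == "bed" else 1])
    return SubjectTraits.sample(scene, np.random.default_rng(ss), ranges)


def cube_for_record(record: ManifestRecord, spec: DatasetSpec,
                    cfg: RadarConfig | None = None,
                    ranges: dict = MOTION_RANGES) -> RawRadarCube:
    """Re-synthesize one recording from its stored seed (exact replay)."""
    cfg = cfg or RadarConfig()
    rng = np.random.default_rng(record.seed)
    traits = subject_traits_for(record.subject_id, record.scene,
                                spec.master_seed, ranges)
    profile = sample_motion_profile(record.activity_class, record.scene, rng,
                                    traits=traits, ranges=ranges,
                                    duration=cfg.recording_duration)
    cube = synthesize_cube(profile, cfg, snr_db=spec.snr_db, rng=rng,
                           subject_id=record.subject_id)
    cube.seed = record.seed
    return cube


def generate_dataset(spec: DatasetSpec | None = None,
                     cfg: RadarConfig | None = None,
                     store_path=None) -> DatasetManifest:
    """Build the manifest and materialize cubes.

    With ``store_path`` the cubes are written to an HDF5 store and the
    manifest records carry the storage path; without it the manifest alone
    is returned and cubes are re-synthesized on demand from their stored
    seeds via :func:`cube_for_record` (bit-identical replay).
    """
    spec = spec or DatasetSpec()
    cfg = cfg or RadarConfig()
    manifest = generate_manifest(spec)
    if store_path is not None:
        from .io_h5 import write_cube_store

        cubes = (cube_for_record(rec, spec, cfg) for rec in manifest.records)
        write_cube_store(store_path, zip(manifest.records, cubes), cfg)
        for rec in manifest.records:
            rec.path = str(store_path)
    return manifest
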