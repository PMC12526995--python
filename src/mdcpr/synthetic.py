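"""Synthetic chest-compression kinematics and FMCW radar returns.

Emulates a mannequin CPR measurement campaign: subjects compress at target
depths of 3-6 cm and rates of 90-110 compressions per minute (CPM) while a
77 GHz FMCW radar observes the chest from one of three positions (above the
chest, at the side, near the head).  Two synthesis paths are provided:

* a fast *phase-level* path that writes the slow-time baseband sequence
  ``exp(+j 4 pi r(t) / lambda)`` directly, and
* a *chirp-level* path that synthesises the de-chirped IF signal of every
  chirp and recovers the slow-time sequence by range processing.

Compression of the chest moves it away from a radar placed above it, so
increasing radial displacement maps to positive Doppler frequency.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .radar import SPEED_OF_LIGHT, RadarConfig

DEFAULT_CASE_ANGLES_DEG = {1: 0.0, 2: 30.0, 3: 45.0}

# Between-subject / between-cycle variability of guided mannequin CPR.
DEFAULT_DEPTH_BIAS_SD_CM = 0.2
DEFAULT_DEPTH_JITTER_SD_CM = 0.15
DEFAULT_RATE_JITTER_SD_CPM = 2.0


@dataclass(frozen=True)
class SubjectProfile:
    """Per-subject deviation from the instructed compression pattern."""

    depth_bias_cm: float = 0.0
    depth_jitter_sd_cm: float = DEFAULT_DEPTH_JITTER_SD_CM
    rate_jitter_sd_cpm: float = DEFAULT_RATE_JITTER_SD_CPM


@dataclass(frozen=True)
class CompressionScenario:
    """One measurement condition of the campaign."""

    target_depth_cm: float = 5.0
    rate_cpm: float = 100.0
    duration_s: float = 30.0
    aspect_angle_deg: float = 0.0
    subject_profile: SubjectProfile = field(default_factory=SubjectProfile)
    noise_snr_db: float | None = 20.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.target_depth_cm < 0:
            raise ValueError("target depth must be non-negative")
        if self.rate_cpm <= 0:
            raise ValueError("compression rate must be positive")
        if self.duration_s <= 0:
            raise ValueError("duration must be positive")
        if not 0.0 <= self.aspect_angle_deg < 90.0:
            raise ValueError("aspect angle must lie in [0, 90) degrees")


@dataclass
class KinematicsTrace:
    """Chest displacement sampled on the radar's slow-time grid.

    ``displacement_m`` is 0 at rest and positive while compressed;
    ``per_cycle_truth`` records one row per complete compression with the
    achieved (chest-frame) depth.
    """

    time_s: np.ndarray
    displacement_m: np.ndarray
    velocity_m_s: np.ndarray
    per_cycle_truth: pd.DataFrame
    prf_hz: float
    aspect_angle_deg: float = 0.0

    def __len__(self) -> int:
        return len(self.time_s)


@dataclass
class SlowTimeSignal:
    """Uniformly sampled complex baseband sequence across radar frames."""

    samples: np.ndarray
    prf_hz: float
    wavelength_m: float
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=complex)
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("slow-time samples must be finite")

    def __len__(self) -> int:
        return len(self.samples)

    @property
    def time_s(self) -> np.ndarray:
        return np.arange(len(self.samples)) / self.prf_hz


@dataclass
class IFDataCube:
    """De-chirped IF samples arranged fast-time x chirp x frame."""

    samples: np.ndarray  # (samples_per_chirp, chirps_per_frame, n_frames)
    config: RadarConfig
    standoff_range_m: float


def simulate_kinematics(
    scenario: CompressionScenario, config: RadarConfig
) -> KinematicsTrace:
    """Generate a raised-sine compression displacement trace.

    Each cycle k lasts ``60 / rate_k`` seconds and follows
    ``d(t') = D_k sin^2(pi t' / T_c)``: smooth, zero displacement and zero
    velocity at the cycle boundaries, one downstroke and one upstroke lobe.
    ``D_k`` is the target depth plus the subject's bias plus per-cycle
    jitter; ``rate_k`` adds per-cycle rate jitter.  Deterministic for a
    given ``scenario.rng_seed``.
    """
    prf = config.prf_hz
    lam = config.wavelength_m
    prof = scenario.subject_profile
    rng = np.random.default_rng(scenario.rng_seed)

    depth_m = scenario.target_depth_cm * 1e-2
    nominal_period = 60.0 / scenario.rate_cpm
    # Aliasing guard: peak Doppler of the raised sine is 2 v_peak / lambda
    # with v_peak = pi D / T_c.
    d_max = depth_m + abs(prof.depth_bias_cm) * 1e-2 + 4 * prof.depth_jitter_sd_cm * 1e-2
    peak_doppler = 2.0 * np.pi * d_max / nominal_period / lam
    if depth_m > 0 and prf < 4.0 * peak_doppler:
        raise ValueError(
            f"PRF {prf:.0f} Hz below 4x expected peak Doppler {peak_doppler:.0f} Hz: "
            "the compression signature would alias"
        )

    n = int(np.floor(scenario.duration_s * prf))
    time_s = np.arange(n) / prf
    disp = np.zeros(n)
    vel = np.zeros(n)
    rows = []

    if depth_m == 0.0:
        truth = pd.DataFrame(
            columns=["cycle", "start_s", "end_s", "depth_cm", "rate_cpm"]
        )
        return KinematicsTrace(time_s, disp, vel, truth, prf)

    t_start = 0.0
    k = 0
    while t_start < scenario.duration_s:
        rate_k = scenario.rate_cpm + rng.normal(0.0, prof.rate_jitter_sd_cpm)
        rate_k = max(rate_k, 1e-3)
        period_k = 60.0 / rate_k
        d_k = depth_m + (prof.depth_bias_cm + rng.normal(0.0, prof.depth_jitter_sd_cm)) * 1e-2
        d_k = max(d_k, 0.0)
        t_end = t_start + period_k
        i0 = int(np.ceil(t_start * prf - 1e-9))
        i1 = min(int(np.floor(t_end * prf)), n - 1)
        if i0 <= i1:
            local = time_s[i0 : i1 + 1] - t_start
            disp[i0 : i1 + 1] = d_k * np.sin(np.pi * local / period_k) ** 2
            vel[i0 : i1 + 1] = (
                d_k * np.pi / period_k * np.sin(2 * np.pi * local / period_k)
            )
        if t_end <= scenario.duration_s + 1e-9:
            rows.append(
                {
                    "cycle": k,
                    "start_s": t_start,
                    "end_s": t_end,
                    "depth_cm": d_k * 1e2,
                    "rate_cpm": rate_k,
                }
            )
        t_start = t_end
        k += 1

    truth = pd.DataFrame(rows, columns=["cycle", "start_s", "end_s", "depth_cm", "rate_cpm"])
    return KinematicsTrace(time_s, disp, vel, truth, prf)


def project_radial(trace: KinematicsTrace, aspect_angle_deg: float) -> KinematicsTrace:
    """Project chest displacement onto the radar line of sight.

    The radar measures only the radial component ``r(t) = d(t) cos(theta)``;
    ``per_cycle_truth`` keeps the chest-frame depth (the quantity estimators
    are judged against after angle compensation).
    """
    if not 0.0 <= aspect_angle_deg < 90.0:
        raise ValueError("aspect angle must lie in [0, 90) degrees")
    c = np.cos(np.deg2rad(aspect_angle_deg))
    return KinematicsTrace(
        time_s=trace.time_s,
        displacement_m=trace.displacement_m * c,
        velocity_m_s=trace.velocity_m_s * c,
        per_cycle_truth=trace.per_cycle_truth.copy(),
        prf_hz=trace.prf_hz,
        aspect_angle_deg=aspect_angle_deg,
    )


def phase_synthesize(
    trace: KinematicsTrace,
    config: RadarConfig,
    noise_snr_db: float | None = None,
    seed: int = 0,
    wavelength_m: float | None = None,
) -> SlowTimeSignal:
    """Synthesize the slow-time baseband sequence from a displacement trace.

    ``samples[n] = exp(+j 4 pi r(t_n) / lambda)``: motion away from the
    radar (increasing r) produces positive instantaneous Doppler under the
    ``e^{-j 2 pi f t}`` analysis convention.  Complex white Gaussian noise
    is added at ``noise_snr_db`` relative to the unit-modulus signal power.
    """
    lam = config.wavelength_m if wavelength_m is None else wavelength_m
    phase = 4.0 * np.pi * trace.displacement_m / lam
    samples = np.exp(1j * phase)
    if noise_snr_db is not None:
        rng = np.random.default_rng(seed)
        noise_power = 10.0 ** (-noise_snr_db / 10.0)
        sigma = np.sqrt(noise_power / 2.0)
        samples = samples + sigma * (
            rng.standard_normal(len(samples)) + 1j * rng.standard_normal(len(samples))
        )
    return SlowTimeSignal(
        samples=samples,
        prf_hz=trace.prf_hz,
        wavelength_m=lam,
        provenance={"path": "phase", "seed": seed, "noise_snr_db": noise_snr_db},
    )


def chirp_level_synthesize(
    trace: KinematicsTrace,
    config: RadarConfig,
    standoff_range_m: float,
    noise_snr_db: float | None = None,
    seed: int = 0,
) -> IFDataCube:
    """Synthesize the de-chirped IF data cube chirp by chirp.

    Each chirp's IF samples follow
    ``A cos(2 pi (Sw tau t + fc tau - Sw tau^2 / 2))`` with round-trip delay
    ``tau = 2 (R + r(t_frame)) / c`` evaluated at the frame's slow time
    (compression moves the chest away from the radar, lengthening the path).
    """
    if not 0.0 < standoff_range_m <= config.max_unambiguous_range_m:
        raise ValueError(
            f"standoff {standoff_range_m} m outside the unambiguous range "
            f"(0, {config.max_unambiguous_range_m:.2f}] m"
        )
    n_frames = len(trace)
    n_fast = config.samples_per_chirp
    sw = config.frequency_slope_hz_s
    fc = config.carrier_frequency_hz
    amp = config.tx_amplitude * config.rx_amplitude / 2.0

    t_fast = np.arange(n_fast) / config.fast_time_sample_rate_hz  # (N,)
    tau = 2.0 * (standoff_range_m + trace.displacement_m) / SPEED_OF_LIGHT  # (F,)
    # phase(t; tau) = 2 pi (Sw tau t + fc tau - Sw tau^2 / 2)
    phase = 2.0 * np.pi * (
        sw * tau[None, :] * t_fast[:, None]
        + fc * tau[None, :]
        - 0.5 * sw * tau[None, :] ** 2
    )
    chirp0 = amp * np.cos(phase)  # (N, F)
    cube = np.repeat(chirp0[:, None, :], config.chirps_per_frame, axis=1)
    if noise_snr_db is not None:
        rng = np.random.default_rng(seed)
        p_sig = float(np.mean(chirp0**2))
        sigma = np.sqrt(p_sig * 10.0 ** (-noise_snr_db / 10.0))
        cube = cube + sigma * rng.standard_normal(cube.shape)
    return IFDataCube(samples=cube, config=config, standoff_range_m=standoff_range_m)


def range_process(cube: IFDataCube) -> SlowTimeSignal:
    """Range-compress each frame and extract the target bin's slow-time phase.

    Chirp 0 of each frame is Hann-windowed and FFT'd over fast time; the
    modal magnitude-peak bin across frames is selected and its complex value
    tracked over frames.  A warning is emitted if the per-frame peak wanders
    by more than one bin between consecutive frames.

    The returned signal's ``wavelength_m`` is the wavelength at the
    effective phase-reference frequency ``fc + Sw (N-1) / (2 fs)`` (the
    chirp-centre frequency for a symmetric window): the phase of a range
    bin advances at that frequency, not at the carrier.
    """
    config = cube.config
    n_fast = config.samples_per_chirp
    x = cube.samples[:, 0, :]  # (N, F) chirp 0
    window = np.hanning(n_fast)
    spectra = np.fft.fft(x * window[:, None], axis=0)  # (N, F)
    half = spectra[1 : n_fast // 2, :]
    peaks = np.argmax(np.abs(half), axis=0) + 1  # per-frame peak bin
    if np.any(np.abs(np.diff(peaks)) > 1):
        warnings.warn(
            "range peak bin wanders by more than one bin between frames; "
            "target may be absent or moving across bins",
            stacklevel=2,
        )
    bins, counts = np.unique(peaks, return_counts=True)
    target_bin = int(bins[np.argmax(counts)])
    slow = spectra[target_bin, :]

    f_eff = config.carrier_frequency_hz + config.frequency_slope_hz_s * (
        n_fast - 1
    ) / (2.0 * config.fast_time_sample_rate_hz)
    return SlowTimeSignal(
        samples=slow,
        prf_hz=config.prf_hz,
        wavelength_m=SPEED_OF_LIGHT / f_eff,
        provenance={"path": "chirp", "range_bin": target_bin},
    )


def subject_profiles(
    n_subjects: int,
    seed: int,
    depth_bias_sd_cm: float = DEFAULT_DEPTH_BIAS_SD_CM,
    depth_jitter_sd_cm: float = DEFAULT_DEPTH_JITTER_SD_CM,
    rate_jitter_sd_cpm: float = DEFAULT_RATE_JITTER_SD_CPM,
) -> list[SubjectProfile]:
    """Draw one variability profile per subject (bias ~ N(0, 0.2 cm))."""
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(0,)))
    return [
        SubjectProfile(
            depth_bias_cm=float(rng.normal(0.0, depth_bias_sd_cm)),
            depth_jitter_sd_cm=depth_jitter_sd_cm,
            rate_jitter_sd_cpm=rate_jitter_sd_cpm,
        )
        for _ in range(n_subjects)
    ]


def generate_campaign(
    config: RadarConfig,
    subjects: int = 8,
    cases: dict[int, float] | None = None,
    depths_cm: tuple[float, ...] = (3.0, 4.0, 5.0, 6.0),
    rates_cpm: tuple[float, ...] = (90.0, 100.0, 110.0),
    seed: int = 0,
    duration_s: float = 30.0,
    noise_snr_db: float | None = 20.0,
) -> pd.DataFrame:
    """Build the manifest of a full measurement campaign.

    The cross product subjects x cases x depths x rates, each condition
    30 s by default, with per-subject variability profiles drawn once per
    subject.  Signals are not materialised here; use :func:`record_signal`
    (deterministic per row) or :func:`write_campaign` to store them.
    """
    if cases is None:
        cases = dict(DEFAULT_CASE_ANGLES_DEG)
    if not cases or not depths_cm or not rates_cpm or subjects < 1:
        raise ValueError("subjects, cases, depths and rates must be non-empty")
    profiles = subject_profiles(subjects, seed)
    rows = []
    rec = 0
    for s in range(subjects):
        prof = profiles[s]
        for case_id, angle in sorted(cases.items()):
            for depth in depths_cm:
                for rate in rates_cpm:
                    rows.append(
                        {
                            "record": rec,
                            "subject": s,
                            "case": case_id,
                            "angle_deg": float(angle),
                            "depth_cm": float(depth),
                            "rate_cpm": float(rate),
                            "duration_s": float(duration_s),
                            "noise_snr_db": noise_snr_db,
                            "depth_bias_cm": prof.depth_bias_cm,
                            "depth_jitter_sd_cm": prof.depth_jitter_sd_cm,
                            "rate_jitter_sd_cpm": prof.rate_jitter_sd_cpm,
                            "seed": int(
                                np.random.SeedSequence(seed, spawn_key=(1, rec)).generate_state(1)[0]
                                % (2**31)
                            ),
                        }
                    )
                    rec += 1
    return pd.DataFrame(rows)


def record_scenario(row: pd.Series) -> CompressionScenario:
    """Reconstruct the scenario of one manifest row."""
    snr = row["noise_snr_db"]
    if pd.isna(snr):
        snr = None
    return CompressionScenario(
        target_depth_cm=row["depth_cm"],
        rate_cpm=row["rate_cpm"],
        duration_s=row["duration_s"],
        aspect_angle_deg=row["angle_deg"],
        subject_profile=SubjectProfile(
            depth_bias_cm=row["depth_bias_cm"],
            depth_jitter_sd_cm=row["depth_jitter_sd_cm"],
            rate_jitter_sd_cpm=row["rate_jitter_sd_cpm"],
        ),
        noise_snr_db=snr,
        rng_seed=int(row["seed"]),
    )


def record_signal(
    row: pd.Series, config: RadarConfig
) -> tuple[SlowTimeSignal, KinematicsTrace]:
    """Deterministically synthesize one manifest row's radar signal.

    Returns the phase-level slow-time signal (noise per the manifest) and
    the underlying chest-frame kinematics with per-cycle ground truth.
    """
    scenario = record_scenario(row)
    trace = simulate_kinematics(scenario, config)
    radial = project_radial(trace, scenario.aspect_angle_deg)
    signal = phase_synthesize(
        radial, config, noise_snr_db=scenario.noise_snr_db, seed=scenario.rng_seed
    )
    signal.provenance.update(
        {"record": int(row["record"]), "subject": int(row["subject"]), "case": int(row["case"])}
    )
    return signal, trace
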