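"""Synthetic stepping-session generator with known ground truth.

Emulates the statistical structure the analysis pipeline assumes: deep-brain
LFP contacts carrying band-limited oscillations whose amplitude is locked to
the gait phase, superposed on 1/f background noise and a common-mode
component shared across contacts; per-foot force-plate traces alternating
between feet with a half-cycle offset; and triaxial trunk-accelerometer
traces with one identifiable extremum per cycle.

The generator's point is controllability, not biomechanical realism: every
session carries its exact per-sample gait phase and per-cycle anchor table,
so downstream estimates (phase reconstruction, modulograms, modulation
indices, state occupancies) can be scored against ground truth.

Amplitude model per LFP contact and configured band::

    x_band(t) = osc(t) * (1 + depth * cos(phase(t) - preferred_phase))

with ``osc`` a unit-RMS band-limited noise carrier independent across
contacts.  Depth 0 therefore yields phase-constant band power and a
modulation index of ~0 downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import h5py
import numpy as np
import yaml
from scipy.signal import butter, sosfiltfilt

from .gaitphase import GaitCycleTable, PhaseSeries, _phase_from_cycles, wrap_phase
from .recording import Recording, save_recording, load_recording

__all__ = ["SessionConfig", "SyntheticSession", "generate_session",
           "save_session", "load_session"]

#: default gait-phase-locked bands: (f_low Hz, f_high Hz, depth, preferred phase rad)
DEFAULT_MODULATION_BANDS = ((8.0, 12.0, 0.4, 0.0), (13.0, 30.0, 0.4, 0.0))


@dataclass
class SessionConfig:
    """Parameters of one synthetic stepping session (one hemisphere).

    ``modulation_bands`` lists ``(f_low, f_high, depth, preferred_phase)``
    tuples; ``depth`` in [0, 1] scales the amplitude swing over the gait
    cycle and ``preferred_phase`` (radians in [-pi, pi)) is the gait phase of
    maximal amplitude.  Per-cycle durations are ``cycle_period_s`` plus
    Gaussian jitter (SD ``cycle_jitter_sd_s``), truncated to more than half
    the nominal period.
    """

    duration_s: float = 120.0
    fs: float = 2048.0
    cycle_period_s: float = 2.0
    cycle_jitter_sd_s: float = 0.05
    n_lfp_contacts: int = 4
    modulation_bands: tuple = DEFAULT_MODULATION_BANDS
    noise_exponent: float = 1.0
    common_mode_gain: float = 1.0
    osc_amplitude: float = 1.0
    noise_amplitude: float = 1.0
    sensor_noise_sd: float = 0.02
    cortical_gain: float = 0.3
    cortical_delay_s: float = 0.025
    seed: int = 0

    def validate(self) -> None:
        if self.fs <= 0:
            raise ValueError(f"fs must be positive, got fs={self.fs}")
        if self.duration_s <= 2 * self.cycle_period_s:
            raise ValueError(
                "duration_s must exceed two cycle periods, got "
                f"duration_s={self.duration_s}"
            )
        if self.cycle_period_s <= 0:
            raise ValueError(
                f"cycle_period_s must be positive, got cycle_period_s={self.cycle_period_s}"
            )
        if self.cycle_jitter_sd_s < 0:
            raise ValueError(
                f"cycle_jitter_sd_s must be >= 0, got cycle_jitter_sd_s={self.cycle_jitter_sd_s}"
            )
        if self.n_lfp_contacts < 2:
            raise ValueError(
                f"n_lfp_contacts must be >= 2, got n_lfp_contacts={self.n_lfp_contacts}"
            )
        for band in self.modulation_bands:
            lo, hi, depth, phi0 = band
            if not 0 < lo < hi < self.fs / 2:
                raise ValueError(
                    f"modulation_bands: band edges ({lo}, {hi}) must satisfy "
                    f"0 < low < high < fs/2"
                )
            if not 0 <= depth <= 1:
                raise ValueError(
                    f"modulation_bands: depth must be in [0, 1], got {depth}"
                )
            if not -np.pi <= phi0 < np.pi:
                raise ValueError(
                    f"modulation_bands: preferred_phase must be in [-pi, pi), got {phi0}"
                )

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["modulation_bands"] = [list(b) for b in self.modulation_bands]
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "SessionConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        d["modulation_bands"] = tuple(tuple(b) for b in d.get(
            "modulation_bands", DEFAULT_MODULATION_BANDS))
        return cls(**d)


@dataclass
class SyntheticSession:
    """A generated session: signals plus exact gait-phase ground truth."""

    recording: Recording
    truth_phase: PhaseSeries
    truth_cycles: GaitCycleTable
    config: SessionConfig


def _one_over_f_noise(rng: np.random.Generator, n: int, exponent: float
                      ) -> np.ndarray:
    """Unit-RMS Gaussian noise with a 1/f^exponent power spectrum (spectral shaping)."""
    white = rng.standard_normal(n)
    if exponent == 0:
        x = white
    else:
        spec = np.fft.rfft(white)
        f = np.fft.rfftfreq(n)
        scale = np.zeros_like(f)
        scale[1:] = f[1:] ** (-exponent / 2.0)
        x = np.fft.irfft(spec * scale, n)
    return x / np.std(x)


def _band_noise(rng: np.random.Generator, n: int, fs: float,
                lo: float, hi: float) -> np.ndarray:
    """Unit-RMS band-limited Gaussian noise carrier."""
    sos = butter(4, [lo, hi], btype="bandpass", fs=fs, output="sos")
    x = sosfiltfilt(sos, rng.standard_normal(n))
    return x / np.std(x)


def _draw_cycles(rng: np.random.Generator, cfg: SessionConfig
                 ) -> np.ndarray:
    """Per-cycle durations: period + N(0, jitter^2), redrawn while <= period/2."""
    n_max = int(np.ceil(cfg.duration_s / cfg.cycle_period_s)) + 3
    durations = np.full(n_max, cfg.cycle_period_s)
    if cfg.cycle_jitter_sd_s > 0:
        durations = durations + rng.normal(0, cfg.cycle_jitter_sd_s, n_max)
        floor = 0.5 * cfg.cycle_period_s
        bad = durations <= floor
        while bad.any():
            durations[bad] = cfg.cycle_period_s + rng.normal(
                0, cfg.cycle_jitter_sd_s, bad.sum())
            bad = durations <= floor
    return durations


def generate_session(config: SessionConfig) -> SyntheticSession:
    """Generate one synthetic stepping session.

    Deterministic given ``config.seed`` (identical configs yield bit-identical
    sessions).  The left foot defines the reference gait phase; the right
    foot's force is offset by half a cycle.  LFP band amplitudes follow
    ``1 + depth*cos(phase - preferred_phase)`` with respect to the left-foot
    phase.
    """
    config.validate()
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n = int(round(cfg.duration_s * cfg.fs))
    fs = cfg.fs

    # --- gait cycles and ground-truth phase -------------------------------
    durations = _draw_cycles(rng, cfg)
    starts_s = np.concatenate([[0.0], np.cumsum(durations)])
    # keep complete cycles that fit inside the session
    keep = starts_s[1:] * fs <= n - 1
    durations = durations[keep]
    starts_s = starts_s[: len(durations) + 1]

    lift = starts_s[:-1] * fs
    next_lift = starts_s[1:] * fs
    strike = (starts_s[:-1] + durations / 2.0) * fs
    cycle_anchors = [
        [(a, -np.pi), (b, 0.0), (c, np.pi)]
        for a, b, c in zip(lift, strike, next_lift)
    ]
    truth_phase = _phase_from_cycles(n, cycle_anchors, fs, True)
    truth_cycles = GaitCycleTable(
        lift_sample=np.round(lift),
        strike_sample=np.round(strike),
        next_lift_sample=np.round(next_lift),
        duration_s=durations,
        lift_duration_s=durations / 2.0,
        fs=fs,
    )

    # continuous (extrapolated) phase for synthesizing smooth kinematic traces
    t = np.arange(n, dtype=float)
    anchor_pos = np.concatenate([lift, [next_lift[-1]]])
    anchor_unwrapped = -np.pi + 2 * np.pi * np.arange(len(anchor_pos))
    rate0 = 2 * np.pi / (durations[0] * fs)
    rate1 = 2 * np.pi / (durations[-1] * fs)
    phi = np.interp(t, anchor_pos, anchor_unwrapped)
    head = t < anchor_pos[0]
    tail = t > anchor_pos[-1]
    phi[head] = anchor_unwrapped[0] + (t[head] - anchor_pos[0]) * rate0
    phi[tail] = anchor_unwrapped[-1] + (t[tail] - anchor_pos[-1]) * rate1

    # --- kinematic channels ----------------------------------------------
    # signed sinusoid of gait phase: positive while the foot is loaded
    # (stance, phase 0..pi), negative in swing, so the 0.5-5 Hz bandpassed
    # trace crosses zero exactly at strike (rising) and lift (falling)
    noise = cfg.sensor_noise_sd
    force_left = np.sin(phi) + rng.normal(0, noise, n)
    force_right = np.sin(phi + np.pi) + rng.normal(0, noise, n)
    accel_x = np.cos(phi) + rng.normal(0, noise, n)
    accel_y = -np.sin(phi) + rng.normal(0, noise, n)
    accel_z = rng.normal(0, noise, n)

    # --- LFP contacts ------------------------------------------------------
    wrapped = wrap_phase(phi)
    common = _one_over_f_noise(rng, n, cfg.noise_exponent)
    cortical_src = np.zeros(n)
    lfp = []
    for i in range(cfg.n_lfp_contacts):
        x = cfg.noise_amplitude * _one_over_f_noise(rng, n, cfg.noise_exponent)
        for lo, hi, depth, phi0 in cfg.modulation_bands:
            osc = cfg.osc_amplitude * _band_noise(rng, n, fs, lo, hi)
            env = 1.0 + depth * np.cos(wrapped - phi0)
            # contact-dependent gain gradient along the lead so that the
            # modulated rhythm survives bipolar derivation and couples to EEG
            gain = 1.0 + 0.2 * i
            x = x + gain * osc * env
            cortical_src = cortical_src + osc
        x = x + cfg.common_mode_gain * common
        lfp.append(x)

    # --- EEG ---------------------------------------------------------------
    delay = int(round(cfg.cortical_delay_s * fs))
    shifted = np.roll(cortical_src, delay)
    eeg_fz = (cfg.noise_amplitude * _one_over_f_noise(rng, n, cfg.noise_exponent)
              + cfg.cortical_gain * shifted / max(np.std(cortical_src), 1e-12))
    eeg_cz = cfg.noise_amplitude * _one_over_f_noise(rng, n, cfg.noise_exponent)

    signals = np.vstack(lfp + [eeg_fz, eeg_cz, force_left, force_right,
                               accel_x, accel_y, accel_z])
    labels = ([f"lfp_{i}" for i in range(cfg.n_lfp_contacts)]
              + ["eeg_fz", "eeg_cz", "force_left", "force_right",
                 "accel_x", "accel_y", "accel_z"])
    kinds = (["lfp"] * cfg.n_lfp_contacts + ["eeg"] * 2 + ["force"] * 2
             + ["accel"] * 3)
    rec = Recording(signals=signals, fs=fs, labels=labels, kinds=kinds)
    return SyntheticSession(rec, truth_phase, truth_cycles, cfg)


# ---------------------------------------------------------------------------
# persistence

def save_session(path, session: SyntheticSession) -> None:
    """Serialize a session to one HDF5 file (signals, labels, fs, truth)."""
    with h5py.File(path, "w") as fh:
        save_recording(fh, session.recording)
        truth = fh.create_group("truth")
        truth.create_dataset("phase", data=session.truth_phase.phase)
        truth.create_dataset("valid", data=session.truth_phase.valid)
        truth.create_dataset(
            "cycles",
            data=np.column_stack([
                session.truth_cycles.lift_sample,
                session.truth_cycles.strike_sample,
                session.truth_cycles.next_lift_sample,
                session.truth_cycles.duration_s,
                session.truth_cycles.lift_duration_s,
            ]),
        )
        d = asdict(session.config)
        d["modulation_bands"] = [list(b) for b in session.config.modulation_bands]
        fh.attrs["config_yaml"] = yaml.safe_dump(d, sort_keys=True)


def load_session(path) -> SyntheticSession:
    with h5py.File(path, "r") as fh:
        rec = load_recording(fh)
        phase = np.asarray(fh["truth/phase"])
        valid = np.asarray(fh["truth/valid"], dtype=bool)
        cyc = np.asarray(fh["truth/cycles"])
        d = yaml.safe_load(fh.attrs["config_yaml"])
    d["modulation_bands"] = tuple(tuple(b) for b in d["modulation_bands"])
    cfg = SessionConfig(**d)
    return SyntheticSession(
        recording=rec,
        truth_phase=PhaseSeries(phase, valid, rec.fs, True),
        truth_cycles=GaitCycleTable(
            cyc[:, 0], cyc[:, 1], cyc[:, 2], cyc[:, 3], cyc[:, 4], fs=rec.fs
        ),
        config=cfg,
    )
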