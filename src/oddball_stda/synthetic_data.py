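"""Forward-modelled simulation of passive/active auditory-oddball sessions.

A session is two task blocks (passive listening, then active target
detection), each a stream of frequent 500 Hz standards and rare 1000 Hz
deviants (325/75 of 400 trials, 950 ms inter-stimulus interval).  Evoked
activity is a superposition of ERP components (N1, MMN, P3), each a focal
current dipole with a Gaussian temporal envelope, projected to the 64
scalp channels through the spherical-head lead field.  Noise is spatially
correlated background activity (many random dipoles with low-pass-filtered
Gaussian moments) plus white sensor noise; between-subject variability is a
multiplicative per-subject, per-component amplitude gain.

Trial-level sensor data are exactly linear in every component amplitude.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import signal, stats

from .forward_model import (
    LeadField,
    Montage,
    _sphere_dipole_gain,
    apply_reference,
)
from .preprocessing import EpochSet

__all__ = [
    "ParadigmConfig",
    "ComponentSpec",
    "NoiseModel",
    "BehavioralResult",
    "generate_trial_sequence",
    "simulate_behavior",
    "synthesize_session",
    "iter_session",
    "simulate_epochs",
    "default_components",
    "component_topography",
    "tangentialize",
]

CONDITIONS = ("standard", "deviant")
TASKS = ("passive", "active")


class InvalidConfigError(ValueError):
    pass


@dataclass(frozen=True)
class ParadigmConfig:
    """Oddball block structure (defaults are the study paradigm)."""

    n_trials: int = 400
    n_deviants: int = 75
    isi_ms: float = 950.0
    tone_duration_ms: float = 50.0
    fade_ms: float = 5.0
    standard_hz: float = 500.0
    deviant_hz: float = 1000.0
    tasks: tuple[str, str] = TASKS
    #: minimum number of standards between two deviants (0 disables)
    min_deviant_spacing: int = 1

    def __post_init__(self):
        if self.n_deviants > self.n_trials:
            raise InvalidConfigError("n_deviants may not exceed n_trials")
        if self.isi_ms <= 0:
            raise InvalidConfigError("isi_ms must be positive")

    @property
    def soa_ms(self) -> float:
        """Stimulus-onset asynchrony: tone duration + inter-stimulus interval."""
        return self.tone_duration_ms + self.isi_ms


@dataclass(frozen=True)
class ComponentSpec:
    """One simulated ERP component: a dipole with a Gaussian time course.

    `amplitude` maps every (condition, task) cell to a source moment in
    nA*m (zero allowed).  Sign convention: a positive moment points along
    `orientation`.
    """

    name: str
    peak_latency_ms: float
    temporal_sd_ms: float
    source_position: tuple[float, float, float]  # cm, head frame
    orientation: tuple[float, float, float]  # unit vector
    amplitude: dict  # {(condition, task): nA*m}

    def __post_init__(self):
        n = np.linalg.norm(self.orientation)
        if not np.isclose(n, 1.0, atol=1e-6):
            raise InvalidConfigError(f"orientation of {self.name} must be unit norm")
        for cond in CONDITIONS:
            for task in TASKS:
                if (cond, task) not in self.amplitude:
                    raise InvalidConfigError(
                        f"amplitude map of {self.name} missing ({cond}, {task})")

    def envelope(self, times_ms: np.ndarray) -> np.ndarray:
        """Unit-peak Gaussian envelope over epoch latencies."""
        return np.exp(-0.5 * ((times_ms - self.peak_latency_ms)
                              / self.temporal_sd_ms) ** 2)


@dataclass(frozen=True)
class NoiseModel:
    """Background (correlated) + sensor (white) noise parameters."""

    sensor_white_sd_uV: float = 4.0
    background_n_dipoles: int = 200
    background_sd_nAm: float = 12.0
    temporal_lowpass_hz: float = 12.0

    def __post_init__(self):
        if min(self.sensor_white_sd_uV, self.background_sd_nAm,
               self.temporal_lowpass_hz) < 0 or self.background_n_dipoles < 0:
            raise InvalidConfigError("noise dispersions must be non-negative")


@dataclass(frozen=True)
class BehavioralResult:
    """Reaction times and hits to deviant trials in the active block."""

    trial_indices: np.ndarray  # deviant trial positions in the block
    rt_ms: np.ndarray
    hit: np.ndarray  # bool

    @property
    def n_hits(self) -> int:
        return int(self.hit.sum())


def tangentialize(position, direction) -> tuple[float, float, float]:
    """Project `direction` onto the tangent plane at `position`; unit-normalise."""
    p = np.asarray(position, float)
    d = np.asarray(direction, float)
    r = p / np.linalg.norm(p)
    t = d - (d @ r) * r
    n = np.linalg.norm(t)
    if n < 1e-12:
        raise InvalidConfigError("direction is purely radial at this position")
    return tuple(t / n)


def _amp(standard=0.0, deviant=0.0, deviant_active=None, standard_active=None) -> dict:
    da = deviant if deviant_active is None else deviant_active
    sa = standard if standard_active is None else standard_active
    return {("standard", "passive"): standard, ("standard", "active"): sa,
            ("deviant", "passive"): deviant, ("deviant", "active"): da}


def default_components() -> list[ComponentSpec]:
    """The study's effect structure on the spherical head.

    * N1 (~95 ms): tangential dipole in the right superior temporal region,
      oriented away from the vertex -> fronto-central negativity for both
      conditions and tasks.
    * MMN (~100 ms): additional deviant-only source at a nearby superior
      temporal position, same orientation; equal across tasks (deviance
      detection is task-insensitive).
    * P3 (~300 ms): radial centro-parietal source (precuneus-like), deviant
      only, larger during active listening (target detection).

    Moments are chosen to give physiological scalp amplitudes (a few uV).
    """
    stg = (5.2, 0.5, 3.0)
    stg2 = (5.2, 1.0, 3.2)
    pcun = (0.0, -2.0, 5.0)
    down_at = lambda p: tangentialize(p, (0.0, 0.0, -1.0))
    radial = tuple(np.asarray(pcun) / np.linalg.norm(pcun))
    return [
        ComponentSpec("N1", 95.0, 15.0, stg, down_at(stg),
                      _amp(standard=30.0, deviant=30.0)),
        ComponentSpec("MMN", 100.0, 18.0, stg2, down_at(stg2),
                      _amp(standard=0.0, deviant=25.0)),
        ComponentSpec("P3", 300.0, 45.0, pcun, radial,
                      _amp(standard=0.0, deviant=20.0, deviant_active=40.0)),
    ]


# ---------------------------------------------------------------------------
# Trial sequence and behavior
# ---------------------------------------------------------------------------

def generate_trial_sequence(cfg: ParadigmConfig, seed: int) -> np.ndarray:
    """Random condition-label sequence with the deviant-spacing constraint.

    Deviant positions are drawn uniformly over all placements with at least
    ``cfg.min_deviant_spacing`` standards between consecutive deviants (the
    classic stars-and-bars bijection), so every admissible sequence is
    equally likely.  Identical (cfg, seed) give identical sequences.
    """
    k, n, s = cfg.n_deviants, cfg.n_trials, cfg.min_deviant_spacing
    if k > n:
        raise InvalidConfigError("n_deviants may not exceed n_trials")
    labels = np.array(["standard"] * n, dtype=object)
    if k == 0:
        return labels.astype(str)
    slots = n - (k - 1) * s
    if slots < k:
        raise InvalidConfigError("spacing constraint admits no sequence")
    rng = np.random.default_rng(seed)
    y = np.sort(rng.choice(slots, size=k, replace=False))
    positions = y + np.arange(k) * s
    labels[positions] = "deviant"
    return labels.astype(str)


def simulate_behavior(cfg: ParadigmConfig, seed: int,
                      rt_mean_ms: float = 285.6, rt_sd_ms: float = 38.5,
                      rt_bounds_ms: tuple[float, float] = (223.0, 379.0),
                      hit_rate: float = 74.8 / 75.0) -> BehavioralResult:
    """Truncated-normal reaction times and Bernoulli hits per deviant trial."""
    lo, hi = rt_bounds_ms
    if not (lo <= rt_mean_ms <= hi) or lo >= hi:
        raise InvalidConfigError("RT bounds must contain the mean")
    seq = generate_trial_sequence(cfg, seed)
    idx = np.flatnonzero(seq == "deviant")
    rng = np.random.default_rng([seed, 1])
    if rt_sd_ms == 0:
        rts = np.full(idx.size, rt_mean_ms)
    else:
        a, b = (lo - rt_mean_ms) / rt_sd_ms, (hi - rt_mean_ms) / rt_sd_ms
        rts = stats.truncnorm.rvs(a, b, loc=rt_mean_ms, scale=rt_sd_ms,
                                  size=idx.size, random_state=rng)
    hits = rng.random(idx.size) < hit_rate
    return BehavioralResult(idx, rts, hits)


# ---------------------------------------------------------------------------
# Forward projection helpers
# ---------------------------------------------------------------------------

def component_topography(comp: ComponentSpec, montage: Montage,
                         leadfield: LeadField) -> np.ndarray:
    """Unit-moment (1 nA*m) sensor topography of a component's dipole.

    Evaluated with the same spherical forward model and reference as
    `leadfield`, restricted to the lead field's channel set; for a source on
    a grid voxel this equals the corresponding lead-field column.
    """
    p = np.asarray(comp.source_position, float)
    if np.linalg.norm(p) >= leadfield.grid.inner_radius_cm:
        raise InvalidConfigError(
            f"source of {comp.name} lies outside the source space")
    sub = montage.subset(leadfield.labels)
    g = _sphere_dipole_gain(sub.positions, p[None, :], montage.head_radius_cm)
    g = apply_reference(g, sub.labels, leadfield.reference)
    return g[:, 0, :] @ np.asarray(comp.orientation, float)


def _background_gain(montage: Montage, leadfield: LeadField, n_dipoles: int,
                     rng: np.random.Generator) -> np.ndarray:
    """Gain (channels x dipoles) of random unit background dipoles."""
    if n_dipoles == 0:
        return np.zeros((len(leadfield.labels), 0))
    r_max = leadfield.grid.inner_radius_cm
    pts = rng.uniform(-r_max, r_max, size=(4 * n_dipoles + 64, 3))
    pts = pts[np.linalg.norm(pts, axis=1) < 0.95 * r_max][:n_dipoles]
    ori = rng.standard_normal((n_dipoles, 3))
    ori /= np.linalg.norm(ori, axis=1, keepdims=True)
    sub = montage.subset(leadfield.labels)
    g = _sphere_dipole_gain(sub.positions, pts, montage.head_radius_cm)
    g = apply_reference(g, sub.labels, leadfield.reference)
    return np.einsum("cdk,dk->cd", g, ori)


def _lowpass_sos(noise: NoiseModel, srate_hz: float):
    if not noise.temporal_lowpass_hz or noise.temporal_lowpass_hz >= srate_hz / 2:
        return None
    return signal.butter(2, noise.temporal_lowpass_hz, btype="low",
                         fs=srate_hz, output="sos")


def _zero_phase_sd_gain(sos, srate_hz: float) -> float:
    """SD of zero-phase-filtered unit white noise: sqrt(mean |H|^4)."""
    _, h = signal.sosfreqz(sos, worN=4096, fs=srate_hz)
    return float(np.sqrt(np.mean(np.abs(h) ** 4)))


def _background_noise(gain_bg: np.ndarray, n_samples: int, srate_hz: float,
                      noise: NoiseModel, rng: np.random.Generator) -> np.ndarray:
    """Spatially correlated, temporally smooth noise at the sensors (uV).

    Dipole moments are unit white noise, zero-phase low-passed, and rescaled
    by the filter's analytic SD gain so each moment keeps unit marginal SD
    before scaling by `background_sd_nAm`.
    """
    if gain_bg.shape[1] == 0 or noise.background_sd_nAm == 0:
        return np.zeros((gain_bg.shape[0], n_samples))
    moments = rng.standard_normal((gain_bg.shape[1], n_samples))
    sos = _lowpass_sos(noise, srate_hz)
    if sos is not None:
        moments = signal.sosfiltfilt(sos, moments, axis=-1)
        moments /= _zero_phase_sd_gain(sos, srate_hz)
    return gain_bg @ (noise.background_sd_nAm * moments)


def _subject_gains(components, n_subjects: int, subject_gain_sd: float,
                   seed: int) -> np.ndarray:
    """Per-subject, per-component multiplicative amplitude gains (>= 0.1)."""
    rng = np.random.default_rng([seed, 2])
    g = 1.0 + subject_gain_sd * rng.standard_normal((n_subjects, len(components)))
    return np.maximum(g, 0.1)


# ---------------------------------------------------------------------------
# Session synthesis
# ---------------------------------------------------------------------------

def _block_events(cfg: ParadigmConfig, task: str, seq: np.ndarray,
                  pad_ms: float) -> pd.DataFrame:
    onsets = pad_ms + np.arange(cfg.n_trials) * cfg.soa_ms
    return pd.DataFrame({"onset_ms": onsets, "task": task, "condition": seq,
                         "trial_index": np.arange(cfg.n_trials)})


def iter_session(cfg: ParadigmConfig, components, noise: NoiseModel,
                 montage: Montage, leadfield: LeadField, n_subjects: int = 12,
                 seed: int = 0, srate_hz: float = 2048.0,
                 subject_gain_sd: float = 0.2, pad_ms: float = 1000.0):
    """Yield (subject_id, task, continuous_uV (channels x samples), events).

    Continuous blocks are generated one at a time so a full session never
    needs to be resident in memory.  Trial sequences differ between the two
    task blocks but are identical across subjects (as in a fixed experimental
    script); all noise and gains are subject-specific.
    """
    topos = {c.name: component_topography(c, montage, leadfield) for c in components}
    gains = _subject_gains(components, n_subjects, subject_gain_sd, seed)
    dt_ms = 1000.0 / srate_hz
    n_total = int(np.ceil((2 * pad_ms + cfg.n_trials * cfg.soa_ms) / dt_ms))
    t_ms = np.arange(n_total) * dt_ms

    for si in range(n_subjects):
        for ti, task in enumerate(cfg.tasks):
            seq = generate_trial_sequence(cfg, seed + 1000 * (ti + 1))
            events = _block_events(cfg, task, seq, pad_ms)
            rng = np.random.default_rng([seed, 3, si, ti])
            data = np.zeros((len(leadfield.labels), n_total))
            for ci, comp in enumerate(components):
                src = np.zeros(n_total)
                half = 4.0 * comp.temporal_sd_ms
                for onset, cond in zip(events["onset_ms"], seq):
                    amp = comp.amplitude[(cond, task)] * gains[si, ci]
                    if amp == 0.0:
                        continue
                    center = onset + comp.peak_latency_ms
                    i0 = max(0, int((center - half) / dt_ms))
                    i1 = min(n_total, int((center + half) / dt_ms) + 1)
                    src[i0:i1] += amp * np.exp(
                        -0.5 * ((t_ms[i0:i1] - center) / comp.temporal_sd_ms) ** 2)
                data += np.outer(topos[comp.name], src)
            gbg = _background_gain(montage, leadfield, noise.background_n_dipoles, rng)
            data += _background_noise(gbg, n_total, srate_hz, noise, rng)
            if noise.sensor_white_sd_uV:
                data += noise.sensor_white_sd_uV * rng.standard_normal(data.shape)
            yield f"S{si:02d}", task, data, events


def synthesize_session(cfg: ParadigmConfig, components, noise: NoiseModel,
                       montage: Montage, leadfield: LeadField,
                       n_subjects: int = 12, seed: int = 0,
                       srate_hz: float = 2048.0, subject_gain_sd: float = 0.2,
                       ) -> list[tuple[str, str, np.ndarray, pd.DataFrame]]:
    """Materialised version of :func:`iter_session` (small configs only)."""
    return list(iter_session(cfg, components, noise, montage, leadfield,
                             n_subjects, seed, srate_hz, subject_gain_sd))


def simulate_epochs(cfg: ParadigmConfig, components, noise: NoiseModel,
                    montage: Montage, leadfield: LeadField, task: str,
                    subject: str, subject_gain: np.ndarray, seed: int,
                    srate_hz: float = 512.0, tmin_ms: float = -100.0,
                    tmax_ms: float = 700.0) -> EpochSet:
    """Fast path: generate baseline-corrected epochs directly at `srate_hz`.

    Bypasses the continuous recording and the filtering chain; background
    noise is already band-limited by its low-pass, epochs are independent.
    Intended for tests and desk-scale statistical studies.
    """
    import zlib

    ti = list(cfg.tasks).index(task)
    seq = generate_trial_sequence(cfg, seed + 1000 * (ti + 1))
    rng = np.random.default_rng([seed, 4, zlib.crc32(subject.encode()), ti])
    dt_ms = 1000.0 / srate_hz
    n_samp = int(np.floor((tmax_ms - tmin_ms) / dt_ms)) + 1
    times = tmin_ms + np.arange(n_samp) * dt_ms

    topos = {c.name: component_topography(c, montage, leadfield) for c in components}
    n_ch = len(leadfield.labels)
    data = np.zeros((cfg.n_trials, n_ch, n_samp))
    for ci, comp in enumerate(components):
        env = comp.envelope(times)
        shape = np.outer(topos[comp.name], env)  # (C, S)
        amps = np.array([comp.amplitude[(c, task)] for c in seq]) * subject_gain[ci]
        data += amps[:, None, None] * shape[None, :, :]

    gbg = _background_gain(montage, leadfield, noise.background_n_dipoles, rng)
    if gbg.shape[1] and noise.background_sd_nAm:
        sos = _lowpass_sos(noise, srate_hz)
        gain = _zero_phase_sd_gain(sos, srate_hz) if sos is not None else 1.0
        # chunk trials to bound the (trials, dipoles, samples) temporary
        for lo in range(0, cfg.n_trials, 64):
            hi = min(cfg.n_trials, lo + 64)
            m = rng.standard_normal((hi - lo, gbg.shape[1], n_samp))
            if sos is not None:
                m = signal.sosfiltfilt(sos, m, axis=-1) / gain
            data[lo:hi] += np.einsum("cd,tds->tcs", gbg,
                                     noise.background_sd_nAm * m)
    if noise.sensor_white_sd_uV:
        data += noise.sensor_white_sd_uV * rng.standard_normal(data.shape)

    bmask = (times >= -100.0) & (times <= 0.0)
    data -= data[:, :, bmask].mean(axis=2, keepdims=True)
    return EpochSet(data, srate_hz, tmin_ms, tmax_ms, tuple(leadfield.labels),
                    np.asarray(seq), np.full(cfg.n_trials, task), subject)


def write_events_tsv(events: pd.DataFrame, path) -> None:
    events.to_csv(path, sep="\t", index=False,
                  columns=["onset_ms", "task", "condition", "trial_index"])


def read_events_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
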