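"""Synthetic fNIRS study generator.

Emulates a prefrontal mental-arithmetic block study: each subject rests for
44 s, then alternates 44-s task and 44-s rest blocks five times, recorded over
16 channels at 1.81 Hz with two wavelengths (760/830 nm).  The generator
produces ground-truth hemodynamics (canonical double-gamma HbO response to the
task boxcar, with an anticorrelated delayed HbR response), adds physiological
noise exactly where a notch-filtering pipeline expects it — cardiac (~1.1 Hz),
respiratory (~0.35 Hz), Mayer-wave (~0.08 Hz) oscillations, slow drift and
white sensor noise — and converts the result to two-wavelength optical density
through the forward modified Beer-Lambert law.

Simulation runs at an internal oversampled rate (default 16 Hz) and is then
point-decimated to the output rate, deliberately reproducing the aliasing a
real 1.81 Hz acquisition shows for cardiac components above its 0.905 Hz
Nyquist frequency.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .mbll import ExtinctionSpec, HemoSeries, OpticalDensity, concentrations_to_od

__all__ = [
    "ParadigmSpec",
    "ActivationSpec",
    "NoiseSpec",
    "SyntheticRecording",
    "ConcentrationSim",
    "build_block_labels",
    "block_bounds",
    "double_gamma_hrf",
    "simulate_concentrations",
    "generate_study",
]

TASK, REST = 1, 0


@dataclass
class ParadigmSpec:
    """Block paradigm and acquisition geometry of the emulated study."""

    rest_pre_s: float = 44.0
    task_s: float = 44.0
    rest_post_s: float = 44.0
    n_trials: int = 5
    fs_out: float = 1.81
    n_channels: int = 16
    n_subjects: int = 7

    def __post_init__(self) -> None:
        for name in ("rest_pre_s", "task_s", "rest_post_s"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.fs_out <= 0:
            raise ValueError("fs_out must be > 0")
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")
        if self.n_channels < 1:
            raise ValueError("n_channels must be >= 1")
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")

    @property
    def duration_s(self) -> float:
        """True total duration: rest + n_trials × (task + rest)."""
        return self.rest_pre_s + self.n_trials * (self.task_s + self.rest_post_s)


@dataclass
class ActivationSpec:
    """Hemodynamic forward model for the task response.

    ``hbo_amp`` sets the peak task-evoked HbO excursion in μM; HbR is a scaled
    (``hbr_ratio``, negative) copy of the HbO response delayed by
    ``hbr_delay_s``, the usual fNIRS anticorrelation.

    The response is phasic-plus-sustained: a strong onset transient over the
    first ``phasic_s`` seconds of each block riding on a weaker plateau
    (``sustained_frac`` of full drive) — the attenuation commonly seen over a
    long cognitive block.  ``trial_jitter`` is the relative SD of per-trial,
    per-channel amplitude variability; ``channel_gain`` optionally modulates
    the response per channel.
    """

    hbo_amp: float = 1.3
    hbr_ratio: float = -1.0 / 3.0
    hbr_delay_s: float = 1.0
    hrf_peak_s: float = 6.0
    hrf_undershoot_s: float = 16.0
    hrf_undershoot_ratio: float = 1.0 / 6.0
    sustained_frac: float = 0.35
    phasic_s: float = 8.0
    trial_jitter: float = 0.25
    channel_gain: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.hbo_amp < 0:
            raise ValueError("hbo_amp must be >= 0")
        if self.hbr_ratio > 0:
            raise ValueError("hbr_ratio must be <= 0")
        if self.hrf_peak_s <= 0:
            raise ValueError("hrf_peak_s must be > 0")
        if self.channel_gain is not None:
            self.channel_gain = np.asarray(self.channel_gain, dtype=float)

    def gains(self, n_channels: int) -> np.ndarray:
        if self.channel_gain is None:
            return np.ones(n_channels)
        if self.channel_gain.size != n_channels:
            raise ValueError("channel_gain length must equal n_channels")
        return self.channel_gain


@dataclass
class NoiseSpec:
    """Physiological and instrumental noise, placed in the notch-reject bands.

    ``amplitudes`` are the (cardiac, respiratory, Mayer) sinusoid amplitudes in
    μM; each channel receives an independent random phase.  ``drift_slope`` is
    the maximum magnitude of a per-channel linear drift in μM/s, ``white_sd``
    the standard deviation of white sensor noise in μM, and ``wander_sd`` the
    standard deviation of stochastic low-frequency baseline wander (Gaussian
    noise low-passed at ``wander_cutoff_hz``), the slow spontaneous
    hemodynamics that make epoch baselines drift between blocks.

    ``freq_jitter`` spreads each oscillation's frequency per channel by the
    given relative fraction (cardiac/respiratory/Mayer rates differ across
    vascular territories and are not phase-locked to the paradigm); the
    defaults keep every realization inside its nominal reject band.
    ``env_mod`` amplitude-modulates each oscillation with a slow stochastic
    envelope (relative depth; breathing and pulse strength vary over tens of
    seconds), with envelope bandwidth ``env_cutoff_hz``.
    """

    cardiac_hz: float = 1.1
    resp_hz: float = 0.35
    mayer_hz: float = 0.08
    amplitudes: tuple[float, float, float] = (0.25, 0.25, 0.2)
    drift_slope: float = 0.002
    white_sd: float = 0.15
    wander_sd: float = 0.45
    wander_cutoff_hz: float = 0.04
    freq_jitter: float = 0.08
    env_mod: float = 0.5
    env_cutoff_hz: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        for f in (self.cardiac_hz, self.resp_hz, self.mayer_hz):
            if f <= 0:
                raise ValueError("noise frequencies must be > 0")
        if any(a < 0 for a in self.amplitudes):
            raise ValueError("noise amplitudes must be >= 0")
        if self.white_sd < 0:
            raise ValueError("white_sd must be >= 0")
        if self.wander_sd < 0:
            raise ValueError("wander_sd must be >= 0")


@dataclass
class ConcentrationSim:
    """Noisy + noiseless concentrations at the output rate, plus the internal trace."""

    hemo: HemoSeries
    truth: HemoSeries
    labels: np.ndarray
    fs_internal: float
    internal_hbo: np.ndarray
    internal_hbr: np.ndarray


@dataclass
class SyntheticRecording:
    """One subject's simulated recording with ground truth."""

    subject_id: int
    od: OpticalDensity
    truth_hbo: np.ndarray
    truth_hbr: np.ndarray
    labels: np.ndarray
    paradigm: ParadigmSpec
    activation: ActivationSpec
    noise: NoiseSpec


def block_bounds(p: ParadigmSpec) -> list[tuple[int, int, int]]:
    """Half-open (label, start, end) sample ranges of the block sequence.

    Each block contributes round(duration × fs_out) samples: the initial rest,
    then n_trials × (task, rest).
    """
    durations = [(REST, p.rest_pre_s)]
    for _ in range(p.n_trials):
        durations.append((TASK, p.task_s))
        durations.append((REST, p.rest_post_s))
    bounds = []
    start = 0
    for label, dur in durations:
        n = int(round(dur * p.fs_out))
        bounds.append((label, start, start + n))
        start += n
    return bounds


def build_block_labels(p: ParadigmSpec) -> np.ndarray:
    """Per-sample task(1)/rest(0) indicator for the block paradigm."""
    bounds = block_bounds(p)
    labels = np.zeros(bounds[-1][2], dtype=np.int8)
    for label, start, end in bounds:
        labels[start:end] = label
    return labels


def double_gamma_hrf(fs: float, peak_s: float = 6.0, undershoot_s: float = 16.0,
                     undershoot_ratio: float = 1.0 / 6.0, length_s: float = 32.0) -> np.ndarray:
    """Canonical double-gamma hemodynamic impulse response sampled at ``fs``.

    Normalized so that the peak response to a sustained step stimulus is 1,
    which makes ``hbo_amp`` the peak task excursion in μM.
    """
    t = np.arange(0.0, length_s, 1.0 / fs)
    # shape parameters chosen so each gamma peaks at (peak_s, undershoot_s)
    a1, a2 = 6.0, 12.0
    b1 = peak_s / (a1 - 1.0)
    b2 = undershoot_s / (a2 - 1.0)
    g1 = t ** (a1 - 1) * np.exp(-t / b1)
    g2 = t ** (a2 - 1) * np.exp(-t / b2)
    h = g1 / g1.max() - undershoot_ratio * g2 / g2.max()
    step_peak = np.cumsum(h).max()
    if step_peak <= 0:
        raise ValueError("degenerate HRF: non-positive step response")
    return h / step_peak


def _baseline_wander(rng: np.random.Generator, n_samples: int, n_channels: int,
                     fs: float, sd: float, cutoff_hz: float) -> np.ndarray:
    """Stochastic slow baseline drift: white noise low-passed below ``cutoff_hz``.

    Rescaled so every channel's realized standard deviation equals ``sd`` (μM).
    """
    if sd <= 0:
        return np.zeros((n_samples, n_channels))
    from scipy.signal import butter, sosfiltfilt

    white = rng.standard_normal((n_samples, n_channels))
    sos = butter(2, cutoff_hz / (fs / 2.0), btype="lowpass", output="sos")
    slow = sosfiltfilt(sos, white, axis=0)
    realized = slow.std(axis=0, keepdims=True)
    realized[realized == 0] = 1.0
    return slow / realized * sd


def _upsample_labels(labels: np.ndarray, fs_out: float, t_internal: np.ndarray) -> np.ndarray:
    idx = np.minimum((t_internal * fs_out).astype(int), labels.size - 1)
    return labels[idx].astype(float)


def simulate_concentrations(
    p: ParadigmSpec,
    a: ActivationSpec,
    n: NoiseSpec,
    fs_internal: float = 16.0,
    rng: np.random.Generator | None = None,
) -> ConcentrationSim:
    """Simulate noiseless + noisy HbO/HbR for one subject at the output rate.

    The task boxcar (from :func:`build_block_labels`) is convolved with the
    double-gamma HRF at ``fs_internal``; noise sinusoids, drift and white noise
    are added; the sum is linearly decimated to ``p.fs_out``.  Identical
    ``rng`` state gives bitwise-identical output.
    """
    if fs_internal < 4.0 * n.cardiac_hz:
        raise ValueError(
            f"internal rate {fs_internal} Hz must be >= 4x cardiac frequency {n.cardiac_hz} Hz"
        )
    if rng is None:
        rng = np.random.default_rng(n.seed)

    labels = build_block_labels(p)
    n_out = labels.size
    t_out = np.arange(n_out) / p.fs_out
    n_int = int(np.ceil(n_out / p.fs_out * fs_internal)) + 1
    t_int = np.arange(n_int) / fs_internal

    # --- noiseless task response ---------------------------------------
    boxcar = _upsample_labels(labels, p.fs_out, t_int)
    hrf = double_gamma_hrf(fs_internal, a.hrf_peak_s, a.hrf_undershoot_s,
                           a.hrf_undershoot_ratio)
    gains = a.gains(p.n_channels)
    # phasic + sustained drive: full drive for the first phasic_s seconds of
    # each block, sustained_frac of it for the remainder
    onsets = np.flatnonzero(np.diff(np.concatenate([[0.0], boxcar])) > 0.5)
    offsets = np.flatnonzero(np.diff(np.concatenate([boxcar, [0.0]])) < -0.5) + 1
    drive = boxcar * a.sustained_frac
    n_phasic = int(round(a.phasic_s * fs_internal))
    for s, e in zip(onsets, offsets):
        drive[s:min(s + n_phasic, e)] = 1.0
    # per-trial, per-channel amplitude jitter: each task block of each channel
    # gets its own multiplicative gain (floored at 0)
    stim = drive[:, None] * gains[None, :]
    if a.trial_jitter > 0:
        for s, e in zip(onsets, offsets):
            jitter = np.maximum(0.0, 1.0 + a.trial_jitter * rng.standard_normal(p.n_channels))
            stim[s:e, :] *= jitter[None, :]
    from scipy.signal import fftconvolve

    response = fftconvolve(stim, hrf[:, None], axes=0)[:n_int] * a.hbo_amp
    delay = int(round(a.hbr_delay_s * fs_internal))
    truth_hbo_int = response
    truth_hbr_int = a.hbr_ratio * np.concatenate(
        [np.zeros((delay, p.n_channels)), response]
    )[:n_int]

    # --- physiological + instrumental noise -----------------------------
    freqs = (n.cardiac_hz, n.resp_hz, n.mayer_hz)

    def oscillation(amp: float, f: float) -> np.ndarray:
        phases = rng.uniform(0, 2 * np.pi, size=p.n_channels)
        f_ch = f * (1.0 + n.freq_jitter * rng.uniform(-1.0, 1.0, size=p.n_channels))
        carrier = np.sin(2 * np.pi * f_ch[None, :] * t_int[:, None] + phases[None, :])
        if n.env_mod > 0:
            env = 1.0 + _baseline_wander(rng, n_int, p.n_channels, fs_internal,
                                         n.env_mod, n.env_cutoff_hz)
            carrier = carrier * np.maximum(env, 0.0)
        return amp * carrier

    noise = np.zeros((n_int, p.n_channels))
    for amp, f in zip(n.amplitudes, freqs):
        noise += oscillation(amp, f)
    slopes = n.drift_slope * rng.uniform(-1.0, 1.0, size=p.n_channels)
    noise += slopes[None, :] * (t_int[:, None] - t_int[-1] / 2.0)
    noise += rng.normal(0.0, n.white_sd, size=(n_int, p.n_channels)) if n.white_sd > 0 else 0.0
    wander = _baseline_wander(rng, n_int, p.n_channels, fs_internal,
                              n.wander_sd, n.wander_cutoff_hz)
    noise += wander
    # HbR carries the same physiological sources at reduced amplitude,
    # matching the smaller HbR signal range seen in practice.
    noise_hbr = np.zeros((n_int, p.n_channels))
    for amp, f in zip(n.amplitudes, freqs):
        noise_hbr += oscillation(0.5 * amp, f)
    noise_hbr += 0.5 * slopes[None, :] * (t_int[:, None] - t_int[-1] / 2.0)
    if n.white_sd > 0:
        noise_hbr += rng.normal(0.0, 0.5 * n.white_sd, size=(n_int, p.n_channels))
    noise_hbr += _baseline_wander(rng, n_int, p.n_channels, fs_internal,
                                  0.5 * n.wander_sd, n.wander_cutoff_hz)

    hbo_int = truth_hbo_int + noise
    hbr_int = truth_hbr_int + noise_hbr

    # --- decimate to the acquisition rate -------------------------------
    def decimate(x: np.ndarray) -> np.ndarray:
        return np.stack([np.interp(t_out, t_int, x[:, c]) for c in range(x.shape[1])], axis=1)

    hemo = HemoSeries(hbo=decimate(hbo_int), hbr=decimate(hbr_int), fs=p.fs_out)
    truth = HemoSeries(hbo=decimate(truth_hbo_int), hbr=decimate(truth_hbr_int), fs=p.fs_out)
    return ConcentrationSim(
        hemo=hemo,
        truth=truth,
        labels=labels,
        fs_internal=fs_internal,
        internal_hbo=hbo_int,
        internal_hbr=hbr_int,
    )


def generate_study(
    p: ParadigmSpec | None = None,
    a: ActivationSpec | None = None,
    n: NoiseSpec | None = None,
    e: ExtinctionSpec | None = None,
    fs_internal: float = 16.0,
) -> list[SyntheticRecording]:
    """Generate one recording per subject, converted to optical density.

    Per-subject random streams derive deterministically from the master seed
    ``n.seed`` via ``default_rng([seed, subject_id])``, so subjects are
    independent but the whole study reproduces exactly.
    """
    p = p or ParadigmSpec()
    a = a or ActivationSpec()
    n = n or NoiseSpec()
    e = e or ExtinctionSpec()
    recordings = []
    for s in range(p.n_subjects):
        rng = np.random.default_rng([int(n.seed) % (2**31), s])
        sim = simulate_concentrations(p, a, n, fs_internal=fs_internal, rng=rng)
        od = concentrations_to_od(sim.hemo, e)
        recordings.append(
            SyntheticRecording(
                subject_id=s,
                od=od,
                truth_hbo=sim.truth.hbo,
                truth_hbr=sim.truth.hbr,
                labels=sim.labels,
                paradigm=p,
                activation=a,
                noise=n,
            )
        )
    return recordings
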