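"""Synthetic cohort generator emulating resting-state optical mammography data.

The generator produces cohorts with the statistical structure the analysis
pipeline assumes, so every downstream stage can be exercised and calibrated
without clinical data.  Per channel ``r``, breast side ``b`` and wavelength
``w`` the detector voltage is::

    x(r, t) = g_r * (1 + c_r * s_bw(t) + l_r(t) + u_r(t) + eps(r, t))

with the following ingredients, all relative to the channel baseline:

* **channel gains** ``g_r``, log-uniform over several decades — continuous-wave
  transillumination readings are dominated by per-channel coupling and
  attenuation factors.  Gains are drawn per subject and channel and shared
  between the two breasts and wavelengths, modelling one fibre interface with
  a roughly mirror-symmetric optode placement on both sides;
* **systemic vasomotion** ``s_bw(t)`` — a low-frequency (< 0.1 Hz by default)
  multi-sinusoid rhythm modulating all channels of one breast coherently.
  Component frequencies, amplitudes and base phases are subject-level
  physiology shared by both breasts; each side sees them with a small
  side-specific phase lag (``side_phase_jitter_rad``), and the two
  wavelengths see the rhythm with correlation ``wavelength_correlation``.
  The per-channel modulation depth ``c_r`` (how strongly a channel couples to
  the systemic rhythm) varies around 1 with a per-subject spread;
* **local vasomotion** ``l_r(t)`` — a channel-incoherent low-frequency
  component present in *every* subject, whose per-subject level (relative to
  the systemic rhythm) varies widely across the cohort.  Its per-channel
  frequency and phase are mirror-symmetric between sides up to the same
  small phase lag;
* a **unilateral tumour effect** ``u_r(t)``: in the tumour-bearing breast a
  contiguous source-major band of ``ceil(tumor_channel_fraction * R)``
  channels receives an extra, channel-incoherent low-frequency component
  that multiplies each affected channel's fluctuation variance by
  ``1 + effect_size``, raising temporal and spatial heterogeneity there;
* **white noise** ``eps``, uniform with half-width ``noise_rel_amplitude``.

Between-subject variability (overall rhythm amplitude, modulation-depth
spread, local-vasomotion level) is shared by the two breasts of a subject.
This is what the bilateral analysis banks on: within-subject referencing
cancels the physiological factors that confound unilateral classification.

All fluctuation amplitudes are small relative to 1, keeping intensities
strictly positive.  Generation is a pure function of the seed; each subject
draws from its own substream so that cohorts of different sizes share the
signal content of their leading subjects.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass

import numpy as np

from ._errors import RangeError, ValidationError
from .core import SIDES, WAVELENGTHS, Cohort, ScanBlock, SubjectRecord


@dataclass(frozen=True)
class SimulationParams:
    """Study-condition parameters of the synthetic cohort generator.

    Defaults mirror the clinical study setup: 63 subjects with 18
    cancer-positive, 32 x 64 channels, 400 frames at 1.8 Hz, vasomotion
    confined below 0.1 Hz.
    """

    n_subjects: int = 63
    prevalence: float = 18 / 63
    n_sources: int = 32
    n_detectors: int = 64
    n_frames: int = 400
    frame_rate_hz: float = 1.8
    #: channel gains drawn log-uniform over this many decades
    gain_log10_range: float = 4.0
    n_vasomotion_components: int = 3
    vasomotion_band_hz: tuple[float, float] = (0.01, 0.1)
    #: median RMS of the systemic rhythm, relative to channel baseline
    vasomotion_rel_amplitude: float = 0.05
    #: half-width of the uniform white noise, relative to channel baseline
    noise_rel_amplitude: float = 0.02
    #: tumour multiplies affected-channel fluctuation variance by (1 + effect_size)
    effect_size: float = 2.0
    tumor_channel_fraction: float = 0.15
    #: correlation of the systemic rhythm between the two wavelengths
    wavelength_correlation: float = 0.8
    #: sd (radians) of the side-specific phase lag of every rhythm component
    side_phase_jitter_rad: float = 0.1
    #: log-sd of the per-subject rhythm amplitude around vasomotion_rel_amplitude
    subject_amplitude_sd_log: float = 0.4
    #: per-subject modulation-depth spread: c_r ~ U(1-d, 1+d), d ~ U(0, this)
    channel_depth_max: float = 0.6
    #: per-subject local/systemic RMS ratio drawn uniformly from this interval
    local_fraction_range: tuple[float, float] = (0.25, 1.0)
    seed: int = 0

    def __post_init__(self) -> None:
        def check(cond: bool, name: str, msg: str) -> None:
            if not cond:
                raise ValidationError(f"{name}: {msg} (got {getattr(self, name)!r})")

        check(self.n_subjects >= 1, "n_subjects", "must be a positive integer")
        check(0.0 <= self.prevalence <= 1.0, "prevalence", "must lie in [0, 1]")
        check(self.n_sources >= 1, "n_sources", "must be positive")
        check(self.n_detectors >= 1, "n_detectors", "must be positive")
        check(self.n_frames >= 1, "n_frames", "must be positive")
        check(self.frame_rate_hz > 0, "frame_rate_hz", "must be positive")
        check(self.gain_log10_range >= 0, "gain_log10_range", "must be >= 0")
        check(self.n_vasomotion_components >= 1, "n_vasomotion_components", "must be positive")
        lo, hi = self.vasomotion_band_hz
        check(0 < lo < hi < self.frame_rate_hz / 2, "vasomotion_band_hz",
              "must be an interval inside (0, frame_rate_hz / 2)")
        check(self.vasomotion_rel_amplitude >= 0, "vasomotion_rel_amplitude", "must be >= 0")
        check(self.noise_rel_amplitude >= 0, "noise_rel_amplitude", "must be >= 0")
        check(self.effect_size >= 0, "effect_size", "must be >= 0")
        check(0 < self.tumor_channel_fraction <= 1, "tumor_channel_fraction", "must lie in (0, 1]")
        check(0 <= self.wavelength_correlation <= 1, "wavelength_correlation", "must lie in [0, 1]")
        check(self.side_phase_jitter_rad >= 0, "side_phase_jitter_rad", "must be >= 0")
        check(self.subject_amplitude_sd_log >= 0, "subject_amplitude_sd_log", "must be >= 0")
        check(0 <= self.channel_depth_max < 1, "channel_depth_max", "must lie in [0, 1)")
        flo, fhi = self.local_fraction_range
        check(0 <= flo <= fhi, "local_fraction_range", "must be an interval with 0 <= lo <= hi")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["vasomotion_band_hz"] = list(self.vasomotion_band_hz)
        d["local_fraction_range"] = list(self.local_fraction_range)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationParams":
        d = dict(d)
        for key in ("vasomotion_band_hz", "local_fraction_range"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


def _generate_record(params: SimulationParams, index: int, positive: bool,
                     t: np.ndarray, subject_id: str) -> SubjectRecord:
    """One subject's four blocks, drawn from the subject's own substream."""
    rng = np.random.default_rng(np.random.SeedSequence([params.seed, 1 + index]))
    R = params.n_sources * params.n_detectors
    n_affected = int(math.ceil(params.tumor_channel_fraction * R))
    K = params.n_vasomotion_components
    jit = params.side_phase_jitter_rad

    tumor_side = str(rng.choice(SIDES)) if positive else "none"
    gains = 10.0 ** rng.uniform(0.0, params.gain_log10_range, size=R)
    tumor_start = int(rng.integers(0, R - n_affected + 1)) if positive else 0

    # subject-level physiology, shared by both sides and wavelengths
    freqs = rng.uniform(*params.vasomotion_band_hz, size=K)
    amps = rng.uniform(0.5, 1.0, size=K)
    amplitude = params.vasomotion_rel_amplitude * math.exp(
        params.subject_amplitude_sd_log * rng.standard_normal())
    rms = math.sqrt(float(np.sum(amps**2)) / 2.0)
    amps = amps * (amplitude / rms) if rms > 0 and amplitude > 0 else np.zeros(K)
    phi = rng.uniform(0, 2 * np.pi, size=K)
    psi = rng.uniform(0, 2 * np.pi, size=K)   # phases of the 830 nm admixture
    depth = rng.uniform(0, params.channel_depth_max)
    c_r = rng.uniform(1 - depth, 1 + depth, size=R)
    local_fraction = rng.uniform(*params.local_fraction_range)
    f_local = rng.uniform(*params.vasomotion_band_hz, size=R)
    ph_local = rng.uniform(0, 2 * np.pi, size=R)
    local_rms = local_fraction * amplitude

    def waveform(base_phases: np.ndarray) -> np.ndarray:
        phases = base_phases + jit * rng.standard_normal(K)
        return (amps[:, None] * np.sin(
            2 * np.pi * freqs[:, None] * t[None, :] + phases[:, None])).sum(axis=0)

    blocks: dict[tuple[str, int], ScanBlock] = {}
    for side in SIDES:
        shared = waveform(phi)
        indep = waveform(psi)
        # correlation-preserving mix: corr(w760, w830) = rho, equal RMS
        rho = params.wavelength_correlation
        waves = {760: shared, 830: rho * shared + math.sqrt(1.0 - rho**2) * indep}
        local = (local_rms * math.sqrt(2.0)) * np.sin(
            2 * np.pi * f_local[:, None] * t[None, :]
            + (ph_local + jit * rng.standard_normal(R))[:, None])
        extra = None
        if positive and side == tumor_side and params.effect_size > 0:
            # channel fluctuation RMS (noise excluded); the added component
            # multiplies the affected channel's fluctuation variance by 1+effect
            ch_rms = np.sqrt((c_r * amplitude) ** 2 + local_rms**2)
            f_t = rng.uniform(*params.vasomotion_band_hz, size=n_affected)
            ph_t = rng.uniform(0, 2 * np.pi, size=n_affected)
            amp_t = math.sqrt(params.effect_size) * ch_rms[tumor_start:tumor_start + n_affected]
            extra = (amp_t * math.sqrt(2.0))[:, None] * np.sin(
                2 * np.pi * f_t[:, None] * t[None, :] + ph_t[:, None])
        for wl in WAVELENGTHS:
            fluct = c_r[:, None] * waves[wl][None, :] + local
            if extra is not None:
                fluct = fluct.copy()
                fluct[tumor_start:tumor_start + n_affected, :] += extra
            if params.noise_rel_amplitude > 0:
                fluct = fluct + rng.uniform(-params.noise_rel_amplitude,
                                            params.noise_rel_amplitude,
                                            size=(R, params.n_frames))
            blocks[(side, wl)] = ScanBlock(
                values=gains[:, None] * (1.0 + fluct), wavelength_nm=wl, side=side,
                n_sources=params.n_sources, n_detectors=params.n_detectors,
            )
    return SubjectRecord(subject_id=subject_id, blocks=blocks,
                         cancer_positive=positive, tumor_side=tumor_side)


def generate_cohort(params: SimulationParams) -> Cohort:
    """Generate a synthetic cohort as a pure function of ``params.seed``.

    Exactly ``round(prevalence * n_subjects)`` subjects are cancer-positive
    (round-half-up), chosen at random; each positive subject's tumour side is
    drawn uniformly from {left, right}.
    """
    n = params.n_subjects
    n_positive = int(math.floor(params.prevalence * n + 0.5))
    cohort_rng = np.random.default_rng(np.random.SeedSequence(params.seed).spawn(1)[0])
    positive_idx = set(cohort_rng.choice(n, size=n_positive, replace=False).tolist())
    t = np.arange(params.n_frames, dtype=float) / params.frame_rate_hz
    pad = max(len(str(n - 1)), 3)
    records = tuple(
        _generate_record(params, i, i in positive_idx, t, f"sim{i:0{pad}d}")
        for i in range(n)
    )
    return Cohort(records, frame_rate_hz=params.frame_rate_hz)


def spectral_check(block: ScanBlock, band_hz: tuple[float, float],
                   frame_rate_hz: float) -> float:
    """Fraction of mean-removed signal power inside a frequency band.

    Power spectra are computed per channel by real FFT (bin frequencies
    ``k * fs / T``), summed over channels, and the in-band share of the total
    (DC excluded) is returned.
    """
    lo, hi = band_hz
    nyquist = frame_rate_hz / 2.0
    if not 0 < lo < hi <= nyquist:
        raise RangeError(f"band {band_hz} must lie inside (0, {nyquist}]")
    x = block.values
    if x.shape[1] < 8:
        raise ValidationError(f"spectral_check needs T >= 8, got T={x.shape[1]}")
    centered = x - x.mean(axis=1, keepdims=True)
    spectrum = np.abs(np.fft.rfft(centered, axis=1)) ** 2
    freqs = np.fft.rfftfreq(x.shape[1], d=1.0 / frame_rate_hz)
    total = float(spectrum[:, 1:].sum())
    if total == 0.0:
        return 0.0
    in_band = (freqs >= lo) & (freqs <= hi)
    return float(spectrum[:, in_band].sum()) / total
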