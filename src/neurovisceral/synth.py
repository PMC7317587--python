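"""Seeded synthetic ECG / R-R / EEG generators and whole-cohort simulation.

The generators produce controlled inputs for every downstream stage:

* R-R interval series with sinusoidal low-frequency (~0.1 Hz, baroreflex-like)
  and high-frequency (~0.25 Hz, respiratory sinus arrhythmia-like) modulation
  of the instantaneous heart rate, plus optional ectopic beats that violate
  the 20 % beat-to-beat change rule.
* A template-QRS ECG waveform with an R wave at each beat time, so the QRS
  detector can be exercised end to end against known ground truth.
* Multichannel EEG built by mixing band-limited shared sources into channels
  with independent white noise.  Because the sources are brick-wall
  band-limited white noise, the in-band magnitude-squared coherence between
  two channels sharing a source has the closed form

      MSC = (a*b*sigma_s^2)^2 / ((a^2 sigma_s^2 + sigma_1^2)(b^2 sigma_s^2 + sigma_2^2))

  which the test suite checks against the spectral estimator.
* Whole cohorts (case/control) with injected group effects: a heart-rate
  shift, multiplicative suppression of HF modulation power, a shift in theta
  coupling strength, and a latent Gaussian copula that couples each case
  subject's R-R variability scale to their theta coupling strength so that
  SDNN-type HRV indices correlate negatively with theta characteristic path
  length in the case group only.

Every generator is a pure function of its spec including the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .connectivity import CHANNELS_1020

__all__ = [
    "RRGenSpec",
    "EEGGenSpec",
    "CohortSpec",
    "generate_rr_series",
    "inject_ectopics",
    "generate_ecg",
    "generate_eeg",
    "iter_subjects",
    "generate_cohort",
    "write_cohort",
]


# ---------------------------------------------------------------------------
# Specs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RRGenSpec:
    """Parameters of the sinusoidally modulated R-R interval generator.

    The instantaneous R-R interval (ms) at beat time t is

        rr(t) = mean_rr + lf_amp*sin(2*pi*lf_freq*t)
                       + hf_amp*sin(2*pi*hf_freq*t) + N(0, noise_sd^2)

    with lf_freq inside the LF band (0.04-0.15 Hz) and hf_freq inside the HF
    band (0.15-0.4 Hz).
    """

    duration_s: float = 300.0
    mean_rr: float = 850.0
    lf_freq: float = 0.1
    hf_freq: float = 0.25
    lf_amp: float = 30.0
    hf_amp: float = 30.0
    noise_sd: float = 10.0
    ectopic_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")
        if self.mean_rr <= 0:
            raise ValueError("mean_rr must be positive")
        if not 0.04 <= self.lf_freq <= 0.15:
            raise ValueError("lf_freq must lie in the LF band [0.04, 0.15] Hz")
        if not 0.15 <= self.hf_freq <= 0.4:
            raise ValueError("hf_freq must lie in the HF band [0.15, 0.4] Hz")
        if not 0.0 <= self.ectopic_rate <= 0.2:
            raise ValueError("ectopic_rate must lie in [0, 0.2]")


@dataclass(frozen=True)
class EEGGenSpec:
    """Parameters of the shared-source multichannel EEG generator.

    ``band_sources`` is a list of ``(band_low_hz, band_high_hz, weights)``
    triples; each triple creates one unit-variance band-limited source and
    mixes it into every channel with the given per-channel weight vector.
    Independent white noise of standard deviation ``channel_noise_sd`` is
    added to each channel.
    """

    n_channels: int = 19
    fs: float = 1000.0
    duration_s: float = 300.0
    band_sources: tuple = ()
    channel_noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_channels < 2:
            raise ValueError("need at least 2 channels")
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")
        for low, high, w in self.band_sources:
            if not (0 < low < high):
                raise ValueError("band edges must satisfy 0 < low < high")
            if self.fs <= 2 * high:
                raise ValueError("fs must exceed twice the highest band edge")
            w = np.asarray(w, dtype=float)
            if w.shape != (self.n_channels,) or not np.all(np.isfinite(w)):
                raise ValueError("mixing weights must be finite, one per channel")


@dataclass(frozen=True)
class CohortSpec:
    """Design of a simulated two-group (case/control) cohort.

    ``effect_hr`` shifts case-group mean heart rate (bpm); ``effect_hf``
    multiplies case-group HF modulation power (1 = no effect, 0.5 = halved);
    ``effect_theta_cpl`` lowers case-group theta coupling strength, raising
    theta characteristic path length; ``rho_sdnn_cpl_case`` is the target
    (negative) Spearman correlation between SDNN-scale variability and theta
    CPL inside the case group, injected through a latent bivariate Gaussian
    copula on (R-R variability scale, theta coupling strength).
    """

    n_case: int = 53
    n_control: int = 58
    effect_hr: float = 5.0
    effect_hf: float = 0.5
    effect_theta_cpl: float = 0.1
    rho_sdnn_cpl_case: float = -0.4
    iq_mean_case: float = 104.78
    iq_sd_case: float = 17.68
    iq_mean_control: float = 117.86
    iq_sd_control: float = 10.96
    hr_mean_control: float = 68.0
    hr_sd: float = 7.0
    duration_s: float = 300.0
    ecg_fs: float = 1000.0
    eeg_fs: float = 1000.0
    cardiac_modality: str = "rr"  # "rr" (interval CSV) or "ecg" (waveform)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_case <= 0 or self.n_control <= 0:
            raise ValueError("group sizes must be positive")
        if not 0 < self.effect_hf <= 1:
            raise ValueError("effect_hf must lie in (0, 1]")
        if not -1 <= self.rho_sdnn_cpl_case <= 0:
            raise ValueError("rho_sdnn_cpl_case must lie in [-1, 0]")
        if self.cardiac_modality not in ("rr", "ecg"):
            raise ValueError("cardiac_modality must be 'rr' or 'ecg'")


# ---------------------------------------------------------------------------
# R-R and ECG
# ---------------------------------------------------------------------------

def generate_rr_series(spec: RRGenSpec) -> tuple[np.ndarray, np.ndarray]:
    """Generate an R-R interval sequence and its beat times.

    Returns ``(rr_ms, beat_times_s)`` where ``rr_ms[i]`` is the interval
    ending at ``beat_times_s[i + 1]``; intervals equal successive beat-time
    differences by construction.

    Raises ``ValueError`` if the duration accommodates fewer than 4 beats.
    """
    rng = np.random.default_rng(spec.seed)
    beat_times = [0.0]
    t = 0.0
    while t < spec.duration_s:
        rr = (
            spec.mean_rr
            + spec.lf_amp * np.sin(2 * np.pi * spec.lf_freq * t)
            + spec.hf_amp * np.sin(2 * np.pi * spec.hf_freq * t)
            + rng.normal(0.0, spec.noise_sd)
        )
        rr = max(rr, 0.25 * spec.mean_rr)  # guard against absurd draws
        t += rr / 1000.0
        if t > spec.duration_s:
            break
        beat_times.append(t)
    if len(beat_times) < 5:
        raise ValueError("duration too short to contain at least 4 beats")
    beat_times = np.asarray(beat_times)
    rr_ms = np.diff(beat_times) * 1000.0
    if spec.ectopic_rate > 0:
        rr_ms, _ = inject_ectopics(rr_ms, spec.ectopic_rate, seed=spec.seed + 1)
        beat_times = np.concatenate([[beat_times[0]], beat_times[0] + np.cumsum(rr_ms) / 1000.0])
    return rr_ms, beat_times


def inject_ectopics(
    rr: np.ndarray, rate: float, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Perturb a fraction of beats so they violate the 20 % change rule.

    Each selected interval is shortened (premature-beat-like) so that it
    deviates from its predecessor by more than 20 %.  Returns the perturbed
    series and a boolean ground-truth flag array.
    """
    rr = np.asarray(rr, dtype=float)
    if rr.size == 0:
        raise ValueError("rr must be nonempty")
    if not 0.0 <= rate <= 1.0:
        raise ValueError("rate must lie in [0, 1]")
    out = rr.copy()
    flags = np.zeros(rr.size, dtype=bool)
    if rate == 0.0:
        return out, flags
    rng = np.random.default_rng(seed)
    n_target = max(1, int(round(rate * rr.size)))
    # never perturb index 0: the rule compares to the predecessor
    candidates = np.arange(1, rr.size)
    chosen = rng.choice(candidates, size=min(n_target, candidates.size), replace=False)
    for i in np.sort(chosen):
        frac = rng.uniform(0.30, 0.55)  # > 0.20 with margin
        out[i] = out[i - 1] * (1.0 - frac)
        flags[i] = True
    return out, flags


def _qrs_template(fs: float) -> np.ndarray:
    """A Mexican-hat-like QRS template ~100 ms wide, R amplitude 1."""
    half = int(round(0.05 * fs))
    t = np.arange(-half, half + 1) / fs
    sigma = 0.012
    x = t / sigma
    w = (1 - x**2) * np.exp(-(x**2) / 2)
    return w / w.max()


def generate_ecg(
    rr: np.ndarray,
    fs: float = 1000.0,
    noise_sd: float = 0.05,
    seed: int = 0,
) -> np.ndarray:
    """Render an R-R sequence as a single-channel ECG-like waveform.

    Places one QRS template at each beat time (beat times are the cumulative
    sum of the intervals, with a beat at t = 0).  R amplitude is 1; baseline
    noise defaults to sd 0.05 so the R wave is >= 5 x noise.
    """
    rr = np.asarray(rr, dtype=float)
    if rr.size == 0:
        raise ValueError("rr must be nonempty")
    if fs < 250:
        raise ValueError("fs must be at least 250 Hz")
    beat_times = np.concatenate([[0.0], np.cumsum(rr) / 1000.0])
    n = int(np.ceil(beat_times[-1] * fs)) + int(0.2 * fs)
    rng = np.random.default_rng(seed)
    sig = rng.normal(0.0, noise_sd, size=n)
    tpl = _qrs_template(fs)
    half = len(tpl) // 2
    for bt in beat_times:
        c = int(round(bt * fs))
        lo, hi = c - half, c + half + 1
        tlo, thi = max(0, -lo), len(tpl) - max(0, hi - n)
        lo, hi = max(lo, 0), min(hi, n)
        sig[lo:hi] += tpl[tlo:thi]
    return sig


# ---------------------------------------------------------------------------
# EEG
# ---------------------------------------------------------------------------

def _bandlimited_noise(
    rng: np.random.Generator, n: int, fs: float, low: float, high: float
) -> np.ndarray:
    """Unit-variance white noise restricted to [low, high] Hz by a brick-wall
    FFT filter.  The in-band power spectral density is left at the white
    level of the generating noise, so mixing arithmetic on variances maps
    directly onto per-bin PSD arithmetic inside the band."""
    w = rng.standard_normal(n)
    spec = np.fft.rfft(w)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    spec[(freqs < low) | (freqs > high)] = 0.0
    return np.fft.irfft(spec, n=n)


def generate_eeg(spec: EEGGenSpec) -> np.ndarray:
    """Generate a ``(n_channels, n_samples)`` shared-source EEG array.

    Each band source is brick-wall band-limited white noise generated from a
    unit-variance white process; channel i receives
    ``sum_k w_ik * s_k + channel_noise_sd * n_i``.  Within a source band the
    per-bin PSD of the source equals that of unit-variance white noise, so
    two channels with weights a, b on a shared source and noise sd sigma have
    in-band magnitude-squared coherence
    ``(ab)^2 / ((a^2 + sigma^2)(b^2 + sigma^2))``.
    """
    n = int(round(spec.duration_s * spec.fs))
    if n <= 0:
        raise ValueError("zero-length recording")
    rng = np.random.default_rng(spec.seed)
    data = rng.normal(0.0, spec.channel_noise_sd, size=(spec.n_channels, n))
    for low, high, weights in spec.band_sources:
        s = _bandlimited_noise(rng, n, spec.fs, low, high)
        data += np.outer(np.asarray(weights, dtype=float), s)
    return data


# ---------------------------------------------------------------------------
# Cohorts
# ---------------------------------------------------------------------------

@dataclass
class SyntheticSubject:
    """One simulated subject: raw recordings plus the latent truth."""

    subject_id: str
    group: str  # "case" or "control"
    iq: float
    rr_ms: np.ndarray
    ecg: np.ndarray | None
    eeg: np.ndarray
    eeg_fs: float
    ecg_fs: float
    latent: dict


@dataclass
class SyntheticCohort:
    subjects: list[SyntheticSubject]
    truth: pd.DataFrame
    spec: CohortSpec


def _theta_band_sources(
    n_channels: int, coupling: float, rng: np.random.Generator
) -> tuple:
    """Source layout for one subject's EEG: a global theta source whose
    mixing weight is the subject's coupling strength, plus weak fixed
    broadband structure shared by all subjects."""
    theta_w = np.full(n_channels, coupling)
    alpha_w = np.full(n_channels, 0.5)
    return (
        (4.0, 8.0, theta_w),
        (8.0, 12.0, alpha_w),
    )


def iter_subjects(spec: CohortSpec):
    """Yield the cohort's subjects one at a time (constant memory).

    Deterministic given ``spec.seed``; :func:`generate_cohort` materialises
    the same sequence into a :class:`SyntheticCohort`.
    """
    rng = np.random.default_rng(spec.seed)
    n_total = spec.n_case + spec.n_control
    for idx in range(n_total):
        is_case = idx < spec.n_case
        group = "case" if is_case else "control"
        sid = f"sub-{idx + 1:03d}"
        # latent bivariate normal: z0 -> RR variability scale, z1 -> theta coupling
        rho_lat = abs(spec.rho_sdnn_cpl_case) if is_case else 0.0
        cov = np.array([[1.0, rho_lat], [rho_lat, 1.0]])
        z = rng.multivariate_normal([0.0, 0.0], cov)
        var_scale = float(np.exp(0.35 * z[0]))  # lognormal spread of variability
        base_coupling = 0.85 - (spec.effect_theta_cpl if is_case else 0.0)
        coupling = float(np.clip(base_coupling + 0.25 * z[1], 0.05, 2.0))

        hr = rng.normal(
            spec.hr_mean_control + (spec.effect_hr if is_case else 0.0), spec.hr_sd
        )
        hr = float(np.clip(hr, 40.0, 120.0))
        hf_amp = 28.0 * var_scale * (np.sqrt(spec.effect_hf) if is_case else 1.0)
        lf_amp = 30.0 * var_scale
        noise_sd = 8.0 * var_scale
        rr_spec = RRGenSpec(
            duration_s=spec.duration_s,
            mean_rr=60000.0 / hr,
            lf_amp=lf_amp,
            hf_amp=hf_amp,
            noise_sd=noise_sd,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        rr_ms, _ = generate_rr_series(rr_spec)
        ecg = (
            generate_ecg(rr_ms, fs=spec.ecg_fs, seed=int(rng.integers(0, 2**31 - 1)))
            if spec.cardiac_modality == "ecg"
            else None
        )

        eeg_spec = EEGGenSpec(
            n_channels=19,
            fs=spec.eeg_fs,
            duration_s=spec.duration_s,
            band_sources=_theta_band_sources(19, coupling, rng),
            channel_noise_sd=1.0,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        eeg = generate_eeg(eeg_spec)

        iq = float(
            rng.normal(spec.iq_mean_case, spec.iq_sd_case)
            if is_case
            else rng.normal(spec.iq_mean_control, spec.iq_sd_control)
        )
        latent = {
            "true_hr": hr,
            "hf_amp": float(hf_amp),
            "lf_amp": float(lf_amp),
            "noise_sd": float(noise_sd),
            "var_scale": var_scale,
            "theta_coupling": coupling,
        }
        yield SyntheticSubject(
            subject_id=sid,
            group=group,
            iq=iq,
            rr_ms=rr_ms,
            ecg=ecg,
            eeg=eeg,
            eeg_fs=spec.eeg_fs,
            ecg_fs=spec.ecg_fs,
            latent=latent,
        )


def generate_cohort(spec: CohortSpec) -> SyntheticCohort:
    """Simulate a two-group cohort of simultaneous cardiac + EEG recordings.

    Case subjects get a heart-rate shift of ``effect_hr`` bpm, HF modulation
    amplitude scaled by ``sqrt(effect_hf)`` (power scales linearly with
    ``effect_hf``), theta coupling lowered by ``effect_theta_cpl``, and a
    latent copula correlating their R-R variability scale with theta
    coupling so SDNN-family indices and theta CPL correlate negatively.
    The returned truth table records every latent parameter.
    """
    subjects = list(iter_subjects(spec))
    rows = [
        {"id": s.subject_id, "group": s.group, "IQ": s.iq, **s.latent}
        for s in subjects
    ]
    truth = pd.DataFrame(rows)
    return SyntheticCohort(subjects=subjects, truth=truth, spec=spec)


def write_cohort(cohort: SyntheticCohort, out_dir: str | Path, overwrite: bool = False) -> Path:
    """Write a cohort to disk: per-subject RR CSV (or one-column ECG text),
    per-subject EEG CSV with 10-20 channel headers, a subject table
    ``subjects.csv`` and a ground-truth ``truth.tsv``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    truth_path = out / "truth.tsv"
    if truth_path.exists() and not overwrite:
        raise FileExistsError(f"{truth_path} exists; pass overwrite=True")
    for s in cohort.subjects:
        if s.ecg is not None:
            np.savetxt(out / f"{s.subject_id}_ecg.txt", s.ecg, fmt="%.6f")
        else:
            pd.DataFrame({"rr_ms": s.rr_ms}).to_csv(out / f"{s.subject_id}_rr.csv", index=False)
        eeg_df = pd.DataFrame(s.eeg.T, columns=CHANNELS_1020[: s.eeg.shape[0]])
        eeg_df.to_csv(out / f"{s.subject_id}_eeg.csv", index=False, float_format="%.5f")
    cohort.truth.to_csv(truth_path, sep="\t", index=False, float_format="%.6f")
    meta = cohort.truth[["id", "group", "IQ"]]
    meta.to_csv(out / "subjects.csv", index=False, float_format="%.4f")
    (out / "cohort_meta.json").write_text(
        pd.Series(
            {
                "eeg_fs": cohort.spec.eeg_fs,
                "ecg_fs": cohort.spec.ecg_fs,
                "duration_s": cohort.spec.duration_s,
                "cardiac_modality": cohort.spec.cardiac_modality,
                "seed": cohort.spec.seed,
            }
        ).to_json()
    )
    return out
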