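"""Synthetic eyes-closed frontal EEG cohorts.

Each channel is band-limited Gaussian noise, synthesized by FFT-domain
spectral shaping: a target power spectral density built from a 1/f^beta
background, seven flat band plateaus whose log-powers carry the
class-conditional contrasts, and a narrowband alpha bump near 10 Hz (the
dominant eyes-closed frontal feature).  Between-subject variability is a
random effect on the log-power scale (multiplicative physiological
variation, keeps powers positive); the three channels share each subject's
band weights with small independent jitter.

The default class contrast encodes a frontal-slowing pattern — the patient
class has elevated relative theta and low-gamma, reduced relative
high-gamma, and slightly reduced delta — so group analyses on simulated
cohorts reproduce those signs.  The generator makes no attempt at
biophysical realism beyond the spectrum: no eye-blink or muscle artifacts,
no nonstationarity, no volume conduction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .evaluation import bootstrap_mean_ci, cliffs_delta
from .features import DEFAULT_BANDS, per_channel_map
from .io_formats import HC, MDD, Recording
from .preprocessing import qc_filter, segment, zscore_recording

#: Baseline per-band log-power offsets (natural log of relative plateau
#: power) shared by both classes: a realistic eyes-closed frontal profile
#: with dominant delta/alpha and weak gamma.
DEFAULT_BAND_LOGPOWER = {
    "delta": 0.0,
    "theta": -0.7,
    "alpha": -0.2,
    "beta": -1.2,
    "gamma_low": -2.2,
    "gamma_mid": -2.6,
    "gamma_high": -3.0,
}

#: Class-conditional shifts added to the patient class, on the log-power
#: scale: theta and low-gamma up, high-gamma down, delta slightly down
#: (frontal slowing).
DEFAULT_MDD_SHIFT = {
    "delta": -0.25,
    "theta": 0.55,
    "alpha": 0.0,
    "beta": 0.0,
    "gamma_low": 0.35,
    "gamma_mid": 0.0,
    "gamma_high": -0.65,
}


@dataclass(frozen=True)
class CohortSpec:
    """Generation parameters for one synthetic cohort.

    Band log-powers are per-class means; per-band class SD and the
    between-subject random-effect SD are on the same log scale, so a class
    gap of g with subject_effect_sd s is a g/s-SD contrast.
    """

    n_hc: int = 12
    n_mdd: int = 8
    fs: float = 250.0
    duration_s: float = 90.0
    band_logpower_hc: dict = field(default_factory=lambda: dict(DEFAULT_BAND_LOGPOWER))
    mdd_shift: dict = field(default_factory=lambda: dict(DEFAULT_MDD_SHIFT))
    band_logpower_sd: float = 0.30
    subject_effect_sd: float = 0.20
    channel_jitter_sd: float = 0.05
    alpha_peak_hz: float = 10.0
    alpha_peak_width_hz: float = 1.0
    alpha_peak_logpower: float = 0.4
    one_over_f_exponent: float = 1.0
    background_weight: float = 0.15
    seed: int = 42

    def __post_init__(self) -> None:
        if self.n_hc < 0 or self.n_mdd < 0:
            raise ValueError("subject counts must be nonnegative")
        if self.duration_s <= 0 or self.fs <= 0:
            raise ValueError("duration and sampling rate must be positive")


def _target_psd(
    freqs: np.ndarray, band_logpowers: np.ndarray, spec: CohortSpec
) -> np.ndarray:
    """Target PSD: band plateaus + 1/f^beta background + alpha bump."""
    psd = np.zeros_like(freqs)
    for (name, lo, hi), logp in zip(DEFAULT_BANDS.bands, band_logpowers):
        mask = (freqs >= lo) & (freqs < hi)
        width = hi - lo
        psd[mask] += np.exp(logp) / width
    with np.errstate(divide="ignore"):
        bg = np.where(freqs > 0, freqs, np.inf) ** (-spec.one_over_f_exponent)
    inband = (freqs >= 0.5) & (freqs <= 100.0)
    psd += spec.background_weight * np.where(inband, bg, 0.0)
    psd += np.exp(spec.alpha_peak_logpower) * np.exp(
        -0.5 * ((freqs - spec.alpha_peak_hz) / spec.alpha_peak_width_hz) ** 2
    )
    psd[freqs == 0] = 0.0
    return psd


def simulate_recording(
    label: str,
    spec: CohortSpec,
    rng: np.random.Generator,
    subject_id: str = "S0",
) -> Recording:
    """One three-channel recording of the given class.

    White noise is shaped in the rFFT domain by the square root of the
    subject's target PSD; the subject's band log-powers are the class means
    plus per-band class noise plus a shared subject random effect, and each
    channel adds small independent jitter.
    """
    if label not in (HC, MDD):
        raise ValueError(f"unknown class {label!r}")
    T = int(round(spec.duration_s * spec.fs))
    freqs = np.fft.rfftfreq(T, d=1.0 / spec.fs)
    names = DEFAULT_BANDS.names
    means = np.array(
        [
            spec.band_logpower_hc[n] + (spec.mdd_shift[n] if label == MDD else 0.0)
            for n in names
        ]
    )
    subject_logp = (
        means
        + rng.normal(0.0, spec.band_logpower_sd, size=len(names))
        + rng.normal(0.0, spec.subject_effect_sd)
    )
    data = np.empty((T, 3))
    for ch in range(3):
        ch_logp = subject_logp + rng.normal(0.0, spec.channel_jitter_sd, size=len(names))
        psd = _target_psd(freqs, ch_logp, spec)
        white = rng.standard_normal(T)
        shaped = np.fft.rfft(white) * np.sqrt(psd)
        data[:, ch] = np.fft.irfft(shaped, n=T)
    return Recording(
        subject_id=subject_id,
        label=label,
        fs=spec.fs,
        data=data,
        meta={"synthetic": True, "band_logpower": dict(zip(names, subject_logp))},
    )


def simulate_cohort(spec: CohortSpec) -> tuple[list[Recording], pd.DataFrame]:
    """n_hc + n_mdd recordings with disjoint subject IDs, plus a manifest."""
    rng = np.random.default_rng(spec.seed)
    recordings: list[Recording] = []
    rows = []
    counter = 1
    for label, n in ((HC, spec.n_hc), (MDD, spec.n_mdd)):
        for _ in range(n):
            sid = f"S{counter:03d}"
            counter += 1
            rec = simulate_recording(label, spec, rng, subject_id=sid)
            recordings.append(rec)
            rows.append(
                {"subject_id": sid, "label": label, "duration_s": rec.duration_s}
            )
    manifest = pd.DataFrame(rows, columns=["subject_id", "label", "duration_s"])
    return recordings, manifest


@dataclass
class SpectralContrast:
    band: str
    channel: str
    delta: float  # Cliff's delta, MDD sample first
    hc_mean_ci: tuple[float, float]
    mdd_mean_ci: tuple[float, float]
    per_subject_hc: np.ndarray
    per_subject_mdd: np.ndarray


def verify_spectral_contrast(
    recordings: Sequence[Recording],
    band: str,
    channel: str = "Fp2",
    L: int = 3840,
    p: float = 50.0,
    bootstrap_B: int = 4000,
    seed: int = 0,
) -> SpectralContrast:
    """Subject-level group comparison of one relative band power.

    Window-level features are aggregated per subject first (mean over
    windows) to avoid pseudo-replication, then Cliff's delta (MDD vs HC)
    and per-class bootstrap CIs of the mean are computed — the same
    aggregate-then-compare pattern used for cohort sanity checks.
    """
    ch_idx = {"Fp1": 0, "Fz": 1, "Fp2": 2}[channel]
    b_idx = DEFAULT_BANDS.index(band)
    per_class: dict[str, list[float]] = {HC: [], MDD: []}
    for rec in recordings:
        ws = segment(zscore_recording(rec), L, p)
        ws, _ = qc_filter(ws)
        if ws.n_windows == 0:
            continue
        vals = [
            per_channel_map(ws.windows[i], rec.fs)[ch_idx, b_idx]
            for i in range(ws.n_windows)
        ]
        per_class[rec.label].append(float(np.mean(vals)))
    if not per_class[HC] or not per_class[MDD]:
        raise ValueError("both classes must be present in the cohort")
    hc = np.asarray(per_class[HC])
    mdd = np.asarray(per_class[MDD])
    return SpectralContrast(
        band=band,
        channel=channel,
        delta=cliffs_delta(mdd, hc),
        hc_mean_ci=bootstrap_mean_ci(hc, B=bootstrap_B, seed=seed),
        mdd_mean_ci=bootstrap_mean_ci(mdd, B=bootstrap_B, seed=seed + 1),
        per_subject_hc=hc,
        per_subject_mdd=mdd,
    )


def well_separated_spec(n_hc: int, n_mdd: int, seed: int = 42,
                        duration_s: float = 90.0) -> CohortSpec:
    """A strongly separated cohort: theta and high-gamma class gaps of at
    least one between-subject SD, for end-to-end pipeline checks."""
    shift = dict(DEFAULT_MDD_SHIFT)
    shift["theta"] = 0.8
    shift["gamma_high"] = -0.9
    return CohortSpec(
        n_hc=n_hc,
        n_mdd=n_mdd,
        duration_s=duration_s,
        mdd_shift=shift,
        band_logpower_sd=0.20,
        subject_effect_sd=0.20,
        seed=seed,
    )
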