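"""Spectral-statistical features for three-channel EEG windows.

Per window and channel: Welch PSD (Hann window of length 2*fs, overlap fs,
constant detrend, 0.5 Hz grid), seven relative band powers over the
canonical bands (delta through high gamma, normalized by total 0.5-100 Hz
power), and the Gaussian differential entropy h = 0.5*ln(2*pi*e*sigma^2).

Two derived containers feed the models: a 3 x 8 per-channel map (7 relative
powers + DE per channel, preserving channel identity), and a 17-value
global vector (mean/SD/skewness/kurtosis per channel, then five spectral
ratios of channel-averaged relative powers).  DE appears only in the map.

Band edges are half-open [lo, hi) on the discrete Welch grid, with the last
band closed at 100 Hz, so the seven bands tile the total range exactly and
the relative powers sum to 1 by construction.  Band and total power use the
same rectangle rule (bin sum x df), which makes the normalization identity
exact rather than approximate.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import signal as sps
from scipy import stats as sstats

RATIO_FLOOR = 1e-12
DE_VARIANCE_FLOOR = 1e-12


@dataclass(frozen=True)
class BandScheme:
    """Contiguous, non-overlapping frequency bands tiling total_range."""

    bands: tuple[tuple[str, float, float], ...] = (
        ("delta", 0.5, 4.0),
        ("theta", 4.0, 8.0),
        ("alpha", 8.0, 13.0),
        ("beta", 13.0, 30.0),
        ("gamma_low", 30.0, 45.0),
        ("gamma_mid", 45.0, 70.0),
        ("gamma_high", 70.0, 100.0),
    )

    def __post_init__(self) -> None:
        for (_, _, hi), (_, lo2, _) in zip(self.bands, self.bands[1:]):
            if hi != lo2:
                raise ValueError("bands must be contiguous and non-overlapping")

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(name for name, _, _ in self.bands)

    @property
    def total_range(self) -> tuple[float, float]:
        return (self.bands[0][1], self.bands[-1][2])

    def index(self, name: str) -> int:
        return self.names.index(name)


DEFAULT_BANDS = BandScheme()

#: Numerator/denominator band names for the five spectral-balance ratios,
#: in global-vector order.
RATIO_DEFS = (
    ("delta", "gamma_low"),
    ("delta", "gamma_mid"),
    ("theta", "beta"),
    ("theta", "gamma_mid"),
    ("alpha", "gamma_low"),
)

GLOBAL_VECTOR_NAMES = tuple(
    f"{stat}_{ch}"
    for ch in ("Fp1", "Fz", "Fp2")
    for stat in ("mean", "sd", "skewness", "kurtosis")
) + tuple(f"ratio_{a}_over_{b}" for a, b in RATIO_DEFS)


def welch_psd(x: np.ndarray, fs: float) -> tuple[np.ndarray, np.ndarray]:
    """One-sided Welch PSD: Hann taper, segment 2*fs, overlap fs, constant
    detrend; frequency resolution 0.5 Hz.

    Requires at least one full Welch segment (L >= 2*fs).
    """
    x = np.asarray(x, dtype=np.float64)
    nperseg = int(round(2 * fs))
    if x.shape[-1] < nperseg:
        raise ValueError(
            f"window of {x.shape[-1]} samples is shorter than one Welch segment "
            f"(2*fs = {nperseg}); use longer windows"
        )
    freqs, psd = sps.welch(
        x,
        fs=fs,
        window="hann",
        nperseg=nperseg,
        noverlap=nperseg // 2,
        detrend="constant",
    )
    return freqs, psd


def _band_masks(freqs: np.ndarray, scheme: BandScheme) -> list[np.ndarray]:
    masks = []
    f_hi_total = scheme.total_range[1]
    for i, (_, lo, hi) in enumerate(scheme.bands):
        if i == len(scheme.bands) - 1:
            masks.append((freqs >= lo) & (freqs <= f_hi_total))
        else:
            masks.append((freqs >= lo) & (freqs < hi))
    return masks


def relative_band_powers(
    freqs: np.ndarray, psd: np.ndarray, scheme: BandScheme = DEFAULT_BANDS
) -> np.ndarray:
    """Seven relative band powers, normalized by total 0.5-100 Hz power.

    Both integrals use the rectangle rule on the Welch grid, so the seven
    values sum to 1 exactly for any non-degenerate spectrum.
    """
    freqs = np.asarray(freqs)
    psd = np.asarray(psd, dtype=np.float64)
    if freqs[-1] < scheme.total_range[1]:
        raise ValueError(
            f"frequency grid tops out at {freqs[-1]} Hz; needs to cover "
            f"{scheme.total_range[1]} Hz"
        )
    masks = _band_masks(freqs, scheme)
    band_powers = np.array([psd[..., m].sum(axis=-1) for m in masks])
    total = band_powers.sum(axis=0)
    if np.any(total <= 0):
        raise ValueError("zero total power in 0.5-100 Hz; window should have been QC-removed")
    return np.moveaxis(band_powers / total, 0, -1)


def differential_entropy(x: np.ndarray) -> float:
    """Gaussian differential entropy 0.5*ln(2*pi*e*sigma^2) in nats.

    sigma^2 is the (biased) sample variance of the window, floored at 1e-12.
    """
    x = np.asarray(x, dtype=np.float64)
    if x.size < 2:
        raise ValueError("need at least 2 samples")
    var = max(float(np.var(x)), DE_VARIANCE_FLOOR)
    return 0.5 * np.log(2.0 * np.pi * np.e * var)


def per_channel_map(
    window: np.ndarray, fs: float, scheme: BandScheme = DEFAULT_BANDS
) -> np.ndarray:
    """3 x 8 per-channel map: row = (7 relative band powers, DE)."""
    window = np.asarray(window, dtype=np.float64)
    freqs, psd = welch_psd(window.T, fs)  # psd: 3 x F
    rel = relative_band_powers(freqs, psd, scheme)  # 3 x 7
    de = np.array([differential_entropy(window[:, ch]) for ch in range(3)])
    return np.column_stack([rel, de])


def global_vector(
    window: np.ndarray,
    per_channel_relpowers: np.ndarray,
    scheme: BandScheme = DEFAULT_BANDS,
) -> np.ndarray:
    """17-value global vector: 12 moments then 5 spectral ratios.

    Moments per channel, in channel order: mean, SD, skewness
    (Fisher-Pearson), kurtosis (Pearson, non-excess); all bias-uncorrected.
    Ratios divide channel-averaged relative band powers, with denominators
    floored at 1e-12.
    """
    window = np.asarray(window, dtype=np.float64)
    rel = np.asarray(per_channel_relpowers, dtype=np.float64)
    moments = np.empty((3, 4))
    moments[:, 0] = window.mean(axis=0)
    moments[:, 1] = window.std(axis=0)
    moments[:, 2] = sstats.skew(window, axis=0, bias=True)
    moments[:, 3] = sstats.kurtosis(window, axis=0, fisher=False, bias=True)
    avg = rel.mean(axis=0)  # channel-averaged relative powers, length 7
    ratios = np.array(
        [
            avg[scheme.index(a)] / max(avg[scheme.index(b)], RATIO_FLOOR)
            for a, b in RATIO_DEFS
        ]
    )
    return np.concatenate([moments.ravel(), ratios])


@dataclass
class FeatureBundleSet:
    """Aligned per-window model inputs: raw windows, 3x8 maps, 17-dim vectors."""

    raw: np.ndarray  # N x L x 3
    maps: np.ndarray  # N x 3 x 8
    glob: np.ndarray  # N x 17
    subject_ids: np.ndarray
    labels: np.ndarray
    fs: float

    @property
    def n(self) -> int:
        return self.raw.shape[0]

    def subset(self, mask: np.ndarray) -> "FeatureBundleSet":
        return FeatureBundleSet(
            raw=self.raw[mask],
            maps=self.maps[mask],
            glob=self.glob[mask],
            subject_ids=self.subject_ids[mask],
            labels=self.labels[mask],
            fs=self.fs,
        )


def compute_bundles(ws, scheme: BandScheme = DEFAULT_BANDS) -> FeatureBundleSet:
    """Compute the per-window FeatureBundle triple for a QC-passed WindowSet."""
    n = ws.n_windows
    L = ws.windows.shape[1]
    maps = np.empty((n, 3, 8))
    glob = np.empty((n, 17))
    for i in range(n):
        w = ws.windows[i]
        m = per_channel_map(w, ws.params.fs, scheme)
        maps[i] = m
        glob[i] = global_vector(w, m[:, :7], scheme)
    return FeatureBundleSet(
        raw=ws.windows.astype(np.float64).reshape(n, L, 3),
        maps=maps,
        glob=glob,
        subject_ids=ws.subject_ids.copy(),
        labels=ws.labels.copy(),
        fs=ws.params.fs,
    )


def export_feature_table(bundles: FeatureBundleSet, path) -> None:
    """Window-level feature CSV for classical-baseline interoperability.

    One row per window: subject_id, label, the 24 map values
    (channel-major), then the 17 global values.
    """
    import pandas as pd

    map_cols = [
        f"map_{ch}_{feat}"
        for ch in ("Fp1", "Fz", "Fp2")
        for feat in DEFAULT_BANDS.names + ("de",)
    ]
    df = pd.DataFrame(bundles.maps.reshape(bundles.n, 24), columns=map_cols)
    for j, name in enumerate(GLOBAL_VECTOR_NAMES):
        df[name] = bundles.glob[:, j]
    df.insert(0, "label", bundles.labels)
    df.insert(0, "subject_id", bundles.subject_ids)
    df.to_csv(path, index=False)
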