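"""Reading and writing three-channel frontal EEG and pipeline outputs.

Every reader harmonizes its input to the canonical channel order
(Fp1, Fz, Fp2).  Native amplitude units are kept as-is on ingest: the
downstream per-recording z-scoring removes scale, so microvolts versus
arbitrary units is irrelevant to the pipeline.

EDF reading goes through MNE.  Writing uses a minimal EDF encoder (16-bit
samples, one data record spanning the whole recording), sufficient for
round-tripping synthetic cohorts through the standard container format.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

HC = "HC"
MDD = "MDD"
UNKNOWN = "unknown"

CANONICAL_CHANNELS = ("Fp1", "Fz", "Fp2")

#: Default alias fragments for resolving vendor-specific EDF labels,
#: e.g. "EEG Fp1-LE" or "FP1-A2" both resolve to Fp1.
DEFAULT_CHANNEL_ALIASES: dict[str, tuple[str, ...]] = {
    "Fp1": ("fp1",),
    "Fz": ("fz",),
    "Fp2": ("fp2",),
}


class ChannelResolutionError(ValueError):
    """A required target channel could not be matched in the source file."""


class FormatError(ValueError):
    """Structurally invalid input file."""


@dataclass
class Recording:
    """One subject's continuous three-channel EEG.

    data is a T x 3 array ordered (Fp1, Fz, Fp2); amplitudes are in native
    units on ingest and in z-units after standardization.  Finiteness is not
    guaranteed structurally — quality control handles that downstream.
    """

    subject_id: str
    label: str  # HC, MDD, or UNKNOWN
    fs: float
    data: np.ndarray
    channel_names: tuple[str, str, str] = CANONICAL_CHANNELS
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2 or self.data.shape[1] != 3:
            raise ValueError("Recording data must be a T x 3 array")
        if self.data.shape[0] < 1:
            raise ValueError("Recording must contain at least one sample")
        if not self.fs > 0:
            raise ValueError("sampling rate must be positive")

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs


@dataclass(frozen=True)
class SubjectPrediction:
    """Voted subject decision with vote bookkeeping and confidence."""

    subject_id: str
    voted_label: str
    n_windows: int
    votes_hc: int
    votes_mdd: int
    confidence: float
    true_label: str | None = None


def _resolve_channels(
    labels: Sequence[str], channel_map: Mapping[str, Iterable[str]] | None
) -> dict[str, str]:
    """Map canonical names to source labels, case-insensitive and alias-aware."""
    aliases = {k: tuple(v) for k, v in (channel_map or DEFAULT_CHANNEL_ALIASES).items()}
    resolved: dict[str, str] = {}
    for target in CANONICAL_CHANNELS:
        frags = aliases.get(target, (target.lower(),))
        # Prefer 'fp1' not matching inside 'fp10' style labels by taking the
        # shortest matching source label; labels are matched on substring.
        hits = [lab for lab in labels if any(f in lab.lower() for f in frags)]
        if not hits:
            raise ChannelResolutionError(
                f"channel {target!r} not found among {list(labels)!r}"
            )
        resolved[target] = min(hits, key=len)
    return resolved


def read_edf(
    path: str | Path, channel_map: Mapping[str, Iterable[str]] | None = None
) -> Recording:
    """Read an EDF/EDF+ file, keeping only (Fp1, Fz, Fp2) in canonical order.

    The sampling rate is taken from the EDF header.  The three target
    channels must share one sampling rate; EDF files with per-channel rates
    that disagree on the targets are rejected.
    """
    import mne

    path = Path(path)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    resolved = _resolve_channels(raw.ch_names, channel_map)
    # mne resamples mixed-rate EDF channels to the maximum rate on load;
    # detect genuine per-channel disagreement from the raw header instead.
    rates = _edf_channel_rates(path)
    if rates:
        target_rates = {
            round(rates[lab], 6) for lab in resolved.values() if lab in rates
        }
        if len(target_rates) > 1:
            raise FormatError(
                f"inconsistent sampling rates among target channels: {sorted(target_rates)}"
            )
    picks = [resolved[c] for c in CANONICAL_CHANNELS]
    data = raw.get_data(picks=picks).T  # T x 3
    return Recording(
        subject_id=path.stem,
        label=UNKNOWN,
        fs=float(raw.info["sfreq"]),
        data=data,
        meta={"source": str(path), "source_channels": picks},
    )


def _edf_channel_rates(path: Path) -> dict[str, float]:
    """Per-channel sampling rates straight from the EDF header."""
    with open(path, "rb") as f:
        header = f.read(256)
        if len(header) < 256:
            return {}
        try:
            ns = int(header[252:256].decode("ascii").strip())
            record_dur = float(header[244:252].decode("ascii").strip())
        except ValueError:
            return {}
        sig = f.read(ns * 256)
        labels = [
            sig[i * 16 : (i + 1) * 16].decode("ascii", "replace").strip()
            for i in range(ns)
        ]
        off = ns * (16 + 80 + 8 + 8 + 8 + 8 + 8 + 80)
        counts = [
            int(sig[off + i * 8 : off + (i + 1) * 8].decode("ascii").strip())
            for i in range(ns)
        ]
    if record_dur <= 0:
        return {}
    return {lab: cnt / record_dur for lab, cnt in zip(labels, counts)}


def write_edf(
    rec: Recording, path: str | Path, channel_labels: Sequence[str] | None = None
) -> Path:
    """Write a Recording as a minimal EDF file (16-bit, one data record).

    Each channel is scaled to its own physical min/max over the recording;
    samples are quantized to the 16-bit digital range, so round-trip error
    is bounded by (physical range)/65534 per channel.  channel_labels
    overrides the stored labels (e.g. vendor-style "EEG Fp1-LE").
    """
    path = Path(path)
    labels = tuple(channel_labels or CANONICAL_CHANNELS)
    T = rec.n_samples
    dig_min, dig_max = -32767, 32767
    chunks = []
    phys = []
    for ch in range(3):
        x = np.nan_to_num(rec.data[:, ch], nan=0.0, posinf=0.0, neginf=0.0)
        lo, hi = float(np.min(x)), float(np.max(x))
        if hi - lo < 1e-12:
            hi = lo + 1.0
        scale = (dig_max - dig_min) / (hi - lo)
        dig = np.round((x - lo) * scale + dig_min).astype("<i2")
        chunks.append(dig)
        phys.append((lo, hi))

    def pad(text: str, width: int) -> bytes:
        return text.encode("ascii")[:width].ljust(width)

    record_dur = T / rec.fs
    hdr = b"".join(
        [
            pad("0", 8),
            pad(f"X X X {rec.subject_id}", 80),
            pad("Startdate X X X X", 80),
            pad("01.01.00", 8),
            pad("00.00.00", 8),
            pad(str(256 + 3 * 256), 8),
            pad("", 44),
            pad("1", 8),  # one data record
            pad(f"{record_dur:.6f}"[:8], 8),
            pad("3", 4),
        ]
    )
    sig = b"".join(pad(name, 16) for name in labels)
    sig += b"".join(pad("", 80) for _ in range(3))
    sig += b"".join(pad("uV", 8) for _ in range(3))
    sig += b"".join(pad(f"{lo:.6g}"[:8], 8) for lo, _ in phys)
    sig += b"".join(pad(f"{hi:.6g}"[:8], 8) for _, hi in phys)
    sig += b"".join(pad(str(dig_min), 8) for _ in range(3))
    sig += b"".join(pad(str(dig_max), 8) for _ in range(3))
    sig += b"".join(pad("", 80) for _ in range(3))
    sig += b"".join(pad(str(T), 8) for _ in range(3))
    sig += b"".join(pad("", 32) for _ in range(3))  # per-signal reserved
    with open(path, "wb") as f:
        f.write(hdr + sig)
        for dig in chunks:
            f.write(dig.tobytes())
    return path


def read_csv3(
    path: str | Path,
    fs: float,
    subject_id: str | None = None,
    label: str = UNKNOWN,
) -> Recording:
    """Read a >=3-column numeric CSV whose first three columns are Fp1, Fz, Fp2.

    A single non-numeric first row is treated as a header.  Extra columns
    (full amplifier montages) are ignored; row order is preserved.
    """
    import pandas as pd

    path = Path(path)
    first = _first_data_line(path)
    has_header = not _row_is_numeric(first)
    df = pd.read_csv(path, header=0 if has_header else None,
                     float_precision="round_trip")
    if df.shape[1] < 3:
        raise FormatError(f"{path}: need >= 3 columns, found {df.shape[1]}")
    sub = df.iloc[:, :3]
    arr = sub.apply(pd.to_numeric, errors="coerce").to_numpy(dtype=np.float64)
    raw_nonnum = sub.isna().to_numpy()
    bad = np.nonzero(np.isnan(arr) & ~raw_nonnum)
    if bad[0].size:
        raise FormatError(f"{path}: unparseable numeric cell at data row {bad[0][0]}")
    return Recording(
        subject_id=subject_id or path.stem,
        label=label,
        fs=fs,
        data=arr,
        meta={"source": str(path)},
    )


def _first_data_line(path: Path) -> list[str]:
    with open(path, "r", encoding="utf-8") as f:
        return next(csv.reader(f))


def _row_is_numeric(cells: Sequence[str]) -> bool:
    try:
        [float(c) for c in cells[:3]]
        return True
    except ValueError:
        return False


def write_csv3(rec: Recording, path: str | Path, header: bool = True) -> Path:
    """Write a Recording's three channels as CSV.

    Values are formatted with repr-faithful precision (%.17g) so that
    write-then-read round-trips bit-for-bit for finite data.
    """
    path = Path(path)
    with open(path, "w", encoding="utf-8", newline="") as f:
        if header:
            f.write(",".join(CANONICAL_CHANNELS) + "\n")
        np.savetxt(f, rec.data, fmt="%.17g", delimiter=",")
    return path


PREDICTION_COLUMNS = (
    "subject_id",
    "voted_label",
    "n_windows",
    "votes_HC",
    "votes_MDD",
    "confidence",
)


def write_predictions(preds: Sequence[SubjectPrediction], path: str | Path) -> Path:
    """Write subject predictions as CSV, one row per subject, sorted by ID."""
    path = Path(path)
    with open(path, "w", encoding="utf-8", newline="") as f:
        writer = csv.writer(f)
        writer.writerow(PREDICTION_COLUMNS)
        for p in sorted(preds, key=lambda p: p.subject_id):
            writer.writerow(
                [
                    p.subject_id,
                    p.voted_label,
                    p.n_windows,
                    p.votes_hc,
                    p.votes_mdd,
                    f"{p.confidence:.17g}",
                ]
            )
    return path


def read_predictions(path: str | Path) -> list[SubjectPrediction]:
    with open(path, "r", encoding="utf-8") as f:
        rows = list(csv.DictReader(f))
    return [
        SubjectPrediction(
            subject_id=r["subject_id"],
            voted_label=r["voted_label"],
            n_windows=int(r["n_windows"]),
            votes_hc=int(r["votes_HC"]),
            votes_mdd=int(r["votes_MDD"]),
            confidence=float(r["confidence"]),
        )
        for r in rows
    ]
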