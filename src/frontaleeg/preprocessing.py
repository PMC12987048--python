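"""Per-recording standardization, overlapped segmentation, and window QC.

The pipeline is deliberately minimal: each channel is z-scored over the
whole recording (no filtering, no resampling, no ICA/ASR), the trace is cut
into fixed-length windows with stride S = round(L * (1 - p/100)), and basic
quality control drops windows with non-finite values, zero variance, or
rail-pinned saturation plateaus.  Sample indices are 0-based and window
intervals are half-open [start, start + L).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .io_formats import Recording

SD_FLOOR = 1e-8
VARIANCE_FLOOR = 1e-12
#: 0.1 s at 250 Hz: minimum run length at a channel's recording-level
#: extreme for a window to count as clipped/saturated.
DEFAULT_CLIP_RUN_SAMPLES = 25


@dataclass(frozen=True)
class SegmentationParams:
    """Window length L (samples), overlap percent p, derived stride S."""

    L: int
    p: float
    fs: float

    def __post_init__(self) -> None:
        if self.L < 1:
            raise ValueError("window length must be >= 1 sample")
        if not 0 <= self.p < 100:
            raise ValueError("overlap percent must be in [0, 100)")

    @property
    def S(self) -> int:
        stride = int(round(self.L * (1.0 - self.p / 100.0)))
        return max(1, min(stride, self.L))

    @property
    def duration_s(self) -> float:
        return self.L / self.fs


@dataclass
class WindowSet:
    """Fixed-length windows with per-window provenance.

    windows: N x L x 3 (z-units); subject_ids/labels/window_start_samples are
    length-N; source_extrema is N x 3 x 2 carrying each source recording's
    per-channel (min, max), used by the clipping detector.
    """

    windows: np.ndarray
    subject_ids: np.ndarray
    labels: np.ndarray
    params: SegmentationParams
    window_start_samples: np.ndarray
    source_extrema: np.ndarray

    @property
    def n_windows(self) -> int:
        return self.windows.shape[0]

    def subset(self, mask: np.ndarray) -> "WindowSet":
        return WindowSet(
            windows=self.windows[mask],
            subject_ids=self.subject_ids[mask],
            labels=self.labels[mask],
            params=self.params,
            window_start_samples=self.window_start_samples[mask],
            source_extrema=self.source_extrema[mask],
        )

    @staticmethod
    def concatenate(sets: Sequence["WindowSet"]) -> "WindowSet":
        sets = [s for s in sets if s.n_windows > 0]
        if not sets:
            raise ValueError("nothing to concatenate")
        params = sets[0].params
        if any(s.params != params for s in sets):
            raise ValueError("all WindowSets must share segmentation parameters")
        return WindowSet(
            windows=np.concatenate([s.windows for s in sets]),
            subject_ids=np.concatenate([s.subject_ids for s in sets]),
            labels=np.concatenate([s.labels for s in sets]),
            params=params,
            window_start_samples=np.concatenate(
                [s.window_start_samples for s in sets]
            ),
            source_extrema=np.concatenate([s.source_extrema for s in sets]),
        )


@dataclass
class QCReport:
    """Removal counts by cause, overall and per subject."""

    n_input: int = 0
    n_retained: int = 0
    removed_by_cause: dict = field(default_factory=dict)
    removed_per_subject: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(
            {
                "n_input": self.n_input,
                "n_retained": self.n_retained,
                "removed_by_cause": self.removed_by_cause,
                "removed_per_subject": self.removed_per_subject,
            },
            indent=2,
        )


def zscore_recording(rec: Recording) -> Recording:
    """Standardize each channel to mean 0, SD 1 over the full recording.

    The SD is floored at 1e-8; an all-constant channel is flagged with a
    warning and left to downstream QC (its windows have zero variance).
    """
    if rec.n_samples < 2:
        raise ValueError("z-scoring requires at least 2 samples")
    mean = rec.data.mean(axis=0)
    sd = rec.data.std(axis=0)
    flat = sd < SD_FLOOR
    if np.any(flat):
        warnings.warn(
            f"recording {rec.subject_id}: constant channel(s) "
            f"{[i for i in range(3) if flat[i]]}; SD floored",
            RuntimeWarning,
            stacklevel=2,
        )
    z = (rec.data - mean) / np.maximum(sd, SD_FLOOR)
    return Recording(
        subject_id=rec.subject_id,
        label=rec.label,
        fs=rec.fs,
        data=z,
        channel_names=rec.channel_names,
        meta={**rec.meta, "zscored": True},
    )


def segment(rec: Recording, L: int, p: float) -> WindowSet:
    """Cut a (z-scored) recording into N = floor((T - L)/S) + 1 windows.

    The trailing partial window is discarded; a recording shorter than one
    window yields an empty WindowSet (an exclusion outcome, not an error).
    """
    params = SegmentationParams(L=L, p=p, fs=rec.fs)
    S = params.S
    T = rec.n_samples
    if T < L:
        n = 0
        starts = np.zeros(0, dtype=int)
    else:
        n = (T - L) // S + 1
        starts = np.arange(n) * S
    windows = np.stack([rec.data[s : s + L] for s in starts]) if n else np.zeros(
        (0, L, 3)
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # all-NaN channels handled by QC
        extrema = np.stack(
            [np.nanmin(rec.data, axis=0), np.nanmax(rec.data, axis=0)], axis=-1
        )
    return WindowSet(
        windows=windows,
        subject_ids=np.array([rec.subject_id] * n, dtype=object),
        labels=np.array([rec.label] * n, dtype=object),
        params=params,
        window_start_samples=starts,
        source_extrema=np.broadcast_to(extrema, (n, 3, 2)).copy(),
    )


def _max_run_at_value(x: np.ndarray, value: float, atol: float = 1e-12) -> int:
    """Longest run of consecutive samples equal to value within atol."""
    hit = np.abs(x - value) <= atol
    if not hit.any():
        return 0
    # run-length encode the boolean mask
    changes = np.diff(hit.astype(np.int8))
    starts = np.flatnonzero(changes == 1) + 1
    ends = np.flatnonzero(changes == -1) + 1
    if hit[0]:
        starts = np.r_[0, starts]
    if hit[-1]:
        ends = np.r_[ends, hit.size]
    return int(np.max(ends - starts))


def window_is_clipped(
    window: np.ndarray, extrema: np.ndarray, clip_run_samples: int = DEFAULT_CLIP_RUN_SAMPLES
) -> bool:
    """Rail-pinned saturation: a run >= clip_run_samples at a channel's
    recording-level min or max."""
    for ch in range(window.shape[1]):
        for rail in extrema[ch]:
            if _max_run_at_value(window[:, ch], rail) >= clip_run_samples:
                return True
    return False


def qc_filter(
    ws: WindowSet, clip_run_samples: int = DEFAULT_CLIP_RUN_SAMPLES
) -> tuple[WindowSet, QCReport]:
    """Drop windows with non-finite values, zero variance, or clipping.

    Causes are checked in that order; each removed window is charged to the
    first cause that fires.
    """
    report = QCReport(n_input=ws.n_windows)
    keep = np.ones(ws.n_windows, dtype=bool)
    for i in range(ws.n_windows):
        w = ws.windows[i]
        if not np.all(np.isfinite(w)):
            cause = "nonfinite"
        elif np.any(w.var(axis=0) <= VARIANCE_FLOOR):
            cause = "zero_variance"
        elif window_is_clipped(w, ws.source_extrema[i], clip_run_samples):
            cause = "clipping"
        else:
            continue
        keep[i] = False
        report.removed_by_cause[cause] = report.removed_by_cause.get(cause, 0) + 1
        sid = str(ws.subject_ids[i])
        report.removed_per_subject.setdefault(sid, {}).setdefault(cause, 0)
        report.removed_per_subject[sid][cause] += 1
    retained = ws.subset(keep)
    report.n_retained = retained.n_windows
    return retained, report


def prepare_windows(
    recordings: Iterable[Recording],
    L: int,
    p: float,
    clip_run_samples: int = DEFAULT_CLIP_RUN_SAMPLES,
    max_removed_fraction: float = 0.20,
) -> tuple[WindowSet, QCReport, list[str]]:
    """Full preprocessing: z-score, segment, QC, recording-level exclusion.

    Recordings shorter than one window, or with more than
    max_removed_fraction of their windows removed by QC, are excluded and
    listed in the returned exclusion list.  The contamination threshold is
    interpretive (the underlying criterion is a visual-inspection rule) and
    configurable.
    """
    kept_sets: list[WindowSet] = []
    excluded: list[str] = []
    report = QCReport()
    for rec in recordings:
        ws = segment(zscore_recording(rec), L, p)
        if ws.n_windows == 0:
            excluded.append(f"{rec.subject_id}: shorter than one window")
            continue
        clean, rep = qc_filter(ws, clip_run_samples)
        report.n_input += rep.n_input
        for cause, cnt in rep.removed_by_cause.items():
            report.removed_by_cause[cause] = report.removed_by_cause.get(cause, 0) + cnt
        report.removed_per_subject.update(rep.removed_per_subject)
        removed_frac = 1.0 - clean.n_windows / ws.n_windows
        if removed_frac > max_removed_fraction:
            excluded.append(
                f"{rec.subject_id}: {removed_frac:.0%} of windows removed by QC"
            )
            continue
        if clean.n_windows:
            kept_sets.append(clean)
    if not kept_sets:
        raise ValueError("no recordings survived preprocessing")
    out = WindowSet.concatenate(kept_sets)
    report.n_retained = out.n_windows
    return out, report, excluded
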