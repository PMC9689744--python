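"""Waveform preprocessing: quality screening, filtering, beat segmentation and labeling.

The chain turns simultaneous PPG/ECG/ABP records into fixed-length labeled
beats: screen for missing data and flat lines, band-pass filter PPG
(0.5-10 Hz) and ECG (0.5-40 Hz), detect R peaks on the filtered ECG, cut all
three channels at consecutive R-R intervals, resample each PPG/ECG beat to
150 samples, read systolic/diastolic pressure off the raw ABP cycle, and
assign one of five American Heart Association blood-pressure categories.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum
from typing import Sequence

import numpy as np
from scipy import signal as sps
from scipy.interpolate import interp1d

logger = logging.getLogger(__name__)

#: Band-pass cut-offs (Hz) per channel.
PPG_BAND = (0.5, 10.0)
ECG_BAND = (0.5, 40.0)

#: Fixed per-beat segment length fed to the classifier.
SEGMENT_LENGTH = 150

#: Minimum spacing between detected R peaks (seconds).
REFRACTORY_S = 0.25


class BPLabel(str, Enum):
    """Five AHA blood-pressure categories plus a sink for out-of-table readings."""

    HYPOTENSION = "hypotension"
    NORMOTENSION = "normotension"
    PREHYPERTENSION = "prehypertension"
    HYPERTENSION_STAGE_1 = "hypertension_stage_1"
    HYPERTENSION_STAGE_2 = "hypertension_stage_2"
    UNCLASSIFIABLE = "unclassifiable"


#: Fixed class order used for label encoding, confusion matrices and reports.
CLASS_ORDER = [
    BPLabel.HYPOTENSION,
    BPLabel.NORMOTENSION,
    BPLabel.PREHYPERTENSION,
    BPLabel.HYPERTENSION_STAGE_1,
    BPLabel.HYPERTENSION_STAGE_2,
]

LABEL_TO_CODE = {lab: i for i, lab in enumerate(CLASS_ORDER)}


def assign_label(sbp: float, dbp: float) -> BPLabel:
    """Map a (systolic, diastolic) pair to an AHA blood-pressure category.

    Rows are evaluated severe-first because the staged rows are OR-joined and
    overlap the milder AND-joined rows (e.g. 125/85 satisfies both the
    prehypertension systolic clause and the stage-1 diastolic clause; the
    higher stage wins, matching clinical staging practice).  Hypotension is
    checked before normotension since its box is a subset of normotension's.
    Readings outside every row (sbp > 180 or dbp > 120, among others) are
    ``UNCLASSIFIABLE``.
    """
    if not (np.isfinite(sbp) and np.isfinite(dbp)):
        raise ValueError("sbp/dbp must be finite")
    if sbp < dbp:
        raise ValueError(f"sbp ({sbp}) must be >= dbp ({dbp})")
    if 140 <= sbp <= 180 or 90 <= dbp <= 120:
        return BPLabel.HYPERTENSION_STAGE_2
    if 130 <= sbp <= 139 or 80 <= dbp <= 89:
        return BPLabel.HYPERTENSION_STAGE_1
    if 120 <= sbp <= 129 and dbp < 80:
        return BPLabel.PREHYPERTENSION
    if sbp < 90 and dbp < 60:
        return BPLabel.HYPOTENSION
    if sbp < 120 and dbp < 80:
        return BPLabel.NORMOTENSION
    return BPLabel.UNCLASSIFIABLE


@dataclass
class BeatTriplet:
    """One cardiac cycle of PPG/ECG/ABP cut at consecutive R peaks."""

    ppg_raw: np.ndarray
    ecg_raw: np.ndarray
    abp_raw: np.ndarray
    start_sample: int
    end_sample: int
    fs: float

    def __post_init__(self) -> None:
        n = self.end_sample - self.start_sample
        if n < 2:
            raise ValueError("beat must span at least 2 samples")
        for name in ("ppg_raw", "ecg_raw", "abp_raw"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} length != end_sample - start_sample")


@dataclass
class LabeledSegment:
    """A 150-sample PPG/ECG beat pair with its blood-pressure label."""

    ppg: np.ndarray
    ecg: np.ndarray
    label: BPLabel
    sbp: float
    dbp: float
    source_record: str = ""
    beat_index: int = 0


@dataclass
class ScreenReport:
    """Per-channel accounting of samples invalidated by quality screening."""

    excluded_samples: dict
    total_samples: int
    rejected: bool = False
    reason: str = ""


@dataclass
class DatasetSplit:
    train: list
    validation: list
    test: list
    split_seed: int = 0


def quality_screen(record, flat_window_s: float = 2.0, flat_rel_tol: float = 1e-3):
    """Mark missing (non-finite) runs and flat-line stretches as invalid.

    A stretch of at least ``flat_window_s`` seconds over which a channel's
    range is below ``flat_rel_tol`` times its overall range counts as a flat
    line (a disconnected sensor).  Non-finite samples are replaced by linear
    interpolation in the returned record so filters stay finite, but remain
    marked invalid; beats that overlap invalid samples are dropped downstream.

    Returns ``(screened_record, ScreenReport)``.  A record whose every sample
    is invalid is returned with ``report.rejected = True`` rather than raising.
    """
    from .synth import WaveformRecord  # local import to avoid cycle at import time

    fs = record.fs
    n = len(record.ppg)
    channels = {"ppg": record.ppg, "ecg": record.ecg, "abp": record.abp}
    win = max(2, int(round(flat_window_s * fs)))
    excluded = {}
    masks = {}
    cleaned = {}
    for name, x in channels.items():
        x = np.asarray(x, dtype=float)
        bad = ~np.isfinite(x)
        xc = x.copy()
        if bad.any():
            good = ~bad
            if good.any():
                xc[bad] = np.interp(np.flatnonzero(bad), np.flatnonzero(good), x[good])
            else:
                xc[:] = 0.0
        finite = xc[np.isfinite(xc)]
        overall = float(np.ptp(finite)) if finite.size else 0.0
        tol = flat_rel_tol * overall if overall > 0 else np.inf
        if overall == 0.0 and n >= win:
            flat = np.ones(n, dtype=bool)
        elif n >= win:
            # range over every window [i, i+win); a flagged window invalidates
            # its whole extent
            sw = np.lib.stride_tricks.sliding_window_view(xc, win)
            starts = np.flatnonzero(sw.max(axis=1) - sw.min(axis=1) < tol)
            diff = np.zeros(n + 1, dtype=int)
            diff[starts] += 1
            diff[starts + win] -= 1
            flat = np.cumsum(diff[:-1]) > 0
        else:
            flat = np.zeros(n, dtype=bool)
        mask = bad | flat
        masks[name] = mask
        cleaned[name] = xc
        excluded[name] = int(mask.sum())
    combined = masks["ppg"] | masks["ecg"] | masks["abp"]
    report = ScreenReport(excluded_samples=excluded, total_samples=n)
    if combined.all():
        report.rejected = True
        report.reason = "all samples invalid"
    screened = WaveformRecord(
        ppg=cleaned["ppg"],
        ecg=cleaned["ecg"],
        abp=cleaned["abp"],
        fs=fs,
        true_r_samples=record.true_r_samples,
        true_beat_bp=record.true_beat_bp,
        record_id=record.record_id,
        invalid_mask=combined,
    )
    return screened, report


def bandpass(x: np.ndarray, fs: float, low: float, high: float, order: int = 4) -> np.ndarray:
    """Zero-phase Butterworth band-pass (applied forward-backward)."""
    if not (0 < low < high < fs / 2):
        raise ValueError(f"require 0 < low < high < fs/2, got low={low}, high={high}, fs={fs}")
    x = np.asarray(x, dtype=float)
    sos = sps.butter(order, [low, high], btype="bandpass", fs=fs, output="sos")
    return sps.sosfiltfilt(sos, x)


def detect_r_peaks(
    ecg_filtered: np.ndarray,
    fs: float,
    refractory_s: float = REFRACTORY_S,
    threshold_frac: float = 0.4,
) -> np.ndarray:
    """Locate R peaks on a band-passed ECG.

    Derivative-squared envelope (a Pan-Tompkins-style transform) smoothed over
    120 ms, candidate peaks at least ``refractory_s`` apart, then an adaptive
    gate at ``threshold_frac`` times the rolling median of the last eight
    accepted envelope heights.  Each accepted candidate is refined to the local
    maximum of the input within +-80 ms so every returned index sits on an ECG
    peak.
    """
    x = np.asarray(ecg_filtered, dtype=float)
    if x.size < int(0.5 * fs) or not np.any(x != 0):
        return np.array([], dtype=int)
    deriv = np.gradient(x)
    env = deriv * deriv
    smooth = max(1, int(round(0.12 * fs)))
    env = np.convolve(env, np.ones(smooth) / smooth, mode="same")
    dist = max(1, int(round(refractory_s * fs)))
    cand, _ = sps.find_peaks(env, distance=dist)
    if cand.size == 0:
        return np.array([], dtype=int)
    bootstrap = float(np.percentile(env[cand], 90))
    if bootstrap <= 0:
        return np.array([], dtype=int)
    recent: list[float] = []
    accepted = []
    for c in cand:
        level = float(np.median(recent)) if recent else bootstrap
        if env[c] > threshold_frac * level:
            accepted.append(c)
            recent.append(float(env[c]))
            if len(recent) > 8:
                recent.pop(0)
    # refine to local maximum of the input ECG
    half = max(1, int(round(0.08 * fs)))
    refined = []
    for c in accepted:
        lo, hi = max(0, c - half), min(x.size, c + half + 1)
        p = lo + int(np.argmax(x[lo:hi]))
        # hill-climb in case the window edge clipped the peak
        while 0 < p < x.size - 1 and x[p + 1] > x[p]:
            p += 1
        while 0 < p < x.size - 1 and x[p - 1] > x[p]:
            p -= 1
        refined.append(p)
    # dedupe while enforcing the refractory period; keep the taller peak
    out: list[int] = []
    for p in sorted(set(refined)):
        if out and p - out[-1] < dist:
            if x[p] > x[out[-1]]:
                out[-1] = p
        else:
            out.append(p)
    return np.asarray(out, dtype=int)


def segment_beats(record, r_peaks: Sequence[int]) -> list:
    """Cut all channels at consecutive R-peak pairs ``[r_k, r_{k+1})``.

    Beats overlapping quality-invalid samples (``record.invalid_mask``) are
    dropped.  Fewer than two peaks yields an empty list.
    """
    r = np.asarray(r_peaks, dtype=int)
    if r.size < 2:
        return []
    if np.any(np.diff(r) <= 0):
        raise ValueError("r_peaks must be strictly increasing")
    if r[0] < 0 or r[-1] > len(record.ppg):
        raise ValueError("r_peaks out of bounds")
    mask = getattr(record, "invalid_mask", None)
    beats = []
    for k in range(r.size - 1):
        a, b = int(r[k]), int(r[k + 1])
        if mask is not None and np.any(mask[a:b]):
            continue
        beats.append(
            BeatTriplet(
                ppg_raw=np.asarray(record.ppg[a:b], dtype=float),
                ecg_raw=np.asarray(record.ecg[a:b], dtype=float),
                abp_raw=np.asarray(record.abp[a:b], dtype=float),
                start_sample=a,
                end_sample=b,
                fs=record.fs,
            )
        )
    return beats


def resample_segment(x: np.ndarray, n: int = SEGMENT_LENGTH) -> np.ndarray:
    """Resample a beat to exactly ``n`` samples over a normalized time axis.

    Cubic interpolation (linear for beats shorter than 4 samples).  Endpoints
    are knots of the interpolant, so first and last values are preserved.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 samples to resample")
    src = np.linspace(0.0, 1.0, x.size)
    dst = np.linspace(0.0, 1.0, n)
    kind = "cubic" if x.size >= 4 else "linear"
    return interp1d(src, x, kind=kind, assume_sorted=True)(dst)


def extract_sbp_dbp(abp_beat: np.ndarray) -> tuple[float, float]:
    """Systolic = within-beat maximum, diastolic = minimum, of the raw ABP cycle."""
    x = np.asarray(abp_beat, dtype=float)
    if x.size == 0:
        raise ValueError("empty ABP beat")
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite ABP values (should have been screened)")
    return float(x.max()), float(x.min())


def minmax_normalize(x: np.ndarray) -> np.ndarray:
    """Scale to [0, 1]; a flat segment maps to zeros."""
    x = np.asarray(x, dtype=float)
    rng = np.ptp(x)
    if rng == 0:
        return np.zeros_like(x)
    return (x - x.min()) / rng


def build_segments(records, n_samples: int = SEGMENT_LENGTH, return_report: bool = False):
    """Full preprocessing chain: records in, labeled 150-sample beat pairs out.

    Per record: quality screen, band-pass PPG (0.5-10 Hz) and ECG (0.5-40 Hz),
    detect R peaks, cut beats at R-R intervals, resample PPG/ECG to
    ``n_samples`` and min-max normalize each, read SBP/DBP off the raw
    (unfiltered) ABP cycle, and label via the AHA table.  Unclassifiable beats
    are dropped and counted.
    """
    from .synth import WaveformRecord

    segments: list[LabeledSegment] = []
    report = {"rejected_records": 0, "dropped_unclassifiable": 0, "dropped_invalid": 0}
    for rec in records:
        screened, screen_rep = quality_screen(rec)
        if screen_rep.rejected:
            report["rejected_records"] += 1
            logger.warning("record %s rejected by quality screen: %s", rec.record_id, screen_rep.reason)
            continue
        ppg_f = bandpass(screened.ppg, screened.fs, *PPG_BAND)
        ecg_f = bandpass(screened.ecg, screened.fs, *ECG_BAND)
        r_peaks = detect_r_peaks(ecg_f, screened.fs)
        filtered = WaveformRecord(
            ppg=ppg_f,
            ecg=ecg_f,
            abp=screened.abp,  # ABP left unfiltered: labels need absolute mmHg
            fs=screened.fs,
            record_id=screened.record_id,
            invalid_mask=screened.invalid_mask,
        )
        beats = segment_beats(filtered, r_peaks)
        for k, beat in enumerate(beats):
            try:
                sbp, dbp = extract_sbp_dbp(beat.abp_raw)
                label = assign_label(sbp, dbp)
            except ValueError:
                report["dropped_invalid"] += 1
                continue
            if label is BPLabel.UNCLASSIFIABLE:
                report["dropped_unclassifiable"] += 1
                continue
            segments.append(
                LabeledSegment(
                    ppg=minmax_normalize(resample_segment(beat.ppg_raw, n_samples)),
                    ecg=minmax_normalize(resample_segment(beat.ecg_raw, n_samples)),
                    label=label,
                    sbp=sbp,
                    dbp=dbp,
                    source_record=rec.record_id,
                    beat_index=k,
                )
            )
    if return_report:
        return segments, report
    return segments


def split_dataset(segments, ratios=(0.64, 0.16, 0.20), seed: int = 0) -> DatasetSplit:
    """Shuffled train/validation/test partition.

    Counts follow the hold-out-then-hold-out convention: the test count is
    ``round(N * test_ratio)`` first, then the validation count is the rounded
    validation share of the remainder; training takes what is left.  For
    N = 14,298 at (0.64, 0.16, 0.20) this reproduces the 9150/2288/2860 split.
    """
    ratios = tuple(float(r) for r in ratios)
    if len(ratios) != 3 or any(r <= 0 for r in ratios):
        raise ValueError("ratios must be three positive numbers")
    if abs(sum(ratios) - 1.0) > 1e-9:
        raise ValueError(f"ratios must sum to 1, got {sum(ratios)}")
    n = len(segments)
    if n < 3:
        raise ValueError("need at least 3 segments to split")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    n_test = int(round(n * ratios[2]))
    remaining = n - n_test
    n_val = int(round(remaining * ratios[1] / (ratios[0] + ratios[1])))
    test_idx = order[:n_test]
    val_idx = order[n_test : n_test + n_val]
    train_idx = order[n_test + n_val :]
    pick = lambda idx: [segments[i] for i in idx]
    return DatasetSplit(train=pick(train_idx), validation=pick(val_idx), test=pick(test_idx), split_seed=seed)
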