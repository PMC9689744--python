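"""Seeded synthetic PPG/ECG/ABP records with known R times and per-beat SBP/DBP.

The generator emulates the simultaneous three-channel bedside recordings the
pipeline consumes: a quasi-periodic Gaussian-bump ECG (P, Q, R, S, T waves
with a dominant R spike), a two-component PPG pulse (systolic wave plus a
smaller delayed dicrotic wave) arriving ~0.2 s after each R, and an ABP pulse
rescaled per beat so that its within-beat maximum/minimum equal a controllable
systolic/diastolic ground truth.

Because the classifier only ever sees PPG and ECG, blood pressure is also
encoded in waveform *shape*: systolic pressure modulates the PPG (dicrotic
amplitude and delay, systolic width) and diastolic pressure modulates the ECG
(T-wave amplitude, S-wave depth).  Higher pressure -> stiffer arteries ->
larger, earlier reflected wave; chronic pressure load -> repolarization
changes.  The mappings are monotone and deliberately coarse: they make the
five pressure categories learnable from morphology by construction, which is
what the end-to-end tests rely on.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields as dc_fields
from typing import Optional

import numpy as np

from .preprocess import BPLabel, CLASS_ORDER

__all__ = [
    "SynthConfig",
    "WaveformRecord",
    "generate_record",
    "generate_dataset",
    "CLASS_SAMPLING_BOXES",
]


@dataclass
class SynthConfig:
    """Knobs of the synthetic record generator.

    ``noise_snr_db`` sets additive white Gaussian noise on PPG and ECG relative
    to each channel's signal power (``None`` disables it).  ABP noise is a
    separate absolute scale, ``abp_noise_mmHg`` (default 0), because the ABP
    channel is the labeling ground truth: SNR-scaled noise on a ~50 mmHg pulse
    would shift per-beat extrema by several mmHg and blur class boundaries.
    ``bp_jitter_mmHg`` is the half-range of a uniform per-beat perturbation of
    the SBP/DBP targets, bounded so it cannot cross the 2 mmHg class margins
    used by :func:`generate_dataset`.
    """

    duration_s: float = 10.0
    fs: float = 125.0
    heart_rate_bpm: float = 70.0
    hr_jitter_frac: float = 0.0
    sbp_mmHg: float = 110.0
    dbp_mmHg: float = 70.0
    bp_jitter_mmHg: float = 1.5
    noise_snr_db: Optional[float] = 20.0
    abp_noise_mmHg: float = 0.0
    shape_jitter: float = 0.01
    ppg_delay_s: float = 0.2
    first_r_s: float = 0.2
    baseline_wander_amp: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.fs <= 0:
            raise ValueError(f"fs must be > 0, got {self.fs}")
        if self.duration_s <= 0:
            raise ValueError(f"duration_s must be > 0, got {self.duration_s}")
        if not (20 <= self.heart_rate_bpm <= 220):
            raise ValueError(f"heart_rate_bpm must be in [20, 220], got {self.heart_rate_bpm}")
        if not (self.sbp_mmHg > self.dbp_mmHg > 0):
            raise ValueError(f"require sbp_mmHg > dbp_mmHg > 0, got sbp_mmHg={self.sbp_mmHg}, dbp_mmHg={self.dbp_mmHg}")
        if not (0 <= self.hr_jitter_frac <= 0.2):
            raise ValueError(f"hr_jitter_frac must be in [0, 0.2], got {self.hr_jitter_frac}")
        if self.bp_jitter_mmHg < 0:
            raise ValueError(f"bp_jitter_mmHg must be >= 0, got {self.bp_jitter_mmHg}")

    def replace(self, **kw) -> "SynthConfig":
        vals = {f.name: getattr(self, f.name) for f in dc_fields(self)}
        vals.update(kw)
        return SynthConfig(**vals)


@dataclass
class WaveformRecord:
    """Simultaneous PPG/ECG/ABP arrays at one sampling rate.

    ``true_r_samples`` / ``true_beat_bp`` carry the generator's ground truth
    (one (sbp, dbp) pair per R peak); they are absent for imported records.
    """

    ppg: np.ndarray
    ecg: np.ndarray
    abp: np.ndarray
    fs: float
    true_r_samples: Optional[np.ndarray] = None
    true_beat_bp: Optional[np.ndarray] = None
    record_id: str = ""
    invalid_mask: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        if not (len(self.ppg) == len(self.ecg) == len(self.abp)):
            raise ValueError("ppg, ecg, abp must have identical length")
        if self.true_r_samples is not None:
            r = np.asarray(self.true_r_samples)
            if r.size and (np.any(np.diff(r) <= 0) or r[0] < 0 or r[-1] >= len(self.ppg)):
                raise ValueError("true_r_samples must be strictly increasing and in bounds")
            if self.true_beat_bp is not None and len(self.true_beat_bp) != r.size:
                raise ValueError("true_beat_bp must have one (sbp, dbp) pair per R peak")

    def __len__(self) -> int:
        return len(self.ppg)


# ----------------------------------------------------------------------------
# shape parameter mappings (pressure -> morphology)

def _sbp_coord(sbp: float) -> float:
    return float(np.clip((sbp - 60.0) / 120.0, 0.0, 1.0))


def _dbp_coord(dbp: float) -> float:
    return float(np.clip((dbp - 40.0) / 80.0, 0.0, 1.0))


def _gauss(t: np.ndarray, mu: float, sigma: float, amp: float) -> np.ndarray:
    return amp * np.exp(-0.5 * ((t - mu) / sigma) ** 2)


def _pulse_shape(t: np.ndarray, t0: float, T: float, width_f: float, dicrotic_amp: float, dicrotic_pos: float) -> np.ndarray:
    """Two-component pulse: systolic wave + delayed dicrotic wave, onset at t0."""
    y = _gauss(t, t0 + 0.13 * T, width_f * T, 1.0)
    y += _gauss(t, t0 + dicrotic_pos * T, 0.09 * T, dicrotic_amp)
    return y


def _beat_times(cfg: SynthConfig, rng: np.random.Generator) -> np.ndarray:
    base = 60.0 / cfg.heart_rate_bpm
    times = [cfg.first_r_s]
    while True:
        T = base * (1.0 + cfg.hr_jitter_frac * rng.uniform(-1.0, 1.0))
        nxt = times[-1] + T
        if nxt >= cfg.duration_s:
            break
        times.append(nxt)
    return np.asarray(times)


def generate_record(config: SynthConfig) -> WaveformRecord:
    """Deterministically synthesize one record from its config (incl. seed)."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    fs = config.fs
    n = int(round(config.duration_s * fs))
    t = np.arange(n) / fs
    r_times = _beat_times(config, rng)
    r_samples = np.round(r_times * fs).astype(int)
    keep = r_samples < n
    r_samples, r_times = r_samples[keep], r_times[keep]
    n_beats = r_samples.size

    # per-beat jittered BP targets (uniform, bounded by bp_jitter_mmHg)
    jit = config.bp_jitter_mmHg
    sbp_i = config.sbp_mmHg + rng.uniform(-jit, jit, size=n_beats)
    dbp_i = config.dbp_mmHg + rng.uniform(-jit, jit, size=n_beats)

    ecg = np.zeros(n)
    ppg = np.zeros(n)
    abp = np.zeros(n)
    base_T = 60.0 / config.heart_rate_bpm

    sj = config.shape_jitter
    for k in range(n_beats):
        tr = r_times[k]
        T = (r_times[k + 1] - tr) if k + 1 < n_beats else base_T
        lo = max(0, int((tr - 0.35 * T) * fs))
        hi = min(n, int((tr + 1.25 * T) * fs) + 1)
        tt = t[lo:hi]
        # --- ECG: P Q R S T Gaussian bumps; T amplitude / S depth follow DBP
        cd = _dbp_coord(dbp_i[k])
        amp_T = 0.15 + 0.45 * cd + rng.normal(0.0, sj)
        amp_S = -(0.10 + 0.15 * cd + rng.normal(0.0, sj))
        w = np.zeros_like(tt)
        w += _gauss(tt, tr - 0.18 * T, 0.030 * T, 0.12)
        w += _gauss(tt, tr - 0.035 * T, 0.012 * T, -0.12)
        w += _gauss(tt, tr, 0.018 * T, 1.0)
        w += _gauss(tt, tr + 0.035 * T, 0.012 * T, amp_S)
        w += _gauss(tt, tr + 0.32 * T, 0.060 * T, amp_T)
        ecg[lo:hi] += w
        # --- PPG: systolic + dicrotic wave; shape follows SBP
        cs = _sbp_coord(sbp_i[k])
        dic_amp = 0.15 + 0.55 * cs + rng.normal(0.0, sj)
        dic_pos = 0.45 - 0.08 * cs
        width_f = 0.085 + 0.035 * cs
        t_on = tr + config.ppg_delay_s
        ppg[lo:hi] += _pulse_shape(tt, t_on, T, width_f, dic_amp, dic_pos)

    # --- ABP: fixed pulse family, rescaled per R-R interval so the within-beat
    # max/min hit that beat's jittered SBP/DBP exactly on the sampled grid
    abp_shape = np.zeros(n)
    for k in range(n_beats):
        tr = r_times[k]
        T = (r_times[k + 1] - tr) if k + 1 < n_beats else base_T
        lo = max(0, int((tr - 0.1 * T) * fs))
        hi = min(n, int((tr + 1.3 * T) * fs) + 1)
        tt = t[lo:hi]
        abp_shape[lo:hi] += _pulse_shape(tt, tr + 0.06 * T, T, 0.10, 0.30, 0.42)
    bounds = list(r_samples) + [n]
    for k in range(n_beats):
        a, b = bounds[k], bounds[k + 1]
        if b - a < 2:
            continue
        seg = abp_shape[a:b]
        rngv = np.ptp(seg)
        unit = (seg - seg.min()) / rngv if rngv > 0 else np.zeros_like(seg)
        abp[a:b] = dbp_i[k] + (sbp_i[k] - dbp_i[k]) * unit
    if r_samples[0] > 0:
        abp[: r_samples[0]] = dbp_i[0]

    if config.baseline_wander_amp > 0:
        wander = config.baseline_wander_amp * np.sin(2 * np.pi * 0.25 * t + rng.uniform(0, 2 * np.pi))
        ppg = ppg + wander
        ecg = ecg + wander

    if config.noise_snr_db is not None and math.isfinite(config.noise_snr_db):
        for arr in (ppg, ecg):
            p_sig = float(np.var(arr))
            sigma = math.sqrt(p_sig / (10.0 ** (config.noise_snr_db / 10.0)))
            arr += rng.normal(0.0, sigma, size=n)
    if config.abp_noise_mmHg > 0:
        abp = abp + rng.normal(0.0, config.abp_noise_mmHg, size=n)

    return WaveformRecord(
        ppg=ppg,
        ecg=ecg,
        abp=abp,
        fs=fs,
        true_r_samples=r_samples,
        true_beat_bp=np.column_stack([sbp_i, dbp_i]),
        record_id=f"synth-{config.seed}",
    )


# ----------------------------------------------------------------------------
# class-conditional dataset generation

#: Printed AHA boxes restricted to their unambiguous (AND) interior, with
#: synthetic floors where the table leaves a bound open.  Format:
#: label -> (sbp_lo, sbp_hi, dbp_lo, dbp_hi) BEFORE the safety margin.
_RAW_BOXES = {
    BPLabel.HYPOTENSION: (60.0, 90.0, 40.0, 60.0),
    BPLabel.NORMOTENSION: (90.0, 120.0, 60.0, 80.0),
    BPLabel.PREHYPERTENSION: (120.0, 129.0, 60.0, 80.0),
    BPLabel.HYPERTENSION_STAGE_1: (130.0, 139.0, 80.0, 89.0),
    BPLabel.HYPERTENSION_STAGE_2: (140.0, 180.0, 90.0, 120.0),
}


def class_sampling_box(label: BPLabel, margin: float = 2.0) -> tuple[float, float, float, float]:
    """Interior of a class's pressure box, ``margin`` mmHg from every boundary."""
    if label not in _RAW_BOXES:
        raise ValueError(f"no sampling box for label {label}")
    s_lo, s_hi, d_lo, d_hi = _RAW_BOXES[label]
    box = (s_lo + margin, s_hi - margin, d_lo + margin, d_hi - margin)
    if box[0] >= box[1] or box[2] >= box[3]:
        raise ValueError(f"sampling box for {label.value} is empty under margin {margin}")
    return box


CLASS_SAMPLING_BOXES = {lab: class_sampling_box(lab) for lab in CLASS_ORDER}


def generate_dataset(
    class_counts: dict,
    base_config: Optional[SynthConfig] = None,
    beats_per_record: int = 16,
    margin: float = 2.0,
) -> list[WaveformRecord]:
    """Generate records whose beats fall in requested AHA classes.

    Per class, SBP/DBP targets are drawn uniformly from the interior of that
    class's pressure box (``margin`` mmHg inside every boundary, so per-beat
    jitter cannot cross a class line) and heart rate varies uniformly across
    records in 55-95 bpm.  Records are added until at least the requested
    number of complete R-R beats exists for the class.
    """
    if base_config is None:
        base_config = SynthConfig()
    for lab, cnt in class_counts.items():
        if cnt < 0:
            raise ValueError(f"negative count for {lab}")
    rng = np.random.default_rng(base_config.seed)
    jit = min(base_config.bp_jitter_mmHg, margin)
    records: list[WaveformRecord] = []
    for lab in CLASS_ORDER:
        want = int(class_counts.get(lab, 0))
        if want == 0:
            continue
        s_lo, s_hi, d_lo, d_hi = class_sampling_box(lab, margin)
        got = 0
        idx = 0
        while got < want:
            sbp = rng.uniform(s_lo, s_hi)
            dbp = rng.uniform(d_lo, d_hi)
            hr = rng.uniform(55.0, 95.0)
            base_T = 60.0 / hr
            duration = base_config.first_r_s + (beats_per_record + 0.5) * base_T
            cfg = base_config.replace(
                duration_s=duration,
                heart_rate_bpm=hr,
                sbp_mmHg=sbp,
                dbp_mmHg=dbp,
                bp_jitter_mmHg=jit,
                seed=int(rng.integers(0, 2**31 - 1)),
            )
            rec = generate_record(cfg)
            rec.record_id = f"{lab.value}-{idx}"
            n_beats = max(0, len(rec.true_r_samples) - 1)
            if n_beats == 0:
                idx += 1
                continue
            records.append(rec)
            got += n_beats
            idx += 1
    return records
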