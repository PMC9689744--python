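"""Record and segment containers, plus a minimal WFDB-style reader/writer.

Two on-disk forms for records: a portable ``.npz`` container that round-trips
every :class:`~pulsestage.synth.WaveformRecord` field losslessly (including
ground-truth annotations), and a WFDB-style header + 16-bit signal pair for
interoperability testing with bedside-monitor exports.  Channel names map
through a case-insensitive synonym table (PLETH -> ppg, II/ECG/MLII -> ecg,
ABP/ART -> abp); records missing a required channel raise
:class:`ChannelNotFoundError` listing what was found.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .preprocess import CLASS_ORDER, LABEL_TO_CODE, LabeledSegment
from .synth import WaveformRecord

#: case-insensitive channel-name synonyms for monitor-style headers
CHANNEL_SYNONYMS = {
    "pleth": "ppg",
    "ppg": "ppg",
    "ii": "ecg",
    "ecg": "ecg",
    "mlii": "ecg",
    "lead ii": "ecg",
    "abp": "abp",
    "art": "abp",
}

_WFDB_CHANNEL_NAMES = {"ppg": "PLETH", "ecg": "II", "abp": "ABP"}
_WFDB_UNITS = {"ppg": "NU", "ecg": "mV", "abp": "mmHg"}


class ChannelNotFoundError(KeyError):
    pass


# ---------------------------------------------------------------------------
# portable .npz container

def save_record(record: WaveformRecord, path) -> Path:
    """Write a record to the portable .npz container (lossless round trip)."""
    path = Path(path)
    data = {
        "ppg": np.asarray(record.ppg, dtype=float),
        "ecg": np.asarray(record.ecg, dtype=float),
        "abp": np.asarray(record.abp, dtype=float),
        "fs": np.array(record.fs, dtype=float),
        "record_id": np.frombuffer(record.record_id.encode(), dtype=np.uint8),
    }
    if record.true_r_samples is not None:
        data["true_r_samples"] = np.asarray(record.true_r_samples, dtype=int)
    if record.true_beat_bp is not None:
        data["true_beat_bp"] = np.asarray(record.true_beat_bp, dtype=float)
    np.savez(path, **data)
    return path


def _load_npz_record(path: Path) -> WaveformRecord:
    with np.load(path) as z:
        return WaveformRecord(
            ppg=z["ppg"],
            ecg=z["ecg"],
            abp=z["abp"],
            fs=float(z["fs"]),
            true_r_samples=z["true_r_samples"] if "true_r_samples" in z else None,
            true_beat_bp=z["true_beat_bp"] if "true_beat_bp" in z else None,
            record_id=bytes(z["record_id"]).decode() if "record_id" in z else path.stem,
        )


# ---------------------------------------------------------------------------
# minimal WFDB-style record/header (format 16, one interleaved .dat)

def write_wfdb(record: WaveformRecord, basepath) -> Path:
    """Write header (.hea) + interleaved little-endian int16 signals (.dat).

    Per channel, gain is chosen so the signal spans most of the int16 range;
    round trips agree within one quantization step.  Ground-truth annotations
    are not representable in this format (use the .npz container for those).
    """
    basepath = Path(basepath)
    name = basepath.name
    channels = {"ppg": record.ppg, "ecg": record.ecg, "abp": record.abp}
    n = len(record.ppg)
    gains, digital = {}, {}
    for key, x in channels.items():
        x = np.asarray(x, dtype=float)
        scale = float(np.max(np.abs(x))) if n else 1.0
        gain = 30000.0 / scale if scale > 0 else 1.0
        d = np.round(x * gain).astype("<i2")
        gains[key] = gain
        digital[key] = d
    fs = record.fs
    fs_str = f"{fs:g}"
    lines = [f"{name} 3 {fs_str} {n}"]
    inter = np.empty(n * 3, dtype="<i2")
    for i, key in enumerate(("ppg", "ecg", "abp")):
        d = digital[key]
        inter[i::3] = d
        first = int(d[0]) if n else 0
        checksum = int(np.sum(d.astype(np.int64)) % 65536)
        lines.append(
            f"{name}.dat 16 {gains[key]:.6f}(0)/{_WFDB_UNITS[key]} 16 0 {first} {checksum} 0 {_WFDB_CHANNEL_NAMES[key]}"
        )
    hea = basepath.with_suffix(".hea")
    hea.write_text("\n".join(lines) + "\n")
    basepath.with_suffix(".dat").write_bytes(inter.tobytes())
    return hea


def _read_wfdb(hea_path: Path) -> WaveformRecord:
    lines = [ln for ln in hea_path.read_text().splitlines() if ln.strip() and not ln.startswith("#")]
    head = lines[0].split()
    name, nsig, fs, nsamp = head[0], int(head[1]), float(head[2]), int(head[3])
    sig_lines = lines[1 : 1 + nsig]
    dat_file = hea_path.with_name(sig_lines[0].split()[0])
    raw = np.frombuffer(dat_file.read_bytes(), dtype="<i2")
    if raw.size != nsig * nsamp:
        raise ValueError(f"{dat_file} has {raw.size} samples, expected {nsig * nsamp}")
    found = {}
    names_seen = []
    for i, ln in enumerate(sig_lines):
        parts = ln.split()
        fmt = parts[1]
        if fmt != "16":
            raise ValueError(f"unsupported WFDB format {fmt} (only 16 is supported)")
        gain_spec = parts[2]
        gain = float(gain_spec.split("(")[0])
        baseline = 0.0
        if "(" in gain_spec:
            baseline = float(gain_spec.split("(")[1].split(")")[0])
        desc = parts[-1]
        names_seen.append(desc)
        key = CHANNEL_SYNONYMS.get(desc.lower())
        if key is None:
            continue
        found[key] = (raw[i::nsig].astype(float) - baseline) / gain
    missing = [k for k in ("ppg", "ecg", "abp") if k not in found]
    if missing:
        raise ChannelNotFoundError(
            f"record {name} lacks channel(s) {missing}; channels found: {names_seen}"
        )
    return WaveformRecord(ppg=found["ppg"], ecg=found["ecg"], abp=found["abp"], fs=fs, record_id=name)


def read_record(path) -> WaveformRecord:
    """Read a record from the .npz container or a WFDB-style .hea header."""
    path = Path(path)
    if path.suffix == ".npz":
        return _load_npz_record(path)
    if path.suffix == ".hea":
        return _read_wfdb(path)
    if path.with_suffix(".hea").exists():
        return _read_wfdb(path.with_suffix(".hea"))
    raise FileNotFoundError(f"no readable record at {path}")


# ---------------------------------------------------------------------------
# labeled-segment datasets

def save_segments(segments, path) -> Path:
    """Write labeled segments to a columnar .npz container."""
    path = Path(path)
    ids = "\n".join(s.source_record for s in segments)
    np.savez(
        path,
        ppg=np.stack([s.ppg for s in segments]) if segments else np.zeros((0, 150)),
        ecg=np.stack([s.ecg for s in segments]) if segments else np.zeros((0, 150)),
        label=np.array([LABEL_TO_CODE[s.label] for s in segments], dtype=int),
        sbp=np.array([s.sbp for s in segments], dtype=float),
        dbp=np.array([s.dbp for s in segments], dtype=float),
        beat_index=np.array([s.beat_index for s in segments], dtype=int),
        record_ids=np.frombuffer(ids.encode(), dtype=np.uint8),
    )
    return path


def load_segments(path) -> list:
    path = Path(path)
    with np.load(path) as z:
        ids = bytes(z["record_ids"]).decode().split("\n") if z["record_ids"].size else []
        out = []
        for i in range(z["label"].size):
            out.append(
                LabeledSegment(
                    ppg=z["ppg"][i],
                    ecg=z["ecg"][i],
                    label=CLASS_ORDER[int(z["label"][i])],
                    sbp=float(z["sbp"][i]),
                    dbp=float(z["dbp"][i]),
                    source_record=ids[i] if i < len(ids) else "",
                    beat_index=int(z["beat_index"][i]),
                )
            )
    return out


def segments_to_dataframe(segments) -> pd.DataFrame:
    """Tabular view (one row per segment) for inspection / CSV export."""
    rows = []
    for s in segments:
        row = {
            "source_record": s.source_record,
            "beat_index": s.beat_index,
            "label": s.label.value,
            "sbp": s.sbp,
            "dbp": s.dbp,
        }
        row.update({f"ppg_{i}": v for i, v in enumerate(s.ppg)})
        row.update({f"ecg_{i}": v for i, v in enumerate(s.ecg)})
        rows.append(row)
    return pd.DataFrame(rows)
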