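"""Reading and writing the package's plain-text formats.

Raw recordings travel as open tabular text (optionally gzip-compressed), not
the proprietary device binary: a few ``#``-prefixed header lines carry the
device/protocol metadata, then one CSV row per sample with an ISO-8601
timestamp (fractional seconds) and the three axes in g.

    # wristacc-raw v1
    # participant_id: P001
    # sample_rate_hz: 85.7
    # dynamic_range_g: 8.0
    # start_time: 2012-06-04T00:00:00.000000
    time,x,y,z
    2012-06-04T00:00:00.000000,0.0123,-0.9987,0.0456
"""

from __future__ import annotations

import gzip
import io as _io
from pathlib import Path

import numpy as np
import pandas as pd

from .recording import ParticipantMeta, RawRecording

_MAGIC = "# wristacc-raw v1"


def _open_text(path: Path, mode: str):
    if str(path).endswith(".gz"):
        return gzip.open(path, mode + "t")
    return open(path, mode)


def write_recording(rec: RawRecording, path: str | Path) -> None:
    """Write a recording; axis values use 17-significant-digit formatting so
    that a read-back recording is bit-identical."""
    path = Path(path)
    offs = rec.sample_offsets()
    times = rec.day0 + pd.to_timedelta(np.round(offs * 1e6).astype(np.int64), unit="us")
    tstr = times.strftime("%Y-%m-%dT%H:%M:%S.%f")
    with _open_text(path, "w") as fh:
        fh.write(_MAGIC + "\n")
        fh.write(f"# participant_id: {rec.participant_id}\n")
        fh.write(f"# sample_rate_hz: {rec.sample_rate_hz!r}\n")
        fh.write(f"# dynamic_range_g: {rec.dynamic_range_g!r}\n")
        fh.write(f"# start_time: {rec.start_time.isoformat()}\n")
        df = pd.DataFrame(
            {
                "time": tstr,
                "x": rec.samples[:, 0],
                "y": rec.samples[:, 1],
                "z": rec.samples[:, 2],
            }
        )
        df.to_csv(fh, index=False, float_format="%.17g", lineterminator="\n")


class RecordingFormatError(ValueError):
    pass


def read_recording(path: str | Path, expected_rate: float | None = None) -> RawRecording:
    """Read a raw-signal file.

    Validates monotone timestamps (a duplicate or backward step is a hard
    error naming the offending line), applies a unit heuristic (median vector
    norm far from 1 g suggests m/s² data), and records gaps wider than two
    sample intervals as missing runs.
    """
    path = Path(path)
    header: dict[str, str] = {}
    with _open_text(path, "r") as fh:
        pos = 0
        n_header = 0
        for line in fh:
            if not line.startswith("#"):
                break
            n_header += 1
            body = line[1:].strip()
            if ":" in body:
                key, _, val = body.partition(":")
                header[key.strip()] = val.strip()
        fh.seek(0)
        text = fh.read()
    df = pd.read_csv(_io.StringIO(text), comment="#", float_precision="round_trip")
    if list(df.columns) != ["time", "x", "y", "z"]:
        raise RecordingFormatError(
            f"{path}: expected columns time,x,y,z, found {list(df.columns)}"
        )
    times = pd.to_datetime(df["time"], format="ISO8601")
    t_ns = times.astype("int64").to_numpy()
    dt = np.diff(t_ns)
    bad = np.flatnonzero(dt <= 0)
    if bad.size:
        line_no = n_header + 2 + int(bad[0]) + 1  # header + column row + 1-based
        raise RecordingFormatError(
            f"{path}: non-monotone timestamp at line {line_no}"
        )

    samples = df[["x", "y", "z"]].to_numpy(dtype=float)
    norms = np.linalg.norm(samples, axis=1)
    med = float(np.median(norms))
    if not (0.5 <= med <= 1.5):
        hint = " (values look like m/s²; expected g)" if 5.0 <= med <= 15.0 else ""
        raise RecordingFormatError(
            f"{path}: median vector norm {med:.2f} outside [0.5, 1.5] g{hint}"
        )

    rate = float(header["sample_rate_hz"]) if "sample_rate_hz" in header else None
    if rate is None:
        rate = 1e9 / float(np.median(dt))
    if expected_rate is not None and abs(rate - expected_rate) > 0.01 * expected_rate:
        raise RecordingFormatError(
            f"{path}: sample rate {rate:.3f} Hz differs from expected {expected_rate} Hz"
        )

    start_time = (
        pd.Timestamp(header["start_time"]) if "start_time" in header else times.iloc[0]
    )
    day0 = start_time.normalize()
    offs = (t_ns - day0.value) / 1e9

    # uniformity check: keep explicit per-sample times only when needed
    missing_runs: list[tuple[float, float]] = []
    nominal = 1e9 / rate
    if dt.size and (np.abs(dt - nominal) > 0.02 * nominal).any():
        sample_times = offs
        gap = np.flatnonzero(dt > 2 * nominal)
        for gi in gap:
            missing_runs.append((float(offs[gi]), float(offs[gi + 1])))
    else:
        sample_times = None

    return RawRecording(
        participant_id=header.get("participant_id", path.stem),
        start_time=start_time,
        sample_rate_hz=rate,
        samples=samples,
        dynamic_range_g=float(header.get("dynamic_range_g", 8.0)),
        sample_times_s=sample_times,
        missing_runs=missing_runs,
    )


def read_metadata(path: str | Path) -> list[ParticipantMeta]:
    """Participant metadata table: CSV with columns participant_id, sex,
    cohort, ses_quintile, weight_status; categories are validated and ids
    must be unique."""
    df = pd.read_csv(path, dtype=str)
    required = ["participant_id", "sex", "cohort", "ses_quintile", "weight_status"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing metadata columns {missing}")
    if df["participant_id"].duplicated().any():
        dup = df.loc[df["participant_id"].duplicated(), "participant_id"].iloc[0]
        raise ValueError(f"{path}: duplicate participant_id {dup!r}")
    return [
        ParticipantMeta(
            participant_id=r.participant_id,
            sex=r.sex,
            cohort=r.cohort,
            ses_quintile=r.ses_quintile,
            weight_status=r.weight_status,
        )
        for r in df.itertuples()
    ]


def meta_frame(metas: list[ParticipantMeta]) -> pd.DataFrame:
    return pd.DataFrame([m.__dict__ for m in metas])
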