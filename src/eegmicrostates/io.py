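"""Reading and writing EEG recordings, metadata tables and pipeline artifacts.

Two on-disk EEG dialects are supported:

* **matrix** — lossless plain text: one header line of tab-separated
  channel labels, then one row per channel of tab-separated samples
  (``%.17g``, so float64 round-trips bitwise), plus a JSON sidecar
  ``<name>.meta.json`` carrying the sampling rate and subject id.
* **edf** — European Data Format.  Reading goes through
  ``mne.io.read_raw_edf``; writing uses a minimal built-in 16-bit EDF
  encoder (EDF stores integers, so a write/read round trip quantizes the
  amplitudes to ~1e-4 of the physical range).

Metadata tables are tab-separated with the fixed columns
``subject_id, group, age, sex, fma_total, fma_upper, fma_lower, iadl``.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import EEGRecording, LabelSequence, PrototypeSet, SubjectMeta, UNASSIGNED

METADATA_COLUMNS = [
    "subject_id", "group", "age", "sex",
    "fma_total", "fma_upper", "fma_lower", "iadl",
]


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".meta.json")


def write_matrix(rec: EEGRecording, path: str | Path) -> Path:
    """Write a recording in the tab-delimited matrix dialect (lossless)."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("\t".join(rec.channel_labels) + "\n")
        np.savetxt(fh, rec.data, fmt="%.17g", delimiter="\t")
    _sidecar(path).write_text(json.dumps({
        "subject_id": rec.subject_id,
        "fs": rec.fs,
        "n_channels": rec.n_channels,
        "n_samples": rec.n_samples,
    }))
    return path


def read_matrix(path: str | Path, fs: float | None = None) -> EEGRecording:
    """Read the matrix dialect; ``fs`` overrides / replaces the sidecar."""
    path = Path(path)
    try:
        with open(path) as fh:
            header = fh.readline()
            if not header.strip():
                raise ValueError(f"{path}: empty or headerless file")
            labels = header.rstrip("\n").split("\t")
            rows = []
            for lineno, line in enumerate(fh, start=2):
                if not line.strip():
                    continue
                values = line.split("\t")
                if rows and len(values) != len(rows[0]):
                    raise ValueError(
                        f"{path}: line {lineno} has {len(values)} values, "
                        f"expected {len(rows[0])}"
                    )
                try:
                    rows.append([float(v) for v in values])
                except ValueError as exc:
                    raise ValueError(f"{path}: line {lineno}: {exc}") from None
    except OSError as exc:
        raise ValueError(f"cannot read {path}: {exc}") from exc
    if len(rows) != len(labels):
        raise ValueError(
            f"{path}: {len(rows)} data rows but {len(labels)} channel labels"
        )
    meta = {}
    sidecar = _sidecar(path)
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
    if fs is None:
        fs = meta.get("fs")
    if fs is None:
        raise ValueError(f"{path}: no sampling rate (missing sidecar and no fs given)")
    return EEGRecording(
        data=np.asarray(rows, dtype=float),
        fs=float(fs),
        channel_labels=labels,
        subject_id=str(meta.get("subject_id", path.stem)),
    )


def write_edf(rec: EEGRecording, path: str | Path) -> Path:
    """Write a minimal EDF file (16-bit, one 1 s data record per second).

    Amplitudes are scaled per channel to the full digital range, so the
    quantization step is ``(max - min) / 65535`` of each channel's span.
    """
    path = Path(path)
    n_per_rec = int(round(rec.fs))
    if abs(n_per_rec - rec.fs) > 1e-9:
        raise ValueError("EDF writer requires an integer sampling rate")
    n_rec = int(np.ceil(rec.n_samples / n_per_rec))
    data = np.zeros((rec.n_channels, n_rec * n_per_rec))
    data[:, : rec.n_samples] = rec.data

    def fit8(v: float) -> str:
        """Shortest decimal representation of ``v`` within 8 characters."""
        for fmt in ("%.7g", "%.6g", "%.5g", "%.4g", "%.3g", "%.2g", "%.1g"):
            s = fmt % v
            if len(s) <= 8:
                return s
        return "%.0e" % v

    # round the physical range to what fits the 8-char header fields and
    # scale with the rounded values, so decoding inverts the encoding exactly
    pmin_s = [fit8(v) for v in data.min(axis=1)]
    pmax_s = [fit8(v + 1e-12 * max(1.0, abs(v))) for v in data.max(axis=1)]
    pmin = np.array([float(s) for s in pmin_s])
    pmax = np.array([float(s) for s in pmax_s])
    pmax = np.maximum(pmax, data.max(axis=1))
    pmax_s = [fit8(v) for v in pmax]
    pmax = np.array([float(s) for s in pmax_s])
    span = np.where(pmax - pmin > 0, pmax - pmin, 1.0)
    dmin, dmax = -32768, 32767
    digital = np.round((data - pmin[:, None]) / span[:, None] * (dmax - dmin) + dmin)
    digital = np.clip(digital, dmin, dmax).astype("<i2")

    def pad(text: str, width: int) -> bytes:
        return text[:width].ljust(width).encode("ascii")

    nch = rec.n_channels
    header = b"".join([
        pad("0", 8),
        pad(rec.subject_id or "X", 80),
        pad("synthetic recording", 80),
        pad("01.01.00", 8), pad("00.00.00", 8),
        pad(str(256 * (nch + 1)), 8),
        pad("", 44),
        pad(str(n_rec), 8),
        pad("1", 8),                       # record duration, seconds
        pad(str(nch), 4),
    ])
    fields = [
        (16, rec.channel_labels),
        (80, [""] * nch),                  # transducer
        (8, ["uV"] * nch),
        (8, pmin_s),
        (8, pmax_s),
        (8, [str(dmin)] * nch),
        (8, [str(dmax)] * nch),
        (80, [""] * nch),                  # prefiltering
        (8, [str(n_per_rec)] * nch),
        (32, [""] * nch),
    ]
    sig_header = b"".join(
        b"".join(pad(v, width) for v in values) for width, values in fields
    )
    with open(path, "wb") as fh:
        fh.write(header + sig_header)
        for r in range(n_rec):
            block = digital[:, r * n_per_rec : (r + 1) * n_per_rec]
            fh.write(block.tobytes())
    return path


def read_edf(path: str | Path) -> EEGRecording:
    """Read an EDF file via MNE; data returned in microvolts."""
    import mne

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    return EEGRecording(
        data=raw.get_data() * 1e6,
        fs=float(raw.info["sfreq"]),
        channel_labels=list(raw.ch_names),
        subject_id=Path(path).stem,
    )


def read_eeg(path: str | Path, format: str = "auto", fs: float | None = None) -> EEGRecording:
    """Dispatch on ``format`` (``edf`` / ``matrix``; ``auto`` by suffix)."""
    path = Path(path)
    if format == "auto":
        format = "edf" if path.suffix.lower() == ".edf" else "matrix"
    if format == "edf":
        return read_edf(path)
    if format == "matrix":
        return read_matrix(path, fs=fs)
    raise ValueError(f"unknown format {format!r}")


def write_metadata(metas: list[SubjectMeta], path: str | Path) -> Path:
    df = pd.DataFrame([m.as_dict() for m in metas])[METADATA_COLUMNS]
    df.to_csv(path, sep="\t", index=False)
    return Path(path)


def read_metadata(path: str | Path) -> list[SubjectMeta]:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in METADATA_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing metadata columns {missing}")
    metas = []
    for _, row in df.iterrows():
        kwargs = {c: row[c] for c in METADATA_COLUMNS}
        for key in ("fma_total", "fma_upper", "fma_lower", "iadl"):
            if pd.isna(kwargs[key]):
                kwargs[key] = None
        metas.append(SubjectMeta(**kwargs))
    return metas


def write_prototypes(ps: PrototypeSet, path: str | Path) -> Path:
    """Prototype maps as a delimited matrix with a JSON metadata sidecar."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("\t".join(ps.class_names()) + "\n")
        np.savetxt(fh, ps.maps.T, fmt="%.17g", delimiter="\t")
    _sidecar(path).write_text(json.dumps({
        "labels": ps.labels,
        "gev_per_class": None if ps.gev_per_class is None else ps.gev_per_class.tolist(),
        "diagnostics": {k: v for k, v in ps.diagnostics.items()
                        if isinstance(v, (int, float, str, list))},
    }))
    return path


def read_prototypes(path: str | Path) -> PrototypeSet:
    path = Path(path)
    with open(path) as fh:
        names = fh.readline().rstrip("\n").split("\t")
        maps = np.loadtxt(fh, delimiter="\t").T
    meta = {}
    if _sidecar(path).exists():
        meta = json.loads(_sidecar(path).read_text())
    gev = meta.get("gev_per_class")
    return PrototypeSet(
        maps=np.atleast_2d(maps),
        labels=meta.get("labels") if meta.get("labels") else (
            names if any(n in "ABCDEFGH" for n in names) else None),
        gev_per_class=None if gev is None else np.asarray(gev),
        diagnostics=meta.get("diagnostics", {}),
    )


def write_labels(seq: LabelSequence, path: str | Path,
                 class_names: list[str] | None = None) -> Path:
    """Run-length encoded label sequence: class, start_ms, duration_ms."""
    rows = []
    for s in seq.segments():
        name = class_names[s.label] if class_names else str(s.label)
        rows.append({
            "class": name,
            "start_ms": s.start * 1000.0 / seq.fs,
            "duration_ms": s.length * 1000.0 / seq.fs,
        })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
    return Path(path)


def read_labels(path: str | Path, fs: float, n_samples: int,
                class_names: list[str] | None = None) -> LabelSequence:
    df = pd.read_csv(path, sep="\t")
    labels = np.full(n_samples, UNASSIGNED, dtype=int)
    for _, row in df.iterrows():
        cls = row["class"]
        idx = class_names.index(str(cls)) if class_names else int(cls)
        start = int(round(row["start_ms"] * fs / 1000.0))
        length = int(round(row["duration_ms"] * fs / 1000.0))
        labels[start : start + length] = idx
    return LabelSequence(labels=labels, fs=fs)
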