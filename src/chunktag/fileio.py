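"""Readers and writers: event TSVs, EDF / flat-binary recordings, result tables.

Tab-separated outputs carry provenance as leading ``#`` comment lines (tool
version, seed, config hash); readers skip them. Event tables follow the
BIDS-events column dialect (``onset``, ``duration``, ``trial_type`` first).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .agdesign import EVENT_COLUMNS
from .synth import Recording, grid_adjacency

__all__ = [
    "FileFormatError",
    "write_events",
    "read_events",
    "write_flat",
    "read_flat",
    "write_edf",
    "read_edf",
    "write_table",
    "read_table",
]


class FileFormatError(ValueError):
    """Raised when a file does not match the expected on-disk format."""


def provenance_lines(seed=None, config_hash=None, **extra) -> list[str]:
    fields = {"tool": f"chunktag {__version__}"}
    if seed is not None:
        fields["seed"] = seed
    if config_hash is not None:
        fields["config_hash"] = config_hash
    fields.update(extra)
    return [f"# {k}: {v}" for k, v in fields.items()]


# ---------------------------------------------------------------------------
# event tables


def write_events(table: pd.DataFrame, path, seed=None, config_hash=None) -> None:
    """Write an event table as BIDS-dialect TSV (onset/duration/trial_type)."""
    path = Path(path)
    out = table.copy()
    out.insert(0, "onset", out.pop("onset_s"))
    out.insert(1, "duration", out.pop("duration_s"))
    out.insert(2, "trial_type", out["role"])
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for line in provenance_lines(seed=seed, config_hash=config_hash):
            fh.write(line + "\n")
        out.to_csv(fh, sep="\t", index=False, lineterminator="\n")


def read_events(path) -> pd.DataFrame:
    """Read an event TSV back into the internal column layout."""
    path = Path(path)
    # keep_default_na: the syllable "NA" must not be parsed as missing
    table = pd.read_csv(
        path, sep="\t", comment="#", encoding="utf-8", keep_default_na=False,
        na_values=[],
    )
    required = {"onset", "duration"}
    if not required <= set(table.columns):
        raise FileFormatError(f"{path}: missing columns {required - set(table.columns)}")
    table = table.rename(columns={"onset": "onset_s", "duration": "duration_s"})
    table = table.drop(columns=["trial_type"], errors="ignore")
    missing = set(EVENT_COLUMNS) - set(table.columns)
    if missing:
        raise FileFormatError(f"{path}: missing columns {missing}")
    return table[EVENT_COLUMNS]


# ---------------------------------------------------------------------------
# flat binary recording (little-endian float32 + JSON sidecar)


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_flat(recording: Recording, path, seed=None, config_hash=None) -> None:
    """Write channels x samples little-endian float32 plus a JSON sidecar."""
    path = Path(path)
    data = np.ascontiguousarray(recording.data, dtype="<f4")
    data.tofile(path)
    meta = {
        "format": "chunktag-flat-v1",
        "dtype": "<f4",
        "shape": list(recording.data.shape),
        "srate": recording.srate,
        "channel_labels": list(recording.channel_labels),
        "provenance": {
            "tool": f"chunktag {__version__}",
            "seed": seed,
            "config_hash": config_hash,
        },
    }
    _sidecar_path(path).write_text(json.dumps(meta, indent=1), encoding="utf-8")


def read_flat(path) -> Recording:
    path = Path(path)
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise FileFormatError(f"missing sidecar {sidecar}")
    meta = json.loads(sidecar.read_text(encoding="utf-8"))
    if meta.get("format") != "chunktag-flat-v1":
        raise FileFormatError(f"{sidecar}: unknown format {meta.get('format')!r}")
    n_ch, n_samp = meta["shape"]
    data = np.fromfile(path, dtype=meta["dtype"])
    if data.size != n_ch * n_samp:
        raise FileFormatError(
            f"{path}: expected {n_ch * n_samp} samples, found {data.size}"
        )
    labels, adjacency = grid_adjacency(n_ch)
    stored = meta.get("channel_labels") or labels
    return Recording(
        data=data.reshape(n_ch, n_samp).astype(float),
        srate=float(meta["srate"]),
        channel_labels=list(stored),
        adjacency=adjacency,
    )


# ---------------------------------------------------------------------------
# EDF (16-bit European Data Format, single data record)


def _num8(x: float) -> str:
    """Format a number into at most 8 ASCII characters."""
    for fmt in (".6g", ".5g", ".4g", ".3g", ".2g", ".1g"):
        s = format(x, fmt)
        if len(s) <= 8:
            return s
    raise FileFormatError(f"cannot format {x!r} in 8 characters")


def _pad(text: str, width: int) -> bytes:
    b = text.encode("ascii")
    if len(b) > width:
        raise FileFormatError(f"EDF field too long: {text!r}")
    return b.ljust(width)


def write_edf(recording: Recording, path) -> None:
    """Write a minimal EDF file (one data record holding all samples).

    Data are scaled to the int16 digital range per the physical min/max of
    the whole recording, so round trips are exact only up to quantization.
    """
    path = Path(path)
    n_ch, n_samp = recording.data.shape
    # round the physical range to its 8-char header representation first, so
    # the reader's rescaling uses exactly the range the writer scaled with
    pmin = float(_num8(np.floor(recording.data.min() * 1e4) / 1e4))
    pmax = float(_num8(np.ceil(recording.data.max() * 1e4) / 1e4))
    if pmax <= pmin:
        pmax = pmin + 1.0
    dmin, dmax = -32768, 32767
    scale = (dmax - dmin) / (pmax - pmin)
    digital = np.clip(
        np.round((recording.data - pmin) * scale + dmin), dmin, dmax
    ).astype("<i2")

    duration = n_samp / recording.srate
    header_bytes = 256 + 256 * n_ch
    head = b"".join(
        [
            _pad("0", 8),
            _pad("synthetic", 80),
            _pad("chunktag", 80),
            _pad("01.01.00", 8),
            _pad("00.00.00", 8),
            _pad(str(header_bytes), 8),
            _pad("", 44),
            _pad("1", 8),
            _pad(_num8(duration), 8),
            _pad(str(n_ch), 4),
        ]
    )
    sig = b"".join(
        [
            b"".join(_pad(lbl, 16) for lbl in recording.channel_labels),
            b"".join(_pad("", 80) for _ in range(n_ch)),
            b"".join(_pad("uV", 8) for _ in range(n_ch)),
            b"".join(_pad(_num8(pmin), 8) for _ in range(n_ch)),
            b"".join(_pad(_num8(pmax), 8) for _ in range(n_ch)),
            b"".join(_pad(str(dmin), 8) for _ in range(n_ch)),
            b"".join(_pad(str(dmax), 8) for _ in range(n_ch)),
            b"".join(_pad("", 80) for _ in range(n_ch)),
            b"".join(_pad(str(n_samp), 8) for _ in range(n_ch)),
            b"".join(_pad("", 32) for _ in range(n_ch)),
        ]
    )
    with open(path, "wb") as fh:
        fh.write(head)
        fh.write(sig)
        fh.write(digital.tobytes())


def read_edf(path, expected_srate: float | None = None) -> Recording:
    """Read an EDF file written by :func:`write_edf` (single data record)."""
    path = Path(path)
    raw = path.read_bytes()
    if len(raw) < 256:
        raise FileFormatError(f"{path}: truncated EDF header")

    def field(offset: int, width: int) -> str:
        return raw[offset : offset + width].decode("ascii", errors="replace").strip()

    n_records = int(field(236, 8))
    duration = float(field(244, 8))
    n_ch = int(field(252, 4))
    if n_records != 1:
        raise FileFormatError(f"{path}: only single-record EDF files are supported")
    off = 256
    labels = [field(off + 16 * i, 16) for i in range(n_ch)]
    off += 16 * n_ch + 80 * n_ch + 8 * n_ch
    pmins = np.array([float(field(off + 8 * i, 8)) for i in range(n_ch)])
    off += 8 * n_ch
    pmaxs = np.array([float(field(off + 8 * i, 8)) for i in range(n_ch)])
    off += 8 * n_ch
    dmins = np.array([int(field(off + 8 * i, 8)) for i in range(n_ch)])
    off += 8 * n_ch
    dmaxs = np.array([int(field(off + 8 * i, 8)) for i in range(n_ch)])
    off += 8 * n_ch + 80 * n_ch
    n_samps = [int(field(off + 8 * i, 8)) for i in range(n_ch)]
    if len(set(n_samps)) != 1:
        raise FileFormatError(f"{path}: per-signal sample counts differ")
    n_samp = n_samps[0]
    header_bytes = 256 + 256 * n_ch

    digital = np.frombuffer(
        raw, dtype="<i2", count=n_ch * n_samp, offset=header_bytes
    ).reshape(n_ch, n_samp)
    scale = (pmaxs - pmins) / (dmaxs - dmins)
    data = (digital - dmins[:, None]) * scale[:, None] + pmins[:, None]
    srate = n_samp / duration
    if expected_srate is not None and abs(srate - expected_srate) > 1e-6 * expected_srate:
        raise FileFormatError(
            f"{path}: sampling rate {srate:.6g} Hz does not match expected "
            f"{expected_srate:.6g} Hz"
        )
    _, adjacency = grid_adjacency(n_ch)
    return Recording(
        data=data.astype(float), srate=srate, channel_labels=labels, adjacency=adjacency
    )


# ---------------------------------------------------------------------------
# generic result tables (spectra, cluster tables, ...)


def write_table(table: pd.DataFrame, path, seed=None, config_hash=None) -> None:
    """Write any result table as TSV with provenance comment lines."""
    path = Path(path)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for line in provenance_lines(seed=seed, config_hash=config_hash):
            fh.write(line + "\n")
        table.to_csv(fh, sep="\t", index=False, lineterminator="\n", float_format="%.12g")


def read_table(path) -> pd.DataFrame:
    path = Path(path)
    try:
        return pd.read_csv(path, sep="\t", comment="#", encoding="utf-8")
    except pd.errors.ParserError as exc:
        raise FileFormatError(f"{path}: {exc}") from exc
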