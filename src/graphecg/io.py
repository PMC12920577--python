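"""Reading and writing ECG recordings and beat annotations.

Two on-disk representations are supported:

* **Delimited text** — comma-separated samples, one column per lead, preceded
  by a single header line ``# fs=<Hz> leads=<name,...>``.  This is the
  package's native fixture format.
* **WFDB (single-segment)** — PhysioNet ``.hea``/``.dat`` signal pairs in
  format 16 (interleaved little-endian 16-bit integers with gain/baseline
  digital-to-physical conversion) and MIT-format ``.atr`` beat annotations.
  The reader/writer here is a minimal self-contained implementation covering
  exactly that subset; multi-segment records and other storage formats are
  out of scope.

Beat annotations carry a sample index and one of the four rhythm-class
symbols ``N`` (normal), ``S`` (supraventricular), ``V`` (ventricular) and
``E`` (ectopic).  Raw annotation symbols (e.g. MIT-BIH beat codes) are mapped
into that set through a configurable symbol map.
"""

from __future__ import annotations

import logging
import struct
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import DataError, FormatError, ValidationError

logger = logging.getLogger(__name__)

CLASS_SYMBOLS = ("N", "S", "V", "E")

#: Default raw-symbol -> class-symbol map.  Identity on the four class symbols
#: plus the unambiguous AAMI beat letters.  MIT-BIH 'F' (fusion), 'f' (paced
#: fusion) and 'Q' (unclassifiable) have no agreed class here and are left
#: unmapped (dropped in lenient mode); extend the map to route them.
DEFAULT_SYMBOL_MAP: dict[str, str] = {
    "N": "N", "L": "N", "R": "N", "e": "N", "j": "N",
    "A": "S", "a": "S", "J": "S", "S": "S",
    "V": "V",
    "E": "E",
}

# MIT annotation code <-> symbol (subset used for beats)
_ATR_CODE_TO_SYMBOL = {
    1: "N", 2: "L", 3: "R", 4: "a", 5: "V", 6: "F", 7: "J", 8: "A",
    9: "S", 10: "E", 11: "j", 12: "/", 13: "Q", 34: "e", 38: "f",
}
_SYMBOL_TO_ATR_CODE = {s: c for c, s in _ATR_CODE_TO_SYMBOL.items()}


@dataclass
class Recording:
    """A multi-lead ECG signal in physical units (millivolts).

    ``signal`` has shape ``(n_samples, n_leads)``; all leads share the
    sampling frequency ``fs``.
    """

    signal: np.ndarray
    fs: float
    lead_names: list[str]
    patient_id: str | None = None
    units_per_lead: list[str] | None = None

    def __post_init__(self) -> None:
        self.signal = np.atleast_2d(np.asarray(self.signal, dtype=np.float64))
        if self.signal.ndim != 2:
            raise ValidationError("signal must be a samples x leads matrix")
        if self.fs <= 0:
            raise ValidationError(f"sampling frequency must be positive, got {self.fs}")
        if self.signal.shape[1] < 1:
            raise ValidationError("recording needs at least one lead")
        if len(self.lead_names) != self.signal.shape[1]:
            raise ValidationError("lead_names length must match lead count")
        if np.isnan(self.signal).any():
            raise DataError("signal contains NaN values")

    @property
    def n_samples(self) -> int:
        return self.signal.shape[0]

    @property
    def n_leads(self) -> int:
        return self.signal.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs


@dataclass(frozen=True, order=True)
class BeatAnnotation:
    """A beat label: 0-based R-peak sample index plus class symbol."""

    sample_index: int
    symbol: str

    def __post_init__(self) -> None:
        if self.sample_index < 0:
            raise ValidationError(f"sample_index must be >= 0, got {self.sample_index}")
        if self.symbol not in CLASS_SYMBOLS:
            raise ValidationError(f"symbol must be one of {CLASS_SYMBOLS}, got {self.symbol!r}")


# ---------------------------------------------------------------------------
# delimited text format
# ---------------------------------------------------------------------------

def _parse_delimited_header(line: str) -> tuple[float, list[str]]:
    if not line.startswith("#"):
        raise FormatError("delimited file must start with '# fs=<Hz> leads=<name,...>'")
    fs = None
    leads: list[str] | None = None
    for token in line.lstrip("#").split():
        if token.startswith("fs="):
            try:
                fs = float(token[3:])
            except ValueError as exc:
                raise FormatError(f"unparseable fs in header: {token}") from exc
        elif token.startswith("leads="):
            leads = token[6:].split(",")
    if fs is None or leads is None:
        raise FormatError("header must declare both fs= and leads=")
    if fs <= 0:
        raise ValidationError(f"fs must be positive, got {fs}")
    return fs, leads


def _read_delimited(path: Path) -> Recording:
    with open(path) as fh:
        header = fh.readline()
        fs, leads = _parse_delimited_header(header)
        try:
            data = pd.read_csv(fh, header=None).to_numpy(dtype=np.float64)
        except (ValueError, pd.errors.ParserError) as exc:
            raise DataError(f"non-numeric or ragged rows in {path}: {exc}") from exc
    if np.isnan(data).any():
        raise DataError(f"NaN or missing cells in {path}")
    if data.shape[1] != len(leads):
        raise DataError(
            f"{path}: header declares {len(leads)} leads but rows have {data.shape[1]} columns")
    return Recording(signal=data, fs=fs, lead_names=leads, patient_id=path.stem)


def _write_delimited(rec: Recording, path: Path) -> None:
    header = f"# fs={rec.fs:g} leads={','.join(rec.lead_names)}\n"
    with open(path, "w") as fh:
        fh.write(header)
        pd.DataFrame(rec.signal).to_csv(fh, header=False, index=False)


# ---------------------------------------------------------------------------
# WFDB single-segment, format 16
# ---------------------------------------------------------------------------

_DEFAULT_GAIN = 200.0  # adu/mV, the WFDB default


def _read_wfdb_header(hea_path: Path):
    lines = [ln.strip() for ln in hea_path.read_text().splitlines()
             if ln.strip() and not ln.startswith("#")]
    if not lines:
        raise FormatError(f"empty WFDB header {hea_path}")
    rec_tokens = lines[0].split()
    if len(rec_tokens) < 2:
        raise FormatError(f"malformed WFDB record line: {lines[0]!r}")
    name = rec_tokens[0]
    if "/" in name:
        raise FormatError("multi-segment WFDB records are not supported")
    try:
        n_sig = int(rec_tokens[1])
        fs = float(rec_tokens[2]) if len(rec_tokens) > 2 else 250.0
        n_samples = int(rec_tokens[3]) if len(rec_tokens) > 3 else 0
    except ValueError as exc:
        raise FormatError(f"malformed WFDB record line: {lines[0]!r}") from exc
    if fs <= 0:
        raise ValidationError(f"fs must be positive, got {fs}")
    signals = []
    for ln in lines[1:1 + n_sig]:
        tok = ln.split()
        if len(tok) < 2:
            raise FormatError(f"malformed WFDB signal line: {ln!r}")
        fname, fmt = tok[0], tok[1]
        if fmt.split("x")[0] != "16":
            raise FormatError(f"unsupported WFDB storage format {fmt!r} (only 16)")
        gain, baseline, units = _DEFAULT_GAIN, 0, "mV"
        if len(tok) > 2:
            g = tok[2]
            if "/" in g:
                g, units = g.split("/", 1)
            if "(" in g:
                g, base = g.split("(", 1)
                baseline = int(base.rstrip(")"))
            gain = float(g) if g else _DEFAULT_GAIN
            if gain == 0:
                gain = _DEFAULT_GAIN
        desc = tok[8] if len(tok) > 8 else f"lead{len(signals)}"
        signals.append((fname, gain, baseline, units, desc))
    if len(signals) != n_sig:
        raise FormatError(f"{hea_path}: header declares {n_sig} signals, found {len(signals)}")
    return name, fs, n_samples, signals


def _read_wfdb(path: Path) -> Recording:
    hea_path = path.with_suffix(".hea")
    if not hea_path.exists():
        raise FormatError(f"missing WFDB header {hea_path}")
    name, fs, n_samples, signals = _read_wfdb_header(hea_path)
    dat_files = {s[0] for s in signals}
    if len(dat_files) != 1:
        raise FormatError("signals split across multiple .dat files are not supported")
    dat_path = hea_path.with_name(next(iter(dat_files)))
    raw = np.fromfile(dat_path, dtype="<i2")
    n_sig = len(signals)
    if n_samples and raw.size < n_samples * n_sig:
        raise DataError(f"{dat_path}: expected {n_samples * n_sig} samples, found {raw.size}")
    if n_samples == 0:
        n_samples = raw.size // n_sig
    digital = raw[: n_samples * n_sig].reshape(n_samples, n_sig).astype(np.float64)
    gains = np.array([s[1] for s in signals])
    baselines = np.array([s[2] for s in signals])
    physical = (digital - baselines) / gains
    return Recording(
        signal=physical, fs=fs,
        lead_names=[s[4] for s in signals],
        units_per_lead=[s[3] for s in signals],
        patient_id=name,
    )


def _write_wfdb(rec: Recording, path: Path, gain: float = _DEFAULT_GAIN) -> None:
    base = path.with_suffix("")
    digital = np.round(rec.signal * gain)
    if np.abs(digital).max(initial=0) > 32767:
        raise DataError("signal amplitude exceeds int16 range at the chosen gain")
    digital = digital.astype("<i2")
    digital.tofile(base.with_suffix(".dat"))
    units = rec.units_per_lead or ["mV"] * rec.n_leads
    lines = [f"{base.name} {rec.n_leads} {rec.fs:g} {rec.n_samples}"]
    for i, lead in enumerate(rec.lead_names):
        first = int(digital[0, i]) if rec.n_samples else 0
        checksum = int(digital[:, i].astype(np.int64).sum() % 65536)
        lines.append(
            f"{base.name}.dat 16 {gain:g}(0)/{units[i]} 16 0 {first} {checksum} 0 {lead}")
    base.with_suffix(".hea").write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# public recording API
# ---------------------------------------------------------------------------

def read_recording(path: str | Path, format_hint: str = "auto") -> Recording:
    """Read a recording from delimited text or a WFDB header path.

    ``format_hint`` is one of ``wfdb``, ``delimited`` or ``auto`` (decide from
    the file extension: ``.hea``/``.dat`` mean WFDB).
    """
    path = Path(path)
    if format_hint == "auto":
        format_hint = "wfdb" if path.suffix in {".hea", ".dat"} else "delimited"
    if format_hint == "wfdb":
        return _read_wfdb(path)
    if format_hint == "delimited":
        if not path.exists():
            raise FormatError(f"no such file: {path}")
        return _read_delimited(path)
    raise ValidationError(f"unknown format hint {format_hint!r}")


def write_recording(rec: Recording, path: str | Path, fmt: str = "auto") -> Path:
    """Write ``rec`` as delimited text or WFDB (.hea/.dat) and return the path."""
    path = Path(path)
    if fmt == "auto":
        fmt = "wfdb" if path.suffix in {".hea", ".dat"} else "delimited"
    if fmt == "wfdb":
        _write_wfdb(rec, path)
    elif fmt == "delimited":
        _write_delimited(rec, path)
    else:
        raise ValidationError(f"unknown format {fmt!r}")
    return path


# ---------------------------------------------------------------------------
# annotations
# ---------------------------------------------------------------------------

def _map_symbols(raw: list[tuple[int, str]], symbol_map: Mapping[str, str],
                 strict: bool) -> list[BeatAnnotation]:
    out = []
    for idx, sym in raw:
        mapped = symbol_map.get(sym)
        if mapped is None:
            if strict:
                raise ValidationError(f"unmapped annotation symbol {sym!r} at sample {idx}")
            logger.info("dropping annotation with unmapped symbol %r at sample %d", sym, idx)
            continue
        out.append(BeatAnnotation(sample_index=int(idx), symbol=mapped))
    out.sort()
    return out


def _read_atr(path: Path) -> list[tuple[int, str]]:
    data = path.read_bytes()
    raw: list[tuple[int, str]] = []
    t = 0
    i = 0
    while i + 1 < len(data):
        word = struct.unpack_from("<H", data, i)[0]
        i += 2
        code = word >> 10
        delta = word & 0x3FF
        if code == 0 and delta == 0:  # end of file
            break
        if code == 59:  # SKIP: 4-byte interval, high word first
            if i + 3 >= len(data):
                raise FormatError(f"{path}: truncated SKIP annotation")
            hi = struct.unpack_from("<H", data, i)[0]
            lo = struct.unpack_from("<H", data, i + 2)[0]
            i += 4
            t += (hi << 16) | lo
            continue
        if code in (60, 61, 62):  # NUM / SUB / CHN modifiers: value in delta
            continue
        if code == 63:  # AUX: delta bytes of text, padded to even
            i += delta + (delta & 1)
            continue
        t += delta
        sym = _ATR_CODE_TO_SYMBOL.get(code, "Q")
        raw.append((t, sym))
    return raw


def write_annotations(anns: Sequence[BeatAnnotation], path: str | Path) -> Path:
    """Write annotations as CSV (``sample_index,symbol``) or MIT ``.atr``."""
    path = Path(path)
    anns = sorted(anns)
    if path.suffix == ".atr":
        with open(path, "wb") as fh:
            prev = 0
            for ann in anns:
                delta = ann.sample_index - prev
                prev = ann.sample_index
                while delta > 1023:  # emit SKIP for long gaps
                    fh.write(struct.pack("<H", 59 << 10))
                    fh.write(struct.pack("<HH", (delta >> 16) & 0xFFFF, delta & 0xFFFF))
                    delta = 0
                code = _SYMBOL_TO_ATR_CODE[ann.symbol]
                fh.write(struct.pack("<H", (code << 10) | delta))
            fh.write(struct.pack("<H", 0))
    else:
        pd.DataFrame(
            {"sample_index": [a.sample_index for a in anns],
             "symbol": [a.symbol for a in anns]}
        ).to_csv(path, index=False)
    return path


def read_annotations(path: str | Path, fs: float | None = None,
                     signal_length: int | None = None,
                     symbol_map: Mapping[str, str] | None = None,
                     strict: bool = False) -> list[BeatAnnotation]:
    """Read beat annotations (CSV or MIT ``.atr``), map symbols, sort.

    Unmapped symbols raise in ``strict`` mode and are dropped with a log line
    otherwise.  When ``signal_length`` is given, out-of-range indices raise a
    :class:`ValidationError`.
    """
    path = Path(path)
    if path.suffix == ".atr":
        raw = _read_atr(path)
    else:
        df = pd.read_csv(path)
        if not {"sample_index", "symbol"} <= set(df.columns):
            raise FormatError(f"{path}: expected columns sample_index,symbol")
        raw = list(zip(df["sample_index"].astype(int), df["symbol"].astype(str)))
    anns = _map_symbols(raw, symbol_map or DEFAULT_SYMBOL_MAP, strict)
    if signal_length is not None:
        for a in anns:
            if a.sample_index >= signal_length:
                raise ValidationError(
                    f"annotation at sample {a.sample_index} beyond signal length {signal_length}")
    return anns


# ---------------------------------------------------------------------------
# feature tables
# ---------------------------------------------------------------------------

def write_feature_table(rows: Iterable[Mapping[str, object]], path: str | Path) -> int:
    """Write homogeneous feature records as CSV with header; return row count.

    Floats are written at full round-trip precision so that
    ``read_feature_table(write_feature_table(rows))`` reproduces values to
    better than 1e-9.
    """
    rows = list(rows)
    path = Path(path)
    if rows:
        keys = set(rows[0].keys())
        for r in rows[1:]:
            if set(r.keys()) != keys:
                raise ValidationError("feature records are not homogeneous")
        df = pd.DataFrame(rows)
    else:
        df = pd.DataFrame()
    try:
        df.to_csv(path, index=False)
    except OSError as exc:
        raise OSError(f"cannot write feature table to {path}: {exc}") from exc
    return len(df)


def read_feature_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
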