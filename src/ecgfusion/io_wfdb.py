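"""WFDB format-212 record I/O and AAMI beat-class mapping.

Format 212 packs two 12-bit two's-complement ADC samples into three
bytes: the first sample is byte 1 plus the low nibble of byte 2 as its
high bits, the second is byte 3 plus the high nibble of byte 2.
Annotations are supported both in the standard MIT binary dialect
(6-bit type code + 10-bit sample interval per 16-bit word, with SKIP
words for long gaps) and in a plain-text ``index symbol`` fallback that
is convenient for fixtures.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "AAMI_MAP",
    "ECGRecord",
    "NotABeatError",
    "map_symbol_to_aami",
    "read_annotations",
    "read_record",
    "write_record",
]


class NotABeatError(ValueError):
    """Raised when an annotation symbol does not denote a heartbeat."""


#: MIT annotation symbol -> AAMI super-class, per the ANSI/AAMI EC57
#: convention: normal + bundle branch block + escape beats -> N,
#: atrial/supraventricular ectopics -> S, ventricular ectopics -> V,
#: fusion of ventricular and normal -> F, paced/unclassifiable -> Q.
AAMI_MAP: dict[str, str] = {
    "N": "N", "L": "N", "R": "N", "e": "N", "j": "N",
    "A": "S", "a": "S", "J": "S", "S": "S",
    "V": "V", "E": "V",
    "F": "F",
    "/": "Q", "f": "Q", "Q": "Q",
}

# MIT annotation type codes for the binary .atr dialect.
_CODE_TO_SYMBOL = {
    1: "N", 2: "L", 3: "R", 4: "a", 5: "V", 6: "F", 7: "J", 8: "A",
    9: "S", 10: "E", 11: "j", 12: "/", 13: "Q", 14: "~", 16: "|",
    18: "s", 19: "T", 22: '"', 25: "t", 28: "'", 30: "?", 31: "!",
    32: "[", 33: "]", 34: "e", 35: "n", 37: "@", 38: "f", 41: "r",
}
_SYMBOL_TO_CODE = {s: c for c, s in _CODE_TO_SYMBOL.items()}
_SKIP = 59
_NUM = 60
_SUB = 61
_CHN = 62
_AUX = 63


def map_symbol_to_aami(symbol: str, table: dict[str, str] | None = None) -> str:
    """Map a beat annotation symbol to its AAMI class in {N,S,V,F,Q}.

    ``table`` overrides the default EC57 mapping. Non-beat symbols
    (rhythm changes '+', noise '~', ...) raise :class:`NotABeatError`.
    """
    mapping = AAMI_MAP if table is None else table
    try:
        return mapping[symbol]
    except KeyError:
        raise NotABeatError(f"{symbol!r} is not a beat annotation symbol") from None


@dataclass
class ECGRecord:
    """A sampled multi-lead ECG with per-beat annotations.

    ``signal`` has shape (n_leads, n_samples); ``annotations`` is a list
    of (sample_index, symbol) pairs sorted by index.
    """

    signal: np.ndarray
    fs: float
    lead_names: list[str] = field(default_factory=list)
    annotations: list[tuple[int, str]] = field(default_factory=list)
    name: str = "rec"

    def __post_init__(self) -> None:
        self.signal = np.atleast_2d(np.asarray(self.signal))
        if self.fs <= 0:
            raise ValueError("sampling frequency must be positive")
        n = self.signal.shape[1]
        last = -1
        for idx, sym in self.annotations:
            if not 0 <= idx < n:
                raise ValueError(f"annotation index {idx} outside [0, {n})")
            if idx <= last:
                raise ValueError("annotation indices must be strictly increasing")
            last = idx
        if not self.lead_names:
            self.lead_names = [f"lead{i}" for i in range(self.signal.shape[0])]

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]

    @property
    def n_leads(self) -> int:
        return self.signal.shape[0]

    def lead(self, index: int = 0) -> np.ndarray:
        return self.signal[index]

    def aami_labels(self) -> list[tuple[int, str]]:
        """Annotations mapped to AAMI classes; non-beat symbols dropped."""
        out = []
        for idx, sym in self.annotations:
            try:
                out.append((idx, map_symbol_to_aami(sym)))
            except NotABeatError:
                continue
        return out


# ----------------------------------------------------------------- dat codec

def _pack_212(samples: np.ndarray) -> bytes:
    """Pack a flat int array of 12-bit samples into format-212 bytes."""
    s = np.asarray(samples, dtype=np.int64)
    if s.size and (s.max() > 2047 or s.min() < -2048):
        raise ValueError("sample overflow: format 212 holds -2048..2047")
    if s.size % 2:
        s = np.concatenate([s, [0]])  # zero-padded final pair
    a = s[0::2] & 0xFFF
    b = s[1::2] & 0xFFF
    out = np.empty(3 * a.size, dtype=np.uint8)
    out[0::3] = a & 0xFF
    out[1::3] = ((a >> 8) & 0x0F) | (((b >> 8) & 0x0F) << 4)
    out[2::3] = b & 0xFF
    return out.tobytes()


def _unpack_212(raw: bytes) -> np.ndarray:
    """Inverse of :func:`_pack_212`; returns a flat int16 array."""
    buf = np.frombuffer(raw, dtype=np.uint8)
    if buf.size % 3:
        raise ValueError("truncated format-212 data (length not a multiple of 3)")
    b0 = buf[0::3].astype(np.int32)
    b1 = buf[1::3].astype(np.int32)
    b2 = buf[2::3].astype(np.int32)
    s1 = b0 | ((b1 & 0x0F) << 8)
    s2 = b2 | ((b1 >> 4) << 8)
    out = np.empty(2 * s1.size, dtype=np.int32)
    out[0::2] = s1
    out[1::2] = s2
    out[out >= 2048] -= 4096  # 12-bit two's complement
    return out.astype(np.int16)


# ----------------------------------------------------------- annotation file

def _write_annotations_atr(path: Path, annotations: list[tuple[int, str]]) -> None:
    words = bytearray()
    prev = 0
    for idx, sym in annotations:
        code = _SYMBOL_TO_CODE.get(sym)
        if code is None:
            raise ValueError(f"no MIT annotation code for symbol {sym!r}")
        delta = idx - prev
        if delta > 1023:
            words += int((_SKIP << 10)).to_bytes(2, "little")
            words += ((delta >> 16) & 0xFFFF).to_bytes(2, "little")
            words += (delta & 0xFFFF).to_bytes(2, "little")
            delta = 0
        words += ((code << 10) | delta).to_bytes(2, "little")
        prev = idx
    words += (0).to_bytes(2, "little")  # EOF
    path.write_bytes(bytes(words))


def _read_annotations_atr(path: Path) -> list[tuple[int, str]]:
    raw = path.read_bytes()
    out: list[tuple[int, str]] = []
    t = 0
    i = 0
    pending_skip = 0
    while i + 1 < len(raw):
        word = int.from_bytes(raw[i : i + 2], "little")
        i += 2
        code, interval = word >> 10, word & 0x3FF
        if word == 0:
            break  # EOF
        if code == _SKIP:
            hi = int.from_bytes(raw[i : i + 2], "little")
            lo = int.from_bytes(raw[i + 2 : i + 4], "little")
            pending_skip = (hi << 16) | lo
            i += 4
        elif code in (_NUM, _SUB, _CHN, _AUX):
            if code == _AUX:
                i += interval + (interval & 1)
        else:
            t += interval + pending_skip
            pending_skip = 0
            sym = _CODE_TO_SYMBOL.get(code, "Q")
            out.append((t, sym))
    return out


def _write_annotations_txt(path: Path, annotations: list[tuple[int, str]]) -> None:
    lines = [f"{idx} {sym}" for idx, sym in annotations]
    path.write_text("\n".join(lines) + ("\n" if lines else ""))


def _read_annotations_txt(path: Path) -> list[tuple[int, str]]:
    out = []
    for line in path.read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        idx, sym = line.split()
        out.append((int(idx), sym))
    return out


def read_annotations(path: str | Path) -> list[tuple[int, str]]:
    """Read an annotation file, binary (.atr) or plain text (.txt)."""
    path = Path(path)
    if path.suffix == ".txt":
        return _read_annotations_txt(path)
    return _read_annotations_atr(path)


# ------------------------------------------------------------------- header

def _checksum(samples: np.ndarray) -> int:
    return int(np.sum(samples, dtype=np.int64) & 0xFFFF)


def write_record(
    record: ECGRecord,
    directory: str | Path,
    gain: float = 200.0,
    adc_zero: int = 0,
    ann_format: str = "atr",
) -> Path:
    """Write ``record`` as WFDB .hea/.dat (format 212) plus annotations.

    Float signals are digitized as ``round(x * gain) + adc_zero``;
    integer signals are stored as-is. Returns the header path.
    """
    if record.n_samples == 0:
        raise ValueError("cannot write an empty record")
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    sig = record.signal
    if np.issubdtype(sig.dtype, np.floating):
        adc = np.rint(sig * gain).astype(np.int64) + adc_zero
    else:
        adc = sig.astype(np.int64)
    if adc.max() > 2047 or adc.min() < -2048:
        raise ValueError("sample overflow: format 212 holds -2048..2047")

    name = record.name
    n_sig, n = adc.shape
    # Interleave leads frame-major: lead0[t], lead1[t], ...
    flat = adc.T.reshape(-1)
    (directory / f"{name}.dat").write_bytes(_pack_212(flat))

    lines = [f"{name} {n_sig} {record.fs:g} {n}"]
    for i in range(n_sig):
        lines.append(
            f"{name}.dat 212 {gain:g}({adc_zero})/mV 12 {adc_zero} "
            f"{adc[i, 0]} {_checksum(adc[i])} 0 {record.lead_names[i]}"
        )
    header = directory / f"{name}.hea"
    header.write_text("\n".join(lines) + "\n")

    ext = "atr" if ann_format == "atr" else "txt"
    ann_path = directory / f"{name}.{ext}"
    if ann_format == "atr":
        _write_annotations_atr(ann_path, record.annotations)
    else:
        _write_annotations_txt(ann_path, record.annotations)
    return header


def _parse_gain(tok: str) -> tuple[float, int]:
    """Parse a header gain token like ``200``, ``200(0)`` or ``200(0)/mV``."""
    tok = tok.split("/")[0]
    baseline = 0
    if "(" in tok:
        tok, rest = tok.split("(")
        baseline = int(rest.rstrip(")"))
    gain = float(tok) if tok else 200.0
    return (gain if gain else 200.0), baseline


def read_record(header_path: str | Path, physical: bool = False) -> ECGRecord:
    """Read a WFDB format-212 record given its .hea path.

    With ``physical=True`` samples are converted to physical units via
    ``(adc - baseline) / gain`` from the header. A checksum mismatch
    emits a warning rather than failing.
    """
    header_path = Path(header_path)
    lines = [
        ln for ln in header_path.read_text().splitlines()
        if ln.strip() and not ln.startswith("#")
    ]
    rec_tok = lines[0].split()
    name, n_sig, fs = rec_tok[0].split("/")[0], int(rec_tok[1]), float(rec_tok[2])
    n_samples = int(rec_tok[3]) if len(rec_tok) > 3 else None

    gains, baselines, leads, checks = [], [], [], []
    dat_name = None
    for ln in lines[1 : 1 + n_sig]:
        tok = ln.split()
        dat_name = tok[0]
        fmt = tok[1].split("x")[0].split(":")[0].split("+")[0]
        if fmt != "212":
            raise ValueError(f"unsupported signal format {tok[1]!r} (only 212)")
        g, b = _parse_gain(tok[2]) if len(tok) > 2 else (200.0, 0)
        gains.append(g)
        baselines.append(b)
        checks.append(int(tok[6]) if len(tok) > 6 else None)
        leads.append(tok[8] if len(tok) > 8 else f"lead{len(leads)}")

    dat_path = header_path.parent / dat_name
    if not dat_path.exists():
        raise FileNotFoundError(f"data file {dat_path} referenced by header is missing")
    flat = _unpack_212(dat_path.read_bytes())
    if n_samples is None:
        n_samples = flat.size // n_sig
    if flat.size < n_sig * n_samples:
        raise ValueError("truncated .dat file: fewer samples than header declares")
    sig = flat[: n_sig * n_samples].reshape(n_samples, n_sig).T.copy()

    for i, c in enumerate(checks):
        if c is not None and _checksum(sig[i]) != c:
            warnings.warn(
                f"checksum mismatch on signal {i} of record {name}", stacklevel=2
            )

    annotations: list[tuple[int, str]] = []
    for ext in (".atr", ".txt"):
        ann = header_path.with_suffix(ext)
        if ann.exists():
            annotations = read_annotations(ann)
            break

    out_sig: np.ndarray = sig
    if physical:
        out_sig = (sig.astype(np.float64) - np.array(baselines)[:, None]) / np.array(
            gains
        )[:, None]
    return ECGRecord(
        signal=out_sig, fs=fs, lead_names=leads, annotations=annotations, name=name
    )
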