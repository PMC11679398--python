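"""WFDB-format ECG record I/O, AAMI class mapping, stratified splits.

Implements a compact reader/writer for the WFDB conventions the MIT-BIH
Arrhythmia Database uses: ``.hea`` text headers, ``.dat`` signal files in
storage formats 212 (packed 12-bit pairs) and 16 (little-endian int16),
and ``.atr`` annotation files in the MIT annotation byte format.  Only
the features those databases need are covered (no skew, no multi-segment
records).

Annotation symbols are grouped into the five AAMI/EC57 beat classes::

    N <- N, L, R, e, j        (normal + bundle branch block + escape)
    S <- A, a, J, S           (supraventricular ectopic)
    V <- V, E                 (ventricular ectopic)
    F <- F                    (fusion of ventricular and normal)
    Q <- /, f, Q              (paced / fusion of paced / unclassifiable)

Non-beat annotations (rhythm changes, noise, artifacts) map to ``None``
and are skipped by callers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

logger = logging.getLogger(__name__)

AAMI_CLASSES = ("N", "S", "V", "F", "Q")

_SYMBOL_TO_AAMI = {
    "N": "N", "L": "N", "R": "N", "e": "N", "j": "N",
    "A": "S", "a": "S", "J": "S", "S": "S",
    "V": "V", "E": "V",
    "F": "F",
    "/": "Q", "f": "Q", "Q": "Q",
}

# WFDB non-beat annotation symbols (rhythm/signal-quality/waveform marks)
_NON_BEAT = set('+~|^x[]!"=pt u`\'*D@()rsT?') | {""}

# MIT annotation code <-> symbol (subset covering the mapped symbols)
_CODE_TO_SYMBOL = {
    1: "N", 2: "L", 3: "R", 4: "a", 5: "V", 6: "F", 7: "J", 8: "A",
    9: "S", 10: "E", 11: "j", 12: "/", 13: "Q", 14: "~", 16: "|",
    18: "s", 19: "T", 20: "*", 21: "D", 22: '"', 23: "=", 24: "p",
    25: "B", 26: "^", 27: "t", 28: "+", 29: "u", 30: "?", 31: "!",
    32: "[", 33: "]", 34: "e", 35: "n", 36: "@", 37: "x", 38: "f",
    39: "(", 40: ")", 41: "r",
}
_SYMBOL_TO_CODE = {s: c for c, s in _CODE_TO_SYMBOL.items()}

_SKIP = 59
_AUX = 63
_NUM = 60
_SUB = 61
_CHN = 62


@dataclass
class ECGRecord:
    """A single-channel voltage trace with beat annotations.

    ``annotations`` is a list of ``(sample_index, symbol)`` pairs with
    0-based indices at the record's native sampling rate.
    """

    samples: np.ndarray
    fs: float
    channel_name: str = "MLII"
    annotations: list = field(default_factory=list)
    record_id: str = "synth"

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples must be finite")
        n = len(self.samples)
        for idx, sym in self.annotations:
            if not 0 <= idx < n:
                raise ValueError(f"annotation index {idx} out of range")


def map_symbol_to_aami(symbol: str):
    """Beat symbol -> AAMI class, or None for non-beat annotations."""
    if symbol in _SYMBOL_TO_AAMI:
        return _SYMBOL_TO_AAMI[symbol]
    if symbol in _NON_BEAT:
        return None
    logger.warning("unknown beat-like annotation symbol %r mapped to Q",
                   symbol)
    return "Q"


# ---------------------------------------------------------------------------
# WFDB signal files
# ---------------------------------------------------------------------------

def _decode_212(raw: bytes, n_samples_total: int) -> np.ndarray:
    b = np.frombuffer(raw, dtype=np.uint8)
    n_pairs = len(b) // 3
    b = b[:n_pairs * 3].reshape(-1, 3).astype(np.int32)
    s0 = ((b[:, 1] & 0x0F) << 8) | b[:, 0]
    s1 = ((b[:, 1] & 0xF0) << 4) | b[:, 2]
    out = np.empty(n_pairs * 2, dtype=np.int32)
    out[0::2] = s0
    out[1::2] = s1
    out[out > 2047] -= 4096  # 12-bit two's complement
    return out[:n_samples_total]


def _encode_212(adc: np.ndarray) -> bytes:
    adc = np.asarray(adc, dtype=np.int32)
    if adc.min() < -2048 or adc.max() > 2047:
        raise ValueError("format 212 requires 12-bit sample range")
    if len(adc) % 2:
        adc = np.concatenate([adc, [0]])
    u = np.where(adc < 0, adc + 4096, adc).astype(np.uint16)
    s0, s1 = u[0::2], u[1::2]
    out = np.empty((len(s0), 3), dtype=np.uint8)
    out[:, 0] = s0 & 0xFF
    out[:, 1] = ((s0 >> 8) & 0x0F) | (((s1 >> 8) & 0x0F) << 4)
    out[:, 2] = s1 & 0xFF
    return out.tobytes()


def read_wfdb_record(header_path, preferred_channel="MLII") -> ECGRecord:
    """Read a WFDB record (.hea + .dat + optional .atr).

    Selects ``preferred_channel`` by name; falls back to channel 0 with a
    logged warning when absent.  Raises on missing or truncated files.
    """
    header_path = Path(header_path)
    if not header_path.exists():
        raise FileNotFoundError(header_path)
    lines = [ln.strip() for ln in header_path.read_text().splitlines()
             if ln.strip() and not ln.startswith("#")]
    rec_line = lines[0].split()
    name = rec_line[0].split("/")[0]
    n_sig = int(rec_line[1])
    fs = float(rec_line[2].split("/")[0]) if len(rec_line) > 2 else 250.0
    n_samples = int(rec_line[3]) if len(rec_line) > 3 else 0

    sigs = []
    for ln in lines[1:1 + n_sig]:
        tok = ln.split()
        fname = tok[0]
        fmt = int(tok[1].split("x")[0].split(":")[0].split("+")[0])
        gain, baseline = 200.0, None
        if len(tok) > 2:
            g = tok[2].split("/")[0]
            if "(" in g:
                g, b = g.split("(")
                baseline = int(b.rstrip(")"))
            if float(g) != 0:
                gain = float(g)
        if baseline is None:
            # baseline defaults to the ADC zero field when not given
            baseline = int(tok[4]) if len(tok) > 4 else 0
        desc = " ".join(tok[8:]) if len(tok) > 8 else f"ch{len(sigs)}"
        sigs.append(dict(fname=fname, fmt=fmt, gain=gain,
                         baseline=baseline, desc=desc))

    if not sigs:
        raise ValueError(f"no signal lines in {header_path}")
    names = [s["desc"] for s in sigs]
    if preferred_channel in names:
        chan = names.index(preferred_channel)
    else:
        logger.warning("channel %r not in %s; falling back to channel 0",
                       preferred_channel, names)
        chan = 0

    dat_path = header_path.with_name(sigs[chan]["fname"])
    if not dat_path.exists():
        raise FileNotFoundError(dat_path)
    raw = dat_path.read_bytes()
    fmt = sigs[chan]["fmt"]
    total = n_samples * n_sig
    if fmt == 212:
        need = -(-total * 3 // 2)  # ceil(total*1.5)
        if len(raw) < need:
            raise ValueError(f"{dat_path} truncated: {len(raw)} bytes, "
                             f"need {need}")
        adc = _decode_212(raw, total)
    elif fmt == 16:
        if len(raw) < total * 2:
            raise ValueError(f"{dat_path} truncated: {len(raw)} bytes, "
                             f"need {total * 2}")
        adc = np.frombuffer(raw, dtype="<i2")[:total].astype(np.int32)
    else:
        raise ValueError(f"unsupported WFDB signal format {fmt}")
    adc = adc.reshape(-1, n_sig)[:, chan]
    physical = (adc - sigs[chan]["baseline"]) / sigs[chan]["gain"]

    annotations = []
    atr_path = header_path.with_suffix(".atr")
    if atr_path.exists():
        annotations = _read_annotations(atr_path)

    return ECGRecord(samples=physical, fs=fs,
                     channel_name=sigs[chan]["desc"],
                     annotations=annotations, record_id=name)


def write_wfdb_record(record: ECGRecord, directory, name=None, fmt=16,
                      gain=2000.0):
    """Write a record as .hea + .dat (+ .atr when annotated).

    Returns the header path.  ``gain`` sets amplitude quantization
    (physical = adc/gain); the default keeps round-trip error below
    5e-4 a.u. in 16-bit storage.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    name = name or record.record_id
    adc = np.round(record.samples * gain).astype(np.int32)
    if fmt == 16:
        if adc.min() < -32768 or adc.max() > 32767:
            raise ValueError("signal exceeds 16-bit range at this gain")
        data = adc.astype("<i2").tobytes()
    elif fmt == 212:
        data = _encode_212(adc)
    else:
        raise ValueError(f"unsupported WFDB signal format {fmt}")
    (directory / f"{name}.dat").write_bytes(data)
    fs_txt = f"{record.fs:g}"
    header = (f"{name} 1 {fs_txt} {len(record.samples)}\n"
              f"{name}.dat {fmt} {gain:g}(0)/mV 16 0 {adc[0] if len(adc) else 0}"
              f" 0 0 {record.channel_name}\n")
    hea = directory / f"{name}.hea"
    hea.write_text(header)
    if record.annotations:
        _write_annotations(directory / f"{name}.atr", record.annotations)
    return hea


# ---------------------------------------------------------------------------
# MIT annotation files
# ---------------------------------------------------------------------------

def _read_annotations(path) -> list:
    raw = Path(path).read_bytes()
    words = np.frombuffer(raw, dtype="<u2")
    out = []
    t = 0
    i = 0
    while i < len(words):
        w = int(words[i])
        code = w >> 10
        delta = w & 0x3FF
        if code == 0 and delta == 0:
            break
        if code == _SKIP:
            hi = int(words[i + 1])
            lo = int(words[i + 2])
            t += (hi << 16) | lo
            i += 3
            continue
        if code in (_NUM, _SUB, _CHN):
            i += 1
            continue
        if code == _AUX:
            i += 1 + (delta + 1) // 2
            continue
        t += delta
        out.append((t, _CODE_TO_SYMBOL.get(code, "Q")))
        i += 1
    return out


def _write_annotations(path, annotations):
    words = []
    prev = 0
    for idx, sym in sorted(annotations):
        code = _SYMBOL_TO_CODE.get(sym)
        if code is None:
            raise ValueError(f"cannot encode annotation symbol {sym!r}")
        delta = idx - prev
        if delta >= 1024 or delta < 0:
            words.append(_SKIP << 10)
            words.append((delta >> 16) & 0xFFFF)
            words.append(delta & 0xFFFF)
            delta = 0
        words.append((code << 10) | delta)
        prev = idx
    words.append(0)
    Path(path).write_bytes(np.asarray(words, dtype="<u2").tobytes())


# ---------------------------------------------------------------------------
# Stratified splitting
# ---------------------------------------------------------------------------

def stratified_split(labels, test_fraction=0.2, seed=0):
    """Largest-remainder stratified split -> (train_indices, test_indices).

    Per-class test counts are the floor of ``count * test_fraction`` with
    the remaining slots given to the classes with the largest fractional
    remainders, so the total equals ``round(n * test_fraction)`` and each
    class deviates from the target fraction by at most one beat.
    """
    labels = np.asarray(labels)
    if labels.size == 0:
        raise ValueError("labels must be nonempty")
    if not 0 < test_fraction < 1:
        raise ValueError("test_fraction must be in (0, 1)")
    classes, counts = np.unique(labels, return_counts=True)
    if counts.min() < 2:
        tiny = classes[counts < 2]
        raise ValueError(f"classes with fewer than 2 members: {list(tiny)}")

    quotas = counts * test_fraction
    base = np.floor(quotas).astype(int)
    total_test = int(round(labels.size * test_fraction))
    short = total_test - base.sum()
    order = np.argsort(-(quotas - base))
    take = base.copy()
    for j in order[:max(short, 0)]:
        take[j] += 1
    take = np.minimum(take, counts - 1)  # keep >=1 training member

    rng = np.random.default_rng(seed)
    test_idx = []
    for cls, k in zip(classes, take):
        members = np.flatnonzero(labels == cls)
        test_idx.extend(rng.permutation(members)[:k])
    test_idx = np.sort(np.asarray(test_idx, dtype=int))
    train_idx = np.setdiff1d(np.arange(labels.size), test_idx)
    return train_idx, test_idx
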