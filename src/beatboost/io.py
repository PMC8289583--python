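"""ECG record I/O, AAMI symbol mapping, segmentation and splits.

The WFDB codec here reads and writes the classic MIT-BIH record layout:
a ``.hea`` text header, a format-212 ``.dat`` signal file (two 12-bit
two's-complement samples packed into 3 bytes, channels interleaved per
frame), and a ``.atr`` annotation file (16-bit little-endian words, the
high 6 bits an annotation type code and the low 10 bits the sample
interval since the previous annotation, with SKIP/AUX/NUM/SUB/CHN
escape codes).  Only format 212 is supported; anything else raises a
format error naming the file.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "ECGRecord",
    "LabeledBeat",
    "WFDBFormatError",
    "map_to_aami",
    "read_wfdb",
    "write_wfdb",
    "segment_beats",
    "split_train_test",
    "split_indices",
    "write_split_manifest",
]


class WFDBFormatError(ValueError):
    """Malformed or unsupported WFDB file."""


@dataclass
class ECGRecord:
    """A sampled multi-lead record with beat annotations.

    ``leads`` is an ordered list of ``(lead_name, samples_in_mV)``;
    ``annotations`` a list of ``(sample_index, symbol)``.
    """

    record_id: str
    sampling_rate: float
    leads: list[tuple[str, np.ndarray]]
    annotations: list[tuple[int, str]]

    def __post_init__(self) -> None:
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        lengths = {len(sig) for _, sig in self.leads}
        if len(lengths) > 1:
            raise ValueError("all leads must have equal length")
        n = self.n_samples
        for s, _ in self.annotations:
            if not (0 <= s < n):
                raise ValueError(f"annotation index {s} outside [0, {n})")

    @property
    def n_samples(self) -> int:
        return len(self.leads[0][1]) if self.leads else 0

    def lead(self, idx: int) -> np.ndarray:
        return self.leads[idx][1]


@dataclass
class LabeledBeat:
    """One segmented beat: fixed-length windows around the R peak."""

    record_id: str
    r_sample: int
    aami_class: str
    lead_a_window: np.ndarray
    lead_b_window: np.ndarray | None = None


# ---------------------------------------------------------------------------
# AAMI EC57 symbol mapping
# ---------------------------------------------------------------------------

_AAMI_MAP = {
    **{s: "N" for s in "NLRej"},
    **{s: "S" for s in "AaJS"},
    **{s: "V" for s in "VE"},
    "F": "F",
    **{s: "Q" for s in "/fQ"},
}


def map_to_aami(symbol: str) -> str | None:
    """Map an MIT-BIH beat annotation symbol to its AAMI class.

    Non-beat symbols (rhythm changes, artifacts, ...) and unknown
    symbols return ``None`` (excluded) — unknown ones are logged.
    """
    cls = _AAMI_MAP.get(symbol)
    if cls is None and symbol not in "+~|\"!x[](){}pt=su@*D^`'?rnBT":
        logger.info("unknown annotation symbol %r excluded", symbol)
    return cls


# ---------------------------------------------------------------------------
# WFDB header + format-212 signal codec
# ---------------------------------------------------------------------------

_DEFAULT_GAIN = 200.0  # adu/mV, the MIT-BIH convention
_DEFAULT_ADC_RES = 12


def _pack_212(samples: np.ndarray) -> bytes:
    """Pack interleaved 12-bit two's-complement samples, 2 per 3 bytes."""
    s = np.asarray(samples, dtype=np.int64)
    if s.size % 2:
        s = np.concatenate([s, [0]])
    u = (s & 0xFFF).reshape(-1, 2)
    out = np.empty((u.shape[0], 3), dtype=np.uint8)
    out[:, 0] = u[:, 0] & 0xFF
    out[:, 1] = ((u[:, 0] >> 8) & 0x0F) | (((u[:, 1] >> 8) & 0x0F) << 4)
    out[:, 2] = u[:, 1] & 0xFF
    return out.tobytes()


def _unpack_212(raw: bytes, n_values: int) -> np.ndarray:
    need = (n_values + 1) // 2 * 3
    if len(raw) < need:
        raise WFDBFormatError(
            f".dat too short: {len(raw)} bytes, need {need} (offset {len(raw)})"
        )
    b = np.frombuffer(raw[:need], dtype=np.uint8).reshape(-1, 3).astype(np.int64)
    first = ((b[:, 1] & 0x0F) << 8) | b[:, 0]
    second = ((b[:, 1] & 0xF0) << 4) | b[:, 2]
    vals = np.empty(b.shape[0] * 2, dtype=np.int64)
    vals[0::2] = first
    vals[1::2] = second
    vals = vals[:n_values]
    vals[vals >= 2048] -= 4096  # 12-bit two's complement
    return vals


def write_wfdb(record: ECGRecord, directory, gain: float = _DEFAULT_GAIN) -> Path:
    """Write ``.hea`` + ``.dat`` (format 212) + ``.atr`` for ``record``.

    Returns the header path.  Samples are quantized to 12 bits at
    ``gain`` adu/mV; the annotation file stores beat symbols at their
    sample indices.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    name = record.record_id
    n_sig = len(record.leads)
    n_samp = record.n_samples

    digital = []
    for _, sig in record.leads:
        d = np.clip(np.round(np.asarray(sig) * gain), -2048, 2047).astype(np.int64)
        digital.append(d)
    interleaved = np.empty(n_sig * n_samp, dtype=np.int64)
    for i, d in enumerate(digital):
        interleaved[i::n_sig] = d
    (directory / f"{name}.dat").write_bytes(_pack_212(interleaved))

    fs = record.sampling_rate
    fs_txt = f"{fs:g}"
    lines = [f"{name} {n_sig} {fs_txt} {n_samp}"]
    for (lead_name, _), d in zip(record.leads, digital):
        first = int(d[0]) if n_samp else 0
        checksum = int(np.int16(d.sum() & 0xFFFF))
        lines.append(
            f"{name}.dat 212 {gain:g} {_DEFAULT_ADC_RES} 0 {first} {checksum} 0 {lead_name}"
        )
    (directory / f"{name}.hea").write_text("\n".join(lines) + "\n")

    _write_atr(directory / f"{name}.atr", record.annotations)
    return directory / f"{name}.hea"


def read_wfdb(record_path) -> ECGRecord:
    """Read a WFDB record (``.hea``/``.dat``/optional ``.atr``).

    ``record_path`` is the path to the header or its extension-less
    prefix.  Signals are returned in physical units (mV); annotation
    sample indices are preserved exactly.
    """
    path = Path(record_path)
    hea = path if path.suffix == ".hea" else path.with_suffix(".hea")
    if not hea.exists():
        raise WFDBFormatError(f"missing header file {hea}")
    lines = [
        ln.strip()
        for ln in hea.read_text().splitlines()
        if ln.strip() and not ln.startswith("#")
    ]
    head = lines[0].split()
    try:
        name = head[0].split("/")[0]
        n_sig = int(head[1])
        fs = float(head[2].split("/")[0]) if len(head) > 2 else 250.0
        n_samp = int(head[3]) if len(head) > 3 else 0
    except (IndexError, ValueError) as exc:
        raise WFDBFormatError(f"malformed record line in {hea}: {lines[0]!r}") from exc

    sig_lines = lines[1 : 1 + n_sig]
    if len(sig_lines) < n_sig:
        raise WFDBFormatError(f"{hea}: expected {n_sig} signal lines")
    dat_name = None
    gains, baselines, names = [], [], []
    for i, ln in enumerate(sig_lines):
        parts = ln.split()
        try:
            fname, fmt = parts[0], parts[1].split("x")[0]
        except IndexError as exc:
            raise WFDBFormatError(f"malformed signal line {i} in {hea}: {ln!r}") from exc
        if fmt != "212":
            raise WFDBFormatError(f"{hea}: unsupported signal format {fmt!r} (line {i})")
        if dat_name is None:
            dat_name = fname
        elif fname != dat_name:
            raise WFDBFormatError(f"{hea}: multi-file records are unsupported")
        gain_field = parts[2] if len(parts) > 2 else "200"
        gtxt = gain_field.split("/")[0]
        if "(" in gtxt:
            gtxt, btxt = gtxt.split("(")
            baseline = int(btxt.rstrip(")"))
        else:
            baseline = int(parts[4]) if len(parts) > 4 else 0
        gain = float(gtxt) or _DEFAULT_GAIN
        gains.append(gain)
        baselines.append(baseline)
        names.append(parts[8] if len(parts) > 8 else f"sig{i}")

    dat = hea.parent / dat_name
    if not dat.exists():
        raise WFDBFormatError(f"missing signal file {dat}")
    vals = _unpack_212(dat.read_bytes(), n_sig * n_samp)
    leads = []
    for i in range(n_sig):
        d = vals[i::n_sig]
        leads.append((names[i], (d - baselines[i]) / gains[i]))

    atr = hea.with_suffix(".atr")
    annotations = _read_atr(atr) if atr.exists() else []
    return ECGRecord(
        record_id=name, sampling_rate=fs, leads=leads, annotations=annotations
    )


# ---------------------------------------------------------------------------
# MIT annotation (.atr) codec
# ---------------------------------------------------------------------------

# Standard WFDB annotation type codes <-> symbols (beat + common non-beat).
_CODE_OF = {
    "N": 1, "L": 2, "R": 3, "a": 4, "V": 5, "F": 6, "J": 7, "A": 8,
    "S": 9, "E": 10, "j": 11, "/": 12, "Q": 13, "~": 14, "|": 16,
    "s": 18, "T": 19, '"': 22, "p": 24, "B": 25, "^": 26, "t": 27,
    "+": 28, "u": 29, "?": 30, "!": 31, "[": 32, "]": 33, "e": 34,
    "n": 35, "x": 37, "f": 38, "(": 39, ")": 40, "r": 41,
}
_SYMBOL_OF = {v: k for k, v in _CODE_OF.items()}
_SKIP, _NUM, _SUB, _CHN, _AUX = 59, 60, 61, 62, 63


def _write_atr(path: Path, annotations: list[tuple[int, str]]) -> None:
    out = bytearray()
    prev = 0
    for sample, symbol in sorted(annotations):
        code = _CODE_OF.get(symbol, _CODE_OF["Q"])
        dt = sample - prev
        if dt > 1023 or dt < 0:
            out += int(_SKIP << 10).to_bytes(2, "little")
            out += ((dt >> 16) & 0xFFFF).to_bytes(2, "little")
            out += (dt & 0xFFFF).to_bytes(2, "little")
            dt = 0
        out += ((code << 10) | dt).to_bytes(2, "little")
        prev = sample
    out += (0).to_bytes(2, "little")
    path.write_bytes(bytes(out))


def _read_atr(path: Path) -> list[tuple[int, str]]:
    raw = path.read_bytes()
    annotations: list[tuple[int, str]] = []
    time = 0
    pending = 0
    i = 0
    while i + 1 < len(raw):
        word = int.from_bytes(raw[i : i + 2], "little")
        i += 2
        code, dt = word >> 10, word & 0x3FF
        if code == 0 and dt == 0:
            break
        if code == _SKIP:
            if i + 3 >= len(raw):
                raise WFDBFormatError(f"{path}: truncated SKIP at offset {i}")
            high = int.from_bytes(raw[i : i + 2], "little")
            low = int.from_bytes(raw[i + 2 : i + 4], "little")
            i += 4
            pending += (high << 16) | low
            continue
        if code in (_NUM, _SUB, _CHN):
            continue
        if code == _AUX:
            i += dt + (dt & 1)  # aux string, padded to even length
            continue
        time += pending + dt
        pending = 0
        annotations.append((time, _SYMBOL_OF.get(code, "Q")))
    return annotations


# ---------------------------------------------------------------------------
# Segmentation and splits
# ---------------------------------------------------------------------------

def segment_beats(
    record: ECGRecord,
    r_indices,
    labels,
    pre: int = 90,
    post: int = 144,
    signals: list[np.ndarray] | None = None,
) -> list[LabeledBeat]:
    """Cut fixed windows ``[r-pre, r+post]`` (inclusive) around R peaks.

    Beats whose window would exceed the record bounds are dropped.  With
    the defaults the window holds ``pre + post + 1 = 235`` samples per
    lead.  ``signals`` may supply preprocessed per-lead arrays to window
    instead of the raw record samples (same lengths required).
    """
    r_indices = np.asarray(r_indices, dtype=int)
    if np.any(np.diff(r_indices) < 0):
        raise ValueError("r_indices must be sorted ascending")
    if signals is None:
        signals = [sig for _, sig in record.leads]
    n = len(signals[0])
    beats = []
    for r, lab in zip(r_indices, labels):
        if r - pre < 0 or r + post >= n:
            continue
        win_a = np.asarray(signals[0][r - pre : r + post + 1])
        win_b = (
            np.asarray(signals[1][r - pre : r + post + 1])
            if len(signals) > 1
            else None
        )
        beats.append(
            LabeledBeat(
                record_id=record.record_id,
                r_sample=int(r),
                aami_class=str(lab),
                lead_a_window=win_a,
                lead_b_window=win_b,
            )
        )
    return beats


def split_indices(
    labels,
    train_frac: float = 0.9,
    seed: int = 0,
    stratify: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Disjoint, exhaustive train/test index partition.

    Stratified by class by default: each class contributes
    ``round(count * (1 - train_frac))`` test beats (at least 0); a class
    with fewer than 2 members goes wholly to training with a warning.
    Deterministic under ``seed``.
    """
    if not 0 < train_frac < 1:
        raise ValueError("train_frac must be in (0, 1)")
    labels = np.asarray(labels, dtype=object)
    rng = np.random.default_rng(seed)
    n = len(labels)
    if not stratify:
        perm = rng.permutation(n)
        n_test = int(round(n * (1 - train_frac)))
        test = np.sort(perm[:n_test])
        train = np.sort(perm[n_test:])
        return train, test
    test_parts = []
    # iterate classes in stable first-appearance order for determinism
    seen: dict[object, list[int]] = {}
    for i, lab in enumerate(labels):
        seen.setdefault(lab, []).append(i)
    for lab, idx in seen.items():
        idx = np.array(idx)
        if len(idx) < 2:
            warnings.warn(
                f"class {lab!r} has {len(idx)} beat(s); placed wholly in training",
                stacklevel=2,
            )
            continue
        n_test = int(round(len(idx) * (1 - train_frac)))
        n_test = min(n_test, len(idx) - 1)
        perm = rng.permutation(len(idx))
        test_parts.append(idx[perm[:n_test]])
    test = np.sort(np.concatenate(test_parts)) if test_parts else np.array([], dtype=int)
    mask = np.ones(n, dtype=bool)
    mask[test] = False
    train = np.nonzero(mask)[0]
    return train, test


def split_train_test(
    beats,
    train_frac: float = 0.9,
    seed: int = 0,
    stratify: bool = True,
):
    """Partition a sequence of :class:`LabeledBeat` (or labels) 90/10.

    Returns ``(train, test)`` sub-sequences in original order.
    """
    labels = [
        b.aami_class if isinstance(b, LabeledBeat) else b for b in beats
    ]
    train_idx, test_idx = split_indices(labels, train_frac, seed, stratify)
    return [beats[i] for i in train_idx], [beats[i] for i in test_idx]


def write_split_manifest(path, seed: int, train_ids, test_ids) -> None:
    payload = {
        "seed": int(seed),
        "train_ids": [int(i) for i in train_ids],
        "test_ids": [int(i) for i in test_ids],
    }
    Path(path).write_text(json.dumps(payload, sort_keys=True))
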