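"""Per-beat attributable feature sets A–E and matrix assembly.

Set A  235 lead-A morphology samples (90 before the R peak, the R
       sample itself, 144 after).
Set B  470 dual-lead morphology samples (lead A window ++ lead B window).
Set C  7 interval features in seconds: P-wave interval, QRS interval,
       T-wave interval, PR segment, ST-T interval, QT interval, RR
       interval — each a simple difference of fiducial samples divided
       by the sampling rate.
Set D  QRS area (mV*s): trapezoidal integral of |signal - baseline|
       over the QRS complex, baseline = mean of the PR segment (making
       the area invariant to constant offsets).
Set E  db6 discrete wavelet coefficients of the lead-A window
       (level 4 by default; periodized, so the transform is orthogonal
       and energy-preserving).

Interval features that cannot be computed for a beat (undetected P,
last beat's RR) are NaN at the per-beat level; at assembly time they
are imputed with the per-record median of that column (and the
imputation is flagged), keeping the matrix rectangular.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pywt

from beatboost.io import LabeledBeat
from beatboost.preprocess import BeatFiducials

logger = logging.getLogger(__name__)

__all__ = [
    "FeatureMatrix",
    "INTERVAL_NAMES",
    "assemble",
    "interval_features",
    "morphology_features",
    "qrs_area",
    "wavelet_features",
    "wavelet_feature_length",
]

INTERVAL_NAMES = ("C_P", "C_QRS", "C_T", "C_PR", "C_STT", "C_QT", "C_RR")
SET_ORDER = "ABCDE"


@dataclass
class FeatureMatrix:
    """Rectangular per-beat feature matrix tagged by active sets."""

    X: np.ndarray
    column_names: list[str]
    labels: np.ndarray
    active_sets: str
    imputed: np.ndarray = field(default_factory=lambda: np.array([], dtype=bool))

    def __post_init__(self) -> None:
        if self.X.ndim != 2 or self.X.shape[1] != len(self.column_names):
            raise ValueError("column names must match matrix width")
        if len(self.labels) != self.X.shape[0]:
            raise ValueError("labels must match matrix height")

    @property
    def n_beats(self) -> int:
        return self.X.shape[0]

    def subset(self, active_sets: str) -> "FeatureMatrix":
        """Column-restrict to a sub-combination of the active sets."""
        active = _canon_sets(active_sets)
        for s in active:
            if s not in self.active_sets:
                raise ValueError(f"set {s!r} not present in this matrix")
        cols = [
            i
            for i, name in enumerate(self.column_names)
            if name.split("_")[0] in active
        ]
        return FeatureMatrix(
            X=self.X[:, cols],
            column_names=[self.column_names[i] for i in cols],
            labels=self.labels,
            active_sets=active,
            imputed=self.imputed,
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.X, columns=self.column_names)
        df["label"] = self.labels
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.10g")

    @classmethod
    def from_csv(cls, path) -> "FeatureMatrix":
        df = pd.read_csv(path)
        labels = df.pop("label").to_numpy(dtype=object)
        sets = "".join(
            s for s in SET_ORDER if any(c.startswith(s + "_") for c in df.columns)
        )
        return cls(
            X=df.to_numpy(dtype=float),
            column_names=list(df.columns),
            labels=labels,
            active_sets=sets,
        )


def _canon_sets(active_sets: str) -> str:
    s = "".join(dict.fromkeys(active_sets.upper()))
    if not s or any(c not in SET_ORDER for c in s):
        raise ValueError(f"invalid feature-set spec {active_sets!r}")
    return "".join(c for c in SET_ORDER if c in s)


def morphology_features(beat: LabeledBeat, dual_lead: bool = False) -> np.ndarray:
    """Set A (235 samples, lead A) or set B (470 samples, both leads)."""
    a = np.asarray(beat.lead_a_window, dtype=float)
    if not dual_lead:
        return a.copy()
    if beat.lead_b_window is None:
        raise ValueError("dual-lead features requested but lead B is missing")
    return np.concatenate([a, np.asarray(beat.lead_b_window, dtype=float)])


def interval_features(
    fid: BeatFiducials,
    next_r: int | float | None,
    sampling_rate: float,
) -> np.ndarray:
    """The 7 set-C interval features (seconds) of one beat.

    ``next_r`` is the following beat's R sample (``None`` or NaN for
    the last beat, whose RR is NaN here and imputed downstream).
    Undetected waves yield NaN in the affected entries.
    """
    if sampling_rate <= 0:
        raise ValueError("sampling_rate must be positive")
    fs = sampling_rate
    out = np.full(7, np.nan)
    if fid.p_detected:
        out[0] = (fid.p_off - fid.p_on) / fs
        if fid.qrs_on is not None:
            out[3] = (fid.qrs_on - fid.p_off) / fs  # PR segment
    if fid.qrs_on is not None and fid.qrs_off is not None:
        out[1] = (fid.qrs_off - fid.qrs_on) / fs
    if fid.t_detected:
        out[2] = (fid.t_off - fid.t_on) / fs
        if fid.qrs_off is not None:
            out[4] = (fid.t_off - fid.qrs_off) / fs  # ST-T
        if fid.qrs_on is not None:
            out[5] = (fid.t_off - fid.qrs_on) / fs  # QT
    if next_r is not None and not (isinstance(next_r, float) and np.isnan(next_r)):
        if next_r <= fid.r_peak:
            raise ValueError("next_r must exceed the current R peak")
        out[6] = (next_r - fid.r_peak) / fs
    return out


def qrs_area(
    signal: np.ndarray,
    fid: BeatFiducials,
    sampling_rate: float,
) -> float:
    """Trapezoidal integral of |signal - baseline| over the QRS (mV*s).

    Baseline is the PR-segment mean (P offset to QRS onset); when no P
    was detected, the 40 ms preceding QRS onset.  Subtracting it makes
    the area invariant to constant offsets.
    """
    x = np.asarray(signal, dtype=float)
    if fid.qrs_on is None or fid.qrs_off is None:
        raise ValueError("QRS boundaries are required")
    on, off = int(fid.qrs_on), int(fid.qrs_off)
    if off - on < 2:
        raise ValueError(f"degenerate QRS window [{on}, {off}]")
    if fid.p_detected and fid.p_off < on:
        base_seg = x[fid.p_off : on]
    else:
        lo = max(0, on - int(round(0.04 * sampling_rate)))
        base_seg = x[lo:on]
    baseline = float(base_seg.mean()) if len(base_seg) else 0.0
    seg = np.abs(x[on : off + 1] - baseline)
    return float(np.trapezoid(seg, dx=1.0 / sampling_rate))


def wavelet_features(
    beat_window: np.ndarray,
    wavelet: str = "db6",
    level: int = 4,
) -> np.ndarray:
    """Set E: concatenated multilevel db6 DWT coefficients of a window.

    The window is extended to the next multiple of ``2**level`` by
    repeating its last sample, so the periodized decomposition is
    exactly orthogonal (coefficient energy equals the extended
    window's energy), constant windows keep exactly-zero detail
    coefficients, and the output length is fixed for a fixed (window
    length, level) — 240 coefficients for the default 235-sample
    window at level 4.
    """
    x = np.asarray(beat_window, dtype=float)
    w = pywt.Wavelet(wavelet)
    block = 2 ** level
    padded = (len(x) + block - 1) // block * block
    max_level = pywt.dwt_max_level(padded, w.dec_len)
    if level < 1 or level > max_level:
        raise ValueError(
            f"level {level} unsupported for window length {len(x)} "
            f"(max {max_level})"
        )
    if padded > len(x):
        x = np.concatenate([x, np.full(padded - len(x), x[-1])])
    coeffs = pywt.wavedec(x, w, mode="periodization", level=level)
    return np.concatenate(coeffs)


def wavelet_feature_length(window_len: int, wavelet: str = "db6", level: int = 4) -> int:
    block = 2 ** level
    return (window_len + block - 1) // block * block


def assemble(
    beats: list[LabeledBeat],
    fiducials: list[BeatFiducials] | None,
    active_sets: str,
    sampling_rate: float = 360.0,
    next_r: list[int | None] | None = None,
    signal: np.ndarray | None = None,
    wavelet_level: int = 4,
    impute: bool = True,
) -> FeatureMatrix:
    """Build the feature matrix for any combination of sets A–E.

    Columns follow the canonical order A, B, C, D, E restricted to the
    active sets.  Sets C and D require ``fiducials`` (one per beat, in
    the coordinates of ``signal``, the full lead-A record array — set D
    integrates over it); set C's RR additionally uses ``next_r`` (the
    next beat's R sample, ``None`` for the last beat of a record).
    NaN entries (undetected waves, final RR) are imputed with the
    per-record column median and flagged in ``imputed``.
    """
    active = _canon_sets(active_sets)
    if not beats:
        raise ValueError("no beats to assemble")
    if ("C" in active or "D" in active) and fiducials is None:
        raise ValueError("sets C/D require per-beat fiducials")
    if "D" in active and signal is None:
        raise ValueError("set D requires the full lead-A signal")
    if fiducials is not None and len(fiducials) != len(beats):
        raise ValueError("fiducials must match beats one-to-one")
    if next_r is None:
        next_r = [None] * len(beats)

    blocks: list[np.ndarray] = []
    names: list[str] = []
    for s in active:
        if s == "A":
            block = np.stack([morphology_features(b, dual_lead=False) for b in beats])
            names += [f"A_{i:03d}" for i in range(block.shape[1])]
        elif s == "B":
            block = np.stack([morphology_features(b, dual_lead=True) for b in beats])
            names += [f"B_{i:03d}" for i in range(block.shape[1])]
        elif s == "C":
            block = np.stack(
                [
                    interval_features(f, nr, sampling_rate)
                    for f, nr in zip(fiducials, next_r)
                ]
            )
            names += list(INTERVAL_NAMES)
        elif s == "D":
            block = np.array(
                [[qrs_area(signal, f, sampling_rate)] for f in fiducials]
            )
            names += ["D_area"]
        else:  # E
            block = np.stack(
                [
                    wavelet_features(b.lead_a_window, level=wavelet_level)
                    for b in beats
                ]
            )
            names += [f"E_{i:03d}" for i in range(block.shape[1])]
        blocks.append(block)

    X = np.hstack(blocks)
    imputed = np.zeros(X.shape[0], dtype=bool)
    if impute:
        nan_mask = np.isnan(X)
        if nan_mask.any():
            imputed = nan_mask.any(axis=1)
            col_med = np.nanmedian(X, axis=0)
            col_med = np.where(np.isnan(col_med), 0.0, col_med)
            X = np.where(nan_mask, col_med[None, :], X)
            logger.info(
                "imputed %d NaN entries in %d beats with column medians",
                int(nan_mask.sum()),
                int(imputed.sum()),
            )
    labels = np.array([b.aami_class for b in beats], dtype=object)
    return FeatureMatrix(
        X=X, column_names=names, labels=labels, active_sets=active, imputed=imputed
    )
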