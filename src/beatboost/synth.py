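"""Synthetic two-lead ECG generator with exact ground truth.

Each heartbeat is modeled as a sum of three Gaussian bumps (P, QRS, T)
per lead.  The model is deliberately simple: a Gaussian bump of
amplitude ``a`` (mV), total width ``w`` (s, taken as six standard
deviations) and center offset ``c`` (s, relative to the R peak) has
analytically known wave boundaries at ``c - 3*sigma`` and
``c + 3*sigma``, so the generator can emit exact fiducial indices
alongside the signal.  Class-dependent morphology and rhythm (absent P
waves, widened QRS, premature RR intervals, inverted T) emulate the
AAMI five-class taxonomy at the level needed to exercise detection,
delineation, feature extraction and classification — not at the level
of a physiological torso model.

Lead A plays the role of a limb lead (II) with a dominant positive QRS;
lead B is derived from the same wave parameters through a per-wave
scale/sign transform, emulating a precordial lead (V1).

Noise is additive: sinusoidal baseline wander, sinusoidal powerline
interference, and white Gaussian noise, each per lead.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from beatboost.evaluate import AAMI_CLASSES

__all__ = [
    "BeatTemplate",
    "GroundTruth",
    "GroundTruthBeat",
    "NoiseConfig",
    "SynthConfig",
    "TABLE1_PROPORTIONS",
    "default_templates",
    "generate_record",
    "ground_truth_feature_table",
]

#: Per-class beat counts of the MIT-BIH arrhythmia database under the
#: AAMI grouping, used as default class proportions.
TABLE1_COUNTS = {"N": 90595, "S": 2781, "V": 7235, "F": 802, "Q": 8041}
_TOTAL = sum(TABLE1_COUNTS.values())
TABLE1_PROPORTIONS = {k: v / _TOTAL for k, v in TABLE1_COUNTS.items()}

#: Sentinel index for an absent wave in ground-truth fiducials.
MISSING = -1


@dataclass(frozen=True)
class BeatTemplate:
    """Morphology/rhythm template for one AAMI class.

    ``wave_params`` maps wave name ('P', 'QRS', 'T') to
    ``(amplitude_mV, width_s, center_offset_s)``; the QRS center offset
    is 0 by definition (the R peak).  ``width_s`` spans six standard
    deviations of the Gaussian bump, so the true wave boundaries sit at
    the center +/- half the width.
    """

    class_label: str
    wave_params: dict[str, tuple[float, float, float]]
    rr_mean: float
    rr_sd: float
    p_present: bool = True
    #: relative beat-to-beat variation of wave amplitudes and widths
    #: (multiplicative, clipped to keep the QRS dominant); real rhythms
    #: vary beat to beat, and without this the classes would be
    #: trivially separable from any single feature
    amp_jitter: float = 0.15
    width_jitter: float = 0.08

    def __post_init__(self) -> None:
        if self.class_label not in AAMI_CLASSES:
            raise ValueError(f"unknown AAMI class {self.class_label!r}")
        if self.rr_mean <= 0:
            raise ValueError("rr_mean must be positive")
        for wave, (_, width, center) in self.wave_params.items():
            if width <= 0:
                raise ValueError(f"{wave} width must be positive")
            if wave == "QRS" and center != 0.0:
                raise ValueError("QRS center offset must be 0")


@dataclass(frozen=True)
class NoiseConfig:
    """Additive noise amplitudes (mV) and frequencies (Hz)."""

    baseline_wander_amp: float = 0.10
    baseline_wander_freq: float = 0.30
    powerline_amp: float = 0.02
    powerline_freq: float = 60.0
    white_sd: float = 0.03

    @classmethod
    def none(cls) -> "NoiseConfig":
        return cls(baseline_wander_amp=0.0, powerline_amp=0.0, white_sd=0.0)


@dataclass(frozen=True)
class SynthConfig:
    """Configuration of one synthetic record."""

    sampling_rate: float = 360.0
    n_beats: int = 500
    class_proportions: dict[str, float] = field(
        default_factory=lambda: dict(TABLE1_PROPORTIONS)
    )
    noise: NoiseConfig = field(default_factory=NoiseConfig)
    #: Per-wave (scale) factors applied to lead A's wave amplitudes to
    #: build lead B; signs may flip (e.g. a mostly negative QRS in V1).
    lead_transform: dict[str, float] = field(
        default_factory=lambda: {"P": 0.5, "QRS": -0.7, "T": 0.4}
    )
    rr_min: float = 0.3
    lead_in: float = 0.4
    lead_out: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if self.n_beats < 1:
            raise ValueError("n_beats must be >= 1")
        total = sum(self.class_proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"class proportions sum to {total}, expected 1")
        for k in self.class_proportions:
            if k not in AAMI_CLASSES:
                raise ValueError(f"unknown class {k!r} in proportions")


@dataclass(frozen=True)
class GroundTruthBeat:
    """True fiducial indices (samples) and label of one beat.

    Absent waves carry :data:`MISSING` for both boundaries.
    """

    beat_index: int
    r_sample: int
    p_on: int
    p_off: int
    qrs_on: int
    qrs_off: int
    t_on: int
    t_off: int
    label: str


@dataclass(frozen=True)
class GroundTruth:
    beats: tuple[GroundTruthBeat, ...]
    sampling_rate: float
    n_samples: int

    def r_samples(self) -> np.ndarray:
        return np.array([b.r_sample for b in self.beats], dtype=int)

    def labels(self) -> np.ndarray:
        return np.array([b.label for b in self.beats], dtype=object)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([dataclasses.asdict(b) for b in self.beats])


def default_templates() -> dict[str, BeatTemplate]:
    """Class templates emulating the AAMI taxonomy's gross morphology.

    N: full P-QRS-T at a resting rhythm.  S: premature (short RR) with
    absent P.  V: wide, tall QRS with inverted T and no P.  F: fusion —
    intermediate QRS width with a small P.  Q: low-amplitude, wide,
    atypical complex (paced/unknown morphology).
    """
    return {
        "N": BeatTemplate(
            "N",
            {"P": (0.15, 0.09, -0.17), "QRS": (1.0, 0.07, 0.0), "T": (0.35, 0.16, 0.30)},
            rr_mean=0.80,
            rr_sd=0.05,
        ),
        "S": BeatTemplate(
            "S",
            {"QRS": (0.9, 0.06, 0.0), "T": (0.25, 0.14, 0.28)},
            rr_mean=0.58,
            rr_sd=0.05,
            p_present=False,
        ),
        "V": BeatTemplate(
            "V",
            {"QRS": (1.4, 0.14, 0.0), "T": (-0.45, 0.18, 0.32)},
            rr_mean=0.85,
            rr_sd=0.10,
            p_present=False,
        ),
        "F": BeatTemplate(
            "F",
            {"P": (0.12, 0.09, -0.17), "QRS": (1.1, 0.11, 0.0), "T": (0.30, 0.16, 0.30)},
            rr_mean=0.78,
            rr_sd=0.06,
        ),
        "Q": BeatTemplate(
            "Q",
            {"QRS": (0.7, 0.12, 0.0), "T": (0.12, 0.14, 0.30)},
            rr_mean=0.72,
            rr_sd=0.10,
            p_present=False,
        ),
    }


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float,
                      low: float, size: int) -> np.ndarray:
    """Normal draws resampled (not clipped) until all exceed ``low``."""
    out = rng.normal(mean, sd, size)
    bad = out < low
    # bounded loop: with sane templates the truncation mass is tiny
    for _ in range(100):
        if not bad.any():
            break
        out[bad] = rng.normal(mean, sd, int(bad.sum()))
        bad = out < low
    out[out < low] = low
    return out


def _add_bump(signal: np.ndarray, fs: float, center_s: float,
              amp: float, width_s: float) -> None:
    sigma = width_s / 6.0
    lo = max(0, int(math.floor((center_s - 4 * sigma) * fs)))
    hi = min(len(signal), int(math.ceil((center_s + 4 * sigma) * fs)) + 1)
    if hi <= lo:
        return
    t = np.arange(lo, hi) / fs
    signal[lo:hi] += amp * np.exp(-0.5 * ((t - center_s) / sigma) ** 2)


def generate_record(
    config: SynthConfig,
    templates: dict[str, BeatTemplate] | None = None,
) -> tuple["ECGRecord", GroundTruth]:
    """Generate a labeled two-lead record plus exact ground truth.

    Deterministic: identical ``(config, templates)`` (including
    ``config.seed``) yield bit-identical signals and ground truth.

    Returns an :class:`beatboost.io.ECGRecord` whose annotations are
    ``(r_sample, symbol)`` pairs using one representative MIT-BIH beat
    symbol per class, and a :class:`GroundTruth` with per-beat fiducials.
    """
    from beatboost.io import ECGRecord  # local import to avoid a cycle

    if templates is None:
        templates = default_templates()
    fs = config.sampling_rate
    rng = np.random.default_rng(config.seed)

    classes = [c for c in AAMI_CLASSES if config.class_proportions.get(c, 0.0) > 0]
    probs = np.array([config.class_proportions[c] for c in classes])
    for c in classes:
        if c not in templates:
            raise ValueError(f"no template for sampled class {c!r}")
    labels = rng.choice(np.array(classes, dtype=object), size=config.n_beats, p=probs)

    # RR interval preceding beat i drawn from beat i's own template
    # (premature beats arrive early).
    rr = np.empty(config.n_beats)
    rr[0] = 0.0
    for i in range(1, config.n_beats):
        tpl = templates[labels[i]]
        rr[i] = _truncated_normal(rng, tpl.rr_mean, tpl.rr_sd, config.rr_min, 1)[0]
    r_times = config.lead_in + np.cumsum(rr)

    n_samples = int(math.ceil((r_times[-1] + config.lead_out) * fs))
    leads = {"leadA": np.zeros(n_samples), "leadB": np.zeros(n_samples)}

    beats: list[GroundTruthBeat] = []
    for i, (t_r, lab) in enumerate(zip(r_times, labels)):
        tpl = templates[lab]
        fid: dict[str, tuple[int, int]] = {}
        for wave, (amp, width, center) in tpl.wave_params.items():
            if wave == "P" and not tpl.p_present:
                continue
            amp = amp * float(np.clip(rng.normal(1.0, tpl.amp_jitter), 0.7, 1.3))
            width = width * float(np.clip(rng.normal(1.0, tpl.width_jitter), 0.8, 1.2))
            _add_bump(leads["leadA"], fs, t_r + center, amp, width)
            scale = config.lead_transform.get(wave, 1.0)
            _add_bump(leads["leadB"], fs, t_r + center, amp * scale, width)
            sigma = width / 6.0
            fid[wave] = (
                int(round((t_r + center - 3 * sigma) * fs)),
                int(round((t_r + center + 3 * sigma) * fs)),
            )
        p_on, p_off = fid.get("P", (MISSING, MISSING))
        beats.append(
            GroundTruthBeat(
                beat_index=i,
                r_sample=int(round(t_r * fs)),
                p_on=p_on,
                p_off=p_off,
                qrs_on=fid["QRS"][0],
                qrs_off=fid["QRS"][1],
                t_on=fid["T"][0],
                t_off=fid["T"][1],
                label=str(lab),
            )
        )

    t = np.arange(n_samples) / fs
    nz = config.noise
    for name in leads:
        if nz.baseline_wander_amp > 0:
            phase = rng.uniform(0, 2 * np.pi)
            leads[name] += nz.baseline_wander_amp * np.sin(
                2 * np.pi * nz.baseline_wander_freq * t + phase
            )
        if nz.powerline_amp > 0:
            phase = rng.uniform(0, 2 * np.pi)
            leads[name] += nz.powerline_amp * np.sin(
                2 * np.pi * nz.powerline_freq * t + phase
            )
        if nz.white_sd > 0:
            leads[name] += rng.normal(0.0, nz.white_sd, n_samples)

    symbol_of = {"N": "N", "S": "A", "V": "V", "F": "F", "Q": "Q"}
    annotations = [(b.r_sample, symbol_of[b.label]) for b in beats]
    record = ECGRecord(
        record_id=f"synth{config.seed:04d}",
        sampling_rate=fs,
        leads=[(name, sig) for name, sig in leads.items()],
        annotations=annotations,
    )
    gt = GroundTruth(beats=tuple(beats), sampling_rate=fs, n_samples=n_samples)
    return record, gt


def ground_truth_feature_table(
    gt: GroundTruth,
    config: SynthConfig,
    pre: int = 90,
    post: int = 144,
) -> pd.DataFrame:
    """Interval features computed directly from true fiducials.

    Serves as the oracle for the detected-fiducial feature path: one row
    per beat whose segmentation window ``[r-pre, r+post]`` fits inside
    the record (out-of-bounds beats are excluded, mirroring beat
    segmentation).  Columns match the feature module's set-C naming.
    The RR interval of the final beat repeats the previous beat's RR
    (documented sentinel); intervals of absent waves are NaN.
    """
    if not gt.beats:
        raise ValueError("ground truth is empty")
    fs = gt.sampling_rate
    rows = []
    r_all = gt.r_samples()
    for i, b in enumerate(gt.beats):
        if b.r_sample - pre < 0 or b.r_sample + post >= gt.n_samples:
            continue
        has_p = b.p_on != MISSING
        p_int = (b.p_off - b.p_on) / fs if has_p else np.nan
        pr_seg = (b.qrs_on - b.p_off) / fs if has_p else np.nan
        if i + 1 < len(gt.beats):
            rr = (r_all[i + 1] - b.r_sample) / fs
        elif i > 0:
            rr = (b.r_sample - r_all[i - 1]) / fs  # repeat previous RR
        else:
            rr = np.nan
        rows.append(
            {
                "beat_index": b.beat_index,
                "C_P": p_int,
                "C_QRS": (b.qrs_off - b.qrs_on) / fs,
                "C_T": (b.t_off - b.t_on) / fs,
                "C_PR": pr_seg,
                "C_STT": (b.t_off - b.qrs_off) / fs,
                "C_QT": (b.t_off - b.qrs_on) / fs,
                "C_RR": rr,
                "label": b.label,
            }
        )
    return pd.DataFrame(rows)
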