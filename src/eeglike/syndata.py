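"""Synthetic multichannel EEG recordings with a planted liking signature.

The generator emulates the shape of a gallery-walk EEG study: per subject,
a 60 s blank-wall baseline followed by one 60 s observation segment per
painting, recorded from a 64-channel dry-electrode cap at 512 Hz, with an
integer liking score in [0, 50] per (subject, painting) trial.

Scores are drawn from a two-component truncated-normal mixture (defaults:
means 15 and 35, sd 6, equal weights), rounded to integers — a non-normal
distribution symmetric about the scale midpoint of 25.  Trials whose score
came from the high ("like") component carry a band-limited oscillatory
burst (default 36-44 Hz, inside the gamma range) on a subset of target
channels during a contiguous random sub-window of the trial; "dislike"
trials carry no burst by default.  The background on every channel is
white noise low-pass filtered to the analysis range (0, 52] Hz, so every
4 Hz analysis band is populated.

Everything is a pure function of (config, seed): identical inputs give
bit-identical output.
"""

from __future__ import annotations

import os
import struct
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy import stats

__all__ = [
    "PatternSpec",
    "ScoreModel",
    "SimConfig",
    "Annotation",
    "Recording",
    "simulate_scores",
    "simulate_recording",
    "write_recording",
    "read_recording",
]


@dataclass(frozen=True)
class PatternSpec:
    """Planted class-dependent oscillatory burst.

    carrier_band:     (low, high) Hz of the burst's band-limited carrier
    target_channels:  channel ids carrying the burst (None: first two channels)
    burst_fraction:   fraction of the trial covered by the contiguous burst
    like_amplitude:   carrier standard deviation added on "like" trials
    dislike_amplitude: same for "dislike" trials
    """

    carrier_band: tuple[float, float] = (36.0, 44.0)
    target_channels: tuple[str, ...] | None = None
    burst_fraction: float = 0.3
    like_amplitude: float = 2.0
    dislike_amplitude: float = 0.0

    def __post_init__(self):
        lo, hi = self.carrier_band
        if not (0.0 < lo < hi):
            raise ValueError(f"invalid carrier band {self.carrier_band}")
        if not (0.0 < self.burst_fraction <= 1.0):
            raise ValueError("burst_fraction must be in (0, 1]")


@dataclass(frozen=True)
class ScoreModel:
    """Two-component truncated-normal mixture of VAS liking scores on [0, 50]."""

    component_means: tuple[float, float] = (15.0, 35.0)
    component_sd: float = 6.0
    mixture_weight: float = 0.5
    vmin: int = 0
    vmax: int = 50


@dataclass(frozen=True)
class SimConfig:
    n_subjects: int = 16
    n_paintings: int = 18
    n_channels: int = 64
    fs: float = 512.0
    trial_seconds: float = 60.0
    blank_seconds: float = 60.0
    noise_sd: float = 1.0
    pattern: PatternSpec = field(default_factory=PatternSpec)
    score_model: ScoreModel = field(default_factory=ScoreModel)
    seed: int = 0

    def __post_init__(self):
        if self.fs <= 0 or self.trial_seconds <= 0 or self.n_channels < 1:
            raise ValueError("fs and trial_seconds must be positive, n_channels >= 1")
        if self.pattern.carrier_band[1] >= self.fs / 2:
            raise ValueError(
                f"carrier band {self.pattern.carrier_band} reaches the Nyquist "
                f"frequency {self.fs / 2} Hz; lower the band or raise fs"
            )


@dataclass(frozen=True)
class Annotation:
    onset: float  # s, relative to recording start
    duration: float  # s
    painting: int
    subject: int


@dataclass
class Recording:
    """Multichannel signal plus trial annotations and liking scores."""

    signal: np.ndarray  # channels x samples
    fs: float
    channel_ids: list[str]
    annotations: list[Annotation]
    scores: dict[tuple[int, int], int]  # (subject, painting) -> VAS integer

    def __post_init__(self):
        if len(set(self.channel_ids)) != len(self.channel_ids):
            raise ValueError("channel ids must be unique")
        n = self.signal.shape[1]
        for a in self.annotations:
            if a.onset < 0 or round((a.onset + a.duration) * self.fs) > n:
                raise ValueError(f"annotation {a} lies outside the signal")


def default_channel_ids(n_channels: int) -> list[str]:
    return [f"E{i + 1}" for i in range(n_channels)]


# ---------------------------------------------------------------------------
# scores
# ---------------------------------------------------------------------------


def _draw_component_scores(model: ScoreModel, comps: np.ndarray, rng) -> np.ndarray:
    """Truncated-normal draw per component assignment, rounded to integers."""
    out = np.empty(comps.size, dtype=int)
    for c in (0, 1):
        mask = comps == c
        k = int(mask.sum())
        if k == 0:
            continue
        mu = model.component_means[c]
        sd = model.component_sd
        if sd == 0:
            vals = np.full(k, mu)
        else:
            a = (model.vmin - mu) / sd
            b = (model.vmax - mu) / sd
            vals = stats.truncnorm.rvs(a, b, loc=mu, scale=sd, size=k, random_state=rng)
        out[mask] = np.clip(np.rint(vals), model.vmin, model.vmax).astype(int)
    return out


def simulate_scores(model: ScoreModel, n: int, seed: int) -> list[int]:
    """Draw ``n`` integer VAS scores from the mixture model."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    comps = (rng.random(n) >= model.mixture_weight).astype(int)
    return [int(v) for v in _draw_component_scores(model, comps, rng)]


# ---------------------------------------------------------------------------
# signal synthesis
# ---------------------------------------------------------------------------


def _lowpass_noise(rng, n_channels: int, n_samples: int, fs: float, sd: float,
                   cutoff: float = 52.0) -> np.ndarray:
    """White noise filtered to (0, cutoff] Hz, per channel."""
    x = rng.standard_normal((n_channels, n_samples)) * sd
    if sd == 0 or n_samples == 0:
        return x
    if cutoff < fs / 2:
        sos = sps.butter(6, cutoff, btype="low", fs=fs, output="sos")
        x = sps.sosfiltfilt(sos, x, axis=1)
    return np.ascontiguousarray(x)


def _bandlimited_carrier(rng, n_samples: int, fs: float,
                         band: tuple[float, float]) -> np.ndarray:
    """Unit-variance noise band-passed to ``band``."""
    x = rng.standard_normal(n_samples)
    sos = sps.butter(4, band, btype="bandpass", fs=fs, output="sos")
    y = sps.sosfiltfilt(sos, x)
    sd = y.std()
    return y / sd if sd > 0 else y


def simulate_recording(config: SimConfig) -> Recording:
    """Synthesize the full study recording.

    The signal concatenates, per subject, a blank segment followed by one
    segment per painting; annotations mark the painting segments only.
    Like-component trials receive the planted burst on the pattern's target
    channels during a contiguous window with a uniformly random onset.
    """
    rng = np.random.default_rng(config.seed)
    fs = config.fs
    n_trial = round(config.trial_seconds * fs)
    n_blank = round(config.blank_seconds * fs)
    per_subject = n_blank + config.n_paintings * n_trial
    n_total = config.n_subjects * per_subject
    channel_ids = default_channel_ids(config.n_channels)

    pattern = config.pattern
    if pattern.target_channels is None:
        targets = channel_ids[: min(2, config.n_channels)]
    else:
        missing = set(pattern.target_channels) - set(channel_ids)
        if missing:
            raise ValueError(f"target channels not in montage: {sorted(missing)}")
        targets = list(pattern.target_channels)
    target_idx = [channel_ids.index(t) for t in targets]

    sig = _lowpass_noise(rng, config.n_channels, n_total, fs, config.noise_sd)

    annotations: list[Annotation] = []
    scores: dict[tuple[int, int], int] = {}
    n_burst = max(1, round(pattern.burst_fraction * n_trial))
    for s in range(config.n_subjects):
        comps = (rng.random(config.n_paintings) >= config.score_model.mixture_weight).astype(int)
        svals = _draw_component_scores(config.score_model, comps, rng)
        for p in range(config.n_paintings):
            onset_samp = s * per_subject + n_blank + p * n_trial
            annotations.append(
                Annotation(onset=onset_samp / fs, duration=config.trial_seconds,
                           painting=p, subject=s)
            )
            scores[(s, p)] = int(svals[p])
            amp = pattern.like_amplitude if comps[p] == 1 else pattern.dislike_amplitude
            start = int(rng.integers(0, n_trial - n_burst + 1))
            if amp != 0.0:
                carrier = _bandlimited_carrier(rng, n_burst, fs, pattern.carrier_band)
                for ci in target_idx:
                    sig[ci, onset_samp + start : onset_samp + start + n_burst] += amp * carrier
            else:
                # keep the stream position identical across like/dislike draws
                rng.standard_normal(n_burst)
    return Recording(signal=sig, fs=fs, channel_ids=channel_ids,
                     annotations=annotations, scores=scores)


# ---------------------------------------------------------------------------
# I/O: EDF+ and delimited text
# ---------------------------------------------------------------------------


def _edf_field(value, width: int) -> bytes:
    s = str(value)
    if len(s) > width:
        s = s[:width]
    return s.ljust(width).encode("ascii")


def _edf_num(v: float) -> str:
    """Shortest decimal rendering of ``v`` that fits the 8-char EDF field."""
    for p in range(7, 0, -1):
        s = f"{v:.{p}g}"
        if len(s) <= 8:
            return s
    return f"{v:.0e}"[:8]


def _write_edf(recording: Recording, path: Path) -> None:
    """Minimal EDF+C writer: 16-bit samples, 1 s data records, one
    'EDF Annotations' channel carrying the trial markers as TALs."""
    fs = recording.fs
    if abs(fs - round(fs)) > 1e-9:
        raise ValueError("EDF writer requires an integer sampling rate")
    fs = int(round(fs))
    n_ch, n_samp = recording.signal.shape
    if n_samp % fs != 0:
        raise ValueError("EDF writer requires a whole number of seconds")
    n_rec = n_samp // fs

    # physical scaling per channel; use the header's decimal rendering for the
    # encoding too, so reader and writer agree exactly on the scale
    pmins, pmaxs = [], []
    for c in range(n_ch):
        lo, hi = float(recording.signal[c].min()), float(recording.signal[c].max())
        if lo == hi:
            lo, hi = lo - 1.0, hi + 1.0
        lo = float(_edf_num(lo - abs(lo) * 1e-6 - 1e-12))
        hi = float(_edf_num(hi + abs(hi) * 1e-6 + 1e-12))
        pmins.append(lo)
        pmaxs.append(hi)

    # annotation TALs, assigned to the data record containing their onset
    tals: dict[int, bytes] = {}
    for a in recording.annotations:
        rec = min(int(a.onset), n_rec - 1)
        txt = f"trial s{a.subject} p{a.painting}"
        tal = f"+{a.onset:g}\x15{a.duration:g}\x14{txt}\x14\x00".encode("ascii")
        tals[rec] = tals.get(rec, b"") + tal
    ann_bytes = max(
        [len(f"+{r}\x14\x14\x00") + len(t) for r, t in tals.items()] + [16]
    )
    ann_bytes += ann_bytes % 2  # whole number of 2-byte samples
    ann_ns = ann_bytes // 2

    ns = n_ch + 1
    header = b""
    header += _edf_field("0", 8)
    header += _edf_field("X X X X", 80)  # local patient id
    header += _edf_field("Startdate X X X X", 80)
    header += _edf_field("01.01.00", 8)
    header += _edf_field("00.00.00", 8)
    header += _edf_field(256 * (ns + 1), 8)
    header += _edf_field("EDF+C", 44)
    header += _edf_field(n_rec, 8)
    header += _edf_field(1, 8)
    header += _edf_field(ns, 4)

    labels = [ch[:16] for ch in recording.channel_ids] + ["EDF Annotations"]
    header += b"".join(_edf_field(lab, 16) for lab in labels)
    header += b"".join(_edf_field("", 80) for _ in range(ns))  # transducer
    header += b"".join(_edf_field("uV", 8) for _ in range(n_ch)) + _edf_field("", 8)
    header += b"".join(_edf_field(_edf_num(v), 8) for v in pmins) + _edf_field(-1, 8)
    header += b"".join(_edf_field(_edf_num(v), 8) for v in pmaxs) + _edf_field(1, 8)
    header += b"".join(_edf_field(-32768, 8) for _ in range(ns))
    header += b"".join(_edf_field(32767, 8) for _ in range(ns))
    header += b"".join(_edf_field("", 80) for _ in range(ns))  # prefiltering
    header += b"".join(_edf_field(fs, 8) for _ in range(n_ch)) + _edf_field(ann_ns, 8)
    header += b"".join(_edf_field("", 32) for _ in range(ns))

    scale = [(pmaxs[c] - pmins[c]) / 65535.0 for c in range(n_ch)]
    tmp = path.with_name(path.name + ".part")
    with open(tmp, "wb") as fh:
        fh.write(header)
        for r in range(n_rec):
            for c in range(n_ch):
                seg = recording.signal[c, r * fs : (r + 1) * fs]
                dig = np.rint((seg - pmins[c]) / scale[c]) - 32768
                fh.write(dig.astype("<i2").tobytes())
            rec_tal = f"+{r}\x14\x14\x00".encode("ascii") + tals.get(r, b"")
            fh.write(rec_tal.ljust(ann_bytes, b"\x00"))
    os.replace(tmp, path)


def _read_edf(path: Path) -> tuple[np.ndarray, float, list[str], list[Annotation]]:
    import mne

    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    sig = raw.get_data() * 1e6  # mne converts uV to V on load
    annotations = []
    for onset, duration, desc in zip(
        raw.annotations.onset, raw.annotations.duration, raw.annotations.description
    ):
        parts = desc.split()
        if parts and parts[0] == "trial":
            subject = int(parts[1][1:])
            painting = int(parts[2][1:])
            annotations.append(Annotation(float(onset), float(duration), painting, subject))
    return sig, float(raw.info["sfreq"]), list(raw.ch_names), annotations


def _scores_frame(scores: dict[tuple[int, int], int]) -> pd.DataFrame:
    rows = [(s, p, v) for (s, p), v in sorted(scores.items())]
    return pd.DataFrame(rows, columns=["subject", "painting", "score"])


def write_recording(recording: Recording, path: str | Path, format: str = "edf") -> None:
    """Write a recording to ``path``.

    ``edf`` writes an EDF+ file plus a ``<stem>_scores.csv`` sidecar;
    ``txt`` writes ``<stem>_signal.csv`` (one row per sample, one column per
    channel), ``<stem>_annotations.csv`` and ``<stem>_scores.csv``.
    """
    path = Path(path)
    if format == "edf":
        _write_edf(recording, path)
        _scores_frame(recording.scores).to_csv(
            path.with_name(path.stem + "_scores.csv"), index=False
        )
    elif format == "txt":
        stem = path.with_suffix("")
        df = pd.DataFrame(recording.signal.T, columns=recording.channel_ids)
        tmp = stem.with_name(stem.name + "_signal.csv.part")
        df.to_csv(tmp, index=False, float_format="%.10g")
        ann = pd.DataFrame(
            [(a.onset, a.duration, a.painting, a.subject) for a in recording.annotations],
            columns=["onset", "duration", "painting", "subject"],
        )
        ann.insert(0, "fs", recording.fs)
        ann.to_csv(stem.with_name(stem.name + "_annotations.csv"), index=False)
        _scores_frame(recording.scores).to_csv(
            stem.with_name(stem.name + "_scores.csv"), index=False
        )
        os.replace(tmp, stem.with_name(stem.name + "_signal.csv"))
    else:
        raise ValueError(f"unsupported format {format!r}; use 'edf' or 'txt'")


def read_recording(path: str | Path, format: str = "edf") -> Recording:
    """Read a recording previously written by :func:`write_recording`."""
    path = Path(path)
    if format == "edf":
        sig, fs, ch, annotations = _read_edf(path)
        scores_path = path.with_name(path.stem + "_scores.csv")
    elif format == "txt":
        stem = path.with_suffix("")
        df = pd.read_csv(stem.with_name(stem.name + "_signal.csv"))
        ann = pd.read_csv(stem.with_name(stem.name + "_annotations.csv"))
        sig = df.to_numpy().T
        ch = list(df.columns)
        fs = float(ann["fs"].iloc[0]) if len(ann) else 512.0
        annotations = [
            Annotation(float(r.onset), float(r.duration), int(r.painting), int(r.subject))
            for r in ann.itertuples()
        ]
        scores_path = stem.with_name(stem.name + "_scores.csv")
    else:
        raise ValueError(f"unsupported format {format!r}; use 'edf' or 'txt'")
    scores = {}
    if scores_path.exists():
        sdf = pd.read_csv(scores_path)
        scores = {
            (int(r.subject), int(r.painting)): int(r.score) for r in sdf.itertuples()
        }
    return Recording(signal=np.asarray(sig, dtype=float), fs=fs, channel_ids=ch,
                     annotations=annotations, scores=scores)
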