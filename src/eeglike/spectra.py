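"""Trial slicing and spectral band decomposition.

Each annotated painting observation is cut from the long recording, the
512 Hz signal is resampled to 104 Hz (putting the Nyquist frequency at
52 Hz), and a short-time Fourier transform converts every electrode's
trace into 13 log10 band-power series.  The 13 bands tile (0, 52] Hz in
4 Hz steps (DC excluded) and group into the conventional wavebands:
F1 = delta (0-4), F2 = theta (4-8), F3 = alpha (8-12), F4-F8 = beta
(12-32), F9-F13 = gamma (32-52).

Framing convention: rectangular, non-centred frames; frame f covers
samples [f*step, f*step + window); trailing partial frames are dropped.
At 104 Hz the default 50 ms window / 20 ms step become 5- and 2-sample
frames, zero-padded to a 64-point transform so that the 4 Hz bands are
resolvable (bin spacing 1.625 Hz).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import signal as sps

from .syndata import Recording

__all__ = [
    "TrialSlice",
    "BandDefinition",
    "BandSpectrogram",
    "BAND_DEFINITIONS",
    "WAVEBAND_BANDS",
    "slice_trials",
    "resample_to_104",
    "band_power",
    "waveband_subset",
]

LOG_FLOOR = 1e-12  # power floor applied before log10
_NFFT = 64


@dataclass(frozen=True)
class BandDefinition:
    """4 Hz analysis band F_i covering (4(i-1), 4i] Hz."""

    index: int  # 1..13
    lower: float  # Hz, exclusive
    upper: float  # Hz, inclusive
    waveband: str  # delta | theta | alpha | beta | gamma


def _waveband(i: int) -> str:
    if i == 1:
        return "delta"
    if i == 2:
        return "theta"
    if i == 3:
        return "alpha"
    if i <= 8:
        return "beta"
    return "gamma"


BAND_DEFINITIONS: tuple[BandDefinition, ...] = tuple(
    BandDefinition(i, 4.0 * (i - 1), 4.0 * i, _waveband(i)) for i in range(1, 14)
)

#: band indices per waveband selector
WAVEBAND_BANDS: dict[str, tuple[int, ...]] = {
    "all": tuple(range(1, 14)),
    "beta": tuple(range(4, 9)),
    "gamma": tuple(range(9, 14)),
    "betagamma": tuple(range(4, 14)),
}


@dataclass
class TrialSlice:
    subject: int
    painting: int
    signal: np.ndarray  # channels x samples
    fs: float
    score: int
    channel_ids: list[str]


@dataclass
class BandSpectrogram:
    """Per-trial electrodes x bands x frames array of log10 band power."""

    subject: int
    painting: int
    score: int
    electrode_ids: list[str]
    bands: tuple[int, ...]  # original band indices present (subset of 1..13)
    values: np.ndarray  # electrodes x len(bands) x frames
    frame_times: np.ndarray  # s, frame centres
    stft_window_ms: float
    stft_step_ms: float

    @property
    def key(self) -> tuple[int, int]:
        return (self.subject, self.painting)

    @property
    def n_frames(self) -> int:
        return self.values.shape[2]

    def series(self, electrode: str, band: int) -> np.ndarray:
        """Frame series for one (electrode, band); band uses original 1..13 indexing."""
        try:
            e = self.electrode_ids.index(electrode)
        except ValueError:
            raise KeyError(f"unknown electrode {electrode!r}") from None
        try:
            b = self.bands.index(band)
        except ValueError:
            raise KeyError(f"band F{band} not present (have {self.bands})") from None
        return self.values[e, b, :]


def slice_trials(recording: Recording) -> list[TrialSlice]:
    """One TrialSlice per (subject, painting) annotation, carrying its score."""
    n = recording.signal.shape[1]
    slices = []
    spans = []
    for a in recording.annotations:
        if a.duration <= 0:
            raise ValueError(f"zero- or negative-duration annotation: {a}")
        start = round(a.onset * recording.fs)
        length = round(a.duration * recording.fs)
        if start < 0 or start + length > n:
            raise ValueError(f"annotation exceeds signal extent: {a}")
        for s0, s1 in spans:
            if start < s1 and s0 < start + length:
                raise ValueError(f"annotation overlaps an earlier one: {a}")
        spans.append((start, start + length))
        score = recording.scores.get((a.subject, a.painting))
        if score is None:
            raise KeyError(f"no score for subject {a.subject}, painting {a.painting}")
        slices.append(
            TrialSlice(
                subject=a.subject,
                painting=a.painting,
                signal=recording.signal[:, start : start + length],
                fs=recording.fs,
                score=score,
                channel_ids=list(recording.channel_ids),
            )
        )
    return slices


def resample_to_104(trial: TrialSlice) -> TrialSlice:
    """Polyphase resampling 512 -> 104 Hz (ratio 13/64) with anti-alias filtering."""
    if trial.fs != 512.0:
        raise ValueError(f"expected a 512 Hz slice, got fs={trial.fs}")
    if trial.signal.shape[1] < 1:
        raise ValueError("empty slice")
    out = sps.resample_poly(trial.signal, 13, 64, axis=1, padtype="line")
    return replace(trial, signal=np.ascontiguousarray(out), fs=104.0)


def band_power(trial: TrialSlice, window_ms: float = 50.0, step_ms: float = 20.0) -> BandSpectrogram:
    """STFT band power: per electrode and frame, spectral power summed within
    each 4 Hz band of the (0, 52] Hz range, then log10 with a floor."""
    if trial.fs != 104.0:
        raise ValueError("band_power expects a 104 Hz slice; resample first")
    if not (window_ms >= step_ms > 0):
        raise ValueError("require window_ms >= step_ms > 0")
    fs = trial.fs
    win = round(window_ms * fs / 1000.0)
    hop = round(step_ms * fs / 1000.0)
    n = trial.signal.shape[1]
    if win > n:
        raise ValueError(f"window of {win} samples longer than slice of {n}")

    n_frames = (n - win) // hop + 1
    frames = np.lib.stride_tricks.sliding_window_view(trial.signal, win, axis=1)[:, ::hop, :]
    frames = frames[:, :n_frames, :]
    spec = np.abs(np.fft.rfft(frames, n=_NFFT, axis=2)) ** 2  # ch x frames x bins
    freqs = np.fft.rfftfreq(_NFFT, d=1.0 / fs)

    power = np.empty((trial.signal.shape[0], 13, n_frames))
    for bd in BAND_DEFINITIONS:
        mask = (freqs > bd.lower) & (freqs <= bd.upper)
        power[:, bd.index - 1, :] = spec[:, :, mask].sum(axis=2)
    values = np.log10(np.maximum(power, LOG_FLOOR))
    frame_times = (np.arange(n_frames) * hop + win / 2.0) / fs
    return BandSpectrogram(
        subject=trial.subject,
        painting=trial.painting,
        score=trial.score,
        electrode_ids=list(trial.channel_ids),
        bands=tuple(range(1, 14)),
        values=values,
        frame_times=frame_times,
        stft_window_ms=window_ms,
        stft_step_ms=step_ms,
    )


def waveband_subset(spec: BandSpectrogram, selector: str) -> BandSpectrogram:
    """Restrict a spectrogram to a waveband configuration: all, beta, gamma, betagamma."""
    if selector not in WAVEBAND_BANDS:
        raise ValueError(f"unknown band selector {selector!r}; "
                         f"choose from {sorted(WAVEBAND_BANDS)}")
    keep = [b for b in WAVEBAND_BANDS[selector] if b in spec.bands]
    if keep == list(spec.bands):
        return spec
    idx = [spec.bands.index(b) for b in keep]
    return replace(spec, bands=tuple(keep), values=spec.values[:, idx, :])
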