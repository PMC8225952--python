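"""Spectrograms and per-event acoustic descriptors.

Two feature sets are computed per annotated event, mirroring the two levels
of complexity used when comparing played sound objects with whale units:

* **basic** (5): duration plus the spectral minimum, maximum, bandwidth and
  peak frequency of the event-averaged spectrum. ``bandwidth = fmax − fmin``
  holds exactly by construction. The min/max criterion is a −20 dB floor
  relative to the spectral peak (the convention here; any floor can be
  passed).
* **extended** (74): 8 frame-level descriptors paired with delta
  counterparts (ZCR, energy, energy entropy, spectral centroid, spread,
  spectral entropy, flux, roll-off → 16), 6 unpaired spectral summaries
  (bandwidth, flatness, RMS level, Rényi entropy of order 2, Shannon
  entropy, spectral kurtosis), 13 MFCC + 13 MFCC deltas, and 13 chroma
  + 13 chroma deltas (12 pitch classes plus a chroma-deviation summary).

Spectrograms use a 512-sample FFT with a Blackman–Harris window at 75%
overlap, the session-analysis convention. Frame-level descriptors aggregate
to one value per event by the arithmetic mean; deltas aggregate the mean
absolute frame-to-frame first difference.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.fft import dct, rfft
from scipy.signal import get_window
from scipy.spatial.distance import pdist

__all__ = [
    "spectrogram",
    "BasicFeatures",
    "basic_features",
    "extended_features",
    "EXTENDED_FEATURE_NAMES",
    "feature_layout",
    "FeatureTable",
    "CategoryStats",
    "category_stats",
]

_EPS = 1e-12


def spectrogram(
    waveform: np.ndarray,
    sample_rate: float,
    nfft: int = 512,
    window: str = "blackmanharris",
    overlap: float = 0.75,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Magnitude spectrogram with explicit framing.

    hop = nfft × (1 − overlap); frame count = floor((L − nfft)/hop) + 1.

    Returns ``(S, freqs, times)`` with ``S`` of shape (nfft//2 + 1, n_frames),
    magnitudes ≥ 0.
    """
    x = np.asarray(waveform, dtype=float)
    if len(x) < nfft:
        raise ValueError(f"waveform of {len(x)} samples shorter than one {nfft}-sample frame")
    hop = int(round(nfft * (1.0 - overlap)))
    if hop < 1:
        raise ValueError("overlap too high: hop collapses to zero")
    n_frames = (len(x) - nfft) // hop + 1
    win = get_window(window, nfft, fftbins=True)
    idx = np.arange(nfft)[None, :] + hop * np.arange(n_frames)[:, None]
    frames = x[idx] * win
    S = np.abs(rfft(frames, axis=1)).T
    freqs = np.arange(nfft // 2 + 1) * sample_rate / nfft
    times = (np.arange(n_frames) * hop + nfft / 2) / sample_rate
    return S, freqs, times


@dataclass(frozen=True)
class BasicFeatures:
    """The five basic descriptors of one event (frequencies in Hz).

    ``silent`` is set (and the spectral fields are None) when the segment has
    no usable energy; no numbers are fabricated for silence.
    """

    duration_s: float
    fmin_hz: float | None
    fmax_hz: float | None
    bandwidth_hz: float | None
    fpeak_hz: float | None
    silent: bool = False

    def as_khz_row(self) -> dict:
        """Reporting convenience: frequencies in kHz, as session tables print."""
        if self.silent:
            return {"min_khz": None, "max_khz": None, "bandwidth_khz": None,
                    "peak_khz": None, "duration_s": self.duration_s}
        return {
            "min_khz": self.fmin_hz / 1e3,
            "max_khz": self.fmax_hz / 1e3,
            "bandwidth_khz": self.bandwidth_hz / 1e3,
            "peak_khz": self.fpeak_hz / 1e3,
            "duration_s": self.duration_s,
        }


def basic_features(
    segment: np.ndarray,
    sample_rate: float,
    floor_db: float = -20.0,
    nfft: int = 512,
    overlap: float = 0.75,
) -> BasicFeatures:
    """Duration and spectral min/max/bandwidth/peak of one event.

    The event-averaged magnitude spectrum is scanned for the lowest and
    highest frequencies within ``floor_db`` of its peak; the peak frequency
    is its argmax. ``bandwidth = fmax − fmin`` exactly.
    """
    x = np.asarray(segment, dtype=float)
    duration = len(x) / sample_rate
    if len(x) < nfft or not np.any(np.abs(x) > 0):
        return BasicFeatures(duration, None, None, None, None, silent=True)
    S, freqs, _ = spectrogram(x, sample_rate, nfft=nfft, overlap=overlap)
    avg = S.mean(axis=1)
    peak_mag = avg.max()
    if peak_mag <= 0:
        return BasicFeatures(duration, None, None, None, None, silent=True)
    above = np.flatnonzero(20.0 * np.log10(avg / peak_mag + _EPS) >= floor_db)
    fmin = float(freqs[above[0]])
    fmax = float(freqs[above[-1]])
    fpeak = float(freqs[int(np.argmax(avg))])
    return BasicFeatures(duration, fmin, fmax, fmax - fmin, fpeak)


# ---------------------------------------------------------------------------
# Extended (74-descriptor) feature set

_PAIRED = (
    "zcr",
    "energy",
    "energy_entropy",
    "spectral_centroid",
    "spectral_spread",
    "spectral_entropy",
    "spectral_flux",
    "spectral_rolloff",
)
_UNPAIRED = (
    "spectral_bandwidth",
    "spectral_flatness",
    "rms_level",
    "renyi_entropy",
    "shannon_entropy",
    "spectral_kurtosis",
)

EXTENDED_FEATURE_NAMES: tuple[str, ...] = (
    _PAIRED
    + tuple(f"{n}_delta" for n in _PAIRED)
    + _UNPAIRED
    + tuple(f"mfcc_{i}" for i in range(1, 14))
    + tuple(f"mfcc_delta_{i}" for i in range(1, 14))
    + tuple(f"chroma_{i}" for i in range(1, 13))
    + ("chroma_dev",)
    + tuple(f"chroma_delta_{i}" for i in range(1, 13))
    + ("chroma_dev_delta",)
)


def feature_layout() -> dict[str, int]:
    """Composition of the 74-descriptor set, for auditing the layout."""
    return {
        "paired_with_delta": len(_PAIRED),
        "unpaired": len(_UNPAIRED),
        "mfcc": 13,
        "mfcc_delta": 13,
        "chroma": 13,
        "chroma_delta": 13,
        "total": len(EXTENDED_FEATURE_NAMES),
    }


def _hz_to_mel(f):
    return 2595.0 * np.log10(1.0 + np.asarray(f) / 700.0)


def _mel_to_hz(m):
    return 700.0 * (10.0 ** (np.asarray(m) / 2595.0) - 1.0)


def _mel_filterbank(n_filters: int, nfft: int, sample_rate: float) -> np.ndarray:
    pts = _mel_to_hz(np.linspace(0.0, _hz_to_mel(sample_rate / 2.0), n_filters + 2))
    bins = np.floor((nfft + 1) * pts / sample_rate).astype(int)
    fb = np.zeros((n_filters, nfft // 2 + 1))
    for i in range(n_filters):
        lo, mid, hi = bins[i], bins[i + 1], bins[i + 2]
        if mid > lo:
            fb[i, lo:mid] = (np.arange(lo, mid) - lo) / (mid - lo)
        if hi > mid:
            fb[i, mid:hi] = (hi - np.arange(mid, hi)) / (hi - mid)
    return fb


def _chroma_map(nfft: int, sample_rate: float) -> np.ndarray:
    """Map rfft bins to 12 pitch classes (A440 reference); DC excluded."""
    n_bins = nfft // 2 + 1
    freqs = np.arange(1, n_bins) * sample_rate / nfft
    pitch = (np.round(12.0 * np.log2(freqs / 440.0)).astype(int) + 9) % 12
    M = np.zeros((12, n_bins))
    M[pitch, np.arange(1, n_bins)] = 1.0
    return M


def _entropy_bits(p: np.ndarray) -> float:
    p = p[p > _EPS]
    if p.size == 0:
        return 0.0
    return float(-(p * np.log2(p)).sum())


def extended_features(
    segment: np.ndarray,
    sample_rate: float,
    frame_len: int = 1024,
    hop: int = 512,
    n_mels: int = 26,
) -> np.ndarray:
    """The 74-component descriptor vector of one event.

    Needs at least two frames (deltas are frame-to-frame differences). All
    values are finite for any finite input, silence included: entropies and
    spectral moments of an empty spectrum are defined as zero.
    """
    x = np.asarray(segment, dtype=float)
    n_frames = (len(x) - frame_len) // hop + 1 if len(x) >= frame_len else 0
    if n_frames < 2:
        raise ValueError(
            f"segment of {len(x)} samples spans {n_frames} frame(s); "
            "need ≥ 2 frames for delta descriptors"
        )
    idx = np.arange(frame_len)[None, :] + hop * np.arange(n_frames)[:, None]
    frames = x[idx]
    win = get_window("hann", frame_len, fftbins=True)
    spec = np.abs(rfft(frames * win, axis=1))          # (frames, bins)
    power = spec**2
    freqs = np.arange(frame_len // 2 + 1) * sample_rate / frame_len

    tot_pow = power.sum(axis=1)
    p_norm = power / np.maximum(tot_pow, _EPS)[:, None]
    nonzero = tot_pow > _EPS

    # --- paired frame-level descriptors
    zcr = np.mean(np.abs(np.diff(np.signbit(frames), axis=1)), axis=1)
    energy = np.mean(frames**2, axis=1)
    # energy entropy over 10 sub-blocks of the frame
    sub = frames[:, : (frame_len // 10) * 10].reshape(n_frames, 10, -1)
    sub_e = (sub**2).sum(axis=2)
    sub_p = sub_e / np.maximum(sub_e.sum(axis=1), _EPS)[:, None]
    energy_entropy = np.array([_entropy_bits(p) for p in sub_p])
    centroid = (p_norm * freqs).sum(axis=1)
    spread = np.sqrt((p_norm * (freqs - centroid[:, None]) ** 2).sum(axis=1))
    spectral_entropy = np.array([_entropy_bits(p) for p in p_norm])
    sn = spec / np.maximum(spec.sum(axis=1), _EPS)[:, None]
    flux = np.concatenate([[0.0], np.sqrt(((np.diff(sn, axis=0)) ** 2).sum(axis=1))])
    cum = np.cumsum(power, axis=1)
    thresh = 0.9 * np.maximum(cum[:, -1], _EPS)
    rolloff = freqs[np.argmax(cum >= thresh[:, None], axis=1)]

    # --- unpaired summaries (weights from magnitude, not power)
    m_norm = spec / np.maximum(spec.sum(axis=1), _EPS)[:, None]
    bw_centroid = (m_norm * freqs).sum(axis=1)
    bandwidth = np.sqrt((m_norm * (freqs - bw_centroid[:, None]) ** 2).sum(axis=1))
    flatness = np.where(
        nonzero,
        np.exp(np.mean(np.log(power + _EPS), axis=1)) / np.maximum(np.mean(power, axis=1), _EPS),
        0.0,
    )
    rms = np.sqrt(np.mean(frames**2, axis=1))
    renyi = np.where(nonzero, -np.log2(np.maximum((p_norm**2).sum(axis=1), _EPS)), 0.0)
    shannon = np.array([_entropy_bits(p) for p in p_norm])
    spread_safe = np.maximum(spread, _EPS)
    kurt = np.where(
        nonzero,
        (p_norm * (freqs - centroid[:, None]) ** 4).sum(axis=1) / spread_safe**4,
        0.0,
    )

    # --- MFCC
    mel = _mel_filterbank(n_mels, frame_len, sample_rate) @ power.T  # (mels, frames)
    mfcc = dct(np.log(mel + _EPS), type=2, axis=0, norm="ortho")[:13].T  # (frames, 13)

    # --- chroma: 12 pitch classes + per-frame deviation summary
    chroma12 = (_chroma_map(frame_len, sample_rate) @ power.T).T       # (frames, 12)
    chroma12 = chroma12 / np.maximum(chroma12.sum(axis=1), _EPS)[:, None]
    chroma_dev = chroma12.std(axis=1)
    chroma = np.column_stack([chroma12, chroma_dev])                    # (frames, 13)

    def agg(v: np.ndarray) -> float:
        return float(np.mean(v))

    def agg_delta(v: np.ndarray) -> np.ndarray | float:
        d = np.abs(np.diff(v, axis=0))
        return d.mean(axis=0)

    paired_vals = [zcr, energy, energy_entropy, centroid, spread, spectral_entropy, flux, rolloff]
    out = [agg(v) for v in paired_vals]
    out += [float(agg_delta(v)) for v in paired_vals]
    out += [agg(bandwidth), agg(flatness), agg(rms), agg(renyi), agg(shannon), agg(kurt)]
    out += list(mfcc.mean(axis=0))
    out += list(agg_delta(mfcc))
    out += list(chroma.mean(axis=0))
    out += list(agg_delta(chroma))
    vec = np.asarray(out, dtype=float)
    assert vec.shape == (len(EXTENDED_FEATURE_NAMES),)
    return vec


# ---------------------------------------------------------------------------
# Feature tables and per-category statistics


@dataclass(frozen=True)
class FeatureTable:
    """Per-event feature vectors with category labels.

    ``values`` is (n_events, n_features); ``sources`` entries are "unit" or
    "cse". Stored column-wise as CSV with one named column per descriptor.
    """

    event_ids: tuple[str, ...]
    labels: tuple[str, ...]
    sources: tuple[str, ...]
    values: np.ndarray
    feature_names: tuple[str, ...]

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2:
            raise ValueError("values must be a 2-D array")
        n = len(self.event_ids)
        if not (len(self.labels) == len(self.sources) == v.shape[0] == n):
            raise ValueError("event ids, labels, sources and rows must agree in length")
        if v.shape[1] != len(self.feature_names):
            raise ValueError("feature_names must match the vector length")
        object.__setattr__(self, "values", v)

    def __len__(self) -> int:
        return len(self.event_ids)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=list(self.feature_names))
        df.insert(0, "source", self.sources)
        df.insert(0, "label", self.labels)
        df.insert(0, "event_id", self.event_ids)
        return df

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "FeatureTable":
        meta = ["event_id", "label", "source"]
        feats = [c for c in df.columns if c not in meta]
        return cls(
            event_ids=tuple(str(v) for v in df["event_id"]),
            labels=tuple(str(v) for v in df["label"]),
            sources=tuple(str(v) for v in df["source"]),
            values=df[feats].to_numpy(dtype=float),
            feature_names=tuple(feats),
        )

    @classmethod
    def from_csv(cls, path: str | Path) -> "FeatureTable":
        return cls.from_frame(pd.read_csv(path))


@dataclass(frozen=True)
class CategoryStats:
    """Within-category summary: mean/sd per feature and dispersion.

    ``dispersion`` is the mean pairwise Euclidean distance between the
    category's vectors; it is None ("NC", not computable) for singleton
    categories.
    """

    label: str
    n: int
    mean: np.ndarray
    sd: np.ndarray
    dispersion: float | None


def category_stats(table: FeatureTable) -> list[CategoryStats]:
    """Per-category mean, standard deviation and dispersion.

    Categories are visited in first-appearance order. Heterogeneous vector
    lengths cannot occur inside a :class:`FeatureTable`; an empty table is an
    error.
    """
    if len(table) == 0:
        raise ValueError("empty feature table")
    order: list[str] = []
    for lab in table.labels:
        if lab not in order:
            order.append(lab)
    out = []
    labels = np.asarray(table.labels)
    for lab in order:
        rows = table.values[labels == lab]
        disp = float(pdist(rows).mean()) if len(rows) >= 2 else None
        out.append(
            CategoryStats(
                label=lab,
                n=len(rows),
                mean=rows.mean(axis=0),
                sd=rows.std(axis=0, ddof=0),
                dispersion=disp,
            )
        )
    return out
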