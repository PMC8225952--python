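"""Mono PCM WAV read/write (16/24/32-bit) on top of the stdlib wave module.

Session recordings in this domain are typically 48 kHz / 24-bit; the stdlib
`wave` module handles 24-bit frames (sampwidth 3) natively, so no third-party
audio dependency is needed. Samples are exchanged as float64 in [-1, 1].
"""

from __future__ import annotations

import wave
from pathlib import Path

import numpy as np

__all__ = ["write_wav", "read_wav"]

_SCALES = {2: 2**15, 3: 2**23, 4: 2**31}


def write_wav(
    path: str | Path,
    waveform: np.ndarray,
    sample_rate: int,
    bit_depth: int = 24,
) -> None:
    """Write a mono float waveform as integer PCM.

    Values are clipped to [-1, 1] before quantization. ``bit_depth`` may be
    16, 24, or 32.
    """
    sampwidth = bit_depth // 8
    if sampwidth not in _SCALES:
        raise ValueError(f"unsupported bit depth {bit_depth}; use 16, 24 or 32")
    scale = _SCALES[sampwidth]
    x = np.clip(np.asarray(waveform, dtype=np.float64), -1.0, 1.0)
    ints = np.round(x * (scale - 1)).astype(np.int64)
    if sampwidth == 3:
        # pack the low 3 bytes of little-endian int32
        b = ints.astype("<i4").tobytes()
        frames = bytes(
            byte for i in range(0, len(b), 4) for byte in b[i : i + 3]
        )
    else:
        frames = ints.astype(f"<i{sampwidth}").tobytes()
    with wave.open(str(path), "wb") as w:
        w.setnchannels(1)
        w.setsampwidth(sampwidth)
        w.setframerate(int(sample_rate))
        w.writeframes(frames)


def read_wav(path: str | Path) -> tuple[np.ndarray, int]:
    """Read a mono PCM WAV; returns (float64 waveform in [-1, 1], sample rate)."""
    with wave.open(str(path), "rb") as w:
        if w.getnchannels() != 1:
            raise ValueError(f"{path}: expected mono audio, got {w.getnchannels()} channels")
        sampwidth = w.getsampwidth()
        rate = w.getframerate()
        raw = w.readframes(w.getnframes())
    if sampwidth not in _SCALES:
        raise ValueError(f"{path}: unsupported sample width {sampwidth}")
    if sampwidth == 3:
        b = np.frombuffer(raw, dtype=np.uint8).reshape(-1, 3)
        ints = (
            b[:, 0].astype(np.int32)
            | (b[:, 1].astype(np.int32) << 8)
            | (b[:, 2].astype(np.int32) << 16)
        )
        ints = np.where(ints >= 2**23, ints - 2**24, ints)
    else:
        ints = np.frombuffer(raw, dtype=f"<i{sampwidth}").astype(np.int64)
    return ints / (_SCALES[sampwidth] - 1), rate
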