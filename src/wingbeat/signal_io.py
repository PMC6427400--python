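"""WAV input/output and track manipulation for optoelectronic sensor signals.

The sensor chain is digitized through a sound card as mono PCM WAV with
amplitudes normalized to [-1, 1].  This module enforces that convention,
segments long recordings into fixed-length chunks, and supports anti-aliased
sub-sampling to lower working rates.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps
from scipy.io import wavfile

__all__ = ["SignalTrack", "read_wav", "write_wav", "segment_track", "downsample"]

#: full-scale magnitude of 16-bit PCM; -32768 maps to -1.0 exactly
_FULL_SCALE_16 = 32768.0


@dataclass
class SignalTrack:
    """A sampled, amplitude-normalized sensor waveform.

    Parameters
    ----------
    samples : ndarray
        Dimensionless amplitudes, each in [-1, 1].
    fs : float
        Sampling rate in samples/s.
    origin : str
        Free-text provenance label (file path, simulator config hash, ...).
    """

    samples: np.ndarray
    fs: float
    origin: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 1 or self.samples.size < 1:
            raise ValueError("samples must be a non-empty 1-D array")
        if not self.fs > 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        amax = float(np.max(np.abs(self.samples)))
        if amax > 1.0 + 1e-9:
            raise ValueError(
                f"samples exceed the normalized range [-1, 1] (max |s| = {amax:.6g})"
            )

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.fs

    def __len__(self) -> int:
        return self.samples.size


def read_wav(path: str | os.PathLike) -> SignalTrack:
    """Read a mono PCM WAV file into a normalized :class:`SignalTrack`.

    Integer PCM is converted to [-1, 1] by dividing by the full-scale
    magnitude of the bit depth (32768 for 16-bit), so -32768 maps to -1.0.

    Raises
    ------
    ValueError
        If the file is multi-channel or uses an unsupported sample format.
    """
    fs, data = wavfile.read(os.fspath(path))
    if data.ndim != 1:
        raise ValueError(f"expected mono WAV, got {data.shape[1]} channels: {path}")
    if data.dtype == np.int16:
        samples = data.astype(np.float64) / _FULL_SCALE_16
    elif data.dtype == np.int32:
        samples = data.astype(np.float64) / 2147483648.0
    elif data.dtype in (np.float32, np.float64):
        samples = np.clip(data.astype(np.float64), -1.0, 1.0)
    else:
        raise ValueError(f"unsupported WAV sample format {data.dtype}: {path}")
    return SignalTrack(samples, float(fs), origin=os.fspath(path))


def write_wav(track: SignalTrack, path: str | os.PathLike, bit_depth: int = 16) -> None:
    """Write a track as mono PCM WAV.

    Values are clipped to [-1, 1] then scaled by 32768 and saturated at the
    positive full scale (so +1.0 maps to +32767).
    """
    if bit_depth != 16:
        raise ValueError(f"only 16-bit PCM output is supported, got {bit_depth}")
    fs = int(round(track.fs))
    if not (0 < fs <= 2**32 - 1) or abs(fs - track.fs) > 1e-6:
        raise ValueError(f"sampling rate {track.fs} cannot be written to a WAV header")
    scaled = np.clip(track.samples, -1.0, 1.0) * _FULL_SCALE_16
    ints = np.clip(np.round(scaled), -32768, 32767).astype(np.int16)
    wavfile.write(os.fspath(path), fs, ints)


def segment_track(track: SignalTrack, chunk_s: float) -> list[SignalTrack]:
    """Split a track into consecutive non-overlapping chunks of ``chunk_s`` seconds.

    The final chunk may be shorter; concatenating the chunks reproduces the
    input exactly.
    """
    if not chunk_s > 0:
        raise ValueError("chunk_s must be positive")
    n = int(round(chunk_s * track.fs))
    if n < 1:
        raise ValueError("chunk_s shorter than one sample")
    chunks = []
    for i, start in enumerate(range(0, len(track), n)):
        chunks.append(
            SignalTrack(
                track.samples[start : start + n],
                track.fs,
                origin=f"{track.origin}[chunk {i}]",
            )
        )
    return chunks


def downsample(
    track: SignalTrack, factor: int, band_edge_hz: float = 2000.0
) -> SignalTrack:
    """Anti-alias filter and decimate a track by an integer factor.

    A zero-phase FIR anti-alias filter is used so event timing is not
    shifted.  The decimated rate must stay at least twice ``band_edge_hz``
    (the upper edge of the analysis band) to keep the band alias-free.
    """
    if factor < 1 or int(factor) != factor:
        raise ValueError("factor must be a positive integer")
    factor = int(factor)
    if factor == 1:
        return SignalTrack(track.samples.copy(), track.fs, origin=track.origin)
    new_fs = track.fs / factor
    if new_fs < 2.0 * band_edge_hz:
        raise ValueError(
            f"decimation by {factor} gives fs = {new_fs:g} < 2 x {band_edge_hz:g} Hz"
        )
    out = sps.decimate(track.samples, factor, ftype="fir", zero_phase=True)
    out = np.clip(out, -1.0, 1.0)
    return SignalTrack(out, new_fs, origin=f"{track.origin}[/{factor}]")
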