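"""Source-filter synthesis of sustained vowel phonations.

The synthesizer drives a cascade of second-order all-pole resonators with a
glottal source (impulse train at f0 plus white aspiration noise at a
configurable SNR, both shaped by the same tract) after an overall
-6 dB/octave spectral tilt (lumped glottal-pulse plus lip-radiation
shaping).  Resonator centre frequencies and bandwidths are therefore known
analytically (pole angle 2*pi*Fc/fs, pole radius exp(-pi*BW/fs)), which is
what makes these waveforms usable as formant-tracking ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal
from scipy.io import wavfile

from .cohort import VOWEL_TABLE_FEMALE

__all__ = ["VowelSynthesisSpec", "synthesize_vowel", "table_spec", "write_wav", "read_wav"]


@dataclass(frozen=True)
class VowelSynthesisSpec:
    """Parameters for one synthetic sustained phonation."""

    vowel: str
    f0: float = 200.0
    formants: tuple[tuple[float, float], ...] = ()  # (Fc Hz, BW Hz)
    duration: float = 1.5
    fs: int = 16000
    noise_snr_db: float = 30.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.vowel not in "aeiou" or len(self.vowel) != 1:
            raise ValueError("vowel must be one of a, e, i, o, u")
        if self.f0 <= 0:
            raise ValueError("f0 must be positive")
        if self.duration < 1.0:
            raise ValueError("duration must be >= 1.0 s (steady segment needs 800 ms)")
        freqs = [fc for fc, _ in self.formants]
        if any(f2 <= f1 for f1, f2 in zip(freqs, freqs[1:])):
            raise ValueError("formant frequencies must be strictly increasing")
        for fc, bw in self.formants:
            if bw <= 0:
                raise ValueError("bandwidths must be positive")
            if not 0 < fc < self.fs / 2:
                raise ValueError("formant frequencies must lie in (0, fs/2)")


def table_spec(vowel: str, f0: float = 200.0, duration: float = 1.5,
               fs: int = 16000, noise_snr_db: float = 30.0,
               seed: int = 0, upper_formants: bool = True) -> VowelSynthesisSpec:
    """Spec whose F1-F3 resonances are the female-population mean values.

    ``upper_formants`` appends canonical female F4/F5 resonances (F3+500 Hz
    but at least 3900 Hz, and 800 Hz above that); real vocal tracts always
    have them, and without upper poles the synthetic spectrum above F3 is
    bare noise roll-off that no all-pole analysis can fit sensibly.
    """
    row = VOWEL_TABLE_FEMALE[vowel]
    formants = tuple(
        (row[f"F{i}"][0], row[f"BW{i}"][0]) for i in (1, 2, 3)
    )
    if upper_formants:
        f4 = max(3900.0, formants[2][0] + 500.0)
        formants = formants + ((f4, 350.0), (f4 + 800.0, 450.0))
    return VowelSynthesisSpec(vowel=vowel, f0=f0, formants=formants,
                              duration=duration, fs=fs,
                              noise_snr_db=noise_snr_db, seed=seed)


def synthesize_vowel(spec: VowelSynthesisSpec) -> tuple[np.ndarray, int]:
    """Render the waveform; deterministic for a fixed seed.

    Returns (samples, fs) with samples float64 scaled to peak 0.5.
    """
    fs = spec.fs
    n = int(round(spec.duration * fs))
    rng = np.random.default_rng(spec.seed)

    # glottal source: impulse train at f0; white aspiration noise is added
    # at the source so it is shaped by the same vocal tract (the spectrum
    # stays all-pole, as in real phonation where turbulence passes through
    # the tract); -6 dB/oct lumped glottal/radiation tilt
    source = np.zeros(n)
    period = fs / spec.f0
    pulses = np.arange(0.0, n, period)
    source[pulses.astype(int)] = 1.0
    if np.isfinite(spec.noise_snr_db):
        p_src = np.mean(source**2)
        sigma = np.sqrt(p_src / 10.0 ** (spec.noise_snr_db / 10.0))
        source = source + sigma * rng.standard_normal(n)
    source = signal.lfilter([1.0], [1.0, -0.95], source)

    # cascade of second-order resonators, unity gain at the pole angle
    x = source
    for fc, bw in spec.formants:
        r = np.exp(-np.pi * bw / fs)
        theta = 2.0 * np.pi * fc / fs
        a = [1.0, -2.0 * r * np.cos(theta), r * r]
        gain = np.abs(np.polyval(a[::-1], np.exp(-1j * theta)))
        x = signal.lfilter([gain], a, x)

    x = 0.5 * x / np.max(np.abs(x))
    return x, fs


def write_wav(path, samples: np.ndarray, fs: int) -> None:
    """Write mono 16-bit PCM."""
    clipped = np.clip(samples, -1.0, 1.0)
    wavfile.write(path, fs, (clipped * 32767.0).astype(np.int16))


def read_wav(path) -> tuple[np.ndarray, int]:
    """Read a mono WAV as float64 in [-1, 1] (PCM 16/24/32 or float)."""
    fs, data = wavfile.read(path)
    if data.ndim > 1:
        data = data.mean(axis=1)
    if np.issubdtype(data.dtype, np.integer):
        data = data.astype(np.float64) / float(np.iinfo(data.dtype).max)
    else:
        data = data.astype(np.float64)
    return data, int(fs)
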