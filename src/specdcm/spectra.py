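"""Cross-spectral density estimation and spectral bookkeeping.

The data feature for model fitting is the cross-spectral density (CSD): a
Hermitian complex matrix per frequency, estimated from epoched source
timecourses with discrete prolate spheroidal (multitaper) windows and
averaged over epochs and tapers.  Frequencies live on a declared analysis
grid (default 2-100 Hz in 1 Hz steps) and epochs are cut from canonical
800 ms task windows (baseline, early delay, late delay).

All spectra use the one-sided power spectral density convention: for a unit
variance white signal sampled at ``fs``, the PSD is ``2 / fs`` per Hz.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import windows

__all__ = [
    "FrequencyGrid",
    "EpochWindow",
    "CrossSpectrum",
    "canonical_windows",
    "slice_window",
    "estimate_csd",
    "coherence",
    "BASELINE",
    "EARLY_DELAY",
    "LATE_DELAY",
]

BASELINE = "baseline"
EARLY_DELAY = "early_delay"
LATE_DELAY = "late_delay"


@dataclass(frozen=True)
class FrequencyGrid:
    """Analysis frequencies ``f_min : step : f_max`` (Hz), inclusive."""

    f_min: float = 2.0
    f_max: float = 100.0
    step: float = 1.0

    def __post_init__(self):
        if not (0 < self.f_min < self.f_max):
            raise ValueError("need 0 < f_min < f_max")
        if self.step <= 0:
            raise ValueError("step must be positive")

    @property
    def frequencies(self) -> np.ndarray:
        n = int(round((self.f_max - self.f_min) / self.step)) + 1
        return self.f_min + self.step * np.arange(n)

    def check_nyquist(self, fs: float) -> None:
        if self.f_max * 2 > fs:
            raise ValueError(
                f"grid reaches {self.f_max} Hz but Nyquist is {fs / 2} Hz"
            )


@dataclass(frozen=True)
class EpochWindow:
    """A labelled analysis window, in ms relative to stimulus onset."""

    label: str
    start_ms: float
    end_ms: float

    def __post_init__(self):
        if self.end_ms <= self.start_ms:
            raise ValueError("window must have positive length")

    @property
    def length_ms(self) -> float:
        return self.end_ms - self.start_ms


def canonical_windows() -> tuple[EpochWindow, EpochWindow, EpochWindow]:
    """The three 800 ms task windows: baseline, early delay, late delay.

    All keep at least 100 ms clearance from the stimulus (0-200 ms) and the
    report period (from 2200 ms).
    """
    return (
        EpochWindow(BASELINE, -900.0, -100.0),
        EpochWindow(EARLY_DELAY, 400.0, 1200.0),
        EpochWindow(LATE_DELAY, 1200.0, 2000.0),
    )


@dataclass
class CrossSpectrum:
    """Hermitian cross-spectral matrices on a frequency grid.

    ``values`` has shape (n_freqs, n_nodes, n_nodes); the diagonal holds the
    real, non-negative auto-spectra (one-sided PSD).
    """

    frequencies: np.ndarray
    values: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        self.values = np.asarray(self.values, dtype=complex)
        if self.values.ndim != 3 or self.values.shape[1] != self.values.shape[2]:
            raise ValueError("values must be (n_freqs, n, n)")
        if self.values.shape[0] != self.frequencies.shape[0]:
            raise ValueError("frequency axis mismatch")

    @property
    def n_nodes(self) -> int:
        return self.values.shape[1]

    def check_hermitian(self, atol: float = 1e-10) -> None:
        dev = np.abs(self.values - self.values.conj().transpose(0, 2, 1)).max()
        if dev > atol:
            raise ValueError(f"not Hermitian: max deviation {dev:.3g}")
        if np.any(self.values.diagonal(axis1=1, axis2=2).real < -atol):
            raise ValueError("negative auto-spectrum")


def slice_window(
    epochs: np.ndarray,
    fs: float,
    epoch_start_ms: float,
    window: EpochWindow,
) -> np.ndarray:
    """Cut a window out of full epochs.

    ``epochs`` is (n_epochs, n_nodes, n_samples) with sample 0 at
    ``epoch_start_ms`` relative to stimulus onset.
    """
    i0 = int(round((window.start_ms - epoch_start_ms) * fs / 1000.0))
    i1 = int(round((window.end_ms - epoch_start_ms) * fs / 1000.0))
    if i0 < 0 or i1 > epochs.shape[-1]:
        raise ValueError(
            f"window {window.label} [{window.start_ms}, {window.end_ms}] ms "
            "falls outside the epoch"
        )
    return epochs[..., i0:i1]


def estimate_csd(
    epochs: np.ndarray,
    fs: float,
    grid: FrequencyGrid | None = None,
    half_bandwidth_hz: float = 2.0,
    detrend: bool = False,
    metadata: dict | None = None,
) -> CrossSpectrum:
    """Multitaper cross-spectral density of epoched timecourses.

    Parameters
    ----------
    epochs : array, shape (n_epochs, n_nodes, n_samples)
    fs : sampling rate in Hz
    grid : target frequency grid (default 2-100 Hz, 1 Hz steps); taper
        spectra are estimated on the Fourier grid of the window and linearly
        interpolated onto it
    half_bandwidth_hz : spectral half-bandwidth W of the DPSS family; the
        number of tapers is ``max(1, floor(2 N W / fs) - 1)``
    detrend : remove a per-epoch linear trend (the per-epoch mean is always
        removed)

    Returns a :class:`CrossSpectrum`, Hermitian by construction, averaged
    over epochs and tapers.
    """
    epochs = np.asarray(epochs, dtype=float)
    if epochs.ndim != 3:
        raise ValueError("epochs must be (n_epochs, n_nodes, n_samples)")
    n_epochs, n_nodes, n_samples = epochs.shape
    grid = grid or FrequencyGrid()
    grid.check_nyquist(fs)
    df = fs / n_samples
    if df > grid.f_min:
        min_len = int(np.ceil(fs / grid.f_min))
        raise ValueError(
            f"epoch of {n_samples} samples gives {df:.2f} Hz resolution, "
            f"too coarse for f_min={grid.f_min} Hz; need >= {min_len} samples"
        )

    nw = n_samples * half_bandwidth_hz / fs
    k = max(1, int(2 * nw) - 1)
    tapers = windows.dpss(n_samples, nw, Kmax=k)  # unit-energy rows

    x = epochs - epochs.mean(axis=-1, keepdims=True)
    if detrend:
        t = np.arange(n_samples) - (n_samples - 1) / 2.0
        slope = (x * t).sum(axis=-1, keepdims=True) / (t * t).sum()
        x = x - slope * t

    # (n_epochs, n_tapers, n_nodes, n_freq_fft)
    spectra = np.fft.rfft(x[:, None, :, :] * tapers[None, :, None, :], axis=-1)
    fft_freqs = np.fft.rfftfreq(n_samples, 1.0 / fs)
    # one-sided scaling with unit-energy tapers
    cross = np.einsum("etif,etjf->fij", spectra, spectra.conj())
    cross *= 2.0 / (fs * n_epochs * k)

    target = grid.frequencies
    values = np.empty((target.size, n_nodes, n_nodes), dtype=complex)
    for i in range(n_nodes):
        for j in range(n_nodes):
            values[:, i, j] = np.interp(
                target, fft_freqs, cross[:, i, j].real
            ) + 1j * np.interp(target, fft_freqs, cross[:, i, j].imag)
    # enforce exact Hermitian symmetry after interpolation
    values = 0.5 * (values + values.conj().transpose(0, 2, 1))

    meta = {"n_epochs": n_epochs, "n_tapers": k, "half_bandwidth_hz": half_bandwidth_hz}
    meta.update(metadata or {})
    return CrossSpectrum(target, values, meta)


def coherence(cs: CrossSpectrum) -> np.ndarray:
    """Magnitude-squared coherence |S_ij|^2 / (S_ii S_jj), in [0, 1]."""
    diag = cs.values.diagonal(axis1=1, axis2=2).real
    if np.any(diag <= 0):
        raise ValueError("zero or negative auto-spectrum")
    denom = diag[:, :, None] * diag[:, None, :]
    coh = np.abs(cs.values) ** 2 / denom
    return np.minimum(coh, 1.0)
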