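"""Complex Morlet time-frequency decomposition, percent PSD, imaginary coherence.

The decomposition follows the package-wide convention: a linear 1-95 Hz grid
(1 Hz step) with the number of wavelet cycles linearly spaced from 4 at the
lowest to 8 at the highest frequency.  Coefficients within half a wavelet
support of either edge are flagged invalid and excluded from every average,
so short gait blocks are not biased by boundary effects.

Imaginary coherence between two channels a and b is

    IC(f) = |Im(G_ab(f))| / sqrt(G_aa(f) * G_bb(f)),

with cross/auto spectral densities estimated by averaging products of wavelet
coefficients over the analysis mask.  Discarding the real part makes the
measure blind to zero-lag (volume-conducted or artifactual) coupling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .recording import Recording

__all__ = [
    "TimeFrequency",
    "PSDPercent",
    "CoherenceSpectrum",
    "MorletTransform",
    "default_freqs",
    "default_n_cycles",
    "morlet_tfr",
    "psd_percent",
    "imaginary_coherence",
    "save_tfr",
    "load_tfr",
]


def default_freqs(f_min: float = 1.0, f_max: float = 95.0, step: float = 1.0
                  ) -> np.ndarray:
    """Linear frequency grid, 1-95 Hz inclusive at 1 Hz step by default."""
    return np.arange(f_min, f_max + step / 2, step)


def default_n_cycles(freqs: np.ndarray, lo: float = 4.0, hi: float = 8.0
                     ) -> np.ndarray:
    """Per-frequency wavelet cycle counts, linearly spaced 4..8 across the grid."""
    return np.linspace(lo, hi, len(freqs))


@dataclass
class TimeFrequency:
    """Complex wavelet coefficients, ``(n_channels, n_freqs, n_times)``.

    ``decim`` is the integer factor by which the coefficient time axis was
    decimated relative to the source sampling rate ``fs`` (the effective
    coefficient rate is ``fs / decim``).  ``edge_valid`` marks, per frequency,
    the coefficient columns farther than half a wavelet support from either
    edge.
    """

    coef: np.ndarray
    freqs: np.ndarray
    n_cycles: np.ndarray
    fs: float
    decim: int = 1
    labels: list[str] = field(default_factory=list)
    edge_valid: np.ndarray = None

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.n_cycles = np.asarray(self.n_cycles, dtype=float)
        if len(self.n_cycles) != len(self.freqs):
            raise ValueError("n_cycles must have one entry per frequency")
        if np.any(np.diff(self.n_cycles) < 0):
            raise ValueError("n_cycles must be non-decreasing across the grid")
        if not self.labels:
            self.labels = [f"ch{i}" for i in range(self.coef.shape[0])]
        if self.edge_valid is None:
            n_t = self.coef.shape[-1]
            half = np.ceil(self.n_cycles / self.freqs / 2 * self.fs / self.decim)
            cols = np.arange(n_t)
            self.edge_valid = (cols >= half[:, None]) & (cols < n_t - half[:, None])

    @property
    def power(self) -> np.ndarray:
        return np.abs(self.coef) ** 2

    @property
    def n_times(self) -> int:
        return self.coef.shape[-1]

    @property
    def valid_all_freqs(self) -> np.ndarray:
        """Columns valid at every frequency (limited by the widest wavelet)."""
        return self.edge_valid.all(axis=0)

    def pick(self, label: str) -> "TimeFrequency":
        i = self.labels.index(label)
        return TimeFrequency(self.coef[[i]], self.freqs, self.n_cycles,
                             self.fs, self.decim, [label], self.edge_valid)


@dataclass
class PSDPercent:
    """Per-channel PSD normalized to sum to 100% over the frequency grid."""

    values: np.ndarray  # (n_channels, n_freqs)
    freqs: np.ndarray
    labels: list[str] = field(default_factory=list)


@dataclass
class CoherenceSpectrum:
    """Imaginary coherence spectrum for one channel pair, values in [0, 1]."""

    values: np.ndarray
    freqs: np.ndarray
    pair: tuple[str, str] = ("a", "b")


class MorletTransform(TransformerMixin, BaseEstimator):
    """Continuous complex Morlet wavelet transform as a transformer.

    ``transform`` maps ``(n_samples, n_channels)`` arrays to a
    :class:`TimeFrequency`.  Wavelets are zero-mean and L2-normalized (tone
    power is frequency-independent); ``decim`` keeps every ``decim``-th
    coefficient column, which is ample for gait-phase binning where the
    envelope bandwidth is far below the sampling rate.
    """

    def __init__(self, fs: float = 2048.0, freqs=None, n_cycles=None,
                 decim: int = 1):
        self.fs = fs
        self.freqs = freqs
        self.n_cycles = n_cycles
        self.decim = decim

    def fit(self, X=None, y=None):
        self.freqs_ = (default_freqs() if self.freqs is None
                       else np.asarray(self.freqs, dtype=float))
        self.n_cycles_ = (default_n_cycles(self.freqs_) if self.n_cycles is None
                          else np.asarray(self.n_cycles, dtype=float))
        if self.freqs_.max() >= self.fs / 2:
            raise ValueError(
                f"max frequency {self.freqs_.max()} Hz must be below "
                f"Nyquist {self.fs / 2} Hz"
            )
        return self

    def transform(self, X) -> TimeFrequency:
        from mne.time_frequency import tfr_array_morlet

        if not hasattr(self, "freqs_"):
            self.fit(X)
        X = np.asarray(X, dtype=float)
        squeeze = X.ndim == 1
        data = (X[None, None, :] if squeeze else X.T[None])  # (1, n_ch, n_t)
        support = (self.n_cycles_ / self.freqs_).max() * self.fs
        if data.shape[-1] <= support:
            raise ValueError(
                f"signal length {data.shape[-1]} is shorter than the longest "
                f"wavelet support ({int(np.ceil(support))} samples)"
            )
        coef = tfr_array_morlet(
            data, sfreq=self.fs, freqs=self.freqs_, n_cycles=self.n_cycles_,
            zero_mean=True, output="complex", decim=self.decim, verbose="error",
        )[0]
        # rescale the L2-normalized wavelets to a flat tone response: the
        # response of a unit-norm Gaussian-envelope wavelet (sigma_t samples
        # = s) to its center complex exponential is sqrt(2*pi)*sqrt(s)/pi^(1/4)
        s = self.n_cycles_ / (2 * np.pi * self.freqs_) * self.fs
        gain = np.sqrt(2 * np.pi) * np.sqrt(s) / np.pi**0.25
        coef = coef / gain[None, :, None]
        return TimeFrequency(coef, self.freqs_, self.n_cycles_, self.fs,
                             self.decim)


def morlet_tfr(rec: Recording | np.ndarray, freqs=None, n_cycles=None,
               decim: int = 1, fs: float | None = None) -> TimeFrequency:
    """Morlet TFR of a Recording (or array with explicit ``fs``)."""
    if isinstance(rec, Recording):
        X, fs_, labels = rec.signals.T, rec.fs, list(rec.labels)
    else:
        if fs is None:
            raise ValueError("fs is required for array input")
        X, fs_, labels = np.atleast_2d(rec).T, fs, None
    tfr = MorletTransform(fs=fs_, freqs=freqs, n_cycles=n_cycles,
                          decim=decim).fit().transform(X)
    if labels:
        tfr.labels = labels
    return tfr


def save_tfr(path, tfr: TimeFrequency) -> None:
    """Persist a decomposition to HDF5 (/tfr/coef_real, /tfr/coef_imag, ...)."""
    import h5py

    with h5py.File(path, "w") as fh:
        g = fh.create_group("tfr")
        g.create_dataset("coef_real", data=tfr.coef.real)
        g.create_dataset("coef_imag", data=tfr.coef.imag)
        g.create_dataset("freqs", data=tfr.freqs)
        g.create_dataset("n_cycles", data=tfr.n_cycles)
        g.create_dataset("labels", data=np.array(tfr.labels,
                                                 dtype=h5py.string_dtype()))
        g.attrs["fs"] = tfr.fs
        g.attrs["decim"] = tfr.decim


def load_tfr(path) -> TimeFrequency:
    import h5py

    with h5py.File(path, "r") as fh:
        g = fh["tfr"]
        coef = np.asarray(g["coef_real"]) + 1j * np.asarray(g["coef_imag"])
        return TimeFrequency(
            coef, np.asarray(g["freqs"]), np.asarray(g["n_cycles"]),
            float(g.attrs["fs"]), int(g.attrs["decim"]),
            [s.decode() if isinstance(s, bytes) else str(s)
             for s in g["labels"][()]],
        )


def _combine_mask(tfr: TimeFrequency, time_mask) -> np.ndarray:
    mask = tfr.valid_all_freqs
    if time_mask is not None:
        time_mask = np.asarray(time_mask, dtype=bool)
        if time_mask.shape != (tfr.n_times,):
            raise ValueError(
                f"time_mask length {time_mask.shape} does not match "
                f"{tfr.n_times} coefficient columns"
            )
        mask = mask & time_mask
    if not mask.any():
        raise ValueError("time mask selects no valid samples")
    return mask


def psd_percent(tfr: TimeFrequency, time_mask=None) -> PSDPercent:
    """Mean wavelet power over the mask, normalized per channel to 100%."""
    mask = _combine_mask(tfr, time_mask)
    mean_power = tfr.power[..., mask].mean(axis=-1)  # (n_ch, n_f)
    total = mean_power.sum(axis=1, keepdims=True)
    if np.any(total == 0):
        raise ValueError("zero total power; cannot normalize PSD")
    return PSDPercent(100.0 * mean_power / total, tfr.freqs, list(tfr.labels))


def imaginary_coherence(tfr_a: TimeFrequency, tfr_b: TimeFrequency,
                        time_mask=None) -> CoherenceSpectrum:
    """Imaginary coherence between two single-channel decompositions."""
    if tfr_a.coef.shape[0] != 1 or tfr_b.coef.shape[0] != 1:
        raise ValueError("imaginary_coherence expects single-channel TFRs; "
                         "use TimeFrequency.pick")
    if (len(tfr_a.freqs) != len(tfr_b.freqs)
            or not np.allclose(tfr_a.freqs, tfr_b.freqs)
            or tfr_a.fs != tfr_b.fs or tfr_a.n_times != tfr_b.n_times):
        raise ValueError("TFR grids do not match between the two inputs")
    mask = _combine_mask(tfr_a, time_mask) & _combine_mask(tfr_b, time_mask)
    a = tfr_a.coef[0][:, mask]
    b = tfr_b.coef[0][:, mask]
    g_ab = (a * np.conj(b)).mean(axis=1)
    g_aa = (np.abs(a) ** 2).mean(axis=1)
    g_bb = (np.abs(b) ** 2).mean(axis=1)
    denom = np.sqrt(g_aa * g_bb)
    denom = np.where(denom == 0, np.inf, denom)
    ic = np.abs(np.imag(g_ab)) / denom
    return CoherenceSpectrum(ic, tfr_a.freqs,
                             (tfr_a.labels[0], tfr_b.labels[0]))
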