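"""Phase-binned power modulograms and the KL-divergence modulation index.

For each frequency, wavelet power is averaged within 18 non-overlapping gait
phase bins spanning ``[-pi, pi)``.  Two normalizations are kept side by side:

* ``mean_norm`` — bin means as a percentage of the across-bin mean (100% =
  phase-constant power), the display/statistics surface;
* ``sum_norm`` — bin means divided by their sum, a probability vector P per
  frequency, the input to the modulation index.

The modulation index is the Kullback-Leibler divergence of P from the
uniform distribution U = 1/N, normalized to [0, 1]:

    MI(f) = D_KL(P, U) / log(N),   D_KL(P, U) = sum_j P_j log(P_j / U_j),

with the standard convention 0*log(0) = 0.  MI is 0 iff power is flat over
phase and 1 iff all power falls in a single bin, and is invariant to overall
power gain.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator

from .gaitphase import PhaseSeries
from .spectral import TimeFrequency

__all__ = [
    "Modulogram",
    "MISpectrum",
    "GaitPhaseModulation",
    "modulogram",
    "modulation_index",
    "max_mi",
    "phase_bin_index",
    "plot_modulogram",
]

N_BINS_DEFAULT = 18


def phase_bin_edges(n_bins: int = N_BINS_DEFAULT) -> np.ndarray:
    return np.linspace(-np.pi, np.pi, n_bins + 1)


def phase_bin_index(phase: np.ndarray, n_bins: int = N_BINS_DEFAULT
                    ) -> np.ndarray:
    """Half-open bin assignment over [-pi, pi): bin k covers [edge_k, edge_{k+1})."""
    idx = np.floor((np.asarray(phase) + np.pi) / (2 * np.pi / n_bins))
    return np.clip(idx, 0, n_bins - 1).astype(np.intp)


@dataclass
class Modulogram:
    """Phase-binned normalized power, ``(n_freqs, n_bins)``."""

    mean_norm: np.ndarray  # percent of across-bin mean
    sum_norm: np.ndarray   # probability rows (input to the MI)
    bin_edges: np.ndarray
    freqs: np.ndarray

    def __post_init__(self) -> None:
        self.mean_norm = np.atleast_2d(np.asarray(self.mean_norm, dtype=float))
        self.sum_norm = np.atleast_2d(np.asarray(self.sum_norm, dtype=float))
        if self.mean_norm.shape != self.sum_norm.shape:
            raise ValueError("mean_norm and sum_norm shapes differ")
        if np.any(self.sum_norm < 0):
            raise ValueError("sum_norm contains negative probabilities")

    @property
    def n_bins(self) -> int:
        return self.mean_norm.shape[1]

    @property
    def bin_centers(self) -> np.ndarray:
        return (self.bin_edges[:-1] + self.bin_edges[1:]) / 2


@dataclass
class MISpectrum:
    """Per-frequency modulation index in [0, 1]."""

    mi: np.ndarray
    freqs: np.ndarray


def binned_power(power: np.ndarray, bin_idx: np.ndarray, n_bins: int
                 ) -> np.ndarray:
    """Mean power per (frequency, phase bin) via a flat weighted bincount.

    ``power`` is ``(n_freqs, n_times)``; ``bin_idx`` the per-column bin
    assignment.  Raises if any bin receives no samples.
    """
    n_f = power.shape[0]
    counts = np.bincount(bin_idx, minlength=n_bins)
    empty = np.where(counts == 0)[0]
    if empty.size:
        raise ValueError(f"empty phase bins: {empty.tolist()}")
    flat = bin_idx[None, :] + n_bins * np.arange(n_f)[:, None]
    sums = np.bincount(flat.ravel(), weights=power.ravel(),
                       minlength=n_f * n_bins).reshape(n_f, n_bins)
    return sums / counts


def _normalize(bin_mean: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mean_norm = 100.0 * bin_mean / bin_mean.mean(axis=1, keepdims=True)
    sum_norm = bin_mean / bin_mean.sum(axis=1, keepdims=True)
    return mean_norm, sum_norm


class GaitPhaseModulation(BaseEstimator):
    """Estimator mapping (power, gait phase) to a modulogram and MI spectrum.

    ``fit`` takes ``X`` of shape ``(n_samples, n_freqs)`` (wavelet power on
    any time grid) and ``y`` the per-sample gait phase (radians, same grid);
    samples with non-finite phase are ignored.  Fitted attributes:
    ``modulogram_``, ``mi_``, ``max_mi_freq_``, ``max_mi_``.
    """

    def __init__(self, n_bins: int = N_BINS_DEFAULT, freqs=None):
        self.n_bins = n_bins
        self.freqs = freqs

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        phase = np.asarray(y, dtype=float)
        if X.ndim != 2 or phase.shape != (X.shape[0],):
            raise ValueError("X must be (n_samples, n_freqs) and y per-sample phase")
        keep = np.isfinite(phase)
        if not keep.any():
            raise ValueError("no valid phase samples")
        freqs = (np.arange(1, X.shape[1] + 1, dtype=float)
                 if self.freqs is None else np.asarray(self.freqs, dtype=float))
        idx = phase_bin_index(phase[keep], self.n_bins)
        bin_mean = binned_power(X[keep].T, idx, self.n_bins)
        mean_norm, sum_norm = _normalize(bin_mean)
        self.modulogram_ = Modulogram(mean_norm, sum_norm,
                                      phase_bin_edges(self.n_bins), freqs)
        self.mi_ = modulation_index(self.modulogram_)
        f, v = max_mi(self.mi_, band=(freqs.min(), freqs.max()))
        self.max_mi_freq_, self.max_mi_ = f, v
        return self


def modulogram(tfr: TimeFrequency, phase: PhaseSeries,
               n_bins: int = N_BINS_DEFAULT, channel: int | str = 0
               ) -> Modulogram:
    """Phase-binned modulogram of one TFR channel.

    ``phase`` may be sampled at the recording rate; it is decimated to the
    coefficient grid when the TFR was computed with ``decim > 1``.  Only
    samples that are inside detected cycles *and* clear of wavelet edge
    effects contribute.
    """
    if isinstance(channel, str):
        channel = tfr.labels.index(channel)
    if len(phase.phase) != tfr.n_times:
        if len(phase.phase) // tfr.decim in (tfr.n_times, tfr.n_times + 1):
            phase = phase.decimate(tfr.decim)
            phase = PhaseSeries(phase.phase[:tfr.n_times],
                                phase.valid[:tfr.n_times], phase.fs,
                                phase.strike_anchored)
        else:
            raise ValueError(
                f"phase length {len(phase.phase)} does not match TFR time "
                f"base {tfr.n_times} (decim={tfr.decim})"
            )
    mask = phase.valid & tfr.valid_all_freqs
    if not mask.any():
        raise ValueError("no valid samples shared by phase and TFR")
    idx = phase_bin_index(phase.phase[mask], n_bins)
    bin_mean = binned_power(tfr.power[channel][:, mask], idx, n_bins)
    mean_norm, sum_norm = _normalize(bin_mean)
    return Modulogram(mean_norm, sum_norm, phase_bin_edges(n_bins), tfr.freqs)


def modulation_index(m: Modulogram) -> MISpectrum:
    """Normalized KL divergence of each sum_norm row from uniform."""
    P = m.sum_norm
    if np.any(P < 0):
        raise ValueError("negative probabilities in sum_norm")
    N = m.n_bins
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(P > 0, P * np.log(P * N), 0.0)
    mi = terms.sum(axis=1) / np.log(N)
    return MISpectrum(np.clip(mi, 0.0, 1.0), m.freqs)


def max_mi(spec: MISpectrum, band: tuple = (1.0, 95.0)) -> tuple[float, float]:
    """(frequency, value) of the maximum MI within ``band`` (ties -> lower freq)."""
    lo, hi = band
    sel = (spec.freqs >= lo) & (spec.freqs <= hi)
    if not sel.any():
        raise ValueError(f"band {band} is outside the frequency grid")
    f = spec.freqs[sel]
    v = spec.mi[sel]
    i = int(np.argmax(v))
    return float(f[i]), float(v[i])


def plot_modulogram(m: Modulogram, mi: MISpectrum | None = None, ax=None):
    """Modulogram heat map with the MI spectrum alongside (display utility)."""
    import matplotlib.pyplot as plt

    if mi is None:
        mi = modulation_index(m)
    if ax is None:
        fig, (ax_mi, ax_map) = plt.subplots(
            1, 2, figsize=(8, 4), width_ratios=[1, 3], sharey=True)
    else:
        ax_mi, ax_map = ax
        fig = ax_map.figure
    ax_mi.plot(mi.mi, mi.freqs)
    ax_mi.set_xlabel("modulation index")
    ax_mi.set_ylabel("frequency (Hz)")
    ax_mi.invert_xaxis()
    pc = ax_map.pcolormesh(m.bin_centers, m.freqs, m.mean_norm, shading="auto")
    ax_map.set_xlabel("gait phase (rad)")
    fig.colorbar(pc, ax=ax_map, label="power (% of bin mean)")
    return fig
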