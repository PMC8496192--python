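"""Bipolar re-referencing, zero-phase Butterworth filtering, resampling.

The estimator classes (:class:`BipolarReference`, :class:`ZeroPhaseButterworth`,
:class:`Downsampler`) are stateless sklearn-style transformers over
``(n_samples, n_channels)`` arrays and compose with sklearn pipelines; the
module functions operate on :class:`~gaitmod.recording.Recording` objects and
are what the study pipeline uses.

Filter-order convention: a "6th/8th-order zero-phase Butterworth band
filter" is designed at the stated transfer-function order (scipy ``butter``
with ``N = order/2`` for band filters) and applied forward-backward
(``sosfiltfilt``), doubling the effective magnitude order and cancelling the
phase response.  Reflect padding of three settle lengths keeps edge
transients out of short gait blocks.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.signal import butter, resample_poly, sosfiltfilt
from sklearn.base import BaseEstimator, TransformerMixin

from .recording import Recording

__all__ = [
    "FilterSpec",
    "BipolarReference",
    "ZeroPhaseButterworth",
    "Downsampler",
    "make_bipolar",
    "apply_filter",
    "resample",
    "preprocess_recording",
    "flag_artifacts",
]


@dataclass(frozen=True)
class FilterSpec:
    """Design of one zero-phase Butterworth band filter.

    ``order`` is the design order of the band filter before forward-backward
    application (must be even: scipy designs band filters at twice the
    prototype order).
    """

    kind: str  # "bandpass" | "bandstop"
    order: int
    edges: tuple[float, float]
    zero_phase: bool = True

    def validate(self, fs: float) -> None:
        if self.kind not in ("bandpass", "bandstop"):
            raise ValueError(f"kind must be bandpass|bandstop, got {self.kind!r}")
        if self.order < 2 or self.order % 2:
            raise ValueError(f"order must be a positive even integer, got {self.order}")
        lo, hi = self.edges
        if not 0 < lo < hi < fs / 2:
            raise ValueError(
                f"edges must satisfy 0 < low < high < fs/2 = {fs / 2}, got {self.edges}"
            )

    def sos(self, fs: float) -> np.ndarray:
        self.validate(fs)
        return butter(self.order // 2, self.edges, btype=self.kind, fs=fs,
                      output="sos")


#: default per-kind filter chains (LFP/EEG: mains stop then broadband pass;
#: force/accelerometer: step-band pass)
LFP_STOP = FilterSpec("bandstop", 8, (48.0, 52.0))
LFP_PASS = FilterSpec("bandpass", 8, (0.5, 250.0))
KINEMATIC_PASS = FilterSpec("bandpass", 6, (0.5, 5.0))


def _filtfilt(sos: np.ndarray, x: np.ndarray, fs: float, low_edge: float
              ) -> np.ndarray:
    """Forward-backward filtering with reflect padding of 3 settle lengths."""
    settle = int(round(3 * fs / max(low_edge, 1e-6)))
    padlen = min(x.shape[-1] - 1, max(settle, 3 * (2 * sos.shape[0] + 1)))
    return sosfiltfilt(sos, x, axis=-1, padlen=padlen)


# ---------------------------------------------------------------------------
# sklearn-style transformers (axis 0 = time)

class ZeroPhaseButterworth(TransformerMixin, BaseEstimator):
    """Zero-phase Butterworth band filter as a stateless transformer.

    Operates column-wise on ``(n_samples, n_channels)`` arrays.
    """

    def __init__(self, fs: float = 2048.0, kind: str = "bandpass",
                 order: int = 8, edges: tuple = (0.5, 250.0)):
        self.fs = fs
        self.kind = kind
        self.order = order
        self.edges = edges

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        self.spec_ = FilterSpec(self.kind, self.order, tuple(self.edges))
        self.spec_.validate(self.fs)
        self.n_features_in_ = X.shape[1] if X.ndim == 2 else 1
        return self

    def transform(self, X):
        if not hasattr(self, "spec_"):
            self.fit(X)
        X = np.asarray(X, dtype=float)
        squeeze = X.ndim == 1
        X2 = np.atleast_2d(X.T)
        out = _filtfilt(self.spec_.sos(self.fs), X2, self.fs, self.spec_.edges[0])
        return out[0] if squeeze else out.T


class BipolarReference(TransformerMixin, BaseEstimator):
    """Adjacent-contact differencing: channel k -> contact k - contact k+1."""

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.shape[1] < 2:
            raise ValueError("need at least 2 contacts for a bipolar derivation")
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        X = np.asarray(X, dtype=float)
        return X[:, :-1] - X[:, 1:]


class Downsampler(TransformerMixin, BaseEstimator):
    """Polyphase anti-aliased resampling from ``fs`` to ``fs_new`` (< fs)."""

    def __init__(self, fs: float = 2048.0, fs_new: float = 256.0):
        self.fs = fs
        self.fs_new = fs_new

    def fit(self, X, y=None):
        if self.fs_new >= self.fs:
            raise ValueError(
                f"fs_new must be below fs, got fs_new={self.fs_new} >= fs={self.fs}"
            )
        from fractions import Fraction

        frac = Fraction(self.fs_new / self.fs).limit_denominator(1000)
        self.up_, self.down_ = frac.numerator, frac.denominator
        return self

    def transform(self, X):
        if not hasattr(self, "up_"):
            self.fit(X)
        X = np.asarray(X, dtype=float)
        return resample_poly(X, self.up_, self.down_, axis=0)


# ---------------------------------------------------------------------------
# Recording-level operations

def make_bipolar(rec: Recording, contact_order: list[str]) -> Recording:
    """Bipolar LFPs from each pair of spatially adjacent contacts.

    ``contact_order`` lists the monopolar contact labels along the lead;
    the result has ``len(contact_order) - 1`` channels, channel k being
    contact k minus contact k+1, labeled ``"<k>-<k+1>"``.
    """
    if len(contact_order) < 2:
        raise ValueError("need at least 2 contacts for a bipolar montage")
    idx = [rec.index(lab) for lab in contact_order]
    mono = rec.signals[idx]
    signals = mono[:-1] - mono[1:]
    labels = [f"{a}-{b}" for a, b in zip(contact_order[:-1], contact_order[1:])]
    kinds = [rec.kinds[i] for i in idx[:-1]]
    return Recording(signals=signals, fs=rec.fs, labels=labels, kinds=kinds)


def apply_filter(rec: Recording, spec: FilterSpec, channels=None) -> Recording:
    """Zero-phase filter the selected channels (labels list, kind name, or all)."""
    spec.validate(rec.fs)
    if isinstance(channels, str):  # a kind tag
        idx = [i for i, k in enumerate(rec.kinds) if k == channels]
    elif channels is None:
        idx = list(range(rec.n_channels))
    else:
        idx = [rec.index(lab) for lab in channels]
    out = rec.signals.copy()
    if idx:
        out[idx] = _filtfilt(spec.sos(rec.fs), out[idx], rec.fs, spec.edges[0])
    return replace(rec, signals=out, labels=list(rec.labels), kinds=list(rec.kinds))


def resample(rec: Recording, fs_new: float) -> Recording:
    """Anti-aliased resampling of all channels to ``fs_new`` Hz."""
    ds = Downsampler(fs=rec.fs, fs_new=fs_new).fit(None)
    signals = ds.transform(rec.signals.T).T
    return replace(rec, signals=signals, fs=fs_new,
                   labels=list(rec.labels), kinds=list(rec.kinds))


def preprocess_recording(rec: Recording, mains_band: tuple = (48.0, 52.0)
                         ) -> Recording:
    """Default per-kind filter chain.

    LFP/EEG channels: mains band-stop (skipped when the Nyquist frequency is
    below the stop band) followed by a broadband bandpass whose upper edge is
    ``min(250, 0.9 * fs/2)`` so the chain stays valid at reduced sampling
    rates.  Force/accelerometer channels: 0.5-5 Hz bandpass.
    """
    out = rec
    hi = min(250.0, 0.9 * rec.fs / 2)
    neuro = [lab for lab, k in zip(rec.labels, rec.kinds) if k in ("lfp", "eeg")]
    kinematic = [lab for lab, k in zip(rec.labels, rec.kinds)
                 if k in ("force", "accel")]
    if neuro:
        if rec.fs / 2 > mains_band[1] * 1.1:
            out = apply_filter(out, FilterSpec("bandstop", 8, mains_band), neuro)
        out = apply_filter(out, FilterSpec("bandpass", 8, (0.5, hi)), neuro)
    if kinematic:
        out = apply_filter(out, KINEMATIC_PASS, kinematic)
    return out


def flag_artifacts(rec: Recording, threshold_sd: float = 5.0) -> np.ndarray:
    """Amplitude-threshold artifact flags (True = suspect sample).

    A pragmatic stand-in for visual artifact screening: flags samples where
    any channel exceeds ``threshold_sd`` robust SDs (1.4826 * MAD) of its own
    trace.
    """
    x = rec.signals
    med = np.median(x, axis=1, keepdims=True)
    mad = np.median(np.abs(x - med), axis=1, keepdims=True)
    sd = 1.4826 * np.maximum(mad, 1e-12)
    return (np.abs(x - med) > threshold_sd * sd).any(axis=0)
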