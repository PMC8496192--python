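"""Unsupervised LFP state analysis: AR-HMM, phase occupancy, K-medoids.

A hidden Markov model whose per-state observation model is a multivariate
autoregressive (AR) process segments multichannel LFP (downsampled to
256 Hz) into recurring dynamical states:

    x_t | s_t = k  ~  N( sum_l A_k,l x_{t-l} + b_k,  Sigma_k ),

fitted by maximum-likelihood EM (forward-backward E step from hmmlearn; the
AR weighted-least-squares M step implemented here), with hard state
assignment by Viterbi and occupancy-based pruning of unused states.  This is
a deliberate simplification of variational-Bayes AR-HMM toolboxes: no
automatic complexity control beyond the state-count cap and pruning.

Each state's gait-phase occupancy is summarized as a 100-bin histogram over
``[-pi, pi)`` (uniform reference 1% per bin); histograms are grouped with a
PAM-style K-medoids (written here: no maintained K-medoids is available in
the supported dependency set), and deviation of a state's phase distribution
from uniformity is assessed with a one-sample Kolmogorov-Smirnov test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from hmmlearn.base import BaseHMM
from scipy.spatial.distance import cdist
from scipy.stats import kstest
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.utils import check_random_state

from .gaitphase import PhaseSeries
from .recording import Recording

__all__ = [
    "ARHMM",
    "StateModel",
    "OccupancyHistogram",
    "HistogramClustering",
    "KMedoids",
    "fit_state_model",
    "occupancy_histograms",
    "cluster_histograms",
    "ks_uniformity",
]


def _ar_design(X: np.ndarray, order: int) -> np.ndarray:
    """Combined [lagged design | intercept | current] feature rows.

    Row t holds (x_{t-1}, ..., x_{t-order}, 1, x_t); the HMM treats these
    rows as its observations so that conditional AR likelihoods can be
    evaluated per state.
    """
    T, d = X.shape
    if T <= order:
        raise ValueError("series shorter than the AR order")
    lags = [X[order - l - 1: T - l - 1] for l in range(order)]
    Z = np.hstack(lags + [np.ones((T - order, 1))])
    return np.hstack([Z, X[order:]])


class ARHMM(BaseHMM):
    """HMM with multivariate-AR observation states (sklearn/hmmlearn API).

    ``fit`` expects the combined rows produced by :func:`_ar_design`; use
    :meth:`fit_series` / :meth:`predict_series` for raw ``(n_samples,
    n_channels)`` input.  EM updates start probabilities, the transition
    matrix, per-state AR coefficient blocks ``coef_`` ((order*d+1) x d,
    intercept last) and noise covariances ``covars_``.
    """

    def __init__(self, n_states: int = 30, ar_order: int = 3,
                 n_iter: int = 50, tol: float = 1e-3, random_state=None,
                 reg: float = 1e-6, verbose: bool = False):
        super().__init__(n_components=n_states, n_iter=n_iter, tol=tol,
                         random_state=random_state, verbose=verbose,
                         params="st", init_params="st",
                         implementation="log")
        self.n_states = n_states
        self.ar_order = ar_order
        self.reg = reg

    # hmmlearn plumbing ----------------------------------------------------

    def _split(self, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        d = self._n_channels
        return X[:, : -d], X[:, -d:]

    @property
    def _n_channels(self) -> int:
        return (self.n_features - 1) // (self.ar_order + 1)

    def _init(self, X, lengths=None):
        self.n_components = self.n_states
        super()._init(X, lengths)
        rng = check_random_state(self.random_state)
        d = self._n_channels
        m = X.shape[1] - d
        # responsibility-seeded M step: random soft assignment, then the
        # exact weighted-least-squares update below
        resp = rng.dirichlet(np.ones(self.n_components), size=X.shape[0])
        Z, y = self._split(X)
        self.coef_ = np.zeros((self.n_components, m, d))
        self.covars_ = np.zeros((self.n_components, d, d))
        for k in range(self.n_components):
            w = resp[:, k]
            self._wls_update(k, Z, y, w)

    def _wls_update(self, k: int, Z: np.ndarray, y: np.ndarray,
                    w: np.ndarray) -> None:
        Zw = Z * w[:, None]
        ZZ = Z.T @ Zw + self.reg * np.eye(Z.shape[1])
        Zy = Zw.T @ y
        B = np.linalg.solve(ZZ, Zy)
        resid = y - Z @ B
        cov = (resid * w[:, None]).T @ resid / max(w.sum(), 1e-12)
        cov = (cov + cov.T) / 2 + self.reg * np.eye(y.shape[1])
        self.coef_[k] = B
        self.covars_[k] = cov

    def _check(self):
        super()._check()
        if self.coef_.shape[0] != self.n_components:
            raise ValueError("coef_ does not match n_components")

    def _get_n_fit_scalars_per_param(self):
        nc = self.n_components
        return {"s": nc - 1, "t": nc * (nc - 1)}

    def _compute_log_likelihood(self, X):
        Z, y = self._split(X)
        T = X.shape[0]
        d = y.shape[1]
        out = np.empty((T, self.n_components))
        for k in range(self.n_components):
            resid = y - Z @ self.coef_[k]
            L = np.linalg.cholesky(self.covars_[k])
            logdet = 2 * np.sum(np.log(np.diag(L)))
            sol = np.linalg.solve(L, resid.T)
            quad = np.sum(sol**2, axis=0)
            out[:, k] = -0.5 * (d * np.log(2 * np.pi) + logdet + quad)
        return out

    def _initialize_sufficient_statistics(self):
        stats = super()._initialize_sufficient_statistics()
        d = getattr(self, "_suffstats_d", None)
        if hasattr(self, "coef_"):
            m, d = self.coef_.shape[1], self.coef_.shape[2]
            stats["ZZ"] = np.zeros((self.n_components, m, m))
            stats["Zy"] = np.zeros((self.n_components, m, d))
            stats["yy"] = np.zeros((self.n_components, d, d))
            stats["w"] = np.zeros(self.n_components)
        return stats

    def _accumulate_sufficient_statistics(self, stats, X, lattice, posteriors,
                                          fwdlattice, bwdlattice):
        super()._accumulate_sufficient_statistics(
            stats, X, lattice, posteriors, fwdlattice, bwdlattice)
        Z, y = self._split(X)
        for k in range(self.n_components):
            w = posteriors[:, k]
            Zw = Z * w[:, None]
            stats["ZZ"][k] += Z.T @ Zw
            stats["Zy"][k] += Zw.T @ y
            stats["yy"][k] += (y * w[:, None]).T @ y
            stats["w"][k] += w.sum()

    def _do_mstep(self, stats):
        super()._do_mstep(stats)
        d = self.coef_.shape[2]
        for k in range(self.n_components):
            ZZ = stats["ZZ"][k] + self.reg * np.eye(stats["ZZ"].shape[1])
            B = np.linalg.solve(ZZ, stats["Zy"][k])
            w = max(stats["w"][k], 1e-12)
            cov = (stats["yy"][k] - stats["Zy"][k].T @ B - B.T @ stats["Zy"][k]
                   + B.T @ stats["ZZ"][k] @ B) / w
            cov = (cov + cov.T) / 2 + self.reg * np.eye(d)
            self.coef_[k] = B
            self.covars_[k] = cov

    # raw-series convenience ----------------------------------------------

    def fit_series(self, X: np.ndarray) -> "ARHMM":
        return self.fit(_ar_design(np.asarray(X, dtype=float), self.ar_order))

    def predict_series(self, X: np.ndarray) -> np.ndarray:
        """Viterbi state per sample; the first ``ar_order`` samples are unassigned (-1)."""
        states = self.predict(_ar_design(np.asarray(X, dtype=float),
                                         self.ar_order))
        return np.concatenate([np.full(self.ar_order, -1), states])


@dataclass
class StateModel:
    """Fitted state segmentation of a multichannel LFP recording.

    ``state_sequence`` is aligned to the input samples (-1 for the first
    ``ar_order`` samples, which have no complete lag vector); states with
    occupancy below the pruning threshold have been relabeled away and
    ``fractional_occupancy`` covers the kept states only.
    """

    model: ARHMM
    state_sequence: np.ndarray
    fractional_occupancy: np.ndarray
    kept_states: np.ndarray
    log_likelihoods: np.ndarray
    fs: float
    ar_order: int


def fit_state_model(rec: Recording | np.ndarray, n_states_max: int = 30,
                    ar_order: int = 3, seed: int | None = None,
                    n_iter: int = 50, tol: float = 1e-3,
                    prune_threshold: float = 1e-6,
                    standardize: bool = True) -> StateModel:
    """Fit the AR-HMM to multichannel LFP and decode the state sequence.

    Channels are standardized to unit variance by default (the model input
    pools bipolar channels whose gains are not comparable).  States whose
    Viterbi occupancy falls below ``prune_threshold`` are pruned and the
    sequence relabeled to consecutive integers.
    """
    if isinstance(rec, Recording):
        X, fs = rec.signals.T.copy(), rec.fs
    else:
        X, fs = np.asarray(rec, dtype=float).copy(), float("nan")
    if X.ndim == 1:
        X = X[:, None]
    if standardize:
        X = (X - X.mean(axis=0)) / np.maximum(X.std(axis=0), 1e-12)
    hmm = ARHMM(n_states=n_states_max, ar_order=ar_order, n_iter=n_iter,
                tol=tol, random_state=seed)
    hmm.fit_series(X)
    if not hmm.monitor_.converged:
        warnings.warn(
            "AR-HMM EM did not converge within n_iter; returning best model",
            RuntimeWarning,
        )
    seq = hmm.predict_series(X)
    assigned = seq[seq >= 0]
    occ = np.bincount(assigned, minlength=n_states_max) / len(assigned)
    kept = np.where(occ >= max(prune_threshold, 0))[0]
    kept = kept[occ[kept] > prune_threshold]
    relabel = -np.ones(n_states_max, dtype=int)
    relabel[kept] = np.arange(len(kept))
    seq_rel = np.where(seq >= 0, relabel[np.maximum(seq, 0)], -1)
    return StateModel(
        model=hmm,
        state_sequence=seq_rel,
        fractional_occupancy=occ[kept] / occ[kept].sum(),
        kept_states=kept,
        log_likelihoods=np.asarray(hmm.monitor_.history, dtype=float),
        fs=fs,
        ar_order=ar_order,
    )


@dataclass
class OccupancyHistogram:
    """Gait-phase occurrence histogram of one state (100 bins over [-pi, pi))."""

    probs: np.ndarray
    bin_edges: np.ndarray
    state: int
    n_samples: int
    phases: np.ndarray = field(repr=False, default=None)

    @property
    def uniform_reference(self) -> float:
        return 1.0 / len(self.probs)


def occupancy_histograms(model: StateModel | np.ndarray, phase: PhaseSeries,
                         n_bins: int = 100) -> list[OccupancyHistogram]:
    """Per-state histograms of the gait phase at that state's samples."""
    seq = model.state_sequence if isinstance(model, StateModel) else np.asarray(model)
    if len(seq) != len(phase.phase):
        raise ValueError(
            f"state sequence length {len(seq)} does not match phase length "
            f"{len(phase.phase)}"
        )
    valid = phase.valid & (seq >= 0)
    if not valid.any():
        raise ValueError("no valid phase samples overlap the state sequence")
    edges = np.linspace(-np.pi, np.pi, n_bins + 1)
    out = []
    for k in np.unique(seq[valid]):
        ph = phase.phase[valid & (seq == k)]
        counts, _ = np.histogram(ph, bins=edges)
        out.append(OccupancyHistogram(
            probs=counts / counts.sum(), bin_edges=edges, state=int(k),
            n_samples=len(ph), phases=ph,
        ))
    return out


def ks_uniformity(hist: OccupancyHistogram) -> float:
    """One-sample KS p value of the state's phase samples against uniform on [-pi, pi)."""
    if hist.phases is None:
        raise ValueError("histogram carries no raw phase samples")
    if hist.n_samples < 10:
        warnings.warn(
            f"only {hist.n_samples} samples behind the histogram; "
            "KS p value is unreliable", RuntimeWarning,
        )
    res = kstest(hist.phases, lambda x: (x + np.pi) / (2 * np.pi))
    return float(res.pvalue)


class KMedoids(ClusterMixin, BaseEstimator):
    """PAM-style K-medoids with k-medoids++ seeding (deterministic given seed).

    Alternates nearest-medoid assignment with exact per-cluster medoid
    updates until the medoid set is stable; medoids are always members of
    the data set.
    """

    def __init__(self, n_clusters: int = 3, max_iter: int = 100,
                 random_state=None):
        self.n_clusters = n_clusters
        self.max_iter = max_iter
        self.random_state = random_state

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        n = X.shape[0]
        k = self.n_clusters
        if n < k:
            raise ValueError(f"need at least {k} samples, got {n}")
        rng = check_random_state(self.random_state)
        D = cdist(X, X)

        # k-medoids++ seeding
        medoids = [int(rng.randint(n))]
        while len(medoids) < k:
            d2 = D[:, medoids].min(axis=1) ** 2
            total = d2.sum()
            if total == 0:
                pool = [i for i in range(n) if i not in medoids]
                medoids.append(int(pool[rng.randint(len(pool))]))
                continue
            medoids.append(int(rng.choice(n, p=d2 / total)))
        medoids = np.array(sorted(medoids))

        for _ in range(self.max_iter):
            labels = np.argmin(D[:, medoids], axis=1)
            new = medoids.copy()
            for c in range(k):
                members = np.where(labels == c)[0]
                if members.size == 0:
                    continue
                within = D[np.ix_(members, members)].sum(axis=1)
                new[c] = members[int(np.argmin(within))]
            new = np.sort(new)
            if np.array_equal(new, medoids):
                break
            medoids = new
        self.medoid_indices_ = medoids
        self.labels_ = np.argmin(D[:, medoids], axis=1)
        self.cluster_centers_ = X[medoids]
        self.inertia_ = float(D[np.arange(n), medoids[self.labels_]].sum())
        return self

    def predict(self, X):
        return np.argmin(cdist(np.asarray(X, dtype=float),
                               self.cluster_centers_), axis=1)


@dataclass
class HistogramClustering:
    """K-medoids grouping of state occupancy histograms."""

    medoid_indices: np.ndarray
    labels: np.ndarray
    k: int
    metric: str = "euclidean"


def cluster_histograms(hists, k: int = 3, seed: int | None = None
                       ) -> HistogramClustering:
    """Cluster occupancy histograms into ``k`` groups (Euclidean K-medoids)."""
    X = np.vstack([h.probs if isinstance(h, OccupancyHistogram) else h
                   for h in hists])
    if X.shape[0] < k:
        raise ValueError(f"need at least {k} histograms, got {X.shape[0]}")
    km = KMedoids(n_clusters=k, random_state=seed).fit(X)
    return HistogramClustering(km.medoid_indices_, km.labels_, k)
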