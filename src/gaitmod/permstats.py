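"""Permutation inference and exact small-sample tests.

Two permutation schemes with cluster-based multiple-comparison control:

* within-cycle phase shuffling — each gait cycle's phase vector is cut at a
  random point and the two segments swapped (a circular rotation), destroying
  phase locking while preserving each cycle's phase multiset.  Repeating the
  modulogram computation on shuffled phase builds the null; the null mean/SD
  z-score the observed map, suprathreshold cells are clustered
  (4-connectivity, phase axis circular) and cluster mass |sum z| is compared
  against the permutation distribution of maximal masses.
* condition sign-flip — for paired per-hemisphere spectra, the order of
  subtraction is flipped independently per hemisphere; clusters form over
  contiguous frequencies.

Exact tests reported in small cohorts: a Wilcoxon signed-rank test whose
two-sided p is computed from the full distribution of the rank sum over all
2^n sign assignments, and a Spearman correlation whose two-sided p is the
fraction of all n! rank permutations at least as extreme as the observed
|rho|.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import label as nd_label
from scipy.stats import norm, rankdata

from .gaitphase import GaitCycleTable, PhaseSeries
from .modulation import (N_BINS_DEFAULT, _normalize, binned_power,
                         phase_bin_edges, phase_bin_index)
from .spectral import TimeFrequency

__all__ = [
    "Cluster",
    "PermutationResult",
    "shuffle_phase_within_cycles",
    "cluster_perm_modulogram",
    "cluster_perm_conditions",
    "wilcoxon_exact",
    "spearman_exact",
]


@dataclass
class Cluster:
    """One suprathreshold cluster: member cells, mass = |sum z|, p value."""

    cells: np.ndarray  # (n_cells, ndim) integer indices into the stat map
    mass: float
    p_value: float
    sign: int


@dataclass
class PermutationResult:
    observed: np.ndarray
    z_map: np.ndarray
    clusters: list[Cluster]
    null_masses: np.ndarray
    n_perm: int
    seed: int | None = None
    freqs: np.ndarray = None
    bin_edges: np.ndarray = None
    extras: dict = field(default_factory=dict)

    @property
    def significant_clusters(self) -> list[Cluster]:
        return [c for c in self.clusters if c.p_value < self.extras.get("alpha", 0.05)]


# ---------------------------------------------------------------------------
# within-cycle phase shuffling

def _cycle_slices(cycles: GaitCycleTable, n: int, decim: int = 1
                  ) -> list[tuple[int, int]]:
    out = []
    for a, c in zip(cycles.lift_sample, cycles.next_lift_sample):
        lo = int(np.ceil(a / decim))
        hi = min(n, int(np.ceil(c / decim)))
        if hi - lo >= 2:
            out.append((lo, hi))
    return out


def _rotate_within(values: np.ndarray, slices, offsets) -> np.ndarray:
    out = values.copy()
    for (lo, hi), k in zip(slices, offsets):
        out[lo:hi] = np.roll(values[lo:hi], -int(k))
    return out


def shuffle_phase_within_cycles(phase: PhaseSeries, cycles: GaitCycleTable,
                                rng: np.random.Generator) -> PhaseSeries:
    """Cut each cycle's phase vector at a random point and swap the segments.

    Equivalent to an independent circular rotation per cycle; the multiset of
    phase values within each cycle is preserved and samples outside cycles
    are untouched.
    """
    slices = _cycle_slices(cycles, len(phase.phase), decim=1)
    offsets = [rng.integers(0, hi - lo) for lo, hi in slices]
    shuffled = _rotate_within(phase.phase, slices, offsets)
    return PhaseSeries(shuffled, phase.valid.copy(), phase.fs,
                       phase.strike_anchored)


# ---------------------------------------------------------------------------
# cluster machinery

_STRUCT_2D = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)


def _label_circular(mask: np.ndarray) -> tuple[np.ndarray, int]:
    """4-connected labeling of a (freq, bin) mask, bin axis circular."""
    lab, n = nd_label(mask, structure=_STRUCT_2D)
    if n > 1 and mask.shape[1] > 1:
        # merge labels touching across the phase wrap (last bin adjacent to first)
        mapping = np.arange(n + 1)

        def find(i):
            while mapping[i] != i:
                mapping[i] = mapping[mapping[i]]
                i = mapping[i]
            return i

        for f in range(mask.shape[0]):
            a, b = lab[f, 0], lab[f, -1]
            if a and b and find(a) != find(b):
                mapping[find(max(a, b))] = find(min(a, b))
        for i in range(1, n + 1):
            mapping[i] = find(i)
        lab = mapping[lab]
        n = len(np.unique(lab)) - (1 if (lab == 0).any() else 0)
    return lab, n


def _cluster_masses(z: np.ndarray, thresh, circular: bool
                    ) -> tuple[list[tuple[np.ndarray, float, int]], float]:
    """Signed suprathreshold clusters of a z map; returns clusters and max mass."""
    z = np.atleast_2d(z)
    thresh = np.broadcast_to(np.asarray(thresh, dtype=float), z.shape)
    clusters = []
    max_mass = 0.0
    for sign in (1, -1):
        mask = sign * z > thresh
        if not mask.any():
            continue
        if circular:
            lab, n = _label_circular(mask)
        else:
            lab, n = nd_label(mask, structure=_STRUCT_2D)
        for li in np.unique(lab):
            if li == 0:
                continue
            cells = np.argwhere(lab == li)
            mass = float(np.abs(z[lab == li].sum()))
            clusters.append((cells, mass, sign))
            max_mass = max(max_mass, mass)
    return clusters, max_mass


def _null_z_threshold(z_null: np.ndarray, alpha: float, mode: str) -> np.ndarray:
    """Per-cell |z| precluster threshold from the permutation null."""
    n_perm = z_null.shape[0]
    use_empirical = mode == "empirical" or (mode == "auto" and n_perm >= 500)
    if use_empirical:
        return np.quantile(np.abs(z_null), 1 - alpha, axis=0)
    return np.full(z_null.shape[1:], norm.isf(alpha / 2))


def cluster_perm_modulogram(tfr: TimeFrequency, phase: PhaseSeries,
                            cycles: GaitCycleTable, n_perm: int = 1000,
                            alpha: float = 0.05, seed: int | None = None,
                            cell_p_mode: str = "auto", channel: int | str = 0,
                            n_bins: int = N_BINS_DEFAULT) -> PermutationResult:
    """Cluster-based permutation test of one channel's modulogram.

    The observed phase-binned power map (percent of bin mean) is z-scored
    cell-wise against ``n_perm`` within-cycle phase shuffles; cells beyond the
    two-sided ``alpha`` precluster threshold are joined by 4-connectivity
    (phase bins circular) and each cluster's |sum z| is compared with the
    permutation distribution of maximal cluster masses.  Deterministic given
    ``seed``.
    """
    if n_perm < 100:
        raise ValueError(f"n_perm must be >= 100, got {n_perm}")
    if isinstance(channel, str):
        channel = tfr.labels.index(channel)
    rng = np.random.default_rng(seed)

    if len(phase.phase) != tfr.n_times:
        phase = phase.decimate(tfr.decim)
        phase = PhaseSeries(phase.phase[:tfr.n_times], phase.valid[:tfr.n_times],
                            phase.fs, phase.strike_anchored)
        decim = tfr.decim
    else:
        decim = tfr.decim
    mask = phase.valid & tfr.valid_all_freqs
    if not mask.any():
        raise ValueError("no valid samples shared by phase and TFR")

    power = tfr.power[channel][:, mask]
    bins = phase_bin_index(phase.phase[mask], n_bins)
    # contiguous runs of masked samples per cycle, in masked-index space
    pos = np.where(mask)[0]
    runs = []
    for lo, hi in _cycle_slices(cycles, tfr.n_times, decim=decim):
        sel = np.searchsorted(pos, [lo, hi])
        if sel[1] - sel[0] >= 2:
            runs.append((int(sel[0]), int(sel[1])))

    observed, _ = _normalize(binned_power(power, bins, n_bins))

    null = np.empty((n_perm,) + observed.shape)
    for p in range(n_perm):
        offsets = [rng.integers(0, hi - lo) for lo, hi in runs]
        b = _rotate_within(bins, runs, offsets)
        null[p], _ = _normalize(binned_power(power, b, n_bins))

    mu = null.mean(axis=0)
    sd = null.std(axis=0)
    sd = np.where(sd == 0, np.inf, sd)
    z_obs = (observed - mu) / sd
    z_null = (null - mu) / sd

    thresh = _null_z_threshold(z_null, alpha, cell_p_mode)
    null_masses = np.array(
        [_cluster_masses(z_null[p], thresh, circular=True)[1]
         for p in range(n_perm)]
    )
    raw_clusters, _ = _cluster_masses(z_obs, thresh, circular=True)
    clusters = [
        Cluster(cells, mass,
                float((1 + np.sum(null_masses >= mass)) / (n_perm + 1)), sign)
        for cells, mass, sign in raw_clusters
    ]
    return PermutationResult(
        observed=observed, z_map=z_obs, clusters=clusters,
        null_masses=null_masses, n_perm=n_perm, seed=seed, freqs=tfr.freqs,
        bin_edges=phase_bin_edges(n_bins), extras={"alpha": alpha},
    )


def cluster_perm_conditions(samples_a: np.ndarray, samples_b: np.ndarray,
                            paired_by_hemisphere: bool = True,
                            n_perm: int = 1000, seed: int | None = None,
                            alpha: float = 0.05, statistic: str = "mean",
                            cell_p_mode: str = "auto",
                            freqs: np.ndarray | None = None
                            ) -> PermutationResult:
    """Paired condition contrast of per-hemisphere spectra with sign-flip null.

    ``samples_a``/``samples_b`` are ``(n_hemispheres, n_freqs)``; the
    statistic per frequency is the mean paired difference (or the paired t
    with ``statistic='t'``).  The null flips the order of subtraction
    independently per hemisphere; clusters are contiguous frequency runs.
    """
    a = np.atleast_2d(np.asarray(samples_a, dtype=float))
    b = np.atleast_2d(np.asarray(samples_b, dtype=float))
    if a.shape != b.shape:
        raise ValueError(
            f"unpaired inputs: shapes {a.shape} and {b.shape} differ"
        )
    if not paired_by_hemisphere:
        raise NotImplementedError("only the paired contrast is implemented")
    if statistic not in ("mean", "t"):
        raise ValueError(f"statistic must be 'mean' or 't', got {statistic!r}")
    rng = np.random.default_rng(seed)
    d = a - b  # (H, F)
    n_h = d.shape[0]

    def stat(x):
        if statistic == "mean":
            return x.mean(axis=0)
        sd = x.std(axis=0, ddof=1)
        sd = np.where(sd == 0, np.inf, sd)
        return x.mean(axis=0) / (sd / np.sqrt(n_h))

    observed = stat(d)
    flips = rng.choice([-1.0, 1.0], size=(n_perm, n_h))
    null = np.stack([stat(d * f[:, None]) for f in flips])

    mu = null.mean(axis=0)
    sd = null.std(axis=0)
    sd = np.where(sd == 0, np.inf, sd)
    z_obs = (observed - mu) / sd
    z_null = (null - mu) / sd

    thresh = _null_z_threshold(z_null, alpha, cell_p_mode)
    null_masses = np.array(
        [_cluster_masses(z_null[p][None, :], thresh[None, :], circular=False)[1]
         for p in range(n_perm)]
    )
    raw_clusters, _ = _cluster_masses(z_obs[None, :], thresh[None, :],
                                      circular=False)
    clusters = [
        Cluster(cells, mass,
                float((1 + np.sum(null_masses >= mass)) / (n_perm + 1)), sign)
        for cells, mass, sign in raw_clusters
    ]
    return PermutationResult(
        observed=observed, z_map=z_obs, clusters=clusters,
        null_masses=null_masses, n_perm=n_perm, seed=seed, freqs=freqs,
        extras={"alpha": alpha, "statistic": statistic},
    )


# ---------------------------------------------------------------------------
# exact small-sample tests

def _signed_rank_distribution(ranks2: np.ndarray) -> np.ndarray:
    """Counts of the positive rank sum over all 2^n sign assignments.

    ``ranks2`` are the (tie-midrank) ranks doubled to integers; entry s of the
    returned array counts assignments with doubled positive rank sum s.
    """
    total = int(ranks2.sum())
    counts = np.zeros(total + 1, dtype=float)
    counts[0] = 1.0
    for r in ranks2:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: total + 1 - r]
        counts = counts + shifted
    return counts


def wilcoxon_exact(x, y) -> tuple[float, float]:
    """Exact two-sided Wilcoxon signed-rank test for paired samples.

    Zero differences are dropped; ties among |differences| take midranks.
    The two-sided p is computed from the exact distribution of the rank sum
    over all 2^n sign assignments; the reported W is the larger of the
    positive/negative rank sums.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must be paired (equal length)")
    d = x - y
    d = d[d != 0]
    n = len(d)
    if n == 0:
        raise ValueError("all paired differences are zero")
    if not 2 <= n <= 25:
        raise ValueError(f"exact enumeration supports 2 <= n <= 25, got n={n}")
    ranks = rankdata(np.abs(d))
    ranks2 = np.round(2 * ranks).astype(int)
    w_pos2 = int(ranks2[d > 0].sum())
    total2 = int(ranks2.sum())
    w_small2 = min(w_pos2, total2 - w_pos2)
    counts = _signed_rank_distribution(ranks2)
    p = min(1.0, 2.0 * counts[: w_small2 + 1].sum() / 2**n)
    W = max(w_pos2, total2 - w_pos2) / 2.0
    return W, float(p)


def spearman_exact(x, y) -> tuple[float, float]:
    """Exact two-sided Spearman correlation test by full rank-permutation enumeration.

    Supports 3 <= n <= 9 (n! grows too fast beyond); ties are handled with
    midranks, in which case rho is the Pearson correlation of the midrank
    vectors and the permutation distribution is computed on those vectors.
    Raises for n outside the supported range rather than silently
    approximating.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must be paired (equal length)")
    n = len(x)
    if not 3 <= n <= 9:
        raise ValueError(
            f"exact enumeration supports 3 <= n <= 9, got n={n}; "
            "use scipy.stats.spearmanr for larger samples"
        )
    rx = rankdata(x)
    ry = rankdata(y)
    rxc = rx - rx.mean()
    ryc = ry - ry.mean()
    denom = np.sqrt((rxc**2).sum() * (ryc**2).sum())
    if denom == 0:
        raise ValueError("constant input: rho is undefined")
    rho = float(rxc @ ryc / denom)
    perms = np.array(list(itertools.permutations(ryc)))
    rhos = perms @ rxc / denom
    p = float(np.mean(np.abs(rhos) >= abs(rho) - 1e-12))
    return rho, p
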