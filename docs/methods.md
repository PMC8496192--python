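# Methods

This note documents the models, conventions and numerical choices behind
`gaitmod`, in the order the pipeline runs them, and states what the
synthetic-data validation does and does not establish.

## Gait-phase convention

One full gait cycle of a given foot — lift → heel strike → next lift — maps
onto [−π, π). The heel strike (loading onset) carries phase 0; the lift
carries −π when it opens a cycle and +π when it closes it, so phase
increases strictly within each cycle. Between anchors, phase is linearly
interpolated: swing (lift → strike) spans [−π, 0], stance (strike → next
lift) spans [0, π]. Phase is therefore proportional to elapsed time within
each half-cycle, not to any kinematic quantity.

**Force-based reconstruction** takes the zero crossings of the 0.5–5 Hz
zero-phase bandpassed force trace: rising crossings are strikes, falling
crossings are lifts. Crossing positions are localized to sub-sample
precision by linear interpolation between the straddling samples; the
integer anchor in the cycle table is the nearest sample. Crossings closer
than 0.25 s (configurable) to the previous accepted crossing are merged, and
rising/falling alternation is enforced (first of a same-type run wins) —
both guards against sensor chatter. Samples outside complete
lift–strike–lift triplets are marked invalid and excluded from all averages.

**Accelerometer-based reconstruction** anchors cycles at local minima of the
x-axis trunk acceleration where the y-axis acceleration is increasing, with
phase running linearly −π → π between consecutive anchors. The strike is
not observable from the trunk, so the result is flagged
`strike_anchored=False` and its nominal phase 0 (the inter-anchor midpoint)
need not coincide with force-based phase 0. Downstream code treats the two
sources identically but the flag is preserved in metadata.

**Cycle regularity.** Per-cycle regularity is the absolute deviation of the
cycle duration from the mean duration; the 25% smallest deviations form the
"regular" group and the 25% largest the "less regular" group
(floor-rounded counts, ties broken by cycle order). Stepping variability is
the sample SD (ddof = 1) of the swing (foot-lifted) duration.

## Preprocessing

LFPs are re-referenced to adjacent-contact bipolar derivations (channel k =
contact k − contact k+1), which cancels common-mode and volume-conducted
components. LFP/EEG channels then pass a 48–52 Hz band-stop and a
0.5–250 Hz bandpass; force/accelerometer channels a 0.5–5 Hz bandpass. All
filters are Butterworth designs applied forward–backward (`sosfiltfilt`)
with reflect padding of three settle lengths (3·fs/f_low samples), so the
effective magnitude response is the squared design response and the phase
response is zero.

A stated "8th-order band filter" is interpreted as a transfer function of
order 8 (scipy `butter` with N = 4 for a band design) applied forward–
backward. Users who read the order as the prototype order can double the
`FilterSpec.order`. At reduced sampling rates the default chain adapts: the
bandpass upper edge becomes min(250, 0.9·fs/2) and the mains stop is skipped
when the Nyquist frequency is below it.

Manual artifact screening is out of scope; `flag_artifacts` provides an
amplitude-threshold surrogate (samples beyond 5 robust SDs on any channel).

## Time–frequency decomposition

Complex Morlet wavelets on a linear frequency grid, 1–95 Hz at 1 Hz step by
default (the grid step is configurable; coarse 2 Hz grids are used in some
simulations), with the number of cycles linearly spaced from 4 at the lowest
to 8 at the highest frequency. The implementation wraps
`mne.time_frequency.tfr_array_morlet` and rescales its L2-normalized
wavelets by π^(1/4)/(√(2π)·√σ_t) per frequency so that a unit-amplitude tone
produces the same power at every grid frequency (a flat tone response rather
than a flat noise response). Coefficients within half a wavelet support of
either signal edge are flagged and excluded from every average; because the
1 Hz/4-cycle wavelet is the widest, a shared all-frequency validity mask
(≈2 s at each edge) is used for phase binning.

PSDs are mean wavelet power over the analysis mask, normalized per channel
to sum to 100% over the 1–95 Hz grid. Imaginary coherence between two
channels is |Im G_xy| / √(G_xx·G_yy) with spectral densities estimated by
averaging products of wavelet coefficients over the mask; it is symmetric
in its arguments, bounded in [0, 1], and exactly zero for any real-scaled
copy of a signal (zero-lag coupling).

## Modulogram and modulation index

Per frequency, wavelet power is averaged within 18 half-open phase bins
[−π + k·2π/18, −π + (k+1)·2π/18); phase 0 is a bin edge. Two normalizations
coexist: bin means as a percentage of the across-bin mean (display and
cluster statistics; 100% = flat) and bin means divided by their sum (a
probability vector P, the MI input, guaranteed non-negative). The
modulation index is MI = D_KL(P, U)/log 18 with the 0·log 0 ≡ 0 convention;
it is 0 iff P is uniform, 1 iff P is a point mass, and invariant to overall
power gain. `max_mi` reports the argmax over a band (default 1–95 Hz), ties
broken toward the lower frequency.

Per-hemisphere and group aggregation follows channels → hemisphere → group
(arithmetic means at each level); the "strongest modulation" channel of a
hemisphere is selected by maximum MI by default, with maximum cluster mass
available as an alternative selector.

## Permutation statistics

**Within-cycle phase shuffling.** The null for modulogram inference cuts
each cycle's phase vector at an independently random point and swaps the two
segments — a circular rotation that preserves each cycle's phase multiset
and the power time series exactly, destroying only the phase–power
alignment. The observed map (percent-of-bin-mean units) is z-scored
cell-wise by the permutation mean and SD; cells beyond the two-sided
precluster threshold (p < 0.05) are clustered by 4-connectivity in the
frequency × bin grid with the bin axis circular (bin 18 adjacent to bin 1,
matching phase periodicity); positive and negative excursions cluster
separately. A cluster's mass is |Σz|, and its p value is the fraction of
permutations whose maximal cluster mass reaches it (with the +1
correction). The precluster threshold comes from the per-cell empirical
null quantile when n_perm ≥ 500 and from the Gaussian tail otherwise; both
modes are selectable.

**Condition contrasts.** Paired per-hemisphere spectra are compared by the
mean paired difference per frequency (a paired t statistic is available),
with a null of independent per-hemisphere sign flips and clusters over
contiguous frequencies.

**Exact tests.** The Wilcoxon signed-rank p value is two-sided and exact:
the distribution of the positive rank sum over all 2^n sign assignments is
built by dynamic programming over (tie-midrank, doubled-to-integer) ranks —
equivalent to full enumeration — and p = min(1, 2·P(T ≤ min(T⁺, T⁻))). Zero
differences are dropped; the reported W is the larger rank sum. The Spearman
p value enumerates all n! rank permutations (supported for 3 ≤ n ≤ 9;
larger n raise rather than silently approximate); with ties, rho is the
Pearson correlation of midrank vectors and the enumeration runs on those
vectors.

## State analysis

The AR-HMM observation model is x_t | s_t = k ~ N(Σ_l A_{k,l} x_{t−l} + b_k,
Σ_k) with lag order 3 at 256 Hz (≈12 ms of history, enough to express
distinct spectral resonances below Nyquist; configurable). Channels are
standardized to unit variance before fitting, since pooled bipolar channels
have incommensurate gains. Fitting is maximum-likelihood EM: the
forward–backward/Viterbi machinery comes from `hmmlearn`, while the M step
(per-state weighted least squares with ridge regularization 1e-6 and
symmetrized residual covariance) is implemented here. Initialization draws
Dirichlet responsibilities from the seeded RNG and applies one M step;
per-iteration log-likelihood is recorded and is non-decreasing (asserted in
tests). The state cap defaults to 30 with hard Viterbi assignment; states
whose occupancy falls below 1e-6 are pruned and the sequence relabeled.
This is a deliberate simplification of variational-Bayes AR-HMM toolboxes —
no automatic complexity control beyond the cap and pruning — and its
validation rests on synthetic recovery, not on matching any toolbox.

State–phase association uses 100-bin occupancy histograms over [−π, π)
(uniform reference 1%/bin), a one-sample Kolmogorov–Smirnov test of each
state's phase sample against uniformity, and PAM-style K-medoids (k = 3,
Euclidean distance, k-medoids++ seeding, exact per-cluster medoid updates)
written in this package because no maintained K-medoids implementation is
available in the supported dependency set.

## Synthetic sessions: what they emulate, and what they do not

The generator plants, per LFP contact and configured band, a unit-RMS
band-limited Gaussian carrier multiplied by 1 + depth·cos(phase − φ₀), on
top of 1/f^α background noise (spectral shaping of white noise, α = 1
default), a common-mode 1/f component shared identically across contacts,
and a contact-dependent gain gradient (1 + 0.2·i) so the planted rhythm
survives bipolar derivation. EEG channels carry their own 1/f noise plus a
delayed (25 ms), scaled copy of the oscillatory source, giving nonzero
imaginary coherence. Cycle durations are cycle_period + N(0, jitter²)
truncated (by redraw) to > half the nominal period; the right foot is the
left foot shifted by half a cycle.

The force trace is a signed sinusoid of gait phase — positive while the
foot is loaded, negative in swing — plus sensor noise. A half-rectified
(physically non-negative) force was considered and rejected: removing its
DC component, as the 0.5–5 Hz bandpass necessarily does, shifts the zero
crossings ≈0.33 rad away from the strike/lift events, which would build a
systematic bias into any ground-truth comparison. The signed shape keeps
the bandpassed crossings exactly at the anchors; real force plates sit
between these idealizations, so phase-reconstruction accuracy on real data
should be expected between the generator's (≈0.005 rad RMS) and the
bin-width scale. Accelerometer traces are cos(phase) on x (one minimum per
cycle at ±π), −sin(phase) on y (increasing at the anchor), noise on z.

Defaults not fixed by the emulated protocol are free parameters chosen once
at plausible values and documented as such: modulation depth 0.4 in the
alpha (8–12 Hz) and beta (13–30 Hz) bands at preferred phase 0, oscillation
and noise amplitudes 1.0 (in-band SNR well above real recordings), cycle
jitter SD 0.05 s, sensor noise SD 0.02. The generator does not model
biomechanical gait dynamics, freezing episodes, EMG, movement artifacts, or
nonstationary carrier spectra; passing the synthetic benchmarks therefore
demonstrates correctness of the estimators under the assumed signal model,
not robustness to real-data pathologies.

## Simulation sizes and numerical choices

Validation simulations run at 256 Hz (the state-analysis rate; the hardware
rate of the emulated amplifier is 2048 Hz and remains the generator
default), with wavelet coefficients decimated 8–16× before phase binning —
the binned envelope bandwidth is far below even the decimated rate. The
benchmark suite uses: 20 sessions of ~100 cycles for parameter recovery
(planted depth 0.8 at 20–25 Hz, phase 0); 200 unmodulated sessions of ~50
cycles at 200 permutations each for the family-wise error rate; 60 s
two-channel simulations for AR-HMM recovery (two AR(2) regimes at 8 and
35 Hz, pole radius 0.97, 0.5 s Markov dwell, state cap 4). These sizes keep
every benchmark re-runnable in minutes on one core; the measured properties
(recovery, calibration, closed-form identities) are invariant to the grid
density and sampling rate.

Phase-recovery success in the benchmark is defined at the resolution the
18-bin histogram affords: the planted preferred phase 0 lies exactly on a
bin edge, so the peak bin is accepted when it touches phase 0 (center
within one bin width). Degenerate inputs raise informative errors rather
than propagating: empty phase bins (listing the bins), constant force
traces, fewer than 2 cycles for variability, fewer histograms than medoids,
all-zero Wilcoxon differences.

## Known limitations

- The accelerometer path has no strike anchor; modulograms built on it have
  a phase origin offset of unknown sign relative to force-based ones.
- The cluster permutation test's Gaussian precluster mode (used for
  n_perm < 500) assumes approximate normality of the cell-wise permutation
  distribution; the empirical mode removes the assumption at the cost of
  more permutations.
- The AR-HMM likelihood surface is multimodal; different seeds can yield
  different segmentations of weakly separated regimes. Occupancy-based
  pruning does not substitute for principled model selection.
- Exact Spearman enumeration is limited to n ≤ 9; larger cohorts should use
  asymptotic methods.
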