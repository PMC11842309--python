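# Methods

This note documents the models and procedures implemented in `rwefc`, the
defaults and why they were chosen, what the synthetic cohorts do and do not
emulate, and the package's known limitations.

## Signal model and preprocessing

Input recordings are channel × sample matrices in microvolts at 500 Hz with
the eight 10-10 electrodes F7, T7, CP3, P5, F8, T8, CP4, P6 (that fixed
order is the contract every downstream feature index depends on). The
preprocessing chain is:

1. **Channel selection** to the canonical eight (extra channels from denser
   montages are dropped).
2. **Mean subtraction** per channel.
3. **Butterworth cascade**, each filter 5th order and applied
   forward-backward (`sosfiltfilt`): 0.5 Hz high-pass, 100 Hz low-pass,
   band-stop at the powerline frequency and its first two harmonics, ±2 Hz
   half-width. Zero-phase application was chosen because connectivity
   compares channels; causal filtering would add a frequency-dependent phase
   common to all channels but would distort epoch boundaries differently
   from the analysis this mirrors. It doubles the effective order and
   attenuation (the 20 dB notch requirement is met with a wide margin).
   Band-stop half-width and order are configurable (`FilterSpec`).
4. **Conditional linear detrend.** A channel is detrended when the fitted
   line's total excursion exceeds 3× the residual standard deviation
   (`auto`, the default; `always`/`never` are available). The trigger runs
   *after* filtering: the high-pass removes most drift, and detrending is a
   fallback for the residual case. The threshold of 3 residual SDs makes
   the trigger insensitive to oscillatory content while catching drifts
   that would bias epoch statistics.
5. **Common average reference** (instantaneous cross-channel mean removed).
6. **Epoching** into non-overlapping 8.192 s segments (4096 samples at
   500 Hz; the power-of-two length is what makes the depth-6 wavelet-packet
   decomposition exact). The trailing partial epoch is discarded;
   overlapping epochs are deliberately not offered, to keep epoch counts
   and participant votes independent.

Units do not matter: every feature is a ratio or an entropy of energies, and
a scale-invariance test (gain 137× and 250×) enforces this to 1e-6.

## Band energies and Relative Wavelet Entropy

Rhythms: delta 0.5–4, theta 4–8, alpha 8–12, beta 12–20, gamma 20–50 Hz.
Two interchangeable band-energy backends:

* **Wavelet backend (default):** wavelet-packet decomposition, Daubechies-4,
  depth 6. At 500 Hz the 64 terminal nodes nominally cover ≈3.906 Hz each;
  band energy is the sum of squared coefficients of the frequency-ordered
  (Gray-code) terminal nodes, with bins straddling a band edge weighted by
  fractional overlap. db4/depth-6 balances temporal support (4096 samples)
  against frequency selectivity; its leakage between neighboring bins is
  real (a pure 10 Hz sine puts ≈74 % of its energy in alpha rather than
  ≈99 %), which is why the second backend exists.
* **Bandpass backend:** 5th-order zero-phase Butterworth band-pass per
  rhythm, summing squared samples. It serves as the independent cross-check:
  on broadband epochs the two backends' relative distributions agree to a
  mean absolute difference below 0.05 (tested), and all group-contrast
  information used downstream lives at that broadband scale.

Each channel's five band energies are normalized over their five-band total,
giving a proper probability vector (normalizing over total broadband power
would leave the vectors summing below one and break the divergence). The
**RWE** between channels a and b is the Kullback–Leibler divergence
`Σ_j p_j(a) ln(p_j(a)/p_j(b))` with natural logarithm, `0·ln(0/x) = 0`, and
the comparison distribution floored at `ε = 1e-12` and renormalized so that
narrowband inputs cannot produce infinities. Convention (frozen in the
feature-ordering contract): row = reference electrode (the "true"
distribution), column = comparison electrode. The diagonal is fixed at 0;
the 56 off-diagonal entries are flattened row-major as features f001–f056.

## Graph metrics

The non-symmetric RWE matrix W is symmetrized by averaging into a distance
matrix `D = (W + Wᵀ)/2` and inverted into a similarity
`S = 1 − D / max(D)` (off-diagonal maximum; zero diagonal; all-zero W maps
to all-zero S). Strength-type metrics use S; path-type metrics use D
directly as edge length — a deliberate split: clustering and density need
"how connected", paths need "how far".

* **Clustering coefficient** per node: geometric-mean-of-triangle-weights
  formulation on S, `c_u = Σ_{v<w}(ŵ_uv ŵ_uw ŵ_vw)^{1/3} · 2/(k_u(k_u−1))`.
  S is already normalized to [0, 1], so no further max-weight rescaling is
  applied (library implementations that rescale by the graph-wide maximum
  would silently change S). Verified against literal triangle enumeration.
* **Characteristic path length**: mean shortest-path distance on D over the
  28 unordered pairs (mean rather than sum, for scale stability across
  epochs); Floyd–Warshall, verified against exhaustive simple-path
  enumeration and `scipy.sparse.csgraph`.
* **Path efficiency**: mean inverse shortest-path distance; zero-length
  paths capped at 1/ε.
* **Connection density**: fraction of pairs with similarity above τ.
  τ defaults to the epoch's own median off-diagonal similarity — the paper
  leaves the threshold open, and an epoch-relative τ makes the density a
  shape statistic (≈0.5 at baseline) rather than an arbitrary absolute cut.
* **Small-world index**: `(CC/CC_rand)/(CPL/CPL_rand)` against `n_random =
  20` null graphs obtained by shuffling the off-diagonal weight multiset of
  S (and correspondingly D) with a seeded generator — "random graphs of the
  same size" with the weight multiset preserved. The index is deterministic
  given a seed and invariant to node relabeling only in expectation; per-
  epoch seeds are derived stably from (run seed, participant, epoch index).

Hemispheric aggregates LMC/RMC/IMC are means of raw W over the 12 ordered
within-left, 12 within-right, and 32 cross-hemisphere pairs. They are
computed on the raw RWE scale; published group tables of these quantities
use an unknown normalization, so only orderings, not magnitudes, are
meaningful comparisons.

## Feature vector

113 = 56 FC + 12 graph (CC ×8 in canonical channel order, CPL, CPE, CD, SW)
+ 45 energy ratios (whole-EEG δ…γ, then five per electrode in canonical
order). Column ids f001–f113 with a machine-readable name map
(`feature_map.json`).

## Classification

* **Split**: participant-stratified, seeded. For the source-study layout
  (8/8/14 participants) the published 6/5/10 train counts are used;
  otherwise `round(0.7·n)` clipped to leave at least one participant per
  side. All epochs follow their participant, making epoch-level leakage
  structurally impossible (asserted in tests).
* **Normalization**: per-feature min-max to [0, 1] fitted on training
  epochs only; test values clipped; constant features map to 0.
* **Classifiers**: k-NN (k ∈ {1, 3, 101}; cityblock, euclidean, cosine
  where cosine distance = 1 − cosine similarity) and SVM (linear;
  polynomial `(x·y + 1)^d`, d ∈ {3, 11}; RBF with
  `K = exp(−‖x−y‖²/(2σ²))`, σ ∈ {1e-5, 0.7, 1.1, 1.38}; box constraint
  C ∈ {1, 10}; multiclass one-vs-one). Grid entries infeasible on a given
  split (k exceeding the training size) are skipped and logged.
* **Majority vote**: each participant receives the modal epoch label. Ties
  break by the larger mean classifier score over the tied classes, then by
  canonical order HC < MCI < PPA; tied participants are flagged in the
  report, never silent.
* **Grid search** ranks by test participant accuracy, then test epoch
  accuracy. This reproduces the published protocol of tuning on the test
  set — a known leakage caveat, kept deliberately and logged on every
  evaluation. For honest selection, pass a nested split of the training
  participants to the same functions.
* **C4.5 ranking**: exhaustive midpoint search per feature, gain-ratio
  selection (ties → lower threshold, then lower feature index), growth
  until purity or zero gain, pessimistic pruning at confidence 0.25
  (a subtree collapses when the parent's upper-bound error estimate does
  not exceed the children's combined estimate). Rank value =
  `1/(1 + first-use depth)`, min-max normalized so the root feature scores
  1 and unused features 0; ties within a depth tier break by total
  sample-weighted gain. The depth-based rank value is a documented
  surrogate — only orderings are asserted, not magnitudes.

## Synthetic cohorts

The generator emulates the *conditions* of the source cohorts: 8 HC, 8 MCI,
14 PPA; recording lengths uniform in 120–240 s; 500 Hz; powerline 50 Hz for
PPA and 60 Hz for HC/MCI (the two recording sites differ, which is exactly
the heterogeneous-source concern the notch stage must handle per group).
Each channel sums: per-rhythm band-limited noise weighted by the group's
band profile, shared band-limited sources coupling channel sets (coupling is
*shared additive energy*, the direct mechanism by which RWE drops between
channels — not lagged dependence, which RWE cannot see), a 1/f background
(exponent 1.0; amplitudes keep every band above ~1 % of total so the KL
never leans on the ε floor), a common-mode powerline sine, a per-channel
random linear drift (peak 40 µV) and DC offset (±50 µV).

Group contrasts (chosen once, strong enough to be recoverable, making no
claim of clinical magnitudes): HC balanced band profile with mild global
coupling; MCI strong coupling on the four homologous cross-hemisphere pairs
and weakened within-hemisphere coupling; PPA strong left-hemisphere (and
moderate right-hemisphere) coupling, elevated delta, reduced alpha
(strongest over the left). The `effect` dial linearly interpolates every
group toward the HC profile: at `none` the groups are statistically
identical *including* a common 60 Hz powerline — otherwise the PPA-specific
50 Hz notch would leave a genuine gamma-band footprint and keep null cohorts
classifiable above chance.

What passing tests do **not** show: these cohorts contain no artifacts
(ocular, muscle, electrode pops), no non-stationarity beyond drift, no
within-group clinical heterogeneity (PPA variants, MCI subtypes), and their
group contrasts are far cleaner than clinical EEG. Recovery results on them
validate the pipeline's mechanics, not clinical accuracy.

## Numerical and testing choices

* Chance-level control: the grid maximum over 23 specs selected on ≤9 test
  participants is far above chance even on null data (selection bias by
  construction), so the zero-effect guard uses a fixed classifier
  (k-NN k=1 cityblock) and pools three seeds × three pairwise comparisons;
  pooled means must sit within 15 points of 50 % (pairwise) and 33.3 %
  (three-way).
* End-to-end recovery is asserted on five seeded default cohorts (majority
  must reach ≥90 % pairwise / ≥70 % three-way held-out participant
  accuracy); the test suite memoizes one pipeline run per seed.
* Problem sizes in the suite: full-size cohorts (30 participants, ~600
  epochs) for recovery; reduced cohorts (2–6 participants, 30–120 s
  recordings) for mechanics-only tests.
* Degenerate inputs: zero-energy channels raise (named channel); an
  all-zero connectivity matrix yields an all-zero similarity and an
  undefined small-world index (error), as does any graph with zero mean
  clustering in the null ensemble.

## Limitations

* The wavelet backend's band leakage (db4, depth 6) biases narrowband
  energy shares toward neighbors; distributions remain comparable because
  every channel is affected identically.
* Gamma (20–50 Hz) overlaps the 50 Hz notch for 50 Hz-powerline recordings;
  notched energy is simply absent from gamma for those groups.
* Test-set model selection (inherited protocol) inflates grid-best
  accuracies; treat reported grid maxima accordingly.
* ICA, phase-based connectivity (PLV, coherence), source localization and
  statistical group comparison of per-group feature values are out of
  scope.
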