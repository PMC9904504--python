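# Methods

## The measure

Active information storage (AIS) quantifies how much of a process's next
sample is predictable from its own past:

    AIS(Y_t) = I(Y_t ; Y_<t),      Y_<t = (Y_{t-d_1}, ..., Y_{t-d_k})

in nats, where the past state `Y_<t` is a vector of selected past lags.
A memoryless process stores nothing; an oscillation or a long-memory
process stores much.  AIS is a *time-domain* quantity: it says nothing
about which rhythm or frequency band generates the predictability.

The spectral decomposition implemented here answers that question by
destruction: scramble the signal's content in one frequency band only,
and see whether the storage drops.

## The spectral test

1. Transform each trial with the maximal-overlap discrete wavelet
   transform (MODWT, least-asymmetric filter of length 8 by default,
   circular boundary).  Scale `j` represents the nominal band
   `(fs/2^(j+1), fs/2^j)` Hz; the transform is non-decimated, exactly
   invertible and energy-preserving.
2. Randomize the detail coefficients of the scale under test — by
   permuting randomly cut contiguous blocks (default) or by IAAFT —
   leaving every other scale untouched.
3. Rebuild a time-domain surrogate with the inverse transform.  The
   surrogate differs from the original only in the target band.
4. Re-estimate the storage with the *present values from the original*
   signal and the *past states from the surrogate*, with the embedding
   held fixed.  Repeat S times per scale.
5. The one-sided add-one permutation p-value per scale is
   `p_j = (1 + #{AIS'_j >= AIS}) / (1 + S)`; each scale is tested at the
   Bonferroni-corrected level `alpha / J0`.  The per-scale contribution
   is `delta_j = AIS - median(AIS'_j)`; only positive values indicate a
   contribution.  The scale with the maximal drop is reported as a
   separate field.

Because the wavelet filtering acts only on the surrogate side, any bias
it introduces *raises* the surrogate estimates and can never produce a
spurious significant drop: the test errs conservative.  The converse
effect — spectral leakage — is discussed under "Known limitations".

The spectral stage is gated on a significant time-domain AIS by default
(`require_significant_ais`); calibration studies can override the gate.

## Embedding selection

The past state is selected greedily from candidate lags `1..k_max`
(default 20 samples): at each step, the candidate maximizing the
conditional mutual information with the present, given the already
selected lags, is admitted only if it beats the maximum-statistic
permutation distribution (every remaining candidate shuffled in time
within trials, maximum CMI taken per permutation) at `alpha = 0.05`.
The maximum over candidates controls the family-wise error of the
selection, so a memoryless process receives an empty embedding at rate
about alpha.  Ties break to the smaller lag.

Selection operates on a pooled sample capped at 10 000 (present,
candidate) pairs, taken with an even temporal stride inside trials; the
full pool is always used for the reported estimates.  The cap is a
design choice: with ~10^5 pooled samples every minuscule CMI becomes
detectable and the selected embedding grows toward `k_max`, which adds
cost without changing which bands are detected.

For multi-condition comparisons the union-embedding protocol applies:
select per condition (optionally per trial), take the union of the lag
sets, and re-estimate every condition with that one embedding so the
estimation bias is equalized across conditions.

## Estimators

* `gaussian` (default): covariance-determinant closed form; exact for
  jointly Gaussian data, measures linear predictability otherwise;
  non-negative; fast enough for 10^3-10^4 surrogate evaluations.  The
  surrogate loop uses an algebraically identical fused implementation
  (Gram products + a Schur complement) validated against the covariance
  route to 1e-13.
* `ksg`: Kraskov-Stoegbauer-Grassberger k-nearest-neighbour estimator
  (algorithm 1; conditional variant of Frenzel-Pompe), Chebyshev metric,
  `k = 4` neighbours.  Consistent for nonlinear dependence; slightly
  negative small-sample values are possible.  Pools larger than
  `max_samples_ksg` (default 2000) are subsampled with an even stride;
  inside embedding selection a coarser cap (800 points, 50 permutations)
  keeps the thousands of neighbour searches tractable.

Singular covariances are regularized with a 1e-10 ridge and a warning.

## Surrogate construction details

Block permutation cuts each trial's coefficient sequence at randomly
drawn positions into `ceil(N / block_len)` blocks (default mean length
`N/20`) and permutes them.  Random cut positions matter: a fixed block
grid whose length is an integer multiple of an oscillation's period
reorders identical-phase segments and destroys nothing — at fs = 120 Hz
with N = 1200, the fixed default grid of 60 samples contains exactly 25
cycles of 50 Hz and 6 cycles of 12 Hz, a degenerate configuration that
random cuts avoid for every frequency.

IAAFT iterates amplitude-spectrum matching and rank-remapping onto the
original coefficient values (cap 100 iterations, early stop below 1e-8
RMS spectrum change).  Note that IAAFT preserves spectral lines, hence
also the linear predictability of strictly periodic content; it is the
right tool for broadband signals, while block permutation is the
default for rhythm-dominated data.

Trials are always scrambled independently.  Because the inverse MODWT
is linear, a surrogate is computed as
`x + synth_j(scramble(W_j) - W_j)`, one FFT pair per draw instead of a
full inverse pyramid; an identity permutation therefore returns the
original signal bit-exactly.

## Simulators and the conditions they emulate

* White noise: the storage-free null.  Null-calibration runs use 10
  trials of 10 s at 120 Hz per repetition.
* Two sinusoids, 50 Hz + 12 Hz at fs = 120 Hz, 10 s, 50 trials, random
  phase per trial, Gaussian noise floor SD 0.1 (a nonzero floor is
  required by continuous estimators).  Ground truth: storage in scales
  1 and 3, none generated in scale 2.
* ARFIMA: AR(2) with conjugate poles of modulus p = 0.98 at 50 Hz
  (`A1 = 2 p cos(2 pi f1 / fs)`, `A2 = -p^2`; the oscillation argument
  is in cycles/sample so the resonance lands at 50 Hz at fs = 120),
  driven by fractionally integrated unit Gaussian noise of order
  d = 0.3 via FFT-based fast fractional differencing; 10 s, 100 trials,
  2000-sample burn-in.  Ground truth: dominant storage in scale 1.
* Delay-coupled Roessler pair (a = 0.15, b = 0.2, c = 10; natural
  frequencies w1 = 0.8, w2 = 0.9; unidirectional coupling eps = 0.07
  into the first oscillator with a 2-step delay), integrated with
  fixed-step RK4, only x1 observed, relative observation noise SD 0.1.
  The integration step (0.1257 model-time units per 1/500 s sample) was
  calibrated once so the x1 rhythm lands near 8 Hz at fs = 500 Hz — the
  system itself fixes only the dimensionless frequencies, so the
  model-time-to-seconds mapping is a free constant; the printed
  spectral peak is the anchor.  Scaled-down analyses use 10 trials of
  4 s, 100 surrogates and a 1000-point ksg subsample.
* Burst trio: (i) 6-12 Hann-windowed three-cycle 10 Hz packets at random
  positions and phases on unit Gaussian noise, (ii) one such packet in
  the final fifth of a noise series, (iii) a sinusoid with per-signal
  frequency uniform in 8-15 Hz plus noise (SD 0.5) — all scaled to the
  same mean 8-15 Hz Welch band power.  Matched power, very different
  predictability: the storage measure separates them, band power does
  not.

All generators are seeded and bit-reproducible.  What these simulations
do *not* emulate: nonstationarity across trials, 1/f backgrounds,
recording artifacts, or volume-conducted mixtures — passing them shows
correct band attribution and calibration for stationary trial
ensembles, not robustness to real-recording pathologies.

## Numerical choices

* p-values always use the add-one formula; `p` is never 0 and the
  minimum surrogate count `S >= J0/alpha - 1` is enforced.
* An empty embedding defines AIS = 0 with p = 1 (I(Y_t; {}) = 0).
* MODWT levels default to `min(floor(log2 N), 6)`; at fs = 120 the
  lowest tested band is then 0.94-1.88 Hz.
* The full analysis is bit-reproducible from (data, parameters, seed).

## Known limitations

* Spectral leakage: wavelet bands overlap, so a strong rhythm near a
  band edge leaks into the neighbouring scale, and the leaked
  component's contribution is destroyed together with that scale's own
  content.  With a low noise floor this produces a *consistent* small
  drop on the adjacent scale which the permutation test — sensitive to
  any consistent drop, however small — flags as significant.  In the
  two-sinusoid design the 12 Hz tone (0.8 of the way through the scale-3
  band) leaks into scale 2 with squared gain 0.19 (LA8; 0.11 for LA16),
  and scale 2 is flagged alongside the true scales 1 and 3.  This is why
  the maximal-drop scale is reported separately: the drop *ordering*
  reliably reflects the generating band (deltas 1.87 / 0.55 / 1.84 at
  scales 1/2/3 in that design), while per-scale significance should be
  read as "contains storage-bearing content", which for leak-adjacent
  scales is literally true of the filtered signal.
* Null calibration is at the family level, not zero: every finite
  realization of even a storage-free process has a nonzero in-sample
  alignment between the present and each band's past content, and
  scrambling a band removes the realized alignment.  For the roughly
  alpha fraction of datasets in which some band's realized alignment is
  extreme, the drop is consistent across scrambles and is flagged.
  Measured on white noise: ~4% family-wise false positives at
  alpha = 0.05 with the gaussian estimator — calibrated, but not the
  near-zero rate a noisier estimator exhibits, because per-evaluation
  estimator noise (e.g. the ksg estimator's) otherwise swamps these
  O(1e-4 nat) in-sample effects.
* Block length trades destruction sharpness against preserved local
  statistics; very long blocks destroy too little (drops vanish), very
  short ones approach sample-wise shuffling.
* The gaussian estimator misses purely nonlinear storage; the ksg
  estimator's permutation loops are expensive and its subsample caps
  bound the detectable effect size.
* Circular (periodic) boundary handling wraps trial edges; for trials
  much longer than the largest filter width (L_j = (2^j-1)(L-1)+1) the
  effect is negligible, but very short trials at deep scales inherit
  wrap-around artifacts.
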