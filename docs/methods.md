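# Methods

## The measurement being modeled

In diffusion-based spFRET, doubly-labeled mononucleosomes at picomolar
concentration transit a confocal detection volume one at a time. Each transit
produces a burst of photons split between a donor (Cy3) and an acceptor (Cy5)
detection channel. Conformation is read out per burst through the proximity
ratio

    E_PR = (I_a − l·I_d) / (I_a + (1 − l)·I_d),      l = 0.19,

where `I_a` and `I_d` are background-corrected channel intensities and `l`
is the spectral crosstalk — the fraction of donor fluorescence detected in
the acceptor channel for this dye/filter combination. `E_PR` is not corrected
for the gamma factor or acceptor direct excitation, so it is a proximity
ratio, not an absolute FRET efficiency; under shot noise it can fall slightly
outside [0, 1], and for non-negative intensities it is confined to
[−l/(1−l), 1] ≈ [−0.235, 1].

The identity `I_a + (1−l)·I_d = (I_a − l·I_d) + I_d` makes the ratio the
exact algebraic inverse of the forward leakage `I_a ← I_a* + l·I_d*`. This
exactness is the package's central internal oracle: analysis of noiseless
simulated bursts must return the generative FRET efficiency to machine
precision, which couples the simulator and the analyzer without reference to
any external data.

## Forward burst model

Per burst: (1) a species (LF = unfolded, HF = folded) is drawn by mixture
weight; (2) a total signal photon count N is drawn from a lognormal whose
mean equals the species brightness, then rounded; (3) the ideal split is
A* = E·N, D* = (1−E)·N; (4) detection applies crosstalk, adds per-channel
background, and Poisson shot noise:

    I_a ~ Poisson(A* + l·D* + b_a),    I_d ~ Poisson(D* + b_d).

A noiseless mode replaces every random draw by its mean and is used by the
oracle tests. All randomness flows from one integer seed per sample
(`numpy.random.default_rng`); the same specification always yields a
byte-identical burst table.

The lognormal burst-size law (σ_log = 0.4) mimics the broad brightness
distribution produced by variable diffusion paths through the Gaussian
detection volume; it mainly widens the tails of the burst-size distribution
while leaving E_PR peak positions unchanged, since E_PR is a ratio.

**What the simulator does not emulate:** photon-by-photon arrival times,
diffusion kinetics and burst-search artifacts, photobleaching and blinking,
acceptor dark states, gamma-factor miscalibration, acceptor direct
excitation, or within-burst conformational dynamics. Passing recovery tests
therefore demonstrate that the analysis chain is unbiased for data that
match its own generative assumptions — not that real measurements are free
of the instrument effects listed above.

## Parameters, units, defaults

| parameter | unit | default | rationale |
|---|---|---|---|
| crosstalk `l` | — | 0.19 | leakage for the Cy3/Cy5 filter set; the complement 0.81 is always derived, never free |
| E_LF, E_HF | — | 0.15, 0.70 | generator defaults giving well-separated peaks; the true peak positions of the measurement are not encoded as ground truth |
| brightness | photons/burst | 100 | typical detected burst size in diffusion spFRET |
| σ_log | — | 0.4 | lognormal burst-size spread (diffusion-path variability) |
| background b_d, b_a | photons/burst | 2 | small per-channel background typical after burst selection |
| n_bursts | — | 4000 | within the hundreds-to-thousands of signals per measured sample |
| min_total | photons | 30 | burst-selection floor, standard burst-search practice; keeps shot-noise peak widths realistic |
| bin width | E_PR | 0.05 | smooth histograms at thousands of bursts |
| histogram range | E_PR | [−0.25, 1.25] | covers the attainable range including the negative crosstalk bound |
| bootstrap resamples | — | 2000 | stable 95% percentile intervals |
| replicates | — | 3 | independent experiments for mean ± SEM |

Condition-ladder folded-state weights (nucleosome 0.85, +FACT 0.85, +CBL0137
0.75, +FACT+CBL0137 0.25, +competitor chase 0.75) encode only the qualitative
ordering of the unfolding experiment — no change with chaperone alone, minor
unfolding with curaxin alone, a profound transition with both, largely
reversed by competitor DNA. They are package defaults, not measured values.
The competitor reversal is modeled purely as a change of species weights:
the readout is an equilibrium population, and the generator has no kinetics.

## Analysis chain and numerical choices

1. **Background correction** subtracts a scalar per-channel mean (from config
   or a calibration table). Intensities may go negative; a flag on the table
   prevents accidental double correction.
2. **Burst selection** keeps bursts with a positive E_PR denominator and
   total signal ≥ `min_total`; rejected bursts go to a sidecar table with a
   reason column. Invalid bursts never become silent NaNs downstream.
3. **Histogramming** produces a relative frequency distribution; values
   outside the range are clipped into the end bins (and logged) so every
   burst contributes to the normalization.
4. **Two-Gaussian fit** is unweighted nonlinear least squares (lmfit,
   trust-region under the hood) on the binned curve at bin centers — the
   curve-fitting workflow traditional for this analysis; a per-bin
   shot-noise weighting is available as a flag. Initial means sit on the two
   most separated prominent maxima of a lightly smoothed histogram (single
   mode: the mode plus the far 15%/85% mass quantile); initial widths are
   0.08. Bounds: means inside the histogram range, widths in [bin/2, full
   range], amplitudes in [0, 2·max frequency]. On failure the fit restarts
   up to 5 times from seeded jittered values; persistent failure raises an
   explicit error. Peaks are relabeled after fitting so mean_LF < mean_HF.
5. **Degenerate fits.** If the two means collapse within one bin width the
   result is flagged and the single peak is reported as HF when its mean
   lies above the histogram midpoint, LF otherwise; a width stuck at its
   bound also flags the fit. Fractions always sum to 1 by construction
   (areas normalized to their sum).
6. **Replicate summary.** SEM uses the sample (n−1) standard deviation over
   √n and is reported as NaN — undefined, never zero — for one replicate.
7. **Seeding.** Replicate seeds derive as `base_seed + 1000·condition_index
   + replicate_index`, giving reproducible, non-overlapping streams.

## Census statistics

Integer percentages use largest-remainder (Hamilton) rounding — floor the
proportional shares, then assign leftover points to the largest fractional
remainders, ties broken by category order — so printed triples always total
exactly 100 (e.g. 2:1:1.6 → 43/22/35). Confidence intervals are seeded
percentile bootstrap over particles (multinomial resampling of the observed
fractions, 2000 resamples); Wilson intervals (statsmodels) are available for
two-category tallies. Pooling categories sums raw counts first, so pooled
percentages are consistent with pooling before or after normalization
(43:22:35 with compact+closed pooled gives 35:65).

## Validation design

- **Exactness:** crosstalk inversion on noiseless bursts across an
  efficiency grid, to machine precision.
- **Unbiasedness:** mean per-burst E_PR of a bright species (≥500 photons,
  no background) within 0.01 of the true efficiency over 10⁴ bursts.
- **Recovery:** 3 replicates × 4000 bursts at true unfolded weights 0.15,
  0.25, 0.50, 0.75, 0.85 with default noise; the estimated mean LF fraction
  must lie within 0.05 of truth at every point and increase monotonically.
  These problem sizes match the package's default study conditions.
- **Ordering:** the chaperone+curaxin condition must show the largest
  unfolded fraction of the ladder, and the competitor chase must return to
  within 0.1 of the curaxin-only condition.
- **Calibration:** 95% bootstrap CIs cover true multinomial proportions
  (p = 0.43/0.22/0.35, n = 1000) in 93–97% of 500 simulated datasets.

## Known limitations

- Two states only: no three-state or dynamic (within-burst switching)
  models; strongly overlapping peaks make area partitioning ill-conditioned.
- Binned least squares is the reference method; there is no unbinned
  likelihood mixture mode.
- The background estimator is a scalar channel mean supplied by the caller,
  not inferred from the data.
- The burst-selection threshold is a declared analysis choice; results for
  dim samples depend on it.
- Generator realism limits are listed under the forward model above; in
  particular, agreement with the simulator does not certify gamma-related
  absolute accuracy of E_PR on real instruments.
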