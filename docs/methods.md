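# Methods

## Scope and data model

`cbhkin` analyses single-molecule fluorescence experiments on processive
cellulases bound to surface-deposited crystalline cellulose microfibrils.
The pipeline starts from localized data — an event table (fibril id, bind
time, unbind time, end cause), a trajectory table (track id, frame, time,
x, y in nm) and a fibril table (id, length, endpoints, bundle count) — not
from raw movies; spot detection and localization are upstream concerns.
A bulk-assay table (substrate concentration, hydrolysis rate) feeds the
Michaelis–Menten fit.

## Binding (on-rate) analysis

Each fibril's binding rate constant is the number of observed arrivals
normalized by enzyme concentration, fibril length and observation time,
divided by the labeling ratio (unlabeled molecules bind but are
invisible): `k_on = N/(C·L·T·r)`, in M⁻¹ μm⁻¹ s⁻¹. Fibrils with zero
events are kept as `k_on = 0` rows; dropping them would bias the low end
of the distribution upward.

Because microfibrils are bundles of elementary fibrils and bundle count
multiplies the arrival rate, the per-fibril `k_on` histogram is fitted
with a sum of 1–3 Gaussians by nonlinear least squares on histogram
counts. Model selection walks k upward and stops as soon as adding a
component improves R² by less than a threshold (default 0.01). Two
safeguards prevent noise-driven peak splitting, both treated as fit
rejection for that component count:

* a component's width may not be narrower than one histogram bin;
* adjacent peaks must be separated by at least 1.5× the sum of their
  widths, the package's resolvability limit — histograms of a few hundred
  fibrils otherwise support spurious two-peak decompositions of a single
  mode.

The default bin width is Freedman–Diaconis on the pooled sample, capped so
the range spans at least 20 bins (FD alone is too coarse for well-separated
multimodal samples because the IQR straddles the modes). The smallest
fitted peak is reported as the single-bundle `k_on`.

## Dissociation (dwell-time) analysis

Binding times `t_end − t_bind` of events not censored by the movie end are
histogrammed at the frame interval; events shorter than `min_frames`
intervals (default 1) are discarded as unresolvable. The histogram is
fitted with one or two exponential decays by unweighted least squares on
counts (matching how R² is conventionally reported for such fits); a
maximum-likelihood fit of the truncated mixture exists in the test suite
as an independent oracle, and the two agree within 5% at large n.

Mode fractions are area ratios `f_i = (A_i/k_i)/Σ_j(A_j/k_j)` — each
component's decay integrated over [0, ∞). Model selection between single
and double fits prefers the double model on a tie (two binding modes are
the default physical picture for the two crystal-face classes), with a tie
tolerance of 0.005 in R², but rejects a double fit whose components are
not credible: rate ratio below 2 ("ill-separated") or smallest area
fraction below 0.10 ("minor component"). Both patterns are what a second
exponential looks like when it merely absorbs counting noise; with the
two flags, a one-mode truth selects the single model in ≥95% of synthetic
experiments while none of the published two-mode parameter sets is ever
flagged.

Observed disappearance rates are the sum of dissociation and
photobleaching. `bleach_correct` subtracts the bleach rate from each
fitted rate (floored at 1e-6 s⁻¹) and recomputes fractions; it is off by
default, since with a bleach rate of 0.053 s⁻¹ the uncorrected convention
is what reproduces the published dissociation constants. The correction is
flagged unreliable when the bleach rate is not below the slowest fitted
rate. Movie-end censoring is handled by exclusion; with 400-s movies and a
slow rate near 0.086 s⁻¹ the induced bias on the slow rate is ~3%,
verified by a test that quadruples the movie length.

## Motility analysis

Per track, the translational rate is the Euclidean first-to-last
displacement divided by the track's time span ("moving time") — net
displacement, not path length, so diffusing molecules produce apparently
fast rates, which is exactly the feature that separates the populations.
Tracks shorter than 2 frames are dropped; tracks whose displacement does
not exceed 3× the pooled localization precision (RMS of the x and y
precisions, ~4.55 nm here) are classified static and excluded, with
counts reported. The `k_tr` histogram is decomposed with the same Gaussian
machinery as the on-rate analysis (max 2 components); the smallest peak is
the processive velocity.

Moving-time histograms are fitted with a single exponential in two modes:
the full range excluding the first bin (short tracks are a mixture of
processive and diffusive molecules and the first bin is additionally
depleted by the resolution limits), or restricted to times beyond a
threshold (default 10 s) where, experimentally, only processive molecules
remain. For purely processive synthetic data the 10-s restriction wastes
~89% of the tracks for no benefit, so recovery tests fit from 3 s — just
above the static-filter truncation (a 2-frame track moving at ~11.6 nm/s
sits near the 13.6 nm static threshold, so the 1–3 s bins are partially
depleted) — which makes the estimate unbiased while using the full
statistics.

Processivity is `v_slow × τ / product length` with the cellobiose length
1.0 nm, reported rounded to an integer with the unrounded value retained;
the per-molecule hydrolytic rate is `v_slow / product length`.

## Kinetic table and bulk comparison

The total `k_on` is split between the fast and slow dissociation modes in
proportion to their area fractions, and `K_d,i = k_off,i / k_on,i`
(M μm). Rendered tables round to 2 significant figures with halves away
from zero — the convention of printed kinetic tables (1.05e8 renders as
1.1e8). Dissociation constants are computed from the *unrounded* split
rate constants and then rendered; fold ratios between constructs are
computed from the *rendered* values. These two conventions are the unique
pair that reproduces the published derived cells and fold-changes
(unrounded ratios give ≈135 where the rendered convention gives 133).

Bulk data are fitted with `v = kcat·S/(Km+S)` by nonlinear least squares
(a grid-search minimizer in the tests agrees within 1%). The productive
fraction is `kcat / k_single`; for 2.4 s⁻¹ against 11.6 s⁻¹ this is
0.207, reported both exactly and as a whole percent.

## The simulator

`simulate` generates experiments with exactly the statistical structure
the analysis assumes:

* **Fibrils**: lengths from a normal truncated at zero (defaults ~5 μm),
  bundle counts from a user probability vector, uniform positions and
  orientations in a 50 μm field.
* **Arrivals**: per fibril, homogeneous Poisson with rate
  `k_on · n_bundles · C · L` per second; a `labeling_ratio` fraction of
  arrivals is emitted (thinning), mirroring the downstream correction.
  No spatial binding profile along the fibril is modeled.
* **Dwells**: mode fast with probability `frac_fast`; dwell ~
  Exp(k_off,mode); independent bleach time ~ Exp(bleach rate); the event
  ends at the earliest of dwell, bleach and movie end, with the cause
  recorded (censoring is never silently dropped). Sub-frame events are
  written to the table; visibility filtering is an analysis decision.
* **Tracks**: processive tracks slide along the fibril axis at constant
  `v_proc` for a run ~ Exp(τ_move); diffusive tracks are unbiased random
  walks whose per-frame step SD is calibrated per track so the expected
  first-to-last displacement rate equals `v_diff` (the experiments
  constrain only that apparent rate, not a diffusion mechanism). Every
  localization gets independent Gaussian noise (defaults 4.5/4.6 nm);
  sampling at the frame rate (5 fps binding movies, 1 fps motility).
* **Bulk assay**: Michaelis–Menten rates plus Gaussian noise, clipped at
  zero.

Defaults in `presets` are the published operating conditions: 50 pM
enzyme, 0.053 s⁻¹ bleach rate (time constant 18.9 s) for binding movies
and a 14.9 s bleach time constant for motility movies, localization
precisions 4.5/4.6 nm, and the four constructs' kinetic parameters as
simulation truths. Two quantities the experiments do not pin down are
package choices: the movie duration (400 s, consistent with the event
counts the binding analysis is quoted at) and the labeling ratio (1.0).
The mean run time of the diffusive population is likewise free (default
2.0 s, short enough that essentially no diffusive track exceeds 10 s, as
observed). Simulated processive tracks may overrun the fibril end on rare
long runs; run lengths (~50 nm) are short against fibril lengths (~5 μm),
so the approximation is harmless.

What the simulator does **not** emulate — and what passing recovery tests
therefore do not establish for real data: camera noise and PSF shape,
spot-detection and linking errors, pauses or velocity heterogeneity
within a run, spatially clustered binding sites, fibril curvature or
crossing fibrils, and day-to-day variation in labeling efficiency.

## Problem sizes and determinism

Recovery tests use the sizes at which the corresponding estimates are
quoted: ≥5000 dwells (50 fibrils at 200 pM for 400 s), 200 fibrils for the
on-rate peak, 500 tracks for motility; stochastic recovery checks take the
median of five replicate movies to test estimator centering rather than
single-draw luck. All simulation entry points take an integer seed and are
byte-deterministic given it; pipeline stages derive per-stage seeds from
the run seed via CRC-hashed seed sequences, so reports are reproducible
end to end.

## Known limitations

* Moving time is the full track span; pauses are not segmented out, so a
  pausing slider underestimates its instantaneous velocity.
* The histogram Gaussian decomposition reports point estimates and R²,
  not confidence intervals; bootstrap CIs are a natural extension.
* The apparent `k_tr` of diffusive tracks depends on track duration, so
  the fast peak position is a property of the acquisition as much as of
  the molecule; only the slow (processive) peak is interpreted
  quantitatively.
* The bulk activity's dependence on enzyme concentration is not modeled;
  `kcat` comparisons assume the assay's own enzyme concentration.
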