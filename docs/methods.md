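# Methods

This note documents the models, conventions, defaults and numerical
choices behind `rsfret`, and what the synthetic-data tests do and do not
demonstrate about real data.

## Conformational model

The riboswitch is modeled as a continuous-time Markov chain over five
states: `heteroduplex` (pre-release RNA:DNA duplex), `open` (stem-loop,
S–D site exposed), `closed` (H-type pseudoknot), `closed_liganded`
(SAM/SAH-stabilized pseudoknot) and `oligo_bound` (ribosome-mimic duplex).
`closed` and `closed_liganded` share their FRET emission — they are
indistinguishable by distance, differing only kinetically — so a two-state
analysis over mid/high E is the right resolution for pre-folded data, and
the low-FRET heteroduplex/oligo states are handled by classification and
three-component mixtures rather than a larger HMM.

Default emission palette (FRET efficiency mean, per-frame conformational
sd 0.02): open 0.40, closed/liganded 0.84, heteroduplex 0.20, oligo-bound
0.22 for the 9-nt mimic and 0.18 for the 15-nt mimic, matching the peak
positions of this riboswitch's published single-molecule histograms.

State paths are generated by exact stochastic simulation (Gillespie):
exponential holding times at the total exit rate, successor states chosen
proportionally to outgoing rates, absorbing states terminating the jump
process.

## Heterogeneity and archetypes

Molecule-to-molecule kinetic variation is modeled two ways at once:

* **Archetypes** — `static_mid`, `static_high` and `dynamic` molecules,
  implemented as zero-rate edges out of the home state rather than
  separate models (one code path, exact truth labels).  The ligand-free
  default weights are (0.29, 0.16, 0.55); at 1 mM SAM the constant-high
  weight rises to 0.43 at the expense of the dynamic pool, the constant-mid
  weight staying fixed.  These weights are the observed population
  fractions for this riboswitch and are the study conditions for the
  recovery tests.
* **Continuous heterogeneity** — dynamic molecules carry one shared
  log-normal factor (median 1, sigma 1.15 in natural log) on both folding
  rates.  Sigma 1.15 (≈ 0.5 decades sd) was chosen so that per-molecule
  mean dwell times span roughly 2.5–3 orders of magnitude across an
  ensemble, the hallmark "static heterogeneity" of this system; the
  factor is fixed per molecule for the whole trace.

Default dynamic rates are k(open→closed) = 1/3 s⁻¹ and k(closed→open) =
1 s⁻¹: the open conformation is the longer-lived one, dwells are long
relative to the 75-ms frame but short relative to a one-minute movie, so
a typical dynamic molecule shows dozens of transitions.

## Photophysics and rendering

Frames integrate the state path exactly: the per-frame FRET is the
occupancy-weighted state mean (true motion blur), not a subsample, so
frames that straddle a jump land between the peaks just as camera frames
do.  The background-free signal channels are donor = I(1−e̅),
acceptor = I·e̅ with I = 500 counts/frame × the state intensity scale;
observed channels add donor leakage into the acceptor (β = 0.10), acceptor
direct excitation (δ = 5 counts), backgrounds (50/40 counts) and Gaussian
read noise (sd 30 counts/channel, ≈ 0.05 in E).  Leakage is applied to the
background-free donor signal so that the standard correction
(D′ = D − bg; A′ = A − bg − βD′ − δ) inverts the simulator exactly at zero
noise — an invariant the tests assert to 1e-9.

Photobleaching draws exponential times per dye (default 0.002 s⁻¹ each,
appropriate for cyanine dyes under an oxygen-scavenging system).  An
acceptor bleach transfers all signal to the donor channel (the classic
anti-correlated step); a donor bleach drops both channels to background.
The PIFE spike of the vectorial assay multiplies total intensity by 1.5
for 0.3 s as the helicase approaches the donor dye.

Per-molecule RNG substreams are keyed by (seed, molecule index), so
ensembles are reproducible and independent of generation order.

## Preprocessing

Correction constants are configuration, not per-trace estimates, mirroring
fixed-protocol instrument corrections; no gamma correction is applied (E
is the corrected proximity ratio).  Frames with corrected total intensity
below 20% of the configured intensity are masked; efficiencies are clipped
to [−0.2, 1.2] (slightly out-of-range values are kept for histogram
fidelity).  Bleach detection uses a 5-frame sustained-condition window:
total intensity below threshold calls a donor bleach, an anti-correlated
acceptor-down/donor-up step calls an acceptor bleach, earliest event wins,
and the validity mask ends there.  Masking is monotone in the threshold.

## Two-state HMM

Per-trace maximum-likelihood Baum–Welch with Gaussian emissions replaces
the variational empirical-Bayes machinery often used for experimental
data: for two well-separated states it is deterministic, dependency-free
and sufficient, and this substitution is deliberate — equivalence with
any specific external tool is not claimed.  Masked frames are treated as
missing: their emission term is skipped and transitions bridge across
them (verified against exhaustive path enumeration).  Convergence is
Δlog-likelihood < 1e-6, at most 500 iterations, emission sd floored at
0.01 to prevent collapse; log-likelihood monotonicity is asserted.

The default ensemble mode fits emissions once globally (two-component
mixture of the pooled efficiencies) and freezes them for per-trace
transition EM.  This two-pass scheme is what makes single-state (static)
traces decodable: a free per-trace fit would split their single cluster.
States are always relabeled so the high-FRET state has the larger mean.
Viterbi ties break toward the previous state (hysteresis); a first-frame
tie goes to the initial-distribution argmax.

Dwell extraction merges interior runs shorter than 2 frames into their
flanking state (shortest first, then re-scan) to guard against blur-frame
flicker; edge runs are censored and excluded from mean dwells, which is
standard censoring practice.

## Classification

`dynamic` requires ≥ 2 merged transitions, so one spurious excursion never
flips a static label; otherwise the majority decoded state decides the
static label.  Traces with fewer than 40 analyzable frames are `rejected`.
The mid/high boundary always derives from the fitted emission means, so a
mutant with shifted peaks classifies identically.

Locking (flow-in) is scored only on molecules that are dynamic before the
injection and observable for at least `lock_dwell_seconds` (default 30 s,
an order of magnitude above typical closed dwells; no standard criterion
exists, so this is a declared convention) after it —
without the observability requirement, photobleaching would deflate the
locked percentage for purely geometric reasons.  Locked means the
post-event path ends in an uninterrupted high run ≥ 30 s.

Vectorial traces are scored after locating release: the first sustained
(5-frame) departure of E above 0.31 from the initial heteroduplex level,
with a 3-frame grace period for release blur and the PIFE spike.  The
post-release segment is thresholded at the mid/high midpoint and merged;
no mid dwell → type i, no high dwell → type ii, otherwise type iv if the
terminal high run exceeds the locking dwell and type iii if not.

Population tables report simultaneous 95% multinomial (Goodman) intervals;
rejected/unresolved traces are excluded from denominators and reported
separately.

## Mixtures and titrations

Histograms pool per-frame efficiencies from the first 20 valid frames per
molecule (per-molecule means are available as an option) — short movies
are brief relative to dwell times, so frames are the natural unit.
Mixture EM is deterministic (quantile initialization, no random restarts),
sd-floored at 0.01, components sorted by mean; a component below 5% weight
or two components closer than one sd flag the fit degenerate.  K is chosen
by scenario (2 by default, 3 when an oligo adds the low state), never by
model selection, mirroring the fixed two-Gaussian convention of the
underlying assay.

The high-FRET fraction is the top component's weight over the mid+high
weight (the low component is excluded from the denominator in competition
analyses).  Isotherm fits are weighted least squares with Kd = exp(log Kd)
for positivity, f0 and fmax free by default (whether the original fits
fixed f0 is unknown, so both options exist); a response flatter than twice
the median uncertainty raises an unidentifiability error, and grids
topping out below 5× the fitted Kd mark the result extrapolated (the
regime of the weakest pseudoknot mutants).  Confidence intervals resample
molecules, not frames (cluster bootstrap), because frames within a
molecule are strongly correlated.

The titration generator is phenomenological: the static high-state weight
at concentration c is the isotherm value with f0 = 0.30 and fmax = 0.85
(the frame-weighted ligand-free high fraction and a realistic saturation
level for this system).  Equilibrium fractions — not microscopic ligand
on/off rates, which are not published — are what the titration analysis
consumes, so the generator produces them directly; a mechanistic mode
(explicit kon/koff with defaults flagged as free parameters) exists for
kinetic property tests.

## Problem sizes

The recovery analyses use the ensemble sizes of the corresponding assays:
300 molecules for histogram decompositions, 500 one-minute traces for
behavioral fractions, 200 flow-in traces, 2000 molecules per titration
point, 400 per vectorial concentration.  These sizes put binomial
counting error comfortably inside the stated recovery tolerances; the
vectorial apparent-Kd fit is the statistically tightest case, with a
seed-to-seed spread of roughly 15–20% at 400 molecules per point (near
the binomial floor for a 3-parameter fit over six concentrations).

## What the synthetic data does not show

The simulator reproduces the statistical structure the analysis relies on
(state palette, dwell heterogeneity, crosstalk, blur, bleaching, PIFE),
not the full physics: no triplet blinking, no photon-level shot noise
(Gaussian read noise only), no gamma-factor drift, no surface artifacts,
no baseline drift, and ligand kinetics enter phenomenologically.  Passing
recovery tests therefore demonstrates that the pipeline is a consistent
estimator of the quantities it reports under realistic noise — not that
any particular laboratory dataset would yield these exact numbers.

## Known limitations

* The HMM is fixed at two states; three-state fits are out of scope by
  design.
* Dwell means are uncensored-only; no lifetime correction for the
  observation window is applied, so very slow molecules are
  under-represented in dwell scatters (visible in the heterogeneity
  tests).
* The binary trace dialect is a defined convention modeled on the de-facto
  TIRF layout, not a claim about any particular lab's files.
* Intermittent-exposure (duty-cycled) long observations are supported only
  through scenario duration/episodes, without laser-off photophysics.
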