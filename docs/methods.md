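# Methods

This package re-implements, as a tested pipeline, the multi-scale analysis of
paired dorsal-CA1 (dCA1) / medial orbitofrontal cortex (mOFC) recordings
taken while rats learn two new rewarded locations per day on a 150-cm
cheeseboard maze, together with a short-term-synaptic-plasticity (STSP)
recurrent-network model of the navigation behaviour.  Because no raw
recordings ship with the package, every stage is exercised against a
synthetic session generator with known ground truth; this note documents the
models, the tunable parameters, the numerical choices, and what the synthetic
tests do and do not establish.

## Session model and behavioural segmentation

A session holds spike trains with region and cell-type labels, a 50-Hz head
position track, one 1-kHz LFP channel per region, the two goal locations of
the current and the previous day, and 40 learning trials grouped into four
blocks of ten.  Units are typed from two waveform/autocorrelogram metrics:
trough-to-peak latency <= 0.425 ms marks narrow-waveform interneurons, wider
units with autocorrelogram tau-rise > 6 ms are wide-waveform interneurons,
and the remainder are putative pyramidal cells; units below 0.3 Hz mean rate
are excluded.  Ties at tau-rise exactly 6 ms fall to the pyramidal class
(strict inequality, as printed in the classification rule).

Within a trial, epochs are Goal (within 15 cm of a rewarded well) and
Navigation (start box to first goal, first to second goal), ordered by
arrival.  Two operationalizations were left open by the source procedure and
are package choices, recorded in output metadata: "start-box exit" is the
first frame outside the start-box rectangle stored in the session, and a Goal
epoch ends at the last in-zone frame before a continuous absence of at least
1 s (the same 50-frame merge logic used for probe-session goal visits).
Goal-visit counting merges consecutive in-ROI frames and bridges gaps up to
50 frames.

Learning curves are summarized with a continuous one-breakpoint
piecewise-linear model `y = b0 + b1 x + b2 (x - tau)+` fitted by OLS at every
integer candidate breakpoint; candidates run over trials 3..n-2 so both
segments keep support, and RSS ties resolve to the smallest candidate.

## Spatial coding

Rate maps use 5 x 5 cm bins, a >4 cm/s speed gate, exclusion of bins
occupied under 200 ms, and Gaussian smoothing (5-bin kernel, sigma 1.5
bins).  Two choices the written procedure leaves open: the division
(spikes/occupancy) happens before smoothing, and the smoothing kernel is
renormalized over valid bins so rate does not bleed into unvisited
territory.  Skaggs information `I = sum p_i (r_i/rbar) log2(r_i/rbar)` is
computed on the smoothed map (the map used everywhere else) with occupancy
probabilities renormalized over valid bins; a config switch exposes the raw
map instead.

Goal coding: the peak region is every valid bin with rate >= 80% of the map
peak (maps need a >1 Hz peak), the goal window is the 3 x 3 block of bins
centred on the bin containing the well, and the overlap score per goal set
is the maximum over its two wells.  A unit is goal-related if it overlaps
the previous-day goals in the pre-probe map or the current-day goals in the
post-probe map, and a reorganization cell if both hold.  Grid convention:
bin (0, 0) at the lower-left of a square grid covering the maze, goals
assigned to bins by floor division.

## Oscillations

Filtering is a 4th-order Butterworth applied forward-backward; filters are
realized as second-order sections because the 1-4 Hz delta band (used only in
the theta/delta gate; the band itself is a package convention) is numerically
unstable in transfer-function form at 1 kHz.  Phase and envelope come from
the analytic signal.  Band conventions: theta 4-12 Hz, low gamma 30-60 Hz,
high gamma 60-90 Hz, ripple 150-250 Hz.  Welch spectra use 1-s windows with
90% overlap.

PLV is `|mean exp(i(phi1 - phi2))|`.  The n:m phase-phase statistic is
computed as `|mean exp(i(m phi_theta - n phi_gamma))|` for a ratio of n theta
cycles to m gamma cycles: with the gamma phase advancing m/n times as fast as
theta the weighted difference is stationary, so a 1:m scan peaks at the
generating frequency ratio (the weighting follows the ratio semantics rather
than the symbol order of the usual shorthand formula, which does not lock at
its own labelled ratio).  The modulation index bins phase into 18 x 20
degrees, normalizes the per-bin mean envelope into a distribution P_j, and
reports `MI = (Hmax - H)/Hmax` with `Hmax = log 18`; empty bins carry zero
amplitude mass and are flagged.

Theta cycles are trough-to-trough intervals kept when speed > 4 cm/s, the
theta/delta envelope ratio exceeds 3 throughout, and no ripple exclusion
applies.  Ripples are detected where the 150-250 Hz envelope (smoothed 10 ms)
exceeds 3 SD above the immobility baseline (all speed < 4 cm/s samples),
restricted to immobility, with a 20-ms minimum duration; the exclusion mask
extends 100 ms past each event and is shared by the phase-locking, coupling,
pair-timing and assembly stages.  Epoch-level coupling is computed on
concatenated epoch samples; a per-trial option exists.

## Spike timing

Phase locking restricts spikes to valid theta cycles, requires at least 50
spikes, tests uniformity with the Rayleigh test, and fits a von Mises
concentration kappa only for significant units.  Pairwise coordination
binarizes trains at 1 ms, computes the directed cross-correlogram over
+-50 ms normalized by the reference spike count, subtracts a baseline from
absolute lags 20-50 ms, and takes the maximum excess in lags 1-3 ms
(within-region) or 1-5 ms (cross-region), both ends inclusive.  The null
shifts every target spike by an independent integer offset uniform on
[-25, 25] ms (collisions re-binarized), recomputes the statistic 1,000
times, and reports `p = (1 + #{T_k >= T_obs}) / 1001`; Benjamini-Hochberg
correction at q = 0.05 runs within each reference-neuron group.  Surrogate
generation is vectorized across all 1,000 surrogates (per-spike offsets are
added to precomputed pair lags), which keeps a 200-pair calibration run in
tens of seconds; surrogate RNG streams derive per pair from a master seed.
Block trends are labelled increased/decreased only when the OLS slope across
blocks and the Block4 - Block1 difference agree in sign.  The long-lag
baseline pools negative and positive lags.

## Assemblies

Counts in 20-ms bins (ripple bins plus 100 ms dropped, zero-variance neurons
dropped with a warning) are z-scored per neuron; the number of co-activation
patterns is the number of correlation-matrix eigenvalues above the
Marchenko-Pastur upper edge `(1 + sqrt(n/T))^2` (the standard edge for
unit-variance data; the source names the threshold without a formula).
FastICA runs on the data projected into the significant principal subspace
(the standard estimator family for this method); weight vectors are mapped
back to neuron space, unit-normalized, and sign-fixed so the largest weight
is positive.  Pattern expression is `S(t) = z' P z` with the outer-product
projector's diagonal zeroed; events are local peaks of S above 5, with
plateaus credited to their first bin.

## Decoding

Epochs are cut into non-overlapping 400-ms windows (remainders dropped);
features are per-neuron spike counts in 20-ms bins converted to rates.
Behavioural-stage decoding uses the final learning block's four epochs as
classes; block decoding uses Goal-only or Navigation-only windows with block
labels.  Classes are balanced once per task by subsampling to the smallest
class (a re-draw flag exists).  The classifier is Gaussian naive Bayes;
z-scoring statistics come from the training fold only.  Evaluation is
leave-one-trial-out; held-out posteriors are pooled over folds and scored
once as the micro-average ROC-AUC of the flattened one-hot/posterior
matrices (pooling is required because a block-decoding test trial contains a
single class, so per-fold AUC is undefined).  The fixed-N replacement
control swaps floor(fraction x N) source-region neurons for donor-region
neurons, 200 resamples per fraction, holding N constant.

## STSP network model

Two rate subnetworks - reward (4 inputs -> 80 recurrent, 64E/16I) and
spatial (10 place inputs -> 100 recurrent, 90E/10I) - project their
excitatory units to two velocity readouts.  Per presynaptic neuron, resource
x and utilization u follow `dx/dt = (1-x)/tau_x - u x r` and
`du/dt = (U-u)/tau_u + U(1-u) r`, with facilitating (0.2 s, 1.5 s, 0.15) and
depressing (1.5 s, 0.2 s, 0.45) parameter sets; drive is `W x u r`.
Cross-subnetwork excitatory projections facilitate and within-subnetwork
recurrence depresses (a package default, configurable); because the two
classes cannot share one state pair, each neuron carries one (x, u) pair per
class.  Integration is forward Euler at dt = 10 ms; the algebraic fixed
points `u_ss = U(1 + tau_u r)/(1 + U tau_u r)`, `x_ss = 1/(1 + u_ss tau_x r)`
are reproduced by simulation within 1% for rates 0-20 Hz.

Several training ingredients are unspecified in the source and are package
choices: the transfer function is a saturating rectifier bounded at 100 Hz;
readout speed saturates at 40 cm/s; the arena is a built-in 60-cm square
with ten Gaussian place inputs (sigma 15 cm) and a 5-cm goal radius; reward
inputs encode the goal egocentrically (unit direction to goal, proximity,
arrival flag) - the encoding that makes a learned policy transferable when
the goal moves; the loss is time-integrated distance to goal plus a small
squared-rate penalty; gradients are analytic with one-step truncation
(each step's velocity is credited with the next step's distance change
only), which is cheap, stable, and sufficient for this homing task; the
optimizer is Adam (implemented in-package) with connectivity-masked,
norm-clipped updates, and Dale's sign constraint plus the mask re-imposed
after every step, so masked entries stay exactly zero.  Recurrent weights
initialize weakly (SD 0.2/sqrt(n)) to keep early dynamics input-driven;
strong recurrent initialization traps training in an input-ignoring
attractor.  Variants: `no_stsp` pins x*u at its rest value U; `no_cross`
masks reward<->spatial recurrent connections.

The goal-switch experiment trains a pre-trained and a naive network on a new
goal under an identical protocol and reports episodes until the trailing
10-episode median time-to-goal meets a shared criterion (60% of the episode
timeout).  Only the direction of the contrast (pre-trained adapts in fewer
episodes) is contractual; test runs use reduced networks (16 + 24 recurrent
units), 300 pre-training and 150 adaptation episodes of up to 4.5 s.

## Synthetic sessions

The generator emulates the study conditions: 40 trials in four blocks, goals
>50 cm apart, >50 cm from the previous day's goals and >20 cm inside the
maze edge, ~25-min probe sessions, per-session unit yields of 14-17
pyramidal cells and 4-5 interneurons per region, 8-Hz theta, 40/75-Hz gamma.
Trials run start box -> goal 1 -> goal 2 -> start box with low-speed dwells
inside the goal ROIs; per-trial path length follows a piecewise-linear
schedule (default: intercept 700 cm, -30 cm/trial to a breakpoint at trial
10, flat after) realized by sinusoidal detours whose amplitude is bisected
against the target arc length with maze-edge clipping applied inside the
search.  LFP: dCA1 carries reference theta plus noise and, at goal dwells,
150-250 Hz burst transients; mOFC theta lags dCA1 by a mean 0.8 rad with
Ornstein-Uhlenbeck fluctuation (SD = `plv_lag_jitter`), and mOFC gamma rides
on dCA1 theta phase with envelope `1 + pac_depth cos(phase)`.  Spiking is
inhomogeneous Poisson by 1-ms Bernoulli thinning: Gaussian place fields
(sigma 15 cm, 8 Hz peak over 0.5 Hz baseline), goal cells whose fields sit
on a previous-day goal pre-learning and (for remapping cells) a current-day
goal after, von Mises theta-phase multipliers (kappa 1.5) for half the
units, planted short-latency pairs (reference spikes copied into the target
at fixed latency with a set probability), and assembly members co-spiking
within 20 ms of latent Poisson events.  Everything derives from one
`numpy.random.default_rng(seed)` stream, so a fixed seed reproduces the
session bit-for-bit.

What the generator does not emulate: biophysical LFP (1/f background,
current sources, volume conduction), spike-sorting artefacts, non-Poisson
firing statistics (bursting, refractoriness), behavioural idiosyncrasies
(grooming, rearing), and electrode drift.  Passing tests therefore establish
that each estimator recovers the structure it targets under its own model
family at realistic signal levels - not that the estimators are robust to
every failure mode of real recordings.

## Problem sizes in the test suite

The default suite runs sessions of 12-20 trials and probes of 7-25 minutes,
200-300 s blocks for pair calibration (200 null pairs at 5 Hz, 1,000
surrogates each), 100 x 10,000 matrices for assembly recovery, and 20 seeds
of the reduced goal-switch experiment; these sizes were chosen so each
statistical check retains its nominal power while the whole suite completes
in minutes.
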