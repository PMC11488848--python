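# Methods

This note documents the model, the analysis pipeline, the numerical
choices, and the known limitations of `clusterplay`. All defaults live in
`clusterplay.config`; symbols follow the field's standard usage.

## Model

### Neurons

Conductance-based leaky integrate-and-fire neurons with spike-rate
adaptation (SRA). The membrane obeys

    C_m dV/dt = -g_L (V - E_L) - g_E (V - E_E) - g_I (V - E_I)
                - g_SRA (V - E_SRA) - g_ext (V - E_ext)

with `C_m = 0.4 nF`, `g_L = 10 nS` (membrane time constant
`tau_m = C_m / g_L = 40 ms`), `E_L = E_I = -70 mV`, `E_E = E_ext = 0 mV`,
`E_SRA = -80 mV`, threshold `-50 mV`, reset `-70 mV`, and no explicit
refractory period. Each conductance decays exponentially
(`tau_E = 10 ms`, `tau_I = 3 ms`, `tau_SRA = 30 ms`) and steps up at
presynaptic spikes (`W_EE = 220 pS`, `W_EI = W_IE = 400 pS`) or, for
`g_SRA`, at the neuron's own spikes (`delta_SRA = 3 pS`). At these values
SRA is a very weak current relative to the leak; it is retained for
completeness but plays no role in burst termination, which is carried by
feedback inhibition and the post-spike reset.

### Network

`n = 500` neurons, 75% excitatory. E cells are randomly assigned to
`n_c = 15` equally sized, overlapping clusters with mean participation
`mu_c = 1.25`: every cell first joins exactly one cluster (round-robin
over a random cell order, so base sizes are equal whenever `n_c` divides
`n_E`), then each cluster adds `round(n_E (mu_c - 1)/n_c)` further
distinct cells. E-to-E connections exist only between cells sharing a
cluster, each eligible ordered pair receiving a single Bernoulli trial at
the within-cluster probability `p_c * C_tot / C_clust` with
`C_tot = n_E (n_E - 1)` and `C_clust = n_clust (n_clust - 1) n_c`
(real-valued `n_clust = n_E mu_c / n_c`). Because ordered pairs that
share two clusters are counted twice in `C_clust` but receive one trial,
the realized global density settles about 2% below the nominal
`p_c = 0.08` (0.0784 at the fiducial point); the network tests assert the
analytic expectation of the construction, not the nominal value. E-I
wiring is cluster-independent at `p = 0.25`; there are no I-to-I
connections.

### Inputs

Three feed-forward Poisson cues. Two location cues ramp linearly in
opposite directions along the 1 m track with rates summing to
`r_G = 5000 Hz` everywhere (the left cue peaks at the track's left end);
one context cue fires at `r_G` independent of position, in both run and
sleep. Synaptic strengths are drawn log-normally with arithmetic mean
`W_in = 72 pS` and SD 5 pS (location) or 1.25 pS (context); the printed
parameterization is moment-matched: `mu = ln(W^2 / sqrt(sd^2 + W^2))`,
`sigma^2 = ln(1 + sd^2 / W^2)`. Inhibitory cells receive only the
context cue.

Each environment assigns the clusters a random permutation of evenly
spaced rank biases in [-1, +1]; a cell's bias is `0.04` times the mean
rank of its clusters, scaling its left cue weight by `1 + bias` and right
by `1 - bias`. An environment redraws both the location-cue weights and
the context weights (stream keyed by environment id); the sleep session
has its own context draw and no location input. Redrawing the location
weights per environment is required for remapping: with shared draws the
cell-level left/right weight asymmetry (~10%) dominates the ±4% cluster
bias and would leave cross-environment map correlations near 0.45 rather
than near zero.

### Context-scaling calibration

The four context scaling factors (`f_E-awake`, `f_E-sleep`, `f_I-awake`,
`f_I-sleep`) are calibration constants: their role is to set appropriate
population activity per session kind, compensating for the presence or
absence of the location cues. This calibration is integrator-specific,
because the network sits deliberately close to threshold: the mean
feed-forward drive (`W_in r_G tau_E = 3.6 nS`) places the subthreshold
membrane about 1.5 mV below threshold, and a 3-4% change in effective E
drive moves the sleep network across the entire range from silent, through
punctate population bursts, to tonic ~3 Hz asynchronous firing. Any two
faithful integrators that differ by a percent in effective drive therefore
land in visibly different regimes with the same factor values.

For this package's integrator the calibrated values are `f_I-awake = 1`,
`f_I-sleep = 0.75`, `f_E-sleep = 0.985` and `f_E-awake = 0`. The two E
factors were selected on a coarse grid against activity-level anchors
only: for sleep, (a) a punctate-burst regime (discrete PBEs above the
mean + 1 SD threshold rather than tonic firing) and (b) a candidate-event
yield of roughly 0.2 decodable events per second, the yield implied by the
size of the pooled event ensembles the method is designed to produce; for
run, (a) the 3 Hz place-cell gate must bind (a substantial minority of
cells fail it) and (b) cross-environment map correlations must be near
zero. With these values a fiducial network shows sleep background
population rates near 1.8 Hz with clear bursts, run-session place cells
(~210/375) with median peak ~6 Hz and specificity ~0.4, and
cross-environment map correlations of ~0.03.

### Sessions and integration

Run sessions are five independent 2 s constant-speed laps per trajectory
(leftward and rightward) per environment; sleep is one 120 s session.
Time-field protocols add laps at twice the speed. Forward Euler at
`dt = 0.1 ms`: each step draws exact Poisson input counts per neuron per
cue (inversion sampling, so the input statistics are independent of
`dt`), applies them to `g_ext`, updates the membrane with the current
conductances, decays all conductances, and then tests for threshold;
spikes reset the membrane for the remainder of the step, increment
`g_SRA`, and deliver recurrent steps that act from the next step. The
initial state is `V = E_L`, zero recurrent/SRA conductances, and `g_ext`
drawn per cue from a Gaussian at the shot-noise steady state (mean
`w r tau_E`, SD `w sqrt(r tau_E / 2)`, truncated at zero). Per-step
Bernoulli thinning (probability `rate * dt`) was rejected because at
`rate * dt = 0.5` it halves the input count variance; in the
fluctuation-driven sleep regime that biased session-mean rates by a
factor ~3 between `dt = 0.1 ms` and `dt = 0.05 ms`, violating the
integrator-convergence requirement that exact Poisson sampling satisfies
(run ~4%, sleep within realization noise, at halved `dt`).

All randomness derives from one master seed through named
`SeedSequence` substreams (clusters, connectivity, per-environment
weights, per-session noise, shuffles), so each stage is independently
reproducible; the simulation kernel uses an inline xorshift64* stream
seeded from its session substream.

## Analysis pipeline

* **Place fields** — trial-averaged occupancy-discounted rates in fifty
  2 cm bins (occupancy is uniform under constant speed), then a
  truncated-renormalized Gaussian kernel (4 cm SD), so a constant map is
  exactly preserved and no rate leaks off-track. Place cells: smoothed
  peak > 3 Hz, per trajectory. Statistics: peak rate; specificity
  (1 minus the fraction of bins above a quarter of the peak); spatial
  information `sum_i p_i (r_i/rbar) log2(r_i/rbar)` on the smoothed map;
  KL divergence of the peak-bin distribution from uniform; fraction of
  peaks in the central third (bins 17-33 of 50, 1-based); per-bin
  population-vector Pearson correlations averaged over bins for map
  similarity (zero-variance bins skipped).
* **Burst detection** — mean E-cell rate on the simulation grid smoothed
  with a 15 ms SD Gaussian (truncated at 4 SD); threshold at session
  mean + 1 SD (statistics computed over the whole session, events
  included); excursions gated on duration ≥ 30 ms and peak ≥ 0.5 Hz,
  then merged across gaps < 10 ms; decodable events have ≥ 5
  participating E cells and ≥ 50 ms.
* **Decoding** — place-cell spikes binned in 10 ms windows tiled from
  event start (a trailing partial bin is dropped); memoryless Bayesian
  posterior per bin, `P(x|s) ∝ prod_i r_i(x)^{s_i} exp(-tau sum_i
  r_i(x))`, computed in log space with rates floored at 0.01 Hz.
  Zero-spike bins follow the same formula. Statistics: weighted
  space-time Pearson correlation (posterior probabilities as weights;
  undefined when a weighted variance vanishes, such events are excluded
  and counted); maximum jump of the posterior peak between adjacent bins
  (ties to the lowest bin); mean per-bin entropy.
* **Shuffle significance** — 100 uniform permutations of each event's
  posterior columns (exactly equivalent to permuting the binned spikes,
  since the decoder is memoryless), streams keyed by event. Ensemble
  tests pool events across networks: two-sample KS on |r| against the
  pooled shuffles with the median shift as effect size; a bootstrap
  p-grid over (minimum |r|, maximum jump) thresholds where shuffle
  dataset k is the k-th shuffle of every event and ties count toward p
  (so the all-pass corner is p = 1, never significant); per-event p as
  the fraction of the event's own shuffles with strictly higher |r|.
* **Cluster dynamics** — per-cluster mean member rates in the event
  window smoothed with the same 15 ms kernel on a 1 ms grid; a cluster is
  active if at some instant its rate exceeds twice every other cluster's;
  sequences are ordered by first strict dominance and durations are
  dominance times. Identity shuffles: `across` (uniform permutation),
  `within_cluster` (composition of 10·n_E random transpositions
  restricted to cluster-sharing pairs; chained swaps make the composite
  only approximately membership-preserving, and exactly preserve
  per-cluster spike counts only in the single-cluster variant),
  `within_single_cluster` (multi-cluster cells are fixed points). Spike
  ranks use each participant's mean spike time, normalized to [0, 1],
  inverted in events whose decoded slope (sign of the weighted
  correlation) is negative; a cell's field location is its smoothed
  field's center of mass.
* **Graph metrics** — directed clustering after Fagiolo (`S = A + A^T`,
  triangles `(S^3)_ii / 2`, possible `d(d-1) - 2 d_bi`), with the global
  triplet ratio as the headline value and the per-node mean also
  reported; mean shortest directed path over ordered pairs (unreachable
  pairs excluded and their fraction reported; fiducial graphs are
  strongly connected). SWI uses the closed-form lattice/random
  references `C_l = 3(k-2)/(4(k-1))`, `C_r = p`, `L_l = n/(2k) + 1/2`,
  `L_r = (ln n - γ)/ln k + 1/2` with k the empirical mean out-degree.

## Problem sizes

The package's canonical experiment is 10 networks with 120 s sleep,
pooling all decodable events (typically 200-400) for the ensemble tests.
Parameter sweeps in the test suite use a reduced grid
(`n_c ∈ {10, 20} × mu_c ∈ {1.25, 1.75}` at `p_c ∈ {0.04, 0.08, 0.12}`,
with `W_EE` rescaled inversely with `p_c`, infeasible points dropped) at
4 networks × 120 s per point; identity-shuffle controls use 5 replicates
per mode. These sizes keep full runs in the minutes range on one core;
the grid statistics are correspondingly noisier than 20-network / 300 s
ensembles, and sign-level claims are the appropriate resolution there.

## What the simulations do and do not show

The generator reproduces the intended structural conditions exactly
(cluster geometry, calibrated connectivity, input statistics), and the
dynamics reproduce the study's qualitative phenomena: sparse sleep with
punctate bursts driven by transiently dominant clusters, place fields
without environment-specific wiring, preplay significant against
time-bin shuffles (all grid-bootstrap patterns, with 9 of 10 networks
showing positive median shifts at the fiducial point), abolition of
preplay by across-network identity shuffles with preservation under
single-cluster shuffles, positive SWI-preplay rank correlations at each
connection density, and remapping with near-zero cross-environment map
correlations under which all four trajectory decodings remain
significant.

Three quantitative behaviors fall short of the reference phenomenology
and are genuine model-behavior differences under this integrator, not
sampling noise: (1) the fiducial KS statistic against shuffles comes out
near 0.20 rather than ~0.29; (2) decode quality *rises* from zero/one
toward two active clusters instead of falling monotonically with
active-cluster count, because single-cluster events here decode as
localized, weakly linear posteriors (the negative count-quality
correlation appears only beyond two clusters, and events with three or
more active clusters are rare — the mean is ~1.3 active clusters per
event); (3) general within-cluster identity shuffles degrade preplay to
chance rather than merely reducing it. All three trace to the same
mechanism: cluster cascades are shorter and within-cluster field
coherence weaker than in the reference behavior, so more of the sequence
information rides on individual cells. The razor-thin regime sensitivity
described under calibration is the likely origin; the acceptance suite
keeps these three checks at their stated thresholds and they fail
honestly.

Real hippocampal data differ in ways the generator does not emulate:
no theta rhythm or phase precession, no behavioral variability in
running speed or occupancy, no ripple-band field potentials (event
detection here is purely rate-based), one interneuron class, and no
synaptic plasticity within or between sessions.
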