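# Methods

This note records the models implemented in `mechpath`, the defaults and
calibrations of the synthetic-data generator, the numerical choices inside
each analysis stage, and what the package does and does not claim about real
AFM data. Units are fixed package-wide: nm, pN, s, Hz; thermal energy
kBT = 4.114 pN·nm (≈ 297 K, room temperature).

## Generative model of mechanical unfolding

A protein under force is described as a set of structural elements, each
carrying a contour gain (nm of chain released when it unfolds) and Bell
kinetics `k(F) = k0·exp(F·Δx/kBT)` with zero-force rate `k0` (s⁻¹) and
transition-state distance `Δx` (nm). The state space is the lattice of
folded-element subsets; an optional acyclic prerequisite relation restricts
which element may unfold next. Trajectories are sampled by

* **Gillespie simulation** at constant force (exponential dwell at the
  summed eligible rate; element chosen proportional to its rate),
* **exact inversion of the integrated hazard** under a linear force ramp
  `F(t) = r·t` capped at 300 pN (the cumulative Bell hazard has closed form
  below the cap and is linear above it; event times solve Λ(t) = Exp(1)
  draws by bracketed root finding),
* **per-sample thinning** along a quasi-static constant-velocity
  retraction.

The measured extension is the worm-like-chain equilibrium extension of the
cumulative unfolded contour at the instantaneous force, using the
Marko–Siggia interpolation with persistence length ρ = 0.4 nm, plus i.i.d.
Gaussian noise on the extension channel (default sd 0.5 nm — the simplest
noise model that makes 3 nm step detection non-trivial; no 1/f or drift
terms). Force feedback is ideal: the clamp force channel carries the
setpoint exactly. Refolding during force quenches (cycles protocol) is
instantaneous and complete; refolding kinetics are out of scope.

### Default network and its calibration

`default_network()` builds six equal elements — strands s1–s5 plus an
ordered loop. Contour gains are calibrated so that the WLC-equilibrated
extension of the fully unfolded chain at the 40 pN reference force equals
the configured total of 19 nm (≈ 3.17 nm of observable extension per
element; total contour ≈ 26 nm). Because fractional WLC extension grows
with force, the observable total rises mildly from ≈ 15.7 nm at 20 pN to
≈ 21.2 nm at 80 pN — the elastic adaptation expected of an unfolded chain.
Quoting element sizes in extension at the working force, rather than raw
contour, is deliberate: step detection and clustering operate on observed
extension, and the emulated experiments report ~3 nm steps summing to
~19 nm at these forces.

Kinetic defaults encode heterogeneous multi-pathway unfolding:

| transition | k0 (s⁻¹) | Δx (nm) | notes |
|---|---|---|---|
| s5 "sweep" channel | 0.20 | 0.05 | commits to fast route; downstream rates ×400 |
| s5 "trapped" channel | 0.005 | 0.50 | commits to slow route; base rates |
| s4 | 0.28 | 0.2 | requires s5 |
| loop | 0.20 | 0.2 | requires s5 |
| s1 | 0.14 | 0.2 | requires s5 |
| s2 | 0.055 | 0.2 | requires s5 |
| s3 | 30 | 0.2 | requires s2; near-instant follower |

Unfolding always nucleates at strand s5 (the force-bearing terminal
strand), after which the remaining elements unfold in stochastic order. The
first event is a kinetic competition between two channels of s5 with
different transition-state distances, so their Bell competition shifts flux
with force: the trapped route carries ~18% of molecules at 20 pN, ~2/3 at
40 pN and nearly all at 60–80 pN, while its dwells shorten with force until
they slip below the instrument resolution. The result is the observed
phenomenology: resolvable intermediates per trace span 0–4, their mean
rises from 20 to 40 pN, plateaus at 40–60 pN and falls again at 80 pN, and
single-sweep traces coexist with multi-second intermediates at the same
force. Strand s3 following s2 near-instantly caps the resolvable
intermediates at four (five visible steps), mirroring the tendency of two
strands to unravel jointly at the end of the process.

A design note: a model in which every element keeps one fixed,
state-independent rate at a given force cannot reproduce this coexistence —
all inter-step dwells would share a single rate scale, making frequent
single sweeps and long-lived traps mutually exclusive. The two-channel
branch is the minimal extension that produces both, while keeping every
transition a single-element event (apparent multi-element steps emerge only
from dwells shorter than the resolution, never from concerted moves).
Networks without a branch behave exactly as independent-element models, and
all analyses accept arbitrary networks.

The resolution floor `t_res` defaults to 50 ms — the feedback-response
scale of a force-clamp instrument — and is used consistently by the
ground-truth bookkeeping, the pipeline's detector dwell floor and the
sequential-pathway test.

## Step detection

1. median pre-filter, half-width 5 samples;
2. binary segmentation on the filtered signal: a split is accepted when the
   within-segment sum-of-squares gain exceeds `3·σ²·ln n`, with σ estimated
   robustly from the median absolute first difference of the raw signal
   (exact detection on noiseless staircases follows from the near-zero
   penalty);
3. per-segment levels are raw-signal medians; interior segments shorter
   than `min_dwell` are absorbed into the closer-level neighbour and
   adjacent levels closer than `min_step` (default 2 nm, the smallest
   unfolding length the emulated experiments resolve) are merged. The first
   and last segments are exempt from duration-based absorption: they anchor
   the pulse-start baseline and the final level, and removing them would
   corrupt every step length (visible at high force, where unfolding can
   begin within tens of milliseconds of the pulse start).

Steps are the remaining positive level increments; dwell of the first step
is measured from the pulse start, and the dwell "of" an intermediate is the
dwell before the step that destroys it. The analysis window of a clamp
trace is the contiguous run where the force stays within max(2 pN, 10%) of
the setpoint, which automatically excludes the 150 pN fingerprint segment;
ramp traces are analysed up to the force cap (between-step extension drift
along a ramp is tolerated by the level-merging pass). Traces whose summed
steps fall short of the expected total extension (when known) are flagged
censored: they contribute step statistics but not first-passage times.
Sub-resolution intermediates are not inferred; hidden-state modelling is
out of scope.

## Worm-like-chain fitting

`fit_wlc` estimates the contour length by least squares on the
Marko–Siggia form with ρ fixed at 0.4 nm (option to co-fit); the fit needs
≥ 10 points and starts from Lc = 1.15·max(x) with Lc bounded below by the
data. The inverse (`wlc_extension`) solves the monotone force law by Brent
bracketing to 10⁻⁹ pN; the simulator interpolates the fractional extension
on a cached 1024-point force grid (error < 10⁻³).

## Cluster analysis of step lengths

k-means++ (Euclidean, 1-D) is run `n_replicas` times per candidate k and
the lowest within-cluster sum of squares kept; clusters are relabelled in
ascending centroid order (C1, C2, …). Model selection scans k = 2..10 and
keeps the solution with the highest mean silhouette; ties break by fewest
negative silhouettes, then smallest k. Singleton clusters score s = 0.
`n_replicas` defaults to 20,000 (replication to guaranteed convergence);
the tests and acceptance checks use 200, which on these 1-D data sets
reaches the same optimum in a fraction of the time. Histogram
reconstruction models each force's step-length distribution as a Gaussian
mixture with cluster means/SDs and subset-occupancy weights (σ floor
0.05 nm for under-populated clusters).

The pooled-data acceptance check mixes five intermediate components
(spread 0.4 nm, the pooled step-length scale) with three extended-state
components at 18/19/20.5 nm whose spread is set to 0.2 nm: an extended-state
length is a per-force total measured against a fixed baseline, and its
within-force scatter in this package's own simulations is instrumental
(~0.1–0.3 nm), distinctly tighter than pooled step lengths. The 0.2 nm
value also keeps adjacent components ≥ 5 SDs apart, the separation at which
silhouette selection reliably recovers the true component count; at
substantially broader overlap the mean-silhouette criterion prefers merging
near-neighbours, as it should.

## MFPT rates and the kinetic network

Per clamp force, α = 1/mean(first-passage time) over uncensored traces
(censored fraction reported; conditions with < 5 uncensored traces are
dropped with a warning). The fit of ln α on F is weighted least squares
with weights 1/SE², SE(ln α) = sd(FPT)/(mean·√n); α₀ = exp(intercept) with
a delta-method 95% CI, and Δx_eff = slope·kBT.

States are labelled by step length (the cluster of the step that creates
each intermediate); a trace with steps l₁…lₙ reads N → C(l₁) → … →
C(lₙ₋₁) → U, the final step being the transition into U. A cumulative-
extension labelling mode is available. Steps beyond 3 cluster SDs of every
centroid are labelled outliers and excluded from transition counts (but
reported). Transition counts per force satisfy Σ out-of-N = number of
labelled traces. The connectivity audit enumerates intermediate pairs
satisfying L(origin) + L(destiny) ≤ L(total) and reports observed
violations and allowed-but-unobserved pairs; N (length 0) and U are exempt,
since the native state may connect to everything and every intermediate may
complete unfolding.

## Sequential-versus-multiple-pathway test

Analytic part: an intermediate on a sequential pathway that usually escapes
detection is seen only when its exponential dwell exceeds the resolution,
with probability `p = exp(−t_res/τ)`; at t_res ≥ 3τ, p ≤ e⁻³ < 0.05, and
observing m such intermediates in one trace has probability ≤ p^m (0.05²,
0.05³, … for m = 2, 3, …).

Monte Carlo part: the per-trace intermediate multiplicities (capped at 5
stages) are fitted by the Poisson-binomial law of a strict sequential chain
with free per-stage detection probabilities (maximum likelihood,
multi-start Nelder–Mead on logits; fitting detection probabilities directly
profiles out the unknown assignment of observed dwells to stages). Goodness
of fit is χ² over multiplicity bins {0, 1, 2, 3, ≥4} with expected counts
floored at 0.5; the null distribution comes from a parametric bootstrap
without per-replicate refitting, which biases p-values upward — the test is
conservative, appropriate for a rejection claim. "Sequential rejected"
requires Monte Carlo p < 0.01; fewer than 20 traces yields "insufficient
data". The report also states how surprising the longest observed dwell is
under the fitted chain. Bimodal multiplicity histograms — simultaneous
excesses of zero-intermediate sweeps and of 3–4-intermediate traces, as the
default generator produces — lie outside the Poisson-binomial family and
are rejected essentially always; data truly generated by a sequential chain
is rejected at well under the nominal rate (verified by a type-I property
test).

## Pipeline and reproducibility

`pipeline.run` chains simulation (or file ingestion), detection,
clustering, histogram reconstruction, rate fitting, network building,
connectivity audit, heterogeneity profiling and the pathway test, writing
TSV tables plus a JSON run log (package version, config, seeds — no
timestamps, so a fixed seed reproduces the report byte for byte). All
randomness flows through spawned children of one seed, making each stage
independently reproducible.

Problem sizes: the emulated study design is 56–57 traces per force at
20/40/60/80 pN, 5–20 s pulses at 0.5–4 kHz; the pipeline defaults to
57 traces × 10 s × 1 kHz per force. The test suite and acceptance script
use 100–400 trace ensembles, 10⁴–5×10⁴ Gillespie paths for distributional
checks, 100 replicate WLC fits, and 200 k-means replicas — sizes chosen so
statistical tolerances (3 SE bands, KS at α = 0.01, 95% CIs) are meaningful
while a full run completes in about a minute.

## Limitations

* The generator reproduces the qualitative heterogeneity of the emulated
  experiments (0–4 intermediates, heterogeneity maximal near 40–60 pN,
  single sweeps coexisting with traps), not any measured per-force
  intermediate frequencies or per-pathway fluxes — those are not available
  to calibrate against.
* No cantilever dynamics, feedback lag, baseline drift, surface-detachment
  artefacts or multi-molecule tethers; passing tests demonstrate the
  analysis chain is correct on data obeying the stated model, not that it
  is robust to every instrumental pathology of real traces.
* The extended-state force dependence is purely WLC-elastic; slow unfolded-
  chain relaxations are not modelled.
* The sequential-chain null fixes the number of stages (default 5) and
  tests only the multiplicity fingerprint; dwell-time shapes enter the
  report descriptively, not in the statistic.
* Vendor AFM file formats are not read; traces enter as the documented TSV
  or HDF5 layouts.
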