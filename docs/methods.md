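# Methods

## Model

The system is a modular continuous-time recurrent neural network (CTRNN).
Every neuron follows the leaky-integrator equation

    τ dγ_i/dt = −γ_i + Σ_k ws_ik I_k + Σ_m wp_im A_m,    A_i = σ(γ_i − θ_i)

with a single shared time constant τ = 0.25 (all neurons identical by
construction, so no module is structurally privileged) and logistic
activations in (0, 1).  Modules are fully connected internally; every
depicted inter-module arrow is all-to-all (each source neuron projects to
each target neuron).  Two architectures are built from these modules:

* **Interval timing** (8 modules, 44 neurons, 1432 parameters):
  oscillators → tSen1 (16) ⇄ tSen2 (16) → six 2-neuron duration modules,
  which also receive the tone line and all six event-id lines.
* **When + how-long** (16 modules, 88 neurons, 3184 parameters): adds a
  16-neuron tDuration hub and a 16-neuron tDistance hub reading tSen2,
  and six 2-neuron distance modules.  Event-level modules keep their
  direct tSen2 afferents alongside the new hub afferents.  Because the
  added links can be initialised at zero, a trained interval-timing model
  lifts into the combined architecture with bit-identical behaviour —
  this is what makes the incremental extend-and-retrain workflow exact,
  and it is why we chose this wiring over a hub-only routing.

### Time, units and discretization

One *simulation moment* is one oscillator sample and one synchronous
network update; at each moment every module integrates using the afferent
activations of the previous moment, which makes module evaluation order
irrelevant.  Within a moment the drive is held constant and the potentials
relax toward it by forward-Euler sub-stepping (default 10 sub-steps),
which with constant drive is algebraically the closed form
`γ' = d + (γ − d)(1 − h/τ)^substeps`.

The dynamical time advanced per moment, `moment_dt`, is a free parameter
of the implementation: the sampling clock of the oscillators (one moment
per sample of Eq.-style `sin(ω t)`) does not by itself fix the neuron
clock.  We set `moment_dt = 0.01`, i.e. we read τ = 0.25 as 250 ms and a
moment as a 10 ms tick — the physical correspondence usually quoted for
this class of model — giving each neuron an integration memory of ~25
moments.  This value was identified empirically as the regime in which
the tuning procedure below can actually produce accurate ramp-coded
timing: with a much faster neuron clock (e.g. a full 0.25-unit relaxation
per moment) the per-moment map is effectively memoryless, every timing
solution requires exactly tuned marginal recurrence, and the evolutionary
search demonstrably stalls at duration errors of ~10–20 moments; with
~25-moment neuron memory, slow ramp dynamics are generic and the same
search reaches a few moments of error.  `moment_dt`, τ and the sub-step
count are recorded in all result metadata and configurable everywhere.

## Stimuli

Sessions are generated, not loaded: four oscillator channels
`sin(ω_j t + k_j) + U(−a, a)` with ω = (4, 1, 0.25, 0.1) rad/moment,
phases drawn once per session from U[0, π], and independent per-moment
noise of amplitude a = 0.05 (other amplitudes only in the noise studies);
a binary tone line; six one-hot id lines.  A session is T = 1000 moments
with six events.  Durations are uniform integers in [10, 50) so that the
scalar study's probes (20–45) lie inside the trained range; consecutive
events are ≥ 100 moments apart; the first onset is ≥ 100 (which keeps
log10(t/st) ≤ 1, inside the sigmoid's range); the last event ends ≥ 10
moments before the horizon so the readout window always exists.  The
feasibility slack is split uniformly at random over the inter-event
offsets.  Id lines are active only while the tone is on; remembering an
event after it ends is the network's job, not the stimulus's.

What the generator does *not* emulate: real sensory streams, correlated
noise, attention, or any mapping of moments to physical seconds beyond
the unit convention above.  Passing tests therefore show that the
*method* recovers the study's own synthetic conditions, not that it
times real-world events.

## Targets, errors, fitness

Duration target: piecewise ramp `D_i(t)` with slope 1/M during the event
and a constant plateau `(e_i − st_i)/M` afterwards.  Distance target:
`TD_i(t) = log10(t/st_i)` after onset, 0 before.  The base-10 logarithm is
fixed by the worked example log(1000/443) = 0.353 (a natural log would
give 0.814).  Errors are sums of squared deviations over the full session
(pre-event moments included: spurious output before the event is a real
failure), summed over the evaluation sessions of a generation.  Fitness:
1000/(E + ε) with ε = 1e−9 guarding exact-zero errors; products compose
the tree (event modules → hubs → TimeSense root).  Products of up to
twelve factors stay comfortably inside float64 range even at ε-level
errors.

## Cooperative coevolution

One population per module.  A chromosome is scored by substituting it
into a model otherwise assembled from the current representatives (the
previous generation's best) of all other populations — one collaborator,
generation-lagged, the standard linear-cost choice.  All candidates of
all populations within a generation see the same sessions, so fitness
differences reflect genomes rather than schedule luck; session sets are
redrawn every 10 generations (`session_refresh_every`) — a compromise
between a stationary landscape the search can climb and enough schedule
turnover to prevent overfitting any single session.

Reproduction per population: the top 20% survive unchanged and serve as
parents; offspring are single-point crossovers of uniformly drawn parent
pairs; each offspring gene mutates with probability 2% by additive
uniform noise of ±10% of its magnitude, with a ±10%-of-0.1 floor so
near-zero genes can move.  Initialisation: weights uniform in [−5, 5];
biases are *center-crossing* — set to half the presynaptic row sum (plus
U[−0.5, 0.5] jitter) so every neuron starts at the centre of its sigmoid,
where slow and near-marginal dynamics are reachable.  This follows the
established recipe for evolving rich CTRNN dynamics and measurably
improves the tail of the initial population compared with independent
uniform biases.

Because a candidate can only influence its own module and modules
downstream of it, candidate evaluation freezes all upstream neuron rows
to the representative base trace; evaluating a 2-neuron event module does
not re-integrate the 16-neuron TimeSense chain.  This makes event-module
evaluations ~50× cheaper than hub evaluations, which the scaled profile
exploits by giving event modules a larger population (1024) than hubs
(48).  The full-scale defaults remain 1000 chromosomes per module and 500
generations (300 for the extension stage).

Cooperative coevolution with simultaneous representative updates can
de-synchronise a team (a candidate scored against last generation's
collaborators ships with this generation's).  We therefore score the
representative team after every update on a small fixed validation suite
(5 sessions drawn once per run) and return the best team ever seen, not
the last one.  The validation score is the mean absolute decoded-duration
error normalised by M, plus the mean absolute distance-trace error for
the combined model.

### Extension stage

Populations of pre-existing modules are seeded with the lifted genome —
kept verbatim as chromosome 0 and as the initial representative, so the
reload reproduces the stage-1 duration pathway exactly — plus copies
mutated at a 10% per-gene rate for diversity; new modules start from
random center-crossing genomes.  Evolution then proceeds under the
extended fitness tree (generations and epochs are treated as the same
unit).

## Evaluation protocols

* **Scalar study**: for each probe duration (20, 25, 30, 35, 40, 45), 50
  single-tone sessions with fresh phases and noise, onset uniform in
  [100, 400], horizon 600, and the probe placed on a *random* id line
  (the six modules are interchangeable; randomising the line folds
  module-to-module variation into the reported spread).  Statistics are
  the sample mean, standard deviation (ddof = 1) and CV of the decoded
  estimates.
* **Noise study**: full six-event sessions at amplitudes 0.03–0.13, 20
  sessions per level; the average absolute decoded-duration error per
  event, and the mean count per session of *mismeasured* events —
  decoded duration off by more than 5 moments (10% of M; the threshold
  is a package choice).
* **Transient noise**: paired sessions with and without an extra uniform
  burst (amplitude 0.13, < 10 moments, one burst per event starting at a
  random moment within it); reported as the mean increase in absolute
  duration error.

Readout window: the 10 moments following an event's end (configurable);
the duration estimate is M times the mean output there, the exact inverse
of the ramp plateau.

## Numerical choices

Euler sub-stepping with h = moment_dt/substeps = 0.001 gives h/τ = 0.004,
far inside the stability region; sub-stepped trajectories match a
1000-sub-step reference to ~1e−5 on linear test cases.  The sigmoid is
evaluated in its numerically stable split form and saturates without
overflow.  All randomness flows from a single seed through named
substreams (initialisation, per-generation sessions, per-population
reproduction, validation, evaluation), so every run is bit-reproducible;
derived seeds stay below 2^31.

## Known limitations

* The scaled-down tuning budget (~30k evaluations per event module
  against ~500k at full scale) reaches mean held-out duration errors of
  ~3–5 moments, not the sub-moment accuracy a full-scale run reports.
  Consequently the scalar study's spread is a few moments rather than ~1,
  its growth with duration is not reliably monotone at this precision,
  and the probe means can deviate from truth by slightly more than 10%
  at intermediate durations.
* The evolved desk-scale models lean on the tone and id lines more than
  on the oscillatory pathway, so their duration error is dominated by
  model imprecision rather than input noise: error stays roughly flat
  across noise amplitudes 0.03–0.13 instead of being small (< 1 moment)
  up to 0.07 and degrading sharply beyond 0.09.  Short high-amplitude
  bursts are smoothed out by the leaky integration, as expected — but at
  this scale sustained noise is too, so the transient/sustained contrast
  is weak.
* The combined when+how-long model is exercised at small scale in tests
  and examples (distance-trace error falls below 0.1 log10 units) but is
  not tuned to the interval model's accuracy within the desk budget.
* Sigmoid outputs bound TD at 1, so only onsets ≥ T/10 are representable
  — the generator's first-onset constraint enforces this; multi-scale
  (decade-jumping) time representation is out of scope.
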