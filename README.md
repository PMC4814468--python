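# timesense

A computational model of two basic capacities of temporal cognition:
estimating **how long** events last (interval timing) and remembering
**when** they happened (temporal distance to the present).  The model is a
small modular continuous-time recurrent neural network (CTRNN) that fuses
four noisy sinusoidal "cortical oscillator" channels — the intuition of the
striatal beat frequency account of interval timing — into an internal sense
of time, and is tuned end-to-end by hierarchical cooperative coevolution.

## The model

A session lasts T = 1000 simulation moments and contains six tone events
with random durations below M = 50 moments, at least 100 moments apart.
Inputs per moment: four oscillators `sin(ω_j t + k_j) + U(−a, a)` with
ω = (4, 1, 0.25, 0.1), phases `k_j ~ U[0, π]` per session and noise
a = 0.05; a binary tone line; six one-hot event-id lines.

Neurons are leaky integrators with a shared time constant τ,

    τ dγ_i/dt = −γ_i + Σ_k ws_ik I_k + Σ_m wp_im A_m,     A_i = σ(γ_i − θ_i),

grouped into modules: a recurrently coupled 16-neuron pair tSen1 ⇄ tSen2
(the TimeSense front end; only tSen1 sees the oscillators), and six
2-neuron duration modules fed by tSen2, the tone and the id lines.  The
extended "when + how-long" architecture adds 16-neuron tDuration and
tDistance hubs and six 2-neuron distance modules.

Each duration module *i* must reproduce a ramp target

    D_i(t) = 0 (t < st_i),  (t − st_i)/M (during),  (e_i − st_i)/M (after),

so an event of duration 42 plateaus at 42/50 = 0.84; each distance module
must reproduce the base-10 logarithmic temporal distance

    TD_i(t) = log10(t / st_i)   for t > st_i,

so an event that started at moment 443 reads 0.353 at moment 1000, i.e.
557 moments in the past.  Module performance is the summed squared tracking
error E; fitness is 1000/E per event module, the product of event fitnesses
for each hub, and the product of both branch products for the TimeSense
root — one population of chromosomes (flat weight+bias vectors) per module,
top-20% selection, single-point crossover, 2% per-gene mutation of ±10%.

Duration is decoded by inverting the ramp code (M × the mean output over
the 10 moments after the event ends); temporal distance by inverting the
log code (the event lies `t·(1 − 10^−out)` moments back).

## A worked example

`examples/01_stimuli_and_targets.py` builds one random session and prints
its target codes:

```
event schedule (start, end, duration):
  event 1:  103 ..  147  (44 moments)
  ...
event 3 duration target plateau: 0.600  (= duration 30 / M 50)
event 3 temporal distance at t=999: 0.377  (= log10(999/419); decodes to 580 moments back)
```

The plateau is the duration normalised by the maximum M; the distance
output, pushed through the inverse log code, says how many moments ago the
event started.  `examples/03_evolve_small.py` runs a one-minute
coevolution and decodes a held-out session:

```
validation mean |duration error| (moments) every 10 generations:
0     18.61
...
40    12.82
```

and `examples/04_extend_to_when.py` lifts a trained interval model into
the combined architecture (new links start at zero, so behaviour is
preserved exactly) and retrains briefly:

```
stage 2 (when + how-long) distance error, first -> last generation: 0.544 -> 0.096 (log10 units)
```

At the scaled profile used for acceptance (48 chromosomes per hub module,
1024 per event module, 300 generations, ~8 minutes on one CPU) the decoded
duration error on held-out random sessions falls to ~3 moments.

There is also a thin CLI: `timesense evolve|extend|simulate|eval-scalar|
eval-noise|report` (see `timesense --help`), which writes genomes,
traces and Table-style CSV reports.

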