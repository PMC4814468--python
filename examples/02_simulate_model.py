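"""Assemble an interval-timing model and run a session through it.

Uses small random genomes (an untrained network) to show the mechanics:
module layout, the synchronous whole-model update, and the plateau
readout that decodes a duration estimate for every event.  An untrained
model produces poor estimates; see 03_evolve_small.py for tuning.
"""

import numpy as np

import timesense as ts

spec = ts.interval_timing_model()
print(f"model '{spec.name}': {len(spec.modules)} modules, "
      f"{spec.n_neurons} neurons, {spec.total_parameters} parameters")
for m in spec.modules[:3]:
    print(f"  {m.name}: {m.n_neurons} neurons, ext channels {m.ext_channels},"
          f" afferents {m.afferents}")
print("  ...")

rng = np.random.default_rng(1)
genomes = {m.name: rng.normal(0, 0.5, spec.genome_length(m.name))
           for m in spec.modules}
model = ts.AssembledModel(spec, genomes)

sched = ts.generate_schedule(rng)
bank = ts.OscillatorBank.random(rng)
session = ts.render_session(sched, bank, rng)
trace = model.run_session(session)

print("\nuntrained duration estimates (plateau readout, M x mean output"
      " over 10 moments after each event):")
for i in range(sched.n_events):
    est = ts.read_duration(trace, i, sched)
    print(f"  event {i+1}: true {sched.durations[i]:2d}, decoded {est:5.1f}")
print("estimates are far off because the genomes are random noise.")
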