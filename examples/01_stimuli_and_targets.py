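"""Generate one stimulus session and its target traces.

Builds a random 6-event session (noisy oscillators, tone, one-hot event
ids), prints the schedule, and evaluates the two target codes at the
moments of interest: the ramp-coded duration plateau and the base-10
logarithmic temporal distance seen from the end of the session.
"""

import numpy as np

import timesense as ts

rng = np.random.default_rng(0)
sched = ts.generate_schedule(rng)
bank = ts.OscillatorBank.random(rng)
session = ts.render_session(sched, bank, rng)

print("event schedule (start, end, duration):")
for i in range(sched.n_events):
    print(f"  event {i+1}: {sched.starts[i]:4d} .. {sched.ends[i]:4d}"
          f"  ({sched.durations[i]} moments)")

print(f"\ntone active {session.tone.sum()} of {session.horizon} moments")
print(f"oscillator range [{session.osc.min():.3f}, {session.osc.max():.3f}]"
      " (|sin| + uniform noise 0.05)")

i = 2
st, e = int(sched.starts[i]), int(sched.ends[i])
plateau = ts.duration_target(e + 100, st, e, sched.max_duration)
td = ts.distance_target(999, st)
print(f"\nevent {i+1} duration target plateau: {plateau:.3f}"
      f"  (= duration {e-st} / M {sched.max_duration})")
print(f"event {i+1} temporal distance at t=999: {td:.3f}"
      f"  (= log10(999/{st}); decodes to {999*(1-10**(-td)):.0f} moments back)")
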