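"""Simulate force-clamp unfolding traces and detect their steps.

Generates a small 40 pN constant-force ensemble from the default
six-element unfolding network (five beta-strands + ordered loop, ~19 nm of
total extension at 40 pN), runs the step detector, and prints the per-trace
step pattern.  The step lengths are the extension gained at each unfolding
event; their per-trace sum is the total unfolding length.
"""

import mechpath as mp

network = mp.default_network()
cfg = mp.SimConfig(force=40.0, n_traces=6, duration=10.0, noise_sd=0.5)
traces, truth = mp.generate_ensemble(network, cfg, seed=8)

params = mp.DetectorParams(min_step=2.0, min_dwell=0.05)
print(f"total extension at 40 pN: {network.total_length_at(40.0):.2f} nm\n")
for trace in traces:
    events = mp.detect_steps(trace, params)
    steps = " + ".join(f"{e.step_length:.1f}" for e in events)
    total = events[-1].cumulative_length if events else 0.0
    n_int = max(len(events) - 1, 0)
    print(
        f"{trace.trace_id}: {len(events)} step(s) [{steps}] nm, "
        f"total {total:.1f} nm, {n_int} intermediate(s)"
    )
print(
    "\nSingle-step traces unfold in one sweep; multi-step traces pause in "
    "partially unfolded intermediates of ~3 nm multiples."
)
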