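"""Detect population bursts in simulated sleep and decode one of them.

During sleep only the context cue drives the network, yet recurrent
cluster structure generates spontaneous population burst events (PBEs).
Each decodable burst (>= 5 cells, >= 50 ms) is decoded in 10 ms bins with
a memoryless Bayesian decoder using the place fields from the run session;
the weighted space-time correlation r measures how linear the decoded
trajectory is, the maximum jump how continuous, and the entropy how
concentrated the posterior.
"""

import numpy as np

from clusterplay import RunConfig, build_network, simulate_run_trials, simulate_sleep
from clusterplay.decode import decode_event, decode_stats
from clusterplay.events import detect_pbes, population_rate
from clusterplay.placefield import compute_rate_map

config = RunConfig(seed=1)
net = build_network(config)
fields = compute_rate_map(simulate_run_trials(net, 0, "left"), config.analysis)

sleep = simulate_sleep(net, duration=60.0)
trace = population_rate(sleep, config.analysis)
pbes = detect_pbes(trace, sleep, config.analysis)
print(f"sleep population rate: mean {trace.mean:.2f} Hz, sd {trace.sd:.2f} Hz "
      f"(threshold {trace.mean + trace.sd:.2f} Hz)")
print(f"{len(pbes)} PBEs in 60 s; {len(pbes.decodable())} decodable")

event = max(pbes.decodable(), key=lambda e: e.duration)
post = decode_event(sleep, event, fields, config.analysis)
stats = decode_stats(post.p)
print(f"longest event: {event.duration * 1e3:.0f} ms, {event.n_cells} cells, "
      f"{post.n_time_bins} time bins")
print(f"decoded |r| = {stats.abs_r:.2f}, max jump = {stats.max_jump:.2f} of "
      f"track, mean entropy = {stats.entropy:.2f} bits (uniform would be "
      f"{np.log2(50):.2f})")
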