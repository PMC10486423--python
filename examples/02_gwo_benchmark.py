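"""Gray wolf optimizer on an analytic benchmark.

Runs the canonical GWO on the 5-D sphere function and prints the best-so-far
fitness at a few points of the trace; the monotone decay toward 0 shows the
alpha/beta/delta-guided pack converging on the optimum.
"""

from lesionselect.gwo import GWOConfig, optimize, sphere

config = GWOConfig(n_wolves=30, n_iterations=300, bounds=(-5.12, 5.12), seed=3)
result = optimize(config, dim=5, objective=sphere, sense="minimize")

for t in (0, 50, 100, 200, 300):
    print(f"iteration {t:>3}: best fitness {result.trace[t]:.3e}")
print(f"best position: {result.best_position.round(6)}")
# The sphere minimum is 0 at the origin; the final fitness shows how close
# the pack gets within the iteration budget.
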