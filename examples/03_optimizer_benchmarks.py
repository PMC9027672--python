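"""Convergence of the two swarm optimizers on analytic benchmarks.

Runs EPO and MLO on the 5-D sphere and the shifted quadratic, printing
the best fitness found; both should be near the analytic minimum of 0.
"""

from pentumor import EPOParams, MLOParams, benchmark_objectives, epo_optimize, mlo_optimize

suite = benchmark_objectives(5)
for name in ("sphere", "shifted_quadratic"):
    obj = suite[name]
    r_epo = epo_optimize(obj, EPOParams(max_iterations=500, seed=0))
    r_mlo = mlo_optimize(obj, MLOParams(max_iterations=200, seed=0))
    print(f"{name:18s}  EPO best={r_epo.best_fitness:.3e}  "
          f"MLO best={r_mlo.best_fitness:.3e}")
print("both columns should be ~0: the analytic minimum of each objective; "
      "the best-so-far traces are non-increasing by construction")
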