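"""The metaheuristic core on standard benchmarks.

Minimizes the 5-D sphere and rastrigin functions with alternating
jellyfish-search and walrus-optimization steps; greedy acceptance makes
the best-fitness history monotone.
"""

from mitodet import SearchBounds, benchmark_objective, hybrid_minimize

for name in ("sphere", "rastrigin"):
    objective, lb, ub, x_opt, f_opt = benchmark_objective(name, 5)
    state, history = hybrid_minimize(
        objective, SearchBounds(lb, ub), n=30, iterations=200, seed=3
    )
    print(f"{name:10s} known optimum {f_opt:.1f}  "
          f"found {state.best_fitness:.3e}  "
          f"(iteration 1: {history[0]:.2f}, monotone: "
          f"{all(b <= a for a, b in zip(history, history[1:]))})")
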