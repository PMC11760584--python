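"""Escape Coati Optimization Algorithm vs the plain-COA baseline.

Both run a population of 50 for 10 iterations (the budget also used for
hyperparameter tuning). The escape variant adds a per-coati escape
probability with a Levy-flight retry, which helps on multimodal
objectives such as Rastrigin.
"""

import numpy as np

from inkpd.ecoa import OBJECTIVES, SearchSpace, minimize

space = SearchSpace(np.array([-5.0, -5.0]), np.array([5.0, 5.0]))

for name in ("sphere", "rastrigin"):
    print(f"\n{name} (m=2, N=50, T=10, median over 10 seeds):")
    for variant in ("coa", "ecoa"):
        fits = [minimize(OBJECTIVES[name], space, n_coatis=50,
                         n_iterations=10, seed=s, variant=variant).best_fitness
                for s in range(10)]
        print(f"  {variant:5s} median best fitness = {np.median(fits):.3e}")

res = minimize(OBJECTIVES["rastrigin"], space, 50, 10, seed=0)
print("\necoa best-so-far trajectory (monotone non-increasing):")
print("  " + "  ".join(f"{v:.2e}" for v in res.trajectory))
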