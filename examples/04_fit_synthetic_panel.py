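"""Parameter recovery on a synthetic nine-inhibitor panel.

Generates a 9-drug x 7-dose max-normalized dose–response panel from known
unified-model parameters (three inhibitor archetypes, 5% multiplicative
noise), fits it with the multi-start protocol (shared autoinhibition
constant, per-drug K_d/f/g), and compares recovered values with the
ground truth. Uses a reduced start count so the example runs in ~a minute;
the acceptance pipeline uses 100 starts.
"""

import numpy as np

from rafpa import identifiability_report, make_panel, multistart_fit, simulate_responses

panel = simulate_responses(make_panel(seed=1), noise_cv=0.05, seed=2)
problem = panel.to_fit_problem()

result = multistart_fit(problem, n_starts=20, seed=3)
bp = result.best_params()

print(f"best fit metric (mean sq. rel. dev.): {result.best_metric:.3e}")
print(f"ensemble size (within 10% of best)  : {result.n_members}/{result.n_starts}")
print(f"\nshared K_A: recovered {bp['K_A']:.3f}  (truth {panel.shared['K_A']})\n")
print(f"{'drug':>10} {'K_d fit':>9} {'K_d true':>9} {'f fit':>8} {'f true':>8}")
for i, drug in enumerate(panel.drugs):
    t = panel.ground_truth[i]
    print(f"{drug:>10} {bp[drug + ':K_d']:9.4f} {t.K_d:9.4f} "
          f"{bp[drug + ':f']:8.4f} {t.f:8.4f}")

rep = identifiability_report(result)
wide = rep.summary[rep.summary["cv"] > 1.0]["parameter"].tolist()
print(f"\nweakly constrained parameters (ensemble CV > 1): {wide}")
# K_d and f come back near truth and cluster by archetype; the g values
# (negative cooperativity) are typically in the weakly constrained list —
# the 7-point curves carry little information about the second dimer
# binding site once it is strongly disfavored.
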