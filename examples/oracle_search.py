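"""The automata team solving a known, enumerable reward table.

A 3-automaton x 4-action "single-peak" oracle rewards one joint action far
above the rest.  The team (a = b = 0.5, 30% exploration) searches it; the
printed best joint action should equal the table's known optimum, and the
best quality should be the table's peak, 0.95.  Because evaluation is a
table lookup, this runs in well under a second — it is how the search loop
is tested without any neural training.
"""

import numpy as np

from neoseg import LearningAutomaton, make_oracle_table, run_search

env = make_oracle_table(3, [4, 4, 4], structure="single-peak", seed=7)
team = [LearningAutomaton(4, 0.5, 0.5, 0.3) for _ in range(3)]
best, state = run_search(env, team, T=500, K=500, rng=np.random.default_rng(7))

print("known optimum :", env.known_optimum)
print("search best   :", tuple(best), f"quality {state.best_quality:.3f}")
print("found at iter :", state.best_iteration, "| stopped:", state.stop_reason)
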