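"""How a learning automaton's probability vector reacts to feedback.

Builds a 3-action automaton with reward/penalty steps a = b = 0.5, applies
one reward and one penalty, and prints the vector after each update.  The
rewarded action's mass moves halfway to 1; a penalty halves the chosen
action's mass and spreads the remainder evenly over the other actions.
The vector stays a probability distribution throughout.
"""

import numpy as np

from neoseg import LearningAutomaton

la = LearningAutomaton(n_actions=3, reward_coeff=0.5, penalty_coeff=0.5)
print("initial:        ", la.probabilities)

la.apply_reward(2)
print("after reward(2):", la.probabilities, " sum =", la.probabilities.sum())

la.apply_penalty(2)
print("after penalty(2):", np.round(la.probabilities, 4),
      " sum =", la.probabilities.sum())

rng = np.random.default_rng(0)
choice = la.select_action(rng)
print(f"selected action {choice} (30% uniform exploration by default)")
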