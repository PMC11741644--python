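"""End-to-end configuration search at desk scale.

The full pipeline: 21 automata (19 convolution automata with 375 actions
each, 2 pooling automata) propose genotypes; each candidate CNN is trained
for 2 epochs on six 16x16 phantoms and scored by mean validation Dice over
CSF/GM/WM; reward/penalty updates steer the team.  Six iterations keep the
run to a couple of minutes on one CPU.  The printed best genotype is the
configuration the search would hand to a longer training run.
"""

import numpy as np

from neoseg import (
    PhantomSpec,
    TrainingSettings,
    assemble_configuration,
    generate_dataset,
    make_cnn_automata,
    make_cnn_environment,
    run_search,
)

dataset = generate_dataset(8, PhantomSpec(shape=(16, 16), seed=0), seed=0)
settings = TrainingSettings(max_epochs=2, patience_epochs=2, batch_size=4,
                            patch_shape=(16, 16), seed=0)
env = make_cnn_environment(dataset[:6], dataset[6:], settings, spatial_rank=2)
team = make_cnn_automata()  # a = b = 0.5, 30% exploration

best, state = run_search(env, team, T=6, K=6, rng=np.random.default_rng(0))

config = assemble_configuration(best[:19], best[19:])
print(f"best mean validation Dice {state.best_quality:.4f} "
      f"at iteration {state.best_iteration} ({state.stop_reason})")
print("pooling:", [p.name for p in config.pooling_actions])
print("first encoder block:",
      [a.as_tuple() for a in config.conv_actions[:3]])
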