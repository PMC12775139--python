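"""Decision rules on a worked example.

Hard switching commits to the most probable frustration state's MI model;
probabilistic fusion weights all three MI outputs by the state probability
vector.  With an ambiguous state estimate the two can disagree.
"""

import numpy as np

from frustmi import fuse_hard, fuse_soft

p_f = np.array([0.40, 0.38, 0.22])  # low / medium / high frustration
per_state_mi = np.array([
    [0.30, 0.70],  # low-state model: leans right
    [0.80, 0.20],  # medium-state model: leans left
    [0.75, 0.25],  # high-state model: leans left
])

hard = fuse_hard(p_f, per_state_mi)
soft = fuse_soft(p_f, per_state_mi)

print(f"state probabilities      : {p_f}")
print(f"hard switch  -> state {hard.s_hat}, MI probabilities {hard.p_final}, "
      f"decision {hard.y_hat}")
print(f"soft fusion  -> MI probabilities {np.round(soft.p_final, 3)}, "
      f"decision {soft.y_hat}")
print()
print("Hard switching trusts only the (barely) most probable low state, so it")
print("answers 'right'; fusion lets the medium/high models, which jointly")
print("carry 60% of the probability mass, pull the decision to 'left'.")
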