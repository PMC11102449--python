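"""Global sensitivity ranking and identifiability screen, reduced scale.

Latin-hypercube samples model parameters within +/-50% of their defaults,
runs the untreated model on a 60x60 grid for 3 days, and ranks parameters
by the partial rank correlation (PRCC) between parameter and mean tumor
volume.  The analysis uses the raw absolute-level modulation form
(reference levels zeroed), in which the adenosine parameters dominate:
production (beta), elimination (r) and the adenosine->tumor coupling
(r_At) should take the top ranks, while gamma (the siRNA effect) is inert
without treatment and serves as a built-in null check.  Then a
finite-difference identifiability screen checks that no parameter pair
has |sensitivity correlation| >= 0.9 across all outputs.
"""

import tmesim as tm
from tmesim.analysis import global_sensitivity, identifiability

params = tm.make_default_parameters().replace(
    N=60, N_D=20, N_T=150, hypoxia_ref=0.0, adenosine_ref=0.0)
names = ["beta", "r", "r_At", "a", "gamma", "r_Ht", "P_tumor", "f_bar"]

ranking = global_sensitivity(params, names, rel_range=0.5, n_samples=80,
                             seed=0, replicates_per_sample=2, horizon_days=3)
print(ranking.to_string(index=False))
print("\n|PRCC| near 1 = strong monotone influence on tumor burden;")
print("gamma's near-zero index confirms the null-parameter control.\n")

screen = identifiability(params, ["beta", "r", "r_At", "a", "f_bar", "mu"],
                         delta=0.1, seed=0, horizon_days=3, replicates=2)
print("non-identifiable pairs (|corr| >= 0.9 in every output):",
      screen.non_identifiable_pairs or "none")
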