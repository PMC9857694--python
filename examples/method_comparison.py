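"""Compare EMA against plain EM and the random baseline across observed
fractions.

Sweeps the observed node fraction c over {0.3, 0.5, 0.7} with 5 paired
repetitions per cell (every method scores the identical partial
observation) and prints the pooled mean MCC and G-mean per method and c.
"""

from emaplex import SynthSpec, generate_multiplex, run_sweep

net, _ = generate_multiplex(SynthSpec(150, 2, ("poisson", 3.0), 0.7, rng_seed=5))
result = run_sweep(net, c_grid=[0.3, 0.5, 0.7], reps=5, master_seed=17)

agg = result.aggregate()
pooled = agg[agg["layer"] == "all"]
cols = ["method", "c", "mcc_mean", "mcc_std", "gmean_mean", "iterations_mean"]
print(pooled[cols].to_string(index=False, float_format=lambda v: f"{v:.3f}"))
print()
print("EMA's advantage comes from the aggregation step: a link witnessed")
print("in one layer is Bayesian evidence for the same pair in the others.")
print("The random model (rm) centers on MCC 0 by construction; its listed")
print("iteration count is 0 because it performs no inference.")
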