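"""Twin-experiment calibration: recover known parameters from noisy data.

Observations are sampled from a known truth, then the adaptive-Metropolis
sampler (3 chains, here 30k proposals each for a quick demonstration;
raise --proposals for production) explores the 28-dimensional posterior.
The printed intervals should bracket the truth for well-constrained
quantities.
"""

import fenfusion as ff
from fenfusion import calibration as cal, dalec

drivers = ff.generate_drivers()
truth = ff.generate_truth(drivers=drivers)
obs = ff.sample_observations(truth, seed=3)

config = cal.McmcConfig(n_chains=3, n_proposals=30_000, seed=3)
chains = ff.run_mcmc(obs, drivers, config=config)
ensemble = ff.extract_ensemble(chains, per_chain=100)

print(f"posterior ensemble: {len(ensemble)} members "
      f"({config.n_chains} chains x 100 subsamples)")
print("acceptance rates:",
      ", ".join(f"{r:.2f}" for r in chains.acceptance_rates))

reg = dalec.default_registry()
print(f"\n{'quantity':12s} {'truth':>10s} {'median':>10s} "
      f"{'2.5%':>10s} {'97.5%':>10s}  in 95% CI?")
for name in ("f_auto", "c_eff", "theta", "r_som", "lma", "big_f_fall"):
    true_val = reg.defaults[reg.index(name)]
    lo, hi = ensemble.interval(name)
    med = ensemble.median(name)
    print(f"{name:12s} {true_val:10.4g} {med:10.4g} {lo:10.4g} {hi:10.4g}  "
          f"{'yes' if lo <= true_val <= hi else 'no'}")
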