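"""Sample the noisy observation streams a flux tower and satellite provide.

The truth trajectory is perturbed with the published stream uncertainties
(NEE 0.58, Reco 1.0 gC m-2 d-1, LAI 20% floored at 0.5 m2 m-2), LAI is
restricted to its April-September availability window, and alternate years
are flagged for assimilation versus validation.
"""

import numpy as np

import fenfusion as ff

drivers = ff.generate_drivers()
truth = ff.generate_truth(drivers=drivers)
obs = ff.sample_observations(truth, seed=7)

print(f"weeks: {obs.n_weeks}; assimilated: {obs.assimilate.sum()} "
      f"(years 2014/16/18/20), validation: {(~obs.assimilate).sum()}")
print(f"LAI present in {obs.lai_present.sum()} weeks "
      "(ISO weeks 14-39, the April-September retrieval window)")
print(f"NEE residual s.d. {np.std(obs.nee - truth.flux('nee')):.3f} "
      f"(sigma = {obs.nee_sigma[0]})")
print(f"Reco residual s.d. {np.std(obs.reco - truth.flux('reco')):.3f} "
      f"(sigma = {obs.reco_sigma[0]})")
print("stock observations (gC m-2):")
for s in obs.stocks:
    print(f"  {s.pool:12s} {s.value:9.1f} +/- {s.sigma:.1f}")
print("a perfect model scores log-likelihood "
      f"{ff.log_likelihood(truth, ff.sample_observations(truth, seed=0, zero_noise=True)):.2f}")
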