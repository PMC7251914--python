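"""Model evaluation: nonparametric bootstrap and visual predictive check.

The bootstrap resamples studies with replacement and refits, giving
percentile intervals that should agree with the Wald intervals of the
original fit.  The VPC simulates replicate datasets on the observed
design and checks that observed quantiles per visit week sit inside
their simulated 95% bands (they should, since the data were generated
by the same model family).
"""

from adprog import bootstrap, default_config, final_model_spec, fit, \
    generate_trial_set, vpc

trials, _ = generate_trial_set(default_config(seed=11, n_studies=60))
spec = final_model_spec(trials)
result = fit(trials, spec, seed=11)

boot = bootstrap(trials, spec, B=100, seed=11, reference_fit=result)
print(f"bootstrap: {boot.n_converged}/{boot.n_requested} replicates converged")
print(boot.summary.to_string(index=False))

check = vpc(trials, result, n_sim=500, seed=11)
print("\nVPC band coverage per observed quantile "
      "(fraction of time bins inside the simulated 95% band):")
print(check.coverage())
print(check.table[["bin_time", "n_obs", "obs_med", "sim_med_low",
                   "sim_med_high"]].to_string(index=False))
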