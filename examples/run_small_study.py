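"""A reduced-replication run of the full simulation study.

Uses the complete 30-configuration grid (c in {0.60, 0.75, 0.90},
tau2/tau1 in {0.5 ... 2.0}, 50 photons per dataset) at 20 replicates per
configuration and prints the per-method summary: failure proportions,
5th/50th/95th quantiles of tau2_hat/tau2 over the datasets where both
methods delivered an estimate, and the 100 ns-capped mean squared error in
ns^2.  Raise n_reps to 1000 for the full design (minutes, not hours).
"""

from decayfit import StudyConfig, run_study

cfg = StudyConfig(n_reps=20, seed=1, hellinger_n=2000)
result = run_study(cfg)

print(result.summary().to_string(float_format=lambda v: f"{v:.4g}"))
print(
    "\nreading: the direct fit fails far more often and its surviving "
    "tau2_hat spread is far wider (q95) and costlier (capped MSE) than the "
    "gamma-conversion path's."
)
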